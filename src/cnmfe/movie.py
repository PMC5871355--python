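"""Movie containers, TIFF/HDF5 readers and writers, and decimation.

The in-memory contract used throughout the package is a pixels-by-frames
matrix: frames are flattened row-major, so pixel ``i`` of a ``(height,
width)`` field of view sits at ``(i // width, i % width)``.  Intensities are
stored as 32-bit floats (lossless for 16-bit acquisition data).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile

__all__ = ["Movie", "load_movie", "save_movie", "decimate", "save_results", "load_results"]


@dataclass
class Movie:
    """A motion-corrected fluorescence movie.

    Parameters
    ----------
    data : ndarray, shape (d, T)
        Pixel-by-frame intensity matrix, row-major flattened frames.
    fov_shape : tuple of int
        Field-of-view ``(height, width)`` in pixels; ``d = height * width``.
    frame_rate : float, optional
        Acquisition rate in frames per second (metadata only).
    """

    data: np.ndarray
    fov_shape: tuple
    frame_rate: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        h, w = self.fov_shape
        self.fov_shape = (int(h), int(w))
        if self.data.ndim != 2:
            raise ValueError("movie data must be 2-D (pixels x frames)")
        if self.data.shape[0] != h * w:
            raise ValueError(
                f"pixel count {self.data.shape[0]} does not match fov {self.fov_shape}"
            )
        if self.data.shape[1] < 1:
            raise ValueError("movie must contain at least one frame")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def frames(self) -> np.ndarray:
        """Return a (T, height, width) view of the data."""
        h, w = self.fov_shape
        return self.data.T.reshape(self.data.shape[1], h, w)

    @classmethod
    def from_frames(cls, frames: np.ndarray, frame_rate: float | None = None) -> "Movie":
        frames = np.asarray(frames)
        if frames.ndim != 3:
            raise ValueError("frame stack must be 3-D (frames, height, width)")
        t, h, w = frames.shape
        data = frames.reshape(t, h * w).T
        return cls(data=data, fov_shape=(h, w), frame_rate=frame_rate)


def load_movie(path: str, fmt: str | None = None, dataset: str | None = None) -> Movie:
    """Load a movie from a multi-page grayscale TIFF or an HDF5 stack.

    Parameters
    ----------
    path : str
        File path.
    fmt : {"tiff", "hdf5"}, optional
        Forced format; inferred from the extension when omitted.
    dataset : str, optional
        Name of the 3-D dataset inside an HDF5 file.  When omitted the first
        3-D dataset found is used.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"file not found: {path}")
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = "hdf5" if ext in (".h5", ".hdf5", ".hdf") else "tiff"
    if fmt == "tiff":
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise ValueError(f"expected grayscale pages, got array of shape {frames.shape}")
    elif fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if dataset is None:
                names = []
                f.visititems(
                    lambda name, obj: names.append(name)
                    if isinstance(obj, h5py.Dataset) and obj.ndim == 3
                    else None
                )
                if not names:
                    raise ValueError(f"no 3-D dataset found in {path}")
                dataset = names[0]
            frames = f[dataset][:]
        if frames.ndim != 3:
            raise ValueError(f"dataset {dataset!r} is not 3-D")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return Movie.from_frames(np.asarray(frames, dtype=np.float32))


def save_movie(movie: Movie, path: str, dataset: str = "movie") -> None:
    """Write a movie as multi-page TIFF or HDF5 (frames-first layout)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "w") as f:
            f.create_dataset(dataset, data=movie.frames())
            if movie.frame_rate is not None:
                f[dataset].attrs["frame_rate"] = movie.frame_rate
    else:
        tifffile.imwrite(path, movie.frames(), photometric="minisblack")


def _reduceat_mean(x: np.ndarray, factor: int, axis: int) -> np.ndarray:
    """Non-overlapping block means along one axis; trailing partial blocks
    are averaged over their actual extent."""
    n = x.shape[axis]
    starts = np.arange(0, n, factor)
    sums = np.add.reduceat(x, starts, axis=axis)
    counts = np.minimum(starts + factor, n) - starts
    shape = [1] * x.ndim
    shape[axis] = len(starts)
    return sums / counts.reshape(shape)


def decimate(movie: Movie, spatial_factor: int = 1, temporal_factor: int = 1) -> Movie:
    """Downsample a movie by non-overlapping block averaging.

    Blocks are ``spatial_factor x spatial_factor`` in space and
    ``temporal_factor`` frames in time; trailing partial blocks are averaged
    over their actual extent so the total duration is preserved.
    """
    if spatial_factor < 1 or temporal_factor < 1:
        raise ValueError("decimation factors must be >= 1")
    h, w = movie.fov_shape
    if spatial_factor > min(h, w) or temporal_factor > movie.n_frames:
        raise ValueError("decimation factor exceeds movie extent")
    if spatial_factor == 1 and temporal_factor == 1:
        return Movie(movie.data.copy(), movie.fov_shape, movie.frame_rate)
    frames = movie.frames().astype(np.float64)
    frames = _reduceat_mean(frames, temporal_factor, axis=0)
    frames = _reduceat_mean(frames, spatial_factor, axis=1)
    frames = _reduceat_mean(frames, spatial_factor, axis=2)
    rate = movie.frame_rate / temporal_factor if movie.frame_rate else None
    return Movie.from_frames(frames.astype(np.float32), frame_rate=rate)


def save_results(model, background, path: str, config: dict | None = None,
                 log: list | None = None) -> None:
    """Write fitted results to HDF5.

    Datasets: ``A`` (d x K footprints), ``C`` (K x T denoised traces),
    ``S`` (K x T deconvolved activity), ``C_raw`` (K x T projected traces),
    ring weights ``W`` as sparse triplets (``W_row``/``W_col``/``W_data``
    plus the dense shape), baseline ``b0`` (d), a YAML snapshot of the
    configuration and the intervention log.
    """
    import scipy.sparse as sp
    import yaml

    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=np.asarray(model.A))
        f.create_dataset("C", data=np.asarray(model.C))
        f.create_dataset("S", data=np.asarray(model.S))
        f.create_dataset("C_raw", data=np.asarray(model.C_raw))
        f.create_dataset("b0", data=np.asarray(background.b0))
        W = background.W
        if W is None:
            W = sp.csr_matrix((len(background.b0), len(background.b0)))
        W = sp.coo_matrix(W)
        f.create_dataset("W_row", data=W.row)
        f.create_dataset("W_col", data=W.col)
        f.create_dataset("W_data", data=W.data)
        f.create_dataset("W_shape", data=np.array(W.shape))
        f.attrs["fov_height"], f.attrs["fov_width"] = model.fov_shape
        f.create_dataset("config", data=yaml.safe_dump(config or {}))
        f.create_dataset("log", data=yaml.safe_dump(log or []))


def load_results(path: str) -> dict:
    """Load arrays written by :func:`save_results` back into a dict."""
    import scipy.sparse as sp
    import yaml

    out = {}
    with h5py.File(path, "r") as f:
        for key in ("A", "C", "S", "C_raw", "b0"):
            out[key] = f[key][:]
        shape = tuple(f["W_shape"][:])
        out["W"] = sp.coo_matrix(
            (f["W_data"][:], (f["W_row"][:], f["W_col"][:])), shape=shape
        ).tocsr()
        out["fov_shape"] = (int(f.attrs["fov_height"]), int(f.attrs["fov_width"]))
        out["config"] = yaml.safe_load(f["config"][()])
        out["log"] = yaml.safe_load(f["log"][()])
    return out
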