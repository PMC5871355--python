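"""Footprint updates: support-constrained HALS and morphological cleanup.

Spatial sparsity and locality are enforced structurally: every footprint is
only allowed nonzeros inside a mildly dilated version of its previous
support, updates are projected onto the nonnegative orthant, and a
morphological opening / largest-connected-component mask removes stray
pixels after each round of updates.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

__all__ = ["determine_supports", "update_spatial", "postprocess_footprints"]


def determine_supports(A, fov_shape, dilation_radius: int = 2):
    """Dilate each footprint's nonzero set by a disk, clipped to the FOV.

    Returns a list of per-neuron boolean masks over pixels; an empty
    footprint yields an empty support (the component should be deleted).
    """
    H, W = fov_shape
    selem = disk(dilation_radius) if dilation_radius > 0 else None
    supports = []
    for k in range(A.shape[1]):
        mask = (A[:, k] > 0).reshape(H, W)
        if selem is not None and mask.any():
            mask = ndimage.binary_dilation(mask, structure=selem)
        supports.append(mask.ravel())
    return supports


def update_spatial(Y_tilde, C_tilde, A, supports, n_sweeps: int = 5):
    """HALS sweeps for the footprints at fixed (mean-centred) traces.

    Solves ``min_{A >= 0, supp(a_k) in P_k} ||Y~ - A C~||_F^2`` by
    per-component closed-form coordinate updates; the objective is
    non-increasing at every sweep.

    Parameters
    ----------
    Y_tilde : ndarray (d, T)
        Movie with background and per-pixel temporal means removed.
    C_tilde : ndarray (K, T)
        Mean-centred traces.
    A : ndarray (d, K)
        Current footprints (warm start).
    supports : list of boolean masks
        Allowed pixels per component.
    """
    A = A.astype(np.float64).copy()
    K = A.shape[1]
    if K == 0:
        return A
    U = Y_tilde @ C_tilde.T              # (d, K)
    V = C_tilde @ C_tilde.T              # (K, K)
    energy = np.diag(V)
    order = np.argsort(-energy, kind="stable")
    for _ in range(n_sweeps):
        for k in order:
            if V[k, k] <= 0:
                continue  # dead trace; component flagged upstream
            ak = A[:, k] + (U[:, k] - A @ V[:, k]) / V[k, k]
            ak = np.maximum(ak, 0.0)
            ak[~supports[k]] = 0.0
            A[:, k] = ak
    return A


def postprocess_footprints(A, fov_shape, opening_radius: int = 1):
    """Morphological cleanup of each footprint.

    Binarise at > 0, open with a disk, keep only the largest 8-connected
    component, and zero everything outside that mask.  Returns ``(A, kept)``
    where ``kept`` flags footprints that did not vanish.
    """
    H, W = fov_shape
    A = A.copy()
    kept = np.ones(A.shape[1], dtype=bool)
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    for k in range(A.shape[1]):
        img = A[:, k].reshape(H, W)
        mask = img > 0
        if not mask.any():
            kept[k] = False
            continue
        # edge-pad so footprints touching the border are not eroded away
        rpad = max(opening_radius, 1)
        padded = np.pad(mask, rpad, mode="edge")
        opened = ndimage.binary_opening(padded, structure=disk(opening_radius))
        opened = opened[rpad:-rpad, rpad:-rpad]
        if not opened.any():
            kept[k] = False
            A[:, k] = 0.0
            continue
        labels, n = ndimage.label(opened, structure=structure)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
            keep_label = int(np.argmax(sizes)) + 1
            opened = labels == keep_label
        img = np.where(opened, img, 0.0)
        if not np.any(img > 0):
            kept[k] = False
        A[:, k] = img.ravel()
    return A, kept
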