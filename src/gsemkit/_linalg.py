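"""Small linear-algebra helpers shared across the package.

The half-vectorization convention used everywhere (LDSC sampling matrix V,
DWLS objective, per-SNP expansion) is column-major over the lower triangle:
for a k x k symmetric matrix the entry order is
(0,0), (1,0), ..., (k-1,0), (1,1), (2,1), ..., (k-1,k-1).
"""

from __future__ import annotations

import numpy as np


def vech_indices(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column index arrays of the lower triangle in vech order."""
    rows, cols = [], []
    for j in range(k):
        for i in range(j, k):
            rows.append(i)
            cols.append(j)
    return np.asarray(rows), np.asarray(cols)


def vech(mat: np.ndarray) -> np.ndarray:
    """Half-vectorize a symmetric matrix (lower triangle, column-major)."""
    mat = np.asarray(mat)
    r, c = vech_indices(mat.shape[0])
    return mat[r, c]


def unvech(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vech`."""
    v = np.asarray(v)
    q = v.shape[0]
    k = int(round((np.sqrt(8 * q + 1) - 1) / 2))
    if k * (k + 1) // 2 != q:
        raise ValueError(f"length {q} is not a triangular number")
    out = np.zeros((k, k), dtype=v.dtype)
    r, c = vech_indices(k)
    out[r, c] = v
    out[c, r] = v
    return out


def vech_pair_index(k: int) -> dict[tuple[int, int], int]:
    """Map unordered variable-index pairs to their vech position."""
    r, c = vech_indices(k)
    idx = {}
    for pos, (i, j) in enumerate(zip(r, c)):
        idx[(i, j)] = pos
        idx[(j, i)] = pos
    return idx


def subset_vech_positions(labels_full: list[str], labels_sub: list[str]) -> np.ndarray:
    """Vech positions (in the full frame) of all pairs within a label subset.

    The returned positions are ordered so that V[np.ix_(pos, pos)] is the
    sampling covariance of vech(S_sub) with S_sub = S[sub, sub] in
    ``labels_sub`` order.
    """
    full_idx = {lab: i for i, lab in enumerate(labels_full)}
    missing = [lab for lab in labels_sub if lab not in full_idx]
    if missing:
        raise KeyError(f"labels not in covariance estimate: {missing}")
    pair_idx = vech_pair_index(len(labels_full))
    ksub = len(labels_sub)
    r, c = vech_indices(ksub)
    pos = [pair_idx[(full_idx[labels_sub[i]], full_idx[labels_sub[j]])]
           for i, j in zip(r, c)]
    return np.asarray(pos)


def nearest_psd(mat: np.ndarray, eig_floor: float = 1e-8) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix onto the PSD cone via an eigenvalue floor.

    Returns the smoothed matrix and the maximum absolute perturbation of any
    entry (0.0 when the input already satisfies the floor).
    """
    mat = np.asarray(mat, dtype=float)
    sym = (mat + mat.T) / 2.0
    w, u = np.linalg.eigh(sym)
    if w.min() >= eig_floor:
        return sym, 0.0
    w_clipped = np.clip(w, eig_floor, None)
    smoothed = (u * w_clipped) @ u.T
    smoothed = (smoothed + smoothed.T) / 2.0
    return smoothed, float(np.abs(smoothed - sym).max())
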