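"""Pedigree and genomic relationship matrices, and IBD-based inbreeding.

The numerator relationship matrix A is built by the tabular method (parents
precede offspring; unknown parents are treated as unrelated, non-inbred
base animals).  Its sparse inverse uses Henderson's rules with inbreeding
accounted for.  The genomic matrix G is VanRaden method 1, centered at the
known base-population allele frequencies and blended with a small weight of
A for guaranteed invertibility.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "build_A",
    "extend_A",
    "inbreeding_from_A",
    "build_A_inverse",
    "build_G",
    "true_inbreeding",
]

UNKNOWN = -1


def _check_ordered(sire: np.ndarray, dam: np.ndarray) -> None:
    n = sire.size
    idx = np.arange(n)
    if np.any(sire >= idx) or np.any(dam >= idx):
        raise ValueError("pedigree must be sorted with parents before offspring")
    if np.any((sire < UNKNOWN)) or np.any(dam < UNKNOWN):
        raise ValueError("parent codes must be >= -1")


def build_A(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Tabular-method numerator relationship matrix.

    ``sire[i]``/``dam[i]`` are row indices of animal ``i``'s parents, or -1
    if unknown.  Animals must be ordered so parents precede offspring.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    _check_ordered(sire, dam)
    n = sire.size
    a = np.zeros((n, n))
    return extend_A(a[:0, :0], sire, dam)


def extend_A(
    a_prev: np.ndarray, sire: np.ndarray, dam: np.ndarray
) -> np.ndarray:
    """Grow a tabular A for an extended pedigree.

    ``a_prev`` is the relationship matrix of the first ``m`` animals of the
    pedigree; rows ``m..n-1`` are appended using the tabular recurrence.
    Passing an empty ``a_prev`` builds A from scratch.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    _check_ordered(sire, dam)
    n = sire.size
    m = a_prev.shape[0]
    a = np.zeros((n, n))
    a[:m, :m] = a_prev
    for i in range(m, n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * a[s, :i]
        if d != UNKNOWN:
            row += 0.5 * a[d, :i]
        a[i, :i] = row
        a[:i, i] = row
        diag = 1.0
        if s != UNKNOWN and d != UNKNOWN:
            diag += 0.5 * a[s, d]
        a[i, i] = diag
    return a


def inbreeding_from_A(a: np.ndarray) -> np.ndarray:
    return np.diag(a) - 1.0


def build_A_inverse(
    sire: np.ndarray, dam: np.ndarray, inbreeding: np.ndarray | None = None
) -> sp.csr_matrix:
    """Henderson's sparse inverse of A, with inbreeding accounted for.

    If ``inbreeding`` is omitted it is computed via the tabular method
    (quadratic in pedigree size but fine at the scales used here).
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    _check_ordered(sire, dam)
    n = sire.size
    if inbreeding is None:
        inbreeding = inbreeding_from_A(build_A(sire, dam))
    f = np.concatenate([np.asarray(inbreeding, dtype=float), [0.0]])  # F[-1] for unknown

    rows, cols, vals = [], [], []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        # Mendelian-sampling variance given known parents
        var = 1.0
        if s != UNKNOWN:
            var -= 0.25 * (1.0 + f[s])
        if d != UNKNOWN:
            var -= 0.25 * (1.0 + f[d])
        w = 1.0 / var
        add(i, i, w)
        for p in (s, d):
            if p != UNKNOWN:
                add(i, p, -0.5 * w)
                add(p, i, -0.5 * w)
        for p in (s, d):
            for q in (s, d):
                if p != UNKNOWN and q != UNKNOWN:
                    add(p, q, 0.25 * w)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def build_G(
    marker_dosage: np.ndarray,
    base_frequencies: np.ndarray,
    a_matrix: np.ndarray | None = None,
    blend: float = 0.01,
) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    Dosages are centered at twice the base-population allele frequencies
    (known exactly in simulation) and scaled by ``2 sum p (1 - p)``.  The
    result is blended as ``(1 - blend) G + blend A`` (identity if no A is
    supplied) so it is safely positive definite.
    """
    p = np.asarray(base_frequencies, dtype=float)
    poly = (p > 0) & (p < 1)
    if not np.any(poly):
        raise ValueError("all markers are monomorphic; G undefined")
    z = marker_dosage[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    g = (z @ z.T) / denom
    anchor = np.eye(g.shape[0]) if a_matrix is None else a_matrix
    return (1.0 - blend) * g + blend * anchor


def true_inbreeding(labels: np.ndarray) -> np.ndarray:
    """IBD inbreeding: fraction of loci with identical founder labels.

    ``labels`` has shape ``(n_animals, 2, n_loci)``; all simulated loci
    (markers and QTL) contribute equally.
    """
    return np.mean(labels[:, 0, :] == labels[:, 1, :], axis=1)
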