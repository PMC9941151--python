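"""Shared numerical helpers used by several analysis stages."""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree


def log_normalize(counts: sp.spmatrix | np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalize to ``target_sum`` per spot, then log1p.

    Returns a dense float array (sections here are small enough that density
    is not a concern).  Spots with zero total counts are left at zero.
    """
    X = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    return np.log1p(X * scale)


def neighbor_graph(coords: np.ndarray, radius_um: float) -> sp.csr_matrix:
    """Binary symmetric spot-adjacency matrix: pairs within ``radius_um``.

    Self-adjacency is excluded.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=radius_um, output_type="ndarray")
    if pairs.size == 0:
        return sp.csr_matrix((n, n))
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    data = np.ones(rows.size)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def grid_spacing(coords: np.ndarray) -> float:
    """Median nearest-neighbour spot distance (the array pitch)."""
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    return float(np.median(d[:, 1]))


def smooth_expression(X: np.ndarray, coords: np.ndarray, radius_um: float, alpha: float) -> np.ndarray:
    """Blend each spot's expression with the mean of its spatial neighbours.

    ``alpha`` is the weight on the neighbour mean (0 = no smoothing).  Spots
    without neighbours keep their own expression.
    """
    if alpha == 0:
        return X
    adj = neighbor_graph(coords, radius_um)
    degree = np.asarray(adj.sum(axis=1)).ravel()
    inv = np.divide(1.0, degree, out=np.zeros_like(degree), where=degree > 0)
    neighbor_mean = adj.multiply(inv[:, None]) @ X
    out = (1 - alpha) * X + alpha * neighbor_mean
    isolated = degree == 0
    if isolated.any():
        out[isolated] = X[isolated]
    return out


def resolve_signed_scores(score_maps: Iterable[Mapping[str, float]]) -> dict[str, float]:
    """Merge signed gene scores, keeping the value of greatest magnitude.

    When a gene appears with conflicting signs of equal magnitude the
    positive value is kept (deterministic tie rule).
    """
    merged: dict[str, float] = {}
    for scores in score_maps:
        for gene, value in scores.items():
            if gene not in merged:
                merged[gene] = value
            else:
                old = merged[gene]
                if abs(value) > abs(old) or (abs(value) == abs(old) and value > old):
                    merged[gene] = value
    return merged
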