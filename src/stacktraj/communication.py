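"""Ligand-receptor communication density along trajectories.

For each ligand-receptor pair the per-spot raw interaction intensity is

    raw_i = 1/2 * ( L_i * mean(R over neighbours of i)
                  + R_i * mean(L over neighbours of i) )

on log-normalized expression, with neighbours the spots within a fixed
radius (spots without neighbours use a neighbour mean of 0).  The raw
intensity is z-scored against a spatial permutation null: the spot labels
of the ligand and receptor vectors are permuted jointly (preserving the
within-spot L/R coupling while destroying spatial structure) and the raw
intensity recomputed; ``Zscore_i = (raw_i - mean_null_i) / sd_null_i``.

Z-scores are discretized to ``ZT_i`` (by default binary: 1 when
``Zscore_i >= z*``, z* = 1.96) and aggregated over the N spots of a
trajectory's regions into ``ZT_Total = sum_i ZT_i`` and the communication
density ``Density = ZT_Total / N``.  Densities of the trajectory's LR pairs
at different time points are compared with the Kruskal-Wallis test.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from ._utils import log_normalize, neighbor_graph
from .io import LRPair, MultiSectionDataset, SectionDataset

__all__ = [
    "CommunicationResult",
    "DensityComparison",
    "communication_table",
    "compare_densities",
    "discretize_and_density",
    "permutation_zscore",
    "select_trajectory_spots",
    "spot_intensity",
]


class GeneMissingError(KeyError):
    """A ligand or receptor gene is absent from the section's gene universe."""

    def __str__(self) -> str:  # KeyError would re-quote the message
        return self.args[0]


def select_trajectory_spots(section: SectionDataset, chain: Sequence[str]) -> np.ndarray:
    """Indices of the spots whose region label lies on the chain."""
    mask = np.isin(np.asarray(section.region_labels), list(chain))
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError(f"no spots of section {section.section_id} lie on chain {tuple(chain)}")
    return idx


def _pair_expression(section: SectionDataset, pair: LRPair) -> tuple[np.ndarray, np.ndarray]:
    index = {g.upper(): j for j, g in enumerate(section.gene_ids)}
    try:
        jl = index[pair.ligand_gene.upper()]
        jr = index[pair.receptor_gene.upper()]
    except KeyError as e:
        raise GeneMissingError(
            f"pair {pair.pair_id}: gene {e.args[0]!r} absent from section {section.section_id}"
        ) from e
    expr = log_normalize(section.counts)
    return expr[:, jl], expr[:, jr]


def _raw_intensity(L: np.ndarray, R: np.ndarray, mean_op: "np.ndarray") -> np.ndarray:
    return 0.5 * (L * (mean_op @ R) + R * (mean_op @ L))


def _neighbor_mean_operator(section: SectionDataset, radius_um: float):
    adj = neighbor_graph(section.coords, radius_um)
    degree = np.asarray(adj.sum(axis=1)).ravel()
    inv = np.divide(1.0, degree, out=np.zeros_like(degree), where=degree > 0)
    return adj.multiply(inv[:, None]).tocsr()


def spot_intensity(
    section: SectionDataset, pair: LRPair, neighbor_radius_um: float
) -> np.ndarray:
    """Raw per-spot interaction intensity for one ligand-receptor pair."""
    L, R = _pair_expression(section, pair)
    mean_op = _neighbor_mean_operator(section, neighbor_radius_um)
    return _raw_intensity(L, R, mean_op)


@dataclass
class PairZscores:
    """Per-spot z-scored intensities with degeneracy bookkeeping."""

    zscores: np.ndarray
    raw: np.ndarray
    degenerate: np.ndarray


def permutation_zscore(
    section: SectionDataset,
    pair: LRPair,
    neighbor_radius_um: float,
    n_perm: int = 200,
    seed: int = 0,
) -> PairZscores:
    """Z-score raw intensities against a spatial permutation null.

    Spots where the null has zero spread get a z-score of 0 and are flagged
    degenerate.  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    L, R = _pair_expression(section, pair)
    mean_op = _neighbor_mean_operator(section, neighbor_radius_um)
    raw = _raw_intensity(L, R, mean_op)

    rng = np.random.default_rng(seed)
    n = L.size
    # columns = one joint permutation of the spot labels of L and R
    perm = np.stack([rng.permutation(n) for _ in range(n_perm)], axis=1)
    Lp, Rp = L[perm], R[perm]
    null = 0.5 * (Lp * (mean_op @ Rp) + Rp * (mean_op @ Lp))
    mean_null = null.mean(axis=1)
    sd_null = null.std(axis=1)

    degenerate = sd_null == 0
    z = np.zeros(n)
    ok = ~degenerate
    z[ok] = (raw[ok] - mean_null[ok]) / sd_null[ok]
    return PairZscores(zscores=z, raw=raw, degenerate=degenerate)


@dataclass
class CommunicationResult:
    """Discretized communication intensity of one pair along a trajectory."""

    trajectory_id: str
    timepoint: str
    pair_id: str
    zscores: np.ndarray
    zt: np.ndarray
    n_spots: int
    zt_total: int
    density: float
    spot_ids: list[str] = field(default_factory=list)


def discretize_and_density(
    zscores: np.ndarray,
    trajectory_id: str = "",
    timepoint: str = "",
    pair_id: str = "",
    z_threshold: float = 1.96,
    mode: str = "binary",
) -> CommunicationResult:
    """Convert continuous z-scores to discrete intensities and a density.

    ``binary`` mode (default): ``ZT_i = 1`` when ``Zscore_i >= z*`` else 0,
    so the density is the fraction of significant spots and lies in [0, 1].
    ``binned`` mode: ``ZT_i = trunc(Zscore_i / z*)`` — a signed integer
    count of threshold multiples, kept for sensitivity analysis.
    """
    z = np.asarray(zscores, dtype=float)
    if z.size == 0:
        raise ValueError("empty z-score vector")
    if mode == "binary":
        zt = (z >= z_threshold).astype(int)
    elif mode == "binned":
        zt = np.trunc(z / z_threshold).astype(int)
    else:
        raise ValueError(f"unknown discretization mode {mode!r}")
    zt_total = int(zt.sum())
    return CommunicationResult(
        trajectory_id=trajectory_id,
        timepoint=timepoint,
        pair_id=pair_id,
        zscores=z,
        zt=zt,
        n_spots=int(z.size),
        zt_total=zt_total,
        density=zt_total / z.size,
    )


def communication_table(
    mds: MultiSectionDataset,
    chain: Sequence[str],
    pairs: Sequence[LRPair],
    trajectory_id: str,
    neighbor_radius_um: float,
    n_perm: int = 200,
    z_threshold: float = 1.96,
    mode: str = "binary",
    seed: int = 0,
) -> tuple[pd.DataFrame, list[CommunicationResult]]:
    """Per-(timepoint, pair) densities for one trajectory, pooling sections.

    Z-scores are computed per section (the permutation null is spatial and
    therefore section-local), restricted to the chain's spots, and pooled
    over the time point's serial sections before discretization, giving one
    density per ``CellT^trajectory_time`` and LR pair.  Pairs with a gene
    missing from a section are skipped with a warning.
    """
    seeds = _seed_grid(mds, pairs, seed)
    rows = []
    results = []
    for timepoint, sections in mds.sections_by_timepoint.items():
        for pair in pairs:
            pooled: list[np.ndarray] = []
            pooled_spots: list[str] = []
            for section in sections:
                try:
                    pz = permutation_zscore(
                        section,
                        pair,
                        neighbor_radius_um,
                        n_perm=n_perm,
                        seed=seeds[(timepoint, pair.pair_id, section.section_id)],
                    )
                except GeneMissingError as e:
                    warnings.warn(str(e), stacklevel=2)
                    continue
                idx = select_trajectory_spots(section, chain)
                pooled.append(pz.zscores[idx])
                pooled_spots.extend(section.spot_ids[i] for i in idx)
            if not pooled:
                continue
            result = discretize_and_density(
                np.concatenate(pooled),
                trajectory_id=trajectory_id,
                timepoint=timepoint,
                pair_id=pair.pair_id,
                z_threshold=z_threshold,
                mode=mode,
            )
            result.spot_ids = pooled_spots
            results.append(result)
            rows.append(
                {
                    "trajectory": trajectory_id,
                    "timepoint": timepoint,
                    "pair": pair.pair_id,
                    "n_spots": result.n_spots,
                    "zt_total": result.zt_total,
                    "density": result.density,
                }
            )
    return pd.DataFrame(rows), results


def _seed_grid(
    mds: MultiSectionDataset, pairs: Sequence[LRPair], seed: int
) -> dict[tuple[str, str, str], int]:
    """Deterministic per-(timepoint, pair, section) seeds derived from ``seed``.

    Keys are hashed with a stable digest so the streams do not depend on
    iteration order or the interpreter's hash randomization.
    """
    seeds: dict[tuple[str, str, str], int] = {}
    for tp, sections in mds.sections_by_timepoint.items():
        for pair in pairs:
            for section in sections:
                key = f"{tp}|{pair.pair_id}|{section.section_id}".encode()
                digest = int.from_bytes(hashlib.sha256(key).digest()[:4], "little")
                ss = np.random.SeedSequence([int(seed), digest])
                seeds[(tp, pair.pair_id, section.section_id)] = int(
                    ss.generate_state(1)[0] % (2**31)
                )
    return seeds


@dataclass
class DensityComparison:
    """Kruskal-Wallis comparison of density vectors across time points."""

    groups: dict[str, np.ndarray]
    h_statistic: float
    p_value: float
    method: str


def compare_densities(
    groups: Mapping[str, Sequence[float]],
    method: str = "asymptotic",
    n_perm: int = 9999,
    seed: int = 0,
) -> DensityComparison:
    """Kruskal-Wallis test of densities across >= 2 groups (tie-corrected).

    ``method="asymptotic"`` uses the chi-squared approximation;
    ``method="permutation"`` computes an exact-style p-value by shuffling
    the pooled observations (recommended for small numbers of LR pairs per
    group).  When every observation is identical the convention H = 0,
    p = 1 is returned.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for name, arr in arrays.items():
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
    values = list(arrays.values())
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        return DensityComparison(groups=arrays, h_statistic=0.0, p_value=1.0, method=method)

    h, p = scipy.stats.kruskal(*values)
    if method == "asymptotic":
        return DensityComparison(groups=arrays, h_statistic=float(h), p_value=float(p), method=method)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    sizes = [len(v) for v in values]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        shuffled = rng.permutation(pooled)
        parts = np.split(shuffled, np.cumsum(sizes)[:-1])
        if np.all(shuffled == shuffled[0]):
            h_perm = 0.0
        else:
            try:
                h_perm, _ = scipy.stats.kruskal(*parts)
            except ValueError:  # all identical within the shuffle
                h_perm = 0.0
        if h_perm >= h - 1e-12:
            count += 1
    p_perm = (1 + count) / (1 + n_perm)
    return DensityComparison(groups=arrays, h_statistic=float(h), p_value=float(p_perm), method=method)
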