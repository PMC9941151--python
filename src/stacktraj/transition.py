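"""Transition genes: Spearman ranking along pseudotime and the 3D union.

For each *subtrajectory* — one consecutive region pair of a trajectory
chain — every gene's log-normalized expression is correlated (Spearman)
with pseudotime over the spots of the two regions.  The top-K positively
correlated genes are the up-regulated transition genes, the top-K negative
the down-regulated ones (K = 30 by default).

Per-section lists for the same subtrajectory and time point are then merged
into a 3D transition gene set: the union of the planar lists, where a gene
appearing with conflicting signs in different sections keeps the signed
score of greatest absolute value, re-truncated to the top K per direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from ._utils import log_normalize, resolve_signed_scores
from .io import SectionDataset

__all__ = ["TransitionGeneSet", "rank_transition_genes", "union_3d"]


@dataclass
class TransitionGeneSet:
    """Signed Spearman scores with top-K up/down gene lists.

    ``section_id`` is ``"3D"`` for sets merged across serial sections.
    ``scores`` holds the signed rho of every listed gene (and, for planar
    sets, of every non-constant gene considered).
    """

    subtrajectory: tuple[str, str]
    timepoint: str
    section_id: str
    scores: dict[str, float]
    up: list[str]
    down: list[str]
    k: int = 30

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down lists overlap")
        if len(self.up) > self.k or len(self.down) > self.k:
            raise ValueError("list longer than K")

    def signed_markers(self) -> dict[str, float]:
        """Signed scores of the listed genes only."""
        return {g: self.scores[g] for g in [*self.up, *self.down]}


def _spearman_vs_pseudotime(expr: np.ndarray, pt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Spearman rho of expression vs pseudotime.

    Returns (rho, keep) where ``keep`` is False for zero-variance genes.
    """
    ranks = rankdata(expr, axis=0)
    pt_ranks = rankdata(pt)
    keep = ranks.std(axis=0) > 0
    rho = np.zeros(expr.shape[1])
    if pt_ranks.std() == 0:
        return rho, np.zeros_like(keep)
    rc = ranks[:, keep] - ranks[:, keep].mean(axis=0)
    pc = pt_ranks - pt_ranks.mean()
    denom = np.sqrt((rc**2).sum(axis=0) * (pc**2).sum())
    rho[keep] = (rc * pc[:, None]).sum(axis=0) / denom
    return rho, keep


def rank_transition_genes(
    section: SectionDataset,
    subtrajectory: tuple[str, str],
    pseudotime: np.ndarray,
    k: int = 30,
    min_spots: int = 10,
) -> TransitionGeneSet:
    """Rank a section's genes by Spearman correlation with pseudotime.

    The correlation is computed over the spots of the subtrajectory's two
    regions only.  Zero-variance genes are excluded; ties in rho are broken
    by gene identifier.
    """
    regions = np.asarray(section.region_labels)
    mask = np.isin(regions, subtrajectory) & np.isfinite(pseudotime)
    n = int(mask.sum())
    if n < min_spots:
        raise ValueError(
            f"only {n} spots in subtrajectory {subtrajectory} "
            f"(need at least {min_spots})"
        )
    expr = log_normalize(section.counts)[mask]
    if not expr.any():
        raise ValueError("all-zero expression over the subtrajectory spots")
    rho, keep = _spearman_vs_pseudotime(expr, pseudotime[mask])

    genes = np.asarray(section.gene_ids)
    scores = {str(g): float(r) for g, r in zip(genes[keep], rho[keep])}
    up_pool = sorted((g for g, r in scores.items() if r > 0), key=lambda g: (-scores[g], g))
    down_pool = sorted((g for g, r in scores.items() if r < 0), key=lambda g: (scores[g], g))
    return TransitionGeneSet(
        subtrajectory=subtrajectory,
        timepoint=section.timepoint,
        section_id=section.section_id,
        scores=scores,
        up=up_pool[:k],
        down=down_pool[:k],
        k=k,
    )


def union_3d(sets: Sequence[TransitionGeneSet]) -> TransitionGeneSet:
    """Merge planar top-K lists for one subtrajectory into the 3D set.

    The union of the sections' up/down lists is formed; a gene reported
    with conflicting signs by different sections keeps the signed score of
    greatest absolute value.  The merged pool is then re-truncated to the
    top K genes per direction by |rho| (ties by gene identifier), so the 3D
    set is again a top-K set.  Idempotent and independent of input order.
    """
    if not sets:
        raise ValueError("no transition gene sets to merge")
    subtrajectory = sets[0].subtrajectory
    timepoint = sets[0].timepoint
    k = sets[0].k
    for s in sets[1:]:
        if s.subtrajectory != subtrajectory:
            raise ValueError(
                f"cannot merge subtrajectories {subtrajectory} and {s.subtrajectory}"
            )
        if s.timepoint != timepoint:
            raise ValueError("cannot merge sets from different timepoints")

    merged = resolve_signed_scores([s.signed_markers() for s in sets])
    up_pool = sorted((g for g, r in merged.items() if r > 0), key=lambda g: (-abs(merged[g]), g))
    down_pool = sorted((g for g, r in merged.items() if r < 0), key=lambda g: (-abs(merged[g]), g))
    up, down = up_pool[:k], down_pool[:k]
    kept = {g: merged[g] for g in [*up, *down]}
    return TransitionGeneSet(
        subtrajectory=subtrajectory,
        timepoint=timepoint,
        section_id="3D",
        scores=kept,
        up=up,
        down=down,
        k=k,
    )
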