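"""Cell-subtype profiles, their similarity over time, cell-type matching
and pathway-set comparison.

A *subtype profile* represents the transcriptional state of one trajectory
at one time point: the union of the trajectory's 3D transition gene sets,
with each gene carrying a sign (+1 up-regulated along the trajectory, -1
down-regulated).  Profiles at different time points of the same trajectory
are compared with a sign-aware Jaccard similarity, matched against a local
cell-type marker database by hypergeometric enrichment, and the pathway
sets of a subtype and its matched cell types are compared with the overlap
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from ._utils import resolve_signed_scores
from .io import MarkerDB
from .transition import TransitionGeneSet

__all__ = [
    "CellTypeMatch",
    "PathwaySets",
    "SubtypeProfile",
    "build_subtype_profile",
    "match_cell_types",
    "pathway_set_similarity",
    "subtype_similarity",
    "union_top_types",
]


@dataclass
class SubtypeProfile:
    """Signed marker-gene profile of a trajectory at a time point."""

    trajectory_id: str
    timepoint: str
    markers: dict[str, int]
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("empty subtype profile")
        bad = [g for g, s in self.markers.items() if s not in (-1, 1)]
        if bad:
            raise ValueError(f"marker signs must be +/-1 (offending: {bad[:3]})")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.markers)


def build_subtype_profile(
    transition_sets: Sequence[TransitionGeneSet],
    trajectory_id: str,
    timepoint: str,
) -> SubtypeProfile:
    """Union the trajectory's per-subtrajectory 3D transition sets.

    A gene listed with conflicting signs by different subtrajectories keeps
    the sign of the score with greatest absolute value (the same rule used
    when merging planar sections).
    """
    if not transition_sets:
        raise ValueError("no transition gene sets given")
    scores = resolve_signed_scores([s.signed_markers() for s in transition_sets])
    markers = {g: (1 if r > 0 else -1) for g, r in scores.items() if r != 0}
    return SubtypeProfile(
        trajectory_id=trajectory_id, timepoint=timepoint, markers=markers, scores=scores
    )


def subtype_similarity(a: SubtypeProfile, b: SubtypeProfile) -> float:
    """Sign-aware Jaccard similarity between two subtype profiles.

    The number of genes present in both profiles *with the same sign*,
    divided by the size of the union of their gene sets.  Symmetric, in
    [0, 1], equal to 1 exactly when the profiles are identical (same genes,
    same signs) and 0 exactly when no gene agrees.
    """
    union = a.genes | b.genes
    agree = sum(
        1 for g in a.genes & b.genes if a.markers[g] == b.markers[g]
    )
    return agree / len(union)


@dataclass(frozen=True)
class CellTypeMatch:
    """One candidate cell type with its enrichment evidence."""

    cell_type: str
    p_value: float
    overlap: int
    marker_set_size: int


def match_cell_types(
    profile: SubtypeProfile,
    marker_db: MarkerDB,
    top_n: int = 5,
    universe: Iterable[str] | None = None,
) -> list[CellTypeMatch]:
    """Rank database cell types against a profile by marker enrichment.

    Each cell type is scored with the hypergeometric upper tail of the
    overlap between the profile's genes (sign ignored, case-insensitive)
    and the type's marker set, against a gene universe (by default the
    union of the database's genes and the profile's genes).  The ``top_n``
    types by p-value are returned; ties prefer larger overlap, then the
    lexicographically smaller name.
    """
    if not marker_db.markers:
        raise ValueError("empty marker database")
    profile_genes = {g.upper() for g in profile.genes}
    if universe is None:
        universe_set = set(marker_db.gene_universe) | profile_genes
    else:
        universe_set = {g.upper() for g in universe}
    M = len(universe_set)
    N = len(profile_genes & universe_set)

    matches = []
    for cell_type, markers in marker_db.markers.items():
        markers_in = markers & universe_set
        n = len(markers_in)
        k = len(markers_in & profile_genes)
        p = float(hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
        matches.append(CellTypeMatch(cell_type, p, k, len(markers)))
    matches.sort(key=lambda m: (m.p_value, -m.overlap, m.cell_type))
    return matches[:top_n]


def union_top_types(matches_by_timepoint: Mapping[str, Sequence[CellTypeMatch]]) -> list[str]:
    """Union of the top matched cell types across a trajectory's time points."""
    seen: set[str] = set()
    out: list[str] = []
    for timepoint in matches_by_timepoint:
        for m in matches_by_timepoint[timepoint]:
            if m.cell_type not in seen:
                seen.add(m.cell_type)
                out.append(m.cell_type)
    return sorted(out)


@dataclass
class PathwaySets:
    """Mutual pathway set and overlap-coefficient similarity.

    ``p_inter`` is the intersection of the subtype's pathway set ``p_a``
    and the matched cell types' pathway set ``p_b``; similarity is
    ``|p_inter| / min(|p_a|, |p_b|)`` (0 when either set is empty).
    """

    p_a: frozenset[str]
    p_b: frozenset[str]
    p_inter: frozenset[str]
    similarity: float


def pathway_set_similarity(p_a: Iterable[str], p_b: Iterable[str]) -> PathwaySets:
    """Overlap-coefficient similarity between two pathway-ID sets."""
    a = frozenset(str(p).strip() for p in p_a)
    b = frozenset(str(p).strip() for p in p_b)
    inter = a & b
    if not a or not b:
        similarity = 0.0
    else:
        similarity = len(inter) / min(len(a), len(b))
    return PathwaySets(p_a=a, p_b=b, p_inter=inter, similarity=similarity)
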