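"""Synthetic multi-section Visium-like data with known ground truth.

The generator emulates the *structure* of a serial-section spatial
transcriptomics study of an injured mouse brain — several coronal sections
per time point, spots on a regular grid, contiguous anatomical region bands,
a planted pseudospace gradient running from a root region (the lateral
ventricle stand-in ``VL``) through a chain of downstream regions — without
attempting to model the underlying biology.

Planted structure, all recorded in :class:`GroundTruth`:

* **Pseudotime** — the normalized arc-length of each spot along the band
  axis of the planted chain, so spatial position *is* the true ordering.
* **Transition genes** — for every consecutive region pair of the chain, a
  set of genes whose log-mean expression rises (or falls) linearly with the
  local pseudotime at a configurable slope (``effect_size``, natural-log
  units over the pair).  Injured time points share one gene pool (with a
  configurable overlap between successive injury days) while sham/control
  time points use a disjoint pool, so subtype profiles built downstream are
  similar within the injury phase and dissimilar to sham.
* **Ligand-receptor hotspots** — spatially contiguous patches of spots in a
  chosen region where both genes of a pair are multiplied above baseline.
  Per-timepoint effects scale the multiplier, emulating communication that
  rises after injury and subsides later.

Counts are negative-binomial with per-gene baseline log-means drawn once
from a normal distribution and a shared dispersion.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import LRPair, MultiSectionDataset, SectionDataset, ValidationError, write_section

__all__ = [
    "GroundTruth",
    "LRHotspot",
    "SyntheticConfig",
    "generate_dataset",
    "ground_truth_summary",
    "write_dataset",
]


@dataclass(frozen=True)
class LRHotspot:
    """A planted ligand-receptor co-expression patch."""

    ligand: str
    receptor: str
    region: str
    fraction: float = 0.15
    multiplier: float = 5.0

    @property
    def pair_id(self) -> str:
        return f"{self.ligand.upper()}_{self.receptor.upper()}"


def _default_hotspots() -> tuple[LRHotspot, ...]:
    return tuple(
        LRHotspot(ligand=f"Lg{i}", receptor=f"Rc{i}", region="B") for i in range(1, 9)
    )


def _default_timepoint_effects() -> dict[str, float]:
    # communication rises sharply at day 3 and has largely subsided by day 7
    return {"sham": 0.0, "d3": 1.0, "d7": 0.1}


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults give three sections per time point of 400 spots on a 100 µm
    square grid, four region bands forming the planted chain
    ``VL -> A -> B -> C``, 30 up- and 30 down-regulated transition genes per
    region pair at unit log-slope, and eight ligand-receptor hotspots in
    region ``B`` whose intensity peaks at day 3.
    """

    timepoints: tuple[str, ...] = ("sham", "d3", "d7")
    n_sections_per_timepoint: int = 3
    spots_per_section: int = 400
    grid_spacing_um: float = 100.0
    z_step_um: float = 20.0
    region_layout: tuple[str, ...] = ("VL", "A", "B", "C")
    planted_chain: tuple[str, ...] = ("VL", "A", "B", "C")
    n_genes: int = 500
    n_transition_up: int = 30
    n_transition_down: int = 30
    effect_size: float = 1.0
    nb_dispersion: float = 0.3
    base_logmean_mu: float = 2.0
    base_logmean_sigma: float = 0.5
    lr_gene_logmean: float = 2.0
    lr_hotspots: tuple[LRHotspot, ...] = field(default_factory=_default_hotspots)
    hotspot_timepoint_effects: dict[str, float] = field(default_factory=_default_timepoint_effects)
    injury_marker_overlap: float = 0.8
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if not set(self.planted_chain) <= set(self.region_layout):
            missing = set(self.planted_chain) - set(self.region_layout)
            raise ValidationError(f"planted chain regions {sorted(missing)} absent from layout")
        if self.spots_per_section < len(self.region_layout):
            raise ValidationError("fewer spots than regions")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0 (signs come from direction)")
        for h in self.lr_hotspots:
            if not (0 < h.fraction <= 1):
                raise ValidationError(f"hotspot fraction {h.fraction} not in (0, 1]")
            if h.region not in self.region_layout:
                raise ValidationError(f"hotspot region {h.region!r} absent from layout")
        if not (0 <= self.injury_marker_overlap <= 1):
            raise ValidationError("injury_marker_overlap must be in [0, 1]")
        needed = self._n_planted_genes() + 2 * len(self.lr_hotspots)
        if self.n_genes < needed:
            raise ValidationError(
                f"n_genes={self.n_genes} too small for {needed} planted + LR genes"
            )
        return self

    @property
    def subtrajectories(self) -> list[tuple[str, str]]:
        chain = self.planted_chain
        return [(chain[i], chain[i + 1]) for i in range(len(chain) - 1)]

    def _n_swap(self) -> int:
        return (
            int(round((1 - self.injury_marker_overlap) * self.n_transition_up)),
            int(round((1 - self.injury_marker_overlap) * self.n_transition_down)),
        )

    def _n_planted_genes(self) -> int:
        pool = self.n_transition_up + self.n_transition_down
        swap_up, swap_down = self._n_swap()
        return len(self.subtrajectories) * (2 * pool + swap_up + swap_down)


@dataclass
class GroundTruth:
    """Planted facts matching a generated dataset.

    ``pseudotime`` maps section_id to the per-spot true ordering in [0, 1];
    ``transition_genes`` maps ``(timepoint, (region_a, region_b))`` to
    ``{gene: +1/-1}``; ``hotspots`` maps ``(timepoint, pair_id, section_id)``
    to the planted patch's spot barcodes; ``marker_sets`` maps a timepoint to
    the signed union of its transition genes over the whole chain.
    """

    pseudotime: dict[str, np.ndarray]
    transition_genes: dict[tuple[str, tuple[str, str]], dict[str, int]]
    hotspots: dict[tuple[str, str, str], list[str]]
    marker_sets: dict[str, dict[str, int]]
    config: SyntheticConfig


def _grid(config: SyntheticConfig) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Square-grid coordinates, region band labels and true pseudotime."""
    n = config.spots_per_section
    ncols = int(np.ceil(np.sqrt(n)))
    if ncols < len(config.region_layout):
        raise ValidationError("grid too narrow for the region layout")
    idx = np.arange(n)
    cols, rows = idx % ncols, idx // ncols
    coords = np.column_stack([cols, rows]).astype(float) * config.grid_spacing_um
    band_of_col = np.concatenate(
        [np.full(len(chunk), i) for i, chunk in enumerate(np.array_split(np.arange(ncols), len(config.region_layout)))]
    )
    regions = [config.region_layout[band_of_col[c]] for c in cols]
    xmax = cols.max() * config.grid_spacing_um
    pt = coords[:, 0] / xmax if xmax > 0 else np.zeros(n)
    return coords, regions, pt


def _assign_gene_pools(
    config: SyntheticConfig,
) -> tuple[list[str], dict[tuple[str, tuple[str, str]], dict[str, int]]]:
    """Name all genes and assign the per-(timepoint, subtrajectory) pools."""
    n_up, n_down = config.n_transition_up, config.n_transition_down
    swap_up, swap_down = config._n_swap()
    pool = n_up + n_down

    genes: list[str] = []

    def take(k: int) -> list[str]:
        start = len(genes)
        names = [f"G{start + i + 1:04d}" for i in range(k)]
        genes.extend(names)
        return names

    sham_like = [tp for tp in config.timepoints if tp in ("sham", "control")]
    injury = [tp for tp in config.timepoints if tp not in ("sham", "control")]

    assignment: dict[tuple[str, tuple[str, str]], dict[str, int]] = {}
    for subtraj in config.subtrajectories:
        baseline_pool = take(pool)
        injury_pool = take(pool)
        swap_pool = take(swap_up + swap_down)

        def signed(names: Sequence[str], nu: int = n_up) -> dict[str, int]:
            return {g: (1 if i < nu else -1) for i, g in enumerate(names)}

        base_set = signed(baseline_pool)
        first_injury_set = signed(injury_pool)
        # later injury days keep `injury_marker_overlap` of the first day's
        # genes and swap the remainder for fresh ones
        later_up = injury_pool[: n_up - swap_up] + swap_pool[:swap_up]
        later_down = injury_pool[n_up : n_up + n_down - swap_down] + swap_pool[swap_up:]
        later_set = {g: 1 for g in later_up} | {g: -1 for g in later_down}

        for tp in sham_like:
            assignment[(tp, subtraj)] = dict(base_set)
        for i, tp in enumerate(injury):
            assignment[(tp, subtraj)] = dict(first_injury_set if i == 0 else later_set)

    for h in config.lr_hotspots:
        genes.append(h.ligand)
        genes.append(h.receptor)
    n_background = config.n_genes - len(genes)
    take(n_background)
    return genes, assignment


def generate_dataset(config: SyntheticConfig) -> tuple[MultiSectionDataset, GroundTruth]:
    """Generate a multi-section dataset plus its ground truth.

    Deterministic given ``config.seed``: the same configuration always
    yields byte-identical count matrices.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    structure_rng = np.random.default_rng(master.spawn(1)[0])

    coords, regions, true_pt = _grid(config)
    genes, assignment = _assign_gene_pools(config)
    gene_index = {g: j for j, g in enumerate(genes)}
    region_arr = np.asarray(regions)

    base_logmean = structure_rng.normal(config.base_logmean_mu, config.base_logmean_sigma, len(genes))
    for h in config.lr_hotspots:
        base_logmean[gene_index[h.ligand]] = config.lr_gene_logmean
        base_logmean[gene_index[h.receptor]] = config.lr_gene_logmean

    groups: dict[str, list[SectionDataset]] = {}
    gt_pt: dict[str, np.ndarray] = {}
    gt_hotspots: dict[tuple[str, str, str], list[str]] = {}

    section_seeds = iter(master.spawn(len(config.timepoints) * config.n_sections_per_timepoint + 1)[1:])
    for tp in config.timepoints:
        effect_tp = float(config.hotspot_timepoint_effects.get(tp, 0.0))
        for k in range(config.n_sections_per_timepoint):
            rng = np.random.default_rng(next(section_seeds))
            section_id = f"{tp}-sec{k}"
            spot_ids = [f"{section_id}:spot{i:04d}" for i in range(len(regions))]

            logmean = np.tile(base_logmean, (len(regions), 1))
            for subtraj in config.subtrajectories:
                mask = np.isin(region_arr, subtraj)
                lo, hi = true_pt[mask].min(), true_pt[mask].max()
                # ramp across the pair, plateau outside: globally monotone
                span = hi - lo
                ramp = np.clip((true_pt - lo) / span, 0, 1) if span > 0 else np.zeros_like(true_pt)
                for gene, sign in assignment[(tp, subtraj)].items():
                    logmean[:, gene_index[gene]] += sign * config.effect_size * ramp

            for h in config.lr_hotspots:
                applied = 1.0 + (h.multiplier - 1.0) * effect_tp
                if applied <= 1.0:
                    continue
                region_idx = np.nonzero(region_arr == h.region)[0]
                n_patch = max(1, int(np.ceil(h.fraction * len(region_idx))))
                seed_spot = rng.choice(region_idx)
                dists = np.linalg.norm(coords[region_idx] - coords[seed_spot], axis=1)
                patch = region_idx[np.argsort(dists, kind="stable")[:n_patch]]
                for g in (h.ligand, h.receptor):
                    logmean[patch, gene_index[g]] += np.log(applied)
                gt_hotspots[(tp, h.pair_id, section_id)] = [spot_ids[i] for i in patch]

            mu = np.exp(logmean)
            if config.nb_dispersion > 0:
                r = 1.0 / config.nb_dispersion
                counts = rng.negative_binomial(r, r / (r + mu))
            else:
                counts = rng.poisson(mu)

            section = SectionDataset(
                section_id=section_id,
                timepoint=tp,
                z_um=k * config.z_step_um,
                spot_ids=spot_ids,
                coords=coords.copy(),
                counts=sp.csr_matrix(counts.astype(np.int64)),
                gene_ids=list(genes),
                region_labels=list(regions),
                meta={"synthetic": True, "grid_spacing_um": config.grid_spacing_um},
            ).validate()
            groups.setdefault(tp, []).append(section)
            gt_pt[section_id] = true_pt.copy()

    mds = MultiSectionDataset(
        sections_by_timepoint=groups,
        gene_universe_policy="intersection",
        gene_universe={tp: list(genes) for tp in config.timepoints},
    )
    marker_sets = {
        tp: dict(
            _merge_marker_sets([assignment[(tp, s)] for s in config.subtrajectories])
        )
        for tp in config.timepoints
    }
    gt = GroundTruth(
        pseudotime=gt_pt,
        transition_genes=assignment,
        hotspots=gt_hotspots,
        marker_sets=marker_sets,
        config=config,
    )
    return mds, gt


def _merge_marker_sets(sets: Sequence[Mapping[str, int]]) -> dict[str, int]:
    merged: dict[str, int] = {}
    for s in sets:
        merged.update(s)  # pools are disjoint across subtrajectories
    return merged


def ground_truth_summary(gt: GroundTruth) -> pd.DataFrame:
    """Tidy table of planted facts, one row per (kind, key, item)."""
    rows: list[dict] = []
    for (tp, subtraj), genes in sorted(gt.transition_genes.items()):
        for gene, sign in sorted(genes.items()):
            rows.append(
                {
                    "kind": "transition_gene",
                    "timepoint": tp,
                    "key": f"{subtraj[0]}->{subtraj[1]}",
                    "item": gene,
                    "value": sign,
                }
            )
    for (tp, pair_id, section_id), spots in sorted(gt.hotspots.items()):
        for spot in spots:
            rows.append(
                {
                    "kind": "hotspot_spot",
                    "timepoint": tp,
                    "key": f"{pair_id}@{section_id}",
                    "item": spot,
                    "value": 1,
                }
            )
    columns = ["kind", "timepoint", "key", "item", "value"]
    return pd.DataFrame(rows, columns=columns)


def write_dataset(
    mds: MultiSectionDataset,
    gt: GroundTruth,
    outdir: str | Path,
    n_decoy_celltypes: int = 5,
    n_decoy_lr: int = 4,
) -> Path:
    """Write the dataset in the exact on-disk layout the loaders read.

    Emits per-section MTX/CSV files, ``manifest.json``,
    ``ground_truth.json``, a CellTalkDB-dialect ``lr_pairs.tsv`` covering the
    planted pairs plus decoys, a marker database ``marker_db.tsv`` whose
    cell types are the planted per-timepoint marker sets plus decoy types,
    and a pair of overlapping pathway lists.  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = gt.config
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xD15C)))

    entries = []
    for section in mds.sections:
        entries.append(write_section(section, outdir / section.section_id))
        # keep manifest paths relative to the manifest itself
        for key in ("counts_dir", "positions", "regions"):
            entries[-1][key] = str(Path(entries[-1][key]).relative_to(outdir))
    manifest = {
        "gene_universe": mds.gene_universe_policy,
        "timepoints": sorted(set(mds.timepoints) - set(("control", "sham", "d1", "d3", "d7"))),
        "sections": entries,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))

    all_genes = mds.sections[0].gene_ids
    lr_rows = [(h.ligand, h.receptor) for h in config.lr_hotspots]
    background = [g for g in all_genes if g.startswith("G")]
    for i in range(n_decoy_lr):
        pair = rng.choice(background, size=2, replace=False)
        lr_rows.append((str(pair[0]), str(pair[1])))
    pd.DataFrame(lr_rows, columns=["ligand_gene_symbol", "receptor_gene_symbol"]).to_csv(
        outdir / "lr_pairs.tsv", sep="\t", index=False
    )

    marker_rows = []
    for tp, markers in sorted(gt.marker_sets.items()):
        for gene in sorted(markers):
            marker_rows.append((f"PlantedType_{tp}", gene))
    for i in range(n_decoy_celltypes):
        for gene in rng.choice(background, size=30, replace=False):
            marker_rows.append((f"DecoyType_{i}", str(gene)))
    pd.DataFrame(marker_rows, columns=["cell_type", "gene"]).to_csv(
        outdir / "marker_db.tsv", sep="\t", index=False
    )

    pathways_a = [f"PW{i:03d}" for i in range(1, 16)]
    pathways_b = [f"PW{i:03d}" for i in range(8, 28)]
    (outdir / "pathways_A.txt").write_text("\n".join(pathways_a) + "\n")
    (outdir / "pathways_B.txt").write_text("\n".join(pathways_b) + "\n")

    gt_json = {
        "pseudotime": {sid: np.round(pt, 6).tolist() for sid, pt in gt.pseudotime.items()},
        "transition_genes": [
            {"timepoint": tp, "subtrajectory": list(subtraj), "genes": genes}
            for (tp, subtraj), genes in sorted(gt.transition_genes.items())
        ],
        "hotspots": [
            {"timepoint": tp, "pair_id": pid, "section_id": sid, "spots": spots}
            for (tp, pid, sid), spots in sorted(gt.hotspots.items())
        ],
        "marker_sets": gt.marker_sets,
        "config": {
            **{
                k: v
                for k, v in asdict(config).items()
                if k not in ("lr_hotspots", "hotspot_timepoint_effects")
            },
            "lr_hotspots": [asdict(h) for h in config.lr_hotspots],
            "hotspot_timepoint_effects": config.hotspot_timepoint_effects,
        },
    }
    (outdir / "ground_truth.json").write_text(json.dumps(gt_json, indent=1))
    return manifest_path
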