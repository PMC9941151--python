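"""End-to-end orchestration: load -> trajectories -> transition genes ->
subtypes -> communication -> pathways, with a machine-readable run report.

Every stage writes tidy TSV tables to the output directory; ``report.json``
echoes the configuration, the seed, per-stage record counts and a SHA-256
checksum of every output file, so a rerun with the same configuration and
seed can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import grid_spacing as _grid_spacing
from .communication import communication_table, compare_densities
from .io import (
    MultiSectionDataset,
    SectionDataset,
    load_lr_database,
    load_marker_db,
    load_multisection,
    load_pathway_set,
)
from .subtypes import build_subtype_profile, match_cell_types, pathway_set_similarity, subtype_similarity
from .trajectories import (
    BundleRules,
    Trajectory3D,
    build_region_graph,
    compute_pseudotime,
    extract_planar_trajectories,
    reconstruct_3d,
)
from .transition import rank_transition_genes, union_3d

__all__ = ["PipelineError", "RunConfig", "run_full_pipeline"]

_FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All inputs and stage parameters for a full run."""

    manifest: str
    lr_db: str
    outdir: str
    marker_db: str | None = None
    pathways_a: str | None = None
    pathways_b: str | None = None
    root_region: str = "VL"
    k_neighbors: int = 15
    n_pcs: int = 30
    adjacency_radius_factor: float = 1.5
    min_delta: float = 0.05
    min_adjacent: int = 3
    min_support: int = 2
    merge_mode: str = "subsequence"
    top_k: int = 30
    top_n_celltypes: int = 5
    z_threshold: float = 1.96
    n_perm: int = 200
    discretize_mode: str = "binary"
    seed: int = 0
    bundle_rules: dict[str, list[str]] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def resolve_bundle_rules(self) -> BundleRules:
        if self.bundle_rules is None:
            return BundleRules()
        kwargs = {k: frozenset(v) for k, v in self.bundle_rules.items()}
        return BundleRules(**kwargs)

    def validate(self) -> "RunConfig":
        for name in ("manifest", "lr_db"):
            path = getattr(self, name)
            if not Path(path).is_file():
                raise FileNotFoundError(f"{name}: {path}")
        for name in ("marker_db", "pathways_a", "pathways_b"):
            path = getattr(self, name)
            if path is not None and not Path(path).is_file():
                raise FileNotFoundError(f"{name}: {path}")
        return self


def grid_spacing(section: SectionDataset) -> float:
    """Median nearest-neighbour spot distance (the array pitch)."""
    return _grid_spacing(section.coords)


def _write(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    rules = config.resolve_bundle_rules()

    # -- load ---------------------------------------------------------------
    try:
        mds = load_multisection(config.manifest)
        lr_pairs = load_lr_database(config.lr_db)
        marker_db = load_marker_db(config.marker_db) if config.marker_db else None
    except Exception as e:
        raise PipelineError("load", str(e)) from e
    report["stages"]["load"] = {
        "n_sections": len(mds.sections),
        "timepoints": mds.timepoints,
        "n_lr_pairs": len(lr_pairs),
        "gene_universe_policy": mds.gene_universe_policy,
    }

    # -- trajectories -------------------------------------------------------
    try:
        pt_by_section: dict[str, np.ndarray] = {}
        planar_by_timepoint: dict[str, list] = {tp: [] for tp in mds.timepoints}
        section_z = {s.section_id: s.z_um for s in mds.sections}
        pt_rows = []
        for section in mds.sections:
            result = compute_pseudotime(
                section, config.root_region, config.k_neighbors, config.n_pcs
            )
            pt_by_section[section.section_id] = result.values
            radius = config.adjacency_radius_factor * grid_spacing(section)
            graph = build_region_graph(
                section, result.values, radius, config.min_delta, config.min_adjacent
            )
            planar = extract_planar_trajectories(
                graph, config.root_region, section, result.values
            )
            planar_by_timepoint[section.timepoint].extend(planar)
            for i, spot in enumerate(section.spot_ids):
                pt_rows.append(
                    {
                        "section": section.section_id,
                        "timepoint": section.timepoint,
                        "spot": spot,
                        "region": section.region_labels[i],
                        "pseudotime": result.values[i],
                        "degenerate": result.degenerate,
                    }
                )
        trajectories = reconstruct_3d(
            planar_by_timepoint,
            section_z,
            min_support=config.min_support,
            merge_mode=config.merge_mode,
            bundle_rules=rules,
        )
        _write(pd.DataFrame(pt_rows), outdir / "pseudotime.tsv")
        _write(
            pd.DataFrame(
                {
                    "timepoint": [t.timepoint for t in trajectories],
                    "chain": ["->".join(t.chain) for t in trajectories],
                    "support": [t.support for t in trajectories],
                    "bundle": [t.bundle for t in trajectories],
                    "sections": [";".join(s for s, _ in t.supporting_sections) for t in trajectories],
                }
            ),
            outdir / "trajectories.tsv",
        )
    except Exception as e:
        raise PipelineError("trajectories", str(e)) from e
    report["stages"]["trajectories"] = {
        "n_planar": sum(len(v) for v in planar_by_timepoint.values()),
        "n_3d": len(trajectories),
    }

    # -- transition genes ---------------------------------------------------
    try:
        sets_3d: dict[tuple[tuple[str, ...], str], list] = {}
        tg_rows = []
        for traj in trajectories:
            sections = [mds.section(sid) for sid, _ in traj.supporting_sections]
            merged_sets = []
            for subtraj in zip(traj.chain[:-1], traj.chain[1:]):
                planar_sets = []
                for section in sections:
                    try:
                        planar_sets.append(
                            rank_transition_genes(
                                section,
                                subtraj,
                                pt_by_section[section.section_id],
                                k=config.top_k,
                            )
                        )
                    except ValueError:
                        continue  # subtrajectory too sparse in this section
                if not planar_sets:
                    continue
                merged = union_3d(planar_sets)
                merged_sets.append(merged)
                chain_id = "->".join(traj.chain)
                for direction, genes in (("up", merged.up), ("down", merged.down)):
                    for gene in genes:
                        tg_rows.append(
                            {
                                "trajectory": chain_id,
                                "timepoint": traj.timepoint,
                                "subtrajectory": f"{subtraj[0]}->{subtraj[1]}",
                                "gene": gene,
                                "rho": merged.scores[gene],
                                "direction": direction,
                            }
                        )
            if merged_sets:
                sets_3d[(traj.chain, traj.timepoint)] = merged_sets
        _write(pd.DataFrame(tg_rows), outdir / "transition_genes.tsv")
    except Exception as e:
        raise PipelineError("transition_genes", str(e)) from e
    report["stages"]["transition_genes"] = {"n_records": len(tg_rows)}

    # -- subtypes -----------------------------------------------------------
    try:
        profiles: dict[tuple[tuple[str, ...], str], object] = {}
        profile_rows = []
        for (chain, timepoint), merged_sets in sets_3d.items():
            profile = build_subtype_profile(merged_sets, "->".join(chain), timepoint)
            profiles[(chain, timepoint)] = profile
            for gene, sign in sorted(profile.markers.items()):
                profile_rows.append(
                    {
                        "trajectory": profile.trajectory_id,
                        "timepoint": timepoint,
                        "gene": gene,
                        "sign": sign,
                        "score": profile.scores.get(gene, np.nan),
                    }
                )
        sim_rows = []
        chains = sorted(set(chain for chain, _ in profiles), key="->".join)
        for chain in chains:
            tps = [tp for c, tp in profiles if c == chain]
            for i, tp_a in enumerate(tps):
                for tp_b in tps[i + 1 :]:
                    sim = subtype_similarity(profiles[(chain, tp_a)], profiles[(chain, tp_b)])
                    sim_rows.append(
                        {
                            "trajectory": "->".join(chain),
                            "timepoint_a": tp_a,
                            "timepoint_b": tp_b,
                            "similarity": sim,
                        }
                    )
        match_rows = []
        if marker_db is not None:
            for (chain, timepoint), profile in sorted(
                profiles.items(), key=lambda kv: ("->".join(kv[0][0]), kv[0][1])
            ):
                for rank, m in enumerate(
                    match_cell_types(profile, marker_db, config.top_n_celltypes), start=1
                ):
                    match_rows.append(
                        {
                            "trajectory": "->".join(chain),
                            "timepoint": timepoint,
                            "rank": rank,
                            "cell_type": m.cell_type,
                            "p_value": m.p_value,
                            "overlap": m.overlap,
                        }
                    )
        _write(pd.DataFrame(profile_rows), outdir / "subtype_profiles.tsv")
        _write(pd.DataFrame(sim_rows), outdir / "subtype_similarity.tsv")
        _write(pd.DataFrame(match_rows), outdir / "cell_type_matches.tsv")
    except Exception as e:
        raise PipelineError("subtypes", str(e)) from e
    report["stages"]["subtypes"] = {
        "n_profiles": len(profiles),
        "n_similarities": len(sim_rows),
        "n_matches": len(match_rows),
    }

    # -- communication ------------------------------------------------------
    try:
        density_tables = []
        spot_frames = []
        test_rows = []
        distinct_chains = sorted(set(t.chain for t in trajectories), key="->".join)
        mean_spacing = float(np.mean([grid_spacing(s) for s in mds.sections]))
        radius = config.adjacency_radius_factor * mean_spacing
        for chain in distinct_chains:
            table, results = communication_table(
                mds,
                chain,
                lr_pairs,
                "->".join(chain),
                neighbor_radius_um=radius,
                n_perm=config.n_perm,
                z_threshold=config.z_threshold,
                mode=config.discretize_mode,
                seed=config.seed,
            )
            density_tables.append(table)
            for r in results:
                spot_frames.append(
                    pd.DataFrame(
                        {
                            "trajectory": r.trajectory_id,
                            "timepoint": r.timepoint,
                            "pair": r.pair_id,
                            "spot": r.spot_ids,
                            "zscore": r.zscores,
                            "zt": r.zt,
                        }
                    )
                )
            if not table.empty and table["timepoint"].nunique() >= 2:
                groups = {
                    tp: sub["density"].to_numpy() for tp, sub in table.groupby("timepoint")
                }
                if min(len(v) for v in groups.values()) >= 2:
                    cmp = compare_densities(groups, method="asymptotic")
                    test_rows.append(
                        {
                            "trajectory": "->".join(chain),
                            "h_statistic": cmp.h_statistic,
                            "p_value": cmp.p_value,
                            "method": cmp.method,
                        }
                    )
        density = (
            pd.concat(density_tables, ignore_index=True) if density_tables else pd.DataFrame()
        )
        _write(density, outdir / "communication_density.tsv")
        spots = pd.concat(spot_frames, ignore_index=True) if spot_frames else pd.DataFrame()
        _write(spots, outdir / "communication_spots.tsv")
        _write(pd.DataFrame(test_rows), outdir / "density_tests.tsv")
    except Exception as e:
        raise PipelineError("communication", str(e)) from e
    report["stages"]["communication"] = {
        "n_density_records": 0 if density.empty else len(density),
        "n_tests": len(test_rows),
    }

    # -- pathways -----------------------------------------------------------
    try:
        pathway_rows = []
        if config.pathways_a and config.pathways_b:
            p_a = load_pathway_set(config.pathways_a)
            p_b = load_pathway_set(config.pathways_b)
            ps = pathway_set_similarity(p_a, p_b)
            pathway_rows.append(
                {
                    "n_a": len(ps.p_a),
                    "n_b": len(ps.p_b),
                    "n_mutual": len(ps.p_inter),
                    "mutual": ";".join(sorted(ps.p_inter)),
                    "similarity": ps.similarity,
                }
            )
        _write(pd.DataFrame(pathway_rows), outdir / "pathway_similarity.tsv")
    except Exception as e:
        raise PipelineError("pathways", str(e)) from e
    report["stages"]["pathways"] = {"n_records": len(pathway_rows)}

    checksums = {}
    for path in sorted(outdir.glob("*.tsv")):
        checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    report["checksums"] = checksums
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
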