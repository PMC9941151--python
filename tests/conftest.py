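"""Shared fixtures: synthetic datasets at the default study conditions."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import stacktraj as st
from stacktraj.pipeline import grid_spacing

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 3 timepoints x 3 sections x 400 spots."""
    return st.generate_dataset(st.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def dataset_200():
    """Default conditions at 200 spots per section (transition-gene checks)."""
    return st.generate_dataset(st.SyntheticConfig(spots_per_section=200, seed=0))


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    """Pseudotime + planar trajectories for every section of the default set."""
    mds, gt = default_dataset
    pt = {}
    planar = {tp: [] for tp in mds.timepoints}
    for section in mds.sections:
        res = st.compute_pseudotime(section, "VL")
        pt[section.section_id] = res.values
        graph = st.build_region_graph(
            section, res.values, 1.5 * grid_spacing(section)
        )
        planar[section.timepoint].extend(
            st.extract_planar_trajectories(graph, "VL", section, res.values)
        )
    section_z = {s.section_id: s.z_um for s in mds.sections}
    return {"pt": pt, "planar": planar, "section_z": section_z}


@pytest.fixture(scope="session")
def transition_recovery_rate(dataset_200):
    """Fraction of planted transition genes recovered in the correct 3D
    top-30 list, using estimated (not true) pseudotime."""
    mds, gt = dataset_200
    hits = total = 0
    for tp, sections in mds.sections_by_timepoint.items():
        pts = {s.section_id: st.compute_pseudotime(s, "VL").values for s in sections}
        for subtraj in gt.config.subtrajectories:
            merged = st.union_3d(
                [st.rank_transition_genes(s, subtraj, pts[s.section_id]) for s in sections]
            )
            truth = gt.transition_genes[(tp, subtraj)]
            for gene, sign in truth.items():
                hits += gene in (merged.up if sign > 0 else merged.down)
                total += 1
    return hits / total, total


@pytest.fixture(scope="session")
def disk_dataset(tmp_path_factory):
    """A compact dataset written to disk in the loader formats."""
    cfg = st.SyntheticConfig(
        n_sections_per_timepoint=2, spots_per_section=144, n_genes=450, seed=3
    )
    mds, gt = st.generate_dataset(cfg)
    outdir = tmp_path_factory.mktemp("dataset")
    manifest = st.simulate.write_dataset(mds, gt, outdir)
    return {"dir": outdir, "manifest": manifest, "mds": mds, "gt": gt, "config": cfg}


def make_section(
    coords: np.ndarray,
    regions: list[str],
    counts: np.ndarray,
    section_id: str = "s0",
    timepoint: str = "d3",
    gene_ids: list[str] | None = None,
) -> st.SectionDataset:
    """Hand-build a small validated section for unit tests."""
    import scipy.sparse as sp

    n, g = counts.shape
    return st.SectionDataset(
        section_id=section_id,
        timepoint=timepoint,
        z_um=0.0,
        spot_ids=[f"{section_id}:{i}" for i in range(n)],
        coords=np.asarray(coords, dtype=float),
        counts=sp.csr_matrix(np.asarray(counts)),
        gene_ids=gene_ids or [f"g{j}" for j in range(g)],
        region_labels=list(regions),
    ).validate()


@pytest.fixture
def section_factory():
    return make_section
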