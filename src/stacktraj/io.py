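"""Reading, validating and writing the on-disk formats.

A *section* is one planar Visium-like capture area: a spots x genes count
matrix (Matrix Market MTX + barcodes/features TSV), spot positions in the
Space Ranger ``tissue_positions`` dialect, and a per-spot anatomical region
annotation CSV.  Sections carry a z position (micrometres) so that serial
sections stack into a 3D dataset, and a time-point label so that stacks from
different post-injury days can be contrasted.

Supporting databases are plain TSV: ligand-receptor pairs (CellTalkDB
dialect, columns ``ligand_gene_symbol``/``receptor_gene_symbol``) and a
cell-type marker table (columns ``cell_type``/``gene``).  Pathway sets are
one identifier per line, or JSON arrays.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "DEFAULT_TIMEPOINTS",
    "LRPair",
    "MarkerDB",
    "MultiSectionDataset",
    "SectionDataset",
    "ValidationError",
    "load_lr_database",
    "load_marker_db",
    "load_multisection",
    "load_pathway_set",
    "load_section",
    "write_section",
]

#: Time-point vocabulary: unoperated control, needle-puncture sham, and
#: post-injury days 1/3/7.  Extensible through the manifest.
DEFAULT_TIMEPOINTS: tuple[str, ...] = ("control", "sham", "d1", "d3", "d7")


class ValidationError(ValueError):
    """An input file violates a dataset invariant."""


@dataclass
class SectionDataset:
    """One planar section: counts, coordinates, region labels, z position.

    Attributes
    ----------
    section_id
        Unique identifier of the section.
    timepoint
        Time-point label (see :data:`DEFAULT_TIMEPOINTS`).
    z_um
        Position of the section plane along the cutting axis, micrometres.
    spot_ids
        Spot barcodes, in the row order of ``counts``.
    coords
        ``(n_spots, 2)`` array of spot centres in micrometres.
    counts
        ``(n_spots, n_genes)`` non-negative integer count matrix (CSR).
    gene_ids
        Gene identifiers, in the column order of ``counts``.
    region_labels
        One anatomical region label per spot.
    meta
        Free-form metadata (loader bookkeeping, simulation provenance).
    """

    section_id: str
    timepoint: str
    z_um: float
    spot_ids: list[str]
    coords: np.ndarray
    counts: sp.csr_matrix
    gene_ids: list[str]
    region_labels: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> "SectionDataset":
        n, g = self.counts.shape
        if not (len(self.spot_ids) == len(self.region_labels) == n):
            raise ValidationError(
                f"section {self.section_id}: {len(self.spot_ids)} barcodes, "
                f"{len(self.region_labels)} region labels, {n} count rows"
            )
        if self.coords.shape != (n, 2):
            raise ValidationError(f"section {self.section_id}: coords shape {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"section {self.section_id}: non-finite coordinates")
        if len(set(self.gene_ids)) != g:
            raise ValidationError(f"section {self.section_id}: duplicate gene ids")
        if len(set(self.spot_ids)) != n:
            raise ValidationError(f"section {self.section_id}: duplicate spot barcodes")
        data = self.counts.data
        if data.size and not np.all(np.isfinite(data)):
            raise ValidationError(f"section {self.section_id}: non-finite counts")
        if data.size and data.min() < 0:
            r, c = _first_offending_cell(self.counts, lambda v: v < 0)
            raise ValidationError(
                f"section {self.section_id}: negative count at spot "
                f"{self.spot_ids[r]!r}, gene {self.gene_ids[c]!r}"
            )
        if data.size and np.any(data != np.round(data)):
            r, c = _first_offending_cell(self.counts, lambda v: v != np.round(v))
            raise ValidationError(
                f"section {self.section_id}: non-integer count at spot "
                f"{self.spot_ids[r]!r}, gene {self.gene_ids[c]!r}"
            )
        return self

    def to_anndata(self) -> AnnData:
        """View the section as an :class:`anndata.AnnData` for scanpy steps."""
        adata = AnnData(
            X=self.counts.astype(np.float32).copy(),
            obs=pd.DataFrame(
                {"region": pd.Categorical(self.region_labels)},
                index=pd.Index(self.spot_ids, name="barcode"),
            ),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene")),
        )
        adata.obsm["spatial"] = np.asarray(self.coords, dtype=float).copy()
        return adata

    def subset_genes(self, genes: Sequence[str]) -> "SectionDataset":
        """Restrict to ``genes`` (kept in the given order)."""
        index = {gid: j for j, gid in enumerate(self.gene_ids)}
        cols = [index[gene] for gene in genes]
        return SectionDataset(
            section_id=self.section_id,
            timepoint=self.timepoint,
            z_um=self.z_um,
            spot_ids=list(self.spot_ids),
            coords=self.coords.copy(),
            counts=sp.csr_matrix(self.counts[:, cols]),
            gene_ids=list(genes),
            region_labels=list(self.region_labels),
            meta=dict(self.meta),
        )


def _first_offending_cell(counts: sp.spmatrix, predicate) -> tuple[int, int]:
    coo = counts.tocoo()
    bad = np.nonzero(predicate(coo.data))[0]
    i = bad[0]
    return int(coo.row[i]), int(coo.col[i])


@dataclass
class MultiSectionDataset:
    """Serial sections grouped by time point under a shared gene universe.

    ``sections_by_timepoint`` maps each time-point label to its sections in
    increasing ``z_um`` order.  ``gene_universe_policy`` records whether the
    per-timepoint gene universe is the intersection or the union of the
    member sections' gene sets; under ``intersection`` every section is
    subset to the shared (sorted) universe, under ``union`` sections keep
    their own gene sets and genes absent from a section are treated as not
    measured there.
    """

    sections_by_timepoint: dict[str, list[SectionDataset]]
    gene_universe_policy: str = "intersection"
    gene_universe: dict[str, list[str]] = field(default_factory=dict)

    @property
    def timepoints(self) -> list[str]:
        return list(self.sections_by_timepoint)

    @property
    def sections(self) -> list[SectionDataset]:
        return [s for group in self.sections_by_timepoint.values() for s in group]

    def section(self, section_id: str) -> SectionDataset:
        for s in self.sections:
            if s.section_id == section_id:
                return s
        raise KeyError(section_id)


@dataclass(frozen=True)
class LRPair:
    """A ligand-receptor gene pair.  Identity is case-insensitive."""

    ligand_gene: str
    receptor_gene: str

    @property
    def pair_id(self) -> str:
        return f"{self.ligand_gene.upper()}_{self.receptor_gene.upper()}"


@dataclass
class MarkerDB:
    """Local cell-type marker table: ``cell_type -> set of gene symbols``.

    Gene symbols are stored uppercased so lookups are case-insensitive.
    """

    markers: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for cell_type, genes in self.markers.items():
            if not genes:
                raise ValidationError(f"cell type {cell_type!r} has an empty marker set")

    @property
    def cell_types(self) -> list[str]:
        return list(self.markers)

    @property
    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.markers.values():
            out |= genes
        return frozenset(out)


# ---------------------------------------------------------------------------
# section loading / writing
# ---------------------------------------------------------------------------

_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def load_section(
    counts_dir: str | Path,
    positions_path: str | Path,
    regions_path: str | Path,
    meta: Mapping,
) -> SectionDataset:
    """Load and validate one section from disk.

    Parameters
    ----------
    counts_dir
        Directory containing ``matrix.mtx`` (genes x spots, Matrix Market),
        ``barcodes.tsv`` and ``features.tsv``.
    positions_path
        Space-Ranger-style ``tissue_positions`` CSV with header
        ``barcode,in_tissue,array_row,array_col,pxl_row_in_fullres,pxl_col_in_fullres``.
        Only ``in_tissue == 1`` spots are retained; pixel coordinates are
        converted to micrometres via ``meta['microns_per_pixel']``.
    regions_path
        CSV with header ``barcode,region`` covering every in-tissue barcode.
    meta
        Mapping with keys ``section_id``, ``timepoint``, ``z_um`` and
        optionally ``microns_per_pixel`` (default 1.0) and
        ``extra_timepoints`` (labels accepted beyond the default vocabulary).
    """
    counts_dir = Path(counts_dir)
    for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (counts_dir / name).is_file():
            raise FileNotFoundError(counts_dir / name)
    for p in (positions_path, regions_path):
        if not Path(p).is_file():
            raise FileNotFoundError(p)

    timepoint = str(meta["timepoint"])
    allowed = set(DEFAULT_TIMEPOINTS) | set(meta.get("extra_timepoints", ()))
    if timepoint not in allowed:
        raise ValidationError(
            f"unknown timepoint {timepoint!r}; expected one of {sorted(allowed)}"
        )

    matrix = sp.csr_matrix(scipy.io.mmread(counts_dir / "matrix.mtx").T)  # spots x genes
    barcodes = pd.read_csv(counts_dir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    features = pd.read_csv(counts_dir / "features.tsv", sep="\t", header=None)
    gene_ids = features[0].astype(str).tolist()
    if matrix.shape != (len(barcodes), len(gene_ids)):
        raise ValidationError(
            f"matrix shape {matrix.shape} does not match {len(barcodes)} barcodes "
            f"x {len(gene_ids)} features"
        )

    positions = pd.read_csv(positions_path)
    missing_cols = set(_POSITION_COLUMNS) - set(positions.columns)
    if missing_cols:
        raise ValidationError(f"positions file missing columns {sorted(missing_cols)}")
    positions = positions.set_index(positions["barcode"].astype(str))

    regions = pd.read_csv(regions_path)
    if not {"barcode", "region"} <= set(regions.columns):
        raise ValidationError("region annotation must have columns barcode,region")
    regions = regions.set_index(regions["barcode"].astype(str))
    if regions.index.has_duplicates:
        raise ValidationError("duplicate barcodes in region annotation")

    missing_pos = [b for b in barcodes if b not in positions.index]
    if missing_pos:
        raise ValidationError(
            f"barcode mismatch: {len(missing_pos)} count barcodes absent from "
            f"positions file (first: {missing_pos[0]!r})"
        )

    in_tissue = positions.loc[barcodes, "in_tissue"].to_numpy().astype(int) == 1
    keep = np.nonzero(in_tissue)[0]
    kept_barcodes = [barcodes.iloc[i] for i in keep]

    missing_reg = [b for b in kept_barcodes if b not in regions.index]
    if missing_reg:
        raise ValidationError(
            f"barcode mismatch: {len(missing_reg)} in-tissue barcodes absent from "
            f"region annotation (first: {missing_reg[0]!r})"
        )

    scale = float(meta.get("microns_per_pixel", 1.0))
    px = positions.loc[kept_barcodes, ["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy(float)
    coords = px * scale

    dataset = SectionDataset(
        section_id=str(meta["section_id"]),
        timepoint=timepoint,
        z_um=float(meta["z_um"]),
        spot_ids=kept_barcodes,
        coords=coords,
        counts=sp.csr_matrix(matrix[keep]),
        gene_ids=gene_ids,
        region_labels=regions.loc[kept_barcodes, "region"].astype(str).tolist(),
        meta={
            "n_input_spots": int(len(barcodes)),
            "n_retained": int(len(keep)),
            "n_rejected": int(len(barcodes) - len(keep)),
            "microns_per_pixel": scale,
        },
    )
    return dataset.validate()


def write_section(dataset: SectionDataset, outdir: str | Path, microns_per_pixel: float = 1.0) -> dict:
    """Write a section in the exact formats :func:`load_section` reads.

    Returns the ``meta`` mapping to place in a manifest entry.
    """
    outdir = Path(outdir)
    counts_dir = outdir / "counts"
    counts_dir.mkdir(parents=True, exist_ok=True)

    scipy.io.mmwrite(counts_dir / "matrix.mtx", sp.coo_matrix(dataset.counts.T.astype(np.int64)))
    pd.Series(dataset.spot_ids).to_csv(counts_dir / "barcodes.tsv", sep="\t", header=False, index=False)
    features = pd.DataFrame(
        {0: dataset.gene_ids, 1: dataset.gene_ids, 2: "Gene Expression"}
    )
    features.to_csv(counts_dir / "features.tsv", sep="\t", header=False, index=False)

    n = dataset.n_spots
    positions = pd.DataFrame(
        {
            "barcode": dataset.spot_ids,
            "in_tissue": np.ones(n, dtype=int),
            "array_row": np.zeros(n, dtype=int),
            "array_col": np.arange(n, dtype=int),
            "pxl_row_in_fullres": dataset.coords[:, 1] / microns_per_pixel,
            "pxl_col_in_fullres": dataset.coords[:, 0] / microns_per_pixel,
        }
    )
    positions.to_csv(outdir / "tissue_positions.csv", index=False)
    pd.DataFrame({"barcode": dataset.spot_ids, "region": dataset.region_labels}).to_csv(
        outdir / "regions.csv", index=False
    )
    return {
        "section_id": dataset.section_id,
        "timepoint": dataset.timepoint,
        "z_um": dataset.z_um,
        "microns_per_pixel": microns_per_pixel,
        "counts_dir": str(counts_dir),
        "positions": str(outdir / "tissue_positions.csv"),
        "regions": str(outdir / "regions.csv"),
    }


# ---------------------------------------------------------------------------
# multi-section assembly
# ---------------------------------------------------------------------------


def load_multisection(manifest_path: str | Path) -> MultiSectionDataset:
    """Assemble a multi-section dataset from a JSON manifest.

    The manifest lists per-section entries (``section_id``, ``timepoint``,
    ``z_um``, ``counts_dir``, ``positions``, ``regions``, optional
    ``microns_per_pixel``) plus optional top-level keys ``gene_universe``
    (``"intersection"``, the default, or ``"union"``) and ``timepoints``
    (extra accepted labels).  Relative paths are resolved against the
    manifest location.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    entries = manifest.get("sections", [])
    if not entries:
        raise ValidationError("manifest lists no sections")
    policy = manifest.get("gene_universe", "intersection")
    if policy not in ("intersection", "union"):
        raise ValidationError(f"unknown gene_universe policy {policy!r}")
    extra_timepoints = manifest.get("timepoints", [])

    seen_ids: set[str] = set()
    groups: dict[str, list[SectionDataset]] = {}
    for entry in entries:
        meta = dict(entry)
        meta.setdefault("microns_per_pixel", manifest.get("microns_per_pixel", 1.0))
        meta["extra_timepoints"] = extra_timepoints
        base = manifest_path.parent
        section = load_section(
            base / entry["counts_dir"],
            base / entry["positions"],
            base / entry["regions"],
            meta,
        )
        if section.section_id in seen_ids:
            raise ValidationError(f"duplicate section_id {section.section_id!r}")
        seen_ids.add(section.section_id)
        groups.setdefault(section.timepoint, []).append(section)

    universes: dict[str, list[str]] = {}
    for timepoint, sections in groups.items():
        zs = [s.z_um for s in sections]
        if len(set(zs)) != len(zs):
            raise ValidationError(f"duplicate z_um within timepoint {timepoint!r}")
        sections.sort(key=lambda s: s.z_um)
        gene_sets = [set(s.gene_ids) for s in sections]
        if policy == "intersection":
            shared = sorted(set.intersection(*gene_sets))
            groups[timepoint] = [s.subset_genes(shared) for s in sections]
            universes[timepoint] = shared
        else:
            universes[timepoint] = sorted(set.union(*gene_sets))

    return MultiSectionDataset(
        sections_by_timepoint=groups,
        gene_universe_policy=policy,
        gene_universe=universes,
    )


# ---------------------------------------------------------------------------
# databases
# ---------------------------------------------------------------------------


def load_lr_database(path: str | Path) -> list[LRPair]:
    """Load ligand-receptor pairs from a CellTalkDB-dialect TSV.

    Rows with an empty ligand or receptor field are skipped with a warning;
    duplicate pairs (case-insensitive) are dropped, keeping file order.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"ligand_gene_symbol", "receptor_gene_symbol"}
    if not required <= set(table.columns):
        raise ValidationError(f"LR database must have columns {sorted(required)}")
    if table.empty:
        raise ValidationError("LR database is empty")

    pairs: list[LRPair] = []
    seen: set[str] = set()
    n_skipped = 0
    for ligand, receptor in zip(table["ligand_gene_symbol"], table["receptor_gene_symbol"]):
        if pd.isna(ligand) or pd.isna(receptor) or not str(ligand).strip() or not str(receptor).strip():
            n_skipped += 1
            continue
        pair = LRPair(str(ligand).strip(), str(receptor).strip())
        if pair.pair_id in seen:
            continue
        seen.add(pair.pair_id)
        pairs.append(pair)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} LR rows with empty fields", stacklevel=2)
    return pairs


def load_marker_db(path: str | Path) -> MarkerDB:
    """Load a cell-type marker TSV with columns ``cell_type`` and ``gene``."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_type", "gene"} <= set(table.columns):
        raise ValidationError("marker database must have columns cell_type,gene")
    if table.empty:
        raise ValidationError("marker database is empty")
    markers: dict[str, set[str]] = {}
    for cell_type, gene in zip(table["cell_type"], table["gene"]):
        if pd.isna(cell_type) or pd.isna(gene):
            continue
        markers.setdefault(str(cell_type), set()).add(str(gene).upper())
    return MarkerDB({ct: frozenset(genes) for ct, genes in markers.items()})


def load_pathway_set(path: str | Path) -> list[str]:
    """Load a pathway-ID set: one ID per line, or a JSON array."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        ids = json.loads(text)
        if not isinstance(ids, list):
            raise ValidationError("JSON pathway set must be an array")
    else:
        ids = [line.strip() for line in text.splitlines() if line.strip()]
    out: list[str] = []
    seen: set[str] = set()
    for pid in ids:
        pid = str(pid).strip()
        if pid and pid not in seen:
            seen.add(pid)
            out.append(pid)
    return out
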