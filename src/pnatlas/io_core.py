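"""Data model, file I/O, configuration and logging.

The central container is :class:`ExpressionDataset`: a genes x cells raw
count matrix with lazily computed CPM and log2(CPM+1) layers, plus cell and
gene annotation tables keyed by the matrix identifiers.  Counts travel as
Matrix Market sparse files with gene/cell TSV sidecars (the layout the
field's deposition archives use) or as dense CSV; all derived outputs are
plain TSV/JSON with deterministic field ordering.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("pnatlas")

#: Default ordered developmental stages: 0 h APF, 24 h APF, 48 h APF, adult.
DEFAULT_STAGES: tuple[str, ...] = ("P0", "P24", "P48", "Adult")

#: Neuroblast-lineage labels: anterodorsal and lateral excitatory PN
#: lineages, ventral (inhibitory) PNs, and the anterior paired lateral neuron.
LINEAGES: tuple[str, ...] = ("adPN", "lPN", "vPN", "APL")

#: Lineages carrying the excitatory (cholinergic) neurotransmitter program.
EXCITATORY_LINEAGES: tuple[str, ...] = ("adPN", "lPN")

#: Canonical pan-neuronal marker panel used by the neuronal QC filter.
NEURONAL_MARKER_PANEL_SIZE = 6

CELL_COLUMNS = ["stage", "lineage", "type_label", "birth_rank", "total_reads", "qc_pass"]
GENE_COLUMNS = ["role", "is_neuronal_marker"]

FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """Malformed input file (header/sidecar disagreement and the like)."""


class ValidationError(ValueError):
    """Input violates a data-model invariant."""


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Genes x cells counts with derived CPM / log2(CPM+1) layers.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes in rows, cells in columns.
    gene_ids, cell_ids
        Ordered unique identifiers; matrix order is authoritative.
    cells, genes
        Annotation tables indexed by the respective identifiers.  Missing
        columns are created with null/default values.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cells: pd.DataFrame = None  # type: ignore[assignment]
    genes: pd.DataFrame = None  # type: ignore[assignment]
    cpm: np.ndarray | None = None
    logcpm: np.ndarray | None = None
    stage_order: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D genes x cells matrix")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell_ids")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.cells is None:
            self.cells = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.cells = self.cells.copy()
            self.cells.index = pd.Index(self.cell_ids, name="cell_id")
        for col, default in (
            ("stage", None), ("lineage", None), ("type_label", None),
            ("birth_rank", np.nan), ("total_reads", np.nan), ("qc_pass", True),
        ):
            if col not in self.cells.columns:
                self.cells[col] = default
        if self.genes is None:
            self.genes = pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        else:
            self.genes = self.genes.copy()
            self.genes.index = pd.Index(self.gene_ids, name="gene_id")
        if "role" not in self.genes.columns:
            self.genes["role"] = "housekeeping"
        if "is_neuronal_marker" not in self.genes.columns:
            self.genes["is_neuronal_marker"] = False

    # -- basic properties ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"unknown gene id {exc.args[0]!r}") from None

    def require_logcpm(self) -> np.ndarray:
        if self.logcpm is None:
            raise ValidationError("logcpm layer not computed; run cpm_normalize first")
        return self.logcpm

    # -- subsetting ---------------------------------------------------------
    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        """Return a new dataset keeping cells where ``mask`` is True (order kept)."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_cells,):
            raise ValidationError("cell mask has wrong length")
        idx = np.flatnonzero(mask)
        return ExpressionDataset(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            cells=self.cells.iloc[idx],
            genes=self.genes,
            cpm=None if self.cpm is None else self.cpm[:, idx],
            logcpm=None if self.logcpm is None else self.logcpm[:, idx],
            stage_order=self.stage_order,
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        """Return a new dataset restricted to ``gene_ids`` (given order)."""
        idx = self.gene_index(gene_ids)
        return ExpressionDataset(
            counts=self.counts[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            cells=self.cells,
            genes=self.genes.iloc[idx],
            cpm=None if self.cpm is None else self.cpm[idx, :],
            logcpm=None if self.logcpm is None else self.logcpm[idx, :],
            stage_order=self.stage_order,
        )

    def subset_stage(self, stage: str) -> "ExpressionDataset":
        return self.subset_cells((self.cells["stage"] == stage).to_numpy())

    def subset_lineage(self, lineages: str | Sequence[str]) -> "ExpressionDataset":
        if isinstance(lineages, str):
            lineages = [lineages]
        return self.subset_cells(self.cells["lineage"].isin(lineages).to_numpy())

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.counts, other.counts)
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_id_column(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_counts_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    *,
    transpose: bool = False,
) -> ExpressionDataset:
    """Read a Matrix Market coordinate count matrix with TSV sidecars.

    The sidecars list gene and cell identifiers in matrix order, one per
    line (first tab-separated field).  ``transpose=True`` accepts matrices
    stored cells x genes.
    """
    matrix_path, genes_path, cells_path = Path(matrix_path), Path(genes_path), Path(cells_path)
    for p in (matrix_path, genes_path, cells_path):
        if not p.exists():
            raise FileNotFoundError(p)
    mat = scipy.io.mmread(matrix_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    if transpose:
        mat = mat.T
    if np.issubdtype(mat.dtype, np.floating) and not np.all(mat == np.round(mat)):
        raise ValidationError(f"{matrix_path}: non-integer count entries")
    if mat.size and mat.min() < 0:
        raise ValidationError(f"{matrix_path}: negative count entries")
    gene_ids = _read_id_column(genes_path)
    cell_ids = _read_id_column(cells_path)
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"matrix is {mat.shape[0]}x{mat.shape[1]} but sidecars list "
            f"{len(gene_ids)} genes and {len(cell_ids)} cells"
        )
    return ExpressionDataset(counts=mat.astype(np.int64), gene_ids=gene_ids, cell_ids=cell_ids)


def read_counts_csv(path: str | Path, *, transpose: bool = False) -> ExpressionDataset:
    """Read a dense CSV: first column gene ids, header row cell ids."""
    df = pd.read_csv(path, index_col=0)
    if transpose:
        df = df.T
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dupes}")
    values = df.to_numpy()
    if values.size and (np.issubdtype(values.dtype, np.floating)
                        and not np.all(values == np.round(values))):
        raise ValidationError("non-integer count entries")
    return ExpressionDataset(
        counts=values.astype(np.int64) if values.size else values.reshape(df.shape).astype(np.int64),
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
    )


def read_cell_metadata(dataset: ExpressionDataset, path: str | Path) -> ExpressionDataset:
    """Attach a metadata TSV (cell_id, stage, lineage, type_label, birth_rank, ...)."""
    meta = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    if "cell_id" not in meta.columns:
        raise FormatError("metadata table must have a cell_id column")
    meta = meta.set_index("cell_id")
    missing = set(dataset.cell_ids) - set(meta.index)
    if missing:
        raise ValidationError(f"metadata missing {len(missing)} cell ids")
    meta = meta.loc[dataset.cell_ids]
    for col in meta.columns:
        dataset.cells[col] = meta[col].to_numpy()
    return dataset


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_counts_mtx(dataset: ExpressionDataset, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "genes": out_dir / "genes.tsv",
        "cells": out_dir / "cells.tsv",
        "metadata": out_dir / "metadata.tsv",
    }
    scipy.io.mmwrite(paths["matrix"], scipy.sparse.coo_matrix(dataset.counts), field="integer")
    paths["genes"].write_text("".join(f"{g}\n" for g in dataset.gene_ids))
    paths["cells"].write_text("".join(f"{c}\n" for c in dataset.cell_ids))
    meta = dataset.cells.reset_index()
    meta.to_csv(paths["metadata"], sep="\t", index=False, float_format=FLOAT_FMT)
    return paths


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(result, out_dir: str | Path, *, name: str | None = None) -> list[Path]:
    """Write a pipeline result to ``out_dir`` as TSV tables + a JSON summary.

    Dispatches on the result object: dataclasses with ``to_frames`` /
    ``summary`` hooks use them; bare DataFrames become one TSV; mappings
    become one JSON file.  Field ordering is deterministic.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    base = name or type(result).__name__.lower()
    written: list[Path] = []
    frames: Mapping[str, pd.DataFrame] = {}
    summary = None
    if hasattr(result, "to_frames"):
        frames = result.to_frames()
    elif isinstance(result, pd.DataFrame):
        frames = {base: result}
    if hasattr(result, "summary"):
        summary = result.summary()
    elif isinstance(result, Mapping):
        summary = dict(result)
    elif dataclasses.is_dataclass(result) and not frames:
        summary = dataclasses.asdict(result)

    for key in sorted(frames):
        path = out_dir / f"{key}.tsv"
        frames[key].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        written.append(path)
    if summary is not None:
        path = out_dir / f"{base}_summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n")
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Tunable parameters for every pipeline stage, with literature defaults.

    QC: cells need >= ``min_reads`` total reads and >= ``marker_min_count``
    of the neuronal panel genes at >= ``marker_min_expr`` log2(CPM+1).
    DE keeps genes at BH-adjusted p < ``de_alpha``; stage-pair lists take the
    ``top_k_pairs`` most significant genes; bootstrap and permutation
    iteration counts default to 1000 and 5000 draws.
    """

    min_reads: int = 100_000
    marker_min_expr: float = 8.0
    marker_min_count: int = 2
    n_top_overdispersed: int = 500
    n_dispersion_bins: int = 20
    icim_min_cells: int = 10
    icim_max_depth: int = 8
    icim_min_markers: int = 5
    min_cluster_size: int = 15
    min_samples: int | None = None
    resolution: float = 1.0
    knn_k: int = 15
    de_alpha: float = 0.01
    top_k_pairs: int = 150
    expr_threshold: float = 4.0
    frac_threshold: float = 0.5
    max_pair_search: int = 200
    n_bootstrap: int = 1000
    n_permutations: int = 5000
    min_group: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.de_alpha < 1.0):
            raise ValidationError("de_alpha must lie in (0, 1)")
        for attr in ("n_bootstrap", "n_permutations", "top_k_pairs"):
            if getattr(self, attr) < 1:
                raise ValidationError(f"{attr} must be >= 1")
        if self.min_reads < 0:
            raise ValidationError("min_reads must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Parse a plain-text ``key = value`` config file; kwargs override."""
        values: dict[str, object] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key = value")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise FormatError(f"{path}:{lineno}: unknown key {key!r}")
            if raw.lower() in ("none", "null"):
                values[key] = None
            elif fields[key].type in ("float", float):
                values[key] = float(raw)
            else:
                try:
                    values[key] = int(raw)
                except ValueError:
                    values[key] = float(raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)  # type: ignore[arg-type]

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


def stage_sort_key(stages: Sequence[str], order: Sequence[str] = DEFAULT_STAGES):
    """Return stages sorted by the dataset's total stage order."""
    rank = {s: i for i, s in enumerate(order)}
    unknown = [s for s in stages if s not in rank]
    if unknown:
        warnings.warn(f"stages {unknown} not in declared order; appended alphabetically")
    return sorted(stages, key=lambda s: (rank.get(s, len(rank)), s))
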