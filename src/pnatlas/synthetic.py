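"""Synthetic multi-stage PN count matrices with planted ground truth.

The generator emulates the statistical structure of a stage-resolved
SMART-seq2 census of olfactory projection neurons: four ordered
developmental stages; two excitatory neuroblast lineages (15 anterodorsal
and 10 lateral types) plus small inhibitory populations (3 ventral PN
types, 1 APL); per-type marker genes whose separability peaks at the
second stage (circuit assembly) and fades towards adulthood; global
monotone stage programs (five down-regulated and two up-regulated
sub-profiles); a pruning module elevated only in embryonic-born
anterodorsal types at the first stage; birth-order expression gradients
present early and fully attenuated by the third stage; and
neurotransmitter programs separating excitatory from inhibitory cells most
strongly at the adult stage.

Counts are negative-binomial draws: per-cell expected expression is the
softmax of gene baselines plus additive log-scale effects, multiplied by a
log-normal library size, so CPM semantics are exact by construction.
Effect sizes default to values typical of neuronal cell-type markers
(near on/off: ~4.5 log2 units at the peak stage, ~2.3 at the trough) and
developmentally regulated genes (~3 log2 units across the time course);
the pruning and birth-order modules are planted at smaller amplitudes so
the type-effect schedule remains the dominant within-stage structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    DEFAULT_STAGES,
    EXCITATORY_LINEAGES,
    ExpressionDataset,
    ValidationError,
    logger,
    write_counts_mtx,
)

LN2 = float(np.log(2.0))

#: Canonical pan-neuronal genes used as the QC marker panel.
NEURONAL_PANEL = ("elav", "brp", "Syt1", "nSyb", "CadN", "mCD8-GFP")

#: Monotone-decreasing stage sub-profiles (multiplier on the program
#: amplitude per stage); five distinct shapes as in the down-regulated
#: gene groups the dynamics module recovers.
DOWN_SHAPES = (
    (1.0, 0.66, 0.33, 0.0),
    (1.0, 0.90, 0.55, 0.0),
    (1.0, 0.45, 0.10, 0.0),
    (1.0, 0.80, 0.60, 0.35),
    (1.0, 0.35, 0.15, 0.05),
)
#: Monotone-increasing sub-profiles (two up-regulated groups).
UP_SHAPES = (
    (0.0, 0.33, 0.66, 1.0),
    (0.0, 0.55, 0.85, 1.0),
)

#: Neurotransmitter classes and the lineages that carry each program.
NT_CLASSES = {"ACh": ("adPN", "lPN"), "GABA": ("APL",), "Glut": ("vPN",)}


@dataclass
class SimConfig:
    """Generator parameters; defaults define the emulated study conditions."""

    seed: int = 0
    n_genes: int = 5000
    stages: tuple[str, ...] = DEFAULT_STAGES
    lineage_spec: dict = field(
        default_factory=lambda: {"adPN": 15, "lPN": 10, "vPN": 3, "APL": 1})
    cells_per_type_per_stage: int = 30
    # log-normal gene baselines and library sizes (natural-log parameters)
    baseline_logmean_mu: float = 0.0
    baseline_logmean_sigma: float = 1.5
    library_size_mu: float = float(np.log(500_000.0))
    library_size_sigma: float = 0.7
    # type identity.  Marker baselines are drawn low (off state near zero
    # expression) so markers are on/off across types, as canonical
    # type markers are.
    markers_per_type: int = 10
    marker_lfc: float = 4.5  # log2 fold-change at the schedule peak
    marker_baseline_mu: float = -2.0
    marker_baseline_sigma: float = 0.8
    type_effect_schedule: tuple[float, ...] = (0.6, 1.0, 0.8, 0.5)
    # global stage programs
    n_stage_down: int = 150  # spread over len(DOWN_SHAPES) sub-profiles
    n_stage_up: int = 60     # spread over len(UP_SHAPES) sub-profiles
    stage_program_lfc: float = 3.0  # log2 amplitude first-to-last stage
    # pruning module (embryonic-born adPN subset, first stage only)
    pruning_frac: float = 0.3
    n_pruning: int = 20
    pruning_lfc: float = 2.0
    # birth-order gradients
    n_gradient: int = 15
    gradient_slope: float = 0.15  # log2 per birth-rank step; sign alternates
    gradient_attenuation: tuple[float, ...] = (1.0, 0.6, 0.0, 0.0)
    # neurotransmitter programs
    nt_genes_per_class: int = 2
    nt_lfc: float = 3.0
    nt_schedule: tuple[float, ...] = (0.5, 0.5, 0.5, 1.0)
    # counts
    dispersion: float = 10.0  # negative-binomial shape (larger = less noise)
    panel_baseline_mu: float = 3.0
    panel_baseline_sigma: float = 0.2

    def __post_init__(self) -> None:
        n_stages = len(self.stages)
        for name in ("type_effect_schedule", "gradient_attenuation", "nt_schedule"):
            sched = getattr(self, name)
            if len(sched) != n_stages:
                raise ValidationError(
                    f"{name} has {len(sched)} entries for {n_stages} stages")
            if not np.all(np.isfinite(sched)):
                raise ValidationError(f"{name} entries must be finite")
        if self.cells_per_type_per_stage < 1 or self.n_genes < 1:
            raise ValidationError("counts must be positive")
        for name in ("marker_lfc", "stage_program_lfc", "pruning_lfc",
                     "gradient_slope", "nt_lfc"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")

    @property
    def n_types(self) -> int:
        return int(sum(self.lineage_spec.values()))

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        """Load generator parameters from a JSON file (tuples accepted as lists)."""
        raw = json.loads(Path(path).read_text())
        for key in ("stages", "type_effect_schedule", "gradient_attenuation",
                    "nt_schedule"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def type_table(self) -> pd.DataFrame:
        """One row per planted type: label, lineage, birth rank, embryonic flag."""
        rows = []
        for lineage, n in self.lineage_spec.items():
            n_embryonic = int(round(self.pruning_frac * n)) if lineage == "adPN" else 0
            for r in range(1, n + 1):
                ranked = lineage in EXCITATORY_LINEAGES
                rows.append({
                    "type_label": f"{lineage}_{r:02d}",
                    "lineage": lineage,
                    "birth_rank": r if ranked else np.nan,
                    "embryonic_born": lineage == "adPN" and r <= n_embryonic,
                })
        return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Planted truth: per-cell identities, gene roles, cross-stage type map."""

    cells: pd.DataFrame   # cell_id, stage, lineage, type_label, birth_rank, embryonic_born
    genes: pd.DataFrame   # gene_id, role, marker_type, program, slope, nt_class
    type_map: dict        # persistent type identity across stages (bijection)
    config: SimConfig

    def markers_of(self, type_label: str) -> list[str]:
        sel = self.genes["marker_type"] == type_label
        return list(self.genes.index[sel])


def _assign_gene_roles(cfg: SimConfig, types: pd.DataFrame) -> pd.DataFrame:
    """Lay out gene roles over gene ids (panel first, then planted effects)."""
    n_nt = cfg.nt_genes_per_class * len(NT_CLASSES)
    needed = (len(NEURONAL_PANEL) + cfg.n_types * cfg.markers_per_type
              + cfg.n_stage_down + cfg.n_stage_up + cfg.n_pruning
              + cfg.n_gradient + n_nt)
    if needed > cfg.n_genes:
        raise ValidationError(f"n_genes={cfg.n_genes} too small for {needed} planted genes")
    width = len(str(cfg.n_genes))
    gene_ids = list(NEURONAL_PANEL) + [
        f"g{i:0{width}d}" for i in range(cfg.n_genes - len(NEURONAL_PANEL))]
    genes = pd.DataFrame(
        {"role": "housekeeping", "marker_type": None, "program": None,
         "slope": np.nan, "nt_class": None,
         "is_neuronal_marker": False},
        index=pd.Index(gene_ids, name="gene_id"))
    genes.loc[list(NEURONAL_PANEL), "role"] = "panel"
    genes.loc[list(NEURONAL_PANEL), "is_neuronal_marker"] = True
    cursor = len(NEURONAL_PANEL)

    def take(n: int) -> list[str]:
        nonlocal cursor
        ids = gene_ids[cursor:cursor + n]
        cursor += n
        return ids

    for t in types["type_label"]:
        ids = take(cfg.markers_per_type)
        genes.loc[ids, "role"] = f"marker:{t}"
        genes.loc[ids, "marker_type"] = t
    for kind, total, shapes in (("stage_down", cfg.n_stage_down, DOWN_SHAPES),
                                ("stage_up", cfg.n_stage_up, UP_SHAPES)):
        per = max(1, total // len(shapes))
        assigned = 0
        for si in range(len(shapes)):
            n_here = per if si < len(shapes) - 1 else total - assigned
            ids = take(n_here)
            genes.loc[ids, "role"] = kind
            genes.loc[ids, "program"] = f"{kind}_{si}"
            assigned += n_here
    ids = take(cfg.n_pruning)
    genes.loc[ids, "role"] = "pruning"
    ids = take(cfg.n_gradient)
    genes.loc[ids, "role"] = "gradient"
    slopes = np.where(np.arange(cfg.n_gradient) % 2 == 0, 1.0, -1.0) * cfg.gradient_slope
    genes.loc[ids, "slope"] = slopes
    for cls in NT_CLASSES:
        ids = take(cfg.nt_genes_per_class)
        genes.loc[ids, "role"] = f"neurotransmitter:{cls}"
        genes.loc[ids, "nt_class"] = cls
    return genes


def expected_log2_effects(cfg: SimConfig, genes: pd.DataFrame,
                          cells: pd.DataFrame) -> np.ndarray:
    """Deterministic planted log2 effect for every (gene, cell) pair.

    This is the additive (log2-scale) term on top of each gene's baseline;
    ``simulate`` exponentiates it, so tests can verify planted structure
    against exactly the quantity the generator used.
    """
    stage_idx = {s: i for i, s in enumerate(cfg.stages)}
    s_of = cells["stage"].map(stage_idx).to_numpy()
    n_genes, n_cells = len(genes), len(cells)
    E = np.zeros((n_genes, n_cells), dtype=np.float64)

    sched = np.asarray(cfg.type_effect_schedule, dtype=float)[s_of]
    marker_type = genes["marker_type"].to_numpy()
    cell_type = cells["type_label"].to_numpy()
    for gi in np.flatnonzero(pd.notna(marker_type)):
        E[gi, cell_type == marker_type[gi]] += cfg.marker_lfc * sched[cell_type == marker_type[gi]]

    shapes = {f"stage_down_{i}": np.asarray(s) for i, s in enumerate(DOWN_SHAPES)}
    shapes.update({f"stage_up_{i}": np.asarray(s) for i, s in enumerate(UP_SHAPES)})
    program = genes["program"].to_numpy()
    for gi in np.flatnonzero(pd.notna(program)):
        E[gi, :] += cfg.stage_program_lfc * shapes[program[gi]][s_of]

    pruning_rows = np.flatnonzero((genes["role"] == "pruning").to_numpy())
    pruning_cells = (cells["embryonic_born"].to_numpy(dtype=bool)) & (s_of == 0)
    E[np.ix_(pruning_rows, np.flatnonzero(pruning_cells))] += cfg.pruning_lfc

    atten = np.asarray(cfg.gradient_attenuation, dtype=float)[s_of]
    rank = cells["birth_rank"].to_numpy(dtype=float)
    centered = np.zeros(n_cells)
    for lineage in EXCITATORY_LINEAGES:
        sel = (cells["lineage"] == lineage).to_numpy() & ~np.isnan(rank)
        if sel.any():
            centered[sel] = rank[sel] - (cfg.lineage_spec.get(lineage, 0) + 1) / 2.0
    grad_rows = np.flatnonzero((genes["role"] == "gradient").to_numpy())
    slopes = genes["slope"].to_numpy(dtype=float)
    for gi in grad_rows:
        E[gi, :] += slopes[gi] * centered * atten

    nt_sched = np.asarray(cfg.nt_schedule, dtype=float)[s_of]
    nt_class = genes["nt_class"].to_numpy()
    cell_lineage = cells["lineage"].to_numpy()
    for gi in np.flatnonzero(pd.notna(nt_class)):
        carrier = np.isin(cell_lineage, NT_CLASSES[nt_class[gi]])
        E[gi, carrier] += cfg.nt_lfc * nt_sched[carrier]
    return E


def simulate(config: SimConfig,
             only_stages: tuple[str, ...] | None = None
             ) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw a full multi-stage count matrix plus its ground truth.

    Deterministic given ``config.seed``.  ``only_stages`` restricts cell
    generation to a subset of the configured stages (an independent
    replicate of those stages under the same model — effect schedules stay
    indexed by the full stage list).
    """
    stages = tuple(only_stages) if only_stages else tuple(config.stages)
    unknown = set(stages) - set(config.stages)
    if unknown:
        raise ValidationError(f"unknown stages {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    types = config.type_table()
    genes = _assign_gene_roles(config, types)

    cell_rows = []
    for stage in stages:
        for _, t in types.iterrows():
            for i in range(config.cells_per_type_per_stage):
                cell_rows.append({
                    "cell_id": f"{stage}_{t.type_label}_c{i:03d}",
                    "stage": stage,
                    "lineage": t.lineage,
                    "type_label": t.type_label,
                    "birth_rank": t.birth_rank,
                    "embryonic_born": bool(t.embryonic_born),
                })
    cells = pd.DataFrame(cell_rows).set_index("cell_id")

    baselines = rng.normal(config.baseline_logmean_mu,
                           config.baseline_logmean_sigma, size=len(genes))
    panel_idx = np.flatnonzero((genes["role"] == "panel").to_numpy())
    baselines[panel_idx] = rng.normal(config.panel_baseline_mu,
                                      config.panel_baseline_sigma, size=panel_idx.size)
    marker_idx = np.flatnonzero(genes["marker_type"].notna().to_numpy())
    baselines[marker_idx] = rng.normal(config.marker_baseline_mu,
                                       config.marker_baseline_sigma, size=marker_idx.size)

    E = expected_log2_effects(config, genes, cells)
    weights = np.exp(baselines[:, None] + LN2 * E)
    fractions = weights / weights.sum(axis=0, keepdims=True)
    del weights
    lib = rng.lognormal(config.library_size_mu, config.library_size_sigma,
                        size=len(cells))
    mu = fractions * lib[None, :]
    del fractions
    # negative binomial via its gamma-Poisson mixture (faster to vectorize)
    r = config.dispersion
    counts = rng.poisson(rng.gamma(r, mu / r)).astype(np.int64)
    del mu, E

    dataset = ExpressionDataset(
        counts=counts,
        gene_ids=list(genes.index),
        cell_ids=list(cells.index),
        cells=cells.assign(total_reads=counts.sum(axis=0)),
        genes=genes[["role", "is_neuronal_marker"]],
        stage_order=tuple(config.stages),
    )
    truth = GroundTruth(
        cells=cells.copy(),
        genes=genes.drop(columns=["is_neuronal_marker"]),
        type_map={t: t for t in types["type_label"]},
        config=config,
    )
    logger.info("simulate: %d genes x %d cells (seed %d)",
                dataset.n_genes, dataset.n_cells, config.seed)
    return dataset, truth


def export_fixture(dataset: ExpressionDataset, truth: GroundTruth,
                   out_dir: str | Path) -> dict[str, Path]:
    """Write MTX + sidecars + metadata + ground truth, loadable by io_core."""
    out_dir = Path(out_dir)
    paths = write_counts_mtx(dataset, out_dir)
    paths["truth_cells"] = out_dir / "truth_cells.tsv"
    truth.cells.reset_index().to_csv(paths["truth_cells"], sep="\t", index=False)
    paths["truth_genes"] = out_dir / "truth_genes.tsv"
    truth.genes.reset_index().to_csv(paths["truth_genes"], sep="\t", index=False)
    paths["sim_config"] = out_dir / "sim_config.json"
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(truth.config).items()}
    paths["sim_config"].write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    return paths
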