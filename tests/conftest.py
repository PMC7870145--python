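"""Shared fixtures: hand-built datasets, scaled-down simulations, and one
session-scoped sweep of the full pipeline over ten default-condition seeds
(used by the acceptance tests and by cross-module invariants)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pnatlas as pa
from pnatlas import pipeline


def make_dataset(counts, gene_ids=None, cell_ids=None, **kwargs):
    counts = np.asarray(counts)
    gene_ids = gene_ids or [f"g{i}" for i in range(counts.shape[0])]
    cell_ids = cell_ids or [f"c{j}" for j in range(counts.shape[1])]
    return pa.ExpressionDataset(counts=counts, gene_ids=gene_ids,
                                cell_ids=cell_ids, **kwargs)


@pytest.fixture
def toy_dataset():
    """3 genes x 2 cells with known counts."""
    return make_dataset([[9, 0], [1, 5], [0, 5]])


def two_type_config(seed=0, **overrides):
    """Scaled-down generator: one lineage, two types, default effect sizes."""
    kwargs = dict(
        seed=seed,
        n_genes=300,
        lineage_spec={"adPN": 2},
        cells_per_type_per_stage=30,
        n_stage_down=25,
        n_stage_up=10,
        n_pruning=5,
        n_gradient=4,
    )
    kwargs.update(overrides)
    return pa.SimConfig(**kwargs)


def planted_type_codes(cells: pd.DataFrame) -> np.ndarray:
    return np.unique(cells["type_label"].to_numpy(), return_inverse=True)[1]


def _run_default_seed(seed: int) -> dict:
    """Full pipeline under the default study conditions for one seed."""
    sim_cfg = pa.SimConfig(seed=seed)
    ds, truth = pa.simulate(sim_cfg)
    config = pa.PipelineConfig(seed=seed)
    dsq = pipeline.preprocess_all(ds, config)
    analyses = pipeline.run_cross_stage(dsq, config)

    out = {"seed": seed, "ari": {}, "n_clusters": {}}
    for s, a in analyses.items():
        out["ari"][s] = pa.agreement_ari(a.labels.labels,
                                         planted_type_codes(a.dataset.cells))
        out["n_clusters"][s] = a.labels.n_clusters()

    n_excitatory_types = int(truth.cells.loc[
        truth.cells["lineage"].isin(pa.EXCITATORY_LINEAGES), "type_label"].nunique())
    out["matches"] = []
    for m in pipeline.adjacent_stage_matches(analyses, dsq.stage_order):
        acc = pipeline.match_accuracy(m, analyses[m.stage_a], analyses[m.stage_b])
        acc["stage_a"], acc["stage_b"] = m.stage_a, m.stage_b
        acc["n_types"] = n_excitatory_types
        out["matches"].append(acc)

    out["diversity"] = pipeline.diversity_by_stage(dsq, config, analyses=analyses).table

    union = pa.dynamic_gene_union(dsq, k=config.top_k_pairs)
    groups = pa.profile_and_group(dsq, union, seed=seed)
    trend = groups.trend_of()
    roles = truth.genes["role"]
    up = [g for g in union if roles.get(g) == "stage_up"]
    down = [g for g in union if roles.get(g) == "stage_down"]
    out["dynamics"] = {
        "union_size": len(union),
        "n_up": len(up), "n_up_correct": sum(trend.get(g) == "up" for g in up),
        "n_down": len(down), "n_down_correct": sum(trend.get(g) == "down" for g in down),
    }

    sub = dsq.subset_stage(dsq.stage_order[0]).subset_lineage("adPN")
    corr, ranks = pa.type_correlation_matrix(sub)
    res = pa.birth_order_permutation(corr, ranks, n_iter=1000, seed=seed)
    out["birth_order_p0"] = {"observed": res.observed, "p": res.p_value}
    return out


@pytest.fixture(scope="session")
def default_runs() -> list[dict]:
    """Pipeline summaries for seeds 0..9 under the default study conditions."""
    return [_run_default_seed(seed) for seed in range(10)]


# ---------------------------------------------------------------------------
# CLI end-to-end runs (shared by functional CLI tests and determinism checks)
# ---------------------------------------------------------------------------

def small_cli_sim_config(seed=0) -> pa.SimConfig:
    """Compact study: 12 types, 576 cells, 1200 genes — CLI-sized.

    Gene count stays in the thousands so per-gene CPM levels (and hence
    normalized profile drops) remain realistic."""
    return pa.SimConfig(
        seed=seed,
        n_genes=1200,
        lineage_spec={"adPN": 8, "lPN": 2, "vPN": 1, "APL": 1},
        cells_per_type_per_stage=12,
        n_stage_down=60,
        n_stage_up=20,
        n_pruning=10,
        n_gradient=8,
    )


def run_cli_suite(root) -> "Path":
    """Exercise every CLI subcommand once; returns the output directory."""
    import dataclasses
    import json
    from pathlib import Path

    from pnatlas import cli

    root = Path(root)
    out = root / "out"
    sim_json = root / "sim_config.json"
    cfg = small_cli_sim_config()
    sim_json.write_text(json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in dataclasses.asdict(cfg).items()}, sort_keys=True))
    data = out / "sim"

    def run(argv):
        assert cli.main(argv) == 0

    run(["--seed", "0", "--config", str(sim_json), "simulate", "--out", str(data)])
    run(["--seed", "0", "qc", "--data", str(data), "--out", str(out / "qc")])
    run(["--seed", "0", "features", "--data", str(data), "--stage", "P24",
         "--n-top", "100", "--out", str(out / "features")])
    feats = str(out / "features" / "features.tsv")
    for stage in ("P24", "P48"):
        run(["--seed", "0", "cluster", "--data", str(data), "--stage", stage,
             "--features", feats, "--method", "leiden",
             "--out", str(out / f"cl_{stage}")])
        run(["--seed", "0", "de", "--data", str(data), "--stage", stage,
             "--labels", str(out / f"cl_{stage}" / "labels.tsv"),
             "--out", str(out / f"de_{stage}")])
    run(["--seed", "0", "match",
         "--sig-a", str(out / "de_P24" / "signatures.tsv"),
         "--sig-b", str(out / "de_P48" / "signatures.tsv"),
         "--out", str(out / "match")])
    run(["--seed", "0", "diversity", "--data", str(data),
         "--out", str(out / "diversity")])
    run(["--seed", "0", "birthorder", "--data", str(data), "--stage", "P0",
         "--n-iter", "300", "--out", str(out / "birthorder")])
    run(["--seed", "0", "dynamics", "--data", str(data), "--k", "60",
         "--out", str(out / "dynamics")])
    run(["--seed", "0", "report", "--data", str(data),
         "--out", str(out / "report")])
    return out


@pytest.fixture(scope="session")
def cli_double_run(tmp_path_factory):
    """The full CLI suite run twice with identical config and seed."""
    run1 = run_cli_suite(tmp_path_factory.mktemp("cli_run1"))
    run2 = run_cli_suite(tmp_path_factory.mktemp("cli_run2"))
    return run1, run2
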