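"""Full analysis pipeline: describe -> screen -> networks -> centrality ->
bootstrap accuracy -> case-dropping stability -> paired comparisons -> CLPN.

Every stage writes CSV/JSON outputs into the configured directory and is
recorded in a manifest.  Identical configurations reproduce byte-identical
numeric outputs (all randomness is explicitly seeded; floats are formatted
with a fixed precision).
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd

from . import clpn as clpn_mod
from . import cohort
from .centrality import centrality_table
from .ggm import estimate_network, redundancy_screen
from .io import PipelineConfig, read_panel, write_panel
from .simulate import SymptomPanel, make_default_truth, simulate_panel
from .stability import bootstrap_edges, network_stability

_FLOAT_FMT = "%.10g"

STAGES = (
    "describe",
    "screen",
    "estimate",
    "centrality",
    "bootstrap",
    "stability",
    "compare",
    "clpn",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _acquire_panel(config: PipelineConfig, outdir: Path) -> SymptomPanel:
    if config.input_path is not None:
        panel, rejects = read_panel(config.input_path)
        _write_csv(rejects.to_frame(), outdir / "rejects.csv")
        return panel
    truth = make_default_truth(
        config.simulate_seed, n0=config.n0, retention=config.retention
    )
    truth.to_json(outdir / "simulation_truth.json")
    panel = simulate_panel(truth)
    write_panel(panel, outdir / "panel.csv")
    return panel


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every analysis stage; returns the run manifest (also written
    to ``manifest.json``).  A stage failure halts the run with a
    machine-readable error record in the manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "package_version": _pkg_version("panelnet"),
        "stages": {},
    }

    panel = _acquire_panel(config, outdir)
    manifest["n_subjects"] = int(panel.n_subjects)
    manifest["n_completers"] = int(panel.observed.all(axis=1).sum())

    est_kwargs = dict(
        gamma=config.gamma,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
        cor_method=config.cor_method,
    )
    waves = panel.wave_labels
    networks: dict[str, object] = {}

    def _run(stage: str, fn) -> None:
        try:
            fn()
            manifest["stages"][stage] = {"status": "completed"}
        except Exception as exc:  # halt, record the failing stage
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
            raise StageError(stage, exc) from exc

    def stage_describe():
        for wave in waves:
            _write_csv(cohort.describe(panel, wave), outdir / f"describe_{wave}.csv")

    def stage_screen():
        rep = redundancy_screen(panel.wave_frame(waves[0]))
        _write_csv(rep.candidate_pairs, outdir / "redundancy_candidates.csv")
        (outdir / "redundancy_flagged.json").write_text(
            json.dumps({"flagged_pairs": [list(t) for t in rep.flagged_pairs]}, sort_keys=True)
        )

    def stage_estimate():
        for wave in waves:
            net = estimate_network(panel.wave_frame(wave), **est_kwargs)
            networks[wave] = net
            net.to_json(outdir / f"network_{wave}.json")
            _write_csv(net.edge_list(), outdir / f"edges_{wave}.csv")
            net.to_matrix_frame().to_csv(outdir / f"weights_{wave}.csv", float_format=_FLOAT_FMT)

    def stage_centrality():
        for wave in waves:
            _write_csv(centrality_table(networks[wave]), outdir / f"centrality_{wave}.csv")

    def stage_bootstrap():
        for wave in waves:
            tab = bootstrap_edges(
                panel.wave_frame(wave),
                B=config.bootstrap_B,
                seed=config.bootstrap_seed,
                estimator_kwargs=est_kwargs,
            )
            _write_csv(tab.table, outdir / f"edge_bootstrap_{wave}.csv")

    def stage_stability():
        cs_summary = {}
        for wave in waves:
            res = network_stability(
                panel.wave_frame(wave),
                B_per_drop=config.cs_B_per_drop,
                corr_threshold=config.cs_corr_threshold,
                confidence=config.cs_confidence,
                seed=config.cs_seed,
                estimator_kwargs=est_kwargs,
            )
            for idx, df in res.correlations.items():
                _write_csv(df, outdir / f"stability_{wave}_{idx}.csv")
            cs_summary[wave] = res.cs
        (outdir / "cs_coefficients.json").write_text(
            json.dumps(cs_summary, indent=1, sort_keys=True)
        )

    def stage_compare():
        _write_csv(cohort.compare_waves(panel), outdir / "paired_comparisons.csv")

    def stage_clpn():
        model = clpn_mod.fit_clpn(
            panel,
            n_folds=config.clpn_folds,
            seed=config.clpn_seed,
            report_threshold=config.clpn_threshold,
        )
        model.to_json(outdir / "clpn_model.json")
        _write_csv(clpn_mod.reported_edges(model), outdir / "clpn_edges.csv")
        _write_csv(clpn_mod.temporal_ei(model), outdir / "clpn_temporal_ei.csv")

    fns = {
        "describe": stage_describe,
        "screen": stage_screen,
        "estimate": stage_estimate,
        "centrality": stage_centrality,
        "bootstrap": stage_bootstrap,
        "stability": stage_stability,
        "compare": stage_compare,
        "clpn": stage_clpn,
    }
    for stage in STAGES:
        _run(stage, fns[stage])

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
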