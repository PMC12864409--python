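"""Panel file I/O and run configuration.

Canonical on-disk format is long: one row per (subject, wave) with a header
``subject_id, wave, D1..SSRT``.  Wide files (one row per subject, per-wave
column suffixes) are accepted behind a flag.  Malformed rows are collected in
a reject report rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import NODE_LABELS, WAVE_LABELS, SymptomPanel


@dataclass
class RejectReport:
    rows: list[dict] = field(default_factory=list)

    def add(self, subject, reason: str) -> None:
        self.rows.append({"subject_id": str(subject), "reason": reason})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["subject_id", "reason"])


def read_panel(
    path: str | Path,
    *,
    node_labels: list[str] | None = None,
    wide: bool = False,
) -> tuple[SymptomPanel, RejectReport]:
    """Read a delimited panel file; invalid subjects go to the reject report.

    Raises if more than half of the subjects are rejected.
    """
    labels = list(node_labels or NODE_LABELS)
    df = pd.read_csv(path)
    report = RejectReport()
    if wide:
        df = _wide_to_long(df, labels)
    required = {"subject_id", "wave", *labels}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")

    bad_wave = ~df["wave"].isin(WAVE_LABELS)
    for sid in df.loc[bad_wave, "subject_id"].unique():
        report.add(sid, "unknown wave label")
    df = df[~df["subject_id"].isin(df.loc[bad_wave, "subject_id"])]

    dup = df.duplicated(subset=["subject_id", "wave"], keep=False)
    for sid in df.loc[dup, "subject_id"].unique():
        report.add(sid, "duplicate (subject, wave) row")
    df = df[~df["subject_id"].isin(df.loc[dup, "subject_id"])]

    bad_numeric = set()
    for lbl in labels:
        coerced = pd.to_numeric(df[lbl], errors="coerce")
        bad = coerced.isna() & df[lbl].notna()
        bad_numeric |= set(df.loc[bad, "subject_id"])
        df = df.assign(**{lbl: coerced})
    for sid in sorted(bad_numeric):
        report.add(sid, "non-numeric score")
    df = df[~df["subject_id"].isin(bad_numeric)]

    # subjects must have a T0 row; incomplete T1 rows are rejected
    no_t0 = []
    partial_t1 = []
    subjects = []
    for sid, grp in df.groupby("subject_id", sort=False):
        waves = set(grp["wave"])
        if WAVE_LABELS[0] not in waves:
            no_t0.append(sid)
            continue
        if WAVE_LABELS[1] in waves:
            row1 = grp[grp["wave"] == WAVE_LABELS[1]].iloc[0]
            if row1[labels].isna().any():
                partial_t1.append(sid)
                continue
        subjects.append(sid)
    for sid in no_t0:
        report.add(sid, "no wave-1 row")
    for sid in partial_t1:
        report.add(sid, "incomplete wave-2 scores")
    df = df[df["subject_id"].isin(subjects)]

    n_total = len(set(df["subject_id"])) + len(report.rows)
    if n_total and len(report.rows) > 0.5 * n_total:
        raise ValueError(
            f"{len(report.rows)} of {n_total} subjects rejected; input unusable"
        )

    n = len(subjects)
    scores = np.full((n, len(labels), 2), np.nan)
    observed = np.zeros((n, 2), dtype=bool)
    pos = {sid: i for i, sid in enumerate(subjects)}
    for w, wave in enumerate(WAVE_LABELS):
        sub = df[df["wave"] == wave]
        for _, row in sub.iterrows():
            i = pos[row["subject_id"]]
            scores[i, :, w] = row[labels].to_numpy(dtype=float)
            observed[i, w] = True
    panel = SymptomPanel(
        subject_ids=np.array([str(s) for s in subjects]),
        scores=scores,
        observed=observed,
        node_labels=labels,
    )
    return panel, report


def _wide_to_long(df: pd.DataFrame, labels: list[str]) -> pd.DataFrame:
    rows = []
    for wave in WAVE_LABELS:
        cols = [f"{lbl}_{wave}" for lbl in labels]
        if not all(c in df.columns for c in cols):
            if wave == WAVE_LABELS[0]:
                raise ValueError(f"wide file lacks wave-1 columns {cols}")
            continue
        sub = df[["subject_id", *cols]].copy()
        sub.columns = ["subject_id", *labels]
        sub = sub.dropna(subset=labels, how="all")
        sub.insert(1, "wave", wave)
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def write_panel(panel: SymptomPanel, path: str | Path) -> None:
    """Write a panel as long CSV (lossless round-trip with read_panel)."""
    panel.to_long_frame().to_csv(path, index=False, float_format="%.10g")


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run; every random stage is seeded."""

    input_path: str | None = None  # None -> simulate
    simulate_seed: int = 1
    n0: int = 361
    retention: float = 209 / 361
    cor_method: str = "pearson"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    bootstrap_B: int = 1000
    bootstrap_seed: int = 11
    cs_B_per_drop: int = 200
    cs_seed: int = 12
    cs_corr_threshold: float = 0.7
    cs_confidence: float = 0.95
    clpn_folds: int = 10
    clpn_seed: int = 13
    clpn_threshold: float = 0.1
    output_dir: str = "panelnet_out"

    def validate(self) -> None:
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)
        if self.cor_method not in ("pearson", "spearman"):
            raise ValueError("cor_method must be pearson or spearman")
        for name in ("simulate_seed", "bootstrap_seed", "cs_seed", "clpn_seed"):
            if getattr(self, name) is None:
                raise ValueError(f"{name} must be set explicitly")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(obj) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**obj)

    def to_dict(self) -> dict:
        return asdict(self)
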