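"""File formats, configuration, and pipeline orchestration.

Traces travel as CSV with header ``time_s,od,temp_c`` (the temperature
column is optional), cohorts as JSON manifests listing run files plus a
condition label, and configuration/reports as JSON.  ``run_pipeline`` ties
the stages together: screening, feature extraction, MAD outlier rejection,
cohort summaries, and measured + stretched group comparisons, with every
rejection logged by run id.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    DegenerateTraceError,
    InputError,
    InsufficientWindowError,
    TraceRejected,
    UndefinedCrossingError,
)
from .features import RunFeatures, Trace, extract_features, screen_trace, stretch_time
from .stats import CohortSummary, compare_groups, summarize_cohort
from .synthetic import SimulatedRun

__all__ = [
    "Manifest",
    "AnalysisConfig",
    "read_trace_csv",
    "write_trace_csv",
    "write_run",
    "write_cohort",
    "load_manifest",
    "load_cohort",
    "run_pipeline",
]

PathLike = Union[str, Path]


@dataclass
class Manifest:
    """A cohort: a condition label and the trace files belonging to it."""

    label: str
    paths: list[str]
    nominal_temp_c: Optional[float] = None
    exposure: str = ""
    seed: Optional[int] = None

    def __post_init__(self):
        if not self.label:
            raise InputError("manifest label must be non-empty")
        if len(set(self.paths)) != len(self.paths):
            raise InputError("manifest paths must be distinct")

    def to_json(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    Defaults: fit window 0.1-0.4 on the normalized curve, unit time 1 s,
    MAD threshold k = 3, significance flagged at 1e-3 (strict) and 0.05
    (weak), stretching against the group-averaged curve.
    """

    window_lo: float = 0.1
    window_hi: float = 0.4
    t_u: float = 1.0
    mad_k: float = 3.0
    threshold_strict: float = 1e-3
    threshold_weak: float = 0.05
    stretch_mode: str = "mean_curve"
    normality_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.window_lo < self.window_hi < 1.0:
            raise InputError("require 0 < window_lo < window_hi < 1")
        for thr in (self.threshold_strict, self.threshold_weak, self.normality_alpha):
            if not 0.0 < thr < 1.0:
                raise InputError("thresholds must lie in (0, 1)")

    @classmethod
    def from_json(cls, path: PathLike) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")


def read_trace_csv(path: PathLike, condition_label: str = "",
                   run_id: Optional[str] = None) -> Trace:
    """Read one trace from CSV with header ``time_s,od[,temp_c]``.

    Malformed input raises :class:`InputError` naming the offending row
    (1-based, excluding the header) and column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "od"):
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    cols = ["time_s", "od"] + (["temp_c"] if "temp_c" in df.columns else [])
    for col in cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise InputError(f"{path}: non-numeric value in column {col!r}, row {row}")
        df[col] = numeric
    t = df["time_s"].to_numpy(dtype=float)
    non_mono = np.flatnonzero(np.diff(t) <= 0)
    if non_mono.size:
        row = int(non_mono[0]) + 2
        raise InputError(f"{path}: time_s not strictly increasing at row {row}")
    return Trace(
        times=t,
        od=df["od"].to_numpy(dtype=float),
        temperature=df["temp_c"].to_numpy(dtype=float) if "temp_c" in df.columns else None,
        condition_label=condition_label,
        run_id=run_id if run_id is not None else path.stem,
    )


def write_trace_csv(trace: Trace, path: PathLike) -> None:
    """Write a trace as ``time_s,od[,temp_c]`` CSV (full float precision)."""
    data = {"time_s": trace.times, "od": trace.od}
    if trace.temperature is not None:
        data["temp_c"] = trace.temperature
    pd.DataFrame(data).to_csv(path, index=False)


def write_run(run: SimulatedRun, path: PathLike, truth_sidecar: bool = True) -> None:
    """Write a simulated run as CSV plus a JSON sidecar of its ground truth."""
    path = Path(path)
    write_trace_csv(run.to_trace(), path)
    if truth_sidecar:
        truth = dataclasses.asdict(run.truth)
        truth.update(tau_factor=run.tau_factor, od_factor=run.od_factor,
                     artifact_flag=run.artifact_flag, run_id=run.run_id)
        path.with_suffix(".truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n")


def write_cohort(runs: Sequence[SimulatedRun], out_dir: PathLike, label: str,
                 seed: Optional[int] = None, nominal_temp_c: Optional[float] = None,
                 exposure: str = "") -> Manifest:
    """Write a simulated cohort (run CSVs + manifest.json) into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, run in enumerate(runs):
        name = f"{label}_{i:03d}.csv"
        write_run(run, out_dir / name)
        paths.append(name)
    manifest = Manifest(label=label, paths=paths, nominal_temp_c=nominal_temp_c,
                        exposure=exposure, seed=seed)
    manifest.to_json(out_dir / "manifest.json")
    return manifest


def load_manifest(path: PathLike) -> Manifest:
    return Manifest(**json.loads(Path(path).read_text()))


def load_cohort(manifest: Manifest, base_dir: PathLike = ".") -> list[Trace]:
    """Load every trace listed in a manifest (paths relative to ``base_dir``)."""
    base = Path(base_dir)
    return [read_trace_csv(base / p, condition_label=manifest.label)
            for p in manifest.paths]


def _screen_and_extract(traces: Sequence[Trace], config: AnalysisConfig):
    """Screen traces and extract features; collect a rejection log."""
    kept_traces: list[Trace] = []
    features: list[RunFeatures] = []
    dts: list[float] = []
    rejections: list[dict] = []
    for tr in traces:
        try:
            screen_trace(tr)
        except TraceRejected as exc:
            rejections.append({"run_id": tr.run_id, "stage": "screen",
                               "reason": exc.reason})
            continue
        try:
            feats = extract_features(tr, window_lo=config.window_lo,
                                     window_hi=config.window_hi, t_u=config.t_u)
        except (DegenerateTraceError, UndefinedCrossingError,
                InsufficientWindowError) as exc:
            rejections.append({"run_id": tr.run_id, "stage": "features",
                               "reason": type(exc).__name__, "detail": str(exc)})
            continue
        kept_traces.append(tr)
        features.append(feats)
        if tr.temperature is not None:
            dts.append(float(tr.temperature[-1] - tr.temperature[0]))
        else:
            dts.append(float("nan"))
    return kept_traces, features, dts, rejections


def _summary_row(s: CohortSummary) -> dict:
    return {
        "label": s.label, "n_input": s.n_input, "n": s.n,
        "dt_c": _jsonable(s.dt_c),
        "od_final_mean": s.od_final_mean, "od_final_se": _jsonable(s.od_final_se),
        "t10_mean": s.t10_mean, "t10_se": _jsonable(s.t10_se),
        "b_mean": s.b_mean, "b_se": _jsonable(s.b_se),
    }


def _jsonable(x: float):
    return None if (isinstance(x, float) and math.isnan(x)) else x


def run_pipeline(
    manifest_a: Manifest,
    manifest_b: Manifest,
    config: Optional[AnalysisConfig] = None,
    base_dir: PathLike = ".",
    out_dir: Optional[PathLike] = None,
    traces_a: Optional[Sequence[Trace]] = None,
    traces_b: Optional[Sequence[Trace]] = None,
) -> dict:
    """Run the full two-cohort comparison and return a JSON-ready report.

    Stages: screening (bubbles, spikes), feature extraction, per-parameter
    MAD rejection with run-level removal, cohort summary rows, and
    Mann-Whitney comparisons of measured values plus t10 after stretching
    cohort B onto cohort A.  Pre-loaded traces may be passed to skip file
    IO.  The report is deterministic for fixed inputs and configuration.
    """
    config = config or AnalysisConfig()
    if traces_a is None:
        traces_a = load_cohort(manifest_a, base_dir)
    if traces_b is None:
        traces_b = load_cohort(manifest_b, base_dir)

    report: dict = {"config": dataclasses.asdict(config), "cohorts": {},
                    "rejections": []}
    kept: dict[str, tuple] = {}
    for manifest, traces in ((manifest_a, traces_a), (manifest_b, traces_b)):
        k_traces, feats, dts, rejections = _screen_and_extract(traces, config)
        if not feats:
            raise InputError(f"cohort {manifest.label!r}: no usable traces")
        summary = summarize_cohort(feats, dt_values=dts, mad_k=config.mad_k,
                                   label=manifest.label)
        for i in summary.rejected_indices:
            rejections.append({"run_id": feats[int(i)].run_id, "stage": "mad",
                               "reason": "outlier"})
        keep_idx = list(summary.kept_indices)
        kept[manifest.label] = (
            [feats[i] for i in keep_idx],
            [k_traces[i] for i in keep_idx],
        )
        report["cohorts"][manifest.label] = _summary_row(summary)
        report["rejections"].extend(rejections)

    feats_a, tr_a = kept[manifest_a.label]
    feats_b, tr_b = kept[manifest_b.label]
    results = compare_groups(
        feats_a, feats_b, traces_a=tr_a, traces_b=tr_b,
        threshold=config.threshold_strict, alpha=config.threshold_weak,
        stretch_mode=config.stretch_mode,
    )
    stretch = stretch_time(tr_b, tr_a, mode=config.stretch_mode)
    report["stretch_factor"] = stretch.factor
    report["comparisons"] = [
        {
            "parameter": r.parameter,
            "U": r.u,
            "p_measured": r.p_measured,
            "p_stretched": r.p_stretched,
            "significant_strict": r.significant_strict,
            "significant_weak": r.significant_weak,
        }
        for r in results
    ]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        pd.DataFrame([report["cohorts"][m.label] for m in (manifest_a, manifest_b)]
                     ).to_csv(out_dir / "cohort_summaries.csv", index=False)
        pd.DataFrame(report["comparisons"]).to_csv(out_dir / "comparisons.csv",
                                                   index=False)
    return report
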