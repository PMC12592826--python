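"""Recording bundles on disk, configuration, and the pipeline driver.

A recording bundle is a directory of three CSVs sharing one time origin
(recording start = 0 s): ``rr.csv`` (beat_time_s, rr_s),
``hypnogram.csv`` (epoch_start_s, stage) and ``events.csv`` (start_s,
end_s, kind), plus optional ``truth.json`` ground truth from the
simulator.  ``run_pipeline`` chains detection, GLM fitting, feature
extraction and goodness of fit, isolating failures per stage.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detect import AvalancheDetector, stage_rates
from .features import HistoryFeatures, ModulationCurve, extract_features, modulation_curve
from .glm import PointProcessGLM
from .gof import KSResult, ks_test
from .schemas import FeaturesJSON, FitJSON, GofJSON, PipelineStatusJSON, StageRatesJSON
from .spline import HistoryBasis
from .types import (
    RAW_STAGE_MAP,
    EventInterval,
    EventKind,
    Hypnogram,
    NAAEventTrain,
    RRSeries,
    StageCode,
    ValidationError,
)

log = logging.getLogger("naaglm")


@dataclass
class AnalysisConfig:
    """Every tunable knob of the per-recording analysis."""

    bin_width: float = 1.0
    burn_in_s: float = 120.0
    tension: float = 0.5
    knot_spacing: str = "linear"
    ridge: float = 0.0
    tol: float = 1e-8
    max_iter: int = 100
    min_events: int = 5
    sdb_pad_s: float = 0.0
    baseline_window_s: float = 600.0
    drop_fraction: float = 0.30
    recovery_fraction: float = 0.90
    grid_step: float = 0.1
    width_mode: str = "half_prominence"
    alpha: float = 0.05
    gof_jitter: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


@dataclass
class RecordingBundle:
    """Validated in-memory recording: R-R series, hypnogram, events."""

    rr: RRSeries
    hypnogram: Hypnogram
    events: list[EventInterval]
    metadata: dict = field(default_factory=dict)
    truth: dict | None = None


def _parse_stage(value, problems: list[str], row: int) -> StageCode | None:
    s = str(value).strip().upper()
    if s in StageCode.__members__:
        return StageCode[s]
    try:
        code = int(float(s))
    except ValueError:
        problems.append(f"hypnogram row {row}: unknown stage label {value!r}")
        return None
    if code in RAW_STAGE_MAP:
        log.info("hypnogram row %d: raw stage code %d mapped to %s",
                 row, code, RAW_STAGE_MAP[code].value)
        return RAW_STAGE_MAP[code]
    problems.append(f"hypnogram row {row}: unknown stage code {code}")
    return None


def read_bundle(directory) -> RecordingBundle:
    """Load and cross-validate a recording bundle directory.

    All violations are collected and reported together.  Raw AASM/R&K
    stage codes 0-5 are auto-mapped (1,2 -> LIGHT; 3,4 -> DEEP;
    5 -> REM; 0 -> WAKE) with the mapping logged.
    """
    d = Path(directory)
    problems: list[str] = []
    for name in ("rr.csv", "hypnogram.csv", "events.csv"):
        if not (d / name).exists():
            problems.append(f"missing {name}")
    if problems:
        raise ValidationError("; ".join(problems))

    rr_df = pd.read_csv(d / "rr.csv")
    hyp_df = pd.read_csv(d / "hypnogram.csv")
    ev_df = pd.read_csv(d / "events.csv")

    if np.any(rr_df["beat_time_s"].to_numpy() < 0):
        problems.append("rr.csv: negative beat times")
    if np.any(np.diff(rr_df["beat_time_s"].to_numpy()) <= 0):
        problems.append("rr.csv: beat times not strictly increasing")
    if np.any(rr_df["rr_s"].to_numpy() <= 0):
        problems.append("rr.csv: non-positive intervals")

    stages: list[StageCode] = []
    starts = hyp_df["epoch_start_s"].to_numpy(dtype=float)
    if starts.size == 0:
        problems.append("hypnogram.csv: empty")
        epoch_len = 30.0
    else:
        epoch_len = float(np.diff(starts)[0]) if starts.size > 1 else 30.0
        if starts.size > 1 and not np.allclose(np.diff(starts), epoch_len):
            problems.append("hypnogram.csv: epochs overlap or are non-uniform")
        if np.any(starts < 0):
            problems.append("hypnogram.csv: negative epoch start")
    for i, v in enumerate(hyp_df["stage"]):
        st = _parse_stage(v, problems, i)
        if st is not None:
            stages.append(st)

    events: list[EventInterval] = []
    for i, row in ev_df.iterrows():
        kind = str(row["kind"]).strip().upper()
        if kind not in EventKind.__members__:
            problems.append(f"events.csv row {i}: unknown event kind {row['kind']!r}")
            continue
        if not row["end_s"] > row["start_s"]:
            problems.append(f"events.csv row {i}: end <= start")
            continue
        if row["start_s"] < 0:
            problems.append(f"events.csv row {i}: negative start")
            continue
        events.append(EventInterval(float(row["start_s"]), float(row["end_s"]),
                                    EventKind[kind]))

    if problems:
        raise ValidationError("; ".join(problems))

    hyp = Hypnogram(tuple(stages), epoch_len, float(starts[0]))
    span = max(float(rr_df["beat_time_s"].iloc[-1]), hyp.end_time)
    for i, ev in enumerate(events):
        if ev.end > span + hyp.epoch_length:
            problems.append(f"events.csv row {i}: event beyond recording span")
    if problems:
        raise ValidationError("; ".join(problems))

    truth = None
    if (d / "truth.json").exists():
        truth = json.loads((d / "truth.json").read_text())
    meta = {}
    if (d / "metadata.json").exists():
        meta = json.loads((d / "metadata.json").read_text())
    rr = RRSeries(rr_df["beat_time_s"].to_numpy(), rr_df["rr_s"].to_numpy())
    return RecordingBundle(rr, hyp, events, meta, truth)


def write_bundle(directory, hypnogram: Hypnogram, events: list[EventInterval],
                 rr: RRSeries, truth: dict | None = None) -> Path:
    """Write the standard three-CSV (+ truth.json) bundle."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"beat_time_s": rr.beat_time, "rr_s": rr.rr}).to_csv(
        d / "rr.csv", index=False
    )
    pd.DataFrame({
        "epoch_start_s": hypnogram.start_time
        + hypnogram.epoch_length * np.arange(hypnogram.n_epochs),
        "stage": [s.value for s in hypnogram.stages],
    }).to_csv(d / "hypnogram.csv", index=False)
    pd.DataFrame({
        "start_s": [e.start for e in events],
        "end_s": [e.end for e in events],
        "kind": [e.kind.value for e in events],
    }).to_csv(d / "events.csv", index=False)
    if truth is not None:
        (d / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return d


def episodes_frame(train: NAAEventTrain) -> pd.DataFrame:
    return pd.DataFrame({
        "onset_s": [e.onset_time for e in train.episodes],
        "end_s": [e.end_time for e in train.episodes],
        "baseline_rr_s": [e.baseline_rr for e in train.episodes],
        "min_rr_s": [e.min_rr for e in train.episodes],
        "n_beats": [e.n_beats for e in train.episodes],
        "truncated": [e.truncated for e in train.episodes],
    })


def fit_to_json(fit: PointProcessGLM) -> dict:
    basis = getattr(fit, "basis_", None)
    payload = FitJSON(
        columns=list(fit.column_names_),
        coef=[float(c) for c in fit.coef_],
        covariance=[[float(v) for v in row] for row in fit.covariance_],
        log_likelihood=float(fit.log_likelihood_),
        n_events=fit.n_events_,
        n_bins=fit.n_bins_,
        converged=bool(fit.converged_),
        regularized=bool(fit.regularized_),
        reliable=bool(fit.reliable_),
        knots=[float(k) for k in basis.knots] if basis is not None else [],
        tension=fit.tension,
        bin_width=fit.bin_width,
        burn_in_s=fit.burn_in_s,
        stage_log_rates={
            s.value: (None if np.isnan(v) else float(v))
            for s, v in fit.stage_log_rates_.items()
        },
        sdb_multiplier=None if np.isnan(fit.sdb_multiplier_) else fit.sdb_multiplier_,
        arousal_multiplier=(
            None if np.isnan(fit.arousal_multiplier_) else fit.arousal_multiplier_
        ),
    )
    return payload.model_dump()


def fit_from_json(data: dict) -> PointProcessGLM:
    """Rehydrate a fitted model (coefficients + basis) from fit.json."""
    fit = PointProcessGLM(bin_width=data["bin_width"], burn_in_s=data["burn_in_s"],
                          tension=data["tension"])
    fit.column_names_ = tuple(data["columns"])
    fit.coef_ = np.array(data["coef"], dtype=float)
    fit.covariance_ = np.array(data["covariance"], dtype=float)
    fit.log_likelihood_ = data["log_likelihood"]
    fit.n_events_ = data["n_events"]
    fit.n_bins_ = data["n_bins"]
    fit.converged_ = data["converged"]
    fit.regularized_ = data["regularized"]
    fit.reliable_ = data["reliable"]
    fit.dropped_columns_ = ()
    if data["knots"]:
        fit.basis_ = HistoryBasis(np.array(data["knots"]), tension=data["tension"])
    return fit


@dataclass
class PipelineResult:
    """Per-recording pipeline outputs with per-stage status."""

    status: dict[str, str]
    messages: dict[str, str]
    train: NAAEventTrain | None = None
    fit: PointProcessGLM | None = None
    curve: ModulationCurve | None = None
    features: HistoryFeatures | None = None
    ks: KSResult | None = None
    rates: dict | None = None


def run_pipeline(
    bundle: RecordingBundle,
    config: AnalysisConfig | None = None,
    out_dir=None,
) -> PipelineResult:
    """detect -> design/fit -> curve -> features -> gof, failures isolated.

    Each stage's output is written (when ``out_dir`` is given) and its
    status recorded; a failed stage skips everything downstream of it.
    """
    cfg = config or AnalysisConfig()
    status: dict[str, str] = {}
    messages: dict[str, str] = {}
    res = PipelineResult(status, messages)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def fail(stage: str, exc: Exception, *downstream: str) -> None:
        status[stage] = "failed"
        messages[stage] = f"{type(exc).__name__}: {exc}"
        log.warning("stage %s failed: %s", stage, exc)
        for s in downstream:
            status[s] = "skipped"

    try:
        detector = AvalancheDetector(cfg.baseline_window_s, cfg.drop_fraction,
                                     cfg.recovery_fraction)
        res.train = detector.detect(bundle.rr)
        res.rates = stage_rates(res.train, bundle.hypnogram)
        status["detect"] = "ok"
        if out is not None:
            episodes_frame(res.train).to_csv(out / "episodes.csv", index=False)
            rates_payload = StageRatesJSON(
                rates_per_hour={
                    (k.value if isinstance(k, StageCode) else k): v
                    for k, v in res.rates.items() if k != "overall"
                },
                overall_per_hour=res.rates.get("overall"),
            )
            (out / "stage_rates.json").write_text(
                json.dumps(rates_payload.model_dump(), indent=2) + "\n"
            )
    except Exception as exc:  # noqa: BLE001 - stage isolation by design
        fail("detect", exc, "fit", "features", "gof")
        return res

    if not bundle.events:
        messages["fit"] = "no scored events: SDB/arousal indicators identically 0"
        log.warning(messages["fit"])
    try:
        model = PointProcessGLM(
            bin_width=cfg.bin_width, burn_in_s=cfg.burn_in_s, tension=cfg.tension,
            knot_spacing=cfg.knot_spacing, ridge=cfg.ridge, tol=cfg.tol,
            max_iter=cfg.max_iter, min_events=cfg.min_events,
            sdb_pad_s=cfg.sdb_pad_s,
        )
        res.fit = model.fit_night(res.train, bundle.hypnogram, bundle.events)
        status["fit"] = "ok" if res.fit.reliable_ else "ok-unreliable"
        if out is not None:
            (out / "fit.json").write_text(
                json.dumps(fit_to_json(res.fit), indent=2) + "\n"
            )
    except Exception as exc:  # noqa: BLE001
        fail("fit", exc, "features", "gof")
        return res

    try:
        res.curve = modulation_curve(res.fit, grid_step=cfg.grid_step)
        res.features = extract_features(res.curve, cfg.width_mode)
        status["features"] = "ok"
        if out is not None:
            pd.DataFrame({
                "lag_s": res.curve.lag,
                "modulation": res.curve.modulation,
                "lcb": res.curve.lcb if res.curve.lcb is not None else np.nan,
                "ucb": res.curve.ucb if res.curve.ucb is not None else np.nan,
            }).to_csv(out / "curve.csv", index=False)
            f = res.features
            payload = FeaturesJSON(
                refractory_s=None if np.isnan(f.refractory_s) else f.refractory_s,
                ip_duration_s=None if np.isnan(f.ip_duration_s) else f.ip_duration_s,
                ip_peak_height=f.ip_peak_height,
                ip_peak_lag_s=f.ip_peak_lag_s,
                ip_peak_width_s=f.ip_peak_width_s,
                width_mode=cfg.width_mode,
            )
            (out / "features.json").write_text(
                json.dumps(payload.model_dump(), indent=2) + "\n"
            )
    except Exception as exc:  # noqa: BLE001
        fail("features", exc, "gof")
        return res

    try:
        m = res.fit.design_.include
        intensity = res.fit.predict_intensity(res.fit.design_)
        intensity.lam = intensity.lam[m]
        intensity.bin_start = intensity.bin_start[m]
        res.ks = ks_test(intensity, res.train, alpha=cfg.alpha,
                         jitter=cfg.gof_jitter, seed=cfg.seed)
        status["gof"] = "ok"
        if out is not None:
            payload = GofJSON(
                ks_stat=None if np.isnan(res.ks.ks_stat) else res.ks.ks_stat,
                threshold=None if np.isnan(res.ks.threshold) else res.ks.threshold,
                n_events=res.ks.n_events,
                passed=res.ks.passed,
                alpha=cfg.alpha,
            )
            (out / "gof.json").write_text(
                json.dumps(payload.model_dump(), indent=2) + "\n"
            )
    except Exception as exc:  # noqa: BLE001
        fail("gof", exc)
        return res

    if out is not None:
        (out / "status.json").write_text(
            json.dumps(PipelineStatusJSON(stages=status, messages=messages)
                       .model_dump(), indent=2) + "\n"
        )
    return res
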