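"""Cohort-level summaries and group comparisons.

Per-participant model outputs (multipliers, history features, stage
rates, KS results) are aggregated and compared across demographic
groups: multiplier CDFs and classification fractions, t/ANOVA/ANCOVA on
scalar features, permutation tests on whole modulation curves, and
exposure-weighted chi-square contrasts of stage-specific rates.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import HistoryFeatures, ModulationCurve
from .types import StageCode, _warn

AGE_BIN_EDGES = (65.0, 75.0)
AGE_BIN_LABELS = ("<65", "65-75", ">=75")
BMI_BIN_EDGES = (25.0, 30.0)
BMI_BIN_LABELS = ("<25", "25-30", ">=30")


@dataclass
class ParticipantRecord:
    """One participant's demographics and per-night model outputs."""

    id: str
    sex: str | None = None
    age: float | None = None
    bmi: float | None = None
    af_history: bool = False
    htn_history: bool = False
    sdb_multiplier: float = np.nan
    arousal_multiplier: float = np.nan
    converged: bool = True
    features: HistoryFeatures | None = None
    stage_counts: dict[StageCode, tuple[int, float]] | None = None
    ks_stat: float = np.nan
    ks_passed: bool | None = None
    curve: ModulationCurve | None = None

    def feature_value(self, name: str) -> float:
        if self.features is not None and name in self.features.as_dict():
            return self.features.as_dict()[name]
        if hasattr(self, name):
            return float(getattr(self, name))
        raise KeyError(f"unknown feature {name!r}")

    def age_group(self) -> str | None:
        if self.age is None:
            return None
        i = int(np.searchsorted(AGE_BIN_EDGES, self.age, side="right"))
        return AGE_BIN_LABELS[i]

    def bmi_group(self) -> str | None:
        if self.bmi is None:
            return None
        i = int(np.searchsorted(BMI_BIN_EDGES, self.bmi, side="right"))
        return BMI_BIN_LABELS[i]


@dataclass
class MultiplierSummary:
    """Classification and empirical CDF of per-participant multipliers."""

    which: str
    values: np.ndarray
    frac_gt1: float
    frac_0to1: float
    frac_near0: float
    near0_eps: float
    cdf_x: np.ndarray
    cdf_y: np.ndarray


def multiplier_summary(
    records: Sequence[ParticipantRecord],
    which: str = "SDB",
    near0_eps: float = 1e-3,
) -> MultiplierSummary:
    """Fractions of participants with multiplier > 1, in (eps, 1], in [0, eps].

    Only converged fits contribute.  The three fractions sum to 1; the
    CDF is the empirical distribution of the multipliers.
    """
    attr = {"SDB": "sdb_multiplier", "AROUSAL": "arousal_multiplier"}[which.upper()]
    vals = np.array(
        [getattr(r, attr) for r in records if r.converged and np.isfinite(getattr(r, attr))]
    )
    if vals.size == 0:
        raise ValueError("no converged fits with a finite multiplier")
    gt1 = np.mean(vals > 1.0)
    near0 = np.mean(vals <= near0_eps)
    mid = 1.0 - gt1 - near0
    x = np.sort(vals)
    y = np.arange(1, x.size + 1) / x.size
    return MultiplierSummary(which, vals, float(gt1), float(mid), float(near0),
                             near0_eps, x, y)


# ------------------------------------------------------------ group tests
@dataclass
class GroupTestResult:
    feature: str
    grouping: str
    test: str  # "welch_t" | "anova" | "ancova"
    statistic: float
    p_value: float
    group_means: dict[str, float]
    group_n: dict[str, int]
    adjusted_means: dict[str, float] | None = None


def _group_label(record: ParticipantRecord, grouping: str | Callable) -> Any:
    if callable(grouping):
        return grouping(record)
    if grouping == "sex":
        return record.sex
    if grouping == "age":
        return record.age_group()
    if grouping == "bmi":
        return record.bmi_group()
    raise ValueError("grouping must be 'sex', 'age', 'bmi' or a callable")


def feature_group_test(
    records: Sequence[ParticipantRecord],
    feature: str,
    grouping: str | Callable = "sex",
    covariates: Sequence[str] | None = None,
) -> GroupTestResult:
    """Compare a scalar feature across demographic groups.

    Two groups: Welch's t-test; three or more: one-way ANOVA; with
    covariates an ANCOVA linear model ``feature ~ group + covariates``
    is fitted and the group effect reported with covariate-adjusted
    means.  Groups with fewer than two members are dropped with a
    warning.
    """
    rows = []
    for r in records:
        g = _group_label(r, grouping)
        v = r.feature_value(feature)
        if g is None or not np.isfinite(v):
            continue
        row = {"group": str(g), "value": v}
        for c in covariates or ():
            row[c] = float(getattr(r, c))
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no usable records")
    sizes = df.groupby("group").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        _warn(f"dropping groups with < 2 members: {small}")
        df = df[~df["group"].isin(small)]
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups with >= 2 members")
    by = {g: df.loc[df["group"] == g, "value"].to_numpy() for g in groups}
    means = {g: float(v.mean()) for g, v in by.items()}
    ns = {g: int(v.size) for g, v in by.items()}
    gname = grouping if isinstance(grouping, str) else "custom"

    if covariates:
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        formula = "value ~ C(group) + " + " + ".join(covariates)
        model = smf.ols(formula, data=df).fit()
        table = anova_lm(model, typ=2)
        fstat = float(table.loc["C(group)", "F"])
        p = float(table.loc["C(group)", "PR(>F)"])
        cov_means = {c: df[c].mean() for c in covariates}
        adj = {}
        for g in groups:
            pred_df = pd.DataFrame({"group": [g], **{c: [cov_means[c]] for c in covariates}})
            adj[g] = float(model.predict(pred_df).iloc[0])
        return GroupTestResult(feature, gname, "ancova", fstat, p, means, ns, adj)
    if len(groups) == 2:
        a, b = by[groups[0]], by[groups[1]]
        if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0 and a.mean() == b.mean():
            return GroupTestResult(feature, gname, "welch_t", 0.0, 1.0, means, ns)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return GroupTestResult(feature, gname, "welch_t", float(t), float(p), means, ns)
    f, p = stats.f_oneway(*(by[g] for g in groups))
    return GroupTestResult(feature, gname, "anova", float(f), float(p), means, ns)


# ---------------------------------------------------- permutation curve test
@dataclass
class PermutationCurveResult:
    statistic_name: str  # "mean_|t|" or "mean_F"
    observed: float
    p_value: float | None
    observed_max: float
    p_value_max: float | None
    pointwise: np.ndarray  # pointwise statistic trace over the lag grid
    global_band: np.ndarray | None  # 95th percentile of permuted pointwise stat
    n_perm: int


def _pointwise_stat(M: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Pointwise two-group t (pooled) or one-way F across the lag grid."""
    if groups.size == 2:
        a = M[labels == groups[0]]
        b = M[labels == groups[1]]
        na, nb = a.shape[0], b.shape[0]
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        denom = np.sqrt(sp * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (a.mean(axis=0) - b.mean(axis=0)) / denom
        return np.nan_to_num(t)
    n = M.shape[0]
    grand = M.mean(axis=0)
    ssb = np.zeros(M.shape[1])
    ssw = np.zeros(M.shape[1])
    for g in groups:
        sub = M[labels == g]
        ssb += sub.shape[0] * (sub.mean(axis=0) - grand) ** 2
        ssw += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    dfb = groups.size - 1
    dfw = n - groups.size
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    return np.nan_to_num(f)


def permutation_curve_test(
    curves: Sequence[ModulationCurve | np.ndarray],
    labels: Sequence[Any],
    n_perm: int = 1000,
    seed=None,
) -> PermutationCurveResult:
    """Global permutation comparison of modulation curves across groups.

    The observed statistic is the mean over the lag grid of the
    pointwise group statistic (|t| for two groups, F for three or more);
    its null distribution comes from relabelling participants.  The
    max-over-lags variant and the 95th-percentile permutation envelope
    of the pointwise statistic support global pointwise bounds.
    """
    M = np.vstack([
        c.modulation if isinstance(c, ModulationCurve) else np.asarray(c, dtype=float)
        for c in curves
    ])
    first = curves[0]
    if isinstance(first, ModulationCurve):
        for c in curves[1:]:
            if isinstance(c, ModulationCurve) and not np.array_equal(c.lag, first.lag):
                raise ValueError("curves must share a common lag grid")
    labels = np.asarray([str(l) for l in labels])
    if labels.size != M.shape[0]:
        raise ValueError("one label per curve required")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two groups")
    two = groups.size == 2

    def summary(stat: np.ndarray) -> tuple[float, float]:
        s = np.abs(stat) if two else stat
        return float(s.mean()), float(s.max())

    pointwise = _pointwise_stat(M, labels, groups)
    obs_mean, obs_max = summary(pointwise)
    name = "mean_|t|" if two else "mean_F"
    if n_perm == 0:
        return PermutationCurveResult(name, obs_mean, None, obs_max, None,
                                      pointwise, None, 0)
    if n_perm < 100:
        _warn("n_perm < 100: permutation p-value has coarse resolution")
    rng = np.random.default_rng(seed)
    null_mean = np.empty(n_perm)
    null_max = np.empty(n_perm)
    null_point = np.empty((n_perm, M.shape[1]))
    for i in range(n_perm):
        perm = rng.permutation(labels)
        st = _pointwise_stat(M, perm, groups)
        null_point[i] = np.abs(st) if two else st
        null_mean[i], null_max[i] = summary(st)
    p_mean = (1 + np.sum(null_mean >= obs_mean)) / (n_perm + 1)
    p_max = (1 + np.sum(null_max >= obs_max)) / (n_perm + 1)
    band = np.quantile(null_point, 0.95, axis=0)
    return PermutationCurveResult(name, obs_mean, float(p_mean), obs_max,
                                  float(p_max), pointwise, band, n_perm)


# ------------------------------------------------------- stage-rate tests
@dataclass
class StageContrast:
    name: str
    chi2: float
    p_chi2: float
    t_stat: float
    p_t: float
    n_participants: int
    mean_rate_a: float
    mean_rate_b: float


def stage_rate_test(records: Sequence[ParticipantRecord]) -> dict[str, StageContrast]:
    """Paired stage-rate contrasts: light vs deep, light vs REM, sleep vs wake.

    Pooled event counts are compared with an exposure-weighted
    chi-square (expected counts proportional to stage exposure), with a
    paired t-test on per-participant rates as a robustness companion.
    Participants lacking exposure to either side of a contrast are
    excluded from it.
    """
    usable = [r for r in records if r.stage_counts is not None]
    if len(usable) < 2:
        raise ValueError("need at least two participants with stage counts")
    sleep_stages = (StageCode.LIGHT, StageCode.DEEP, StageCode.REM)
    contrasts = {
        "light_vs_deep": ((StageCode.LIGHT,), (StageCode.DEEP,)),
        "light_vs_rem": ((StageCode.LIGHT,), (StageCode.REM,)),
        "sleep_vs_wake": (sleep_stages, (StageCode.WAKE,)),
    }
    out: dict[str, StageContrast] = {}
    for name, (side_a, side_b) in contrasts.items():
        rates_a, rates_b = [], []
        na = nb = 0
        ta = tb = 0.0
        for r in usable:
            ca = sum(r.stage_counts[s][0] for s in side_a)
            ha = sum(r.stage_counts[s][1] for s in side_a)
            cb = sum(r.stage_counts[s][0] for s in side_b)
            hb = sum(r.stage_counts[s][1] for s in side_b)
            if ha <= 0 or hb <= 0:
                continue
            rates_a.append(ca / ha)
            rates_b.append(cb / hb)
            na += ca
            nb += cb
            ta += ha
            tb += hb
        if len(rates_a) < 2:
            continue
        total = na + nb
        ea = total * ta / (ta + tb)
        eb = total * tb / (ta + tb)
        if total > 0 and ea > 0 and eb > 0:
            chi2 = (na - ea) ** 2 / ea + (nb - eb) ** 2 / eb
            p_chi2 = float(stats.chi2.sf(chi2, df=1))
        else:
            chi2, p_chi2 = 0.0, 1.0
        diff = np.array(rates_a) - np.array(rates_b)
        if np.allclose(diff, diff[0]) and np.isclose(diff[0], 0.0):
            t_stat, p_t = 0.0, 1.0
        else:
            t_stat, p_t = stats.ttest_rel(rates_a, rates_b)
        out[name] = StageContrast(
            name, float(chi2), p_chi2, float(t_stat), float(p_t),
            len(rates_a), float(np.mean(rates_a)), float(np.mean(rates_b)),
        )
    return out
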