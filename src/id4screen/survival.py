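"""Median-dichotomized overall-survival analysis.

Target-gene expression is split at the within-stratum median ("high" strictly
above, ties at the median labelled "low"), a Kaplan-Meier product-limit curve
is fitted per arm, and the arms are compared with the standard two-group
log-rank test.  Conventions, stated because they change small-sample results:

* the dichotomy median is the lower-interpolation sample median;
* individuals censored at an event time remain at risk for events at that
  time (events precede censoring at ties);
* the log-rank variance term at a time with ``n`` at risk and ``d`` events is
  d * (n1/n) * (1 - n1/n) * (n - d) / (n - 1), zero when n = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_io import Cohort
from .errors import DegenerateInputError, ValidationError


@dataclass(frozen=True)
class DichotomyLabels:
    labels: dict[str, str]  # sample_id -> "high" | "low"
    median_used: float

    def arm(self, name: str) -> list[str]:
        return [s for s, v in self.labels.items() if v == name]


@dataclass(frozen=True)
class KMCurve:
    event_times: np.ndarray  # distinct times with >= 1 event, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    n_total: int

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of the product-limit estimate."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


@dataclass(frozen=True)
class StratumSurvival:
    stratum: str
    dichotomy: DichotomyLabels | None
    km_high: KMCurve | None
    km_low: KMCurve | None
    logrank: LogRankResult | None
    skipped_reason: str | None = None


def dichotomize_by_median(values: dict[str, float]) -> DichotomyLabels:
    """Label samples high/low around the lower-interpolation sample median.

    ``high`` iff value strictly greater than the median; values equal to the
    median go to ``low``.  All-equal values admit no split and raise.
    """
    items = [(s, float(v)) for s, v in values.items() if np.isfinite(v)]
    if len(items) < 2:
        raise DegenerateInputError("need >= 2 finite values to dichotomize")
    arr = np.array([v for _, v in items])
    if np.ptp(arr) == 0:
        raise DegenerateInputError("all values equal; no median split possible")
    median = float(np.percentile(arr, 50, method="lower"))
    labels = {s: ("high" if v > median else "low") for s, v in items}
    return DichotomyLabels(labels=labels, median_used=median)


def _check_times(times: np.ndarray) -> None:
    if (times < 0).any():
        raise ValidationError("negative survival time")


def km_estimate(os_months, os_event) -> KMCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(os_event, dtype=bool)
    if t.shape != e.shape:
        raise ValidationError("times and event flags differ in length")
    if t.size == 0:
        raise ValidationError("empty survival input")
    _check_times(t)
    event_times = np.unique(t[e])
    at_risk = np.array([(t >= u).sum() for u in event_times], dtype=int)
    events = np.array([((t == u) & e).sum() for u in event_times], dtype=int)
    with np.errstate(invalid="ignore"):
        survival = np.cumprod(1.0 - events / at_risk) if event_times.size else np.array([])
    return KMCurve(
        event_times=event_times, at_risk=at_risk, events=events,
        survival=survival, n_total=int(t.size),
    )


def logrank_test(group_a: tuple, group_b: tuple) -> LogRankResult:
    """Two-group log-rank test aggregating the 2x2 table at each event time.

    At each distinct event time the expected events in group A come from the
    hypergeometric mean d*nA/n with the matching variance; the chi-square is
    (O_A - E_A)^2 / V on one degree of freedom.
    """
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], bool)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], bool)
    _check_times(ta)
    _check_times(tb)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("each group needs >= 1 individual")
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    if not all_e.any():
        raise DegenerateInputError("log-rank undefined with zero events")
    event_times = np.unique(all_t[all_e])
    obs_a = exp_a = var = 0.0
    for u in event_times:
        n_a = float((ta >= u).sum())
        n_b = float((tb >= u).sum())
        n = n_a + n_b
        d_a = float(((ta == u) & ea).sum())
        d = d_a + float(((tb == u) & eb).sum())
        obs_a += d_a
        exp_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1.0 - n_a / n) * (n - d) / (n - 1.0)
    total_events = float(all_e.sum())
    if var == 0.0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (obs_a - exp_a) ** 2 / var
        p = float(max(stats.chi2.sf(chi2, df=1), np.finfo(float).tiny))
    return LogRankResult(
        chi_square=float(chi2), p_value=float(p),
        observed=(obs_a, total_events - obs_a),
        expected=(exp_a, total_events - exp_a),
    )


def stratified_survival_analysis(
    cohort: Cohort, target_gene: str, stratum_variable: str = "er_status"
) -> list[StratumSurvival]:
    """Per-stratum median dichotomy, KM per arm, and log-rank across arms.

    The median is computed within each stratum, not cohort-wide.  Strata whose
    dichotomy fails (all-equal expression) or leaves an arm with fewer than 2
    samples are reported as skipped rather than raising.
    """
    expr = cohort.expression.values
    if target_gene not in expr.index:
        raise ValidationError(f"target gene {target_gene!r} absent from expression")
    clin = cohort.clinical.data
    out: list[StratumSurvival] = []
    for stratum in sorted(s for s in clin[stratum_variable].unique() if s != "unknown"):
        members = clin.index[clin[stratum_variable] == stratum]
        usable = [
            s for s in members
            if np.isfinite(clin.loc[s, "os_months"])
            and clin.loc[s, "os_event"] in (True, False)
        ]
        values = {s: float(expr.loc[target_gene, s]) for s in usable}
        try:
            dichotomy = dichotomize_by_median(values)
        except DegenerateInputError as err:
            warnings.warn(f"stratum {stratum!r} skipped: {err}", stacklevel=2)
            out.append(StratumSurvival(stratum, None, None, None, None, str(err)))
            continue
        high, low = dichotomy.arm("high"), dichotomy.arm("low")
        if len(high) < 2 or len(low) < 2:
            reason = f"arm too small (high={len(high)}, low={len(low)})"
            warnings.warn(f"stratum {stratum!r} skipped: {reason}", stacklevel=2)
            out.append(StratumSurvival(stratum, dichotomy, None, None, None, reason))
            continue

        def _surv(samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
            return (
                clin.loc[samples, "os_months"].to_numpy(dtype=float),
                clin.loc[samples, "os_event"].to_numpy(dtype=bool),
            )

        th, eh = _surv(high)
        tl, el = _surv(low)
        km_high = km_estimate(th, eh)
        km_low = km_estimate(tl, el)
        try:
            lr = logrank_test((th, eh), (tl, el))
        except DegenerateInputError as err:
            out.append(StratumSurvival(stratum, dichotomy, km_high, km_low,
                                       None, str(err)))
            continue
        out.append(StratumSurvival(stratum, dichotomy, km_high, km_low, lr))
    return out
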