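"""Four-parameter logistic psychometrics for the visual-acuity task.

Hit rate and mean reaction time as functions of Gabor spatial frequency x
(cycles/degree) are fitted with

    f(x) = gamma + (lambda - gamma) / (1 + (x / alpha)^beta)

where gamma = f(inf) is the high-frequency asymptote (fixed at the 12.5%
chance rate of the 8-alternative task for hit rates), lambda = f(0+) the
low-frequency asymptote, alpha the inflection point (the acuity threshold:
the frequency at which performance is halfway between the asymptotes), and
beta the steepness.  Note that for reaction times the numerically smaller
asymptote is lambda (fast responses at low frequency): the "upper/lower"
labels of the two asymptotes refer to their magnitude, not to the gamma /
lambda roles in the formula.

Per-condition summaries use exact Clopper-Pearson intervals for hit rates
and BCa bootstrap intervals for mean reaction times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "SPATIAL_FREQUENCIES",
    "CHANCE_RATE_PCT",
    "LogisticParams",
    "logistic4",
    "summarize_conditions",
    "fit_logistic",
    "acuity_threshold",
    "classify_response",
]

# task condition set, cycles/degree
SPATIAL_FREQUENCIES = (1.5, 2.75, 4.0, 5.25, 6.5, 7.75, 9.0, 10.25, 11.5)
# 8-alternative forced choice chance performance
CHANCE_RATE_PCT = 100.0 / 8.0

EARLY_CUTOFF_MS = 50.0
RESPONSE_DEADLINE_MS = 500.0


@dataclass
class LogisticParams:
    """gamma, lambda, alpha, beta of the four-parameter logistic."""

    gamma: float
    lam: float
    alpha: float
    beta: float
    mode: str = "hit_rate"  # "hit_rate" | "rt"
    converged: bool = True
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


def logistic4(x, p: LogisticParams):
    """Evaluate the four-parameter logistic; f(alpha) = (gamma + lambda)/2."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("spatial frequency must be positive")
    val = p.gamma + (p.lam - p.gamma) / (1.0 + (x / p.alpha) ** p.beta)
    return float(val) if val.ndim == 0 else val


def classify_response(t_response_ms: float, to_target: bool = True) -> str:
    """Categorize a saccadic response by its latency from target onset.

    Faster than 50 ms counts as an anticipatory early response; a saccade to
    the correct target within 50-500 ms is a hit; anything else (too late,
    or wrong target) is a miss.
    """
    if t_response_ms < 0:
        raise ValueError("response latency must be non-negative")
    if t_response_ms < EARLY_CUTOFF_MS:
        return "early"
    if t_response_ms <= RESPONSE_DEADLINE_MS and to_target:
        return "hit"
    return "miss"


def summarize_conditions(
    trials: pd.DataFrame,
    conf: float = 0.999,
    n_boot: int = 10000,
    rng_seed: int = 0,
    include_incomplete: bool = False,
) -> pd.DataFrame:
    """Per-condition hit rates and mean RTs with confidence intervals.

    ``trials`` needs columns ``spatial_frequency``, ``outcome`` (hit, miss,
    early, break) and ``rt_ms`` (hits only).  The hit-rate denominator is
    hits + misses: early responses and fixation breaks are not completed
    choices among the 8 alternatives, so they are excluded unless
    ``include_incomplete``.  Hit-rate CIs are exact Clopper-Pearson; mean-RT
    CIs are BCa bootstrap with ``n_boot`` replications.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for x, grp in trials.groupby("spatial_frequency"):
        hits = int((grp["outcome"] == "hit").sum())
        misses = int((grp["outcome"] == "miss").sum())
        n = len(grp) if include_incomplete else hits + misses
        row = {"spatial_frequency": x, "n_trials": len(grp), "n_hits": hits}
        if n > 0:
            lo, hi = proportion_confint(hits, n, alpha=1.0 - conf, method="beta")
            row.update(hit_rate=100.0 * hits / n, hit_ci_lo=100.0 * lo, hit_ci_hi=100.0 * hi)
        else:
            row.update(hit_rate=np.nan, hit_ci_lo=np.nan, hit_ci_hi=np.nan)
        rts = grp.loc[grp["outcome"] == "hit", "rt_ms"].to_numpy(dtype=float)
        if rts.size >= 2 and np.ptp(rts) > 0:
            import warnings

            with warnings.catch_warnings():
                # tiny bootstrap samples can degenerate; reported as NaN CI
                warnings.simplefilter("ignore")
                res = stats.bootstrap(
                    (rts,), np.mean, n_resamples=n_boot, confidence_level=conf,
                    method="BCa", random_state=rng,
                )
            lo, hi = res.confidence_interval.low, res.confidence_interval.high
            row.update(mean_rt=rts.mean(), rt_ci_lo=lo, rt_ci_hi=hi,
                       rt_flag="" if np.isfinite(lo) and np.isfinite(hi) else "degenerate_ci")
        elif rts.size >= 1:
            row.update(mean_rt=rts.mean(), rt_ci_lo=np.nan, rt_ci_hi=np.nan, rt_flag="too_few_hits")
        else:
            row.update(mean_rt=np.nan, rt_ci_lo=np.nan, rt_ci_hi=np.nan, rt_flag="no_hits")
        rows.append(row)
    return pd.DataFrame.from_records(rows).sort_values("spatial_frequency").reset_index(drop=True)


def _logistic_raw(x, gamma, lam, alpha, beta):
    return gamma + (lam - gamma) / (1.0 + (x / alpha) ** beta)


def fit_logistic(summary: pd.DataFrame, mode: str = "hit_rate") -> LogisticParams:
    """Bounded least-squares fit of the four-parameter logistic to condition
    means.

    Hit-rate mode fixes gamma at the 12.5% chance rate and bounds lambda in
    [12.5, 100]; RT mode bounds both asymptotes in [50, 500] ms.  Conditions
    are weighted equally.
    """
    if mode == "hit_rate":
        y_col = "hit_rate"
    elif mode == "rt":
        y_col = "mean_rt"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    data = summary.dropna(subset=[y_col])
    x = data["spatial_frequency"].to_numpy(dtype=float)
    y = data[y_col].to_numpy(dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 conditions")
    alpha0 = float(np.median(x))
    flags = []
    if mode == "hit_rate":
        lam0 = min(max(y.max(), CHANCE_RATE_PCT + 1e-6), 100.0)

        def f(xx, lam, alpha, beta):
            return _logistic_raw(xx, CHANCE_RATE_PCT, lam, alpha, beta)

        try:
            popt, _ = optimize.curve_fit(
                f, x, y, p0=[lam0, alpha0, 2.0],
                bounds=([CHANCE_RATE_PCT, 1e-3, 0.05], [100.0, 1e3, 200.0]),
                maxfev=10000,
            )
            converged = True
        except RuntimeError:
            popt, converged = [lam0, alpha0, 2.0], False
        lam, alpha, beta = popt
        gamma = CHANCE_RATE_PCT
    else:
        gamma0 = min(max(y.max(), 50.0), 500.0)  # slow asymptote at high x
        lam0 = min(max(y.min(), 50.0), 500.0)  # fast asymptote at low x
        try:
            popt, _ = optimize.curve_fit(
                _logistic_raw, x, y, p0=[gamma0, lam0, alpha0, 2.0],
                bounds=([50.0, 50.0, 1e-3, 0.05], [500.0, 500.0, 1e3, 200.0]),
                maxfev=10000,
            )
            converged = True
        except RuntimeError:
            popt, converged = [gamma0, lam0, alpha0, 2.0], False
        gamma, lam, alpha, beta = popt
    if not converged:
        flags.append("non_convergence")
    if not (x.min() <= alpha <= x.max()):
        flags.append("threshold_extrapolated")
    return LogisticParams(float(gamma), float(lam), float(alpha), float(beta),
                          mode=mode, converged=converged, flags=flags)


def acuity_threshold(p: LogisticParams) -> float:
    """The acuity threshold: the inflection point alpha of the fit."""
    return p.alpha
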