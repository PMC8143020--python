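"""Receptive-field estimation from annulus/wedge responses.

Two complementary readouts of the same epochs:

* **Tuning fits** — the mean response per annulus (vs. midpoint
  eccentricity) is fitted with a Gaussian ``b + A exp(-(e-mu)^2/(2 sigma^2))``
  and the mean response per wedge (vs. polar center) with a von Mises
  ``b + A exp(kappa (cos(theta-mu) - 1))``, the circular analogue of the
  Gaussian.  The Gaussian mean is the peak eccentricity, the circular mean
  the polar angle.  RF size along the eccentricity axis (RFS_e) is the
  Gaussian FWHM; perpendicular to it (RFS_c) the chord subtending the von
  Mises FWHM arc at the peak eccentricity; overall RF size is the geometric
  mean sqrt(RFS_e * RFS_c).

* **Reverse-correlation maps** — each presented mask weighted by the evoked
  response, summed, and divided by the bias image (sum of presented masks)
  to normalize unequal repetition counts; annulus and wedge maps are
  multiplied pixel-wise and rescaled to [0, 1].

Mapping efficiency is quantified by recomputing maps and fits from r = 1..9
randomly drawn repetitions per condition (100 draws each): SNR in dB against
the full-data half-max ROI, and position/size errors against the full-data
estimate, with a baseline-window control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .geometry import MonitorSpec, polar_to_cartesian
from .neural_preproc import EpochSet
from .stimuli import StimulusCatalog

__all__ = [
    "TuningProfile",
    "TuningFit",
    "RFEstimate",
    "RFMap",
    "condition_profiles",
    "fit_gaussian_profile",
    "fit_vonmises_profile",
    "gaussian_fwhm",
    "vonmises_fwhm",
    "chord_from_arc",
    "rf_estimate",
    "reverse_correlation_map",
    "combine_maps",
    "model_map",
    "roi_from_map",
    "snr_db",
    "subsample_analysis",
]

log = logging.getLogger(__name__)

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = 2.3548 sigma
SNR_CAP_DB = 100.0


@dataclass
class TuningProfile:
    """Mean response per condition along one polar axis."""

    axis: np.ndarray  # annulus midpoints or wedge centers, degrees
    response: np.ndarray  # mean MUA per condition
    n_reps: np.ndarray  # repetitions entering each mean
    kind: str  # "annulus" | "wedge"

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.n_reps = np.asarray(self.n_reps, dtype=int)
        if np.any(self.n_reps < 1):
            raise ValueError("every included condition needs >=1 repetition")

    @property
    def circular(self) -> bool:
        return self.kind == "wedge"


@dataclass
class TuningFit:
    kind: str  # "gaussian" | "von_mises"
    amplitude: float
    offset: float
    loc: float  # mu, degrees; circular (mod 360) for von Mises
    spread: float  # sigma (deg) for gaussian, kappa (unitless) for von Mises
    resid_norm: float
    converged: bool = True
    flags: list = field(default_factory=list)


@dataclass
class RFEstimate:
    peak_eccentricity: float
    polar_angle: float
    rfs_e: float  # FWHM along the eccentricity axis, degrees
    rfs_c: float  # chord length perpendicular to it, degrees
    rf_size: float  # geometric mean of the two
    flags: list = field(default_factory=list)


@dataclass
class RFMap:
    values: np.ndarray  # height x width
    monitor: MonitorSpec
    provenance: str  # annulus | wedge | combined | model
    flags: list = field(default_factory=list)
    coverage: np.ndarray = None  # pixels reached by >=1 stimulus (bias > 0)


# ---------------------------------------------------------------------------
# tuning profiles and fits
# ---------------------------------------------------------------------------

def condition_profiles(
    epochs: EpochSet,
    catalog: StimulusCatalog,
    channel: int = 0,
    response_window=(0.0, 100.0),
) -> tuple[TuningProfile, TuningProfile]:
    """Annulus and wedge tuning profiles for one channel.

    Per condition: mean over valid epochs of the epoch-mean MUA in the
    response window.  Conditions without valid epochs are excluded (logged).
    """
    resp = epochs.window_mean(*response_window)[:, channel]
    valid = epochs.valid[:, channel]

    def profile(ids, axis_values, kind):
        ax, mean, reps = [], [], []
        for sid, a in zip(ids, axis_values):
            idx = (epochs.condition_ids == sid) & valid
            n = int(idx.sum())
            if n == 0:
                log.info("condition %s absent from valid epochs, excluded", sid)
                continue
            ax.append(a)
            mean.append(resp[idx].mean())
            reps.append(n)
        return TuningProfile(np.array(ax), np.array(mean), np.array(reps), kind)

    return (
        profile(catalog.annulus_ids, catalog.annulus_midpoints(), "annulus"),
        profile(catalog.wedge_ids, catalog.wedge_centers(), "wedge"),
    )


def _gauss(e, b, A, mu, sigma):
    return b + A * np.exp(-((e - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian_profile(p: TuningProfile) -> TuningFit:
    """Least-squares Gaussian fit of an eccentricity tuning profile."""
    if p.axis.size < 4:
        raise ValueError("need at least 4 conditions for a Gaussian fit")
    y = p.response
    span = p.axis.max() - p.axis.min()
    b0 = y.min()
    A0 = max(y.max() - y.min(), 1e-12)
    mu0 = p.axis[int(np.argmax(y))]
    w = np.clip(y - b0, 0, None)
    sigma0 = math.sqrt(np.sum(w * (p.axis - mu0) ** 2) / max(np.sum(w), 1e-12)) or span / 4
    sigma0 = min(max(sigma0, span / 50), span)
    # a Gaussian wider than the sampled extent is not measurable from these
    # conditions; bound sigma there and flag fits pinned against the bound
    lo = [-np.inf, 0.0, p.axis.min(), span / 200]
    hi = [np.inf, np.inf, p.axis.max(), span]
    try:
        popt, _ = optimize.curve_fit(
            _gauss, p.axis, y, p0=[b0, A0, mu0, sigma0], bounds=(lo, hi), maxfev=5000
        )
        converged = True
    except RuntimeError:
        popt, converged = [b0, A0, mu0, sigma0], False
    b, A, mu, sigma = popt
    resid = float(np.linalg.norm(_gauss(p.axis, *popt) - y))
    flags = [] if converged else ["non_convergence"]
    # an amplitude that does not clear twice the residual noise level is not
    # resolvable; widths from such fits are meaningless
    if A < max(1e-6 * max(1.0, abs(b)), 2.0 * resid / math.sqrt(p.axis.size)):
        flags.append("low_amplitude")
    if sigma >= 0.95 * span:
        flags.append("width_at_bound")
    return TuningFit("gaussian", float(A), float(b), float(mu), float(sigma), resid, converged, flags)


def _vonmises(theta_deg, b, A, mu_deg, kappa):
    d = np.radians(theta_deg - mu_deg)
    return b + A * np.exp(kappa * (np.cos(d) - 1.0))


def fit_vonmises_profile(p: TuningProfile) -> TuningFit:
    """Least-squares von Mises fit of a polar-angle tuning profile.

    The location parameter is fitted unbounded around the circular-mean
    initialization and reported modulo 360.
    """
    if p.axis.size < 4:
        raise ValueError("need at least 4 conditions for a von Mises fit")
    y = p.response
    b0 = y.min()
    A0 = max(y.max() - y.min(), 1e-12)
    w = np.clip(y - b0, 0, None)
    if w.sum() <= 0:
        mu0, kappa0 = p.axis[int(np.argmax(y))], 1.0
    else:
        z = np.sum(w * np.exp(1j * np.radians(p.axis))) / w.sum()
        mu0 = math.degrees(np.angle(z)) % 360.0
        R = min(abs(z), 0.999)
        kappa0 = max(R * (2.0 - R**2) / (1.0 - R**2), 0.1)  # circular-stats approximation
    lo = [-np.inf, 0.0, mu0 - 180.0, 1e-3]
    hi = [np.inf, np.inf, mu0 + 180.0, 500.0]
    try:
        popt, _ = optimize.curve_fit(
            _vonmises, p.axis, y, p0=[b0, A0, mu0, min(kappa0, 500.0)], bounds=(lo, hi), maxfev=5000
        )
        converged = True
    except RuntimeError:
        popt, converged = [b0, A0, mu0, kappa0], False
    b, A, mu, kappa = popt
    resid = float(np.linalg.norm(_vonmises(p.axis, *popt) - y))
    flags = [] if converged else ["non_convergence"]
    if A < max(1e-6 * max(1.0, abs(b)), 2.0 * resid / math.sqrt(p.axis.size)):
        flags.append("low_amplitude")
    return TuningFit("von_mises", float(A), float(b), float(mu % 360.0), float(kappa), resid, converged, flags)


def gaussian_fwhm(sigma: float) -> float:
    """Full width at half maximum of a Gaussian: 2 sqrt(2 ln 2) sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return FWHM_FACTOR * sigma


def vonmises_fwhm(kappa: float) -> float:
    """FWHM of ``exp(kappa (cos(theta) - 1))`` in degrees of polar angle.

    Half maximum requires ``cos(theta) = 1 - ln2/kappa``; for
    ``kappa <= ln2 / 2`` the curve never falls to half its peak-to-trough
    range on the circle and the width saturates at 360 degrees.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    c = 1.0 - math.log(2.0) / kappa
    if c <= -1.0:
        return 360.0
    return 2.0 * math.degrees(math.acos(c))


def chord_from_arc(arc_angle_deg: float, radius: float) -> float:
    """Chord length subtending ``arc_angle_deg`` at ``radius``: 2 r sin(a/2)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0 < arc_angle_deg <= 360:
        raise ValueError("arc angle must lie in (0, 360]")
    return 2.0 * radius * math.sin(math.radians(arc_angle_deg) / 2.0)


def rf_estimate(gfit: TuningFit, vfit: TuningFit) -> RFEstimate:
    """Combine the Gaussian and von Mises fits into one RF estimate."""
    if not (gfit.converged and vfit.converged):
        raise ValueError("both tuning fits must have converged")
    if gfit.loc <= 0:
        raise ValueError("peak eccentricity must be positive")
    flags = []
    width_deg = vonmises_fwhm(vfit.spread)
    if width_deg >= 360.0:
        flags.append("width_saturated")
    rfs_e = gaussian_fwhm(gfit.spread)
    rfs_c = chord_from_arc(width_deg, gfit.loc)
    return RFEstimate(
        peak_eccentricity=gfit.loc,
        polar_angle=vfit.loc % 360.0,
        rfs_e=rfs_e,
        rfs_c=rfs_c,
        rf_size=math.sqrt(rfs_e * rfs_c),
        flags=flags + gfit.flags + vfit.flags,
    )


# ---------------------------------------------------------------------------
# reverse-correlation maps
# ---------------------------------------------------------------------------

def _bias_normalized_map(weights, counts, mask_matrix, shape):
    """(sum_e resp_e * mask_e) / (sum_e mask_e), both expressed per
    condition: weights = summed response per condition, counts =
    presentations per condition.  Zero-bias pixels are set to 0."""
    num = weights @ mask_matrix
    bias = counts.astype(float) @ mask_matrix
    out = np.divide(num, bias, out=np.zeros_like(num), where=bias > 0)
    return out.reshape(shape), bool((bias == 0).any())


def reverse_correlation_map(
    epochs: EpochSet,
    catalog: StimulusCatalog,
    response_window=(0.0, 100.0),
    channel: int = 0,
) -> tuple[RFMap, RFMap]:
    """Bias-normalized response-weighted stimulus average, separately for
    annuli and wedges.

    Each valid epoch's mean MUA in the window multiplies the presented
    stimulus mask; the summed image is divided pixel-wise by the bias image
    (sum of all presented masks).  Pixels never covered by a stimulus have
    zero bias and are set to 0 with a flag.
    """
    resp = epochs.window_mean(*response_window)[:, channel]
    valid = epochs.valid[:, channel]
    shape = (catalog.monitor.height_px, catalog.monitor.width_px)
    maps = []
    for ids, provenance in ((catalog.annulus_ids, "annulus"), (catalog.wedge_ids, "wedge")):
        weights = np.zeros(len(ids))
        counts = np.zeros(len(ids))
        for j, sid in enumerate(ids):
            idx = (epochs.condition_ids == sid) & valid
            weights[j] = resp[idx].sum()
            counts[j] = idx.sum()
        if counts.sum() == 0:
            raise ValueError(f"no valid {provenance} epochs")
        mm = catalog.mask_matrix(ids)
        values, zero_bias = _bias_normalized_map(weights, counts, mm, shape)
        flags = ["zero_bias_pixels"] if zero_bias else []
        coverage = ((counts.astype(float) @ mm) > 0).reshape(shape)
        maps.append(
            RFMap(values=values, monitor=catalog.monitor, provenance=provenance,
                  flags=flags, coverage=coverage)
        )
    return maps[0], maps[1]


def _minmax_scale(values, coverage=None):
    """Rescale to [0,1] over the covered field; uncovered pixels go to 0.

    The minimum and maximum are taken over covered pixels only, so pixels
    never reached by a stimulus (which carry no response information) do not
    anchor the scale.
    """
    if coverage is None:
        sub = values
    else:
        sub = values[coverage]
    lo, hi = sub.min(), sub.max()
    if hi == lo:
        return np.zeros_like(values), True
    out = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    if coverage is not None:
        out = np.where(coverage, out, 0.0)
    return out, False


def combine_maps(a: RFMap, w: RFMap) -> RFMap:
    """Pixel-wise product of the annulus and wedge maps, rescaled to [0,1]."""
    if a.values.shape != w.values.shape:
        raise ValueError("maps must share a grid")
    prod = a.values * w.values
    coverage = None
    if a.coverage is not None and w.coverage is not None:
        coverage = a.coverage & w.coverage
    scaled, degenerate = _minmax_scale(prod, coverage)
    flags = ["degenerate"] if degenerate else []
    return RFMap(values=scaled, monitor=a.monitor, provenance="combined",
                 flags=flags, coverage=coverage)


def model_map(gfit: TuningFit, vfit: TuningFit, catalog: StimulusCatalog) -> RFMap:
    """RF model image: radial Gaussian x angular von Mises, evaluated at
    each pixel's polar coordinates and rescaled to [0,1]."""
    if not (gfit.converged and vfit.converged):
        raise ValueError("both tuning fits must have converged")
    ecc, ang = catalog.pixel_polar()
    radial = np.exp(-((ecc - gfit.loc) ** 2) / (2.0 * gfit.spread**2))
    angular = np.exp(vfit.spread * (np.cos(np.radians(ang - vfit.loc)) - 1.0))
    scaled, degenerate = _minmax_scale(radial * angular)
    flags = ["degenerate"] if degenerate else []
    return RFMap(values=scaled, monitor=catalog.monitor, provenance="model", flags=flags)


def roi_from_map(rfmap: RFMap) -> np.ndarray:
    """Pixels strictly above half the map maximum.

    On a uniform map every pixel exceeds max/2 (the value equals the max),
    so the ROI is the whole map; degenerate all-zero maps are rejected.
    """
    if "degenerate" in rfmap.flags or rfmap.values.max() <= 0:
        raise ValueError("cannot derive an ROI from a degenerate map")
    return rfmap.values > rfmap.values.max() / 2.0


def snr_db(rfmap: RFMap, roi: np.ndarray) -> float:
    """Amplitude SNR in dB: 20 log10(mean inside ROI / mean outside)."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any() or roi.all():
        raise ValueError("ROI and its complement must both be non-empty")
    inside = rfmap.values[roi].mean()
    outside = rfmap.values[~roi].mean()
    if outside <= 0:
        return SNR_CAP_DB
    return 20.0 * math.log10(inside / outside) if inside > 0 else -SNR_CAP_DB


# ---------------------------------------------------------------------------
# subsampling / SNR analysis
# ---------------------------------------------------------------------------

def _site_estimate(ann_profile, wdg_profile):
    gfit = fit_gaussian_profile(ann_profile)
    vfit = fit_vonmises_profile(wdg_profile)
    return gfit, vfit, rf_estimate(gfit, vfit)


def _center_xy(est: RFEstimate):
    return polar_to_cartesian(est.peak_eccentricity, est.polar_angle)


def _condition_responses(epochs, catalog, channel, window):
    """Per condition: array of per-epoch window means (valid epochs only),
    ordered as catalog annuli then wedges."""
    resp = epochs.window_mean(*window)[:, channel]
    valid = epochs.valid[:, channel]
    per_cond = []
    for sid in catalog.annulus_ids + catalog.wedge_ids:
        idx = (epochs.condition_ids == sid) & valid
        per_cond.append(resp[idx])
    return per_cond


def subsample_analysis(
    epochs: EpochSet,
    catalog: StimulusCatalog,
    channel: int = 0,
    max_reps: int = 9,
    n_draws: int = 100,
    n_boot: int = 10000,
    rng_seed: int = 0,
    response_window=(0.0, 100.0),
    baseline_window=(-100.0, 0.0),
    conf: float = 0.95,
    include_full: bool = True,
    fit_errors: bool = True,
):
    """Repetition-subsampling analysis of mapping efficiency for one site.

    For each repetition count r = 1..max_reps and each of ``n_draws``
    seeded draws, r presentations per condition are drawn without
    replacement and the maps and tuning fits recomputed.  Reported per draw:

    * ``snr_db`` — SNR of the subsampled combined map against the ROI from
      the full-data map (the ROI is fixed across all runs of a site);
    * ``snr_db_baseline`` — the same computation on the pre-stimulus window,
      a control that should carry no spatial signal;
    * ``pos_err_deg`` — Euclidean distance in degrees between the subsampled
      and full-data RF centers (from the tuning fits);
    * ``size_err_deg`` — subsampled minus full-data RF size (signed; negative
      means underestimation) and the corresponding relative errors.

    Each (r, draw) uses an independent seeded substream, reproducible in
    isolation.  Returns ``(draws, summary, full_estimate)``: the per-draw
    table, a per-r summary with percentile-bootstrap CIs of the mean SNR,
    and the full-data :class:`RFEstimate`.
    """
    n_cond_a = len(catalog.annulus_ids)
    resp_by_cond = _condition_responses(epochs, catalog, channel, response_window)
    base_by_cond = _condition_responses(epochs, catalog, channel, baseline_window)
    counts_all = np.array([len(r) for r in resp_by_cond])
    n_avail = counts_all.min()
    if n_avail < max_reps:
        log.warning("only %d repetitions available; truncating r steps from %d", n_avail, max_reps)
        max_reps = int(n_avail)

    ann_axis = catalog.annulus_midpoints()
    wdg_axis = catalog.wedge_centers()
    mm_a = catalog.mask_matrix(catalog.annulus_ids)
    mm_w = catalog.mask_matrix(catalog.wedge_ids)
    shape = (catalog.monitor.height_px, catalog.monitor.width_px)

    # full-data reference: ROI from the combined map, center/size from fits
    amap, wmap = reverse_correlation_map(epochs, catalog, response_window, channel)
    full_combined = combine_maps(amap, wmap)
    roi = roi_from_map(full_combined).ravel()
    coverage = full_combined.coverage.ravel() if full_combined.coverage is not None else None
    full_ann = TuningProfile(ann_axis, [r.mean() for r in resp_by_cond[:n_cond_a]], counts_all[:n_cond_a], "annulus")
    full_wdg = TuningProfile(wdg_axis, [r.mean() for r in resp_by_cond[n_cond_a:]], counts_all[n_cond_a:], "wedge")
    _, _, full_est = _site_estimate(full_ann, full_wdg)
    full_xy = _center_xy(full_est)

    def combined_snr(w_a, w_w, c_a, c_w):
        ma, _ = _bias_normalized_map(w_a, c_a, mm_a, shape)
        mw, _ = _bias_normalized_map(w_w, c_w, mm_w, shape)
        scaled, degenerate = _minmax_scale((ma * mw).ravel(), coverage)
        if degenerate:
            return np.nan
        inside, outside = scaled[roi].mean(), scaled[~roi].mean()
        if outside <= 0:
            return SNR_CAP_DB
        return 20.0 * math.log10(inside / outside) if inside > 0 else -SNR_CAP_DB

    records = []
    r_values = list(range(1, max_reps + 1)) + ([int(n_avail)] if include_full and n_avail > max_reps else [])
    for r in r_values:
        full_r = r == n_avail
        for draw in range(n_draws if not full_r else 1):
            rng = np.random.default_rng(np.random.SeedSequence([rng_seed, r, draw]))
            means_s = np.empty(len(resp_by_cond))
            means_b = np.empty(len(resp_by_cond))
            for j, (rs, bs) in enumerate(zip(resp_by_cond, base_by_cond)):
                pick = np.arange(len(rs)) if full_r else rng.choice(len(rs), size=r, replace=False)
                means_s[j] = rs[pick].mean()
                means_b[j] = bs[pick].mean()
            snr_s = combined_snr(means_s[:n_cond_a] * r, means_s[n_cond_a:] * r,
                                 np.full(n_cond_a, r), np.full(len(wdg_axis), r))
            snr_b = combined_snr(means_b[:n_cond_a] * r, means_b[n_cond_a:] * r,
                                 np.full(n_cond_a, r), np.full(len(wdg_axis), r))
            rec = {"r": r, "draw": draw, "snr_db": snr_s, "snr_db_baseline": snr_b,
                   "full_data": full_r}
            if fit_errors:
                # flagged fits (saturated or bound-pinned widths, failed
                # convergence) carry no usable size/position estimate and
                # are excluded from the error aggregates
                try:
                    _, _, est = _site_estimate(
                        TuningProfile(ann_axis, means_s[:n_cond_a], np.full(n_cond_a, r), "annulus"),
                        TuningProfile(wdg_axis, means_s[n_cond_a:], np.full(len(wdg_axis), r), "wedge"),
                    )
                    if est.flags:
                        raise ValueError("flagged fit")
                    xy = _center_xy(est)
                    pos = math.hypot(xy[0] - full_xy[0], xy[1] - full_xy[1])
                    size = est.rf_size - full_est.rf_size
                    rec.update(
                        fit_ok=True,
                        pos_err_deg=pos,
                        size_err_deg=size,
                        rel_pos_err=pos / full_est.rf_size,
                        rel_size_err=size / full_est.rf_size,
                    )
                except ValueError:
                    rec.update(fit_ok=False, pos_err_deg=np.nan, size_err_deg=np.nan,
                               rel_pos_err=np.nan, rel_size_err=np.nan)
            records.append(rec)
    draws = pd.DataFrame.from_records(records)

    # percentile bootstrap of the mean across draws, per r and measure
    boot_rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 7_654_321]))
    rows = []
    for r, grp in draws.groupby("r"):
        for measure in ("snr_db", "snr_db_baseline") + (("pos_err_deg", "size_err_deg") if fit_errors else ()):
            vals = grp[measure].dropna().to_numpy()
            if vals.size == 0:
                continue
            mean = vals.mean()
            if vals.size > 1:
                idx = boot_rng.integers(0, vals.size, size=(n_boot, vals.size))
                boot_means = vals[idx].mean(axis=1)
                lo, hi = np.quantile(boot_means, [(1 - conf) / 2, 1 - (1 - conf) / 2])
            else:
                lo = hi = mean
            rows.append({"r": r, "measure": measure, "mean": mean, "ci_lo": lo, "ci_hi": hi})
    summary = pd.DataFrame.from_records(rows)
    return draws, summary, full_est
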