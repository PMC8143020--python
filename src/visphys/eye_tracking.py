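"""Offline gaze calibration and per-session accuracy/precision.

Raw tracker coordinates from a calibration session are clustered at the
known target locations; one anchor (density mode) per target is extracted
and a full third-order bivariate polynomial (10 terms per output dimension)
is fitted mapping raw coordinates to screen degrees.  The resulting template
is applied to later sessions without further correction.

Session quality is quantified on the calibrated central fixation data:
2D-histogram the samples (0.05 deg bins, central 2.5 deg square), fit 1D
Gaussians to the x and y marginal profiles, and report the fitted means as
accuracy offsets and the fitted SDs as precision sigmas; absolute offset and
sigma are the Euclidean norms of the per-axis values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geometry import MonitorSpec

__all__ = [
    "GazeSamples",
    "CalibrationTargets",
    "CalibrationModel",
    "SessionQuality",
    "DEFAULT_TARGETS_PX",
    "polynomial_basis",
    "estimate_cluster_anchors",
    "fit_calibration",
    "apply_calibration",
    "session_accuracy_precision",
    "offset_sigma_correlation",
]

# nine-point target grid, pixels from screen center
DEFAULT_TARGETS_PX = np.array(
    [
        (0, 0),
        (-300, -150), (-300, 0), (-300, 150),
        (0, 150), (300, 150), (300, 0), (300, -150),
        (0, -150),
    ],
    dtype=float,
)


@dataclass
class GazeSamples:
    """Gaze stream: time in ms, coordinates raw (tracker units) or degrees."""

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray = None
    unit: str = "raw"  # "raw" | "deg"

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t_ms.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(np.diff(self.t_ms) < 0):
            raise ValueError("time must be non-decreasing")

    def __len__(self):
        return self.t_ms.size


@dataclass(frozen=True)
class CalibrationTargets:
    """Calibration target positions; pixels referenced from screen center."""

    positions_px: np.ndarray = field(default_factory=lambda: DEFAULT_TARGETS_PX.copy())
    monitor: MonitorSpec = field(default_factory=MonitorSpec)

    def __post_init__(self):
        pos = np.asarray(self.positions_px, dtype=float)
        object.__setattr__(self, "positions_px", pos)
        if len(np.unique(pos, axis=0)) != len(pos):
            raise ValueError("target positions must be distinct")
        if not (pos == 0).all(axis=1).any():
            raise ValueError("target set must include the center")

    @property
    def positions_deg(self) -> np.ndarray:
        return self.positions_px / self.monitor.px_per_deg


def polynomial_basis(x, y):
    """Full bivariate cubic basis: columns 1, x, y, x2, xy, y2, x3, x2y, xy2, y3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.stack(
        [np.ones_like(x), x, y, x * x, x * y, y * y, x**3, x * x * y, x * y * y, y**3],
        axis=-1,
    )


@dataclass
class CalibrationModel:
    """Third-order bivariate polynomial raw -> screen degrees.

    Raw inputs are centered and scaled (stored in ``center``/``scale``)
    before the basis is evaluated, for numerical conditioning.
    """

    coef_x: np.ndarray  # 10 coefficients for the x output
    coef_y: np.ndarray
    center: np.ndarray  # raw-space normalization
    scale: np.ndarray
    residuals: np.ndarray = None  # per-anchor Euclidean residual, degrees

    def predict(self, raw_x, raw_y):
        u = (np.asarray(raw_x, dtype=float) - self.center[0]) / self.scale[0]
        v = (np.asarray(raw_y, dtype=float) - self.center[1]) / self.scale[1]
        phi = polynomial_basis(u, v)
        return phi @ self.coef_x, phi @ self.coef_y

    def to_json(self, path):
        payload = {
            "order": 3,
            "coef_x": self.coef_x.tolist(),
            "coef_y": self.coef_y.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "residuals": None if self.residuals is None else self.residuals.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            coef_x=np.array(p["coef_x"]),
            coef_y=np.array(p["coef_y"]),
            center=np.array(p["center"]),
            scale=np.array(p["scale"]),
            residuals=None if p["residuals"] is None else np.array(p["residuals"]),
        )


@dataclass
class SessionQuality:
    offset_x: float
    offset_y: float
    sigma_x: float
    sigma_y: float
    flags: list = field(default_factory=list)

    @property
    def absolute_offset(self) -> float:
        return float(np.hypot(self.offset_x, self.offset_y))

    @property
    def absolute_sigma(self) -> float:
        return float(np.hypot(self.sigma_x, self.sigma_y))


# ---------------------------------------------------------------------------
# anchors and polynomial fit
# ---------------------------------------------------------------------------

def _mean_shift_mode(points, start, bandwidth, n_iter=20):
    """Density mode near ``start``: iterated mean of samples within the
    bandwidth window."""
    mode = np.asarray(start, dtype=float)
    for _ in range(n_iter):
        d = np.linalg.norm(points - mode, axis=1)
        inside = d <= bandwidth
        if not inside.any():
            return None
        new = points[inside].mean(axis=0)
        if np.linalg.norm(new - mode) < 1e-12:
            break
        mode = new
    return mode


def estimate_cluster_anchors(
    gaze: GazeSamples,
    targets: CalibrationTargets,
    mode: str = "auto",
    manual_anchors: np.ndarray | None = None,
    n_bins: int = 64,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """One raw-space anchor (gaze density peak) per calibration target.

    ``manual`` mode accepts user-picked anchor coordinates verbatim, in
    target order — the faithful analogue of picking density peaks by hand.
    ``auto`` mode is a surrogate: a coarse moment-matching affine maps the
    targets into raw space, a 2D histogram locates density peaks, each
    warped target is matched to its nearest peak, and the anchor is refined
    by mean-shift.  Returns (raw anchor, target degrees) pairs.
    """
    tdeg = targets.positions_deg
    if mode == "manual":
        if manual_anchors is None:
            raise ValueError("manual mode requires manual_anchors")
        anchors = np.asarray(manual_anchors, dtype=float)
        if anchors.shape != tdeg.shape:
            raise ValueError("one anchor per target required")
        return [(anchors[i], tdeg[i]) for i in range(len(tdeg))]

    pts = np.column_stack([gaze.x[gaze.valid], gaze.y[gaze.valid]])
    if len(pts) < 10 * len(tdeg):
        raise ValueError("too few valid samples for anchor estimation")
    # coarse affine pre-alignment: match the robust extent of the raw cloud
    # to the target extent (moment matching would be dominated by the
    # over-represented central fixations)
    q_lo, q_hi = np.quantile(pts, [0.005, 0.995], axis=0)
    t_lo, t_hi = tdeg.min(axis=0), tdeg.max(axis=0)
    span_t = np.where(t_hi > t_lo, t_hi - t_lo, 1.0)
    scale = (q_hi - q_lo) / span_t
    warped = (q_lo + q_hi) / 2.0 + (tdeg - (t_lo + t_hi) / 2.0) * scale

    hist, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=n_bins)
    from scipy.ndimage import maximum_filter

    peaks_mask = (hist == maximum_filter(hist, size=3)) & (hist > 0)
    xi, yi = np.where(peaks_mask)
    order = np.argsort(hist[xi, yi])[::-1][: 4 * len(tdeg)]
    peak_xy = np.column_stack(
        [(xe[xi[order]] + xe[xi[order] + 1]) / 2, (ye[yi[order]] + ye[yi[order] + 1]) / 2]
    )
    if len(peak_xy) < len(tdeg):
        raise ValueError(f"found only {len(peak_xy)} density peaks for {len(tdeg)} targets")

    min_sep = np.min(
        [np.linalg.norm(warped[i] - warped[j]) for i in range(len(warped)) for j in range(i + 1, len(warped))]
    )
    bandwidth = 0.35 * min_sep
    anchors, unmatched = [], []
    for i, wt in enumerate(warped):
        d = np.linalg.norm(peak_xy - wt, axis=1)
        j = int(np.argmin(d))
        if d[j] > min_sep:
            unmatched.append(i)
            continue
        refined = _mean_shift_mode(pts, peak_xy[j], bandwidth)
        if refined is None:
            unmatched.append(i)
            continue
        anchors.append((refined, tdeg[i]))
    if unmatched:
        raise ValueError(f"no density peak matched targets at indices {unmatched}")
    return anchors


def fit_calibration(anchors, targets_deg=None, max_condition: float = 1e10) -> CalibrationModel:
    """Fit the cubic polynomial mapping raw anchors to target degrees.

    ``anchors`` may be the (raw, target) pair list from
    :func:`estimate_cluster_anchors`, or a raw (n, 2) array with
    ``targets_deg`` given separately.  With nine anchors the 10-term cubic
    is underdetermined; the minimum-norm least-squares solution is used,
    which still interpolates the anchors exactly.  Collinear (rank-deficient)
    anchor configurations are rejected with the condition number.
    """
    if targets_deg is None:
        raw = np.array([a[0] for a in anchors], dtype=float)
        tgt = np.array([a[1] for a in anchors], dtype=float)
    else:
        raw = np.asarray(anchors, dtype=float)
        tgt = np.asarray(targets_deg, dtype=float)
    if raw.shape[0] < 6:
        raise ValueError("need at least 6 anchor/target pairs")
    center = raw.mean(axis=0)
    scale = raw.std(axis=0)
    scale[scale == 0] = 1.0
    u = (raw - center) / scale
    phi = polynomial_basis(u[:, 0], u[:, 1])
    # geometric degeneracy check on the affine part: collinear anchors make
    # the 2D map unidentifiable.  Higher-order collinearities (e.g. x^3 vs x
    # on a 3x3 grid) are benign: the minimum-norm solution still
    # interpolates the anchors.
    s = np.linalg.svd(phi[:, :3], compute_uv=False)
    if s[2] <= s[0] / max_condition:
        raise ValueError(
            f"anchor configuration is rank-deficient / collinear "
            f"(affine condition number {s[0] / max(s[2], 1e-300):.3g})"
        )
    coef, *_ = np.linalg.lstsq(phi, tgt, rcond=None)
    model = CalibrationModel(coef_x=coef[:, 0], coef_y=coef[:, 1], center=center, scale=scale)
    px, py = model.predict(raw[:, 0], raw[:, 1])
    model.residuals = np.hypot(px - tgt[:, 0], py - tgt[:, 1])
    return model


def apply_calibration(model: CalibrationModel, gaze: GazeSamples) -> GazeSamples:
    """Map raw gaze through the polynomial; validity flags are preserved."""
    cx, cy = model.predict(gaze.x, gaze.y)
    return GazeSamples(t_ms=gaze.t_ms, x=cx, y=cy, valid=gaze.valid.copy(), unit="deg")


# ---------------------------------------------------------------------------
# session quality
# ---------------------------------------------------------------------------

def _gauss1d(v, amp, mu, sigma):
    return amp * np.exp(-((v - mu) ** 2) / (2.0 * sigma**2))


def _fit_marginal(centers, profile):
    """Gaussian (amplitude, mean, SD) fit of one marginal histogram profile.

    No additive offset: a histogram of fixation samples has no count floor,
    and within the narrow central window an offset term trades off against
    the SD, leaving the width unidentifiable.
    """
    amp0 = max(profile.max(), 1e-12)
    mu0 = centers[int(np.argmax(profile))]
    w = np.clip(profile, 0, None)
    sigma0 = np.sqrt(np.sum(w * (centers - mu0) ** 2) / max(w.sum(), 1e-12)) or (centers[-1] - centers[0]) / 4
    popt, _ = optimize.curve_fit(
        _gauss1d,
        centers,
        profile,
        p0=[amp0, mu0, max(sigma0, 0.05)],
        bounds=([0, centers[0], 1e-3], [np.inf, centers[-1], np.inf]),
        maxfev=10000,
    )
    return popt[1], abs(popt[2])


def session_accuracy_precision(
    gaze: GazeSamples,
    bin_deg: float = 0.05,
    extent_deg: float = 2.5,
    center=(0.0, 0.0),
    min_samples: int = 1000,
) -> SessionQuality:
    """Accuracy (offset) and precision (sigma) of calibrated fixation data.

    Samples in the central square of full side ``extent_deg`` are binned at
    ``bin_deg`` (left-closed bins); the x and y components are averaged into
    marginal profiles and each fitted with a 1D Gaussian (amplitude, mean,
    SD).  Fitted means are the per-axis offsets, fitted SDs the sigmas.
    """
    if gaze.unit != "deg":
        raise ValueError("session_accuracy_precision expects calibrated gaze (degrees)")
    half = extent_deg / 2.0
    x = gaze.x[gaze.valid] - center[0]
    y = gaze.y[gaze.valid] - center[1]
    inside = (x >= -half) & (x < half) & (y >= -half) & (y < half)
    if inside.sum() < min_samples:
        raise ValueError(f"only {inside.sum()} samples inside the central {extent_deg} degrees")
    edges = np.arange(-half, half + bin_deg / 2, bin_deg)
    hist, _, _ = np.histogram2d(x[inside], y[inside], bins=[edges, edges])
    centers = (edges[:-1] + edges[1:]) / 2.0
    flags = []
    try:
        off_x, sig_x = _fit_marginal(centers, hist.mean(axis=1))
        off_y, sig_y = _fit_marginal(centers, hist.mean(axis=0))
    except RuntimeError:
        return SessionQuality(np.nan, np.nan, np.nan, np.nan, flags=["fit_failed"])
    return SessionQuality(off_x + center[0], off_y + center[1], sig_x, sig_y, flags=flags)


def offset_sigma_correlation(sessions: pd.DataFrame) -> tuple[float, float]:
    """Correlation between session accuracy and precision across subjects.

    ``sessions`` needs columns ``subject``, ``absolute_offset`` and
    ``absolute_sigma``.  Both measures are z-transformed within subject
    (removing per-subject baselines), pooled, and Pearson-correlated.
    Subjects with fewer than 3 sessions or zero variance are excluded with a
    warning.
    """
    zs_off, zs_sig = [], []
    for subject, grp in sessions.groupby("subject"):
        off = grp["absolute_offset"].to_numpy(dtype=float)
        sig = grp["absolute_sigma"].to_numpy(dtype=float)
        if len(grp) < 3 or off.std(ddof=1) == 0 or sig.std(ddof=1) == 0:
            warnings.warn(f"subject {subject!r} excluded from correlation", stacklevel=2)
            continue
        zs_off.append((off - off.mean()) / off.std(ddof=1))
        zs_sig.append((sig - sig.mean()) / sig.std(ddof=1))
    if len(zs_off) < 2:
        raise ValueError("need at least 2 usable subjects")
    rho, p = stats.pearsonr(np.concatenate(zs_off), np.concatenate(zs_sig))
    return float(rho), float(p)
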