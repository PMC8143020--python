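"""Seeded generators for every input the analysis pipelines consume.

No recordings ship with this package; all tests and worked examples run on
synthetic data with known ground truth.  Every generator is a pure function
of its specification and seed, and returns (or embeds) the ground truth so
that recovery tests never re-derive it.

What the generators emulate, and what they do not, is documented in
docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eye_tracking import DEFAULT_TARGETS_PX, CalibrationTargets, GazeSamples, polynomial_basis
from .geometry import MonitorSpec
from .neural_preproc import EpochSet, RawRecording
from .psychometrics import SPATIAL_FREQUENCIES, LogisticParams, logistic4
from .stimuli import StimulusCatalog

__all__ = [
    "GroundTruthRF",
    "ObserverSpec",
    "GazeSessionSpec",
    "rf_profile_image",
    "simulate_rf_epochs",
    "simulate_raw_trace",
    "simulate_gaze_session",
    "simulate_observer",
]

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class GroundTruthRF:
    """A known 2D receptive field: polar center, FWHM extents, response gain.

    ``fwhm_e`` is the radial FWHM in degrees; ``fwhm_c`` the FWHM along the
    perpendicular axis, expressed as a chord length in degrees at the center
    eccentricity.  Responses are ``baseline + gain * normalized overlap``
    with additive Gaussian noise of SD ``noise_sd`` (so ``gain / noise_sd``
    is the peak-condition SNR).
    """

    eccentricity: float = 6.0
    polar_angle: float = 120.0
    fwhm_e: float = 2.0
    fwhm_c: float = 2.0
    gain: float = 5.0
    baseline: float = 10.0
    noise_sd: float = 1.0

    def __post_init__(self):
        if min(self.fwhm_e, self.fwhm_c, self.gain, self.noise_sd) <= 0:
            raise ValueError("widths, gain and noise_sd must be positive")

    @property
    def kappa(self) -> float:
        """Von Mises concentration whose FWHM arc subtends ``fwhm_c`` as a
        chord at the center eccentricity."""
        half_arc = math.asin(min(self.fwhm_c / (2.0 * self.eccentricity), 1.0))
        return math.log(2.0) / (1.0 - math.cos(half_arc))

    @property
    def sigma_e(self) -> float:
        return self.fwhm_e / FWHM_FACTOR


def rf_profile_image(rf: GroundTruthRF, catalog: StimulusCatalog) -> np.ndarray:
    """Ground-truth RF intensity over the catalog's pixel grid: product of
    a radial Gaussian and an angular von Mises, peak 1."""
    ecc, ang = catalog.pixel_polar()
    radial = np.exp(-((ecc - rf.eccentricity) ** 2) / (2.0 * rf.sigma_e**2))
    angular = np.exp(rf.kappa * (np.cos(np.radians(ang - rf.polar_angle)) - 1.0))
    return radial * angular


def simulate_rf_epochs(
    rf: GroundTruthRF,
    catalog: StimulusCatalog,
    n_reps: int = 20,
    rng_seed: int = 0,
    n_channels: int = 1,
) -> EpochSet:
    """Epoch-level MUA responses of a known RF to the full catalog.

    Every stimulus is presented ``n_reps`` times in shuffled order.  The
    response-window (0-100 ms) level of an epoch is ``baseline + gain *
    overlap`` where overlap is the pixel-mean of RF profile x stimulus mask,
    normalized to 1 at the best stimulus; the baseline window carries
    baseline only.  One Gaussian noise draw per window (SD ``noise_sd``) is
    added and the trace clipped at zero, matching how downstream analyses
    average within windows.  Epochs are shaped exactly like the
    preprocessing output (-100..+180 ms at 1 kHz).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rf.eccentricity > catalog.monitor.corner_eccentricity_deg:
        import warnings

        warnings.warn("RF center lies outside the mapped field", stacklevel=2)
    rng = np.random.default_rng(rng_seed)
    profile = rf_profile_image(rf, catalog)
    ids = catalog.ids
    overlap = np.array([(profile * catalog.mask(i)).mean() for i in ids])
    peak = overlap.max()
    overlap = overlap / peak if peak > 0 else overlap

    cond = np.repeat(np.arange(len(ids)), n_reps)
    rng.shuffle(cond)
    n_epochs = cond.size
    pre, post = 100, 180
    data = np.empty((n_epochs, n_channels, pre + post))
    onset_spacing = 300.0
    for ch in range(n_channels):
        level = rf.baseline + rf.gain * overlap[cond]
        noise_resp = rng.normal(0.0, rf.noise_sd, size=n_epochs)
        noise_base = rng.normal(0.0, rf.noise_sd, size=n_epochs)
        noise_tail = rng.normal(0.0, rf.noise_sd, size=n_epochs)
        data[:, ch, :pre] = (rf.baseline + noise_base)[:, None]
        data[:, ch, pre : pre + 100] = (level + noise_resp)[:, None]
        data[:, ch, pre + 100 :] = (rf.baseline + noise_tail)[:, None]
    np.clip(data, 0.0, None, out=data)
    return EpochSet(
        data=data,
        condition_ids=np.array([ids[c] for c in cond], dtype=object),
        onset_ms=pre + onset_spacing * np.arange(n_epochs, dtype=float),
        pre_ms=pre,
        post_ms=post,
    )


def simulate_rf_population(
    n_sites: int = 20,
    rng_seed: int = 0,
    ecc_range: tuple = (3.0, 15.0),
    gain: float = 5.0,
    baseline: float = 10.0,
    noise_sd: float = 1.0,
) -> list[GroundTruthRF]:
    """A population of ground-truth RFs emulating V1/V6 recording sites.

    Eccentricities are uniform over ``ecc_range`` with uniform polar angles;
    RF FWHM grows linearly with eccentricity (0.75 deg + 0.2 deg per degree
    of eccentricity, with 20% multiplicative jitter), the well-known
    cortical-magnification scaling.  Response gain, baseline and noise are
    common to all sites.
    """
    rng = np.random.default_rng(rng_seed)
    sites = []
    for _ in range(n_sites):
        ecc = rng.uniform(*ecc_range)
        width = (0.75 + 0.2 * ecc) * rng.uniform(0.8, 1.2)
        sites.append(
            GroundTruthRF(
                eccentricity=ecc,
                polar_angle=rng.uniform(0.0, 360.0),
                fwhm_e=width,
                fwhm_c=width * rng.uniform(0.9, 1.1),
                gain=gain,
                baseline=baseline,
                noise_sd=noise_sd,
            )
        )
    return sites


def _pink_noise(n, rng):
    """1/f-amplitude noise, unit SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return out / out.std()


def default_spike_waveform(fs: float) -> np.ndarray:
    """Biphasic extracellular spike template, ~1 ms, peak-normalized."""
    t = np.arange(int(round(1.5e-3 * fs))) / fs
    w = -np.exp(-((t - 3e-4) ** 2) / (2 * (8e-5) ** 2)) + 0.4 * np.exp(
        -((t - 6.5e-4) ** 2) / (2 * (1.6e-4) ** 2)
    )
    return w / np.abs(w).max()


def simulate_raw_trace(
    rate_hz,
    fs: float = 25000.0,
    duration_s: float = 1.0,
    waveform: np.ndarray | None = None,
    n_channels: int = 4,
    spike_uv: float = 80.0,
    noise_uv: float = 10.0,
    common_mode_uv: float = 0.0,
    rng_seed: int = 0,
) -> tuple[RawRecording, list[np.ndarray]]:
    """Raw voltage with Poisson spiking, pink noise and per-shank common mode.

    ``rate_hz`` is a scalar, an array sampled at 1 kHz, or a callable of
    time (s).  All channels belong to one shank and share the common-mode
    signal but have independent spike trains and noise.  Returns the
    recording and the ground-truth spike times (s) per channel.
    """
    if fs < 10000:
        raise ValueError("fs must be at least 10 kHz")
    rng = np.random.default_rng(rng_seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    if callable(rate_hz):
        rate = np.asarray(rate_hz(t), dtype=float)
    else:
        rate = np.asarray(rate_hz, dtype=float)
        if rate.ndim == 0:
            rate = np.full(n, float(rate))
        else:  # 1 kHz rate profile resampled by nearest neighbor
            rate = rate[np.minimum((t * 1000).astype(int), rate.size - 1)]
    wave = default_spike_waveform(fs) if waveform is None else np.asarray(waveform, dtype=float)
    common = common_mode_uv * _pink_noise(n, rng) if common_mode_uv > 0 else np.zeros(n)
    samples = np.empty((n_channels, n))
    spike_times = []
    for ch in range(n_channels):
        x = noise_uv * _pink_noise(n, rng) + common
        spikes = np.where(rng.random(n) < rate / fs)[0]
        train = np.zeros(n)
        train[spikes] = spike_uv
        x += np.convolve(train, wave)[:n]
        samples[ch] = x
        spike_times.append(spikes / fs)
    rec = RawRecording(samples=samples, fs=fs, shank_map=np.zeros(n_channels, dtype=int))
    return rec, spike_times


# ---------------------------------------------------------------------------
# gaze sessions
# ---------------------------------------------------------------------------

def _default_warp():
    """Mildly nonlinear degrees -> tracker-unit warp (full cubic basis).

    Rows are the 10 cubic basis coefficients (1, x, y, x2, xy, y2, x3, x2y,
    xy2, y3); two columns for the raw x and y outputs.
    """
    cx = np.array([120.0, 22.0, 0.8, 0.12, 0.05, -0.08, 0.010, 0.0, 0.006, 0.0])
    cy = np.array([-40.0, -0.6, 19.0, 0.06, -0.04, 0.10, 0.0, 0.005, 0.0, 0.009])
    return cx, cy


@dataclass(frozen=True)
class GazeSessionSpec:
    """Ground truth for a simulated calibration session.

    The warp maps true gaze (degrees) to raw tracker units through the full
    cubic basis; noise is white Gaussian per sample and drift a slow
    Ornstein-Uhlenbeck walk, both in raw units scaled to the warp's gain.
    """

    warp_coef_x: np.ndarray = None
    warp_coef_y: np.ndarray = None
    noise_sd_deg: float = 0.3
    drift_sd_deg: float = 0.0
    drift_tau_ms: float = 20000.0
    fixation_ms: tuple = (150.0, 300.0)
    target_hold_ms: tuple = (100.0, 200.0)
    fs: float = 1000.0

    def __post_init__(self):
        cx, cy = _default_warp()
        if self.warp_coef_x is None:
            object.__setattr__(self, "warp_coef_x", cx)
        if self.warp_coef_y is None:
            object.__setattr__(self, "warp_coef_y", cy)

    def warp(self, x_deg, y_deg):
        phi = polynomial_basis(x_deg, y_deg)
        return phi @ np.asarray(self.warp_coef_x), phi @ np.asarray(self.warp_coef_y)

    def check_invertible(self, extent_deg: float = 20.0, n: int = 41) -> bool:
        """Numerically verify the warp's Jacobian keeps one sign over the
        screen extent."""
        g = np.linspace(-extent_deg, extent_deg, n)
        xx, yy = np.meshgrid(g, g)
        eps = 1e-4
        fx1, fy1 = self.warp(xx + eps, yy)
        fx0, fy0 = self.warp(xx - eps, yy)
        gx1, gy1 = self.warp(xx, yy + eps)
        gx0, gy0 = self.warp(xx, yy - eps)
        jac = ((fx1 - fx0) * (gy1 - gy0) - (gx1 - gx0) * (fy1 - fy0)) / (2 * eps) ** 2
        return bool(np.all(jac > 0) or np.all(jac < 0))


def simulate_gaze_session(
    spec: GazeSessionSpec,
    n_trials: int = 200,
    rng_seed: int = 0,
    monitor: MonitorSpec | None = None,
    targets_px: np.ndarray = None,
) -> tuple[GazeSamples, CalibrationTargets, dict]:
    """Raw gaze from a simulated calibration session.

    Each trial fixates the center (150-300 ms) then saccades to one of the
    nine targets and holds it (100-200 ms); true gaze is distorted by the
    spec's warp, plus noise and drift.  Central fixations are over-
    represented by construction, as in the task.  Returns the raw samples,
    the target set, and a truth dict with the spec and the true gaze.
    """
    if not spec.check_invertible():
        raise ValueError("ground-truth warp is not invertible over the screen")
    rng = np.random.default_rng(rng_seed)
    targets = CalibrationTargets(
        positions_px=DEFAULT_TARGETS_PX.copy() if targets_px is None else targets_px,
        monitor=monitor or MonitorSpec(),
    )
    tdeg = targets.positions_deg
    dt = 1000.0 / spec.fs
    true_x, true_y = [], []
    for _ in range(n_trials):
        n_fix = int(rng.uniform(*spec.fixation_ms) / dt)
        k = int(rng.integers(len(tdeg)))
        n_hold = int(rng.uniform(*spec.target_hold_ms) / dt)
        true_x.extend([0.0] * n_fix + [tdeg[k, 0]] * n_hold)
        true_y.extend([0.0] * n_fix + [tdeg[k, 1]] * n_hold)
    true_x = np.array(true_x)
    true_y = np.array(true_y)
    n = true_x.size
    t_ms = np.arange(n) * dt

    # raw-unit scale of one degree, from the warp's linear gain
    gain_x = abs(spec.warp_coef_x[1]) or 1.0
    gain_y = abs(spec.warp_coef_y[2]) or 1.0
    raw_x, raw_y = spec.warp(true_x, true_y)
    raw_x = raw_x + rng.normal(0, spec.noise_sd_deg * gain_x, n)
    raw_y = raw_y + rng.normal(0, spec.noise_sd_deg * gain_y, n)
    if spec.drift_sd_deg > 0:
        theta = dt / spec.drift_tau_ms
        for raw, gain in ((raw_x, gain_x), (raw_y, gain_y)):
            d = np.empty(n)
            d[0] = 0.0
            eta = rng.normal(0, spec.drift_sd_deg * gain * math.sqrt(2 * theta), n)
            for i in range(1, n):
                d[i] = d[i - 1] * (1 - theta) + eta[i]
            raw += d
    gaze = GazeSamples(t_ms=t_ms, x=raw_x, y=raw_y, unit="raw")
    truth = {"spec": spec, "true_x": true_x, "true_y": true_y}
    return gaze, targets, truth


# ---------------------------------------------------------------------------
# behavioral observers
# ---------------------------------------------------------------------------

def _default_hit_params():
    return LogisticParams(gamma=12.5, lam=95.0, alpha=6.4, beta=5.0, mode="hit_rate")


def _default_rt_params():
    return LogisticParams(gamma=245.0, lam=132.0, alpha=5.2, beta=5.0, mode="rt")


@dataclass(frozen=True)
class ObserverSpec:
    """A synthetic observer: hit-rate and RT logistic curves plus RT noise.

    The default condition weights double the sampling probability of the
    lowest spatial frequency relative to each of the others.
    """

    hit_params: LogisticParams = field(default_factory=_default_hit_params)
    rt_params: LogisticParams = field(default_factory=_default_rt_params)
    rt_noise_sd: float = 20.0
    frequencies: tuple = SPATIAL_FREQUENCIES
    weights: tuple = None

    def __post_init__(self):
        if self.weights is None:
            w = np.ones(len(self.frequencies))
            w[int(np.argmin(self.frequencies))] = 2.0
            object.__setattr__(self, "weights", tuple(w / w.sum()))
        else:
            w = np.asarray(self.weights, dtype=float)
            if abs(w.sum() - 1.0) > 1e-9 or len(w) != len(self.frequencies):
                raise ValueError("weights must match frequencies and sum to 1")


def simulate_observer(
    spec: ObserverSpec,
    n_trials: int = 5000,
    rng_seed: int = 0,
    subject: str = "sim",
    session: int = 0,
) -> pd.DataFrame:
    """Trial table from a synthetic observer.

    Conditions are drawn with the spec's weights; the outcome is Bernoulli
    with probability ``logistic4(x, hit_params)/100``; hit RTs are
    ``logistic4(x, rt_params)`` plus Gaussian noise, clipped to the valid
    50-500 ms response window.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(rng_seed)
    freqs = np.asarray(spec.frequencies, dtype=float)
    cond = rng.choice(len(freqs), size=n_trials, p=np.asarray(spec.weights))
    x = freqs[cond]
    p_hit = logistic4(x, spec.hit_params) / 100.0
    hit = rng.random(n_trials) < p_hit
    rt = np.full(n_trials, np.nan)
    rt[hit] = np.clip(
        logistic4(x[hit], spec.rt_params) + rng.normal(0, spec.rt_noise_sd, int(hit.sum())),
        50.0,
        500.0,
    )
    return pd.DataFrame(
        {
            "subject": subject,
            "session": session,
            "spatial_frequency": x,
            "outcome": np.where(hit, "hit", "miss"),
            "rt_ms": rt,
        }
    )


def simulate_sessions(
    spec: ObserverSpec,
    n_sessions: int = 30,
    trials_per_session: int = 170,
    rng_seed: int = 0,
    subject: str = "sim",
) -> pd.DataFrame:
    """Multi-session trial table (sessions concatenated, distinct seeds)."""
    frames = [
        simulate_observer(
            spec,
            n_trials=trials_per_session,
            rng_seed=np.random.SeedSequence([rng_seed, s]).generate_state(1)[0] % (2**31),
            subject=subject,
            session=s,
        )
        for s in range(n_sessions)
    ]
    return pd.concat(frames, ignore_index=True)
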