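"""Annulus-and-wedge stimulus catalog, rasterization, and trial sequences.

The stimulus set tiles the monitor in polar coordinates: wedges sample polar
angle (9 deg subtense in 4.5 deg steps by default, so every angle is covered
by exactly two wedges) and contiguous annuli sample eccentricity, each
annulus as wide as a wedge is at the annulus midpoint.  Widths therefore grow
with eccentricity, mirroring cortical magnification.

Masks are binary intensity images (stimulus pixels 1, background 0): for
black-on-gray stimuli the mask is the informative quantity for reverse
correlation, and the final receptive-field map is rescaled to [0, 1] anyway.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import MonitorSpec, frames_to_ms

__all__ = [
    "WedgeSpec",
    "AnnulusSpec",
    "StimulusCatalog",
    "build_wedge_set",
    "build_annulus_set",
    "build_catalog",
    "rasterize_stimulus",
    "generate_trial_sequence",
]


@dataclass(frozen=True)
class WedgeSpec:
    """Pie-slice stimulus: an angular sector spanning a radial interval."""

    id: str
    polar_center: float  # degrees in [0, 360)
    polar_subtense: float = 9.0
    inner_radius: float = 0.0
    outer_radius: float = 0.0

    def __post_init__(self):
        if self.polar_subtense <= 0:
            raise ValueError("polar_subtense must be positive")
        if self.outer_radius <= self.inner_radius:
            raise ValueError("outer_radius must exceed inner_radius")
        object.__setattr__(self, "polar_center", self.polar_center % 360.0)


@dataclass(frozen=True)
class AnnulusSpec:
    """Ring stimulus spanning a radial interval at all polar angles."""

    id: str
    inner_radius: float
    outer_radius: float

    def __post_init__(self):
        if self.inner_radius < 0:
            raise ValueError("inner_radius must be non-negative")
        if self.outer_radius <= self.inner_radius:
            raise ValueError("outer_radius must exceed inner_radius")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.inner_radius + self.outer_radius)

    @property
    def width(self) -> float:
        return self.outer_radius - self.inner_radius


def build_wedge_set(
    step_deg: float = 4.5,
    subtense_deg: float = 9.0,
    monitor: MonitorSpec | None = None,
    inner_radius: float = 0.0,
    outer_radius: float | None = None,
) -> list[WedgeSpec]:
    """Wedges centered at every multiple of ``step_deg`` around the circle.

    With the defaults (9 deg subtense, 4.5 deg step) each polar angle is
    covered by exactly two wedges.  Radially the wedges reach the monitor
    corner so that, together with the annuli, they cover the whole screen.
    """
    if step_deg <= 0 or subtense_deg <= 0:
        raise ValueError("step_deg and subtense_deg must be positive")
    n = 360.0 / step_deg
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"360 must be divisible by step_deg, got step_deg={step_deg}")
    n = int(round(n))
    if outer_radius is None:
        outer_radius = (monitor or MonitorSpec()).corner_eccentricity_deg
    return [
        WedgeSpec(
            id=f"w{k:03d}",
            polar_center=k * step_deg,
            polar_subtense=subtense_deg,
            inner_radius=inner_radius,
            outer_radius=outer_radius,
        )
        for k in range(n)
    ]


def build_annulus_set(
    monitor: MonitorSpec | None = None,
    inner_start_deg: float = 0.5,
    step_deg: float = 4.5,
) -> list[AnnulusSpec]:
    """Contiguous annuli whose widths match the wedge width at their midpoint.

    A wedge of subtense ``2*step_deg`` has chord width ``2*m*sin(step)`` at
    radius m.  Requiring the annulus width w at inner radius r to equal the
    wedge width at the midpoint m = r + w/2 gives the recursion
    ``w = 2*r*sin(step) / (1 - sin(step))`` and ``r_next = r + w``; widths
    grow geometrically with eccentricity.  Annuli are appended until they
    cover the monitor corner.
    """
    if inner_start_deg < 0:
        raise ValueError("inner_start_deg must be non-negative")
    if step_deg <= 0 or step_deg >= 90:
        raise ValueError("step_deg must lie in (0, 90)")
    monitor = monitor or MonitorSpec()
    s = math.sin(math.radians(step_deg))
    corner = monitor.corner_eccentricity_deg
    annuli: list[AnnulusSpec] = []
    r = inner_start_deg
    if r == 0.0:
        # innermost annulus is a disk; give it the width a wedge would have
        # at its own midpoint: w = 2*(w/2)*sin(step) has only w=0, so seed
        # the recursion from half a step of visual angle instead.
        r = 0.0
        w = 2.0 * (step_deg / 2.0) * s / (1.0 - s)
        annuli.append(AnnulusSpec(id="a000", inner_radius=0.0, outer_radius=w))
        r = w
    i = len(annuli)
    while r < corner:
        w = 2.0 * r * s / (1.0 - s)
        annuli.append(AnnulusSpec(id=f"a{i:03d}", inner_radius=r, outer_radius=r + w))
        r += w
        i += 1
    return annuli


@dataclass
class StimulusCatalog:
    """The full annulus + wedge set over one monitor.

    Rasterized masks are computed on demand and cached per stimulus id; the
    cache is keyed on this catalog's monitor raster.
    """

    wedges: list[WedgeSpec]
    annuli: list[AnnulusSpec]
    monitor: MonitorSpec = field(default_factory=MonitorSpec)
    stimulus_value: float = 1.0
    background_value: float = 0.0

    def __post_init__(self):
        ids = [s.id for s in self.wedges] + [s.id for s in self.annuli]
        if len(set(ids)) != len(ids):
            raise ValueError("stimulus ids must be unique")
        self._by_id = {s.id: s for s in self.wedges + self.annuli}
        self._mask_cache: dict[str, np.ndarray] = {}
        self._polar_grid: tuple[np.ndarray, np.ndarray] | None = None

    # -- lookups ---------------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.annuli] + [s.id for s in self.wedges]

    @property
    def annulus_ids(self) -> list[str]:
        return [s.id for s in self.annuli]

    @property
    def wedge_ids(self) -> list[str]:
        return [s.id for s in self.wedges]

    def spec(self, stimulus_id: str):
        return self._by_id[stimulus_id]

    def is_wedge(self, stimulus_id: str) -> bool:
        return isinstance(self._by_id[stimulus_id], WedgeSpec)

    def annulus_midpoints(self) -> np.ndarray:
        return np.array([a.midpoint for a in self.annuli])

    def wedge_centers(self) -> np.ndarray:
        return np.array([w.polar_center for w in self.wedges])

    # -- rasterization ---------------------------------------------------
    def pixel_polar(self) -> tuple[np.ndarray, np.ndarray]:
        """(eccentricity, polar angle) of every pixel center, degrees.

        Pixel rows index downward in the raster but y points upward in
        degree space; the flip is owned here.
        """
        if self._polar_grid is None:
            m = self.monitor
            cols = np.arange(m.width_px)
            rows = np.arange(m.height_px)
            x = (cols - (m.width_px - 1) / 2.0) / m.px_per_deg
            y = ((m.height_px - 1) / 2.0 - rows) / m.px_per_deg
            xx, yy = np.meshgrid(x, y)
            ecc = np.hypot(xx, yy)
            ang = np.degrees(np.arctan2(yy, xx)) % 360.0
            self._polar_grid = (ecc, ang)
        return self._polar_grid

    def mask(self, stimulus_id: str) -> np.ndarray:
        if stimulus_id not in self._mask_cache:
            self._mask_cache[stimulus_id] = rasterize_stimulus(self._by_id[stimulus_id], self)
        return self._mask_cache[stimulus_id]

    def mask_matrix(self, ids: list[str]) -> np.ndarray:
        """Stack of flattened masks, shape (n_stimuli, height*width)."""
        return np.stack([self.mask(i).ravel() for i in ids])

    # -- serialization ---------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "monitor": {
                "width_px": self.monitor.width_px,
                "height_px": self.monitor.height_px,
                "px_per_deg": self.monitor.px_per_deg,
                "distance_mm": self.monitor.distance_mm,
                "refresh_hz": self.monitor.refresh_hz,
            },
            "stimulus_value": self.stimulus_value,
            "background_value": self.background_value,
            "wedges": [
                {
                    "id": w.id,
                    "polar_center": w.polar_center,
                    "polar_subtense": w.polar_subtense,
                    "inner_radius": w.inner_radius,
                    "outer_radius": w.outer_radius,
                }
                for w in self.wedges
            ],
            "annuli": [
                {"id": a.id, "inner_radius": a.inner_radius, "outer_radius": a.outer_radius}
                for a in self.annuli
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StimulusCatalog":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            wedges=[WedgeSpec(**w) for w in payload["wedges"]],
            annuli=[AnnulusSpec(**a) for a in payload["annuli"]],
            monitor=MonitorSpec(**payload["monitor"]),
            stimulus_value=payload["stimulus_value"],
            background_value=payload["background_value"],
        )


def build_catalog(
    monitor: MonitorSpec | None = None,
    step_deg: float = 4.5,
    subtense_deg: float = 9.0,
    inner_start_deg: float = 0.5,
) -> StimulusCatalog:
    """Convenience constructor for the default annulus-and-wedge catalog."""
    monitor = monitor or MonitorSpec()
    annuli = build_annulus_set(monitor, inner_start_deg=inner_start_deg, step_deg=step_deg)
    wedges = build_wedge_set(
        step_deg=step_deg,
        subtense_deg=subtense_deg,
        monitor=monitor,
        inner_radius=0.0,
        outer_radius=annuli[-1].outer_radius,
    )
    return StimulusCatalog(wedges=wedges, annuli=annuli, monitor=monitor)


def rasterize_stimulus(spec: WedgeSpec | AnnulusSpec, catalog: StimulusCatalog) -> np.ndarray:
    """Binary intensity image of one stimulus over the catalog's monitor.

    Radial intervals are half-open [inner, outer); angular intervals are
    half-open [center - subtense/2, center + subtense/2), taken modulo 360,
    which makes per-pixel coverage counts exact.  The fixation point (zero
    eccentricity) is never covered.
    """
    ecc, ang = catalog.pixel_polar()
    inside = (ecc >= spec.inner_radius) & (ecc < spec.outer_radius)
    if isinstance(spec, WedgeSpec):
        half = spec.polar_subtense / 2.0
        delta = (ang - (spec.polar_center - half)) % 360.0
        inside &= delta < spec.polar_subtense
    inside &= ecc > 0
    out = np.full(ecc.shape, catalog.background_value, dtype=np.float32)
    out[inside] = catalog.stimulus_value
    return out


def generate_trial_sequence(
    catalog: StimulusCatalog,
    n_trials: int,
    stimuli_per_trial: tuple[int, int] = (9, 10),
    rng_seed: int | np.random.Generator = 0,
    presentation_frames: int = 8,
    inter_trial_ms: float = 500.0,
) -> pd.DataFrame:
    """Random presentation log: per trial, 9-10 stimuli drawn uniformly
    without within-trial repetition, flashed back-to-back for eight frames
    each.

    Returns a DataFrame with columns epoch_id, stimulus_id, onset_ms,
    trial_id, completed.  The sequence always runs to the end of the trial;
    completion flags are bookkeeping for downstream epoch validity, which is
    decided by eye position, not by this log.
    """
    ids = catalog.ids
    if not ids:
        raise ValueError("catalog is empty")
    lo, hi = stimuli_per_trial
    if hi > len(ids):
        raise ValueError(f"stimuli_per_trial={stimuli_per_trial} exceeds catalog size {len(ids)}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    spacing = frames_to_ms(presentation_frames, catalog.monitor.refresh_hz)
    records = []
    t = 0.0
    epoch_id = 0
    for trial in range(n_trials):
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(ids), size=k, replace=False)
        for j, idx in enumerate(chosen):
            records.append(
                {
                    "epoch_id": epoch_id,
                    "stimulus_id": ids[idx],
                    "onset_ms": t + j * spacing,
                    "trial_id": trial,
                    "completed": True,
                }
            )
            epoch_id += 1
        t += k * spacing + inter_trial_ms
    return pd.DataFrame.from_records(records)
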