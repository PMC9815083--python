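"""Synthetic microfluidic data with the statistical structure of the real
experiments.

Three generators mirror the three cultivation formats:

* :func:`simulate_mother_machine_tracks` — division-event lineages under
  steady glucose, with per-cell substrate affinity drawn from a
  zero-truncated normal and multiplicative lognormal timing noise;
* :func:`render_phase_image` — optical-path-difference maps of
  spherocylindrical cells (or spherical calibration beads) on a pixel grid,
  with additive Gaussian background noise;
* :func:`simulate_picoliter_batch` — a sealed-chamber batch culture run to
  substrate exhaustion, observed as a projected-colony-area time series.

Defaults reproduce the study conditions: E. coli-like rods of density
0.13-0.28 pg/um^3 imaged at 0.045 um/px, Monod kinetics with
mu_max = 0.66 1/h and mean KS = 486 ug/L with ~48% cell-to-cell spread,
~40% multiplicative timing noise, 5-min mother-machine frames, 20-min batch
frames, and a 606 pL reactor.

The timing noise is lognormal with unit median (log-mean zero), so the
geometric mean of observed doubling times is an unbiased estimate of the
noise-free doubling time — the property the geometric-mean estimator
downstream relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from picophys.qpi import PhaseImage

__all__ = [
    "CellSpec", "GeneratorConfig", "simulate_mother_machine_tracks",
    "render_phase_image", "simulate_picoliter_batch",
]

LN2 = math.log(2.0)

#: Study-condition defaults for the mother-machine generator.
DEFAULT_MU_MAX = 0.66            # 1/h
DEFAULT_KS_MEAN = 4.86e-4        # g/L (486 ug/L)
DEFAULT_KS_CV = 234.0 / 486.0    # spread of the observed KS distribution
DEFAULT_NOISE_CV = 0.40          # ~±40% division-timing heterogeneity
DEFAULT_GLUCOSE_LEVELS = tuple(float(s) for s in np.logspace(-5, 1, 8))


@dataclass(frozen=True)
class CellSpec:
    """Geometry and optical properties of one rendered object.

    A cell is a spherocylinder of total ``length`` and diameter ``width``
    lying in the focal plane; ``length == width`` degenerates to a sphere
    (a calibration bead).  ``density`` is dry-mass density in pg/um^3 and
    ``refraction_increment`` in mL/g, so their product is the refractive
    index excess over the medium.
    """

    length: float                       # um
    width: float                        # um
    density: float                      # pg/um^3
    refraction_increment: float = 0.18  # mL/g
    position: tuple[float, float] = (0.0, 0.0)  # (x, y) um
    orientation: float = 0.0            # radians, in-plane

    def __post_init__(self) -> None:
        if not self.length >= self.width > 0:
            raise ValueError("need length >= width > 0")
        if self.density <= 0 or self.refraction_increment <= 0:
            raise ValueError("density and refraction_increment must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the mother-machine track generator."""

    mu_max: float = DEFAULT_MU_MAX
    ks_mean: float = DEFAULT_KS_MEAN
    ks_cv: float = DEFAULT_KS_CV
    noise_cv: float = DEFAULT_NOISE_CV
    glucose_levels: tuple[float, ...] = DEFAULT_GLUCOSE_LEVELS
    events_per_level: int = 60
    frame_interval: float = 5.0          # min
    consecutive_division_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_max <= 0 or self.ks_mean <= 0:
            raise ValueError("rates and concentrations must be positive")
        if self.ks_cv < 0 or self.noise_cv < 0:
            raise ValueError("ks_cv and noise_cv must be nonnegative")
        if self.events_per_level < 1:
            raise ValueError("events_per_level must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if any(s <= 0 for s in self.glucose_levels):
            raise ValueError("glucose levels must be positive; got "
                             f"{min(self.glucose_levels)}")


def _sample_ks(rng: np.random.Generator, mean: float, cv: float, size: int
               ) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    sd = cv * mean
    a = -mean / sd  # truncate at zero
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                         random_state=rng)


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int
                     ) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    # unit median: symmetric in log, so geometric means stay unbiased
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def simulate_mother_machine_tracks(cfg: GeneratorConfig,
                                   quantize: bool = True) -> pd.DataFrame:
    """Division-event tables for one mother line per glucose level.

    Each offspring cell draws its own substrate affinity KS from the
    zero-truncated normal, grows at the Monod rate for the level's glucose
    concentration, and divides after ``ln2 / mu`` scaled by multiplicative
    lognormal timing noise.  Occasional consecutive-division artifacts
    (doubling time of one frame) are injected at the configured rate, and
    timestamps are quantized to the imaging frame interval when
    ``quantize`` is set.

    Returns a long-format table with columns ``lineage_id``, ``cell_id``,
    ``parent_id``, ``generation``, ``division_time_min``,
    ``glucose_g_per_L``; fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    cell_id = 0
    for lineage_id, S in enumerate(cfg.glucose_levels):
        # one extra event: the first inter-division interval is discarded
        # downstream, leaving events_per_level usable doubling times
        n = cfg.events_per_level + 2
        ks = _sample_ks(rng, cfg.ks_mean, cfg.ks_cv, n)
        mu = cfg.mu_max * S / (ks + S)                       # 1/h
        td_min = LN2 / mu * 60.0 * _lognormal_noise(rng, cfg.noise_cv, n)
        artifacts = rng.random(n) < cfg.consecutive_division_rate
        td_min[artifacts] = cfg.frame_interval
        times = np.cumsum(td_min)
        if quantize:
            times = np.round(times / cfg.frame_interval) * cfg.frame_interval
            # frame-limited detection cannot order two divisions within one
            # frame; enforce strictly increasing stamps
            for i in range(1, n):
                if times[i] <= times[i - 1]:
                    times[i] = times[i - 1] + cfg.frame_interval
        for gen, t in enumerate(times):
            rows.append((lineage_id, cell_id, cell_id - 1 if gen else -1,
                         gen, float(t), S))
            cell_id += 1
    return pd.DataFrame(rows, columns=[
        "lineage_id", "cell_id", "parent_id", "generation",
        "division_time_min", "glucose_g_per_L"])


def _projected_thickness(spec: CellSpec, X: np.ndarray, Y: np.ndarray
                         ) -> np.ndarray:
    """Projected chord length of a spherocylinder through each (x, y), um.

    The axis is the in-plane segment of length ``length - width`` centred
    at ``position`` with the given orientation; the local thickness is that
    of a sphere of radius width/2 centred at the nearest axis point.
    """
    r = spec.width / 2.0
    half = max(spec.length - spec.width, 0.0) / 2.0
    cx, cy = spec.position
    c, s = math.cos(spec.orientation), math.sin(spec.orientation)
    # coordinates along/perpendicular to the axis
    u = (X - cx) * c + (Y - cy) * s
    v = -(X - cx) * s + (Y - cy) * c
    du = np.clip(np.abs(u) - half, 0.0, None)   # distance beyond the rod body
    d2 = du ** 2 + v ** 2
    return 2.0 * np.sqrt(np.clip(r * r - d2, 0.0, None))


def render_phase_image(cells_or_beads: list[CellSpec], pixel_size: float = 0.045,
                       image_shape: tuple[int, int] = (256, 256),
                       noise_sd: float = 0.0, supersample: int = 2,
                       rng: np.random.Generator | None = None) -> PhaseImage:
    """Render an optical-path-difference map of cells or beads.

    Each object contributes ``(density * refraction_increment) * thickness``
    to the OPD, with the projected thickness of its 3-D shape evaluated on a
    ``supersample``-fold finer grid and box-averaged down to the pixel grid.
    Additive Gaussian background noise of SD ``noise_sd`` (um) is applied
    last.

    Raises
    ------
    ValueError
        If any object's footprint extends beyond the image bounds (the
        offending object index is named).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    ny, nx = image_shape
    width_um, height_um = nx * pixel_size, ny * pixel_size
    for i, spec in enumerate(cells_or_beads):
        half_foot = spec.length / 2.0
        x0, y0 = spec.position
        if (x0 - half_foot < 0 or x0 + half_foot > width_um
                or y0 - half_foot < 0 or y0 + half_foot > height_um):
            raise ValueError(f"object {i} extends beyond image bounds")
    h = pixel_size / supersample
    xs = (np.arange(nx * supersample) + 0.5) * h
    ys = (np.arange(ny * supersample) + 0.5) * h
    X, Y = np.meshgrid(xs, ys)
    opd_fine = np.zeros_like(X)
    for spec in cells_or_beads:
        opd_fine += (spec.density * spec.refraction_increment
                     * _projected_thickness(spec, X, Y))
    opd = opd_fine.reshape(ny, supersample, nx, supersample).mean(axis=(1, 3))
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        opd = opd + rng.normal(0.0, noise_sd, size=opd.shape)
    return PhaseImage(opd, pixel_size)


def simulate_picoliter_batch(s0_mass: float, reactor_volume: float = 606.0,
                             chamber_height: float = 1.0,
                             yield_true: float = 0.45,
                             mu_max: float = DEFAULT_MU_MAX,
                             ks: float = DEFAULT_KS_MEAN,
                             x0_mass: float = 6.0,
                             density: float = 0.2,
                             dt: float = 20.0,
                             t_max: float = 7200.0,
                             area_noise_cv: float = 0.0,
                             seed: int = 0) -> pd.DataFrame:
    """Sealed-chamber batch growth observed as projected colony area.

    Biomass (pg) grows at the Monod rate on the instantaneous concentration
    ``S = s_mass / reactor_volume`` (pg/pL == g/L); substrate is consumed
    at ``mu * X / yield_true``.  The observable is the projected monolayer
    area ``X / (density * chamber_height)`` sampled every ``dt`` minutes,
    optionally with multiplicative lognormal observation noise.  The series
    ends when the substrate falls below 1e-6 of ``s0_mass`` or ``t_max`` is
    reached.

    Returns a DataFrame with columns ``time_min``, ``area_um2``,
    ``substrate_pg``.
    """
    if yield_true <= 0:
        raise ValueError("yield_true must be positive")
    if s0_mass < 0 or x0_mass < 0:
        raise ValueError("masses must be nonnegative")
    rng = np.random.default_rng(seed)
    # integrate on a fine internal grid; observe every dt
    n_sub = 50
    h = dt / 60.0 / n_sub  # h per internal step

    def rates(x: float, s: float) -> tuple[float, float]:
        conc = s / reactor_volume
        mu = mu_max * conc / (ks + conc)
        return mu * x, -mu * x / yield_true

    times, areas, substrates = [], [], []
    t, x, s = 0.0, x0_mass, s0_mass

    def record() -> None:
        area = x / (density * chamber_height)
        if area_noise_cv > 0:
            sigma = math.sqrt(math.log1p(area_noise_cv ** 2))
            area *= rng.lognormal(0.0, sigma)
        times.append(t); areas.append(area); substrates.append(s)

    record()
    while s > 1e-6 * s0_mass and t < t_max:
        for _ in range(n_sub):
            k1 = rates(x, s)
            k2 = rates(x + h / 2 * k1[0], s + h / 2 * k1[1])
            k3 = rates(x + h / 2 * k2[0], s + h / 2 * k2[1])
            k4 = rates(x + h * k3[0], s + h * k3[1])
            dx = h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            ds = h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            if s + ds <= 0:
                frac = s / -ds if ds < 0 else 0.0
                x += dx * frac
                s = 0.0
                break
            x += dx
            s += ds
        t += dt
        record()
    return pd.DataFrame({"time_min": times, "area_um2": areas,
                         "substrate_pg": substrates})
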