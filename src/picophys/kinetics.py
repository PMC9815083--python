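"""Single-cell Monod growth kinetics from division-event records.

Mother-machine cultivations hold single cells at a steady extracellular
glucose concentration; the division timestamps of one mother line (and its
offspring) give per-generation doubling times.  This module turns those
records into specific growth rates, applies the growth/no-growth
classification rules, fits the Monod model

    mu(S) = mu_max * S / (KS + S)

on a logarithmic concentration axis (where it is sigmoidal), and inverts it
per cell to characterise the distribution of the whole-cell substrate
affinity KS across the population.

Conventions: doubling times in minutes inside track tables, growth rates in
1/h, concentrations in g/L internally (reported in ug/L where customary).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DivisionTrack", "GrowthPoint", "MonodParams", "KsDistribution",
    "doubling_times", "classify_growth", "geometric_mean_mu", "monod_mu",
    "MonodModel", "MonodResults", "fit_monod", "ks_distribution",
    "growth_points_from_tracks", "tracks_from_frame",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class DivisionTrack:
    """Division events of one mother line at one glucose concentration.

    ``times_min`` are the division timestamps in minutes (strictly
    increasing); ``generations`` the generation index at each event.
    """

    lineage_id: int
    times_min: tuple[float, ...]
    generations: tuple[int, ...]
    glucose_g_L: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("division timestamps must be strictly increasing")
        if any(g < 0 for g in self.generations):
            raise ValueError("generations must be nonnegative")
        if len(self.generations) != t.size:
            raise ValueError("generations must align with times_min")

    @property
    def n_events(self) -> int:
        return len(self.times_min)

    @property
    def n_generations(self) -> int:
        return max(self.generations) if self.generations else 0


@dataclass(frozen=True)
class GrowthPoint:
    """Growth-rate summary for one glucose level."""

    glucose_g_L: float
    mu_gm: float          # geometric-mean growth rate, 1/h
    mu_sd: float          # weighted SD of per-event rates, 1/h
    n_events: int
    status: str           # 'valid' | 'pooled' | 'no_growth'

    def __post_init__(self) -> None:
        if self.mu_gm < 0 or self.n_events < 0:
            raise ValueError("mu_gm and n_events must be nonnegative")
        if self.status not in ("valid", "pooled", "no_growth"):
            raise ValueError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class MonodParams:
    """Monod parameters: mu = mu_max * S / (ks + S)."""

    mu_max: float         # 1/h
    ks: float             # g/L
    variant: str = "mean"  # 'mean' | 'upper_boundary' | 'lower_boundary'
    fit_r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.mu_max <= 0 or self.ks <= 0:
            raise ValueError("mu_max and ks must be positive")

    @property
    def ks_ug_L(self) -> float:
        return self.ks * 1e6


@dataclass(frozen=True)
class KsDistribution:
    """Empirical distribution of per-cell substrate affinities."""

    mean: float            # g/L
    sd: float              # g/L
    values: np.ndarray     # per-cell ks, g/L
    bin_edges: np.ndarray
    counts: np.ndarray
    n_skipped: int = 0     # cells with mu >= mu_max, not invertible


def monod_mu(S: float | np.ndarray, params: MonodParams) -> float | np.ndarray:
    """Monod specific growth rate at substrate concentration ``S`` (g/L)."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("S must be nonnegative")
    out = params.mu_max * S / (params.ks + S)
    return float(out) if out.ndim == 0 else out


def doubling_times(track: DivisionTrack, frame_interval_min: float = 5.0
                   ) -> list[tuple[float, int]]:
    """Doubling times (min) with outlier weights from one division track.

    The first inter-division interval is excluded (the mother's history
    before the first observed division is unknown).  Intervals no longer
    than one imaging frame are physiologically impossible "consecutive
    division" artifacts and receive weight 0; all others weight 1.
    """
    if track.n_events < 2:
        return []
    tds = np.diff(np.asarray(track.times_min, dtype=float))[1:]
    return [(float(td), 0 if td <= frame_interval_min else 1) for td in tds]


def classify_growth(tracks: list[DivisionTrack]) -> str:
    """Growth classification for one glucose level.

    * ``valid``  — a single lineage alone provides >= 50 division events;
    * ``pooled`` — lineages summed give >= 4 generations but < 50 events;
    * ``no_growth`` — fewer than 4 generations in total.
    """
    if any(t.n_events >= 50 for t in tracks):
        return "valid"
    if sum(t.n_generations for t in tracks) >= 4:
        return "pooled"
    return "no_growth"


def geometric_mean_mu(tds: list[tuple[float, int]]) -> tuple[float, float]:
    """Geometric-mean growth rate and weighted SD from weighted doubling times.

    The geometric mean of the weight-1 doubling times gives
    ``mu_gm = ln2 / td_gm`` (robust to outliers); the heterogeneity measure
    is the weighted standard deviation of the per-event rates
    ``mu_i = ln2 / td_i`` with frequency weights and a ``sum(w) - 1``
    denominator.  Both rates are returned in 1/h for doubling times in
    minutes.

    Raises
    ------
    ValueError
        If no event has nonzero weight.
    """
    if not tds:
        raise ValueError("no admissible events")
    td = np.array([t for t, _ in tds], dtype=float)
    w = np.array([wt for _, wt in tds], dtype=float)
    n1 = w.sum()
    if n1 == 0:
        raise ValueError("no admissible events")
    td_gm = float(np.exp(np.sum(w * np.log(td)) / n1))
    mu_gm = LN2 / td_gm * 60.0
    mu_i = LN2 / td * 60.0
    mu_bar = float(np.sum(w * mu_i) / n1)
    if n1 > 1:
        mu_sd = float(np.sqrt(np.sum(w * (mu_i - mu_bar) ** 2) / (n1 - 1)))
    else:
        mu_sd = 0.0
    return mu_gm, mu_sd


def growth_points_from_tracks(tracks: pd.DataFrame, frame_interval_min: float = 5.0
                              ) -> list[GrowthPoint]:
    """Summarise a long-format track table into one GrowthPoint per glucose level.

    ``tracks`` uses the canonical schema (columns ``lineage_id``, ``cell_id``,
    ``parent_id``, ``generation``, ``division_time_min``, ``glucose_g_per_L``).
    """
    points = []
    for glucose, sub in tracks.groupby("glucose_g_per_L"):
        level_tracks = [
            DivisionTrack(
                lineage_id=int(lid),
                times_min=tuple(lin.sort_values("division_time_min")["division_time_min"]),
                generations=tuple(lin.sort_values("division_time_min")["generation"].astype(int)),
                glucose_g_L=float(glucose),
            )
            for lid, lin in sub.groupby("lineage_id")
        ]
        status = classify_growth(level_tracks)
        tds: list[tuple[float, int]] = []
        for tr in level_tracks:
            tds.extend(doubling_times(tr, frame_interval_min))
        if status == "no_growth" or not any(w for _, w in tds):
            points.append(GrowthPoint(float(glucose), 0.0, 0.0, len(tds), "no_growth"))
            continue
        mu_gm, mu_sd = geometric_mean_mu(tds)
        points.append(GrowthPoint(float(glucose), mu_gm, mu_sd, len(tds), status))
    return points


def tracks_from_frame(tracks: pd.DataFrame) -> list[DivisionTrack]:
    """All DivisionTracks contained in a long-format track table."""
    out = []
    for (glucose, lid), lin in tracks.groupby(["glucose_g_per_L", "lineage_id"]):
        lin = lin.sort_values("division_time_min")
        out.append(DivisionTrack(int(lid), tuple(lin["division_time_min"]),
                                 tuple(lin["generation"].astype(int)), float(glucose)))
    return out


def _sigmoid_log10(x: np.ndarray, mu_max: float, ks: float) -> np.ndarray:
    # Monod on a log10 concentration axis, where it is sigmoidal
    s = 10.0 ** x
    return mu_max * s / (ks + s)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


class MonodModel:
    """Monod growth model fitted to per-concentration growth-rate summaries.

    The model describes the saturating dependence of the specific growth
    rate on substrate concentration; on a log10 concentration axis the curve
    is sigmoidal, and the half-saturation constant KS is the abscissa of the
    half-maximum.  ``fit()`` performs nonlinear least squares of this
    sigmoid and returns a :class:`MonodResults` carrying three parameter
    sets: the fit to the mean rates, plus upper and lower boundary fits to
    ``mu +/- sd`` capturing the cell-to-cell heterogeneity band.

    Parameters
    ----------
    points
        Growth summaries (one per glucose level); ``no_growth`` points are
        retained with mu = 0 and anchor the low-concentration flank.
    """

    def __init__(self, points: list[GrowthPoint]):
        usable = [p for p in points if p.glucose_g_L > 0]
        if len(usable) < 4:
            raise ValueError("need at least 4 growth points at positive glucose")
        self.points = sorted(usable, key=lambda p: p.glucose_g_L)

    @classmethod
    def from_dataframe(cls, tracks: pd.DataFrame, frame_interval_min: float = 5.0
                       ) -> "MonodModel":
        """Build the model directly from a long-format division-track table."""
        return cls(growth_points_from_tracks(tracks, frame_interval_min))

    def _fit_one(self, y: np.ndarray, variant: str) -> MonodParams:
        x = np.log10([p.glucose_g_L for p in self.points])
        mu0 = float(y.max())
        if mu0 <= 0:
            raise ValueError("all growth rates are zero: no sigmoid to fit")
        # initial ks: concentration nearest the half-maximum rate
        ks0 = float(10.0 ** x[np.argmin(np.abs(y - mu0 / 2))])
        try:
            popt, _ = curve_fit(_sigmoid_log10, x, y, p0=[mu0, ks0],
                                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                                maxfev=20000)
        except RuntimeError as err:
            raise RuntimeError(
                f"Monod fit ({variant}) did not converge: {err}; "
                f"x range {x.min():.2f}..{x.max():.2f}, mu range 0..{mu0:.3f}"
            ) from err
        mu_max, ks = popt
        if 10.0 ** x.min() > 10 * ks:
            warnings.warn("ks poorly identified: all concentrations saturating",
                          stacklevel=3)
        r2 = _r_squared(y, _sigmoid_log10(x, *popt))
        return MonodParams(float(mu_max), float(ks), variant, r2)

    def fit(self) -> "MonodResults":
        """Fit mean, upper-boundary and lower-boundary Monod curves."""
        mu = np.array([p.mu_gm for p in self.points])
        sd = np.array([p.mu_sd for p in self.points])
        mean = self._fit_one(mu, "mean")
        upper = self._fit_one(mu + sd, "upper_boundary")
        lower = self._fit_one(np.clip(mu - sd, 0.0, None), "lower_boundary")
        return MonodResults(self, mean, upper, lower)


class MonodResults:
    """Fitted Monod parameters with heterogeneity boundaries.

    Note the field convention: the *upper* boundary (fit to ``mu + sd``,
    faster growth) has the *smaller* KS, and vice versa.
    """

    def __init__(self, model: MonodModel, mean: MonodParams,
                 upper: MonodParams, lower: MonodParams):
        self.model = model
        self.mean = mean
        self.upper_boundary = upper
        self.lower_boundary = lower

    @property
    def params(self) -> tuple[MonodParams, MonodParams, MonodParams]:
        return self.mean, self.upper_boundary, self.lower_boundary

    def predict(self, S: float | np.ndarray, variant: str = "mean"
                ) -> float | np.ndarray:
        return monod_mu(S, getattr(self, variant if variant != "mean" else "mean"))

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "variant": p.variant, "mu_max_per_h": p.mu_max,
            "ks_g_per_L": p.ks, "ks_ug_per_L": p.ks_ug_L, "r2": p.fit_r2,
        } for p in self.params]
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Plot the growth points and the three fitted curves."""
        from picophys.plots import plot_monod_fit
        return plot_monod_fit(self, ax)

    def summary(self) -> str:
        lines = ["Monod growth-kinetics fit",
                 "=" * 60,
                 f"{'variant':<16}{'mu_max [1/h]':>14}{'KS [ug/L]':>14}{'R^2':>10}"]
        for p in self.params:
            lines.append(f"{p.variant:<16}{p.mu_max:>14.4f}{p.ks_ug_L:>14.1f}"
                         f"{p.fit_r2:>10.4f}")
        lines.append("-" * 60)
        lines.append(f"n growth points: {len(self.model.points)} "
                     f"(glucose {self.model.points[0].glucose_g_L:g}"
                     f"..{self.model.points[-1].glucose_g_L:g} g/L)")
        return "\n".join(lines)


def fit_monod(points: list[GrowthPoint]) -> MonodResults:
    """Functional wrapper: fit the Monod model to growth points."""
    return MonodModel(points).fit()


def ks_distribution(per_cell_tracks: list[DivisionTrack], mu_max: float,
                    frame_interval_min: float = 5.0, n_bins: int = 20
                    ) -> KsDistribution:
    """Per-cell substrate affinities by inverting the Monod equation.

    Each admissible doubling time at known glucose S gives a per-cell rate
    ``mu_cell``; inverting the Monod relation yields
    ``ks = S * (mu_max / mu_cell - 1)``.  Cells growing at or above
    ``mu_max`` cannot be inverted and are skipped (their count is reported
    in ``n_skipped``).
    """
    if mu_max <= 0:
        raise ValueError("mu_max must be positive")
    values = []
    n_skipped = 0
    for track in per_cell_tracks:
        for td, w in doubling_times(track, frame_interval_min):
            if w == 0:
                continue
            mu_cell = LN2 / td * 60.0
            if mu_cell >= mu_max:
                n_skipped += 1
                continue
            values.append(track.glucose_g_L * (mu_max / mu_cell - 1.0))
    if not values:
        raise ValueError("no invertible cells")
    values = np.asarray(values)
    counts, edges = np.histogram(values, bins=n_bins)
    return KsDistribution(
        mean=float(values.mean()), sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        values=values, bin_edges=edges, counts=counts, n_skipped=n_skipped)
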