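"""Map extraction, synthetic experimental maps and goodness-of-fit.

A simulated map is summarised per RGC by the weighted mean SC position of
its terminals.  Experimental maps — point sets of (retinal position, SC
position), possibly with two labelled populations — are smoothed by
local-linear regression (:mod:`retinotopy.regression`), and a simulated
map is scored against the smooth by the goodness-of-fit

    g = (1/N) * sum_i [ (ybar_i - yhat(x_i))^2 / sigma_hat(x_i)^2 ]

the average over RGCs of the squared deviation between the simulated mean
position ybar_i and the regression estimate yhat(x_i), weighted by the
regression's standard error of the mean.  Lower is better; g = 0 iff the
simulated means lie exactly on the fitted curve.  For double maps g is
computed per population against its own fitted curve and the values are
averaged.  Only RGCs whose retinal position lies within the convex hull
of the experimental x values are scored (no extrapolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .regression import LocalLinearFit, loclin_fit
from .simulate import SimResult, SimState

__all__ = [
    "MapEstimate", "ExperimentalMap", "FitScore",
    "weighted_mean_positions", "map_estimate",
    "synth_experimental_map", "fit_experimental_map",
    "goodness_of_fit", "split_and_score_double_map",
    "order_metrics", "dii_injection",
]

#: standard-error floor, in SC-axis units, applied before weighting
STDERR_FLOOR = 1e-3


@dataclass
class MapEstimate:
    """Per-RGC map summary: retinal position -> weighted mean SC position."""

    df: pd.DataFrame  # columns: rgc_index, x, mean_sc, total_terminals, population

    def __len__(self):
        return len(self.df)

    @property
    def x(self) -> np.ndarray:
        return self.df["x"].to_numpy()

    @property
    def mean_sc(self) -> np.ndarray:
        return self.df["mean_sc"].to_numpy()

    @property
    def populations(self) -> list[str]:
        return sorted(self.df["population"].unique())


def weighted_mean_positions(state: SimState, sc_pos: np.ndarray,
                            retinal_pos: Optional[np.ndarray] = None,
                            labels: Optional[np.ndarray] = None,
                            rgc_index: Optional[np.ndarray] = None
                            ) -> MapEstimate:
    """Mean SC position of each RGC's terminals, weighted by counts."""
    counts = state.counts
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("an RGC with zero terminals cannot be mapped")
    n = counts.shape[0]
    mean_sc = counts @ np.asarray(sc_pos, dtype=float) / totals
    df = pd.DataFrame({
        "rgc_index": np.arange(n) if rgc_index is None else rgc_index,
        "x": np.full(n, np.nan) if retinal_pos is None else retinal_pos,
        "mean_sc": mean_sc,
        "total_terminals": totals,
        "population": ["wt"] * n if labels is None else list(labels),
    })
    return MapEstimate(df)


def map_estimate(result: SimResult, state: Optional[SimState] = None
                 ) -> MapEstimate:
    """Map estimate for a run's final state (or a given snapshot state)."""
    return weighted_mean_positions(
        state if state is not None else result.final,
        result.sc_pos, result.retinal_pos, result.labels, result.rgc_index)


@dataclass
class ExperimentalMap:
    """Point set of (retinal position, SC position), optionally labelled."""

    df: pd.DataFrame  # columns: x, y[, population]

    def __post_init__(self):
        if "population" not in self.df.columns:
            self.df = self.df.assign(population="wt")
        xy = self.df[["x", "y"]].to_numpy()
        if np.any(xy < 0) or np.any(xy > 1):
            raise ValueError("map positions must be normalised to [0, 1]")

    @classmethod
    def read(cls, path) -> "ExperimentalMap":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(df)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def populations(self) -> list[str]:
        return sorted(self.df["population"].unique())


def synth_experimental_map(truth: Callable[[np.ndarray], np.ndarray],
                           noise_sd: float = 0.05, n_points: int = 100,
                           double_map_offset: Optional[float] = None,
                           seed: Optional[int] = None) -> ExperimentalMap:
    """Generate a noisy (possibly double) topographic map.

    Retinal positions are sampled uniformly on [0, 1]; SC positions are
    ``truth(x)`` plus Gaussian noise of sd ``noise_sd``, clamped to [0, 1].
    With ``double_map_offset`` the points alternate between two labelled
    populations, the ``"ki"`` one displaced rostrally (toward 0) by the
    offset — emulating the doubled maps of EphA3 knock-ins.
    """
    if n_points < 5:
        raise ValueError("n_points must be >= 5")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n_points)
    y = np.asarray(truth(x), dtype=float)
    pop = np.array(["wt"] * n_points, dtype=object)
    if double_map_offset is not None:
        pop[1::2] = "ki"
        y = y - np.where(pop == "ki", double_map_offset, 0.0)
    y = y + rng.normal(0.0, noise_sd, n_points)
    return ExperimentalMap(pd.DataFrame({
        "x": np.clip(x, 0, 1), "y": np.clip(y, 0, 1), "population": pop}))


def fit_experimental_map(exp_map: ExperimentalMap,
                         bandwidth: Optional[float] = None
                         ) -> dict[str, LocalLinearFit]:
    """Local-linear fit per population of an experimental map."""
    return {
        pop: loclin_fit(sub["x"], sub["y"], bandwidth=bandwidth)
        for pop, sub in exp_map.df.groupby("population")
    }


@dataclass
class FitScore:
    """Goodness-of-fit of a simulated map to an experimental map."""

    g: float
    n_rgc_used: int
    components: dict = field(default_factory=dict)  # per-population g


def goodness_of_fit(estimate: MapEstimate, fit: LocalLinearFit,
                    stderr_floor: float = STDERR_FLOOR) -> FitScore:
    """Error-weighted mean squared deviation of a map from a fitted curve.

    Only retinal positions inside the support of the experimental data are
    evaluated; standard errors below ``stderr_floor`` are clamped before
    weighting.
    """
    if len(estimate) == 0:
        raise ValueError("empty map estimate")
    x = estimate.x
    keep = fit.in_support(x)
    x = x[keep]
    if x.size == 0:
        raise ValueError("no RGC lies inside the experimental map support")
    ybar = estimate.mean_sc[keep]
    yhat = np.atleast_1d(fit(x))
    se = np.maximum(np.atleast_1d(fit.stderr(x)), stderr_floor)
    g = float(np.mean(((ybar - yhat) / se) ** 2))
    return FitScore(g=g, n_rgc_used=int(x.size))


def split_and_score_double_map(estimate: MapEstimate,
                               fits: Mapping[str, LocalLinearFit],
                               stderr_floor: float = STDERR_FLOOR) -> FitScore:
    """Score each population against its own curve and average the g values.

    A single-population estimate scored against a single fit reduces to
    :func:`goodness_of_fit`.
    """
    components = {}
    n_used = 0
    for pop in estimate.populations:
        if pop not in fits:
            raise ValueError(f"no fitted experimental map for population {pop!r}")
        sub = MapEstimate(estimate.df[estimate.df["population"] == pop])
        score = goodness_of_fit(sub, fits[pop], stderr_floor)
        components[pop] = score.g
        n_used += score.n_rgc_used
    return FitScore(g=float(np.mean(list(components.values()))),
                    n_rgc_used=n_used, components=components)


def order_metrics(estimate: MapEstimate,
                  density: Optional[np.ndarray] = None) -> dict:
    """Summary statistics of map quality.

    Returns rank (Spearman) correlation between retinal position and mean
    SC position, RMS deviation from the identity map, mean signed shift
    (negative = rostral), and — when a density profile is given — three
    coverage summaries: the fraction of SC cells holding at least one
    terminal, the caudal-most occupied position, and the contiguous
    occupied span measured from the rostral pole.
    """
    if len(estimate) == 0:
        raise ValueError("empty map estimate")
    x, ybar = estimate.x, estimate.mean_sc
    if len(estimate) > 1 and np.ptp(x) > 0 and np.ptp(ybar) > 0:
        rank_corr = float(stats.spearmanr(x, ybar).statistic)
    else:
        rank_corr = float("nan")
    out = {
        "rank_correlation": rank_corr,
        "rms_from_identity": float(np.sqrt(np.mean((ybar - x) ** 2))),
        "mean_signed_shift": float(np.mean(ybar - x)),
    }
    if density is not None:
        density = np.asarray(density)
        occ = density > 0
        out["occupied_fraction"] = float(occ.mean())
        out["occupied_extent"] = float(
            (np.max(np.nonzero(occ)[0]) + 1) / density.size) if occ.any() else 0.0
        # contiguous occupied span measured from the rostral pole
        out["rostral_contiguous_fraction"] = float(
            (np.argmin(occ) if not occ.all() else occ.size) / occ.size)
    return out


def dii_injection(estimate: MapEstimate, centre: float,
                  radius: float = 0.05) -> pd.DataFrame:
    """Terminal summaries of all RGCs within a retinal injection radius.

    Emulates labelling by a focal DiI injection, for qualitative
    inspection of apparent map collapse in double maps; no statistic is
    defined on it.
    """
    sel = np.abs(estimate.x - centre) <= radius
    return estimate.df[sel].copy()
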