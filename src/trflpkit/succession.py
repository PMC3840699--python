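"""Distance-decay analysis of community similarity within a water mass.

Builds the similarity-to-reference series for one water mass, fits an
ordinary least-squares distance-decay regression, and tests the slope
against zero two ways: a stations-bootstrap percentile interval (the
resampling unit is the station, because every point shares the single
reference sample) and an ANCOVA homogeneity-of-slopes comparison of the
observed series against a permutation null ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .structure import ResemblanceMatrix, bray_curtis_matrix
from .trflp import FingerprintMatrix

__all__ = [
    "SuccessionSeries",
    "RegressionResult",
    "SlopeTestResult",
    "similarity_to_reference",
    "fit_distance_decay",
    "bootstrap_slope",
    "make_null_ensemble",
    "ancova_slope_test",
    "run_succession_analysis",
]


@dataclass
class SuccessionSeries:
    """Per-station similarity (percent) to the reference station."""

    water_mass: str
    reference_station: Union[int, str]
    stations: List[Union[int, str]]
    distances_km: np.ndarray
    similarities: np.ndarray

    def __post_init__(self) -> None:
        self.distances_km = np.asarray(self.distances_km, dtype=float)
        self.similarities = np.asarray(self.similarities, dtype=float)
        if self.distances_km.shape != self.similarities.shape:
            raise ValueError("distances and similarities must align")
        if (self.distances_km < 0).any():
            raise ValueError("distances must be >= 0")

    def drop_reference(self) -> "SuccessionSeries":
        """Remove the reference station's self-comparison point."""
        keep = [s != self.reference_station for s in self.stations]
        return SuccessionSeries(
            water_mass=self.water_mass,
            reference_station=self.reference_station,
            stations=[s for s, k in zip(self.stations, keep) if k],
            distances_km=self.distances_km[keep],
            similarities=self.similarities[keep],
        )


@dataclass(frozen=True)
class RegressionResult:
    slope: float  # percent similarity per km
    intercept: float
    r_squared: float
    n: int
    p_parametric: float


@dataclass
class SlopeTestResult:
    observed_slope: float
    boot_mean: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_boot: int = 0
    p_bootstrap: Optional[float] = None
    ancova_f: Optional[float] = None
    ancova_p: Optional[float] = None
    low_precision: bool = False


def similarity_to_reference(
    resemblance: ResemblanceMatrix,
    layout: pd.DataFrame,
    water_mass: str,
    reference_station: Union[int, str],
    mode: str = "mean",
) -> Union[SuccessionSeries, Dict[str, SuccessionSeries]]:
    """Similarity of each station's community to the reference station.

    ``layout`` must carry one row per sample with columns ``sample_id,
    station, layer, group, along_path_km``. For water masses with several
    depth sub-layers per station, each station's similarity is the mean over
    sub-layer pairs with the reference's matching sub-layer (``mode="mean"``,
    the default) or one series per sub-layer (``mode="per-layer"``).
    """
    required = {"sample_id", "station", "layer", "group", "along_path_km"}
    missing = required - set(layout.columns)
    if missing:
        raise ValueError(f"layout is missing columns: {sorted(missing)}")
    sel = layout[layout["group"] == water_mass]
    if sel.empty:
        raise ValueError(f"no samples in water mass {water_mass!r}")
    ref_rows = sel[sel["station"] == reference_station]
    if ref_rows.empty:
        raise ValueError(
            f"reference station {reference_station!r} absent from {water_mass!r}"
        )
    ref_by_layer = dict(zip(ref_rows["layer"], ref_rows["sample_id"]))
    ref_km = float(ref_rows["along_path_km"].iloc[0])

    def station_series(layer_filter: Optional[str]) -> SuccessionSeries:
        stations, dists, sims = [], [], []
        for station, grp in sel.groupby("station", sort=True):
            vals = []
            for _, row in grp.iterrows():
                if layer_filter is not None and row["layer"] != layer_filter:
                    continue
                ref_sample = ref_by_layer.get(row["layer"])
                if ref_sample is None:
                    continue
                vals.append(resemblance.similarity(row["sample_id"], ref_sample))
            if not vals:
                continue
            stations.append(station)
            dists.append(abs(float(grp["along_path_km"].iloc[0]) - ref_km))
            sims.append(float(np.mean(vals)))
        return SuccessionSeries(
            water_mass=water_mass,
            reference_station=reference_station,
            stations=stations,
            distances_km=np.array(dists),
            similarities=np.array(sims),
        )

    if mode == "mean":
        return station_series(None)
    if mode == "per-layer":
        return {
            layer: station_series(layer) for layer in sorted(ref_by_layer)
        }
    raise ValueError(f"unknown mode {mode!r}")


def fit_distance_decay(
    series: SuccessionSeries, include_reference: bool = False
) -> RegressionResult:
    """OLS regression of similarity on along-path distance.

    The reference's self-comparison point (100% at 0 km) is excluded by
    default: it is not an observation of community turnover.
    """
    s = series if include_reference else series.drop_reference()
    x, y = s.distances_km, s.similarities
    if len(x) < 3:
        raise ValueError("at least 3 points required")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in distances")
    if np.ptp(y) == 0:  # constant similarity: flat line, no fit uncertainty
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, n=len(x),
            p_parametric=1.0,
        )
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(x),
        p_parametric=float(res.pvalue),
    )


def _boot_slopes(
    x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized stations-bootstrap slopes; replicates with < 3 distinct
    distances are redrawn."""
    n = len(x)
    slopes = np.empty(n_boot)
    todo = np.arange(n_boot)
    for _ in range(1000):
        idx = rng.integers(0, n, size=(len(todo), n))
        xb, yb = x[idx], y[idx]
        xm = xb.mean(axis=1, keepdims=True)
        ym = yb.mean(axis=1, keepdims=True)
        sxx = ((xb - xm) ** 2).sum(axis=1)
        distinct = np.array([len(np.unique(row)) for row in xb])
        ok = distinct >= 3
        with np.errstate(invalid="ignore", divide="ignore"):
            sl = ((xb - xm) * (yb - ym)).sum(axis=1) / sxx
        slopes[todo[ok]] = sl[ok]
        todo = todo[~ok]
        if len(todo) == 0:
            return slopes
    raise RuntimeError("could not draw enough valid bootstrap replicates")


def bootstrap_slope(
    series: SuccessionSeries,
    n_boot: int = 10_000,
    seed: Optional[int] = None,
    include_reference: bool = False,
    ci: float = 0.95,
) -> SlopeTestResult:
    """Stations-bootstrap percentile CI and sign test for the decay slope.

    Stations (points) are resampled with replacement; each replicate refits
    the OLS slope. p_bootstrap = 2 * min(frac <= 0, frac >= 0) for
    H0: slope = 0.
    """
    s = series if include_reference else series.drop_reference()
    if len(s.distances_km) < 4:
        raise ValueError("at least 4 points required for the bootstrap")
    observed = fit_distance_decay(series, include_reference=include_reference)
    rng = np.random.default_rng(seed)
    slopes = _boot_slopes(s.distances_km, s.similarities, n_boot, rng)
    alpha = 1.0 - ci
    lo, hi = np.quantile(slopes, [alpha / 2, 1 - alpha / 2])
    p = 2.0 * min((slopes <= 0).mean(), (slopes >= 0).mean())
    return SlopeTestResult(
        observed_slope=observed.slope,
        boot_mean=float(slopes.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        p_bootstrap=float(min(max(p, 1.0 / n_boot), 1.0)),
        low_precision=n_boot < 100,
    )


def make_null_ensemble(
    series: SuccessionSeries,
    n_null: int = 1000,
    seed: Optional[int] = None,
    include_reference: bool = False,
) -> List[SuccessionSeries]:
    """Permutation null: shuffle similarities across the distance labels."""
    s = series if include_reference else series.drop_reference()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_null):
        out.append(
            SuccessionSeries(
                water_mass=s.water_mass,
                reference_station=s.reference_station,
                stations=list(s.stations),
                distances_km=s.distances_km.copy(),
                similarities=rng.permutation(s.similarities),
            )
        )
    return out


def ancova_slope_test(
    series: SuccessionSeries,
    null_ensemble: Sequence[SuccessionSeries],
    include_reference: bool = False,
    base: Optional[SlopeTestResult] = None,
) -> SlopeTestResult:
    """Homogeneity-of-slopes ANCOVA of observed vs null-ensemble series.

    Pools the observed points with every null replicate's points under a
    group indicator and F-tests the distance x group interaction (full
    model y ~ d + g + d:g against reduced y ~ d + g).
    """
    if not null_ensemble:
        raise ValueError("null ensemble must not be empty")
    s = series if include_reference else series.drop_reference()
    xs = [s.distances_km]
    ys = [s.similarities]
    gs = [np.ones_like(s.distances_km)]
    for ns in null_ensemble:
        xs.append(ns.distances_km)
        ys.append(ns.similarities)
        gs.append(np.zeros_like(ns.distances_km))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    g = np.concatenate(gs)
    ones = np.ones_like(x)
    full = np.column_stack([ones, x, g, x * g])
    reduced = full[:, :3]

    def rss(design: np.ndarray) -> Tuple[float, int]:
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        return float(resid @ resid), design.shape[1]

    rss_f, k_f = rss(full)
    rss_r, k_r = rss(reduced)
    df_num = k_f - k_r
    df_den = len(y) - k_f
    if df_den <= 0:
        raise ValueError("not enough points for the ANCOVA")
    if rss_f <= 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    observed = fit_distance_decay(series, include_reference=include_reference)
    result = base if base is not None else SlopeTestResult(observed_slope=observed.slope)
    result.ancova_f = float(f_stat)
    result.ancova_p = max(p, np.finfo(float).tiny)
    return result


def run_succession_analysis(
    fingerprints: Union[FingerprintMatrix, pd.DataFrame],
    layout: pd.DataFrame,
    water_masses: Optional[Sequence[str]] = None,
    regions: Sequence[str] = ("transect",),
    reference_station: Optional[Union[int, str]] = None,
    n_boot: int = 10_000,
    n_null: int = 1000,
    seed: Optional[int] = None,
    min_stations: int = 5,
) -> pd.DataFrame:
    """Full distance-decay chain for every water mass and region.

    Computes the Bray-Curtis resemblance once, builds each water mass's
    similarity-to-reference series restricted to a region's stations, fits
    the decay regression and runs both slope tests. Returns a tidy frame
    with one row per (water mass, region).
    """
    res = bray_curtis_matrix(fingerprints)
    if "region" not in layout.columns:
        layout = layout.assign(region="transect")
    if water_masses is None:
        water_masses = sorted(layout["group"].unique())
    if len(set(layout["group"])) < 1:
        raise ValueError("no water masses in layout")
    rng = np.random.default_rng(seed)
    rows = []
    for wm in water_masses:
        wm_layout = layout[layout["group"] == wm]
        if wm_layout.empty:
            continue
        ref = reference_station
        if ref is None:
            ref = wm_layout.loc[wm_layout["along_path_km"].idxmin(), "station"]
        series_all = similarity_to_reference(res, layout, wm, ref)
        for region in regions:
            region_stations = set(
                layout.loc[layout["region"] == region, "station"]
            ) | {ref}
            keep = [st in region_stations for st in series_all.stations]
            series = SuccessionSeries(
                water_mass=wm,
                reference_station=ref,
                stations=[s for s, k in zip(series_all.stations, keep) if k],
                distances_km=series_all.distances_km[keep],
                similarities=series_all.similarities[keep],
            )
            if len(series.drop_reference().stations) < max(min_stations, 4):
                continue
            fit = fit_distance_decay(series)
            boot = bootstrap_slope(
                series, n_boot=n_boot, seed=int(rng.integers(0, 2**31 - 1))
            )
            nulls = make_null_ensemble(
                series, n_null=n_null, seed=int(rng.integers(0, 2**31 - 1))
            )
            full = ancova_slope_test(series, nulls, base=boot)
            rows.append(
                {
                    "water_mass": wm,
                    "region": region,
                    "n": fit.n,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r2": fit.r_squared,
                    "p_parametric": fit.p_parametric,
                    "ci_low": full.ci_low,
                    "ci_high": full.ci_high,
                    "p_bootstrap": full.p_bootstrap,
                    "ancova_F": full.ancova_f,
                    "ancova_p": full.ancova_p,
                }
            )
    return pd.DataFrame(rows)
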