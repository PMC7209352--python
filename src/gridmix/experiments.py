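"""Scaling studies of the coding range.

Monte-Carlo sweeps over random projection draws: capacity versus module count
and input dimension, the 1D benchmark Δ·(1/Δ²)^M, power-law dependence on the
phase resolution, and the flexibility curve L(N) for a fixed projection set.
Statistics are computed in the log domain (geometric mean and geometric SD),
since the per-draw ranges are roughly log-normally distributed.

Every run is reproducible from its configuration and base seed: trial t of
M-block b uses seed ``base_seed + b*trials + t``, recorded in each output row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .capacity import SearchConfig, coding_range
from .encoding import ProjectionSet, sample_projections
from .lattice import HexLattice

__all__ = [
    "ScalingFit",
    "geometric_stats",
    "benchmark_curve",
    "capacity_scaling",
    "benchmark_1d",
    "interpolate_range",
    "resolution_sweep",
    "flexibility_sweep",
    "flexibility_trials",
    "excess_dimension_summary",
]

_TABLE_COLUMNS = ["M", "N", "delta", "trial", "seed", "L", "certified", "ok", "error"]


@dataclass(frozen=True)
class ScalingFit:
    """Log-linear regression summary: log(geometric mean L) against a predictor."""

    slope: float
    intercept: float
    r2: float
    predictor: str


def geometric_stats(values) -> tuple[float, float]:
    """Geometric mean and geometric SD (exp of the population SD of logs)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("geometric statistics require positive finite values")
    logs = np.log(v)
    return float(np.exp(logs.mean())), float(np.exp(logs.std(ddof=0)))


def benchmark_curve(delta: float, M) -> np.ndarray:
    """The 1D coding-range benchmark Δ·(1/Δ²)^M."""
    M = np.asarray(M, dtype=float)
    return delta * (1.0 / delta**2) ** M


def _cfg(delta: float, **kwargs) -> SearchConfig:
    return SearchConfig(delta=delta, **kwargs)


def _run_rows(rows: list, M: int, N: int, delta: float, trial: int, seed: int,
              P: ProjectionSet, cfg: SearchConfig, lattice: HexLattice) -> None:
    try:
        res = coding_range(P, N, cfg, lattice)
        rows.append((M, N, delta, trial, seed, res.L, res.certified, True, ""))
    except Exception as exc:  # failed rows are flagged, never dropped
        rows.append((M, N, delta, trial, seed, np.nan, False, False, str(exc)))


def _summarize(table: pd.DataFrame) -> pd.DataFrame:
    ok = table[table["ok"] & table["certified"]]
    groups = []
    for (M, N, delta), g in ok.groupby(["M", "N", "delta"]):
        gm, gsd = geometric_stats(g["L"].to_numpy())
        groups.append((M, N, delta, len(g), gm, gsd))
    return pd.DataFrame(groups, columns=["M", "N", "delta", "n", "geo_mean", "geo_sd"])


def capacity_scaling(
    M_list,
    N_list,
    delta: float,
    trials: int,
    base_seed: int,
    lattice: HexLattice | None = None,
    **cfg_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coding range over a grid of (M, N) pairs.

    Each trial of an M-block draws ONE projection set with N_max = max(N_list)
    and computes L for every requested N from its left sub-blocks, so the same
    draw supports the flexibility analysis.  Returns the per-trial table and a
    per-(M, N) geometric-mean/SD summary.
    """
    lattice = lattice or HexLattice()
    M_list, N_list = list(M_list), list(N_list)
    if trials < 1:
        raise ValueError("trials must be >= 1")
    cfg = _cfg(delta, **cfg_kwargs)
    N_max = max(N_list)
    rows: list = []
    for b, M in enumerate(M_list):
        for t in range(trials):
            seed = base_seed + b * trials + t
            P = sample_projections(M, N_max, seed)
            for N in N_list:
                _run_rows(rows, M, N, delta, t, seed, P, cfg, lattice)
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    return table, _summarize(table)


def benchmark_1d(
    M_list,
    delta: float,
    trials: int,
    base_seed: int,
    lattice: HexLattice | None = None,
    **cfg_kwargs,
) -> dict:
    """1D capacity distribution per module count, with the analytic benchmark.

    Runs N = 1 capacity searches, reports per-M geometric statistics and the
    OLS fit of log(geometric mean L) against M.  The benchmark predicts a
    slope of log(1/Δ²).
    """
    table, summary = capacity_scaling(
        M_list, [1], delta, trials, base_seed, lattice, **cfg_kwargs
    )
    fit = (
        _fit_loglinear(summary["M"].to_numpy(float), summary["geo_mean"].to_numpy(), "M")
        if len(summary) >= 3
        else None
    )
    return {
        "table": table,
        "summary": summary,
        "fit": fit,
        "benchmark": benchmark_curve(delta, np.asarray(list(M_list), float)),
    }


def _fit_loglinear(x: np.ndarray, geo_means: np.ndarray, predictor: str) -> ScalingFit:
    if x.size < 3:
        raise ValueError("log-linear fit needs at least 3 points")
    res = sps.linregress(x, np.log(geo_means))
    return ScalingFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        predictor=predictor,
    )


def interpolate_range(
    dist_floor,
    dist_ceil,
    ratio: float,
    ratio_floor: float | None = None,
    ratio_ceil: float | None = None,
    quantiles: np.ndarray | None = None,
) -> dict:
    """Log-domain quantile interpolation between two range distributions.

    For a modules-per-dimension ratio M/N between two anchor ratios, the
    interpolated distribution has quantiles
    ``exp((1-t) log q_floor + t log q_ceil)`` where t is the fractional
    position of the ratio between the anchors.
    """
    if ratio_floor is None:
        ratio_floor = float(np.floor(ratio))
    if ratio_ceil is None:
        ratio_ceil = ratio_floor + 1.0
    if not ratio_floor <= ratio <= ratio_ceil:
        raise ValueError(
            f"ratio {ratio} outside anchor interval [{ratio_floor}, {ratio_ceil}]"
        )
    t = 0.0 if ratio_ceil == ratio_floor else (ratio - ratio_floor) / (ratio_ceil - ratio_floor)
    if quantiles is None:
        quantiles = np.linspace(0.05, 0.95, 19)
    qf = np.quantile(np.asarray(dist_floor, float), quantiles)
    qc = np.quantile(np.asarray(dist_ceil, float), quantiles)
    if np.any(qf <= 0) or np.any(qc <= 0):
        raise ValueError("distributions must be positive for log interpolation")
    vals = np.exp((1.0 - t) * np.log(qf) + t * np.log(qc))
    return {"quantiles": quantiles, "values": vals, "t": t}


def resolution_sweep(
    M: int,
    N: int,
    delta_list,
    trials: int,
    base_seed: int,
    lattice: HexLattice | None = None,
    **cfg_kwargs,
) -> dict:
    """Coding range versus phase resolution for fixed (M, N).

    The same projection draw (seed ``base_seed + t``) is reused across all Δ
    so that per-seed monotonicity in Δ can be checked.  Fits
    log(geometric mean L) against log(1/Δ); needs >= 3 resolutions.
    """
    lattice = lattice or HexLattice()
    delta_list = list(delta_list)
    if len(delta_list) < 3:
        raise ValueError("resolution sweep needs at least 3 phase resolutions")
    if any(d2 >= d1 for d1, d2 in zip(delta_list, delta_list[1:])):
        raise ValueError("delta_list must be strictly decreasing")
    rows: list = []
    for t in range(trials):
        seed = base_seed + t
        P = sample_projections(M, N, seed)
        for delta in delta_list:
            _run_rows(rows, M, N, delta, t, seed, P, _cfg(delta, **cfg_kwargs), lattice)
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    summary = _summarize(table)
    fit = _fit_loglinear(
        np.log(1.0 / summary["delta"].to_numpy()),
        summary["geo_mean"].to_numpy(),
        "log 1/delta",
    )
    return {"table": table, "summary": summary, "fit": fit}


def flexibility_sweep(
    P: ProjectionSet,
    N_list,
    cfg: SearchConfig,
    lattice: HexLattice | None = None,
) -> pd.DataFrame:
    """L(N) for one fixed projection set, using its left 2 x N sub-blocks."""
    lattice = lattice or HexLattice()
    N_list = list(N_list)
    if max(N_list) > P.N_max:
        raise ValueError("N_list exceeds the projection set's N_max")
    rows: list = []
    for N in N_list:
        _run_rows(rows, P.M, N, cfg.delta, 0, P.seed if P.seed is not None else -1,
                  P, cfg, lattice)
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def flexibility_trials(
    M: int,
    N_max: int,
    N_list,
    trials: int,
    base_seed: int,
    delta: float,
    lattice: HexLattice | None = None,
    **cfg_kwargs,
) -> pd.DataFrame:
    """Flexibility curves for several independent projection draws."""
    cfg = _cfg(delta, **cfg_kwargs)
    frames = []
    for t in range(trials):
        P = sample_projections(M, N_max, base_seed + t)
        df = flexibility_sweep(P, N_list, cfg, lattice)
        df["trial"] = t
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def excess_dimension_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean L grouped by excess dimension 2M - N.

    For each excess value present for more than one N, reports the spread
    (max/min ratio) of the geometric means across N — the quantity behind the
    excess-dimension collapse claim.
    """
    s = summary.copy()
    s["excess"] = 2 * s["M"] - s["N"]
    rows = []
    for e, g in s.groupby("excess"):
        gm = g["geo_mean"].to_numpy()
        rows.append((e, len(g), gm.min(), gm.max(), gm.max() / gm.min()))
    return pd.DataFrame(rows, columns=["excess", "n_pairs", "gm_min", "gm_max", "spread"])
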