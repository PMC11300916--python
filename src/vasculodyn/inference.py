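"""Hierarchical-bootstrap inference for dissimilarity and stability scores.

The biological unit is the culture well; the four imaged quadrants are
technical replicates nested within it.  One bootstrap replicate therefore
resamples, per cell line, wells with replacement (keeping the original
number of wells) and then, within each drawn well, its quadrants with
replacement (keeping the original per-well count).  Well averages, the
time/object transformations and the cubic fits are recomputed from scratch
on every resampled dataset, and all objects are evaluated on the *same*
resampled data within a replicate — a requirement for the between-object
correlation of bootstrap scores to be meaningful.

Uncertainty is summarised by percentile intervals of the B bootstrap
scores (linear-interpolation empirical quantiles).  Everything is
deterministic given the seed.

Two code paths produce identical draws: a generic one that rebuilds a
feature table and applies any user statistic, and a vectorised one for the
standard OLS score pipeline on balanced designs (used for large B).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import scoring, trajectory
from .scoring import ScoreSet, TimeWindow


@dataclass(frozen=True)
class BootstrapConfig:
    """Replication count, interval level and seed of one bootstrap run."""

    B: int = 4000
    level: float = 0.95
    rng_seed: int = 0
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")


@dataclass
class BootstrapDistribution:
    """Realised bootstrap values of one statistic with its interval."""

    name: str
    values: np.ndarray
    point: float
    lo: float
    hi: float
    level: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("interval endpoints out of order")


def percentile_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval, linear-interpolation quantiles."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one value")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1D arrays with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("rank correlation undefined for a constant vector")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# Resampling plans
# ---------------------------------------------------------------------------

def _structure(table: pd.DataFrame) -> dict[str, list[tuple[str, list[str]]]]:
    """Nested design of the table: line -> [(well, [quadrants...]), ...],
    everything sorted so draw order is reproducible."""
    out: dict[str, list[tuple[str, list[str]]]] = {}
    for line, grp in table.groupby("cell_line", sort=True):
        wells = []
        for well, wgrp in grp.groupby("well", sort=True):
            wells.append((well, sorted(wgrp["quadrant"].unique())))
        out[line] = wells
    return out


def _draw_indices(rng: np.random.Generator,
                  structure: dict[str, list[tuple[str, list[str]]]],
                  ) -> dict[str, list[tuple[int, np.ndarray]]]:
    """One replicate's draws: per line, well indices with replacement, then
    quadrant indices with replacement within each drawn well.  The rng
    consumption order is fixed (lines sorted, wells in drawn order), so
    alternative execution paths reproduce identical datasets."""
    plan: dict[str, list[tuple[int, np.ndarray]]] = {}
    for line in sorted(structure):
        wells = structure[line]
        w_idx = rng.integers(0, len(wells), size=len(wells))
        draws = []
        for wi in w_idx:
            n_q = len(wells[wi][1])
            q_idx = rng.integers(0, n_q, size=n_q)
            draws.append((int(wi), q_idx))
        plan[line] = draws
    return plan


def resample_table(table: pd.DataFrame,
                   structure: dict[str, list[tuple[str, list[str]]]],
                   plan: dict[str, list[tuple[int, np.ndarray]]]) -> pd.DataFrame:
    """Materialise one replicate as a feature table with relabelled wells
    and quadrants (duplicates drawn twice stay distinct units)."""
    groups = {key: df for key, df in table.groupby(["cell_line", "well", "quadrant"], sort=False)}
    parts = []
    for line, draws in plan.items():
        wells = structure[line]
        for slot, (wi, q_idx) in enumerate(draws):
            well, quadrants = wells[wi]
            for qslot, qi in enumerate(q_idx):
                block = groups[(line, well, quadrants[qi])].copy()
                block["well"] = f"{well}~{slot}"
                block["quadrant"] = f"{quadrants[qi]}~{qslot}"
                parts.append(block)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Generic hierarchical bootstrap
# ---------------------------------------------------------------------------

def _as_dict(value) -> dict[str, float]:
    if isinstance(value, dict):
        return {str(k): float(v) for k, v in value.items()}
    return {"statistic": float(value)}


def hierarchical_bootstrap(table: pd.DataFrame, statistic,
                           config: BootstrapConfig = BootstrapConfig(),
                           ) -> dict[str, BootstrapDistribution]:
    """Bootstrap any deterministic statistic of a feature table.

    ``statistic`` maps a feature table to a number or a ``{name: number}``
    dict; every named output gets its own percentile interval from the
    joint replicates.  A replicate whose resampled design breaks the
    statistic (e.g. a rank-deficient fit) is redrawn, up to
    ``config.max_redraws`` times.
    """
    struct = _structure(table)
    point = _as_dict(statistic(table))
    rng = np.random.default_rng(config.rng_seed)
    realised: dict[str, list[float]] = {name: [] for name in point}
    for _b in range(config.B):
        for attempt in range(config.max_redraws + 1):
            plan = _draw_indices(rng, struct)
            resampled = resample_table(table, struct, plan)
            try:
                vals = _as_dict(statistic(resampled))
            except (trajectory.FitError, np.linalg.LinAlgError):
                if attempt == config.max_redraws:
                    raise RuntimeError(
                        f"bootstrap replicate failed after {config.max_redraws} redraws")
                continue
            break
        for name in point:
            realised[name].append(vals[name])
    out = {}
    for name in point:
        values = np.asarray(realised[name])
        lo, hi = percentile_interval(values, config.level)
        out[name] = BootstrapDistribution(name=name, values=values, point=point[name],
                                          lo=lo, hi=hi, level=config.level)
    return out


# ---------------------------------------------------------------------------
# Correlation of bootstrap score vectors
# ---------------------------------------------------------------------------

def bootstrap_correlation_matrix(score_vectors: dict[str, np.ndarray]) -> pd.DataFrame:
    """Spearman correlation matrix between per-object bootstrap scores.

    All vectors must come from the same joint resampling draws.  Objects
    constant across replicates have undefined correlation and are flagged
    with NaN off-diagonals; the diagonal is always 1.
    """
    names = sorted(score_vectors)
    lengths = {len(np.asarray(v)) for v in score_vectors.values()}
    if len(lengths) != 1:
        raise ValueError("all bootstrap vectors must share the same B")
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        va, vb = np.asarray(score_vectors[a]), np.asarray(score_vectors[b])
        try:
            rho = spearman_rho(va, vb)
        except ValueError:
            rho = np.nan
        mat.loc[a, b] = mat.loc[b, a] = rho
    return mat


# ---------------------------------------------------------------------------
# Vectorised bootstrap of the standard score pipeline
# ---------------------------------------------------------------------------

def _dense_arrays(table: pd.DataFrame, windows: dict[str, TimeWindow]):
    """Per-line dense value arrays (wells x quadrants x times x objects),
    or None where the design is unbalanced (ragged or missing cells)."""
    objects = sorted(table["object"].unique())
    dense = {}
    for line, grp in table.groupby("cell_line", sort=True):
        win = windows[line]
        grp = grp[(grp["time_h"] >= win.t_l) & (grp["time_h"] <= win.t_u)]
        wells = sorted(grp["well"].unique())
        quads = sorted(grp["quadrant"].unique())
        times = np.asarray(sorted(grp["time_h"].unique()), dtype=float)
        shape = (len(wells), len(quads), len(times), len(objects))
        pivot = grp.set_index(["well", "quadrant", "time_h", "object"])["value"].sort_index()
        if len(pivot) != np.prod(shape) or not pivot.index.is_unique:
            return None
        arr = pivot.to_numpy().reshape(shape)
        if np.isnan(arr).any():
            return None
        t_star = scoring.standardize_time(times, win)
        X = np.vander(t_star, 4, increasing=True)
        X_full = np.tile(X, (len(wells), 1))
        dense[line] = {
            "Y": arr, "times": times, "t_star": t_star,
            "pinv": np.linalg.pinv(X_full),
            "n_wells": len(wells), "n_quads": len(quads), "objects": objects,
        }
    return dense


def _batch_real_roots(c3, c2, c1, c0, pad: float):
    """Real roots of up-to-cubic polynomials given per-row descending
    coefficients; invalid/complex roots are replaced by ``pad``.
    Returns an (N, 3) array."""
    n = len(c3)
    roots = np.full((n, 3), pad, dtype=float)
    scale = np.max(np.abs(np.stack([c3, c2, c1, c0])), axis=0)
    nz = scale > 0
    tol = 1e-14 * np.where(nz, scale, 1.0)
    is3 = np.abs(c3) > tol
    is2 = ~is3 & (np.abs(c2) > tol)
    is1 = ~is3 & ~is2 & (np.abs(c1) > tol)
    if is3.any():
        a, b, c, d = c3[is3], c2[is3], c1[is3], c0[is3]
        comp = np.zeros((is3.sum(), 3, 3))
        comp[:, 1, 0] = 1.0
        comp[:, 2, 1] = 1.0
        comp[:, 0, 2] = -d / a
        comp[:, 1, 2] = -c / a
        comp[:, 2, 2] = -b / a
        ev = np.linalg.eigvals(comp)
        real = np.abs(ev.imag) <= 1e-9 * (1.0 + np.abs(ev.real))
        sub = np.full(ev.shape, pad, dtype=float)
        sub[real] = ev.real[real]
        roots[is3] = sub
    if is2.any():
        a, b, c = c2[is2], c1[is2], c0[is2]
        disc = b * b - 4 * a * c
        ok = disc >= 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        # cancellation-stable form: q = -(b + sign(b) sqrt(disc)) / 2
        sign_b = np.where(b >= 0, 1.0, -1.0)
        q = -0.5 * (b + sign_b * sq)
        with np.errstate(invalid="ignore", divide="ignore"):
            r1 = np.where(ok, q / a, pad)
            r2 = np.where(ok & (q != 0), c / np.where(q != 0, q, 1.0),
                          np.where(ok, -b / (2 * a), pad))
        idx = np.flatnonzero(is2)
        roots[idx, 0] = r1
        roots[idx, 1] = r2
    if is1.any():
        idx = np.flatnonzero(is1)
        roots[idx, 0] = -c0[is1] / c1[is1]
    return roots


def batch_abs_cubic_integral(beta: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Exact integral of |p_i(t)| over [lo, hi] for many cubics at once.

    ``beta`` has shape (4, N), ascending coefficients per column.  Matches
    :func:`vasculodyn.scoring.abs_poly_integral` column-wise.
    """
    b0, b1, b2, b3 = (np.asarray(beta[i], dtype=float) for i in range(4))
    roots = _batch_real_roots(b3, b2, b1, b0, pad=hi)
    pts = np.concatenate([
        np.full((len(b0), 1), lo), np.clip(roots, lo, hi), np.full((len(b0), 1), hi)
    ], axis=1)
    pts.sort(axis=1)
    t = pts
    F = (b0[:, None] * t + b1[:, None] * t**2 / 2.0
         + b2[:, None] * t**3 / 3.0 + b3[:, None] * t**4 / 4.0)
    return np.abs(np.diff(F, axis=1)).sum(axis=1)


def batch_spread(beta: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Attained range of many cubics on [lo, hi]; beta shape (4, N)."""
    b0, b1, b2, b3 = (np.asarray(beta[i], dtype=float) for i in range(4))
    # critical points: roots of b1 + 2 b2 t + 3 b3 t^2
    roots = _batch_real_roots(np.zeros_like(b1), 3.0 * b3, 2.0 * b2, b1, pad=lo)[:, :2]
    cand = np.concatenate([
        np.full((len(b0), 1), lo), np.full((len(b0), 1), hi), np.clip(roots, lo, hi)
    ], axis=1)
    vals = (b0[:, None] + b1[:, None] * cand + b2[:, None] * cand**2
            + b3[:, None] * cand**3)
    return vals.max(axis=1) - vals.min(axis=1)


def _scores_from_betas(betas: dict[str, np.ndarray], objects: list[str],
                       tau_l: float, tau_u: float):
    """Dissimilarity per object and stability per line from per-line
    coefficient matrices of shape (4, n_objects)."""
    lines = sorted(betas)
    dissim = np.zeros(len(objects))
    pair_blocks = []
    for j, k in itertools.combinations(lines, 2):
        pair_blocks.append(betas[j] - betas[k])
    if pair_blocks:
        stacked = np.concatenate(pair_blocks, axis=1)  # (4, n_pairs * n_obj)
        integrals = batch_abs_cubic_integral(stacked, tau_l, tau_u)
        dissim = integrals.reshape(-1, len(objects)).sum(axis=0)
    spread_stack = np.concatenate([betas[line] for line in lines], axis=1)
    spreads = batch_spread(spread_stack, tau_l, tau_u).reshape(len(lines), len(objects))
    stability = spreads.sum(axis=1)
    return dict(zip(objects, dissim)), dict(zip(lines, stability))


@dataclass
class ScoreReport:
    """Point scores with hierarchical-bootstrap percentile intervals."""

    point: ScoreSet
    dissimilarity: dict[str, BootstrapDistribution]
    stability: dict[str, BootstrapDistribution]
    correlation: pd.DataFrame
    config: BootstrapConfig
    meta: dict = field(default_factory=dict)


def bootstrap_scores(table: pd.DataFrame, windows: dict[str, TimeWindow],
                     config: BootstrapConfig = BootstrapConfig(),
                     estimator: str = "ols", strata: str = "object",
                     ) -> ScoreReport:
    """Point estimates plus bootstrap intervals for all scores.

    Uses the vectorised path (identical draws and arithmetic) when the
    design is balanced and the estimator is OLS; falls back to the generic
    table-rebuilding path otherwise.  Within each replicate all objects
    share the same resampled dataset.
    """
    point = scoring.compute_scores(table, windows, estimator=estimator, strata=strata)
    objects = sorted({obj for (_l, obj) in point.fits})
    lines = sorted({line for (line, _o) in point.fits})
    (tau_l, tau_u) = point.meta["tau"]
    rng = np.random.default_rng(config.rng_seed)

    dense = _dense_arrays(table, windows) if estimator == "ols" else None
    dissim_vals = {obj: np.empty(config.B) for obj in objects} if len(lines) >= 2 else {}
    stab_vals = {line: np.empty(config.B) for line in lines}

    if dense is not None:
        for b in range(config.B):
            betas = {}
            for line in lines:
                d = dense[line]
                W, Q = d["n_wells"], d["n_quads"]
                Y = d["Y"]
                w_idx = rng.integers(0, W, size=W)
                ybar = np.empty((W,) + Y.shape[2:])
                for i, wi in enumerate(w_idx):
                    q_idx = rng.integers(0, Q, size=Q)
                    ybar[i] = Y[wi, q_idx].mean(axis=0)
                if strata == "object":
                    flat = ybar.reshape(-1, ybar.shape[-1])
                    mu = flat.mean(axis=0)
                    sd = flat.std(axis=0, ddof=1)
                else:
                    mu = ybar.mean(axis=0)
                    sd = ybar.std(axis=0, ddof=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    z = np.where(sd > 0, (ybar - mu) / np.where(sd > 0, sd, 1.0), 0.0)
                betas[line] = d["pinv"] @ z.reshape(-1, z.shape[-1])
            dis, stab = _scores_from_betas(betas, objects, tau_l, tau_u)
            for obj in dissim_vals:
                dissim_vals[obj][b] = dis[obj]
            for line in lines:
                stab_vals[line][b] = stab[line]
    else:
        struct = _structure(table)
        for b in range(config.B):
            for attempt in range(config.max_redraws + 1):
                plan = _draw_indices(rng, struct)
                resampled = resample_table(table, struct, plan)
                try:
                    rep = scoring.compute_scores(resampled, windows,
                                                 estimator=estimator, strata=strata)
                except (trajectory.FitError, np.linalg.LinAlgError):
                    if attempt == config.max_redraws:
                        raise RuntimeError(
                            f"bootstrap replicate failed after {config.max_redraws} redraws")
                    continue
                break
            for obj in dissim_vals:
                dissim_vals[obj][b] = rep.dissimilarity[obj]
            for line in lines:
                stab_vals[line][b] = rep.stability[line]

    def _dist(name, values, pt):
        lo, hi = percentile_interval(values, config.level)
        return BootstrapDistribution(name=name, values=values, point=pt,
                                     lo=lo, hi=hi, level=config.level)

    dissim_dists = {obj: _dist(f"dissimilarity[{obj}]", dissim_vals[obj],
                               point.dissimilarity[obj]) for obj in dissim_vals}
    stab_dists = {line: _dist(f"stability[{line}]", stab_vals[line],
                              point.stability[line]) for line in lines}
    correlation = (bootstrap_correlation_matrix(dissim_vals)
                   if len(dissim_vals) >= 2 and config.B >= 3 else pd.DataFrame())
    return ScoreReport(point=point, dissimilarity=dissim_dists, stability=stab_dists,
                       correlation=correlation, config=config,
                       meta={"fast_path": dense is not None, "estimator": estimator,
                             "strata": strata})
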