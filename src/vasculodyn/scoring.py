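"""Dissimilarity, spread and stability scores of fitted trajectories.

Scores compare cell lines on common scales:

1. *Time standardisation* — each cell line's analysis window ``(t_l, t_u)``
   maps affinely onto a shared range ``(tau_l, tau_u)``, default ``(0, 1)``,
   so lines whose networks live on very different schedules (e.g. 8-12 h
   vs 17-29 h) become comparable.
2. *Z-normalisation* — object values are centred and scaled to unit
   sample variance within a stratum, so objects measured in counts, um
   and um^2 contribute comparably.  The default stratum is
   ``(cell_line, object)``, pooled over wells and timepoints; the
   per-timepoint variant ``"object_time"`` is available but note that it
   removes the temporal signal itself (each timepoint is re-centred), so
   pooled fits through such data are identically zero on balanced designs.
3. *Integrated discrepancy* — for a pair of cell lines and one object,
   d_jk = integral over the standardised window of |g_j(t) - g_k(t)|,
   computed exactly from the cubic difference (piecewise antiderivative
   between its real roots).  Per object, the dissimilarity score sums
   d_jk over all cell-line pairs.
4. *Spread / stability* — per object, the spread is the attained range
   (max - min) of the fitted standardised curve; a cell line's stability
   score sums the spreads of its retained objects.  Lower = more stable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import trajectory
from .trajectory import PolynomialFit

ZSCORE_STRATA = ("object", "object_time")


@dataclass(frozen=True)
class TimeWindow:
    """A cell line's analysis window and the shared standardised range."""

    cell_line: str
    t_l: float
    t_u: float
    tau_l: float = 0.0
    tau_u: float = 1.0

    def __post_init__(self) -> None:
        if not self.t_l < self.t_u:
            raise ValueError(f"window for {self.cell_line!r} needs t_l < t_u")
        if not self.tau_l < self.tau_u:
            raise ValueError("standardised range needs tau_l < tau_u")


def standardize_time(t, window: TimeWindow) -> np.ndarray:
    """Affine map of hours onto the standardised range.

    ``t_l`` maps to ``tau_l`` and ``t_u`` to ``tau_u`` exactly; values
    outside the window follow the same affine rule.
    """
    t = np.asarray(t, dtype=float)
    span = window.t_u - window.t_l
    return (t - window.t_l) / span * (window.tau_u - window.tau_l) + window.tau_l


def inverse_standardize_time(t_star, window: TimeWindow) -> np.ndarray:
    t_star = np.asarray(t_star, dtype=float)
    span_tau = window.tau_u - window.tau_l
    return (t_star - window.tau_l) / span_tau * (window.t_u - window.t_l) + window.t_l


# ---------------------------------------------------------------------------
# Z-normalisation
# ---------------------------------------------------------------------------

def _strata_cols(strata: str) -> list[str]:
    if strata == "object":
        return ["cell_line", "object"]
    if strata == "object_time":
        return ["cell_line", "object", "time_h"]
    raise ValueError(f"strata must be one of {ZSCORE_STRATA}")


def normalization_stats(well_table: pd.DataFrame, strata: str = "object") -> pd.DataFrame:
    """Per-stratum mean, sample sd (n-1) and count of well-level values."""
    cols = _strata_cols(strata)
    g = well_table.groupby(cols, sort=True)["value"]
    stats = g.agg(mu="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    stats["sd"] = stats["sd"].fillna(0.0)
    stats["degenerate"] = (stats["sd"] == 0.0) | (stats["n"] < 2)
    return stats


def zscore(well_table: pd.DataFrame, stats: pd.DataFrame | None = None,
           strata: str = "object") -> pd.DataFrame:
    """Z-transform well-level values within strata.

    Degenerate strata (single observation or zero spread) map to 0 and are
    flagged in the ``degenerate`` column rather than producing NaN.
    """
    cols = _strata_cols(strata)
    if stats is None:
        stats = normalization_stats(well_table, strata=strata)
    merged = well_table.merge(stats, on=cols, how="left", validate="many_to_one")
    if merged["mu"].isna().any():
        missing = merged.loc[merged["mu"].isna(), cols].drop_duplicates()
        raise ValueError(f"normalisation stats missing for strata:\n{missing}")
    z = np.where(merged["degenerate"], 0.0,
                 (merged["value"] - merged["mu"]) / merged["sd"].where(merged["sd"] > 0, 1.0))
    out = well_table.copy()
    out["value"] = z
    out["degenerate"] = merged["degenerate"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Exact integrals and extrema of cubic differences
# ---------------------------------------------------------------------------

def _real_roots(coeffs_desc: np.ndarray) -> np.ndarray:
    """Real roots of a polynomial given descending coefficients, with
    near-zero leading coefficients trimmed relative to the scale."""
    c = np.asarray(coeffs_desc, dtype=float)
    scale = np.max(np.abs(c), initial=0.0)
    if scale == 0.0:
        return np.empty(0)
    keep = np.abs(c) > 1e-14 * scale
    first = int(np.argmax(keep)) if keep.any() else len(c)
    c = c[first:]
    if c.size <= 1:
        return np.empty(0)
    roots = np.roots(c)
    real = roots[np.abs(roots.imag) <= 1e-9 * (1.0 + np.abs(roots.real))].real
    return real


def abs_poly_integral(beta_ascending: np.ndarray, lo: float, hi: float) -> float:
    """Exact integral of |p(t)| on [lo, hi] for a cubic (or lower) ``p``.

    Splits at the real roots of ``p`` inside the window and sums the
    absolute values of the signed antiderivative over each piece.
    """
    b = np.asarray(beta_ascending, dtype=float)
    if b.shape != (4,):
        raise ValueError("expected four ascending coefficients")
    if not lo <= hi:
        raise ValueError("need lo <= hi")
    roots = _real_roots(b[::-1])
    pts = sorted({lo, hi, *[float(r) for r in roots if lo < r < hi]})
    # antiderivative: b0 t + b1 t^2/2 + b2 t^3/3 + b3 t^4/4
    anti = np.array([0.0, b[0], b[1] / 2.0, b[2] / 3.0, b[3] / 4.0])

    def F(t: float) -> float:
        return float(np.polyval(anti[::-1], t))

    return float(sum(abs(F(t1) - F(t0)) for t0, t1 in zip(pts, pts[1:])))


def integrated_discrepancy(fit_j: PolynomialFit, fit_k: PolynomialFit,
                           tau_l: float = 0.0, tau_u: float = 1.0) -> float:
    """d_jk: integral of |g_j - g_k| over the standardised window, exact."""
    return abs_poly_integral(fit_j.beta - fit_k.beta, tau_l, tau_u)


def spread_score(fit: PolynomialFit, tau_l: float = 0.0, tau_u: float = 1.0) -> float:
    """Attained range (max - min) of the fitted curve on the window."""
    gmax, gmin = trajectory.extrema(fit, (tau_l, tau_u))
    return gmax - gmin


# ---------------------------------------------------------------------------
# Score assembly
# ---------------------------------------------------------------------------

@dataclass
class ScoreSet:
    """Point scores plus the ingredients they were assembled from."""

    dissimilarity: dict[str, float]                       # object -> score
    pairwise: dict[str, pd.DataFrame]                     # object -> d_jk matrix
    spread: dict[tuple[str, str], float]                  # (cell_line, object) -> s_f
    stability: dict[str, float]                           # cell_line -> score
    fits: dict[tuple[str, str], PolynomialFit]
    meta: dict = field(default_factory=dict)


def dissimilarity_score(fits_by_line: dict[str, PolynomialFit],
                        tau_l: float = 0.0, tau_u: float = 1.0,
                        ) -> tuple[float, pd.DataFrame]:
    """Sum of pairwise integrated discrepancies for one object.

    Returns the score and the symmetric zero-diagonal pairwise matrix.
    """
    lines = sorted(fits_by_line)
    if len(lines) < 2:
        raise ValueError("dissimilarity needs fits for at least 2 cell lines")
    mat = pd.DataFrame(0.0, index=lines, columns=lines)
    total = 0.0
    for j, k in itertools.combinations(lines, 2):
        d = integrated_discrepancy(fits_by_line[j], fits_by_line[k], tau_l, tau_u)
        mat.loc[j, k] = mat.loc[k, j] = d
        total += d
    return total, mat


def stability_scores(fits: dict[tuple[str, str], PolynomialFit],
                     tau_l: float = 0.0, tau_u: float = 1.0,
                     ) -> tuple[dict[tuple[str, str], float], dict[str, float]]:
    """Per-object spreads and their per-cell-line sums (lower = more stable)."""
    spreads = {key: spread_score(fit, tau_l, tau_u) for key, fit in fits.items()}
    stability: dict[str, float] = {}
    for (line, _obj), s in spreads.items():
        stability[line] = stability.get(line, 0.0) + s
    return spreads, stability


def mean_discrepancy_stability(fits: dict[tuple[str, str], PolynomialFit],
                               tau_l: float = 0.0, tau_u: float = 1.0,
                               ) -> dict[str, float]:
    """Alternative stability variant: per object, the integrated discrepancy
    between the fitted curve and the horizontal line at its mean level,
    summed per cell line.  Kept as a sensitivity check on the primary
    range-based score."""
    out: dict[str, float] = {}
    span = tau_u - tau_l
    for (line, _obj), fit in fits.items():
        mean_level = float(np.polyval(
            [fit.beta[3] / 4, fit.beta[2] / 3, fit.beta[1] / 2, fit.beta[0], 0.0], tau_u
        ) - np.polyval(
            [fit.beta[3] / 4, fit.beta[2] / 3, fit.beta[1] / 2, fit.beta[0], 0.0], tau_l
        )) / span
        b = fit.beta.copy()
        b[0] -= mean_level
        out[line] = out.get(line, 0.0) + abs_poly_integral(b, tau_l, tau_u)
    return out


def make_windows(windows: dict[str, tuple[float, float]],
                 tau: tuple[float, float] = (0.0, 1.0)) -> dict[str, TimeWindow]:
    return {line: TimeWindow(line, float(tl), float(tu), tau[0], tau[1])
            for line, (tl, tu) in windows.items()}


def transform_table(well_table: pd.DataFrame, windows: dict[str, TimeWindow],
                    strata: str = "object") -> pd.DataFrame:
    """Restrict to each line's window, standardise time, z-score values.

    Adds a ``t_star`` column; the ``value`` column holds z-scores.
    """
    missing = set(well_table["cell_line"].unique()) - set(windows)
    if missing:
        raise ValueError(f"no time window for cell line(s): {sorted(missing)}")
    parts = []
    for line, grp in well_table.groupby("cell_line", sort=True):
        win = windows[line]
        inside = grp[(grp["time_h"] >= win.t_l) & (grp["time_h"] <= win.t_u)].copy()
        inside["t_star"] = standardize_time(inside["time_h"].to_numpy(), win)
        parts.append(inside)
    trimmed = pd.concat(parts, ignore_index=True)
    return zscore(trimmed, strata=strata)


def compute_scores(table: pd.DataFrame, windows: dict[str, TimeWindow],
                   estimator: str = "ols", strata: str = "object",
                   ) -> ScoreSet:
    """Full scoring pass over a raw feature table.

    Averages technical replicates, transforms time and values, pools each
    cell line's wells into one cubic fit per object, then assembles
    dissimilarity (per object) and stability (per cell line) scores on the
    standardised window.
    """
    taus = {(w.tau_l, w.tau_u) for w in windows.values()}
    if len(taus) != 1:
        raise ValueError("all windows must share the same standardised range")
    (tau_l, tau_u), = taus
    well = trajectory.average_replicates(table)
    transformed = transform_table(well, windows, strata=strata)
    fits = trajectory.pooled_fits(transformed, estimator=estimator,
                                  time_col="t_star", value_col="value")
    objects = sorted({obj for (_line, obj) in fits})
    lines = sorted({line for (line, _obj) in fits})
    dissim: dict[str, float] = {}
    pairwise: dict[str, pd.DataFrame] = {}
    if len(lines) >= 2:
        for obj in objects:
            by_line = {line: fits[(line, obj)] for line in lines if (line, obj) in fits}
            if len(by_line) >= 2:
                dissim[obj], pairwise[obj] = dissimilarity_score(by_line, tau_l, tau_u)
    spreads, stability = stability_scores(fits, tau_l, tau_u)
    return ScoreSet(dissimilarity=dissim, pairwise=pairwise, spread=spreads,
                    stability=stability, fits=fits,
                    meta={"estimator": estimator, "strata": strata,
                          "tau": (tau_l, tau_u),
                          "windows": {w.cell_line: (w.t_l, w.t_u) for w in windows.values()}})
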