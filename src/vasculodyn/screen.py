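"""Drug-response comparisons and growth-metric utilities.

The screening stage compares each (compound, concentration) condition to
its vehicle control per mesh-related object at a fixed timepoint, using a
Welch t-test on the square-root scale.  Counts and areas are
right-skewed with variance tied to the mean; the square root stabilises
both before the unequal-variance comparison.  No multiplicity correction
is applied across concentrations or objects by default (stars report
per-test significance); a Holm adjustment is available as an option.

Growth utilities estimate the exponential-phase doubling time from
confluence time courses and correlate it with the network-formation time
window across cell lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .inference import spearman_rho

#: Mesh-related objects compared in the screen by default.
DEFAULT_SCREEN_OBJECTS = ("nb_meshes", "mean_mesh_size", "tot_mesh_area")

#: Two-sided p-value cutoffs for the star codes, most stringent first.
STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))

WINDOW_CONVENTIONS = ("midpoint", "width", "upper", "lower")


class NoGrowthError(ValueError):
    """Raised when a confluence series shows no positive exponential slope."""


def stars(p: float) -> str:
    for cutoff, code in STAR_LEVELS:
        if p < cutoff:
            return code
    return ""


@dataclass
class WelchResult:
    """One treated-vs-control comparison on the square-root scale."""

    compound: str
    concentration_um: float
    object: str
    t: float
    df: float
    p: float
    stars: str
    n_treated: int
    n_control: int


def welch_compare(treated, control, object_name: str = "",
                  compound: str = "", concentration_um: float = float("nan"),
                  ) -> WelchResult:
    """Welch t-test of treated vs control object values, sqrt-transformed.

    Values must be non-negative (they are counts or areas).  If both
    groups are constant with equal means the difference is exactly zero
    and the result reports no difference (t = 0, p = 1).
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size < 2 or control.size < 2:
        raise ValueError("need at least 2 values per group")
    if (treated < 0).any() or (control < 0).any():
        raise ValueError("square-root transform requires non-negative values")
    a, b = np.sqrt(treated), np.sqrt(control)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return WelchResult(compound, concentration_um, object_name,
                               0.0, float(na + nb - 2), 1.0, "", na, nb)
        # degenerate but unambiguous separation
        t = math.inf if a.mean() > b.mean() else -math.inf
        return WelchResult(compound, concentration_um, object_name,
                           t, float(na + nb - 2), 0.0, stars(0.0), na, nb)
    se2a, se2b = va / na, vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(compound, concentration_um, object_name,
                       float(t), float(df), float(p), stars(p), na, nb)


def run_screen(table: pd.DataFrame, design: pd.DataFrame, time_h: float,
               objects=DEFAULT_SCREEN_OBJECTS, control_compound: str = "control",
               holm: bool = False) -> pd.DataFrame:
    """All treated-vs-control Welch comparisons at one timepoint.

    ``design`` maps wells to conditions (columns ``well``, ``compound``,
    ``concentration_um``); rows whose compound equals ``control_compound``
    are the vehicle wells.  Observations are well-level replicate averages
    of each object at ``time_h``.  With ``holm=True`` an optional Holm
    step-down adjustment is applied across all reported tests.
    """
    from .trajectory import average_replicates

    well = average_replicates(table)
    at_t = well[well["time_h"] == time_h]
    if at_t.empty:
        raise ValueError(f"no observations at time_h={time_h}")
    cond = design.set_index("well")
    control_wells = cond.index[cond["compound"] == control_compound]
    if control_wells.empty:
        raise ValueError(f"design has no {control_compound!r} wells")
    rows = []
    treated_conditions = (design[design["compound"] != control_compound]
                          [["compound", "concentration_um"]].drop_duplicates()
                          .sort_values(["compound", "concentration_um"]))
    for _, c in treated_conditions.iterrows():
        wells = cond.index[(cond["compound"] == c["compound"])
                           & (cond["concentration_um"] == c["concentration_um"])]
        for obj in objects:
            tvals = at_t[(at_t["well"].isin(wells)) & (at_t["object"] == obj)]["value"]
            cvals = at_t[(at_t["well"].isin(control_wells)) & (at_t["object"] == obj)]["value"]
            res = welch_compare(tvals.to_numpy(), cvals.to_numpy(), obj,
                                c["compound"], float(c["concentration_um"]))
            rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    if holm and not out.empty:
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
        out["stars"] = [stars(p) for p in adj]
    return out


# ---------------------------------------------------------------------------
# Growth metrics
# ---------------------------------------------------------------------------

def doubling_time(time_h, confluence, ceiling: float = 0.8) -> float:
    """Exponential-phase doubling time (hours) from a confluence series.

    Fits log2(confluence) against time by least squares over the points
    below ``ceiling`` (saturation near full confluence biases the slope
    down, so the plateau is excluded); doubling time is the reciprocal
    slope.
    """
    t = np.asarray(time_h, dtype=float)
    c = np.asarray(confluence, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("time and confluence must be equal-length 1D arrays")
    if (c < 0).any() or (c > 1).any():
        raise ValueError("confluence must lie in [0, 1]")
    keep = (c > 0) & (c <= ceiling)
    if keep.sum() < 3:
        raise ValueError("need at least 3 sub-ceiling positive timepoints")
    slope = sps.linregress(t[keep], np.log2(c[keep])).slope
    if slope <= 0:
        raise NoGrowthError("no growth detected (non-positive log2 slope)")
    return 1.0 / slope


@dataclass
class CorrelationResult:
    """Spearman correlation with the window-summary convention recorded."""

    rho: float
    convention: str
    n: int


def _window_summary(t_l: float, t_u: float, convention: str) -> float:
    if convention == "midpoint":
        return 0.5 * (t_l + t_u)
    if convention == "width":
        return t_u - t_l
    if convention == "upper":
        return t_u
    if convention == "lower":
        return t_l
    raise ValueError(f"convention must be one of {WINDOW_CONVENTIONS}")


def growth_network_correlation(doubling_times: dict[str, float],
                               windows: dict[str, tuple[float, float]],
                               convention: str = "midpoint") -> CorrelationResult:
    """Spearman correlation between doubling time and the network time
    window across cell lines.

    The window is summarised by one scalar per line; the midpoint is the
    default and the convention used is always recorded in the result, so a
    different summary is never silently substituted.
    """
    lines = sorted(doubling_times)
    if sorted(windows) != lines:
        raise ValueError("doubling_times and windows must cover the same cell lines")
    if len(lines) < 3:
        raise ValueError("need at least 3 cell lines")
    x = np.array([doubling_times[l] for l in lines])
    y = np.array([_window_summary(*windows[l], convention) for l in lines])
    return CorrelationResult(rho=spearman_rho(x, y), convention=convention, n=len(lines))
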