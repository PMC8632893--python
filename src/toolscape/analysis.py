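"""Derived quantities: tool-use locations, displacement, assemblage structure,
distance decay, and sweep-level statistics.

Everything here is recomputable from a persisted :class:`~toolscape.experiment.RunRecord`
alone — the analysis layer holds no hidden simulation state. Distances default
to Chebyshev cells (the model's native metric); Euclidean reporting is
available via ``metric="euclidean"`` where it makes sense.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "Snapshot",
    "RunSummary",
    "DecaySummary",
    "count_tool_use_locations",
    "max_displacement",
    "build_assemblages",
    "distance_decay",
    "pct_assemblages_with_usable",
    "summarize_run",
    "sweep_statistics",
]


@dataclass(frozen=True)
class Snapshot:
    """Positions-and-masses view of a world at one instant.

    ``trees``/``sources``/``tool_positions`` are (n, 2) integer arrays of cell
    coordinates; ``tool_masses`` is parallel to ``tool_positions``.
    """

    trees: np.ndarray
    sources: np.ndarray
    tool_positions: np.ndarray
    tool_masses: np.ndarray
    usable_threshold: float = 2000.0
    location_radius: int = 3


@dataclass(frozen=True)
class RunSummary:
    """Headline per-run quantities, all recomputable from the RunRecord."""

    run_id: str
    max_displacement: float
    n_locations_start: int
    n_locations_end: int
    any_transport_beyond_3: bool
    pct_assemblages_with_usable: float


@dataclass(frozen=True)
class DecaySummary:
    """Distance-decay of the material record around raw-material sources.

    Count side (assemblage density vs. distance to the *nearest* source):
    ``count_spearman``, ``count_slope`` — Spearman rank correlation and the
    slope of an OLS fit of log(n_total + 1) on distance.

    Mass side (each usable tool's mass vs. the distance to its *own origin*
    source): ``mass_spearman``, ``mass_slope`` — same pair on log(mass + 1).

    ``*_degenerate`` flags mark sides with too little distance variation to
    fit (fewer than 3 points or fewer than 2 distinct distances).
    """

    count_spearman: float
    count_spearman_p: float
    count_slope: float
    count_degenerate: bool
    mass_spearman: float
    mass_spearman_p: float
    mass_slope: float
    mass_degenerate: bool


def _nearest_distances(points: np.ndarray, items: np.ndarray, metric: str = "chebyshev") -> np.ndarray:
    """Distance from each point to the nearest item (inf if no items)."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    items = np.asarray(items, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        return np.empty(0)
    if len(items) == 0:
        return np.full(len(points), np.inf)
    p = np.inf if metric == "chebyshev" else 2
    d, _ = cKDTree(items).query(points, k=1, p=p)
    return d


def count_tool_use_locations(world_or_snapshot) -> int:
    """Number of live trees with a source or usable pounding tool within the
    tool-use-location radius (3 cells under the defaults).

    Accepts a live :class:`~toolscape.model.World` or a :class:`Snapshot`;
    either way the count is recomputed from entity positions (KD-tree), not
    read from the world's internal monitoring grid.
    """
    snap = world_or_snapshot if isinstance(world_or_snapshot, Snapshot) else world_or_snapshot.snapshot()
    usable = snap.tool_masses >= snap.usable_threshold
    items_list = [snap.sources.reshape(-1, 2)]
    if usable.any():
        items_list.append(snap.tool_positions[usable])
    items = np.vstack(items_list)
    d = _nearest_distances(snap.trees, items)
    return int(np.count_nonzero(d <= snap.location_radius))


def _displacements(tools: pd.DataFrame, metric: str = "chebyshev") -> np.ndarray:
    dx = (tools["x"] - tools["origin_x"]).to_numpy(dtype=float)
    dy = (tools["y"] - tools["origin_y"]).to_numpy(dtype=float)
    if metric == "chebyshev":
        return np.maximum(np.abs(dx), np.abs(dy))
    return np.hypot(dx, dy)


def max_displacement(record, metric: str = "chebyshev") -> float:
    """Maximum distance any non-fragment pounding tool ends up from the source
    it was struck at (0 if the run created no tools)."""
    tools = record.tools_final
    originals = tools[~tools["is_fragment"].astype(bool)]
    if len(originals) == 0:
        return 0.0
    return float(_displacements(originals, metric).max())


def build_assemblages(record, metric: str = "chebyshev") -> pd.DataFrame:
    """Per-cell composition of the material record at run end.

    One row per grid cell holding at least one tool record, with columns
    ``x, y, n_usable, n_exhausted, n_fragments, n_total, total_mass,
    nearest_source_distance``. A usable fragment counts under ``n_usable``
    (it can be picked up and reused, exactly like an unbroken hammer);
    ``n_fragments`` tallies sub-threshold fragments; ``n_exhausted`` counts
    worn-out non-fragment tools. Empty record → empty table.
    """
    tools = record.tools_final
    thr = record.config.usable_threshold
    cols = [
        "x",
        "y",
        "n_usable",
        "n_exhausted",
        "n_fragments",
        "n_total",
        "total_mass",
        "nearest_source_distance",
    ]
    if len(tools) == 0:
        return pd.DataFrame(columns=cols)
    t = tools.assign(
        usable=tools["mass"] >= thr,
        fragment=tools["is_fragment"].astype(bool),
    )
    t["exhausted"] = ~t["usable"] & ~t["fragment"]
    t["sub_fragment"] = ~t["usable"] & t["fragment"]
    grouped = (
        t.groupby(["x", "y"], sort=True)
        .agg(
            n_usable=("usable", "sum"),
            n_exhausted=("exhausted", "sum"),
            n_fragments=("sub_fragment", "sum"),
            n_total=("mass", "size"),
            total_mass=("mass", "sum"),
        )
        .reset_index()
    )
    sources = record.sources_final[["x", "y"]].to_numpy()
    grouped["nearest_source_distance"] = _nearest_distances(
        grouped[["x", "y"]].to_numpy(), sources, metric
    )
    return grouped[cols]


def pct_assemblages_with_usable(table: pd.DataFrame) -> float:
    """Percentage of assemblages (cells with any record) containing at least
    one usable pounding tool."""
    if len(table) == 0:
        raise ValueError("empty assemblage table: percentage undefined")
    return 100.0 * float((table["n_usable"] >= 1).sum()) / float(len(table))


def _decay_fit(dist: np.ndarray, values: np.ndarray) -> tuple[float, float, float, bool]:
    """Spearman rho/p and exponential-fit slope of values vs distance; the fit
    is OLS of log(value + 1) on distance. Returns (rho, p, slope, degenerate)."""
    if len(dist) < 3 or len(np.unique(dist)) < 2:
        return (float("nan"), float("nan"), float("nan"), True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, p = stats.spearmanr(dist, values)
    slope = float(np.polyfit(dist, np.log(values + 1.0), 1)[0])
    return (float(rho), float(p), slope, False)


def distance_decay(
    table: pd.DataFrame,
    tools: pd.DataFrame | None = None,
    usable_threshold: float = 2000.0,
    metric: str = "chebyshev",
) -> DecaySummary:
    """Distance-decay summary of an assemblage table.

    The count side regresses per-cell record counts on the distance to the
    nearest source. If ``tools`` (a ``tools_final`` table) is given, the mass
    side pairs every usable tool's mass with the distance to its own origin
    source; otherwise the mass side is marked degenerate.
    """
    c_rho, c_p, c_slope, c_deg = _decay_fit(
        table["nearest_source_distance"].to_numpy(dtype=float),
        table["n_total"].to_numpy(dtype=float),
    )
    if tools is not None and len(tools) > 0:
        usable = tools[tools["mass"] >= usable_threshold]
        m_rho, m_p, m_slope, m_deg = _decay_fit(
            _displacements(usable, metric), usable["mass"].to_numpy(dtype=float)
        )
    else:
        m_rho = m_p = m_slope = float("nan")
        m_deg = True
    return DecaySummary(c_rho, c_p, c_slope, c_deg, m_rho, m_p, m_slope, m_deg)


def summarize_run(record, run_id: str = "") -> RunSummary:
    """Compute the headline per-run quantities from a complete RunRecord."""
    tools = record.tools_final
    n_start = int(record.timeseries["n_tool_use_locations"].iloc[0])
    n_end = int(record.timeseries["n_tool_use_locations"].iloc[-1])
    if len(tools) > 0:
        sources = record.sources_final[["x", "y"]].to_numpy()
        d_near = _nearest_distances(tools[["x", "y"]].to_numpy(), sources)
        beyond = bool((d_near > record.config.location_radius).any())
        pct = pct_assemblages_with_usable(build_assemblages(record))
    else:
        beyond = False
        pct = float("nan")
    return RunSummary(
        run_id=run_id,
        max_displacement=max_displacement(record),
        n_locations_start=n_start,
        n_locations_end=n_end,
        any_transport_beyond_3=beyond,
        pct_assemblages_with_usable=pct,
    )


def _kruskal_by(summaries: pd.DataFrame, value: str, group: str) -> dict:
    groups = [g[value].to_numpy(dtype=float) for _, g in summaries.groupby(group)]
    if len(groups) < 2:
        return {"statistic": None, "pvalue": None, "skipped": "single group"}
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # identical values in every group: no variation to rank, H is 0
        return {"statistic": 0.0, "pvalue": 1.0, "skipped": None}
    stat, p = stats.kruskal(*groups)
    return {"statistic": float(stat), "pvalue": float(p), "skipped": None}


def sweep_statistics(summaries: pd.DataFrame) -> dict:
    """Sweep-level report from a table of per-run summaries.

    Expects columns ``max_displacement``, ``n_trees``, ``n_sources``,
    ``any_transport_beyond_3``, ``n_locations_start``, ``n_locations_end``.

    Returns a dict with Kruskal–Wallis tests of max displacement across tree-
    and source-count groups, an OLS of max displacement on (n_trees,
    n_sources) with R² and coefficients (raw and standardized, so the two
    predictors' effect sizes are comparable), and the pooled fractions of runs
    with any tool beyond the location radius from the nearest source and with
    more tool-use locations at the end than at the start.
    """
    report: dict = {
        "kruskal_trees": _kruskal_by(summaries, "max_displacement", "n_trees"),
        "kruskal_sources": _kruskal_by(summaries, "max_displacement", "n_sources"),
    }
    y = summaries["max_displacement"].to_numpy(dtype=float)
    X = summaries[["n_trees", "n_sources"]].to_numpy(dtype=float)
    fit = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    std = X.std(axis=0, ddof=0)
    std[std == 0] = np.nan
    report["ols"] = {
        "r_squared": float(fit.rsquared),
        "coef_trees": float(fit.params[1]),
        "coef_sources": float(fit.params[2]),
        "pvalue_trees": float(fit.pvalues[1]),
        "pvalue_sources": float(fit.pvalues[2]),
        "std_coef_trees": float(fit.params[1] * std[0]),
        "std_coef_sources": float(fit.params[2] * std[1]),
    }
    n = len(summaries)
    report["frac_any_transport_beyond_3"] = float(
        summaries["any_transport_beyond_3"].astype(bool).sum() / n
    )
    report["frac_locations_increase"] = float(
        (summaries["n_locations_end"] > summaries["n_locations_start"]).sum() / n
    )
    report["n_runs"] = int(n)
    return report
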