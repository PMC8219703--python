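"""Half-lives, detectability thresholds, goodness of fit and results tables.

Posterior removal rates are converted samplewise to half-lives
(DT50 = ln 2 / k); because the map is monotone decreasing, the median DT50
equals ln 2 over the median k and the DT50 quartiles are the reflected k
quartiles.  A half-life is only reportable if the implied concentration
drop over the flowpath's median travel time exceeds what the measurement
precision can resolve; medians beyond that threshold are rendered as "Inf".
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .inference import ObservationSet, PosteriorSummary
from .transport import (
    BoundarySeries,
    BreakthroughCurve,
    PecletWarning,
    SpatialGrid,
    solve_ade,
)

__all__ = [
    "CompoundFlowpathResult",
    "k_to_dt50",
    "dt50_threshold",
    "apply_inf_mask",
    "rmse",
    "average_rmse",
    "result_from_summary",
    "assemble_results_table",
    "parse_results_table",
    "format_sig",
]

LN2 = math.log(2.0)

FLOWPATH_ORDER = ("a", "b", "c", "d")


def k_to_dt50(k):
    """Half-life DT50 = ln 2 / k (hours) for removal rate(s) k (1/h, > 0)."""
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("DT50 requires k > 0")
    out = LN2 / k
    return float(out) if out.ndim == 0 else out


def dt50_threshold(rel_sd: float, travel_time: float) -> float:
    """Largest detectable half-life (h) on a flowpath of median travel time tau.

    Removal is only measurable if concentrations drop by at least twice the
    relative measurement precision over the passage.  The smallest resolvable
    rate satisfies exp(-k_min tau) = 1 - 2 rel_sd, giving

        threshold = ln 2 * tau / (-ln(1 - 2 rel_sd)).

    Half-life medians above this value represent removal the measurements
    cannot distinguish from none.
    """
    if travel_time <= 0:
        raise ValueError("travel time must be positive")
    if not 0.0 < 2.0 * rel_sd < 1.0:
        raise ValueError("need 0 < 2*rel_sd < 1")
    return LN2 * travel_time / (-math.log1p(-2.0 * rel_sd))


@dataclass(frozen=True)
class CompoundFlowpathResult:
    """Posterior summary for one compound on one flowpath (one table cell group)."""

    compound: str
    flowpath: str
    r_median: float
    r_iqr: float
    k_median: float
    k_iqr: float
    dt50_median: float
    dt50_iqr: float
    rmse: float
    threshold: float
    dt50_masked: bool = False


def result_from_summary(
    summary: PosteriorSummary,
    compound: str,
    flowpath: str,
    obs: ObservationSet,
    boundary: BoundarySeries,
    travel_time: float,
    rel_sd: float,
    grid: SpatialGrid | None = None,
) -> CompoundFlowpathResult:
    """Assemble one results cell from a posterior summary (mask not yet applied).

    DT50 quartiles follow from the k quartiles by monotonicity:
    median(ln2/k) = ln2/median(k) and the quartiles swap roles.
    """
    k_med, k_q25, k_q75 = summary.median["k"], summary.q25["k"], summary.q75["k"]
    dt50_med = k_to_dt50(k_med)
    dt50_iqr = k_to_dt50(k_q25) - k_to_dt50(k_q75)
    fitted = _fitted_at_observations(summary, obs, boundary, grid)
    return CompoundFlowpathResult(
        compound=compound,
        flowpath=flowpath,
        r_median=summary.median["R"],
        r_iqr=summary.iqr("R"),
        k_median=k_med,
        k_iqr=summary.iqr("k"),
        dt50_median=dt50_med,
        dt50_iqr=dt50_iqr,
        rmse=rmse(obs, fitted),
        threshold=dt50_threshold(rel_sd, travel_time),
    )


def _fitted_at_observations(summary, obs, boundary, grid) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PecletWarning)
        curve = solve_ade(summary.median_params(), boundary,
                          grid or SpatialGrid.for_inference())
    return curve.at(obs.times)


def apply_inf_mask(result: CompoundFlowpathResult,
                   threshold: float | None = None) -> CompoundFlowpathResult:
    """Mark the half-life non-detectable if its median exceeds the threshold.

    Strict inequality: a median exactly at the threshold stays reported.
    Idempotent.
    """
    thr = result.threshold if threshold is None else threshold
    masked = result.dt50_median > thr
    return replace(result, dt50_masked=masked, threshold=thr)


def rmse(observed: ObservationSet, fitted: np.ndarray | BreakthroughCurve) -> float:
    """Root mean square error between observations and the fitted curve (ug/L)."""
    if isinstance(fitted, BreakthroughCurve):
        fitted = fitted.at(observed.times)
    fitted = np.asarray(fitted, dtype=float)
    if fitted.shape != observed.times.shape:
        raise ValueError("fitted values must align with the observation times")
    resid = observed.concentrations - fitted
    if resid.size == 0:
        raise ValueError("empty observation set")
    return float(np.sqrt(np.mean(resid ** 2)))


def average_rmse(per_flowpath: dict[str, float]) -> float:
    """Compound-level goodness of fit: arithmetic mean over flowpaths."""
    if not per_flowpath:
        raise ValueError("no flowpath RMSE values to average")
    return float(np.mean(list(per_flowpath.values())))


def format_sig(x: float, sig: int = 3) -> str:
    """Format to ``sig`` significant figures, plain notation."""
    if x == 0:
        return "0"
    if not np.isfinite(x):
        return "Inf"
    exponent = math.floor(math.log10(abs(x)))
    decimals = max(sig - 1 - exponent, 0)
    return f"{x:.{decimals}f}"


def _cell(median: float, iqr: float) -> str:
    return f"{format_sig(median)} ({format_sig(iqr)})"

_GAP = ""


def assemble_results_table(results: list[CompoundFlowpathResult]) -> pd.DataFrame:
    """Wide results table: one row per compound, R and DT50 per flowpath, mean RMSE.

    Medians carry their interquartile range in brackets at three significant
    figures; non-detectable half-lives render as the literal ``Inf`` (IQR
    suppressed); flowpaths without a result render as an empty-string gap
    marker rather than being dropped.
    """
    by_compound: dict[str, dict[str, CompoundFlowpathResult]] = {}
    for res in results:
        by_compound.setdefault(res.compound, {})[res.flowpath] = res
    rows = []
    for compound in sorted(by_compound):
        cells = by_compound[compound]
        row: dict[str, object] = {"compound": compound}
        rmses = {}
        for fp in FLOWPATH_ORDER:
            res = cells.get(fp)
            if res is None:
                row[f"R_{fp}"] = _GAP
                row[f"DT50_{fp}"] = _GAP
                continue
            row[f"R_{fp}"] = _cell(res.r_median, res.r_iqr)
            row[f"DT50_{fp}"] = ("Inf" if res.dt50_masked
                                 else _cell(res.dt50_median, res.dt50_iqr))
            rmses[fp] = res.rmse
        row["RMSE_average"] = format_sig(average_rmse(rmses)) if rmses else _GAP
        rows.append(row)
    columns = (["compound"] + [f"R_{fp}" for fp in FLOWPATH_ORDER]
               + [f"DT50_{fp}" for fp in FLOWPATH_ORDER] + ["RMSE_average"])
    return pd.DataFrame(rows, columns=columns)


_CELL_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*\(\s*([0-9.eE+-]+)\s*\)\s*$")


def parse_results_table(table: pd.DataFrame) -> list[dict]:
    """Parse a rendered results table back into numeric records.

    Numbers round-trip at the rendered (3 significant figure) precision, so
    ``assemble -> parse -> assemble`` reproduces the table exactly.
    """
    records = []
    for _, row in table.iterrows():
        for fp in FLOWPATH_ORDER:
            r_cell = row.get(f"R_{fp}", _GAP)
            d_cell = row.get(f"DT50_{fp}", _GAP)
            if r_cell == _GAP and d_cell == _GAP:
                continue
            rec = {"compound": row["compound"], "flowpath": fp}
            m = _CELL_RE.match(str(r_cell))
            if not m:
                raise ValueError(f"unparseable R cell {r_cell!r}")
            rec["r_median"], rec["r_iqr"] = float(m.group(1)), float(m.group(2))
            if str(d_cell).strip() == "Inf":
                rec["dt50_median"] = math.inf
                rec["dt50_iqr"] = math.nan
                rec["dt50_masked"] = True
            else:
                m = _CELL_RE.match(str(d_cell))
                if not m:
                    raise ValueError(f"unparseable DT50 cell {d_cell!r}")
                rec["dt50_median"], rec["dt50_iqr"] = float(m.group(1)), float(m.group(2))
                rec["dt50_masked"] = False
            records.append(rec)
    return records
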