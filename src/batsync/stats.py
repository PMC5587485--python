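"""Correspondence statistics for paired acoustic / visual detections.

Covers the summary statistics of the study design: across-night average of
the synchronous proportion, Pearson correlation of nightly acoustic and
visual counts, contingency tables of detections with/without acoustics by
proximity, flight type and interaction, Fisher's exact test for r x c
tables (full enumeration of tables with the observed margins), Bonferroni
family-wise control, and the sampled-airspace geometry of the camera
frustum versus the omnidirectional microphone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .camera import CameraModel

__all__ = [
    "ContingencyTable", "TestResult",
    "average_nightly_proportion", "pearson_correlation",
    "build_tables", "layout_with_percentages",
    "fisher_exact", "bonferroni", "sampling_volumes", "round_half_up",
]


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class TestResult:
    name: str
    p_raw: float
    p_adjusted: float
    method: str
    n_tests: int


def round_half_up(x: float) -> int:
    """Round half away from zero, the convention used for printed percentages."""
    return int(math.floor(x + 0.5))


def average_nightly_proportion(tallies: pd.DataFrame) -> float:
    """Unweighted across-night mean of the synchronous proportion (%).

    Accepts a tally frame with columns visual_n / synchronous_n (rows named
    'total'/'average' are ignored); nights without visual detections have
    no defined proportion and are excluded.
    """
    df = tallies
    if "night" in df.columns:
        df = df[~df["night"].isin(["total", "average"])]
    df = df[df["visual_n"] > 0]
    if df.empty:
        raise ValueError("no nights with visual detections")
    return float((100.0 * df["synchronous_n"] / df["visual_n"]).mean())


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# --------------------------------------------------------------------------
# Fisher's exact test for r x c tables

def _log_table_prob(table: np.ndarray, logfact_rows: float, logfact_cols: float,
                    logfact_n: float) -> float:
    return logfact_rows + logfact_cols - logfact_n - gammaln(table + 1.0).sum()


def _enumerate_margin_tables(rows: np.ndarray, cols: np.ndarray):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(rows), len(cols)
    table = np.zeros((r, c), dtype=int)

    def fill_row(i: int, remaining_cols: np.ndarray):
        if i == r - 1:
            if np.all(remaining_cols >= 0):
                table[i] = remaining_cols
                yield table
            return
        target = rows[i]

        def fill_cell(j: int, left: int, rem: np.ndarray):
            if j == c - 1:
                if 0 <= left <= rem[j]:
                    table[i, j] = left
                    rem2 = rem.copy()
                    rem2[j] -= left
                    yield from fill_row(i + 1, rem2)
                return
            hi = min(left, rem[j])
            for v in range(hi + 1):
                table[i, j] = v
                rem2 = rem.copy()
                rem2[j] -= v
                yield from fill_cell(j + 1, left - v, rem2)

        yield from fill_cell(0, target, remaining_cols)

    yield from fill_row(0, cols.copy())


def fisher_exact(table: ContingencyTable | np.ndarray,
                 max_total: int = 10_000) -> float:
    """Exact two-sided p for an r x c table by margin enumeration.

    All tables sharing the observed margins are enumerated; each receives
    its multivariate hypergeometric probability (computed with
    log-factorials) and the p-value is the sum of probabilities no larger
    than the observed table's (with a 1e-12 tie tolerance) — the standard
    two-sided convention for exact r x c tests.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=int)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = int(counts.sum())
    if n > max_total:
        raise ValueError(f"table total {n} exceeds enumeration bound {max_total}")
    # degenerate margins: drop empty rows/columns; nothing left to test -> p=1
    counts = counts[rows > 0][:, cols > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        return 1.0
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    lf_rows = gammaln(rows + 1.0).sum()
    lf_cols = gammaln(cols + 1.0).sum()
    lf_n = gammaln(n + 1.0)
    logp_obs = _log_table_prob(counts, lf_rows, lf_cols, lf_n)
    p_obs = math.exp(logp_obs)
    p = 0.0
    for tbl in _enumerate_margin_tables(rows, cols):
        prob = math.exp(_log_table_prob(tbl, lf_rows, lf_cols, lf_n))
        if prob <= p_obs + 1e-12:
            p += prob
    return min(p, 1.0)


def bonferroni(p_values: dict[str, float] | list[float],
               n_tests: int | None = None) -> list[TestResult]:
    """Bonferroni family-wise control: p_adjusted = min(1, m * p)."""
    if isinstance(p_values, dict):
        items = list(p_values.items())
    else:
        items = [(f"test_{i}", p) for i, p in enumerate(p_values)]
    m = n_tests if n_tests is not None else len(items)
    out = []
    for name, p in items:
        if not 0 < p <= 1:
            raise ValueError("p-values must lie in (0, 1]")
        out.append(TestResult(name=name, p_raw=float(p),
                              p_adjusted=float(min(1.0, m * p)),
                              method="fisher_exact+bonferroni", n_tests=m))
    return out


# --------------------------------------------------------------------------
# contingency-table construction and display layout

PROXIMITY_ORDER = ["near", "mid", "far"]
FLIGHT_ORDER = ["straight", "curved", "erratic"]


def _crosstab(events: pd.DataFrame, row_col: str, order: list[str]) -> ContingencyTable:
    counts = np.zeros((len(order), 2), dtype=int)
    for i, lab in enumerate(order):
        sel = events[events[row_col] == lab]
        counts[i, 0] = int(sel["synchronous"].sum())
        counts[i, 1] = int((~sel["synchronous"].astype(bool)).sum())
    return ContingencyTable(order, ["acoustics", "no_acoustics"], counts)


def build_tables(events: pd.DataFrame) -> dict:
    """Contingency tables of visual detections with/without acoustics.

    ``events`` needs columns proximity, flight, synchronous, and (for the
    interaction tables) n_bats and interaction.  Returns the overall
    proximity x acoustics table, per-proximity flight x acoustics tables,
    and per-proximity interaction x acoustics tables for the multi-bat
    subset.
    """
    out: dict = {"proximity": _crosstab(events, "proximity", PROXIMITY_ORDER)}
    out["flight_by_proximity"] = {
        prox: _crosstab(events[events["proximity"] == prox], "flight", FLIGHT_ORDER)
        for prox in PROXIMITY_ORDER
    }
    if "n_bats" in events.columns and "interaction" in events.columns:
        multi = events[events["n_bats"] >= 2]
        tabs = {}
        for prox in PROXIMITY_ORDER:
            sel = multi[multi["proximity"] == prox]
            counts = np.zeros((2, 2), dtype=int)
            for i, inter in enumerate(["agonistic", "noninteracting"]):
                s = sel[sel["interaction"] == inter]
                counts[i, 0] = int(s["synchronous"].sum())
                counts[i, 1] = int((~s["synchronous"].astype(bool)).sum())
            tabs[prox] = ContingencyTable(["agonistic", "noninteracting"],
                                          ["acoustics", "no_acoustics"], counts)
        out["interaction_by_proximity"] = tabs
    return out


def layout_with_percentages(tables_by_prox: dict[str, ContingencyTable]) -> pd.DataFrame:
    """Printed-table layout: counts with row/subtotal/total percentages.

    Row percentages are within-row (acoustics vs not); the subtotal column
    carries each row's share of its proximity block, and subtotal rows
    carry the block's share of the grand total.  Percentages are rounded
    half-up to integers, matching the field-report convention.
    """
    grand = sum(int(t.counts.sum()) for t in tables_by_prox.values())
    rows = []
    tot_with = tot_without = 0
    for prox, tab in tables_by_prox.items():
        block = int(tab.counts.sum())
        for i, lab in enumerate(tab.row_labels):
            w, wo = int(tab.counts[i, 0]), int(tab.counts[i, 1])
            sub = w + wo
            rows.append({
                "proximity": prox, "row": lab, "with_acoustics": w,
                "with_pct": round_half_up(100 * w / sub) if sub else 0,
                "without_acoustics": wo,
                "without_pct": round_half_up(100 * wo / sub) if sub else 0,
                "subtotal": sub,
                "subtotal_pct": round_half_up(100 * sub / block) if block else 0,
            })
        w, wo = (int(v) for v in tab.counts.sum(axis=0))
        rows.append({
            "proximity": prox, "row": "subtotal", "with_acoustics": w,
            "with_pct": round_half_up(100 * w / block) if block else 0,
            "without_acoustics": wo,
            "without_pct": round_half_up(100 * wo / block) if block else 0,
            "subtotal": block,
            "subtotal_pct": round_half_up(100 * block / grand) if grand else 0,
        })
        tot_with += w
        tot_without += wo
    rows.append({
        "proximity": "", "row": "total", "with_acoustics": tot_with,
        "with_pct": round_half_up(100 * tot_with / grand) if grand else 0,
        "without_acoustics": tot_without,
        "without_pct": round_half_up(100 * tot_without / grand) if grand else 0,
        "subtotal": grand, "subtotal_pct": 100,
    })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# sampled-airspace geometry

def sampling_volumes(camera: CameraModel, range_m: float = 50.0
                     ) -> tuple[float, float, float]:
    """Airspace sampled by the camera frustum vs the microphone hemisphere.

    The camera volume is the rectangular pyramid (1/3 * W * H * d) with the
    field-of-view width and height quoted to the nearest meter, as field
    reports do (54 x 41 m at 50 m); the omnidirectional microphone above
    ground samples a hemisphere (2/3 * pi * d^3).  Returns (v_camera,
    v_mic, ratio %).
    """
    if range_m < 0:
        raise ValueError("range must be non-negative")
    if range_m == 0:
        return 0.0, 0.0, float("nan")
    w, h = camera.fov_dims_at(range_m)
    v_cam = round(w) * round(h) * range_m / 3.0
    v_mic = 2.0 / 3.0 * math.pi * range_m ** 3
    return v_cam, v_mic, 100.0 * v_cam / v_mic
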