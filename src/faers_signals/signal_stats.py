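"""Disproportionality statistics over per-event 2x2 contingency tables.

For each adverse-event Preferred Term (PT) occurring in the cohort, the
2x2 table counts distinct reports:

    a  cohort reports with the PT          b  cohort reports without it
    c  background reports with the PT     d  background reports without it

Four frequentist/Bayesian-style measures are computed, with N = a+b+c+d:

* ROR  = (a·d)/(b·c), with 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
  signal if the lower bound exceeds 1 and a ≥ 3.
* PRR  = (a/(a+b))/(c/(c+d)), CI exp(ln PRR ± 1.96·√(1/a−1/(a+b)+1/c−1/(c+d))),
  plus the (uncorrected) Pearson chi-square
  χ² = (ad−bc)²·N / ((a+b)(c+d)(a+c)(b+d)); signal if a ≥ 3, lower CI > 1,
  PRR ≥ 2 and χ² ≥ 4 (conjunction of both published criterion rows).
* Information component IC = log₂( a·N / ((a+c)(a+b)) ), the BCPNN point
  estimate; signal if the lower credibility bound (IC−2SD / IC025) > 0.
* EBGM = a·N / ((a+c)(a+b)) — the relative reporting ratio, identical to
  2^IC — with the log-normal interval exp(ln EBGM ± 1.96·√(1/a+1/b+1/c+1/d));
  signal if EBGM05 > 2. This closed form (not the DuMouchel gamma-Poisson
  mixture posterior) is deliberate; see the methods note.

Zero cells make a statistic undefined (returned as NaN, flags False); no
continuity correction is applied. The IC interval offers two dialects:
``log2-transform`` (default; the log-normal bound of the same ratio on a
log₂ scale) and ``bcpnn-approx`` (the Bate posterior-moment
approximation with uniform-information priors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from faers_signals.cohort_builder import SocMap

Z95 = 1.96
NAN = float("nan")

IC_DIALECTS = ("log2-transform", "bcpnn-approx")

FOREST_COLUMNS = [
    "pt", "soc", "n", "ror", "ror_lo", "ror_hi", "prr", "chi2",
    "ebgm", "ebgm05", "ic", "ic025",
    "ror_pos", "prr_pos", "bcpnn_pos", "mgps_pos",
]


class ContingencyTable(NamedTuple):
    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalThresholds:
    """Signal-criterion cut-offs; defaults as conventionally published."""

    min_a: int = 3
    ror_lower: float = 1.0
    prr_lower: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0
    z: float = Z95


def build_tables(
    cohort: pd.DataFrame, background: pd.DataFrame
) -> list[tuple[str, ContingencyTable]]:
    """One 2x2 table per distinct PT occurring in the cohort.

    Counting is report-level: a report listing a PT twice contributes one
    to `a`; PTs present only in the background yield no table.
    """
    n_cohort, n_background = len(cohort), len(background)
    a_counts: dict[str, int] = {}
    for pts in cohort["pts"]:
        for pt in pts:
            a_counts[pt] = a_counts.get(pt, 0) + 1
    c_counts: dict[str, int] = {}
    for pts in background["pts"]:
        for pt in pts:
            c_counts[pt] = c_counts.get(pt, 0) + 1
    tables = []
    for pt in sorted(a_counts):
        a = a_counts[pt]
        c = c_counts.get(pt, 0)
        tables.append((pt, ContingencyTable(a, n_cohort - a, c, n_background - c)))
    return tables


def ror_stat(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with its 95% log-normal CI.

    Undefined (NaN) on any zero cell — no continuity correction.
    """
    a, b, c, d = t
    if min(a, b, c, d) <= 0:
        return NAN, NAN, NAN
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se)


def prr_stat(t: ContingencyTable) -> tuple[float, float, float, float]:
    """Proportional reporting ratio, its 95% CI, and the uncorrected chi2."""
    a, b, c, d = t
    if a <= 0 or c <= 0 or (a + b) <= 0 or (c + d) <= 0:
        return NAN, NAN, NAN, NAN
    prr = (a / (a + b)) / (c / (c + d))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(var, 0.0))
    lo, hi = prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se)
    n = t.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = ((a * d - b * c) ** 2) * n / denom if denom > 0 else NAN
    return prr, lo, hi, chi2


def _rrr(t: ContingencyTable) -> float:
    """Relative reporting ratio a·N / ((a+c)(a+b)): shared by IC and EBGM."""
    a, b, c, d = t
    if a <= 0 or (a + c) <= 0 or (a + b) <= 0:
        return NAN
    return a * t.n / ((a + c) * (a + b))


def _bcpnn_ic025(t: ContingencyTable) -> float:
    """Bate-style BCPNN posterior approximation of IC − 2SD.

    Uses the classical uniform-information priors (alpha1 = beta1 = 1,
    alpha = beta = 2, gamma11 = 1) and the delta-method posterior variance.
    """
    a, b, c, d = t
    n = t.n
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    g = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
    e_ic = math.log2(
        (a + g11) * (n + al) * (n + be) / ((n + g) * (a + b + a1) * (a + c + b1))
    )
    v_ic = (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - a - b + al - a1) / ((a + b + a1) * (1 + n + al))
        + (n - a - c + be - b1) / ((a + c + b1) * (1 + n + be))
    ) / (math.log(2) ** 2)
    return e_ic - 2.0 * math.sqrt(v_ic)


def ic_stat(t: ContingencyTable, dialect: str = "log2-transform") -> tuple[float, float]:
    """BCPNN information component and its lower bound.

    The point estimate is always log2 of the relative reporting ratio.
    ``dialect`` selects the lower bound: the log-normal bound transformed
    to the log2 scale (default), or the Bate posterior approximation.
    """
    if dialect not in IC_DIALECTS:
        raise ValueError(f"unknown IC dialect {dialect!r}")
    a, b, c, d = t
    rrr = _rrr(t)
    if not np.isfinite(rrr) or rrr <= 0:
        return NAN, NAN
    ic = math.log2(rrr)
    if dialect == "log2-transform":
        if min(a, b, c, d) <= 0:
            return ic, NAN
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ic025 = math.log2(rrr * math.exp(-Z95 * se))
    else:
        ic025 = _bcpnn_ic025(t)
    return ic, ic025


def ebgm_stat(t: ContingencyTable) -> tuple[float, float, float]:
    """Relative reporting ratio ("EBGM") with 95% log-normal bounds."""
    a, b, c, d = t
    rrr = _rrr(t)
    if not np.isfinite(rrr):
        return NAN, NAN, NAN
    if min(a, b, c, d) <= 0:
        return rrr, NAN, NAN
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return rrr, rrr * math.exp(-Z95 * se), rrr * math.exp(Z95 * se)


def classify_signal(
    row: dict, thresholds: SignalThresholds = SignalThresholds()
) -> dict[str, bool]:
    """Apply the four per-algorithm signal criteria; NaN never signals."""
    th = thresholds

    def ok(value, cut, strict=True) -> bool:
        if value is None or not np.isfinite(value):
            return False
        return value > cut if strict else value >= cut

    a_ok = row["n"] >= th.min_a
    return {
        "ror_pos": a_ok and ok(row["ror_lo"], th.ror_lower),
        "prr_pos": (a_ok and ok(row["prr_lo"], th.prr_lower)
                    and ok(row["prr"], th.prr_min, strict=False)
                    and ok(row["chi2"], th.chi2_min, strict=False)),
        "bcpnn_pos": ok(row["ic025"], th.ic025_min),
        "mgps_pos": ok(row["ebgm05"], th.ebgm05_min),
    }


def compute_signals(
    cohort: pd.DataFrame,
    background: pd.DataFrame,
    soc_map: SocMap | None = None,
    ic_dialect: str = "log2-transform",
    thresholds: SignalThresholds = SignalThresholds(),
) -> pd.DataFrame:
    """Full per-PT signal table for a cohort/background partition.

    Returns one row per cohort PT with all four statistics, interval
    bounds, and per-algorithm flags. The IC dialect used is recorded in
    ``df.attrs["ic_dialect"]``.
    """
    rows = []
    for pt, t in build_tables(cohort, background):
        ror, ror_lo, ror_hi = ror_stat(t)
        prr, prr_lo, prr_hi, chi2 = prr_stat(t)
        ic, ic025 = ic_stat(t, dialect=ic_dialect)
        ebgm, ebgm05, ebgm95 = ebgm_stat(t)
        row = {
            "pt": pt,
            "soc": soc_map.lookup(pt) if soc_map else SocMap.FALLBACK,
            "n": t.a, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": ror, "ror_lo": ror_lo, "ror_hi": ror_hi,
            "prr": prr, "prr_lo": prr_lo, "prr_hi": prr_hi, "chi2": chi2,
            "ic": ic, "ic025": ic025,
            "ebgm": ebgm, "ebgm05": ebgm05, "ebgm95": ebgm95,
        }
        row.update(classify_signal(row, thresholds))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["ic_dialect"] = ic_dialect
    return df


def rank_results(results: pd.DataFrame, mode: str = "frequency", k: int = 30) -> pd.DataFrame:
    """Top-k ROR-positive PTs, by report count or by signal strength.

    ``frequency`` sorts by n descending (ties: higher ROR, then PT name);
    ``strength`` sorts by ROR descending (ties: higher n, then PT name).
    """
    if mode not in ("frequency", "strength"):
        raise ValueError(f"unknown ranking mode {mode!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    pos = results[results["ror_pos"]].copy()
    if mode == "frequency":
        pos = pos.sort_values(["n", "ror", "pt"], ascending=[False, False, True],
                              kind="mergesort")
    else:
        pos = pos.sort_values(["ror", "n", "pt"], ascending=[False, False, True],
                              kind="mergesort")
    return pos.head(k).reset_index(drop=True)


def export_forest(results: pd.DataFrame, path: str | Path,
                  render_figure: bool = False) -> Path:
    """Write the ranked results as a fixed-column delimited table.

    Numeric values are serialized at 4 decimals; the optional matplotlib
    forest figure (``<path stem>.png``) never feeds back into any number.
    """
    if results.empty:
        raise ValueError("no results to export")
    path = Path(path)
    out = results[FOREST_COLUMNS].copy()
    num = out.select_dtypes(include=[float]).columns
    out[num] = out[num].round(4)
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")
    if render_figure:
        _render_forest(results, path.with_suffix(".png"))
    return path


def _render_forest(results: pd.DataFrame, png_path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results.iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, max(2, 0.3 * len(df) + 1)))
    y = np.arange(len(df))
    ax.errorbar(df["ror"], y,
                xerr=[df["ror"] - df["ror_lo"], df["ror_hi"] - df["ror"]],
                fmt="s", color="black", ecolor="gray", capsize=2, markersize=3)
    ax.axvline(1.0, color="red", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(df["pt"], fontsize=7)
    ax.set_xscale("log")
    ax.set_xlabel("ROR (95% CI)")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
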