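"""Benchmark statistics between calculated and experimental free energies.

Retrospective validation of a perturbation campaign: mean absolute error
(via scikit-learn), Pearson R² with a Fisher-z 95% confidence interval
(appropriate for the small datasets typical of FEP benchmarks), ordinary
least-squares slope/intercept, IC50-ratio conversion to ΔΔG, and report
rendering (CSV/JSON/markdown with scatter data and ±1/±2 kcal/mol bands).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.metrics import mean_absolute_error

from .constants import DEFAULT_TEMPERATURE, R_KCAL

__all__ = [
    "BenchmarkTable",
    "ic50_to_ddg",
    "mae",
    "pearson_r2",
    "fisher_ci",
    "ols_fit",
    "table_statistics",
    "render_report",
]


@dataclass
class BenchmarkTable:
    """Paired experimental/calculated values (kcal/mol) per ligand.

    ``data`` columns: ``ligand``, ``experimental``, ``calculated`` and
    optionally ``sem``.  The reference ligand of a radial perturbation
    design may lack a calculated value (its row is the anchor).
    """

    data: pd.DataFrame
    reference_ligand: str | None = None

    def __post_init__(self):
        missing = {"ligand", "experimental", "calculated"} - set(self.data.columns)
        if missing:
            raise ValueError(f"benchmark table lacks columns {sorted(missing)}")

    @classmethod
    def from_csv(cls, path, reference_ligand: str | None = None) -> "BenchmarkTable":
        return cls(pd.read_csv(path), reference_ligand=reference_ligand)

    def paired(self) -> pd.DataFrame:
        """Rows with both values present and finite."""
        d = self.data.dropna(subset=["experimental", "calculated"])
        return d[np.isfinite(d["experimental"]) & np.isfinite(d["calculated"])]


def ic50_to_ddg(ic50_a: float, ic50_b: float,
                temperature: float = DEFAULT_TEMPERATURE) -> float:
    """ΔΔG_bind (kcal/mol) of B relative to A from an IC50 ratio.

    ΔΔG = RT·ln(IC50(B)/IC50(A)); any common concentration unit cancels.
    """
    if ic50_a <= 0 or ic50_b <= 0:
        raise ValueError("IC50 values must be positive")
    return float(R_KCAL * temperature * math.log(ic50_b / ic50_a))


def mae(table: BenchmarkTable, include_reference_as_zero: bool = False) -> float:
    """Mean absolute error |calculated − experimental| in kcal/mol.

    With the flag set, a reference row lacking a calculated value
    contributes zero deviation (the anchor of a radial design is exact by
    construction), which increases the denominator by one.
    """
    paired = table.paired()
    if len(paired) == 0:
        raise ValueError("no paired rows")
    exp = paired["experimental"].to_numpy()
    calc = paired["calculated"].to_numpy()
    if include_reference_as_zero:
        n_ref = int(table.data["calculated"].isna().sum())
        if n_ref:
            exp = np.concatenate([exp, np.zeros(n_ref)])
            calc = np.concatenate([calc, np.zeros(n_ref)])
    return float(mean_absolute_error(exp, calc))


def pearson_r2(table: BenchmarkTable) -> float:
    """Squared Pearson correlation of the paired columns."""
    paired = table.paired()
    if len(paired) < 3:
        raise ValueError("need at least three paired rows")
    exp = paired["experimental"].to_numpy()
    calc = paired["calculated"].to_numpy()
    if np.var(exp) == 0 or np.var(calc) == 0:
        raise ValueError("zero variance in a column")
    r, _ = sp_stats.pearsonr(exp, calc)
    return float(r * r)


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation.

    (lower, upper) = tanh(artanh(r) ± z_{1−α/2}/√(n−3)); always contains r.
    Degenerate |r| = 1 returns the point interval (r, r).
    """
    if n < 4:
        raise ValueError("Fisher interval needs n >= 4")
    if abs(r) > 1:
        raise ValueError("|r| must not exceed 1")
    if abs(r) == 1.0:
        return (r, r)
    z = math.atanh(r)
    half = sp_stats.norm.ppf(1.0 - alpha / 2.0) / math.sqrt(n - 3)
    return (math.tanh(z - half), math.tanh(z + half))


def ols_fit(table: BenchmarkTable, response: str = "calculated"
            ) -> tuple[float, float]:
    """Ordinary least squares (slope, intercept) of one column on the other.

    Default regresses calculated on experimental; the axis is configurable
    because conventions differ between studies.
    """
    if response not in ("calculated", "experimental"):
        raise ValueError("response must be 'calculated' or 'experimental'")
    paired = table.paired()
    if len(paired) < 2:
        raise ValueError("need at least two paired rows")
    predictor = "experimental" if response == "calculated" else "calculated"
    x = paired[predictor].to_numpy()
    y = paired[response].to_numpy()
    if np.var(x) == 0:
        raise ValueError("degenerate predictor variance")
    res = sp_stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def table_statistics(table: BenchmarkTable,
                     include_reference_as_zero: bool = False,
                     response: str = "calculated") -> dict:
    """All benchmark statistics for one table, 95% CI included."""
    paired = table.paired()
    r2 = pearson_r2(table)
    slope, intercept = ols_fit(table, response=response)
    lo, hi = fisher_ci(math.copysign(math.sqrt(r2), slope), len(paired))
    return {
        "n": int(len(paired)),
        "mae": mae(table, include_reference_as_zero=include_reference_as_zero),
        "r2": r2,
        "r2_ci95": [max(lo, 0.0) ** 2, max(hi, 0.0) ** 2],
        "slope": slope,
        "intercept": intercept,
    }


def render_report(tables: dict[str, BenchmarkTable], outdir,
                  include_reference_as_zero: bool = False,
                  response: str = "calculated") -> dict:
    """Render a benchmark report as CSV + JSON + markdown.

    Per table: the statistics block and the scatter rows (experimental,
    calculated, deviation, and whether the point falls inside the ±1 and
    ±2 kcal/mol agreement bands).  Returns the JSON-serializable summary;
    an empty input yields an empty-but-valid report.
    """
    os.makedirs(outdir, exist_ok=True)
    summary: dict[str, dict] = {}
    scatter_frames = []
    for name, table in tables.items():
        summary[name] = table_statistics(
            table, include_reference_as_zero=include_reference_as_zero,
            response=response)
        sc = table.paired().copy()
        sc.insert(0, "dataset", name)
        sc["deviation"] = sc["calculated"] - sc["experimental"]
        sc["within_1kcal"] = sc["deviation"].abs() <= 1.0
        sc["within_2kcal"] = sc["deviation"].abs() <= 2.0
        scatter_frames.append(sc)
    scatter = (pd.concat(scatter_frames, ignore_index=True) if scatter_frames
               else pd.DataFrame(columns=["dataset", "ligand", "experimental",
                                          "calculated", "deviation",
                                          "within_1kcal", "within_2kcal"]))
    scatter.to_csv(os.path.join(outdir, "scatter.csv"), index=False)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    lines = ["# Benchmark report", ""]
    for name, s in summary.items():
        lines += [f"## {name}", "",
                  f"- n = {s['n']}",
                  f"- MAE = {s['mae']:.2f} kcal/mol",
                  f"- R² = {s['r2']:.2f} "
                  f"[95% CI {s['r2_ci95'][0]:.2f}–{s['r2_ci95'][1]:.2f}]",
                  f"- slope = {s['slope']:.2f}, intercept = {s['intercept']:.2f}",
                  ""]
    with open(os.path.join(outdir, "report.md"), "w") as fh:
        fh.write("\n".join(lines))
    return summary
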