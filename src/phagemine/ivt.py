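"""In vitro transcription (IVT) analytics.

Quantitative bookkeeping around IVT quality control: the dsRNA content of a
transcription reaction as a mass fraction of total RNA, fold-reductions in
dsRNA relative to a reference enzyme (T7 by default), per-enzyme summaries
across DNA templates, and activity expressed as fluorescence of an RNA
aptamer reporter normalized to the reference polymerase.

A transcription of the published characterization table for T7 and the two
mined polymerases (No. 1575, No. 2049) across four templates (a 240-nt
Broccoli aptamer, GFP, FLuc, and Cas9 mRNA) ships with the package; see
:func:`load_reference_measurements`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: sentinel returned when the test dsRNA level is zero (fold is unbounded)
BELOW_QUANTIFICATION = "below_quantification"

MEASUREMENT_COLUMNS = [
    "enzyme",
    "template",
    "yield_mg_per_ml",
    "integrity_pct",
    "dsrna_pct",
]


@dataclass(frozen=True)
class IvtMeasurement:
    """One enzyme x template row of an IVT characterization table."""

    enzyme: str
    template: str
    yield_mg_per_ml: float
    integrity_pct: Optional[float] = None
    dsrna_ng_per_ml: Optional[float] = None
    dsrna_pct: Optional[float] = None
    ph: Optional[float] = None
    temperature_c: Optional[float] = None

    def __post_init__(self) -> None:
        if self.integrity_pct is not None and not (0 <= self.integrity_pct <= 100):
            raise ValueError(f"integrity {self.integrity_pct} outside 0..100")


@dataclass(frozen=True)
class FluorescenceCurve:
    times: np.ndarray  # minutes, strictly increasing
    values: np.ndarray  # relative fluorescence units

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values differ in length")
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing with >= 2 points")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


def dsrna_percent(dsrna_ng_per_ml: float, rna_yield_mg_per_ml: float) -> float:
    """dsRNA content as mass percent of total RNA.

    100 * (dsRNA ng/mL) / (yield mg/mL * 1e6 ng/mg).
    """
    if dsrna_ng_per_ml <= 0 or rna_yield_mg_per_ml <= 0:
        raise ValueError("dsRNA concentration and RNA yield must be positive")
    return 100.0 * dsrna_ng_per_ml / (rna_yield_mg_per_ml * 1e6)


def fold_reduction(reference_pct: float, test_pct: float, rounding: str = "none"):
    """Reference over test dsRNA content; optionally rounded to the nearest
    integer (published folds are printed as integers)."""
    if test_pct < 0:
        raise ValueError("test dsRNA percent must be >= 0")
    if test_pct == 0:
        return BELOW_QUANTIFICATION
    fold = reference_pct / test_pct
    if rounding == "nearest_int":
        return int(round(fold))
    if rounding != "none":
        raise ValueError(f"unknown rounding {rounding!r}")
    return fold


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read an IVT measurements TSV ('n/a' entries become NaN)."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a", "NA", ""])
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurements table lacks columns {sorted(missing)}")
    return df


def load_reference_measurements() -> pd.DataFrame:
    """The packaged published characterization table (T7, 1575, 2049)."""
    ref = resources.files("phagemine.data") / "reference_ivt_measurements.tsv"
    with resources.as_file(ref) as path:
        return read_measurements(path)


def fold_report(
    df: pd.DataFrame, reference: str = "T7", rounding: str = "nearest_int"
) -> pd.DataFrame:
    """Per enzyme x template dsRNA fold-reductions versus the reference.

    Rows without a dsRNA value (e.g. aptamer templates marked n/a) are
    reported with a null fold and ``dsrna_available=False``.
    """
    if reference not in set(df["enzyme"]):
        raise ValueError(f"reference enzyme {reference!r} not in table")
    ref_rows = df[df["enzyme"] == reference].set_index("template")["dsrna_pct"]
    records = []
    for _, row in df[df["enzyme"] != reference].iterrows():
        ref_pct = ref_rows.get(row["template"], float("nan"))
        available = not (pd.isna(row["dsrna_pct"]) or pd.isna(ref_pct))
        fold = (
            fold_reduction(float(ref_pct), float(row["dsrna_pct"]), rounding)
            if available
            else None
        )
        records.append(
            {
                "enzyme": row["enzyme"],
                "template": row["template"],
                "reference": reference,
                "reference_dsrna_pct": ref_pct,
                "dsrna_pct": row["dsrna_pct"],
                "dsrna_available": available,
                "fold_reduction": fold,
            }
        )
    return pd.DataFrame.from_records(records)


def summarize_enzyme(df: pd.DataFrame, enzyme: str) -> dict:
    """Min/max/median of dsRNA %, yield, and integrity across templates.

    Templates lacking a dsRNA value are excluded from the dsRNA summary.
    """
    sub = df[df["enzyme"] == enzyme]
    if sub.empty:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    out = {"enzyme": enzyme, "n_templates": len(sub)}
    for col, key in [
        ("dsrna_pct", "dsrna"),
        ("yield_mg_per_ml", "yield"),
        ("integrity_pct", "integrity"),
    ]:
        vals = sub[col].dropna()
        out[f"{key}_min"] = float(vals.min()) if len(vals) else None
        out[f"{key}_max"] = float(vals.max()) if len(vals) else None
        out[f"{key}_median"] = float(vals.median()) if len(vals) else None
    return out


def normalize_fluorescence(
    test: FluorescenceCurve, reference: FluorescenceCurve, mode: str = "endpoint"
) -> float:
    """Test-enzyme aptamer fluorescence as percent of the reference enzyme.

    ``endpoint`` compares the value at the final common time; ``auc``
    compares trapezoidal areas over the common time range. Curves on
    different grids are linearly interpolated.
    """
    t_lo = max(test.times[0], reference.times[0])
    t_hi = min(test.times[-1], reference.times[-1])
    if t_hi <= t_lo:
        raise ValueError("fluorescence curves do not overlap in time")
    grid = np.unique(
        np.concatenate(
            [
                test.times[(test.times >= t_lo) & (test.times <= t_hi)],
                reference.times[(reference.times >= t_lo) & (reference.times <= t_hi)],
                [t_lo, t_hi],
            ]
        )
    )
    tv = np.interp(grid, test.times, test.values)
    rv = np.interp(grid, reference.times, reference.values)
    if mode == "endpoint":
        if rv[-1] <= 0:
            raise ValueError("reference endpoint fluorescence must be positive")
        return 100.0 * tv[-1] / rv[-1]
    if mode == "auc":
        ref_auc = float(np.trapezoid(rv, grid))
        if ref_auc <= 0:
            raise ValueError("reference fluorescence area must be positive")
        return 100.0 * float(np.trapezoid(tv, grid)) / ref_auc
    raise ValueError(f"unknown mode {mode!r}")
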