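"""HPLC quantification and biotransformation outcome arithmetic.

Covers the analysis behind a THIQ synthesis campaign: external-standard
calibration curves (peak area vs concentration), product yields (directly
from product formation, or from substrate consumption when the product is
too unstable to quantify), enantiomeric excess from chiral peak areas, and
the fold-improvement in yield when the reaction is coupled to a
G6PDH NADPH-recycling system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Published retention-time windows (min) per compound on the achiral method.
RETENTION_WINDOWS = {
    "1a": 3.3, "3a": 3.6, "4a": 3.9, "5a": 5.6,
    "1b": 4.1, "3b": 4.5, "5b": 5.2,
}

#: Half-width of the retention window used for peak-to-compound assignment.
RETENTION_TOLERANCE = 0.2

#: Yields may overshoot 100% by at most this much (calibration noise).
YIELD_TOLERANCE = 5.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear external-standard response: area = slope * conc + intercept."""

    compound: str
    slope: float  # area units per mM
    intercept: float
    r2: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be positive ({self.compound})")


@dataclass(frozen=True)
class YieldResult:
    enzyme: str
    substrate: str
    mode: str  # "product_formation" | "substrate_consumption"
    yield_pct: float
    coupled: bool


@dataclass(frozen=True)
class EEResult:
    product: str
    major_isomer: str  # "R" | "S"
    ee: float

    @property
    def display(self) -> str:
        """Table formatting: values >= 99.05 print as ``>99``."""
        return ">99" if self.ee >= 99.05 else f"{self.ee:.0f}"


def fit_calibration(
    compound: str, concs_mM, areas
) -> CalibrationCurve:
    """Least-squares line through >= 3 external standards."""
    concs = np.asarray(concs_mM, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if concs.size < 3:
        raise ValueError("calibration needs at least 3 standards")
    slope, intercept = np.polyfit(concs, areas, 1)
    resid = areas - (slope * concs + intercept)
    ss_tot = float(np.sum((areas - areas.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(compound, float(slope), float(intercept), r2)


def quantify(peak_area: float, curve: CalibrationCurve):
    """Concentration (mM) from a peak area; negatives floor at 0, flagged.

    Returns ``(conc_mM, floored)``.
    """
    conc = (peak_area - curve.intercept) / curve.slope
    if conc < 0:
        return 0.0, True
    return float(conc), False


def yield_percent(
    substrate_initial_mM: float,
    product_mM: float | None = None,
    substrate_final_mM: float | None = None,
) -> float:
    """Reaction yield in percent.

    Product mode: ``100 * product / initial``. Consumption mode (used when
    the product cannot be quantified): ``100 * (1 - final / initial)``.
    Exactly one of ``product_mM`` / ``substrate_final_mM`` must be given.
    """
    if substrate_initial_mM <= 0:
        raise ValueError("initial substrate concentration must be positive")
    if (product_mM is None) == (substrate_final_mM is None):
        raise ValueError("give exactly one of product_mM or substrate_final_mM")
    if product_mM is not None:
        pct = 100.0 * product_mM / substrate_initial_mM
    else:
        if substrate_final_mM > substrate_initial_mM * (1 + YIELD_TOLERANCE / 100.0):
            raise ValueError("final substrate exceeds initial beyond tolerance")
        pct = 100.0 * (1.0 - substrate_final_mM / substrate_initial_mM)
    if pct > 100.0 + YIELD_TOLERANCE:
        raise ValueError(f"yield {pct:.1f}% overshoots 100% beyond tolerance")
    return max(0.0, pct)


def enantiomeric_excess(
    area_major: float, area_minor: float, major_isomer: str = "R", product: str = ""
) -> EEResult:
    """ee% from the two chiral peak areas."""
    if area_major < 0 or area_minor < 0:
        raise ValueError("peak areas must be non-negative")
    total = area_major + area_minor
    if total == 0:
        raise ValueError("both chiral peak areas are zero")
    ee = 100.0 * abs(area_major - area_minor) / total
    return EEResult(product=product, major_isomer=major_isomer, ee=ee)


def fold_improvement(coupled_yield: float, uncoupled_yield: float) -> float | None:
    """Yield ratio coupled/uncoupled; ``None`` when not computable."""
    if uncoupled_yield <= 0:
        return None
    return coupled_yield / uncoupled_yield


def panel_fold_range(table: pd.DataFrame):
    """(min, max) fold-improvement over a Table-2-shaped yield table.

    Expects columns ``yield_uncoupled`` and ``yield_coupled``; the range is
    reported to one decimal. Pairs with zero uncoupled yield are skipped.
    """
    folds = [
        f
        for f in (
            fold_improvement(row.yield_coupled, row.yield_uncoupled)
            for row in table.itertuples()
        )
        if f is not None
    ]
    if not folds:
        raise ValueError("no computable fold improvements")
    return round(min(folds), 1), round(max(folds), 1)


def assign_compound(retention_time: float) -> str | None:
    """Nearest retention window within the tolerance, else ``None``."""
    best, best_dist = None, RETENTION_TOLERANCE
    for compound, rt in RETENTION_WINDOWS.items():
        dist = abs(retention_time - rt)
        if dist <= best_dist:
            best, best_dist = compound, dist
    return best


def calibrate_standards(standards: pd.DataFrame) -> dict:
    """Per-compound calibration curves from a standards table.

    Expects columns ``compound``, ``conc_mM``, ``area``.
    """
    curves = {}
    for compound, grp in standards.groupby("compound"):
        curves[compound] = fit_calibration(
            compound, grp["conc_mM"].to_numpy(), grp["area"].to_numpy()
        )
    return curves


def yields_table(
    peaks: pd.DataFrame,
    standards: pd.DataFrame,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Compute a Table-2-shaped yield table from peak areas.

    ``peaks`` has columns sample, compound (or retention_time), area;
    ``design`` has one row per (enzyme, substrate, coupled) reaction with
    columns enzyme, substrate, product, mode, coupled, initial_mM, sample.
    Output: enzyme, substrate, yield_uncoupled, yield_coupled, fold.
    """
    curves = calibrate_standards(standards)
    peaks = peaks.copy()
    if "compound" not in peaks.columns:
        peaks["compound"] = peaks["retention_time"].map(assign_compound)

    def conc_of(sample: str, compound: str) -> float:
        sel = peaks[(peaks["sample"] == sample) & (peaks["compound"] == compound)]
        if sel.empty:
            raise ValueError(f"no peak for compound {compound!r} in sample {sample!r}")
        conc, _ = quantify(float(sel["area"].iloc[0]), curves[compound])
        return conc

    rows = {}
    for r in design.itertuples():
        if r.mode == "product_formation":
            pct = yield_percent(r.initial_mM, product_mM=conc_of(r.sample, r.product))
        elif r.mode == "substrate_consumption":
            pct = yield_percent(
                r.initial_mM, substrate_final_mM=conc_of(r.sample, r.substrate)
            )
        else:
            raise ValueError(f"unknown mode {r.mode!r}")
        key = (r.enzyme, r.substrate)
        rows.setdefault(key, {"enzyme": r.enzyme, "substrate": r.substrate})
        rows[key]["yield_coupled" if r.coupled else "yield_uncoupled"] = pct

    out = pd.DataFrame(sorted(rows.values(), key=lambda d: (d["enzyme"], d["substrate"])))
    for col in ("yield_uncoupled", "yield_coupled"):
        if col not in out.columns:
            out[col] = np.nan
    out["fold"] = [
        fold_improvement(c, u) if np.isfinite(c) and np.isfinite(u) else None
        for c, u in zip(out["yield_coupled"], out["yield_uncoupled"])
    ]
    return out
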