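"""Chlorophyll and carotenoid concentrations from extract absorbances.

The quantities follow the classical three-wavelength spectrophotometric
equations for 96% ethanol extracts (optical densities at 663, 646 and
470 nm):

    chl_a = 12.21*A663 - 2.81*A646
    chl_b = 20.13*A646 - 5.10*A663
    chl_total = chl_a + chl_b
    carotenoid = (1000*A470 - 3.27*chl_a - 104*chl_b) / 227

Values are reported in raw equation units (no dilution or per-fresh-weight
normalisation). Extreme absorbance ratios can yield negative concentrations;
those are returned as computed, flagged in the ``warnings`` field rather
than clamped, because the equations are linear and no clamping rule exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Equation coefficients, kept in one table for auditability.
COEFFICIENTS = {
    "chl_a": {"a663": 12.21, "a646": -2.81, "a470": 0.0},
    "chl_b": {"a663": -5.1, "a646": 20.13, "a470": 0.0},
}
CAROTENOID_DENOM = 227.0
CAROTENOID_CHLA = 3.27
CAROTENOID_CHLB = 104.0

PIGMENT_COLUMNS = ["chl_a", "chl_b", "chl_total", "carotenoid"]


@dataclass
class PigmentResult:
    chl_a: float
    chl_b: float
    chl_total: float
    carotenoid: float
    warnings: list = field(default_factory=list)


def compute_pigments(a663: float, a646: float, a470: float) -> PigmentResult:
    """Pigment concentrations for one absorbance panel."""
    panel = np.asarray([a663, a646, a470], dtype=float)
    if np.any(~np.isfinite(panel)) or np.any(panel < 0):
        raise ValidationError(f"absorbances must be finite and >= 0, got {panel.tolist()}")
    chl_a = COEFFICIENTS["chl_a"]["a663"] * a663 + COEFFICIENTS["chl_a"]["a646"] * a646
    chl_b = COEFFICIENTS["chl_b"]["a663"] * a663 + COEFFICIENTS["chl_b"]["a646"] * a646
    chl_total = chl_a + chl_b
    car = (1000.0 * a470 - CAROTENOID_CHLA * chl_a - CAROTENOID_CHLB * chl_b) / CAROTENOID_DENOM
    warnings = [
        f"negative {name} ({value:g})"
        for name, value in zip(PIGMENT_COLUMNS, (chl_a, chl_b, chl_total, car))
        if value < 0
    ]
    return PigmentResult(chl_a, chl_b, chl_total, car, warnings)


def add_pigments(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Append pigment columns to a trait table holding a663/a646/a470 columns.

    Returns the augmented table and a list of human-readable warnings for any
    negative concentrations (identified by genotype and condition).
    """
    for col in ("a663", "a646", "a470"):
        if (table[col] < 0).any():
            raise ValidationError(f"negative absorbance in column {col}")
    out = table.copy()
    out["chl_a"] = 12.21 * out["a663"] - 2.81 * out["a646"]
    out["chl_b"] = 20.13 * out["a646"] - 5.1 * out["a663"]
    out["chl_total"] = out["chl_a"] + out["chl_b"]
    out["carotenoid"] = (
        1000.0 * out["a470"] - CAROTENOID_CHLA * out["chl_a"] - CAROTENOID_CHLB * out["chl_b"]
    ) / CAROTENOID_DENOM
    warnings = []
    for col in PIGMENT_COLUMNS:
        neg = out[out[col] < 0]
        for _, row in neg.iterrows():
            warnings.append(
                f"negative {col} for genotype {int(row['genotype_id'])} ({row['condition']})"
                if "genotype_id" in out.columns
                else f"negative {col}"
            )
    return out, warnings
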