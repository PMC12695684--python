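"""Derived root-architecture traits from tube-level primary measurements.

All derived quantities follow the printed seedling-screen formulary for a
homorhizous (fibrous) root system measured destructively in sand-filled
tubes:

====================================  =============================================
trait                                 formula
====================================  =============================================
root area (cm^2)                      2 * sqrt(root_volume * pi * root_length)
root diameter (cm)                    sqrt(4 * root_fresh_weight / (root_length * pi))
specific root length (cm/g)           root_length / root_dry_weight
root length density (cm/cm^3)         root_length / soil_volume
root specific mass (g/cm^3)           root_dry_weight / soil_volume
root tissue density                   root_dry_weight * root_volume   (default; see below)
root mass density (g/cm^3)            root_fresh_weight / soil_volume
root fineness (cm/cm^3)               root_length / root_volume
root surface area density (cm^2)      root_length * root_diameter * pi
====================================  =============================================

Two deliberate reproduction switches exist. ``pi_value`` defaults to the
rounded constant 3.14 used in the source formulary (set it to ``math.pi``
for full precision). ``rtd_mode`` selects the root-tissue-density form:
``paper_multiply`` is the literal printed product dry_weight * volume
(units g*cm^3), while ``standard_divide`` is the conventional quotient
dry_weight / volume (g/cm^3).

The soil (tube) volume is a required configuration value with no default:
it is a physical property of the experiment, not a universal constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .io import MeasurementRecord, records_to_frame

PRIMARY_TRAITS = [
    "root_length",
    "root_fresh_weight",
    "root_dry_weight",
    "root_volume",
    "seedling_length",
    "seedling_fresh_weight",
    "seedling_dry_weight",
]

DERIVED_TRAITS = [
    "root_area",
    "root_diameter",
    "specific_root_length",
    "root_length_density",
    "root_specific_mass",
    "root_tissue_density",
    "root_mass_density",
    "root_fineness",
    "root_surface_area_density",
]

#: The thirteen root traits analysed downstream (group ANOVA, LDA, clustering).
ROOT_TRAITS = [
    "root_length",
    "root_fresh_weight",
    "root_volume",
    "root_dry_weight",
    "root_fineness",
    "root_diameter",
    "specific_root_length",
    "root_length_density",
    "root_specific_mass",
    "root_tissue_density",
    "root_mass_density",
    "root_surface_area_density",
    "root_area",
]

TRAIT_COLUMNS = PRIMARY_TRAITS + DERIVED_TRAITS


@dataclass(frozen=True)
class TraitConfig:
    """Configuration of the derived-trait formulary.

    soil_volume: tube (soil) volume in cm^3, required, > 0.
    pi_value: the pi constant used in area/diameter formulas (default 3.14).
    rtd_mode: 'paper_multiply' (dry weight * volume) or 'standard_divide'.
    """

    soil_volume: float
    pi_value: float = 3.14
    rtd_mode: str = "paper_multiply"

    def __post_init__(self):
        if not (self.soil_volume > 0):
            raise ValidationError("soil_volume must be > 0")
        if not (self.pi_value > 0):
            raise ValidationError("pi_value must be > 0")
        if self.rtd_mode not in ("paper_multiply", "standard_divide"):
            raise ValidationError(f"unknown rtd_mode {self.rtd_mode!r}")


def _derive_arrays(
    length: np.ndarray,
    fresh: np.ndarray,
    dry: np.ndarray,
    volume: np.ndarray,
    cfg: TraitConfig,
) -> dict[str, np.ndarray]:
    if np.any(length < 0) or np.any(fresh < 0) or np.any(dry < 0) or np.any(volume < 0):
        raise ValidationError("negative primary measurement")
    if np.any(length == 0):
        raise DomainError("root_length is 0: root_diameter and specific_root_length undefined")
    if np.any(volume == 0):
        raise DomainError("root_volume is 0: root_fineness undefined")
    if np.any(dry == 0):
        raise DomainError("root_dry_weight is 0: specific_root_length undefined")
    pi = cfg.pi_value
    diameter = np.sqrt(4.0 * fresh / (length * pi))
    out = {
        "root_area": 2.0 * np.sqrt(volume * pi * length),
        "root_diameter": diameter,
        "specific_root_length": length / dry,
        "root_length_density": length / cfg.soil_volume,
        "root_specific_mass": dry / cfg.soil_volume,
        "root_mass_density": fresh / cfg.soil_volume,
        "root_fineness": length / volume,
        "root_surface_area_density": length * diameter * pi,
    }
    if cfg.rtd_mode == "paper_multiply":
        out["root_tissue_density"] = dry * volume
    else:
        out["root_tissue_density"] = dry / volume
    return {k: out[k] for k in DERIVED_TRAITS}


def derive_traits(m: MeasurementRecord, cfg: TraitConfig) -> dict[str, float]:
    """Derived trait vector for a single tube (primary + derived values)."""
    arrays = _derive_arrays(
        np.asarray([m.root_length], dtype=float),
        np.asarray([m.root_fresh_weight], dtype=float),
        np.asarray([m.root_dry_weight], dtype=float),
        np.asarray([m.root_volume], dtype=float),
        cfg,
    )
    vec = {name: float(getattr(m, name)) for name in PRIMARY_TRAITS}
    vec.update({k: float(v[0]) for k, v in arrays.items()})
    return vec


def derive_all(records: Iterable[MeasurementRecord] | pd.DataFrame, cfg: TraitConfig) -> pd.DataFrame:
    """Trait table for a batch of tubes: one row per record.

    Keeps the design key columns (genotype_id, is_check, block, condition)
    and the absorbance columns alongside the trait values; aggregation to
    genotype x condition happens downstream (after design adjustment).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = records_to_frame(list(records))
    try:
        arrays = _derive_arrays(
            df["root_length"].to_numpy(dtype=float),
            df["root_fresh_weight"].to_numpy(dtype=float),
            df["root_dry_weight"].to_numpy(dtype=float),
            df["root_volume"].to_numpy(dtype=float),
            cfg,
        )
    except (DomainError, ValidationError) as exc:
        # re-raise with the first offending tube identified
        for _, row in df.iterrows():
            try:
                _derive_arrays(
                    np.asarray([row["root_length"]], dtype=float),
                    np.asarray([row["root_fresh_weight"]], dtype=float),
                    np.asarray([row["root_dry_weight"]], dtype=float),
                    np.asarray([row["root_volume"]], dtype=float),
                    cfg,
                )
            except (DomainError, ValidationError) as inner:
                raise type(inner)(
                    f"genotype {row['genotype_id']} block {row['block']} "
                    f"({row['condition']}): {inner}"
                ) from exc
        raise
    for name, values in arrays.items():
        df[name] = values
    return df
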