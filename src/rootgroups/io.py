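"""Domain types, CSV readers/writers and validation for tube-level measurements.

The interchange format is a plain comma-separated file (UTF-8, header row,
"." decimal mark) with one row per culture tube:

``genotype_id,is_check,block,condition,root_length_cm,root_fresh_weight_g,
root_dry_weight_g,root_volume_cm3,seedling_length_cm,seedling_fresh_weight_g,
seedling_dry_weight_g,a663,a646,a470``

Each tube carries the design coordinates of an augmented block design:
replicated check genotypes appear once in every block, unreplicated test
genotypes in exactly one block, separately per moisture condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

CONDITIONS = ("normal", "stress")

#: Measurement columns in schema order (name -> unit).
MEASUREMENT_COLUMNS = {
    "root_length": "cm",
    "root_fresh_weight": "g",
    "root_dry_weight": "g",
    "root_volume": "cm3",
    "seedling_length": "cm",
    "seedling_fresh_weight": "g",
    "seedling_dry_weight": "g",
    "a663": "",
    "a646": "",
    "a470": "",
}

#: CSV header names for the measurement columns (units suffixed where they exist).
CSV_MEASUREMENT_HEADER = {
    "root_length": "root_length_cm",
    "root_fresh_weight": "root_fresh_weight_g",
    "root_dry_weight": "root_dry_weight_g",
    "root_volume": "root_volume_cm3",
    "seedling_length": "seedling_length_cm",
    "seedling_fresh_weight": "seedling_fresh_weight_g",
    "seedling_dry_weight": "seedling_dry_weight_g",
    "a663": "a663",
    "a646": "a646",
    "a470": "a470",
}

KEY_COLUMNS = ["genotype_id", "is_check", "block", "condition"]
CSV_HEADER = KEY_COLUMNS + list(CSV_MEASUREMENT_HEADER.values())


@dataclass(frozen=True)
class DesignLayout:
    """Shape of the augmented block design.

    Checks are replicated in every block; each test genotype appears in
    exactly one block per condition, so per condition the tube count is
    ``n_blocks * (tests per block + len(check_ids))``.
    """

    n_blocks: int = 5
    check_ids: frozenset = frozenset({1, 10, 24, 34, 35, 51, 74, 104, 113})
    test_ids: frozenset = frozenset(
        i for i in range(1, 115) if i not in {1, 10, 24, 34, 35, 51, 74, 104, 113}
    )
    conditions: tuple = CONDITIONS

    def __post_init__(self):
        overlap = set(self.check_ids) & set(self.test_ids)
        if overlap:
            raise ValidationError(f"genotypes cannot be both check and test: {sorted(overlap)}")
        if self.n_blocks < 1:
            raise ValidationError("n_blocks must be >= 1")

    @property
    def n_genotypes(self) -> int:
        return len(self.check_ids) + len(self.test_ids)

    @property
    def tubes_per_condition(self) -> int:
        return len(self.test_ids) + self.n_blocks * len(self.check_ids)

    def known_ids(self) -> frozenset:
        return frozenset(self.check_ids) | frozenset(self.test_ids)


@dataclass
class MeasurementRecord:
    """One tube's primary measurements with its design coordinates.

    Weights are grams, lengths centimetres, volume cm^3; the tube value is the
    per-tube mean over the (five) plants grown in it. Absorbances are the raw
    optical densities of the ethanol extract at 663, 646 and 470 nm.
    """

    genotype_id: int
    is_check: bool
    block: int
    condition: str
    root_length: float
    root_fresh_weight: float
    root_dry_weight: float
    root_volume: float
    seedling_length: float
    seedling_fresh_weight: float
    seedling_dry_weight: float
    a663: float
    a646: float
    a470: float

    def validate(self, layout: DesignLayout | None = None) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        for name in MEASUREMENT_COLUMNS:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValidationError(f"{name} is not finite for genotype {self.genotype_id}")
            if v < 0:
                raise ValidationError(
                    f"negative {name} ({v}) for genotype {self.genotype_id}"
                )
        if self.root_dry_weight > self.root_fresh_weight:
            raise ValidationError(
                f"root_dry_weight > root_fresh_weight for genotype {self.genotype_id}"
            )
        if self.seedling_dry_weight > self.seedling_fresh_weight:
            raise ValidationError(
                f"seedling_dry_weight > seedling_fresh_weight for genotype {self.genotype_id}"
            )
        if layout is not None:
            if self.genotype_id not in layout.known_ids():
                raise SchemaError(f"unknown genotype id {self.genotype_id}")
            if not (1 <= self.block <= layout.n_blocks):
                raise DesignError(
                    f"block {self.block} outside layout range 1..{layout.n_blocks}"
                )


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    """Tabulate records, one row per tube, columns in schema order."""
    names = [f.name for f in fields(MeasurementRecord)]
    df = pd.DataFrame([[getattr(r, n) for n in names] for r in records], columns=names)
    return df


def frame_to_records(df: pd.DataFrame) -> list[MeasurementRecord]:
    names = [f.name for f in fields(MeasurementRecord)]
    return [
        MeasurementRecord(**{n: row[n] for n in names})
        for row in df[names].astype(object).to_dict("records")
    ]


def validate_design(df: pd.DataFrame, layout: DesignLayout) -> None:
    """Check the full design structure of a measurement table.

    Every check genotype must appear in every block of each condition; every
    test genotype must appear in exactly one block per condition.
    """
    for cond, sub in df.groupby("condition"):
        present = set(sub["genotype_id"])
        for cid in layout.check_ids:
            blocks = set(sub.loc[sub["genotype_id"] == cid, "block"])
            missing = set(range(1, layout.n_blocks + 1)) - blocks
            if missing:
                raise DesignError(
                    f"check {cid} absent from block(s) {sorted(missing)} in condition {cond}"
                )
        for tid in layout.test_ids:
            n = int((sub["genotype_id"] == tid).sum())
            if n != 1:
                raise DesignError(
                    f"test genotype {tid} appears {n} times in condition {cond} (expected 1)"
                )
        extra = present - layout.known_ids()
        if extra:
            raise SchemaError(f"unknown genotype ids {sorted(extra)} in condition {cond}")


def read_measurements(path: str | Path, layout: DesignLayout) -> list[MeasurementRecord]:
    """Read and validate a tube-level measurement CSV.

    Rows with any missing primary measurement are dropped with a logged
    warning (no imputation). Raises :class:`SchemaError` for header or
    genotype-id problems, :class:`ValidationError` for physically impossible
    values and :class:`DesignError` for layout violations.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing_cols = [c for c in CSV_HEADER if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {missing_cols}")
    df = df[CSV_HEADER].rename(
        columns={v: k for k, v in CSV_MEASUREMENT_HEADER.items()}
    )
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        logger.warning(
            "%s: dropped %d row(s) with missing measurements", path, n_before - len(df)
        )
    df["genotype_id"] = df["genotype_id"].astype(int)
    df["block"] = df["block"].astype(int)
    df["is_check"] = df["is_check"].astype(bool)
    bad_cond = set(df["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise SchemaError(f"{path}: unknown condition values {sorted(bad_cond)}")
    # check flags must agree with the layout
    for gid, flag in df[["genotype_id", "is_check"]].drop_duplicates().itertuples(index=False):
        if gid in layout.check_ids and not flag:
            raise SchemaError(f"{path}: genotype {gid} is a check but flagged is_check=False")
        if gid in layout.test_ids and flag:
            raise SchemaError(f"{path}: genotype {gid} is a test but flagged is_check=True")
    records = frame_to_records(df)
    for r in records:
        r.validate(layout)
    validate_design(df, layout)
    return records


def write_measurements(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    """Write tube-level records to the documented CSV schema."""
    df = records_to_frame(records).rename(columns=CSV_MEASUREMENT_HEADER)
    df.to_csv(path, index=False)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trait table as CSV (UTF-8, header, '.' decimal).

    Floats are serialised with 17 significant digits so that a write/read
    round-trip is numerically exact well beyond 12 significant digits.
    """
    table.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_table`."""
    return pd.read_csv(path, encoding="utf-8")
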