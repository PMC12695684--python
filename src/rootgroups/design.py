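"""Check-based adjustment for the augmented block design, plus the factorial
ANOVA on the replicated checks.

In an augmented block design the test genotypes are unreplicated, so block
effects cannot be separated from genotype effects using the tests alone.
The replicated check genotypes, present once in every block, estimate each
block's effect as

    effect(condition, block, trait) = mean of checks in the block
                                      - grand mean of checks over all blocks

(the classical Federer-style correction). Test observations have their
block's effect subtracted; checks get one value per condition, the
across-block mean of their corrected observations. On additive noise-free
data (y = genotype + block) the corrected test-genotype contrasts are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, DomainError
from .io import DesignLayout
from .traits import TRAIT_COLUMNS

from .pigments import PIGMENT_COLUMNS


def analysis_columns(table: pd.DataFrame) -> list[str]:
    """Trait columns present in a table, in canonical order."""
    return [c for c in TRAIT_COLUMNS + PIGMENT_COLUMNS if c in table.columns]


def estimate_block_effects(table: pd.DataFrame, layout: DesignLayout) -> pd.DataFrame:
    """Per-(condition, block, trait) block effects estimated from the checks.

    Returns a long-format frame with columns condition, block, trait, effect.
    Within each condition and trait the effects average to zero over blocks
    (the design is balanced in the checks: every check once per block).
    """
    traits = analysis_columns(table)
    checks = table[table["genotype_id"].isin(layout.check_ids)]
    rows = []
    for cond, sub in checks.groupby("condition", sort=True):
        counts = sub.groupby("block")["genotype_id"].nunique()
        expected = set(range(1, layout.n_blocks + 1))
        if set(counts.index) != expected or (counts != len(layout.check_ids)).any():
            raise DesignError(
                f"condition {cond}: checks are not fully replicated across blocks"
            )
        grand = sub[traits].mean()
        block_means = sub.groupby("block")[traits].mean()
        for block, bm in block_means.iterrows():
            for t in traits:
                rows.append((cond, int(block), t, float(bm[t] - grand[t])))
    return pd.DataFrame(rows, columns=["condition", "block", "trait", "effect"])


def adjust_augmented(
    table: pd.DataFrame, effects: pd.DataFrame, layout: DesignLayout
) -> pd.DataFrame:
    """Block-corrected genotype-level trait table.

    One row per (genotype, condition). Test genotypes: observed minus their
    block's effect. Check genotypes: across-block mean of corrected
    observations. A ``provenance`` column records which rule produced each row.
    """
    traits = analysis_columns(table)
    eff = effects.pivot_table(
        index=["condition", "block"], columns="trait", values="effect"
    )
    out_rows = []
    for cond, sub in table.groupby("condition", sort=True):
        blocks_seen = set(sub["block"])
        missing = [
            (cond, b) for b in blocks_seen if (cond, b) not in eff.index
        ]
        if missing:
            raise DesignError(f"no block-effect estimate for {missing}")
        corrected = sub.copy()
        eff_matrix = eff.loc[
            [(cond, b) for b in corrected["block"]], traits
        ].to_numpy()
        corrected[traits] = corrected[traits].to_numpy() - eff_matrix
        for gid, g in corrected.groupby("genotype_id", sort=True):
            is_check = gid in layout.check_ids
            if not is_check and len(g) != 1:
                raise DesignError(
                    f"test genotype {gid} has {len(g)} observations in {cond}"
                )
            row = {"genotype_id": int(gid), "condition": cond,
                   "is_check": bool(is_check),
                   "provenance": "check-mean" if is_check else "test-adjusted"}
            row.update(g[traits].mean().to_dict())
            out_rows.append(row)
        for gid in layout.known_ids() - set(sub["genotype_id"]):
            raise DesignError(f"genotype {gid} has no observation in condition {cond}")
    cols = ["genotype_id", "condition", "is_check", "provenance"] + traits
    return pd.DataFrame(out_rows)[cols]


def genotype_means(table: pd.DataFrame) -> pd.DataFrame:
    """Unadjusted genotype x condition means (bypass for the adjustment step)."""
    traits = analysis_columns(table)
    grouped = table.groupby(["genotype_id", "condition"], sort=True)
    out = grouped[traits].mean().reset_index()
    if "is_check" in table.columns:
        out.insert(2, "is_check", grouped["is_check"].first().to_numpy().astype(bool))
    else:
        out.insert(2, "is_check", False)
    out.insert(3, "provenance", "raw-mean")
    return out


@dataclass
class AnovaTerm:
    term: str
    df: int
    ss: float
    ms: float
    f: float
    p: float
    stars: str


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def factorial_check_anova(
    table: pd.DataFrame, layout: DesignLayout, trait: str
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA (genotype x condition) on tube-level check data.

    The check sub-design is a balanced factorial (each check in every block of
    every condition), so sums of squares are computed from cell means. The
    block replicates form the error term. Returns a table with one row per
    term: genotype, stress, genotype:stress, error, total.

    Degenerate data with zero total variation is reported with SS = 0, F = 0
    and p = 1 by convention.
    """
    checks = table[table["genotype_id"].isin(layout.check_ids)]
    counts = checks.groupby(["condition", "genotype_id"])[trait].count()
    n_rep = layout.n_blocks
    if len(counts) != len(layout.check_ids) * len(layout.conditions) or (
        counts != n_rep
    ).any():
        raise DesignError("unbalanced check data: factorial ANOVA requires full replication")
    y = checks[trait].to_numpy(dtype=float)
    n = y.size
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    geno_means = checks.groupby("genotype_id")[trait].mean()
    cond_means = checks.groupby("condition")[trait].mean()
    cell_means = checks.groupby(["genotype_id", "condition"])[trait].mean()
    a = len(geno_means)
    b = len(cond_means)
    ss_geno = n_rep * b * float(np.sum((geno_means - grand) ** 2))
    ss_cond = n_rep * a * float(np.sum((cond_means - grand) ** 2))
    ss_cells = n_rep * float(np.sum((cell_means - grand) ** 2))
    ss_inter = ss_cells - ss_geno - ss_cond
    ss_error = ss_total - ss_cells
    df_geno, df_cond = a - 1, b - 1
    df_inter = df_geno * df_cond
    df_error = n - a * b
    rows = []
    ms_error = ss_error / df_error if df_error > 0 else np.nan

    def term(name, df, ss):
        ms = ss / df if df > 0 else np.nan
        if ss_total == 0 or ms_error == 0 or not np.isfinite(ms_error):
            f, p = 0.0, 1.0
        else:
            f = ms / ms_error
            p = float(stats.f.sf(f, df, df_error))
        rows.append(AnovaTerm(name, df, ss, ms, f, p, _stars(p)))

    term("genotype", df_geno, ss_geno)
    term("stress", df_cond, ss_cond)
    term("genotype:stress", df_inter, ss_inter)
    rows.append(AnovaTerm("error", df_error, ss_error, ms_error, np.nan, np.nan, ""))
    rows.append(AnovaTerm("total", n - 1, ss_total, np.nan, np.nan, np.nan, ""))
    return pd.DataFrame([r.__dict__ for r in rows])
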