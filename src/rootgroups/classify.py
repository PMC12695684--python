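"""Nine-group root classification by the 95% confidence interval of the mean.

Per moisture condition, the population of genotype-level values of a trait
defines a Student-t confidence interval of its mean,

    mean +/- t(1 - alpha/2, n - 1) * sd / sqrt(n),

and each genotype is placed relative to that band: strictly below the lower
limit, inside the closed band, or strictly above the upper limit. Applied to
root length this yields the depth classes (superficial / semi-deep / deep);
applied to root tissue density, the density classes (non-dense / semi-dense /
dense). The two three-way splits combine into nine root groups, numbered

    group = 3 * (depth rank - 1) + density rank

with depth ranks superficial=1, semi-deep=2, deep=3 and density ranks
non-dense=1, semi-dense=2, dense=3 (so group 1 is superficial non-dense and
group 9 is deep dense, the architecture best placed for water uptake from
both shallow and deep soil layers).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ClassificationError, DomainError

DEPTH_CLASSES = ("superficial", "semi_deep", "deep")
DENSITY_CLASSES = ("non_dense", "semi_dense", "dense")

GROUP_NAMES = {
    1: "superficial non-dense",
    2: "superficial semi-dense",
    3: "superficial dense",
    4: "semi-deep non-dense",
    5: "semi-deep semi-dense",
    6: "semi-deep dense",
    7: "deep non-dense",
    8: "deep semi-dense",
    9: "deep dense",
}


@dataclass(frozen=True)
class ClassIntervals:
    """Confidence interval of the mean used as classification thresholds."""

    condition: str
    trait: str
    mean: float
    lower: float
    upper: float
    n: int
    alpha: float = 0.05


def compute_ci(values, alpha: float = 0.05, condition: str = "", trait: str = "") -> ClassIntervals:
    """Student-t confidence interval of the mean of ``values``.

    Uses the sample standard deviation (n-1 denominator); requires n >= 2.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError(f"need at least 2 values for a confidence interval, got {x.size}")
    if np.any(~np.isfinite(x)):
        raise DomainError("values must be finite")
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = float(stats.t.ppf(1 - alpha / 2, x.size - 1)) * sd / np.sqrt(x.size)
    return ClassIntervals(condition, trait, mean, mean - half, mean + half, int(x.size), alpha)


def _three_way(value: float, ci: ClassIntervals, classes: tuple[str, str, str]) -> str:
    if value < ci.lower:
        return classes[0]
    if value > ci.upper:
        return classes[2]
    return classes[1]  # closed middle interval


def group_index(depth_class: str, density_class: str) -> int:
    return 3 * DEPTH_CLASSES.index(depth_class) + DENSITY_CLASSES.index(density_class) + 1


def classify_genotypes(
    adjusted: pd.DataFrame,
    alpha: float = 0.05,
    depth_trait: str = "root_length",
    density_trait: str = "root_tissue_density",
) -> pd.DataFrame:
    """Assign every genotype a depth class, density class and group per condition.

    ``adjusted`` must hold one row per (genotype_id, condition) with the two
    classification traits. Confidence intervals are computed per condition
    from that condition's genotype values only.
    """
    for col in ("genotype_id", "condition", depth_trait, density_trait):
        if col not in adjusted.columns:
            raise ClassificationError(f"missing column {col!r} in adjusted table")
    if adjusted[[depth_trait, density_trait]].isna().any().any():
        bad = adjusted.loc[
            adjusted[[depth_trait, density_trait]].isna().any(axis=1), "genotype_id"
        ].tolist()
        raise ClassificationError(f"missing trait value for genotype(s) {bad}")
    dup = adjusted.duplicated(["genotype_id", "condition"])
    if dup.any():
        raise ClassificationError(
            f"duplicate rows for {adjusted.loc[dup, 'genotype_id'].tolist()}"
        )
    rows = []
    for cond, sub in adjusted.groupby("condition", sort=True):
        ci_depth = compute_ci(sub[depth_trait], alpha, cond, depth_trait)
        ci_density = compute_ci(sub[density_trait], alpha, cond, density_trait)
        for _, r in sub.iterrows():
            d = _three_way(r[depth_trait], ci_depth, DEPTH_CLASSES)
            dn = _three_way(r[density_trait], ci_density, DENSITY_CLASSES)
            rows.append(
                {
                    "genotype_id": int(r["genotype_id"]),
                    "condition": cond,
                    "depth_class": d,
                    "density_class": dn,
                    "group_index": group_index(d, dn),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GroupTally:
    """3x3 genotype counts (depth x density) with marginals for one condition."""

    condition: str
    counts: pd.DataFrame  # index DEPTH_CLASSES, columns DENSITY_CLASSES

    @property
    def depth_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1).to_numpy()

    @property
    def density_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0).to_numpy()

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def group_counts(self) -> dict[int, int]:
        return {
            group_index(d, dn): int(self.counts.loc[d, dn])
            for d in DEPTH_CLASSES
            for dn in DENSITY_CLASSES
        }


def tally_groups(assignments: pd.DataFrame, condition: str) -> GroupTally:
    """Count genotypes per depth x density cell for one condition."""
    sub = assignments[assignments["condition"] == condition]
    counts = pd.DataFrame(0, index=list(DEPTH_CLASSES), columns=list(DENSITY_CLASSES))
    for _, r in sub.iterrows():
        counts.loc[r["depth_class"], r["density_class"]] += 1
    return GroupTally(condition, counts)


def stability_report(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype group transition between the two conditions.

    Returns one row per genotype with its normal and stress group indices and
    a ``changed`` flag; genotypes must be classified under both conditions.
    """
    by_cond = {
        cond: sub.set_index("genotype_id")
        for cond, sub in assignments.groupby("condition")
    }
    if set(by_cond) != {"normal", "stress"}:
        raise ClassificationError(
            f"need both conditions classified, got {sorted(by_cond)}"
        )
    normal, stress = by_cond["normal"], by_cond["stress"]
    only = set(normal.index) ^ set(stress.index)
    if only:
        raise ClassificationError(f"genotype(s) {sorted(only)} present in only one condition")
    rows = []
    for gid in sorted(normal.index):
        gn = int(normal.loc[gid, "group_index"])
        gs = int(stress.loc[gid, "group_index"])
        rows.append(
            {
                "genotype_id": int(gid),
                "normal_group": gn,
                "stress_group": gs,
                "changed": gn != gs,
            }
        )
    return pd.DataFrame(rows)


def load_reference_classification() -> pd.DataFrame:
    """Published nine-group classification of the 114-genotype wild barley panel.

    The bundled fixture lists, for each genotype, the reported depth and
    density classes under both moisture conditions; it is used to validate
    the tally and stability machinery against the published counts.
    Returns an assignment frame in the same format as :func:`classify_genotypes`.
    """
    ref = resources.files("rootgroups.data").joinpath("reference_classification.csv")
    with resources.as_file(ref) as path:
        wide = pd.read_csv(path)
    rows = []
    for _, r in wide.iterrows():
        for cond in ("normal", "stress"):
            d = r[f"{cond}_depth"]
            dn = r[f"{cond}_density"]
            rows.append(
                {
                    "genotype_id": int(r["genotype_id"]),
                    "condition": cond,
                    "depth_class": d,
                    "density_class": dn,
                    "group_index": group_index(d, dn),
                }
            )
    return pd.DataFrame(rows)
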