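"""Group-level statistics for the nine root groups.

Covers the downstream analyses of the classification: one-way fixed-effects
ANOVA of each trait across the groups with LSD mean separation, canonical
discriminant analysis in the pooled within-group scatter convention (the
SPSS-style analysis whose eigenvalue lambda maps to a canonical correlation
sqrt(lambda / (1 + lambda))), optional Wilks-lambda stepwise variable
selection, Pearson correlation matrices with 5%/1% significance flags, and
Ward minimum-variance clustering of standardized group profiles with Newick
export.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import DomainError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# one-way ANOVA + LSD
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    trait: str
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ms_between: float
    ms_within: float
    f: float
    p: float
    stars: str


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def oneway_group_anova(values, groups, trait: str = "") -> AnovaTable:
    """One-way fixed-effects ANOVA of genotype-level values across groups.

    At the full design scale (9 groups, 114 genotypes) the degrees of freedom
    are (8, 105). Zero total variation is reported as F = 0, p = 1.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape:
        raise DomainError("values and groups must have equal length")
    labels, inverse = np.unique(g, return_inverse=True)
    k = len(labels)
    n = y.size
    if k < 2:
        raise DomainError("need at least 2 non-empty groups")
    if n <= k:
        raise DomainError("need more observations than groups")
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    group_means = np.array([y[inverse == i].mean() for i in range(k)])
    group_sizes = np.array([(inverse == i).sum() for i in range(k)])
    ss_between = float(np.sum(group_sizes * (group_means - grand) ** 2))
    ss_within = ss_total - ss_between
    df_b, df_w = k - 1, n - k
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ss_total == 0 or ms_w == 0:
        f, p = 0.0, 1.0
    else:
        f = ms_b / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaTable(trait, df_b, df_w, ss_between, ss_within, ms_b, ms_w, f, p, _stars(p))


def lsd_compare(
    group_means: dict, group_sizes: dict, anova: AnovaTable, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise least-significant-difference comparisons after an ANOVA.

    LSD(i, j) = t(1 - alpha/2, df_within) * sqrt(ms_within * (1/n_i + 1/n_j));
    a pair is significant iff |mean_i - mean_j| strictly exceeds its LSD.
    """
    if not anova.ms_within > 0:
        raise DomainError("ms_within must be > 0 for LSD comparisons")
    tcrit = float(stats.t.ppf(1 - alpha / 2, anova.df_within))
    rows = []
    for gi, gj in itertools.combinations(sorted(group_means), 2):
        lsd = tcrit * np.sqrt(anova.ms_within * (1 / group_sizes[gi] + 1 / group_sizes[gj]))
        diff = abs(group_means[gi] - group_means[gj])
        rows.append(
            {
                "group_i": gi,
                "group_j": gj,
                "mean_diff": group_means[gi] - group_means[gj],
                "lsd": float(lsd),
                "significant": bool(diff > lsd),
                "alpha": alpha,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# canonical discriminant analysis
# ---------------------------------------------------------------------------

def canonical_correlation_from_eigenvalue(lam) -> float | np.ndarray:
    """Canonical correlation implied by a discriminant eigenvalue.

    In the pooled within-group scatter convention each discriminant
    eigenvalue lambda (between-to-within variance ratio of its canonical
    scores) corresponds to the canonical correlation
    r = sqrt(lambda / (1 + lambda)).
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise DomainError("discriminant eigenvalues must be >= 0")
    r = np.sqrt(lam / (1.0 + lam))
    return float(r) if r.ndim == 0 else r


@dataclass
class DiscriminantModel:
    """Canonical discriminant analysis summary.

    eigenvalues: between/within variance ratios, descending.
    pct_variance / cumulative_pct: percent of the discriminating variance.
    canonical_correlations: sqrt(lambda / (1 + lambda)) per function.
    raw_coef: unstandardized coefficients (within-group score variance 1).
    std_coef: coefficients for variables standardized by pooled within sd.
    structure_matrix: pooled within-group correlations variable x function.
    centroids: group means of the canonical scores (grand-centred).
    """

    variables: list
    group_labels: list
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    cumulative_pct: np.ndarray
    canonical_correlations: np.ndarray
    raw_coef: np.ndarray
    std_coef: np.ndarray
    structure_matrix: np.ndarray
    centroids: np.ndarray
    scores: np.ndarray
    warnings: list = field(default_factory=list)

    @property
    def n_functions(self) -> int:
        return len(self.eigenvalues)


def canonical_lda(X, labels, variables=None, ridge: float = 1e-8) -> DiscriminantModel:
    """Canonical discriminant analysis of a trait matrix grouped by labels.

    Solves the generalized eigenproblem Sb v = lambda Sw v where Sw is the
    pooled within-group scatter and Sb the between-group scatter. If Sw is
    singular, a ridge of ``ridge * trace(Sw)/p`` is added to its diagonal
    (logged in ``warnings``). At most min(groups - 1, variables) functions
    are retained.
    """
    X = np.asarray(X, dtype=float)
    g = np.asarray(labels)
    n, p = X.shape
    if variables is None:
        variables = [f"var{i}" for i in range(p)]
    glabels, inverse = np.unique(g, return_inverse=True)
    k = len(glabels)
    if k < 2:
        raise DomainError("need at least 2 groups")
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for i in range(k):
        Xi = X[inverse == i]
        mi = Xi.mean(axis=0)
        D = Xi - mi
        Sw += D.T @ D
        d = (mi - grand)[:, None]
        Sb += len(Xi) * (d @ d.T)
    warnings = []
    Sw_used = Sw
    sw_eigs = np.linalg.eigvalsh(Sw)
    if sw_eigs[0] <= 1e-10 * max(sw_eigs[-1], 1.0):
        eps = ridge * np.trace(Sw) / p
        if eps == 0:
            eps = ridge
        Sw_used = Sw + eps * np.eye(p)
        warnings.append(f"singular within-group scatter: ridge {eps:g} added")
        logger.warning(warnings[-1])
    evals, evecs = linalg.eigh(Sb, Sw_used)
    order = np.argsort(evals)[::-1]
    m = min(k - 1, p)
    evals = np.clip(evals[order][:m], 0.0, None)
    V = evecs[:, order][:, :m]
    # scale so canonical scores have pooled within-group variance 1
    df_w = n - k
    for j in range(m):
        s2 = V[:, j] @ Sw_used @ V[:, j] / df_w
        if s2 > 0:
            V[:, j] = V[:, j] / np.sqrt(s2)
    scores = (X - grand) @ V
    total = evals.sum()
    pct = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    centroids = np.vstack([scores[inverse == i].mean(axis=0) for i in range(k)])
    # pooled within-group correlations between variables and scores
    within_var = np.array([Sw[i, i] / df_w for i in range(p)])
    Swx = np.zeros((p, m))
    for i in range(k):
        Xi = X[inverse == i]
        Si = scores[inverse == i]
        Swx += (Xi - Xi.mean(axis=0)).T @ (Si - Si.mean(axis=0))
    score_within_var = np.array(
        [V[:, j] @ Sw @ V[:, j] / df_w for j in range(m)]
    )
    denom = np.sqrt(np.outer(within_var, score_within_var)) * df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        structure = np.where(denom > 0, Swx / denom, 0.0)
    std_coef = V * np.sqrt(within_var)[:, None]
    return DiscriminantModel(
        variables=list(variables),
        group_labels=list(glabels),
        eigenvalues=evals,
        pct_variance=pct,
        cumulative_pct=np.cumsum(pct),
        canonical_correlations=canonical_correlation_from_eigenvalue(evals),
        raw_coef=V,
        std_coef=std_coef,
        structure_matrix=structure,
        centroids=centroids,
        scores=scores,
        warnings=warnings,
    )


def _wilks_lambda(X, inverse, k, cols) -> float:
    """Wilks' lambda det(Sw)/det(St) for the variable subset ``cols``."""
    Xs = X[:, cols]
    grand = Xs.mean(axis=0)
    St = (Xs - grand).T @ (Xs - grand)
    Sw = np.zeros_like(St)
    for i in range(k):
        Xi = Xs[inverse == i]
        D = Xi - Xi.mean(axis=0)
        Sw += D.T @ D
    det_t = linalg.det(np.atleast_2d(St))
    det_w = linalg.det(np.atleast_2d(Sw))
    if det_t <= 0:
        return 1.0
    return max(det_w / det_t, 0.0)


def stepwise_select(
    X, labels, f_enter: float = 3.84, f_remove: float = 2.71, variables=None
) -> list:
    """Greedy Wilks-lambda stepwise variable selection for discriminant analysis.

    At each step the candidate with the largest partial F enters if its
    partial F >= f_enter; entered variables whose partial F falls below
    f_remove are removed. Terminates because each entry requires a strict
    improvement of Wilks' lambda.
    """
    X = np.asarray(X, dtype=float)
    g = np.asarray(labels)
    n, p = X.shape
    if variables is None:
        variables = list(range(p))
    glabels, inverse = np.unique(g, return_inverse=True)
    k = len(glabels)
    selected: list[int] = []

    def partial_f(lam_old: float, lam_new: float, q: int) -> float:
        # F for the change in Wilks' lambda after adding the (q+1)-th variable
        if lam_new <= 0:
            return np.inf
        ratio = lam_old / lam_new
        df2 = n - k - q
        if df2 <= 0:
            return 0.0
        return (ratio - 1.0) * df2 / (k - 1)

    lam_cur = 1.0
    while True:
        changed = False
        # entry step
        best_j, best_f, best_lam = None, -np.inf, None
        for j in range(p):
            if j in selected:
                continue
            lam_new = _wilks_lambda(X, inverse, k, selected + [j])
            if lam_new >= lam_cur - 1e-12:  # no strict improvement (collinear copy)
                continue
            fj = partial_f(lam_cur, lam_new, len(selected))
            if fj > best_f:
                best_j, best_f, best_lam = j, fj, lam_new
        if best_j is not None and best_f >= f_enter:
            selected.append(best_j)
            lam_cur = best_lam
            changed = True
        # removal step
        removed = True
        while removed and len(selected) > 1:
            removed = False
            for j in list(selected):
                rest = [s for s in selected if s != j]
                lam_rest = _wilks_lambda(X, inverse, k, rest)
                fj = partial_f(lam_rest, lam_cur, len(rest))
                if fj < f_remove:
                    selected = rest
                    lam_cur = lam_rest
                    removed = True
                    changed = True
                    break
        if not changed:
            break
    return [variables[j] for j in selected]


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    flags: pd.DataFrame  # '', '*', '**'
    warnings: list = field(default_factory=list)


def pearson_correlation_matrix(table: pd.DataFrame, traits=None) -> CorrelationMatrix:
    """Pairwise Pearson correlations over genotype-level values.

    Two-sided p from the t distribution with n-2 df. Zero-variance traits
    yield NaN correlations for their pairs, recorded as warnings.
    """
    if traits is None:
        traits = [c for c in table.columns if table[c].dtype.kind in "fc"]
    X = table[traits].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise DomainError("need at least 3 rows for correlation p-values")
    sd = X.std(axis=0, ddof=1)
    warnings = [f"zero-variance trait {t}: correlations undefined"
                for t, s in zip(traits, sd) if s == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    for i, s in enumerate(sd):  # zero variance: undefined, keep NaN off-diagonal
        if s == 0:
            R[i, :] = np.nan
            R[:, i] = np.nan
            R[i, i] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = R * np.sqrt((n - 2) / np.clip(1.0 - R**2, 1e-300, None))
        P = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    np.fill_diagonal(P, 0.0)
    flags = np.where(P < 0.01, "**", np.where(P < 0.05, "*", ""))
    flags = np.where(np.isnan(P), "", flags)
    idx = pd.Index(traits)
    return CorrelationMatrix(
        r=pd.DataFrame(R, index=idx, columns=idx),
        p=pd.DataFrame(P, index=idx, columns=idx),
        flags=pd.DataFrame(flags, index=idx, columns=idx),
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

@dataclass
class DendrogramNode:
    """Binary dendrogram node; ``members`` is the sorted tuple of leaf labels."""

    members: tuple
    height: float
    children: tuple = ()  # () for leaves

    @property
    def is_leaf(self) -> bool:
        return not self.children


def ward_cluster(profiles: pd.DataFrame, standardize: bool = True) -> DendrogramNode:
    """Agglomerative Ward minimum-variance clustering of row profiles.

    Traits are z-scored across rows first (so heterogeneous units contribute
    comparably), distances are Euclidean, and the Lance-Williams recurrence
    updates squared distances; reported merge heights are the square roots
    (Ward.D2 convention). Ties are broken deterministically by the
    lexicographically smallest pair of sorted member tuples, which makes the
    result invariant to input row order.
    """
    if len(profiles) < 2:
        raise DomainError("need at least 2 profiles to cluster")
    X = profiles.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    labels = list(profiles.index)
    nodes = {i: DendrogramNode((labels[i],), 0.0) for i in range(len(labels))}
    sizes = {i: 1 for i in range(len(labels))}
    d2 = {}
    for i, j in itertools.combinations(range(len(labels)), 2):
        d2[(i, j)] = float(np.sum((X[i] - X[j]) ** 2))
    active = set(range(len(labels)))
    next_id = len(labels)

    def key(i, j):
        return (i, j) if i < j else (j, i)

    while len(active) > 1:
        # minimal distance with deterministic lexicographic tie-break
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            dij = d2[key(i, j)]
            tag = tuple(sorted((nodes[i].members, nodes[j].members)))
            if best is None or dij < best[0] - 1e-12 or (
                abs(dij - best[0]) <= 1e-12 and tag < best[1]
            ):
                best = (dij, tag, i, j)
        dij, _, i, j = best
        ni, nj = sizes[i], sizes[j]
        merged = DendrogramNode(
            tuple(sorted(nodes[i].members + nodes[j].members)),
            float(np.sqrt(dij)),
            (nodes[i], nodes[j]),
        )
        for m in active - {i, j}:
            nm = sizes[m]
            dim, djm = d2[key(i, m)], d2[key(j, m)]
            d2[key(next_id, m)] = (
                (ni + nm) * dim + (nj + nm) * djm - nm * dij
            ) / (ni + nj + nm)
        active -= {i, j}
        active.add(next_id)
        nodes[next_id] = merged
        sizes[next_id] = ni + nj
        next_id += 1
    return nodes[next_id - 1]


def merge_table(root: DendrogramNode) -> pd.DataFrame:
    """Flatten a dendrogram into a merge table (children member sets, height)."""
    rows = []

    def walk(node):
        if node.is_leaf:
            return
        a, b = node.children
        walk(a)
        walk(b)
        rows.append(
            {
                "left": "|".join(map(str, a.members)),
                "right": "|".join(map(str, b.members)),
                "height": node.height,
            }
        )

    walk(root)
    rows.sort(key=lambda r: (r["height"], r["left"], r["right"]))
    return pd.DataFrame(rows)


def cut_tree(root: DendrogramNode, k: int) -> dict:
    """Cut the dendrogram into k clusters (remove the k-1 highest merges).

    Returns {leaf label: cluster label}; cluster labels are the smallest
    member of each cluster, so they are stable across runs and row orders.
    """
    n_leaves = len(root.members)
    if not 1 <= k <= n_leaves:
        raise DomainError(f"k must be in 1..{n_leaves}, got {k}")
    clusters = [root]
    # repeatedly split the cluster whose top merge is highest
    while len(clusters) < k:
        splittable = [c for c in clusters if not c.is_leaf]
        target = max(splittable, key=lambda c: (c.height, c.members))
        clusters.remove(target)
        clusters.extend(target.children)
    out = {}
    for c in clusters:
        lab = min(c.members)
        for m in c.members:
            out[m] = lab
    return out


def to_newick(root: DendrogramNode) -> str:
    """Serialise a dendrogram to Newick with branch lengths = height drops."""

    def fmt(node, parent_height):
        bl = max(parent_height - node.height, 0.0)
        if node.is_leaf:
            return f"{node.members[0]}:{bl:.10g}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner}):{bl:.10g}"

    a, b = root.children
    return f"({fmt(a, root.height)},{fmt(b, root.height)});"
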