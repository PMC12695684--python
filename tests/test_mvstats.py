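import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats
from scipy.cluster import hierarchy

from rootgroups.errors import DomainError
from rootgroups.mvstats import (
    canonical_correlation_from_eigenvalue,
    canonical_lda,
    cut_tree,
    lsd_compare,
    merge_table,
    oneway_group_anova,
    pearson_correlation_matrix,
    stepwise_select,
    to_newick,
    ward_cluster,
)


# --- one-way ANOVA ----------------------------------------------------------

def brute_force_anova(values, groups):
    """Direct mean-decomposition oracle."""
    y = np.asarray(values, float)
    g = np.asarray(groups)
    grand = y.mean()
    ss_b = sum(
        (y[g == lab].mean() - grand) ** 2 * (g == lab).sum() for lab in np.unique(g)
    )
    ss_w = sum(((y[g == lab] - y[g == lab].mean()) ** 2).sum() for lab in np.unique(g))
    return ss_b, ss_w


def test_oneway_matches_bruteforce_and_scipy():
    rng = np.random.default_rng(12)
    y = rng.normal(0, 1, 12)
    g = np.repeat([1, 2, 3], 4)
    at = oneway_group_anova(y, g)
    ss_b, ss_w = brute_force_anova(y, g)
    assert at.ss_between == pytest.approx(ss_b, rel=1e-10)
    assert at.ss_within == pytest.approx(ss_w, rel=1e-10)
    f_ref, p_ref = stats.f_oneway(*(y[g == lab] for lab in (1, 2, 3)))
    assert at.f == pytest.approx(f_ref, rel=1e-10)
    assert at.p == pytest.approx(p_ref, rel=1e-10)


def test_oneway_paper_shape_df():
    """Nine groups over 114 genotypes give df = (8, 105)."""
    rng = np.random.default_rng(13)
    g = np.repeat(np.arange(1, 10), [10, 5, 4, 25, 28, 10, 7, 20, 5])
    at = oneway_group_anova(rng.normal(size=114), g)
    assert (at.df_between, at.df_within) == (8, 105)


def test_oneway_partition_identity_random():
    rng = np.random.default_rng(14)
    for _ in range(100):
        n = rng.integers(8, 40)
        k = rng.integers(2, 5)
        g = rng.integers(0, k, n)
        if len(np.unique(g)) < 2 or n <= len(np.unique(g)):
            continue
        y = rng.normal(size=n)
        at = oneway_group_anova(y, g)
        ss_total = ((y - y.mean()) ** 2).sum()
        assert at.ss_between + at.ss_within == pytest.approx(ss_total, rel=1e-9)


def test_oneway_degenerate_constant():
    at = oneway_group_anova([3.0] * 9, [1, 1, 1, 2, 2, 2, 3, 3, 3])
    assert at.ss_between == 0.0 and at.f == 0.0 and at.p == 1.0


# --- LSD --------------------------------------------------------------------

def test_lsd_hand_computed_three_groups():
    rng = np.random.default_rng(15)
    y = np.concatenate([rng.normal(0, 1, 5), rng.normal(1, 1, 5), rng.normal(5, 1, 5)])
    g = np.repeat([1, 2, 3], 5)
    at = oneway_group_anova(y, g)
    means = {lab: y[g == lab].mean() for lab in (1, 2, 3)}
    sizes = {lab: 5 for lab in (1, 2, 3)}
    table = lsd_compare(means, sizes, at, alpha=0.05)
    tcrit = stats.t.ppf(0.975, at.df_within)
    for _, r in table.iterrows():
        lsd = tcrit * np.sqrt(at.ms_within * (2 / 5))
        assert r["lsd"] == pytest.approx(lsd, rel=1e-10)
        assert r["significant"] == (abs(r["mean_diff"]) > lsd)


def test_lsd_equal_means_not_significant():
    at = oneway_group_anova([1.0, 2.0, 1.0, 2.0], [1, 1, 2, 2])
    table = lsd_compare({1: 1.5, 2: 1.5}, {1: 2, 2: 2}, at)
    assert not table["significant"].any()


def test_lsd_boundary_is_strict():
    at = oneway_group_anova([0.0, 2.0, 0.0, 2.0], [1, 1, 2, 2])
    tcrit = stats.t.ppf(0.975, at.df_within)
    lsd = tcrit * np.sqrt(at.ms_within * (2 / 2))
    table = lsd_compare({1: 0.0, 2: lsd}, {1: 2, 2: 2}, at)
    assert not table["significant"].iloc[0]  # |diff| == LSD is not significant


# --- canonical discriminant analysis ---------------------------------------

def brute_force_lda_eigs(X, g):
    """Independent oracle: explicit scatter matrices + generic solver."""
    X = np.asarray(X, float)
    labs = np.unique(g)
    grand = X.mean(axis=0)
    p = X.shape[1]
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for lab in labs:
        Xi = X[np.asarray(g) == lab]
        mi = Xi.mean(axis=0)
        Sw += (Xi - mi).T @ (Xi - mi)
        Sb += len(Xi) * np.outer(mi - grand, mi - grand)
    evals = linalg.eigvals(np.linalg.solve(Sw, Sb))
    evals = np.sort(np.real(evals))[::-1]
    return evals[: min(len(labs) - 1, p)]


def test_lda_eigen_matches_bruteforce_small_fixture():
    rng = np.random.default_rng(16)
    X = rng.normal(size=(12, 1)) + np.repeat([0.0, 3.0], 6)[:, None]
    g = np.repeat([0, 1], 6)
    model = canonical_lda(X, g)
    ref = brute_force_lda_eigs(X, g)
    assert model.eigenvalues[0] == pytest.approx(ref[0], rel=1e-10)


def test_lda_identical_group_means_zero_eigenvalues():
    rng = np.random.default_rng(17)
    base = rng.normal(size=(6, 3))
    X = np.vstack([base, base])  # two groups with identical composition
    g = np.repeat([0, 1], 6)
    model = canonical_lda(X, g)
    assert np.all(model.eigenvalues <= 1e-12)


def test_lda_random_instances_match_oracle():
    """Eigenvalues agree with the brute-force generalized-eigenvalue oracle."""
    rng = np.random.default_rng(18)
    for _ in range(100):
        n = int(rng.integers(12, 41))
        p = int(rng.integers(1, 6))
        k = int(rng.integers(2, 5))
        g = rng.integers(0, k, n)
        while len(np.unique(g)) < k or np.min(np.bincount(g, minlength=k)) < 2:
            g = rng.integers(0, k, n)
        X = rng.normal(size=(n, p)) + g[:, None] * rng.normal(0, 1, p)
        model = canonical_lda(X, g)
        ref = brute_force_lda_eigs(X, g)
        assert np.allclose(model.eigenvalues, np.clip(ref, 0, None),
                           rtol=1e-8, atol=1e-10)
        sizes = np.bincount(g)[np.array(model.group_labels)]
        wmean = (model.centroids * sizes[:, None]).sum(axis=0) / sizes.sum()
        assert np.max(np.abs(wmean)) <= 1e-8
        r = model.canonical_correlations
        assert np.allclose(r**2 * (1 + model.eigenvalues), model.eigenvalues, atol=1e-9)


def test_lda_variance_percentages_and_structure_shape():
    rng = np.random.default_rng(19)
    X = rng.normal(size=(40, 4)) + np.repeat(np.arange(4), 10)[:, None]
    model = canonical_lda(X, np.repeat(np.arange(4), 10))
    assert model.pct_variance.sum() == pytest.approx(100.0, abs=0.1)
    assert model.structure_matrix.shape == (4, 3)
    assert np.all(np.abs(model.structure_matrix) <= 1 + 1e-9)
    assert np.all(np.diff(model.eigenvalues) <= 1e-12)


def test_printed_eigenvalue_correlation_pairs():
    """The lambda -> r mapping reproduces the published discriminant summary."""
    pairs = {5.599: 0.921, 2.899: 0.862, 0.946: 0.697,
             7.173: 0.937, 3.026: 0.867, 0.599: 0.612}
    for lam, r in pairs.items():
        assert round(canonical_correlation_from_eigenvalue(lam), 3) == r


def test_lda_singular_ridge_fallback():
    rng = np.random.default_rng(20)
    x = rng.normal(size=(12, 1))
    X = np.hstack([x, 2 * x])  # exactly collinear
    model = canonical_lda(X, np.repeat([0, 1], 6))
    assert model.warnings  # ridge applied and logged


# --- stepwise ---------------------------------------------------------------

def test_stepwise_picks_separating_variable_first():
    rng = np.random.default_rng(22)
    g = np.repeat([0, 1, 2], 15)
    signal = g * 5.0 + rng.normal(0, 1, 45)
    noise = rng.normal(size=(45, 3))
    X = np.column_stack([noise[:, 0], signal, noise[:, 1:]])
    sel = stepwise_select(X, g, variables=["n1", "sig", "n2", "n3"])
    assert sel[0] == "sig"


def test_stepwise_infinite_threshold_selects_nothing():
    rng = np.random.default_rng(23)
    X = rng.normal(size=(30, 3))
    assert stepwise_select(X, np.repeat([0, 1], 15), f_enter=np.inf) == []


def test_stepwise_duplicate_variable_never_enters():
    rng = np.random.default_rng(24)
    g = np.repeat([0, 1], 20)
    x = g * 3.0 + rng.normal(0, 1, 40)
    X = np.column_stack([x, x])  # exact copy
    sel = stepwise_select(X, g, variables=["a", "a_copy"])
    assert sel == ["a"]


# --- correlations -------------------------------------------------------------

def test_correlation_self_and_collinear():
    rng = np.random.default_rng(25)
    df = pd.DataFrame({"x": rng.normal(size=20)})
    df["y"] = 3.0 * df["x"]  # positive scalar multiple
    df["z"] = rng.normal(size=20)
    cm = pearson_correlation_matrix(df)
    assert cm.r.loc["x", "x"] == 1.0
    assert cm.r.loc["x", "y"] == pytest.approx(1.0, abs=1e-12)
    assert cm.flags.loc["x", "y"] == "**"


def test_correlation_hand_computed_five_points():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([1.0, 3.0, 2.0, 4.0, 5.0])
    r_hand = np.corrcoef(x, y)[0, 1]
    cm = pearson_correlation_matrix(pd.DataFrame({"x": x, "y": y}))
    assert cm.r.loc["x", "y"] == pytest.approx(r_hand, abs=1e-12)
    t_ref, p_ref = stats.pearsonr(x, y)
    assert cm.p.loc["x", "y"] == pytest.approx(p_ref, rel=1e-9)


def test_correlation_matrix_psd_and_symmetric():
    rng = np.random.default_rng(26)
    df = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("abcdef"))
    cm = pearson_correlation_matrix(df)
    R = cm.r.to_numpy()
    assert np.allclose(R, R.T, atol=1e-12)
    assert np.min(np.linalg.eigvalsh(R)) >= -1e-10


def test_correlation_zero_variance_flagged():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
    cm = pearson_correlation_matrix(df)
    assert cm.warnings
    assert np.isnan(cm.r.loc["x", "c"])


# --- Ward clustering ---------------------------------------------------------

def triplet_profiles():
    rng = np.random.default_rng(27)
    centers = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0]])
    pts = np.vstack([c + rng.normal(0, 0.5, (3, 2)) for c in centers])
    return pd.DataFrame(pts, index=[f"g{i}" for i in range(9)])


def test_ward_recovers_planted_triplets():
    profiles = triplet_profiles()
    root = ward_cluster(profiles, standardize=True)
    labels = cut_tree(root, 3)
    clusters = {}
    for leaf, lab in labels.items():
        clusters.setdefault(lab, set()).add(leaf)
    expected = [{f"g{i}" for i in range(j, j + 3)} for j in (0, 3, 6)]
    assert sorted(map(sorted, clusters.values())) == sorted(map(sorted, expected))


def test_ward_identical_profiles_merge_at_zero():
    df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]], index=list("abc"))
    root = ward_cluster(df, standardize=False)
    mt = merge_table(root)
    assert mt["height"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_ward_monotone_heights_random():
    rng = np.random.default_rng(28)
    for _ in range(100):
        n = int(rng.integers(3, 12))
        df = pd.DataFrame(rng.normal(size=(n, 3)))
        mt = merge_table(ward_cluster(df))
        h = mt["height"].to_numpy()
        assert np.all(np.diff(h) >= -1e-10)


def test_ward_matches_scipy_linkage_heights():
    """Cross-check merge heights against scipy's ward linkage."""
    rng = np.random.default_rng(29)
    df = pd.DataFrame(rng.normal(size=(10, 4)))
    mt = merge_table(ward_cluster(df, standardize=False))
    Z = hierarchy.linkage(df.to_numpy(), method="ward")
    assert np.allclose(np.sort(mt["height"].to_numpy()), np.sort(Z[:, 2]), rtol=1e-8)


def test_ward_row_permutation_invariance():
    rng = np.random.default_rng(30)
    df = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"r{i}" for i in range(8)])
    base = cut_tree(ward_cluster(df), 3)
    for _ in range(5):
        perm = df.iloc[rng.permutation(8)]
        assert cut_tree(ward_cluster(perm), 3) == base


def test_cut_tree_extremes_and_newick():
    df = triplet_profiles()
    root = ward_cluster(df)
    assert len(set(cut_tree(root, 9).values())) == 9
    assert len(set(cut_tree(root, 1).values())) == 1
    with pytest.raises(DomainError):
        cut_tree(root, 0)
    nwk = to_newick(root)
    assert nwk.endswith(";") and nwk.count("(") == nwk.count(")")
    # newick leaves match the profile labels
    import re

    leaves = set(re.findall(r"g\d+", nwk))
    assert leaves == set(df.index)


def test_ward_requires_two_profiles():
    with pytest.raises(DomainError):
        ward_cluster(pd.DataFrame([[1.0, 2.0]]))
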