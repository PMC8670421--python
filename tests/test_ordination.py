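"""PCA, predictor selection, tb-RDA, variance partitioning, PERMANOVA and
Ward.D2 clustering, each against closed-form identities or an independent
implementation (scikit-bio PERMANOVA; R vegan for the RDA fractions)."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from stratiscope.io_model import StratiscopeError
from stratiscope.normalize import TransformedMatrix, hellinger
from stratiscope.ordination import (
    hierarchical_clusters,
    pca,
    permanova,
    prepare_env,
    rda,
    select_env_variables,
    variance_partition,
)


def as_tm(arr, tag="hellinger"):
    arr = np.asarray(arr, dtype=float)
    return TransformedMatrix(
        pd.DataFrame(arr, index=[f"o{i}" for i in range(arr.shape[0])],
                     columns=[f"s{j}" for j in range(arr.shape[1])]),
        tag,
    )


def env_frame(arrays, names):
    n = len(arrays[0])
    df = pd.DataFrame(dict(zip(names, arrays)))
    df["sample_id"] = [f"s{j}" for j in range(n)]
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_rank_one_data_single_axis():
    base = np.array([1.0, 2.0, 3.0, 4.0])
    tm = as_tm(np.column_stack([base, 2 * base, 3 * base, 0.5 * base]))
    res = pca(tm)
    assert res.explained_fraction[0] == pytest.approx(1.0)


def test_pca_reconstruction_identity():
    rng = np.random.default_rng(0)
    y = rng.normal(size=(15, 8))
    tm = as_tm(y)
    res = pca(tm)
    centered = y.T - y.T.mean(axis=0)
    recon = res.sample_scores.to_numpy() @ res.variable_loadings.to_numpy().T
    assert np.abs(recon - centered).max() < 1e-8
    # explained fractions = eigenvalues / trace, to 1e-10
    total = (centered**2).sum() / (centered.shape[0] - 1)
    assert np.allclose(res.explained_fraction, res.eigenvalues / total, atol=1e-10)
    assert (np.diff(res.explained_fraction) <= 1e-12).all()


def test_pca_separates_synthetic_strata(default_dataset):
    from stratiscope.normalize import abundance_filter

    cm = abundance_filter(default_dataset.counts)
    res = pca(hellinger(cm))
    strata = default_dataset.truth.sample_strata.set_index("sample_id")
    scores = res.sample_scores["PC1"]
    surface = scores[strata["stratum_depth2"] == "surface"]
    deep = scores[strata["stratum_depth2"] == "deep"]
    assert (surface.max() < deep.min()) or (deep.max() < surface.min())


def test_pca_requires_two_samples():
    with pytest.raises(StratiscopeError):
        pca(as_tm([[1.0], [2.0]]))


# ---------------------------------------------------------------------------
# Predictor selection
# ---------------------------------------------------------------------------

def test_duplicated_variable_dropped():
    rng = np.random.default_rng(1)
    a = rng.normal(size=10)
    b = rng.normal(size=10)
    meta = env_frame([a, a.copy(), b], ["v1", "v1_dup", "v2"])
    kept = select_env_variables(meta, candidates=["v1", "v1_dup", "v2"])
    assert "v2" in kept and len(kept) == 2


def test_orthogonal_variables_all_retained():
    n = 8
    basis = np.linalg.qr(np.random.default_rng(2).normal(size=(n, 3)))[0]
    meta = env_frame([basis[:, 0], basis[:, 1], basis[:, 2]], ["v1", "v2", "v3"])
    kept = select_env_variables(meta, candidates=["v1", "v2", "v3"])
    assert kept == ["v1", "v2", "v3"]


def test_constant_variable_dropped_with_warning():
    rng = np.random.default_rng(3)
    meta = env_frame([np.ones(8), rng.normal(size=8)], ["const", "v"])
    kept = select_env_variables(meta, candidates=["const", "v"])
    assert kept == ["v"]


def brute_force_min_removals(env, r_max, vif_max):
    """Smallest removal sets leaving all |r| < r_max and VIF < vif_max."""
    from stratiscope.ordination import _vif

    cols = list(env.columns)
    for n_keep in range(len(cols), 0, -1):
        survivors = []
        for keep in itertools.combinations(cols, n_keep):
            sub = env[list(keep)].to_numpy()
            if len(keep) > 1:
                corr = np.corrcoef(sub, rowvar=False)
                np.fill_diagonal(corr, 0)
                if np.abs(corr).max() >= r_max:
                    continue
                if np.nanmax(_vif(sub)) >= vif_max:
                    continue
            survivors.append(set(keep))
        if survivors:
            return survivors
    return []


def test_selection_matches_exhaustive_minimal_removal():
    """The greedy survivor set is one of the maximal admissible sets found
    by exhaustive search over removal orders."""
    rng = np.random.default_rng(4)
    z = rng.normal(size=12)
    arrays = [
        z + rng.normal(0, 0.05, 12),      # collinear block
        z + rng.normal(0, 0.05, 12),
        -z + rng.normal(0, 0.05, 12),
        rng.normal(size=12),
        rng.normal(size=12),
    ]
    names = ["c1", "c2", "c3", "f1", "f2"]
    meta = env_frame(arrays, names)
    kept = set(select_env_variables(meta, candidates=names))
    best = brute_force_min_removals(prepare_env(meta, names), 0.9, 10.0)
    assert kept in best


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

def test_rda_noiseless_limit():
    rng = np.random.default_rng(5)
    x = rng.normal(size=16)
    y = np.outer(rng.normal(size=10), x)  # response exactly linear in x
    tm = as_tm(y)
    meta = env_frame([x, rng.normal(size=16)], ["driver", "noise"])
    res, tests = rda(tm, meta, ["driver", "noise"], n_permutations=99, seed=0)
    assert res.constrained_fraction == pytest.approx(1.0)
    marg = tests[(tests.family == "margin") & (tests.term == "driver")]
    assert marg["p_value"].iloc[0] == pytest.approx(1 / 100)


def test_rda_rejects_overparameterized_model():
    rng = np.random.default_rng(6)
    tm = as_tm(rng.normal(size=(5, 4)))
    meta = env_frame([rng.normal(size=4) for _ in range(4)], list("abcd"))
    with pytest.raises(StratiscopeError, match="predictors"):
        rda(tm, meta, list("abcd"), n_permutations=9)


def test_rda_permutation_reproducibility_and_p_floor():
    rng = np.random.default_rng(7)
    tm = as_tm(rng.normal(size=(12, 10)))
    meta = env_frame([rng.normal(size=10), rng.normal(size=10)], ["a", "b"])
    _, t1 = rda(tm, meta, ["a", "b"], n_permutations=49, seed=3)
    _, t2 = rda(tm, meta, ["a", "b"], n_permutations=49, seed=3)
    pd.testing.assert_frame_equal(t1, t2)
    assert (t1["p_value"] >= 1 / 50).all()
    # Holm never decreases a p-value
    assert (t1["p_adjusted"] >= t1["p_value"] - 1e-12).all()


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_rda_fractions_match_vegan(tmp_path):
    """Constrained R2, adjusted R2 and leading eigenvalues agree with vegan's
    rda() on a shared fixture."""
    rng = np.random.default_rng(8)
    n, p = 12, 8
    x = rng.normal(size=(n, 3))
    y = x @ rng.normal(size=(3, p)) * 0.5 + rng.normal(size=(n, p))
    np.savetxt(tmp_path / "Y.csv", y, delimiter=",")
    np.savetxt(tmp_path / "X.csv", x, delimiter=",")
    tm = as_tm(y.T)
    meta = env_frame([x[:, 0], x[:, 1], x[:, 2]], ["v1", "v2", "v3"])
    res, _ = rda(tm, meta, ["v1", "v2", "v3"], n_permutations=9, seed=0)
    vp = variance_partition(tm, meta, ["v1", "v2", "v3"])
    script = f"""
    suppressMessages(library(vegan))
    Y <- as.matrix(read.csv("{tmp_path}/Y.csv", header=FALSE))
    X <- as.data.frame(scale(read.csv("{tmp_path}/X.csv", header=FALSE)))
    colnames(X) <- c("v1","v2","v3")
    m <- rda(Y ~ v1 + v2 + v3, data=X)
    v <- varpart(Y, ~v1, ~v2, ~v3, data=X)
    cat(RsquareAdj(m)$r.squared, RsquareAdj(m)$adj.r.squared,
        m$CCA$eig[1:2], v$part$indfract$Adj.R.square[1:3], sep="\\n")
    """
    out = subprocess.run(["Rscript", "-"], input=script, text=True,
                         capture_output=True, check=True)
    vals = [float(v) for v in out.stdout.split()]
    assert res.constrained_fraction == pytest.approx(vals[0], abs=1e-6)
    assert res.adjusted_r2 == pytest.approx(vals[1], abs=1e-6)
    assert res.eigenvalues[:2] == pytest.approx(vals[2:4], abs=1e-6)
    assert vp.unique.loc[["v1", "v2", "v3"]].to_numpy() == pytest.approx(
        vals[4:7], abs=1e-6
    )


# ---------------------------------------------------------------------------
# Variance partitioning
# ---------------------------------------------------------------------------

def test_varpart_orthogonal_predictors():
    # large n: the adjusted-R2 penalty difference between submodels (the only
    # source of nonzero "shared" here) decays as (1 - R2)/n
    n = 40
    rng = np.random.default_rng(9)
    basis = np.linalg.qr(rng.normal(size=(n, 2)))[0]
    y = (np.outer(rng.normal(size=6), basis[:, 0])
         + np.outer(rng.normal(size=6), basis[:, 1])
         + 0.1 * rng.normal(size=(6, n)))
    tm = as_tm(y)
    meta = env_frame([basis[:, 0], basis[:, 1]], ["a", "b"])
    vp = variance_partition(tm, meta, ["a", "b"])
    shared = vp.atoms.loc[vp.atoms.subset == "a & b", "fraction"].iloc[0]
    assert abs(shared) < 0.05
    assert vp.atoms["fraction"].sum() == pytest.approx(vp.total_adjusted_r2, abs=1e-6)


def test_varpart_duplicated_predictor_is_all_shared():
    rng = np.random.default_rng(10)
    x = rng.normal(size=14)
    y = np.outer(rng.normal(size=6), x) + 0.2 * rng.normal(size=(6, 14))
    tm = as_tm(y)
    meta = env_frame([x, x + 1e-9 * rng.normal(size=14)], ["a", "b"])
    vp = variance_partition(tm, meta, ["a", "b"])
    assert abs(vp.unique["a"]) < 0.02 and abs(vp.unique["b"]) < 0.02
    shared = vp.atoms.loc[vp.atoms.subset == "a & b", "fraction"].iloc[0]
    assert shared == pytest.approx(vp.total_adjusted_r2, abs=0.02)


def test_varpart_additive_on_random_designs():
    rng = np.random.default_rng(11)
    for _ in range(20):
        y = rng.normal(size=(7, 12))
        arrays = [rng.normal(size=12) for _ in range(3)]
        tm = as_tm(y)
        meta = env_frame(arrays, ["a", "b", "c"])
        vp = variance_partition(tm, meta, ["a", "b", "c"])
        assert vp.atoms["fraction"].sum() == pytest.approx(
            vp.total_adjusted_r2, abs=1e-6
        )


def test_varpart_variable_count_limits():
    rng = np.random.default_rng(12)
    tm = as_tm(rng.normal(size=(5, 12)))
    arrays = [rng.normal(size=12) for _ in range(5)]
    meta = env_frame(arrays, list("abcde"))
    with pytest.raises(StratiscopeError, match="2-4"):
        variance_partition(tm, meta, list("abcde"))
    with pytest.raises(StratiscopeError, match="2-4"):
        variance_partition(tm, meta, ["a"])


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def test_permanova_agrees_with_skbio():
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(13)
    y = rng.normal(size=(9, 14))
    tm = as_tm(y.T)
    groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    got = permanova(tm, pd.Series(groups, index=tm.sample_ids),
                    n_permutations=99, seed=0)
    from scipy.spatial.distance import pdist, squareform

    dm = skbio_distance.DistanceMatrix(squareform(pdist(y)), ids=tm.sample_ids)
    ref = skbio_distance.permanova(dm, grouping=groups, permutations=99)
    assert got["pseudo_f"] == pytest.approx(ref["test statistic"], abs=1e-9)


def test_permanova_separated_clusters():
    rng = np.random.default_rng(14)
    y = np.vstack([rng.normal(0, 0.05, size=(5, 10)),
                   rng.normal(8, 0.05, size=(5, 10))])
    tm = as_tm(y.T)
    groups = pd.Series(["a"] * 5 + ["b"] * 5, index=tm.sample_ids)
    got = permanova(tm, groups, n_permutations=199, seed=1)
    # permutations reproducing the same 5|5 partition tie the F statistic
    # (probability 2/C(10,5) each), so p sits at its effective floor
    assert got["p_value"] <= 4 / 200
    assert got["r2"] > 0.99


def test_permanova_r2_bounds_and_errors():
    rng = np.random.default_rng(15)
    for _ in range(20):
        y = rng.normal(size=(8, 6))
        tm = as_tm(y.T)
        groups = pd.Series(rng.permutation(["a"] * 4 + ["b"] * 4),
                           index=tm.sample_ids)
        got = permanova(tm, groups, n_permutations=19, seed=0)
        assert 0.0 <= got["r2"] <= 1.0
    bad = pd.Series(["a"] * 7 + ["b"], index=tm.sample_ids)
    with pytest.raises(StratiscopeError, match="singleton"):
        permanova(tm, bad, n_permutations=19)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def test_ward_merge_heights_non_decreasing(default_dataset):
    from stratiscope.normalize import abundance_filter

    cm = abundance_filter(default_dataset.counts)
    res = hierarchical_clusters(hellinger(cm))
    heights = res.linkage_matrix[:, 2]
    assert (np.diff(heights) >= -1e-9).all()


def test_clustering_recovers_surface_deep_partition(default_dataset):
    from sklearn.metrics import adjusted_rand_score

    from stratiscope.normalize import abundance_filter

    cm = abundance_filter(default_dataset.counts)
    res = hierarchical_clusters(hellinger(cm))
    strata = default_dataset.truth.sample_strata.set_index("sample_id")
    truth2 = strata.loc[res.sample_ids, "stratum_depth2"]
    ari = adjusted_rand_score(truth2, res.labels_for(2))
    assert ari >= 0.9
    assert res.chosen_k in range(2, 9)


def test_clustering_k_range_capped_at_n_minus_one():
    rng = np.random.default_rng(16)
    tm = as_tm(rng.normal(size=(6, 4)))
    res = hierarchical_clusters(tm, k_range=range(2, 20))
    assert res.silhouette["k"].max() <= 3
    with pytest.raises(StratiscopeError):
        hierarchical_clusters(as_tm(rng.normal(size=(6, 2))))


def test_clustering_four_programmed_strata():
    """With a strong month effect at every depth, the k=4 cut recovers the
    month x depth-layer partition."""
    from sklearn.metrics import adjusted_rand_score

    from stratiscope.normalize import abundance_filter
    from stratiscope.synthetic_data import SyntheticConfig, default_taxa, generate_dataset

    taxa = default_taxa()
    for i, t in enumerate(taxa):  # amplify month contrasts
        t.september_factor = 2.0 if i % 2 else 0.5
    ds = generate_dataset(SyntheticConfig(taxa=taxa, seed=7))
    cm = abundance_filter(ds.counts)
    res = hierarchical_clusters(hellinger(cm))
    strata = ds.truth.sample_strata.set_index("sample_id")
    truth4 = strata.loc[res.sample_ids, "stratum_month_depth4"]
    ari = adjusted_rand_score(truth4, res.labels_for(4))
    assert ari >= 0.8
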