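"""Multivariate community statistics on Hellinger-transformed counts.

Transformation-based ordination sensu Legendre & Gallagher: the Hellinger
transform makes Euclidean geometry appropriate for sparse count data, after
which ordinary PCA / redundancy analysis (RDA) / Euclidean PERMANOVA /
Ward.D2 clustering apply.

The RDA here is the classical least-squares constrained ordination: the
sample x ORF response matrix is column-centered, projected onto the span of
standardized environmental predictors, and the fitted matrix is
eigen-decomposed.  Inference is by free permutation of sample rows (Monte
Carlo), with Holm's correction within each test family (axes; marginal
variable tests) and Ezekiel's adjusted R^2.  Variance partitioning
decomposes the full-model adjusted R^2 into unique and shared fractions
over all predictor subsets (partial-RDA inclusion-exclusion), additive by
construction.

Environmental predictors below the NH4+ detection limit are substituted
with a small value (0.001) before standardization, matching standard
practice for censored nutrient data in constrained ordination.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from stratiscope.io_model import ENV_COLUMNS, StratiscopeError
from stratiscope.normalize import TransformedMatrix

logger = logging.getLogger(__name__)

NH4_SUBSTITUTE = 0.001


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    method: str                      # "PCA" or "RDA"
    sample_scores: pd.DataFrame      # samples x axes
    variable_loadings: pd.DataFrame  # ORFs (PCA) or predictors (RDA) x axes
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray   # per axis, of total variance
    constrained_fraction: float | None = None
    adjusted_r2: float | None = None


@dataclass
class VariancePartition:
    """Unique/shared adjusted-R^2 fractions over predictor subsets."""

    atoms: pd.DataFrame              # subset label -> exclusive fraction
    unique: pd.Series                # per single variable
    total_adjusted_r2: float


@dataclass
class ClusteringResult:
    linkage_matrix: np.ndarray
    sample_ids: list
    chosen_k: int
    labels: pd.Series                # at chosen_k
    elbow: pd.DataFrame              # k, within_ss
    silhouette: pd.DataFrame         # k, mean_silhouette

    def labels_for(self, k: int) -> pd.Series:
        lab = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(lab, index=self.sample_ids, name=f"k{k}")


# ---------------------------------------------------------------------------
# Environmental predictor preparation and selection
# ---------------------------------------------------------------------------

def prepare_env(
    metadata: pd.DataFrame, variables=None, nh4_substitute: float = NH4_SUBSTITUTE
) -> pd.DataFrame:
    """Standardized (z-score) predictor matrix, one row per sample.

    NH4+ values flagged below the detection limit are replaced with
    ``nh4_substitute`` before standardization.
    """
    if variables is None:
        variables = [c for c in ENV_COLUMNS if c in metadata.columns]
    env = metadata[list(variables)].astype(float).copy()
    if "nh4_uM" in env.columns and "nh4_below_detection" in metadata.columns:
        env.loc[metadata["nh4_below_detection"].astype(bool), "nh4_uM"] = nh4_substitute
    sd = env.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.warning("dropping constant environmental variable(s): %s", constant)
        env = env.drop(columns=constant)
        sd = sd.drop(constant)
    return (env - env.mean()) / sd


def select_env_variables(
    metadata: pd.DataFrame,
    candidates=None,
    r_max: float = 0.9,
    vif_max: float = 10.0,
) -> list[str]:
    """Greedy collinearity pruning: pairwise |r| < r_max, then VIF < vif_max.

    While any pair correlates at |r| >= r_max, the member of the worst pair
    with the larger mean |r| to the other variables is dropped; then the
    largest-VIF variable is dropped until all VIFs are below the cap.
    Deterministic (ties fall to the later column in the candidate order).
    """
    env = prepare_env(metadata, candidates)
    cols = list(env.columns)
    if len(cols) < 2:
        return cols
    while len(cols) > 1:
        corr = env[cols].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        if corr.max() < r_max:
            break
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        mean_r = corr.mean(axis=0) * len(cols) / (len(cols) - 1)
        drop = cols[i] if mean_r[i] > mean_r[j] else cols[j]
        logger.info("dropping %s (pairwise |r|=%.3f)", drop, corr[i, j])
        cols.remove(drop)
    while len(cols) > 1:
        vifs = _vif(env[cols].to_numpy())
        if np.nanmax(vifs) < vif_max:
            break
        drop = cols[int(np.nanargmax(vifs))]
        logger.info("dropping %s (VIF=%.1f)", drop, np.nanmax(vifs))
        cols.remove(drop)
    return cols


def _vif(x: np.ndarray) -> np.ndarray:
    """Variance inflation factors from the correlation-matrix inverse."""
    corr = np.corrcoef(x, rowvar=False)
    try:
        return np.diag(np.linalg.inv(corr))
    except np.linalg.LinAlgError:
        return np.diag(np.linalg.pinv(corr))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(tm: TransformedMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal components of the sample x ORF transformed matrix.

    Samples are observations; ORF columns are centered; scores are in
    principal coordinates (U·S) and loadings are the orthonormal ORF axes.
    """
    y = tm.values.to_numpy(dtype=float).T
    n = y.shape[0]
    if n < 2:
        raise StratiscopeError("PCA needs at least 2 samples")
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    k = min(n - 1, yc.shape[1]) if n_axes is None else n_axes
    u, s, vt = u[:, :k], s[:k], vt[:k]
    eig = s**2 / (n - 1)
    total = (yc**2).sum() / (n - 1)
    axes = [f"PC{i + 1}" for i in range(k)]
    return OrdinationResult(
        method="PCA",
        sample_scores=pd.DataFrame(u * s, index=tm.sample_ids, columns=axes),
        variable_loadings=pd.DataFrame(vt.T, index=tm.orf_ids, columns=axes),
        eigenvalues=eig,
        explained_fraction=eig / total if total > 0 else eig,
    )


# ---------------------------------------------------------------------------
# RDA with permutation inference
# ---------------------------------------------------------------------------

def _fit_ss(q: np.ndarray, y: np.ndarray) -> float:
    proj = q.T @ y
    return float((proj**2).sum())


def rda(
    tm: TransformedMatrix,
    metadata: pd.DataFrame,
    selected_vars: list[str],
    n_permutations: int = 999,
    seed: int = 0,
    test_axes: bool = True,
    test_margins: bool = True,
) -> tuple[OrdinationResult, pd.DataFrame]:
    """Constrained ordination of the transformed matrix on predictors.

    Returns the ordination result and a tidy permutation-test table with
    one row per test (family ``global`` / ``axis`` / ``margin``), raw and
    Holm-adjusted p-values.  Marginal tests are Type-III style: each
    variable's added sum of squares given all others.
    """
    y = tm.values.to_numpy(dtype=float).T
    n = y.shape[0]
    env = prepare_env(metadata.loc[tm.sample_ids], selected_vars)
    missing = [v for v in selected_vars if v not in env.columns]
    if missing:
        raise StratiscopeError(f"predictor(s) dropped as constant: {missing}")
    x = env.to_numpy(dtype=float)
    m = x.shape[1]
    if m > n - 1:
        raise StratiscopeError(f"{m} predictors for {n} samples (need m <= n-1)")
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    q_full = np.linalg.qr(xc)[0]
    ss_tot = float((yc**2).sum())
    fitted = q_full @ (q_full.T @ yc)
    ss_fit = float((fitted**2).sum())
    ss_res = ss_tot - ss_fit
    df_res = n - m - 1
    r2 = ss_fit / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_res

    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    k = int((s > s[0] * 1e-9).sum()) if s.size and s[0] > 0 else 0
    u, s, vt = u[:, :k], s[:k], vt[:k]
    axes = [f"RDA{i + 1}" for i in range(k)]
    eig = s**2 / (n - 1)
    # predictor loadings: correlation of predictors with site scores
    site_scores = u * s
    with np.errstate(invalid="ignore"):
        loadings = np.array(
            [[_safe_corr(xc[:, j], site_scores[:, a]) for a in range(k)]
             for j in range(m)]
        )
    result = OrdinationResult(
        method="RDA",
        sample_scores=pd.DataFrame(site_scores, index=tm.sample_ids, columns=axes),
        variable_loadings=pd.DataFrame(loadings, index=env.columns, columns=axes),
        eigenvalues=eig,
        explained_fraction=(s**2) / ss_tot,
        constrained_fraction=r2,
        adjusted_r2=adj_r2,
    )

    # permutation inference: free permutation of sample rows of Y
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_permutations)]
    rows = []

    if ss_tot <= 0:
        raise StratiscopeError("constant response matrix")
    tiny = 1e-12 * ss_tot  # floor for the residual mean square (noiseless limit)
    f_obs = (ss_fit / m) / max(ss_res / df_res, tiny)
    exceed = 0
    axis_stats = np.zeros((n_permutations, k))
    for i, perm in enumerate(perms):
        yp = yc[perm]
        ssf = _fit_ss(q_full, yp)
        fp = (ssf / m) / max((ss_tot - ssf) / df_res, tiny)
        if fp >= f_obs:
            exceed += 1
        if test_axes and k:
            sp = np.linalg.svd(q_full @ (q_full.T @ yp), compute_uv=False)
            axis_stats[i, :] = (sp[:k] ** 2) / (n - 1)
    p_global = (1 + exceed) / (n_permutations + 1)
    rows.append(("global", "model", f_obs, p_global))

    if test_axes and k:
        for a in range(k):
            p = (1 + int((axis_stats[:, a] >= eig[a]).sum())) / (n_permutations + 1)
            rows.append(("axis", axes[a], eig[a], p))

    if test_margins and m > 1:
        # Freedman-Lane: permute the residuals of the reduced model, keeping
        # its fitted part, so the tested variable's added SS is compared
        # against a null that preserves the other predictors' signal
        for j, v in enumerate(env.columns):
            q_red = np.linalg.qr(np.delete(xc, j, axis=1))[0]
            fit_red = q_red @ (q_red.T @ yc)
            res_red = yc - fit_red
            ss_marg = ss_fit - _fit_ss(q_red, yc)
            f_v = (ss_marg / 1) / max(ss_res / df_res, tiny)
            exceed = 0
            for perm in perms:
                ystar = fit_red + res_red[perm]
                ssf = _fit_ss(q_full, ystar)
                ssm = ssf - _fit_ss(q_red, ystar)
                fp = ssm / max((float((ystar**2).sum()) - ssf) / df_res, tiny)
                if fp >= f_v:
                    exceed += 1
            rows.append(("margin", v, f_v, (1 + exceed) / (n_permutations + 1)))

    tests = pd.DataFrame(rows, columns=["family", "term", "statistic", "p_value"])
    tests["p_adjusted"] = tests["p_value"]
    for fam in ("axis", "margin"):
        mask = tests["family"] == fam
        if mask.sum():
            tests.loc[mask, "p_adjusted"] = multipletests(
                tests.loc[mask, "p_value"], method="holm"
            )[1]
    tests["n_permutations"] = n_permutations
    tests["seed"] = seed
    return result, tests


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _adjusted_r2(yc: np.ndarray, xc: np.ndarray) -> float:
    n, m = xc.shape
    if m > n - 1:
        raise StratiscopeError("more predictors than samples - 1")
    q = np.linalg.qr(xc)[0]
    ss_tot = float((yc**2).sum())
    r2 = _fit_ss(q, yc) / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def variance_partition(
    tm: TransformedMatrix, metadata: pd.DataFrame, variables: list[str]
) -> VariancePartition:
    """Partition the full-model adjusted R^2 into Venn-diagram fractions.

    For every nonempty subset T of predictors, the exclusive fraction
    attributable to exactly T is obtained by inclusion-exclusion over the
    adjusted R^2 of submodels; fractions sum to the full-model adjusted R^2
    identically.  Limited to 2-4 predictors (2^4 subsets), matching typical
    partition plots.
    """
    if not 2 <= len(variables) <= 4:
        raise StratiscopeError("variance partition supports 2-4 variables")
    y = tm.values.to_numpy(dtype=float).T
    yc = y - y.mean(axis=0)
    env = prepare_env(metadata.loc[tm.sample_ids], variables)
    if list(env.columns) != list(variables):
        raise StratiscopeError("a requested variable was dropped as constant")
    xall = env.to_numpy(dtype=float)
    xall = xall - xall.mean(axis=0)
    v = list(variables)

    def f(subset: frozenset) -> float:
        if not subset:
            return 0.0
        idx = [v.index(s) for s in sorted(subset, key=v.index)]
        return _adjusted_r2(yc, xall[:, idx])

    full = frozenset(v)
    # exclusive Venn fractions: c(T) = sum_{U subset T} (-1)^(|T|-|U|+1) f(V\U),
    # the Moebius inversion of f(V) - f(V\W) = sum_{T subset W} c(T)
    atoms = {}
    for size in range(1, len(v) + 1):
        for t in itertools.combinations(v, size):
            t = frozenset(t)
            val = 0.0
            for usize in range(len(t) + 1):
                for usub in itertools.combinations(sorted(t, key=v.index), usize):
                    sign = (-1) ** (len(t) - usize + 1)
                    val += sign * f(full - frozenset(usub))
            atoms[t] = val
    labels = {
        t: " & ".join(sorted(t, key=v.index)) + (" (unique)" if len(t) == 1 else "")
        for t in atoms
    }
    atom_df = pd.DataFrame(
        {"subset": [labels[t] for t in atoms], "fraction": list(atoms.values())}
    )
    unique = pd.Series(
        {next(iter(t)): frac for t, frac in atoms.items() if len(t) == 1}
    )
    return VariancePartition(
        atoms=atom_df, unique=unique, total_adjusted_r2=f(full)
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def permanova(
    data, grouping, n_permutations: int = 999, seed: int = 0
) -> dict:
    """One-way PERMANOVA on Euclidean distances between samples.

    ``data`` is a :class:`TransformedMatrix` (columns = samples; Euclidean
    distances computed on the transposed matrix, i.e. on Hellinger space)
    or a precomputed square distance DataFrame.  ``grouping`` maps sample
    id to group label.  Returns pseudo-F, R^2 = SS_between/SS_total and the
    permutation p-value.
    """
    if isinstance(data, TransformedMatrix):
        samples = data.sample_ids
        y = data.values.to_numpy(dtype=float).T
        d2 = _sq_euclidean(y)
    else:
        samples = list(data.index)
        d2 = np.asarray(data, dtype=float) ** 2
    labels = pd.Series(grouping).loc[samples].to_numpy()
    uniq, inv = np.unique(labels, return_inverse=True)
    sizes = np.bincount(inv)
    if len(uniq) < 2:
        raise StratiscopeError("need at least 2 groups")
    if (sizes < 2).any():
        raise StratiscopeError(
            f"singleton group {uniq[np.argmin(sizes)]!r} not allowed"
        )
    n, a = len(samples), len(uniq)

    def stat(inv_labels):
        ss_w = 0.0
        for g in range(a):
            mask = inv_labels == g
            ss_w += d2[np.ix_(mask, mask)].sum() / (2.0 * mask.sum())
        return ss_w

    ss_t = d2.sum() / (2.0 * n)
    ss_w = stat(inv)
    ss_a = ss_t - ss_w
    f_obs = (ss_a / (a - 1)) / (ss_w / (n - a))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(inv)
        ss_w_p = stat(perm)
        f_p = ((ss_t - ss_w_p) / (a - 1)) / (ss_w_p / (n - a))
        if f_p >= f_obs:
            exceed += 1
    return {
        "pseudo_f": float(f_obs),
        "r2": float(ss_a / ss_t),
        "p_value": (1 + exceed) / (n_permutations + 1),
        "n_permutations": n_permutations,
        "seed": seed,
        "groups": dict(zip(uniq.tolist(), sizes.tolist())),
    }


def _sq_euclidean(y: np.ndarray) -> np.ndarray:
    sq = (y**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (y @ y.T)
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


# ---------------------------------------------------------------------------
# Hierarchical clustering (Ward.D2)
# ---------------------------------------------------------------------------

def hierarchical_clusters(
    tm: TransformedMatrix,
    k_range=range(2, 9),
    scale: bool = True,
) -> ClusteringResult:
    """Ward.D2 clustering of samples with elbow and silhouette diagnostics.

    The Hellinger matrix is optionally ORF-wise standardized ("scaled"),
    distances are Euclidean, and the linkage is Ward.D2 (squared distances
    inside the Lance-Williams update; scipy's ``ward``).  ``chosen_k``
    maximizes the mean silhouette; the elbow (within-cluster SS) curve is
    reported but not used for the automatic choice.
    """
    y = tm.values.to_numpy(dtype=float).T
    n = y.shape[0]
    if n < 3:
        raise StratiscopeError("clustering needs at least 3 samples")
    if scale:
        sd = y.std(axis=0, ddof=1)
        constant = sd == 0
        if constant.any():
            logger.warning("dropping %d constant ORF(s) before scaling",
                           int(constant.sum()))
            y = y[:, ~constant]
            sd = sd[~constant]
        y = (y - y.mean(axis=0)) / sd
    z = linkage(y, method="ward")
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise StratiscopeError("k_range leaves no valid k (need 2 <= k <= n-1)")
    elbow_rows, sil_rows = [], []
    best_k, best_sil = ks[0], -np.inf
    labels_by_k = {}
    for k in ks:
        lab = fcluster(z, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        within = 0.0
        for g in np.unique(lab):
            pts = y[lab == g]
            within += ((pts - pts.mean(axis=0)) ** 2).sum()
        elbow_rows.append((k, within))
        sil = silhouette_score(y, lab) if len(np.unique(lab)) > 1 else np.nan
        sil_rows.append((k, sil))
        if sil > best_sil:
            best_k, best_sil = k, sil
    return ClusteringResult(
        linkage_matrix=z,
        sample_ids=tm.sample_ids,
        chosen_k=best_k,
        labels=pd.Series(labels_by_k[best_k], index=tm.sample_ids, name="cluster"),
        elbow=pd.DataFrame(elbow_rows, columns=["k", "within_ss"]),
        silhouette=pd.DataFrame(sil_rows, columns=["k", "mean_silhouette"]),
    )
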