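"""Multivariate integration of chemical and biological soil variables.

The standardized (z-scored) feature matrix combines per-replicate enzyme
stoichiometry and microbial parameters with group-level soil chemistry
broadcast to replicates.  On that matrix the module provides:

* PCA on the correlation (z-scored) matrix with a deterministic sign
  convention, plus a per-component univariate test battery
  (Shapiro-Wilk, Levene, one-way ANOVA, Tukey HSD, Kruskal-Wallis, Dunn);
* k-means clustering of ordination scores with purity against the group
  labels;
* Spearman rank correlation matrices with p-values;
* VIF screening of candidate environmental variables followed by
  redundancy analysis (RDA) with seeded permutation tests (global model,
  axes, sequential terms) and the Ezekiel adjusted R^2;
* PERMANOVA on Euclidean distances with the (1+b)/(1+B) permutation
  p-value convention and a companion homogeneity-of-dispersion test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from sklearn.cluster import KMeans
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "FEATURE_VARIABLES",
    "FeatureMatrix",
    "OrdinationResult",
    "RdaResult",
    "PermanovaResult",
    "zscore",
    "assemble_features",
    "pca",
    "component_tests",
    "kmeans_clusters",
    "spearman_matrix",
    "vif_screen",
    "rda",
    "permanova",
]

#: The 25 integrated variables, in canonical order.
FEATURE_VARIABLES = (
    "CE", "NE", "PE", "CE_NE", "CE_PE", "NE_PE", "VL", "VA", "AF", "SE",
    "TOC", "TN", "PS", "CaS", "KS", "MgS", "NaS", "CEC", "pH",
    "TOC_TN", "TOC_PS", "TN_PS", "MR", "MBC", "MBN",
)

_ROLES = {
    **{v: "biological" for v in ("CE", "NE", "PE", "CE_NE", "CE_PE", "NE_PE",
                                 "VL", "VA", "AF", "SE", "MR", "MBC", "MBN")},
    **{v: "chemical" for v in ("TOC", "TN", "PS", "CaS", "KS", "MgS", "NaS",
                               "CEC", "pH", "TOC_TN", "TOC_PS", "TN_PS")},
}


@dataclass
class FeatureMatrix:
    """Samples x variables table, raw and z-scored, with group labels."""

    data: pd.DataFrame  # z-scored
    raw: pd.DataFrame
    groups: pd.Series
    roles: dict[str, str] = field(default_factory=dict)
    dropped: tuple[str, ...] = ()  # zero-variance columns removed before scaling


@dataclass
class OrdinationResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    explained: np.ndarray  # fractions, sum to 1 over retained axes


@dataclass
class RdaResult(OrdinationResult):
    constrained_fraction: float = math.nan
    r2: float = math.nan
    adj_r2: float = math.nan
    p_global: float = math.nan
    p_axes: tuple[float, ...] = ()
    p_terms: dict[str, float] = field(default_factory=dict)
    vifs: dict[str, float] = field(default_factory=dict)
    unconstrained_eigenvalues: np.ndarray | None = None
    permutations: int = 0


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    permutations: int
    dispersion_p: float = math.nan


def zscore(frame: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Column-wise z-scoring (mean 0, sd 1, sample sd by default)."""
    return (frame - frame.mean()) / frame.std(ddof=ddof)


def assemble_features(
    stoich: pd.DataFrame,
    chemistry: pd.DataFrame,
    microbial: pd.DataFrame,
) -> FeatureMatrix:
    """Build the standardized 25-variable matrix.

    ``stoich`` is the per-sample enzyme activity table (the stoichiometry
    summaries are computed here so AF and SE stay available); ``chemistry``
    is the derived chemistry table with one row per group, broadcast to
    replicates; ``microbial`` is the per-sample MBC/MBN/MR table.  Columns
    with zero variance are dropped (recorded on the result) since they
    cannot be z-scored and carry no distance information.
    """
    from .stoichiometry import summaries_frame

    summaries = summaries_frame(stoich)
    feat = summaries[["sample_id", "group"]].copy()
    feat[["CE", "NE", "PE"]] = summaries[["CE", "NE", "PE"]]
    feat["CE_NE"] = summaries["ratio_CE_NE"]
    feat["CE_PE"] = summaries["ratio_CE_PE"]
    feat["NE_PE"] = summaries["ratio_NE_PE"]
    feat["VL"] = summaries["vector_length"]
    feat["VA"] = summaries["vector_angle"]
    feat["AF"] = stoich["alkaline_phosphatase"].to_numpy()
    feat["SE"] = stoich["arylsulphatase"].to_numpy()

    chem = chemistry.rename(columns={
        "P": "PS", "Ca": "CaS", "K": "KS", "Mg": "MgS", "Na": "NaS",
        "pH_water": "pH", "CS_NS": "TOC_TN", "CS_PS": "TOC_PS", "NS_PS": "TN_PS",
    })
    chem_cols = ["TOC", "TN", "PS", "CaS", "KS", "MgS", "NaS", "CEC", "pH",
                 "TOC_TN", "TOC_PS", "TN_PS"]
    missing = [c for c in chem_cols if c not in chem.columns]
    if missing:
        raise KeyError(f"missing chemistry variable(s): {missing}")
    feat = feat.merge(chem[["group", *chem_cols]], on="group", how="left")

    feat = feat.merge(microbial[["sample_id", "MR", "MBC", "MBN"]], on="sample_id", how="left")
    missing = [v for v in FEATURE_VARIABLES if v not in feat.columns]
    if missing:
        raise KeyError(f"missing feature variable(s): {missing}")
    if feat[list(FEATURE_VARIABLES)].isna().any().any():
        bad = [c for c in FEATURE_VARIABLES if feat[c].isna().any()]
        raise ValueError(f"missing values after assembly in: {bad}")

    raw = feat.set_index("sample_id")[list(FEATURE_VARIABLES)]
    groups = feat.set_index("sample_id")["group"]
    sd = raw.std(ddof=1)
    # relative tolerance: identical values can leave an O(eps) roundoff sd
    tiny = sd <= 1e-9 * raw.abs().mean().clip(lower=1.0)
    dropped = tuple(sd.index[tiny])
    kept = raw.drop(columns=list(dropped))
    return FeatureMatrix(
        data=zscore(kept), raw=raw, groups=groups,
        roles={v: _ROLES[v] for v in FEATURE_VARIABLES}, dropped=dropped,
    )


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude loading of each axis is positive."""
    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def pca(matrix: FeatureMatrix | pd.DataFrame) -> OrdinationResult:
    """PCA of the z-scored matrix via SVD, rank-truncated, deterministic signs."""
    data = matrix.data if isinstance(matrix, FeatureMatrix) else matrix
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    if n < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    s, U, Vt = s[:rank], U[:, :rank], Vt[:rank]
    eig = s**2 / (n - 1)
    load = Vt.T
    signs = _fix_signs(load)
    load = load * signs
    scores = U * s * signs
    axes = [f"PC{i + 1}" for i in range(rank)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=data.index, columns=axes),
        loadings=pd.DataFrame(load, index=data.columns, columns=axes),
        eigenvalues=eig,
        explained=eig / eig.sum(),
    )


def _dunn_posthoc(values: np.ndarray, labels: np.ndarray) -> dict[tuple[str, str], float]:
    """Dunn's rank-based pairwise test with Bonferroni adjustment."""
    ranks = stats.rankdata(values)
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_corr = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    groups = sorted(set(labels))
    pairs = list(itertools.combinations(groups, 2))
    out = {}
    for a, b in pairs:
        ra, rb = ranks[labels == a], ranks[labels == b]
        se = math.sqrt((n * (n + 1) / 12.0 - tie_corr) * (1.0 / len(ra) + 1.0 / len(rb)))
        z = (ra.mean() - rb.mean()) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out[(a, b)] = min(1.0, p * len(pairs))
    return out


def component_tests(scores: pd.DataFrame, groups: pd.Series) -> dict[str, dict]:
    """Univariate test battery per ordination component.

    Returns per component: Shapiro-Wilk p (normality of the pooled scores),
    Levene p (homogeneity of group variances), one-way ANOVA p, Tukey HSD
    pairwise p-values, Kruskal-Wallis p and Bonferroni-adjusted Dunn
    pairwise p-values.  Components with fewer than 3 observations or fewer
    than 2 groups are skipped with a reason.
    """
    glabels = np.asarray(groups)
    results: dict[str, dict] = {}
    unique = sorted(set(glabels))
    for comp in scores.columns:
        vals = scores[comp].to_numpy(dtype=float)
        if len(vals) < 3 or len(unique) < 2:
            results[comp] = {"skipped": "need >=3 observations and >=2 groups"}
            continue
        by_group = [vals[glabels == g] for g in unique]
        if any(len(v) < 2 for v in by_group):
            results[comp] = {"skipped": "each group needs >=2 replicates"}
            continue
        tukey = pairwise_tukeyhsd(vals, glabels)
        tukey_p = {
            (str(a), str(b)): float(p)
            for (a, b), p in zip(
                itertools.combinations(unique, 2), tukey.pvalues
            )
        }
        results[comp] = {
            "shapiro_p": float(stats.shapiro(vals).pvalue),
            "levene_p": float(stats.levene(*by_group).pvalue),
            "anova_p": float(stats.f_oneway(*by_group).pvalue),
            "tukey_p": tukey_p,
            "kruskal_p": float(stats.kruskal(*by_group).pvalue),
            "dunn_p": {(str(a), str(b)): float(p)
                       for (a, b), p in _dunn_posthoc(vals, glabels).items()},
        }
    return results


def kmeans_clusters(
    scores: pd.DataFrame, groups: pd.Series, k: int = 3, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, float]:
    """Seeded k-means on ordination scores; returns (labels, purity).

    Purity is the fraction of samples whose cluster's majority group label
    matches their own group; it is invariant to cluster relabelling.
    """
    X = np.asarray(scores, dtype=float)
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of samples")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    glabels = np.asarray(groups)
    correct = 0
    for c in range(k):
        members = glabels[labels == c]
        if members.size:
            _, counts = np.unique(members, return_counts=True)
            correct += counts.max()
    return labels, correct / len(glabels)


def spearman_matrix(
    a: pd.DataFrame, b: pd.DataFrame | None = None, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlations (tie-corrected) with two-sided p-values.

    Returns (rho, p, significant) DataFrames of shape a-columns x
    b-columns (b defaults to a).  Constant columns give NaN correlations.
    """
    if b is None:
        b = a
    rho = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    pval = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for ca in a.columns:
        x = a[ca].to_numpy(dtype=float)
        for cb in b.columns:
            y = b[cb].to_numpy(dtype=float)
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 3 or np.ptp(x[mask]) == 0 or np.ptp(y[mask]) == 0:
                continue  # leave NaN: undefined for constant input
            r, p = stats.spearmanr(x[mask], y[mask])
            rho.loc[ca, cb], pval.loc[ca, cb] = r, p
    return rho, pval, pval < alpha


def vif_screen(
    env: pd.DataFrame, threshold: float = 2.0
) -> tuple[list[str], dict[str, float], list[str]]:
    """Iteratively drop the highest-VIF variable until all VIFs < threshold.

    VIF_j = 1/(1 - R^2_j) from regressing variable j on the remaining
    candidates (with intercept).  Exact ties drop the lexicographically
    first variable.  Returns (selected, final VIFs, dropped in order).
    """
    def vifs_of(cols: list[str]) -> dict[str, float]:
        if len(cols) == 1:
            return {cols[0]: 1.0}
        out = {}
        for c in cols:
            others = [o for o in cols if o != c]
            X = sm.add_constant(env[others].to_numpy(dtype=float))
            r2 = sm.OLS(env[c].to_numpy(dtype=float), X).fit().rsquared
            out[c] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return out

    cols = list(env.columns)
    if len(cols) < 1:
        raise ValueError("need at least one candidate variable")
    dropped: list[str] = []
    vifs = vifs_of(cols)
    while len(cols) > 1 and max(vifs.values()) >= threshold:
        worst = max(vifs.values())
        victim = sorted(c for c, v in vifs.items() if v == worst)[0]
        cols.remove(victim)
        dropped.append(victim)
        vifs = vifs_of(cols)
    return cols, vifs, dropped


def _fit_ss(Y: np.ndarray, Q: np.ndarray) -> float:
    proj = Q.T @ Y
    return float((proj**2).sum())


def rda(
    response: pd.DataFrame,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    axis_tests: bool = True,
) -> RdaResult:
    """Redundancy analysis with seeded permutation inference.

    Least-squares projection of the centred response matrix on the centred
    environmental variables; eigen-analysis of the fitted values gives the
    constrained axes, of the residuals the unconstrained ones.  Adjusted
    R^2 uses the Ezekiel correction.  Permutation p-values (convention
    (1+b)/(1+B), rows of the response permuted) are reported for the global
    model, for each constrained axis (forward: axis k is tested after
    partialling out the site scores of axes 1..k-1) and for each term
    sequentially in the order of the env columns.
    """
    Y = np.asarray(response, dtype=float)
    X = np.asarray(env, dtype=float)
    n, p = Y.shape
    m = X.shape[1]
    if n - m - 1 <= 0:
        raise ValueError("too few samples for the number of env variables")
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    Q, R = np.linalg.qr(Xc)
    if np.abs(np.diag(R)).min() < 1e-10 * np.abs(np.diag(R)).max():
        raise ValueError("environmental variables are collinear to machine precision; re-screen")

    ss_total = float((Yc**2).sum())
    Yhat = Q @ (Q.T @ Yc)
    ss_fit = float((Yhat**2).sum())
    ss_res = ss_total - ss_fit
    r2 = ss_fit / ss_total
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)

    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    tol = max(s.max(), 1e-300) * max(Yhat.shape) * np.finfo(float).eps
    rank = max(int((s > tol).sum()), 1)
    s, U, Vt = s[:rank], U[:, :rank], Vt[:rank]
    eig = s**2 / (n - 1)
    resid = Yc - Yhat
    s_res = np.linalg.svd(resid, compute_uv=False)
    eig_res = s_res[s_res > tol] ** 2 / (n - 1)

    signs = _fix_signs(Vt.T)
    axes = [f"RDA{i + 1}" for i in range(rank)]
    scores = pd.DataFrame(U * s * signs, index=response.index, columns=axes)
    loadings = pd.DataFrame(Vt.T * signs, index=response.columns, columns=axes)

    rng = np.random.default_rng(seed)
    df_res = n - m - 1
    f_obs = (ss_fit / m) / (ss_res / df_res)

    # sequential term SS via growing QR bases
    term_q = [np.linalg.qr(Xc[:, : j + 1])[0] for j in range(m)]
    term_ss_obs = np.diff([0.0] + [_fit_ss(Yc, q) for q in term_q])
    term_f_obs = (term_ss_obs / 1.0) / (ss_res / df_res)

    ge_global = np.zeros(1)
    ge_terms = np.zeros(m)
    for _ in range(n_perm):
        Yp = Yc[rng.permutation(n)]
        fits = [_fit_ss(Yp, q) for q in term_q]
        ss_fit_p = fits[-1]
        ss_res_p = float((Yp**2).sum()) - ss_fit_p
        f_p = (ss_fit_p / m) / (ss_res_p / df_res)
        ge_global += f_p >= f_obs
        term_ss_p = np.diff([0.0] + fits)
        ge_terms += (term_ss_p / (ss_res_p / df_res)) >= term_f_obs
    p_global = float((1 + ge_global[0]) / (1 + n_perm))
    p_terms = {str(c): float((1 + g) / (1 + n_perm)) for c, g in zip(env.columns, ge_terms)}

    # forward axis tests: axis k tested after partialling out axes 1..k-1
    p_axes = []
    for k in range(rank if axis_tests else 0):
        if k == 0:
            Yk, Xk = Yc, Xc
        else:
            Z = U[:, :k] * s[:k]
            Qz, _ = np.linalg.qr(Z)
            Yk = Yc - Qz @ (Qz.T @ Yc)
            Xk = Xc - Qz @ (Qz.T @ Xc)
        Qk, Rk = np.linalg.qr(Xk)
        keep = np.abs(np.diag(Rk)) > 1e-10 * max(np.abs(np.diag(Rk)).max(), 1e-300)
        Qk = Qk[:, keep]
        sk = np.linalg.svd(Qk @ (Qk.T @ Yk), compute_uv=False)
        lam_obs = sk[0] ** 2 / (n - 1)
        ge = 0
        for _ in range(n_perm):
            Yp = Yk[rng.permutation(n)]
            sp = np.linalg.svd(Qk @ (Qk.T @ Yp), compute_uv=False)
            ge += (sp[0] ** 2 / (n - 1)) >= lam_obs
        p_axes.append(float((1 + ge) / (1 + n_perm)))

    _, vifs, _ = vif_screen(env, threshold=math.inf)
    all_eig = np.concatenate([eig, eig_res])
    return RdaResult(
        scores=scores, loadings=loadings, eigenvalues=eig,
        explained=np.concatenate([eig, eig_res]) / all_eig.sum(),
        constrained_fraction=r2, r2=r2, adj_r2=adj_r2,
        p_global=p_global, p_axes=tuple(p_axes), p_terms=p_terms,
        vifs=vifs, unconstrained_eigenvalues=eig_res, permutations=n_perm,
    )


def _unique_label_permutations(labels: np.ndarray, limit: int = 500_000):
    """All distinct arrangements of a label multiset (small n only)."""
    from math import factorial
    counts = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    total = factorial(len(labels))
    for c in counts.values():
        total //= factorial(c)
    if total > limit:
        raise ValueError(f"{total} distinct permutations; exact enumeration refused")

    items = sorted(counts)
    def rec(prefix, remaining, n_left):
        if n_left == 0:
            yield tuple(prefix)
            return
        for it in items:
            if remaining[it] > 0:
                remaining[it] -= 1
                prefix.append(it)
                yield from rec(prefix, remaining, n_left - 1)
                prefix.pop()
                remaining[it] += 1
    yield from rec([], dict(counts), len(labels))


def _permanova_ss(d2: np.ndarray, label_codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = len(label_codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(label_codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total, ss_within


def permanova(
    matrix: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int | str = 999,
    seed: int = 0,
    dispersion: bool = True,
) -> PermanovaResult:
    """PERMANOVA on Euclidean distances of the feature matrix.

    pseudo-F = (SS_among/(k-1)) / (SS_within/(n-k)) with sums of squares
    computed from pairwise squared distances; p = (1 + #{F_perm >= F_obs})
    / (n_perm + 1) under seeded label permutation, or an exact enumeration
    over all distinct label arrangements when ``n_perm='exact'``.  The
    companion dispersion test runs a one-way ANOVA on distances to group
    centroids (for the Euclidean metric, centroid distances in the feature
    space coincide with the principal-coordinate ones).
    """
    X = np.asarray(matrix, dtype=float)
    glabels = np.asarray(groups)
    codes, uniques = pd.factorize(glabels)
    k = len(uniques)
    n = len(codes)
    if k < 2 or min(np.bincount(codes)) < 2:
        raise ValueError("need >=2 groups with >=2 samples each")

    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum(d2, 0.0)
    if d2.max() == 0:
        return PermanovaResult(math.nan, math.nan, math.nan, 0, math.nan)

    ss_total, ss_within = _permanova_ss(d2, codes, k)
    ss_among = ss_total - ss_within
    f_obs = (ss_among / (k - 1)) / (ss_within / (n - k))
    r2 = ss_among / ss_total

    if n_perm == "exact":
        f_perm = []
        for arrangement in _unique_label_permutations(codes):
            _, ssw = _permanova_ss(d2, np.asarray(arrangement), k)
            f_perm.append(((ss_total - ssw) / (k - 1)) / (ssw / (n - k)))
        f_perm = np.asarray(f_perm)
        p = float((f_perm >= f_obs - 1e-12).mean())
        used = len(f_perm)
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(codes) for _ in range(int(n_perm))])
        masks = (perms[:, None, :] == np.arange(k)[None, :, None]).astype(float)  # B x k x n
        group_sizes = masks.sum(axis=2)  # B x k
        within = np.einsum("bgi,ij,bgj->bg", masks, d2, masks) / (2.0 * group_sizes)
        ssw_perm = within.sum(axis=1)
        f_perm = ((ss_total - ssw_perm) / (k - 1)) / (ssw_perm / (n - k))
        p = float((1 + (f_perm >= f_obs).sum()) / (1 + int(n_perm)))
        used = int(n_perm)

    disp_p = math.nan
    if dispersion:
        dists = []
        for g in range(k):
            idx = codes == g
            centroid = X[idx].mean(axis=0)
            dists.append(np.linalg.norm(X[idx] - centroid, axis=1))
        disp_p = float(stats.f_oneway(*dists).pvalue)
    return PermanovaResult(float(f_obs), float(r2), p, used, disp_p)
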