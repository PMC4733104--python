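"""Statistical models on Procrustes shape variables.

Allometry regression (and the residuals used by every downstream stage),
homogeneity-of-slopes checks, size comparisons, nested MANCOVA with Wilks'
Lambda, the Procrustes-distance permutation test of mean shapes,
leave-one-out discriminant classification, and between-group PCA.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import AllometryModel, ModelTestResult, ShapeData
from .linmodels import (
    DesignMatrix,
    design_continuous,
    design_factor,
    design_intercept,
    design_interaction,
    fit_ols,
    rao_f,
    rrpp_compare,
    wilks_lambda,
)

__all__ = [
    "regress_shape_on_size",
    "homogeneity_of_slopes_test",
    "size_comparison",
    "nested_mancova",
    "mean_shape_permutation_test",
    "lda_crossval",
    "bg_pca",
    "pca_scores",
]


def pca_scores(y: np.ndarray, rel_tol: float = 1e-12) -> np.ndarray:
    """Full-rank PCA scores of a (possibly rank-deficient) response matrix.

    Shape variables after GPA have rank at most 2k - 4; MANCOVA and LDA need
    a nonsingular error matrix, so they operate on the scores of components
    whose eigenvalues exceed ``rel_tol`` times the total variance.
    """
    y = np.asarray(y, dtype=float)
    yc = y - y.mean(axis=0)
    u, s, _ = np.linalg.svd(yc, full_matrices=False)
    ev = s**2
    keep = ev > rel_tol * ev.sum()
    return u[:, keep] * s[keep]


def _shapes_matrix(shapes) -> np.ndarray:
    if isinstance(shapes, ShapeData):
        return shapes.flat
    return np.asarray(shapes, dtype=float)


def regress_shape_on_size(
    shapes: ShapeData,
    predictor: str = "cs",
    n_perm: int = 10000,
    seed: int | None = None,
) -> AllometryModel:
    """Multivariate regression of shape on centroid size (allometry).

    Fits every shape variable on size jointly, reports the percentage of
    total shape variance explained (100 * SS_model / SS_total) with a
    permutation p-value (sizes permuted against shape rows), and returns
    the residuals — the allometry-corrected data used downstream.
    """
    y = shapes.flat
    n = y.shape[0]
    if n < 3:
        raise ValueError("allometry regression needs n > 2")
    cs = shapes.centroid_sizes
    if predictor == "log_cs":
        s = np.log(cs)
    elif predictor == "cs":
        s = cs.astype(float)
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    if np.ptp(s) == 0:
        raise ValueError("centroid size has zero variance")

    yc = y - y.mean(axis=0)
    sc = s - s.mean()
    ss_s = float(sc @ sc)
    proj = (sc @ yc) / ss_s                  # slope vector (d,)
    ss_model = float(proj @ proj) * ss_s
    ss_total = float(np.sum(yc * yc))
    fitted = y.mean(axis=0) + np.outer(sc, proj)
    residuals = y - fitted

    rng = np.random.default_rng(seed)
    count = 0
    # vectorized permutation of the size vector in blocks
    block = 1000
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        perms = np.array([rng.permutation(sc) for _ in range(m)])
        num = perms @ yc                      # (m, d)
        ss_perm = np.sum(num**2, axis=1) / ss_s
        count += int(np.sum(ss_perm >= ss_model - 1e-12))
        done += m
    p = (count + 1) / (n_perm + 1)

    coeffs = np.vstack([y.mean(axis=0) - s.mean() * proj, proj])
    return AllometryModel(
        coefficients=coeffs,
        predictor_name=predictor,
        percent_variance=100.0 * ss_model / ss_total,
        residuals=residuals,
        fitted=fitted,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed if seed is not None else -1,
    )


def homogeneity_of_slopes_test(
    shapes,
    cs: np.ndarray,
    factor,
    n_perm: int = 999,
    seed: int | None = None,
    variant: str = "full_factorial",
) -> ModelTestResult:
    """Test a factor x size interaction (common-slopes hypothesis) by RRPP.

    ``full_factorial`` compares shape ~ cs + factor + cs:factor against
    shape ~ cs + factor; ``size_only`` compares shape ~ cs + cs:factor
    against shape ~ cs.  A non-significant interaction licenses analyses
    with main effects only.
    """
    y = _shapes_matrix(shapes)
    factor = np.asarray(factor)
    levels, counts = np.unique(factor, return_counts=True)
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    if counts.min() < 3:
        raise ValueError("every factor level needs at least 3 specimens")
    n = y.shape[0]
    base = design_intercept(n).hstack(design_continuous(cs, "cs"))
    fac = design_factor(factor, "factor")
    inter = design_interaction(design_continuous(cs, "cs"), fac)
    if variant == "full_factorial":
        reduced = base.hstack(fac)
    elif variant == "size_only":
        reduced = base
    else:
        raise ValueError(f"unknown variant {variant!r}")
    full = reduced.hstack(inter)
    f, z, p, df = rrpp_compare(y, full, reduced, n_perm=n_perm, seed=seed)
    return ModelTestResult(
        statistic_name="F", statistic=f, p=p, method="rrpp", df=df,
        n_perm=n_perm, z=z, term=f"cs:factor ({variant})",
    )


def size_comparison(cs, race, weight=None) -> ModelTestResult:
    """Compare centroid size between races (ANOVA, or ANCOVA with weight).

    Uses an ordinary linear model of CS on race; when body weight is given
    it enters as a covariate (allometry control) and both terms are
    reported.  Specimens with missing weight are dropped listwise, with a
    warning if they exceed 20%.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"cs": np.asarray(cs, float), "race": np.asarray(race)})
    if len(df["race"].unique()) < 2:
        raise ValueError("need at least 2 races")
    if weight is not None:
        df["weight"] = np.asarray(weight, float)
        n_missing = int(df["weight"].isna().sum())
        if n_missing > 0.2 * len(df):
            warnings.warn(
                f"{n_missing}/{len(df)} specimens lack weight; dropped listwise",
                stacklevel=2,
            )
        df = df.dropna(subset=["weight"])
        model = smf.ols("cs ~ weight + C(race)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        # degenerate term: an SS that is numerically zero relative to the
        # total (e.g. CS an exact multiple of weight) carries no signal
        total_ss = float(np.sum((df["cs"] - df["cs"].mean()) ** 2))
        if float(table.loc["C(race)", "sum_sq"]) < 1e-12 * total_ss:
            table.loc["C(race)", "F"] = 0.0
            table.loc["C(race)", "PR(>F)"] = 1.0
        race_row = table.loc["C(race)"]
        extra = {
            "weight_F": float(table.loc["weight", "F"]),
            "weight_p": float(table.loc["weight", "PR(>F)"]),
            "n_used": int(len(df)),
        }
    else:
        model = smf.ols("cs ~ C(race)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        race_row = table.loc["C(race)"]
        extra = {"n_used": int(len(df))}
    return ModelTestResult(
        statistic_name="F",
        statistic=float(race_row["F"]),
        p=float(race_row["PR(>F)"]),
        method="parametric",
        df=(int(race_row["df"]), int(table.loc["Residual", "df"])),
        term="race",
        extra=extra,
    )


def nested_mancova(shapes, race, population, cs=None) -> list[ModelTestResult]:
    """Nested MANCOVA: shape ~ cs + race + population(race).

    The response is reduced to full-rank PCA scores first (Wilks' Lambda
    needs a nonsingular error matrix).  Terms are added sequentially
    (cs, then race, then population-within-race); each term's H matrix is
    the difference of residual cross-products between the model without and
    with the term, E is the full-model residual cross-product, and Wilks'
    Lambda det(E)/det(E+H) is converted to Rao's F.
    """
    y_raw = _shapes_matrix(shapes)
    race = np.asarray(race)
    population = np.asarray(population)
    pops_per_race = pd.DataFrame({"race": race, "pop": population}).groupby("pop")["race"].nunique()
    if (pops_per_race > 1).any():
        bad = list(pops_per_race[pops_per_race > 1].index)
        raise ValueError(f"population(s) spanning more than one race: {bad}")
    y = pca_scores(y_raw)
    n, p = y.shape
    yc = y - y.mean(axis=0)

    base = design_intercept(n)
    x_race = design_factor(race, "race")
    x_pop = design_factor(population, "population")

    designs = []
    current = base
    if cs is not None:
        current = current.hstack(design_continuous(cs, "cs"))
        designs.append(("cs", current))
    current = current.hstack(x_race)
    designs.append(("race", current))
    current = current.hstack(x_pop)
    designs.append(("population(race)", current))
    # residual cross-product matrices for the sequence of nested models
    def resid_cross(x: DesignMatrix) -> np.ndarray:
        _, _, r = fit_ols(yc, x.x)
        return r.T @ r

    cross = [resid_cross(base)] + [resid_cross(x) for _, x in designs]
    e = cross[-1]
    full_rank = np.linalg.matrix_rank(designs[-1][1].x)
    v = n - full_rank
    results = []
    for i, (term, x) in enumerate(designs):
        h = cross[i] - cross[i + 1]
        q = np.linalg.matrix_rank(x.x) - np.linalg.matrix_rank(
            designs[i - 1][1].x if i else base.x
        )
        if q == 0:
            continue  # term adds nothing estimable (e.g. one population per race)
        lmbda = wilks_lambda(e, h)
        f, df1, df2, pval = rao_f(lmbda, p, q, v)
        results.append(
            ModelTestResult(
                statistic_name="WilksLambda",
                statistic=lmbda,
                p=pval,
                method="parametric",
                df=(df1, df2),
                term=term,
                extra={"F": f, "p_variables": p, "q": q, "error_df": v},
            )
        )
    return results


def mean_shape_permutation_test(
    residuals: np.ndarray,
    groups,
    n_perm: int = 10000,
    seed: int | None = None,
) -> ModelTestResult:
    """Permutation test of mean-shape difference between two groups.

    The statistic is the (tangent) Procrustes distance between the two
    group mean shapes computed on allometry-corrected data; the null
    distribution reshuffles group labels, and the p-value includes the
    observed statistic: p = (#{perm >= obs} + 1) / (n_perm + 1).

    When the number of distinct label assignments C(n, n1) is at most
    ``n_perm``, all of them are enumerated and the p-value is exact.
    """
    y = np.asarray(residuals, dtype=float)
    groups = np.asarray(groups)
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) != 2:
        raise ValueError("exactly 2 groups are required")
    if counts.min() < 3:
        raise ValueError("each group needs at least 3 specimens")
    n = y.shape[0]
    n1 = int(counts[0])
    mask1 = groups == levels[0]

    total = y.sum(axis=0)

    def stat(sum1: np.ndarray) -> float:
        m1 = sum1 / n1
        m2 = (total - sum1) / (n - n1)
        return float(np.linalg.norm(m1 - m2))

    obs = stat(y[mask1].sum(axis=0))
    from math import comb
    from itertools import combinations

    n_assign = comb(n, n1)
    if n_assign <= n_perm:
        stats_all = [
            stat(y[list(idx)].sum(axis=0)) for idx in combinations(range(n), n1)
        ]
        count = int(np.sum(np.asarray(stats_all) >= obs - 1e-15))
        p = count / n_assign
        n_perm = n_assign
        method = "permutation (exact enumeration)"
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            idx = rng.permutation(n)[:n1]
            if stat(y[idx].sum(axis=0)) >= obs - 1e-15:
                count += 1
        p = (count + 1) / (n_perm + 1)
        method = "permutation"
    return ModelTestResult(
        statistic_name="ProcrustesDistance",
        statistic=obs,
        p=float(p),
        method=method,
        n_perm=n_perm,
        term="mean shape difference",
        extra={"groups": levels.tolist(), "n": (int(counts[0]), int(counts[1]))},
    )


def lda_crossval(residuals: np.ndarray, groups, rel_tol: float = 1e-12) -> float:
    """Leave-one-out cross-validated linear discriminant classification rate.

    Shape variables are reduced to full-rank PCA scores; for every specimen
    the discriminant is refit without it and the specimen is then
    classified.  Ties (a decision score of exactly zero) count as
    misclassifications.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    y = np.asarray(residuals, dtype=float)
    groups = np.asarray(groups)
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) != 2:
        raise ValueError("LOO discriminant analysis expects exactly 2 groups")
    scores = pca_scores(y, rel_tol=rel_tol)
    n, d = scores.shape
    max_d = n - len(levels) - 1
    if d > max_d:
        warnings.warn(
            f"retained dimensions reduced from {d} to {max_d} "
            "(group sizes too small for the full-rank space)",
            stacklevel=2,
        )
        scores = scores[:, :max_d]
    codes = (groups == levels[1]).astype(int)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        lda = LinearDiscriminantAnalysis(solver="svd")
        lda.fit(scores[mask], codes[mask])
        score = float(lda.decision_function(scores[i : i + 1])[0])
        if score == 0.0:
            continue  # tie -> conservative: misclassified
        pred = int(score > 0)
        correct += int(pred == codes[i])
    return correct / n


def bg_pca(residuals: np.ndarray, groups):
    """Between-group PCA: eigenvectors of the group-means covariance.

    All individuals are projected onto the axes, and each axis' share of the
    total variance of the full dataset is reported.  At most (#groups - 1)
    axes are non-degenerate.
    """
    y = np.asarray(residuals, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    if len(levels) < 2:
        raise ValueError("between-group PCA needs at least 2 groups")
    means = np.vstack([y[groups == g].mean(axis=0) for g in levels])
    center = means.mean(axis=0)
    mc = means - center
    # eigenvectors of the group-means covariance via SVD of the means
    _, s, vt = np.linalg.svd(mc, full_matrices=False)
    n_axes = min(len(levels) - 1, vt.shape[0])
    axes = vt[:n_axes].T
    eigenvalues = (s[:n_axes] ** 2) / (len(levels) - 1)
    scores = (y - center) @ axes
    total_var = np.sum((y - y.mean(axis=0)) ** 2)
    percent = 100.0 * np.sum((scores - scores.mean(axis=0)) ** 2, axis=0) / total_var
    group_scores = mc @ axes
    return {
        "scores": scores,
        "axes": axes,
        "eigenvalues": eigenvalues,
        "percent_total_variance": percent,
        "group_labels": levels,
        "group_scores": group_scores,
    }
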