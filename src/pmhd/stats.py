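"""Association statistics linking molecular measurements to GD phenotypes.

This layer provides the statistical toolkit used to relate per-strain
molecular quantities (piRNA RPM, P/KP mRNA, cluster-read fraction) to
gonadal-dysgenesis scores: Pearson correlation, small-n multiple regression
with standardized partial coefficients and partial correlations,
furthest-neighbor (complete-linkage) hierarchical clustering on z-scored
features, the classical two-sample t test, and the GD < 10% phenotype
criterion for P inducibility (cross A) and P susceptibility (cross A*).

Panels in this field are tiny (often n = 5 strains against 2 predictors,
leaving 2 residual degrees of freedom); the regression deliberately accepts
such fits rather than refusing small n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm

GD_LOW_THRESHOLD_PCT = 10.0


def _as_vector(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty vector")
    return v


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson product-moment correlation with a two-sided t-based p-value.

    Returns (R, p, n).  Requires n >= 3 and nonzero variance in both inputs.
    """
    xv, yv = _as_vector(x), _as_vector(y)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    n = xv.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.isclose(xv.std(), 0.0) or np.isclose(yv.std(), 0.0):
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(xv, yv)
    return float(r), float(p), n


@dataclass(frozen=True)
class RegressionResult:
    """Multiple-regression summary on z-scored predictors.

    ``coef`` are partial regression coefficients of raw y on z-scored
    predictors (one unit = one predictor SD); ``std_coef`` additionally
    z-scores y (fully standardized coefficients); ``partial_corr`` is the
    partial correlation recovered from each coefficient's t statistic via
    r = t / sqrt(t^2 + df).
    """

    predictors: tuple[str, ...]
    coef: tuple[float, ...]
    std_coef: tuple[float, ...]
    partial_corr: tuple[float, ...]
    t_values: tuple[float, ...]
    p_values: tuple[float, ...]
    intercept: float
    df_resid: int
    n: int


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    if np.any(np.isclose(sd, 0.0)):
        raise ValueError("zero-variance column: cannot z-score")
    return (a - a.mean(axis=0)) / sd


def multiple_regression(
    y, X, names: Sequence[str] | None = None
) -> RegressionResult:
    """OLS of y on z-scored predictors with partial statistics.

    ``X`` is (n, p).  Requires n > p + 1 and full column rank.  Two-sided
    p-values come from the t distribution with n - p - 1 degrees of freedom.
    """
    yv = _as_vector(y)
    Xm = np.asarray(X, dtype=float)
    if Xm.ndim == 1:
        Xm = Xm[:, None]
    n, p = Xm.shape
    if yv.size != n:
        raise ValueError("y and X row counts differ")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    if np.linalg.matrix_rank(Xm) < p:
        raise ValueError("rank-deficient design matrix")
    Z = _zscore(Xm)
    fit = sm.OLS(yv, sm.add_constant(Z)).fit()
    df = int(fit.df_resid)
    tvals = np.asarray(fit.tvalues)[1:]
    coefs = np.asarray(fit.params)[1:]
    sd_y = yv.std(ddof=1)
    std_coef = coefs / sd_y if sd_y > 0 else np.full_like(coefs, np.nan)
    partial = tvals / np.sqrt(tvals**2 + df)
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df)
    if names is None:
        names = tuple(f"x{i + 1}" for i in range(p))
    return RegressionResult(
        predictors=tuple(names),
        coef=tuple(float(c) for c in coefs),
        std_coef=tuple(float(c) for c in std_coef),
        partial_corr=tuple(float(c) for c in partial),
        t_values=tuple(float(t) for t in tvals),
        p_values=tuple(float(v) for v in pvals),
        intercept=float(fit.params[0]),
        df_resid=df,
        n=n,
    )


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: the two cluster labels joined and the height."""

    left: str
    right: str
    height: float


@dataclass(frozen=True)
class Dendrogram:
    labels: tuple[str, ...]
    merges: tuple[Merge, ...]

    def to_newick(self) -> str:
        """Newick string with merge heights as branch-length annotations."""
        trees = {lab: lab for lab in self.labels}
        heights = {lab: 0.0 for lab in self.labels}
        for m in self.merges:
            lab = min(m.left, m.right)
            other = max(m.left, m.right)
            bl_l = (m.height - heights[m.left]) / 2.0
            bl_r = (m.height - heights[m.right]) / 2.0
            node = f"({trees[m.left]}:{bl_l:.6g},{trees[m.right]}:{bl_r:.6g})"
            trees[lab] = node
            heights[lab] = m.height
            if other != lab:
                del trees[other]
        (root,) = trees.values()
        return root + ";"


def hcluster(
    points: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    zscore: bool = True,
) -> Dendrogram:
    """Complete-linkage (furthest-neighbor) agglomerative clustering.

    Euclidean distance on (optionally z-scored) features.  At every step the
    pair with the smallest complete-linkage distance merges; exact ties are
    broken by the lexicographically smallest (label, label) pair, where a
    cluster is identified by its smallest member label.  The result is
    therefore invariant under permutation of the input order.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    n = P.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if labels is None:
        labels = tuple(f"p{i + 1}" for i in range(n))
    labels = tuple(str(l) for l in labels)
    if len(set(labels)) != n:
        raise ValueError("labels must be unique")
    if zscore:
        sd = P.std(axis=0, ddof=1)
        sd[np.isclose(sd, 0.0)] = 1.0
        P = (P - P.mean(axis=0)) / sd

    # Pairwise distances between current clusters; complete linkage.
    members: dict[str, list[int]] = {lab: [i] for i, lab in enumerate(labels)}

    def linkage(a: str, b: str) -> float:
        return max(
            float(np.linalg.norm(P[i] - P[j]))
            for i in members[a]
            for j in members[b]
        )

    merges: list[Merge] = []
    while len(members) > 1:
        keys = sorted(members)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                d = linkage(a, b)
                cand = (d, a, b)
                if best is None or cand < best:
                    best = cand
        d, a, b = best
        merges.append(Merge(a, b, d))
        members[a] = members[a] + members[b]
        del members[b]
    return Dendrogram(labels=labels, merges=tuple(merges))


def t_test(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t test (pooled-variance Student by default).

    Degenerate zero-variance comparisons with equal means return (0, 1).
    """
    av, bv = _as_vector(a), _as_vector(b)
    if av.size < 2 or bv.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.isclose(av.std(), 0.0) and np.isclose(bv.std(), 0.0):
        if np.isclose(av.mean(), bv.mean()):
            return 0.0, 1.0
    t, p = sps.ttest_ind(av, bv, equal_var=not welch)
    return float(t), float(p)


def label_phenotype(gd_pct: float, cross: str) -> tuple[str, str]:
    """GD-based phenotype label: ("low"|"high", trait name).

    Cross A measures P inducibility of the paternal line; cross A* measures
    P susceptibility of the maternal line.  "low" iff GD% < 10.0 (strict).
    """
    if not (0.0 <= gd_pct <= 100.0):
        raise ValueError("GD percentage must be in [0, 100]")
    if cross not in ("A", "A*"):
        raise ValueError("cross must be 'A' or 'A*'")
    trait = "inducibility" if cross == "A" else "susceptibility"
    return ("low" if gd_pct < GD_LOW_THRESHOLD_PCT else "high"), trait
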