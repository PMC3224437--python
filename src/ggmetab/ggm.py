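"""Pearson and partial correlation estimation with Fisher-z significance.

The Gaussian graphical model (GGM) of an n x m data matrix is the undirected
graph of nonzero partial correlations

    zeta_ij = -omega_ij / sqrt(omega_ii * omega_jj),   (omega_ij) = P^{-1},

where P is the Pearson correlation matrix.  Each zeta_ij is the correlation
of metabolites i and j conditioned on all remaining m-2 variables, and equals
the Pearson correlation of the residuals from regressing i and j on the rest.
Significance follows Fisher's z-transform: with q conditioned variables,
sqrt(n - q - 3) * z(zeta) is approximately standard normal under the null.

:class:`GaussianGraphicalModel` wraps the whole procedure as a scikit-learn
style estimator; the module-level functions expose the individual steps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = [
    "CorrelationResult",
    "GaussianGraphicalModel",
    "DegenerateDataError",
    "IllConditionedError",
    "pearson_matrix",
    "partial_matrix",
    "low_order_partial",
    "fisher_pvalue",
    "bonferroni_alpha",
    "significance_cutoff",
    "bootstrap_stability",
    "subsample_stability",
    "edge_table",
]


class DegenerateDataError(ValueError):
    """Zero-variance column or too few samples."""


class IllConditionedError(ValueError):
    """Correlation matrix is (numerically) singular; needs n > m."""


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if hasattr(X, "data") and isinstance(getattr(X, "data"), pd.DataFrame):
        df = X.data  # ConcentrationEnsemble
        return df.to_numpy(dtype=float), list(df.columns)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[1])]


# ---------------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------------

def pearson_matrix(X) -> np.ndarray:
    """Pearson product-moment correlation matrix of the columns of X."""
    arr, ids = _as_matrix(X)
    n, m = arr.shape
    if n < 3:
        raise DegenerateDataError("need at least 3 samples")
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [ids[i] for i in np.flatnonzero(sd == 0)]
        raise DegenerateDataError(f"zero-variance column(s): {bad}")
    P = np.corrcoef(arr, rowvar=False)
    return np.clip((P + P.T) / 2.0, -1.0, 1.0)


def partial_matrix(P: np.ndarray, cond_threshold: float = 1e12) -> np.ndarray:
    """Full-order partial correlations from a correlation matrix.

    zeta_ij = -omega_ij / sqrt(omega_ii omega_jj) with Omega = P^{-1},
    computed via a Cholesky factorization.  The diagonal is set to 1 by
    convention (the formula itself yields -1) and is excluded from all
    downstream statistics.
    """
    P = np.asarray(P, dtype=float)
    if np.linalg.cond(P) > cond_threshold:
        raise IllConditionedError(
            "correlation matrix is ill-conditioned; partial correlations need n > m"
        )
    try:
        c, low = cho_factor(P)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise IllConditionedError(str(exc)) from exc
    omega = cho_solve((c, low), np.eye(P.shape[0]))
    d = np.sqrt(np.diag(omega))
    Z = -omega / np.outer(d, d)
    Z = (Z + Z.T) / 2.0
    np.fill_diagonal(Z, 1.0)
    return np.clip(Z, -1.0, 1.0)


def _subset_partial(P: np.ndarray, i: int, j: int, cond: tuple[int, ...]) -> float:
    """Partial correlation of i, j given the variables in ``cond``.

    Obtained from the inverse of the (q+2) x (q+2) submatrix of P, which is
    algebraically identical to the classical recursion over conditioning
    variables.
    """
    idx = [i, j, *cond]
    sub = P[np.ix_(idx, idx)]
    omega = np.linalg.inv(sub)
    return float(-omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1]))


def low_order_partial(
    X,
    q: int,
    alpha_adj: float | None = None,
    n: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Order-q partial correlations (q = 1, 2 or 3) with the all-subsets rule.

    For each pair (i, j) the partial correlation is evaluated against every
    conditioning subset of size q drawn from the other variables.  The
    returned matrix holds the minimum-magnitude (signed) value over subsets;
    the boolean mask marks edges whose partial correlation is significant at
    ``alpha_adj`` for *every* subset.  When ``alpha_adj`` is None the mask is
    all-True for nonzero entries and no test is performed.

    Raises a domain error when ``q >= m - 1`` (use the full GGM instead).
    """
    arr, _ = _as_matrix(X)
    n_samples, m = arr.shape
    if n is None:
        n = n_samples
    if q < 0 or q >= m - 1:
        raise ValueError("conditioning order must satisfy 0 <= q < m - 1")
    if n <= q + 2:
        raise DegenerateDataError("too few samples for this conditioning order")
    P = pearson_matrix(arr)
    Z = np.eye(m)
    keep = np.zeros((m, m), dtype=bool)
    others = set(range(m))
    for i in range(m):
        for j in range(i + 1, m):
            best = None
            all_sig = True
            for cond in itertools.combinations(sorted(others - {i, j}), q):
                val = _subset_partial(P, i, j, cond) if q else float(P[i, j])
                if best is None or abs(val) < abs(best):
                    best = val
                if alpha_adj is not None:
                    if fisher_pvalue(val, n, q) > alpha_adj:
                        all_sig = False
            Z[i, j] = Z[j, i] = best
            keep[i, j] = keep[j, i] = all_sig and (alpha_adj is not None or best != 0)
    return Z, keep


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def fisher_pvalue(zeta, n: int, q: int):
    """Two-sided p-value of a (partial) correlation via Fisher's z-transform.

    z(zeta) = atanh(zeta); p = 2 * (1 - Phi(sqrt(n - q - 3) * |z|)) where q is
    the number of conditioned variables (m - 2 for the full GGM, 0 for plain
    Pearson correlations).  |zeta| = 1 returns an exact p of 0.
    """
    if n - q - 3 <= 0:
        raise ValueError("need n - q - 3 > 0 for the Fisher z test")
    zeta_arr = np.asarray(zeta, dtype=float)
    if np.any(np.abs(zeta_arr) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(zeta_arr, -1.0, 1.0))
    p = 2.0 * norm.sf(np.sqrt(n - q - 3) * np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    p = np.where(np.abs(zeta_arr) >= 1.0, 0.0, p)
    return float(p) if np.isscalar(zeta) or np.ndim(zeta) == 0 else p


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted significance level alpha / n_tests."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def significance_cutoff(alpha_adj: float, n: int, q: int) -> float:
    """|zeta| at which the Fisher-z p-value equals ``alpha_adj``.

    Inverts the transform: zeta* = tanh(Phi^{-1}(1 - alpha_adj / 2) /
    sqrt(n - q - 3)).  Monotone decreasing in n.
    """
    if not 0 < alpha_adj < 1:
        raise ValueError("alpha_adj must be in (0, 1)")
    if n - q - 3 <= 0:
        raise ValueError("need n - q - 3 > 0")
    return float(np.tanh(norm.isf(alpha_adj / 2.0) / np.sqrt(n - q - 3)))


# ---------------------------------------------------------------------------
# result container and estimator
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """Correlation matrices plus their significance assessment for one data set."""

    metabolite_ids: list[str]
    P: np.ndarray
    Z: np.ndarray
    p_pearson: np.ndarray
    p_partial: np.ndarray
    n: int
    order_q: int
    alpha: float
    alpha_adj: float
    cutoff: float
    classes: dict[str, str] | None = None
    retained: np.ndarray | None = None  # low-order all-subsets mask, if applicable

    @property
    def m(self) -> int:
        return len(self.metabolite_ids)

    def significant_partial(self, sign: str = "both") -> np.ndarray:
        """Boolean matrix of significant partial correlations.

        ``sign`` restricts to ``"positive"`` (zeta > 0), ``"negative"`` or
        ``"both"``.  For low-order results the all-subsets retention mask is
        applied on top of the per-value test.
        """
        sig = self.p_partial <= self.alpha_adj
        np.fill_diagonal(sig, False)
        if self.retained is not None:
            sig &= self.retained
        if sign == "positive":
            sig &= self.Z > 0
        elif sign == "negative":
            sig &= self.Z < 0
        elif sign != "both":
            raise ValueError("sign must be positive, negative or both")
        return sig


class GaussianGraphicalModel(BaseEstimator):
    """Estimate a Gaussian graphical model from log-concentration data.

    Parameters
    ----------
    alpha : float, default 0.01
        Nominal two-sided significance level.
    correction : {"bonferroni", "none"}, default "bonferroni"
        Multiple-testing correction over the m(m-1)/2 pairwise tests.
    order : int or None, default None
        ``None`` fits the full-order GGM (conditioning on all m-2 remaining
        variables); 1, 2 or 3 fit low-order partial correlations with the
        all-subsets retention rule; 0 reduces to plain Pearson correlations.
    cond_threshold : float, default 1e12
        Condition-number guard for inverting the correlation matrix.

    Attributes (after :meth:`fit`)
    ------------------------------
    pearson_, partial_ : ndarray of shape (m, m)
    pvalue_pearson_, pvalue_partial_ : ndarray of shape (m, m)
    alpha_adj_, cutoff_ : float
    n_samples_, n_features_, order_q_ : int
    feature_names_ : list of str
    """

    def __init__(
        self,
        alpha: float = 0.01,
        correction: str = "bonferroni",
        order: int | None = None,
        cond_threshold: float = 1e12,
    ):
        self.alpha = alpha
        self.correction = correction
        self.order = order
        self.cond_threshold = cond_threshold

    def fit(self, X, y=None):
        arr, ids = _as_matrix(X)
        classes = getattr(X, "classes", None)
        n, m = arr.shape
        n_tests = m * (m - 1) // 2
        if self.correction == "bonferroni":
            alpha_adj = bonferroni_alpha(self.alpha, n_tests)
        elif self.correction == "none":
            alpha_adj = self.alpha
        else:
            raise ValueError(f"unknown correction {self.correction!r}")

        P = pearson_matrix(arr)
        retained = None
        if self.order is None:
            if n <= m:
                raise IllConditionedError(
                    f"full-order GGM needs n > m (got n={n}, m={m}); "
                    "use a low-order model instead"
                )
            q = m - 2
            Z = partial_matrix(P, cond_threshold=self.cond_threshold)
        elif self.order == 0:
            q = 0
            Z = P.copy()
        else:
            q = int(self.order)
            Z, retained = low_order_partial(arr, q, alpha_adj=alpha_adj, n=n)

        offdiag = ~np.eye(m, dtype=bool)
        p_partial = np.ones((m, m))
        p_partial[offdiag] = fisher_pvalue(Z[offdiag], n, q)
        p_pearson = np.ones((m, m))
        p_pearson[offdiag] = fisher_pvalue(P[offdiag], n, 0)

        self.feature_names_ = ids
        self.classes_map_ = dict(classes) if classes else None
        self.pearson_ = P
        self.partial_ = Z
        self.pvalue_pearson_ = p_pearson
        self.pvalue_partial_ = p_partial
        self.retained_ = retained
        self.n_samples_ = n
        self.n_features_ = m
        self.order_q_ = q
        self.alpha_adj_ = alpha_adj
        self.cutoff_ = significance_cutoff(alpha_adj, n, q)
        return self

    def to_result(self) -> CorrelationResult:
        """Package the fitted matrices as a :class:`CorrelationResult`."""
        return CorrelationResult(
            metabolite_ids=self.feature_names_,
            P=self.pearson_,
            Z=self.partial_,
            p_pearson=self.pvalue_pearson_,
            p_partial=self.pvalue_partial_,
            n=self.n_samples_,
            order_q=self.order_q_,
            alpha=self.alpha,
            alpha_adj=self.alpha_adj_,
            cutoff=self.cutoff_,
            classes=self.classes_map_,
            retained=self.retained_,
        )

    def fit_result(self, X) -> CorrelationResult:
        return self.fit(X).to_result()


def fit_ggm(X, alpha: float = 0.01, correction: str = "bonferroni", order: int | None = None) -> CorrelationResult:
    """Convenience wrapper: fit a GGM and return its :class:`CorrelationResult`."""
    return GaussianGraphicalModel(alpha=alpha, correction=correction, order=order).fit_result(X)


# ---------------------------------------------------------------------------
# stability diagnostics
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    mean: float
    sd: float
    n_replicates: int
    n_skipped: int


def _mean_abs_offdiag_diff(Z1: np.ndarray, Z2: np.ndarray) -> float:
    off = ~np.eye(Z1.shape[0], dtype=bool)
    return float(np.mean(np.abs(Z1[off] - Z2[off])))


def bootstrap_stability(X, B: int = 100, seed: int | None = None) -> StabilityReport:
    """Bootstrap robustness of the partial-correlation matrix.

    Draws B resamples of size n with replacement, refits the partial
    correlations, and reports mean and sd (over replicates) of the mean
    absolute off-diagonal difference from the original matrix.  Replicates
    with singular correlation matrices are skipped and counted.
    """
    if B < 2:
        raise ValueError("need at least two bootstrap replicates")
    arr, _ = _as_matrix(X)
    n = arr.shape[0]
    rng = np.random.default_rng(seed)
    Z0 = partial_matrix(pearson_matrix(arr))
    diffs = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            Zb = partial_matrix(pearson_matrix(arr[idx]))
        except (DegenerateDataError, IllConditionedError):
            skipped += 1
            continue
        diffs.append(_mean_abs_offdiag_diff(Zb, Z0))
    d = np.asarray(diffs)
    return StabilityReport(
        mean=float(d.mean()) if d.size else float("nan"),
        sd=float(d.std(ddof=1)) if d.size > 1 else float("nan"),
        n_replicates=len(diffs),
        n_skipped=skipped,
    )


def subsample_stability(
    X, sizes: list[int], reps: int = 100, seed: int | None = None
) -> pd.DataFrame:
    """Partial-correlation stability under decreasing sample size.

    For each requested size draws ``reps`` subsamples without replacement and
    reports the same difference statistic as :func:`bootstrap_stability`.
    Sizes at or below m (ill-conditioned by construction) are reported with
    all replicates skipped.
    """
    if reps < 2:
        raise ValueError("need at least two repetitions")
    arr, _ = _as_matrix(X)
    n, m = arr.shape
    if any(s > n for s in sizes):
        raise ValueError("subsample size exceeds available samples")
    rng = np.random.default_rng(seed)
    Z0 = partial_matrix(pearson_matrix(arr))
    rows = []
    for size in sizes:
        diffs = []
        skipped = 0
        for _ in range(reps):
            if size <= m:
                skipped += 1
                continue
            idx = rng.choice(n, size=size, replace=False)
            try:
                Zs = partial_matrix(pearson_matrix(arr[idx]))
            except (DegenerateDataError, IllConditionedError):
                skipped += 1
                continue
            diffs.append(_mean_abs_offdiag_diff(Zs, Z0))
        d = np.asarray(diffs)
        rows.append(
            {
                "size": size,
                "mean": float(d.mean()) if d.size else float("nan"),
                "sd": float(d.std(ddof=1)) if d.size > 1 else float("nan"),
                "n_replicates": len(diffs),
                "n_skipped": skipped,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# long-format export
# ---------------------------------------------------------------------------

def edge_table(result: CorrelationResult) -> pd.DataFrame:
    """Long-format table of all metabolite pairs with both correlation types."""
    ids = result.metabolite_ids
    sig = result.significant_partial("both")
    rows = []
    for i in range(result.m):
        for j in range(i + 1, result.m):
            rows.append(
                {
                    "met_a": ids[i],
                    "met_b": ids[j],
                    "pearson": result.P[i, j],
                    "partial": result.Z[i, j],
                    "p_pearson": result.p_pearson[i, j],
                    "p_partial": result.p_partial[i, j],
                    "significant": bool(sig[i, j]),
                }
            )
    return pd.DataFrame(rows)
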