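"""Multiple discriminant analysis of seed trait tables.

Implements, from first principles, the discrimination statistics used to
separate *Elatine* species and populations on the six seed descriptors:

* Wilks Λ = det(W)/det(T) with Rao's F approximation and its degrees of
  freedom (W = pooled within-group scatter, T = total scatter);
* per-variable diagnostics: partial Λ (ratio of the full model's Λ to the
  model without the variable), the F-to-remove statistic, tolerance
  (1 − R² of the variable on the remaining variables, pooled within groups);
* squared Mahalanobis distances between group centroids under the pooled
  within-group covariance;
* linear discriminant classification (resubstitution classification matrix)
  and canonical variates.

The estimator follows the scikit-learn protocol (fit / predict / transform,
fitted attributes with trailing underscores) and composes with sklearn
pipelines; the module-level functions are thin wrappers taking a labelled
trait table (a DataFrame) and a grouping column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .exceptions import SingularScatterError, TraitTableError
from .synthetic import TRAIT_COLUMNS

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class WilksReport:
    """Wilks Λ with Rao's F approximation."""

    lambda_: float
    df1: int
    df2: int
    F: float
    p_value: float

    def __str__(self) -> str:  # Table-2-style header line
        return (
            f"lambda = {self.lambda_:.5f}  "
            f"F({self.df1}, {self.df2}) = {self.F:.2f}  p = {self.p_value:.4g}"
        )


def rao_f_approx(lambda_: float, p: int, g: int, N: int) -> WilksReport:
    """Rao's F transformation of Wilks Λ.

    df1 = p(g−1); s = sqrt((p²(g−1)²−4)/(p²+(g−1)²−5)) (s = 1 when the
    denominator degenerates); df2 = s[(N−1)−(p+g)/2] − (p(g−1)−2)/2,
    floor-truncated to an integer for reporting and for the F statistic
    (the truncated-df convention of the classic implementations). With
    p = 1 this reduces exactly to the one-way ANOVA F on (g−1, N−g).
    """
    if not (0.0 < lambda_ <= 1.0):
        raise ValueError(f"lambda must be in (0, 1], got {lambda_}")
    if p < 1 or g < 2 or N <= p + g:
        raise ValueError(f"invalid dimensions p={p}, g={g}, N={N}")
    df1 = p * (g - 1)
    denom = p**2 + (g - 1) ** 2 - 5
    s = np.sqrt((p**2 * (g - 1) ** 2 - 4) / denom) if denom > 0 else 1.0
    df2 = int(np.floor(s * ((N - 1) - (p + g) / 2.0) - (df1 - 2) / 2.0))
    lam_s = lambda_ ** (1.0 / s)
    F = (1.0 - lam_s) / lam_s * (df2 / df1)
    return WilksReport(
        lambda_=float(lambda_),
        df1=df1,
        df2=df2,
        F=float(F),
        p_value=float(stats.f.sf(F, df1, df2)),
    )


def f_to_remove(partial_lambda: float, p: int, g: int, N: int) -> float:
    """F-to-remove from a partial Wilks Λ: ((1−Λp)/Λp)·((N−g−p+1)/(g−1))."""
    if not (0.0 < partial_lambda <= 1.0):
        raise ValueError(f"partial lambda must be in (0, 1], got {partial_lambda}")
    return float((1.0 - partial_lambda) / partial_lambda * ((N - g - p + 1) / (g - 1)))


# ---------------------------------------------------------------------------
# scatter matrices
# ---------------------------------------------------------------------------


def _scatters(X: np.ndarray, y: np.ndarray):
    classes, idx = np.unique(y, return_inverse=True)
    n, p = X.shape
    g = len(classes)
    if g < 2:
        raise TraitTableError("need at least two groups")
    sizes = np.bincount(idx)
    if sizes.min() < 2:
        small = classes[sizes.argmin()]
        raise TraitTableError(f"group {small!r} has fewer than 2 rows")
    if n - g < p:
        raise SingularScatterError(
            f"within-group scatter cannot be full rank: N−g = {n - g} < p = {p}"
        )
    means = np.stack([X[idx == k].mean(axis=0) for k in range(g)])
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    for k in range(g):
        d = X[idx == k] - means[k]
        W += d.T @ d
    db = means - grand
    B = (db.T * sizes) @ db
    T = W + B
    return classes, sizes, means, grand, W, B, T


def _safe_det_ratio(W: np.ndarray, T: np.ndarray) -> float:
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0 or np.linalg.cond(W) > _COND_LIMIT:
        raise SingularScatterError(
            "within-group scatter is singular or ill-conditioned; remove a "
            "redundant trait (check the tolerance column of the diagnostics)"
        )
    return float(np.exp(logdet_w - logdet_t))


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class SeedDiscriminantAnalysis(BaseEstimator, ClassifierMixin, TransformerMixin):
    """Linear discriminant analysis with the survey's reporting conventions.

    Parameters
    ----------
    priors : {"equal", "proportional"}
        Class priors for classification. "equal" matches the default used
        for the published classification matrices.
    n_components : int, optional
        Number of canonical variates kept by :meth:`transform`
        (default min(p, g−1)).

    Attributes (after fit)
    ----------------------
    classes_, feature_names_in_, means_, pooled_covariance_,
    wilks_lambda_, wilks_report_ : overall Λ and its Rao F report
    eigenvalues_ : canonical eigenvalues of W⁻¹B (descending)
    scalings_ : canonical coefficients, unit pooled within-group variance,
        sign fixed so each variate's largest-magnitude coefficient is positive
    diagnostics_ : per-trait DataFrame (partial_lambda, F_to_remove, df,
        p_value, tolerance, r_squared)
    mahalanobis_sq_ : DataFrame of squared centroid distances D²
    """

    def __init__(self, priors: str = "equal", n_components: int | None = None):
        self.priors = priors
        self.n_components = n_components

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        X, feature_names = _as_matrix(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if not np.isfinite(X).all():
            raise TraitTableError("X contains NaN or infinite values")
        if self.priors not in ("equal", "proportional"):
            raise ValueError("priors must be 'equal' or 'proportional'")
        classes, sizes, means, grand, W, B, T = _scatters(X, y)
        n, p = X.shape
        g = len(classes)
        self.classes_ = classes
        self.feature_names_in_ = np.asarray(feature_names)
        self.n_features_in_ = p
        self.group_sizes_ = pd.Series(sizes, index=classes, name="n")
        self.means_ = pd.DataFrame(means, index=classes, columns=feature_names)
        self.grand_mean_ = pd.Series(grand, index=feature_names)
        self._W, self._B, self._T = W, B, T
        self._n, self._g = n, g

        self.wilks_lambda_ = _safe_det_ratio(W, T)
        self.wilks_report_ = rao_f_approx(self.wilks_lambda_, p, g, n)
        self.pooled_covariance_ = pd.DataFrame(
            W / (n - g), index=feature_names, columns=feature_names
        )

        # canonical variates: B a = λ W a, scaled to unit pooled variance
        evals, evecs = linalg.eigh(B, W)
        order = np.argsort(evals)[::-1]
        k = min(p, g - 1)
        evals, evecs = evals[order][:k], evecs[:, order][:, :k]
        Sp = W / (n - g)
        scal = np.empty_like(evecs)
        for j in range(evecs.shape[1]):
            a = evecs[:, j]
            a = a / np.sqrt(a @ Sp @ a)
            if a[np.argmax(np.abs(a))] < 0:
                a = -a
            scal[:, j] = a
        self.eigenvalues_ = np.clip(evals, 0.0, None)
        self.scalings_ = pd.DataFrame(
            scal,
            index=feature_names,
            columns=[f"can{j + 1}" for j in range(scal.shape[1])],
        )

        self.mahalanobis_sq_ = self._mahalanobis(means, Sp, classes)
        self.diagnostics_ = self._diagnostics(X, y, W, feature_names) if p > 1 else None
        self._log_priors = self._compute_log_priors(sizes, n)
        return self

    @staticmethod
    def _mahalanobis(means, Sp, classes) -> pd.DataFrame:
        Si = np.linalg.inv(Sp)
        diff = means[:, None, :] - means[None, :, :]
        d2 = np.einsum("ijk,kl,ijl->ij", diff, Si, diff)
        d2 = 0.5 * (d2 + d2.T)  # symmetrize rounding noise
        np.fill_diagonal(d2, 0.0)
        return pd.DataFrame(d2, index=classes, columns=classes)

    def _diagnostics(self, X, y, W, feature_names) -> pd.DataFrame:
        n, p = X.shape
        g = self._g
        lam_full = self.wilks_lambda_
        rows = []
        dfn, dfd = g - 1, n - g - p + 1
        # pooled within-group correlations drive tolerance / R²
        sd = np.sqrt(np.diag(W))
        R = W / np.outer(sd, sd)
        Rinv = np.linalg.inv(R)
        for i, name in enumerate(feature_names):
            keep = [j for j in range(p) if j != i]
            _, _, _, _, Wi, _, Ti = _scatters(X[:, keep], y)
            lam_wo = _safe_det_ratio(Wi, Ti)
            partial = lam_full / lam_wo
            F = f_to_remove(partial, p, g, n)
            tol = 1.0 / Rinv[i, i]
            rows.append(
                {
                    "trait": name,
                    "wilks_lambda": lam_wo * partial,  # = model Λ, repeated per row
                    "partial_lambda": partial,
                    "F_to_remove": F,
                    "df1": dfn,
                    "df2": dfd,
                    "p_value": float(stats.f.sf(F, dfn, dfd)),
                    "tolerance": tol,
                    "r_squared": 1.0 - tol,
                }
            )
        return pd.DataFrame(rows).set_index("trait")

    def _compute_log_priors(self, sizes, n):
        if self.priors == "proportional":
            return np.log(sizes / n)
        return np.zeros(len(sizes))

    # -- prediction ---------------------------------------------------------

    def decision_function(self, X):
        X, _ = _as_matrix(X, self.feature_names_in_)
        Si = np.linalg.inv(self.pooled_covariance_.to_numpy())
        M = self.means_.to_numpy()
        lin = X @ Si @ M.T
        const = -0.5 * np.einsum("kj,jl,kl->k", M, Si, M) + self._log_priors
        return lin + const

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def transform(self, X):
        """Canonical variate scores (centred at the grand mean)."""
        X, _ = _as_matrix(X, self.feature_names_in_)
        k = self.n_components or self.scalings_.shape[1]
        return (X - self.grand_mean_.to_numpy()) @ self.scalings_.to_numpy()[:, :k]

    # -- reports ------------------------------------------------------------

    def classification_matrix(self, X, y) -> "ClassificationResult":
        """Resubstitution classification-count matrix for labelled data."""
        pred = self.predict(X)
        y = np.asarray(y)
        counts = pd.crosstab(
            pd.Series(y, name="true"), pd.Series(pred, name="assigned")
        ).reindex(index=self.classes_, columns=self.classes_, fill_value=0)
        return ClassificationResult(counts=counts)


def _as_matrix(X, expected_names=None):
    if isinstance(X, pd.DataFrame):
        if expected_names is not None:
            X = X[list(expected_names)]
        names = list(X.columns)
        return X.to_numpy(dtype=float), names
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    names = (
        list(expected_names)
        if expected_names is not None
        else [f"x{i}" for i in range(X.shape[1])]
    )
    return X, names


# ---------------------------------------------------------------------------
# classification summaries
# ---------------------------------------------------------------------------


@dataclass
class ClassificationSummary:
    """Summary in the published table's layout."""

    percent_correct: pd.Series  # per group, rounded half-up to integers
    overall_percent: int
    total_classified: pd.Series  # per assigned-group column
    correct_minus_classified: pd.Series  # group size − column total
    n: int


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def summarize_classification(counts: pd.DataFrame) -> ClassificationSummary:
    """Percent-correct and bookkeeping rows recomputed from a count matrix."""
    counts = counts.astype(int)
    if (counts < 0).any().any():
        raise ValueError("counts must be nonnegative")
    row_sums = counts.sum(axis=1)
    if (row_sums == 0).any():
        zero = row_sums[row_sums == 0].index[0]
        raise ValueError(f"group {zero!r} has no classified rows")
    diag = pd.Series(np.diag(counts.to_numpy()), index=counts.index)
    pct = pd.Series(_round_half_up(100.0 * diag / row_sums), index=counts.index)
    overall = int(_round_half_up(100.0 * diag.sum() / row_sums.sum()))
    col_tot = counts.sum(axis=0)
    return ClassificationSummary(
        percent_correct=pct,
        overall_percent=overall,
        total_classified=col_tot,
        correct_minus_classified=row_sums - col_tot,
        n=int(row_sums.sum()),
    )


@dataclass
class ClassificationResult:
    counts: pd.DataFrame

    @property
    def summary(self) -> ClassificationSummary:
        return summarize_classification(self.counts)


# ---------------------------------------------------------------------------
# table-level wrappers
# ---------------------------------------------------------------------------


def _table_xy(table: pd.DataFrame, grouping: str, traits=None):
    if grouping not in table.columns:
        raise TraitTableError(f"grouping column {grouping!r} missing")
    traits = list(traits) if traits is not None else [
        c for c in TRAIT_COLUMNS if c in table.columns
    ]
    missing = [c for c in traits if c not in table.columns]
    if missing:
        raise TraitTableError(f"missing trait columns: {missing}")
    sub = table[traits]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()[:5]
        raise TraitTableError(f"NaN trait values in rows {bad}")
    return sub, table[grouping].to_numpy()


def fit_discriminant(
    table: pd.DataFrame, grouping: str = "species", traits=None, priors: str = "equal"
) -> SeedDiscriminantAnalysis:
    X, y = _table_xy(table, grouping, traits)
    return SeedDiscriminantAnalysis(priors=priors).fit(X, y)


def wilks_lambda(table: pd.DataFrame, grouping: str = "species", traits=None) -> float:
    """Overall Wilks Λ of the grouping on the chosen traits."""
    return fit_discriminant(table, grouping, traits).wilks_lambda_


def variable_diagnostics(
    table: pd.DataFrame, grouping: str = "species", traits=None
) -> pd.DataFrame:
    """Partial Λ, F-to-remove, tolerance and R² per trait."""
    model = fit_discriminant(table, grouping, traits)
    if model.diagnostics_ is None:
        raise ValueError("diagnostics require at least two traits")
    return model.diagnostics_


def mahalanobis_matrix(
    table: pd.DataFrame, grouping: str = "species", traits=None
) -> pd.DataFrame:
    """Squared Mahalanobis distances D² between group centroids."""
    return fit_discriminant(table, grouping, traits).mahalanobis_sq_


def lda_classify(
    table: pd.DataFrame,
    grouping: str = "species",
    traits=None,
    priors: str = "equal",
) -> ClassificationResult:
    """Resubstitution linear-discriminant classification matrix."""
    model = fit_discriminant(table, grouping, traits, priors=priors)
    X, y = _table_xy(table, grouping, traits)
    return model.classification_matrix(X, y)


def canonical_scores(
    table: pd.DataFrame, grouping: str = "species", traits=None
) -> pd.DataFrame:
    """Per-seed scores on the canonical variates (unit pooled variance)."""
    model = fit_discriminant(table, grouping, traits)
    X, y = _table_xy(table, grouping, traits)
    scores = model.transform(X)
    out = pd.DataFrame(scores, columns=list(model.scalings_.columns), index=table.index)
    out.insert(0, grouping, y)
    return out
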