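"""Second-order response-surface model: representation, fitting, ANOVA.

The model for k coded factors is the full quadratic polynomial

    y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j

with 1 + 2k + k(k-1)/2 coefficients.  Fitting is ordinary least squares
via an orthogonal decomposition of the model matrix (never the normal
equations), the ANOVA reports partial (drop-one-term) sums of squares,
and replicated runs feed a lack-of-fit test against pure error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignTable

__all__ = [
    "QuadraticModel",
    "FitResult",
    "AnovaTable",
    "LackOfFitResult",
    "fit",
    "lack_of_fit_test",
    "partial_correlation",
    "simplify",
    "drop_insignificant",
    "main_effect_ranking",
]


def _term_labels(k: int) -> list[str]:
    """Coefficient labels: b0, b1..bk, b11..bkk, then b12, b13, ... (i<j)."""
    labels = ["b0"] + [f"b{i + 1}" for i in range(k)] + [f"b{i + 1}{i + 1}" for i in range(k)]
    labels += [f"b{i + 1}{j + 1}" for i in range(k) for j in range(i + 1, k)]
    return labels


@dataclass
class QuadraticModel:
    """Full second-order polynomial in coded factors.

    ``linear`` and ``quadratic`` are length-k vectors; ``interaction``
    is a symmetric (k, k) matrix with zero diagonal whose (i, j) entry
    is the coefficient of ``x_i * x_j``.
    """

    factors: list[str]
    intercept: float
    linear: np.ndarray
    quadratic: np.ndarray
    interaction: np.ndarray

    def __post_init__(self) -> None:
        k = self.k
        self.linear = np.asarray(self.linear, dtype=float).reshape(k)
        self.quadratic = np.asarray(self.quadratic, dtype=float).reshape(k)
        inter = np.asarray(self.interaction, dtype=float)
        if inter.shape != (k, k):
            raise ValueError(f"interaction matrix must be ({k}, {k}), got {inter.shape}")
        inter = np.triu(inter, 1) + np.triu(inter, 1).T  # enforce symmetry, zero diagonal
        self.interaction = inter

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_terms(self) -> int:
        k = self.k
        return 1 + 2 * k + k * (k - 1) // 2

    @classmethod
    def from_coefficients(
        cls, factors: Sequence[str], coefficients: Mapping[str, float]
    ) -> "QuadraticModel":
        """Build from a label->value map (``b0``, ``b1``, ``b11``, ``b12``...).

        Missing labels default to 0, so reduced models round-trip too.
        """
        k = len(factors)
        linear = np.zeros(k)
        quad = np.zeros(k)
        inter = np.zeros((k, k))
        for i in range(k):
            linear[i] = coefficients.get(f"b{i + 1}", 0.0)
            quad[i] = coefficients.get(f"b{i + 1}{i + 1}", 0.0)
            for j in range(i + 1, k):
                inter[i, j] = coefficients.get(f"b{i + 1}{j + 1}", 0.0)
        return cls(
            factors=list(factors),
            intercept=float(coefficients.get("b0", 0.0)),
            linear=linear,
            quadratic=quad,
            interaction=inter,
        )

    def coefficients(self) -> dict[str, float]:
        out = {"b0": float(self.intercept)}
        for i in range(self.k):
            out[f"b{i + 1}"] = float(self.linear[i])
        for i in range(self.k):
            out[f"b{i + 1}{i + 1}"] = float(self.quadratic[i])
        for i in range(self.k):
            for j in range(i + 1, self.k):
                out[f"b{i + 1}{j + 1}"] = float(self.interaction[i, j])
        return out

    def evaluate(self, point: Sequence[float] | np.ndarray) -> float | np.ndarray:
        """Predicted response at one coded point or an (n, k) batch."""
        x = np.asarray(point, dtype=float)
        single = x.ndim == 1
        x = np.atleast_2d(x)
        if x.shape[1] != self.k:
            raise ValueError(f"point has dimension {x.shape[1]}, model has k={self.k}")
        y = (
            self.intercept
            + x @ self.linear
            + (x**2) @ self.quadratic
            + 0.5 * np.einsum("ni,ij,nj->n", x, self.interaction, x)
        )
        return float(y[0]) if single else y

    __call__ = evaluate

    def gradient(self, point: Sequence[float]) -> np.ndarray:
        x = np.asarray(point, dtype=float)
        return self.linear + 2.0 * self.quadratic * x + self.interaction @ x

    def to_dict(self) -> dict:
        return {"factors": list(self.factors), "coefficients": self.coefficients()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "QuadraticModel":
        return cls.from_coefficients(d["factors"], d["coefficients"])


# ---------------------------------------------------------------------------
# Model matrix and least-squares fit


def _term_names(factors: Sequence[str]) -> list[str]:
    k = len(factors)
    names = ["intercept"]
    names += [f"{factors[i]}" for i in range(k)]
    names += [f"{factors[i]}^2" for i in range(k)]
    names += [f"{factors[i]}*{factors[j]}" for i in range(k) for j in range(i + 1, k)]
    return names


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """Columns ordered intercept, linear, pure-quadratic, interactions (i<j)."""
    x = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = x.shape
    cols = [np.ones(n)]
    cols += [x[:, i] for i in range(k)]
    cols += [x[:, i] ** 2 for i in range(k)]
    cols += [x[:, i] * x[:, j] for i in range(k) for j in range(i + 1, k)]
    return np.column_stack(cols)


@dataclass
class AnovaTable:
    """Per-term partial-SS ANOVA plus the regression/residual partition.

    ``terms`` has one row per non-intercept model term (SS, df, MS, F,
    partial correlation, p).  The partition rows report regression,
    residual ("remainder"), lack of fit ("misfit"), pure error and
    total.  Lack-of-fit rows are NaN when the design has no replicates.
    """

    terms: pd.DataFrame
    ss_regression: float
    df_regression: int
    ss_residual: float
    df_residual: int
    ss_lack_of_fit: float
    df_lack_of_fit: int
    ss_pure_error: float
    df_pure_error: int
    ss_total: float
    df_total: int
    f_regression: float
    p_regression: float

    @property
    def has_pure_error(self) -> bool:
        return self.df_pure_error > 0

    def to_frame(self) -> pd.DataFrame:
        rows = self.terms.copy()
        ms_res = self.ss_residual / self.df_residual if self.df_residual else math.nan
        extra = pd.DataFrame(
            {
                "SS": [self.ss_regression, self.ss_residual, self.ss_lack_of_fit,
                       self.ss_pure_error, self.ss_total],
                "df": [self.df_regression, self.df_residual, self.df_lack_of_fit,
                       self.df_pure_error, self.df_total],
                "MS": [
                    self.ss_regression / self.df_regression if self.df_regression else math.nan,
                    ms_res,
                    self.ss_lack_of_fit / self.df_lack_of_fit if self.df_lack_of_fit > 0 else math.nan,
                    self.ss_pure_error / self.df_pure_error if self.df_pure_error > 0 else math.nan,
                    math.nan,
                ],
                "F": [self.f_regression, math.nan, math.nan, math.nan, math.nan],
                "partial_r": math.nan,
                "p": [self.p_regression, math.nan, math.nan, math.nan, math.nan],
            },
            index=["regression", "residual", "lack_of_fit", "pure_error", "total"],
        )
        return pd.concat([rows, extra])


@dataclass
class FitResult:
    """A fitted quadratic surface with its diagnostics."""

    model: QuadraticModel
    design: DesignTable
    fitted: np.ndarray
    residuals: np.ndarray
    anova: AnovaTable
    rss: float

    @property
    def term_pvalues(self) -> dict[str, float]:
        return dict(zip(self.anova.terms.index, self.anova.terms["p"]))


def _lstsq(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # identify collinear columns for the error message
        q, r = np.linalg.qr(X)
        bad = [i for i in range(X.shape[1]) if abs(r[i, i]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise np.linalg.LinAlgError(
            f"singular design: rank {rank} < {X.shape[1]} columns; "
            f"collinear column indices {bad}"
        )
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit(design: DesignTable) -> FitResult:
    """Least-squares fit of the full quadratic model to a design's responses.

    Pure-quadratic columns are centered about their column means while
    solving (reducing their collinearity with the intercept on a CCD);
    the coefficients are mapped back to the raw polynomial
    parameterization before being reported.
    """
    if design.response is None:
        raise ValueError("design has no responses to fit")
    y = design.response
    k = design.k
    X = model_matrix(design.coded)
    p = X.shape[1]
    n = len(y)
    if n <= p - 1:
        raise ValueError(f"need more runs ({n}) than model terms ({p}) to test the fit")

    quad_cols = slice(1 + k, 1 + 2 * k)
    means = X[:, quad_cols].mean(axis=0)
    Xc = X.copy()
    Xc[:, quad_cols] -= means
    beta, rss = _lstsq(Xc, y)
    beta = beta.copy()
    beta[0] -= beta[quad_cols] @ means  # undo centering: raw intercept

    labels = _term_labels(k)
    coef = dict(zip(labels, beta))
    qmodel = QuadraticModel.from_coefficients(design.factors, coef)
    fitted = X @ beta
    residuals = y - fitted

    anova_table = _anova(design, X, beta, rss)
    return FitResult(
        model=qmodel, design=design, fitted=fitted, residuals=residuals,
        anova=anova_table, rss=rss,
    )


def _anova(design: DesignTable, X: np.ndarray, beta: np.ndarray, rss: float) -> AnovaTable:
    y = design.response
    n, p = X.shape
    df_res = n - p
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_reg = ss_total - rss
    ms_res = rss / df_res if df_res > 0 else math.nan

    # partial (drop-one) SS for each non-intercept term
    term_names = _term_names(design.factors)
    records = []
    for j in range(1, p):
        keep = [c for c in range(p) if c != j]
        _, rss_red = _lstsq(X[:, keep], y)
        ss_j = max(rss_red - rss, 0.0)
        F_j = ss_j / ms_res if df_res > 0 and ms_res > 0 else math.inf if ss_j > 0 else 0.0
        p_j = float(stats.f.sf(F_j, 1, df_res)) if np.isfinite(F_j) else 0.0
        r_j = math.copysign(math.sqrt(F_j / (F_j + df_res)), beta[j]) if np.isfinite(F_j) else math.copysign(1.0, beta[j])
        records.append((term_names[j], ss_j, 1, ss_j, F_j, r_j, p_j))
    terms = pd.DataFrame(
        records, columns=["term", "SS", "df", "MS", "F", "partial_r", "p"]
    ).set_index("term")

    # pure error from replicate groups
    ss_pe, df_pe = 0.0, 0
    for idx in design.replicate_groups():
        if len(idx) > 1:
            ss_pe += float(np.sum((y[idx] - y[idx].mean()) ** 2))
            df_pe += len(idx) - 1
    ss_lof = rss - ss_pe if df_pe > 0 else math.nan
    df_lof = df_res - df_pe if df_pe > 0 else 0

    df_reg = p - 1
    F_reg = (ss_reg / df_reg) / ms_res if df_res > 0 and ms_res > 0 else math.inf
    p_reg = float(stats.f.sf(F_reg, df_reg, df_res)) if np.isfinite(F_reg) else 0.0

    return AnovaTable(
        terms=terms,
        ss_regression=ss_reg, df_regression=df_reg,
        ss_residual=rss, df_residual=df_res,
        ss_lack_of_fit=ss_lof if df_pe > 0 else math.nan, df_lack_of_fit=df_lof,
        ss_pure_error=ss_pe if df_pe > 0 else math.nan, df_pure_error=df_pe,
        ss_total=ss_total, df_total=n - 1,
        f_regression=F_reg, p_regression=p_reg,
    )


@dataclass
class LackOfFitResult:
    f_statistic: float
    df_lack_of_fit: int
    df_pure_error: int
    critical_value: float
    alpha: float
    adequate: bool
    caveat: str = ""


def lack_of_fit_test(anova: AnovaTable, alpha: float = 0.05) -> LackOfFitResult:
    """Compare misfit mean square to pure-error mean square.

    The model is declared adequate when F_lof stays below the upper-alpha
    F quantile at (df_lof, df_pe).  A zero pure-error mean square with
    nonzero misfit is reported as inadequate with a caveat instead of a
    division blow-up.
    """
    if anova.df_pure_error < 1 or anova.df_lack_of_fit < 1:
        raise ValueError("lack-of-fit test requires replicate runs and misfit df >= 1")
    ms_lof = anova.ss_lack_of_fit / anova.df_lack_of_fit
    ms_pe = anova.ss_pure_error / anova.df_pure_error
    crit = float(stats.f.ppf(1 - alpha, anova.df_lack_of_fit, anova.df_pure_error))
    if ms_pe == 0:
        if ms_lof == 0:
            return LackOfFitResult(0.0, anova.df_lack_of_fit, anova.df_pure_error,
                                   crit, alpha, adequate=True)
        return LackOfFitResult(math.inf, anova.df_lack_of_fit, anova.df_pure_error,
                               crit, alpha, adequate=False,
                               caveat="pure-error mean square is zero; F is unbounded")
    f_lof = ms_lof / ms_pe
    return LackOfFitResult(f_lof, anova.df_lack_of_fit, anova.df_pure_error,
                           crit, alpha, adequate=f_lof < crit)


def partial_correlation(f_statistic: float, df_residual: int, coefficient_sign: float = 1.0) -> float:
    """Signed partial correlation of a term: sign(b) * sqrt(F / (F + df))."""
    if not np.isfinite(f_statistic):
        return math.copysign(1.0, coefficient_sign)
    r = math.sqrt(f_statistic / (f_statistic + df_residual))
    return math.copysign(r, coefficient_sign) if coefficient_sign != 0 else r


def drop_insignificant(
    model: QuadraticModel, pvalues: Mapping[str, float], alpha: float = 0.10
) -> tuple[QuadraticModel, list[str]]:
    """Zero out non-intercept terms whose p-value exceeds ``alpha``.

    Retained coefficients keep their full-model values — re-estimating
    the reduced model is deliberately not done, so the simplified
    polynomial is the full model with insignificant terms removed.
    Returns the reduced model and the list of dropped term names.
    """
    coef = model.coefficients()
    names = _term_names(model.factors)
    labels = _term_labels(model.k)
    dropped = []
    for name, label in zip(names[1:], labels[1:]):
        if name in pvalues and pvalues[name] > alpha and coef[label] != 0.0:
            coef[label] = 0.0
            dropped.append(name)
    return QuadraticModel.from_coefficients(model.factors, coef), dropped


def simplify(fit_result: FitResult, alpha: float = 0.10) -> tuple[QuadraticModel, list[str]]:
    """Apply the alpha-threshold term screen to a fitted model."""
    return drop_insignificant(fit_result.model, fit_result.term_pvalues, alpha)


def main_effect_ranking(model: QuadraticModel) -> list[str]:
    """Factors ordered by decreasing |linear coefficient|.

    On a coded (dimensionless) design the linear coefficients are
    directly comparable, so their magnitudes rank the factors' main
    effects on the response.
    """
    order = np.argsort(-np.abs(model.linear), kind="stable")
    return [model.factors[i] for i in order]
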