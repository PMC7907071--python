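"""Individual-effect estimation for case-control data.

Crude odds ratios with Woolf (log-normal) confidence intervals and the
Haldane-Anscombe zero-cell correction, the classical 2x2 chi-square and
pooled-variance t tests, and unconditional maximum-likelihood logistic
regression (Newton/IRLS via statsmodels) reported in the conventional
B / SE / Wald / df / p / OR / CI layout.

The matched design is analysed unconditionally throughout: no conditional
likelihood is fitted, matching the crude/unconditional analyses this
package reproduces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cohort import SubjectRecord, VariableCodebook
from .errors import DomainError, SingularDesignError
from .tables import FourfoldTable

logger = logging.getLogger(__name__)


def z_quantile(level: float) -> float:
    """Two-sided standard-normal quantile for a confidence level."""
    if not 0 < level < 1:
        raise DomainError(f"confidence level {level} outside (0,1)")
    return float(stats.norm.ppf(0.5 + level / 2))


@dataclass(frozen=True)
class OddsRatioEstimate:
    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "woolf"
    corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise DomainError("odds-ratio CI does not contain the point estimate")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float


@dataclass(frozen=True)
class CoefficientEstimate:
    name: str
    b: float
    se: float
    wald: float
    df: int
    p: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float


@dataclass(frozen=True)
class LogisticFit:
    coefficients: tuple[CoefficientEstimate, ...]
    converged: bool
    iterations: int
    log_likelihood: float

    def __getitem__(self, name: str) -> CoefficientEstimate:
        for coef in self.coefficients:
            if coef.name == name:
                return coef
        raise KeyError(name)


def crude_or(table: FourfoldTable, level: float = 0.95) -> OddsRatioEstimate:
    """Crude odds ratio ad/bc with the Woolf log-normal confidence interval.

    A table containing a zero cell receives the Haldane-Anscombe +0.5
    correction first and the estimate is flagged ``corrected``.
    """
    corrected = table.has_zero_cell()
    t = table.corrected() if corrected else table
    a, b, c, d = t.counts
    point = (a * d) / (b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = z_quantile(level)
    log_or = float(np.log(point))
    return OddsRatioEstimate(
        point=point,
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        level=level,
        method="woolf",
        corrected=corrected,
    )


def chi_square_2x2(table: FourfoldTable) -> ChiSquareResult:
    """Pearson chi-square for a 2x2 table: N(ad-bc)^2 / product of margins."""
    a, b, c, d = table.counts
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if min(margins) == 0:
        raise DomainError("chi-square undefined: zero margin")
    n = table.total
    statistic = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    return ChiSquareResult(
        statistic=float(statistic), df=1, p_value=float(stats.chi2.sf(statistic, 1))
    )


def t_test_two_sample(
    values_cases: Sequence[float], values_controls: Sequence[float]
) -> TTestResult:
    """Pooled-variance (Student) two-sample t test; df = n1 + n2 - 2."""
    if len(values_cases) < 2 or len(values_controls) < 2:
        raise DomainError("each group needs at least 2 values")
    res = stats.ttest_ind(values_cases, values_controls, equal_var=True)
    return TTestResult(
        statistic=float(res.statistic),
        df=float(len(values_cases) + len(values_controls) - 2),
        p_value=float(res.pvalue),
    )


def _covariate_score(
    record: SubjectRecord, variable: str, codebook: VariableCodebook
) -> float | None:
    """Numeric code of one covariate: ordinal level index (binary '0'/'1' as is)."""
    level = record.exposures.get(variable)
    if level is None:
        return None
    if level in ("0", "1"):
        return float(level)
    return float(codebook[variable].level_score(level))


def build_design(
    records: Sequence[SubjectRecord],
    covariates: Sequence[str],
    codebook: VariableCodebook,
    adjust_for_sex: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix (with intercept), outcome vector and column names.

    Covariates enter as integer level scores per the codebook's level order,
    so each contributes a single degree of freedom.  Records missing any
    requested covariate are excluded (listwise within this model).
    """
    names = ["constant"] + list(covariates) + (["sex"] if adjust_for_sex else [])
    rows: list[list[float]] = []
    y: list[float] = []
    n_dropped = 0
    for rec in records:
        scores = [_covariate_score(rec, v, codebook) for v in covariates]
        if any(s is None for s in scores):
            n_dropped += 1
            continue
        row = [1.0] + [float(s) for s in scores]  # type: ignore[arg-type]
        if adjust_for_sex:
            row.append(float(codebook["sex"].level_score(rec.sex)))
        rows.append(row)
        y.append(1.0 if rec.is_case else 0.0)
    if n_dropped:
        logger.info("design matrix: %d records dropped for missingness", n_dropped)
    if not rows:
        raise DomainError("no complete records for the requested covariates")
    return np.asarray(rows), np.asarray(y), names


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns responsible for rank deficiency (QR pivot diagnostic)."""
    from scipy.linalg import qr

    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return sorted(names[j] for j in piv[rank:])


def fit_logistic(
    records: Sequence[SubjectRecord],
    covariates: Sequence[str],
    codebook: VariableCodebook,
    adjust_for_sex: bool = False,
    level: float = 0.95,
    max_iter: int = 50,
) -> LogisticFit:
    """Unconditional logistic regression of case status on coded covariates.

    Maximum likelihood via Newton iteration (iteratively reweighted least
    squares); Wald statistics are (B/SE)^2 on 1 df and OR intervals are
    exp(B -/+ z SE).  A rank-deficient design raises
    :class:`SingularDesignError` naming the collinear columns; a fit that
    fails to converge within ``max_iter`` iterations is returned with
    ``converged=False`` rather than raised.
    """
    x, y, names = build_design(records, covariates, codebook, adjust_for_sex)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise SingularDesignError(_collinear_columns(x, names))
    if y.min() == y.max():
        raise DomainError("outcome is constant; logistic model undefined")

    model = sm.Logit(y, x)
    with np.errstate(all="ignore"):
        result = model.fit(method="newton", maxiter=max_iter, tol=1e-10, disp=0)

    z = z_quantile(level)
    coefs = []
    for j, name in enumerate(names):
        b = float(result.params[j])
        se = float(result.bse[j])
        wald = (b / se) ** 2 if se > 0 else float("inf")
        coefs.append(
            CoefficientEstimate(
                name=name,
                b=b,
                se=se,
                wald=wald,
                df=1,
                p=float(stats.chi2.sf(wald, 1)),
                odds_ratio=float(np.exp(b)),
                or_ci_low=float(np.exp(b - z * se)),
                or_ci_high=float(np.exp(b + z * se)),
            )
        )
    return LogisticFit(
        coefficients=tuple(coefs),
        converged=bool(result.mle_retvals.get("converged", False)),
        iterations=int(result.mle_retvals.get("iterations", max_iter)),
        log_likelihood=float(result.llf),
    )
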