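"""Additive-scale interaction between two binary exposures.

Given the 2x2x2 cross-classification of two exposures in a case-control
study, each non-reference stratum gets an odds ratio against the
double-unexposed cell:

    OR10 (exposure 1 only), OR01 (exposure 2 only), OR11 (both).

Departure from additivity of the excess odds is summarised by

    RERI = OR11 - OR10 - OR01 + 1
    SI   = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1))
    AP   = RERI / OR11
    PAP  = RERI / (OR11 - 1)

RERI = 0 (equivalently SI = 1) under exact additivity; RERI > 0 / SI > 1
indicate synergy.  AP is the fraction of the dual-exposure effect due to
interaction; PAP is the same fraction relative to the excess (above
baseline) effect only.  Case-control data identify odds ratios, so all
measures are OR approximations of their risk-ratio originals.

Two direction verdicts are reported side by side, because they are not
equivalent: the sum rule compares OR11 against OR10 + OR01 (departure from
RERI = 1), while the RERI sign tests departure from RERI = 0.

Interval estimation offers the delta method on the log-odds scale — the
covariance of the three stratum log odds ratios is the closed-form
covariance of the saturated two-factor logistic model — and a stratified
bootstrap that resamples cases and controls separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .association import OddsRatioEstimate, crude_or, z_quantile
from .errors import DomainError
from .tables import CELLS, REFERENCE_CELL, JointExposureTable, collapse_to_fourfold

NON_REFERENCE = ((0, 1), (1, 0), (1, 1))


def _require_positive_finite(**ors: float) -> None:
    for name, value in ors.items():
        if not math.isfinite(value) or value <= 0:
            raise DomainError(f"{name} must be positive and finite, got {value}")


def reri(or01: float, or10: float, or11: float) -> float:
    """Relative excess risk due to interaction: OR11 - OR10 - OR01 + 1."""
    _require_positive_finite(or01=or01, or10=or10, or11=or11)
    return or11 - or10 - or01 + 1.0


def synergy_index(or01: float, or10: float, or11: float) -> float | None:
    """Synergy index (OR11-1)/((OR10-1)+(OR01-1)); None when undefined.

    The denominator vanishes when the two individual excess effects cancel
    (e.g. both exposures null); the index is then undefined rather than
    infinite.
    """
    _require_positive_finite(or01=or01, or10=or10, or11=or11)
    denom = (or10 - 1.0) + (or01 - 1.0)
    if denom == 0.0:
        return None
    return (or11 - 1.0) / denom


def attributable_proportions(
    or01: float, or10: float, or11: float
) -> tuple[float, float | None]:
    """(AP, PAP) = (RERI/OR11, RERI/(OR11-1)); PAP is None when OR11 = 1.

    Both are returned as fractions; reports render them as percentages.
    """
    _require_positive_finite(or01=or01, or10=or10, or11=or11)
    excess = reri(or01, or10, or11)
    ap = excess / or11
    pap = excess / (or11 - 1.0) if or11 != 1.0 else None
    return ap, pap


def classify_direction(or01: float, or10: float, or11: float) -> tuple[str, str]:
    """Direction verdicts: (sum rule, RERI-sign rule).

    Sum rule: ``positive`` if OR11 > OR10 + OR01, ``reverse`` if smaller,
    ``additive`` if equal.  RERI rule: ``positive``/``negative``/``none``
    by the sign of OR11 - OR10 - OR01 + 1.  The two disagree whenever
    0 < RERI < 1.
    """
    _require_positive_finite(or01=or01, or10=or10, or11=or11)
    total = or10 + or01
    if or11 > total:
        sum_rule = "positive"
    elif or11 < total:
        sum_rule = "reverse"
    else:
        sum_rule = "additive"
    excess = or11 - total + 1.0
    if excess > 0:
        reri_rule = "positive"
    elif excess < 0:
        reri_rule = "negative"
    else:
        reri_rule = "none"
    return sum_rule, reri_rule


def joint_odds_ratios(
    joint: JointExposureTable, level: float = 0.95
) -> tuple[OddsRatioEstimate, OddsRatioEstimate, OddsRatioEstimate]:
    """Stratum odds ratios (or01, or10, or11) against the (0,0) reference."""
    ref_cases, ref_controls = joint.counts[REFERENCE_CELL]
    if ref_cases + 0.5 <= 0 or ref_controls + 0.5 <= 0:
        raise DomainError("reference cell empty; stratum odds ratios undefined")
    estimates = {
        cell: crude_or(collapse_to_fourfold(joint, cell), level=level)
        for cell in NON_REFERENCE
    }
    return estimates[(0, 1)], estimates[(1, 0)], estimates[(1, 1)]


# ---------------------------------------------------------------------------
# Interval estimation


@dataclass(frozen=True)
class InteractionCIs:
    """Confidence intervals for RERI, AP and SI."""

    reri: tuple[float, float]
    ap: tuple[float, float] | None
    si: tuple[float, float] | None
    method: str
    level: float
    reps: int = 0
    seed: int | None = None
    n_undefined: int = 0
    warning: str | None = None


def _corrected_counts(joint: JointExposureTable) -> dict[tuple[int, int], tuple[float, float]]:
    """Counts with Haldane +0.5 applied to every cell if any cell is zero."""
    flat = [v for pair in joint.counts.values() for v in pair]
    if min(flat) == 0:
        return {cell: (ca + 0.5, co + 0.5) for cell, (ca, co) in joint.counts.items()}
    return dict(joint.counts)


def _log_or_moments(
    joint: JointExposureTable,
) -> tuple[np.ndarray, np.ndarray]:
    """Log stratum ORs (order 10, 01, 11) and their asymptotic covariance.

    For stratum s with cases a_s and controls b_s against reference
    (a_0, b_0): var(ln OR_s) = 1/a_s + 1/b_s + 1/a_0 + 1/b_0 and
    cov(ln OR_s, ln OR_t) = 1/a_0 + 1/b_0 — the covariance of the
    saturated two-factor logistic maximum-likelihood fit.
    """
    counts = _corrected_counts(joint)
    a0, b0 = counts[REFERENCE_CELL]
    order = ((1, 0), (0, 1), (1, 1))
    log_ors = np.empty(3)
    var = np.empty(3)
    for i, cell in enumerate(order):
        a, b = counts[cell]
        log_ors[i] = math.log((a * b0) / (b * a0))
        var[i] = 1 / a + 1 / b + 1 / a0 + 1 / b0
    shared = 1 / a0 + 1 / b0
    cov = np.full((3, 3), shared)
    np.fill_diagonal(cov, var)
    return log_ors, cov


def delta_ci(joint: JointExposureTable, level: float = 0.95) -> InteractionCIs:
    """Delta-method intervals for RERI, AP and SI on the log-odds scale.

    RERI and AP intervals are symmetric on their own scale; the SI interval
    is computed on ln SI and exponentiated.  The SI interval is undefined
    (None) unless OR11 > 1 and OR10 + OR01 > 2.
    """
    log_ors, cov = _log_or_moments(joint)
    or10, or01, or11 = np.exp(log_ors)
    z = z_quantile(level)

    excess = or11 - or10 - or01 + 1.0
    grad = np.array([-or10, -or01, or11])
    se = math.sqrt(float(grad @ cov @ grad))
    reri_ci = (excess - z * se, excess + z * se)

    ap = excess / or11
    grad_ap = np.array(
        [-or10 / or11, -or01 / or11, (or10 + or01) / or11 - 1.0 / or11]
    )
    se_ap = math.sqrt(float(grad_ap @ cov @ grad_ap))
    ap_ci = (ap - z * se_ap, ap + z * se_ap)

    si_ci = None
    denom = or10 + or01 - 2.0
    if or11 > 1.0 and denom > 0.0:
        log_si = math.log(or11 - 1.0) - math.log(denom)
        grad_si = np.array([-or10 / denom, -or01 / denom, or11 / (or11 - 1.0)])
        se_si = math.sqrt(float(grad_si @ cov @ grad_si))
        si_ci = (math.exp(log_si - z * se_si), math.exp(log_si + z * se_si))

    return InteractionCIs(reri=reri_ci, ap=ap_ci, si=si_ci, method="delta", level=level)


def bootstrap_ci(
    joint: JointExposureTable,
    level: float = 0.95,
    reps: int = 2000,
    seed: int | None = None,
) -> InteractionCIs:
    """Percentile bootstrap resampling cases and controls separately.

    Each replicate redraws the case stratum counts from a multinomial on
    the observed case proportions (likewise controls), applies the zero-cell
    correction where needed, and recomputes RERI, AP and SI.  Replicates
    with an undefined SI are excluded from the SI interval and counted; if
    more than 10% of replicates are undefined a warning is attached.
    """
    if reps < 1000:
        raise DomainError("bootstrap requires at least 1000 replicates")
    if seed is None:
        raise DomainError("bootstrap requires an explicit seed")
    rng = np.random.default_rng(seed)

    n_cases = int(joint.n_cases)
    n_controls = int(joint.n_controls)
    if n_cases == 0 or n_controls == 0:
        raise DomainError("bootstrap requires cases and controls")
    p_cases = np.array([joint.cases(c) for c in CELLS], dtype=float) / n_cases
    p_controls = np.array([joint.controls(c) for c in CELLS], dtype=float) / n_controls

    case_draws = rng.multinomial(n_cases, p_cases, size=reps).astype(float)
    ctrl_draws = rng.multinomial(n_controls, p_controls, size=reps).astype(float)
    zero = (case_draws.min(axis=1) == 0) | (ctrl_draws.min(axis=1) == 0)
    case_draws[zero] += 0.5
    ctrl_draws[zero] += 0.5

    idx = {cell: i for i, cell in enumerate(CELLS)}
    a0, b0 = case_draws[:, idx[(0, 0)]], ctrl_draws[:, idx[(0, 0)]]

    def stratum_or(cell):
        a, b = case_draws[:, idx[cell]], ctrl_draws[:, idx[cell]]
        return (a * b0) / (b * a0)

    or10 = stratum_or((1, 0))
    or01 = stratum_or((0, 1))
    or11 = stratum_or((1, 1))

    excess = or11 - or10 - or01 + 1.0
    ap = excess / or11
    si_denom = (or10 - 1.0) + (or01 - 1.0)
    defined = si_denom != 0.0
    n_undefined = int((~defined).sum())

    alpha = 100 * (1 - level) / 2

    def percentile(values: np.ndarray) -> tuple[float, float]:
        return (
            float(np.percentile(values, alpha)),
            float(np.percentile(values, 100 - alpha)),
        )

    si_ci = None
    if defined.sum() > 0:
        si_values = (or11[defined] - 1.0) / si_denom[defined]
        si_ci = percentile(si_values)

    warning = None
    if n_undefined > 0.1 * reps:
        warning = (
            f"{n_undefined}/{reps} bootstrap replicates had an undefined "
            "synergy index"
        )

    return InteractionCIs(
        reri=percentile(excess),
        ap=percentile(ap),
        si=si_ci,
        method="bootstrap",
        level=level,
        reps=reps,
        seed=seed,
        n_undefined=n_undefined,
        warning=warning,
    )


def interaction_ci(
    joint: JointExposureTable,
    method: str = "delta",
    level: float = 0.95,
    reps: int = 2000,
    seed: int | None = None,
) -> InteractionCIs:
    """Dispatch to :func:`delta_ci` or :func:`bootstrap_ci`."""
    if method == "delta":
        return delta_ci(joint, level=level)
    if method == "bootstrap":
        return bootstrap_ci(joint, level=level, reps=reps, seed=seed)
    raise DomainError(f"unknown interval method {method!r}")


# ---------------------------------------------------------------------------
# Composite analysis


@dataclass(frozen=True)
class InteractionMeasures:
    """Full additive-interaction result for one exposure pair."""

    exposure_names: tuple[str, str]
    joint: JointExposureTable
    or01: OddsRatioEstimate
    or10: OddsRatioEstimate
    or11: OddsRatioEstimate
    reri: float
    si: float | None
    ap: float
    pap: float | None
    direction_sum_rule: str
    direction_reri: str
    cis: InteractionCIs | None = None


def measures_from_table(
    joint: JointExposureTable,
    level: float = 0.95,
    ci_method: str | None = "delta",
    reps: int = 2000,
    seed: int | None = None,
) -> InteractionMeasures:
    """All interaction measures for one 2x2x2 table."""
    or01, or10, or11 = joint_odds_ratios(joint, level=level)
    p01, p10, p11 = or01.point, or10.point, or11.point
    ap, pap = attributable_proportions(p01, p10, p11)
    sum_rule, reri_rule = classify_direction(p01, p10, p11)
    cis = (
        interaction_ci(joint, method=ci_method, level=level, reps=reps, seed=seed)
        if ci_method
        else None
    )
    return InteractionMeasures(
        exposure_names=joint.exposure_names,
        joint=joint,
        or01=or01,
        or10=or10,
        or11=or11,
        reri=reri(p01, p10, p11),
        si=synergy_index(p01, p10, p11),
        ap=ap,
        pap=pap,
        direction_sum_rule=sum_rule,
        direction_reri=reri_rule,
        cis=cis,
    )


def run_interaction_analysis(
    records,
    variable1: str,
    variable2: str,
    level: float = 0.95,
    ci_method: str | None = "delta",
    reps: int = 2000,
    seed: int | None = None,
) -> InteractionMeasures:
    """Cross-tabulate two dichotomized exposures and compute all measures."""
    from .tables import crosstab_joint

    joint = crosstab_joint(records, variable1, variable2)
    return measures_from_table(
        joint, level=level, ci_method=ci_method, reps=reps, seed=seed
    )
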