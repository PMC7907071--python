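"""Synthetic 1:1 matched case-control cohorts with known interaction truth.

A cohort is specified by the control-arm joint exposure distribution over
the four (e1, e2) strata and the three stratum odds ratios (OR01, OR10,
OR11) against the double-unexposed reference.  Cases are drawn from the
distribution proportional to control probability x stratum OR — a direct
construction in exposure-stratum space under which the population stratum
odds ratios equal the specified values exactly.  No latent disease model is
simulated: a case-control design identifies only the odds ratios, so the
construction loses nothing and makes the truth exact rather than
approximate.

Matching variables (sex, age) are generated independently of the exposures,
so matched and unmatched analyses agree asymptotically.  Under pair
matching each case-control pair shares its sex and the age gap is bounded
(default 5 years).  Optional extra variables are independent noise
exposures with equal prevalence in both arms.

One master seed drives everything; per-component substreams are derived
from it deterministically (numpy ``SeedSequence.spawn``), so an identical
spec yields a byte-identical cohort file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import SubjectRecord, Variable, VariableCodebook
from .errors import DomainError, GenerationError
from .interaction import attributable_proportions, reri, synergy_index
from .tables import CELLS, Cell, JointExposureTable

GENERATOR_NAME = "stratum-multinomial case-control generator (numpy PCG64)"


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Ground-truth parameters of a synthetic matched case-control cohort."""

    #: control-arm probability of each (e1, e2) exposure stratum
    control_joint_distribution: dict[Cell, float]
    #: (or01, or10, or11) against the (0,0) reference; or00 = 1 implicitly
    stratum_ors: tuple[float, float, float]
    n_cases: int = 342
    n_controls: int = 342
    matching: str = "pair"
    sex_ratio: float = 0.5  # fraction male
    age_range: tuple[int, int] = (28, 87)
    max_age_gap: int = 5
    exposure_names: tuple[str, str] = ("family_history", "diabetes")
    #: independent noise exposures: name -> prevalence (same in both arms)
    extra_variables: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = self.control_joint_distribution
        if set(probs) != set(CELLS):
            raise DomainError("control distribution must cover the four strata")
        for cell, p in probs.items():
            if not 0 < p < 1:
                raise DomainError(f"stratum probability {p} for {cell} outside (0,1)")
        if abs(sum(probs.values()) - 1.0) > 1e-12:
            raise DomainError("control stratum probabilities must sum to 1")
        for o in self.stratum_ors:
            if not math.isfinite(o) or o <= 0:
                raise DomainError(f"stratum OR {o} must be positive and finite")
        if self.matching not in ("none", "pair"):
            raise DomainError(f"unknown matching mode {self.matching!r}")
        if self.matching == "pair" and self.n_cases != self.n_controls:
            raise DomainError("pair matching requires n_cases == n_controls")
        if not 0 <= self.sex_ratio <= 1:
            raise DomainError("sex ratio outside [0,1]")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise DomainError("sample sizes must be positive")

    def stratum_or(self, cell: Cell) -> float:
        or01, or10, or11 = self.stratum_ors
        return {(0, 0): 1.0, (0, 1): or01, (1, 0): or10, (1, 1): or11}[cell]

    @property
    def case_joint_distribution(self) -> dict[Cell, float]:
        """Case stratum probabilities: control probability x OR, renormalised."""
        raw = {
            cell: p * self.stratum_or(cell)
            for cell, p in self.control_joint_distribution.items()
        }
        total = sum(raw.values())
        return {cell: v / total for cell, v in raw.items()}


def true_measures(spec: SyntheticCohortSpec) -> dict[str, float | None]:
    """The interaction measures implied exactly by the spec's stratum ORs."""
    or01, or10, or11 = spec.stratum_ors
    ap, pap = attributable_proportions(or01, or10, or11)
    return {
        "or01": or01,
        "or10": or10,
        "or11": or11,
        "reri": reri(or01, or10, or11),
        "si": synergy_index(or01, or10, or11),
        "ap": ap,
        "pap": pap,
    }


def expected_tables(spec: SyntheticCohortSpec) -> JointExposureTable:
    """Analytic expected (real-valued) joint counts: n x stratum probability.

    Feeding this table to the stratum odds-ratio machinery recovers the
    spec's ORs exactly, which makes it the closed-form oracle for recovery
    tests.
    """
    p_case = spec.case_joint_distribution
    p_ctrl = spec.control_joint_distribution
    counts = {
        cell: (spec.n_cases * p_case[cell], spec.n_controls * p_ctrl[cell])
        for cell in CELLS
    }
    return JointExposureTable(
        counts=counts, exposure_names=spec.exposure_names, label="expected"
    )


def sample_joint_table(
    spec: SyntheticCohortSpec,
    rng: np.random.Generator | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> JointExposureTable:
    """One multinomial draw of the joint stratum counts for both arms.

    This is the count-space core of :func:`generate_cohort`, exposed
    directly for simulation studies that need many replicate tables without
    materialising subject records.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_cases = spec.n_cases if n_cases is None else n_cases
    n_controls = spec.n_controls if n_controls is None else n_controls
    p_case = np.array([spec.case_joint_distribution[c] for c in CELLS])
    p_ctrl = np.array([spec.control_joint_distribution[c] for c in CELLS])
    case_counts = rng.multinomial(n_cases, p_case)
    ctrl_counts = rng.multinomial(n_controls, p_ctrl)
    return JointExposureTable(
        counts={
            cell: (int(case_counts[i]), int(ctrl_counts[i]))
            for i, cell in enumerate(CELLS)
        },
        exposure_names=spec.exposure_names,
    )


def _expand_strata(counts: np.ndarray, rng: np.random.Generator) -> list[Cell]:
    strata = [cell for i, cell in enumerate(CELLS) for _ in range(int(counts[i]))]
    order = rng.permutation(len(strata))
    return [strata[i] for i in order]


def generate_cohort(spec: SyntheticCohortSpec) -> list[SubjectRecord]:
    """Draw a full subject-level cohort from the spec.

    Exposures carry binary level codes ("0"/"1").  Under pair matching each
    case shares a ``pair_id`` and sex with one control and the age gap never
    exceeds ``spec.max_age_gap`` (control age is the case age plus a bounded
    offset, clipped into the age range).
    """
    lo, hi = spec.age_range
    if lo > hi or lo < 0:
        raise GenerationError(f"degenerate age range {spec.age_range}")
    if spec.matching == "pair" and hi - lo < 1:
        raise GenerationError("age range too narrow for matched-pair ages")

    ss = np.random.SeedSequence(spec.seed)
    rng_counts, rng_assign, rng_demo, rng_extra = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    p_case = np.array([spec.case_joint_distribution[c] for c in CELLS])
    p_ctrl = np.array([spec.control_joint_distribution[c] for c in CELLS])
    case_counts = rng_counts.multinomial(spec.n_cases, p_case)
    ctrl_counts = rng_counts.multinomial(spec.n_controls, p_ctrl)
    case_strata = _expand_strata(case_counts, rng_assign)
    ctrl_strata = _expand_strata(ctrl_counts, rng_assign)

    name1, name2 = spec.exposure_names
    extras = list(spec.extra_variables.items())

    def extra_values(rng: np.random.Generator) -> dict[str, str]:
        return {
            name: str(int(rng.random() < prev)) for name, prev in extras
        }

    records: list[SubjectRecord] = []
    if spec.matching == "pair":
        for i in range(spec.n_cases):
            sex = "male" if rng_demo.random() < spec.sex_ratio else "female"
            case_age = int(rng_demo.integers(lo, hi + 1))
            offset = int(rng_demo.integers(-spec.max_age_gap, spec.max_age_gap + 1))
            ctrl_age = int(np.clip(case_age + offset, lo, hi))
            pair = f"P{i + 1:06d}"
            for is_case, sid, stratum, age in (
                (True, f"C{i + 1:06d}", case_strata[i], case_age),
                (False, f"N{i + 1:06d}", ctrl_strata[i], ctrl_age),
            ):
                exposures = {name1: str(stratum[0]), name2: str(stratum[1])}
                exposures.update(extra_values(rng_extra))
                records.append(
                    SubjectRecord(
                        subject_id=sid,
                        is_case=is_case,
                        sex=sex,
                        age=age,
                        pair_id=pair,
                        exposures=exposures,
                    )
                )
    else:
        for arm, strata, prefix in (
            (True, case_strata, "C"),
            (False, ctrl_strata, "N"),
        ):
            for i, stratum in enumerate(strata):
                sex = "male" if rng_demo.random() < spec.sex_ratio else "female"
                age = int(rng_demo.integers(lo, hi + 1))
                exposures = {name1: str(stratum[0]), name2: str(stratum[1])}
                exposures.update(extra_values(rng_extra))
                records.append(
                    SubjectRecord(
                        subject_id=f"{prefix}{i + 1:06d}",
                        is_case=arm,
                        sex=sex,
                        age=age,
                        pair_id=None,
                        exposures=exposures,
                    )
                )
    return records


def simulated_codebook(spec: SyntheticCohortSpec) -> VariableCodebook:
    """Codebook matching the binary-coded variables a generated cohort carries."""
    identity = {"0": 0, "1": 1}
    variables = [
        Variable("hypertension", ("0", "1"), identity, "outcome"),
        Variable("sex", ("male", "female"), None, "matching"),
    ]
    for name in spec.exposure_names:
        variables.append(Variable(name, ("0", "1"), identity, "exposure"))
    for name in spec.extra_variables:
        variables.append(Variable(name, ("0", "1"), identity, "exposure"))
    return VariableCodebook({v.name: v for v in variables})


def write_truth_sidecar(spec: SyntheticCohortSpec, path: str | Path) -> None:
    """Write a YAML sidecar echoing the spec and its implied true measures."""
    doc = {
        "generator": GENERATOR_NAME,
        "seed": spec.seed,
        "n_cases": spec.n_cases,
        "n_controls": spec.n_controls,
        "matching": spec.matching,
        "exposure_names": list(spec.exposure_names),
        "control_joint_distribution": {
            f"{e1}{e2}": p for (e1, e2), p in spec.control_joint_distribution.items()
        },
        "stratum_ors": {
            "or01": spec.stratum_ors[0],
            "or10": spec.stratum_ors[1],
            "or11": spec.stratum_ors[2],
        },
        "true_measures": {
            k: (None if v is None else float(v)) for k, v in true_measures(spec).items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def table2_control_distribution() -> dict[Cell, float]:
    """Control-arm stratum distribution of the published family-history x
    diabetes table: counts (95, 16, 123, 36) over 270 controls."""
    counts = {(0, 0): 95, (0, 1): 16, (1, 0): 123, (1, 1): 36}
    total = sum(counts.values())
    return {cell: n / total for cell, n in counts.items()}
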