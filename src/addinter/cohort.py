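"""Subject-level data model for matched case-control cohorts.

A cohort is a collection of :class:`SubjectRecord` — one row per participant
carrying case/control status, sex, age, an optional matched-pair identifier
and a mapping of categorical exposure levels.  A :class:`VariableCodebook`
declares, per variable, the ordered level list, the collapse-to-binary recode
used by the interaction analyses (e.g. drinking ``occasionally``/``regular``
both count as exposed) and a role tag.

I/O is plain UTF-8 comma-separated text with a mandatory header row; the
empty string encodes a missing value.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import DomainError, FormatError, ValidationError

logger = logging.getLogger(__name__)

ROLES = ("exposure", "outcome", "matching", "descriptive")

#: Level codes produced by :func:`dichotomize`; values already in this set
#: pass through unchanged, which makes the recode idempotent.
BINARY_LEVELS = ("0", "1")


@dataclass(frozen=True)
class Variable:
    """One categorical variable: ordered levels, optional binary recode, role."""

    name: str
    levels: tuple[str, ...]
    binary_map: Mapping[str, int] | None = None
    role: str = "exposure"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"variable {self.name!r}: unknown role {self.role!r}")
        if len(set(self.levels)) != len(self.levels):
            raise ValidationError(f"variable {self.name!r}: duplicate levels")
        if self.binary_map is not None:
            missing = set(self.levels) - set(self.binary_map)
            if missing:
                raise ValidationError(
                    f"variable {self.name!r}: binary map not total, missing "
                    f"levels {sorted(missing)}"
                )
            image = set(self.binary_map.values())
            if not image <= {0, 1}:
                raise ValidationError(
                    f"variable {self.name!r}: binary map image {sorted(image)} "
                    "is not a subset of {0, 1}"
                )

    def level_score(self, level: str) -> int:
        """Integer score of a level = its index in the declared order."""
        try:
            return self.levels.index(level)
        except ValueError:
            raise ValidationError(
                f"level {level!r} not declared for variable {self.name!r}"
            ) from None


@dataclass
class VariableCodebook:
    """Declaration of every variable a cohort file may carry."""

    variables: dict[str, Variable]

    def __post_init__(self) -> None:
        outcomes = [v for v in self.variables.values() if v.role == "outcome"]
        if len(outcomes) != 1:
            raise ValidationError(
                f"codebook must declare exactly one outcome variable, found "
                f"{len(outcomes)}"
            )
        for name, var in self.variables.items():
            if name != var.name:
                raise ValidationError(f"codebook key {name!r} != variable {var.name!r}")

    def __getitem__(self, name: str) -> Variable:
        return self.variables[name]

    def __contains__(self, name: str) -> bool:
        return name in self.variables

    @property
    def outcome(self) -> Variable:
        return next(v for v in self.variables.values() if v.role == "outcome")

    def data_columns(self) -> list[str]:
        """Variable columns expected in a cohort file (everything non-outcome)."""
        return [n for n, v in self.variables.items() if v.role != "outcome"]

    # -- serialisation (YAML keyed by variable name) -------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            name: {
                "levels": list(v.levels),
                "binary_map": dict(v.binary_map) if v.binary_map is not None else None,
                "role": v.role,
            }
            for name, v in self.variables.items()
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VariableCodebook":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        variables = {
            name: Variable(
                name=name,
                levels=tuple(entry["levels"]),
                binary_map=entry.get("binary_map"),
                role=entry.get("role", "exposure"),
            )
            for name, entry in doc.items()
        }
        return cls(variables)


def default_codebook() -> VariableCodebook:
    """Codebook for the hypertension case-control study variables.

    Three-level lifestyle behaviours collapse to binary with
    ``occasionally``/``regular`` counting as exposed; taste is exposed only
    when ``salty``; work/life pressure is exposed for ``little`` or ``more``.
    """
    three_level = {"no": 0, "occasionally": 1, "regular": 1}
    variables = [
        Variable("hypertension", BINARY_LEVELS, {"0": 0, "1": 1}, "outcome"),
        Variable("sex", ("male", "female"), None, "matching"),
        Variable("family_history", ("no", "yes"), {"no": 0, "yes": 1}),
        Variable("diabetes", ("no", "yes"), {"no": 0, "yes": 1}),
        Variable("taste", ("light", "balance", "salty"), {"light": 0, "balance": 0, "salty": 1}),
        Variable("drinking", ("no", "occasionally", "regular"), three_level),
        Variable("smoking", ("no", "occasionally", "regular"), three_level),
        Variable("sports", ("no", "occasionally", "regular"), three_level),
        Variable("pressure", ("none", "little", "more"), {"none": 0, "little": 1, "more": 1}),
        Variable("education", ("primary", "secondary", "tertiary"), None, "descriptive"),
        Variable("occupation", ("manual", "nonmanual", "retired"), None, "descriptive"),
        Variable("noise", ("no", "yes"), {"no": 0, "yes": 1}, "descriptive"),
        Variable("sleeping_time", ("short", "normal", "long"), None, "descriptive"),
    ]
    return VariableCodebook({v.name: v for v in variables})


@dataclass
class SubjectRecord:
    """One study participant."""

    subject_id: str
    is_case: bool
    sex: str
    age: int
    pair_id: str | None = None
    exposures: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"subject {self.subject_id!r}: negative age")


FIXED_COLUMNS = ("subject_id", "pair_id", "case", "sex", "age")


def read_cohort(path: str | Path, codebook: VariableCodebook) -> list[SubjectRecord]:
    """Read a cohort CSV, validating every level code against the codebook.

    Raises :class:`FormatError` for a missing mandatory column and
    :class:`ValidationError` (naming row and variable) for an undeclared
    level code.  Row count and per-variable missingness are logged.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        wanted = [c for c in FIXED_COLUMNS if c != "pair_id"]
        wanted += [c for c in codebook.data_columns() if c != "sex"]
        for col in wanted:
            if col not in header:
                raise FormatError(f"{path.name}: missing mandatory column {col!r}")
        has_pair = "pair_id" in header
        var_columns = [c for c in codebook.data_columns() if c != "sex"]

        records: list[SubjectRecord] = []
        missing_counts = dict.fromkeys(var_columns, 0)
        seen_ids: set[str] = set()
        for i, row in enumerate(reader, start=2):  # header is line 1
            sid = row["subject_id"]
            if sid in seen_ids:
                raise ValidationError(f"row {i}: duplicate subject_id {sid!r}")
            seen_ids.add(sid)
            sex = row["sex"]
            if sex not in codebook["sex"].levels:
                raise ValidationError(f"row {i}: undeclared level {sex!r} for 'sex'")
            exposures: dict[str, str | None] = {}
            for var in var_columns:
                value = row[var]
                if value == "":
                    exposures[var] = None
                    missing_counts[var] += 1
                    continue
                declared = codebook[var].levels
                if value not in declared and value not in BINARY_LEVELS:
                    raise ValidationError(
                        f"row {i}: undeclared level {value!r} for {var!r}"
                    )
                exposures[var] = value
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    is_case=row["case"] == "1",
                    sex=sex,
                    age=int(row["age"]),
                    pair_id=(row["pair_id"] or None) if has_pair else None,
                    exposures=exposures,
                )
            )
    logger.info("read %d records from %s", len(records), path)
    for var, n_missing in missing_counts.items():
        if n_missing:
            logger.info("variable %s: %d missing values", var, n_missing)
    return records


def write_cohort(
    records: Sequence[SubjectRecord], path: str | Path, codebook: VariableCodebook | None = None
) -> None:
    """Write a cohort to CSV in the dialect :func:`read_cohort` expects."""
    if not records:
        raise DomainError("cannot write an empty cohort")
    if codebook is not None:
        var_columns = [c for c in codebook.data_columns() if c != "sex"]
    else:
        var_columns = list(records[0].exposures)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(FIXED_COLUMNS) + var_columns)
        for rec in records:
            row = [
                rec.subject_id,
                rec.pair_id or "",
                "1" if rec.is_case else "0",
                rec.sex,
                str(rec.age),
            ]
            row += ["" if rec.exposures.get(v) is None else rec.exposures[v] for v in var_columns]
            writer.writerow(row)
    logger.info("wrote %d records to %s", len(records), path)


def dichotomize(
    records: Iterable[SubjectRecord], variable: str, codebook: VariableCodebook
) -> list[SubjectRecord]:
    """Recode one variable to binary ``"0"``/``"1"`` via the codebook map.

    Values already in the binary image pass through unchanged (idempotent);
    missing values stay missing.  Raises ``KeyError`` if the variable is
    absent or declares no binary recode.
    """
    var = codebook.variables.get(variable)
    if var is None:
        raise KeyError(f"variable {variable!r} not in codebook")
    if var.binary_map is None:
        raise KeyError(f"variable {variable!r} declares no binary recode")

    source_tally: dict[str, int] = {}
    out: list[SubjectRecord] = []
    for rec in records:
        level = rec.exposures.get(variable)
        if level is None:
            recoded = None
        elif level in var.binary_map:
            recoded = str(var.binary_map[level])
        elif level in BINARY_LEVELS:
            recoded = level
        else:
            raise ValidationError(
                f"subject {rec.subject_id!r}: undeclared level {level!r} "
                f"for {variable!r}"
            )
        if level is not None:
            source_tally[level] = source_tally.get(level, 0) + 1
        out.append(replace(rec, exposures={**rec.exposures, variable: recoded}))
    logger.info("dichotomized %s: source level counts %s", variable, source_tally)
    return out


@dataclass
class CohortSummary:
    """Descriptive summary: level tallies by arm and the age distribution."""

    n_total: int
    n_cases: int
    n_controls: int
    age_mean_cases: float
    age_sd_cases: float
    age_mean_controls: float
    age_sd_controls: float
    # variable -> level -> {"cases": n, "controls": n, "pct_cases": %, "pct_controls": %}
    level_counts: dict[str, dict[str, dict[str, float]]]


def summarize_cohort(records: Sequence[SubjectRecord]) -> CohortSummary:
    """Counts and percentages per variable level split by case status.

    Percentages are over observed (non-missing) levels within each arm and
    sum to 100 within rounding.  Raises :class:`DomainError` on an empty
    cohort.
    """
    if not records:
        raise DomainError("empty cohort")
    import numpy as np

    cases = [r for r in records if r.is_case]
    controls = [r for r in records if not r.is_case]

    def age_stats(group: list[SubjectRecord]) -> tuple[float, float]:
        if not group:
            return float("nan"), float("nan")
        ages = np.array([r.age for r in group], dtype=float)
        sd = float(ages.std(ddof=1)) if len(ages) > 1 else 0.0
        return float(ages.mean()), sd

    variables: list[str] = []
    for rec in records:
        for name in rec.exposures:
            if name not in variables:
                variables.append(name)

    level_counts: dict[str, dict[str, dict[str, float]]] = {}
    for var in variables:
        tallies: dict[str, dict[str, float]] = {}
        for rec in records:
            level = rec.exposures.get(var)
            if level is None:
                continue
            cell = tallies.setdefault(level, {"cases": 0, "controls": 0})
            cell["cases" if rec.is_case else "controls"] += 1
        n_case_obs = sum(c["cases"] for c in tallies.values())
        n_ctrl_obs = sum(c["controls"] for c in tallies.values())
        for cell in tallies.values():
            cell["pct_cases"] = 100.0 * cell["cases"] / n_case_obs if n_case_obs else 0.0
            cell["pct_controls"] = (
                100.0 * cell["controls"] / n_ctrl_obs if n_ctrl_obs else 0.0
            )
        level_counts[var] = tallies

    mean_ca, sd_ca = age_stats(cases)
    mean_co, sd_co = age_stats(controls)
    return CohortSummary(
        n_total=len(records),
        n_cases=len(cases),
        n_controls=len(controls),
        age_mean_cases=mean_ca,
        age_sd_cases=sd_ca,
        age_mean_controls=mean_co,
        age_sd_controls=sd_co,
        level_counts=level_counts,
    )
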