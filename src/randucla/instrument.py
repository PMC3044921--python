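"""Five-criterion instrument for grading moderator (subgroup) analyses in RCTs.

A moderator is a baseline variable, measured before randomisation, that
interacts with treatment allocation — it identifies for whom a treatment
works.  When a systematic review pools moderator findings across trials, each
trial's subgroup analysis is appraised on five criteria:

C1  the analysis was a priori (an explicit hypothesis planned in protocol);
C2  factor selection was clinically plausible and theory/evidence driven;
C3  the moderator was measured prior to randomisation;
C4  baseline factors were measured with adequate quality;
C5  an explicit moderator-by-treatment interaction test was reported.

All five satisfied makes the finding *confirmatory* evidence; only the last
three (C3-C5) satisfied makes it *exploratory* (hypothesis-generating); any
of C3-C5 failing excludes the study from meta-analysis of moderators.  C3
admits not-applicable exceptions for time-invariant factors (e.g. sex) and
for cluster randomisation where baseline data precede awareness of
allocation.  A C1 or C2 failure can therefore demote a study but never
exclude it.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Criterion",
    "Response",
    "CriterionAnswer",
    "StudyAppraisal",
    "Grade",
    "EvidenceGrade",
    "AppraisalError",
    "judge_criterion",
    "grade_study",
    "summarize_review",
    "load_appraisals",
    "write_grades",
]


class AppraisalError(ValueError):
    """An appraisal violates the instrument's input contract."""


class Criterion(str, Enum):
    C1_A_PRIORI = "C1_a_priori"
    C2_THEORY_EVIDENCE = "C2_theory_evidence"
    C3_PRE_RANDOMISATION = "C3_pre_randomisation"
    C4_MEASUREMENT_QUALITY = "C4_measurement_quality"
    C5_INTERACTION_TEST = "C5_interaction_test"


#: criteria whose failure excludes a study from moderator meta-analysis
CORE_CRITERIA = (
    Criterion.C3_PRE_RANDOMISATION,
    Criterion.C4_MEASUREMENT_QUALITY,
    Criterion.C5_INTERACTION_TEST,
)


class Response(str, Enum):
    YES = "yes"
    NO = "no"
    NOT_APPLICABLE = "not_applicable"
    #: real reviews meet unreported items; mapped to unsatisfied, never a waiver
    UNKNOWN = "unknown"


#: not-applicable exception codes that *waive* a criterion
NA_EXCEPTION_CODES: dict[Criterion, frozenset[str]] = {
    Criterion.C1_A_PRIORI: frozenset(),
    Criterion.C2_THEORY_EVIDENCE: frozenset(),
    Criterion.C3_PRE_RANDOMISATION: frozenset(
        {"time_invariant_factor", "cluster_randomisation_pre_awareness"}
    ),
    Criterion.C4_MEASUREMENT_QUALITY: frozenset(),
    Criterion.C5_INTERACTION_TEST: frozenset(),
}

#: annotation codes for *why* a criterion failed (attached to "no" answers)
FAILURE_CODES: dict[Criterion, frozenset[str]] = {
    Criterion.C1_A_PRIORI: frozenset({"vague_hypothesis", "hypothesis_list_too_large"}),
    Criterion.C2_THEORY_EVIDENCE: frozenset({"weak_theory_or_evidence"}),
    Criterion.C3_PRE_RANDOMISATION: frozenset(),
    Criterion.C4_MEASUREMENT_QUALITY: frozenset({"inadequate_variability"}),
    Criterion.C5_INTERACTION_TEST: frozenset(
        {"subgroups_tested_separately", "excessive_multiple_testing"}
    ),
}


@dataclass(frozen=True)
class CriterionAnswer:
    criterion: Criterion
    response: Response
    exception_code: str | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.response is Response.NOT_APPLICABLE:
            valid = NA_EXCEPTION_CODES[self.criterion]
            if not self.exception_code:
                raise AppraisalError(
                    f"{self.criterion.value}: not_applicable requires an exception code"
                )
            if self.exception_code not in valid:
                raise AppraisalError(
                    f"{self.criterion.value}: {self.exception_code!r} is not a valid "
                    f"not-applicable exception (valid: {sorted(valid) or 'none'})"
                )
        elif self.exception_code is not None:
            valid = FAILURE_CODES[self.criterion] | NA_EXCEPTION_CODES[self.criterion]
            if self.exception_code not in valid:
                raise AppraisalError(
                    f"{self.criterion.value}: unknown exception code "
                    f"{self.exception_code!r} (valid: {sorted(valid) or 'none'})"
                )


def judge_criterion(answer: CriterionAnswer) -> bool:
    """Whether a single criterion is satisfied.

    Yes satisfies; no fails; a valid not-applicable exception waives the
    requirement (counts as satisfied); unknown/not-reported never waives.
    """
    if answer.response is Response.YES:
        return True
    if answer.response is Response.NOT_APPLICABLE:
        return True  # validity of the exception code enforced at construction
    return False


@dataclass
class StudyAppraisal:
    """One appraiser's answers to all five criteria for one study."""

    study_id: str
    answers: Mapping[Criterion, CriterionAnswer]
    appraiser: str = ""
    date: _dt.date | None = None

    def __post_init__(self) -> None:
        self.answers = dict(self.answers)
        missing = [c.value for c in Criterion if c not in self.answers]
        if missing:
            raise AppraisalError(
                f"study {self.study_id!r}: unanswered criteria {missing}"
            )
        for criterion, answer in self.answers.items():
            if answer.criterion is not criterion:
                raise AppraisalError(
                    f"study {self.study_id!r}: answer for {answer.criterion.value} "
                    f"filed under {criterion.value}"
                )


class Grade(str, Enum):
    CONFIRMATORY = "confirmatory"
    EXPLORATORY = "exploratory"
    EXCLUDED = "excluded"


#: ordering used by the monotonicity property: more satisfied => never lower
GRADE_ORDER = {Grade.EXCLUDED: 0, Grade.EXPLORATORY: 1, Grade.CONFIRMATORY: 2}


@dataclass(frozen=True)
class EvidenceGrade:
    study_id: str
    grade: Grade
    failed_criteria: tuple[Criterion, ...]
    rationale: str


_RATIONALE = {
    Criterion.C1_A_PRIORI: "no explicit a-priori hypothesis planned in protocol",
    Criterion.C2_THEORY_EVIDENCE: "factor selection not theory/evidence driven",
    Criterion.C3_PRE_RANDOMISATION: "moderator not measured prior to randomisation",
    Criterion.C4_MEASUREMENT_QUALITY: "inadequate quality of baseline measurement",
    Criterion.C5_INTERACTION_TEST: "no explicit moderator-by-treatment interaction test",
}


def grade_study(appraisal: StudyAppraisal) -> EvidenceGrade:
    """Grade a study's moderator analysis as confirmatory, exploratory or excluded.

    Confirmatory requires all five criteria; exploratory requires the three
    core criteria (C3-C5) with C1 or C2 failing; any core failure excludes.
    """
    satisfied = {c: judge_criterion(a) for c, a in appraisal.answers.items()}
    failed = tuple(c for c in Criterion if not satisfied[c])

    if all(satisfied.values()):
        grade = Grade.CONFIRMATORY
        rationale = "all five criteria satisfied; findings usable as confirmatory evidence"
    elif all(satisfied[c] for c in CORE_CRITERIA):
        grade = Grade.EXPLORATORY
        parts = [_RATIONALE[c] for c in failed]
        rationale = (
            "core criteria (pre-randomisation measurement, measurement quality, "
            "interaction test) satisfied but " + "; ".join(parts)
            + "; findings usable for exploratory (hypothesis-generating) synthesis"
        )
    else:
        grade = Grade.EXCLUDED
        core_failed = [_RATIONALE[c] for c in failed if c in CORE_CRITERIA]
        rationale = "; ".join(core_failed) + "; study excluded from moderator meta-analysis"
    for c in failed:
        answer = appraisal.answers[c]
        if answer.response is Response.UNKNOWN:
            rationale += f" [{c.value}: not reported]"
        elif answer.exception_code:
            rationale += f" [{c.value}: {answer.exception_code}]"
    return EvidenceGrade(
        study_id=appraisal.study_id, grade=grade, failed_criteria=failed, rationale=rationale
    )


def summarize_review(grades: Iterable[EvidenceGrade]) -> dict:
    """Counts per grade plus per-criterion failure frequencies, CSV-writable."""
    grades = list(grades)
    counts = {g.value: 0 for g in Grade}
    failures = {c.value: 0 for c in Criterion}
    for g in grades:
        counts[g.grade.value] += 1
        for c in g.failed_criteria:
            failures[c.value] += 1
    satisfied = {c: len(grades) - f for c, f in failures.items()}
    return {
        "n_studies": len(grades),
        "grade_counts": counts,
        "criterion_satisfied": satisfied,
        "criterion_failed": failures,
    }


_CRITERION_ALIASES = {c.value.lower(): c for c in Criterion}
_CRITERION_ALIASES.update({c.value.split("_")[0].lower(): c for c in Criterion})


def _parse_criterion(label: str) -> Criterion:
    key = label.strip().lower()
    if key not in _CRITERION_ALIASES:
        raise AppraisalError(f"unknown criterion {label!r}")
    return _CRITERION_ALIASES[key]


def load_appraisals(path: str | Path) -> list[StudyAppraisal]:
    """Read appraisals from CSV (one row per study x criterion).

    Columns: ``study_id, criterion, response, exception_code, note`` with
    optional ``appraiser``.  Criterion accepts the full id or the short form
    (``C1`` .. ``C5``).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"study_id", "criterion", "response"}
    if not required.issubset(df.columns):
        raise AppraisalError(
            f"appraisal file must have columns {sorted(required)}, found {list(df.columns)}"
        )
    appraisals: list[StudyAppraisal] = []
    for (study_id), group in df.groupby("study_id", sort=False):
        answers: dict[Criterion, CriterionAnswer] = {}
        for row in group.itertuples(index=False):
            criterion = _parse_criterion(row.criterion)
            if criterion in answers:
                raise AppraisalError(
                    f"study {study_id!r}: duplicate answer for {criterion.value}"
                )
            try:
                response = Response(row.response.strip().lower())
            except ValueError:
                raise AppraisalError(
                    f"study {study_id!r}, {criterion.value}: invalid response "
                    f"{row.response!r}"
                ) from None
            code = getattr(row, "exception_code", "") or None
            if isinstance(code, str):
                code = code.strip() or None
            answers[criterion] = CriterionAnswer(
                criterion=criterion,
                response=response,
                exception_code=code,
                note=str(getattr(row, "note", "") or ""),
            )
        appraiser = str(getattr(group.itertuples(index=False).__next__(), "appraiser", ""))
        appraisals.append(
            StudyAppraisal(study_id=str(study_id), answers=answers, appraiser=appraiser)
        )
    return appraisals


def write_grades(grades: Sequence[EvidenceGrade], path: str | Path) -> None:
    rows = [
        {
            "study_id": g.study_id,
            "grade": g.grade.value,
            "failed_criteria": ";".join(c.value for c in g.failed_criteria),
            "rationale": g.rationale,
        }
        for g in grades
    ]
    pd.DataFrame(rows, columns=["study_id", "grade", "failed_criteria", "rationale"]).to_csv(
        path, index=False
    )
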