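"""Grade trials' moderator analyses as confirmatory or exploratory evidence.

Each trial's subgroup analysis is appraised on five criteria: a-priori
hypothesis (C1), theory/evidence-driven factor selection (C2),
pre-randomisation measurement (C3), measurement quality (C4), and an
explicit interaction test (C5).  All five -> confirmatory; C3-C5 only ->
exploratory; any of C3-C5 failing -> excluded.
"""

from randucla import (
    Criterion,
    CriterionAnswer,
    Response,
    StudyAppraisal,
    grade_study,
    summarize_review,
)


def appraise(study_id, **responses):
    answers = {}
    for c in Criterion:
        short = c.value.split("_")[0].lower()  # c1 .. c5
        resp, code = responses.get(short, ("yes", None))
        answers[c] = CriterionAnswer(c, Response(resp), code)
    return StudyAppraisal(study_id=study_id, answers=answers)


appraisals = [
    # protocolised interaction analysis, all criteria met
    appraise("trial_A"),
    # post-hoc subgroup with thin rationale: core criteria still met
    appraise("trial_B", c1=("no", "vague_hypothesis"),
             c2=("no", "weak_theory_or_evidence")),
    # subgroups tested separately instead of an interaction test
    appraise("trial_C", c5=("no", "subgroups_tested_separately")),
    # sex as moderator: pre-randomisation measurement waived (time-invariant)
    appraise("trial_D", c3=("not_applicable", "time_invariant_factor")),
]

grades = [grade_study(a) for a in appraisals]
for g in grades:
    failed = ", ".join(c.value for c in g.failed_criteria) or "none"
    print(f"{g.study_id}: {g.grade.value:<12} (failed: {failed})")
summary = summarize_review(grades)
print("review totals:", summary["grade_counts"])

# trial_A and trial_D are confirmatory (a valid not-applicable exception
# waives C3), trial_B drops to exploratory (usable for hypothesis
# generation), and trial_C is excluded: without an interaction test a
# subgroup effect cannot enter a meta-analysis of moderators at all.
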