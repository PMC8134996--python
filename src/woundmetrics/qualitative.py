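"""Masked-reviewer survey analysis.

Each reviewer saw the three tracings of a photograph in randomized order and
answered, per tracing, whether it met the standardized wound-area definition
(Q1, yes/no per annotator), which single tracing they believed was produced
by the AI (Q2), and which they found most accurate (Q3).  Missing answers
are excluded listwise per question — denominators therefore vary across
questions and reviewers, with no imputation.

Q1 is tested per reviewer with a Fisher exact test on the 2x2 table of
AI yes/no against the two human annotators pooled into one class; Q2/Q3 are
tested per reviewer against uniform random selection over the three
annotators with a chi-square goodness-of-fit test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DegenerateSampleError, ValidationError
from .stats import TestResult, chi_square_gof, fisher_exact_2x2

__all__ = [
    "ANNOTATORS",
    "SurveyResponse",
    "AgreementTable",
    "load_survey",
    "agreement_table",
    "q1_fisher",
    "selection_bias",
    "survey_report",
]

ANNOTATORS = ("AI", "H1", "H2")
HUMANS = ("H1", "H2")


@dataclass(frozen=True)
class SurveyResponse:
    """One reviewer's answers for one photograph.

    ``q1`` maps annotator -> True/False/None (None = skipped); the choice
    fields are an annotator label or None.
    """

    site: str
    reviewer_id: str
    photo_id: str
    q1: dict = field(default_factory=dict)
    q2_choice: str | None = None
    q3_choice: str | None = None

    def __post_init__(self):
        for key in self.q1:
            if key not in ANNOTATORS:
                raise ValidationError(f"unknown annotator {key!r} in Q1 answers")
        for choice in (self.q2_choice, self.q3_choice):
            if choice is not None and choice not in ANNOTATORS:
                raise ValidationError(f"unknown annotator choice {choice!r}")

    @property
    def reviewer(self) -> tuple[str, str]:
        return (self.site, self.reviewer_id)


@dataclass(frozen=True)
class AgreementTable:
    """Q1 yes/total counts per (reviewer, annotator) plus pooled AI/human rates."""

    per_reviewer: pd.DataFrame  # site, reviewer_id, annotator, yes, total
    ai_yes: int
    ai_total: int
    human_yes: int
    human_total: int

    @property
    def ai_rate(self) -> float:
        return self.ai_yes / self.ai_total if self.ai_total else float("nan")

    @property
    def human_rate(self) -> float:
        return self.human_yes / self.human_total if self.human_total else float("nan")


def load_survey(csv_path: str | Path) -> list[SurveyResponse]:
    """Read the survey CSV (site, reviewer_id, photo_id, q1_AI, q1_H1, q1_H2,
    q2_choice, q3_choice; Y/N or blank for Q1, annotator label or blank for
    the choices)."""
    df = pd.read_csv(csv_path, dtype=str, comment="#", keep_default_na=False)
    required = ["site", "reviewer_id", "photo_id", "q1_AI", "q1_H1", "q1_H2",
                "q2_choice", "q3_choice"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"survey CSV is missing columns {missing}")

    def yn(v: str):
        v = v.strip().upper()
        if v in ("Y", "YES", "1", "TRUE"):
            return True
        if v in ("N", "NO", "0", "FALSE"):
            return False
        if v == "":
            return None
        raise ValidationError(f"bad Q1 answer {v!r} (expected Y/N/blank)")

    responses = []
    for row in df.itertuples(index=False):
        q1 = {}
        for ann in ANNOTATORS:
            ans = yn(getattr(row, f"q1_{ann}"))
            if ans is not None:
                q1[ann] = ans
        responses.append(
            SurveyResponse(
                site=row.site,
                reviewer_id=row.reviewer_id,
                photo_id=row.photo_id,
                q1=q1,
                q2_choice=row.q2_choice.strip() or None,
                q3_choice=row.q3_choice.strip() or None,
            )
        )
    return responses


def responses_from_q1_counts(
    site: str, reviewer_id: str, counts: dict[str, tuple[int, int]]
) -> list[SurveyResponse]:
    """Expand per-annotator Q1 (yes, total) counts into individual responses.

    Useful for feeding published count tables through the same aggregation
    path as raw survey CSVs.  The alignment of answers across annotators
    within a response is arbitrary; it does not affect any Q1 statistic,
    which depends only on the marginal counts.
    """
    n_rows = max(t for _, t in counts.values())
    out = []
    for i in range(n_rows):
        q1 = {}
        for ann, (yes, total) in counts.items():
            if i < total:
                q1[ann] = i < yes
        out.append(
            SurveyResponse(site=site, reviewer_id=reviewer_id,
                           photo_id=f"{site}-{reviewer_id}-{i + 1}", q1=q1)
        )
    return out


def _q1_counts(responses, reviewer=None):
    """yes/total per annotator, optionally restricted to one (site, reviewer)."""
    counts = {ann: [0, 0] for ann in ANNOTATORS}
    for r in responses:
        if reviewer is not None and r.reviewer != tuple(reviewer):
            continue
        for ann, ans in r.q1.items():
            counts[ann][1] += 1
            counts[ann][0] += int(bool(ans))
    return counts


def agreement_table(responses: list[SurveyResponse]) -> AgreementTable:
    """Aggregate Q1 agreement counts per reviewer and pooled by annotator class.

    Pooled AI counts sum over all reviewers; pooled human counts sum over
    both human annotators and all reviewers.  The per-reviewer table and the
    pooled totals satisfy an accounting identity (pooled = column sums),
    asserted on every run.
    """
    reviewers = sorted({r.reviewer for r in responses})
    rows = []
    for rev in reviewers:
        counts = _q1_counts(responses, reviewer=rev)
        for ann in ANNOTATORS:
            yes, total = counts[ann]
            rows.append(
                {"site": rev[0], "reviewer_id": rev[1], "annotator": ann,
                 "yes": yes, "total": total}
            )
    per_reviewer = pd.DataFrame(
        rows, columns=["site", "reviewer_id", "annotator", "yes", "total"]
    )
    pooled = _q1_counts(responses)
    ai_yes, ai_total = pooled["AI"]
    human_yes = sum(pooled[h][0] for h in HUMANS)
    human_total = sum(pooled[h][1] for h in HUMANS)
    if not per_reviewer.empty:
        ai_rows = per_reviewer[per_reviewer.annotator == "AI"]
        assert int(ai_rows.yes.sum()) == ai_yes and int(ai_rows.total.sum()) == ai_total
        h_rows = per_reviewer[per_reviewer.annotator.isin(HUMANS)]
        assert int(h_rows.yes.sum()) == human_yes and int(h_rows.total.sum()) == human_total
    return AgreementTable(per_reviewer, ai_yes, ai_total, human_yes, human_total)


def q1_fisher(responses: list[SurveyResponse], reviewer) -> TestResult:
    """Fisher exact test of Q1 agreement, AI vs pooled humans, for one reviewer.

    Builds the 2x2 table [[AI yes, AI no], [human yes, human no]] with both
    human annotators pooled into one class, and delegates to the exact test.
    """
    counts = _q1_counts(responses, reviewer=reviewer)
    ai_yes, ai_total = counts["AI"]
    h_yes = sum(counts[h][0] for h in HUMANS)
    h_total = sum(counts[h][1] for h in HUMANS)
    if ai_total == 0 or h_total == 0:
        raise DegenerateSampleError(
            f"reviewer {reviewer} has no Q1 answers for AI or for humans"
        )
    table = [[ai_yes, ai_total - ai_yes], [h_yes, h_total - h_yes]]
    return fisher_exact_2x2(table)


def selection_counts(responses, question: str, reviewer=None) -> dict[str, int]:
    """Choice counts per annotator for Q2 or Q3, missing answers excluded."""
    if question not in ("q2", "q3"):
        raise ValidationError("question must be 'q2' or 'q3'")
    attr = f"{question}_choice"
    counts = dict.fromkeys(ANNOTATORS, 0)
    for r in responses:
        if reviewer is not None and r.reviewer != tuple(reviewer):
            continue
        choice = getattr(r, attr)
        if choice is not None:
            counts[choice] += 1
    return counts


def selection_bias(responses, question: str, reviewer) -> TestResult:
    """Chi-square test of annotator-selection bias vs uniform random choice."""
    counts = selection_counts(responses, question, reviewer=reviewer)
    return chi_square_gof([counts[a] for a in ANNOTATORS])


def survey_report(responses: list[SurveyResponse]) -> pd.DataFrame:
    """Per-reviewer report shaped like the study's survey summary table.

    One row per (question, reviewer): counts per annotator, the question's
    test p-value (Fisher for Q1, chi-square vs uniform for Q2/Q3) and the
    denominator.
    """
    from .stats import format_p

    reviewers = sorted({r.reviewer for r in responses})
    rows = []
    for site, rid in reviewers:
        rev = (site, rid)
        c1 = _q1_counts(responses, reviewer=rev)
        try:
            p1 = q1_fisher(responses, rev).p_value
            p1s = format_p(p1)
        except DegenerateSampleError:
            p1, p1s = float("nan"), ""
        rows.append(
            {"question": "q1", "site": site, "reviewer_id": rid,
             "AI": f"{c1['AI'][0]}/{c1['AI'][1]}",
             "H1": f"{c1['H1'][0]}/{c1['H1'][1]}",
             "H2": f"{c1['H2'][0]}/{c1['H2'][1]}",
             "p_value": p1, "p_formatted": p1s}
        )
        for q in ("q2", "q3"):
            counts = selection_counts(responses, q, reviewer=rev)
            total = sum(counts.values())
            if total:
                p = selection_bias(responses, q, rev).p_value
                ps = format_p(p)
            else:
                p, ps = float("nan"), ""
            rows.append(
                {"question": q, "site": site, "reviewer_id": rid,
                 "AI": f"{counts['AI']}/{total}",
                 "H1": f"{counts['H1']}/{total}",
                 "H2": f"{counts['H2']}/{total}",
                 "p_value": p, "p_formatted": ps}
            )
    return pd.DataFrame(
        rows,
        columns=["question", "site", "reviewer_id", "AI", "H1", "H2",
                 "p_value", "p_formatted"],
    )
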