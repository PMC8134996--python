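"""The reference/test comparison design and error-distribution summaries.

For each photograph annotated by one automated tracer (AI) and two humans
(H1, H2), each human tracing serves as both reference and test, giving four
comparisons: AI vs H1, AI vs H2, H1 vs H2 and H2 vs H1 (named test vs
reference; the AI trace is never the reference).  When a tracer judged the
wound completely epithelialized its trace is absent and the missing-trace
rules apply: with exactly one trace absent, the comparison(s) between the
two remaining traces are kept; with two or more absent, the photograph
contributes nothing.  Note the asymmetry: an absent AI leaves both
human-vs-human records (2), while an absent human leaves only the single
AI-vs-remaining-human record, because the AI cannot serve as reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics import AreaTriple, ErrorMeasures, area_triple, dice, error_measures, jaccard, rasterize
from .roi_io import PhotoTraces

__all__ = [
    "AI_VS_HUMAN",
    "HUMAN_VS_HUMAN",
    "ComparisonRecord",
    "DistributionSummary",
    "build_comparisons",
    "comparisons_frame",
    "paired_error_table",
    "summarize",
    "are_vs_size_table",
    "MEASURES",
]

AI_VS_HUMAN = "ai_vs_human"
HUMAN_VS_HUMAN = "human_vs_human"
MEASURES = ("FNA", "FPA", "ARE")


@dataclass(frozen=True)
class ComparisonRecord:
    """One test-vs-reference comparison for one photograph."""

    photo_id: str
    reference_id: str
    test_id: str
    kind: str
    group: str  # AI_VS_HUMAN when the test trace is the AI's
    triple: AreaTriple
    errors: ErrorMeasures


@dataclass(frozen=True)
class DistributionSummary:
    """Median and quartiles of an error-measure distribution."""

    n: int
    median: float
    q1: float
    q3: float

    def __post_init__(self):
        if not (self.q1 <= self.median <= self.q3):
            raise ValidationError("quartiles out of order")


def build_comparisons(
    photo: PhotoTraces, ai_id: str = "AI"
) -> list[ComparisonRecord]:
    """Build the comparison records for one photograph under the design rules.

    All three traces present -> 4 records; AI absent -> the two human-vs-
    human records; one human absent -> the single AI-vs-remaining-human
    record; two or more absent -> no records.
    """
    traces = photo.traces
    ids = list(traces)
    human_ids = [t for t in ids if t != ai_id]
    if ai_id in ids and sum(t == ai_id for t in ids) > 1:
        raise ValidationError("more than one AI tracer configured")
    if len(human_ids) > 2:
        raise ValidationError(f"design supports at most 2 human tracers, got {human_ids}")

    present = {t for t, tr in traces.items() if not tr.is_absent}
    if len(present) < 2:
        return []

    masks = {t: rasterize(traces[t], photo.canvas) for t in present}

    pairs: list[tuple[str, str]] = []  # (test, reference); reference never AI
    humans_present = [h for h in human_ids if h in present]
    if ai_id in present:
        for h in humans_present:
            pairs.append((ai_id, h))
    if len(humans_present) == 2:
        h1, h2 = humans_present
        pairs.append((h1, h2))
        pairs.append((h2, h1))

    records = []
    for test, ref in pairs:
        triple = area_triple(masks[ref], masks[test])
        records.append(
            ComparisonRecord(
                photo_id=photo.photo_id,
                reference_id=ref,
                test_id=test,
                kind=traces[ref].kind,
                group=AI_VS_HUMAN if test == ai_id else HUMAN_VS_HUMAN,
                triple=triple,
                errors=error_measures(triple),
            )
        )
    return records


def comparisons_frame(records: list[ComparisonRecord]) -> pd.DataFrame:
    """Tidy per-comparison table (one row per record) with auxiliary indices."""
    rows = []
    for r in records:
        rows.append(
            {
                "photo_id": r.photo_id,
                "ref": r.reference_id,
                "test": r.test_id,
                "kind": r.kind,
                "group": r.group,
                "R": r.triple.R,
                "T": r.triple.T,
                "O": r.triple.O,
                "FNA": r.errors.FNA,
                "FPA": r.errors.FPA,
                "RE": r.errors.RE,
                "ARE": r.errors.ARE,
                "jaccard": jaccard(r.triple),
                "dice": dice(r.triple),
            }
        )
    columns = [
        "photo_id", "ref", "test", "kind", "group",
        "R", "T", "O", "FNA", "FPA", "RE", "ARE", "jaccard", "dice",
    ]
    return pd.DataFrame(rows, columns=columns)


def paired_error_table(
    records: list[ComparisonRecord], measure: str, ai_id: str = "AI"
) -> pd.DataFrame:
    """Matched (AI-vs-human, human-vs-human) error pairs sharing a reference.

    For each photograph and each human reference h, the AI-vs-h error is
    paired with the other-human-vs-h error.  Sharing the reference trace
    cancels reference variability within each pair, which is what makes the
    signed-rank comparison of the two groups a matched-pairs test.  A
    complete photograph contributes two pairs; photographs lacking either
    member of a pair contribute nothing for that reference.
    """
    if measure not in ("FNA", "FPA", "RE", "ARE"):
        raise ValidationError(f"unknown measure {measure!r}")
    by_key: dict[tuple[str, str], dict[str, float]] = {}
    for r in records:
        key = (r.photo_id, r.reference_id)
        by_key.setdefault(key, {})[r.group] = getattr(r.errors, measure)
    rows = [
        {
            "photo_id": photo,
            "reference_id": ref,
            "ai_vs_human": vals[AI_VS_HUMAN],
            "human_vs_human": vals[HUMAN_VS_HUMAN],
        }
        for (photo, ref), vals in by_key.items()
        if AI_VS_HUMAN in vals and HUMAN_VS_HUMAN in vals
    ]
    return pd.DataFrame(
        rows, columns=["photo_id", "reference_id", "ai_vs_human", "human_vs_human"]
    )


def summarize(values) -> DistributionSummary:
    """Median and quartiles by linear interpolation of order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot summarize an empty sample")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return DistributionSummary(n=int(values.size), median=float(med), q1=float(q1), q3=float(q3))


def are_vs_size_table(records: list[ComparisonRecord]) -> pd.DataFrame:
    """(reference area, ARE) pairs, used to study size-dependence of error."""
    rows = [
        {
            "photo_id": r.photo_id,
            "group": r.group,
            "reference_area": r.triple.R,
            "ARE": r.errors.ARE,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["photo_id", "group", "reference_area", "ARE"])


def summary_frame(records: list[ComparisonRecord]) -> pd.DataFrame:
    """Group summaries (median/IQR per measure per group), tidy."""
    df = comparisons_frame(records)
    rows = []
    for (kind, group), sub in df.groupby(["kind", "group"], sort=True):
        for measure in MEASURES:
            s = summarize(sub[measure].to_numpy())
            rows.append(
                {
                    "kind": kind,
                    "group": group,
                    "measure": measure,
                    "n": s.n,
                    "median": s.median,
                    "q1": s.q1,
                    "q3": s.q3,
                }
            )
    return pd.DataFrame(
        rows, columns=["kind", "group", "measure", "n", "median", "q1", "q3"]
    )
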