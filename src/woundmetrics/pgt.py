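"""Percent-granulation-tissue (PGT) agreement analysis.

Three masked reviewers visually estimated, to the nearest 10%, the fraction
of each wound bed covered by granulation tissue; the automated tool reports
a continuous PGT measurement.  The question asked of the data: is the
absolute difference between the tool's PGT and the mean reviewer estimate of
the same magnitude as the disagreement among the reviewers themselves?  The
inter-reviewer variability is expressed per photograph as the range
(max - min) and the sample SD (n-1 denominator) of the three estimates, and
compared with the AI-vs-mean absolute differences by paired t tests (paired
by photograph).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stats import TestResult, paired_t

__all__ = [
    "PGTRecord",
    "PGTSummary",
    "load_pgt",
    "pgt_differences",
    "pgt_variability",
    "pgt_compare",
    "ai_pgt_from_areas",
]

N_REVIEWERS = 3


@dataclass(frozen=True)
class PGTRecord:
    """Three reviewer PGT estimates plus the AI PGT measurement, all in percent."""

    photo_id: str
    reviewer_estimates: tuple[float, float, float]
    ai_pgt: float

    def __post_init__(self):
        if len(self.reviewer_estimates) != N_REVIEWERS:
            raise ValidationError(
                f"exactly {N_REVIEWERS} reviewer estimates required, "
                f"got {len(self.reviewer_estimates)}"
            )
        for v in self.reviewer_estimates:
            if not 0 <= v <= 100:
                raise ValidationError(f"PGT estimate {v} outside [0, 100]")
            if v % 10 != 0:
                # estimates were elicited to the nearest 10%; an off-grid value
                # is kept (not re-rounded) so data-entry issues stay visible
                warnings.warn(
                    f"PGT estimate {v} for {self.photo_id} is not a multiple of 10",
                    stacklevel=3,
                )
        if not 0 <= self.ai_pgt <= 100:
            raise ValidationError(f"AI PGT {self.ai_pgt} outside [0, 100]")


@dataclass(frozen=True)
class PGTSummary:
    """Summary of AI-vs-reviewer differences against inter-reviewer variability."""

    n: int
    mean_abs_diff: float
    sd_abs_diff: float
    mean_range: float
    sd_range: float
    mean_sd: float
    sd_sd: float
    t_test_vs_range: TestResult
    t_test_vs_sd: TestResult
    range_histogram: pd.DataFrame  # bin_low, bin_high, count
    n_range_100: int
    n_range_within_20: int
    n_range_0: int


def load_pgt(csv_path: str | Path) -> list[PGTRecord]:
    """Read the PGT CSV (photo_id, r1, r2, r3, ai_pgt)."""
    df = pd.read_csv(csv_path, comment="#")
    required = ["photo_id", "r1", "r2", "r3", "ai_pgt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"PGT CSV is missing columns {missing}")
    return [
        PGTRecord(
            photo_id=str(row.photo_id),
            reviewer_estimates=(float(row.r1), float(row.r2), float(row.r3)),
            ai_pgt=float(row.ai_pgt),
        )
        for row in df.itertuples(index=False)
    ]


def ai_pgt_from_areas(granulation_area: float, wound_area: float) -> float:
    """PGT in percent from the tool's own granulation and wound trace areas."""
    if wound_area <= 0:
        raise ValidationError("wound area must be positive to compute PGT")
    if granulation_area < 0 or granulation_area > wound_area:
        raise ValidationError("granulation area must lie within [0, wound area]")
    return 100.0 * granulation_area / wound_area


def pgt_differences(records: list[PGTRecord]) -> np.ndarray:
    """|AI PGT - mean reviewer estimate| per photograph, in percent."""
    return np.array(
        [abs(r.ai_pgt - float(np.mean(r.reviewer_estimates))) for r in records]
    )


def pgt_variability(records: list[PGTRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Per-photograph range and SD (n-1 denominator) of the 3 estimates."""
    est = np.array([r.reviewer_estimates for r in records], dtype=float)
    if est.size == 0:
        return np.array([]), np.array([])
    ranges = est.max(axis=1) - est.min(axis=1)
    sds = est.std(axis=1, ddof=1)
    return ranges, sds


def pgt_compare(records: list[PGTRecord]) -> PGTSummary:
    """Full PGT comparison: paired t tests and the range histogram.

    The histogram uses 10%-wide bins [0,10), [10,20), ..., [90,100]; the
    category counts (range = 100, range <= 20, range = 0) are tallied on the
    same per-photo ranges, so they stay consistent with n.
    """
    if len(records) < 2:
        raise ValidationError("need at least 2 PGT records")
    diffs = pgt_differences(records)
    ranges, sds = pgt_variability(records)

    edges = np.arange(0, 110, 10)
    counts, _ = np.histogram(ranges, bins=edges)
    hist = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
    assert int(hist["count"].sum()) == len(records)

    return PGTSummary(
        n=len(records),
        mean_abs_diff=float(diffs.mean()),
        sd_abs_diff=float(diffs.std(ddof=1)),
        mean_range=float(ranges.mean()),
        sd_range=float(ranges.std(ddof=1)),
        mean_sd=float(sds.mean()),
        sd_sd=float(sds.std(ddof=1)),
        t_test_vs_range=paired_t(diffs, ranges),
        t_test_vs_sd=paired_t(diffs, sds),
        range_histogram=hist,
        n_range_100=int((ranges == 100).sum()),
        n_range_within_20=int((ranges <= 20).sum()),
        n_range_0=int((ranges == 0).sum()),
    )
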