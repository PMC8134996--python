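"""End-to-end study analysis: from a trace manifest to tidy result tables.

Thin orchestration over the other modules; every function takes and returns
plain in-memory objects (lists of records, pandas DataFrames) so it can be
driven equally from Python or the command line.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from .errors import DegenerateSampleError
from .roi_io import PhotoTraces, load_manifest
from .stats import format_p, wilcoxon_signed_rank
from .study_design import (
    MEASURES,
    ComparisonRecord,
    build_comparisons,
    comparisons_frame,
    paired_error_table,
    summary_frame,
    are_vs_size_table,
)

__all__ = [
    "compare_manifest",
    "records_from_groups",
    "wilcoxon_table",
    "write_csv",
]


def records_from_groups(
    groups: dict[str, dict[str, PhotoTraces]], ai_id: str = "AI"
) -> list[ComparisonRecord]:
    """Comparison records for every photograph of every kind."""
    records: list[ComparisonRecord] = []
    for kind in sorted(groups):
        for photo_id in sorted(groups[kind]):
            records.extend(build_comparisons(groups[kind][photo_id], ai_id=ai_id))
    return records


def compare_manifest(
    manifest_csv: str | Path, ai_id: str = "AI"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the comparison design over a manifest.

    Returns (per-comparison table, group summary table, ARE-vs-size table).
    """
    groups = load_manifest(manifest_csv)
    records = records_from_groups(groups, ai_id=ai_id)
    return comparisons_frame(records), summary_frame(records), are_vs_size_table(records)


def wilcoxon_table(records: list[ComparisonRecord], ai_id: str = "AI") -> pd.DataFrame:
    """Matched-pairs signed-rank tests of AI-vs-human against human-vs-human.

    One row per (kind, measure).  Matching is one shared-reference pair per
    photograph: for each photo the first human reference (sorted order) is
    taken and the AI-vs-reference error is paired with the other-human-vs-
    same-reference error.  With a single common reference the paired
    difference is, under equally accurate annotators, symmetric about zero
    (swapping the AI and the other human negates it), which is exactly the
    signed-rank null; using both references per photo gives correlated,
    asymmetric pairs and an anti-conservative test.  Measures with too few
    informative pairs yield a warning row (NaN statistic) rather than an
    error.
    """
    by_kind: dict[str, list[ComparisonRecord]] = {}
    for r in records:
        by_kind.setdefault(r.kind, []).append(r)

    rows = []
    for kind in sorted(by_kind):
        for measure in MEASURES:
            pairs = paired_error_table(by_kind[kind], measure, ai_id=ai_id)
            if not pairs.empty:
                pairs = (
                    pairs.sort_values(["photo_id", "reference_id"])
                    .groupby("photo_id", as_index=False)
                    .first()
                )
            row = {"kind": kind, "measure": measure, "n_pairs": len(pairs)}
            try:
                if len(pairs) < 1:
                    raise DegenerateSampleError("no matched pairs")
                res = wilcoxon_signed_rank(
                    pairs["ai_vs_human"].to_numpy(), pairs["human_vs_human"].to_numpy()
                )
                row.update(
                    statistic=res.statistic, p_value=res.p_value,
                    p_formatted=format_p(res.p_value), n=res.n, exact=res.exact,
                    note="",
                )
            except DegenerateSampleError as exc:
                row.update(
                    statistic=float("nan"), p_value=float("nan"), p_formatted="",
                    n=0, exact=False, note=str(exc),
                )
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["kind", "measure", "n_pairs", "statistic", "p_value",
                 "p_formatted", "n", "exact", "note"],
    )


def write_csv(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a result table with a run-metadata comment header.

    The header records the package version, the seed (when the producing
    computation was stochastic) and a content hash, so identical inputs are
    verifiably byte-identical outputs.
    """
    from . import __version__

    body = df.to_csv(index=False)
    digest = hashlib.sha256(body.encode()).hexdigest()[:12]
    seed_part = f" seed={seed}" if seed is not None else ""
    header = f"# woundmetrics v{__version__}{seed_part} sha256={digest}\n"
    Path(path).write_text(header + body)
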