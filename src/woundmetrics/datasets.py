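"""Worked-example data: masked-reviewer survey counts from a published
two-site evaluation of an AI wound-tracing tool.

Six attending wound-care clinicians (three per site) reviewed each
photograph's three tracings (AI, H1, H2) and answered, per tracing or per
photograph: Q1 — does the tracing meet the standardized wound-area
definition (yes/no per annotator); Q2 — which tracing was produced by the
AI (one choice); Q3 — which tracing is most accurate (one choice).
Denominators vary because reviewers could skip items.

These counts serve as the package's worked example and as inputs to the
survey-analysis test suite: aggregating them must reproduce the study's
pooled agreement rates (352/583 = 60.4% for AI, 793/1166 = 68.0% for
humans) and per-reviewer test results.
"""

from __future__ import annotations

__all__ = ["EXAMPLE_SURVEY_COUNTS"]

# (site, reviewer) -> question -> annotator -> (count, total)
# For q1 the count is "yes" answers; for q2/q3 it is selection frequency.
EXAMPLE_SURVEY_COUNTS: dict = {
    ("S1", "R1"): {
        "q1": {"AI": (42, 100), "H1": (65, 100), "H2": (51, 100)},
        "q2": {"AI": (37, 105), "H1": (39, 105), "H2": (29, 105)},
        "q3": {"AI": (32, 91), "H1": (27, 91), "H2": (32, 91)},
    },
    ("S1", "R2"): {
        "q1": {"AI": (53, 110), "H1": (59, 110), "H2": (53, 110)},
        "q2": {"AI": (42, 109), "H1": (27, 109), "H2": (40, 109)},
        "q3": {"AI": (39, 108), "H1": (32, 108), "H2": (37, 108)},
    },
    ("S1", "R3"): {
        "q1": {"AI": (67, 110), "H1": (82, 110), "H2": (72, 110)},
        "q2": {"AI": (42, 109), "H1": (33, 109), "H2": (34, 109)},
        "q3": {"AI": (35, 109), "H1": (42, 109), "H2": (32, 109)},
    },
    ("S2", "R1"): {
        "q1": {"AI": (65, 89), "H1": (67, 89), "H2": (65, 89)},
        "q2": {"AI": (3, 89), "H1": (36, 89), "H2": (50, 89)},
        "q3": {"AI": (19, 89), "H1": (48, 89), "H2": (22, 89)},
    },
    ("S2", "R2"): {
        "q1": {"AI": (78, 85), "H1": (79, 85), "H2": (82, 85)},
        "q2": {"AI": (42, 85), "H1": (20, 85), "H2": (23, 85)},
        "q3": {"AI": (25, 85), "H1": (38, 85), "H2": (22, 85)},
    },
    ("S2", "R3"): {
        "q1": {"AI": (47, 89), "H1": (63, 89), "H2": (55, 89)},
        "q2": {"AI": (24, 89), "H1": (44, 89), "H2": (21, 89)},
        "q3": {"AI": (24, 89), "H1": (44, 89), "H2": (21, 89)},
    },
}
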