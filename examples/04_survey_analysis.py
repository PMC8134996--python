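"""Masked-reviewer survey analysis on the bundled worked-example counts.

Six clinicians answered, per photograph: Q1 - does each tracing meet the
wound-area definition; Q2 - which tracing is the AI's; Q3 - which is most
accurate.  The bundled counts aggregate to the pooled Q1 agreement rates
60.4% (AI) vs 68.0% (human), and each reviewer gets a Fisher exact (Q1) or
chi-square (Q2/Q3) test.
"""

from woundmetrics import agreement_table, chi_square_gof, q1_fisher
from woundmetrics.datasets import EXAMPLE_SURVEY_COUNTS
from woundmetrics.qualitative import responses_from_q1_counts
from woundmetrics.stats import format_p

responses = []
for (site, reviewer_id), questions in EXAMPLE_SURVEY_COUNTS.items():
    responses.extend(responses_from_q1_counts(site, reviewer_id, questions["q1"]))

table = agreement_table(responses)
print(
    f"pooled Q1 agreement: AI {table.ai_yes}/{table.ai_total} "
    f"= {100 * table.ai_rate:.1f}%, "
    f"human {table.human_yes}/{table.human_total} = {100 * table.human_rate:.1f}%"
)

print("\nper-reviewer Q1 Fisher exact (AI vs pooled humans):")
for rev in sorted({r.reviewer for r in responses}):
    res = q1_fisher(responses, rev)
    print(f"  {rev[0]}/{rev[1]}: P = {format_p(res.p_value)}")

print("\nper-reviewer Q2 'which tracing is the AI?' vs uniform chance:")
for (site, rid), questions in sorted(EXAMPLE_SURVEY_COUNTS.items()):
    counts = [questions["q2"][a][0] for a in ("AI", "H1", "H2")]
    res = chi_square_gof(counts)
    print(f"  {site}/{rid}: counts {counts}, chi2 = {res.statistic:.2f}, "
          f"P = {format_p(res.p_value)}")
# A significant Q2 chi-square means the reviewer picked some tracing
# systematically - not necessarily the AI's (see the S2/R1 counts, which
# almost never point at the AI).
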