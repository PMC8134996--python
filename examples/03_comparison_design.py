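"""The one-AI / two-human comparison design and its missing-trace rules.

Each human tracing serves as both reference and test (4 records per fully
annotated photograph); the AI never serves as reference.  Demonstrates the
record counts and the median [IQR] group summaries on a small synthetic
study.
"""

from woundmetrics import build_comparisons, simulate_study
from woundmetrics.pipeline import records_from_groups
from woundmetrics.study_design import summary_frame

study = simulate_study(n_photos=20, granulation_photo_fraction=0.0, seed=7)

# record-count law on the simulated photographs
wound_photos = study.photos["wound_area"]
for photo_id in list(wound_photos)[:3]:
    photo = wound_photos[photo_id]
    absent = [t for t, tr in photo.traces.items() if tr.is_absent]
    n = len(build_comparisons(photo))
    print(f"{photo_id}: absent={absent or 'none'} -> {n} comparison records")

records = records_from_groups(study.photos)
print(f"\ntotal records over {len(wound_photos)} photographs: {len(records)}")

summary = summary_frame(records)
print("\nmedian [IQR] per group and measure (fractions of reference area):")
for _, row in summary.iterrows():
    print(
        f"  {row.group:<16} {row.measure}: "
        f"{100 * row['median']:.1f}% [{100 * row.q1:.1f}%-{100 * row.q3:.1f}%]  (n={row.n})"
    )
# With equally accurate annotators (the default), the ai_vs_human and
# human_vs_human rows should look alike.
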