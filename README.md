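# woundmetrics

Evaluation framework for AI-based digital wound assessment: quantify how
well an automated wound-tracing tool agrees with human annotators, using
reference-normalized overlap errors, a matched comparison design, an exact
small-sample statistical battery, masked-reviewer survey analysis, and
percent-granulation-tissue (PGT) agreement — plus a synthetic-study
generator so the whole pipeline is testable without clinical photographs.

## The scientific problem

Wound care tracks healing by the wound's area over time. Digital planimetry
replaces ruler estimates with traced boundaries on photographs, and
AI tools now draw those boundaries automatically. Before such a tool can be
trusted, its tracings must be compared against expert human tracings — but
there is no single ground truth: two careful humans disagree with each
other, so the right question is whether the AI-vs-human disagreement is
larger than the human-vs-human disagreement on the same photographs.

`woundmetrics` implements that evaluation. For a test trace T measured
against a reference trace R with overlap O (all pixel areas):

- **FNA** = (R − O)/R — fraction of the reference the test missed,
- **FPA** = (T − O)/R — test area outside the reference, per reference area,
- **RE** = (T − R)/R and **ARE** = |T − R|/R — signed/absolute relative
  area error (size only; blind to location).

Each photograph has one AI trace and two human traces; each human trace
serves as both reference and test (the AI is never the reference), giving 4
comparison records per fully annotated photograph, with explicit rules for
absent (fully epithelialized) traces. AI-vs-human errors are tested against
human-vs-human errors with an exact Wilcoxon matched-pairs signed-rank test
on shared-reference pairs. Masked-reviewer surveys (is each tracing
adequate? which one is the AI's? which is most accurate?) are analyzed with
Fisher exact and chi-square tests, and the tool's PGT measurement is
compared against three reviewers' visual estimates with paired t tests.

See [docs/methods.md](docs/methods.md) for the full model, parameter
defaults and their rationale, and limitations.

## Worked example

The package bundles the per-reviewer survey counts of a two-site clinical
evaluation (`woundmetrics.datasets.EXAMPLE_SURVEY_COUNTS`; six wound-care
clinicians, three questions each). Running
`python examples/04_survey_analysis.py` prints:

```
pooled Q1 agreement: AI 352/583 = 60.4%, human 793/1166 = 68.0%

per-reviewer Q1 Fisher exact (AI vs pooled humans):
  S1/R1: P = .0101
  S1/R2: P = .726
  S1/R3: P = .107
  S2/R1: P = .883
  S2/R2: P = .414
  S2/R3: P = .0447

per-reviewer Q2 'which tracing is the AI?' vs uniform chance:
  S1/R1: counts [37, 39, 29], chi2 = 1.60, P = .449
  S1/R2: counts [42, 27, 40], chi2 = 3.65, P = .161
  S1/R3: counts [42, 33, 34], chi2 = 1.34, P = .512
  S2/R1: counts [3, 36, 50], chi2 = 39.26, P = <.001
  S2/R2: counts [42, 20, 23], chi2 = 10.05, P = .00658
  S2/R3: counts [24, 44, 21], chi2 = 10.54, P = .00515
```

Reviewers found AI tracings adequate slightly less often than human ones
(60.4% vs 68.0% pooled), only one of six reviewers showed a significant
per-reviewer difference at the .01 level, and the site-2 reviewers picked
"the AI tracing" far from uniformly — reviewer S2/R1 almost never pointed
at the actual AI (3 of 89).

The same analyses run end-to-end on simulated studies. From
`python examples/06_full_study_simulation.py`, where the simulated AI has
3× the humans' boundary jitter (40 photographs, seed 21):

```
         group measure  n  median_pct
   ai_vs_human     FNA 76        10.3
   ai_vs_human     FPA 76        28.5
   ai_vs_human     ARE 76        28.9
human_vs_human     FNA 76         8.2
human_vs_human     FPA 76         8.4
human_vs_human     ARE 76         8.3

matched-pairs Wilcoxon, AI-vs-human against human-vs-human:
  FNA: n = 37 pairs, P = .113
  FPA: n = 37 pairs, P = <.001
  ARE: n = 37 pairs, P = <.001
```

The inferior AI is detected on the size-sensitive measures. All examples in
`examples/` are runnable as-is and print one-line interpretations.

## Command line

A thin CLI wraps the library:

```sh
woundmetrics simulate --out study/ --seed 1 --n-photos 40 --ai-jitter 9
woundmetrics compare  --manifest study/manifest.csv --out results/
woundmetrics stats    --manifest study/manifest.csv --out results/
woundmetrics survey   --survey-csv study/survey.csv --out results/
woundmetrics pgt      --pgt-csv study/pgt.csv --out results/
```

Input formats: a `manifest.csv` (photo_id, tracer_id, kind, path,
canvas_width, canvas_height) pointing at ImageJ `.roi` files (polygon,
freehand or traced types, subpixel supported; `;`-separated paths for
satellite lesions; empty path = absent trace), plus survey and PGT CSVs.
The `.roi` codec is built in — files written by `woundmetrics` open in
ImageJ and vice versa.

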