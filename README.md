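# mitostruct

Population-structure and demographic-inference toolkit for **grouped,
heterochronous mitochondrial genome alignments** — the kind of dataset
produced by ancient-DNA studies in which complete mtDNA sequences from
several archaeological groups (different sites, cultures and calendar
ages) are compared with each other and with competing demographic
hypotheses.

It was built around a concrete study design: 36 ancient mitogenomes
from five Sicilian localities (Bronze Age to Iron Age, seven
locality-by-culture groups, packaged as a metadata fixture), asking
whether an Iron Age group (the Sicanians) descends directly from the
local Bronze Age population (*continuity*) or from a lineage that
split from their ancestors during the Neolithic (*discontinuity*).
Every stage runs on synthetic data generated by the built-in
coalescent simulator, so nothing needs to be downloaded.

## What it computes

- **Haplogroup structure** — fine haplogroup labels (`T2b3+151`)
  collapsed to macro-haplogroups by longest-prefix match; per-group
  count/frequency tables; PCA biplots of group frequencies.
- **Within-group diversity** — number of haplotypes *K*, haplotype
  (gene) diversity *H* = n/(n−1)·(1 − Σpᵢ²), segregating sites *S*,
  mean pairwise differences π, and Tajima's
  *D* = (π − S/a₁)/√(e₁S + e₂S(S−1)).
- **Differentiation** — pairwise-difference and Kimura-2-parameter
  distance matrices (d = −½·ln((1−2P−Q)·√(1−2Q))); one-level AMOVA
  with Φ_ST = σ²ₐ/(σ²ₐ+σ²_w) and a label-permutation test (+1-smoothed
  p with binomial standard error); pairwise Φ_ST matrices; classical
  MDS (Torgerson double-centering).
- **Coalescent simulation** — haploid serial-sampling coalescent
  (rate k(k−1)/2/N per generation, lineages activate at their sampling
  age) under the continuity/discontinuity topologies, with
  finite-sites Jukes–Cantor mutation on an mtDNA-length locus.
- **ABC-RF model choice** — a reference table of 11 summary statistics
  (K, H, S, D, π per deme + pairwise Φ_ST) per simulated dataset,
  augmented with the Fisher LDA axis, classified by a 500-tree random
  forest; out-of-bag confusion matrix and per-model classification
  error; posterior probability of the selected model from a regression
  forest fitted to the OOB misclassification indicator.

## Worked example

```python
import mitostruct as ms

# packaged study metadata: 36 samples, 7 locality-by-culture groups
table = ms.make_table1_fixture()
freq = ms.frequency_table(table)
print(freq.frequencies.loc["Baucina_Sicanian", "T"])   # 0.4117647058823529
print(freq.frequencies.loc["Motya_Bronze_Age", "H"])   # 0.375
```

Macro-haplogroup T accounts for 7/17 ≈ 41% of the Baucina Sicanian
group and H for 3/8 = 37.5% of the Motya Bronze Age group — the
frequency pattern the group comparison is built on.

```python
import numpy as np
from mitostruct import coalescent as co
from mitostruct.abc_rf import (
    ModelChoiceForest, build_reference_table, summary_vector,
)
from mitostruct.synthetic import make_pseudo_observed

priors = {t: co.default_priors(t) for t in ("continuity", "discontinuity")}
table = build_reference_table(priors, co.SamplingConfig(), 5000, seed=1)
forest = ModelChoiceForest(table, n_trees=500, seed=2)
print({k: float(v) for k, v in forest.classification_error.items()})
# {'continuity': 0.305, 'discontinuity': 0.3104}

obs = make_pseudo_observed("continuity", {"n_anc": 1500.0, "mu": 2.2e-8}, seed=3)
res = forest.select(summary_vector(obs))
print(res.selected, res.votes, round(res.posterior_probability, 3))
# continuity {'continuity': 354, 'discontinuity': 146} 0.678
```

With the default overlapping priors the two demographic models are
genuinely hard to tell apart (OOB classification error ≈ 0.3), and a
dataset simulated under continuity is correctly selected with a
moderate posterior — which is exactly how an honest model-choice
procedure should behave in this regime.

The same analysis runs from the shell:

```bash
mitostruct synth --seed 5 --rung high --out demo/
mitostruct freqs --metadata demo/metadata.csv --out demo/freqs
mitostruct amova --alignment demo/alignment.fasta --metadata demo/metadata.csv
mitostruct run config.yaml          # full pipeline from a YAML config
```

## Layout

| module | contents |
| --- | --- |
| `mitostruct.seq_io` | FASTA/CSV IO, `Alignment`/`SampleTable`/`GroupedAlignment`, date parsing |
| `mitostruct.haplogroups` | macro collapsing, frequency tables, PCA |
| `mitostruct.diversity` | K, H, S, π, Tajima's D |
| `mitostruct.differentiation` | distances, AMOVA/Φ_ST, pairwise Φ_ST, MDS |
| `mitostruct.coalescent` | serial-sampling simulator, priors, mutation |
| `mitostruct.abc_rf` | summary vectors, reference tables, LDA, RF model choice |
| `mitostruct.synthetic` | synthetic fixtures and the packaged study table |
| `mitostruct.pipeline` / `mitostruct.cli` | YAML-driven orchestration, `mitostruct` CLI |

See `docs/methods.md` for the statistical model, parameter defaults
and the design decisions behind them.
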