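# Methods

This note documents the statistical machinery implemented in
`mitostruct`, the defaults it ships with, and the design decisions
taken where reasonable alternatives existed.

## Data model

Sequences are complete (or near-complete) mitochondrial genomes,
pre-aligned to a fixed coordinate frame (for humans, the 16,569-site
rCRS frame). The package never realigns: multiple sequence alignment
is an upstream step, and all statistics assume a shared site frame.
Characters are normalised to `{A,C,G,T,N,-}`; `U` maps to `T` and all
other IUPAC ambiguity codes to `N`. Gaps are treated as missing
exactly like `N` — mtDNA indel handling is not standardised across
tools, and pooling gaps with missing data avoids manufacturing
spurious segregating sites from alignment artifacts.

Calendar dates are converted to years BP (before 1950) by a midpoint
rule: "600–400 BCE" → 500 BCE → 2450 BP; "cal." qualifiers are
ignored; "3rd cen. BCE" → 250 BCE. Only coarse ages are needed — they
set sampling times for the serial coalescent, where a ±100-year error
is ~4 generations against coalescent timescales of thousands.

## Haplogroup frequencies and PCA

Fine haplogroup labels are collapsed to macro-haplogroups by
longest-prefix match against an ordered scheme
(L0–L5, HV, H, V, J, T, U, K, I, W, X, N, R, M), after stripping
diagnostic-position suffixes (`+151`, `+16,311`, `+72at`). Longest
prefix is what makes `HV0a` map to HV rather than H. L sub-lineages
outside L0–L5 fall back to `L`; any other unmatched label is an error
— frequency tables drive the headline ordination, and silently
pooling unknown labels into an "other" bin would bias it.

PCA operates on group-wise **relative frequencies**, column-centred;
unit-variance scaling is available behind a flag but off by default
(with ~10–20 frequency columns on a common 0–1 scale, scaling mostly
amplifies rare-haplogroup noise). Whether counts or frequencies,
scaled or not, is a genuinely open choice for this kind of biplot;
both are exposed, one is the documented default. Scores come from the
SVD of the centred matrix; with all-constant columns dropped (warned).
The fully degenerate case (identical rows) returns zero scores rather
than erroring.

## Diversity statistics

For one group of n sequences:

- **K** — distinct haplotypes after complete deletion (columns with
  any missing character removed first).
- **H** — haplotype (gene) diversity n/(n−1)·(1 − Σpᵢ²) over haplotype
  frequencies pᵢ (the unbiased estimator; H = 0 iff K = 1).
- **S** — polymorphic retained columns.
- **π** — mean pairwise difference count over all C(n,2) pairs;
  reported as a *count*, not per site. Default policy is pairwise
  deletion for π (each pair compared over its jointly complete sites)
  and complete deletion for K/H/S, mirroring common practice in
  Arlequin-style analyses; both policies are exposed because tools
  differ and the choice is rarely reported.
- **Tajima's D** — (π − S/a₁)/√(e₁S + e₂S(S−1)) with the standard
  constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂; undefined (None) when
  S = 0, and refused for n < 4 where the variance terms are unstable.
  Inside ABC feature vectors only, an undefined D is imputed as 0 and
  flagged — forest features cannot be missing, and discarding
  monomorphic simulations would bias the prior predictive.

## Differentiation

**Φ_ST / AMOVA.** "FST" throughout the package is the molecular,
distance-based Φ_ST of a one-level analysis of molecular variance
computed from raw pairwise difference counts (the Arlequin default for
DNA sequences). With N samples in P groups of sizes n_k:

    SSD_total  = (1/N) Σ_{i<j} d_ij
    SSD_within = Σ_k (1/n_k) Σ_{i<j∈k} d_ij
    SSD_among  = SSD_total − SSD_within
    σ²_within  = SSD_within/(N−P)
    n'         = (N − Σn_k²/N)/(P−1)
    σ²_among   = (SSD_among/(P−1) − σ²_within)/n'
    Φ_ST       = σ²_among/(σ²_among + σ²_within)

Significance comes from permuting individual group labels:
p = (1 + #{Φ_perm ≥ Φ_obs})/(n_perm + 1), ties counted (conservative),
default 10,000 permutations, reported with its binomial standard
error √(p(1−p)/n_perm) to match the "p ± se" convention of
permutation-based AMOVA reports. Pairwise Φ_ST runs the two-group
decomposition for every pair; negative estimates (sampling noise
around zero) are retained in tables and clamped to zero only when a
matrix feeds MDS, which requires a dissimilarity.

**K2P.** Kimura's two-parameter distance per pair over jointly
complete sites, d = −½·ln((1−2P−Q)·√(1−2Q)) with transition
proportion P and transversion proportion Q; a non-positive log
argument (saturation) yields a null entry with a warning rather than
a fabricated value.

**Classical MDS.** Torgerson scaling: B = −½·J·D∘D·J, eigendecomposed;
coordinates are the top-k eigenvectors scaled by √λ. If fewer than k
eigenvalues are positive, fewer axes are returned with a warning.

## Coalescent simulator

A haploid, serial-sampling coalescent with two topologies:

- **continuity** — one constant-size deme (haploid effective size
  `N_anc`) containing both sample groups; the younger group descends
  directly from the population that produced the older one.
- **discontinuity** — the younger group's lineages live in their own
  deme of size `N_sic` back to a divergence time `T_div` (years BP,
  required to predate the oldest sample), then merge into the
  `N_anc` deme.

N counts transmitting mtDNA lineages, so k active lineages coalesce
at rate k(k−1)/2/N per generation. Sampled lineages activate when the
(backwards) clock passes their age; between structural events
(activation, deme merger) waiting times are exponential at the
current rates, redrawn after each event (valid by memorylessness).
The continuity model has no size change — the hypothesis as drawn has
no bottleneck — but the parameterisation accepts distinct sizes
per deme, which is the hook for piecewise extensions.

Mutation is finite-sites Jukes–Cantor: per branch, a Poisson number
of hits at rate μ·gen_time·L per branch-generation; each hit picks a
uniform site and a uniform different base; the root sequence is drawn
uniformly. Finite sites (rather than infinite sites) matches how
sequence simulators in this field operate; at 16.6 kb and ancient
timescales recurrent hits are rare but free to model. For
reference-table construction the simulator returns only the touched
sites (`simulate_variants`) — every statistic in the package depends
on variable columns alone — which makes a 10,000-row table a
sub-minute computation; `drop_mutations` materialises the full
alignment when one is wanted. Both paths share the same mutation
engine, and a test pins their statistics to byte-level agreement.
The simulator's S, TMRCA (including serial sampling) and two-deme
Φ_ST distributions are cross-checked against msprime in the test
suite; msprime is only ever the oracle, never the implementation.

**Defaults** (all configurable; priors substitutable via YAML):

| parameter | default | why |
| --- | --- | --- |
| generation time | 25 y | conventional human mtDNA value |
| locus length L | 16,569 | rCRS frame |
| μ prior | log-uniform [1e-8, 5e-8] /site/y | conventional whole-mtDNA range |
| N priors | log-uniform [500, 5000] | broad, weakly informative size range for a regional maternal population |
| T_div prior | Uniform(6,000, 8,000) BP | the stated Neolithic divergence window of the discontinuity hypothesis |
| sampling | 8 at 3,500 BP + 17 at 2,450 BP | the study's Bronze Age (n=8) and Sicanian (n=17) group sizes and midpoint ages |

## ABC-RF model choice

Each simulated (or observed) two-deme dataset is summarised by 11
statistics — K, H, S, D, π per deme plus pairwise Φ_ST — in a fixed,
documented order. Per-deme statistics plus a differentiation index is
the standard summary set for two-population model choice; pooled
variants would add little beyond the per-deme values.

A reference table of equal numbers of simulations per model (labels
balanced by construction) is augmented with the single Fisher LDA
axis (two models ⇒ M−1 = 1 axis), fitted on the table only and
applied to the observation — an extra feature that linearises the
direction of maximal between-model separation. A random forest
(default 500 trees, √p features per split, no depth cap) is trained
on the augmented table. The OOB predictions give the confusion
matrix and per-model classification error; the observation's votes
are the per-tree predictions; the selected model is the majority
(lexicographic first on an exact tie, with a warning).

The posterior probability of the selected model follows the
regression-forest construction of the ABC-RF literature: a second
forest regresses the OOB misclassification indicator on the features,
and the posterior is 1 minus its prediction at the observed point.
Raw vote share is reported alongside, since the two can be compared.
Two cautions that the tests encode: the regression forest must be
evaluated at *fresh* points (at its own training rows it reproduces
the 0/1 targets), and per-class OOB error under pure label noise is
only centred at 0.5 when classes are exactly balanced (the forest's
majority bias otherwise skews per-class error in opposite
directions).

Under the default overlapping priors the two demographic models are
intrinsically hard to separate — per-model OOB error lands around
0.3 — and the meaningful guarantee is *calibration*: held-out
simulated datasets are misclassified at the rate the OOB error
predicts. The test suite asserts that calibration (±0.05 with
1,000 held-out datasets per model, where Monte-Carlo noise is small
against the tolerance), chance-level behaviour for indistinguishable
models, and near-perfect discrimination (error < 0.05, posterior
> 0.9) when priors are separated by two orders of magnitude in θ.

## Synthetic data

The generator ships three divergence rungs for two-group fixtures
(8 samples at 3,500 BP + 17 at 2,450 BP, matching the study design):

- **low** — panmixia (continuity, N = 1000): realised Φ_ST centred
  on 0;
- **medium** — discontinuity, T_div = 20,000 BP, N_sic = 1000;
- **high** — discontinuity, T_div = 100,000 BP, N_sic = 200: drift in
  a small isolated deme pushes realised Φ_ST above 0.3 in ≥90% of
  seeds.

Synthetic metadata assigns each distinct haplotype a random macro
class with a numeric subclade suffix, so frequency/PCA stages run on
simulator output. What the generator does *not* emulate: post-mortem
damage (statistics assume consensus-quality sequences), contamination,
coverage-dependent missingness (simulated data contain no Ns, unlike
real ancient genomes), recombination (absent in mtDNA), migration
after divergence, and selection. Passing tests therefore demonstrate
correctness of the statistics and the inference machinery, not
robustness to ancient-DNA artefacts — on real data those are handled
upstream, at consensus-calling.

The packaged study table (36 samples, seven locality-by-culture
groups) is a committed 2 kB CSV; alignment fixtures are generated on
demand from pinned seeds rather than committed.

## Reproducing the published comparison

Applying the pipeline to the real data requires inputs that are not
redistributable here: the deposited mitogenomes (GenBank accessions
listed in the data-availability statement of the originating study),
the literature comparison panel (336 individuals, 35 populations) and
the study's exact prior file. With those supplied — alignment +
metadata via the standard readers, priors via the YAML prior format —
the pipeline computes the same quantities the study reports (regional
AMOVA Φ_ST with permutation p, pairwise Φ_ST heatmap/MDS, and the
Table-2-style error/votes/posterior). This is an external-data
reproduction to run on demand, not part of the test suite.

## Numerical choices and limitations

- Permutation p-values use the +1 convention and ≥ ties: conservative,
  never exactly zero.
- AMOVA requires every group to have ≥ 2 members; the pipeline
  excludes singleton groups from Φ_ST/AMOVA with a logged warning
  (the packaged study table contains one singleton group).
- Saturated K2P pairs and pairs with no jointly complete site produce
  explicit nulls, not imputed numbers.
- Problem sizes in the test suite (reference tables of 5,000
  simulations per model, 2,000-replicate closed-form checks,
  1,000-site loci in distributional tests) are chosen so the whole
  suite completes in a few minutes while keeping Monte-Carlo noise
  well inside each asserted tolerance.
- Multi-level (hierarchical) AMOVA, Slatkin-linearised FST, mismatch
  distributions, Fu's Fs, ABC *parameter* estimation and >2-model
  choice are out of scope.
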