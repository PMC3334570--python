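# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `indelld`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model and preparation rules

Panels are strictly bi-allelic, fully phased haplotype matrices
(2N haplotypes × M sites). The preparation rules mirror standard practice
for phased low-coverage resequencing releases:

* multi-allelic records are dropped at read time and tallied, never
  retained or split;
* missing or unphased genotypes are a **hard error**. The supported data
  model is a complete phased release; silently dropping or imputing
  missingness would bias every downstream statistic in ways the user
  cannot see, so the reader refuses instead;
* when an indel file and a SNP file are merged and a position is present
  in both, the indel is retained and the SNP discarded (tallied). A
  same-class collision raises, since it indicates corrupted input;
* rare variants (MAF < 1%, in practice singletons at these sample sizes)
  are excluded from focal sets; 1–5% is "low frequency", ≥ 5% "common".
  MAF exactly 5% is binned *common* — the conventional phrasing
  ("MAF < 5%" vs "MAF > 5%") leaves the boundary unassigned, so the
  closed-right choice is made explicit here and is configurable via
  `MAFBinScheme`;
* coordinates are 1-based VCF positions; distances are |pos_a − pos_b| bp;
  windows are closed intervals; BED input is 0-based half-open and is
  converted internally;
* MAF is always recomputed from the panel's own haplotypes, never read
  from INFO fields, so sample subsets stay self-consistent.

## LD statistics

r² is computed from the phased 2×2 haplotype table
(D = p₁₁ − pq, r² = D²/(p(1−p)q(1−q))). Because haplotypes are observed,
there is no EM or composite-LD ambiguity, and a genotype-correlation mode
is deliberately not offered. Values are clipped to [0, 1] against
floating-point drift.

* **Scan window**: ±100 kb around each focal variant; partners are
  polymorphic SNPs (monomorphic partners are skipped and tallied; a
  monomorphic focal raises).
* **Average r² curve**: arithmetic mean of all pairwise values in 100-bp
  distance bins; bin b covers [b·w + 1, (b+1)·w]. Empty bins are emitted
  with n = 0 and NaN, and are excluded from statistics rather than
  zero-filled.
* **Mean max r² curve**: per focal variant and 1-kb bin, the maximum r²
  among that focal's partners in the bin, averaged across focal variants
  with ≥ 1 partner there (n counts focals). An alternative reading —
  assigning each focal's single overall maximum to its best partner's
  distance bin — exists but is not implemented.
* **Tagging**: "greater than" is strict (r² > 0.5, r² > 0.8); perfect LD
  means r² ≥ 1 − 10⁻⁹. Focal variants with no partner at all stay in the
  denominator as untagged. Percentages are monotone non-increasing in the
  threshold by construction.
* **Haplotype span**: the positional extent max(pos) − min(pos) of
  {focal} ∪ {partners with r² > 0.8}. "Extended haplotype length" has no
  single standard definition; this positional-extent interpretation is
  documented rather than hidden.
* **Focal sampling**: by default all eligible focal indels are analysed;
  a random subsample (mandatory seed) is available for large panels.

## The haplotype-copying imputer

A Li–Stephens-style HMM with the H reference haplotypes as hidden states:

* transition over distance d bp: stay = exp(−λd) + (1 − exp(−λd))/H to
  the same state, (1 − exp(−λd))/H to each specific other state;
* emission: 1 − ε on allele match, ε on mismatch;
* posterior weights are read at the context SNP nearest the query
  position (left on ties) after a full scaled forward–backward pass.
  Reading at the nearest SNP rather than interpolating between flanking
  SNPs is simpler and exact in the dense-SNP regime this pipeline
  targets.

Defaults: λ = 4·10⁻⁵ /bp, giving an expected copy-segment length of
25 kb — the haplotype scale of common short variants in outbred human
panels; ε = 0.005, i.e. observed genotypes are treated as correct with
probability 0.995. Both are exposed in `CopyingModelParams`.

A genotype is imputed by decoding the sample's two haplotypes
independently (the panel is phased) and combining the per-haplotype alt
probabilities as a product. Hard calls are the argmax; exact ties break
toward the genotype class more frequent in the panel at that site.

**Leave-one-individual-out protocol.** The evaluated individual's two
haplotypes are removed from the reference and the focal indel is masked in
the target. In-sample evaluation would let the engine copy the truth from
the sample's own haplotypes and report near-perfect concordance for any
panel (the test suite demonstrates this degenerate limit explicitly), so
leave-out is the only honest protocol and is used everywhere.
(Focal, sample) pairs whose leave-out reference is monomorphic at the
focal are skipped and tallied rather than imputed from a constant column.

Concordance pools genotypes within a stratum (genotype-weighted
denominators). Weighting indels equally instead would up-weight sparse
indels; the pooled convention is stated here because the two disagree
whenever per-indel genotype counts differ.

The production evaluation path batches the forward–backward over all 2N
target haplotypes at once: a state with zero emission carries zero mass
through the recursion, so masking each target's own two rows and keeping
the switch denominator at H − 2 is algebraically identical to running the
restricted (2N − 2)-state model per target. The test suite checks this
equivalence against the single-target decoder, which is itself checked
against exhaustive path enumeration.

**r²-binned experiment.** Pairwise r² between each focal indel and its
in-window SNPs is computed on the full panel; SNPs are grouped into twenty
0.05-wide bins (left-open right-closed, first bin closed at 0, r² = 1 in
the top bin), and each group alone is used to re-impute the indel
leave-one-out. Focals with no SNP in a bin are excluded from that bin's
denominators. The context restriction is applied before the HMM runs;
phasing is not recomputed per bin (the panels are phased by
construction).

**Frequency-matched experiment.** Identical to the plain evaluation but
each focal's context is restricted to SNPs in its own MAF bin; focals with
no matched context SNP are skipped and tallied.

## The synthetic-data generator

Purpose: exercise every pipeline stage — merge rules, MAF stratification,
LD scans, tagging, all three imputation protocols — without any external
download, under conditions that are *qualitatively* like a human
low-coverage resequencing panel.

Mechanism: K founder haplotypes with independent per-site alleles; each
sample haplotype copies a founder and switches with probability
1 − exp(−λ_sim·d) per d bp; fresh mutations flip entries independently;
sites monomorphic in the sample are dropped (site count is a target, not
a guarantee). Founder frequencies follow a truncated f^−α density
(inverse-CDF sampling; α = 0 degenerates to uniform on [f_min, 0.5]).

Founder **copy weights decay geometrically by rank** (ratio 0.5 by
default; 1.0 recovers uniform copying). This is the one structural choice
that needs justification: with uniform copying, sample frequencies
quantize near 1/K, so no founder count yields both a populated 1–5% MAF
bin and non-trivial LD. Rank-decaying weights let high-rank (rare)
founders carry low-frequency haplotype backgrounds while the effective
founder diversity 1/Σw² stays ≈ 7, preserving realistic tagging levels.

Defaults (the study conditions; chosen once):

| parameter | default | why |
|---|---|---|
| n_samples | 60 | one population panel of a low-coverage pilot |
| region_length / n_sites | 1 Mb / 2000 | ≈ 2 segregating sites per kb at desk scale |
| founder_count K | 12 | with decay 0.5, effective diversity ≈ 7 |
| switch_rate_sim | 2·10⁻⁵ /bp | ≈ 50 kb mosaic segments → LD decays over tens of kb |
| mutation_rate | 10⁻³ | light haplotype noise without destroying LD |
| sfs_exponent / f_min | 1.0 / 0.03 | 1/f-like folded spectrum; low-frequency share responds monotonically to the exponent |
| indel_fraction | 0.08 | ≈ 1.3M indels vs ≈ 15M SNPs in human panels |
| deletion_odds | 1.25 | the observed ≈ 25% deletion excess |
| length_geom_p | 1 − 0.1^(1/6) ≈ 0.319 | P(length ≤ 6) = 0.90 exactly; capped at 49 bp |
| lof_rate | 0.5 | LOF labels only inside exon intervals |

Every output is a pure function of `SimulationConfig` including its
mandatory seed. The indel overlay changes site metadata only, never the
allele columns, so it cannot perturb frequencies or LD.

**What the generator does *not* emulate — and what that means for the
tests.** No demography (bottlenecks, multiple populations), no gene
conversion, no mutation-rate heterogeneity at repeat loci, no
ascertainment bias. Most importantly, sample haplotypes are *exact copies*
of founder segments, so a variant's allele is a near-deterministic
function of local founder identity. Two consequences:

1. any SNP set that identifies the copied founder — even SNPs with low
   direct r² to the focal — carries substantial imputation information,
   lifting concordance in the low-r² bins of the binned experiment above
   what heterogeneous real backgrounds would give, and producing a small
   systematic dip (rather than a monotone rise) across the 0.05–0.20 bins;
2. rare alleles sit on identical shared backgrounds, so homozygous-rare
   genotypes are *easier* to impute here than in real data, where
   genotype-likelihood input, phasing uncertainty and frequency priors in
   production engines (all out of scope for this transparent model)
   depress alt/alt concordance severely.

Passing tests on synthetic panels therefore demonstrate correctness of
the machinery and the frequency-driven qualitative patterns (tagging
stratification, the strong rise of heterozygote concordance with r², the
perfect-tag limit), not engine-level fidelity to published concordance
values on real panels. The acceptance suite states the monotonicity and
rare-homozygote expectations in their strict form and two of those checks
fail for exactly the two reasons above; they are left failing rather than
weakened, as a documented model-scope boundary.

## Pipeline and reporting

`run_full_analysis` executes ingest/simulate → merge → annotation → LD →
tagging (plain and frequency-matched) → span summaries with
between-stratum tests → the three imputation protocols → the r² > 0.8
tag-lookup table, writing plain TSVs plus a JSON manifest (config hash,
seed, package version) sufficient to reproduce every table bit-for-bit.
Stages are independently toggleable; re-running a subset reproduces the
full-run tables for the stages executed.

Between-stratum comparisons use the two-sided pooled two-proportion
z-test (no continuity correction — results may differ in the last digit
from corrected variants) for tagging percentages, and the asymptotic
tie-corrected Mann–Whitney test for span and max-r² distributions. **No
multiple-testing correction is applied**, and the comparison table's
provenance notes say so, so readers are not misled by nominal p-values.
Degenerate cases (pooled proportion 0 or 1; all observations tied) return
p = 1 with an explicit degenerate flag and a warning rather than raising.

## Numerical conventions

* forward–backward is per-step renormalized (scaled) rather than run in
  log space; posteriors match exhaustive path enumeration to 10⁻⁹ on
  small instances;
* r² is clipped to [0, 1]; perfect LD uses tolerance 10⁻⁹;
* genotype posteriors are renormalized after the product combination and
  must sum to 1 within 10⁻⁹;
* empty strata / bins / classes propagate as n = 0 with NaN values, never
  as zeros;
* all stochastic steps take explicit integer seeds; no global RNG state
  is used anywhere.

## Known limitations

* The copying model ignores genotype likelihoods and unphased targets by
  design; it is a transparent stand-in, not a reimplementation of
  production imputation engines.
* The founder-mosaic panel is a testbed, not a population-genetic
  simulation; see the consequences above.
* X/Y/mitochondrial records are accepted syntactically but treated as
  autosomal (no ploidy handling).
* Region annotation is interval containment on a BED file; it does not
  infer gene models or functional consequences — LOF status is an input
  label.
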