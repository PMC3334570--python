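# indelld

Linkage-disequilibrium profiling and imputation-power evaluation for short
insertion/deletion polymorphisms (indels) in phased population panels.

## The problem

Short indels (< 50 bp) are the second most abundant class of human genetic
variation, yet genotyping arrays type almost exclusively SNPs. Whether an
indel can be studied in an association framework therefore hinges on two
questions about its local haplotype structure:

1. **Tagging** — does some nearby SNP travel on the same haplotype
   background, i.e. is there a SNP with high r² to the indel?
2. **Imputation** — given the SNP genotypes of an individual and a phased
   reference panel, how accurately can the indel genotype be inferred?

`indelld` answers both for any phased, bi-allelic panel (real VCFs or its
bundled simulator), stratifying by minor allele frequency (MAF), indel
size, and loss-of-function (LOF) status.

## The statistics and the model

**Pairwise LD** is computed from phased haplotypes via the 2×2 haplotype
table:

    D  = p₁₁ − p·q,        r² = D² / ( p(1−p) · q(1−q) )

where p, q are the alt-allele frequencies at the two sites and p₁₁ the
frequency of haplotypes carrying alt at both. Every focal variant is
paired with all polymorphic SNPs within ±100 kb. Summaries follow the
standard conventions: *average r²* (mean of all pairwise values in 100-bp
distance bins), *mean max r²* (per focal variant and 1-kb bin, the maximum
r² among partners in the bin, averaged over focal variants), and tagging
tables at r² > 0.5, r² > 0.8 and r² = 1.

**Imputation** uses a transparent Li–Stephens-style haplotype-copying HMM:
a target haplotype is an imperfect mosaic of the H reference haplotypes,
switching between copies with probability 1 − exp(−λd) per d bp
(λ = 4·10⁻⁵ by default, ≈ 25 kb copy segments) and emitting the observed
allele with error ε = 0.005. Posterior copying weights w at the focal
position give the per-haplotype alt probability Σₕ wₕ·alleleₕ, and the two
phased haplotypes combine independently into P(ref/ref), P(ref/alt),
P(alt/alt). Evaluation is **leave-one-individual-out**: the evaluated
sample's two haplotypes are removed from the reference and the indel is
masked, so nothing can be copied from itself. Concordance (argmax call vs
truth) is reported separately per true genotype class — ref/ref, ref/alt,
alt/alt — because the three classes behave very differently at low MAF.

**The simulator** builds panels as recombinant mosaics of a small founder
set with rank-decaying copy weights, a truncated f^−α founder-frequency
spectrum, and an indel overlay with a 1.25:1 deletion excess and geometric
lengths calibrated so 90% of indels are ≤ 6 bp. It exists so the entire
pipeline is testable end-to-end without any external download; it is not a
demographic simulator (see `docs/methods.md`).

## Worked example

```python
from indelld.pipeline import AnalysisConfig, run_full_analysis
from indelld.simulate import SimulationConfig

cfg = AnalysisConfig(
    out_dir="example",
    seed=11,
    simulation=SimulationConfig(
        seed=11, n_samples=40, n_sites=600, region_length=300_000
    ),
)
bundle = run_full_analysis(cfg)
print(bundle.tables["tagging"])
print(bundle.tables["concordance"])
```

prints (among other tables)

```
stratified_by stratum  threshold  n_total  n_tagged   percent
      maf_bin  common        0.5       29        27 93.103448
      maf_bin  common        0.8       29        21 72.413793
      maf_bin  common        1.0       29         7 24.137931
      maf_bin     low        0.5        9         8 88.888889
      maf_bin     low        0.8        9         6 66.666667
      maf_bin     low        1.0        9         6 66.666667

stratified_by stratum    n  refref_concordance  refalt_concordance  altalt_concordance  overall_concordance
      maf_bin  common 1160            0.986916            0.956835            0.980769             0.975000
      maf_bin     low  355            1.000000            0.777778                 NaN             0.994366
```

Reading: of the 29 common focal indels in this simulated region, 72% have
at least one SNP in high LD (r² > 0.8) and 24% a perfect proxy; common
indel genotypes are imputed with 97.5% overall concordance, while for
low-frequency indels the heterozygote class is clearly harder (77.8%) and
the panel contains no alt/alt genotype at all (NaN) — the frequency-driven
asymmetry this package is built to quantify. Every table is also written
as TSV under `out_dir`, together with a `manifest.json` (config hash,
seed, version) that reproduces the run bit-for-bit.

The same analyses run from the shell:

```
indelld simulate --seed 5 --out-dir sim/
indelld report --config analysis.yaml
```

with subcommands `simulate`, `merge`, `annotate`, `ld`, `tagging`,
`impute-eval`, `r2bins`, `tag-lookup`, `report`.

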