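"""Founder-mosaic simulator for phased haplotype panels.

The generator exists so every pipeline stage — merge rules, LD scans,
tagging, imputation — can be exercised end-to-end without any external
download.  It is deliberately *not* a demographic simulator: sample
haplotypes are recombinant mosaics of a small founder set, which yields
distance-decaying LD with a tunable scale, and per-site founder
frequencies are drawn from a truncated f^-alpha density, which yields a
1/f-like folded site-frequency spectrum.  Fidelity to human demographic
history (bottlenecks, multiple populations, gene conversion) is explicitly
out of scope.

The indel overlay relabels a configurable fraction of sites as indels with

* a deletion excess of 1.25 : 1 (deletions : insertions),
* geometric lengths calibrated so ~90% of indels are <= 6 bp
  (P(L <= 6) = 1 - (1-p)^6 = 0.9 by default), capped below 50 bp,
* LOF labels assigned only inside exon intervals, at a configurable rate.

Every output is a pure function of :class:`SimulationConfig`, including
its mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .vcf_io import (
    HaplotypePanel,
    SiteList,
    VariantSite,
    write_vcf,
)

_BASES = np.array(list("ACGT"))

# P(L <= 6) = 1 - (1 - p)^6 = 0.90
DEFAULT_LENGTH_GEOM_P = 1.0 - 0.1 ** (1.0 / 6.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic panel.

    Defaults describe the regime this package targets: a human-like,
    low-coverage-resequencing-scale panel of 60 diploid samples over a
    1 Mb region, with LD decaying on the tens-of-kb scale and indels
    forming ~8% of segregating sites.
    """

    seed: int
    n_samples: int = 60
    region_length: int = 1_000_000
    n_sites: int = 2_000
    founder_count: int = 12
    switch_rate_sim: float = 2e-5  # per-bp founder-mosaic switch intensity
    mutation_rate: float = 0.001  # per-(haplotype, site) flip probability
    sfs_exponent: float = 1.0  # founder-frequency density ~ f^-alpha
    f_min: float = 0.03  # lower truncation of the founder-frequency density
    founder_weight_decay: float = 0.5  # copy-weight ratio between ranks; 1 = uniform
    indel_fraction: float = 0.08
    deletion_odds: float = 1.25  # deletions : insertions
    length_geom_p: float = DEFAULT_LENGTH_GEOM_P
    lof_rate: float = 0.5  # P(LOF | exonic indel)
    exon_intervals: tuple[tuple[int, int], ...] = ()  # 0-based half-open
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.founder_count < 2:
            raise ConfigError("founder_count must be >= 2")
        if self.n_sites > self.region_length:
            raise ConfigError("n_sites may not exceed region_length")
        for name in ("mutation_rate", "indel_fraction", "lof_rate", "length_geom_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.deletion_odds <= 0:
            raise ConfigError("deletion_odds must be positive")
        if self.switch_rate_sim < 0:
            raise ConfigError("switch_rate_sim must be >= 0")
        if not (0.0 < self.f_min < 0.5):
            raise ConfigError("f_min must lie in (0, 0.5)")
        if not (0.0 < self.founder_weight_decay <= 1.0):
            raise ConfigError("founder_weight_decay must lie in (0, 1]")
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")

    @property
    def founder_weights(self) -> np.ndarray:
        """Copy probability of each founder, decaying geometrically by rank.

        With decay 1 every founder is copied uniformly; with decay < 1 the
        low-rank founders dominate and high-rank founders carry rare
        haplotype backgrounds, which is what populates the low-frequency
        (1-5% MAF) part of the sample spectrum without collapsing LD (the
        effective founder diversity 1/sum(w^2) stays moderate)."""
        w = self.founder_weight_decay ** np.arange(self.founder_count, dtype=float)
        return w / w.sum()


def _sample_founder_freqs(
    rng: np.random.Generator, n: int, alpha: float, f_min: float
) -> np.ndarray:
    """Inverse-CDF draws from density ~ f^-alpha truncated to [f_min, 0.5]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return f_min * (0.5 / f_min) ** u
    a = 1.0 - alpha
    lo, hi = f_min**a, 0.5**a
    return (lo + u * (hi - lo)) ** (1.0 / a)


def simulate_founders(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw founder haplotypes.

    Returns (founders K x M binary, positions (1-based, sorted), realized
    population alt frequencies, i.e. the copy-weighted founder column
    means).  Sites that come out monomorphic across founders are resampled
    so each founder column segregates.
    """
    rng = rng or np.random.default_rng(config.seed)
    positions = np.sort(
        rng.choice(config.region_length, size=config.n_sites, replace=False) + 1
    )
    K, M = config.founder_count, config.n_sites
    freqs = _sample_founder_freqs(rng, M, config.sfs_exponent, config.f_min)
    founders = (rng.random((K, M)) < freqs).astype(np.int8)
    while True:
        counts = founders.sum(axis=0)
        mono = (counts == 0) | (counts == K)
        if not mono.any():
            break
        idx = np.flatnonzero(mono)
        freqs[idx] = _sample_founder_freqs(
            rng, idx.size, config.sfs_exponent, config.f_min
        )
        founders[:, idx] = rng.random((K, idx.size)) < freqs[idx]
    pop_freqs = config.founder_weights @ founders
    return founders, positions, pop_freqs


def mosaic_sample(
    founders: np.ndarray,
    positions: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    freqs: np.ndarray | None = None,
) -> tuple[HaplotypePanel, np.ndarray]:
    """Build 2N sample haplotypes as recombinant founder mosaics.

    Each haplotype starts on a founder drawn from the copy weights;
    between consecutive sites at distance d the copied founder is redrawn
    from the weights with probability 1 - exp(-switch_rate_sim * d).  Fresh
    mutations then flip each (haplotype, site) entry independently with
    probability ``mutation_rate``.  Sites monomorphic in the sample are
    dropped and tallied in ``panel.meta["monomorphic_dropped"]``.

    Returns the panel (all sites still SNPs) and the founder frequencies
    of the retained sites (for truth records).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    K, M = founders.shape
    n_haps = 2 * config.n_samples
    weights = config.founder_weights

    founder_ids = np.empty((n_haps, M), dtype=np.int32)
    founder_ids[:, 0] = rng.choice(K, size=n_haps, p=weights)
    gaps = np.diff(positions).astype(float)
    switch_p = 1.0 - np.exp(-config.switch_rate_sim * gaps)
    for s in range(1, M):
        switch = rng.random(n_haps) < switch_p[s - 1]
        founder_ids[:, s] = np.where(
            switch, rng.choice(K, size=n_haps, p=weights), founder_ids[:, s - 1]
        )
    haps = founders[founder_ids, np.arange(M)[None, :]]

    if config.mutation_rate > 0:
        flips = rng.random((n_haps, M)) < config.mutation_rate
        haps = haps ^ flips

    counts = haps.sum(axis=0)
    keep = (counts > 0) & (counts < n_haps)
    dropped = int(M - keep.sum())
    haps = haps[:, keep]
    positions = positions[keep]
    kept_freqs = (freqs[keep] if freqs is not None else np.full(keep.sum(), np.nan))

    ref_idx = rng.integers(0, 4, size=positions.size)
    alt_idx = (ref_idx + rng.integers(1, 4, size=positions.size)) % 4
    sites = [
        VariantSite(
            chrom=config.chrom,
            pos=int(p),
            site_id=f"var{p}",
            ref_allele=str(_BASES[ref_idx[k]]),
            alt_allele=str(_BASES[alt_idx[k]]),
        )
        for k, p in enumerate(positions)
    ]
    panel = HaplotypePanel(
        sites=sites,
        hap_matrix=haps.astype(np.int8),
        sample_ids=[f"sample{i:03d}" for i in range(config.n_samples)],
    )
    panel.meta["monomorphic_dropped"] = dropped
    return panel, kept_freqs


def draw_indel_alleles(
    rng: np.random.Generator, config: SimulationConfig, ref_base: str
) -> tuple[str, str, str, int]:
    """Draw (vclass, ref, alt, length) for one overlay indel."""
    is_deletion = rng.random() < config.deletion_odds / (1.0 + config.deletion_odds)
    length = min(int(rng.geometric(config.length_geom_p)), 49)
    extra = "".join(rng.choice(_BASES, size=length))
    if is_deletion:
        return "deletion", ref_base + extra, ref_base, length
    return "insertion", ref_base, ref_base + extra, length


def _in_exon(pos: int, intervals: Sequence[tuple[int, int]]) -> bool:
    # intervals 0-based half-open; pos 1-based
    return any(start < pos <= end for start, end in intervals)


def overlay_indels(
    panel: HaplotypePanel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    pop_freqs: np.ndarray | None = None,
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Relabel a random fraction of sites as indels; return panel + truth.

    Allele columns are untouched — only the site metadata changes — so the
    overlay never perturbs frequencies or LD.  Deletion vs insertion and
    length follow the configured odds and geometric law; exonic indels are
    flagged LOF with probability ``lof_rate``.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    M = panel.n_sites
    n_indels = int(round(config.indel_fraction * M))
    indel_idx = set(
        rng.choice(M, size=n_indels, replace=False).tolist() if n_indels else []
    )

    new_sites: list[VariantSite] = []
    truth_rows = []
    f = panel.hap_matrix.mean(axis=0)
    for j, s in enumerate(panel.sites):
        if j in indel_idx:
            vclass, ref, alt, length = draw_indel_alleles(rng, config, s.ref_allele)
            lof = _in_exon(s.pos, config.exon_intervals) and (
                rng.random() < config.lof_rate
            )
            s = VariantSite(
                chrom=s.chrom,
                pos=s.pos,
                site_id=s.site_id,
                ref_allele=ref,
                alt_allele=alt,
                lof=lof,
            )
        else:
            vclass, length, lof = "SNP", 0, False
        new_sites.append(s)
        truth_rows.append(
            {
                "site_id": s.site_id,
                "chrom": s.chrom,
                "pos": s.pos,
                "true_class": vclass,
                "true_length": length,
                "pop_freq": (
                    float(pop_freqs[j]) if pop_freqs is not None else float(f[j])
                ),
                "sample_alt_freq": float(f[j]),
                "lof": lof,
                "best_tag_id": "",
            }
        )
    out = HaplotypePanel(
        sites=new_sites,
        hap_matrix=panel.hap_matrix.copy(),
        sample_ids=list(panel.sample_ids),
        meta=dict(panel.meta),
    )
    return out, pd.DataFrame(truth_rows)


def simulate_panel(
    config: SimulationConfig,
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Founders -> mosaic -> indel overlay, fully determined by the config."""
    rng = np.random.default_rng(config.seed)
    founders, positions, freqs = simulate_founders(config, rng)
    panel, kept_freqs = mosaic_sample(founders, positions, config, rng, freqs)
    return overlay_indels(panel, config, rng, kept_freqs)


def fill_best_tags(truth: pd.DataFrame, panel: HaplotypePanel, pairs) -> pd.DataFrame:
    """Post-hoc: record each focal's highest-r^2 partner SNP in the truth."""
    truth = truth.copy()
    if len(pairs):
        best = pairs.loc[pairs.groupby("focal_index")["r2"].idxmax()]
        id_by_pos = {s.pos: s.site_id for s in panel.sites}
        for _, row in best.iterrows():
            focal = panel.sites[int(row["focal_index"])]
            truth.loc[truth["site_id"] == focal.site_id, "best_tag_id"] = panel.sites[
                int(row["partner_index"])
            ].site_id
    return truth


def with_perfect_tag_snps(panel: HaplotypePanel) -> HaplotypePanel:
    """Plant an r^2 = 1 tag SNP immediately next to every indel.

    Constructs the perfect-LD regime (every indel carried on a haplotype
    background marked by one adjacent SNP) by duplicating each indel's
    allele column as a SNP at pos + 1.  Positions already occupied shift
    until free.  Used by tests and calibration runs to exercise the
    perfect-tag limit of the imputer.
    """
    taken = {s.key for s in panel.sites}
    entries = [(s, panel.hap_matrix[:, j]) for j, s in enumerate(panel.sites)]
    for j in panel.indel_indices:
        s = panel.sites[j]
        pos = s.pos + 1
        while (s.chrom, pos) in taken:
            pos += 1
        taken.add((s.chrom, pos))
        tag = VariantSite(
            chrom=s.chrom,
            pos=pos,
            site_id=f"{s.site_id}_tag",
            ref_allele="A",
            alt_allele="G",
        )
        entries.append((tag, panel.hap_matrix[:, j].copy()))
    entries.sort(key=lambda e: (e[0].chrom, e[0].pos))
    return HaplotypePanel(
        sites=[e[0] for e in entries],
        hap_matrix=np.stack([e[1] for e in entries], axis=1),
        sample_ids=list(panel.sample_ids),
    )


def write_outputs(
    panel: HaplotypePanel,
    truth: pd.DataFrame,
    out_dir: str | Path,
    sitelist_fraction: float | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Write VCFs (merged, indel-only, SNP-only), truth TSV, optional SiteList.

    The indel-only + SNP-only pair exists to exercise the merge rule; the
    optional site list subsamples SNP positions at ``sitelist_fraction``
    to emulate a sparse array panel.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["merged_vcf"] = out_dir / "panel.vcf"
    write_vcf(panel, paths["merged_vcf"])

    indel_idx = panel.indel_indices
    snp_idx = panel.snp_indices
    if indel_idx.size:
        paths["indel_vcf"] = out_dir / "indels.vcf"
        write_vcf(panel.subset_sites(indel_idx), paths["indel_vcf"])
    if snp_idx.size:
        paths["snp_vcf"] = out_dir / "snps.vcf"
        write_vcf(panel.subset_sites(snp_idx), paths["snp_vcf"])

    paths["truth_tsv"] = out_dir / "truth.tsv"
    truth.to_csv(paths["truth_tsv"], sep="\t", index=False)

    if sitelist_fraction is not None:
        rng = np.random.default_rng(seed)
        keep = rng.random(snp_idx.size) < sitelist_fraction
        sites = SiteList(
            [panel.sites[j].key for j in snp_idx[keep]]
        )
        paths["sitelist_tsv"] = out_dir / "sites.tsv"
        sites.write_tsv(paths["sitelist_tsv"])
    return paths


def default_config(seed: int, **overrides) -> SimulationConfig:
    """Convenience constructor mirroring dataclasses.replace semantics."""
    return replace(SimulationConfig(seed=seed), **overrides)
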