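"""Per-site frequency statistics, MAF binning, size classes and tests.

Minor allele frequencies are always recomputed from the panel's own
haplotypes, never taken from VCF INFO fields, so per-population subsets
stay internally consistent.

The MAF convention follows the low-coverage human resequencing literature:
rare variants (MAF < 1%, singletons in practice at these sample sizes) are
excluded from analysis, 1% <= MAF < 5% is "low frequency", MAF >= 5% is
"common".  MAF exactly 5% is binned common; the boundary is configurable
through :class:`MAFBinScheme`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ClassError,
    DegenerateTestWarning,
    DomainError,
    ParseError,
)
from .vcf_io import HaplotypePanel, VariantSite

SMALL_INDEL_CUTOFF = 6  # bp; <= cutoff is "small"

BIN_EXCLUDED = "excluded"
BIN_LOW = "low"
BIN_COMMON = "common"


@dataclass(frozen=True)
class MAFBinScheme:
    """Frequency bin boundaries.

    ``excluded_below`` removes rare variants (default 1%); ``low_upper``
    separates low-frequency from common (default 5%, closed on the common
    side so MAF = 5% is common).
    """

    excluded_below: float = 0.01
    low_upper: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.excluded_below < self.low_upper <= 0.5):
            raise DomainError(
                "require 0 < excluded_below < low_upper <= 0.5, got "
                f"{self.excluded_below}, {self.low_upper}"
            )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Frequencies and bins
# ---------------------------------------------------------------------------


def alt_allele_freqs(panel: HaplotypePanel) -> np.ndarray:
    """Alt-allele frequency of every site, from the haplotype matrix."""
    return panel.hap_matrix.mean(axis=0)


def minor_allele_counts(panel: HaplotypePanel) -> np.ndarray:
    alt = panel.hap_matrix.sum(axis=0, dtype=np.int64)
    return np.minimum(alt, panel.n_haplotypes - alt)


def minor_allele_freq(panel: HaplotypePanel, site_index: int) -> float:
    """Folded allele frequency min(f, 1-f) of one site."""
    f = panel.alt_freq(site_index)
    return min(f, 1.0 - f)


def minor_allele_freqs(panel: HaplotypePanel) -> np.ndarray:
    f = alt_allele_freqs(panel)
    return np.minimum(f, 1.0 - f)


def maf_bin(f: float, minor_count: int, scheme: MAFBinScheme | None = None) -> str:
    """Assign a folded frequency to the excluded / low / common bins."""
    scheme = scheme or MAFBinScheme()
    if not (0.0 <= f <= 0.5 + 1e-12):
        raise DomainError(f"MAF {f} outside [0, 0.5]")
    if f < scheme.excluded_below:
        return BIN_EXCLUDED
    if f < scheme.low_upper:
        return BIN_LOW
    return BIN_COMMON


def is_singleton(minor_count: int) -> bool:
    return minor_count == 1


def maf_bins(panel: HaplotypePanel, scheme: MAFBinScheme | None = None) -> np.ndarray:
    """Vectorised bin labels for every site of a panel."""
    scheme = scheme or MAFBinScheme()
    f = minor_allele_freqs(panel)
    out = np.full(panel.n_sites, BIN_COMMON, dtype=object)
    out[f < scheme.low_upper] = BIN_LOW
    out[f < scheme.excluded_below] = BIN_EXCLUDED
    return out


def classify_indel_size(
    site: VariantSite, small_cutoff: int = SMALL_INDEL_CUTOFF
) -> str:
    """'small' (length <= cutoff, default 6 bp) or 'large' for an indel."""
    if not site.is_indel:
        raise ClassError(f"{site.chrom}:{site.pos} is a SNP, not an indel")
    return "small" if site.indel_length <= small_cutoff else "large"


def site_table(
    panel: HaplotypePanel, scheme: MAFBinScheme | None = None
) -> pd.DataFrame:
    """Per-site summary: class, length, MAF, bin, singleton, LOF, region."""
    scheme = scheme or MAFBinScheme()
    f = minor_allele_freqs(panel)
    counts = minor_allele_counts(panel)
    bins = maf_bins(panel, scheme)
    rows = []
    for j, s in enumerate(panel.sites):
        rows.append(
            {
                "site_index": j,
                "site_id": s.site_id,
                "chrom": s.chrom,
                "pos": s.pos,
                "vclass": s.vclass.value,
                "indel_length": s.indel_length,
                "size_class": (
                    classify_indel_size(s) if s.is_indel else ""
                ),
                "maf": float(f[j]),
                "minor_count": int(counts[j]),
                "maf_bin": bins[j],
                "singleton": bool(counts[j] == 1),
                "lof": s.lof,
                "region": s.region_label or "intergenic",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------


def _parse_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    intervals = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: BED line needs >= 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad BED coordinates") from exc
        if end < start:
            raise ParseError(f"{path}:{lineno}: end < start")
        label = parts[3] if len(parts) > 3 else "region"
        intervals.append((parts[0], start, end, label))
    return intervals


def annotate_regions(
    panel: HaplotypePanel,
    bed: str | Path | Iterable[tuple[str, int, int, str]],
    label_map: Mapping[str, str] | None = None,
) -> HaplotypePanel:
    """Label each site with the first covering BED interval, else intergenic.

    BED intervals are 0-based half-open; a site at 1-based position p is
    covered by (start, end) iff start < p <= end.  On overlapping intervals
    the first one in file order wins.  ``label_map`` optionally maps raw
    BED names onto region classes.
    """
    if isinstance(bed, (str, Path)):
        intervals = _parse_bed(bed)
    else:
        intervals = list(bed)

    labels: list[str | None] = [None] * panel.n_sites
    for chrom, start, end, raw in intervals:
        label = label_map.get(raw, raw) if label_map else raw
        for j, s in enumerate(panel.sites):
            if labels[j] is None and s.chrom == chrom and start < s.pos <= end:
                labels[j] = label

    new_sites = [
        VariantSite(
            chrom=s.chrom,
            pos=s.pos,
            site_id=s.site_id,
            ref_allele=s.ref_allele,
            alt_allele=s.alt_allele,
            lof=s.lof,
            region_label=labels[j] if labels[j] is not None else "intergenic",
        )
        for j, s in enumerate(panel.sites)
    ]
    return HaplotypePanel(
        sites=new_sites,
        hap_matrix=panel.hap_matrix.copy(),
        sample_ids=list(panel.sample_ids),
        meta=dict(panel.meta),
    )


# ---------------------------------------------------------------------------
# Significance tests
# ---------------------------------------------------------------------------


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Two-sided pooled two-proportion z-test.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion;
    no continuity correction.  A pooled proportion of exactly 0 or 1 makes
    the statistic undefined; by convention the result is p = 1, flagged
    degenerate, with a :class:`DegenerateTestWarning`.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 <= 0 or n2 <= 0:
        raise DomainError("counts must satisfy 0 <= x <= n with n > 0")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn(
            "two-proportion test degenerate: pooled proportion is 0 or 1",
            DegenerateTestWarning,
        )
        return TestResult(0.0, 1.0, "two_proportion", degenerate=True)
    from statsmodels.stats.proportion import proportions_ztest

    z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return TestResult(float(z), float(p), "two_proportion")


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test (normal approximation).

    The statistic reported is U for the first sample, computed from rank
    sums with midranks on ties; the p-value uses the tie-corrected normal
    approximation with continuity correction (appropriate for the large
    samples this pipeline compares).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("mann_whitney requires two non-empty samples")
    from scipy.stats import mannwhitneyu

    if np.all(a == a[0]) and np.all(b == a[0]):
        # all observations tied: no evidence either way, and the normal
        # approximation would divide by a zero variance
        warnings.warn("mann_whitney degenerate: all values tied", DegenerateTestWarning)
        return TestResult(a.size * b.size / 2.0, 1.0, "mann_whitney", degenerate=True)
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), "mann_whitney")
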