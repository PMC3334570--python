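"""Phased variant panels: VCF reading/writing, merging and site filtering.

The central container is :class:`HaplotypePanel`, a strictly bi-allelic,
fully phased haplotype matrix (rows = haplotypes, columns = sites) plus
per-site metadata (:class:`VariantSite`).  Panels are produced from VCF v4.x
files (via cyvcf2) or by the bundled simulator, and all downstream LD and
imputation machinery consumes them.

Data-preparation rules enforced here:

* only bi-allelic records enter a panel; multi-allelic records are dropped
  at read time and counted in ``panel.meta["dropped_non_biallelic"]``;
* genotypes must be complete and phased ('0|1'); missing or unphased calls
  are a hard error, never silently repaired;
* when an indel panel and a SNP panel are merged, a position collision is
  resolved by keeping the indel and discarding the SNP;
* indels are short (< 50 bp) and alleles are plain ACGT strings.

Coordinates are 1-based VCF positions throughout; distances between sites
are ``|pos_a - pos_b|`` in bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DuplicateSiteError,
    EmptyPanelError,
    MissingOrUnphasedGenotypeError,
    PanelContentError,
    ParseError,
    SampleMismatchError,
    UnsupportedAlleleError,
)

_ACGT = frozenset("ACGT")

MAX_INDEL_LENGTH = 50  # exclusive bound: short indels only


class VariantClass(str, Enum):
    SNP = "SNP"
    INSERTION = "insertion"
    DELETION = "deletion"


@dataclass(frozen=True)
class VariantSite:
    """One bi-allelic site.

    The variant class and indel length are derived from the allele strings,
    so they can never disagree with them: a deletion has ``len(ref) >
    len(alt)``, an insertion the converse, and a SNP has two single-base
    alleles.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    site_id: str
    ref_allele: str
    alt_allele: str
    lof: bool = False
    region_label: str | None = None

    def __post_init__(self) -> None:
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or not _ACGT.issuperset(allele):
                raise UnsupportedAlleleError(
                    f"{self.chrom}:{self.pos} allele {allele!r} is not a "
                    "plain ACGT string"
                )
        lr, la = len(self.ref_allele), len(self.alt_allele)
        if lr == la and lr != 1:
            raise UnsupportedAlleleError(
                f"{self.chrom}:{self.pos} {self.ref_allele}>{self.alt_allele}: "
                "multi-base substitutions are not supported"
            )
        if abs(lr - la) >= MAX_INDEL_LENGTH:
            raise UnsupportedAlleleError(
                f"{self.chrom}:{self.pos}: indel length {abs(lr - la)} "
                f">= {MAX_INDEL_LENGTH} bp"
            )

    @property
    def vclass(self) -> VariantClass:
        lr, la = len(self.ref_allele), len(self.alt_allele)
        if lr > la:
            return VariantClass.DELETION
        if lr < la:
            return VariantClass.INSERTION
        return VariantClass.SNP

    @property
    def indel_length(self) -> int:
        """|len(ref) - len(alt)| in bp; 0 for a SNP."""
        return abs(len(self.ref_allele) - len(self.alt_allele))

    @property
    def is_indel(self) -> bool:
        return self.vclass is not VariantClass.SNP

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class HaplotypePanel:
    """Ordered sites x phased binary haplotype matrix.

    ``hap_matrix`` has shape (2N, M): haplotypes ``2i`` and ``2i + 1``
    belong to sample ``i``.  Entries are strictly 0 (ref) / 1 (alt); no
    missing data is representable.  Sites are sorted by position within each
    chromosome and chromosome blocks are contiguous.

    ``meta`` carries bookkeeping tallies (dropped records, skip counts) and
    never participates in equality.
    """

    sites: list[VariantSite]
    hap_matrix: np.ndarray
    sample_ids: list[str]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.hap_matrix, dtype=np.int8)
        if m.ndim != 2:
            raise ValueError("hap_matrix must be 2-D (haplotypes x sites)")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("hap_matrix entries must be strictly 0/1")
        if m.shape[0] % 2 != 0:
            raise ValueError("number of haplotype rows must be even")
        if m.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("hap_matrix rows != 2 * number of samples")
        if m.shape[1] != len(self.sites):
            raise ValueError("hap_matrix columns != number of sites")
        self.hap_matrix = m
        self._check_sorted()

    def _check_sorted(self) -> None:
        seen_chroms: list[str] = []
        prev_chrom, prev_pos = None, -1
        for s in self.sites:
            if s.chrom != prev_chrom:
                if s.chrom in seen_chroms:
                    raise ValueError(
                        f"chromosome block {s.chrom} is not contiguous"
                    )
                seen_chroms.append(s.chrom)
                prev_chrom, prev_pos = s.chrom, s.pos
            else:
                if s.pos <= prev_pos:
                    raise ValueError(
                        f"sites not strictly increasing at {s.chrom}:{s.pos}"
                    )
                prev_pos = s.pos

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.hap_matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites])

    @property
    def is_indel(self) -> np.ndarray:
        return np.array([s.is_indel for s in self.sites], dtype=bool)

    @property
    def indel_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_indel)

    @property
    def snp_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_indel)

    def column(self, j: int) -> np.ndarray:
        return self.hap_matrix[:, j]

    def alt_freq(self, j: int) -> float:
        return float(self.hap_matrix[:, j].mean())

    def genotype(self, sample_index: int, site_index: int) -> int:
        """Alt-allele dosage (0, 1 or 2) of one sample at one site."""
        rows = self.hap_matrix[2 * sample_index : 2 * sample_index + 2, site_index]
        return int(rows.sum())

    def sample_haplotypes(self, sample_index: int) -> np.ndarray:
        return self.hap_matrix[2 * sample_index : 2 * sample_index + 2, :]

    def subset_sites(self, indices: Sequence[int]) -> "HaplotypePanel":
        idx = np.asarray(indices, dtype=np.int64)
        return HaplotypePanel(
            sites=[self.sites[i] for i in idx],
            hap_matrix=self.hap_matrix[:, idx],
            sample_ids=list(self.sample_ids),
        )

    def site_keys(self) -> list[tuple[str, int]]:
        return [s.key for s in self.sites]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.hap_matrix, other.hap_matrix)
        )


class SiteList:
    """Set of (chrom, pos) keys, e.g. an array-panel site manifest."""

    def __init__(self, keys: Iterable[tuple[str, int]]):
        keys = [(str(c), int(p)) for c, p in keys]
        self.keys = frozenset(keys)
        if len(self.keys) != len(keys):
            # silently collapsing duplicates would hide a malformed input
            warnings.warn("duplicate entries in site list collapsed")

    def __contains__(self, key: tuple[str, int]) -> bool:
        return (str(key[0]), int(key[1])) in self.keys

    def __len__(self) -> int:
        return len(self.keys)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SiteList":
        keys = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>pos'")
            try:
                keys.append((parts[0], int(parts[1])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad position {parts[1]!r}") from exc
        return cls(keys)

    def write_tsv(self, path: str | Path) -> None:
        rows = sorted(self.keys)
        Path(path).write_text("".join(f"{c}\t{p}\n" for c, p in rows))


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, expect: str = "mixed") -> HaplotypePanel:
    """Read a phased VCF v4.x into a :class:`HaplotypePanel`.

    Parameters
    ----------
    path
        Plain-text or bgzipped VCF with phased GT fields for every sample.
    expect
        One of ``"snps"``, ``"indels"``, ``"mixed"``.  With ``"snps"`` or
        ``"indels"`` the panel content is validated against the declared
        class and a :class:`PanelContentError` is raised on disagreement.

    Notes
    -----
    Multi-allelic records (and records with no ALT) are dropped and counted
    in ``panel.meta["dropped_non_biallelic"]``.  Missing or unphased
    genotypes raise; symbolic or non-ACGT alleles raise.
    """
    from cyvcf2 import VCF  # deferred: htslib import is slow

    if expect not in ("snps", "indels", "mixed"):
        raise ValueError(f"expect must be snps/indels/mixed, got {expect!r}")

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            dropped += 1
            continue
        site = VariantSite(
            chrom=rec.CHROM,
            pos=rec.POS,
            site_id=rec.ID or f"{rec.CHROM}:{rec.POS}",
            ref_allele=rec.REF,
            alt_allele=rec.ALT[0],
        )
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            if len(gt) != 3:
                raise MissingOrUnphasedGenotypeError(
                    f"{rec.CHROM}:{rec.POS} sample {samples[i]}: "
                    "non-diploid genotype"
                )
            a, b, phased = gt
            if a < 0 or b < 0:
                raise MissingOrUnphasedGenotypeError(
                    f"{rec.CHROM}:{rec.POS} sample {samples[i]}: missing genotype"
                )
            if not phased:
                raise MissingOrUnphasedGenotypeError(
                    f"{rec.CHROM}:{rec.POS} sample {samples[i]}: unphased genotype"
                )
            col[2 * i] = a
            col[2 * i + 1] = b
        sites.append(site)
        columns.append(col)
    vcf.close()

    if not sites:
        raise EmptyPanelError(f"no usable bi-allelic records in {path}")
    matrix = np.stack(columns, axis=1)
    panel = HaplotypePanel(sites=sites, hap_matrix=matrix, sample_ids=samples)
    panel.meta["dropped_non_biallelic"] = dropped

    if expect == "snps" and panel.is_indel.any():
        raise PanelContentError(f"{path}: indel records in a SNP-only panel")
    if expect == "indels" and not panel.is_indel.all():
        raise PanelContentError(f"{path}: SNP records in an indel-only panel")
    return panel


def write_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as a plain-text VCF v4.2 with phased GT fields.

    Output ordering is deterministic (panel site order, which is sorted)."""
    path = Path(path)
    chrom_max: dict[str, int] = {}
    for s in panel.sites:
        chrom_max[s.chrom] = max(chrom_max.get(s.chrom, 0), s.pos)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=indelld\n")
        for chrom, mx in chrom_max.items():
            fh.write(f"##contig=<ID={chrom},length={mx + MAX_INDEL_LENGTH}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for j, s in enumerate(panel.sites):
            col = panel.hap_matrix[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(panel.n_samples)
            )
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.site_id}\t{s.ref_allele}\t"
                f"{s.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Panel algebra
# ---------------------------------------------------------------------------


def _chrom_order(sites: Iterable[VariantSite]) -> dict[str, int]:
    order: dict[str, int] = {}
    for s in sites:
        if s.chrom not in order:
            order[s.chrom] = len(order)
    return order


def merge_panels(
    indel_panel: HaplotypePanel, snp_panel: HaplotypePanel
) -> HaplotypePanel:
    """Merge an indel panel with a SNP panel over identical samples.

    On a position collision the indel is retained and the SNP discarded;
    the number of discarded SNPs is reported in
    ``merged.meta["snps_discarded_at_indel_positions"]``.  Two sites of the
    same class at one position raise :class:`DuplicateSiteError`.
    """
    if indel_panel.sample_ids != snp_panel.sample_ids:
        raise SampleMismatchError(
            "panels carry different samples (or a different order)"
        )

    for panel, name in ((indel_panel, "indel"), (snp_panel, "snp")):
        keys = panel.site_keys()
        if len(keys) != len(set(keys)):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise DuplicateSiteError(f"{name} panel has two sites at {dup[0]}:{dup[1]}")

    indel_class = {s.key: s.is_indel for s in indel_panel.sites}
    keep_snp = []
    discarded = 0
    for j, s in enumerate(snp_panel.sites):
        if s.key not in indel_class:
            keep_snp.append(j)
        elif indel_class[s.key] and not s.is_indel:
            discarded += 1  # the collision rule: indel retained, SNP dropped
        else:
            raise DuplicateSiteError(
                f"two sites of the same class collide at {s.chrom}:{s.pos}"
            )

    entries = [(s, indel_panel.hap_matrix[:, j]) for j, s in enumerate(indel_panel.sites)]
    entries += [(snp_panel.sites[j], snp_panel.hap_matrix[:, j]) for j in keep_snp]

    order = _chrom_order(list(indel_panel.sites) + list(snp_panel.sites))
    entries.sort(key=lambda e: (order[e[0].chrom], e[0].pos))

    merged = HaplotypePanel(
        sites=[e[0] for e in entries],
        hap_matrix=np.stack([e[1] for e in entries], axis=1),
        sample_ids=list(indel_panel.sample_ids),
    )
    merged.meta["snps_discarded_at_indel_positions"] = discarded
    return merged


def restrict_to_sites(
    panel: HaplotypePanel, sites: SiteList, keep_indels: bool = True
) -> HaplotypePanel:
    """Keep only SNPs present in ``sites`` (emulating an array panel).

    With ``keep_indels`` the indel sites survive regardless, so focal
    indels remain available when the SNP context is thinned to OMNI- or
    HapMap-like density."""
    keep = [
        j
        for j, s in enumerate(panel.sites)
        if (s.is_indel and keep_indels) or (not s.is_indel and s.key in sites)
    ]
    if not keep:
        raise EmptyPanelError("site-list restriction removed every site")
    out = panel.subset_sites(keep)
    out.meta["sites_removed"] = panel.n_sites - len(keep)
    return out


def flag_lof(panel: HaplotypePanel, lof_sites: SiteList) -> HaplotypePanel:
    """Return a panel whose indels at the listed positions carry lof=True.

    SNPs are never flagged: a list entry matching a SNP-only position
    produces a warning and no flag."""
    new_sites: list[VariantSite] = []
    matched: set[tuple[str, int]] = set()
    for s in panel.sites:
        if s.is_indel and s.key in lof_sites:
            matched.add(s.key)
            s = VariantSite(
                chrom=s.chrom,
                pos=s.pos,
                site_id=s.site_id,
                ref_allele=s.ref_allele,
                alt_allele=s.alt_allele,
                lof=True,
                region_label=s.region_label,
            )
        else:
            s = VariantSite(
                chrom=s.chrom,
                pos=s.pos,
                site_id=s.site_id,
                ref_allele=s.ref_allele,
                alt_allele=s.alt_allele,
                lof=False,
                region_label=s.region_label,
            )
        new_sites.append(s)
    snp_keys = {s.key for s in panel.sites if not s.is_indel}
    for key in lof_sites.keys:
        if key in snp_keys and key not in matched:
            warnings.warn(
                f"LOF list entry {key[0]}:{key[1]} matches a SNP position; not flagged"
            )
    return HaplotypePanel(
        sites=new_sites,
        hap_matrix=panel.hap_matrix.copy(),
        sample_ids=list(panel.sample_ids),
        meta=dict(panel.meta),
    )
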