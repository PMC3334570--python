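"""Exception hierarchy shared across the package.

Every error raised by indelld derives from :class:`IndelLDError` so callers
can catch package failures with a single except clause.
"""


class IndelLDError(Exception):
    """Base class for all indelld errors."""


class ParseError(IndelLDError):
    """A text input (VCF, BED, TSV) could not be parsed."""


class MissingOrUnphasedGenotypeError(IndelLDError):
    """A genotype was missing ('./.') or unphased ('0/1').

    Panels must be complete and phased; missingness is a hard error because
    silently dropping or imputing it would bias every downstream statistic.
    """


class UnsupportedAlleleError(IndelLDError):
    """Allele outside {A,C,G,T}+ (symbolic ALT, MNP, or indel >= 50 bp)."""


class SampleMismatchError(IndelLDError):
    """Two panels to be merged do not carry identical sample lists."""


class DuplicateSiteError(IndelLDError):
    """Two sites of the same variant class share one (chrom, pos)."""


class EmptyPanelError(IndelLDError):
    """An operation produced or received a panel with zero sites."""


class PanelContentError(IndelLDError):
    """Panel content contradicts the declared expectation (snps/indels)."""


class ClassError(IndelLDError):
    """A site of the wrong variant class was passed (e.g. SNP where an
    indel is required)."""


class DomainError(IndelLDError):
    """Numeric argument outside its documented domain."""


class MonomorphicSiteError(IndelLDError):
    """LD requested for a site with no variation in the panel."""


class NoHighLDPartnerError(IndelLDError):
    """Focal variant has no partner above the r^2 threshold."""


class EmptyReferencePanelError(IndelLDError):
    """Haplotype-copying model invoked with zero reference haplotypes."""


class NoContextError(IndelLDError):
    """No polymorphic context SNP available for imputation."""


class ConfigError(IndelLDError):
    """Invalid simulation or analysis configuration."""


class DegenerateTestWarning(UserWarning):
    """A significance test was degenerate (e.g. pooled proportion 0 or 1)."""
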