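"""Haplotype-copying imputation and its concordance evaluation protocols.

The engine is a transparent Li-Stephens-style hidden Markov model: a target
haplotype is modelled as an imperfect mosaic of the H reference haplotypes.
Between adjacent context SNPs at distance d bp the copied haplotype is kept
with probability exp(-lambda d) and otherwise re-drawn uniformly from all H
references (so the per-step transition is stay = exp(-lambda d) +
(1 - exp(-lambda d))/H and switch-to-a-specific-other = (1 - exp(-lambda d))/H).
Emission is 1 - epsilon on an allele match and epsilon on a mismatch.
Posterior copying weights are read at the context SNP nearest the query
position (left on ties) after a full forward-backward pass.

An indel genotype is imputed by leaving the evaluated individual's two
haplotypes out of the reference panel, masking the indel itself, running
the HMM over the SNP context within a +/- 100 kb window, and combining the
two per-haplotype alt-allele probabilities independently (the targets are
phased):

    p_alt(hap) = sum_h w_h * allele_h(indel)
    P(ref/ref), P(ref/alt), P(alt/alt) = product combination

Concordance compares the argmax hard call to the panel's true genotype,
accumulated into 3x3 tables stratified by the true genotype class
(ref/ref, ref/alt, alt/alt) and by whatever site strata the caller
supplies (MAF bin, size class, LOF status).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    EmptyReferencePanelError,
    NoContextError,
)
from .vcf_io import HaplotypePanel

logger = logging.getLogger(__name__)

GENOTYPE_CLASSES = ("refref", "refalt", "altalt")


@dataclass(frozen=True)
class CopyingModelParams:
    """Tunable parameters of the copying model.

    switch_rate
        Per-bp switch intensity lambda.  The default 4e-5 gives an expected
        copy-segment length of 25 kb, matching the haplotype scale of
        common short variants in outbred human panels.
    emission_error
        Allele mismatch probability epsilon; the default 0.005 mirrors
        treating observed genotypes as correct with likelihood 0.995.
    window
        Context radius in bp around the focal site (default +/- 100 kb).
    """

    switch_rate: float = 4e-5
    emission_error: float = 0.005
    window: int = 100_000

    def __post_init__(self) -> None:
        if not self.switch_rate > 0:
            raise DomainError("switch_rate must be > 0")
        if not (0.0 < self.emission_error < 0.5):
            raise DomainError("emission_error must lie in (0, 0.5)")
        if self.window <= 0:
            raise DomainError("window must be positive")


@dataclass(frozen=True)
class GenotypePosterior:
    p_refref: float
    p_refalt: float
    p_altalt: float
    hard_call: str  # one of GENOTYPE_CLASSES

    def __post_init__(self) -> None:
        total = self.p_refref + self.p_refalt + self.p_altalt
        if abs(total - 1.0) > 1e-9:
            raise DomainError(f"genotype posterior sums to {total}, not 1")

    @property
    def probs(self) -> tuple[float, float, float]:
        return (self.p_refref, self.p_refalt, self.p_altalt)


class ConcordanceTable:
    """3x3 true-class x imputed-class counts with per-class concordance."""

    def __init__(self, counts: np.ndarray | None = None):
        self.counts = (
            np.zeros((3, 3), dtype=np.int64)
            if counts is None
            else np.asarray(counts, dtype=np.int64)
        )
        if self.counts.shape != (3, 3):
            raise DomainError("concordance table must be 3x3")

    def add(self, true_class: int, called_class: int, n: int = 1) -> None:
        self.counts[true_class, called_class] += n

    def merge(self, other: "ConcordanceTable") -> "ConcordanceTable":
        return ConcordanceTable(self.counts + other.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def per_class_concordance(self) -> np.ndarray:
        """diag / row sum; NaN for an empty true class."""
        rows = self.row_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(rows > 0, np.diag(self.counts) / rows, np.nan)

    @property
    def overall_concordance(self) -> float:
        return float(np.trace(self.counts) / self.total) if self.total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts,
            index=[f"true_{c}" for c in GENOTYPE_CLASSES],
            columns=[f"called_{c}" for c in GENOTYPE_CLASSES],
        )
        return df

    def summary(self) -> dict:
        pc = self.per_class_concordance
        return {
            "n": self.total,
            "refref_concordance": float(pc[0]),
            "refalt_concordance": float(pc[1]),
            "altalt_concordance": float(pc[2]),
            "overall_concordance": self.overall_concordance,
        }


# ---------------------------------------------------------------------------
# Copying-model forward-backward
# ---------------------------------------------------------------------------


def copying_posteriors(
    target_hap: np.ndarray,
    ref_haps: np.ndarray,
    positions: Sequence[int],
    query_pos: int,
    params: CopyingModelParams | None = None,
) -> np.ndarray:
    """Posterior copying weights over the reference haplotypes.

    Parameters
    ----------
    target_hap
        Binary alleles of the target haplotype at the S context SNPs.
    ref_haps
        H x S binary reference haplotype matrix (the hidden-state space).
    positions
        Strictly increasing bp positions of the S context SNPs.
    query_pos
        Position at which the weights are wanted; the posterior is read at
        the context SNP nearest to it (left on ties).

    Returns
    -------
    Length-H weight vector summing to 1.
    """
    params = params or CopyingModelParams()
    ref = np.asarray(ref_haps, dtype=np.int8)
    tgt = np.asarray(target_hap, dtype=np.int8)
    if ref.ndim != 2:
        raise DomainError("ref_haps must be H x S")
    H, S = ref.shape
    if H == 0:
        raise EmptyReferencePanelError("no reference haplotypes")
    if S == 0 or tgt.shape[0] != S:
        raise NoContextError("target and reference need >= 1 shared context SNP")
    pos = np.asarray(positions, dtype=np.int64)
    if pos.shape[0] != S or (S > 1 and not np.all(np.diff(pos) > 0)):
        raise DomainError("positions must be strictly increasing, one per SNP")

    eps = params.emission_error
    # emission[s, h]
    match = ref.T == tgt[:, None]
    emit = np.where(match, 1.0 - eps, eps)

    stay = np.exp(-params.switch_rate * np.diff(pos).astype(float)) if S > 1 else None

    # scaled forward
    fwd = np.empty((S, H))
    f = emit[0] / H
    fwd[0] = f / f.sum()
    for s in range(1, S):
        rho = 1.0 - stay[s - 1]
        prev = fwd[s - 1]
        f = emit[s] * (stay[s - 1] * prev + rho / H * prev.sum())
        fwd[s] = f / f.sum()

    # scaled backward
    bwd = np.empty((S, H))
    bwd[S - 1] = 1.0
    for s in range(S - 2, -1, -1):
        rho = 1.0 - stay[s]
        nxt = emit[s + 1] * bwd[s + 1]
        b = stay[s] * nxt + rho / H * nxt.sum()
        bwd[s] = b / b.sum()

    s_star = int(np.argmin(np.abs(pos - query_pos)))
    post = fwd[s_star] * bwd[s_star]
    return post / post.sum()


def _batched_loo_alt_probs(
    panel: HaplotypePanel,
    focal_index: int,
    ctx: np.ndarray,
    params: CopyingModelParams,
) -> np.ndarray:
    """Per-haplotype alt probabilities at the focal site for every target.

    Runs the same forward-backward recursion as :func:`copying_posteriors`
    for all 2N panel haplotypes at once, each against the reference panel
    that excludes its own individual's two rows.  Exactness of the
    batching: a state with zero emission carries zero mass through the
    whole recursion, and with the switch denominator set to H - 2 the
    masked recursion over all 2N states is algebraically identical to the
    restricted recursion over the 2N - 2 live states.

    Returns an array of shape (2N,) with p_alt for each target haplotype.
    """
    eps = params.emission_error
    mat = panel.hap_matrix
    H = mat.shape[0]
    cols = mat[:, ctx]  # (H, S)
    S = cols.shape[1]
    pos = panel.positions[ctx].astype(float)
    query = float(panel.positions[focal_index])
    s_star = int(np.argmin(np.abs(pos - query)))
    stay = np.exp(-params.switch_rate * np.diff(pos)) if S > 1 else np.empty(0)
    h_live = H - 2

    # live-state mask: target t excludes its own sample's two rows
    mask = np.ones((H, H))
    t_idx = np.arange(H)
    mask[t_idx, (t_idx // 2) * 2] = 0.0
    mask[t_idx, (t_idx // 2) * 2 + 1] = 0.0

    def emit(s: int) -> np.ndarray:
        m = cols[:, s]
        return (eps + (1.0 - 2.0 * eps) * (m[:, None] == m[None, :])) * mask

    f = emit(0) / h_live
    f /= f.sum(axis=1, keepdims=True)
    f_star = f if s_star == 0 else None
    for s in range(1, S):
        rho = 1.0 - stay[s - 1]
        f = emit(s) * (stay[s - 1] * f + (rho / h_live) * f.sum(axis=1, keepdims=True))
        f /= f.sum(axis=1, keepdims=True)
        if s == s_star:
            f_star = f

    b = np.ones((H, H)) * mask
    for s in range(S - 2, s_star - 1, -1):
        rho = 1.0 - stay[s]
        nxt = emit(s + 1) * b
        b = stay[s] * nxt + (rho / h_live) * nxt.sum(axis=1, keepdims=True)
        b *= mask
        b /= b.sum(axis=1, keepdims=True)

    post = f_star * b
    post /= post.sum(axis=1, keepdims=True)
    return post @ mat[:, focal_index].astype(float)


# ---------------------------------------------------------------------------
# Genotype imputation
# ---------------------------------------------------------------------------


def _context_snps(
    panel: HaplotypePanel,
    focal_index: int,
    window: int,
    candidates: np.ndarray | None = None,
) -> np.ndarray:
    """Polymorphic SNP indices within +/- window of the focal site."""
    pos = panel.positions
    chroms = panel.chroms
    cand = panel.snp_indices if candidates is None else np.asarray(candidates)
    same = chroms[cand] == chroms[focal_index]
    cand = cand[same]
    cand = cand[np.abs(pos[cand] - pos[focal_index]) <= window]
    cand = cand[cand != focal_index]
    alt = panel.hap_matrix[:, cand].sum(axis=0)
    return cand[(alt > 0) & (alt < panel.n_haplotypes)]


def _hard_call(
    probs: np.ndarray, class_freq_rank: np.ndarray, tol: float = 1e-12
) -> int:
    """argmax with ties broken toward the class with higher panel frequency."""
    best = probs.max()
    tied = np.flatnonzero(probs >= best - tol)
    if tied.size == 1:
        return int(tied[0])
    return int(tied[np.argmax(class_freq_rank[tied])])


def impute_indel_genotype(
    panel: HaplotypePanel,
    sample_index: int,
    focal_index: int,
    params: CopyingModelParams | None = None,
    context_indices: Sequence[int] | None = None,
    mask_focal: bool = True,
) -> GenotypePosterior:
    """Impute one sample's genotype at one focal site, leave-one-out.

    The sample's two haplotypes are removed from the reference panel and
    the focal site is masked in the target (``mask_focal=False`` exists
    only for the degenerate self-copy check).  ``context_indices``
    optionally restricts the context SNP set (r^2 bins, frequency
    matching); by default all polymorphic SNPs within the window are used.
    """
    params = params or CopyingModelParams()
    if context_indices is None:
        ctx = _context_snps(panel, focal_index, params.window)
    else:
        ctx = np.asarray(context_indices, dtype=np.int64)
    if not mask_focal:
        ctx = np.sort(np.append(ctx, focal_index))
    if ctx.size == 0:
        raise NoContextError(
            f"no polymorphic context SNP within +/- {params.window} bp of "
            f"site {focal_index}"
        )

    rows = np.ones(panel.n_haplotypes, dtype=bool)
    rows[2 * sample_index] = rows[2 * sample_index + 1] = False
    ref_ctx = panel.hap_matrix[rows][:, ctx]
    ref_focal = panel.hap_matrix[rows, focal_index].astype(float)
    pos_ctx = panel.positions[ctx]
    query = panel.positions[focal_index]

    p_alt = np.empty(2)
    for k, hap_row in enumerate((2 * sample_index, 2 * sample_index + 1)):
        tgt = panel.hap_matrix[hap_row, ctx]
        w = copying_posteriors(tgt, ref_ctx, pos_ctx, query, params)
        p_alt[k] = float(w @ ref_focal)

    a1, a2 = p_alt
    probs = np.array(
        [
            (1 - a1) * (1 - a2),
            a1 * (1 - a2) + (1 - a1) * a2,
            a1 * a2,
        ]
    )
    probs /= probs.sum()

    # panel genotype-class frequencies at the focal site, for tie-breaks
    dosages = panel.hap_matrix[0::2, focal_index] + panel.hap_matrix[1::2, focal_index]
    class_freq = np.bincount(dosages, minlength=3).astype(float)
    call = _hard_call(probs, class_freq)
    return GenotypePosterior(
        p_refref=float(probs[0]),
        p_refalt=float(probs[1]),
        p_altalt=float(probs[2]),
        hard_call=GENOTYPE_CLASSES[call],
    )


# ---------------------------------------------------------------------------
# Evaluation protocols
# ---------------------------------------------------------------------------


def _loo_single_focal(
    panel: HaplotypePanel,
    focal_index: int,
    params: CopyingModelParams,
    context_indices: np.ndarray | None,
    table: ConcordanceTable,
    records: list | None = None,
) -> int:
    """Accumulate one focal indel's leave-one-out calls; returns skips.

    All 2N target haplotypes are decoded in one batched forward-backward
    pass; the per-sample genotype combination, tie-breaking and truth
    comparison then follow the same rules as :func:`impute_indel_genotype`.
    """
    if context_indices is None:
        ctx = _context_snps(panel, focal_index, params.window)
    else:
        ctx = np.asarray(context_indices, dtype=np.int64)
    if ctx.size == 0:
        raise NoContextError(
            f"no polymorphic context SNP within +/- {params.window} bp of "
            f"site {focal_index}"
        )

    skipped = 0
    col = panel.hap_matrix[:, focal_index]
    total_alt = int(col.sum())
    H = panel.n_haplotypes
    p_alt = _batched_loo_alt_probs(panel, focal_index, ctx, params)

    dosages = col[0::2] + col[1::2]
    class_freq = np.bincount(dosages, minlength=3).astype(float)

    for sample in range(panel.n_samples):
        own = int(col[2 * sample]) + int(col[2 * sample + 1])
        remaining = total_alt - own
        if remaining == 0 or remaining == H - 2:
            skipped += 1  # focal monomorphic after leaving this individual out
            continue
        a1, a2 = p_alt[2 * sample], p_alt[2 * sample + 1]
        probs = np.array(
            [
                (1 - a1) * (1 - a2),
                a1 * (1 - a2) + (1 - a1) * a2,
                a1 * a2,
            ]
        )
        probs /= probs.sum()
        true_class = own  # dosage == class index
        called = _hard_call(probs, class_freq)
        table.add(true_class, called)
        if records is not None:
            records.append(
                {
                    "focal_index": focal_index,
                    "sample": panel.sample_ids[sample],
                    "true_class": GENOTYPE_CLASSES[true_class],
                    "called_class": GENOTYPE_CLASSES[called],
                    "p_refref": float(probs[0]),
                    "p_refalt": float(probs[1]),
                    "p_altalt": float(probs[2]),
                }
            )
    return skipped


def loo_concordance(
    panel: HaplotypePanel,
    focal_set: Sequence[int],
    strata: Mapping[int, str] | None = None,
    params: CopyingModelParams | None = None,
    context_map: Mapping[int, Sequence[int]] | None = None,
    collect_records: bool = False,
) -> dict[str, ConcordanceTable]:
    """Leave-one-individual-out concordance, stratified by ``strata``.

    For every focal indel and every sample, the individual is removed from
    the reference, the genotype imputed and the hard call compared with the
    truth.  Genotypes are pooled within each stratum (genotype-weighted
    denominators).  (focal, sample) pairs whose leave-out reference is
    monomorphic at the focal are skipped and tallied.

    Returns a dict stratum -> :class:`ConcordanceTable`; with no strata a
    single table under the key ``"all"``.  Skip tallies and (optionally)
    per-genotype records land in ``result["all"].meta``-style attributes on
    the function's ``.last_records`` / return via ``collect_records``.
    """
    params = params or CopyingModelParams()
    strata = dict(strata) if strata is not None else {int(i): "all" for i in focal_set}
    tables: dict[str, ConcordanceTable] = {}
    records: list | None = [] if collect_records else None
    skipped = 0
    no_context = 0
    for i in focal_set:
        i = int(i)
        label = strata[i]
        table = tables.setdefault(label, ConcordanceTable())
        ctx = None
        if context_map is not None:
            ctx = np.asarray(context_map[i], dtype=np.int64)
            if ctx.size == 0:
                no_context += 1
                continue
        try:
            skipped += _loo_single_focal(panel, i, params, ctx, table, records)
        except NoContextError:
            no_context += 1
            logger.info("focal %d skipped: no context SNP", i)
    loo_concordance.last_records = (
        pd.DataFrame(records) if records is not None else None
    )
    loo_concordance.last_tallies = {
        "monomorphic_after_leave_out": skipped,
        "no_context": no_context,
    }
    return tables


def r2_binned_concordance(
    panel: HaplotypePanel,
    focal_set: Sequence[int],
    params: CopyingModelParams | None = None,
    bin_width: float = 0.05,
) -> dict[tuple[float, float], ConcordanceTable]:
    """Leave-one-out concordance using only context SNPs from one r^2 bin.

    The pairwise r^2 between each focal indel and its in-window context
    SNPs is computed on the full panel, and the SNPs are grouped into
    1/bin_width bins (0 to 0.05, 0.05 to 0.10, ..., 0.95 to 1; left-open,
    right-closed, the first bin closed at 0).  Each bin's SNP group is then
    used alone to impute the focal indel; focals with no SNP in a bin are
    excluded from that bin's denominators.
    """
    params = params or CopyingModelParams()
    n_bins = int(round(1.0 / bin_width))
    edges = [(k * bin_width, (k + 1) * bin_width) for k in range(n_bins)]
    tables = {e: ConcordanceTable() for e in edges}

    for i in focal_set:
        i = int(i)
        ctx = _context_snps(panel, i, params.window)
        if ctx.size == 0:
            continue
        a = panel.hap_matrix[:, i].astype(float)
        B = panel.hap_matrix[:, ctx].astype(float)
        p, q = a.mean(), B.mean(axis=0)
        d = (a @ B) / len(a) - p * q
        r2 = np.clip(d * d / (p * (1 - p) * q * (1 - q)), 0.0, 1.0)
        # bin k is (k*w, (k+1)*w]; values exactly 0 go to bin 0
        k = np.ceil(r2 / bin_width).astype(int) - 1
        k = np.clip(k, 0, n_bins - 1)
        for b in range(n_bins):
            sub = ctx[k == b]
            if sub.size == 0:
                continue
            _loo_single_focal(panel, i, params, sub, tables[edges[b]])
    return tables


def freq_matched_concordance(
    panel: HaplotypePanel,
    focal_set: Sequence[int],
    scheme=None,
    params: CopyingModelParams | None = None,
) -> dict[str, ConcordanceTable]:
    """Leave-one-out concordance with context SNPs of the focal's MAF bin.

    Identical to :func:`loo_concordance` except each focal indel's context
    is restricted to SNPs in the same MAF bin as the indel itself.  Focals
    with no frequency-matched context SNP are skipped (tallied)."""
    from .variant_stats import maf_bins

    params = params or CopyingModelParams()
    bins = maf_bins(panel, scheme)
    context_map: dict[int, np.ndarray] = {}
    for i in focal_set:
        i = int(i)
        ctx = _context_snps(panel, i, params.window)
        context_map[i] = ctx[bins[ctx] == bins[i]]
    strata = {int(i): str(bins[int(i)]) for i in focal_set}
    return loo_concordance(
        panel, focal_set, strata=strata, params=params, context_map=context_map
    )


def tables_to_frame(
    tables: Mapping, key_name: str = "stratum"
) -> pd.DataFrame:
    """Flatten {key: ConcordanceTable} into a tidy summary DataFrame."""
    rows = []
    for key, table in tables.items():
        row = {key_name: str(key)}
        row.update(table.summary())
        rows.append(row)
    return pd.DataFrame(rows)
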