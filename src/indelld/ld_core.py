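"""Pairwise linkage disequilibrium and its windowed summaries.

r^2 is computed from phased haplotypes via the 2x2 haplotype table:

    D  = p11 - p * q
    r2 = D^2 / (p (1 - p) q (1 - q))

where p and q are the alt-allele frequencies at the two sites and p11 the
frequency of haplotypes carrying alt at both.  Because the panels are
phased there is no EM / composite-LD ambiguity; a genotype-correlation mode
is deliberately not provided.

Scans pair each focal variant with every polymorphic partner SNP within a
+/- 100 kb window (the window radius is configurable).  Summaries follow
the standard conventions for LD-decay reporting: the *average r^2* curve
means all pairwise values within 100-bp distance bins, the *mean max r^2*
curve takes, per focal variant and 1-kb distance bin, the maximum r^2 among
that focal's partners in the bin and averages those maxima across focal
variants.

Tagging thresholds are strict for 0.5 and 0.8 ("greater than") and perfect
LD means r^2 = 1 within 1e-9.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, MonomorphicSiteError, NoHighLDPartnerError
from .vcf_io import HaplotypePanel

DEFAULT_WINDOW = 100_000  # bp, radius
PERFECT_LD_TOL = 1e-9

PAIR_COLUMNS = ["focal_index", "partner_index", "distance", "r2"]


# ---------------------------------------------------------------------------
# Pairwise r^2
# ---------------------------------------------------------------------------


def r2_from_columns(a: np.ndarray, b: np.ndarray) -> float:
    """r^2 between two binary haplotype columns of equal length."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    p = a.mean()
    q = b.mean()
    if p in (0.0, 1.0) or q in (0.0, 1.0):
        raise MonomorphicSiteError("r^2 undefined for a monomorphic site")
    p11 = (a * b).mean()
    d = p11 - p * q
    r2 = d * d / (p * (1.0 - p) * q * (1.0 - q))
    return float(min(max(r2, 0.0), 1.0))


def pairwise_r2(panel: HaplotypePanel, i: int, j: int) -> float:
    """r^2 between sites i and j of a panel (symmetric, label-invariant)."""
    if i == j:
        raise DomainError("pairwise_r2 requires two distinct sites")
    return r2_from_columns(panel.column(i), panel.column(j))


# ---------------------------------------------------------------------------
# Windowed scan
# ---------------------------------------------------------------------------


def ld_scan(
    panel: HaplotypePanel,
    focal_indices: Sequence[int],
    window: int = DEFAULT_WINDOW,
    partner_indices: Sequence[int] | None = None,
) -> pd.DataFrame:
    """All (focal, partner-SNP) r^2 pairs within the window.

    Parameters
    ----------
    focal_indices
        Site indices of the focal variants (indels for indel-SNP LD, SNPs
        for the SNP-SNP control).  Monomorphic focals raise.
    window
        Radius in bp; partners at |pos difference| <= window are paired.
    partner_indices
        Partner site pool; defaults to every SNP of the panel.  Focal
        sites are never paired with themselves; monomorphic partners are
        skipped and tallied in ``result.attrs["monomorphic_partners_skipped"]``.

    Returns
    -------
    DataFrame with columns focal_index, partner_index, distance, r2.
    """
    if window <= 0:
        raise DomainError("window must be positive")
    focal_indices = np.asarray(focal_indices, dtype=np.int64)
    if focal_indices.size and (
        focal_indices.min() < 0 or focal_indices.max() >= panel.n_sites
    ):
        raise IndexError("focal index out of range")
    if partner_indices is None:
        partner_indices = panel.snp_indices
    partner_indices = np.asarray(partner_indices, dtype=np.int64)

    H = panel.n_haplotypes
    mat = panel.hap_matrix
    pos = panel.positions
    chroms = panel.chroms

    alt_counts = mat.sum(axis=0, dtype=np.int64)
    poly = (alt_counts > 0) & (alt_counts < H)

    partner_sets: dict[str, np.ndarray] = {}
    for chrom in np.unique(chroms):
        mask = chroms[partner_indices] == chrom
        partner_sets[chrom] = partner_indices[mask]

    rows_focal, rows_partner, rows_dist, rows_r2 = [], [], [], []
    skipped_mono = 0
    for fi in focal_indices:
        if not poly[fi]:
            raise MonomorphicSiteError(
                f"focal site {panel.sites[fi].site_id} is monomorphic"
            )
        cand = partner_sets.get(str(chroms[fi]), np.empty(0, dtype=np.int64))
        if cand.size == 0:
            continue
        dist = np.abs(pos[cand] - pos[fi])
        in_win = (dist <= window) & (cand != fi)
        cand_w = cand[in_win]
        dist_w = dist[in_win]
        if cand_w.size == 0:
            continue
        mono = ~poly[cand_w]
        skipped_mono += int(mono.sum())
        cand_w, dist_w = cand_w[~mono], dist_w[~mono]
        if cand_w.size == 0:
            continue
        a = mat[:, fi].astype(np.float64)
        B = mat[:, cand_w].astype(np.float64)
        p = a.mean()
        q = B.mean(axis=0)
        p11 = (a @ B) / H
        d = p11 - p * q
        r2 = np.clip(d * d / (p * (1 - p) * q * (1 - q)), 0.0, 1.0)
        rows_focal.append(np.full(cand_w.size, fi, dtype=np.int64))
        rows_partner.append(cand_w)
        rows_dist.append(dist_w)
        rows_r2.append(r2)

    if rows_focal:
        out = pd.DataFrame(
            {
                "focal_index": np.concatenate(rows_focal),
                "partner_index": np.concatenate(rows_partner),
                "distance": np.concatenate(rows_dist),
                "r2": np.concatenate(rows_r2),
            }
        )
    else:
        out = pd.DataFrame(
            {
                "focal_index": np.empty(0, dtype=np.int64),
                "partner_index": np.empty(0, dtype=np.int64),
                "distance": np.empty(0, dtype=np.int64),
                "r2": np.empty(0, dtype=float),
            }
        )
    out.attrs["monomorphic_partners_skipped"] = skipped_mono
    out.attrs["window"] = int(window)
    return out


# ---------------------------------------------------------------------------
# Distance-binned curves
# ---------------------------------------------------------------------------


def _bin_index(distance: np.ndarray, bin_width: int) -> np.ndarray:
    # bin b covers [b*w + 1, (b+1)*w]; distance >= 1 always (distinct sites)
    return (np.asarray(distance, dtype=np.int64) - 1) // bin_width


def average_r2_curve(
    pairs: pd.DataFrame, bin_width: int = 100, window: int | None = None
) -> pd.DataFrame:
    """Mean r^2 of all pairs within contiguous distance bins.

    Bin b covers distances [b*w + 1, (b+1)*w].  Empty bins are emitted with
    n = 0 and value NaN so the curve always spans [0, window].
    """
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    window = window or int(pairs.attrs.get("window", DEFAULT_WINDOW))
    n_bins = int(np.ceil(window / bin_width))
    values = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=np.int64)
    if len(pairs):
        b = _bin_index(pairs["distance"].to_numpy(), bin_width)
        sums = np.bincount(b, weights=pairs["r2"].to_numpy(), minlength=n_bins)[:n_bins]
        cnt = np.bincount(b, minlength=n_bins)[:n_bins]
        nz = cnt > 0
        values[nz] = sums[nz] / cnt[nz]
        counts = cnt
    return pd.DataFrame(
        {
            "bin_start": np.arange(n_bins, dtype=np.int64) * bin_width,
            "bin_width": bin_width,
            "value": values,
            "n": counts,
        }
    )


def mean_max_r2_curve(
    pairs: pd.DataFrame, bin_width: int = 1000, window: int | None = None
) -> pd.DataFrame:
    """Average, across focal variants, of the per-focal maximum r^2 per bin.

    For each focal variant and each distance bin, the maximum r^2 among
    that focal's partners in the bin is taken; the bin value averages these
    maxima over the focal variants that have at least one partner there
    (n counts contributing focals, not pairs).
    """
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    window = window or int(pairs.attrs.get("window", DEFAULT_WINDOW))
    n_bins = int(np.ceil(window / bin_width))
    values = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=np.int64)
    if len(pairs):
        df = pairs.assign(bin=_bin_index(pairs["distance"].to_numpy(), bin_width))
        per_focal_max = df.groupby(["bin", "focal_index"])["r2"].max()
        agg = per_focal_max.groupby(level="bin").agg(["mean", "size"])
        idx = agg.index.to_numpy()
        keep = idx < n_bins
        values[idx[keep]] = agg["mean"].to_numpy()[keep]
        counts[idx[keep]] = agg["size"].to_numpy()[keep]
    return pd.DataFrame(
        {
            "bin_start": np.arange(n_bins, dtype=np.int64) * bin_width,
            "bin_width": bin_width,
            "value": values,
            "n": counts,
        }
    )


# ---------------------------------------------------------------------------
# Tagging
# ---------------------------------------------------------------------------


def _tagged_at(max_r2: float, threshold: float) -> bool:
    if threshold >= 1.0:
        return max_r2 >= 1.0 - PERFECT_LD_TOL
    return max_r2 > threshold


def tagging_summary(
    pairs: pd.DataFrame,
    strata: Mapping[int, str],
    thresholds: Sequence[float] = (0.5, 0.8, 1.0),
) -> pd.DataFrame:
    """Percentage of focal variants with >= 1 partner above each threshold.

    ``strata`` maps every focal site index to a stratum label and defines
    the denominators; focals absent from ``pairs`` (no partner at all)
    count as untagged.  Thresholds 0.5 and 0.8 are strict (r^2 > t);
    threshold 1.0 means perfect LD within 1e-9.
    """
    max_r2 = (
        pairs.groupby("focal_index")["r2"].max() if len(pairs) else pd.Series(dtype=float)
    )
    rows = []
    labels = sorted(set(strata.values()))
    for label in labels:
        members = [i for i, s in strata.items() if s == label]
        n_total = len(members)
        for t in thresholds:
            n_tagged = sum(
                1 for i in members if _tagged_at(float(max_r2.get(i, 0.0)), t)
            )
            rows.append(
                {
                    "stratum": label,
                    "threshold": t,
                    "n_total": n_total,
                    "n_tagged": n_tagged,
                    "percent": (100.0 * n_tagged / n_total) if n_total else np.nan,
                }
            )
    return pd.DataFrame(rows)


def freq_matched_tagging(
    panel: HaplotypePanel,
    pairs: pd.DataFrame,
    scheme=None,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Cross-tabulated tagging: focal MAF bin x partner-SNP MAF bin.

    For each focal bin in {low, common} and partner bin in {low, common},
    the percentage of focal variants having >= 1 partner of that bin with
    r^2 > threshold.  Cells with an empty focal stratum report n = 0 and
    NaN percent.
    """
    from .variant_stats import BIN_COMMON, BIN_LOW, maf_bins

    bins = maf_bins(panel, scheme)
    focal_ids = sorted(set(pairs["focal_index"])) if len(pairs) else []
    focal_by_bin: dict[str, list[int]] = {BIN_LOW: [], BIN_COMMON: []}
    for i in focal_ids:
        if bins[i] in focal_by_bin:
            focal_by_bin[bins[i]].append(i)

    rows = []
    for fb in (BIN_LOW, BIN_COMMON):
        members = focal_by_bin[fb]
        for pb in (BIN_LOW, BIN_COMMON):
            n_tagged = 0
            for i in members:
                sub = pairs[pairs["focal_index"] == i]
                partner_bins = bins[sub["partner_index"].to_numpy()]
                hit = (sub["r2"].to_numpy() > threshold) & (partner_bins == pb)
                if hit.any():
                    n_tagged += 1
            rows.append(
                {
                    "focal_bin": fb,
                    "partner_bin": pb,
                    "threshold": threshold,
                    "n_total": len(members),
                    "n_tagged": n_tagged,
                    "percent": (100.0 * n_tagged / len(members))
                    if members
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Extended haplotype span
# ---------------------------------------------------------------------------


def haplotype_span(
    panel: HaplotypePanel,
    pairs: pd.DataFrame,
    focal_index: int,
    threshold: float = 0.8,
) -> int:
    """Positional extent (bp) of the high-LD partner set of one focal.

    span = max(position) - min(position) over {focal} plus all partners
    with r^2 > threshold.  This positional-extent definition is an
    interpretation of "extended haplotype length"; see the methods note.
    """
    sub = pairs[(pairs["focal_index"] == focal_index) & (pairs["r2"] > threshold)]
    if not len(sub):
        raise NoHighLDPartnerError(
            f"focal site {focal_index} has no partner with r^2 > {threshold}"
        )
    pos = panel.positions
    points = np.concatenate(
        [[pos[focal_index]], pos[sub["partner_index"].to_numpy()]]
    )
    return int(points.max() - points.min())


def haplotype_spans(
    panel: HaplotypePanel,
    pairs: pd.DataFrame,
    focal_indices: Sequence[int],
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Spans for every focal that has a qualifying partner (others omitted)."""
    rows = []
    for i in focal_indices:
        try:
            rows.append({"focal_index": int(i), "span": haplotype_span(panel, pairs, int(i), threshold)})
        except NoHighLDPartnerError:
            continue
    df = pd.DataFrame(rows, columns=["focal_index", "span"])
    df.attrs["n_without_high_ld_partner"] = len(list(focal_indices)) - len(df)
    return df


def sample_focals(
    focal_indices: Sequence[int], n: int, seed: int
) -> np.ndarray:
    """Seeded random subsample of focal variants (without replacement)."""
    focal_indices = np.asarray(focal_indices, dtype=np.int64)
    if n >= focal_indices.size:
        return focal_indices
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(focal_indices, size=n, replace=False))
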