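"""End-to-end analysis orchestration and report writing.

``run_full_analysis`` drives the whole study design over one panel:
ingest (or simulate) -> merge -> MAF / class annotation -> LOF flags ->
windowed LD scan -> decay curves -> tagging tables (plain and
frequency-matched) -> haplotype-span summaries with between-stratum tests
-> leave-one-out imputation concordance (per stratum, frequency-matched,
and r^2-binned) -> tag-SNP lookup table.

Everything is written as plain TSV plus a JSON run manifest (config hash,
seed, package version) so any table can be reproduced bit-for-bit from the
manifest alone.  Stratum comparisons deliberately carry *no*
multiple-testing correction; the report header says so, so downstream
readers are not misled.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, imputation, ld_core, simulate, variant_stats, vcf_io
from .errors import ConfigError
from .imputation import CopyingModelParams
from .simulate import SimulationConfig
from .variant_stats import BIN_EXCLUDED, MAFBinScheme

logger = logging.getLogger(__name__)

STAGES = ("ld", "tagging", "spans", "impute", "freq_matched", "r2bins", "tag_lookup")


@dataclass
class AnalysisConfig:
    """Validated configuration of a full run.

    Exactly one input source must be given: a simulation block, a merged
    VCF, or an indel + SNP VCF pair.
    """

    out_dir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    merged_vcf: str | None = None
    indel_vcf: str | None = None
    snp_vcf: str | None = None
    sitelist_tsv: str | None = None
    lof_tsv: str | None = None
    regions_bed: str | None = None
    window: int = ld_core.DEFAULT_WINDOW
    maf_scheme: MAFBinScheme = field(default_factory=MAFBinScheme)
    copying: CopyingModelParams = field(default_factory=CopyingModelParams)
    thresholds: tuple[float, ...] = (0.5, 0.8, 1.0)
    focal_sample_size: int | None = None  # None = analyse all focal indels
    stages: tuple[str, ...] = STAGES
    strata_by: tuple[str, ...] = ("maf_bin",)  # maf_bin / size / lof / vclass

    def __post_init__(self) -> None:
        n_inputs = sum(
            1
            for cond in (
                self.simulation is not None,
                self.merged_vcf is not None,
                self.indel_vcf is not None or self.snp_vcf is not None,
            )
            if cond
        )
        if n_inputs != 1:
            raise ConfigError(
                "exactly one of simulation / merged_vcf / indel_vcf+snp_vcf "
                "must be configured"
            )
        if (self.indel_vcf is None) != (self.snp_vcf is None):
            raise ConfigError("indel_vcf and snp_vcf must be given together")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        for s in self.strata_by:
            if s not in ("maf_bin", "size", "lof", "vclass"):
                raise ConfigError(f"unknown stratification: {s}")
        if self.window <= 0:
            raise ConfigError("window must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "AnalysisConfig":
        raw = dict(raw)
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            if "exon_intervals" in sim:
                sim["exon_intervals"] = tuple(
                    tuple(iv) for iv in sim["exon_intervals"]
                )
            raw["simulation"] = SimulationConfig(**sim)
        if "maf_scheme" in raw and raw["maf_scheme"] is not None:
            raw["maf_scheme"] = MAFBinScheme(**raw["maf_scheme"])
        if "copying" in raw and raw["copying"] is not None:
            raw["copying"] = CopyingModelParams(**raw["copying"])
        for key in ("thresholds", "stages", "strata_by"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """The tables of one run plus the manifest describing how they arose."""

    tables: dict[str, pd.DataFrame]
    manifest: dict
    out_dir: Path

    def path(self, name: str) -> Path:
        return self.out_dir / f"{name}.tsv"


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def load_panel(config: AnalysisConfig) -> tuple[vcf_io.HaplotypePanel, pd.DataFrame | None]:
    """Ingest or simulate the merged panel; returns (panel, truth-or-None)."""
    if config.simulation is not None:
        panel, truth = simulate.simulate_panel(config.simulation)
        return panel, truth
    if config.merged_vcf is not None:
        return vcf_io.read_vcf(config.merged_vcf, expect="mixed"), None
    indels = vcf_io.read_vcf(config.indel_vcf, expect="indels")
    snps = vcf_io.read_vcf(config.snp_vcf, expect="snps")
    return vcf_io.merge_panels(indels, snps), None


def prepare_panel(config: AnalysisConfig) -> tuple[vcf_io.HaplotypePanel, pd.DataFrame]:
    """Ingest, apply site-list restriction / LOF flags, build site table."""
    panel, truth = load_panel(config)
    if config.sitelist_tsv is not None:
        panel = vcf_io.restrict_to_sites(
            panel, vcf_io.SiteList.read_tsv(config.sitelist_tsv), keep_indels=True
        )
    if config.lof_tsv is not None:
        panel = vcf_io.flag_lof(panel, vcf_io.SiteList.read_tsv(config.lof_tsv))
    elif truth is not None:
        lof_keys = [
            (r["chrom"], int(r["pos"]))
            for _, r in truth.iterrows()
            if bool(r["lof"])
        ]
        if lof_keys:
            panel = vcf_io.flag_lof(panel, vcf_io.SiteList(lof_keys))
    if config.regions_bed is not None:
        panel = variant_stats.annotate_regions(panel, config.regions_bed)
    sites = variant_stats.site_table(panel, config.maf_scheme)
    return panel, sites


def select_focal_indels(
    panel: vcf_io.HaplotypePanel, sites: pd.DataFrame, config: AnalysisConfig
) -> np.ndarray:
    """Analysable focal indels: polymorphic, not in the excluded MAF bin."""
    mask = (sites["vclass"] != "SNP") & (sites["maf_bin"] != BIN_EXCLUDED)
    focal = sites.loc[mask, "site_index"].to_numpy()
    if config.focal_sample_size is not None:
        focal = ld_core.sample_focals(focal, config.focal_sample_size, config.seed)
    return focal


def build_strata(
    sites: pd.DataFrame, focal: np.ndarray, by: str
) -> dict[int, str]:
    sub = sites.set_index("site_index").loc[focal]
    if by == "maf_bin":
        labels = sub["maf_bin"]
    elif by == "size":
        labels = sub["size_class"]
    elif by == "lof":
        labels = sub["lof"].map({True: "LOF", False: "non-LOF"})
    elif by == "vclass":
        labels = sub["vclass"]
    else:
        raise ConfigError(f"unknown stratification {by!r}")
    return {int(i): str(v) for i, v in labels.items()}


def build_tag_lookup(
    panel: vcf_io.HaplotypePanel, pairs: pd.DataFrame, threshold: float = 0.8
) -> pd.DataFrame:
    """Community lookup table: every (indel, SNP) pair with r^2 > threshold.

    One row per qualifying pair, sorted by indel position then descending
    r^2; indels with no qualifying SNP are absent (their count is reported
    in ``result.attrs["indels_without_tag"]``).
    """
    is_indel = panel.is_indel
    focal_is_indel = is_indel[pairs["focal_index"].to_numpy()] if len(pairs) else []
    sub = pairs[(pairs["r2"] > threshold) & focal_is_indel] if len(pairs) else pairs
    rows = []
    for _, row in sub.iterrows():
        s = panel.sites[int(row["focal_index"])]
        t = panel.sites[int(row["partner_index"])]
        rows.append(
            {
                "indel_id": s.site_id,
                "indel_chrom": s.chrom,
                "indel_pos": s.pos,
                "indel_ref": s.ref_allele,
                "indel_alt": s.alt_allele,
                "snp_id": t.site_id,
                "snp_pos": t.pos,
                "r2": float(row["r2"]),
                "distance": int(row["distance"]),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "indel_id",
            "indel_chrom",
            "indel_pos",
            "indel_ref",
            "indel_alt",
            "snp_id",
            "snp_pos",
            "r2",
            "distance",
        ],
    )
    if len(out):
        out = out.sort_values(
            ["indel_chrom", "indel_pos", "r2"], ascending=[True, True, False]
        ).reset_index(drop=True)
    all_focal_indels = (
        set(pairs.loc[focal_is_indel, "focal_index"].tolist()) if len(pairs) else set()
    )
    tagged = set(
        pairs.loc[
            (pairs["r2"] > threshold) & focal_is_indel, "focal_index"
        ].tolist()
    ) if len(pairs) else set()
    out.attrs["indels_without_tag"] = len(all_focal_indels - tagged)
    return out


def compare_strata(
    tagging: pd.DataFrame,
    spans_by_stratum: Mapping[str, np.ndarray] | None = None,
    max_r2_by_stratum: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Pairwise stratum comparisons: tagging proportions and distributions.

    Tagging percentages are compared with the two-proportion z-test,
    haplotype spans and per-focal max-r^2 distributions with the
    Mann-Whitney test.  No multiple-testing correction is applied.  With a
    single stratum the comparison block is empty.
    """
    rows = []
    strata = sorted(tagging["stratum"].unique()) if len(tagging) else []
    for a, b in combinations(strata, 2):
        for t in sorted(tagging["threshold"].unique()):
            ra = tagging[(tagging["stratum"] == a) & (tagging["threshold"] == t)]
            rb = tagging[(tagging["stratum"] == b) & (tagging["threshold"] == t)]
            if not len(ra) or not len(rb):
                continue
            ra, rb = ra.iloc[0], rb.iloc[0]
            if ra["n_total"] == 0 or rb["n_total"] == 0:
                continue
            res = variant_stats.two_proportion_test(
                int(ra["n_tagged"]), int(ra["n_total"]),
                int(rb["n_tagged"]), int(rb["n_total"]),
            )
            rows.append(
                {
                    "comparison": "tagging_percent",
                    "detail": f"threshold={t}",
                    "stratum_a": a,
                    "stratum_b": b,
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
    for name, dists in (
        ("haplotype_span", spans_by_stratum),
        ("max_r2", max_r2_by_stratum),
    ):
        if not dists:
            continue
        for a, b in combinations(sorted(dists), 2):
            if len(dists[a]) == 0 or len(dists[b]) == 0:
                continue
            res = variant_stats.mann_whitney(dists[a], dists[b])
            rows.append(
                {
                    "comparison": name,
                    "detail": "",
                    "stratum_a": a,
                    "stratum_b": b,
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "comparison",
            "detail",
            "stratum_a",
            "stratum_b",
            "test",
            "statistic",
            "p_value",
        ],
    )


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute every configured stage and write the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    panel, sites = prepare_panel(config)
    tables["sites"] = sites
    focal = select_focal_indels(panel, sites, config)
    logger.info("panel: %d sites, %d focal indels", panel.n_sites, focal.size)

    pairs = pd.DataFrame(columns=ld_core.PAIR_COLUMNS)
    if "ld" in config.stages and focal.size:
        pairs = ld_core.ld_scan(panel, focal, window=config.window)
        tables["ld_pairs"] = _pairs_with_ids(panel, pairs)
        tables["avg_r2_curve"] = ld_core.average_r2_curve(pairs)
        tables["mean_max_r2_curve"] = ld_core.mean_max_r2_curve(pairs)

    strata_maps = {
        by: build_strata(sites, focal, by) for by in config.strata_by
    }

    spans_by_stratum: dict[str, np.ndarray] = {}
    max_r2_by_stratum: dict[str, np.ndarray] = {}
    if "tagging" in config.stages and len(pairs):
        tag_frames = []
        for by, strata in strata_maps.items():
            tf = ld_core.tagging_summary(pairs, strata, config.thresholds)
            tf.insert(0, "stratified_by", by)
            tag_frames.append(tf)
        tables["tagging"] = pd.concat(tag_frames, ignore_index=True)
        tables["freq_matched_tagging"] = ld_core.freq_matched_tagging(
            panel, pairs, config.maf_scheme
        )

    if "spans" in config.stages and len(pairs):
        spans = ld_core.haplotype_spans(panel, pairs, focal)
        tables["haplotype_spans"] = spans
        strata = strata_maps.get("maf_bin") or next(iter(strata_maps.values()))
        max_r2 = pairs.groupby("focal_index")["r2"].max()
        for i, label in strata.items():
            if i in spans["focal_index"].values:
                spans_by_stratum.setdefault(label, []).append(
                    int(spans.loc[spans["focal_index"] == i, "span"].iloc[0])
                )
            if i in max_r2.index:
                max_r2_by_stratum.setdefault(label, []).append(float(max_r2[i]))
        spans_by_stratum = {k: np.asarray(v) for k, v in spans_by_stratum.items()}
        max_r2_by_stratum = {k: np.asarray(v) for k, v in max_r2_by_stratum.items()}

    if ("tagging" in config.stages) and "tagging" in tables:
        primary_by = config.strata_by[0]
        tables["strata_comparisons"] = compare_strata(
            tables["tagging"][tables["tagging"]["stratified_by"] == primary_by],
            spans_by_stratum or None,
            max_r2_by_stratum or None,
        )

    if "impute" in config.stages and focal.size:
        for by, strata in strata_maps.items():
            res = imputation.loo_concordance(
                panel, focal, strata=strata, params=config.copying
            )
            frame = imputation.tables_to_frame(res)
            frame.insert(0, "stratified_by", by)
            tables.setdefault("concordance", pd.DataFrame())
            tables["concordance"] = pd.concat(
                [tables["concordance"], frame], ignore_index=True
            )

    if "freq_matched" in config.stages and focal.size:
        res = imputation.freq_matched_concordance(
            panel, focal, config.maf_scheme, config.copying
        )
        tables["freq_matched_concordance"] = imputation.tables_to_frame(res)

    if "r2bins" in config.stages and focal.size:
        res = imputation.r2_binned_concordance(panel, focal, config.copying)
        frame = imputation.tables_to_frame(res, key_name="r2_bin")
        tables["r2_binned_concordance"] = frame

    if "tag_lookup" in config.stages and len(pairs):
        tables["tag_lookup"] = build_tag_lookup(panel, pairs)

    manifest = {
        "package": "indelld",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_sites": int(panel.n_sites),
        "n_samples": int(panel.n_samples),
        "n_focal_indels": int(focal.size),
        "notes": [
            "stratum comparisons carry no multiple-testing correction",
        ],
    }

    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return ReportBundle(tables=tables, manifest=manifest, out_dir=out_dir)


def _pairs_with_ids(panel: vcf_io.HaplotypePanel, pairs: pd.DataFrame) -> pd.DataFrame:
    out = pairs.copy()
    ids = np.array([s.site_id for s in panel.sites])
    out.insert(0, "focal_id", ids[out["focal_index"].to_numpy()])
    out.insert(1, "partner_id", ids[out["partner_index"].to_numpy()])
    return out
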