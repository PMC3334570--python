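import numpy as np
import pytest

from indelld.vcf_io import HaplotypePanel, VariantSite


def make_site(pos, ref="A", alt="G", chrom="1", site_id=None, lof=False):
    return VariantSite(
        chrom=chrom,
        pos=pos,
        site_id=site_id or f"v{pos}",
        ref_allele=ref,
        alt_allele=alt,
        lof=lof,
    )


def panel_from_columns(entries, sample_prefix="s"):
    """Build a panel from [(pos, ref, alt, column), ...] on one chromosome."""
    entries = sorted(entries, key=lambda e: e[0])
    sites = [make_site(pos, ref, alt) for pos, ref, alt, _ in entries]
    matrix = np.stack([np.asarray(col, dtype=np.int8) for *_, col in entries], axis=1)
    n = matrix.shape[0] // 2
    return HaplotypePanel(
        sites=sites,
        hap_matrix=matrix,
        sample_ids=[f"{sample_prefix}{i}" for i in range(n)],
    )


@pytest.fixture
def small_sim_panel():
    from indelld.simulate import SimulationConfig, simulate_panel

    cfg = SimulationConfig(
        seed=7, n_samples=20, n_sites=200, region_length=100_000, indel_fraction=0.1
    )
    panel, truth = simulate_panel(cfg)
    return panel, truth
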