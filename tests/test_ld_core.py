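"""Pairwise r^2, windowed scans, decay curves, tagging and spans."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import panel_from_columns
from indelld import ld_core
from indelld.errors import DomainError, MonomorphicSiteError, NoHighLDPartnerError


def phi_squared(a, b):
    """Independent oracle: squared Pearson correlation of the two columns."""
    return float(np.corrcoef(a, b)[0, 1] ** 2)


class TestPairwiseR2:
    def test_identical_columns_perfect_ld(self):
        panel = panel_from_columns(
            [(100, "A", "G", [0, 0, 1, 1]), (200, "C", "T", [0, 0, 1, 1])]
        )
        assert ld_core.pairwise_r2(panel, 0, 1) == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        panel = panel_from_columns(
            [(100, "A", "G", [0, 1, 0, 1]), (200, "C", "T", [1, 0, 1, 0])]
        )
        assert ld_core.pairwise_r2(panel, 0, 1) == pytest.approx(1.0)

    def test_six_haplotype_worked_example(self):
        # p = 1/3, q = 1/6, p11 = 1/6, D = 1/9, r^2 = (1/81)/(2/9 * 5/36) = 0.4
        panel = panel_from_columns(
            [(100, "A", "G", [1, 1, 0, 0, 0, 0]), (200, "C", "T", [1, 0, 0, 0, 0, 0])]
        )
        assert ld_core.pairwise_r2(panel, 0, 1) == pytest.approx(0.4)

    def test_symmetry_and_flip_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.integers(0, 2, 10)
            b = rng.integers(0, 2, 10)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            panel = panel_from_columns(
                [(100, "A", "G", a), (200, "C", "T", b), (300, "G", "A", 1 - a)]
            )
            r_ab = ld_core.pairwise_r2(panel, 0, 1)
            assert r_ab == pytest.approx(ld_core.pairwise_r2(panel, 1, 0))
            assert r_ab == pytest.approx(ld_core.pairwise_r2(panel, 2, 1))
            assert ld_core.pairwise_r2(panel, 0, 2) == pytest.approx(1.0)

    def test_exhaustive_oracle_small_panels(self):
        """D-formula equals the phi^2 oracle on all 6-haplotype two-site panels."""
        for bits_a in itertools.product((0, 1), repeat=6):
            a = np.array(bits_a)
            if a.sum() in (0, 6):
                continue
            for bits_b in itertools.product((0, 1), repeat=6):
                b = np.array(bits_b)
                if b.sum() in (0, 6):
                    continue
                assert ld_core.r2_from_columns(a, b) == pytest.approx(
                    phi_squared(a, b), abs=1e-12
                )

    def test_monomorphic_rejected(self):
        panel = panel_from_columns(
            [(100, "A", "G", [0, 0, 0, 0]), (200, "C", "T", [0, 1, 0, 1])]
        )
        with pytest.raises(MonomorphicSiteError):
            ld_core.pairwise_r2(panel, 0, 1)


class TestLdScan:
    def _panel(self):
        cols = [
            (10_000, "AT", "A", [0, 1, 0, 1, 0, 1]),   # focal indel
            (10_500, "A", "G", [0, 1, 0, 1, 0, 1]),
            (30_000, "C", "T", [1, 1, 0, 0, 1, 0]),
            (80_000, "G", "A", [0, 0, 0, 0, 0, 0]),    # monomorphic
            (160_000, "T", "C", [1, 0, 1, 0, 1, 0]),   # beyond 100 kb
        ]
        return panel_from_columns(cols)

    def test_window_and_monomorphic_skip(self):
        panel = self._panel()
        pairs = ld_core.ld_scan(panel, [0])
        assert set(pairs["partner_index"]) == {1, 2}
        assert pairs.attrs["monomorphic_partners_skipped"] == 1

    def test_pair_count(self):
        panel = panel_from_columns(
            [
                (10_000, "AT", "A", [0, 1, 0, 1]),
                (11_000, "A", "G", [0, 1, 1, 0]),
                (12_000, "C", "T", [1, 1, 0, 0]),
                (13_000, "G", "A", [0, 0, 1, 1]),
            ]
        )
        pairs = ld_core.ld_scan(panel, [0])
        assert len(pairs) == 3

    def test_focal_out_of_range(self):
        with pytest.raises(IndexError):
            ld_core.ld_scan(self._panel(), [99])


def pairs_df(rows):
    return pd.DataFrame(rows, columns=["focal_index", "partner_index", "distance", "r2"])


class TestCurves:
    def test_average_r2_bin_edges_and_mean(self):
        pairs = pairs_df([(0, 1, 100, 0.2), (0, 2, 55, 0.6), (0, 3, 101, 1.0)])
        curve = ld_core.average_r2_curve(pairs, bin_width=100, window=300)
        # bin 0 covers 1..100 -> mean(0.2, 0.6); bin 1 covers 101..200
        assert curve.loc[0, "value"] == pytest.approx(0.4)
        assert curve.loc[0, "n"] == 2
        assert curve.loc[1, "value"] == pytest.approx(1.0)
        assert curve.loc[2, "n"] == 0 and np.isnan(curve.loc[2, "value"])

    def test_average_r2_rejects_bad_width(self):
        with pytest.raises(DomainError):
            ld_core.average_r2_curve(pairs_df([]), bin_width=0)

    def test_mean_max_within_bin(self):
        pairs = pairs_df([(0, 1, 500, 0.3), (0, 2, 700, 0.9)])
        curve = ld_core.mean_max_r2_curve(pairs, bin_width=1000, window=2000)
        assert curve.loc[0, "value"] == pytest.approx(0.9)
        assert curve.loc[0, "n"] == 1

    def test_mean_of_per_focal_maxima(self):
        pairs = pairs_df(
            [(0, 1, 500, 0.8), (0, 2, 900, 0.2), (1, 3, 400, 0.4), (2, 4, 1500, 0.7)]
        )
        curve = ld_core.mean_max_r2_curve(pairs, bin_width=1000, window=2000)
        assert curve.loc[0, "value"] == pytest.approx((0.8 + 0.4) / 2)
        assert curve.loc[0, "n"] == 2  # focal 2 has no partner in bin 0
        assert curve.loc[1, "value"] == pytest.approx(0.7)


class TestTagging:
    def test_threshold_semantics(self):
        pairs = pairs_df([(0, 10, 100, 0.85)])
        table = ld_core.tagging_summary(pairs, {0: "all"})
        by_t = table.set_index("threshold")["percent"]
        assert by_t[0.5] == 100.0 and by_t[0.8] == 100.0 and by_t[1.0] == 0.0

    def test_perfect_everywhere(self):
        pairs = pairs_df([(0, 10, 100, 1.0), (1, 11, 50, 1.0)])
        table = ld_core.tagging_summary(pairs, {0: "all", 1: "all"})
        assert (table["percent"] == 100.0).all()

    def test_no_partner_counts_as_untagged(self):
        pairs = pairs_df([(0, 10, 100, 0.9)])
        table = ld_core.tagging_summary(pairs, {0: "all", 1: "all"})
        assert table.set_index("threshold").loc[0.8, "percent"] == 50.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        rows = [
            (f, p, rng.integers(1, 1000), rng.random())
            for f in range(10)
            for p in range(20, 26)
        ]
        table = ld_core.tagging_summary(
            pairs_df(rows), {f: "all" for f in range(10)}
        )
        pct = table.set_index("threshold")["percent"]
        assert pct[0.5] >= pct[0.8] >= pct[1.0]


class TestFreqMatchedTagging:
    def test_cross_tab_cells(self):
        # focal 0: low MAF, tagged only by the low-MAF partner
        panel = panel_from_columns(
            [
                (100, "AT", "A", [1] + [0] * 39),          # low-MAF indel
                (200, "A", "G", [1] + [0] * 39),           # low-MAF perfect tag
                (300, "C", "T", [1] * 20 + [0] * 20),      # common SNP, unlinked
            ]
        )
        from indelld.variant_stats import MAFBinScheme

        scheme = MAFBinScheme(excluded_below=0.01, low_upper=0.05)
        pairs = ld_core.ld_scan(panel, [0])
        table = ld_core.freq_matched_tagging(panel, pairs, scheme)
        cell = table.set_index(["focal_bin", "partner_bin"])
        assert cell.loc[("low", "low"), "percent"] == 100.0
        assert cell.loc[("low", "common"), "percent"] == 0.0
        assert cell.loc[("common", "low"), "n_total"] == 0
        assert np.isnan(cell.loc[("common", "common"), "percent"])


class TestHaplotypeSpan:
    def test_span_definitions(self):
        panel = panel_from_columns(
            [
                (10_500, "A", "G", [0, 1, 0, 1]),
                (20_000, "AT", "A", [0, 1, 0, 1]),
                (25_000, "C", "T", [0, 1, 0, 1]),
                (30_700, "G", "A", [0, 1, 0, 1]),
            ]
        )
        pairs = ld_core.ld_scan(panel, [1])
        assert ld_core.haplotype_span(panel, pairs, 1) == 20_200
        one_partner = pairs[pairs["partner_index"] == 2]
        assert ld_core.haplotype_span(panel, one_partner, 1) == 5_000

    def test_no_qualifying_partner(self):
        panel = panel_from_columns(
            [(10_000, "AT", "A", [0, 1, 0, 1]), (20_000, "A", "G", [1, 1, 0, 0])]
        )
        pairs = ld_core.ld_scan(panel, [0])
        with pytest.raises(NoHighLDPartnerError):
            ld_core.haplotype_span(panel, pairs, 0, threshold=0.8)


def test_ld_decay_on_simulated_panels():
    """Mean max r^2 declines with distance, averaged over replicates."""
    from indelld.simulate import SimulationConfig, simulate_panel

    near, far = [], []
    for seed in range(20):
        cfg = SimulationConfig(
            seed=seed, n_samples=30, n_sites=300, region_length=300_000
        )
        panel, _ = simulate_panel(cfg)
        pairs = ld_core.ld_scan(panel, panel.indel_indices)
        curve = ld_core.mean_max_r2_curve(pairs, bin_width=10_000)
        near.append(curve.loc[0, "value"])
        far.append(curve.loc[8, "value"])
    assert np.nanmean(near) > np.nanmean(far)


def test_sampled_focals_reproduce_tagging_within_binomial_error():
    """Tagging percentages from a random focal subsample agree with the
    all-focal percentages within Monte-Carlo (hypergeometric) tolerance."""
    from indelld.simulate import SimulationConfig, simulate_panel

    cfg = SimulationConfig(
        seed=19, n_samples=40, n_sites=1200, region_length=600_000, indel_fraction=0.3
    )
    panel, _ = simulate_panel(cfg)
    focal = panel.indel_indices
    pairs = ld_core.ld_scan(panel, focal)
    full = ld_core.tagging_summary(pairs, {int(i): "all" for i in focal})
    n_sub = 150
    sub = ld_core.sample_focals(focal, n_sub, seed=19)
    sub_pairs = pairs[pairs["focal_index"].isin(sub)]
    sampled = ld_core.tagging_summary(sub_pairs, {int(i): "all" for i in sub})
    for t in (0.5, 0.8):
        p_full = full.set_index("threshold").loc[t, "percent"] / 100
        p_sub = sampled.set_index("threshold").loc[t, "percent"] / 100
        se = np.sqrt(max(p_full * (1 - p_full), 1e-9) / n_sub)
        assert abs(p_sub - p_full) < 4 * se


def test_focal_sampling_reproducible_and_consistent():
    rng_focals = np.arange(100)
    sub1 = ld_core.sample_focals(rng_focals, 30, seed=11)
    sub2 = ld_core.sample_focals(rng_focals, 30, seed=11)
    assert np.array_equal(sub1, sub2)
    assert len(set(sub1)) == 30
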