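"""TAD disruption, virtual 4C, enhancer loss, interaction disruption, and
the position-effect support score."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from svdriver.direct_effects import DirectEffectClass
from svdriver.model import GenomicInterval, SVSet
from svdriver.position_effects import (
    COMPONENT_NAMES,
    V4CProfile,
    count_lost_enhancers,
    expression_component,
    extract_v4c_profile,
    interaction_disruption,
    support_score,
    sv_effect,
    tad_disruption,
    top_expressing_cell_types,
    v4c_disruption_fraction,
)

from conftest import make_gene, make_junction
from oracles import brute_v4c_fraction


def svset(*junctions):
    return SVSet("P", list(junctions))


class TestTadDisruption:
    TADS = [(0, 1_000_000), (1_000_000, 2_000_000)]

    def test_junction_outside_gene_tad_does_not_disrupt(self):
        gene = make_gene("G", "chr1", 190_000, 210_000)
        svs = svset(make_junction("j", "chr1", 1_500_000, "chr2", 0))
        assert tad_disruption(gene, self.TADS, svs) == (False, None)

    def test_portion_is_far_side_of_nearest_junction(self):
        gene = make_gene("G", "chr1", 200_000, 220_000)  # TSS 200,000
        svs = svset(make_junction("j", "chr1", 600_000, "chr2", 0))
        disrupted, portion = tad_disruption(gene, self.TADS, svs)
        assert disrupted and portion == GenomicInterval("chr1", 600_000, 1_000_000)

    def test_junction_left_of_tss_gives_left_portion(self):
        gene = make_gene("G", "chr1", 500_000, 520_000)
        svs = svset(make_junction("j", "chr1", 100_000, "chr2", 0))
        _, portion = tad_disruption(gene, self.TADS, svs)
        assert portion == GenomicInterval("chr1", 0, 100_000)

    def test_boundary_junction_is_not_inside(self):
        gene = make_gene("G", "chr1", 200_000, 220_000)
        svs = svset(make_junction("j", "chr1", 1_000_000, "chr2", 0))
        assert tad_disruption(gene, self.TADS, svs) == (False, None)

    def test_tss_outside_all_tads(self):
        gene = make_gene("G", "chr1", 2_500_000, 2_520_000)
        svs = svset(make_junction("j", "chr1", 500_000, "chr2", 0))
        assert tad_disruption(gene, self.TADS, svs) == (False, None)

    def test_overlapping_tads_use_smallest_containing(self):
        tads = [(0, 1_000_000), (100_000, 400_000)]
        gene = make_gene("G", "chr1", 200_000, 220_000)
        svs = svset(make_junction("j", "chr1", 700_000, "chr2", 0))
        # 700,000 is outside the smallest containing TAD [100k, 400k)
        assert tad_disruption(gene, tads, svs) == (False, None)


class TestTopExpressing:
    def test_tie_break_lexicographic(self):
        expr = pd.DataFrame(
            {"ct_e": [9.0], "ct_b": [7.0], "ct_a": [7.0], "ct_c": [3.0], "ct_d": [0.4]},
            index=["G"],
        )
        gene = make_gene("G", "chr1", 0, 1000)
        assert top_expressing_cell_types(gene, expr) == ["ct_e", "ct_a", "ct_b"]

    def test_single_expressed_cell_type(self):
        expr = pd.DataFrame({"x": [2.0], "y": [0.1]}, index=["G"])
        gene = make_gene("G", "chr1", 0, 1000)
        assert top_expressing_cell_types(gene, expr) == ["x"]

    def test_rpkm_cutoff_is_strict(self):
        expr = pd.DataFrame({"x": [0.5], "y": [0.51]}, index=["G"])
        gene = make_gene("G", "chr1", 0, 1000)
        assert top_expressing_cell_types(gene, expr) == ["y"]


class TestEnhancerLoss:
    PORTION = GenomicInterval("chr1", 600_000, 1_000_000)

    def test_empty_portion_counts_zero(self):
        assert count_lost_enhancers(None, [(650_000, 651_500)]) == 0

    def test_enhancers_inside_portion_counted(self):
        enh = [(650_000, 651_500), (700_000, 701_500), (990_000, 991_500)]
        assert count_lost_enhancers(self.PORTION, enh) == 3

    def test_enhancer_straddling_the_junction_counted(self):
        assert count_lost_enhancers(self.PORTION, [(599_000, 601_000)]) == 1

    def test_enhancer_outside_portion_not_counted(self):
        assert count_lost_enhancers(self.PORTION, [(100_000, 101_500), (1_000_000, 1_001_500)]) == 0


class TestV4C:
    def make_profile(self, n_bins=101, resolution=40_000, signal=None):
        vp = n_bins // 2
        return V4CProfile(
            cell_type="ct", chrom="chr1", resolution=resolution,
            viewpoint_bin=vp, window_start_bin=0,
            signal=np.ones(n_bins) if signal is None else signal,
        )

    def test_no_junction_in_window_gives_zero(self):
        p = self.make_profile()
        tss = int((p.viewpoint_bin + 0.5) * p.resolution)
        assert v4c_disruption_fraction(p, svset(), tss) == 0.0

    def test_single_junction_next_to_viewpoint_cuts_half(self):
        p = self.make_profile()
        tss = int((p.viewpoint_bin + 0.5) * p.resolution)
        svs = svset(make_junction("j", "chr1", tss + p.resolution, "chr2", 0))
        frac = v4c_disruption_fraction(p, svs, tss)
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_all_zero_profile_gives_zero(self):
        p = self.make_profile(signal=np.zeros(101))
        tss = int((p.viewpoint_bin + 0.5) * p.resolution)
        svs = svset(make_junction("j", "chr1", tss + 100_000, "chr2", 0))
        assert v4c_disruption_fraction(p, svs, tss) == 0.0

    def test_matches_brute_force_on_random_profiles(self, rng):
        for _ in range(30):
            n_bins = int(rng.integers(10, 80))
            res = 10_000
            signal = rng.random(n_bins) * 10
            vp = int(rng.integers(0, n_bins))
            start = int(rng.integers(0, 5))
            p = V4CProfile("ct", "chr1", res, vp + start, start, signal)
            tss = int((vp + start + 0.5) * res)
            junctions = [
                make_junction(f"j{k}", "chr1", int(rng.integers(0, (n_bins + start) * res)),
                              "chr2", 0)
                for k in range(int(rng.integers(0, 4)))
            ]
            svs = svset(*junctions)
            got = v4c_disruption_fraction(p, svs, tss)
            want = brute_v4c_fraction(
                signal, range(start, start + n_bins), res, vp + start, tss,
                svs.junction_positions("chr1"),
            )
            assert got == pytest.approx(want, abs=1e-12)

    def test_adding_junctions_never_decreases_fraction(self, rng):
        p = self.make_profile(signal=rng.random(101))
        tss = int((p.viewpoint_bin + 0.5) * p.resolution)
        junctions = []
        prev = 0.0
        for k in range(6):
            junctions.append(
                make_junction(f"j{k}", "chr1", int(rng.integers(0, 101 * p.resolution)), "chr2", 0)
            )
            frac = v4c_disruption_fraction(p, svset(*junctions), tss)
            assert frac >= prev - 1e-12
            prev = frac
        # duplication and order invariance
        doubled = junctions + junctions[::-1]
        assert v4c_disruption_fraction(p, svset(*doubled), tss) == pytest.approx(prev)

    def test_extract_profile_truncates_at_chromosome_ends(self):
        m = np.arange(100.0).reshape(10, 10)
        prof = extract_v4c_profile(m, 1000, "chr1", 500, "ct", window_bp=3000)
        assert prof.viewpoint_bin == 0
        assert prof.window_start_bin == 0
        np.testing.assert_allclose(prof.signal, m[0, :4])


class TestInteractionDisruption:
    def make_ix(self, tss, others, chrom="chr1"):
        anchor = GenomicInterval(chrom, tss - 2000, tss + 2000)
        return [(anchor, GenomicInterval(chrom, o, o + 4000)) for o in others]

    def test_no_interactions_gives_zero(self):
        gene = make_gene("G", "chr1", 1_000_000, 1_010_000)
        frac, n = interaction_disruption([], gene, svset())
        assert (frac, n) == (0.0, 0)

    def test_same_side_anchors_not_broken(self):
        gene = make_gene("G", "chr1", 1_000_000, 1_010_000)
        ix = self.make_ix(gene.tss, [1_200_000, 1_300_000])
        svs = svset(make_junction("j", "chr1", 2_000_000, "chr2", 0))
        assert interaction_disruption(ix, gene, svs)[0] == 0.0

    def test_seven_of_twenty_crossing_gives_035(self):
        gene = make_gene("G", "chr1", 1_000_000, 1_010_000)
        # 7 anchors beyond the junction at 1.5 Mb, 13 before it
        others = [1_600_000 + i * 10_000 for i in range(7)] + [
            1_100_000 + i * 10_000 for i in range(13)
        ]
        ix = self.make_ix(gene.tss, others)
        svs = svset(make_junction("j", "chr1", 1_500_000, "chr2", 0))
        frac, n = interaction_disruption(ix, gene, svs)
        assert n == 20 and frac == pytest.approx(0.35)

    def test_non_promoter_interactions_ignored(self):
        gene = make_gene("G", "chr1", 1_000_000, 1_010_000)
        far = [(GenomicInterval("chr1", 5_000_000, 5_004_000),
                GenomicInterval("chr1", 6_000_000, 6_004_000))]
        assert interaction_disruption(far, gene, svset())[1] == 0

    def test_inter_chromosomal_interaction_never_broken(self):
        gene = make_gene("G", "chr1", 1_000_000, 1_010_000)
        ix = [(GenomicInterval("chr1", gene.tss - 1000, gene.tss + 1000),
               GenomicInterval("chr2", 0, 4000))]
        svs = svset(make_junction("j", "chr1", 1_500_000, "chr2", 0))
        assert interaction_disruption(ix, gene, svs)[0] == 0.0


class TestExpressionComponent:
    GENE = make_gene("G", "chr1", 0, 1000)

    @pytest.mark.parametrize(
        "lfc,p,expected",
        [(-1.2, 0.01, True), (0.8, 0.2, False), (0.1, 0.01, False), (0.51, 0.049, True)],
    )
    def test_cutoffs(self, lfc, p, expected):
        de = pd.DataFrame({"log2fc": [lfc], "p": [p]}, index=["G"])
        assert expression_component(de, self.GENE) is expected

    def test_absent_gene_is_false(self):
        de = pd.DataFrame({"log2fc": [-2.0], "p": [0.001]}, index=["OTHER"])
        assert expression_component(de, self.GENE) is False
        assert expression_component(None, self.GENE) is False


class TestSupportScore:
    def test_score_is_popcount_for_all_64_combinations(self):
        for bits in itertools.product([False, True], repeat=6):
            components = dict(zip(COMPONENT_NAMES, bits))
            assert support_score(components) == sum(bits)

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError):
            support_score({"bogus": True})


class TestSvEffect:
    def direct(self, category):
        return DirectEffectClass(category, 0 if category in ("deleted", "truncated") else 10)

    def test_del_trunc_strong_regardless_of_support(self):
        for cat in ("deleted", "truncated"):
            e = sv_effect(self.direct(cat), 0)
            assert e.strength == "strong" and e.basis == "direct_del_trunc"

    @pytest.mark.parametrize("support,strength", [(4, "strong"), (2, "weak"), (1, "none"), (0, "none")])
    def test_adjacent_support_cutoffs(self, support, strength):
        assert sv_effect(self.direct("adjacent"), support).strength == strength

    def test_inverted_behaves_like_adjacent(self):
        assert sv_effect(self.direct("inverted"), 4).strength == "strong"
        assert sv_effect(self.direct("inverted"), 0).strength == "none"

    @pytest.mark.parametrize("support,strength", [(0, "weak"), (3, "weak"), (5, "strong")])
    def test_duplicated_at_least_weak(self, support, strength):
        e = sv_effect(self.direct("duplicated"), support)
        assert e.strength == strength and e.basis == "direct_dup"
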