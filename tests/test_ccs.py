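"""Copy-number screening: signal series, segmentation, karyotype strings."""

import numpy as np
import pytest

from pgtsr import (
    CNVSegment, balanced_or_unbalanced, copy_signals, emit_array, karyotype_string,
    make_embryo, parse_karyotype, screen_sample, segment_copy, simulate_meiosis,
    spouse_gamete,
)
from pgtsr.ccs import BALANCED_KARYOTYPE
from pgtsr.cohort import embryo_truth_arrays
from pgtsr.observe import HET


def make_truth_embryo(family, genome, panel, rng, mode):
    cg = simulate_meiosis(family, genome, panel, rng, mode=mode)
    return make_embryo("e", cg, spouse_gamete(family, genome, panel, rng))


class TestCopySignals:
    def test_noiseless_disomic_signal_is_zero(self, family, genome, panel, rng):
        emb = make_truth_embryo(family, genome, panel, rng, "alternate")
        obs = emit_array(family, panel, emb)
        for chrom in panel.chromosomes:
            series = copy_signals(obs, panel.positions, chrom)
            assert np.allclose(series["copy_signal"], 0.0)
            assert series["position"].is_monotonic_increasing

    def test_monosomic_segment_has_no_heterozygous_fractions(self, family, genome, panel, rng):
        emb = make_truth_embryo(family, genome, panel, rng, "adjacent1")
        obs = emit_array(family, panel, emb)
        spec = family.spec
        seen = False
        for chrom in (spec.chromA, spec.chromB):
            copy, _, _ = embryo_truth_arrays(family, panel, emb, chrom)
            mono = copy == 1
            if mono.any():
                assert np.allclose(obs.copy_signal[chrom][mono], np.log2(0.5))
                assert not (obs.calls[chrom][mono] == HET).any()
                af = obs.allele_fraction[chrom][mono]
                assert np.all((af == 0) | (af == 1))
                seen = True
        assert seen

    def test_nocalls_are_masked_from_series(self, family, genome, panel, rng):
        emb = make_truth_embryo(family, genome, panel, rng, "alternate")
        obs = emit_array(family, panel, emb)
        chrom = family.spec.chromA
        obs.calls[chrom][:10] = -1
        series = copy_signals(obs, panel.positions, chrom)
        assert len(series) == panel.n_sites(chrom) - 10


class TestSegmentation:
    def planted_series(self, seed, sd=0.0, n=300, cut=4_000_000, copy_sig=-1.0):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(np.arange(1, 5_000_001), n, replace=False))
        sig = np.where(pos >= cut, copy_sig, 0.0) + rng.normal(0, sd, n)
        return pos, sig

    def test_noiseless_terminal_loss_recovered(self, genome):
        pos, sig = self.planted_series(0)
        (seg,) = segment_copy(pos, sig, "chr1", genome)
        assert seg.copy == 1
        assert seg.end == genome.length("chr1")
        assert abs(seg.start - 4_000_000) <= 2 * (5_000_000 / 300) * 8  # window span

    def test_all_disomic_series_yields_no_segments(self, genome):
        pos, _ = self.planted_series(1)
        assert segment_copy(pos, np.zeros(len(pos)), "chr1", genome) == []

    def test_noisy_recovery_across_seeds(self, genome):
        # simulation oracle: sd=0.1 noise, planted loss found in >= 19/20 runs
        hits = 0
        spacing = 5_000_000 / 300
        for seed in range(20):
            pos, sig = self.planted_series(seed, sd=0.1)
            segs = segment_copy(pos, sig, "chr1", genome)
            if (
                len(segs) == 1
                and segs[0].copy == 1
                and abs(segs[0].start - 4_000_000) <= 15 * spacing
            ):
                hits += 1
        assert hits >= 19

    def test_short_series_rejected(self, genome):
        with pytest.raises(ValueError, match="shorter"):
            segment_copy(np.arange(1, 11), np.zeros(10), "chr1", genome)

    def test_window_below_five_rejected(self, genome):
        pos, sig = self.planted_series(0)
        with pytest.raises(ValueError):
            segment_copy(pos, sig, "chr1", genome, window_snps=3)


class TestKaryotypeString:
    def test_reciprocal_terminal_imbalance_renders_case_style(self, hg19):
        segs = [
            CNVSegment("chr1", 244_573_199, 249_250_621, 1, -1.0),
            CNVSegment("chr2", 182_319_608, 243_199_373, 3, 0.58),
        ]
        karyo = karyotype_string(segs, hg19)
        assert karyo.string == "1q44*1; 2q32.1q37.3*3"
        assert not karyo.balanced

    def test_p_arm_gain_with_q_arm_loss_renders_case_style(self, hg19):
        segs = [
            CNVSegment("chr12", 1, 5_959_384, 3, 0.58),
            CNVSegment("chr14", 66_307_383, 107_349_540, 1, -1.0),
        ]
        assert karyotype_string(segs, hg19).string == "12p13.33p13.31*3; 14q23.3q32.33*1"

    def test_balanced_notation_is_verbatim(self, hg19):
        karyo = karyotype_string([], hg19)
        assert karyo.string == BALANCED_KARYOTYPE == "(1–22)*1,(XN)*1"
        assert karyo.balanced

    def test_round_trip_at_band_resolution(self, hg19):
        segs = [
            CNVSegment("chr1", 244_573_199, 249_250_621, 1, -1.0),
            CNVSegment("chr2", 182_319_608, 243_199_373, 3, 0.58),
        ]
        karyo = karyotype_string(segs, hg19)
        parsed = parse_karyotype(karyo.string, hg19)
        for orig, back in zip(segs, parsed):
            assert back.chrom == orig.chrom and back.copy == orig.copy
            # band-resolution-limited: parsed bounds are the band bounds
            assert back.start <= orig.start and back.end >= orig.end
        assert parse_karyotype(BALANCED_KARYOTYPE, hg19) == []


class TestVerdicts:
    def test_balanced_iff_no_abnormal_segment(self, hg19):
        assert balanced_or_unbalanced(karyotype_string([], hg19)) == "balanced"
        seg = CNVSegment("chr1", 244_573_199, 249_250_621, 1, -1.0)
        assert balanced_or_unbalanced(karyotype_string([seg], hg19)) == "unbalanced"

    def test_adjacent2_embryo_screens_unbalanced(self, family, genome, panel, rng):
        emb = make_truth_embryo(family, genome, panel, rng, "adjacent2")
        obs = emit_array(family, panel, emb)
        karyo = screen_sample(obs, panel.positions, genome)
        assert balanced_or_unbalanced(karyo) == "unbalanced"

    def test_adjacent1_truth_imbalance_is_reciprocal(self, family, genome, panel, rng):
        # the gained distal span on one chromosome pairs with the lost distal
        # span on the other (checked on truth copy counts)
        spec = family.spec
        for _ in range(10):
            emb = make_truth_embryo(family, genome, panel, rng, "adjacent1")
            ca, _, _ = embryo_truth_arrays(family, panel, emb, spec.chromA)
            cb, _, _ = embryo_truth_arrays(family, panel, emb, spec.chromB)
            pa, pb = panel.positions[spec.chromA], panel.positions[spec.chromB]
            dist_a, dist_b = pa > spec.posA, pb > spec.posB
            assert (ca[~dist_a] == 2).all() and (cb[~dist_b] == 2).all()
            gained_a = (ca[dist_a] == 3).all()
            lost_a = (ca[dist_a] == 1).all()
            gained_b = (cb[dist_b] == 3).all()
            lost_b = (cb[dist_b] == 1).all()
            assert (gained_a and lost_b) or (lost_a and gained_b)
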