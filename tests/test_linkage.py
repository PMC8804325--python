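"""Informative-SNP selection, phasing, region votes, recombination."""

import warnings

import numpy as np
import pytest

from pgtsr import (
    emit_array, linkage_classify, make_embryo, phase_with_embryo,
    phase_with_grandparent, recombination_in_breakpoint_region,
    recombination_scan, region_call, select_informative, simulate_meiosis,
    spouse_gamete,
)
from pgtsr.cohort import HAP_T
from pgtsr.linkage import InformativeSNP, RegionCall, mendelian_error_fraction
from pgtsr.observe import HET, HOM_ALT, HOM_REF


def family_calls(family, panel, chrom):
    return (
        family.carrier.genotypes(chrom),
        family.spouse.genotypes(chrom),
        family.grandparent_transmitting.genotypes(chrom),
    )


class TestInformativeSelection:
    def test_criteria_het_hom_hom(self):
        pos = np.array([10, 20, 30, 40])
        carrier = np.array([HET, HOM_REF, HET, HET])
        spouse = np.array([HOM_REF, HOM_REF, HET, HOM_ALT])
        reference = np.array([HOM_ALT, HOM_ALT, HOM_REF, -1])
        idx = select_informative("chr1", pos, carrier, spouse, reference)
        # site 0: all criteria met; 1: carrier hom; 2: spouse het; 3: ref missing
        assert list(idx) == [0]

    def test_grandparent_phasing_tracks_transmitted_haplotype(self, family, panel):
        chrom = family.spec.chromA
        phased = phase_with_grandparent(
            chrom, panel.positions[chrom], *family_calls(family, panel, chrom)
        )
        assert len(phased) > 5
        hap_t = family.carrier.haplotypes[chrom][HAP_T]
        for snp in phased:
            assert snp.derivative_allele == hap_t[snp.index]
            assert snp.derivative_allele != snp.normal_allele


class TestEmbryoReferencePhasing:
    def test_consistent_with_grandparent_phasing(self, family, genome, panel, rng):
        # an unbalanced embryo with a known retained derivative phases the
        # same derivative alleles as the grandparent route on shared SNPs
        chrom_checked = 0
        for _ in range(6):
            cg = simulate_meiosis(family, genome, panel, rng, mode="adjacent1")
            emb = make_embryo("e", cg, spouse_gamete(family, genome, panel, rng))
            obs = emit_array(family, panel, emb)
            for chrom in (family.spec.chromA, family.spec.chromB):
                carrier_c, spouse_c, grand_c = family_calls(family, panel, chrom)
                via_emb = phase_with_embryo(
                    chrom, panel.positions[chrom], carrier_c, spouse_c,
                    obs.calls[chrom], cg,
                )
                via_grand = {
                    s.index: s.derivative_allele
                    for s in phase_with_grandparent(
                        chrom, panel.positions[chrom], carrier_c, spouse_c, grand_c
                    )
                }
                shared = [s for s in via_emb if s.index in via_grand]
                assert all(s.derivative_allele == via_grand[s.index] for s in shared)
                chrom_checked += len(shared)
        assert chrom_checked > 20

    def test_sites_covered_twice_by_carrier_are_skipped(self, family, genome, panel, rng):
        # adjacent-2 covers one chromosome's proximal region twice (normal +
        # derivative homolog): those sites cannot be phased from the embryo
        cg = simulate_meiosis(family, genome, panel, rng, mode="adjacent2")
        emb = make_embryo("e", cg, spouse_gamete(family, genome, panel, rng))
        obs = emit_array(family, panel, emb)
        for chrom in (family.spec.chromA, family.spec.chromB):
            pieces = [p for p in cg.pieces if p.chrom == chrom]
            phased = phase_with_embryo(
                chrom, panel.positions[chrom],
                family.carrier.genotypes(chrom), family.spouse.genotypes(chrom),
                obs.calls[chrom], cg,
            )
            for snp in phased:
                cover = sum(p.start <= snp.position <= p.end for p in pieces)
                assert cover == 1


class TestRegionCall:
    def make_markers(self, n, derivative_allele=1, spouse_allele=0, start=1_000_000):
        return [
            InformativeSNP("chr1", start + i * 50_000, i, spouse_allele,
                           derivative_allele, 1 - derivative_allele)
            for i in range(n)
        ]

    def test_unanimous_votes_give_verdict(self):
        markers = self.make_markers(18)
        calls = np.full(18, HET)  # spouse 0 + derivative 1 -> het
        rc = region_call(calls, markers, breakpoint=1_400_000, half_width=1_000_000)
        assert rc.verdict == "derivative" and rc.votes_derivative == 18

    def test_tie_is_ambiguous(self):
        markers = self.make_markers(4)
        calls = np.array([HET, HET, HOM_REF, HOM_REF])  # 2 derivative, 2 normal
        rc = region_call(calls, markers, breakpoint=1_100_000)
        assert rc.verdict == "ambiguous"

    def test_below_min_votes_is_ambiguous(self):
        markers = self.make_markers(2)
        rc = region_call(np.full(2, HET), markers, breakpoint=1_025_000)
        assert rc.verdict == "ambiguous" and rc.n_votes == 2

    def test_markers_outside_region_do_not_vote(self):
        markers = self.make_markers(10)
        calls = np.full(10, HET)
        rc = region_call(calls, markers, breakpoint=1_000_000, half_width=100_000)
        assert rc.n_votes == 3  # only sites within ±100 kb

    def test_noise_robustness_with_ten_markers(self):
        # binomial-vote oracle: ado 0.2, miscall 0.01, 10 informative SNPs
        correct = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            markers, calls = [], np.zeros(10, dtype=np.int8)
            for i in range(10):
                s, d = int(rng.integers(2)), int(rng.integers(2))
                markers.append(InformativeSNP("chr1", 1_000_000 + i * 100_000, i, s, d, 1 - d))
                call = HET if s != d else (HOM_REF if s == 0 else HOM_ALT)
                if call == HET and rng.random() < 0.2:  # allele dropout
                    call = HOM_REF if rng.random() < 0.5 else HOM_ALT
                if rng.random() < 0.01:  # miscall
                    call = (call + int(rng.integers(1, 3))) % 3
                calls[i] = call
            rc = region_call(calls, markers, breakpoint=1_500_000, half_width=1_000_000)
            correct += rc.verdict == "derivative"
        assert correct >= 95


class TestRecombinationScan:
    def scan_setup(self, family, panel, chrom):
        return phase_with_grandparent(
            chrom, panel.positions[chrom], *family_calls(family, panel, chrom)
        )

    def embryo_with_crossovers(self, family, genome, panel, rate, seed):
        rng = np.random.default_rng(seed)
        cg = simulate_meiosis(
            family, genome, panel, rng, mode="alternate", crossover_rate_per_mb=rate
        )
        emb = make_embryo("e", cg, spouse_gamete(family, genome, panel, rng))
        return emb, emit_array(family, panel, emb)

    def test_no_events_without_crossovers_or_noise(self, family, genome, panel):
        emb, obs = self.embryo_with_crossovers(family, genome, panel, 0.0, 1)
        for chrom in (family.spec.chromA, family.spec.chromB):
            phased = self.scan_setup(family, panel, chrom)
            assert recombination_scan(obs.calls[chrom], phased) == []

    def test_planted_crossover_recovered_and_not_flagged_far_away(self, family, genome, panel):
        # find a draw whose crossover lands mid-arm with phased markers around
        spec = family.spec
        recovered = 0
        for seed in range(30):
            emb, obs = self.embryo_with_crossovers(family, genome, panel, 0.4, seed)
            for chrom in (spec.chromA, spec.chromB):
                xs = emb.crossovers.get(chrom, [])
                if len(xs) != 1:
                    continue
                phased = self.scan_setup(family, panel, chrom)
                inner = [s for s in phased if abs(s.position - xs[0]) > 1]
                if sum(s.position < xs[0] for s in phased) < 3:
                    continue
                if sum(s.position > xs[0] for s in phased) < 3:
                    continue
                events = recombination_scan(
                    obs.calls[chrom], phased, breakpoints=[10**9]
                )
                assert len(events) == 1
                assert events[0].start <= xs[0] <= events[0].end
                assert not events[0].in_breakpoint_region
                recovered += 1
        assert recovered >= 3

    def test_isolated_discordant_marker_is_rejected_as_noise(self):
        markers = [
            InformativeSNP("chr1", 1_000_000 + i * 100_000, i, 0, 1, 0) for i in range(9)
        ]
        calls = np.full(9, HET)
        calls[4] = HOM_REF  # single opposite call
        assert recombination_scan(calls, markers) == []

    def test_too_few_markers_warns_and_returns_empty(self):
        markers = [InformativeSNP("chr1", 1_000_000, 0, 0, 1, 0)]
        with pytest.warns(UserWarning, match="fewer"):
            assert recombination_scan(np.array([HET]), markers) == []

    def test_flag_requires_straddling_the_breakpoint(self):
        assert recombination_in_breakpoint_region(100, 200, [150])
        assert not recombination_in_breakpoint_region(100, 200, [250])
        # reaching into the flank without crossing the junction does not flag
        assert not recombination_in_breakpoint_region(245_135_196, 249_250_621, [244_573_198])


class TestClassification:
    def rc(self, verdict):
        return RegionCall("chr1", 1, 10**6, 0, 0, 0, verdict)

    def test_double_derivative_balanced_is_carrier(self):
        cls = linkage_classify("e", self.rc("derivative"), self.rc("derivative"), "balanced")
        assert cls.comprehensive == "carrier"

    def test_mixed_verdicts_unbalanced_ccs_is_unbalanced(self):
        cls = linkage_classify("e", self.rc("normal"), self.rc("derivative"), "unbalanced")
        assert cls.comprehensive == "unbalanced"

    def test_mixed_verdicts_balanced_ccs_is_ambiguous_with_warning(self):
        with pytest.warns(UserWarning, match="recombination"):
            cls = linkage_classify("e", self.rc("derivative"), self.rc("normal"), "balanced")
        assert cls.comprehensive == "ambiguous"

    def test_concordance_flag_against_pcr(self):
        cls = linkage_classify(
            "e", self.rc("normal"), self.rc("normal"), "balanced", pcr_class="normal"
        )
        assert cls.concordant is True

    def test_mendelian_error_fraction_zero_at_zero_noise(self, family, genome, panel, rng):
        cg = simulate_meiosis(family, genome, panel, rng, mode="alternate")
        emb = make_embryo("e", cg, spouse_gamete(family, genome, panel, rng))
        obs = emit_array(family, panel, emb)
        chrom = family.spec.chromA
        frac = mendelian_error_fraction(
            family.carrier.genotypes(chrom), family.spouse.genotypes(chrom), obs.calls[chrom]
        )
        assert frac == 0.0
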