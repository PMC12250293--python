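"""Paralog deconvolution: proportion, correction, LOQ, reliability, profile."""

import pytest

from paralogmeth.deconvolution import (
    AnalysisParams,
    ReliabilityTier,
    apply_loq,
    build_profile,
    classify_reliability,
    correct_specific_cpg,
    estimate_paralog_proportion,
)
from paralogmeth.errors import DeconvolutionError
from paralogmeth.pyrogram import simulate_pyrogram
from paralogmeth.synthetic import template_mix


def simulate_sample(duplex_fixture, p_a, methylation, noise_sd=0.0, seed=None):
    pair, truth, config = duplex_fixture
    return [
        simulate_pyrogram(template_mix(pair, w, p_a, methylation), d,
                          noise_sd=noise_sd, seed=seed)
        for w, d in zip(config.windows, config.dispensations)
    ]


class TestApplyLoq:
    @pytest.mark.parametrize("value,expected", [
        (4.00, 2.50),     # at/below LLOQ -> low default
        (5.00, 2.50),
        (96.00, 97.50),   # at/above ULOQ -> high default
        (95.00, 97.50),
        (50.00, 50.00),
        (0.0, 2.50),
        (100.0, 97.50),
    ])
    def test_substitution_rule(self, value, expected):
        assert apply_loq(value) == expected

    def test_idempotent(self):
        for v in (0.0, 4.0, 5.01, 42.0, 94.99, 96.0, 100.0):
            once = apply_loq(v)
            assert apply_loq(once) == once

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_loq(101.0)


class TestClassifyReliability:
    @pytest.mark.parametrize("p,tier", [
        (51.2, ReliabilityTier.SPECIFIC_ONLY),
        (79.99, ReliabilityTier.SPECIFIC_ONLY),
        (80.0, ReliabilityTier.MODERATE),   # boundaries belong to the band
        (85.0, ReliabilityTier.MODERATE),
        (90.0, ReliabilityTier.MODERATE),
        (90.01, ReliabilityTier.FULL),
        (95.0, ReliabilityTier.FULL),
    ])
    def test_tiers(self, p, tier):
        assert classify_reliability(p) is tier


class TestCorrectSpecificCpg:
    @pytest.mark.parametrize("raw,prop,expected", [
        (50.0, 100.0, 50.0),   # identity at pure paralog
        (45.0, 90.0, 50.0),
        (80.0, 80.0, 100.0),
    ])
    def test_formula(self, raw, prop, expected):
        assert correct_specific_cpg(raw, prop) == pytest.approx(expected)

    def test_clipped_at_100(self):
        assert correct_specific_cpg(60.0, 50.0) == 100.0

    def test_zero_proportion_undefined(self):
        with pytest.raises(DeconvolutionError):
            correct_specific_cpg(50.0, 0.0)

    def test_monotone_in_raw_and_antitone_in_proportion(self):
        raws = [10, 30, 50, 70]
        assert [correct_specific_cpg(r, 80.0) for r in raws] == \
            sorted(correct_specific_cpg(r, 80.0) for r in raws)
        props = [95, 80, 60, 40]
        vals = [correct_specific_cpg(30.0, p) for p in props]
        assert vals == sorted(vals)


class TestEstimateProportion:
    def test_recovers_mixing_ratio_exactly_noise_free(
            self, duplex_fixture, duplex_positions):
        params = AnalysisParams(loq_on_markers=False)
        for p in (10, 25, 50, 75, 90):
            pyros = simulate_sample(duplex_fixture, p / 100, 0.5)
            prop = estimate_paralog_proportion(pyros, duplex_positions, params)
            assert prop.p_a == pytest.approx(p, abs=1e-9)
            assert prop.f_marker_a == pytest.approx(p, abs=1e-9)
            assert prop.f_marker_b == pytest.approx(100 - p, abs=1e-9)

    def test_pure_endpoints(self, duplex_fixture, duplex_positions):
        params = AnalysisParams(loq_on_markers=False)
        for p, expected in ((1.0, 100.0), (0.0, 0.0)):
            pyros = simulate_sample(duplex_fixture, p, 1.0)
            prop = estimate_paralog_proportion(pyros, duplex_positions, params)
            assert prop.p_a == pytest.approx(expected, abs=1e-9)

    def test_noise_robustness_over_seeds(self, duplex_fixture, duplex_positions):
        params = AnalysisParams(loq_on_markers=False)
        worst = 0.0
        for seed in range(100):
            pyros = simulate_sample(duplex_fixture, 0.6, 0.5,
                                    noise_sd=0.02, seed=seed)
            prop = estimate_paralog_proportion(pyros, duplex_positions, params)
            worst = max(worst, abs(prop.p_a - 60.0))
        assert worst <= 3.0

    def test_no_marker_positions_is_an_error(self, duplex_fixture,
                                             duplex_positions):
        pyros = simulate_sample(duplex_fixture, 0.5, 0.5)
        cpg_only = [p for p in duplex_positions if p.kind == "cpg"]
        with pytest.raises(DeconvolutionError, match="impossible"):
            estimate_paralog_proportion(pyros, cpg_only)

    def test_marker_loq_substitution_applied_by_default(
            self, duplex_fixture, duplex_positions):
        pyros = simulate_sample(duplex_fixture, 1.0, 1.0)
        prop = estimate_paralog_proportion(pyros, duplex_positions)
        assert prop.p_a == pytest.approx(97.5)      # post-LOQ on fractions
        assert prop.p_a_raw == pytest.approx(100.0)  # raw kept alongside


class TestBuildProfile:
    def test_parameter_recovery_grid_pre_loq(self, duplex_fixture,
                                             duplex_positions):
        """Noiseless corrected values for paralog-specific CpGs equal the
        simulated truth to 1e-6 before LOQ substitution."""
        for p in (20, 40, 60, 80, 95):
            for meth in (0, 25, 50, 75, 100):
                pyros = simulate_sample(duplex_fixture, p / 100, meth / 100)
                prof = build_profile(pyros, duplex_positions)
                assert prof.proportion.p_a_raw == pytest.approx(p, abs=1e-6)
                for r in prof.records:
                    if r.specificity in ("a_specific", "b_specific"):
                        assert r.corrected_raw == pytest.approx(meth, abs=1e-6)
                    elif r.specificity == "shared":
                        assert r.raw == pytest.approx(meth, abs=1e-6)

    def test_pure_methylated_a_standard_reports_loq_defaults(
            self, duplex_fixture, duplex_positions):
        pyros = simulate_sample(duplex_fixture, 1.0, 1.0)
        prof = build_profile(pyros, duplex_positions)
        assert prof.proportion.p_a == pytest.approx(97.5)
        assert prof.reliability is ReliabilityTier.FULL
        for r in prof.records:
            if r.specificity == "b_specific":
                # with zero paralog-B product there is nothing to correct by
                assert r.not_analyzable
            else:
                assert r.corrected == pytest.approx(97.5)

    def test_shared_cpgs_masked_below_full_reliability(
            self, duplex_fixture, duplex_positions):
        # 50/50 duplex standard: shared CpGs are not analyzable, specific
        # CpGs are corrected
        pyros = simulate_sample(duplex_fixture, 0.5, 0.5)
        prof = build_profile(pyros, duplex_positions)
        assert prof.reliability is ReliabilityTier.SPECIFIC_ONLY
        shared = [r for r in prof.records if r.specificity == "shared"]
        specific = [r for r in prof.records
                    if r.specificity in ("a_specific", "b_specific")]
        assert shared and all(r.not_analyzable and r.corrected is None
                              for r in shared)
        assert specific and all(r.corrected is not None for r in specific)

    def test_profile_is_fixed_point_of_loq(self, duplex_fixture,
                                           duplex_positions):
        pyros = simulate_sample(duplex_fixture, 0.9, 0.3)
        prof = build_profile(pyros, duplex_positions)
        for r in prof.records:
            if r.corrected is not None:
                assert apply_loq(r.corrected) == r.corrected

    def test_shift_positions_excluded_by_default(self, duplex_fixture,
                                                 duplex_positions):
        pyros = simulate_sample(duplex_fixture, 0.8, 0.5)
        prof = build_profile(pyros, duplex_positions)
        shift_numbers = {p.cpg_number_a for p in duplex_positions
                        if p.kind == "cpg_shift"}
        profiled = {r.cpg_number_a for r in prof.records}
        assert shift_numbers and not (shift_numbers & profiled)

    def test_single_locus_profile_reports_raw_with_loq(self):
        from paralogmeth.assay import (AssayConfig, Primers,
                                       design_dispensation,
                                       map_dispensation_positions)
        from paralogmeth.pyrogram import DispensationOrder, TemplateMix
        from paralogmeth.sequences import (MethylationPattern,
                                           NucleotideSequence,
                                           bisulfite_convert)
        region = NucleotideSequence(id="prom", bases="GGATTACGATTAGGAACGTAGG")
        conv_m = bisulfite_convert(region, MethylationPattern.methylated())
        conv_u = bisulfite_convert(region, MethylationPattern.unmethylated())
        w = (1, len(region) - 1)
        disp = DispensationOrder(design_dispensation(
            [conv_m.bases[w[0]:w[1]], conv_u.bases[w[0]:w[1]]]))
        config = AssayConfig(name="prom", primers=Primers(None, None, ()),
                             dispensations=(disp,), region=region, windows=(w,))
        positions = map_dispensation_positions(config)
        mix = TemplateMix.from_pairs([
            (conv_m.subsequence(*w), 0.3), (conv_u.subsequence(*w), 0.7)])
        prof = build_profile([simulate_pyrogram(mix, disp)], positions)
        assert prof.proportion is None and prof.reliability is None
        assert [r.raw for r in prof.records] == pytest.approx([30.0, 30.0])
        assert all(r.corrected == pytest.approx(30.0) for r in prof.records)
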