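"""Assay model: discriminating positions, dispensation mapping, validation."""

import pytest

from paralogmeth.assay import (
    A_SPECIFIC,
    B_SPECIFIC,
    CPG_SHIFT,
    AssayConfig,
    ParalogPair,
    Primers,
    design_dispensation,
    discover_discriminating_positions,
    map_dispensation_positions,
    validate_assay,
)
from paralogmeth.errors import AssayConfigError, StallError
from paralogmeth.pyrogram import DispensationOrder
from paralogmeth.sequences import MethylationPattern, NucleotideSequence


def seq(bases, id="s"):
    return NucleotideSequence(id=id, bases=bases)


U = MethylationPattern.unmethylated()
M = MethylationPattern.methylated()


class TestDiscoverDiscriminatingPositions:
    def test_identical_pair_has_none(self):
        pair = ParalogPair(seq("GATTACAGG", "a"), seq("GATTACAGG", "b"))
        assert discover_discriminating_positions(pair, U, U) == []

    def test_single_substitution_found(self):
        pair = ParalogPair(seq("GGAGG", "a"), seq("GGTGG", "b"))
        sites = discover_discriminating_positions(pair, M, M)
        assert len(sites) == 1
        s = sites[0]
        assert (s.offset, s.base_a, s.base_b) == (2, "A", "T")
        assert s.classification == A_SPECIFIC

    def test_new_cpg_in_one_paralog_is_specific_for_it(self):
        pair = ParalogPair(seq("GGAGG", "a"), seq("GGCGG", "b"))
        sites = discover_discriminating_positions(pair, M, M)
        assert [s.classification for s in sites] == [B_SPECIFIC]

    def test_cpg_disruption_visible_only_when_methylated(self):
        # A has a CpG, B carries T: converted sequences differ only for
        # methylated templates
        pair = ParalogPair(seq("GACGAG", "a"), seq("GATGAG", "b"))
        assert discover_discriminating_positions(pair, U, U) == []
        sites = discover_discriminating_positions(pair, M, M)
        assert [(s.offset, s.classification) for s in sites] == [(2, A_SPECIFIC)]

    def test_engineered_preset_classifications(self, duplex_fixture):
        pair, truth, _ = duplex_fixture
        sites = discover_discriminating_positions(pair, M, M)
        by_offset = {s.offset: s.classification for s in sites}
        assert by_offset[truth.marker_a_column] == A_SPECIFIC
        assert by_offset[truth.marker_b_column] == B_SPECIFIC
        for col in truth.disrupted_columns:
            assert by_offset[col] == A_SPECIFIC
        for col in truth.b_new_columns:
            assert by_offset[col] == B_SPECIFIC
        assert any(by_offset.get(c) == CPG_SHIFT for c in truth.shift_columns)

    def test_window_outside_sequence_rejected(self):
        pair = ParalogPair(seq("GGAGG", "a"), seq("GGCGG", "b"))
        with pytest.raises(AssayConfigError):
            discover_discriminating_positions(pair, U, U, window=(0, 99))


class TestDesignDispensation:
    def test_single_read_round_trip(self):
        read = "GATTACA"
        disp = design_dispensation([read])
        from paralogmeth.pyrogram import template_walk
        _, _, consumed = template_walk(read, disp)
        assert consumed == len(read)

    def test_ensemble_fully_consumed(self, duplex_fixture):
        pair, truth, config = duplex_fixture
        from paralogmeth.pyrogram import template_walk
        from paralogmeth.sequences import bisulfite_convert
        for (w0, w1), disp in zip(config.windows, config.dispensations):
            for pattern in (M, U):
                for p in (pair.paralog_a, pair.paralog_b):
                    read = bisulfite_convert(p, pattern).bases[w0:w1]
                    _, _, consumed = template_walk(read, disp.nucleotides)
                    assert consumed == len(read)


class TestMapDispensationPositions:
    def test_region_without_cpgs_has_no_variable_positions(self):
        region = seq("GATTAGATTAGGATTA" * 3, "r")
        disp = DispensationOrder(design_dispensation([region.bases[2:30]]))
        config = AssayConfig(name="toy", primers=Primers(None, None, ()),
                             dispensations=(disp,), region=region,
                             windows=((2, 30),))
        assert map_dispensation_positions(config) == ()

    def test_toy_single_cpg_mapped_with_ct_slots(self):
        region = seq("GGATTACGATTAGG", "r")  # one CpG at index 6
        disp = DispensationOrder("GATTACTGATTAGG")
        config = AssayConfig(name="toy", primers=Primers(None, None, ()),
                             dispensations=(disp,), region=region,
                             windows=((1, 14),))
        positions = map_dispensation_positions(config)
        assert len(positions) == 1
        pos = positions[0]
        assert pos.kind == "cpg" and pos.cpg_number_a == 1
        # C dispensed at slot 5, T (converted) at slot 6
        assert pos.dispensation_indices == {"variant": (5,), "reference": (6,)}

    def test_deterministic(self, duplex_fixture):
        _, _, config = duplex_fixture
        assert map_dispensation_positions(config) == \
            map_dispensation_positions(config)

    def test_preset_marker_and_cpg_counts(self, duplex_fixture, duplex_positions):
        pair, truth, _ = duplex_fixture
        markers = [p for p in duplex_positions if p.kind == "paralog_marker"]
        assert {m.marker_for for m in markers} == {"a", "b"}
        a_specific = [p for p in duplex_positions
                      if p.kind == "cpg" and p.specificity == "a_specific"]
        assert sorted(p.cpg_number_a for p in a_specific) == \
            sorted(truth.disrupted_ordinals)
        shifts = [p for p in duplex_positions if p.kind == "cpg_shift"]
        assert len(shifts) == 1

    def test_every_sequenced_discriminating_column_is_mapped(
            self, duplex_fixture, duplex_positions):
        pair, truth, config = duplex_fixture
        mapped_cols = set()
        for p in duplex_positions:
            if p.column is not None:
                mapped_cols.add(p.column)
        sites = discover_discriminating_positions(pair, M, M)
        windowed = [s for s in sites
                    if any(w0 <= s.offset < w1 for w0, w1 in config.windows)]
        for s in windowed:
            assert any(abs(s.offset - c) <= 2 for c in mapped_cols), \
                f"column {s.offset} missing from the variable-position map"

    def test_stalling_dispensation_reported(self, duplex_fixture):
        _, _, config = duplex_fixture
        from dataclasses import replace
        bad = replace(config, dispensations=(DispensationOrder("ACGT"),) * 2)
        with pytest.raises(StallError, match="stalls"):
            map_dispensation_positions(bad)


class TestValidateAssay:
    def test_preset_assay_passes(self, duplex_fixture):
        _, _, config = duplex_fixture
        report = validate_assay(config)
        assert report.ok, [c.name for c in report.failures]

    def test_reverse_primer_mismatch_counts_match_engineering(self, duplex_fixture):
        """The engineered pair mirrors the published mispriming pattern:
        one mismatch on unmethylated, three on methylated paralog-B."""
        pair, truth, config = duplex_fixture
        from paralogmeth.sequences import bisulfite_convert, match_primer
        rev = config.primers.reverse
        for pattern, expected in ((U, 1), (M, 3)):
            conv = bisulfite_convert(pair.paralog_b, pattern)
            hits = match_primer(rev, conv, "-", max_mismatch=3)
            assert hits[0].mismatch_count == expected

    def test_missing_sequencing_primer_is_soft_failure(self, duplex_fixture):
        _, _, config = duplex_fixture
        from dataclasses import replace
        broken = replace(config, primers=Primers(config.primers.forward,
                                                 config.primers.reverse, ()))
        report = validate_assay(broken)
        assert not report.ok
        assert any(c.name == "sequencing_primer_present"
                   for c in report.failures)

    def test_single_region_skips_marker_checks(self):
        region = seq("GGATTACGATTAGG", "r")
        config = AssayConfig(name="prom", primers=Primers(None, None, ()),
                             dispensations=(), region=region)
        report = validate_assay(config)
        assert not any("marker" in c.name for c in report.checks)

    def test_identical_pair_flagged_deconvolution_impossible(self):
        """A pair with zero post-conversion differences must yield no marker
        positions, so validation reports deconvolution as impossible."""
        from paralogmeth.synthetic import build_assay, generate_paralog_pair
        pair, truth = generate_paralog_pair(
            seed=3, length=120, target_identity_percent=100.0, n_cpgs=4,
            n_markers_per_paralog=0, n_seq_primers=1)
        assert pair.paralog_a.bases == pair.paralog_b.bases
        config = build_assay(pair, truth)
        report = validate_assay(config)
        assert any(c.name.startswith("marker_present") and not c.passed
                   for c in report.checks)


class TestBuiltinConfigs:
    def test_published_assays_load_with_dispensations(self):
        from paralogmeth.io import builtin_config
        prom = builtin_config("promoter")
        exon2 = builtin_config("exon2")
        assert len(prom.dispensations) == 1
        assert len(exon2.dispensations) == 2
        assert len(exon2.primers.sequencing) == 2
        # ingest strips hyphenation artifacts: orders are pure ACGT
        for cfg in (prom, exon2):
            for d in cfg.dispensations:
                assert set(d.nucleotides) <= set("ACGT")

    def test_builtin_validation_skips_sequence_checks(self):
        from paralogmeth.io import builtin_config
        report = validate_assay(builtin_config("promoter"))
        assert any(c.name == "template_sequences_attached" for c in report.checks)
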