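"""Retrieval-signal extraction, motif matrices and abundance summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kdelquant import proteomics as pt
from kdelquant import synthetic as sy


def rec(seq, id="p", abundance=1.0, unit="uM"):
    return pt.ProteinRecord(id=id, sequence=seq, abundance=abundance, unit=unit)


class TestExtraction:
    @pytest.mark.parametrize(
        "seq,L,tetra,variant,canonical,window",
        [
            ("MKKSDEKDEL", 6, "KDEL", "K", True, "DEKDEL"),
            ("MAAAAAAHEEL", 4, "HEEL", "H", False, "HEEL"),
            ("MAAAAAAADEL", 4, "ADEL", "A", True, "ADEL"),
            ("MAAAAAAKDEV", 4, "KDEV", "K", False, "KDEV"),
        ],
    )
    def test_terminal_signal(self, seq, L, tetra, variant, canonical, window):
        s = pt.extract_terminal_signal(rec(seq), window_length=L)
        assert (s.tetrapeptide, s.variant, s.canonical, s.window) == (
            tetra, variant, canonical, window,
        )

    def test_extended_suffix_set_accepts_heel(self):
        s = pt.extract_terminal_signal(
            rec("MAAAAAAHEEL"), 4, suffixes=pt.EXTENDED_SUFFIXES
        )
        assert s.canonical and s.variant == "H"

    def test_short_sequence_raises_length_error(self):
        with pytest.raises(pt.SequenceLengthError):
            pt.extract_terminal_signal(rec("KDEL"), window_length=6)

    def test_illegal_characters_rejected_at_construction(self):
        with pytest.raises(pt.SequenceValidationError):
            rec("MKKSDEKD3L")

    def test_empty_sequence_rejected(self):
        with pytest.raises(pt.SequenceValidationError):
            rec("")


class TestClassify:
    def test_counts_partition_canonical_variants(self):
        records = [rec("MAAKDEL", "a"), rec("MAAHDEL", "b"), rec("MAARDEL", "c")]
        _, counts = pt.classify_proteome(records, window_length=4)
        assert counts == {"K": 1, "H": 1, "R": 1}

    def test_non_canonical_excluded_from_counts(self):
        records = [rec("MAAKDEV", "a"), rec("MAAKDEL", "b")]
        sigs, counts = pt.classify_proteome(records, window_length=4)
        assert counts == {"K": 1}
        assert [s.canonical for s in sigs] == [False, True]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            pt.classify_proteome([], 4)

    def test_counts_invariant_to_record_order(self):
        records, _ = sy.gen_proteome(sy.GeneratorConfig(seed=5, n_proteins=60))
        _, fwd = pt.classify_proteome(records)
        _, rev = pt.classify_proteome(records[::-1])
        assert fwd == rev

    def test_planted_frequencies_recovered_within_binomial_error(self):
        # oracle: the generator's planted labels
        cfg = sy.GeneratorConfig(seed=11, n_proteins=300)
        records, manifest = sy.gen_proteome(cfg)
        _, counts = pt.classify_proteome(records)
        for v in ("K", "H", "R"):
            assert counts[v] == manifest["planted_counts"][v]
            n, p = cfg.n_proteins, cfg.variant_frequencies[v]
            assert abs(counts[v] - n * p) <= 3 * math.sqrt(n * p * (1 - p))


class TestMotifMatrix:
    def test_single_signal_is_one_hot_with_max_information(self):
        s = pt.extract_terminal_signal(rec("AAAAKDEL"), 4)
        m = pt.motif_matrix([s])
        assert np.allclose(m.probabilities.sum(axis=0), 1.0)
        assert np.allclose(m.information_content, math.log2(20))
        assert m.to_frame().loc["K", -4] == 1.0

    def test_abundance_weighted_column(self):
        # hand-computed: weights 5 and 1 give p(K) = 5/6 at position -4
        sigs = [
            pt.extract_terminal_signal(rec("AAAAKDEL", "k"), 4),
            pt.extract_terminal_signal(rec("AAAAHDEL", "h"), 4),
        ]
        m = pt.motif_matrix(sigs, weights={"k": 5.0, "h": 1.0}, mode="abundance")
        f = m.to_frame()
        assert f.loc["K", -4] == pytest.approx(5 / 6)
        assert f.loc["H", -4] == pytest.approx(1 / 6)

    def test_uniform_column_has_zero_information(self):
        sigs = [
            pt.extract_terminal_signal(rec("AAAA" + aa + "DEL", aa), 4)
            for aa in pt.AMINO_ACIDS
        ]
        m = pt.motif_matrix(sigs)
        assert m.information_content[0] == pytest.approx(0.0, abs=1e-12)
        assert m.information_content[1] == pytest.approx(math.log2(20))

    def test_all_zero_weights_degenerate(self):
        sigs = [pt.extract_terminal_signal(rec("AAAAKDEL", "k"), 4)]
        with pytest.raises(pt.DegenerateWeightError):
            pt.motif_matrix(sigs, weights={"k": 0.0}, mode="abundance")

    def test_missing_weight_names_record(self):
        sigs = [pt.extract_terminal_signal(rec("AAAAKDEL", "k"), 4)]
        with pytest.raises(pt.MissingWeightError, match="k"):
            pt.motif_matrix(sigs, weights={}, mode="abundance")

    def test_x_residue_keeps_denominator_mass(self):
        sigs = [
            pt.extract_terminal_signal(rec("AAAXKDEL", "a"), 5),
            pt.extract_terminal_signal(rec("AAAAKDEL", "b"), 5),
        ]
        m = pt.motif_matrix(sigs)
        # position -5: one X, one A -> p(A) = 1/2, column sums to 1/2
        assert m.probabilities[:, 0].sum() == pytest.approx(0.5)
        assert m.to_frame().loc["A", -5] == pytest.approx(0.5)

    @given(
        st.lists(
            st.tuples(
                st.text(alphabet=pt.AMINO_ACIDS, min_size=6, max_size=6),
                st.floats(min_value=0.1, max_value=10.0),
            ),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_frequency_equals_abundance_with_equal_weights(self, items):
        sigs = [
            pt.extract_terminal_signal(rec("AA" + s, f"r{i}"), 6)
            for i, (s, _) in enumerate(items)
        ]
        freq = pt.motif_matrix(sigs, mode="frequency")
        const = pt.motif_matrix(
            sigs, weights={f"r{i}": 2.5 for i in range(len(items))}, mode="abundance"
        )
        assert np.allclose(freq.probabilities, const.probabilities)
        assert np.all(freq.information_content >= -1e-12)
        assert np.all(freq.information_content <= math.log2(20) + 1e-12)
        assert np.allclose(freq.probabilities.sum(axis=0), 1.0)


class TestAbundanceSummary:
    def test_simple_ratio(self):
        records = [rec("MAAKDEL", "a", 10.0), rec("MAAHDEL", "b", 2.0)]
        sigs, _ = pt.classify_proteome(records, 4)
        s = pt.abundance_summary(sigs, records, ratio_pairs=[("K", "H")])
        assert s.totals == {"K": 10.0, "H": 2.0}
        assert s.ratios[("K", "H")] == pytest.approx(5.0)

    def test_planted_total_ratio_recovered_exactly(self):
        cfg = sy.GeneratorConfig(seed=2, n_proteins=200, abundance_ratio_k_h=5.5)
        records, manifest = sy.gen_proteome(cfg)
        sigs, _ = pt.classify_proteome(records)
        s = pt.abundance_summary(sigs, records, ratio_pairs=[("K", "H")])
        assert s.ratios[("K", "H")] == pytest.approx(5.5, rel=1e-12)
        assert s.totals["K"] == pytest.approx(manifest["planted_totals"]["K"])

    def test_empty_variant_flagged_not_computed(self):
        records = [rec("MAAKDEL", "a", 10.0)]
        sigs, _ = pt.classify_proteome(records, 4)
        s = pt.abundance_summary(sigs, records, ratio_pairs=[("K", "H")])
        assert ("K", "H") in s.undefined_ratios
        assert ("K", "H") not in s.ratios

    def test_mixed_units_raise(self):
        records = [
            rec("MAAKDEL", "a", 10.0, unit="uM"),
            rec("MAAHDEL", "b", 2.0, unit="copies"),
        ]
        sigs, _ = pt.classify_proteome(records, 4)
        with pytest.raises(pt.UnitMismatchError):
            pt.abundance_summary(sigs, records)


def test_fasta_round_trip(tmp_path):
    cfg = sy.GeneratorConfig(seed=7, n_proteins=40)
    records, _ = sy.gen_proteome(cfg, out_dir=tmp_path)
    loaded = pt.read_proteome(tmp_path / "proteome.fasta", tmp_path / "abundance.tsv")
    assert [r.id for r in loaded] == [r.id for r in records]
    assert [r.sequence for r in loaded] == [r.sequence for r in records]
    assert np.allclose([r.abundance for r in loaded], [r.abundance for r in records])
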