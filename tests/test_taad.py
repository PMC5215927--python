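"""9aaTAD layer: default pattern, context extension, background statistics."""

import itertools
import math

import pytest

from taadscan import (
    BackgroundModel,
    ExtensionPolicy,
    RefinementCriterion,
    default_pattern,
    empirical_match_rate,
    generate_synthetic,
    parse_pattern,
    scan,
    scan_9aatad,
    window_match_probability,
)
from taadscan.taad import RESIDUE_ORDER

from conftest import oracle_window_ok


class TestDefaultPattern:
    def test_position_classes_as_printed(self):
        pattern = default_pattern()
        assert len(pattern) == 9
        kinds = [p.kind for p in pattern]
        assert kinds == ["inclusion", "exclusion", "inclusion", "exclusion",
                         "exclusion", "exclusion", "inclusion", "exclusion",
                         "exclusion"]
        assert pattern.positions[4].residues == frozenset("CGP")
        assert pattern.positions[6].residues == frozenset("ILVFWM")

    def test_cached_instance_is_stable(self):
        assert default_pattern() is default_pattern()


class TestExtension:
    def test_interior_match_extends_to_fourteen(self):
        matches = scan_9aatad("GMFNTTTMDDVYNYLFDDEDT")
        assert len(matches) == 1
        m = matches[0]
        assert (m.core_start, m.core_end) == (9, 17)
        assert (m.ext_start, m.ext_end) == (5, 18)
        assert m.ext_end - m.ext_start + 1 == 14
        assert m.ext_peptide == "TTTMDDVYNYLFDD"
        assert m.annotations["full_context"] is True

    def test_clipping_at_both_sequence_ends(self):
        matches = scan_9aatad("DDVYNYLFD")
        assert len(matches) == 1
        m = matches[0]
        assert (m.ext_start, m.ext_end) == (1, 9)
        assert m.ext_peptide == "DDVYNYLFD"
        assert m.annotations["full_context"] is False

    @pytest.mark.parametrize("up, down", [(0, 0), (2, 1), (4, 1), (10, 10)])
    def test_extended_length_is_min_of_rule_and_span(self, up, down):
        seq = "GMFNTTTMDDVYNYLFDDEDT"
        policy = ExtensionPolicy(upstream=up, downstream=down)
        (m,) = scan_9aatad(seq, policy=policy)
        expected = min(len(seq), m.core_end + down) - max(1, m.core_start - up) + 1
        length = m.ext_end - m.ext_start + 1
        assert length == expected
        assert length <= 9 + up + down

    def test_negative_extension_rejected(self):
        with pytest.raises(ValueError):
            ExtensionPolicy(upstream=-1)

    def test_annotations_acidic_and_hydrophobic(self):
        (m,) = scan_9aatad("DDVYNYLFD")
        assert m.annotations["acidic_count"] == 3  # D, D, D
        assert m.annotations["hydrophobic_cluster"] == ("V", "L")

    def test_no_match_for_artifact_peptide(self):
        assert scan_9aatad("RVWNHYRDV") == []


class TestCriteriaHook:
    def test_empty_criteria_equal_raw_scan(self):
        seqs = [r.residues for r in generate_synthetic(30, 150, seed=3)]
        for seq in seqs:
            cores = [(m.core_start, m.core_peptide) for m in scan_9aatad(seq)]
            raw = [(m.core_start, m.core_peptide)
                   for m in scan(seq, default_pattern())]
            assert cores == raw

    def test_criteria_filter_in_order(self):
        reject_all = RefinementCriterion("reject", lambda m, s: (False, "no"))
        accept_all = RefinementCriterion("accept", lambda m, s: (True, "ok"))
        seq = "GMFNTTTMDDVYNYLFDDEDT"
        assert scan_9aatad(seq, criteria=[accept_all]) == scan_9aatad(seq)
        assert scan_9aatad(seq, criteria=[accept_all, reject_all]) == []


class TestImplantRecovery:
    def test_implanted_core_always_found_at_offset(self):
        for seed in range(10):
            (rec,) = generate_synthetic(
                1, 80, implant=("DDVYNYLFD", 31), seed=seed
            )
            starts = [m.core_start for m in scan_9aatad(rec.residues)]
            assert 31 in starts


class TestBackgroundModel:
    def test_uniform_frequencies(self):
        model = BackgroundModel.uniform()
        assert math.isclose(sum(model.frequencies.values()), 1.0)
        assert all(math.isclose(v, 0.05) for v in model.frequencies.values())

    def test_composition_from_sequences(self):
        model = BackgroundModel.from_sequences(["AAAC", "CG"])
        assert math.isclose(model.frequencies["A"], 3 / 6)
        assert math.isclose(model.frequencies["C"], 2 / 6)
        assert math.isclose(model.frequencies["G"], 1 / 6)
        assert model.frequencies["W"] == 0.0

    def test_invalid_frequencies_rejected(self):
        freqs = {r: 0.05 for r in RESIDUE_ORDER}
        freqs["A"] = 0.5
        with pytest.raises(ValueError):
            BackgroundModel("composition", freqs)


class TestWindowProbability:
    def test_certain_match_single_position(self):
        pattern = parse_pattern("[ACDEFGHIKLMNPQRSTVWY]")
        assert window_match_probability(BackgroundModel.uniform(), pattern) == 1.0

    def test_uniform_default_pattern_closed_form(self):
        prob = window_match_probability(BackgroundModel.uniform())
        expected = (9 * 14 * 6 * 14 * 17 * 17 * 6 * 17 * 17) / 20**9
        assert math.isclose(prob, expected, rel_tol=1e-12)

    def test_zero_mass_on_required_class_gives_zero(self):
        hydrophobic = set("ILVFWM")
        rest = [r for r in RESIDUE_ORDER if r not in hydrophobic]
        freqs = {r: (1 / len(rest) if r in rest else 0.0) for r in RESIDUE_ORDER}
        model = BackgroundModel("composition", freqs)
        assert window_match_probability(model) == 0.0

    def test_closed_form_agrees_with_exhaustive_enumeration(self):
        # Reduced 4-letter analogue: enumerate every window exactly.
        alphabet = "ADLS"
        pattern = parse_pattern("[AD] {L} [LS] {A}")
        constraints = [("in", set("AD")), ("out", set("L")),
                       ("in", set("LS")), ("out", set("A"))]
        n_match = sum(
            oracle_window_ok("".join(w), constraints)
            for w in itertools.product(alphabet, repeat=4)
        )
        freqs = {r: (0.25 if r in alphabet else 0.0) for r in RESIDUE_ORDER}
        model = BackgroundModel("composition", freqs)
        assert math.isclose(
            window_match_probability(model, pattern),
            n_match / 4**4,
            rel_tol=1e-12,
        )


class TestEmpiricalRate:
    def test_rate_within_three_binomial_se(self):
        model = BackgroundModel.uniform()
        p = window_match_probability(model)
        n = 100_000
        rate = empirical_match_rate(model, n_windows=n, seed=42)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(rate - p) <= 3 * se

    def test_deterministic_for_fixed_seed(self):
        model = BackgroundModel.uniform()
        assert empirical_match_rate(model, n_windows=5000, seed=9) == \
            empirical_match_rate(model, n_windows=5000, seed=9)

    def test_single_window_rate_is_zero_or_one(self):
        model = BackgroundModel.uniform()
        assert empirical_match_rate(model, n_windows=1, seed=3) in (0.0, 1.0)

    def test_impossible_class_rate_is_zero(self):
        freqs = {r: (1.0 if r == "D" else 0.0) for r in RESIDUE_ORDER}
        model = BackgroundModel("composition", freqs)
        assert empirical_match_rate(model, n_windows=2000, seed=0) == 0.0
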