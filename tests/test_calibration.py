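import itertools
import math

import numpy as np
import pytest

from sptax.calibration import (
    ErrorModel,
    _mutate_sequence,
    error_shift_check,
    evaluate_specificity,
    inequality_probability,
    inject_errors,
    match_to_reference,
    pairs_from_taxonomy,
)
from sptax.io_formats import RegionAnnotation, RegionInterval, SPRecord, SPTable
from sptax.synthetic import reverse_translate, simulate_annotated_genome
from sptax.taxa_count import AnchoredSequence

SP = SPRecord("FYALPQAPQ", "6.1.1.12")


class TestInequalityProbability:
    def test_identical_proteins_zero(self):
        res = inequality_probability([("MKLVW" * 4, "MKLVW" * 4)], W=5)
        assert res.p_ine == 0.0

    def test_disjoint_alphabets_one(self):
        res = inequality_probability([("AAAAA", "WWWWWWW")], W=3)
        assert res.p_ine == 1.0

    def test_enumerated_example(self):
        # windows of "ACDE" at W=2: {AC, CD, DE}; "WACDW" contains AC, CD
        res = inequality_probability([("ACDE", "WACDW")], W=2)
        assert (res.n_dif, res.sigma) == (1, 3)
        assert res.p_ine == pytest.approx(1 / 3)

    def test_short_pair_skipped(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            res = inequality_probability(
                [("AC", "WACDW"), ("ACDE", "WACDW")], W=3
            )
        assert "skipping" in caplog.text
        assert res.sigma == 2  # only the second pair contributes

    def test_all_pairs_too_short_raises(self):
        with pytest.raises(ValueError):
            inequality_probability([("AC", "ACDE")], W=5)

    def test_orientation_irrelevant(self):
        a, b = "ACDE", "WACDW"
        assert (
            inequality_probability([(a, b)], 2).p_ine
            == inequality_probability([(b, a)], 2).p_ine
        )

    def test_no_match_indicator_monotone_in_w(self):
        # for a fixed window start, no-match at W implies no-match at W+1
        rng = np.random.default_rng(0)
        alphabet = "ACDE"
        for _ in range(20):
            shorter = "".join(rng.choice(list(alphabet), size=12))
            longer = "".join(rng.choice(list(alphabet), size=30))
            for start in range(len(shorter)):
                prev = False
                for W in range(1, len(shorter) - start + 1):
                    window = shorter[start : start + W]
                    missing = longer.find(window) < 0
                    assert missing or not prev  # no-match is monotone in W
                    prev = missing


def test_pairs_from_taxonomy():
    proteins = [
        ("AAA", ("F1", "G1")),
        ("CCC", ("F1", "G2")),
        ("DDD", ("F2", "G3")),
    ]
    pairs = pairs_from_taxonomy(proteins, higher=0, lower=1)
    assert pairs == [("AAA", "CCC")]


class TestInjectErrors:
    def _seqs(self, n=5, length=40):
        seq = "MK" + SP.peptide + "W" * (length - 11)
        return [AnchoredSequence(f"r{i}", seq, 2) for i in range(n)]

    def test_zero_rate_identity(self):
        seqs = self._seqs()
        out = inject_errors(seqs, ErrorModel(p=0.0, seed=1), sp_length=SP.length)
        assert out.sequences == seqs
        assert out.n_dropped == 0 and out.n_substitutions == 0

    def test_rate_one_every_residue_differs(self):
        rng = np.random.default_rng(0)
        original = "MKFYALPQAPQWWW"
        mutated = _mutate_sequence(original, 1.0, rng)
        assert all(a != b for a, b in zip(original, mutated))

    def test_rate_one_drops_everything(self):
        out = inject_errors(
            self._seqs(), ErrorModel(p=1.0, seed=1), sp_length=SP.length
        )
        assert out.sequences == [] and out.n_dropped == 5

    def test_binomial_substitution_count(self):
        # 10^5 residues at p=0.01: within 4 sigma of 1000
        seqs = [
            AnchoredSequence(f"r{i}", "A" * 100, 0) for i in range(1000)
        ]
        out = inject_errors(seqs, ErrorModel(p=0.01, seed=7), sp_length=0)
        sigma = math.sqrt(1e5 * 0.01 * 0.99)
        assert abs(out.n_substitutions - 1000) < 4 * sigma

    def test_anchors_preserved(self):
        out = inject_errors(
            self._seqs(), ErrorModel(p=0.5, seed=3), sp_length=SP.length
        )
        for s in out.sequences:
            assert s.anchor == 2
            assert s.sequence[2 : 2 + SP.length] == SP.peptide

    def test_drop_rate_matches_expectation(self):
        # P(marker untouched) = (1-p)^L
        seqs = self._seqs(n=2000)
        p = 0.05
        out = inject_errors(seqs, ErrorModel(p=p, seed=11), sp_length=SP.length)
        expected = 2000 * (1 - (1 - p) ** SP.length)
        sigma = math.sqrt(2000 * 0.35 * 0.65)
        assert abs(out.n_dropped - expected) < 4 * sigma

    def test_bit_reproducible(self):
        seqs = self._seqs()
        a = inject_errors(seqs, ErrorModel(p=0.3, seed=5), sp_length=SP.length)
        b = inject_errors(seqs, ErrorModel(p=0.3, seed=5), sp_length=SP.length)
        assert a.sequences == b.sequences

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            ErrorModel(p=1.5)


class TestErrorShiftCheck:
    def _seqs(self):
        base = "MK" + SP.peptide + "WDEFGHIKLMNPQRST"
        variants = []
        for i, c in enumerate("ACDEF"):
            seq = base[:12] + c * 8 + base[20:]
            variants.append(AnchoredSequence(f"t{i}", seq, 2))
        return variants

    def test_zero_rate_shift_is_curve_difference(self):
        seqs = self._seqs()
        df = error_shift_check(seqs, ErrorModel(p=0.0, seed=1), d_max=4,
                               sp_length=SP.length)
        for _, row in df.iterrows():
            d = int(row["d"])
            if d + 1 <= 4:
                expected = (
                    df.loc[df["d"] == d + 1, "count_original"].iloc[0]
                    - row["count_original"]
                )
                assert row["shift"] == expected
            else:
                assert math.isnan(row["shift"])

    def test_single_sequence_degenerate(self):
        df = error_shift_check(
            [AnchoredSequence("a", "MK" + SP.peptide + "W", 2)],
            ErrorModel(p=0.0, seed=1), d_max=2, sp_length=SP.length,
        )
        assert (df["count_original"] == 1).all()


class TestEvaluateSpecificity:
    def test_planted_ground_truth(self):
        protein = "MKLV" + SP.peptide + "WDEG"
        genes = [
            (protein, SP.ec),
            (protein, SP.ec),
            (protein, SP.ec),
            (protein, "1.1.1.1"),  # mismatching EC -> FP
        ]
        genome, ann = simulate_annotated_genome(genes, spacer_length=60, seed=4)
        table = SPTable(records=[SP], min_length=9)
        result = evaluate_specificity(genome, ann, table)
        row = result.table.loc[SP.length]
        assert row["TP"] == 3
        assert row["FP"] == 1
        assert row["error"] == pytest.approx(0.25)
        assert row["EFP"] == 0

    def test_random_intergenic_hits_rare(self):
        rng = np.random.default_rng(0)
        genome = "".join("ACGT"[i] for i in rng.integers(4, size=100_000))
        ann = RegionAnnotation(
            intervals=[RegionInterval("genome", 0, 100_000, "intergenic")]
        )
        table = SPTable(records=[SP], min_length=9)
        result = evaluate_specificity(genome, ann, table)
        total = int(result.table["intergenic"].sum()) if len(result.table) else 0
        assert total == 0  # P(random 9-mer hit) ~ 6e5 * 20^-9 << 1

    def test_equal_lengths_efp_is_raw_count(self):
        rng = np.random.default_rng(1)
        nt = reverse_translate("W" + SP.peptide + "W", rng)
        pad = "".join("ACGT"[i] for i in rng.integers(4, size=len(nt)))
        genome = nt + pad
        ann = RegionAnnotation(
            intervals=[
                RegionInterval("genome", 0, len(nt), "intergenic"),
                RegionInterval("genome", len(nt), 2 * len(nt), "genic", SP.ec),
            ]
        )
        table = SPTable(records=[SP], min_length=9)
        result = evaluate_specificity(genome, ann, table)
        assert result.genic_length == result.intergenic_length
        row = result.table.loc[SP.length]
        assert row["EFP"] == row["intergenic"] == 1

    def test_uncovered_hit_warned_unclassified(self, caplog):
        import logging

        rng = np.random.default_rng(2)
        genome = reverse_translate("W" + SP.peptide + "W", rng)
        ann = RegionAnnotation(intervals=[])
        table = SPTable(records=[SP], min_length=9)
        with caplog.at_level(logging.WARNING):
            result = evaluate_specificity(genome, ann, table)
        assert result.unclassified >= 1
        assert "not covered" in caplog.text

    def test_classification_partition(self):
        protein = "MKLV" + SP.peptide + "WDEG"
        genome, ann = simulate_annotated_genome(
            [(protein, SP.ec)], spacer_length=50, seed=9
        )
        table = SPTable(records=[SP], min_length=9)
        result = evaluate_specificity(genome, ann, table)
        total_genic = int(result.table[["FP", "TP"]].sum().sum())
        assert total_genic + result.unclassified >= 1


class TestMatchToReference:
    QUERY = "DEFG" + SP.peptide + "KLMNP"

    def _queries(self, seqs):
        return [
            AnchoredSequence(f"q{i}", s, s.index(SP.peptide))
            for i, s in enumerate(seqs)
        ]

    def test_verbatim_queries_match_at_zero(self):
        ref = ["WWWW" + self.QUERY + "WWWW"]
        profile = match_to_reference(
            self._queries([self.QUERY]), ref, k_max=3, sp=SP.peptide
        )
        assert profile[0] == 1.0

    def test_disjoint_flanks_never_match(self):
        # reference shares only the marker; flanks differ everywhere
        ref = ["WWWW" + SP.peptide + "WWWWW"]
        q = self._queries([self.QUERY])
        profile = match_to_reference(q, ref, k_max=5, sp=SP.peptide)
        assert all(profile[k] == 0.0 for k in range(6))  # 9 flank mismatches

    def test_planted_single_mismatch(self):
        mutated = "A" + self.QUERY[1:]
        profile = match_to_reference(
            self._queries([mutated]), [self.QUERY], k_max=2, sp=SP.peptide
        )
        assert profile[0] == 0.0
        assert profile[1] == 1.0

    def test_profile_nondecreasing(self):
        rng = np.random.default_rng(8)
        refs = []
        for _ in range(4):
            flanks = "".join(rng.choice(list("ACDEFGHIKL"), size=10))
            refs.append(flanks[:5] + SP.peptide + flanks[5:])
        queries = self._queries(
            ["DE" + SP.peptide + "KLMNP", "AC" + SP.peptide + "GHIKL"]
        )
        profile = match_to_reference(queries, refs, k_max=8, sp=SP.peptide)
        values = [profile[k] for k in range(9)]
        assert values == sorted(values)
        assert all(0.0 <= v <= 1.0 for v in values)

    def test_free_offset_mode(self):
        ref = ["WWWW" + self.QUERY + "WWWW"]
        profile = match_to_reference(
            self._queries([self.QUERY]), ref, k_max=1, free_offset=True
        )
        assert profile[0] == 1.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            match_to_reference(self._queries([self.QUERY]), [], 2, sp=SP.peptide)
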