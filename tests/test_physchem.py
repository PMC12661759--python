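"""Digest, MW/GRAVY/pI and distribution comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from csfbench.physchem import (
    WATER_MONO,
    compare_distributions,
    digest,
    isoelectric_point,
    net_charge,
    peptide_properties,
    reference_distribution,
)


def digest_oracle(sequence, max_missed, proline_rule):
    """Brute-force cut-set enumeration, independent of the implementation."""
    cut_after = [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR"
        and not (proline_rule and sequence[i + 1] == "P")
    ]
    boundaries = [0] + [i + 1 for i in cut_after] + [len(sequence)]
    products = set()
    for a, b in itertools.combinations(range(len(boundaries)), 2):
        missed = b - a - 1
        if missed <= max_missed:
            products.add((boundaries[a], boundaries[b], missed))
    return sorted(products)


class TestDigest:
    def test_spec_examples(self):
        assert [p.sequence for p in digest("GKGRGG", max_missed=0)] == [
            "GK",
            "GR",
            "GG",
        ]
        assert [p.sequence for p in digest("GKPGG", max_missed=0)] == ["GKPGG"]
        assert [
            p.sequence for p in digest("GKPGG", max_missed=0, proline_rule=False)
        ] == ["GK", "PGG"]
        assert [p.sequence for p in digest("GGG", max_missed=2)] == ["GGG"]

    @pytest.mark.parametrize("max_missed", [0, 1, 2])
    @pytest.mark.parametrize("proline_rule", [True, False])
    def test_matches_cut_set_oracle_exhaustively(self, max_missed, proline_rule):
        """Every sequence over {G,K,R,P} up to length 7, both rule settings."""
        for length in range(1, 8):
            for letters in itertools.product("GKRP", repeat=length):
                seq = "".join(letters)
                ours = sorted(
                    (p.start - 1, p.end, p.missed_cleavages)
                    for p in digest(seq, max_missed=max_missed,
                                    proline_rule=proline_rule)
                )
                assert ours == digest_oracle(seq, max_missed, proline_rule), seq

    def test_matches_oracle_on_random_long_sequences(self, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(200):
            seq = "".join(rng.choice(letters, size=rng.integers(8, 60)))
            for max_missed in (0, 2):
                ours = sorted(
                    (p.start - 1, p.end, p.missed_cleavages)
                    for p in digest(seq, max_missed=max_missed)
                )
                assert ours == digest_oracle(seq, max_missed, True)

    def test_zero_missed_products_reconstruct_parent(self, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(50):
            seq = "".join(rng.choice(letters, size=30))
            parts = [p.sequence for p in digest(seq, max_missed=0)]
            assert "".join(parts) == seq

    def test_coordinates_match_parent_slice(self):
        for p in digest("MKAAARGGGKPLLK", "X", max_missed=2):
            assert p.sequence == "MKAAARGGGKPLLK"[p.start - 1 : p.end]


class TestProperties:
    def test_mw_hand_sum(self):
        prof = peptide_properties("GG")
        assert prof.molecular_weight == pytest.approx(
            2 * 57.02146 + 18.01056, abs=1e-4
        )
        assert prof.molecular_weight == pytest.approx(132.0535, abs=1e-4)

    def test_gravy_alanine(self):
        assert peptide_properties("AAA").gravy == pytest.approx(1.8)

    def test_invalid_residue_named(self):
        with pytest.raises(ValueError, match="position 2"):
            peptide_properties("AZA")

    def test_charge_at_pi_is_zero(self, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        worst = 0.0
        for _ in range(1000):
            seq = "".join(rng.choice(letters, size=rng.integers(5, 35)))
            pi = isoelectric_point(seq)
            worst = max(worst, abs(net_charge(seq, pi)))
        assert worst < 1e-3

    def test_gravy_concatenation_is_length_weighted_mean(self):
        a, b = "AAAK", "DDDDDD"
        ga = peptide_properties(a).gravy
        gb = peptide_properties(b).gravy
        gab = peptide_properties(a + b).gravy
        expected = (len(a) * ga + len(b) * gb) / (len(a) + len(b))
        assert gab == pytest.approx(expected)

    def test_pi_monotone_in_charged_residues(self, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(50):
            seq = "".join(rng.choice(letters, size=12))
            pi = isoelectric_point(seq)
            assert isoelectric_point(seq + "D") <= pi + 1e-5
            assert isoelectric_point(seq + "E") <= pi + 1e-5
            assert isoelectric_point(seq + "K") >= pi - 1e-5
            assert isoelectric_point(seq + "R") >= pi - 1e-5


class TestReferenceDistribution:
    PROTEOME = {"Q1": "MAAAKGGGGGGRPPPPPPK", "Q2": "CCCCCCKDDDDDDR"}

    def test_peptide_count_matches_oracle(self):
        peptides, proteins = reference_distribution(
            self.PROTEOME, max_missed=0, length_range=(1, 10**6),
            unique_only=False,
        )
        expected = sum(
            len(digest_oracle(seq, 0, True)) for seq in self.PROTEOME.values()
        )
        assert len(peptides) == expected
        assert len(proteins) == len(self.PROTEOME)

    def test_length_window_filters(self):
        narrow, _ = reference_distribution(
            self.PROTEOME, max_missed=0, length_range=(7, 35)
        )
        wide, _ = reference_distribution(
            self.PROTEOME, max_missed=0, length_range=(1, 10**6)
        )
        assert len(narrow) < len(wide)
        assert (narrow["sequence"].str.len() >= 7).all()

    def test_unique_only_deduplicates_proteome_wide(self):
        proteome = {"A1": "AAAKGGGK", "A2": "AAAKCCCK"}
        deduped, _ = reference_distribution(
            proteome, max_missed=0, length_range=(1, 100), unique_only=True
        )
        assert deduped["sequence"].is_unique
        assert "AAAK" in set(deduped["sequence"])


class TestCompareDistributions:
    def test_identical_distribution_null(self, rng):
        values = rng.normal(0, 1, 300)
        observed = {
            "M1": pd.DataFrame({"gravy": values}),
            "M2": pd.DataFrame({"gravy": values}),
        }
        table = compare_distributions(
            observed, pd.DataFrame({"gravy": values}), properties=("gravy",)
        )
        row = table[(table.method == "M1") & (table.contrast == "vs_rest")]
        assert row["p"].iloc[0] > 0.9
        assert abs(row["shift"].iloc[0]) < 1e-9

    def test_planted_gravy_shift_detected(self, rng):
        base = rng.normal(-0.4, 0.8, 500)
        shifted = rng.normal(-0.4 + 0.5, 0.8, 500)
        observed = {
            "N-Gp": pd.DataFrame({"gravy": shifted}),
            "Rest": pd.DataFrame({"gravy": base}),
        }
        table = compare_distributions(
            observed, pd.DataFrame({"gravy": base}), properties=("gravy",)
        )
        row = table[(table.method == "N-Gp") & (table.contrast == "vs_rest")]
        assert row["shift"].iloc[0] > 0
        assert row["adjusted_p"].iloc[0] < 0.05

    def test_one_row_per_property_method_contrast(self, rng):
        observed = {
            m: pd.DataFrame(
                {
                    "mw": rng.normal(1500, 300, 20),
                    "gravy": rng.normal(0, 1, 20),
                    "pi": rng.uniform(3, 11, 20),
                }
            )
            for m in ("A", "B", "C")
        }
        reference = observed["A"].copy()
        table = compare_distributions(observed, reference)
        assert len(table) == 3 * 3 * 2
        assert not table.duplicated(["property", "method", "contrast"]).any()
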