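"""Global affine-gap alignment, identity filters and cross-species SAV
extraction with the back-mutation convention."""

import numpy as np
import pytest
from savkit import (
    AlignmentParams,
    ProteinRecord,
    SAV,
    extract_cross_species_savs,
    global_align_affine,
    housekeeping_subset,
    pide_measures,
    select_best_ortholog,
)
from savkit.ortholog_alignment import (
    AlignmentError,
    AlignmentResult,
    NoOrthologPassesError,
    PideBelowThresholdError,
    identity_measures,
)
from savkit.synthetic_data import generate_ortholog_pair

from _oracles import BLOSUM62, enumerate_best_score


class TestGlobalAlignment:
    def test_identity_score_is_diagonal_sum(self):
        aln = global_align_affine("ACDE", "ACDE")
        assert aln.score == 4 + 9 + 6 + 5 == 24
        assert aln.pide_nogap == 1.0
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_single_deletion_matches_oracle(self):
        aln = global_align_affine("ACDE", "ACE")
        assert aln.aligned_b.count("-") == 1
        assert aln.aligned_a.replace("-", "") == "ACDE"
        assert aln.aligned_b.replace("-", "") == "ACE"
        assert aln.score == enumerate_best_score("ACDE", "ACE")

    def test_self_alignment_property(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=8))
            aln = global_align_affine(seq, seq)
            assert aln.pide_nogap == 1.0
            assert aln.score == sum(BLOSUM62[c][c] for c in seq)

    def test_optimality_against_exhaustive_enumeration(self, rng):
        """Affine-gap score equals the maximum over all global alignments
        for >= 200 random short pairs."""
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(200):
            la, lb = rng.integers(1, 7, size=2)
            a = "".join(rng.choice(aas, size=la))
            b = "".join(rng.choice(aas, size=lb))
            aln = global_align_affine(a, b)
            assert aln.score == pytest.approx(enumerate_best_score(a, b)), (a, b)

    def test_non_standard_residue_named(self):
        with pytest.raises(AlignmentError, match="position 2"):
            global_align_affine("AXC", "AAC")

    def test_row_roundtrip_invariant(self):
        aln = global_align_affine("MKTAYIAKQRQISFVK", "MKTAYIAKQISVK")
        assert aln.aligned_a.replace("-", "") == "MKTAYIAKQRQISFVK"
        assert aln.aligned_b.replace("-", "") == "MKTAYIAKQISVK"
        assert not any(x == y == "-" for x, y in zip(aln.aligned_a, aln.aligned_b))


class TestIdentityMeasures:
    @pytest.mark.parametrize(
        "rows, pide, ungapped",
        [
            (("AC-E", "ACDE"), 3 / 3, 3 / 3),
            (("ACDE", "ACDD"), 3 / 4, 3 / 4),
            (("A---", "AAAA"), 1 / 1, 1 / 1),
        ],
    )
    def test_counts(self, rows, pide, ungapped):
        got_pide, got_ungapped = identity_measures(*rows)
        assert got_pide == pytest.approx(pide)
        assert got_ungapped == pytest.approx(ungapped)

    def test_pide_measures_wrapper(self):
        aln = AlignmentResult("AC-E", "ACDE", 0.0, 1.0, 1.0)
        assert pide_measures(aln) == (1.0, 1.0)

    def test_both_gapped_column_rejected(self):
        with pytest.raises(AlignmentError):
            identity_measures("A-", "A-")


class TestBestOrtholog:
    human = ProteinRecord("HUM1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")

    def test_argmax_on_identity(self):
        close = ProteinRecord("ORT_A", self.human.sequence[:-2] + "GG")
        far = ProteinRecord("ORT_B", "MKTAYIAKQRWWWWWKSHFSRQLEERLGLIEVQ")
        chosen, aln = select_best_ortholog(self.human, [far, close])
        assert chosen.id == "ORT_A"
        assert aln.ungapped_identity > 0.9

    def test_tie_breaks_on_smaller_id(self):
        c1 = ProteinRecord("ORT_B", self.human.sequence)
        c2 = ProteinRecord("ORT_A", self.human.sequence)
        chosen, _ = select_best_ortholog(self.human, [c1, c2])
        assert chosen.id == "ORT_A"

    def test_all_fail_pide(self):
        junk = ProteinRecord("ORT_X", "WWWWWWWWWWPPPPPPPPPPGGGGGGGGGG")
        with pytest.raises(NoOrthologPassesError) as exc:
            select_best_ortholog(self.human, [junk])
        assert "ORT_X" in str(exc.value)


class TestCrossSpeciesExtraction:
    def test_back_mutation_convention_worked_example(self):
        """Human L at position 42 vs ortholog V yields SAV V42L evaluated on
        the human sequence carrying V at 42."""
        base = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVG" * 2
        human = ProteinRecord("Xp", base[:41] + "L" + base[42:])
        ortho = ProteinRecord("Xd", base[:41] + "V" + base[42:])
        (item,) = extract_cross_species_savs(human, ortho)
        assert item.sav.notation == "V42L"
        assert item.context_sequence[41] == "V"
        # applying alt at position on the context recovers the human sequence
        ctx = item.context_sequence
        pos = item.sav.position
        assert ctx[: pos - 1] + item.sav.alt_aa + ctx[pos:] == human.sequence

    def test_identical_orthologs_yield_nothing(self):
        p = ProteinRecord("h", "MKTAYIAKQRQISFVK")
        assert extract_cross_species_savs(p, ProteinRecord("o", p.sequence)) == []

    def test_low_pide_pair_rejected(self):
        human = ProteinRecord("h", "MKTAYIAKQRQISFVKSHFS")
        # ~35% identity: well below the 70% threshold
        ortho = ProteinRecord("o", "MKTAWWWWWWWWWWVKSHFS")
        with pytest.raises(PideBelowThresholdError):
            extract_cross_species_savs(human, ortho)

    def test_extraction_count_equals_mismatching_columns(self, rng):
        protein = ProteinRecord(
            "h", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        )
        ortho = generate_ortholog_pair(protein, 0.08, seed=11)
        items = extract_cross_species_savs(protein, ortho)
        n_mismatch = sum(
            1 for x, y in zip(protein.sequence, ortho.sequence) if x != y
        )
        assert len(items) == n_mismatch
        for item in items:
            pos = item.sav.position
            assert protein.sequence[pos - 1] == item.sav.alt_aa
            assert ortho.sequence[pos - 1] == item.sav.ref_aa

    def test_monotone_divergence(self, rng):
        """Mean extracted-SAV count increases with the substitution rate."""
        proteins = [
            ProteinRecord(
                f"p{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
            )
            for i in range(5)
        ]
        means = []
        for rate in (0.01, 0.05, 0.10):
            counts = []
            for protein in proteins:
                ortho = generate_ortholog_pair(protein, rate, seed=42)
                counts.append(len(extract_cross_species_savs(protein, ortho)))
            means.append(np.mean(counts))
        assert means[0] < means[1] < means[2]


class TestHousekeepingSubset:
    savs = {
        "chimp": [SAV("pA", 1, "A", "C"), SAV("pB", 2, "C", "D")],
        "mouse": [SAV("pA", 3, "D", "E")],
    }
    human = [SAV("pA", 5, "E", "F"), SAV("pB", 6, "F", "G"),
             SAV("pC", 7, "G", "H")]

    def test_protein_missing_from_one_species_excluded(self):
        restricted, human = housekeeping_subset(self.savs, self.human)
        assert {s.protein_id for s in restricted["chimp"]} == {"pA"}
        assert {s.protein_id for s in restricted["mouse"]} == {"pA"}
        assert {s.protein_id for s in human} == {"pA"}

    def test_protein_without_savs_in_one_set_excluded(self):
        savs = {"chimp": [SAV("pA", 1, "A", "C")],
                "mouse": [SAV("pB", 1, "A", "C")]}
        restricted, human = housekeeping_subset(savs, self.human)
        assert restricted == {"chimp": [], "mouse": []}
        assert human == []

    def test_shared_protein_retained_everywhere(self):
        savs = {"chimp": [SAV("pA", 1, "A", "C")],
                "mouse": [SAV("pA", 2, "C", "D")]}
        restricted, human = housekeeping_subset(savs, [SAV("pA", 3, "D", "E")])
        assert all(len(v) == 1 for v in restricted.values())
        assert len(human) == 1
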