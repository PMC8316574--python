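import numpy as np
import pytest

from phosphoprio.conservation import (
    OrthologAlignment,
    conserved_species,
    map_site_to_column,
    max_branch_length,
    residue_conservation_score,
)
from phosphoprio.core_io import PhosphositeRecord, ValidationError, read_newick


class TestColumnMapping:
    msa = OrthologAlignment(rows={"ref": "M-ST", "sp": "MAST"}, reference_species="ref")

    def test_gap_skipped(self):
        col = map_site_to_column(self.msa, 2)
        assert col == 2
        assert self.msa.reference_row[col] == "S"

    def test_identity_without_gaps(self):
        msa = OrthologAlignment(rows={"ref": "MSTY"}, reference_species="ref")
        for pos in range(1, 5):
            assert map_site_to_column(msa, pos) == pos - 1

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            map_site_to_column(self.msa, 5)


class TestConservedSpecies:
    def test_st_interchangeable(self):
        msa = OrthologAlignment(
            rows={"ref": "S", "A": "T", "B": "A", "C": "S"}, reference_species="ref"
        )
        assert conserved_species(msa, 0, "S") == {"ref", "A", "C"}

    def test_strict_residue_mode(self):
        msa = OrthologAlignment(
            rows={"ref": "S", "A": "T", "C": "S"}, reference_species="ref"
        )
        assert conserved_species(msa, 0, "S", strict_residue=True) == {"ref", "C"}

    def test_tyrosine_is_its_own_class(self):
        msa = OrthologAlignment(
            rows={"ref": "Y", "A": "F", "B": "S"}, reference_species="ref"
        )
        assert conserved_species(msa, 0, "Y") == {"ref"}

    def test_all_gaps_except_reference(self):
        msa = OrthologAlignment(
            rows={"ref": "S", "A": "-", "B": "-"}, reference_species="ref"
        )
        assert conserved_species(msa, 0, "S") == {"ref"}


class TestMaxBranchLength:
    def test_toy_tree_pairs(self, toy_tree):
        mbl, pairs = max_branch_length(toy_tree, {"A", "B", "C"})
        assert mbl == pytest.approx(4.0)
        assert set(pairs) == {("A", "C"), ("B", "C")}

    def test_singleton_is_zero(self, toy_tree):
        assert max_branch_length(toy_tree, {"A"}) == (0.0, [])

    def test_cherry(self, toy_tree):
        mbl, pairs = max_branch_length(toy_tree, {"A", "B"})
        assert mbl == pytest.approx(2.0)

    def test_absent_species_rejected(self, toy_tree):
        with pytest.raises(KeyError):
            max_branch_length(toy_tree, {"A", "Z"})

    def test_matches_independent_path_sum_oracle(self, tmp_path):
        # random binary trees built here by hand; the pairwise-distance table
        # is accumulated during construction, independent of the tree parser
        rng = np.random.default_rng(17)
        for rep in range(20):
            n = int(rng.integers(3, 13))
            # each node: (newick, {leaf: distance to this subtree's root})
            nodes = [(f"L{i}", {f"L{i}": 0.0}) for i in range(n)]
            oracle: dict[frozenset, float] = {}
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                (nwk_i, d_i), (nwk_j, d_j) = nodes[i], nodes[j]
                bi, bj = rng.uniform(0.1, 2.0, size=2).round(4)
                for a, da in d_i.items():  # pairs meeting at this merge node
                    for b, db in d_j.items():
                        oracle[frozenset((a, b))] = da + bi + db + bj
                merged = (
                    f"({nwk_i}:{bi},{nwk_j}:{bj})",
                    {**{k: v + bi for k, v in d_i.items()},
                     **{k: v + bj for k, v in d_j.items()}},
                )
                nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
                nodes.append(merged)
            p = tmp_path / f"r{rep}.nwk"
            p.write_text(nodes[0][0] + ";")
            tree = read_newick(p)
            leaves = sorted(tree.leaf_labels)
            k = int(rng.integers(2, n + 1))
            subset = set(rng.choice(leaves, size=k, replace=False))
            mbl, pairs = max_branch_length(tree, subset)
            ss = sorted(subset)
            brute = max(
                oracle[frozenset((a, b))]
                for idx, a in enumerate(ss)
                for b in ss[idx + 1 :]
            )
            assert mbl == pytest.approx(brute)
            for a, b in pairs:
                assert oracle[frozenset((a, b))] == pytest.approx(mbl)


class TestResidueConservationScore:
    def make_msa(self, chars):
        # single-column alignment over the toy species
        return OrthologAlignment(
            rows={sp: c for sp, c in chars.items()}, reference_species="A"
        )

    def test_reference_only_scores_zero(self, toy_tree):
        msa = self.make_msa({"A": "S", "B": "G", "C": "G", "D": "G"})
        sc = residue_conservation_score(msa, toy_tree, PhosphositeRecord("X", 1, "S"))
        assert sc.mbl == 0.0 and sc.rcs == 0.0

    def test_toy_example_rcs_three(self, toy_tree):
        msa = self.make_msa({"A": "S", "B": "T", "C": "S", "D": "G"})
        sc = residue_conservation_score(msa, toy_tree, PhosphositeRecord("X", 1, "S"))
        assert sc.mbl == pytest.approx(4.0)
        assert (sc.np_conserved, sc.n_clade) == (3, 4)
        assert sc.rcs == pytest.approx(3.0)

    def test_fully_conserved_gives_tree_diameter(self, toy_tree):
        msa = self.make_msa({"A": "S", "B": "S", "C": "S", "D": "S"})
        sc = residue_conservation_score(msa, toy_tree, PhosphositeRecord("X", 1, "S"))
        assert sc.rcr == 1.0
        assert sc.rcs == pytest.approx(6.0)  # diameter: A/B to D

    def test_absent_species_excluded_from_clade_count(self, toy_tree):
        # D has no ortholog row: clade of {A,B,C} spans the root, but only
        # three analysis species exist, so N = 3 and RCR = 1
        msa = self.make_msa({"A": "S", "B": "S", "C": "S"})
        sc = residue_conservation_score(msa, toy_tree, PhosphositeRecord("X", 1, "S"))
        assert (sc.np_conserved, sc.n_clade) == (3, 3)
        assert sc.rcs == pytest.approx(4.0)

    def test_monotone_in_conserved_set_within_clade(self, toy_tree):
        small = self.make_msa({"A": "S", "B": "G", "C": "S", "D": "G"})
        large = self.make_msa({"A": "S", "B": "S", "C": "S", "D": "G"})
        site = PhosphositeRecord("X", 1, "S")
        sc_small = residue_conservation_score(small, toy_tree, site)
        sc_large = residue_conservation_score(large, toy_tree, site)
        assert sc_small.mbl == sc_large.mbl  # same spanning clade
        assert sc_large.rcs >= sc_small.rcs

    def test_invariant_under_row_reordering(self, toy_tree):
        site = PhosphositeRecord("X", 1, "S")
        rows = {"A": "S", "B": "T", "C": "S", "D": "G"}
        fwd = OrthologAlignment(rows=dict(rows), reference_species="A")
        rev = OrthologAlignment(
            rows=dict(reversed(list(rows.items()))), reference_species="A"
        )
        a = residue_conservation_score(fwd, toy_tree, site)
        b = residue_conservation_score(rev, toy_tree, site)
        assert a.rcs == b.rcs

    def test_alignment_reference_mismatch_rejected(self, toy_tree):
        msa = self.make_msa({"A": "T", "B": "S", "C": "S", "D": "G"})
        with pytest.raises(ValidationError):
            residue_conservation_score(msa, toy_tree, PhosphositeRecord("X", 1, "S"))


class TestAlignmentInvariants:
    def test_unequal_row_lengths_rejected(self):
        with pytest.raises(ValidationError):
            OrthologAlignment(rows={"ref": "MST", "A": "MS"}, reference_species="ref")

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError):
            OrthologAlignment(rows={"A": "MST"}, reference_species="ref")
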