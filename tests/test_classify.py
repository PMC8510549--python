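"""Descriptor search, alignment mapping, residue rules, neighbor joining."""

import numpy as np
import pytest

from metaregulon.classify import (ConservationRule, GlobalAlignment,
                                  ProteinRecord, apply_rules, default_rules,
                                  domain_identity, find_candidates,
                                  fractional_identity, global_align,
                                  identity_distance_matrix,
                                  load_reference_proteins,
                                  map_reference_position, nj_from_distances,
                                  nj_tree)

REFS = load_reference_proteins()
RULES = default_rules()
FAMILY_TO_REF = {"FNR": "FNR_ref", "DNR": "DNR_ref", "NnrR": "NnrR_ref",
                 "CRP": "CRP_ref", "MalR": "MalR_ref"}


class TestFindCandidates:
    PROTS = [
        ProteinRecord("p1", "MKL", product="Fumarate and nitrate reduction regulatory protein Fnr"),
        ProteinRecord("p2", "MKL", product="sucrose transporter"),
        ProteinRecord("p3", "MKL", product="cAMP receptor protein (CRP)"),
        ProteinRecord("p4", "MKL", product="CRISPR-associated endonuclease"),
    ]

    def test_token_matching(self):
        found = {p.protein_id for p in find_candidates(self.PROTS)}
        assert found == {"p1", "p3"}

    def test_duplicate_token_hits_report_once(self):
        out = find_candidates([ProteinRecord("x", "MKL", product="CRP family protein CRP")])
        assert len(out) == 1

    def test_crispr_does_not_match_crp(self):
        assert find_candidates([self.PROTS[3]]) == []

    def test_empty_descriptor_list_rejected(self):
        with pytest.raises(ValueError):
            find_candidates(self.PROTS, descriptors=[])


def nw_affine_oracle(a, b, sub, gap_open, gap_extend):
    """Independent affine-gap global alignment score by Gotoh DP."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (deletion)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (insertion)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


class TestGlobalAlign:
    def test_self_alignment_is_diagonal_sum(self):
        from Bio.Align import substitution_matrices
        blosum = substitution_matrices.load("BLOSUM62")
        aln = global_align("MKC", "MKC")
        assert aln.score == sum(blosum[c, c] for c in "MKC")
        assert aln.aligned_a == aln.aligned_b == "MKC"

    def test_single_residue(self):
        aln = global_align("A", "A")
        assert (aln.aligned_a, aln.aligned_b) == ("A", "A")

    def test_matches_gotoh_oracle_on_random_pairs(self):
        from Bio.Align import substitution_matrices
        blosum = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(17)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(8):
            a = "".join(rng.choice(aas, size=8))
            b = "".join(rng.choice(aas, size=int(rng.integers(5, 11))))
            aln = global_align(a, b, gap_open=-10.0, gap_extend=-0.5)
            # oracle gap model: first gap residue costs gap_open, each
            # further residue gap_extend — the same affine convention
            oracle = nw_affine_oracle(a, b, blosum, -10.0, -0.5)
            assert aln.score == pytest.approx(oracle)

    def test_symmetry_of_score(self):
        rng = np.random.default_rng(23)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aas, size=12))
        b = "".join(rng.choice(aas, size=15))
        assert global_align(a, b).score == pytest.approx(global_align(b, a).score)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "MK")


class TestMapReferencePosition:
    def test_identity_maps_to_self(self):
        aln = global_align("MKLVH", "MKLVH")
        for pos in range(1, 6):
            mapped = map_reference_position(aln, pos)
            assert mapped.candidate_pos == pos

    def test_n_terminal_insertion_shifts_by_one(self):
        aln = GlobalAlignment(aligned_a="-MKL", aligned_b="XMKL", score=0)
        mapped = map_reference_position(aln, 1)  # reference M
        assert mapped.candidate_pos == 2 and mapped.residue == "M"

    def test_deletion_maps_to_gap(self):
        aln = GlobalAlignment(aligned_a="MKL", aligned_b="M-L", score=0)
        mapped = map_reference_position(aln, 2)
        assert mapped.candidate_pos is None and mapped.residue == "-"

    def test_out_of_range_rejected(self):
        aln = global_align("MK", "MK")
        with pytest.raises(ValueError):
            map_reference_position(aln, 3)


class TestRules:
    @pytest.mark.parametrize("family,ref_id", sorted(FAMILY_TO_REF.items()))
    def test_reference_passes_its_own_family_rule(self, family, ref_id):
        call = apply_rules(REFS[ref_id], RULES, REFS)
        own = next(e for e in call.evidence if e["family"] == family)
        assert own["passed"]
        assert call.family == family

    def test_three_cysteines_fail_fnr(self):
        seq = "".join("C" if i in (4, 9, 14) else "A" for i in range(150))
        call = apply_rules(ProteinRecord("lowC", seq), RULES, REFS)
        fnr = next(e for e in call.evidence if e["family"] == "FNR")
        assert not fnr["passed"] and fnr["count"] == 3

    @pytest.mark.parametrize("family,ref_id,pos", [("DNR", "DNR_ref", 139),
                                                   ("NnrR", "NnrR_ref", 93)])
    def test_point_mutant_fails_only_its_rule(self, family, ref_id, pos):
        ref = REFS[ref_id]
        mutant = ProteinRecord(f"{ref_id}_mut",
                               ref.seq[:pos - 1] + "A" + ref.seq[pos:])
        before = {e["family"]: e["passed"]
                  for e in apply_rules(ref, RULES, REFS).evidence}
        after = {e["family"]: e["passed"]
                 for e in apply_rules(mutant, RULES, REFS).evidence}
        flipped = {f for f in before if before[f] != after[f]}
        assert flipped == {family}

    def test_missing_reference_is_config_error(self):
        rule = ConservationRule(family="DNR", kind="reference-position",
                                residue="H", ref_id="NOPE", ref_pos=139)
        with pytest.raises(KeyError):
            apply_rules(REFS["DNR_ref"], [rule], {})

    def test_domain_identity_on_self_is_full(self):
        aln = global_align(REFS["MalR_ref"].seq, REFS["MalR_ref"].seq)
        assert domain_identity(aln, 120, 220) == pytest.approx(1.0)


class TestNeighborJoining:
    def test_four_taxa_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) with internal edge 3
        D = np.array([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float)
        newick = nj_from_distances(D, ["A", "B", "C", "D"])
        import re
        lengths = {m[0]: float(m[1]) for m in re.findall(r"([A-D]):([\d.]+)", newick)}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 4.0, "D": 5.0}
        assert "(A:1,B:2)" in newick.replace(" ", "")

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        newick = nj_from_distances(D, ["x", "y", "z"])
        # l_x = (5 + 9 - 10)/2 = 2, l_y = 3, l_z = 7
        assert "x:2" in newick and "y:3" in newick and "z:7" in newick

    def test_random_additive_trees_recovered(self):
        """Random additive trees (<= 8 taxa): NJ recovers the topology."""
        from skbio import TreeNode
        import io as _io
        rng = np.random.default_rng(31)
        for trial in range(20):
            n = int(rng.integers(4, 9))
            ids = [f"t{i}" for i in range(n)]
            # random additive tree by random sequential attachment
            true = TreeNode.read(_io.StringIO(f"({ids[0]}:1,{ids[1]}:1,{ids[2]}:1);"))
            for leaf in ids[3:]:
                nodes = [t for t in true.traverse() if not t.is_root()]
                target = nodes[int(rng.integers(len(nodes)))]
                new_internal = TreeNode(length=float(rng.uniform(0.1, 2)))
                parent = target.parent
                parent.remove(target)
                target.length = float(rng.uniform(0.1, 2))
                new_leaf = TreeNode(name=leaf, length=float(rng.uniform(0.1, 2)))
                new_internal.extend([target, new_leaf])
                parent.extend([new_internal])
            dm = true.tip_tip_distances(endpoints=ids)
            got = TreeNode.read(_io.StringIO(nj_from_distances(dm.data, ids)))
            rf = true.compare_rfd(got)
            assert rf == 0.0, f"trial {trial}: RF {rf}"
            # on an additive matrix NJ also reproduces every branch
            # length, so leaf-to-leaf distances match exactly
            got_dm = got.tip_tip_distances(endpoints=ids)
            assert np.allclose(got_dm.data, dm.data, atol=1e-9)

    def test_identical_sequences_form_zero_length_cherry(self):
        prots = [ProteinRecord("a", "MKLVWYHE" * 4), ProteinRecord("b", "MKLVWYHE" * 4),
                 ProteinRecord("c", "MWYHEKLV" * 4), ProteinRecord("d", "HEKLMWYV" * 4)]
        d, ids = identity_distance_matrix(prots)
        assert d[0, 1] == 0.0
        newick = nj_tree(prots)
        assert "a:0" in newick and "b:0" in newick

    def test_duplicate_ids_rejected(self):
        prots = [ProteinRecord("a", "MKL"), ProteinRecord("a", "MKV"),
                 ProteinRecord("c", "MKI")]
        with pytest.raises(ValueError, match="duplicate"):
            nj_tree(prots)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            nj_from_distances(np.zeros((2, 2)), ["a", "b"])
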