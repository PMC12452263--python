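"""Tree scaling, clade discovery, marker finding, database round trips."""

import numpy as np
import pandas as pd
import pytest

import dendropy
from clademix.basecalls import hamming_distances
from clademix.clades import (
    CladeDefinition,
    DatabaseParams,
    PhylogenyModel,
    build_database,
    discover_clades,
    find_cs_alleles,
    scale_tree,
)
from conftest import matrix_from_strings


def model_from(newick: str) -> PhylogenyModel:
    return PhylogenyModel.from_newick(newick)


# --- scale_tree ------------------------------------------------------------

class TestScaleTree:
    def _dist(self, labels, values):
        return pd.DataFrame(values, index=labels, columns=labels)

    def test_already_in_snv_units(self):
        m = model_from("((a:1,b:1)1.0:2,(c:1,d:1)1.0:2):0;")
        pat = {("a", "b"): 2, ("c", "d"): 2, ("a", "c"): 6, ("a", "d"): 6,
               ("b", "c"): 6, ("b", "d"): 6}
        labels = list("abcd")
        vals = np.zeros((4, 4))
        for (x, y), v in pat.items():
            i, j = labels.index(x), labels.index(y)
            vals[i, j] = vals[j, i] = v
        out = scale_tree(m, self._dist(labels, vals))
        assert out.snv_scaled
        lengths = sorted(e.length for e in out.tree.preorder_edge_iter() if e.length)
        assert lengths == [1, 1, 1, 1, 2, 2]

    def test_half_scale_doubles_lengths(self):
        # Hamming = 2 x patristic everywhere -> origin-constrained slope 2
        m = model_from("((a:1,b:1)1.0:2,(c:1,d:1)1.0:2):0;")
        labels = list("abcd")
        vals = np.zeros((4, 4))
        for (x, y), v in {("a", "b"): 4, ("c", "d"): 4, ("a", "c"): 12,
                          ("a", "d"): 12, ("b", "c"): 12, ("b", "d"): 12}.items():
            i, j = labels.index(x), labels.index(y)
            vals[i, j] = vals[j, i] = v
        out = scale_tree(m, self._dist(labels, vals))
        assert out.snv_scaled
        lengths = sorted(e.length for e in out.tree.preorder_edge_iter() if e.length)
        assert lengths == [2, 2, 2, 2, 4, 4]

    def test_uncorrelated_distances_left_unscaled(self):
        m = model_from("((a:1,b:1)1.0:2,(c:1,d:1)1.0:2):0;")
        labels = list("abcd")
        # anti-correlated with the patristic structure
        vals = np.zeros((4, 4))
        for (x, y), v in {("a", "b"): 12, ("c", "d"): 12, ("a", "c"): 2,
                          ("a", "d"): 2, ("b", "c"): 2, ("b", "d"): 2}.items():
            i, j = labels.index(x), labels.index(y)
            vals[i, j] = vals[j, i] = v
        with pytest.warns(UserWarning, match="unscaled"):
            out = scale_tree(m, self._dist(labels, vals))
        assert not out.snv_scaled
        lengths = sorted(e.length for e in out.tree.preorder_edge_iter() if e.length)
        assert lengths == [1, 1, 1, 1, 2, 2]

    def test_too_few_tips_errors(self):
        m = model_from("(a:1,b:1):0;")
        with pytest.raises(ValueError):
            scale_tree(m, self._dist(["a", "b"], [[0, 1], [1, 0]]))

    def test_topology_preserved(self, small_species):
        dist = hamming_distances(small_species.to_basecall_matrix())
        out = scale_tree(small_species.model, dist)
        assert out.snv_scaled  # infinite sites: patristic == Hamming exactly
        a = small_species.model.tree.as_string(schema="newick", suppress_edge_lengths=True)
        b = out.tree.as_string(schema="newick", suppress_edge_lengths=True)
        assert a == b


# --- discover_clades -------------------------------------------------------

def brute_force_clades(model, min_genomes, min_branch, min_bootstrap):
    """Independent oracle: exhaustive branch scan with naive criteria checks."""
    out = []
    root = model.tree.seed_node
    for nd in model.tree.preorder_node_iter():
        if nd.is_leaf() or nd is root or nd.parent_node is root:
            continue
        tips = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        length = nd.edge.length or 0.0
        try:
            support = float(nd.label)
        except (TypeError, ValueError):
            support = None
        if support is not None and support > 1:
            support /= 100.0
        if (len(tips) >= min_genomes and length >= min_branch
                and support is not None and support > min_bootstrap):
            out.append(tips)
    return out


# root -> (h, X); X -> (g, Y); Y -> (AB, Z); Z -> (CD, EF). Only Y and Z are
# non-root-incident internal branches with >= 3 descendant tips.
DEEP8 = (
    "(h:2000,(g:2000,((a:2000,b:2000)1.0:2000,((c:2000,d:2000)1.0:2000,"
    "(e:2000,f:2000)1.0:2000)1.0:2000)1.0:2000)1.0:2000):0;"
)


class TestDiscoverClades:
    def test_exhaustive_branch_scan_matches_brute_force(self):
        m = PhylogenyModel.from_newick(DEEP8, snv_scaled=True)
        found = {c.members for c in discover_clades(m)}
        expected = set(brute_force_clades(m, 3, 1000, 0.75))
        assert found == expected
        # cherries fail min_genomes; root-incident branches are skipped
        assert found == {frozenset("abcdef"), frozenset("cdef")}

    def test_two_tip_branch_never_a_clade(self):
        m = PhylogenyModel.from_newick(DEEP8, snv_scaled=True)
        for c in discover_clades(m, min_genomes=3):
            assert len(c.members) >= 3

    def test_low_bootstrap_excluded(self):
        nwk = DEEP8.replace("(e:2000,f:2000)1.0:2000)1.0:2000",
                            "(e:2000,f:2000)1.0:2000)0.70:2000")
        m = PhylogenyModel.from_newick(nwk, snv_scaled=True)
        found = {c.members for c in discover_clades(m)}
        assert frozenset("cdef") not in found
        assert frozenset("abcdef") in found

    def test_short_branch_excluded(self):
        nwk = DEEP8.replace(")1.0:2000)1.0:2000):0;", ")1.0:500)1.0:2000):0;")
        m = PhylogenyModel.from_newick(nwk, snv_scaled=True)
        found = {c.members for c in discover_clades(m)}
        assert frozenset("abcdef") not in found
        assert frozenset("cdef") in found

    def test_manual_clades_appended(self):
        m = PhylogenyModel.from_newick(DEEP8, snv_scaled=True)
        clades = discover_clades(m, manual_clades=[("typeA", {"a", "e", "g"})])
        assert any(c.clade_id == "typeA" and c.members == frozenset("aeg") for c in clades)

    def test_monotonic_in_bootstrap_threshold(self, small_species):
        m = small_species.model
        n_low = len(discover_clades(m, min_bootstrap=0.5))
        n_high = len(discover_clades(m, min_bootstrap=0.99))
        assert n_high <= n_low


# --- find_cs_alleles -------------------------------------------------------

def brute_force_cs(matrix, members, ambig_max=0.10):
    """Independent oracle: per-position scan with explicit loops."""
    chars = matrix.calls_char()
    idx = {g: i for i, g in enumerate(matrix.genomes)}
    inside = [idx[g] for g in sorted(members)]
    outside = [i for i in range(len(matrix.genomes)) if i not in inside]
    out = []
    for j in range(matrix.n_positions):
        in_calls = [chars[i][j] for i in inside]
        non_n = [c for c in in_calls if c != "N"]
        if not non_n or len(set(non_n)) != 1:
            continue
        if in_calls.count("N") / len(in_calls) >= ambig_max:
            continue
        allele = non_n[0]
        out_calls = [chars[i][j] for i in outside]
        out_non_n = [c for c in out_calls if c != "N"]
        if not out_non_n or allele in out_non_n:
            continue
        out.append((int(matrix.positions[j]), "ACGT".index(allele)))
    return out


# 6 genomes x 12 positions: clade {g1,g2,g3} has private unanimous alleles at
# positions 0,1,2,3 but the position-3 allele is shared with g5; position 11
# is ambiguous in 1/3 of clade members.
SIX_GENOME = {
    "g1": "TTTTACGTACGC",
    "g2": "TTTTACGTACGC",
    "g3": "TTTTACGTACGN",
    "g4": "ACGAACGTACGA",
    "g5": "ACGTACGTACGA",
    "g6": "ACGAACGTACGA",
}


class TestFindCsAlleles:
    def test_printed_fixture_matches_brute_force(self):
        m = matrix_from_strings(SIX_GENOME)
        clade = CladeDefinition("c1", frozenset({"g1", "g2", "g3"}))
        out = find_cs_alleles(m, clade, min_cssnvs=10)
        expected = brute_force_cs(m, {"g1", "g2", "g3"})
        assert list(out.cs_alleles) == expected
        # only the 3 truly private positions; shared pos 3 and ambiguous
        # pos 11 are excluded; dropped because 3 < 10 markers
        assert [p for p, _ in out.cs_alleles] == [0, 1, 2]
        assert not out.passed
        relaxed = find_cs_alleles(m, clade, min_cssnvs=3)
        assert relaxed.passed

    def test_allele_shared_outside_never_specific(self):
        m = matrix_from_strings(SIX_GENOME)
        out = find_cs_alleles(m, CladeDefinition("c1", frozenset({"g1", "g2", "g3"})),
                              min_cssnvs=1)
        assert 3 not in [p for p, _ in out.cs_alleles]  # T shared with g5

    def test_within_clade_ambiguity_excludes_position(self):
        m = matrix_from_strings(SIX_GENOME)
        out = find_cs_alleles(m, CladeDefinition("c1", frozenset({"g1", "g2", "g3"})),
                              min_cssnvs=1)
        # position 11: N in 1/3 of members (0.33 >= 0.10)
        assert 11 not in [p for p, _ in out.cs_alleles]

    def test_outgroup_positions_excluded(self):
        m = matrix_from_strings(SIX_GENOME)
        og = matrix_from_strings({"og1": "ANNNNNNNNNNN", "og2": "CNNNNNNNNNNN"})
        out = find_cs_alleles(m, CladeDefinition("c1", frozenset({"g1", "g2", "g3"})),
                              outgroup_calls=og, min_cssnvs=1)
        # position 0 has non-ambiguous calls in 100% of outgroup genomes
        assert 0 not in [p for p, _ in out.cs_alleles]
        assert [p for p, _ in out.cs_alleles] == [1, 2]

    def test_missing_members_error(self):
        m = matrix_from_strings(SIX_GENOME)
        with pytest.raises(ValueError, match="absent"):
            find_cs_alleles(m, CladeDefinition("c1", frozenset({"g1", "gX"})))

    def test_markers_absent_outside_by_construction(self, small_species, small_db):
        chars = small_species.to_basecall_matrix().calls_char()
        idx = {g: i for i, g in enumerate(small_species.genomes)}
        pos_col = {int(p): j for j, p in enumerate(small_species.positions)}
        for clade in small_db.clades:
            outside = [idx[g] for g in small_species.genomes if g not in clade.members]
            for p, a in clade.cs_alleles:
                col = pos_col[p]
                assert all(chars[i][col] != "ACGT"[a] for i in outside)

    def test_nested_clades_have_disjoint_markers(self, small_db):
        for a in small_db.clades:
            for b in small_db.clades:
                if a is not b and a.members < b.members:
                    assert not set(a.cs_alleles) & set(b.cs_alleles)


# --- build_database --------------------------------------------------------

class TestBuildDatabase:
    def test_deterministic_and_round_trip(self, small_species, tmp_path):
        m = small_species.to_basecall_matrix()
        db1 = build_database(m, small_species.model)
        db2 = build_database(m, small_species.model)
        p1, p2 = tmp_path / "a.h5", tmp_path / "b.h5"
        db1.save(p1)
        db2.save(p2)
        assert p1.read_bytes() == p2.read_bytes()  # byte-identical rebuild
        from clademix.clades import ReferenceDatabase

        loaded = ReferenceDatabase.load(p1)
        assert loaded.clade_ids() == db1.clade_ids()
        for c1, c2 in zip(db1.clades, loaded.clades):
            assert c1.members == c2.members
            assert tuple(c1.cs_alleles) == tuple(c2.cs_alleles)
        assert loaded.params == db1.params
        assert loaded.matrix_hash == db1.matrix_hash

    def test_raising_min_cssnvs_never_adds_clades(self, small_species):
        m = small_species.to_basecall_matrix()
        lo = build_database(m, small_species.model, DatabaseParams(min_cssnvs=5))
        hi = build_database(m, small_species.model, DatabaseParams(min_cssnvs=500))
        assert {c.members for c in hi.clades} <= {c.members for c in lo.clades}

    def test_zero_clades_errors(self):
        m = matrix_from_strings(SIX_GENOME)
        nwk = "((g1:1,g2:1)1.0:1,((g3:1,g4:1)1.0:1,(g5:1,g6:1)1.0:1)1.0:1):0;"
        model = PhylogenyModel.from_newick(nwk, snv_scaled=True)
        with pytest.raises(ValueError, match="no clade"):
            build_database(m, model)  # every branch fails min_branch=1000

    def test_tsv_export_header_is_one_based(self, small_db, tmp_path):
        out = tmp_path / "cs.tsv"
        small_db.cs_alleles_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("#") and "1-based" in lines[0]
        first = lines[2].split("\t")
        clade = small_db.get(first[0])
        assert (int(first[1]) - 1, "ACGT".index(first[2])) in set(clade.cs_alleles)
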