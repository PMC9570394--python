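"""K2P distances, NJ reconstruction, bootstrap and topology classification."""

import itertools
import math

import numpy as np
import pytest

from sexlinkscan import synthdata
from sexlinkscan.genetree import (
    SaturationError,
    bootstrap_supports,
    classify_external_tree,
    classify_topology,
    k2p_distance,
    k2p_matrix,
    nj_tree,
    retrieve_homologs,
    build_multilocus_trees,
    tree_bipartitions,
)
from sexlinkscan.io_formats import read_newick


def _mutate(seq, positions, repl):
    out = list(seq)
    for p, b in zip(positions, repl):
        out[p] = b
    return "".join(out)


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGT" * 25, "ACGT" * 25) == 0.0

    def test_one_transition_in_100_sites(self):
        a = "A" * 100
        b = "G" + "A" * 99
        expected = -0.5 * math.log(1 - 2 * 0.01) - 0.25 * math.log(1.0)
        assert k2p_distance(a, b) == pytest.approx(expected, rel=1e-12)
        assert k2p_distance(a, b) == pytest.approx(0.01010, abs=5e-6)

    def test_quarter_quarter_is_finite(self):
        # P = 0.25, Q = 0.25: 1-2P-Q = 0.25 > 0 and 1-2Q = 0.5 > 0
        n = 100
        a = "A" * n
        b = "G" * 25 + "C" * 25 + "A" * 50
        d = k2p_distance(a, b)
        assert math.isfinite(d) and d > 0

    def test_saturation_raises(self):
        # P = 0.4, Q = 0.2: 1-2P-Q = -0.2
        a = "A" * 100
        b = "G" * 40 + "C" * 20 + "A" * 40
        with pytest.raises(SaturationError):
            k2p_distance(a, b)

    def test_gaps_and_ambiguity_excluded_pairwise(self):
        a = "A" * 50 + "N" * 50
        b = "G" + "A" * 49 + "A" * 50
        # only the first 50 columns are comparable: P = 1/50
        expected = -0.5 * math.log(1 - 2 / 50)
        assert k2p_distance(a, b) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        b = _mutate(a, rng.choice(200, 10, replace=False), "ACGTACGTAC")
        assert k2p_distance(a, b) == k2p_distance(b, a) >= 0
        assert (k2p_distance(a, b) == 0) == (a == b)

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(1)
        aln = {}
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        for i in range(5):
            aln[f"t{i}"] = _mutate(
                base, rng.choice(120, 6, replace=False), "GGGGGG"
            )
        labels, mat = k2p_matrix(aln)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert mat[i, j] == pytest.approx(
                    k2p_distance(aln[a], aln[b]), abs=1e-12
                )


# --- brute-force least-squares topology oracle ------------------------------

def _unrooted_topologies(labels):
    """All unrooted binary topologies as lists of internal splits."""
    n = len(labels)
    if n == 4:
        a, b, c, d = labels
        return [[frozenset({a, b})], [frozenset({a, c})], [frozenset({a, d})]]
    assert n == 5
    out = []
    for quartet_split_pair in _five_taxon_split_pairs(labels):
        out.append(quartet_split_pair)
    return out


def _five_taxon_split_pairs(labels):
    """Each unrooted 5-taxon tree has two internal edges: a 2|3 split pair
    that is compatible; enumerate all 15 trees."""
    pairs = []
    twos = [frozenset(c) for c in itertools.combinations(labels, 2)]
    for s1, s2 in itertools.combinations(twos, 2):
        if s1 & s2:
            continue  # incompatible 2-subsets overlap -> not a tree
        pairs.append([s1, s2])
    return pairs


def _path_matrix(labels, splits):
    """Design matrix: rows = taxon pairs, cols = edges (terminal + internal);
    entry 1 when the edge lies on the path between the pair."""
    pair_list = list(itertools.combinations(labels, 2))
    edges = [frozenset({t}) for t in labels] + list(splits)
    A = np.zeros((len(pair_list), len(edges)))
    for r, (a, b) in enumerate(pair_list):
        for c, side in enumerate(edges):
            if (a in side) != (b in side):
                A[r, c] = 1.0
    return pair_list, A


def _ls_fit_sse(labels, splits, dmat, index):
    pair_list, A = _path_matrix(labels, splits)
    y = np.array([dmat[index[a], index[b]] for a, b in pair_list])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ coef - y) ** 2).sum())


def _random_additive_matrix(rng, labels):
    """Distances from a random binary tree with positive branch lengths."""
    import dendropy

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
        num_extant_tips=len(labels), rng=_PyRandom(rng),
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(rng.uniform(0.1, 2.0))
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    d = np.zeros((n, n))
    for t1 in taxa:
        for t2 in taxa:
            d[index[t1.label], index[t2.label]] = pdm.distance(t1, t2)
    return d, tree


class _PyRandom:
    """Adapter so dendropy's simulator draws from a numpy Generator."""

    def __init__(self, rng):
        self._rng = rng

    def __getattr__(self, name):
        import random

        r = random.Random(int(self._rng.integers(0, 2**31)))
        return getattr(r, name)


def _topology_splits(tree):
    return set(tree_bipartitions(tree))


class TestNJ:
    def test_two_taxa_single_edge_halved(self):
        t = nj_tree(np.array([[0.0, 4.0], [4.0, 0.0]]), ["A", "B"])
        lengths = [leaf.edge.length for leaf in t.leaf_node_iter()]
        assert lengths == [2.0, 2.0]

    def test_zero_matrix_gives_star(self):
        t = nj_tree(np.zeros((4, 4)), list("ABCD"))
        assert _topology_splits(t) in (set(), {frozenset()})
        for leaf in t.leaf_node_iter():
            assert leaf.edge.length == 0.0

    def test_nonsymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d, ["A", "B"])

    def test_four_taxon_additive_recovers_generating_topology(self):
        # tree ((A:1,B:2):1,C:3,D:4): additive distances
        labels = list("ABCD")
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        t = nj_tree(d, labels)
        assert _topology_splits(t) == {frozenset({"C", "D"})}
        # brute force: the AB|CD topology minimises least-squares error
        index = {lab: i for i, lab in enumerate(labels)}
        sses = {
            tuple(sorted(s[0])): _ls_fit_sse(labels, s, d, index)
            for s in _unrooted_topologies(labels)
        }
        assert min(sses, key=sses.get) == ("A", "B")

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (4, 1), (5, 2), (5, 3),
                                             (6, 4), (7, 5), (8, 6)])
    def test_additive_matrices_recover_true_tree(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(n_taxa)]
        d, true_tree = _random_additive_matrix(rng, labels)
        mine = nj_tree(d, labels)
        assert _topology_splits(mine) == _topology_splits(true_tree)
        if n_taxa <= 5:
            # cross-check with exhaustive least-squares over all topologies
            index = {lab: i for i, lab in enumerate(labels)}
            anchor = min(labels)
            tips = frozenset(labels)

            def canon(split):
                return tips - split if anchor in split else split

            best = min(
                _unrooted_topologies(labels),
                key=lambda s: _ls_fit_sse(labels, s, d, index),
            )
            assert {canon(s) for s in best} == _topology_splits(mine)
            assert _ls_fit_sse(labels, list(_topology_splits(mine)), d, index) \
                == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_independent_nj_implementation(self, seed):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(40 + seed)
        labels = [f"t{i}" for i in range(7)]
        d, _ = _random_additive_matrix(rng, labels)
        mine = _topology_splits(nj_tree(d, labels))
        ref_tree = skbio_nj(DistanceMatrix(d, labels))
        ref = set()
        tips = frozenset(labels)
        anchor = min(labels)
        for node in ref_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(tips) - 2:
                side = tips - side if anchor in side else side
                ref.add(side)
        assert mine == ref


class TestBootstrap:
    def _two_cluster_alignment(self):
        # 50 diagnostic columns separating {A1,A2} from {B1,B2}
        left = "A" * 50 + "C" * 50
        right = "G" * 50 + "C" * 50
        return {
            "A1": left, "A2": _mutate(left, [60], "T"),
            "B1": right, "B2": _mutate(right, [70], "T"),
        }

    def test_clear_split_gets_full_support(self):
        tree, supports = bootstrap_supports(
            self._two_cluster_alignment(), 100, seed=0
        )
        assert supports[frozenset({"B1", "B2"})] == 100.0

    def test_identical_sequences_zero_information(self):
        aln = {f"t{i}": "ACGT" * 10 for i in range(4)}
        tree, supports = bootstrap_supports(aln, 10, seed=0)
        labels, d = k2p_matrix(aln)
        assert np.all(d == 0)  # caller-detectable zero-information flag
        for s in supports.values():
            assert 0 <= s <= 100

    def test_seed_determinism(self):
        aln = self._two_cluster_alignment()
        _, s1 = bootstrap_supports(aln, 50, seed=7)
        _, s2 = bootstrap_supports(aln, 50, seed=7)
        assert s1 == s2

    def test_taxon_order_invariance(self):
        aln = self._two_cluster_alignment()
        reordered = dict(reversed(list(aln.items())))
        _, s1 = bootstrap_supports(aln, 50, seed=7)
        _, s2 = bootstrap_supports(reordered, 50, seed=7)
        assert s1 == s2

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_supports(self._two_cluster_alignment(), 0, seed=0)


class TestClassify:
    def _labels(self):
        return {
            "spA-M01-X1": ("spA", "X"), "spA-M01-Y2": ("spA", "Y"),
            "spB-M01-X1": ("spB", "X"), "spB-M01-Y2": ("spB", "Y"),
        }

    def test_gametolog_clustered_topology(self):
        res = classify_external_tree(
            "((spA-M01-X1:1,spB-M01-X1:1)100:2,(spA-M01-Y2:1,spB-M01-Y2:1)100:2);",
            self._labels(),
        )
        assert res.classification == "gametolog_clustered"

    def test_species_clustered_topology(self):
        res = classify_external_tree(
            "((spA-M01-X1:1,spA-M01-Y2:1)100:2,(spB-M01-X1:1,spB-M01-Y2:1)100:2);",
            self._labels(),
        )
        assert res.classification == "species_clustered"

    def test_star_tree_unresolved(self):
        res = classify_external_tree(
            "(spA-M01-X1:1,spA-M01-Y2:1,spB-M01-X1:1,spB-M01-Y2:1);",
            self._labels(),
        )
        assert res.classification == "unresolved"

    def test_low_support_unresolved(self):
        res = classify_external_tree(
            "((spA-M01-X1:1,spB-M01-X1:1)40:2,(spA-M01-Y2:1,spB-M01-Y2:1)40:2);",
            self._labels(),
        )
        assert res.classification == "unresolved"

    def test_single_species_rejected(self):
        labels = {
            "spA-M01-X1": ("spA", "X"), "spA-M01-Y2": ("spA", "Y"),
            "spA-M02-X1": ("spA", "X"), "spA-M02-Y2": ("spA", "Y"),
        }
        with pytest.raises(ValueError, match="2 species"):
            classify_external_tree(
                "((spA-M01-X1:1,spA-M02-X1:1):1,(spA-M01-Y2:1,spA-M02-Y2:1):1);",
                labels,
            )


@pytest.fixture(scope="module")
def sdr_study():
    cfg = synthdata.SimulationConfig(
        n_species=3, n_males=3, n_females=3, n_autosomal_loci=5,
        n_xy_snp_loci=3, n_y_limited_loci=0,
        sdr_shared_species=("sp1", "sp2"),
        species_tree="((sp1:0.5,sp2:0.5):0.5,sp3:1.0);", seed=21,
    )
    return synthdata.simulate_catalog(cfg)


class TestRetrieveHomologs:
    def _sdr_marker(self, study, sp):
        from sexlinkscan.screen import screen_allele_frequency

        markers = screen_allele_frequency(
            study.catalogs[sp], study.registry, species_id=sp
        )
        [m] = [m for m in markers if "sdr" in m.locus_id
               and m.system_consistency == "XY_type"]
        return m

    def test_focal_haplotypes_phased_by_sex_allele(self, sdr_study):
        study = sdr_study
        marker = self._sdr_marker(study, "sp1")
        alleles = retrieve_homologs(
            marker, study.catalogs, study.registry, "sp1"
        )
        focal = [a for a in alleles if a.species_id == "sp1"]
        from sexlinkscan.io_formats import Sex

        for a in focal:
            if a.sex is Sex.MALE:
                carries = a.sequence[marker.site] == marker.sex_specific_allele
                assert a.allele_class == ("Y" if carries else "X")
            else:
                assert a.allele_class == "X"

    def test_homologous_species_included_others_omitted(self, sdr_study):
        study = sdr_study
        marker = self._sdr_marker(study, "sp1")
        alleles = retrieve_homologs(
            marker, study.catalogs, study.registry, "sp1"
        )
        species = {a.species_id for a in alleles}
        assert "sp2" in species      # diverged copy of the shared tag
        assert "sp3" not in species  # no homolog planted in sp3
        assert all(a.allele_class == "unphased"
                   for a in alleles if a.species_id == "sp2")

    def test_marker_of_second_species_phases_it_too(self, sdr_study):
        study = sdr_study
        m1 = self._sdr_marker(study, "sp1")
        m2 = self._sdr_marker(study, "sp2")
        alleles = retrieve_homologs(
            m1, study.catalogs, study.registry, "sp1",
            markers_by_species={"sp2": m2},
        )
        sp2_classes = {a.allele_class for a in alleles if a.species_id == "sp2"}
        assert "Y" in sp2_classes and "X" in sp2_classes

    def test_single_locus_run_equals_concatenated(self, sdr_study):
        study = sdr_study
        marker = self._sdr_marker(study, "sp1")
        out = build_multilocus_trees(
            [marker], study.catalogs, study.registry, "sp1",
            n_bootstrap=20, seed=3,
        )
        assert out["concatenated"] is out["per_locus"][0]


class TestScenarioRecovery:
    @pytest.mark.parametrize("scenario,species,expected", [
        ("ancestral_suppression", ["sp3", "sp4"], "gametolog_clustered"),
        ("ongoing_recombination",
         ["sp2", "sp4", "sp6", "sp8"], "species_clustered"),
    ])
    def test_default_generator_classified_correctly(self, scenario, species,
                                                    expected):
        hits = 0
        n = 8
        for seed in range(n):
            alleles = synthdata.simulate_gene_history(
                scenario, species, synthdata.DEFAULT_SPECIES_TREE, seed=seed,
            )
            aln = {a.label: a.sequence for a in alleles}
            labels = {a.label: (a.species_id, a.allele_class) for a in alleles}
            tree, supports = bootstrap_supports(aln, 100, seed)
            if classify_topology(tree, labels, 50, supports) == expected:
                hits += 1
        assert hits >= n - 1


class TestK2PHypothesis:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @staticmethod
    def _mutated_pair(draw):
        from hypothesis import strategies as st

        n = draw(st.integers(min_value=20, max_value=150))
        a = draw(st.text(alphabet="ACGT", min_size=n, max_size=n))
        k = draw(st.integers(min_value=0, max_value=n))
        positions = draw(
            st.lists(st.integers(0, n - 1), min_size=k, max_size=k,
                     unique=True)
        )
        bases = draw(st.lists(st.sampled_from("ACGT"), min_size=k, max_size=k))
        b = list(a)
        for p, base in zip(positions, bases):
            b[p] = base
        return a, "".join(b)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_metric_properties(self, data):
        a, b = self._mutated_pair(data.draw)
        try:
            d_ab = k2p_distance(a, b)
        except SaturationError:
            with pytest.raises(SaturationError):
                k2p_distance(b, a)
            return
        assert d_ab == k2p_distance(b, a)
        assert d_ab >= 0
        assert (d_ab == 0) == (a == b)
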