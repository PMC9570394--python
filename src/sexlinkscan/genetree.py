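"""Gametolog gene trees: K2P distances, NJ with bootstrap, topology tests.

The in-silico test for ongoing X–Y recombination compares, for a locus that is
sex-linked in a focal species, the genealogy of that locus' haplotypes across
several species.  If recombination between X and Y stopped in the common
ancestor of the sampled species, X- and Y-borne copies (gametologs) diverge
independently and the tree clusters by gametolog: all Y alleles form a clade
across species.  If X–Y recombination is ongoing outside the sex-determining
region, the Y copy is continually homogenised with the X pool within each
species, and the tree clusters by species instead.

The tree engine here is neighbour joining on Kimura two-parameter distances
with nonparametric bootstrap over alignment columns.  Externally estimated
trees (e.g. maximum likelihood) can be supplied as Newick and classified with
the same topology rules (``method="external"``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import LocusCatalog, Sex, SexRegistry, read_newick
from .search import approx_evalue

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleSequence",
    "GeneTreeResult",
    "k2p_distance",
    "k2p_matrix",
    "nj_tree",
    "tree_bipartitions",
    "bootstrap_supports",
    "classify_topology",
    "retrieve_homologs",
    "build_multilocus_trees",
    "SaturationError",
]

# Distance substituted for a saturated pair inside bootstrap replicates only,
# where a hard error would abort the whole resampling run.
_BOOTSTRAP_SATURATION_CEILING = 10.0

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """K2P distance undefined: observed divergence beyond the model's domain."""


# ---------------------------------------------------------------------------
# Allele sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleSequence:
    """One haplotype of one individual at one locus, with its gametolog label.

    ``allele_class`` is ``"X"``, ``"Y"`` or ``"unphased"``; Y is only
    assignable for males (the haplotype carrying a validated male-limited
    allele).  ``copy`` (1 or 2) is the diploid haplotype slot, so an
    individual's two same-class copies get distinct labels.  The tip label
    encodes species, sex, individual, allele and copy, e.g. ``spA-M03-Y2``.
    """

    species_id: str
    sample_id: str
    sex: Sex
    allele_class: str
    sequence: str
    locus_id: str
    copy: int = 1

    def __post_init__(self) -> None:
        if self.allele_class not in {"X", "Y", "unphased"}:
            raise ValueError(f"bad allele_class {self.allele_class!r}")
        if self.allele_class == "Y" and self.sex is not Sex.MALE:
            raise ValueError("Y allele class is only assignable to males")

    @property
    def label(self) -> str:
        sex_code = "M" if self.sex is Sex.MALE else "F"
        allele = {"X": "X", "Y": "Y", "unphased": "U"}[self.allele_class]
        return f"{self.species_id}-{sex_code}{self.sample_id}-{allele}{self.copy}"


# ---------------------------------------------------------------------------
# K2P distance
# ---------------------------------------------------------------------------

def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype="S1")


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`` with P and Q the transition
    and transversion proportions over pairwise-comparable sites (positions
    where either sequence has a gap or non-ACGT code are excluded).

    Raises
    ------
    SaturationError
        when ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a, b = _seq_array(seq_a), _seq_array(seq_b)
    valid = np.isin(a, (b"A", b"C", b"G", b"T")) & np.isin(b, (b"A", b"C", b"G", b"T"))
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable sites")
    a, b = a[valid], b[valid]
    diff = a != b
    if not diff.any():
        return 0.0
    purine_a = np.isin(a, (b"A", b"G"))
    purine_b = np.isin(b, (b"A", b"G"))
    transitions = int((diff & (purine_a == purine_b)).sum())
    transversions = int((diff & (purine_a != purine_b)).sum())
    p = transitions / n
    q = transversions / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"saturated pair (P={p:.3f}, Q={q:.3f}): K2P distance undefined"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _encode_alignment(alignment: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    labels = sorted(alignment)
    lengths = {len(alignment[lab]) for lab in labels}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal length")
    # 0..3 = A,C,G,T; 255 = excluded (gap/ambiguity)
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    mat = np.vstack([
        lut[np.frombuffer(alignment[lab].upper().encode("ascii"), dtype=np.uint8)]
        for lab in labels
    ])
    return labels, mat


def _k2p_from_encoded(
    mat: np.ndarray, saturation_ceiling: float | None
) -> np.ndarray:
    """Vectorised all-pairs K2P over an encoded alignment (taxa x columns)."""
    valid = mat != 255
    purine = (mat == 0) | (mat == 2)  # A or G
    v = valid.astype(np.float64)
    n_comp = v @ v.T
    if np.any(n_comp == 0):
        raise ValueError("no comparable sites for some pair")
    # pairwise differing-site counts, split into transitions/transversions
    n_taxa = mat.shape[0]
    diff = (mat[:, None, :] != mat[None, :, :]) & valid[:, None, :] & valid[None, :, :]
    same_class = purine[:, None, :] == purine[None, :, :]
    ts = (diff & same_class).sum(axis=2)
    tv = (diff & ~same_class).sum(axis=2)
    p = ts / n_comp
    q = tv / n_comp
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    saturated = (w1 <= 0.0) | (w2 <= 0.0)
    if saturated.any():
        if saturation_ceiling is None:
            raise SaturationError("saturated pair(s): K2P distance undefined")
        w1 = np.where(saturated, 1.0, w1)
        w2 = np.where(saturated, 1.0, w2)
    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    if saturated.any():
        d[saturated] = saturation_ceiling
    np.fill_diagonal(d, 0.0)
    return d


def k2p_matrix(
    alignment: Mapping[str, str],
    *,
    saturation_ceiling: float | None = None,
) -> tuple[list[str], np.ndarray]:
    """Pairwise K2P matrix over an alignment, labels sorted for determinism.

    ``saturation_ceiling`` substitutes a large finite distance for saturated
    pairs instead of raising (used inside bootstrap replicates).
    """
    labels, mat = _encode_alignment(alignment)
    return labels, _k2p_from_encoded(mat, saturation_ceiling)


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def nj_tree(
    distances: np.ndarray | Sequence[Sequence[float]],
    labels: Sequence[str],
) -> dendropy.Tree:
    """Saitou–Nei neighbour joining.

    Deterministic: ties in the Q criterion are broken by the lexicographic
    order of each cluster's smallest member label.  Negative branch lengths
    are clamped to zero with the deficit moved onto the sister edge, so the
    joined pair's path length is preserved.  The returned tree is rooted at
    the final join (a trifurcation for >= 3 taxa) and should be read as
    unrooted.
    """
    d = np.asarray(distances, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if n < 2:
        raise ValueError("need at least two taxa")
    if len(set(labels)) != n:
        raise ValueError("duplicate taxon labels")

    # Process taxa in sorted order so output is invariant to input order.
    order = sorted(range(n), key=lambda i: labels[i])
    d = d[np.ix_(order, order)].copy()
    names = [labels[i] for i in order]

    taxa = dendropy.TaxonNamespace(names)
    nodes: list[dendropy.Node] = []
    reps: list[str] = []  # smallest leaf label per active cluster
    for name in names:
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(node)
        reps.append(name)

    def _join(i: int, j: int, li: float, lj: float) -> None:
        nonlocal d, nodes, reps
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        m = d.shape[0]
        keep = [k for k in range(m) if k not in (i, j)]
        new_row = np.array([(d[i, k] + d[j, k] - d[i, j]) / 2.0 for k in keep])
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    while len(nodes) > 3:
        m = d.shape[0]
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        qvals = q[iu]
        qmin = qvals.min()
        # among exact minima, break ties by lexicographic representative pair
        best = None
        for flat in np.nonzero(qvals == qmin)[0]:
            i, j = int(iu[0][flat]), int(iu[1][flat])
            key = tuple(sorted((reps[i], reps[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        _join(i, j, li, lj)

    root = dendropy.Node()
    if len(nodes) == 2:
        half = d[0, 1] / 2.0
        for k in (0, 1):
            root.add_child(nodes[k])
            nodes[k].edge.length = half
    else:  # final 3-way join
        for k, (a, b, c) in enumerate([(0, 1, 2), (1, 0, 2), (2, 0, 1)]):
            length = (d[a, b] + d[a, c] - d[b, c]) / 2.0
            root.add_child(nodes[k])
            nodes[k].edge.length = max(length, 0.0)

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    # an internal edge of exactly zero length carries no signal: collapse it,
    # so an all-zero matrix yields a star tree
    for node in list(tree.preorder_node_iter()):
        if (
            node.parent_node is not None
            and not node.is_leaf()
            and node.edge.length == 0.0
        ):
            node.edge.collapse()
    return tree


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap
# ---------------------------------------------------------------------------

def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _canonical_split(side: frozenset[str], all_tips: frozenset[str]) -> frozenset[str]:
    """Encode an unrooted bipartition as the side not containing the
    lexicographically smallest tip."""
    anchor = min(all_tips)
    return frozenset(all_tips - side) if anchor in side else side


def tree_bipartitions(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Non-trivial bipartitions of a tree, canonically encoded.

    Maps each split (the side without the lexicographically smallest taxon)
    to the child node of its edge.
    """
    all_tips = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = _leafset(node)
        if len(side) < 2 or len(all_tips) - len(side) < 2:
            continue
        out[_canonical_split(side, all_tips)] = node
    return out


def bootstrap_supports(
    alignment: Mapping[str, str],
    n_replicates: int,
    seed: int,
    tree_builder: Callable[[Mapping[str, str]], dendropy.Tree] | None = None,
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """Point-estimate tree plus column-resampling bootstrap supports.

    Supports are the percentage of replicate trees containing each internal
    bipartition of the point tree and are written onto the point tree's
    internal node labels.  Deterministic given ``seed``; invariant to taxon
    input order because all processing is over sorted labels.  An alignment
    with no variable columns yields a star-like tree whose splits all receive
    the supports of arbitrary resolutions; callers can detect this via zero
    pairwise distances.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels, mat = _encode_alignment(alignment)
    n_cols = mat.shape[1]

    fast_path = tree_builder is None
    if fast_path:
        def tree_builder(aln: Mapping[str, str]) -> dendropy.Tree:
            labs, d = k2p_matrix(
                aln, saturation_ceiling=_BOOTSTRAP_SATURATION_CEILING
            )
            return nj_tree(d, labs)

    point_tree = tree_builder(alignment)
    point_splits = tree_bipartitions(point_tree)
    counts = {split: 0 for split in point_splits}

    char_arrays = {lab: _seq_array(alignment[lab]) for lab in labels}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        if fast_path:
            d = _k2p_from_encoded(mat[:, cols], _BOOTSTRAP_SATURATION_CEILING)
            rep_tree = nj_tree(d, labels)
        else:
            rep_aln = {
                lab: char_arrays[lab][cols].tobytes().decode("ascii")
                for lab in labels
            }
            rep_tree = tree_builder(rep_aln)
        rep_splits = tree_bipartitions(rep_tree)
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    supports = {
        split: 100.0 * c / n_replicates for split, c in counts.items()
    }
    for split, node in point_splits.items():
        node.label = str(int(round(supports[split])))
    return point_tree, supports


# ---------------------------------------------------------------------------
# Topology classification
# ---------------------------------------------------------------------------

def _supports_from_tree(tree: dendropy.Tree) -> dict[frozenset[str], float]:
    out = {}
    for split, node in tree_bipartitions(tree).items():
        try:
            out[split] = float(node.label)
        except (TypeError, ValueError):
            out[split] = 100.0  # unlabelled internal edge: topology taken as given
    return out


def classify_topology(
    tree: dendropy.Tree,
    labels: Mapping[str, tuple[str, str]],
    support_threshold: float = 50.0,
    supports: Mapping[frozenset[str], float] | None = None,
) -> str:
    """Classify a gene tree as gametolog- vs species-clustered.

    ``labels`` maps each tip label to ``(species_id, allele_class)``.

    * ``gametolog_clustered``: the Y-class tips span >= 2 species and form one
      side of a supported bipartition (monophyly in the unrooted sense).
    * ``species_clustered``: every species' tip set is monophyletic with
      support, and at least one species contributes both X and Y tips.
    * otherwise ``unresolved``.

    Single-tip (or complement-single) groups are trivially monophyletic.
    """
    all_tips = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    missing = all_tips - set(labels)
    if missing:
        raise ValueError(f"tips without labels: {sorted(missing)[:5]}")
    species = {labels[t][0] for t in all_tips}
    if len(species) < 2:
        raise ValueError("classification needs tips from >= 2 species")
    if supports is None:
        supports = _supports_from_tree(tree)

    def clade_supported(tipset: frozenset[str]) -> bool:
        if len(tipset) <= 1 or len(all_tips - tipset) <= 1:
            return True
        split = _canonical_split(tipset, all_tips)
        return split in supports and supports[split] >= support_threshold

    y_tips = frozenset(t for t in all_tips if labels[t][1] == "Y")
    y_species = {labels[t][0] for t in y_tips}
    gametolog = len(y_species) >= 2 and clade_supported(y_tips)

    per_species: dict[str, set[str]] = {}
    for t in all_tips:
        per_species.setdefault(labels[t][0], set()).add(t)
    mixed = any(
        {"X", "Y"} <= {labels[t][1] for t in tips} for tips in per_species.values()
    )
    species_clustered = mixed and all(
        clade_supported(frozenset(tips)) for tips in per_species.values()
    )

    if gametolog and species_clustered:
        # Geometrically impossible when >= 2 species carry non-Y tips.
        non_y_species = {labels[t][0] for t in all_tips if labels[t][1] != "Y"}
        assert len(non_y_species) < 2, "contradictory clustering classification"
    if gametolog:
        return "gametolog_clustered"
    if species_clustered:
        return "species_clustered"
    return "unresolved"


@dataclass
class GeneTreeResult:
    """A labelled gene tree with bootstrap supports and its classification."""

    tree: dendropy.Tree
    supports: dict[frozenset[str], float]
    method: str  # "NJ" or "external"
    classification: str
    support_threshold: float
    locus_ids: tuple[str, ...] = ()
    tip_labels: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def newick(self) -> str:
        from .io_formats import write_newick

        return write_newick(self.tree)


def classify_external_tree(
    newick: str,
    labels: Mapping[str, tuple[str, str]],
    support_threshold: float = 50.0,
) -> GeneTreeResult:
    """Classify an externally estimated tree (e.g. ML) supplied as Newick."""
    tree = read_newick(newick)
    supports = _supports_from_tree(tree)
    cls = classify_topology(tree, labels, support_threshold, supports)
    return GeneTreeResult(
        tree=tree,
        supports=supports,
        method="external",
        classification=cls,
        support_threshold=support_threshold,
        tip_labels=dict(labels),
    )


# ---------------------------------------------------------------------------
# Homolog retrieval
# ---------------------------------------------------------------------------

def _ungapped_identity(a: str, b: str) -> int:
    return sum(x == y for x, y in zip(a, b))


def _best_homolog(
    query: str, catalog: LocusCatalog, evalue_cutoff: float
) -> str | None:
    """Best same-length locus by full-length ungapped comparison, both strands.

    The score is a crude bit approximation (+2 per match, -3 per mismatch)
    feeding the same Karlin–Altschul-style E-value used by the exact matcher;
    it exists so the E <= cutoff retention rule runs on the in-package path.
    """
    from .io_formats import revcomp

    db_len = sum(len(loc.consensus) for loc in catalog)
    best: tuple[float, float, str] | None = None
    for loc in catalog:
        if len(loc.consensus) != len(query):
            continue
        ident = max(
            _ungapped_identity(query, loc.consensus),
            _ungapped_identity(query, revcomp(loc.consensus)),
        )
        mism = len(query) - ident
        bits = 2.0 * ident - 3.0 * mism
        if bits <= 0:
            continue
        log10e = math.log10(max(len(query), 1)) + math.log10(max(db_len, 1)) \
            - bits * math.log10(2.0)
        evalue = 10.0 ** max(log10e, -300.0)
        key = (evalue, -ident, loc.locus_id)
        if best is None or key < (best[0], -best[1], best[2]):
            if evalue <= evalue_cutoff:
                best = (evalue, ident, loc.locus_id)
    return best[2] if best else None


def _phased_alleles(
    locus, sample: str, sex: Sex, species: str,
    column: int | None, sex_allele: str | None,
) -> list[AlleleSequence]:
    haps = locus.haplotypes(sample)
    if haps is None:
        return []
    out = []
    for slot, hap in enumerate(haps, start=1):
        if sex is Sex.FEMALE:
            cls = "X" if sex_allele is not None else "unphased"
        elif sex_allele is None or column is None:
            cls = "unphased"
        else:
            cls = "Y" if hap[column] == sex_allele else "X"
        out.append(
            AlleleSequence(
                species_id=species, sample_id=sample, sex=sex,
                allele_class=cls, sequence=hap, locus_id=locus.locus_id,
                copy=slot,
            )
        )
    return out


def retrieve_homologs(
    marker,
    catalogs: Mapping[str, LocusCatalog],
    registry: SexRegistry,
    focal_species: str,
    markers_by_species: Mapping[str, object] | None = None,
    evalue_cutoff: float = 1e-20,
) -> list[AlleleSequence]:
    """Haplotypes of a sex-linked locus and its cross-species homologs.

    The focal species' haplotypes are phased by the marker's sex-specific
    allele: the male haplotype carrying it is Y, the other X; females are X.
    Other species contribute the per-individual haplotypes of their best-hit
    homologous locus (E <= cutoff), labelled unphased — unless that species
    itself has a confirmed marker at the homologous locus (supplied via
    ``markers_by_species``), in which case its haplotypes are phased the same
    way.  Species with no qualifying homolog are omitted and logged.

    Catalog loci are fixed-length tags; homology search compares equal-length
    loci only.
    """
    focal_catalog = catalogs[focal_species]
    locus = focal_catalog[marker.locus_id]
    column = getattr(marker, "site", None)
    sex_allele = getattr(marker, "sex_specific_allele", None)
    phase_info: dict[str, tuple[str, int | None, str | None]] = {
        focal_species: (marker.locus_id, column, sex_allele)
    }
    if markers_by_species:
        for sp, mk in markers_by_species.items():
            if sp == focal_species or sp not in catalogs:
                continue
            phase_info[sp] = (
                mk.locus_id,
                getattr(mk, "site", None),
                getattr(mk, "sex_specific_allele", None),
            )

    out: list[AlleleSequence] = []
    for species in sorted(catalogs):
        catalog = catalogs[species]
        if species in phase_info:
            locus_id, col, allele = phase_info[species]
        else:
            locus_id = _best_homolog(locus.consensus, catalog, evalue_cutoff)
            if locus_id is None:
                logger.info(
                    "no homolog of %s at E<=%g in species %s; omitted",
                    marker.locus_id, evalue_cutoff, species,
                )
                continue
            col = allele = None
        target = catalog[locus_id]
        for sample in catalog.samples:
            out.extend(
                _phased_alleles(
                    target, sample, registry.sex_of(sample), species, col, allele
                )
            )
    return out


# ---------------------------------------------------------------------------
# Single- and multi-locus tree building
# ---------------------------------------------------------------------------

def _tree_from_alleles(
    alleles: Sequence[AlleleSequence],
    n_bootstrap: int,
    seed: int,
    support_threshold: float,
    locus_ids: tuple[str, ...],
) -> GeneTreeResult:
    alignment = {a.label: a.sequence for a in alleles}
    if len(alignment) != len(alleles):
        raise ValueError("duplicate tip labels among allele sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("allele sequences differ in length; expected fixed-length tags")
    labels = {a.label: (a.species_id, a.allele_class) for a in alleles}
    tree, supports = bootstrap_supports(alignment, n_bootstrap, seed)
    cls = classify_topology(tree, labels, support_threshold, supports)
    return GeneTreeResult(
        tree=tree,
        supports=supports,
        method="NJ",
        classification=cls,
        support_threshold=support_threshold,
        locus_ids=locus_ids,
        tip_labels=labels,
    )


def build_multilocus_trees(
    markers: Sequence,
    catalogs: Mapping[str, LocusCatalog],
    registry: SexRegistry,
    focal_species: str,
    *,
    markers_by_species_per_locus: Sequence[Mapping[str, object]] | None = None,
    n_bootstrap: int = 100,
    seed: int = 0,
    support_threshold: float = 50.0,
    evalue_cutoff: float = 1e-20,
) -> dict:
    """Per-locus and concatenated gene trees for 1..k sex-linked loci.

    For multi-locus runs the per-locus alignments are concatenated over the
    set of (species, sample) pairs present at every locus before distance
    computation; haplotype pairing across loci follows the phased X/Y labels
    where available and sorted order otherwise.  With a single locus the
    concatenated analysis is identical to the per-locus one.
    Returns ``{"per_locus": [GeneTreeResult...], "concatenated": GeneTreeResult | None}``.
    """
    per_locus_alleles: list[list[AlleleSequence]] = []
    for i, marker in enumerate(markers):
        by_sp = (
            markers_by_species_per_locus[i] if markers_by_species_per_locus else None
        )
        per_locus_alleles.append(
            retrieve_homologs(
                marker, catalogs, registry, focal_species,
                markers_by_species=by_sp, evalue_cutoff=evalue_cutoff,
            )
        )

    results = [
        _tree_from_alleles(
            alleles, n_bootstrap, seed + i, support_threshold,
            (markers[i].locus_id,),
        )
        for i, alleles in enumerate(per_locus_alleles)
    ]

    if len(markers) == 1:
        return {"per_locus": results, "concatenated": results[0]}

    concatenated = None
    keys_per_locus = [
        {(a.species_id, a.sample_id) for a in alleles}
        for alleles in per_locus_alleles
    ]
    shared = set.intersection(*keys_per_locus) if keys_per_locus else set()
    if shared:
        # slot 0/1 per individual: (Y, X) when phased, sorted haplotypes otherwise
        def slots(alleles: list[AlleleSequence]):
            by_ind: dict[tuple[str, str], list[AlleleSequence]] = {}
            for a in alleles:
                if (a.species_id, a.sample_id) in shared:
                    by_ind.setdefault((a.species_id, a.sample_id), []).append(a)
            out = {}
            for key, pair in by_ind.items():
                pair.sort(key=lambda a: (a.allele_class != "Y", a.sequence))
                out[key] = pair
            return out

        per_locus_slots = [slots(a) for a in per_locus_alleles]
        merged: list[AlleleSequence] = []
        ok = True
        for key in sorted(shared):
            n_haps = {len(s[key]) for s in per_locus_slots}
            if n_haps != {2}:
                ok = False
                break
            for slot in (0, 1):
                parts = [s[key][slot] for s in per_locus_slots]
                classes = {p.allele_class for p in parts}
                cls = classes.pop() if len(classes) == 1 else "unphased"
                first = parts[0]
                merged.append(
                    AlleleSequence(
                        species_id=first.species_id,
                        sample_id=first.sample_id,
                        sex=first.sex,
                        allele_class=cls,
                        sequence="".join(p.sequence for p in parts),
                        locus_id="+".join(p.locus_id for p in parts),
                    )
                )
        if ok and merged:
            concatenated = _tree_from_alleles(
                merged, n_bootstrap, seed + len(markers), support_threshold,
                tuple(m.locus_id for m in markers),
            )
    else:
        logger.info("no samples shared across loci; reporting per-locus trees only")

    return {"per_locus": results, "concatenated": concatenated}
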