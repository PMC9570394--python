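"""Synthetic multi-species RAD/GBS catalogs with known ground truth.

Generates what the field's reduced-representation pipelines emit — per-species
locus catalogs (consensus tag, per-individual diploid genotypes, per-individual
presence/depth) — with sex-linked structure planted by construction:

* ``xy_snp`` loci: before error injection every female is homozygous and every
  male heterozygous for a male-limited allele (the Y allele); mirrored for ZW
  species (``zw_snp``).
* ``y_limited`` / ``w_limited`` loci: present only in the heterogametic sex.
* ``autosomal`` loci: sex-independent genotypes drawn at a configurable minor
  allele frequency under Hardy–Weinberg proportions.
* ``ancestral_sdr`` loci: one homologous, sex-linked tag shared across a
  configured subset of species, emulating a sex-determining region that
  predates their divergence.

Every locus consensus is embedded at a recorded position in a synthetic
reference genome on its true chromosome, so mapping-stage accuracy is checkable
against the truth table.  Sequence evolution (for cross-species homologs and
the two gene-history scenarios) places Poisson(rate x branch length)
substitutions per branch under Kimura's two-parameter process with a
configurable transition/transversion ratio, so downstream K2P distance
estimation is self-consistent.

All randomness flows from one integer seed through ``numpy.random.default_rng``
(an integer-state generator with a documented algorithm), making outputs
reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .genetree import AlleleSequence
from .io_formats import (
    Locus,
    LocusCatalog,
    ReferenceGenome,
    RegistryEntry,
    Sex,
    SexRegistry,
    SnpSite,
    read_newick,
)

__all__ = [
    "SimulationConfig",
    "LocusTruth",
    "TruthTable",
    "SimulatedStudy",
    "simulate_catalog",
    "simulate_reads",
    "simulate_gene_history",
    "DEFAULT_SPECIES_TREE",
]

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}

# Nine-tip demo phylogeny: one eastern-clade species sister to eight western
# ones, ultrametric with root-to-tip depth 1.0 branch-length units.
DEFAULT_SPECIES_TREE = (
    "(sp1:1.0,((sp2:0.45,sp3:0.45):0.45,((sp4:0.45,sp5:0.45):0.3,"
    "((sp6:0.45,sp7:0.45):0.15,(sp8:0.45,sp9:0.45):0.15):0.15):0.15):0.1);"
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic catalogs.

    Defaults emulate the source study's sampling design: nine species, ten
    males and ten females per species, 150 bp tags (paired-end 150 GBS), an
    XY system in every species.  Noise knobs default to zero; they are free
    parameters, not estimates of any real dataset's noise.
    """

    n_species: int = 9
    n_males: int = 10
    n_females: int = 10
    n_autosomal_loci: int = 100
    n_xy_snp_loci: int = 30
    n_y_limited_loci: int = 10
    system: str | Mapping[str, str] = "XY"  # per-species "XY" / "ZW"
    genotyping_error_rate: float = 0.0
    locus_dropout_rate: float = 0.0
    locus_length: int = 150
    mutation_rate: float = 0.15  # substitutions / site / branch-length unit
    ts_tv_ratio: float = 2.0
    minor_allele_frequency: float = 0.2
    species_tree: str = DEFAULT_SPECIES_TREE
    sdr_shared_species: tuple[str, ...] = ()
    sex_chromosome: str | Mapping[str, str] = "chr5"
    n_autosomes: int = 3
    seed: int = 0

    species_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.species_names:
            self.species_names = tuple(f"sp{i + 1}" for i in range(self.n_species))
        self.n_species = len(self.species_names)
        for name, rate in [
            ("genotyping_error_rate", self.genotyping_error_rate),
            ("locus_dropout_rate", self.locus_dropout_rate),
            ("minor_allele_frequency", self.minor_allele_frequency),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("every species needs at least one male and one female")
        unknown = set(self.sdr_shared_species) - set(self.species_names)
        if unknown:
            raise ValueError(f"sdr_shared_species not in species set: {sorted(unknown)}")
        if len(self.sdr_shared_species) == 1:
            raise ValueError("sdr_shared_species needs >= 2 species (or none)")

    def system_of(self, species: str) -> str:
        if isinstance(self.system, str):
            return self.system
        return self.system.get(species, "XY")

    def sex_chromosome_of(self, species: str) -> str:
        if isinstance(self.sex_chromosome, str):
            return self.sex_chromosome
        return self.sex_chromosome.get(species, "chr5")


@dataclass(frozen=True)
class LocusTruth:
    species_id: str
    locus_id: str
    locus_class: str  # autosomal | xy_snp | zw_snp | y_limited | w_limited | ancestral_sdr
    sex_linked: bool
    chromosome: str
    position: int  # 0-based offset of the consensus on its chromosome
    unified_id: str | None = None  # cross-species homology family

    _CLASSES = frozenset(
        {"autosomal", "xy_snp", "zw_snp", "y_limited", "w_limited", "ancestral_sdr"}
    )

    def __post_init__(self) -> None:
        if self.locus_class not in self._CLASSES:
            raise ValueError(f"unknown locus class {self.locus_class!r}")


@dataclass
class TruthTable:
    records: list[LocusTruth] = field(default_factory=list)

    def for_species(self, species: str) -> list[LocusTruth]:
        return [r for r in self.records if r.species_id == species]

    def sex_linked_ids(self, species: str) -> set[str]:
        return {r.locus_id for r in self.for_species(species) if r.sex_linked}

    def classes(self, species: str) -> dict[str, str]:
        return {r.locus_id: r.locus_class for r in self.for_species(species)}

    def unified_map(self) -> dict[str, dict[str, str]]:
        """unified id -> {species -> locus id} over homology families."""
        out: dict[str, dict[str, str]] = {}
        for r in self.records:
            if r.unified_id is not None:
                out.setdefault(r.unified_id, {})[r.species_id] = r.locus_id
        return out


@dataclass
class SimulatedStudy:
    catalogs: dict[str, LocusCatalog]
    registry: SexRegistry
    truth: TruthTable
    reference: ReferenceGenome
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Sequence evolution (K2P substitution process)
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _evolve(
    seq: str, branch_length: float, rate: float, ts_tv: float,
    rng: np.random.Generator,
) -> str:
    """Apply Poisson(rate * branch_length * L) substitutions, transitions
    favoured ts_tv : 1 over (either) transversion."""
    n_sub = rng.poisson(rate * branch_length * len(seq))
    if n_sub == 0:
        return seq
    out = list(seq)
    p_ts = ts_tv / (ts_tv + 1.0)
    for _ in range(n_sub):
        pos = int(rng.integers(0, len(out)))
        base = out[pos]
        if base not in _TRANSITION:
            continue
        if rng.random() < p_ts:
            out[pos] = _TRANSITION[base]
        else:
            out[pos] = _TRANSVERSIONS[base][int(rng.integers(0, 2))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Catalog simulation
# ---------------------------------------------------------------------------

def _make_registry(config: SimulationConfig) -> SexRegistry:
    entries = []
    for sp in config.species_names:
        for i in range(config.n_males):
            entries.append(RegistryEntry(f"{sp}_M{i + 1:02d}", sp, Sex.MALE))
        for i in range(config.n_females):
            entries.append(RegistryEntry(f"{sp}_F{i + 1:02d}", sp, Sex.FEMALE))
    return SexRegistry(entries)


def _hwe_genotype(rng, ref: str, alt: str, maf: float) -> tuple[str, str]:
    a = alt if rng.random() < maf else ref
    b = alt if rng.random() < maf else ref
    return (a, b) if a <= b else (b, a)


def _pick_alt(rng, ref: str, ts_tv: float) -> str:
    if rng.random() < ts_tv / (ts_tv + 1.0):
        return _TRANSITION[ref]
    return _TRANSVERSIONS[ref][int(rng.integers(0, 2))]


def _inject_noise(
    rng, genotypes: dict[str, tuple[str, str] | None],
    alleles: Sequence[str], error_rate: float,
) -> None:
    """Genotyping error model: with probability ``error_rate`` per called
    genotype, one uniformly chosen allele copy is redrawn uniformly from the
    site's allele set (so a call changes with probability
    ``error_rate * (k-1)/k`` for k alleles)."""
    if error_rate <= 0:
        return
    alleles = sorted(alleles)
    for sample, gt in genotypes.items():
        if gt is None or rng.random() >= error_rate:
            continue
        copy = int(rng.integers(0, 2))
        new = alleles[int(rng.integers(0, len(alleles)))]
        pair = list(gt)
        pair[copy] = new
        pair.sort()
        genotypes[sample] = (pair[0], pair[1])


def simulate_catalog(config: SimulationConfig) -> SimulatedStudy:
    """Generate per-species catalogs, registry, truth table and reference.

    Deterministic given ``config.seed``.  Before noise injection, planted
    sex-linked SNP loci satisfy the perfect pattern (every heterogametic-sex
    individual heterozygous for a sex-limited allele, every homogametic-sex
    individual homozygous); sex-limited loci are present only in the
    heterogametic sex.
    """
    rng = np.random.default_rng(config.seed)
    registry = _make_registry(config)
    tree = read_newick(config.species_tree)
    tree_species = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if config.sdr_shared_species and not set(config.sdr_shared_species) <= tree_species:
        raise ValueError("sdr_shared_species must be tips of the species tree")

    truth_records: list[LocusTruth] = []
    catalogs: dict[str, LocusCatalog] = {}
    # chromosome -> list of (species, locus_id, consensus); embedding deferred
    placements: dict[str, list[tuple[str, str, str]]] = {}

    # Shared ancestral-SDR family: one homologous tag, diverged per species.
    sdr_consensus: dict[str, tuple[str, int, str, str]] = {}
    if config.sdr_shared_species:
        L = config.locus_length
        col = int(rng.integers(0, L))
        ancestral = _random_seq(rng, L)
        ref_allele = ancestral[col]
        alt_allele = _pick_alt(rng, ref_allele, config.ts_tv_ratio)
        for sp in config.sdr_shared_species:
            # small per-species divergence outside the diagnostic column
            seq = _evolve(ancestral, 0.3, config.mutation_rate / 2,
                          config.ts_tv_ratio, rng)
            seq = seq[:col] + ref_allele + seq[col + 1:]
            sdr_consensus[sp] = (seq, col, ref_allele, alt_allele)

    for sp in config.species_names:
        samples = registry.samples(sp)
        males = registry.samples(sp, Sex.MALE)
        females = registry.samples(sp, Sex.FEMALE)
        system = config.system_of(sp)
        # heterogametic/homogametic role assignment; one code path for ZW
        het_sex_samples, hom_sex_samples = (
            (males, females) if system == "XY" else (females, males)
        )
        sex_chrom = config.sex_chromosome_of(sp)
        loci: list[Locus] = []

        def add_locus(lid, consensus, sites, presence, depth, lclass,
                      chrom, unified=None):
            loci.append(
                Locus(locus_id=lid, consensus=consensus, snp_sites=sites,
                      presence=presence, depth=depth)
            )
            placements.setdefault(chrom, []).append((sp, lid, consensus))
            truth_records.append(
                LocusTruth(
                    species_id=sp, locus_id=lid, locus_class=lclass,
                    sex_linked=lclass != "autosomal", chromosome=chrom,
                    position=-1, unified_id=unified,
                )
            )

        def full_presence():
            pres = {s: True for s in samples}
            depth = {s: int(rng.integers(5, 60)) for s in samples}
            return pres, depth

        def apply_dropout(pres, depth, genotypes_by_site):
            if config.locus_dropout_rate <= 0:
                return
            for s in samples:
                if pres[s] and rng.random() < config.locus_dropout_rate:
                    pres[s] = False
                    depth[s] = 0
                    for gts in genotypes_by_site:
                        gts[s] = None

        def sexlinked_site(lid, consensus, col, ref, alt):
            genotypes: dict[str, tuple[str, str] | None] = {}
            for s in het_sex_samples:
                genotypes[s] = tuple(sorted((ref, alt)))
            for s in hom_sex_samples:
                genotypes[s] = (ref, ref)
            _inject_noise(rng, genotypes, (ref, alt), config.genotyping_error_rate)
            return SnpSite(locus_id=lid, column=col,
                           alleles=frozenset((ref, alt)), genotypes=genotypes)

        # planted sex-linked SNP loci
        n_private = config.n_xy_snp_loci - (1 if sp in sdr_consensus else 0)
        for k in range(max(n_private, 0)):
            lid = f"{sp}_sex{k + 1:04d}"
            consensus = _random_seq(rng, config.locus_length)
            col = int(rng.integers(0, config.locus_length))
            ref = consensus[col]
            alt = _pick_alt(rng, ref, config.ts_tv_ratio)
            site = sexlinked_site(lid, consensus, col, ref, alt)
            pres, depth = full_presence()
            apply_dropout(pres, depth, [site.genotypes])
            lclass = "xy_snp" if system == "XY" else "zw_snp"
            add_locus(lid, consensus, [site], pres, depth, lclass, sex_chrom)

        if sp in sdr_consensus:
            seq, col, ref, alt = sdr_consensus[sp]
            lid = f"{sp}_sdr0001"
            site = sexlinked_site(lid, seq, col, ref, alt)
            pres, depth = full_presence()
            apply_dropout(pres, depth, [site.genotypes])
            add_locus(lid, seq, [site], pres, depth, "ancestral_sdr",
                      sex_chrom, unified="sdr_family_1")

        # sex-limited tags: present only in the heterogametic sex
        for k in range(config.n_y_limited_loci):
            lid = f"{sp}_lim{k + 1:04d}"
            consensus = _random_seq(rng, config.locus_length)
            pres = {s: s in set(het_sex_samples) for s in samples}
            depth = {s: int(rng.integers(5, 60)) if pres[s] else 0 for s in samples}
            apply_dropout(pres, depth, [])
            lclass = "y_limited" if system == "XY" else "w_limited"
            add_locus(lid, consensus, [], pres, depth, lclass, sex_chrom)

        # autosomal background
        for k in range(config.n_autosomal_loci):
            lid = f"{sp}_aut{k + 1:05d}"
            consensus = _random_seq(rng, config.locus_length)
            col = int(rng.integers(0, config.locus_length))
            ref = consensus[col]
            alt = _pick_alt(rng, ref, config.ts_tv_ratio)
            genotypes = {
                s: _hwe_genotype(rng, ref, alt, config.minor_allele_frequency)
                for s in samples
            }
            _inject_noise(rng, genotypes, (ref, alt), config.genotyping_error_rate)
            site = SnpSite(locus_id=lid, column=col,
                           alleles=frozenset((ref, alt)), genotypes=genotypes)
            pres, depth = full_presence()
            apply_dropout(pres, depth, [site.genotypes])
            chrom = f"chr{1 + k % config.n_autosomes}"
            add_locus(lid, consensus, [site], pres, depth, "autosomal", chrom)

        catalogs[sp] = LocusCatalog(loci=loci, samples=list(samples))

    # Build the reference: loci embedded with random spacers, positions recorded.
    sequences: dict[str, str] = {}
    positions: dict[tuple[str, str], int] = {}
    for chrom in sorted(placements):
        parts: list[str] = []
        offset = 0
        for sp, lid, consensus in placements[chrom]:
            spacer = _random_seq(rng, 100)
            parts.append(spacer)
            offset += len(spacer)
            positions[(sp, lid)] = offset
            parts.append(consensus)
            offset += len(consensus)
        parts.append(_random_seq(rng, 100))
        sequences[chrom] = "".join(parts)
    reference = ReferenceGenome(sequences=sequences,
                                chromosome_names=set(sequences))

    truth = TruthTable(
        records=[
            LocusTruth(
                species_id=r.species_id, locus_id=r.locus_id,
                locus_class=r.locus_class, sex_linked=r.sex_linked,
                chromosome=r.chromosome,
                position=positions[(r.species_id, r.locus_id)],
                unified_id=r.unified_id,
            )
            for r in truth_records
        ]
    )
    return SimulatedStudy(
        catalogs=catalogs, registry=registry, truth=truth,
        reference=reference, config=config,
    )


# ---------------------------------------------------------------------------
# Read simulation (per-sex pools for in-silico verification)
# ---------------------------------------------------------------------------

def simulate_reads(
    catalog: LocusCatalog,
    registry: SexRegistry,
    coverage: int = 1,
    seed: int = 0,
) -> dict[Sex, list[tuple[str, str]]]:
    """Per-sex pooled read collections for one species' catalog.

    Each sample's recovered loci emit ``coverage`` error-free full-length
    copies of that sample's haplotypes (two per locus; both carry the same
    base at homozygous sites).  A locus absent from an individual emits
    nothing for it, so sex-limited haplotypes never enter the homogametic
    pool.  The generator is deterministic; ``seed`` is accepted for interface
    symmetry with the other simulators.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    pools: dict[Sex, list[tuple[str, str]]] = {Sex.MALE: [], Sex.FEMALE: []}
    for locus in catalog:
        for sample in catalog.samples:
            haps = locus.haplotypes(sample)
            if haps is None:
                continue
            sex = registry.sex_of(sample)
            for h_idx, hap in enumerate(haps):
                for c in range(coverage):
                    rid = f"{sample}:{locus.locus_id}:h{h_idx}:c{c}"
                    pools[sex].append((rid, hap))
    return pools


# ---------------------------------------------------------------------------
# Gene-history scenarios
# ---------------------------------------------------------------------------

def _evolve_down_tree(
    tree: dendropy.Tree, root_seq: str, rate: float, ts_tv: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Evolve a sequence down a species tree; returns tip label -> sequence.

    Children are visited in sorted-label order so the substitution history is
    reproducible regardless of Newick rotation.
    """
    tip_seqs: dict[str, str] = {}

    def rep(node) -> str:
        return min(leaf.taxon.label for leaf in node.leaf_iter())

    def walk(node, seq: str) -> None:
        for child in sorted(node.child_nodes(), key=rep):
            bl = child.edge.length or 0.0
            child_seq = _evolve(seq, bl, rate, ts_tv, rng)
            if child.is_leaf():
                tip_seqs[child.taxon.label] = child_seq
            else:
                walk(child, child_seq)

    if tree.seed_node.is_leaf():
        tip_seqs[tree.seed_node.taxon.label] = root_seq
    else:
        walk(tree.seed_node, root_seq)
    return tip_seqs


def simulate_gene_history(
    scenario: str,
    species: Sequence[str],
    tree: str | dendropy.Tree,
    mutation_rate: float = 0.15,
    seed: int = 0,
    *,
    n_males: int = 2,
    n_females: int = 2,
    locus_length: int = 150,
    ts_tv_ratio: float = 2.0,
    xy_split_depth_factor: float = 2.0,
    allele_branch_length: float = 0.02,
    individual_branch_length: float = 0.01,
    locus_id: str = "sim_locus",
) -> list[AlleleSequence]:
    """Aligned X/Y allele sequences per species under one of two histories.

    ``ancestral_suppression``: the X and Y lineages split on a stem branch
    ancestral to all selected species (length ``xy_split_depth_factor`` times
    the tree depth, i.e. a deep split), then each evolves independently down
    the species tree — the Y never recombines, so the true genealogy clusters
    by gametolog.  Every species is sex-linked; male tips carry one X and one
    Y copy (labelled), female tips two X copies.

    ``ongoing_recombination``: a single lineage evolves down the species tree;
    within each species the X and Y alleles diverge only on short terminal
    allele branches (``allele_branch_length``), emulating complete X–Y
    homogenisation up to each speciation — within-species X–Y divergence
    stays below between-species divergence and the true genealogy clusters by
    species.  Only the first (focal) species is sex-linked and phased; other
    species' copies are unphased.

    Individual copies receive ``individual_branch_length`` of private
    evolution.  Deterministic given ``seed``.
    """
    if scenario not in {"ancestral_suppression", "ongoing_recombination"}:
        raise ValueError(f"unknown scenario {scenario!r}")
    if mutation_rate < 0:
        raise ValueError("mutation rate must be non-negative")
    if len(species) < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(seed)

    full = tree if isinstance(tree, dendropy.Tree) else read_newick(tree)
    taxa = [t for t in full.taxon_namespace if t.label in set(species)]
    if len(taxa) != len(set(species)):
        missing = set(species) - {t.label for t in taxa}
        raise ValueError(f"species not in tree: {sorted(missing)}")
    pruned = full.extract_tree_with_taxa(taxa=taxa)
    depth = max(
        leaf.distance_from_root() for leaf in pruned.leaf_node_iter()
    ) or 1.0

    root_seq = _random_seq(rng, locus_length)
    out: list[AlleleSequence] = []

    def emit(sp: str, sample: str, sex: Sex, cls: str, base_seq: str,
             copy: int) -> None:
        seq = _evolve(base_seq, individual_branch_length, mutation_rate,
                      ts_tv_ratio, rng)
        out.append(
            AlleleSequence(species_id=sp, sample_id=sample, sex=sex,
                           allele_class=cls, sequence=seq, locus_id=locus_id,
                           copy=copy)
        )

    if scenario == "ancestral_suppression":
        stem = xy_split_depth_factor * depth
        x_root = _evolve(root_seq, stem, mutation_rate, ts_tv_ratio, rng)
        y_root = _evolve(root_seq, stem, mutation_rate, ts_tv_ratio, rng)
        x_tips = _evolve_down_tree(pruned, x_root, mutation_rate, ts_tv_ratio, rng)
        y_tips = _evolve_down_tree(pruned, y_root, mutation_rate, ts_tv_ratio, rng)
        for sp in sorted(species):
            for i in range(n_males):
                sid = f"{i + 1:02d}"
                emit(sp, sid, Sex.MALE, "X", x_tips[sp], 1)
                emit(sp, sid, Sex.MALE, "Y", y_tips[sp], 2)
            for i in range(n_females):
                sid = f"{n_males + i + 1:02d}"
                emit(sp, sid, Sex.FEMALE, "X", x_tips[sp], 1)
                emit(sp, sid, Sex.FEMALE, "X", x_tips[sp], 2)
    else:
        tips = _evolve_down_tree(pruned, root_seq, mutation_rate, ts_tv_ratio, rng)
        focal = species[0]
        for sp in sorted(species):
            x_allele = _evolve(tips[sp], allele_branch_length, mutation_rate,
                               ts_tv_ratio, rng)
            y_allele = _evolve(tips[sp], allele_branch_length, mutation_rate,
                               ts_tv_ratio, rng)
            phased = sp == focal
            for i in range(n_males):
                sid = f"{i + 1:02d}"
                emit(sp, sid, Sex.MALE, "X" if phased else "unphased",
                     x_allele, 1)
                emit(sp, sid, Sex.MALE, "Y" if phased else "unphased",
                     y_allele, 2)
            for i in range(n_females):
                sid = f"{n_males + i + 1:02d}"
                cls = "X" if phased else "unphased"
                emit(sp, sid, Sex.FEMALE, cls, x_allele, 1)
                emit(sp, sid, Sex.FEMALE, cls, x_allele, 2)
    return out
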