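"""Readers and writers for the external formats the pipeline touches.

All downstream modules operate on the in-memory domain types defined here:
:class:`LocusCatalog` (RAD/GBS tag catalogs with per-individual genotypes and
presence), :class:`SexRegistry` (sample -> species, phenotypic sex),
:class:`HitTable` (12-column tabular sequence-search results) and
:class:`ReferenceGenome`.

Conventions
-----------
* Internal coordinates are 0-based half-open; anything written to reports is
  1-based inclusive, matching the habit of tabular BLAST output.
* Minus-strand hits are normalised at parse time to a strand flag plus
  ascending subject coordinates.
* A missing genotype is represented as ``None`` and is distinct from a
  homozygous-reference call; IUPAC ambiguity codes in input are demoted to
  missing.

Table dialects
--------------
The genotype table is tab-separated with header
``locus_id  column  alleles  <sample_1> ... <sample_n>``; genotype cells are
``T/A`` style unordered pairs, ``-`` for missing.  The presence/depth table has
header ``locus_id  <sample_1> ...`` with non-negative integer read depths
(0 = locus not recovered in that individual).  Consensus sequences travel as
FASTA keyed by locus id.  These schemas are this package's documented
convention for catalog exchange, modelled on the per-locus summary tables that
RAD assemblers emit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Sex",
    "SexRegistry",
    "SnpSite",
    "Locus",
    "LocusCatalog",
    "Hit",
    "HitTable",
    "ReferenceGenome",
    "read_registry",
    "read_catalog",
    "write_catalog",
    "read_hits",
    "write_hits",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "revcomp",
]

_DNA_BASES = frozenset("ACGT")
_MISSING_TOKENS = frozenset({"-", ".", "", "./.", "-/-", "NA"})


class FormatError(ValueError):
    """Raised on malformed or internally inconsistent input files."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"

    @property
    def opposite(self) -> "Sex":
        return Sex.FEMALE if self is Sex.MALE else Sex.MALE


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Sex registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistryEntry:
    sample_id: str
    species_id: str
    sex: Sex


@dataclass
class SexRegistry:
    """Sample -> (species, phenotypic sex) lookup.

    Sample ids are unique.  Downstream screens require at least one individual
    of each sex per species and refuse to run otherwise; see
    :meth:`require_both_sexes`.
    """

    entries: list[RegistryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.sample_id in seen:
                raise FormatError(f"duplicate sample id in registry: {e.sample_id!r}")
            seen.add(e.sample_id)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.species_id not in out:
                out.append(e.species_id)
        return out

    def sex_of(self, sample_id: str) -> Sex:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e.sex
        raise KeyError(sample_id)

    def samples(self, species_id: str | None = None, sex: Sex | None = None) -> list[str]:
        return [
            e.sample_id
            for e in self.entries
            if (species_id is None or e.species_id == species_id)
            and (sex is None or e.sex == sex)
        ]

    def require_both_sexes(self, species_id: str) -> None:
        for sex in (Sex.MALE, Sex.FEMALE):
            if not self.samples(species_id, sex):
                raise FormatError(
                    f"species {species_id!r} has no {sex.value} samples; "
                    "sex-linkage screens need both sexes"
                )

    def subset(self, species_id: str) -> "SexRegistry":
        return SexRegistry([e for e in self.entries if e.species_id == species_id])


# ---------------------------------------------------------------------------
# Locus catalog
# ---------------------------------------------------------------------------

Genotype = tuple[str, str] | None  # unordered base pair, or missing


@dataclass
class SnpSite:
    """One variant column of a locus with per-sample diploid genotypes."""

    locus_id: str
    column: int  # 0-based offset into the locus consensus
    alleles: frozenset[str]
    genotypes: dict[str, Genotype]

    def __post_init__(self) -> None:
        self.alleles = frozenset(self.alleles)
        if not self.alleles <= _DNA_BASES:
            raise FormatError(
                f"{self.locus_id}:{self.column}: alleles must be ACGT, got {sorted(self.alleles)}"
            )
        if len(self.alleles) > 4:
            raise FormatError("more than four alleles at a site")
        for sample, gt in self.genotypes.items():
            if gt is None:
                continue
            if not set(gt) <= self.alleles:
                raise FormatError(
                    f"{self.locus_id}:{self.column}: genotype {gt} of {sample!r} "
                    f"uses bases outside alleles {sorted(self.alleles)}"
                )

    def genotyped(self, samples: Iterable[str]) -> list[str]:
        return [s for s in samples if self.genotypes.get(s) is not None]

    def is_het(self, sample: str) -> bool:
        gt = self.genotypes.get(sample)
        return gt is not None and gt[0] != gt[1]

    def is_hom(self, sample: str) -> bool:
        gt = self.genotypes.get(sample)
        return gt is not None and gt[0] == gt[1]


@dataclass
class Locus:
    locus_id: str
    consensus: str
    snp_sites: list[SnpSite] = field(default_factory=list)
    presence: dict[str, bool] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        for site in self.snp_sites:
            if not 0 <= site.column < len(self.consensus):
                raise FormatError(
                    f"{self.locus_id}: SNP column {site.column} outside consensus "
                    f"of length {len(self.consensus)}"
                )
        for sample, d in self.depth.items():
            if d < 0:
                raise FormatError(f"{self.locus_id}: negative depth for {sample!r}")
        # Absent locus implies no genotype calls for that individual.
        for sample, present in self.presence.items():
            if not present:
                for site in self.snp_sites:
                    if site.genotypes.get(sample) is not None:
                        raise FormatError(
                            f"{self.locus_id}: sample {sample!r} absent but genotyped "
                            f"at column {site.column}"
                        )

    def haplotypes(self, sample: str) -> tuple[str, str] | None:
        """The sample's two haplotype sequences at this locus.

        Built from the consensus with each SNP column substituted by the
        sample's alleles.  With more than one heterozygous site the phase is
        arbitrary (alleles paired in sorted order per column); fixed-length
        RAD/GBS tags carry mostly single SNPs so this is rarely exercised.
        Returns ``None`` when the locus is absent or any site is uncalled.
        """
        if not self.presence.get(sample, False):
            return None
        hap_a = list(self.consensus)
        hap_b = list(self.consensus)
        for site in self.snp_sites:
            gt = site.genotypes.get(sample)
            if gt is None:
                return None
            a, b = sorted(gt)
            hap_a[site.column] = a
            hap_b[site.column] = b
        return "".join(hap_a), "".join(hap_b)


@dataclass
class LocusCatalog:
    """All loci of one species plus the ordered sample list."""

    loci: list[Locus]
    samples: list[str]

    def __post_init__(self) -> None:
        ids = [loc.locus_id for loc in self.loci]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise FormatError(f"duplicate locus ids in catalog: {sorted(dup)}")
        known = set(self.samples)
        for loc in self.loci:
            for site in loc.snp_sites:
                extra = set(site.genotypes) - known
                if extra:
                    raise FormatError(
                        f"{loc.locus_id}: genotypes reference unknown sample(s) "
                        f"{sorted(extra)}"
                    )
        self._by_id = {loc.locus_id: loc for loc in self.loci}

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, locus_id: str) -> Locus:
        return self._by_id[locus_id]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    @property
    def snp_sites(self) -> list[SnpSite]:
        return [site for loc in self.loci for site in loc.snp_sites]


# ---------------------------------------------------------------------------
# Hit tables (12-column tabular search results)
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
]


@dataclass(frozen=True)
class Hit:
    """One alignment, coordinates normalised.

    ``q_lo/q_hi`` and ``s_lo/s_hi`` are 0-based half-open on the plus strand
    of query and subject; ``strand`` is ``+1`` or ``-1`` (subject orientation).
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    q_lo: int
    q_hi: int
    s_lo: int
    s_hi: int
    strand: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise FormatError(f"negative E-value for {self.query_id}->{self.subject_id}")

    def covers_query_column(self, column: int) -> bool:
        return self.q_lo <= column < self.q_hi


@dataclass
class HitTable:
    rows: list[Hit]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def for_query(self, query_id: str) -> list[Hit]:
        return [h for h in self.rows if h.query_id == query_id]

    @property
    def query_ids(self) -> list[str]:
        out: list[str] = []
        for h in self.rows:
            if h.query_id not in out:
                out.append(h.query_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        """1-based inclusive report frame in the standard 12-column layout."""
        recs = []
        for h in self.rows:
            s_start, s_end = (h.s_lo + 1, h.s_hi) if h.strand > 0 else (h.s_hi, h.s_lo + 1)
            recs.append(
                dict(
                    query_id=h.query_id,
                    subject_id=h.subject_id,
                    percent_identity=h.percent_identity,
                    alignment_length=h.alignment_length,
                    mismatches=0,
                    gap_opens=0,
                    q_start=h.q_lo + 1,
                    q_end=h.q_hi,
                    s_start=s_start,
                    s_end=s_end,
                    e_value=h.e_value,
                    bit_score=h.bit_score,
                )
            )
        return pd.DataFrame(recs, columns=HIT_COLUMNS)


def _hit_from_raw(
    query_id: str,
    subject_id: str,
    percent_identity: float,
    alignment_length: int,
    q_start: int,
    q_end: int,
    s_start: int,
    s_end: int,
    e_value: float,
    bit_score: float,
) -> Hit:
    if s_start <= s_end:
        strand, s_lo, s_hi = 1, s_start - 1, s_end
    else:
        strand, s_lo, s_hi = -1, s_end - 1, s_start
    return Hit(
        query_id=str(query_id),
        subject_id=str(subject_id),
        percent_identity=float(percent_identity),
        alignment_length=int(alignment_length),
        q_lo=int(q_start) - 1,
        q_hi=int(q_end),
        s_lo=s_lo,
        s_hi=s_hi,
        strand=strand,
        e_value=float(e_value),
        bit_score=float(bit_score),
    )


def read_hits(path: str | Path) -> HitTable:
    """Parse a 12-column tab-separated hit file (BLAST ``-outfmt 6`` dialect)."""
    rows: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                rows.append(
                    _hit_from_raw(
                        parts[0], parts[1], float(parts[2]), int(parts[3]),
                        int(parts[6]), int(parts[7]), int(parts[8]), int(parts[9]),
                        float(parts[10]), float(parts[11]),
                    )
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed hit row ({exc})") from exc
    return HitTable(rows)


def write_hits(table: HitTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGenome:
    sequences: dict[str, str] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)
    chromosome_names: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if name in self.lengths and self.lengths[name] != len(seq):
                raise FormatError(
                    f"length table says {self.lengths[name]} for {name!r} but "
                    f"sequence has {len(seq)} bases"
                )
            self.lengths.setdefault(name, len(seq))
        for name, n in self.lengths.items():
            if n <= 0:
                raise FormatError(f"non-positive length for {name!r}")
        unknown = self.chromosome_names - set(self.lengths)
        if unknown:
            raise FormatError(f"chromosome names absent from genome: {sorted(unknown)}")
        if not self.chromosome_names:
            self.chromosome_names = set(self.lengths)

    @property
    def total_chromosome_length(self) -> int:
        return sum(self.lengths[c] for c in self.chromosome_names)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_registry(
    path: str | Path,
    sex_codes: Mapping[str, Sex] | None = None,
) -> SexRegistry:
    """Read a sample-sex registry table.

    Tab-separated, three columns ``sample_id  species_id  sex`` (a header line
    is recognised and skipped).  The sex alphabet defaults to M/F and is
    configurable via ``sex_codes``.
    """
    codes = dict(sex_codes) if sex_codes else {"M": Sex.MALE, "F": Sex.FEMALE}
    codes.update({"male": Sex.MALE, "female": Sex.FEMALE})
    entries: list[RegistryEntry] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in {"sample_id", "sample"}:
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            sample, species, sex_code = parts[0], parts[1], parts[2]
            if sex_code not in codes:
                raise FormatError(
                    f"{path}:{lineno}: unknown sex code {sex_code!r} for sample "
                    f"{sample!r} (expected one of {sorted(set(codes))})"
                )
            entries.append(RegistryEntry(sample, species, codes[sex_code]))
    if not entries:
        raise FormatError(f"{path}: registry file contains no entries")
    return SexRegistry(entries)


def write_registry(registry: SexRegistry, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tspecies_id\tsex\n")
        for e in registry.entries:
            code = "M" if e.sex is Sex.MALE else "F"
            fh.write(f"{e.sample_id}\t{e.species_id}\t{code}\n")


def _parse_genotype(cell: str, lineno: int, path) -> Genotype:
    cell = cell.strip()
    if cell in _MISSING_TOKENS:
        return None
    m = re.fullmatch(r"([A-Za-z])/?([A-Za-z])", cell)
    if not m:
        raise FormatError(f"{path}:{lineno}: unparseable genotype cell {cell!r}")
    a, b = m.group(1).upper(), m.group(2).upper()
    if a not in _DNA_BASES or b not in _DNA_BASES:
        return None  # ambiguity codes are demoted to missing
    return (a, b) if a <= b else (b, a)


def read_catalog(
    genotype_table_path: str | Path,
    presence_table_path: str | Path,
    fasta_path: str | Path,
) -> LocusCatalog:
    """Assemble a :class:`LocusCatalog` from the three on-disk pieces.

    The presence table's sample columns define the catalog's sample list; a
    genotype table referencing a sample outside that list is a hard error.
    Missing genotypes are preserved as missing, never imputed.
    """
    consensus = read_fasta(fasta_path)

    pres_df = pd.read_csv(presence_table_path, sep="\t", dtype=str)
    if pres_df.columns[0] != "locus_id":
        raise FormatError(f"{presence_table_path}: first column must be 'locus_id'")
    samples = list(pres_df.columns[1:])
    if len(set(samples)) != len(samples):
        raise FormatError(f"{presence_table_path}: duplicated sample columns")
    depth: dict[str, dict[str, int]] = {}
    for _, row in pres_df.iterrows():
        lid = row["locus_id"]
        if lid in depth:
            raise FormatError(f"{presence_table_path}: duplicate locus id {lid!r}")
        if lid not in consensus:
            raise FormatError(f"{presence_table_path}: locus {lid!r} missing from FASTA")
        depth[lid] = {s: int(row[s]) for s in samples}

    sites: dict[str, list[SnpSite]] = {lid: [] for lid in depth}
    gt_df = pd.read_csv(genotype_table_path, sep="\t", dtype=str)
    expected_head = ["locus_id", "column", "alleles"]
    if list(gt_df.columns[:3]) != expected_head:
        raise FormatError(
            f"{genotype_table_path}: header must start with {expected_head}"
        )
    extra = set(gt_df.columns[3:]) - set(samples)
    if extra:
        raise FormatError(
            f"{genotype_table_path}: sample(s) {sorted(extra)} not declared in the "
            "presence table"
        )
    for i, row in gt_df.iterrows():
        lineno = i + 2
        lid = row["locus_id"]
        if lid not in depth:
            raise FormatError(f"{genotype_table_path}:{lineno}: unknown locus {lid!r}")
        genotypes = {
            s: _parse_genotype(row[s], lineno, genotype_table_path)
            for s in gt_df.columns[3:]
        }
        alleles = frozenset(row["alleles"].replace(",", "").upper()) & _DNA_BASES
        sites[lid].append(
            SnpSite(
                locus_id=lid,
                column=int(row["column"]),
                alleles=alleles,
                genotypes=genotypes,
            )
        )

    loci = [
        Locus(
            locus_id=lid,
            consensus=consensus[lid],
            snp_sites=sites[lid],
            presence={s: d > 0 for s, d in per_sample.items()},
            depth=per_sample,
        )
        for lid, per_sample in depth.items()
    ]
    return LocusCatalog(loci=loci, samples=samples)


def write_catalog(
    catalog: LocusCatalog,
    genotype_table_path: str | Path,
    presence_table_path: str | Path,
    fasta_path: str | Path,
) -> None:
    """Inverse of :func:`read_catalog` (round-trips byte-identically)."""
    write_fasta({loc.locus_id: loc.consensus for loc in catalog}, fasta_path)

    with open(presence_table_path, "w") as fh:
        fh.write("locus_id\t" + "\t".join(catalog.samples) + "\n")
        for loc in catalog:
            fh.write(
                loc.locus_id
                + "\t"
                + "\t".join(str(loc.depth.get(s, 0)) for s in catalog.samples)
                + "\n"
            )

    with open(genotype_table_path, "w") as fh:
        fh.write("locus_id\tcolumn\talleles\t" + "\t".join(catalog.samples) + "\n")
        for loc in catalog:
            for site in loc.snp_sites:
                cells = []
                for s in catalog.samples:
                    gt = site.genotypes.get(s)
                    cells.append("-" if gt is None else f"{gt[0]}/{gt[1]}")
                fh.write(
                    f"{loc.locus_id}\t{site.column}\t"
                    + "".join(sorted(site.alleles))
                    + "\t"
                    + "\t".join(cells)
                    + "\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta-2line")


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree (path or literal string) with branch lengths and
    optional internal support labels preserved."""
    text = str(source)
    if not text.lstrip().startswith("("):
        text = Path(source).read_text()
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialise a tree; internal-node labels (bootstrap supports) are kept."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
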