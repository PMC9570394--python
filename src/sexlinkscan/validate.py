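"""In-silico validation of candidate markers and heterogamety calls.

Opposite-sex verification: the sequencing reads of each species are pooled by
phenotypic sex, and a candidate is kept only when its sex-diagnostic sequence
is absent from the homogametic-sex pool and present in the heterogametic-sex
pool.  SNP candidates are checked through an alignment search (E-value
cutoff applied, default 1e-20) for the haplotype carrying the sex-specific
allele; sex-limited tags are checked as exact full-length substrings.

Status names follow the XY convention (the common case): for a ZW-type
candidate ``rejected_female_evidence`` means disqualifying evidence in the
homogametic pool (males) and ``rejected_male_inconsistent`` means the
heterogametic pool (females) lacked the diagnostic sequence.

The heterogamety call per species tests the counts of confirmed XY- versus
ZW-consistent markers against the random-expectation null (both patterns
equally likely among false positives) with a two-sided exact binomial test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import binomtest

from .io_formats import Sex, revcomp
from .screen import CandidateMarker
from .search import exact_search

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationResult",
    "SystemCall",
    "SharedLocus",
    "verify_snp_marker",
    "verify_sex_limited_marker",
    "validate_markers",
    "call_system",
    "find_trans_species_markers",
]

Pool = Sequence[tuple[str, str]]  # (read id, sequence)


@dataclass(frozen=True)
class ValidationResult:
    marker: CandidateMarker
    status: str  # confirmed | rejected_female_evidence | rejected_male_inconsistent | insufficient_data
    n_heterogametic_occurrences: int = 0
    n_homogametic_occurrences: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        allowed = {
            "confirmed", "rejected_female_evidence",
            "rejected_male_inconsistent", "insufficient_data",
        }
        if self.status not in allowed:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "confirmed" and self.n_homogametic_occurrences > 0:
            raise ValueError(
                "confirmed marker cannot have disqualifying homogametic occurrences"
            )


@dataclass(frozen=True)
class SystemCall:
    species_id: str
    n_confirmed_xy: int
    n_confirmed_zw: int
    p_value: float | None
    call: str  # XY | ZW | undetermined
    excluded_markers: tuple[CandidateMarker, ...] = ()

    def __post_init__(self) -> None:
        if self.call not in {"XY", "ZW", "undetermined"}:
            raise ValueError(f"unknown call {self.call!r}")


def _pools_by_role(
    marker: CandidateMarker, male_pool: Pool, female_pool: Pool
) -> tuple[Pool, Pool]:
    """(heterogametic pool, homogametic pool) for the marker's system type."""
    if marker.system_consistency == "XY_type":
        return male_pool, female_pool
    return female_pool, male_pool


def _count_hits(
    query: str, pool: Pool, evalue_cutoff: float, column: int | None
) -> int:
    """Alignment occurrences of ``query`` in a pool at E <= cutoff that cover
    the given query column (any column if None)."""
    hits = exact_search({"q": query}, dict(pool))
    n = 0
    for h in hits:
        if h.e_value > evalue_cutoff:
            continue
        if column is not None and not h.covers_query_column(column):
            continue
        n += 1
    return n


def verify_snp_marker(
    marker: CandidateMarker,
    male_pool: Pool,
    female_pool: Pool,
    evalue_cutoff: float = 1e-20,
    min_heterogametic_occurrences: int = 1,
) -> ValidationResult:
    """Opposite-sex verification of a SNP candidate.

    Confirmed iff (a) no alignment at E <= cutoff in the homogametic pool
    carries the sex-specific allele at the SNP column, and (b) at least
    ``min_heterogametic_occurrences`` alignments in the heterogametic pool do.
    A marker without a recorded sex-specific allele is routed to
    heterozygosity-only verification: condition (a) applies to every
    non-consensus base at the site (logged in ``note``).
    """
    if marker.site is None or marker.consensus is None:
        raise ValueError("SNP verification needs a site column and consensus")
    het_pool, hom_pool = _pools_by_role(marker, male_pool, female_pool)

    col = marker.site
    ref = marker.consensus[col]
    if marker.sex_specific_allele is not None:
        alt_alleles = [marker.sex_specific_allele]
        note = ""
    else:
        alt_alleles = [b for b in "ACGT" if b != ref]
        note = "no sex-specific allele recorded; heterozygosity-only verification"
        logger.info("%s:%s %s", marker.locus_id, col, note)

    def haplotype(allele: str) -> str:
        return marker.consensus[:col] + allele + marker.consensus[col + 1:]

    n_hom = sum(
        _count_hits(haplotype(a), hom_pool, evalue_cutoff, col) for a in alt_alleles
    )
    n_het = sum(
        _count_hits(haplotype(a), het_pool, evalue_cutoff, col) for a in alt_alleles
    )
    # any alignment of the locus at all, to distinguish "no data" from clean
    any_hits = n_hom + n_het + _count_hits(
        haplotype(ref), het_pool, evalue_cutoff, None
    ) + _count_hits(haplotype(ref), hom_pool, evalue_cutoff, None)

    if any_hits == 0:
        status = "insufficient_data"
    elif n_hom > 0:
        status = "rejected_female_evidence"
    elif n_het < min_heterogametic_occurrences:
        status = "rejected_male_inconsistent"
    else:
        status = "confirmed"
    return ValidationResult(
        marker=marker, status=status,
        n_heterogametic_occurrences=n_het,
        n_homogametic_occurrences=n_hom,
        note=note,
    )


def verify_sex_limited_marker(
    marker: CandidateMarker,
    male_pool: Pool,
    female_pool: Pool,
    strand_aware: bool = True,
    min_heterogametic_occurrences: int = 1,
) -> ValidationResult:
    """Opposite-sex verification of a whole-locus sex-limited candidate.

    Confirmed iff the locus consensus occurs as an exact full-length substring
    of zero homogametic-pool sequences and at least one heterogametic-pool
    sequence.  ``strand_aware=True`` (default) counts a reverse-complement
    occurrence too; ``False`` restores a literal text-match rule.
    """
    if marker.consensus is None:
        raise ValueError("sex-limited verification needs the locus consensus")
    het_pool, hom_pool = _pools_by_role(marker, male_pool, female_pool)
    if not het_pool and not hom_pool:
        return ValidationResult(marker=marker, status="insufficient_data")

    needles = [marker.consensus.upper()]
    if strand_aware:
        rc = revcomp(marker.consensus)
        if rc not in needles:
            needles.append(rc)

    def occurrences(pool: Pool) -> int:
        return sum(
            1 for _, seq in pool for n in needles if n in seq.upper()
        )

    n_hom = occurrences(hom_pool)
    n_het = occurrences(het_pool)
    if n_hom > 0:
        status = "rejected_female_evidence"
    elif n_het < min_heterogametic_occurrences:
        status = "rejected_male_inconsistent"
    else:
        status = "confirmed"
    return ValidationResult(
        marker=marker, status=status,
        n_heterogametic_occurrences=n_het,
        n_homogametic_occurrences=n_hom,
    )


def validate_markers(
    markers: Iterable[CandidateMarker],
    male_pool: Pool,
    female_pool: Pool,
    evalue_cutoff: float = 1e-20,
    strand_aware: bool = True,
) -> list[ValidationResult]:
    """Route each candidate to the appropriate verification rule."""
    out = []
    for m in markers:
        if m.site is None:
            out.append(
                verify_sex_limited_marker(m, male_pool, female_pool, strand_aware)
            )
        else:
            out.append(verify_snp_marker(m, male_pool, female_pool, evalue_cutoff))
    return out


def call_system(
    confirmed_markers: Iterable[CandidateMarker] | tuple[int, int],
    alpha: float = 0.05,
    species_id: str = "",
) -> SystemCall:
    """Call the heterogametic system from confirmed marker counts.

    Two-sided exact binomial test of the XY- vs ZW-consistent counts against
    p = 0.5; the majority system is called when p < alpha, otherwise
    undetermined.  Markers of the excluded minority system are reported, not
    silently dropped.
    """
    if isinstance(confirmed_markers, tuple):
        n_xy, n_zw = confirmed_markers
        xy_markers: tuple[CandidateMarker, ...] = ()
        zw_markers: tuple[CandidateMarker, ...] = ()
    else:
        markers = list(confirmed_markers)
        xy_markers = tuple(
            m for m in markers if m.system_consistency == "XY_type"
        )
        zw_markers = tuple(
            m for m in markers if m.system_consistency == "ZW_type"
        )
        n_xy, n_zw = len(xy_markers), len(zw_markers)
        if not species_id:
            species = {m.species_id for m in markers if m.species_id}
            if len(species) == 1:
                species_id = species.pop()

    n = n_xy + n_zw
    if n == 0:
        return SystemCall(species_id, 0, 0, None, "undetermined")
    p = binomtest(n_xy, n, 0.5, alternative="two-sided").pvalue
    if p < alpha and n_xy != n_zw:
        call = "XY" if n_xy > n_zw else "ZW"
        excluded = zw_markers if call == "XY" else xy_markers
    else:
        call = "undetermined"
        excluded = ()
    return SystemCall(species_id, n_xy, n_zw, p, call, excluded)


@dataclass(frozen=True)
class SharedLocus:
    unified_id: str
    species: frozenset[str]
    locus_by_species: Mapping[str, str] = field(default_factory=dict)


def find_trans_species_markers(
    confirmed_by_species: Mapping[str, Iterable[CandidateMarker]],
    unified_catalog: Mapping[str, Mapping[str, str]],
) -> dict:
    """Cross-species sharing of confirmed sex-linked loci.

    ``unified_catalog`` maps each species to its locus-id -> unified-locus-id
    translation (from a joint multi-species assembly).  Loci missing from the
    translation are treated as species-private.  Returns the per-unified-locus
    sharing sets, the loci shared by >= 2 species, and the maximal sharing set.
    """
    missing = set(confirmed_by_species) - set(unified_catalog)
    if missing:
        raise ValueError(
            f"species absent from unified catalog: {sorted(missing)}"
        )
    sharing: dict[str, dict[str, str]] = {}
    for sp, markers in confirmed_by_species.items():
        translation = unified_catalog[sp]
        for m in markers:
            uid = translation.get(m.locus_id, f"{sp}:{m.locus_id}")
            sharing.setdefault(uid, {})[sp] = m.locus_id
    shared = [
        SharedLocus(uid, frozenset(by_sp), dict(by_sp))
        for uid, by_sp in sorted(sharing.items())
        if len(by_sp) >= 2
    ]
    maximal = max(shared, key=lambda s: len(s.species), default=None)
    return {
        "per_locus": {uid: frozenset(by_sp) for uid, by_sp in sharing.items()},
        "shared": shared,
        "maximal_sharing_set": maximal.species if maximal else frozenset(),
    }
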