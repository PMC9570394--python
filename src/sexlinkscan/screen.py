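"""Screens for putative sex-linked SNPs and sex-limited loci.

Three complementary strategies, each evaluated for both the XY expectation
(males heterogametic) and its ZW mirror (sexes swapped — one code path):

(i)  ``allele_frequency``: one allele is strictly limited to the heterogametic
     sex (zero copies among genotyped homogametic individuals, >0 among
     heterogametic ones) and the heterozygosity fractions below also hold.
     The sex-limited allele is recorded (it is the putative Y/W allele).
(ii) ``heterozygosity``: the site is heterozygous in at least a threshold
     fraction (default 1/3) of genotyped heterogametic-sex individuals and
     homozygous in at least a threshold fraction (default 1/3) of genotyped
     homogametic-sex individuals.
(iii) ``sex_limited``: the whole locus is absent from every homogametic-sex
     individual and present in at least half of the heterogametic sex.

Fractions are computed over genotyped (non-missing) individuals with a floor
on the number genotyped per sex; boundary fractions are inclusive ("at
least").  Strategy (i) is strictly stronger than (ii) by construction; a
``frequency_difference`` alternative predicate (allele-frequency gap >= a
cutoff instead of strict sex-limitation) is available for users who prefer a
laxer rule.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .io_formats import Locus, LocusCatalog, Sex, SexRegistry, SnpSite

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenThresholds",
    "SupportCounts",
    "CandidateMarker",
    "screen_heterozygosity",
    "screen_allele_frequency",
    "screen_sex_limited",
    "screen_all",
    "combine_candidates",
]


@dataclass(frozen=True)
class ScreenThresholds:
    """Screen thresholds; the defaults reproduce the published rules
    (one-third heterozygous / homozygous; absent vs present-in-half)."""

    min_frac_het_heterogametic: float = 1.0 / 3.0
    min_frac_hom_homogametic: float = 1.0 / 3.0
    min_frac_present_heterogametic: float = 0.5
    max_present_homogametic: int = 0
    min_genotyped_per_sex: int = 3
    # off-by-default strict mode: additionally require zero heterozygous
    # individuals of the homogametic sex
    strict_no_het_homogametic: bool = False
    # alternative strategy-(i) predicate: allele-frequency difference cutoff
    # instead of strict sex-limitation (None = strict rule)
    frequency_difference: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "min_frac_het_heterogametic",
            "min_frac_hom_homogametic",
            "min_frac_present_heterogametic",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.max_present_homogametic < 0:
            raise ValueError("max_present_homogametic must be >= 0")


@dataclass(frozen=True)
class SupportCounts:
    n_het_heterogametic: int = 0
    n_hom_homogametic: int = 0
    n_present_heterogametic: int = 0
    n_present_homogametic: int = 0
    n_genotyped_heterogametic: int = 0
    n_genotyped_homogametic: int = 0


@dataclass(frozen=True)
class CandidateMarker:
    """A flagged SNP site (or whole sex-limited locus, ``site is None``)."""

    locus_id: str
    site: int | None  # SNP column; None for whole-locus sex-limited tags
    strategy: str  # allele_frequency | heterozygosity | sex_limited
    system_consistency: str  # XY_type | ZW_type
    support: SupportCounts
    sex_specific_allele: str | None = None
    species_id: str | None = None
    consensus: str | None = None
    dataset: str = "default"
    strategies: frozenset[str] = frozenset()
    conflict: bool = False  # same site flagged with opposing system types

    def __post_init__(self) -> None:
        if self.strategy not in {"allele_frequency", "heterozygosity", "sex_limited"}:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.system_consistency not in {"XY_type", "ZW_type"}:
            raise ValueError(f"unknown system type {self.system_consistency!r}")
        if not self.strategies:
            object.__setattr__(self, "strategies", frozenset({self.strategy}))

    @property
    def key(self) -> tuple:
        """Identity for deduplication: consensus sequence, site, sex allele."""
        return (self.consensus or self.locus_id, self.site, self.sex_specific_allele)


def _sex_partition(
    registry: SexRegistry, species_id: str | None, heterogametic: Sex
) -> tuple[list[str], list[str]]:
    if species_id is not None:
        registry = registry.subset(species_id)
        registry.require_both_sexes(species_id)
    else:
        for sp in registry.species:
            registry.subset(sp)  # existence check only
    het = registry.samples(species_id, heterogametic)
    hom = registry.samples(species_id, heterogametic.opposite)
    if not het or not hom:
        raise ValueError("registry must contain both sexes")
    return het, hom


def _site_counts(
    site: SnpSite, het_samples: Sequence[str], hom_samples: Sequence[str],
    locus: Locus,
) -> SupportCounts:
    return SupportCounts(
        n_het_heterogametic=sum(site.is_het(s) for s in het_samples),
        n_hom_homogametic=sum(site.is_hom(s) for s in hom_samples),
        n_present_heterogametic=sum(
            locus.presence.get(s, False) for s in het_samples
        ),
        n_present_homogametic=sum(
            locus.presence.get(s, False) for s in hom_samples
        ),
        n_genotyped_heterogametic=len(site.genotyped(het_samples)),
        n_genotyped_homogametic=len(site.genotyped(hom_samples)),
    )


def _het_predicate_holds(
    site: SnpSite, het_samples: Sequence[str], hom_samples: Sequence[str],
    thresholds: ScreenThresholds, counts: SupportCounts,
) -> bool:
    n_het_g = counts.n_genotyped_heterogametic
    n_hom_g = counts.n_genotyped_homogametic
    if n_het_g < thresholds.min_genotyped_per_sex or \
            n_hom_g < thresholds.min_genotyped_per_sex:
        return False
    if counts.n_het_heterogametic / n_het_g < thresholds.min_frac_het_heterogametic:
        return False
    if counts.n_hom_homogametic / n_hom_g < thresholds.min_frac_hom_homogametic:
        return False
    if thresholds.strict_no_het_homogametic and any(
        site.is_het(s) for s in hom_samples
    ):
        return False
    return True


def _allele_counts(site: SnpSite, samples: Iterable[str]) -> Counter:
    counts: Counter = Counter()
    for s in samples:
        gt = site.genotypes.get(s)
        if gt is not None:
            counts.update(gt)
    return counts


def _sex_limited_allele(
    site: SnpSite, het_samples: Sequence[str], hom_samples: Sequence[str],
    thresholds: ScreenThresholds,
) -> str | None:
    """The putative Y (or W) allele under strategy (i), or None.

    Strict rule: zero copies among genotyped homogametic individuals, > 0
    among heterogametic ones.  With ``frequency_difference`` set, instead
    requires the allele-frequency gap between the sexes to reach the cutoff.
    """
    het_counts = _allele_counts(site, het_samples)
    hom_counts = _allele_counts(site, hom_samples)
    het_total = sum(het_counts.values())
    hom_total = sum(hom_counts.values())
    if het_total == 0 or hom_total == 0:
        return None
    candidates = []
    for allele in sorted(site.alleles):
        if het_counts[allele] == 0:
            continue
        if thresholds.frequency_difference is None:
            if hom_counts[allele] == 0:
                candidates.append(allele)
        else:
            gap = het_counts[allele] / het_total - hom_counts[allele] / hom_total
            if gap >= thresholds.frequency_difference:
                candidates.append(allele)
    if len(candidates) != 1:
        # zero: no sex-limited allele; >1 only possible in degenerate
        # multi-allelic sites — ambiguous, not flagged
        return None
    return candidates[0]


def _screen_sites(
    catalog: LocusCatalog,
    registry: SexRegistry,
    thresholds: ScreenThresholds,
    species_id: str | None,
    strategy: str,
    dataset: str,
) -> list[CandidateMarker]:
    out: list[CandidateMarker] = []
    for system, heterogametic in (("XY_type", Sex.MALE), ("ZW_type", Sex.FEMALE)):
        het, hom = _sex_partition(registry, species_id, heterogametic)
        for locus in catalog:
            for site in locus.snp_sites:
                counts = _site_counts(site, het, hom, locus)
                if counts.n_genotyped_heterogametic == 0 or \
                        counts.n_genotyped_homogametic == 0:
                    logger.debug(
                        "%s:%s skipped: zero genotyped individuals of a sex",
                        site.locus_id, site.column,
                    )
                    continue
                if not _het_predicate_holds(site, het, hom, thresholds, counts):
                    continue
                allele = None
                if strategy == "allele_frequency":
                    allele = _sex_limited_allele(site, het, hom, thresholds)
                    if allele is None:
                        continue
                out.append(
                    CandidateMarker(
                        locus_id=locus.locus_id,
                        site=site.column,
                        strategy=strategy,
                        system_consistency=system,
                        support=counts,
                        sex_specific_allele=allele,
                        species_id=species_id,
                        consensus=locus.consensus,
                        dataset=dataset,
                    )
                )
    return out


def screen_heterozygosity(
    catalog: LocusCatalog,
    registry: SexRegistry,
    thresholds: ScreenThresholds = ScreenThresholds(),
    species_id: str | None = None,
    dataset: str = "default",
) -> list[CandidateMarker]:
    """Strategy (ii): sex-differential heterozygosity at SNP sites."""
    return _screen_sites(
        catalog, registry, thresholds, species_id, "heterozygosity", dataset
    )


def screen_allele_frequency(
    catalog: LocusCatalog,
    registry: SexRegistry,
    thresholds: ScreenThresholds = ScreenThresholds(),
    species_id: str | None = None,
    dataset: str = "default",
) -> list[CandidateMarker]:
    """Strategy (i): a strictly sex-limited allele plus the heterozygosity
    conditions; records the sex-specific allele."""
    return _screen_sites(
        catalog, registry, thresholds, species_id, "allele_frequency", dataset
    )


def screen_sex_limited(
    catalog: LocusCatalog,
    registry: SexRegistry,
    thresholds: ScreenThresholds = ScreenThresholds(),
    species_id: str | None = None,
    dataset: str = "default",
) -> list[CandidateMarker]:
    """Strategy (iii): whole loci absent from the homogametic sex and present
    in at least half of the heterogametic sex."""
    out: list[CandidateMarker] = []
    for system, heterogametic in (("XY_type", Sex.MALE), ("ZW_type", Sex.FEMALE)):
        het, hom = _sex_partition(registry, species_id, heterogametic)
        for locus in catalog:
            n_het = sum(locus.presence.get(s, False) for s in het)
            n_hom = sum(locus.presence.get(s, False) for s in hom)
            if n_hom > thresholds.max_present_homogametic:
                continue
            if n_het / len(het) < thresholds.min_frac_present_heterogametic:
                continue
            out.append(
                CandidateMarker(
                    locus_id=locus.locus_id,
                    site=None,
                    strategy="sex_limited",
                    system_consistency=system,
                    support=SupportCounts(
                        n_present_heterogametic=n_het,
                        n_present_homogametic=n_hom,
                    ),
                    species_id=species_id,
                    consensus=locus.consensus,
                    dataset=dataset,
                )
            )
    return out


def screen_all(
    catalog: LocusCatalog,
    registry: SexRegistry,
    thresholds: ScreenThresholds = ScreenThresholds(),
    species_id: str | None = None,
    dataset: str = "default",
) -> list[CandidateMarker]:
    """All three strategies, deduplicated."""
    return combine_candidates(
        screen_allele_frequency(catalog, registry, thresholds, species_id, dataset),
        screen_heterozygosity(catalog, registry, thresholds, species_id, dataset),
        screen_sex_limited(catalog, registry, thresholds, species_id, dataset),
    )


def combine_candidates(*candidate_lists: Sequence[CandidateMarker]) -> list[CandidateMarker]:
    """Merge candidates across strategies and assembly datasets.

    Duplicates collapse on (locus consensus sequence, site column,
    sex-specific allele); strategy tags and dataset provenance accumulate.
    A site flagged with opposing system consistency by different inputs is
    retained under both types with ``conflict=True`` for the validation stage
    to settle.
    """
    def merge(prev: CandidateMarker, m: CandidateMarker) -> CandidateMarker:
        datasets = prev.dataset
        if m.dataset not in datasets.split(";"):
            datasets = f"{datasets};{m.dataset}"
        return replace(
            prev,
            strategies=frozenset(prev.strategies | m.strategies | {m.strategy}),
            dataset=datasets,
            sex_specific_allele=prev.sex_specific_allele or m.sex_specific_allele,
        )

    # Group on (consensus identity, site column, system); within a group a
    # marker without a recorded sex-specific allele matches any allele, so a
    # strategy-(ii) hit folds into the strategy-(i) marker at the same site.
    groups: dict[tuple, dict[str | None, CandidateMarker]] = {}
    for markers in candidate_lists:
        for m in markers:
            gkey = (m.consensus or m.locus_id, m.site, m.system_consistency)
            by_allele = groups.setdefault(gkey, {})
            alleles = [a for a in by_allele if a is not None]
            slot = m.sex_specific_allele
            if slot is None and len(alleles) == 1:
                slot = alleles[0]
            if slot is not None and None in by_allele:
                by_allele[slot] = merge(by_allele.pop(None), m) if slot not in \
                    by_allele else merge(merge(by_allele[slot], by_allele.pop(None)), m)
                continue
            if slot in by_allele:
                by_allele[slot] = merge(by_allele[slot], m)
            else:
                by_allele[slot] = m

    # flag opposing-system duplicates of the same site
    site_systems: dict[tuple, set[str]] = {}
    for (cons, site, system) in groups:
        site_systems.setdefault((cons, site), set()).add(system)
    merged: list[CandidateMarker] = []
    for (cons, site, system), by_allele in groups.items():
        conflict = len(site_systems[(cons, site)]) > 1
        for m in by_allele.values():
            merged.append(replace(m, conflict=True) if conflict else m)
    merged.sort(key=lambda m: (m.locus_id, m.site if m.site is not None else -1,
                               m.system_consistency))
    return merged
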