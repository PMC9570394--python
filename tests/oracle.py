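"""Naive brute-force re-statements of the screening predicates.

Written independently of the screen module (plain loops over the raw
genotype/presence data, no shared helpers) so the two can be compared on
random catalogs.
"""

from sexlinkscan.io_formats import Sex


def brute_force_screen(catalog, registry, species, *, min_genotyped=3,
                       frac_het=1 / 3, frac_hom=1 / 3, frac_present=0.5):
    """Return a set of (locus_id, site_or_None, strategy, system) tuples."""
    males = [e.sample_id for e in registry.entries
             if e.species_id == species and e.sex is Sex.MALE]
    females = [e.sample_id for e in registry.entries
               if e.species_id == species and e.sex is Sex.FEMALE]
    found = set()
    for locus in catalog.loci:
        for site in locus.snp_sites:
            for system, het_sex, hom_sex in (
                ("XY_type", males, females), ("ZW_type", females, males)
            ):
                het_gts = [site.genotypes[s] for s in het_sex
                           if site.genotypes.get(s) is not None]
                hom_gts = [site.genotypes[s] for s in hom_sex
                           if site.genotypes.get(s) is not None]
                if len(het_gts) < min_genotyped or len(hom_gts) < min_genotyped:
                    continue
                n_het = sum(1 for g in het_gts if g[0] != g[1])
                n_hom = sum(1 for g in hom_gts if g[0] == g[1])
                passes_het = (n_het / len(het_gts) >= frac_het
                              and n_hom / len(hom_gts) >= frac_hom)
                if passes_het:
                    found.add((locus.locus_id, site.column,
                               "heterozygosity", system))
                    # strategy (i): some allele with zero copies in the
                    # homogametic sex and at least one in the heterogametic
                    het_bases = [b for g in het_gts for b in g]
                    hom_bases = [b for g in hom_gts for b in g]
                    limited = [a for a in sorted(site.alleles)
                               if a in het_bases and a not in hom_bases]
                    if len(limited) == 1:
                        found.add((locus.locus_id, site.column,
                                   "allele_frequency", system))
        for system, het_sex, hom_sex in (
            ("XY_type", males, females), ("ZW_type", females, males)
        ):
            n_het_present = sum(
                1 for s in het_sex if locus.presence.get(s, False)
            )
            n_hom_present = sum(
                1 for s in hom_sex if locus.presence.get(s, False)
            )
            if n_hom_present == 0 and n_het_present / len(het_sex) >= frac_present:
                found.add((locus.locus_id, None, "sex_limited", system))
    return found


def screen_output_as_set(markers):
    out = set()
    for m in markers:
        for strat in m.strategies:
            out.add((m.locus_id, m.site, strat, m.system_consistency))
    return out


def random_catalog(rng, n_loci=8, n_males=5, n_females=5, locus_length=30):
    """A random small catalog + registry with arbitrary genotype patterns,
    missing data and presence gaps (independent of the synthetic generator)."""
    from sexlinkscan.io_formats import (
        Locus, LocusCatalog, RegistryEntry, Sex, SexRegistry, SnpSite,
    )

    bases = "ACGT"
    samples = [f"m{i}" for i in range(n_males)] + \
        [f"f{i}" for i in range(n_females)]
    registry = SexRegistry(
        [RegistryEntry(f"m{i}", "spX", Sex.MALE) for i in range(n_males)]
        + [RegistryEntry(f"f{i}", "spX", Sex.FEMALE) for i in range(n_females)]
    )
    loci = []
    for k in range(n_loci):
        consensus = "".join(bases[rng.integers(4)] for _ in range(locus_length))
        presence = {s: bool(rng.random() > 0.15) for s in samples}
        depth = {s: int(rng.integers(1, 40)) if presence[s] else 0
                 for s in samples}
        col = int(rng.integers(locus_length))
        a1 = consensus[col]
        a2 = bases[(bases.index(a1) + 1 + int(rng.integers(3))) % 4]
        genotypes = {}
        for s in samples:
            if not presence[s] or rng.random() < 0.2:
                genotypes[s] = None
            else:
                pair = tuple(sorted(
                    (a1 if rng.random() < 0.6 else a2,
                     a1 if rng.random() < 0.6 else a2)
                ))
                genotypes[s] = pair
        site = SnpSite(locus_id=f"L{k}", column=col,
                       alleles=frozenset((a1, a2)), genotypes=genotypes)
        loci.append(Locus(locus_id=f"L{k}", consensus=consensus,
                          snp_sites=[site], presence=presence, depth=depth))
    return LocusCatalog(loci=loci, samples=samples), registry
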