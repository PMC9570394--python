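# sexlinkscan

Inference of sex-determination systems and sex-chromosome evolution from
reduced-representation sequencing (RAD-seq / GBS) of multiple closely related
species.

Many fishes, amphibians and non-avian reptiles carry *homomorphic* sex
chromosomes: X and Y (or Z and W) look alike and cannot be told apart
cytogenetically. Two forces can keep them that way — frequent **turnover**
(a new chromosome pair takes over sex determination before the old one can
degenerate) and **ongoing X–Y recombination** outside the sex-determining
region (SDR), which continually homogenises the gametologs. Distinguishing
the two requires population genotype data from males and females of several
related species. `sexlinkscan` implements that workflow for researchers
working from per-species RAD/GBS locus catalogs (consensus tag sequences plus
per-individual diploid genotypes and locus presence):

1. **Screen** — flag candidate sex-linked markers with three complementary
   rules, each evaluated under both the XY and the ZW expectation:
   (i) an allele strictly limited to the heterogametic sex,
   (ii) heterozygous in ≥ 1/3 of the heterogametic sex and homozygous in
   ≥ 1/3 of the homogametic sex, and
   (iii) whole tags present in ≥ 1/2 of the heterogametic sex and absent from
   the homogametic sex.
2. **Validate** — opposite-sex in-silico verification: the sex-diagnostic
   haplotype must be absent from the pooled reads of the homogametic sex
   (alignment search at E ≤ 10⁻²⁰ for SNP markers; exact, strand-aware
   substring match for sex-limited tags) and present in the heterogametic
   pool. The heterogametic system is then called per species by an exact
   two-sided binomial test of confirmed XY- vs ZW-consistent marker counts
   against p = ½.
3. **Map** — assign confirmed markers to chromosomes of a reference genome,
   directly or through a bridge assembly (2 kb flanks extracted around the
   bridge hit), keeping hits with E ≤ 10⁻²⁰ whose best hit beats the next
   best by ≥ 5 orders of magnitude of E-value; test per-chromosome
   concentration with one-sided exact binomial tests (expected fraction =
   chromosome length / genome length) under Holm correction.
4. **Trees** — build multispecies gene trees of a sex-linked locus and its
   cross-species homologs with neighbour joining on Kimura two-parameter
   distances,

   d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),

   with nonparametric bootstrap over alignment columns, and classify each
   genealogy: Y alleles of ≥ 2 species monophyletic ⇒ *gametolog-clustered*
   (recombination stopped before the species split); every species
   monophyletic ⇒ *species-clustered* (ongoing X–Y recombination).
   Externally estimated trees (e.g. ML) are accepted as Newick.
5. **Turnover** — place per-species sex-chromosome identities and
   heterogamety on a fixed species phylogeny and count the minimum number of
   turnover events and heterogamety shifts by unit-cost small parsimony
   (unknown tips are wildcards).

A first-class **synthetic-data generator** produces multi-species catalogs
with planted sex-linked SNPs (males heterozygous for a male-limited allele,
females homozygous), Y-limited tags, autosomal background at configurable
minor-allele frequency, missing data, a shared ancestral-SDR tag, and
cross-species homologs evolved under the two gene-history scenarios — so the
whole pipeline is testable end to end with known ground truth.

## Worked example

The bundled demo simulates nine XY species on a two-clade phylogeny. Eight
species carry their sex-linked markers on the chromosome homologous to
`chr5`; one species (`sp1`, the lone member of the other clade) carries them
on `chr8`, i.e. one planted turnover. Two species (`sp3`, `sp4`) share an
ancestral-SDR tag.

```sh
sexlinkscan run-all --seed 1 --out demo_run
```

runs simulate → screen → validate → map → trees → turnover and prints the
turnover block of `demo_run/summary.json`:

```json
{
  "identity_by_species": {
    "sp1": "chr8", "sp2": "chr5", "sp3": "chr5", "sp4": "chr5",
    "sp5": "chr5", "sp6": "chr5", "sp7": "chr5", "sp8": "chr5", "sp9": "chr5"
  },
  "min_heterogamety_shifts": 0,
  "min_turnovers": 1,
  "n_identities": 2,
  "turnover_branches": [["sp1"]]
}
```

Reading: the confirmed markers of every species mapped overwhelmingly to one
chromosome (the `identity_by_species` labels), two distinct sex-chromosome
identities exist among the nine species, the most parsimonious history needs
exactly one turnover — placed on the branch leading to `sp1` — and zero
XY↔ZW shifts. The full `summary.json` additionally reports, per species, the
candidate and confirmed marker counts, the binomial p-value behind each XY
call, per-chromosome assignment counts with the concentration test, the
trans-species shared locus (`sp3`+`sp4`), and the two scenario gene trees:
the shared ancestral-SDR history classifies as `gametolog_clustered` and the
ongoing-recombination history as `species_clustered`.

Every stage is also available as a library function
(`sexlinkscan.screen_all`, `validate_markers`, `assign_direct`,
`build_multilocus_trees`, `fitch_min_changes`, …) and as a separate
subcommand (`simulate`, `screen`, `validate`, `map`, `trees`, `turnover`)
operating on TSV/FASTA/Newick files.

## Limitations

The built-in sequence search is an exact/ungapped matcher with an approximate
E-value, adequate for the error-free synthetic tags; for real data, supply
standard 12-column tabular hit files from a local aligner. Catalog loci are
assumed fixed-length (RAD/GBS tags); length-variable loci would need external
alignment first. See `docs/methods.md` for model assumptions, parameter
choices and numerical details.
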