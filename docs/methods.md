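# Methods

This note documents the models, rules and numerical choices behind
`sexlinkscan`, and what the synthetic-data generator does and does not
emulate.

## Screening rules

A SNP site is evaluated for both heterogametic expectations; the ZW case is
the exact sex-mirror of the XY case and shares one code path.

* **Heterozygosity rule (strategy ii).** Flag XY-consistent when
  `frac(heterozygous | genotyped males) ≥ 1/3` and
  `frac(homozygous | genotyped females) ≥ 1/3`. Boundaries are inclusive
  ("at least"). Fractions are computed over genotyped (non-missing)
  individuals only, with a floor of 3 genotyped individuals per sex —
  the source rules are silent on missing data, and conditioning on the
  genotyped subset is the natural reading for catalogs with per-individual
  dropout. The rule deliberately places no cap on heterozygous females; a
  strict mode (`strict_no_het_homogametic`) adds that cap, off by default.
* **Allele-frequency rule (strategy i).** The published description shares
  the one-third conditions with (ii) but does not state how (i) differs. We
  interpret "screened based on frequency" as constraining *alleles*: (i)
  additionally requires an allele with zero copies among genotyped
  homogametic individuals and at least one copy among heterogametic ones
  (the putative Y/W allele, which is recorded on the marker). This makes (i)
  strictly stronger than (ii). An alternative predicate — an
  allele-frequency gap ≥ a cutoff instead of strict sex-limitation — is
  available via `frequency_difference` for users who prefer a laxer reading.
* **Sex-limited rule (strategy iii).** A whole tag is flagged when present
  in 0 homogametic individuals and ≥ 1/2 of heterogametic ones (inclusive).
* **Deduplication.** Candidates merge on (consensus sequence identity, SNP
  column, sex-specific allele), accumulating strategy tags and dataset
  provenance; a candidate without a recorded allele folds into the same
  site's allele-bearing marker. Opposing XY/ZW flags at one site are both
  retained, marked as conflicting, for the validation stage to settle.

## Opposite-sex validation

Reads are pooled by phenotypic sex. A SNP candidate is confirmed when no
alignment at E ≤ 10⁻²⁰ in the homogametic pool carries the sex-specific
allele at the SNP column and at least one alignment in the heterogametic
pool does (minimum occurrence count configurable; default 1, the rule
states no minimum). Candidates
lacking a recorded sex-specific allele are verified on heterozygosity alone:
condition (a) is applied to every non-consensus base at the site. Sex-limited
candidates are confirmed when the tag occurs as an exact full-length
substring of zero homogametic-pool reads and ≥ 1 heterogametic-pool read;
the search is strand-aware by default (a reverse-complement occurrence
counts), with a flag restoring literal text matching.

The sequence search is pluggable. The built-in matcher reports exact
full-query occurrences (both strands) with a Karlin–Altschul-style E-value,
`E = m·n·4^(−L)` (λ = ln 4, K = 1), floored at 10⁻³⁰⁰. It exists so E-value
cutoffs run on the same code path as externally supplied 12-column hit
tables; it is not a general aligner. A consequence worth knowing: an exact
match shorter than ~35 bp does not reach E ≤ 10⁻²⁰, mirroring how short
tags behave in a real search.

**System call.** "Differs from random expectation" is operationalised as an
exact two-sided binomial test of the confirmed XY- vs ZW-consistent counts
against p = ½ — the simplest null in which both false-positive patterns are
equally likely. The majority system is called when p < α (default 0.05);
minority markers are reported as excluded, never silently dropped.

## Chromosome assignment

Hits with E ≤ 10⁻²⁰ qualify. A query is assigned to its best hit's
chromosome when it is the only qualifying hit or when
`log10(E_next) − log10(E_best) ≥ 5`; otherwise it is recorded as
`ambiguous_gap` (and `no_hit` / `fails_evalue` when applicable). E = 0 is
floored at 10⁻³⁰⁸ so order-of-magnitude gaps stay finite. Indirect mapping
runs the E-value rule at the bridge step and both rules at the target step
by default (`gap_rule_at_bridge_step` applies it at both steps). Flanks of 2000 bp
are extracted on the bridge scaffold's plus strand, clipped at scaffold ends
with the clipping recorded.

**Concentration test.** Per chromosome, a one-sided (greater) exact binomial
test of the assigned count out of all assigned markers, expected fraction =
chromosome length / summed chromosome length, Holm-adjusted across
chromosomes. No particular test is standard for this question; the binomial/Holm
procedure is the package's choice, and its type-I error is
verified ≤ α by Monte-Carlo in the test suite.

## Gene trees

* **Distances.** Kimura two-parameter,
  `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`, over pairwise-comparable sites
  (gaps/ambiguity codes excluded per pair). Saturation (`1−2P−Q ≤ 0` or
  `1−2Q ≤ 0`) raises an error in direct use; inside bootstrap replicates a
  saturated pair instead receives a fixed ceiling distance of 10
  substitutions/site so a single extreme resample cannot abort the run.
* **Neighbour joining.** Standard Saitou–Nei agglomeration. Ties in the Q
  criterion break by the lexicographic order of each cluster's smallest
  member label, so output is deterministic and invariant to input order.
  Negative branch lengths are clamped to zero with the deficit moved to the
  sister edge (path lengths preserved). Internal edges of exactly zero
  length are collapsed, so a zero matrix yields a star tree. Trees are
  reported rooted at the final join but interpreted as unrooted throughout.
* **Bootstrap.** Column resampling with replacement; support of each
  internal bipartition of the point tree = % of replicate trees containing
  it, written onto internal node labels. The package default is 100
  replicates: for 150 bp tag alignments with ≤ ~60 tips, supports are stable
  to a few percent at 100 replicates, and the classification threshold sits
  at 50%; a 10,000-replicate run is one flag away.
* **Classification.** On the unrooted tree (monophyly = bipartition
  membership; the published figures are drawn rooted but state no rooting
  rule): *gametolog-clustered* iff the Y-labelled tips span ≥ 2 species and
  form a supported bipartition; *species-clustered* iff every species' tips
  are monophyletic with support and ≥ 1 species contributes both X and Y
  tips. Single-tip groups are trivially monophyletic. Both-sub-threshold ⇒
  `unresolved`. The species-clustered rule does not require the focal
  species' X and Y to separate from each other — only its monophyly.
* **Phasing.** The Y haplotype is the male haplotype carrying the validated
  sex-specific allele; haplotypes of markers without such an allele stay
  unphased and can support species-clustering but never gametolog-clustering.
  Homolog retrieval compares equal-length tags by full-length ungapped
  identity (best hit at E ≤ 10⁻²⁰, both strands); length-variable loci raise
  an error rather than being silently aligned. With multiple heterozygous
  sites on one tag, phase across sites is arbitrary (sorted per column) —
  single-SNP tags, the common case, are unaffected.
* **Concatenation.** Multi-locus analyses concatenate per-locus alignments
  over the (species, individual) pairs present at every locus; haplotype
  pairing across loci follows the phased X/Y labels where available and
  sorted order otherwise. With one locus the concatenated analysis *is* the
  per-locus analysis.
* Maximum-likelihood tree estimation is intentionally out of scope: the
  classification logic is the contribution, and externally computed trees
  are accepted as Newick (`method="external"`).

## Turnover counting

Unit-cost small parsimony (Sankoff DP with 0/1 costs, equal to Fitch
counting) over the observed states; `unknown` tips are wildcards that never
force a change. The tree is derooted first so each unrooted branch is one
edge; counts are invariant to rerooting and tip order. Branch placements are
classified by constrained re-runs of the DP: forbidding a change on an edge
(forcing equal endpoint states) tests whether every most-parsimonious
reconstruction changes there; forcing a change tests whether some
reconstruction does. The species tree is input data from published
phylogenies and is never re-estimated. A "not chromosome-5" identity is
encoded as a distinct concrete state by default (an `unknown` encoding is
available), since treating it as missing would erase the very signal the
count measures.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analysis assumes:
nine species, ten males and ten females each (the study's sampling design),
150 bp tags, per-individual diploid genotypes with sex-linked SNP loci
(heterogametic sex heterozygous for a sex-limited allele), sex-limited tags,
autosomal background under Hardy–Weinberg at minor-allele frequency 0.2,
optional genotyping error (per called genotype, one allele copy redrawn
uniformly with the configured probability) and locus dropout, a reference
genome with every tag embedded at a recorded position on its true
chromosome, and an optional ancestral-SDR tag shared across chosen species.
ZW species are generated by the same code path with the sexes swapped.

Gene histories follow the two contrasted scenarios. Substitutions are placed
per branch as Poisson(rate × branch length × sites) events under the K2P
process (transition:transversion weight 2:1 by default), making the
downstream K2P estimator self-consistent. Under *ancestral suppression* the
X and Y lineages split on a stem of 2× the tree depth (a deep split) and
evolve independently down the species tree. Under *ongoing recombination*
a single lineage evolves down the tree and X/Y diverge only on short
terminal allele branches — complete homogenisation of Y with X up to each
speciation, the simplest generator of species-clustered genealogies; partial
suppression gradients are out of scope.

**Rate and branch-length choices.** The demo phylogeny is ultrametric with
depth 1.0 and terminal branches 0.45; the default rate is 0.15
substitutions/site per unit branch length. These were set by a power
argument: a species' monophyly is recoverable with bootstrap support ≥ 50%
only if its terminal branch carries enough diagnostic substitutions, and
with 150 bp tags the expected count is `0.45 × 0.15 × 150 ≈ 10`, putting the
probability of an uninformative stem (≤ 2 substitutions) below 1%. Shorter
terminals or lower rates (e.g. ~4.5 expected substitutions) leave per-locus
classification at the mercy of Poisson noise. The implied root-to-tip
divergence (~15%) is in the range that explains why such tags largely fail
to align across frog families. Within-species allele and individual branches
(0.02 and 0.01) keep X–Y divergence at 1–3 substitutions — homomorphic,
recently recombining chromosomes — well below between-species divergence.

**Not modelled:** read-level sequencing error, coalescent demography and
incomplete lineage sorting, restriction-site dropout (dropout here is
uniform), library-size effects, paralogy, and length variation among tags.
Passing tests therefore demonstrate correctness of the *rules and
algorithms* under the assumed structure, not robustness to every artefact of
real reduced-representation data; the noise knobs are free parameters, not
estimates of any deposited dataset.

## Degenerate inputs and tie-breaks

* Registry species lacking either sex refuse to screen; sites with zero
  genotyped individuals of a sex are skipped and logged, not errored.
* An all-identical alignment yields zero distances; bootstrap still reports
  supports (of arbitrary resolutions) and callers detect the
  zero-information case from the distance matrix.
* Hit-table processing is invariant to row order (internal deterministic
  sort by E-value, bit score, subject, position).
* Minus-strand hits are normalised at parse time to ascending coordinates
  plus a strand flag; internal coordinates are 0-based half-open, all
  reports 1-based inclusive.
* Every pipeline output directory carries a `MANIFEST.json` with the config
  hash and seed; stage TSVs repeat the stamp in a leading comment line.

## Problem sizes

The shipped demo and test configurations use 9 species × 20 individuals,
~100 loci per species, 50 loci per gene-history scenario and 100 bootstrap
replicates, 1000 Monte-Carlo replicates for the concentration-test
calibration — sizes chosen so the complete suite and the acceptance script
each run in minutes on a single CPU while keeping every statistical check
well-powered. All are configuration values, not limits.
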