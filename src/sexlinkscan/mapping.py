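"""Chromosome assignment of confirmed markers and concentration testing.

Markers are placed on a reference genome either directly (marker -> reference
hits) or indirectly via a bridge assembly: marker -> bridge scaffold, extract
a fixed flank (default 2 kb) each side of the hit, then extended fragment ->
target genome.  Both routes apply an E-value cutoff (default 1e-20); an
assignment additionally requires the best hit to beat the next-best by a
margin in orders of magnitude of E-value (default 5) unless it is the only
qualifying hit.

Whether the markers concentrate on one chromosome (as expected if they tag a
single sex-determining region, given enough cross-species sequence
conservation) is tested per chromosome with a one-sided exact binomial test
of the assigned count against the chromosome's length fraction of the genome,
Holm-adjusted across chromosomes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .io_formats import Hit, HitTable, ReferenceGenome

logger = logging.getLogger(__name__)

__all__ = [
    "AssignmentRules",
    "MarkerAssignment",
    "ConcentrationReport",
    "assign_direct",
    "extract_flanks",
    "assign_indirect",
    "concentration_test",
    "annotate_candidate_genes",
]

# log10 floor for reported E-values of 0, so order-of-magnitude gaps stay finite
_E_FLOOR = 1e-308


@dataclass(frozen=True)
class AssignmentRules:
    evalue_cutoff: float = 1e-20
    best_hit_gap_orders: float = 5.0
    flank_length: int = 2000
    # apply the gap rule at step 1 of indirect mapping too (default: step 2 only)
    gap_rule_at_bridge_step: bool = False

    def __post_init__(self) -> None:
        if self.best_hit_gap_orders < 0:
            raise ValueError("best_hit_gap_orders must be >= 0")
        if self.flank_length < 0:
            raise ValueError("flank_length must be >= 0")


@dataclass(frozen=True)
class MarkerAssignment:
    marker_id: str
    chromosome: str | None
    reason: str | None  # no_hit | fails_evalue | ambiguous_gap when unassigned
    position: int | None  # 0-based subject start of the best hit
    method: str  # direct | indirect
    best_hit: Hit | None = None
    supporting_hits: tuple[Hit, ...] = ()

    def __post_init__(self) -> None:
        if (self.chromosome is None) == (self.reason is None):
            raise ValueError("exactly one of chromosome / reason must be set")
        if self.reason is not None and self.reason not in {
            "no_hit", "fails_evalue", "ambiguous_gap"
        }:
            raise ValueError(f"unknown reason {self.reason!r}")

    @property
    def assigned(self) -> bool:
        return self.chromosome is not None


def _log10e(e: float) -> float:
    return math.log10(max(e, _E_FLOOR))


def _hit_order(h: Hit) -> tuple:
    # deterministic best-first order regardless of input row order
    return (h.e_value, -h.bit_score, h.subject_id, h.s_lo, h.strand)


def _pick_best(
    marker_id: str, hits: Sequence[Hit], rules: AssignmentRules,
    method: str, apply_gap: bool = True,
) -> MarkerAssignment:
    if not hits:
        return MarkerAssignment(marker_id, None, "no_hit", None, method)
    qualifying = sorted(
        (h for h in hits if h.e_value <= rules.evalue_cutoff), key=_hit_order
    )
    if not qualifying:
        return MarkerAssignment(
            marker_id, None, "fails_evalue", None, method,
            supporting_hits=tuple(sorted(hits, key=_hit_order)),
        )
    best = qualifying[0]
    if apply_gap and len(qualifying) > 1:
        nxt = qualifying[1]
        gap = _log10e(nxt.e_value) - _log10e(best.e_value)
        if gap < rules.best_hit_gap_orders:
            return MarkerAssignment(
                marker_id, None, "ambiguous_gap", None, method,
                supporting_hits=tuple(qualifying),
            )
    return MarkerAssignment(
        marker_id, best.subject_id, None, best.s_lo, method,
        best_hit=best, supporting_hits=tuple(qualifying),
    )


def assign_direct(
    hits: HitTable, rules: AssignmentRules = AssignmentRules()
) -> list[MarkerAssignment]:
    """Direct mapping: each query is assigned to its best reference hit,
    subject to the E-value and best-hit-gap rules.  Every query in the table
    yields an assignment record; ordering of input rows is immaterial."""
    return [
        _pick_best(qid, hits.for_query(qid), rules, "direct")
        for qid in sorted(hits.query_ids)
    ]


def extract_flanks(
    hit: Hit,
    scaffold_sequences: Mapping[str, str],
    flank_length: int = 2000,
) -> tuple[str, bool, bool]:
    """Plus-strand scaffold sequence of the hit interval extended by
    ``flank_length`` each side, clipped at scaffold ends.

    Returns ``(sequence, left_clipped, right_clipped)``.
    """
    if hit.subject_id not in scaffold_sequences:
        raise KeyError(f"scaffold {hit.subject_id!r} not in scaffold set")
    scaffold = scaffold_sequences[hit.subject_id]
    lo = max(0, hit.s_lo - flank_length)
    hi = min(len(scaffold), hit.s_hi + flank_length)
    return scaffold[lo:hi], lo == 0 and hit.s_lo - flank_length < 0, \
        hi == len(scaffold) and hit.s_hi + flank_length > len(scaffold)


def assign_indirect(
    marker_hits_to_bridge: HitTable,
    bridge_scaffolds: Mapping[str, str],
    extended_hits_to_target: HitTable | None,
    rules: AssignmentRules = AssignmentRules(),
    *,
    searcher=None,
) -> list[MarkerAssignment]:
    """Two-step indirect mapping through a bridge assembly.

    Step 1 places each marker on a bridge scaffold (E-value rule; the gap rule
    optionally via ``rules.gap_rule_at_bridge_step``), the hit is extended by
    ``rules.flank_length`` each side, and step 2 places the extended fragment
    on the target genome under both rules.  The marker inherits the fragment's
    assignment, recorded as ``method="indirect"``.

    ``extended_hits_to_target`` holds externally computed hits of the extended
    fragments (query ids = marker ids); alternatively a ``searcher`` callable
    ``(fragments: dict) -> HitTable`` computes them (used with the built-in
    exact matcher on synthetic genomes).
    """
    step1 = [
        _pick_best(
            qid, marker_hits_to_bridge.for_query(qid), rules, "indirect",
            apply_gap=rules.gap_rule_at_bridge_step,
        )
        for qid in sorted(marker_hits_to_bridge.query_ids)
    ]
    fragments: dict[str, str] = {}
    out: list[MarkerAssignment] = []
    for a in step1:
        if not a.assigned:
            out.append(a)
            continue
        frag, left_clip, right_clip = extract_flanks(
            a.best_hit, bridge_scaffolds, rules.flank_length
        )
        if left_clip or right_clip:
            logger.debug("fragment of %s clipped at scaffold end", a.marker_id)
        fragments[a.marker_id] = frag

    if fragments:
        if extended_hits_to_target is None:
            if searcher is None:
                raise ValueError(
                    "need extended_hits_to_target or a searcher callable"
                )
            extended_hits_to_target = searcher(fragments)
        for marker_id in sorted(fragments):
            hits2 = extended_hits_to_target.for_query(marker_id)
            out.append(_pick_best(marker_id, hits2, rules, "indirect"))
    out.sort(key=lambda a: a.marker_id)
    return out


@dataclass(frozen=True)
class ChromosomeConcentration:
    chromosome: str
    n_assigned: int
    expected_fraction: float
    p_value: float
    adjusted_p_value: float


@dataclass
class ConcentrationReport:
    per_chromosome: list[ChromosomeConcentration]
    n_assigned_total: int
    fraction_unmapped: float
    alpha: float = 0.05
    tested: bool = True

    @property
    def concentrated_chromosomes(self) -> list[str]:
        return [
            c.chromosome for c in self.per_chromosome
            if c.adjusted_p_value < self.alpha
        ]


def concentration_test(
    assignments: Iterable[MarkerAssignment],
    genome: ReferenceGenome,
    alpha: float = 0.05,
) -> ConcentrationReport:
    """Per-chromosome enrichment of assigned markers.

    One-sided (greater) exact binomial p-value for each chromosome's assigned
    count out of the total assigned, with expected fraction = chromosome
    length / summed chromosome length; Holm adjustment across chromosomes.
    Also reports the fraction of markers left unassigned.
    """
    assignments = list(assignments)
    n_total = len(assignments)
    assigned = [a for a in assignments if a.assigned]
    n_assigned = len(assigned)
    frac_unmapped = 1.0 - n_assigned / n_total if n_total else 0.0
    chroms = sorted(genome.chromosome_names)
    total_len = genome.total_chromosome_length
    if n_assigned == 0:
        return ConcentrationReport(
            per_chromosome=[], n_assigned_total=0,
            fraction_unmapped=frac_unmapped, alpha=alpha, tested=False,
        )
    counts = {c: 0 for c in chroms}
    for a in assigned:
        if a.chromosome not in counts:
            logger.warning(
                "%s assigned to %s, not a flagged chromosome; excluded from "
                "the concentration test", a.marker_id, a.chromosome,
            )
            continue
        counts[a.chromosome] += 1
    raw = []
    for c in chroms:
        frac = genome.lengths[c] / total_len
        p = binomtest(counts[c], n_assigned, frac, alternative="greater").pvalue
        raw.append(p)
    adjusted = multipletests(raw, method="holm")[1]
    per_chrom = [
        ChromosomeConcentration(
            chromosome=c, n_assigned=counts[c],
            expected_fraction=genome.lengths[c] / total_len,
            p_value=raw[i], adjusted_p_value=float(adjusted[i]),
        )
        for i, c in enumerate(chroms)
    ]
    return ConcentrationReport(
        per_chromosome=per_chrom, n_assigned_total=n_assigned,
        fraction_unmapped=frac_unmapped, alpha=alpha,
    )


@dataclass(frozen=True)
class GeneAnnotation:
    marker_id: str
    gene: str
    percent_identity: float
    e_value: float
    subject_start: int  # 1-based inclusive, as reported
    subject_end: int


def annotate_candidate_genes(
    hits: HitTable,
    gene_names: Mapping[str, str] | None = None,
    evalue_cutoff: float = 1e-20,
    min_identity: float = 77.0,
) -> dict[str, list[GeneAnnotation]]:
    """Label markers hitting sex-determination candidate genes.

    ``hits`` is a search of markers against candidate-gene sequences (e.g.
    AMH, AR, CYP17, CYP19A1, DMRT1, FOXL2, SOX3, SF1); ``gene_names``
    optionally maps subject ids to gene symbols.  A marker is labelled when a
    hit passes the E-value cutoff and the identity threshold; markers with no
    qualifying hit are absent from the result.
    """
    out: dict[str, list[GeneAnnotation]] = {}
    for h in hits:
        if h.e_value > evalue_cutoff or h.percent_identity < min_identity:
            continue
        gene = gene_names.get(h.subject_id, h.subject_id) if gene_names \
            else h.subject_id
        s_start, s_end = (h.s_lo + 1, h.s_hi) if h.strand > 0 else (h.s_hi, h.s_lo + 1)
        out.setdefault(h.query_id, []).append(
            GeneAnnotation(
                marker_id=h.query_id, gene=gene,
                percent_identity=h.percent_identity, e_value=h.e_value,
                subject_start=s_start, subject_end=s_end,
            )
        )
    for anns in out.values():
        anns.sort(key=lambda a: (a.e_value, a.gene))
    return out
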