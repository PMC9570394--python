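"""Built-in exact-occurrence sequence search.

The validation and mapping stages consume :class:`~sexlinkscan.io_formats.HitTable`
rows and apply E-value rules to them.  On real data those tables come from an
external local aligner; for synthetic catalogs (error-free tags embedded
verbatim in their reference) an exact full-query occurrence search is
sufficient and is what this module provides.

E-values for exact matches use a Karlin–Altschul-style approximation with
lambda = ln 4 and K = 1, i.e. ``E = m * n * 4**(-L)`` for a length-``L`` exact
match against ``m`` query and ``n`` database letters, floored at 1e-300.  The
approximation exists solely so that downstream E-value cutoffs are exercised
on the same code path as externally supplied tables.
"""

from __future__ import annotations

from typing import Mapping

from .io_formats import Hit, HitTable, revcomp

__all__ = ["exact_search", "approx_evalue"]

_E_FLOOR = 1e-300


def approx_evalue(match_length: int, query_length: int, db_length: int) -> float:
    import math

    log10e = math.log10(max(query_length, 1)) + math.log10(max(db_length, 1)) \
        - match_length * math.log10(4.0)
    if log10e < -300:
        return _E_FLOOR
    return 10.0 ** log10e


def _occurrences(needle: str, haystack: str) -> list[int]:
    out = []
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def exact_search(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    *,
    both_strands: bool = True,
) -> HitTable:
    """All exact full-length occurrences of each query in each subject.

    Minus-strand occurrences (the query's reverse complement found on the
    subject's plus strand) are reported with ``strand = -1`` and ascending
    subject coordinates, matching the parse-time normalisation of external
    hit tables.
    """
    db_length = sum(len(s) for s in subjects.values())
    rows: list[Hit] = []
    for qid, qseq in queries.items():
        qseq = qseq.upper()
        L = len(qseq)
        if L == 0:
            continue
        evalue = approx_evalue(L, L, db_length)
        variants = [(qseq, 1)]
        if both_strands:
            rc = revcomp(qseq)
            if rc != qseq:
                variants.append((rc, -1))
        for sid, sseq in subjects.items():
            sseq = sseq.upper()
            for needle, strand in variants:
                for pos in _occurrences(needle, sseq):
                    rows.append(
                        Hit(
                            query_id=qid,
                            subject_id=sid,
                            percent_identity=100.0,
                            alignment_length=L,
                            q_lo=0,
                            q_hi=L,
                            s_lo=pos,
                            s_hi=pos + L,
                            strand=strand,
                            e_value=evalue,
                            bit_score=2.0 * L,
                        )
                    )
    return HitTable(rows)
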