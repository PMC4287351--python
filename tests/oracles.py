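"""Independent brute-force oracles used by the test suite.

Every function here re-derives its answer from first principles (plain
loops, regex, per-base set arithmetic) without calling the implementation
under test.
"""

from __future__ import annotations

import math
import re

from Bio.Data.IUPACData import ambiguous_dna_values

_IUPAC = {code: set(bases) for code, bases in ambiguous_dna_values.items()}
_BASE_ORDER = "ACGT"


def oracle_score(probs, background, seq: str, start: int) -> float:
    """Per-position log2 arithmetic with explicit loops."""
    total = 0.0
    for i, row in enumerate(probs):
        base = seq[start + i]
        if base == "N":
            continue
        j = _BASE_ORDER.index(base)
        total += math.log2(row[j] / background[j])
    return total


def oracle_best_window(probs, background, seq: str, starts=None):
    """Exhaustive enumeration of all windows; ties -> smaller start."""
    length = len(probs)
    if starts is None:
        starts = range(len(seq) - length + 1)
    scored = [(s, oracle_score(probs, background, seq, s)) for s in starts]
    best = scored[0]
    for s, sc in scored[1:]:
        if sc > best[1]:
            best = (s, sc)
    return best


def oracle_iupac_matches(motif: str, seq: str) -> list[int]:
    """Overlapping matches via a regex lookahead built from the IUPAC table."""
    body = "".join(
        "[" + "".join(sorted(_IUPAC[sym])) + "]" for sym in motif.upper()
    )
    return [m.start() for m in re.finditer(f"(?=(?:{body}))", seq.upper())]


def oracle_first_polyT(seq: str, min_run: int):
    """First >=min_run T-run via regex; (start, length) or None."""
    m = re.search("T{%d,}" % min_run, seq)
    return None if m is None else (m.start(), len(m.group(0)))


def oracle_internal_promoter(seq: str, abox: str, bbox: str) -> bool:
    """Exhaustive match-pair check: any A-box match strictly before a
    non-overlapping B-box match."""
    a_hits = oracle_iupac_matches(abox, seq)
    b_hits = oracle_iupac_matches(bbox, seq)
    return any(b >= a + len(abox) for a in a_hits for b in b_hits)


def oracle_placement(locus_start, locus_end, transcripts) -> str:
    """Per-base placement oracle.

    ``transcripts``: list of (exons, strand) with exons as sorted
    0-based half-open (start, end) pairs; genes assumed non-overlapping.
    Returns "overlapping_exon" | "intronic" | "intergenic".
    """
    locus_bases = set(range(locus_start, locus_end))
    exon_bases = set()
    intron_sets = []
    for exons, _strand in transcripts:
        for s, e in exons:
            exon_bases |= set(range(s, e))
        for i in range(len(exons) - 1):
            intron_sets.append(set(range(exons[i][1], exons[i + 1][0])))
    if locus_bases & exon_bases:
        return "overlapping_exon"
    if any(locus_bases <= intron for intron in intron_sets):
        return "intronic"
    return "intergenic"
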