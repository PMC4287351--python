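"""Promoter-architecture scanning around a candidate locus.

The type-3 pol III promoter lies outside the transcribed region: a PSE in a
fixed upstream window, a TATA box whose 3' end sits a constrained number of
bases upstream of the transcript start, and a run of >=4 T's just downstream
of the 3' end acting as terminator.  tRNA-type genes instead carry internal
A-box/B-box elements.  The verdict implemented here follows the published
classification rule: a locus is pol III-positive iff it has a PSE hit AND an
appropriately positioned TATA hit; the terminator and internal-promoter
calls are recorded as supporting evidence only, because poly-T runs occur at
variable positions even next to promoterless genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .defaults import (
    DEFAULT_ABOX,
    DEFAULT_BBOX,
    DEFAULT_MIN_POLYT_RUN,
    DEFAULT_PROXIMAL_WINDOW,
)
from .loci import NcRNALocus
from .pwm import PWM, PromoterModel, score_window
from .seqs import iupac_regex, revcomp

#: Downstream context (bp past the locus 3' end) extracted for terminator
#: calling; deliberately longer than the proximal window so distal runs are
#: still reported (with proximal=False).
DEFAULT_DOWNSTREAM_CONTEXT = 100


@dataclass(frozen=True)
class MotifHit:
    """A PWM match on the locus-sense strand of the scanned window."""

    start: int
    score: float
    motif_length: int


@dataclass(frozen=True)
class TerminatorCall:
    """First downstream poly-T run of at least the minimum length.

    ``run_start`` is 0-based bp downstream of the locus 3' end.
    """

    run_start: int
    run_length: int
    proximal: bool


@dataclass(frozen=True)
class PolIIIStatus:
    """Evidence bundle and verdict for one locus."""

    pse_hit: Optional[MotifHit]
    tata_hit: Optional[MotifHit]
    tata_positioned: bool
    terminator: Optional[TerminatorCall]
    internal_promoter: bool
    verdict: str  # "polIII_positive" | "polIII_negative"

    def __post_init__(self) -> None:
        positive = self.pse_hit is not None and self.tata_positioned
        expected = "polIII_positive" if positive else "polIII_negative"
        if self.verdict != expected:
            raise ValueError(
                "verdict must equal (PSE present AND TATA positioned); "
                f"got {self.verdict!r} with pse_hit={self.pse_hit is not None}, "
                f"tata_positioned={self.tata_positioned}"
            )


def scan_best_hit(
    pwm: PWM, seq: str, threshold: float, window: tuple[int, int]
) -> Optional[MotifHit]:
    """Best window (ties -> smaller start) with score >= threshold among
    start offsets in the inclusive ``window``; None if no window passes."""
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty scan window {window}")
    if lo < 0 or hi + pwm.length > len(seq):
        raise ValueError(
            f"scan window {window} (+ motif length {pwm.length}) outside "
            f"sequence of length {len(seq)}"
        )
    best: Optional[MotifHit] = None
    for s in range(lo, hi + 1):
        score = score_window(pwm, seq, s)
        if score >= threshold and (best is None or score > best.score):
            best = MotifHit(start=s, score=score, motif_length=pwm.length)
    return best


def scan_pse(upstream_seq: str, model: PromoterModel) -> Optional[MotifHit]:
    """Scan for the PSE with its start between ``pse_search_window`` bases
    upstream of the locus start (``upstream_seq`` must end at the locus)."""
    d_lo, d_hi = model.pse_search_window
    length = len(upstream_seq)
    if length < d_hi:
        raise ValueError(
            f"upstream context of {length} bp too short: PSE search needs "
            f"{d_hi} bp"
        )
    return scan_best_hit(
        model.pse,
        upstream_seq,
        model.pse_threshold,
        (length - d_hi, length - d_lo),
    )


def scan_tata_positioned(
    upstream_seq: str, model: PromoterModel
) -> tuple[Optional[MotifHit], bool]:
    """Scan the whole upstream context for TATA hits.

    The gap of a hit is the number of bases between the last base of the
    match and the first base of the locus (``upstream_seq`` ends at the
    locus start).  If any passing hit has its gap inside
    ``tata_offset_window`` (inclusive), the best such hit is returned with
    ``tata_positioned=True``; otherwise the best passing hit anywhere is
    returned with ``tata_positioned=False``.
    """
    tlen = model.tata.length
    required = model.tata_offset_window[1] + tlen
    length = len(upstream_seq)
    if length < required:
        raise ValueError(
            f"upstream context of {length} bp too short for positioned-TATA "
            f"scan: need at least {required} bp"
        )
    g_lo, g_hi = model.tata_offset_window
    best_any: Optional[MotifHit] = None
    best_positioned: Optional[MotifHit] = None
    for s in range(length - tlen + 1):
        score = score_window(model.tata, upstream_seq, s)
        if score < model.tata_threshold:
            continue
        hit = MotifHit(start=s, score=score, motif_length=tlen)
        gap = length - (s + tlen)
        if best_any is None or score > best_any.score:
            best_any = hit
        if g_lo <= gap <= g_hi and (
            best_positioned is None or score > best_positioned.score
        ):
            best_positioned = hit
    if best_positioned is not None:
        return best_positioned, True
    return best_any, False


def tata_gap(hit: MotifHit, upstream_length: int) -> int:
    """Bases between the TATA 3' end and the locus 5' end."""
    return upstream_length - (hit.start + hit.motif_length)


def scan_polyT(
    downstream_seq: str,
    min_run: int = DEFAULT_MIN_POLYT_RUN,
    proximal_window: int = DEFAULT_PROXIMAL_WINDOW,
) -> Optional[TerminatorCall]:
    """First run of >= ``min_run`` consecutive T on the locus sense strand
    downstream of the 3' end (``downstream_seq`` starts at 3' end + 1)."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    i, n = 0, len(downstream_seq)
    while i < n:
        if downstream_seq[i] == "T":
            j = i
            while j < n and downstream_seq[j] == "T":
                j += 1
            if j - i >= min_run:
                return TerminatorCall(
                    run_start=i, run_length=j - i, proximal=i <= proximal_window
                )
            i = j
        else:
            i += 1
    return None


def scan_internal_promoter(
    locus_seq: str, abox: str = DEFAULT_ABOX, bbox: str = DEFAULT_BBOX
) -> tuple[bool, Optional[tuple[int, int]]]:
    """tRNA-type internal promoter: True iff an A-box match is followed
    (non-overlapping, in order) by a B-box match within the locus.  Returns
    the flag and the leftmost such (a_start, b_start) pair, if any."""
    a_starts = [m.start() for m in iupac_regex(abox).finditer(locus_seq.upper())]
    b_starts = [m.start() for m in iupac_regex(bbox).finditer(locus_seq.upper())]
    alen = len(abox)
    for a in a_starts:
        for b in b_starts:
            if b >= a + alen:
                return True, (a, b)
    return False, None


def assemble_polIII_evidence(
    pse_hit: Optional[MotifHit],
    tata_hit: Optional[MotifHit],
    tata_positioned: bool,
    terminator: Optional[TerminatorCall],
    internal_promoter: bool,
) -> PolIIIStatus:
    """Pure evidence -> verdict mapping: pol III-positive iff a PSE hit is
    present AND the TATA hit is appropriately positioned."""
    positive = pse_hit is not None and tata_positioned
    return PolIIIStatus(
        pse_hit=pse_hit,
        tata_hit=tata_hit,
        tata_positioned=bool(tata_positioned and tata_hit is not None),
        terminator=terminator,
        internal_promoter=internal_promoter,
        verdict="polIII_positive"
        if (pse_hit is not None and tata_positioned and tata_hit is not None)
        else "polIII_negative",
    )


def locus_flanks(
    genome: Mapping[str, str],
    locus: NcRNALocus,
    upstream_length: int,
    downstream_length: int,
) -> tuple[str, str, str]:
    """(upstream, body, downstream) on the locus sense strand.

    Upstream ends at the locus 5' base; downstream starts at 3' end + 1.
    Flanks are clipped at contig edges.
    """
    if locus.chrom not in genome:
        raise KeyError(f"locus {locus.locus_id}: unknown sequence id {locus.chrom!r}")
    chrom_seq = genome[locus.chrom]
    body = chrom_seq[locus.start : locus.end]
    if locus.strand == "+":
        up = chrom_seq[max(0, locus.start - upstream_length) : locus.start]
        down = chrom_seq[locus.end : locus.end + downstream_length]
        return up, body, down
    up = revcomp(chrom_seq[locus.end : locus.end + upstream_length])
    down = revcomp(chrom_seq[max(0, locus.start - downstream_length) : locus.start])
    return up, revcomp(body), down


def scan_locus(
    genome: Mapping[str, str],
    locus: NcRNALocus,
    model: PromoterModel,
    min_polyT_run: int = DEFAULT_MIN_POLYT_RUN,
    proximal_window: int = DEFAULT_PROXIMAL_WINDOW,
    abox: str = DEFAULT_ABOX,
    bbox: str = DEFAULT_BBOX,
    downstream_context: int = DEFAULT_DOWNSTREAM_CONTEXT,
) -> PolIIIStatus:
    """Full strand-aware evidence scan for one locus."""
    upstream_len = max(model.min_upstream_length, model.pse_search_window[1])
    up, body, down = locus_flanks(genome, locus, upstream_len, downstream_context)
    pse_hit = scan_pse(up, model)
    tata_hit, positioned = scan_tata_positioned(up, model)
    terminator = scan_polyT(down, min_polyT_run, proximal_window)
    internal, _ = scan_internal_promoter(body, abox, bbox)
    return assemble_polIII_evidence(pse_hit, tata_hit, positioned, terminator, internal)
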