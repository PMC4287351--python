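"""IUPAC signature-motif validation of candidate RPR/MRP RNAs.

Candidates found by homology search are confirmed by the presence of
diagnostic degenerate motifs in the transcript sequence — e.g. the
five-nucleotide GARAR consensus in the L8 loop of MRP RNA, and the
conserved regions mCR-I and mCR-V.  Matching is presence-based by default
(no positional constraint between motifs); an ordered mode requires the
motifs to occur left-to-right in the listed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .defaults import DEFAULT_SIGNATURES
from .seqs import iupac_regex, validate_iupac


def match_iupac(motif: str, seq: str) -> list[int]:
    """All (possibly overlapping) 0-based start positions where ``seq``
    matches the IUPAC ``motif``."""
    pattern = iupac_regex(motif)  # validates the motif
    seq = seq.upper()
    hits = []
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            return hits
        hits.append(m.start())
        pos = m.start() + 1


@dataclass(frozen=True)
class SignatureSet:
    """Named IUPAC motifs with required-set logic.

    ``require_all=True`` demands every motif; otherwise at least
    ``min_required`` motifs must match.  ``ordered`` additionally requires
    the matched motifs to appear left-to-right in listing order.
    """

    motifs: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SIGNATURES))
    require_all: bool = True
    min_required: int = 1
    ordered: bool = False

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("signature set must name at least one motif")
        for name, motif in self.motifs.items():
            try:
                validate_iupac(motif)
            except ValueError as err:
                raise ValueError(f"signature {name!r}: {err}") from err
        if not self.require_all and not 1 <= self.min_required <= len(self.motifs):
            raise ValueError("min_required must be in [1, n_motifs]")

    @classmethod
    def from_yaml(cls, path) -> "SignatureSet":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            motifs=dict(payload["motifs"]),
            require_all=bool(payload.get("require_all", True)),
            min_required=int(payload.get("min_required", 1)),
            ordered=bool(payload.get("ordered", False)),
        )


@dataclass(frozen=True)
class SignatureReport:
    passed: bool
    hits: Mapping[str, tuple[int, ...]]  # motif name -> start positions
    missing: tuple[str, ...]


def verify_candidate(seq: str, sigs: SignatureSet | None = None) -> SignatureReport:
    """Check the required-set logic of ``sigs`` against ``seq`` and report
    every motif's hit positions (missing motifs named explicitly)."""
    sigs = sigs or SignatureSet()
    hits = {name: tuple(match_iupac(m, seq)) for name, m in sigs.motifs.items()}
    present = [name for name in sigs.motifs if hits[name]]
    missing = tuple(name for name in sigs.motifs if not hits[name])
    if sigs.require_all:
        passed = not missing
    else:
        passed = len(present) >= sigs.min_required
    if passed and sigs.ordered:
        passed = _in_order([hits[name] for name in sigs.motifs if hits[name]])
    return SignatureReport(passed=passed, hits=hits, missing=missing)


def _in_order(hit_lists: Sequence[Sequence[int]]) -> bool:
    """True iff one strictly increasing start can be picked per motif,
    respecting listing order (greedy earliest-feasible choice)."""
    floor = -1
    for starts in hit_lists:
        nxt = [s for s in starts if s > floor]
        if not nxt:
            return False
        floor = min(nxt)
    return True
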