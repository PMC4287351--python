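"""Small DNA-string utilities shared across modules.

Internal convention everywhere in this package: plain upper-case Python
strings over {A,C,G,T,N}, 0-based half-open coordinates.
"""

from __future__ import annotations

import re

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC code -> frozenset of concrete bases (N -> {A,C,G,T}).
IUPAC_TO_BASES = {
    code: frozenset(expansion)
    for code, expansion in ambiguous_dna_values.items()
    if code != "X"
}

#: frozenset of concrete bases -> IUPAC code.
BASES_TO_IUPAC = {bases: code for code, bases in IUPAC_TO_BASES.items()}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def validate_iupac(motif: str) -> None:
    """Raise ValueError if *motif* is empty or uses a non-IUPAC symbol."""
    if not motif:
        raise ValueError("motif must be a nonempty IUPAC string")
    bad = sorted(set(motif.upper()) - set(IUPAC_TO_BASES))
    if bad:
        raise ValueError(f"invalid IUPAC symbol(s) {bad} in motif {motif!r}")


def iupac_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC motif to a plain regex over ACGT."""
    validate_iupac(motif)
    parts = []
    for sym in motif.upper():
        bases = sorted(IUPAC_TO_BASES[sym])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return re.compile("".join(parts))


def iupac_matches_at(motif: str, seq: str, start: int) -> bool:
    """True iff seq[start:start+len(motif)] matches the IUPAC motif."""
    if start < 0 or start + len(motif) > len(seq):
        return False
    for sym, base in zip(motif.upper(), seq[start : start + len(motif)]):
        if base not in IUPAC_TO_BASES[sym]:
            return False
    return True


def random_dna(rng: np.random.Generator, length: int, gc_content: float = 0.5) -> str:
    """I.i.d. nucleotides with the given GC fraction (AT and GC split evenly)."""
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    return "".join(
        rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at])
    )


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-site substitution at probability *rate*, uniform over the 3
    non-identical bases. rate 0 returns the input unchanged."""
    if rate <= 0:
        return seq
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        out[i] = rng.choice([b for b in BASES if b != out[i]])
    return "".join(out)


def realize_iupac(rng: np.random.Generator, motif: str) -> str:
    """Draw one concrete ACGT realization of an IUPAC motif."""
    validate_iupac(motif)
    return "".join(rng.choice(sorted(IUPAC_TO_BASES[s])) for s in motif.upper())
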