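"""Position-weight-matrix promoter models for type-3 pol III genes.

A species' PSE and TATA models are built from its U6/7SK-like promoter
training sequences: each training sequence is anchored to a seed consensus
(best IUPAC-mismatch window, leftmost on ties), the anchored windows are
stacked into a count matrix with pseudocounts, and windows are scored in
bits as sum_i log2(p_i(base) / background(base)).

Score thresholds are calibrated on the training set itself: the threshold
is the worst best-window score over the training promoters minus a margin,
so every training promoter passes its own model at margin 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .defaults import (
    DEFAULT_PSE_CONSENSUS,
    DEFAULT_PSE_SEARCH_WINDOW,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_TATA_CONSENSUS,
    DEFAULT_TATA_OFFSET_WINDOW,
    DEFAULT_THRESHOLD_MARGIN,
)
from .seqs import BASE_INDEX, BASES, BASES_TO_IUPAC, iupac_matches_at, validate_iupac

MODEL_FORMAT_VERSION = 1

_UNIFORM = np.full(4, 0.25)


@dataclass(frozen=True)
class PWM:
    """Per-position base probabilities plus a 0-order background model."""

    probs: np.ndarray  # shape (length, 4), base order ACGT
    background: np.ndarray = field(default_factory=lambda: _UNIFORM.copy())
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("PWM probs must have shape (length>=1, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must be 4 probabilities summing to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")

    @property
    def length(self) -> int:
        return int(self.probs.shape[0])


def build_pwm(
    aligned_seqs: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | Sequence[float] | None = None,
) -> PWM:
    """Count matrix over equal-length aligned sequences -> probability PWM.

    ``probs[i][b] = (count[i][b] + pseudocount) / (n_seqs + 4 * pseudocount)``.
    An N contributes 1/4 of a count to each base at its position.
    """
    if not aligned_seqs:
        raise ValueError("need at least one training sequence")
    length = len(aligned_seqs[0])
    if length < 1:
        raise ValueError("training sequences must be nonempty")
    if any(len(s) != length for s in aligned_seqs):
        raise ValueError("training sequences must all have the same length")
    counts = np.zeros((length, 4), dtype=float)
    for seq in aligned_seqs:
        for i, base in enumerate(seq.upper()):
            if base == "N":
                counts[i] += 0.25
            elif base in BASE_INDEX:
                counts[i, BASE_INDEX[base]] += 1.0
            else:
                raise ValueError(f"unexpected symbol {base!r} (alphabet ACGTN)")
    n = len(aligned_seqs)
    probs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    bg = _UNIFORM.copy() if background is None else np.asarray(background, float)
    return PWM(probs=probs, background=bg, pseudocount=pseudocount)


def consensus_iupac(pwm: PWM, inclusion_fraction: float = 0.5) -> str:
    """Collapse each column to the IUPAC code of every base whose probability
    is at least ``inclusion_fraction`` times the column maximum."""
    if not 0 < inclusion_fraction <= 1:
        raise ValueError("inclusion_fraction must be in (0, 1]")
    out = []
    for row in pwm.probs:
        cutoff = inclusion_fraction * row.max()
        included = frozenset(BASES[i] for i in range(4) if row[i] >= cutoff - 1e-12)
        out.append(BASES_TO_IUPAC[included])
    return "".join(out)


def score_window(pwm: PWM, seq: str, start: int) -> float:
    """Log-odds score in bits of the window seq[start : start+pwm.length].

    N in the sequence contributes 0 bits at its position (neutral, so
    assembly gaps are neither rewarded nor penalized).
    """
    if start < 0 or start + pwm.length > len(seq):
        raise IndexError(
            f"window [{start}, {start + pwm.length}) outside sequence of "
            f"length {len(seq)}"
        )
    total = 0.0
    for i in range(pwm.length):
        base = seq[start + i].upper()
        if base == "N":
            continue
        if base not in BASE_INDEX:
            raise ValueError(f"unexpected symbol {base!r} in sequence")
        j = BASE_INDEX[base]
        total += np.log2(pwm.probs[i, j] / pwm.background[j])
    return float(total)


def best_window(
    pwm: PWM, seq: str, starts: Iterable[int] | None = None
) -> tuple[int, float]:
    """Highest-scoring window; ties broken by the smaller start.

    ``starts`` defaults to every valid start offset.
    """
    if starts is None:
        starts = range(len(seq) - pwm.length + 1)
    best: tuple[int, float] | None = None
    for s in starts:
        score = score_window(pwm, seq, s)
        if best is None or score > best[1]:
            best = (s, score)
    if best is None:
        raise ValueError("no valid window start for this sequence/PWM")
    return best


def calibrate_threshold(
    pwm: PWM, training_seqs: Sequence[str], margin: float = DEFAULT_THRESHOLD_MARGIN
) -> float:
    """Threshold (bits) = min over training sequences of that sequence's best
    window score, minus ``margin``; every training promoter then scores at or
    above the threshold of its own model."""
    if not training_seqs:
        raise ValueError("need at least one training sequence")
    per_seq = []
    for seq in training_seqs:
        if len(seq) < pwm.length:
            raise ValueError(
                f"training sequence of length {len(seq)} shorter than PWM "
                f"length {pwm.length}"
            )
        per_seq.append(best_window(pwm, seq)[1])
    return float(min(per_seq) - margin)


def anchor_windows(seqs: Sequence[str], seed_consensus: str) -> list[str]:
    """Align unaligned training sequences by anchoring to a seed consensus.

    For each sequence, the window with the fewest IUPAC mismatches to the
    seed is extracted (leftmost on ties).  This stands in for a full multiple
    alignment of the U6/7SK promoter regions.
    """
    validate_iupac(seed_consensus)
    k = len(seed_consensus)
    windows = []
    for seq in seqs:
        seq = seq.upper()
        if len(seq) < k:
            raise ValueError(
                f"sequence of length {len(seq)} shorter than seed consensus ({k})"
            )
        best_start, best_mm = 0, k + 1
        for s in range(len(seq) - k + 1):
            mm = sum(
                0 if iupac_matches_at(sym, seq, s + i) else 1
                for i, sym in enumerate(seed_consensus.upper())
            )
            if mm < best_mm:
                best_start, best_mm = s, mm
        windows.append(seq[best_start : best_start + k])
    return windows


@dataclass(frozen=True)
class PromoterModel:
    """Calibrated species model of the gene-external type-3 pol III promoter:
    a PSE PWM searched in a fixed upstream window and a TATA PWM whose hit
    must sit 21-27 nt (default) upstream of the transcript start."""

    pse: PWM
    tata: PWM
    pse_threshold: float
    tata_threshold: float
    tata_offset_window: tuple[int, int] = DEFAULT_TATA_OFFSET_WINDOW
    pse_search_window: tuple[int, int] = DEFAULT_PSE_SEARCH_WINDOW

    def __post_init__(self) -> None:
        for name in ("pse_threshold", "tata_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("tata_offset_window", "pse_search_window"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} must be a nonempty nonnegative window")

    @property
    def min_upstream_length(self) -> int:
        """Shortest upstream context that covers both search windows."""
        return max(
            self.pse_search_window[1],
            self.tata_offset_window[1] + self.tata.length,
        )


def build_promoter_model(
    training_seqs: Sequence[str],
    pse_consensus: str = DEFAULT_PSE_CONSENSUS,
    tata_consensus: str = DEFAULT_TATA_CONSENSUS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Sequence[float] | None = None,
    margin: float = DEFAULT_THRESHOLD_MARGIN,
    tata_offset_window: tuple[int, int] = DEFAULT_TATA_OFFSET_WINDOW,
    pse_search_window: tuple[int, int] = DEFAULT_PSE_SEARCH_WINDOW,
) -> PromoterModel:
    """Anchor the training promoters to the PSE and TATA seed consensi,
    build both PWMs, and calibrate their thresholds on the same set."""
    pse_pwm = build_pwm(anchor_windows(training_seqs, pse_consensus), pseudocount, background)
    tata_pwm = build_pwm(anchor_windows(training_seqs, tata_consensus), pseudocount, background)
    return PromoterModel(
        pse=pse_pwm,
        tata=tata_pwm,
        pse_threshold=calibrate_threshold(pse_pwm, training_seqs, margin),
        tata_threshold=calibrate_threshold(tata_pwm, training_seqs, margin),
        tata_offset_window=tuple(tata_offset_window),
        pse_search_window=tuple(pse_search_window),
    )


def _pwm_to_dict(pwm: PWM) -> dict:
    return {
        "probs": [[round(float(p), 6) for p in row] for row in pwm.probs],
        "background": [round(float(p), 6) for p in pwm.background],
        "pseudocount": pwm.pseudocount,
    }


def _pwm_from_dict(d: dict) -> PWM:
    probs = np.asarray(d["probs"], dtype=float)
    probs = probs / probs.sum(axis=1, keepdims=True)  # re-normalize 6-decimal rounding
    bg = np.asarray(d["background"], dtype=float)
    return PWM(probs=probs, background=bg / bg.sum(), pseudocount=d["pseudocount"])


def save_model(model: PromoterModel, path) -> None:
    payload = {
        "format": "pol3scan-promoter-model",
        "version": MODEL_FORMAT_VERSION,
        "pse": _pwm_to_dict(model.pse),
        "tata": _pwm_to_dict(model.tata),
        "pse_threshold": round(model.pse_threshold, 6),
        "tata_threshold": round(model.tata_threshold, 6),
        "tata_offset_window": list(model.tata_offset_window),
        "pse_search_window": list(model.pse_search_window),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path) -> PromoterModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "pol3scan-promoter-model":
        raise ValueError(f"{path} is not a pol3scan promoter model file")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {payload.get('version')}")
    return PromoterModel(
        pse=_pwm_from_dict(payload["pse"]),
        tata=_pwm_from_dict(payload["tata"]),
        pse_threshold=float(payload["pse_threshold"]),
        tata_threshold=float(payload["tata_threshold"]),
        tata_offset_window=tuple(payload["tata_offset_window"]),
        pse_search_window=tuple(payload["pse_search_window"]),
    )
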