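"""The two-group divide: per-locus and per-species classification.

A locus with a complete gene-external pol III promoter is an independent
pol III transcription unit wherever it sits.  A signal-free locus fully
embedded in a host-gene intron is a promoterless passenger transcribed by
pol II from the recipient gene's promoter.  A signal-free locus that is not
embedded cannot be resolved by sequence alone and stays unresolved (the
body-louse situation: no pol III signals, currently annotated between two
genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .context import ContextCall
from .scan import PolIIIStatus

EMBEDDED = "embedded_polII"
INDEPENDENT = "independent_polIII"
UNRESOLVED = "unresolved"

GROUP_EMBEDDED = "embedded group"
GROUP_POLIII = "polIII group"
GROUP_MIXED = "mixed/unresolved"


@dataclass(frozen=True)
class ClassificationRecord:
    species_id: str
    locus_id: str
    verdict: str  # polIII_positive | polIII_negative
    placement: str
    recipient_gene_id: str | None
    intron_ordinal: int | None
    last_intron: bool
    orientation: str
    final_class: str

    def __post_init__(self) -> None:
        if self.final_class == EMBEDDED and not (
            self.verdict == "polIII_negative" and self.placement == "intronic"
        ):
            raise ValueError("embedded_polII requires polIII_negative + intronic")
        if self.final_class == INDEPENDENT and self.verdict != "polIII_positive":
            raise ValueError("independent_polIII requires polIII_positive")


def classify_locus(status: PolIIIStatus, context: ContextCall) -> str:
    """Map (pol III verdict, genomic context) to the final class.

    Orientation does not gate the embedded class: the group definition
    rests on signal absence plus intronic embedding, and a pol III-positive
    intronic locus (the centipede arrangement) is classed independent by
    its signals, not excluded by its orientation.
    """
    if status.verdict == "polIII_positive":
        return INDEPENDENT
    if context.placement == "intronic":
        return EMBEDDED
    return UNRESOLVED


def make_record(
    species_id: str, status: PolIIIStatus, context: ContextCall
) -> ClassificationRecord:
    return ClassificationRecord(
        species_id=species_id,
        locus_id=context.locus_id,
        verdict=status.verdict,
        placement=context.placement,
        recipient_gene_id=context.recipient_gene_id,
        intron_ordinal=context.intron_ordinal,
        last_intron=context.last_intron,
        orientation=context.orientation,
        final_class=classify_locus(status, context),
    )


def summarize_species(records: Sequence[ClassificationRecord]) -> pd.DataFrame:
    """Per-species class counts and divide assignment.

    A species joins the embedded group iff it has at least one embedded
    locus and no independent pol III locus; the pol III group iff it has at
    least one independent locus and no embedded one.  Species with both
    classes (a would-be counterexample to the observed divide) or with only
    unresolved loci are flagged mixed/unresolved rather than forced into
    either side.
    """
    if not records:
        raise ValueError("summarize_species needs at least one record")
    rows = []
    frame = pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "final_class": [r.final_class for r in records],
        }
    )
    for species_id, grp in frame.groupby("species_id", sort=True):
        n_emb = int((grp["final_class"] == EMBEDDED).sum())
        n_ind = int((grp["final_class"] == INDEPENDENT).sum())
        n_unres = int((grp["final_class"] == UNRESOLVED).sum())
        if n_emb >= 1 and n_ind == 0:
            group = GROUP_EMBEDDED
        elif n_ind >= 1 and n_emb == 0:
            group = GROUP_POLIII
        else:
            group = GROUP_MIXED
        rows.append(
            {
                "species_id": species_id,
                "n_loci": len(grp),
                "n_embedded_polII": n_emb,
                "n_independent_polIII": n_ind,
                "n_unresolved": n_unres,
                "group": group,
            }
        )
    return pd.DataFrame(rows)


def records_to_frame(records: Sequence[ClassificationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "locus_id": r.locus_id,
                "verdict": r.verdict,
                "placement": r.placement,
                "recipient_gene_id": r.recipient_gene_id or "",
                "intron_ordinal": "" if r.intron_ordinal is None else r.intron_ordinal,
                "last_intron": r.last_intron,
                "orientation": r.orientation,
                "final_class": r.final_class,
            }
            for r in records
        ]
    )
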