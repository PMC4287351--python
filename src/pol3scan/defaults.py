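"""Shipped default parameters.

The source studies build species-specific PSE/TATA consensi from U6/7SK
promoter alignments and never publish a single universal string, so every
motif here is a configurable seed, not a fixed truth.  The mCR-I / mCR-V
strings in particular are synthetic placeholders (see docs/methods.md).
"""

# Type-3 pol III promoter architecture -------------------------------------

#: Seed consensus for the proximal sequence element (PSE), a 14-mer.
DEFAULT_PSE_CONSENSUS = "CTCACCCTAACTCA"

#: Seed consensus for the TATA box.
DEFAULT_TATA_CONSENSUS = "TATAAA"

#: Inclusive gap window (bases between the TATA 3' end and the locus 5' end)
#: within which a TATA hit counts as "appropriately positioned".
DEFAULT_TATA_OFFSET_WINDOW = (21, 27)

#: Inclusive window of upstream distances (locus start minus PSE start)
#: searched for the PSE.
DEFAULT_PSE_SEARCH_WINDOW = (45, 80)

# Terminator ---------------------------------------------------------------

#: Minimum poly-T run length called as a candidate pol III terminator.
DEFAULT_MIN_POLYT_RUN = 4

#: A terminator starting within this many bp of the locus 3' end is
#: flagged proximal.
DEFAULT_PROXIMAL_WINDOW = 30

# Gene-internal pol III promoter (tRNA-type) --------------------------------

DEFAULT_ABOX = "TGGCNNAGTGG"
DEFAULT_BBOX = "GTTCGANNC"

# RPR / MRP identity signatures ---------------------------------------------

#: GARAR is the five-nucleotide L8-loop consensus diagnostic of MRP RNA.
#: The mCR-I/mCR-V entries are synthetic placeholder consensi: the conserved
#: regions are named in the literature without a printed IUPAC string, so
#: these defaults exist to exercise the machinery and must be overridden
#: with curated motifs for real analyses.
DEFAULT_SIGNATURES = {
    "GARAR": "GARAR",
    "mCR-I": "GAGGAAAGTCC",
    "mCR-V": "AGGCWGAGARA",
}

# PWM ------------------------------------------------------------------------

DEFAULT_PSEUDOCOUNT = 0.25
DEFAULT_THRESHOLD_MARGIN = 0.0
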