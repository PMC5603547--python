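"""Length/ORF-based partitioning of transcripts into lncRNA and mRNA.

A transcript is called lncRNA when it is at least ``min_lnc_len``
nucleotides long, its longest open reading frame in any of the six frames
is shorter than ``max_orf_aa`` amino acids, and (optionally) it has no
protein-database hit; a long ORF or a protein hit makes it mRNA; anything
else is ambiguous.  The 200 nt floor is the conventional lncRNA length
definition; the 100 aa ORF ceiling is a widespread coding-potential
heuristic.  Both are exposed as parameters.
"""

from __future__ import annotations

import re
from typing import Iterable

import pandas as pd
from Bio.Seq import Seq

__all__ = ["longest_orf", "classify_transcripts", "transcript_table_from_fasta"]

_STOPS = {"TAA", "TAG", "TGA"}
_VALID = re.compile(r"^[ACGTN]+$")


def _longest_orf_frame(seq: str, offset: int) -> int:
    """Longest ATG..stop span (aa, stop excluded) in one reading frame."""
    best = 0
    start: int | None = None
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in _STOPS:
            if start is not None:
                best = max(best, (i - start) // 3)
                start = None
        elif codon == "ATG" and start is None:
            start = i
    return best


def longest_orf(sequence: str) -> int:
    """Length in amino acids of the longest ORF over all six frames.

    ORFs run from an ATG to the first in-frame stop codon; the stop is not
    counted.  N never matches a start or stop.  Returns 0 when no complete
    ORF exists.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    if not _VALID.match(seq):
        raise ValueError("sequence must be over {A, C, G, T, N}")
    rc = str(Seq(seq).reverse_complement())
    return max(
        _longest_orf_frame(strand, frame) for strand in (seq, rc) for frame in (0, 1, 2)
    )


def classify_transcripts(
    records: pd.DataFrame,
    min_lnc_len: int = 200,
    max_orf_aa: int = 100,
    use_hits: bool = False,
) -> pd.DataFrame:
    """Assign a biotype (lncRNA / mRNA / ambiguous) to every transcript.

    ``records`` needs columns ``length`` and ``longest_orf_aa`` (the latter
    is computed from a ``sequence`` column when absent); with
    ``use_hits=True`` a boolean ``hit_flag`` column (protein-database hit)
    is consulted as well.  The result adds a ``biotype`` column; every row
    receives exactly one label and the order of rows is preserved.
    """
    out = records.copy()
    if "length" not in out.columns or out["length"].isna().any():
        raise ValueError("every transcript needs a length")
    if "longest_orf_aa" not in out.columns:
        if "sequence" not in out.columns:
            raise ValueError("need longest_orf_aa or sequence to classify")
        out["longest_orf_aa"] = out["sequence"].map(longest_orf)
    hit = (
        out["hit_flag"].fillna(False).astype(bool)
        if use_hits and "hit_flag" in out.columns
        else pd.Series(False, index=out.index)
    )
    is_coding = (out["longest_orf_aa"] >= max_orf_aa) | hit
    is_lnc = (out["length"] >= min_lnc_len) & (out["longest_orf_aa"] < max_orf_aa) & ~hit
    out["biotype"] = "ambiguous"
    out.loc[is_coding, "biotype"] = "mRNA"
    out.loc[is_lnc, "biotype"] = "lncRNA"
    return out


def transcript_table_from_fasta(path) -> pd.DataFrame:
    """Build an (id, length, longest_orf_aa) table from a FASTA file."""
    from Bio import SeqIO

    rows = [
        {"id": rec.id, "length": len(rec.seq), "longest_orf_aa": longest_orf(str(rec.seq))}
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not rows:
        raise ValueError(f"no sequences in {path}")
    return pd.DataFrame(rows).set_index("id")
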