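"""lncRNA discovery: candidate filtering, coding potential, positional classes.

The candidate filter keeps assembled transcripts that are at least 200 nt of
spliced length and are not redundant re-assemblies of known mRNAs (identical
intron chain on the same strand; for mono-exonic transcripts, reciprocal
same-strand exonic overlap of at least 50%). Candidates called non-coding by
every available predictor (Venn intersection) become lncRNAs, which are then
assigned one of four positional classes relative to protein-coding genes:
lincRNA, antisense, sense_intronic, sense_overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .models import CodingCall, TranscriptModel, ValidationError

MIN_LNCRNA_LENGTH = 200      # nt, inclusive: exactly 200 survives
ORF_CODING_THRESHOLD = 300   # nt (100 codons) for the builtin predictor

LNCRNA_CLASSES = ("lincRNA", "antisense", "sense_intronic", "sense_overlapping")

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class LncRNAClass:
    transcript_id: str
    lncrna_class: str


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _mono_redundant(t: TranscriptModel, m: TranscriptModel) -> bool:
    ov = _overlap(t.span, m.span)
    return (ov >= 0.5 * t.spliced_length) and (ov >= 0.5 * m.spliced_length)


def filter_candidates(
    transcripts: Sequence[TranscriptModel],
    known_mrna: Sequence[TranscriptModel],
) -> list[TranscriptModel]:
    """Length + redundancy filter producing lncRNA candidates.

    Input order is preserved; retained transcripts are returned as copies
    with ``biotype='candidate'``.
    """
    for t in list(transcripts) + list(known_mrna):
        t.validate()

    by_loc: dict[tuple[str, str], list[TranscriptModel]] = {}
    for m in known_mrna:
        by_loc.setdefault((m.chrom, m.strand), []).append(m)

    kept: list[TranscriptModel] = []
    for t in transcripts:
        if t.spliced_length < MIN_LNCRNA_LENGTH:
            continue
        redundant = False
        for m in by_loc.get((t.chrom, t.strand), []):
            if len(t.exons) > 1 and len(m.exons) > 1:
                if t.intron_chain() == m.intron_chain():
                    redundant = True
                    break
            elif len(t.exons) == 1 and len(m.exons) == 1:
                if _mono_redundant(t, m):
                    redundant = True
                    break
        if not redundant:
            kept.append(TranscriptModel(t.transcript_id, t.gene_id, t.chrom,
                                        t.strand, list(t.exons), "candidate"))
    return kept


def longest_orf(seq: str) -> int:
    """Length (nt, stop included) of the longest forward-frame ORF; 0 if none.

    U is treated as T; the scan covers the three forward frames only.
    """
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in "ACGT":
            raise ValidationError(f"non-nucleotide character {ch!r} at position {i}")
    best = 0
    n = len(s)
    for frame in range(3):
        start = None
        for pos in range(frame, n - 2, 3):
            codon = s[pos:pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOPS:
                best = max(best, pos + 3 - start)
                start = None
    return best


def builtin_coding_calls(
    candidates: Sequence[TranscriptModel],
    sequences: dict[str, str],
    orf_threshold: int = ORF_CODING_THRESHOLD,
) -> list[CodingCall]:
    """Builtin ORF-length predictor: coding iff longest ORF >= threshold."""
    missing = [t.transcript_id for t in candidates
               if t.transcript_id not in sequences]
    if missing:
        raise ValidationError(f"missing sequences for candidates: {missing}")
    return [
        CodingCall(t.transcript_id, "builtin-ORF",
                   longest_orf(sequences[t.transcript_id]) >= orf_threshold)
        for t in candidates
    ]


def consensus_noncoding(
    candidates: Sequence[TranscriptModel],
    coding_calls: Iterable[CodingCall],
    min_predictors: int = 1,
) -> list[TranscriptModel]:
    """Venn intersection: a candidate is a lncRNA iff every predictor that
    scored it called it non-coding."""
    calls_by_tid: dict[str, list[CodingCall]] = {}
    for c in coding_calls:
        calls_by_tid.setdefault(c.transcript_id, []).append(c)
    short = [t.transcript_id for t in candidates
             if len(calls_by_tid.get(t.transcript_id, [])) < min_predictors]
    if short:
        raise ValidationError(
            f"candidates with fewer than {min_predictors} coding calls: {short}")
    out = []
    for t in candidates:
        if all(not c.is_coding for c in calls_by_tid[t.transcript_id]):
            out.append(TranscriptModel(t.transcript_id, t.gene_id, t.chrom,
                                       t.strand, list(t.exons), "lncRNA"))
    return out


def classify_lncrna(
    lncrna: TranscriptModel,
    genes: Sequence[TranscriptModel],
) -> LncRNAClass:
    """Positional class of one lncRNA against a set of coding gene models.

    Precedence: (1) no genomic-span overlap with any gene -> lincRNA;
    (2) overlap with an opposite-strand gene -> antisense; (3) same strand,
    span entirely inside one intron -> sense_intronic; (4) otherwise
    (same-strand overlap touching exons) -> sense_overlapping.
    """
    lncrna.validate()
    span = lncrna.span
    overlapping = [g for g in genes
                   if g.chrom == lncrna.chrom and _overlap(span, g.span) > 0]
    if not overlapping:
        return LncRNAClass(lncrna.transcript_id, "lincRNA")
    if any(g.strand != lncrna.strand for g in overlapping):
        return LncRNAClass(lncrna.transcript_id, "antisense")
    for g in overlapping:
        for istart, iend in g.introns:
            if istart <= span[0] and span[1] <= iend:
                return LncRNAClass(lncrna.transcript_id, "sense_intronic")
    return LncRNAClass(lncrna.transcript_id, "sense_overlapping")


def classify_all(
    lncrnas: Sequence[TranscriptModel],
    genes: Sequence[TranscriptModel],
) -> pd.DataFrame:
    rows = [(c.transcript_id, c.lncrna_class)
            for c in (classify_lncrna(l, genes) for l in lncrnas)]
    return pd.DataFrame(rows, columns=["transcript_id", "class"])
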