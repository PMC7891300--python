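"""File I/O: GTF, FASTA, counts/samples TSV, coding-call TSV, truth TSVs.

GTF on disk is 1-based inclusive; in memory everything is 0-based half-open.
The conversion (start-1, end unchanged) is applied symmetrically on read and
write and is covered by an explicit round-trip test.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import CodingCall, CountMatrix, SimTruth, TranscriptModel, ValidationError


# ---------------------------------------------------------------------------
# GTF

def _gtf_attributes(pairs: dict[str, str]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs.items())


def write_gtf(transcripts: Iterable[TranscriptModel], path: str) -> None:
    """Write transcripts (with gene, transcript and exon lines) as GTF."""
    lines: list[str] = []
    for t in transcripts:
        attrs = {"gene_id": t.gene_id, "transcript_id": t.transcript_id,
                 "biotype": t.biotype}
        gene_attrs = {"gene_id": t.gene_id, "biotype": t.biotype}
        # 0-based half-open -> 1-based inclusive: start+1, end unchanged
        lines.append("\t".join([
            t.chrom, "cerna", "gene", str(t.start + 1), str(t.end), ".",
            t.strand, ".", _gtf_attributes(gene_attrs)]))
        lines.append("\t".join([
            t.chrom, "cerna", "transcript", str(t.start + 1), str(t.end), ".",
            t.strand, ".", _gtf_attributes(attrs)]))
        for s, e in t.exons:
            lines.append("\t".join([
                t.chrom, "cerna", "exon", str(s + 1), str(e), ".",
                t.strand, ".", _gtf_attributes(attrs)]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def _parse_attributes(field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path: str) -> list[TranscriptModel]:
    """Read a GTF into TranscriptModels (exon lines define structure)."""
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValidationError(f"malformed GTF line in {path}: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attr = fields
            if ftype != "exon":
                continue
            attrs = _parse_attributes(attr)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValidationError(f"exon without transcript_id in {path}")
            if tid not in meta:
                meta[tid] = (attrs.get("gene_id", tid), chrom, strand,
                             attrs.get("biotype", "other"))
                order.append(tid)
            # 1-based inclusive -> 0-based half-open
            exons.setdefault(tid, []).append((int(start) - 1, int(end)))
    models = []
    for tid in order:
        gene_id, chrom, strand, biotype = meta[tid]
        t = TranscriptModel(tid, gene_id, chrom, strand,
                            sorted(exons[tid]), biotype)
        t.validate()
        models.append(t)
    return models


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# Counts / samples / coding calls / truth TSVs

def write_counts(cm: CountMatrix, counts_path: str,
                 samples_path: str | None = None) -> None:
    df = cm.counts.copy()
    df.index.name = "feature_id"
    df.to_csv(counts_path, sep="\t")
    if samples_path is not None:
        pd.DataFrame({
            "sample_id": list(cm.counts.columns),
            "condition": [cm.condition_of[s] for s in cm.counts.columns],
        }).to_csv(samples_path, sep="\t", index=False)


def read_counts(counts_path: str, samples_path: str,
                lengths: pd.Series | None = None) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    condition_of = dict(zip(samples["sample_id"], samples["condition"]))
    cm = CountMatrix(df, condition_of, lengths)
    cm.validate()
    return cm


def read_coding_calls(path: str) -> list[CodingCall]:
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "predictor", "is_coding"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"coding-call TSV must have columns {sorted(required)}")
    truthy = {"1", "true", "yes", "coding"}
    calls = []
    for row in df.itertuples(index=False):
        val = row.is_coding
        is_coding = (str(val).strip().lower() in truthy) if not isinstance(
            val, (bool,)) else bool(val)
        if isinstance(val, (int, float)) and not isinstance(val, bool):
            is_coding = bool(val)
        calls.append(CodingCall(row.transcript_id, row.predictor, is_coding))
    return calls


def write_truth(truth: SimTruth, outdir: str, prefix: str = "truth") -> None:
    os.makedirs(outdir, exist_ok=True)
    pd.DataFrame(sorted(truth.de_features),
                 columns=["feature_id", "direction"]).to_csv(
        os.path.join(outdir, f"{prefix}_de.tsv"), sep="\t", index=False)
    pd.DataFrame(sorted(truth.planted_target_pairs),
                 columns=["mirna_id", "target_id"]).to_csv(
        os.path.join(outdir, f"{prefix}_pairs.tsv"), sep="\t", index=False)
    pd.DataFrame(sorted(truth.planted_triplets),
                 columns=["lncrna_id", "mirna_id", "mrna_id"]).to_csv(
        os.path.join(outdir, f"{prefix}_triplets.tsv"), sep="\t", index=False)


def read_truth(outdir: str, prefix: str = "truth") -> SimTruth:
    de = pd.read_csv(os.path.join(outdir, f"{prefix}_de.tsv"), sep="\t")
    pairs = pd.read_csv(os.path.join(outdir, f"{prefix}_pairs.tsv"), sep="\t")
    trips = pd.read_csv(os.path.join(outdir, f"{prefix}_triplets.tsv"), sep="\t")
    truth = SimTruth(
        de_features=set(map(tuple, de.itertuples(index=False, name=None))),
        planted_target_pairs=set(map(tuple, pairs.itertuples(index=False, name=None))),
        planted_triplets=set(map(tuple, trips.itertuples(index=False, name=None))),
    )
    truth.validate()
    return truth
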