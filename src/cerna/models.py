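"""Core domain containers shared across the pipeline.

Coordinates are 0-based half-open throughout the package; GTF I/O converts
to/from the on-disk 1-based inclusive convention (see :mod:`cerna.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input object violates a documented invariant."""


class SizingError(ValueError):
    """A chromosome is too short to place the requested loci."""


class SequenceDesignError(RuntimeError):
    """Sequence scrubbing/placement exceeded its attempt cap."""


Interval = tuple[int, int]

STRANDS = ("+", "-")


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript on a genome.

    ``exons`` are [start, end) 0-based half-open genomic intervals, sorted
    ascending and non-overlapping.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    biotype: str = "other"  # mRNA | candidate | lncRNA | other

    def validate(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(
                f"transcript {self.transcript_id}: bad strand {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValidationError(
                    f"transcript {self.transcript_id}: malformed exon "
                    f"[{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons overlap or are "
                    f"unsorted at [{start}, {end})"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> list[Interval]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def intron_chain(self) -> tuple[Interval, ...]:
        return tuple(self.introns)


@dataclass
class CodingCall:
    """One coding-potential verdict for one transcript from one predictor."""

    transcript_id: str
    predictor: str
    is_coding: bool


@dataclass
class CountMatrix:
    """Feature-by-sample integer counts with a sample->condition map.

    ``counts`` is a pandas DataFrame (rows = features, columns = samples).
    ``feature_lengths`` (nt) enables FPKM.
    """

    counts: pd.DataFrame
    condition_of: dict[str, str]
    feature_lengths: pd.Series | None = None

    def validate(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
        if arr.size and (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.condition_of]
        if missing:
            raise ValidationError(f"samples without condition label: {missing}")
        conds = self.conditions
        if len(conds) != 2:
            raise ValidationError(
                f"expected exactly two conditions, found {conds}"
            )
        for c in conds:
            if len(self.samples_in(c)) < 2:
                raise ValidationError(
                    f"condition {c!r} has fewer than 2 replicates"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            c = self.condition_of[s]
            if c not in seen:
                seen.append(c)
        return sorted(seen)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_of[s] == condition]


@dataclass
class SimTruth:
    """Ground-truth ledger written by the simulator, read by recovery tests."""

    de_features: set[tuple[str, str]] = field(default_factory=set)
    planted_target_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_triplets: set[tuple[str, str, str]] = field(default_factory=set)

    def validate(self) -> None:
        de_ids = {f for f, _ in self.de_features}
        for lnc, mir, mrna in self.planted_triplets:
            if (mir, lnc) not in self.planted_target_pairs:
                raise ValidationError(
                    f"triplet ({lnc},{mir},{mrna}): missing planted pair ({mir},{lnc})"
                )
            if (mir, mrna) not in self.planted_target_pairs:
                raise ValidationError(
                    f"triplet ({lnc},{mir},{mrna}): missing planted pair ({mir},{mrna})"
                )
            for member in (lnc, mir, mrna):
                if member not in de_ids:
                    raise ValidationError(
                        f"triplet member {member} is not a planted DE feature"
                    )

    def direction_of(self, feature_id: str) -> str | None:
        for f, d in self.de_features:
            if f == feature_id:
                return d
        return None
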