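"""Synthetic two-stage RNA-seq study with planted truth.

Emulates the study design the pipeline is built for: two conditions
("IB_I", "IB_III") with three biological replicates each; negative-binomial
counts with lognormal per-feature means and lognormal library-size factors;
a subset of mRNAs, lncRNAs and miRNAs differentially expressed at a planted
fold change; and planted ceRNA triplets in which a lncRNA and an mRNA carry
an exact 8mer site for the same miRNA, share a per-sample lognormal factor
(inducing strong positive co-expression) and move opposite to that miRNA.

Everything is deterministic given ``SimConfig.seed``; annotation, sequence
and count generation draw from independent seeded streams so each can be
re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (CountMatrix, SequenceDesignError, SimTruth, SizingError,
                     TranscriptModel, ValidationError)
from .targets import revcomp

CONDITIONS = ("IB_I", "IB_III")
_CLASS_CYCLE = ("lincRNA", "antisense", "sense_intronic", "sense_overlapping")
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-design and generative parameters; defaults are the conditions
    the recovery experiments run under."""

    n_mrna: int = 500
    n_lncrna: int = 200
    n_mirna: int = 50
    n_chrom: int = 5
    replicates_per_condition: int = 3
    n_de_mrna: int = 50
    n_de_lncrna: int = 30
    n_de_mirna: int = 10
    n_planted_triplets: int = 10
    baseline_log_mean: float = 6.0   # ln of the typical feature mean (~400)
    baseline_log_sd: float = 0.5
    dispersion: float = 0.02         # NB phi: Var = mu + phi*mu^2
    de_fold: float = 4.0
    shared_factor_sd: float = 0.8    # sd of ln(shared per-sample factor)
    library_factor_sd: float = 0.1
    transcript_len_range: tuple[int, int] = (200, 2000)
    mirna_len_range: tuple[int, int] = (20, 24)
    chrom_length: int | None = None  # None: sized to fit; else hard bound
    max_rejection_attempts: int = 1000
    seed: int = 0
    conditions: tuple[str, str] = CONDITIONS

    def validate(self) -> None:
        counts = dict(n_mrna=self.n_mrna, n_lncrna=self.n_lncrna,
                      n_mirna=self.n_mirna, n_chrom=self.n_chrom,
                      n_de_mrna=self.n_de_mrna, n_de_lncrna=self.n_de_lncrna,
                      n_de_mirna=self.n_de_mirna,
                      n_planted_triplets=self.n_planted_triplets)
        for name, value in counts.items():
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")
        if self.replicates_per_condition < 2:
            raise ValidationError("replicates_per_condition must be >= 2")
        if self.n_planted_triplets > min(self.n_de_mrna, self.n_de_lncrna,
                                         self.n_de_mirna):
            raise ValidationError(
                "n_planted_triplets exceeds a planted-DE pool: "
                f"{self.n_planted_triplets} > min("
                f"{self.n_de_mrna}, {self.n_de_lncrna}, {self.n_de_mirna})")
        if self.n_de_mrna > self.n_mrna or self.n_de_lncrna > self.n_lncrna \
                or self.n_de_mirna > self.n_mirna:
            raise ValidationError("DE counts exceed feature counts")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.de_fold <= 1:
            raise ValidationError("de_fold must be > 1")
        if self.shared_factor_sd < 0:
            raise ValidationError("shared_factor_sd must be >= 0")
        lo, hi = self.transcript_len_range
        if lo < 50 or hi < lo:
            raise ValidationError("bad transcript_len_range")

    # ids ------------------------------------------------------------------
    def mrna_ids(self) -> list[str]:
        return [f"mRNA_{i:05d}" for i in range(1, self.n_mrna + 1)]

    def lncrna_ids(self) -> list[str]:
        return [f"LNC_{i:05d}" for i in range(1, self.n_lncrna + 1)]

    def mirna_ids(self) -> list[str]:
        return [f"miR_{i:04d}" for i in range(1, self.n_mirna + 1)]

    def sample_ids(self) -> list[str]:
        return [f"{c}_{r}" for c in self.conditions
                for r in range(1, self.replicates_per_condition + 1)]

    def condition_of(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_ids()}


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2 ** 31), stream])


# ---------------------------------------------------------------------------
# Annotation

def _split_length(rng: np.random.Generator, total: int, parts: int,
                  minimum: int = 50) -> list[int]:
    """Split `total` into `parts` pieces of at least `minimum` each."""
    if total < parts * minimum:
        return [total]
    lens: list[int] = []
    remaining = total
    for k in range(parts - 1):
        max_here = remaining - minimum * (parts - 1 - k)
        ln = int(rng.integers(minimum, max_here + 1))
        lens.append(ln)
        remaining -= ln
    lens.append(remaining)
    return lens


def simulate_annotation(config: SimConfig) -> list[TranscriptModel]:
    """Place mRNA gene models and lncRNAs of all four positional classes.

    mRNA genes are non-overlapping, three-exon loci laid out left to right on
    ``n_chrom`` chromosomes; lncRNAs cycle through the positional classes,
    hosted by (or placed between) successive genes.
    """
    config.validate()
    rng = _rng(config, 1)
    lo, hi = config.transcript_len_range
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]

    genes: list[TranscriptModel] = []
    cursors = {c: 10_000 for c in chroms}
    for i, tid in enumerate(config.mrna_ids()):
        chrom = chroms[i % len(chroms)]
        strand = "+" if rng.integers(2) == 0 else "-"
        spliced = int(rng.integers(max(lo, 300), hi + 1))
        exon_lens = _split_length(rng, spliced, 3, minimum=80)
        intron_lens = [int(rng.integers(600, 1500)) for _ in range(len(exon_lens) - 1)]
        start = cursors[chrom]
        exons, pos = [], start
        for k, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if k < len(intron_lens):
                pos += intron_lens[k]
        cursors[chrom] = pos + int(rng.integers(20_000, 40_000))
        genes.append(TranscriptModel(tid, f"gene_{tid}", chrom, strand,
                                     exons, "mRNA"))

    genes_by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    lncs: list[TranscriptModel] = []
    for j, tid in enumerate(config.lncrna_ids()):
        klass = _CLASS_CYCLE[j % len(_CLASS_CYCLE)]
        host = genes[j % len(genes)] if genes else None
        if host is None:
            raise ValidationError("lncRNA placement requires at least one mRNA gene")
        other = "-" if host.strand == "+" else "+"
        length = int(rng.integers(lo, hi + 1))
        if klass == "lincRNA":
            start = host.end + 5_000 + int(rng.integers(0, 2_000))
            half = length // 2
            exons = [(start, start + half),
                     (start + half + 400, start + length + 400)]
            strand = "+" if rng.integers(2) == 0 else "-"
        elif klass == "antisense":
            start = max(0, host.start - length // 2)
            exons = [(start, start + length)]
            strand = other
        elif klass == "sense_intronic":
            istart, iend = host.introns[0]
            fit = min(length, iend - istart - 20)
            if fit < 200:
                fit = iend - istart - 20  # introns are >=600 so >=200 fits
            start = istart + 10
            exons = [(start, start + fit)]
            strand = host.strand
        else:  # sense_overlapping
            start = max(0, host.start - length // 2)
            exons = [(start, start + length)]
            strand = host.strand
        lncs.append(TranscriptModel(tid, f"gene_{tid}", host.chrom, strand,
                                    exons, "lncRNA"))

    out = genes + lncs
    if config.chrom_length is not None:
        for t in out:
            if t.end > config.chrom_length:
                raise SizingError(
                    f"chromosome {t.chrom} too short "
                    f"({config.chrom_length} bp) to place {t.transcript_id} "
                    f"ending at {t.end}")
    for t in out:
        t.validate()
    return out


# ---------------------------------------------------------------------------
# Counts

def simulate_counts(
    config: SimConfig,
) -> tuple[CountMatrix, CountMatrix, CountMatrix, SimTruth]:
    """NB count matrices for mRNA, lncRNA and miRNA plus the truth ledger."""
    config.validate()
    rng = _rng(config, 3)
    samples = config.sample_ids()
    condition_of = config.condition_of()
    n_rep = config.replicates_per_condition
    cond_idx = np.array([0] * n_rep + [1] * n_rep)  # 0 = first condition

    lib = np.exp(rng.normal(0.0, config.library_factor_sd, size=len(samples)))

    ids = {"mrna": config.mrna_ids(), "lnc": config.lncrna_ids(),
           "mir": config.mirna_ids()}
    n_de = {"mrna": config.n_de_mrna, "lnc": config.n_de_lncrna,
            "mir": config.n_de_mirna}
    de_sets = {k: [ids[k][i] for i in
                   rng.choice(len(ids[k]), size=n_de[k], replace=False)]
               for k in ids}

    directions: dict[str, str] = {}
    truth = SimTruth()
    # triplets take the first members of each shuffled DE pool
    for t in range(config.n_planted_triplets):
        lnc, mir, mrna = de_sets["lnc"][t], de_sets["mir"][t], de_sets["mrna"][t]
        d = "up" if rng.integers(2) == 0 else "down"
        directions[lnc] = d
        directions[mrna] = d
        directions[mir] = "down" if d == "up" else "up"
        truth.planted_triplets.add((lnc, mir, mrna))
        truth.planted_target_pairs.add((mir, lnc))
        truth.planted_target_pairs.add((mir, mrna))
    for k in ids:
        for f in de_sets[k]:
            if f not in directions:
                directions[f] = "up" if rng.integers(2) == 0 else "down"
            truth.de_features.add((f, directions[f]))

    # shared per-sample factor per triplet, applied to lncRNA and mRNA means
    shared = np.exp(rng.normal(0.0, config.shared_factor_sd,
                               size=(config.n_planted_triplets, len(samples)))) \
        if config.shared_factor_sd > 0 else \
        np.ones((config.n_planted_triplets, len(samples)))
    shared_of: dict[str, int] = {}
    for t, (lnc, mir, mrna) in enumerate(
            (de_sets["lnc"][t], de_sets["mir"][t], de_sets["mrna"][t])
            for t in range(config.n_planted_triplets)):
        shared_of[lnc] = t
        shared_of[mrna] = t

    def make_matrix(feature_ids: list[str]) -> CountMatrix:
        lam = np.exp(rng.normal(config.baseline_log_mean,
                                config.baseline_log_sd, size=len(feature_ids)))
        mean = np.tile(lam[:, None], (1, len(samples))).astype(float)
        for i, f in enumerate(feature_ids):
            d = directions.get(f)
            if d is not None and (f, d) in truth.de_features:
                factor = config.de_fold if d == "up" else 1.0 / config.de_fold
                mean[i, cond_idx == 1] *= factor
            t = shared_of.get(f)
            if t is not None:
                mean[i, :] *= shared[t, :]
        mean *= lib[None, :]
        if config.dispersion == 0:
            counts = rng.poisson(mean)
        else:
            r = 1.0 / config.dispersion
            p = r / (r + mean)
            counts = rng.negative_binomial(r, p)
        df = pd.DataFrame(counts, index=feature_ids, columns=samples)
        cm = CountMatrix(df, dict(condition_of))
        cm.validate()
        return cm

    cm_mrna = make_matrix(ids["mrna"])
    cm_lnc = make_matrix(ids["lnc"])
    cm_mir = make_matrix(ids["mir"])
    truth.validate()
    return cm_mrna, cm_lnc, cm_mir, truth


# ---------------------------------------------------------------------------
# Sequences

def _random_seq(rng: np.random.Generator, length: int,
                alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet),
                                                         size=length)])


def _forbidden_patterns(mirna_seq: str) -> tuple[str, str]:
    """The two 7-mers whose presence creates a >=7mer site: the full seed
    match (nt 2-8) and the 6mer core followed by A (7mer-A1)."""
    m = mirna_seq.upper().replace("U", "T")
    return revcomp(m[1:8]), revcomp(m[1:7]) + "A"


def _scan_forbidden(seq: str, patterns: set[str],
                    protected: list[tuple[int, int]]) -> list[int]:
    """Start positions of forbidden 7-mers not fully inside protected spans."""
    hits = []
    for i in range(len(seq) - 6):
        if seq[i:i + 7] in patterns:
            if any(ps <= i and i + 7 <= pe for ps, pe in protected):
                continue
            hits.append(i)
    return hits


def _scrub(seq: str, patterns: set[str], protected: list[tuple[int, int]],
           rng: np.random.Generator, cap: int, label: str) -> str:
    s = list(seq)
    for _ in range(cap):
        hits = _scan_forbidden("".join(s), patterns, protected)
        if not hits:
            return "".join(s)
        for i in hits:
            # mutate one base of the site outside any protected span
            positions = [j for j in range(i, i + 7)
                         if not any(ps <= j < pe for ps, pe in protected)]
            j = positions[int(rng.integers(len(positions)))]
            choices = [b for b in "ACGT" if b != s[j]]
            s[j] = choices[int(rng.integers(3))]
    raise SequenceDesignError(
        f"could not make {label} free of seed sites within {cap} attempts; "
        "use longer transcripts or fewer miRNAs")


def simulate_sequences(
    config: SimConfig,
    truth: SimTruth,
    transcripts: list[TranscriptModel] | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Transcript (DNA) and miRNA (RNA) sequences honoring the planted truth.

    Planted (miRNA, target) pairs receive exactly one engineered 8mer site;
    every other transcript/miRNA combination is scrubbed free of 7mer-or-
    better sites. miRNA seed-derived 7-mer patterns are forced pairwise
    distinct so planted sites are unambiguous.
    """
    config.validate()
    rng = _rng(config, 2)
    lo, hi = config.transcript_len_range
    mlo, mhi = config.mirna_len_range

    mirna_seqs: dict[str, str] = {}
    used_patterns: set[str] = set()
    for mid in config.mirna_ids():
        for attempt in range(config.max_rejection_attempts + 1):
            seq = _random_seq(rng, int(rng.integers(mlo, mhi + 1)), "ACGU")
            pats = set(_forbidden_patterns(seq))
            if len(pats) == 2 and not (pats & used_patterns):
                used_patterns |= pats
                mirna_seqs[mid] = seq
                break
        else:
            raise SequenceDesignError(
                f"could not draw a miRNA with unique seed patterns for {mid}")

    all_patterns = set()
    patterns_of: dict[str, tuple[str, str]] = {}
    for mid, seq in mirna_seqs.items():
        patterns_of[mid] = _forbidden_patterns(seq)
        all_patterns.update(patterns_of[mid])

    planted_by_target: dict[str, list[str]] = {}
    for mir, target in sorted(truth.planted_target_pairs):
        planted_by_target.setdefault(target, []).append(mir)

    if transcripts is not None:
        lengths = {t.transcript_id: t.spliced_length for t in transcripts}
        tids = [t.transcript_id for t in transcripts]
    else:
        tids = config.mrna_ids() + config.lncrna_ids()
        lengths = {tid: int(rng.integers(max(lo, 500), hi + 1)) for tid in tids}

    transcript_seqs: dict[str, str] = {}
    cap = config.max_rejection_attempts
    for tid in tids:
        length = lengths[tid]
        seq = _random_seq(rng, length)
        planted = planted_by_target.get(tid, [])
        protected: list[tuple[int, int]] = []
        for k, mir in enumerate(planted):
            site = patterns_of[mir][0] + "A"  # seed match + A = 8mer, 8 nt
            pos = 10 + 12 * k
            if pos + len(site) > length:
                raise SequenceDesignError(
                    f"transcript {tid} too short ({length} nt) for planted sites")
            seq = seq[:pos] + site + seq[pos + len(site):]
            protected.append((pos, pos + len(site)))
        transcript_seqs[tid] = _scrub(seq, all_patterns, protected, rng, cap, tid)
    return transcript_seqs, mirna_seqs
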