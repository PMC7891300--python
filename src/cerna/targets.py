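"""Target prediction: miRNA seed matching, cis co-location, trans co-expression.

Seed matching implements the canonical site classes. With the miRNA written
5'->3', the seed is nucleotides 2-8. A site in the target is anchored at an
exact match to the reverse complement of seed nt 2-7 (the 6mer core) and
upgraded by context: a match extending to nt 8 on its 5' side gives 7mer-m8,
an A in the target immediately 3' of the core gives 7mer-A1, and both give
8mer. Each core match is reported once with its best class; the reported
position is the start of the full matched substring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import TranscriptModel, ValidationError

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}

COLOCATION_WINDOW = 100_000  # bp, boundary inclusive
TRANS_R_THRESHOLD = 0.95     # |r| gate for trans targets
TRANS_P_THRESHOLD = 0.05

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return _dna(seq).translate(_COMPLEMENT)[::-1]


@dataclass
class SeedSite:
    position: int      # 0-based start of the matched substring in the target
    site_type: str

    @property
    def rank(self) -> int:
        return SITE_RANK[self.site_type]


@dataclass
class TargetPair:
    """Directed regulator -> target edge with its evidence."""

    regulator_id: str
    target_id: str
    kind: str                       # seed | cis | trans
    sites: list[SeedSite] = field(default_factory=list)
    distance: int | None = None     # signed bp, cis only
    r: float | None = None          # trans only
    pvalue: float | None = None


def find_seed_sites(mirna_seq: str, target_seq: str) -> list[SeedSite]:
    """All canonical seed sites of one miRNA in one target, sorted by position."""
    m = _dna(mirna_seq)
    if len(m) < 8:
        raise ValidationError(f"miRNA shorter than 8 nt: {len(m)}")
    t = _dna(target_seq)
    core6 = revcomp(m[1:7])          # complements seed nt 2-7
    m8_base = m[7].translate(_COMPLEMENT)  # target base pairing miRNA nt 8
    sites: list[SeedSite] = []
    start = 0
    while True:
        q = t.find(core6, start)
        if q == -1:
            break
        has_m8 = q > 0 and t[q - 1] == m8_base
        has_a1 = q + 6 < len(t) and t[q + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite(q - 1, "8mer"))
        elif has_m8:
            sites.append(SeedSite(q - 1, "7mer-m8"))
        elif has_a1:
            sites.append(SeedSite(q, "7mer-A1"))
        else:
            sites.append(SeedSite(q, "6mer"))
        start = q + 1
    sites.sort(key=lambda s: s.position)
    return sites


def predict_mirna_targets(
    mirna_seqs: dict[str, str],
    target_seqs: dict[str, str],
    min_site_type: str = "7mer-m8",
) -> list[TargetPair]:
    """Emit (miRNA, target) pairs with at least one site of the minimum class."""
    if min_site_type not in SITE_RANK:
        raise ValidationError(f"unknown site type {min_site_type!r}")
    missing = [k for k, v in {**mirna_seqs, **target_seqs}.items() if not v]
    if missing:
        raise ValidationError(f"missing sequences for: {missing}")
    min_rank = SITE_RANK[min_site_type]
    pairs: list[TargetPair] = []
    for mid in sorted(mirna_seqs):
        for tid in sorted(target_seqs):
            sites = [s for s in find_seed_sites(mirna_seqs[mid], target_seqs[tid])
                     if s.rank >= min_rank]
            if sites:
                pairs.append(TargetPair(mid, tid, "seed", sites=sites))
    return pairs


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def cor_test(r: float, n: int) -> float:
    """Two-sided p for H0: rho = 0 via the t transform with n-2 df."""
    if n < 3:
        raise ValidationError("correlation test needs n >= 3")
    if not np.isfinite(r) or abs(r) > 1:
        raise ValidationError(f"invalid correlation {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def colocate_targets(
    lncrnas: list[TranscriptModel],
    genes: list[TranscriptModel],
    window: int = COLOCATION_WINDOW,
) -> list[TargetPair]:
    """Cis targets: genes within `window` bp of the lncRNA span (inclusive).

    Distance is signed on the + axis: positive when the gene lies downstream
    (to the right) of the lncRNA, 0 when the spans overlap.
    """
    pairs: list[TargetPair] = []
    for l in lncrnas:
        for g in genes:
            if g.chrom != l.chrom:
                continue
            if g.start >= l.end:
                dist = g.start - l.end
            elif l.start >= g.end:
                dist = -(l.start - g.end)
            else:
                dist = 0
            if abs(dist) <= window:
                pairs.append(TargetPair(l.transcript_id, g.transcript_id,
                                        "cis", distance=dist))
    pairs.sort(key=lambda p: (p.regulator_id, p.target_id))
    return pairs


def pairwise_correlations(
    expr_a: pd.DataFrame, expr_b: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """r and p matrices (rows of a x rows of b) over shared ordered samples."""
    if list(expr_a.columns) != list(expr_b.columns):
        raise ValidationError("expression matrices must share ordered samples")
    n = expr_a.shape[1]
    a = expr_a.to_numpy(dtype=float)
    b = expr_b.to_numpy(dtype=float)
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    a_sd = np.sqrt((a_c ** 2).sum(axis=1))
    b_sd = np.sqrt((b_c ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a_c @ b_c.T) / np.outer(a_sd, b_sd)
    r = np.clip(r, -1.0, 1.0)
    r[np.outer(a_sd == 0, np.ones(len(b_sd), dtype=bool))] = np.nan
    r[np.outer(np.ones(len(a_sd), dtype=bool), b_sd == 0)] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def coexpression_targets(
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    r_thresh: float = TRANS_R_THRESHOLD,
    p_thresh: float = TRANS_P_THRESHOLD,
) -> list[TargetPair]:
    """Trans targets: |r| > r_thresh and p < p_thresh (both strict).

    Expression should be log1p of size-factor-normalized counts; constant
    features (undefined r) never pair.
    """
    r, p = pairwise_correlations(lnc_expr, gene_expr)
    pairs: list[TargetPair] = []
    for i, lid in enumerate(lnc_expr.index):
        for j, gid in enumerate(gene_expr.index):
            if np.isnan(r[i, j]):
                continue
            if abs(r[i, j]) > r_thresh and p[i, j] < p_thresh:
                pairs.append(TargetPair(lid, gid, "trans",
                                        r=float(r[i, j]), pvalue=float(p[i, j])))
    pairs.sort(key=lambda q: (q.regulator_id, q.target_id))
    return pairs


def log_expression(counts: pd.DataFrame, sf: np.ndarray) -> pd.DataFrame:
    """log1p of size-factor-normalized counts (the correlation input)."""
    return np.log1p(counts / sf[None, :])
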