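"""End-to-end ceRNA discovery on in-memory inputs, plus recovery metrics.

Order of operations mirrors the discovery workflow: differential expression
per matrix, seed-match target prediction restricted to DE features,
positive co-expression screening of DE lncRNA x DE mRNA pairs, co-targeting,
and the merge into the final triplet list and network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import diffexpr, network, targets
from .models import CountMatrix, SimTruth
from .network import CeRNATriplet, CoexpressionPair


@dataclass
class PipelineResult:
    de_mrna: pd.DataFrame
    de_lncrna: pd.DataFrame
    de_mirna: pd.DataFrame
    mirna_lnc_pairs: list[targets.TargetPair]
    mirna_mrna_pairs: list[targets.TargetPair]
    coexpression: list[CoexpressionPair]
    candidates: list[CeRNATriplet]
    triplets: list[CeRNATriplet]
    graph: nx.Graph
    directions: dict[str, str] = field(default_factory=dict)

    def triplet_keys(self) -> set[tuple[str, str, str]]:
        return {t.key for t in self.triplets}


def de_direction_map(*tables: pd.DataFrame) -> dict[str, str]:
    out: dict[str, str] = {}
    for table in tables:
        for fid, call in table["call"].items():
            if call != "ns":
                out[fid] = call
    return out


def run_pipeline(
    cm_mrna: CountMatrix,
    cm_lncrna: CountMatrix,
    cm_mirna: CountMatrix,
    transcript_seqs: dict[str, str],
    mirna_seqs: dict[str, str],
    q_thresh: float = diffexpr.Q_THRESHOLD,
    fc_thresh: float = diffexpr.FC_THRESHOLD,
    min_site_type: str = "7mer-m8",
    r_thresh: float = network.CERNA_R_THRESHOLD,
    p_thresh: float = network.CERNA_P_THRESHOLD,
    sign_filter: bool = False,
) -> PipelineResult:
    de_mrna = diffexpr.run_de(cm_mrna, q_thresh, fc_thresh)
    de_lnc = diffexpr.run_de(cm_lncrna, q_thresh, fc_thresh)
    de_mir = diffexpr.run_de(cm_mirna, q_thresh, fc_thresh)
    directions = de_direction_map(de_mrna, de_lnc, de_mir)

    de_mrna_ids = [f for f in cm_mrna.feature_ids if directions.get(f)]
    de_lnc_ids = [f for f in cm_lncrna.feature_ids if directions.get(f)]
    de_mir_ids = {f for f in cm_mirna.feature_ids if directions.get(f)}

    mir_seq_de = {m: mirna_seqs[m] for m in sorted(de_mir_ids) if m in mirna_seqs}
    lnc_seq_de = {t: transcript_seqs[t] for t in de_lnc_ids
                  if t in transcript_seqs}
    mrna_seq_de = {t: transcript_seqs[t] for t in de_mrna_ids
                   if t in transcript_seqs}
    pairs_lnc = targets.predict_mirna_targets(mir_seq_de, lnc_seq_de,
                                              min_site_type)
    pairs_mrna = targets.predict_mirna_targets(mir_seq_de, mrna_seq_de,
                                               min_site_type)

    sf_lnc = diffexpr.size_factors(cm_lncrna.counts)
    sf_mrna = diffexpr.size_factors(cm_mrna.counts)
    lnc_expr = targets.log_expression(cm_lncrna.counts.loc[de_lnc_ids], sf_lnc)
    mrna_expr = targets.log_expression(cm_mrna.counts.loc[de_mrna_ids], sf_mrna)
    coex = network.coexpressed_pairs(lnc_expr, mrna_expr, r_thresh, p_thresh)

    candidates = network.cotargeted_triplets(pairs_lnc, pairs_mrna, de_mir_ids,
                                             sign_filter, directions)
    graph, kept = network.assemble_cerna(candidates, coex)
    return PipelineResult(de_mrna, de_lnc, de_mir, pairs_lnc, pairs_mrna,
                          coex, candidates, kept, graph, directions)


def recovery_metrics(result: PipelineResult, truth: SimTruth) -> dict[str, float]:
    """Precision/recall of planted triplets and directional DE recall."""
    found = result.triplet_keys()
    planted = set(truth.planted_triplets)
    tp = len(found & planted)
    precision = tp / len(found) if found else float("nan")
    recall = tp / len(planted) if planted else float("nan")

    de_hits = sum(1 for f, d in truth.de_features
                  if result.directions.get(f) == d)
    de_recall = de_hits / len(truth.de_features) if truth.de_features else float("nan")
    return {
        "triplet_precision": precision,
        "triplet_recall": recall,
        "n_reported_triplets": float(len(found)),
        "de_recall": de_recall,
        "n_coexpression_pairs": float(len(result.coexpression)),
        "n_candidate_triplets": float(len(result.candidates)),
    }
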