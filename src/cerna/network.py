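"""ceRNA network assembly: positive co-expression screen, co-targeting,
merge, hub scoring and Cytoscape-readable export.

A ceRNA triplet is a (lncRNA, miRNA, mRNA) triple in which the miRNA has a
predicted site in both the lncRNA and the mRNA (co-targeting) and the
lncRNA-mRNA pair is strongly positively co-expressed (r > 0.95, P < 0.001
by default). The network is the union of nodes and edges of the kept
triplets; miRNA->RNA edges are typed "targets" and lncRNA-mRNA edges
"coexpressed_with".
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .models import ValidationError
from .targets import SeedSite, TargetPair, pairwise_correlations

CERNA_R_THRESHOLD = 0.95   # strictly positive r gate
CERNA_P_THRESHOLD = 0.001


@dataclass
class CoexpressionPair:
    lncrna_id: str
    mrna_id: str
    r: float
    pvalue: float


@dataclass
class CeRNATriplet:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    r: float | None = None
    pvalue: float | None = None
    lnc_sites: list[SeedSite] = field(default_factory=list)
    mrna_sites: list[SeedSite] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lncrna_id, self.mirna_id, self.mrna_id)


def coexpressed_pairs(
    de_lnc_expr: pd.DataFrame,
    de_mrna_expr: pd.DataFrame,
    r_thresh: float = CERNA_R_THRESHOLD,
    p_thresh: float = CERNA_P_THRESHOLD,
) -> list[CoexpressionPair]:
    """Positively co-expressed DE lncRNA-mRNA pairs (r > thresh, p < thresh)."""
    r, p = pairwise_correlations(de_lnc_expr, de_mrna_expr)
    out: list[CoexpressionPair] = []
    for i, lid in enumerate(de_lnc_expr.index):
        for j, gid in enumerate(de_mrna_expr.index):
            rij = r[i, j]
            if rij == rij and rij > r_thresh and p[i, j] < p_thresh:
                out.append(CoexpressionPair(lid, gid, float(rij), float(p[i, j])))
    out.sort(key=lambda q: (q.lncrna_id, q.mrna_id))
    return out


def cotargeted_triplets(
    lnc_mirna_pairs: list[TargetPair],
    mrna_mirna_pairs: list[TargetPair],
    de_mirna: set[str],
    sign_filter: bool = False,
    directions: dict[str, str] | None = None,
) -> list[CeRNATriplet]:
    """Candidate triplets sharing a DE miRNA that targets both partners.

    With ``sign_filter`` the miRNA's DE direction must be opposite to both
    partners' directions (requires ``directions``).
    """
    if sign_filter and directions is None:
        raise ValidationError("sign_filter requires a feature->direction map")
    lnc_by_mirna: dict[str, list[TargetPair]] = {}
    for p in lnc_mirna_pairs:
        if p.regulator_id in de_mirna:
            lnc_by_mirna.setdefault(p.regulator_id, []).append(p)
    mrna_by_mirna: dict[str, list[TargetPair]] = {}
    for p in mrna_mirna_pairs:
        if p.regulator_id in de_mirna:
            mrna_by_mirna.setdefault(p.regulator_id, []).append(p)
    opposite = {"up": "down", "down": "up"}
    out: list[CeRNATriplet] = []
    for mir in sorted(set(lnc_by_mirna) & set(mrna_by_mirna)):
        for lp in lnc_by_mirna[mir]:
            for mp in mrna_by_mirna[mir]:
                if sign_filter:
                    want = opposite.get(directions.get(mir, ""))
                    if want is None:
                        continue
                    if (directions.get(lp.target_id) != want
                            or directions.get(mp.target_id) != want):
                        continue
                out.append(CeRNATriplet(lp.target_id, mir, mp.target_id,
                                        lnc_sites=list(lp.sites),
                                        mrna_sites=list(mp.sites)))
    out.sort(key=lambda t: t.key)
    return out


def assemble_cerna(
    candidates: list[CeRNATriplet],
    coexpression: list[CoexpressionPair],
) -> tuple[nx.Graph, list[CeRNATriplet]]:
    """Merge: keep candidates whose lncRNA-mRNA pair is co-expressed."""
    coex = {(c.lncrna_id, c.mrna_id): c for c in coexpression}
    kept: list[CeRNATriplet] = []
    for t in candidates:
        c = coex.get((t.lncrna_id, t.mrna_id))
        if c is None:
            continue
        kept.append(CeRNATriplet(t.lncrna_id, t.mirna_id, t.mrna_id,
                                 r=c.r, pvalue=c.pvalue,
                                 lnc_sites=t.lnc_sites, mrna_sites=t.mrna_sites))
    kept.sort(key=lambda t: t.key)
    graph = nx.Graph()
    for t in kept:
        graph.add_node(t.lncrna_id, node_type="lncRNA")
        graph.add_node(t.mirna_id, node_type="miRNA")
        graph.add_node(t.mrna_id, node_type="mRNA")
        graph.add_edge(t.mirna_id, t.lncrna_id, edge_type="targets",
                       n_sites=len(t.lnc_sites))
        graph.add_edge(t.mirna_id, t.mrna_id, edge_type="targets",
                       n_sites=len(t.mrna_sites))
        graph.add_edge(t.lncrna_id, t.mrna_id, edge_type="coexpressed_with",
                       r=t.r, pvalue=t.pvalue)
    return graph, kept


def hub_scores(graph: nx.Graph) -> pd.DataFrame:
    """Degree table (distinct neighbors), sorted by degree desc then id."""
    rows = sorted(((node, graph.degree(node)) for node in graph.nodes),
                  key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["node", "degree"])


def _sif_edge_lines(graph: nx.Graph) -> list[str]:
    lines = []
    for u, v, data in graph.edges(data=True):
        etype = data["edge_type"]
        if etype == "targets":
            # direction: miRNA -> RNA
            src, dst = (u, v) if graph.nodes[u]["node_type"] == "miRNA" else (v, u)
        else:
            # lncRNA listed first on co-expression edges
            src, dst = (u, v) if graph.nodes[u]["node_type"] == "lncRNA" else (v, u)
        lines.append(f"{src}\t{etype}\t{dst}")
    return sorted(lines)


def export_network(
    graph: nx.Graph,
    triplets: list[CeRNATriplet],
    outdir: str,
    directions: dict[str, str] | None = None,
) -> dict[str, str]:
    """Write SIF + node/edge/triplet attribute TSVs with stable ordering."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "sif": os.path.join(outdir, "cerna_network.sif"),
        "nodes": os.path.join(outdir, "cerna_nodes.tsv"),
        "edges": os.path.join(outdir, "cerna_edges.tsv"),
        "triplets": os.path.join(outdir, "cerna_triplets.tsv"),
    }
    with open(paths["sif"], "w") as fh:
        for line in _sif_edge_lines(graph):
            fh.write(line + "\n")
    directions = directions or {}
    nodes = pd.DataFrame(
        [(n, graph.nodes[n]["node_type"], directions.get(n, ""))
         for n in sorted(graph.nodes)],
        columns=["id", "type", "de_direction"])
    nodes.to_csv(paths["nodes"], sep="\t", index=False)
    edge_rows = []
    for line in _sif_edge_lines(graph):
        src, etype, dst = line.split("\t")
        data = graph.get_edge_data(src, dst)
        edge_rows.append((src, etype, dst,
                          "" if data.get("r") is None else f"{data['r']:.6g}",
                          "" if data.get("pvalue") is None else f"{data['pvalue']:.6g}",
                          data.get("n_sites", "")))
    pd.DataFrame(edge_rows, columns=["source", "interaction", "target",
                                     "r", "pvalue", "n_sites"]).to_csv(
        paths["edges"], sep="\t", index=False)
    trip_rows = [(t.lncrna_id, t.mirna_id, t.mrna_id,
                  "" if t.r is None else f"{t.r:.6g}",
                  "" if t.pvalue is None else f"{t.pvalue:.6g}",
                  len(t.lnc_sites), len(t.mrna_sites))
                 for t in sorted(triplets, key=lambda t: t.key)]
    pd.DataFrame(trip_rows, columns=["lncrna_id", "mirna_id", "mrna_id", "r",
                                     "pvalue", "lnc_sites", "mrna_sites"]).to_csv(
        paths["triplets"], sep="\t", index=False)
    return paths


def read_sif(path: str) -> set[tuple[str, str, str]]:
    """Parse a SIF file into a set of (source, interaction, target) edges."""
    edges: set[tuple[str, str, str]] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            src, etype, dst = line.rstrip("\n").split("\t")
            edges.add((src, etype, dst))
    return edges
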