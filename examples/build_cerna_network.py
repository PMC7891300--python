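"""Full ceRNA discovery: DE -> targeting -> co-expression -> merge -> export.

A triplet (lncRNA, miRNA, mRNA) is reported when the miRNA has predicted
sites in both partners (all three differentially expressed) and the
lncRNA-mRNA pair is strongly positively co-expressed (r > 0.95, P < 0.001).
"""

from cerna.network import export_network, hub_scores
from cerna.pipeline import recovery_metrics, run_pipeline
from cerna.simulate import SimConfig, simulate_counts, simulate_sequences

cfg = SimConfig(seed=1)   # 500 mRNA / 200 lncRNA / 50 miRNA, 10 triplets
cm_mrna, cm_lnc, cm_mir, truth = simulate_counts(cfg)
seqs, mirs = simulate_sequences(cfg, truth)

result = run_pipeline(cm_mrna, cm_lnc, cm_mir, seqs, mirs)
metrics = recovery_metrics(result, truth)

print(f"DE features: {int((result.de_mrna['call'] != 'ns').sum())} mRNA, "
      f"{int((result.de_lncrna['call'] != 'ns').sum())} lncRNA, "
      f"{int((result.de_mirna['call'] != 'ns').sum())} miRNA")
print(f"co-expressed DE lncRNA-mRNA pairs (r>0.95, P<0.001): "
      f"{len(result.coexpression)}")
print(f"co-targeted candidates: {len(result.candidates)}")
print(f"ceRNA triplets after merge: {len(result.triplets)}")
for t in result.triplets:
    print(f"  {t.lncrna_id} -- {t.mirna_id} -- {t.mrna_id}  "
          f"(r={t.r:.3f}, p={t.pvalue:.2e})")
print(f"planted-triplet precision {metrics['triplet_precision']:.2f}, "
      f"recall {metrics['triplet_recall']:.2f}")
print("hub degrees:")
print(hub_scores(result.graph).head(5).to_string(index=False))
paths = export_network(result.graph, result.triplets,
                       "scratch_example_network", result.directions)
print(f"Cytoscape files: {paths['sif']}")
# Every reported triplet here is planted (precision 1); recall is limited by
# the DE and co-expression gates under the strong shared-factor noise.
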