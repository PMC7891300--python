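# cerna

Competing-endogenous-RNA (ceRNA) discovery for two-condition RNA-seq
designs: lncRNA identification and positional classification, two-group
differential expression with a negative-binomial exact test, miRNA target
prediction by canonical seed matching, lncRNA target assignment by
co-location and co-expression, and assembly of the lncRNA–miRNA–mRNA ceRNA
network with Cytoscape-readable exports — plus the ΔΔCt and dual-luciferase
arithmetic used to validate candidate axes at the bench.

The package targets transcriptomics studies like the comparison of fast-
and slow-growth intermuscular-bone stages in fish (two stages, three
biological replicates), where a lncRNA is proposed to de-repress an mRNA by
sponging a shared miRNA. A ceRNA triplet (lncRNA, miRNA, mRNA) is reported
when

* all three members are differentially expressed (q < 0.05 by BH, fold
  change > 2, NB exact test on median-of-ratios-normalized counts),
* the miRNA has a canonical seed site (≥ 7mer-m8 by default) in both the
  lncRNA and the mRNA, and
* the lncRNA–mRNA pair is strongly positively co-expressed
  (Pearson r > 0.95 and P < 0.001 across samples).

A first-class simulator generates annotation, sequences and NB count
matrices with planted DE features and planted triplets, so the entire
pipeline is exercisable — and its operating characteristics measurable —
without any downloads. See `docs/methods.md` for the models and design
choices, and `examples/` for one narrative script per capability.

## Worked example

```bash
python examples/build_cerna_network.py
```

runs the full pipeline on a simulated study (500 mRNAs, 200 lncRNAs,
50 miRNAs, 10 planted triplets, fold change 4, NB dispersion 0.02) and
prints:

```
DE features: 45 mRNA, 25 lncRNA, 10 miRNA
co-expressed DE lncRNA-mRNA pairs (r>0.95, P<0.001): 182
co-targeted candidates: 5
ceRNA triplets after merge: 3
  LNC_00004 -- miR_0034 -- mRNA_00206  (r=0.979, p=6.63e-04)
  LNC_00059 -- miR_0027 -- mRNA_00121  (r=0.995, p=3.07e-05)
  LNC_00178 -- miR_0023 -- mRNA_00274  (r=0.981, p=5.45e-04)
planted-triplet precision 1.00, recall 0.30
```

Reading the numbers: 80 of 90 planted DE features are called with the
correct direction; the co-expression screen admits many DE–DE pairs (a
shared two-condition pattern alone produces high r at n = 6), but the
shared-miRNA requirement cuts these to 5 candidates, and the merge keeps 3
triplets — every one of them planted (precision 1.0). Recall is limited to
~0.3 by the very noise process that creates the planted co-expression; the
methods note quantifies why that ceiling exists at these thresholds and
sample sizes. The export directory contains `cerna_network.sif` plus node,
edge and triplet attribute TSVs that Cytoscape loads directly.

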