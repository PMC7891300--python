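"""Identify and classify lncRNAs from an assembled transcript set.

Candidates must be >= 200 nt spliced and non-redundant with known mRNAs;
they become lncRNAs when every coding-potential predictor (here the builtin
ORF-length rule, < 300 nt) calls them non-coding, and each lncRNA gets one
positional class relative to the coding genes.
"""

from cerna.lncrna import (builtin_coding_calls, classify_all,
                          consensus_noncoding, filter_candidates)
from cerna.simulate import (SimConfig, simulate_annotation, simulate_counts,
                            simulate_sequences)

cfg = SimConfig(n_mrna=40, n_lncrna=20, n_mirna=10, n_chrom=3,
                n_de_mrna=10, n_de_lncrna=8, n_de_mirna=6,
                n_planted_triplets=4, seed=11)
transcripts = simulate_annotation(cfg)
_, _, _, truth = simulate_counts(cfg)
seqs, _ = simulate_sequences(cfg, truth, transcripts)

known_mrna = [t for t in transcripts if t.biotype == "mRNA"]
candidates = filter_candidates(transcripts, known_mrna)
calls = builtin_coding_calls(candidates, seqs)
lncs = consensus_noncoding(candidates, calls)
classes = classify_all(lncs, known_mrna)

print(f"input transcripts: {len(transcripts)}")
print(f"candidates after length/redundancy filter: {len(candidates)}")
print(f"lncRNAs after coding-potential consensus: {len(lncs)}")
print("positional classes:")
print(classes["class"].value_counts().to_string())
# lincRNA = intergenic; antisense = opposite-strand overlap; sense_intronic =
# inside an intron of a same-strand gene; sense_overlapping = touches exons.
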