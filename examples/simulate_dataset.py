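"""Simulate a small two-stage IB study and write it to disk.

Generates annotation (GTF), transcript and miRNA sequences (FASTA), and NB
count matrices for the two conditions (IB_I vs IB_III, 3 replicates each),
with 4 planted ceRNA triplets recorded in the truth ledger.
"""

from cerna import io
from cerna.simulate import (SimConfig, simulate_annotation, simulate_counts,
                            simulate_sequences)

cfg = SimConfig(n_mrna=40, n_lncrna=20, n_mirna=10, n_chrom=3,
                n_de_mrna=10, n_de_lncrna=8, n_de_mirna=6,
                n_planted_triplets=4, seed=11)
transcripts = simulate_annotation(cfg)
cm_mrna, cm_lnc, cm_mir, truth = simulate_counts(cfg)
seqs, mirs = simulate_sequences(cfg, truth, transcripts)

outdir = "scratch_example_dataset"
import os; os.makedirs(outdir, exist_ok=True)
io.write_gtf(transcripts, f"{outdir}/annotation.gtf")
io.write_fasta(seqs, f"{outdir}/transcripts.fa")
io.write_fasta(mirs, f"{outdir}/mirnas.fa")
io.write_counts(cm_mrna, f"{outdir}/counts_mrna.tsv", f"{outdir}/samples.tsv")
io.write_counts(cm_lnc, f"{outdir}/counts_lncrna.tsv")
io.write_counts(cm_mir, f"{outdir}/counts_mirna.tsv")
io.write_truth(truth, outdir)

print(f"transcript models: {len(transcripts)}")
print(f"count matrices: mRNA {cm_mrna.counts.shape}, "
      f"lncRNA {cm_lnc.counts.shape}, miRNA {cm_mir.counts.shape}")
print(f"planted DE features: {len(truth.de_features)}")
print("planted triplets (lncRNA, miRNA, mRNA):")
for trip in sorted(truth.planted_triplets):
    print("  ", trip)
# Each triplet's lncRNA and mRNA carry an 8mer site for the shared miRNA and
# are positively co-expressed; the miRNA moves in the opposite direction.
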