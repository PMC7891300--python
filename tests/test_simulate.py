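"""Simulator contracts: determinism, geometry, planted sites, count moments."""

import numpy as np
import pytest
from scipy import stats

from cerna.diffexpr import size_factors
from cerna.lncrna import classify_all
from cerna.models import SizingError, ValidationError
from cerna.simulate import (SimConfig, simulate_annotation, simulate_counts,
                            simulate_sequences)
from cerna.targets import find_seed_sites, log_expression


class TestConfig:
    def test_triplets_bounded_by_de_pools(self):
        with pytest.raises(ValidationError, match="n_planted_triplets"):
            SimConfig(n_de_mrna=2, n_de_lncrna=5, n_de_mirna=5,
                      n_planted_triplets=3).validate()

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValidationError, match="dispersion"):
            SimConfig(dispersion=-0.1).validate()

    def test_minimum_replication(self):
        with pytest.raises(ValidationError, match="replicates"):
            SimConfig(replicates_per_condition=1).validate()


class TestAnnotation:
    def test_cardinality_and_containment(self):
        cfg = SimConfig(n_mrna=10, n_lncrna=8, n_mirna=3, n_chrom=2,
                        n_de_mrna=3, n_de_lncrna=3, n_de_mirna=3,
                        n_planted_triplets=2, seed=1)
        models = simulate_annotation(cfg)
        assert len(models) == 18
        for t in models:
            assert t.start >= 0
            for s, e in t.exons:
                assert 0 <= s < e

    def test_deterministic_given_seed(self, small_config):
        a = simulate_annotation(small_config)
        b = simulate_annotation(small_config)
        assert a == b

    def test_all_four_positional_classes_realized(self):
        cfg = SimConfig(n_mrna=8, n_lncrna=4, n_mirna=2, n_chrom=2,
                        n_de_mrna=2, n_de_lncrna=2, n_de_mirna=2,
                        n_planted_triplets=2, seed=3)
        models = simulate_annotation(cfg)
        genes = [t for t in models if t.biotype == "mRNA"]
        lncs = [t for t in models if t.biotype == "lncRNA"]
        classes = set(classify_all(lncs, genes)["class"])
        assert classes == {"lincRNA", "antisense", "sense_intronic",
                           "sense_overlapping"}

    def test_mrna_loci_do_not_overlap(self, small_config):
        genes = [t for t in simulate_annotation(small_config)
                 if t.biotype == "mRNA"]
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g.span)
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_short_chromosome_raises_naming_it(self):
        cfg = SimConfig(n_mrna=10, n_lncrna=4, n_mirna=2, n_chrom=1,
                        n_de_mrna=2, n_de_lncrna=2, n_de_mirna=2,
                        n_planted_triplets=2, chrom_length=5_000, seed=1)
        with pytest.raises(SizingError, match="chr1"):
            simulate_annotation(cfg)


class TestSequences:
    def test_planted_pairs_have_8mer_sites(self, small_config):
        _, _, _, truth = simulate_counts(small_config)
        seqs, mirs = simulate_sequences(small_config, truth)
        for mir, target in truth.planted_target_pairs:
            sites = find_seed_sites(mirs[mir], seqs[target])
            assert any(s.site_type == "8mer" for s in sites)

    def test_non_planted_transcripts_free_of_7mer_or_better(self, small_config):
        _, _, _, truth = simulate_counts(small_config)
        seqs, mirs = simulate_sequences(small_config, truth)
        for tid, seq in seqs.items():
            for mid, mseq in mirs.items():
                if (mid, tid) in truth.planted_target_pairs:
                    continue
                assert all(s.site_type == "6mer"
                           for s in find_seed_sites(mseq, seq))

    def test_mirna_lengths_and_alphabet(self, small_config):
        _, _, _, truth = simulate_counts(small_config)
        _, mirs = simulate_sequences(small_config, truth)
        for seq in mirs.values():
            assert 20 <= len(seq) <= 24
            assert set(seq) <= set("ACGU")

    def test_deterministic_given_seed(self, small_config):
        _, _, _, truth = simulate_counts(small_config)
        a = simulate_sequences(small_config, truth)
        b = simulate_sequences(small_config, truth)
        assert a == b


class TestCounts:
    def test_dimensions_and_integrality(self, small_config):
        cm_m, cm_l, cm_r, _ = simulate_counts(small_config)
        assert cm_m.counts.shape == (20, 6)
        assert cm_l.counts.shape == (12, 6)
        assert cm_r.counts.shape == (6, 6)
        for cm in (cm_m, cm_l, cm_r):
            assert (cm.counts.to_numpy() >= 0).all()

    def test_no_planted_effects_empty_truth(self):
        cfg = SimConfig(n_mrna=10, n_lncrna=5, n_mirna=3, n_de_mrna=0,
                        n_de_lncrna=0, n_de_mirna=0, n_planted_triplets=0,
                        seed=2)
        _, _, _, truth = simulate_counts(cfg)
        assert not truth.de_features
        assert not truth.planted_triplets

    def test_truth_ledger_satisfies_invariants(self, small_config):
        _, _, _, truth = simulate_counts(small_config)
        truth.validate()  # raises on violation
        assert len(truth.planted_triplets) == small_config.n_planted_triplets

    def test_deterministic_given_seed(self, small_config):
        a = simulate_counts(small_config)
        b = simulate_counts(small_config)
        for x, y in zip(a[:3], b[:3]):
            assert x.counts.equals(y.counts)
        assert a[3].de_features == b[3].de_features

    def test_de_fold_recovered_at_zero_dispersion(self):
        """Planted up features have condition-2 means ~4x condition-1 means."""
        cfg = SimConfig(n_mrna=400, n_lncrna=0, n_mirna=0, n_de_mrna=200,
                        n_de_lncrna=0, n_de_mirna=0, n_planted_triplets=0,
                        dispersion=0.0, de_fold=4.0, baseline_log_mean=6.0,
                        library_factor_sd=0.0, seed=3)
        cm, _, _, truth = simulate_counts(cfg)
        ups = [f for f, d in truth.de_features if d == "up"]
        assert len(ups) >= 80
        arr = cm.counts.loc[ups].to_numpy(dtype=float)
        m1 = arr[:, :3].mean(axis=1)
        m2 = arr[:, 3:].mean(axis=1)
        ratios = m2 / m1
        # Poisson error of each mean at lambda >= 100 is a few percent
        assert abs(np.mean(ratios) - 4.0) < 0.2
        assert np.median(np.abs(ratios - 4.0)) < 0.5

    def test_variance_mean_relationship_matches_nb(self):
        """var/mean follows 1 + phi*mean (binned chi-square GOF, alpha=0.01)."""
        phi = 0.1
        cfg = SimConfig(n_mrna=2000, n_lncrna=0, n_mirna=0, n_de_mrna=0,
                        n_de_lncrna=0, n_de_mirna=0, n_planted_triplets=0,
                        dispersion=phi, shared_factor_sd=0.0,
                        library_factor_sd=0.0, baseline_log_mean=5.0,
                        baseline_log_sd=0.6, seed=9)
        cm, _, _, _ = simulate_counts(cfg)
        arr = cm.counts.to_numpy(dtype=float)
        ratios, means = [], []
        for idx in (slice(0, 3), slice(3, 6)):
            sub = arr[:, idx]
            mu = sub.mean(axis=1)
            keep = mu > 0
            ratios.append((sub.var(axis=1, ddof=1) / mu)[keep])
            means.append(mu[keep])
        ratios = np.concatenate(ratios)
        means = np.concatenate(means)
        # bin by mean; within-bin average ratio should match 1 + phi*mean
        bins = np.quantile(means, np.linspace(0, 1, 11))
        which = np.clip(np.digitize(means, bins[1:-1]), 0, 9)
        chi2 = 0.0
        n_bins = 0
        for b in range(10):
            sel = which == b
            if sel.sum() < 50:
                continue
            observed = ratios[sel].mean()
            expected = 1 + phi * means[sel].mean()
            se = ratios[sel].std(ddof=1) / np.sqrt(sel.sum())
            chi2 += ((observed - expected) / se) ** 2
            n_bins += 1
        p = stats.chi2.sf(chi2, df=n_bins)
        assert p > 0.01

    def test_planted_triplet_correlation(self):
        """Shared factor >= 0.5 with low dispersion gives r > 0.8 for >=90%
        of planted lncRNA-mRNA pairs (log1p normalized counts)."""
        hits = total = 0
        for seed in (1, 2, 3):
            cfg = SimConfig(n_mrna=80, n_lncrna=60, n_mirna=20, n_de_mrna=15,
                            n_de_lncrna=15, n_de_mirna=12,
                            n_planted_triplets=12, dispersion=0.05,
                            shared_factor_sd=0.5, seed=seed)
            cm_m, cm_l, _, truth = simulate_counts(cfg)
            lnc = log_expression(cm_l.counts, size_factors(cm_l.counts))
            mrna = log_expression(cm_m.counts, size_factors(cm_m.counts))
            for l, _, g in truth.planted_triplets:
                x = lnc.loc[l].to_numpy()
                y = mrna.loc[g].to_numpy()
                r = np.corrcoef(x, y)[0, 1]
                hits += r > 0.8
                total += 1
        assert hits / total >= 0.9

    def test_mirna_direction_opposite_to_partners(self, small_config):
        _, _, _, truth = simulate_counts(small_config)
        directions = dict(truth.de_features)
        for l, m, g in truth.planted_triplets:
            assert directions[l] == directions[g]
            assert directions[m] != directions[l]
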