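"""Seed matching, correlation statistics, co-location and co-expression."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from scipy import stats

from cerna.models import ValidationError
from cerna.simulate import SimConfig, simulate_counts
from cerna.targets import (coexpression_targets, colocate_targets, cor_test,
                           find_seed_sites, log_expression, pearson,
                           predict_mirna_targets)
from cerna.diffexpr import size_factors

from conftest import make_transcript


def _rc(seq):
    return str(Seq(seq.upper().replace("U", "T")).reverse_complement())


def _seed_oracle(mirna, target):
    """Independent scan anchored at 6mer-core matches, classified from the
    site definitions, using Biopython reverse complement."""
    m = mirna.upper().replace("U", "T")
    t = target.upper().replace("U", "T")
    core = _rc(m[1:7])
    seed7 = _rc(m[1:8])
    out = []
    for q in range(len(t) - 5):
        if t[q:q + 6] != core:
            continue
        m8 = q >= 1 and t[q - 1:q + 6] == seed7
        a1 = q + 6 < len(t) and t[q + 6] == "A"
        if m8 and a1:
            out.append((q - 1, "8mer"))
        elif m8:
            out.append((q - 1, "7mer-m8"))
        elif a1:
            out.append((q, "7mer-A1"))
        else:
            out.append((q, "6mer"))
    return out


class TestSeedSites:
    def test_worked_8mer_example(self):
        sites = find_seed_sites("UAGCUUAUCAGACUGAUGUUGA", "GGGATAAGCTACCC")
        assert [(s.position, s.site_type) for s in sites] == [(3, "8mer")]

    def test_target_without_complement_has_no_sites(self):
        assert find_seed_sites("UAGCUUAUCAGACUGAUGUUGA", "AAAAAAAAAA") == []

    def test_full_revcomp_target_has_one_m8_or_better_site(self, rng):
        for _ in range(20):
            mirna = "".join(rng.choice(list("ACGU"), size=22))
            target = _rc(mirna)
            good = [s for s in find_seed_sites(mirna, target)
                    if s.site_type in ("7mer-m8", "8mer")]
            assert len(good) == 1

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(500):
            mirna = "".join(rng.choice(list("ACGU"), size=int(rng.integers(20, 25))))
            # AT-rich alphabet so matches actually occur
            target = "".join(rng.choice(list("ACGTAT"), size=int(rng.integers(30, 120))))
            got = [(s.position, s.site_type) for s in find_seed_sites(mirna, target)]
            assert got == _seed_oracle(mirna, target)

    def test_short_mirna_rejected(self):
        with pytest.raises(ValidationError):
            find_seed_sites("UAGCUUA", "ACGT")


class TestPredictTargets:
    def test_min_site_type_threshold(self):
        mirna = {"m1": "UAGCUUAUCAGACUGAUGUUGA"}
        only_6mer = {"t1": "CCC" + _rc("AGCUUA")[0:6] + "CCC"}
        pairs = predict_mirna_targets(mirna, only_6mer, "7mer-m8")
        assert pairs == []
        pairs = predict_mirna_targets(mirna, only_6mer, "6mer")
        assert [(p.regulator_id, p.target_id) for p in pairs] == [("m1", "t1")]

    def test_exhaustive_toy_set_matches_oracle(self, rng):
        mirnas = {f"m{i}": "".join(rng.choice(list("ACGU"), size=21))
                  for i in range(5)}
        targets = {f"t{j}": "".join(rng.choice(list("ACGTAT"), size=80))
                   for j in range(20)}
        got = {(p.regulator_id, p.target_id)
               for p in predict_mirna_targets(mirnas, targets, "7mer-m8")}
        want = set()
        for mid, ms in mirnas.items():
            for tid, ts in targets.items():
                if any(t in ("7mer-m8", "8mer") for _, t in _seed_oracle(ms, ts)):
                    want.add((mid, tid))
        assert got == want

    def test_output_sorted(self, rng):
        mirnas = {"m2": "UAGCUUAUCAGACUGAUGUUGA", "m1": "UAGCUUAUCAGACUGAUGUUGA"}
        targets = {"t2": "GGGATAAGCTACCC", "t1": "GGGATAAGCTACCC"}
        pairs = predict_mirna_targets(mirnas, targets)
        assert [(p.regulator_id, p.target_id) for p in pairs] == [
            ("m1", "t1"), ("m1", "t2"), ("m2", "t1"), ("m2", "t2")]


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(1, 7)
        assert pearson(x, 2 * x) == pytest.approx(1.0)
        assert pearson(np.array([1, 2, 3]), np.array([3, 2, 1])) == pytest.approx(-1.0)

    def test_constant_vector_is_undefined(self):
        assert np.isnan(pearson(np.ones(5), np.arange(5)))

    def test_matches_textbook_formula(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            num = np.sum((x - x.mean()) * (y - y.mean()))
            den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            assert pearson(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            pearson(np.arange(4), np.arange(5))


class TestCorTest:
    def test_zero_r_gives_p_one(self):
        assert cor_test(0.0, 10) == pytest.approx(1.0)

    def test_r95_n6_fails_strict_gate(self):
        p = cor_test(0.95, 6)
        assert p == pytest.approx(3.7e-3, rel=0.01)
        assert p < 0.05 and not p < 0.001

    def test_perfect_correlation_gives_zero(self):
        assert cor_test(1.0, 6) == 0.0
        assert cor_test(-1.0, 6) == 0.0

    def test_matches_t_cdf_and_monotone(self, rng):
        rs = np.sort(rng.uniform(0, 0.999, size=50))
        n = 8
        ps = [cor_test(r, n) for r in rs]
        for r, p in zip(rs, ps):
            t = r * np.sqrt((n - 2) / (1 - r * r))
            assert p == pytest.approx(2 * stats.t.sf(t, n - 2), rel=1e-12)
        assert (np.diff(ps) <= 1e-15).all()

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            cor_test(0.5, 2)


class TestColocate:
    def test_window_examples(self):
        lnc = make_transcript("l1", "chr1", "+", [(100_000, 101_000)], "lncRNA")
        near = make_transcript("g1", "chr1", "+", [(150_000, 160_000)], "mRNA")
        far = make_transcript("g2", "chr1", "+", [(220_000, 230_000)], "mRNA")
        other = make_transcript("g3", "chr2", "+", [(150_000, 160_000)], "mRNA")
        pairs = colocate_targets([lnc], [near, far, other])
        assert [(p.target_id, p.distance) for p in pairs] == [("g1", 49_000)]

    def test_boundary_inclusive_and_signed_distance(self):
        lnc = make_transcript("l1", "chr1", "+", [(200_000, 201_000)], "lncRNA")
        at_window = make_transcript("g1", "chr1", "+", [(301_000, 302_000)], "mRNA")
        upstream = make_transcript("g2", "chr1", "-", [(90_000, 105_000)], "mRNA")
        pairs = colocate_targets([lnc], [at_window, upstream])
        by_id = {p.target_id: p.distance for p in pairs}
        assert by_id == {"g1": 100_000, "g2": -95_000}

    def test_zero_window_is_overlap_detection(self):
        lnc = make_transcript("l1", "chr1", "+", [(1000, 2000)], "lncRNA")
        touch = make_transcript("g1", "chr1", "+", [(1500, 2500)], "mRNA")
        apart = make_transcript("g2", "chr1", "+", [(2001, 2500)], "mRNA")
        pairs = colocate_targets([lnc], [touch, apart], window=0)
        assert [(p.target_id, p.distance) for p in pairs] == [("g1", 0)]

    def test_role_swap_flips_distance_sign(self, rng):
        for _ in range(20):
            a0 = int(rng.integers(0, 500_000))
            b0 = int(rng.integers(0, 500_000))
            a = make_transcript("a", "chr1", "+", [(a0, a0 + 1000)], "lncRNA")
            b = make_transcript("b", "chr1", "+", [(b0, b0 + 2000)], "mRNA")
            ab = colocate_targets([a], [b])
            ba = colocate_targets([b], [a])
            assert bool(ab) == bool(ba)
            if ab:
                assert ab[0].distance == -ba[0].distance


class TestCoexpression:
    def _expr(self, rows, samples=6):
        return pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))],
                            columns=[f"s{j}" for j in range(samples)])

    def test_constant_vector_never_pairs(self):
        lnc = self._expr([[3.0] * 6])
        gene = self._expr([[1, 2, 3, 4, 5, 6]])
        assert coexpression_targets(lnc, gene) == []

    def test_threshold_is_strict(self):
        x = np.array([0.1, 0.9, 2.2, 2.8, 4.1, 4.9])
        y = 2 * x + np.array([0.3, -0.3, 0.2, -0.2, 0.1, -0.1])
        r = pearson(x, y)
        lnc, gene = self._expr([x]), self._expr([y])
        assert coexpression_targets(lnc, gene, r_thresh=r, p_thresh=0.5) == []
        got = coexpression_targets(lnc, gene, r_thresh=r - 1e-9, p_thresh=0.5)
        assert len(got) == 1 and got[0].r == pytest.approx(r)

    def test_planted_triplet_pair_recovered_from_simulator(self):
        cfg = SimConfig(n_mrna=60, n_lncrna=40, n_mirna=10, n_de_mrna=10,
                        n_de_lncrna=10, n_de_mirna=5, n_planted_triplets=5,
                        dispersion=0.02, shared_factor_sd=0.8, seed=21)
        cm_m, cm_l, _, truth = simulate_counts(cfg)
        lnc_expr = log_expression(cm_l.counts, size_factors(cm_l.counts))
        mrna_expr = log_expression(cm_m.counts, size_factors(cm_m.counts))
        pairs = {(p.regulator_id, p.target_id)
                 for p in coexpression_targets(lnc_expr, mrna_expr,
                                               r_thresh=0.8, p_thresh=0.05)}
        planted = {(l, g) for l, _, g in truth.planted_triplets}
        recovered = len(planted & pairs) / len(planted)
        assert recovered >= 0.8

    def test_sample_mismatch_rejected(self):
        lnc = self._expr([[1, 2, 3, 4, 5, 6]])
        gene = self._expr([[1, 2, 3, 4, 5, 6]]).rename(columns={"s0": "zz"})
        with pytest.raises(ValidationError):
            coexpression_targets(lnc, gene)
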