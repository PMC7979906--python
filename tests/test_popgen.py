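import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_gm

from radpop.genotype_io import MISSING
from radpop.popgen import (
    PopFreqs,
    PopulationMap,
    _block_jackknife,
    f3,
    f4,
    heterozygosity_fis,
    pairwise_fst,
    pop_allele_freqs,
    wc_fst,
)
from radpop.simulate import SimConfig, simulate_genotypes


def freqs_from_table(freq, n_called=None, n_het=None):
    """Build a PopFreqs directly from a pops x sites frequency table."""
    freq = np.asarray(freq, dtype=float)
    pops = [f"P{k + 1}" for k in range(freq.shape[0])]
    n_called = (
        np.asarray(n_called)
        if n_called is not None
        else np.full(freq.shape, 10, dtype=np.int64)
    )
    n_het = (
        np.asarray(n_het) if n_het is not None else np.zeros(freq.shape, dtype=np.int64)
    )
    return PopFreqs(pops=pops, freq=freq, n_called=n_called, n_het=n_het)


class TestAlleleFrequencies:
    def test_hand_counted(self):
        gm = make_gm(
            [[0, 2], [1, 2], [2, MISSING], [0, 0], [0, 1], [2, 1], [1, 2], [1, 0]],
        )
        pm = PopulationMap({f"s{i}": "P1" if i <= 4 else "P2" for i in range(1, 9)})
        pf = pop_allele_freqs(gm, pm)
        # P1 site 0: genotypes 0,1,2,0 -> 3/8; P1 site 1: 2,2,0 called -> 4/6
        assert pf.freq[0, 0] == pytest.approx(3 / 8)
        assert pf.freq[0, 1] == pytest.approx(4 / 6)
        # P2 site 0: 0,2,1,1 -> 4/8
        assert pf.freq[1, 0] == pytest.approx(0.5)
        assert pf.n_called[0, 1] == 3

    def test_all_missing_site_flagged_nan(self):
        gm = make_gm([[MISSING, 1], [MISSING, 0], [0, 1], [1, 2]])
        pm = PopulationMap({"s1": "P1", "s2": "P1", "s3": "P2", "s4": "P2"})
        pf = pop_allele_freqs(gm, pm)
        assert np.isnan(pf.freq[0, 0])
        assert np.isfinite(pf.freq[1, 0])

    def test_empty_population_rejected(self):
        gm = make_gm([[0], [1]])
        pm = PopulationMap({"s1": "P1", "s2": "P1", "ghost": "P2"})
        with pytest.raises(ValueError, match="P2"):
            pop_allele_freqs(gm, pm)


class TestFis:
    def test_fully_heterozygous_population_strongly_negative(self):
        gm = make_gm(np.ones((6, 20), dtype=np.int8))
        pm = PopulationMap({f"s{i}": "P1" for i in range(1, 7)})
        fis = heterozygosity_fis(gm, pm).loc["P1", "Fis"]
        assert fis < -0.5  # Ho = 1 exceeds He ~ 0.5

    def test_hardy_weinberg_population_near_zero(self):
        cfg = SimConfig(
            pop_sizes={"P1": 200},
            divergence_F={"P1": 0.0},
            n_sites=4000,
            seed=13,
        )
        gm, _ = simulate_genotypes(cfg)
        pm = PopulationMap({s: "P1" for s in gm.samples})
        fis = heterozygosity_fis(gm, pm).loc["P1", "Fis"]
        assert abs(fis) < 0.02

    def test_monomorphic_population_undefined(self):
        gm = make_gm([[0, 0], [0, 0], [1, 0], [1, 2]])
        pm = PopulationMap({"s1": "P1", "s2": "P1", "s3": "P2", "s4": "P2"})
        out = heterozygosity_fis(gm, pm)
        assert np.isnan(out.loc["P1", "Fis"])
        assert np.isfinite(out.loc["P2", "Fis"])


class TestFst:
    def test_null_split_near_zero(self):
        cfg = SimConfig(
            pop_sizes={"P1": 100},
            divergence_F={"P1": 0.1},
            n_sites=4000,
            seed=19,
        )
        gm, _ = simulate_genotypes(cfg)
        pm = PopulationMap(
            {s: ("A" if i < 50 else "B") for i, s in enumerate(gm.samples)}
        )
        fst = pairwise_fst(gm, pm).loc["A", "B"]
        assert abs(fst) < 0.01

    def test_fixed_differences_give_one(self):
        gm = make_gm(np.vstack([np.zeros((4, 10)), np.full((4, 10), 2)]).astype(np.int8))
        pm = PopulationMap({f"s{i}": ("A" if i <= 4 else "B") for i in range(1, 9)})
        assert pairwise_fst(gm, pm).loc["A", "B"] == pytest.approx(1.0)

    def test_matches_loop_oracle_with_missing_data(self):
        rng = np.random.default_rng(29)
        calls = rng.integers(0, 3, size=(16, 120)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.15] = MISSING
        gm = make_gm(calls)
        pm = PopulationMap({f"s{i}": ("A" if i <= 8 else "B") for i in range(1, 17)})
        pf = pop_allele_freqs(gm, pm)
        rows_a = [gm.sample_index(f"s{i}") for i in range(1, 9)]
        rows_b = [gm.sample_index(f"s{i}") for i in range(9, 17)]
        expect = oracles.wc_theta(gm.calls[rows_a], gm.calls[rows_b])
        assert wc_fst(pf, "A", "B") == pytest.approx(expect)

    def test_symmetry_and_sample_order_invariance(self):
        rng = np.random.default_rng(37)
        calls = rng.integers(0, 3, size=(12, 100)).astype(np.int8)
        gm = make_gm(calls)
        pm = PopulationMap({f"s{i}": ("A" if i <= 6 else "B") for i in range(1, 13)})
        fst = pairwise_fst(gm, pm)
        assert fst.loc["A", "B"] == fst.loc["B", "A"]
        perm = rng.permutation(12)
        gm_p = gm.take_samples([gm.samples[i] for i in perm])
        assert pairwise_fst(gm_p, pm).loc["A", "B"] == pytest.approx(fst.loc["A", "B"])

    def test_rank_order_follows_configured_divergence(self):
        from scipy.stats import spearmanr

        cfg = SimConfig(
            pop_sizes={"P1": 20, "P2": 20, "P3": 20, "P4": 20},
            divergence_F={"P1": 0.02, "P2": 0.08, "P3": 0.16, "P4": 0.3},
            n_sites=3000,
            seed=41,
        )
        gm, _ = simulate_genotypes(cfg)
        pm = PopulationMap({s: s.split("_")[0] for s in gm.samples})
        fst = pairwise_fst(gm, pm)
        fvals = cfg.divergence_F
        pairs = [(a, b) for i, a in enumerate(fst.index) for b in fst.index[i + 1:]]
        observed = [fst.loc[a, b] for a, b in pairs]
        configured = [fvals[a] + fvals[b] for a, b in pairs]
        rho, _ = spearmanr(observed, configured)
        assert rho == 1.0


class TestF3F4:
    def test_f3_tiny_table_matches_enumeration(self):
        rng = np.random.default_rng(43)
        freq = rng.uniform(0.05, 0.95, size=(3, 6))
        n_called = np.full((3, 6), 8)
        pf = freqs_from_table(freq, n_called=n_called)
        res = f3(pf, "P1", "P2", "P3", block_size=6)
        expect = oracles.f3_single_block(freq[0], freq[1], freq[2], n_called[0])
        assert res.estimate == pytest.approx(expect)
        assert res.n_blocks == 1 and np.isnan(res.se)

    def test_f3_admixed_target_negative(self):
        rng = np.random.default_rng(47)
        cfg = SimConfig(
            pop_sizes={"B": 20, "C": 20},
            divergence_F={"B": 0.2, "C": 0.2},
            n_sites=5000,
            seed=53,
            admixed={f"mix{i}": {"B": 0.5, "C": 0.5} for i in range(10)},
        )
        gm, truth = simulate_genotypes(cfg)
        pm = PopulationMap(
            {s: ("A" if truth.labels[s] == "admixed" else truth.labels[s])
             for s in gm.samples}
        )
        pf = pop_allele_freqs(gm, pm)
        res = f3(pf, "A", "B", "C", block_size=500)
        assert res.estimate < 0
        assert res.z < -3

    def test_f3_duplicate_source_non_negative(self):
        rng = np.random.default_rng(59)
        freq = rng.uniform(0.1, 0.9, size=(2, 400))
        pf = freqs_from_table(freq, n_called=np.full((2, 400), 50))
        res = f3(pf, "P1", "P2", "P2", block_size=100)
        assert res.estimate >= -1e-3  # an f2 plus sampling noise

    def test_f4_identity_and_antisymmetry_exact(self):
        rng = np.random.default_rng(61)
        freq = rng.uniform(0, 1, size=(4, 200))
        pf = freqs_from_table(freq)
        assert f4(pf, "P1", "P2", "P3", "P3").estimate == 0.0
        fwd = f4(pf, "P1", "P2", "P3", "P4")
        rev = f4(pf, "P1", "P2", "P4", "P3")
        assert fwd.estimate == -rev.estimate

    def test_f4_additivity_identity(self):
        rng = np.random.default_rng(67)
        freq = rng.uniform(0, 1, size=(5, 300))
        pf = freqs_from_table(freq)
        lhs = f4(pf, "P1", "P2", "P3", "P4").estimate
        part1 = f4(pf, "P1", "P2", "P3", "P5").estimate
        part2 = f4(pf, "P1", "P2", "P5", "P4").estimate
        assert lhs == pytest.approx(part1 + part2, abs=1e-12)

    def test_f4_gene_flow_z_grows_with_admixture(self):
        zs = []
        for frac in (0.0, 0.2, 0.4):
            admixed = (
                {f"bmix{i}": {"B": 1 - frac, "C": frac} for i in range(12)}
                if frac > 0
                else {}
            )
            cfg = SimConfig(
                pop_sizes={"A": 12, "B": 12 if frac == 0 else 1, "C": 12, "D": 12},
                divergence_F={"A": 0.1, "B": 0.1, "C": 0.1, "D": 0.1},
                n_sites=5000,
                seed=71,
                admixed=admixed,
            )
            gm, truth = simulate_genotypes(cfg)
            pm = PopulationMap(
                {
                    s: ("B" if truth.labels[s] == "admixed" else truth.labels[s])
                    for s in gm.samples
                    if not (frac > 0 and s == "B_1")
                }
            )
            gm = gm.take_samples(list(pm))
            pf = pop_allele_freqs(gm, pm)
            zs.append(abs(f4(pf, "A", "B", "C", "D").z))
        assert zs[0] < 3
        assert zs[0] < zs[1] < zs[2]

    def test_f3_target_must_differ_from_sources(self):
        pf = freqs_from_table(np.full((2, 10), 0.5))
        with pytest.raises(ValueError):
            f3(pf, "P1", "P1", "P2")


class TestJackknife:
    def test_block_size_one_equals_delete_one_oracle(self):
        rng = np.random.default_rng(73)
        values = rng.normal(size=150)
        est, se, g, n = _block_jackknife(values, block_size=1)
        assert est == pytest.approx(values.mean())
        assert g == 150 and n == 150
        assert se == pytest.approx(oracles.delete_one_jackknife_se(values))

    def test_trailing_partial_block_kept_and_weighted(self):
        rng = np.random.default_rng(79)
        values = rng.normal(size=130)  # 2 full blocks of 50 + partial 30
        est, se, g, n = _block_jackknife(values, block_size=50)
        assert g == 3 and n == 130
        assert np.isfinite(se) and se > 0

    def test_nan_sites_excluded(self):
        values = np.array([1.0, np.nan, 3.0, 5.0, np.nan, 7.0])
        est, se, g, n = _block_jackknife(values, block_size=2)
        assert n == 4
        assert est == pytest.approx(4.0)
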