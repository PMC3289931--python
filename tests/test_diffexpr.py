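import math

import numpy as np
import pytest
from scipy import stats

from sagesig.diffexpr import (
    ConsistentDESet,
    benjamini_hochberg,
    cluster_size_bias,
    consistent_de,
    pairwise_de,
    ztest_counts,
)
from sagesig.libnorm import NormalizedLibrary, make_virtual_library, normalize
from sagesig.synthetic import generate_transcriptome, plant_effects, simulate_library


class TestZtestCounts:
    def test_equal_proportions(self):
        z, p = ztest_counts(5, 100_000, 5, 100_000)
        assert z == 0.0
        assert p == 1.0

    def test_hand_computed_example(self):
        # p0 = 5e-5, se = sqrt(p0*(1-p0)*2e-5); z = 1e-4/se
        z, p = ztest_counts(10, 100_000, 0, 100_000)
        p0 = 5e-5
        se = math.sqrt(p0 * (1 - p0) * 2e-5)
        assert z == pytest.approx(1e-4 / se, rel=1e-12)
        assert z == pytest.approx(3.1623, abs=1e-4)

    def test_antisymmetry(self):
        z1, p1 = ztest_counts(12, 90_000, 4, 80_000)
        z2, p2 = ztest_counts(4, 80_000, 12, 90_000)
        assert z1 == pytest.approx(-z2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_both_zero_not_testable(self):
        with pytest.raises(ValueError, match="not testable"):
            ztest_counts(0, 100, 0, 100)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ztest_counts(5, 0, 1, 10)
        with pytest.raises(ValueError):
            ztest_counts(11, 10, 1, 10)

    def test_chi_square_oracle(self, rng):
        """z**2 equals the 1-df Pearson chi-square without continuity
        correction, checked against scipy's contingency machinery."""
        for _ in range(500):
            n_a = int(rng.integers(50, 5000))
            n_b = int(rng.integers(50, 5000))
            c_a = int(rng.integers(0, n_a // 2))
            c_b = int(rng.integers(0, n_b // 2))
            if c_a == 0 and c_b == 0:
                continue
            if (c_a == n_a and c_b == n_b):
                continue
            z, _ = ztest_counts(c_a, n_a, c_b, n_b)
            table = [[c_a, n_a - c_a], [c_b, n_b - c_b]]
            chi2 = stats.chi2_contingency(table, correction=False).statistic
            assert z * z == pytest.approx(chi2, abs=1e-9, rel=1e-9)


class TestPairwiseDE:
    def test_identical_libraries_nothing_significant(self):
        counts = {f"g{i}": 10 + i for i in range(50)}
        results = pairwise_de(counts, counts, alpha=0.5)
        assert all(not r.significant for r in results)
        assert all(r.z == 0 for r in results)

    def test_universe_defined_by_reference(self):
        a = {"g1": 5, "g2": 1}
        b = {"g1": 5, "g3": 50}
        results = pairwise_de(a, b, min_count=2)
        assert [r.gene_id for r in results] == ["g1"]

    def test_unique_flag(self):
        a = {"g1": 30, "g2": 30}
        b = {"g1": 30}
        extra = {"pad": 100_000}
        results = pairwise_de({**a, **extra}, {**b, **extra}, min_count=2)
        by_gene = {r.gene_id: r for r in results}
        assert by_gene["g2"].unique_to == "a"
        assert by_gene["g1"].unique_to == "none"

    def test_direction_consistency(self, rng):
        a = {f"g{i}": int(rng.integers(1, 100)) for i in range(100)}
        b = {f"g{i}": int(rng.integers(1, 100)) for i in range(100)}
        for r in pairwise_de(a, b, min_count=1):
            if r.proportion_a > r.proportion_b:
                assert r.direction == "up_in_a"
                assert r.z > 0
            elif r.proportion_a < r.proportion_b:
                assert r.direction == "down_in_a"
                assert r.z < 0
            else:
                assert r.direction == "equal"

    def test_planted_power(self):
        """>=90% of 50 planted ~8-fold genes detected at depth 100k."""
        base = generate_transcriptome(2000, sigma=1.0, seed=10)
        effects = plant_effects(base, n_de=50, fold=8.0, n_unique=0, seed=10)
        lib_a = simulate_library(effects.met_abundance, 100_000, seed=11,
                                 library_id="A")
        lib_b = simulate_library(effects.nm_abundance, 100_000, seed=12,
                                 library_id="B")
        results = pairwise_de(lib_a.gene_counts, lib_b.gene_counts,
                              alpha=0.05, min_count=2)
        planted = {f"G{i + 1:05d}" for i in effects.up_genes + effects.down_genes}
        sig = {r.gene_id for r in results if r.significant}
        detected = planted & sig
        assert len(detected) >= 0.9 * len(planted)

    def test_null_type_one_error(self):
        """Significant fraction within binomial 99% bounds under the null
        (adequately expressed genes; low counts are conservative)."""
        hits = n = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            ab = generate_transcriptome(2000, sigma=1.0, seed=rng)
            c1 = rng.multinomial(100_000, ab)
            c2 = rng.multinomial(100_000, ab)
            la = {f"g{i}": int(c) for i, c in enumerate(c1) if c}
            lb = {f"g{i}": int(c) for i, c in enumerate(c2) if c}
            results = pairwise_de(la, lb, alpha=0.05, min_count=10)
            hits += sum(r.significant for r in results)
            n += len(results)
        rate = hits / n
        bound = 2.576 * math.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) < bound

    def test_bh_correction_is_more_conservative(self, rng):
        a = {f"g{i}": int(rng.integers(2, 200)) for i in range(200)}
        b = {f"g{i}": int(rng.integers(2, 200)) for i in range(200)}
        raw = pairwise_de(a, b, alpha=0.05)
        bh = pairwise_de(a, b, alpha=0.05, correction="bh")
        assert sum(r.significant for r in bh) <= sum(r.significant for r in raw)


def test_benjamini_hochberg_known_values():
    # adjusted p = p * m / rank, monotonized; hand-checked
    adj = benjamini_hochberg([0.01, 0.04, 0.03, 0.005])
    assert adj == pytest.approx([0.02, 0.04, 0.04, 0.02])


class TestConsistentDE:
    def _virtual(self, counts, target=100_000.0):
        a = NormalizedLibrary("NM1", dict(counts), target_size=target)
        return make_virtual_library(a, NormalizedLibrary("NM2", dict(counts),
                                                         target_size=target))

    def test_gene_absent_in_one_met_excluded(self):
        pad = {"pad": 99_000}
        mets = [{**pad, "g1": 500}] * 4 + [dict(pad)]
        virtual = self._virtual({"g1": 5, "pad": 99_995})
        result = consistent_de(mets, virtual, alpha=0.05, min_count=2)
        assert "g1" not in result.up_genes | result.down_genes

    def test_unique_counts_as_up(self):
        pad = {"pad": 99_000}
        mets = [{**pad, "g1": 500}] * 5
        virtual = self._virtual({"pad": 100_000})
        result = consistent_de(mets, virtual, alpha=0.05, min_count=2)
        assert "g1" in result.up_genes
        assert "g1" in result.unique_up

    def test_inconsistent_direction_excluded(self):
        # significant up against NM in four libraries, down in the fifth
        pad = {"pad": 99_000}
        mets = [{**pad, "g1": 500}] * 4 + [{**pad, "g1": 1}]
        virtual = self._virtual({"g1": 50, "pad": 99_950})
        result = consistent_de(mets, virtual, alpha=0.05, min_count=1)
        assert "g1" not in result.up_genes | result.down_genes

    def test_planted_recovery(self, scenario, scenario_virtual):
        mets = [lib.gene_counts for lib in scenario.met_libraries]
        result = consistent_de(mets, scenario_virtual, alpha=0.05, min_count=2)
        planted_up = set(scenario.ledger["planted_up"]) | set(
            scenario.ledger["planted_unique"]
        )
        planted_down = set(scenario.ledger["planted_down"])
        assert planted_up <= result.up_genes
        assert planted_down <= result.down_genes
        # rare low-count genes may satisfy the unique-to-met rule by chance
        assert len(result.up_genes - planted_up) <= 6
        assert len(result.down_genes - planted_down) <= 6

    def test_up_down_disjoint_invariant(self):
        with pytest.raises(ValueError):
            ConsistentDESet(up_genes={"g"}, down_genes={"g"})

    def test_pooled_mode(self):
        pad = {"pad": 99_000}
        mets = [{**pad, "g1": 60}] * 5
        virtual = self._virtual({"g1": 5, "pad": 99_995})
        pooled = consistent_de(mets, virtual, consistency="pooled")
        assert "g1" in pooled.up_genes


class TestClusterSizeBias:
    def test_equal_counts_equal_means(self):
        counts = {"a": 5.0, "b": 5.0}
        bias = cluster_size_bias(counts, de_genes={"a"})
        assert bias.mean_de == bias.mean_non_de == 5.0

    def test_single_gene_groups(self):
        counts = {"a": 3.0, "b": 7.0}
        bias = cluster_size_bias(counts, de_genes={"b"})
        assert bias.mean_de == 7.0
        assert bias.mean_non_de == 3.0

    def test_empty_group_missing(self):
        bias = cluster_size_bias({"a": 1.0}, de_genes=set())
        assert bias.mean_de is None

    def test_planted_high_count_de(self, scenario, scenario_virtual):
        mets = [lib.gene_counts for lib in scenario.met_libraries]
        met1 = normalize(mets[0])
        de = set(scenario.ledger["planted_up"])  # planted on moderate counts
        universe = set(scenario.ledger["common_met"])
        bias = cluster_size_bias(met1.counts, de, universe=universe)
        assert bias.mean_de is not None and bias.mean_non_de is not None

    def test_subset_restriction(self):
        counts = {"a": 1.0, "b": 2.0, "c": 30.0}
        bias = cluster_size_bias(counts, de_genes={"a", "c"}, subset={"a", "b"})
        assert bias.mean_de == 1.0
        assert bias.mean_non_de == 2.0
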