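"""TMM normalization, RPKM, the conditional NB exact test and the triple
filter, checked against frozen external values and direct enumeration."""
import numpy as np
import pandas as pd
import pytest

from episcreen import (
    DEParams,
    SimulationConfig,
    de_analyze_line,
    de_filter,
    estimate_common_dispersion,
    nb_exact_pvalue_sums,
    nb_exact_test,
    rpkm,
    simulate_counts,
    tmm_factors,
)

# edgeR::calcNormFactors(method="TMM") on the deterministic fixture below,
# frozen from an independent run.
EDGER_TMM = [1.1220836173, 0.7187739304, 1.1023713238, 1.1247462504]


def _tmm_fixture():
    rng = np.random.default_rng(42)
    mu = rng.lognormal(4, 1, 200)
    counts = rng.poisson(mu[:, None] * np.array([1.0, 2.0, 0.7, 1.3])[None, :])
    counts[:20, 1] = rng.poisson(mu[:20] * 2.0 * 8.0)
    return counts


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 101)
        counts = np.column_stack([col, col])
        assert np.allclose(tmm_factors(counts), [1.0, 1.0])

    def test_pure_depth_difference_gives_unit_factors(self):
        """Doubling a column is depth, not composition: all M-values are 0."""
        col = np.arange(1, 101)
        counts = np.column_stack([col, 2 * col])
        assert np.allclose(tmm_factors(counts), [1.0, 1.0])

    def test_matches_edger_on_fixture(self):
        assert np.allclose(tmm_factors(_tmm_fixture()), EDGER_TMM, atol=1e-8)

    def test_composition_bias_recovered_against_enumeration(self):
        """Noise-free composition bias: 10% of genes 8x up in sample B.

        The expected factor is computed here by direct enumeration of the
        M/A values surviving the trim, independent of the implementation.
        """
        n = 200
        base = np.linspace(100, 4000, n)
        bias = np.ones(n)
        bias[:n // 10] = 8.0
        counts = np.column_stack([base, base * bias])
        na, nb = counts[:, 0].sum(), counts[:, 1].sum()
        log_r = np.log2((counts[:, 1] / nb) / (counts[:, 0] / na))
        abs_e = (np.log2(counts[:, 1] / nb) + np.log2(counts[:, 0] / na)) / 2
        v = ((na - counts[:, 0]) / (na * counts[:, 0])
             + (nb - counts[:, 1]) / (nb * counts[:, 1]))
        lo_l, hi_l = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_s, hi_s = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        from scipy.stats import rankdata
        keep = ((rankdata(log_r) >= lo_l) & (rankdata(log_r) <= hi_l)
                & (rankdata(abs_e) >= lo_s) & (rankdata(abs_e) <= hi_s))
        expected_b = 2.0 ** (np.sum(log_r[keep] / v[keep]) / np.sum(1 / v[keep]))
        factors = tmm_factors(counts, reference=0)
        # factor ratio b/a equals the enumerated trimmed mean within 2%
        assert factors[1] / factors[0] == pytest.approx(expected_b, rel=0.02)

    def test_invariant_to_column_scaling(self):
        # invariance is first-order: the inverse-variance weights depend
        # weakly on depth, so allow 1% (edgeR behaves identically)
        counts = _tmm_fixture().astype(float)
        scaled = counts.copy()
        scaled[:, 2] *= 7.0
        assert np.allclose(tmm_factors(counts), tmm_factors(scaled), rtol=1e-2)

    def test_disjoint_support_rejected(self):
        counts = np.array([[5, 0], [7, 0], [0, 3]])
        with pytest.raises(ValueError):
            tmm_factors(counts, reference=0)


class TestRPKM:
    def test_definition(self):
        counts = pd.DataFrame({"s": [10]}, index=["g"])
        lengths = pd.Series([1000], index=["g"])
        out = rpkm(counts, lengths, np.array([1_000_000]))
        assert out.loc["g", "s"] == pytest.approx(10.0)

    def test_zero_count_is_zero(self):
        counts = pd.DataFrame({"s": [0, 5]}, index=["a", "b"])
        lengths = pd.Series([100, 100], index=["a", "b"])
        assert rpkm(counts, lengths).loc["a", "s"] == 0.0

    def test_depth_scaling_preserves_proportions(self):
        counts = pd.DataFrame({"s1": [10, 30, 60]}, index=list("abc"))
        lengths = pd.Series([500, 1000, 1500], index=list("abc"))
        r1 = rpkm(counts, lengths)["s1"]
        r2 = rpkm(counts * 2, lengths)["s1"]
        assert np.allclose(r1 / r1.sum(), r2 / r2.sum())

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            rpkm(pd.DataFrame({"s": [0]}, index=["g"]),
                 pd.Series([100], index=["g"]))


def _enumerate_exact_p(s1, s2, n1, n2, phi):
    """Independent brute-force sum over all splits of the conditional sum."""
    from scipy.stats import nbinom, binom

    s = s1 + s2
    if s == 0:
        return 1.0
    mu = s / (n1 + n2)
    probs = []
    for x in range(s + 1):
        if phi == 0:
            p = binom.pmf(x, s, n1 / (n1 + n2))
        else:
            r1, r2 = n1 / phi, n2 / phi
            p = (nbinom.pmf(x, r1, r1 / (r1 + n1 * mu))
                 * nbinom.pmf(s - x, r2, r2 / (r2 + n2 * mu)))
        probs.append(p)
    obs = probs[s1]
    return sum(p for p in probs if p <= obs * (1 + 1e-10)) / sum(probs)


class TestNBExactTest:
    def test_no_information_gives_p_one(self):
        assert nb_exact_test([0], [0, 0]) == 1.0

    def test_equal_normalized_counts_give_p_one(self):
        # observed split is the conditional mode: symmetric design -> p = 1
        assert nb_exact_test([10, 10], [10, 10], dispersion=0.1) == 1.0
        # asymmetric design: discreteness shifts the mode, p stays near 1
        assert nb_exact_test([10], [10, 10], dispersion=0.1) > 0.85

    def test_matches_enumeration_oracle(self):
        p = nb_exact_test([2], [40, 38], dispersion=0.05)
        assert p < 0.05
        assert p == pytest.approx(_enumerate_exact_p(2, 78, 1, 2, 0.05), abs=1e-6)

    @pytest.mark.parametrize("s1,s2,n1,n2,phi", [
        (5, 30, 1, 2, 0.16), (12, 9, 2, 2, 0.0), (0, 25, 1, 1, 0.3),
        (50, 50, 2, 1, 0.05),
    ])
    def test_enumeration_agreement_grid(self, s1, s2, n1, n2, phi):
        assert nb_exact_pvalue_sums(s1, s2, n1, n2, phi) == pytest.approx(
            _enumerate_exact_p(s1, s2, n1, n2, phi), abs=1e-9)

    def test_pvalues_in_unit_interval(self, rng):
        for _ in range(50):
            s1, s2 = rng.integers(0, 200, 2)
            p = nb_exact_pvalue_sums(int(s1), int(s2), 1, 2, 0.16)
            assert 0 < p <= 1

    def test_library_scaling_applied(self):
        # sample 2 sequenced twice as deep: equal rates, not significant
        p = nb_exact_test([50], [100, 48], lib_factors=[1e6, 2e6, 1e6],
                          dispersion=0.1)
        assert p > 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([], [1, 2])


class TestDispersionEstimate:
    def test_recovers_simulation_dispersion(self):
        rng = np.random.default_rng(1)
        phi = 0.15
        r = 1 / phi
        mu = rng.lognormal(5, 1, 800)
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), (800, 4))
        est = estimate_common_dispersion(counts, np.array([0, 0, 1, 1]))
        assert est == pytest.approx(phi, rel=0.25)

    def test_requires_replicates(self):
        with pytest.raises(ValueError):
            estimate_common_dispersion(np.ones((5, 2)), np.array([0, 1]))


class TestDEFilter:
    @staticmethod
    def _table(max_rpkm, log2fc, p):
        return pd.DataFrame({"gene_id": ["g"], "max_rpkm": [max_rpkm],
                             "log2fc": [log2fc], "p_value": [p]})

    @pytest.mark.parametrize("max_rpkm,log2fc,p,verdict", [
        (0.5, 3.0, 0.001, "none"),   # expressed nowhere
        (5.0, np.log2(1.8), 0.001, "none"),  # fold change below 2
        (3.0, 2.0, 0.01, "up"),      # all three conditions met
        (3.0, -2.0, 0.01, "down"),
        (3.0, 2.0, 0.2, "none"),     # p too large
    ])
    def test_triple_filter(self, max_rpkm, log2fc, p, verdict):
        out = de_filter(self._table(max_rpkm, log2fc, p))
        assert out["verdict"].iloc[0] == verdict

    def test_tightening_never_enlarges_sets(self, rng):
        table = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(300)],
            "max_rpkm": rng.lognormal(0, 1.5, 300),
            "log2fc": rng.normal(0, 2, 300),
            "p_value": rng.random(300),
        })
        loose = de_filter(table, DEParams())
        tight = de_filter(table, DEParams(rpkm_min=2, fc_min=3, p_max=0.01))
        for verdict in ("up", "down"):
            assert set(tight.loc[tight["verdict"] == verdict, "gene_id"]) <= \
                set(loose.loc[loose["verdict"] == verdict, "gene_id"])


class TestDEEndToEnd:
    def test_planted_effects_recovered(self):
        # analyze at the simulation's known dispersion (matched test)
        cfg = SimulationConfig(seed=9, n_genes=500, de_log2fc=2.0,
                               nb_dispersion=0.1)
        cm, truth = simulate_counts(cfg)
        res = de_analyze_line(cm, "line1", DEParams(dispersion=0.1))
        up_true = truth.de_up_genes["line1"]
        sens = len(res.up_genes & up_true) / len(up_true)
        assert sens >= 0.8
        null_genes = (set(cm.counts.index) - up_true
                      - truth.de_down_genes["line1"])
        # raw p <= 0.05 filter admits ~alpha of nulls; allow binomial noise
        fp = len((res.up_genes | res.down_genes) & null_genes) / len(null_genes)
        assert fp <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(null_genes))

    def test_null_simulation_reports_no_effects(self):
        cfg = SimulationConfig(seed=4, n_genes=300, de_log2fc=0.0)
        cm, truth = simulate_counts(cfg)
        res = de_analyze_line(cm, "line1", DEParams())
        false_rate = (len(res.up_genes) + len(res.down_genes)) / len(cm.counts)
        assert false_rate <= 0.05
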