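"""Differential-methylation screen: threshold rules, aggregation, clustering."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from episcreen import (
    ScreenParams,
    SimulationConfig,
    aggregate_to_genes,
    call_differential_cpg,
    classify_probe,
    cluster_probes,
    generate_manifest,
    screen_gene_sets,
    screen_line,
    simulate_beta_matrix,
)
from episcreen.simulate import BetaMatrix

PARAMS = ScreenParams()


class TestClassifyProbe:
    @pytest.mark.parametrize("beta,state", [
        (0.60, "methylated"),
        (0.10, "unmethylated"),
        (0.35, "methylated"),  # boundary is inclusive
        (0.3499, "unmethylated"),
    ])
    def test_threshold_rule(self, beta, state):
        assert classify_probe(beta, PARAMS) == state

    def test_missing_beta_returns_none(self):
        assert classify_probe(float("nan"), PARAMS) is None

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_probe(1.2, PARAMS)


class TestCallDifferentialCpg:
    def test_hypo_call(self):
        call = call_differential_cpg(0.60, [0.30, 0.20], PARAMS)
        assert call.verdict == "hypo"
        assert call.delta_beta == pytest.approx(0.35)

    def test_small_delta_is_none(self):
        call = call_differential_cpg(0.40, [0.32, 0.28], PARAMS)
        assert call.verdict == "none"
        assert call.delta_beta == pytest.approx(0.10)

    def test_hyper_mirror(self):
        assert call_differential_cpg(0.20, [0.60, 0.70], PARAMS).verdict == "hyper"

    def test_missing_input_flags_and_abstains(self):
        call = call_differential_cpg(float("nan"), [0.2, 0.3], PARAMS)
        assert call.verdict == "none" and call.missing

    def test_empty_kd_list_rejected(self):
        with pytest.raises(ValueError):
            call_differential_cpg(0.5, [], PARAMS)

    @given(ctrl=st.floats(0, 1), kd1=st.floats(0, 1), kd2=st.floats(0, 1))
    @settings(derandomize=True, max_examples=200)
    def test_control_knockdown_swap_mirrors_verdict(self, ctrl, kd1, kd2):
        """Relabeling control vs knockdown swaps hypo and hyper exactly."""
        kd_mean = float(np.mean([kd1, kd2]))
        fwd = call_differential_cpg(ctrl, [kd1, kd2], PARAMS).verdict
        rev = call_differential_cpg(kd_mean, [ctrl], PARAMS).verdict
        assert fwd == {"hypo": "hyper", "hyper": "hypo", "none": "none"}[rev]

    @given(ctrl=st.floats(0, 1), kd=st.floats(0, 1),
           tighter=st.floats(0.15, 0.9))
    @settings(derandomize=True, max_examples=200)
    def test_raising_delta_min_never_adds_calls(self, ctrl, kd, tighter):
        loose = call_differential_cpg(ctrl, [kd], ScreenParams(0.35, 0.15)).verdict
        tight = call_differential_cpg(ctrl, [kd], ScreenParams(0.35, tighter)).verdict
        if tight != "none":
            assert tight == loose


class TestScreenMatrix:
    def test_matches_row_by_row_oracle(self, small_beta):
        """Vectorized calls equal a per-row evaluation of the three rules."""
        matrix, _ = small_beta
        calls = screen_line(matrix, "line1", PARAMS)
        kd_cols = ["line1_kd1", "line1_kd2"]
        for _, row in calls.iterrows():
            betas = matrix.values.loc[row["probe_id"]]
            oracle = call_differential_cpg(
                betas["line1_control"], list(betas[kd_cols]), PARAMS)
            assert row["verdict"] == oracle.verdict
            if not oracle.missing:
                assert row["delta_beta"] == pytest.approx(oracle.delta_beta)

    def test_missing_values_excluded_and_counted(self, small_beta):
        matrix, _ = small_beta
        values = matrix.values.copy()
        values.iloc[0, 0] = np.nan
        calls = screen_line(BetaMatrix(values, matrix.samples), "line1", PARAMS)
        assert bool(calls.iloc[0]["missing"])
        assert calls.iloc[0]["verdict"] == "none"

    def test_recovery_of_strong_planted_effects(self):
        """Planted methylated-to-unmethylated effects are recovered at high
        sensitivity with a negligible false-call rate."""
        sens, fpr = [], []
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, n_genes=300, cpgs_per_gene=2,
                                   delta_beta_effect=0.5)
            matrix, truth = simulate_beta_matrix(generate_manifest(cfg), cfg)
            calls = screen_line(matrix, "line1", PARAMS)
            planted = calls["probe_id"].isin(truth.hypo_cpgs["line1"])
            null = ~calls["probe_id"].isin(
                truth.hypo_cpgs["line1"] | truth.hyper_cpgs["line1"])
            sens.append((calls.loc[planted, "verdict"] == "hypo").mean())
            fpr.append((calls.loc[null, "verdict"] != "none").mean())
        assert np.mean(sens) >= 0.90
        assert np.mean(fpr) <= 0.05


class TestAggregateToGenes:
    @staticmethod
    def _manifest(mapping):
        return pd.DataFrame({"probe_id": list(mapping),
                             "chrom": "chr1", "pos": range(1, len(mapping) + 1),
                             "gene": list(mapping.values()), "region": "promoter"})

    @staticmethod
    def _calls(verdicts):
        return pd.DataFrame({"probe_id": list(verdicts),
                             "verdict": list(verdicts.values())})

    def test_single_probe_supports_gene(self):
        gcs = aggregate_to_genes(self._calls({"p1": "hypo"}),
                                 self._manifest({"p1": "GA"}), "line1")
        assert gcs.hypo_genes == {"GA"}

    def test_conflicting_gene_excluded(self):
        gcs = aggregate_to_genes(self._calls({"p1": "hypo", "p2": "hyper"}),
                                 self._manifest({"p1": "GA", "p2": "GA"}), "line1")
        assert gcs.hypo_genes == set() and gcs.hyper_genes == set()
        assert gcs.conflicted_genes == {"GA"}

    def test_no_differential_probes(self):
        gcs = aggregate_to_genes(self._calls({"p1": "none"}),
                                 self._manifest({"p1": "GA"}), "line1")
        assert gcs.hypo_genes == set() and gcs.hyper_genes == set()

    def test_multi_gene_probe_contributes_to_each(self):
        gcs = aggregate_to_genes(self._calls({"p1": "hypo"}),
                                 self._manifest({"p1": "GA;GB"}), "line1")
        assert gcs.hypo_genes == {"GA", "GB"}

    def test_unknown_probe_rejected_with_ids(self):
        with pytest.raises(KeyError, match="p9"):
            aggregate_to_genes(self._calls({"p9": "hypo"}),
                               self._manifest({"p1": "GA"}), "line1")

    def test_promoter_only_option_restricts_probes(self, small_beta, small_manifest):
        matrix, _ = small_beta
        full = screen_gene_sets(matrix, small_manifest, PARAMS)
        promoter = screen_gene_sets(matrix, small_manifest, PARAMS,
                                    promoter_only=True)
        for line in full:
            assert promoter[line].hypo_genes <= full[line].hypo_genes | \
                full[line].conflicted_genes


def _brute_force_upgma(dist: np.ndarray):
    """O(n^3) agglomeration oracle: average linkage over original distances."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if i >= j:
                    continue
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        merges.append((frozenset(clusters[i]), frozenset(clusters[j]), d))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return merges


class TestClusterProbes:
    def test_identical_rows_merge_first_at_zero(self, rng):
        values = pd.DataFrame(rng.random((5, 4)))
        values.iloc[1] = values.iloc[0]
        samples = pd.DataFrame({"sample": values.columns, "line": "l",
                                "role": "control", "replicate": "c"})
        values.columns = samples["sample"]
        Z, order, kept = cluster_probes(BetaMatrix(values.clip(0, 1), samples),
                                        metric="euclidean")
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(0.0)

    def test_leaf_count_conserved(self, small_beta):
        matrix, _ = small_beta
        Z, order, kept = cluster_probes(matrix)
        assert len(order) == len(kept) == Z.shape[0] + 1

    def test_merge_sequence_matches_brute_force(self, rng):
        from scipy.spatial.distance import squareform, pdist

        data = rng.random((12, 6))
        samples = pd.DataFrame({"sample": [f"s{i}" for i in range(6)],
                                "line": "l", "role": "control", "replicate": "c"})
        values = pd.DataFrame(data, columns=samples["sample"])
        Z, _, _ = cluster_probes(BetaMatrix(values, samples), metric="correlation")
        dist = squareform(pdist(data, metric="correlation"))
        oracle = _brute_force_upgma(dist)
        # scipy merge heights must match the oracle's, in order
        assert np.allclose(Z[:, 2], [m[2] for m in oracle])

    def test_constant_rows_excluded_with_warning(self, rng):
        values = pd.DataFrame(rng.random((4, 5)))
        values.iloc[2] = 0.5
        samples = pd.DataFrame({"sample": values.columns, "line": "l",
                                "role": "control", "replicate": "c"})
        values.columns = samples["sample"]
        with pytest.warns(UserWarning, match="constant"):
            Z, order, kept = cluster_probes(BetaMatrix(values, samples))
        assert 2 not in kept
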