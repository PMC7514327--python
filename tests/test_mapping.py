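"""Complexity tables, level aggregation, divergence map, paired tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainmse import (
    CohortSpec,
    EntropyParams,
    divergence_map,
    edge_based_node_mse,
    edge_index,
    edge_mse_table,
    edge_series_from_nodes,
    generate_cohort,
    mean_over_scales,
    network_mse,
    node_mse_table,
    paired_level_test,
    preprocess_runs,
    sample_entropy,
    stanford_atlas,
    uniform_atlas,
    whole_brain_mse,
)
from brainmse.mapping import TABLE_COLUMNS


def synth_table(n_nodes, n_subjects, scales, rng, measure="nMSE", level="node",
                fail_prob=0.0):
    """Random tidy complexity table (values uniform, optional failures)."""
    recs = []
    units = (
        [str(i) for i in range(1, n_nodes + 1)]
        if level == "node"
        else [f"{i}-{j}" for i, j in edge_index(n_nodes)]
    )
    for unit in units:
        for s in range(1, n_subjects + 1):
            for l in scales:
                failed = bool(rng.random() < fail_prob)
                recs.append(
                    {
                        "measure": measure,
                        "level": level,
                        "unit": unit,
                        "subject": s,
                        "scale": l,
                        "value": float("nan") if failed else float(rng.uniform(0.5, 2)),
                        "failed": failed,
                    }
                )
    return pd.DataFrame.from_records(recs, columns=TABLE_COLUMNS)


@pytest.fixture(scope="module")
def small_tables(small_cohort):
    params = EntropyParams(m=2, r=0.2, scales=(1, 2, 3, 4))
    signals = {
        s + 1: preprocess_runs(runs) for s, runs in enumerate(small_cohort.node_signals)
    }
    nmse = node_mse_table(signals, params)
    edge_sets = {s: edge_series_from_nodes(sig) for s, sig in signals.items()}
    emse = edge_mse_table(edge_sets, params)
    return signals, nmse, emse, params


class TestNodeTable:
    def test_record_count(self, rng):
        signals = {s: rng.standard_normal((5, 400)) for s in (1, 2, 3)}
        table = node_mse_table(signals, EntropyParams(m=2, r=0.2))
        assert len(table) == 5 * 3 * 10  # nodes x subjects x scales

    def test_constant_node_zero_entropy(self):
        signals = {1: np.vstack([np.full(200, 2.0), np.random.default_rng(0).standard_normal(200)])}
        table = node_mse_table(signals, EntropyParams(m=2, r=0.2, scales=(1,)))
        const_row = table[(table["unit"] == "1") & (table["scale"] == 1)]
        assert const_row["value"].iloc[0] == 0.0

    def test_white_noise_group_mean_decreases(self, rng):
        signals = {s: rng.standard_normal((3, 1000)) for s in range(6)}
        table = node_mse_table(signals, EntropyParams(m=2, r=0.2, scales=(1, 2, 4, 8)))
        mean = table.groupby("scale")["value"].mean()
        assert np.all(np.diff(mean.to_numpy()) < 0)


class TestEdgeTables:
    def test_edge_profile_count(self, small_tables):
        _, _, emse, params = small_tables
        n_edges = 6 * 5 // 2
        assert len(emse) == n_edges * 12 * len(params.scales)

    def test_identical_nodes_give_zero_edge_entropy(self, rng):
        x = rng.standard_normal(300)
        es = edge_series_from_nodes(np.vstack([x, x, rng.standard_normal(300)]))
        table = edge_mse_table({1: es}, EntropyParams(m=2, r=0.2, scales=(1,)))
        edge12 = table[table["unit"] == "1-2"]
        assert edge12["value"].iloc[0] == 0.0

    def test_edge_based_node_equals_adjacency_oracle(self, rng):
        # independent oracle: walk the reconstructed adjacency per subject/scale
        table = synth_table(5, 3, (1, 2), rng, measure="eMSE", level="edge",
                            fail_prob=0.2)
        idx = edge_index(5)
        result = edge_based_node_mse(table, idx)
        for node in range(1, 6):
            incident = [f"{i}-{j}" for i, j in idx if node in (i, j)]
            assert len(incident) == 4
            for s in (1, 2, 3):
                for l in (1, 2):
                    cell = table[
                        (table["unit"].isin(incident))
                        & (table["subject"] == s)
                        & (table["scale"] == l)
                    ]
                    ok = cell.loc[~cell["failed"], "value"]
                    got = result[
                        (result["unit"] == str(node))
                        & (result["subject"] == s)
                        & (result["scale"] == l)
                    ].iloc[0]
                    if len(ok) == 0:
                        assert got["failed"]
                    else:
                        assert got["value"] == pytest.approx(ok.mean())
                        assert got["n_skipped"] == int(cell["failed"].sum())

    def test_two_node_graph_node_equals_edge(self, rng):
        table = synth_table(2, 2, (1,), rng, measure="eMSE", level="edge")
        result = edge_based_node_mse(table, edge_index(2))
        for node in ("1", "2"):
            got = result[result["unit"] == node]["value"].to_numpy()
            np.testing.assert_allclose(got, table["value"].to_numpy())


class TestNetworkAndWholeBrain:
    def test_constant_nodes_give_constant_networks(self, rng):
        table = synth_table(90, 2, (1,), rng)
        table["value"] = 1.25
        net = network_mse(table, stanford_atlas())
        assert np.allclose(net["value"], 1.25)
        assert len(net) == 14 * 2  # networks x subjects (x 1 scale)

    def test_network_means_match_groupby_oracle(self, rng):
        atlas = uniform_atlas(8, 3)
        table = synth_table(8, 2, (1, 2), rng, fail_prob=0.1)
        net = network_mse(table, atlas)
        for name in atlas.network_names:
            members = [str(i) for i in atlas.nodes_in(name)]
            for s in (1, 2):
                for l in (1, 2):
                    cell = table[
                        table["unit"].isin(members)
                        & (table["subject"] == s)
                        & (table["scale"] == l)
                    ]
                    ok = cell.loc[~cell["failed"], "value"]
                    got = net[
                        (net["unit"] == name)
                        & (net["subject"] == s)
                        & (net["scale"] == l)
                    ].iloc[0]
                    if len(ok):
                        assert got["value"] == pytest.approx(ok.mean())

    def test_unmapped_node_rejected(self, rng):
        table = synth_table(8, 1, (1,), rng)
        with pytest.raises(ValueError, match="without a network"):
            network_mse(table, uniform_atlas(5, 2))

    def test_whole_brain_is_weighted_network_mean(self, rng):
        # exact algebraic identity on a random failure-free table
        atlas = uniform_atlas(10, 3)
        table = synth_table(10, 3, (1, 2, 3), rng)
        wb = whole_brain_mse(table)
        net = network_mse(table, atlas)
        sizes = {name: len(atlas.nodes_in(name)) for name in atlas.network_names}
        for s in (1, 2, 3):
            for l in (1, 2, 3):
                nsub = net[(net["subject"] == s) & (net["scale"] == l)]
                weighted = sum(
                    nsub[nsub["unit"] == n]["value"].iloc[0] * sizes[n]
                    for n in atlas.network_names
                ) / sum(sizes.values())
                got = wb[(wb["subject"] == s) & (wb["scale"] == l)]["value"].iloc[0]
                assert got == pytest.approx(weighted)

    def test_single_node_whole_brain(self, rng):
        signals = {1: rng.standard_normal((1, 300))}
        table = node_mse_table(signals, EntropyParams(m=2, r=0.2, scales=(1, 2)))
        wb = whole_brain_mse(table)
        np.testing.assert_allclose(wb["value"].to_numpy(), table["value"].to_numpy())

    def test_failure_counts_conserved(self, rng):
        table = synth_table(6, 4, (1, 2), rng, fail_prob=0.3)
        wb = whole_brain_mse(table)
        assert wb["n_skipped"].sum() == table["failed"].sum()


class TestMeanOverScales:
    def test_constant_profile_unchanged(self, rng):
        table = synth_table(3, 2, (1, 2, 3), rng)
        table["value"] = 0.7
        summary = mean_over_scales(table, (1, 2, 3))
        assert np.allclose(summary.per_subject["value"], 0.7)

    def test_single_scale_is_slice(self, rng):
        table = synth_table(3, 2, (1, 2, 3), rng)
        summary = mean_over_scales(table, (2,))
        merged = summary.per_subject.merge(
            table[table["scale"] == 2], on=["unit", "subject"], suffixes=("_s", "")
        )
        np.testing.assert_allclose(merged["value_s"], merged["value"])

    def test_quartiles_match_order_statistics(self, rng):
        table = synth_table(2, 9, (1, 2), rng)
        summary = mean_over_scales(table, (1, 2))
        for _, row in summary.across_subjects.iterrows():
            vals = np.sort(
                summary.per_subject[
                    summary.per_subject["unit"] == row["unit"]
                ]["value"].to_numpy()
            )
            assert row["median"] == pytest.approx(np.quantile(vals, 0.5))
            assert row["q25"] == pytest.approx(np.quantile(vals, 0.25))
            assert row["q75"] == pytest.approx(np.quantile(vals, 0.75))

    def test_missing_scale_rejected(self, rng):
        with pytest.raises(ValueError, match="absent"):
            mean_over_scales(synth_table(2, 2, (1, 2), rng), (1, 5))


class TestDivergenceMap:
    def test_identical_scales_give_zero_map(self, rng):
        table = synth_table(4, 3, (2, 10), rng, measure="eMSE", level="edge")
        v2 = table[table["scale"] == 2]["value"].to_numpy()
        table.loc[table["scale"] == 10, "value"] = v2
        div = divergence_map(table)
        np.testing.assert_allclose(div.table["divergence"], 0.0, atol=1e-12)

    def test_white_noise_edge_series_diverge_negative(self, rng):
        # edge series that are literally white noise lose entropy with
        # scale (the Gaussian closed form decreases in l), so the map is
        # negative for every edge
        from brainmse import EdgeSeriesSet, edge_index

        idx = edge_index(4)
        es = EdgeSeriesSet(
            edge_values=rng.standard_normal((len(idx), 800)),
            edge_index=idx,
            n_nodes=4,
        )
        table = edge_mse_table({1: es, 2: es}, EntropyParams(m=2, r=0.2, scales=(2, 10)))
        div = divergence_map(table)
        assert (div.table["divergence"] < 0).all()
        assert div.fraction_positive() == 0.0

    def test_phase_coherence_emse_rises_initially(self, small_tables):
        # functional complexity shows an initial rise across scales
        _, _, emse, _ = small_tables
        mean = emse.groupby("scale")["value"].mean()
        assert mean[2] > mean[1]

    def test_failed_edges_excluded(self, rng):
        table = synth_table(4, 2, (2, 10), rng, measure="eMSE", level="edge")
        table.loc[
            (table["unit"] == "1-2") & (table["subject"] == 1) & (table["scale"] == 10),
            "failed",
        ] = True
        div = divergence_map(table)
        assert div.excluded == ["1-2"]
        assert "1-2" not in set(div.table["unit"])


class TestPairedTest:
    def test_zero_difference_variance_rejected(self, rng):
        a = rng.standard_normal(10)
        with pytest.raises(ValueError, match="zero variance"):
            paired_level_test(a, a)
        with pytest.raises(ValueError, match="zero variance"):
            paired_level_test(a + 1.0, a)  # constant shift: d exactly constant

    def test_shift_with_noise_gives_large_t(self, rng):
        b = rng.standard_normal(30)
        a = b + 1.0 + rng.normal(0, 0.01, size=30)
        res = paired_level_test(a, b)
        assert res.df == 29
        assert abs(res.t) > 50
        assert res.p < 1e-6
        # cross-check against the scipy statistic directly
        ref = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(float(ref.statistic))

    def test_df_is_n_minus_one(self, rng):
        a = rng.standard_normal(17)
        b = a + rng.standard_normal(17)
        assert paired_level_test(a, b).df == 16


class TestPlantedStructure:
    def test_lambda_drives_scale1_entropy(self):
        # the mechanism behind planted-node recovery: within planted nodes,
        # realized noise weight and scale-1 SampEn are positively correlated
        hits = 0
        consistent = 0
        for seed in range(5):
            spec = CohortSpec(
                n_subjects=12, n_nodes=6, n_runs=2, run_length=200,
                planted_nodes=(1, 2), n_csf_signals=2, seed=100 + seed,
            )
            cohort = generate_cohort(spec)
            per_subj_lam, per_subj_ent = [], []
            lams, ents = [], []
            for s, runs in enumerate(cohort.node_signals):
                sig = preprocess_runs(runs)
                node_ents = [sample_entropy(sig[node], 2, 0.2) for node in (0, 1)]
                node_lams = [cohort.truth["lambdas"][s, node] for node in (0, 1)]
                lams.extend(node_lams)
                ents.extend(node_ents)
                per_subj_lam.append(np.mean(node_lams))
                per_subj_ent.append(np.mean(node_ents))
            r = stats.pearsonr(lams, ents)
            if r.statistic > 0 and r.pvalue < 0.01:
                hits += 1
            # subjects whose planted nodes are noisier have higher planted
            # group-mean entropy (same nodes, so no identity confound)
            order = np.argsort(per_subj_lam)
            lo, hi = order[:6], order[6:]
            if np.mean(np.take(per_subj_ent, hi)) > np.mean(np.take(per_subj_ent, lo)):
                consistent += 1
        assert hits >= 4
        assert consistent >= 4
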