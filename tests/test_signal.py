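"""Feature-table processing: QC flag rule, orientation arithmetic, loess
and scale normalization, replicate selection, complementary averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cghkit import signal
from cghkit.simulate import FLAG_COLUMNS, Probe, SimConfig, generate_genome_pair, \
    simulate_signal_tables


def make_table(n=3, g=100.0, r=200.0, **flags):
    t = pd.DataFrame({"ProbeID": [f"P{i}" for i in range(n)],
                      "gSignal": g, "rSignal": r})
    for col in FLAG_COLUMNS:
        t[col] = flags.get(col, 0)
    return t


class TestReadFeatureTable:
    def test_well_formed(self, tmp_path):
        path = tmp_path / "a.tsv"
        make_table(3).to_csv(path, sep="\t", index=False)
        assert len(signal.read_feature_table(path)) == 3

    def test_missing_flag_column_is_schema_error(self, tmp_path):
        path = tmp_path / "a.tsv"
        make_table(3).drop(columns=["rIsBGPopnOL"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(signal.SchemaError, match="rIsBGPopnOL"):
            signal.read_feature_table(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "a.tsv"
        t = make_table(3)
        t["gSignal"] = t["gSignal"].astype(object)
        t.loc[1, "gSignal"] = "oops"
        t.to_csv(path, sep="\t", index=False)
        with pytest.raises(signal.SchemaError, match="line 3"):
            signal.read_feature_table(path)

    def test_synthetic_arrays_round_trip(self, tmp_path, clean_pair):
        cfg, pair, truth = clean_pair
        simulate_ok = simulate_signal_tables(pair, truth, cfg)
        table = simulate_ok[0][0]
        path = tmp_path / "array01.tsv"
        table.to_csv(path, sep="\t", index=False)
        back = signal.read_feature_table(path)
        pd.testing.assert_frame_equal(back, table[signal.REQUIRED_COLUMNS])


class TestFlagPoor:
    def test_both_channels_flagged_excluded(self):
        t = make_table(1, gIsFeatNonUnifOL=1, rIsFeatNonUnifOL=1)
        assert signal.flag_poor(t).tolist() == [True]

    def test_single_channel_flag_retained(self):
        t = make_table(1, gIsFeatNonUnifOL=1)
        assert signal.flag_poor(t).tolist() == [False]

    def test_mixed_pairs_do_not_pair_across_variables(self):
        # green flagged in one variable, red in another: not a pair
        t = make_table(1, gIsFeatNonUnifOL=1, rIsBGPopnOL=1)
        assert signal.flag_poor(t).tolist() == [False]

    def test_all_clear_retained(self):
        assert signal.flag_poor(make_table(2)).tolist() == [False, False]


class TestOrientAndLog:
    def test_query_in_red(self):
        out = signal.orient_and_log(make_table(1, g=100, r=200), "query_in_red")
        assert out["M"].iloc[0] == pytest.approx(1.0)
        assert out["A"].iloc[0] == pytest.approx((np.log2(200) + np.log2(100)) / 2)

    def test_dye_swap_antisymmetry(self):
        t = make_table(5, g=100, r=200)
        m_red = signal.orient_and_log(t, "query_in_red")["M"]
        m_green = signal.orient_and_log(t, "query_in_green")["M"]
        assert np.allclose(m_red, -m_green)

    def test_equal_channels_zero(self):
        out = signal.orient_and_log(make_table(1, g=150, r=150), "query_in_red")
        assert out["M"].iloc[0] == 0.0

    def test_zero_intensity_floored(self):
        out = signal.orient_and_log(make_table(1, g=0.0, r=64.0), "query_in_red")
        assert np.isfinite(out["M"].iloc[0])
        assert out["M"].iloc[0] == pytest.approx(np.log2(64) - np.log2(0.5))


class TestLoess:
    def test_constant_m_goes_to_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"probe_id": [str(i) for i in range(200)],
                           "M": 0.7, "A": rng.normal(10, 1, 200)})
        out = signal.loess_normalize_within_array(df)
        assert np.abs(out["M"]).max() < 1e-6

    def test_linear_dye_bias_removed(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10, 1, 4000)
        m = 0.5 * (a - a.mean()) + rng.normal(0, 0.01, 4000)
        out = signal.loess_normalize_within_array(
            pd.DataFrame({"probe_id": np.arange(4000).astype(str), "M": m, "A": a}))
        assert np.mean(np.abs(out["M"]) <= 0.05) >= 0.99
        # residual trend: mean residual within each A-decile is small
        deciles = pd.qcut(a, 10, labels=False)
        for d in range(10):
            assert abs(out["M"][deciles == d].mean()) <= 0.05

    def test_class_separation_preserved(self):
        rng = np.random.default_rng(2)
        absent = rng.random(5000) < 0.1
        m = np.where(absent, rng.normal(-4, 0.5, 5000), rng.normal(0, 0.25, 5000))
        a = rng.normal(10, 1, 5000)
        out = signal.loess_normalize_within_array(
            pd.DataFrame({"probe_id": np.arange(5000).astype(str), "M": m, "A": a}))
        sep_before = m[~absent].mean() - m[absent].mean()
        sep_after = out["M"][~absent].mean() - out["M"][absent].mean()
        assert abs(sep_after - sep_before) / sep_before < 0.05

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            signal.loess_normalize_within_array(
                pd.DataFrame({"probe_id": ["1"], "M": [0.0], "A": [10.0]}))


class TestScaleNormalize:
    @staticmethod
    def _array(mad):
        m = np.tile([-2 * mad, -mad, 0.0, mad, 2 * mad], 20)
        return pd.DataFrame({"probe_id": np.arange(100).astype(str), "M": m})

    def test_geometric_mean_mad(self):
        out = signal.scale_normalize_between_arrays(
            {"a": self._array(0.2), "b": self._array(0.8)})
        target = np.sqrt(0.2 * 0.8)
        for df in out.values():
            m = df["M"].to_numpy()
            assert np.median(np.abs(m - np.median(m))) == pytest.approx(target)

    def test_identical_arrays_unchanged(self):
        arr = self._array(0.5)
        out = signal.scale_normalize_between_arrays({"a": arr.copy(), "b": arr.copy()})
        assert np.allclose(out["a"]["M"], arr["M"])

    def test_ranking_preserved(self):
        rng = np.random.default_rng(3)
        a = pd.DataFrame({"probe_id": np.arange(100).astype(str),
                          "M": rng.normal(0, 0.3, 100)})
        b = pd.DataFrame({"probe_id": np.arange(100).astype(str),
                          "M": rng.normal(0, 0.9, 100)})
        out = signal.scale_normalize_between_arrays({"a": a, "b": b})
        assert (np.argsort(out["a"]["M"].to_numpy())
                == np.argsort(a["M"].to_numpy())).all()

    def test_zero_mad_error(self):
        flat = pd.DataFrame({"probe_id": ["1", "2"], "M": [0.1, 0.1]})
        with pytest.raises(ValueError, match="zero MAD"):
            signal.scale_normalize_between_arrays({"a": flat, "b": self._array(0.5)})


class TestSelectReplicates:
    @staticmethod
    def _values(rows):
        return pd.DataFrame(rows, columns=["probe_id", "array_id",
                                           "dye_orientation", "M"])

    def test_one_per_orientation_retained(self):
        v = self._values([("P1", "a1", "query_in_red", 0.1),
                          ("P1", "a2", "query_in_green", 0.2)])
        out = signal.select_replicates(v, np.random.default_rng(0))
        assert len(out) == 2

    def test_three_values_drop_one_overrepresented(self):
        v = self._values([("P1", "a1", "query_in_red", 0.1),
                          ("P1", "a2", "query_in_red", 0.3),
                          ("P1", "a3", "query_in_green", 0.2)])
        out = signal.select_replicates(v, np.random.default_rng(0))
        assert len(out) == 2
        assert (out["dye_orientation"] == "query_in_red").sum() == 1
        assert (out["dye_orientation"] == "query_in_green").sum() == 1

    def test_single_value_probe_dropped(self):
        v = self._values([("P1", "a1", "query_in_red", 0.1),
                          ("P2", "a1", "query_in_red", 0.0),
                          ("P2", "a2", "query_in_green", 0.0)])
        out = signal.select_replicates(v, np.random.default_rng(0))
        assert set(out["probe_id"]) == {"P2"}

    def test_unbalanced_pair_dropped(self):
        v = self._values([("P1", "a1", "query_in_red", 0.1),
                          ("P1", "a2", "query_in_red", 0.2)])
        out = signal.select_replicates(v, np.random.default_rng(0))
        assert len(out) == 0


class TestSummarizeAndAverage:
    def test_median_examples(self):
        sel = pd.DataFrame({"probe_id": ["P1"] * 3 + ["P2"] * 2,
                            "M": [-0.1, 0.0, 0.2, -4.1, -3.9]})
        out = signal.summarize_median(sel)
        assert dict(zip(out["probe_id"], out["M"])) == {"P1": 0.0, "P2": -4.0}
        assert dict(zip(out["probe_id"], out["n_used"])) == {"P1": 3, "P2": 2}

    def test_complementary_pair_averaged(self):
        probes = [Probe("P1", 100, 159, "+"), Probe("P2", 100, 159, "-"),
                  Probe("P3", 200, 259, "+")]
        summary = pd.DataFrame({"probe_id": ["P1", "P2", "P3"],
                                "M": [-3.0, -3.4, 0.1], "n_used": [2, 2, 2]})
        out = signal.average_complementary(summary, probes)
        assert len(out) == 2
        merged = out[out["start"] == 100].iloc[0]
        assert merged["M"] == pytest.approx(-3.2)
        assert out[out["start"] == 200].iloc[0]["M"] == pytest.approx(0.1)

    def test_survivor_of_dropped_pair_passes_through(self):
        probes = [Probe("P1", 100, 159, "+"), Probe("P2", 100, 159, "-")]
        summary = pd.DataFrame({"probe_id": ["P1"], "M": [-3.0], "n_used": [2]})
        out = signal.average_complementary(summary, probes)
        assert len(out) == 1
        assert out.iloc[0]["M"] == -3.0


def test_summarized_distribution_matches_generating_mixture():
    """With no flags and no dye bias the pipeline's summarized medians are
    distributed like medians of the generating two-component mixture
    (two-sample KS after aligning the present-component centers; the
    loess step shifts all ratios by the mixture mean, which carries no
    information for the downstream mode-anchored classification)."""
    cfg = SimConfig(genome_length=160_000, n_genes=130, flag_rate=0.0, seed=21)
    pair, truth = generate_genome_pair(cfg)
    tables, manifest = simulate_signal_tables(pair, truth, cfg)
    track = signal.process_arrays(
        {row.array_id: t for row, t in zip(manifest.itertuples(), tables)},
        manifest, pair.probes, seed=21)
    observed = track["M"].to_numpy()
    assert len(observed) >= 5000

    rng = np.random.default_rng(99)
    p_absent = np.mean([not truth.probe_binds[p.probe_id] for p in pair.probes])
    n = len(observed)
    comp = rng.random((n, 4)) < p_absent
    draws = np.where(comp, rng.normal(cfg.absent_ratio_mean, cfg.absent_ratio_sd, (n, 4)),
                     rng.normal(0.0, cfg.present_ratio_sd, (n, 4)))
    # same per-probe component across the 4 arrays, as in the generator
    draws[:] = np.where(comp[:, [0]],
                        rng.normal(cfg.absent_ratio_mean, cfg.absent_ratio_sd, (n, 4)),
                        rng.normal(0.0, cfg.present_ratio_sd, (n, 4)))
    reference = np.median(draws, axis=1)
    res = stats.ks_2samp(observed - np.median(observed),
                         reference - np.median(reference))
    assert res.pvalue > 0.01


def test_full_processing_is_deterministic(clean_pair, tmp_path):
    cfg, pair, truth = clean_pair
    tables, manifest = simulate_signal_tables(pair, truth, cfg)
    named = {row.array_id: t for row, t in zip(manifest.itertuples(), tables)}
    t1 = signal.process_arrays(named, manifest, pair.probes, seed=5)
    t2 = signal.process_arrays(named, manifest, pair.probes, seed=5)
    pd.testing.assert_frame_equal(t1, t2)
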