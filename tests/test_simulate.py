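"""Read simulator: determinism, conservation, statistical fidelity."""

import numpy as np
import pandas as pd
import pytest

from qtermseq.simulate import (
    SimulationConfig,
    simulate_facs_bins,
    simulate_sample,
    simulate_te_table,
    simulate_temperature_series,
)


def make_config(variants, te, **kw):
    defaults = dict(n_reads=5000, seed=42, base_error_rate=0.0,
                    quality_mean=38.0, quality_sd=1.0, truncation_rate=0.0)
    defaults.update(kw)
    return SimulationConfig(variants=variants, true_te=te, **defaults)


class TestSimulateSample:
    def test_seed_determinism_byte_identical(self, small_library):
        cfg = make_config(small_library, [0.8] * 20)
        reads_a, _ = simulate_sample(cfg)
        reads_b, _ = simulate_sample(cfg)
        assert reads_a == reads_b

    def test_different_seed_differs(self, small_library):
        a, _ = simulate_sample(make_config(small_library, [0.8] * 20, seed=1))
        b, _ = simulate_sample(make_config(small_library, [0.8] * 20, seed=2))
        assert a != b

    def test_te_one_all_offsets_in_terminated_window(self, small_library):
        cfg = make_config(small_library, [1.0] * 20)
        _, truth = simulate_sample(cfg)
        assert truth.per_read["offset"].between(1, 8).all()
        assert (truth.per_read["class"] == "terminated").all()

    def test_te_zero_all_offsets_beyond_window(self, small_library):
        cfg = make_config(small_library, [0.0] * 20)
        _, truth = simulate_sample(cfg)
        assert (truth.per_read["offset"] > 8).all()
        assert (truth.per_read["class"] == "readthrough").all()

    def test_terminated_fraction_within_binomial_ci(self, small_library):
        te = 0.95
        cfg = make_config([small_library[0]], [te], n_reads=10_000)
        _, truth = simulate_sample(cfg)
        row = truth.per_variant.iloc[0]
        n = row.reads_terminated + row.reads_readthrough
        phat = row.reads_terminated / n
        se = np.sqrt(te * (1 - te) / n)
        assert abs(phat - te) <= 3 * se

    def test_counts_conserved(self, small_library):
        cfg = make_config(small_library, [0.7] * 20, truncation_rate=0.2)
        reads, truth = simulate_sample(cfg)
        pv = truth.per_variant
        assert pv["reads_emitted"].sum() == cfg.n_reads == len(reads)
        assert (
            pv[["reads_terminated", "reads_readthrough", "reads_truncated"]]
            .sum(axis=1)
            .equals(pv["reads_emitted"])
        )

    def test_truncation_rate_respected(self, small_library):
        cfg = make_config(small_library, [0.8] * 20, truncation_rate=0.25,
                          n_reads=20_000)
        _, truth = simulate_sample(cfg)
        frac = (truth.per_read["class"] == "truncated").mean()
        assert abs(frac - 0.25) < 0.02
        # truncated 3' ends sit inside the hairpin
        trunc = truth.per_read.loc[truth.per_read["class"] == "truncated", "offset"]
        assert (trunc <= 0).all()

    def test_empirical_te_unbiased_over_seeds(self, small_library):
        te = 0.9
        diffs = []
        for seed in range(20):
            cfg = make_config([small_library[0]], [te], n_reads=2000, seed=seed)
            _, truth = simulate_sample(cfg)
            row = truth.per_variant.iloc[0]
            n = row.reads_terminated + row.reads_readthrough
            diffs.append(row.reads_terminated / n - te)
        se = np.sqrt(te * (1 - te) / 2000 / 20)
        assert abs(np.mean(diffs)) < 2 * se

    def test_reads_carry_template_prefix(self, small_library):
        cfg = make_config(small_library, [0.5] * 20, n_reads=500)
        reads, truth = simulate_sample(cfg)
        by_id = {v.variant_id: v for v in small_library}
        for (rid, seq, qual), row in zip(reads, truth.per_read.itertuples()):
            assert rid == row.read_id
            assert len(seq) == len(qual)
            assert by_id[row.variant_id].forward_seq.startswith(seq[:30])

    def test_invalid_configs_rejected(self, small_library):
        with pytest.raises(ValueError):
            make_config(small_library, [1.5] * 20)
        with pytest.raises(ValueError):
            make_config(small_library, [0.5] * 20, n_reads=0)
        with pytest.raises(ValueError):
            make_config(small_library, [0.5] * 20,
                        terminated_offset_dist=[1.0, 1.0])
        with pytest.raises(ValueError):
            make_config(small_library, [0.5] * 20, abundance=[0.0] * 20)


class TestFacsBins:
    def test_zero_noise_routes_to_true_gate(self, small_library):
        te = [0.99] * 5 + [0.3] * 5 + [0.7] * 5 + [0.9] * 5
        cfg = make_config(small_library, te, n_reads=1000)
        sim = simulate_facs_bins(cfg, sort_noise_sd=0.0, replicates=2)
        routed = sim.routing
        expected = {0.99: "strong", 0.3: "weak", 0.7: "intermediate-weak",
                    0.9: "intermediate-strong"}
        for row in routed.itertuples():
            assert row.bin == expected[round(row.true_te, 2)]
        # all of a strong variant's reads land in the strong bin only
        strong_ids = {v.variant_id for v, t in zip(small_library, te) if t == 0.99}
        for (label, rep), (reads, truth) in sim.samples.items():
            seen = set(truth.per_read["variant_id"].unique())
            if label == "strong":
                assert seen <= strong_ids or seen == strong_ids
            else:
                assert not (seen & strong_ids)

    def test_boundary_te_left_closed(self, small_library):
        # 0.50 sits exactly on the weak/intermediate-weak boundary:
        # gates are left-closed, so 50.0 belongs to intermediate-weak
        cfg = make_config(small_library[:1], [0.50], n_reads=100)
        sim = simulate_facs_bins(cfg, sort_noise_sd=0.0, replicates=1)
        assert sim.routing["bin"].unique().tolist() == ["intermediate-weak"]

    def test_default_gate_labels(self, small_library):
        cfg = make_config(small_library[:4], [0.2, 0.6, 0.9, 0.99], n_reads=100)
        sim = simulate_facs_bins(cfg, sort_noise_sd=0.0, replicates=1)
        labels = {g.label for g in sim.gates}
        assert labels == {"weak", "intermediate-weak", "intermediate-strong",
                          "strong"}

    def test_replicates_reroute_independently_under_noise(self, small_library):
        cfg = make_config(small_library[:1], [0.87], n_reads=100)
        sim = simulate_facs_bins(cfg, sort_noise_sd=10.0, replicates=20)
        assert sim.routing["bin"].nunique() > 1


class TestTemperatureSeries:
    def test_single_condition_single_replicate_reduces_to_sample(self, small_library):
        te_by_temp = {v.variant_id: {37: 0.8} for v in small_library}
        cfg = make_config(small_library, [0.8] * 20, n_reads=500)
        out = simulate_temperature_series(cfg, [37], te_by_temp, replicates=1)
        assert set(out) == {(37, 0)}
        reads, truth = out[(37, 0)]
        assert len(reads) == 500
        assert truth.per_variant["reads_emitted"].sum() == 500

    def test_missing_te_entry_errors(self, small_library):
        te_by_temp = {v.variant_id: {37: 0.8} for v in small_library[:-1]}
        cfg = make_config(small_library, [0.8] * 20)
        with pytest.raises(ValueError, match="missing TE"):
            simulate_temperature_series(cfg, [37], te_by_temp)

    def test_conditions_are_independent_but_deterministic(self, small_library):
        te_by_temp = {v.variant_id: {14: 0.5, 37: 0.5} for v in small_library}
        cfg = make_config(small_library, [0.5] * 20, n_reads=300)
        out1 = simulate_temperature_series(cfg, [14, 37], te_by_temp, replicates=2)
        out2 = simulate_temperature_series(cfg, [14, 37], te_by_temp, replicates=2)
        for key in out1:
            assert out1[key][0] == out2[key][0]
        assert out1[(14, 0)][0] != out1[(37, 0)][0]
        assert out1[(14, 0)][0] != out1[(14, 1)][0]


class TestTeTable:
    def test_binomial_sampling_law(self):
        tbl = simulate_te_table([0.9], 1000, ["a"], replicates=200, seed=0)
        te = tbl["te"].to_numpy() / 100
        assert abs(te.mean() - 0.9) < 3 * np.sqrt(0.9 * 0.1 / 1000 / 200)
        assert abs(te.std() - np.sqrt(0.9 * 0.1 / 1000)) < 0.002

    def test_shape_and_columns(self):
        tbl = simulate_te_table([0.5, 0.8], 100, [14, 37], replicates=3, seed=1)
        assert len(tbl) == 2 * 2 * 3
        assert set(tbl.columns) == {"variant_id", "condition", "replicate", "te"}
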