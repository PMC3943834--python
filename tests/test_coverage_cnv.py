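import math

import numpy as np
import pytest

from paneldx.coverage_cnv import (
    BaselineTooSmallError,
    DepthMatrix,
    call_cnvs,
    call_cnvs_for_run,
    cnv_zscores,
    coverage_stats,
    depth_matrix_from_tables,
    region_depth_rates,
    zscore_percentile,
)
from paneldx.panel_io import DepthTable, GenePanel, TargetRegion
from paneldx.synthetic_fixtures import CnvEvent, SimConfig, gen_depth_matrix


def one_region_panel(length=100):
    return GenePanel(regions=[TargetRegion("chr7", 100, 100 + length, "GCK", "CDS", 1)])


def table_with(depths_by_pos1, sample_id="s1"):
    t = DepthTable(sample_id=sample_id)
    for (chrom, pos), d in depths_by_pos1.items():
        t.add(chrom, pos, d)
    return t


class TestCoverageStats:
    def test_uniform_depth(self):
        panel = one_region_panel(100)
        table = table_with({("chr7", p): 50 for p in range(101, 201)})
        rep = coverage_stats(table, panel, thresholds=[1, 20, 51])
        assert rep.mean_depth_target == pytest.approx(50.0)
        assert rep.coverage_at[1] == 100.0
        assert rep.coverage_at[20] == 100.0
        assert rep.coverage_at[51] == 0.0

    def test_zero_depth_everywhere(self):
        rep = coverage_stats(DepthTable("s1"), one_region_panel(), thresholds=[1, 20])
        assert rep.mean_depth_target == 0.0
        assert rep.coverage_at[1] == 0.0 and rep.coverage_at[20] == 0.0

    def test_half_at_10_half_at_30(self):
        panel = one_region_panel(100)
        depths = {("chr7", p): (10 if p <= 150 else 30) for p in range(101, 201)}
        rep = coverage_stats(table_with(depths), panel, thresholds=[20])
        assert rep.coverage_at[20] == pytest.approx(50.0)
        assert rep.mean_depth_target == pytest.approx(20.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        panel = one_region_panel(200)
        depths = {("chr7", 100 + i + 1): int(d) for i, d in
                  enumerate(rng.integers(0, 100, 200))}
        rep = coverage_stats(table_with(depths), panel, thresholds=[1, 5, 20, 50, 80])
        values = [rep.coverage_at[t] for t in sorted(rep.coverage_at)]
        assert values == sorted(values, reverse=True)
        assert all(0.0 <= v <= 100.0 for v in values)

    def test_flanking_excludes_target_bases(self):
        # two adjacent regions: flank of one overlaps the other's target
        panel = GenePanel(regions=[
            TargetRegion("chr7", 100, 200, "GCK", "CDS", 1),
            TargetRegion("chr7", 250, 350, "GCK", "CDS", 2),
        ])
        depths = {("chr7", p): 10 for p in range(1, 600)}
        rep = coverage_stats(table_with(depths), panel, thresholds=[1], flank_bp=200)
        assert rep.coverage_flanking_1x == pytest.approx(100.0)
        assert rep.mean_depth_flanking == pytest.approx(10.0)

    def test_capture_specificity_ratio(self):
        rep = coverage_stats(
            table_with({("chr7", 101): 1}),
            one_region_panel(),
            thresholds=[1],
            mapped_total=48535673.13,
            mapped_on_target=25879158.93,
        )
        assert rep.capture_specificity == pytest.approx(53.32, abs=0.01)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            coverage_stats(DepthTable("s1"), GenePanel(regions=[]), thresholds=[1])


def simple_matrix(depth_rows, sample_ids=None):
    depth = np.asarray(depth_rows, dtype=float)
    n_s, n_r = depth.shape
    regions = [
        TargetRegion("chr7", 100 * i, 100 * i + 50, "GCK", "CDS", i + 1)
        for i in range(n_r)
    ]
    return DepthMatrix(
        run_id="run1",
        samples=sample_ids or [f"s{i}" for i in range(n_s)],
        regions=regions,
        mean_depth=depth,
        sample_mean_depth=depth.mean(axis=1),
    )


class TestDepthRates:
    def test_identity_rate(self):
        m = simple_matrix([[412.0, 412.0]])
        rates, samples = region_depth_rates(m)
        assert rates[0, 0] == pytest.approx(1.0)

    def test_scaling_invariance(self):
        m1 = simple_matrix([[100.0, 300.0], [200.0, 200.0], [150.0, 250.0], [90.0, 110.0]])
        m2 = simple_matrix([[300.0, 900.0], [200.0, 200.0], [150.0, 250.0], [90.0, 110.0]])
        r1, _ = region_depth_rates(m1)
        r2, _ = region_depth_rates(m2)
        np.testing.assert_allclose(r1[0], r2[0])

    def test_hand_arithmetic(self):
        m = simple_matrix([[100.0, 300.0]])
        rates, _ = region_depth_rates(m)
        np.testing.assert_allclose(rates[0], [0.5, 1.5])

    def test_zero_mean_sample_excluded(self):
        m = simple_matrix([[100.0, 300.0], [0.0, 0.0]])
        rates, samples = region_depth_rates(m)
        assert samples == ["s0"] and rates.shape == (1, 2)


class TestZScores:
    def test_hand_computed_deletion_candidate(self):
        rates = np.array([[0.4], [1.0], [0.9], [1.1], [1.0]])
        z = cnv_zscores(rates, ["t", "b1", "b2", "b3", "b4"], "t")
        # baseline mean 1.0, sample SD sqrt(0.02/3) ~= 0.0816
        assert z[0] == pytest.approx(-7.348, abs=1e-3)

    def test_rate_equal_to_baseline_mean_gives_zero(self):
        rates = np.array([[1.0], [0.9], [1.1], [1.0]])
        z = cnv_zscores(rates, ["t", "b1", "b2", "b3"], "t")
        assert z[0] == pytest.approx(0.0)

    def test_degenerate_baseline_is_uninformative(self):
        rates = np.array([[1.0], [1.0], [1.0], [1.0]])
        z = cnv_zscores(rates, ["t", "b1", "b2", "b3"], "t")
        assert math.isnan(z[0])
        assert call_cnvs(z, [TargetRegion("c", 0, 1, "G", "CDS", 1)], "t") == []

    def test_baseline_below_minimum_rejected(self):
        rates = np.array([[1.0], [1.0], [1.0]])
        with pytest.raises(BaselineTooSmallError):
            cnv_zscores(rates, ["t", "b1", "b2"], "t")

    def test_equivalence_with_two_pass_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_s, n_r = int(rng.integers(5, 12)), int(rng.integers(2, 8))
            rates = rng.uniform(0.2, 2.0, (n_s, n_r))
            samples = [f"s{i}" for i in range(n_s)]
            sid = samples[int(rng.integers(n_s))]
            z = cnv_zscores(rates, samples, sid)
            idx = samples.index(sid)
            others = [rates[i] for i in range(n_s) if i != idx]
            for r in range(n_r):
                vals = [o[r] for o in others]
                mean = sum(vals) / len(vals)
                sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
                assert z[r] == pytest.approx((rates[idx, r] - mean) / sd, abs=1e-9)


class TestCallCnvs:
    regions5 = [
        TargetRegion("chr7", 100 * i, 100 * i + 50, "GCK", "CDS", i + 1)
        for i in range(5)
    ]

    def test_boundary_is_exclusive(self):
        calls = call_cnvs(np.array([-3.0, 3.0]), self.regions5[:2], "s")
        assert calls == []

    def test_just_beyond_boundary_called(self):
        calls = call_cnvs(np.array([-3.01]), self.regions5[:1], "s")
        assert len(calls) == 1 and calls[0].direction == "deletion"

    def test_consecutive_regions_merge(self):
        z = np.array([-5.0, -6.0, -4.0, 0.2, 0.1])
        calls = call_cnvs(z, self.regions5, "s")
        assert len(calls) == 1
        c = calls[0]
        assert c.direction == "deletion"
        assert c.regions == [0, 1, 2]
        assert c.start == self.regions5[0].start and c.end == self.regions5[2].end
        assert c.z_extreme == pytest.approx(-6.0)

    def test_single_exon_duplication(self):
        calls = call_cnvs(np.array([0.0, 3.5, 0.0]), self.regions5[:3], "s")
        assert len(calls) == 1
        assert calls[0].direction == "duplication" and calls[0].regions == [1]

    def test_opposite_directions_not_merged(self):
        calls = call_cnvs(np.array([-5.0, 5.0]), self.regions5[:2], "s")
        assert len(calls) == 2

    def test_different_genes_not_merged(self):
        regions = [
            TargetRegion("chr7", 0, 50, "GCK", "CDS", 1),
            TargetRegion("chr7", 100, 150, "HNF1A", "CDS", 1),
        ]
        calls = call_cnvs(np.array([-5.0, -5.0]), regions, "s")
        assert len(calls) == 2


class TestZScorePercentile:
    def test_symmetry_at_zero(self):
        assert zscore_percentile(0) == pytest.approx(50.0)

    def test_cutoff_three_is_one_tailed_999(self):
        assert round(zscore_percentile(3), 1) == 99.9

    def test_limit(self):
        assert zscore_percentile(50) == pytest.approx(100.0)


class TestCalibrationAndRecovery:
    def test_null_calibration(self):
        """With no implanted events, |z|>3 is rare and z is near-standard."""
        zs = []
        for seed in range(4):
            cfg = SimConfig(seed=seed, n_samples=20)
            matrix, manifest = gen_depth_matrix(cfg)
            assert manifest == []
            rates, samples = region_depth_rates(matrix)
            for sid in samples:
                zs.append(cnv_zscores(rates, samples, sid))
        z = np.concatenate(zs)
        assert np.mean(np.abs(z) > 3) < 0.02
        assert abs(z.mean()) < 0.1
        assert 0.8 < z.std() < 1.3

    @pytest.mark.parametrize(
        "factor,direction,min_rate",
        [(0.5, "deletion", 0.95), (1.5, "duplication", 0.95), (0.0, "deletion", 1.0)],
    )
    def test_implant_recovery(self, factor, direction, min_rate):
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            event = CnvEvent("run1_S01", "GCK", exon_first=3, exon_last=3, copy_factor=factor)
            cfg = SimConfig(seed=1000 + rep, n_samples=20, cnv_events=(event,))
            matrix, manifest = gen_depth_matrix(cfg)
            assert manifest == [event]
            calls = call_cnvs_for_run(matrix)["run1_S01"]
            if any(c.gene == "GCK" and c.direction == direction for c in calls):
                hits += 1
        assert hits / n_rep >= min_rate


class TestMatrixFromTables:
    def test_region_means_and_sample_mean(self, small_panel):
        depths = {}
        for r in small_panel.regions:
            for pos0 in range(r.start, r.end):
                depths[(r.chrom, pos0 + 1)] = 10 if r.region_class == "CDS" else 20
        tables = {f"s{i}": table_with(depths, f"s{i}") for i in range(4)}
        m = depth_matrix_from_tables("run1", tables, small_panel)
        # CDS regions only, each uniform depth 10
        assert all(r.region_class == "CDS" for r in m.regions)
        np.testing.assert_allclose(m.mean_depth, 10.0)
        assert m.sample_mean_depth[0] == pytest.approx(
            sum(
                (10 if r.region_class == "CDS" else 20) * r.length
                for r in small_panel.regions
            )
            / small_panel.total_target_bp
        )
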