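import numpy as np
import pandas as pd
import pytest

from chiptile import peaks, simulate
from chiptile.io import ArrayScan, Region
from tests.conftest import make_scan


def brute_force_runs(positions, values, y0, min_probes, max_gap_bp, probe_length):
    """O(n^2) oracle: enumerate every maximal qualifying run directly."""
    n = len(positions)
    passing = set(i for i in range(n) if values[i] >= y0)
    runs = []
    for i in sorted(passing):
        # i starts a run iff no passing predecessor within max_gap_bp
        if any(j in passing and positions[i] - positions[j] <= max_gap_bp for j in range(i)):
            continue
        run = [i]
        for j in range(i + 1, n):
            if j in passing and positions[j] - positions[run[-1]] <= max_gap_bp:
                run.append(j)
        if len(run) >= min_probes:
            runs.append((positions[run[0]], positions[run[-1]] + probe_length))
    return runs


class TestNormalize:
    def test_median_centering(self, make_uniform_scan):
        scan = make_uniform_scan(np.full(200, 0.7))
        with pytest.warns(UserWarning):
            out = peaks.normalize_scan(scan)
        assert abs(out.probes["log2_ratio"].median()) < 1e-9

    def test_duplicates_averaged(self):
        n = 150
        starts = np.arange(n) * 25
        frames = []
        for dup, offset in ((1, 1.0), (2, 3.0)):
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": [f"p{i}" for i in range(n)],
                        "chrom": "chr",
                        "start": starts,
                        "log2_ratio": np.zeros(n) + offset,
                        "duplicate_index": dup,
                    }
                )
            )
        scan = ArrayScan("s", "chip-replicate", pd.concat(frames, ignore_index=True))
        with pytest.warns(UserWarning):  # all averaged values identical
            out = peaks.normalize_scan(scan)
        assert len(out.probes) == n
        # duplicates (1.0, 3.0) average to 2.0 before centering
        assert np.allclose(out.probes["log2_ratio"] + 2.0, 2.0)

    def test_centering_preserves_differences(self, make_uniform_scan):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.4, 1.0, size=300)
        out = peaks.normalize_scan(make_scan(vals))
        assert np.allclose(np.diff(out.probes["log2_ratio"]), np.diff(vals))

    def test_too_few_probes_rejected(self, make_uniform_scan):
        with pytest.raises(ValueError, match="100"):
            peaks.normalize_scan(make_scan(np.zeros(50)))


class TestSmooth:
    def test_constant_unchanged(self, make_uniform_scan):
        out = peaks.smooth_scan(make_scan(np.full(100, 1.3)), 400)
        assert np.allclose(out.probes["log2_ratio"], 1.3)

    def test_single_spike_removed(self, make_uniform_scan):
        vals = np.zeros(101)
        vals[50] = 5.0
        out = peaks.smooth_scan(make_scan(vals), 400)  # window spans 33 probes
        assert out.probes["log2_ratio"].iloc[50] == 0.0

    def test_idempotent_on_plateau_interior(self):
        vals = np.zeros(200)
        vals[80:120] = 2.0  # 40-probe plateau at step 25 = 1000 bp
        once = peaks.smooth_scan(make_scan(vals), 200)
        twice = peaks.smooth_scan(once, 200)
        interior = slice(89, 111)  # > half-width from both plateau edges
        assert np.allclose(
            once.probes["log2_ratio"].iloc[interior],
            twice.probes["log2_ratio"].iloc[interior],
        )
        assert np.allclose(once.probes["log2_ratio"].iloc[interior], 2.0)

    def test_brute_force_window_recomputation(self):
        rng = np.random.default_rng(1)
        # deliberately non-uniform probe spacing
        pos = np.sort(rng.choice(np.arange(0, 20000), size=400, replace=False))
        vals = rng.normal(size=400)
        df = pd.DataFrame(
            {"probe_id": [f"p{i}" for i in range(400)], "chrom": "c", "start": pos, "log2_ratio": vals}
        )
        scan = ArrayScan("s", "chip-replicate", df)
        out = peaks.smooth_scan(scan, 300)
        for i in range(400):
            window = vals[np.abs(pos - pos[i]) <= 300]
            assert out.probes["log2_ratio"].iloc[i] == pytest.approx(np.median(window))

    def test_circular_wrap(self):
        vals = np.zeros(100)
        vals[:3] = 2.0
        vals[-3:] = 2.0  # one 6-probe plateau across the origin
        out = peaks.smooth_scan(make_scan(vals), 80, genome_length=2500, circular=True)
        lin = peaks.smooth_scan(make_scan(vals), 80, genome_length=None, circular=False)
        # wrapped window sees the plateau from both sides at the origin probe
        assert out.probes["log2_ratio"].iloc[0] >= lin.probes["log2_ratio"].iloc[0]
        assert out.probes["log2_ratio"].iloc[0] == 2.0


class TestCallRegions:
    def test_all_zero_yields_nothing(self):
        assert peaks.call_regions(make_scan(np.zeros(100))) == []

    def test_single_block(self):
        vals = np.zeros(50)
        vals[20:30] = 1.5
        regions = peaks.call_regions(make_scan(vals))
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (20 * 25, 29 * 25 + 50)

    def test_min_probes_edge(self):
        vals = np.zeros(50)
        vals[10:12] = 2.0
        assert peaks.call_regions(make_scan(vals), min_probes=3) == []
        assert len(peaks.call_regions(make_scan(vals), min_probes=2)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_run_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 500
        vals = rng.normal(0.7, 0.6, size=n)
        scan = make_scan(vals)
        pos = scan.probes["start"].to_numpy()
        got = [(r.start, r.end) for r in peaks.call_regions(scan, y0=1.0, min_probes=3, max_gap_bp=50)]
        want = brute_force_runs(list(pos), list(vals), 1.0, 3, 50, 50)
        assert got == want

    def test_gap_splitting(self):
        # passing probes separated by a gap wider than max_gap_bp split in two
        vals = np.zeros(60)
        vals[10:14] = 1.5
        vals[16:20] = 1.5
        one = peaks.call_regions(make_scan(vals), max_gap_bp=100)  # 2-probe hole bridged
        two = peaks.call_regions(make_scan(vals), max_gap_bp=50)
        assert len(one) == 1 and len(two) == 2

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_monotone_in_y0_on_smoothed_peaks(self, seed):
        """On smoothed scans with separated unimodal peaks (the caller's
        contract), raising y0 shrinks regions and never increases their
        number."""
        from chiptile.simulate import PlantedSite, SimConfig

        cfg = SimConfig(genome_length=20_000, seed=seed)
        pos = np.arange(0, 20_000, 25) + 25
        sites = [
            PlantedSite(5_000, "+", "A" * 15, 1e-7, 1e-7, True, 0.9),
            PlantedSite(13_000, "+", "A" * 15, 1e-7, 1e-7, True, 0.7),
        ]
        rng = np.random.default_rng(seed)
        vals = simulate._true_signal(pos, sites, cfg) + rng.normal(0, 0.25, size=len(pos))
        scan = peaks.smooth_scan(make_scan(vals), 400, genome_length=20_000)
        prev = None
        for y0 in (0.5, 0.8, 1.0, 1.3, 1.7):
            regions = peaks.call_regions(scan, y0=y0)
            if prev is not None:
                assert len(regions) <= len(prev)
                for r in regions:  # every region shrinks into some lower-threshold region
                    assert any(p.start <= r.start and r.end <= p.end for p in prev)
            prev = regions


class TestCombine:
    def _scans(self, peak_vals, n=200):
        scans = []
        for v in peak_vals:
            vals = np.zeros(n)
            if v is not None:
                vals[80:100] = v
            scans.append(make_scan(vals))
        return scans

    def test_all_replicate_rule(self):
        scans = self._scans([1.5, 1.5, None])
        regions = [peaks.call_regions(s) for s in scans]
        mock = self._scans([None])[0]
        assert peaks.combine_replicates(regions, scans, mock) == []

    def test_mock_rule(self):
        scans = self._scans([1.5, 1.5, 1.5])
        regions = [peaks.call_regions(s) for s in scans]
        mock = self._scans([1.2])[0]  # mock is also hot there
        assert peaks.combine_replicates(regions, scans, mock) == []
        quiet_mock = self._scans([None])[0]
        kept = peaks.combine_replicates(regions, scans, quiet_mock)
        assert len(kept) == 1
        assert kept[0].fold_enrichment == pytest.approx(2 ** 1.5)

    def test_fold_threshold_applies_per_replicate(self):
        scans = self._scans([1.5, 1.5, 0.95])  # third called only at lower y0
        regions = [peaks.call_regions(s, y0=0.9) for s in scans]
        mock = self._scans([None])[0]
        # all three overlap, but replicate 3 max (0.95) < log2(2)
        assert peaks.combine_replicates(regions, scans, mock, fold_threshold=2.0) == []
        kept = peaks.combine_replicates(regions, scans, mock, fold_threshold=1.8)
        assert len(kept) == 1

    def test_needs_two_replicates(self):
        scans = self._scans([1.5])
        with pytest.raises(ValueError):
            peaks.combine_replicates([peaks.call_regions(scans[0])], scans, scans[0])
        with pytest.raises(ValueError):
            peaks.combine_replicates([], [], scans[0])


class TestQpcr:
    def test_fold_identities(self):
        cq = pd.DataFrame(
            {
                "target": ["t1", "t1", "t2", "t2", "spike", "spike"],
                "assay": ["IP", "input"] * 3,
                "cq": [20.0, 23.0, 21.0, 21.0, 25.0, 25.0],
            }
        )
        folds = peaks.qpcr_enrichment(cq)
        assert folds["t1"] == pytest.approx(8.0)  # target dCq exceeds ref by 3
        assert folds["t2"] == pytest.approx(1.0)

    def test_missing_cell_named(self):
        cq = pd.DataFrame(
            {"target": ["t1", "spike", "spike"], "assay": ["IP", "IP", "input"], "cq": [20, 25, 25]}
        )
        with pytest.raises(ValueError, match="t1"):
            peaks.qpcr_enrichment(cq)

    def test_simulated_recovery(self):
        cq = simulate.simulate_chip_qpcr(["a", "b"], [5.0, 2.0], noise_sd=0.0, seed=3)
        folds = peaks.qpcr_enrichment(cq)
        assert folds["a"] == pytest.approx(5.0, rel=1e-6)
        assert folds["b"] == pytest.approx(2.0, rel=1e-6)

    def test_correlation_identities(self):
        x = np.arange(1, 11, dtype=float)
        rho, _ = peaks.validate_correlation(x, x * 3)
        assert rho == pytest.approx(1.0)
        rho, _ = peaks.validate_correlation(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_correlation_on_noisy_replica(self):
        rng = np.random.default_rng(0)
        chip = rng.uniform(2, 11, size=30)
        qpcr = chip * rng.lognormal(0.3, 0.25, size=30)
        rho, p = peaks.validate_correlation(chip, qpcr)
        assert rho > 0 and p < 0.05
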