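import numpy as np
import pytest

from chiptile import motif, peaks, quant, simulate
from chiptile.simulate import PlantedSite, SimConfig


def small_config(**kw):
    defaults = dict(genome_length=20_000, n_genes=8, seed=1)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestGenome:
    def test_deterministic_under_seed(self):
        g1 = simulate.generate_genome(small_config())
        g2 = simulate.generate_genome(small_config())
        assert g1.sequence == g2.sequence
        assert g1.genes == g2.genes and g1.tss == g2.tss

    def test_seed_sensitivity(self):
        g1 = simulate.generate_genome(small_config(seed=1))
        g2 = simulate.generate_genome(small_config(seed=2))
        assert g1.sequence != g2.sequence

    def test_extreme_gc(self):
        g = simulate.generate_genome(small_config(gc_content=1.0))
        assert set(g.sequence) <= {"G", "C"}

    def test_structure(self):
        g = simulate.generate_genome(small_config(n_genes=5))
        assert g.length == 20_000 and len(g.genes) == 5 and len(g.tss) == 5
        # ORFs do not overlap
        spans = sorted((x.start, x.end) for x in g.genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_infeasible_packing_refused(self):
        with pytest.raises(ValueError, match="pack"):
            simulate.generate_genome(small_config(n_genes=25))

    def test_config_invariants(self):
        with pytest.raises(ValueError, match="probe_step"):
            SimConfig(probe_step=300, fragment_length=500)
        with pytest.raises(ValueError, match="fragment_length"):
            SimConfig(genome_length=4000, fragment_length=500)
        with pytest.raises(ValueError, match="outside"):
            SimConfig(planted_sites=[(500_000, 1e-7, True)])


class TestPlanting:
    def test_consensus_target_plants_consensus(self, pwm):
        g = simulate.generate_genome(small_config())
        _, planted = simulate.plant_motifs(g, pwm, [(5000, pwm.kd_consensus, True)])
        assert planted[0].word == pwm.consensus
        assert planted[0].realized_kd == pytest.approx(pwm.kd_consensus)

    @pytest.mark.parametrize("target_kd", [6.3e-8, 2e-7, 1e-6, 14e-6, 2.9e-4])
    def test_realized_kd_within_factor(self, pwm, target_kd):
        g = simulate.generate_genome(small_config())
        _, planted = simulate.plant_motifs(g, pwm, [(5000, target_kd, True)])
        ratio = planted[0].realized_kd / target_kd
        assert 1 / 1.5 <= ratio <= 1.5

    def test_unreachable_target_names_maximum(self, pwm):
        g = simulate.generate_genome(small_config())
        with pytest.raises(ValueError, match="maximal attainable"):
            simulate.plant_motifs(g, pwm, [(5000, 1e12, True)])
        with pytest.raises(ValueError, match="below the consensus"):
            simulate.plant_motifs(g, pwm, [(5000, 1e-9, True)])

    def test_round_trip_scan_recovers_planted_sites(self, pwm):
        sites = [(3000, 6.3e-8, True), (9000, 5e-7, True), (15_000, 1e-5, False)]
        g = simulate.generate_genome(small_config(gc_content=0.7, seed=3))
        g2, planted = simulate.plant_motifs(g, pwm, sites, rng=np.random.default_rng(3))
        threshold = max(s.realized_kd for s in planted) * 1.001
        hits = motif.scan_sequence(pwm, g2, threshold)
        starts = {h.start for h in hits}
        half = pwm.width // 2
        for s in planted:
            assert (s.position - half) % g2.length in starts

    def test_occupancy_follows_mass_action(self, pwm):
        g = simulate.generate_genome(small_config())
        _, planted = simulate.plant_motifs(
            g, pwm, [(5000, pwm.kd_consensus, True)], protein_conc=pwm.kd_consensus
        )
        assert planted[0].occupancy == pytest.approx(0.5)


class TestChipSignal:
    def test_kernel_peak_at_site(self, pwm):
        cfg = small_config(noise_sd=0.0, planted_sites=[(10_000, 6.3e-8, True)])
        g = simulate.generate_genome(cfg)
        g, planted = simulate.plant_motifs(g, pwm, cfg.planted_sites)
        scans = simulate.simulate_chip(g, planted, cfg)
        probes = scans[0].probes[scans[0].probes["duplicate_index"] == 1]
        top = probes.loc[probes["log2_ratio"].idxmax()]
        center = top["start"] + cfg.probe_length // 2
        assert abs(center - 10_000) <= cfg.probe_step

    def test_amplitude_inside_reported_fold_range(self, pwm):
        """A near-saturated site peaks around 2^2.5 ~ 5.7-fold, inside the
        2.2-10.8 fold window such arrays report."""
        cfg = small_config(noise_sd=0.0, planted_sites=[(10_000, 6.3e-8, True)])
        g = simulate.generate_genome(cfg)
        g, planted = simulate.plant_motifs(g, pwm, cfg.planted_sites)
        scans = simulate.simulate_chip(g, planted, cfg)
        fold = 2 ** scans[0].probes["log2_ratio"].max()
        assert 2.2 <= fold <= 10.8
        assert fold == pytest.approx(2 ** (2.5 * planted[0].occupancy), rel=0.1)

    def test_non_permissive_site_silent(self, pwm):
        cfg = small_config(noise_sd=0.0, planted_sites=[(10_000, 6.3e-8, False)])
        g = simulate.generate_genome(cfg)
        g, planted = simulate.plant_motifs(g, pwm, cfg.planted_sites)
        scans = simulate.simulate_chip(g, planted, cfg)
        assert np.allclose(scans[0].probes["log2_ratio"], 0.0)

    def test_signal_linear_in_occupancy(self):
        cfg = small_config()
        pos = np.arange(0, 20_000, 25)
        site = lambda occ: PlantedSite(10_000, "+", "A" * 15, 1e-7, 1e-7, True, occ)
        s1 = simulate._true_signal(pos, [site(0.3)], cfg)
        s2 = simulate._true_signal(pos, [site(0.6)], cfg)
        assert np.allclose(s2, 2 * s1)

    def test_mock_is_pure_noise_and_duplicates_present(self, pwm):
        cfg = small_config(noise_sd=0.2, planted_sites=[(10_000, 6.3e-8, True)])
        g = simulate.generate_genome(cfg)
        g, planted = simulate.plant_motifs(g, pwm, cfg.planted_sites)
        scans = simulate.simulate_chip(g, planted, cfg)
        assert [s.role for s in scans] == ["chip-replicate"] * 3 + ["mock"]
        mock = scans[-1].probes
        assert sorted(mock["duplicate_index"].unique()) == [1, 2]
        assert abs(mock["log2_ratio"].mean()) < 0.02
        assert mock["log2_ratio"].std() == pytest.approx(0.2, rel=0.1)

    def test_reproducible_bit_exact(self, pwm):
        cfg = small_config(planted_sites=[(10_000, 1e-7, True)])

        def run():
            g = simulate.generate_genome(cfg)
            g, p = simulate.plant_motifs(g, pwm, cfg.planted_sites, rng=np.random.default_rng(0))
            return simulate.simulate_chip(g, p, cfg)

        a, b = run(), run()
        for sa, sb in zip(a, b):
            assert sa.probes.equals(sb.probes)

    def test_null_genome_produces_no_regions(self):
        """Site-free data must yield zero called regions at the default
        thresholds, across 20 seeds."""
        for seed in range(20):
            cfg = small_config(seed=seed)
            g = simulate.generate_genome(cfg)
            scans = simulate.simulate_chip(g, [], cfg)
            smoothed = [
                peaks.smooth_scan(peaks.normalize_scan(s), 400, genome_length=cfg.genome_length)
                for s in scans[:3]
            ]
            mock = peaks.smooth_scan(
                peaks.normalize_scan(scans[3]), 400, genome_length=cfg.genome_length
            )
            rep = [peaks.call_regions(s) for s in smoothed]
            assert peaks.combine_replicates(rep, smoothed, mock) == []


class TestIsothermAndCq:
    def test_half_saturation_identity(self):
        iso = simulate.simulate_isotherm(63e-9, [63e-9, 126e-9, 252e-9, 504e-9], noise_sd=0.0)
        assert iso["fraction_bound"].iloc[0] == pytest.approx(0.5)

    def test_saturation_limit(self):
        iso = simulate.simulate_isotherm(63e-9, [63e-9, 1e-3], noise_sd=0.0)
        assert iso["fraction_bound"].iloc[-1] == pytest.approx(1.0, abs=1e-3)

    def test_fit_recovers_generating_kd(self):
        conc = [10e-9 * 2**i for i in range(8)]  # 10-1280 nM titration
        iso = simulate.simulate_isotherm(63e-9, conc, noise_sd=0.03, seed=5)
        fit = quant.fit_kd(iso)
        assert abs(fit.kd - 63e-9) / 63e-9 < 0.15

    def test_concentration_validation(self):
        with pytest.raises(ValueError, match="positive"):
            simulate.simulate_isotherm(1e-7, [0.0, 1e-7], noise_sd=0.0)
        with pytest.raises(ValueError, match="sorted"):
            simulate.simulate_isotherm(1e-7, [2e-7, 1e-7], noise_sd=0.0)

    def test_null_cq_table_gives_unit_folds(self):
        cq = simulate.simulate_cq_table(["geneA", "geneB"], [1.0, 1.0], noise_sd=0.0)
        for gene in ("geneA", "geneB"):
            res = quant.ddct(cq, "tbp", gene)
            assert res.fold == pytest.approx(1.0)

    def test_planted_twofold_down_recovered(self):
        cq = simulate.simulate_cq_table(["crisprB"], [0.5], noise_sd=0.0, seed=2)
        assert quant.ddct(cq, "tbp", "crisprB").fold == pytest.approx(0.5)

    def test_planted_knockout_magnitude_recovered(self):
        cq = simulate.simulate_cq_table(["lrpB"], [0.0031], noise_sd=0.0, seed=2)
        assert quant.ddct(cq, "tbp", "lrpB").fold == pytest.approx(0.0031, rel=1e-6)
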