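"""Generator correctness: determinism, noiseless closed forms, planted truth."""

import json

import numpy as np
import pytest

from phagekit.aai import read_fasta, write_fasta
from phagekit.adsorption import read_adsorption_tsv, write_adsorption_tsv
from phagekit.consensus import jaccard_matrix
from phagekit.growth import read_growth_tsv, write_growth_tsv
from phagekit.simulate import (
    PlantedTruth,
    SimulationConfig,
    simulate_adsorption_series,
    simulate_growth_curve,
    simulate_host_range,
    simulate_predictions,
    simulate_proteome_pair,
)


class TestGrowthGenerator:
    def test_zero_burst_gives_constant_curve(self, noiseless):
        curve, _ = simulate_growth_curve(1e8, 60, 120, burst=0, config=noiseless)
        assert np.all(curve.titers == 1e8)

    def test_noiseless_plateau_equals_initial_times_one_plus_burst(self, noiseless):
        curve, _ = simulate_growth_curve(1e8, 60, 120, burst=103, config=noiseless)
        assert curve.titers[-1] == pytest.approx(1.04e10, rel=1e-12)
        # plateau holds from latent+rise onwards
        plateau = curve.titers[curve.times >= 180]
        assert np.all(plateau == plateau[0])

    def test_latent_segment_is_flat_at_initial(self, noiseless):
        curve, _ = simulate_growth_curve(1e8, 60, 120, burst=50, config=noiseless)
        assert np.all(curve.titers[curve.times < 60] == 1e8)

    def test_initial_point_is_noiseless(self, noisy):
        curve, _ = simulate_growth_curve(1e8, 60, 120, 103, config=noisy)
        assert curve.titers[0] == 1e8

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(seed=7, noise_sd=0.05)
        c1, _ = simulate_growth_curve(1e8, 60, 120, 103, config=cfg)
        c2, _ = simulate_growth_curve(1e8, 60, 120, 103, config=cfg)
        assert np.array_equal(c1.titers, c2.titers)
        c3, _ = simulate_growth_curve(1e8, 60, 120, 103, config=SimulationConfig(seed=8, noise_sd=0.05))
        assert not np.array_equal(c1.titers, c3.titers)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"step": 0},
            {"t_max": -1},
            {"burst": -1},
            {"latent_min": 200, "rise_min": 100},  # latent+rise >= t_max
        ],
    )
    def test_invalid_parameters_raise(self, kwargs, noiseless):
        params = dict(initial_titer=1e8, latent_min=60, rise_min=120, burst=10,
                      t_max=240, step=10, config=noiseless)
        params.update(kwargs)
        with pytest.raises(ValueError):
            simulate_growth_curve(**params)


class TestAdsorptionGenerator:
    def test_zero_rate_is_constant(self, noiseless):
        series, _ = simulate_adsorption_series(1e9, 1e8, K=0, config=noiseless)
        assert np.all(series.free_phage == 1e9)

    def test_one_decade_drop(self, noiseless):
        # K*B*t = 2.3026 ~ ln(10) at t=10 min
        series, _ = simulate_adsorption_series(1e9, 1e8, K=2.3026e-9, config=noiseless)
        assert series.free_phage[1] == pytest.approx(1e8, rel=1e-3)

    def test_t0_exact_and_noiseless_strictly_decreasing(self, noisy):
        series, _ = simulate_adsorption_series(1e9, 1e8, 1e-9, config=noisy)
        assert series.P0 == 1e9
        clean, _ = simulate_adsorption_series(1e9, 1e8, 1e-9,
                                              config=SimulationConfig(seed=0, noise_sd=0))
        assert np.all(np.diff(clean.free_phage) < 0)

    @pytest.mark.parametrize("times", [(0, 20, 10), (10, 20, 30), (0, -5, 10)])
    def test_bad_times_raise(self, times, noiseless):
        with pytest.raises(ValueError):
            simulate_adsorption_series(1e9, 1e8, 1e-9, times=times, config=noiseless)


class TestHostRangeGenerator:
    def test_full_breadth_all_susceptible(self, noiseless):
        m, refs, _ = simulate_host_range(2, 21, [1.0, 1.0], config=noiseless)
        assert (m.to_numpy() > 0).all()

    def test_zero_breadth_all_zero(self, noiseless):
        m, _, _ = simulate_host_range(1, 21, [0.0], config=noiseless)
        assert (m.to_numpy() == 0).all()

    def test_exact_susceptible_count_per_phage(self, noisy):
        breadths = [20 / 21, 10 / 21, 13 / 21, 12 / 21]
        m, _, truth = simulate_host_range(4, 21, breadths, config=noisy)
        for row, b in zip(m.to_numpy(), breadths):
            assert int((row > 0).sum()) == round(b * 21)
        assert truth.true_breadths == tuple(breadths)

    def test_breadth_out_of_range_raises(self, noiseless):
        with pytest.raises(ValueError):
            simulate_host_range(1, 21, [1.5], config=noiseless)


class TestPredictionGenerator:
    def test_no_perturbation_gives_identical_tools(self, noiseless):
        sets, _ = simulate_predictions(
            60000, 40, miss_rate=0, spurious_rate=0, start_jitter=0, config=noiseless
        )
        keys = [ps.keys() for ps in sets]
        assert all(k == keys[0] for k in keys)
        jac = jaccard_matrix(sets)
        assert (jac.to_numpy() == 1.0).all()

    def test_three_prime_anchor_shared_despite_jitter(self, noisy):
        sets, truth = simulate_predictions(60000, 40, miss_rate=0, spurious_rate=0,
                                           start_jitter=30, config=noisy)
        true_keys = {
            (strand, stop if strand == "+" else start)
            for start, stop, strand in truth.true_gene_set
        }
        for ps in sets:
            assert ps.keys() == frozenset(true_keys)

    def test_spurious_keys_absent_from_truth(self, noisy):
        sets, truth = simulate_predictions(60000, 30, miss_rate=0.1, spurious_rate=4,
                                           config=noisy)
        true_keys = {
            (strand, stop if strand == "+" else start)
            for start, stop, strand in truth.true_gene_set
        }
        for ps in sets:
            spur = truth.spurious_calls[ps.tool]
            for start, stop, strand in spur:
                key = (strand, stop if strand == "+" else start)
                assert key not in true_keys

    def test_genes_fit_genome_or_raise(self, noiseless):
        with pytest.raises(ValueError):
            simulate_predictions(5000, 100, config=noiseless)

    def test_determinism(self):
        cfg = SimulationConfig(seed=11)
        s1, _ = simulate_predictions(60000, 40, config=cfg)
        s2, _ = simulate_predictions(60000, 40, config=cfg)
        assert [ps.calls for ps in s1] == [ps.calls for ps in s2]


class TestProteomeGenerator:
    def test_zero_divergence_identical(self, noiseless):
        a, b, truth = simulate_proteome_pair(5, (50, 80), divergence=0, config=noiseless)
        assert [p.sequence for p in a] == [p.sequence for p in b]
        assert truth.pair_identity_pct == (100.0,) * 5

    def test_planted_identity_matches_direct_count(self, noisy):
        a, b, truth = simulate_proteome_pair(10, (100, 200), divergence=0.1, config=noisy)
        for pa, pb, planted in zip(a, b, truth.pair_identity_pct):
            same = sum(x == y for x, y in zip(pa.sequence, pb.sequence))
            assert 100.0 * same / len(pa) == pytest.approx(planted)

    def test_expected_identity_near_one_minus_divergence(self, noisy):
        _, _, truth = simulate_proteome_pair(50, (200, 400), divergence=0.05, config=noisy)
        assert np.mean(truth.pair_identity_pct) == pytest.approx(95.0, abs=1.0)

    def test_divergence_bounds(self, noiseless):
        with pytest.raises(ValueError):
            simulate_proteome_pair(5, divergence=1.0, config=noiseless)


class TestRoundTrips:
    def test_growth_tsv(self, tmp_path, noisy):
        curve, _ = simulate_growth_curve(1e8, 60, 120, 103, config=noisy)
        path = tmp_path / "c.tsv"
        write_growth_tsv(curve, path)
        back = read_growth_tsv(path)
        assert np.array_equal(back.times, curve.times)
        assert np.array_equal(back.titers, curve.titers)

    def test_adsorption_tsv(self, tmp_path, noisy):
        series, _ = simulate_adsorption_series(1e9, 1e8, 1e-9, config=noisy)
        path = tmp_path / "s.tsv"
        write_adsorption_tsv(series, path)
        back = read_adsorption_tsv(path, B=1e8)
        assert np.array_equal(back.free_phage, series.free_phage)

    def test_fasta(self, tmp_path, noisy):
        a, _, _ = simulate_proteome_pair(5, (50, 80), 0.05, config=noisy)
        path = tmp_path / "p.faa"
        write_fasta(a, path)
        back = read_fasta(path)
        assert [(p.id, p.sequence) for p in back] == [(p.id, p.sequence) for p in a]

    def test_planted_truth_json(self, tmp_path, noisy):
        _, truth = simulate_growth_curve(1e8, 60, 120, 103, config=noisy)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        data = json.loads(path.read_text())
        assert data["true_burst"] == 103

    def test_truth_dataclass_only_populates_planted_fields(self, noisy):
        _, truth = simulate_adsorption_series(1e9, 1e8, 1e-9, config=noisy)
        assert truth.true_K == 1e-9
        assert truth.true_burst is None
        assert isinstance(truth, PlantedTruth)
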