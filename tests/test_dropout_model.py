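import numpy as np
import pandas as pd
import pytest

from scrobust import (
    DropoutInjectionModel,
    DropoutModels,
    compute_recovery_distribution,
    fit_dropout_injection,
    fit_dropout_models,
    injection_probability,
    sample_recovery,
)
from scrobust.data_io import CountsMatrix, SpikeInReference
from scrobust.dropout_model import DropoutModelError
from scrobust.synthetic import PlantedModel, generate_spikein_counts


def spike_frame(rows: dict[str, list[int]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


class TestInjectionFit:
    def test_exact_two_point_line(self):
        # spike A: y=1, half zeros; spike B: y=2, quarter zeros
        counts = spike_frame({"A": [0, 0, 1, 1], "B": [0, 1, 1, 1]})
        ref = SpikeInReference(molecules=pd.Series([1.0, 2.0], index=["A", "B"]))
        model = fit_dropout_injection(counts, ref)
        assert model.slope == pytest.approx(-0.25)
        assert model.intercept == pytest.approx(0.75)
        assert model.k == 2  # line hits zero exactly at y = 3

    def test_no_zeros_gives_k_zero(self):
        counts = spike_frame({"A": [1, 2], "B": [3, 4]})
        ref = SpikeInReference(molecules=pd.Series([1.0, 2.0], index=["A", "B"]))
        with pytest.warns(UserWarning, match="no zeros"):
            model = fit_dropout_injection(counts, ref)
        assert model.k == 0

    def test_flat_line_k_capped_at_max_molecules(self):
        counts = spike_frame({"A": [0, 1], "B": [0, 1]})  # both D = 0.5
        ref = SpikeInReference(molecules=pd.Series([2.0, 6.0], index=["A", "B"]))
        model = fit_dropout_injection(counts, ref)
        assert model.slope == pytest.approx(0.0, abs=1e-12)
        assert model.intercept == pytest.approx(0.5)
        assert model.k == 6

    def test_too_few_shared_spikeins(self):
        counts = spike_frame({"A": [0, 1]})
        ref = SpikeInReference(molecules=pd.Series([1.0], index=["A"]))
        with pytest.raises(DropoutModelError):
            fit_dropout_injection(counts, ref)


class TestInjectionProbability:
    model = DropoutInjectionModel(slope=-0.25, intercept=0.75, k=2)

    def test_linear_value(self):
        assert injection_probability(self.model, 1.0) == pytest.approx(0.5)

    def test_zero_beyond_threshold(self):
        assert injection_probability(self.model, 3.0) == 0.0

    def test_clamped_at_one(self):
        m = DropoutInjectionModel(slope=0.0, intercept=1.3, k=5)
        assert injection_probability(m, 0.0) == 1.0

    def test_monotone_nonincreasing_for_negative_slope(self):
        ys = np.linspace(0, 5, 50)
        d = injection_probability(self.model, ys)
        assert (np.diff(d) <= 1e-12).all()


class TestRecoveryDistribution:
    def test_worked_example_k2(self):
        model = DropoutInjectionModel(slope=-0.25, intercept=0.75, k=2)
        dist = compute_recovery_distribution(0.5, model, "g")
        assert dist.prior_zero == pytest.approx(0.2)
        assert dist.prior_uniform == pytest.approx(0.4)
        np.testing.assert_allclose(dist.recovery, [0.4, 0.4, 0.2])
        # law of total probability reproduces the zero fraction
        inj = [1.0, 0.5, 0.25]
        prior = [0.2, 0.4, 0.4]
        assert np.dot(inj, prior) == pytest.approx(0.5)

    def test_worked_example_k1(self):
        model = DropoutInjectionModel(slope=-0.5, intercept=1.0, k=1)
        dist = compute_recovery_distribution(0.75, model, "g")
        assert dist.prior_zero == pytest.approx(0.5)
        assert dist.prior_uniform == pytest.approx(0.5)
        np.testing.assert_allclose(dist.recovery, [2 / 3, 1 / 3])

    def test_all_zero_gene_mass_sums_to_one(self):
        model = DropoutInjectionModel(slope=-0.25, intercept=0.75, k=2)
        dist = compute_recovery_distribution(1.0, model, "g")
        assert dist.recovery.sum() == pytest.approx(1.0)

    def test_zero_fraction_zero_rejected(self):
        model = DropoutInjectionModel(slope=-0.25, intercept=0.75, k=2)
        with pytest.raises(DropoutModelError):
            compute_recovery_distribution(0.0, model)

    def test_degenerate_all_certain_injection(self):
        model = DropoutInjectionModel(slope=0.0, intercept=1.0, k=3)
        with pytest.warns(UserWarning, match="degenerate"):
            dist = compute_recovery_distribution(0.4, model, "g")
        assert dist.prior_zero == pytest.approx(0.4)
        assert dist.recovery.sum() == pytest.approx(1.0)

    def test_clamping_renormalizes(self):
        # zero fraction below the mean injection density S -> raw prior < 0
        model = DropoutInjectionModel(slope=0.0, intercept=0.6, k=4)
        dist = compute_recovery_distribution(0.1, model, "g")
        assert dist.prior_zero == 0.0
        assert dist.recovery.sum() == pytest.approx(1.0)
        assert dist.recovery[0] == pytest.approx(0.0)


class TestConservationLaws:
    def test_bayes_identities_across_synthetic_genes(self):
        """Eq. of total probability and unity hold for every fitted gene."""
        pm = PlantedModel(n_cells=150, seed=2)
        m, ref = generate_spikein_counts(pm)
        models = fit_dropout_models(m, ref)
        inj = models.injection
        assert len(models.recovery) > 0
        dens = injection_probability(inj, np.arange(1, inj.k + 1))
        for dist in models.recovery.values():
            # unity: prior_zero + k * n = 1
            assert dist.prior_zero + inj.k * dist.prior_uniform == pytest.approx(
                1.0, abs=1e-9
            )
            # total probability (pre-clamping cases only)
            raw_prior_zero = (dist.zero_fraction - dens.mean()) / (1 - dens.mean())
            if 0.0 <= raw_prior_zero <= 1.0:
                prior = np.concatenate(
                    [[dist.prior_zero], np.full(inj.k, dist.prior_uniform)]
                )
                lik = np.concatenate([[1.0], dens])
                assert np.dot(lik, prior) == pytest.approx(
                    dist.zero_fraction, abs=1e-9
                )
            assert dist.recovery.sum() == pytest.approx(1.0, abs=1e-9)
            assert (dist.recovery >= 0).all()


class TestSampleRecovery:
    def test_point_mass(self):
        model = DropoutInjectionModel(slope=0.0, intercept=0.0, k=2)
        dist = compute_recovery_distribution(0.5, model, "g")
        dist.recovery = np.array([1.0, 0.0, 0.0])
        rng = np.random.default_rng(0)
        assert all(sample_recovery(dist, rng) == 0 for _ in range(20))

    def test_frequencies_match_probabilities(self):
        model = DropoutInjectionModel(slope=-0.25, intercept=0.75, k=2)
        dist = compute_recovery_distribution(0.5, model, "g")  # (0.4, 0.4, 0.2)
        rng = np.random.default_rng(1)
        draws = sample_recovery(dist, rng, size=100_000)
        freq = np.bincount(draws, minlength=3) / draws.size
        for f, p in zip(freq, dist.recovery):
            se = np.sqrt(p * (1 - p) / draws.size)
            assert abs(f - p) < 3 * se
        expected_mean = np.dot(np.arange(3), dist.recovery)
        assert draws.mean() == pytest.approx(expected_mean, abs=0.01)


def test_dropout_models_tsv_round_trip(tmp_path):
    pm = PlantedModel(n_cells=60, seed=4)
    m, ref = generate_spikein_counts(pm)
    models = fit_dropout_models(m, ref)
    p = tmp_path / "dropout.tsv"
    models.to_tsv(p)
    back = DropoutModels.from_tsv(p)
    assert back.injection == models.injection
    assert set(back.recovery) == set(models.recovery)
    gid = next(iter(models.recovery))
    np.testing.assert_allclose(back.recovery[gid].recovery, models.recovery[gid].recovery)


def test_fit_dropout_models_covers_spikein_rows_too():
    pm = PlantedModel(n_cells=80, seed=6)
    m, ref = generate_spikein_counts(pm)
    models = fit_dropout_models(m, ref)
    spike_with_zero = [
        gid
        for gid in m.values.index
        if (m.values.loc[gid] == 0).any()
    ]
    assert all(g in models.recovery for g in spike_with_zero)


def test_counts_matrix_with_zero_row_still_fits():
    # gene never observed: zero_fraction 1, needs a valid recovery distribution
    pm = PlantedModel(n_cells=50, seed=8)
    spikes, ref = generate_spikein_counts(pm)
    values = pd.concat(
        [pd.DataFrame([[0] * 50], index=["dead"], columns=spikes.values.columns), spikes.values]
    )
    flags = pd.concat([pd.Series(False, index=["dead"]), pd.Series(True, index=spikes.values.index)])
    models = fit_dropout_models(CountsMatrix(values=values, is_spikein=flags), ref)
    assert models.recovery["dead"].zero_fraction == 1.0
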