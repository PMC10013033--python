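"""Simulator physics: planted spectral radii, stationary statistics,
oddball bookkeeping, MMN recovery, determinism."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.linalg import solve_discrete_lyapunov

from dnmcrit.synthetic import (
    GroupSpec,
    LinearNetworkModel,
    SimulationConfig,
    generate_study,
    make_linear_model,
    scaled_config,
    simulate_difference_process,
    simulate_oddball_recording,
)


def small_config(**kw):
    defaults = dict(
        n_channels=12,
        dnm_members=tuple(range(8)),
        group_specs={"HC": GroupSpec(2, 0.9, -3.0, 170.0)},
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def power_iteration_radius(a, iters=2000):
    """Independent spectral-radius estimate (no eigendecomposition)."""
    v = np.ones(a.shape[0]) / np.sqrt(a.shape[0])
    lam = 0.0
    for _ in range(iters):
        w = a @ v
        lam = np.linalg.norm(w)
        if lam == 0:
            return 0.0
        v = w / lam
    return lam


class TestLinearModel:
    def test_diagonal_one_member_block_radius(self):
        cfg = small_config(dnm_members=(0,))
        model = make_linear_model(cfg, 0.9)
        assert model.A[0, 0] == pytest.approx(0.9)  # gamma * J(1)/1 = gamma
        assert model.gamma == 0.9

    def test_gamma_out_of_open_interval_rejected(self):
        cfg = small_config()
        for bad in (0.0, 1.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                make_linear_model(cfg, bad)

    def test_block_radius_matches_power_iteration(self):
        cfg = small_config()
        model = make_linear_model(cfg, 0.95)
        block = model.A[np.ix_(model.dnm_members, model.dnm_members)]
        assert power_iteration_radius(block) == pytest.approx(0.95, abs=1e-6)
        assert power_iteration_radius(model.A) < 1.0

    def test_members_must_be_strict_subset(self):
        with pytest.raises(ValueError, match="strict subset"):
            LinearNetworkModel(
                n_channels=4, A=np.eye(4) * 0.5, dnm_members=(0, 1, 2, 3),
                gamma=0.5, offblock_coupling=0.3, noise_sd=1.0,
            )

    def test_block_radius_validated_against_gamma(self):
        with pytest.raises(ValueError, match="spectral radius"):
            LinearNetworkModel(
                n_channels=4, A=np.eye(4) * 0.5, dnm_members=(0, 1),
                gamma=0.9, offblock_coupling=0.3, noise_sd=1.0,
            )


class TestDifferenceProcess:
    def test_zero_noise_is_identically_zero(self):
        cfg = small_config(noise_sd=0.0)
        model = make_linear_model(cfg, 0.9)
        z = simulate_difference_process(model, 100, seed=0)
        assert np.all(z == 0.0)

    def test_same_seed_bitwise_identical(self):
        model = make_linear_model(small_config(), 0.9)
        z1 = simulate_difference_process(model, 500, seed=42)
        z2 = simulate_difference_process(model, 500, seed=42)
        assert np.array_equal(z1, z2)

    def test_ar1_stationary_sd(self):
        # channel 0 is a pure AR(1) with gamma 0.9, sigma 1:
        # stationary SD = 1/sqrt(1 - 0.81) = 2.294
        cfg = small_config(n_channels=2, dnm_members=(0,))
        model = make_linear_model(cfg, 0.9)
        z = simulate_difference_process(model, 50_000, seed=1)
        expected = 1.0 / np.sqrt(1.0 - 0.81)
        assert z[0].std() == pytest.approx(expected, rel=0.05)

    def test_covariance_solves_lyapunov_equation(self):
        cfg = small_config()
        model = make_linear_model(cfg, 0.9)
        z = simulate_difference_process(model, 50_000, seed=2)
        target = solve_discrete_lyapunov(model.A, np.eye(model.n_channels))
        emp = np.cov(z)
        atol = 0.05 * np.max(np.diag(target))
        assert np.allclose(emp, target, rtol=0.05, atol=atol)

    def test_member_variance_increases_with_gamma(self):
        cfg = small_config()
        means = []
        for gamma in (0.5, 0.7, 0.9, 0.98):
            model = make_linear_model(cfg, gamma)
            sds = []
            for seed in range(5):
                z = simulate_difference_process(model, 8000, seed=seed)
                sds.append(z[list(cfg.dnm_members)].std())
            means.append(np.mean(sds))
        assert np.all(np.diff(means) > 0)

    def test_nonmember_variance_unaffected_by_gamma(self):
        cfg = small_config()
        sds = []
        for gamma in (0.5, 0.98):
            model = make_linear_model(cfg, gamma)
            z = simulate_difference_process(model, 30_000, seed=3)
            sds.append(z[8:].std())
        assert sds[0] == pytest.approx(sds[1], rel=0.05)


class TestOddballRecording:
    def test_event_counts_and_deviant_fraction(self):
        cfg = small_config(n_stimuli=2000)
        model = make_linear_model(cfg, 0.9)
        rec = simulate_oddball_recording(cfg, model, "S1", seed=0)
        assert len(rec.events) == 2000
        n_dev = sum(k == "deviant" for _, k in rec.events)
        se = np.sqrt(0.1 * 0.9 / 2000)
        assert abs(n_dev / 2000 - 0.1) < 3 * se

    def test_no_consecutive_deviants_by_default(self):
        cfg = small_config(n_stimuli=2000)
        model = make_linear_model(cfg, 0.9)
        rec = simulate_oddball_recording(cfg, model, "S1", seed=5)
        kinds = [k for _, k in rec.events]
        assert all(
            not (a == b == "deviant") for a, b in zip(kinds, kinds[1:])
        )

    def test_channel_count_mismatch_rejected(self):
        cfg = small_config()
        model = make_linear_model(small_config(n_channels=10), 0.9)
        with pytest.raises(ValueError, match="channels"):
            simulate_oddball_recording(cfg, model, "S1", seed=0)

    def test_zero_injection_means_identical_responses(self):
        # no MMN, no dynamics noise: deviant and standard epochs differ only
        # by sensor noise, so the epoch means coincide within its SE
        cfg = small_config(n_stimuli=400, noise_sd=0.0, sensor_noise_sd=0.0)
        model = make_linear_model(cfg, 0.9)
        rec = simulate_oddball_recording(
            cfg, model, "S1", seed=0, mmn_amplitude=0.0
        )
        from dnmcrit.preprocess import PreprocessConfig, extract_epochs

        es = extract_epochs(rec, PreprocessConfig())
        assert np.allclose(
            es.standard_epochs.mean(axis=0), es.deviant_epochs.mean(axis=0)
        )

    def test_planted_mmn_recovered(self):
        # -3 µV at 170 ms, sensor noise 5 µV, dynamics off: the corrected
        # ERP minimum must sit at the planted amplitude and latency within
        # the standard error of the epoch mean
        cfg = small_config(
            n_stimuli=2000, noise_sd=0.0, sensor_noise_sd=5.0,
            no_consecutive_deviants=False, amplitude_jitter_sd=0.0,
        )
        model = make_linear_model(cfg, 0.9)
        rec = simulate_oddball_recording(
            cfg, model, "S1", seed=9, mmn_amplitude=-3.0, mmn_latency=170.0
        )
        from dnmcrit.preprocess import PreprocessConfig, correct_epochs, extract_epochs

        cor = correct_epochs(extract_epochs(rec, PreprocessConfig()))
        n_dev = cor.n_epochs
        n_std = 2000 - n_dev
        member = list(cfg.dnm_members)[0]
        wave = cor.data.mean(axis=0)[member]
        i_min = int(np.argmin(wave))
        se = 5.0 * np.sqrt(1.0 / n_dev + 1.0 / n_std)
        assert wave[i_min] == pytest.approx(-3.0, abs=3 * se)
        # argmin latency jitter on a Gaussian bump of width w: the noise can
        # shift the minimum to where the bump deficit A*(dt/w)^2/2 matches
        # the noise scale, i.e. dt ~ w*sqrt(2*c*se/A); se = 0.37 µV gives
        # roughly +-12 ms here
        jitter = 25.0 * np.sqrt(2 * 2.0 * se / 3.0)
        assert cor.time_axis[i_min] == pytest.approx(170.0, abs=jitter)

    def test_planted_mmn_latency_precise_at_low_noise(self):
        # with near-noiseless epochs the peak sample is on the grid point
        # closest to the planted latency
        cfg = small_config(
            n_stimuli=400, noise_sd=0.0, sensor_noise_sd=0.05,
            no_consecutive_deviants=False, amplitude_jitter_sd=0.0,
        )
        model = make_linear_model(cfg, 0.9)
        rec = simulate_oddball_recording(
            cfg, model, "S1", seed=9, mmn_amplitude=-3.0, mmn_latency=170.0
        )
        from dnmcrit.preprocess import PreprocessConfig, correct_epochs, extract_epochs

        cor = correct_epochs(extract_epochs(rec, PreprocessConfig()))
        wave = cor.data.mean(axis=0)[list(cfg.dnm_members)[0]]
        assert cor.time_axis[int(np.argmin(wave))] == pytest.approx(170.0, abs=2.0)


class TestGenerateStudy:
    def test_labels_and_counts(self):
        cfg = scaled_config({"HC": 2, "PD": 2}, n_channels=16, n_stimuli=50, seed=1)
        recs = generate_study(cfg)
        assert [r.group for r in recs] == ["HC", "HC", "PD", "PD"]
        assert len({r.subject_id for r in recs}) == 4

    def test_same_seed_reproduces_study(self):
        cfg = scaled_config({"HC": 1, "PD": 1}, n_channels=16, n_stimuli=50, seed=4)
        a = generate_study(cfg)
        b = generate_study(cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.signal, rb.signal)
            assert ra.events == rb.events

    def test_empty_group_spec_rejected(self):
        with pytest.raises(ValueError):
            scaled_config({"HC": 0}, n_channels=16)

    def test_member_fluctuation_higher_in_critical_group(self):
        cfg = scaled_config({"HC": 4, "PD": 4}, n_channels=16, n_stimuli=120, seed=2)
        recs = generate_study(cfg)
        from dnmcrit.dnmnet import node_fluctuation
        from dnmcrit.preprocess import PreprocessConfig, correct_epochs, extract_epochs

        members = list(cfg.dnm_members)
        sds = {"HC": [], "PD": []}
        for rec in recs:
            cor = correct_epochs(extract_epochs(rec, PreprocessConfig()))
            sds[rec.group].append(node_fluctuation(cor)[members].mean())
        assert np.mean(sds["HC"]) > np.mean(sds["PD"])
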