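"""Synthetic two-group EEG generator: determinism, coupling control,
zero-lag leakage contract, noise spectrum, and ground-truth bookkeeping."""

import numpy as np
import pytest

import restsync as rs

from conftest import make_recording

FS = 256.0


def _theta_ciplv_of_sources(signals_pair):
    rec = make_recording(signals_pair)
    pa = rs.analytic_phase(rec, (4.0, 9.0))
    return rs.connectivity_matrix(pa, "ciplv").values[0, 1]


# ---------------------------------------------------------------------------
# simulate_sources
# ---------------------------------------------------------------------------

def test_same_seed_identical_sources():
    cfg = rs.default_study_config(duration_s=6.0)
    a = rs.simulate_sources(cfg, "SCZ", seed=13)
    b = rs.simulate_sources(cfg, "SCZ", seed=13)
    np.testing.assert_array_equal(a.signals, b.signals)


def test_full_strength_coupling_constant_lag():
    cfg = rs.default_study_config(duration_s=20.0)
    cfg = rs.StudyConfig(
        sources=cfg.sources, duration_s=20.0,
        couplings={"SCZ": [rs.CouplingSpec((1, 2), 6.0, np.pi / 2, 1.0)]},
    )
    src = rs.simulate_sources(cfg, "SCZ", seed=3)
    assert _theta_ciplv_of_sources(src.signals[[1, 2]]) > 0.9


def test_zero_strength_coupling_near_uncoupled_baseline():
    cfg0 = rs.default_study_config(duration_s=20.0)
    base_cfg = rs.StudyConfig(sources=cfg0.sources, duration_s=20.0)
    zero_cfg = rs.StudyConfig(
        sources=cfg0.sources, duration_s=20.0,
        couplings={"SCZ": [rs.CouplingSpec((1, 2), 6.0, np.pi / 2, 0.0)]},
    )
    base = np.mean([
        _theta_ciplv_of_sources(rs.simulate_sources(base_cfg, "SCZ", s).signals[[1, 2]])
        for s in range(8)
    ])
    zero = np.mean([
        _theta_ciplv_of_sources(rs.simulate_sources(zero_cfg, "SCZ", s).signals[[1, 2]])
        for s in range(8)
    ])
    assert abs(zero - base) < 0.1


def test_coupling_strength_monotone():
    cfg0 = rs.default_study_config(duration_s=12.0)
    strengths = [0.0, 0.25, 0.5, 0.75, 1.0]
    means = []
    for s in strengths:
        cfg = rs.StudyConfig(
            sources=cfg0.sources, duration_s=12.0,
            couplings={"SCZ": [rs.CouplingSpec((1, 2), 6.0, np.pi / 2, s)]},
        )
        vals = [
            _theta_ciplv_of_sources(rs.simulate_sources(cfg, "SCZ", seed).signals[[1, 2]])
            for seed in range(6)
        ]
        means.append(np.mean(vals))
    assert all(b > a - 0.02 for a, b in zip(means, means[1:]))
    assert means[-1] > means[0] + 0.3


def test_coupling_to_missing_source_is_error():
    cfg0 = rs.default_study_config(duration_s=4.0)
    cfg = rs.StudyConfig(
        sources=cfg0.sources, duration_s=4.0,
        couplings={"SCZ": [rs.CouplingSpec((1, 99), 6.0, 0.5, 0.5)]},
    )
    with pytest.raises(ValueError, match="nonexistent"):
        rs.simulate_sources(cfg, "SCZ", seed=0)


def test_source_centre_frequency_dominates_spectrum():
    cfg = rs.default_study_config(duration_s=30.0)
    src = rs.simulate_sources(cfg, "CON", seed=2)
    ep = rs.segment_epochs(make_recording(src.signals[[0]]), 1.0)
    ps = rs.welch_psd(ep)
    assert abs(ps.freqs[np.argmax(ps.psd[0])] - 6.0) <= 1.0


# ---------------------------------------------------------------------------
# project_to_sensors
# ---------------------------------------------------------------------------

def test_zero_lag_mixture_of_one_source(montage):
    cfg = rs.default_study_config(duration_s=8.0, snr=1e9)  # effectively no noise
    single = rs.StudyConfig(sources=cfg.sources[:1], duration_s=8.0, snr=1e9)
    src = rs.simulate_sources(single, "CON", seed=4)
    rec = rs.project_to_sensors(src, montage, single, seed=5)
    pa = rs.analytic_phase(rec, (4.0, 9.0))
    sub = [montage.index(l) for l in ("CPz", "Pz", "Cz", "CP1")]  # strong gains
    plv = rs.connectivity_matrix(pa, "plv").values[np.ix_(sub, sub)]
    ciplv = rs.connectivity_matrix(pa, "ciplv").values[np.ix_(sub, sub)]
    off = ~np.eye(len(sub), dtype=bool)
    assert plv[off].min() > 0.99
    assert ciplv[off].max() < 0.05


def test_leakage_width_limit_is_near_diagonal(montage):
    pos = montage.positions[:3]
    m = rs.simulate.mixing_matrix(
        rs.Montage(labels=montage.labels[:3], positions=pos), pos, leakage_width=0.01
    )
    np.testing.assert_allclose(m, np.eye(3), atol=1e-10)


def test_noise_only_psd_slope_matches_exponent(montage):
    cfg = rs.StudyConfig(sources=[], duration_s=60.0, noise_exponent=1.0)
    src = rs.SourceSet(signals=np.zeros((0, cfg.n_samples)),
                       source_positions=np.zeros((0, 3)),
                       center_freqs=np.array([]), fs=FS)
    rec = rs.project_to_sensors(src, montage, cfg, seed=8)
    ps = rs.welch_psd(rs.segment_epochs(rec, 1.0))
    sel = (ps.freqs >= 2) & (ps.freqs <= 46)
    logf = np.log(ps.freqs[sel])
    slopes = [np.polyfit(logf, np.log(ps.psd[ch, sel]), 1)[0] for ch in range(0, 64, 16)]
    assert np.allclose(slopes, -1.0, atol=0.25)


def test_projection_deterministic(montage):
    cfg = rs.default_study_config(duration_s=4.0)
    src = rs.simulate_sources(cfg, "CON", seed=1)
    r1 = rs.project_to_sensors(src, montage, cfg, seed=2)
    r2 = rs.project_to_sensors(src, montage, cfg, seed=2)
    np.testing.assert_array_equal(r1.data, r2.data)


# ---------------------------------------------------------------------------
# simulate_group_study + GroundTruth
# ---------------------------------------------------------------------------

def test_group_study_shapes_and_determinism(tiny_study):
    cfg, recordings, truth = tiny_study
    assert len(recordings["SCZ"]) == 3 and len(recordings["CON"]) == 3
    rec = recordings["SCZ"][0]
    assert rec.n_channels == 64
    assert rec.continuous().shape[1] == int(10.0 * FS)
    recordings2, _ = rs.simulate_group_study(cfg)
    np.testing.assert_array_equal(rec.data, recordings2["SCZ"][0].data)


def test_ground_truth_covers_planted_effects(tiny_study):
    _, _, truth = tiny_study
    theta_plus = truth.power_effect.index[truth.power_effect["theta"] > 0]
    assert "CPz" in theta_plus and "Pz" in theta_plus
    primary = [e for e in truth.edge_effect if e["primary"]]
    assert {tuple(sorted(e["channels"])) for e in primary} == {("FT7", "FT8"), ("F3", "P3")}
    assert all(e["sign"] == 1 for e in truth.edge_effect)
    bands = {e["band"] for e in truth.edge_effect}
    assert bands == {"theta", "beta"}


def test_zero_effect_config_empty_ground_truth(montage):
    cfg = rs.StudyConfig(
        sources=rs.default_study_config().sources, duration_s=4.0, n_per_group=(2, 2)
    )
    truth = rs.simulate.build_ground_truth(cfg, montage)
    assert (truth.power_effect.to_numpy() == 0).all()
    assert truth.edge_effect == []


def test_group_sizes_below_two_are_error():
    with pytest.raises(ValueError):
        rs.simulate_group_study(rs.default_study_config(n_per_group=(1, 5), duration_s=4.0))


def test_theta_boost_raises_group_power_at_pz(tiny_study, montage):
    """Group-mean theta relative power at Pz is higher in the boosted group."""
    _, recordings, _ = tiny_study
    scheme = rs.BandScheme.default()

    def theta_rp_at_pz(rec):
        clean, _, _ = rs.preprocess_recording(rec)
        rp = rs.relative_band_power(rs.welch_psd(clean), scheme)
        return rp.values.loc["Pz", "theta"]

    mean_scz = np.mean([theta_rp_at_pz(r) for r in recordings["SCZ"]])
    mean_con = np.mean([theta_rp_at_pz(r) for r in recordings["CON"]])
    assert mean_scz > mean_con
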