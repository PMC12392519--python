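import numpy as np
import pytest

from thetadefeat.connectivity import amplitude_envelope
from thetadefeat.io import average_channels, extract_epochs, write_session
from thetadefeat.simulate import (DEFAULT_BEHAVIOR, Group, GroupPreset,
                                  PRESETS, Phase, SimConfig,
                                  simulate_behavior, simulate_envelope_pair,
                                  simulate_session)
from thetadefeat.spectral import BAND_ORDER, Stage, band_power, dominant_band, stft_psd


class TestSimConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(theta_center_hz=20.0)
        with pytest.raises(ValueError):
            SimConfig(coupling_gain=1.5)
        with pytest.raises(ValueError):
            SimConfig(coupling_lag_s=100.0, duration_s=60.0)

    def test_serialization_round_trip(self):
        cfg = SimConfig(seed=9, coupling_gain=0.3)
        assert SimConfig.from_dict(cfg.to_dict()) == cfg


class TestSimulateSession:
    def test_bit_identical_for_equal_config_and_seed(self, tmp_path):
        cfg = SimConfig(seed=21, duration_s=20.0)
        a = simulate_session(cfg, Group.CON, Phase.WITH_CD1, 0)
        b = simulate_session(cfg, Group.CON, Phase.WITH_CD1, 0)
        for region in a.signals:
            assert np.array_equal(a.signals[region], b.signals[region])
        assert np.array_equal(a.events_s, b.events_s)
        # byte-for-byte after serialization too
        write_session(a, tmp_path / "a")
        write_session(b, tmp_path / "b")
        for name in ("signal.h5", "meta.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_duration_too_short_names_minimum(self):
        with pytest.raises(ValueError, match="minimum is 6"):
            simulate_session(SimConfig(duration_s=5.0), Group.CON, Phase.NO_CD1)

    def test_events_keep_margins_and_gaps(self):
        cfg = SimConfig(seed=2, duration_s=120.0)
        rec = simulate_session(cfg, Group.CON, Phase.NO_CD1, 3)
        ev = rec.events_s
        assert np.all(ev >= 3.0) and np.all(ev <= rec.duration_s - 3.0)
        if ev.size > 1:
            assert np.all(np.diff(ev) >= 6.0)

    def test_theta_is_dominant_band_in_both_regions(self):
        cfg = SimConfig(seed=4, duration_s=600.0, n_channels_per_region=2)
        rec = simulate_session(cfg, Group.CON, Phase.NO_CD1, 0)
        epochs, _ = extract_epochs(rec)
        for region in ("BLA", "vHPC"):
            ep = next(e for e in epochs if e.region == region)
            assert dominant_band(stft_psd(ep)) == "theta"

    def test_group_presets_shift_theta_power(self):
        # susceptible stress raises BLA theta and lowers vHPC theta
        def theta(group, region):
            cfg = SimConfig(seed=8, duration_s=60.0, n_channels_per_region=2)
            out = []
            for i in range(4):
                rec = simulate_session(cfg, group, Phase.WITH_CD1, i)
                eps, _ = extract_epochs(rec)
                out += [band_power(stft_psd(e), "theta", Stage.FULL).value
                        for e in eps if e.region == region]
            return np.mean(out)

        assert theta(Group.RSDS_SUSCEPTIBLE, "BLA") > theta(Group.CON, "BLA")
        assert theta(Group.RSDS_SUSCEPTIBLE, "vHPC") < theta(Group.CON, "vHPC")

    def test_theta_share_monotone_in_amplitude(self):
        shares = []
        for amp in (0.5, 1.0, 2.0):
            cfg = SimConfig(seed=6, duration_s=30.0, theta_amp_bla=amp,
                            n_channels_per_region=1)
            rec = simulate_session(cfg, GroupPreset(Group.CON, {}),
                                   Phase.NO_CD1, 0)
            eps, _ = extract_epochs(rec)
            ep = next(e for e in eps if e.region == "BLA")
            spec = stft_psd(ep)
            profile = spec.power.mean(axis=1)
            theta = (spec.freqs_hz >= 4) & (spec.freqs_hz < 12)
            shares.append(profile[theta].sum() / profile.sum())
        assert shares[0] < shares[1] < shares[2]

    def test_envelope_coupling_lag_ground_truth(self):
        cfg = SimConfig(seed=5, coupling_gain=0.8, coupling_lag_s=0.1,
                        n_channels_per_region=2)
        rec = simulate_session(cfg, GroupPreset(Group.CON, {}), Phase.NO_CD1, 0)
        envs = {r: amplitude_envelope(average_channels(rec.signals[r]), fs=2000.0)
                for r in ("BLA", "vHPC")}
        eb = envs["BLA"] - envs["BLA"].mean()
        ev = envs["vHPC"] - envs["vHPC"].mean()
        lags = np.arange(0, 31)
        cc = [np.corrcoef(eb[:-L] if L else eb, ev[L:] if L else ev)[0, 1]
              for L in lags]
        assert abs(int(lags[np.argmax(cc)]) - 10) <= 1  # 0.1 s at 100 Hz


class TestEnvelopePairGenerator:
    def test_deterministic(self):
        a = simulate_envelope_pair(1000, 0.5, 0.1, seed=3)
        b = simulate_envelope_pair(1000, 0.5, 0.1, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_uncoupled_target_independent(self):
        src, tgt = simulate_envelope_pair(5000, 0.0, 0.1, seed=1)
        r = np.corrcoef(src, tgt)[0, 1]
        assert abs(r) < 0.1

    def test_envelopes_positive(self):
        src, tgt = simulate_envelope_pair(2000, 0.9, 0.2, seed=2)
        assert np.all(src > 0) and np.all(tgt > 0)


class TestGroupPresets:
    def test_stress_and_treatment_directions(self):
        con = PRESETS[Group.CON].overrides
        rsds = PRESETS[Group.RSDS_SUSCEPTIBLE].overrides
        ket = PRESETS[Group.KETAMINE].overrides
        assert rsds["theta_amp_bla"] > con["theta_amp_bla"]
        assert rsds["theta_amp_vhpc"] < con["theta_amp_vhpc"]
        assert rsds["coupling_gain"] < con["coupling_gain"]
        # larger-magnitude post-entry change in stressed animals
        assert (rsds["post_entry_theta_factor"]["WITH_CD1"]
                < con["post_entry_theta_factor"]["WITH_CD1"])
        # ketamine moves every effect strictly back toward control
        for key in ("theta_amp_bla", "theta_amp_vhpc", "coupling_gain"):
            lo, hi = sorted((con[key], rsds[key]))
            assert lo < ket[key] < hi
        lo, hi = sorted((con["post_entry_theta_factor"]["WITH_CD1"],
                         rsds["post_entry_theta_factor"]["WITH_CD1"]))
        assert lo < ket["post_entry_theta_factor"]["WITH_CD1"] < hi


class TestSimulateBehavior:
    def test_same_seed_identical(self):
        a = simulate_behavior(Group.CON, 5)
        b = simulate_behavior(Group.CON, 5)
        assert a == b

    def test_unknown_group_raises(self):
        with pytest.raises(KeyError):
            simulate_behavior(Group.CON, 0, params={})

    def test_defaults_are_reported_group_means(self):
        con = DEFAULT_BEHAVIOR[Group.CON]
        rsds = DEFAULT_BEHAVIOR[Group.RSDS_SUSCEPTIBLE]
        assert con.time_zone_with_cd1_mean_s == pytest.approx(277.3)
        assert rsds.time_zone_with_cd1_mean_s == pytest.approx(91.12)
        assert con.time_zone_no_cd1_mean_s == pytest.approx(195.9)
        assert rsds.time_zone_no_cd1_mean_s == pytest.approx(239.8)
        assert con.tst_immobility_mean_s == pytest.approx(102.2)
        assert rsds.tst_immobility_mean_s == pytest.approx(184.4)
        # SD derived from the printed SEM at n = 8
        assert con.time_zone_with_cd1_sd_s == pytest.approx(31.83 * np.sqrt(8))

    def test_sample_means_match_configured_means(self):
        draws = {k: [] for k in ("time_zone_no_cd1_s", "time_zone_with_cd1_s",
                                 "tst_immobility_s")}
        for i in range(10000):
            beh = simulate_behavior(Group.RSDS_SUSCEPTIBLE, i)
            for k in draws:
                draws[k].append(beh[k])
        p = DEFAULT_BEHAVIOR[Group.RSDS_SUSCEPTIBLE]
        targets = {"time_zone_no_cd1_s": p.time_zone_no_cd1_mean_s,
                   "time_zone_with_cd1_s": p.time_zone_with_cd1_mean_s,
                   "tst_immobility_s": p.tst_immobility_mean_s}
        for k, target in targets.items():
            assert abs(np.mean(draws[k]) / target - 1) < 0.02
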