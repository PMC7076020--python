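import numpy as np
import pandas as pd
import pytest

from mweeg.hfd import HFDParams, higuchi_fd, sliding_hfd
from mweeg.fbm import simulate_fbm
from mweeg.montage import REGIONS, default_region_map, aggregate_by_region
from mweeg.synth import (
    Participant,
    SynthConfig,
    default_hurst_by_cell,
    make_participants,
    null_config,
    simulate_cognitive_profiles,
    simulate_hfd_records,
    simulate_participant_eeg,
    simulate_responses,
    simulate_study,
)


def test_config_validates_probabilities():
    probs = {k: (0.5, 0.5, 0.0, 0.1) for k in
             [("CTRL", "Sync"), ("CTRL", "NoSync"), ("SZQ", "Sync"), ("SZQ", "NoSync")]}
    with pytest.raises(ValueError, match="sum to 1"):
        SynthConfig(answer_probs=probs)


def test_config_validates_hurst():
    table = default_hurst_by_cell()
    table[("CTRL", "Sync", "MW", "F")] = 1.2
    with pytest.raises(ValueError, match="Hurst"):
        SynthConfig(hurst_by_cell=table)


def test_config_yaml_round_trip(tmp_path):
    cfg = SynthConfig(seed=5, n_ctrl=4, n_szq=3, noise_sd=0.01)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    again = SynthConfig.from_yaml(path)
    assert again == cfg


def test_participant_clinical_fields_group_consistency():
    with pytest.raises(ValueError, match="absent"):
        Participant("P01", "CTRL", 30.0, "F", "R", illness_duration=5.0,
                    chlorpromazine_equiv=300.0, antidepressant=False,
                    mood_stabilizer=False)
    with pytest.raises(ValueError, match="required"):
        Participant("P02", "SZQ", 30.0, "F", "R")


def test_make_participants_counts_and_fields(study_cfg):
    parts = make_participants(study_cfg)
    assert sum(p.group == "CTRL" for p in parts) == 23
    assert sum(p.group == "SZQ" for p in parts) == 22
    for p in parts:
        if p.group == "SZQ":
            assert p.chlorpromazine_equiv > 0 and 1 <= p.illness_duration <= 35


def test_responses_reproducible_and_labeled(study_cfg, participants):
    p = participants[0]
    a = simulate_responses(p, study_cfg)
    b = simulate_responses(p, study_cfg)
    assert a == b
    per_video = pd.Series([r.video_idx for r in a]).value_counts()
    assert set(per_video.index) == {0, 1, 2, 3}
    assert per_video.between(4, 5).all()
    syncs = {r.video_idx: r.synchrony for r in a}
    assert syncs == {0: "Sync", 1: "NoSync", 2: "Sync", 3: "NoSync"}


def test_adding_participant_does_not_perturb_others(study_cfg):
    cfg_small = SynthConfig(n_ctrl=2, n_szq=1, seed=study_cfg.seed)
    cfg_big = SynthConfig(n_ctrl=2, n_szq=2, seed=study_cfg.seed)
    small = {p.id: simulate_responses(p, cfg_small) for p in make_participants(cfg_small)}
    big = {p.id: simulate_responses(p, cfg_big) for p in make_participants(cfg_big)}
    for pid, resp in small.items():
        assert big[pid] == resp


def test_degenerate_probs_all_mw():
    cfg = null_config()
    probs = {k: (0.0, 0.0, 0.0, 1.0) for k in cfg.answer_probs}
    cfg = SynthConfig(hurst_by_cell=cfg.hurst_by_cell, answer_probs=probs)
    p = make_participants(cfg)[0]
    resp = simulate_responses(p, cfg)
    assert all(r.answer == "MW" for r in resp)


def test_zero_length_video_no_probes():
    cfg = SynthConfig(video_length_s=0.0)
    p = make_participants(cfg)[0]
    assert simulate_responses(p, cfg) == []


def test_eeg_segment_shapes_and_labels(small_eeg_cfg):
    p = make_participants(small_eeg_cfg)[0]
    resp = simulate_responses(p, small_eeg_cfg)
    segs = simulate_participant_eeg(p, small_eeg_cfg, resp)
    assert len(segs) == len(resp)
    n = int(small_eeg_cfg.segment_length * small_eeg_cfg.sfreq)
    for seg, r in zip(segs, resp):
        assert seg.data.shape == (31, n)
        assert (seg.answer, seg.synchrony) == (r.answer, r.synchrony)
    # label bookkeeping: segment counts match response counts per cell
    seg_counts = pd.Series([(s.answer, s.synchrony) for s in segs]).value_counts()
    resp_counts = pd.Series([(r.answer, r.synchrony) for r in resp]).value_counts()
    assert seg_counts.equals(resp_counts)


def test_eeg_reproducible(small_eeg_cfg):
    p = make_participants(small_eeg_cfg)[0]
    resp = simulate_responses(p, small_eeg_cfg)[:2]
    a = simulate_participant_eeg(p, small_eeg_cfg, resp)
    b = simulate_participant_eeg(p, small_eeg_cfg, resp)
    for s1, s2 in zip(a, b):
        np.testing.assert_array_equal(s1.data, s2.data)


def test_no_responses_no_segments(small_eeg_cfg):
    p = make_participants(small_eeg_cfg)[0]
    assert simulate_participant_eeg(p, small_eeg_cfg, []) == []


def test_mw_complexity_elevation_end_to_end(small_eeg_cfg):
    """Lower Hurst for MW propagates to higher mean HFD through the estimator."""
    table = default_hurst_by_cell(mw_gap=0.0)
    for area in REGIONS:
        table[("CTRL", "Sync", "MW", area)] = 0.35
        table[("CTRL", "Sync", "Full", area)] = 0.65
    cfg = SynthConfig(n_ctrl=1, n_szq=1, sfreq=small_eeg_cfg.sfreq,
                      segment_length=small_eeg_cfg.segment_length,
                      hurst_by_cell=table, seed=1)
    p = make_participants(cfg)[0]
    from mweeg.preprocess import ProbeResponse
    resp = [ProbeResponse(p.id, 0, 60.0, "Sync", a) for a in ("MW", "Full") for _ in range(2)]
    segs = simulate_participant_eeg(p, cfg, resp)
    params = HFDParams()
    means = {}
    for answer in ("MW", "Full"):
        vals = [sliding_hfd(s.data, s.sfreq, params).mean()
                for s in segs if s.answer == answer]
        means[answer] = np.mean(vals)
    assert means["MW"] > means["Full"] + 0.1


def test_fractal_ground_truth_monotone_through_pipeline():
    """Across H in {0.2, 0.5, 0.8}, estimated HFD strictly decreases (20 reps)."""
    means = []
    for h in (0.2, 0.5, 0.8):
        vals = [higuchi_fd(simulate_fbm(25000, h, seed=s), 10) for s in range(20)]
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]


def test_profiles_structure(study_cfg, participants):
    prof = simulate_cognitive_profiles(participants, study_cfg)
    assert len(prof) == 45
    szq = prof[prof["group"] == "SZQ"]
    ctrl = prof[prof["group"] == "CTRL"]
    assert szq["PANSS_positive"].notna().all()
    assert ctrl["PANSS_positive"].isna().all()
    assert (prof["D2_TH"] <= prof["D2_TR"]).all()
    assert (prof["D2_TRminus"] <= prof["D2_TRplus"]).all()


def test_panss_positive_calibration():
    """PANSS positive drawn at M=14, SD=6.08: mean within 3 SE at n=1000."""
    cfg = SynthConfig(n_ctrl=0, n_szq=1000, seed=9)
    prof = simulate_cognitive_profiles(make_participants(cfg), cfg)
    x = prof["PANSS_positive"]
    se = 6.08 / np.sqrt(len(x))
    assert abs(x.mean() - 14.0) < 3 * se


def test_profiles_reproducible(study_cfg, participants):
    a = simulate_cognitive_profiles(participants, study_cfg)
    b = simulate_cognitive_profiles(participants, study_cfg)
    pd.testing.assert_frame_equal(a, b)


def test_hfd_records_mean_structure(study_cfg, participants):
    """Record means track 2 - H per cell within a few SE."""
    rec = simulate_hfd_records(participants, study_cfg)
    cell = rec[(rec.group == "CTRL") & (rec.synchrony == "Sync")
               & (rec.answer == "Full") & (rec.area == "F")]["hfd"]
    h = study_cfg.hurst_by_cell[("CTRL", "Sync", "Full", "F")]
    tol = 4 * np.sqrt(study_cfg.hfd_participant_sd**2 + study_cfg.hfd_noise_sd**2) / np.sqrt(len(cell))
    assert cell.mean() == pytest.approx(2.0 - h, abs=5 * tol)


def test_simulate_study_bitwise_reproducible(tmp_path):
    cfg = SynthConfig(n_ctrl=3, n_szq=3, seed=21)
    _, resp_a, prof_a, _ = simulate_study(cfg)
    _, resp_b, prof_b, _ = simulate_study(cfg)
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    resp_a.to_csv(a, index=False)
    resp_b.to_csv(b, index=False)
    assert a.read_bytes() == b.read_bytes()
    pd.testing.assert_frame_equal(prof_a, prof_b)
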