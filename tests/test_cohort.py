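"""Synthetic cohort generator: determinism, label coverage, class-energy
ordering, GMFCS heterogeneity structure, and the free-living sequence."""

import numpy as np
import pytest
from scipy import stats

from cpactivity import (attach_labels, make_cohort, simulate_free_living,
                        simulate_structured_protocol, simulate_trial,
                        window_signal)
from cpactivity.cohort import (DEFAULT_LEVEL_PARAMS, PLACEMENTS, CohortError,
                               LabelTrack)
from cpactivity.features import extract_window_features


def test_cohort_composition_matches_requested_counts():
    profiles = make_cohort({"I": 10, "II": 20, "III": 8}, master_seed=3)
    assert len(profiles) == 38
    counts = {lvl: sum(p.gmfcs_level == lvl for p in profiles)
              for lvl in ("I", "II", "III")}
    assert counts == {"I": 10, "II": 20, "III": 8}
    assert len({p.subject_id for p in profiles}) == 38


def test_cohort_is_deterministic_and_seed_sensitive():
    a = make_cohort({"I": 1, "II": 1, "III": 1}, master_seed=5)
    b = make_cohort({"I": 1, "II": 1, "III": 1}, master_seed=5)
    c = make_cohort({"I": 1, "II": 1, "III": 1}, master_seed=6)
    assert a == b
    assert any(x.step_frequency != y.step_frequency or
               x.sed_noise_scale != y.sed_noise_scale
               for x, y in zip(a, c))


def test_cohort_rejects_non_positive_counts():
    with pytest.raises(CohortError):
        make_cohort({"I": 0, "II": 1, "III": 1}, master_seed=1)


def test_impairment_gradient_across_levels():
    """Amplitude decreases and gait irregularity increases with GMFCS level."""
    profiles = make_cohort({"I": 12, "II": 12, "III": 12}, master_seed=9)
    by = {lvl: [p for p in profiles if p.gmfcs_level == lvl]
          for lvl in ("I", "III")}
    amp = {lvl: np.mean([p.step_amplitude for p in ps])
           for lvl, ps in by.items()}
    irr = {lvl: np.mean([p.gait_irregularity for p in ps])
           for lvl, ps in by.items()}
    assert amp["I"] > amp["III"]
    assert irr["III"] > irr["I"]


def test_trial_length_and_determinism(level1_profile):
    rec, track = simulate_trial(level1_profile, "ankle", "WALK", 360, seed=7)
    assert rec.n_samples == 10_800
    assert track.intervals == ((0.0, 360.0, "WALK"),)
    rec2, _ = simulate_trial(level1_profile, "ankle", "WALK", 360, seed=7)
    np.testing.assert_array_equal(rec.samples, rec2.samples)


def test_trial_rejects_sub_window_duration(level1_profile):
    with pytest.raises(CohortError):
        simulate_trial(level1_profile, "hip", "SED", 5, seed=1)


def test_sed_quieter_than_walk_on_every_axis(level1_profile):
    sed, _ = simulate_trial(level1_profile, "ankle", "SED", 60, seed=4)
    walk, _ = simulate_trial(level1_profile, "ankle", "WALK", 60, seed=4)
    assert (sed.samples.var(axis=0) < walk.samples.var(axis=0)).all()


def test_walk_dominant_frequency_tracks_step_frequency(level1_profile):
    rec, track = simulate_trial(level1_profile, "ankle", "WALK", 120, seed=21)
    labels = attach_labels(rec, track)
    wins = window_signal(rec, labels)
    domfreqs = [extract_window_features(w)["ankle_y_domfreq"] for w in wins]
    assert abs(np.median(domfreqs) - level1_profile.step_frequency) <= 0.2


def test_class_energy_ordering_within_subject(tiny_cohort):
    """Mean vector-magnitude variance: SED < SUM < WALK for every subject
    and placement, over 36 windows per class."""
    for prof in tiny_cohort:
        for placement in PLACEMENTS:
            means = {}
            for cls in ("SED", "SUM", "WALK"):
                rec, track = simulate_trial(prof, placement, cls, 360,
                                            seed=prof.rng_seed)
                vm = np.sqrt((rec.samples ** 2).sum(axis=1))
                win = vm.reshape(36, 300)
                means[cls] = win.var(axis=1).mean()
            assert means["SED"] < means["SUM"] < means["WALK"], \
                (prof.subject_id, placement)


def test_placements_share_event_timeline(level1_profile):
    """Same seed, different placements: identical label track and matching
    dominant frequency (shared gait events), different noise."""
    recs = {p: simulate_trial(level1_profile, p, "WALK", 60, seed=77)
            for p in PLACEMENTS}
    tracks = {p: t for p, (_, t) in recs.items()}
    assert tracks["wrist"] == tracks["ankle"] == tracks["hip"]
    feats = {}
    for p, (rec, track) in recs.items():
        wins = window_signal(rec, attach_labels(rec, track))
        feats[p] = extract_window_features(wins[0])[f"{p}_y_domfreq"]
    assert feats["ankle"] == feats["hip"]
    assert not np.array_equal(recs["ankle"][0].samples,
                              recs["hip"][0].samples)


def test_structured_protocols_have_expected_class_multisets(level1_profile):
    for pid, expected in ((1, {"SED": 2, "SUM": 1, "WALK": 2}),
                          (2, {"SED": 1, "SUM": 2, "WALK": 2})):
        trials = simulate_structured_protocol(level1_profile, protocol_id=pid,
                                              seed=31, trial_duration_s=30)
        for placement, items in trials.items():
            classes = [t.classes()[0] for _, _, t in items]
            assert {c: classes.count(c) for c in set(classes)} == expected
            assert sum(t.total_duration for _, _, t in items) == 5 * 30


def test_brisk_walk_is_faster_than_comfortable(level1_profile):
    trials = simulate_structured_protocol(level1_profile, protocol_id=1,
                                          seed=13, trial_duration_s=60)
    by_name = {name: rec for name, rec, _ in trials["ankle"]}
    freqs = {}
    for name in ("comfortable_walk", "brisk_walk"):
        rec = by_name[name]
        wins = window_signal(rec, attach_labels(
            rec, LabelTrack(((0.0, 60.0, "WALK"),))))
        freqs[name] = np.median([
            extract_window_features(w)["ankle_y_domfreq"] for w in wins])
    assert freqs["brisk_walk"] > freqs["comfortable_walk"]


def test_free_living_duration_and_sequence(level1_profile):
    recs, track = simulate_free_living(level1_profile, seed=19)
    for rec in recs.values():
        assert rec.n_samples == 10_800
    starts = [s for s, _, _ in track.intervals]
    assert starts[0] == 0.0
    assert track.intervals[-1][1] == 360.0
    pattern = ("SED", "WALK", "SUM", "WALK")
    for i, cls in enumerate(track.classes()):
        assert cls == pattern[i % 4]


def test_every_sample_covered_by_exactly_one_interval(level1_profile):
    recs, track = simulate_free_living(level1_profile, seed=23)
    labels = attach_labels(recs["hip"], track)
    assert (labels >= 0).all()


def test_zero_domain_shift_matches_structured_distributions(level1_profile):
    """With no domain shift, free-living per-class window variances are
    statistically indistinguishable from structured-trial output."""
    recs, track = simulate_free_living(level1_profile, seed=29,
                                       domain_shift=0.0)
    labels = attach_labels(recs["ankle"], track)
    # only homogeneous windows: transitions are a separate phenomenon
    wins = window_signal(recs["ankle"], labels, policy="drop")

    def win_vars(windows, cls):
        return [np.sqrt((w.samples ** 2).sum(axis=1)).var()
                for w in windows if w.label == cls]

    trial, ttrack = simulate_trial(level1_profile, "ankle", "SED", 300,
                                   seed=41, posture="sitting")
    twins = window_signal(trial, attach_labels(trial, ttrack))
    fl_sed = win_vars(wins, "SED")[:30]
    lab_sed = win_vars(twins, "SED")[:30]
    assert len(fl_sed) >= 5
    _, p = stats.ranksums(fl_sed, lab_sed)
    assert p > 0.01


def test_default_domain_shift_raises_sed_movement(level1_profile):
    recs0, track0 = simulate_free_living(level1_profile, seed=37,
                                         domain_shift=0.0)
    recs1, track1 = simulate_free_living(level1_profile, seed=37,
                                         domain_shift=0.75)

    def sed_var(recs, track):
        labels = attach_labels(recs["wrist"], track)
        wins = window_signal(recs["wrist"], labels, policy="drop")
        return np.mean([w.samples.var(axis=0).sum()
                        for w in wins if w.label == "SED"])

    assert sed_var(recs1, track1) > 2 * sed_var(recs0, track0)


def test_heterogeneity_knob_widens_between_subject_spread():
    """Larger dispersion strictly increases the between-subject variance of
    the per-subject walking dominant frequency."""
    spread = {}
    for h in (0.5, 1.5):
        profiles = make_cohort({"I": 4, "II": 4, "III": 4}, master_seed=55,
                               heterogeneity=h)
        means = []
        for prof in profiles:
            rec, track = simulate_trial(prof, "ankle", "WALK", 30,
                                        seed=prof.rng_seed)
            wins = window_signal(rec, attach_labels(rec, track))
            means.append(np.mean([
                extract_window_features(w)["ankle_y_domfreq"] for w in wins]))
        spread[h] = np.var(means)
    assert spread[1.5] > spread[0.5]


def test_label_track_validation():
    with pytest.raises(CohortError):
        LabelTrack(((0.0, 10.0, "SED"), (5.0, 15.0, "WALK")))
    with pytest.raises(CohortError):
        LabelTrack(((0.0, 0.0, "SED"),))
    with pytest.raises(CohortError):
        LabelTrack(((0.0, 5.0, "JOG"),))
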