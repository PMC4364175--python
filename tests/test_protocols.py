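"""Stimulus coding, trial mechanics and schedule construction."""

import numpy as np
import pytest

from amygsim import (AChState, NetworkParams, StimulusSpec, TrialSpec,
                     build_network, build_schedule, make_input_vector,
                     run_trial)
from amygsim.protocols import (load_schedule, save_schedule,
                               schedule_from_frame, schedule_to_frame)


class TestInputVectors:
    def test_cortex_salient_unit(self, params, rng):
        v = make_input_vector(StimulusSpec("Cortex", 0), params, rng)
        assert v[0] == pytest.approx(1.5)
        assert np.all((v[1:] >= 0) & (v[1:] <= 0.1))

    def test_hippo_salient_unit(self, params, rng):
        v = make_input_vector(StimulusSpec("Hippo", 3), params, rng)
        assert v[3] == pytest.approx(1.0)

    def test_absent_stimulus_is_background(self, params, rng):
        v = make_input_vector(StimulusSpec("Cortex", None), params, rng)
        assert np.all((v >= 0) & (v <= 0.1))

    def test_salience_multiplier(self, params, rng):
        v = make_input_vector(
            StimulusSpec("Cortex", 2, salience_multiplier=0.5), params, rng)
        assert v[2] == pytest.approx(0.75)

    def test_out_of_range_index(self, params, rng):
        with pytest.raises(ValueError):
            make_input_vector(StimulusSpec("Cortex", 10), params, rng)

    def test_bad_multiplier_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec("Cortex", 0, salience_multiplier=1.5)


class TestRunTrial:
    def test_probe_trial_freezes_everything(self, params):
        net = build_network(params, np.random.default_rng(0))
        before = {p.name: p.W.copy() for p in net.plastic_projections}
        trial = TrialSpec(stimuli=(StimulusSpec("Cortex", 0),), US=0.0,
                          learning=False, label="probe")
        ach0 = AChState(V_ach=0.2, level=1.4)
        rec, ach = run_trial(net, ach0, trial, np.random.default_rng(1))
        for proj in net.plastic_projections:
            np.testing.assert_array_equal(proj.W, before[proj.name])
        assert ach.V_ach == ach0.V_ach

    def test_learning_trial_updates_once(self, params):
        net = build_network(params, np.random.default_rng(0))
        before = {p.name: float(np.mean(p.W)) for p in net.plastic_projections}
        trial = TrialSpec(stimuli=(StimulusSpec("Cortex", 0),
                                   StimulusSpec("Hippo", 0)),
                          US=1.0, learning=True, label="conditioning")
        rec, ach = run_trial(net, AChState(), trial, np.random.default_rng(1))
        # with US=1 and low prediction, both fear pathways must have moved
        assert rec.mean_W["Cortex->LA"] > before["Cortex->LA"]
        assert rec.mean_W["Hippo->BAf"] > before["Hippo->BAf"]
        assert ach.V_ach > 0

    def test_determinism(self, params):
        frames = []
        for _ in range(2):
            net = build_network(params, np.random.default_rng(5))
            trial = TrialSpec(stimuli=(StimulusSpec("Cortex", 1),), US=1.0)
            rec, _ = run_trial(net, AChState(), trial,
                               np.random.default_rng(5))
            frames.append(rec)
        assert frames[0].prediction == frames[1].prediction
        assert frames[0].mean_U == frames[1].mean_U

    def test_baseline_trial_prediction_near_rest(self, params):
        net = build_network(params, np.random.default_rng(0))
        trial = TrialSpec(stimuli=(), US=0.0, learning=False, label="baseline")
        rec, _ = run_trial(net, AChState(), trial, np.random.default_rng(2))
        assert 0.0 <= rec.prediction < 0.5


class TestSchedules:
    def test_extinction_renewal_layout(self):
        sched = build_schedule("extinction_renewal")
        assert len(sched) == 22
        assert sched[0].label == "baseline"
        assert all(t.US == 1.0 for t in sched[1:10])
        il_on = [t.stimulus("IL") is not None for t in sched]
        assert il_on == [False] * 10 + [True] * 11 + [False]
        assert sched[-1].label == "renewal" and not sched[-1].learning

    def test_standalone_counts(self):
        sched = build_schedule("extinction_renewal", n_conditioning=11,
                               n_extinction=14, baseline=False)
        labels = [t.label for t in sched]
        assert labels.count("conditioning") == 11
        assert labels.count("extinction") == 14

    def test_unpairing_multipliers(self):
        sched = build_schedule("unpairing", rng=np.random.default_rng(0))
        mults = [t.stimulus("Cortex").salience_multiplier
                 for t in sched if t.label == "conditioning"]
        assert len(mults) == 11
        assert all(0.0 <= m <= 1.0 for m in mults)
        assert len(set(mults)) > 1  # actually random

    def test_high_ach_clamp(self):
        sched = build_schedule("pairing_high_ach")
        assert all(t.ach_clamp == 3.0 for t in sched if t.learning)

    def test_depletion_last_trial(self):
        sched = build_schedule("ach_depletion_last_trial")
        last = sched[-1]
        assert last.ach_clamp == 0.5 and not last.learning
        assert last.stimulus("IL") is not None  # extinction context test

    def test_unknown_paradigm(self):
        with pytest.raises(ValueError):
            build_schedule("inflation")

    def test_csv_round_trip(self, tmp_path):
        sched = build_schedule("unpairing", rng=np.random.default_rng(3))
        path = tmp_path / "schedule.csv"
        save_schedule(sched, path)
        back = load_schedule(path)
        assert len(back) == len(sched)
        for a, b in zip(sched, back):
            assert a.US == b.US and a.learning == b.learning
            assert a.ach_clamp == b.ach_clamp
            sa, sb = a.stimulus("Cortex"), b.stimulus("Cortex")
            if sa is None:
                assert sb is None
            else:
                assert sa.salient_index == sb.salient_index
                assert sa.salience_multiplier == pytest.approx(
                    sb.salience_multiplier)
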