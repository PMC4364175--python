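"""Stimulus coding, three-phase trials, and declarative paradigm schedules.

A behavioural episode (trial) has three phases of ``cycles_per_phase``
Euler steps each:

1. the stimulus phase — Cortex/Hippo/IL input vectors are clamped and the
   network settles; the CeLOn rate at the end of this phase is the
   network's US prediction;
2. the US phase — at its very start the prediction error is computed and,
   on learning trials, the plastic weights and the ACh level are updated;
   stimuli stay on;
3. the rest phase — all inputs are zeroed and activity returns to baseline.

An input vector has one strongly activated (salient) unit — 1.5 for the
sensory cue in Cortex, 1.0 for contexts in Hippo and the extinction signal
in IL — over a background of small values drawn uniformly on
``[0, 1/size]``.  Background is redrawn for every trial and frozen within
the trial.  Whether IL is salient is a protocol flag: the schedule turns it
on for extinction-context trials (how a real IL would detect such a context
is outside the model).

Paradigms are expressed as lists of :class:`TrialSpec` built by
:func:`build_schedule`, serialisable to/from CSV one trial per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Network
from .neuromodulation import AChState, update_ach
from .params import NetworkParams
from .plasticity import compute_error, extinction_update, fear_update

__all__ = [
    "StimulusSpec", "TrialSpec", "TrialRecord",
    "make_input_vector", "run_trial", "build_schedule",
    "schedule_to_frame", "schedule_from_frame",
    "save_schedule", "load_schedule", "PARADIGMS",
]

_DEFAULT_SALIENCE = {"Cortex": "cortex_salience",
                     "Hippo": "hippo_salience",
                     "IL": "il_salience"}


@dataclass(frozen=True)
class StimulusSpec:
    """One input channel's configuration for a trial.

    ``salient_index=None`` means the stimulus is absent: the vector is pure
    background.  ``salience_multiplier`` scales the salient unit (used to
    degrade cue reliability in the unpairing experiment).
    """

    channel: str                      # "Cortex" | "Hippo" | "IL"
    salient_index: Optional[int] = None
    salience: Optional[float] = None  # None -> channel default from params
    salience_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.channel not in _DEFAULT_SALIENCE:
            raise ValueError(f"unknown input channel {self.channel!r}")
        if not 0.0 <= self.salience_multiplier <= 1.0:
            raise ValueError("salience_multiplier must lie in [0, 1]")


@dataclass(frozen=True)
class TrialSpec:
    """Stimulus configuration, US value and modulatory state for one trial."""

    stimuli: Tuple[StimulusSpec, ...] = ()
    US: float = 0.0
    ach_clamp: Optional[float] = None
    learning: bool = True
    label: str = ""

    def stimulus(self, channel: str) -> Optional[StimulusSpec]:
        for s in self.stimuli:
            if s.channel == channel:
                return s
        return None


@dataclass
class TrialRecord:
    """Per-trial observables, sampled at the moment of US arrival."""

    trial: int
    label: str
    US: float
    learning: bool
    mean_U: Dict[str, float]
    prediction: float
    ERR: float
    ach_level: float
    ach_v: float
    ach_clamped: bool
    mean_W: Dict[str, float]
    norm_W: Dict[str, float] = field(default_factory=dict)


def make_input_vector(spec: Optional[StimulusSpec], params: NetworkParams,
                      rng: np.random.Generator,
                      channel: Optional[str] = None) -> np.ndarray:
    """Build one input vector: salient unit over uniform background.

    Background entries are uniform on ``[0, 1/size]``; the salient entry is
    ``salience * salience_multiplier``.  ``spec=None`` (with ``channel``
    given) yields a background-only vector.
    """
    size = params.input_size
    v = rng.uniform(0.0, 1.0 / size, size=size)
    if spec is None:
        return v
    if spec.salient_index is not None:
        if not 0 <= spec.salient_index < size:
            raise ValueError(
                f"salient_index {spec.salient_index} out of range for size {size}")
        salience = spec.salience
        if salience is None:
            salience = getattr(params, _DEFAULT_SALIENCE[spec.channel])
        v[spec.salient_index] = salience * spec.salience_multiplier
    return v


def run_trial(network: Network, ach: AChState, trial: TrialSpec,
              rng: np.random.Generator,
              trial_index: int = 0) -> Tuple[TrialRecord, AChState]:
    """Simulate one three-phase trial; returns its record and the new ACh state.

    Weights and the ACh trace are updated once, at the start of phase 2, and
    only on learning trials.  Probe/test trials (``learning=False``) leave
    every weight and the modulatory state untouched.
    """
    p = network.params
    ach = ach.with_clamp(trial.ach_clamp)

    inputs = {ch: make_input_vector(trial.stimulus(ch), p, rng, channel=ch)
              for ch in ("Cortex", "Hippo", "IL")}

    # phase 1: stimulus on, settle; read the prediction at US arrival
    network.run_phase(inputs, p.cycles_per_phase, rng, ach.level)
    prediction = float(np.mean(network.rates("CeLOn")))
    mean_U = {name: float(np.mean(network.rates(name)))
              for name in network.pops}
    err = compute_error(trial.US, prediction)

    # phase 2 start: single plasticity + neuromodulation update
    if trial.learning:
        pr = network.projections
        pre_rates = {"Cortex->LA": inputs["Cortex"],
                     "Hippo->BAf": inputs["Hippo"],
                     "LA->BAf": network.rates("LA")}
        for name, pre in pre_rates.items():
            proj = pr[name]
            if proj.plastic and proj.rule == "fear":
                fear_update(proj, err, p.alpha, pre,
                            network.rates(proj.post), p.w_max_clip)
        il = pr["IL->BAe"]
        if il.plastic and il.rule == "extinction":
            extinction_update(il, err, p.alpha,
                              network.rates("BAe"), inputs["IL"], p.w_max_clip)
        ach = update_ach(ach, err, p, rng)

    # phase 2: stimuli held while the US is delivered
    network.run_phase(inputs, p.cycles_per_phase, rng, ach.level)
    # phase 3: inputs off, return toward rest
    zeros = {ch: np.zeros(p.input_size) for ch in ("Cortex", "Hippo", "IL")}
    network.run_phase(zeros, p.cycles_per_phase, rng, ach.level)

    mean_W = {proj.name: float(np.mean(proj.W))
              for proj in network.plastic_projections}
    record = TrialRecord(
        trial=trial_index, label=trial.label, US=trial.US,
        learning=trial.learning, mean_U=mean_U, prediction=prediction,
        ERR=err.ERR, ach_level=ach.level, ach_v=ach.V_ach,
        ach_clamped=trial.ach_clamp is not None, mean_W=mean_W)
    return record, ach


# ---------------------------------------------------------------------------
# schedules

PARADIGMS = (
    "extinction_renewal",
    "extinction_renewal_ach_depleted",
    "ach_depletion_last_trial",
    "pairing",
    "pairing_high_ach",
    "unpairing",
    "unpairing_ach_depleted",
)


def _cond_trial(cs_mult: float = 1.0, cs_index: int = 0, ctx_index: int = 0,
                ach_clamp: Optional[float] = None, label: str = "conditioning"
                ) -> TrialSpec:
    return TrialSpec(
        stimuli=(StimulusSpec("Cortex", cs_index, salience_multiplier=cs_mult),
                 StimulusSpec("Hippo", ctx_index)),
        US=1.0, ach_clamp=ach_clamp, learning=True, label=label)


def build_schedule(paradigm: str,
                   n_conditioning: Optional[int] = None,
                   n_extinction: Optional[int] = None,
                   baseline: Optional[bool] = None,
                   cs_index: int = 0, ctx1_index: int = 0, ctx2_index: int = 1,
                   il_index: int = 0,
                   rng: np.random.Generator | int | None = None
                   ) -> List[TrialSpec]:
    """Return the trial list of a named paradigm.

    ``extinction_renewal`` defaults to the 22-trial layout (1 baseline
    trial, conditioning trials 2–10, extinction trials 11–21, renewal probe
    at trial 22); pass ``n_conditioning=11, n_extinction=14,
    baseline=False`` for the standalone acquisition/extinction counts.
    Pairing/unpairing paradigms run a baseline trial, 11 conditioning
    trials and two probes (cue only, context only); the unpairing variants
    draw each conditioning trial's cue salience multiplier uniformly on
    [0, 1] from ``rng``.  ``*_ach_depleted`` / ``*_high_ach`` variants clamp
    the tonic ACh level at 0.5 / 3.0 on the stated trials.
    """
    if paradigm not in PARADIGMS:
        raise ValueError(f"unknown paradigm {paradigm!r}; choose from {PARADIGMS}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    if paradigm in ("extinction_renewal", "extinction_renewal_ach_depleted",
                    "ach_depletion_last_trial"):
        base = True if baseline is None else baseline
        n_cond = (9 if base else 11) if n_conditioning is None else n_conditioning
        n_ext = (11 if base else 14) if n_extinction is None else n_extinction
        ext_clamp = 0.5 if paradigm == "extinction_renewal_ach_depleted" else None

        trials: List[TrialSpec] = []
        if base:
            trials.append(TrialSpec(stimuli=(), US=0.0, learning=False,
                                    label="baseline"))
        trials += [_cond_trial(cs_index=cs_index, ctx_index=ctx1_index)
                   for _ in range(n_cond)]
        trials += [TrialSpec(
            stimuli=(StimulusSpec("Cortex", cs_index),
                     StimulusSpec("Hippo", ctx2_index),
                     StimulusSpec("IL", il_index)),
            US=0.0, ach_clamp=ext_clamp, learning=True, label="extinction")
            for _ in range(n_ext)]
        if paradigm == "ach_depletion_last_trial":
            # post-extinction test in the extinction context, ACh depleted
            trials.append(TrialSpec(
                stimuli=(StimulusSpec("Cortex", cs_index),
                         StimulusSpec("Hippo", ctx2_index),
                         StimulusSpec("IL", il_index)),
                US=0.0, ach_clamp=0.5, learning=False, label="depleted_test"))
        else:
            trials.append(TrialSpec(
                stimuli=(StimulusSpec("Cortex", cs_index),
                         StimulusSpec("Hippo", ctx1_index)),
                US=0.0, ach_clamp=ext_clamp, learning=False, label="renewal"))
        return trials

    # pairing / unpairing family
    n_cond = 11 if n_conditioning is None else n_conditioning
    clamp = {"pairing": None, "pairing_high_ach": 3.0,
             "unpairing": None, "unpairing_ach_depleted": 0.5}[paradigm]
    unpaired = paradigm.startswith("unpairing")

    trials = [TrialSpec(stimuli=(), US=0.0, ach_clamp=clamp, learning=False,
                        label="baseline")]
    for _ in range(n_cond):
        mult = float(rng.uniform(0.0, 1.0)) if unpaired else 1.0
        trials.append(_cond_trial(cs_mult=mult, cs_index=cs_index,
                                  ctx_index=ctx1_index, ach_clamp=clamp))
    trials.append(TrialSpec(
        stimuli=(StimulusSpec("Cortex", cs_index),),
        US=0.0, ach_clamp=clamp, learning=False, label="probe_cs"))
    trials.append(TrialSpec(
        stimuli=(StimulusSpec("Hippo", ctx1_index),),
        US=0.0, ach_clamp=clamp, learning=False, label="probe_ctx"))
    return trials


# ---------------------------------------------------------------------------
# plain-text round trip

_CHANNELS = ("Cortex", "Hippo", "IL")


def schedule_to_frame(schedule: Sequence[TrialSpec]) -> pd.DataFrame:
    rows = []
    for i, t in enumerate(schedule, start=1):
        row: Dict[str, object] = {"trial": i, "label": t.label, "US": t.US,
                                  "ach_clamp": t.ach_clamp,
                                  "learning": t.learning}
        for ch in _CHANNELS:
            s = t.stimulus(ch)
            row[f"{ch}_index"] = None if s is None else s.salient_index
            row[f"{ch}_multiplier"] = None if s is None else s.salience_multiplier
        rows.append(row)
    return pd.DataFrame(rows)


def schedule_from_frame(frame: pd.DataFrame) -> List[TrialSpec]:
    schedule = []
    for _, row in frame.iterrows():
        stimuli = []
        for ch in _CHANNELS:
            idx = row.get(f"{ch}_index")
            if idx is not None and not pd.isna(idx):
                mult = row.get(f"{ch}_multiplier", 1.0)
                mult = 1.0 if pd.isna(mult) else float(mult)
                stimuli.append(StimulusSpec(ch, int(idx),
                                            salience_multiplier=mult))
        clamp = row.get("ach_clamp")
        clamp = None if clamp is None or pd.isna(clamp) else float(clamp)
        schedule.append(TrialSpec(
            stimuli=tuple(stimuli), US=float(row["US"]), ach_clamp=clamp,
            learning=bool(row["learning"]), label=str(row.get("label", ""))))
    return schedule


def save_schedule(schedule: Sequence[TrialSpec], path: str | Path) -> None:
    schedule_to_frame(schedule).to_csv(path, index=False)


def load_schedule(path: str | Path) -> List[TrialSpec]:
    return schedule_from_frame(pd.read_csv(path))
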