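"""Tonic acetylcholine as an expected-uncertainty signal.

A scalar trace ``V_ach`` low-pass filters the unsigned prediction error,
one update per trial:

    V_ach <- V_ach + (-V_ach + F(|ERR|)) / tau_ach

with the same threshold function ``F`` as the rate dynamics and a time
constant of ``tau_ach`` trials.  The broadcast tonic level is

    ACh = ach_strength * (baseline + ach_uncertainty_strength
                          * noise(sigmoid(V_ach)))

clipped to ``[ACh_min, ACh_max]`` when free-running.  Experimental clamps
(depletion to 0.5, elevation to 3.0) override the level entirely and bypass
the clip.  The level multiplies BAf and BAe firing rates — high uncertainty
biases the competition toward context-driven basal populations, low
uncertainty toward the cue-driven LA pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .core import threshold_F
from .params import NetworkParams
from .plasticity import PredictionError

__all__ = ["AChState", "update_ach", "apply_ach_gain"]


@dataclass(frozen=True)
class AChState:
    """Filtered uncertainty trace and current tonic ACh level."""

    V_ach: float = 0.0
    level: float = 1.0
    clamp: Optional[float] = None

    def with_clamp(self, clamp: Optional[float]) -> "AChState":
        level = self.level if clamp is None else float(clamp)
        return replace(self, clamp=clamp, level=level)


def update_ach(state: AChState, err: PredictionError, params: NetworkParams,
               rng: np.random.Generator | None = None) -> AChState:
    """One per-trial update of the ACh trace and tonic level.

    Called at US arrival together with the weight update.  The trace always
    integrates the unsigned error, clamped or not, so releasing a clamp
    resumes from the uncertainty actually experienced.
    """
    p = params
    v = state.V_ach + (-state.V_ach + float(threshold_F(abs(err.ERR), p))) / p.il_tau
    if state.clamp is not None:
        return AChState(V_ach=v, level=float(state.clamp), clamp=state.clamp)
    s = 1.0 / (1.0 + np.exp(-p.ach_sigmoid_gain * (v - p.ach_sigmoid_mid)))
    if p.noise_level > 0:
        if rng is None:
            raise ValueError("rng required when noise_level > 0")
        half = p.noise_level / 2.0
        s *= rng.uniform(1.0 - half, 1.0 + half)
    level = p.ach_strength * (p.ach_baseline + p.ach_uncertainty_strength * s)
    level = float(np.clip(level, p.ach_min, p.ach_max))
    return AChState(V_ach=v, level=level, clamp=None)


def apply_ach_gain(baf_U: np.ndarray, bae_U: np.ndarray,
                   state: AChState) -> Tuple[np.ndarray, np.ndarray]:
    """Multiply basal-nucleus rates by the tonic ACh level.

    LA, CeLOn and CeLOff are unaffected by the cholinergic gain.
    """
    return state.level * np.asarray(baf_U, float), state.level * np.asarray(bae_U, float)
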