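"""Per-trial synaptic plasticity driven by the PAG prediction error.

Both rules are Rescorla–Wagner-like: weights stop changing once the CeLOn
output correctly predicts the US.  The error ``ERR = US - U_CeLOn`` is
computed once per trial from the CeLOn rate at the end of the stimulus
phase (the moment of US arrival) and applied in a single weight update.

Fear pathways (Cortex->LA, Hippo->BAf):

    dW_ij = ERR * US * alpha * U_pre_j * U_post_i

so fear neurons learn only on trials where the aversive US actually occurs
(US = 0 makes the update vanish).

Extinction pathway (IL->BAe):

    dW_ij = -ERR * alpha * U_BAe_i * U_IL_j      only when ERR < 0

i.e. only over-prediction (the US was expected but did not come) recruits
extinction learning; positive errors never weaken the extinction memory.
All weights are clamped at zero from below; an optional upper clip is off
by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Projection

__all__ = ["PredictionError", "compute_error", "fear_update", "extinction_update"]


@dataclass(frozen=True)
class PredictionError:
    """Per-trial Rescorla–Wagner error ``ERR = US - prediction``."""

    US: float
    prediction: float

    @property
    def ERR(self) -> float:
        return self.US - self.prediction


def compute_error(US: float, celon_rate: float) -> PredictionError:
    """Prediction error from the trial's US value and the CeLOn rate at
    the end of phase 1 (the network's US prediction)."""
    return PredictionError(US=float(US), prediction=float(celon_rate))


def _clip(W: np.ndarray, w_max_clip) -> np.ndarray:
    np.maximum(W, 0.0, out=W)
    if w_max_clip is not None:
        np.minimum(W, w_max_clip, out=W)
    return W


def fear_update(proj: Projection, err: PredictionError, alpha: float,
                pre_U: np.ndarray, post_U: np.ndarray,
                w_max_clip=None) -> np.ndarray:
    """Apply the fear rule to a plastic projection; returns the updated W.

    ``pre_U`` / ``post_U`` are the rectified pre- and postsynaptic rates at
    US arrival.  The US factor gates learning to trials where the aversive
    event occurred.
    """
    if proj.rule != "fear":
        raise ValueError(f"fear_update applied to {proj.name} (rule={proj.rule})")
    pre = np.maximum(np.asarray(pre_U, dtype=float), 0.0)
    post = np.maximum(np.asarray(post_U, dtype=float), 0.0)
    proj.W += err.ERR * err.US * alpha * np.outer(post, pre)
    return _clip(proj.W, w_max_clip)


def extinction_update(proj: Projection, err: PredictionError, alpha: float,
                      bae_U: np.ndarray, il_U: np.ndarray,
                      w_max_clip=None) -> np.ndarray:
    """Apply the extinction rule to IL->BAe; returns the updated W.

    Half-rectified in the error: only ERR < 0 (over-prediction) changes the
    weights, so extinction memory is never unlearned by positive errors.
    """
    if proj.rule != "extinction":
        raise ValueError(
            f"extinction_update applied to {proj.name} (rule={proj.rule})")
    if err.ERR < 0:
        post = np.maximum(np.asarray(bae_U, dtype=float), 0.0)
        pre = np.maximum(np.asarray(il_U, dtype=float), 0.0)
        proj.W += -err.ERR * alpha * np.outer(post, pre)
    return _clip(proj.W, w_max_clip)
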