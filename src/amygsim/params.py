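"""Model parameters and flat-file configuration.

All scalar constants of the network live in a single :class:`NetworkParams`
dataclass.  Defaults are the circuit's reference values (population
sizes, time constants, fixed synaptic weights, learning and acetylcholine
constants) plus a small number of implementation constants that the rate
equations leave open: the Euler integration step ``dt``, the logistic shape
of the firing-rate sigmoid, and the success tolerances used by the
behavioural criteria.

Configuration files are flat YAML (or ``key: value`` text) documents.  Keys
may use either the dataclass field names or the capitalised aliases commonly
used for the circuit constants (``Cel_input_W``, ``ACh_min``, ...).  Unknown
keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = ["NetworkParams", "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown configuration keys or invalid parameter values."""


@dataclass
class NetworkParams:
    # -- architecture -------------------------------------------------------
    input_size: int = 10          # Cortex / Hippo / IL vector length
    la_size: int = 10
    baf_size: int = 10
    bae_size: int = 10
    celon_size: int = 1
    celoff_size: int = 1

    # -- rate dynamics -------------------------------------------------------
    tau: float = 0.05             # membrane time constant
    theta: float = 0.3            # input threshold of F(.)
    min_value: float = 1e-3       # floor of F(.)
    noise_level: float = 0.01     # total width of the multiplicative noise
                                  # interval, as a fraction of sigmoid(V)
    dt: float = 0.001             # Euler step; one "cycle" of the protocol
    cycles_per_phase: int = 500   # steps per trial phase

    # sigmoid shape (implementation constants, calibrated once; the rate
    # nonlinearity is logistic 1/(1+exp(-gain*(V-mid))))
    sigmoid_gain: float = 2.2
    sigmoid_mid: float = 0.5

    # -- fixed synaptic weights ---------------------------------------------
    cel_input_w: float = 0.2      # LA,BAf -> CeLOn and BAe -> CeLOff
    la_to_baf_w: float = 0.1
    la_inhib_w: float = 0.1       # lateral inhibition within LA
    cel_inhib_w: float = 0.25     # CeLOn <-> CeLOff mutual inhibition
    ba_inhib_w: float = 0.05      # BAf <-> BAe mutual inhibition
    fixed_weight_jitter: float = 0.04  # total width of the uniform interval
                                       # around each fixed weight at build time
    randomize_fixed: bool = True

    # -- plasticity ----------------------------------------------------------
    alpha: float = 1.0            # learning-rate coefficient, all pathways
    wmin: float = 0.01            # plastic-weight initialisation interval
    wmax: float = 0.05
    w_max_clip: Optional[float] = None  # optional upper clip, off by default
    plastic_la_to_baf: bool = False     # optionally learn LA->BAf (fear rule)

    # -- acetylcholine -------------------------------------------------------
    ach_baseline: float = 1.0
    ach_strength: float = 0.5
    ach_uncertainty_strength: float = 5.0
    il_tau: float = 5.0           # ACh trace time constant, in trials
    ach_min: float = 1.0
    ach_max: float = 2.5
    # shape of the sigmoid inside the ACh formula (implementation constants;
    # chosen so the free-running level rests at its floor under low
    # uncertainty and approaches ACh_max under sustained full-size errors)
    ach_sigmoid_gain: float = 4.0
    ach_sigmoid_mid: float = 0.45

    # -- stimulus coding -----------------------------------------------------
    cortex_salience: float = 1.5
    hippo_salience: float = 1.0
    il_salience: float = 1.0

    # -- behavioural criteria -----------------------------------------------
    acquisition_tol: float = 0.15   # |1 - prediction| band for acquisition
    extinction_frac: float = 0.3    # fraction of peak prediction for extinction
    baseline_band: float = 0.1      # "close to baseline" band for probes

    def __post_init__(self) -> None:
        for name in ("input_size", "la_size", "baf_size", "bae_size",
                     "celon_size", "celoff_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0 < self.dt < self.tau:
            raise ConfigError(f"dt must satisfy 0 < dt < tau, got dt={self.dt}")
        if self.cycles_per_phase * self.dt < 5 * self.tau:
            raise ConfigError(
                "a phase must span at least 5 membrane time constants "
                f"(cycles_per_phase*dt={self.cycles_per_phase * self.dt}, "
                f"5*tau={5 * self.tau})")
        if self.noise_level < 0:
            raise ConfigError("noise_level must be nonnegative")
        if self.wmin > self.wmax:
            raise ConfigError("wmin must not exceed wmax")

    def replace(self, **changes: Any) -> "NetworkParams":
        """Return a copy with ``changes`` applied (config keys or field names)."""
        mapped = {_canonical_key(k): v for k, v in changes.items()}
        return dataclasses.replace(self, **mapped)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# Aliases for the printed circuit-constant names; lowercase-only lookup.
_ALIASES = {
    "celon_size": "celon_size",
    "celoff_size": "celoff_size",
    "cel_input_w": "cel_input_w",
    "la_to_baf_w": "la_to_baf_w",
    "la_inhib_w": "la_inhib_w",
    "cel_inhib_w": "cel_inhib_w",
    "ba_inhib_w": "ba_inhib_w",
    "ach_min": "ach_min",
    "ach_max": "ach_max",
    "ach_strength": "ach_strength",
    "ach_uncertainty_strength": "ach_uncertainty_strength",
    "baseline": "ach_baseline",
    "ach_baseline": "ach_baseline",
    "il_tau": "il_tau",
    "tau_ach": "il_tau",
}

_FIELD_NAMES = {f.name for f in dataclasses.fields(NetworkParams)}


def _canonical_key(key: str) -> str:
    low = key.lower()
    if low in _FIELD_NAMES:
        return low
    if low in _ALIASES:
        return _ALIASES[low]
    raise ConfigError(f"unknown configuration key: {key!r}")


def load_config(path: str | Path) -> NetworkParams:
    """Load a flat YAML configuration file into a :class:`NetworkParams`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"configuration must be a flat mapping, got {type(doc)}")
    return NetworkParams().replace(**doc)


def dump_config(params: NetworkParams, path: str | Path) -> None:
    """Write every parameter to a flat YAML document."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)
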