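"""Population rate dynamics of the amygdalar circuit.

Five populations are simulated with a mean-field rate formalism: the lateral
nucleus (LA, 10 units), basal fear and extinction populations (BAf, BAe, 10
units each) and single CeLOn / CeLOff units of the lateral central nucleus.
Each unit carries a membrane potential ``V`` and a firing rate ``U``:

    dV_i/dt = (-V_i + F(sum_j W_ij * U_j)) / tau
    U_i     = noise(sigmoid(V_i)) - sum_k Winhib_ik * U_k

with threshold function ``F(x) = max(min_value, x - theta)``, a logistic
sigmoid, and multiplicative uniform noise whose total interval width is a
fixed fraction of ``sigmoid(V)``.  Excitatory and inhibitory influences are
kept in separate nonnegative weight matrices; any firing rate used as
presynaptic drive is rectified at zero first.

Cortex, Hippo and IL are pure input vectors with no dynamics of their own:
their ``U`` is the stimulus vector, clamped for the duration of a phase.

Integration is explicit Euler with step ``dt`` (one protocol "cycle"); all
populations update synchronously: every ``V`` advances from the previous
step's rectified rates, then every ``U`` is computed from the new ``V`` and
the previous step's inhibitory rates, which avoids order dependence between
mutually inhibiting populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np

from .params import NetworkParams, ConfigError

__all__ = [
    "PopulationState",
    "Projection",
    "Network",
    "threshold_F",
    "sigmoid",
    "build_network",
]

POPULATIONS = ("LA", "BAf", "BAe", "CeLOn", "CeLOff")
INPUT_CHANNELS = ("Cortex", "Hippo", "IL")


def threshold_F(x, params: NetworkParams):
    """Threshold nonlinearity ``F(x) = max(min_value, x - theta)``.

    Applied to the summed excitatory drive before membrane integration.
    Accepts scalars or arrays; rejects non-finite input.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite drive passed to threshold function")
    return np.maximum(params.min_value, x - params.theta)


def sigmoid(v, params: NetworkParams):
    """Logistic firing-rate nonlinearity ``1/(1+exp(-gain*(v-mid)))``."""
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp(-params.sigmoid_gain * (v - params.sigmoid_mid)))


@dataclass
class PopulationState:
    """Membrane potentials and firing rates of one population."""

    name: str
    V: np.ndarray
    U: np.ndarray

    @property
    def rates(self) -> np.ndarray:
        """Firing rates rectified at zero — the exported presynaptic drive."""
        return np.maximum(self.U, 0.0)

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        if self.V.shape != self.U.shape:
            raise ValueError(f"{self.name}: V and U must have the same length")


@dataclass
class Projection:
    """All-to-all weighted connection between two populations.

    ``W`` is (post-size, pre-size) and nonnegative; the sign of the influence
    is carried by ``kind``.  Only the three input pathways are plastic:
    Cortex->LA and Hippo->BAf under the fear rule, IL->BAe under the
    extinction rule.
    """

    pre: str
    post: str
    W: np.ndarray
    kind: str            # "excitatory" | "inhibitory"
    plastic: bool = False
    rule: str = "none"   # "fear" | "extinction" | "none"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.kind not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown projection kind {self.kind!r}")
        if self.rule not in ("fear", "extinction", "none"):
            raise ValueError(f"unknown plasticity rule {self.rule!r}")
        if np.any(self.W < 0):
            raise ValueError(f"{self.pre}->{self.post}: weights must be nonnegative")

    @property
    def name(self) -> str:
        return f"{self.pre}->{self.post}"


def _uniform_around(rng: np.random.Generator, center: float, width: float,
                    shape: Tuple[int, ...], enabled: bool) -> np.ndarray:
    if not enabled or width <= 0:
        return np.full(shape, center, dtype=float)
    lo = max(center - width / 2.0, 0.0)
    hi = center + width / 2.0
    return rng.uniform(lo, hi, size=shape)


class Network:
    """The wired circuit: population states plus named projections.

    Excitatory wiring (Figure-level architecture): Cortex->LA, Hippo->BAf,
    IL->BAe (plastic); LA->BAf; LA->CeLOn, BAf->CeLOn, BAe->CeLOff (fixed).
    Inhibitory wiring: LA lateral inhibition (no self-connections),
    BAf<->BAe mutual inhibition, CeLOn<->CeLOff mutual inhibition.
    """

    def __init__(self, params: NetworkParams, rng: np.random.Generator):
        p = params
        self.params = p
        self.pops: Dict[str, PopulationState] = {
            "LA": PopulationState("LA", np.zeros(p.la_size), np.zeros(p.la_size)),
            "BAf": PopulationState("BAf", np.zeros(p.baf_size), np.zeros(p.baf_size)),
            "BAe": PopulationState("BAe", np.zeros(p.bae_size), np.zeros(p.bae_size)),
            "CeLOn": PopulationState("CeLOn", np.zeros(p.celon_size), np.zeros(p.celon_size)),
            "CeLOff": PopulationState("CeLOff", np.zeros(p.celoff_size), np.zeros(p.celoff_size)),
        }

        jit = p.fixed_weight_jitter
        rnd = p.randomize_fixed
        proj: Dict[str, Projection] = {}

        def add(pre, post, W, kind, plastic=False, rule="none"):
            proj[f"{pre}->{post}"] = Projection(pre, post, W, kind, plastic, rule)

        # plastic input pathways, uniform on [wmin, wmax]
        add("Cortex", "LA",
            rng.uniform(p.wmin, p.wmax, size=(p.la_size, p.input_size)),
            "excitatory", plastic=True, rule="fear")
        add("Hippo", "BAf",
            rng.uniform(p.wmin, p.wmax, size=(p.baf_size, p.input_size)),
            "excitatory", plastic=True, rule="fear")
        add("IL", "BAe",
            rng.uniform(p.wmin, p.wmax, size=(p.bae_size, p.input_size)),
            "excitatory", plastic=True, rule="extinction")

        # fixed excitatory pathways
        add("LA", "BAf",
            _uniform_around(rng, p.la_to_baf_w, jit, (p.baf_size, p.la_size), rnd),
            "excitatory", plastic=p.plastic_la_to_baf,
            rule="fear" if p.plastic_la_to_baf else "none")
        add("LA", "CeLOn",
            _uniform_around(rng, p.cel_input_w, jit, (p.celon_size, p.la_size), rnd),
            "excitatory")
        add("BAf", "CeLOn",
            _uniform_around(rng, p.cel_input_w, jit, (p.celon_size, p.baf_size), rnd),
            "excitatory")
        add("BAe", "CeLOff",
            _uniform_around(rng, p.cel_input_w, jit, (p.celoff_size, p.bae_size), rnd),
            "excitatory")

        # inhibitory pathways
        W_lat = _uniform_around(rng, p.la_inhib_w, jit, (p.la_size, p.la_size), rnd)
        np.fill_diagonal(W_lat, 0.0)  # lateral, no self-inhibition
        add("LA", "LA", W_lat, "inhibitory")
        add("BAe", "BAf",
            _uniform_around(rng, p.ba_inhib_w, jit, (p.baf_size, p.bae_size), rnd),
            "inhibitory")
        add("BAf", "BAe",
            _uniform_around(rng, p.ba_inhib_w, jit, (p.bae_size, p.baf_size), rnd),
            "inhibitory")
        add("CeLOff", "CeLOn",
            _uniform_around(rng, p.cel_inhib_w, jit, (p.celon_size, p.celoff_size), rnd),
            "inhibitory")
        add("CeLOn", "CeLOff",
            _uniform_around(rng, p.cel_inhib_w, jit, (p.celoff_size, p.celon_size), rnd),
            "inhibitory")
        self.projections = proj

    # -- access helpers ------------------------------------------------------

    @property
    def plastic_projections(self) -> List[Projection]:
        return [pr for pr in self.projections.values() if pr.plastic]

    def rates(self, name: str) -> np.ndarray:
        return self.pops[name].rates

    def reset_activity(self) -> None:
        """Zero all membrane potentials and rates (weights untouched)."""
        for pop in self.pops.values():
            pop.V[:] = 0.0
            pop.U[:] = 0.0

    # -- dynamics ------------------------------------------------------------

    def run_phase(self, inputs: Dict[str, np.ndarray], n_steps: int,
                  rng: np.random.Generator, ach_level: float = 1.0) -> None:
        """Advance the circuit ``n_steps`` Euler steps with clamped inputs.

        ``inputs`` maps channel names (Cortex, Hippo, IL) to stimulus
        vectors, held constant for the whole phase; missing channels are
        treated as silent.  ``ach_level`` multiplies the BAf and BAe firing
        rates at every step (cholinergic gain on the basal nucleus).
        """
        p = self.params
        zeros = np.zeros(p.input_size)
        cortex = np.maximum(np.asarray(inputs.get("Cortex", zeros), float), 0.0)
        hippo = np.maximum(np.asarray(inputs.get("Hippo", zeros), float), 0.0)
        il = np.maximum(np.asarray(inputs.get("IL", zeros), float), 0.0)
        for name, vec in (("Cortex", cortex), ("Hippo", hippo), ("IL", il)):
            if vec.shape != (p.input_size,):
                raise ConfigError(
                    f"{name} input has shape {vec.shape}, expected ({p.input_size},)")

        pr = self.projections
        W_cx_la = pr["Cortex->LA"].W
        W_hip_baf = pr["Hippo->BAf"].W
        W_il_bae = pr["IL->BAe"].W
        W_la_baf = pr["LA->BAf"].W
        W_la_on = pr["LA->CeLOn"].W
        W_baf_on = pr["BAf->CeLOn"].W
        W_bae_off = pr["BAe->CeLOff"].W
        W_la_la = pr["LA->LA"].W
        W_bae_baf = pr["BAe->BAf"].W
        W_baf_bae = pr["BAf->BAe"].W
        W_off_on = pr["CeLOff->CeLOn"].W
        W_on_off = pr["CeLOn->CeLOff"].W

        la, baf, bae = self.pops["LA"], self.pops["BAf"], self.pops["BAe"]
        on, off = self.pops["CeLOn"], self.pops["CeLOff"]
        # constant feed-forward drive from the clamped input vectors
        drive_cx = W_cx_la @ cortex
        drive_hip = W_hip_baf @ hippo
        drive_il = W_il_bae @ il

        dt_tau = p.dt / p.tau
        mv, th = p.min_value, p.theta
        g, m = p.sigmoid_gain, p.sigmoid_mid
        half = p.noise_level / 2.0

        # pre-drawn multiplicative noise factors, one row per step
        if p.noise_level > 0:
            sizes = (la.V.size, baf.V.size, bae.V.size, on.V.size, off.V.size)
            noise = [rng.uniform(1.0 - half, 1.0 + half, size=(n_steps, n))
                     for n in sizes]
        else:
            noise = None

        V_la, V_baf, V_bae, V_on, V_off = la.V, baf.V, bae.V, on.V, off.V
        U_la, U_baf, U_bae, U_on, U_off = la.U, baf.U, bae.U, on.U, off.U

        for t in range(n_steps):
            r_la = np.maximum(U_la, 0.0)
            r_baf = np.maximum(U_baf, 0.0)
            r_bae = np.maximum(U_bae, 0.0)
            r_on = np.maximum(U_on, 0.0)
            r_off = np.maximum(U_off, 0.0)

            V_la += dt_tau * (-V_la + np.maximum(mv, drive_cx - th))
            V_baf += dt_tau * (-V_baf + np.maximum(mv, drive_hip + W_la_baf @ r_la - th))
            V_bae += dt_tau * (-V_bae + np.maximum(mv, drive_il - th))
            V_on += dt_tau * (-V_on + np.maximum(
                mv, W_la_on @ r_la + W_baf_on @ r_baf - th))
            V_off += dt_tau * (-V_off + np.maximum(mv, W_bae_off @ r_bae - th))

            s_la = 1.0 / (1.0 + np.exp(-g * (V_la - m)))
            s_baf = 1.0 / (1.0 + np.exp(-g * (V_baf - m)))
            s_bae = 1.0 / (1.0 + np.exp(-g * (V_bae - m)))
            s_on = 1.0 / (1.0 + np.exp(-g * (V_on - m)))
            s_off = 1.0 / (1.0 + np.exp(-g * (V_off - m)))
            if noise is not None:
                s_la = s_la * noise[0][t]
                s_baf = s_baf * noise[1][t]
                s_bae = s_bae * noise[2][t]
                s_on = s_on * noise[3][t]
                s_off = s_off * noise[4][t]

            # ACh multiplies the basal-nucleus excitatory drive term; the
            # inhibitory subtraction is not gained, so the BAf/BAe
            # competition's loop gain stays independent of the ACh level
            U_la[:] = s_la - W_la_la @ r_la
            U_baf[:] = s_baf * ach_level - W_bae_baf @ r_bae
            U_bae[:] = s_bae * ach_level - W_baf_bae @ r_baf
            U_on[:] = s_on - W_off_on @ r_off
            U_off[:] = s_off - W_on_off @ r_on


def step_potential(pop: PopulationState,
                   excit_inputs: Iterable[Tuple[Projection, np.ndarray]],
                   params: NetworkParams) -> np.ndarray:
    """One Euler step of the membrane equation for a single population.

    ``excit_inputs`` pairs each excitatory projection with its presynaptic
    rate vector (rectified before use).  Updates ``pop.V`` in place and
    returns it.  Equivalent to one step of :meth:`Network.run_phase` for
    that population.
    """
    drive = np.zeros_like(pop.V)
    for proj, pre_U in excit_inputs:
        if proj.kind != "excitatory":
            raise ValueError(f"{proj.name} is not excitatory")
        pre_U = np.maximum(np.asarray(pre_U, dtype=float), 0.0)
        if proj.W.shape[1] != pre_U.shape[0] or proj.W.shape[0] != pop.V.shape[0]:
            raise ValueError(
                f"{proj.name}: weight shape {proj.W.shape} incompatible with "
                f"pre {pre_U.shape} / post {pop.V.shape}")
        drive += proj.W @ pre_U
    pop.V += (params.dt / params.tau) * (-pop.V + threshold_F(drive, params))
    return pop.V


def compute_rate(pop: PopulationState,
                 inhib_inputs: Iterable[Tuple[Projection, np.ndarray]],
                 params: NetworkParams,
                 rng: np.random.Generator | None = None,
                 gain: float = 1.0) -> np.ndarray:
    """Firing rate from the current membrane potential, minus inhibition.

    ``U_i = gain * noise(sigmoid(V_i)) - sum_k W_ik * U_k(inhib)`` where
    ``gain`` is the cholinergic gain on the excitatory drive term (BAf/BAe
    only, 1 elsewhere).  Updates ``pop.U`` in place and returns it; callers
    export ``pop.rates`` as presynaptic drive.
    """
    s = sigmoid(pop.V, params)
    if params.noise_level > 0:
        if rng is None:
            raise ValueError("rng required when noise_level > 0")
        half = params.noise_level / 2.0
        s = s * rng.uniform(1.0 - half, 1.0 + half, size=s.shape)
    s = s * gain
    inhib = np.zeros_like(pop.U)
    for proj, pre_U in inhib_inputs:
        if proj.kind != "inhibitory":
            raise ValueError(f"{proj.name} is not inhibitory")
        pre_U = np.maximum(np.asarray(pre_U, dtype=float), 0.0)
        if proj.W.shape[1] != pre_U.shape[0] or proj.W.shape[0] != pop.U.shape[0]:
            raise ValueError(
                f"{proj.name}: weight shape {proj.W.shape} incompatible with "
                f"pre {pre_U.shape} / post {pop.U.shape}")
        inhib += proj.W @ pre_U
    pop.U[:] = s - inhib
    return pop.U


def build_network(params: NetworkParams | None = None,
                  rng: np.random.Generator | int | None = None) -> Network:
    """Construct and wire the circuit; weights drawn from ``rng``."""
    if params is None:
        params = NetworkParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return Network(params, rng)
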