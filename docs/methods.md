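# Methods

## The model

`amygsim` simulates pavlovian fear learning in a mean-field rate model of
the amygdala. Five populations are modelled: the lateral nucleus (LA, 10
units), fear and extinction populations of the basal nucleus (BAf and BAe,
10 units each, mutually inhibitory), and single CeLOn / CeLOff units of the
lateral central nucleus, themselves mutually inhibitory. CeLOn's firing
rate is read out as the network's prediction of the aversive unconditioned
stimulus (US). Three input channels carry the world: a sensory cue vector
("Cortex", projecting to LA), a spatial-context vector ("Hippo", to BAf),
and an infralimbic extinction signal ("IL", to BAe). Inputs are vectors of
length 10 with one salient unit (1.5 for the cue, 1.0 for contexts and IL)
over a uniform background on [0, 0.1]; whether IL is salient is a protocol
flag — the model deliberately does not attempt to detect an extinction
context itself.

Each unit carries a membrane potential `V` and a rate `U`:

    dV_i/dt = (-V_i + F(Σ_j W_ij U_j)) / τ,     F(x) = max(10⁻³, x - θ)
    U_i     = noise(σ(V_i)) · g_ACh - Σ_k Winhib_ik U_k

with τ = 0.05, θ = 0.3, and multiplicative uniform noise whose total
interval is `noise_level` (default 1%) of σ(V). `g_ACh` is the tonic
acetylcholine level for BAf and BAe and 1 for all other populations.
Rates are rectified at zero wherever they act as presynaptic drive.
Excitatory wiring: Cortex→LA, Hippo→BAf, IL→BAe (plastic), LA→BAf (0.1),
LA→CeLOn, BAf→CeLOn, BAe→CeLOff (0.2). Inhibitory wiring: LA lateral
(0.1, no self-connections), BAf↔BAe (0.05), CeLOn↔CeLOff (0.25). Fixed
weights are jittered uniformly (interval 0.04) around their nominal values
at build time; plastic weights start uniform on [0.01, 0.05].

Learning is Rescorla–Wagner-like, driven by the prediction error
`ERR = US − U_CeLOn` evaluated at US arrival, applied once per trial:

    fear pathways (Cortex→LA, Hippo→BAf):  ΔW_ij = ERR · US · α · U_pre,j · U_post,i
    extinction pathway (IL→BAe):           ΔW_ij = −ERR · α · U_BAe,i · U_IL,j   (only if ERR < 0)

with α = 1. Fear neurons learn only when the US occurs; extinction
neurons learn only from over-prediction and never unlearn on positive
errors. Weights are clamped at zero from below; no upper clip by default.

Tonic ACh tracks expected uncertainty: a scalar trace filters the unsigned
error once per trial, `V_ACh ← V_ACh + (−V_ACh + F(|ERR|)) / τ_ACh` with
τ_ACh = 5 trials, and the broadcast level is
`ACh = 0.5 · (1 + 5 · noise(σ_ACh(V_ACh)))`, clipped to [1, 2.5] when
free-running. Experimental clamps (0.5 depletion, 3.0 elevation) override
the level and bypass the clip; the trace keeps integrating underneath so
releasing a clamp resumes from the uncertainty actually experienced.

## Trials and paradigms

A trial is three phases of 500 Euler steps each: stimulus phase (inputs
clamped; the CeLOn rate at its end is the trial's prediction), US phase (at
its first instant ERR is computed and, on learning trials, weights and ACh
are updated once; stimuli stay on), and rest phase (inputs zeroed).
Paradigms are declarative trial lists: conditioning (cue + context + US),
contextual extinction (cue + second context + IL, no US), a renewal probe
(cue + original context, learning off), pairing (11 reliable cue–context–US
trials then cue-only and context-only probes), unpairing (the same with the
cue's salience multiplied by a fresh uniform [0, 1] draw each trial), and
ACh-clamped variants of each. Probe and baseline trials never learn.

## Implementation constants

The rate equations leave four quantities open; they are configuration
fields with the following defaults, fixed once during development:

* **Integration step** `dt = 0.001` (dt/τ = 0.02): one protocol "cycle" is
  one explicit Euler step, so a 500-cycle phase spans 10 membrane time
  constants — comfortably past the ~7τ needed for settling. All updates
  are synchronous (every V advances from the previous step's rectified
  rates, then every U from the new V and the previous inhibitory rates),
  which avoids order dependence between mutually inhibiting populations.
* **Rate sigmoid** σ(x) = 1/(1+exp(−g·(x−m))) with g = 2.2, m = 0.5.
  The calibration is constrained from several directions at once: the
  baseline output σ(10⁻³) ≈ 0.29 must be large enough for the
  multiplicative learning rules to bootstrap from rest (both fear
  acquisition and, against BAf's inhibition, extinction), while the
  response to the trained LA population alone must sit near the midpoint
  so that CeLOff's inhibition can silence CeLOn during extinction.
* **ACh sigmoid** g = 4.0, m = 0.45 (the formula's own squashing
  function). Sharing the network sigmoid would leave the free-running
  level floored near 1.2 — never returning to baseline after acquisition —
  because the network sigmoid's baseline output is deliberately high.
  With these values the level rests at its floor (1.0) under low
  uncertainty and reaches ≈ 2.3 under sustained full-size errors.
* **ACh gain placement**: the gain multiplies the noisy sigmoid term of
  U_BAf/U_BAe, not the post-inhibition rate. Gaining the final rate makes
  the BAf↔BAe loop gain scale with ACh²; above ACh ≈ 2 the mutual
  inhibition then becomes a bistable latch whose winner is chosen by noise
  at rest, which contradicts the graded competition the elevated-ACh
  experiments require. Learning post-factors use the rates as computed,
  so the gain still accelerates basal-nucleus learning.

## Success criteria

Quantitative read-outs formalise the qualitative claims of the
conditioning literature. Acquisition: the first conditioning trial from
which |1 − prediction| ≤ 0.15 holds for the rest of the phase. Extinction:
the first extinction trial from which prediction ≤ 0.3 × (conditioning
peak) holds sustainedly. Renewal: the probe recovers ≥ 80% of the final
conditioning prediction. Probe comparison: which of the cue-only and
context-only probes elicits the larger prediction (the distance of the
loser from the no-stimulus baseline is reported alongside, with a ±0.1
band, but does not gate the verdict). Extinction ordering: the onset of
BAe's sustained rise must strictly precede BAf's sustained fall, onsets
being the first trial from which every later value stays beyond the
pre-onset level. "Sustained" always means "holds for every remaining
trial of the phase", guarding against single-trial noise flukes. Because
the model is stochastic, paradigm verdicts are aggregated over 20 seeds
with a 90% pass requirement.

## What the simulations do and do not emulate

All inputs are generated internally; there is no external data. The
stimulus coding (single salient unit over weak background) emulates an
attended cue or context, not realistic sensory statistics; trials are
temporally rigid (no CS–US delay manipulation), extinction-context
detection is exogenous, and the intercalated-cell pathway, CeA plasticity
and other neuromodulators are outside the model. Passing tests therefore
show that the circuit-level interactions produce the behavioural
phenomenology under idealised drive, not that the model generalises to
realistic sensory input.

## Known limitations

With the reference constants, the cue–context balance after reliable
pairing at normal ACh comes out context-favoured by about 0.1 prediction
units: the hippocampal pathway's weights free-ride, through the learning
rule's postsynaptic factor, on the compound BAf drive (direct context
input plus the LA→BAf relay), while LA's readout is halved by its lateral
inhibition and the relay hovers at the activation threshold. Across a wide
calibration sweep of the sigmoid this offset never changes sign, so the
cue-only probe does not exceed the context-only probe after reliable
pairing, and the cue-dominance expected after ACh-depleted unpairing holds
in only about half of seeds. The balance point sits at a cue salience of
≈ 1.7 (against the coded 1.5); we keep the reference coding rather than
move it. The ACh-dependence of the balance is nevertheless present and
correctly signed: elevation (3.0) yields context dominance, depletion
shifts credit toward the cue, and the unreliable-cue (unpairing)
experiment yields context dominance at normal ACh. The same structural
coupling caps how sharply the extinction floor and a strong cue-only
probe can coexist, since both are governed by the same response of CeLOn
to the trained LA population.

Long extinction runs grow the IL→BAe weights without bound (the
prediction cannot reach the extinction rule's fixed point at zero because
CeLOff's inhibition is bounded); within the standard trial counts this is
immaterial, but simulations hundreds of trials long should enable the
optional upper weight clip.

## Problem sizes

Default runs use the reference architecture exactly (10-unit populations,
500-cycle phases, 22–24-trial schedules); a full paradigm takes about a
second. Aggregate checks use 20 seeds; the noise-robustness sweep
evaluates the paradigm set at noise intervals of 1, 5, 10 and 20%.
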