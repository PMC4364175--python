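# amygsim

A firing-rate model of the amygdalar circuit for pavlovian fear
conditioning, contextual extinction, renewal, and its cholinergic
modulation — for computational neuroscientists who want a small, fully
tested simulator of the lateral/basal/central-nucleus competition.

## The model in brief

Five rate-coded populations — LA (lateral nucleus), BAf and BAe (basal
fear and extinction neurons, mutually inhibitory), CeLOn and CeLOff
(lateral central nucleus, mutually inhibitory) — obey the mean-field
equations

    dVᵢ/dt = (−Vᵢ + F(Σⱼ Wᵢⱼ Uⱼ)) / τ,   F(x) = max(10⁻³, x − θ)
    Uᵢ     = noise(σ(Vᵢ)) · g_ACh − Σₖ W⁻ᵢₖ Uₖ

with CeLOn's rate read out as the prediction of the US. Sensory cues
reach LA, spatial context reaches BAf, and an infralimbic extinction
signal reaches BAe. The three input pathways are plastic under
Rescorla–Wagner prediction-error learning, updated once per trial at US
arrival with `ERR = US − U_CeLOn`:

    fear (Cortex→LA, Hippo→BAf):  ΔW = ERR · US · α · U_pre U_post
    extinction (IL→BAe):          ΔW = −ERR · α · U_BAe U_IL   (ERR < 0 only)

A tonic acetylcholine level tracks recent unsigned error (expected
uncertainty) and multiplicatively gates the basal nucleus, biasing the
cue-vs-context competition. See `docs/methods.md` for the complete
specification, parameters and calibration.

## Worked example

```python
from amygsim.paradigms import simulate, records_to_frame

frame = records_to_frame(simulate("extinction_renewal", seed=1))
print(frame[["trial", "label", "prediction", "ach_level", "U_BAf", "U_BAe"]])
```

Abridged output (values the package prints for seed 1):

```
 trial        label  prediction  ach_level  U_LA  U_BAf  U_BAe
     1     baseline       0.351      1.000 0.132  0.166  0.165
     2 conditioning       0.349      1.000 0.132  0.166  0.165
     6 conditioning       0.817      1.000 0.262  0.487  0.009
    10 conditioning       0.939      1.000 0.350  0.679  0.000
    11   extinction       0.761      1.033 0.360  0.316  0.090
    16   extinction       0.756      1.530 0.361  0.370  0.340
    18   extinction       0.307      1.305 0.358  0.041  0.963
    21   extinction       0.253      1.052 0.359  0.000  1.033
    22      renewal       0.956      1.052 0.359  0.736  0.000
```

Reading it: during conditioning (trials 2–10) the CeLOn prediction climbs
from baseline (≈ 0.35) to ≈ 0.94 — the network comes to predict the
shock — while fear neurons (LA, BAf) activate and extinction neurons
(BAe) are silenced. In the extinction context (trials 11–21) the
prediction error turns negative, uncertainty drives the ACh level up to
≈ 1.5, extinction neurons ramp up *before* fear neurons shut down, and
the prediction collapses to ≈ 0.25 without any loss of the LA fear
memory (U_LA stays at 0.36 throughout). Returning to the original
context (trial 22) restores the fear prediction immediately — renewal —
with zero weight changes: extinction is inhibition, not forgetting.

The same machinery runs the other paradigms
(`extinction_renewal_ach_depleted`, `ach_depletion_last_trial`,
`pairing`, `pairing_high_ach`, `unpairing`, `unpairing_ach_depleted`),
and each paradigm's behavioural criteria are scored by
`amygsim.paradigms.evaluate_paradigm`.

From the shell:

```
amygsim run extinction_renewal --seed 1 --out results/extrenew
amygsim run pairing --ach-clamp 3.0 --out results/pairing_high
amygsim sweep extinction_renewal --param noise_level --values 0.01,0.05,0.10,0.20
```

Each run directory receives per-trial CSVs, a criteria summary, summary
plots, the trial schedule and the full parameter set, so any result is
reproducible from its own directory.

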