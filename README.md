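# turntaking

Analysis of **turn-taking in dyadic grooming interactions** — built for
behavioural researchers studying how non-vocal exchanges of actions
(e.g. grooming bouts) and signals (gestures) are organised between two
interacting animals, and how demographic and social factors shape that
organisation.

The pipeline goes from annotated event logs (one row per produced
signal/action unit with actor, modality and onset/offset timestamps) to:

1. **Turn transitions** — a transition is a unit produced by one
   interactant followed, with role reversal, by a unit of the other
   whose onset falls within 30 s of the first unit's offset.  Each
   transition is classified as action–action, action–signal,
   signal–action or signal–signal, and carries a signed timing
   `timing = offset₁ − onset₂`: negative values are gaps between turns
   (*overlap avoidance*), positive values are overlaps.
2. **Dominance hierarchy metrics** from pooled decided agonistic
   records (aggression winners plus pant-grunt/pant-bark submissive
   signals, whose producer is subordinate): David's scores
   `DS = w + w₂ − l − l₂` from dyadic win proportions `P_ij`
   (or the chance-corrected `D_ij`), normalised as
   `normDS = (DS + n(n−1)/2)/n`; hierarchy **steepness** (the absolute
   OLS slope of normDS against ordinal rank, 0 = egalitarian,
   1 = despotic) with a permutation test; the improved **linearity
   index h′** (Landau's h with tied/unknown dyads randomly directed)
   with a randomization test; and **I&SI ordinal ranks** minimising the
   number, then the strength, of dominance inconsistencies (exact for
   small groups).
3. **Dyadic Composite Sociality Index** per dyad, from grooming bouts
   and 1-m proximity scans:
   `DSI = G_AB/(G_AB+G_A+G_B) + P_AB/(P_AB+P_A+P_B)` ∈ [0, 2].
4. **Four Bayesian hierarchical models** of (i) the unit-level
   likelihood of a transition (Bernoulli), (ii) per-interaction
   transition counts with a log-duration exposure offset (Poisson),
   (iii) transition-type likelihoods (four joint binary responses, or a
   categorical alternative), and (iv) signed-log-transformed response
   timings (Gaussian, with sum-to-zero transition-type contrasts and
   type × covariate interactions).  Fixed effects are initiator/
   recipient age and rank (z-scored), DSI, relatedness and community;
   random intercepts for initiator, recipient, dyad and interaction.
   Posteriors are sampled with a built-in adaptive Hamiltonian Monte
   Carlo sampler (analytic gradients, non-centered random effects) and
   reported as posterior median, scaled MAD, equal-tailed 89% credible
   interval and probability of direction (pd), with arviz R-hat/ESS
   diagnostics.

A fully seeded **synthetic-data generator** produces every pipeline
input with known ground truth (latent hierarchy of configurable
steepness, latent dyadic bonds driving grooming/proximity, logistic
unit-response model on z-scored covariates, per-type signed latency
distributions), so every stage is testable end to end.

## Worked example

```bash
turntaking simulate --seed 7 -o run/ --n-individuals 12 --n-interactions 60
turntaking transitions run/event_log.tsv -o run/
turntaking dominance run/agonistic.tsv -o run/ --seed 7
turntaking dsi run/grooming.tsv run/scans.tsv run/roster.tsv -o run/
turntaking report run/
```

prints

```
# Turn-taking analysis report

Units: 1145; transitions: 396 in 60 interactions
  action_action: n=145 (37%), median timing -0.12 s
  action_signal: n=64 (16%), median timing +0.11 s
  signal_action: n=125 (32%), median timing -0.05 s
  signal_signal: n=62 (16%), median timing +0.57 s
Overlap avoidance: 46% of transitions
Hierarchy: steepness 0.205 (p=0.207), h' 0.300 (p=0.218), I=8 SI=41
DSI across 66 dyads: range [0.0000, 0.5701]
```

Reading: of the 1145 produced units, 396 formed turn transitions;
action–action transitions have a negative median timing (responses tend
to wait for the first unit to end — overlap avoidance), signal–signal
transitions a positive one (responses tend to overlap).  The shallow
steepness (0.205) and low h′ (0.300) describe an egalitarian, weakly
linear hierarchy; I&SI found 8 rank inconsistencies.  `turntaking fit
run/ -o run/ --model 1 --seed 7` then fits the unit-level model and
prints one line per effect, e.g.

```
initiator_age_z: estimate [MAD] = 0.28 [0.10], 89% CrI [0.13, 0.52], pd = 99.90%  *
```

— the `*` flags an 89% CrI excluding zero (here the generator's true
initiator-age coefficient is 0.30).  The quick profile (2 chains ×
1000 iterations) is for smoke runs and may emit a non-convergence
warning; pass `--full-profile` (4 chains × 4000) for inference-grade
fits.

The same commands run on real annotation exports: the expected TSV
schemas are documented in `turntaking.event_model`.

## Layout

| module | contents |
| --- | --- |
| `turntaking.event_model` | domain types, TSV readers/writers, inter-rater agreement (60%-overlap segment matching + Cohen's κ) |
| `turntaking.transitions` | transition extraction, typing, signed timings, summary + model tables |
| `turntaking.dominance` | dominance matrix, David's scores, steepness, h′, I&SI |
| `turntaking.sociality` | dyad counts and DSI |
| `turntaking.models` | the four hierarchical models, covariate preparation, posterior summaries |
| `turntaking.synthetic_data` | seeded study generator + recovery experiments |
| `turntaking.cli` | the `turntaking` command |

See `docs/methods.md` for the modelling assumptions, parameter
defaults, and known limitations.
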