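# sirmix

Recalibrating homogeneous-mixing SIR models against stochastic epidemics on
temporal contact networks.

## The problem

Large-scale epidemic models (including agent-based models) routinely assume
homogeneous mixing inside schools, workplaces and other closed settings: every
individual meets every other at the same rate, so a susceptible is infected at
rate `beta * I(t)/N`.  Wearable-sensor deployments show that real face-to-face
contacts in such settings are nothing like that — they are bursty,
heavy-tailed in duration, concentrated on few partners, and structured into
groups (classes, departments).  `sirmix` asks, quantitatively: *if an epidemic
spreads on a real (or realistic synthetic) time-resolved contact network, what
homogeneous-mixing parameters best reproduce it, and how good can that
reproduction be?*

The pipeline:

1. **Contacts** — read SocioPatterns-style `t i j` event files (20 s
   resolution, groups in a sidecar metadata file), or generate synthetic
   networks with a memory-driven agent model over `Q` groups: links die with
   probability `dt·z/(1+tau_link)` and agents initiate contacts with
   probability `dt·b/(1+tau_agent)`, partners weighted by group affinity and
   recency.  The aging kernels give heavy-tailed contact and inter-contact
   durations; affinities are calibrated so within-group contacts are ~50×
   more frequent per pair than cross-group ones.
2. **Network SIR** — exact stochastic simulation by a temporal Gillespie
   scheme (per-contact transmission rate `beta_c`, recovery rate `mu_c`, the
   dataset repeated until extinction); `beta_c` is calibrated so the seed
   causes `R0_c` secondary infections in a fully susceptible population.
3. **Homogeneous SIR** — classic Gillespie for the mass-action model with
   `R0_h = beta/mu` in a population of the same size.
4. **Recalibration** — Levenberg–Marquardt fit of `(R0_h, mu_h)` minimising
   the cumulative squared difference between the two mean prevalence curves,
   then evaluation through the epidemic features peak time `T`, peak value
   `P`, epidemic size `alpha`, their relative differences
   `Delta_f = (f_h − f_c)/f_c`, the size power law `alpha_h = a·alpha_c^b`,
   and the linear recalibration laws `R0_h = a·R0_c + b`, `mu_h = d·mu_c + e`.

## Worked example

`examples/03_recalibrate_homogeneous.py` generates a 60-agent, 3-group
network (10 active days), calibrates `beta_c` for `(R0_c, mu_c) =
(1.4, 0.3456/day)`, computes the mean prevalence over 1000 network epidemics,
and fits the homogeneous model:

```
network inputs:        R0_c = 1.4, mu_c = 0.3456 /day
recalibrated best fit: R0_h = 1.53, mu_h = 0.58 /day
objective (cumulative squared difference): 0.0153
Delta_T = +0.41  (peak time 3.49 -> 4.92 days)
Delta_P = +0.01  (peak value 0.038 -> 0.038)
Delta_log_alpha = -0.23
```

Read: to mimic this network epidemic, a well-mixed model must recover
individuals about 1.7× faster (`mu_h ≈ 1.7 mu_c`) with a slightly larger
reproductive number; the recalibrated model then matches the peak height
almost exactly, while its peak arrives later than on the network — real
contact sequences ignite faster than mass action.  `Delta_log_alpha < 0` with
`alpha_h > alpha_c` reflects that the fitted model overshoots the final
epidemic size (the fit targets the prevalence curve, not the attack rate).

The other examples show contact generation and its summary statistics (01),
network epidemic features (02), and the recalibration laws across several
`(R0_c, mu_c)` points (04).  Each runs in roughly a minute or two.

A thin CLI mirrors the library for shell pipelines:

```bash
sirmix generate --groups 3 --group-size 20 --days 10 --seed 1 --out net.tsv
sirmix sir net --events net.tsv --r0 1.4 --mu 0.3456 --nreal 1000 --seed 2 --out curve.tsv
sirmix fit --target curve.tsv --n 60 --init-r0 1.4 --init-mu 0.3456 --seed 3 --out fit.json
sirmix experiment config.yaml   # resumable multi-dataset sweeps
```

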