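# Methods

## Model structure and assumptions

The package treats a tracer culture as two coupled systems. Inside the
cell, metabolite pools are small (0.1–20 fmol/cell) and turn over within
minutes, so their labelling is assumed to be at *isotopic steady state*
conditional on the current boundary enrichments. Outside the cell,
glucose, lactate and pyruvate pools are three orders of magnitude larger
(2–20 pmol/cell) and are *isotopically non-stationary*: they accumulate
or deplete over the experiment and their enrichment drifts. The
integrator alternates a steady-state intracellular solve with an
explicit-Euler update of the extracellular pools. Cell quantity is held
constant over the (≤ 5 h) time course — no growth term — and fluxes are
rates per µg protein times a fixed conversion; glucose enrichment is
held at its initial value while its concentration depletes (uptake does
not fractionate).

Metabolic steady state is enforced structurally: net fluxes are
parameterized in the null space of the stoichiometric matrix over
balanced (intracellular) metabolites, so `S·v = 0` holds for every
candidate during optimisation, never through a penalty.

## Labelling simulation

Intracellular MIDs are computed by EMU decomposition: backward tracing
of target atom subsets through the reaction atom maps yields a layered
network in which each EMU's precursors are boundary EMUs or EMUs of
equal/smaller size, with condensations appearing as convolutions. Each
size level is one dense linear solve; the balance matrices depend only
on the fluxes, so they are LU-factorised once per flux vector and reused
across all Euler steps (this is what makes the optimiser affordable).

Reversible reactions are split into unidirectional pairs with effective
fluxes `max(v,0)+e` / `max(−v,0)+e`. Rotationally symmetric metabolites
(succinate, fumarate) are handled by splitting every producing route
50/50 over the two atom orientations; consumption needs no special
treatment because the pool distribution is then orientation-symmetric.
CO₂ is an unlabelled infinite pool with no label return (no carboxylase
in the network, no bicarbonate measurement).

Pools are tracked as labelled *amounts* (concentration × MID), with
MIDs renormalised on read-out; per-step mass conservation is therefore
exact to rounding, and a cumulative carbon ledger (sources in; pools,
CO₂ and biosynthetic sinks out) closes to < 1e-6 relative in the test
suite. Where a pool feeds a cleaving pathway (lactate → pyruvate →
acetyl-CoA + CO₂), the pool's sub-molecule EMUs are integrated alongside
the full-molecule MID with the same update rule, which keeps the
boundary information positional where it needs to be.

An independent check is built in: a full positional-isotopomer solver
iterates the flux-weighted mixing map over all 2^n labelling states per
metabolite (Gauss–Seidel to 1e-13) and collapses to MIDs. It shares only
the unidirectional network expansion with the EMU path and agrees with
it to < 1e-8 on every bundled network over seeded random flux draws.

## The network

The bundled central-carbon network is a documented reconstruction, not a
published reaction list: glycolysis (G6P → 2 PEP → pyruvate), oxidative
PPP, LDH, reversible lactate and pyruvate transport, mitochondrial
pyruvate uptake, a canonical TCA cycle, glutamine → 2-oxoglutarate
entry, and cytoplasmic malic enzyme returning four-carbon units to
pyruvate. Glutamine stands in for *all* non-glucose carbon sources
(amino-acid catabolism, unlabelled TCA intermediates from the medium),
lumped through the ME1 flux; pyruvate carboxylase is omitted because
anaplerosis cannot be separated from glutaminolysis without TCA
enrichment data. The PPP is modelled as oxidative decarboxylation with
the pentose exported to biosynthesis rather than returned to glycolysis:
the non-oxidative return maps are not published for this model, the flux
is small, and a sink keeps the network atom-exact. Biomass drains are
neglected (short cultures).

The model file dialect is tab-delimited with inline parenthesised atom
maps, `@source`/`@pool`/`@symmetric`/`@normalize` directives, and
role inference for undeclared boundary metabolites; a column-separated
equation/atom-map form is also accepted. Elementary flux modes are
enumerated by double description with exact rational arithmetic
(reversible reactions split; 2-cycles reported but flagged futile).

## Measurement model

Raw fragment spectra are corrected for non-backbone isotope interference
with a matrix built from IUPAC natural abundances (C, H, N, O, Si, S):
column *j* is the predicted spectrum of a species with *j* labelled
backbone carbons, including binomial natural ¹³C on the unlabelled
backbone positions. Correction is an unconstrained least-squares solve;
components below −10⁻³ (or, for the ~0.01-noise raw channel, below four
enrichment sigmas) raise a data-quality error, smaller negatives are
clipped with a warning and the MID renormalised. The elemental formulas
of the monitored MAB ions (pyruvate 142, lactate 115, gluconitrile 314)
are documented assumptions — they affect only the correction matrix.

Concentrations come from ordinary least-squares calibration lines
(residual variance = RSS/(n−2)); inverse prediction carries variance
`residual_variance / slope²`, which supplies the abundance weights in
the objective. Every enrichment fraction is weighted with a uniform
σ = 0.01, the error bound derived from natural-abundance standards.
Acetyl-CoA enrichment is inferred from citrate and malate fractional
labelling as `(6·FL_cit − 4·FL_mal)/2` — our one-line derivation of the
citrate = OAA (malate proxy) + acetyl condensation, clipped to [0, 100]
with a warning when the proxy is strained.

## Estimation and uncertainty

Free parameters are designated free net fluxes (the non-pivot columns of
the RREF of S — for the central network: net lactate efflux, net
pyruvate efflux, the TCA flux at MDH, glutaminolysis, and the PPP sink),
exchange fluxes in the bounded transform `u = x/(1+x) ≤ 0.9999`
(x ≈ 10⁴ cap; a profile upper bound that reaches the cap is reported
"unbounded above"), and initial pool concentrations. Parameters may be
shared across datasets; the FM/EM presets share all fluxes except the
lactate exchange, mirroring the assumption of identical pyruvate
producing/consuming fluxes between parallel experiments.

Two quantities are deliberately *not* estimated in the bundled presets.
The PPP flux is fixed: it is not identifiable from extracellular
lactate/pyruvate/glucose alone. The LDH exchange is fixed fast: LDH and
lactate transport act in series through unobserved intracellular
lactate, so only the combined conductance is identifiable — the
estimated transport exchange is that combination, which is what
"lactate exchange" means throughout. Glucose uptake is anchored to the
measured glucose depletion through the abundance residuals rather than
by a pre-computed slope — same information, one mechanism.

Optimisation is trust-region-reflective least squares with a seeded
Latin-hypercube multi-start (default 10). Profile confidence intervals
re-optimise all remaining parameters at fixed values of the profiled
one, bracket the `SSR_min + 3.84` crossing geometrically and bisect to
10⁻³ of the parameter scale. The shared-ratio test fits pooled
residuals twice (parameter shared vs per-dataset) and compares
ΔSSR to 3.84; Monte Carlo standard errors corrupt every measured value
with a Gaussian draw at its own σ, re-estimate from the optimum (50
replicates), and abort if more than 20 % of replicates fail.
Reversibility labels use CI-against-threshold comparison with the
cut-offs ≥ 20 (default preset) or ≥ 25 (figure preset) for fully
reversible and ≤ 0.05 for irreversible; both presets are kept because
the source material states both, and no adjudication is attempted.

## Synthetic data: what it emulates and what it does not

The generator runs the forward model at the study conditions — FM/EM:
1 vs 10 mM initial lactate, 46.9 % vs 71.7 % labelled glucose,
30-min sampling over 3 h, 1-min steps; PANC-1-style: ~25 mM glucose at
~99 % labelling, hourly sampling over 5 h, 2-min steps — and corrupts
the samples with independent Gaussian noise: σ = 0.01 per enrichment
fraction and the calibration-curve σ per concentration. Noise is *not*
renormalised or clipped: renormalisation correlates the fraction errors
and inflates the variance along the M0/M3 contrast that identifies the
exchange, which would break the nominal level of the χ² profile
construction the fit relies on (and plain Gaussian corruption is what
the in-silico replication procedure specifies). Measured MID rows may
therefore sum to 1 only up to noise, exactly like real corrected data
fitted under an independent-error model.

The synthetic experiments do not emulate chromatogram-level effects
(peak integration, retention drift, detector saturation), derivatization
yields, natural-abundance backbone enrichment of the tracer mixture
(available via `natural_p` but off by default), cell growth, or
concentration-dependent transporter kinetics. Passing tests therefore
demonstrate the correctness and calibration of the *analysis* under its
own assumptions, not robustness to instrument artefacts.

Default scenario fluxes are order-of-magnitude physiological choices
(glycolysis at PK ≈ 1.2, ME1 ≈ 0.4, net lactate efflux ≈ 0.8 µM/h/µg
protein, 150 µg protein per 2-ml culture), with a default lactate
reversibility ratio of 4 — scenario parameters, not fitted values.

## Numerical choices and problem sizes

Euler steps: 1 min (HEK-style) and 2 min (PANC-style) defaults, fixed
grid, no adaptivity; measurement times must lie on the grid (enforced,
not interpolated). A pool driven below zero raises an explicit
instability error. MIDs are clipped at −10⁻¹² and renormalised; MID sums
are asserted to 10⁻⁹. The EMU/oracle comparisons use 20 random flux
draws per network at 10⁻⁸ tolerance.

Estimation-heavy checks run on coarser grids chosen so that generation
and fitting share the same grid (self-consistent, no discretisation
bias): 6-min steps for the noiseless FM+EM recovery (13 parameters,
recovery to 10⁻⁴ relative), 10-min steps for the 50-replicate
profile-CI coverage check, which frees the three scientifically central
parameters (net lactate flux, lactate exchange transform, initial
lactate) and decides coverage by the profile criterion itself —
truth is covered iff the SSR re-optimised with the exchange fixed at
its true value stays within 3.84 of the minimum, which is equivalent to
locating the CI endpoints and ~10× cheaper.

## Known limitations

* The intracellular steady-state assumption breaks in the first minutes
  after tracer addition; early time points carry that bias.
* Exchange fluxes estimated from a single design have very soft upper
  limits (the `x/(x+1)` saturation); designs contrasting pool sizes
  (FM vs EM) are required to bound them.
* The network is deliberately minimal: TCA-intermediate effluxes,
  alanine/aspartate secretion and CO₂ refixation are absent, so their
  carbon is attributed to neighbouring lumped fluxes.
* Measurement tables must provide corrected MIDs or raw spectra of the
  three monitored fragments; other analytes are out of scope.
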