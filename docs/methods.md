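# Methods

## The model

`cfekit` models cell-free gene expression (CFE) in a reconstituted
transcription/translation mix as a coarse-grained, resource-limited kinetic
system. Five states evolve in time: transcript concentration `RNA` (nM), a
transcription resource pool `TsR`, a translation resource pool `TlR` (both
unitless, initialized at 1 and monotonically driven toward 0), immature
reporter protein `P_dark`, and mature fluorescent reporter `P_mat` (nM). The
DNA template is a constant input — the model text names no DNA sink, so no
template degradation is included.

The full structure (variant V1) is

    v_tx = k_r · TsR · DNA / (K_r + DNA)
    v_tl = k_p · TlR · RNA(t − τ_d) / (K_p + RNA(t − τ_d))

    dRNA/dt    = v_tx − δ_r · RNA
    dTsR/dt    = −a · v_tx − δ_TsR · TsR
    dTlR/dt    = −b · v_tl − δ_TlR · TlR / (K_l + TlR)
    dP_dark/dt = v_tl − k_mat · P_dark
    dP_mat/dt  = k_mat · P_dark

The resource pools are phenomenological proxies for everything that fuels
transcription and translation (polymerase and ribosome activity, NTPs,
amino acids, energy regeneration): they are consumed in proportion to the
synthesis fluxes (scaling factors `a`, `b`, per nM synthesized) and decay
spontaneously on their own — first-order for TsR, Michaelis–Menten for TlR.
Because `K_l` at the bulk fit is ~1e-6, TlR decay is effectively
zeroth-order until TlR reaches 0, which is what produces the hard protein
plateau. Translation is a delay term: the flux at time `t` uses the
transcript concentration at `t − τ_d`, with constant history
`RNA(s) = rna0` for `s ≤ 0` (purified-transcript experiments therefore
begin translating immediately after the delay). The same lagged transcript
value is used in the TlR-consumption term, for consistency. A measurement
lag `τ_l` is a pure reporting-time shift: a data point at time `t` reads
the model at `t − τ_l` and reads 0 before `τ_l`. It is a fit parameter
for encapsulated experiments (sample preparation takes ~0.5 h), fixed to 0
by default for bulk plate-reader runs.

Seven structural variants are enumerated for model selection, spanning the
two axes the modelling question poses — kinetic law of the synthesis fluxes
(Michaelis–Menten vs mass action) and the resource-decay structure:

| code | tx law | tl law | TsR decay | TlR decay |
|------|--------|--------|-----------|-----------|
| V1 | MM | MM | first-order | MM |
| V2 | MM | MM | none | MM |
| V3 | MM | MM | first-order | first-order |
| V4 | MM | MM | none | first-order |
| V5 | mass action | MM | first-order | MM |
| V6 | MM | mass action | first-order | MM |
| V7 | mass action | mass action | first-order | MM |

V2 (no TsR decay) is the classic resource-limited reference structure;
V1 adds independent exhaustion of transcription resources.

Reference parameter sets ship with the package: `BULK_MLE` (fit to bulk
DNA/RNA titrations; e.g. k_r = 2894 nM/h, K_r = 3.67 nM, δ_r = 0.0392 1/h,
τ_d = 0.433 h) and `CELL_MLE` (fit to liposome populations, with
τ_l = 0.457 h). The maturation rate k_mat = 2.15 1/h comes from an
independent maturation assay and is held fixed in all fits.

## Numerical integration

The delayed system is integrated with a fixed-step classical Runge–Kutta
(RK4) scheme on a grid commensurate with the delay: the step is
`h = τ_d / m` with `m` chosen so `h ≈ 0.002 h` (7.2 s). The lagged
transcript at a grid node is then exactly a stored node value `m` steps
back; the half-step stage times use cubic Hermite interpolation between
stored node values and derivatives, clamped at 0 (the interpolant can
overshoot near kinks). For `τ_d < 1e-3 h` the system is integrated as a
plain ODE with the lag evaluated at the current time. The kernel is
JIT-compiled (numba), which is what makes multistart fitting and profile
likelihoods affordable on one CPU.

This design was chosen over an adaptive method-of-steps solver for
determinism (bit-identical trajectories independent of error-controller
history — seeded fits reproduce exactly), simplicity of the lag lookup, and
speed. Accuracy is verified rather than assumed: against the closed-form
linear birth–death limit (frozen resources, saturated transcription;
agreement ~1e-7 relative), against a tightly-toleranced adaptive ODE solve
in the τ_d = 0 limit (< 1e-6 normalized), and against an independent
explicit-Euler reference at step 1e-4 h over the full 8 h bulk trajectory
(< 1e-3 normalized maximum error; the bundled study reports ~4e-5).

After every accepted step, states are clipped to their domain
(concentrations ≥ 0, resources in [0, 1]). Resource clips at the TlR = 0
absorbing boundary are expected whenever `K_l` is small (the decay rate
stays finite as TlR → 0, so each step overshoots by ~δ·h) and are logged
at debug level; concentration clips above 1e-9 nM are warned about. The
RHS also clamps its inputs to the domain so intermediate Runge–Kutta
stages near the boundary cannot produce negative fluxes. Likelihood
evaluations run the integrator in quiet mode because optimizer excursions
to extreme parameters routinely trigger clips.

Fitting uses a coarser step (`h ≈ 0.008 h`): the fourth-order error at
that step is orders of magnitude below the 2% measurement noise, and it
cuts fit time ~4×. Data generation always uses the fine default.

## Likelihood and noise model

The likelihood is independent Gaussian per channel (mRNA, protein), per
time point:

    NLL = Σ_channels [ n_c/2 · log(2π σ_c²) + RSS_c / (2 σ_c²) ]

No noise model is prescribed by the experimental setup, so the package
chooses: when replicates exist, σ_c is the replicate SD pooled over time
points (weighted least squares with a data-determined constant scale);
without replicates, σ_c is profiled out analytically, giving the
concentrated form `n_c/2 · (log(2π·RSS_c/n_c) + 1)`. A fixed-σ mode is
available. The constant-σ Gaussian is an approximation when the generator
injects proportional noise; it is adequate for point estimation but means
single-dataset CIs are approximate (coverage of the CI machinery itself is
verified on an exactly-specified toy).

Integration failure or non-finite output at extreme parameters returns a
large finite penalty (1e12) instead of raising, so optimizers continue.

## Fitting strategy

Optimization is over log10-parameters in a box (default [1e-8, 1e8] per
parameter; the bundled studies use physically informed per-parameter boxes,
e.g. synthesis rates in [10, 1e5] nM/h, decay rates in [1e-3, 10] 1/h).
Multistart works as follows: a seeded Latin-hypercube sample (default 128
points) is screened by plain NLL evaluation; the best candidates, subject
to a minimum mutual log-distance of 1 so they cover distinct basins,
become starts. Each start is refined in stages that exploit the model's
one-way coupling — RNA dynamics contain no feedback from translation — so
the transcription parameters (k_r, K_r, δ_r, δ_TsR, a, τ_l) are first
fitted against the RNA channel alone, then the translation parameters
against the protein channel, then everything jointly with L-BFGS-B
(numeric gradients, step 1e-6 in log10 space) and a Nelder–Mead polish.
The staged pass is what makes fits reliable: the joint landscape has a
known local basin in which fast RNA degradation (δ_r ≈ 0.65 1/h instead
of 0.039) mimics resource exhaustion, and the RNA-only stage usually
avoids it. Everything is deterministic given (data, config, seed).

AIC is `2k + 2·NLL̂` with `k` the number of free kinetic parameters;
channel noise scales are treated identically across variants and not
counted (a constant offset cannot change the ranking). Ties break toward
smaller `k`, then variant code.

In the model-selection study a second pass refits every variant
warm-started from the first pass's overall winner, projected onto each
variant's active parameter set (missing parameters start at the geometric
mean of their bounds). All seven variants get the identical treatment, so
the comparison stays fair; the pass exists because V1 effectively nests
the simpler variants within the bounds, and without it a variant could
lose purely through an unlucky multistart.

## Profile likelihoods and confidence intervals

The profile of parameter θ_i is the NLL minimized over all other free
parameters with θ_i fixed, evaluated on a log-spaced grid spanning one
decade either side of the estimate (the identifiability window the
reporting convention refers to). Grid points are visited outward from the
estimate in both directions, each re-optimization warm-started from its
neighbour; failed points are flagged, not fatal.

The 95% CI is the connected region around the estimate where the profiled
NLL stays below `NLL̂ + χ²(0.95, df)/2`. Crossings are located by monotone
(PCHIP) interpolation in log-parameter space within the bracketing grid
interval; a side that never crosses inside the window is reported as ±∞,
meaning the parameter is non- or weakly identifiable within one decade.
The default `df` is the number of free model parameters, a deliberately
conservative convention that yields wider-than-pointwise, simultaneous-style
intervals; `df = 1` produces conventional pointwise intervals and is
available everywhere.
CI endpoint accuracy is limited by grid resolution: for sharply identified
parameters the crossing falls inside the first grid interval, so narrow
intervals should be read as order-of-magnitude statements unless the grid
is refined (`n_grid`).

The machinery is validated against closed forms: a quadratic NLL
`((θ−1)/0.1)²/2` yields 1 ± 0.1·√χ²(0.95, df) for df ∈ {1, 12} to 1e-3,
and an exact ridge (θ₁·θ₂ = const) profiles flat and reports (−∞, +∞).
Coverage is checked by simulation on a 1-parameter Gaussian-mean problem
(150 replicates through the real profile/CI code path, ≥ 90% observed at
nominal 95%); running full-model coverage replicates was judged not worth
minutes of CPU per replicate given the machinery is exercised identically.

## Synthetic data generator

The generator is the package's study-condition definition, not a tuning
surface.

**Bulk titrations** simulate each template level once (default DNA levels
0.94/1.875/3.75/7.5 nM around the observed ~3.75 nM saturation point;
8 h sampled every 10 min like a plate reader) and add independent Gaussian
measurement noise per channel and time point — proportional with CV 0.02
by default, the order of the endpoint CVs seen in calibrated population
data — truncated at zero. Noise-free output is bit-identical to the
deterministic simulation.

**Populations** emulate monodisperse microfluidic liposome populations:
per-cell radius ~ Normal(30.4 μm, CV 0.064) truncated positive, a single
per-cell multiplicative expression factor ~ Normal(1, CV 0.022) applied to
both observed channels, an optional per-batch factor ~ Normal(1, CV 0.10),
the cell-fit parameters including the τ_l ≈ 0.46 h measurement lag, and
per-time-point measurement noise. Radius does not feed back into the
kinetics: concentrations are intensive and no radius–expression coupling
is imposed (a hook exists but is off).

The per-cell factor acts on the *observable* scale rather than on the rate
constants. This is a deliberate design choice, made because the defining
feature of the data being emulated is that the CV is preserved from mRNA
to protein. Routing the same factor through (k_r, k_p) — the obvious
mechanistic alternative, available as `variability_mode="kinetic"` — is
distorted by the resource nonlinearity: at the cell-fit parameters a 5% CV
on the rate constants produces endpoint RNA CV ≈ 0.016 but protein CV
≈ 0.076 (transcription output is compressed by the finite TsR budget,
protein output is amplified because more transcript and faster translation
compound). A generator emulating the observed uniformity must therefore
scale the outputs; the kinetic mode is kept for sensitivity studies.

What the generator deliberately does not emulate: membrane transport
between the outer feeding solution and the lumen, crowding effects,
image-level artifacts (inputs are already per-cell tables), correlated
noise across time points, and copy-number stochasticity (at ~30 μm radius,
nM concentrations correspond to 1e5–1e8 molecules per vesicle, so
low-copy noise is negligible). Passing round-trip tests therefore show
the pipeline is self-consistent under these assumptions, not that real
microscopy data satisfies them.

## Bundled studies and their problem sizes

The reproduction script and the acceptance-style tests run fixed study
designs (all sizes are package choices, stated here for reproducibility):

* **Solver accuracy** — bulk parameters, DNA 3.75 nM, 8 h, Euler reference
  at 1e-4 h, compared on an 801-point subgrid.
* **Parameter recovery** — 20 seeds; per seed a 3-level DNA titration
  (0.94/1.875/3.75 nM) in triplicate at 2% noise; 9 free parameters
  (k_r, K_r, δ_r, k_p, K_p, δ_TsR, δ_TlR, a, b) with k_mat, K_l, τ_d fixed
  at their known values and τ_l = 0; 4 starts. Reported: median relative
  error of k_r, δ_r, k_p. K_l is held because it is non-identifiable at
  the reference values; the delays are structural and known here.
* **Model selection** — 20 seeds; per seed one replicate per level at 1%
  noise sampled every 20 min; all 7 variants, 3 starts each plus the
  warm-start pass. Reported: fraction of seeds where V1 wins.
* **Population round trip** — 20 seeds; 85 cells at the mid-titration DNA
  level with measurement noise off, so the configured per-cell CV is the
  only endpoint variability (measurement noise is a separate knob; with it
  on, the endpoint CV would be the quadrature sum and the comparison would
  conflate two settings). Reported: mean recovered radius/expression CVs
  and their deviation from the configuration in SE units.
* **Batch variability** — 10 batches of 40 cells, batch factor CV 0.10;
  recovered CV across batch-level endpoint means and peak translation
  rates (centered finite differences after a 3-point moving-average
  smooth — the differentiation scheme is a package choice, so batch CVs of
  rate-like quantities are mildly estimator-dependent).

## Known limitations

* The displayed equations reconstruct the model from its verbal
  description; the consumption terms (−a·v_tx, −b·v_tl) and the placement
  of K_l in the TlR decay are the simplest forms consistent with it.
* The constant-σ Gaussian likelihood is misspecified under proportional
  noise; parameter recovery is excellent (median errors ~2–3%), but
  single-dataset CI coverage can be off by a few percent.
* Profile-CI endpoints are grid-resolution-limited (see above).
* The multistart optimizer can miss the global basin in roughly 1 of 20
  replicates at the recovery-study budget; the studies report medians,
  which are robust to this failure mode.
* Real-data effects (batch drift within a run, membrane transport,
  photobleaching) are out of scope of the generator; fits to real data
  should revisit the noise model first.
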