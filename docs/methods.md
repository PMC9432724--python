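# Methods

## Model overview

`mitoloc` simulates single, non-interacting mRNA molecules of
nuclear-encoded mitochondrial genes in a yeast cell, from synthesis to
decay, and scores what fraction of each lifetime is spent localized to the
mitochondrial surface.  Localization is co-translational: an mRNA can bind
only while at least one of its nascent peptides carries a binding-competent
mitochondrial targeting sequence (MTS).  The model therefore couples two
stochastic processes — translation kinetics, which set when the mRNA is
binding-competent, and cytosolic diffusion, which sets when it is close
enough to bind.

### Translation

A transcript has `L` codons.  Ribosomes initiate at rate `k_init` (1/s)
when codon 1 is free, advance to the next codon at `k_elong` (codons/s)
when it is free (one-codon footprint exclusion; a TASEP with open
boundaries), and terminate at `k_elong` from codon `L`.  A ribosome at or
past codon `l_MTS = 100` has fully translated the MTS and cleared the exit
tunnel (up to ~70 aa of MTS plus ~30 aa of tunnel).  Two competence models:

* **instantaneous** — a translated MTS is binding-competent immediately
  (the `k_MTS → ∞` limit);
* **maturation** — each translated MTS becomes competent after an
  independent exponential delay with mean `tau_MTS = 1/k_MTS`, drawn
  inside the Gillespie loop.  Maturation represents folding of the
  amphipathic helix and/or chaperone engagement; it is gene-independent.

A single exponential decay clock at `k_decay` (default 0.0017 1/s, i.e. a
600 s mean lifetime, within the measured range of average yeast mRNA decay
times) runs during cytosolic life only and ends the trajectory.  Before
cytosolic life, the mRNA spends a nuclear residence drawn from a
Normal(60 s, 30 s) truncated to positive values (resampled if negative);
no translation or decay occurs in the nucleus, but nuclear time counts in
the lifetime denominators.

The event loop is an exact Gillespie simulation compiled with numba.  It
reports the full event log on request and always reports compact
summaries: the toggle times of the ">= 1 translated MTS" and ">= 1 mature
MTS" indicators, time integrals of ribosome/MTS counts, and the total time
each indicator was on.

### Geometry and transport

The cytosol around one mitochondrial tubule is modelled as concentric
cylinders (cross-section radii, in micrometres):

| region | radial extent | meaning |
|---|---|---|
| tubule | `r < r_m = 0.350` | reflecting mitochondrial surface |
| 1 (binding) | `r_m < r < r_a = r_m + 0.025` | close enough to bind |
| 2 (imaging) | `r_a < r < r_b = r_m + 0.250` | appears mitochondrial in diffraction-limited imaging |
| 3 (bulk) | `r_b < r < R_out` | rest of the accessible cytosol |

The 25 nm binding range combines the ~13 nm ribosome radius, a ~5 nm MTS
helix (31 aa at 0.54 nm pitch, 3.6 aa per turn) and a few nm of linker;
250 nm is the visible-light diffraction limit.  The outer wall is
reflecting and encodes the reported mitochondrial volume fraction `f_m`:
with 80% of the 42 µm³ cell volume accessible (nucleus and vacuole
excluded), `R_out = r_m / sqrt(f_m / 0.8)`.  `R_out` is the typical
half-separation between tubules of the mitochondrial network, not the cell
radius; network topology and cell-surface confinement are deliberately
ignored.  mRNA diffusivity is `D = 0.1` µm²/s, independent of gene, length
and ribosome load.

Transport is sampled event-wise rather than by fixed-step Brownian
dynamics.  Each region is an annulus with absorbing boundaries displaced a
buffer `eps = 0.010` µm *into* the neighbouring region (entries start
`eps` inside their new region, preventing vanishing time steps).  Because
region membership is purely radial, the problem is 2-D radial diffusion;
the axial coordinate is ignored.  For each region the first-passage-time
distribution — and, in region 2, the exit side — is drawn exactly from the
spectral expansion described under *Numerics*.

### Binding and unbinding

A competent mRNA crossing into region 1 binds at the crossing instant; an
mRNA that gains its first competent MTS while already inside region 1
binds at that instant and its scheduled exit is cancelled.  Bound mRNA
have no radial coordinate; translation continues unmodified while bound.
Binding is irreversible until the number of competent MTSs returns to
zero (all competent-MTS-bearing ribosomes terminated), whereupon the mRNA
is re-placed at a radius with density ∝ r on `[r_m, r_a]` (uniform over
the binding-shell cross-section) and a fresh region-1 exit time is drawn.
If another MTS matures before it leaves region 1, it re-binds immediately.
Decay ends a trajectory anywhere; time spent bound counts as region-1
(and imaging) localized time.

### Coupling by factorization

Translation kinetics never depend on position, and transport depends on
translation only through the competence indicator.  Each trajectory is
therefore generated in two exact stages: the full translation/decay time
course first, then the spatial event loop driven against the resulting
piecewise-constant competence indicator.  Because every translation clock
is memoryless, this is statistically identical to interleaving the two
processes and resampling translation times at each region change — but
each spatial first-passage time is drawn exactly once, and a realized
first-passage time is treated as a fixed future event that only a binding
or unbinding event can cancel.

### Localization measures

Two read-outs mirror the two experimental assays: *binding* localization
(fraction of lifetime in region 1, bound or unbound) and *imaging*
localization (regions 1+2).  Ensembles (default 50 trajectories) are
aggregated with lifetime weighting,
`f_loc = Σ_i f_loc,i T_i / Σ_i T_i`, with `T_i` the full lifetime
including nuclear residence — the probability that an mRNA enters a
measurement is proportional to how long it lives.  Cycloheximide arrest is
an analysis-time statistic, not a modified dynamics: the CHX localization
is the lifetime-weighted fraction of lifetime with at least one fully
translated (not necessarily mature) MTS, since arrested ribosomes leave
every translated MTS exposed indefinitely.

The binding-competent lifetime fraction of translation-only ensembles
includes nuclear residence in the denominator by default, consistent with
the lifetime definition above; whether that is the right denominator for
the competence statistic is genuinely ambiguous, so the estimator accepts
cytosol-only lifetimes as well (`include_nuclear=False` in the parameter
screen, or pass cytosolic lifetimes to `competent_fraction`).

## Closed forms

With ribosome exclusion neglected (valid at low occupancy) and a
deterministic post-MTS elongation horizon `t_max = (L − l_MTS)/k_elong`:

* mean translated-MTS count `beta = k_init (L − l_MTS) / k_elong`;
* mean mature-MTS count `beta_mature = (k_init/k_elong) {L − l_MTS −
  (k_elong/k_MTS)[1 − e^{−(k_MTS/k_elong)(L − l_MTS)}]}`;
* conditional maturation wait `mean_wait_time` (truncated-exponential
  mean) and the per-MTS competent exposure time `mature_exposure_time =
  (1/k_MTS)[1 − e^{−k_MTS t_max}(k_MTS t_max + 1)]`;
* mean diffusive search time to an absorbing inner cylinder
  `t_search = (1/2D)[r2⁴/(r2²−r1²) ln(r2/r1) − (3r2²−r1²)/4]`, which is
  the area-averaged mean first-passage time in the annulus.

Two bookkeepings of the mature exposure time exist: the default form above
(maturing fraction × conditional wait), whose `k_MTS → ∞` limit is 0, and
`mature_exposure_time_all_mts = t_max − (1/k_MTS)(1 − e^{−k_MTS t_max})`
(expected post-maturation exposure per translated MTS), whose limit is the
instantaneous exposure `t_max`.  They agree to leading order when
`k_MTS t_max ≪ 1`, the regime where maturation actually limits
localization; both are exposed and the default mirrors the conventional
form.  Small-argument series guard both expressions (and the wait time)
against catastrophic cancellation below `k_MTS t_max ≈ 1e−4`.

## Four-state model

The reduced model tracks competent/incompetent × near/far with rates
`k_S, k_U` (competence gain/loss) and `k_R, k_L` (arrive/leave), and no
bound-state departure (no direct transition from competent-near to
competent-far).  The stationary law has a closed form; the implementation
validates it against the null space of the explicitly assembled generator
and against a CTMC simulator.  `k_U = 0` or `k_L = 0` make part of the
chain absorbing and raise a degenerate-chain error; the rapid- and
slow-transport limits `f_s + (1−f_s) f_d` and
`1/(1 + (1−f_s)(1−f_d)/f_d)` are separate functions of the equilibrium
fractions `f_s = k_S/(k_S+k_U)`, `f_d = k_R/(k_R+k_L)`.

## Rate estimation

At steady state each mRNA produces protein at `k_init`, balanced by an
effective protein lifetime equal to the 90 min division time `T_div`, so
`k_init = alpha·P/T_div` for relative protein-per-mRNA `P`; `alpha` is
anchored on TIM50 (4095 proteins, 6 mRNA, P = 15.12), giving
`k_init,ref = 0.1264` 1/s and `alpha = 45.14`.  Ribosome occupancy enters
only as a ratio to the reference gene:
`k_elong = k_elong,ref (k_init/k_init,ref)(occ_ref/occ)` with
`k_elong,ref = 4` aa/s.  Occupancy units are arbitrary; when the reference
gene appears in an input table its occupancy defines the unit.  Rows
failing validation are dropped with named warnings; group membership
(conditional/constitutive) is always taken as input, never inferred.

## Synthetic cohorts

The generator emulates the two gene groups by drawing `(L, k_init,
k_elong)` log-normally around the group medians — conditional (L = 393,
k_init = 0.3253 1/s, k_elong = 14.5086 aa/s) and constitutive (L = 483,
k_init = 0.1259 1/s, k_elong = 7.7468 aa/s) — and inverting the
rate-estimation relations into `(P, occ)` columns, so estimation
round-trips exactly.  Only the medians are anchored in measurements; the
log-scale spread (0.4 for all three parameters) is a fixture choice, and
the draws are independent across parameters, which real cohorts are not
(length and elongation rate co-vary).  Tests passing on synthetic cohorts
therefore demonstrate correct mechanics and the median-level group
separation, not distribution-level agreement with any measured gene set.

## Numerics

* **Spectral first-passage sampling.**  Eigenmodes of radial diffusion on
  each annulus are order-0 cylinder-function combinations anchored at an
  absorbing boundary; eigenvalues come from bracketing sign changes of the
  remaining boundary condition on a grid of 1/16 the asymptotic spacing
  and polishing with Brent's method to 1e−14.  Mode norms, survival
  coefficients and boundary-flux (splitting) coefficients use the closed
  cylinder-function forms; 220 modes per region are kept and coefficient
  vectors are normalized so S(0) = 1 (series truncation otherwise leaves
  ~1% deficit for starts near a boundary).  Exit sides in region 2 are
  drawn from the exact logarithmic harmonic measure
  `ln(r_out/r0)/ln(r_out/r_in)`; exit times from the side-conditioned
  flux series.
* **Inversion.**  Sampling inverts the survival function by bisection in
  log-time to 1e−9 relative tolerance, with terms cut off once
  `D λ_n² t > 40`.  Below the resolvable floor `t = 8/(D λ_max²)` the
  sampler falls back to the flat-wall (half-space) survival
  `erf(d/√(4Dt))`, inverted analytically; fewer than ~0.1% of draws take
  this branch with the default geometry.
* **SDE oracle.**  An Euler–Maruyama integrator of
  `dr = (D/r)dt + √(2D) dW` with mirrored reflection and step 1e−5–1e−6 s
  is the assumption-light arbiter; the test suite requires the spectral
  samplers to agree with it (and with closed-form means) within three
  standard errors.  Per-geometry mode sets are cached.
* **Reproducibility.**  All randomness derives from
  `numpy.random.SeedSequence`: trajectory `i` of a run with seed `s` uses
  streams spawned from `SeedSequence(s, spawn_key=(i,))` (one 32-bit seed
  for the numba Gillespie kernel, one PCG64 stream for nuclear residence
  and transport), so ensembles are bit-reproducible regardless of
  execution order and any single trajectory can be replayed in isolation.

## Parameter defaults

| parameter | default | units | meaning |
|---|---|---|---|
| `l_MTS` | 100 | codons | MTS fully translated + exit tunnel cleared |
| `tau_MTS` | (choose; 40 s typical) | s | mean MTS maturation time |
| `k_decay` | 0.0017 | 1/s | cytosolic mRNA decay (600 s mean life) |
| nuclear residence | N(60, 30), > 0 | s | synthesis-to-export delay |
| `r_m` | 0.350 | µm | tubule radius |
| `r_a − r_m` | 0.025 | µm | binding range |
| `r_b − r_m` | 0.250 | µm | imaging range |
| `eps` | 0.010 | µm | propagator boundary buffer |
| `D` | 0.1 | µm²/s | mRNA diffusivity |
| `accessible_fraction` | 0.8 | — | cell volume available to cytosol+mitochondria |
| `T_div` | 5400 | s | effective protein lifetime (division) |
| `n_trajectories` | 50 | — | ensemble size per condition |

## Problem sizes

The test suite and `scripts/acceptance.py` use ensembles chosen to give
three-standard-error discrimination at desk scale: 50-trajectory ensembles
per condition (the package default), 200 parameter sets for the β ≈ 1
competency screen, 8–24 replicate trajectories for flux-balance and
occupancy checks, 4 000–30 000 draws per first-passage comparison, and
1 500–3 000 SDE walkers at 1e−5–1e−6 s steps.  Cohort-level simulations in
the tests use 10–24 genes per group with 12–20 trajectories each.

## Known limitations

* Uniform elongation rate along the transcript: no codon-specific speeds,
  stalling, or collision-induced decay.  A one-codon ribosome footprint;
  real footprints (~10 codons) would raise exclusion effects at high
  occupancy.
* The maturation step is a single memoryless clock; it stands in for
  folding/chaperone engagement without resolving mechanism.
* Geometry is a single straight tubule with a reflecting far wall;
  network junctions, tubule curvature and cell-surface confinement are
  ignored, and diffusivity is state-independent.
* One mRNA at a time: no competition for ribosomes, import sites, or
  chaperones; protein import itself is not modelled.
* Puf3-mediated (Class I) localization is out of scope.
* Closed forms neglect exclusion and are compared to simulation only in
  low-occupancy regimes.
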