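# Methods

`persisterkit` analyses antibiotic persistence — the survival of rare,
phenotypically dormant cells through bactericidal treatment — with four
analysis layers (kill curves, cytometry, single-cell traces, condition
sweeps) exercised on a bundled synthetic-data generator built around a
stochastic alarmone–GTP switch model. This note records the models, their
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## Two-compartment killing model

Population survival under a bactericidal drug is modelled as

    S(t) = (1 − f) e^(−k_s t) + f e^(−k_p t)

with persister fraction `f`, susceptible kill rate `k_s` (1/h) and persister
kill rate `k_p` (1/h, `k_p < k_s`). Fitting happens in log10-survival space:
kill curves span five or more decades, so least squares on the linear scale
would weigh only the first timepoints. Points at the plating detection limit
enter as one-sided censored residuals (penalised only when the model sits
above the limit), never dropped. Initialisation is an 8-point deterministic
multi-start over `f ∈ {1e-4 … 1e-1}` (log-spaced) with `k_s` seeded from the
early log-linear slope; ties are broken by residual sum of squares, then by
the smaller `f`. A single-exponential fit is always computed alongside and
compared by AIC; when the two-compartment model is not supported, the fit is
reported as non-biphasic with `f` pinned to the zero boundary.

Tolerance is the MDK99 (minimum duration for killing 99% of the population)
computed with persister subtraction: the persister compartment is removed
from the fitted survival, `S_adj(t) = (S(t) − f e^(−k_p t))/(1 − f)`, and
MDK99 solves `S_adj = 0.01`. For the fitted model this makes MDK99 a pure
property of the logarithmic killing phase (`ln 100 / k_s`); the closed form
is used when `k_p = 0` and a bracketed root solve (xtol 1e-12) otherwise.
"Logarithmic killing phase" is operationalised as the fitted susceptible
rate, since no explicit time window defines it.

Persister levels are reported by two first-class estimators — the fitted
plateau `f` and the 5-h endpoint survival — because published numbers are
sometimes one and sometimes the other. The serial-passage (spontaneous-only)
scenario is calibrated on the endpoint: its configured `f = 6.3e-4` yields
5-h survivors of 5e-4 (0.05%) under the persister kill rate below.

## Cytometry gating and sort-and-kill

Autofluorescence is handled by subtracting the control-table mean from every
event (negatives clamped at zero, counted). The low-GTP gate is *fold* ×
mean population fluorescence of the corrected events, default fold = 5,
anchored on the mean rather than the median deliberately; with a heavy
bright tail the mean-anchored threshold rises with the tail, which makes the
gated fraction slightly conservative — a sensitivity to keep in mind when
the bright weight exceeds a few percent. Whether the 5× rule applies before
or after subtraction is an open choice; the default gates corrected signal,
and an explicit `threshold_au` override (logged in the result) supports the
raw-gate sensitivity analysis. Antibiotic-induced low-GTP fractions are the
gated fraction after induction minus before, floored at zero with a flag.

Sort-and-kill emulates FACS: events are ranked by fluorescence, the top
fraction (default 0.1%) is split from the remainder, and each event forms a
colony with probability `e^(−k_p t)` (latently dormant) or `e^(−k_s t)`
(otherwise), drawn binomially. The latent labels exist only on synthetic
tables and are never consulted by gating.

## Single-cell analysis

Per-frame specific growth rate is `mu = (1/l)(Δl/Δt)`, computed as the
gradient of log length (centred interiorly, one-sided at the ends).
Divisions halve the length; adding `log 2` back at each division frame makes
log length continuous, bridging `mu` across divisions.

A dormancy entrance requires both an arrest and a bright reporter: `mu`
below 10% of the population median for ≥ 2 consecutive frames (both
constants configurable and reported), with fluorescence at or above the
bright gate at the arrest frame. The fluorescence-rise onset is found by
scanning backward from arrest for the last frame below half the gate. Runs
that reach the record end with fewer than the minimum frames are censored —
indistinguishable from crowding stops. For traces carrying stitched ancestor
history (below), an arrest must include the minimum run within the cell's
own frames; otherwise it belongs to the ancestor's trace.

Two trace-analysis constants differ deliberately from their cytometry
analogues. First, the bright gate for traces uses a 1%-trimmed mean: a
time-lapse record over-samples arrested cells (they persist to the end of
the movie, while growing cells divide away), so an untrimmed mean would be
dragged up by exactly the cells the gate should capture; a flow snapshot has
no such over-sampling, so the cytometry gate keeps the plain mean. Second,
reporter fluorescence at arrest is converted to an estimated GTP
concentration through an explicit inverse-law calibration `G ≈ c / F` with
`c` (AU·mM) a config constant fixed by the shipped calibration routine so
that the median arrest fluorescence maps to the dormancy threshold `G_thr`;
it exists so the 0.1–0.2 mM threshold band can be asserted in model units,
and it is not an independently measured standard curve.

Switch-like versus graded entry is decided by regressing growth rate on
fluorescence twice — linear `mu = b0 + b1 F` and decreasing Hill
`mu = mu_top / (1 + (F/F_half)^h)` — and comparing AIC (differences ≤ 2 are
flagged inconclusive). The Hill fit multi-starts over `F_half` quantiles
because the turnover often sits far into the bright tail. The comparison is
meant for imaging-study sample sizes (~100 traces, pooled frames;
`GrowthFluorescenceModel.sample_traces` reproduces that design, keeping all
entrance traces); on tens of thousands of noiseless frames AIC resolves
arbitrarily small curvature and the verdict degenerates to "any curvature at
all". In the bundled simulations the wild type gives a conclusive steep
sigmoid (h ≳ 5) while the alarmone-free, GTP-lowered mutant gives a shallow
graded relation (h ≲ 3, often statistically indistinguishable from linear —
the contrast of steepness, not always the literal linear-model verdict, is
the robust signature).

## The mechanistic switch model

No published equations exist for this system; the ODE/SDE system in
`mechanistic.py` is this package's construction, with each term anchored to
a stated qualitative mechanism: basal alarmone synthesis with self-activated
Rel, cooperative SasB self-amplification (Hill coefficient 3), optional
envelope-stress SasA input, alarmone-inhibited GTP supply, GTP consumption
by alarmone synthesis, GTP-saturable growth, and a CodY-logic low-GTP
reporter diluted by growth (equations in the module docstring). The
tetra- and penta-phosphate alarmones are collapsed into one species `P`;
the distinction matters only for SasB allostery, which the single-species
Hill term already captures.

Noise is a single extrinsic Ornstein–Uhlenbeck process per cell
(`sigma_eta = 0.40`, `tau_eta = 30` min), entering as the lognormal-positive
factor `Λ = exp(x − σ²/2)` on both alarmone synthesis and growth rate. One
multiplicative, autocorrelated factor is the minimal structure that makes
spontaneous entry rare (~3e-4 per division) yet abrupt; intrinsic
molecule-number noise is omitted because the modelled concentrations (µM/mM)
are far from single-molecule regimes. The noise state is inherited at
division (`x_inherit = 1`); lower values model partitioning noise but
shorten the effective excursions that drive switching. Full inheritance
makes entrance events cluster in related cells (sisters sharing a committed
high-alarmone state both arrest), so entrance counts are modestly
over-dispersed relative to Poisson — visible in multi-seed count spreads.

With cooperative feedback (`n_B = 3`) the alarmone subsystem is bistable:
the growing state sits at `P ≈ 0.2 µM`, the dormant state at `P ≈ 26 µM`,
and flipping requires the noise factor to exceed ~3.5× for minutes — a rare
sustained excursion. GTP then collapses (supply inhibited), growth stops,
and the reporter rises. With `n_B = 1` (feedback disabled or the
allosteric-site mutant) there is a single fixed point and only graded
modulation. End-state GTP bimodality is checked with Sarle's bimodality
coefficient (>0.555 indicates more than one mode) computed on
`log10(G + 1e-3)`; the log scale with a small floor is needed because the
growing-state GTP spread is wide while the dormant state sits at ~0 mM.

Integration is Euler–Maruyama at fixed `dt = 0.1` min with a hard stability
guard (`dt` × fastest rate < 0.2) and a dt/10 convergence check in the test
suite; concentrations are clamped at zero with a counted warning (dormant
cells pin GTP at zero, so the counter is expected to be large in runs with
persisters — it flags pathology only when growing states clamp). Dormancy is
flagged when `mu < eps_mu` (default 0.004/min, 10% of `mu_max`) for at least
`tau_arrest = 30` min; the latent entrance time is backdated to the start of
the qualifying run. Division follows a doubling rule — a cell divides when
its length reaches twice its birth length, with 5% CV threshold noise — and
splits exactly in half, conserving concentrations; nothing is claimed about
division-size control beyond this.

Lineage simulations record every live cell at 15-min frames. When the live
population exceeds the cap (default 400), non-dormant lineages are uniformly
subsampled down to the cap (dormant cells always retained), mirroring
field-of-view crowding; recorded frames of culled cells are kept. Because a
lineage survives on average about one generation under the cap, cells
mid-way to dormancy can be culled, which lowers the per-division entrance
rate relative to independent-cell ensembles — the calibration therefore
targets the lineage pipeline itself. `to_traces` stitches up to 8 ancestor
frames onto each cell's record (division frames flagged), because reporter
induction typically spans more than one division and an entrance's rise
history otherwise lives in the mother's record; optional lognormal
measurement noise on length and fluorescence emulates segmentation and
photometry error.

### Calibration (scripts/calibrate.py)

Two constants are fixed by the shipped routine and stored in
`data/model_params.yaml`, not code:

* `sigma_eta = 0.40`, chosen so a wild-type lineage run of 30,000 division
  events yields ~10 detected entrances (equivalently ~3.3e-4 entrances per
  division, the rate consistent with a ~0.05% standing spontaneous persister
  fraction at balanced growth).
* `gtp_calib_au_mm = 14.12`, the AU·mM constant of the inverse reporter
  calibration above.

The phenomenological kill parameters are calibrated from printed numbers
directly: `k_p = ln(1/0.8)/5 ≈ 0.045 /h` from 80% persister survival after
5 h, `k_s = 4.6 /h` from an MDK99 of ~1 h for wild type under 20× MIC
vancomycin, and the alarmone-null `k_s` is `4.6/0.95` so its
persister-subtracted MDK99 sits exactly 5% below wild type.

## Synthetic-data generators

The kill-curve generator draws CFU by a serial-dilution plating emulation:
ten-fold dilution to a countable 30–300 colony range, Poisson colony counts,
a detection limit of 10 CFU/ml (0.1 ml plated), lognormal replicate scatter
on the inoculum (CV 20%, which cancels in survival ratios) and 5% per-point
technical scatter. In noiseless mode it returns the closed form exactly.
Default timepoints (0, 0.25, 0.5, 1, 2, 3, 5 h) place three points in the
susceptible phase and three on the plateau.

The cytometry generator draws events from a mixture: lognormal bulk
(median 100 AU, σ_ln 0.35), a rare bright dormant component at the
scenario's low-GTP weight (located 12× the bulk mean, σ_ln 0.40 — the
heavy tail), and additive lognormal autofluorescence; the control table is
autofluorescence alone. The wild-type low-GTP weight is 0.002, twice the
kill plateau: with a 0.1% sort cut this leaves ~0.1% dormant events in the
dim fraction, which is the only way the sorted-bright (~80%) and
sorted-dim (~0.1%) survival figures can hold simultaneously.

Scenario parameters (`data/scenarios.yaml`) tie each condition to kill
parameters, a low-GTP weight and a growth rate, each non-default number
carrying a citation anchor; the carbon-source sweep encodes growth rates
decreasing from glucose to glutamate, `k_s` decreasing with growth rate
(slow growth ⇒ tolerance), and persister levels varying independently of
growth rate but always at half the low-GTP weight — the structure that
produces the uncoupling pattern. The registry is append-only and versioned.

## What the generators do and do not emulate

Passing tests show that the analysis layer recovers what the generators
encode: biexponential killing with plating noise, mixture-structured
fluorescence, switch-driven traces. Real data depart in ways the generators
do not model: non-exponential early killing and regrowth after drug
removal; instrument spillover, drift and doublets in cytometry (no
compensation is attempted); segmentation failures and focal drift in
time-lapse; and any biology outside the alarmone–GTP axis (toxin–antitoxin
modules, SOS induction, ppApp). Agreement with the bundled generator is
therefore a check of internal consistency and statistical machinery, not
evidence about real measurements.

## Condition sweeps

Correlations are computed at replicate level (one row per replicate, three
per condition), not on condition means. Persistence and low-GTP fractions
are correlated on the log10 scale (they span decades); growth rate, MDK99
and mean fluorescence on the linear scale. The four headline verdicts
(growth↔tolerance, growth↔persistence, low-GTP↔persistence,
low-GTP↔tolerance) use two-tailed Pearson tests at α = 0.05 with no
multiplicity correction, matching standard practice for this panel size.

## Numerical and degenerate-input choices

* Biphasic fits transform to (logit f, log k_s, log k_p); compartment swaps
  (`k_p > k_s`) are relabelled.
* An all-equal event table gates nothing (threshold 5× mean exceeds every
  event; an all-zero table gates nothing by explicit rule).
* Zero variance in a correlation returns NaN rather than raising.
* A lineage whose live cells all go dormant before the target division
  count returns the partial record with `shortfall=True`.
* Problem sizes in tests and the reproduction script (ensembles of 3–4×10³
  cells, lineage runs of 1–3×10⁴ division events, 10⁵–10⁶ cytometry events)
  were chosen as the smallest sizes at which the checked statistics are
  stable; all complete in minutes on one core.

## Known limitations

* The mechanistic parameter set is one calibrated point, not an inference
  from data; other parameter sets could produce the same observables.
* Dormant cells pin GTP at zero and keep synthesising alarmone — below
  ~0.05 mM the model's concentrations are shape, not chemistry.
* Entrance counts are over-dispersed across seeds (noise-state inheritance);
  treat single-seed counts as order-of-magnitude.
* The switch-vs-graded verdict depends on sampling scale by construction of
  AIC; see the single-cell section.
* FCS ingestion is not implemented; event tables are CSV.
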