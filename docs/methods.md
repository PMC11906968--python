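# Methods

`camtransit` models a leaf as one guard cell (GC) coupled to many mesophyll
cells (MC) over a 24-hour cycle, and asks how the coupled metabolism
reorganises when transpirational water loss is forced down at fixed phloem
output — the metabolic trajectory from C3 photosynthesis to crassulacean
acid metabolism (CAM).

## The combined diel model

A single-cell stoichiometric network is replicated per diel phase and per
cell type. The six phases tile the day as dawn (0–1 h), mid-day (1–11 h),
afternoon (11–12 h), dusk (12–13 h), midnight (13–23 h) and end of night
(23–24 h); phases 1–3 are lit. Within each phase every internal metabolite
is at steady state (ordinary FBA), and phases are coupled only through
*linker* pseudo-reactions that carry the storage species — starch, malate,
sucrose, K⁺ and Cl⁻ — from each phase into the next, cyclically (phase 6
wraps to phase 1, which enforces diel closure: every pool returns to its
start-of-day value).

Units: reaction fluxes are rates (µmol·m⁻² s⁻¹ of leaf, per cell for
cell-internal reactions); linker variables are pool amounts. A linker out
of phase *p* carries stoichiometric coefficients −1/duration(*p*) and
+1/duration(*p*+1), which keeps each phase's balance row in rate units
while conserving mass across the unequal phase lengths (1/10/1 h day,
1/10/1 h night).

The two cell types share, per phase: an atmospheric CO₂ pool filled by a
stomatal intake reaction, an incident-light pool (bounded by the leaf's
light capacity, zero in dark phases), an apoplastic sucrose pool on the
MC→GC transfer path (the MC supplies sucrose, one of the GC osmolytes),
and the phloem sink. Mesophyll contributions to all shared pools are
scaled by the MC:GC cell-number ratio (default 300, within the anatomical
270–400 range), so MC fluxes are per single cell while shared balances are
per leaf area containing 1 GC.

Phloem output is fixed at a phase-uniform rate (default 0.05 sucrose
units·s⁻¹ plus 0.2 amino-acid units per sucrose); maintenance is a
constant ATP drain per cell and phase (default 0.01).

## Guard-cell osmotics, charge balance and stomatal conductance

Stomatal aperture follows GC osmolyte content. Per phase,

    g(p) = g_min + slope · S(p),      S(p) = 2·K⁺_pool(p) + sucrose_pool(p)

where pools are the linker amounts leaving phase *p*; a K⁺ counts twice
(cation plus its counter-anion), sucrose once. CO₂ intake in phase *p* is
bounded by g(p) and capped at g_max (default 1.5) — the finite capacity of
the stomatal apparatus.

Electroneutrality of the accumulated osmolytes ties the GC anion pools to
K⁺: per phase, with Δ the net pool accumulation and f the malate charge
fraction (default 0.90, from the ~50–90 % range malate covers as the K⁺
counter-ion),

    2·Δmalate = f·ΔK⁺        and        ΔCl⁻ = (1 − f)·ΔK⁺.

So nocturnal K⁺ accumulation *forces* GC PEPC/MDH activity (malate must be
synthesised), and daytime K⁺ release forces malate consumption — the
guard cell's own C3→CAM shift emerges from this constraint.

## Gas exchange and the water tally

Water vapour and CO₂ share the stomatal diffusion path. The water cost of
carbon in phase *p* is

    wpc(p) = 1.6 · VPD(p) / ΔpCO₂,    VPD = es(T)·(1 − RH),

with es the Tetens saturation vapour pressure, ΔpCO₂ = (Ca − Ci)·10⁻⁶·P
and Ci fixed at 0.7·Ca (linear coupling; default Ca 400 ppm, P 101.325
kPa). Transpiration runs through the open stoma whether or not CO₂ is
taken up, so the diel tally is conductance-based:

    W_total = Σ_p wpc(p) · duration(p) · g(p).

Because CO₂ intake is bounded by the same g(p) and pools are costly,
optimal solutions open exactly as far as uptake requires, recovering
W_total = Σ wpc(p)·duration(p)·CO₂(p) — while idle open stomata still pay
water. This is what drives the diel K⁺ uptake/release rhythm: holding the
osmolyte pool around the clock would transpire water for nothing.
W_total is the flux of a pseudo-reaction, so it can be minimised (WUE
maximisation at fixed output) or capped (water budget).

## The 2-step solution and the transition scan

Each state is solved in two steps: (1) optimise the primary objective
(phloem output, fixed by its bounds; or W_total for the C3 reference);
(2) fix that optimum and minimise the L1 norm of the enzymatic and
transport fluxes (parsimonious FBA), which selects a unique representative
flux distribution. The norm is **duration-weighted** — it measures total
catalytic turnover over the cycle, not instantaneous rates; otherwise
chemistry scheduled into the two 10-hour phases would look ten times
cheaper than the same chemistry in a 1-hour phase and the solver would
invert the schedule for bookkeeping reasons. The light-capture chain is
included at full weight (photosystems are protein machinery; pricing
photon-derived ATP/NADPH keeps the ME/PEPCK decarboxylation shuttle
cheaper than oxidising the acid and refixing every carbon), while the
accounting pseudo-reactions (stomatal intake, phloem drains, water tally)
are excluded. Storage linkers enter with a small weight (0.01 per unit
carried): holding pools is not free, so stores are emptied as early as
possible — the morning decarboxylation burst. Including the water tally
itself in the norm would collapse every scan point to the CAM extreme
(water coefficients are two orders of magnitude larger than enzyme
fluxes) and destroy the gradual trajectory.

The **C3 reference** minimises W_total with nocturnal stomatal intake
bounded to zero; its water loss is the scan's starting budget. The
**scan** then tightens W_total ≤ budget over a linear schedule (default 50
steps), re-solving the 2-step problem at each budget; the first recorded
point is the C3 reference itself. At the first infeasible budget the
feasibility boundary is bisected to relative tolerance 10⁻⁷ and the last
feasible point — the CAM endpoint — is re-solved there. The endpoint is
cross-checked against an independent single LP (minimise W_total with
night uptake free); the two agree to better than 10⁻⁶ relative. Feasibility
is monotone in the budget by constraint nesting, and step 2 never moves
the step-1 objective by more than 10⁻⁹ relative.

Solved with GLPK (simplex, deterministic, feasibility tolerance 10⁻⁹):
repeated runs give identical flux vectors.

## Classification of WUE-coupled activities

Each (reaction, phase, cell) flux series along the scan, ordered by
increasing WUE (= phloem output / water), is labelled by its Pearson
correlation with WUE: |r| > 0.9 strong up/down, 0.8 < |r| ≤ 0.9 moderate
up/down; a sign change across the trajectory (beyond a 10⁻⁹ solver-noise
floor) overrides as direction-flip; zero-variance series are unclassified
with undefined correlation. Spearman is available by flag; labels are
invariant to positive affine rescaling of the WUE axis.

## The synthetic leaf

The bundled generator builds a ~30-reaction carbon-bookkeeping cell:
light-activated Calvin-cycle carboxylation (lumped), glycolysis and
gluconeogenesis, the PEPC / MDH / ME / PEPCK shuttle (MDH reducing-only,
i.e. NADP-ME-type decarboxylation), starch/malate/sucrose stores, K⁺/Cl⁻
pumps with an ATP cost, lumped respiration, PPP and TCA options, a futile
-pair stress switch, maintenance, and a phloem sink of sucrose plus a
small amino-acid fraction (whose OAA demand gives the mesophyll its
daytime anaplerotic PEPC — the activity the malate-fraction sweep
compares against the guard cell's). Carbon numbers are integers and every
internal reaction conserves carbon exactly.

The default environment is an arid-like diel course sampled at phase
midpoints: temperature follows a half-sine over the photoperiod (25 ± 8
°C, peak at hour 6.5) and decays monotonically at night to a pre-dawn
minimum; relative humidity mirrors it (0.60 ∓ 0.25). Mid-day is therefore
the hottest, driest, water-costliest phase and end-of-night the cheapest —
the physical driver of the CAM advantage. The leaf light capacity (80
photon units·s⁻¹) bounds how much chemistry any one lit phase can run.

What the toy does and does not show: it reproduces the *structure* of the
transition — nocturnal CO₂ uptake rising from zero toward one, daytime
starch and nocturnal malate stores growing, carboxylation strongly
WUE-coupled at night and decarboxylation in the morning, the inverted GC
K⁺ rhythm, and a malate-charge-fraction plausibility limit located by
bisection — but none of the published model's absolute numbers (its water
losses are ~10⁶ µmol·m⁻²·s⁻¹ against the toy's ~10³, since the real
network's per-cell demands and the Indian-climate profiles are far
larger). Passing tests therefore validate mechanism and invariants, not
organism-scale flux values. Real-leaf features deliberately absent:
boundary-layer conductance and energy balance, vacuolar pH, circadian
regulation, succulence, and Rubisco oxygenation.

## Numerical and degenerate-case choices

* Default reaction bounds ±1000; linker pools capped only for sucrose
  (0.5 GC / 5·10⁻⁴ MC per cell: cytosolic sugar pools are osmotically
  constrained, starch is the bulk transient store).
* Fluxes below 10⁻⁹ are treated as zero in direction-flip detection.
* The bisection endpoint re-solve nudges the budget up by growing factors
  if the marginal LP is rejected at the tight two-step tolerances.
* Charge defaults to 0 with a warning when an input model omits it; the
  charge-balance builder requires nonzero charges for K⁺, Cl⁻ and malate.
* Tie-breaking among alternate optima is left to GLPK's deterministic
  pivoting after parsimony; reported tables are sorted by reaction id.

## Limitations

Linear conductance and fixed Ci keep the problem an LP; saturating
aperture laws or free internal CO₂ would need nonlinear programming. The
per-phase steady-state treatment hides within-phase dynamics (a 10-hour
phase is one flux vector). Short flanking phases (dawn, end-of-night)
enter or leave the solution basis discretely along the scan, so their
flux-vs-WUE correlations understate their biological gradualness.
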