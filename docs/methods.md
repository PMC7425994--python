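# Model and methods

`spheroidca` simulates multicellular tumour spheroids (MCTS) as a hybrid,
multiscale cellular automaton: discrete cell agents on a 3D cubic lattice,
coupled to continuous oxygen and drug concentration fields solved on the
same lattice. Treatments are a hypoxia-activated prodrug (HAP; modelled on
evofosfamide/TH-302 and its cytotoxin Br-IPM) and ionising radiation (IR)
under the linear-quadratic (LQ) model with oxygen enhancement.

## Lattice and cells

Each voxel (20 µm edge at full scale) holds at most one cell agent. A cell
carries a stochastic doubling time τ_i ~ N(µ = 40 h, σ = 4 h), redrawn on
the (astronomically rare) non-positive draws so the stated moments are
preserved, and an intrinsic clock that traverses G1 → S → G2 → M occupying
fixed fractions Θ = (11/24, 8/24, 4/24, 1/24) of τ_i. Hypoxia stretches G1
only, through the G1 Delay Factor

    G1DF(p) = 2                    for p < 1 mmHg
            = a1 + a2/(a3 + p)     for 1 ≤ p ≤ 10.5 mmHg
            = 1                    otherwise,

with (a1, a2, a3) = (0.9209, 0.8200, −0.2389). The G1 duration is
re-evaluated from the instantaneous local oxygen at every step (no freezing
at G1 entry); a side effect is that a cell's phase label can regress
briefly when oxygen drops, which we accept as part of the phenomenological
clock.

On completing M, a cell divides if a free voxel exists within its ν-th
order neighbourhood (ν = 3). Shells are "spherical" in either the Chebyshev
(Moore) or Manhattan (von Neumann) metric; each division flips a fair coin
between the two and fills the lowest non-full order, choosing uniformly
among its free voxels. Space-blocked cells become slow-cycling (in-vitro
mode; clock rate ×0.1 — the rate is unquantified in the source data, 0.1
is our choice) or quiescent G0 (in-vivo mode) and resume cycling when
treatment frees nearby space; such re-checks are event-driven (after
removals), since during pure growth no voxel ever becomes free.

The mother keeps her τ_i across cycles; daughters draw a fresh one.
Resting cells use the G0 radiosensitivity row (α(G1)/1.5, β(G1)/1.5²).

## Oxygen

Oxygen obeys ∂K/∂t = ∇·(D_K ∇K) + r_K·m − φ_K·K·cell with no-flux
boundaries; m marks exterior voxels (cell-free space face-connected to the
domain boundary — an enclosed hollow core is *not* exterior), cell marks
viable cells (dying cells occupy space and slow diffusion by the 1.5×
intracellular divisor but no longer consume). Because oxygen equilibrates
orders of magnitude faster than cells cycle, runs use the quasi-steady
solution, obtained directly as the sparse linear system
(−∇·D∇ + φ·cell) K = r·m (Jacobi-preconditioned conjugate gradients,
warm-started; refreshed every 5 h of simulated time once occupancy has
changed, and forced immediately before any IR dose). An explicit,
flux-form FTCS stepper with automatic sub-stepping to dt ≤ Δx²/(6 max D)
is retained for transients and solver certification; it is exactly
mass-conserving under no-flux boundaries.

All biology consumes the *scaled* field K̂ = K/max(K) · h_eff, which is
invariant to r_K. The scale ceiling h_eff defaults to 100 mmHg (the
best-oxygenated voxel is assigned physoxic-to-arterial oxygenation; the
alternative tabulated scaling constant of 0.5 mmHg is recorded in the
configuration but would place the whole lattice far below every response
threshold, so it is not used). Hypoxia is K̂ ≤ 10 mmHg, boundary included.

φ_K is not a published number; its default follows the ~100 µm oxygen
diffusion length (φ = D_intra/L²) and the reference-spheroid calibration
replaces it by bisection so the Small reference shows a configured
hypoxic fraction (default 5%, matching the mildly hypoxic appearance of a
20-day spheroid). The global `oxygen_scale_factor` multiplies K̂ wherever
it is consumed (G1DF, bioreduction, OMF alike).

## Prodrug pharmacology

HAP and AHAP obey coupled reaction–diffusion–decay PDEs. Bioreduction
converts HAP to AHAP at rate b·BRF(K̂) with BRF(p) = p50/(p50 + p),
p50 = 0.2 mmHg, and b = 1 h⁻¹ — so BRF is literally the fraction of
prodrug converted per hour. Decay rates are ln 2 / t_half with the
clinical half-lives 0.81 h (HAP) and 0.70 h (AHAP).

Diffusivities (default anchoring "mixed") implement the two defining
transport properties of this drug class: the inert prodrug is highly
mobile, D_HAP = 2·D_K with the tabulated D_K = 2.5×10⁻⁵ cm²/s, so a dose
floods the entire lattice within minutes and reaches the core of any
spheroid; the cytotoxin is short-lived and confined, D_AHAP =
η_AHAP·L_AHAP² with L_AHAP = 50 µm (half the oxygen diffusion distance),
so lethal concentrations form localised halos around activation sites and
bystander damage is an interface effect. The two published anchors cannot
hold simultaneously — D_AHAP = D_K/4 with the clinical decay rate implies
millimetre-scale cytotoxin penetration, under which all spatial
selectivity washes out — and both pure anchorings remain available as
options (`anchor="oxygen_table"` / `"lengths"`).

Reactions are integrated with the exact exponential solution of the local
linear ODE pair per diffusion step (Lie splitting), so HAP + AHAP is
conserved analytically when decay is off and both fields stay
non-negative at any step size. Diffusion uses backward Euler (CG on the
SPD operator) in production and the explicit sub-stepped scheme for
certification; at the physical prodrug diffusivity the explicit stability
bound would require ~3×10⁵ sub-steps per simulated hour, which is why the
implicit path exists.

Dosing: in vitro, the exterior (medium) voxels are held at the bath
concentration for the dose duration (default 2 h) and then released;
in vivo, the exterior voxels carry a source rate for the duration.
Overlapping doses superpose. A viable cell in any state — cycling, slow,
quiescent — is marked dying the moment local AHAP reaches the lethal
threshold Ψ. Concentrations are in arbitrary units, so Ψ ≡ 1 and only the
dose/Ψ ratio matters. Dying cells stop consuming oxygen immediately and
leave the lattice per the removal policy: never (in-vitro default),
instantaneously, or after one doubling time (T_L→R = τ_i). Drug fields
are integrated only while a dose window is active or either field exceeds
10⁻² Ψ anywhere; below that level no voxel can reach the kill threshold
again, and the integration is idle work.

## Radiotherapy

Survival of one dose d is S = exp(−d(OMF·α + d·OMF²·β)) with
phase-specific (α, β): G1 (0.351, 0.04), S (0.1235, 0.04), G2 and M
(0.793, 0), G0 (α(G1)/1.5, β(G1)/1.5²); OMF = OER/OER_m,
OER(p) = (OER_m·p + K_m)/(p + K_m), OER_m = 3, K_m = 3 mmHg. Each viable
cell survives by one independent Bernoulli draw at the dose instant;
casualties join the same dying/removal pathway as drug kills. No
sublethal-damage repair or post-irradiation cycle arrest is modelled.

## Dose calibration and the tolerated-dose bound

The prodrug dose is not a published number; it is calibrated so that one
HAP dose matches the expected 2 Gy IR kill on the Large reference
spheroid. The probe exploits linearity: one unit-dose drug simulation
(cytotoxicity off, oxygen landscape held over the short window) records
every cell's peak AHAP exposure; the kill set of dose C is then
{cells: C·peak ≥ Ψ}, and bisection over C is immediate. The bracket is
capped at the *maximum tolerated dose* — the largest dose whose
zero-dimensional, fully normoxic (100 mmHg) activation stays below Ψ;
beyond it the compound is no longer a prodrug in any meaningful sense. A
spheroid whose exposure distribution cannot reach the IR kill below that
cap raises a calibration error: the operational definition of
"insufficiently hypoxic for HAPs".

## Reference spheroids (reduced scale)

The published experiments treat ~10⁵-cell spheroids on a 100³ lattice;
those runs take hours. The test suite and worked examples use a reduced
preset: a 44³ lattice, a 0.1 h cell-clock step (still 400× below the
cycle timescale; the full-scale preset keeps the original 10⁻³ h, which
was tied to a coupled explicit oxygen update this implementation replaces
with the quasi-steady solve), a Small reference of 3,000 cells calibrated
to 5% hypoxia, and a Large reference grown from the Small until its
hypoxic fraction reaches 50%. The Large's hypoxic compartment must exceed
the ~45% expected 2 Gy IR kill: the published protocol calibrates the
drug dose against that kill *on the Large*, and only when the matching
kill fits inside the hypoxic compartment does the dose stay harmless to
the mildly hypoxic Small — the property the monotherapy comparison rests
on. At reduced scale this constraint, not a cell count, defines "Large"
(≈19,000 cells).

Because a reduced spheroid grows by a large relative amount between two
doses 48 h apart (its rim is a large fraction of its volume), treatment
comparisons are made growth-free: each dose contributes a survival factor
— the expected LQ survival at the IR instant, and the drug-casualty
fraction among the cells at risk at the HAP dose time — and schedules are
compared through the product of their factors. The scheduling comparison
additionally subtracts the no-interaction reference built from matching
single-dose controls at both dose times (a standard interaction
contrast); at full scale the dose-time drift this removes is negligible
and the contrast reduces to the plain arm difference. The reduced
scheduling gap is 12 h, the shortest of the published family — long
against drug clearance (≈4 h) and the 5 h oxygen-refresh cadence that the
scheduling effect rides on, short against reduced-scale regrowth. If a
neoadjuvant dose eradicates the population before the IR time point, the
combination course's surviving fraction is recorded as 0.

## Synthetic oxygen landscapes

For the landscape experiments every cell is assigned exactly 1 mmHg
("activator") or 100 mmHg ("bystander") and oxygen dynamics are frozen.
Layout A concentrates the activator fraction (default 10%, a visible
central core) in one concentric ball; layout B spreads it over 8 balls on
a jittered body-centred arrangement (the count is our choice; the source
only fixes the equal-count constraint). Cells are ranked by distance to
the nearest sphere centre and the top n_act become activators, so A and B
carry exactly equal activator and bystander counts and B's spheres have
equal radii by construction. The administered dose is the calibrated dose
raised, if needed, to the smallest dose that eliminates every activator
in both landscapes (with a 10% margin) — the regime in which the
bystander comparison is defined — and the identical dose is given to A
and B.

## Numerical choices

* Oxygen steady solves: CG to 10⁻⁷ relative residual in production
  (10⁻¹⁰ in tests), warm-started from the previous field.
* Implicit drug diffusion: CG to 10⁻⁹ on the backward-Euler operator;
  operators are reassembled only when occupancy has changed by more than
  max(50, 1%) voxels since the last assembly.
* Reduced-preset drug macro-step 0.1 h (equal to the cell step); the
  half-life measurements in the acceptance script use 0.005 h with
  log-linear interpolation of the halving time.
* Degenerate states: a lattice with no consuming cells has no oxygen
  steady state; the field is set uniform (its correct limit). An all-zero
  field cannot be scaled and raises.
* Ties and ordering: simultaneous schedule events execute in schedule
  order; division attempts iterate cells in stable index order; every
  stochastic choice draws from the single per-run generator, so runs are
  bit-reproducible given a seed and replicate seeds are spawned via
  `SeedSequence`.

## What the reduced tests do and do not show

The reduced suite demonstrates the mechanism structure — prodrug
selectivity for hypoxic cores, opposite composition shifts under HAP and
IR, reoxygenation-mediated schedule superiority, intensification growing
with hypoxia, interface-driven bystander effects — under the same model
equations and parameters as the full-scale preset, with three declared
reduced-scale accommodations (growth-free efficacy metrics, the 12 h
scheduling gap, the hypoxia-defined Large). It does not reproduce
absolute cell counts or timings of any laboratory spheroid (the oxygen
production/consumption rates behind those are unpublished), and agent
counts, not biology, limit how sharp the reduced spatial gradients can
be. Real tumours add vasculature, necrosis, mechanics, PK — all outside
this model's scope by design.
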