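# Methods

`melimm` is a stochastic agent-based model of B16-OVA melanoma progression in
a 2D section of mouse tissue, and of its response to adoptive transfer of
OT-1 CD8 T cells combined with agonist anti-CD137 (4-1BB) antibody. This
note records the model, its assumptions, the numerical choices, and what the
synthetic-data machinery does and does not emulate.

## Space and time

The tissue is an L×L hexagonal lattice (six neighbours per interior site)
with periodic left/right columns and rigid top/bottom walls. At full scale
L = 946 represents 60 mm × 60 mm, i.e. ~63 µm of tissue per site. Reduced
lattices (default L = 200 for desk runs, L = 100 in the test battery)
represent proportionally smaller sections: densities, doses, the tumor
inoculum, the sacrifice threshold and the infiltration burden limit are all
scaled by the area ratio `(L/946)²`, and the Gompertz growth constant is
shifted by `b·ln(area_scale)` so the reduced tumor follows the same relative
trajectory. The timestep is 8 hours (3 steps/day, shorter than every
characteristic time in the model); a run spans at most 33 days post tumor
injection (99 steps).

All interactions are site-local within one step: there is no action at a
distance between co-resident entities of different sites. Each step runs a
fixed 9-phase sequence (tumor growth, molecular decay/diffusion, agent
death, interactions, duplication, movement, homeostasis, treatment,
observables); agents are iterated in deterministic order and every draw
comes from one per-replicate generator, so a (config, seed) pair reproduces
bit-identically.

## Receptors

Specific recognition uses fixed-width bit-strings (`nbit_str` = 12; a
potential repertoire of 4096 receptors). Two binding sites "match" at every
position where their bits are complementary (lock-and-key; a receptor never
matches itself and matches its complement perfectly). An equality convention
is available behind `match_mode` for comparison. Binding probability is 0
below `min_match` = 9 matching bits, `affinity_level` = 0.05 at exactly 9,
and interpolates geometrically, `affinity_level^((12−m)/(12−9))`, to 1 at a
perfect match — smooth, endpoint-exact, and introducing no new constants.

Thymic education deletes self-reactive thymocytes (best self-match ≥
min_match) with probability `thym_eff` = 99.9%. The self-peptide panel is
drawn once per replicate; its default size is 6. With 12-bit receptors and
threshold 9, each self peptide covers 299/4096 ≈ 7.3% of the repertoire, so
6 peptides make ~36.5% of thymocytes self-reactive and leave a released
self-reactive fraction of ≈ 0.057% — comfortably below the 0.1%
physiological bound on circulating auto-reactive T cells. Larger panels
(≥ ~9) would push the released fraction above that bound, which is why the
default is deliberately small.

Antibody paratopes (and only they) hypermutate: each bit flips independently
with probability `hyper_mut` = 1e-4 per step when a plasma-cell daughter is
created.

## Cells and molecules

Cell types: B, helper T (TH), cytotoxic T (TC), conventional dendritic cells
(cDC; plasmacytoid DCs cannot present antigen and are omitted), macrophages
(M), endothelium (EP), natural killer cells (NK), plasma cells (P) and tumor
cells. Initial densities (per µL): B 260, TH 200, TC 434, cDC/M/EP/NK 351,
P 0; all leukocytes share a 3.3-day half-life. Molecules: IL-2 and
chemoattractant (CA) as per-site integer quanta (half-life 1.6 d), IgG
(23 d), antigen and immune complexes (ICs, 4 d) as per-site quanta tagged
with a bit-string, and anti-CD137 (23 d). Per-step death/decay probability
is `1 − 2^(−dt/half_life)` applied independently per agent/quantum. Tumor
cells have a 10-year half-life — effectively immortal.

Two representation choices matter:

- **Tumor cells are a per-site count field**, not individual agent objects.
  They are immobile, state-free and share one epitope, so the count field is
  an exact aggregation (per-cell death via binomial draws); it is what makes
  ~1e6-cell full-scale tumors tractable. `CellAgent` still supports type
  TUMOR for rule-level unit tests.
- **Anti-CD137 is a single systemic pool.** A circulating IgG equilibrates
  in plasma within minutes, far below the 8-hour step, so a spatial field
  carries no information; boosts consume one quantum each (mass balance) and
  the pool decays at the antibody's 23-day half-life. The i.p. bolus is
  quantised at 4000 quanta/µg (scaled by lattice area) — fine enough that a
  100 µg dose is never exhausted by boost consumption alone.

`density_scale` (default 195 at full scale) converts per-µL densities to
agent counts; it is chosen so the default L = 200 lattice carries ≈ 2×10⁴
leukocytes. Bone-marrow homeostasis refills each resting population to its
initial target every step (rate 1.0 × deficit), with fresh receptors and
thymic selection for T cells; plasma cells and tumor cells are never
replenished. Transferred OT-1 cells are excluded from the homeostatic
census so therapy does not suppress endogenous T-cell production.

## Tumor growth

Growth follows the Gompertz law in differential form, dx/dt = x(a − b ln x),
carrying capacity K = exp(a/b), advanced by forward Euler one step at a
time; the integer newborn count w = x_{t+1} − x_t is introduced on the
lattice each step (fractional parts carried in a residual). Newborns fill
sites adjacent to existing tumor, innermost first, at a per-site capacity of
8 cells, producing a compact expanding disk. Cell count and caliper
diameter interconvert through a disk model with 20 µm mean cell diameter:
`count = (diameter/cell_diameter)²`.

The inoculum is 0.5×10⁶ injected cells of which 60% die before settling,
so x₀ = 200 000. Shipped growth constants a = 0.39477, b = 0.028 per step
(K ≈ 1.33×10⁶ cells ≈ 531 mm²) were calibrated with the fixture pipeline in
`scripts/calibrate.py` so the untreated tumor crosses the 450 mm² sacrifice
threshold near day 29, inside the observed day 25–33 window; the in vivo
caliper series itself is not deposited.

Fitting: diameters → counts → log-space least squares against the closed
form ln x(t) = ln K + (ln x₀ − ln K)e^{−bt}. Since ln K enters linearly for
fixed b, the fit is a profile least squares (closed-form ln K inside a
bounded 1-D search over b), which is initialisation-free; a pure-exponential
(b = 0) alternative is fitted alongside and wins only if it has lower
residual. Supplying the known engrafted x₀ anchors the curve at injection
and roughly halves the (a, b) standard errors. The synthetic fixture
generator emulates the measurement protocol — each recorded diameter is the
mean of two perpendicular caliper readings with independent 5% lognormal
noise — which is what the recovery tests exercise (noise-free recovery to
<1%; with noise, median parameter error <10% over 100 seeds).

## Interaction rules

1. **B (presenting on MHC-II) + TH**: on a receptor/peptide bind the TH
   enters a 16-step duplication programme and secretes IL-2 (4 quanta); the
   B cell duplicates and its daughters differentiate into plasma cells
   (paratope hypermutated).
2. **M (presenting) + TH**: TH side only.
3. **cDC + antigen**: capture with probability 0.02/step; cross-presents on
   MHC-I and II. Macrophages capture antigen at 0.01 and ICs at 0.1,
   presenting MHC-II only; B cells capture antigen specifically through the
   BCR.
4. **Naive TC + presenting cDC**: primed (ACTIVE) on a receptor/peptide
   bind.
5. **Activated TC + tumor cell** (co-located): kill with probability
   bind × base_kill_prob × cd137_kill_mult(if boosted) × IL-2 factor. The
   IL-2 requirement is a saturating factor q/(q + k_half) × IL2_eff rather
   than a strict conjunction with anti-CD137 — a strict AND would erase the
   partial effect that activated OT-1 cells alone have. Effectors make up
   to 4 target contacts per 8-h step (serial killing) and arrest on
   tumor-occupied sites (conjugate formation) instead of wandering off
   mid-kill; both reflect measured CTL behaviour and are what lets a
   remnant be finished off rather than reaching a kill/regrowth
   equilibrium. A kill contact also triggers antigen-driven clonal
   expansion (probability 0.05 → 16-step duplication programme).
6. **Anti-CD137 + activated TC**: permanent boost of cytotoxicity (×1.5),
   duplication probability (×2) and chemotaxis sensitivity (×2), consuming
   one antibody quantum. Boost lasts the agent's lifetime (its 3.3-day
   half-life bounds it anyway).

Duplication: a DUPLICATING cell divides each step with probability
min(1, max_lfact/n_local) × IL-2 factor (lymphocytes) × boost multiplier,
for 16 steps (B_dup/TH_dup/TC_dup), then reverts. Immune complexes form
site-locally from co-located IgG and antigen quanta with the bind
probability of the paratope/epitope match (exact mass balance). Plasma
cells release 1 IgG quantum per step (the 10 ng/µL release rate mapped to
one quantum). Activated effector TCs secrete 1 IL-2 quantum per step
(autocrine); chemoattractant is released by tumor-proximal endothelium,
presenting (activated) macrophages, and activated OT-1 cells engaged at
tumor sites.

## Movement, chemotaxis, and the infiltration gate

Mobile cells step to the current site or a neighbour with weight
1 + sensitivity × CA(site); with a flat field this is an unbiased walk. TC,
TH, M and cDC are chemotaxis-sensitive (sensitivity 1.0; boosted TCs ×2).
Molecular fields diffuse by multinomial quantum splitting (CA fraction 0.3,
IL-2 0.2 per step), conserving totals exactly.

i.v. payloads enter through the vasculature: transferred OT-1 cells join a
circulating pool and extravasate each step — into tumor-proximal vessels
with the infiltration-gate probability, or into random endothelial sites at
a 5% background rate. A random walk from the wall rows could never reach a
central tumor within 33 days at any realistic lattice scale, while blood
recirculates in minutes, so vessel-mediated delivery is the only physical
reading; a "walls" entry mode (deposition on the rigid boundary rows, as
for the i.p. compound) is retained in the configuration. About 4% of an
i.v. dose traffics through the simulated section (`ot1_tissue_fraction`,
scaled by lattice area), putting ~2 500 OT-1 cells in a 2×10⁶-cell dose at
L = 200.

**The CD137 infiltration gate** is the model's core mechanism. T cells
enter tumor-occupied tissue (by extravasation at tumor-proximal vessels or
by stepping onto a tumor site) with probability `infiltration_prob_wt` = 0.6
when the tumor endothelium is in its CD137-ligated, T-cell-admitting state,
and with a residual leak of `infiltration_prob_ko` = 0.002 otherwise. The
competent state requires all three of: CD137 expressed on endothelium (wild
type), systemic agonist antibody present, and tumor burden below
`infiltration_burden_limit` = 4.3×10⁵ full-scale cells (crossed around day 6
untreated). The burden ceiling encodes loss of vascular competence in
established tumors and is what makes treatment timing decisive: day-3
therapy opens the gate while the tumor is still coverable, day-8 therapy
arrives after the window has closed, and the endothelial-CD137 knockout
never opens it regardless of antibody. Because Gompertz growth decelerates,
no burden-free calibration can make later treatment harder — the per-cell
growth rate is *lower* at day 8 than day 3 — so a gate of this form (or an
equivalent saturation mechanism) is required to reproduce the complete
failure of delayed combined therapy.

## Treatment arms and observables

Six arms (control; anti-CD137 100 µg i.p.; naive OT-1 2×10⁶ i.v.; naive +
anti-CD137; activated OT-1; activated + anti-CD137) at day 3 or day 8, in
wild-type or endothelial-CD137-knockout virtual mice. Control rat IgG is
inert. Observables per step: tumor cell count and disk-model area, per
type-and-state censuses, circulating and intratumoral TC counts (the latter
over the tumor's historical footprint by default, so infiltration remains
measurable while the tumor is destroyed), cumulative kills and newborns.
A replicate ends at strict rejection (0 tumor cells), sacrifice (area ≥
450 mm² × area_scale), or day 33; "almost total rejection" is reported
separately as the first day area falls below 1% of its running peak.

## Calibration and free parameters

Beyond the tabulated constants, the effect-size parameters
(base_kill_prob 0.65, cd137_kill/dup/chemo multipliers 1.5/2/2,
kill_attempts_per_step 4, dup_trigger_prob 0.05, il2_k_half 2, infiltration
probabilities and burden limit, antigen shedding 2×10⁻³/cell/step,
ot1_tissue_fraction 0.04, mab quantisation) are free by construction and
were set with `scripts/calibrate.py arms` so the reduced-scale battery
reproduces the qualitative arm outcomes: the three no-effect arms are
indistinguishable from control; activated OT-1 alone and naive OT-1 +
anti-CD137 reduce day-20 area without rejection; day-3 combined therapy
eliminates the tumor (majority of replicates, median elimination ≤ day 20);
day-8 combined therapy and the endothelial-KO combination fail, the KO with
clearly reduced intratumoral TC counts.

## What the synthetic data does and does not emulate

The growth fixture reproduces the caliper protocol (disk model, two
perpendicular readings, multiplicative noise) but not measurement censoring,
mouse-to-mouse growth heterogeneity (one shared (a, b) across virtual mice),
or palpability thresholds at small sizes. The immune model omits NK
effector function (NK agents exist, move and decay but have no rule),
immunoglobulin class switching, Treg/myeloid suppression, checkpoint
molecules, antibody effector functions, and anti-CD137 hepatotoxicity.
Passing the arm-level tests therefore shows the model reproduces the
qualitative treatment logic under the stated mechanism, not that it
quantitatively predicts in vivo curves.

## Problem sizes used

Desk runs and the reproduction script use L = 200 (≈ 4.5% of the full
tissue area, ≈ 2×10⁴ leukocytes, ≈ 9×10³ engrafted tumor cells); the
multi-arm test battery uses L = 100 with 10 replicates per arm. Full-scale
L = 946 runs are supported through the same configuration.
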