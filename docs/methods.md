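# Methods

This note documents the models, numerical choices and limitations behind
`isopart`, in the order data flow through the package.

## Isotope notation and the mixing model

All conversions use one fixed V-PDB ratio, R₁₃ = 0.0111802 (literature
values vary in the fifth decimal; a single stated constant beats silent
drift, and it is echoed in result rows as `standard_r13`). The identities
are exact: R = R₁₃·(δ/1000 + 1), F = R/(1 + R), and their inverses; round
trips are identities to floating-point precision (property-tested to
1e−12).

Two mixing modes are provided and recorded in every result:

- `delta_space` (default) — f_A = (δ_s − δ_B)/(δ_A − δ_B), the conventional
  form. δ is linear in R, not in atom fraction, so with a strongly enriched
  endmember this inversion is biased for interior mixtures. A warning is
  logged (once per endmember) whenever an endmember exceeds 2 atom %.
- `atom_fraction` — f_A = (F_s − F_B)/(F_A − F_B), the exact carbon mass
  balance. Preferred for a ~10 atom% label.

`mixing_mode_bias` quantifies the difference: it generates exact
atom-fraction mixtures on an f-grid and inverts them in δ-space. With both
endmembers within ±50 ‰ of V-PDB the maximum bias over a 101-point grid is
below 1e−3; with a 10 atom% endmember against natural-abundance biomass it
peaks near 0.024 at mid-mixture and vanishes at the endpoints. Whether a
given study applied the δ-form literally or converted internally is usually
unknowable from a methods section; both are provided and neither is
asserted as "the" computation.

Fractions perturbed outside [0, 1] by measurement noise are clipped, with
the raw value and a `clipped` flag retained; downstream sums use the
clipped values so that normalised source-specific quantities stay
non-negative. Endmembers closer than 5 ‰ (configurable) are rejected as
ill-conditioned. First-order noise propagation σ_f = σ_δ/|δ_A − δ_B| shows
why an enriched label is valuable: at 0.2 ‰ instrument accuracy and
~8960 ‰ separation, σ_f ≈ 2e−5.

## Gas processing

MIMS ion currents (m/z 32, 40, 44, 45) are expressed as ratios to the
biologically inert argon channel and treated as uncalibrated trend data —
they come from single unreplicated monitoring bottles; quantitative
partitioning uses only the replicated dissolved-CO₂ measurements. The
45/44 ratio is taken as ¹³C/¹²C with no ¹⁷O (Craig) correction: against an
enrichment signal of thousands of per mil the ¹²C¹⁷O¹⁶O contribution is
negligible. This is a documented approximation that should not be reused
for natural-abundance work.

Headspace equilibration reconstructs the original dissolved concentration
by partitioning total CO₂ between the ideal-gas headspace and the water
phase via a Weiss-type solubility polynomial (ln K₀ = a₁ + a₂(100/T) +
a₃ln(T/100), zero salinity, valid −1…40 °C; the constant-set name is
exported as `SOLUBILITY_CONSTANTS["name"]`). The underlying field method
papers rarely print their constants; the set used here is therefore named
explicitly rather than guessed to match any particular study.

Baseline subtraction is isotope-aware: net ¹³C = total ¹³C(final) − total
¹³C(initial), and the net signature follows. This removes a constant
air-equilibrated background exactly, whatever its δ.

## Partitioning, controls and interactive effects

Partitioning runs per replicate — never on the replicate-mean δ — and
replicate-level results are aggregated afterwards (mean, sd, n), which
preserves the error structure. Single-source controls bypass the mixing
model entirely (their fraction is forced to 1): they contain one carbon
source, and inverting noise around an endmember would only manufacture
spurious cross-attribution. Attributing zero-mass sources any carbon is an
error, since the per-mg normalisation would be undefined.

The control basis for a mixed treatment is the measured sum of the two
single-source controls when their masses match the treatment's; otherwise
each control's per-mg rate is scaled to the treatment's masses
(*pseudocontrol*). The two bases coincide exactly whenever per-mg rates are
mass-independent, which holds for first-order kinetics without priming —
this is verified against the simulator to 1e−6, limited only by integrator
tolerance. A mixture evaluated against controls of a different community
(e.g. a bacterial treatment against complex-community controls) is
computed as asked but flagged `control_community_mismatch`: its IE
conflates non-additivity with the community difference, and with weaker
kinetics it can legitimately be negative.

Treatment CO₂ is corrected by the blanks' mean net production before IE is
computed, making the statistic insensitive to substrate-free background
mineralisation. Only the concentration is corrected; the net signature is
left unchanged — exact when blank production is zero (the simulator's
default) and a stated approximation otherwise.

Carbon budgets close in mg C l⁻¹. Whenever an atom fraction is known,
µmol→mg conversion uses exact isotopologue masses (12.0000/13.00335 g
mol⁻¹, i.e. M(F) = 12 + 1.00335·F): a 10 atom% pool is ~0.8 % heavier than
natural carbon, and using M(F) consistently in both the simulator's
emission and the budget makes noise-free closure exact because mass is
linear in (n¹²C, n¹³C). With F unknown the natural-abundance 12.011 is
used. Residuals above 10 % (configurable) of initial carbon are flagged.
Note that the mixing model partitions carbon *atoms*; partitioning a bulk
mass by a mole fraction inherits the sub-pool molar-mass mismatch (≤0.8 %),
so exact mass-space recovery requires converting to moles first (the
pipeline does; the bulk-POC δ necessarily attributes biomass-bound carbon
to its original substrate, which is the physically meaningful reading).

## PLFA analysis

Compound vocabulary: i15:0, a15:0, cy-17:0, 16:1ω9, 18:1ω9c, 18:1ω9t/7c
(one token — the pair cannot be separated chromatographically), 18:2ω6,9.
Marker grouping clusters per-compound Δconcentration profiles across
treatments: profiles are standardised per compound, compared with
correlation distance (1 − Pearson), average linkage, cut at k = 2. These
specifics are a documented stand-in — field studies rarely state their
clustering scheme — chosen to mirror common PLFA practice; they are
validated only on the simulated fixture. Group labels are anchored
deterministically by canonical markers (18:2ω6,9 eukaryotic; i15:0, a15:0
bacterial) rather than by cluster index; if anchors split across clusters
the labelling is ambiguous and an error with diagnostics is raised. The
assignment is invariant to input order and uniform rescaling.

Compound δ¹³C replicates are pooled by concentration-weighted mean in
atom-fraction space, approximating the physical pooling of extracts that
low PLFA concentrations force in practice. Compounds without any measured
δ are reported as null with a `no_delta` flag rather than dropped.

## The incubation simulator

State (all µmol C l⁻¹): particulate daphnia carbon C_D, leaf carbon C_L,
daphnia leachate DOC, biomass sub-pools B_D and B_L (carbon derived from
each source), cumulative respired CO₂ per source. Dynamics:

    dC_D/dt  = −k_d·C_D
    dC_L/dt  = −k_l·(1 + p·B/(B + K))·C_L      (B = B_D + B_L)
    dDOC/dt  = −k_doc·DOC
    dB_s/dt  = y·U_s − m·B_s
    CO₂_s    = ∫ (1 − y)·U_s + m·B_s dt

with uptake U_D = k_d·C_D + k_doc·DOC, U_L = k_l,eff·C_L. Priming enters as
a Monod-type multiplier on leaf decay driven by total biomass: bounded,
saturating stimulation with a steady-state ceiling (an alternative
labile-uptake-driven form was rejected because it lacks one). Maintenance
respiration drains biomass sub-pools proportionally to their composition
(no fractionation), keeping isotope bookkeeping exact. No kinetic isotope
fractionation anywhere — the mixing model assumes none; a config hook
(`fractionation_alpha`) exists but only the neutral value is implemented.

Defaults and why (units per field):

- `duration_days = 11`, `n_replicates = 4`, `delta_sd_permil = 0.2` —
  the study conditions being emulated (11-day incubation, four replicates,
  stated IRMS accuracy).
- `f13_l = 0.10` (≈ +8938 ‰), `f13_d` ≈ δ −25 ‰ — a ~10 atom% labelled
  leaf substrate against typical fresh-biomass natural abundance.
- `k_d = 0.25 d⁻¹` — ~94 % of the carcass pool mineralised in 11 days,
  matching the observed near-complete degradation of bioavailable OM;
  `k_l = 0.02 d⁻¹` — a persistent pool losing ~20 % over the incubation.
- `priming_p = 2`, `half_sat_b = 20 µmol C l⁻¹` — up to threefold
  stimulation of leaf decay at saturating biomass; the bacterial presets
  scale `k_l` by 0.4 and `priming_p` by 0.15 (restricted lignocellulose
  access, weaker stimulation).
- `yield_y = 0.3`, `maintenance_m = 0.05 d⁻¹` — aquatic heterotroph carbon
  use efficiency in the commonly reported 0.2–0.4 band.
- `c_frac_d = c_frac_l = 0.45` — carbon content of dry OM.
- `doc_frac = 0.08`, `k_doc = 1 d⁻¹` — a small daphnia-leachate DOC pool,
  fully consumed well before day 11 (the leaves are pre-leached and
  contribute none); keeps final DOC in the deliberately-low range.
- `conc_cv = 0.05` — multiplicative lognormal concentration noise typical
  of replicate bottle variability plus analytical error.
- `co2_background_umol = 10` at δ −10 ‰ — air-equilibrated water CO₂,
  constant in time, removed exactly by the isotope-aware subtraction.
- `b0_umol = 0` — inoculum biomass carbon is negligible next to 6 mg l⁻¹
  substrate; starting at zero keeps every atom two-source so that
  atom-mode partitioning of noise-free emissions is *exactly* invertible,
  which is what makes the recovery tests sharp.

Integration is fixed-step classical RK4 at `dt = 0.05 d`. Because the
derivatives conserve each source total identically, conservation of ¹²C
and ¹³C holds to machine rounding (~1e−15 observed, tested against 1e−9);
halving `dt` moves cumulative CO₂ by <1e−6 relative. Any state below
−1e−12 aborts with guidance to reduce the step.

Measurement emission draws an independent seeded noise stream per table
(CO₂, POC, DOC, PLFA), so requesting a subset of tables never changes the
values of another; one root seed fans out per treatment and per table,
making studies byte-reproducible. Gaussian noise is applied in δ-space
(sd = `delta_sd_permil`); concentration noise is mean-preserving lognormal
(cv = `conc_cv`). MIMS series are emitted noise-free from one monitoring
bottle (trend data by design). PLFA emission maps carcass-derived PLFAs
(scaling with daphnia amendment, decaying with the carcass pool) plus
growth PLFAs (proportional to final biomass, split eukaryotic/bacterial by
community) onto the compound vocabulary with fixed within-group weights;
compounds below 5 ng l⁻¹ emit no δ (unmeasurable), exercising the null
path.

## What the simulator does and does not emulate

It reproduces: two isotopically distinct pools at the study's substrate
masses and ratios, saturating priming, community-complexity contrasts,
replicate structure, instrument noise, the full file set the pipeline
reads, and qualitative patterns (highest respiration in the 1:1 complex
mixture; per-mg daphnia utilisation rising as carcasses become scarce;
relative IE highest at low daphnia:leaf ratios).

It does not emulate: community-composition dynamics, grazing structure,
temperature dependence, O₂ limitation, kinetic fractionation, chitin or
other recalcitrant carcass fractions, DOC exchange with the particulate
pool beyond the initial leachate, or bottle-to-bottle biological
variability (replicates differ only by measurement noise). Passing
recovery tests therefore demonstrates the *analysis chain* is correct and
unbiased under stated noise — not that any particular field system follows
these dynamics, and not that a real study's printed percentages are
reproduced (its raw data are not public; magnitudes here depend on the
generator's rate constants).

## Open design choices taken

- Repository shape: importable library plus `examples/` scripts; no
  console CLI (the audience drives analyses from Python).
- The bacterial-vs-complex IE comparison keeps the (mismatched) complex
  controls, as field practice forces, with a flag instead of a refusal.
- IE null scope: the additive-null (IE = 0 at p = 0) is asserted only for
  community-matched treatments; a bacterial mixture against complex
  controls is non-additive for kinetic reasons even without priming.
- Problem sizes in tests and the acceptance script (101-point bias grids,
  200 Monte-Carlo measurement sets, 7 treatments × 221 integrator steps)
  were chosen as the smallest sizes at which the checked statistics are
  stable to well within their asserted tolerances.
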