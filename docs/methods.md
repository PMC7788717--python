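# Methods

## Model and scope

`oleaflux` works with compartmentalized, constraint-based metabolic models:
metabolites with elemental formulas (or annotated molecular weights for
pseudo-species), reactions with signed stoichiometries and flux bounds in
mmol·gDCW⁻¹·h⁻¹, and boolean gene–protein–reaction (GPR) rules. Exchange
reactions are written so positive flux is secretion and negative flux is
uptake. Reaction categories (exchange / transport / metabolic / biomass /
pseudo) are derived structurally — an exchange moves exactly one
extracellular species, a transport spans ≥ 2 compartments — rather than
trusted from annotations, so category censuses are robust to annotation
hygiene. Flux balance analysis (FBA) solves `max c·v` subject to `S·v = 0`
and bounds with the HiGHS solver; every optimal solution is re-verified
against `‖S·v‖∞ ≤ 1e-6` and the bounds before being returned.

## Condition-specific biomass objective

The central assumption is that under nitrogen starvation the dry-cell-weight
(DCW) composition of an oleaginous yeast is determined by the C/N ratio of
the *uptake rates* (chemostat logic: what is taken up is what is built in).
The partition is

- carbohydrate `w_C = 0.11` (constant under starvation),
- "other" (nucleic acids, minerals, cofactors) `w_other = 0.05` (constant),
- total lipid `w_TL = clamp(−0.002·x² + 0.59·x + 1.9, 0, 79)/100` with
  `x` = C/N in g C per g N — an empirical quadratic fitted to culture data,
  with its maximum at x = 147.5 (45.41% lipid),
- protein `w_P = 0.95 − 0.11 − w_TL` (the closure term).

The 79% clamp is exactly the point where `w_P` would go negative. Beyond
the vertex the quadratic is allowed to decrease (no plateau is imposed); at
extreme ratios `w_TL` is floored at 0. Inputs in mol/mol are converted with
the atomic-mass ratio 12.011/14.007 (so the critical ratio 12.83 mol/mol is
11.0 g/g). A nitrogen-replete "static" mode uses a fixed composition
(w_C, w_P, w_TL, w_other) = (0.40, 0.45, 0.10, 0.05); these replete numbers
are configuration defaults, not measurements.

The lipid fraction has a fixed internal profile: 90% TAG, 10% phospholipid
split equally among PS, PE and PC. Fatty acids enter through an artificial
acyl-CoA pool reaction whose coefficients (0.24952 C16:0 + 0.096712 C18:0 +
0.55233 C18:1 + 0.067963 C18:2 → pool) are weight percentages; they sum to
0.966525 and are normalized by that sum whenever true fractions are needed
(the stated per-acid percentages sum to 99%, and normalization reconciles
the two forms to within one percentage point).

Biomass assembly divides each component's mass share by its molecular
weight in g/mmol — protein as an averaged amino-acid residue (0.110),
carbohydrate as an anhydroglucose residue (0.162142), lipid species from
the acyl-profile-weighted mean acyl residue, "other" assigned 1.0 — so the
stoichiometric coefficients satisfy `Σ |coeff_i|·MW_i = 1 g/mmol` exactly:
one flux unit of the biomass reaction is one gram of biomass per gDCW per
hour, i.e. the growth rate in h⁻¹. Growth-associated maintenance (GAM)
enters the reaction as an ATP hydrolysis term, default 60 mmol ATP per g
biomass (adopted template value; configurable). Non-growth-associated
maintenance (NGAM) is a separate ATPase pinned to 1 mmol·gDCW⁻¹·h⁻¹.

## Simulation protocols

*Minimal medium*: unlimited uptake (lb −1000) for CO2, H2O, H+, O2, Fe²⁺,
phosphate, potassium, sodium, sulphate and NH4; all other exchange uptakes
closed; secretion stays open.

*Equal C-mol screens*: when comparing carbon sources, uptakes are scaled by
`u = u_ref · C_ref / C_source` so each source delivers the same C-mol.

*Lipid protocol*: carbon and nitrogen exchanges are pinned on both bounds
(the C/N of the uptake rates must be realized exactly for the biomass to be
condition-consistent), the condition-specific biomass is installed, growth
is maximized (μ*), the biomass flux is pinned to [0.9·0.2, 0.2] h⁻¹ when μ*
exceeds the 0.2 h⁻¹ ceiling or to [0.9·μ*, μ*] otherwise (a window rather
than a point constraint, for solver robustness), and the lipid-body
exchange is maximized. Infeasible conditions are reported as zero growth
with a flag, never raised.

*Knockouts* close all reactions whose GPR evaluates false under the
deletion and re-run the protocol.

*Readout for the dynamic-vs-static contrast*: with a surplus-carbon
maximization stage, the lipid-body exchange flux responds to absolute
carbon supply in both biomass modes; the effect specific to the
condition-dependent biomass is the biomass-coupled lipid productivity
`μ·w_TL` (g lipid·gDCW⁻¹·h⁻¹), which rises with C/N in dynamic mode and is
flat by construction in static mode. The scenario tables report both.

## Energy-cycle audit

Eight dissipation pseudo-reactions are added (NTP + H2O → NDP + Pi + H+ for
ATP/CTP/UTP cytosolic and GTP mitochondrial; NAD(P)H → NAD(P)+ + H+;
FADH2 → FAD + 2 H+; H+(c) → H+(e) for the membrane gradient). All other
reactions are clamped to [−1, 1] if reversible (lb < 0) or [0, 1]
otherwise — forced fluxes such as maintenance are released for the audit —
and every exchange uptake is closed. Each dissipation flux is maximized in
turn; any positive maximum certifies a thermodynamically infeasible
energy-generating cycle, and the non-zero fluxes of that solution are
reported as the implicated support. The redox/proton dissipation reactions
are deliberately charge-unbalanced pseudo-reactions (they stand for
electron disposal) and are exempt from the elemental-balance report, as all
pseudo-species-containing reactions are.

## Flux sampling and Z-scores

The sampler is artificial-centering hit-and-run: warmup points are the FVA
optima of every reaction (all satisfy `S·v = 0` exactly), chain directions
are differences between stored points and the running center (hence lie in
the null space of S), and the step is drawn uniformly from the interval the
bounds allow. A step-count budget (`steps_per_point`, default 25) replaces
wall-clock limits so runs are exactly reproducible from a seed; scenario
cells derive child seeds from the base seed through `SeedSequence` spawn
keys (all below 2³¹). Every stored point is verified against steady state
and bounds at 1e-6. On axis-aligned box polytopes the sampled means and
variances match the uniform closed forms (midpoint, width²/12) within
3 standard errors at n = 5000, which is the calibration the test suite
enforces.

Condition comparison uses `Z = (mean_cond − mean_ref)/√(sd_ref² + sd_cond²)`
per reaction, with C/N = 6 g/g as the reference condition; Z > 0 means the
flux increased. When both spreads are zero, Z is 0 for equal means and
signed infinity otherwise. The default sample size is 5000 points; the test
suite and coarsened scenarios use 150–500 points with correspondingly
qualitative assertions.

## The synthetic network

The generator emulates, at ~129 reactions in four compartments (cytosol,
mitochondrion, extracellular, lipid particle), the physiology that the
analyses probe:

- uptake of glucose, fructose, sucrose (extracellular invertase), xylose
  (reductase/xylitol dehydrogenase/xylulokinase plus a phosphoketolase
  route ending in acetate that is activated only in the mitochondrion),
  glycerol and ethanol;
- glycolysis/gluconeogenesis, oxidative and non-oxidative PPP,
  mitochondrial TCA, lumped oxidative phosphorylation with P/O ratios 1.5
  (NADH) and 0.5 (FADH2);
- citrate export and ATP-citrate lyase (dedicated gene `gACL1`) as the
  *only* route to cytosolic acetyl-CoA — there is no cytosolic acetyl-CoA
  synthetase — so deleting ACL abolishes lipid synthesis and, because every
  biomass composition contains lipid, growth itself;
- ACC, a lumped FAS (1 acetyl-CoA + 7 malonyl-CoA + 14 NADPH → palmitoyl-
  CoA; written with 21 H+ and 7 H2O so it balances elementally while
  keeping the canonical 14-NADPH stoichiometry), elongation and Δ9/Δ12
  desaturation, the acyl-CoA pool, G3P → PA → DAG → TAG and the CDP-DAG
  route to PS → PE → PC, and a lipid-body pseudo-species (90% TAG, 10%
  phospholipids) exported through a dedicated exchange;
- glycogen-like carbohydrate storage through UDP-glucose (elementally
  balanced), lumped protein and "other" synthesis, urease, and an alanine
  overflow (pyruvate + NH4 + NADH → alanine, secreted) that disposes of
  excess nitrogen when uptake rates are pinned above demand — the valve
  that keeps low-C/N conditions feasible under both-bounds pinning.

Deliberate constructions: ethanol assimilation (ADH/ALDH, glyoxylate shunt,
PEP carboxykinase) is absent by default so ethanol supports no growth —
pathway absence is the encoded cause — and restored by a flag. Glycerol
enters by proton symport (offset by the plasma-membrane H+-ATPase) and is
oxidized obligatorily through the FAD-linked glycerol-3-phosphate shuttle;
with the chosen P/O ratios its ATP yield per C-mol falls below glucose's,
reproducing the lower glycerol growth rate at equal C-mol. The acyl-CoA
pool's downstream acyl transfers release CoA in proportion to the pool
coefficients' sum (0.966525 per pool unit), keeping the conserved CoA pool
closed at steady state.

What the toy network does *not* emulate: the full 1553-reaction
reconstruction, peroxisomal β-oxidation, sterol and full amino-acid
metabolism, real transporter energetics, or transcriptional regulation.
Passing tests therefore demonstrate that the pipeline's logic — biomass
construction, protocols, audit, sampling, statistics — behaves correctly on
a network with the right causal structure, not that the toy model's
absolute fluxes match any organism.

## Study conditions and desk scaling

Scenario defaults are the study conditions at desk scale, fixed at
construction time: the C/N grid sweeps carbon uptake over [1.5, 8.5] and
nitrogen over [0.1, 0.8] mmol·gDCW⁻¹·h⁻¹ (glucose/urea; ~8 levels each by
default, the full 141 × 71 grid behind `--full`); the Z-score series uses
glycerol at carbon-source uptake levels 16/24/32 mmol·gDCW⁻¹·h⁻¹ against
the C/N = 6 g/g reference with the C/N list (6, 8, 10, 12, 24, 30, 36, 48,
60, 90, 120, 180, 240) available in full; the acetyl-CoA series pins urea
at 2.5 mmol·gDCW⁻¹·h⁻¹ — a tenth of the laboratory setting — so that the
carbon uptake implied by C/N ratios up to 240 g/g stays inside the model's
±1000 flux caps. Test-suite sampling uses n = 150–500 points.

## Numerical choices and degenerate inputs

- LP: HiGHS via `scipy.optimize.linprog`; solution verification at 1e-6,
  bound tolerance 1e-9. Infeasible/unbounded states are reported, not
  raised; alternate optima are not tie-broken (only objective values and
  protocol outputs are contractual — distributions over optima are the
  sampler's job).
- "No growth" threshold: μ ≤ 1e-6 h⁻¹.
- Default bounds [−1000, 1000] reversible, [0, 1000] irreversible;
  reversibility for audit clamping is `lb < 0`.
- Elemental balance: |imbalance| ≤ 1e-6 per element; reactions touching
  formula-less pseudo-species are exempt and listed as such.
- Molecular weights: IUPAC 2021 atomic masses at four decimals, expressed
  in g/mmol throughout.
- Native JSON round-trips byte-identically (canonical ordering, explicit
  schema version); SBML L3+FBC round-trips exactly for ids, bounds, GPRs
  and annotations, and to float-text precision (~1e-15 relative) for
  stoichiometric coefficients.
- Empty models, nitrogen-free media (C/N = +inf with warning semantics) and
  zero-width sampling dimensions (pinned fluxes) are all handled
  explicitly.

## Known limitations

The protein/other synthesis lumps are intentionally coarse (flagged in the
manifest); absolute growth yields should not be interpreted
quantitatively. The replete-mode composition is a placeholder default. The
Z-score formula is one conventional choice among pooled variants; both sd
and standard error are reported so alternatives can be recomputed from the
emitted tables. Hit-and-run mixing is verified on box polytopes and by
FVA-interval containment, not by formal convergence diagnostics.
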