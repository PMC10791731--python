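# Methods

This note documents the models, conventions and numerical choices behind
`gyflux`, stage by stage, including what the synthetic-culture generator does
and does not emulate.

## Synthetic fed-batch cultures (`gyflux.synth`)

The generator is phenomenological: its purpose is to produce datasets with
the statistical and temporal structure the downstream analysis assumes, with
exactly known ground truth, not to model CHO physiology mechanistically.

**Design.** 14-day fed-batch, inoculation at 0.3×10⁶ cells/mL in 12 mL,
sampling days {0, 2, 4, 5, 6, 7, 8, 10, 12, 14}, 4 % (v/v) boluses on days
{4, 6, 8, 10, 12}, glucose topped up to 6 g/L (days 4–8) and 7 g/L (days
9–12) at bolus events, doses {0.125, 0.25, 0.5, 1.0, 2.0}× GY with 3
replicates each. Measured variables: VCD, viability, titer, and glucose,
lactate, ammonia, the 20 proteinogenic amino acids and ornithine (mM).

**Growth.** The specific growth rate declines exponentially with culture
age, `mu(t) = mu_max · g(dose) · exp(−t/mu_tau)` (`mu_max = 1.0`/day,
`mu_tau = 7` d) until day 8, then first-order decline (0.08/day). VCD is
advanced with a log-space step (`V ← V·exp(rate·dt)`, `dt = 0.1` d), which is
exact for piecewise-constant rates — this is what makes the specific growth
rate recoverable to machine precision from zero-noise data. A logistic
carrying-capacity model was rejected because its saturation equalizes the
day 6–7 SGR across doses, whereas the dose conditions are supposed to be
most separated there.

**Dose response.** Growth and productivity multipliers are unimodal in
log2-dose with a peak at 0.5× and an asymmetric width (Tyr starvation below
the optimum is more damaging than dipeptide excess above it):
`g = 1 − a·log2(d/0.5)²` with `a = 0.10` (below) / `0.03` (above) for
growth and `0.12`/`0.06` for Qp. These were chosen once to reproduce the
qualitative pattern — a clear titer optimum at 0.5×, poor growth at 0.125×,
mild penalties at 1–2× — and are not fitted to any dataset.

**Metabolite balances.** Within each sampling interval,
`C(t2) = C(t1′) + Qm · IVCD(t1, t2)` where `IVCD` is the trapezoid of the
*emitted* VCD values and `t1′` is the post-bolus state (residuals diluted by
1/(1+f), feed mass added, titer and cells diluted, volume grown by (1+f)).
Using the emitted-VCD trapezoid rather than a fine-grid integral makes the
planted rates exactly recoverable by the rate equations; the two differ by
up to ~10 % on early 2-day phases, which would otherwise masquerade as a
kinetics error. Concentrations clip at zero with a log entry (asparagine,
aspartate and late glutamine do deplete under default rates, as real
cultures show).

**Planted rates.** Per-phase specific rates are
`base · g(dose) / (1 + t/t50)` (`t50 = 2` d): uptake scales with how well the
condition grows and attenuates with culture age. Exceptions: glucose is
dose-independent per cell (setpoint-fed cultures show comparable specific
glucose uptake across doses) and lactate switches from production to
consumption after day 4. Every metabolite additionally receives a
*condition-level* lognormal scatter factor (CV = 1.0, deterministic per
(seed, condition, metabolite)) representing media-lot and clone-state
heterogeneity — this is what keeps unplanted nutrients from being
systematically correlated with titer, so that a planted correlation is a
real, detectable ground truth rather than one signal among twenty identical
ones. Set `rate_decay=False` and `rate_heterogeneity=0` for strictly
piecewise-constant planted rates.

**Noise.** Multiplicative lognormal noise (CV = 0.05) is applied to emitted
measurements only, never to the dynamics, so replicates share one true
trajectory; the planted ground truth survives at zero noise exactly.

**Planting.** `plant_outlier` rescales one batch's VCD trajectory.
`plant_titer_correlation` shifts the target metabolite's rate per condition
in proportion to the condition's realized noise-free final titer (obtained
from a probe simulation), by `sign · strength · 2|base| · (s − s̄)`
pmol/cell/day; at `strength = 2` the terminal residual concentrations
correlate with final titer at |r| ≳ 0.95. Planted metabolites are exempt
from the heterogeneity scatter.

**Not emulated.** pH/DO dynamics, osmolality, element balances,
sampling-volume losses, mechanistic metabolism (that is the FBA layer's
job), and any feedback of metabolite state onto growth. Consequently,
passing tests show the *analysis chain* is correct and sensitive; they do
not validate biological effect sizes on real cultures.

## Rate equations (`gyflux.rates`)

Units: 1 mM = 10⁶ pmol/mL and 1 mg/L = 10⁶ pg/mL, so with VCD in 10⁶
cells/mL the ratios come out directly in pmol/cell/day and pg/cell/day.
Glucose supplied in g/L converts at 180.16 g/mol on ingest.

Feed correction: a bolus of fraction `f` contributes `f·C_stock/(1+f)` to
each metabolite and dilutes everything already present by 1/(1+f). The
default mode corrects both effects — for metabolites, product and cells —
because the generator (and any volume-tracked process) physically dilutes
them. `eq2_strict=True` applies only the additive feed term to Qm and no
correction to Qp/SGR, the literal textbook form; both modes agree in phases
without boluses. Phases are half-open `[t1, t2)` and a bolus on day `t1`
belongs to the phase starting at `t1` (cultures are sampled before being
fed).

The SGR uses the exponential-phase definition `ln(V2/V1)/Δt`; no smoothing
or regression-based rate estimation is attempted.

## Replicate screening (`gyflux.qc`)

For each condition, per-timepoint mean and sample SD (ddof = 1) are computed
across replicates *including* the candidate; a batch is flagged when it lies
outside mean ± `band_k`·SD (strict inequality, `band_k = 1`) on one
consistent side at ≥ `frac_threshold` (default 0.5) of timepoints. Identical
replicates have a zero-width band and are never flagged; groups of fewer
than three replicates cannot produce a majority verdict and are skipped with
a warning. With three replicates the standardized deviation is bounded by
2/√3 ≈ 1.155, so the 1-SD rule is sensitive (a 0.5× trajectory sits at
≈ −1.15 SD at essentially every timepoint) yet specific (false-flag rate
≈ 2 % per batch at 5 % measurement CV).

## Batch-level PLS (`gyflux.pls`)

The batch-level matrix has one row per qualified batch and one column per
(variable, timepoint) over the post-feeding days {4, 5, 6, 7, 8, 10, 12,
14}; the response is final-day titer normalized to the dataset maximum.
Columns are autoscaled (mean 0, unit sample variance), the response is
centred and scaled, and coefficients are reported in that scaled space so
sums across differently-scaled variables are comparable. Zero-variance
columns are dropped and logged.

The fit is NIPALS PLS1 (exact for a single response), with weights
unit-norm and scores mutually orthogonal. VIP follows Wold:
`VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)`, which obeys
mean(VIP²) = 1 identically.

**Component count.** Chosen by leave-one-out cross-validation, capped at 5,
with a minimum-gain stopping rule: components are added only while each
raises Q² by ≥ 0.05. Simply maximizing Q² always hits the cap on strongly
collinear batch-level data and merely redistributes coefficient mass among
correlated columns, which destabilizes the coefficient-sum ranking; the
parsimonious rank (typically 1–2 here) keeps coefficients interpretable.

**Ranking.** Per variable, scaled-space coefficients are summed over the
timepoints whose column VIP ≥ 1.00 (config-exposed); variables sort by
signed sum (most negative first) or magnitude, ties lexicographic. Process
variables (VCD, viability, titer) are excluded from the *nutrient* ranking
by default. The magnitude of a coefficient-sum depends on the dataset's
column count and scaling; it is not portable across datasets.

## Metabolic model layer (`gyflux.model`, `gyflux.toynet`)

Identifiers follow the BiGG-like style of CHO genome-scale models;
compartments are `e`/`c`/`m`. Models round-trip through a documented JSON
dialect and SBML Level 3 + FBC (bounds and objective via FBC; subsystems and
kcat/MW annotations in reaction notes). A user-supplied genome-scale SBML
model passes through unmodified.

**GY augmentation** adds exactly three reactions — `EX_glytyr(e)`
(`glytyr[e] ↔`), `GLYTYRPEPT1t` (`glytyr[e] ↔ glytyr[c]`), `GLYTYRHYDRO`
(`h2o[c] + glytyr[c] → gly[c] + tyr_L[c]`, irreversible) — and is
idempotent.

**IgG reaction.** The antibody's amino-acid composition in mol % (printed
values summing to 100.10) is renormalized to an exact simplex; the reaction
consumes free cytosolic amino acids and, by default, 4.3 ATP-equivalents per
residue (hydrolyzed to ADP + Pi; the peptide-bond cost of ~4 GTP/ATP per
elongation cycle plus processing overhead, config-exposed), producing one
unit of the `igg[c]` pseudo-metabolite routed to a secretion sink. Flux unit:
mmol residues/gDCW/h; mass conversion uses a mean residue mass of 110 g/mol.

**Reduced network.** ~115 reactions covering glucose transport and
glycolysis, the oxidative PPP lumped into `G6PDH` (2 NADPH per G6P, CO₂
out) with a lumped non-oxidative return, cytosolic acetyl-CoA supply, a
full TCA cycle (`PDHm`, `PCm`, `CSm`, `ICDHm`, `AKGD` — 2-oxoglutarate
dehydrogenase fused with succinyl-CoA ligase — `SUCD` to FADH2, `FUM`,
`MDH`), oxidative phosphorylation at P/O 2.5 (NADH) and 1.5 (FADH2),
glutamine synthetase/glutaminase, mitochondrial glutamate dehydrogenase,
GABA (4abut) synthesis and secretion, the transaminases ASPTA, ALATA,
ORNTA (with glutamate-5-semialdehyde oxidation) and LEUTA (4mop secreted),
asparaginase, an arginase lump feeding ornithine, exchanges and reversible
transporters for all 20 amino acids plus ornithine, lactate, ammonia, O₂,
CO₂ and water, ATP maintenance, a generic CHO biomass pseudo-reaction
(amino acids ≈ 5 mmol/gDCW, G6P/Ru5P/acetyl-CoA precursors, 30 mmol ATP and
1 mmol NADPH per gDCW) and the IgG reaction.

Bookkeeping conventions worth knowing: sugar phosphates are tracked without
their phosphate group (the kinase returns Pi to the pool), so the
phosphate/adenylate moieties are closed; protons are not tracked; a closed
NADPH-oxidase valve (`NADPHOX`, bounds [0, 0]) exists for forced-PPP
scenarios — closed by default so G6PDH flux is set by biosynthetic NADPH
demand. Amino acids without an explicit catabolic route here carry `DM_`
demand sinks standing in for the catabolism a genome-scale model provides;
without them, the ±20 % bounds (which force *minimum* uptakes) would be
infeasible whenever supply exceeds biosynthetic demand. With all exchanges
closed the network supports no biomass, no IgG and no flux at all in the
parsimonious solution. A subset of 27 enzymatic reactions carries plausible
literature-magnitude kcat (1/h) and MW (g/mmol) annotations; the default
pooled budget is `P_total = 0.05` g/gDCW, generous under measured bounds and
binding under fully open bounds.

Tyrosine is deliberately *not* synthesizable (no phenylalanine
hydroxylase), so free Tyr and GY uptake are the only Tyr sources and the
dipeptide-rescue experiment is well-posed.

## ecFBA (`gyflux.ecfba`)

Per replicate and phase (default day 6–7, the phase where the dose
conditions separate most in SGR and Qp):

1. measured Qm (pmol/cell/day) convert to mmol/gDCW/h via the cell dry
   weight (default 250 pg/cell, config-exposed) and become exchange bounds
   `[r − 0.2|r|, r + 0.2|r|]` intersected with physical bounds (exactly the
   measured set provided is bounded; zero rates widen by ±10⁻⁶ to avoid
   degenerate boxes);
2. measured Qp fixes the IgG reaction flux;
3. the measured SGR (converted to 1/h and scaled by 1 − relaxation) enters
   as a biomass *lower* bound, anchoring the problem to the measured
   physiological state; growth is otherwise free and maximized (an optional
   cap at measured SGR × a factor is available, off by default);
4. the LP maximizes biomass on the split (irreversible) network with the
   pooled capacity row, then a parsimonious second stage minimizes total
   flux with biomass pinned at its optimum (slack 10⁻⁹), yielding a unique,
   deterministic representative vector (HiGHS with fixed problem ordering).

**Bound reconciliation.** Measurement noise can produce bound sets with no
feasible flux state at all — most commonly an apparent net *secretion* of an
essential amino acid the network cannot synthesize. When the first LP is
infeasible, an L1-minimal relaxation LP (slack variables on exchange bounds
only; stoichiometry, the fixed IgG flux, the growth floor and the enzyme
budget stay hard) finds the smallest total bound adjustment that restores
feasibility; the widened bounds are used and the per-exchange slack is
reported on the solution (`relaxed_bounds`) and logged. This is the same
move as the ±20 % relaxation itself, extended adaptively and transparently.

Solutions are verified against `|S·v| ≤ 10⁻⁶` and bounds to 10⁻⁸ (solver
round-off up to 10⁻⁶ is projected onto the box first). Condition-level flux
states average the replicate solutions reaction-wise; infeasible replicates
are skipped with a warning.

## Comparative analysis (`gyflux.compare`)

Fold changes are computed on split fluxes (forward and backward directions
counted separately), reference condition in the numerator, so "> 20 % higher
in the reference" reads FC > 1.2 (strict). Reactions with both fluxes below
the 0.0001 mmol/gDCW/h floor are excluded; a reaction active only in the
reference gets FC = +∞, kept and flagged. Subsystem tallies of repeated
reactions exclude Exchange/Transport/Demand pseudo-reactions, which mirror
metabolic changes without carrying pathway membership. Cofactor summaries
sum coefficient × flux over producing reactions; at steady state production
equals consumption to the LP tolerance. Substrate partitions report each
named sink's share of the substrate's total consumption plus an
`other/secreted` remainder, closing to 1.

## Pipeline (`gyflux.pipeline`, `gyflux.cli`)

Every analysis constant (SD band, majority fraction, VIP threshold,
relaxation, flux floor, FC threshold, DCW, phase, enzyme budget, seed) is a
validated config parameter with the defaults above; unknown keys are
rejected before any stage runs. Outputs are CSV/JSON with fixed float
formatting, so a rerun under the same seed is byte-identical; the manifest
records the config hash (location-independent), seed and package version,
and notes the failing stage if one aborts.

## Problem sizes and limitations

The bundled studies are desk-scale: 5 conditions × 3 replicates × 10
timepoints, a ~115-reaction network, LPs with ~190 split reactions — chosen
so the full validation battery (50-study ranking recovery, 200-study
outlier screens, vertex-enumeration cross-checks) runs in seconds.
Quantities that depend on genome-scale redundancy — absolute fold-change
set sizes, cofactor totals, partition percentages — are structurally
analogous to, but numerically incomparable with, results from a full CHO
genome-scale model; the machinery accepts such a model via SBML unchanged.
Flux comparisons carry no statistical test: replicate averaging yields one
representative state per condition, and differences below the ±20 % bound
relaxation should not be over-interpreted.
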