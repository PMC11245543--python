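# Methods

## Correction model

A mass isotopologue distribution (MID) is a vector of fractions over
integer nominal mass shifts M+0..M+k. For a metabolite with formula F
measured under a tracer labeling n atoms of element E at per-atom isotopic
purity π ∈ (0, 1], the forward model for the measured MID given the true
labeling-state distribution x₀..xₙ is a matrix M with column j built from
three convolution factors:

1. **Impurity**: Binomial(j, π) over shifts 0..j — each of the j designated
   tracer atoms actually carries the heavy isotope with probability π.
   π = 1 degenerates to a unit shift of j, as it should.
2. **Tracer-element natural abundance**: the natural isotope pattern of the
   tracer-element atoms *outside* the designated labeled set. We convolve
   over count(E) − j atoms, not n − j: when the molecule has more E atoms
   than labelable positions (e.g. a serine tracer deuterated at 3 of 7
   hydrogens), the extra atoms still contribute natural abundance. The two
   conventions coincide whenever every E atom is labelable, which covers
   all ¹³C tracers used here and the D₂O default.
3. **Other-element natural abundance** (nominal mode only): the convolved
   natural patterns of every non-tracer element. High-resolution mode
   (default, appropriate for orbitrap-class instruments) assumes these
   isotopologues are mass-resolved away from the tracer series.

Rows beyond the configured `max_shift` are dropped **without**
renormalizing: truncation mirrors what the detector window does to real
data, so a truncated column honestly sums to < 1 and the NNLS fit absorbs
the missing tail into the residual rather than silently redistributing it.

Natural-abundance patterns are exact convolutions of per-atom isotope
distributions (binary-exponentiation self-convolution per element). The
shipped abundance table uses IUPAC/CIAAW-style representative values
(¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364, ¹⁷O 0.00038, ¹⁸O 0.00205 at shift 2,
³³S 0.0075, ³⁴S 0.0425, ³⁶S 0.0001) and is fully replaceable via
`IsotopeTable` / a plain CSV, since published abundances vary in the last
digit and test scenarios want zero-abundance tables.

**Inversion.** Corrected fractions solve min‖Mx − raw‖₂ subject to x ≥ 0
(`scipy.optimize.nnls`), then renormalize to Σx = 1. Raw intensities are
rescaled to unit sum before solving so conditioning is independent of the
absolute intensity scale (validated over 1e5–1e8); the reported
`residual_norm` is mapped back to the intensity scale. An all-zero raw
vector, a negative intensity or a length mismatch is an error, not a
warning. Isotopologue rows absent from a peak table are treated as zero
intensity with a logged warning.

**Choosing n.** When correcting a peak table, the number of labeling
states defaults to min(count of the tracer element in the formula, highest
observed shift): states beyond the measured shift range are not
identifiable from the data, and positions beyond the element count cannot
exist. This is overridable per compound in the pipeline config — relevant
for D₂O fatty-acid data, where the default labels every hydrogen of the
saponified fatty acid but exchangeable-hydrogen arguments might motivate a
smaller n.

## Labeling metrics

Both conventions of "labeling" are always computed: labeled fraction
1 − m₀ and atom-weighted fractional enrichment Σᵢ i·mᵢ / n. Figure-style
outputs default to 1 − m₀; the tables carry both so the choice is never
hidden. No ordering between the two is asserted (enrichment can exceed the
labeled fraction only if shifts beyond n appear, which the pipeline's
choice of n prevents).

In-vivo normalization divides a tumor metabolite's labeling by the serum
tracer enrichment of the same mouse. For serum [U-¹³C₆]-glucose the
denominator convention is itself ambiguous in the field; the package
defaults to atom-fraction enrichment (Σ i·mᵢ / 6) and offers the M+6
fraction behind `serum_glucose_enrichment(..., method="m6")`. The
simulator sidesteps the ambiguity by writing the per-mouse serum
enrichment directly into the sample metadata.

## Active-hydride deconvolution

The NADPH ²H MID b is modeled as (1 − p)·[c; 0] + p·[0; c] where c is the
NADP⁺ ²H MID (both corrected first — the pipeline enforces the ordering).
The model is linear in (1 − p, p) with weights summing to one, so the
least-squares problem reduces to one parameter with the closed form
p\* = ⟨b − c₁, c₂ − c₁⟩/‖c₂ − c₁‖², c₁ = [c; 0], c₂ = [0; c]. The
denominator vanishes only for degenerate non-MID inputs and is guarded.
The tests verify the closed form against a brute-force grid search
(step 1e-5).

Whether to constrain p was a genuinely open choice; the package clips to
[0, 1] but never silently: estimates outside the interval set a `clipped`
flag and log, because p slightly below 0 is the *expected* behaviour of an
unbiased estimator near p ≈ 0 under noise, and hiding it would mask a
useful diagnostic. Zero-padding either MID does not change p. Group
summaries report mean ± SEM per group with SEM left missing for
single-sample groups; hypothesis testing is deliberately out of scope.

## Bench assays

Exact formula transcriptions with units enforced at the boundary
(amounts µg, concentrations mg/L, volumes mL, fluorescence a.u., time h):
serine consumption = (amount₀ − amountₜ)/(Δcells/10⁶) with a declining or
flat cell count an explicit error (the formula presumes growth); ROS =
(F_stained − F_unstained)/cells(10⁶) with a negative difference returned
but warned about; redox ratios as plain pool quotients; proliferation as
the OLS slope of percent confluence against time (≥ 3 strictly increasing
timepoints); relative proliferation as counts over the mean untreated
count. `medium_amount_ug` converts concentration × volume (30 mg/L in
2 mL = 60 µg). Duplicate wells are combined by averaging the per-well
values within group × timepoint.

## Synthetic cohort

The generator emulates a two-arm (WT vs G6PD-knockout) tracing study with
the knockout effect directions of the underlying biology: less
glucose-derived serine synthesis, more serine uptake, a larger share of
NADPH hydrides fed by serine one-carbon flux, less de novo lipogenesis,
slower growth, more ROS, weaker redox poise. Magnitudes are set once at
values a tracing lab would call realistic, and are configurable:

| parameter | WT | KO | rationale |
|---|---|---|---|
| active-H fraction p | 0.05 | 0.15 | one-carbon flux is a minor NADPH source normally, compensatory after oxPPP loss |
| serum ¹³C-glucose enrichment | 0.40 | 0.40 | typical steady-state infusion enrichment |
| tumor serine ¹³C enrichment (per atom) | 0.15 | 0.08 | reduced de novo serine synthesis in KO |
| tumor serine ²H labeling (per position) | 0.10 | 0.20 | increased uptake of labeled serine in KO |
| fatty-acid newly synthesized fraction | 0.25 | 0.10 | overnight lipogenesis window |
| per-H ²H incorporation q | 0.045 | 0.045 | body-water D₂O plateau |
| NADP⁺ background ²H enrichment | 0.05 | 0.05 | non-hydride positions, 2 shifts |
| intensity noise CV | 0.02 | — | orbitrap peak-area repeatability |
| samples per group | 8 | — | cohort size of the emulated design |
| tracer purity | 0.99 | — | vendor-grade labeled substrates |

True MIDs are binomial in the per-atom enrichment (a `custom MID` escape
hatch accepts arbitrary vectors); a fatty-acid pool is a two-component
mixture of unlabeled molecules and newly synthesized molecules with
Binomial(n_H, q) deuterium. The essential fatty acid C18:2 is simulated
with zero synthesis and functions as the internal negative control: after
correction its labeled fraction must sit at the noise floor (≤ 1e-3 under
the default conditions; observed ~2e-4).

Measurement noise is multiplicative lognormal (unit mean) applied to raw
intensities *before* correction — where noise physically enters — never to
fractions. Per-sample intensity scales are drawn log-uniformly over
1e5–1e8. Serine-consumption measurement noise applies to the measured
medium serine amount, which makes early timepoints noise-dominated exactly
as in the real assay (consumed ~1 µg against a 30 µg pool); late
timepoints recover the generating value. All randomness flows through one
`numpy` generator seeded from the config, and the pipeline's run log omits
wall-clock information, so identical configs produce byte-identical
outputs end to end.

**What the simulator does not emulate:** chromatography and peak shape,
isobaric interference and resolution-dependent peak merging, biological
between-animal variance in the true enrichments (group truths are fixed;
only measurement noise varies), positional isotopomer structure beyond the
binomial model, and compartment (cytosolic vs mitochondrial) heterogeneity
of the NADPH pool. Passing tests therefore demonstrate correctness of the
*computations* under a faithful noise model, not robustness to every
pathology of real LC-MS data.

## Problem sizes and numerics

The shipped analysis and acceptance runs use 8 samples per group at 2%
noise; the estimator-error sweep uses 31 grid points × 200 replicates.
These sizes make the whole suite run in seconds while leaving Monte-Carlo
error well below the tolerances asserted. Numerical tolerances follow the
contract of each stage: exact arithmetic identities at 1e-12, convolution
equivalences at 1e-12, noise-free NNLS round trips at 1e-7–1e-8 (NNLS
terminates at machine-level residuals; the slack covers accumulation over
33-state fatty-acid systems), and closed-form-vs-grid agreement at the
grid resolution. Ties and degenerate cases: purity 1 collapses the
impurity factor to a pure shift; excluding every atom from a
natural-abundance convolution yields the delta distribution; a degenerate
NADP⁺ input with coincident shifted/unshifted columns is unreachable for
valid MIDs but guarded.

## Known limitations

Single tracer element per run (no simultaneous ¹³C/²H interference
correction); no resolution-dependent partial merging of near-isobaric
species; no absolute flux estimation or isotopomer spectral analysis —
the package reports labeling fractions and enrichments, not synthesis
rates; elements beyond C, H, N, O, P, S (and exact-mass fine structure)
are out of scope.
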