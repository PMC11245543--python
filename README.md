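# isotrace

Stable-isotope tracing computations for LC-MS metabolomics: mass-isotopologue
natural-abundance and tracer-impurity correction, labeling-fraction and
fractional-enrichment metrics, serum-normalized in-vivo enrichment, NADPH
active-hydride deconvolution, and the bench-assay arithmetic (serine
consumption, ROS, redox ratios, proliferation slope) that accompanies such
studies. A forward simulator generates WT-versus-knockout tracing cohorts
with known ground truth, so every stage of the pipeline can be exercised and
validated without instrument data.

The package is aimed at metabolism researchers analyzing isotope-tracing
experiments — e.g. [U-¹³C₆]-glucose, [2,3,3-²H]-serine or D₂O infusions in
tumor-bearing mice — from El-MAVEN-style peak-table exports.

## The computations

**Isotopologue correction.** For a metabolite with elemental formula F and a
tracer labeling n atoms of element E at per-atom purity π, the measured MID
is modeled as M·x, where column j of the correction matrix M is

&nbsp;&nbsp;&nbsp;&nbsp;M·eⱼ = Binomial(j, π) ⊛ NatAbund(E atoms outside the labeled set) [⊛ NatAbund(other elements), nominal mode]

and x is the distribution over true labeling states x₀..xₙ. Corrected
fractions are recovered by nonnegative least squares, min‖Mx − raw‖₂ s.t.
x ≥ 0, renormalized to sum to one. High-resolution mode (default, for
orbitrap-class data) assumes isotopologues of non-tracer elements are
mass-resolved away.

**Labeling metrics.** From a corrected MID m₀..mₖ the package reports both
the labeled fraction 1 − m₀ and the atom-weighted fractional enrichment
Σᵢ i·mᵢ / n. For in-vivo ¹³C data, tumor metabolite labeling is divided by
the serum tracer enrichment of the same mouse.

**NADPH active-hydride labeling.** NADPH is NADP⁺ plus the redox-active
hydride, so under a ²H tracer the corrected NADPH MID b is a mixture of the
corrected NADP⁺ MID c (hydride unlabeled) and its one-mass-unit shift
(hydride labeled):

&nbsp;&nbsp;&nbsp;&nbsp;b = (1 − p)·[c; 0] + p·[0; c]

The active-H labeling fraction p has the closed-form least-squares solution
p\* = ⟨b − c₁, c₂ − c₁⟩ / ‖c₂ − c₁‖², clipped to [0, 1] with clipping
surfaced in the output.

## Worked example

```python
import isotrace as it

# Eq-style active-hydride deconvolution from a corrected NADP+/NADPH pair
res = it.active_h_labeling([0.8, 0.2], [0.56, 0.38, 0.06])
print(res.p, res.residual_norm)        # 0.3 0.0  -> 30% of active hydrides labeled

# correction of a raw serine isotopologue vector under a 99%-pure 13C3 tracer
m = it.build_correction_matrix(it.parse_formula("C3H7NO3"), it.TracerSpec("C", 3, 0.99))
corrected = it.correct_intensities([811000.0, 152000.0, 29000.0, 8000.0], m)
print(it.labeling_metrics(corrected.fractions, 3))
# LabelingResult(labeled_fraction=0.1637..., fractional_enrichment=0.0687..., n_atoms=3)

# bench assay: 30 mg/L serine in a 2 mL well is 60 ug at 0 h
rec = it.ConsumptionRecord(amount_t0=60, amount_t=40, cells_t0=0.5e6, cells_t=1.5e6, timepoint=24)
print(it.serine_consumption(rec))      # 20.0 ug per 1e6-cell increase
```

The same operations are available from the shell through the `isotrace`
CLI (`simulate`, `correct`, `enrich`, `nadph-p`, `assays`, `run`) and as a
narrative sequence of drivers under `analysis/`:

```bash
python analysis/01_simulate_cohort.py --seed 1   # WT/KO cohort with ground truth
python analysis/02_correct_mids.py               # NNLS correction of every track
python analysis/03_labeling_metrics.py           # labeling + serum normalization
python analysis/04_nadph_active_h.py             # active-H deconvolution per group
python analysis/05_bench_assays.py               # assay arithmetic
```

With the default conditions (8 samples per group, 2% intensity noise) the
active-H step prints group estimates of p = 0.049 ± 0.002 (WT) and
0.151 ± 0.002 (KO) against ground truth 0.05 / 0.15, and the
essential-fatty-acid control C18:2 corrects to a labeled fraction ≤ 2×10⁻⁴
while C16:0 shows its true de novo synthesis signal.

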