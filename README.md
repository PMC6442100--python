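# cubiphase

In-silico screening and analysis toolkit for drug-loaded glyceryl
monooleate (GMO) cubic-phase formulations.

GMO/water mixtures self-assemble into bicontinuous cubic liquid-crystal
phases — bilayers draped over a triply periodic minimal surface enclosing
two interpenetrating water-channel networks — which make excellent
transdermal carriers for hydrophilic drugs such as metformin. Formulating
them is a balancing act: ethanol improves fluidity (spreadability) but
eventually tips the mesophase from cubic to lamellar. `cubiphase`
implements the computational side of that formulation problem for
pharmaceutical scientists:

* **χ-parameterized DPD screening** — candidate GMO/ethanol/water/drug
  compositions are simulated with dissipative particle dynamics
  (Groot–Warren forces, Flory–Huggins χ mapped to bead repulsions via
  a_ij = a_ii + 3.27 χ_ij), their water microstructure classified
  (bicontinuous cubic / lamellar / intermediate / disordered), and the
  optimum selected as the most fluid composition that remains
  bicontinuous cubic, with water diffusivity as the fluidity indicator.
* **SAXS indexing** — Bragg peak positions are indexed against mesophase
  symmetries (Pn3m √2:√3:√4:√6:√8…, Im3m, Ia3d, lamellar 1:2:3,
  hexagonal) and lattice constants fitted from q = 2π√(h²+k²+l²)/a.
* **Franz-cell permeation metrics** — aliquot-corrected cumulative
  permeation Q_n = [C_n·V + V₀·ΣC_i]/A, steady-state flux J_ss, lag time
  T_lag, and the enhancement ratio versus a reference solution.
* **Xenograft efficacy metrics** — caliper tumor volume 0.5·L·W², tumor
  inhibitory rate (W_blank − W_test)/W_blank × 100%, and t-test / ANOVA +
  Student–Newman–Keuls group comparison.
* **Synthetic data generators** with recorded ground truth for every input
  class, so the whole pipeline is testable without laboratory data.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

```python
from cubiphase import (default_chi_matrix, chi_to_repulsion, index_peaks,
                       gen_saxs_peaks, gen_permeation_series, analyze_series,
                       inhibition_rate, dose_content, default_formulation_table)

# 1. chi -> DPD repulsion: the hydrophobic GMO tail vs water
a = chi_to_repulsion(default_chi_matrix())
print("a(B, water) =", round(a[1, 2], 2), "kT/r_c")

# 2. index a two-peak cubic SAXS pattern (reflections at sqrt6 : sqrt8)
peaks, _ = gen_saxs_peaks("Pn3m", 134.0, n_peaks=2, offset=3)
asg = index_peaks(peaks)
print(f"{asg.space_group} {asg.spacing_ratio}  a = {asg.lattice_constant:.1f} A")

# 3. Franz-cell series -> flux and lag time (1% assay noise)
series, _ = gen_permeation_series(Jss=1259.6, Tlag=0.3, noise_rel=0.01, seed=7)
m = analyze_series(series)
print(f"Jss = {m.Jss:.1f} ug/cm2/h, Tlag = {m.Tlag:.2f} h")

# 4. dose bookkeeping and efficacy arithmetic for formulation F4 (64/6/30/5)
f4 = default_formulation_table()[3]
print("Met in 1.5 g dose:", dose_content(f4, 1.5)["MET"], "mg")
print("inhibition:", inhibition_rate(1.73, 0.62), "%")
```

prints

```
a(B, water) = 41.68 kT/r_c
Pn3m √6:√8  a = 134.0 A
Jss = 1246.8 ug/cm2/h, Tlag = 0.29 h
Met in 1.5 g dose: 71.4 mg
inhibition: 64.16 %
```

The tail/water repulsion 41.68 = 25 + 3.27 × 5.1 is what drives bilayer
self-assembly in the screen; the indexer recovers the Pn3m lattice constant
from the two strong 211/220 reflections; the flux fit recovers the
generating J_ss within noise; and the last two lines are the dose and
efficacy arithmetic used on study data.

Running the formulation screen itself (minutes, not seconds):

```python
from cubiphase import run_screen, default_formulation_table
report = run_screen(default_formulation_table(), seeds=(1, 2, 3))
for r in report.records:
    print(r.name, r.majority_label, f"D = {r.D_water_mean:.4f}")
print("selected:", report.selected, "—", report.rationale)
```

A command-line interface mirrors the library
(`cubiphase simulate|analyze|screen|index-saxs|permeation|efficacy|synth`).

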