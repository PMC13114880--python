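# specbind

Analysis toolkit for small-molecule / protein binding studies that combine
fluorescence-quenching titrations, FRET, site-marker competition, FT-IR
secondary-structure analysis and umbrella-sampling free-energy profiles —
the standard experimental battery for characterising how a ligand (a
flavonoid, a drug) binds a carrier protein such as human serum albumin
(HSA).

It is written for spectroscopists and modellers who have the raw
two-column spectra, titration manifests and pull-coordinate window files,
and want the derived binding parameters with the fitting conventions made
explicit and testable. A synthetic-data module generates every input type
with known ground truth, so the full pipeline is verifiable offline.

## What it computes

**Quenching and binding.** Observed intensities are inner-filter
corrected, F_cor = F_obs·10^((A_ex+A_em)/2), then fit two ways:

- Stern–Volmer: F₀/F = 1 + K_SV[Q], with k_q = K_SV/τ₀ (τ₀ = 10⁻⁸ s).
  The quenching mechanism is called from the temperature trend of K_SV
  and whether k_q exceeds the diffusion-controlled ceiling (~2×10¹⁰
  L·mol⁻¹·s⁻¹): static, dynamic, or mixed.
- Double-log: log((F₀−F)/F) = log K_a + n·log[Q], giving the binding
  constant K_a and apparent site number n.

**Thermodynamics.** Van't Hoff regression ln K_a = −ΔH/RT + ΔS/R yields
ΔH and ΔS; ΔG(T) = ΔH − TΔS. The (ΔH, ΔS) sign pattern classifies the
dominant force (Ross–Subramanian rules: both negative → van der
Waals/hydrogen bonding, both positive → hydrophobic, −/+ →
electrostatic).

**FRET.** Overlap integral J = ΣFελ⁴Δλ / ΣFΔλ (λ in cm, ε in
L·mol⁻¹·cm⁻¹), Förster radius R₀⁶ = 8.8×10⁻²⁵·K²·N⁻⁴·φ·J, efficiency
E = (F₀−F)/F₀ and donor–acceptor distance r = R₀((1−E)/E)^(1/6).

**Sites.** Displacement % = 100·F₂/F₁ against warfarin (Sudlow site I),
ibuprofen (site II) and digitoxin (site III) names the binding pocket.

**FT-IR.** The amide-I band (1600–1700 cm⁻¹) is baseline-corrected and
deconvolved into Gaussian components assigned by center to β-sheet,
random coil, α-helix, β-turn and antiparallel β-sheet; area fractions
estimate secondary-structure content.

**Umbrella sampling.** A WHAM solver stitches biased windows into a
potential of mean force with histogram-overlap diagnostics, Bayesian
(Dirichlet-weight) bootstrap error bands and the dissociation barrier in
kJ/mol and kcal/mol.

## Worked example

Build a three-temperature synthetic titration whose binding constants
follow ΔH = −160.28 kJ/mol, ΔS = −451.8 J/mol/K, then run the binding
chain:

```python
from specbind import pipeline, spectra
from specbind.synthetic import TitrationTruth, gen_titration, gen_vant_hoff

ka_by_T = gen_vant_hoff(-160280.0, -451.8, [298.0, 304.0, 310.0])
rows = ["file,q_conc_M,temperature_K,a_ex,a_em"]
for t, ka in ka_by_T.items():
    series, sidecar = gen_titration(TitrationTruth(ka=ka, n=1.0, seed=int(t)),
                                    temperature=t)
    for i, ((q, spec), sp) in enumerate(zip(series.points, sidecar["points"])):
        name = f"t{int(t)}_{i:02d}.csv"
        spectra.write_spectrum(spec, name)
        rows.append(f"{name},{q:.10g},{t:.6g},{sp['a_ex']:.10g},{sp['a_em']:.10g}")
open("manifest.csv", "w").write("\n".join(rows) + "\n")

report = pipeline.run_binding_chain({"manifest": "manifest.csv"})
print(pipeline.binding_tables(report))
```

which prints

```
T_K   Ksv_L_mol   kq_L_mol_s   R2
298   3.127e+04   3.127e+12    1.0000
304   8721        8.721e+11    1.0000
310   2556        2.556e+11    1.0000

T_K   Ka_L_mol    n       R2
298   3.127e+04   1.000   1.0000
304   8721        1.000   1.0000
310   2556        1.000   1.0000

T_K   dH_kJ_mol   dS_J_mol_K   dG_kJ_mol
298   -160.28     -451.8       -25.64
304   -160.28     -451.8       -22.93
310   -160.28     -451.8       -20.22
```

The fits recover the generating K_a at each temperature exactly
(noiseless input), the van't Hoff line returns the generating ΔH/ΔS, and
the negative ΔG values with both ΔH < 0 and ΔS < 0 classify the binding
as spontaneous and van der Waals / hydrogen-bond driven
(`report["thermodynamics"]["force_label"] == "vdw_hbond"`).

The same stages are available from the shell:

```sh
specbind simulate titration --seed 0 --out-dir sim
specbind quench --manifest sim/manifest.csv --out report.json
specbind simulate umbrella --seed 0 --out-dir us
specbind wham --config wham.yaml --out pmf.json
```

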