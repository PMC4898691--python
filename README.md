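# bbekit

A toolkit for the computational characterization of BBE-like (berberine
bridge enzyme-like) flavoenzymes — the pfam 08031 family of FAD-dependent
oxidoreductases with the VAO fold, whose members differ in a handful of
active-site residues that set their covalent FAD tethering, catalytic base
chemistry and oxygen reactivity.

It is written for enzymologists and structural bioinformaticians who need
to turn raw observables (UV-Vis titration series, stopped-flow traces,
protein sequences, coordinate files) into the quantities that characterize
such an enzyme:

- **Spectral unmixing** (`bbekit.spectra`): non-negative least-squares
  decomposition of spectra into oxidized/semiquinone/reduced flavin and
  oxidized/leuco reporter-dye concentrations, A(λ) = l·Σ c_s ε_s(λ).
- **Midpoint potential** (`bbekit.redox`): dye-equilibrium potentiometry.
  At equilibrium both couples obey the Nernst equation, so
  log₁₀([ox]/[red])_enzyme vs log₁₀([ox]/[red])_dye is a line (Minnaert
  plot) with slope n_E/n_D and E°_enz = E°_dye − intercept·s/n_E
  (s = 59.16 mV at 25 °C).
- **Reoxidation kinetics** (`bbekit.kinetics`): monoexponential fits
  A(t) = A_∞ − ΔA·e^(−k_obs t) of 450-nm stopped-flow traces,
  k₂ = k_obs/[O₂], and oxidase vs dehydrogenase classification against
  free FAD (250 M⁻¹s⁻¹).
- **Active-site typing** (`bbekit.activesite`): mapping onto AtBBE-like 28
  reference numbering, the 13-position diagnostic fingerprint, type
  I/IIa/IIb/III/IV calls with covalent-attachment and oxygen-gatekeeper
  rules, and information-content sequence logos.
- **Phylogenetics** (`bbekit.phylo`): the classic jackknife → protein
  distance (Kimura-corrected p-distance) → neighbor joining →
  majority-rule consensus pipeline, implemented natively, with outgroup
  rooting.
- **Geometry** (`bbekit.structgeom`): atom distances, heavy-atom contacts,
  the isoalloxazine butterfly-bend angle about the N5–N10 axis, and Kabsch
  superposition on PDB-format coordinates.
- **Synthetic data** (`bbekit.synthetic_data`): seeded generators with
  ground truth for all of the above, so every estimator is testable as a
  round trip without downloads.

## Worked example

Simulate a thionine dye-equilibrium titration of a +61 mV enzyme and
recover its midpoint potential:

```python
import numpy as np
from bbekit import redox, synthetic_data as sd

cfg = sd.GeneratorConfig(seed=3)                    # 15 uM enzyme + dye, 0.002 AU noise
basis = sd.default_basis(cfg)
series, truth = sd.simulate_dye_equilibrium(cfg, basis,
                                            E0_enz_mV=61.0, E0_dye_mV=64.0)
titration_basis = basis.subset(("flavin_ox", "flavin_red", "dye_ox", "dye_red"))
dye = redox.RedoxCouple(E0_mV=64.0, n_electrons=2, conc_M=cfg.dye_conc_M)
fit = redox.estimate_potential(series, titration_basis, dye)
print(f"slope {fit.slope:.3f}  E0 {fit.E0_enzyme_mV:.2f} +/- {fit.E0_se_mV:.2f} mV")
```

prints

```
slope 0.991  E0 61.06 +/- 0.06 mV
```

The slope near 1 confirms both couples exchange two electrons; the
intercept of the log-log plot converts to a midpoint potential of
+61.0 mV, recovering the generator's truth within the fit's standard
error.  The same round-trip style works for the other stages, e.g. a
stopped-flow trace (`bbekit simulate stoppedflow --seed 3 --out tr.csv`
then `bbekit kinetics-fit tr.csv --o2 1.29e-4`) prints

```json
{
  "k_obs_per_s": 0.3910042040701022,
  "k2_per_M_per_s": 3031.0403416286995,
  "k2_se": 18.652302358327834,
  "fold_vs_free_FAD": 12.124161366514798,
  "reactivity_class": "oxidase-like"
}
```

i.e. the fitted observed rate divided by the dissolved O₂ gives a
bimolecular constant ~12× that of free FAD — an oxidase.

The same operations are available from the shell: `bbekit simulate ...`,
`bbekit redox-fit`, `bbekit kinetics-fit`, `bbekit classify`,
`bbekit phylo-run`, `bbekit geom`.

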