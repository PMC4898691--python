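# Methods

bbekit re-implements, as tested library code, the computational analyses used
to characterize a BBE-like flavoenzyme: spectral deconvolution of flavin redox
states, dye-equilibrium midpoint-potential inference, stopped-flow
reoxidation kinetics with oxidase/dehydrogenase classification, active-site
residue typing with sequence logos, jackknifed protein-distance phylogenetics,
and active-site geometry from coordinates.  Every stage can be exercised
without external data through the `synthetic_data` generators, which return
the ground truth they used.

## Spectral model and unmixing (`spectra`, `synthetic_data`)

Spectra are treated as Beer-Lambert mixtures: A(λ) = l · Σ_s c_s ε_s(λ), with
per-species extinction spectra ε_s collected in a `BasisSet`.  The synthetic
extinction spectra are sums of Gaussian bands.  The default band parameters —
flavin_ox (375 nm, σ 25, 9 500) + (450 nm, σ 28, 11 300); flavin_asq (380 nm,
σ 30, 22 000); flavin_red (345 nm, σ 30, 4 500); dye_ox (600 nm, σ 35,
56 000); leuco dye spectrally silent — are package choices, not measured
values: no extinction coefficients for this enzyme's species are published,
so the defaults merely reproduce the qualitative shapes of flavin/thionine
spectra (the 450-nm flavin band, the ~370-nm anionic-semiquinone rise, the
600-nm thionine band).  All are configurable.

Unmixing solves min‖A − Mc‖ by bounded-variable least squares with c ≥ 0 per
species and an optional unconstrained constant column (default on) that
absorbs wavelength-independent baseline drift.  The default fitting window is
320–700 nm; dye/flavin overlap is handled by joint multiwavelength unmixing
rather than single-wavelength readout, which is strictly more general and
reduces to it.  Species with identically zero extinction over the window
(leuco thionine) carry no spectral information; their pool's reduced
concentration is inferred by mass balance from a declared total.  Pool
fractions with f_ox or f_red below 1e-4 (configurable) are flagged unusable
so downstream log-ratios cannot blow up.

Two-electron titration analyses (potentiometry) use the four-species basis
without the semiquinone column: the Minnaert treatment assumes plain ox/red
pools, and dropping the heavily overlapping 380-nm semiquinone column also
conditions the fit (enzyme-pool mass is then conserved to better than 2% at
default noise).  The semiquinone is quantified only in photoreduction
analyses, and is never counted toward the 2-electron pools.

## Photoreduction ladder (`synthetic_data`)

Stepwise photoreduction is modeled as the equilibrium species ladder
ox ⇌ sq ⇌ red under a cumulative electron dose d ∈ [0, 2] equivalents, with a
semiquinone stability constant K = [sq]² / ([ox][red]).  Given d and K the
fractions solve f_sq² = K f_ox f_red subject to f_ox + f_sq + f_red = 1 and
f_sq + 2 f_red = d (bracketed root-finding, xtol 1e-15).  The photochemistry
of the light/EDTA system itself and the mediator kinetics are deliberately
abstracted into the dose schedule.  Whether a thionine semiquinone is ever
populated is unknown; the dye-equilibrium generator excludes it by decision
and treats both couples as 2-electron systems.

## Dye-equilibrium potentiometry (`redox`)

With both couples at mutual equilibrium, the solution potential E satisfies
Σ n_i c_i f_red,i(E) = delivered equivalents, where f_red(E) =
1/(1 + 10^{n(E−E0)/s}) and s = ln(10)·R·T/F = 59.16 mV at 298.15 K (R =
8.314 J mol⁻¹ K⁻¹, F = 96 485 C mol⁻¹; recomputed if T is overridden).
`partition_electrons` solves this by bracketed Brent root-finding to a
residual below 1e-12 of total capacity.

The Minnaert plot regresses log₁₀([ox]/[red]) of the enzyme on that of the
dye by ordinary least squares over steps where both pools are 10–90% reduced
(outside that window the log-ratio variance explodes).  The slope estimates
n_enzyme/n_dye and the enzyme potential is E0_enz = E0_dye − intercept·s/n_enz,
with its SE propagated from the intercept SE.  Both couples default to n = 2
(flavin and thionine are two-electron dyes); the n values are explicit
parameters because they are an assumption, not a measurement.  OLS rather
than errors-in-variables regression matches the classical practice; with
noise in the x variable this is a known (small) attenuation bias and is
listed as a limitation.  Thionine's E0 is +64 mV; the generator's default
enzyme truth is +61 mV.

## Stopped-flow reoxidation (`kinetics`)

Traces follow A(t) = A_inf − ΔA·e^(−k_obs t) under pseudo-first-order excess
O₂ (the generator warns below a 5× O₂:enzyme ratio).  The fit is nonlinear
least squares with a derivative-free start: A_inf ← last-decile mean, ΔA ←
A_inf − A(0), k ← ln 2 / t at half recovery.  A trace whose head-to-tail
excursion is under 5 standard errors of the decile means is declared
indeterminate rather than fitted.  k₂ = k_obs/[O₂]; its SE comes from a
200-replicate residual bootstrap (the published ±50 M⁻¹s⁻¹ has no stated
method).  The dissolved O₂ after 1:1 mixing of anaerobic enzyme with
air-saturated buffer is not stated anywhere, so the package default is
1.29×10⁻⁴ M (half of 2.58×10⁻⁴ M air saturation at 25 °C) and the value is a
mandatory parameter for real data.  Classification against free FAD
(250 M⁻¹s⁻¹): oxidase-like at ≥ 2×, dehydrogenase-like at ≤ 0.5×, otherwise
indeterminate; the 2×/0.5× thresholds are package decisions — the literature
comparison is qualitative.

## Active-site typing (`activesite`)

Queries are mapped onto AtBBE-like 28 numbering by global pairwise alignment
(BLOSUM62, affine gaps −11/−1); ties take the aligner's canonical first
alignment, which is deterministic.  The fingerprint reads the 13 diagnostic
positions {111, 113, 172, 174, 177, 182, 188, 369, 401, 426, 428, 470, 473};
a warning is raised when the conserved GGHD attachment context (109–112) is
absent.  The default rule table, in reference numbering:

| type | required residues |
|------|-------------------|
| I    | Y113, Q428, Y188, K426, Y473 |
| IIa  | Y113, Q428, Y188, E426, D369, H/Y174 |
| IIb  | Y113, Q428, Y188, E426, C174, H182 |
| III  | E428, and Y188 or Y473 |
| IV   | Q428, Y473, D/E369 |

Scores are matched-position fractions of each type's maximum; a call requires
the best score to reach 60% of its maximum and strictly beat the runner-up,
otherwise `unclassified`.  Cross-protein numbering used by the type III/IV
descriptions (e.g. a Tyr479/Lys436 base motif mapping to reference 473/426)
is an equivalence chosen here, editable by supplying a custom `RuleTable` —
no full equivalence table is published.  Attachment: His111 is prerequisite
for any covalent call; Cys174 adds the C6 linkage (bicovalent), otherwise
mono-8α-His.  Oxygen class from the gatekeepers: Gly172 ∧ Val177 →
oxidase-like; Ala172 ∨ Leu177 → dehydrogenase-like; else ambiguous.

Sequence logos use column information R = log₂20 − H (Shannon entropy of
observed letters, gaps excluded) and letter heights f·R; no small-sample
correction by default.

The packaged reference sequence is a **synthetic stand-in**: a fixed
pseudo-random 500-residue scaffold carrying the GGHD motif and the type-IIa
diagnostic residues at their literal reference positions.  Retrieval of the
real UniProt/TAIR sequence is optional tooling, never a test dependency.
Synthetic families share that scaffold, protect the diagnostic positions and
mutate every other position independently at the requested rate — so passing
round-trip tests demonstrates that mapping, extraction and rules compose
correctly, not that divergent natural homologs align correctly to the real
reference.

## Phylogenetics (`phylo`)

The distance pipeline is native code: column jackknife (default delete
fraction 0.5, the classic convention; only "1000 jackknife sub-alignments" is
on record), pairwise-deletion p-distances with Kimura's correction
d = −ln(1 − p − p²/5) capped at d = 10 (with a warning) when p ≥ 0.8541, NJ
with the Q criterion, smallest-(i,j) tie-break and Studier–Keppler branch
lengths (negative lengths clamped to zero, deficit shifted to the sister edge
so path lengths are preserved), greedy majority-rule consensus (supports =
bipartition frequencies, stored as internal-node labels; no branch lengths on
the consensus), and outgroup rooting at the pendant-edge midpoint.  The JTT
model of the original PROTDIST default is deliberately not re-implemented:
the model actually used is not on record, and the Kimura correction is the
documented substitute.  Distance matrices are required to be symmetric but
not metric — NJ does not need the triangle inequality.  NJ consistency
(exact recovery of additive matrices) is property-tested over random 4–8-taxon
trees.  Pipeline determinism: replicate seeds are spawned from one seed, so a
fixed seed reproduces the newick string byte-for-byte.

`evolve_alignment` evolves ungapped sequences down a user tree; the per-site
substitution probability on a branch of length L is 1 − (1 − p₁)^L, where p₁
is the probability on a unit branch, and substitutions draw uniformly from
the 19 alternatives (a Jukes-Cantor-like protein model — no rate
heterogeneity, no indels).  Consensus supports from such alignments therefore
test the resampling machinery, not robustness to alignment error.

## Geometry (`structgeom`)

PDB-format input is parsed with gemmi; alternate locations other than ''/'A'
are dropped and occupancies ignored (deterministic atom selection for
distance work).  Hydrogen bonds and salt bridges are quoted as heavy-atom
minimum distances over N/O atoms, with no angle criterion — matching how such
contacts are usually printed.  The butterfly bend is the angle in [0°, 90°]
between least-squares (SVD) planes of the pyrimidine ring {N1, C2, N3, C4,
C4X, C10} and the dimethylbenzene ring {C5X, C6, C7, C8, C9, C9A}; flavin
junction-atom naming differs between dictionary versions, so C4A/C4X,
C5A/C5X and C10/C10A are accepted as aliases.  Superposition is Kabsch with
the reflection branch forbidden.  The toy isoalloxazine generator builds the
tricycle from regular hexagons in a plane and rotates the benzene wing about
the N5–N10 axis, so the constructed bend equals the measured inter-ring angle
exactly — the oracle for the bend measurement.  Chain A and residue selection
defaults suit single-ligand checks; measurements on a deposited model require
the user to fetch coordinates themselves (no network access is assumed
anywhere in the package or its tests).

## Problem sizes and reproducibility

Default study conditions: 15 µM enzyme and dye, 1-cm path, 300–700 nm at
1 nm, 0.002 AU additive i.i.d. Gaussian noise, 30-step titration schedule
covering the full 2·[E] + 2·[D] electron capacity, 300-point kinetic traces
spanning six half-lives.  Recovery statistics in the tests use 10–100 seeded
replicates per condition and the phylogenetic property tests use 100 random
trees and 100 jackknife replicates on 1000-column alignments — sizes chosen
so the whole suite completes in seconds while keeping Monte-Carlo bounds
meaningful.  Every stochastic routine takes an explicit seed; equal seeds
give byte-identical outputs.

## Known limitations

- OLS on the Minnaert plot ignores noise in the dye log-ratio (attenuation
  bias, negligible at default noise but not in general).
- The two-step photoreduction ladder is an equilibrium description; no
  photochemical kinetics.
- The rule table encodes one published typology; scores weight all positions
  equally and ignore phylogenetic correlation between positions.
- The synthetic reference scaffold is not the natural AtBBE-like 28 sequence;
  numbering-sensitive results on real homologs need the real reference.
- `evolve_alignment` has no indels, so jackknife behavior under gappy
  alignments is untested by the generators (though `protein_distance`
  handles gaps by pairwise deletion).
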