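# Methods

## Scope and model assumptions

The package treats an [Fe2S2] cluster as an isotropic exchange-coupled
pair of site spins, `H = J S₁·S₂` with J in cm⁻¹ and J > 0
antiferromagnetic. Zero-field splitting, anisotropic/antisymmetric
exchange and pseudocontact shifts are outside scope: Fe–S clusters have
negligible magnetic susceptibility anisotropy, so the hyperfine shifts
are taken as purely contact and the through-space terms enter only via
relaxation. Site spins are restricted to {1/2 … 5/2}; the oxidized
cluster is S₁ = S₂ = 5/2 (two high-spin Fe³⁺) with a diamagnetic S′ = 0
ground multiplet, and the reduced cluster would be 5/2 ⊗ 2.

Contact shifts are Boltzmann averages over the ladder of the projected
per-site moment, `W = Σ c_i S′(S′+1)(2S′+1)e^(−E/kT) / Σ (2S′+1)e^(−E/kT)`,
with the Landé-type projection coefficients and `c_i(S′=0) = 0` (the
singlet carries no electron moment but stays in the partition function).
Two checks pin the implementation: the ladder agrees with dense
diagonalization of the product-basis Hamiltonian for every admissible
spin pair, and the J → 0 homodimer limit reproduces the monomer Curie
law (effective S(S+1) = 8.75 for S = 5/2).

Fitting J and A/h to shift-versus-temperature data is linear in A/h at
fixed J, so the fit profiles J and solves A/h per proton in closed form.
With only two temperatures the (J, A/h) pair lies on a ridge; the fit
then *refuses* to return a point estimate and reports the profile
instead. This is deliberate: two-point temperature series constrain the
sign of the temperature dependence (hence the sign of J) but not its
magnitude.

## Relaxation

Paramagnetic R₁/R₂ use the Solomon point-dipole expressions, the scalar
(contact) term, and the Curie-spin term, with the coupled cluster
entering through a c_i²-weighted Boltzmann average ⟨S(S+1)⟩ over the
ladder — no level-specific electron relaxation times are modeled.
Dipolar and Curie terms share the r⁻⁶ distance law, which justifies the
operational calibration `Δν(r) = floor + (Δν_ref − floor)(r_ref/r)⁶`:
one observed (distance, linewidth) anchor absorbs every unknown
prefactor, in particular the electron relaxation time τ_s, which is
treated as a fit-free nuisance throughout. The full Solomon path is
still available and the two agree exactly on linewidth ratios.

Defaults that matter:

* detection threshold 4 kHz (strict >; configurable) — lines broader
  than this count as beyond detection;
* diamagnetic linewidth floor 30 Hz, from the sharp exchangeable amide
  lines (70–250 Hz) minus plausible exchange contributions;
* electron relaxation time for illustrative Solomon runs 1e-10 s, in the
  fast-relaxing regime typical of Fe–S clusters, making the dipolar
  correlation time electron-dominated (τ_c ≈ τ_s ≪ τ_r).

The ¹⁵N correlation-time estimator inverts the rigid-isotropic-rotor
R₂/R₁ ratio built from N–H dipolar (1.02 Å) and CSA (−160 ppm) spectral
densities, bracketed over 1–50 ns. It requires R₂/R₁ > 1 and raises a
regime error in extreme narrowing. The empirical cross-check is the
0.6 ns/kDa rule at 298 K: a 19.4 kDa dimer gives 11.64 ns, and the
noiseless forward-simulate/invert round trip recovers it to numerical
precision.

## Pulse filters

The inversion-recovery (superWEFT-type) filter is modeled on
longitudinal magnetization only, as the cyclic steady state
`M = 1 − (2 − e^(−R₁ t_rec))·e^(−R₁ τ_IR)`. With the 18 ms inversion
and 16.5 + 11 ms recovery delays the null sits at R₁ ≈ 18.9 s⁻¹. One
model property worth knowing: when t_rec > τ_IR, M dips shallowly
negative (minimum ≈ −0.04 near R₁ ≈ 8.5 s⁻¹) before its single zero
crossing, so "strictly increasing" holds only past the dip; the model
is therefore characterized by its single sign change rather than global
monotonicity. The filter predicts sign from M directly; antiphase
build-up and transfer losses are factored into the INEPT term, and
incomplete IPAP decoupling at shortened delays is not modeled.

The C′–N INEPT transfer uses `f = sin(πJT)·e^(−R₂T)` with total time
T = 2Δ and J(C′N) = 15 Hz by default (a standard one-bond value). The
closed-form optimum `T* = atan(πJ/R₂)/(πJ)` matches brute-force grid
search; the 12.5 ms vs 8 ms crossover sits at R₂ ≈ 33 s⁻¹.

## Structure handling

PDB I/O goes through gemmi; alternate locations resolve to the
highest-occupancy conformer. Backbone amide protons are rebuilt with
idealized geometry (1.01 Å along the opposed bisector of N–CA and
N–C(i−1), in the peptide plane); prolines, chain N-termini and residues
with incomplete backbone are skipped, and existing protons are never
moved. Full side-chain protonation is expected from external tools and
accepted on input.

The covalent graph is distance-thresholded (1.9 Å generic, 2.6 Å for
metal–donor coordination bonds, H–H never bonded) — sufficient for the
ligand/cluster topologies this analysis needs, with no residue topology
dictionary. Through-bond counts are shortest paths on that graph,
computed only when the proton's residue coordinates the iron.

"Nearest iron" is the minimum over all irons in the structure; the
distance to the coordinating iron is emitted alongside it. The blind
sphere is the maximum nearest-iron distance over undetected amides,
with undetected amides beyond a 12 Å cutoff reported separately as
outliers (their absence is attributed to exchange, disorder or overlap
rather than paramagnetism), and the result rounded to 0.5 Å — the
granularity at which such radii are meaningful.

## Assignment rules

Candidate filtering applies, in order: (1) r < 4.0 Å → broadened beyond
detection; (2) more than 3 covalent bonds from the iron *and* not on
the coordinating histidine's imidazole ring → contact coupling below
the ~1 MHz class, excluded from the strongly shifted set (the
conjugated ring delocalizes spin further than σ-bonded frameworks);
(3) exchangeable signals may only match nitrogen-bound protons. The
partition is exhaustive and disjoint, every decision carries a
rule-trace string, and on the packaged distance table it leaves exactly
four CH candidates and one N-bound candidate. NOE matching is exhaustive
over one-to-one pairings (candidate sets here are small), scoring
observed peaks against structure-predicted partners within 0.05 ppm
(typical 1D resolution; no value is standard), weighted by r⁻⁶
intensity normalized per candidate. Ties are reported as ambiguous,
never broken silently — the packaged table itself leaves one two-way
ambiguity (Cys-74 Hα vs His-87 Hβ2) that the data cannot resolve.

## Synthetic data

The generators produce every input with known ground truth: a toy
[Fe2S2] site (Fe–Fe 2.7 Å, thiolate S at 2.3 Å, imidazole N at 2.1 Å,
protons placed on spheres of requested radius with clash rejection at
0.8 Å), forward-modeled two-temperature peak tables (ladder shifts +
diamagnetic offset, r⁻⁶-calibrated linewidths, Gaussian shift noise),
rigid-rotor ¹⁵N tables with multiplicative noise, and sparse NOE peak
lists from a known assignment with configurable dropout. All randomness
flows through one explicit seed per call.

What the toy site does *not* emulate: real ligand conformations and
covalent proton topology (toy protons float unbonded, so bond counts on
the toy are undefined by design), spin diffusion in NOE build-up,
chemical exchange, and crystallographic artifacts. Passing tests on
synthetic data therefore validate the algebra and the decision rules,
not structure-specific numbers; structure-specific claims (e.g. the
amide count within 10 Å of the irons in the mitoNEET crystal structure)
need the actual PDB file, which is read but not bundled.

## Problem sizes and numerics

The bundled analyses use 40-residue relaxation tables, 5 % relaxation
noise, 19-amide synthetic shells and ≤ 25-seed Monte-Carlo scans —
sizes chosen so every driver and the full test battery complete in
seconds while keeping Monte-Carlo medians stable. Root finding uses
bracketed Brent iterations (τ_c in 1–50 ns, IR null in 1e-6–1e4 s⁻¹);
the two-temperature J profile uses a 60-point geometric grid over
1–2000 cm⁻¹. Blind-sphere radii round half-up to 0.5 Å after the
outlier cut, so subset monotonicity is preserved.

## Known limitations

* No level-specific electron relaxation; the ladder average is the
  finest granularity offered.
* The IR filter ignores off-resonance effects, pulse imperfection and
  the antiphase evolution during the HSQC transfer; its sign
  predictions near the null are therefore qualitative.
* The covalent graph can mis-bond exotic chemistry (metal clusters
  other than Fe–S/Fe–N coordination, very short contacts in poor
  structures).
* Amide rebuilding assumes trans peptide geometry and does not check
  for steric clashes of the placed H.
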