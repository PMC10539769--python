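# clusterblind

Paramagnetic NMR analysis of iron–sulfur cluster proteins: hyperfine
contact shifts of exchange-coupled [Fe2S2] spin ladders, paramagnetic
relaxation enhancement (PRE) and linewidth prediction with r⁻⁶
calibration, distance- and NOE-based assignment of hyperfine-shifted
signals, relaxation-tailored pulse-filter transfer functions, and
"blind-sphere" mapping of undetectable residues around the cluster.

## Who this is for

NMR spectroscopists and structural biologists working on paramagnetic
metalloproteins — in particular [Fe2S2] proteins such as the human outer
mitochondrial membrane protein mitoNEET, whose 3-Cys/1-His-ligated
cluster broadens the signals of nearby residues beyond detection in
standard experiments. The package quantifies that broadening, predicts
which protons are recoverable with relaxation-tailored experiments, and
assigns the hyperfine-shifted signals from structure-derived distances
and 1D NOE patterns.

## The models

**Spin ladder.** The two iron sites couple as `H = J S₁·S₂` (J > 0
antiferromagnetic, cm⁻¹). The total-spin multiplets S′ = |S₁−S₂| … S₁+S₂
have energies `E(S′) = (J/2)·S′(S′+1)` (relative) and per-site projection
coefficients `c₁ = [S′(S′+1)+S₁(S₁+1)−S₂(S₂+1)] / (2S′(S′+1))`. The
contact shift of a proton coupled to site *i* with constant A/h is

    δ_con = 2π(A/h) · g μ_B / (3 k T γ_I) · ⟨c_i S′(S′+1)⟩_Boltzmann

For an oxidized [Fe2S2]²⁺ cluster (S₁ = S₂ = 5/2, ground state S′ = 0)
the shift *grows* with temperature — the anti-Curie fingerprint.

**Relaxation.** Transverse PRE is the sum of Solomon dipolar, contact and
Curie-spin terms; dipolar and Curie terms scale as r⁻⁶ with the
metal-to-proton distance. Because the electron relaxation time is
usually unknown, headline linewidth predictions use the calibration

    Δν(r) = floor + (Δν_ref − floor)·(r_ref / r)⁶

anchored on one assigned signal. Lines above 4 kHz count as broadened
beyond detection. Rotational correlation times come from inverting the
rigid-isotropic-rotor ¹⁵N R₂/R₁ ratio (N–H dipolar + −160 ppm CSA).

**Filters.** The inversion-recovery (superWEFT-type) block is modeled as
`M(R₁) = 1 − (2 − e^(−R₁ t_rec))·e^(−R₁ τ_IR)`; the C′–N INEPT transfer
as `f(R₂) = sin(πJT)·e^(−R₂T)` with optimal `T* = atan(πJ/R₂)/(πJ)`.

## Worked example

```python
from clusterblind import (SpinSystem, HyperfineCoupling, contact_shift,
                          Calibration, calibrated_prediction,
                          IRFilterConfig, ir_null_r1)

dimer = SpinSystem(2.5, 2.5, 300.0)          # two Fe3+, J = 300 cm^-1
coup = HyperfineCoupling("A", 2.0, site=1)   # A/h = 2 MHz
print(contact_shift(dimer, coup, 283.0))     # 35.39 ppm
print(contact_shift(dimer, coup, 293.0))     # 35.89 ppm  (anti-Curie)

cal = Calibration(4.94, 2500.0, 30.0)        # anchor: His NHe2 at 4.94 A
print(calibrated_prediction(cal, 3.5))       # 19557.7 Hz  -> undetectable
print(ir_null_r1(IRFilterConfig()))          # 18.9 1/s IR suppression null
```

The contact shift of a 2 MHz-coupled proton grows from 35.4 to 35.9 ppm
between 283 and 293 K (anti-Curie, as expected for the S = 0 ground
state); a proton at 3.5 Å from the iron is predicted at ~19.6 kHz
linewidth, far beyond the 4 kHz detection bound; and the
inversion-recovery filter with 18 ms inversion / 27.5 ms recovery
suppresses amides relaxing slower than ~19 s⁻¹.

The numbered drivers under `analysis/` run the full story — synthetic
input generation (`01`), correlation-time estimation (`02`), the
hyperfine fingerprint (`03`), distance-based assignment (`04`) and the
filter/blind-sphere models (`05`) — writing their tables under
`results/`. A `clusterblind` console script exposes the same stages
(`clusterblind distances|blindsphere|predict|tauc|filters|assign|simulate`).

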