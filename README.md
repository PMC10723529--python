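# mesokit

Tools for characterizing the structure and dynamics of meso-scale
protein assemblies inside biomolecular condensates — the kind of
integrated analysis used to show that an intrinsically disordered
protein (p14ARF) forms an ordered, gel-like network upon phase
separation with its nucleolar chaperone NPM1.

The package covers six analysis stages, each usable on its own:

1. **SANS model fitting** (`mesokit.sans`): reduced small-angle
   scattering curves are fit by weighted least squares to a broad peak
   model, a broad peak model with a correlation length term

   I(q) = C₀ / (1 + (ξ₀|q − q₀|)^m₀) + C₁ / (1 + (Ξ₁q)^m₁) + B,

   or a correlation length model.  The fitted peak position gives the
   real-space d-spacing d₀ = 2π/q₀ and the exponents give polymer
   scaling exponents ν = 1/m (ν ≈ 0.33 collapsed, 0.5 theta,
   ≈ 0.6 expanded coil, → 1 rod).
2. **Conformer ensembles** (`mesokit.conformers`): statistical-coil
   pools (default 10,000 conformers) built from (φ, ψ) sampling with
   secondary-structure directives, cooperative β-strand admixture
   (0–37.5 %) or non-cooperative Gaussian sampling; per-conformer
   radius of gyration, scaling factor ν solving R_g = ρ₀N^ν, and
   surrogate chemical-shift predictions with a plugin seam for
   published predictors.
3. **Bayesian refinement** (`mesokit.bayes`): conformer weights are
   refined against chemical shifts (Gaussian likelihood with variance
   ε²_CS + α²_CS) and the scaling factor (variance ε²_ν), iterating
   Bayes' theorem with each posterior as the next prior; top-160
   selection and rank-sum comparison of refined ensembles.
4. **Lattice assembly** (`mesokit.lattice`): conformers placed on 2D
   square/rectangular lattices, orientationally averaged scattering via
   a pair-distance-histogram Debye sum, an exhaustive chi-squared grid
   search over space groups, array sizes (2×2–4×4) and spacings
   (160–200 Å), and intermolecular Cα–Cα distance histograms.
5. **FRAP** (`mesokit.frap`): background/photofading correction,
   recovery normalization, hyperbolic half-time fits, mobile fraction,
   effective bleach radius from the Gaussian laser profile, and
   D_app = (r_e² + r_n²)/(8 t_½).
6. **Imaging & NMR** (`mesokit.imaging`, `mesokit.nmr`): multi-Otsu +
   density-clustering segmentation of nuclei/nucleoli with per-object
   z-scores, index of dispersion (σ²/μ) phase diagrams; R1/R2/hetNOE
   fitting and CPMG relaxation-dispersion model selection with
   Monte-Carlo errors.

`mesokit.synth` generates every input class with seeded, reproducible
statistics (broad-peak SANS curves, conformer observations,
pure-diffusion bleach movies, nucleolar images, dispersion profiles),
so every stage can be validated end to end without instrument data.

## Worked example

```bash
python examples/fit_sans_curve.py
```

```
reduced chi^2        : 0.76
high-q exponent v0   : 0.662   (chain statistics: ~0.6 = expanded coil)
low-q exponent v1    : 0.353   (~0.35 = collapsed/branched network)
peak position q0     : 0.03497 1/A
d-spacing 2*pi/q0    : 179.7 A  (characteristic intermolecular spacing)
correlation lengths  : xi0=85.5 A, Xi1=161.6 A
```

The fit says the labeled chains are locally expanded (ν₀ ≈ 0.66) but
organized into a branched network at long range (ν₁ ≈ 0.35), with a
pseudo-Bragg peak corresponding to a ~180 Å spacing between chains —
the signature of meso-scale ordering inside the condensate.  The other
examples (`examples/*.py`) walk through ensemble refinement, the
lattice grid search, the FRAP pipeline, segmentation and CPMG fitting
the same way.

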