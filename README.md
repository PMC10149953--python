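# qsmlm

Quantitative single-molecule localization microscopy (qSMLM) analysis of
membrane receptor organization: blinking-corrected molecular counting,
pair-correlation (PC) cluster analysis, and spatiotemporal grouping of
localizations — with a ground-truth simulator for validating every
estimator by parameter recovery.

## Who this is for

SMLM (PALM/dSTORM) labs studying how membrane receptors — e.g. growth
factor receptors such as HER2 under antibody or multivalent-ligand
treatment — reorganize into nanoscale clusters.  The package starts from
localization tables (x, y, frame, photons, precision) exported by any
standard detection pipeline and produces the quantities such studies
report: detected molecular densities, distributions of molecules per
cluster and of cluster radii, and the fraction of receptors found as
monomers, dimers, or clusters of more than two molecules, with
group-level statistics.

## The method

A fluorophore blinks: one molecule yields on average α localizations
(α ≈ 5 for paGFP, ≈ 3 for AF647 under calibrated conditions), so counts
are corrected as N_mol = N_loc / α.  Spatial organization is measured by
the pair-correlation function of the binarized localization image,
computed by FFT with exact rectangular-window edge correction, and fitted
with

    g(r) = c + B·exp(−r² / 4σ_s²) + A·exp(−r / ξ)

where the Gaussian term captures blinking overcounting at the precision
scale σ_s, and the exponential term captures receptor clustering with
correlation length ξ (reported as the cluster radius) and

    N_c = 2π ρ_mol A ξ²   (molecules per cluster).

Localizations are then grouped into molecules using spatiotemporal
thresholds (group radius = 3 × maximum localization precision; maximum
dark time 5 s), and molecules into clusters by single linkage at a link
radius derived from ξ; components of more than two molecules define the
clustered fraction.  See `docs/methods.md` for the full model,
assumptions, and numerical choices.

## Worked example

```python
from qsmlm import analyze_roi, ROI
from qsmlm.simulate import make_scenario, PALM_ACQ

# a simulated acquisition with known truth: half the receptors in
# clusters of Gaussian scale 80 nm, mean occupancy 8, 50 molecules/um^2
pattern, table, meta = make_scenario("mab_single", seed=7)
roi = ROI(0.0, 0.0, pattern.side_nm, pattern.side_nm)

result = analyze_roi(table, roi, PALM_ACQ)
print(f"localizations (filtered): {result.n_locs}")
print(f"molecules (blink-grouped): {result.molecules.n_molecules}")
print(f"alpha-corrected density:   {result.density_per_um2:.1f} molecules/um^2")
print(f"cluster radius (xi):       {result.fit.xi_nm:.1f} nm")
print(f"fraction clustered:        {result.clustering.fraction_clustered:.2f}")
print(f"true fraction clustered:   {pattern.true_fraction_clustered:.2f}")
```

prints

```
localizations (filtered): 3616
molecules (blink-grouped): 779
alpha-corrected density:   45.2 molecules/um^2
cluster radius (xi):       81.4 nm
fraction clustered:        0.55
true fraction clustered:   0.50
```

The 3616 filtered localizations collapse to 779 molecules — consistent
with 3616/5 ≈ 723 from the α rule (the grouped/α-counted ratio is a
logged QC metric).  The fitted cluster radius (81.4 nm) recovers the
generating 80 nm scale, and the measured clustered fraction (0.55) tracks
the generating truth (0.50); the small excess is chance co-location of
monomers with clusters, quantified in `docs/methods.md`.

A command-line interface mirrors the library
(`qsmlm simulate | preprocess | pcf | cluster | report`); run
`qsmlm --help` for the subcommand flags.

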