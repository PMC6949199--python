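# Methods

## Attenuation model and calibration

Reconstructed attenuation is modelled as linear in the local agent
concentrations (Beer–Lambert with Bragg additivity):

    alpha_E = b_E + mu_I,E * C_I + mu_Gd,E * C_Gd + mu_Bi,E * C_Bi

in arbitrary "reconstructed attenuation units". All physics is
unit-consistent as long as phantoms and samples share the reconstruction
scale, so no absolute unit is assumed. The two beam energies (32 and
34 keV) straddle the iodine k-edge at 33.2 keV and sit below the
gadolinium k-edge at 50.3 keV; this ordering (`mu_I,34 > mu_I,32`,
`mu_Gd,32 > mu_Gd,34`) makes the decomposition determinant
`D = mu_I,34 mu_Gd,32 - mu_I,32 mu_Gd,34` strictly positive, which is
asserted on every calibration. A conditioning floor `|D| >= 1e-6`
(calibrated units) guards against near-singular calibrations.

Calibration fits a least-squares line per agent per energy over
single-agent dilution series. The fit includes an intercept by default:
phantoms are aqueous dilutions, so attenuation at zero concentration is the
solvent background, not zero. A through-origin mode is available. The
bismuth term exists only to render the bath (and bath-filled cracks)
bright; with two energies it is never solved for — its known contribution
(`mu_Bi,E * C_Bi,nominal`) is subtracted from bath measurements before
decomposition, which is valid because the nanoparticles neither enter
tissue nor deplete.

## Decomposition

Concentrations are recovered by the closed-form 2x2 inversion (Cramer's
rule, exactly the printed formulas). Raw outputs may be slightly negative
under noise after baseline subtraction; they are preserved in all
intermediate data and clamped to zero only in reported partition tables
behind a flag (`clip_negative`), because clamping before depth averaging
would bias profile means upward. In the sample pipeline, decomposition
operates on depth-averaged profiles (averaging before inversion is
harmless: the inversion is linear), mirroring the order of the
experimental protocol; mixture-phantom validation uses ROI means.

## Synthetic samples

The generator emulates the study conditions with known ground truth; its
defaults *are* the study design and are not tuned per analysis:

- Bath: 5 mg I/mL CA4+, 10 mg Gd/mL gadoteridol, plus 10 mg/mL BiNP in the
  triple mixture; reservoir >= 100x cartilage volume; 2 h immersion.
- Acquisitions: 34, 32, 34 keV separated by 331 s, each 129 s long and
  represented by its mid-scan time; plus an agent-free baseline pair.
- Geometry: 96x64x64 voxels at 13 um (half instrument resolution, so the
  full cohort renders in seconds; instrument resolution is
  config-selectable), bath above cartilage above subchondral bone, smooth
  sinusoidal surface/bone tilt of +/-2 voxels.
- Noise: additive Gaussian sigma = 0.2 reconstructed units per voxel
  (~1% of bath attenuation), a reconstruction-noise proxy; Poisson
  counting noise is out of scope. Phantom ROI-mean measurements carry
  sigma = 0.04 — chosen a priori from error propagation through the 2x2
  inversion so the expected mixture recovery errors (~1%) sit at the
  reference phantom accuracy.

Uptake uses the erfc solution of 1-D semi-infinite Fickian diffusion with
a depth-dependent equilibrium partition factor:

    C_X(z, t) = K_X(z) * C_X,bath(t) * erfc(z / (2 sqrt(D_X t)))

with `K_I = k_I * fcd(z) * water(z)` (cationic agent tracks FCD) and
`K_Gd = k_Gd * water(z) / steric(z)` (neutral agent tracks water, hindered
sterically); `k_I = 2.4`, `k_Gd = 0.5`, `D_I = 5`, `D_Gd = 8` um^2/s give
2-h profiles that are far from equilibrium with the front mid-tissue, the
regime the protocol targets. This is the simplest closed form with the
right qualitative behaviour; it ignores charged-transport (Donnan)
electrochemistry, concentration-dependent diffusivity and lateral
diffusion. The bath depletes by exact mass conservation on the rendered
grid: `C_bath(t) = C_0 / (1 + W(t)/V_bath)` where `W(t)` is the rendered
unit-bath tissue uptake, so bath + tissue mass is conserved identically at
every acquisition.

Groups: *intact*; *PG-depleted* (FCD scaled to 25% superficially with a
residual deep fraction, water x1.05, steric x0.85); *injured* (surface FCD
loss, water x1.10, steric x0.80 — the post-impact water/steric shifts are
free parameters, no quantitative reference exists — plus two bath-filled
planar cracks, 39 um wide, reaching 40% depth, carrying exactly 100%
partition). In cracked columns the fissure is bath-continuous, so the
ground-truth surface is defined as the first non-bath-filled voxel (the
crack bottom): that is the only boundary any attenuation-based
segmentation can see, and it reproduces the deeper agent delivery observed
in injured tissue.

Biological variability enters as clipped multiplicative jitter at patella
and sample level on FCD (sigma 0.12/0.05), water (0.10/0.03), steric
hindrance (0.04/0.03), thickness (0.08, plus 0.02 between the dual/triple
halves of a sample) and per-sample effective diffusivity (sigma 0.35).
The transport CV is deliberately large: at 2 h raw CA4+ uptake is
transport-limited, which is precisely the confound the gadoteridol
normalisation removes, and these magnitudes place the pooled
partition-vs-optical-density correlations in the moderate range the study
design operates in (r ~ 0.8 rather than a noise-free ~0.97). Optical
density is the FCD profile with a per-sample scale error (lognormal sigma
0.15, stained sections are not the imaged volume) and bin-wise staining
noise (0.10).

What passing tests do *not* show about real data: the generator has no
partial-volume blurring, beam hardening, reconstruction artefacts,
registration error between scans, or real biochemistry — recovery accuracy
here bounds only the analysis chain, not the physical measurement.

## Segmentation and profiling

Surface detection is per column and mixture-dependent. Triple: the
BiNP-bright bath sits far above any tissue attenuation, so the surface is
the steepest sustained (3-voxel) bath-to-tissue drop; columns without a
qualifying drop are excluded, and > 20% exclusions abort (a pure-bath
volume has no interface). Dual: an Otsu threshold on the volume histogram
with a 3-voxel sustained crossing — intrinsically biased at 2 h because
enhanced superficial tissue nearly matches the bath, which is the
measured motivation for the triple mixture; the pipeline therefore routes
dual-arm cohort samples through the mask-import path (externally supplied
label volumes; in simulation, the generator's own labels stand in for
manual segmentation). The bone interface is the largest sustained
attenuation rise below the surface at both mixtures.

The VOI is a cylinder through the cartilage thickness, default diameter
1313 um; the default cohort configuration uses 650 um because the
half-resolution grid's 832-um field of view cannot contain the full
cylinder. Crack masking combines a surface-envelope rule (columns whose
detected surface lies > 2 voxels below the 7x7 median-filtered surface are
fissures; their bath-level voxels are relabelled) with an attenuation
threshold (midpoint of bath and cartilage medians) applied >= 3 voxels
below the local surface — the depth guard keeps legitimately bright
superficial tissue from being excluded, the conservative counterpart of
leaving a margin inside the crack. Crack masking is applied to injured
samples, as in the protocol.

Depth profiles assign every included cartilage voxel the fraction
`(z - surface)/(bone - surface)` of its own column, making the binning
invariant to tilt and thickness variation. The default is 40 bins: the
thinnest jittered sample spans ~44 voxels, so every bin stays populated,
and the zone boundaries (0.10, 0.40) fall exactly on bin edges. The two
34 keV profiles are averaged (first-order cancellation of diffusion drift
around the 32 keV scan) and the native profiles subtracted bin-wise.

## Partition and zones

Partition is 100 x C_tissue / C_bath per agent, referenced to the bath
*measured at the matching acquisitions* (baseline-subtracted bath ROI mean
with a 5-voxel guard band under the surface, bismuth term removed, then
decomposed) — the bath is ~0.3% depleted by 2 h and continues to fall
between scans. The normalised profile is the bin-wise ratio of CA4+ to
gadoteridol partition; bins with gadoteridol partition below 1% are
reported missing rather than extrapolated (early-time deep bins would
otherwise explode). Zone means are voxel-count-weighted; the full-thickness
value is the weighted mean over all bins.

## Statistics

- Pearson correlation with two-sided t-based p values; correlations pool
  all 27 samples of a mixture across groups (per-group correlation is
  available but not the default).
- Dependent correlations are compared with Williams' t on n - 3 degrees of
  freedom, the variant recommended for two correlations sharing one
  variable; a Fisher-z variant is available behind a flag. Its empirical
  type-I error at alpha = 0.05 is verified at ~5% by simulation.
- Wilcoxon signed-rank p values are exact by full sign-pattern enumeration
  for up to 12 non-zero differences (average ranks under ties; two-sided p
  = min(1, 2 min(lower tail, upper tail))); larger samples use the normal
  approximation with tie correction. Zero differences are dropped by
  default (Pratt handling optional).
- No multiple-testing adjustment is applied; the significance flag is
  exactly p < 0.05.

At the study's n = 9 pairs per group comparison and n = 27 per
correlation, the middle-zone normalisation benefit (r(normalised, OD) >
r(raw, OD)) is a statistical tendency, not a per-dataset certainty: two
dependent correlations of ~0.85–0.92 differ by about the sampling noise of
their difference, so individual cohorts can invert it — consistent with
the benefit reaching significance only in the middle zone in the original
design.

## Numerical and design notes

- All randomness flows from a single seed (SeedSequence-spawned per
  stage/sample); cohort generation and rendering are byte-reproducible.
- Volumes are float64 multi-page TIFFs with JSON sidecars; round trips are
  bit-exact. NRRD is not supported.
- Degenerate inputs: < 2 distinct phantom concentrations, non-finite
  attenuations, singular calibrations, pure-bath volumes, zero-thickness
  columns, empty zones, all-zero Wilcoxon differences and inconsistent
  correlation matrices all raise typed errors rather than propagating
  NaNs.
- The scaled-down defaults (13-um voxels, 650-um VOI, 40 bins, 9 patellae)
  keep a full cohort run under half a minute on one core; instrument-scale
  settings are plain configuration changes.
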