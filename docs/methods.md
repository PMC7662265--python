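# Methods

This note documents the models implemented in `pephelix`, the calibration
constants and defaults that matter, what the synthetic generators do and do
not emulate, and the numerical choices made where the design was open.

## CD helicity

Raw ellipticity θ (mdeg) is normalized to mean-residue molar ellipticity

    [θ](λ) = θ(λ) / (10 · c · l · N),

with c the molar peptide concentration, l the path length in cm and N the
residue count.  The per-residue normalization is a package choice: it is
the convention under which the 222 nm estimator's limits (below) have their
usual magnitudes, and the linearity tests assert it.

Helix content of a free peptide comes from the single-wavelength affine
estimator

    % helix = 100 · (3000 − [θ]₂₂₂) / 39000,

i.e. the linear interpolation between a random-coil limit of
+3000 deg·cm²·dmol⁻¹ and a full-helix limit of −36000 deg·cm²·dmol⁻¹ at
222 nm.  For table reproduction, percentages are rounded half-away-from-zero
to integers; the unrounded value is always retained, and values outside
[0, 100] are flagged, never clamped.  No multi-basis deconvolution
(CONTIN/CDSSTR-style) is attempted: the single-wavelength estimator is the
method under study.

Smoothing is a Savitzky–Golay polynomial filter (default window 11 points,
order 3, endpoints by polynomial fit).  It stands in for instrument-vendor
"adaptive" smoothing, whose algorithm is unpublished, and is **off** by
default for the 222 nm readout.

Spectral classification uses coarse shape rules on the 190–260 nm band:
*helical* requires local minima within 208 ± 3 and 222 ± 3 nm plus a
positive band below 195 nm; *random coil* requires the global minimum in
195–200 nm without the double minimum; anything else (including a flat
spectrum) is *other*.  Minima are detected with a prominence floor of 1% of
the spectrum's range to ignore noise wiggles.

## Secondary shifts and two-state populations

Secondary shifts are Δδ(i) = δ_obs(i) − δ_RC(aa_i).  The random-coil
reference must be named: the default set `wishart1995` is the Wishart-style
¹H/¹³C peptide table (water, 25 °C, pH ≈ 5); alternative sets can be
registered, and every Δδ profile records which set produced it.
Sequence-neighbor corrections are supported but **off** by default.
Temperature/pH corrections are not applied.

Helical segments are read off the Δδ_Hα profile as maximal runs of at least
3 consecutive residues with Δδ_Hα < −0.05 ppm (the random-coil band
half-width).  A single interior residue at or inside the band — or a gap in
the profile — terminates a run, so one hinge residue splits a helix in two.
The run-length minimum of 3 and the single-residue-breaker rule are package
choices; they reproduce the observed TMH7 (P394–K402) / D403 hinge /
H8 (L404–F408) decomposition of the CB1 elbow peptide, and the detector is
validated against a brute-force enumeration of qualifying runs.

Populations follow the two-state helix–coil model: a segment-averaged
secondary shift maps linearly onto population,

    % helix = 100 · ⟨Δδ⟩ / Δδ₁₀₀%,   Δδ₁₀₀%(Hα) = −0.39 ppm,
                                      Δδ₁₀₀%(Cα) = +3.1 ppm.

The two limits are calibration constants of the package, fixed by requiring
consistency with the full set of published (⟨Δδ⟩, %) pairs for these
peptides to within 1 point (the residual is attributable to the two-decimal
rounding of the published averages).  Errors are propagated linearly from
the per-measurement experimental uncertainties of 0.01 ppm (¹H) and
0.1 ppm (¹³C): ±2.6 points for Hα and ±3.2 points for Cα.  Note the Cα
uncertainty quoted in the source experimental work is "approx. 7%", which
does not follow from 0.1 ppm through this linear map; the package reports
the formula-propagated 3.2% and records the discrepancy here as a known
limitation.  The Hα- and Cα-derived percentages for a segment are combined
as the mean of the two integer-rounded values with the population standard
deviation (half their absolute difference) as the spread.

## Chemical-shift-perturbation interface mapping

Free-versus-mixture perturbations are combined per residue as

    Δδ_w = √(Δδ_Hα² + Δδ_HN² + Δδ_Cα²/4),

where "HN" is the backbone amide proton and the ¼ weight scales the larger
¹³C dispersion onto the ¹H scale.  Only nuclei present in **both** tables
contribute; a missing nucleus contributes zero and is recorded as absent,
so prolines (no HN) and overlapped resonances never silently inflate or
deflate Δδ_w; a residue with no shared nucleus is omitted, not zero-filled.

Significance flagging defaults to `mean_plus_sd`: residues with
Δδ_w > max(mean + 1·SD of the profile, 0.02 ppm) are flagged; a fixed
cutoff policy is also available, and the policy string is embedded in every
output.  The threshold is a package choice — no quantitative cutoff is
published for these peptides.  Note the mean+1·SD rule is a *contrast*
detector: with ~17 background residues it will flag chance excursions when
the injected perturbations are not well separated from the background
(exact recovery needs injections several times the background SD; at
roughly 3× background SD the background tail crosses the threshold in a
substantial fraction of trials).  The recovery tests therefore operate with
injected Δδ_w ≈ 0.6 ppm, an order of magnitude above the noise background
produced by the stated measurement errors.

Flagged residues are exported as twin plain-text and JSON "active residue"
lists — the restraint seed for data-driven docking.  Docking itself
(rigid-body minimization, refinement, scoring) is out of scope.

## Ensemble geometry

Superposition is optimal least-squares (Kabsch) over atom pairs matched by
(residue number, atom name), default backbone {N, CA, C}, via scipy's
rotation alignment plus a small-angle Gauss–Newton polish: the SVD solution
alone carries ~10⁻⁸ rad of rotational noise, which matters when the true
RMSD is near zero; the polish refines the rotation from the residuals,
whose arithmetic is cancellation-free, and brings rigid-motion-invariance
errors below 10⁻⁹ Å.

Helix axes are the dominant principal axis of a segment's CA coordinates
(taken in residue-number order), sign-fixed so the projection of
(last CA − first CA) is positive — a *directed* N→C axis.  Directed axes
make angles in [0°, 180°] meaningful, so an obtuse elbow (e.g. 94°) is
distinguished from its supplement.  The principal-axis fit was chosen over
local rotational (Kahn-style) fitting for robustness on 5-residue helices;
`rms_to_axis` (≈ the 2.3 Å helix radius for a true helix) exposes fit
quality.  Two estimator properties to be aware of:

* *Partial-turn bias*: the principal axis of a discrete helix with a
  non-integer number of turns tilts from the true helix axis — up to
  ~10–18° for 5–7 residue segments, ~1° at 12 residues.  Angle statistics
  on matched constructions are unaffected (the hinged-ensemble builder
  prescribes the angle between *fitted* axes), but absolute axis directions
  of very short helices should be read with this in mind.
* *Boundary folding*: near 0° (or 180°) the arccos statistic folds noise
  outward, biasing the mean angle upward by roughly the per-model angular
  noise.  With 0.2 Å coordinate jitter a 5-residue axis carries ~6° of
  noise, so recovery tests at small angles use longer segments (12/15
  residues), where the noise floor is ~1°.

Inter-helix angles are arccos of the dot product of the two directed axes,
reported per model with arithmetic mean and population SD.  The
Ramachandran summary uses coarse rectangular φ/ψ regions (α, β,
left-handed α) with a 20° margin defining "allowed"; it is a sanity check,
not a validation-grade analysis.  PDB I/O handles ATOM/MODEL/ENDMDL/TER
records; HETATM is ignored and alternate locations other than blank/'A' are
rejected.

The published conformer ensembles behind the elbow-angle observations
(94° ± 15° in TFE, 75° ± 30° in DPC, 97° in the 5XRA crystal) have no
deposited coordinates; they are *inputs* this package can analyze, not
outputs it can regenerate.  The geometry drivers therefore operate on
synthetic hinged ensembles built at those angles, clearly labelled
`*_synthetic` in their filenames.

## Peptide properties

Masses are element-formula sums: residue compositions + one water, plus
C₂H₂O for an acetylated N-terminus and O→NH substitution for an amidated
C-terminus; average masses use IUPAC standard atomic weights and
monoisotopic masses the principal-isotope masses.  Net charge is the
standard single-site Henderson–Hasselbalch sum over the ionizable
inventory — capped termini contribute nothing — under a named pKa scale
(default `lehninger`, `emboss` also shipped; which scale the original
design screening used is not recorded, so it is configurable).  The
isoelectric point is the Brent-solved root of the charge curve on (0, 14),
tolerance 10⁻⁴ pH units; it is undefined (an error, not a number) for
peptides whose charge never crosses zero, e.g. capped sequences lacking
acidic or basic groups.  Helical-propensity prediction (AGADIR-style) is
out of scope.

## Synthetic data: what it does and does not emulate

The generators provide ground truth for every estimator, all bit-reproducible
under a fixed seed:

* **Shift tables** follow the two-state model exactly:
  δ_obs = δ_RC + f_i·Δδ₁₀₀% + ε with independent Gaussian ε of 0.01 ppm
  (¹H) and 0.1 ppm (¹³C) — the stated per-measurement experimental errors.
  The amide proton is given a zero helix limit (it is not a helix reporter
  in this analysis; it exists so CSP backgrounds carry realistic HN noise).
  Pro HN is omitted.  Not emulated: sequence-dependent nearest-neighbor
  effects, fraying gradients within a helix beyond what the per-residue
  profile encodes, exchange broadening, or temperature drifts.
* **Mixture tables** add user-specified (ΔHα, ΔHN, ΔCα) offsets at chosen
  residues plus fresh measurement noise, recording the ground truth.
  Real complexation also shifts neighbors of contact residues; the
  generator perturbs exactly the residues told.
* **CD spectra** are f·B_helix + (1−f)·B_coil with smooth parametric basis
  shapes: the helix basis has a positive band below 195 nm and minima at
  208/222 nm, the coil basis a single minimum near 197 nm.  Both are
  anchored at 222 nm to the estimator's −36000/+3000 limits, so the
  f → % round trip is exact at zero noise.  No claim is made that the full
  curves reproduce measured band shapes away from 222 nm.
* **Hinged ensembles** are ideal α-helices (φ = −57°, ψ = −47°, standard
  bond geometry via NeRF construction) with all atoms from the second
  segment onward rotated about the hinge CA so the angle between the two
  *fitted* axes equals the prescription exactly before jitter; Gaussian
  coordinate jitter is added per model.  The rotation leaves the hinge
  peptide bond geometrically strained — these are geometry fixtures, not
  physically minimized structures.

Consequently, passing tests demonstrate that the estimators are correct and
well-calibrated *under their own model assumptions* (two-state shifts,
Gaussian noise, ideal helices); they do not demonstrate robustness to the
systematic effects real spectra contain (reference-set mismatch, neighbor
corrections, micelle-induced shift perturbations, spectral overlap).

## Problem sizes

The default runs use the study's own scales: 19- and 14-residue peptides,
20-model ensembles, 200-replicate recovery studies at three helix
fractions, 500 random profiles for the segment-detection oracle and 50
random cases for the superposition oracle.  The full suite runs in well
under a minute on one CPU.

## Known limitations

* The Cα population error is reported as the formula-propagated ±3.2
  points; the provenance of the larger "approx. 7%" figure quoted for the
  original data is unknown (see above).
* The random-coil set actually used for the published Δδ values is not
  recorded; a different set shifts Δδ by per-residue-type constants and
  with it the segment averages (though not the two-state map itself).
* CSP flagging with mean+1·SD is scale-free but not a significance test;
  it has no false-positive guarantee for weak perturbations.
* Ballesteros–Weinstein labels are user-supplied configuration; the
  package computes nothing from them.
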