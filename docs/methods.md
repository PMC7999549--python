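# Methods

## Muropeptide chemistry and the compound library

A muropeptide is modelled by its composition: oligomer order 1–4, one stem
peptide per subunit (length 2–5: L-Ala, D-iGlu, meso-DAP, D-Ala, D-Ala),
the number of 1,6-anhydro-MurNAc termini, and a reduced flag. Only linear
D,D (4-3) crosslinked oligomers are enumerated — the canonical
Gram-negative chemotype. Branched trimer/tetramer topologies are excluded;
mass is topology-invariant for a fixed crosslink count, so quantification
is unaffected by this choice.

Neutral monoisotopic mass bookkeeping: condensed residue formulas are
summed; a connected molecule of any order carries exactly one water
(equivalently one water per subunit minus one per crosslink); the
1,6-anhydro modification removes one further water at its terminus;
borohydride reduction adds 2 H per free (non-anhydro) reducing end.
Atomic masses are hard-coded CODATA/IUPAC monoisotopic values; positive
mode [M+zH]^z+ with a proton mass of 1.007276 Da. The test suite checks
every library mass against an independent oracle that assembles the
molecule from free building blocks minus one water per condensation bond
(agreement to 1e-6 Da; the guaranteed tolerance is 1e-4 Da).

Species names are an artifact convention: order letter (M/D/T/Q), stem
lengths as digits in descending order, one `N` per anhydro terminus
(`M4`, `D44N`, …). The real study's in-house library is not published;
the default enumeration here (orders 1–4, stems {3,4,5}, all anhydro
counts, reduced) is a reconstruction and should be read as such.

## EIC quantification

Runs are centroided spectra (strictly increasing retention times,
non-negative intensities), read from mzML or a plain rt/mz/intensity CSV.
The mzML reader is self-contained (MS1, centroid-flagged spectra, 32/64-bit
float arrays, optional zlib); profile-mode spectra are rejected rather than
centroided internally.

Per library species and charge state (1–3) an EIC is formed by summing
intensities within a ±10 ppm window (default; Q-TOF-appropriate). The apex
is the global EIC maximum (restricted to ±0.5 min of the library retention
time when one is present). Peak boundaries are found on a 5-scan
moving-average copy of the trace: the contiguous region above 5% of the
apex, extended downhill to the flanking minima. Integration is trapezoidal
over the nonzero raw samples within the boundaries, after subtracting the
window minimum as baseline; zero-intensity scans are centroid dropouts
(m/z jitter leaving the ppm window) and are bridged rather than integrated
as real zeros. On noiseless Gaussian peaks this recovers areas to <0.1%;
at 5 ppm mass noise and 5% per-scan height noise a five-species
composition is recovered within ~0.5 percentage points per species.

Per record only the best charge state by area is kept, and each record
yields at most one identification. Molar normalisation assumes equimolar
response (area-proportional molarity): `molar% = 100 · area / Σ area`.
Response-factor correction, chromatographic alignment, and isotope-pattern
deconvolution are out of scope.

## Peptidoglycan summary statistics

Given species-level molar percentages and the library to resolve order and
anhydro status:

* oligomer percentage = Σ molar% over species of that order; the four
  classes must sum to 100 within a tolerance of 0.05 (accommodating inputs
  quoted at two decimals);
* crosslinks = `dimers% + 2·trimers% + 3·tetramers%`, i.e. crosslinked
  bonds per 100 muropeptide species, exactly as composition tables print
  it — no conversion to a crosslinked-peptide fraction;
* anhydro% counts each anhydro-containing species once (a
  `count_termini` option weights by terminus count instead);
* mean chain length = `100 / anhydro%` disaccharide units.

Report rounding is half-up at two decimals; underlying values are kept at
full precision.

The chain-length estimator is exact on a per-disaccharide-unit basis: each
strand contributes one anhydro unit, so units/strands = 100/anhydro% when
the percentage denominator is units. When units are grouped into multimeric
species, the species-based anhydro percentage is inflated (there are fewer
species than units) and the estimator no longer equals the strand mean;
the simulation checks therefore exercise it on monomer digests, where
species and units coincide — which is also the estimator's own premise.

## Synthetic data

* **Strands**: lengths are geometric with the requested mean (memoryless
  termination — the simplest law consistent with exactly one anhydro
  terminus per strand). Digestion draws species orders by the given
  probabilities until the unit budget is exhausted and scatters the
  per-strand anhydro marks uniformly over units; emitted molar percentages
  are realized counts, and the truth table carries directly counted
  crosslinks per 100 species, the per-unit anhydro percentage, and the
  realized mean strand length.
* **LC–MS runs**: per species a Gaussian elution peak (σ = 0.04 min) at an
  assigned retention time, sampled at 0.25 s per scan over an 18-min run;
  centroid m/z jittered per scan by the ppm noise, heights jittered per
  scan by the peak CV (per-scan noise averages out over the ~50 scans per
  peak, keeping integrated areas proportional to molar percentages).
  Monoisotopic singly-protonated peaks only — no isotope envelopes.
* **Cell images**: capsules (cylinder + hemispherical caps) at random
  non-overlapping poses, rendered into a light-background phase image and
  a fluorescence image. Widths are drawn with a linearly decreasing
  density over the range (an age-structured dividing population has more
  young, thin cells than deeply constricting ones; this also places the
  thinnest-60% group boundary near 1.0 µm for the default 0.66–1.50 µm
  range, as observed in width-grouped demographs). The localization field
  is a blend of two polar Gaussian foci (σ = 0.15 µm, at the cap centers)
  and a medial septal band (σ = 0.15 µm along the long axis, uniform
  across the short axis); under the default `mixed` model the septal
  weight rises linearly from 0 at 1.0 µm width to 1 at 1.3 µm. The field
  is masked to the cell interior and scaled so the integrated signal is
  density × volume (default 2000 a.u./µm³), then background (100 a.u.)
  and Gaussian noise (σ = 5) are added and the images quantised to 16-bit.
  No PSF/optics simulation: edges are sharp, so segmentation recovers
  dimensions to ~1 pixel. Passing tests therefore demonstrate the
  pipeline's correctness on idealised rods, not robustness to real optics.
* **Titrations**: inhibitory curves `1/(1 + (c/IC50)^h)`, enhancement
  curves `1 + a·c/(c + K)`; seven concentrations over four decades around
  the IC50 (or K), two replicates, 5% multiplicative noise on every lane
  including controls.

All generators take an explicit seed and are deterministic under it.

## Cell measurement conventions

Segmentation is Otsu thresholding of dark-on-light phase images with
8-connected components; objects below the minimum area or touching the
border are discarded. Axes come from the second moments of the mask pixel
coordinates; length and width are the full extents of the pixel
projections on the major/minor axis (+1 px, since projections are of
pixel centers), with length ≥ width enforced. Volume uses the
cylinder-with-hemispherical-caps model, falling back to a sphere of
diameter w when l < w. Background is a single scalar per image — the mode
of non-cell pixels for integer images (the median for float images, where
a mode is ill-defined) — and background-subtracted pixel values are
clipped at zero.

Axis profiles bin background-subtracted fluorescence along the min–max
normalised projection into 100 bins and normalise each cell's profile to
unit sum before any averaging (the per-cell normalisation choice is
deliberate: group means then weight cells, not brightness). Orientation is
deterministic but arbitrary: the end with the lower mean row index (mean
column as tiebreak) is position 0; no attempt is made to identify the
host-attached pole. Peak counting smooths with an edge-corrected 3-bin
moving average and counts maxima with prominence ≥ 0.2 × the smoothed
maximum; an exactly flat profile has no local maxima and counts 0.

Population grouping sorts ascending by width or area and sizes the groups
by cumulative-remainder rounding: each group receives
`round_half_up(remaining_n · f_i / remaining_f)`, so sizes always sum to
n (1258 cells at 0.6/0.2/0.1/0.1 → 755/252/126/125). Group profiles are
arithmetic means of member profiles, renormalised to unit sum.

## Titration conventions

Each replicate is normalised by its own zero-concentration control
(required, exactly one, positive), making the analysis scale-invariant per
replicate. Means and n−1 standard deviations are taken across replicates
per concentration; a single replicate reports sd 0 with a flag.
Classification thresholds (inhibition ≤ 0.5 anywhere; enhancement ≥ 1.2
at the top concentration, checked first) are package defaults exposed as
options — the underlying observations are qualitative. IC50 is the first
crossing of 0.5, linearly interpolated on log10 concentration between the
bracketing measured points; if the lowest nonzero concentration is already
below 0.5 that concentration is returned, and a curve that never crosses
has no IC50. Interpolation was chosen over 4-parameter logistic fitting
deliberately: with n = 2 replicates a nonlinear fit is unstable while the
crossing point is robust. Gel densitometry itself (band finding) is out of
scope; the input is a lane-intensity table.

## Problem sizes used in the checks

The packaged checks run at sizes chosen to make sampling error small
relative to the tested tolerances while keeping the suite quick: 5000
strands for the chain-length estimator (two standard errors ≈ 0.34
disaccharide units at mean 12.58), 400 rendered cells for the
localization-migration and constant-concentration properties, 200 seeded
titrations for IC50 recovery, and the full default library (139 species)
for the mass-oracle comparison.

## Known limitations

* Equimolar LC–MS response is assumed; real muropeptide response factors
  vary and the molar percentages inherit that bias.
* The peak model is a single Gaussian per species; co-eluting isobars
  within the ppm window are summed, not deconvolved.
* Geometry measures are pixel-grid extents, accurate to ~1 pixel; no
  subpixel contouring.
* The localization model is a 2-D intensity field, not a 3-D PSF-rendered
  image; conclusions about real microscopy require validation on real
  data.
* Retention-time prediction, MS/MS fragmentation, modified muropeptides
  (amidation, acetylation, glycine substitution) and 3-3 crosslink
  discrimination are out of scope.
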