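# muroquant

Analysis toolkit for the cell-wall biology of *Candidatus* Thiosymbion
oneisti, a rod-shaped sulfur-oxidizing ectosymbiont that attaches to its
nematode host by one pole, grows in width, and divides by longitudinal
fission. The package reimplements, as tested reusable code, the three
quantitative workflows such a study needs:

1. **Muropeptide LC–MS quantification** (`muroquant.murolib`,
   `muroquant.lcms`, `muroquant.pgfeatures`): enumerate theoretical
   muropeptide species (GlcNAc-MurNAc disaccharides with di- to
   pentapeptide stems, D,D 4-3 crosslinked into dimers/trimers/tetramers,
   optionally 1,6-anhydro-terminated and borohydride-reduced), compute
   their monoisotopic masses and positive-mode m/z, extract and integrate
   ion chromatograms from centroided runs, normalise areas to molar
   percentages, and derive the peptidoglycan summary statistics

   - oligomer percentages: sums of molar abundances per oligomer order,
   - crosslinkage: `dimers% + 2·trimers% + 3·tetramers%`
     (crosslinked bonds per 100 muropeptide species),
   - mean glycan chain length: `100 / anhydro%` disaccharide units
     (every glycan strand ends in exactly one 1,6-anhydro-MurNAc).

2. **Cell-cycle-resolved fluorescence profiling** (`muroquant.cells`):
   segment cells from phase-contrast images, measure length/width/volume
   along principal axes, profile fluorescence along the normalised long or
   short axis, group populations by width or area into division-cycle
   stages (demograph-style), and regress total fluorescence on width.

3. **β-lactam binding titrations** (`muroquant.binding`): normalise
   Bocillin-FL gel-band intensities to the untreated control per
   replicate, classify responses as inhibition / weak / enhancement,
   and interpolate IC50 values on log concentration.

`muroquant.synth` generates synthetic inputs with known ground truth for
every stage: geometric glycan-strand populations digested to muropeptides,
centroided LC–MS runs, phase/fluorescence image pairs with polar-focus to
septal-band localization patterns, and titration lane tables.

## Worked example

Quantify a synthetic run generated from a known composition (monomers
45.16% of which 7.95% anhydro, dimers 43.29%, trimers 10.54%, tetramers
1.01%) with 5 ppm mass noise and 5% peak-height noise:

```python
import pandas as pd
from muroquant import synth, lcms, pgfeatures

quant = pd.DataFrame({"name": ["D44", "M4", "M4N", "Q4444", "T444"],
                      "area": [43.29, 37.21, 7.95, 1.01, 10.54]})
quant["molar_percent"] = 100 * quant["area"] / quant["area"].sum()
library = synth.library_for_quant(quant)

run, _ = synth.gen_lcms_run(quant, library, ppm_noise_sd=5, peak_cv=0.05, seed=0)
recovered = lcms.normalize_molar(lcms.match_run(run, library, tolerance_ppm=10))
print(recovered.round(2).to_string(index=False))
summary = pgfeatures.summarize(recovered, library)
print(f"crosslinks {summary.crosslink_pct:.2f} chain {summary.chain_length:.2f}")
```

prints

```
 name      area  molar_percent
  D44 439867.78          43.77
   M4 371618.79          36.98
  M4N  78527.48           7.81
Q4444  10054.77           1.00
 T444 104824.76          10.43
crosslinks 67.64 chain 12.80
```

Every species is recovered within half a percentage point of the input
composition; the crosslink statistic (67.64 bonds per 100 species vs the
67.40 of the noiseless input) and chain length (12.80 vs 12.58
disaccharides) carry the residual acquisition noise.

The same computation on a directly supplied composition table:

```sh
muroquant from-abundance table.csv     # feature,value rows
```

prints the seven summary rows (Monomers … Chain length) as the composition
table of a sacculus analysis would report them.

## Command line

```
muroquant build-library --max-order 4 --stems 3,4,5 -o library.csv
muroquant quantify run.mzml --library library.csv --ppm 10 -o quant.csv
muroquant summarize quant.csv --library library.csv
muroquant from-abundance abundance.csv
muroquant cells manifest.csv --fractions 0.6,0.2,0.1,0.1 --sort width -o outdir/
muroquant titrate lanes.csv -o results.json
muroquant synth strands|lcms|cells|titration --seed 0 --out ...
```

See `docs/methods.md` for the models, conventions, and numerical choices.
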