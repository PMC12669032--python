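# xenoscreen

Analysis pipeline for high-throughput chemical–bacteria growth screens:
hit calling from OD600 growth curves, minimum inhibitory concentrations,
arrayed and pooled transposon-mutant fitness analysis, chemical-space
coverage statistics, species-specific antibacterial-activity prediction,
and synthetic-community composition / bioaccumulation arithmetic — plus a
synthetic-data generator that plants known ground truth for every stage.

## Who this is for

Microbiome and chemical-biology labs running plate-based growth screens of
chemical libraries (pollutants, drugs, xenobiotics) against bacterial
isolates, and following up hits with dose–response series, barcoded
transposon-mutant competitions and community experiments. The package turns
raw plate-reader time series and barcode count tables into replicate-aware
hit matrices, MICs, per-gene fitness calls and cross-validated activity
classifiers, with every statistical rule exposed and testable.

## The statistics at the core

**Growth inhibition hits.** Each well's growth is summarised as the area
under its baseline-corrected OD600 curve (trapezoid rule on the observed
hourly time stamps). Per replicate, a well is scored against the plate's
DMSO vehicle controls:

    z = (raw AUC − median(control AUCs)) / sd(control AUCs)
    p = Φ(z)                      (one-sided, inhibition direction)

p-values are Benjamini–Hochberg corrected across the compound library, and
a replicate is significant when P_adj < 0.05 **and** the control-normalised
AUC shows a >20% reduction. A compound × strain interaction is a hit when
at least two of three biological replicates are significant. The MIC is the
lowest tested concentration at which the normalised growth metric falls
below 0.1 (>90% inhibition).

**Mutant fitness.** Arrayed screens use the plate-median-relative AUC
(rAUC) and its treatment/control ratio (nrAUC), tested per mutant with
Welch's t-test (hits: p < 0.05 and |nrAUC − 1| > 0.2). Pooled barcoded
transposon screens normalise insertion counts by the trimmed total read
count, keep sites in the central 80% of each coding region, and test
per-gene condition-vs-control differences with a two-sided permutation
(resampling) test — exhaustively enumerated whenever the design allows —
with BH correction, an optional per-doubling fold-change rescaling, and
Fisher-exact pathway enrichment of the hit set.

**Activity prediction.** Per species, a random forest (500 trees, √p
features) predicts inhibition from molecular feature vectors under 20
stratified 8:2 train/test splits; classifications threshold the predicted
probability at the training set's hit frequency, and performance is scored
with balanced accuracy and average precision against shuffled-label nulls.

## Worked example

```python
from xenoscreen import MonocultureScreen
from xenoscreen.simulate import SimulationConfig, gen_screen

cfg = SimulationConfig(seed=1, n_compounds=87, n_strains=3)
curves, plate_maps, truth = gen_screen(cfg)      # one 96-well plate layout
res = MonocultureScreen(curves, plate_maps).fit()
print(res.summary())
```

prints

```
Monoculture screen results
========================================
strains tested:        3
compounds tested:      87
library size (FDR m):  87
interactions (hits):   26
active compounds:      24
broad compounds:       2
strong compounds:      3
```

Here 26 of the 87 × 3 compound–strain pairs are called inhibitory
(`truth.hits` plants exactly those 26 pairs at 50–95% AUC reduction, so
sensitivity and precision are both 1.0 on this example); 24 compounds hit
at least one strain, 2 hit more than one-third of the strains tested
("broad"), and 3 have at least one hit with >90% growth reduction
("strong"). `res.wells` holds the per-replicate z, p and P_adj values and
`res.hit_matrix` the aggregated calls.

The same objects are reachable from the shell:

```
xenoscreen simulate screen --seed 1 --n-compounds 87 --n-strains 3 --out-dir sim/
xenoscreen screen call-hits --timeseries sim/timeseries.tsv \
    --plate-maps sim/map_*.tsv --out-wells wells.tsv \
    --out-hits hits.tsv --out-summary summary.json
```

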