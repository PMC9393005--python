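# bryolat

Latitudinal species-richness profiles for marine clades, built from two
very different kinds of occurrence evidence:

* **DB records** — database-style point occurrences (Darwin-Core CSV with
  `scientificName`, `decimalLatitude`, `decimalLongitude`), as exported
  from aggregators like OBIS or GBIF;
* **TMO records** — *text-mined occurrences*: species–location relations
  extracted from sentences of the taxonomic literature, geocoded to
  named-place bounding boxes.

The package implements the full chain as reusable, tested modules, plus a
synthetic-data generator that produces every input with known ground
truth, so the whole pipeline runs and is validated entirely offline.

## What it computes

Occurrences are binned into latitudinal **bands** (36 bands; either
equal-angle 5° bands or equal-area bands with edges evenly spaced in
sin φ) subdivided into 5° longitudinal **sampling units**; landlocked
units are removed before estimation. Within each band, incidence is the
boolean presence of a species in a unit, and richness is estimated
independently per band with two nonparametric estimators:

```
Chao2       Ŝ = S_obs + Q1²(N−1)/(2NQ2)        (Q2=0: S_obs + Q1(Q1−1)(N−1)/(2N))
Jackknife1  Ŝ = S_obs + Q1(N−1)/N
```

where `S_obs` is observed richness, `N` the number of retained units,
and `Q1`/`Q2` the species found in exactly one/two units. Standard
errors follow the classical Chao variance and the first-order jackknife
variance (the same conventions as `vegan::specpool`, against which the
implementation is tested to 1e-9). A **range-through** profile counts
each species in every band between its southernmost and northernmost
occupied bands, without splitting at the equator.

On the text side, the package consumes linguistically annotated documents
(CoNLL-U + an entity-span sidecar), tags taxon names from a lexicon,
resolves abbreviated genera ("*B. intermedia*" → "*Beania intermedia*")
by scanning the current and 14 previous sentences, and forms one
**candidate** per species-span × location-span pair in a sentence. Two
LSTM classifiers (frozen 300-d token embeddings, two recurrent layers
with dropout 0.2, softmax head, cross-entropy, ADAM, 50 epochs with
best-validation-F1 checkpointing) then (a) verify that a tagged location
span really is a place name and not an author-surname false positive,
and (b) decide whether the sentence asserts the species' presence at the
location, using the shortest dependency path between the two spans.
Train/validation/test splits are grouped by publication so near-duplicate
sentences never leak across the split. Verified positive candidates are
geocoded against a gazetteer; bounding boxes covering more than 2% of the
Earth's surface (spherical-globe area) are discarded as too imprecise.

Both record streams pass the same taxonomic cleaning: open-nomenclature
qualifiers stripped (`Microporella cf. ciliata` → `Microporella
ciliata`), records without species epithets or with unaccepted genera
dropped, synonyms mapped to accepted binomials to a fixpoint, every drop
tagged with a machine-readable reason code.

## Worked example

```python
from bryolat import synth, richness, geo
from scipy.stats import spearmanr
import numpy as np

grid = geo.make_band_grid("equal_angle")          # 36 x 5° bands, 5° units
profile = synth.bimodal_profile(200, 36)          # twin temperate peaks
cfg = synth.SimulationConfig(n_species=200, detection_prob=0.3, seed=7)
records, truth = synth.simulate_occurrences(profile, cfg, grid)

df = richness.richness_profile(records, grid, "chao2")
truth_bands = synth.true_band_richness(truth, grid)
print(len(records))
print(df.loc[10:12, ["band_mid", "S_obs", "Q1", "Q2", "estimate", "se"]])
print("Spearman:", round(spearmanr(df["estimate"], truth_bands).statistic, 3))
```

prints

```
991
    band_mid  S_obs  Q1  Q2   estimate         se
10     -37.5     36  22  11  57.694444  12.249622
11     -32.5     32  15  12  41.244792   6.257632
12     -27.5     23  11   8  30.457465   5.884929
```

followed by `Spearman: 0.956`: with per-unit detection probability 0.3
and only 4 of 72 units visited per band, the observed counts miss
species, the uniques/duplicates ratio measures how much, and the Chao2
correction recovers a per-band profile that rank-correlates strongly
with the true gradient.

The command-line pipeline runs everything end to end on synthetic data:

```
bryolat all --seed 42 --out run/
```

producing cleaned-record CSVs per source, species-overlap statistics,
richness profiles per estimator × source × grid scheme, occurrence
heatmaps, and a deterministic run manifest.

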