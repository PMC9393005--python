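# Methods

This note documents the models and procedures bryolat implements, the
parameters that matter, what the synthetic-data generators emulate (and
what they deliberately do not), and the numerical and design choices
made where the problem left room.

## Sampling geometry

The globe is divided into `n_bands` latitudinal bands (default 36) and
5° longitudinal sampling units. Two band schemes are supported:

* **equal_angle** — edges at −90°, −85°, …, +90°; band areas shrink
  poleward;
* **equal_area** — edge_k = arcsin(2k/n − 1), so each band covers
  exactly 1/n of the sphere (verified to 1e-12 in the tests).

All cells are half-open `[lower, upper)` with the +90° and +180° edges
closed, so every point maps to exactly one cell. Bounding boxes claim
every half-open cell their closed rectangle intersects; boxes crossing
the antimeridian are split at ±180° and the two parts unioned. Sampling
units that are entirely land ("landlocked bins") are removed from the
grid before estimation — marine species cannot occur there, and keeping
them would deflate the per-band detection picture. A consequence,
chosen deliberately and switchable via `assign_units(...,
retained_only=False)`, is that a bounding box credits a band only if it
intersects at least one *ocean* cell of that band.

Bounding-box surface area uses the spherical formula
`fraction = (Δλ/360°)·(sin φ_max − sin φ_min)/2`. Splitting a box at
any interior meridian or parallel conserves total fraction to 1e-12 (a
property test). Records whose box exceeds `max_box_fraction` of the
Earth's surface (default 0.02) are discarded as spatially uninformative;
the threshold is a judgment call and is exposed as configuration.

## Richness estimation

Within one band, the data reduce to a boolean species × units incidence
matrix; duplicate records collapse and cannot inflate richness. With
`S_obs` observed species, `N` retained units, `Q1`/`Q2` species in
exactly one/two units:

* **Chao2**: `S_obs + Q1²(N−1)/(2NQ2)`; when `Q2 = 0` the bias-corrected
  limit `S_obs + Q1(Q1−1)(N−1)/(2N)` is used instead. This pairing —
  the classic ratio form when duplicates exist, the +1-style corrected
  form only in the degenerate case — matches what `vegan::specpool`
  computes, and the implementation reproduces specpool's estimates *and*
  standard errors to 1e-9 on fixed matrices frozen into the test suite.
* **Jackknife1**: `S_obs + Q1(N−1)/N`.
* **Variances**: classical Chao variance (both branches as in vegan);
  the first-order jackknife variance needs the distribution of unique
  species over units, so `IncidenceSummary` carries an optional
  `uniques_per_unit` vector — from a bare summary the jackknife SE is
  reported NOT-DEFINED rather than silently zero. Confidence intervals
  are normal approximations (estimate ± 1.96·SE); the CI method is a
  convention, not a law, and is isolated in one helper.

Bands are treated as independent; a band with `N = 0` after land
masking yields NOT-DEFINED estimates, never zero. **Range-through**
richness counts each species in every band between its southernmost and
northernmost occupied bands inclusive, with no hemisphere split: a
species seen at −37.5° and +12.5° is counted through the tropics. By
construction the range-through count dominates `S_obs` in every band.

Degenerate inputs: `Q1 = 0` collapses both estimators to `S_obs`;
`N = 1` makes the jackknife factor zero; undefined ratios anywhere in
the metrics or estimators surface as NaN sentinels, never as silent
zeros.

## Text mining

Documents arrive already tokenized, sentence-split, dependency-parsed
and location-NER-tagged (CoNLL-U plus a JSON span sidecar; one document
per file, 0-based half-open token spans). The package adds:

* **Taxon tagging** from a lexicon of genera and binomials: "Genus
  epithet", abbreviated "G. epithet", or bare genus; longest match wins
  left-to-right, matches never overlap, and a short function-word
  stoplist keeps "Beania is" from being read as a binomial. Trinomials
  are not matched unless the lexicon sanctions them.
* **Genus de-abbreviation**: an abbreviation like "B." is resolved by
  scanning taxon spans before it — current sentence first, then up to
  14 previous sentences in reverse order — and taking the first full
  genus with the same capital. The window counts the current sentence
  plus 14 previous; paragraph structure is ignored. The result depends
  only on the document prefix, a property the tests check directly.
* **Candidates**: the per-sentence Cartesian product of taxon and
  location spans. Candidates whose genus cannot be de-abbreviated are
  dropped and counted.
* **Shortest dependency path**: the minimum-edge undirected path
  between the two span heads (a span's head is its token not governed
  from inside the span; lowest index breaks ties). Among equal-length
  paths the lexicographically smallest token-index sequence wins,
  canonicalized from the lower-index endpoint so that path(a,b) is
  exactly the reverse of path(b,a). If the graph is disconnected the
  classifier falls back to the inter-span surface tokens, flagged.

## Classifiers

Both classifiers share one architecture: frozen token embeddings
(300-d), for the verifier concatenated with a frozen 2-d orthogonal
indicator embedding marking the candidate span; two stacked LSTM layers
with input dropout 0.2; the final (masked) time step of the second
layer into a 2-unit softmax; cross-entropy loss; ADAM (lr 1e-3, batch
32); 50 epochs with the weights checkpointed whenever validation F1
strictly improves, and the best checkpoint returned. The verifier reads
the whole sentence plus the indicator track; the relation classifier
reads only the dependency-path tokens, no indicators. Padding is
masked so padded steps never touch the recurrent state (a unit test
confirms padding cannot change a prediction).

The network is implemented directly in numpy with hand-derived
backpropagation-through-time; the analytic gradients are verified
against central-difference numerical gradients in the test suite.
Training is deterministic given the config seed in single-threaded
execution. Hidden width (default 64), learning rate and batch size are
configuration — they are tuning knobs, not part of the architectural
contract. The decision threshold on the softmax output is 0.5 by
default and explicit everywhere.

Splits are assigned by whole publication (greedy largest-first into the
split with the largest remaining deficit against 80/10/10 targets),
so all candidates of one publication land in exactly one of
train/validation/test. Evaluation refuses test sets whose publications
leak into train. Undefined metrics (e.g., FPR with no negatives) are
reported NOT-DEFINED. Closed-form random-classifier baselines for a
label-independent Bernoulli(p_pred) predictor against Bernoulli(p_label)
labels — accuracy `p·q + (1−p)(1−q)`, recall = FPR = `q`, precision =
`p` — are checked against a 10⁵-draw Monte-Carlo simulation.

## Taxonomic harmonization

Cleaning is rule-based and fully audited: qualifiers `cf.`/`aff.`
(any case, optional period) are stripped; trinomials truncate to the
binomial; rows without an epithet drop with reason `NO_EPITHET`; genera
absent from the accepted-genera list drop with `GENUS_UNACCEPTED`;
names are pushed through the synonym table to a fixpoint (bounded
depth; a cycle is a configuration error) and drop with `NAME_UNKNOWN`
if the fixpoint is not an accepted species. Coordinates outside
[−90, 90] × [−180, 180] drop with `COORD_INVALID`; unknown place names
with `GEOCODE_NOT_FOUND`; oversized boxes with `BOX_OVERSIZED`. Every
input row ends up either cleaned or in the drop report exactly once
(row conservation, asserted in tests and in the run manifest). Merging
the DB and TMO streams concatenates records and reports species-set
overlap satisfying inclusion–exclusion exactly.

## Synthetic data: what it emulates, what it does not

The generators exist so that every stage has an input with known truth.

* **Gazetteer**: named places with bounding boxes and centroids;
  `oversized_fraction` controls exactly how many entries exceed the 2%
  area threshold; author surnames ("Hincks", "Busk", "Waters") are
  included as flagged non-locations, emulating the false positives a
  generic NER model produces on taxonomic author citations.
* **Occurrence simulation**: each species receives a latitudinally
  contiguous range spanning all longitudes — a deliberate idealization
  that makes range-through exact on the truth map and isolates
  estimator behavior from range-shape effects. Default conditions:
  200 species on a bimodal profile (Gaussian peaks at ±40°, sd 15°,
  5% uniform floor), range width 15° (marine invertebrate species
  commonly span >1000 km of latitude), detection probability 0.3 per
  visited unit, and 4 of 72 units visited per band — sparse, as real
  marine sampling is. When the species total matches the profile and
  ranges fit within one band, home bands are allocated exactly, so
  complete sampling (detection 1, all units) reproduces the profile
  per band *exactly*; otherwise allocation is multinomial and recovery
  is judged against the returned truth map.
* **Corpora**: template sentences with *stored* dependency parses, so
  no external parser is ever invoked and generation is deterministic.
  Four template classes are always present: positive relations,
  negative co-occurrences, abbreviated-genus positives (the full genus
  planted in the directly preceding sentence, inside the 14-sentence
  window), and author-lookalike sentences whose "location" span is a
  flagged surname. Gold labels are positive exactly where the template
  asserts presence; every location span doubles as a verifier example.

What passing on this synthetic data does **not** show: robustness to
real linguistic variety (templates are rigid), to ranges with
longitudinal structure or holes, to spatially biased effort within a
band, or to gazetteer boxes that misrepresent a place. Those are
properties of real corpora and real geocoders, outside what an offline
fixture can certify.

## Experiment sizes

The recovery experiment averages 20 independent simulations of the
default conditions (a few seconds of compute); the classifier
experiment uses a 24-publication corpus in the test suite and a
32-publication corpus in the acceptance script, where the denser
template coverage makes perfect separation robust across arbitrary
seeds. The Chao2 mean-absolute-error improvement over observed richness
is real but modest at these sampling intensities and can invert for
individual seed sets; the jackknife improvement is consistently larger —
both behaviors are visible in the acceptance script's output rather
than smoothed away.

## Known limitations

* Chao2 is unstable when `Q2` is tiny; no smoothing is applied beyond
  the standard `Q2 = 0` fallback.
* The jackknife SE requires per-unit information; profiles built from
  summaries alone report it NOT-DEFINED.
* The verifier and relation classifier are only as good as their
  training corpus; the synthetic corpus makes both tasks linearly
  separable by construction, which upper-bounds nothing about real
  text.
* Geodesic (ellipsoidal) areas, coverage-based rarefaction, abundance
  estimators, and hemisphere-split range-through are out of scope.
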