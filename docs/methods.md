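# Methods

## Model and pipeline

The cohort is an `N × M × K` tensor `κ` of real sensor readings: entry
`A_{i,j} = (a_{i,j,1}, …, a_{i,j,K})` is student `s_i`'s curve for
health criterion `c_j`. An optional boolean mask marks observed
entries; unobserved readings contribute zero to inner products, so the
sign of a projection is driven entirely by observed data.

Hashing proceeds in three steps per (table `t`, repetition `z`):

1. **Projection.** Draw `B ∈ [−1, 1]^K` component-wise uniform and
   compute `Ω_{i,j} = A_{i,j} · B` for every (student, criterion).
2. **Binarization.** `Ψ_{i,j} = 1` iff `Ω_{i,j} > 0`. The tie `Ω = 0`
   maps to 0: the event has measure zero for continuous data, and a
   total, deterministic rule keeps every run reproducible.
3. **Packing.** The `M` bits `(Ψ_{i,1}, …, Ψ_{i,M})` pack MSB-first
   into the integer `π_{i,z}^{(t)} ∈ [0, 2^M − 1]`. Indexes are
   arbitrary-precision (`M` may run to thousands of bits); only
   equality comparison and hash-bucket keying are ever performed on
   them, never arithmetic.

Similarity of two students is the number of repetitions `z` whose
indexes agree in at least one table. "At least one" is the loosening
role of the `p` tables: each extra table adds witnesses, so `Sim` is
monotone non-decreasing in `p` (a property the tests assert). Students
with `Sim ≥ T` (`1 ≤ T ≤ q`) are similar; groups are connected
components of the threshold graph — the transitive closure of the
pairwise rule, deterministic and parameter-free — and anomalies are the
degree-zero vertices. Degree zero rather than "singleton component" is
used as the anomaly rule; the two coincide, but degree zero is the
primitive statement.

**Privacy contract (operational form).** The index table contains only
integers in `[0, 2^M − 1]`, identifiers and configuration; no raw
reading appears in it, and positive per-series rescaling leaves all
bits unchanged. No cryptographic claim is made.

## Randomness discipline

One root seed. The hyperplane for slot (table `t`, repetition `z`[,
criterion `j`]) comes from a dedicated `SeedSequence` substream keyed
by that tuple. Consequences: construction order is irrelevant, and the
first `p′ ≤ p` tables / `q′ ≤ q` repetitions of a large index coincide
bit-for-bit with a freshly built smaller one (`subset_index` exploits
this, and a test pins it).

By default one hyperplane per (table, repetition) is shared across all
`M` criteria — the literal single-`B` construction. Setting
`per_criterion_planes=true` draws an independent plane per criterion,
giving textbook-independent hash bits at `M`-fold plane cost.

## Tunable parameters

| parameter | meaning | default | why |
| --- | --- | --- | --- |
| `p` | hash tables (match loosening) | 6 in examples | mid-grid of the 4–10 range the evaluation sweeps |
| `q` | repetitions per table; `Sim ∈ [0, q]` | 6 in examples | ditto |
| `T` | similarity threshold, `1 ≤ T ≤ q` | 2 | loose enough to keep groups connected, strict enough to isolate planted anomalies |
| `seed` | root seed | — | all randomness derives from it |

## Synthetic cohort generator

The generator provides what a detection method needs and real wearable
data rarely offers: exact ground truth. Per (group, criterion) a smooth
baseline curve is drawn — offset `~ N(0, 3.0)` plus three harmonics of
amplitude `~ N(0, 1.0)` over the `K` points (per-entry baseline spread
≈ 3.2). Normal students get their group's curves plus i.i.d.
`N(0, noise_sd²)` noise; anomalous students take a random group's
baseline displaced by a Gaussian curve with per-entry sd
`separation × spread_j`, `spread_j` being the per-criterion std of the
baselines across groups and time. Group membership is round-robin so
no group is accidentally a singleton. Defaults: `N=100, M=20, K=64`, 4
groups, 5% anomalies, `noise_sd=0.5`, `separation=4`.

Curves are modelled as deviations from the population mean. This is a
deliberate choice: a sign-of-projection hash only carries information
through the *direction* of a curve, so a large level common to all
students (say, a resting heart rate near 70 bpm shared cohort-wide)
would make everyone collide and the index uninformative. A real
deployment would center each criterion first; the generator emits
already-centered signals. The package also exposes an optional
per-series centering flag at read time without claiming any particular
upstream pipeline.

What the generator does **not** emulate: physiologically calibrated
waveforms, autocorrelated sensor noise, drift, missing-not-at-random
gaps, or heterogeneity *within* a group (every normal member of a group
shares one curve up to i.i.d. noise). Passing tests therefore show the
method recovers block structure planted at a declared
signal-to-noise level — not that it handles real ECG streams.

**Masking protocol.** For MAE/RMSE evaluation a uniformly random
`floor(N·M·K·fraction)` of entries is hidden (floor is declared so
counts are bit-exact) and emitted with their true values; the index is
then built from the masked tensor, so the hash never sees a held-out
value.

## Evaluation harness

The detector is binary, so accuracy is operationalized as held-out
entry prediction, the collaborative-filtering tradition the comparison
baseline comes from:

* **ano-det** predicts a hidden `(i, j, k)` as the plain mean of
  `a_{i′,j,k}` over index-similar neighbors `i′` (`Sim ≥ T`);
  fallbacks: cohort mean of criterion `j` at time `k`, then global
  observed mean.
* **ucf** is user-based collaborative filtering on the raw tensor:
  Pearson correlation over co-observed flattened entries, prediction =
  correlation-weighted mean over the top-10 positively correlated
  neighbors, same fallbacks. Correlations are computed with masked
  cross-product sums (BLAS matrix products), exact for every pair with
  ≥ 2 co-observed points; degenerate pairs get weight 0.
* **brute-lsh** is ano-det restricted to one hash table, a generic
  single-table LSH comparator.

Stage timings are recorded in the tidy report CSV but never asserted:
wall-clock numbers are hardware-dependent.

## Profile-scale trend checks, and two that fail by design of the math

The profile-scale configuration is `N=142` students and `M=200`
criteria (reduced from 4500 to keep a desk-scale run; the mechanism
under test does not depend on the reduction), `K=64`, grid
`p, q ∈ {4..10}`, `T ∈ {1,2,3}`, 1% masking, 3 seeds.

**Noise calibration.** A repetition matches only when all `M` bits
agree, so for two same-group students the per-repetition collision
probability decays like `exp(−c·M·noise_sd)` (per-bit flip probability
≈ angle/π ≈ `√2·noise_sd/(π·3.2)` times `M` criteria). The profile runs
therefore use `noise_sd = 0.025`, which holds the within-group
collision probability near 1/2 at `M = 200` — the regime in which the
index retrieves anyone at all. This closed-form calibration is a
stated modelling choice of the profile configuration, not a fitted
value.

Three directional checks are asserted. Measured outcomes:

* *Fewer similar students as `p` shrinks* — *passes*. Removing tables
  removes match witnesses; `Sim` is monotone in `p` by construction.
* *Fewer similar students (hence less work) as `q` grows* — **fails,
  necessarily**. `Sim(s_i, s_j) = Σ_{z≤q} [match at z]` is a sum of
  indicator terms: appending repetitions can only raise it, so at fixed
  `T` the neighbor sets are nested *increasing* in `q` (measured: mean
  neighbor count 3.3 → 14.4 as `q` goes 4 → 10 at `p=4, T=2`). A
  decrease would require `T` to scale with `q` (e.g. a fixed fraction
  `T/q`), which the fixed-`T` sweep rules out.
* *Worst accuracy at the loosest threshold `T=1`* — **fails under this
  data model**. Within a homogeneous group every neighbor is an equally
  good predictor (same curve + i.i.d. noise), so loosening `T` only
  adds informative neighbors and averaging over more of them helps,
  while raising `T` pushes students into the cohort-mean fallback
  (measured mean MAE 0.47 / 0.62 / 1.05 at `T = 1/2/3`). Degradation at
  loose thresholds requires heterogeneous similarity structure —
  marginally-similar students that are genuinely worse predictors —
  which the declared group-plus-noise generator intentionally lacks.

Both failing checks are kept as written, as honest measurements of the
method under the declared generator, with this analysis as the record.

## Numerical choices and degenerate inputs

* Ties `Ω = 0` hash to bit 0 (see above).
* Self-similarity is defined as `q` (a student trivially matches
  itself); the diagonal is never consulted by the anomaly rule.
* Group labels and component orderings are sorted by smallest student
  index for reproducible output.
* Long-CSV serialization writes shortest round-trip decimal text
  (`repr`), so read∘write is bit-exact on float64.
* A long CSV in which every series is a complete 0..k−1 prefix but the
  lengths disagree is rejected as inconsistent; arbitrary missingness
  patterns are read as masks.
* Constant criteria in the generator (spread 0) fall back to unit
  displacement spread so planted anomalies never collapse onto a
  baseline.
* MAE/RMSE require at least one prediction pair; empty inputs are
  validation errors, as are held-out triples that are actually
  observed.

## Known limitations

* The privacy property is strictly "raw values are not transmitted";
  index bits still leak coarse directional information about curves.
* No multi-probe or banded-signature LSH variants; exactly the
  (p, q)-repetition scheme above.
* Anomaly scoring is binary; no soft scores or ranking.
* Batch tensors only; no streaming ingestion.
* The evaluation harness's prediction protocol is this package's
  operationalization; alternative protocols (e.g. mean-centered CF
  adjustment) would shift absolute MAE values.
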