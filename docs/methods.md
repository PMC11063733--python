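# Methods

## Model

The predictor treats miRNA–disease association as bipartite link prediction
under the standard guilt-by-association hypothesis: functionally similar
miRNAs tend to associate with semantically similar diseases. Scores are
produced in three stages — similarity construction, label propagation, and
network consistency projection — each of which is pure linear algebra on
dense matrices; no training or stochastic optimisation is involved, so the
whole pipeline is deterministic given its inputs.

**Orientation convention.** The association matrix `MD` is always
miRNA × disease (`nm × nd`), rows = miRNAs. Every intermediate that mixes
the two propagation results or the two projections is brought into this
orientation before mixing; the disease-network propagation runs on
`MDᵀ` and its fixed point is transposed back.

### Similarity construction

*Disease semantic similarity* uses the information-content form: an
ancestor term appearing in `k` of the `N` disease DAGs contributes
`−log(k/N)`. The logarithm base is configurable (`log_base`, default
natural); changing it rescales numerator and denominator of the similarity
ratio identically except across terms, so it is a genuine (if mild)
modelling choice rather than a cosmetic one. The denominator universe `N`
defaults to the number of diseases carrying a DAG and can be overridden
(`universe_size`) when the hierarchy file covers a larger nomenclature.

A disease pair whose DAGs contain only universal terms has
`DV(i)+DV(j) = 0`; its similarity is defined as 0 and a warning is logged,
rather than raising, so degenerate hierarchies (single-disease universes,
flat forests) remain usable — the GIP kernel then carries the signal.

*miRNA functional similarity* is best-match averaging of `DD` over the two
associated-disease sets. miRNAs with no associations (which arise inside
cross-validation folds) get off-diagonal similarity 0 and diagonal 1; the
integration fallback then substitutes the GIP kernel, so folds never crash.

*GIP kernels* use a single bandwidth per entity type, the reciprocal of the
mean squared profile norm (scaling constant 1). A fully zero association
matrix leaves the bandwidth undefined and is rejected. Since the kernel is
strictly positive, the miRNA integration fallback (`MMf = MM` where
nonzero, else `GM`) produces a strictly positive matrix wherever the
functional similarity vanishes.

### Normalization and propagation

The default normalization divides each entry by the sum of its row and
column totals. For a nonnegative matrix this bounds every row sum by 1, so
`(1−α)W*` has spectral radius below 1 for any `α > 0` and the iteration
`F_{t+1} = (1−α)W*F_t + αY` contracts geometrically to the unique fixed
point `α(I−(1−α)W*)^{-1}Y` — the oracle the tests solve directly. A
symmetric-Laplacian mode (`D^{-1/2} W D^{-1/2}`) is available because much
of the label-propagation literature uses it; both are config switches, not
code paths with different semantics.

Convergence is declared when the max-abs elementwise change drops below
`tolerance` (default `1e-6`); the iteration cap is 1000 and exhaustion is
flagged in the result, never silently returned. With the defaults
(`α = 0.9`) the contraction factor is ≤ 0.1, so convergence takes under ten
iterations in practice.

### Projection and mixing

Both projections are emitted in miRNA × disease orientation. The
normalizing vector norm makes each projection invariant to positive
rescaling of the projected-onto Fe column (miRNA side) or row (disease
side) — an exact identity the tests assert. Zero-norm columns/rows yield
score 0, not NaN, so empty entities stay rankable. A
`literal_pd_transpose` flag applies the disease projection transposed for
square problems, for users who want the alternative orientation.

## Parameters

| name | meaning | default | range |
|---|---|---|---|
| `alpha`, `beta` | restart weight of the disease / miRNA propagation (fraction of the seed labels re-injected each step) | 0.9 | (0, 1] |
| `delta` | weight of the miRNA-network fixed point in `Fe` | 0.9 | [0, 1] |
| `epsilon` | weight of the miRNA-side projection in `MD*` | 0.6 | [0, 1] |
| `tolerance` | propagation stopping threshold (max-abs change) | 1e-6 | > 0 |
| `max_iterations` | propagation cap | 1000 | ≥ 1 |
| `log_base` | base of the information-content log | natural | > 1 |
| `normalization_mode` | `degree_sum` or `symmetric` | `degree_sum` | — |
| `refresh_gip_per_fold` | recompute data-derived similarities inside every CV fold | false | — |
| `threshold_mode` | `youden` or a fixed score threshold for ACC/MCC/F1 | `youden` | — |

The defaults for `alpha/beta/delta/epsilon` are the optimal set of the
original sequential sweep (fix δ = ε = 0.5, sweep α = β; fix the winner,
sweep δ; then ε), which `parameter_sweep` reproduces. That sweep's own
record is internally inconsistent about δ (its AUC curve peaks at 0.6 but
its conclusion fixes 0.9); the package follows the stated optimal set and
leaves δ one keyword away.

## Evaluation protocol

*Global LOOCV*: each known pair is zeroed and rescored; its held-out score
is pooled as a positive against the full-data scores of all never-known
pairs, and the five metrics are computed on that pool. *Cold-start CV*
blanks a whole miRNA row (new miRNA) or disease column (isolated disease)
and ranks that entity's true associations against its non-associations,
pooled over entities.

Two choices here were genuinely open:

* **Threshold for ACC/MCC/F1.** No threshold accompanies the method's
  definition; the default is the Youden-J argmax on the pooled ROC, with a
  fixed-value override. Thresholded metrics are therefore comparable only
  between runs using the same rule.
* **Similarity refresh.** By default the functional and GIP similarities
  are computed once from the full matrix and reused across folds. This is
  fast (the per-fold work is two small propagations and three matrix
  products) but lets the held-out association influence the kernels — a
  leakage that inflates LOOCV scores, dramatically so on random matrices.
  `refresh_gip_per_fold=True` rebuilds all data-derived similarities inside
  every fold and is the protocol used whenever a permuted-label control is
  part of the comparison, since the leakage would otherwise swamp the
  contrast between planted and permuted data.

## Synthetic benchmark

The generator plants the structure the method assumes: miRNAs and diseases
are partitioned into aligned blocks; pairs link with probability 0.6 within
a block and 0.03 across (defaults 40 × 25, 4 blocks, overall density
≈ 15 %); each block's diseases hang as leaves under that block's chain of
internal DAG terms, so within-block semantic similarity exceeds cross-block
similarity by construction. All-zero rows/columns are resampled once and
otherwise kept (they exercise the zero-degree guards). Randomness flows
through `numpy` `SeedSequence([seed, salt])` streams, so fixtures are
bit-reproducible across platforms.

What the fixture does **not** emulate: the extreme sparsity (~1–5 %) and
power-law degree distribution of curated catalogues, MeSH's depth and
multiple inheritance, and annotation noise. Passing the planted-signal
tests therefore shows the pipeline recovers block structure transmitted
through the similarity channels it models — not that it attains any
particular accuracy on real HMDD-scale data, whose headline numbers depend
on that specific catalogue.

## Numerical choices

* Convergence norm: max-abs elementwise difference; ties in ranked output
  broken lexically by (miRNA, disease) so files are byte-stable.
* Similarity matrices are validated symmetric within `1e-12` and clipped
  to `[0, 1]` only where float summation overshoots the closed form
  (diagonals).
* MCC is 0 whenever a confusion-matrix margin is empty; F1 is 0 when
  precision + recall is 0.
* AUC/AUPR are computed by threshold sweep with tie grouping (trapezoidal
  ROC area; step-interpolated PR area). The test suite pins both to
  independent counting oracles (Mann–Whitney pairs with half-credit ties;
  exhaustive threshold enumeration).
* Provenance manifests deliberately contain no wall-clock timestamps so
  identical runs are byte-identical end to end.

## Problem sizes

The shipped evaluations use the default 40 × 25 fixture (≈ 160 LOOCV folds,
each two propagations on 25 × 25 and 40 × 40 networks), 20 seeds for the
planted-vs-permuted comparison, and ≤ 20-node instances for the
oracle-equivalence checks — sizes at which the exact linear-solve and
nested-loop oracles are feasible and the full suite runs in well under a
minute.

## Limitations

* Prediction quality is bounded by the similarity inputs; diseases absent
  from the hierarchy degrade to GIP-only evidence.
* The degree-sum normalization reading was reconstructed from a corrupted
  printed formula; the symmetric alternative is provided but produces
  (slightly) different rankings.
* Scores are relative rankings, not calibrated probabilities.
* LOOCV with the default (non-refreshing) protocol overstates absolute
  performance through kernel leakage, as quantified by the permuted
  control; use per-fold refresh for honest absolute numbers.
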