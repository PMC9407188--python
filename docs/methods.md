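# Methods

This note records the modelling choices behind `patterndict`: the coders,
the analytic bounds, the synthetic benchmark, the parameters that matter,
and what the tests do and do not establish.

## Coders

### Pattern dictionary (typical coder)

The dictionary stores, for every depth `d = 1..Dmax`, all distinct
length-`d` windows of the training sequence with their counts.  The
empirical probability of a depth-`d` pattern uses the number of length-`d`
windows, `L - d + 1`, as denominator.  Per level, prefix codelengths are
assigned by Huffman coding (default) or Shannon–Fano–Elias
(`ceil(log2 1/p) + 1`).  Conventions worth spelling out:

- **Huffman tie-break.**  Codelengths of tied weights depend on merge
  order.  We fix it deterministically: equal-weight leaves merge in
  reverse-lexicographic pattern order, and merged nodes queue after all
  equal-weight leaves in creation order.  Any tie-break yields an optimal
  code; this one is reproducible across runs and platforms.
- **Single-pattern levels** cost 1 bit.  Huffman on one symbol degenerates
  to a zero-length word, which is not a usable prefix code.
- **Depth index.**  The per-phrase depth cost `log2(Dmax)` is used as a
  real number (ideal codelength), the standard choice in MDL-style
  scoring; `integer_depth_index=True` rounds it up for strict
  implementability.  The quantity being compared between coders is a
  description length, not an actual bitstream — only codelengths matter.

### Greedy parser and escapes

The parser takes, at each position, the longest dictionary pattern that
prefixes the remaining suffix (capped at `Dmax`); because the pattern sets
are prefix-closed, grow-until-failure and longest-match coincide and the
parse is unique.  The final phrase is simply the longest dictionary prefix
of the tail, preserving losslessness.

A test symbol absent from depth 1 (possible after quantizer clamping, or
with corrupted inputs) is emitted as an *escape*: one reserved index in an
enlarged depth-1 code plus a literal, costing
`log2(a_1 + 1) + log2 |X|` bits on top of the depth index.  This keeps
every score finite while penalizing novel symbols heavily.  Escapes are a
package choice — the coding theory only covers symbols seen in training —
and their cost model is isolated in one place in `pd_codec`.

### LZ78 (atypical coder)

Standard incremental parsing over a trie; the final, possibly duplicate
phrase is counted.  The codelength is `c·log2(c + 1)` bits for `c`
phrases.  The classical accounting that also charges each phrase's
innovation symbol, `c(log2 c + log2 |X|)`, is available via
`lz78_codelength(..., classical=True)`; it shifts scores by a
data-dependent offset and matters only for absolute thresholds, not for
rankings.

`log_star(l)` sums the iterated logarithm over strictly positive terms
(`log2 l + log2 log2 l + ...`), the universal cost of describing an
unknown window length.

## Analytic bounds

For an X-ary sequence of length `l`, the LZ78 phrase count `c(l)` obeys

- lower: `(sqrt(8l+1) - 1)/2` — a single repeating symbol parses into
  phrases of lengths 1, 2, 3, ...;
- upper: `l·ln X / W((beta/alpha)·X^{-(alpha+1)/alpha}·ln X)` with
  `alpha = X - 1`, `beta = (X-1)^2·l - X`, `W` the principal Lambert W
  branch.  The inversion comes from packing all strings of length `<= k`,
  whose total length is `l_k = [((X-1)k - 1)X^{k+1} + X]/(X-1)^2`; at
  `l = l_k` the bound equals `l_k/(k - 1/alpha)` exactly, which the tests
  verify together with containment of the exhaustive maximum.  The
  `beta = (X-1)^2·l - X` form is forced by the `l_k` identity; with
  `(X-1)·l - X` the bound fails containment for `X >= 3`.

The W-free version `l/((1 - eps_l)·log_X l)` (with `eps_l` as given in `lz78_log_upper_bound`)
and the typical-set bound — substitute the growth rate `m = 2^{h+eps}` of
an entropy-`h` source for the alphabet size — are implemented alongside.
The convergence of the W bound to `l/log_X l` is O(log log l / log l):
slow enough that the ratio is still ~1.36 at `l = 10^7` for binary
alphabets, which is what the monotonicity test asserts.

`pda_score_range(l, X, Dmax)` brackets the difference between dictionary
and LZ78 phrase counts by `[l/Dmax - upper, l - lower]`, using the exact
constituent bounds rather than their asymptotic expansions; the bracket is
what the containment tests need, and its width changes ever more slowly in
`Dmax` (the `l/Dmax - l/(Dmax+1)` increment), which is why large
dictionary depths buy little.

Advisory bounds on the multi-level indexing gap `log2(A/G)` use endpoint
AM−GM inequalities (Kober-type lower bound, logarithmic-mean upper bound)
with conservative denominators so that the exact gap always lies inside;
the exact gap is the quantity of record.

## Quantization

Per channel: half-open uniform bins `[min + k·step, min + (k+1)·step)`
anchored at the observed training minimum, specified either by step size
or by level count (`step = span/levels`; the top edge joins the last bin).
Encoding clamps out-of-range values to the edge bins — test data may drift
outside the training range and must remain codable.  Channels combine by a
row-major product code into one symbol stream; the alphabet is the product
of the per-channel level counts (e.g. 9 × 10 = 90).  Helpers for wearable
streams (block-mean downsampling, a MAD-based spike filter at 5 robust
SDs) are provided; the MAD rule is a generic stand-in for device-specific
artifact removal, not a calibrated procedure.

## Threshold calibration

`calibrate_tau` splits the training stream into contiguous folds
(respecting serial dependence; default 30), builds a dictionary on the
complement of each fold, scores the held-out fold's windows, and returns
an upper quantile of the pooled null scores.  The false-positive contract
is statistical: with `n_pool` null scores and `n_holdout` evaluation
windows, the flag rate on fresh typical data matches `1 - quantile` within
about `2·sqrt(q(1-q)(1/n_holdout + 1/n_pool))` — the quantile estimate
itself carries sampling error, so both sample sizes appear in the SE.

## Synthetic benchmark

The Mackey–Glass equation `dx/dt = -a·x + b·x_delta/(1 + x_delta^10)` is
integrated by fixed-step RK4 (dt = 0.1) with linear interpolation of the
delayed state, constant history 1.2, burn-in 1000 time units, one sample
per time unit.  Halving dt moves the sampled trajectory by < 1e-3 RMS over
the tested horizon.  In the chaotic benchmark regime the decay coefficient
is the small one (decay 0.1, delayed drive 0.2, delay 17); with the roles
reversed the origin is the only attractor and the series dies out, so the
benchmark constructors fix the chaotic assignment while `MGParams` exposes
both.  A seed perturbs the history by ~1e-3, and the burn-in lets the
chaos decorrelate replicates.

Each benchmark replicate grafts 500 samples from the anomalous source
(both coefficients doubled — the same attractor geometry at twice the
speed) into 1000 typical samples at position 500, after an affine rescale
to the host's mean and SD ("normalization" is not otherwise pinned down;
moment matching is the neutral reading).  Training uses 3000 typical
samples, quantized to 90/45/10 levels; a 100-sample window slides at
stride 1; windows count as anomalous at ≥ 50% overlap with the graft; ROC
AUC and PR AUC (rank statistic and step-wise interpolation, via
scikit-learn) are computed per replicate and averaged over 20 replicates.

**What the generator does and does not emulate.**  It produces a clean,
noise-free, densely sampled chaotic signal with an abrupt regime change.
Real symbolized data (e.g. wearable physiology) carry observation noise,
missingness, nonstationary baselines and gradual onsets, none of which are
modelled here.  Under these clean conditions the grafted anomaly is highly
separable: every detector scores mean ROC AUC ≈ 0.95–0.998 at all three
resolutions, and the fine ordering among the compression-based detectors
(PDA, PDD, ZM, CDM) sits inside replicate noise.  Passing benchmark tests
therefore demonstrates that the pipeline ranks anomalous windows above
typical ones almost perfectly *on this synthetic family* — not that the
same margins transfer to noisy field data, where the gap between the
typical and universal coder (PDA's advantage over PDD) is expected to do
more work.  One consequence is visible in the scores themselves: at
saturation the LZ78 term adds variance but little signal, so PDA's mean
AUC can sit marginally below PDD's.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `Dmax` | 40 (benchmark), 30 (wearable-style) | symbols | deep enough that further depth has vanishing effect on the score range |
| quantizer levels | 90 / 45 / 10 | bins | high/medium/low resolution settings of the benchmark |
| window length | 100 | samples | benchmark sliding window |
| `tau` quantile | 0.99 | — | one-percent false-positive target |
| calibration folds | 30 | — | contiguous blocks; 3000-sample train gives 100-sample folds |
| MG (a, b, delta) | (0.1, 0.2, 17) typical; (0.2, 0.4, 17) anomalous | 1/time, 1/time, time | chaotic regime; anomaly = same dynamics, doubled rates |
| overlap threshold | 0.5 | fraction | window counts as anomalous at half overlap |
| escape cost | `log2(a_1+1) + log2 X` | bits | reserved index + literal |

## Numerical choices and degenerate inputs

Lambert W is evaluated on the principal branch (arguments are nonnegative
in-domain) and cross-checked against a bisection oracle to 1e-10.
Degenerate cases are pinned by tests: constant quantizer channels get one
bin; single-pattern dictionary levels cost 1 bit; `Dmax = 1` has a free
depth index; `log*` of 1 is 0; equal level sizes give a zero indexing gap
(computed exactly, not via floating-point cancellation); the LZ78 tail
phrase may duplicate an earlier phrase and is counted.

## Known limitations

- Scores are description lengths, not probabilities; thresholds are
  data-calibrated, and no finite-sample false-positive guarantee beyond
  the quantile argument is claimed.
- The dictionary is static: no online updates during testing.
- Memory grows as the total pattern mass `sum_d a_d·d`; for very large
  `Dmax × L` the per-level hash tables dominate.
- The escape model is deliberately crude (one global cost); heavy-tailed
  novel-symbol traffic would deserve an adaptive escape probability.
- The benchmark's separability ceiling (above) limits how finely it can
  discriminate between good detectors.
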