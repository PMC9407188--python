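# patterndict

Compression-based anomaly detection for discrete sequences and discretized
time series, built around a **multi-level pattern dictionary**.

Many anomaly-detection problems — intrusion traces, symbolized sensor
streams, wearable physiology — reduce to one question: does this window of
symbols look like the training data?  Lossless source coding gives a
principled answer.  Train a coder on typical data; a window that the
trained coder describes cheaply is typical, and a window that a *universal*
coder describes more cheaply than the trained coder is atypical.  This
package implements that programme end to end for sequences over a finite
alphabet, plus the uniform quantizer that turns real-valued (possibly
multichannel) signals into such sequences.

## The method

**Pattern dictionary.**  From a training sequence `x_1..x_L` collect every
distinct subsequence ("pattern") of length (depth) `d = 1..Dmax` into
per-depth sets `S^d`, with empirical probabilities `count / (L - d + 1)`.
Each level gets its own Huffman code, so indexing a pattern costs
`log2(Dmax) + L^d(pattern)` bits.  Splitting by depth is never worse than
one flat index over all patterns: the saving is exactly `log2(A/G)`, with
`A, G` the arithmetic and geometric means of the level sizes `a_d`
(`indexing_codelength_gap`).

**PDD score.**  A test window is parsed greedily into the longest
dictionary patterns (`pd_parse`); its codelength
`sum_i L_D(phrase_i) + c·log2 Dmax` — or just the phrase count `c` — is the
anomaly score (`pdd_score`).

**PDA score.**  The atypicality score pits the trained coder against LZ78,
whose parse into `c_A` incremental phrases costs `c_A·log2(c_A + 1)` bits:

    PDA(x) = L_T(x) - L_A(x)

high = typical coder struggling = anomalous (`pda_score`).  For scans over
unknown window lengths, `L_A` carries the universal integer cost `log*(l)`
and positions are flagged when `max_l [L_T - L_A - log*(l)] > tau`
(`scan`); `tau` can be calibrated to a false-positive target by
cross-validation on the training data alone (`calibrate_tau`).

**Non-asymptotic bounds.**  The LZ78 phrase count of an X-ary length-`l`
sequence obeys closed-form bounds — the lower `(sqrt(8l+1)-1)/2`, the upper
through the principal branch of the Lambert W function — which bracket the
attainable range of the anomaly score (`bounds` module).

## Worked example

The 25-symbol training string `ABACADABBACCADDABABACADAB` over the alphabet
`{A, B, C, D}` (map letters to `0..3`):

```python
>>> import patterndict as pd
>>> seq = [ord(c) - 65 for c in "ABACADABBACCADDABABACADAB"]
>>> d = pd.assign_codelengths(pd.build_dictionary(seq, dmax=3))
>>> d.levels[1][(0,)].prob, d.levels[1][(0,)].codelength   # pattern "A"
(0.44, 1.0)
>>> d.levels[2][(0, 1)].prob, d.levels[2][(0, 1)].codelength  # "AB"
(0.20833333333333334, 2.0)
>>> res = pd.pd_parse(d, [ord(c) - 65 for c in "ABAD"])
>>> res.phrases, res.c, round(res.codelength, 3)
([(0, 1, 0), (3,)], 2, 9.17)
```

`A` occurs in 11 of 25 depth-1 windows (probability 0.44) and, being the
most frequent symbol, gets the 1-bit Huffman word; the test string `ABAD`
parses into two phrases, `ABA` (3 bits) and `D` (3 bits), plus two depth
indices of `log2 3` bits each — 9.17 bits in total.  The multi-level
indexing saving for this dictionary's first two levels `(a_1, a_2) = (4, 9)`:

```python
>>> q = pd.indexing_codelength_gap([4, 9])
>>> round(q["L_uni"], 3), round(q["L_multi"], 3), round(q["gap"], 3)
(3.7, 3.585, 0.115)
```

The same machinery from the shell:

```
patterndict build-dict --train train.txt --dmax 40 --code huffman --out dict.json
patterndict score --dict dict.json --test test.txt --window 100 --out scores.csv
patterndict scan  --dict dict.json --test test.txt --lengths 50,100 --tau 0 --out track.csv
```

## The synthetic benchmark

`run_benchmark` reproduces the package's evaluation study: a chaotic
Mackey–Glass series (3000 samples) trains every detector; replicate test
series (1500 samples) carry a 500-sample segment from an anomalous MG
source (both coefficients doubled), rescaled to the host's mean/std and
grafted at position 500.  Signals are discretized by a uniform quantizer
(alphabet 90/45/10 for high/medium/low resolution), a 100-sample window
slides over each test series, and per-replicate ROC and PR AUCs are
averaged.  Besides PDD and PDA it runs four reference detectors:
Ziv–Merhav cross-parsing, nearest-neighbor similarity, the
compression-based dissimilarity measure, and t-STIDE.

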