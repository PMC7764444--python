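# Methods

## The compression model

The codec targets multichannel physiological telemetry (ECG,
photoplethysmograms, seismo- and gyrocardiograms) sampled as unsigned
M-bit ADC codes. It combines three ingredients:

1. **DPCM.** Each sample is predicted by its predecessor; only the residual
   `r[n] = d[n] − d[n−1]` is coded. For naturally occurring signals the
   residual magnitudes concentrate near zero, so they are far more
   compressible than the samples themselves. DPCM's assumption — adjacent
   samples are highly correlated — is exactly what impulsive noise breaks,
   which is why accelerometer channels end up with the widest residual
   histograms.

2. **Probability classes.** A residual magnitude `z = |r|` is split at bin
   width `2^m` into a class `p = ⌊z / 2^m⌋` (the upper `M − m` bits) and an
   index `q = z mod 2^m` (the lower `m` bits). Residual histograms are
   locally flat, so magnitudes within one class are approximately
   equiprobable: the class is worth entropy-coding, the index is not and is
   transmitted verbatim. This is the same "code the top bits, send the low
   bits in binary" structure as Golomb–Rice coding, but with a Huffman code
   (not unary) over the classes and with `m` learned from data rather than
   from waveform morphology.

3. **Selective Huffman coding.** Only the `k` most frequent classes receive
   codewords. Every sample code starts with a 1-bit indicator: encoded
   (sign bit + class codeword + m index bits) or raw (the M sample bits).
   The raw escape keeps the code total — any value is representable — so
   compression is lossless for every input, including magnitudes never seen
   in training. A raw sample costs `1 + M` bits; an encoded one costs
   `2 + len(code) + m`.

The "standard" full-table method is the special case `m = 0`,
`k = |support|`: a codeword for every observed residual magnitude. The
package implements it as the baseline (`evaluation.baseline_table`) with
the same indicator-bit accounting, so the two methods are directly
comparable and the baseline too stays lossless on unseen magnitudes.

## Learning m and k

Hyperparameters are learned by model validation. The channel's samples are
split into equal, non-overlapping halves — training first, validation
second (an odd trailing sample is dropped). Candidate tables `T_{m,k}` are
built from the `k` most frequent *training* classes and scored by Φ, the
exact bit count of the *validation* data under that table; the search
minimizes Φ over `0 ≤ m < M` and `k ∈ [k1, k2]`. Scoring on held-out data
deliberately penalizes codes that overfit the training half: rare classes
whose presence lengthens the codes of frequent ones get pruned, which is
why the optimum regularly has `k* < k2`.

Φ is evaluated in two forms:

* **Naive**: sum the per-sample code length over the validation samples,
  O(N). Kept as the oracle.
* **Fast**: `Φ = N(1+M) − Σ_a H_m[a]·(λ_m − len(T[a]))` with
  `λ_m = M − m − 1`, summed over classes in both the validation histogram
  `H_m` and the table. This is an algebraic rearrangement, not an
  approximation; tests assert bit-for-bit equality. Its cost is
  O(min(k, support)) per candidate — independent of N.

The histograms themselves are computed once at `m = 0` and then coarsened
by the identity `⌊z/2^(m+1)⌋ = ⌊⌊z/2^m⌋/2⌋`: merging adjacent bin pairs of
the sparse support yields the next histogram without touching the data
again. A property test checks the recurrence against directly built
histograms for every `m` up to the bit depth.

**Conventions.** The first residual of any dataset is taken against a
fictitious predecessor 0, in both histogram construction and Φ, so the two
always agree (skipping the first sample instead would break the fast/naive
identity by one term). The search clamps `k` to the training support and
stops the `m` loop as soon as the support falls below `k1` (coarsening only
shrinks support). If the support is below `k1` already at `m = 0` — e.g. a
constant channel with the default `k1 = 10` — there is no feasible
candidate and `grid_search` raises an invalid-argument error rather than
silently returning something outside the requested range.

**Determinism.** Two tie-break rules make results platform-independent:
equal histogram counts sort by ascending class; equal Huffman subtree
weights merge lower-weight-then-lower-min-class first, with bit 0 to the
first-popped branch. Equal Φ resolves toward smaller m, then smaller k
(smaller tables, less decoder memory). Any consistent rule would preserve
optimality; these make tables byte-reproducible. The degenerate `k = 1`
table, where textbook Huffman yields an empty codeword, is assigned the
1-bit codeword "0" so the stream stays self-delimiting, at a cost of one
bit per encoded sample in that rare configuration.

## Defaults

| parameter | default | rationale |
|---|---|---|
| `k1, k2` | 10, 30 | search range of table sizes; 30 entries bound decoder memory, 10 avoids trivially small codes |
| `samples_per_packet` | 50 | packet granularity of the wearable protocol |
| bit depths | 14 (ECG/SCG/PPG), 16 (GCG) | ADC resolutions of the emulated front-ends |
| sampling rate | 1600 Hz (3200 Hz supported) | native rates of the emulated gyroscope |
| split fraction | 0.5 | equal train/validation halves |
| table ID | 1 (0 = no table, all-raw) | stream/decoder table synchronization |

## Packet framing

Packets are self-contained: the first sample of every channel block is
sent raw, so any packet decodes in isolation and the stream survives
reordering, duplication (dropped exactly, counted) and loss (reported as
sequence gaps). Sensor-data frames carry a CRC32; the frame layout
(docs/formats.md) is this package's own — the 19-byte header/trailer
constant that appears in the uncompressed-bandwidth arithmetic
(`50×(15×7+17×3)/8 + 19 = 994` bytes per packet; ≈32 kB/s at 1600 Hz,
≈64 kB/s at 3200 Hz) is treated as an opaque constant of the deployed
radio protocol by `evaluation.packet_size_bytes`, deliberately not
conflated with this package's framing. Bit order within every field is
MSB-first; per-channel payloads are zero-padded to byte boundaries so
channels are independently addressable.

## Synthetic data

The generators are parametric signal models — periodic templates plus
noise — not physiological simulators. They reproduce the residual
*statistics* that drive codec behaviour:

* `ecg-like`: narrow periodic spikes over a slow baseline → unimodal,
  rapidly decaying residual-magnitude histogram with a heavy spike tail;
* `ppg-like`: smooth pulse harmonics; optional gated high-harmonic
  interference (intermittent contact/motion artifact) adds a second,
  well-separated mode to the magnitude histogram;
  `dynamic_range_fraction → 1` emulates a near-saturating finger PPG;
* `scg-like`: low-amplitude oscillatory bursts plus Bernoulli–Laplace
  impulses that inflate the residual support;
* `gcg-like`: noise-dominated low-amplitude 16-bit channel;
* `uniform-noise`: i.i.d. samples — a stationary, wide-support stress case.

Everything is seeded and byte-reproducible. What passing tests on these
signals shows is that the codec, search and framing behave correctly for
the residual regimes above; they say nothing about compression ratios on
real recordings, whose residual statistics (electrode artifacts, breathing
modulation, true motion) are richer than any of these templates.

## Problem sizes used in tests

The test suite and examples run on seconds of synthetic signal (the
round-trip acceptance check uses 10 s of the 10-channel roster at 1600 Hz,
i.e. 160 000 samples); search-oracle comparisons use 100 random datasets of
up to 500 samples at bit depths up to 10, where the brute-force rescoring
oracle is cheap. These sizes exercise every code path; nothing in the
implementation depends on them.

## Known limitations

* The encoder's hot loop is pure Python; throughput is on the order of a
  hundred thousand samples per second, fine for offline work but not a
  real-time embedded implementation.
* No streaming/online table update driver is provided; the O(1)
  histogram-update primitive exists, but retraining is batch.
* Recovery from a corrupted *length field* loses the remainder of a
  concatenated stream file (frame boundaries are length-derived); per-frame
  corruption is contained by the CRC.
* Signed or floating-point inputs are out of scope; samples are unsigned
  M-bit ADC codes.
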