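# Methods

This note documents the models, parameter choices and numerical decisions
behind `eegpress`, and what the synthetic validation does and does not
establish.

## Signal model and codec assumptions

The codec treats each 10-s epoch of referential scalp EEG as an m x n
real matrix in microvolts and assumes, per epoch:

* **spatial redundancy** — diffuse (encephalopathic) activity has broad
  fields, so the epoch has low effective rank and a truncated SVD captures
  most energy in k << m modes;
* **spectral sparsity** — slow polymorphic rhythms concentrate energy in
  few DCT-II coefficients, so magnitude thresholding after an orthonormal
  transform discards little;
* **stationarity within, independence across epochs** — each epoch is
  coded independently; nothing is predicted across epoch boundaries.

Both assumptions fail gracefully rather than catastrophically: isolated
sharp events are attenuated (not displaced), and incompressible content
surfaces as a higher percent-RMS distortion at the same enforced ratio,
never as a missed rate target (the rate search reports infeasibility
only when even zero retained coefficients cannot reach the target).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `epoch_seconds` | 10 s | page length; fs x epoch_seconds must be integral |
| `target_cr` | 20 | archive-level ratio of raw 16-bit bytes to archive bytes |
| regime `comp1` | k = 12 | SVD stage ~1.7x for 21 x 2560; DCT stage carries ~12x |
| regime `comp2` | k = 6 | SVD stage ~3.5x; DCT stage ~5.8x (balanced split) |
| thresholding `mode` | `pooled` | one magnitude ranking over all k x n coefficients; `per_vector` splits the count evenly instead |
| numeric scoring threshold | 0.20 | relative difference above which numeric responses disagree |

The stage-CR accounting (raw epoch bytes over truncated-factor bytes at
16 bits) is this package's own definition; under it k = 12 and k = 6
reproduce the intended stage ratios for the 21-channel, 256 Hz reference
geometry, and both are plain configuration, not constants.

The default target of 20 reflects the archival motivation (a day of
monitoring stored in roughly an hour's volume). Pooled thresholding is
the default because, for a fixed total count, a global magnitude ranking
retains at least as much energy as any per-vector quota.

## Rate control

Thresholding controls the retained-coefficient count exactly, but the
bytes that count produces depend on the zero-run structure met by the
run-length coder, so the achieved CR is always measured from the fully
serialized epoch block (factors, per-stream offset/scale, checksummed
header included). The search for the count is a secant (Newton-style)
step on the count-vs-serialized-size relation with a bisection fallback
and a hard 50-iteration cap; on the monotone staircase this converges in
at most ~log2(k x n) evaluations and returns the largest count whose CR
still meets the target — i.e. the achieved ratio closest to the target
from above. Strict monotonicity of size in count can be violated by at
most a couple of bytes in pathological zero-run layouts (an isolated
zero costs two words, a literal one); the final local scan around the
bracket absorbs this.

When a whole recording is compressed, the per-epoch target is inflated
just enough to amortize the global archive header, so the archive-level
ratio — the honest, storage-relevant figure — meets the requested target.

## Quantization and zero preservation

All serialized reals use uniform 16-bit quantization on a grid symmetric
about zero (scale = max|v|/32767, offset 0). The symmetric anchor is the
coupling between thresholding and RLE: thresholded-to-zero coefficients
must quantize to code 0, or the zero runs the rate search is counting
would not exist in the code stream. Elementwise error is bounded by
scale/2; constant inputs round-trip exactly. Loadings and singular
values are quantized but not DCT/RLE-coded: they are m x k + k values,
too small to matter for rate and too distortion-critical to sparsify.

## Container

The CEZ container is little-endian: magic `CEZ1`, a versioned global
header (geometry, sampling rate, channel labels and EDF calibration,
regime, start time), then one length-prefixed, CRC-32-checksummed block
per epoch. Checksum failures are per-epoch; decompression can zero-fill
a corrupt epoch and continue, which is the right trade-off for an
archival format. Serialization round-trips bit-exactly.

EDF input must be continuous (EDF or EDF+C; EDF+D rejected) with one
shared sampling rate; the EDF reader and writer are implemented here
directly against the published fixed-layout format, and the writer's
output is cross-checked in the test suite against an independent reader
(`mne`). Trailing partial epochs are dropped with a warning rather than
padded — padding would distort epoch spectra. Reconstruction output is
clipped to each channel's physical range and re-exported as plain EDF
with the input's calibration.

## Synthetic data: what it emulates and what it does not

The generator produces seeded, bit-reproducible recordings of six
scenario classes (diffuse slowing, focal slowing, lateralized periodic
discharges, evolving seizure, burst suppression, 60 Hz line overlay) over
the 21 standard 10-20 electrodes. Spatial structure comes from at most
five smooth scalp-topography-like mixing vectors (so diffuse scenes are
low-rank by construction, exactly rank-r when the pink-noise floor is
disabled); temporal structure from amplitude-modulated delta-theta
oscillators; discharges are a 70 ms biphasic sharp transient plus a
350 ms slow wave at a deterministic ~1/s train, scaled ~2.4x the
background over one hemisphere with a Gaussian field. Default amplitudes
(50 uV dominant pattern, 2 uV pink-noise floor) sit in the clinically
typical scalp range.

This is deliberately *not* a biophysical forward model: no volume
conduction, no electrode artifact beyond mains, no state transitions,
and spatial fields far smoother than real scalp topography. Passing
tests therefore demonstrate the codec's contracts (rate achievement,
error bounds, stage behaviour, the comp1-vs-comp2 sharp-transient
asymmetry) on signals with the right rank and spectral character — they
do not certify diagnostic fidelity on patient data, which is inherently
a human-reader question.

## Concordance scoring

The template is a three-category tree (background I.A-D: symmetry,
organization, continuity, predominant frequency; focal II.A-B: slowing,
attenuation; hyperexcitability III.A-C: sporadic discharges,
rhythmic/periodic patterns, seizures) with 45 leaf features, mixed
binary/nominal/numeric responses, and per-node penalties. Scoring walks
each major's branch depth-first, left-to-right; the first disagreement
on a branch contributes that node's penalty and stops descent, and
within a major the qualifier penalties sum to at most the major's own
penalty, so the maximum omnibus score — total disagreement on all nine
majors — is exactly 60 and every branch is bounded by its major.

Three decisions were genuinely open and are resolved as follows:

* **The full published template is not reproduced here.** The bundled
  YAML is constructed to satisfy every published structural constraint
  (category layout, 45 leaves, anchors 14/1/4/3, cap rule, maximum 60);
  the loader validates any substitute template against the same rules,
  so a site's exact tree can be dropped in.
* **Numeric 20 % rule**: the denominator is the mean of the two values,
  |x-y| / ((|x|+|y|)/2) > 0.20 — the symmetric form keeps the whole
  disagreement score symmetric in its two arguments, which the paired
  design requires; (0, 0) agrees.
* **Qualifier gating**: children of a binary presence feature are
  compared only when both readings mark it present — qualifiers of a
  feature both readers called absent are meaningless, and gating keeps
  the walk total and symmetric.

"Unclear" nominal levels are ordinary levels: any mismatch triggers the
penalty, with no partial credit.

The paired test is the one-sided Wilcoxon signed-rank (null: the
intra-reader baseline's median disagreement is not smaller than the
original-vs-reconstruction's): zero differences dropped, mean ranks for
ties, exact null distribution up to 25 informative pairs and a
continuity-corrected normal approximation beyond; all-zero differences
return a degenerate p = 1 rather than an error.

## Numerical choices and degenerate inputs

* SVD sign ambiguity is fixed by forcing the largest-magnitude entry of
  each loading column positive — serialized archives are deterministic
  across runs. Repeated singular values admit any valid basis; tests
  assert reconstruction, never factor identity.
* DCT-II uses the orthonormal normalization, so Parseval is exact and
  magnitude thresholding is energy-optimal for its count; ties break
  toward the lower index.
* Coefficient rows belonging to zero singular values are zeroed before
  rate search — they cannot affect reconstruction and would waste bytes.
* Zero epochs compress to the payload floor and reconstruct exactly;
  PRD is declared undefined (an error, not NaN) for zero-energy
  originals.
* Quantizing a constant stream yields codes +/-32767 and exact
  round-trip; an all-zero stream uses scale 1 and codes 0.

## Problem sizes

The test suite and the acceptance script run on 10-s to 10-minute
synthetic recordings (up to one hour for epoch-count checks); these
sizes exercise every code path, keep the whole suite in well under a
minute of compute, and the rate-control and distortion behaviour they
measure is per-epoch, so longer records add repetition, not new regimes.

## Known limitations

* Entropy coding stops at RLE: no Huffman/arithmetic stage, no
  inter-epoch prediction — the format favours simplicity and per-epoch
  random access over the last factor of compression.
* The codec never re-montages; it compresses the referential montage as
  stored, and non-EEG channels are the caller's responsibility via the
  channel-selection argument.
* Stage-CR bookkeeping (hence the k behind each regime) is a package
  definition; other accountings would shift the preset ranks.
* Reviewer medians/IQRs and p-values from human readings are outside
  what synthetic data can reproduce; the scorer computes the scores, it
  does not adjudicate clinical equivalence.
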