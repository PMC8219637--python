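# Methods

## Model

The package implements a discriminative lexicon: lexical knowledge is a
set of linear transformations between vector systems, with no morphemes
and no stored exemplars. The vector systems are binary indicator
matrices over orthographic trigrams (**C**ₒ), phonological triphones
(**T**ₐ), and acoustic FBS features (**C**ₐ), plus a real-valued semantic
matrix **S**. All cue encodings share one code path: 3-grams of the
boundary-padded symbol sequence, one `#` on each side, so a form of *n*
phones yields *n* cue tokens (a 1-phone form yields the degenerate cue
`#x#`). Cue inventories are ordered by first appearance in the training
data, which makes every matrix bit-reproducible.

Each mapping **A** is the minimum-norm least-squares solution of
**X A** = **Y**, computed by an SVD solver with relative singular-value
cutoff 1e−10. The Widrow–Hoff incremental path
(**A** ← **A** + η·xᵀ(y − x**A**)) is provided and converges to the same
solution for consistent data; the closed-form solve is the default
because it is exact and fast at desk scale.

### Semantic vectors

Semantic vectors are rows of a lexome-by-lexome association matrix
learned by the Rescorla–Wagner rule applied incrementally to a
lexome-coded corpus: per sentence, cues = outcomes = the sentence's
lexome set (every word also predicts itself), present outcomes have
target λ = 1, all absent lexomes target 0, and a single collapsed
learning rate (default 0.001, configurable) plays the role of α·β with
equal saliences. Learning is one pass in corpus order (epochs
configurable) and is deliberately order-sensitive — it is incremental,
not batch. Post-processing zeroes the self-prediction diagonal and prunes
columns whose population variance falls below 3.4e−8 (configurable).
The vector of a multi-lexome (inflected) word is the sum of its lexomes'
rows; ambiguous surface forms contribute one row of **S** per reading.

### Production

`speak` maps a semantic vector through **G** to triphone supports, keeps
triphones with positive support ≥ the thinning threshold (default 0.1)
as graph vertices, and connects every retained pair overlapping in two
symbols. Thinning is applied to vertices; since a path is only as
available as its weakest triphone, vertex thinning subsumes edge
thinning and matches the worked examples we validate against. Because
string-mergeable transitions can exist that never occur in any training
word, an `edges="attested"` mode restricts edges to transitions observed
in training forms (default: `mergeable`). Candidates are all simple
paths (no vertex revisits — cycles can arise from repeated triphones)
from an initial `#xx` to a final `xx#` vertex, capped at 10,000 with a
logged warning; a `#x#` triphone is a one-vertex path. Candidate ranking
is by Pearson correlation of the re-comprehended semantics with the
target, ties broken by fewer phones, then lexicographic phone order.
ALDC is kept at full precision (the worked value 4/3 prints as 1.33).

### Comprehension and measures

Both routes are always computed: ŝ₁ = c**F** and ŝ₂ = c**E H**꜀.
Pearson correlation (the cosine of centered vectors) is used for all
angle measures. ALC averages over the rows of the semantic space, i.e.
over inflectionally distinct readings rather than surface types.
Zero-variance vectors get correlation 0 (logged) rather than NaN so that
maxima and means over degenerate candidates stay defined; distance
measures are unaffected. The PCA regularization standardizes its input
columns (correlation-matrix PCA) and fixes signs so each component's
largest-magnitude loading is positive.

A desk-scale caveat: when **T**ₐ has full row rank (more distinct
triphones than words, the usual case for small lexicons), the min-norm
solutions make **E H**꜀ = **C**ₐ⁻ **T**ₐ**T**ₐ⁻ **S** = **C**ₐ⁻ **S** =
**F**, so the two routes coincide and DRC ≡ 1 exactly. Route divergence
is a large-lexicon phenomenon; DRC should therefore not be fed to the
PCA on small synthetic worlds (it is constant there).

## Acoustic front end

FBS features summarize the spectral shape of envelope-defined signal
chunks. Choices, with defaults:

- **Envelope & chunking**: magnitude of the analytic (Hilbert) signal,
  smoothed by a 20-ms moving average; chunk boundaries at interior local
  minima with a relative prominence of at least 5% of the envelope peak
  (plateaus take their leftmost index). The prominence floor is this
  package's numerical choice: a bare strict-minima scan would split
  constant-amplitude signals at floating-point ripple.
- **Spectra**: consecutive *non-overlapping* 5-ms windows, trailing
  partial window dropped; chunks shorter than one window are merged into
  their neighbor so the partition is preserved.
- **Bands**: 21 triangular MEL-spaced filters from 0 Hz to Nyquist;
  intensity = log band power.
- **Discretization**: five levels from per-token quantile bins of the
  pooled band intensities (making level patterns invariant to uniform
  amplitude scaling); fixed-range binning is selectable. The median of
  an even-length level series is the lower median, staying on the
  integer grid.

## Synthetic test world

The generator emulates a morphologically structured lexicon: unique
CV/CVC-syllable stems (1–2 syllables over 14 consonants and 5 vowels),
five suffixing exponent categories (with the systematically ambiguous
pairs pre-merged into `past/perfective` and `person3/plural`), lexome
vectors i.i.d. standard normal, and gold word vectors that are exactly
stem + exponent + N(0, noise_sd²) with noise_sd = 0.05 by default.
Default conditions used by the end-to-end tests: 200 stems, semantic
dimension 50, half the words inflected, three fixed seeds. Pseudowords
replace ⌈⅓ × #subsyllabic constituents⌉ onset/nucleus/coda slots of a
sampled base word's stem with different same-category segments,
preserving any inflectional suffix and never colliding with a real word
form; inflection labels are then re-derived purely from form by
longest-suffix match (equal-length matches yield multiple labels).
Synthetic audio renders each phone as a 60–120 ms tone (log-spaced
frequency per phone) with light noise and low-amplitude inter-phone
gaps, giving the envelope chunker realistic minima.

What the synthetic world does *not* emulate: English phonotactics and
transition-probability-matched pseudoword generation, coarticulation and
speaker variability in the audio, and — importantly — the dense
correlational structure of corpus-derived semantics. With i.i.d. lexome
vectors the gold word vectors are near-orthogonal, so each word's mean
correlation with the lexicon is close to zero while a pseudoword's
estimated vector, being a positive-weight blend of word vectors,
correlates mildly positively with many words. The mean-correlation
density measure (ALC) therefore does not show the sparser-neighborhood
direction for pseudowords at desk scale, and the corresponding
acceptance check documents this as a failing assertion; EDNN, NNC and
ALDC separate words from pseudowords strongly in the expected
directions. Passing tests show that the machinery is correct under the
stated generative assumptions, not that real-data effect sizes are
reproduced.

## Problem sizes and determinism

End-to-end tests fit 200-word lexicons with 50-dimensional semantics
(about 2 s per fit including audio synthesis); measure tables use 150–200
pseudowords; micro-example tests are exact and instantaneous. All
randomness flows through seeded NumPy generators; per-word audio seeds
are derived from the model seed and the word index, so identical
configurations give byte-identical outputs.

## Known limitations

- The RW learning rate and pass count for corpus-derived semantics are
  conventions, not calibrated values.
- Production enumerates simple paths only; forms requiring a repeated
  triphone are not representable as simple paths.
- The FBS discretization and envelope smoothing differ in detail from
  other published acoustic front ends; defaults are declared above.
- `edlib` accelerates phone-level edit distance via a compact byte
  alphabet; inventories beyond ~200 distinct symbols in a single
  comparison fall back to a pure-Python dynamic program.
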