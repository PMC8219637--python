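# ldlex

**Linear discriminative learning of the mental lexicon: form–meaning
mappings, triphone-graph speech production, and pseudoword measures.**

`ldlex` is for computational psycholinguists who want to model how words
*and* novel forms (pseudowords) are understood and produced without
morphemes, lexical entries, or a mental dictionary lookup. In the
discriminative-lexicon view, lexical knowledge lives entirely in simple
linear networks between high-dimensional vector systems: knowing a word is
knowing the mappings, not storing the exemplar. Because the mappings are
defined for any cue vector, a pseudoword such as *[loks]* is processed by
exactly the same machinery as a real word — it lands somewhere in semantic
space, and where it lands is measurable.

## The model

Words are rows of paired matrices: orthographic trigram indicators
**C**ₒ, phonological triphone indicators **T**ₐ (3-grams of the
boundary-padded phone string, e.g. `#lo, lok, oks, ks#`), acoustic
frequency-band-summary (FBS) indicators **C**ₐ, and semantic vectors
**S**. Semantic vectors are additive over *lexomes*: the vector of an
inflected word is the sum of its stem and inflectional-function vectors
(e.g. *walks*(verb) = walk + 3sg + present); lexome vectors themselves can
be learned incrementally from a lexome-coded corpus with the
Rescorla–Wagner rule. Each network **A** solves **X A** = **Y** by
minimum-norm least squares through the generalized inverse
(**A** = **X**⁻**Y**), or incrementally by the Widrow–Hoff rule:

| mapping | solves | role |
|---------|-----------------|------|
| **J**   | **C**ₒ**J** = **T**ₐ | trigrams → triphones |
| **H**ₚ  | **T**ₐ**H**ₚ = **S** | triphones → semantics (production check) |
| **G**   | **S G** = **T**ₐ | semantics → triphone support |
| **F**   | **C**ₐ**F** = **S** | acoustics → semantics (direct route) |
| **E**, **H**꜀ | **C**ₐ**E** = **T**ₐ, **T**ₐ**H**꜀ = **S** | indirect route |

**Production** maps a semantic vector through **G** onto triphone
supports, keeps triphones with support ≥ 0.1 as vertices of a directed
graph (edges join string-mergeable triphones), enumerates all simple
paths from an initial `#xx` to a final `xx#` triphone, and selects by
synthesis-by-analysis: each candidate path's binary triphone vector is
re-comprehended through **H**ₚ and the candidate whose semantics best
correlates with the target wins.

**Measures.** Per pseudoword the package computes EDNN (Euclidean distance
to the nearest word vector), NNC (maximum Pearson correlation with any
word), ALC (mean correlation with all words), DRC (direct–indirect route
correlation), ALDC (mean phone-level Levenshtein distance of the
production candidates from the target; the target's phone count when no
candidate is found), and SCPP (maximum correlation of the target
semantics with any candidate's re-comprehended semantics; 0 without
candidates). A PCA regularization and Same/Different/Uninflected
inflectional similarity profiles are included.

A synthetic-lexicon generator (CV/CVC stems, suffixing exponents,
additive gold semantics, Wuggy-style pseudowords by subsyllabic-constituent
exchange, synthetic audio tokens) makes the whole pipeline testable at
desk scale.

## Worked example

```python
from ldlex import LDLModel, LexiconSpec, generate_lexicon, generate_pseudowords

lexicon = generate_lexicon(LexiconSpec(n_stems=60, semantic_dim=40,
                                       noise_sd=0.05, seed=7))
results = LDLModel(lexicon, use_audio=True, seed=7).fit()
print(results.summary())
```

```
Linear discriminative lexicon model
===================================================
words (readings):        60
semantic dimension:      40
trigram cues:            234
triphone cues:           234
acoustic route:          FBS (1793 features)

Training-set reconstruction (mean row correlation):
         mean_row_correlation
mapping
J                      1.0000
H_p                    1.0000
G                      0.8065
F                      1.0000
E                      1.0000
H_c                    1.0000
```

`J` is essentially error-free (trigrams and triphones are in one-to-one
correspondence), comprehension reconstructs the training semantics
exactly (cue dimensions exceed the word count), and `G`'s lower row
correlation reflects that a 40-dimensional semantic vector cannot fully
span 234 triphone columns. Measures for held-out pseudowords:

```python
pws = generate_pseudowords(lexicon, n=5, seed=11)
table = results.measures([p.form for p in pws], ids=[str(p.form) for p in pws])
print(table.round(3).to_string(index=False))
```

```
      id  ednn_1  nnc_1  alc_1  ednn_2  nnc_2  alc_2  drc  aldc  scpp  is_infl infl_category
  ritest   4.845  0.707  0.058   4.845  0.707  0.058  1.0 3.000 0.892     True   superlative
   dibip   5.781  0.616  0.138   5.781  0.616  0.138  1.0 3.000 0.854    False   uninflected
  zutest   5.454  0.599  0.061   5.454  0.599  0.061  1.0 3.000 0.930     True   superlative
zitroest   4.898  0.773  0.064   4.898  0.773  0.064  1.0 3.333 0.882     True   superlative
      gu   5.454  0.622  0.067   5.454  0.622  0.067  1.0 2.000 0.000    False   uninflected
```

Every pseudoword sits several units away from its nearest word neighbor
(EDNN > 0; for training words it is ~0) and correlates imperfectly with
its best neighbor (NNC < 1). *ritest* ends in the synthetic superlative
exponent, so it is labeled inflected purely from its form. *gu* generated
no production candidates: its SCPP is 0 and its ALDC equals its phone
count, 2. Production for one item:

```python
res = results.produce_form(pws[0].form)
print(["".join(c.phones) for c in res.candidates], res.aldc, res.scpp)
# ['nafkuest', 'zitest'] 3.0 0.892
```

The model proposes two pronounceable paths through the thinned triphone
graph; neither matches *ritest* exactly (ALDC 3.0), and the better one
re-comprehends to semantics correlating 0.89 with the pseudoword's.

A `ldlex` command-line interface mirrors the library:
`ldlex simulate`, `train`, `comprehend`, `produce`, `measures`,
`eval-morph`, `pca`.

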