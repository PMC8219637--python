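"""Desk-scale synthetic lexicons for end-to-end testing.

The generator emulates the structure of a morphologically organized
lexicon: CV/CVC-syllable stems, a configurable exponent table of
inflectional suffixes, semantic lexome vectors (i.i.d. standard normal),
and gold word vectors that are additive — stem vector plus exponent
vector plus Gaussian noise. Pseudowords are derived from real words by
exchanging a fraction of subsyllabic constituents (onset/nucleus/coda)
for other same-category segments while preserving any inflectional
suffix, so pseudowords inherit affixal forms; inflection labels are then
re-assigned purely from form by longest-suffix match, with systematically
ambiguous exponents mapped to merged categories. Synthetic audio renders
each phone as a short tone-plus-noise segment with amplitude dips between
phones, giving the envelope-based chunker something to find.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import LdlexError
from .acoustics import AudioToken
from .forms import WordForm
from .lexicon import Lexicon, WordEntry

logger = logging.getLogger("ldlex")

#: (category, phone suffix, inflectional lexome label); ambiguous English
#: exponents appear as merged categories, mirroring form-based labeling
DEFAULT_EXPONENTS: tuple[tuple[str, tuple[str, ...], str], ...] = (
    ("comparative", ("e", "r"), "@comparative"),
    ("superlative", ("e", "s", "t"), "@superlative"),
    ("continuous", ("i", "n"), "@continuous"),
    ("past/perfective", ("d",), "@past/perfective"),
    ("person3/plural", ("s",), "@person3/plural"),
)

DEFAULT_CONSONANTS = tuple("bdfgklmnprtvz")
DEFAULT_VOWELS = tuple("aeiou")


@dataclass
class LexiconSpec:
    n_stems: int = 200
    exponents: tuple = DEFAULT_EXPONENTS
    syllable_templates: tuple[str, ...] = ("CV", "CVC")
    consonants: tuple[str, ...] = DEFAULT_CONSONANTS
    vowels: tuple[str, ...] = DEFAULT_VOWELS
    n_syllables: tuple[int, int] = (1, 2)
    semantic_dim: int = 50
    noise_sd: float = 0.05
    p_inflected: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_stems < 1:
            raise LdlexError("LexiconSpec: n_stems must be >= 1")
        if self.semantic_dim < 2:
            raise LdlexError("LexiconSpec: semantic_dim must be >= 2")
        if not 0.0 <= self.p_inflected <= 1.0:
            raise LdlexError("LexiconSpec: p_inflected must be in [0, 1]")
        if self.noise_sd < 0:
            raise LdlexError("LexiconSpec: noise_sd must be non-negative")


@dataclass
class SyntheticLexicon:
    """A generated lexicon plus its generative ground truth."""

    lexicon: Lexicon
    S: np.ndarray                      # gold word vectors, row-aligned
    lexome_labels: list[str]
    lexome_vectors: np.ndarray
    truth: pd.DataFrame                # id, stem, exponent, syllables
    spec: LexiconSpec
    exponent_table: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def words(self) -> list[WordEntry]:
        return self.lexicon.entries

    def lexome_vector(self, label: str) -> np.ndarray:
        return self.lexome_vectors[self.lexome_labels.index(label)]


def _sample_syllables(rng, spec: LexiconSpec) -> list[str]:
    n = int(rng.integers(spec.n_syllables[0], spec.n_syllables[1] + 1))
    return [str(rng.choice(spec.syllable_templates)) for _ in range(n)]


def _fill_template(rng, template: str, spec: LexiconSpec) -> list[str]:
    return [str(rng.choice(spec.consonants if slot == "C" else spec.vowels))
            for slot in template]


def generate_lexicon(spec: LexiconSpec) -> SyntheticLexicon:
    """Deterministically generate a lexicon from a spec and its seed."""
    rng = np.random.default_rng(spec.seed)
    stems: list[tuple[str, ...]] = []
    syllables: list[list[str]] = []
    seen: set[tuple[str, ...]] = set()
    attempts = 0
    while len(stems) < spec.n_stems:
        attempts += 1
        if attempts > 100 * spec.n_stems:
            raise LdlexError("generate_lexicon: phone inventory too small for "
                             f"{spec.n_stems} unique stems")
        templ = _sample_syllables(rng, spec)
        phones = tuple(p for t in templ for p in _fill_template(rng, t, spec))
        if phones in seen:
            continue
        seen.add(phones)
        stems.append(phones)
        syllables.append(templ)

    exponents = list(spec.exponents)
    lexome_labels = [f"stem{i:04d}" for i in range(len(stems))]
    lexome_labels += [lab for _, _, lab in exponents]
    lexome_vectors = rng.standard_normal((len(lexome_labels), spec.semantic_dim))

    word_forms: set[tuple[str, ...]] = set(stems)
    entries, vectors, truth_rows = [], [], []
    for i, stem in enumerate(stems):
        exponent = None
        if exponents and rng.random() < spec.p_inflected:
            order = rng.permutation(len(exponents))
            for j in order:
                cat, suffix, lab = exponents[int(j)]
                candidate = stem + suffix
                if candidate not in word_forms:
                    exponent = (cat, suffix, lab)
                    break
        phones = stem + exponent[1] if exponent else stem
        word_forms.add(phones)
        vec = lexome_vectors[i].copy()
        lexomes = {lexome_labels[i]}
        if exponent:
            vec = vec + lexome_vectors[lexome_labels.index(exponent[2])]
            lexomes.add(exponent[2])
        vec = vec + rng.normal(0.0, spec.noise_sd, spec.semantic_dim)
        entries.append(WordEntry(
            id=f"w{i:04d}", orthography="".join(phones),
            form=WordForm(phones), lexomes=frozenset(lexomes),
            inflection=exponent[0] if exponent else None))
        vectors.append(vec)
        truth_rows.append({
            "id": f"w{i:04d}", "stem": lexome_labels[i],
            "exponent": exponent[0] if exponent else "",
            "syllables": "-".join(syllables[i]),
        })
    return SyntheticLexicon(
        lexicon=Lexicon(entries),
        S=np.vstack(vectors),
        lexome_labels=lexome_labels,
        lexome_vectors=lexome_vectors,
        truth=pd.DataFrame(truth_rows),
        spec=spec,
        exponent_table={cat: suffix for cat, suffix, _ in exponents},
    )


def generate_corpus(lexicon: SyntheticLexicon, n_sentences: int = 500,
                    words_per_sentence: int = 4, seed: int = 0) -> list[tuple[str, ...]]:
    """Lexome-coded sentences for incremental semantic learning: each
    sentence is the pooled lexome set of a few sampled words."""
    rng = np.random.default_rng(seed)
    events = []
    for _ in range(n_sentences):
        picks = rng.choice(len(lexicon.words), size=words_per_sentence, replace=True)
        lexomes: dict[str, None] = {}
        for p in picks:
            for l in sorted(lexicon.words[int(p)].lexomes):
                lexomes.setdefault(l, None)
        events.append(tuple(lexomes))
    return events


@dataclass
class Pseudoword:
    id: str
    form: WordForm
    base_id: str
    inflection: tuple[str, ...]  # form-based labels; ("uninflected",) if none


def _constituents(syllables: list[str]) -> list[tuple[int, str]]:
    """Flat (position, category) slots of a stem's subsyllabic constituents."""
    slots = []
    pos = 0
    for templ in syllables:
        for slot in templ:
            slots.append((pos, slot))
            pos += 1
    return slots


def generate_pseudowords(lexicon: SyntheticLexicon, n: int,
                         fraction_exchanged: float = 1.0 / 3.0,
                         seed: int = 0, max_retries: int = 50) -> list[Pseudoword]:
    """Wuggy-style pseudowords: exchange ceil(fraction x #constituents)
    onset/nucleus/coda slots of a sampled base word's stem for different
    same-category segments, preserving any inflectional suffix. Outputs
    never collide with real word forms; a base that cannot be derailed
    within the retry budget is skipped with a warning.
    """
    if not lexicon.words:
        raise LdlexError("generate_pseudowords: empty lexicon")
    rng = np.random.default_rng(seed)
    spec = lexicon.spec
    word_forms = {w.form.phones for w in lexicon.words}
    syll_by_id = dict(zip(lexicon.truth["id"], lexicon.truth["syllables"]))
    exp_by_cat = lexicon.exponent_table
    out: list[Pseudoword] = []
    produced: set[tuple[str, ...]] = set()
    while len(out) < n:
        base = lexicon.words[int(rng.integers(len(lexicon.words)))]
        suffix = exp_by_cat.get(base.inflection, ()) if base.inflection else ()
        stem = base.form.phones[: len(base.form.phones) - len(suffix)] \
            if suffix else base.form.phones
        slots = _constituents(syll_by_id[base.id].split("-"))
        k = max(1, math.ceil(fraction_exchanged * len(slots)))
        ok = False
        for _ in range(max_retries):
            chosen = rng.choice(len(slots), size=k, replace=False)
            phones = list(stem)
            for c in chosen:
                pos, cat = slots[int(c)]
                pool = [p for p in
                        (spec.consonants if cat == "C" else spec.vowels)
                        if p != phones[pos]]
                phones[pos] = str(rng.choice(pool))
            candidate = tuple(phones) + tuple(suffix)
            if candidate not in word_forms and candidate not in produced:
                ok = True
                break
        if not ok:
            logger.warning("generate_pseudowords: skipped base %s after %d retries",
                           base.id, max_retries)
            continue
        produced.add(candidate)
        form = WordForm(candidate)
        out.append(Pseudoword(
            id=f"pw{len(out):04d}", form=form, base_id=base.id,
            inflection=label_inflection(form, exp_by_cat)))
    return out


def label_inflection(form: WordForm,
                     exponent_table: dict[str, tuple[str, ...]]) -> tuple[str, ...]:
    """Form-based inflection labeling: longest matching suffix wins; equal
    longest matches are all emitted (multi-label); no match is
    ("uninflected",)."""
    phones = tuple(form.phones)
    best_len = 0
    labels: list[str] = []
    for cat, suffix in exponent_table.items():
        suffix = tuple(suffix)
        if len(suffix) < len(phones) and phones[-len(suffix):] == suffix:
            if len(suffix) > best_len:
                best_len, labels = len(suffix), [cat]
            elif len(suffix) == best_len:
                labels.append(cat)
    return tuple(sorted(labels)) if labels else ("uninflected",)


def make_phone_map(phones, f_lo: float = 300.0, f_hi: float = 3800.0,
                   noise_amp: float = 0.15) -> dict[str, tuple[float, float]]:
    """Deterministic phone -> (tone frequency, noise amplitude) recipes,
    frequencies spread log-uniformly over [f_lo, f_hi] by sorted order."""
    phones = sorted(set(phones))
    freqs = np.geomspace(f_lo, f_hi, max(len(phones), 2))
    return {p: (float(freqs[i]), noise_amp) for i, p in enumerate(phones)}


def synth_audio(form: WordForm, phone_map: dict[str, tuple[float, float]],
                sample_rate: int = 16000, seed: int = 0,
                dur_range: tuple[float, float] = (0.06, 0.12),
                gap_ms: float = 15.0, gap_amp: float = 0.02) -> AudioToken:
    """Render a form as concatenated tone bursts with inter-phone dips."""
    rng = np.random.default_rng(seed)
    segments = []
    gap_n = int(round(sample_rate * gap_ms / 1000.0))
    for i, p in enumerate(form.phones):
        if p not in phone_map:
            raise LdlexError(f"synth_audio: unmapped phone {p!r}")
        freq, namp = phone_map[p]
        dur = float(rng.uniform(*dur_range))
        t = np.arange(int(round(dur * sample_rate))) / sample_rate
        seg = np.sin(2 * np.pi * freq * t) + namp * rng.standard_normal(t.size)
        ramp = np.minimum(1.0, np.minimum(np.arange(t.size),
                                          np.arange(t.size)[::-1]) /
                          max(1, int(0.01 * sample_rate)))
        segments.append(seg * ramp)
        if i < len(form.phones) - 1 and gap_n:
            segments.append(gap_amp * rng.standard_normal(gap_n))
    return AudioToken(np.concatenate(segments), sample_rate)
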