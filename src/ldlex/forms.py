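"""Form encoding: boundary-padded phone/letter 3-gram cues and edit distance.

A word form is an ordered sequence of phone symbols. Its context-sensitive
form units are all contiguous 3-grams of the boundary-padded sequence
(``#`` + phones + ``#``): the first cue starts with the boundary, the last
ends with it, and order information is implicit in the 2-symbol overlap of
consecutive cues. Orthographic trigrams and phonological triphones share
this code path and differ only in the inventory ``kind`` tag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._utils import LdlexError

logger = logging.getLogger("ldlex")

BOUNDARY = "#"

try:  # phone-level edit distance goes through edlib when the alphabet fits
    import edlib as _edlib
except ImportError:  # pragma: no cover
    _edlib = None


@dataclass(frozen=True)
class WordForm:
    """An ordered phone sequence with a word-boundary marker."""

    phones: tuple[str, ...]
    boundary: str = BOUNDARY

    def __post_init__(self):
        object.__setattr__(self, "phones", tuple(self.phones))
        if len(self.phones) == 0:
            raise LdlexError("WordForm: phones must be non-empty")
        if self.boundary in self.phones:
            raise LdlexError("WordForm: boundary symbol may not occur among phones")

    def __str__(self) -> str:
        return "".join(self.phones)


def parse_transcription(text: str, symbols: tuple[str, ...] | None = None,
                        boundary: str = BOUNDARY) -> WordForm:
    """Parse a transcription string into a WordForm.

    By default one character is one phone; a symbol table of multi-character
    phones may be supplied, matched greedily longest-first.
    """
    if symbols is None:
        return WordForm(tuple(text), boundary)
    table = sorted(symbols, key=len, reverse=True)
    phones, i = [], 0
    while i < len(text):
        for sym in table:
            if text.startswith(sym, i):
                phones.append(sym)
                i += len(sym)
                break
        else:
            raise LdlexError(f"parse_transcription: no symbol matches {text[i:]!r}")
    return WordForm(tuple(phones), boundary)


def triphone_tuples(form: WordForm) -> list[tuple[str, ...]]:
    """Ordered 3-gram windows of the padded form, duplicates preserved.

    A form of n >= 2 phones yields exactly n windows; a 1-phone form
    yields the single degenerate window (#, x, #).
    """
    padded = (form.boundary,) + form.phones + (form.boundary,)
    return [padded[i:i + 3] for i in range(len(padded) - 2)]


def cue_string(triple: tuple[str, ...]) -> str:
    return "".join(triple)


def encode_triplets(form: WordForm) -> list[str]:
    """Unique 3-gram cues of a form, in first-appearance order."""
    seen: dict[str, None] = {}
    for t in triphone_tuples(form):
        seen.setdefault(cue_string(t), None)
    return list(seen)


@dataclass
class CueInventory:
    """Ordered inventory of cue strings with a kind tag.

    For triphone inventories built from forms, ``tuples`` keeps the symbol
    decomposition of each cue, needed by the production graph.
    """

    cues: list[str]
    kind: str = "triphone"  # letter_trigram | triphone | fbs_feature
    tuples: list[tuple[str, ...]] | None = None
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if not self.cues:
            raise LdlexError("CueInventory: empty cue inventory")
        if len(set(self.cues)) != len(self.cues):
            raise LdlexError("CueInventory: cues must be unique")
        self.index = {c: j for j, c in enumerate(self.cues)}

    def __len__(self) -> int:
        return len(self.cues)

    def __contains__(self, cue: str) -> bool:
        return cue in self.index


@dataclass
class CueMatrix:
    """Binary (or real, for predicted supports) word-by-cue matrix."""

    values: np.ndarray
    row_index: list[str]
    inventory: CueInventory

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.row_index), len(self.inventory)):
            raise LdlexError("CueMatrix: shape inconsistent with indices")

    def row(self, word_id: str) -> np.ndarray:
        return self.values[self.row_index.index(word_id)]


def cues_to_matrix(cue_lists, row_index=None, inventory: CueInventory | None = None,
                   kind: str = "triphone",
                   cue_tuples=None) -> CueMatrix:
    """Indicator matrix from per-item cue collections.

    Without an inventory, the cue order is first appearance across items
    (bit-reproducible). With a fixed inventory, out-of-inventory cues of
    held-out items are dropped and their count logged.
    """
    cue_lists = [list(cs) for cs in cue_lists]
    if row_index is None:
        row_index = [f"item{i}" for i in range(len(cue_lists))]
    if inventory is None:
        order: dict[str, None] = {}
        tup_for: dict[str, tuple[str, ...]] = {}
        for i, cs in enumerate(cue_lists):
            for j, c in enumerate(cs):
                order.setdefault(c, None)
                if cue_tuples is not None:
                    tup_for.setdefault(c, cue_tuples[i][j])
        if not order:
            raise LdlexError("cues_to_matrix: empty cue inventory")
        tuples = [tup_for[c] for c in order] if cue_tuples is not None else None
        inventory = CueInventory(list(order), kind=kind, tuples=tuples)
    if len(inventory) == 0:
        raise LdlexError("cues_to_matrix: empty cue inventory")
    values = np.zeros((len(cue_lists), len(inventory)), dtype=np.uint8)
    dropped = 0
    for i, cs in enumerate(cue_lists):
        for c in cs:
            j = inventory.index.get(c)
            if j is None:
                dropped += 1
            else:
                values[i, j] = 1
    if dropped:
        logger.info("cues_to_matrix: dropped %d out-of-inventory cue tokens", dropped)
    return CueMatrix(values, list(row_index), inventory)


def build_cue_matrix(forms, inventory: CueInventory | None = None,
                     row_index=None, kind: str = "triphone") -> CueMatrix:
    """Indicator matrix of 3-gram cues for a list of word forms."""
    forms = list(forms)
    if not forms:
        raise LdlexError("build_cue_matrix: forms must be non-empty")
    tuple_lists = []
    cue_lists = []
    for f in forms:
        seen: dict[str, tuple[str, ...]] = {}
        for t in triphone_tuples(f):
            seen.setdefault(cue_string(t), t)
        cue_lists.append(list(seen))
        tuple_lists.append(list(seen.values()))
    return cues_to_matrix(cue_lists, row_index=row_index, inventory=inventory,
                          kind=kind, cue_tuples=tuple_lists)


def _levenshtein_dp(a: tuple, b: tuple) -> int:
    # classic DP fallback for alphabets too large for the byte mapping
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def levenshtein(a, b) -> int:
    """Phone-level edit distance (unit insert/delete/substitute costs).

    Symbol sequences are mapped to a compact byte alphabet and dispatched
    to edlib; sequences over very large alphabets fall back to a DP.
    """
    a = tuple(a.phones) if isinstance(a, WordForm) else tuple(a)
    b = tuple(b.phones) if isinstance(b, WordForm) else tuple(b)
    if not a:
        return len(b)
    if not b:
        return len(a)
    alphabet = {s: i for i, s in enumerate(dict.fromkeys(a + b))}
    if _edlib is None or len(alphabet) > 200:
        return _levenshtein_dp(a, b)
    qa = "".join(chr(33 + alphabet[s]) for s in a)
    qb = "".join(chr(33 + alphabet[s]) for s in b)
    return int(_edlib.align(qa, qb, mode="NW", task="distance")["editDistance"])
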