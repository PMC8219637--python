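"""Lexical entries and word-list I/O.

A word entry ties together a surface form (phone sequence), the lexomes it
expresses (stem plus inflectional-function lexomes), and an optional
inflectional category label. Word lists round-trip through TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._utils import LdlexError
from .forms import WordForm, parse_transcription


@dataclass(frozen=True)
class WordEntry:
    id: str
    orthography: str
    form: WordForm
    lexomes: frozenset[str]
    inflection: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "lexomes", frozenset(self.lexomes))
        if not self.lexomes:
            raise LdlexError(f"WordEntry {self.id}: lexome set must be non-empty")


@dataclass
class Lexicon:
    """An ordered list of word entries (order fixes matrix row order)."""

    entries: list[WordEntry] = field(default_factory=list)

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    @property
    def forms(self) -> list[WordForm]:
        return [e.form for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [e.id for e in self.entries],
                "orthography": [e.orthography for e in self.entries],
                "transcription": [" ".join(e.form.phones) for e in self.entries],
                "lexomes": [",".join(sorted(e.lexomes)) for e in self.entries],
                "inflection": [e.inflection or "" for e in self.entries],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Lexicon":
        required = {"id", "orthography", "transcription", "lexomes"}
        missing = required - set(df.columns)
        if missing:
            raise LdlexError(f"Lexicon: missing columns {sorted(missing)}")
        entries = []
        for _, row in df.iterrows():
            tr = str(row["transcription"])
            phones = tuple(tr.split()) if " " in tr else tuple(tr)
            infl = row.get("inflection", "")
            infl = None if (pd.isna(infl) or infl == "") else str(infl)
            entries.append(
                WordEntry(
                    id=str(row["id"]),
                    orthography=str(row["orthography"]),
                    form=WordForm(phones),
                    lexomes=frozenset(str(row["lexomes"]).split(",")),
                    inflection=infl,
                )
            )
        return cls(entries)

    @classmethod
    def from_tsv(cls, path) -> "Lexicon":
        path = Path(path)
        if not path.exists():
            raise LdlexError(f"Lexicon.from_tsv: no such file: {path}")
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))


def forms_from_tsv(path) -> tuple[list[str], list[WordForm]]:
    """Read a two-column (id, transcription) TSV of bare forms."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "id" not in df.columns or "transcription" not in df.columns:
        raise LdlexError("forms_from_tsv: need columns id, transcription")
    ids, forms = [], []
    for _, row in df.iterrows():
        tr = str(row["transcription"])
        ids.append(str(row["id"]))
        forms.append(WordForm(tuple(tr.split()) if " " in tr else tuple(tr)))
    return ids, forms
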