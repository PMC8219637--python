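"""Model/Results facade over the discriminative-lexicon pipeline.

``LDLModel`` is built from a lexicon (word forms plus row-aligned gold
semantic vectors); ``fit()`` estimates the six linear networks and returns
an ``LDLResults`` object carrying the mappings, their training-set
reconstruction diagnostics, and the comprehension / production / measure
methods. The acoustic route is optional: with ``use_audio=True`` every
word gets a deterministic synthetic audio token whose FBS features form
the acoustic cue matrix; otherwise the comprehension networks are trained
on the orthographic trigram cues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import LdlexError, pearson
from .acoustics import extract_fbs
from .comprehension import RouteOutput, alc, ednn, nnc
from .forms import CueMatrix, WordForm, build_cue_matrix, cues_to_matrix, encode_triplets
from .lexicon import Lexicon
from .mappings import RCOND, MappingRegistry, train_lexicon_mappings
from .production import (MAX_PATHS, THINNING_THRESHOLD, ProductionResult,
                         attested_transitions, speak)
from .semantics import SemanticSpace
from .synthetic import SyntheticLexicon, label_inflection, make_phone_map, synth_audio

logger = logging.getLogger("ldlex")

#: CSV column order of the per-pseudoword measure table
MEASURE_COLUMNS = ["id", "ednn_1", "nnc_1", "alc_1", "ednn_2", "nnc_2", "alc_2",
                   "drc", "aldc", "scpp", "is_infl", "infl_category"]


def _derived_seed(seed: int, index: int) -> int:
    return int((seed * 1_000_003 + index) % (2 ** 31 - 1))


class LDLModel:
    """Discriminative lexicon model over a fixed training lexicon.

    Parameters
    ----------
    lexicon : Lexicon or SyntheticLexicon
        Training words; row order fixes all matrix row orders.
    S : array, optional
        Gold semantic vectors, one row per word (taken from a
        SyntheticLexicon automatically).
    use_audio : bool
        Train the comprehension networks on synthetic-audio FBS cues
        instead of orthographic trigram cues.
    seed : int
        Base seed for the deterministic per-word audio synthesis.
    """

    def __init__(self, lexicon, S=None, *, use_audio: bool = False,
                 sample_rate: int = 16000, seed: int = 0,
                 exponent_table: dict | None = None):
        if isinstance(lexicon, SyntheticLexicon):
            if S is None:
                S = lexicon.S
            if exponent_table is None:
                exponent_table = lexicon.exponent_table
            lexicon = lexicon.lexicon
        if not isinstance(lexicon, Lexicon):
            lexicon = Lexicon(list(lexicon))
        if S is None:
            raise LdlexError("LDLModel: semantic matrix S is required")
        S = np.atleast_2d(np.asarray(S, dtype=float))
        if S.shape[0] != len(lexicon):
            raise LdlexError("LDLModel: S rows misaligned with lexicon")
        self.lexicon = lexicon
        self.space = SemanticSpace(S, lexicon.ids)
        self.use_audio = use_audio
        self.sample_rate = sample_rate
        self.seed = seed
        self.exponent_table = exponent_table or {}

        forms = lexicon.forms
        self.C_o: CueMatrix = build_cue_matrix(forms, row_index=lexicon.ids,
                                               kind="letter_trigram")
        self.T_a: CueMatrix = build_cue_matrix(forms, row_index=lexicon.ids,
                                               kind="triphone")
        self.attested = attested_transitions(forms)
        self.phone_map = make_phone_map(
            {p for f in forms for p in f.phones})
        self.C_a: CueMatrix | None = None
        if use_audio:
            cue_sets = [sorted(self._word_fbs(i)) for i in range(len(lexicon))]
            self.C_a = cues_to_matrix(cue_sets, row_index=lexicon.ids,
                                      kind="fbs_feature")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, S, **kwargs) -> "LDLModel":
        """Build from a word-list DataFrame (id, orthography, transcription,
        lexomes[, inflection]) and a row-aligned semantic matrix."""
        return cls(Lexicon.from_frame(df), S, **kwargs)

    def _word_fbs(self, index: int) -> set[str]:
        form = self.lexicon[index].form
        audio = synth_audio(form, self.phone_map, self.sample_rate,
                            seed=_derived_seed(self.seed, index))
        return extract_fbs(audio)

    def _pseudoword_cues(self, forms, seed_offset: int = 500_000):
        if self.C_a is None:
            return build_cue_matrix(forms, inventory=self.C_o.inventory)
        cue_sets = []
        for i, form in enumerate(forms):
            audio = synth_audio(form, self.phone_map, self.sample_rate,
                                seed=_derived_seed(self.seed, seed_offset + i))
            cue_sets.append(sorted(extract_fbs(audio)))
        return cues_to_matrix(cue_sets, inventory=self.C_a.inventory,
                              kind="fbs_feature")

    def fit(self, rcond: float = RCOND) -> "LDLResults":
        """Estimate all six mappings by regularized least squares."""
        registry = train_lexicon_mappings(
            self.C_o.values, self.T_a.values, self.space.S,
            None if self.C_a is None else self.C_a.values, rcond=rcond)
        return LDLResults(self, registry)


@dataclass
class LDLResults:
    """Fitted mappings plus the derived comprehension/production methods."""

    model: LDLModel
    mappings: MappingRegistry
    diagnostics: pd.DataFrame = field(init=False)

    def __post_init__(self):
        self.diagnostics = self.mappings.diagnostics

    # ------------------------------------------------------------------ #
    def summary(self) -> str:
        m = self.model
        lines = [
            "Linear discriminative lexicon model",
            "=" * 51,
            f"words (readings):        {len(m.lexicon)}",
            f"semantic dimension:      {m.space.dim}",
            f"trigram cues:            {len(m.C_o.inventory)}",
            f"triphone cues:           {len(m.T_a.inventory)}",
            f"acoustic route:          "
            + (f"FBS ({len(m.C_a.inventory)} features)" if m.C_a is not None
               else "orthographic fallback"),
            "",
            "Training-set reconstruction (mean row correlation):",
            self.diagnostics.to_string(float_format=lambda x: f"{x:.4f}"),
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------ #
    def comprehend(self, forms, seed_offset: int = 500_000) -> RouteOutput:
        """Map held-out forms into semantic space via both routes."""
        cues = self.model._pseudoword_cues(forms, seed_offset)
        c = cues.values.astype(float)
        s1 = c @ self.mappings["F"].matrix
        s2 = c @ self.mappings["E"].matrix @ self.mappings["H_c"].matrix
        return RouteOutput(s1=s1, s2=s2)

    def produce(self, s_target, target_form: WordForm,
                threshold: float = THINNING_THRESHOLD,
                max_paths: int = MAX_PATHS,
                edges: str = "mergeable") -> ProductionResult:
        """Run the speak pipeline for one semantic vector."""
        return speak(s_target, self.mappings["G"], self.mappings["H_p"],
                     self.model.T_a.inventory, target_form,
                     threshold=threshold, max_paths=max_paths,
                     edges=edges, attested=self.model.attested)

    def produce_form(self, form: WordForm, **kwargs) -> ProductionResult:
        """Speak from the semantics that the form itself projects: the
        binary triphone vector is re-comprehended through H_p and the
        resulting vector drives production (the pseudoword pathway)."""
        s0 = self._form_semantics(form)
        return self.produce(s0, form, **kwargs)

    def _form_semantics(self, form: WordForm) -> np.ndarray:
        inv = self.model.T_a.inventory
        t = np.zeros(len(inv))
        for c in encode_triplets(form):
            j = inv.index.get(c)
            if j is not None:
                t[j] = 1.0
        return t @ self.mappings["H_p"].matrix

    def recover_training_forms(self, threshold: float = THINNING_THRESHOLD,
                               max_paths: int = MAX_PATHS) -> float:
        """Fraction of training words whose own gold semantic vector
        produces their own form as best candidate."""
        hits = 0
        for entry, s in zip(self.model.lexicon, self.model.space.S):
            res = self.produce(s, entry.form, threshold=threshold,
                               max_paths=max_paths)
            if res.best is not None and res.best.phones == entry.form.phones:
                hits += 1
        return hits / len(self.model.lexicon)

    # ------------------------------------------------------------------ #
    def measures(self, forms, ids=None, threshold: float = THINNING_THRESHOLD,
                 max_paths: int = MAX_PATHS, edges: str = "mergeable",
                 seed_offset: int = 500_000) -> pd.DataFrame:
        """Per-item measure table: EDNN/NNC/ALC per route, DRC, ALDC, SCPP,
        and the form-based inflection label."""
        forms = list(forms)
        if ids is None:
            ids = [f"pw{i:04d}" for i in range(len(forms))]
        routes = self.comprehend(forms, seed_offset)
        space = self.model.space
        rows = []
        for i, form in enumerate(forms):
            s1, s2 = routes.s1[i], routes.s2[i]
            s0 = self._form_semantics(form)
            prod = self.produce(s0, form, threshold=threshold,
                                max_paths=max_paths, edges=edges)
            labels = (label_inflection(form, self.model.exponent_table)
                      if self.model.exponent_table else ("uninflected",))
            rows.append({
                "id": ids[i],
                "ednn_1": ednn(s1, space), "nnc_1": nnc(s1, space),
                "alc_1": alc(s1, space),
                "ednn_2": ednn(s2, space), "nnc_2": nnc(s2, space),
                "alc_2": alc(s2, space),
                "drc": pearson(s1, s2),
                "aldc": prod.aldc, "scpp": prod.scpp,
                "is_infl": labels != ("uninflected",),
                "infl_category": ";".join(labels),
            })
        return pd.DataFrame(rows, columns=MEASURE_COLUMNS)

    def word_measures(self, **kwargs) -> pd.DataFrame:
        """The same measure table for the training words themselves."""
        return self.measures(self.model.lexicon.forms,
                             ids=self.model.lexicon.ids, seed_offset=0,
                             **kwargs)

    # ------------------------------------------------------------------ #
    def plot_measures(self, table: pd.DataFrame, path=None):
        """Histogram grid of the numeric measure columns."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        cols = [c for c in MEASURE_COLUMNS
                if c in table.columns and table[c].dtype.kind == "f"]
        fig, axes = plt.subplots(3, 3, figsize=(9, 7))
        for ax, col in zip(axes.ravel(), cols):
            ax.hist(table[col].dropna(), bins=20, color="steelblue")
            ax.set_title(col, fontsize=9)
        for ax in axes.ravel()[len(cols):]:
            ax.set_axis_off()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=100)
            plt.close(fig)
        return fig
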