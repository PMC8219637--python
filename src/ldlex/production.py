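"""The speak algorithm: semantics -> triphone support -> candidate forms.

A semantic vector is first mapped by the production network G onto a
real-valued support vector over the triphone inventory. Triphones with
support at or above the thinning threshold (default 0.1) become vertices
of a directed graph; a directed edge joins u -> v whenever the last two
symbols of u equal the first two of v (the triphones are mergeable), so
candidate word forms are exactly the simple paths from an initial triphone
(#xx) to a final triphone (xx#). Each path merges deterministically into a
phone sequence, and synthesis-by-analysis re-comprehends each candidate's
binary triphone vector through H_p and selects the candidate whose
predicted semantics correlates best with the intended semantics.

Two production measures are derived: ALDC, the mean phone-level edit
distance of all candidates from the target pronunciation (the target's
phone count when no candidates are produced), and SCPP, the maximum
correlation between the intended semantic vector and any candidate's
re-comprehended semantic vector (0 when no candidates are produced).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._utils import LdlexError, pearson
from .forms import CueInventory, WordForm, cue_string, levenshtein, triphone_tuples
from .mappings import LinearMapping, apply_mapping

logger = logging.getLogger("ldlex")

#: default semantic-support thinning threshold
THINNING_THRESHOLD = 0.1
#: default cap on enumerated simple paths
MAX_PATHS = 10_000


def predict_triphone_support(s, G: LinearMapping) -> np.ndarray:
    """Support for every triphone in the inventory: t̂ = s G."""
    return apply_mapping(s, G)


def attested_transitions(forms) -> set[tuple[str, str]]:
    """Triphone-to-triphone transitions observed in training forms."""
    seen: set[tuple[str, str]] = set()
    for f in forms:
        tups = triphone_tuples(f)
        for u, v in zip(tups, tups[1:]):
            seen.add((cue_string(u), cue_string(v)))
    return seen


@dataclass
class TriphoneGraph:
    graph: nx.DiGraph
    supports: dict[str, float]
    tuples: dict[str, tuple[str, ...]]
    initial: list[str]
    final: list[str]
    boundary: str = "#"


def build_triphone_graph(supports, inventory: CueInventory,
                         threshold: float = THINNING_THRESHOLD,
                         edges: str = "mergeable",
                         attested: set[tuple[str, str]] | None = None,
                         boundary: str = "#") -> TriphoneGraph:
    """Thin the triphone inventory by semantic support and wire up edges.

    Vertices are triphones with positive support >= threshold. Edges join
    every mergeable retained pair; with ``edges="attested"`` they are
    further restricted to transitions seen in the training forms.
    """
    supports = np.asarray(supports, dtype=float).ravel()
    if supports.shape[0] != len(inventory):
        raise LdlexError("build_triphone_graph: supports misaligned with inventory")
    if inventory.tuples is None:
        raise LdlexError("build_triphone_graph: inventory lacks symbol tuples")
    if edges not in {"mergeable", "attested"}:
        raise LdlexError(f"build_triphone_graph: unknown edge mode {edges!r}")
    if edges == "attested" and attested is None:
        raise LdlexError("build_triphone_graph: attested edge mode needs transitions")
    keep = [(c, t, float(s)) for c, t, s in
            zip(inventory.cues, inventory.tuples, supports)
            if s > 0 and s >= threshold]
    g = nx.DiGraph()
    tuples = {c: t for c, t, _ in keep}
    sup = {c: s for c, _, s in keep}
    g.add_nodes_from(tuples)
    for u, tu in tuples.items():
        for v, tv in tuples.items():
            if tu[-2:] == tv[:2] and u != v:
                if edges == "attested" and (u, v) not in attested:
                    continue
                g.add_edge(u, v)
    initial = [c for c, t in tuples.items() if t[0] == boundary]
    final = [c for c, t in tuples.items() if t[-1] == boundary]
    return TriphoneGraph(g, sup, tuples, initial, final, boundary)


@dataclass
class CandidatePath:
    """A path through the triphone graph and its merged phone sequence."""

    triphones: tuple[str, ...]
    phones: tuple[str, ...]
    semantic_vector: np.ndarray | None = None
    correlation_with_target: float | None = None


def merge_path(tuples: list[tuple[str, ...]], boundary: str = "#") -> tuple[str, ...]:
    """Merge overlapping triphones into the phone sequence they spell."""
    symbols = list(tuples[0])
    for t in tuples[1:]:
        if tuple(symbols[-2:]) != t[:2]:
            raise LdlexError(f"merge_path: {symbols[-2:]} does not overlap {t[:2]}")
        symbols.append(t[-1])
    return tuple(s for s in symbols if s != boundary)


def enumerate_candidates(graph: TriphoneGraph,
                         max_paths: int = MAX_PATHS) -> list[CandidatePath]:
    """All simple initial-to-final paths, merged and sorted by phone string.

    Enumeration is truncated (with a logged warning) at ``max_paths``.
    A triphone of the shape #x# is a one-vertex path in its own right.
    """
    found: dict[tuple[str, ...], CandidatePath] = {}
    truncated = False
    count = 0

    def _add(node_path: list[str]) -> bool:
        nonlocal count
        if count >= max_paths:
            return False
        tri = tuple(node_path)
        if tri not in found:
            phones = merge_path([graph.tuples[c] for c in node_path], graph.boundary)
            found[tri] = CandidatePath(tri, phones)
            count += 1
        return True

    for src in sorted(graph.initial):
        if src in graph.final:  # degenerate #x# path
            if not _add([src]):
                truncated = True
                break
        for dst in sorted(graph.final):
            if src == dst:
                continue
            for path in nx.all_simple_paths(graph.graph, src, dst):
                if not _add(path):
                    truncated = True
                    break
            if truncated:
                break
        if truncated:
            break
    if truncated:
        logger.warning("enumerate_candidates: truncated at %d paths", max_paths)
    return sorted(found.values(), key=lambda c: (c.phones, c.triphones))


def path_cue_vector(candidate: CandidatePath, inventory: CueInventory) -> np.ndarray:
    """Binary triphone vector of a candidate, projected onto the inventory."""
    v = np.zeros(len(inventory))
    for c in candidate.triphones:
        j = inventory.index.get(c)
        if j is not None:
            v[j] = 1.0
    return v


def synthesis_by_analysis(candidates, H_p: LinearMapping, s_target,
                          inventory: CueInventory):
    """Re-comprehend each candidate and pick the semantically best one.

    Each candidate's binary triphone vector is mapped through H_p; the
    Pearson correlation with the intended semantic vector is attached.
    Best = highest correlation, ties broken by fewer phones, then by
    lexicographic phone order. Empty input yields (empty list, None).
    """
    candidates = list(candidates)
    s_target = np.asarray(s_target, dtype=float).ravel()
    for cand in candidates:
        cand.semantic_vector = apply_mapping(path_cue_vector(cand, inventory), H_p)
        cand.correlation_with_target = pearson(cand.semantic_vector, s_target)
    if not candidates:
        return [], None
    best = min(candidates,
               key=lambda c: (-c.correlation_with_target, len(c.phones), c.phones))
    return candidates, best


def aldc(candidates, target: WordForm) -> float:
    """Average Levenshtein distance of candidates from the target form.

    With no candidates the measure equals the target's phone count.
    """
    candidates = list(candidates)
    if not candidates:
        return float(len(target.phones))
    dists = [levenshtein(c.phones, target.phones) for c in candidates]
    return float(np.mean(dists))


def scpp(s_target, candidate_semantics) -> float:
    """Maximum correlation of the intended semantics with any candidate's
    re-comprehended semantics; 0 for an empty candidate set."""
    vecs = list(candidate_semantics)
    if not vecs:
        return 0.0
    return float(max(pearson(s_target, v) for v in vecs))


@dataclass
class ProductionResult:
    target_form: WordForm
    candidates: list[CandidatePath] = field(default_factory=list)
    best: CandidatePath | None = None
    aldc: float = 0.0
    scpp: float = 0.0


def speak(s_target, G: LinearMapping, H_p: LinearMapping,
          inventory: CueInventory, target_form: WordForm,
          threshold: float = THINNING_THRESHOLD, max_paths: int = MAX_PATHS,
          edges: str = "mergeable",
          attested: set[tuple[str, str]] | None = None) -> ProductionResult:
    """Full production pipeline for one semantic vector."""
    supports = predict_triphone_support(s_target, G)
    graph = build_triphone_graph(supports, inventory, threshold=threshold,
                                 edges=edges, attested=attested)
    candidates = enumerate_candidates(graph, max_paths=max_paths)
    candidates, best = synthesis_by_analysis(candidates, H_p, s_target, inventory)
    return ProductionResult(
        target_form=target_form,
        candidates=candidates,
        best=best,
        aldc=aldc(candidates, target_form),
        scpp=scpp(s_target, [c.semantic_vector for c in candidates]),
    )
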