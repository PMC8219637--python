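"""Artifact persistence: cue matrices (MTX + inventory), mapping archives
(TSV + manifest with inventory hashes), semantic spaces, measure tables.

All formats are plain text and round-trip exactly; the manifest's
inventory hashes guard against silently applying a mapping to cue vectors
built from a different inventory.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from ._utils import LdlexError
from .forms import CueInventory, CueMatrix
from .mappings import LinearMapping, MappingRegistry
from .semantics import SemanticSpace

CSV_FLOAT = "%.10g"  # measure tables: 10 significant digits


def inventory_hash(inventory: CueInventory) -> str:
    payload = inventory.kind + "\n" + "\n".join(inventory.cues)
    return hashlib.sha1(payload.encode("utf-8")).hexdigest()


def save_cue_matrix(matrix: CueMatrix, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mmwrite(str(prefix) + ".mtx", sparse.coo_matrix(matrix.values))
    inv_lines = [f"#kind={matrix.inventory.kind}"] + list(matrix.inventory.cues)
    (prefix.parent / (prefix.name + ".cues.txt")).write_text(
        "\n".join(inv_lines) + "\n", encoding="utf-8")
    (prefix.parent / (prefix.name + ".rows.txt")).write_text(
        "\n".join(matrix.row_index) + "\n", encoding="utf-8")


def load_cue_matrix(prefix) -> CueMatrix:
    prefix = Path(prefix)
    mtx = Path(str(prefix) + ".mtx")
    if not mtx.exists():
        raise LdlexError(f"load_cue_matrix: missing {mtx}")
    values = np.asarray(mmread(str(mtx)).todense())
    inv_lines = (prefix.parent / (prefix.name + ".cues.txt")).read_text(
        encoding="utf-8").splitlines()
    kind = "triphone"
    if inv_lines and inv_lines[0].startswith("#kind="):
        kind = inv_lines[0].split("=", 1)[1]
        inv_lines = inv_lines[1:]
    rows = (prefix.parent / (prefix.name + ".rows.txt")).read_text(
        encoding="utf-8").splitlines()
    return CueMatrix(values.astype(np.uint8), rows, CueInventory(inv_lines, kind))


def save_mappings(registry: MappingRegistry, directory,
                  hashes: dict[str, str] | None = None) -> None:
    """Archive mappings as dense TSVs plus a JSON manifest.

    ``hashes`` maps vector-system kind -> inventory hash and is embedded
    so that a later load can verify cue alignment.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"hashes": hashes or {}, "mappings": {}}
    for name, M in registry.items():
        fname = name.replace("/", "_") + ".tsv"
        np.savetxt(directory / fname, M.matrix, delimiter="\t", fmt="%.17g")
        manifest["mappings"][name] = {
            "file": fname, "shape": list(M.matrix.shape),
            "source_kind": M.source_kind, "target_kind": M.target_kind,
        }
    if registry.diagnostics is not None:
        registry.diagnostics.to_csv(directory / "diagnostics.csv",
                                    float_format=CSV_FLOAT)
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")


def load_mappings(directory,
                  expect_hashes: dict[str, str] | None = None) -> MappingRegistry:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise LdlexError(f"load_mappings: missing manifest in {directory}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    if expect_hashes:
        stored = manifest.get("hashes", {})
        for kind, h in expect_hashes.items():
            if kind in stored and stored[kind] != h:
                raise LdlexError(
                    f"load_mappings: inventory hash mismatch for {kind!r} "
                    "(cue matrix and mapping archive are misaligned)")
    reg = MappingRegistry()
    for name, meta in manifest["mappings"].items():
        matrix = np.loadtxt(directory / meta["file"], delimiter="\t", ndmin=2)
        reg[name] = LinearMapping(name, matrix, meta["source_kind"],
                                  meta["target_kind"])
    diag = directory / "diagnostics.csv"
    if diag.exists():
        reg.diagnostics = pd.read_csv(diag, index_col=0)
    return reg


def save_semantic_space(space: SemanticSpace, path) -> None:
    df = pd.DataFrame(space.S, index=space.word_index)
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def load_semantic_space(path) -> SemanticSpace:
    path = Path(path)
    if not path.exists():
        raise LdlexError(f"load_semantic_space: no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col="id",
                     float_precision="round_trip")
    return SemanticSpace(df.to_numpy(dtype=float), [str(i) for i in df.index])


def save_measures(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=CSV_FLOAT)


def load_measures(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_corpus(events, path) -> None:
    Path(path).write_text(
        "\n".join(" ".join(ev) for ev in events) + "\n", encoding="utf-8")
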