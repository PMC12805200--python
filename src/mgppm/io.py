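"""File formats: design YAML, delimited parameter/response tables, recoders.

All tabular I/O is delimited text with headers.  Trait indices are 1-based
in files (converted to 0-based in memory); response codes are 1-based
everywhere, matching the canonical pattern enumeration.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .blocks import Block, InvalidResponseError, Statement
from .params import ParameterSet

__all__ = [
    "write_design",
    "read_design",
    "write_parameters",
    "read_parameters",
    "write_responses",
    "read_responses",
    "rank_to_pick",
    "rank_to_mole",
    "write_manifest",
]


# ----------------------------------------------------------------------
# design files
# ----------------------------------------------------------------------

def write_design(path: str | Path, blocks: list[Block]) -> None:
    """Serialize a block design to YAML (traits 1-based)."""
    doc = {"blocks": []}
    for b in blocks:
        entry = {
            "block_id": b.block_id,
            "format": b.fmt,
            "statements": [
                {"trait": int(s.trait) + 1, "keyed_sign": int(s.keyed_sign)}
                for s in b.statements
            ],
        }
        if b.n_categories is not None:
            entry["n_categories"] = int(b.n_categories)
        if b.variant != "primary":
            entry["variant"] = b.variant
        doc["blocks"].append(entry)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_design(path: str | Path) -> list[Block]:
    doc = yaml.safe_load(Path(path).read_text())
    blocks = []
    for entry in doc["blocks"]:
        stmts = [
            Statement(
                statement_id=k + 1,
                trait=int(s["trait"]) - 1,
                slope=float(s.get("keyed_sign", 1)),
            )
            for k, s in enumerate(entry["statements"])
        ]
        blocks.append(Block(
            block_id=entry["block_id"],
            statements=stmts,
            fmt=entry.get("format", "RANK"),
            n_categories=entry.get("n_categories"),
            variant=entry.get("variant", "primary"),
        ))
    return blocks


# ----------------------------------------------------------------------
# parameter tables
# ----------------------------------------------------------------------

def write_parameters(prefix: str | Path, blocks: list[Block],
                     params: ParameterSet) -> None:
    """Write item parameters and correlations as ``<prefix>_items.csv`` /
    ``<prefix>_corr.csv``."""
    prefix = Path(prefix)
    rows = []
    for j, b in enumerate(blocks):
        for k in range(b.size):
            rows.append({
                "block_id": b.block_id, "statement": k + 1,
                "trait": int(b.traits[k]) + 1,
                "slope": params.slopes[j][k],
                "intercept": params.intercepts[j][k],
            })
    pd.DataFrame(rows).to_csv(prefix.with_name(prefix.name + "_items.csv"), index=False)
    pd.DataFrame(params.R).to_csv(prefix.with_name(prefix.name + "_corr.csv"), index=False)


def read_parameters(prefix: str | Path, blocks: list[Block]) -> ParameterSet:
    prefix = Path(prefix)
    items = pd.read_csv(prefix.with_name(prefix.name + "_items.csv"))
    R = pd.read_csv(prefix.with_name(prefix.name + "_corr.csv")).to_numpy(dtype=float)
    slopes, intercepts = [], []
    for b in blocks:
        sub = items[items["block_id"] == b.block_id].sort_values("statement")
        if len(sub) != b.size:
            raise ValueError(f"parameter file misses statements of block {b.block_id}")
        slopes.append(sub["slope"].to_numpy(dtype=float))
        intercepts.append(sub["intercept"].to_numpy(dtype=float))
    return ParameterSet(slopes, intercepts, R)


# ----------------------------------------------------------------------
# response matrices
# ----------------------------------------------------------------------

def write_responses(path: str | Path, responses: np.ndarray,
                    blocks: list[Block]) -> None:
    cols = [f"block_{b.block_id}" for b in blocks]
    pd.DataFrame(np.asarray(responses, dtype=int), columns=cols).to_csv(path, index=False)


def read_responses(path: str | Path, blocks: list[Block]) -> np.ndarray:
    """Read and validate a response matrix against a design.

    Every code must fall in the block's legal response space (``1..B!`` for
    RANK, statement ids for PICK, legal most/least pairs for MOLE, legal
    no-tie rating vectors for HFCL).  Violations raise
    :class:`InvalidResponseError` naming the row and block.
    """
    df = pd.read_csv(path)
    if len(df.columns) != len(blocks):
        raise InvalidResponseError(
            f"{path}: {len(df.columns)} columns for {len(blocks)} blocks"
        )
    out = df.to_numpy()
    if not np.issubdtype(out.dtype, np.integer):
        try:
            out = out.astype(int)
            if not np.array_equal(out, df.to_numpy(dtype=float)):
                raise ValueError
        except (ValueError, TypeError):
            raise InvalidResponseError(f"{path}: non-integer response codes")
    for j, b in enumerate(blocks):
        lo, hi = 1, b.n_responses
        bad = np.flatnonzero((out[:, j] < lo) | (out[:, j] > hi))
        if bad.size:
            raise InvalidResponseError(
                f"{path}: row {bad[0] + 1}, block {b.block_id}: "
                f"code {out[bad[0], j]} outside 1..{hi}"
            )
    return out


# ----------------------------------------------------------------------
# format recoders
# ----------------------------------------------------------------------

def rank_to_pick(responses: np.ndarray, blocks: list[Block]
                 ) -> tuple[np.ndarray, list[Block]]:
    """Project RANK responses to PICK (the rank-1 statement).

    Returns the recoded matrix and blocks re-labelled with the PICK format;
    recoded data carry exactly the information of rankings with all ranks
    below the first planned-missing.
    """
    out = np.empty_like(np.asarray(responses, dtype=int))
    new_blocks = []
    for j, b in enumerate(blocks):
        if b.fmt != "RANK":
            raise InvalidResponseError(f"block {b.block_id} is not RANK format")
        pats = b.patterns
        out[:, j] = [pats[c - 1][0] for c in responses[:, j]]
        new_blocks.append(Block(b.block_id, b.statements, fmt="PICK"))
    return out, new_blocks


def rank_to_mole(responses: np.ndarray, blocks: list[Block]
                 ) -> tuple[np.ndarray, list[Block]]:
    """Project RANK responses to MOLE (rank-1 and rank-B statements)."""
    out = np.empty_like(np.asarray(responses, dtype=int))
    new_blocks = []
    for j, b in enumerate(blocks):
        if b.fmt != "RANK":
            raise InvalidResponseError(f"block {b.block_id} is not RANK format")
        nb = Block(b.block_id, b.statements, fmt="MOLE")
        labels = {lab: i + 1 for i, lab in enumerate(nb.response_labels)}
        pats = b.patterns
        out[:, j] = [labels[(pats[c - 1][0], pats[c - 1][-1])] for c in responses[:, j]]
        new_blocks.append(nb)
    return out, new_blocks


# ----------------------------------------------------------------------
# provenance
# ----------------------------------------------------------------------

def write_manifest(out_dir: str | Path, config: dict,
                   inputs: dict[str, str | Path] | None = None) -> None:
    """Record config, seed, versions, and input hashes alongside outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {},
    }
    from . import __version__
    manifest["versions"]["mgppm"] = __version__
    for name, p in (inputs or {}).items():
        h = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
        manifest["inputs"][name] = {"path": str(p), "sha256_16": h}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
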