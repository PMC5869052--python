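"""Checkpoint save/restore with scope renaming.

A checkpoint is a directory holding the parameter archive (``params.npz``,
keys are full scope paths), the fully resolved configuration
(``config.ini``) and a small ``meta.json`` with the step number.  Restoring
supports a ``scope_renames`` map so that a block trained under one scope
("net/dfs1") can initialize a differently named block of identical shapes
("net2/encoder") — the mechanism behind transplanting conceptual blocks
between networks.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np

from .layers import Module


class CheckpointError(RuntimeError):
    pass


def save_checkpoint(
    module: Module, step: int, config_text: str, directory: str | Path
) -> Path:
    """Write parameters + resolved config + step metadata to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {name: var.data for name, var in module.params.items()}
    np.savez(directory / "params.npz", **arrays)
    (directory / "config.ini").write_text(config_text, encoding="utf-8")
    (directory / "meta.json").write_text(
        json.dumps({"step": int(step), "n_params": len(arrays)}), encoding="utf-8"
    )
    return directory


def load_checkpoint(directory: str | Path) -> tuple[dict[str, np.ndarray], int, str]:
    """Read back (parameter map, step, resolved config text)."""
    directory = Path(directory)
    npz = directory / "params.npz"
    if not npz.exists():
        raise CheckpointError(f"no checkpoint at {directory}")
    with np.load(npz) as data:
        params = {k: data[k].copy() for k in data.files}
    meta = json.loads((directory / "meta.json").read_text(encoding="utf-8"))
    config_text = (directory / "config.ini").read_text(encoding="utf-8")
    return params, int(meta["step"]), config_text


def restore_checkpoint(
    directory: str | Path,
    module: Module,
    scope_renames: Mapping[str, str] | None = None,
    subset: bool = False,
) -> int:
    """Assign stored parameters into ``module`` (already built).

    ``scope_renames`` maps *stored* scope prefixes to *target* prefixes.
    With ``subset=True`` only the renamed scopes are restored (block
    transplant); otherwise every target parameter must resolve.
    Returns the stored step number.
    """
    stored, step, _ = load_checkpoint(directory)
    renames = dict(scope_renames or {})

    # apply renames to the stored keys
    renamed: dict[str, np.ndarray] = {}
    for key, arr in stored.items():
        new_key = key
        for old, new in renames.items():
            if key == old or key.startswith(old + "/"):
                new_key = new + key[len(old):]
                break
        renamed[new_key] = arr

    targets = module.params
    if subset:
        wanted_prefixes = tuple(renames.values())
        names = [
            n for n in targets
            if any(n == p or n.startswith(p + "/") for p in wanted_prefixes)
        ]
    else:
        names = list(targets)

    missing = [n for n in names if n not in renamed]
    if missing:
        raise CheckpointError(f"unmatched scopes on restore: {missing[:5]}")
    for name in names:
        src = renamed[name]
        dst = targets[name]
        if src.shape != dst.data.shape:
            raise CheckpointError(
                f"shape mismatch for {name!r}: stored {src.shape}, "
                f"target {dst.data.shape}"
            )
        dst.data = src.astype(dst.data.dtype).copy()
    return step
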