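"""Deterministic tabular output, provenance blocks, and RNG substreams."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, resolved_dict

__all__ = ["write_table", "seed_streams", "write_provenance"]


def _as_records(records: Iterable[Any]) -> list[dict[str, Any]]:
    out = []
    for rec in records:
        if is_dataclass(rec) and not isinstance(rec, type):
            out.append(asdict(rec))
        elif isinstance(rec, Mapping):
            out.append(dict(rec))
        else:
            raise TypeError(f"cannot tabulate record of type {type(rec).__name__}")
    return out


def write_table(records: Iterable[Any], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write records (dicts or dataclasses) as a TSV with full float precision.

    Row order follows the input; identical inputs give byte-identical
    files.  An empty record list writes a header-only file (``columns``
    must then be given).
    """
    rows = _as_records(records)
    if rows:
        df = pd.DataFrame(rows, columns=columns)
    else:
        if columns is None:
            raise ValueError("columns are required to write an empty table")
        df = pd.DataFrame(columns=list(columns))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # Default float formatting is shortest round-trip repr: full precision
    # and stable byte-for-byte across runs.
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def seed_streams(master_seed: int, n_streams: int) -> list[np.random.Generator]:
    """Spawn ``n_streams`` independent, reproducible generators from one seed."""
    if n_streams < 1:
        raise ValueError("n_streams must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    return [np.random.default_rng(child) for child in ss.spawn(n_streams)]


def write_provenance(config: RunConfig, out_dir: str | Path, command: str) -> Path:
    """Write the resolved config, seed and version next to the outputs.

    Keys that came from the named scenario preset are listed separately
    from package defaults, so scenario settings and artifact choices are
    never conflated.
    """
    resolved = resolved_dict(config)
    all_keys = []
    for key, value in resolved.items():
        if isinstance(value, dict):
            all_keys.extend(f"{key}.{k}" for k in value)
        else:
            all_keys.append(key)
    preset_keys = set(config.preset_keys)
    block = {
        "command": command,
        "version": __version__,
        "seed": config.seed,
        "scenario": config.scenario,
        "config": resolved,
        "from_preset": sorted(preset_keys & set(all_keys)),
        "artifact_defaults": sorted(
            k for k in all_keys if k not in preset_keys and k not in ("seed", "scenario", "output_dir")
        ),
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(block, indent=2, sort_keys=True) + "\n")
    return path
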