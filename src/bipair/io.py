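"""Shared readers/writers and run manifests.

All interval files on disk are BED-style 0-based half-open; tables are TSV
with a header.  Every CLI run writes a JSON manifest recording the command,
configuration snapshot, input checksums, seed and package version so that
deterministic commands can be re-run byte-identically.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import os
from typing import Mapping

import pandas as pd

from . import __version__

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str) -> pd.DataFrame:
    """Read BED3-BED6 into a DataFrame (half-open coordinates pass through)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append(parts[:6] + [None] * (6 - len(parts[:6])))
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based half-open\n")
        df[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path: str, note: str = "") -> None:
    with open(path, "w") as fh:
        if note:
            fh.write(f"# {note}\n")
        df.to_csv(fh, sep="\t", index=False)


def file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from (master seed, stage name)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def write_manifest(out_dir: str, command: str, config: Mapping,
                   inputs: Mapping[str, str], seed: int | None = None,
                   status: str = "ok") -> str:
    manifest = {
        "command": command,
        "config": dict(config),
        "inputs": {name: file_checksum(p) if os.path.exists(p) else None
                   for name, p in inputs.items()},
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "status": status,
    }
    path = os.path.join(out_dir, f"manifest_{command}.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
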