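"""Tab-delimited table I/O with ``#``-prefixed metadata header lines.

Floats are written with 17 significant digits so that a write→read round
trip reproduces float64 values exactly — staged and integrated pipeline
runs therefore produce byte-identical downstream outputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd

__all__ = ["write_tsv", "read_tsv"]

FLOAT_FORMAT = "%.17g"


def write_tsv(df: pd.DataFrame, path, metadata: Optional[Dict[str, object]] = None, index: bool = True) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key in metadata or {}:
            fh.write(f"# {key}={metadata[key]}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT, index=index)


def read_tsv(path, index_col=0) -> Tuple[pd.DataFrame, Dict[str, str]]:
    path = Path(path)
    metadata: Dict[str, str] = {}
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                metadata[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=index_col)
    return df, metadata
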