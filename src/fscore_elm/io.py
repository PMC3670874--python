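"""Plain-text readers/writers for epochs, feature tables and run artifacts.

Epoch files are tab-delimited: two comment lines carrying the sampling
metadata (``#fs=500.0``, ``#t0=-0.2``) followed by a header row
``subject_id  label  s0 … s{N−1}`` and one row per response.  Feature tables
are ordinary CSV with a ``subject_id,label,V_max,…,W_22`` header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ErpResponse

__all__ = [
    "EpochFormatError",
    "write_epochs",
    "read_epochs",
    "write_feature_table",
    "read_feature_table",
    "write_json",
    "read_json",
]


class EpochFormatError(ValueError):
    """Malformed epoch file: ragged rows, missing metadata or columns."""


def write_epochs(responses: list[ErpResponse], path) -> None:
    if not responses:
        raise ValueError("cannot write an empty dataset")
    n = responses[0].samples.size
    fs, t0 = responses[0].fs, responses[0].t0
    for r in responses:
        if r.samples.size != n:
            raise EpochFormatError(
                f"inhomogeneous sample length: {r.samples.size} != {n}"
            )
    path = Path(path)
    cols = "\t".join(f"s{i}" for i in range(n))
    with path.open("w") as fh:
        fh.write(f"#fs={float(fs):.17g}\n#t0={float(t0):.17g}\n")
        fh.write(f"subject_id\tlabel\t{cols}\n")
        for r in responses:
            vals = "\t".join(f"{v:.17g}" for v in r.samples)
            fh.write(f"{r.subject_id}\t{r.label}\t{vals}\n")


def read_epochs(path) -> list[ErpResponse]:
    path = Path(path)
    with path.open() as fh:
        meta = {}
        for _ in range(2):
            line = fh.readline().strip()
            if not line.startswith("#") or "=" not in line:
                raise EpochFormatError(f"missing metadata header in {path}")
            key, val = line[1:].split("=", 1)
            meta[key] = float(val)
        if "fs" not in meta or "t0" not in meta:
            raise EpochFormatError(f"epoch file must declare fs and t0: {path}")
        try:
            df = pd.read_csv(fh, sep="\t", header=0)
        except pd.errors.ParserError as exc:  # ragged rows with extra fields
            raise EpochFormatError(f"ragged rows in {path}: {exc}") from None
    if "subject_id" not in df.columns or "label" not in df.columns:
        raise EpochFormatError(f"missing subject_id/label column in {path}")
    sample_cols = [c for c in df.columns if c not in ("subject_id", "label")]
    values = df[sample_cols].to_numpy(dtype=float)
    if values.size and np.isnan(values).any():
        raise EpochFormatError(f"ragged or non-numeric rows in {path}")
    return [
        ErpResponse(values[i], meta["t0"], meta["fs"], str(df["subject_id"].iloc[i]), int(df["label"].iloc[i]))
        for i in range(len(df))
    ]


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "label" not in df.columns:
        raise EpochFormatError(f"feature table missing subject_id/label: {path}")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
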