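"""Plain-text serialization for feature matrices, masks, and traces.

Feature matrices travel as delimited text (comma for .csv, tab otherwise):
a header row of feature names, one row per sample, final column ``label``.
Files may begin with ``#`` provenance comment lines (seed, config hash),
which readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cuckoo import OptimizationTrace
from .selection import BinaryMask

LABEL_COLUMN = "label"


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def config_digest(config) -> str:
    """Short stable hash of a dataclass-like config, for provenance lines."""
    try:
        payload = json.dumps(vars(config), sort_keys=True, default=str)
    except TypeError:
        payload = repr(config)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_lines(seed=None, config=None, **extra) -> list[str]:
    fields = {"seed": seed}
    if config is not None:
        fields["config_sha"] = config_digest(config)
    fields.update(extra)
    return [f"# {k}={v}" for k, v in fields.items() if v is not None]


def _write_with_header(frame: pd.DataFrame, path: Path, header: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        frame.to_csv(fh, sep=_sep(path), index=False)


def save_feature_matrix(
    path,
    features: np.ndarray,
    labels: np.ndarray,
    column_names: list[str] | None = None,
    header: list[str] | None = None,
) -> None:
    path = Path(path)
    features = np.asarray(features)
    if column_names is None:
        column_names = [f"f{j}" for j in range(features.shape[1])]
    frame = pd.DataFrame(features, columns=column_names)
    frame[LABEL_COLUMN] = np.asarray(labels)
    _write_with_header(frame, path, header or [])


def load_feature_matrix(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a delimited matrix; returns (features, labels, feature_names)."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep(path), comment="#")
    if LABEL_COLUMN not in frame.columns:
        raise ValueError(f"{path}: missing required final column {LABEL_COLUMN!r}")
    labels = frame.pop(LABEL_COLUMN).to_numpy()
    return frame.to_numpy(dtype=float), labels, list(frame.columns)


def save_mask(path, mask: BinaryMask, column_names: list[str] | None = None,
              header: list[str] | None = None) -> None:
    """Write the 0/1 vector plus the selected feature names."""
    path = Path(path)
    if column_names is None:
        column_names = [f"f{j}" for j in range(mask.dim)]
    frame = pd.DataFrame(
        {"feature": column_names, "selected": mask.mask.astype(int)}
    )
    _write_with_header(frame, path, header or [])


def load_mask(path) -> BinaryMask:
    frame = pd.read_csv(Path(path), sep=_sep(Path(path)), comment="#")
    return BinaryMask(frame["selected"].to_numpy())


def save_trace(path, trace: OptimizationTrace, header: list[str] | None = None) -> None:
    _write_with_header(trace.to_frame(), Path(path), header or [])


def load_trace_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep=_sep(Path(path)), comment="#")
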