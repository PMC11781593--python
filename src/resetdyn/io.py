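"""Plain-text interchange: COLVAR-style series, configs, ensemble tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import FPTEnsemble

__all__ = [
    "read_colvar",
    "write_colvar",
    "read_config",
    "ensemble_to_csv",
    "ensemble_from_csv",
]


def read_colvar(path):
    """Read a whitespace-delimited (time, cv) series; '#' lines are comments.

    Files with more than two columns keep the first two, matching the usual
    enhanced-sampling COLVAR layout of time followed by the CV.
    """
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns (time, cv)")
    return data[:, 0], data[:, 1]


def write_colvar(path, times, values, header: str = "time cv"):
    arr = np.column_stack([np.asarray(times), np.asarray(values)])
    np.savetxt(path, arr, header=header, fmt="%.8g")


def read_config(path) -> dict:
    """Read a config as JSON or as key=value lines (numbers parsed)."""
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return json.loads(text)
    out = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        try:
            out[key] = int(value)
        except ValueError:
            try:
                out[key] = float(value)
            except ValueError:
                out[key] = value
    return out


def ensemble_to_csv(ensemble: FPTEnsemble, path):
    ensemble.to_dataframe().to_csv(path, index=False)


def ensemble_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
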