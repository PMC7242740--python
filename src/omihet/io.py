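"""Reading and writing the pipeline's on-disk formats.

Decay stacks travel as multi-page TIFF (one page per time bin, 16-bit
unsigned) with a JSON sidecar carrying the time calibration, channel name and
IRF vector; label masks as 16-bit label TIFF (0 = background); cell tables as
CSV in a long (tidy) layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .flim import DecayStack

LONG_COLUMNS = ["patient_id", "organoid_id", "cell_id", "treatment",
                "timepoint_h", "endpoint", "value", "true_component"]


def write_decay_stack(stack: DecayStack, path: str | Path) -> Path:
    """Write a decay stack as multi-page TIFF + JSON sidecar (``.json``)."""
    path = Path(path)
    counts = np.asarray(stack.counts)
    if counts.max() > np.iinfo(np.uint16).max:
        raise ValueError("counts exceed 16-bit range")
    pages = np.moveaxis(counts.astype(np.uint16), 2, 0)  # (time, row, col)
    tifffile.imwrite(path, pages)
    sidecar = {
        "bin_width_ns": stack.bin_width,
        "channel": stack.channel,
        "n_time_bins": stack.n_time_bins,
        "irf": stack.irf.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def read_decay_stack(path: str | Path) -> DecayStack:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    counts = np.moveaxis(pages, 0, 2).astype(np.int64)
    return DecayStack(counts, meta["bin_width_ns"], meta["channel"],
                      np.asarray(meta["irf"], dtype=float))


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.uint16)


def write_cell_table_long(cells: pd.DataFrame, path: str | Path,
                          endpoints: list[str] | None = None) -> Path:
    """Melt a wide per-cell table into the long CSV interchange layout."""
    path = Path(path)
    id_cols = ["patient_id", "organoid_id", "cell_id", "treatment", "timepoint_h"]
    if endpoints is None:
        endpoints = [c for c in cells.columns
                     if c not in id_cols + ["true_component", "morphology"]
                     and pd.api.types.is_numeric_dtype(cells[c])]
    long = cells.melt(
        id_vars=id_cols + (["true_component"] if "true_component" in cells else []),
        value_vars=endpoints, var_name="endpoint", value_name="value",
    )
    if "true_component" not in long:
        long["true_component"] = 0
    long = long[LONG_COLUMNS].sort_values(
        ["patient_id", "organoid_id", "cell_id", "treatment", "timepoint_h", "endpoint"],
        kind="mergesort",
    ).reset_index(drop=True)
    long.to_csv(path, index=False)
    return path


def read_cell_table_long(path: str | Path) -> pd.DataFrame:
    """Read a long CSV cell table back into the wide per-cell layout."""
    long = pd.read_csv(path)
    wide = long.pivot_table(
        index=["patient_id", "organoid_id", "cell_id", "treatment",
               "timepoint_h", "true_component"],
        columns="endpoint", values="value",
    ).reset_index()
    wide.columns.name = None
    return wide
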