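"""Plain-text and TIFF readers/writers for the pipeline's data formats.

Conventions: ECG traces as CSV with ``time_s, voltage_mV`` columns;
fiber polylines as CSV with ``fiber_id, frame_id, vertex_index, x, y``;
expression matrices as TSV with genes as rows and sample IDs as the
header; binary masks as 8-bit {0, 255} TIFF. A JSON manifest records the
generating spec and seed for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ecg import ECGTrace
from .fibers import FiberTrace
from .imageops import BinaryMask

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_polylines_csv",
    "read_polylines_csv",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_mask_tiff",
    "read_mask_tiff",
    "write_image_tiff",
    "write_manifest",
]


def write_trace_csv(trace: ECGTrace, path: str | Path) -> None:
    t = trace.start_time + np.arange(trace.n_samples) / trace.sampling_rate
    pd.DataFrame({"time_s": t, "voltage_mV": trace.voltage}).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> ECGTrace:
    df = pd.read_csv(path)
    if not {"time_s", "voltage_mV"} <= set(df.columns):
        raise ValueError("trace CSV needs time_s and voltage_mV columns")
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return ECGTrace(df["voltage_mV"].to_numpy(), fs, start_time=float(t[0]))


def write_polylines_csv(traces: list[FiberTrace], path: str | Path) -> None:
    rows = [
        {"fiber_id": t.fiber_id, "frame_id": t.frame_id, "vertex_index": i,
         "x": x, "y": y}
        for t in traces
        for i, (x, y) in enumerate(t.vertices)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_polylines_csv(path: str | Path) -> list[FiberTrace]:
    df = pd.read_csv(path).sort_values(["frame_id", "fiber_id", "vertex_index"])
    return [
        FiberTrace(g[["x", "y"]].to_numpy(), fiber_id=int(fid), frame_id=int(frm))
        for (frm, fid), g in df.groupby(["frame_id", "fiber_id"])
    ]


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_mask_tiff(mask: BinaryMask, path: str | Path) -> None:
    tifffile.imwrite(path, (mask.data.astype(np.uint8) * 255))


def read_mask_tiff(path: str | Path, pixel_size: float = 1.0) -> BinaryMask:
    data = tifffile.imread(path)
    return BinaryMask(data > 0, pixel_size, {"op": "read_mask_tiff", "path": str(path)})


def write_image_tiff(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(image))


def write_manifest(spec: object, path: str | Path, **extra) -> None:
    """Record a generator spec (a dataclass) plus free-form metadata."""
    payload = {"spec_type": type(spec).__name__, **extra}
    if dataclasses.is_dataclass(spec):
        payload["spec"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(spec).items()
            if isinstance(v, (int, float, str, bool, tuple, list, type(None)))
        }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
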