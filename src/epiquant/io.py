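"""File I/O for the pipeline's plain-text and image formats.

EEG traces travel as two-column CSV (``time_s,amplitude_uV``); images as
TIFF; count matrices as Matrix Market ``.mtx`` with ``genes.tsv`` and
``cells.tsv`` sidecars; gene sets as GMT; truth/event tables as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from .eeg_burden import EegRecording, EventSet
from .single_cell import CountMatrix, GeneSet


def read_eeg_csv(path) -> EegRecording:
    """Read a ``time_s,amplitude_uV`` CSV; sampling rate inferred from time."""
    df = pd.read_csv(path)
    required = {"time_s", "amplitude_uV"}
    if not required.issubset(df.columns):
        raise ValueError(f"EEG CSV must contain columns {sorted(required)}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("time axis must be uniformly sampled")
    return EegRecording(
        samples=df["amplitude_uV"].to_numpy(dtype=float),
        fs_hz=1.0 / dt[0],
        subject_id=Path(path).stem,
    )


def write_eeg_csv(rec: EegRecording, path) -> None:
    pd.DataFrame({"time_s": rec.time_axis(), "amplitude_uV": rec.samples}).to_csv(
        path, index=False
    )


def write_events_tsv(events: EventSet, path) -> None:
    """One row per event: class, onset_s, duration_s, peak_uV."""
    rows = []
    for s in events.spikes:
        rows.append(
            {
                "event_class": "spike",
                "onset_s": s.onset_s,
                "duration_s": s.duration_s,
                "peak_uV": s.peak_uV,
            }
        )
    for t in events.trains:
        rows.append(
            {
                "event_class": "train",
                "onset_s": t.onset_s,
                "duration_s": t.total_duration_s,
                "peak_uV": float("nan"),
            }
        )
    for z in events.seizures:
        rows.append(
            {
                "event_class": "seizure",
                "onset_s": z.onset_s,
                "duration_s": z.duration_s,
                "peak_uV": float("nan"),
            }
        )
    pd.DataFrame(
        rows, columns=["event_class", "onset_s", "duration_s", "peak_uV"]
    ).to_csv(path, sep="\t", index=False)


def write_image_tiff(image: np.ndarray, path, as_uint16: bool = True) -> None:
    """Write an image; float images in [0, 1] are rescaled to 16-bit."""
    image = np.asarray(image)
    if as_uint16 and image.dtype.kind == "f":
        peak = image.max() if image.max() > 1 else 1.0
        image = np.clip(image / peak * 65535.0, 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), image)


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_counts_mtx(matrix: CountMatrix, out_dir) -> None:
    """Matrix Market triplet plus genes.tsv / cells.tsv sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out_dir / "matrix.mtx"), sparse.coo_matrix(matrix.counts))
    pd.Series(matrix.gene_names).to_csv(
        out_dir / "genes.tsv", sep="\t", index=False, header=False
    )
    matrix.cell_meta.reset_index().to_csv(out_dir / "cells.tsv", sep="\t", index=False)


def read_counts_mtx(in_dir) -> CountMatrix:
    in_dir = Path(in_dir)
    counts = sparse.csr_matrix(spio.mmread(str(in_dir / "matrix.mtx")))
    genes = pd.read_csv(in_dir / "genes.tsv", sep="\t", header=None)[0].to_numpy(object)
    cells = pd.read_csv(in_dir / "cells.tsv", sep="\t")
    if "cell_id" not in cells.columns:
        raise ValueError("cells.tsv must contain a cell_id column")
    cells = cells.set_index("cell_id")
    return CountMatrix(
        counts=counts,
        gene_names=genes,
        cell_ids=cells.index.to_numpy(object),
        cell_meta=cells,
    )


def read_gmt(path) -> list[GeneSet]:
    """GMT: one set per line — name, description, then member genes."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(name=parts[0], members=tuple(parts[2:])))
    return sets


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
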