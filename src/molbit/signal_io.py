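"""On-disk containers for raw signals.

The native container is deliberately simple: a directory with a
``manifest.tsv`` (columns ``read_id``, ``file`` and optional ``label``)
plus one float32 ``.npy`` array per read. An optional FAST5 reader maps
Oxford Nanopore's HDF5 layout (single- and multi-read files, the
``Raw[/Reads/Read_*]/Signal`` dataset) onto the same in-memory form.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SignalRecord:
    read_id: str
    samples: np.ndarray
    label: int | None = None


def write_container(records: list[SignalRecord], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.read_id}.npy"
        np.save(directory / fname, np.asarray(rec.samples, dtype=np.float32))
        rows.append(
            {
                "read_id": rec.read_id,
                "file": fname,
                "label": "" if rec.label is None else int(rec.label),
            }
        )
    pd.DataFrame(rows, columns=["read_id", "file", "label"]).to_csv(
        directory / "manifest.tsv", sep="\t", index=False
    )


def read_container(directory) -> list[SignalRecord]:
    directory = Path(directory)
    manifest = directory / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.tsv in {directory}")
    df = pd.read_csv(manifest, sep="\t", dtype={"read_id": str})
    records = []
    for row in df.itertuples():
        label = None
        if "label" in df.columns and not pd.isna(row.label) and row.label != "":
            label = int(row.label)
        records.append(
            SignalRecord(
                read_id=str(row.read_id),
                samples=np.load(directory / row.file),
                label=label,
            )
        )
    return records


def read_fast5(path) -> list[SignalRecord]:
    """Read raw signals from a FAST5 (HDF5) file, single- or multi-read."""
    import h5py

    records = []
    with h5py.File(path, "r") as f:
        if "Raw" in f:  # single-read layout
            reads = f["Raw/Reads"]
            for name in reads:
                grp = reads[name]
                read_id = grp.attrs.get("read_id", name)
                if isinstance(read_id, bytes):
                    read_id = read_id.decode()
                records.append(
                    SignalRecord(str(read_id), np.asarray(grp["Signal"][:], float))
                )
        else:  # multi-read layout: one top-level group per read
            for name in f:
                grp = f[name]
                if "Raw" not in grp:
                    continue
                read_id = name[5:] if name.startswith("read_") else name
                records.append(
                    SignalRecord(
                        str(read_id), np.asarray(grp["Raw/Signal"][:], float)
                    )
                )
    return records
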