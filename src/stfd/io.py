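"""Reading and writing epoch containers, masks and result tables.

Epochs travel either as an HDF5 container (datasets ``/values`` and
``/coords``, attributes ``fs``/``subject_id``/``group``) or as a plain-text
pair of TSV files (matrix + 3-column coordinates, metadata in ``#`` header
comments of the values file).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import List, Union

import h5py
import numpy as np
import pandas as pd

from .activation import ActivationMask, SourceEpoch
from .boxcount import FDSeries

__all__ = [
    "save_epoch_h5",
    "load_epoch_h5",
    "save_epoch_tsv",
    "load_epoch_tsv",
    "load_epoch",
    "find_epoch_files",
    "write_mask_rle",
    "write_fd_series",
    "write_cohort_summary",
    "load_cohort_summary",
]

PathLike = Union[str, os.PathLike]


def save_epoch_h5(epoch: SourceEpoch, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=epoch.values)
        f.create_dataset("coords", data=epoch.coords)
        f.attrs["fs"] = epoch.fs
        f.attrs["subject_id"] = epoch.subject_id
        f.attrs["group"] = epoch.group if epoch.group is not None else ""


def load_epoch_h5(path: PathLike) -> SourceEpoch:
    with h5py.File(path, "r") as f:
        group = str(f.attrs.get("group", "")) or None
        return SourceEpoch(
            values=f["values"][()],
            coords=f["coords"][()],
            fs=float(f.attrs["fs"]),
            subject_id=str(f.attrs.get("subject_id", Path(path).stem)),
            group=group,
        )


def save_epoch_tsv(epoch: SourceEpoch, values_path: PathLike, coords_path: PathLike) -> None:
    header = (
        f"# fs={epoch.fs}\n"
        f"# subject_id={epoch.subject_id}\n"
        f"# group={epoch.group if epoch.group is not None else ''}\n"
    )
    with open(values_path, "w") as f:
        f.write(header)
        np.savetxt(f, epoch.values, delimiter="\t", fmt="%.8g")
    np.savetxt(coords_path, epoch.coords, delimiter="\t", fmt="%.8g")


def load_epoch_tsv(values_path: PathLike, coords_path: PathLike) -> SourceEpoch:
    meta = {}
    with open(values_path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    values = np.loadtxt(values_path, delimiter="\t", comments="#", ndmin=2)
    coords = np.loadtxt(coords_path, delimiter="\t", ndmin=2)
    return SourceEpoch(
        values=values,
        coords=coords,
        fs=float(meta.get("fs", "1.0")),
        subject_id=meta.get("subject_id", Path(values_path).stem),
        group=meta.get("group") or None,
    )


def load_epoch(path: PathLike) -> SourceEpoch:
    """Load an epoch by file suffix (.h5/.hdf5, or a *_values.tsv file)."""
    p = Path(path)
    if p.suffix in (".h5", ".hdf5"):
        return load_epoch_h5(p)
    if p.name.endswith("_values.tsv"):
        coords = p.with_name(p.name.replace("_values.tsv", "_coords.tsv"))
        return load_epoch_tsv(p, coords)
    raise ValueError(f"unrecognized epoch container: {p}")


def find_epoch_files(directory: PathLike) -> List[Path]:
    d = Path(directory)
    files = sorted(d.glob("*.h5")) + sorted(d.glob("*.hdf5"))
    files += sorted(d.glob("*_values.tsv"))
    return files


def write_mask_rle(mask: ActivationMask, path: PathLike) -> None:
    """Run-length-encoded mask export, one line per source (inspection only)."""
    with open(path, "w") as f:
        f.write("source\truns(start:length)\n")
        for i, row in enumerate(mask.mask):
            edges = np.flatnonzero(np.diff(np.concatenate(([0], row.view(np.int8), [0]))))
            runs = [f"{s}:{e - s}" for s, e in zip(edges[::2], edges[1::2])]
            f.write(f"{i}\t{','.join(runs)}\n")


def write_fd_series(series: FDSeries, path: PathLike) -> None:
    Path(path).write_text(series.to_tsv())


def write_cohort_summary(rows: pd.DataFrame, path: PathLike) -> None:
    rows.to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_cohort_summary(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
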