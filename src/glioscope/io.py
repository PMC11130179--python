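"""File adapters: TIFF snapshots/movies, HDF5 traces, CSV/JSON tables.

All domain containers round-trip losslessly (32-bit float for image data).
A cohort manifest (CSV) binds sessions to animals, genotypes, days and file
paths, and is validated on load with row-level error context.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import GENOTYPES, ActivityMovie, NeuronTraceSet, SessionImage
from .ensembles import ClusterSet

__all__ = [
    "save_session_image", "load_session_image",
    "save_movie", "load_movie",
    "save_traces", "load_traces",
    "save_cluster_set", "load_cluster_set",
    "save_table", "load_table",
    "write_manifest", "load_manifest",
]


def save_session_image(path, img: SessionImage) -> None:
    """Write a snapshot as TIFF with its metadata in the image description."""
    meta = {"pixel_size": img.pixel_size, "day": img.day, "channel": img.channel,
            "animal_id": img.animal_id, "genotype": img.genotype}
    tifffile.imwrite(path, img.pixels.astype(np.float32),
                     description=json.dumps(meta))


def load_session_image(path) -> SessionImage:
    with tifffile.TiffFile(path) as tif:
        pixels = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return SessionImage(pixels=np.asarray(pixels, dtype=float),
                        pixel_size=float(meta.get("pixel_size", 1.0)),
                        day=int(meta.get("day", 0)),
                        channel=meta.get("channel", "tumor"),
                        animal_id=meta.get("animal_id", ""),
                        genotype=meta.get("genotype", "control"))


def save_movie(path, movie: ActivityMovie) -> None:
    """Write a dF/F movie to HDF5 (dataset ``dff`` + mask + scalar attrs)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("dff", data=movie.dff.astype(np.float32),
                             compression="gzip", compression_opts=1)
        d.attrs["frame_rate"] = movie.frame_rate
        d.attrs["pixel_size"] = movie.pixel_size
        f.create_dataset("valid_mask", data=movie.valid_mask)


def load_movie(path) -> ActivityMovie:
    with h5py.File(path, "r") as f:
        d = f["dff"]
        return ActivityMovie(dff=d[...], frame_rate=float(d.attrs["frame_rate"]),
                             pixel_size=float(d.attrs["pixel_size"]),
                             valid_mask=f["valid_mask"][...])


def save_traces(path, traces: NeuronTraceSet) -> None:
    """Write a neuron trace set (dff, optional ddff/positions, labels) to HDF5."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("dff", data=traces.dff)
        d.attrs["frame_rate"] = traces.frame_rate
        for key in ("location_tag", "time_bin", "animal_id", "genotype"):
            d.attrs[key] = getattr(traces, key)
        if traces.ddff is not None:
            f.create_dataset("ddff", data=traces.ddff)
        if traces.positions is not None:
            f.create_dataset("positions", data=traces.positions)


def load_traces(path) -> NeuronTraceSet:
    with h5py.File(path, "r") as f:
        d = f["dff"]
        return NeuronTraceSet(
            dff=d[...], frame_rate=float(d.attrs["frame_rate"]),
            ddff=f["ddff"][...] if "ddff" in f else None,
            positions=f["positions"][...] if "positions" in f else None,
            location_tag=str(d.attrs["location_tag"]),
            time_bin=str(d.attrs["time_bin"]),
            animal_id=str(d.attrs["animal_id"]),
            genotype=str(d.attrs["genotype"]))


def save_cluster_set(path, clusters: ClusterSet) -> None:
    Path(path).write_text(json.dumps(
        {"clusters": [sorted(int(i) for i in c) for c in clusters]}, indent=1))


def load_cluster_set(path) -> ClusterSet:
    data = json.loads(Path(path).read_text())
    return ClusterSet(clusters=[frozenset(c) for c in data["clusters"]])


def save_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


MANIFEST_COLUMNS = ["animal_id", "genotype", "day", "modality", "channel",
                    "path", "pixel_size", "frame_rate"]


def write_manifest(path, rows: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    rows.to_csv(path, index=False)


def load_manifest(path, base_dir=None) -> pd.DataFrame:
    """Load and validate a cohort manifest CSV.

    Checks the schema, the genotype vocabulary, per-animal day ordering and
    that every referenced file exists; failures name the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns: {missing}")
    base = Path(base_dir) if base_dir is not None else Path(path).parent
    for i, row in df.iterrows():
        if row["genotype"] not in GENOTYPES:
            raise ValueError(f"{path} row {i}: unknown genotype {row['genotype']!r}")
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"{path} row {i}: file not found: {p}")
    for animal, grp in df.groupby("animal_id"):
        days = grp.sort_index()["day"].to_numpy()
        per_modality = grp.groupby(["modality", "channel"])["day"]
        for (mod, ch), d in per_modality:
            if np.any(np.diff(d.to_numpy()) < 0):
                raise ValueError(
                    f"{path}: days not increasing for animal {animal!r} "
                    f"({mod}/{ch})")
        del days
    return df
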