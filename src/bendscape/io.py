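"""Readers and writers for the package's on-disk formats.

AFM fields go to 32-bit float TIFF or a plain-text matrix (one scan line
per row, nm units, pixel size in a header comment); umbrella windows use
the conventional WHAM dialect (per-window two-column time/coordinate
files plus a metadata file of "path centre spring" lines); trajectories
are multi-frame XYZ with a labels JSON; traces and metrics are TSV.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from bendscape.afm import AFMImage, MoleculeTrace
from bendscape.constants import DEFAULT_TEMPERATURE_K
from bendscape.fes import UmbrellaWindow
from bendscape.trajectory import Trajectory

__all__ = [
    "write_afm_tiff", "read_afm_tiff",
    "write_afm_text", "read_afm_text",
    "write_windows", "read_windows",
    "write_xyz", "read_xyz",
    "read_pdb",
    "write_traces_tsv",
    "write_fasta", "read_fasta",
]


# --- AFM images -----------------------------------------------------------

def write_afm_tiff(image: AFMImage, path) -> None:
    tifffile.imwrite(path, image.heights.astype(np.float32),
                     metadata={"pixel_nm": image.pixel_nm,
                               "provenance": image.provenance})


def read_afm_tiff(path, pixel_nm: Optional[float] = None) -> AFMImage:
    with tifffile.TiffFile(path) as tf:
        heights = tf.asarray().astype(float)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    px = pixel_nm if pixel_nm is not None else float(meta.get("pixel_nm", 1.0))
    return AFMImage(heights, px, provenance=str(meta.get("provenance", "")))


def write_afm_text(image: AFMImage, path) -> None:
    header = f"pixel_nm: {image.pixel_nm!r}"
    np.savetxt(path, image.heights, header=header)


def read_afm_text(path, pixel_nm: Optional[float] = None) -> AFMImage:
    px = pixel_nm
    if px is None:
        with open(path) as fh:
            first = fh.readline()
        if "pixel_nm:" in first:
            px = float(first.split("pixel_nm:")[1])
        else:
            px = 1.0
    return AFMImage(np.loadtxt(path), px)


# --- Umbrella windows (WHAM dialect) --------------------------------------

def write_windows(windows: Sequence[UmbrellaWindow], directory,
                  meta_name: str = "metadata.dat") -> Path:
    """Write windows as two-column (time, coordinate) files + metadata.

    The metadata file has one line per window: path, centre, spring
    constant — the dialect accepted by standard WHAM tools.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_lines = []
    for i, w in enumerate(windows):
        fname = f"window_{i:03d}.dat"
        t = np.arange(len(w.samples), dtype=float)
        np.savetxt(directory / fname, np.column_stack([t, w.samples]),
                   fmt="%.1f %.8f")
        meta_lines.append(f"{fname} {w.center:.6f} {w.spring_k:.6f}")
    meta = directory / meta_name
    meta.write_text("\n".join(meta_lines) + "\n")
    return meta


def read_windows(meta_path, temperature_K: float = DEFAULT_TEMPERATURE_K
                 ) -> list[UmbrellaWindow]:
    meta_path = Path(meta_path)
    windows = []
    for line in meta_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fname, center, spring = line.split()[:3]
        fpath = fname if os.path.isabs(fname) else meta_path.parent / fname
        data = np.loadtxt(fpath)
        samples = data[:, 1] if data.ndim == 2 else np.atleast_1d(data)
        windows.append(UmbrellaWindow(samples=samples, center=float(center),
                                      spring_k=float(spring),
                                      temperature_K=temperature_K))
    return windows


# --- Trajectories (multi-frame XYZ) ---------------------------------------

def write_xyz(trajectory: Trajectory, path) -> None:
    """Multi-frame XYZ; the atom symbol column carries the atom name."""
    names = trajectory.topology["atom_name"].tolist()
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            fh.write(f"{trajectory.n_atoms}\n")
            fh.write(f"frame {f} unit {trajectory.unit}\n")
            for name, (x, y, z) in zip(names, trajectory.coords[f]):
                fh.write(f"{name} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path, topology: Optional[pd.DataFrame] = None,
             unit: str = "angstrom") -> Trajectory:
    frames, names = [], None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i].strip())
        comment = lines[i + 1]
        if "unit" in comment:
            unit = comment.split("unit")[1].split()[0]
        block = lines[i + 2:i + 2 + n]
        frame, fnames = [], []
        for row in block:
            parts = row.split()
            fnames.append(parts[0])
            frame.append([float(v) for v in parts[1:4]])
        frames.append(frame)
        names = fnames
        i += 2 + n
    coords = np.asarray(frames, dtype=float)
    if topology is None:
        topology = pd.DataFrame({
            "residue_id": [f"X{k}" for k in range(coords.shape[1])],
            "chain_id": ["A"] * coords.shape[1],
            "atom_name": names,
        })
    return Trajectory(coords=coords, topology=topology, unit=unit)


def read_pdb(path) -> Trajectory:
    """Read a PDB file (one or more models) into a Trajectory (Angstrom)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb.get_structure(pdb_file)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    first = stack[0]
    topology = pd.DataFrame({
        "residue_id": [f"{rn}{ri}" for rn, ri in zip(first.res_name,
                                                     first.res_id)],
        "chain_id": list(first.chain_id),
        "atom_name": list(first.atom_name),
    })
    return Trajectory(coords=np.asarray(stack.coord, dtype=float),
                      topology=topology, unit="angstrom")


# --- Traces and sequences -------------------------------------------------

def write_traces_tsv(traces: Sequence[MoleculeTrace], path) -> None:
    rows = []
    for t in traces:
        for i, ((x, y), h) in enumerate(zip(t.points, t.heights)):
            rows.append({"molecule_id": t.mask_id, "point_index": i,
                         "x_nm": x, "y_nm": y, "height_nm": h})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fasta(records, path) -> None:
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> list:
    return list(SeqIO.parse(path, "fasta"))
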