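"""Geometry and classification of conformational ensembles.

Covers the analysis path from a multi-frame trajectory to binding-mode
assignments: helix-axis contouring, projection onto the best-fit plane
(to imitate surface-deposited imaging), the two-vector bend angle around
a binding site, Kabsch-superposition RMSD, average-linkage clustering of
frames, and donor-H-acceptor hydrogen-bond contact maps.

Coordinates are (n_atoms, 3) arrays; distance units are whatever the
trajectory declares (Angstrom for atomistic input, nm for coarse toys) —
all operations are unit-agnostic except the hydrogen-bond cutoffs, which
are stated in the unit of the coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "HelixAxis",
    "ContactMap",
    "helix_axis",
    "project_best_fit_plane",
    "bend_angle_axis",
    "kabsch_rmsd",
    "cluster_frames",
    "hbond_contact_map",
    "POLAR_DONORS",
    "POLAR_ACCEPTORS",
]


@dataclass
class Trajectory:
    """A stack of conformations sharing one topology.

    ``coords`` has shape (n_frames, n_atoms, 3). ``topology`` is a
    DataFrame with one row per atom and at least the columns
    ``residue_id``, ``chain_id``, ``atom_name``; ``unit`` declares the
    coordinate unit ("angstrom" or "nm").
    """

    coords: np.ndarray
    topology: pd.DataFrame
    unit: str = "angstrom"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.topology) != self.coords.shape[1]:
            raise ValueError("topology rows must match atom count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class HelixAxis:
    """Smoothed DNA helix axis: one 3D point per base pair."""

    points: np.ndarray
    bp_start: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("axis points must be (n_bp, 3)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("axis points must be finite")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ContactMap:
    """Per-residue time-averaged hydrogen-bond occupancy, capped at 1."""

    values: pd.Series               # index: residue label, values in [0, 1]
    side: Optional[pd.Series] = None  # optional near/far-left/right annotation


# ---------------------------------------------------------------------------
# Helix axis and projection
# ---------------------------------------------------------------------------

def helix_axis(frame: np.ndarray,
               bp_pairing: Sequence[tuple[int, int]],
               window: int = 11) -> HelixAxis:
    """Approximate the DNA helix axis of one frame.

    Base-pair centres (midpoints of the paired atoms, e.g. C1'-C1') are
    smoothed by a centred moving average over one helical turn
    (``window`` = 11 points), with the window shrinking symmetrically at
    the ends. This is a surrogate for full helical-axis contouring: it
    removes the helical ripple but is not identical to algorithms that fit
    local helical parameters.
    """
    frame = np.asarray(frame, dtype=float)
    if len(bp_pairing) < window:
        raise ValueError(f"need >= {window} bp, got {len(bp_pairing)}")
    mids = []
    for i, j in bp_pairing:
        if i >= len(frame) or j >= len(frame):
            raise ValueError(f"pairing ({i}, {j}) outside frame")
        mids.append(0.5 * (frame[i] + frame[j]))
    mids = np.asarray(mids)
    half = window // 2
    n = len(mids)
    out = np.empty_like(mids)
    for i in range(n):
        k = min(i, n - 1 - i, half)
        out[i] = mids[i - k:i + k + 1].mean(axis=0)
    return HelixAxis(points=out)


def project_best_fit_plane(axis) -> tuple[np.ndarray, float]:
    """Project an axis polyline onto its total-least-squares plane.

    The plane passes through the centroid with normal given by the
    smallest principal component. Returns the projected points and the
    planarity percentage, 100 * RMS out-of-plane distance / R_g of the
    polyline (small values = nearly flat conformation, as for molecules
    equilibrated on a surface).
    """
    pts = axis.points if isinstance(axis, HelixAxis) else np.asarray(axis, float)
    if len(pts) < 3:
        raise ValueError("need >= 3 points to define a plane")
    centred = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("points are collinear; best-fit plane undefined")
    normal = vt[2]
    out_of_plane = centred @ normal
    projected = pts - np.outer(out_of_plane, normal)
    rg = np.sqrt((centred**2).sum(axis=1).mean())
    planarity_pct = 100.0 * np.sqrt(np.mean(out_of_plane**2)) / rg
    return projected, float(planarity_pct)


def bend_angle_axis(axis, center_bp: int, span_bp: int = 30,
                    gap_bp: int = 30) -> float:
    """Bend angle from two vectors along the helix axis around a site.

    v1 joins bp (c - gap/2 - span) -> (c - gap/2) and v2 joins
    (c + gap/2) -> (c + gap/2 + span): two ``span_bp``-long vectors
    separated by ``gap_bp`` centred on ``center_bp``. The angle between
    them is 0 deg for straight DNA.
    """
    pts = axis.points if isinstance(axis, HelixAxis) else np.asarray(axis, float)
    half_gap = gap_bp // 2
    i0 = center_bp - half_gap - span_bp
    i1 = center_bp - half_gap
    j0 = center_bp + half_gap
    j1 = center_bp + half_gap + span_bp
    if i0 < 0 or j1 > len(pts) - 1:
        raise ValueError(
            f"axis of {len(pts)} points too short: need indices {i0}..{j1} "
            f"for center {center_bp}, span {span_bp}, gap {gap_bp}")
    v1 = pts[i1] - pts[i0]
    v2 = pts[j1] - pts[j0]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# RMSD and clustering
# ---------------------------------------------------------------------------

def kabsch_rmsd(frame_a: np.ndarray, frame_b: np.ndarray,
                selection: Optional[np.ndarray] = None) -> float:
    """Minimum RMSD after optimal superposition (rotation + translation).

    Reflections are excluded (proper rotation via the determinant
    correction of the SVD solution).
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if selection is not None:
        a, b = a[selection], b[selection]
    if a.shape != b.shape:
        raise ValueError("selections must have matching shapes")
    if len(a) < 3:
        raise ValueError("need >= 3 points for superposition")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = a @ rot.T - b
    return float(np.sqrt((diff**2).sum() / len(a)))


def pairwise_rmsd_matrix(trajectory: Trajectory,
                         selection: Optional[np.ndarray] = None) -> np.ndarray:
    """Symmetric matrix of Kabsch RMSDs between all frame pairs."""
    n = trajectory.n_frames
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch_rmsd(
                trajectory.coords[i], trajectory.coords[j], selection)
    return mat


def cluster_frames(trajectory: Trajectory, n_clusters: int = 3,
                   selection: Optional[np.ndarray] = None,
                   rmsd_matrix: Optional[np.ndarray] = None
                   ) -> tuple[np.ndarray, list[int], np.ndarray]:
    """Average-linkage hierarchical clustering of frames by RMSD.

    Agglomerates on the pairwise Kabsch-RMSD matrix until ``n_clusters``
    remain. Labels are renumbered 0..k-1 by first frame occurrence, so the
    result is deterministic. The representative of a cluster is the frame
    minimising the mean RMSD to its cluster mates.

    Returns (labels, representatives, rmsd_matrix).
    """
    if trajectory.n_frames < n_clusters:
        raise ValueError("fewer frames than requested clusters")
    mat = rmsd_matrix if rmsd_matrix is not None else pairwise_rmsd_matrix(
        trajectory, selection)
    z = linkage(squareform(mat, checks=False), method="average")
    raw = fcluster(z, t=n_clusters, criterion="maxclust")
    # renumber by first occurrence for determinism
    mapping: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        labels[i] = mapping[lab]
    reps = []
    for c in range(labels.max() + 1):
        members = np.flatnonzero(labels == c)
        sub = mat[np.ix_(members, members)]
        reps.append(int(members[np.argmin(sub.mean(axis=1))]))
    return labels, reps, mat


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

#: Standard polar donor heavy atoms (protein backbone/side chains and
#: nucleic acid bases). Used to build donor tables from a topology;
#: configurable by passing explicit tables.
POLAR_DONORS = {
    "N", "NE", "NH1", "NH2", "ND1", "ND2", "NE1", "NE2", "NZ", "OG",
    "OG1", "OH", "SG",                       # protein
    "N1", "N2", "N3", "N4", "N6", "O2'",     # nucleic acid
}

#: Standard polar acceptor atoms.
POLAR_ACCEPTORS = {
    "O", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH", "ND1", "NE2", "SD",
    "OP1", "OP2", "O2'", "O3'", "O4'", "O5'", "O2", "O4", "O6",
    "N1", "N3", "N7",
}


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b of the triple a-b-c, in degrees."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hbond_contact_map(trajectory: Trajectory,
                      donors: pd.DataFrame,
                      acceptors: pd.DataFrame,
                      d_cut: float = 3.5,
                      angle_cut: float = 120.0,
                      intermolecular_only: bool = True) -> ContactMap:
    """Time-averaged per-residue hydrogen-bond occupancy.

    ``donors`` needs columns ``donor_idx``, ``h_idx``, ``residue``;
    ``acceptors`` needs ``atom_idx``, ``residue``. A bond exists when the
    donor-acceptor distance is <= ``d_cut`` AND the D-H...A angle (at the
    hydrogen) is >= ``angle_cut`` degrees. Per frame, the bond count of
    each residue is capped at 1, so the time average is the fraction of
    frames in which the residue makes at least one hydrogen bond. Donors
    whose ``h_idx`` is missing/negative are skipped with a warning. With
    ``intermolecular_only`` donor and acceptor must sit on different
    chains (requires ``chain_id`` in the topology).
    """
    all_residues = list(donors["residue"]) + list(acceptors["residue"])
    donors = donors.copy()
    bad = donors["h_idx"].isna() | (donors["h_idx"] < 0)
    if bad.any():
        logger.warning("%d donors without attached hydrogen skipped", bad.sum())
        donors = donors[~bad]
    donors["h_idx"] = donors["h_idx"].astype(int)
    chain = trajectory.topology["chain_id"].to_numpy()

    residues: dict = {}
    counts: dict = {}
    for r in all_residues:
        residues[r] = True
        counts.setdefault(r, 0.0)

    for f in range(trajectory.n_frames):
        xyz = trajectory.coords[f]
        seen: set = set()
        for d_idx, h_idx, d_res in donors[["donor_idx", "h_idx", "residue"]].itertuples(index=False):
            for a_idx, a_res in acceptors[["atom_idx", "residue"]].itertuples(index=False):
                if a_idx == d_idx:
                    continue
                if intermolecular_only and chain[d_idx] == chain[a_idx]:
                    continue
                # 1e-9 guard keeps the inclusive boundaries exact in floats
                if np.linalg.norm(xyz[d_idx] - xyz[a_idx]) > d_cut + 1e-9:
                    continue
                if _angle_deg(xyz[d_idx], xyz[h_idx], xyz[a_idx]) < angle_cut - 1e-9:
                    continue
                seen.add(d_res)
                seen.add(a_res)
        for r in seen:          # cap at one bond per residue per frame
            counts[r] += 1.0

    n = trajectory.n_frames
    values = pd.Series({r: counts[r] / n for r in residues}, name="hbond_occupancy")
    return ContactMap(values=values)
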