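"""Toy conformational ensembles with known family labels.

Frames are reference conformations ("families", e.g. three binding modes)
plus isotropic Gaussian noise, so clustering can be scored against ground
truth. Optional hydrogen-bond fixtures append constructed donor/H/acceptor
triplets with prescribed geometry to every frame, exercising contact-map
detection at exactly known distances and angles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from bendscape.trajectory import Trajectory, kabsch_rmsd

__all__ = ["HBondFixture", "generate_toy_trajectory"]


@dataclass
class HBondFixture:
    """One constructed donor/H/acceptor triplet appended to every frame.

    The donor sits at ``donor_pos``; the hydrogen 1.0 unit towards the
    acceptor direction scaled by ``dh_distance``; the acceptor at
    ``da_distance`` from the donor with a D-H...A angle of
    ``dha_angle_deg`` degrees. Donor and acceptor are placed on different
    chains so they count as intermolecular.
    """

    donor_pos: tuple[float, float, float] = (0.0, 0.0, 0.0)
    da_distance: float = 2.9
    dha_angle_deg: float = 180.0
    dh_distance: float = 1.0
    donor_residue: str = "DON"
    acceptor_residue: str = "ACC"

    def triplet(self) -> np.ndarray:
        """Coordinates (3, 3) for donor, hydrogen, acceptor."""
        d = np.asarray(self.donor_pos, dtype=float)
        h = d + np.array([self.dh_distance, 0.0, 0.0])
        # place A so that the angle at H between H->D and H->A is dha_angle
        ang = np.radians(self.dha_angle_deg)
        # H->D points in -x; H->A makes the requested angle with it
        ha_len = self._ha_length()
        direction = np.array([-np.cos(ang), np.sin(ang), 0.0])
        a = h + ha_len * direction  # so that angle(D,H,A) = dha_angle
        return np.vstack([d, h, a])

    def _ha_length(self) -> float:
        # law of cosines: |DA|^2 = |DH|^2 + |HA|^2 - 2|DH||HA|cos(angle at H)
        ang = np.radians(self.dha_angle_deg)
        b = -2 * self.dh_distance * np.cos(ang)
        c = self.dh_distance**2 - self.da_distance**2
        return (-b + np.sqrt(b**2 - 4 * c)) / 2


def generate_toy_trajectory(n_frames: int,
                            families: Sequence[np.ndarray],
                            noise: float = 0.0,
                            hbond_fixtures: Optional[Sequence[HBondFixture]] = None,
                            seed: Optional[int] = None,
                            rng: Optional[np.random.Generator] = None,
                            unit: str = "angstrom",
                            ) -> tuple[Trajectory, np.ndarray]:
    """Build a labelled toy trajectory from reference conformations.

    Families must be pairwise distinct: every pairwise RMSD must exceed
    10x the noise level (otherwise recovery by clustering is not a
    well-posed check). Frames cycle through families in a random order;
    labels are returned alongside.
    """
    families = [np.asarray(f, dtype=float) for f in families]
    if len(families) < 1:
        raise ValueError("need at least one family")
    shape = families[0].shape
    if any(f.shape != shape for f in families):
        raise ValueError("families must share one topology")
    for i in range(len(families)):
        for j in range(i + 1, len(families)):
            if kabsch_rmsd(families[i], families[j]) <= 10.0 * noise:
                raise ValueError(
                    f"families {i} and {j} are not distinct at this noise level")
    if rng is None:
        rng = np.random.default_rng(seed)

    labels = rng.integers(0, len(families), size=n_frames)
    n_atoms = shape[0]
    fixtures = list(hbond_fixtures or [])
    extra = 3 * len(fixtures)
    coords = np.empty((n_frames, n_atoms + extra, 3))
    for f in range(n_frames):
        base = families[labels[f]] + rng.normal(0.0, noise, size=shape)
        rows = [base]
        for fix in fixtures:
            rows.append(fix.triplet())
        coords[f] = np.vstack(rows)

    topo_rows = [{"residue_id": f"X{i}", "chain_id": "A", "atom_name": "CA"}
                 for i in range(n_atoms)]
    for k, fix in enumerate(fixtures):
        topo_rows += [
            {"residue_id": fix.donor_residue, "chain_id": "D", "atom_name": "N"},
            {"residue_id": fix.donor_residue, "chain_id": "D", "atom_name": "H"},
            {"residue_id": fix.acceptor_residue, "chain_id": "E", "atom_name": "O"},
        ]
    topology = pd.DataFrame(topo_rows)
    return Trajectory(coords=coords, topology=topology, unit=unit), labels
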