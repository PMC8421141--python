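"""Render synthetic AFM fields of deposited DNA with full ground truth.

A field is built by placing molecule backbones (planar polylines in nm)
at random positions and orientations on a pixel grid, rasterising them as
ridges of the DNA apparent height with an optional bound-protein blob at
the kink, blurring with a Gaussian tip point-spread function, and adding
scan-line offsets, pixel noise, and optional scar rows and globular
surface artifacts. Every placed object is recorded in a ground-truth
structure sufficient to score the downstream tracing stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from bendscape.afm import AFMImage, contour_length
from bendscape.constants import IMAGE_PX, PIXEL_NM

__all__ = ["FieldParams", "MoleculeRecord", "FieldGroundTruth", "render_afm_field"]


@dataclass
class FieldParams:
    """Imaging parameters of a rendered AFM field.

    Defaults follow typical tapping-mode imaging of DNA on mica:
    512 x 512 pixels at 3.9 nm/px, DNA apparent height 0.5 nm, tip PSF
    sigma 3 nm, and small scan-line and pixel noise. Scars and globular
    poly-L-lysine artifacts are off by default (rates are expected counts
    per image).
    """

    image_px: tuple[int, int] = IMAGE_PX
    pixel_nm: float = PIXEL_NM
    dna_height_nm: float = 0.5
    psf_sigma_nm: float = 3.0
    noise_sigma_nm: float = 0.05
    line_offset_sigma_nm: float = 0.02
    scar_rate: float = 0.0
    artifact_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pixel_nm", "dna_height_nm", "psf_sigma_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("noise_sigma_nm", "line_offset_sigma_nm",
                     "scar_rate", "artifact_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class MoleculeRecord:
    """One molecule: backbone polyline plus kink annotation.

    As input to :func:`render_afm_field` the backbone is in local nm
    coordinates; the ground truth returned carries the backbone in field
    coordinates (x = column*pixel_nm, y = row*pixel_nm).
    """

    backbone_nm: np.ndarray
    kink_index: Optional[int] = None
    kink_state: Optional[int] = None
    kink_angle_deg: Optional[float] = None
    protein_height_nm: float = 2.0

    def __post_init__(self) -> None:
        self.backbone_nm = np.asarray(self.backbone_nm, dtype=float)

    @property
    def contour_length_nm(self) -> float:
        return contour_length(self.backbone_nm)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["backbone_nm"] = self.backbone_nm.tolist()
        d["contour_length_nm"] = self.contour_length_nm
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MoleculeRecord":
        d = dict(d)
        d.pop("contour_length_nm", None)
        d["backbone_nm"] = np.asarray(d["backbone_nm"], dtype=float)
        return cls(**d)


@dataclass
class FieldGroundTruth:
    """Everything needed to score tracing on a rendered field."""

    molecules: list[MoleculeRecord]
    params: FieldParams
    seed: Optional[int] = None
    scar_rows: list[int] = dc_field(default_factory=list)
    artifacts: list[dict] = dc_field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "molecules": [m.to_dict() for m in self.molecules],
            "params": asdict(self.params),
            "seed": self.seed,
            "scar_rows": self.scar_rows,
            "artifacts": self.artifacts,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "FieldGroundTruth":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        params = FieldParams(**{**payload["params"],
                                "image_px": tuple(payload["params"]["image_px"])})
        return cls(
            molecules=[MoleculeRecord.from_dict(m) for m in payload["molecules"]],
            params=params,
            seed=payload.get("seed"),
            scar_rows=list(payload.get("scar_rows", [])),
            artifacts=list(payload.get("artifacts", [])),
        )


def _rasterize_polyline(points_px: np.ndarray, shape: tuple[int, int],
                        height: float, canvas: np.ndarray) -> np.ndarray:
    """Stamp a polyline as a 1-px ridge of the given height (max-composed)."""
    # supersample each segment so no pixel is skipped
    for a, b in zip(points_px[:-1], points_px[1:]):
        n = max(2, int(np.ceil(np.linalg.norm(b - a) * 4)) + 1)
        seg = a + np.linspace(0, 1, n)[:, None] * (b - a)
        rows = np.clip(np.round(seg[:, 1]).astype(int), 0, shape[0] - 1)
        cols = np.clip(np.round(seg[:, 0]).astype(int), 0, shape[1] - 1)
        np.maximum.at(canvas, (rows, cols), height)
    return canvas


def _stamp_disk(canvas: np.ndarray, center_px: np.ndarray, radius_px: float,
                height: float) -> None:
    r0 = int(np.floor(center_px[1] - radius_px)) - 1
    c0 = int(np.floor(center_px[0] - radius_px)) - 1
    r1 = int(np.ceil(center_px[1] + radius_px)) + 2
    c1 = int(np.ceil(center_px[0] + radius_px)) + 2
    rr, cc = np.mgrid[max(r0, 0):min(r1, canvas.shape[0]),
                      max(c0, 0):min(c1, canvas.shape[1])]
    d2 = (rr - center_px[1])**2 + (cc - center_px[0])**2
    sel = d2 <= radius_px**2
    region = canvas[max(r0, 0):min(r1, canvas.shape[0]),
                    max(c0, 0):min(c1, canvas.shape[1])]
    region[sel] = np.maximum(region[sel], height)


def render_afm_field(molecules: Sequence[MoleculeRecord],
                     params: Optional[FieldParams] = None,
                     seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None,
                     max_placement_tries: int = 200,
                     clearance_px: int = 3,
                     ) -> tuple[AFMImage, FieldGroundTruth]:
    """Place molecules on a field and render the AFM height map.

    Each molecule is rotated by a random angle and translated to a random
    in-bounds position; placements overlapping previously placed molecules
    (within ``clearance_px`` dilation) are rejected and retried up to
    ``max_placement_tries`` times. Failure to place every molecule raises
    ``RuntimeError`` naming the offending molecule indices.

    Returns the rendered :class:`~bendscape.afm.AFMImage` and a
    :class:`FieldGroundTruth` listing every placed object.
    """
    params = params or FieldParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    rows, cols = params.image_px
    canvas = np.zeros((rows, cols), dtype=float)
    occupied = np.zeros((rows, cols), dtype=bool)
    margin = 3
    placed: list[MoleculeRecord] = []
    failures: list[int] = []

    for mi, mol in enumerate(molecules):
        pts = mol.backbone_nm / params.pixel_nm  # local px
        pts = pts - pts.mean(axis=0)
        ok = False
        for _ in range(max_placement_tries):
            ang = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(ang), -np.sin(ang)],
                            [np.sin(ang), np.cos(ang)]])
            cand = pts @ rot.T
            span_lo, span_hi = cand.min(axis=0), cand.max(axis=0)
            free_x = cols - 1 - 2 * margin - (span_hi[0] - span_lo[0])
            free_y = rows - 1 - 2 * margin - (span_hi[1] - span_lo[1])
            if free_x <= 0 or free_y <= 0:
                continue
            shift = np.array([margin - span_lo[0] + rng.uniform(0, free_x),
                              margin - span_lo[1] + rng.uniform(0, free_y)])
            cand = cand + shift
            trial = np.zeros_like(canvas)
            _rasterize_polyline(cand, canvas.shape, 1.0, trial)
            trial_mask = trial > 0
            dil = ndimage.binary_dilation(trial_mask, iterations=clearance_px)
            if (dil & occupied).any():
                continue
            # accept
            _rasterize_polyline(cand, canvas.shape, params.dna_height_nm, canvas)
            if mol.kink_index is not None:
                _stamp_disk(canvas, cand[mol.kink_index], radius_px=1.2,
                            height=mol.protein_height_nm)
            occupied |= dil
            placed.append(MoleculeRecord(
                backbone_nm=cand * params.pixel_nm,
                kink_index=mol.kink_index,
                kink_state=mol.kink_state,
                kink_angle_deg=mol.kink_angle_deg,
                protein_height_nm=mol.protein_height_nm,
            ))
            ok = True
            break
        if not ok:
            failures.append(mi)
    if failures:
        raise RuntimeError(
            f"could not place molecules {failures} after {max_placement_tries} tries"
        )

    # globular artifacts (poly-L-lysine style blobs)
    artifacts: list[dict] = []
    n_art = rng.poisson(params.artifact_rate) if params.artifact_rate > 0 else 0
    for _ in range(n_art):
        r = rng.uniform(margin, rows - margin)
        c = rng.uniform(margin, cols - margin)
        h = rng.uniform(1.0, 3.0)
        rad = rng.uniform(1.0, 3.0)
        _stamp_disk(canvas, np.array([c, r]), rad, h)
        artifacts.append({"row": r, "col": c, "height_nm": h, "radius_px": rad})

    sigma_px = params.psf_sigma_nm / params.pixel_nm
    heights = ndimage.gaussian_filter(canvas, sigma_px)

    if params.line_offset_sigma_nm > 0:
        heights = heights + rng.normal(0, params.line_offset_sigma_nm,
                                       size=(rows, 1))
    if params.noise_sigma_nm > 0:
        heights = heights + rng.normal(0, params.noise_sigma_nm, size=heights.shape)

    scar_rows: list[int] = []
    n_scars = rng.poisson(params.scar_rate) if params.scar_rate > 0 else 0
    for _ in range(n_scars):
        r = int(rng.integers(1, rows - 1))
        start = int(rng.integers(0, cols // 2))
        length = int(rng.integers(cols // 4, cols - start))
        heights[r, start:start + length] += rng.uniform(2.0, 10.0)
        scar_rows.append(r)

    image = AFMImage(heights, params.pixel_nm, provenance="bendscape.simulate")
    truth = FieldGroundTruth(molecules=placed, params=params, seed=seed,
                             scar_rows=scar_rows, artifacts=artifacts)
    return image, truth
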