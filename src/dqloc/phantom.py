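"""Synthetic OCT-B-scan-like phantoms of a serous neurosensory detachment.

A phantom is a grayscale image with horizontal bright bands (the layered
retina), a dark dome-shaped fluid pocket sitting on one band, and
multiplicative speckle noise.  The ground truth for each image is the pair
of lateral extreme points of the dome's chord — the left and right key
boundary points whose separation is the lesion diameter.

Within a patient stack the lesion chord follows a chord-of-sphere profile
across frames: the detachment is approximately dome-shaped in 3-D, so
central frames cut it near its equator (large chord) and peripheral frames
near its edge (small chord).

Coordinate convention used by every module in this package: ``x`` is the
column, ``y`` the row, 0-based, origin at the image's top-left corner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "PhantomConfig",
    "BScan",
    "Annotation",
    "PatientSeries",
    "generate_bscan",
    "generate_patient_series",
    "generate_dataset",
    "augment",
    "write_dataset",
    "read_dataset",
    "MIN_RENDERABLE_DIAMETER",
]

#: Smallest chord (in pixels) the renderer will draw; series profiles are
#: floored here so every frame contains a visible lesion.
MIN_RENDERABLE_DIAMETER = 4


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity and noise settings for phantom generation."""

    image_height: int = 128
    image_width: int = 128
    n_frames_per_patient: int = 24
    lesion_max_diameter_range: tuple[int, int] = (40, 90)
    lesion_height_range: tuple[int, int] = (12, 28)
    band_intensity_levels: tuple[int, ...] = (200, 150, 220, 170)
    fluid_level: int = 15
    background_level: int = 35
    speckle_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.image_height < 16 or self.image_width < 16:
            raise ValueError("image must be at least 16x16")
        lo, hi = self.lesion_max_diameter_range
        if not (MIN_RENDERABLE_DIAMETER <= lo <= hi <= self.image_width - 2):
            raise ValueError(
                "lesion_max_diameter_range must lie within "
                f"[{MIN_RENDERABLE_DIAMETER}, image_width - 2]"
            )
        for v in (*self.band_intensity_levels, self.fluid_level, self.background_level):
            if not 0 <= v <= 255:
                raise ValueError("intensity levels must be in [0, 255]")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be nonnegative")

    def to_json(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["lesion_max_diameter_range"] = list(d["lesion_max_diameter_range"])
        d["lesion_height_range"] = list(d["lesion_height_range"])
        d["band_intensity_levels"] = list(d["band_intensity_levels"])
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "PhantomConfig":
        d = json.loads(Path(path).read_text())
        for k in ("lesion_max_diameter_range", "lesion_height_range",
                  "band_intensity_levels"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class BScan:
    """One grayscale cross-sectional image; the environment the agent explores."""

    pixels: np.ndarray  # uint8, shape (rows, cols)
    patient_id: str = ""
    frame_index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("BScan.pixels must be a non-empty 2-D array")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Annotation:
    """Ground-truth left/right key boundary points of the lesion chord."""

    left_point: tuple[int, int]   # (x, y)
    right_point: tuple[int, int]

    def __post_init__(self):
        if self.left_point[0] >= self.right_point[0]:
            raise ValueError("left_point.x must be < right_point.x")

    def inside(self, scan: BScan) -> bool:
        for x, y in (self.left_point, self.right_point):
            if not (0 <= x < scan.width and 0 <= y < scan.height):
                return False
        return True


@dataclass
class PatientSeries:
    """Ordered frames of one patient; frame_index strictly increasing."""

    patient_id: str
    scans: list[tuple[BScan, Annotation]] = field(default_factory=list)

    def __post_init__(self):
        idx = [s.frame_index for s, _ in self.scans]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame_index must be strictly increasing")


# ---------------------------------------------------------------------------
# generation

def _lesion_geometry(config: PhantomConfig, rng: np.random.Generator):
    """Draw the fixed per-patient geometry: band layout and dome anchor."""
    h, w = config.image_height, config.image_width
    levels = config.band_intensity_levels
    band_h = max(6, h // (2 * len(levels) + 2))
    total = band_h * len(levels)
    y0 = int(rng.integers(h // 6, max(h // 6 + 1, h - total - h // 6)))
    dome_h = int(rng.integers(config.lesion_height_range[0],
                              config.lesion_height_range[1] + 1))
    # chord row: deep enough inside the band block that the dome top stays
    # surrounded by bright tissue
    y_base = min(h - 2, y0 + max(dome_h + 3, total // 2))
    cx = w // 2 + int(rng.integers(-w // 10, w // 10 + 1))
    return {"y0": y0, "band_h": band_h, "y_base": y_base, "cx": cx,
            "dome_h": dome_h}


def _render(config: PhantomConfig, geometry: dict, diameter: int,
            rng: np.random.Generator) -> tuple[BScan, Annotation]:
    h, w = config.image_height, config.image_width
    img = np.full((h, w), float(config.background_level))

    y0, band_h = geometry["y0"], geometry["band_h"]
    for i, level in enumerate(config.band_intensity_levels):
        img[y0 + i * band_h: y0 + (i + 1) * band_h, :] = float(level)

    cx, y_base = geometry["cx"], geometry["y_base"]
    dome_h = min(geometry["dome_h"], y_base - y0 - 2)
    dome_h = max(2, dome_h)
    half = diameter / 2.0
    xl = int(round(cx - half))
    xr = xl + diameter
    if xl < 1 or xr > w - 2:
        raise ValueError(
            f"diameter {diameter} does not fit at chord center {cx} "
            f"in image of width {w}"
        )
    xs = np.arange(xl, xr + 1)
    rel = (xs - (xl + xr) / 2.0) / half
    heights = dome_h * np.sqrt(np.clip(1.0 - rel * rel, 0.0, 1.0))
    for x, hh in zip(xs, heights):
        top = int(round(y_base - hh))
        img[top: y_base + 1, x] = float(config.fluid_level)

    if config.speckle_sigma > 0:
        noise = rng.standard_normal(img.shape)
        img = img * (1.0 + config.speckle_sigma * noise)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    ann = Annotation(left_point=(xl, y_base), right_point=(xr, y_base))
    return BScan(pixels=img), ann


def generate_bscan(config: PhantomConfig, diameter: int,
                   rng: np.random.Generator | int | None = None
                   ) -> tuple[BScan, Annotation]:
    """Render a single phantom B-scan with the given lesion chord diameter.

    The annotation holds the chord's two endpoints, so
    ``right_point.x - left_point.x == diameter`` exactly.
    """
    if not (MIN_RENDERABLE_DIAMETER <= diameter <= config.image_width - 2):
        raise ValueError(
            f"diameter must be in [{MIN_RENDERABLE_DIAMETER}, "
            f"{config.image_width - 2}], got {diameter}"
        )
    rng = np.random.default_rng(config.seed if rng is None else rng)
    geometry = _lesion_geometry(config, rng)
    return _render(config, geometry, int(diameter), rng)


def chord_profile(d_max: int, n_frames: int) -> list[int]:
    """Chord-of-sphere diameter per frame: d_k = D_max * sqrt(1 - (2k/(n-1) - 1)^2)."""
    if n_frames == 1:
        return [int(d_max)]
    out = []
    for k in range(n_frames):
        t = 2.0 * k / (n_frames - 1) - 1.0
        d = d_max * np.sqrt(max(0.0, 1.0 - t * t))
        out.append(max(MIN_RENDERABLE_DIAMETER, int(round(d))))
    return out


def generate_patient_series(config: PhantomConfig,
                            rng: np.random.Generator | int | None = None,
                            patient_id: str = "P000") -> PatientSeries:
    """Generate one patient stack whose chord follows the dome profile.

    Band layout and the dome anchor are fixed across the stack; only the
    chord diameter changes frame to frame, so the maximum over frames of
    ``right.x - left.x`` recovers the drawn D_max.
    """
    if config.n_frames_per_patient < 1:
        raise ValueError("n_frames_per_patient must be >= 1")
    rng = np.random.default_rng(config.seed if rng is None else rng)
    lo, hi = config.lesion_max_diameter_range
    d_max = int(rng.integers(lo, hi + 1))
    geometry = _lesion_geometry(config, rng)
    # keep the widest chord inside the image for this anchor
    cx = geometry["cx"]
    w = config.image_width
    max_fit = 2 * min(cx - 1, w - 2 - cx)
    d_max = min(d_max, max_fit)
    scans = []
    for k, d in enumerate(chord_profile(d_max, config.n_frames_per_patient)):
        scan, ann = _render(config, geometry, d, rng)
        scan.patient_id = patient_id
        scan.frame_index = k
        scans.append((scan, ann))
    return PatientSeries(patient_id=patient_id, scans=scans)


def generate_dataset(config: PhantomConfig, n_patients: int,
                     seed: int | None = None) -> list[PatientSeries]:
    """Generate several patients, each with an independent sub-seed."""
    root = np.random.default_rng(config.seed if seed is None else seed)
    out = []
    for i in range(n_patients):
        sub = np.random.default_rng(root.integers(0, 2**31 - 1))
        out.append(generate_patient_series(config, sub, patient_id=f"P{i:03d}"))
    return out


# ---------------------------------------------------------------------------
# augmentation

def augment(scan: BScan, ann: Annotation, op) -> tuple[BScan, Annotation]:
    """Apply one augmentation: ``"hflip"`` or ``("shift", dx, dy)``.

    Horizontal flipping mirrors the columns and swaps the left/right labels,
    because the mirrored left extreme becomes the right extreme.  Shifting
    translates the image with edge-replicated fill and moves both points by
    (dx, dy); a shift that would push a point out of bounds is rejected.
    """
    h, w = scan.pixels.shape
    if op == "hflip":
        flipped = scan.pixels[:, ::-1].copy()
        lx, ly = ann.left_point
        rx, ry = ann.right_point
        new_ann = Annotation(left_point=(w - 1 - rx, ry),
                             right_point=(w - 1 - lx, ly))
        return BScan(flipped, scan.patient_id, scan.frame_index), new_ann
    if isinstance(op, tuple) and len(op) == 3 and op[0] == "shift":
        _, dx, dy = op
        dx, dy = int(dx), int(dy)
        pts = []
        for x, y in (ann.left_point, ann.right_point):
            nx, ny = x + dx, y + dy
            if not (0 <= nx < w and 0 <= ny < h):
                raise ValueError(
                    f"shift ({dx},{dy}) pushes point ({x},{y}) out of bounds"
                )
            pts.append((nx, ny))
        rows = np.clip(np.arange(h) - dy, 0, h - 1)
        cols = np.clip(np.arange(w) - dx, 0, w - 1)
        shifted = scan.pixels[np.ix_(rows, cols)].copy()
        new_ann = Annotation(left_point=pts[0], right_point=pts[1])
        return BScan(shifted, scan.patient_id, scan.frame_index), new_ann
    raise ValueError(f"unknown augmentation op: {op!r}")


# ---------------------------------------------------------------------------
# dataset IO

_CSV_COLUMNS = ["patient_id", "frame_index", "image_path",
                "left_x", "left_y", "right_x", "right_y"]


def write_dataset(series_list: Iterable[PatientSeries], directory) -> Path:
    """Write PNG images plus one CSV manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for series in series_list:
        for scan, ann in series.scans:
            name = f"{series.patient_id}_f{scan.frame_index:03d}.png"
            iio.imwrite(directory / name, scan.pixels)
            rows.append({
                "patient_id": series.patient_id,
                "frame_index": scan.frame_index,
                "image_path": name,
                "left_x": ann.left_point[0], "left_y": ann.left_point[1],
                "right_x": ann.right_point[0], "right_y": ann.right_point[1],
            })
    manifest = directory / "annotations.csv"
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_dataset(directory) -> list[PatientSeries]:
    """Read a dataset written by :func:`write_dataset`.

    An empty or manifest-less directory yields an empty list.  Malformed
    manifest rows raise with the offending row number.
    """
    directory = Path(directory)
    manifest = directory / "annotations.csv"
    if not manifest.exists():
        return []
    df = pd.read_csv(manifest, dtype=str)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    by_patient: dict[str, list[tuple[BScan, Annotation]]] = {}
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based, counting the header line
        try:
            frame = int(row["frame_index"])
            coords = [int(row[c]) for c in ("left_x", "left_y",
                                            "right_x", "right_y")]
        except (TypeError, ValueError) as exc:
            raise ValueError(f"manifest row {rowno}: non-integer field ({exc})")
        path = directory / row["image_path"]
        if not path.exists():
            raise ValueError(f"manifest row {rowno}: missing image {path.name}")
        pixels = np.asarray(iio.imread(path))
        scan = BScan(pixels, patient_id=row["patient_id"], frame_index=frame)
        ann = Annotation(left_point=(coords[0], coords[1]),
                         right_point=(coords[2], coords[3]))
        by_patient.setdefault(row["patient_id"], []).append((scan, ann))
    out = []
    for pid, scans in by_patient.items():
        scans.sort(key=lambda pair: pair[0].frame_index)
        out.append(PatientSeries(patient_id=pid, scans=scans))
    return out


def flatten(series_list: Sequence[PatientSeries]
            ) -> tuple[list[BScan], list[Annotation]]:
    """All (scan, annotation) pairs across patients as two aligned lists."""
    scans, anns = [], []
    for series in series_list:
        for scan, ann in series.scans:
            scans.append(scan)
            anns.append(ann)
    return scans, anns
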