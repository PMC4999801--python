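"""Synthetic stained-field generator with exact ground truth.

Real Ki-67 fields are not distributable alongside the code, so every
stage of the pipeline is exercised against rendered scenes that emulate
the stain appearance: brown (DAB) and blue (hematoxylin) elliptical
nuclei on a bright background, per-pixel Gaussian color jitter, a
configurable fraction of touching same-class pairs, and scattered 1-2 px
pigment speckles.  Rendering is hard-edged (no anti-aliasing) so the
per-pixel ground truth is exact; realism is secondary to testability.

Default colors keep the blue and hue channels separated by >= 60 units
between classes, matching the premise that these two channels carry the
discriminative signal.  The default scene (512 x 512, 30 DAB + 10
hematoxylin nuclei, radius 8-14 px) is the desk-scale stand-in for a
2040 x 1536 field at x400 magnification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi

from .errors import PlacementError
from .io_images import write_label_png

_MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class SceneParams:
    """Scene description; defaults define the reference study conditions."""

    height: int = 512
    width: int = 512
    n_dab: int = 30
    n_hema: int = 10
    radius_range: tuple[float, float] = (8.0, 14.0)
    axis_ratio_range: tuple[float, float] = (0.7, 1.0)
    touching_fraction: float = 0.2
    touching_sep_range: tuple[float, float] = (1.2, 1.6)  # center distance / radius
    dab_color: tuple[int, int, int] = (120, 70, 30)
    hema_color: tuple[int, int, int] = (70, 80, 160)
    bg_color: tuple[int, int, int] = (235, 228, 218)
    color_jitter_sd: float = 8.0
    speckle_density: float = 5e-4
    seed: int = 0

    def __post_init__(self):
        if self.n_dab < 0 or self.n_hema < 0:
            raise ValueError("nucleus counts must be >= 0")
        if self.radius_range[0] < 3:
            raise ValueError("radii must be >= 3 px")
        if not 0.0 <= self.touching_fraction <= 1.0:
            raise ValueError("touching_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class TruthObject:
    id: int
    cls: str                    # "DAB" or "HEMATOXYLIN"
    center: tuple[float, float]  # (row, col)
    radius: float
    area: int
    touching_pair: int | None   # partner object id, if placed as a pair


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-pixel truth for a rendered field."""

    labels: np.ndarray          # (H, W) int32, 0 = background
    objects: tuple[TruthObject, ...] = field(default=())

    @property
    def n_dab(self) -> int:
        return sum(o.cls == "DAB" for o in self.objects)

    @property
    def n_hema(self) -> int:
        return sum(o.cls == "HEMATOXYLIN" for o in self.objects)

    @property
    def positive_percentage(self) -> float | None:
        total = len(self.objects)
        return 100.0 * self.n_dab / total if total else None

    def class_map(self) -> np.ndarray:
        """(H, W) uint8 map of CLASS_* values derived from the labels."""
        from .io_images import CLASS_DAB, CLASS_HEMATOXYLIN

        out = np.zeros(self.labels.shape, dtype=np.uint8)
        for o in self.objects:
            out[self.labels == o.id] = CLASS_DAB if o.cls == "DAB" else CLASS_HEMATOXYLIN
        return out


def _ellipse_mask(h, w, center, r_major, r_minor, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - center[0]
    dx = xx - center[1]
    ca, sa = np.cos(theta), np.sin(theta)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / r_major) ** 2 + (v / r_minor) ** 2 <= 1.0


def touching_pair_mask(
    rng: np.random.Generator,
    radius_range: tuple[float, float] = (8.0, 14.0),
    sep_range: tuple[float, float] = (1.2, 1.6),
    pad: int = 8,
) -> tuple[np.ndarray, tuple, tuple, float]:
    """Render one merged touching pair of equal-radius discs.

    Returns (mask, center1, center2, radius); used by the watershed
    splitting tests as a geometric fixture with known truth.
    """
    r = rng.uniform(*radius_range)
    sep = rng.uniform(*sep_range) * r
    theta = rng.uniform(0, 2 * np.pi)
    side = int(np.ceil(2 * r + sep)) + 2 * pad
    c = side / 2.0
    off = (sep / 2.0 * np.sin(theta), sep / 2.0 * np.cos(theta))
    c1 = (c - off[0], c - off[1])
    c2 = (c + off[0], c + off[1])
    yy, xx = np.mgrid[0:side, 0:side]
    m = ((yy - c1[0]) ** 2 + (xx - c1[1]) ** 2 <= r * r) | (
        (yy - c2[0]) ** 2 + (xx - c2[1]) ** 2 <= r * r
    )
    return m, c1, c2, r


def _place(rng, params: SceneParams):
    """Choose classes, pairings, centers and shapes by rejection sampling."""
    total = params.n_dab + params.n_hema
    n_pairs = int(round(params.touching_fraction * total / 2.0))
    remaining = {"DAB": params.n_dab, "HEMATOXYLIN": params.n_hema}
    pair_classes = []
    for _ in range(n_pairs):
        cls = max(remaining, key=remaining.get)
        if remaining[cls] < 2:
            break
        remaining[cls] -= 2
        pair_classes.append(cls)
    singles = ["DAB"] * remaining["DAB"] + ["HEMATOXYLIN"] * remaining["HEMATOXYLIN"]
    rng.shuffle(singles)

    placed = []  # (center, radius) for overlap rejection

    def fits(center, r, ignore_last=0):
        if not (r + 1 <= center[0] <= params.height - r - 2
                and r + 1 <= center[1] <= params.width - r - 2):
            return False
        pool = placed[: len(placed) - ignore_last] if ignore_last else placed
        for (cy, cx), pr in pool:
            if (center[0] - cy) ** 2 + (center[1] - cx) ** 2 < (r + pr + 2.0) ** 2:
                return False
        return True

    specs = []  # (cls, center, r_major, r_minor, theta, pair_partner_index)
    attempts = 0
    for cls in pair_classes:
        while True:
            attempts += 1
            if attempts > _MAX_ATTEMPTS:
                raise PlacementError("could not pack the requested nuclei")
            r = rng.uniform(*params.radius_range)
            sep = rng.uniform(*params.touching_sep_range) * r
            theta = rng.uniform(0, 2 * np.pi)
            cy = rng.uniform(0, params.height)
            cx = rng.uniform(0, params.width)
            dy, dx = sep * np.sin(theta), sep * np.cos(theta)
            c1, c2 = (cy, cx), (cy + dy, cx + dx)
            if fits(c1, r) and fits(c2, r):
                # ellipses share the pair axis so the lobes surely merge
                ratio = rng.uniform(*params.axis_ratio_range)
                i = len(specs)
                specs.append((cls, c1, r, r * ratio, theta, i + 1))
                specs.append((cls, c2, r, r * ratio, theta, i))
                placed.append((c1, r))
                placed.append((c2, r))
                break
    for cls in singles:
        while True:
            attempts += 1
            if attempts > _MAX_ATTEMPTS:
                raise PlacementError("could not pack the requested nuclei")
            r = rng.uniform(*params.radius_range)
            cy = rng.uniform(0, params.height)
            cx = rng.uniform(0, params.width)
            if fits((cy, cx), r):
                ratio = rng.uniform(*params.axis_ratio_range)
                theta = rng.uniform(0, np.pi)
                specs.append((cls, (cy, cx), r, r * ratio, theta, None))
                placed.append(((cy, cx), r))
                break
    return specs


def generate_field(params: SceneParams | None = None) -> tuple[np.ndarray, GroundTruth]:
    """Render one field and its exact ground truth.

    Objects are drawn in placement order with later objects on top, so a
    contested pixel of a touching pair belongs unambiguously to the
    later (top) object in the truth.  Deterministic given params.seed.
    """
    params = params or SceneParams()
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    specs = _place(rng, params)

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(params.bg_color, dtype=np.float64)
    labels = np.zeros((h, w), dtype=np.int32)
    colors = {"DAB": params.dab_color, "HEMATOXYLIN": params.hema_color}

    objects = []
    for idx, (cls, center, rmaj, rmin, theta, partner) in enumerate(specs, start=1):
        m = _ellipse_mask(h, w, center, rmaj, rmin, theta)
        img[m] = np.asarray(colors[cls], dtype=np.float64)
        labels[m] = idx
        objects.append((idx, cls, center, rmaj, partner))

    # speckles: 1-2 px pigment dots on background, clear of any nucleus
    n_speckles = int(round(params.speckle_density * h * w))
    if n_speckles:
        bg_clear = ndi.binary_erosion(labels == 0, structure=np.ones((5, 5), bool))
        free_idx = np.flatnonzero(bg_clear)
        if free_idx.size:
            chosen = rng.choice(free_idx, size=min(n_speckles, free_idx.size), replace=False)
            extensions = ((0, 1), (1, 0), (1, 1))
            for flat in chosen:
                r0, c0 = divmod(int(flat), w)
                cls = "DAB" if rng.random() < 0.5 else "HEMATOXYLIN"
                img[r0, c0] = np.asarray(colors[cls], dtype=np.float64)
                if rng.random() < 0.5:  # half the speckles are 2 px
                    dr, dc = extensions[int(rng.integers(3))]
                    rr, cc = min(r0 + dr, h - 1), min(c0 + dc, w - 1)
                    img[rr, cc] = np.asarray(colors[cls], dtype=np.float64)

    img += rng.normal(0.0, params.color_jitter_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth_objects = []
    for idx, cls, center, rmaj, partner in objects:
        area = int((labels == idx).sum())
        truth_objects.append(
            TruthObject(id=idx, cls=cls, center=(float(center[0]), float(center[1])),
                        radius=float(rmaj), area=area,
                        touching_pair=None if partner is None else partner + 1)
        )
    return img, GroundTruth(labels=labels, objects=tuple(truth_objects))


def generate_batch(
    out_dir: str | Path,
    section_count: int,
    fields_per_section: int,
    params: SceneParams | None = None,
    master_seed: int = 0,
    percentage_mean: float = 75.1,
    percentage_sd: float = 6.7,
) -> Path:
    """Write a sections/fields dataset emulating the study design.

    Each section draws a target positive percentage from
    Normal(percentage_mean, percentage_sd) clipped to [2, 98]; each of
    its fields draws n_dab ~ Binomial(n_total, target/100).  Layout:
    <out>/section_XX/field_YY.png, .truth.png (16-bit labels),
    .truth.json.  Byte-identical given the same master seed.
    """
    if section_count < 1 or fields_per_section < 1:
        raise ValueError("section and field counts must be >= 1")
    params = params or SceneParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_total = params.n_dab + params.n_hema
    master = np.random.default_rng(master_seed)
    for s in range(1, section_count + 1):
        sdir = out_dir / f"section_{s:02d}"
        sdir.mkdir(exist_ok=True)
        target = float(np.clip(master.normal(percentage_mean, percentage_sd), 2.0, 98.0))
        for f in range(1, fields_per_section + 1):
            n_dab = int(master.binomial(n_total, target / 100.0))
            seed = int(master.integers(0, 2**31 - 1))
            fparams = replace(params, n_dab=n_dab, n_hema=n_total - n_dab, seed=seed)
            img, truth = generate_field(fparams)
            stem = sdir / f"field_{f:02d}"
            Image.fromarray(img).save(stem.with_suffix(".png"))
            write_label_png(truth.labels, Path(str(stem) + ".truth.png"))
            meta = {
                "section_target_percentage": target,
                "n_dab": truth.n_dab,
                "n_hema": truth.n_hema,
                "positive_percentage": truth.positive_percentage,
                "objects": [
                    {"id": o.id, "class": o.cls, "center": list(o.center),
                     "radius": o.radius, "area": o.area}
                    for o in truth.objects
                ],
                "seed": seed,
            }
            Path(str(stem) + ".truth.json").write_text(
                json.dumps(meta, indent=2, sort_keys=True) + "\n"
            )
    return out_dir
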