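"""Controlled dot-display stimulus generation for numerosity experiments.

Stimuli are 224x224 grayscale images containing 0..N bright items on a dark
background.  Three stimulus sets dissociate numerosity from low-level visual
cues:

* ``standard`` — items are discs whose radii are drawn from U(12, 24) px,
  so the average radius (18 px) is constant across numerosities while
  individual dots vary in size; total bright area grows linearly with
  numerosity in expectation.
* ``control1`` — total item area is fixed at 1200 px^2 (items shrink as
  numerosity grows), the mean pairwise distance between item centers is held
  in the 90–100 px band (a density control), and the image-mean luminance is
  held at the 20% level for every numerosity by raising the uniform
  background.
* ``control2`` — item shapes are drawn uniformly from {circle, rectangle,
  ellipse, triangle}, each area-matched to the radius-18 disc, and for
  numerosities above 2 the convex hull of the item centers is a triangle of
  random location and orientation.

Numerosity 0 is an item-free background (pure dark, except in ``control1``
where the luminance-equating background level applies).  Rendering is
analytic (per-pixel inclusion tests, no anti-aliasing), so connected-
component counting on the rendered image is exact; items are placed fully
inside the image with a >= 2 px gap between item boundaries.

``audit_stimulus`` is the independent verification oracle: it re-measures
every constraint from the rendered pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Item",
    "StimulusSpec",
    "StimulusManifest",
    "AuditReport",
    "GenerationError",
    "STANDARD_RADIUS",
    "CONTROL1_TOTAL_AREA",
    "SETS",
    "generate_stimulus",
    "generate_manifest",
    "render",
    "audit_stimulus",
    "save_manifest",
]

SETS = ("standard", "control1", "control2")
SHAPES = ("circle", "rectangle", "ellipse", "triangle")

STANDARD_RADIUS = 18.0  # mean dot radius
RADIUS_RANGE = (12.0, 24.0)  # per-dot radii are uniform on this range
AREA_SHARE_RANGE = (0.7, 1.3)  # relative spread of per-dot areas in control1
CONTROL1_TOTAL_AREA = 1200.0
CONTROL1_DIST_RANGE = (90.0, 100.0)
CONTROL1_LUMINANCE = 0.20
FOREGROUND = 1.0
GAP = 2.0  # minimum gap between item boundaries and to the image border
MAX_ATTEMPTS = 10_000
REFERENCE_SIZE = 224  # geometric constants above refer to this image size


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy a placement constraint."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass
class Item:
    shape: str  # circle | rectangle | ellipse | triangle
    cx: float
    cy: float
    params: dict  # shape-specific sizes in pixels
    orientation: float = 0.0  # degrees
    intensity: float = FOREGROUND

    def circumradius(self) -> float:
        p = self.params
        if self.shape == "circle":
            return p["radius"]
        if self.shape == "rectangle":
            return 0.5 * float(np.hypot(p["width"], p["height"]))
        if self.shape == "ellipse":
            return max(p["a"], p["b"])
        if self.shape == "triangle":
            return p["circumradius"]
        raise ValueError(self.shape)

    def mask(self, size: int) -> np.ndarray:
        """Boolean inclusion mask on the pixel grid (pixel centers)."""
        yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
        u = xx - self.cx
        v = yy - self.cy
        th = np.deg2rad(self.orientation)
        ur = np.cos(th) * u + np.sin(th) * v
        vr = -np.sin(th) * u + np.cos(th) * v
        p = self.params
        if self.shape == "circle":
            return u * u + v * v <= p["radius"] ** 2
        if self.shape == "rectangle":
            return (np.abs(ur) <= p["width"] / 2) & (np.abs(vr) <= p["height"] / 2)
        if self.shape == "ellipse":
            return (ur / p["a"]) ** 2 + (vr / p["b"]) ** 2 <= 1.0
        if self.shape == "triangle":
            R = p["circumradius"]
            ang = np.deg2rad(self.orientation) + np.array([0, 2, 4]) * np.pi / 3
            vx = self.cx + R * np.cos(ang)
            vy = self.cy + R * np.sin(ang)
            inside = np.ones((size, size), bool)
            for i in range(3):
                ex, ey = vx[(i + 1) % 3] - vx[i], vy[(i + 1) % 3] - vy[i]
                cross = ex * (yy - vy[i]) - ey * (xx - vx[i])
                inside &= cross <= 0 if _signed_area(vx, vy) < 0 else cross >= 0
            return inside
        raise ValueError(self.shape)


def _signed_area(vx, vy) -> float:
    return 0.5 * float(
        (vx[1] - vx[0]) * (vy[2] - vy[0]) - (vx[2] - vx[0]) * (vy[1] - vy[0])
    )


@dataclass
class StimulusSpec:
    numerosity: int
    set_id: str
    items: list[Item]
    background_intensity: float = 0.0
    image_size: int = 224

    def __post_init__(self):
        if self.set_id not in SETS:
            raise ValueError(f"unknown stimulus set {self.set_id!r}")
        if self.numerosity != len(self.items):
            raise ValueError("numerosity must equal the number of items")


def render(spec: StimulusSpec) -> np.ndarray:
    """Rasterize to a float32 image in [0, 1]; no anti-aliasing."""
    img = np.full((spec.image_size, spec.image_size), spec.background_intensity,
                  dtype=np.float32)
    for it in spec.items:
        img[it.mask(spec.image_size)] = it.intensity
    return img


def _mask_area(item: Item, size: int) -> int:
    return int(item.mask(size).sum())


def _calibrate_disc_radius(cx, cy, target_area, size) -> float:
    """Pick the disc radius whose rasterized pixel count is closest to
    ``target_area`` at this sub-pixel center."""
    r0 = float(np.sqrt(target_area / np.pi))
    best, best_err = r0, np.inf
    for r in np.linspace(r0 - 1.5, r0 + 1.5, 25):
        a = _mask_area(Item("circle", cx, cy, {"radius": r}), size)
        err = abs(a - target_area)
        if err < best_err:
            best, best_err = r, err
    return best


# ---------------------------------------------------------------------------
# Placement sampling
# ---------------------------------------------------------------------------


def _sample_centers(rng, n, radii, size, dist_range=None, max_attempts=MAX_ATTEMPTS):
    """Centers with pairwise boundary gaps >= GAP, fully inside the image,
    optionally with mean pairwise distance inside ``dist_range``."""
    for _ in range(max_attempts):
        pts = np.empty((n, 2))
        for i in range(n):
            m = radii[i] + GAP
            pts[i] = rng.uniform(m, size - 1 - m, 2)
        ok = True
        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(*(pts[i] - pts[j])) < radii[i] + radii[j] + GAP:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        if dist_range is not None and n >= 2:
            d = [
                np.hypot(*(pts[i] - pts[j]))
                for i in range(n)
                for j in range(i + 1, n)
            ]
            if not (dist_range[0] <= np.mean(d) <= dist_range[1]):
                continue
        return pts
    constraint = "mean pairwise distance" if dist_range else "non-overlap placement"
    raise GenerationError(
        f"could not satisfy {constraint} for n={n} after {max_attempts} attempts"
    )


def _random_shape(rng, cx, cy, target_area) -> Item:
    """An item of random shape, area-matched to ``target_area``."""
    shape = SHAPES[rng.integers(len(SHAPES))]
    ori = float(rng.uniform(0, 360))
    if shape == "circle":
        return Item("circle", cx, cy, {"radius": float(np.sqrt(target_area / np.pi))})
    if shape == "rectangle":
        aspect = float(rng.uniform(0.5, 2.0))
        w = float(np.sqrt(target_area * aspect))
        return Item("rectangle", cx, cy, {"width": w, "height": target_area / w}, ori)
    if shape == "ellipse":
        aspect = float(rng.uniform(0.5, 2.0))
        a = float(np.sqrt(target_area * aspect / np.pi))
        return Item("ellipse", cx, cy, {"a": a, "b": target_area / (np.pi * a)}, ori)
    # equilateral triangle of matching area: A = (3*sqrt(3)/4) * R^2
    R = float(np.sqrt(target_area * 4 / (3 * np.sqrt(3))))
    return Item("triangle", cx, cy, {"circumradius": R}, ori)


def _triangle_hull_centers(
    rng, n, radii, size, max_attempts=MAX_ATTEMPTS, min_area=6000.0
):
    """n >= 3 centers whose convex hull is a robust triangle: three at the
    vertices of a random triangle, any remainder strictly inside it."""
    for _ in range(max_attempts):
        try:
            verts = _sample_centers(rng, 3, radii[:3], size, max_attempts=50)
        except GenerationError:
            continue
        area = abs(_signed_area(verts[:, 0], verts[:, 1]))
        if area < min_area:  # near-collinear triangles make a fragile hull
            continue
        pts = [verts[0], verts[1], verts[2]]
        ok = True
        for i in range(3, n):
            placed = False
            for _ in range(200):
                u, v = rng.uniform(0.15, 0.85, 2)
                if u + v > 0.85:
                    continue
                p = verts[0] + u * (verts[1] - verts[0]) + v * (verts[2] - verts[0])
                m = radii[i] + GAP
                if not (m <= p[0] <= size - 1 - m and m <= p[1] <= size - 1 - m):
                    continue
                if any(
                    np.hypot(*(p - q)) < radii[i] + radii[k] + GAP
                    for k, q in enumerate(pts)
                ):
                    continue
                pts.append(p)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(pts)
    raise GenerationError(
        f"could not build a triangular convex hull for n={n} "
        f"after {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Per-set generation
# ---------------------------------------------------------------------------


def generate_stimulus(
    numerosity: int,
    set_id: str,
    rng: np.random.Generator,
    image_size: int = 224,
    radius_range: tuple[float, float] | None = None,
) -> tuple[StimulusSpec, np.ndarray]:
    """Generate one stimulus satisfying all constraints of its set, and its
    rendered image.

    For reduced image sizes (test variants) every geometric constant —
    radii, areas, distance bands — scales with image_size/224 so the
    displays keep the reference proportions.  ``radius_range`` overrides
    the default per-dot radius distribution (mean 18 px); wide-range
    protocols (numerosities well above ~8) need smaller dots to remain
    packable.
    """
    if numerosity < 0:
        raise ValueError("numerosity must be >= 0")
    if set_id not in SETS:
        raise ValueError(f"unknown stimulus set {set_id!r}")
    n, S = numerosity, image_size
    sc = image_size / REFERENCE_SIZE
    rr = radius_range if radius_range is not None else RADIUS_RANGE

    if set_id == "standard":
        bg = 0.0
        items = []
        if n:
            radii = sc * rng.uniform(*rr, size=n)
            pts = _sample_centers(rng, n, radii, S)
            items = [
                Item("circle", float(x), float(y), {"radius": float(r)})
                for (x, y), r in zip(pts, radii)
            ]
    elif set_id == "control1":
        bg = CONTROL1_LUMINANCE if n == 0 else _control1_background(S)
        items = []
        if n:
            shares = rng.uniform(*AREA_SHARE_RANGE, size=n)
            areas = sc**2 * CONTROL1_TOTAL_AREA * shares / shares.sum()
            radii = np.sqrt(areas / np.pi)
            # sample in a band slightly inside [90,100] to leave audit slack
            band = (
                sc * (CONTROL1_DIST_RANGE[0] + 0.5),
                sc * (CONTROL1_DIST_RANGE[1] - 0.5),
            )
            pts = _sample_centers(
                rng, n, radii, S, dist_range=band if n >= 2 else None
            )
            for (x, y), a in zip(pts, areas):
                rr = _calibrate_disc_radius(float(x), float(y), float(a), S)
                items.append(Item("circle", float(x), float(y), {"radius": rr}))
    else:  # control2
        bg = 0.0
        items = []
        if n:
            # draw shapes first so circumradii are known for placement
            protos = [
                _random_shape(
                    rng, 0.0, 0.0, np.pi * (sc * rng.uniform(*rr)) ** 2
                )
                for _ in range(n)
            ]
            radii = [it.circumradius() for it in protos]
            if n > 2:
                pts = _triangle_hull_centers(rng, n, radii, S, min_area=6000 * sc**2)
            else:
                pts = _sample_centers(rng, n, radii, S)
            for it, (x, y) in zip(protos, pts):
                it.cx, it.cy = float(x), float(y)
            items = protos

    spec = StimulusSpec(n, set_id, items, background_intensity=bg, image_size=S)
    return spec, render(spec)


def _control1_background(size: int) -> float:
    """Uniform background level making the image-mean luminance equal the 20%
    target given the (size-scaled) fixed foreground area at full intensity."""
    total = size * size
    area = CONTROL1_TOTAL_AREA * (size / REFERENCE_SIZE) ** 2
    return float(
        (CONTROL1_LUMINANCE * total - area * FOREGROUND) / (total - area)
    )


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------


@dataclass
class StimulusManifest:
    """A balanced batch of stimuli with its metadata table.

    ``table`` has one row per stimulus: id, set, numerosity.  ``images`` is
    the (n, size, size) float32 stack in table order.
    """

    specs: list[StimulusSpec]
    images: np.ndarray
    table: pd.DataFrame
    rng_seed: int
    numerosities: tuple = ()
    sets: tuple = ()

    @property
    def n_stimuli(self) -> int:
        return len(self.specs)

    def cell_counts(self) -> pd.DataFrame:
        return self.table.groupby(["numerosity", "set"]).size().unstack()


def generate_manifest(
    numerosities: Sequence[int],
    sets: Sequence[str],
    n_total: int,
    rng_seed: int,
    image_size: int = 224,
    radius_range: tuple[float, float] | None = None,
) -> StimulusManifest:
    """A balanced stimulus batch: n_total / (len(numerosities)*len(sets))
    images per (numerosity, set) cell, reproducible from ``rng_seed``."""
    numerosities = list(numerosities)
    sets = list(sets)
    cells = len(numerosities) * len(sets)
    if n_total % cells:
        raise ValueError(
            f"n_total={n_total} is not divisible by the {cells} "
            "(numerosity x set) cells"
        )
    per_cell = n_total // cells
    rng = np.random.default_rng(rng_seed)
    specs, imgs, rows = [], [], []
    i = 0
    for n in numerosities:
        for s in sets:
            for _ in range(per_cell):
                spec, img = generate_stimulus(n, s, rng, image_size, radius_range)
                specs.append(spec)
                imgs.append(img)
                rows.append({"id": i, "set": s, "numerosity": n})
                i += 1
    return StimulusManifest(
        specs=specs,
        images=np.stack(imgs),
        table=pd.DataFrame(rows),
        rng_seed=rng_seed,
        numerosities=tuple(numerosities),
        sets=tuple(sets),
    )


def save_manifest(manifest: StimulusManifest, out_dir: str) -> None:
    """Write one 8-bit grayscale PNG per stimulus plus a CSV/JSON manifest."""
    import os
    from PIL import Image

    os.makedirs(out_dir, exist_ok=True)
    names = []
    counter: dict = {}
    for spec, img, (_, row) in zip(
        manifest.specs, manifest.images, manifest.table.iterrows()
    ):
        key = (row["set"], row["numerosity"])
        k = counter.get(key, 0)
        counter[key] = k + 1
        name = f"{row['set']}_{row['numerosity']}_{k:03d}.png"
        names.append(name)
        Image.fromarray((img * 255).round().astype(np.uint8), mode="L").save(
            os.path.join(out_dir, name)
        )
    table = manifest.table.copy()
    table["filename"] = names
    table.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(
            {
                "rng_seed": manifest.rng_seed,
                "stimuli": [
                    {
                        "id": int(row["id"]),
                        "set": row["set"],
                        "numerosity": int(row["numerosity"]),
                        "filename": name,
                        "background_intensity": spec.background_intensity,
                        "items": [asdict(it) for it in spec.items],
                    }
                    for (_, row), name, spec in zip(
                        table.iterrows(), names, manifest.specs
                    )
                ],
            },
            fh,
            indent=1,
        )


# ---------------------------------------------------------------------------
# Audit oracle
# ---------------------------------------------------------------------------


@dataclass
class AuditReport:
    n_components: int
    foreground_area: float
    mean_luminance: float
    mean_pairwise_distance: float | None
    hull_vertices: int | None
    checks: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def audit_stimulus(image: np.ndarray, claimed: StimulusSpec) -> AuditReport:
    """Re-measure every set constraint from the rendered pixels.

    Components are found by 8-connected labeling of pixels brighter than the
    claimed background; centers are component centroids.
    """
    from scipy.spatial import ConvexHull, QhullError
    from skimage import measure

    img = np.asarray(image, dtype=np.float64)
    fg = img > claimed.background_intensity + 0.05
    labels = measure.label(fg, connectivity=2)
    props = measure.regionprops(labels)
    n_comp = len(props)
    area = float(fg.sum())
    lum = float(img.mean())
    centers = np.array([[p.centroid[1], p.centroid[0]] for p in props])

    mpd = None
    if n_comp >= 2:
        d = [
            float(np.hypot(*(centers[i] - centers[j])))
            for i in range(n_comp)
            for j in range(i + 1, n_comp)
        ]
        mpd = float(np.mean(d))

    hull_v = None
    if n_comp >= 3:
        try:
            hull_v = len(ConvexHull(centers).vertices)
        except QhullError:
            hull_v = 2  # collinear

    checks = {"component_count": n_comp == claimed.numerosity}
    n = claimed.numerosity
    if claimed.set_id == "standard" and n:
        claimed_areas = sorted(np.pi * it.params["radius"] ** 2 for it in claimed.items)
        measured = sorted(p.area for p in props)
        checks["component_areas"] = len(measured) == n and all(
            abs(a - c) <= 0.05 * c + 4 for a, c in zip(measured, claimed_areas)
        )
    if claimed.set_id == "control1":
        sc = claimed.image_size / REFERENCE_SIZE
        target_area = CONTROL1_TOTAL_AREA * sc**2
        if n >= 1:
            checks["total_area"] = abs(area - target_area) <= 0.02 * target_area
        if n >= 2:
            checks["mean_pairwise_distance"] = (
                mpd is not None
                and sc * CONTROL1_DIST_RANGE[0] <= mpd <= sc * CONTROL1_DIST_RANGE[1]
            )
        checks["mean_luminance"] = abs(lum - CONTROL1_LUMINANCE) <= 0.01
    if claimed.set_id == "control2" and n > 2:
        checks["triangular_hull"] = hull_v == 3
    if n == 0:
        checks["no_bright_pixels"] = n_comp == 0 and area == 0.0

    return AuditReport(
        n_components=n_comp,
        foreground_area=area,
        mean_luminance=lum,
        mean_pairwise_distance=mpd,
        hull_vertices=hull_v,
        checks=checks,
    )
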