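"""Synthetic WGA-like muscle phantoms and topology test fixtures.

Wheat-germ-agglutinin staining outlines muscle fiber membranes in the
green channel, leaves the red channel essentially empty, and nuclei
(DAPI-like) appear as small bright blobs in the blue channel.  Healthy
muscle shows polygonal fibers of fairly uniform cross-section with
*peripheral* nuclei hugging the membrane; diseased muscle (ALS-like or
diabetic-like myopathy) shows *central* nucleation and stronger fiber
size variability.  The phantoms emulate exactly those morphological
contrasts on a Voronoi fiber mosaic:

* fibers: Voronoi cells of seeded points; seed clustering (driven by
  ``fiber_size_cv``) produces the small/irregular fibers of disease;
* membranes: boundaries between Voronoi cells, drawn bright green;
* nuclei: one Gaussian blob per fiber in the blue channel, placed at the
  fiber centroid with probability ``central_nucleus_prob`` and within a
  couple of pixels of the membrane otherwise.

Placement has a visible topological consequence: in the gray luminance
channel a central nucleus is an isolated bright island (one extra loop in
the sublevel filtration), while a peripheral nucleus fuses with the
bright membrane network and creates none — the kind of global signal the
topological block is designed to read.

Everything is a pure function of (config, seed): identical inputs give
bit-identical images.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from scipy.spatial import cKDTree

from .preprocess import ImageRecord, record_from_rgb

#: Study conditions: per-class morphology knobs.
HEALTHY = {"central_nucleus_prob": 0.05, "fiber_size_cv": 0.2}
DISEASED = {"central_nucleus_prob": 0.8, "fiber_size_cv": 0.6}
LABELS = {"healthy": 0, "diseased": 1}


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic WGA-like image."""

    image_size: int = 224
    n_fibers: int = 60
    class_label: str = "healthy"
    central_nucleus_prob: float = 0.05
    fiber_size_cv: float = 0.2
    membrane_intensity: int = 220
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.central_nucleus_prob <= 1.0:
            raise ValueError("central_nucleus_prob must lie in [0, 1]")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.n_fibers > self.image_size ** 2:
            raise ValueError(
                f"cannot pack {self.n_fibers} fibers into a "
                f"{self.image_size}x{self.image_size} image"
            )
        if self.class_label not in LABELS:
            raise ValueError(f"class_label must be one of {sorted(LABELS)}")


def class_config(label: str, **overrides) -> PhantomConfig:
    """A PhantomConfig preset to the study conditions of one class."""
    params = dict(HEALTHY if label == "healthy" else DISEASED)
    params.update(overrides)
    return PhantomConfig(class_label=label, **params)


def _voronoi_labels(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Label image of the fiber mosaic (nearest-seed partition)."""
    n, size = config.n_fibers, config.image_size
    seeds = rng.uniform(0, size, size=(n, 2))
    if config.fiber_size_cv <= 0.35:
        # near-uniform fibers: a couple of Lloyd relaxation steps
        for _ in range(2):
            tree = cKDTree(seeds)
            yy, xx = np.mgrid[0:size, 0:size]
            lab = tree.query(np.column_stack([yy.ravel(), xx.ravel()]))[1]
            for k in range(n):
                pts = np.flatnonzero(lab == k)
                if pts.size:
                    seeds[k] = [yy.ravel()[pts].mean(), xx.ravel()[pts].mean()]
    else:
        # irregular fibers: pull a subset of seeds toward attractor points,
        # creating clusters of small fibers next to large ones
        n_attr = max(2, n // 15)
        attractors = rng.uniform(0, size, size=(n_attr, 2))
        pull = rng.random(n) < 0.6
        nearest = cKDTree(attractors).query(seeds)[1]
        strength = min(0.85, float(config.fiber_size_cv))
        seeds[pull] += strength * (attractors[nearest[pull]] - seeds[pull])
    tree = cKDTree(seeds)
    yy, xx = np.mgrid[0:size, 0:size]
    return tree.query(np.column_stack([yy.ravel(), xx.ravel()]))[1].reshape(size, size)


def _draw_blob(plane: np.ndarray, y: float, x: float, sigma: float,
               amplitude: float) -> None:
    size = plane.shape[0]
    rad = int(np.ceil(3 * sigma))
    y0, y1 = max(0, int(y) - rad), min(size, int(y) + rad + 1)
    x0, x1 = max(0, int(x) - rad), min(size, int(x) + rad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    blob = amplitude * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma ** 2))
    np.maximum(plane[y0:y1, x0:x1], blob, out=plane[y0:y1, x0:x1])


def make_fiber_phantom(config: PhantomConfig) -> ImageRecord:
    """Render one synthetic WGA-like RGB image.

    The returned record's ``meta`` carries ground truth for testing:
    nucleus centers with their central/peripheral flag and distance to the
    membrane, plus the membrane mask and fiber label image.
    """
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    labels = _voronoi_labels(config, rng)

    # membranes: pixels whose 4-neighborhood crosses a fiber boundary
    boundary = np.zeros((size, size), dtype=bool)
    boundary[:-1, :] |= labels[:-1, :] != labels[1:, :]
    boundary[1:, :] |= labels[:-1, :] != labels[1:, :]
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    boundary[:, 1:] |= labels[:, :-1] != labels[:, 1:]

    dist_to_membrane = ndimage.distance_transform_edt(~boundary)

    green = np.full((size, size), 20.0)
    green[boundary] = float(config.membrane_intensity)
    red = np.full((size, size), 2.0)
    blue = np.full((size, size), 10.0)

    sigma = max(1.2, 1.8 * size / 224)
    nuclei: list[dict] = []
    for k in range(config.n_fibers):
        ys, xs = np.nonzero(labels == k)
        if ys.size < 9:  # fiber collapsed to nothing drawable
            continue
        central = bool(rng.random() < config.central_nucleus_prob)
        if central:
            idx = np.argmax(dist_to_membrane[ys, xs])  # innermost pixel
            cy, cx = float(ys[idx]), float(xs[idx])
        else:
            d = dist_to_membrane[ys, xs]
            ring = np.flatnonzero((d >= 1.0) & (d <= 2.0))
            if ring.size == 0:
                ring = np.flatnonzero(d <= 2.0)
            pick = ring[rng.integers(ring.size)]
            cy, cx = float(ys[pick]), float(xs[pick])
        _draw_blob(blue, cy, cx, sigma, 200.0)
        nuclei.append({
            "y": cy, "x": cx, "central": central,
            "dist_to_membrane": float(dist_to_membrane[int(cy), int(cx)]),
        })

    rgb = np.stack([red, green, blue], axis=-1)
    rgb += rng.normal(0.0, config.noise_sd, size=rgb.shape)
    rgb = np.rint(rgb).clip(0, 255).astype(np.uint8)
    return record_from_rgb(
        rgb,
        id=f"phantom_{config.class_label}_{config.seed}",
        label=LABELS[config.class_label],
        meta={"nuclei": nuclei, "membrane": boundary, "fiber_labels": labels,
              "config": config},
    )


def make_topology_fixture(kind: str, k: int = 0, size: int = 64,
                          low: int = 50, high: int = 200) -> ImageRecord:
    """Grayscale images with known sublevel-set topology.

    * ``constant``: uniform image at ``low``.
    * ``k_disks``: k disjoint filled disks at ``low`` on background ``high``
      — k components at thresholds between the two levels.
    * ``k_annuli``: k disjoint rings at ``low`` on background ``high`` — k
      components and k independent loops between the levels.
    * ``checker``: alternating low/high checkerboard.
    """
    if k < 0 or low >= high:
        raise ValueError("need k >= 0 and low < high")
    plane = np.full((size, size), float(high))
    if kind == "constant":
        plane[:] = low
    elif kind in ("k_disks", "k_annuli"):
        per_row = int(np.ceil(np.sqrt(k))) if k else 1
        spacing = size // per_row
        radius = spacing // 4
        if k and (radius < 3 or per_row * per_row < k):
            raise ValueError(f"cannot place {k} disjoint shapes in size {size}")
        yy, xx = np.mgrid[0:size, 0:size]
        for m in range(k):
            cy = (m // per_row) * spacing + spacing // 2
            cx = (m % per_row) * spacing + spacing // 2
            r2 = (yy - cy) ** 2 + (xx - cx) ** 2
            if kind == "k_disks":
                plane[r2 <= radius ** 2] = low
            else:
                inner = max(1, radius - 2)
                plane[(r2 <= radius ** 2) & (r2 >= inner ** 2)] = low
    elif kind == "checker":
        cell = max(1, size // 8)
        yy, xx = np.mgrid[0:size, 0:size]
        plane[((yy // cell) + (xx // cell)) % 2 == 0] = low
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    rgb = np.stack([plane] * 3, axis=-1).astype(np.uint8)
    return record_from_rgb(rgb, id=f"fixture_{kind}_{k}",
                           meta={"kind": kind, "k": k, "low": low, "high": high})


def make_dataset(n_per_class: int, base_config: PhantomConfig | None = None,
                 seed: int = 0, out_dir: str | os.PathLike | None = None,
                 ) -> tuple[list[ImageRecord], pd.DataFrame]:
    """Generate a balanced two-class phantom set (optionally written to disk).

    Per-image seeds are derived deterministically from ``seed``; the same
    seed reproduces identical files and manifest ordering.  When
    ``out_dir`` is given, PNGs plus a ``manifest.csv`` with header
    ``path,label`` are written there.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = base_config or PhantomConfig()
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_class)
    child_seeds = (child_seeds % np.uint32(2 ** 31)).astype(np.int64)

    records: list[ImageRecord] = []
    rows: list[dict] = []
    i = 0
    for label_name in ("healthy", "diseased"):
        params = dict(HEALTHY if label_name == "healthy" else DISEASED)
        for j in range(n_per_class):
            cfg = dataclasses.replace(base, class_label=label_name,
                                      seed=int(child_seeds[i]), **params)
            rec = make_fiber_phantom(cfg)
            fname = f"phantom_{i:04d}_{label_name}.png"
            rec = dataclasses.replace(rec, id=fname)
            records.append(rec)
            rows.append({"path": fname, "label": LABELS[label_name]})
            i += 1
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for rec in records:
            rgb = np.stack([rec.channels["red"], rec.channels["green"],
                            rec.channels["blue"]], axis=-1)
            Image.fromarray(rgb).save(os.path.join(out_dir, rec.id))
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return records, manifest
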