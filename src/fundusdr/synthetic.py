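"""Seeded generator of schematic 5-grade fundus-like images.

Each image is a circular retina disc on a dark background, a bright
optic-disc blob, a handful of smooth dark vessel curves, and
grade-dependent lesions: small dark dots (microaneurysm-like) and
brighter compact blobs (exudate-like).  Lesion *counts* increase
strictly with grade and the count ranges do not overlap between grades,
so severity is decodable from lesion burden alone — a deliberately
learnable signal for desk-scale training, not a model of real fundus
photograph statistics.

Images are RGB uint8 with vessels and lesions expressed most strongly in
the green channel, mirroring real fundus imagery where the green plane
carries the vascular contrast.  Everything is a pure function of
(config, grade, seed): the same inputs yield byte-identical arrays.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FundusSynthConfig",
    "SyntheticFundus",
    "generate_fundus",
    "generate_arrays",
    "generate_dataset",
    "DEFAULT_LESION_COUNTS",
]

# grade -> ((microaneurysm count min, max), (exudate count min, max));
# totals are disjoint across grades: 0, 3-5, 10-13, 19-24, 32-39.
DEFAULT_LESION_COUNTS: dict[int, tuple[tuple[int, int], tuple[int, int]]] = {
    0: ((0, 0), (0, 0)),
    1: ((2, 3), (1, 2)),
    2: ((6, 8), (4, 5)),
    3: ((12, 15), (7, 9)),
    4: ((20, 24), (12, 15)),
}


@dataclass(frozen=True)
class FundusSynthConfig:
    """Configuration of the synthetic fundus generator.

    Defaults: 64x64 RGB images, all five grades, 25 images per grade,
    4 vessels, Gaussian pixel noise with sd 4 (on the 0..255 scale).
    """

    image_size: int = 64
    grades: tuple[int, ...] = (0, 1, 2, 3, 4)
    per_grade_n: int = 25
    lesion_counts: dict[int, tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=lambda: dict(DEFAULT_LESION_COUNTS)
    )
    vessel_count: int = 4
    noise_sd: float = 4.0
    seed: int = 0
    test_fraction: float = 0.15

    def __post_init__(self):
        if any(g not in range(5) for g in self.grades):
            raise ValueError(f"grades must be within 0..4; got {self.grades}")
        lo, hi = self.lesion_counts.get(0, ((0, 0), (0, 0)))
        if lo != (0, 0) or hi != (0, 0):
            raise ValueError("grade 0 must have zero lesions")
        totals = {
            g: (c[0][0] + c[1][0], c[0][1] + c[1][1])
            for g, c in sorted(self.lesion_counts.items())
        }
        prev_hi = -1
        for g, (tlo, thi) in totals.items():
            if tlo <= prev_hi:
                raise ValueError(
                    "total lesion-count ranges must strictly increase with "
                    f"grade; grade {g} overlaps the previous grade"
                )
            prev_hi = thi


@dataclass(frozen=True)
class SyntheticFundus:
    """One generated image plus its label and lesion ground truth."""

    image: np.ndarray  # HxWx3 uint8
    grade: int
    lesion_mask: np.ndarray  # HxW bool
    seed: int


def _disc_mask(n: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _gaussian_blob(n: int, cx: float, cy: float, sigma: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    return np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)))


def _draw_vessel(canvas: np.ndarray, rng: np.random.Generator,
                 cx: float, cy: float, r: float) -> None:
    """Subtract a smooth random-walk curve (dark vessel) from the canvas."""
    n = canvas.shape[0]
    ang = rng.uniform(0.0, 2.0 * np.pi)
    x, y = cx, cy
    heading = ang
    width = rng.uniform(0.8, 1.2)
    depth = rng.uniform(35.0, 45.0)
    for _ in range(int(3 * r)):
        heading += rng.normal(0.0, 0.18)
        x += np.cos(heading)
        y += np.sin(heading)
        if (x - cx) ** 2 + (y - cy) ** 2 > r * r:
            break
        canvas -= depth * _gaussian_blob(n, x, y, width)
    del n  # canvas modified in place


def generate_fundus(
    grade: int, cfg: FundusSynthConfig | None = None, seed: int = 0
) -> SyntheticFundus:
    """Generate one grade-labelled synthetic fundus image.

    Deterministic in ``(grade, cfg, seed)``.  Returns the RGB image, the
    grade, and a boolean mask marking every lesion pixel (empty for
    grade 0).
    """
    cfg = cfg or FundusSynthConfig()
    if grade not in cfg.grades:
        raise ValueError(f"grade {grade!r} not in configured grades {cfg.grades}")
    n = cfg.image_size
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), int(grade), int(seed)])
    )

    cx = n / 2 + rng.uniform(-1.0, 1.0)
    cy = n / 2 + rng.uniform(-1.0, 1.0)
    r = 0.44 * n
    retina = _disc_mask(n, cx, cy, r)

    # retinal background: mid-level green-dominated field with slow shading
    base = np.zeros((n, n), dtype=float)
    base[retina] = 120.0
    shade = _gaussian_blob(n, cx + rng.uniform(-3, 3), cy + rng.uniform(-3, 3),
                           0.8 * r)
    green = base * (0.75 + 0.45 * shade)

    # optic disc: bright blob near the rim
    od_ang = rng.uniform(0.0, 2.0 * np.pi)
    od_x = cx + 0.55 * r * np.cos(od_ang)
    od_y = cy + 0.55 * r * np.sin(od_ang)
    green += 90.0 * _gaussian_blob(n, od_x, od_y, 0.09 * n)

    for _ in range(cfg.vessel_count):
        _draw_vessel(green, rng, cx, cy, r)

    # lesions
    (ma_lo, ma_hi), (ex_lo, ex_hi) = cfg.lesion_counts[grade]
    n_ma = int(rng.integers(ma_lo, ma_hi + 1))
    n_ex = int(rng.integers(ex_lo, ex_hi + 1))
    lesion_mask = np.zeros((n, n), dtype=bool)

    def _lesion_site():
        while True:
            a = rng.uniform(0.0, 2.0 * np.pi)
            rr = r * np.sqrt(rng.uniform(0.0, 0.72))
            x, y = cx + rr * np.cos(a), cy + rr * np.sin(a)
            # keep clear of the optic disc so lesions stay visible
            if (x - od_x) ** 2 + (y - od_y) ** 2 > (0.12 * n) ** 2:
                return x, y

    # lesion sizes are chosen to survive the 2x downsample to the 32x32
    # training resolution (sigma >= ~1 pixel at generation scale)
    for _ in range(n_ma):  # dark dots
        x, y = _lesion_site()
        sigma = rng.uniform(1.3, 1.5)
        green -= 120.0 * _gaussian_blob(n, x, y, sigma)
        lesion_mask |= _disc_mask(n, x, y, 1.7 * sigma)
    for _ in range(n_ex):  # bright blobs
        x, y = _lesion_site()
        sigma = rng.uniform(2.0, 2.4)
        green += 140.0 * _gaussian_blob(n, x, y, sigma)
        lesion_mask |= _disc_mask(n, x, y, 1.7 * sigma)
    lesion_mask &= retina

    green += rng.normal(0.0, cfg.noise_sd, size=(n, n))
    green[~retina] = rng.uniform(0.0, 6.0, size=(~retina).sum())

    red = 0.55 * green + 25.0 * retina
    blue = 0.25 * green
    img = np.stack([red, green, blue], axis=-1)
    # guarantee the full 0..255 range so fuzzification is well defined
    img = np.clip(img, 0.0, 255.0)
    img[0, 0] = (0.0, 0.0, 0.0)
    img[-1, -1] = (255.0, 255.0, 255.0)
    img = np.round(img).astype(np.uint8)
    return SyntheticFundus(image=img, grade=grade, lesion_mask=lesion_mask,
                           seed=seed)


def generate_arrays(
    cfg: FundusSynthConfig | None = None,
) -> tuple[list[SyntheticFundus], list[SyntheticFundus]]:
    """Generate the full dataset in memory and split it train/test.

    Stratified per grade: the last ``round(test_fraction * per_grade_n)``
    images of each grade (at least one) form the test split.  Returns
    ``(train, test)`` lists of :class:`SyntheticFundus`.
    """
    cfg = cfg or FundusSynthConfig()
    if cfg.per_grade_n < 2:
        raise ValueError("per_grade_n must be >= 2 to allow a split")
    n_test = max(1, round(cfg.test_fraction * cfg.per_grade_n))
    train, test = [], []
    for grade in cfg.grades:
        for i in range(cfg.per_grade_n):
            sample = generate_fundus(grade, cfg, seed=i)
            (test if i >= cfg.per_grade_n - n_test else train).append(sample)
    return train, test


def generate_dataset(cfg: FundusSynthConfig, out_dir: str | Path) -> Path:
    """Write PNG images plus a CSV manifest (path, grade, split, seed).

    The split is stratified (default 85/15, echoing a 110-train /
    20-test benchmark layout); no image appears in both splits.
    Returns the manifest path.
    """
    from .enhancement import write_image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    train, test = generate_arrays(cfg)
    rows = []
    for split, samples in (("train", train), ("test", test)):
        for s in samples:
            name = f"grade{s.grade}_seed{s.seed:04d}.png"
            path = out_dir / name
            write_image(path, s.image)
            rows.append((name, s.grade, split, s.seed))
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "grade", "split", "seed"])
        w.writerows(rows)
    return manifest


def dataset_digest(samples: list[SyntheticFundus]) -> str:
    """SHA-256 over all image bytes — handy for determinism checks."""
    h = hashlib.sha256()
    for s in samples:
        h.update(s.image.tobytes())
    return h.hexdigest()
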