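"""Synthetic fluorescence frames: Gaussian bright spots in and around an ROI.

Stands in for high-content microscope output: each frame carries a known
number of spot-like objects (Gaussian intensity profile) whose centers lie
strictly inside a polygonal region of interest, plus distractor spots
outside it, on a flat background with optional additive Gaussian noise.
Ground truth (all spot centers) is returned alongside the pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..hcs_quant import ROI

__all__ = ["ImageSpec", "generate_images", "save_roi", "load_roi"]

_MAX_TRIES = 2000
_U16_MAX = 65535


class SpotPlacementError(RuntimeError):
    """Raised when non-overlapping spot placement fails within bounded retries."""


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of one synthetic frame.

    A spot has profile ``peak * exp(-r^2 / (2 sigma^2))`` with
    ``sigma = spot_radius / 3``, so ~99% of its intensity lies within
    ``spot_radius`` of the center; centers are pairwise separated by more
    than ``2 * spot_radius``, which keeps spots resolvable.
    """

    shape: tuple[int, int] = (256, 256)
    roi: tuple[tuple[float, float], ...] = ((40, 60), (200, 40), (230, 140), (120, 210), (35, 160))
    n_spots_inside: int = 7
    n_spots_outside: int = 3
    spot_radius: float = 5.0
    spot_peak: float = 20000.0
    background: float = 5000.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.shape[0] < 8 or self.shape[1] < 8:
            raise ValueError(f"shape too small: {self.shape}")
        if len(self.roi) < 3:
            raise ValueError("roi needs at least 3 vertices")
        if self.n_spots_inside < 0 or self.n_spots_outside < 0:
            raise ValueError("spot counts must be non-negative")
        if self.spot_radius <= 0:
            raise ValueError(f"spot_radius must be > 0, got {self.spot_radius}")
        if not (0 <= self.background and self.background + self.spot_peak <= _U16_MAX):
            raise ValueError("background + spot_peak must fit the 16-bit range")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _dist_to_polygon(x: float, y: float, verts: np.ndarray) -> float:
    """Distance from a point to the nearest polygon edge."""
    d_best = np.inf
    n = len(verts)
    for i in range(n):
        ax, ay = verts[i]
        bx, by = verts[(i + 1) % n]
        dx, dy = bx - ax, by - ay
        t = ((x - ax) * dx + (y - ay) * dy) / (dx * dx + dy * dy)
        t = min(1.0, max(0.0, t))
        d = np.hypot(x - (ax + t * dx), y - (ay + t * dy))
        d_best = min(d_best, d)
    return float(d_best)


def _place_centers(
    rng: np.random.Generator,
    spec: ImageSpec,
    roi: ROI,
    n: int,
    inside: bool,
    existing: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    h, w = spec.shape
    margin = 2 * spec.spot_radius
    min_sep = 2 * spec.spot_radius
    verts = np.asarray(roi.vertices, dtype=float)
    centers: list[tuple[float, float]] = []
    for _ in range(n):
        for _try in range(_MAX_TRIES):
            x = margin + rng.random() * (w - 2 * margin)
            y = margin + rng.random() * (h - 2 * margin)
            if roi.contains(x, y) != inside:
                continue
            # keep centers clear of the outline so a spot is unambiguously
            # on one side of it
            if _dist_to_polygon(x, y, verts) <= spec.spot_radius:
                continue
            if any((x - ex) ** 2 + (y - ey) ** 2 <= min_sep**2
                   for ex, ey in existing + centers):
                continue
            centers.append((x, y))
            break
        else:
            raise SpotPlacementError(
                f"could not place {'inside' if inside else 'outside'} spot "
                f"{len(centers) + 1}/{n} after {_MAX_TRIES} tries"
            )
    return centers


def generate_images(spec: ImageSpec) -> tuple[np.ndarray, dict]:
    """Render one 16-bit frame and its ground truth.

    Returns ``(image, truth)`` where ``image`` is uint16 of ``spec.shape``
    and ``truth`` records inside/outside spot centers (x, y) and the spec
    parameters needed to interpret them.
    """
    spec.validate()
    roi = ROI(vertices=list(spec.roi))
    rng = np.random.default_rng(spec.seed)

    inside = _place_centers(rng, spec, roi, spec.n_spots_inside, True, [])
    outside = _place_centers(rng, spec, roi, spec.n_spots_outside, False, inside)

    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((h, w), spec.background, dtype=float)
    sigma = spec.spot_radius / 3.0
    for x, y in inside + outside:
        r2 = (xx - x) ** 2 + (yy - y) ** 2
        img += spec.spot_peak * np.exp(-r2 / (2 * sigma**2))
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, _U16_MAX).astype(np.uint16)

    truth = {
        "inside_centers": [[float(x), float(y)] for x, y in inside],
        "outside_centers": [[float(x), float(y)] for x, y in outside],
        "spot_radius": spec.spot_radius,
        "spot_peak": spec.spot_peak,
        "background": spec.background,
        "noise_sd": spec.noise_sd,
        "roi_vertices": [list(v) for v in spec.roi],
    }
    return img, truth


def save_roi(roi_vertices, path: str | Path) -> None:
    """Write ROI polygon JSON: {"vertices": [[x, y], ...]}, 0-based pixels."""
    Path(path).write_text(
        json.dumps({"vertices": [list(map(float, v)) for v in roi_vertices]}),
        encoding="utf-8",
    )


def load_roi(path: str | Path) -> ROI:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return ROI(vertices=[tuple(v) for v in data["vertices"]])
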