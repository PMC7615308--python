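"""Synthetic BaseScope-style fluorescence scenes with ground truth.

A scene is a set of elliptical nuclei (DAPI channel) and small circular
dots in the isoform channels (MINUS = canonical-donor transcripts, PLUS =
extended-donor transcripts) plus an optional MARKER channel in which some
nuclei are painted positive (an SRY-like nuclear stain). Channels are
rendered additively as float arrays with optional Gaussian noise.

Each dot's ground-truth nucleus is the nucleus whose centroid is nearest
the dot centre — the same default rule the quantifier applies — so a
noise-free scene is exactly recoverable. Dots are allowed outside nuclei
(BaseScope signal is perinuclear, not strictly intranuclear).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import disk, ellipse

CHANNELS = ("DAPI", "MINUS", "PLUS", "MARKER")


@dataclass(frozen=True)
class NucleusSpec:
    """One elliptical nucleus: ``center``/``semi_axes`` in (row, col) pixels."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    intensity: float = 1.0
    marker_positive: bool = False
    marker_intensity: float = 1.0


@dataclass(frozen=True)
class DotSpec:
    """One circular signal dot in an isoform or marker channel."""

    channel: str
    center: tuple[float, float]
    radius: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.channel not in ("MINUS", "PLUS", "MARKER"):
            raise ValueError(f"dot channel must be MINUS/PLUS/MARKER, got {self.channel!r}")
        if self.radius <= 0:
            raise ValueError("dot radius must be > 0")


@dataclass
class ImageSceneConfig:
    """Full description of a synthetic scene.

    ``pixel_size`` is the calibration in micrometres per pixel; a dot of
    radius r px has continuous true area pi * r^2 * pixel_size^2, and the
    rasterised pixel count is recorded alongside it in the truth table.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.5
    nuclei: list[NucleusSpec] = field(default_factory=list)
    dots: list[DotSpec] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        h, w = self.shape
        for n in self.nuclei:
            r, c = n.center
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"nucleus center {n.center} outside image {self.shape}")
        for d in self.dots:
            r, c = d.center
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"dot center {d.center} outside image {self.shape}")

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "pixel_size": self.pixel_size,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "nuclei": [
                {
                    "center": list(n.center),
                    "semi_axes": list(n.semi_axes),
                    "intensity": n.intensity,
                    "marker_positive": n.marker_positive,
                    "marker_intensity": n.marker_intensity,
                }
                for n in self.nuclei
            ],
            "dots": [
                {
                    "channel": d.channel,
                    "center": list(d.center),
                    "radius": d.radius,
                    "intensity": d.intensity,
                }
                for d in self.dots
            ],
        }

    @classmethod
    def from_json(cls, source) -> "ImageSceneConfig":
        if isinstance(source, dict):
            d = source
        elif hasattr(source, "read"):
            d = json.load(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(
            shape=tuple(d.get("shape", (256, 256))),
            pixel_size=d.get("pixel_size", 0.5),
            nuclei=[
                NucleusSpec(
                    center=tuple(n["center"]),
                    semi_axes=tuple(n["semi_axes"]),
                    intensity=n.get("intensity", 1.0),
                    marker_positive=n.get("marker_positive", False),
                    marker_intensity=n.get("marker_intensity", 1.0),
                )
                for n in d.get("nuclei", [])
            ],
            dots=[
                DotSpec(
                    channel=dd["channel"],
                    center=tuple(dd["center"]),
                    radius=dd["radius"],
                    intensity=dd.get("intensity", 1.0),
                )
                for dd in d.get("dots", [])
            ],
            noise_sd=d.get("noise_sd", 0.0),
            seed=d.get("seed", 0),
        )


def simulate_basescope_image(
    config: ImageSceneConfig,
) -> tuple[dict[str, np.ndarray], pd.DataFrame, pd.DataFrame]:
    """Render a scene.

    Returns
    -------
    channels:
        Mapping of channel name -> float64 image. MARKER is present only
        when the scene uses it (marker-positive nuclei or MARKER dots).
    nuclei_truth:
        One row per nucleus: ``nucleus`` (1-based id in listing order),
        centroid, rasterised ``area_px``, ``marker_positive``.
    dots_truth:
        One row per dot: channel, centre, continuous ``area_um2``,
        rasterised ``area_px`` and ``raster_area_um2``, and the assigned
        nucleus id (nearest nucleus centroid; 0 when the scene has no
        nuclei).
    """
    h, w = config.shape
    use_marker = any(n.marker_positive for n in config.nuclei) or any(
        d.channel == "MARKER" for d in config.dots
    )
    names = [c for c in CHANNELS if use_marker or c != "MARKER"]
    channels = {name: np.zeros((h, w), dtype=np.float64) for name in names}

    nuc_rows = []
    for i, n in enumerate(config.nuclei, start=1):
        rr, cc = ellipse(*n.center, *n.semi_axes, shape=(h, w))
        channels["DAPI"][rr, cc] += n.intensity
        if n.marker_positive:
            channels["MARKER"][rr, cc] += n.marker_intensity
        nuc_rows.append(
            {
                "nucleus": i,
                "center_row": n.center[0],
                "center_col": n.center[1],
                "area_px": len(rr),
                "marker_positive": n.marker_positive,
            }
        )
    nuclei_truth = pd.DataFrame(
        nuc_rows,
        columns=["nucleus", "center_row", "center_col", "area_px", "marker_positive"],
    )

    centroids = np.array([[n.center[0], n.center[1]] for n in config.nuclei])
    dot_rows = []
    for j, d in enumerate(config.dots, start=1):
        rr, cc = disk(d.center, d.radius, shape=(h, w))
        channels[d.channel][rr, cc] += d.intensity
        if len(centroids):
            dist = np.hypot(centroids[:, 0] - d.center[0], centroids[:, 1] - d.center[1])
            assigned = int(np.argmin(dist)) + 1  # ties -> lowest id
        else:
            assigned = 0
        dot_rows.append(
            {
                "dot": j,
                "channel": d.channel,
                "center_row": d.center[0],
                "center_col": d.center[1],
                "radius_px": d.radius,
                "area_um2": np.pi * d.radius**2 * config.pixel_size**2,
                "area_px": len(rr),
                "raster_area_um2": len(rr) * config.pixel_size**2,
                "nucleus": assigned,
            }
        )
    dots_truth = pd.DataFrame(
        dot_rows,
        columns=[
            "dot",
            "channel",
            "center_row",
            "center_col",
            "radius_px",
            "area_um2",
            "area_px",
            "raster_area_um2",
            "nucleus",
        ],
    )

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        for name in names:  # fixed channel order keeps the draw deterministic
            channels[name] += rng.normal(0.0, config.noise_sd, size=(h, w))
    return channels, nuclei_truth, dots_truth


def random_scene_config(
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = 0.5,
    n_nuclei: tuple[int, int] = (6, 12),
    nucleus_radius: tuple[float, float] = (8.0, 12.0),
    dots_per_nucleus: tuple[int, int] = (0, 4),
    dot_radius: tuple[float, float] = (2.0, 4.0),
    dot_channels: tuple[str, ...] = ("MINUS", "PLUS"),
    marker_positive_fraction: float = 0.0,
    noise_sd: float = 0.0,
    max_dot_offset: float = 12.0,
    disjoint_dots: bool = False,
) -> ImageSceneConfig:
    """Draw a random but well-posed scene.

    Nuclei are near-circular, lie fully inside the frame and are mutually
    separated by more than twice the largest radius, so they never touch;
    each nucleus receives dots placed within ``max_dot_offset`` px of its
    centroid (closer to it than to any other nucleus). These conditions
    make the scene exactly recoverable at zero noise.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    k = int(rng.integers(n_nuclei[0], n_nuclei[1] + 1))
    margin = nucleus_radius[1] + max_dot_offset + dot_radius[1] + 2
    min_sep = 2 * (nucleus_radius[1] + max_dot_offset)
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < k and attempts < 20000:
        attempts += 1
        cand = (
            float(rng.uniform(margin, h - margin)),
            float(rng.uniform(margin, w - margin)),
        )
        if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) >= min_sep for c in centers):
            centers.append(cand)
    k = len(centers)

    n_pos = int(round(marker_positive_fraction * k))
    pos = set(rng.choice(k, size=n_pos, replace=False)) if n_pos else set()
    nuclei = []
    for i, c in enumerate(centers):
        a = float(rng.uniform(*nucleus_radius))
        b = float(rng.uniform(*nucleus_radius))
        nuclei.append(
            NucleusSpec(center=c, semi_axes=(a, b), intensity=1.0, marker_positive=i in pos)
        )

    dots: list[DotSpec] = []
    for c in centers:
        n_dots = int(rng.integers(dots_per_nucleus[0], dots_per_nucleus[1] + 1))
        placed = 0
        tries = 0
        while placed < n_dots and tries < 200:
            tries += 1
            theta = rng.uniform(0, 2 * np.pi)
            rho = rng.uniform(0, max_dot_offset)
            center = (c[0] + rho * np.sin(theta), c[1] + rho * np.cos(theta))
            radius = float(rng.uniform(*dot_radius))
            if disjoint_dots and any(
                np.hypot(center[0] - d.center[0], center[1] - d.center[1])
                < radius + d.radius + 2
                for d in dots
            ):
                continue
            dots.append(
                DotSpec(
                    channel=str(rng.choice(dot_channels)),
                    center=center,
                    radius=radius,
                    intensity=1.0,
                )
            )
            placed += 1
    return ImageSceneConfig(
        shape=shape,
        pixel_size=pixel_size,
        nuclei=nuclei,
        dots=dots,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------


def write_image_stack(channels: dict[str, np.ndarray], path, pixel_size: float) -> None:
    """Write channels as a multi-page float32 TIFF plus a JSON sidecar
    (``<path>.channels.json``) recording page order and calibration."""
    path = Path(path)
    names = list(channels)
    stack = np.stack([channels[n].astype(np.float32) for n in names])
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {"channels": names, "pixel_size_um": pixel_size}
    path.with_suffix(path.suffix + ".channels.json").write_text(json.dumps(sidecar))


def read_image_stack(
    path, channel_map: dict[str, int] | None = None, pixel_size: float | None = None
) -> tuple[dict[str, np.ndarray], float]:
    """Read a multi-page TIFF as named channels.

    Without an explicit ``channel_map`` (name -> page index) the JSON
    sidecar written by :func:`write_image_stack` is consulted.
    """
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if channel_map is None or pixel_size is None:
        sidecar_path = path.with_suffix(path.suffix + ".channels.json")
        if not sidecar_path.exists():
            raise ValueError(
                f"no channel map given and no sidecar at {sidecar_path}"
            )
        sidecar = json.loads(sidecar_path.read_text())
        if channel_map is None:
            channel_map = {n: i for i, n in enumerate(sidecar["channels"])}
        if pixel_size is None:
            pixel_size = sidecar["pixel_size_um"]
    channels = {name: np.asarray(stack[i], dtype=np.float64) for name, i in channel_map.items()}
    shapes = {c.shape for c in channels.values()}
    if len(shapes) > 1:
        raise ValueError(f"channels differ in shape: {shapes}")
    return channels, float(pixel_size)
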