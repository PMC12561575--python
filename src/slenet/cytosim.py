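"""Synthetic rat vaginal-smear image simulator.

The four estrous stages have qualitative cytological signatures:

* **P** (proestrus): nucleated epithelial cells dominate, a few cornified
  cells, no leukocytes.
* **E** (estrus): only anucleated cornified (keratinised) epithelial cells.
* **M** (metestrus): a mixture of all three cell kinds.
* **D** (diestrus): many leukocytes with a small number of nucleated cells,
  no cornified cells.

The simulator draws per-stage cell counts from Poisson distributions whose
means leave a wide margin to the qualitative rules (any violating draw is
rejected and redrawn, so every emitted scene satisfies its stage rule
surely), places cells uniformly on the canvas with overlap allowed, and
renders a methylene-blue-like appearance: blue-stained cells on an off-white
background, a low-frequency multiplicative illumination gradient and
Gaussian pixel noise.  Leukocytes are small dark discs, nucleated epithelial
cells larger pale discs with a dark nucleus, cornified cells irregular
anucleated polygons.  Everything is deterministic given the scene's seed.

The count distributions are invented for the simulator (real smears are only
described qualitatively); they are not biological measurements.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "STAGES",
    "CellKind",
    "CellSpec",
    "SceneSpec",
    "DatasetManifest",
    "DEFAULT_COMPOSITION",
    "DEFAULT_CANVAS",
    "sample_scene",
    "render_scene",
    "rule_based_stager",
    "generate_dataset",
    "read_manifest",
    "write_manifest",
]

STAGES = ("P", "E", "M", "D")
DEFAULT_CANVAS = (448, 448)  # rendered large so the 224 resize is a true downscale


class CellKind(str, enum.Enum):
    LEUKOCYTE = "leukocyte"
    NUCLEATED = "nucleated_epithelial"
    CORNIFIED = "cornified"


# Per-stage Poisson means per cell kind.  Margins are large relative to the
# qualitative composition rules, so rejection is rare.
DEFAULT_COMPOSITION = {
    "P": {CellKind.LEUKOCYTE: 0, CellKind.NUCLEATED: 60, CellKind.CORNIFIED: 6},
    "E": {CellKind.LEUKOCYTE: 0, CellKind.NUCLEATED: 0, CellKind.CORNIFIED: 70},
    "M": {CellKind.LEUKOCYTE: 30, CellKind.NUCLEATED: 25, CellKind.CORNIFIED: 40},
    "D": {CellKind.LEUKOCYTE: 120, CellKind.NUCLEATED: 8, CellKind.CORNIFIED: 0},
}

# radius ranges (pixels on the 448-canvas) per kind
_RADIUS = {
    CellKind.LEUKOCYTE: (3.0, 6.0),
    CellKind.NUCLEATED: (10.0, 18.0),
    CellKind.CORNIFIED: (18.0, 30.0),
}
_NUCLEUS_FRACTION = 0.35

# methylene-blue-like palette (RGB in [0, 1])
_COLORS = {
    CellKind.LEUKOCYTE: np.array([0.22, 0.18, 0.50]),
    CellKind.NUCLEATED: np.array([0.58, 0.64, 0.88]),
    CellKind.CORNIFIED: np.array([0.45, 0.55, 0.82]),
}
_NUCLEUS_COLOR = np.array([0.16, 0.13, 0.45])
_BACKGROUND_TINT = np.array([0.96, 0.96, 1.0])


@dataclass
class CellSpec:
    kind: CellKind
    center: tuple[float, float]  # (x, y) pixels
    radius: float
    elongation: float = 1.0  # major/minor axis ratio, >= 1
    orientation: float = 0.0  # radians
    stain_intensity: float = 0.7
    has_nucleus: bool = False
    vertex_jitter: float = 0.0  # polygon irregularity, cornified only

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.elongation < 1:
            raise ValueError("elongation is an axis ratio >= 1")
        if not 0.0 <= self.stain_intensity <= 1.0:
            raise ValueError("stain intensity must lie in [0, 1]")
        if self.vertex_jitter < 0:
            raise ValueError("vertex jitter must be >= 0")
        if self.kind is CellKind.LEUKOCYTE and not self.has_nucleus:
            raise ValueError("leukocytes are nucleated")
        if self.kind is CellKind.CORNIFIED and self.has_nucleus:
            raise ValueError("cornified cells are anucleated")


@dataclass
class SceneSpec:
    stage: str
    cells: list[CellSpec]
    background_level: float = 0.95
    illumination: tuple[float, float] = (0.1, 0.0)  # (amplitude, direction rad)
    noise_sd: float = 0.01  # on the [0, 1] intensity scale
    rng_seed: int = 0

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background level must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def counts(self) -> dict[CellKind, int]:
        c = {k: 0 for k in CellKind}
        for cell in self.cells:
            c[cell.kind] += 1
        return c


def _stage_of_counts(n_leuk: int, n_nucl: int, n_corn: int) -> str | None:
    """The stage whose composition rule the counts satisfy (rules are disjoint)."""
    if n_corn > 0 and n_leuk == 0 and n_nucl == 0:
        return "E"
    if n_leuk == 0 and n_nucl > n_corn:
        return "P"
    if n_corn == 0 and n_leuk > n_nucl and n_leuk > 0:
        return "D"
    if n_leuk >= 1 and n_nucl >= 1 and n_corn >= 1:
        return "M"
    return None


def rule_based_stager(scene: SceneSpec) -> str:
    """Stage implied by the ground-truth cell counts, or ``"ambiguous"``."""
    c = scene.counts()
    stage = _stage_of_counts(
        c[CellKind.LEUKOCYTE], c[CellKind.NUCLEATED], c[CellKind.CORNIFIED]
    )
    return stage if stage is not None else "ambiguous"


def _make_cell(kind: CellKind, rng: np.random.Generator, canvas) -> CellSpec:
    h, w = canvas
    rlo, rhi = _RADIUS[kind]
    radius = rng.uniform(rlo, rhi)
    margin = radius  # keep centres inside so every cell intersects the canvas
    center = (rng.uniform(margin, w - margin), rng.uniform(margin, h - margin))
    if kind is CellKind.LEUKOCYTE:
        return CellSpec(kind, center, radius, 1.0, 0.0, rng.uniform(0.75, 0.95), True)
    if kind is CellKind.NUCLEATED:
        return CellSpec(
            kind,
            center,
            radius,
            rng.uniform(1.0, 1.3),
            rng.uniform(0, math.pi),
            rng.uniform(0.45, 0.65),
            True,
        )
    return CellSpec(
        kind,
        center,
        radius,
        rng.uniform(1.0, 1.6),
        rng.uniform(0, math.pi),
        rng.uniform(0.45, 0.70),
        False,
        vertex_jitter=rng.uniform(0.15, 0.35),
    )


def sample_scene(
    stage: str,
    sim_params: dict | None = None,
    rng_seed: int = 0,
    canvas=DEFAULT_CANVAS,
) -> SceneSpec:
    """Draw one ground-truth scene for ``stage``; identical seed, identical scene."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    means = (sim_params or DEFAULT_COMPOSITION)[stage]
    rng = np.random.default_rng(rng_seed)
    for _ in range(1000):
        counts = {
            k: (int(rng.poisson(m)) if m > 0 else 0) for k, m in means.items()
        }
        if (
            _stage_of_counts(
                counts[CellKind.LEUKOCYTE],
                counts[CellKind.NUCLEATED],
                counts[CellKind.CORNIFIED],
            )
            == stage
        ):
            break
    else:  # pragma: no cover - means leave overwhelming margins
        raise RuntimeError(f"could not sample a valid {stage} composition")
    cells = []
    for kind in CellKind:  # fixed kind order keeps sampling deterministic
        for _ in range(counts[kind]):
            cells.append(_make_cell(kind, rng, canvas))
    return SceneSpec(
        stage=stage,
        cells=cells,
        background_level=rng.uniform(0.85, 0.98),
        illumination=(rng.uniform(0.05, 0.18), rng.uniform(0, 2 * math.pi)),
        noise_sd=rng.uniform(0.005, 0.02),
        rng_seed=int(rng_seed),
    )


def _blend_ellipse(canvas, cx, cy, r_major, r_minor, theta, color, alpha):
    h, w, _ = canvas.shape
    ext = r_major + 1
    x0, x1 = int(max(0, cx - ext)), int(min(w, cx + ext + 1))
    y0, y1 = int(max(0, cy - ext)), int(min(h, cy + ext + 1))
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    u = (xs - cx) * math.cos(theta) + (ys - cy) * math.sin(theta)
    v = -(xs - cx) * math.sin(theta) + (ys - cy) * math.cos(theta)
    d2 = (u / r_major) ** 2 + (v / r_minor) ** 2
    a = alpha * np.clip((1.0 - d2) / 0.25, 0.0, 1.0)[:, :, None]  # soft rim
    region = canvas[y0:y1, x0:x1]
    region *= 1.0 - a
    region += a * color


def _blend_polygon(canvas, cell: CellSpec, cell_rng, color):
    """Irregular star-shaped polygon: radius modulated per vertex angle."""
    h, w, _ = canvas.shape
    cx, cy = cell.center
    n_vert = int(cell_rng.integers(7, 12))
    angles = np.linspace(0, 2 * math.pi, n_vert, endpoint=False)
    radii = cell.radius * (1.0 + cell.vertex_jitter * cell_rng.uniform(-1, 1, n_vert))
    ext = radii.max() * cell.elongation + 1
    x0, x1 = int(max(0, cx - ext)), int(min(w, cx + ext + 1))
    y0, y1 = int(max(0, cy - ext)), int(min(h, cy + ext + 1))
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    u = (xs - cx) * math.cos(cell.orientation) + (ys - cy) * math.sin(cell.orientation)
    v = -(xs - cx) * math.sin(cell.orientation) + (ys - cy) * math.cos(cell.orientation)
    u = u / cell.elongation  # squash the major axis -> elongated outline
    theta = np.mod(np.arctan2(v, u), 2 * math.pi)
    rho = np.hypot(u, v)
    # piecewise-linear boundary radius over the wrapped vertex angles
    bound = np.interp(
        theta,
        np.concatenate([angles, [2 * math.pi]]),
        np.concatenate([radii, [radii[0]]]),
    )
    a = cell.stain_intensity * np.clip((bound - rho) / 2.0, 0.0, 1.0)[:, :, None]
    region = canvas[y0:y1, x0:x1]
    region *= 1.0 - a
    region += a * color


def render_scene(scene: SceneSpec, size=DEFAULT_CANVAS) -> np.ndarray:
    """Render the scene to an H x W x 3 uint8 image (deterministic)."""
    h, w = size
    if h < 64 or w < 64:
        raise ValueError("canvas must be at least 64 x 64")
    rng = np.random.default_rng(scene.rng_seed)
    canvas = np.ones((h, w, 3), dtype=np.float64)
    canvas *= scene.background_level * _BACKGROUND_TINT
    for idx, cell in enumerate(scene.cells):
        cx, cy = cell.center
        if not (-cell.radius <= cx <= w + cell.radius and -cell.radius <= cy <= h + cell.radius):
            raise ValueError(f"cell {idx} does not intersect the canvas")
        cell_rng = np.random.default_rng([scene.rng_seed, idx])
        color = _COLORS[cell.kind]
        if cell.kind is CellKind.CORNIFIED:
            _blend_polygon(canvas, cell, cell_rng, color)
        else:
            _blend_ellipse(
                canvas,
                cx,
                cy,
                cell.radius * cell.elongation,
                cell.radius,
                cell.orientation,
                color,
                cell.stain_intensity,
            )
            if cell.has_nucleus and cell.kind is CellKind.NUCLEATED:
                _blend_ellipse(
                    canvas,
                    cx,
                    cy,
                    cell.radius * _NUCLEUS_FRACTION,
                    cell.radius * _NUCLEUS_FRACTION,
                    0.0,
                    _NUCLEUS_COLOR,
                    0.9,
                )
    amp, direction = scene.illumination
    ys, xs = np.mgrid[0:h, 0:w]
    ramp = (xs / max(w - 1, 1) - 0.5) * math.cos(direction) + (
        ys / max(h - 1, 1) - 0.5
    ) * math.sin(direction)
    canvas *= (1.0 + amp * 2.0 * ramp)[:, :, None]
    if scene.noise_sd > 0:
        canvas += rng.normal(0.0, scene.noise_sd, canvas.shape)
    return (np.clip(canvas, 0.0, 1.0) * 255.0).round().astype(np.uint8)


@dataclass
class DatasetManifest:
    """Table of (image path, stage label, split) records."""

    frame: pd.DataFrame  # columns: path, stage, split
    generator_seed: int | None = None

    def __post_init__(self):
        missing = {"path", "stage", "split"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"manifest is missing columns {sorted(missing)}")
        if self.frame["path"].duplicated().any():
            raise ValueError("manifest paths must be unique")
        bad = set(self.frame["stage"]) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages in manifest: {sorted(bad)}")

    def __len__(self):
        return len(self.frame)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.frame["stage"].value_counts().to_dict()
        return {s: int(counts.get(s, 0)) for s in STAGES}

    def subset(self, split: str) -> pd.DataFrame:
        return self.frame[self.frame["split"] == split].reset_index(drop=True)


def write_manifest(manifest: DatasetManifest, path):
    manifest.frame.to_csv(path, index=False, columns=["path", "stage", "split"])


def read_manifest(path) -> DatasetManifest:
    frame = pd.read_csv(path, dtype={"path": str, "stage": str, "split": str})
    return DatasetManifest(frame)


def generate_dataset(
    counts: dict[str, int],
    outdir,
    seed: int = 0,
    size=DEFAULT_CANVAS,
    image_format: str = "png",
    sim_params: dict | None = None,
) -> DatasetManifest:
    """Render ``counts[stage]`` labelled images per stage into ``outdir``.

    Bit-reproducible for a given (counts, seed): per-image seeds derive from
    a seed sequence keyed on (dataset seed, stage index, image index).
    """
    if image_format not in ("png", "jpg"):
        raise ValueError("image format must be png or jpg")
    if any(c < 0 for c in counts.values()):
        raise ValueError("per-stage counts must be >= 0")
    unknown = set(counts) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for stage_idx, stage in enumerate(STAGES):
        for i in range(counts.get(stage, 0)):
            img_seed = int(
                np.random.SeedSequence([int(seed), stage_idx, i]).generate_state(1)[0]
            )
            scene = sample_scene(stage, sim_params, rng_seed=img_seed, canvas=size)
            img = render_scene(scene, size=size)
            name = f"{stage}_{i:04d}.{image_format}"
            path = outdir / name
            pil = Image.fromarray(img)
            if image_format == "jpg":
                pil.save(path, quality=95)
            else:
                pil.save(path)
            rows.append({"path": name, "stage": stage, "split": "unassigned"})
    frame = pd.DataFrame(rows, columns=["path", "stage", "split"])
    manifest = DatasetManifest(frame, generator_seed=int(seed))
    write_manifest(manifest, outdir / "manifest.csv")
    return manifest
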