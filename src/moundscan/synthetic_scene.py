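"""Synthetic hyperspectral scenes with planted termite mounds.

The generator emulates the arid-savannah scenery the detector was designed
for: a patchy background of bush, grass and soil materials, on which each
planted mound is painted as an eroded-soil core (oval- or diamond-based,
rotated) collared by a bright-grass ring.  Field mounds measure a mean
bounding rectangle of about 1.951 m^2; at the survey ground sample
distance of 4.7 cm/pixel that corresponds to a core bounding box of
roughly 34 x 26 pixels, which is the default planted size.

Grass collars in the field are rarely perfectly closed, so the ring is
painted with one angular gap (default 25 degrees, random orientation);
a broken collar also exercises the proximity logic of the detector the
way real scenes do, because the contour of an open collar reaches the
core on its inner edge.

Reflectance is converted to radiance through a smooth synthetic illuminant
so that reflectance recovery inverts the generator exactly; degradations
(Gaussian blur, smooth sinusoidal spatial distortion, per-pixel Gaussian
noise) are applied on top and are all off-by-default-zero except a small
sensor-like noise floor.  Everything is reproducible from the scene seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .hypercube_io import HyperCube, WhiteReference
from .material_classify import MaterialLibrary
from .mound_detect import ShapeTemplate, ShapeTemplateSet, log_hu

__all__ = [
    "MoundSpec",
    "SceneSpec",
    "GroundTruthEntry",
    "GroundTruthSet",
    "GenerationError",
    "default_spectra",
    "generate_scene",
    "plan_mounds",
    "render_templates",
    "SOIL_NAME",
    "GRASS_NAME",
]

SOIL_NAME = "Eroded Soil"
GRASS_NAME = "Light Grass"


class GenerationError(ValueError):
    """Scene specification cannot be painted (e.g. overlapping mounds)."""


@dataclass
class MoundSpec:
    """One planted mound: core geometry plus its grass collar."""

    center: tuple[float, float]  # (row, col)
    core_axes_px: tuple[float, float] = (17.0, 13.0)  # semi-axes (major, minor)
    ring_width_px: float = 3.0
    shape: str = "oval"  # "oval" | "diamond"
    rotation_deg: float = 0.0
    ring_gap_deg: float = 25.0
    ring_gap_phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("oval", "diamond"):
            raise ValueError(f"unknown mound shape {self.shape!r}")
        if min(self.core_axes_px) <= 0 or self.ring_width_px <= 0:
            raise ValueError("mound axes and ring width must be positive")


@dataclass
class SceneSpec:
    """Full description of one synthetic ROI."""

    rows: int = 256
    cols: int = 256
    n_bands: int = 274
    gsd_cm_per_px: float = 4.7
    mounds: list[MoundSpec] = field(default_factory=list)
    background_materials: list[str] | None = None
    noise_sd: float = 0.01
    blur_sigma_px: float = 0.5
    distortion_amp_px: float = 0.0
    distortion_wavelength_px: float = 48.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 8 or self.cols < 8 or self.n_bands < 1:
            raise ValueError("scene too small")
        if self.noise_sd < 0 or self.blur_sigma_px < 0 or self.distortion_amp_px < 0:
            raise ValueError("noise/blur/distortion amplitudes must be >= 0")


@dataclass
class GroundTruthEntry:
    centroid: tuple[float, float]  # (row, col)
    core_polygon: list[tuple[float, float]]  # (row, col) vertices
    ring_polygon: list[tuple[float, float]]
    shape: str
    core_axes_px: tuple[float, float]

    @property
    def major_axis_px(self) -> float:
        return 2.0 * max(self.core_axes_px)


@dataclass
class GroundTruthSet:
    entries: list[GroundTruthEntry]
    material_map: np.ndarray | None = None  # (rows, cols) indices into the library

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mounds": [
                {
                    "centroid_row": e.centroid[0],
                    "centroid_col": e.centroid[1],
                    "core_polygon_row_col": [list(p) for p in e.core_polygon],
                    "ring_polygon_row_col": [list(p) for p in e.ring_polygon],
                    "shape": e.shape,
                    "core_axes_px": list(e.core_axes_px),
                }
                for e in self.entries
            ]
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthSet":
        payload = json.loads(Path(path).read_text())
        entries = [
            GroundTruthEntry(
                centroid=(m["centroid_row"], m["centroid_col"]),
                core_polygon=[tuple(p) for p in m["core_polygon_row_col"]],
                ring_polygon=[tuple(p) for p in m["ring_polygon_row_col"]],
                shape=m["shape"],
                core_axes_px=tuple(m["core_axes_px"]),
            )
            for m in payload["mounds"]
        ]
        return cls(entries)


# ---------------------------------------------------------------------------
# material spectra
# ---------------------------------------------------------------------------

# (name, base offset, bump amplitudes over the three discriminative windows)
_MATERIAL_RECIPE = [
    ("Eroded Soil", 0.20, (0.45, 0.40, 0.35)),
    ("Light Grass", 0.10, (0.30, 0.55, 0.20)),
    ("Red Soil", 0.16, (0.38, 0.28, 0.30)),
    ("Gravel", 0.14, (0.33, 0.20, 0.24)),
    ("Dry Grass", 0.12, (0.27, 0.34, 0.12)),
    ("Dead Wood", 0.10, (0.20, 0.24, 0.18)),
    ("Buffel Grass", 0.08, (0.14, 0.46, 0.10)),
    ("Green Bush", 0.06, (0.08, 0.38, 0.06)),
    ("Dark Bush", 0.04, (0.04, 0.26, 0.03)),
    ("Shadow", 0.02, (0.02, 0.05, 0.01)),
]

# discriminative wavelength windows (nm): green/red edge, NIR plateau, far NIR
_WINDOWS = ((620.0, 38.0), (760.0, 19.0), (962.0, 22.0))


def default_spectra(n_bands: int = 274) -> MaterialLibrary:
    """Ten smooth synthetic reflectance signatures over 385-1000 nm.

    Inter-material contrast is concentrated in the 540-700, 720-800 and
    924-1000 nm windows (Gaussian bumps of material-specific amplitude);
    outside those windows the materials differ only by small flat offsets.
    Pure function: identical calls return identical libraries.
    """
    if n_bands < 10:
        raise ValueError("need at least 10 bands")
    wavelengths = np.linspace(385.0, 1000.0, n_bands)
    spectra = np.empty((len(_MATERIAL_RECIPE), n_bands))
    slope = 0.05 * (wavelengths - 385.0) / 615.0
    for i, (_, base, amps) in enumerate(_MATERIAL_RECIPE):
        s = base + slope.copy()
        for (center, width), amp in zip(_WINDOWS, amps):
            s = s + amp * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
        spectra[i] = s
    spectra = np.clip(spectra, 0.0, 1.0)
    names = [name for name, _, _ in _MATERIAL_RECIPE]
    return MaterialLibrary(names, spectra, wavelengths)


def synthetic_illuminant(wavelengths_nm: np.ndarray) -> WhiteReference:
    """A smooth, strictly positive stand-in for the white-panel spectrum.

    Synthetic: broad solar-like hump peaking in the green, falling toward
    both spectral ends but bounded well away from zero.
    """
    w = np.asarray(wavelengths_nm, dtype=float)
    intensity = 0.55 + 0.85 * np.exp(-0.5 * ((w - 540.0) / 240.0) ** 2)
    return WhiteReference(w, intensity)


# ---------------------------------------------------------------------------
# scene painting
# ---------------------------------------------------------------------------


def _core_mask(spec: MoundSpec, rows: int, cols: int) -> np.ndarray:
    r0, c0 = spec.center
    a, b = spec.core_axes_px
    theta = np.deg2rad(spec.rotation_deg)
    rr, cc = np.mgrid[0:rows, 0:cols]
    dy = rr - r0
    dx = cc - c0
    # rotate into the mound frame (u along the major axis)
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    if spec.shape == "oval":
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return np.abs(u / a) + np.abs(v / b) <= 1.0


def _ring_mask(spec: MoundSpec, core: np.ndarray) -> np.ndarray:
    dist = ndimage.distance_transform_edt(~core)
    ring = (dist > 0) & (dist <= spec.ring_width_px)
    if spec.ring_gap_deg > 0:
        rows, cols = core.shape
        rr, cc = np.mgrid[0:rows, 0:cols]
        ang = np.rad2deg(np.arctan2(rr - spec.center[0], cc - spec.center[1]))
        diff = (ang - spec.ring_gap_phase_deg + 180.0) % 360.0 - 180.0
        ring &= np.abs(diff) > spec.ring_gap_deg / 2.0
    return ring


def _shape_polygon(spec: MoundSpec, scale: float = 1.0, n_vertices: int = 64) -> list:
    a, b = spec.core_axes_px[0] * scale, spec.core_axes_px[1] * scale
    theta = np.deg2rad(spec.rotation_deg)
    if spec.shape == "oval":
        t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
        u, v = a * np.cos(t), b * np.sin(t)
    else:
        u = np.array([a, 0.0, -a, 0.0])
        v = np.array([0.0, b, 0.0, -b])
    dx = u * np.cos(theta) - v * np.sin(theta)
    dy = u * np.sin(theta) + v * np.cos(theta)
    return [(float(spec.center[0] + y), float(spec.center[1] + x)) for y, x in zip(dy, dx)]


def generate_scene(
    spec: SceneSpec, library: MaterialLibrary
) -> tuple[HyperCube, WhiteReference, GroundTruthSet]:
    """Paint a scene, degrade it, and return radiance cube + truth.

    The returned ``GroundTruthSet`` carries one entry per planted mound and
    the post-distortion material index raster (``material_map``), which is
    the exact target for pixel classification.
    """
    for name in (SOIL_NAME, GRASS_NAME):
        if name not in library.names:
            raise ValueError(f"library must contain {name!r}")
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.rows, spec.cols

    bg_names = spec.background_materials
    if bg_names is None:
        bg_names = [n for n in library.names if n not in (SOIL_NAME, GRASS_NAME)]
    if not bg_names:
        raise ValueError("no background materials available")

    # contiguous background patches: seeded Voronoi tessellation
    n_patches = max(6, rows * cols // 2500)
    seeds = np.column_stack(
        [rng.uniform(0, rows, n_patches), rng.uniform(0, cols, n_patches)]
    )
    patch_material = rng.choice([library.index(n) for n in bg_names], size=n_patches)
    rr, cc = np.mgrid[0:rows, 0:cols]
    from scipy.spatial import cKDTree

    _, nearest = cKDTree(seeds).query(np.column_stack([rr.ravel(), cc.ravel()]))
    index_map = patch_material[nearest].reshape(rows, cols).astype(np.int32)

    soil_idx = library.index(SOIL_NAME)
    grass_idx = library.index(GRASS_NAME)
    occupied = np.zeros((rows, cols), dtype=bool)
    entries = []
    for m in spec.mounds:
        core = _core_mask(m, rows, cols)
        if not core.any():
            raise GenerationError(f"mound at {m.center} paints no pixels")
        ring = _ring_mask(m, core)
        footprint = core | ring
        edge = (
            core[0, :].any() or core[-1, :].any() or core[:, 0].any() or core[:, -1].any()
        )
        if edge:
            raise GenerationError(f"mound core at {m.center} leaves the raster")
        if (occupied & footprint).any():
            raise GenerationError(f"mound at {m.center} overlaps another mound")
        occupied |= footprint
        index_map[core] = soil_idx
        index_map[ring] = grass_idx
        entries.append(
            GroundTruthEntry(
                centroid=(float(m.center[0]), float(m.center[1])),
                core_polygon=_shape_polygon(m, 1.0),
                ring_polygon=_shape_polygon(m, 1.0 + m.ring_width_px / min(m.core_axes_px)),
                shape=m.shape,
                core_axes_px=(float(m.core_axes_px[0]), float(m.core_axes_px[1])),
            )
        )

    if spec.distortion_amp_px > 0:
        lam = spec.distortion_wavelength_px
        ph = rng.uniform(0.0, 2.0 * np.pi, size=2)
        dr = spec.distortion_amp_px * np.sin(2.0 * np.pi * cc / lam + ph[0])
        dc = spec.distortion_amp_px * np.sin(2.0 * np.pi * rr / lam + ph[1])
        index_map = ndimage.map_coordinates(
            index_map, [rr - dr, cc - dc], order=0, mode="nearest"
        )

    reflectance = library.spectra[index_map].astype(np.float64)
    if spec.blur_sigma_px > 0:
        reflectance = ndimage.gaussian_filter(
            reflectance, sigma=(spec.blur_sigma_px, spec.blur_sigma_px, 0.0)
        )
    if spec.noise_sd > 0:
        reflectance = reflectance + rng.normal(0.0, spec.noise_sd, size=reflectance.shape)
    np.clip(reflectance, 0.0, None, out=reflectance)

    white = synthetic_illuminant(library.wavelengths_nm)
    radiance = reflectance * white.intensity[None, None, :]
    cube = HyperCube(
        radiance, library.wavelengths_nm, quantity="radiance", gsd_cm_per_px=spec.gsd_cm_per_px
    )
    return cube, white, GroundTruthSet(entries, material_map=index_map)


def plan_mounds(
    rows: int,
    cols: int,
    n: int,
    seed: int = 0,
    core_axes_px: tuple[float, float] = (17.0, 13.0),
    axis_jitter: float = 0.12,
    ring_width_px: float = 3.0,
    margin_px: float = 4.0,
    max_tries: int = 4000,
) -> list[MoundSpec]:
    """Place ``n`` non-overlapping mounds of field-typical size at random.

    Shapes alternate randomly between oval and diamond, rotations are
    uniform, semi-axes are jittered around the default 17 x 13 px.
    Raises :class:`GenerationError` if the raster cannot hold ``n`` mounds.
    """
    rng = np.random.default_rng(seed)
    mounds: list[MoundSpec] = []
    reach = max(core_axes_px) * (1 + axis_jitter) + ring_width_px + 2
    for _ in range(max_tries):
        if len(mounds) >= n:
            break
        r = rng.uniform(reach + margin_px, rows - reach - margin_px)
        c = rng.uniform(reach + margin_px, cols - reach - margin_px)
        if any(np.hypot(r - m.center[0], c - m.center[1]) < 2 * reach + 2 for m in mounds):
            continue
        jit = 1.0 + rng.uniform(-axis_jitter, axis_jitter, size=2)
        mounds.append(
            MoundSpec(
                center=(float(r), float(c)),
                core_axes_px=(core_axes_px[0] * jit[0], core_axes_px[1] * jit[1]),
                ring_width_px=ring_width_px,
                shape="oval" if rng.random() < 0.5 else "diamond",
                rotation_deg=float(rng.uniform(0.0, 180.0)),
                ring_gap_phase_deg=float(rng.uniform(0.0, 360.0)),
            )
        )
    if len(mounds) < n:
        raise GenerationError(f"could not place {n} mounds in a {rows}x{cols} raster")
    return mounds


# ---------------------------------------------------------------------------
# shape templates
# ---------------------------------------------------------------------------


def render_templates(
    shapes: list[tuple[str, str, float]] | None = None, size_px: int = 64
) -> ShapeTemplateSet:
    """Rasterize the key mound-core shapes as binary templates.

    ``shapes`` is a list of (name, kind, aspect) with kind "oval" or
    "diamond" and aspect = minor/major axis ratio; the default set spans
    the aspect range of field mound cores.
    """
    if size_px < 32:
        raise ValueError("size_px must be >= 32")
    if shapes is None:
        shapes = [
            ("oval_100", "oval", 1.00),
            ("oval_076", "oval", 0.76),
            ("oval_060", "oval", 0.60),
            ("diamond_100", "diamond", 1.00),
            ("diamond_076", "diamond", 0.76),
            ("diamond_060", "diamond", 0.60),
        ]
    templates = []
    for name, kind, aspect in shapes:
        a = size_px / 2.0 - 3.0
        b = a * aspect
        c0 = (size_px - 1) / 2.0
        rr, cc = np.mgrid[0:size_px, 0:size_px]
        u, v = cc - c0, rr - c0
        if kind == "oval":
            mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        elif kind == "diamond":
            mask = np.abs(u / a) + np.abs(v / b) <= 1.0
        else:
            raise ValueError(f"unknown template kind {kind!r}")
        templates.append(ShapeTemplate(name, mask, log_hu(mask)))
    return ShapeTemplateSet(templates)


def save_templates(templates: ShapeTemplateSet, directory: str | Path) -> None:
    """Write a template set as binary PNGs consumable by load_templates."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in templates.templates:
        iio.imwrite(directory / f"{t.name}.png", (t.image * 255).astype(np.uint8))
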