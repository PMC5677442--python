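"""Two-layer contour and shape analysis for termite-mound detection.

A pre-existing mound appears as an eroded-soil core (oval or diamond)
collared by bright grass.  Detection conditions the two binary material
layers, gates on their spatial overlap, extracts soil contours by border
following, filters them by Hu-moment shape matching against a template
library, and confirms each surviving soil contour by pairing it with a
nearby grass contour (centroid distance, perimeter proportion and minimum
inter-contour distance thresholds).

Shape matching compares the seven Hu moment invariants of the soil
contour's filled region with those of a template in signed-log space,

    m_i = sign(h_i) * log10|h_i|,     ratio = sum_i |1/m_i^S - 1/m_i^T|,

so that a low ratio means a close shape match regardless of rotation,
translation and scale.  Terms with |h_i| below a zero floor (1e-30) are
excluded from the sum for either shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

from .material_classify import BinaryLayer

__all__ = [
    "DetectionParams",
    "Contour",
    "ShapeTemplate",
    "ShapeTemplateSet",
    "Detection",
    "DegenerateShapeError",
    "IncomparableShapesError",
    "condition_soil",
    "make_soil_halo",
    "overlap_gate",
    "find_contours",
    "log_hu",
    "shape_ratio",
    "filter_soil_contours",
    "pair_and_confirm",
    "detect_mounds",
    "load_templates",
    "detections_to_json",
]

_RECT3 = np.ones((3, 3), dtype=bool)
_CROSS3 = ndimage.generate_binary_structure(2, 1)  # the 3x3 "ellipse" element
_HU_ZERO_FLOOR = 1e-30


class DegenerateShapeError(ValueError):
    """Contour has no interior; moments are undefined."""


class IncomparableShapesError(ValueError):
    """All seven Hu terms excluded by the zero floor for at least one shape."""


@dataclass
class DetectionParams:
    """Thresholds of the contour/pairing stage (raster-space pixels).

    ``ratio_max`` caps the Hu shape-match ratio, ``perimeter_min_px`` drops
    speckle contours, ``radius_factor`` scales the soil contour's enclosing
    radius into the allowed centroid distance, ``perimeter_prop_min`` is the
    minimum grass/soil perimeter proportion, and ``ild_max_px`` bounds the
    minimum inter-contour distance.
    """

    ratio_max: float = 0.15
    perimeter_min_px: float = 10.0
    dilation_iters: int = 2
    radius_factor: float = 1.2
    perimeter_prop_min: float = 0.8
    ild_max_px: float = 2.5
    median_kernel: int = 3

    def __post_init__(self) -> None:
        for name in (
            "ratio_max",
            "perimeter_min_px",
            "dilation_iters",
            "radius_factor",
            "perimeter_prop_min",
            "ild_max_px",
            "median_kernel",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd")


@dataclass
class Contour:
    """Ordered outer boundary of one connected foreground component.

    ``points`` are (row, col) pixel-centre coordinates from border
    following; ``area_px2`` is the Green's-theorem (shoelace) area of that
    polygon; ``centroid`` and ``log_hu`` come from the raster moments of
    the filled component; ``enclosing_radius_px`` is the minimum enclosing
    circle radius of the boundary points.
    """

    points: np.ndarray  # (N, 2) float, (row, col)
    perimeter_px: float
    area_px2: float
    centroid: tuple[float, float]  # (row, col)
    enclosing_radius_px: float
    log_hu: np.ndarray  # (7,), NaN where excluded by the zero floor
    best_ratio: float | None = None
    best_template: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape[0] < 3:
            raise ValueError("a contour needs at least 3 boundary points")
        if self.perimeter_px <= 0 or self.area_px2 < 0:
            raise ValueError("invalid contour geometry")


@dataclass
class ShapeTemplate:
    name: str
    image: np.ndarray  # bool
    log_hu: np.ndarray


@dataclass
class ShapeTemplateSet:
    templates: list[ShapeTemplate] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.templates:
            _, n = ndimage.label(t.image, structure=_RECT3)
            if n != 1:
                raise ValueError(
                    f"template {t.name!r} must contain exactly one foreground component"
                )

    def __len__(self) -> int:
        return len(self.templates)


@dataclass
class Detection:
    """One confirmed mound: a soil contour plus its qualifying grass partners."""

    soil_contour: Contour
    paired_grass_contours: list[Contour]
    best_ratio: float
    best_template: str
    d_px: float
    ild_px: float
    prop: float


# ---------------------------------------------------------------------------
# layer conditioning
# ---------------------------------------------------------------------------


def _binary_closing_rect3(mask: np.ndarray) -> np.ndarray:
    # border values chosen so objects touching the frame are not eroded away
    dil = ndimage.binary_dilation(mask, structure=_RECT3, border_value=0)
    return ndimage.binary_erosion(dil, structure=_RECT3, border_value=1)


def condition_soil(layer: BinaryLayer, params: DetectionParams | None = None) -> BinaryLayer:
    """Median-smooth then close the soil layer (kills speckle, fills pinholes)."""
    params = params or DetectionParams()
    k = params.median_kernel
    med = ndimage.median_filter(layer.mask.astype(np.uint8), size=k).astype(bool)
    return BinaryLayer(_binary_closing_rect3(med), material_name=layer.material_name)


def condition_grass(layer: BinaryLayer, params: DetectionParams | None = None) -> BinaryLayer:
    """Median-smooth the grass layer (median only; no closing on this branch)."""
    params = params or DetectionParams()
    med = ndimage.median_filter(layer.mask.astype(np.uint8), size=params.median_kernel)
    return BinaryLayer(med.astype(bool), material_name=layer.material_name)


def make_soil_halo(conditioned_soil: BinaryLayer, params: DetectionParams | None = None) -> BinaryLayer:
    """Dilate the soil layer twice with the 3x3 elliptical (cross) element.

    The result T1 is a halo superset of the soil layer used to test for
    adjacent grass.
    """
    params = params or DetectionParams()
    halo = ndimage.binary_dilation(
        conditioned_soil.mask, structure=_CROSS3, iterations=params.dilation_iters
    )
    return BinaryLayer(halo, material_name=conditioned_soil.material_name)


def overlap_gate(grass: BinaryLayer, halo: BinaryLayer) -> tuple[bool, BinaryLayer]:
    """AND the grass layer with the soil halo and test its mean intensity.

    The gate passes iff the mean of T2 = grass AND halo over all pixels is
    non-zero, i.e. the two layers touch somewhere; otherwise the ROI holds
    no mound and contour analysis is skipped entirely.
    """
    if grass.mask.shape != halo.mask.shape:
        raise ValueError(
            f"layer shapes differ: {grass.mask.shape} vs {halo.mask.shape}"
        )
    t2 = grass.mask & halo.mask
    mean = float(t2.sum()) / t2.size
    return mean > 0.0, BinaryLayer(t2, material_name="overlap")


# ---------------------------------------------------------------------------
# border following and contour geometry
# ---------------------------------------------------------------------------

# Moore neighbourhood in clockwise order starting due west
_MOORE = np.array(
    [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)], dtype=int
)


_MOORE_INDEX = {(int(d[0]), int(d[1])): i for i, d in enumerate(_MOORE)}


def _trace_outer_border(comp: np.ndarray) -> np.ndarray:
    """Follow the outer border of a single 8-connected component.

    Moore-neighbour tracing from the first foreground pixel in raster scan
    order, stopping when the initial boundary move repeats.  Returns (N, 2)
    integer (row, col) coordinates ordered along the border.
    """
    rows, cols = np.nonzero(comp)
    start = (int(rows[0]), int(cols[0]))
    if len(rows) == 1:
        return np.array([start])
    H, W = comp.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < H and 0 <= c < W and comp[r, c]

    boundary = [start]
    p = start
    backtrack = (start[0], start[1] - 1)  # west neighbour, background by scan order
    first_move: tuple | None = None
    for _ in range(4 * (H * W) + 8):
        bidx = _MOORE_INDEX[(backtrack[0] - p[0], backtrack[1] - p[1])]
        q = None
        for k in range(1, 9):
            d = (bidx + k) % 8
            cand = (p[0] + _MOORE[d][0], p[1] + _MOORE[d][1])
            if fg(*cand):
                q = cand
                # last background neighbour tested before q becomes the new
                # backtrack (for k == 1 it is the previous backtrack itself)
                prev = (bidx + k - 1) % 8
                backtrack = (p[0] + _MOORE[prev][0], p[1] + _MOORE[prev][1])
                break
        if q is None:  # isolated pixel; cannot occur for multi-pixel components
            break
        if first_move is None:
            first_move = (p, q)
        elif (p, q) == first_move:
            break
        boundary.append(q)
        p = q
    if len(boundary) > 1 and boundary[-1] == boundary[0]:
        boundary.pop()
    return np.array(boundary)


def _raster_hu(rows: np.ndarray, cols: np.ndarray) -> tuple[tuple[float, float], np.ndarray]:
    """Centroid and the 7 Hu invariants of a filled pixel set (unit mass per pixel)."""
    x = cols.astype(float)
    y = rows.astype(float)
    m00 = float(x.size)
    if m00 == 0:
        raise DegenerateShapeError("empty region")
    xb, yb = x.mean(), y.mean()
    dx, dy = x - xb, y - yb

    def mu(p, q):
        return float(np.sum(dx**p * dy**q))

    mu20, mu02, mu11 = mu(2, 0), mu(0, 2), mu(1, 1)
    mu30, mu03 = mu(3, 0), mu(0, 3)
    mu21, mu12 = mu(2, 1), mu(1, 2)

    def eta(m, p, q):
        return m / m00 ** (1 + (p + q) / 2.0)

    n20, n02, n11 = eta(mu20, 2, 0), eta(mu02, 0, 2), eta(mu11, 1, 1)
    n30, n03 = eta(mu30, 3, 0), eta(mu03, 0, 3)
    n21, n12 = eta(mu21, 2, 1), eta(mu12, 1, 2)

    h = np.empty(7)
    h[0] = n20 + n02
    h[1] = (n20 - n02) ** 2 + 4 * n11**2
    h[2] = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    h[3] = (n30 + n12) ** 2 + (n21 + n03) ** 2
    h[4] = (n30 - 3 * n12) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) + (3 * n21 - n03) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    h[5] = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (
        n30 + n12
    ) * (n21 + n03)
    h[6] = (3 * n21 - n03) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) - (n30 - 3 * n12) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    return (yb, xb), h


def _signed_log(h: np.ndarray) -> np.ndarray:
    out = np.full(7, np.nan)
    big = np.abs(h) >= _HU_ZERO_FLOOR
    out[big] = np.sign(h[big]) * np.log10(np.abs(h[big]))
    return out


def log_hu(obj: "Contour | ShapeTemplate | np.ndarray") -> np.ndarray:
    """Signed-log Hu vector of a contour, template, or binary mask.

    Entries excluded by the zero floor are NaN ("absent").
    """
    if isinstance(obj, Contour) or isinstance(obj, ShapeTemplate):
        return np.asarray(obj.log_hu, dtype=float)
    mask = np.asarray(obj).astype(bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise DegenerateShapeError("mask has no foreground")
    _, h = _raster_hu(rows, cols)
    return _signed_log(h)


def _shoelace_area(points: np.ndarray) -> float:
    y = points[:, 0]
    x = points[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _polyline_length(points: np.ndarray) -> float:
    closed = np.vstack([points, points[:1]])
    return float(np.sum(np.hypot(*(np.diff(closed, axis=0).T))))


def find_contours(layer: BinaryLayer) -> list[Contour]:
    """Extract the outer border of every 8-connected foreground component.

    Border following yields the ordered boundary pixel centres of each
    component (outermost borders only; holes are ignored).  Components with
    fewer than 3 boundary points cannot form a polygon and are dropped.
    Geometry per contour: shoelace (Green's theorem) area of the boundary
    polygon, polygonal perimeter, raster centroid, minimum enclosing circle
    radius and the signed-log Hu vector of the filled component.
    """
    mask = layer.mask
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=_RECT3)
    contours: list[Contour] = []
    for sl, idx in zip(ndimage.find_objects(labels), range(1, n + 1)):
        comp = labels[sl] == idx
        pts = _trace_outer_border(comp).astype(float)
        if pts.shape[0] < 3:
            continue
        pts[:, 0] += sl[0].start
        pts[:, 1] += sl[1].start
        rr, cc = np.nonzero(comp)
        centroid, h = _raster_hu(rr + sl[0].start, cc + sl[1].start)
        radius = float(
            shapely.minimum_bounding_radius(MultiPoint(pts[:, ::-1]))  # (x, y)
        )
        contours.append(
            Contour(
                points=pts,
                perimeter_px=_polyline_length(pts),
                area_px2=_shoelace_area(pts),
                centroid=centroid,
                enclosing_radius_px=max(radius, 0.5),
                log_hu=_signed_log(h),
            )
        )
    return contours


# ---------------------------------------------------------------------------
# shape matching and pairing
# ---------------------------------------------------------------------------


def shape_ratio(a: np.ndarray, b: np.ndarray) -> float:
    """Hu-moment match ratio: sum over included terms of |1/m_i^S - 1/m_i^T|.

    Lower is closer.  A term is skipped if excluded (NaN) for either shape;
    if all seven are excluded the shapes are incomparable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    valid = np.isfinite(a) & np.isfinite(b) & (a != 0) & (b != 0)
    if not valid.any():
        raise IncomparableShapesError("no comparable Hu terms between shapes")
    return float(np.sum(np.abs(1.0 / a[valid] - 1.0 / b[valid])))


def filter_soil_contours(
    contours: list[Contour],
    templates: ShapeTemplateSet,
    params: DetectionParams | None = None,
) -> list[Contour]:
    """Keep soil contours that match a mound template and are large enough.

    A contour survives iff its best (minimum over templates) shape ratio is
    <= ``ratio_max`` and its perimeter is >= ``perimeter_min_px``.  The best
    ratio and the matching template name are recorded on the contour.
    """
    if len(templates) == 0:
        raise ValueError("template set is empty")
    params = params or DetectionParams()
    kept = []
    for c in contours:
        ratios = []
        for t in templates.templates:
            try:
                ratios.append(shape_ratio(c.log_hu, t.log_hu))
            except IncomparableShapesError:
                ratios.append(np.inf)
        best = int(np.argmin(ratios))
        c.best_ratio = float(ratios[best])
        c.best_template = templates.templates[best].name
        if c.best_ratio <= params.ratio_max and c.perimeter_px >= params.perimeter_min_px:
            kept.append(c)
    return kept


def _min_inter_contour_distance(a: Contour, b: Contour) -> float:
    """ILD: minimum Euclidean distance over all point pairs of two contours."""
    tree = cKDTree(b.points)
    d, _ = tree.query(a.points, k=1)
    return float(d.min())


def pair_and_confirm(
    soil: list[Contour],
    grass: list[Contour],
    params: DetectionParams | None = None,
) -> list[Detection]:
    """Confirm soil contours by proximity to a qualifying grass contour.

    A grass contour GC qualifies for soil contour SC iff

    * centroid distance d(SC, GC) <= ``radius_factor`` * rad(SC), where rad
      is SC's enclosing-circle radius,
    * P_gc >= P_sc or P_gc / P_sc >= ``perimeter_prop_min`` (the first
      condition implies the second at the default 0.8; both are evaluated),
    * the minimum inter-contour distance ILD <= ``ild_max_px``.

    Each soil contour yields at most one Detection listing all qualifying
    partners; the reported d/ILD/prop are those of the nearest partner.
    """
    params = params or DetectionParams()
    detections = []
    for sc in soil:
        partners: list[tuple[float, float, float, Contour]] = []
        for gc in grass:
            d = float(
                np.hypot(
                    sc.centroid[0] - gc.centroid[0], sc.centroid[1] - gc.centroid[1]
                )
            )
            if d > params.radius_factor * sc.enclosing_radius_px:
                continue
            prop = gc.perimeter_px / sc.perimeter_px
            if not (gc.perimeter_px >= sc.perimeter_px or prop >= params.perimeter_prop_min):
                continue
            ild = _min_inter_contour_distance(sc, gc)
            if ild > params.ild_max_px:
                continue
            partners.append((d, ild, prop, gc))
        if partners:
            partners.sort(key=lambda t: t[0])
            d, ild, prop, _ = partners[0]
            detections.append(
                Detection(
                    soil_contour=sc,
                    paired_grass_contours=[p[3] for p in partners],
                    best_ratio=sc.best_ratio if sc.best_ratio is not None else 0.0,
                    best_template=sc.best_template or "",
                    d_px=d,
                    ild_px=ild,
                    prop=prop,
                )
            )
    return detections


# ---------------------------------------------------------------------------
# templates and end-to-end detection
# ---------------------------------------------------------------------------


def load_templates(directory: str | Path) -> ShapeTemplateSet:
    """Load binary shape templates from a directory of PNG images."""
    import imageio.v3 as iio

    directory = Path(directory)
    templates = []
    for path in sorted(directory.glob("*.png")):
        img = np.asarray(iio.imread(path))
        if img.ndim == 3:
            img = img[..., 0]
        mask = img > (img.max() / 2 if img.max() > 1 else 0)
        templates.append(ShapeTemplate(path.stem, mask, log_hu(mask)))
    if not templates:
        raise FileNotFoundError(f"no PNG templates found in {directory}")
    return ShapeTemplateSet(templates)


def _draw_contour(overlay: np.ndarray, contour: Contour, color: tuple[int, int, int]) -> None:
    pts = np.round(contour.points).astype(int)
    r = np.clip(pts[:, 0], 0, overlay.shape[0] - 1)
    c = np.clip(pts[:, 1], 0, overlay.shape[1] - 1)
    overlay[r, c] = color


def detect_mounds(
    soil: BinaryLayer,
    grass: BinaryLayer,
    templates: ShapeTemplateSet,
    params: DetectionParams | None = None,
) -> tuple[list[Detection], np.ndarray]:
    """Run the full two-layer detection on one ROI.

    Orchestrates condition -> halo -> overlap gate -> soil contours ->
    shape filter -> grass contours -> pairing.  If the overlap gate fails,
    the empty result is returned without any contour analysis.  The overlay
    raster draws soil contours in blue, grass contours in magenta and
    confirmed mound contours in yellow.
    """
    params = params or DetectionParams()
    if soil.mask.shape != grass.mask.shape:
        raise ValueError("soil and grass layers must share one ROI raster")
    overlay = np.zeros(soil.mask.shape + (3,), dtype=np.uint8)
    overlay[soil.mask] = (60, 40, 25)
    overlay[grass.mask] = (30, 70, 30)

    soil_c = condition_soil(soil, params)
    grass_c = condition_grass(grass, params)
    halo = make_soil_halo(soil_c, params)
    passes, _t2 = overlap_gate(grass_c, halo)
    if not passes:
        return [], overlay

    soil_contours = find_contours(soil_c)
    kept = filter_soil_contours(soil_contours, templates, params)
    grass_contours = find_contours(grass_c)
    detections = pair_and_confirm(kept, grass_contours, params)

    for c in soil_contours:
        _draw_contour(overlay, c, (80, 120, 255))
    for c in grass_contours:
        _draw_contour(overlay, c, (255, 105, 180))
    for det in detections:
        _draw_contour(overlay, det.soil_contour, (255, 230, 40))
        for gc in det.paired_grass_contours:
            _draw_contour(overlay, gc, (255, 160, 40))
    return detections, overlay


def detections_to_json(detections: list[Detection]) -> str:
    """Serialize detections deterministically (sorted keys, plain floats)."""
    payload = []
    for det in detections:
        payload.append(
            {
                "centroid_row": round(det.soil_contour.centroid[0], 6),
                "centroid_col": round(det.soil_contour.centroid[1], 6),
                "polygon_row_col": [
                    [float(r), float(c)] for r, c in det.soil_contour.points
                ],
                "perimeter_px": round(det.soil_contour.perimeter_px, 6),
                "area_px2": round(det.soil_contour.area_px2, 6),
                "best_ratio": round(det.best_ratio, 6),
                "best_template": det.best_template,
                "d_px": round(det.d_px, 6),
                "ild_px": round(det.ild_px, 6),
                "prop": round(det.prop, 6),
                "n_grass_partners": len(det.paired_grass_contours),
            }
        )
    return json.dumps(payload, sort_keys=True, indent=1)
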