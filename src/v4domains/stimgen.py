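"""Parametric visual stimuli: contour features and non-Cartesian gratings.

Stimuli follow the display conventions of the experiment they model: a
30 pixel/degree display, two-pixel-wide contour strokes, bars and corner
edges of 10 and 20 px, curve radii of 10 and 20 px, and sinusoidal gratings
3 degrees (90 px) in diameter at spatial frequencies of 1, 2 and 4 cycle/deg.

Coordinate conventions
----------------------
Images are row-major with the origin at the top-left pixel.  Parametric
geometry lives in a math frame centered on the canvas center with x to the
right and y upward; orientation is a counter-clockwise rotation in that
frame.  Orientation 0 is the canonical pose: a horizontal bar, a curve
opening upward (arc at the bottom of its circle), a corner with its apex up.

Rasterization is binary and anti-alias free: a pixel is foreground when its
center lies within ``line_width/2`` of the ideal contour, which makes pixel
counts reproducible integers and rotation by multiples of 90 degrees an
exact symmetry of the pixel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "DisplayGeometry",
    "ShapeClass",
    "GratingClass",
    "ContourStimulus",
    "GratingStimulus",
    "StimulusSet",
    "make_bar",
    "make_curve",
    "make_corner",
    "make_pi_shape",
    "make_cartesian_grating",
    "make_concentric_grating",
    "make_radial_grating",
    "build_protocol",
]

# Allowed parameter grids
CURVE_RADIANS_4X = (120.0, 180.0)
CURVE_RADIANS_16X = (60.0, 90.0, 120.0, 180.0)
CORNER_ANGLES = (45.0, 90.0, 135.0)
SIZES_PX = (10, 20)
SPATIAL_FREQS = (1.0, 2.0, 4.0)
BAR_ORIENTATIONS = tuple(22.5 * i for i in range(8))
CONTOUR_ORIENTATIONS = tuple(45.0 * i for i in range(8))

#: sampling step (px) along ideal contours for distance queries
_SAMPLE_STEP = 0.02


class ShapeClass(str, Enum):
    bar = "bar"
    curve = "curve"
    corner = "corner"
    pi_shape = "pi_shape"


class GratingClass(str, Enum):
    cartesian = "cartesian"
    concentric = "concentric"
    radial = "radial"


@dataclass(frozen=True)
class DisplayGeometry:
    """Display metadata: pixel pitch, canvas size and background level."""

    pixels_per_degree: float = 30.0
    canvas_size: tuple[int, int] = (64, 64)  # (rows, cols)
    background_luminance: float = 0.5

    def __post_init__(self) -> None:
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be positive")
        if min(self.canvas_size) <= 0:
            raise ValueError("canvas dimensions must be positive")

    @property
    def center(self) -> tuple[float, float]:
        """Canvas center (row, col) in pixel-center coordinates."""
        return ((self.canvas_size[0] - 1) / 2.0, (self.canvas_size[1] - 1) / 2.0)


@dataclass(frozen=True)
class ContourStimulus:
    """A parametric contour feature (bar, curve, corner or Pi-shape)."""

    shape_class: ShapeClass
    size_px: float  # bar/corner edge length or curve radius
    orientation_deg: float
    radian_deg: float = float("nan")  # arc extent; curves/Pi only
    separation_angle_deg: float = float("nan")  # corner opening; corners only
    line_width_px: float = 2.0

    # -- parametric geometry ------------------------------------------------
    def polyline(self, n_per_segment: int | None = None) -> np.ndarray:
        """Dense (x, y) sample of the ideal contour in the centered math frame.

        The sample is fine enough (step ``_SAMPLE_STEP`` px) that the distance
        from any point to the sample approximates the distance to the ideal
        contour to within half the step.
        """
        pts = _canonical_points(self)
        theta = np.deg2rad(self.orientation_deg)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        return pts @ rot.T

    def rasterize(self, geometry: DisplayGeometry | None = None) -> np.ndarray:
        """Binary image: pixel centers within line_width/2 of the contour."""
        geometry = geometry or DisplayGeometry()
        pts = self.polyline()
        nrow, ncol = geometry.canvas_size
        crow, ccol = geometry.center
        # math frame -> image frame: x -> col offset, y -> -row offset
        sample = np.column_stack([crow - pts[:, 1], ccol + pts[:, 0]])
        tree = cKDTree(sample)
        rows, cols = np.mgrid[0:nrow, 0:ncol]
        centers = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
        d, _ = tree.query(centers, k=1)
        mask = d <= self.line_width_px / 2.0
        return mask.reshape(nrow, ncol)


def _canonical_points(stim: ContourStimulus) -> np.ndarray:
    """Sample the orientation-0 contour at ~_SAMPLE_STEP px spacing."""
    if stim.shape_class is ShapeClass.bar:
        L = stim.size_px
        n = max(2, int(np.ceil(L / _SAMPLE_STEP)) + 1)
        x = np.linspace(-L / 2.0, L / 2.0, n)
        return np.column_stack([x, np.zeros_like(x)])
    if stim.shape_class is ShapeClass.curve:
        r, rad = stim.size_px, np.deg2rad(stim.radian_deg)
        arc_len = r * rad
        n = max(2, int(np.ceil(arc_len / _SAMPLE_STEP)) + 1)
        # arc at the bottom of the circle -> opens upward
        phi = np.linspace(-np.pi / 2 - rad / 2, -np.pi / 2 + rad / 2, n)
        return np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    if stim.shape_class is ShapeClass.corner:
        L, sep = stim.size_px, np.deg2rad(stim.separation_angle_deg)
        n = max(2, int(np.ceil(L / _SAMPLE_STEP)) + 1)
        t = np.linspace(0.0, L, n)
        # apex at origin pointing up; edges descend symmetrically
        a1 = -np.pi / 2 - sep / 2
        a2 = -np.pi / 2 + sep / 2
        e1 = np.column_stack([t * np.cos(a1), t * np.sin(a1)])
        e2 = np.column_stack([t * np.cos(a2), t * np.sin(a2)])
        return np.vstack([e1[::-1], e2])
    if stim.shape_class is ShapeClass.pi_shape:
        r, rad = stim.size_px, np.deg2rad(stim.radian_deg)
        # three equal chords inscribed in the matched arc's circle
        knots = np.linspace(-np.pi / 2 - rad / 2, -np.pi / 2 + rad / 2, 4)
        verts = np.column_stack([r * np.cos(knots), r * np.sin(knots)])
        segs = []
        for a, b in zip(verts[:-1], verts[1:]):
            seg_len = float(np.hypot(*(b - a)))
            n = max(2, int(np.ceil(seg_len / _SAMPLE_STEP)) + 1)
            t = np.linspace(0.0, 1.0, n)[:, None]
            segs.append(a + t * (b - a))
        return np.vstack(segs)
    raise ValueError(f"unknown shape class {stim.shape_class}")


# -- contour constructors ---------------------------------------------------

def make_bar(length_px: float, orientation_deg: float, line_width_px: float = 2.0) -> ContourStimulus:
    """A straight bar segment centered on the canvas center."""
    if length_px <= 0:
        raise ValueError("bar length must be positive")
    return ContourStimulus(ShapeClass.bar, length_px, orientation_deg, line_width_px=line_width_px)


def make_curve(radius_px: float, radian_deg: float, orientation_deg: float,
               line_width_px: float = 2.0) -> ContourStimulus:
    """A circular arc of the given radius subtending ``radian_deg``."""
    if radius_px <= 0:
        raise ValueError("curve radius must be positive")
    if not 0.0 < radian_deg <= 360.0:
        raise ValueError("arc extent must be in (0, 360] degrees")
    return ContourStimulus(ShapeClass.curve, radius_px, orientation_deg,
                           radian_deg=radian_deg, line_width_px=line_width_px)


def make_corner(edge_px: float, separation_angle_deg: float, orientation_deg: float,
                line_width_px: float = 2.0) -> ContourStimulus:
    """Two equal edges meeting at a vertex with the given opening angle."""
    if edge_px <= 0:
        raise ValueError("edge length must be positive")
    if separation_angle_deg not in CORNER_ANGLES:
        raise ValueError(f"separation angle must be one of {CORNER_ANGLES}")
    return ContourStimulus(ShapeClass.corner, edge_px, orientation_deg,
                           separation_angle_deg=separation_angle_deg,
                           line_width_px=line_width_px)


def make_pi_shape(radius_px: float, radian_deg: float, orientation_deg: float,
                  line_width_px: float = 2.0) -> ContourStimulus:
    """Hexagonal-segment (Pi-shape) stimulus shadowing a smooth curve.

    Three equal chords are inscribed in the matched arc's circle, so the
    Pi-shape shares its endpoints with the curve of the same radius and arc
    extent but is rectilinear rather than smooth.
    """
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    if not 0.0 < radian_deg <= 360.0:
        raise ValueError("arc extent must be in (0, 360] degrees")
    return ContourStimulus(ShapeClass.pi_shape, radius_px, orientation_deg,
                           radian_deg=radian_deg, line_width_px=line_width_px)


# -- gratings ---------------------------------------------------------------

@dataclass(frozen=True)
class GratingStimulus:
    """Full-contrast sinusoidal grating in a blurred circular aperture."""

    grating_class: GratingClass
    spatial_frequency: float  # cycle/deg
    orientation_deg: float = 0.0  # cartesian only
    diameter_px: int = 90
    blur_margin_frac: float = 0.1  # raised-cosine taper over outer fraction of radius

    def rasterize(self, geometry: DisplayGeometry | None = None) -> np.ndarray:
        """Luminance image in [0, 1]; background at 0.5 (mid-gray)."""
        geometry = geometry or DisplayGeometry()
        nrow, ncol = geometry.canvas_size
        crow, ccol = geometry.center
        rows, cols = np.mgrid[0:nrow, 0:ncol]
        # degrees from patch center; y upward
        x = (cols - ccol) / geometry.pixels_per_degree
        y = (crow - rows) / geometry.pixels_per_degree
        value = self.carrier(x, y)
        r_px = np.hypot(cols - ccol, rows - crow)
        value = value * _aperture(r_px, self.diameter_px / 2.0, self.blur_margin_frac)
        return 0.5 * (1.0 + value)

    def carrier(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Analytic carrier sin value at (x, y) in degrees, before aperture."""
        sf = self.spatial_frequency
        if self.grating_class is GratingClass.cartesian:
            th = np.deg2rad(self.orientation_deg)
            return np.sin(2 * np.pi * sf * (x * np.cos(th) + y * np.sin(th)))
        if self.grating_class is GratingClass.concentric:
            return np.sin(2 * np.pi * sf * np.hypot(x, y))
        if self.grating_class is GratingClass.radial:
            return np.sin(2 * np.pi * sf * np.arctan2(y, x))
        raise ValueError(f"unknown grating class {self.grating_class}")


def _aperture(r_px: np.ndarray, radius_px: float, blur_frac: float) -> np.ndarray:
    """Raised-cosine taper: 1 inside, soft edge over the outer blur fraction."""
    inner = radius_px * (1.0 - blur_frac)
    out = np.ones_like(r_px, dtype=float)
    ramp = (r_px - inner) / (radius_px - inner)
    edge = 0.5 * (1.0 + np.cos(np.pi * np.clip(ramp, 0.0, 1.0)))
    out = np.where(r_px > inner, edge, out)
    out[r_px >= radius_px] = 0.0
    return out


def make_cartesian_grating(sf: float, orientation_deg: float, diameter_px: int = 90) -> GratingStimulus:
    return GratingStimulus(GratingClass.cartesian, sf, orientation_deg, diameter_px)


def make_concentric_grating(sf: float, diameter_px: int = 90) -> GratingStimulus:
    return GratingStimulus(GratingClass.concentric, sf, diameter_px=diameter_px)


def make_radial_grating(sf: float, diameter_px: int = 90) -> GratingStimulus:
    return GratingStimulus(GratingClass.radial, sf, diameter_px=diameter_px)


# -- protocols --------------------------------------------------------------

@dataclass
class StimulusSet:
    """An ordered stimulus protocol with category and form annotations.

    ``category_of`` maps stim_id to a family label (curve/corner/bar/pi_shape/
    cartesian/concentric/radial); ``form_of`` collapses orientation, so every
    form groups the 8 rotations of one geometry (or the SFs of one grating
    family where orientation does not apply).
    """

    protocol_name: str
    stimuli: list[ContourStimulus | GratingStimulus]
    category_of: dict[int, str] = field(default_factory=dict)
    form_of: dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.stimuli)

    @property
    def stim_ids(self) -> list[int]:
        return list(range(len(self.stimuli)))

    def ids_in_category(self, category: str | Iterable[str]) -> list[int]:
        cats = {category} if isinstance(category, str) else set(category)
        return [i for i in self.stim_ids if self.category_of[i] in cats]

    @property
    def forms(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in self.stim_ids:
            seen.setdefault(self.form_of[i], None)
        return list(seen)

    def ids_in_form(self, form: str) -> list[int]:
        return [i for i in self.stim_ids if self.form_of[i] == form]

    def manifest(self) -> pd.DataFrame:
        """Tabular description, one row per stimulus."""
        rows = []
        for i, s in enumerate(self.stimuli):
            if isinstance(s, ContourStimulus):
                rows.append(dict(stim_id=i, **{"class": s.shape_class.value},
                                 form_id=self.form_of[i], size_px=s.size_px,
                                 radian_deg=s.radian_deg,
                                 sep_angle_deg=s.separation_angle_deg,
                                 orientation_deg=s.orientation_deg, sf_cpd=np.nan))
            else:
                rows.append(dict(stim_id=i, **{"class": s.grating_class.value},
                                 form_id=self.form_of[i], size_px=s.diameter_px,
                                 radian_deg=np.nan, sep_angle_deg=np.nan,
                                 orientation_deg=s.orientation_deg,
                                 sf_cpd=s.spatial_frequency))
        return pd.DataFrame(rows)


def build_protocol(name: str) -> StimulusSet:
    """Build one of the named stimulus protocols.

    map4x
        Widefield contour set: bars (2 lengths x 8 orientations, 22.5 deg
        grid), curves (2 radii x {120, 180} deg arcs x 8 orientations) and
        corners (2 edges x 3 opening angles x 8 orientations) = 96 stimuli.
    map16x
        Single-cell contour set: as map4x but curves at 4 arc extents and
        additionally 4 Pi-shape forms x 8 orientations = 160 stimuli,
        20 orientation-collapsed forms.
    gratings
        Cartesian (8 orientations x 3 SF), concentric (3 SF) and radial
        (3 SF) gratings = 30 stimuli.
    """
    stimuli: list[ContourStimulus | GratingStimulus] = []
    category: dict[int, str] = {}
    form: dict[int, str] = {}

    def add(stim, cat: str, form_id: str) -> None:
        category[len(stimuli)] = cat
        form[len(stimuli)] = form_id
        stimuli.append(stim)

    if name in ("map4x", "map16x"):
        for L in SIZES_PX:
            for ori in BAR_ORIENTATIONS:
                add(make_bar(L, ori), "bar", f"bar_L{L}")
        radians = CURVE_RADIANS_4X if name == "map4x" else CURVE_RADIANS_16X
        for r in SIZES_PX:
            for rad in radians:
                for ori in CONTOUR_ORIENTATIONS:
                    add(make_curve(r, rad, ori), "curve", f"curve_r{r}_a{rad:g}")
        for L in SIZES_PX:
            for sep in CORNER_ANGLES:
                for ori in CONTOUR_ORIENTATIONS:
                    add(make_corner(L, sep, ori), "corner", f"corner_L{L}_s{sep:g}")
        if name == "map16x":
            for r in SIZES_PX:
                for rad in CURVE_RADIANS_4X:  # Pi-shapes shadow the 120/180 arcs
                    for ori in CONTOUR_ORIENTATIONS:
                        add(make_pi_shape(r, rad, ori), "pi_shape", f"pi_r{r}_a{rad:g}")
    elif name == "gratings":
        for sf in SPATIAL_FREQS:
            for ori in CONTOUR_ORIENTATIONS:
                add(make_cartesian_grating(sf, ori), "cartesian", f"cartesian_sf{sf:g}")
        for sf in SPATIAL_FREQS:
            add(make_concentric_grating(sf), "concentric", f"concentric_sf{sf:g}")
        for sf in SPATIAL_FREQS:
            add(make_radial_grating(sf), "radial", f"radial_sf{sf:g}")
    else:
        raise ValueError(f"unknown protocol {name!r}; expected map4x, map16x or gratings")

    return StimulusSet(name, stimuli, category, form)
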