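"""Synthetic sagittal B-mode-like bladder phantoms.

A phantom is a 2D grayscale image with known ground truth: an anechoic
(near-black) elliptical lumen, a hyperechoic (bright) wall band whose
ventral/dorsal thicknesses are specified, mid-level surrounding tissue,
and multiplicative Rayleigh speckle.  The transducer sits at the top of
the image, so row 0 is the ventral (superficial) side.

The renderer is a flat-intensity tissue model, not a wave-propagation
simulator: its job is to exercise the pixel-based measurement operators
under realistic segmentation conditions, with an exact ground-truth
sidecar for every image.

Two ultrasound artifacts can be injected (both compromise only the dorsal
measurement): an anechoic shadow cone cast downward by an intravesical air
bubble, and a bright near-field echo band from high-impedance superficial
tissue.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "LUMEN_LEVEL",
    "WALL_LEVEL",
    "TISSUE_LEVEL",
    "Artifact",
    "LumenEllipse",
    "GroundTruth",
    "SpeckleModel",
    "BModePhantom",
    "geometry_for_volume",
    "truth_masks",
    "render",
    "inject_artifact",
    "save_phantom",
    "load_phantom",
]

# Echogenicity classes of the flat-intensity tissue model (arbitrary units
# in [0, 1]).  The measurement thresholds are derived from these levels.
LUMEN_LEVEL = 0.05
WALL_LEVEL = 0.80
TISSUE_LEVEL = 0.35
_SHADOW_ATTENUATION = 0.03

DEFAULT_SPACING_MM = 0.02
DEFAULT_SHAPE = (1024, 1024)


@dataclass(frozen=True)
class Artifact:
    """Descriptor of an injected imaging artifact.

    ``air_bubble_shadow``: anechoic cone with apex at (x_mm, y_mm) opening
    downward (away from the transducer) with the given half angle.
    ``near_field_echo``: bright band covering the top ``depth_mm`` of the
    image with the given gain.
    """

    kind: str
    x_mm: float = 0.0
    y_mm: float = 0.0
    half_angle_deg: float = 8.0
    depth_mm: float = 1.0
    gain: float = 0.6

    KINDS = ("air_bubble_shadow", "near_field_echo")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown artifact type {self.kind!r}; expected {self.KINDS}")


@dataclass(frozen=True)
class LumenEllipse:
    """Lumen cross-section in the sagittal plane (mm, image coordinates)."""

    cx_mm: float
    cy_mm: float
    semi_x_mm: float
    semi_y_mm: float
    rot_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.semi_x_mm <= 0 or self.semi_y_mm <= 0:
            raise ValueError("lumen semi-axes must be > 0")

    @property
    def is_circle(self) -> bool:
        return self.semi_x_mm == self.semi_y_mm

    def area_mm2(self) -> float:
        return float(np.pi * self.semi_x_mm * self.semi_y_mm)


@dataclass(frozen=True)
class GroundTruth:
    """Exact geometry behind a rendered phantom."""

    lumen: LumenEllipse
    t_ventral_mm: float
    t_dorsal_mm: float
    volume_ml: float
    artifacts: tuple[Artifact, ...] = ()

    def __post_init__(self) -> None:
        if self.t_ventral_mm <= 0 or self.t_dorsal_mm <= 0:
            raise ValueError("wall thicknesses must be > 0")
        if self.volume_ml <= 0:
            raise ValueError("volume must be > 0")


@dataclass(frozen=True)
class SpeckleModel:
    """Multiplicative Rayleigh speckle: unit-mean factor field, spatially
    correlated with a Gaussian grain of ``grain_px`` pixels."""

    enabled: bool = True
    grain_px: float = 1.0


@dataclass
class BModePhantom:
    """Rendered B-mode-like image plus its ground-truth sidecar."""

    image: np.ndarray
    spacing_mm: float = DEFAULT_SPACING_MM
    plane: str = "sagittal"
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        if self.image.ndim != 2 or min(self.image.shape) < 256:
            raise ValueError("phantom grid must be 2D and at least 256x256")
        if self.spacing_mm <= 0:
            raise ValueError("pixel spacing must be > 0")

    @property
    def fov_mm(self) -> tuple[float, float]:
        return (self.image.shape[0] * self.spacing_mm, self.image.shape[1] * self.spacing_mm)


def geometry_for_volume(
    volume_ml: float,
    t_ventral_mm: float,
    t_dorsal_mm: float,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    spacing_mm: float = DEFAULT_SPACING_MM,
) -> GroundTruth:
    """Spherical-bladder ground truth centered in the field of view."""
    if volume_ml <= 0:
        raise ValueError("volume must be > 0")
    r_mm = 10.0 * (3.0 * volume_ml / (4.0 * np.pi)) ** (1.0 / 3.0)
    cy = shape[0] * spacing_mm / 2.0
    cx = shape[1] * spacing_mm / 2.0
    lumen = LumenEllipse(cx, cy, r_mm, r_mm)
    return GroundTruth(lumen, t_ventral_mm, t_dorsal_mm, volume_ml)


_MESH_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _mesh(shape: tuple[int, int], spacing: float) -> tuple[np.ndarray, np.ndarray]:
    key = (shape, spacing)
    if key not in _MESH_CACHE:
        y = (np.arange(shape[0], dtype=np.float32) * spacing)[:, None]
        x = (np.arange(shape[1], dtype=np.float32) * spacing)[None, :]
        _MESH_CACHE[key] = (np.broadcast_to(y, shape), np.broadcast_to(x, shape))
    return _MESH_CACHE[key]


def truth_masks(
    truth: GroundTruth, shape: tuple[int, int], spacing_mm: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean (lumen, ventral wall, dorsal wall) masks at pixel centers.

    The wall band is the set of pixels within Euclidean distance t of the
    lumen, with t = t_ventral above the lumen center row and t_dorsal
    below.  For an axis-aligned circular lumen the distance is exact; for
    a general ellipse it is taken from a Euclidean distance transform.
    """
    lum = truth.lumen
    Y, X = _mesh(shape, spacing_mm)
    if lum.is_circle and lum.rot_deg == 0.0:
        r = np.hypot(X - lum.cx_mm, Y - lum.cy_mm)
        lumen = r <= lum.semi_x_mm
        dist = r - lum.semi_x_mm
    else:
        th = np.deg2rad(lum.rot_deg)
        xr = (X - lum.cx_mm) * np.cos(th) + (Y - lum.cy_mm) * np.sin(th)
        yr = -(X - lum.cx_mm) * np.sin(th) + (Y - lum.cy_mm) * np.cos(th)
        lumen = (xr / lum.semi_x_mm) ** 2 + (yr / lum.semi_y_mm) ** 2 <= 1.0
        dist = ndimage.distance_transform_edt(~lumen, sampling=spacing_mm)
    t_side = np.where(Y < lum.cy_mm, truth.t_ventral_mm, truth.t_dorsal_mm)
    wall = (~lumen) & (dist > 0) & (dist <= t_side)
    ventral = wall & (Y < lum.cy_mm)
    dorsal = wall & ~ventral
    return lumen, ventral, dorsal


def _validate_fov(truth: GroundTruth, shape, spacing, margin_mm: float = 0.2) -> None:
    lum = truth.lumen
    t_max = max(truth.t_ventral_mm, truth.t_dorsal_mm)
    # conservative bound: rotated ellipse fits in its semi-major circle
    reach = max(lum.semi_x_mm, lum.semi_y_mm) + t_max + margin_mm
    fy = shape[0] * spacing
    fx = shape[1] * spacing
    if (
        lum.cx_mm - reach < 0
        or lum.cy_mm - reach < 0
        or lum.cx_mm + reach > fx
        or lum.cy_mm + reach > fy
    ):
        raise ValueError(
            "geometry does not fit the field of view with wall margins: "
            f"center=({lum.cx_mm:.2f},{lum.cy_mm:.2f}) mm, reach={reach:.2f} mm, "
            f"FOV=({fx:.2f},{fy:.2f}) mm"
        )


def _apply_artifact(image: np.ndarray, art: Artifact, spacing: float) -> np.ndarray:
    Y, X = _mesh(image.shape, spacing)
    fy, fx = image.shape[0] * spacing, image.shape[1] * spacing
    out = image.copy()
    if art.kind == "air_bubble_shadow":
        if not (0 <= art.x_mm <= fx and 0 <= art.y_mm <= fy):
            raise ValueError("artifact location outside the field of view")
        halfwidth = (Y - art.y_mm) * np.tan(np.deg2rad(art.half_angle_deg)) + 0.05
        cone = (Y >= art.y_mm) & (np.abs(X - art.x_mm) <= halfwidth)
        out[cone] *= _SHADOW_ATTENUATION
    elif art.kind == "near_field_echo":
        if not 0 < art.depth_mm <= fy:
            raise ValueError("near-field echo depth outside the field of view")
        band = Y < art.depth_mm
        out[band] = 1.0 - (1.0 - out[band]) * (1.0 - art.gain)
    return out


def render(
    truth: GroundTruth,
    spacing_mm: float = DEFAULT_SPACING_MM,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    speckle: SpeckleModel = SpeckleModel(),
    seed: int | np.random.SeedSequence | None = None,
) -> BModePhantom:
    """Render the phantom: flat tissue classes, speckle, then artifacts.

    Deterministic for a fixed ``seed``.  With ``speckle.enabled=False`` the
    image consists of the exact class levels, which makes automated
    delineation recover the ground-truth masks pixel for pixel.
    """
    _validate_fov(truth, shape, spacing_mm)
    lumen, ventral, dorsal = truth_masks(truth, shape, spacing_mm)
    img = np.full(shape, TISSUE_LEVEL, dtype=np.float32)
    img[ventral | dorsal] = WALL_LEVEL
    img[lumen] = LUMEN_LEVEL
    if speckle.enabled:
        rng = np.random.default_rng(seed)
        factor = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=shape).astype(np.float32)
        if speckle.grain_px > 0:
            factor = ndimage.gaussian_filter(factor, speckle.grain_px)
        factor /= factor.mean()
        img = np.clip(img * factor, 0.0, 1.0)
    for art in truth.artifacts:
        img = _apply_artifact(img, art, spacing_mm)
        img = np.clip(img, 0.0, 1.0)
    return BModePhantom(image=img, spacing_mm=spacing_mm, truth=truth)


def inject_artifact(phantom: BModePhantom, artifact: Artifact) -> BModePhantom:
    """Return a new phantom with the artifact burnt into image and sidecar."""
    img = np.clip(_apply_artifact(phantom.image, artifact, phantom.spacing_mm), 0.0, 1.0)
    truth = phantom.truth
    if truth is not None:
        truth = replace(truth, artifacts=truth.artifacts + (artifact,))
    return BModePhantom(image=img, spacing_mm=phantom.spacing_mm, plane=phantom.plane, truth=truth)


def _truth_to_json(truth: GroundTruth) -> dict:
    lum = truth.lumen
    return {
        "lumen": {
            "cx": lum.cx_mm,
            "cy": lum.cy_mm,
            "a": lum.semi_x_mm,
            "b": lum.semi_y_mm,
            "rot": lum.rot_deg,
        },
        "t_ventral": truth.t_ventral_mm,
        "t_dorsal": truth.t_dorsal_mm,
        "volume_mL": truth.volume_ml,
        "artifacts": [asdict(a) for a in truth.artifacts],
    }


def _truth_from_json(d: dict) -> GroundTruth:
    lum = d["lumen"]
    return GroundTruth(
        lumen=LumenEllipse(lum["cx"], lum["cy"], lum["a"], lum["b"], lum.get("rot", 0.0)),
        t_ventral_mm=d["t_ventral"],
        t_dorsal_mm=d["t_dorsal"],
        volume_ml=d["volume_mL"],
        artifacts=tuple(Artifact(**a) for a in d.get("artifacts", [])),
    )


def save_phantom(phantom: BModePhantom, basepath: str) -> tuple[str, str]:
    """Write ``<basepath>.png`` (8-bit grayscale) and ``<basepath>.json``."""
    img_path = f"{basepath}.png"
    sidecar_path = f"{basepath}.json"
    iio.imwrite(img_path, np.round(phantom.image * 255.0).astype(np.uint8))
    sidecar = {"spacing_mm": phantom.spacing_mm, "plane": phantom.plane}
    if phantom.truth is not None:
        sidecar.update(_truth_to_json(phantom.truth))
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return img_path, sidecar_path


def load_phantom(basepath: str) -> BModePhantom:
    """Load a phantom written by :func:`save_phantom`."""
    img = iio.imread(f"{basepath}.png").astype(np.float32) / 255.0
    with open(f"{basepath}.json") as fh:
        sidecar = json.load(fh)
    truth = _truth_from_json(sidecar) if "lumen" in sidecar else None
    return BModePhantom(
        image=img,
        spacing_mm=sidecar["spacing_mm"],
        plane=sidecar.get("plane", "sagittal"),
        truth=truth,
    )
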