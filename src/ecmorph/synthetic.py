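"""Ground-truthed synthetic birefringence-like fiber images.

The generator emulates the three extracellular-matrix states seen in
long-term skin expansion: a homeostatic *control* dermis (moderate fiber
length and width, weak alignment), a *deposition* / fibrosis-like state
(longer, thicker fibers aligned along the stretch axis, mature/red
dominant), and a *degradation* / aging-like state (sparse, short,
fragmented, disorganized fibers with more immature/green signal).

Each image is built in optical-density space: fibers are anti-aliased
constant-width strokes accumulated into a per-stain OD plane, converted to
RGB transmittance through the stain basis (Beer-Lambert), with optional
Gaussian noise added in OD space.  The generating parameters are returned
alongside the image so every downstream stage can be tested as a recovery
problem.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .deconvolution import DEFAULT_BASIS, StainBasis

__all__ = [
    "FiberSpec",
    "ClassPreset",
    "SyntheticImage",
    "GroundTruth",
    "PRESET_NAMES",
    "make_preset",
    "sample_fibers",
    "render_image",
    "simulate_image",
    "gradient_series",
]

logger = logging.getLogger(__name__)

PRESET_NAMES = ("control", "deposition", "degradation")

#: Default field geometry: 512x512 px at 0.5 um/px (256x256 um).
DEFAULT_SHAPE = (512, 512)
DEFAULT_PIXEL_SIZE = 0.5

#: Peak optical density at the core of a fiber stroke.
_PEAK_OD = 1.0
#: Fraction of each fragment's arclength removed at fragment boundaries.
_GAP_FRACTION = 0.25


@dataclass(frozen=True)
class FiberSpec:
    """One fiber: where it sits and how it was drawn.

    ``orientation`` is axial (fibers are undirected) in [0, pi), measured
    from the +x (column) axis.  ``waviness`` is the amplitude of a single
    sinusoidal bend divided by the contour length; 0 means straight.
    ``fragments`` > 1 breaks the fiber into that many pieces with gaps.
    """

    anchor_um: tuple[float, float]  # (x, y) in image coordinates
    orientation: float
    length_um: float
    width_um: float
    waviness: float = 0.0
    stain: str = "mature"
    fragments: int = 1

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("fiber length must be > 0")
        if self.width_um <= 0:
            raise ValueError("fiber width must be > 0")
        if self.fragments < 1:
            raise ValueError("fragment count must be >= 1")
        if not 0.0 <= self.orientation < math.pi:
            raise ValueError("orientation must lie in [0, pi)")
        if self.waviness < 0:
            raise ValueError("waviness must be >= 0")
        if self.stain not in ("mature", "immature"):
            raise ValueError("stain must be 'mature' or 'immature'")


@dataclass(frozen=True)
class ClassPreset:
    """Sampling distributions for one ECM state.

    Lengths and widths are log-normal, parameterized by the median (um)
    and the log-space sigma.  Orientations follow a von Mises law on
    doubled angles (the standard axial-data device) centred on the stretch
    axis; ``kappa`` is its concentration, 0 meaning isotropic.  ``p_red``
    is the probability a fiber is mature (red channel).
    """

    name: str
    fiber_rate: float  # expected fibers per field
    length_median_um: float
    length_sigma: float
    width_median_um: float
    width_sigma: float
    kappa: float
    p_red: float
    mean_fragments: float = 1.0
    waviness: float = 0.05
    noise_sigma: float = 0.02  # OD units

    def __post_init__(self) -> None:
        for name in ("fiber_rate", "length_sigma", "width_sigma", "kappa",
                     "waviness", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_red <= 1.0:
            raise ValueError("p_red must lie in [0, 1]")
        if self.mean_fragments < 1:
            raise ValueError("mean_fragments must be >= 1")
        if self.length_median_um <= 0 or self.width_median_um <= 0:
            raise ValueError("length/width medians must be > 0")


_PRESETS = {
    "control": ClassPreset(
        name="control", fiber_rate=60, length_median_um=40.0, length_sigma=0.4,
        width_median_um=3.0, width_sigma=0.2, kappa=0.5, p_red=0.7,
        mean_fragments=1.0, waviness=0.08, noise_sigma=0.02,
    ),
    "deposition": ClassPreset(
        name="deposition", fiber_rate=90, length_median_um=80.0, length_sigma=0.4,
        width_median_um=5.0, width_sigma=0.2, kappa=4.0, p_red=0.85,
        mean_fragments=1.0, waviness=0.04, noise_sigma=0.02,
    ),
    "degradation": ClassPreset(
        name="degradation", fiber_rate=50, length_median_um=15.0, length_sigma=0.4,
        width_median_um=2.5, width_sigma=0.2, kappa=0.3, p_red=0.5,
        mean_fragments=3.0, waviness=0.12, noise_sigma=0.02,
    ),
}


def make_preset(name: str) -> ClassPreset:
    """Return the preset for one of the three ECM states."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid names are {', '.join(PRESET_NAMES)}"
        ) from None


@dataclass
class SyntheticImage:
    """Rendered RGB transmittance raster with its provenance."""

    rgb: np.ndarray  # HxWx3, values in [0, 1]
    pixel_size_um: float
    seed: int | None = None
    preset: str | None = None


@dataclass
class GroundTruth:
    """The fibers an image was rendered from, plus summary statistics.

    All summaries except porosity and the mature-area fraction are pure
    functions of the fiber list (see :meth:`recompute_summaries`); the two
    area fractions additionally depend on the rasterized geometry and are
    measured on the rendered coverage masks.
    """

    fibers: list[FiberSpec]
    fiber_count: int
    mean_length_um: float
    mean_width_um: float
    orientation_circular_variance: float
    porosity_pct: float
    mature_area_fraction: float

    @staticmethod
    def summaries_from_fibers(fibers: list[FiberSpec]) -> dict[str, float]:
        n = len(fibers)
        if n == 0:
            return {
                "fiber_count": 0,
                "mean_length_um": 0.0,
                "mean_width_um": 0.0,
                "orientation_circular_variance": 0.0,
            }
        lengths = np.array([f.length_um for f in fibers])
        widths = np.array([f.width_um for f in fibers])
        doubled = np.array([2.0 * f.orientation for f in fibers])
        resultant = abs(np.mean(np.exp(1j * doubled)))
        return {
            "fiber_count": n,
            "mean_length_um": float(lengths.mean()),
            "mean_width_um": float(widths.mean()),
            "orientation_circular_variance": float(1.0 - resultant),
        }

    def recompute_summaries(self) -> dict[str, float]:
        """Re-derive the fiber-list summaries (self-consistency check)."""
        return self.summaries_from_fibers(self.fibers)


def sample_fibers(
    preset: ClassPreset,
    field_um: tuple[float, float] = (
        DEFAULT_SHAPE[1] * DEFAULT_PIXEL_SIZE,
        DEFAULT_SHAPE[0] * DEFAULT_PIXEL_SIZE,
    ),
    seed: int | None = None,
) -> list[FiberSpec]:
    """Draw a Poisson number of fibers from the preset's distributions.

    ``field_um`` is (width, height) of the field in micrometres; anchors
    are uniform over the field.  Reproducible under a fixed seed.
    """
    w, h = field_um
    if w <= 0 or h <= 0:
        raise ValueError("field dimensions must be > 0")
    rng = np.random.default_rng(seed)
    count = rng.poisson(preset.fiber_rate)
    fibers = []
    for _ in range(count):
        anchor = (rng.uniform(0, w), rng.uniform(0, h))
        if preset.kappa > 0:
            theta = rng.vonmises(0.0, preset.kappa) / 2.0 % math.pi
        else:
            theta = rng.uniform(0.0, math.pi)
        length = float(rng.lognormal(math.log(preset.length_median_um), preset.length_sigma))
        width = float(rng.lognormal(math.log(preset.width_median_um), preset.width_sigma))
        if preset.mean_fragments > 1:
            frags = 1 + int(rng.poisson(preset.mean_fragments - 1))
        else:
            frags = 1
        stain = "mature" if rng.random() < preset.p_red else "immature"
        fibers.append(
            FiberSpec(
                anchor_um=anchor,
                orientation=theta,
                length_um=length,
                width_um=width,
                waviness=preset.waviness,
                stain=stain,
                fragments=frags,
            )
        )
    return fibers


def _fiber_polyline(fiber: FiberSpec, pixel_size: float) -> np.ndarray:
    """Sample the fiber's centreline in pixel coordinates (x, y) columns.

    The curve is one sinusoidal bend of amplitude ``waviness * length``,
    rescaled about its midpoint so its arclength equals the contour length.
    """
    n = max(9, int(fiber.length_um / pixel_size / 8.0) | 1)
    s = np.linspace(-0.5, 0.5, n)
    amp = fiber.waviness * fiber.length_um
    ux, uy = math.cos(fiber.orientation), math.sin(fiber.orientation)
    along = s * fiber.length_um
    perp = amp * np.sin(math.pi * (s + 0.5))
    x = along * ux - perp * uy
    y = along * uy + perp * ux
    pts = np.column_stack([x, y])
    arclen = np.sqrt(np.diff(pts, axis=0) ** 2 @ np.ones(2)).sum()
    if arclen > 0:
        pts *= fiber.length_um / arclen
    pts += np.asarray(fiber.anchor_um)
    return pts / pixel_size


def _fragment_slices(n_pts: int, fragments: int) -> list[slice]:
    if fragments <= 1:
        return [slice(0, n_pts)]
    edges = np.linspace(0, n_pts, fragments + 1)
    out = []
    for i in range(fragments):
        trim = (edges[i + 1] - edges[i]) * _GAP_FRACTION / 2.0
        lo = int(round(edges[i] + (trim if i > 0 else 0)))
        hi = int(round(edges[i + 1] - (trim if i < fragments - 1 else 0)))
        if hi - lo >= 2:
            out.append(slice(lo, hi))
    return out


def _stroke_alpha(plane: np.ndarray, pts: np.ndarray, width_px: float) -> None:
    """Accumulate an anti-aliased stroke of the polyline into ``plane``.

    Coverage ramps linearly over one pixel around the half-width, so a
    0.5 threshold on the OD plane reproduces the nominal stroke width.
    Overlaps combine by maximum (a mask-like, not additive, model).
    """
    h, w = plane.shape
    half = width_px / 2.0
    pad = half + 1.5
    x0 = max(int(np.floor(pts[:, 0].min() - pad)), 0)
    x1 = min(int(np.ceil(pts[:, 0].max() + pad)) + 1, w)
    y0 = max(int(np.floor(pts[:, 1].min() - pad)), 0)
    y1 = min(int(np.ceil(pts[:, 1].max() + pad)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    px = xx.astype(float)
    py = yy.astype(float)
    dist2 = np.full(px.shape, np.inf)
    # running minimum of squared point-to-segment distance over segments
    for (ax, ay), (dx, dy) in zip(pts[:-1], np.diff(pts, axis=0)):
        len2 = max(dx * dx + dy * dy, 1e-12)
        t = np.clip(((px - ax) * dx + (py - ay) * dy) / len2, 0.0, 1.0)
        ex = px - (ax + t * dx)
        ey = py - (ay + t * dy)
        np.minimum(dist2, ex * ex + ey * ey, out=dist2)
    dist = np.sqrt(dist2)
    alpha = np.clip(half + 0.5 - dist, 0.0, 1.0)
    region = plane[y0:y1, x0:x1]
    np.maximum(region, _PEAK_OD * alpha, out=region)


def render_image(
    fibers: list[FiberSpec],
    pixel_size_um: float = DEFAULT_PIXEL_SIZE,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    basis: StainBasis | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    preset_name: str | None = None,
) -> tuple[SyntheticImage, GroundTruth]:
    """Rasterize fibers into an RGB transmittance image plus ground truth.

    Each fiber is drawn into the OD plane of its stain class; the stain
    planes are mixed through the (normalized) stain basis and converted to
    transmittance as ``T = 10**(-OD)``.  Gaussian noise of standard
    deviation ``noise_sigma`` is added in OD space, then transmittance is
    clipped to [0, 1].  Fibers extending outside the field are clipped
    silently (logged at DEBUG).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be > 0")
    basis = DEFAULT_BASIS if basis is None else basis
    h, w = shape
    planes = {"mature": np.zeros((h, w)), "immature": np.zeros((h, w))}
    for fiber in fibers:
        pts = _fiber_polyline(fiber, pixel_size_um)
        if (pts < -0.5).any() or (pts[:, 0] > w - 0.5).any() or (pts[:, 1] > h - 0.5).any():
            logger.debug("fiber at %s extends outside the field; clipped", fiber.anchor_um)
        width_px = fiber.width_um / pixel_size_um
        for sl in _fragment_slices(len(pts), fiber.fragments):
            _stroke_alpha(planes[fiber.stain], pts[sl], width_px)

    coverage = (planes["mature"] >= 0.5 * _PEAK_OD) | (planes["immature"] >= 0.5 * _PEAK_OD)
    mature_cov = planes["mature"] >= 0.5 * _PEAK_OD
    porosity = 100.0 * (1.0 - coverage.mean())
    mature_frac = float(mature_cov.sum() / max(coverage.sum(), 1))

    norm = basis.normalized
    amounts = np.stack(
        [planes["mature"], planes["immature"], np.zeros((h, w))], axis=-1
    )
    od = amounts.reshape(-1, 3) @ norm
    od = od.reshape(h, w, 3)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sigma, size=od.shape)
    rgb = np.clip(10.0 ** (-od), 0.0, 1.0)

    summaries = GroundTruth.summaries_from_fibers(fibers)
    truth = GroundTruth(
        fibers=list(fibers),
        porosity_pct=float(porosity),
        mature_area_fraction=mature_frac,
        **summaries,
    )
    image = SyntheticImage(
        rgb=rgb, pixel_size_um=pixel_size_um, seed=seed, preset=preset_name
    )
    return image, truth


def simulate_image(
    preset: ClassPreset | str,
    seed: int,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE,
    basis: StainBasis | None = None,
) -> tuple[SyntheticImage, GroundTruth]:
    """Sample fibers from a preset and render them; one call, one image."""
    if isinstance(preset, str):
        preset = make_preset(preset)
    h, w = shape
    field_um = (w * pixel_size_um, h * pixel_size_um)
    fibers = sample_fibers(preset, field_um=field_um, seed=seed)
    return render_image(
        fibers,
        pixel_size_um=pixel_size_um,
        shape=shape,
        basis=basis,
        noise_sigma=preset.noise_sigma,
        seed=seed,
        preset_name=preset.name,
    )


_INTERP_FIELDS = (
    "fiber_rate", "length_median_um", "length_sigma", "width_median_um",
    "width_sigma", "kappa", "p_red", "mean_fragments", "waviness",
    "noise_sigma",
)


def interpolate_presets(a: ClassPreset, b: ClassPreset, t: float) -> ClassPreset:
    """Linear interpolation of every numeric preset field."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("interpolation coordinate t must lie in [0, 1]")
    vals = {
        name: (1.0 - t) * getattr(a, name) + t * getattr(b, name)
        for name in _INTERP_FIELDS
    }
    return ClassPreset(name=f"gradient_t={t:g}", **vals)


def gradient_series(
    t: float,
    n_per_step: int,
    seed: int,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE,
) -> list[tuple[SyntheticImage, GroundTruth]]:
    """Images from the control->deposition gradient at coordinate ``t``.

    ``t=0`` reproduces the control preset, ``t=1`` the deposition preset;
    in between every numeric parameter is linearly interpolated, giving a
    morphological continuum from homeostatic to fibrotic matrix.
    """
    preset = interpolate_presets(make_preset("control"), make_preset("deposition"), t)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_per_step)
    return [
        simulate_image(preset, int(s) % (2**31), shape=shape, pixel_size_um=pixel_size_um)
        for s in child_seeds
    ]
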