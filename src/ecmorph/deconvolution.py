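"""Colour deconvolution of picrosirius-red birefringence images.

Under polarized light, picrosirius-red-stained collagen shifts from green to
red with fiber packing and maturity, so the red signal proxies mature
(COL1-like) and the green signal immature (COL3-like) collagen.  Stain
amounts are linear in optical density (Beer-Lambert), so per-pixel unmixing
is a linear solve against a basis of stain absorbance vectors:

    OD(pixel) = amounts(pixel) @ B        =>   amounts = OD @ B^{-1}

where the rows of ``B`` are the unit-normalized stain absorbance vectors in
RGB space.  The default basis assigns pure red to the mature channel, pure
green to the immature channel, and a grey residual::

    mature   = [1, 0, 0]
    immature = [0, 1, 0]
    residual = [1, 1, 1]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainBasis",
    "ChannelImages",
    "DEFAULT_BASIS",
    "rgb_to_absorbance",
    "deconvolve",
]

STAIN_LABELS = ("mature", "immature", "residual")

#: Largest acceptable condition number before a basis is declared degenerate.
_MAX_CONDITION = 1e8

#: Transmittance floor, as a fraction of the white point (16-bit quantum).
_T_FLOOR = 1.0 / 65536.0


@dataclass(frozen=True)
class StainBasis:
    """Absorbance vectors of the three stains, one row per stain.

    Rows are stored as given and unit-normalized (Euclidean) just before
    inversion; an all-zero row or a (near-)singular normalized matrix is
    rejected.
    """

    rows: np.ndarray
    labels: tuple[str, str, str] = STAIN_LABELS

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.shape != (3, 3):
            raise ValueError(f"stain basis must be 3x3, got {rows.shape}")
        if not np.all(np.isfinite(rows)):
            raise ValueError("stain basis contains non-finite entries")
        norms = np.linalg.norm(rows, axis=1)
        if np.any(norms == 0):
            raise ValueError("stain basis has an all-zero row")
        object.__setattr__(self, "rows", rows)

    @property
    def normalized(self) -> np.ndarray:
        """Rows scaled to unit Euclidean length."""
        rows = self.rows
        return rows / np.linalg.norm(rows, axis=1, keepdims=True)

    @property
    def inverse(self) -> np.ndarray:
        """Inverse of the normalized basis; raises on degeneracy."""
        m = self.normalized
        if np.linalg.cond(m) > _MAX_CONDITION:
            raise ValueError("degenerate stain basis: normalized matrix is singular")
        return np.linalg.inv(m)


#: Red / green / grey basis used throughout unless overridden.
DEFAULT_BASIS = StainBasis(
    rows=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.0, 1.0, 1.0]])
)


@dataclass
class ChannelImages:
    """Per-stain optical-density images produced by :func:`deconvolve`."""

    mature: np.ndarray
    immature: np.ndarray
    residual: np.ndarray
    basis: StainBasis = field(default_factory=lambda: DEFAULT_BASIS)
    i0: np.ndarray | None = None
    #: total negative stain amount clipped to zero, in OD units
    clipped_mass: float = 0.0

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return getattr(self, label)
        except AttributeError:
            raise KeyError(label) from None


def rgb_to_absorbance(image: np.ndarray, i0: np.ndarray | float | None = None) -> np.ndarray:
    """Convert an RGB transmittance raster to optical density.

    OD = -log10(I / I0) per channel.  ``i0`` is the incident (white-point)
    intensity per channel; when omitted it is estimated as the per-channel
    99th percentile, a robust white-point for both synthetic and real
    images.  Intensities are floored at ``I0 / 65536`` so fully opaque
    pixels stay finite, and OD is clipped at zero (pixels brighter than the
    white point carry no stain).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB raster, got shape {image.shape}")
    bad = int(np.size(image) - np.isfinite(image).sum())
    if bad:
        raise ValueError(f"image contains {bad} non-finite pixel values")
    if i0 is None:
        i0 = np.percentile(image.reshape(-1, 3), 99, axis=0)
    i0 = np.broadcast_to(np.asarray(i0, dtype=float), (3,)).copy()
    if np.any(i0 <= 0):
        raise ValueError("background intensity I0 must be positive in every channel")
    floored = np.maximum(image, i0 * _T_FLOOR)
    od = -np.log10(floored / i0)
    return np.maximum(od, 0.0)


def deconvolve(od: np.ndarray, basis: StainBasis | None = None) -> ChannelImages:
    """Unmix an OD raster into per-stain amount images.

    Per pixel, stain amounts solve ``amounts @ B = od`` for the normalized
    basis ``B``.  Negative amounts (noise, basis mismatch) are clipped to
    zero; the total clipped mass is recorded on the result.
    """
    basis = DEFAULT_BASIS if basis is None else basis
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 OD raster, got shape {od.shape}")
    amounts = od.reshape(-1, 3) @ basis.inverse
    clipped = float(-amounts[amounts < 0].sum())
    amounts = np.maximum(amounts, 0.0).reshape(od.shape)
    return ChannelImages(
        mature=amounts[..., 0],
        immature=amounts[..., 1],
        residual=amounts[..., 2],
        basis=basis,
        clipped_mass=clipped,
    )
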