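"""Retinal layer thickness summaries over an annulus.

Consumes already-segmented boundary surfaces or per-layer thickness rasters
(the scanner's segmentation itself is upstream of this package) and reduces
them to per-eye layer means over an ETDRS-style annulus centred on the optic
nerve head. Total retinal thickness (TRT, ILM→OLM) is derived as the sum of
the five layer means, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidParameterError, SegmentationIntegrityError

#: Inner-to-outer retinal layers summarized by the pipeline.
LAYERS = ("RNFL", "GCIPL", "INL", "OPL", "ONL")


@dataclass(frozen=True)
class AnnulusSpec:
    """Annulus on the en-face raster. ETDRS outer ring: 3–6 mm diameters."""

    center: tuple[float, float] = (0.0, 0.0)  # mm, (x, y) of the ONH
    inner_diameter: float = 3.0               # mm
    outer_diameter: float = 6.0               # mm

    def __post_init__(self) -> None:
        if not 0 <= self.inner_diameter < self.outer_diameter:
            raise InvalidParameterError(
                f"need 0 <= inner < outer, got {self.inner_diameter}, "
                f"{self.outer_diameter}")


@dataclass(frozen=True)
class ThicknessGrid:
    """Per-layer thickness (µm) on one shared regular raster (mm)."""

    x: np.ndarray                      # (nx,) mm
    y: np.ndarray                      # (ny,) mm
    layers: Mapping[str, np.ndarray]   # name -> (ny, nx) µm

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        layers = {k: np.asarray(v, dtype=float) for k, v in self.layers.items()}
        object.__setattr__(self, "layers", layers)
        for name, grid in layers.items():
            if grid.shape != (y.size, x.size):
                raise InvalidParameterError(
                    f"layer {name}: shape {grid.shape} != ({y.size}, {x.size})")
            if np.nanmin(grid) < 0:
                raise InvalidParameterError(f"layer {name}: negative thickness")


@dataclass(frozen=True)
class LayerSummary:
    """Annulus means per layer plus the derived total retinal thickness."""

    means: Mapping[str, float]     # µm
    trt: float                     # µm, sum of the five layer means
    n_pixels_used: Mapping[str, int]
    annulus: AnnulusSpec


def thickness_from_boundaries(x: Sequence[float], y: Sequence[float],
                              surfaces: Sequence[np.ndarray],
                              layer_names: Sequence[str] = LAYERS,
                              tol_um: float = 1e-9) -> ThicknessGrid:
    """Turn ordered boundary surfaces (µm depth, inner to outer) into layer
    thicknesses by adjacent differences.

    ``surfaces`` must contain ``len(layer_names) + 1`` rasters. Any pixel
    where an outer surface lies above an inner one (beyond ``tol_um``) raises
    :class:`SegmentationIntegrityError` reporting the offending pixel count.
    """
    if len(surfaces) != len(layer_names) + 1:
        raise InvalidParameterError(
            f"{len(layer_names)} layers need {len(layer_names) + 1} surfaces, "
            f"got {len(surfaces)}")
    surfaces = [np.asarray(s, dtype=float) for s in surfaces]
    layers = {}
    for name, inner, outer in zip(layer_names, surfaces[:-1], surfaces[1:]):
        thickness = outer - inner
        bad = np.sum(thickness < -tol_um)
        if bad:
            raise SegmentationIntegrityError(
                f"surfaces cross at {int(bad)} pixel(s) around layer {name}")
        layers[name] = np.clip(thickness, 0.0, None)
    return ThicknessGrid(np.asarray(x, float), np.asarray(y, float), layers)


def _annulus_mask(grid: ThicknessGrid, annulus: AnnulusSpec) -> np.ndarray:
    xx, yy = np.meshgrid(grid.x, grid.y)
    r = np.hypot(xx - annulus.center[0], yy - annulus.center[1])
    # pixel-center rule on the half-open radial interval [inner/2, outer/2)
    return (r >= annulus.inner_diameter / 2.0) & (r < annulus.outer_diameter / 2.0)


def annulus_mean(grid: ThicknessGrid, annulus: AnnulusSpec,
                 layer: str) -> tuple[float, int]:
    """Mean thickness (µm) of one layer over the annulus.

    Pixels are included if their centre lies in ``[inner/2, outer/2)`` from
    the annulus centre; NaN pixels are excluded from the mean but reported
    via the pixel count. Returns ``(mean, n_pixels_used)``.
    """
    if layer not in grid.layers:
        raise ConfigurationError(f"layer {layer!r} missing from grid")
    mask = _annulus_mask(grid, annulus)
    values = grid.layers[layer][mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ConfigurationError("annulus does not intersect any valid pixel")
    return float(values.mean()), int(values.size)


def summarize_layers(grid: ThicknessGrid,
                     annulus: AnnulusSpec = AnnulusSpec()) -> LayerSummary:
    """Annulus mean for each of the five layers plus the derived TRT."""
    missing = [l for l in LAYERS if l not in grid.layers]
    if missing:
        raise ConfigurationError(f"grid is missing layer(s): {', '.join(missing)}")
    means, counts = {}, {}
    for layer in LAYERS:
        means[layer], counts[layer] = annulus_mean(grid, annulus, layer)
    return LayerSummary(means=means, trt=float(sum(means.values())),
                        n_pixels_used=counts, annulus=annulus)


def radial_grid(profile, n: int = 256, extent_mm: float = 4.05,
                layers: Sequence[str] = LAYERS) -> ThicknessGrid:
    """Build a grid whose layer thicknesses are radial functions ``T(r)``.

    ``profile`` maps a layer name and a radius array (mm) to thickness (µm):
    ``profile(layer, r) -> array``. Useful for analytic checks and as the
    simulator's en-face scaffold.
    """
    x = np.linspace(-extent_mm, extent_mm, n)
    y = np.linspace(-extent_mm, extent_mm, n)
    xx, yy = np.meshgrid(x, y)
    r = np.hypot(xx, yy)
    return ThicknessGrid(x, y, {name: profile(name, r) for name in layers})
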