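"""Radiance-to-reflectance conversion and plot spectrum assembly.

Sunlit-leaf radiance is ratioed against the in-scene white reference
panel band by band,

    R = (S_sunlit / S_ref) * R_ref,

where S_ref is the panel's observed radiance and R_ref the panel's
lab-calibrated reflectance.  The ratio cancels the (unknown) incident
irradiance, which is why multiplying the whole cube by any constant
leaves R unchanged.  Per-pixel reflectance is averaged to one mean
(+/- SD) spectrum per plot, the two cameras' spectra are joined at
their 900 nm crossover, the joined spectrum is Savitzky-Golay
smoothed (window 11, order 2), and noisy/water-absorption bands are
masked: keep 450-1700 nm, drop 1313-1440 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .envi import HyperCube, Unit
from .segment import (
    PixelClassMap,
    assign_semantics,
    extract_class_spectra,
    kmeans_segment,
    transfer_semantics,
)

__all__ = [
    "Spectrum",
    "PlotSpectrum",
    "to_reflectance",
    "savgol_smooth",
    "mask_bands",
    "join_cameras",
    "aggregate_plot",
    "plot_reflectance_pipeline",
    "KEEP_RANGE_NM",
    "DROP_RANGES_NM",
]

# Band-masking defaults: bands below 450 nm and above 1700 nm carry
# excess sensor noise; 1313-1440 nm sits in the atmospheric water
# absorption feature.  All interval bounds are inclusive.
KEEP_RANGE_NM = (450.0, 1700.0)
DROP_RANGES_NM = ((1313.0, 1440.0),)


@dataclass
class Spectrum:
    """One spectrum on a strictly increasing wavelength grid."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    unit: Unit = Unit.REFLECTANCE

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths_nm.shape != self.values.shape:
            raise ValueError("wavelengths and values must have equal length")
        if self.wavelengths_nm.size and not np.all(
            np.diff(self.wavelengths_nm) > 0
        ):
            raise ValueError("wavelengths must be strictly increasing")
        self.unit = Unit(self.unit)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PlotSpectrum:
    """Mean +/- SD sunlit-leaf reflectance for one plot."""

    mean: Spectrum
    sd: np.ndarray
    n_pixels: int
    plot_id: str = ""
    band_mask: np.ndarray | None = None  # True = retained, on the pre-mask grid

    def __post_init__(self) -> None:
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.sd < 0):
            raise ValueError("per-band SD must be non-negative")
        if self.n_pixels < 1:
            raise ValueError("a plot spectrum needs at least one pixel")


def to_reflectance(
    sunlit: np.ndarray,
    panel: Spectrum,
    panel_reference: np.ndarray | float = 0.99,
) -> np.ndarray:
    """Per-pixel reflectance from sunlit radiance and panel radiance.

    ``sunlit`` is (n_pixels, bands) radiance on the panel's grid;
    ``panel_reference`` is the panel's lab-calibrated reflectance
    (scalar or per band).  Returns (n_pixels, bands) reflectance.
    """
    sunlit = np.atleast_2d(np.asarray(sunlit, dtype=float))
    s_ref = panel.values
    if sunlit.shape[1] != s_ref.size:
        raise ValueError("sunlit spectra and panel must share the band grid")
    bad = np.flatnonzero(s_ref <= 0)
    if bad.size:
        raise ZeroDivisionError(
            "panel radiance non-positive at band(s) "
            f"{panel.wavelengths_nm[bad][:5]} nm"
        )
    r_ref = np.broadcast_to(np.asarray(panel_reference, dtype=float), s_ref.shape)
    return sunlit / s_ref * r_ref


def savgol_smooth(s: Spectrum, window: int = 11, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay smoothing; edges handled by a polynomial fit on
    the truncated window (no padding artifacts)."""
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if len(s) < window:
        raise ValueError(f"spectrum has {len(s)} bands, window is {window}")
    smoothed = savgol_filter(s.values, window, polyorder, mode="interp")
    return replace(s, values=smoothed)


def _band_retained(
    wl: np.ndarray,
    keep: tuple[float, float] = KEEP_RANGE_NM,
    drop: tuple[tuple[float, float], ...] = DROP_RANGES_NM,
) -> np.ndarray:
    mask = (wl >= keep[0]) & (wl <= keep[1])
    for lo, hi in drop:
        mask &= ~((wl >= lo) & (wl <= hi))
    return mask


def mask_bands(
    s: Spectrum,
    keep: tuple[float, float] = KEEP_RANGE_NM,
    drop: tuple[tuple[float, float], ...] = DROP_RANGES_NM,
) -> Spectrum:
    """Retain bands inside ``keep`` and outside every ``drop`` interval
    (all bounds inclusive)."""
    mask = _band_retained(s.wavelengths_nm, keep, drop)
    if not mask.any():
        raise ValueError("band mask removed every band")
    return Spectrum(
        wavelengths_nm=s.wavelengths_nm[mask], values=s.values[mask], unit=s.unit
    )


def join_cameras(
    vnir: Spectrum, nir: Spectrum, crossover_nm: float = 900.0
) -> Spectrum:
    """Concatenate the two cameras' spectra at the crossover wavelength:
    VNIR bands strictly below it, NIR bands at/above it."""
    if vnir.unit is not nir.unit:
        raise ValueError("cannot join spectra with different units")
    keep_v = vnir.wavelengths_nm < crossover_nm
    keep_n = nir.wavelengths_nm >= crossover_nm
    wl = np.concatenate([vnir.wavelengths_nm[keep_v], nir.wavelengths_nm[keep_n]])
    vals = np.concatenate([vnir.values[keep_v], nir.values[keep_n]])
    order = np.argsort(wl)
    wl, vals = wl[order], vals[order]
    if np.any(np.diff(wl) <= 0):
        raise ValueError("duplicate wavelengths remain after crossover resolution")
    return Spectrum(wavelengths_nm=wl, values=vals, unit=vnir.unit)


def aggregate_plot(
    pixels: np.ndarray, wavelengths_nm: np.ndarray, plot_id: str = ""
) -> PlotSpectrum:
    """Per-band arithmetic mean and population SD over sunlit pixels."""
    pixels = np.atleast_2d(np.asarray(pixels, dtype=float))
    if pixels.shape[0] == 0:
        raise ValueError(f"no sunlit pixels for plot {plot_id!r}")
    mean = pixels.mean(axis=0)
    sd = pixels.std(axis=0)  # population SD
    return PlotSpectrum(
        mean=Spectrum(wavelengths_nm=wavelengths_nm, values=mean),
        sd=sd,
        n_pixels=pixels.shape[0],
        plot_id=plot_id,
    )


def plot_reflectance_pipeline(
    cubes: dict[str, HyperCube],
    panel_reference: float | np.ndarray = 0.99,
    plot_id: str = "",
    k: int = 6,
    seed: int = 0,
    smooth: bool = True,
    mask: bool = True,
    vnir_camera: str = "vnir",
) -> tuple[PlotSpectrum, dict[str, PixelClassMap]]:
    """Full plot pipeline on one or two radiance cubes:

    segment -> label -> panel-ratio reflectance -> per-camera plot
    mean -> join cameras -> smooth -> mask.

    Cluster semantics come from brightness + NDVI on the camera that
    covers the red edge; other (co-registered) cameras inherit labels
    by spatial majority vote.  Smoothing is applied to the plot-mean
    spectrum, not per pixel (identical mean, far cheaper); both the
    smoothing and masking stages can be switched off to inspect
    intermediate products.
    """
    if vnir_camera not in cubes and len(cubes) == 1:
        vnir_camera = next(iter(cubes))
    maps: dict[str, PixelClassMap] = {}
    ref_map = None
    for cam in sorted(cubes, key=lambda c: (c != vnir_camera, c)):
        cmap = kmeans_segment(cubes[cam], k=k, seed=seed)
        if cam == vnir_camera or ref_map is None:
            cmap = assign_semantics(cmap, cubes[cam])
            ref_map = cmap
        else:
            cmap = transfer_semantics(cmap, ref_map)
        maps[cam] = cmap

    per_camera: dict[str, PlotSpectrum] = {}
    for cam, cube in cubes.items():
        sunlit = extract_class_spectra(cube, maps[cam], "sunlit_leaf")
        panel_pixels = extract_class_spectra(cube, maps[cam], "panel")
        if panel_pixels.shape[0] == 0:
            raise ValueError(f"no panel pixels found in camera {cam!r}")
        panel = Spectrum(
            wavelengths_nm=cube.wavelengths_nm,
            values=panel_pixels.mean(axis=0),
            unit=Unit.RADIANCE,
        )
        refl = to_reflectance(sunlit, panel, panel_reference)
        per_camera[cam] = aggregate_plot(refl, cube.wavelengths_nm, plot_id)

    if len(per_camera) == 2:
        cams = sorted(
            per_camera, key=lambda c: per_camera[c].mean.wavelengths_nm[0]
        )
        lo, hi = per_camera[cams[0]], per_camera[cams[1]]
        joined = join_cameras(lo.mean, hi.mean)
        sd = join_cameras(
            Spectrum(lo.mean.wavelengths_nm, lo.sd),
            Spectrum(hi.mean.wavelengths_nm, hi.sd),
        ).values
        n_pixels = min(lo.n_pixels, hi.n_pixels)
    else:
        only = next(iter(per_camera.values()))
        joined, sd, n_pixels = only.mean, only.sd, only.n_pixels

    if smooth:
        joined = savgol_smooth(joined)
    if mask:
        keep = KEEP_RANGE_NM
        if len(per_camera) == 1:  # single-camera (VNIR-only) runs
            keep = (KEEP_RANGE_NM[0], min(KEEP_RANGE_NM[1], 900.0))
        retained = _band_retained(joined.wavelengths_nm, keep, DROP_RANGES_NM)
        sd = sd[retained]
        joined = Spectrum(
            joined.wavelengths_nm[retained], joined.values[retained], joined.unit
        )
    return (
        PlotSpectrum(
            mean=joined, sd=sd, n_pixels=n_pixels, plot_id=plot_id
        ),
        maps,
    )
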