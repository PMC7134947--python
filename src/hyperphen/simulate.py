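"""Synthetic scenes, spectra, trait datasets and gas-exchange curves.

Every downstream stage of the pipeline is testable without field data
because the generators here emit their own ground truth:

* ``simulate_scene`` builds plot hypercubes for the two push-broom
  cameras (VNIR 400-900 nm at 2.1 nm, NIR 900-1800 nm at 4.9 nm)
  containing the six material classes the segmentation stage must
  separate — sunlit leaves, shaded leaves, soil, a near-unity white
  reference panel, platform shadow, and non-biological matter.
* ``simulate_trait_dataset`` draws collinear, smoothly varying plot
  reflectance spectra and couples a trait to them through a sparse
  band-localized linear model — the regime PLSR exists for.
* ``simulate_gas_exchange`` runs the forward photosynthesis models on
  the instrument step grids and adds observation noise.

Sunlit and shaded pixels share one leaf reflectance endmember and
differ only by an illumination scalar, which is exactly the contrast
that lets K-means separate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import gasex
from .envi import HyperCube, Interleave, Unit

__all__ = [
    "CLASS_NAMES",
    "vnir_grid",
    "nir_grid",
    "default_leaf_reflectance",
    "default_soil_reflectance",
    "default_nonbio_reflectance",
    "SceneConfig",
    "SceneTruth",
    "TraitCoupling",
    "simulate_scene",
    "simulate_trait_dataset",
    "simulate_gas_exchange",
]

# canonical class order; class_map labels index into this list
CLASS_NAMES = (
    "sunlit_leaf",
    "shaded_leaf",
    "soil",
    "panel",
    "platform_shadow",
    "non_biological",
)

# classes lit by direct sun vs in shadow
_SUNLIT_CLASSES = {"sunlit_leaf", "soil", "panel", "non_biological"}


def vnir_grid() -> np.ndarray:
    """VNIR camera wavelengths: 400-900 nm in 2.1 nm contiguous bands."""
    n = int(np.floor((900.0 - 400.0) / 2.1)) + 1
    return 400.0 + 2.1 * np.arange(n)


def nir_grid() -> np.ndarray:
    """NIR camera wavelengths: 900-1800 nm in 4.9 nm contiguous bands."""
    n = int(np.floor((1800.0 - 900.0) / 4.9)) + 1
    return 900.0 + 4.9 * np.arange(n)


# ---------------------------------------------------------------------------
# Endmember reflectance models (smooth analytic stand-ins for field
# materials; all return fractions in [0, 1])


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def default_leaf_reflectance(wl: np.ndarray) -> np.ndarray:
    """Green-vegetation reflectance: chlorophyll absorption troughs in
    the visible, a green bump at 550 nm, red-edge rise to a NIR
    plateau, and water-absorption dips near 1450 nm."""
    wl = np.asarray(wl, dtype=float)
    visible = 0.04 + 0.08 * _gauss(wl, 550.0, 35.0)
    red_edge = 0.41 / (1.0 + np.exp(-(wl - 718.0) / 14.0))
    water = 1.0 - 0.55 * _gauss(wl, 1450.0, 45.0) - 0.25 * _gauss(wl, 1780.0, 90.0)
    nir_decline = 1.0 - 0.12 / (1.0 + np.exp(-(wl - 1300.0) / 60.0))
    r = (visible + red_edge) * water * nir_decline
    return np.clip(r, 0.0, 1.0)


def default_soil_reflectance(wl: np.ndarray) -> np.ndarray:
    """Bare-soil reflectance: featureless ramp rising with wavelength."""
    wl = np.asarray(wl, dtype=float)
    return np.clip(0.12 + 0.10 * (wl - 400.0) / 1400.0, 0.0, 1.0)


def default_nonbio_reflectance(wl: np.ndarray) -> np.ndarray:
    """Bright grey man-made matter (platform parts, stakes): flat."""
    return np.full_like(np.asarray(wl, dtype=float), 0.45)


def default_panel_reflectance(wl: np.ndarray) -> np.ndarray:
    """Lab-calibrated white Teflon reference panel: ~99 % reflective."""
    return np.full_like(np.asarray(wl, dtype=float), 0.99)


# ---------------------------------------------------------------------------


def _default_fractions() -> dict[str, float]:
    return {
        "sunlit_leaf": 0.40,
        "shaded_leaf": 0.20,
        "soil": 0.20,
        "panel": 0.10,
        "platform_shadow": 0.05,
        "non_biological": 0.05,
    }


def _default_cameras() -> dict[str, np.ndarray]:
    return {"vnir": vnir_grid(), "nir": nir_grid()}


@dataclass
class SceneConfig:
    """Study conditions for one simulated plot scene.

    Reflectance endmembers are wavelength functions so that a single
    config serves both camera grids; illumination scalars are
    relative (sunlit = 1 by convention), and noise_sd is the relative
    (multiplicative) radiance noise per pixel per band.
    """

    lines: int = 100
    samples: int = 100
    class_fractions: dict[str, float] = field(default_factory=_default_fractions)
    leaf_reflectance: callable = default_leaf_reflectance
    soil_reflectance: callable = default_soil_reflectance
    non_bio_reflectance: callable = default_nonbio_reflectance
    panel_reflectance: callable = default_panel_reflectance
    sunlit_illumination: float = 1.0
    shaded_illumination: float = 0.3
    noise_sd: float = 0.0
    seed: int = 0
    cameras: dict[str, np.ndarray] = field(default_factory=_default_cameras)

    def __post_init__(self) -> None:
        unknown = set(self.class_fractions) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown scene classes: {sorted(unknown)}")
        fr = np.array(list(self.class_fractions.values()))
        if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("class fractions must be non-negative and sum to 1")
        if not (0 < self.shaded_illumination < self.sunlit_illumination):
            raise ValueError("need 0 < shaded_illumination < sunlit_illumination")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for cam, wl in self.cameras.items():
            panel = self.panel_reflectance(wl)
            for f in (
                self.leaf_reflectance,
                self.soil_reflectance,
                self.non_bio_reflectance,
            ):
                if np.any(f(wl) > panel + 1e-12):
                    raise ValueError(
                        f"panel must be the brightest endmember per band ({cam})"
                    )

    def class_reflectance(self, name: str, wl: np.ndarray) -> np.ndarray:
        if name in ("sunlit_leaf", "shaded_leaf"):
            return self.leaf_reflectance(wl)
        if name in ("soil", "platform_shadow"):  # shadow falls on soil
            return self.soil_reflectance(wl)
        if name == "panel":
            return self.panel_reflectance(wl)
        return self.non_bio_reflectance(wl)

    def class_illumination(self, name: str) -> float:
        return (
            self.sunlit_illumination
            if name in _SUNLIT_CLASSES
            else self.shaded_illumination
        )

    def class_radiance(self, name: str, wl: np.ndarray) -> np.ndarray:
        return self.class_illumination(name) * self.class_reflectance(name, wl)

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        """Load scene conditions from a YAML/JSON mapping; reflectance
        endmembers stay at their defaults (they are functions, not
        serializable scalars)."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {
            "lines", "samples", "class_fractions", "sunlit_illumination",
            "shaded_illumination", "noise_sd", "seed",
        }
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown scene config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class SceneTruth:
    """Ground truth emitted with every simulated scene."""

    class_map: np.ndarray  # (lines, samples) int labels into class_names
    class_names: tuple[str, ...]
    endmembers: dict[str, dict[str, np.ndarray]]  # camera -> class -> radiance
    trait_values: dict[str, float] = field(default_factory=dict)

    def class_count(self, name: str) -> int:
        idx = self.class_names.index(name)
        return int(np.sum(self.class_map == idx))


def _largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer class counts summing to ``total``, each within one pixel
    of fraction*total (largest-remainder apportionment)."""
    exact = fractions * total
    counts = np.floor(exact).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:short]] += 1
    return counts


def simulate_scene(config: SceneConfig) -> tuple[dict[str, HyperCube], SceneTruth]:
    """Render one plot scene for every configured camera.

    Each pixel's radiance is illumination(class) x endmember
    reflectance(class) x (1 + eps), eps ~ Normal(0, noise_sd); panel
    pixels are always sunlit.  The class map is drawn to match the
    configured fractions within one pixel of rounding and is shared by
    the cameras (co-registered fields of view).  Deterministic under
    the configured seed.
    """
    rng = np.random.default_rng(config.seed)
    names = [c for c in CLASS_NAMES if config.class_fractions.get(c, 0.0) > 0]
    fractions = np.array([config.class_fractions[c] for c in names])
    n_pix = config.lines * config.samples
    counts = _largest_remainder_counts(fractions, n_pix)
    flat = np.repeat([CLASS_NAMES.index(c) for c in names], counts)
    rng.shuffle(flat)
    class_map = flat.reshape(config.lines, config.samples)

    cubes: dict[str, HyperCube] = {}
    endmembers: dict[str, dict[str, np.ndarray]] = {}
    for cam, wl in config.cameras.items():
        em = {c: config.class_radiance(c, wl) for c in names}
        endmembers[cam] = em
        lut = np.zeros((len(CLASS_NAMES), wl.size))
        for c in names:
            lut[CLASS_NAMES.index(c)] = em[c]
        data = lut[class_map]  # (lines, samples, bands)
        if config.noise_sd > 0:
            eps = rng.normal(0.0, config.noise_sd, size=data.shape)
            data = data * (1.0 + eps)
            np.clip(data, 0.0, None, out=data)
        cubes[cam] = HyperCube(
            data=data,
            wavelengths_nm=wl,
            unit=Unit.RADIANCE,
            camera_id=cam,
            interleave=Interleave.BIL,
        )
    truth = SceneTruth(
        class_map=class_map, class_names=CLASS_NAMES, endmembers=endmembers
    )
    return cubes, truth


# ---------------------------------------------------------------------------
# Trait-coupled spectral datasets


@dataclass
class TraitCoupling:
    """Sparse linear trait-spectrum coupling: y = intercept + X beta + noise."""

    beta: np.ndarray
    intercept: float = 0.0
    noise_sd_y: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.noise_sd_y < 0:
            raise ValueError("noise_sd_y must be non-negative")

    @property
    def support_bands(self) -> np.ndarray:
        return np.flatnonzero(self.beta)

    @classmethod
    def band_localized(
        cls,
        n_bands: int,
        support: list[int] | np.ndarray,
        weights: list[float] | np.ndarray,
        intercept: float = 0.0,
        noise_sd_y: float = 0.0,
    ) -> "TraitCoupling":
        beta = np.zeros(n_bands)
        beta[np.asarray(support, dtype=int)] = weights
        return cls(beta=beta, intercept=intercept, noise_sd_y=noise_sd_y)


def _smooth_spectra(
    wl: np.ndarray, n_plots: int, rng: np.random.Generator, n_bumps: int = 40,
    bump_sd: float = 0.06, scale_sd: float = 0.05,
) -> np.ndarray:
    """Collinear plot spectra: the mean vegetation spectrum perturbed by
    smooth Gaussian bumps (correlation length of a few bands) and a
    global amplitude factor.  Neighbouring bands stay strongly
    collinear, as real reflectance is, while bands a bump-width apart
    vary enough to be separately identifiable."""
    base = default_leaf_reflectance(wl)
    centers = np.linspace(wl[0], wl[-1], n_bumps)
    width = (wl[-1] - wl[0]) / (n_bumps - 1)
    basis = np.stack([_gauss(wl, c, width) for c in centers])  # (n_bumps, p)
    amps = rng.normal(0.0, bump_sd, size=(n_plots, n_bumps))
    scale = 1.0 + rng.normal(0.0, scale_sd, size=(n_plots, 1))
    spectra = base * scale * (1.0 + amps @ basis)
    return np.clip(spectra, 0.0, 1.0)


def simulate_trait_dataset(
    n_plots: int,
    coupling: TraitCoupling,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
    target_r2: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, TraitCoupling]:
    """Draw (spectra, trait) pairs with known coupling.

    Returns (X, y, wavelengths, coupling) where coupling carries the
    realized noise level.  When ``target_r2`` is given the trait noise
    SD is set so the true linear signal explains that fraction of
    variance in this draw: noise_sd_y = sd(X beta) * sqrt((1-R2)/R2).
    """
    if n_plots < 4:
        raise ValueError("need at least 4 plots to cross-validate")
    if wavelengths is None:
        wavelengths = vnir_grid()
    wavelengths = np.asarray(wavelengths, dtype=float)
    if coupling.beta.size != wavelengths.size:
        raise ValueError("coupling beta length must match the wavelength grid")
    rng = np.random.default_rng(seed)
    X = _smooth_spectra(wavelengths, n_plots, rng)
    signal = X @ coupling.beta
    noise_sd = coupling.noise_sd_y
    if target_r2 is not None:
        if not (0 < target_r2 <= 1):
            raise ValueError("target_r2 must lie in (0, 1]")
        sig_sd = float(np.std(signal))
        noise_sd = sig_sd * np.sqrt((1.0 - target_r2) / target_r2)
    y = coupling.intercept + signal
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_plots)
    realized = TraitCoupling(
        beta=coupling.beta.copy(),
        intercept=coupling.intercept,
        noise_sd_y=noise_sd,
    )
    return X, y, wavelengths, realized


# ---------------------------------------------------------------------------
# Gas-exchange curves


def simulate_gas_exchange(
    kind: gasex.CurveKind | str,
    params: gasex.FvCBParams | gasex.NRHParams,
    steps: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    constants: gasex.FvCBConstants | None = None,
) -> gasex.GasExchangeCurve:
    """Forward-simulate one response curve on the instrument step grid
    (the printed CO2 or light sequences by default) plus Normal(0,
    noise_sd) observation noise on A."""
    kind = gasex.CurveKind(kind)
    rng = np.random.default_rng(seed)
    if kind is gasex.CurveKind.ACI:
        if not isinstance(params, gasex.FvCBParams):
            raise ValueError("A/Ci simulation requires FvCBParams")
        steps = gasex.ACI_CO2_STEPS if steps is None else np.asarray(steps, float)
        A, _ = gasex.fvcb_forward(params, steps, constants=constants)
        if noise_sd > 0:
            A = A + rng.normal(0.0, noise_sd, size=A.shape)
        return gasex.GasExchangeCurve(
            kind=kind,
            A=A,
            driver=steps,
            leaf_T=params.leaf_T,
            metadata={"RH_pct": 65, "PAR": 1800},
        )
    if not isinstance(params, gasex.NRHParams):
        raise ValueError("A/Q simulation requires NRHParams")
    steps = gasex.AQ_LIGHT_STEPS if steps is None else np.asarray(steps, float)
    ia = gasex.correct_absorbed_irradiance(steps, params.absorptance)
    A = gasex.nrh_forward(ia, params.phi, params.theta, params.pmax, params.rd)
    if noise_sd > 0:
        A = A + rng.normal(0.0, noise_sd, size=A.shape)
    return gasex.GasExchangeCurve(
        kind=kind,
        A=A,
        driver=steps,
        leaf_T=25.0,
        Ia=ia,
        metadata={"RH_pct": 65, "CO2": 400, "absorptance": params.absorptance},
    )
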