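"""Leaf gas-exchange curve fitting: the physiological ground truth.

Two response-curve fitters produce the trait values that spectral
models are trained against:

* A/Ci curves (net assimilation vs intercellular CO2 at saturating
  light) fitted with the Farquhar–von Caemmerer–Berry (FvCB) model of
  C3 photosynthesis to retrieve Vc,max and J1800.  Mesophyll
  conductance gm is not fitted but constrained by its linear
  temperature response gm = -0.44 + 0.058*T.
* A/Q light-response curves fitted with the non-rectangular hyperbola
  to retrieve Pmax, phi, theta and Rd; the apparent quantum yield
  phiCO2 is estimated separately as the OLS slope of A on absorbed
  irradiance below 150 umol m-2 s-1.

J1800 denotes electron transport at the measurement irradiance of
1800 umol m-2 s-1 — deliberately not called Jmax, since light
saturation at higher irradiance is not established by the protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CurveKind",
    "GasExchangeCurve",
    "FvCBConstants",
    "FvCBParams",
    "NRHParams",
    "FvCBFit",
    "NRHFit",
    "Limitation",
    "gm_at_temperature",
    "fvcb_forward",
    "nrh_forward",
    "fit_aci",
    "correct_absorbed_irradiance",
    "fit_light_response",
    "phi_co2",
    "ACI_CO2_STEPS",
    "AQ_LIGHT_STEPS",
]

# Measurement-protocol step sequences (set-point order as run on the
# instrument): CO2 in umol mol-1 for A/Ci, irradiance in umol m-2 s-1
# for A/Q.
ACI_CO2_STEPS = np.array(
    [400, 200, 50, 100, 300, 400, 600, 900, 1200, 1500, 1800, 2000], dtype=float
)
AQ_LIGHT_STEPS = np.array(
    [2000, 1800, 1400, 1000, 600, 400, 200, 150, 100, 75, 50, 0], dtype=float
)

GM_FLOOR = 0.05  # mol m-2 s-1 bar-1; guard against the linear gm(T) going <= 0
R_GAS = 8.314e-3  # kJ mol-1 K-1


class CurveKind(str, Enum):
    ACI = "ACi"
    AQ = "AQ"


class Limitation(str, Enum):
    RUBISCO = "Rubisco"
    RUBP = "RuBP"


@dataclass
class GasExchangeCurve:
    """One response curve: A vs Ci (A/Ci) or A vs Q (A/Q).

    A in umol m-2 s-1; Ci in umol mol-1; Q and Ia in umol m-2 s-1.
    ``Ia`` (absorbed irradiance) is set for A/Q curves only.
    """

    kind: CurveKind
    A: np.ndarray
    driver: np.ndarray  # Ci for ACi, Q for AQ
    leaf_T: float = 25.0  # degrees C
    Ia: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kind = CurveKind(self.kind)
        self.A = np.asarray(self.A, dtype=float)
        self.driver = np.asarray(self.driver, dtype=float)
        if self.A.shape != self.driver.shape:
            raise ValueError("A and driver must have equal length")
        if self.A.size < 6:
            raise ValueError("a response curve needs at least 6 points")
        if self.kind is CurveKind.ACI and np.any(self.driver <= 0):
            raise ValueError("Ci must be strictly positive")
        if self.kind is CurveKind.AQ and np.any(self.driver < 0):
            raise ValueError("Q must be non-negative")
        if not np.isfinite(self.leaf_T):
            raise ValueError("leaf temperature must be finite")
        if self.Ia is not None:
            self.Ia = np.asarray(self.Ia, dtype=float)


@dataclass
class FvCBConstants:
    """Rubisco kinetics at 25 C with Arrhenius temperature response.

    Defaults are the standard tobacco-derived parameterization
    (Kc, Ko, Gamma* and their activation energies); O is the oxygen
    partial pressure.  Kc and Gamma* in umol mol-1, Ko in mmol mol-1,
    activation energies in kJ mol-1, O in mbar.
    """

    kc25: float = 404.9
    ko25: float = 278.4
    gamma_star25: float = 42.75
    ea_kc: float = 79.43
    ea_ko: float = 36.38
    ea_gamma_star: float = 37.83
    O: float = 210.0

    def __post_init__(self) -> None:
        for name in ("kc25", "ko25", "gamma_star25", "O"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def at_temperature(self, T: float) -> tuple[float, float, float]:
        """(Kc, Ko*1000, Gamma*) at leaf temperature T in C, all in
        umol mol-1 (Ko converted from mmol mol-1)."""

        def arrh(p25: float, ea: float) -> float:
            return p25 * np.exp(ea * (T - 25.0) / (298.15 * R_GAS * (T + 273.15)))

        kc = arrh(self.kc25, self.ea_kc)
        ko = arrh(self.ko25, self.ea_ko) * 1000.0  # -> umol mol-1
        gs = arrh(self.gamma_star25, self.ea_gamma_star)
        return kc, ko, gs

    def km(self, T: float) -> float:
        """Effective Michaelis constant Kc*(1 + O/Ko) at T, umol mol-1."""
        kc, ko, _ = self.at_temperature(T)
        return kc * (1.0 + self.O * 1000.0 / ko)  # O mbar -> ubar


@dataclass
class FvCBParams:
    """Forward-model parameters for one A/Ci curve."""

    vcmax: float
    j: float
    rd: float = 1.5
    leaf_T: float = 25.0

    def __post_init__(self) -> None:
        if self.vcmax <= 0 or self.j <= 0 or self.rd < 0:
            raise ValueError("rates must be positive (rd non-negative)")


@dataclass
class NRHParams:
    """Non-rectangular hyperbola parameters for one A/Q curve."""

    phi: float
    theta: float
    pmax: float
    rd: float = 1.5
    absorptance: float = 0.85

    def __post_init__(self) -> None:
        if not (0 < self.theta <= 1):
            raise ValueError("theta must lie in (0, 1]")
        if not (0 < self.phi <= 0.125):
            raise ValueError("phi must lie in (0, 0.125]")
        if self.pmax <= 0 or self.rd < 0:
            raise ValueError("pmax must be positive, rd non-negative")
        if not (0 < self.absorptance <= 1):
            raise ValueError("absorptance must lie in (0, 1]")


@dataclass
class FvCBFit:
    vcmax: float
    j1800: float | None  # None when no RuBP-limited region is identifiable
    rd: float
    gm: float
    limitation: list[Limitation]
    rss: float


@dataclass
class NRHFit:
    pmax: float
    phi: float
    theta: float
    rd: float
    phi_co2: float | None = None
    rss: float = 0.0


# ---------------------------------------------------------------------------
# gm-temperature constraint


def gm_at_temperature(T: float) -> float:
    """Mesophyll conductance at leaf temperature T (C), from the linear
    tobacco relationship gm = -0.44 + 0.058*T (mol m-2 s-1 bar-1).

    Outside 5-45 C a warning is raised but the value still returned;
    non-physical (<= 0) values are clipped to a small positive floor.
    """
    if not (5.0 <= T <= 45.0):
        warnings.warn(f"leaf temperature {T} C outside sanity bounds [5, 45]")
    gm = -0.44 + 0.058 * T
    if gm <= 0:
        warnings.warn(f"gm(T={T}) = {gm:.3f} <= 0; clipped to {GM_FLOOR}")
        return GM_FLOOR
    return gm


# ---------------------------------------------------------------------------
# FvCB forward model


def _limited_rate(
    Ci: np.ndarray,
    x1: float,
    x2: float,
    rd: float,
    gm: float,
    gamma_star: float,
    strict: bool = True,
) -> np.ndarray:
    """Net assimilation for one limitation, solving Cc = Ci - A/gm.

    Both FvCB limitations share the rational form
    A = x1*(Cc - Gamma*)/(Cc + x2) - Rd; substituting Cc yields a
    quadratic in A whose physical root approaches the Ci-based closed
    form as gm -> infinity.  With strict=False a negative discriminant
    (no real Cc solution, reachable only for non-physical trial
    parameters during fitting) is clipped instead of raised.
    """
    Ci = np.asarray(Ci, dtype=float)
    a = -1.0 / gm
    b = Ci + x2 + (x1 - rd) / gm
    c = rd * (Ci + x2) - x1 * (Ci - gamma_star)
    disc = b * b - 4.0 * a * c
    if np.any(disc < 0):
        if strict:
            raise FloatingPointError(
                "non-convergent Cc solve: negative discriminant"
            )
        disc = np.maximum(disc, 0.0)
    # physical root (-b + sqrt(disc)) / (2a), written in the
    # cancellation-free (Citardauq) form for the common b > 0 case —
    # at large gm the naive form loses ~half the significant digits
    sqrt_d = np.sqrt(disc)
    return np.where(
        b >= 0, -2.0 * c / (b + sqrt_d), (-b + sqrt_d) / (2.0 * a)
    )


def fvcb_forward(
    params: FvCBParams,
    Ci: np.ndarray,
    constants: FvCBConstants | None = None,
    gm: float | None = None,
) -> tuple[np.ndarray, list[Limitation]]:
    """Net assimilation A (umol m-2 s-1) on a Ci grid (umol mol-1).

    A = min(Ac, Aj) with
    Ac = Vcmax*(Cc - Gamma*)/(Cc + Kc*(1 + O/Ko)) - Rd   (Rubisco)
    Aj = J*(Cc - Gamma*)/(4*Cc + 8*Gamma*) - Rd          (RuBP regen.)
    and Cc = Ci - A/gm solved self-consistently per limitation.
    Ci is in umol mol-1, treated as ubar at ~1 bar total pressure.
    Returns (A, per-point limitation states).
    """
    constants = constants or FvCBConstants()
    if gm is None:
        gm = gm_at_temperature(params.leaf_T)
    km = constants.km(params.leaf_T)
    _, _, gs = constants.at_temperature(params.leaf_T)
    ac = _limited_rate(Ci, params.vcmax, km, params.rd, gm, gs)
    aj = _limited_rate(Ci, params.j / 4.0, 2.0 * gs, params.rd, gm, gs)
    A = np.minimum(ac, aj)
    states = [
        Limitation.RUBISCO if a <= j else Limitation.RUBP for a, j in zip(ac, aj)
    ]
    return A, states


# ---------------------------------------------------------------------------
# A/Ci fitting


def fit_aci(
    curve: GasExchangeCurve,
    constants: FvCBConstants | None = None,
    min_rubisco_points: int = 4,
) -> FvCBFit:
    """Fit (Vcmax, J, Rd) to an A/Ci curve with gm fixed by temperature.

    The Ci axis is split at an enumerated cutover into a Rubisco-limited
    low-Ci region and a RuBP-regeneration-limited high-Ci region; for
    each candidate split the three parameters are fitted by least
    squares and the split minimizing total RSS wins (ties broken toward
    more Rubisco-limited points).  J1800 is only reported when at least
    two points fall in the RuBP-limited region — genotypes with very
    low Rubisco never become electron-transport limited, and for them
    J is unidentifiable from the curve.
    """
    if curve.kind is not CurveKind.ACI:
        raise ValueError("fit_aci requires an A/Ci curve")
    constants = constants or FvCBConstants()
    gm = gm_at_temperature(curve.leaf_T)
    km = constants.km(curve.leaf_T)
    _, _, gs = constants.at_temperature(curve.leaf_T)

    order = np.argsort(curve.driver)
    ci = curve.driver[order]
    a_obs = curve.A[order]
    n = ci.size
    if n < min_rubisco_points:
        raise ValueError("too few Rubisco-limited candidates: Vcmax unidentifiable")

    rd0 = max(0.1, -float(a_obs[0]) if a_obs[0] < 0 else 1.0)
    amax = float(a_obs.max())

    def residuals(x: np.ndarray, cut: int) -> np.ndarray:
        vcmax, j, rd = x
        res = np.empty(n)
        if cut > 0:
            res[:cut] = (
                _limited_rate(ci[:cut], vcmax, km, rd, gm, gs, strict=False)
                - a_obs[:cut]
            )
        if cut < n:
            res[cut:] = (
                _limited_rate(ci[cut:], j / 4.0, 2.0 * gs, rd, gm, gs, strict=False)
                - a_obs[cut:]
            )
        return res

    # cut = number of Rubisco-limited points (low-Ci side); cut == n
    # means the whole curve is Rubisco limited (J unavailable).
    best = None
    for cut in range(min_rubisco_points, n + 1):
        if 0 < n - cut < 2:  # a 1-point RuBP region cannot constrain J
            continue
        x0 = np.array(
            [
                max(4.0 * (amax + rd0), 10.0),
                max(4.0 * (amax + rd0), 10.0),
                rd0,
            ]
        )
        # crude Vcmax start from a mid-curve point
        mid = ci[min(cut - 1, n // 2)]
        x0[0] = max((amax + rd0) / max((mid - gs) / (mid + km), 0.05), 10.0)
        sol = least_squares(
            residuals,
            x0,
            args=(cut,),
            bounds=([1e-3, 1e-3, 0.0], [2000.0, 2000.0, 50.0]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        rss = float(np.sum(sol.fun**2))
        # ties (within numerical noise) broken toward more Rubisco-
        # limited points, i.e. the larger cut wins on a near-tie
        if best is None:
            best = (rss, cut, sol.x)
        else:
            tol = 1e-10 * (1.0 + best[0])
            if rss < best[0] - tol or (rss <= best[0] + tol and cut > best[1]):
                best = (rss, cut, sol.x)
    if best is None:
        raise RuntimeError("A/Ci fit failed for every cutover assignment")
    rss, cut, (vcmax, j, rd) = best
    limitation = [Limitation.RUBISCO] * cut + [Limitation.RUBP] * (n - cut)
    j1800 = float(j) if n - cut >= 2 else None
    return FvCBFit(
        vcmax=float(vcmax),
        j1800=j1800,
        rd=float(rd),
        gm=gm,
        limitation=limitation,
        rss=rss,
    )


# ---------------------------------------------------------------------------
# Light response


def correct_absorbed_irradiance(Q: np.ndarray, absorptance: float) -> np.ndarray:
    """Absorbed irradiance Ia = Q * leaf absorptance."""
    if not (0 < absorptance <= 1):
        raise ValueError("absorptance must lie in (0, 1]")
    return np.asarray(Q, dtype=float) * absorptance


def nrh_forward(
    Ia: np.ndarray, phi: float, theta: float, pmax: float, rd: float
) -> np.ndarray:
    """Non-rectangular hyperbola light response:

    A = [phi*Ia + Pmax - sqrt((phi*Ia + Pmax)^2 - 4*phi*Ia*theta*Pmax)]
        / (2*theta) - Rd
    """
    Ia = np.asarray(Ia, dtype=float)
    s = phi * Ia + pmax
    disc = s * s - 4.0 * phi * Ia * theta * pmax
    return (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * theta) - rd


def fit_light_response(curve: GasExchangeCurve) -> NRHFit:
    """Fit (phi, theta, Pmax, Rd) of the non-rectangular hyperbola to an
    A/Q curve by bounded least squares on absorbed irradiance.

    Starts from the data: phi0 = low-light slope, Rd0 = -A(Q=0),
    Pmax0 = max(A) + Rd0, theta0 = 0.7.
    """
    if curve.kind is not CurveKind.AQ:
        raise ValueError("fit_light_response requires an A/Q curve")
    ia = curve.Ia if curve.Ia is not None else curve.driver
    ia = np.asarray(ia, dtype=float)
    a_obs = curve.A
    if ia.size < 8:
        raise ValueError("light-response fit needs at least 8 points")
    if not np.any(ia == 0):
        raise ValueError("light-response fit needs a dark (Q=0) point")
    if ia.max() < 1000:
        raise ValueError("light-response fit needs near-saturating light")

    rd0 = max(float(-a_obs[ia == 0].mean()), 0.0)
    low = ia < 200
    if low.sum() >= 2:
        phi0 = float(np.polyfit(ia[low], a_obs[low], 1)[0])
    else:
        phi0 = 0.05
    phi0 = min(max(phi0, 0.011), 0.125)
    pmax0 = float(a_obs.max()) + rd0

    def residuals(x: np.ndarray) -> np.ndarray:
        phi, theta, pmax, rd = x
        return nrh_forward(ia, phi, theta, pmax, rd) - a_obs

    sol = least_squares(
        residuals,
        np.array([phi0, 0.7, max(pmax0, 1.0), rd0]),
        bounds=([0.01, 0.01, 1e-3, 0.0], [0.125, 1.0, 500.0, 50.0]),
        xtol=1e-13,
        ftol=1e-13,
        gtol=1e-13,
    )
    if not sol.success:
        raise RuntimeError(f"light-response fit failed: {sol.message}")
    phi, theta, pmax, rd = sol.x
    return NRHFit(
        pmax=float(pmax),
        phi=float(phi),
        theta=float(theta),
        rd=float(rd),
        rss=float(np.sum(sol.fun**2)),
    )


def phi_co2(curve: GasExchangeCurve, cutoff: float = 150.0) -> float:
    """Apparent quantum yield of CO2 fixation: OLS slope (intercept
    free) of A on absorbed irradiance, restricted to Ia < cutoff."""
    if curve.kind is not CurveKind.AQ:
        raise ValueError("phi_co2 requires an A/Q curve")
    ia = curve.Ia if curve.Ia is not None else curve.driver
    ia = np.asarray(ia, dtype=float)
    sel = ia < cutoff
    if sel.sum() < 3:
        raise ValueError(
            f"phi_co2 needs >= 3 points below Ia = {cutoff}, got {int(sel.sum())}"
        )
    slope, _ = np.polyfit(ia[sel], curve.A[sel], 1)
    return float(slope)
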