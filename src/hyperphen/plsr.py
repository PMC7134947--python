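"""Partial least squares regression of traits on reflectance spectra.

Contiguous spectral bands are strongly collinear, which is the regime
PLSR is built for: it projects the centered spectra onto a small
number of latent variables (LVs) chosen to covary with the trait, and
composes them into a single linear model of waveband coefficients.

This module implements PLS1 NIPALS on mean-centered (unscaled) data,
leave-one-out PRESS for selecting the LV count (minimum RMSE of the
predicted residual sum of squares; ties broken toward fewer LVs),
1000x random-resampling cross-validation for the stability statistics
reported per trait (Train R2, CV R2, RMSE, RMSE%, bias), and VIP
(variable importance in projection) scores,

    VIP_j = sqrt( p * sum_a [ SSY_a * (w_ja / ||w_a||)^2 ] / sum_a SSY_a ),

whose squares average to 1 over the p retained bands.  RMSE% is the
RMSE as a percentage of the observed trait range, max(y) - min(y).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PLSRModel",
    "CVStats",
    "fit_plsr",
    "predict",
    "vip_scores",
    "resample_validate",
    "rmse_percent",
]

_EPS = 1e-12


@dataclass
class PLSRModel:
    """A fitted PLS1 model: weights, loadings, composed coefficients,
    the PRESS curve that selected the LV count, and VIP scores."""

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # W, (p, n_lv), unit-norm columns
    x_loadings: np.ndarray  # P, (p, n_lv)
    y_loadings: np.ndarray  # q, (n_lv,)
    coefficients: np.ndarray  # (p,): y ~ y_mean + (x - x_mean) @ coefficients
    press_curve: np.ndarray  # LOO RMSE per candidate LV (index 0 = 1 LV)
    explained_y: np.ndarray  # SSY_a per component (for VIP)
    vip: np.ndarray | None = None
    trait_name: str = ""
    wavelength_grid: np.ndarray | None = None
    band_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.n_lv <= self.weights.shape[1]:
            raise ValueError("n_lv must lie in [1, fitted rank]")

    @property
    def p(self) -> int:
        return self.x_mean.size

    def to_json(self, path: str | Path) -> Path:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        d = {
            "n_lv": self.n_lv,
            "x_mean": arr(self.x_mean),
            "y_mean": self.y_mean,
            "weights": arr(self.weights),
            "x_loadings": arr(self.x_loadings),
            "y_loadings": arr(self.y_loadings),
            "coefficients": arr(self.coefficients),
            "press_curve": arr(self.press_curve),
            "explained_y": arr(self.explained_y),
            "vip": arr(self.vip),
            "trait_name": self.trait_name,
            "wavelength_grid": arr(self.wavelength_grid),
            "band_mask": arr(self.band_mask),
        }
        path = Path(path)
        path.write_text(json.dumps(d))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSRModel":
        d = json.loads(Path(path).read_text())

        def arr(x, dtype=float):
            return None if x is None else np.asarray(x, dtype=dtype)

        return cls(
            n_lv=int(d["n_lv"]),
            x_mean=arr(d["x_mean"]),
            y_mean=float(d["y_mean"]),
            weights=arr(d["weights"]),
            x_loadings=arr(d["x_loadings"]),
            y_loadings=arr(d["y_loadings"]),
            coefficients=arr(d["coefficients"]),
            press_curve=arr(d["press_curve"]),
            explained_y=arr(d["explained_y"]),
            vip=arr(d["vip"]),
            trait_name=d.get("trait_name", ""),
            wavelength_grid=arr(d.get("wavelength_grid")),
            band_mask=arr(d.get("band_mask"), dtype=bool),
        )


@dataclass
class CVStats:
    """Resampling-validation statistics for one trait model."""

    r2_train: float
    r2_cv: float
    rmse: float  # trait units, on mean held-out predictions
    rmse_pct: float  # 100 * rmse / (max(y) - min(y))
    bias: float  # mean(predicted - observed)
    n_lv: int

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.rmse_pct < 0:
            raise ValueError("rmse and rmse_pct must be non-negative")
        if self.r2_train < self.r2_cv - 1e-9:
            warnings.warn(
                f"CV R2 ({self.r2_cv:.3f}) exceeds train R2 "
                f"({self.r2_train:.3f}); unusual but not fatal"
            )


def rmse_percent(rmse: float, y_min: float, y_max: float) -> float:
    """RMSE as a percentage of the observed trait range."""
    if y_max <= y_min:
        raise ValueError("trait range must be positive")
    return 100.0 * rmse / (y_max - y_min)


# ---------------------------------------------------------------------------
# NIPALS core


def _nipals(X0: np.ndarray, y0: np.ndarray, n_comp: int):
    """PLS1 NIPALS on centered data.  Returns (W, P, q, ssy, rank):
    unit-norm weights, X loadings, y loadings, per-component explained
    y sum of squares (q_a^2 * t_a't_a), and the achieved rank (may be
    below n_comp when the residual collapses)."""
    n, p = X0.shape
    W = np.zeros((p, n_comp))
    P = np.zeros((p, n_comp))
    q = np.zeros(n_comp)
    ssy = np.zeros(n_comp)
    Xr = X0.astype(float, copy=True)
    yr = y0.astype(float, copy=True)
    rank = 0
    for a in range(n_comp):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw < _EPS * max(1.0, np.abs(y0).max()):
            break
        w /= nw
        t = Xr @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        pa = Xr.T @ t / tt
        qa = float(yr @ t) / tt
        Xr -= np.outer(t, pa)
        yr -= qa * t
        W[:, a], P[:, a], q[a] = w, pa, qa
        ssy[a] = qa * qa * tt
        rank = a + 1
    return W[:, :rank], P[:, :rank], q[:rank], ssy[:rank], rank


def _compose_coefficients(
    W: np.ndarray, P: np.ndarray, q: np.ndarray
) -> np.ndarray:
    """Regression vector B = W (P'W)^-1 q for the fitted rank."""
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


# ---------------------------------------------------------------------------
# Leave-one-out PRESS (vectorized across the n folds)


def _loo_predictions(X: np.ndarray, y: np.ndarray, max_lv: int) -> np.ndarray:
    """(n, max_lv) matrix of leave-one-out predictions: entry (i, a) is
    the prediction for sample i from a model with a+1 components fitted
    to the other n-1 samples.

    All n folds run simultaneously in the kernel (Gram-matrix) form of
    PLS1: per fold the centered cross-products G = X'X and s = X'y are
    obtained from the full-data products by rank-one downdates, and
    each component deflates G and s instead of the data matrix —
    algebraically identical to NIPALS (X'ₐ₊₁Xₐ₊₁ = G − t't pp',
    X'ₐ₊₁yₐ₊₁ = s − t't q p) at a fraction of the memory traffic.
    Components whose weight or score norm collapses leave the fold's
    prediction frozen at the previous rank.
    """
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    sx = X.sum(axis=0)
    sy = float(y.sum())
    xm = (sx[None, :] - X) / (n - 1)  # (n, p): mean of each fold
    ym = (sy - y) / (n - 1)
    # fold Gram and cross-covariance by rank-one downdates:
    # G_f = X'X - x_f x_f' - (n-1) xm_f xm_f'
    G = np.broadcast_to(XtX, (n, p, p)).copy()
    G -= X[:, :, None] * X[:, None, :]
    G -= (n - 1) * (xm[:, :, None] * xm[:, None, :])
    s = (Xty[None, :] - X * y[:, None]) - (n - 1) * xm * ym[:, None]
    x0 = X - xm  # centered held-out rows, deflated in place
    preds = np.empty((n, max_lv))
    running = ym.copy()
    scale = max(1.0, float(np.abs(y).max()))
    for a in range(max_lv):
        ns = np.linalg.norm(s, axis=1)
        alive = ns > _EPS * scale
        w = np.where(alive[:, None], s / np.where(alive, ns, 1.0)[:, None], 0.0)
        Gw = (G @ w[:, :, None])[:, :, 0]
        tt = (w * Gw).sum(axis=1)
        alive &= tt > _EPS
        tts = np.where(alive, tt, 1.0)
        pa = np.where(alive[:, None], Gw / tts[:, None], 0.0)
        qa = np.where(alive, (s * w).sum(axis=1) / tts, 0.0)
        G -= tts[:, None, None] * (pa[:, :, None] * pa[:, None, :])
        s = s - (tts * qa)[:, None] * pa
        tstar = (x0 * w).sum(axis=1)
        x0 = x0 - tstar[:, None] * pa
        running = running + qa * tstar
        preds[:, a] = running
    return preds


def _press_curve(X: np.ndarray, y: np.ndarray, max_lv: int) -> np.ndarray:
    """LOO RMSE per candidate LV count (1..max_lv)."""
    preds = _loo_predictions(X, y, max_lv)
    resid = preds - y[:, None]
    return np.sqrt(np.mean(resid**2, axis=0))


# ---------------------------------------------------------------------------
# Public fitting API


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with one y per row")
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples to fit and cross-validate")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite (no missing values)")
    if np.ptp(y) < _EPS:
        raise ValueError("constant trait vector: nothing to regress")
    return X, y


def _candidate_lv(n: int, p: int, max_lv: int | None) -> int:
    # LOO training folds hold n-1 samples, capping the usable rank
    cap = min(n - 2, p)
    return max(1, min(max_lv if max_lv is not None else 15, cap))


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int | None = None,
    trait_name: str = "",
    wavelength_grid: np.ndarray | None = None,
    band_mask: np.ndarray | None = None,
    compute_vip: bool = True,
) -> PLSRModel:
    """Fit PLS1 with the LV count selected at the minimum of the
    leave-one-out PRESS RMSE curve (ties toward fewer LVs).

    ``max_lv`` defaults to min(15, n-2, p).  X columns are the
    retained (masked) bands; no scaling is applied beyond centering.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    n_cand = _candidate_lv(n, p, max_lv)
    press = _press_curve(X, y, n_cand)
    n_lv = int(np.argmin(press)) + 1  # argmin takes the first = fewest LVs

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, ssy, rank = _nipals(X - x_mean, y - y_mean, n_lv)
    if rank == 0:
        raise ValueError("spectra carry no covariance with the trait")
    if rank < n_lv:  # residual collapsed early; honest rank wins
        n_lv = rank
    coef = _compose_coefficients(W, P, q)
    model = PLSRModel(
        n_lv=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=coef,
        press_curve=press,
        explained_y=ssy,
        trait_name=trait_name,
        wavelength_grid=(
            None if wavelength_grid is None else np.asarray(wavelength_grid)
        ),
        band_mask=None if band_mask is None else np.asarray(band_mask, bool),
    )
    if compute_vip:
        model.vip = vip_scores(model)
    return model


def predict(model: PLSRModel, spectra: np.ndarray) -> np.ndarray:
    """Apply the composed linear model: yhat = y_mean + (X - x_mean) B.

    The spectra must already be on the model's band grid — no silent
    interpolation.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[1] != model.p:
        raise ValueError(
            f"spectra have {spectra.shape[1]} bands, model expects {model.p} "
            "(wavelength grids must align; interpolate explicitly upstream)"
        )
    return model.y_mean + (spectra - model.x_mean) @ model.coefficients


def vip_scores(model: PLSRModel) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a); the weights
    are unit-norm per component, and sum_j VIP_j^2 = p identically."""
    ssy = model.explained_y
    total = float(ssy.sum())
    if total <= 0:
        raise ValueError("model explains no trait variance; VIP undefined")
    w2 = model.weights**2  # columns already unit norm
    return np.sqrt(model.p * (w2 @ ssy) / total)


# ---------------------------------------------------------------------------
# Resampling validation


def resample_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int | None = None,
    n_resamples: int = 1000,
    holdout_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[CVStats, np.ndarray]:
    """Model-stability statistics from repeated random resampling.

    Each resample holds out ``holdout_fraction`` of the samples, re-runs
    the full LV-selection rule (LOO PRESS) on the training part alone —
    no information leaks from the full-data fit — and predicts the
    held-out part.  A sample's final prediction is the mean over every
    resample in which it was held out; R2_cv, RMSE and bias are
    computed on those mean predictions against the observations, and
    RMSE% normalizes by the observed trait range.  Train R2 comes from
    the full-data fit.  Deterministic under ``seed``.

    Returns (CVStats, per-sample mean predictions); samples never held
    out get NaN predictions and a coverage warning.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    n_test = int(round(n * holdout_fraction))
    if n_test < 1:
        raise ValueError("holdout_fraction leaves no test samples")
    if n - n_test < 4:
        raise ValueError("holdout_fraction leaves too few training samples")
    rng = np.random.default_rng(seed)

    pred_sum = np.zeros(n)
    pred_count = np.zeros(n, dtype=int)
    for _ in range(n_resamples):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        Xtr, ytr = X[train], y[train]
        n_cand = _candidate_lv(train.size, p, max_lv)
        press = _press_curve(Xtr, ytr, n_cand)
        a_star = int(np.argmin(press)) + 1
        xm, ym = Xtr.mean(axis=0), float(ytr.mean())
        W, P, q, _, rank = _nipals(Xtr - xm, ytr - ym, a_star)
        coef = _compose_coefficients(W, P, q)
        pred_sum[test] += ym + (X[test] - xm) @ coef
        pred_count[test] += 1

    covered = pred_count > 0
    if not covered.all():
        warnings.warn(
            f"{int((~covered).sum())} sample(s) never held out across "
            f"{n_resamples} resamples; omitted from CV statistics"
        )
    mean_pred = np.full(n, np.nan)
    mean_pred[covered] = pred_sum[covered] / pred_count[covered]

    obs = y[covered]
    pred = mean_pred[covered]
    ss_res = float(np.sum((pred - obs) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2_cv = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    bias = float(np.mean(pred - obs))

    full = fit_plsr(X, y, max_lv=max_lv, compute_vip=False)
    fitted = predict(full, X)
    r2_train = 1.0 - float(
        np.sum((fitted - y) ** 2) / np.sum((y - y.mean()) ** 2)
    )
    stats = CVStats(
        r2_train=r2_train,
        r2_cv=r2_cv,
        rmse=rmse,
        rmse_pct=rmse_percent(rmse, float(y.min()), float(y.max())),
        bias=bias,
        n_lv=full.n_lv,
    )
    return stats, mean_pred
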