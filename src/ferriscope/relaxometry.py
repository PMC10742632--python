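"""Multi-echo T2* decay fitting and organ iron metrics.

Magnitude signal in a gradient-echo multi-echo acquisition decays with the
effective transverse relaxation time T2*::

    S(TE) = S0 * exp(-TE / T2*) + C

where the constant offset ``C`` absorbs the noise floor of magnitude
images.  Tissue iron shortens T2*, so low T2* means high iron.  Two fitting
modes are provided: the offset model above, and a truncation model
(``C`` fixed to 0, late low-SNR echoes discarded) for heavily
iron-overloaded tissue where the signal hits the noise floor within the
echo train.  Fitting operates on ROI-mean decay curves, not per pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "EchoSeries",
    "RelaxFit",
    "LiverIron",
    "PancreasT2Star",
    "default_echo_times",
    "roi_mean_decay",
    "fit_offset_model",
    "fit_truncated_model",
    "select_fit",
    "pancreas_global",
    "lic_from_liver_t2star",
]

#: Default echo spacing of the multi-echo gradient-echo protocol, ms.
ECHO_SPACING_MS = 2.26
#: Default number of echoes.
N_ECHOES = 10


def default_echo_times(n_echoes: int = N_ECHOES, spacing_ms: float = ECHO_SPACING_MS,
                       first_echo_ms: float | None = None) -> np.ndarray:
    """Uniform echo grid TE_k = first + k*spacing; first defaults to the spacing."""
    if first_echo_ms is None:
        first_echo_ms = spacing_ms
    return first_echo_ms + spacing_ms * np.arange(n_echoes, dtype=float)


@dataclass(frozen=True)
class EchoSeries:
    """ROI-mean signal magnitude versus echo time.

    Parameters
    ----------
    echo_times : sequence of float
        Echo times in milliseconds, strictly increasing, all positive.
    signal : sequence of float
        Mean magnitude under the ROI at each echo, arbitrary units, >= 0.
    noise_sd : float, optional
        Background noise standard deviation estimate (same units as signal).
    """

    echo_times: np.ndarray
    signal: np.ndarray
    noise_sd: float | None = None

    def __init__(self, echo_times: Sequence[float], signal: Sequence[float],
                 noise_sd: float | None = None) -> None:
        te = np.asarray(echo_times, dtype=float)
        sig = np.asarray(signal, dtype=float)
        if te.ndim != 1 or sig.ndim != 1 or te.size != sig.size:
            raise ValueError("echo_times and signal must be 1-D and the same length")
        if te.size < 2:
            raise ValueError("at least two echoes required")
        if not np.all(np.diff(te) > 0):
            raise ValueError("echo_times must be strictly increasing")
        if te[0] <= 0:
            raise ValueError("echo_times must be positive")
        if np.any(sig < 0) or not np.all(np.isfinite(sig)):
            raise ValueError("signal must be finite and non-negative")
        if noise_sd is not None and noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "echo_times", te)
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "noise_sd", noise_sd)

    def __len__(self) -> int:
        return int(self.echo_times.size)

    def truncated(self, n: int) -> "EchoSeries":
        """First ``n`` echoes as a new series."""
        return EchoSeries(self.echo_times[:n], self.signal[:n], self.noise_sd)


@dataclass(frozen=True)
class RelaxFit:
    """Result of a mono-exponential decay fit."""

    t2star: float                      # ms
    s0: float                          # a.u.
    offset: float                      # a.u.; 0 under the truncation model
    model: Literal["offset", "truncation"]
    n_echoes_used: int
    rmse: float
    r_squared: float

    @property
    def r2star(self) -> float:
        """Relaxation rate R2* = 1000 / T2*, in Hz."""
        return 1000.0 / self.t2star

    def to_dict(self) -> dict:
        return {
            "t2star_ms": self.t2star,
            "s0": self.s0,
            "offset": self.offset,
            "model": self.model,
            "n_echoes_used": self.n_echoes_used,
            "rmse": self.rmse,
            "r_squared": self.r_squared,
        }


@dataclass(frozen=True)
class LiverIron:
    """Liver iron concentration derived from hepatic T2*."""

    t2star: float          # ms
    lic: float             # mg Fe / g dry weight
    calibration_id: str


@dataclass(frozen=True)
class PancreasT2Star:
    """Head/body/tail pancreatic T2* with their arithmetic-mean global value."""

    head: float
    body: float
    tail: float
    global_value: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if math.isnan(self.global_value):
            object.__setattr__(self, "global_value", (self.head + self.body + self.tail) / 3.0)


class FitError(RuntimeError):
    """Raised when a decay fit cannot be performed or does not converge."""

    def __init__(self, message: str, last_iterate: tuple | None = None) -> None:
        super().__init__(message)
        self.last_iterate = last_iterate


def roi_mean_decay(image_stack: np.ndarray | Sequence[np.ndarray],
                   roi_mask: np.ndarray,
                   echo_times: Sequence[float],
                   noise_sd: float | None = None) -> EchoSeries:
    """Average the per-echo magnitude images under a ROI mask.

    ``image_stack`` is shaped ``(n_echo, ny, nx)`` (or a sequence of 2-D
    arrays); ``roi_mask`` is a boolean array of shape ``(ny, nx)``.  The
    returned series holds the ROI-mean signal at each echo.
    """
    stack = np.asarray(image_stack, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if stack.ndim != 3:
        raise ValueError("image_stack must be 3-D: (n_echo, ny, nx)")
    if mask.shape != stack.shape[1:]:
        raise ValueError(f"mask shape {mask.shape} does not match image shape {stack.shape[1:]}")
    if not mask.any():
        raise ValueError("empty ROI")
    te = np.asarray(echo_times, dtype=float)
    if te.size != stack.shape[0]:
        raise ValueError("echo count does not match metadata echo_times")
    signal = stack[:, mask].mean(axis=1)
    return EchoSeries(te, signal, noise_sd=noise_sd)


def _loglinear_init(te: np.ndarray, sig: np.ndarray, c0: float) -> tuple[float, float]:
    """(S0, T2*) start values from a log-linear fit to the first half of echoes."""
    half = max(2, te.size // 2)
    s = sig[:half] - c0
    t = te[:half]
    good = s > 0
    if good.sum() < 2:
        # decay already at the floor: seed from the first two echoes
        s = np.maximum(sig[:half] - c0, 1e-12)
        good = np.ones_like(s, dtype=bool)
    slope, intercept = np.polyfit(t[good], np.log(s[good]), 1)
    if slope >= 0:
        slope = -1.0 / max(te[-1], 1.0)
    t2star0 = -1.0 / slope
    s0 = float(np.exp(intercept))
    return max(s0, 1e-9), float(np.clip(t2star0, 0.05, 1e4))


def _fit_stats(sig: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    resid = sig - pred
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((sig - sig.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return rmse, r2


def fit_offset_model(series: EchoSeries) -> RelaxFit:
    """Least-squares fit of ``S(TE) = S0*exp(-TE/T2*) + C``.

    Requires at least 4 echoes.  Initialization: ``C0 = min(signal)`` and a
    log-linear regression on the first half of the echo train; refinement by
    trust-region least squares to 1e-8 relative parameter tolerance.
    """
    te, sig = series.echo_times, series.signal
    if len(series) < 4:
        raise FitError("offset-model fit requires at least 4 echoes")
    if np.allclose(sig, sig[0]):
        raise FitError("no decay")

    c0 = float(sig.min())
    s0_init, t2_init = _loglinear_init(te, sig, c0)
    # finite box keeps the solver off the degenerate S0 -> inf, T2* -> 0
    # ridge that flat heavy-iron traces otherwise produce
    s0_hi = 1e3 * float(sig.max())
    x0 = np.array([min(s0_init, s0_hi), np.clip(t2_init, 1e-2, 1e5),
                   min(c0, float(sig.max()))])

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * np.exp(-te / p[1]) + p[2] - sig

    sol = least_squares(resid, x0, bounds=([0.0, 1e-2, 0.0],
                                           [s0_hi, 1e5, float(sig.max())]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000)
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise FitError("offset-model fit did not converge", last_iterate=tuple(sol.x))
    s0, t2star, offset = (float(v) for v in sol.x)
    rmse, r2 = _fit_stats(sig, s0 * np.exp(-te / t2star) + offset)
    return RelaxFit(t2star=t2star, s0=s0, offset=offset, model="offset",
                    n_echoes_used=len(series), rmse=rmse, r_squared=r2)


def _fit_pure_exponential(te: np.ndarray, sig: np.ndarray) -> tuple[float, float]:
    s0_init, t2_init = _loglinear_init(te, sig, 0.0)
    s0_hi = 1e3 * float(sig.max())
    x0 = np.array([min(s0_init, s0_hi), np.clip(t2_init, 1e-2, 1e5)])

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * np.exp(-te / p[1]) - sig

    sol = least_squares(resid, x0, bounds=([0.0, 1e-2], [s0_hi, 1e5]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000)
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise FitError("truncation-model fit did not converge", last_iterate=tuple(sol.x))
    return float(sol.x[0]), float(sol.x[1])


def _rician_mean(nu: float, sigma: float) -> float:
    """Expected magnitude of a complex Gaussian with modulus ``nu``, noise ``sigma``."""
    from scipy.special import hyp1f1

    return float(sigma * np.sqrt(np.pi / 2) * hyp1f1(-0.5, 1.0, -nu ** 2 / (2 * sigma ** 2)))


def _rician_debias(m: float, sigma: float) -> float:
    """Invert the Rician first moment: underlying signal given observed mean.

    Magnitude images have a noise floor (mean ``sigma*sqrt(pi/2)`` at zero
    signal); near that floor the observed ROI mean overestimates the true
    decay value.  Observations at or below the floor map to zero.
    """
    from scipy.optimize import brentq

    floor = _rician_mean(0.0, sigma)
    if m <= floor:
        return 0.0
    hi = m + 5 * sigma
    return float(brentq(lambda nu: _rician_mean(nu, sigma) - m, 0.0, hi, xtol=1e-10))


def _adjusted_r2(sig: np.ndarray, pred: np.ndarray, n_params: int = 2) -> float:
    n = sig.size
    _, r2 = _fit_stats(sig, pred)
    if n - n_params - 1 <= 0:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def fit_truncated_model(series: EchoSeries, min_points: int = 3) -> RelaxFit:
    """Offset-free fit ``S0*exp(-TE/T2*)`` discarding late low-SNR echoes.

    While the last retained echo lies below the noise floor (signal below
    ``2 * noise_sd``), it is dropped and the remaining points are refit.
    Without a noise estimate the last echo is dropped as long as doing so
    improves the bias-corrected r².  Never fewer than ``min_points`` echoes.
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    if len(series) < min_points:
        raise FitError(f"truncation fit requires at least {min_points} echoes")

    te, sig = series.echo_times, series.signal
    n = te.size
    if series.noise_sd is not None and series.noise_sd > 0:
        floor = 2.0 * series.noise_sd
        while n > min_points and sig[n - 1] < floor:
            n -= 1
        # low-SNR retained echoes (below ~4 sigma, including any kept only by
        # min_points) sit on the magnitude noise floor; replace them by the
        # Rician-debiased signal so they do not drag the offset-free fit up
        sig = sig.copy()
        for k in range(n):
            if sig[k] < 2.0 * floor:
                sig[k] = _rician_debias(sig[k], series.noise_sd)
        s0, t2 = _fit_pure_exponential(te[:n], sig[:n])
    else:
        s0, t2 = _fit_pure_exponential(te[:n], sig[:n])
        best = _adjusted_r2(sig[:n], s0 * np.exp(-te[:n] / t2))
        while n > min_points:
            s0_c, t2_c = _fit_pure_exponential(te[:n - 1], sig[:n - 1])
            cand = _adjusted_r2(sig[:n - 1], s0_c * np.exp(-te[:n - 1] / t2_c))
            if cand <= best + 1e-12:
                break
            n -= 1
            s0, t2, best = s0_c, t2_c, cand

    rmse, r2 = _fit_stats(sig[:n], s0 * np.exp(-te[:n] / t2))
    return RelaxFit(t2star=t2, s0=s0, offset=0.0, model="truncation",
                    n_echoes_used=int(n), rmse=rmse, r_squared=r2)


def select_fit(series: EchoSeries, heavy_iron_t2star_threshold: float = 10.0) -> RelaxFit:
    """Offset-model fit, re-fit with truncation when T2* indicates heavy iron.

    A provisional offset fit below ``heavy_iron_t2star_threshold`` (default
    10 ms, the conventional severe-cardiac-iron boundary) triggers a
    truncation-model refit, which is returned instead.
    """
    fit = fit_offset_model(series)
    if fit.t2star < heavy_iron_t2star_threshold:
        return fit_truncated_model(series)
    return fit


def pancreas_global(head: RelaxFit | float, body: RelaxFit | float,
                    tail: RelaxFit | float) -> PancreasT2Star:
    """Global pancreatic T2* as the mean of head, body and tail ROI values."""
    vals = [f.t2star if isinstance(f, RelaxFit) else float(f) for f in (head, body, tail)]
    if not all(math.isfinite(v) and v > 0 for v in vals):
        raise ValueError("pancreatic T2* values must be finite and positive")
    return PancreasT2Star(head=vals[0], body=vals[1], tail=vals[2])


#: Default linear-in-R2* liver calibration: LIC = a * R2* + b with R2* in Hz.
DEFAULT_LIC_CALIBRATION = {"id": "linear_r2star_default", "a": 0.0254, "b": 0.202}


def lic_from_liver_t2star(t2star: float, calibration: dict | None = None) -> LiverIron:
    """Liver iron concentration (mg/g dry weight) from hepatic T2*.

    Default calibration is linear in R2* = 1000/T2*:
    ``LIC = a * R2* + b`` with a = 0.0254 mg/g/Hz and b = 0.202 mg/g, so LIC
    decreases monotonically with T2*.  Alternative coefficient sets can be
    supplied as ``{"id": ..., "a": ..., "b": ...}``; every result is stamped
    with the calibration id used.
    """
    if not (math.isfinite(t2star) and t2star > 0):
        raise ValueError("t2star must be positive and finite")
    cal = DEFAULT_LIC_CALIBRATION if calibration is None else calibration
    lic = cal["a"] * (1000.0 / t2star) + cal["b"]
    return LiverIron(t2star=float(t2star), lic=float(lic), calibration_id=str(cal["id"]))
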