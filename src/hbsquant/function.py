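"""Global and regional liver-function indices from HBS and SPECT.

Global function is the hepatic mebrofenin uptake rate (TL-F, %/min)
estimated over the 150-350 s post-injection window — the phase of
homogeneous blood-pool distribution before biliary excretion — and the
liver's percentage share of field-of-view activity (TL-U, %).  The
regional share of function within the future liver remnant (FLR-C) is
the ratio of SPECT counts in the FLR volume of interest to counts in
the whole-liver volume of interest.  The two remnant-function scores
combine these:

    FLR-F  = TL-F x FLR-C / BSA     (%/min/m2)
    HIBA-i = TL-U x FLR-C           (%, no BSA normalisation)

A suggested safe reference band for remnant function, rather than a
single cutoff, is FLR-F 1.9-2.8 %/min/m2 and HIBA-i 17-23 %.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from hbsquant.planar import TimeActivityCurve

__all__ = [
    "EkmanWindow",
    "FunctionalIndices",
    "bsa_dubois",
    "tl_f_ekman",
    "tl_u",
    "flr_c",
    "flr_f",
    "hiba_index",
    "FLR_F_REFERENCE_RANGE",
    "HIBA_I_REFERENCE_RANGE",
]

#: Suggested safe reference band for remnant function (lower, upper).
FLR_F_REFERENCE_RANGE: tuple[float, float] = (1.9, 2.8)
HIBA_I_REFERENCE_RANGE: tuple[float, float] = (17.0, 23.0)


@dataclass(frozen=True)
class EkmanWindow:
    """Measurement window for uptake-phase calculations, in seconds."""

    t_start: float = 150.0
    t_end: float = 350.0

    def __post_init__(self) -> None:
        if not 0 <= self.t_start < self.t_end:
            raise ValueError("need 0 <= t_start < t_end")


@dataclass(frozen=True)
class FunctionalIndices:
    """All functional indices for one study, with their inputs."""

    tl_f: float
    tl_u: float
    flr_c: float
    bsa: float
    flr_f: float
    hiba_i: float

    @classmethod
    def compute(cls, tl_f: float, tl_u: float, flr_c: float, bsa: float) -> "FunctionalIndices":
        return cls(
            tl_f=tl_f,
            tl_u=tl_u,
            flr_c=flr_c,
            bsa=bsa,
            flr_f=flr_f(tl_f, flr_c, bsa),
            hiba_i=hiba_index(tl_u, flr_c),
        )


def bsa_dubois(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m2) by the DuBois & DuBois formula.

    ``BSA = 0.007184 * weight^0.425 * height^0.725``.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def _interp(curve: TimeActivityCurve, t: float) -> float:
    if t < curve.times[0] or t > curve.times[-1]:
        raise ValueError(
            f"time {t} s outside curve span [{curve.times[0]}, {curve.times[-1]}] s"
        )
    return float(np.interp(t, curve.times, curve.counts))


def _window_grid(curve: TimeActivityCurve, window: EkmanWindow) -> np.ndarray:
    inner = curve.times[(curve.times > window.t_start) & (curve.times < window.t_end)]
    return np.concatenate(([window.t_start], inner, [window.t_end]))


def tl_f_ekman(
    liver: TimeActivityCurve,
    blood: TimeActivityCurve,
    fov: TimeActivityCurve,
    window: EkmanWindow = EkmanWindow(),
    estimator: str = "two-point",
) -> float:
    """Hepatic uptake rate TL-F in %/min over the measurement window.

    With ``fL(t) = liver(t)/fov(t)`` the liver's fractional share of
    field-of-view activity and ``b(t) = blood(t)/blood(t_start)`` the
    blood-pool curve normalised at the window start, the default
    two-point estimator is

        TL-F = 100 * [fL(t_end) - fL(t_start)] / int_{t_start}^{t_end} b(t) dt

    with the integral by the trapezoid rule and time in minutes — the
    uptake increment per unit of normalised blood-pool exposure.  The
    alternative ``estimator="slope"`` fits a least-squares line to
    ``fL(t)`` over the window and reports its slope as %/min, without
    blood normalisation; it is provided for sensitivity checks.

    Negative results (possible under extreme noise) are flagged with a
    warning, not clamped.
    """
    for name, c in (("liver", liver), ("blood", blood), ("fov", fov)):
        if window.t_start < c.times[0] or window.t_end > c.times[-1]:
            raise ValueError(f"window [{window.t_start}, {window.t_end}] s outside {name} curve span")
    if estimator not in {"two-point", "slope"}:
        raise ValueError(f"unknown estimator {estimator!r}")

    if estimator == "slope":
        grid = _window_grid(liver, window)
        fl = np.array([_interp(liver, t) / _interp(fov, t) for t in grid])
        slope_per_s = np.polyfit(grid, fl, 1)[0]
        value = 100.0 * slope_per_s * 60.0
    else:
        fov_s, fov_e = _interp(fov, window.t_start), _interp(fov, window.t_end)
        if fov_s <= 0 or fov_e <= 0:
            raise ValueError("FOV counts are zero inside the window")
        b_ref = _interp(blood, window.t_start)
        if b_ref <= 0:
            raise ValueError("blood-pool reference at window start is zero")
        fl_start = _interp(liver, window.t_start) / fov_s
        fl_end = _interp(liver, window.t_end) / fov_e
        grid = _window_grid(blood, window)
        b = np.array([_interp(blood, t) for t in grid]) / b_ref
        integral_min = np.trapezoid(b, grid) / 60.0
        value = 100.0 * (fl_end - fl_start) / integral_min
    if value < 0:
        warnings.warn(f"negative TL-F ({value:.3g} %/min) — check count levels", stacklevel=2)
    return float(value)


def tl_u(
    liver: TimeActivityCurve,
    fov: TimeActivityCurve,
    window: EkmanWindow = EkmanWindow(),
    mode: str = "endpoint",
) -> float:
    """Total liver uptake TL-U: liver share of FOV activity, in percent.

    ``mode="endpoint"`` (default) evaluates ``100 * liver/fov`` at the
    window end (350 s); ``mode="window-mean"`` averages the ratio over
    the window on the observed time grid.
    """
    if mode not in {"endpoint", "window-mean"}:
        raise ValueError(f"unknown TL-U mode {mode!r}")
    if window.t_start < fov.times[0] or window.t_end > fov.times[-1]:
        raise ValueError("window outside FOV curve span")
    if mode == "endpoint":
        denom = _interp(fov, window.t_end)
        if denom <= 0:
            raise ValueError("FOV counts are zero at the window end")
        return float(100.0 * _interp(liver, window.t_end) / denom)
    grid = _window_grid(fov, window)
    denom = np.array([_interp(fov, t) for t in grid])
    if np.any(denom <= 0):
        raise ValueError("FOV counts are zero inside the window")
    num = np.array([_interp(liver, t) for t in grid])
    return float(100.0 * np.mean(num / denom))


def flr_c(spect: np.ndarray, flr_voi: np.ndarray, liver_voi: np.ndarray) -> float:
    """Regional function share: FLR VOI counts over whole-liver VOI counts.

    Voxels outside the liver VOI (e.g. extrahepatic bile duct) are
    ignored.  Requires ``flr_voi`` to be a subset of ``liver_voi`` and
    positive counts in the liver VOI.
    """
    spect = np.asarray(spect, dtype=float)
    flr_voi = np.asarray(flr_voi, dtype=bool)
    liver_voi = np.asarray(liver_voi, dtype=bool)
    if spect.shape != flr_voi.shape or spect.shape != liver_voi.shape:
        raise ValueError("volume and VOI shapes differ")
    if not flr_voi.any() or not liver_voi.any():
        raise ValueError("VOI masks must be nonempty")
    if (flr_voi & ~liver_voi).any():
        raise ValueError("FLR VOI must be a subset of the liver VOI")
    total = spect[liver_voi].sum()
    if total <= 0:
        raise ValueError("liver VOI contains no counts")
    value = float(spect[flr_voi].sum() / total)
    return value


def flr_f(tl_f: float, flr_c: float, bsa: float) -> float:
    """Remnant function score FLR-F = TL-F x FLR-C / BSA, in %/min/m2."""
    if bsa <= 0:
        raise ValueError("BSA must be positive")
    if not 0 <= flr_c <= 1:
        raise ValueError("FLR-C must lie in [0, 1]")
    return tl_f * flr_c / bsa


def hiba_index(tl_u: float, flr_c: float) -> float:
    """HIBA index = TL-U x FLR-C, in percent (no BSA normalisation)."""
    if not 0 <= flr_c <= 1:
        raise ValueError("FLR-C must lie in [0, 1]")
    if not 0 <= tl_u <= 100:
        raise ValueError("TL-U must lie in [0, 100] %")
    return tl_u * flr_c
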