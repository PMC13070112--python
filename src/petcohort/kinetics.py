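"""Reference-tissue kinetic estimators for framewise TACs.

Two estimators are provided:

* a three-coefficient multilinear reference tissue model (MRTM) for
  reversible ligands, yielding the non-displaceable binding potential
  ``BP_ND = -beta1/beta2 - 1``;
* a reference-Patlak graphical fit for irreversible ligands, applied after
  an exponential adjustment of the cerebellar reference curve
  ``C_ref(t) = C_cer(t) * exp(-lambda_bar * t)``, yielding the uptake rate
  constant ``Ki_ref`` as the Patlak slope.

TACs are assumed decay-corrected; the exponential reference adjustment is a
property of the Patlak method, not isotope decay, and is kept separate from
the decay utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import FrameSchedule, TimeActivityCurve

__all__ = [
    "KineticFitError",
    "SingularFitError",
    "PatlakConfig",
    "KineticFit",
    "frame_midpoints",
    "running_integral",
    "fit_mrtm",
    "fit_reference_patlak",
    "decay_remaining_fraction",
]


class KineticFitError(ValueError):
    """A kinetic fit could not be computed from the given curves."""


class SingularFitError(KineticFitError):
    """The design matrix is numerically rank deficient (collinear TACs)."""


@dataclass(frozen=True)
class PatlakConfig:
    """Configuration of the reference-Patlak fit.

    Parameters
    ----------
    lambda_bar : float
        Rate constant (1/min) of the exponential reference adjustment.
    fit_frames : tuple of int
        Inclusive 1-based frame-index window used for the linear fit.
    """

    lambda_bar: float = 0.04
    fit_frames: tuple[int, int] = (4, 26)

    def __post_init__(self) -> None:
        if self.lambda_bar < 0:
            raise ValueError("lambda_bar must be >= 0")
        lo, hi = self.fit_frames
        if lo < 1 or hi < lo:
            raise ValueError("fit_frames must be an increasing 1-based window")
        if hi - lo + 1 < 3:
            raise ValueError("fit window must contain at least 3 frames")

    def window_slice(self, schedule: FrameSchedule) -> slice:
        lo, hi = self.fit_frames
        if hi > schedule.n_frames:
            raise ValueError(
                f"fit window {self.fit_frames} exceeds schedule of "
                f"{schedule.n_frames} frames"
            )
        return slice(lo - 1, hi)


@dataclass
class KineticFit:
    """Result of a reference-tissue fit for one region."""

    model: str  # "MRTM" | "refPatlak"
    estimate: float  # BP_ND or Ki_ref
    coefficients: np.ndarray
    rss: float
    r_squared: float
    region: str = ""

    @property
    def intercept(self) -> float:
        """Patlak intercept (effective distribution volume); NaN for MRTM."""
        if self.model == "refPatlak":
            return float(self.coefficients[1])
        return float("nan")


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Frame midpoint times in minutes."""
    return schedule.midpoints_min


def running_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Cumulative integral of a TAC at its frame midpoints (kBq*min/ml).

    Trapezoidal rule between midpoints, with an initial triangle from
    ``t = 0`` (activity assumed zero at injection). Nondecreasing for
    nonnegative input.
    """
    t = tac.times_min
    c = tac.activity
    out = np.empty_like(c)
    out[0] = 0.5 * t[0] * c[0]
    np.cumsum(0.5 * (c[1:] + c[:-1]) * np.diff(t), out=out[1:])
    out[1:] += out[0]
    return out


def _ols(X: np.ndarray, y: np.ndarray, cond_limit: float = 1e10):
    """Least squares with an explicit conditioning guard."""
    scale = np.abs(X).max(axis=0)
    if np.any(scale == 0):
        raise SingularFitError("all-zero column in design matrix")
    cond = np.linalg.cond(X / scale)
    if not np.isfinite(cond) or cond > cond_limit:
        raise SingularFitError(
            f"design matrix ill-conditioned (cond={cond:.3g}); "
            "target may be proportional to reference"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    return beta, rss, r2


def fit_mrtm(target: TimeActivityCurve, reference: TimeActivityCurve) -> KineticFit:
    """Multilinear reference tissue fit over all frames.

    Regresses ``C_T(T)`` on ``[int_0^T C_R, int_0^T C_T, C_R(T)]`` by
    ordinary least squares; ``BP_ND = -beta1/beta2 - 1``.

    Raises
    ------
    SingularFitError
        If the design is numerically collinear (e.g. target proportional
        to the reference), instead of returning a silent pseudo-inverse
        answer.
    """
    if target.schedule != reference.schedule:
        raise KineticFitError("target and reference must share a frame schedule")
    if target.schedule.n_frames < 4:
        raise KineticFitError("MRTM requires at least 4 frames")
    X = np.column_stack(
        [running_integral(reference), running_integral(target), reference.activity]
    )
    y = target.activity
    beta, rss, r2 = _ols(X, y)
    if beta[1] == 0:
        raise SingularFitError("beta2 = 0; BP_ND undefined")
    bp_nd = -beta[0] / beta[1] - 1.0
    return KineticFit(
        model="MRTM",
        estimate=float(bp_nd),
        coefficients=beta,
        rss=rss,
        r_squared=r2,
        region=target.region,
    )


def fit_reference_patlak(
    target: TimeActivityCurve,
    cerebellum: TimeActivityCurve,
    config: PatlakConfig | None = None,
) -> KineticFit:
    """Reference-Patlak fit with exponential reference adjustment.

    The reference is ``C_ref(t) = C_cer(t) * exp(-lambda_bar * t)``; the
    normalized plot ``C_T/C_ref`` versus ``int C_ref / C_ref`` is fit
    linearly over the configured frame window. ``Ki_ref`` is the slope and
    the intercept an effective distribution volume.
    """
    if config is None:
        config = PatlakConfig()
    if target.schedule != cerebellum.schedule:
        raise KineticFitError("target and cerebellum must share a frame schedule")
    win = config.window_slice(target.schedule)
    t = target.times_min
    c_ref = cerebellum.activity * np.exp(-config.lambda_bar * t)
    if np.any(c_ref[win] <= 0):
        raise KineticFitError("nonpositive reference activity inside the fit window")
    int_ref = running_integral(cerebellum.with_activity(c_ref))
    x = (int_ref / c_ref)[win]
    y = (target.activity / c_ref)[win]
    X = np.column_stack([x, np.ones_like(x)])
    beta, rss, r2 = _ols(X, y)
    return KineticFit(
        model="refPatlak",
        estimate=float(beta[0]),
        coefficients=beta,
        rss=rss,
        r_squared=r2,
        region=target.region,
    )


def decay_remaining_fraction(half_life_min: float, elapsed_min: float) -> float:
    """Fraction of activity remaining after ``elapsed_min`` of decay."""
    if half_life_min <= 0:
        raise ValueError("half_life_min must be > 0")
    if elapsed_min < 0:
        raise ValueError("elapsed_min must be >= 0")
    return float(2.0 ** (-elapsed_min / half_life_min))
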