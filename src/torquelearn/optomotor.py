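"""Optomotor-response fitting and the asymmetry index.

During a 30-s optomotor period the arena rotates clockwise or
counterclockwise and a healthy fly produces torque that rises toward an
asymptote in the direction of perceived motion.  Each period's trace is
fitted per direction with either a straight line (no detectable rise)
or a double-sigmoidal model

    f(t) = B + A * s(k1 (t - t1)) * [1 - (1 - r) * s(k2 (t - t2))]

with ``s`` the logistic function, ``k1, k2 > 0``, ``t2 > t1`` and
``r in [0, 1]`` — a rise to ``B + A`` followed by an optional partial
decay to the late-time asymptote ``B + A r``.  The optomotor magnitude
is the fitted value at the window midpoint for lines and the late-time
asymptote for double sigmoids.

The asymmetry index is (R - L)/(R + L) on the per-direction magnitudes
(absolute values of direction-congruent responses; a wrong-signed
response contributes 0 to its own direction), and is sign-adjusted so
positive values point toward the unpunished torque domain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data_model import Domain, ExperimentRecord, OmDirection, PeriodSchedule
from .errors import UndefinedIndexError, UnsupportedProtocolError, ValidationError

__all__ = [
    "OmFit",
    "AsymmetryIndex",
    "select_model",
    "fit_line",
    "fit_double_sigmoidal",
    "fit_om_trace",
    "om_phase_fits",
    "om_magnitudes",
    "asymmetry_index",
    "adjust_sign",
    "om_analysis",
]

#: |t|-statistic of the line slope above which a rise is "detected".
SLOPE_T_THRESHOLD = 3.0
#: Minimum total rise as a fraction of the trace's interquartile range.
RISE_IQR_FRAC = 0.2

_N_STARTS = 8


@dataclass
class OmFit:
    """One fitted optomotor period for one stimulus direction."""

    direction: OmDirection
    model: str  # "line" | "double_sigmoidal"
    params: dict[str, float]
    magnitude: float  # signed torque units
    goodness: float  # residual standard deviation
    fallback: bool = False  # nonlinear fit failed, line used instead


@dataclass(frozen=True)
class AsymmetryIndex:
    raw: float       # (R - L) / (R + L), positive = right-shifted
    adjusted: float  # positive = shifted toward the unpunished domain


def _check_window(t: np.ndarray) -> None:
    if len(t) < 3 or t[-1] - t[0] < 2.0:
        raise ValidationError("optomotor trace shorter than 2 s")


def select_model(t: np.ndarray, y: np.ndarray) -> str:
    """Choose "line" or "double_sigmoidal" from the detected slope.

    A rise is detected when the least-squares slope is significantly
    nonzero (|t| > 3) and the implied total rise over the window exceeds
    20 % of the trace's interquartile range.  The significance test keeps
    the choice stable under noise for both flat and rising traces.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_window(t)
    res = stats.linregress(t, y)
    rise = res.slope * (t[-1] - t[0])
    if res.stderr == 0:
        significant = res.slope != 0
    else:
        significant = abs(res.slope / res.stderr) > SLOPE_T_THRESHOLD
    iqr = float(np.subtract(*np.percentile(y, [75, 25])))
    if significant and abs(rise) > RISE_IQR_FRAC * iqr:
        return "double_sigmoidal"
    return "line"


def fit_line(t: np.ndarray, y: np.ndarray, direction: OmDirection = OmDirection.NONE) -> OmFit:
    """Least-squares line; magnitude is the fitted value at the window midpoint."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_window(t)
    if np.ptp(t) == 0:
        raise ValidationError("degenerate optomotor trace (no time spread)")
    slope, intercept = np.polyfit(t, y, 1)
    mid = 0.5 * (t[0] + t[-1])
    resid = y - (intercept + slope * t)
    return OmFit(
        direction=direction,
        model="line",
        params={"slope": float(slope), "intercept": float(intercept)},
        magnitude=float(intercept + slope * mid),
        goodness=float(np.std(resid)),
    )


def _dsig(t, B, A, k1, k2, t1, d21, r):
    s1 = 1.0 / (1.0 + np.exp(-np.clip(k1 * (t - t1), -500, 500)))
    s2 = 1.0 / (1.0 + np.exp(-np.clip(k2 * (t - t1 - d21), -500, 500)))
    return B + A * s1 * (1.0 - (1.0 - r) * s2)


def _dsig_jac(t, B, A, k1, k2, t1, d21, r):
    u1 = t - t1
    u2 = t - t1 - d21
    s1 = 1.0 / (1.0 + np.exp(-np.clip(k1 * u1, -500, 500)))
    s2 = 1.0 / (1.0 + np.exp(-np.clip(k2 * u2, -500, 500)))
    g1 = s1 * (1.0 - s1)
    g2 = s2 * (1.0 - s2)
    w = 1.0 - (1.0 - r) * s2
    J = np.empty((len(t), 7))
    J[:, 0] = 1.0
    J[:, 1] = s1 * w
    J[:, 2] = A * w * g1 * u1
    J[:, 3] = -A * s1 * (1.0 - r) * g2 * u2
    J[:, 4] = A * (-k1 * g1 * w + s1 * (1.0 - r) * k2 * g2)
    J[:, 5] = A * s1 * (1.0 - r) * k2 * g2
    J[:, 6] = A * s1 * s2
    return J


def fit_double_sigmoidal(
    t: np.ndarray, y: np.ndarray, direction: OmDirection = OmDirection.NONE
) -> OmFit:
    """Nonlinear least squares of the double-sigmoidal model.

    Eight deterministic multi-starts over (onset time, steepness,
    decay fraction); the trace is normalised by its span before fitting
    so the procedure is exactly scale- and sign-equivariant.  If no
    start converges the line fit is returned with ``fallback=True``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_window(t)
    span = float(np.ptp(y))
    if span == 0:
        # constant trace: asymptote is the constant itself
        return OmFit(
            direction=direction,
            model="double_sigmoidal",
            params={"B": float(y[0]), "A": 0.0, "k1": 1.0, "k2": 1.0,
                    "t1": float(t[0]), "d21": 1.0, "r": 1.0},
            magnitude=float(y[0]),
            goodness=0.0,
        )
    t0, T = float(t[0]), float(t[-1] - t[0])
    yn = (y - y[0]) / span

    def resid(theta):
        return _dsig(t - t0, *theta) - yn

    def jac(theta):
        return _dsig_jac(t - t0, *theta)

    lo = np.array([-3.0, -4.0, 1e-3, 1e-3, -T, 0.0, 0.0])
    hi = np.array([3.0, 4.0, 100.0, 100.0, T, 2.0 * T, 1.0])
    a0 = float(np.mean(yn[-max(3, len(yn) // 4):]) - np.mean(yn[: max(3, len(yn) // 4)]))
    if a0 == 0:
        a0 = 0.5
    best = None
    stale = 0
    for t1_0, k_0, r_0 in itertools.product((T / 8, T / 3), (0.5, 2.0), (1.0, 0.6)):
        theta0 = np.array([float(yn[0]), a0 / max(r_0, 1e-6), k_0, k_0, t1_0, T / 3, r_0])
        theta0 = np.clip(theta0, lo + 1e-9, hi - 1e-9)
        try:
            sol = optimize.least_squares(
                resid, theta0, jac=jac, bounds=(lo, hi), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=200,
            )
        except Exception:
            continue
        improved = best is None or sol.cost < best.cost * (1.0 - 1e-3)
        if best is None or sol.cost < best.cost:
            best = sol
        # deterministic early stop: two consecutive starts without
        # meaningful improvement means the basin is already found
        stale = 0 if improved else stale + 1
        if stale >= 2:
            break
    if best is None or not np.isfinite(best.cost):
        line = fit_line(t, y, direction)
        line.fallback = True
        return line
    B, A, k1, k2, t1, d21, r = best.x
    resid_sd = float(np.std(best.fun)) * span
    magnitude = (B + A * r) * span + float(y[0])
    return OmFit(
        direction=direction,
        model="double_sigmoidal",
        params={
            "B": float(B * span + y[0]),
            "A": float(A * span),
            "k1": float(k1),
            "k2": float(k2),
            "t1": float(t1 + t0),
            "d21": float(d21),
            "r": float(r),
        },
        magnitude=float(magnitude),
        goodness=resid_sd,
    )


def fit_om_trace(
    t: np.ndarray, y: np.ndarray, direction: OmDirection = OmDirection.NONE
) -> OmFit:
    """Model-select then fit one optomotor period trace."""
    model = select_model(t, y)
    if model == "line":
        return fit_line(t, y, direction)
    return fit_double_sigmoidal(t, y, direction)


def om_phase_fits(record: ExperimentRecord, phase: str) -> list[OmFit]:
    """Fits for every optomotor period of one phase ("before"/"after")."""
    periods = record.schedule.om_periods(phase)
    if not periods:
        raise UnsupportedProtocolError(
            f"{record.schedule.setup!r} record has no stored optomotor periods"
        )
    fits = []
    for p in periods:
        sl = record.period_slice(p.index)
        start, _ = record.schedule.period_bounds(p.index)
        t = sl["t_s"].to_numpy(dtype=float) - start
        y = sl["torque"].to_numpy(dtype=float)
        fits.append(fit_om_trace(t, y, p.om_direction))
    return fits


def magnitudes_from_fits(fits: list[OmFit]) -> tuple[float, float]:
    """(right_mag, left_mag) from per-period fits.

    right_mag averages the clockwise periods' magnitudes, left_mag the
    counterclockwise ones, each rectified to its direction-congruent
    sign (clockwise stimuli should give positive torque, counter-
    clockwise negative); a wrong-signed response contributes 0.
    """
    cw = [max(0.0, f.magnitude) for f in fits if f.direction is OmDirection.CLOCKWISE]
    ccw = [
        max(0.0, -f.magnitude)
        for f in fits
        if f.direction is OmDirection.COUNTERCLOCKWISE
    ]
    if not cw or not ccw:
        raise UnsupportedProtocolError("phase lacks periods for one direction")
    return float(np.mean(cw)), float(np.mean(ccw))


def om_magnitudes(record: ExperimentRecord, phase: str) -> tuple[float, float]:
    """(right_mag, left_mag) for one phase ("before"/"after")."""
    return magnitudes_from_fits(om_phase_fits(record, phase))


def asymmetry_index(right_mag: float, left_mag: float) -> float:
    """(R - L) / (R + L) on non-negative magnitudes.

    +1 when only the clockwise (right-turning) response remains, -1 when
    only the counterclockwise one does, 0 for equal magnitudes.
    """
    if right_mag < 0 or left_mag < 0:
        raise ValueError("magnitudes must be non-negative absolute values")
    total = right_mag + left_mag
    if total == 0:
        raise UndefinedIndexError("both optomotor magnitudes are zero (no OMR)")
    return (right_mag - left_mag) / total


def adjust_sign(raw: float, punished_domain: Domain | str) -> float:
    """Orient the index so positive = shifted toward the unpunished domain."""
    punished = Domain(punished_domain)
    return raw if punished is Domain.LEFT else -raw


def om_analysis(
    record: ExperimentRecord, fits_by_phase: dict[str, list[OmFit]] | None = None
) -> dict:
    """Per-phase fits, magnitudes and asymmetry indices for one fly.

    Returns a dict with keys "before" and "after", each holding the
    fits, (right_mag, left_mag), and the raw and adjusted indices.
    Precomputed fits may be passed to avoid refitting.
    """
    out = {}
    for phase in ("before", "after"):
        if fits_by_phase is not None and phase in fits_by_phase:
            fits = fits_by_phase[phase]
        else:
            fits = om_phase_fits(record, phase)
        right, left = magnitudes_from_fits(fits)
        try:
            raw = asymmetry_index(right, left)
            adjusted = adjust_sign(raw, record.punished_domain)
        except UndefinedIndexError:
            raw = adjusted = float("nan")
        out[phase] = {
            "fits": fits,
            "right_mag": right,
            "left_mag": left,
            "raw": raw,
            "adjusted": adjusted,
        }
    return out
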