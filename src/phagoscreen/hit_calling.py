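"""Compound classification and dose-response fitting.

Each compound is screened in singlicate at a five-point dose ladder
(1.39, 2.78, 5.56, 11.11, 22.22 µM).  Classification follows the screen's
decision rules: only doses strictly above the 5 µM gate are evaluated; a
toxic well at a qualifying dose makes the compound toxic; otherwise percent
phagocytosis below 70 (above 130) at a qualifying dose in (5, 20] µM calls a
decrease (increase), and crossings confined to doses above 20 µM fall in the
"_gt20" sub-categories.  Dose-response curves are summarised by a
four-parameter logistic (4PL) fit with the EC50 on a log-dose scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InsufficientDataError, ValidationError
from .plate_screen import ScreenThresholds

CALL_CATEGORIES = (
    "increase",
    "increase_gt20",
    "decrease",
    "decrease_gt20",
    "no_effect",
    "toxic",
)


@dataclass(frozen=True)
class CompoundDoseSeries:
    """One compound's singlicate dose series.

    ``points`` holds (concentration_um, pct_phagocytosis, toxic) tuples sorted
    by strictly increasing concentration.
    """

    compound_id: str
    points: tuple

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValidationError("dose series needs at least one point")
        concs = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValidationError("concentrations must be strictly increasing")


@dataclass(frozen=True)
class HillFit:
    bottom: float
    top: float
    ec50_um: float
    hill_slope: float
    sse: float
    converged: bool


@dataclass(frozen=True)
class CompoundCall:
    compound_id: str
    call: str
    supporting_doses: tuple = ()
    conflict: bool = False
    note: str = ""
    fit: HillFit | None = field(default=None, compare=False)


def classify_compound(
    series: CompoundDoseSeries, thresholds: ScreenThresholds | None = None
) -> CompoundCall:
    """Classify one dose series into the six screen categories.

    Only points above the dose gate matter; toxicity there takes precedence
    over direction.  If both a <70 and a >130 crossing occur (a conflicting
    series), the direction of the highest crossing dose wins and the
    ``conflict`` flag is set.
    """
    thresholds = thresholds or ScreenThresholds()
    gate, high = thresholds.dose_gate_um, thresholds.high_dose_um
    lo, hi = thresholds.decrease_cut_pct, thresholds.increase_cut_pct

    qualifying = [p for p in series.points if p[0] > gate]
    if not qualifying:
        return CompoundCall(series.compound_id, "no_effect", note="no-qualifying-dose")
    if any(p[2] for p in qualifying):
        return CompoundCall(series.compound_id, "toxic")

    down = [c for c, pct, _ in qualifying if pct < lo]
    up = [c for c, pct, _ in qualifying if pct > hi]
    conflict = bool(down) and bool(up)
    if conflict:
        # direction of the highest crossing dose wins
        direction = "decrease" if max(down) > max(up) else "increase"
        crossings = down if direction == "decrease" else up
    elif down:
        direction, crossings = "decrease", down
    elif up:
        direction, crossings = "increase", up
    else:
        return CompoundCall(series.compound_id, "no_effect")

    call = direction if any(c <= high for c in crossings) else f"{direction}_gt20"
    return CompoundCall(
        series.compound_id, call, supporting_doses=tuple(sorted(crossings)),
        conflict=conflict,
    )


def series_from_normalized(normalized: pd.DataFrame, aggregate: str | None = None):
    """Yield a CompoundDoseSeries per compound from a normalized well table.

    The screen is singlicate; duplicate (compound, dose) rows raise a
    :class:`ValidationError` unless ``aggregate="median"`` is given.
    """
    data = normalized[(normalized["role"] == "data") & (normalized["compound_id"] != "")]
    for compound_id, grp in data.groupby("compound_id", sort=True):
        if grp["concentration_um"].duplicated().any():
            if aggregate != "median":
                raise ValidationError(
                    f"duplicate dose rows for compound {compound_id!r}; "
                    "singlicate expected (pass aggregate='median' to collapse)"
                )
            grp = (
                grp.groupby("concentration_um", as_index=False)
                .agg({"pct_phagocytosis": "median", "toxic": "max"})
            )
        grp = grp.sort_values("concentration_um")
        points = tuple(
            (float(c), float(p), bool(t))
            for c, p, t in zip(
                grp["concentration_um"], grp["pct_phagocytosis"], grp["toxic"]
            )
        )
        yield CompoundDoseSeries(str(compound_id), points)


def classify_screen(
    normalized: pd.DataFrame,
    thresholds: ScreenThresholds | None = None,
    aggregate: str | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every compound of a normalized screen.

    Returns a call table (one row per compound) and the category counts over
    the six classes.  Deterministic given the input: compounds are processed
    in sorted id order and the result does not depend on input row order.
    """
    calls = [
        classify_compound(s, thresholds)
        for s in series_from_normalized(normalized, aggregate=aggregate)
    ]
    table = pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in calls],
            "call": [c.call for c in calls],
            "supporting_doses": [
                ";".join(f"{d:g}" for d in c.supporting_doses) for c in calls
            ],
            "conflict": [c.conflict for c in calls],
        }
    )
    counts = (
        table["call"].value_counts().reindex(CALL_CATEGORIES, fill_value=0)
    )
    return table, counts


def four_param_logistic(conc, bottom, top, ec50, slope):
    """4PL response: ``bottom + (top - bottom) / (1 + (conc/ec50)**slope)``.

    With ``slope > 0`` the curve falls from ``top`` (low dose) to ``bottom``;
    negative slopes give rising curves.
    """
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ec50) ** slope)


def fit_dose_response(
    series: CompoundDoseSeries,
    baseline: float | None = None,
    fix_slope: float | None = None,
    loss: str = "linear",
) -> HillFit:
    """Least-squares 4PL fit of percent phagocytosis against dose.

    Uses non-toxic points only (at least four required), fits on a log-dose
    scale with the EC50 constrained to [min_dose/100, max_dose*100], and
    multi-starts over both slope signs and several EC50 guesses.  Optimizer
    failure is reported as ``converged=False`` rather than raised.

    A free four-parameter fit is weakly identified on a five-point singlicate
    ladder, so two constraints are available for percent-normalized screen
    data: ``baseline`` anchors the zero-dose asymptote (100 for
    percent-of-median responses, since untreated wells sit at 100 by
    construction) and ``fix_slope`` pins the Hill slope magnitude (1 is the
    standard-slope fit).  ``loss="log"`` minimizes residuals of log response,
    matching multiplicative (lognormal) intensity noise.  The reported
    ``sse`` is always on the linear response scale.
    """
    if loss not in ("linear", "log"):
        raise ValidationError(f"unknown loss: {loss!r}")
    pts = [(c, p) for c, p, t in series.points if not t]
    if len(pts) < 4:
        raise InsufficientDataError(
            f"compound {series.compound_id!r}: {len(pts)} usable points, need >= 4"
        )
    conc = np.array([c for c, _ in pts])
    pct = np.array([p for _, p in pts])

    lo_ec, hi_ec = conc.min() / 100.0, conc.max() * 100.0
    p_min, p_max = float(pct.min()), float(pct.max())
    span = max(p_max - p_min, 1.0)
    mid = 0.5 * (p_min + p_max)
    ec_starts = {float(conc[np.argmin(np.abs(pct - mid))])}
    ec_starts.update(float(c) for c in conc[1:-1])

    def _params(theta, sign):
        """Unpack the active parametrization into (bottom, top, ec50, slope)."""
        i = 0
        if baseline is None:
            bottom, top = theta[0], theta[1]
            i = 2
        else:
            # anchored zero-dose asymptote: top for falling, bottom for rising
            other = theta[0]
            i = 1
            bottom, top = (other, baseline) if sign > 0 else (baseline, other)
        ec50 = 10.0 ** theta[i]
        slope = sign * (fix_slope if fix_slope is not None else abs(theta[i + 1]))
        return bottom, top, ec50, slope

    def _resid(theta, sign):
        f = four_param_logistic(conc, *_params(theta, sign))
        if loss == "log":
            return np.log(np.maximum(f, 1e-9)) - np.log(np.maximum(pct, 1e-9))
        return f - pct

    best, best_sse, best_sign = None, np.inf, 1.0
    for sign in (1.0, -1.0):
        lo = [np.log10(lo_ec)]
        hi = [np.log10(hi_ec)]
        if baseline is None:
            lo = [p_min - 10 * span - 1] * 2 + lo
            hi = [p_max + 10 * span + 1] * 2 + hi
            base0 = [p_min, p_max]
        else:
            lo = [min(0.0, p_min - span)] + lo
            hi = [p_max + 10 * span + 1] + hi
            base0 = [p_min if sign > 0 else p_max]
        if fix_slope is None:
            lo, hi = lo + [0.05], hi + [20.0]
        for ec0 in sorted(ec_starts):
            theta0 = base0 + [np.log10(min(max(ec0, lo_ec), hi_ec))]
            if fix_slope is None:
                theta0 = theta0 + [1.0]
            try:
                res = least_squares(
                    _resid, theta0, args=(sign,), bounds=(lo, hi), max_nfev=20000
                )
            except (RuntimeError, ValueError):
                continue
            bottom, top, ec50, slope = _params(res.x, sign)
            lin = four_param_logistic(conc, bottom, top, ec50, slope) - pct
            sse = float(lin @ lin)
            obj = 2.0 * res.cost if loss == "log" else sse
            if obj < best_sse:
                best, best_sse, best_sign = (bottom, top, ec50, slope, sse), obj, sign
    if best is None:
        return HillFit(np.nan, np.nan, np.nan, np.nan, np.inf, converged=False)
    bottom, top, ec50, slope, sse = best
    return HillFit(
        bottom=float(bottom),
        top=float(top),
        ec50_um=float(ec50),
        hill_slope=float(slope),
        sse=sse,
        converged=True,
    )


@dataclass(frozen=True)
class Timecourse:
    """Hourly phagocytosis signal at one dose (``dose_um=0`` for vehicle)."""

    hours: tuple
    signal: tuple
    dose_um: float

    def __post_init__(self) -> None:
        if len(self.hours) != len(self.signal):
            raise ValidationError("hours and signal must have the same length")
        if any(b <= a for a, b in zip(self.hours, self.hours[1:])):
            raise ValidationError("hours must be strictly increasing")


def timecourse_auc(tc: Timecourse, vehicle: Timecourse) -> float:
    """Trapezoidal AUC of a dose time-course as a percent of the vehicle AUC."""
    if tuple(tc.hours) != tuple(vehicle.hours):
        raise ValidationError("time grids of dose and vehicle series differ")
    auc = float(np.trapezoid(tc.signal, tc.hours))
    auc_v = float(np.trapezoid(vehicle.signal, vehicle.hours))
    if auc_v == 0.0:
        raise ZeroDivisionError("vehicle AUC is zero")
    return 100.0 * auc / auc_v
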