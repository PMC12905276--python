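"""Dose-response fitting and ZIP synergy scoring for drug combinations.

Monotherapy curves are modeled as four-parameter logistics (4PL)

    y(x) = bottom + (top - bottom) / (1 + (IC50 / x)^h)

on the inhibition scale.  For a two-drug dose matrix, the zero
interaction potency (ZIP) reference response at dose pair (x1, x2) is
``y1 + y2 - y1*y2`` on fractional inhibition — the effect expected if the
drugs act independently.  The synergy delta at each dose pair is the
observed response minus that expectation, in percentage points; its mean
over the positive-dose cells is the summary synergy score, the maximal
windowed mean is the most-synergistic-area (MSA) score, and the mean
observed inhibition is the efficacy volume.

The ZIP reference here is computed from the fitted monotherapy margins
only (the zero-dose row and column), not from re-fitting every row and
column of the combination matrix as the full potency-shift procedure
does; for matrices generated under the ZIP null plus an additive bonus
the two coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseFit",
    "DoseResponseMatrix",
    "SynergyResult",
    "normalize_viability",
    "four_pl",
    "fit_dose_response",
    "zip_delta",
    "most_synergistic_area",
    "efficacy_volume",
]


def four_pl(x, bottom: float, top: float, ic50: float, hill: float):
    """Four-parameter logistic response; defined as ``bottom`` at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, bottom, dtype=float)
    pos = x > 0
    out[pos] = bottom + (top - bottom) / (1.0 + (ic50 / x[pos]) ** hill)
    return out


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted monotherapy curve with IC50/AUC summaries.

    ``degraded`` marks fits that fell back to monotone log-dose
    interpolation (the 4PL optimizer failed) and ``flat`` marks constant
    responses whose IC50 is undefined.
    """

    bottom: float
    top: float
    ic50: float
    hill: float
    auc: float
    doses: tuple[float, ...]
    responses: tuple[float, ...]
    degraded: bool = False
    flat: bool = False

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.flat:
            return np.full_like(x, self.bottom, dtype=float)
        if self.degraded:
            logd = np.log10(np.asarray(self.doses))
            resp = np.asarray(self.responses)
            out = np.empty_like(x, dtype=float)
            pos = x > 0
            out[pos] = np.interp(np.log10(x[pos]), logd, resp)
            out[~pos] = resp[0] if len(resp) else 0.0
            return out
        return four_pl(x, self.bottom, self.top, self.ic50, self.hill)


def normalize_viability(raw: Sequence[float], controls: Sequence[float]) -> np.ndarray:
    """Percent viability relative to the mean of control wells."""
    controls = np.asarray(controls, dtype=float)
    if controls.size == 0:
        raise ValueError("at least one control well is required")
    mean_control = controls.mean()
    if mean_control <= 0:
        raise ValueError("mean control readout must be positive")
    return 100.0 * np.asarray(raw, dtype=float) / mean_control


def _auc_log_dose(doses: np.ndarray, responses: np.ndarray) -> float:
    """Trapezoid AUC of response over normalized log10-dose in [0, 1]."""
    if len(doses) < 2:
        return 0.0
    logd = np.log10(doses)
    span = logd[-1] - logd[0]
    if span <= 0:
        return 0.0
    return float(np.trapezoid(responses, (logd - logd[0]) / span))


def fit_dose_response(doses: Sequence[float], inhibition: Sequence[float]) -> DoseResponseFit:
    """Least-squares 4PL fit of an inhibition curve.

    Zero doses are excluded from the fit; at least 4 distinct positive
    doses are required.  Starting values are bottom=min, top=max,
    IC50=median dose, h=1, with the Hill slope bounded to [0.1, 10].  If
    the optimizer fails, the fit degrades to monotone linear
    interpolation on log-dose (flagged); an all-equal response yields a
    flat fit with undefined (NaN) IC50.
    """
    doses = np.asarray(doses, dtype=float)
    inhibition = np.asarray(inhibition, dtype=float)
    if doses.shape != inhibition.shape:
        raise ValueError("doses and responses must have equal length")
    pos = doses > 0
    x, y = doses[pos], inhibition[pos]
    order = np.argsort(x)
    x, y = x[order], y[order]
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct positive doses")

    auc = _auc_log_dose(x, y)
    if np.allclose(y, y[0]):
        return DoseResponseFit(bottom=float(y[0]), top=float(y[0]), ic50=float("nan"),
                               hill=float("nan"), auc=auc, doses=tuple(x),
                               responses=tuple(y), flat=True)

    span = y.max() - y.min()
    p0 = [y.min(), y.max(), float(np.exp(np.median(np.log(x)))), 1.0]
    lower = [y.min() - 2 * span, y.min() - 2 * span, x.min() / 1e4, 0.1]
    upper = [y.max() + 2 * span, y.max() + 2 * span, x.max() * 1e4, 10.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda xx, b, t, i, h: four_pl(xx, b, t, i, h),
                x, y, p0=p0, bounds=(lower, upper), maxfev=20000,
            )
        bottom, top, ic50, hill = (float(v) for v in popt)
        if not np.isfinite([bottom, top, ic50, hill]).all():
            raise RuntimeError("non-finite fit")
        return DoseResponseFit(bottom=bottom, top=top, ic50=ic50, hill=hill,
                               auc=auc, doses=tuple(x), responses=tuple(y))
    except (RuntimeError, ValueError):
        # degrade to monotone interpolation on log-dose; still exact at
        # the measured doses, so downstream deltas remain usable
        return DoseResponseFit(bottom=float(y[0]), top=float(y[-1]), ic50=float("nan"),
                               hill=float("nan"), auc=auc, doses=tuple(x),
                               responses=tuple(y), degraded=True)


@dataclass(frozen=True)
class DoseResponseMatrix:
    """Two-drug percent-viability grid including zero-dose margins."""

    doses1: tuple[float, ...]
    doses2: tuple[float, ...]
    viability: np.ndarray  # percent, rows = drug-1 doses, cols = drug-2 doses

    def __post_init__(self) -> None:
        d1, d2 = np.asarray(self.doses1), np.asarray(self.doses2)
        if (np.diff(d1) <= 0).any() or (np.diff(d2) <= 0).any():
            raise ValueError("dose grids must be strictly increasing")
        if d1[0] != 0 or d2[0] != 0:
            raise ValueError("dose grids must start at 0 (control margins)")
        if self.viability.shape != (len(d1), len(d2)):
            raise ValueError("viability shape does not match dose grids")

    @property
    def inhibition(self) -> np.ndarray:
        """Percent inhibition, clipped to [0, 100]."""
        return np.clip(100.0 - self.viability, 0.0, 100.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.viability, index=list(self.doses1),
                            columns=list(self.doses2))

    def transposed(self) -> "DoseResponseMatrix":
        return DoseResponseMatrix(doses1=self.doses2, doses2=self.doses1,
                                  viability=self.viability.T)


@dataclass(frozen=True)
class SynergyResult:
    """Per-cell ZIP deltas with summary synergy statistics.

    ``delta`` covers the strictly positive dose cells (percentage
    points); ``mean_delta`` is the overall synergy score, ``msa`` the
    most-synergistic-area score, and ``efficacy_volume`` the mean percent
    inhibition over the same cells.
    """

    delta: pd.DataFrame
    mean_delta: float
    msa: float
    efficacy_volume: float
    fit1: DoseResponseFit = field(repr=False, default=None)
    fit2: DoseResponseFit = field(repr=False, default=None)


def zip_delta(matrix: DoseResponseMatrix, msa_window: int = 3) -> SynergyResult:
    """ZIP synergy delta of a combination matrix.

    The zero-dose margins give each drug's monotherapy curve, fitted by
    4PL on fractional inhibition.  The ZIP expectation at dose pair
    (i, j) is ``y1(i) + y2(j) - y1(i)*y2(j)``; the per-cell delta is
    ``100 * (observed - expected)``.
    """
    inh = matrix.inhibition / 100.0
    d1 = np.asarray(matrix.doses1)
    d2 = np.asarray(matrix.doses2)
    fit1 = fit_dose_response(d1, inh[:, 0])
    fit2 = fit_dose_response(d2, inh[0, :])

    pos1, pos2 = d1[1:], d2[1:]
    y1 = fit1.predict(pos1)
    y2 = fit2.predict(pos2)
    expected = y1[:, None] + y2[None, :] - y1[:, None] * y2[None, :]
    observed = inh[1:, 1:]
    delta = 100.0 * (observed - expected)
    delta_frame = pd.DataFrame(delta, index=list(pos1), columns=list(pos2))
    if min(delta.shape) >= msa_window:
        msa = most_synergistic_area(delta_frame, window=msa_window)
    else:
        msa = float(delta.mean())
    return SynergyResult(
        delta=delta_frame,
        mean_delta=float(delta.mean()),
        msa=msa,
        efficacy_volume=float((100.0 * observed).mean()),
        fit1=fit1,
        fit2=fit2,
    )


def most_synergistic_area(delta, window: int = 3) -> float:
    """Maximal mean delta over contiguous window x window dose blocks."""
    d = np.asarray(delta, dtype=float)
    if d.ndim != 2:
        raise ValueError("delta must be a 2-D matrix")
    n1, n2 = d.shape
    if n1 < window or n2 < window:
        raise ValueError(f"delta matrix {d.shape} smaller than window {window}")
    best = -np.inf
    for i in range(n1 - window + 1):
        for j in range(n2 - window + 1):
            best = max(best, d[i:i + window, j:j + window].mean())
    return float(best)


def efficacy_volume(matrix: DoseResponseMatrix) -> float:
    """Mean percent inhibition over all strictly positive dose cells."""
    inh = matrix.inhibition
    if inh[1:, 1:].size == 0:
        raise ValueError("matrix has no positive-dose cells")
    return float(inh[1:, 1:].mean())
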