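"""Assay analysis: uptake ratios, growth, clonogenic survival, ROS, IC50.

Operates on small tidy tables (pandas DataFrames) matching the CSV schemas
emitted by :mod:`celldose.synth` and by plate readers / ICP-MS exports:

* uptake records: columns ``element`` (B/Fe), ``compartment``
  (cytoplasm/nucleus), ``amount_ng_per_1e6_cells``, ``group``, ``replicate``;
* dose–response: ``concentration_um``, ``viability``, ``replicate``;
* kinetics: ``time_h``, ``value``, ``replicate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AlignmentError, FitError, InvalidArgumentError

ATOMIC_MASS_B = 10.811
ATOMIC_MASS_FE = 55.845
#: boron atoms per ferrabis(dicarbollide) anion [3,3'-Fe(1,2-C2B9H11)2]-
BORON_PER_ANION = 18
#: stoichiometric B:Fe mass ratio of the intact compound
STOICHIOMETRIC_B_FE_MASS_RATIO = BORON_PER_ANION * ATOMIC_MASS_B / ATOMIC_MASS_FE


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half away from zero."""
    x = float(x)
    if x == 0:
        return 0.0
    from decimal import Decimal, ROUND_HALF_UP
    exponent = math.floor(math.log10(abs(x)))
    quant = Decimal(1).scaleb(exponent - sig + 1)
    return float(Decimal(repr(x)).quantize(quant, rounding=ROUND_HALF_UP))


def fold_change(treated_mean: float, control_mean: float) -> tuple[float, float]:
    """Treated/control ratio; returns (raw ratio, 2-significant-figure report)."""
    if control_mean == 0:
        raise ZeroDivisionError("control mean is zero")
    if control_mean < 0 or treated_mean < 0:
        raise InvalidArgumentError("means must be non-negative")
    raw = treated_mean / control_mean
    return raw, round_sig(raw, 2)


def b_fe_ratio(records: pd.DataFrame) -> dict:
    """Measured B:Fe mass ratio per compartment vs the compound stoichiometry.

    Returns ``{"ratios": {compartment: ratio}, "theoretical": 3.4845...,
    "molar_theoretical": 18}``.  Raises KeyError naming the compartment when
    either element is missing.
    """
    ratios = {}
    for compartment, sub in records.groupby("compartment"):
        means = sub.groupby("element")["amount_ng_per_1e6_cells"].mean()
        for el in ("B", "Fe"):
            if el not in means.index:
                raise KeyError(f"no {el} records for compartment {compartment!r}")
        ratios[compartment] = float(means["B"] / means["Fe"])
    return {"ratios": ratios,
            "theoretical": STOICHIOMETRIC_B_FE_MASS_RATIO,
            "molar_theoretical": float(BORON_PER_ANION)}


@dataclass(frozen=True)
class GrowthCurve:
    times_days: np.ndarray
    values: np.ndarray      # protein-equivalent cell quantity, a.u.

    def __post_init__(self) -> None:
        t = np.asarray(self.times_days, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_days", t)
        object.__setattr__(self, "values", v)
        if len(t) != len(v) or len(t) < 1:
            raise InvalidArgumentError("times and values must match, length >= 1")
        if np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if v[0] <= 0:
            raise InvalidArgumentError("initial quantity must be positive")


def growth_rate(curve: GrowthCurve, ti: float) -> float:
    """Percent growth relative to the first time point: (N(ti)-N(t0))/N(t0)×100."""
    matches = np.flatnonzero(np.isclose(curve.times_days, ti))
    if len(matches) == 0:
        raise KeyError(f"time point {ti} not sampled")
    n_t = curve.values[matches[0]]
    n_0 = curve.values[0]
    return (n_t - n_0) / n_0 * 100.0


@dataclass(frozen=True)
class SurvivalResult:
    fraction: float
    clipped: bool           # True when the raw estimate exceeded 1


def survival_fraction(colonies: int, seeded: int,
                      plating_efficiency_control: float) -> SurvivalResult:
    """Clonogenic survival: colonies / (seeded × control plating efficiency)."""
    if seeded <= 0:
        raise InvalidArgumentError("seeded must be positive")
    if not 0.0 < plating_efficiency_control <= 1.0:
        raise InvalidArgumentError("plating efficiency must be in (0, 1]")
    if colonies < 0:
        raise InvalidArgumentError("colony count must be >= 0")
    raw = colonies / (seeded * plating_efficiency_control)
    return SurvivalResult(fraction=raw, clipped=raw > 1.0)


def ros_fold(treated: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Pointwise fold change of fluorescence means with delta-method SD.

    Both inputs need columns ``time_h`` and ``value`` (replicates as repeated
    times); the time grids must coincide exactly.
    """
    gt = treated.groupby("time_h")["value"]
    gr = reference.groupby("time_h")["value"]
    t_grid = gt.mean().index.to_numpy()
    r_grid = gr.mean().index.to_numpy()
    if len(t_grid) != len(r_grid) or not np.allclose(t_grid, r_grid):
        raise AlignmentError("treated and reference time grids differ")
    m_t, m_r = gt.mean().to_numpy(), gr.mean().to_numpy()
    n_t, n_r = gt.count().to_numpy(), gr.count().to_numpy()
    v_t = np.nan_to_num(gt.var(ddof=1).to_numpy()) / n_t
    v_r = np.nan_to_num(gr.var(ddof=1).to_numpy()) / n_r
    ratio = m_t / m_r
    sd = np.sqrt(v_t / m_r ** 2 + (m_t ** 2 / m_r ** 4) * v_r)
    return pd.DataFrame({"time_h": t_grid, "fold_change": ratio, "sd": sd})


# --- IC50 -------------------------------------------------------------------

def four_pl(c, bottom, top, ic50, slope):
    """4-parameter logistic viability model, decreasing with concentration."""
    return bottom + (top - bottom) / (1.0 + (np.asarray(c) / ic50) ** slope)


@dataclass
class DoseResponse:
    concentrations_um: np.ndarray
    viability: np.ndarray
    bottom: float
    top: float
    ic50: float
    slope: float
    ic50_ci: tuple[float, float]
    covariance: np.ndarray = field(repr=False, default=None)


def fit_ic50(data: pd.DataFrame, confidence: float = 0.95) -> DoseResponse:
    """Fit a four-parameter logistic and return IC50 with a confidence interval.

    Weighted least squares on the replicate-level data (curve_fit); the CI is
    the t-interval from the parameter covariance on log(IC50).  Raises
    :class:`FitError` for non-convergence or for data whose viability
    *increases* with concentration (no IC50 exists).
    """
    c = data["concentration_um"].to_numpy(dtype=float)
    v = data["viability"].to_numpy(dtype=float)
    if len(np.unique(c)) < 5:
        raise InvalidArgumentError("need >= 5 distinct concentrations")
    rho = stats.spearmanr(np.log(c), v).statistic
    if rho > 0.5:
        raise FitError("viability increases with concentration; no IC50")

    def model(x, bottom, top, log_ic50, slope):
        return four_pl(x, bottom, top, math.exp(log_ic50), slope)

    p0 = [float(np.min(v)), float(np.max(v)),
          float(np.log(np.median(c))), 1.0]
    try:
        popt, pcov = optimize.curve_fit(
            model, c, v, p0=p0, maxfev=20000,
            bounds=([-0.5, 0.0, math.log(np.min(c) / 100.0), 0.05],
                    [1.5, 2.0, math.log(np.max(c) * 100.0), 20.0]))
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"4PL fit failed: {exc}") from exc
    bottom, top, log_ic50, slope = popt
    if bottom >= top:
        raise FitError("degenerate fit: bottom >= top")
    dof = max(len(c) - 4, 1)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, dof)
    se_log = math.sqrt(max(pcov[2, 2], 0.0))
    ci = (math.exp(log_ic50 - tcrit * se_log),
          math.exp(log_ic50 + tcrit * se_log))
    return DoseResponse(c, v, float(bottom), float(top),
                        float(math.exp(log_ic50)), float(slope), ci, pcov)
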