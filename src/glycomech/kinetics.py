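"""Transition-state-theory conversions and Michaelis-Menten kinetics.

The Eyring-Polanyi expression k = (k_B T / h) exp(-dG/RT) links a
first-order rate constant to the activation free energy, assuming a
transmission coefficient of one (recrossing, tunneling and nonequilibrium
effects neglected).  Constants are CODATA 2018; energies are kcal/mol.

Michaelis-Menten parameters are fitted by nonlinear least squares on
v = kcat * S / (Km + S) with initial guesses from a Hanes-Woolf
linearization; standard errors come from the fit covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "R_KCAL",
    "KB_OVER_H",
    "EyringResult",
    "RateMeasurement",
    "MMParams",
    "KineticsError",
    "eyring_barrier",
    "eyring_rate",
    "mm_fit",
    "efficiency",
    "relative_activity",
    "celsius_to_kelvin",
    "round_sig",
]

# CODATA 2018
R_KCAL = 1.98720425864083e-3          # kcal / (mol K)
_KB = 1.380649e-23                    # J/K (exact, SI 2019)
_H = 6.62607015e-34                   # J s (exact)
KB_OVER_H = _KB / _H                  # 1/(s K): prefactor is KB_OVER_H * T


class KineticsError(ValueError):
    pass


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


@dataclass(frozen=True)
class EyringResult:
    dG: float          # kcal/mol
    prefactor: float   # k_B T / h, 1/s
    k: float           # input rate constant, 1/s
    T: float           # K


@dataclass(frozen=True)
class RateMeasurement:
    substrate_conc: float   # mM
    velocity: float         # 1/s (or specific-activity units, used as given)

    def __post_init__(self):
        if self.substrate_conc < 0 or self.velocity < 0:
            raise KineticsError("concentrations and velocities must be >= 0")


@dataclass(frozen=True)
class MMParams:
    Km: float
    Km_se: float
    kcat: float
    kcat_se: float
    n_obs: int = 0
    Km_ci95: float = float("nan")    # half-width, t-based with n-2 dof
    kcat_ci95: float = float("nan")
    converged: bool = True
    wide_Km_flag: bool = False   # set when the data poorly constrain Km

    @property
    def efficiency(self) -> float:
        return self.kcat / self.Km


def eyring_barrier(k: float, T: float) -> EyringResult:
    """Activation free energy dG = RT ln(k_B T / (h k)) in kcal/mol.

    Transmission coefficient is fixed at 1.  For the wild-type hydrolysis
    rate k = 36.1 1/s at 333.15 K (60 C) this gives 17.2 kcal/mol.
    """
    if k <= 0 or T <= 0:
        raise KineticsError("rate constant and temperature must be positive")
    pref = KB_OVER_H * T
    dG = R_KCAL * T * math.log(pref / k)
    return EyringResult(dG=dG, prefactor=pref, k=k, T=T)


def eyring_rate(dG: float, T: float) -> float:
    """Rate constant k = (k_B T / h) exp(-dG / RT); exact inverse of
    :func:`eyring_barrier`."""
    if T <= 0:
        raise KineticsError("temperature must be positive")
    return KB_OVER_H * T * math.exp(-dG / (R_KCAL * T))


def _hanes_woolf_guess(S: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Initial (Km, kcat) from the S/v vs S line; robust fallbacks if the
    slope or intercept comes out nonpositive."""
    mask = v > 0
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(S[mask], S[mask] / v[mask], 1)
        if slope > 0 and intercept > 0:
            return intercept / slope, 1.0 / slope
    return float(np.median(S)), float(v.max()) if v.max() > 0 else 1.0


def mm_fit(data: Sequence[RateMeasurement],
           weighting: str = "relative") -> MMParams:
    """Nonlinear least-squares Michaelis-Menten fit.

    Requires at least 4 distinct substrate concentrations.  The default
    ``weighting="relative"`` assumes errors proportional to the velocity
    (the classical 1/v^2 weighting of enzyme kinetics, appropriate for
    initial-rate assays whose error scales with the signal);
    ``weighting="none"`` fits unweighted.  Standard errors come from the
    fit covariance (residual-scaled), and the 95% confidence half-widths
    use the t distribution with n-2 degrees of freedom.

    If the fitted Km exceeds the largest measured concentration (all
    points effectively saturating), the Km is poorly identified and the
    result carries ``wide_Km_flag``.
    """
    S = np.array([d.substrate_conc for d in data], float)
    v = np.array([d.velocity for d in data], float)
    if len(np.unique(S)) < 4:
        raise KineticsError("need >= 4 distinct substrate concentrations")
    if weighting not in ("relative", "none"):
        raise KineticsError(f"unknown weighting {weighting!r}")

    def model(s, kcat, km):
        return kcat * s / (km + s)

    kw = {}
    if weighting == "relative" and np.all(v > 0):
        kw = {"sigma": v, "absolute_sigma": False}
    km0, kcat0 = _hanes_woolf_guess(S, v)
    guesses = [(kcat0, km0), (v.max(), np.median(S)), (v.max(), S.max())]
    last_exc: Exception | None = None
    for g in guesses:
        try:
            popt, pcov = curve_fit(model, S, v, p0=g,
                                   bounds=([0, 0], [np.inf, np.inf]),
                                   maxfev=20000, **kw)
            kcat, km = popt
            se = np.sqrt(np.diag(pcov))
            dof = max(len(S) - 2, 1)
            tq = float(stats.t.ppf(0.975, dof))
            wide = bool(km > S.max() or se[1] > km)
            return MMParams(Km=float(km), Km_se=float(se[1]),
                            kcat=float(kcat), kcat_se=float(se[0]),
                            n_obs=len(S),
                            Km_ci95=float(tq * se[1]),
                            kcat_ci95=float(tq * se[0]),
                            converged=True, wide_Km_flag=wide)
        except (RuntimeError, ValueError) as exc:
            last_exc = exc
    raise KineticsError(f"Michaelis-Menten fit failed to converge: {last_exc}")


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def efficiency(p: MMParams, sig_figs: int = 3) -> float:
    """Catalytic efficiency kcat/Km, rounded to ``sig_figs`` significant
    figures (3 matches common table conventions)."""
    return round_sig(p.kcat / p.Km, sig_figs)


def relative_activity(table: pd.DataFrame,
                      reference_substrate: str,
                      wild_type: str | None = None,
                      sig_figs: int = 2) -> pd.DataFrame:
    """Percent-of-reference and fold-reduction bookkeeping for an activity table.

    ``table`` needs columns (enzyme, substrate, activity).  For each enzyme,
    percent = 100 * activity / activity(reference_substrate), so the
    reference row is exactly 100%.  If ``wild_type`` names an enzyme,
    fold_reduction = wild-type activity / enzyme activity on the same
    substrate.  Rounded columns (percent, fold_reduction) sit alongside the
    raw ones (percent_raw, fold_reduction_raw).
    """
    req = {"enzyme", "substrate", "activity"}
    if not req.issubset(table.columns):
        raise KineticsError(f"activity table needs columns {sorted(req)}")
    out = table.copy()
    ref = (table[table.substrate == reference_substrate]
           .set_index("enzyme")["activity"])
    missing = set(table.enzyme) - set(ref.index)
    if missing:
        raise KineticsError(
            f"no {reference_substrate!r} reference row for enzymes {sorted(missing)}")
    if (ref <= 0).any():
        raise KineticsError("zero or negative reference activity")
    out["percent_raw"] = 100.0 * out.activity / out.enzyme.map(ref)
    out["percent"] = out.percent_raw.map(lambda x: round_sig(x, sig_figs))
    if wild_type is not None:
        wt = (table[table.enzyme == wild_type]
              .set_index("substrate")["activity"])
        out["fold_reduction_raw"] = out.substrate.map(wt) / out.activity
        out.loc[out.enzyme == wild_type, "fold_reduction_raw"] = 1.0
        out["fold_reduction"] = out.fold_reduction_raw.map(
            lambda x: round_sig(x, sig_figs))
    return out
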