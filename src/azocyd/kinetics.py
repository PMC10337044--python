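"""First-order thermal relaxation, photostationary-state composition,
switching-fatigue metrics and van't Hoff thermodynamics.

The metastable Z-azobenzene reverts thermally to E with first-order
kinetics; monitoring the pi->pi* absorption band gives
``I(t) = I_inf + (I0 - I_inf) exp(-k t)`` and a half-life
``tau_1/2 = ln 2 / k``.  Temperature dependence of the association
constant yields the standard enthalpy and entropy through the linear
van't Hoff equation ``ln K = -dH/(R T) + dS/R``.

Units: time in min, k in min^-1, temperature in K (a Celsius helper is
provided), dH in kJ/mol, dS in J/(K mol).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import stats

__all__ = [
    "R_GAS",
    "DecayTrace",
    "DecayFitResult",
    "VantHoffResult",
    "celsius_to_kelvin",
    "fit_first_order",
    "pss_composition",
    "fatigue_metrics",
    "vant_hoff",
]

R_GAS = 8.314  # J/(K mol)


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + 273.15


@dataclass
class DecayTrace:
    """Band-intensity time course at fixed temperature."""

    times: np.ndarray        # min, strictly increasing, nonnegative
    intensities: np.ndarray
    temperature: float | None = None  # K

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(self.times < 0):
            raise ValueError("times must be nonnegative")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class DecayFitResult:
    k: float                 # min^-1
    I0: float
    I_inf: float
    k_se: float | None
    I0_se: float | None
    I_inf_se: float | None
    rss: float

    @property
    def tau_half(self) -> float:
        """Half-life in min, ln(2)/k."""
        return np.log(2.0) / self.k

    @property
    def tau_half_se(self) -> float | None:
        if self.k_se is None:
            return None
        return np.log(2.0) / self.k**2 * self.k_se


@dataclass
class VantHoffResult:
    dH: float        # kJ/mol
    dS: float        # J/(K mol)
    se_dH: float
    se_dS: float
    r2: float
    n: int

    def dG_at(self, T: float) -> float:
        """Standard Gibbs energy in kJ/mol at temperature T (K)."""
        return self.dH - T * self.dS / 1000.0


def fit_first_order(trace: DecayTrace) -> DecayFitResult:
    """Least-squares single-exponential fit of a decay trace.

    The fit runs in natural intensity space (additive-noise assumption);
    a log-linear estimate seeds the rate constant.  Raises if the trace
    carries no decay (flat, or fitted k <= 0) and warns when the observed
    window is shorter than ~0.2/k, where the rate is weakly identified.
    """
    t, y = trace.times, trace.intensities
    if t.size < 5:
        raise ValueError("need >= 5 points for a decay fit")
    span = float(y[0] - y[-1])
    if np.ptp(y) == 0 or span <= 0:
        raise ValueError("no decay detected: trace is flat or non-decreasing")

    # log-linear seed on the decaying part
    I_inf0 = float(y[-1]) - 0.05 * span
    pos = y - I_inf0 > 0
    if np.count_nonzero(pos) >= 3:
        slope = stats.linregress(t[pos], np.log(y[pos] - I_inf0)).slope
        k0 = -slope if slope < 0 else 1.0 / (t[-1] - t[0])
    else:
        k0 = 1.0 / (t[-1] - t[0])

    params = lmfit.Parameters()
    params.add("k", value=max(k0, 1e-12), min=1e-12)
    params.add("I0", value=float(y[0]))
    params.add("I_inf", value=I_inf0)

    def residual(p):
        return y - (p["I_inf"].value
                    + (p["I0"].value - p["I_inf"].value) * np.exp(-p["k"].value * t))

    out = lmfit.minimize(residual, params, method="leastsq")
    if not out.success:
        raise RuntimeError(f"decay fit failed to converge: {out.message}")
    k = out.params["k"].value
    if k <= 1e-10:
        raise ValueError("no decay detected: fitted rate is not positive")
    if (t[-1] - t[0]) * k < 0.2:
        warnings.warn(
            "observation window shorter than 0.2/k: rate weakly identified",
            stacklevel=2,
        )
    return DecayFitResult(
        k=k,
        I0=out.params["I0"].value,
        I_inf=out.params["I_inf"].value,
        k_se=out.params["k"].stderr,
        I0_se=out.params["I0"].stderr,
        I_inf_se=out.params["I_inf"].stderr,
        rss=float(np.sum(out.residual**2)),
    )


def fit_first_order_loglinear(trace: DecayTrace, I_inf: float) -> float:
    """Cross-check rate from a log-linear regression with a known plateau."""
    t, y = trace.times, trace.intensities
    excess = y - I_inf
    if np.any(excess <= 0):
        raise ValueError("log-linear fit needs all intensities above the plateau")
    return -stats.linregress(t, np.log(excess)).slope


def pss_composition(integrals: dict[str, float]) -> dict[str, float]:
    """Isomer fractions at the photostationary state from NMR integrals.

    Normalizes nonnegative peak areas (one per isomer) to fractions that
    sum to one.
    """
    if any(v < 0 for v in integrals.values()):
        raise ValueError("integrals must be nonnegative")
    total = sum(integrals.values())
    if total <= 0:
        raise ValueError("all integrals are zero: composition undefined")
    return {k: v / total for k, v in integrals.items()}


def fatigue_metrics(cycle_amplitudes: list[float] | np.ndarray) -> dict:
    """Per-cycle retention of the switching amplitude over irradiation cycles.

    Returns the geometric-mean per-cycle retention
    ``(a_n / a_1)^(1/(n-1))``, the total retention ``a_n / a_1`` and the
    regression slope of log amplitude on cycle index with its standard
    error (slope = log of per-cycle retention).
    """
    a = np.asarray(cycle_amplitudes, dtype=float)
    if a.size < 2:
        raise ValueError("need >= 2 cycles")
    if np.any(a <= 0):
        raise ValueError("cycle amplitudes must be positive")
    idx = np.arange(a.size, dtype=float)
    res = stats.linregress(idx, np.log(a))
    return {
        "retention_per_cycle": float((a[-1] / a[0]) ** (1.0 / (a.size - 1))),
        "total_retention": float(a[-1] / a[0]),
        "slope_retention": float(np.exp(res.slope)),
        "slope_se": float(res.stderr),
        "n_cycles": int(a.size),
    }


def vant_hoff(Ks: list[tuple[float, float]]) -> VantHoffResult:
    """Linear van't Hoff regression of ln K on 1/T.

    ``Ks`` is a list of (temperature K, association constant M^-1) pairs.
    dH = -R * slope (kJ/mol), dS = R * intercept (J/(K mol)); standard
    errors propagate directly from the regression.
    """
    arr = np.asarray(Ks, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (T, K) pairs")
    T, K = arr[:, 0], arr[:, 1]
    if np.any(T <= 0) or np.any(K <= 0):
        raise ValueError("temperatures and constants must be positive")
    res = stats.linregress(1.0 / T, np.log(K))
    return VantHoffResult(
        dH=-R_GAS * res.slope / 1000.0,
        dS=R_GAS * res.intercept,
        se_dH=R_GAS * (res.stderr or 0.0) / 1000.0,
        se_dS=R_GAS * (res.intercept_stderr or 0.0),
        r2=res.rvalue**2,
        n=int(T.size),
    )
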