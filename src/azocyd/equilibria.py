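"""Exact equilibrium speciation and binding-isotherm fitting.

Models
------
1:1 host-guest inclusion        H + G <-> HG          K   = [HG]/([H][G])
homodimerization                2 M   <-> D           K_d = [D]/[M]^2
competitive 1:1 binding         H + G1 <-> HG1, H + G2 <-> HG2
homodimer + heterodimer         2 M <-> D  and  M + H <-> MH

All speciation solvers are exact (closed-form quadratic where one exists,
bracketed scalar root otherwise) and every result satisfies component mass
balance and its equilibrium quotient to high precision.  Titration and
dilution fitting is nonlinear least squares on the exact-speciation signal
model; a Benesi-Hildebrand double-reciprocal linearization is provided for
cross-checks in the host-excess regime.

Concentrations are mol/L and association constants M^-1 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
from scipy import optimize, stats

__all__ = [
    "SpeciesState",
    "BindingFitResult",
    "TitrationSeries",
    "DilutionSeries",
    "solve_1to1",
    "bound_fraction",
    "solve_dimer",
    "solve_competition",
    "solve_dimer_plus_host",
    "fit_titration_1to1",
    "fit_titration_linearized",
    "fit_dilution_dimer",
    "read_series",
    "write_series",
]


@dataclass
class SpeciesState:
    """Equilibrium concentrations (mol/L) keyed by species name."""

    model: str
    concentrations: dict[str, float]
    totals: dict[str, float]

    def __getitem__(self, species: str) -> float:
        return self.concentrations[species]


@dataclass
class TitrationSeries:
    """(host total, observed signal) table at fixed guest total."""

    host_totals: np.ndarray          # mol/L
    signals: np.ndarray
    guest_total: float               # mol/L
    signal_kind: str = "ellipticity_mdeg"   # or "shift_ppm"
    temperature: float | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.host_totals = np.asarray(self.host_totals, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.host_totals.shape != self.signals.shape:
            raise ValueError("host_totals and signals must have equal length")
        if self.guest_total <= 0:
            raise ValueError("guest_total must be > 0")


@dataclass
class DilutionSeries:
    """(total concentration, observed chemical shift) serial-dilution table."""

    concentrations: np.ndarray       # mol/L
    shifts: np.ndarray               # ppm
    temperature: float | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.concentrations.shape != self.shifts.shape:
            raise ValueError("concentrations and shifts must have equal length")


@dataclass
class BindingFitResult:
    """Fitted binding parameters with standard errors and diagnostics."""

    model: str
    params: dict[str, float]
    stderr: dict[str, float | None]
    rss: float
    n: int
    covar: np.ndarray | None = None
    message: str = ""

    @property
    def K(self) -> float:
        for key in ("K", "K_d"):
            if key in self.params:
                return self.params[key]
        raise KeyError("no association constant in this fit")

    @property
    def K_se(self) -> float | None:
        for key in ("K", "K_d"):
            if key in self.params:
                return self.stderr.get(key)
        raise KeyError("no association constant in this fit")


# --------------------------------------------------------------------------
# speciation solvers
# --------------------------------------------------------------------------

def _check_nonneg(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")


def solve_1to1(H_T: float, G_T: float, K: float) -> SpeciesState:
    """Exact 1:1 speciation.

    [HG] is the physically meaningful (smaller) root of
    ``K x^2 - (K (H_T + G_T) + 1) x + K H_T G_T = 0``, evaluated in the
    cancellation-free form ``2 K H_T G_T / (b + sqrt(b^2 - 4 K^2 H_T G_T))``.
    """
    _check_nonneg(H_T=H_T, G_T=G_T, K=K)
    if K == 0.0 or H_T == 0.0 or G_T == 0.0:
        hg = 0.0
    else:
        b = K * (H_T + G_T) + 1.0
        disc = b * b - 4.0 * K * K * H_T * G_T
        hg = 2.0 * K * H_T * G_T / (b + np.sqrt(disc))
    return SpeciesState(
        model="1:1",
        concentrations={"H": H_T - hg, "G": G_T - hg, "HG": hg},
        totals={"H": H_T, "G": G_T},
    )


def bound_fraction(H_T: float, G_T: float, K: float) -> float:
    """Fraction of guest present as the 1:1 complex, [HG]/G_T."""
    if G_T == 0:
        raise ValueError("bound fraction undefined at zero guest total")
    return solve_1to1(H_T, G_T, K)["HG"] / G_T


def solve_dimer(C_T: float, K_d: float) -> SpeciesState:
    """Exact monomer-dimer speciation for 2M <-> D.

    [M] = 2 C_T / (1 + sqrt(1 + 8 K_d C_T)), which is the closed-form
    quadratic root written stably and reduces to [M] = C_T at K_d = 0.
    The molecule-wise dimer fraction is f_d = 2[D]/C_T.
    """
    _check_nonneg(C_T=C_T, K_d=K_d)
    if C_T == 0.0:
        m = 0.0
    else:
        m = 2.0 * C_T / (1.0 + np.sqrt(1.0 + 8.0 * K_d * C_T))
    # K_d m^2, not (C_T - m)/2: avoids cancellation at small dimer fractions
    d = K_d * m * m
    state = SpeciesState(
        model="dimer",
        concentrations={"M": m, "D": d},
        totals={"C": C_T},
    )
    state.concentrations["f_d"] = 2.0 * d / C_T if C_T > 0 else 0.0
    return state


def solve_competition(
    H_T: float, G1_T: float, G2_T: float, K1: float, K2: float
) -> SpeciesState:
    """Two guests competing for one host, both 1:1.

    Solved by a bracketed scalar root on the free-host concentration h:
    ``H_T = h + K1 h G1_T/(1 + K1 h) + K2 h G2_T/(1 + K2 h)``.
    """
    _check_nonneg(H_T=H_T, G1_T=G1_T, G2_T=G2_T, K1=K1, K2=K2)

    def residual(h: float) -> float:
        return (
            h
            + K1 * h * G1_T / (1.0 + K1 * h)
            + K2 * h * G2_T / (1.0 + K2 * h)
            - H_T
        )

    if H_T == 0.0:
        h = 0.0
    else:
        try:
            h = optimize.brentq(residual, 0.0, H_T, xtol=1e-300, rtol=1e-15)
        except ValueError as exc:  # pragma: no cover - bracket is exact by construction
            raise RuntimeError(
                f"competition solver failed to converge on bracket [0, {H_T}]: {exc}"
            ) from exc
    g1 = G1_T / (1.0 + K1 * h)
    g2 = G2_T / (1.0 + K2 * h)
    return SpeciesState(
        model="competition",
        concentrations={
            "H": h,
            "G1": g1,
            "G2": g2,
            "HG1": K1 * h * g1,
            "HG2": K2 * h * g2,
        },
        totals={"H": H_T, "G1": G1_T, "G2": G2_T},
    )


def solve_dimer_plus_host(
    C_T: float, H_T: float, K_d: float, K_het: float
) -> SpeciesState:
    """Coupled homodimerization and 1:1 heterocomplexation.

    2M <-> D (K_d) competing with M + H <-> MH (K_het).  The free-host
    balance gives h = H_T / (1 + K_het m), reducing the system to one
    monotone scalar equation in the free monomer m, solved by bracketing
    on [0, C_T].
    """
    _check_nonneg(C_T=C_T, H_T=H_T, K_d=K_d, K_het=K_het)

    def residual(m: float) -> float:
        h = H_T / (1.0 + K_het * m)
        return m + 2.0 * K_d * m * m + K_het * m * h - C_T

    if C_T == 0.0:
        m = 0.0
    else:
        try:
            m = optimize.brentq(residual, 0.0, C_T, xtol=1e-300, rtol=1e-15)
        except ValueError as exc:  # pragma: no cover
            raise RuntimeError(
                f"dimer+host solver failed to converge on bracket [0, {C_T}]: {exc}"
            ) from exc
    h = H_T / (1.0 + K_het * m)
    return SpeciesState(
        model="dimer+host",
        concentrations={
            "M": m,
            "D": K_d * m * m,
            "H": h,
            "MH": K_het * m * h,
        },
        totals={"C": C_T, "H": H_T},
    )


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

_K_SCAN_GRID = np.logspace(0.0, 6.0, 25)


def _check_converged(out, what: str) -> None:
    """Raise on a genuinely failed optimization; warn when only the
    error-bar estimation struggled (parameters are still the best fit)."""
    values = [p.value for p in out.params.values()]
    if not np.all(np.isfinite(values)):
        raise RuntimeError(f"{what} failed to converge: {out.message}")
    if not out.success:
        warnings.warn(f"{what} did not fully converge: {out.message}", stacklevel=3)


def _signal_1to1(H: np.ndarray, G_T: float, K: float,
                 s_free: float, s_complex: float) -> np.ndarray:
    f = np.array([bound_fraction(h, G_T, K) for h in np.atleast_1d(H)])
    return s_free + (s_complex - s_free) * f


def _best_linear_given_K(H, y, G_T, K, fix_free_zero):
    """Variable-projection step: optimal signal endpoints for a fixed K."""
    f = np.array([bound_fraction(h, G_T, K) for h in H])
    if fix_free_zero:
        denom = float(f @ f)
        if denom == 0:
            return 0.0, 0.0, float(y @ y)
        sc = float(f @ y) / denom
        resid = y - sc * f
        return 0.0, sc, float(resid @ resid)
    X = np.column_stack([1.0 - f, f])
    coef, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_titration_1to1(
    series: TitrationSeries,
    fix_free_zero: bool | None = None,
    weights: np.ndarray | None = None,
) -> BindingFitResult:
    """Nonlinear 1:1 fit of an observed-signal titration.

    Model: ``signal = s_free + (s_complex - s_free) * f_bound(H_T, G_T, K)``
    with exact speciation inside.  For induced-CD ellipticity the free
    guest carries no signal, so ``s_free`` is fixed at zero by default for
    that kind; for fast-exchange NMR shifts it floats.

    The starting K comes from a deterministic coarse log-grid scan
    (1 to 1e6 M^-1) where the signal endpoints are profiled out linearly;
    the refinement is unweighted least squares unless ``weights`` (1/sigma)
    are given.  Standard errors come from the Jacobian-based covariance.
    """
    H = series.host_totals
    y = series.signals
    G_T = series.guest_total
    if H.size < 5:
        raise ValueError("need >= 5 titration points")
    if fix_free_zero is None:
        fix_free_zero = series.signal_kind.startswith("ellipticity")

    span = float(np.ptp(y))
    if span == 0.0:
        warnings.warn("flat signal series: association constant unidentifiable", stacklevel=2)

    # deterministic coarse scan for the initial K
    scans = [(_best_linear_given_K(H, y, G_T, K, fix_free_zero), K) for K in _K_SCAN_GRID]
    (s_free0, s_complex0, _), K0 = min(scans, key=lambda t: t[0][2])

    params = lmfit.Parameters()
    params.add("K", value=K0, min=1e-12)
    params.add("s_free", value=s_free0, vary=not fix_free_zero)
    params.add("s_complex", value=s_complex0)

    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return w * (y - _signal_1to1(H, G_T, p["K"].value,
                                     p["s_free"].value, p["s_complex"].value))

    out = lmfit.minimize(residual, params, method="leastsq")
    _check_converged(out, "1:1 titration fit")

    K_hat = out.params["K"].value
    K_se = out.params["K"].stderr
    if K_se is None or (K_se is not None and K_se > K_hat):
        warnings.warn(
            "plateau not reached or no curvature: K is poorly identified (wide se)",
            stacklevel=2,
        )
    fitted = {name: out.params[name].value for name in out.params}
    errs = {name: out.params[name].stderr for name in out.params}
    return BindingFitResult(
        model="titration_1to1",
        params=fitted,
        stderr=errs,
        rss=float(np.sum(out.residual**2)),
        n=int(H.size),
        covar=getattr(out, "covar", None),
        message=str(out.message),
    )


def fit_titration_linearized(series: TitrationSeries) -> BindingFitResult:
    """Benesi-Hildebrand double-reciprocal estimate of K.

    Regresses 1/signal on 1/H_T; under host excess
    ``1/signal = 1/s_complex + 1/(K s_complex H_T)`` so
    ``K = intercept/slope``.  Points at zero host are excluded (the
    reciprocal is undefined there); a zero signal anywhere is an error.
    Known to be biased under heteroscedastic noise relative to the
    nonlinear fit; intended as a cross-check.
    """
    mask = series.host_totals > 0
    H = series.host_totals[mask]
    y = series.signals[mask]
    if np.any(y == 0):
        raise ValueError("zero signal in series: double-reciprocal transform undefined")
    if H.size < 3:
        raise ValueError("need >= 3 nonzero-host points")
    x = 1.0 / H
    res = stats.linregress(x, 1.0 / y)
    if res.slope == 0:
        raise ValueError("zero slope: K undefined in the linearized form")
    K = res.intercept / res.slope
    # first-order propagation, ignoring slope/intercept covariance
    K_se = abs(K) * np.sqrt(
        (res.intercept_stderr / res.intercept) ** 2 + (res.stderr / res.slope) ** 2
    ) if res.intercept != 0 else None
    s_complex = 1.0 / res.intercept if res.intercept != 0 else np.inf
    pred = res.intercept + res.slope * x
    return BindingFitResult(
        model="titration_1to1_linearized",
        params={"K": K, "s_complex": s_complex,
                "slope": res.slope, "intercept": res.intercept},
        stderr={"K": K_se, "s_complex": None,
                "slope": res.stderr, "intercept": res.intercept_stderr},
        rss=float(np.sum((1.0 / y - pred) ** 2)),
        n=int(H.size),
    )


def fit_dilution_dimer(
    series: DilutionSeries,
    weights: np.ndarray | None = None,
) -> BindingFitResult:
    """Fast-exchange dimerization fit of a serial-dilution shift series.

    Model: ``delta_obs = (1 - f_d) delta_M + f_d delta_D`` with the
    molecule-wise dimer fraction f_d from exact monomer-dimer speciation.
    Returns K_d (M^-1), the monomer and dimer limiting shifts, and their
    standard errors.
    """
    C = series.concentrations
    y = series.shifts
    if C.size < 5:
        raise ValueError("need >= 5 concentrations for a dilution fit")
    span_ratio = C.max() / C.min()
    if span_ratio < 10:
        warnings.warn(
            f"concentration span {span_ratio:.1f}x < 10x: K_d poorly identified",
            stacklevel=2,
        )

    def f_d(Kd: float) -> np.ndarray:
        return np.array([solve_dimer(c, Kd)["f_d"] for c in C])

    # coarse deterministic scan, shifts profiled out linearly
    def lin_rss(Kd: float):
        f = f_d(Kd)
        X = np.column_stack([1.0 - f, f])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(coef[0]), float(coef[1]), float(r @ r)

    scans = [(lin_rss(Kd), Kd) for Kd in _K_SCAN_GRID]
    (dM0, dD0, _), Kd0 = min(scans, key=lambda t: t[0][2])

    params = lmfit.Parameters()
    params.add("K_d", value=Kd0, min=1e-12)
    params.add("delta_M", value=dM0)
    params.add("delta_D", value=dD0)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    def residual(p):
        f = f_d(p["K_d"].value)
        return w * (y - ((1.0 - f) * p["delta_M"].value + f * p["delta_D"].value))

    out = lmfit.minimize(residual, params, method="leastsq")
    _check_converged(out, "dilution fit")
    return BindingFitResult(
        model="dilution_dimer",
        params={name: out.params[name].value for name in out.params},
        stderr={name: out.params[name].stderr for name in out.params},
        rss=float(np.sum(out.residual**2)),
        n=int(C.size),
        covar=getattr(out, "covar", None),
        message=str(out.message),
    )


# --------------------------------------------------------------------------
# delimited-text I/O
# --------------------------------------------------------------------------

def write_series(path: str | Path, series: TitrationSeries | DilutionSeries) -> None:
    lines = []
    if isinstance(series, TitrationSeries):
        lines.append(f"# guest_total_M: {series.guest_total!r}")
        lines.append(f"# signal_kind: {series.signal_kind}")
        if series.temperature is not None:
            lines.append(f"# temperature_K: {series.temperature!r}")
        lines.append("host_total_M,signal")
        for h, s in zip(series.host_totals, series.signals):
            lines.append(f"{float(h)!r},{float(s)!r}")
    else:
        if series.temperature is not None:
            lines.append(f"# temperature_K: {series.temperature!r}")
        lines.append("conc_total_M,shift_ppm")
        for c, d in zip(series.concentrations, series.shifts):
            lines.append(f"{float(c)!r},{float(d)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_series(path: str | Path) -> TitrationSeries | DilutionSeries:
    meta: dict = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                k, v = line.lstrip("# ").split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        if header is None:
            header = [h.strip() for h in line.split(",")]
            continue
        rows.append(line.split(","))
    if header is None or not rows:
        raise ValueError(f"no data rows in {path}")
    data = np.array(rows, dtype=float)
    temp = float(meta["temperature_K"]) if "temperature_K" in meta else None
    if header[0] == "host_total_M":
        if "guest_total_M" not in meta:
            raise ValueError("titration file missing '# guest_total_M:' header")
        return TitrationSeries(
            host_totals=data[:, 0],
            signals=data[:, 1],
            guest_total=float(meta["guest_total_M"]),
            signal_kind=meta.get("signal_kind", "ellipticity_mdeg"),
            temperature=temp,
        )
    if header[0] == "conc_total_M":
        return DilutionSeries(concentrations=data[:, 0], shifts=data[:, 1], temperature=temp)
    raise ValueError(
        f"unrecognized first column {header[0]!r}; expected 'host_total_M' or 'conc_total_M'"
    )
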