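"""Spectral data model and spectrum-level analyses.

Absorbance (AU) and induced circular dichroism / ellipticity (mdeg) traces
are stored on a strictly increasing wavelength grid in nm.  The operations
here cover the routine photochemistry workflow for an azobenzene
chromophore: molar-absorptivity (Beer-Lambert) regression, isosbestic-point
detection across a two-state spectral family, bisignate exciton-couplet
metrics, and band-maximum location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "CoupletMetrics",
    "normalize_spectrum",
    "fit_molar_absorptivity",
    "find_isosbestic_points",
    "couplet_metrics",
    "band_maximum",
    "resample_spectrum",
    "read_spectra",
    "write_spectra",
]

VALID_KINDS = ("absorbance", "ellipticity")


@dataclass
class Spectrum:
    """A single wavelength-indexed trace.

    Parameters
    ----------
    wavelengths : array-like
        Wavelength grid in nm, strictly increasing.
    values : array-like
        Signal at each wavelength; AU for ``kind="absorbance"``,
        mdeg for ``kind="ellipticity"``.
    concentration : float, optional
        Sample concentration in mol/L.
    pathlength : float
        Optical pathlength in cm (default 1).
    temperature : float, optional
        Sample temperature in K.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "absorbance"
    concentration: float | None = None
    pathlength: float = 1.0
    temperature: float | None = None
    label: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        if self.wavelengths.size == 0:
            raise ValueError("spectrum must contain at least one point")
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if self.concentration is not None and self.concentration <= 0:
            raise ValueError("concentration must be > 0 when present")
        if self.pathlength <= 0:
            raise ValueError("pathlength must be > 0")


@dataclass
class SpectrumSet:
    """A family of spectra on one shared wavelength grid.

    ``series_variable`` names the condition that varies across members
    (concentration, irradiation state, time, ...).
    """

    spectra: list[Spectrum]
    series_variable: str = ""

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("SpectrumSet requires at least one spectrum")
        grid = self.spectra[0].wavelengths
        for s in self.spectra[1:]:
            if s.wavelengths.shape != grid.shape or not np.array_equal(s.wavelengths, grid):
                raise ValueError("all member spectra must share one wavelength grid")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    def value_matrix(self) -> np.ndarray:
        """Stack member values as an (n_spectra, n_wavelengths) array."""
        return np.vstack([s.values for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass
class CoupletMetrics:
    """Summary of a bisignate exciton couplet.

    Amplitude is the sum of the magnitudes of the positive and negative
    branches; the crossing is the zero-crossing wavelength between them.
    """

    pos_peak_nm: float | None
    pos_peak_mdeg: float
    neg_peak_nm: float | None
    neg_peak_mdeg: float
    amplitude_mdeg: float
    crossing_nm: float | None


def normalize_spectrum(s: Spectrum) -> Spectrum:
    """Convert a raw spectrum to molar units (divide by c*l).

    For an absorbance spectrum this yields the molar absorptivity trace
    epsilon(lambda) in L mol^-1 cm^-1; for ellipticity, mdeg M^-1 cm^-1.
    """
    if s.concentration is None:
        raise ValueError("cannot normalize: 'concentration' is not set on this spectrum")
    return replace(
        s,
        values=s.values / (s.concentration * s.pathlength),
        normalized=True,
    )


def fit_molar_absorptivity(
    points: list[tuple[float, float]] | np.ndarray,
    pathlength: float = 1.0,
) -> dict:
    """Beer-Lambert regression of absorbance on concentration.

    Ordinary least squares with a free intercept (baseline offsets are
    common and forcing the origin hides them).  Returns
    ``epsilon = slope / pathlength`` in L mol^-1 cm^-1 along with the
    intercept, standard errors and r^2.

    Parameters
    ----------
    points : sequence of (concentration_M, absorbance_AU)
    pathlength : float, cm
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (concentration, absorbance) pairs")
    c, a = arr[:, 0], arr[:, 1]
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if np.unique(c).size < 3:
        raise ValueError("need >= 3 distinct concentrations for a Beer-Lambert fit")
    if pathlength <= 0:
        raise ValueError("pathlength must be > 0")
    res = stats.linregress(c, a)
    return {
        "epsilon": res.slope / pathlength,
        "epsilon_se": res.stderr / pathlength,
        "intercept": res.intercept,
        "intercept_se": res.intercept_stderr,
        "r2": res.rvalue**2,
        "n": int(c.size),
    }


def find_isosbestic_points(
    spectrum_set: SpectrumSet,
    tol: float,
    min_separation_nm: float = 5.0,
    min_signal: float | None = None,
) -> list[float]:
    """Locate isosbestic points in a spectral family.

    An isosbestic point is taken as a wavelength where the across-spectra
    standard deviation has a local minimum below ``tol`` (in the signal's
    own units).  Candidates closer than ``min_separation_nm`` are merged,
    keeping the lowest-deviation one.  Regions where the family itself is
    silent (mean |signal| below ``min_signal``, default ``tol``) are not
    crossings and are excluded.  Requires at least three spectra
    normalized to a common scale.
    """
    if len(spectrum_set) < 3:
        raise ValueError("isosbestic detection needs >= 3 spectra")
    if min_signal is None:
        min_signal = tol
    wl = spectrum_set.wavelengths
    mat = spectrum_set.value_matrix()
    sd = mat.std(axis=0)
    mean_abs = np.abs(mat).mean(axis=0)
    if np.all(sd < tol):
        raise ValueError(
            "degenerate family: spectra agree everywhere within tol, no isolated crossings"
        )
    # interior local minima of the deviation profile, at nonzero signal
    cand = [
        i
        for i in range(1, sd.size - 1)
        if sd[i] < tol and sd[i] <= sd[i - 1] and sd[i] <= sd[i + 1]
        and mean_abs[i] >= min_signal
    ]
    # merge clusters closer than min_separation, keep lowest sd
    merged: list[int] = []
    for i in sorted(cand, key=lambda i: sd[i]):
        if all(abs(wl[i] - wl[j]) >= min_separation_nm for j in merged):
            merged.append(i)
    return sorted(float(wl[i]) for i in merged)


def couplet_metrics(
    s: Spectrum,
    window: tuple[float, float],
    use_areas: bool = False,
) -> CoupletMetrics:
    """Characterize a bisignate couplet inside a wavelength window.

    Finds the largest positive extremum and the largest-magnitude negative
    extremum; amplitude is the sum of their magnitudes (the conventional
    exciton-couplet total intensity).  The crossing is the linear-
    interpolated zero between the two peaks.  When the window contains no
    sign change, the single extremum carries the amplitude and the
    crossing is absent.  With ``use_areas=True`` the amplitude instead
    sums the integrated |signal| of the positive and negative lobes.
    """
    lo, hi = window
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"empty window {window} for grid "
                         f"[{s.wavelengths[0]}, {s.wavelengths[-1]}] nm")
    wl = s.wavelengths[mask]
    v = s.values[mask]

    pos_val = float(v.max())
    neg_val = float(v.min())
    pos_nm = float(wl[np.argmax(v)]) if pos_val > 0 else None
    neg_nm = float(wl[np.argmin(v)]) if neg_val < 0 else None
    pos = pos_val if pos_val > 0 else 0.0
    neg = neg_val if neg_val < 0 else 0.0

    if use_areas:
        amplitude = float(np.trapezoid(np.clip(v, 0, None), wl)
                          - np.trapezoid(np.clip(v, None, 0), wl))
    else:
        amplitude = pos + abs(neg)

    crossing = None
    if pos_nm is not None and neg_nm is not None:
        i0, i1 = sorted((int(np.argmax(v)), int(np.argmin(v))))
        seg_v, seg_wl = v[i0 : i1 + 1], wl[i0 : i1 + 1]
        sign_change = np.nonzero(np.diff(np.sign(seg_v)) != 0)[0]
        if sign_change.size:
            j = sign_change[0]
            y0, y1 = seg_v[j], seg_v[j + 1]
            x0, x1 = seg_wl[j], seg_wl[j + 1]
            crossing = float(x0 - y0 * (x1 - x0) / (y1 - y0))

    return CoupletMetrics(
        pos_peak_nm=pos_nm,
        pos_peak_mdeg=pos,
        neg_peak_nm=neg_nm,
        neg_peak_mdeg=neg,
        amplitude_mdeg=amplitude,
        crossing_nm=crossing,
    )


def band_maximum(
    s: Spectrum,
    window: tuple[float, float],
    absolute: bool = False,
) -> tuple[float, float]:
    """Locate the band maximum inside a window.

    Returns ``(lambda_max_nm, value)``; with ``absolute=True`` the arg-max
    of |value| is used.  Ties and flat stretches resolve to the leftmost
    wavelength, with a warning.
    """
    lo, hi = window
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"empty window {window}")
    wl = s.wavelengths[mask]
    v = s.values[mask]
    key = np.abs(v) if absolute else v
    i = int(np.argmax(key))  # argmax takes the first (leftmost) of ties
    if np.count_nonzero(key == key[i]) > 1:
        warnings.warn("flat or tied maximum; leftmost wavelength reported", stacklevel=2)
    return float(wl[i]), float(v[i])


def resample_spectrum(s: Spectrum, new_grid: np.ndarray) -> Spectrum:
    """Linear-interpolate a spectrum onto a new strictly increasing grid."""
    new_grid = np.asarray(new_grid, dtype=float)
    if new_grid.size > 1 and not np.all(np.diff(new_grid) > 0):
        raise ValueError("new grid must be strictly increasing")
    if new_grid[0] < s.wavelengths[0] or new_grid[-1] > s.wavelengths[-1]:
        raise ValueError("new grid extends beyond the measured range")
    return replace(s, wavelengths=new_grid, values=np.interp(new_grid, s.wavelengths, s.values))


# -- delimited-text I/O ------------------------------------------------------
#
# Format: optional '# key: value' header comments, then a header row
# 'wavelength_nm<delim>label1<delim>label2...', one column per spectrum.

_META_FIELDS = {
    "kind": str,
    "concentration_M": float,
    "pathlength_cm": float,
    "temperature_K": float,
    "series_variable": str,
}


def write_spectra(path: str | Path, sset: SpectrumSet, delimiter: str = ",") -> None:
    s0 = sset.spectra[0]
    lines = []
    lines.append(f"# kind: {s0.kind}")
    if sset.series_variable:
        lines.append(f"# series_variable: {sset.series_variable}")
    if s0.concentration is not None:
        lines.append(f"# concentration_M: {s0.concentration!r}")
    lines.append(f"# pathlength_cm: {s0.pathlength!r}")
    if s0.temperature is not None:
        lines.append(f"# temperature_K: {s0.temperature!r}")
    labels = [s.label or f"s{i}" for i, s in enumerate(sset.spectra)]
    lines.append(delimiter.join(["wavelength_nm", *labels]))
    mat = sset.value_matrix()
    for j, wl in enumerate(sset.wavelengths):
        lines.append(delimiter.join([repr(float(wl))] + [repr(float(x)) for x in mat[:, j]]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectra(path: str | Path, delimiter: str = ",") -> SpectrumSet:
    meta: dict = {}
    rows: list[list[str]] = []
    header: list[str] | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                key, val = line.lstrip("# ").split(":", 1)
                key = key.strip()
                if key in _META_FIELDS:
                    meta[key] = _META_FIELDS[key](val.strip())
            continue
        if header is None:
            header = line.split(delimiter)
            continue
        rows.append(line.split(delimiter))
    if header is None or not rows:
        raise ValueError(f"no spectral data found in {path}")
    data = np.array(rows, dtype=float)
    wl = data[:, 0]
    spectra = [
        Spectrum(
            wavelengths=wl,
            values=data[:, k],
            kind=meta.get("kind", "absorbance"),
            concentration=meta.get("concentration_M"),
            pathlength=meta.get("pathlength_cm", 1.0),
            temperature=meta.get("temperature_K"),
            label=header[k],
        )
        for k in range(1, data.shape[1])
    ]
    return SpectrumSet(spectra, series_variable=meta.get("series_variable", ""))
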