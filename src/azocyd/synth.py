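"""Seeded synthetic-data generators for every input the analysis modules
consume.

Each generator is a deterministic function of its parameters and seed,
produces data that satisfies its model exactly at zero noise, and attaches
the ground-truth parameters so recovery tests never re-derive them.  Noise
is additive homoscedastic Gaussian throughout.

The default designs mirror the experimental protocols for the
beta-cyclodextrin / azobenzene system: an induced-CD titration at 0.094 mM
guest with host from 0 to 16.6 mM, a two-fold NMR serial dilution from
20 mM to 0.078 mM, first-order dark-relaxation traces, two-state spectral
families with designed isosbestic crossings and bisignate exciton
couplets, and a coarse-grained heptagonal macroring plus rod chromophore
with known axis/angle ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .equilibria import DilutionSeries, TitrationSeries, bound_fraction, solve_dimer
from .geometry import AxisFrame, Structure, classify_location
from .kinetics import DecayTrace
from .spectra import Spectrum, SpectrumSet

__all__ = [
    "GeneratorSpec",
    "DEFAULT_TITRATION_HOST_GRID",
    "DEFAULT_DILUTION_GRID",
    "gen_titration",
    "gen_dilution",
    "gen_decay",
    "gen_two_state_spectra",
    "gen_toy_complex",
    "gen_fatigue",
    "write_truth_sidecar",
]

# host grid: 12 points, 0 to 16.6 mM (the ICD titration design)
DEFAULT_TITRATION_HOST_GRID = np.linspace(0.0, 16.6e-3, 12)
# two-fold dilution ladder, 20 mM down to 0.078 mM (9 points)
DEFAULT_DILUTION_GRID = 20e-3 / 2.0 ** np.arange(9)
DEFAULT_GUEST_TOTAL = 9.4e-5  # 0.094 mM


@dataclass
class GeneratorSpec:
    """Record of what a generator produced: model, truth, design, noise."""

    model: str
    truth: dict
    design: dict
    sigma: float
    seed: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_titration(
    K: float,
    s_free: float = 0.0,
    s_complex: float = 10.0,
    G_T: float = DEFAULT_GUEST_TOTAL,
    H_grid: np.ndarray | None = None,
    sigma: float = 0.0,
    seed: int = 0,
    signal_kind: str = "ellipticity_mdeg",
) -> TitrationSeries:
    """Synthetic 1:1 titration: exact-speciation signal plus N(0, sigma^2)."""
    H = DEFAULT_TITRATION_HOST_GRID if H_grid is None else np.asarray(H_grid, float)
    f = np.array([bound_fraction(h, G_T, K) for h in H])
    y = s_free + (s_complex - s_free) * f
    y = y + _rng(seed).normal(0.0, sigma, size=y.shape) if sigma > 0 else y
    spec = GeneratorSpec(
        model="titration_1to1",
        truth={"K": K, "s_free": s_free, "s_complex": s_complex, "G_T": G_T},
        design={"H_grid_M": [float(h) for h in H]},
        sigma=sigma,
        seed=seed,
    )
    return TitrationSeries(
        host_totals=H, signals=y, guest_total=G_T,
        signal_kind=signal_kind, truth=spec.__dict__,
    )


def gen_dilution(
    K_d: float,
    delta_M: float = 7.80,
    delta_D: float = 7.65,
    C_grid: np.ndarray | None = None,
    sigma: float = 0.0,
    seed: int = 0,
) -> DilutionSeries:
    """Synthetic fast-exchange serial dilution for a homodimerizing solute."""
    C = DEFAULT_DILUTION_GRID if C_grid is None else np.asarray(C_grid, float)
    f = np.array([solve_dimer(c, K_d)["f_d"] for c in C])
    y = (1.0 - f) * delta_M + f * delta_D
    y = y + _rng(seed).normal(0.0, sigma, size=y.shape) if sigma > 0 else y
    spec = GeneratorSpec(
        model="dilution_dimer",
        truth={"K_d": K_d, "delta_M": delta_M, "delta_D": delta_D},
        design={"C_grid_M": [float(c) for c in C]},
        sigma=sigma,
        seed=seed,
    )
    return DilutionSeries(concentrations=C, shifts=y, truth=spec.__dict__)


def gen_decay(
    k: float,
    I0: float = 1.0,
    I_inf: float = 0.0,
    t_grid: np.ndarray | None = None,
    sigma: float = 0.0,
    seed: int = 0,
) -> DecayTrace:
    """Synthetic first-order relaxation trace I(t) = I_inf + (I0-I_inf) e^{-kt}."""
    t = np.linspace(0.0, 3.0 / k, 25) if t_grid is None else np.asarray(t_grid, float)
    y = I_inf + (I0 - I_inf) * np.exp(-k * t)
    y = y + _rng(seed).normal(0.0, sigma, size=y.shape) if sigma > 0 else y
    return DecayTrace(times=t, intensities=y)


def _gaussian_bands(wl: np.ndarray, bands: list[tuple[float, float, float]]) -> np.ndarray:
    """Sum of Gaussian bands given as (center_nm, amplitude, width_nm)."""
    out = np.zeros_like(wl)
    for center, amp, width in bands:
        out += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return out


def gen_two_state_spectra(
    bandsA: list[tuple[float, float, float]],
    bandsB: list[tuple[float, float, float]],
    fractions: list[float],
    wl_grid: np.ndarray | None = None,
    sigma: float = 0.0,
    seed: int = 0,
    kind: str = "absorbance",
) -> tuple[SpectrumSet, list[float]]:
    """Two-component spectral family with designed isosbestic crossings.

    Each member is ``f * specA + (1-f) * specB`` for one mixing fraction
    f, plus noise.  Bands are (center_nm, amplitude, width_nm) Gaussian
    triples.  Returns the family and the ground-truth crossing
    wavelengths of the two pure components (where the member spectra all
    intersect), found by sign changes of the component difference on the
    grid with bisection refinement.
    """
    wl = np.linspace(220.0, 500.0, 561) if wl_grid is None else np.asarray(wl_grid, float)
    specA = _gaussian_bands(wl, bandsA)
    specB = _gaussian_bands(wl, bandsB)

    diff = specA - specB
    crossings: list[float] = []
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    # a true isosbestic crossing carries nonzero signal; sign flips in the
    # silent tails where both components vanish are numerical noise
    floor = 1e-6 * max(np.abs(specA).max(), np.abs(specB).max())
    for j in sign_change:
        if abs(specA[j]) < floor and abs(specB[j]) < floor:
            continue
        # linear refinement within the grid cell; exact enough at fine grids
        x0, x1, y0, y1 = wl[j], wl[j + 1], diff[j], diff[j + 1]
        if y1 != y0:
            x = float(x0 - y0 * (x1 - x0) / (y1 - y0))
            # an exact zero on a grid point flags both adjacent cells
            if not crossings or x - crossings[-1] > (x1 - x0):
                crossings.append(x)

    rng = _rng(seed)
    spectra = []
    for i, frac in enumerate(fractions):
        v = frac * specA + (1.0 - frac) * specB
        if sigma > 0:
            v = v + rng.normal(0.0, sigma, size=v.shape)
        spectra.append(Spectrum(wavelengths=wl, values=v, kind=kind,
                                label=f"f={frac:g}"))
    return SpectrumSet(spectra, series_variable="fraction"), crossings


def gen_toy_complex(
    n_ring: int = 7,
    ring_radius_nm: float = 0.5,
    rod_length_nm: float = 0.9,
    theta_deg: float = 0.0,
    penetration_nm: float = 0.0,
    n_rod: int = 5,
    noise_nm: float = 0.0,
    seed: int = 0,
    rim_offsets: tuple[float, float] = (0.4, 0.4),
    radial_cutoff: float = 0.4,
) -> tuple[Structure, Structure, dict]:
    """Coarse-grained macroring + rod chromophore with known ground truth.

    The ring is a regular ``n_ring``-gon (heptagonal by default, matching
    the seven glycosidic oxygens of a beta-cyclodextrin) in the z=0 plane
    centered at the origin; its true axis is +z.  The rod is ``n_rod``
    collinear beads of total length ``rod_length_nm``, tilted by
    ``theta_deg`` from the axis (in the xz-plane) with its centroid at
    ``penetration_nm`` along the axis.  Optional Gaussian jitter of sd
    ``noise_nm`` perturbs the ring coordinates only, so the rod truth
    stays exact.

    Returns (ring, rod, truth) with truth holding the axis, angle,
    centroid and the inside/outside call implied by the stated cavity
    bounds.
    """
    rng = _rng(seed)
    ang = 2.0 * np.pi * np.arange(n_ring) / n_ring
    ring_xyz = np.column_stack(
        [ring_radius_nm * np.cos(ang), ring_radius_nm * np.sin(ang), np.zeros(n_ring)]
    )
    if noise_nm > 0:
        ring_xyz = ring_xyz + rng.normal(0.0, noise_nm, size=ring_xyz.shape)
    ring = Structure(
        labels=["O"] * n_ring,
        coords=ring_xyz,
        selections={"glycosidic_oxygens": list(range(n_ring))},
    )

    direction = np.array(
        [np.sin(np.radians(theta_deg)), 0.0, np.cos(np.radians(theta_deg))]
    )
    s = np.linspace(-0.5, 0.5, n_rod) * rod_length_nm
    centroid = np.array([0.0, 0.0, penetration_nm])
    rod_xyz = centroid + s[:, None] * direction
    rod = Structure(
        labels=["C"] * n_rod,
        coords=rod_xyz,
        selections={"chromophore": list(range(n_rod)),
                    "dipole": [0, n_rod - 1]},
    )

    true_frame = AxisFrame(origin=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]))
    truth = {
        "axis": [0.0, 0.0, 1.0],
        "theta_deg": theta_deg,
        "centroid": [float(x) for x in centroid],
        "location": classify_location(centroid, true_frame, rim_offsets, radial_cutoff),
        "rim_offsets": list(rim_offsets),
        "radial_cutoff": radial_cutoff,
    }
    return ring, rod, truth


def gen_fatigue(
    n_cycles: int = 6,
    retention: float = 1.0,
    amp0: float = 1.0,
    sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Geometric amplitude ladder across irradiation cycles:
    amp_i = amp0 * retention^i + noise."""
    if n_cycles < 2:
        raise ValueError("need >= 2 cycles")
    amps = amp0 * retention ** np.arange(n_cycles, dtype=float)
    if sigma > 0:
        amps = amps + _rng(seed).normal(0.0, sigma, size=amps.shape)
    return amps


def write_truth_sidecar(path, truth: dict) -> None:
    """Write a generator's ground-truth metadata next to its data file."""
    from pathlib import Path

    Path(path).write_text(yaml.safe_dump(truth, sort_keys=True))
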