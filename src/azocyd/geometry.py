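"""Geometry engine for induced-CD sign prediction and rigid-body
approach scans.

The macrocyclic host (a beta-cyclodextrin-like ring) is reduced to a
labeled point set; its pseudo-C7 axis is the best-fit-plane normal of the
glycosidic oxygens.  A guest chromophore's transition-dipole orientation
relative to that axis, together with an inside/outside location call,
feeds the Kodaka sign rules: a transition moment parallel to the axis of
an included chromophore gives a positive ICD band, perpendicular gives
negative, the signal vanishes at the magic angle (arccos(1/sqrt 3) =
54.74 deg), and all signs invert when the chromophore sits outside the
cavity.  The orientation weight is the second Legendre polynomial
``(3 cos^2 theta - 1)/2``.

The approach-scan protocol translates a rigid mobile body along the host
axis over a pose grid (axial displacement x dihedral rotation), scoring
each pose with a coarse-grained Lennard-Jones + Coulomb pair energy and
selecting the minimum-binding-energy (MBE) pose.

Coordinates are nm internally (Angstrom accepted at the readers);
energies are in generic kcal/mol-like units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

__all__ = [
    "Structure",
    "AxisFrame",
    "Pose",
    "EnergyBreakdown",
    "AngleStats",
    "ScanProfile",
    "COULOMB_CONSTANT",
    "MAGIC_ANGLE_DEG",
    "ring_axis",
    "dipole_axis_angle",
    "classify_location",
    "icd_sign",
    "orientation_weight",
    "dihedral",
    "make_scan_grid",
    "place_pose",
    "pair_energy",
    "scan_profile",
    "angle_history_stats",
    "read_xyz",
    "write_xyz",
    "load_parameters",
    "write_profile",
]

# Coulomb constant in (kcal/mol) nm e^-2
COULOMB_CONSTANT = 33.2063711
MAGIC_ANGLE_DEG = float(np.degrees(np.arccos(1.0 / np.sqrt(3.0))))
NM_PER_ANGSTROM = 0.1


@dataclass
class Structure:
    """Labeled 3-D point set with optional coarse-grained parameters.

    Coordinates in nm.  ``charges`` in elementary charges, ``lj_sigma``
    in nm, ``lj_epsilon`` in energy units.  ``selections`` maps names
    (e.g. ``glycosidic_oxygens``, ``chromophore``) to atom indices.
    """

    labels: list[str]
    coords: np.ndarray
    charges: np.ndarray | None = None
    lj_sigma: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None
    selections: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("structure needs at least one atom")
        if len(self.labels) != n:
            raise ValueError("labels and coords length mismatch")
        for arr_name in ("charges", "lj_sigma", "lj_epsilon"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,):
                    raise ValueError(f"{arr_name} must have one entry per atom")
                setattr(self, arr_name, arr)
        for name, idx in self.selections.items():
            if any(i < 0 or i >= n for i in idx):
                raise ValueError(f"selection {name!r} references missing atoms")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def centroid(self, selection: str | None = None) -> np.ndarray:
        return self.subcoords(selection).mean(axis=0)

    def subcoords(self, selection: str | None = None) -> np.ndarray:
        if selection is None:
            return self.coords
        return self.coords[self.selections[selection]]


@dataclass
class AxisFrame:
    """Macroring reference frame: origin, unit pseudo-axis, rim sense.

    ``rim_sign`` = +1 means the axis points toward the wider secondary
    rim.
    """

    origin: np.ndarray
    axis: np.ndarray
    rim_sign: int = 1

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if not np.isclose(norm, 1.0, atol=1e-9):
            if norm == 0:
                raise ValueError("axis must be nonzero")
            self.axis = self.axis / norm


@dataclass(frozen=True)
class Pose:
    """Rigid pose of the mobile body: signed axial displacement (nm)
    along the approach axis and dihedral rotation (deg) about it."""

    displacement: float
    dihedral: float


@dataclass
class EnergyBreakdown:
    total: float
    vdw: float
    electrostatic: float

    def __post_init__(self) -> None:
        if abs(self.total - (self.vdw + self.electrostatic)) > 1e-12 * max(
            1.0, abs(self.total)
        ):
            raise ValueError("total must equal vdw + electrostatic")


@dataclass
class AngleStats:
    mean: float   # degrees
    sd: float     # degrees
    n: int


@dataclass
class ScanProfile:
    poses: list[Pose]
    energies: list[EnergyBreakdown]
    mbe_index: int

    @property
    def mbe_pose(self) -> Pose:
        return self.poses[self.mbe_index]

    @property
    def mbe_energy(self) -> EnergyBreakdown:
        return self.energies[self.mbe_index]


# --------------------------------------------------------------------------
# frames, angles, location, sign rules
# --------------------------------------------------------------------------

def ring_axis(
    struct: Structure,
    selection: str,
    toward: np.ndarray | None = None,
) -> AxisFrame:
    """Best-fit-plane frame of a ring selection.

    Origin is the selection centroid; the axis is the smallest-variance
    singular direction of the centered ring coordinates (the plane
    normal).  When ``toward`` (a point on the secondary-rim side) is
    given, the axis is flipped to point at it.
    """
    pts = struct.subcoords(selection)
    if pts.shape[0] < 3:
        raise ValueError("ring selection needs >= 3 atoms")
    origin = pts.mean(axis=0)
    centered = pts - origin
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1e-30):
        raise ValueError("ring selection is collinear: plane normal undefined")
    axis = vt[2]
    if toward is not None:
        if np.dot(np.asarray(toward, dtype=float) - origin, axis) < 0:
            axis = -axis
    return AxisFrame(origin=origin, axis=axis)


def dipole_axis_angle(dipole: np.ndarray, frame: AxisFrame) -> float:
    """Acute angle (deg, in [0, 90]) between a dipole vector and the
    ring axis; the sense of either vector is immaterial."""
    d = np.asarray(dipole, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("zero dipole vector")
    cosang = abs(np.dot(d / norm, frame.axis))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def classify_location(
    point: np.ndarray,
    frame: AxisFrame,
    rim_offsets: tuple[float, float] = (0.4, 0.4),
    radial_cutoff: float = 0.4,
) -> str:
    """Inside/outside call for a chromophore centroid.

    ``rim_offsets = (below, above)`` give the cavity extent (nm) along
    the axis on either side of the origin; ``radial_cutoff`` the radial
    extent.  Boundaries are closed: a point exactly on a rim plane or
    the radial wall counts as inside.
    """
    p = np.asarray(point, dtype=float) - frame.origin
    axial = float(np.dot(p, frame.axis))
    radial = float(np.linalg.norm(p - axial * frame.axis))
    below, above = rim_offsets
    inside = (-below <= axial <= above) and radial <= radial_cutoff
    return "inside" if inside else "outside"


def orientation_weight(theta_deg: float) -> float:
    """Second Legendre polynomial of the orientation angle,
    (3 cos^2 theta - 1)/2; zero at the magic angle 54.74 deg."""
    c = np.cos(np.radians(theta_deg))
    return float((3.0 * c * c - 1.0) / 2.0)


def icd_sign(theta_deg: float, location: str, band: str | None = None) -> tuple[int, float]:
    """Kodaka-rule ICD sign and magnitude weight.

    Returns ``(sign, weight)`` where weight = (3 cos^2 theta - 1)/2 and
    sign is its sign for an included chromophore, inverted for an outside
    one, and 0 when |weight| < 1e-6 (angles within ~4e-5 deg of the
    magic-angle null, covering inputs quoted to four decimals).  ``band`` is a free
    annotation (e.g. which electronic transition the dipole belongs to);
    it does not alter the rule.
    """
    if not 0.0 <= theta_deg <= 90.0:
        raise ValueError(f"theta must be in [0, 90] deg, got {theta_deg}")
    if location not in ("inside", "outside"):
        raise ValueError("location must be 'inside' or 'outside'")
    w = orientation_weight(theta_deg)
    if abs(w) < 1e-6:
        return 0, w
    sign = 1 if w > 0 else -1
    if location == "outside":
        sign = -sign
    return sign, w


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, range (-180, 180].

    Positive for a right-handed rotation of the p3->p4 bond relative to
    p1->p2 when sighting along p2->p3 (the IUPAC convention).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if np.linalg.norm(b1) < 1e-12 or np.linalg.norm(b2) < 1e-12 or np.linalg.norm(b3) < 1e-12:
        raise ValueError("consecutive points coincide: torsion undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


# --------------------------------------------------------------------------
# pose grids, placement, energies
# --------------------------------------------------------------------------

def make_scan_grid(
    start_nm: float,
    stop_nm: float,
    step_nm: float,
    dihedrals_deg: list[float] = (0.0,),
) -> list[Pose]:
    """Inclusive-endpoint approach grid: one pose per (distance, dihedral).

    Distances run from ``start_nm`` toward ``stop_nm`` at ``step_nm``
    intervals (e.g. 2.5 to -2.5 at 0.05 gives 101 distances).  A step
    larger than the range degenerates to the single start point, with a
    warning.
    """
    if step_nm <= 0:
        raise ValueError("step must be > 0")
    span = abs(stop_nm - start_nm)
    if step_nm > span:
        warnings.warn("step exceeds scan range: single-point grid", stacklevel=2)
        distances = np.array([start_nm])
    else:
        n = int(round(span / step_nm)) + 1
        distances = np.linspace(start_nm, stop_nm, n)
    return [Pose(float(d), float(a)) for d in distances for a in dihedrals_deg]


def place_pose(mobile: Structure, frame: AxisFrame, pose: Pose) -> Structure:
    """Rigidly place the mobile body at a scan pose.

    The body is rotated by ``pose.dihedral`` about the frame axis (through
    its own centroid, so rotation and translation commute) and translated
    so its centroid sits at ``origin + displacement * axis``.  All
    intra-body distances are preserved.
    """
    rot = Rotation.from_rotvec(np.radians(pose.dihedral) * frame.axis)
    centroid = mobile.centroid()
    coords = rot.apply(mobile.coords - centroid)
    target = frame.origin + pose.displacement * frame.axis
    return replace(mobile, coords=coords + target)


def pair_energy(
    a: Structure,
    b: Structure,
    cutoff_nm: float = 2.5,
    dielectric: float = 78.5,
) -> EnergyBreakdown:
    """Coarse-grained intermolecular score: Lennard-Jones + Coulomb.

    vdw = sum 4 eps_ij [(sig_ij/r)^12 - (sig_ij/r)^6] with Lorentz-
    Berthelot combination; electrostatic = sum k_e q_i q_j /
    (dielectric r).  Pairs beyond ``cutoff_nm`` are skipped.  This is a
    generic bead score for profile shapes and minimum-energy poses, not a
    calibrated force field.
    """
    for s, name in ((a, "a"), (b, "b")):
        if s.lj_sigma is None or s.lj_epsilon is None or s.charges is None:
            raise ValueError(f"structure {name!r} lacks LJ/charge parameters")
    r = cdist(a.coords, b.coords)
    if np.any(r < 1e-6):
        raise ValueError("overlapping atoms (r < 1e-6 nm): energy singular")
    mask = r <= cutoff_nm
    sig = 0.5 * (a.lj_sigma[:, None] + b.lj_sigma[None, :])
    eps = np.sqrt(a.lj_epsilon[:, None] * b.lj_epsilon[None, :])
    qq = a.charges[:, None] * b.charges[None, :]
    with np.errstate(over="raise"):
        sr6 = (sig / r) ** 6
        vdw_terms = 4.0 * eps * (sr6 * sr6 - sr6)
        elec_terms = COULOMB_CONSTANT * qq / (dielectric * r)
    vdw = float(np.sum(vdw_terms[mask]))
    elec = float(np.sum(elec_terms[mask]))
    return EnergyBreakdown(total=vdw + elec, vdw=vdw, electrostatic=elec)


def scan_profile(
    host: Structure,
    mobile: Structure,
    frame: AxisFrame,
    grid: list[Pose],
    cutoff_nm: float = 2.5,
    dielectric: float = 78.5,
) -> ScanProfile:
    """Score every pose on the grid and select the minimum-binding-energy
    (MBE) pose.

    Ties on total energy resolve toward the larger axial separation to
    avoid picking a clash-adjacent pose.
    """
    if not grid:
        raise ValueError("empty pose grid")
    energies = [
        pair_energy(host, place_pose(mobile, frame, pose), cutoff_nm, dielectric)
        for pose in grid
    ]
    best = min(
        range(len(grid)),
        key=lambda i: (energies[i].total, -abs(grid[i].displacement)),
    )
    return ScanProfile(poses=list(grid), energies=energies, mbe_index=best)


def angle_history_stats(
    frames: list[Structure],
    dipole_selection: str,
    frame_def: AxisFrame | tuple[str, np.ndarray | None],
) -> AngleStats:
    """Dipole-axis angle statistics over a trajectory of structures.

    ``dipole_selection`` names a two-atom selection whose difference
    vector is the transition dipole.  ``frame_def`` is either a fixed
    AxisFrame or ``(ring_selection, toward)`` to rebuild the frame per
    snapshot.  Angles live on [0, 90] so a plain arithmetic mean and
    sample sd apply (no circular statistics needed).
    """
    if not frames:
        raise ValueError("need >= 1 frame")
    angles = []
    for s in frames:
        if isinstance(frame_def, AxisFrame):
            fr = frame_def
        else:
            ring_sel, toward = frame_def
            fr = ring_axis(s, ring_sel, toward=toward)
        i, j = s.selections[dipole_selection]
        angles.append(dipole_axis_angle(s.coords[j] - s.coords[i], fr))
    angles = np.asarray(angles)
    sd = float(np.std(angles, ddof=1)) if angles.size > 1 else 0.0
    return AngleStats(mean=float(np.mean(angles)), sd=sd, n=int(angles.size))


# --------------------------------------------------------------------------
# I/O: XYZ coordinates, YAML parameters, scan-profile tables
# --------------------------------------------------------------------------

def read_xyz(path: str | Path, units: str = "angstrom") -> Structure:
    """Read a plain XYZ file (count, comment, then 'label x y z' rows).

    ``units`` is 'angstrom' (converted to nm) or 'nm'.
    """
    if units not in ("angstrom", "nm"):
        raise ValueError("units must be 'angstrom' or 'nm'")
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].strip())
    labels, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        labels.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    coords = np.asarray(coords)
    if units == "angstrom":
        coords = coords * NM_PER_ANGSTROM
    return Structure(labels=labels, coords=coords)


def write_xyz(path: str | Path, struct: Structure, units: str = "angstrom",
              comment: str = "") -> None:
    if units not in ("angstrom", "nm"):
        raise ValueError("units must be 'angstrom' or 'nm'")
    coords = struct.coords / NM_PER_ANGSTROM if units == "angstrom" else struct.coords
    lines = [str(struct.n_atoms), comment]
    for lab, (x, y, z) in zip(struct.labels, coords):
        lines.append(f"{lab} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_parameters(struct: Structure, path: str | Path,
                    apply_selections: bool = True) -> Structure:
    """Attach per-label charges / LJ parameters and named selections from
    a YAML file.

    Schema::

        types:
          C: {charge: 0.0, sigma_nm: 0.35, epsilon: 0.1}
        selections:
          glycosidic_oxygens: [0, 1, 2, 3, 4, 5, 6]
    """
    spec = yaml.safe_load(Path(path).read_text())
    types = spec.get("types", {})
    n = struct.n_atoms
    charges = np.zeros(n)
    sigma = np.zeros(n)
    epsilon = np.zeros(n)
    for i, lab in enumerate(struct.labels):
        if lab not in types:
            raise ValueError(f"no parameters for atom label {lab!r}")
        t = types[lab]
        charges[i] = t.get("charge", 0.0)
        sigma[i] = t["sigma_nm"]
        epsilon[i] = t["epsilon"]
    selections = dict(struct.selections)
    if apply_selections:
        selections.update({k: list(v) for k, v in spec.get("selections", {}).items()})
    return replace(struct, charges=charges, lj_sigma=sigma,
                   lj_epsilon=epsilon, selections=selections)


def write_profile(path: str | Path, profile: ScanProfile) -> None:
    """Scan profile as delimited text:
    distance_nm,dihedral_deg,vdw,elec,total."""
    lines = ["distance_nm,dihedral_deg,vdw,elec,total"]
    for pose, e in zip(profile.poses, profile.energies):
        lines.append(
            f"{pose.displacement!r},{pose.dihedral!r},{e.vdw!r},{e.electrostatic!r},{e.total!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
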