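"""Core experiment-model types and crystal/cell mathematics.

Lab frame convention (used throughout the package):

* right-handed Cartesian frame, lengths in mm, reciprocal space in 1/angstrom;
* the nominal incident beam propagates along ``+z``;
* the nominal goniometer rotation axis lies along ``+x``; positive rotation
  angles are right-handed about that axis;
* detector panels are nominally perpendicular to the beam, with the panel
  ``fast`` axis nominally along ``+x`` and ``slow`` along ``+y``.

Angles are degrees at every public interface; radians are used internally.
Pixel coordinates are 0-based continuous ``(X fast, Y slow)`` values measured
from the outer corner of pixel ``(0, 0)``, so the centre of pixel ``(i, j)``
is at ``(i + 0.5, j + 0.5)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "EdgeomError",
    "InvalidArgumentError",
    "InvalidCellError",
    "NoSolutionError",
    "OutOfRangeError",
    "UnsupportedError",
    "SchemaError",
    "RefinementError",
    "LatticeSystem",
    "BeamModel",
    "PanelModel",
    "DetectorModel",
    "GoniometerModel",
    "ScanModel",
    "CrystalModel",
    "ScanVaryingStates",
    "ExperimentModel",
    "wavelength_from_kv",
    "xray_wavelength_from_kev",
    "metrical_from_cell",
    "cell_from_metrical",
    "b_matrix_from_metrical",
    "free_metrical_elements",
    "metrical_from_free",
    "free_from_metrical",
    "rotation_about_axis",
]

# --------------------------------------------------------------------------
# Physical constants (CODATA 2018), frozen here and nowhere else.
# --------------------------------------------------------------------------
PLANCK_H = 6.62607015e-34  # J s (exact)
ELEMENTARY_CHARGE = 1.602176634e-19  # C (exact)
SPEED_OF_LIGHT = 2.99792458e8  # m/s (exact)
ELECTRON_MASS = 9.1093837015e-31  # kg

#: hc/e expressed in keV * angstrom; lambda[A] = HC_KEV_ANGSTROM / E[keV]
HC_KEV_ANGSTROM = PLANCK_H * SPEED_OF_LIGHT / ELEMENTARY_CHARGE * 1e7


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------
class EdgeomError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EdgeomError, ValueError):
    """An argument violates a documented precondition."""


class InvalidCellError(InvalidArgumentError):
    """A unit cell is degenerate (non-positive volume) or otherwise invalid."""


class NoSolutionError(EdgeomError):
    """A geometric construction has no solution (e.g. beyond the limiting sphere)."""


class OutOfRangeError(EdgeomError, ValueError):
    """A coordinate falls outside the valid range of a panel or scan."""


class UnsupportedError(EdgeomError):
    """A requested combination of features is not supported."""


class SchemaError(EdgeomError, ValueError):
    """A serialized file violates the documented schema."""


class RefinementError(EdgeomError):
    """Refinement failed (non-finite residuals, no usable reflections, ...)."""


# --------------------------------------------------------------------------
# Small helpers
# --------------------------------------------------------------------------
def _as_unit(v: Sequence[float], name: str, tol: float = 1e-10) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise InvalidArgumentError(f"{name} must be a 3-vector, got shape {v.shape}")
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > tol:
        raise InvalidArgumentError(f"{name} must be a unit vector (|v| = {n!r})")
    return v


def rotation_about_axis(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    """Proper rotation matrix for a right-handed rotation about ``axis``.

    ``axis`` must be a unit 3-vector; ``angle_deg`` is in degrees.
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise InvalidArgumentError("rotation axis must be non-zero")
    return Rotation.from_rotvec(axis / n * math.radians(angle_deg)).as_matrix()


# --------------------------------------------------------------------------
# Wavelengths
# --------------------------------------------------------------------------
def wavelength_from_kv(accel_voltage_kv: float) -> float:
    """Relativistic de Broglie wavelength (angstrom) of electrons at ``accel_voltage_kv``.

    lambda = h / sqrt(2 m0 e V (1 + e V / (2 m0 c^2))).
    For 200 kV this evaluates to 0.02508 A.
    """
    if accel_voltage_kv <= 0:
        raise InvalidArgumentError("accelerating voltage must be positive")
    ev = ELEMENTARY_CHARGE * accel_voltage_kv * 1e3  # J
    rel = 1.0 + ev / (2.0 * ELECTRON_MASS * SPEED_OF_LIGHT**2)
    p = math.sqrt(2.0 * ELECTRON_MASS * ev * rel)
    return PLANCK_H / p * 1e10


def xray_wavelength_from_kev(energy_kev: float) -> float:
    """X-ray wavelength (angstrom) for photon energy in keV: lambda = hc/(eE)."""
    if energy_kev <= 0:
        raise InvalidArgumentError("photon energy must be positive")
    return HC_KEV_ANGSTROM / energy_kev


# --------------------------------------------------------------------------
# Cell mathematics
# --------------------------------------------------------------------------
def _real_metric_from_cell(cell: Sequence[float]) -> np.ndarray:
    a, b, c, al, be, ga = (float(x) for x in cell)
    if a <= 0 or b <= 0 or c <= 0:
        raise InvalidCellError(f"cell lengths must be positive: {cell}")
    for ang in (al, be, ga):
        if not 0.0 < ang < 180.0:
            raise InvalidCellError(f"cell angles must lie in (0, 180): {cell}")
    ca, cb, cg = (math.cos(math.radians(x)) for x in (al, be, ga))
    G = np.array(
        [
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ]
    )
    if np.linalg.det(G) <= 0:
        raise InvalidCellError(f"degenerate cell (non-positive volume): {cell}")
    return G


def metrical_from_cell(cell: Sequence[float]) -> np.ndarray:
    """Reciprocal metrical matrix g* (1/A^2) for real cell (a, b, c, alpha, beta, gamma).

    g* is the inverse of the real-space metric tensor; it is symmetric positive
    definite for any valid cell and its elements are the natural refinement
    parameters for the unit cell.
    """
    G = _real_metric_from_cell(cell)
    g_star = np.linalg.inv(G)
    return 0.5 * (g_star + g_star.T)


def cell_from_metrical(g_star: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Real-space cell (a, b, c in A; alpha, beta, gamma in deg) from g*."""
    g_star = np.asarray(g_star, dtype=float)
    _check_spd(g_star, "g_star")
    G = np.linalg.inv(g_star)
    a, b, c = (math.sqrt(G[i, i]) for i in range(3))
    al = math.degrees(math.acos(np.clip(G[1, 2] / (b * c), -1.0, 1.0)))
    be = math.degrees(math.acos(np.clip(G[0, 2] / (a * c), -1.0, 1.0)))
    ga = math.degrees(math.acos(np.clip(G[0, 1] / (a * b), -1.0, 1.0)))
    return (a, b, c, al, be, ga)


def _check_spd(m: np.ndarray, name: str) -> None:
    if m.shape != (3, 3):
        raise InvalidArgumentError(f"{name} must be 3x3, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10 * max(1.0, float(np.abs(m).max()))):
        raise InvalidArgumentError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(m)
    except np.linalg.LinAlgError as exc:
        raise InvalidArgumentError(f"{name} must be positive definite") from exc


def b_matrix_from_metrical(g_star: np.ndarray) -> np.ndarray:
    """Upper-triangular reciprocal-basis matrix B with Bt.B = g*.

    Columns of B are the reciprocal basis vectors in a crystal-fixed Cartesian
    frame (Busing-Levy convention: a* along x, b* in the x-y plane); the
    reciprocal-lattice vector of reflection hkl is ``r = U @ B @ hkl``.
    """
    g_star = np.asarray(g_star, dtype=float)
    _check_spd(g_star, "g_star")
    return np.linalg.cholesky(g_star).T


class LatticeSystem(str, enum.Enum):
    triclinic = "triclinic"
    monoclinic = "monoclinic"
    orthorhombic = "orthorhombic"
    tetragonal = "tetragonal"
    hexagonal = "hexagonal"
    cubic = "cubic"


#: order of the six independent g* elements used everywhere
_GSTAR_LABELS = ("g11", "g22", "g33", "g12", "g13", "g23")
_GSTAR_INDEX = {"g11": (0, 0), "g22": (1, 1), "g33": (2, 2), "g12": (0, 1), "g13": (0, 2), "g23": (1, 2)}

_FREE_ELEMENTS = {
    LatticeSystem.triclinic: ("g11", "g22", "g33", "g12", "g13", "g23"),
    LatticeSystem.monoclinic: ("g11", "g22", "g33", "g13"),  # b-unique, beta free
    LatticeSystem.orthorhombic: ("g11", "g22", "g33"),
    LatticeSystem.tetragonal: ("g11", "g33"),
    LatticeSystem.hexagonal: ("g11", "g33"),
    LatticeSystem.cubic: ("g11",),
}

#: real-space cell parameters free under each lattice constraint
FREE_CELL_PARAMETERS = {
    LatticeSystem.triclinic: ("a", "b", "c", "alpha", "beta", "gamma"),
    LatticeSystem.monoclinic: ("a", "b", "c", "beta"),
    LatticeSystem.orthorhombic: ("a", "b", "c"),
    LatticeSystem.tetragonal: ("a", "c"),
    LatticeSystem.hexagonal: ("a", "c"),
    LatticeSystem.cubic: ("a",),
}


def free_metrical_elements(lattice_constraint: LatticeSystem | str) -> list[str]:
    """Labels of the independent g* elements for a lattice symmetry.

    Off-list elements are either zero (orthogonal systems) or tied to a listed
    element (e.g. g22 = g11 for tetragonal; g12 = g11/2 for hexagonal).
    """
    return list(_FREE_ELEMENTS[LatticeSystem(lattice_constraint)])


def metrical_from_free(values: Sequence[float], lattice_constraint: LatticeSystem | str) -> np.ndarray:
    """Rebuild the full symmetric g* from its free elements (same order as
    :func:`free_metrical_elements`)."""
    sysname = LatticeSystem(lattice_constraint)
    labels = _FREE_ELEMENTS[sysname]
    if len(values) != len(labels):
        raise InvalidArgumentError(f"expected {len(labels)} values for {sysname.value}, got {len(values)}")
    v = dict(zip(labels, (float(x) for x in values)))
    g = np.zeros((3, 3))
    if sysname is LatticeSystem.cubic:
        v["g22"] = v["g33"] = v["g11"]
    elif sysname in (LatticeSystem.tetragonal, LatticeSystem.hexagonal):
        v["g22"] = v["g11"]
    if sysname is LatticeSystem.hexagonal:
        # gamma = 120 deg => gamma* = 60 deg => g12 = a*^2/2
        v["g12"] = 0.5 * v["g11"]
    for lbl, (i, j) in _GSTAR_INDEX.items():
        val = v.get(lbl, 0.0)
        g[i, j] = g[j, i] = val
    return g


def free_from_metrical(g_star: np.ndarray, lattice_constraint: LatticeSystem | str) -> np.ndarray:
    """Extract the free g* elements (order of :func:`free_metrical_elements`)."""
    g_star = np.asarray(g_star, dtype=float)
    labels = _FREE_ELEMENTS[LatticeSystem(lattice_constraint)]
    return np.array([g_star[_GSTAR_INDEX[lbl]] for lbl in labels])


# --------------------------------------------------------------------------
# Experiment models
# --------------------------------------------------------------------------
@dataclass
class BeamModel:
    """Incident beam: unit propagation direction (lab frame) and wavelength in A.

    The wavevector is ``s0 = direction / wavelength`` (|s0| = 1/lambda).
    """

    direction: np.ndarray
    wavelength: float

    def __post_init__(self) -> None:
        self.direction = _as_unit(self.direction, "beam direction")
        self.wavelength = float(self.wavelength)
        if self.wavelength <= 0:
            raise InvalidArgumentError("wavelength must be positive")

    @property
    def s0(self) -> np.ndarray:
        """Incident wavevector (1/A)."""
        return self.direction / self.wavelength


@dataclass
class PanelModel:
    """One rectangular detector panel.

    ``origin`` is the lab position (mm) of the outer corner of pixel (0, 0);
    continuous pixel coordinate (X, Y) maps to the lab point
    ``origin + X * pixel_size[0] * fast_axis + Y * pixel_size[1] * slow_axis``.
    """

    origin: np.ndarray
    fast_axis: np.ndarray
    slow_axis: np.ndarray
    pixel_size: tuple[float, float]
    n_pixels: tuple[int, int]  # (fast, slow)
    gain: float = 1.0
    distortion: Optional["object"] = None  # DistortionMapPair, set via image_prep

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise InvalidArgumentError("panel origin must be a 3-vector")
        self.fast_axis = _as_unit(self.fast_axis, "fast_axis")
        self.slow_axis = _as_unit(self.slow_axis, "slow_axis")
        if abs(float(self.fast_axis @ self.slow_axis)) >= 1e-8:
            raise InvalidArgumentError("fast and slow axes must be orthogonal")
        self.pixel_size = (float(self.pixel_size[0]), float(self.pixel_size[1]))
        self.n_pixels = (int(self.n_pixels[0]), int(self.n_pixels[1]))
        if min(self.pixel_size) <= 0:
            raise InvalidArgumentError("pixel sizes must be positive")
        if min(self.n_pixels) <= 0:
            raise InvalidArgumentError("pixel counts must be positive")
        self.gain = float(self.gain)
        if self.gain <= 0:
            raise InvalidArgumentError("gain must be positive")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.fast_axis, self.slow_axis)

    def lab_coord_mm(self, mm_fast, mm_slow) -> np.ndarray:
        """Lab position(s) of millimetre coordinates on this panel."""
        mm_fast = np.asarray(mm_fast, dtype=float)
        mm_slow = np.asarray(mm_slow, dtype=float)
        return (
            self.origin
            + np.multiply.outer(mm_fast, self.fast_axis)
            + np.multiply.outer(mm_slow, self.slow_axis)
        )


@dataclass
class DetectorModel:
    """Ordered list of panels; panel ids are list positions."""

    panels: list[PanelModel]

    def __post_init__(self) -> None:
        if not self.panels:
            raise InvalidArgumentError("detector must have at least one panel")

    def __getitem__(self, i: int) -> PanelModel:
        return self.panels[i]

    def __len__(self) -> int:
        return len(self.panels)


@dataclass
class GoniometerModel:
    """Single rotation axis, unit 3-vector in the lab frame.

    Positive scan angles are right-handed rotations about ``rotation_axis``;
    the inverted-handedness hypothesis is represented by negating the axis.
    """

    rotation_axis: np.ndarray

    def __post_init__(self) -> None:
        self.rotation_axis = _as_unit(self.rotation_axis, "rotation_axis")


@dataclass
class ScanModel:
    """Contiguous rotation scan: 1-based inclusive image range and oscillation.

    ``oscillation = (phi_start_deg, delta_phi_deg_per_image)``; image ``i``
    covers [phi_start + (i - first) * dphi, phi_start + (i - first + 1) * dphi].
    """

    image_range: tuple[int, int]
    oscillation: tuple[float, float]

    def __post_init__(self) -> None:
        self.image_range = (int(self.image_range[0]), int(self.image_range[1]))
        self.oscillation = (float(self.oscillation[0]), float(self.oscillation[1]))
        if self.oscillation[1] <= 0:
            raise InvalidArgumentError("delta_phi must be positive")
        if self.image_range[1] < self.image_range[0]:
            raise InvalidArgumentError("image_range must be non-decreasing")

    @property
    def n_images(self) -> int:
        return self.image_range[1] - self.image_range[0] + 1

    @property
    def phi_start(self) -> float:
        return self.oscillation[0]

    @property
    def phi_end(self) -> float:
        return self.oscillation[0] + self.n_images * self.oscillation[1]

    def phi_of_image_centre(self, image: np.ndarray | int) -> np.ndarray | float:
        """Rotation angle at the centre of (1-based, possibly fractional) image."""
        image = np.asarray(image, dtype=float)
        return self.oscillation[0] + (image - self.image_range[0] + 0.5) * self.oscillation[1]

    def image_of_phi(self, phi) -> np.ndarray:
        """0-based image index containing rotation angle phi (clipped to scan)."""
        phi = np.asarray(phi, dtype=float)
        idx = np.floor((phi - self.oscillation[0]) / self.oscillation[1]).astype(int)
        return np.clip(idx, 0, self.n_images - 1)


@dataclass
class CrystalModel:
    """Crystal orientation U (proper rotation) plus reciprocal metrical matrix g*.

    ``U`` rotates the crystal-fixed Cartesian frame of :func:`b_matrix_from_metrical`
    into the lab frame at scan angle zero: ``r(phi) = R(phi) @ U @ B @ hkl``.
    """

    U: np.ndarray
    g_star: np.ndarray
    lattice_constraint: LatticeSystem = LatticeSystem.triclinic

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.g_star = 0.5 * (np.asarray(self.g_star, dtype=float) + np.asarray(self.g_star, dtype=float).T)
        self.lattice_constraint = LatticeSystem(self.lattice_constraint)
        if self.U.shape != (3, 3):
            raise InvalidArgumentError("U must be 3x3")
        if abs(np.linalg.det(self.U) - 1.0) > 1e-9 or not np.allclose(self.U.T @ self.U, np.eye(3), atol=1e-9):
            raise InvalidArgumentError("U must be a proper rotation")
        _check_spd(self.g_star, "g_star")
        # raises InvalidCellError if the derived real cell is degenerate
        cell_from_metrical(self.g_star)

    @classmethod
    def from_cell(
        cls,
        cell: Sequence[float],
        U: Optional[np.ndarray] = None,
        lattice_constraint: LatticeSystem | str = LatticeSystem.triclinic,
    ) -> "CrystalModel":
        return cls(
            U=np.eye(3) if U is None else U,
            g_star=metrical_from_cell(cell),
            lattice_constraint=LatticeSystem(lattice_constraint),
        )

    @property
    def B(self) -> np.ndarray:
        return b_matrix_from_metrical(self.g_star)

    @property
    def cell(self) -> tuple[float, float, float, float, float, float]:
        return cell_from_metrical(self.g_star)


@dataclass
class ScanVaryingStates:
    """Per-image sampled model states (one entry per scan image).

    Any field may be None (that component is static). Shapes: ``U`` is
    (n_images, 3, 3), ``g_star`` (n_images, 3, 3), ``beam_direction``
    (n_images, 3).
    """

    U: Optional[np.ndarray] = None
    g_star: Optional[np.ndarray] = None
    beam_direction: Optional[np.ndarray] = None

    def n_images(self) -> Optional[int]:
        for arr in (self.U, self.g_star, self.beam_direction):
            if arr is not None:
                return int(np.asarray(arr).shape[0])
        return None


@dataclass
class ExperimentModel:
    """Complete description of one rotation-method diffraction experiment."""

    beam: BeamModel
    detector: DetectorModel
    goniometer: GoniometerModel
    scan: ScanModel
    crystal: CrystalModel
    scan_varying: Optional[ScanVaryingStates] = None

    def __post_init__(self) -> None:
        if self.scan_varying is not None:
            n = self.scan_varying.n_images()
            if n is not None and n != self.scan.n_images:
                raise InvalidArgumentError(
                    f"scan-varying states span {n} images but the scan has {self.scan.n_images}"
                )

    # convenience accessors used by prediction ---------------------------------
    def models_at_image(self, image_idx: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(U, B, s0) at 0-based image index, honouring scan-varying states."""
        sv = self.scan_varying
        U = self.crystal.U
        g = self.crystal.g_star
        direction = self.beam.direction
        if sv is not None:
            if sv.U is not None:
                U = sv.U[image_idx]
            if sv.g_star is not None:
                g = sv.g_star[image_idx]
            if sv.beam_direction is not None:
                direction = sv.beam_direction[image_idx]
        return U, b_matrix_from_metrical(g), direction / self.beam.wavelength
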