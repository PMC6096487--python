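"""Ewald-construction computations.

The diffraction condition for the rotation method: a reciprocal-lattice point
``r0 = U B hkl`` rotated by ``phi`` about the goniometer axis diffracts when it
lies on the Ewald sphere of radius 1/lambda centred at ``-s0``:

    |R(phi) r0 + s0| = 1/lambda    <=>    R(phi) r0 . s0 = -|r0|^2 / 2.

Decomposing r0 into components along and perpendicular to the axis turns this
into ``A cos(phi) + B sin(phi) = C`` which is solved in closed form (up to two
crossings per reflection; none for points in the blind region near the axis or
beyond the limiting sphere).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    BeamModel,
    CrystalModel,
    ExperimentModel,
    GoniometerModel,
    InvalidArgumentError,
    NoSolutionError,
    rotation_about_axis,
)
from . import image_prep

logger = logging.getLogger(__name__)

__all__ = [
    "Flags",
    "ReflectionTable",
    "two_theta",
    "ewald_crossing_angles",
    "calibrate_crossing",
    "predict_centroids",
    "predict_for_observations",
    "map_to_reciprocal_space",
    "ewald_residual",
]


class Flags(enum.IntFlag):
    """Bitset flags for reflection-table rows."""

    OBSERVED = 1
    PREDICTED = 2
    INDEXED = 4
    OUTLIER = 8
    USED_IN_REFINEMENT = 16


#: canonical column order of a reflection table
COLUMNS = [
    "h",
    "k",
    "l",
    "panel",
    "X_o",
    "Y_o",
    "phi_o",
    "var_X",
    "var_Y",
    "var_phi",
    "X_c",
    "Y_c",
    "phi_c",
    "flags",
]


class ReflectionTable:
    """Observed and predicted reflection centroids (X px, Y px, phi deg).

    Thin wrapper over a :class:`pandas.DataFrame` with the canonical columns;
    missing columns are filled (NaN for floats, 0 for flags). Variances are in
    px^2 / deg^2.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in COLUMNS:
            if col not in df.columns:
                if col in ("h", "k", "l", "panel", "flags"):
                    df[col] = 0
                else:
                    df[col] = np.nan
        df = df[COLUMNS]
        for col in ("h", "k", "l", "panel", "flags"):
            df[col] = df[col].astype(np.int64)
        for col in ("var_X", "var_Y", "var_phi"):
            bad = df[col].to_numpy() < 0
            if np.any(bad):
                raise InvalidArgumentError(f"negative variances in column {col}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def hkl(self) -> np.ndarray:
        return self.df[["h", "k", "l"]].to_numpy()

    def has_flag(self, flag: Flags) -> np.ndarray:
        return (self.df["flags"].to_numpy() & int(flag)) != 0

    def set_flag(self, flag: Flags, mask=None) -> None:
        if mask is None:
            self.df["flags"] |= int(flag)
        else:
            self.df.loc[np.asarray(mask), "flags"] |= int(flag)

    def unset_flag(self, flag: Flags, mask=None) -> None:
        inv = ~np.int64(int(flag))
        if mask is None:
            self.df["flags"] &= inv
        else:
            self.df.loc[np.asarray(mask), "flags"] &= inv

    def select(self, mask) -> "ReflectionTable":
        return ReflectionTable(self.df[np.asarray(mask)])

    def copy(self) -> "ReflectionTable":
        return ReflectionTable(self.df)


# --------------------------------------------------------------------------
# Scattering angles
# --------------------------------------------------------------------------
def two_theta(d_spacing: float, wavelength: float) -> float:
    """Scattering angle 2*theta (deg) from Bragg's law: 2 theta = 2 asin(lambda/2d)."""
    if d_spacing <= 0:
        raise InvalidArgumentError("d-spacing must be positive")
    if wavelength <= 0:
        raise InvalidArgumentError("wavelength must be positive")
    s = wavelength / (2.0 * d_spacing)
    if s > 1.0:
        raise NoSolutionError(
            f"d = {d_spacing} A is beyond the limiting sphere for lambda = {wavelength} A"
        )
    return math.degrees(2.0 * math.asin(s))


# --------------------------------------------------------------------------
# Crossing angles (closed form)
# --------------------------------------------------------------------------
def _crossing_terms(r0: np.ndarray, axis: np.ndarray, s0: np.ndarray):
    """Coefficients of A cos(phi) + B sin(phi) = C for the Ewald condition.

    ``r0`` may be (..., 3); ``s0`` broadcasts against it.
    """
    e = axis
    a_par = r0 @ e
    e_dot_s0 = s0 @ e if s0.ndim == 1 else np.einsum("...i,i->...", s0, e)
    A = np.einsum("...i,...i->...", r0 - np.multiply.outer(a_par, e), s0)
    B = np.einsum("...i,...i->...", np.cross(np.broadcast_to(e, r0.shape), r0), s0)
    C = -0.5 * np.einsum("...i,...i->...", r0, r0) - a_par * e_dot_s0
    return A, B, C


def _solve_crossings(A, B, C, clip: bool = False):
    """Both solutions of A cos(phi) + B sin(phi) = C, in degrees mod 360.

    Returns (phi1, phi2, valid). With ``clip`` the acos argument is clamped to
    [-1, 1] so tangent reflections degenerate gracefully instead of vanishing.
    """
    rad = np.hypot(A, B)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(rad > 0, C / np.where(rad > 0, rad, 1.0), np.inf)
    valid = np.abs(u) <= 1.0
    if clip:
        near = np.isfinite(u)
        u = np.clip(u, -1.0, 1.0)
        valid = near
    delta = np.arctan2(B, A)
    half = np.arccos(np.clip(u, -1.0, 1.0))
    phi1 = np.degrees(delta + half) % 360.0
    phi2 = np.degrees(delta - half) % 360.0
    return phi1, phi2, valid


def _rotate_about(axis: np.ndarray, phi_deg, vec: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of ``vec`` (..., 3) by per-element angles about ``axis``."""
    phi = np.radians(np.asarray(phi_deg, dtype=float))
    e = axis
    c = np.cos(phi)[..., None]
    s = np.sin(phi)[..., None]
    par = np.multiply.outer(vec @ e, e)
    return par + c * (vec - par) + s * np.cross(np.broadcast_to(e, vec.shape), vec)


def ewald_crossing_angles(
    crystal: CrystalModel,
    beam: BeamModel,
    goniometer: GoniometerModel,
    hkl: Sequence[int],
    entering_only: bool = False,
) -> list[float]:
    """All rotation angles phi in [0, 360) at which ``hkl`` crosses the Ewald sphere.

    Empty for reflections in the blind region (parallel to the axis) or beyond
    the limiting sphere. With ``entering_only`` only the crossing at which the
    point moves from outside to inside the sphere is returned; for a collinear
    family of reflections this selects a consistent branch, so the angles are
    directly comparable across the family.
    """
    hkl = np.asarray(hkl, dtype=float)
    if np.all(hkl == 0):
        raise InvalidArgumentError("hkl must not be (0, 0, 0)")
    r0 = crystal.U @ crystal.B @ hkl
    A, B, C = _crossing_terms(r0[None, :], goniometer.rotation_axis, beam.s0)
    phi1, phi2, valid = _solve_crossings(A, B, C)
    if not valid[0]:
        return []
    sols = sorted({round(float(phi1[0]), 12) % 360.0, round(float(phi2[0]), 12) % 360.0})
    if entering_only:
        sols = [p for p in sols if _entering(r0[None], goniometer.rotation_axis, beam.s0, [p])[0]]
    return [float(p) for p in sols]


def _entering(r0: np.ndarray, axis: np.ndarray, s0: np.ndarray, phi_deg) -> np.ndarray:
    """True where the relp is moving from outside to inside the sphere at phi."""
    r = _rotate_about(axis, phi_deg, r0)
    drdphi = np.cross(np.broadcast_to(axis, r.shape), r)
    return np.einsum("...i,...i->...", drdphi, s0) < 0


def calibrate_crossing(
    crystal: CrystalModel,
    beam: BeamModel,
    goniometer: GoniometerModel,
    hkl: Sequence[int],
    phi_target: float,
) -> CrystalModel:
    """Pre-rotate the crystal about the goniometer axis so that the *entering*
    crossing of ``hkl`` occurs at ``phi_target`` (deg).

    Printed crossing angles embed an arbitrary starting orientation; only
    differences between crossing angles are orientation-free. This helper
    fixes the gauge so that absolute angles become comparable.
    """
    sols = ewald_crossing_angles(crystal, beam, goniometer, hkl)
    if not sols:
        raise NoSolutionError(f"reflection {tuple(hkl)} never crosses the Ewald sphere")
    r0 = crystal.U @ crystal.B @ np.asarray(hkl, dtype=float)
    axis = goniometer.rotation_axis
    entering = [p for p in sols if _entering(r0[None], axis, beam.s0, [p])[0]]
    phi0 = entering[0] if entering else sols[0]
    delta = phi0 - float(phi_target)
    U_new = rotation_about_axis(axis, delta) @ crystal.U
    return CrystalModel(U=U_new, g_star=crystal.g_star, lattice_constraint=crystal.lattice_constraint)


# --------------------------------------------------------------------------
# Centroid prediction
# --------------------------------------------------------------------------
def _intersect_panel(panel, s1: np.ndarray):
    """Intersect rays ``s1`` (n, 3) from the origin with one panel plane.

    Returns (mm_fast, mm_slow, ok); ``ok`` is False for rays parallel to the
    plane or hitting it from behind.
    """
    n_hat = panel.normal
    denom = s1 @ n_hat
    d0 = float(panel.origin @ n_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(np.abs(denom) > 1e-12, d0 / np.where(denom != 0, denom, 1.0), np.nan)
    ok = np.isfinite(t) & (t > 0)
    p = t[:, None] * s1
    rel = p - panel.origin
    mm_fast = rel @ panel.fast_axis
    mm_slow = rel @ panel.slow_axis
    return mm_fast, mm_slow, ok


def predict_centroids(
    experiment: ExperimentModel,
    hkl_list: np.ndarray,
) -> ReflectionTable:
    """Predict (X_c, Y_c px; phi_c deg) for every Ewald crossing inside the scan.

    Each crossing is intersected with the panels in order; the first panel
    whose pixel bounds contain the intersection receives the record (with the
    panel's distortion maps applied when attached). Crossings at the scan
    boundaries are included (closed interval). Reflections missing every panel
    are dropped and counted in the log.
    """
    hkl_list = np.atleast_2d(np.asarray(hkl_list, dtype=int))
    scan = experiment.scan
    axis = experiment.goniometer.rotation_axis

    records: list[pd.DataFrame] = []
    n_off_panel = 0
    n_parallel = 0

    sv = experiment.scan_varying
    if sv is None:
        image_groups = [(None, scan.phi_start, scan.phi_end)]
    else:
        dphi = scan.oscillation[1]
        image_groups = [
            (i, scan.phi_start + i * dphi, scan.phi_start + (i + 1) * dphi)
            for i in range(scan.n_images)
        ]

    hklf = hkl_list.astype(float)
    nonzero = ~np.all(hkl_list == 0, axis=1)

    for img, lo, hi in image_groups:
        U, B, s0 = experiment.models_at_image(0 if img is None else img)
        r0 = hklf @ (U @ B).T
        A, Bc, C = _crossing_terms(r0, axis, s0)
        phi1, phi2, valid = _solve_crossings(A, Bc, C)
        for phis in (phi1, phi2):
            # bring each solution into the scan's angular window (scan may
            # exceed 360 deg in principle; here a single unwrap suffices)
            cand = phis.copy()
            cand = np.where(cand < lo - 1e-9, cand + 360.0 * np.ceil((lo - cand) / 360.0), cand)
            sel = valid & nonzero & (cand >= lo - 1e-9) & (cand <= hi + 1e-9)
            if not np.any(sel):
                continue
            idx = np.where(sel)[0]
            phi_sel = cand[idx]
            r = _rotate_about(axis, phi_sel, r0[idx])
            s1 = r + s0
            assigned = np.zeros(len(idx), dtype=bool)
            out = np.full((len(idx), 3), np.nan)
            panel_id = np.full(len(idx), -1, dtype=int)
            for pid, panel in enumerate(experiment.detector.panels):
                mm_f, mm_s, ok = _intersect_panel(panel, s1)
                n_parallel += int(np.sum(~ok & ~assigned))
                X, Y = image_prep.mm_to_px(panel, mm_f, mm_s)
                inb = (
                    ok
                    & (X >= 0)
                    & (X <= panel.n_pixels[0])
                    & (Y >= 0)
                    & (Y <= panel.n_pixels[1])
                )
                take = inb & ~assigned
                out[take, 0] = X[take]
                out[take, 1] = Y[take]
                panel_id[take] = pid
                assigned |= inb
            n_off_panel += int(np.sum(~assigned))
            keep = assigned
            if not np.any(keep):
                continue
            records.append(
                pd.DataFrame(
                    {
                        "h": hkl_list[idx[keep], 0],
                        "k": hkl_list[idx[keep], 1],
                        "l": hkl_list[idx[keep], 2],
                        "panel": panel_id[keep],
                        "X_c": out[keep, 0],
                        "Y_c": out[keep, 1],
                        "phi_c": phi_sel[keep],
                        "flags": int(Flags.PREDICTED),
                    }
                )
            )

    if n_off_panel or n_parallel:
        logger.info(
            "prediction dropped %d reflections missing all panels, %d parallel rays",
            n_off_panel,
            n_parallel,
        )
    if not records:
        return ReflectionTable(pd.DataFrame(columns=COLUMNS))
    df = pd.concat(records, ignore_index=True)
    df = df.drop_duplicates(subset=["h", "k", "l", "phi_c"]).reset_index(drop=True)
    return ReflectionTable(df)


def predict_for_observations(
    experiment: ExperimentModel,
    obs: ReflectionTable,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predict (X_c, Y_c, phi_c) matched one-to-one to observed centroids.

    For each observation the Ewald crossing nearest to ``phi_o`` is chosen and
    intersected with the observation's own panel plane (no pixel-bound or scan
    filtering), which keeps the residual vector a smooth function of the model
    parameters for finite-difference derivatives. ``phi_c`` is returned on the
    branch continuous with ``phi_o`` (not wrapped to [0, 360)).
    """
    df = obs.df
    n = len(df)
    hkl = df[["h", "k", "l"]].to_numpy(dtype=float)
    phi_o = df["phi_o"].to_numpy(dtype=float)
    panel_ids = df["panel"].to_numpy(dtype=int)
    axis = experiment.goniometer.rotation_axis

    sv = experiment.scan_varying
    if sv is None:
        U, B, s0 = experiment.models_at_image(0)
        UB = np.broadcast_to(U @ B, (n, 3, 3))
        s0_arr = np.broadcast_to(s0, (n, 3))
    else:
        img = experiment.scan.image_of_phi(phi_o)
        UB = np.empty((n, 3, 3))
        s0_arr = np.empty((n, 3))
        for i in np.unique(img):
            Ui, Bi, s0i = experiment.models_at_image(int(i))
            sel = img == i
            UB[sel] = Ui @ Bi
            s0_arr[sel] = s0i

    r0 = np.einsum("nij,nj->ni", UB, hkl)
    A, Bc, C = _crossing_terms(r0, axis, s0_arr)
    phi1, phi2, _ = _solve_crossings(A, Bc, C, clip=True)

    def _near(phi_sol):
        d = (phi_sol - phi_o + 180.0) % 360.0 - 180.0
        return phi_o + d, np.abs(d)

    p1, d1 = _near(phi1)
    p2, d2 = _near(phi2)
    phi_c = np.where(d1 <= d2, p1, p2)

    r = _rotate_about(axis, phi_c, r0)
    s1 = r + s0_arr

    X_c = np.full(n, np.nan)
    Y_c = np.full(n, np.nan)
    for pid in np.unique(panel_ids):
        panel = experiment.detector[int(pid)]
        sel = panel_ids == pid
        mm_f, mm_s, ok = _intersect_panel(panel, s1[sel])
        X, Y = image_prep.mm_to_px(panel, mm_f, mm_s)
        X_c[sel] = np.where(ok, X, np.nan)
        Y_c[sel] = np.where(ok, Y, np.nan)
    return X_c, Y_c, phi_c


def ewald_residual(experiment: ExperimentModel, table: ReflectionTable) -> np.ndarray:
    """Dimensionless Ewald-condition residual ``| |r+s0| - 1/lambda | * lambda``
    for each predicted record (static models)."""
    U, B, s0 = experiment.models_at_image(0)
    r0 = table.hkl.astype(float) @ (U @ B).T
    r = _rotate_about(experiment.goniometer.rotation_axis, table.df["phi_c"].to_numpy(), r0)
    return np.abs(np.linalg.norm(r + s0, axis=1) - 1.0 / experiment.beam.wavelength) * experiment.beam.wavelength


def assign_indices(
    obs: ReflectionTable,
    experiment: ExperimentModel,
    invert_axis: bool = False,
    tolerance: float = 0.3,
) -> ReflectionTable:
    """Nearest-integer Miller-index assignment given a known crystal model.

    Observed centroids are mapped into the crystal frame, expressed in
    fractional reciprocal coordinates ``(U B)^-1 (s1 - s0)`` and rounded.
    Rows whose fractional indices deviate from integers by more than
    ``tolerance`` in any component are left unindexed. This is plumbing for
    models that are already known; basis determination is out of scope.
    """
    pts = map_to_reciprocal_space(obs, experiment, invert_axis)
    UB = experiment.crystal.U @ experiment.crystal.B
    frac = np.linalg.solve(UB, pts.T).T
    hkl = np.rint(frac).astype(int)
    ok = np.all(np.abs(frac - hkl) <= tolerance, axis=1) & np.any(hkl != 0, axis=1)
    out = obs.copy()
    out.df.loc[ok, ["h", "k", "l"]] = hkl[ok]
    out.set_flag(Flags.INDEXED, ok)
    out.unset_flag(Flags.INDEXED, ~ok)
    return out


# --------------------------------------------------------------------------
# Mapping observations into reciprocal space
# --------------------------------------------------------------------------
def map_to_reciprocal_space(
    obs: ReflectionTable,
    experiment: ExperimentModel,
    invert_axis: bool = False,
) -> np.ndarray:
    """Map observed centroids to crystal-fixed reciprocal-space vectors (1/A).

    Each observation's scattering vector ``s1 - s0`` (from its panel position
    and the wavelength) is rotated by ``-phi_o`` about the goniometer axis
    (negated when ``invert_axis``), undoing the scan rotation. With the wrong
    handedness the reconstructed lattice of an X-ray experiment acquires a
    distinct curvature; for the near-flat Ewald sphere of electron diffraction
    both choices give almost identical, nearly regular lattices.
    """
    df = obs.df
    axis = -experiment.goniometer.rotation_axis if invert_axis else experiment.goniometer.rotation_axis
    lam = experiment.beam.wavelength
    s0 = experiment.beam.s0
    n = len(df)
    out = np.empty((n, 3))
    panel_ids = df["panel"].to_numpy(dtype=int)
    for pid in np.unique(panel_ids):
        panel = experiment.detector[int(pid)]
        sel = panel_ids == pid
        mm_f, mm_s = image_prep.px_to_mm(
            panel, df["X_o"].to_numpy()[sel], df["Y_o"].to_numpy()[sel]
        )
        lab = panel.lab_coord_mm(mm_f, mm_s)
        s1 = lab / np.linalg.norm(lab, axis=1, keepdims=True) / lam
        out[sel] = s1 - s0
    return _rotate_about(axis, -df["phi_o"].to_numpy(dtype=float), out)
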