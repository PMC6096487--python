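"""Global static and scan-varying refinement of diffraction geometry.

The model is refined against observed centroids (X px, Y px, phi deg) by
nonlinear least squares. Each step solves the linearized subproblem
``J dp = -dr`` where the residual vector ``dr`` contains first the
(X - X_o) components, then (Y - Y_o), then (phi - phi_o), and ``J`` is the
Jacobian of the residuals with respect to the free parameters, built by
central finite differences. Rows are weighted by the inverse standard
deviation of each centroid coordinate.

Parameters and units
--------------------
===========  =============================================================
label        meaning
===========  =============================================================
mu1, mu2     beam-direction rotations (mrad): mu1 about the goniometer
             axis (fixed by default -- it is nearly degenerate with a
             crystal setting rotation), mu2 about the axis perpendicular
             to both the goniometer axis and the beam
phi1..phi3   crystal orientation missets (mrad) about the lab x, y, z axes
             applied ahead of the initial orientation U0
g11..g23     free reciprocal metrical matrix elements for the lattice
             symmetry; parameter value = g* element (1/A^2) times 1e5 so
             all Jacobian columns have comparable natural magnitudes
dist         detector translation along the reference panel normal (mm)
shift1/2     detector translations along the reference fast/slow axes (mm)
tau1..tau3   detector rotations (mrad) about the reference normal, fast
             and slow axes, acting about the detector centre
===========  =============================================================

The default free set for a single-panel experiment is 6 detector + 1 beam +
3 orientation + n_cell parameters (13 for an orthorhombic crystal).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .geometry import (
    FREE_CELL_PARAMETERS,
    BeamModel,
    CrystalModel,
    DetectorModel,
    ExperimentModel,
    GoniometerModel,
    InvalidArgumentError,
    LatticeSystem,
    PanelModel,
    RefinementError,
    ScanModel,
    ScanVaryingStates,
    UnsupportedError,
    cell_from_metrical,
    free_from_metrical,
    free_metrical_elements,
    metrical_from_free,
    rotation_about_axis,
)
from .prediction import Flags, ReflectionTable, predict_for_observations, _rotate_about

__all__ = [
    "GSTAR_PARAM_SCALE",
    "GaussianSmoother",
    "smoother_value",
    "Parameterisation",
    "build_parameterisation",
    "JacobianBundle",
    "RestraintSpec",
    "residuals_and_jacobian",
    "add_restraints",
    "levenberg_marquardt",
    "ConvergenceReport",
    "reject_outliers",
    "RefinementProtocol",
    "RefineResult",
    "refine",
]

#: parameter value = g* element * GSTAR_PARAM_SCALE
GSTAR_PARAM_SCALE = 1e5

_DETECTOR_LABELS = ("dist", "shift1", "shift2", "tau1", "tau2", "tau3")
_BEAM_LABELS = ("mu1", "mu2")
_ORIENTATION_LABELS = ("phi1", "phi2", "phi3")

#: characteristic scale per parameter family (finite-difference steps are
#: 1e-4 of these): 1 mrad for angles, 1e-6 1/A^2 for g* (= 0.1 in scaled
#: parameter units), 0.01 mm for detector translations
_CHAR_SCALE = {"angle": 1.0, "gstar": 1e-6 * GSTAR_PARAM_SCALE, "length": 0.01}
_FD_FRACTION = 1e-4

_CELL_PARAM_NAMES = ("a", "b", "c", "alpha", "beta", "gamma")


def _char_scale(label: str) -> float:
    base = label.split("[")[0]
    if base in ("dist", "shift1", "shift2"):
        return _CHAR_SCALE["length"]
    if base.startswith("g"):
        return _CHAR_SCALE["gstar"]
    return _CHAR_SCALE["angle"]


# --------------------------------------------------------------------------
# Gaussian smoother
# --------------------------------------------------------------------------
class GaussianSmoother:
    """Smooth interpolation of per-parameter sample values across a scan.

    ``n_samples >= 2`` sample points are evenly spaced over the scan
    (endpoints included) at normalized positions 0 .. n-1. The value at
    fractional scan position x in [0, 1] uses Gaussian weights
    ``w_i = exp(-(d_i / sigma)^2)`` with ``d_i`` the distance to sample i in
    sample-spacing units, restricted to the nearest 3 samples (all samples
    when n <= 3), normalized to sum to 1.
    """

    def __init__(self, n_samples: int, sigma: float = 1.0):
        if n_samples < 2:
            raise InvalidArgumentError("a smoother needs at least 2 sample points")
        if sigma <= 0:
            raise InvalidArgumentError("smoothing width must be positive")
        self.n_samples = int(n_samples)
        self.sigma = float(sigma)

    def weights(self, x) -> np.ndarray:
        """Normalized interpolation weights, shape (len(x), n_samples)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = x * (self.n_samples - 1)  # position in sample-spacing units
        pos = np.arange(self.n_samples, dtype=float)
        d = z[:, None] - pos[None, :]
        w = np.exp(-((d / self.sigma) ** 2))
        if self.n_samples > 3:
            order = np.argsort(np.abs(d), axis=1)
            keep = np.zeros_like(w, dtype=bool)
            np.put_along_axis(keep, order[:, :3], True, axis=1)
            w = np.where(keep, w, 0.0)
        return w / w.sum(axis=1, keepdims=True)


def smoother_value(smoother: GaussianSmoother, sample_values: Sequence[float], position) -> np.ndarray | float:
    """Interpolated value(s) at fractional scan position(s) in [0, 1]."""
    vals = np.asarray(sample_values, dtype=float)
    if vals.shape != (smoother.n_samples,):
        raise InvalidArgumentError("sample_values length must equal n_samples")
    out = smoother.weights(position) @ vals
    return float(out[0]) if np.isscalar(position) else out


# --------------------------------------------------------------------------
# Parameterisation
# --------------------------------------------------------------------------
@dataclass
class _ParamEntry:
    label: str
    n_samples: int  # 1 = static
    start: np.ndarray  # shape (n_samples,)


class Parameterisation:
    """Maps a flat parameter vector to a full :class:`ExperimentModel`.

    Holds the reference models captured at construction; parameter values are
    offsets from those models (angles, detector) or absolute scaled g*
    elements (cell). Scan-varying parameters carry ``n_samples`` smoother
    sub-parameters each.
    """

    def __init__(
        self,
        experiment: ExperimentModel,
        fix: Iterable[str] = (),
        scan_varying: Optional[Mapping[str, int]] = None,
        free: Iterable[str] = (),
        smoother_sigma: float = 1.0,
    ):
        self.experiment = experiment
        self.smoother_sigma = float(smoother_sigma)
        scan_varying = dict(scan_varying or {})

        cell_labels = free_metrical_elements(experiment.crystal.lattice_constraint)
        self._cell_labels = tuple(cell_labels)
        all_labels = list(_DETECTOR_LABELS + _BEAM_LABELS + _ORIENTATION_LABELS) + list(cell_labels)

        fixed = set(self._expand_groups(fix, cell_labels))
        for lbl in fixed - set(all_labels):
            raise InvalidArgumentError(f"unknown parameter label {lbl!r}; valid: {all_labels}")
        for lbl in set(scan_varying) - set(all_labels):
            raise InvalidArgumentError(f"unknown scan-varying label {lbl!r}; valid: {all_labels}")
        # mu1 is fixed by default (degenerate with a crystal setting rotation)
        if "mu1" not in free and "mu1" not in scan_varying:
            fixed.add("mu1")

        # reference models
        self._U0 = experiment.crystal.U.copy()
        self._g0_free = free_from_metrical(experiment.crystal.g_star, experiment.crystal.lattice_constraint)
        self._dir0 = experiment.beam.direction.copy()
        axis = experiment.goniometer.rotation_axis
        self._mu1_axis = axis.copy()
        n2 = np.cross(axis, self._dir0)
        nrm = np.linalg.norm(n2)
        if nrm < 1e-8:  # beam parallel to the rotation axis: pick any normal
            n2 = np.cross(self._dir0, [1.0, 0.0, 0.0])
            nrm = np.linalg.norm(n2)
        self._mu2_axis = n2 / nrm
        det = experiment.detector
        ref = det[0]
        self._det_f0 = ref.fast_axis.copy()
        self._det_s0 = ref.slow_axis.copy()
        self._det_n0 = ref.normal.copy()
        centres = [
            p.origin
            + 0.5 * p.n_pixels[0] * p.pixel_size[0] * p.fast_axis
            + 0.5 * p.n_pixels[1] * p.pixel_size[1] * p.slow_axis
            for p in det.panels
        ]
        self._det_c0 = np.mean(centres, axis=0)
        self._det_ref = [(p.origin.copy(), p.fast_axis.copy(), p.slow_axis.copy()) for p in det.panels]

        # free-parameter bookkeeping
        self.entries: list[_ParamEntry] = []
        start_of = {lbl: 0.0 for lbl in all_labels}
        for lbl, g0 in zip(cell_labels, self._g0_free):
            start_of[lbl] = g0 * GSTAR_PARAM_SCALE
        for lbl in all_labels:
            if lbl in fixed:
                continue
            n = int(scan_varying.get(lbl, 1))
            if n < 1:
                raise InvalidArgumentError("n_samples must be >= 1")
            self.entries.append(_ParamEntry(lbl, n, np.full(n, start_of[lbl])))
        if not self.entries:
            raise InvalidArgumentError("at least one parameter must be free")
        if any(e.label in cell_labels and e.n_samples > 1 for e in self.entries):
            self._cell_scan_varying = True
        else:
            self._cell_scan_varying = False

        # per-image smoother weights, built once
        n_img = experiment.scan.n_images
        x = (np.arange(n_img) + 0.5) / n_img
        self._img_weights: dict[int, np.ndarray] = {}
        for e in self.entries:
            if e.n_samples > 1 and e.n_samples not in self._img_weights:
                self._img_weights[e.n_samples] = GaussianSmoother(e.n_samples, self.smoother_sigma).weights(x)

    @staticmethod
    def _expand_groups(labels: Iterable[str], cell_labels: Sequence[str]) -> list[str]:
        out: list[str] = []
        for lbl in labels:
            if lbl == "detector":
                out.extend(_DETECTOR_LABELS)
            elif lbl == "beam":
                out.extend(_BEAM_LABELS)
            elif lbl == "cell":
                out.extend(cell_labels)
            else:
                out.append(lbl)
        return out

    # -- vector interface ---------------------------------------------------
    @property
    def labels(self) -> list[str]:
        out = []
        for e in self.entries:
            if e.n_samples == 1:
                out.append(e.label)
            else:
                out.extend(f"{e.label}[{i}]" for i in range(e.n_samples))
        return out

    @property
    def n_free(self) -> int:
        return sum(e.n_samples for e in self.entries)

    def start_values(self) -> np.ndarray:
        return np.concatenate([e.start for e in self.entries])

    def fd_steps(self) -> np.ndarray:
        return np.array([_FD_FRACTION * _char_scale(lbl) for lbl in self.labels])

    def is_scan_varying(self) -> bool:
        return any(e.n_samples > 1 for e in self.entries)

    @property
    def cell_scan_varying(self) -> bool:
        return self._cell_scan_varying

    def _split(self, values: np.ndarray) -> dict[str, np.ndarray]:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_free,):
            raise InvalidArgumentError(f"expected {self.n_free} values, got {values.shape}")
        out = {}
        i = 0
        for e in self.entries:
            out[e.label] = values[i : i + e.n_samples]
            i += e.n_samples
        return out

    def _per_image(self, sub: np.ndarray) -> np.ndarray:
        """Per-image values of one parameter (constant if static)."""
        if len(sub) == 1:
            return np.full(self.experiment.scan.n_images, sub[0])
        return self._img_weights[len(sub)] @ sub

    # -- model composition --------------------------------------------------
    def _compose_U(self, p1, p2, p3) -> np.ndarray:
        """Orientation from misset angles (mrad, arrays broadcast together)."""
        from scipy.spatial.transform import Rotation

        ang = np.stack(np.broadcast_arrays(np.asarray(p3), np.asarray(p2), np.asarray(p1)), axis=-1) * 1e-3
        R = Rotation.from_euler("zyx", ang.reshape(-1, 3)).as_matrix()
        return R.reshape(ang.shape[:-1] + (3, 3)) @ self._U0

    def _compose_beam_dir(self, mu1, mu2) -> np.ndarray:
        d = np.broadcast_to(self._dir0, np.shape(mu1) + (3,)) if np.ndim(mu1) else self._dir0
        d = _rotate_about(self._mu1_axis, np.degrees(np.asarray(mu1) * 1e-3), d)
        return _rotate_about(self._mu2_axis, np.degrees(np.asarray(mu2) * 1e-3), d)

    def _compose_detector(self, vals: Mapping[str, np.ndarray]) -> DetectorModel:
        def v(lbl):
            arr = vals.get(lbl)
            return float(arr[0]) if arr is not None else 0.0

        R = (
            rotation_about_axis(self._det_n0, math.degrees(v("tau1") * 1e-3))
            @ rotation_about_axis(self._det_f0, math.degrees(v("tau2") * 1e-3))
            @ rotation_about_axis(self._det_s0, math.degrees(v("tau3") * 1e-3))
        )
        t = v("shift1") * self._det_f0 + v("shift2") * self._det_s0 + v("dist") * self._det_n0
        panels = []
        for p, (o0, f0, s0) in zip(self.experiment.detector.panels, self._det_ref):
            panels.append(
                PanelModel(
                    origin=self._det_c0 + R @ (o0 - self._det_c0) + t,
                    fast_axis=R @ f0,
                    slow_axis=R @ s0,
                    pixel_size=p.pixel_size,
                    n_pixels=p.n_pixels,
                    gain=p.gain,
                    distortion=p.distortion,
                )
            )
        return DetectorModel(panels)

    def build_experiment(self, values: np.ndarray) -> ExperimentModel:
        """Rebuild a full experiment model from a flat parameter vector."""
        vals = self._split(values)
        exp = self.experiment

        def get(lbl):
            return vals.get(lbl, np.array([0.0]))

        sv_needed = self.is_scan_varying()
        detector = self._compose_detector(vals)

        # static components
        mu1_s, mu2_s = get("mu1"), get("mu2")
        p1_s, p2_s, p3_s = get("phi1"), get("phi2"), get("phi3")
        cell_sub = [vals.get(lbl) for lbl in self._cell_labels]
        g_free_static = np.array(
            [
                (sub[0] / GSTAR_PARAM_SCALE) if sub is not None else g0
                for sub, g0 in zip(cell_sub, self._g0_free)
            ]
        )
        g_static = metrical_from_free(g_free_static, exp.crystal.lattice_constraint)
        U_static = self._compose_U(
            float(p1_s[0]) if len(p1_s) == 1 else 0.0,
            float(p2_s[0]) if len(p2_s) == 1 else 0.0,
            float(p3_s[0]) if len(p3_s) == 1 else 0.0,
        )
        beam_dir_static = self._compose_beam_dir(
            float(mu1_s[0]) if len(mu1_s) == 1 else 0.0,
            float(mu2_s[0]) if len(mu2_s) == 1 else 0.0,
        )

        sv = None
        if sv_needed:
            n_img = exp.scan.n_images
            U_arr = g_arr = beam_arr = None
            if any(len(get(l)) > 1 for l in _ORIENTATION_LABELS):
                U_arr = self._compose_U(
                    self._per_image(p1_s), self._per_image(p2_s), self._per_image(p3_s)
                )
            if any(sub is not None and len(sub) > 1 for sub in cell_sub):
                g_free_img = np.stack(
                    [
                        self._per_image(sub) / GSTAR_PARAM_SCALE if sub is not None else np.full(n_img, g0)
                        for sub, g0 in zip(cell_sub, self._g0_free)
                    ],
                    axis=1,
                )
                g_arr = np.stack(
                    [metrical_from_free(row, exp.crystal.lattice_constraint) for row in g_free_img]
                )
            if any(len(get(l)) > 1 for l in _BEAM_LABELS):
                beam_arr = self._compose_beam_dir(self._per_image(mu1_s), self._per_image(mu2_s))
            sv = ScanVaryingStates(U=U_arr, g_star=g_arr, beam_direction=beam_arr)

        return ExperimentModel(
            beam=BeamModel(direction=beam_dir_static, wavelength=exp.beam.wavelength),
            detector=detector,
            goniometer=GoniometerModel(rotation_axis=exp.goniometer.rotation_axis.copy()),
            scan=ScanModel(image_range=exp.scan.image_range, oscillation=exp.scan.oscillation),
            crystal=CrystalModel(
                U=U_static, g_star=g_static, lattice_constraint=exp.crystal.lattice_constraint
            ),
            scan_varying=sv,
        )

    def cell_of(self, values: np.ndarray) -> tuple[float, ...]:
        """Real-space cell implied by the (static) cell parameters in ``values``."""
        vals = self._split(values)
        g_free = np.array(
            [
                (vals[lbl][0] / GSTAR_PARAM_SCALE) if lbl in vals else g0
                for lbl, g0 in zip(self._cell_labels, self._g0_free)
            ]
        )
        return cell_from_metrical(metrical_from_free(g_free, self.experiment.crystal.lattice_constraint))


def build_parameterisation(
    experiment: ExperimentModel,
    fix: Iterable[str] = (),
    scan_varying: Optional[Mapping[str, int]] = None,
    free: Iterable[str] = (),
) -> Parameterisation:
    """Construct a :class:`Parameterisation` for an experiment.

    ``fix`` accepts individual labels or the groups ``"detector"``,
    ``"beam"``, ``"cell"``; ``scan_varying`` maps labels to smoother sample
    counts; ``free`` lifts the default fixing of ``mu1``. The default static
    single-panel set has 13 free parameters for an orthorhombic crystal.
    """
    return Parameterisation(experiment, fix=fix, scan_varying=scan_varying, free=free)


# --------------------------------------------------------------------------
# Residuals, Jacobian, restraints
# --------------------------------------------------------------------------
@dataclass
class JacobianBundle:
    """Weighted residuals and Jacobian in X / Y / phi blocks.

    Rows 0..n-1 are the X-block (px), n..2n-1 the Y-block (px), 2n..3n-1 the
    phi-block (deg), each weighted by the inverse centroid standard deviation.
    Restraint pseudo-observation rows, if any, are appended after the three
    blocks and are excluded from diagnostics.
    """

    J: np.ndarray
    delta_r: np.ndarray
    weights: np.ndarray
    block_bounds: tuple[slice, slice, slice]
    labels: list[str]
    n_restraint: int = 0
    rmsd: tuple[float, float, float] = (np.nan, np.nan, np.nan)

    @property
    def J_main(self) -> np.ndarray:
        m = self.J.shape[0] - self.n_restraint
        return self.J[:m]

    @property
    def residuals_main(self) -> np.ndarray:
        m = self.delta_r.shape[0] - self.n_restraint
        return self.delta_r[:m]

    def cost(self) -> float:
        return float(self.delta_r @ self.delta_r)


@dataclass
class RestraintSpec:
    """Targets and sigmas for real-space cell restraints.

    ``targets`` maps a subset of {a, b, c, alpha, beta, gamma} to
    ``(target_value, sigma)``; lengths in A, angles in deg, sigma > 0 (the
    weight is 1/sigma^2). Guidance: sigma ~ 0.001 for qualitatively strong
    restraints, sigma ~ 0.1 for weak ones. Restraints on parameters already
    constrained by lattice symmetry are dropped automatically.
    """

    targets: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (target, sigma) in self.targets.items():
            if name not in _CELL_PARAM_NAMES:
                raise InvalidArgumentError(f"unknown cell parameter {name!r}")
            if sigma <= 0:
                raise InvalidArgumentError("restraint sigma must be positive")

    @classmethod
    def from_cell(cls, cell: Sequence[float], sigma: float | Sequence[float]) -> "RestraintSpec":
        sigmas = [sigma] * 6 if np.isscalar(sigma) else list(sigma)
        return cls({n: (float(v), float(s)) for n, v, s in zip(_CELL_PARAM_NAMES, cell, sigmas)})


def _residual_arrays(param: Parameterisation, obs: ReflectionTable, values: np.ndarray):
    exp = param.build_experiment(values)
    X_c, Y_c, phi_c = predict_for_observations(exp, obs)
    df = obs.df
    rx = X_c - df["X_o"].to_numpy()
    ry = Y_c - df["Y_o"].to_numpy()
    rphi = phi_c - df["phi_o"].to_numpy()
    return rx, ry, rphi


def residuals_and_jacobian(
    param: Parameterisation,
    obs: ReflectionTable,
    values: Optional[np.ndarray] = None,
) -> JacobianBundle:
    """Residuals and central-finite-difference Jacobian for the used reflections.

    ``obs`` must contain only the rows to refine against (flag filtering is
    the caller's job). Detector parameters have exactly zero derivatives in
    the phi block: the rotation angle at which a reflection diffracts does not
    depend on where the detector is.
    """
    if len(obs) == 0:
        raise RefinementError("no usable reflections")
    values = param.start_values() if values is None else np.asarray(values, dtype=float)

    rx, ry, rphi = _residual_arrays(param, obs, values)
    if not (np.all(np.isfinite(rx)) and np.all(np.isfinite(ry)) and np.all(np.isfinite(rphi))):
        bad = int(np.sum(~np.isfinite(rx) | ~np.isfinite(ry) | ~np.isfinite(rphi)))
        raise RefinementError(
            f"non-finite residuals for {bad} reflections; parameter state: "
            + ", ".join(f"{l}={v:.6g}" for l, v in zip(param.labels, values))
        )

    df = obs.df
    n = len(df)

    def w_of(col):
        var = df[col].to_numpy(dtype=float)
        w = np.ones(n)
        ok = np.isfinite(var) & (var > 0)
        w[ok] = 1.0 / np.sqrt(var[ok])
        return w

    wx, wy, wphi = w_of("var_X"), w_of("var_Y"), w_of("var_phi")
    weights = np.concatenate([wx, wy, wphi])
    delta_r = np.concatenate([rx, ry, rphi]) * weights

    steps = param.fd_steps()
    P = param.n_free
    J = np.empty((3 * n, P))
    for p in range(P):
        vp = values.copy()
        vp[p] += steps[p]
        rxp, ryp, rphip = _residual_arrays(param, obs, vp)
        vm = values.copy()
        vm[p] -= steps[p]
        rxm, rym, rphim = _residual_arrays(param, obs, vm)
        inv = 1.0 / (2.0 * steps[p])
        J[:n, p] = (rxp - rxm) * inv
        J[n : 2 * n, p] = (ryp - rym) * inv
        J[2 * n :, p] = (rphip - rphim) * inv
    J *= weights[:, None]

    rmsd = (
        float(np.sqrt(np.mean(rx**2))),
        float(np.sqrt(np.mean(ry**2))),
        float(np.sqrt(np.mean(rphi**2))),
    )
    return JacobianBundle(
        J=J,
        delta_r=delta_r,
        weights=weights,
        block_bounds=(slice(0, n), slice(n, 2 * n), slice(2 * n, 3 * n)),
        labels=param.labels,
        n_restraint=0,
        rmsd=rmsd,
    )


def add_restraints(
    bundle: JacobianBundle,
    param: Parameterisation,
    values: np.ndarray,
    spec: RestraintSpec,
) -> JacobianBundle:
    """Append one pseudo-observation row per active cell restraint.

    Each active restraint on cell parameter ``a`` contributes residual
    ``sqrt(w) (a - a_t)`` and gradient row ``sqrt(w) da/dp`` (w = 1/sigma^2),
    so the summed squared residual includes ``R_a = w (a - a_t)^2`` and its
    gradient ``2 w (a - a_t) da/dp``. Restraints on cell parameters already
    constrained by the lattice symmetry are excluded; restraint rows are
    flagged and never enter the diagnostics.
    """
    if param.cell_scan_varying:
        raise UnsupportedError("cell restraints are available for static cell models only")
    constraint = LatticeSystem(param.experiment.crystal.lattice_constraint)
    active = [n for n in _CELL_PARAM_NAMES if n in spec.targets and n in FREE_CELL_PARAMETERS[constraint]]
    if not active:
        return bundle

    values = np.asarray(values, dtype=float)
    cell0 = np.array(param.cell_of(values))
    steps = param.fd_steps()
    labels = param.labels
    rows = np.zeros((len(active), len(labels)))
    res = np.zeros(len(active))
    cell_cols = [i for i, lbl in enumerate(labels) if lbl.split("[")[0].startswith("g")]
    # derivative of each cell parameter w.r.t. each free cell parameter, by FD
    dcell = np.zeros((6, len(labels)))
    for col in cell_cols:
        vp = values.copy()
        vp[col] += steps[col]
        vm = values.copy()
        vm[col] -= steps[col]
        dcell[:, col] = (np.array(param.cell_of(vp)) - np.array(param.cell_of(vm))) / (2 * steps[col])
    for i, name in enumerate(active):
        target, sigma = spec.targets[name]
        sw = 1.0 / sigma
        k = _CELL_PARAM_NAMES.index(name)
        res[i] = sw * (cell0[k] - target)
        rows[i] = sw * dcell[k]

    w = np.ones(len(active))
    return JacobianBundle(
        J=np.vstack([bundle.J, rows]),
        delta_r=np.concatenate([bundle.delta_r, res]),
        weights=np.concatenate([bundle.weights, w]),
        block_bounds=bundle.block_bounds,
        labels=bundle.labels,
        n_restraint=bundle.n_restraint + len(active),
        rmsd=bundle.rmsd,
    )


# --------------------------------------------------------------------------
# Levenberg-Marquardt
# --------------------------------------------------------------------------
@dataclass
class ConvergenceReport:
    """Per-iteration r.m.s.d.s (X px, Y px, phi deg) and termination status."""

    rmsd_history: list[tuple[float, float, float]] = field(default_factory=list)
    status: str = ""
    n_iterations: int = 0

    @property
    def final_rmsd(self) -> tuple[float, float, float]:
        return self.rmsd_history[-1] if self.rmsd_history else (np.nan,) * 3


def levenberg_marquardt(
    bundle_factory: Callable[[np.ndarray], JacobianBundle],
    values: np.ndarray,
    max_iterations: int = 100,
    rmsd_convergence: float = 1e-4,
) -> tuple[np.ndarray, ConvergenceReport, JacobianBundle]:
    """Standard Levenberg-Marquardt on the weighted least-squares problem.

    Damping starts at ``1e-3 * max(diag(JtJ))``, is multiplied by 10 on a
    rejected step and divided by 10 on an accepted one. Terminates when every
    residual dimension's r.m.s.d. improves by less than ``rmsd_convergence``
    (fraction; default 0.01%) over a step, or at ``max_iterations``.
    Returns (refined values, report, final bundle).
    """
    if max_iterations < 1:
        raise InvalidArgumentError("max_iterations must be >= 1")
    values = np.asarray(values, dtype=float).copy()
    bundle = bundle_factory(values)
    cost = bundle.cost()
    report = ConvergenceReport(rmsd_history=[bundle.rmsd])

    if max(bundle.rmsd) < 1e-12:
        report.status = "converged"
        report.n_iterations = 0
        return values, report, bundle

    JtJ = bundle.J.T @ bundle.J
    lam = 1e-3 * float(np.max(np.diag(JtJ)))
    lam0 = lam

    for it in range(1, max_iterations + 1):
        g = bundle.J.T @ bundle.delta_r
        accepted = False
        for _ in range(25):
            try:
                step = np.linalg.solve(JtJ + lam * np.eye(JtJ.shape[0]), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = values + step
            trial_bundle = bundle_factory(trial)
            if trial_bundle.cost() < cost:
                accepted = True
                break
            lam *= 10.0
            if lam > 1e12 * max(lam0, 1e-300):
                break
        if not accepted:
            # no improving step exists: at the residual floor this is
            # convergence, otherwise a genuine stall
            report.status = "converged" if max(bundle.rmsd) < 1e-10 else "stalled"
            report.n_iterations = it - 1
            return values, report, bundle

        prev_rmsd = bundle.rmsd
        values, bundle, cost = trial, trial_bundle, trial_bundle.cost()
        lam = max(lam / 10.0, 1e-300)
        JtJ = bundle.J.T @ bundle.J
        report.rmsd_history.append(bundle.rmsd)
        report.n_iterations = it

        rel = [
            (p - c) / p if p > 0 else 0.0
            for p, c in zip(prev_rmsd, bundle.rmsd)
        ]
        if all(r < rmsd_convergence for r in rel):
            report.status = "converged"
            return values, report, bundle

    report.status = "max_iterations"
    return values, report, bundle


# --------------------------------------------------------------------------
# Outlier rejection
# --------------------------------------------------------------------------
def reject_outliers(obs: ReflectionTable, residuals: tuple[np.ndarray, np.ndarray, np.ndarray]) -> int:
    """Flag outliers by per-dimension Tukey fences at 3 x IQR.

    ``residuals`` are (rx, ry, rphi) for the rows of ``obs`` in order. A
    reflection is an outlier if any dimension falls outside its fences; the
    OUTLIER flag is set (rows are never deleted). Returns the number flagged.
    Idempotent for unchanged residuals.
    """
    out = np.zeros(len(obs), dtype=bool)
    for r in residuals:
        r = np.asarray(r, dtype=float)
        q1, q3 = np.percentile(r, [25, 75])
        iqr = q3 - q1
        if iqr <= 0:
            continue
        out |= (r < q1 - 3 * iqr) | (r > q3 + 3 * iqr)
    obs.set_flag(Flags.OUTLIER, out)
    obs.unset_flag(Flags.USED_IN_REFINEMENT, out)
    return int(out.sum())


# --------------------------------------------------------------------------
# Protocol driver
# --------------------------------------------------------------------------
@dataclass
class RefinementProtocol:
    """Configuration of a full refinement run.

    Scan-varying defaults follow the protocol that performed best on real
    narrow-wedge ED data: 3 smoother samples per crystal orientation angle
    and, when beam drift is modelled, the simplest 2-sample model per beam
    angle. The detector is always held at its static values during the
    scan-varying stage.
    """

    fix: tuple[str, ...] = ()
    restraints: Optional[RestraintSpec] = None
    scan_varying: bool = False
    orientation_samples: int = 3
    beam_samples: Optional[int] = None
    cell_samples: Optional[int] = None
    max_iterations: int = 100
    outlier_rejection: bool = True


@dataclass
class RefineResult:
    experiment: ExperimentModel
    static_report: ConvergenceReport
    scan_varying_report: Optional[ConvergenceReport]
    final_bundle: JacobianBundle
    static_bundle: JacobianBundle
    n_outliers: int = 0


def _used(obs: ReflectionTable) -> ReflectionTable:
    return obs.select(obs.has_flag(Flags.USED_IN_REFINEMENT))


def refine(
    experiment: ExperimentModel,
    obs: ReflectionTable,
    protocol: Optional[RefinementProtocol] = None,
) -> RefineResult:
    """Static refinement, outlier rejection, then optional scan-varying refinement."""
    protocol = protocol or RefinementProtocol()
    obs = obs.copy()
    fresh = ~obs.has_flag(Flags.OUTLIER)
    obs.set_flag(Flags.USED_IN_REFINEMENT, fresh)

    def run(param: Parameterisation, table: ReflectionTable):
        def factory(v):
            bundle = residuals_and_jacobian(param, table, v)
            if protocol.restraints is not None:
                bundle = add_restraints(bundle, param, v, protocol.restraints)
            return bundle

        return levenberg_marquardt(
            factory, param.start_values(), max_iterations=protocol.max_iterations
        )

    # static stage
    param = build_parameterisation(experiment, fix=protocol.fix)
    values, static_report, static_bundle = run(param, _used(obs))
    exp1 = param.build_experiment(values)

    n_out = 0
    if protocol.outlier_rejection:
        used = _used(obs)
        rx, ry, rphi = _residual_arrays(param, used, values)
        flag_local = np.zeros(len(used), dtype=bool)
        tmp = used.copy()
        n_out = reject_outliers(tmp, (rx, ry, rphi))
        if n_out:
            # propagate flags back to the master table by row identity
            mask_used = obs.has_flag(Flags.USED_IN_REFINEMENT)
            idx = np.where(mask_used)[0][tmp.has_flag(Flags.OUTLIER)]
            m = np.zeros(len(obs), dtype=bool)
            m[idx] = True
            obs.set_flag(Flags.OUTLIER, m)
            obs.unset_flag(Flags.USED_IN_REFINEMENT, m)
            param = build_parameterisation(exp1, fix=protocol.fix)
            values, static_report, static_bundle = run(param, _used(obs))
            exp1 = param.build_experiment(values)

    sv_report = None
    final_bundle = static_bundle
    final_exp = exp1
    if protocol.scan_varying:
        scan_map: dict[str, int] = {}
        if protocol.orientation_samples and protocol.orientation_samples > 1:
            for lbl in _ORIENTATION_LABELS:
                scan_map[lbl] = protocol.orientation_samples
        if protocol.beam_samples:
            for lbl in _BEAM_LABELS:
                scan_map[lbl] = protocol.beam_samples
        if protocol.cell_samples:
            if protocol.restraints is not None:
                raise UnsupportedError("cell restraints are not available with a scan-varying cell")
            for lbl in free_metrical_elements(experiment.crystal.lattice_constraint):
                scan_map[lbl] = protocol.cell_samples
        sv_param = Parameterisation(
            exp1,
            fix=tuple(set(protocol.fix) | set(_DETECTOR_LABELS)),
            scan_varying=scan_map,
        )

        def sv_factory(v):
            return residuals_and_jacobian(sv_param, _used(obs), v)

        sv_values, sv_report, final_bundle = levenberg_marquardt(
            sv_factory, sv_param.start_values(), max_iterations=protocol.max_iterations
        )
        final_exp = sv_param.build_experiment(sv_values)

    return RefineResult(
        experiment=final_exp,
        static_report=static_report,
        scan_varying_report=sv_report,
        final_bundle=final_bundle,
        static_bundle=static_bundle,
        n_outliers=n_out,
    )
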