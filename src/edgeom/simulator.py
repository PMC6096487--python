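"""Synthetic rotation-diffraction experiments with known ground truth.

The simulator generates fully specified experiments -- reflection lists with
noisy centroids, optional smooth beam drift, optional elliptical distortion,
and rendered detector frames -- for an electron-diffraction (ED) geometry and
a matched X-ray (MX) geometry. The two presets share the crystal, scan,
rotation axis and candidate reflection list and differ only in wavelength and
detector distance, so comparisons of refinement conditioning between them
isolate the effect of the diffraction geometry alone.

Preset conditions (ED): lambda = 0.02508 A (200 keV electrons), effective
detector distance 2000 mm, a lysozyme-like orthorhombic cell (32, 68, 105 A)
with the short axis closest to the rotation axis, a single 1024 x 1024 panel
of 55 um pixels, a 40 deg narrow-wedge scan at 0.1 deg/image, d_min = 6 A
(~10^3 reflections) and centroid noise of 0.3 px / 0.02 deg. The MX preset
uses lambda = 1.0332 A (12 keV X-rays) and the distance that places d_min at
the panel edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import (
    BeamModel,
    CrystalModel,
    DetectorModel,
    ExperimentModel,
    GoniometerModel,
    InvalidArgumentError,
    LatticeSystem,
    PanelModel,
    ScanModel,
    ScanVaryingStates,
    rotation_about_axis,
)
from .image_prep import RawFrame, generate_elliptical_distortion_maps
from .prediction import Flags, ReflectionTable, predict_centroids, two_theta
from . import prediction

__all__ = [
    "SimulationSpec",
    "ed_preset",
    "mx_preset",
    "standard_pair",
    "enumerate_hkl",
    "simulate_reflections",
    "apply_beam_drift",
    "render_frames",
]

LAMBDA_ED = 0.02508  # A, 200 keV electrons
LAMBDA_MX = 1.0332  # A, 12 keV X-rays
_CELL = (32.0, 68.0, 105.0, 90.0, 90.0, 90.0)
_ED_DISTANCE = 2000.0  # mm
_PIXEL = 0.055  # mm
_N_PIX = 1024
_D_MIN = 6.0  # A
_SCAN_IMAGES = 400
_DPHI = 0.1  # deg/image


@dataclass
class SimulationSpec:
    """Ground-truth description of one synthetic experiment.

    ``experiment`` holds the true static models. Centroid noise sigmas are in
    px / deg; ``beam_drift_mrad`` is the total smooth drift of the beam
    direction across the scan (half-cosine ramp); ``distortion`` optionally
    holds ``(centre_xy_px, scale_major, scale_minor, axis_angle_deg)`` of an
    elliptical lens distortion. A fixed ``seed`` makes every output bitwise
    reproducible.
    """

    experiment: ExperimentModel
    d_min: float
    sigma_x: float = 0.3
    sigma_y: float = 0.3
    sigma_phi: float = 0.02
    beam_drift_mrad: float = 0.0
    distortion: Optional[tuple] = None
    seed: int = 0
    preset: str = ""

    def __post_init__(self) -> None:
        if self.d_min <= self.experiment.beam.wavelength / 2:
            raise InvalidArgumentError("d_min must exceed lambda/2 (limiting sphere)")
        if min(self.sigma_x, self.sigma_y, self.sigma_phi) < 0 or self.beam_drift_mrad < 0:
            raise InvalidArgumentError("noise and drift must be non-negative")


def _crystal() -> CrystalModel:
    # short axis a (along x after B) closest to the rotation axis (+x), with a
    # small fixed tilt so low-order h00 reflections are not exactly blind
    U0 = rotation_about_axis([0.0, 1.0, 0.0], 6.0) @ rotation_about_axis([0.0, 0.0, 1.0], 4.0)
    return CrystalModel.from_cell(_CELL, U=U0, lattice_constraint=LatticeSystem.orthorhombic)


def _panel(distance_mm: float) -> PanelModel:
    half = 0.5 * _N_PIX * _PIXEL
    return PanelModel(
        origin=[-half, -half, distance_mm],
        fast_axis=[1.0, 0.0, 0.0],
        slow_axis=[0.0, 1.0, 0.0],
        pixel_size=(_PIXEL, _PIXEL),
        n_pixels=(_N_PIX, _N_PIX),
        gain=1.0,
    )


def _experiment(wavelength: float, distance_mm: float, n_images: int = _SCAN_IMAGES) -> ExperimentModel:
    return ExperimentModel(
        beam=BeamModel(direction=[0.0, 0.0, 1.0], wavelength=wavelength),
        detector=DetectorModel([_panel(distance_mm)]),
        goniometer=GoniometerModel(rotation_axis=[1.0, 0.0, 0.0]),
        scan=ScanModel(image_range=(1, n_images), oscillation=(0.0, _DPHI)),
        crystal=_crystal(),
    )


def mx_distance(d_min: float = _D_MIN) -> float:
    """MX detector distance placing ``d_min`` at the panel edge."""
    half = 0.5 * _N_PIX * _PIXEL
    return half / math.tan(math.radians(two_theta(d_min, LAMBDA_MX)))


def ed_preset(seed: int = 0, **overrides) -> SimulationSpec:
    """Standard electron-diffraction simulation conditions."""
    spec = SimulationSpec(
        experiment=_experiment(LAMBDA_ED, _ED_DISTANCE),
        d_min=_D_MIN,
        seed=seed,
        preset="ED",
    )
    return replace(spec, **overrides) if overrides else spec


def mx_preset(seed: int = 0, **overrides) -> SimulationSpec:
    """Matched X-ray geometry: same crystal, scan and axis; only wavelength
    and detector distance differ."""
    spec = SimulationSpec(
        experiment=_experiment(LAMBDA_MX, mx_distance()),
        d_min=_D_MIN,
        seed=seed,
        preset="MX",
    )
    return replace(spec, **overrides) if overrides else spec


def standard_pair(seed: int = 0) -> tuple[SimulationSpec, SimulationSpec]:
    """The shared-crystal ED/MX pair used for conditioning comparisons."""
    return ed_preset(seed), mx_preset(seed)


# --------------------------------------------------------------------------
def enumerate_hkl(crystal: CrystalModel, d_min: float) -> np.ndarray:
    """All hkl (excluding 000) with d-spacing >= d_min."""
    a, b, c, *_ = crystal.cell
    B = crystal.B
    hmax = int(math.floor(a / d_min)) + 1
    kmax = int(math.floor(b / d_min)) + 1
    lmax = int(math.floor(c / d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1), np.arange(-kmax, kmax + 1), np.arange(-lmax, lmax + 1), indexing="ij"
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    r = hkl.astype(float) @ B.T
    d = 1.0 / np.linalg.norm(r, axis=1)
    return hkl[d >= d_min]


def _drift_states(experiment: ExperimentModel, total_mrad: float) -> ScanVaryingStates:
    """Per-image true beam directions for a half-cosine drift ramp."""
    n = experiment.scan.n_images
    x = (np.arange(n) + 0.5) / n
    ramp_mrad = 0.5 * total_mrad * (1.0 - np.cos(np.pi * x))
    axis = np.cross(experiment.goniometer.rotation_axis, experiment.beam.direction)
    axis = axis / np.linalg.norm(axis)
    dirs = prediction._rotate_about(
        axis, np.degrees(ramp_mrad * 1e-3), np.broadcast_to(experiment.beam.direction, (n, 3))
    )
    return ScanVaryingStates(beam_direction=dirs)


def simulate_reflections(spec: SimulationSpec) -> tuple[ExperimentModel, ReflectionTable]:
    """Generate an experiment and its reflection table with noisy centroids.

    Enumerates all reflections with d >= d_min, keeps Ewald crossings inside
    the scan that land on a panel, then adds seeded Gaussian noise with the
    spec's sigmas to the noiseless centroids. True variances are recorded in
    the table. When ``beam_drift_mrad`` > 0 the returned experiment carries
    the per-image true beam directions, and observations are generated from
    them; when ``distortion`` is set the maps are attached to the panel
    before prediction.
    """
    exp = spec.experiment
    if spec.distortion is not None:
        centre, smaj, smin, ang = spec.distortion
        panels = []
        for p in exp.detector.panels:
            maps = generate_elliptical_distortion_maps(p, centre, smaj, smin, ang)
            panels.append(
                PanelModel(
                    origin=p.origin,
                    fast_axis=p.fast_axis,
                    slow_axis=p.slow_axis,
                    pixel_size=p.pixel_size,
                    n_pixels=p.n_pixels,
                    gain=p.gain,
                    distortion=maps,
                )
            )
        exp = ExperimentModel(
            beam=exp.beam,
            detector=DetectorModel(panels),
            goniometer=exp.goniometer,
            scan=exp.scan,
            crystal=exp.crystal,
            scan_varying=exp.scan_varying,
        )
    if spec.beam_drift_mrad > 0:
        exp = ExperimentModel(
            beam=exp.beam,
            detector=exp.detector,
            goniometer=exp.goniometer,
            scan=exp.scan,
            crystal=exp.crystal,
            scan_varying=_drift_states(exp, spec.beam_drift_mrad),
        )

    hkl = enumerate_hkl(exp.crystal, spec.d_min)
    table = predict_centroids(exp, hkl)
    if len(table) == 0:
        raise InvalidArgumentError(
            "no reflections predicted; widen the scan or lower d_min"
        )
    rng = np.random.default_rng(spec.seed)
    df = table.df
    n = len(df)
    df["X_o"] = df["X_c"] + rng.normal(0.0, spec.sigma_x, n) if spec.sigma_x else df["X_c"]
    df["Y_o"] = df["Y_c"] + rng.normal(0.0, spec.sigma_y, n) if spec.sigma_y else df["Y_c"]
    df["phi_o"] = df["phi_c"] + rng.normal(0.0, spec.sigma_phi, n) if spec.sigma_phi else df["phi_c"]
    df["var_X"] = spec.sigma_x**2
    df["var_Y"] = spec.sigma_y**2
    df["var_phi"] = spec.sigma_phi**2
    out = ReflectionTable(df)
    out.set_flag(Flags.OBSERVED | Flags.INDEXED)
    return exp, out


def apply_beam_drift(spec: SimulationSpec, total_mrad: float) -> tuple[ExperimentModel, ReflectionTable]:
    """Regenerate observations with a smooth beam drift baked in.

    The beam direction follows a half-cosine ramp from 0 to ``total_mrad``
    across the scan (rotation about the axis perpendicular to both the
    goniometer axis and the beam). The per-image ground-truth directions are
    stored on the returned experiment for recovery tests. Zero drift returns
    the undrifted simulation unchanged.
    """
    return simulate_reflections(replace(spec, beam_drift_mrad=total_mrad))


def render_frames(
    spec: SimulationSpec,
    table: ReflectionTable,
    background_mean: float = 5.0,
    spot_peak: float = 100.0,
    spot_sigma_px: float = 1.5,
) -> list[RawFrame]:
    """Render per-image detector frames: Poisson background + Gaussian spots.

    Each table row whose observed phi falls inside an image's rotation range
    plants a 2-D Gaussian blob of peak ``spot_peak`` at its (panel-local)
    centroid; the whole frame is then Poisson sampled (seeded from the
    simulation description).
    """
    exp = spec.experiment
    scan = exp.scan
    rng = np.random.default_rng(spec.seed + 1)
    df = table.df
    img_idx = scan.image_of_phi(df["phi_o"].to_numpy())
    frames: list[RawFrame] = []
    w = max(3, int(math.ceil(4 * spot_sigma_px)))
    for i in range(scan.n_images):
        panels = []
        rows = df[(img_idx == i)]
        for pid, panel in enumerate(exp.detector.panels):
            nf, ns = panel.n_pixels
            lam = np.full((ns, nf), float(background_mean))
            sub = rows[rows["panel"] == pid]
            for x0, y0 in zip(sub["X_o"], sub["Y_o"]):
                ci, cj = int(round(x0)), int(round(y0))
                i0, i1 = max(cj - w, 0), min(cj + w + 1, ns)
                j0, j1 = max(ci - w, 0), min(ci + w + 1, nf)
                if i0 >= i1 or j0 >= j1:
                    continue
                yy, xx = np.mgrid[i0:i1, j0:j1]
                lam[i0:i1, j0:j1] += spot_peak * np.exp(
                    -(((xx + 0.5 - x0) ** 2) + ((yy + 0.5 - y0) ** 2)) / (2 * spot_sigma_px**2)
                )
            panels.append(rng.poisson(lam).astype(np.int64))
        frames.append(RawFrame(panels=panels, image_number=scan.image_range[0] + i))
    return frames
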