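"""Refinement-conditioning diagnostics.

Two diagnostics built from the Jacobian of the least-squares subproblem:

* per-block *corrgrams* -- pairwise Pearson correlations between Jacobian
  columns, computed separately for the X, Y and phi residual blocks (the three
  centroid dimensions come from different distributions and must not be mixed
  in one correlation);
* the condition number kappa(J) = sigma_max / sigma_min of the weighted
  Jacobian, a scalar measure of how well posed the subproblem is.

Both exclude restraint pseudo-observation rows: they describe the underlying
geometric degeneracy of the problem, not modifications introduced to
stabilize it. A third tool compares the two rotation-handedness hypotheses by
the angular r.m.s.d. each achieves after orientation-only refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import (
    BeamModel,
    ExperimentModel,
    GoniometerModel,
    InvalidArgumentError,
)
from .prediction import ReflectionTable
from .refinement import (
    ConvergenceReport,
    JacobianBundle,
    Parameterisation,
    levenberg_marquardt,
    residuals_and_jacobian,
)

__all__ = [
    "CorrgramBlock",
    "corrgram_blocks",
    "condition_number",
    "HandednessReport",
    "handedness_test",
    "plot_corrgram",
]

_BLOCK_NAMES = ("X", "Y", "phi")


@dataclass
class CorrgramBlock:
    """Correlation matrix between Jacobian columns within one residual block."""

    block: str
    labels: list[str]
    matrix: np.ndarray
    dropped: list[str] = field(default_factory=list)
    note: str = ""

    def mean_abs_off_diagonal(self) -> float:
        m = self.matrix
        if m.size == 0 or m.shape[0] < 2:
            return np.nan
        mask = ~np.eye(m.shape[0], dtype=bool)
        return float(np.mean(np.abs(m[mask])))


def corrgram_blocks(bundle: JacobianBundle) -> dict[str, CorrgramBlock]:
    """Pairwise column correlations of the weighted Jacobian, per residual block.

    Columns with (near-)zero norm within a block -- e.g. the detector
    parameters in the phi block, which cannot affect the diffraction angle --
    are omitted from that block's matrix with a note.
    """
    J = bundle.J_main
    out: dict[str, CorrgramBlock] = {}
    for name, sl in zip(_BLOCK_NAMES, bundle.block_bounds):
        block = J[sl]
        norms = np.linalg.norm(block, axis=0)
        # threshold sits well above finite-difference noise (~1e-11 relative)
        # so analytically-zero columns are dropped consistently
        thresh = 1e-8 * float(norms.max()) if norms.size else 0.0
        keep = norms > thresh
        labels = [l for l, k in zip(bundle.labels, keep) if k]
        dropped = [l for l, k in zip(bundle.labels, keep) if not k]
        note = f"columns with zero norm in this block omitted: {dropped}" if dropped else ""
        if keep.sum() < 2:
            out[name] = CorrgramBlock(name, labels, np.empty((0, 0)), dropped, note or "fewer than 2 usable columns")
            continue
        sub = block[:, keep]
        corr = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(corr, 1.0)
        out[name] = CorrgramBlock(name, labels, np.clip(corr, -1.0, 1.0), dropped, note)
    return out


def condition_number(bundle: JacobianBundle) -> float:
    """kappa(J) = sigma_max / sigma_min of the weighted Jacobian (SVD).

    Restraint rows are excluded. Returns +inf when the smallest singular
    value falls below 1e-14 times the largest (J numerically singular).
    """
    J = bundle.J_main
    if J.size == 0:
        raise InvalidArgumentError("empty Jacobian")
    s = np.linalg.svd(J, compute_uv=False)
    if s[-1] <= 1e-14 * s[0]:
        return float("inf")
    return float(s[0] / s[-1])


@dataclass
class HandednessReport:
    """Angular r.m.s.d. (deg) under both rotation-axis hypotheses."""

    forward_rmsd_phi: float
    inverted_rmsd_phi: float
    verdict: str  # "forward" | "inverted" | "ambiguous"
    forward_error: Optional[str] = None
    inverted_error: Optional[str] = None


def handedness_test(experiment: ExperimentModel, obs: ReflectionTable) -> HandednessReport:
    """Compare the two rotation-handedness hypotheses.

    The crystal orientation angles alone are refined (everything else fixed)
    under the as-modelled axis and under the inverted axis; the hypothesis
    with the lower angular r.m.s.d. wins. For near-flat Ewald spheres both
    residuals can be small; the verdict is "ambiguous" when the two r.m.s.d.s
    differ by less than 10%.
    """
    results: list[float] = []
    errors: list[Optional[str]] = []
    for invert in (False, True):
        axis = experiment.goniometer.rotation_axis * (-1.0 if invert else 1.0)
        exp = ExperimentModel(
            beam=experiment.beam,
            detector=experiment.detector,
            goniometer=GoniometerModel(rotation_axis=axis),
            scan=experiment.scan,
            crystal=experiment.crystal,
            scan_varying=experiment.scan_varying,
        )
        try:
            param = Parameterisation(exp, fix=("detector", "beam", "cell"))
            _, report, _ = levenberg_marquardt(
                lambda v, p=param, e=exp: residuals_and_jacobian(p, obs, v),
                param.start_values(),
            )
            results.append(report.final_rmsd[2])
            errors.append(None)
        except Exception as exc:  # refinement failure is reported per hypothesis
            results.append(float("inf"))
            errors.append(str(exc))

    fwd, inv = results
    if np.isfinite(fwd) and np.isfinite(inv) and (
        max(fwd, inv) == 0 or abs(fwd - inv) / max(fwd, inv) < 0.1
    ):
        verdict = "ambiguous"
    elif fwd <= inv:
        verdict = "forward"
    else:
        verdict = "inverted"
    if not np.isfinite(fwd) and not np.isfinite(inv):
        verdict = "ambiguous"
    return HandednessReport(
        forward_rmsd_phi=fwd,
        inverted_rmsd_phi=inv,
        verdict=verdict,
        forward_error=errors[0],
        inverted_error=errors[1],
    )


def plot_corrgram(block: CorrgramBlock, path: str) -> None:
    """Render one corrgram as a PNG (circle area/colour encodes correlation)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(block.labels)
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * n), max(4, 0.5 * n)))
    if n:
        ii, jj = np.meshgrid(range(n), range(n))
        c = block.matrix.flatten()
        ax.scatter(
            ii.flatten(),
            jj.flatten(),
            s=400 * np.abs(c),
            c=c,
            cmap="RdBu",
            vmin=-1,
            vmax=1,
            edgecolors="k",
            linewidths=0.3,
        )
        ax.set_xticks(range(n), block.labels, rotation=90)
        ax.set_yticks(range(n), block.labels)
        ax.invert_yaxis()
    ax.set_title(f"corrgram: {block.block} block")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
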