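"""Reference-based blood cell-type deconvolution by constrained projection.

Each sample's beta values at a set of cell-type-discriminating marker
probes are projected onto sorted-cell reference profiles (Houseman-style
constrained projection): the estimated fractions minimise the squared
reconstruction error subject to non-negativity and a per-sample sum of at
most one. The sum constraint is an inequality by default; an optional
post-hoc renormalisation to the simplex is available but off by default.

The solver is deterministic: unconstrained non-negative least squares
first (which already satisfies both constraints for most blood samples),
falling back to an SLSQP quadratic program only when the NNLS solution
overshoots the sum constraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

CONSTRAINT_TOL = 1e-8


class DeconvolutionError(ValueError):
    pass


@dataclass
class ReferencePanel:
    """Sorted-cell reference beta profiles at marker probes.

    ``profiles`` is a probes x cell-types DataFrame of reference beta
    values (the on-disk TSV layout).
    """

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.profiles.to_numpy(dtype=float)
        if vals.shape[1] < 2:
            raise DeconvolutionError("reference panel needs at least 2 cell types")
        if np.any(vals < -1e-9) or np.any(vals > 1 + 1e-9):
            raise DeconvolutionError("reference panel beta values must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return self.profiles.columns.tolist()

    @property
    def marker_probes(self) -> list[str]:
        return self.profiles.index.tolist()

    @classmethod
    def read(cls, path) -> "ReferencePanel":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write(self, path) -> None:
        self.profiles.to_csv(path, sep="\t", index_label="probe_id")


def _solve_one(P: np.ndarray, y: np.ndarray) -> np.ndarray:
    """min ||P f - y||^2 s.t. f >= 0, sum(f) <= 1."""
    f, _ = optimize.nnls(P, y)
    if f.sum() <= 1 + CONSTRAINT_TOL:
        return f
    k = P.shape[1]
    PtP = P.T @ P
    Pty = P.T @ y

    def obj(x):
        return 0.5 * x @ PtP @ x - Pty @ x

    def grad(x):
        return PtP @ x - Pty

    x0 = f / f.sum()
    res = optimize.minimize(
        obj,
        x0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, None)] * k,
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum(), "jac": lambda x: -np.ones(k)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    x = np.maximum(res.x, 0.0)
    if x.sum() > 1.0:
        x = x / x.sum()
    return x


def estimate_fractions(
    beta_markers: pd.DataFrame,
    panel: ReferencePanel,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Estimate cell-type fractions for every sample.

    Parameters
    ----------
    beta_markers
        Probes x samples beta matrix covering (at least) the panel's
        marker probes; no missing values allowed among the markers.
    panel
        Reference profiles to project onto.
    renormalize
        If True, rescale each sample's fractions to sum exactly to 1.

    Returns
    -------
    Samples x cell-types DataFrame of fractions (non-negative, sum <= 1,
    or exactly 1 under ``renormalize``).
    """
    markers = panel.marker_probes
    missing = [m for m in markers if m not in beta_markers.index]
    if missing:
        raise DeconvolutionError(
            f"{len(missing)} marker probes missing from beta matrix: {missing[:5]}"
        )
    if len(markers) < len(panel.cell_types):
        raise DeconvolutionError("need at least as many marker probes as cell types")
    Y = beta_markers.loc[markers].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise DeconvolutionError("missing values in the marker submatrix")
    P = panel.profiles.to_numpy(dtype=float)
    if np.linalg.matrix_rank(P) < P.shape[1]:
        warnings.warn(
            "reference panel is rank deficient; fractions are a pseudo-solution",
            stacklevel=2,
        )
    out = np.empty((Y.shape[1], P.shape[1]))
    for j in range(Y.shape[1]):
        out[j] = _solve_one(P, Y[:, j])
    if renormalize:
        s = out.sum(axis=1, keepdims=True)
        s[s == 0] = 1.0
        out = out / s
    return pd.DataFrame(out, index=beta_markers.columns, columns=panel.cell_types)
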