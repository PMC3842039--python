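"""Far-UV CD spectrum conversion and secondary-structure unmixing.

A far-UV circular dichroism spectrum of a protein is, to first order, a
non-negative mixture of characteristic basis curves, one per aggregate
secondary-structure class (α-helix, β-sheet, other). Given a spectrum in mean
residue ellipticity (MRE, deg·cm²·dmol⁻¹) and a basis matrix B on the same
wavelength grid, the structure fractions f are estimated by constrained,
ridge-regularized least squares:

    minimize  ||θ − B f||² + α ||f||²   subject to  f ≥ 0,  Σ f = 1

with the sum constraint enforced exactly so the estimate is interpretable as
a composition. α may be a fixed weight or "auto", which selects it by
generalized cross-validation (GCV) over a log grid on the sum-constrained
reduced problem. This is the same constrained-linear-combination idea used by
the classical CONTIN-style reference-set programs, with a plain ridge penalty
over the K aggregate classes in place of a smoothness operator over many
reference proteins.

Raw instrument output in millidegrees is converted to MRE with the
molar-residue convention

    MRE(λ) = θ_mdeg(λ) / (10 · l_cm · C_M · N_res)

where l is the cuvette pathlength in cm, C the molar protein concentration
and N_res the residue count of the construct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.linalg import null_space

__all__ = [
    "CDSpectrum",
    "BasisSet",
    "FractionEstimate",
    "default_basis",
    "mdeg_to_mre",
    "fit_fractions",
    "goodness_of_fit",
]


@dataclass(frozen=True)
class CDSpectrum:
    """Wavelength-indexed mean-residue-ellipticity curve."""

    wavelengths: np.ndarray  # nm, strictly increasing
    ellipticity: np.ndarray  # deg cm^2 dmol^-1

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        el = np.asarray(self.ellipticity, dtype=float)
        if wl.ndim != 1 or wl.shape != el.shape:
            raise ValueError("wavelengths and ellipticity must be equal-length 1-D")
        if len(wl) < 2 or not (np.diff(wl) > 0).all():
            raise ValueError("wavelengths must be strictly increasing")
        if wl.min() < 170 or wl.max() > 300:
            raise ValueError("wavelengths outside the plausible far-UV range")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "ellipticity", el)


@dataclass(frozen=True)
class BasisSet:
    """Structure-class basis spectra on a shared wavelength grid."""

    wavelengths: np.ndarray
    matrix: np.ndarray  # (n_wavelengths, K)
    class_names: tuple[str, ...]

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        B = np.asarray(self.matrix, dtype=float)
        if B.ndim != 2 or B.shape[0] != len(wl):
            raise ValueError("basis matrix must have one row per wavelength")
        if B.shape[1] < 2:
            raise ValueError("basis needs at least 2 structure classes")
        if len(self.class_names) != B.shape[1]:
            raise ValueError("one class name per basis column required")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "matrix", B)

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class FractionEstimate:
    """Estimated structure composition with fit diagnostics."""

    fractions: np.ndarray  # K-vector on the simplex
    class_names: tuple[str, ...]
    residual_norm: float  # ||theta - B f|| in MRE units
    alpha: float

    def as_dict(self) -> dict[str, float]:
        return {c: float(f) for c, f in zip(self.class_names, self.fractions)}


def default_basis(wavelengths: np.ndarray | None = None) -> BasisSet:
    """The packaged synthetic 3-class basis evaluated on a grid.

    Basis curves are sums of Gaussians in wavelength with the qualitative
    far-UV shapes of helix, sheet and unordered structure; the Gaussian
    parameters live in the packaged ``cd_basis.json``, not in code.
    """
    if wavelengths is None:
        wavelengths = np.arange(182.0, 261.0, 1.0)
    wl = np.asarray(wavelengths, dtype=float)
    params = json.loads(
        resources.files("gipscape.data").joinpath("cd_basis.json").read_text()
    )
    names = tuple(params["classes"].keys())
    cols = []
    for name in names:
        col = np.zeros_like(wl)
        for amp, center, width in params["classes"][name]:
            col += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        cols.append(col)
    return BasisSet(wavelengths=wl, matrix=np.column_stack(cols), class_names=names)


def mdeg_to_mre(
    theta_mdeg: np.ndarray,
    pathlength_cm: float,
    concentration_molar: float,
    n_residues: int,
    wavelengths: np.ndarray | None = None,
) -> CDSpectrum | np.ndarray:
    """Convert raw ellipticity in millidegrees to mean residue ellipticity.

    MRE(λ) = θ_mdeg(λ) / (10 · l_cm · C_M · N_res); linear in θ. Returns a
    :class:`CDSpectrum` when a wavelength grid is supplied, else the bare
    converted array.
    """
    if pathlength_cm <= 0:
        raise ValueError("pathlength must be positive")
    if concentration_molar <= 0:
        raise ValueError("concentration must be positive")
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    theta = np.asarray(theta_mdeg, dtype=float)
    mre = theta / (10.0 * pathlength_cm * concentration_molar * n_residues)
    if wavelengths is None:
        return mre
    return CDSpectrum(wavelengths=np.asarray(wavelengths, float), ellipticity=mre)


def _solve_simplex_ridge(
    B: np.ndarray, theta: np.ndarray, alpha: float
) -> np.ndarray:
    """Minimize ||theta - Bf||^2 + alpha ||f||^2 on the probability simplex.

    Exact active-set enumeration: for a convex QP the optimum is attained on
    some support S of positive coordinates, where it solves the equality-
    constrained KKT system restricted to S. With K aggregate structure
    classes (typically 3), trying every non-empty support is cheap and gives
    the deterministic exact solution; the best feasible candidate over all
    supports is the global optimum.
    """
    K = B.shape[1]
    G = B.T @ B + alpha * np.eye(K)
    c = B.T @ theta
    best_f: np.ndarray | None = None
    best_obj = np.inf
    for mask in range(1, 2**K):
        idx = np.array([k for k in range(K) if mask >> k & 1])
        m = len(idx)
        Ga = G[np.ix_(idx, idx)]
        ca = c[idx]
        ones = np.ones(m)
        kkt = np.block(
            [[2.0 * Ga, ones[:, None]], [ones[None, :], np.zeros((1, 1))]]
        )
        rhs = np.concatenate([2.0 * ca, [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            continue
        fa = sol[:m]
        if (fa < -1e-12).any():
            continue
        f = np.zeros(K)
        f[idx] = np.clip(fa, 0.0, None)
        f /= f.sum()
        obj = float(f @ G @ f - 2.0 * c @ f)
        if obj < best_obj:
            best_obj, best_f = obj, f
    if best_f is None:  # pragma: no cover - simplex always has a vertex
        best_f = np.full(K, 1.0 / K)
    return best_f


def _gcv_alpha(B: np.ndarray, theta: np.ndarray) -> float:
    """GCV choice of alpha on the sum-constrained reduced ridge problem."""
    K = B.shape[1]
    f0 = np.full(K, 1.0 / K)
    N = null_space(np.ones((1, K)))  # orthonormal, K x (K-1)
    A = B @ N
    r0 = theta - B @ f0
    m = len(theta)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    Ur0 = U.T @ r0
    best_alpha, best_gcv = 0.0, np.inf
    for alpha in np.logspace(-4, 10, 57):
        shrink = s**2 / (s**2 + alpha)
        fitted = U @ (shrink * Ur0)
        rss = float(((r0 - fitted) ** 2).sum())
        edf = float(shrink.sum())
        gcv = m * rss / (m - edf) ** 2
        if gcv < best_gcv:
            best_gcv, best_alpha = gcv, alpha
    return best_alpha


def fit_fractions(
    spectrum: CDSpectrum, basis: BasisSet, alpha: float | str = 0.0
) -> FractionEstimate:
    """Estimate secondary-structure fractions of a spectrum against a basis.

    Solves the simplex-constrained ridge problem described in the module
    docstring. ``alpha="auto"`` picks the weight by GCV over a log grid.

    Raises
    ------
    ValueError
        If the grids differ, there are fewer wavelengths than classes, or the
        basis is rank-deficient and ``alpha`` is 0 (regularization required).
    """
    if len(spectrum.wavelengths) != len(basis.wavelengths) or not np.allclose(
        spectrum.wavelengths, basis.wavelengths
    ):
        raise ValueError("spectrum and basis wavelength grids differ")
    B = basis.matrix
    theta = spectrum.ellipticity
    if B.shape[0] < basis.n_classes:
        raise ValueError("need at least as many wavelengths as basis classes")
    if alpha == "auto":
        alpha_val = _gcv_alpha(B, theta)
    else:
        alpha_val = float(alpha)
        if alpha_val < 0:
            raise ValueError("alpha must be >= 0")
    if alpha_val == 0.0 and np.linalg.matrix_rank(B) < basis.n_classes:
        raise ValueError(
            "basis is rank-deficient with alpha=0; set alpha>0 (or 'auto')"
        )
    f = _solve_simplex_ridge(B, theta, alpha_val)
    resid = theta - B @ f
    return FractionEstimate(
        fractions=f,
        class_names=basis.class_names,
        residual_norm=float(np.linalg.norm(resid)),
        alpha=alpha_val,
    )


def goodness_of_fit(
    spectrum: CDSpectrum, basis: BasisSet, estimate: FractionEstimate
) -> dict:
    """Residual diagnostics of a fit: per-wavelength residuals and RMS (MRE)."""
    if len(spectrum.wavelengths) != basis.matrix.shape[0]:
        raise ValueError("spectrum and basis dimensions differ")
    if len(estimate.fractions) != basis.n_classes:
        raise ValueError("estimate and basis class counts differ")
    residuals = spectrum.ellipticity - basis.matrix @ estimate.fractions
    return {
        "residuals": residuals,
        "rms_mre": float(np.sqrt(np.mean(residuals**2))),
        "max_abs_mre": float(np.max(np.abs(residuals))),
    }
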