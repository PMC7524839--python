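"""Masked sparse polynomial ODE identification (SINDy with Z-scored library).

A trajectory ``V`` (T x d) is described by ``dV = Xi^T Theta`` where Theta
holds all monomials of total degree <= 3 of the state (constant term first)
and the binary mask decides which entries of Xi may be nonzero.  Derivatives
are estimated with a 5-point fourth-order central stencil followed by a
3-point moving average.  Library columns are Z-scored per fitted snippet (the
constant column is exempt), so integration and stability analysis must carry
the change of coordinates ``dV'(t) = Xi^T [E(V'(t-1)) - mu] / sigma``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LibrarySpec:
    """Ordered monomial library: exponent tuples in graded-lexicographic
    order, constant first."""

    d: int
    max_degree: int
    terms: tuple[tuple[int, ...], ...]

    @property
    def n_terms(self) -> int:
        return len(self.terms)


@dataclass
class NormStats:
    mu: np.ndarray
    sigma: np.ndarray


@dataclass
class CoeffMatrix:
    """Fitted coefficients in the Z-scored library basis plus the
    normalization statistics needed to integrate or analyze them."""

    xi: np.ndarray  # (n_terms, d)
    mask: np.ndarray  # binary (n_terms, d)
    norm: NormStats
    library: LibrarySpec
    fit_r2: np.ndarray | None = None

    def feature_vector(self) -> np.ndarray:
        """Nonzero coefficients in mask order (fixed length per mask)."""
        return self.xi[self.mask.astype(bool)]

    def denormalized(self) -> np.ndarray:
        """Coefficients in the raw monomial basis: since
        dV = Xi^T (Theta - mu)/sigma, the raw coefficient of term m is
        Xi_m/sigma_m, with the constant term absorbing -sum_m Xi_m mu_m/sigma_m.
        """
        raw = self.xi / self.norm.sigma[:, None]
        raw[0] = self.xi[0] - (self.xi[1:] * (self.norm.mu[1:] / self.norm.sigma[1:])[:, None]).sum(axis=0)
        return raw


def build_library(d: int, max_degree: int = 3) -> LibrarySpec:
    """All monomials of total degree <= max_degree in d variables, constant
    first, graded-lexicographic order."""
    if d < 1:
        raise ValueError("d must be >= 1")
    terms = []
    for deg in range(max_degree + 1):
        combos = [
            e
            for e in itertools.product(range(deg + 1), repeat=d)
            if sum(e) == deg
        ]
        combos.sort(reverse=True)  # lexicographic within a degree
        terms.extend(combos)
    return LibrarySpec(d=d, max_degree=max_degree, terms=tuple(terms))


def evaluate_library(spec: LibrarySpec, V: np.ndarray) -> np.ndarray:
    """Theta = E(V): raw monomial values, (T, n_terms)."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    T = V.shape[0]
    cols = np.empty((T, spec.n_terms))
    for j, exps in enumerate(spec.terms):
        col = np.ones(T)
        for k, e in enumerate(exps):
            if e:
                col = col * V[:, k] ** e
        cols[:, j] = col
    return cols


def library_jacobian(spec: LibrarySpec, v: np.ndarray) -> np.ndarray:
    """dE_m/dV_l at a single point v -> (n_terms, d)."""
    v = np.asarray(v, dtype=float)
    J = np.zeros((spec.n_terms, spec.d))
    for m, exps in enumerate(spec.terms):
        for l, e in enumerate(exps):
            if e == 0:
                continue
            val = e * v[l] ** (e - 1)
            for k, ek in enumerate(exps):
                if k != l and ek:
                    val *= v[k] ** ek
            J[m, l] = val
    return J


def estimate_derivatives(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fourth-order 5-point central differences, 3-point smoothed.

    Returns ``(V_trim, dV)`` where the two samples at each end are trimmed so
    both arrays have ``T - 4`` rows and are index-aligned.  The step is one
    sample (1 ms at 1 kHz), so derivatives are per-sample increments.
    """
    V = np.atleast_2d(np.asarray(points, dtype=float))
    if V.shape[0] < 7:
        raise ValueError("trajectory too short for derivative estimation")
    dV = (-V[4:] + 8 * V[3:-1] - 8 * V[1:-3] + V[:-4]) / 12.0
    # 3-point moving average with truncated ends (keeps length T-4)
    sm = dV.copy()
    sm[1:-1] = (dV[:-2] + dV[1:-1] + dV[2:]) / 3.0
    sm[0] = (dV[0] + dV[1]) / 2.0
    sm[-1] = (dV[-2] + dV[-1]) / 2.0
    return V[2:-2], sm


def normalize_library(theta: np.ndarray, spec: LibrarySpec | None = None):
    """Z-score non-constant columns over the fitted snippet.

    The constant column (index 0) is left as ones with (mu, sigma) = (0, 1).
    Returns ``(theta_z, NormStats)``.
    """
    theta = np.asarray(theta, dtype=float)
    mu = theta.mean(axis=0)
    sigma = theta.std(axis=0)
    mu[0] = 0.0
    sigma[0] = 1.0
    bad = np.where(sigma <= 0)[0]
    if len(bad):
        name = bad[0]
        if spec is not None:
            name = spec.terms[bad[0]]
        raise ValueError(f"zero-variance non-constant library column: {name}")
    return (theta - mu) / sigma, NormStats(mu=mu, sigma=sigma)


def fit_coefficients(
    theta_z: np.ndarray,
    dV: np.ndarray,
    mask: np.ndarray,
    norm: NormStats,
    library: LibrarySpec,
) -> CoeffMatrix:
    """Masked ordinary least squares, one output dimension at a time."""
    theta_z = np.asarray(theta_z, dtype=float)
    dV = np.atleast_2d(np.asarray(dV, dtype=float))
    mask = np.asarray(mask, dtype=bool)
    if theta_z.shape[0] != dV.shape[0]:
        raise ValueError("theta_z and dV row counts differ")
    n_terms, d = mask.shape
    if (mask.sum(axis=0) == 0).any():
        raise ValueError("mask must select >=1 term per output dimension")
    xi = np.zeros((n_terms, d))
    r2 = np.zeros(d)
    ss_tot = ((dV - dV.mean(axis=0)) ** 2).sum(axis=0)
    for k in range(d):
        sel = mask[:, k]
        A = theta_z[:, sel]
        coef, _, rank, _ = np.linalg.lstsq(A, dV[:, k], rcond=None)
        xi[sel, k] = coef
        resid = dV[:, k] - A @ coef
        denom = ss_tot[k] if ss_tot[k] > 0 else 1.0
        r2[k] = 1.0 - (resid**2).sum() / denom
    return CoeffMatrix(xi=xi, mask=mask.astype(np.uint8), norm=norm,
                       library=library, fit_r2=r2)


def fit_trajectory(points: np.ndarray, mask: np.ndarray,
                   library: LibrarySpec) -> CoeffMatrix:
    """Convenience: derivatives + library + normalization + masked fit."""
    V, dV = estimate_derivatives(points)
    theta = evaluate_library(library, V)
    theta_z, norm = normalize_library(theta, library)
    return fit_coefficients(theta_z, dV, mask, norm, library)


def rhs(coeffs: CoeffMatrix, V: np.ndarray) -> np.ndarray:
    """De-normalized right-hand side dV = Xi^T [E(V) - mu]/sigma, vectorized
    over rows of V."""
    V2 = np.atleast_2d(V)
    theta = evaluate_library(coeffs.library, V2)
    out = ((theta - coeffs.norm.mu) / coeffs.norm.sigma) @ coeffs.xi
    return out if np.ndim(V) > 1 else out[0]


def integrate_model(
    coeffs: CoeffMatrix,
    ic: np.ndarray,
    n_steps: int,
    data_scale: float = 1.0,
    stiff: bool = False,
) -> tuple[np.ndarray, bool]:
    """Euler-integrate the fitted model for ``n_steps`` one-sample steps.

    Returns ``(trajectory, blew_up)``.  Divergence beyond 1e6 x ``data_scale``
    truncates the run and sets the blow-up flag.  ``stiff=True`` uses scipy's
    BDF solver on the same right-hand side instead of the Euler update.
    """
    ic = np.asarray(ic, dtype=float)
    if stiff:
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda t, y: rhs(coeffs, y),
            (0, n_steps),
            ic,
            method="BDF",
            t_eval=np.arange(n_steps + 1),
        )
        return sol.y.T, not sol.success
    out = np.empty((n_steps + 1, len(ic)))
    out[0] = ic
    v = ic.copy()
    limit = 1e6 * max(data_scale, 1e-300)
    for t in range(1, n_steps + 1):
        v = v + rhs(coeffs, v)
        out[t] = v
        if not np.all(np.isfinite(v)) or np.max(np.abs(v)) > limit:
            return out[: t + 1], True
    return out, False


def multi_step_prediction(
    coeffs: CoeffMatrix, points: np.ndarray, n_steps: int = 4
) -> np.ndarray:
    """Euler-integrate ``n_steps`` from every trajectory point at once."""
    V = np.asarray(points, dtype=float).copy()
    for _ in range(n_steps):
        V = V + rhs(coeffs, V)
    return V


def screen_initial_conditions(
    coeffs: CoeffMatrix,
    source_points: np.ndarray,
    candidates: np.ndarray,
) -> list[int]:
    """Indices of candidate initial conditions whose simulated trajectories
    explore a volume comparable to the source: per-dimension std within
    [1/20, 5] x the source std over the source's duration."""
    src = np.asarray(source_points, dtype=float)
    n_steps = len(src) - 1
    src_std = src.std(axis=0)
    scale = float(np.max(np.abs(src))) or 1.0
    accepted = []
    for i, ic in enumerate(np.atleast_2d(candidates)):
        sim, blew_up = integrate_model(coeffs, ic, n_steps, data_scale=scale)
        if blew_up or len(sim) < n_steps + 1:
            continue
        sim_std = sim.std(axis=0)
        if np.all(sim_std <= 5 * src_std) and np.all(sim_std >= src_std / 20):
            accepted.append(i)
    return accepted
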