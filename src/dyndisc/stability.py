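"""Linear stability analysis of fitted polynomial ODEs.

Fixed points are real solutions of the de-normalized right-hand side
``Xi^T [E(V) - mu]/sigma = 0``, found by multi-start numeric root finding
with relative-tolerance deduplication.  Each fixed point is classified from
the eigenvalues of the analytic Jacobian ``J_kl = sum_m (Xi_mk/sigma_m)
dE_m/dV_l``: oscillatory if any eigenvalue has an imaginary part, convergent
or divergent by the sign of the largest real part, neutral when it sits at
zero; "net convergent" uses the trace (sum of real parts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .sindy import CoeffMatrix, LibrarySpec, NormStats, build_library, \
    evaluate_library, library_jacobian, rhs


@dataclass
class FixedPoint:
    coords: np.ndarray
    eigenvalues: np.ndarray | None = None
    klass: set = field(default_factory=set)
    net_convergent: bool | None = None
    strictly_convergent: bool | None = None
    residual: float = 0.0


def lorenz_coeff_matrix(sigma: float = 10.0, beta: float = 8.0 / 3.0,
                        rho: float = 28.0) -> CoeffMatrix:
    """The Lorenz system expressed as a CoeffMatrix with identity
    normalization (useful as an analytic reference for this module)."""
    lib = build_library(3, 3)
    n = lib.n_terms
    xi = np.zeros((n, 3))
    idx = {t: i for i, t in enumerate(lib.terms)}
    x, y, z = (1, 0, 0), (0, 1, 0), (0, 0, 1)
    xz, xy = (1, 0, 1), (1, 1, 0)
    xi[idx[x], 0] = -sigma
    xi[idx[y], 0] = sigma
    xi[idx[x], 1] = rho
    xi[idx[y], 1] = -1.0
    xi[idx[xz], 1] = -1.0
    xi[idx[xy], 2] = 1.0
    xi[idx[z], 2] = -beta
    mask = (xi != 0).astype(np.uint8)
    mask[0, :] = 1
    return CoeffMatrix(
        xi=xi, mask=mask,
        norm=NormStats(mu=np.zeros(n), sigma=np.ones(n)),
        library=lib,
    )


def jacobian(coeffs: CoeffMatrix, v: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the de-normalized right-hand side at v."""
    JE = library_jacobian(coeffs.library, v)  # (n_terms, d)
    scaled = coeffs.xi / coeffs.norm.sigma[:, None]  # (n_terms, d_out)
    return scaled.T @ JE  # (d_out, d_in)


def find_fixed_points(
    coeffs: CoeffMatrix,
    search_scale: float | np.ndarray = 1.0,
    n_starts: int = 200,
    seed: int = 0,
    tol: float = 1e-10,
    dedup_rtol: float = 1e-6,
) -> list[FixedPoint]:
    """Multi-start root finding for real fixed points.

    Starts are drawn uniformly from a box of half-width ``3 * search_scale``
    per dimension (plus the origin).  Solutions are deduplicated at relative
    tolerance ``dedup_rtol`` and filtered by a scaled residual < 1e-8.
    """
    d = coeffs.library.d
    rng = np.random.default_rng(seed)
    scale = np.broadcast_to(np.asarray(search_scale, dtype=float), (d,))
    starts = [np.zeros(d)]
    starts += list(rng.uniform(-3 * scale, 3 * scale, size=(n_starts, d)))

    def f(v):
        return rhs(coeffs, v)

    def jac(v):
        return jacobian(coeffs, v)

    found: list[np.ndarray] = []
    fscale = max(float(np.max(np.abs(coeffs.xi))), 1.0)
    for x0 in starts:
        sol = root(f, x0, jac=jac, method="hybr", tol=tol)
        if not sol.success:
            continue
        resid = float(np.max(np.abs(f(sol.x)))) / fscale
        if resid > 1e-8:
            continue
        ref = max(float(np.max(np.abs(sol.x))), float(np.max(scale)), 1e-12)
        if any(np.max(np.abs(sol.x - p)) <= dedup_rtol * ref for p in found):
            continue
        found.append(sol.x.copy())
    found.sort(key=lambda p: tuple(np.round(p, 9)))
    return [
        FixedPoint(coords=p,
                   residual=float(np.max(np.abs(f(p)))) / fscale)
        for p in found
    ]


def classify_fixed_points(
    coeffs: CoeffMatrix, points: list[FixedPoint]
) -> list[FixedPoint]:
    """Attach eigen-data and stability classes to fixed points in place."""
    for fp in points:
        J = jacobian(coeffs, fp.coords)
        ev = np.linalg.eigvals(J)
        fp.eigenvalues = ev
        tol = 1e-6 * max(float(np.max(np.abs(ev))), 1e-300)
        klass = set()
        if np.any(np.abs(ev.imag) > tol):
            klass.add("oscillatory")
        max_re = float(np.max(ev.real))
        if max_re < -tol:
            klass.add("convergent")
        elif max_re > tol:
            klass.add("divergent")
        else:
            klass.add("neutral")
        fp.klass = klass
        fp.net_convergent = bool(np.sum(ev.real) < 0)
        fp.strictly_convergent = bool(max_re < -tol)
    return points


def regime_summary(per_trial_points: list[list[FixedPoint]], labels) -> dict:
    """Per-stimulus distribution of fixed-point counts and stability
    fractions (over trials analyzed with the top-ranked mask)."""
    out: dict = {}
    labels = list(labels)
    for lab in sorted(set(labels)):
        fps = [pts for pts, l in zip(per_trial_points, labels) if l == lab]
        counts = [len(p) for p in fps]
        flat = [fp for pts in fps for fp in pts]
        n = len(flat)
        out[lab] = {
            "n_trials": len(fps),
            "fixed_point_counts": counts,
            "frac_net_convergent": (
                sum(fp.net_convergent for fp in flat) / n if n else np.nan
            ),
            "frac_oscillatory": (
                sum("oscillatory" in fp.klass for fp in flat) / n
                if n else np.nan
            ),
        }
    return out


def hopf_threshold_analytic(sigma: float = 10.0,
                            beta: float = 8.0 / 3.0) -> float:
    """Lorenz rho at which the non-origin fixed points lose stability:
    sigma (sigma + beta + 3) / (sigma - beta - 1)."""
    return sigma * (sigma + beta + 3.0) / (sigma - beta - 1.0)


def hopf_threshold_numeric(
    sigma: float = 10.0,
    beta: float = 8.0 / 3.0,
    lo: float = 20.0,
    hi: float = 30.0,
    tol: float = 1e-6,
) -> float:
    """Bisection on rho for the sign flip of the largest Jacobian eigenvalue
    real part at the non-origin Lorenz fixed points (independent numeric
    cross-check of the analytic formula, using this module's Jacobian)."""

    def max_re(rho: float) -> float:
        cm = lorenz_coeff_matrix(sigma, beta, rho)
        q = np.sqrt(beta * (rho - 1.0))
        fp = np.array([q, q, rho - 1.0])
        ev = np.linalg.eigvals(jacobian(cm, fp))
        return float(np.max(ev.real))

    flo, fhi = max_re(lo), max_re(hi)
    if flo * fhi > 0:
        raise ValueError("no eigenvalue sign change in [lo, hi]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if max_re(mid) * flo <= 0:
            hi = mid
        else:
            lo = mid
            flo = max_re(lo)
    return 0.5 * (lo + hi)
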