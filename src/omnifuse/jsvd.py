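"""Joint SVD of multiple omics matrices with a shared orthonormal sample factor.

Each domain matrix ``A_i`` (samples x features, all domains on the same
aligned samples) is factorized as ``A_i ~ U Sigma_i V_i^T`` where ``U``
(I x k) is shared across domains and ``U``, ``V_i`` have orthonormal
columns.  With ``Sigma_i = diag(U^T A_i V_i)`` — the least-squares-optimal
diagonal for fixed factors — the residual

    f(U, V) = sum_i ||A_i - U Sigma_i V_i^T||_F^2
            = sum_i ||A_i||_F^2 - sum_i sum_j (u_j^T A_i v_ij)^2

is minimized over the product of Stiefel manifolds
St(I,k) x St(N_1,k) x ... x St(N_m,k) by a Riemannian trust-region method
(truncated-CG subproblem, QR retraction, exact Riemannian Hessian).
Optimization stops when the projected-gradient norm falls below
``mingradnorm`` (default 1e-12) or after ``max_iterations`` accepted steps.

The rows of the fitted ``U`` are the fused sample embedding used for
clustering downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from omnifuse.io_formats import OmicsMatrix

__all__ = [
    "JsvdOptions",
    "JointFactorization",
    "jsvd_objective",
    "jsvd_gradient",
    "fit_jsvd",
]


# ---------------------------------------------------------------------------
# Stiefel-product geometry.  Points and tangent vectors are lists of arrays
# [U, V_1, ..., V_m]; the metric is the embedded (Frobenius) inner product.
# ---------------------------------------------------------------------------

def _sym(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def _proj(X: list[np.ndarray], Z: list[np.ndarray]) -> list[np.ndarray]:
    """Project an ambient vector onto the tangent space at X (per factor)."""
    return [z - x @ _sym(x.T @ z) for x, z in zip(X, Z)]


def _retract(X: list[np.ndarray], Z: list[np.ndarray]) -> list[np.ndarray]:
    """QR retraction with positive-diagonal sign convention."""
    out = []
    for x, z in zip(X, Z):
        q, r = np.linalg.qr(x + z)
        sign = np.sign(np.diag(r))
        sign[sign == 0] = 1.0
        out.append(q * sign)
    return out


def _inner(A: list[np.ndarray], B: list[np.ndarray]) -> float:
    return float(sum(np.sum(a * b) for a, b in zip(A, B)))


def _norm(A: list[np.ndarray]) -> float:
    return np.sqrt(_inner(A, A))


def _check_dims(U: np.ndarray, V: list[np.ndarray], A: list[np.ndarray]) -> None:
    if len(V) != len(A):
        raise ValueError(f"{len(V)} V factors for {len(A)} domain matrices")
    I, k = U.shape
    for i, (Vi, Ai) in enumerate(zip(V, A)):
        if Ai.shape[0] != I:
            raise ValueError(f"domain {i}: A has {Ai.shape[0]} samples, U has {I}")
        if Vi.shape != (Ai.shape[1], k):
            raise ValueError(
                f"domain {i}: V has shape {Vi.shape}, expected ({Ai.shape[1]}, {k})"
            )


def jsvd_objective(U: np.ndarray, V: list[np.ndarray], A: list[np.ndarray]) -> float:
    """Residual objective sum_i ||A_i - U diag(U^T A_i V_i) V_i^T||_F^2."""
    _check_dims(U, V, A)
    total = 0.0
    for Vi, Ai in zip(V, A):
        d = np.einsum("ji,ji->i", U, Ai @ Vi)  # diag(U^T A_i V_i)
        total += float(np.sum(Ai * Ai)) - float(np.sum(d * d))
    return total


def jsvd_gradient(
    U: np.ndarray, V: list[np.ndarray], A: list[np.ndarray]
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Euclidean gradient of the residual objective w.r.t. U and each V_i.

    G_U = -2 sum_i A_i V_i D_i and G_Vi = -2 A_i^T U D_i with
    D_i = diag(diag(U^T A_i V_i)).  Callers project onto the Stiefel tangent
    space to obtain the Riemannian gradient.
    """
    _check_dims(U, V, A)
    G_U = np.zeros_like(U)
    G_V = []
    for Vi, Ai in zip(V, A):
        AiVi = Ai @ Vi
        d = np.einsum("ji,ji->i", U, AiVi)
        G_U -= 2.0 * AiVi * d
        G_V.append(-2.0 * (Ai.T @ U) * d)
    return G_U, G_V


def _diag_uav(U: np.ndarray, Ai: np.ndarray, Vi: np.ndarray) -> np.ndarray:
    return np.einsum("ji,ji->i", U, Ai @ Vi)


def _egrad(X: list[np.ndarray], A: list[np.ndarray]) -> list[np.ndarray]:
    U, Vs = X[0], X[1:]
    G_U = np.zeros_like(U)
    G_V = []
    for Vi, Ai in zip(Vs, A):
        AiVi = Ai @ Vi
        d = np.einsum("ji,ji->i", U, AiVi)
        G_U -= 2.0 * AiVi * d
        G_V.append(-2.0 * (Ai.T @ U) * d)
    return [G_U, *G_V]


def _ehess(X: list[np.ndarray], xi: list[np.ndarray], A: list[np.ndarray]) -> list[np.ndarray]:
    """Euclidean Hessian-vector product of the residual objective."""
    U, Vs = X[0], X[1:]
    xU, xVs = xi[0], xi[1:]
    H_U = np.zeros_like(U)
    H_V = []
    for Vi, xVi, Ai in zip(Vs, xVs, A):
        AiVi = Ai @ Vi
        AixVi = Ai @ xVi
        d = np.einsum("ji,ji->i", U, AiVi)
        dd = np.einsum("ji,ji->i", xU, AiVi) + np.einsum("ji,ji->i", U, AixVi)
        H_U -= 2.0 * (AixVi * d + AiVi * dd)
        H_V.append(-2.0 * ((Ai.T @ xU) * d + (Ai.T @ U) * dd))
    return [H_U, *H_V]


def _rgrad(X: list[np.ndarray], A: list[np.ndarray]) -> list[np.ndarray]:
    return _proj(X, _egrad(X, A))


def _rhess(
    X: list[np.ndarray], xi: list[np.ndarray], A: list[np.ndarray], eg: list[np.ndarray]
) -> list[np.ndarray]:
    # embedded-Stiefel Hessian: Proj(ehess[xi] - xi * sym(X^T egrad))
    eh = _ehess(X, xi, A)
    corr = [h - x_ @ _sym(x.T @ g) for h, x_, x, g in zip(eh, xi, X, eg)]
    return _proj(X, corr)


# ---------------------------------------------------------------------------
# Truncated CG + Riemannian trust region (Absil, Baker & Gallivan scheme).
# ---------------------------------------------------------------------------

def _truncated_cg(X, A, grad, eg, delta, kappa=0.1, theta=1.0, maxinner=None):
    eta = [np.zeros_like(g) for g in grad]
    r = [g.copy() for g in grad]
    d = [-g for g in grad]
    r_norm0 = _norm(r)
    if maxinner is None:
        maxinner = sum(g.size for g in grad)
    e_e = 0.0
    e_d = 0.0
    d_d = _inner(d, d)
    r_r = r_norm0 ** 2
    for _ in range(maxinner):
        Hd = _rhess(X, d, A, eg)
        dHd = _inner(d, Hd)
        if dHd <= 0:
            # negative curvature: go to the trust-region boundary
            tau = (-e_d + np.sqrt(e_d ** 2 + d_d * (delta ** 2 - e_e))) / d_d
            return [e + tau * di for e, di in zip(eta, d)], True
        alpha = r_r / dHd
        e_e_new = e_e + 2 * alpha * e_d + alpha ** 2 * d_d
        if e_e_new >= delta ** 2:
            tau = (-e_d + np.sqrt(e_d ** 2 + d_d * (delta ** 2 - e_e))) / d_d
            return [e + tau * di for e, di in zip(eta, d)], True
        eta = [e + alpha * di for e, di in zip(eta, d)]
        e_e = e_e_new
        r = [ri + alpha * hi for ri, hi in zip(r, Hd)]
        r = _proj(X, r)  # guard against tangent-space drift
        r_r_new = _inner(r, r)
        if np.sqrt(r_r_new) <= r_norm0 * min(r_norm0 ** theta, kappa):
            return eta, False
        beta = r_r_new / r_r
        r_r = r_r_new
        d = [-ri + beta * di for ri, di in zip(r, d)]
        e_d = beta * (e_d + alpha * d_d)
        d_d = r_r + beta ** 2 * d_d
    return eta, False


def _solve_trust_region(X0, A, mingradnorm, max_iterations):
    """Minimize the residual objective; returns (X, trace, gradnorm, converged)."""
    X = [x.copy() for x in X0]
    f = jsvd_objective(X[0], X[1:], A)
    dim = sum(x.size for x in X)
    delta_bar = np.sqrt(float(dim))
    delta = delta_bar / 8.0
    trace = [f]
    converged = False
    gn = np.inf
    scale = max(1.0, abs(f))
    for _ in range(max_iterations):
        eg = _egrad(X, A)
        grad = _proj(X, eg)
        gn = _norm(grad)
        if gn < mingradnorm:
            converged = True
            break
        eta, on_boundary = _truncated_cg(X, A, grad, eg, delta)
        Heta = _rhess(X, eta, A, eg)
        model_decrease = -(_inner(grad, eta) + 0.5 * _inner(eta, Heta))
        X_new = _retract(X, eta)
        f_new = jsvd_objective(X_new[0], X_new[1:], A)
        rho_reg = 1e-13 * scale
        rho = (f - f_new + rho_reg) / (model_decrease + rho_reg)
        if rho < 0.25:
            delta *= 0.25
        elif rho > 0.75 and on_boundary:
            delta = min(2.0 * delta, delta_bar)
        if rho > 0.05 and f_new <= f:
            X = X_new
            f = f_new
            trace.append(f)
        if delta < 1e-12 * delta_bar:
            # trust region at the floating-point floor: no further progress
            break
    else:
        eg = _egrad(X, A)
        gn = _norm(_proj(X, eg))
        converged = gn < mingradnorm
    return X, trace, gn, converged


# ---------------------------------------------------------------------------
# Public fitting interface
# ---------------------------------------------------------------------------

@dataclass
class JsvdOptions:
    """Options for :func:`fit_jsvd`.

    ``mingradnorm`` is the projected-gradient stopping threshold (1e-12 in
    the melanoma profile); ``init`` is ``"svd"`` (deterministic: U from the
    left singular vectors of the column-concatenated domains) or ``"random"``
    (QR of a seeded Gaussian, for multi-start).
    """

    k: int = 3
    mingradnorm: float = 1e-12
    max_iterations: int = 1000
    init: str = "svd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("rank k must be >= 1")
        if self.mingradnorm <= 0:
            raise ValueError("mingradnorm must be positive")
        if self.init not in ("svd", "random"):
            raise ValueError("init must be 'svd' or 'random'")


@dataclass
class JointFactorization:
    """Fitted joint factorization A_i ~ U Sigma_i V_i^T.

    ``U`` has orthonormal columns ordered by decreasing total energy
    sum_i Sigma_i[j]^2, with signs fixed so each column's largest-magnitude
    entry is positive; every ``Sigma_i`` entry is non-negative.
    """

    sample_ids: list[str]
    domains: list[str]
    U: np.ndarray
    V: list[np.ndarray]
    Sigma: list[np.ndarray]
    feature_ids: list[list[str]]
    k: int
    objective_trace: list[float] = field(default_factory=list)
    final_gradnorm: float = np.inf
    converged: bool = False


def _init_point(A: list[np.ndarray], k: int, init: str, seed: int) -> list[np.ndarray]:
    I = A[0].shape[0]
    if init == "svd":
        concat = np.hstack(A)
        U0 = np.linalg.svd(concat, full_matrices=False)[0][:, :k]
        Vs = []
        for Ai in A:
            B = Ai.T @ U0
            W, _, Zt = np.linalg.svd(B, full_matrices=False)
            Vs.append(W @ Zt)  # polar factor: closest orthonormal V to A^T U
        return [U0, *Vs]
    rng = np.random.default_rng(seed)
    point = []
    for shape in [(I, k)] + [(Ai.shape[1], k) for Ai in A]:
        q, r = np.linalg.qr(rng.standard_normal(shape))
        sign = np.sign(np.diag(r))
        sign[sign == 0] = 1.0
        point.append(q * sign)
    return point


def _canonicalize(U, Vs, A):
    """Order/sign-fix columns: energy-descending, Sigma >= 0, U-major sign +."""
    sigmas = [_diag_uav(U, Ai, Vi) for Ai, Vi in zip(A, Vs)]
    # make every sigma entry non-negative by flipping the domain's V column
    for i, sig in enumerate(sigmas):
        neg = sig < 0
        Vs[i][:, neg] *= -1.0
        sigmas[i] = np.abs(sig)
    energy = np.sum([s ** 2 for s in sigmas], axis=0)
    order = np.argsort(-energy, kind="stable")
    U = U[:, order]
    Vs = [Vi[:, order] for Vi in Vs]
    sigmas = [s[order] for s in sigmas]
    # sign convention on U: largest-|entry| positive; flip paired V columns too
    for j in range(U.shape[1]):
        if U[np.argmax(np.abs(U[:, j])), j] < 0:
            U[:, j] *= -1.0
            for Vi in Vs:
                Vi[:, j] *= -1.0
    return U, Vs, sigmas


def fit_jsvd(A: list[OmicsMatrix], opts: JsvdOptions | None = None) -> JointFactorization:
    """Fit the joint SVD over all domains by Riemannian trust-region descent.

    All matrices must already share identical, aligned sample ids (use
    :func:`omnifuse.io_formats.align_samples`).  The fit is deterministic
    given ``opts.seed`` and ``opts.init``.
    """
    if opts is None:
        opts = JsvdOptions()
    if not A:
        raise ValueError("need at least one domain matrix")
    sample_ids = A[0].sample_ids
    for m in A[1:]:
        if m.sample_ids != sample_ids:
            raise ValueError("domain matrices are not sample-aligned; run align_samples first")
    I = len(sample_ids)
    max_k = min([I] + [m.n_features for m in A])
    if opts.k > max_k:
        raise ValueError(f"k={opts.k} exceeds min(samples, features) = {max_k}")
    mats = [m.values for m in A]
    X0 = _init_point(mats, opts.k, opts.init, opts.seed)
    X, trace, gn, converged = _solve_trust_region(
        X0, mats, opts.mingradnorm, opts.max_iterations
    )
    U, Vs, sigmas = _canonicalize(X[0], X[1:], mats)
    return JointFactorization(
        sample_ids=list(sample_ids),
        domains=[m.domain for m in A],
        U=U,
        V=Vs,
        Sigma=sigmas,
        feature_ids=[list(m.feature_ids) for m in A],
        k=opts.k,
        objective_trace=[float(f) for f in trace],
        final_gradnorm=float(gn),
        converged=bool(converged),
    )
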