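"""Independent oracle for the weighted edge-sparse subproblem.

Solves the identical convex program through a completely different route: an
epigraph reformulation (linear objective, linear inequality constraints, one
convex quadratic constraint) handed to scipy's generic ``trust-constr`` NLP
solver.  Shares no code with the package's ADMM backend.
"""

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, NonlinearConstraint, minimize


def oracle_objective(Kw, phi_w, V, A, state, alpha, beta_sq, gtol=1e-9):
    """Optimal objective value of the weighted subproblem (independent solver).

    minimize  sum_i ||W_d,i V j_i||_1 + alpha sum_i ||W_i j_i||_1
    s.t.      ||phi_w - Kw J A||_F^2 <= beta_sq

    via variables (j, t, s) with t >= |W_d V j| and s >= |alpha W j|.
    """
    E, N = Kw.shape
    n_c, T = A.shape
    M = V.shape[0]
    Ds = [sp.diags(state.W_grad[i]) @ V for i in range(n_c)]
    Ws = [alpha * sp.diags(state.W_src[i]) for i in range(n_c)]
    nj, nt, ns = N * n_c, M * n_c, N * n_c
    nv = nj + nt + ns
    c = np.concatenate([np.zeros(nj), np.ones(nt), np.ones(ns)])

    Dbig, Wbig = sp.block_diag(Ds), sp.block_diag(Ws)
    I_t, I_s = sp.eye(nt), sp.eye(ns)
    Z_ts, Z_st = sp.csr_matrix((nt, ns)), sp.csr_matrix((ns, nt))
    Alin = sp.vstack([
        sp.hstack([Dbig, -I_t, Z_ts]),
        sp.hstack([-Dbig, -I_t, Z_ts]),
        sp.hstack([Wbig, Z_st, -I_s]),
        sp.hstack([-Wbig, Z_st, -I_s]),
    ]).toarray()
    lin = LinearConstraint(Alin, -np.inf, 0.0)

    KtK = Kw.T @ Kw
    P = A @ A.T
    KtPA = Kw.T @ phi_w @ A.T

    def h(v):
        J = v[:nj].reshape((N, n_c), order="F")
        return float(np.sum((phi_w - Kw @ J @ A) ** 2))

    def h_jac(v):
        J = v[:nj].reshape((N, n_c), order="F")
        out = np.zeros(nv)
        out[:nj] = (2 * (KtK @ J @ P - KtPA)).reshape(-1, order="F")
        return out

    nonlin = NonlinearConstraint(h, -np.inf, beta_sq, jac=h_jac)
    x0 = np.zeros(nv)
    J0 = np.linalg.pinv(Kw) @ phi_w @ np.linalg.pinv(A)
    x0[:nj] = J0.reshape(-1, order="F")
    x0[nj:nj + nt] = np.abs(Dbig @ x0[:nj]) * 1.5 + 1e-6
    x0[nj + nt:] = np.abs(Wbig @ x0[:nj]) * 1.5 + 1e-6
    res = minimize(lambda v: c @ v, x0, jac=lambda v: c, method="trust-constr",
                   constraints=[lin, nonlin],
                   options=dict(gtol=gtol, xtol=1e-12, maxiter=3000))
    J = res.x[:nj].reshape((N, n_c), order="F")
    obj = sum(float(np.abs(Ds[i] @ J[:, i]).sum() + np.abs(Ws[i] @ J[:, i]).sum())
              for i in range(n_c))
    return obj, J
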