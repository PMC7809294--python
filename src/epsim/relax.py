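"""Red-black SOR relaxation for 7-point variable-coefficient stencils.

Both the electrostatic (variable-sigma Laplace) and the implicit bioheat
step reduce to the same discrete form on the node lattice:

    (extra_diag + sum_f w_f) x_i  -  sum_f w_f x_nb(f)  =  rhs_i

where the sum runs over the faces f incident to node i, with per-face
weights ``w`` (harmonic-mean conductivities over h^2).  Faces to missing
neighbors (domain boundary) simply do not appear, which *is* the zero-flux
mirror condition.  Nodes outside ``free`` are Dirichlet: they keep their
value in ``x0`` and feed the right-hand side through the neighbor sums.

Convergence is declared on the relative L2 residual of the reduced system,
normalized by the effective right-hand side (rhs plus Dirichlet coupling).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .errors import SolverError


def neighbor_sum(x: np.ndarray, wx: np.ndarray, wy: np.ndarray,
                 wz: np.ndarray) -> np.ndarray:
    """Sum of w_f * x_neighbor over the (up to six) incident faces."""
    s = np.zeros_like(x)
    s[:-1, :, :] += wx * x[1:, :, :]
    s[1:, :, :] += wx * x[:-1, :, :]
    s[:, :-1, :] += wy * x[:, 1:, :]
    s[:, 1:, :] += wy * x[:, :-1, :]
    s[:, :, :-1] += wz * x[:, :, 1:]
    s[:, :, 1:] += wz * x[:, :, :-1]
    return s


def weight_degree(wx: np.ndarray, wy: np.ndarray, wz: np.ndarray,
                  shape) -> np.ndarray:
    """Sum of incident face weights per node (the stencil diagonal part)."""
    d = np.zeros(shape)
    d[:-1, :, :] += wx
    d[1:, :, :] += wx
    d[:, :-1, :] += wy
    d[:, 1:, :] += wy
    d[:, :, :-1] += wz
    d[:, :, 1:] += wz
    return d


def _checkerboard(shape) -> np.ndarray:
    i, j, k = np.indices(shape)
    return (i + j + k) % 2 == 0


def solve(x0: np.ndarray, free: np.ndarray, wx: np.ndarray, wy: np.ndarray,
          wz: np.ndarray, extra_diag, rhs, omega: float = 1.8,
          tol: float = 1e-6, max_iter: int = 50000):
    """Red-black SOR solve; returns (x, iterations, relative residual).

    ``x0`` provides both the warm start on free nodes and the Dirichlet
    values on fixed nodes.  Raises SolverError on non-convergence.
    """
    if not 0.0 < omega < 2.0:
        raise SolverError(f"SOR relaxation factor must be in (0, 2), got {omega}")
    x = np.array(x0, dtype=float, copy=True)
    shape = x.shape
    diag = weight_degree(wx, wy, wz, shape) + extra_diag
    if np.any(diag[free] <= 0):
        raise SolverError("non-positive stencil diagonal on a free node")
    rhs_arr = np.broadcast_to(np.asarray(rhs, dtype=float), shape)

    fixed_vals = np.where(free, 0.0, x)
    b_eff = rhs_arr + neighbor_sum(fixed_vals, wx, wy, wz)
    ref = float(np.linalg.norm(b_eff[free]))
    if ref == 0.0:
        ref = 1.0

    red = _checkerboard(shape)
    masks = (red & free, ~red & free)

    s = neighbor_sum(x, wx, wy, wz)
    res = float(np.linalg.norm((rhs_arr + s - diag * x)[free])) / ref
    if res <= tol:
        return x, 0, res

    for it in range(1, max_iter + 1):
        for m in masks:
            s = neighbor_sum(x, wx, wy, wz)
            x[m] += omega * ((rhs_arr[m] + s[m]) / diag[m] - x[m])
        s = neighbor_sum(x, wx, wy, wz)
        res = float(np.linalg.norm((rhs_arr + s - diag * x)[free])) / ref
        if res <= tol:
            return x, it, res
    raise SolverError(
        f"relaxation did not converge in {max_iter} iterations "
        f"(relative residual {res:.3e}, tolerance {tol:.1e})",
        residual=res, iterations=max_iter)


def assemble_system(free: np.ndarray, wx: np.ndarray, wy: np.ndarray,
                    wz: np.ndarray, extra_diag, rhs, x_fixed: np.ndarray):
    """Sparse matrix/rhs of the reduced system over free nodes.

    Used by the direct-solve oracle in the test suite; the matrix is the
    *identical* stencil the relaxation iterates on.
    """
    shape = free.shape
    n = int(free.sum())
    index = -np.ones(shape, dtype=np.int64)
    index[free] = np.arange(n)
    diag = weight_degree(wx, wy, wz, shape) + extra_diag
    rhs_arr = np.broadcast_to(np.asarray(rhs, dtype=float), shape)
    fixed_vals = np.where(free, 0.0, x_fixed)
    b = (rhs_arr + neighbor_sum(fixed_vals, wx, wy, wz))[free].copy()

    rows = [index[free]]
    cols = [index[free]]
    vals = [diag[free]]
    slabs = (
        (wx, (slice(None, -1), slice(None), slice(None)),
             (slice(1, None), slice(None), slice(None))),
        (wy, (slice(None), slice(None, -1), slice(None)),
             (slice(None), slice(1, None), slice(None))),
        (wz, (slice(None), slice(None), slice(None, -1)),
             (slice(None), slice(None), slice(1, None))),
    )
    for w, sl_a, sl_b in slabs:
        fa, fb = free[sl_a], free[sl_b]
        both = fa & fb
        ia, ib = index[sl_a][both], index[sl_b][both]
        ww = w[both]
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [-ww, -ww]
    a_mat = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n))
    return a_mat, b, index


def direct_solve(x0: np.ndarray, free: np.ndarray, wx, wy, wz,
                 extra_diag, rhs) -> np.ndarray:
    """Sparse direct solve of the same stencil (oracle path)."""
    a_mat, b, index = assemble_system(free, wx, wy, wz, extra_diag, rhs, x0)
    sol = sp.linalg.spsolve(a_mat.tocsc(), b)
    x = np.array(x0, dtype=float, copy=True)
    x[free] = sol[index[free]]
    return x
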