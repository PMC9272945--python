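"""Closed-form Tikhonov-regularized super-resolution reconstruction.

The regularized least-squares problem ``min ||Ax - y||^2 + lambda ||x||^2``
has the closed-form solution ``x = (A^T A + lambda I)^{-1} A^T y``. The
unnormalized weight makes the intensity scale depend on lambda, so the
reconstruction is reparameterized with ``lambda' in [0, 1]``:

    x' = ((1 - lambda') A^T A + lambda' N_R alpha I)^{-1} A^T y = C y

With the overlap-area weight convention (interior rows of ``A`` sum to
``alpha``, per-rotation columns to 1), ``lambda' = 1`` returns the
average low-resolution signal on the high-resolution grid corrected for
the voxel-volume intensity gain, and the reconstruction of constant
data is the constant at every regularization level. The two weights are
related by ``lambda = lambda' N_R alpha / (1 - lambda')``.

Negative outputs (ringing near sharp edges) are preserved, not clipped:
clipping would bias the noise statistics the operator is used to study.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from srrmri.geometry import SamplingOperator

__all__ = ["ReconOperator", "SingularSystemError", "build_recon_operator", "reconstruct"]

logger = logging.getLogger(__name__)


class SingularSystemError(np.linalg.LinAlgError):
    """The unregularized normal equations are rank deficient."""


class ReconOperator:
    """The reconstruction map ``C`` for one sampling operator and lambda'.

    Parameters
    ----------
    sampling : SamplingOperator
        Joint (or single-rotation) sampling operator ``A``.
    lambda_prime : float
        Normalized Tikhonov weight in ``[0, 1]``. 0 is the unregularized
        pseudo-inverse (usually ill-posed for ``alpha > 1``); 1 is the
        volume-normalized back-projection ``A^T / (N_R alpha)``.
    solver : {"auto", "direct", "cg"}
        "direct" factorizes the normal matrix with sparse LU; "cg" uses
        conjugate gradients on the SPD normal equations. "auto" picks
        "direct" below ``direct_threshold`` unknowns.
    direct_threshold : int
        Grid-size cutoff (in voxels) for the direct solver under "auto".
    cg_tol : float
        Relative residual tolerance of the CG solver.
    """

    def __init__(
        self,
        sampling: SamplingOperator,
        lambda_prime: float,
        solver: str = "auto",
        direct_threshold: int = 128 ** 2,
        cg_tol: float = 1e-12,
    ):
        if not 0.0 <= lambda_prime <= 1.0:
            raise ValueError(f"lambda_prime must lie in [0, 1], got {lambda_prime}")
        if solver not in ("auto", "direct", "cg"):
            raise ValueError(f"unknown solver {solver!r}")
        self.sampling = sampling
        self.lambda_prime = float(lambda_prime)
        self.geometry = sampling.geometry
        A = sampling.matrix
        n = A.shape[1]
        scale = sampling.n_rotations * self.geometry.aspect_factor
        self.normalization = scale
        self.normal = ((1.0 - lambda_prime) * sampling.gram
                       + lambda_prime * scale * sp.identity(n, format="csc"))
        if solver == "auto":
            solver = "direct" if n <= direct_threshold else "cg"
        self.solver = solver
        self.cg_tol = cg_tol
        self._lu = None
        if solver == "direct":
            try:
                # the normal matrix is symmetric: MMD on A^T+A cuts fill
                self._lu = spla.splu(self.normal, permc_spec="MMD_AT_PLUS_A")
            except RuntimeError as err:  # SuperLU: "Factor is exactly singular"
                if lambda_prime == 0.0:
                    raise SingularSystemError(
                        "A^T A is rank deficient at lambda_prime = 0; the "
                        "down-sampling makes the problem ill-posed -- use "
                        "lambda_prime > 0"
                    ) from err
                raise

    @property
    def lambda_unnormalized(self) -> float:
        """The raw Tikhonov weight ``lambda = lambda' N_R alpha / (1 - lambda')``."""
        if self.lambda_prime == 1.0:
            return np.inf
        return self.lambda_prime * self.normalization / (1.0 - self.lambda_prime)

    def _solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve ``normal @ x = rhs`` (rhs may hold multiple columns)."""
        if self.solver == "direct":
            x = self._lu.solve(rhs)
            if self.lambda_prime == 0.0:
                res = self.normal @ x - rhs
                denom = max(np.linalg.norm(rhs), 1e-300)
                if np.linalg.norm(res) / denom > 1e-6:
                    raise SingularSystemError(
                        "unregularized normal equations are numerically "
                        "singular; use lambda_prime > 0"
                    )
            return x
        rhs2 = rhs if rhs.ndim == 2 else rhs[:, None]
        out = np.empty_like(rhs2)
        for k in range(rhs2.shape[1]):
            x, info = spla.cg(self.normal, rhs2[:, k], rtol=self.cg_tol, maxiter=10 * rhs2.shape[0])
            if info != 0:
                raise SingularSystemError(
                    f"CG did not converge (info={info}); the system may be "
                    "singular -- use lambda_prime > 0"
                )
            out[:, k] = x
        return out if rhs.ndim == 2 else out[:, 0]

    def apply(self, y: np.ndarray) -> np.ndarray:
        """Apply ``C`` to stacked low-resolution data (last axis = voxels)."""
        y = np.asarray(y, dtype=float)
        m, n = self.sampling.shape[0], self.sampling.shape[1]
        if y.shape[-1] != m:
            raise ValueError(f"data length {y.shape[-1]} does not match operator rows {m}")
        lead = y.shape[:-1]
        rhs = self.sampling.matrix.T @ y.reshape(-1, m).T  # (n, k)
        x = self._solve(rhs)
        return x.T.reshape(*lead, n)

    def reconstruct(self, y) -> np.ndarray:
        """Reconstruct high-resolution plane(s) from low-resolution data.

        ``y`` is either a stacked data vector (last axis = all low-res
        voxels, leading axes e.g. b-values/repetitions/planes) or a list
        of per-rotation images matching the operator's blocks.
        """
        if isinstance(y, (list, tuple)):
            y = self.sampling.stack(y)
        x = self.apply(np.asarray(y, dtype=float))
        return x.reshape(*x.shape[:-1], *self.geometry.grid_shape)

    def noise_std_map(self, method: str = "auto", chunk: int = 1024) -> np.ndarray:
        """Per-voxel noise amplification ``sigma_x(i)/sigma_y``.

        For unit-variance i.i.d. noise on the low-resolution data, the
        reconstructed voxel i has standard deviation equal to the L2
        norm of row i of ``C``, i.e. ``sqrt(diag(M^-1 A^T A M^-1))``
        with M the regularized normal matrix. "eigh" evaluates this in
        the cached eigenbasis of ``A^T A`` (exact, fast on plane-sized
        grids); "solve" accumulates it from linear solves against
        blocks of ``A^T`` columns; "auto" uses "eigh" for direct-solver
        systems and "solve" otherwise.
        """
        if method == "auto":
            method = "eigh" if self.solver == "direct" else "solve"
        if method == "eigh":
            eigvals, eigvecs = self.sampling.gram_eigh()
            den = (1.0 - self.lambda_prime) * eigvals \
                + self.lambda_prime * self.normalization
            sq = (eigvecs ** 2) @ (eigvals / den ** 2)
            return np.sqrt(np.maximum(sq, 0.0)).reshape(self.geometry.grid_shape)
        if method != "solve":
            raise ValueError(f"unknown method {method!r}")
        A = self.sampling.matrix
        m, n = A.shape
        sq = np.zeros(n)
        At = A.T.tocsc()
        for j0 in range(0, m, chunk):
            block = np.asarray(At[:, j0:j0 + chunk].todense())
            X = self._solve(block)
            sq += np.einsum("ij,ij->i", X, X)
        return np.sqrt(sq).reshape(self.geometry.grid_shape)

    def coverage_mask(self, border: int | None = None) -> np.ndarray:
        """Interior mask excluding voxels touched by partial FOV sampling."""
        return self.geometry.interior_mask(border)


def build_recon_operator(
    sampling: SamplingOperator, lambda_prime: float, **kwargs
) -> ReconOperator:
    """Construct the reconstruction operator ``C`` for a sampling system."""
    op = ReconOperator(sampling, lambda_prime, **kwargs)
    logger.debug(
        "recon operator: alpha=%.3g N_R=%d lambda'=%.4g solver=%s",
        op.geometry.aspect_factor, sampling.n_rotations, lambda_prime, op.solver,
    )
    return op


def reconstruct(y, recon: ReconOperator) -> np.ndarray:
    """Functional form of :meth:`ReconOperator.reconstruct`."""
    return recon.reconstruct(y)
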