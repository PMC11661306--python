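"""Hilbert-space approximate Gaussian process (HSGP) basis.

A zero-mean GP with squared-exponential kernel
k(x, x') = sigma exp(-(x - x')^2 / (2 l^2)) (amplitude = variance at zero
distance) is approximated on a standardized input domain [-L, L] by the
Laplacian eigenbasis

    phi_j(x) = sqrt(1/L) sin(omega_j (x + L)),  omega_j = j pi / (2 L),

so that f(x) = sum_j sqrt(sigma S(omega_j)) phi_j(x) z_j with i.i.d.
standard-normal weights z_j and the unit-amplitude SE spectral density
S(omega) = sqrt(2 pi) l exp(-l^2 omega^2 / 2).  The boundary L is the
observed half-range inflated by a boundary factor > 1 so edge effects of
the Dirichlet eigenbasis stay outside the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HSGPConfig:
    """Basis size and domain inflation for the smooth age effect."""

    n_basis: int = 30
    boundary_factor: float = 1.5

    def __post_init__(self):
        if self.n_basis < 10:
            raise ValueError("use at least 10 basis functions")
        if self.boundary_factor <= 1.0:
            raise ValueError("boundary factor must exceed 1")


@dataclass
class HSGPBasis:
    """Standardization constants, eigenfrequencies and a basis evaluator."""

    center: float
    scale: float
    L: float
    omega: np.ndarray

    @classmethod
    def from_values(cls, x: np.ndarray, config: HSGPConfig) -> "HSGPBasis":
        x = np.asarray(x, dtype=float)
        center = x.mean()
        scale = x.std()
        if scale == 0:
            raise ValueError("cannot standardize constant inputs")
        z = (x - center) / scale
        L = config.boundary_factor * np.abs(z).max()
        j = np.arange(1, config.n_basis + 1)
        omega = j * np.pi / (2.0 * L)
        return cls(center=center, scale=scale, L=L, omega=omega)

    def design(self, x: np.ndarray) -> np.ndarray:
        """Eigenfunction matrix Phi with rows phi(x_i), shape (n, m)."""
        z = (np.asarray(x, dtype=float) - self.center) / self.scale
        return np.sin(self.omega[None, :] * (z[:, None] + self.L)) / np.sqrt(self.L)

    def sqrt_spectral(self, sigma, ell) -> np.ndarray:
        """sqrt(sigma S(omega_j)) per walker: sigma, ell (m,) -> (m, n_basis)."""
        sigma = np.atleast_1d(sigma)
        ell = np.atleast_1d(ell)
        S = (np.sqrt(2.0 * np.pi) * ell[:, None]
             * np.exp(-0.5 * (ell[:, None] * self.omega[None, :]) ** 2))
        return np.sqrt(sigma[:, None] * S)


# ---------------------------------------------------------------------------
# closed-form Gaussian-likelihood regressors, used to validate the basis
# approximation against the exact GP


def exact_gp_posterior_mean(x, y, sigma, ell, noise_var, x_new=None) -> np.ndarray:
    """Exact SE-kernel GP regression posterior mean (Gaussian likelihood)."""
    x = np.asarray(x, dtype=float)
    x_new = x if x_new is None else np.asarray(x_new, dtype=float)
    d = x[:, None] - x[None, :]
    K = sigma * np.exp(-0.5 * (d / ell) ** 2)
    Ks = sigma * np.exp(-0.5 * ((x_new[:, None] - x[None, :]) / ell) ** 2)
    A = K + noise_var * np.eye(len(x))
    return Ks @ np.linalg.solve(A, np.asarray(y, dtype=float))


def hsgp_posterior_mean(x, y, sigma, ell, noise_var, config: HSGPConfig,
                        x_new=None) -> np.ndarray:
    """HSGP posterior mean under the same Gaussian likelihood.

    Equivalent to Bayesian ridge regression on the eigenbasis with prior
    weight variances sigma S(omega_j).
    """
    basis = HSGPBasis.from_values(np.asarray(x, dtype=float), config)
    Phi = basis.design(x)
    sq = basis.sqrt_spectral(np.array([sigma]), np.array([ell]))[0]
    B = Phi * sq[None, :]
    A = B.T @ B + noise_var * np.eye(B.shape[1])
    w = np.linalg.solve(A, B.T @ np.asarray(y, dtype=float))
    Phi_new = basis.design(x if x_new is None else np.asarray(x_new, dtype=float))
    return (Phi_new * sq[None, :]) @ w
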