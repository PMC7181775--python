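"""Volume-conductor forward model and sensor-noise model.

The head is modeled as three concentric spherical shells — brain, skull, scalp —
with conductivities 0.33, 0.0165 and 0.33 S/m by default.  The potential of a
current dipole inside the innermost sphere is expanded in spherical harmonics;
for each harmonic order the radial boundary-value problem (potential and normal
current continuity at the two interfaces, zero normal current at the scalp) is
solved as a small linear system, so the same code covers any conductivity
profile, including the homogeneous sphere used for validation.

Sources follow the cortical current density convention: one dipole per mesh
vertex, oriented along the outward surface normal, unit amplitude per unit of
``J``.  The lead field is therefore an E x N gain matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import CorticalMesh

__all__ = [
    "LeadField",
    "NoiseModel",
    "threeshell_leadfield",
    "estimate_noise_covariance",
    "add_noise",
    "DEFAULT_CONDUCTIVITIES",
    "DEFAULT_RADII",
]

#: brain, skull, scalp conductivities in S/m
DEFAULT_CONDUCTIVITIES = (0.33, 0.0165, 0.33)
#: inner-skull, outer-skull, scalp radii in mm (standard adult head defaults)
DEFAULT_RADII = (80.0, 85.0, 92.0)


@dataclass
class LeadField:
    """Gain matrix mapping N source amplitudes to E electrode potentials."""

    K: np.ndarray
    channel_names: list
    units: str = "arb"

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        if not np.isfinite(self.K).all():
            raise ValueError("lead field contains non-finite entries")
        if self.K.ndim != 2 or self.K.shape[0] < 1 or self.K.shape[1] < 1:
            raise ValueError("lead field must be a non-empty E x N matrix")
        if np.any(np.all(self.K == 0, axis=0)):
            raise ValueError("lead field has all-zero columns (invisible sources)")

    @property
    def n_channels(self) -> int:
        return self.K.shape[0]

    @property
    def n_sources(self) -> int:
        return self.K.shape[1]


@dataclass
class NoiseModel:
    """Sensor-noise covariance estimated from baseline activity."""

    sigma: np.ndarray
    baseline_span: tuple = (0.0, 0.0)

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim != 2 or self.sigma.shape[0] != self.sigma.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() <= 0:
            raise ValueError("covariance must be positive definite")

    @property
    def n_channels(self) -> int:
        return self.sigma.shape[0]

    def whitener(self) -> np.ndarray:
        """Symmetric inverse square root of the covariance."""
        w, U = np.linalg.eigh(self.sigma)
        return (U / np.sqrt(w)) @ U.T


def _shell_coefficients(n_orders: int, rho1: float, rho2: float,
                        conductivities) -> np.ndarray:
    """Scalp-surface transfer coefficient T_n for each harmonic order.

    Works in radii scaled by the outer (scalp) radius.  For each order n the
    region potentials are ``rho^-(n+1) + A1 rho^n`` (brain, unit source
    coefficient), ``A2 rho^n + B2 rho^-(n+1)`` (skull) and
    ``A3 rho^n + B3 rho^-(n+1)`` (scalp); continuity of potential and of
    ``sigma dV/drho`` at both interfaces plus zero current at the scalp give a
    5x5 system.  T_n = A3 + B3 is the surface value per unit source
    coefficient.  For equal conductivities T_n reduces to (2n+1)/n.
    """
    s1, s2, s3 = conductivities
    T = np.zeros(n_orders + 1)
    for n in range(1, n_orders + 1):
        r1n, r1m = rho1 ** n, rho1 ** -(n + 1)
        r2n, r2m = rho2 ** n, rho2 ** -(n + 1)
        M = np.array([
            [r1n, -r1n, -r1m, 0.0, 0.0],
            [s1 * n * r1n, -s2 * n * r1n, s2 * (n + 1) * r1m, 0.0, 0.0],
            [0.0, r2n, r2m, -r2n, -r2m],
            [0.0, s2 * n * r2n, -s2 * (n + 1) * r2m, -s3 * n * r2n, s3 * (n + 1) * r2m],
            [0.0, 0.0, 0.0, n, -(n + 1)],
        ])
        rhs = np.array([-r1m, s1 * (n + 1) * r1m, 0.0, 0.0, 0.0])
        sol = np.linalg.solve(M, rhs)
        T[n] = sol[3] + sol[4]
    return T


def threeshell_leadfield(
    mesh: CorticalMesh,
    electrodes: np.ndarray,
    radii=DEFAULT_RADII,
    conductivities=DEFAULT_CONDUCTIVITIES,
    n_orders: int = 60,
    channel_names=None,
) -> LeadField:
    """Analytic lead field for normal dipoles in a three-shell spherical head.

    Parameters
    ----------
    mesh : CorticalMesh
        Source surface; all vertices must lie strictly inside the inner shell.
        Dipoles are unit-amplitude along the outward vertex normals.
    electrodes : (E, 3) array
        Electrode positions in mm; projected radially onto the scalp shell.
    radii : (r_brain, r_skull, r_scalp) in mm, strictly increasing.
    conductivities : three shell conductivities in S/m.
    n_orders : truncation order of the harmonic series.
    """
    r1, r2, r3 = (float(r) for r in radii)
    if not (0 < r1 < r2 < r3):
        raise ValueError("shell radii must be strictly increasing and positive")
    electrodes = np.asarray(electrodes, dtype=float)
    if electrodes.ndim != 2 or electrodes.shape[1] != 3:
        raise ValueError("electrodes must be an (E, 3) array")
    e_norm = np.linalg.norm(electrodes, axis=1)
    if np.any(e_norm == 0):
        raise ValueError("electrode at origin")
    e_hat = electrodes / e_norm[:, None]  # projected onto the scalp sphere

    pos = mesh.vertices
    b = np.linalg.norm(pos, axis=1)
    if np.any(b >= r1):
        bad = np.flatnonzero(b >= r1)
        raise ValueError(
            f"{bad.size} source(s) at or outside the inner shell radius {r1} mm; "
            "scale the mesh to fit"
        )
    orient = mesh.vertex_normals()

    T = _shell_coefficients(n_orders, r1 / r3, r2 / r3, conductivities)

    # angular geometry: cos(gamma) between each electrode and source direction
    with np.errstate(invalid="ignore"):
        r0_hat = np.where(b[:, None] > 0, pos / np.where(b[:, None] > 0, b[:, None], 1.0), 0.0)
    cosg = np.clip(e_hat @ r0_hat.T, -1.0, 1.0)  # E x N
    m_r = np.einsum("nk,nk->n", orient, r0_hat)  # radial moment per source
    p_t = orient - m_r[:, None] * r0_hat  # tangential moment vector
    tang = e_hat @ p_t.T  # E x N: p_t . e_hat (= p_t . e_t since p_t _|_ r0)

    # Legendre recurrences, accumulating the series
    E, N = cosg.shape
    x = cosg
    P_prev = np.ones_like(x)  # P_0
    P_cur = x.copy()  # P_1
    dP_prev = np.zeros_like(x)  # P_0'
    dP_cur = np.ones_like(x)  # P_1'
    ratio = np.clip(b / r3, 0.0, None)  # (b/r3) per source
    rad = np.ones(N)  # (b/r3)^(n-1) running factor
    K = np.zeros((E, N))
    for n in range(1, n_orders + 1):
        f = T[n] * rad  # per-source radial factor
        K += f * (n * m_r * P_cur + tang * dP_cur)
        if n < n_orders:
            P_next = ((2 * n + 1) * x * P_cur - n * P_prev) / (n + 1)
            dP_next = dP_prev + (2 * n + 1) * P_cur
            P_prev, P_cur = P_cur, P_next
            dP_prev, dP_cur = dP_cur, dP_next
            rad = rad * ratio
    K /= 4.0 * np.pi * conductivities[0] * r3 ** 2
    if channel_names is None:
        channel_names = [f"E{i:03d}" for i in range(E)]
    return LeadField(K=K, channel_names=list(channel_names))


def estimate_noise_covariance(
    baseline: np.ndarray,
    shrinkage: float = 0.1,
    baseline_span=(0.0, 0.0),
) -> NoiseModel:
    """Shrunk sample covariance of baseline activity.

    ``Sigma = (1 - shrinkage) * S + shrinkage * diag(S)`` with S the sample
    covariance over time; shrinkage toward the diagonal keeps the estimate
    positive definite even for short or rank-deficient baselines.
    """
    baseline = np.asarray(baseline, dtype=float)
    if baseline.ndim != 2:
        raise ValueError("baseline must be E x T_b")
    e, t_b = baseline.shape
    if t_b < 2:
        raise ValueError("baseline too short: need at least 2 samples")
    S = np.cov(baseline)
    S = np.atleast_2d(S)
    d = np.diag(S)
    if np.any(d <= 0):
        raise ValueError("degenerate baseline: zero-variance channel")
    sigma = (1.0 - shrinkage) * S + shrinkage * np.diag(d)
    return NoiseModel(sigma=sigma, baseline_span=tuple(baseline_span))


def add_noise(clean: np.ndarray, snr_db: float, noise_model: NoiseModel,
              rng=None) -> np.ndarray:
    """Add covariance-shaped noise at a prescribed broadband SNR.

    SNR is defined as ``10 log10(signal power / noise power)`` with power the
    mean squared amplitude over all channels and samples.  The drawn noise is
    rescaled exactly, so the realized broadband SNR equals ``snr_db`` by
    construction.
    """
    clean = np.asarray(clean, dtype=float)
    if np.isposinf(snr_db):
        return clean.copy()
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite or +inf")
    sig_power = np.mean(clean ** 2)
    if sig_power == 0:
        raise ValueError("zero-power signal cannot be given a finite SNR")
    rng = np.random.default_rng(rng)
    e, t = clean.shape
    if noise_model.n_channels != e:
        raise ValueError("noise model channel count does not match signal")
    chol = np.linalg.cholesky(noise_model.sigma)
    noise = chol @ rng.standard_normal((e, t))
    noise_power = np.mean(noise ** 2)
    target_power = sig_power / 10.0 ** (snr_db / 10.0)
    noise *= np.sqrt(target_power / noise_power)
    return clean + noise
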