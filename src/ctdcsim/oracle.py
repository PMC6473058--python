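"""Closed-form series solution for the potential in concentric spherical
shells due to balanced point-current injection on the outer surface.

This is the independent verification route for the finite-element solver: in
a piecewise-homogeneous concentric-sphere conductor the quasistatic potential
admits a Legendre expansion per shell,

    Phi_k(r, gamma) = sum_n [ A_kn (r/b_k)^n + B_kn (a_k/r)^(n+1) ] P_n(cos gamma),

with continuity of Phi and of the radial current density sigma dPhi/dr at
every interface, regularity at the origin, and a Neumann surface condition
matching the injected current density.  A point electrode carrying current I
at the surface expands as sigma dPhi/dr |_R = I (2n+1)/(4 pi R^2) per degree.
The n = 0 mode is excluded, which fixes the gauge to zero mean over every
concentric sphere (and hence over the outer surface).

Units: shell radii in mm, conductivities in S/m, currents in mA, potentials
in volts.  The per-shell basis is normalized by the shell's own radii so the
interface system stays well conditioned at high degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import ShellSpec

__all__ = [
    "SeriesSolution",
    "series_solution",
    "potential_multishell",
    "potential_homogeneous_sphere",
]

_MM = 1e-3  # mm -> m
_MA = 1e-3  # mA -> A


@dataclass
class SeriesSolution:
    """Radial expansion coefficients (per degree, per shell) for a unit (1 mA)
    point source on the outer surface, plus the electrode configuration."""

    shells: list[ShellSpec]
    coeff_a: np.ndarray  # (n_terms, K)
    coeff_b: np.ndarray  # (n_terms, K)
    source_pos: np.ndarray  # unit vector
    sink_pos: np.ndarray  # unit vector
    source_current_ma: float
    convergence: float  # last-degree relative contribution estimate

    @property
    def n_terms(self) -> int:
        return int(self.coeff_a.shape[0])

    def potentials(self, obs_points: np.ndarray) -> np.ndarray:
        """Potential (V) at observation points (mm) inside the outer radius."""
        phi, _ = self.potentials_with_convergence(obs_points)
        return phi

    def potentials_with_convergence(
        self, obs_points: np.ndarray
    ) -> tuple[np.ndarray, float]:
        """Potentials plus the truncation estimate: RMS contribution of the
        final degree relative to the RMS of the running sum.  The estimate
        shrinks like (r/R)^n, so it is the quantity to check at the radii one
        actually evaluates (the series does not converge on the surface
        itself)."""
        obs = np.atleast_2d(np.asarray(obs_points, dtype=float))
        radii_asc = np.array(sorted(s.outer_radius for s in self.shells))
        R = radii_asc[-1]
        r = np.linalg.norm(obs, axis=1)
        if np.any(r > R * (1 + 1e-9)):
            raise ValueError("observation points must lie inside the outer radius")
        r = np.minimum(r, R)
        shell_idx = np.minimum(
            np.searchsorted(radii_asc, r, side="left"), len(radii_asc) - 1
        )
        a_k = np.concatenate([[0.0], radii_asc[:-1]])  # inner radius per shell
        b_k = radii_asc

        with np.errstate(invalid="ignore"):
            units = obs / np.where(r[:, None] > 0, r[:, None], np.inf)
        cos_src = np.clip(units @ self.source_pos, -1.0, 1.0)
        cos_snk = np.clip(units @ self.sink_pos, -1.0, 1.0)
        # r == 0: direction irrelevant (radial part vanishes for n >= 1)
        cos_src = np.where(r > 0, cos_src, 1.0)
        cos_snk = np.where(r > 0, cos_snk, 1.0)

        bk = b_k[shell_idx] * _MM
        ak = a_k[shell_idx] * _MM
        rm = np.where(r > 0, r, 1.0) * _MM

        phi = np.zeros(len(obs))
        # Legendre recurrence, both electrodes at once
        p_prev_s = np.ones_like(cos_src)
        p_cur_s = cos_src.copy()
        p_prev_k = np.ones_like(cos_snk)
        p_cur_k = cos_snk.copy()
        I = self.source_current_ma * _MA
        contrib = np.zeros_like(phi)
        for n in range(1, self.n_terms + 1):
            A = self.coeff_a[n - 1, shell_idx]
            B = self.coeff_b[n - 1, shell_idx]
            radial = A * (rm / bk) ** n
            inner = ak > 0
            radial = radial + np.where(
                inner & (r > 0), B * (np.where(inner, ak, rm) / rm) ** (n + 1), 0.0
            )
            ang = p_cur_s - p_cur_k  # source +I, sink -I
            contrib = I * radial * ang
            phi += contrib
            # advance recurrence to degree n+1
            p_next_s = ((2 * n + 1) * cos_src * p_cur_s - n * p_prev_s) / (n + 1)
            p_prev_s, p_cur_s = p_cur_s, p_next_s
            p_next_k = ((2 * n + 1) * cos_snk * p_cur_k - n * p_prev_k) / (n + 1)
            p_prev_k, p_cur_k = p_cur_k, p_next_k
        denom = float(np.sqrt(np.mean(phi**2)))
        conv = float(np.sqrt(np.mean(contrib**2))) / denom if denom > 0 else 0.0
        return phi, conv


def _solve_coefficients(shells: list[ShellSpec], n_terms: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-degree interface systems for a unit (1 mA) point source at the
    outer surface.  Returns (A, B) of shape (n_terms, K) and a convergence
    estimate (surface-potential contribution of the last degree relative to
    the running sum)."""
    order = sorted(shells, key=lambda s: s.outer_radius)
    K = len(order)
    b_k = np.array([s.outer_radius for s in order]) * _MM
    a_k = np.concatenate([[0.0], b_k[:-1]])
    sig = np.array([s.conductivity for s in order])
    R = b_k[-1]

    A = np.zeros((n_terms, K))
    B = np.zeros((n_terms, K))
    surf_sum = 0.0
    last = 0.0
    for n in range(1, n_terms + 1):
        m = np.zeros((2 * K - 1, 2 * K - 1))
        rhs = np.zeros(2 * K - 1)
        # unknown ordering: A_1, A_2, B_2, A_3, B_3, ...
        def col_a(k):  # 0-based shell
            return 0 if k == 0 else 2 * k - 1

        def col_b(k):
            return 2 * k

        row = 0
        for k in range(K - 1):  # interface at b_k[k]
            rb = b_k[k]
            # potential continuity
            m[row, col_a(k)] = 1.0  # (rb/b_k)^n = 1
            if k > 0:
                m[row, col_b(k)] = (a_k[k] / rb) ** (n + 1)
            m[row, col_a(k + 1)] = -((rb / b_k[k + 1]) ** n)
            m[row, col_b(k + 1)] = -1.0  # (a_{k+1}/rb)^(n+1) with a_{k+1}=rb
            row += 1
            # flux continuity: sigma * dPhi/dr
            m[row, col_a(k)] = sig[k] * n / rb
            if k > 0:
                m[row, col_b(k)] = -sig[k] * (n + 1) / rb * (a_k[k] / rb) ** (n + 1)
            m[row, col_a(k + 1)] = -sig[k + 1] * (n / rb) * (rb / b_k[k + 1]) ** n
            m[row, col_b(k + 1)] = sig[k + 1] * (n + 1) / rb
            row += 1
        # outer Neumann: sigma_K dPhi/dr |_R = (2n+1)/(4 pi R^2) per unit current
        m[row, col_a(K - 1)] = sig[-1] * n / R
        if K > 1:
            m[row, col_b(K - 1)] = -sig[-1] * (n + 1) / R * (a_k[-1] / R) ** (n + 1)
        rhs[row] = (2 * n + 1) / (4 * np.pi * R * R)

        sol = np.linalg.solve(m, rhs)
        A[n - 1, 0] = sol[0]
        for k in range(1, K):
            A[n - 1, k] = sol[col_a(k)]
            B[n - 1, k] = sol[col_b(k)]
        # surface-potential magnitude of this degree (basis values are ~1 at R)
        last = abs(A[n - 1, -1]) + abs(B[n - 1, -1]) * (a_k[-1] / R) ** (n + 1)
        surf_sum += last
    conv = last / surf_sum if surf_sum > 0 else 0.0
    return A, B, conv


def potential_multishell(
    shells: list[ShellSpec] | tuple[ShellSpec, ...],
    source: tuple[np.ndarray, float],
    sink: tuple[np.ndarray, float],
    obs_points: np.ndarray,
    n_terms: int = 100,
    convergence_tol: float | None = 1e-8,
) -> np.ndarray:
    """Series potential (V) at ``obs_points`` (mm) for point electrodes on the
    outer surface.

    ``source``/``sink`` are (position_mm, current_mA) with balanced currents
    of opposite sign (Neumann compatibility).  Positions are projected onto
    the outer sphere.  When ``convergence_tol`` is set, the last-degree
    contribution at the observation radii (relative RMS) must fall below it,
    else a RuntimeError asks for more terms — point-electrode series converge
    slowly near the surface, so a fixed default truncation is never trusted
    blindly.
    """
    sol = series_solution(shells, source, sink, n_terms)
    phi, conv = sol.potentials_with_convergence(obs_points)
    if sol.source_current_ma != 0 and convergence_tol is not None and conv > convergence_tol:
        raise RuntimeError(
            f"series not converged at the observation points: last-degree "
            f"relative contribution {conv:.2e} > {convergence_tol:.0e}; "
            f"increase n_terms or move points inward"
        )
    return phi


def series_solution(
    shells,
    source: tuple[np.ndarray, float],
    sink: tuple[np.ndarray, float],
    n_terms: int = 100,
) -> SeriesSolution:
    """Build the reusable :class:`SeriesSolution` (see potential_multishell)."""
    shells = list(shells)
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    (src_pos, i_src), (snk_pos, i_snk) = source, sink
    if abs(i_src + i_snk) > 1e-12 * max(abs(i_src), abs(i_snk), 1.0):
        raise ValueError(
            f"source and sink currents must balance (got {i_src} and {i_snk} mA)"
        )
    if i_src != 0 and i_src * i_snk >= 0:
        raise ValueError("source and sink currents must have opposite signs")
    src = np.asarray(src_pos, dtype=float)
    snk = np.asarray(snk_pos, dtype=float)
    src = src / np.linalg.norm(src)
    snk = snk / np.linalg.norm(snk)

    A, B, conv = _solve_coefficients(shells, n_terms)
    if i_src == 0:
        A = np.zeros_like(A)
        B = np.zeros_like(B)
    return SeriesSolution(
        shells=shells,
        coeff_a=A,
        coeff_b=B,
        source_pos=src,
        sink_pos=snk,
        source_current_ma=float(i_src),
        convergence=conv,
    )


def potential_homogeneous_sphere(
    radius_mm: float,
    sigma: float,
    source: tuple[np.ndarray, float],
    sink: tuple[np.ndarray, float],
    obs_points: np.ndarray,
) -> np.ndarray:
    """Closed form for the homogeneous sphere (same zero-mean gauge as the
    series): for a unit point current at surface point with angle gamma,

        Phi = I/(4 pi sigma R) [ 2R/d - 2 + ln( 2R / (R - r cos gamma + d) ) ],

    where d is the chord distance from the observation point to the
    electrode.  Obtained by summing sum_{n>=1} (2n+1)/n x^n P_n in closed
    form."""
    obs = np.atleast_2d(np.asarray(obs_points, dtype=float)) * _MM
    R = radius_mm * _MM
    out = np.zeros(len(obs))
    for pos, cur in (source, sink):
        if cur == 0:
            continue
        e = np.asarray(pos, dtype=float)
        e = e / np.linalg.norm(e) * R
        d = np.linalg.norm(obs - e, axis=1)
        r = np.linalg.norm(obs, axis=1)
        rc = obs @ e / R  # r cos(gamma)
        term = 2 * R / d - 2.0 + np.log(2 * R / (R - rc + d))
        out += (cur * _MA) / (4 * np.pi * sigma * R) * term
    return out
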