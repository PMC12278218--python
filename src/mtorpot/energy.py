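"""The multitorsional potential: window terms, chain sums, gradients.

The potential couples all virtual-bond dihedrals γ (and angles θ) of a
chain window of ``m`` residues (7 ≤ m ≤ m_max) in a single product term:
the two γ at the window ends enter through sine factors, the interior γ
through cosine factors, and every factor is damped by powers of sin θ so
that the term is large only for folded (θ ≈ 90°) geometry.  Summed over
all windows of a chain, these products encode the cooperativity of
α-helix formation: a contiguous helical stretch accumulates many mutually
reinforcing negative contributions.

For a window starting at 0-based residue ``s`` with length ``m`` and
multiplicity M (φ_c = γ_c + Ψ of the axis-bond residue pair; compact
index ``c`` as in :mod:`mtorpot.geometry`)::

    U(s, m) = - sum_M w_M  sinθ_s^M sin(M φ_s)
              * prod_{c=s+1}^{s+m-5} sinθ_c^{2M} cos(M φ_c)
              * sinθ_{s+m-4}^{2M} sin(M φ_{s+m-4}) * sinθ_{s+m-3}^M

(θ compact index c sits at residue c+1; γ compact index c has its axis on
the virtual bond between residues c+1 and c+2.)
"""

from __future__ import annotations

import logging
from typing import Iterator

import numpy as np

from .geometry import (
    CAlphaTrace,
    InternalGeometry,
    ReducedSequence,
    bond_angle_gradient,
    dihedral_gradient,
    internal_from_trace,
)
from .params import PAIR_INDEX, MtorParamSet, TemperatureConfig

__all__ = [
    "temperature_factor",
    "segment_term",
    "chain_energy",
    "chain_energy_angles",
    "chain_energy_and_angle_grads",
    "chain_gradient",
    "mtor_contribution",
    "pair_indices",
]

logger = logging.getLogger(__name__)

MIN_WINDOW = 7


def temperature_factor(n: int, cfg: TemperatureConfig | None = None, *,
                       T: float | None = None) -> float:
    """Temperature damping factor f_n(T) of order-n cooperative terms.

    f_n(T) = ln(e + 1/e) / ln(exp(x) + exp(-x)) with x = (T / T_o)^(n-1).
    Equals 1 at T = T_o and decreases with T above it, melting cooperative
    terms faster the higher their order.
    """
    if cfg is None:
        cfg = TemperatureConfig()
    if T is None:
        T = cfg.T
    if n < 2:
        raise ValueError("factor order n must be >= 2")
    if T <= 0:
        raise ValueError("temperature must be positive")
    x = (T / cfg.T_o) ** (n - 1)
    return float(np.log(np.exp(1) + np.exp(-1)) / np.log(np.exp(x) + np.exp(-x)))


def mtor_contribution(U: float, w_mtor: float, cfg: TemperatureConfig | None = None) -> float:
    """Weighted, temperature-scaled contribution f_{n_f}(T) * w_mtor * U.

    This is the amount the multitorsional chain energy ``U`` adds to a host
    force field; the host energy itself is an external input.
    """
    if w_mtor < 0:
        raise ValueError("w_mtor must be non-negative")
    if cfg is None:
        cfg = TemperatureConfig()
    return temperature_factor(cfg.n_f, cfg) * w_mtor * U


def pair_indices(seq: ReducedSequence | str) -> np.ndarray:
    """Phase-angle lookup indices for every γ of a chain.

    Entry ``c`` is the `PAIRS` index of the ordered residue-type pair on the
    axis bond of γ_c, i.e. residues ``c+1`` and ``c+2``.
    """
    types = seq.types if isinstance(seq, ReducedSequence) else str(seq)
    n = len(types)
    return np.array([PAIR_INDEX[types[c + 1] + types[c + 2]] for c in range(max(n - 3, 0))],
                    dtype=np.intp)


def iter_windows(n: int, m_max: int) -> Iterator[tuple[int, int]]:
    """All (start, length) windows the chain sum runs over."""
    for m in range(MIN_WINDOW, min(m_max, n) + 1):
        for s in range(n - m + 1):
            yield s, m


def _window_valid(theta_ok: np.ndarray, gamma_ok: np.ndarray, s: int, m: int) -> bool:
    return bool(theta_ok[s:s + m - 2].all() and gamma_ok[s:s + m - 3].all())


def _prepare(theta_deg, gamma_deg, pair_idx, params: MtorParamSet):
    theta = np.nan_to_num(np.radians(np.asarray(theta_deg, dtype=float)))
    gamma = np.radians(np.asarray(gamma_deg, dtype=float))
    pair_idx = np.asarray(pair_idx, dtype=np.intp)
    psi = np.radians(params.psi_vector)
    phase = np.nan_to_num(gamma) + psi[pair_idx]
    return np.sin(theta), np.cos(theta), phase


def chain_energy_angles(theta_deg, gamma_deg, pair_idx, params: MtorParamSet, *,
                        theta_ok: np.ndarray | None = None,
                        gamma_ok: np.ndarray | None = None,
                        per_window: bool = False):
    """Multitorsional chain energy evaluated directly on internal angles.

    Vectorized over any leading batch dimensions of ``theta_deg``
    (shape ``(..., n-2)``) and ``gamma_deg`` (``(..., n-3)``); ``pair_idx``
    gives the phase-angle index per γ (see :func:`pair_indices`).

    ``theta_ok``/``gamma_ok`` are 1-D validity masks shared across the
    batch; windows touching an undefined angle contribute zero.  With
    ``per_window=True`` returns ``{(s, m): energy}`` instead of the sum.
    """
    sin_t, _, phase = _prepare(theta_deg, gamma_deg, pair_idx, params)
    nt = sin_t.shape[-1]
    n = nt + 2
    if phase.shape[-1] != nt - 1:
        raise ValueError("gamma must have one entry fewer than theta")
    if theta_ok is None:
        theta_ok = np.ones(nt, dtype=bool)
    if gamma_ok is None:
        gamma_ok = np.ones(max(n - 3, 0), dtype=bool)

    total = np.zeros(np.broadcast_shapes(sin_t.shape[:-1], phase.shape[:-1]))
    windows: dict[tuple[int, int], np.ndarray] = {}
    for M, w in params.active_multiplicities():
        stM = sin_t ** M
        st2M = stM * stM
        sM = np.sin(M * phase)
        cM = np.cos(M * phase)
        for s, m in iter_windows(n, params.m_max):
            if not _window_valid(theta_ok, gamma_ok, s, m):
                continue
            core = np.prod(st2M[..., s + 1:s + m - 4] * cM[..., s + 1:s + m - 4], axis=-1)
            term = (-w * stM[..., s] * sM[..., s] * core
                    * st2M[..., s + m - 4] * sM[..., s + m - 4] * stM[..., s + m - 3])
            total = total + term
            if per_window:
                key = (s, m)
                windows[key] = windows.get(key, 0.0) + term
    return windows if per_window else total


def segment_term(geom: InternalGeometry, seq: ReducedSequence, params: MtorParamSet,
                 i: int, m: int) -> float:
    """Single-window multitorsional term for the window ``[i, i+m-1]``.

    ``i`` is the 0-based start residue.  Windows shorter than 7 residues or
    extending past the chain raise; a window touching an undefined angle
    returns 0 (the factors' sin θ vanish at the degeneracy anyway).
    """
    n = geom.n
    if m < MIN_WINDOW:
        raise ValueError(f"window length m={m} below minimum {MIN_WINDOW}")
    if i < 0 or i + m > n:
        raise ValueError(f"window [{i}, {i + m - 1}] outside chain of {n} residues")
    if not _window_valid(geom.theta_defined, geom.gamma_defined, i, m):
        logger.info("window (i=%d, m=%d) touches undefined angles: term skipped", i, m)
        return 0.0
    total = 0.0
    for M, w in params.active_multiplicities():
        th = np.radians(geom.theta)
        psi = np.radians(params.psi_vector)[pair_indices(seq)]
        ph = np.radians(geom.gamma) + psi
        st = np.sin(th)
        core = np.prod((st[i + 1:i + m - 4] ** (2 * M)) * np.cos(M * ph[i + 1:i + m - 4]))
        total += (-w * st[i] ** M * np.sin(M * ph[i]) * core
                  * st[i + m - 4] ** (2 * M) * np.sin(M * ph[i + m - 4])
                  * st[i + m - 3] ** M)
    return float(total)


def chain_energy(geom: InternalGeometry, seq: ReducedSequence, params: MtorParamSet) -> float:
    """Total multitorsional energy: sum over all windows m = 7..m_max.

    Chains shorter than 7 residues have no admissible window and return 0.
    Applied to an isolated fragment this is exactly the folded-fragment
    energy V_mtor;n that the likelihood fit works with.
    """
    n = geom.n
    if len(seq) != n:
        raise ValueError("sequence length does not match geometry")
    if n < MIN_WINDOW:
        return 0.0
    return float(chain_energy_angles(
        geom.theta, geom.gamma, pair_indices(seq), params,
        theta_ok=geom.theta_defined, gamma_ok=geom.gamma_defined))


def chain_energy_and_angle_grads(theta_deg, gamma_deg, pair_idx, params: MtorParamSet, *,
                                 theta_ok: np.ndarray | None = None,
                                 gamma_ok: np.ndarray | None = None):
    """Energy plus analytic derivatives w.r.t. every θ and γ (per radian).

    Returns ``(E, dE_dtheta, dE_dgamma)`` with the derivative arrays
    matching the input shapes.  Because each γ enters the potential only
    through γ + Ψ, ``dE_dgamma`` doubles as the derivative w.r.t. the phase
    angle attached to that γ, which is what the likelihood fit needs.
    """
    sin_t, cos_t, phase = _prepare(theta_deg, gamma_deg, pair_idx, params)
    nt = sin_t.shape[-1]
    n = nt + 2
    if theta_ok is None:
        theta_ok = np.ones(nt, dtype=bool)
    if gamma_ok is None:
        gamma_ok = np.ones(max(n - 3, 0), dtype=bool)

    batch = np.broadcast_shapes(sin_t.shape[:-1], phase.shape[:-1])
    E = np.zeros(batch)
    dth = np.zeros(batch + (nt,))
    dga = np.zeros(batch + (nt - 1,))

    # cot θ is safe here: terms with sin θ -> 0 vanish faster than cot blows up,
    # and exactly-degenerate angles are excluded by the validity masks upstream.
    with np.errstate(divide="ignore", invalid="ignore"):
        cot = np.where(np.abs(sin_t) > 1e-12, cos_t / np.where(sin_t == 0, 1.0, sin_t), 0.0)

    for M, w in params.active_multiplicities():
        stM = sin_t ** M
        st2M = stM * stM
        sM = np.sin(M * phase)
        cM = np.cos(M * phase)
        F = st2M[..., :nt - 1] * cM  # interior factors by compact index
        for s, m in iter_windows(n, params.m_max):
            if not _window_valid(theta_ok, gamma_ok, s, m):
                continue
            lead = stM[..., s] * sM[..., s]
            pen = st2M[..., s + m - 4] * sM[..., s + m - 4]
            last = stM[..., s + m - 3]
            inner = F[..., s + 1:s + m - 4]
            L = inner.shape[-1]
            core = np.prod(inner, axis=-1)
            term = -w * lead * core * pen * last
            E += term

            # exclusion products for the interior factors
            pre = np.cumprod(inner, axis=-1)
            suf = np.flip(np.cumprod(np.flip(inner, axis=-1), axis=-1), axis=-1)
            base = -w * lead * pen * last  # common factor when one interior is replaced

            # lead position (sin factor, exponents M / M)
            dth[..., s] += -w * (M * cot[..., s] * lead) * core * pen * last
            dga[..., s] += -w * (stM[..., s] * M * cM[..., s]) * core * pen * last
            # interior positions
            for j in range(L):
                c = s + 1 + j
                excl = np.ones(batch)
                if j > 0:
                    excl = excl * pre[..., j - 1]
                if j < L - 1:
                    excl = excl * suf[..., j + 1]
                dth[..., c] += base * excl * (2 * M * cot[..., c] * F[..., c])
                dga[..., c] += base * excl * (-st2M[..., c] * M * sM[..., c])
            # penultimate position (sin factor, exponent 2M)
            p = s + m - 4
            dth[..., p] += -w * lead * core * (2 * M * cot[..., p] * pen) * last
            dga[..., p] += -w * lead * core * (st2M[..., p] * M * cM[..., p]) * last
            # last θ
            q = s + m - 3
            dth[..., q] += -w * lead * core * pen * (M * cot[..., q] * last)
    return E, dth, dga


def chain_gradient(trace: CAlphaTrace, seq: ReducedSequence, params: MtorParamSet,
                   geom: InternalGeometry | None = None) -> np.ndarray:
    """Cartesian gradient of the chain energy: ∂U/∂x for every Cα atom.

    Obtained by the chain rule through the internal coordinates; matches
    central finite differences of :func:`chain_energy`.  Windows touching
    degenerate (collinear) geometry contribute zero, as does the energy.
    """
    if geom is None:
        geom = internal_from_trace(trace)
    n = geom.n
    grad = np.zeros((n, 3))
    if n < MIN_WINDOW:
        return grad
    _, dth, dga = chain_energy_and_angle_grads(
        geom.theta, geom.gamma, pair_indices(seq), params,
        theta_ok=geom.theta_defined, gamma_ok=geom.gamma_defined)
    x = trace.coords
    for c in range(n - 2):
        if dth[c] == 0.0:
            continue
        _, g0, g1, g2 = bond_angle_gradient(x[c], x[c + 1], x[c + 2])
        for a, g in zip(range(c, c + 3), (g0, g1, g2)):
            grad[a] += dth[c] * g
    for c in range(n - 3):
        if dga[c] == 0.0:
            continue
        _, gs = dihedral_gradient(x[c], x[c + 1], x[c + 2], x[c + 3])
        for a, g in zip(range(c, c + 4), gs):
            grad[a] += dga[c] * g
    return grad
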