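"""Maximum-likelihood parametrization of the phase angles Ψ.

Under the assumption that the internal angles of folded-helical fragments
follow a Boltzmann distribution with the fragment's multitorsional energy
V, the negative log-likelihood of a fragment collection is

    L = Σ_j [ V(Θ_j, Γ_j; w, Ψ) / RT + ln Q_n_j(w, Ψ) ]

with Q_n the configurational integral of exp(-V/RT) over all θ ∈ (0°,180°)
and γ ∈ [0°,360°) of an n-residue fragment.  Because every γ enters V only
through γ + Ψ and γ lives on a full circle, Q_n is independent of Ψ at
fixed weights: fitting Ψ therefore only needs the Σ V/RT part, while
comparing different weight combinations needs the ln Q_n terms (estimated
here by plain Monte Carlo).

A Metropolis sampler for fragments under exp(-V/RT) is included so the
fitting machinery can be validated by parameter recovery on synthetic data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .energy import chain_energy_angles, chain_energy_and_angle_grads, pair_indices
from .params import PAIRS, MtorParamSet
from .segments import SegmentDataset

__all__ = [
    "FitResult",
    "SampledFragmentSet",
    "neg_log_likelihood",
    "estimate_partition",
    "fit_phase_angles",
    "scan_weights",
    "sample_boltzmann_fragments",
]

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    """Outcome of one phase-angle optimization at fixed weights."""

    psi_deg: dict[str, float]
    weights: tuple[float, float]
    L: float
    lnQ_included: bool
    converged: bool
    iterations: int
    grad_norm: float

    def to_param_set(self, m_max: int = 20, name: str = "fitted") -> MtorParamSet:
        return MtorParamSet(weights={1: self.weights[0], 2: self.weights[1]},
                            psi_deg=dict(self.psi_deg), m_max=m_max, name=name)

    def to_dict(self) -> dict:
        return {
            "psi_deg": dict(self.psi_deg),
            "weights": list(self.weights),
            "L": self.L,
            "lnQ_included": self.lnQ_included,
            "converged": self.converged,
            "iterations": self.iterations,
            "grad_norm": self.grad_norm,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


@dataclass
class SampledFragmentSet:
    """Synthetic fragments of equal length with their generator manifest."""

    theta: np.ndarray            # (count, n-2) degrees
    gamma: np.ndarray            # (count, n-3) degrees
    rtypes: str                  # shared reduced sequence, length n
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        n = len(self.rtypes)
        if self.theta.shape[1:] != (n - 2,) or self.gamma.shape[1:] != (n - 3,):
            raise ValueError("angle array widths inconsistent with sequence length")

    @property
    def n(self) -> int:
        return len(self.rtypes)

    @property
    def count(self) -> int:
        return len(self.theta)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in range(self.count):
            for p in range(self.n - 2):
                has_g = p < self.n - 3
                rows.append({
                    "fragment": f, "position": p,
                    "pair": (self.rtypes[p + 1] + self.rtypes[p + 2]) if has_g else "",
                    "theta": self.theta[f, p],
                    "gamma": self.gamma[f, p] if has_g else np.nan,
                })
        return pd.DataFrame(rows)

    def save(self, tsv_path, manifest_path=None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if manifest_path is not None:
            Path(manifest_path).write_text(json.dumps(self.manifest, indent=1) + "\n")


def _fragment_groups(ds) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Group a dataset into equal-length batches of (theta, gamma, pair_idx)."""
    if isinstance(ds, SampledFragmentSet):
        pid = np.broadcast_to(pair_indices(ds.rtypes), ds.gamma.shape)
        return {ds.n: (ds.theta, ds.gamma, pid)}
    if not isinstance(ds, SegmentDataset):
        raise TypeError("expected SegmentDataset or SampledFragmentSet")
    buckets: dict[int, list] = {}
    skipped = 0
    for seg in ds.segments:
        if np.isnan(seg.theta).any() or np.isnan(seg.gamma).any():
            skipped += 1
            continue
        buckets.setdefault(seg.length, []).append(seg)
    if skipped:
        logger.warning("%d segment(s) with undefined angles excluded from the fit", skipped)
    out = {}
    for n, segs in sorted(buckets.items()):
        out[n] = (np.stack([s.theta for s in segs]),
                  np.stack([s.gamma for s in segs]),
                  np.stack([pair_indices(s.rtypes) for s in segs]))
    return out


def estimate_partition(n: int, params: MtorParamSet, RT: float = 1.0,
                       n_samples: int = 20000, seed: int = 0,
                       pair_idx: np.ndarray | None = None) -> tuple[float, float]:
    """Plain Monte Carlo estimate of the fragment partition function Q_n.

    The integral of exp(-V/RT) runs over the flat measure dΘ dΓ with
    θ ∈ (0°, 180°) and γ ∈ [0°, 360°), in degree units; the zero-potential
    value is therefore exactly 180^(n-2) * 360^(n-3).  Returns
    ``(estimate, standard error)``; deterministic for a given seed.
    """
    if not 7 <= n:
        raise ValueError("fragment length must be at least 7")
    if n_samples < 1000:
        raise ValueError("n_samples must be at least 1000")
    rng = np.random.default_rng(seed)
    if pair_idx is None:
        pair_idx = np.full(n - 3, PAIRS.index("AA"), dtype=np.intp)
    volume = 180.0 ** (n - 2) * 360.0 ** (n - 3)
    if not params.active_multiplicities():
        return volume, 0.0
    theta = rng.uniform(0.0, 180.0, (n_samples, n - 2))
    gamma = rng.uniform(0.0, 360.0, (n_samples, n - 3))
    boltz = np.exp(-chain_energy_angles(theta, gamma, pair_idx, params) / RT)
    q = volume * float(boltz.mean())
    se = volume * float(boltz.std(ddof=1)) / np.sqrt(n_samples)
    return q, se


def neg_log_likelihood(ds, params: MtorParamSet, include_lnQ: bool = False,
                       RT: float = 1.0, lnQ_samples: int = 50000,
                       lnQ_seed: int = 0) -> float:
    """Negative log-likelihood L of a fragment dataset under the potential.

    Without the ln Q terms this is exactly Σ_j V_j / RT — the objective the
    phase-angle fit minimizes.  With ``include_lnQ`` each fragment adds
    ln Q_n for its length (Monte Carlo estimate, shared per length).
    """
    groups = _fragment_groups(ds)
    if not groups:
        raise ValueError("empty dataset")
    total = 0.0
    for n, (th, ga, pid) in groups.items():
        total += float(np.sum(chain_energy_angles(th, ga, pid, params))) / RT
        if include_lnQ:
            q, _ = estimate_partition(n, params, RT=RT, n_samples=lnQ_samples,
                                      seed=lnQ_seed, pair_idx=pid[0])
            total += len(th) * float(np.log(q))
    return total


def _wrap_deg(psi: np.ndarray) -> np.ndarray:
    """Wrap phase angles into (-180°, 180°]."""
    return -((-np.asarray(psi) + 180.0) % 360.0 - 180.0)


def fit_phase_angles(ds, fixed_weights=(1.0, 0.0), init_psi=None, *,
                     RT: float = 1.0, m_max: int = 20, gtol: float = 1e-8,
                     max_iter: int = 500, multistart: bool = False) -> FitResult:
    """Fit the 9 phase angles by minimizing Σ V/RT at fixed weights.

    Quasi-Newton (BFGS) with analytic ∂L/∂Ψ: the derivative of V w.r.t. a
    phase angle equals the summed derivative w.r.t. the dihedrals it is
    attached to, since both appear only as γ + Ψ.  ``init_psi`` is a 9-
    vector in degrees (default 0°); ``multistart`` additionally tries the
    uniform offsets ±120°, ±60° to guard against the potential's
    periodic local minima.  Fitted angles are wrapped to (-180°, 180°].
    """
    groups = _fragment_groups(ds)
    if not groups:
        raise ValueError("empty dataset")
    w1, w2 = (float(w) for w in fixed_weights)
    base = MtorParamSet(weights={1: w1, 2: w2},
                        psi_deg=dict.fromkeys(PAIRS, 0.0), m_max=m_max)

    def objective(psi_deg_vec):
        p = base.with_psi_vector(psi_deg_vec)
        L = 0.0
        g = np.zeros(9)
        for n, (th, ga, pid) in groups.items():
            E, _, dga = chain_energy_and_angle_grads(th, ga, pid, p)
            L += float(E.sum()) / RT
            g += np.bincount(pid.ravel(), weights=dga.ravel(), minlength=9) / RT
        return L, np.radians(1.0) * g  # gradient per degree

    starts = [np.zeros(9) if init_psi is None else np.asarray(init_psi, dtype=float)]
    if multistart:
        starts += [starts[0] + off for off in (-120.0, -60.0, 60.0, 120.0)]

    best = None
    for x0 in starts:
        res = minimize(objective, x0, jac=True, method="BFGS",
                       options={"gtol": gtol, "maxiter": max_iter})
        if best is None or res.fun < best.fun:
            best = res
    gnorm = float(np.linalg.norm(best.jac, ord=np.inf))
    return FitResult(
        psi_deg=dict(zip(PAIRS, _wrap_deg(best.x))),
        weights=(w1, w2),
        L=float(best.fun),
        lnQ_included=False,
        converged=bool(best.success or gnorm < 1e-6),
        iterations=int(best.nit),
        grad_norm=gnorm,
    )


def scan_weights(ds, grid_step: float = 0.2, *, include_lnQ: bool = False,
                 RT: float = 1.0, m_max: int = 20, lnQ_samples: int = 50000,
                 lnQ_seed: int = 0, **fit_opts) -> list[FitResult]:
    """Scan multiplicity weights on a grid with w1 + w2 = 1, fitting Ψ at each.

    Returns the fits sorted by ascending L.  Note that without the ln Q
    terms L values at different weights are not comparable as likelihoods
    (Σ V alone is minimized at an extreme weight); ``include_lnQ=True``
    adds the Monte Carlo ln Q_n terms to the reported L, making the
    ranking a proper likelihood comparison.
    """
    if not 0 < grid_step <= 0.5:
        raise ValueError("grid_step must be in (0, 0.5]")
    groups = _fragment_groups(ds)
    results = []
    grid = np.round(np.arange(0.0, 1.0 + 1e-9, grid_step), 12)
    for w1 in grid:
        w = (float(w1), float(1.0 - w1))
        r = fit_phase_angles(ds, fixed_weights=w, RT=RT, m_max=m_max, **fit_opts)
        if include_lnQ:
            p = MtorParamSet(weights={1: w[0], 2: w[1]}, psi_deg=dict(r.psi_deg),
                             m_max=m_max)
            lnq_total = 0.0
            for n, (th, ga, pid) in groups.items():
                q, _ = estimate_partition(n, p, RT=RT, n_samples=lnQ_samples,
                                          seed=lnQ_seed, pair_idx=pid[0])
                lnq_total += len(th) * float(np.log(q))
            r = FitResult(psi_deg=r.psi_deg, weights=r.weights, L=r.L + lnq_total,
                          lnQ_included=True, converged=r.converged,
                          iterations=r.iterations, grad_norm=r.grad_norm)
        results.append(r)
    return sorted(results, key=lambda r: r.L)


def sample_boltzmann_fragments(params: MtorParamSet, n: int, count: int, *,
                               RT: float = 1.0, seed: int = 0, rtypes: str | None = None,
                               sigma: float = 10.0, burn_in: int = 1000, thin: int = 10,
                               redraw_prob: float = 0.15) -> SampledFragmentSet:
    """Sample fragment angle sets from exp(-V/RT) with a flat base measure.

    Runs ``count`` independent single-fragment Metropolis chains in
    parallel (vectorized single-site sweeps).  Proposals mix a Gaussian
    step of ``sigma`` degrees with an occasional full-range redraw
    (probability ``redraw_prob``) so chains can hop between the periodic
    basins of the potential; θ proposals outside (0°, 180°) are rejected,
    γ wraps on the circle.  Each chain is burned in for ``burn_in`` sweeps
    plus ``thin`` decorrelation sweeps, and its final state is the sample.
    Fully reproducible from ``seed``.
    """
    if n < 7:
        raise ValueError("fragment length must be at least 7")
    if rtypes is None:
        rtypes = "A" * n
    if len(rtypes) != n:
        raise ValueError("rtypes length must equal n")
    rng = np.random.default_rng(seed)
    pid = pair_indices(rtypes)
    nt, ng = n - 2, n - 3

    theta = rng.uniform(0.0, 180.0, (count, nt))
    gamma = rng.uniform(0.0, 360.0, (count, ng))
    energy = chain_energy_angles(theta, gamma, pid, params)

    def metropolis_update(cur, col, is_theta):
        nonlocal energy
        old = cur[:, col].copy()
        redraw = rng.random(count) < redraw_prob
        step = rng.normal(0.0, sigma, count)
        if is_theta:
            prop = np.where(redraw, rng.uniform(0.0, 180.0, count), old + step)
            in_range = (prop > 0.0) & (prop < 180.0)
        else:
            prop = np.where(redraw, rng.uniform(0.0, 360.0, count), (old + step) % 360.0)
            in_range = np.ones(count, dtype=bool)
        cur[:, col] = np.where(in_range, prop, old)
        new_e = chain_energy_angles(theta, gamma, pid, params)
        accept = in_range & (np.log(rng.uniform(1e-300, 1.0, count)) < -(new_e - energy) / RT)
        cur[:, col] = np.where(accept, prop, old)
        energy = np.where(accept, new_e, energy)

    for _ in range(burn_in + thin):
        for col in range(nt):
            metropolis_update(theta, col, True)
        for col in range(ng):
            metropolis_update(gamma, col, False)

    manifest = {
        "psi_deg": dict(params.psi_deg), "weights": {str(k): v for k, v in params.weights.items()},
        "m_max": params.m_max, "n": n, "count": count, "RT": RT, "seed": seed,
        "rtypes": rtypes, "sigma": sigma, "burn_in": burn_in, "thin": thin,
        "redraw_prob": redraw_prob,
    }
    return SampledFragmentSet(theta=theta, gamma=gamma, rtypes=rtypes, manifest=manifest)
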