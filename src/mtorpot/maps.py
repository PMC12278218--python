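"""Diagnostic maps of the multitorsional potential.

Two views are provided:

* the fragment energy surface of an idealized 20-residue folded-helical
  segment as a function of its two terminal dihedrals (γ_N, γ_C), which
  control the direction in which the chain leaves the helix at either end;
* the per-window component map U(i, m) of a real chain, which paints
  helical stretches as blocks of negative window contributions without any
  secondary-structure input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import chain_energy_angles, pair_indices
from .geometry import InternalGeometry, ReducedSequence
from .params import PAIRS, MtorParamSet

__all__ = ["EnergySurface", "ComponentMap", "surface_map", "locate_extrema", "component_map"]


@dataclass
class EnergySurface:
    """V over a (γ_N, γ_C) grid for an idealized folded segment."""

    gamma_n: np.ndarray          # grid axis, degrees
    gamma_c: np.ndarray          # grid axis, degrees
    values: np.ndarray           # (len(gamma_n), len(gamma_c))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gamma_n = np.asarray(self.gamma_n, dtype=float)
        self.gamma_c = np.asarray(self.gamma_c, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gamma_n), len(self.gamma_c)):
            raise ValueError("value matrix does not match grid axes")
        if not np.isfinite(self.values).all():
            raise ValueError("surface contains non-finite values")

    def global_min(self) -> tuple[float, float, float]:
        i, j = np.unravel_index(np.argmin(self.values), self.values.shape)
        return float(self.gamma_n[i]), float(self.gamma_c[j]), float(self.values[i, j])

    def global_max(self) -> tuple[float, float, float]:
        i, j = np.unravel_index(np.argmax(self.values), self.values.shape)
        return float(self.gamma_n[i]), float(self.gamma_c[j]), float(self.values[i, j])

    def min_in_gamma_n_band(self, lo: float, hi: float) -> tuple[float, float, float]:
        """Lowest grid value among points with γ_N in [lo, hi)."""
        band = (self.gamma_n >= lo) & (self.gamma_n < hi)
        sub = self.values[band]
        i, j = np.unravel_index(np.argmin(sub), sub.shape)
        return float(self.gamma_n[band][i]), float(self.gamma_c[j]), float(sub[i, j])

    def to_frame(self) -> pd.DataFrame:
        gn, gc = np.meshgrid(self.gamma_n, self.gamma_c, indexing="ij")
        return pd.DataFrame({"gammaN": gn.ravel(), "gammaC": gc.ravel(),
                             "V": self.values.ravel()})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ComponentMap:
    """Window components U(i, m): rows are start residues, columns lengths."""

    starts: np.ndarray           # 0-based window start index i
    lengths: np.ndarray          # window length m = 7..m_max
    values: np.ndarray           # (len(starts), len(lengths)); NaN = window invalid/outside

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.starts), len(self.lengths)):
            raise ValueError("component matrix does not match axes")

    def total(self) -> float:
        """Sum of all defined components; equals the chain energy."""
        return float(np.nansum(self.values))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, i in enumerate(self.starts):
            for b, m in enumerate(self.lengths):
                if np.isfinite(self.values[a, b]):
                    rows.append({"i": int(i), "m": int(m), "U": self.values[a, b]})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def surface_map(params: MtorParamSet, n: int = 20, theta_fill: float = 90.0,
                gamma_fill: float = 45.0, grid_step: float = 5.0) -> EnergySurface:
    """Fragment energy over the terminal dihedrals of an idealized segment.

    Builds an ``n``-residue all-alanine fragment with every θ at
    ``theta_fill`` and every interior γ at ``gamma_fill``; the first and
    last γ sweep a (γ_N, γ_C) grid over [0°, 360°)² with spacing
    ``grid_step`` and the full fragment energy (all windows m = 7..m_max)
    is evaluated at each grid point.
    """
    if 360.0 % grid_step:
        raise ValueError("grid_step must divide 360")
    if n < 7:
        raise ValueError("fragment must have at least 7 residues")
    axis = np.arange(0.0, 360.0, grid_step)
    theta = np.full(n - 2, float(theta_fill))
    gn, gc = np.meshgrid(axis, axis, indexing="ij")
    gamma = np.full(gn.shape + (n - 3,), float(gamma_fill))
    gamma[..., 0] = gn
    gamma[..., -1] = gc
    pid = np.full(n - 3, PAIRS.index("AA"), dtype=np.intp)
    values = chain_energy_angles(theta, gamma, pid, params)
    meta = {"n": n, "theta_fill": float(theta_fill), "gamma_fill": float(gamma_fill),
            "grid_step": float(grid_step), "params": params.name or "custom"}
    return EnergySurface(axis, axis.copy(), values, meta)


def locate_extrema(surface: EnergySurface) -> list[dict]:
    """Grid-local extrema of a surface under periodic boundary conditions.

    A grid point is a local minimum (maximum) if no 8-neighbour is lower
    (higher) and at least one is strictly higher (lower); flat plateaus
    are reported cell-wise, a constant surface has no extrema.  Results
    are sorted by value, ascending, with the global extrema flagged.
    """
    v = surface.values
    neigh = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di or dj:
                neigh.append(np.roll(np.roll(v, di, axis=0), dj, axis=1))
    neigh = np.stack(neigh)
    is_min = (v <= neigh.min(axis=0)) & (v < neigh.max(axis=0))
    is_max = (v >= neigh.max(axis=0)) & (v > neigh.min(axis=0))
    gmin, gmax = v.min(), v.max()
    out = []
    for kind, mask in (("min", is_min), ("max", is_max)):
        for i, j in zip(*np.nonzero(mask)):
            val = float(v[i, j])
            out.append({
                "kind": kind,
                "gammaN": float(surface.gamma_n[i]),
                "gammaC": float(surface.gamma_c[j]),
                "value": val,
                "global": bool(val == (gmin if kind == "min" else gmax)),
            })
    return sorted(out, key=lambda d: d["value"])


def component_map(geom: InternalGeometry, seq: ReducedSequence,
                  params: MtorParamSet) -> ComponentMap:
    """All window components U(i, m) of a chain.

    Entries are defined exactly where the window fits the chain
    (i + m - 1 <= n); windows touching undefined angles hold 0 like in the
    chain sum.  The nansum of the matrix reconstructs the chain energy.
    """
    n = geom.n
    if n < 7:
        raise ValueError("chain must have at least 7 residues")
    m_hi = min(params.m_max, n)
    lengths = np.arange(7, m_hi + 1)
    starts = np.arange(0, n - 7 + 1)
    values = np.full((len(starts), len(lengths)), np.nan)
    windows = chain_energy_angles(
        geom.theta, geom.gamma, pair_indices(seq), params,
        theta_ok=geom.theta_defined, gamma_ok=geom.gamma_defined, per_window=True)
    for b, m in enumerate(lengths):
        for a, i in enumerate(starts):
            if i + m <= n:
                values[a, b] = float(windows.get((int(i), int(m)), 0.0))
    return ComponentMap(starts, lengths, values)
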