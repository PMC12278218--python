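"""Parameter sets of the multitorsional potential.

A parameter set consists of the multiplicity weights ``w_M`` (M = 1, 2) and
the 9 phase angles Ψ, one per ordered pair of basic residue types
(G = glycine, A = alanine class, P = proline).  The phase angle attached to
a dihedral γ is looked up by the ordered pair of reduced types of the two
residues forming the axis virtual bond of that γ.

Three maximum-likelihood parameter sets are bundled:

=====  ==========  =============================
set    (w1, w2)    character
=====  ==========  =============================
A      (1.0, 0.0)  single multiplicity, M = 1
B      (0.6, 0.4)  mixed multiplicity
C      (0.0, 1.0)  single multiplicity, M = 2
=====  ==========  =============================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "PAIRS",
    "MtorParamSet",
    "TemperatureConfig",
    "load_param_set",
    "bundled_param_set",
]

#: ordered residue-type pairs, fixed indexing used throughout the package
PAIRS: tuple[str, ...] = ("GG", "GA", "GP", "AG", "AA", "AP", "PG", "PA", "PP")
PAIR_INDEX: dict[str, int] = {p: i for i, p in enumerate(PAIRS)}


@dataclass
class MtorParamSet:
    """Weights and phase angles of the multitorsional potential.

    Parameters
    ----------
    weights : mapping {1: w1, 2: w2}
        Non-negative multiplicity weights.
    psi_deg : mapping pair -> phase angle in degrees
        All 9 ordered pairs over {G, A, P} must be present.
    m_max : int
        Longest chain window the potential is applied to (default 20).
    name : str
        Optional label for provenance.
    """

    weights: dict[int, float]
    psi_deg: dict[str, float]
    m_max: int = 20
    name: str = ""
    M_max: int = field(init=False)

    def __post_init__(self) -> None:
        self.weights = {int(k): float(v) for k, v in self.weights.items()}
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("multiplicity weights must be non-negative")
        missing = set(PAIRS) - set(self.psi_deg)
        if missing:
            raise ValueError(f"missing phase angles for pairs: {sorted(missing)}")
        self.psi_deg = {p: float(self.psi_deg[p]) for p in PAIRS}
        if self.m_max < 7:
            raise ValueError("m_max must be at least 7")
        self.M_max = max(self.weights) if self.weights else 0

    @property
    def psi_vector(self) -> np.ndarray:
        """Phase angles as a (9,) degree vector in `PAIRS` order."""
        return np.array([self.psi_deg[p] for p in PAIRS])

    def with_psi_vector(self, psi_deg: np.ndarray, name: str | None = None) -> "MtorParamSet":
        return MtorParamSet(
            weights=dict(self.weights),
            psi_deg=dict(zip(PAIRS, np.asarray(psi_deg, dtype=float))),
            m_max=self.m_max,
            name=self.name if name is None else name,
        )

    def active_multiplicities(self) -> list[tuple[int, float]]:
        return [(M, w) for M, w in sorted(self.weights.items()) if w != 0.0]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "weights": {str(M): w for M, w in self.weights.items()},
            "psi_deg": dict(self.psi_deg),
            "m_max": self.m_max,
            "name": self.name,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "MtorParamSet":
        return cls(
            weights={int(k): v for k, v in d["weights"].items()},
            psi_deg=d["psi_deg"],
            m_max=int(d.get("m_max", 20)),
            name=d.get("name", ""),
        )


def load_param_set(path) -> MtorParamSet:
    """Load a parameter set from a JSON file."""
    return MtorParamSet.from_dict(json.loads(Path(path).read_text()))


def bundled_param_set(name: str) -> MtorParamSet:
    """Return one of the bundled maximum-likelihood sets: "A", "B" or "C".

    Accepts also "setA"/"seta" spellings.
    """
    key = name.strip().upper().removeprefix("SET")
    if key not in {"A", "B", "C"}:
        raise KeyError(f"no bundled parameter set named {name!r}")
    text = resources.files("mtorpot.data").joinpath(f"set{key}.json").read_text()
    return MtorParamSet.from_dict(json.loads(text))


@dataclass
class TemperatureConfig:
    """Temperature handling of the multitorsional contribution.

    The term enters the total force-field energy through the multiplicative
    factor f_n(T) that melts cooperative terms above the reference
    temperature ``T_o`` = 300 K; the multitorsional term uses order
    ``n_f`` = 4.
    """

    T: float = 300.0
    T_o: float = 300.0
    n_f: int = 4

    def __post_init__(self) -> None:
        if self.T <= 0 or self.T_o <= 0:
            raise ValueError("temperatures must be positive (kelvin)")
        if self.n_f < 2:
            raise ValueError("factor order n_f must be >= 2")
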