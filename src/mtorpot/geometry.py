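"""Cα-trace geometry: internal coordinates from Cartesian traces and back.

A protein chain is reduced to its Cα atoms joined by ~3.8 Å virtual bonds.
The internal coordinates of such a trace are the virtual-bond angles θ
(planar angle at each interior Cα) and the virtual-bond dihedral angles γ
(torsion over four consecutive Cα atoms, rooted at the middle virtual bond).
All angles are exchanged in degrees; γ is reported in [0°, 360°) using the
right-handed (IUPAC) convention, so the 240° basin of helix-flanking
dihedrals keeps its conventional coordinate.

Index conventions (0-based, chain of ``n`` residues):

* ``theta[c]`` (``c = 0 .. n-3``) is the angle with vertex at residue
  ``c+1``, built from atoms ``c, c+1, c+2``.
* ``gamma[c]`` (``c = 0 .. n-4``) is the dihedral of atoms
  ``c, c+1, c+2, c+3``; its axis is the virtual bond between residues
  ``c+1`` and ``c+2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CAlphaTrace",
    "InternalGeometry",
    "ReducedSequence",
    "GeometryError",
    "internal_from_trace",
    "reduce_sequence",
    "build_trace_from_internal",
]

logger = logging.getLogger(__name__)

#: canonical trans Cα···Cα virtual-bond length (Å)
DEFAULT_BOND = 3.8
#: a bond is treated as intact if its length falls in this window (Å)
CONTIGUOUS_RANGE = (2.8, 4.8)
#: below this separation two consecutive points are considered coincident (Å)
COINCIDENT_TOL = 1e-6
#: sin θ below this marks a collinear triple; adjacent dihedrals are undefined
COLLINEAR_TOL = 1e-8


class GeometryError(ValueError):
    """Raised for traces whose geometry is degenerate beyond repair."""


@dataclass
class CAlphaTrace:
    """Ordered Cα coordinates of one chain.

    Parameters
    ----------
    coords : (n, 3) array of float
        Cα positions in Å, in chain order.
    contiguous : (n-1,) array of bool, optional
        Per-virtual-bond flag; ``False`` marks a chain break.  By default
        every bond whose length lies in ``CONTIGUOUS_RANGE`` is contiguous.
    chain_id : str
        Chain label, carried through for provenance.
    """

    coords: np.ndarray
    contiguous: np.ndarray | None = None
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise GeometryError("coords must be an (n, 3) array")
        n = len(self.coords)
        if 0 < n < 2:
            raise GeometryError("a nonempty trace needs at least 2 points")
        if n >= 2:
            d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
            if np.any(d < COINCIDENT_TOL):
                raise GeometryError("consecutive trace points coincide")
            if self.contiguous is None:
                lo, hi = CONTIGUOUS_RANGE
                self.contiguous = (d >= lo) & (d <= hi)
            else:
                self.contiguous = np.asarray(self.contiguous, dtype=bool)
                if self.contiguous.shape != (n - 1,):
                    raise GeometryError("contiguous must have n-1 entries")
        elif self.contiguous is None:
            self.contiguous = np.zeros(0, dtype=bool)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    def transformed(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "CAlphaTrace":
        """Return a copy under the rigid motion x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        new = self.coords @ rotation.T + np.asarray(translation, dtype=float)
        return CAlphaTrace(new, contiguous=self.contiguous.copy(), chain_id=self.chain_id)


@dataclass
class InternalGeometry:
    """θ/γ internal coordinates of a trace, in degrees.

    ``theta`` has ``n-2`` entries, ``gamma`` has ``n-3``; undefined entries
    (spanning a chain break or a collinear triple) hold NaN and are flagged
    ``False`` in the corresponding mask.
    """

    n: int
    theta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    theta_defined: np.ndarray | None = None
    gamma_defined: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        nt, ng = max(self.n - 2, 0), max(self.n - 3, 0)
        if self.theta.shape != (nt,) or self.gamma.shape != (ng,):
            raise GeometryError(
                f"inconsistent internal-coordinate lengths for n={self.n}: "
                f"theta {self.theta.shape}, gamma {self.gamma.shape}"
            )
        if self.theta_defined is None:
            self.theta_defined = ~np.isnan(self.theta)
        if self.gamma_defined is None:
            self.gamma_defined = ~np.isnan(self.gamma)
        self.theta_defined = np.asarray(self.theta_defined, dtype=bool)
        self.gamma_defined = np.asarray(self.gamma_defined, dtype=bool)


@dataclass(frozen=True)
class ReducedSequence:
    """Residue identities reduced to the three basic types G, A, P.

    Glycine keeps its own class (no side chain), proline its own (the ring
    restricts the backbone), and every other residue type is lumped into the
    alanine class.
    """

    types: str

    def __post_init__(self) -> None:
        if set(self.types) - set("GAP"):
            raise ValueError("reduced sequence may contain only G, A, P")

    def __len__(self) -> int:
        return len(self.types)

    def __getitem__(self, item):
        res = self.types[item]
        return ReducedSequence(res) if isinstance(item, slice) else res


# ---------------------------------------------------------------------------
# scalar angle/dihedral primitives (shared with the gradient code)
# ---------------------------------------------------------------------------

def bond_angle(p0, p1, p2) -> float:
    """Planar angle at ``p1`` in radians, in [0, pi]."""
    u = np.asarray(p0, float) - p1
    v = np.asarray(p2, float) - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def dihedral(p0, p1, p2, p3) -> float:
    """Right-handed torsion of four points in radians, in (-pi, pi]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    return float(np.arctan2(y, np.dot(n1, n2)))


def bond_angle_gradient(p0, p1, p2):
    """θ and its Cartesian gradients: returns (theta, dθ/dp0, dθ/dp1, dθ/dp2).

    Near-collinear input (sin θ below ``COLLINEAR_TOL``) returns zero
    gradients; all energy terms carry a sin θ factor that vanishes there.
    """
    p0, p1, p2 = (np.asarray(p, float) for p in (p0, p1, p2))
    u = p0 - p1
    v = p2 - p1
    lu, lv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / lu, v / lv
    c = np.clip(np.dot(uh, vh), -1.0, 1.0)
    theta = float(np.arccos(c))
    s = np.sqrt(max(1.0 - c * c, 0.0))
    if s < COLLINEAR_TOL:
        z = np.zeros(3)
        return theta, z, z.copy(), z.copy()
    d0 = (c * uh - vh) / (lu * s)
    d2 = (c * vh - uh) / (lv * s)
    return theta, d0, -(d0 + d2), d2


def dihedral_gradient(p0, p1, p2, p3):
    """γ and its Cartesian gradients (radians; same convention as `dihedral`).

    Returns ``(gamma, (g0, g1, g2, g3))``.  Degenerate (collinear) geometry
    yields zero gradients.
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    lb2 = np.linalg.norm(b2)
    n1sq = np.dot(n1, n1)
    n2sq = np.dot(n2, n2)
    y = np.dot(np.cross(n1, n2), b2 / lb2)
    gamma = float(np.arctan2(y, np.dot(n1, n2)))
    if n1sq < COLLINEAR_TOL**2 or n2sq < COLLINEAR_TOL**2:
        z = np.zeros(3)
        return gamma, (z, z.copy(), z.copy(), z.copy())
    g0 = -lb2 / n1sq * n1
    g3 = lb2 / n2sq * n2
    a = np.dot(b1, b2) / (lb2 * lb2)
    b = np.dot(b3, b2) / (lb2 * lb2)
    g1 = (-1.0 - a) * g0 + b * g3
    g2 = a * g0 - (1.0 + b) * g3
    return gamma, (g0, g1, g2, g3)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def internal_from_trace(trace: CAlphaTrace) -> InternalGeometry:
    """Compute θ/γ internal coordinates (degrees) of a Cα trace.

    θ entries exist for every interior vertex; γ entries for every run of
    four consecutive atoms.  Entries whose atom span crosses a chain break,
    or dihedrals rooted at a collinear triple, are undefined (NaN, mask
    ``False``).  γ is mapped into [0°, 360°).
    """
    n = len(trace)
    if n < 3:
        if n > 0:
            logger.warning("trace with %d point(s): no internal coordinates", n)
        return InternalGeometry(n=n)
    x = trace.coords
    cont = trace.contiguous

    nt = n - 2
    theta = np.full(nt, np.nan)
    for c in range(nt):
        if cont[c] and cont[c + 1]:
            theta[c] = np.degrees(bond_angle(x[c], x[c + 1], x[c + 2]))

    ng = max(n - 3, 0)
    gamma = np.full(ng, np.nan)
    for c in range(ng):
        if not (cont[c] and cont[c + 1] and cont[c + 2]):
            continue
        b1 = x[c + 1] - x[c]
        b2 = x[c + 2] - x[c + 1]
        b3 = x[c + 3] - x[c + 2]
        if (np.linalg.norm(np.cross(b1, b2)) < COLLINEAR_TOL
                or np.linalg.norm(np.cross(b2, b3)) < COLLINEAR_TOL):
            continue  # collinear triple: dihedral undefined, term vanishes
        g = np.degrees(dihedral(x[c], x[c + 1], x[c + 2], x[c + 3]))
        gamma[c] = g % 360.0
    return InternalGeometry(n=n, theta=theta, gamma=gamma)


_REDUCED = {"GLY": "G", "PRO": "P"}
_KNOWN_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


def reduce_sequence(residue_names) -> ReducedSequence:
    """Map 3-letter residue codes onto the three basic types {G, A, P}.

    GLY -> G, PRO -> P, everything else (including modified residues such
    as MSE) -> A.  Codes outside the standard table still map to A, with a
    logged warning.
    """
    out = []
    for name in residue_names:
        code = str(name).strip().upper()
        if code not in _KNOWN_AA:
            logger.warning("unknown residue code %r mapped to alanine class", name)
        out.append(_REDUCED.get(code, "A"))
    return ReducedSequence("".join(out))


def build_trace_from_internal(n: int, theta, gamma, bond: float = DEFAULT_BOND,
                              chain_id: str = "A") -> CAlphaTrace:
    """Build a Cα trace realizing prescribed internal coordinates.

    The first three atoms are placed canonically (origin, +x axis,
    xy-plane); each further atom is appended by natural-extension placement
    from the last three.  ``theta`` (n-2 entries) and ``gamma`` (n-3
    entries) are in degrees; scalars broadcast.

    ``internal_from_trace(build_trace_from_internal(n, θ, γ))`` reproduces
    θ and γ to well below 1e-6°.
    """
    if n < 2:
        raise GeometryError("need at least 2 residues")
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (max(n - 2, 0),)).copy()
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (max(n - 3, 0),)).copy()
    if bond <= 0:
        raise GeometryError("bond length must be positive")
    th = np.radians(theta)
    ga = np.radians(gamma)

    x = np.zeros((n, 3))
    x[1] = (bond, 0.0, 0.0)
    if n >= 3:
        x[2] = x[1] + bond * np.array([-np.cos(th[0]), np.sin(th[0]), 0.0])
    for j in range(3, n):
        t = th[j - 2]
        g = ga[j - 3]
        bc = x[j - 1] - x[j - 2]
        bc /= np.linalg.norm(bc)
        ab = x[j - 2] - x[j - 3]
        nvec = np.cross(ab, bc)
        nn = np.linalg.norm(nvec)
        if nn < COLLINEAR_TOL:
            raise GeometryError("collinear support atoms: dihedral placement undefined")
        nvec /= nn
        mvec = np.cross(nvec, bc)
        d = bond * np.array([-np.cos(t), np.sin(t) * np.cos(g), np.sin(t) * np.sin(g)])
        x[j] = x[j - 1] + d[0] * bc + d[1] * mvec + d[2] * nvec
    return CAlphaTrace(x, chain_id=chain_id)
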