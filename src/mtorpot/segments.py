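"""PDB ingestion and folded-helical (FH) segment extraction.

An FH segment is a chain stretch whose interior virtual-bond angles satisfy
θ < 100° and whose interior dihedrals lie in [0°, 70°] — the geometry of
α-helices in the Cα representation — or a stretch covered by the HELIX
records of the PDB entry (extended by one residue at each end, since the
criterion leaves the two boundary residues unconstrained).  Segments never
span a chain break.

PDB reading is delegated to :mod:`gemmi`; only CA atoms are consumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import gemmi
import numpy as np
import pandas as pd

from .geometry import (
    CAlphaTrace,
    InternalGeometry,
    ReducedSequence,
    internal_from_trace,
    reduce_sequence,
)
from .energy import pair_indices

__all__ = [
    "HelixAnnotation",
    "FoldedSegment",
    "SegmentDataset",
    "ParsedChain",
    "parse_pdb_chain",
    "find_fh_segments",
    "build_dataset",
    "gamma_histograms",
    "write_toy_pdb",
]

logger = logging.getLogger(__name__)

THETA_MAX = 100.0   # deg, interior virtual-bond angle bound of the FH criterion
GAMMA_RANGE = (0.0, 70.0)  # deg, closed interval for interior dihedrals


@dataclass(frozen=True)
class HelixAnnotation:
    """HELIX-record intervals: (chain_id, first residue id, last residue id)."""

    intervals: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self):
        for chain, first, last in self.intervals:
            if first > last:
                raise ValueError(f"helix interval {first}..{last} reversed")

    def for_chain(self, chain_id: str) -> list[tuple[int, int]]:
        return [(a, b) for c, a, b in self.intervals if c == chain_id]


@dataclass
class FoldedSegment:
    """One extracted FH segment with its angles and reduced residue types."""

    source: tuple[str, str]      # (structure id, chain id)
    start: int                   # 0-based index of the first residue in the chain
    length: int                  # m, number of residues
    theta: np.ndarray            # (m-2,) degrees
    gamma: np.ndarray            # (m-3,) degrees
    rtypes: ReducedSequence      # length m
    by_helix_record: bool = False

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        m = self.length
        if m < 7:
            raise ValueError("FH segments have at least 7 residues")
        if self.theta.shape != (m - 2,) or self.gamma.shape != (m - 3,) or len(self.rtypes) != m:
            raise ValueError("segment angle/sequence lengths inconsistent with m")

    @property
    def end(self) -> int:
        """0-based index of the last residue (inclusive)."""
        return self.start + self.length - 1

    def angle_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(theta, gamma, pair index per gamma) for energy evaluation."""
        return self.theta, self.gamma, pair_indices(self.rtypes)


@dataclass
class SegmentDataset:
    """A collection of FH segments with a provenance log."""

    segments: list[FoldedSegment] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def extend(self, other: "SegmentDataset") -> None:
        self.segments.extend(other.segments)
        self.provenance.extend(other.provenance)

    def to_frame(self) -> pd.DataFrame:
        """One row per θ position of every segment.

        γ and the residue-type pair of its axis bond live on the same row
        (position ``p`` carries θ at compact index p and γ at compact index
        p); every segment has one more θ than γ, so the last row of a
        segment leaves the γ/pair columns empty.
        """
        rows = []
        for sid, seg in enumerate(self.segments):
            struct, chain = seg.source
            for p in range(seg.length - 2):
                has_g = p < seg.length - 3
                rows.append({
                    "structure": struct, "chain": chain, "segment": sid,
                    "position": p,
                    "pair": (seg.rtypes[p + 1] + seg.rtypes[p + 2]) if has_g else "",
                    "theta": seg.theta[p],
                    "gamma": seg.gamma[p] if has_g else np.nan,
                    "start": seg.start, "length": seg.length,
                    "by_helix_record": seg.by_helix_record,
                    "rtypes": seg.rtypes.types,
                })
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SegmentDataset":
        ds = cls()
        for (struct, chain, sid), grp in df.groupby(["structure", "chain", "segment"], sort=True):
            grp = grp.sort_values("position")
            m = int(grp["length"].iloc[0])
            ds.segments.append(FoldedSegment(
                source=(str(struct), str(chain)),
                start=int(grp["start"].iloc[0]), length=m,
                theta=grp["theta"].to_numpy(),
                gamma=grp["gamma"].to_numpy()[: m - 3],
                rtypes=ReducedSequence(str(grp["rtypes"].iloc[0])),
                by_helix_record=bool(grp["by_helix_record"].iloc[0]),
            ))
        return ds

    @classmethod
    def from_tsv(cls, path) -> "SegmentDataset":
        return cls.from_frame(pd.read_csv(path, sep="\t", keep_default_na=True,
                                          dtype={"rtypes": str, "pair": str}))


class ParsedChain(NamedTuple):
    trace: CAlphaTrace
    residue_names: list[str]
    helix: HelixAnnotation
    resids: list[int]
    structure_id: str


def _pick_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """The CA atom of a residue, resolving altlocs by occupancy (ties: 'A')."""
    cas = [a for a in residue if a.name == "CA"]
    if not cas:
        return None
    return max(cas, key=lambda a: (a.occ, a.altloc in ("", "A"), -ord(a.altloc or "A")))


def parse_pdb_chain(source, chain_id: str | None = None) -> ParsedChain:
    """Read one chain's Cα trace and HELIX annotation from PDB text or a file.

    ``source`` may be a path or a PDB-format string.  ``chain_id=None``
    picks the first chain.  Contiguity flags are set from the inter-Cα
    distance and the author residue-number gap.
    """
    text, struct_id = _read_source(source)
    st = gemmi.read_pdb_string(text)
    if st.name:
        struct_id = st.name.strip() or struct_id
    if len(st) == 0:
        raise ValueError("no model in PDB input")
    model = st[0]
    names = [ch.name for ch in model]
    if chain_id is None:
        if not names:
            raise ValueError("no chains in PDB input")
        chain_id = names[0]
    if chain_id not in names:
        raise ValueError(f"chain {chain_id!r} not present (chains: {names})")
    chain = model[chain_id]

    coords, resnames, resids = [], [], []
    for res in chain:
        ca = _pick_ca(res)
        if ca is None:
            continue
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        resnames.append(res.name)
        resids.append(res.seqid.num)
    if not coords:
        raise ValueError(f"no CA atoms for chain {chain_id!r}")

    trace = CAlphaTrace(np.asarray(coords), chain_id=chain_id)
    if len(trace) >= 2:
        gaps = np.abs(np.diff(np.asarray(resids))) > 1
        trace.contiguous &= ~gaps

    intervals = []
    for h in st.helices:
        if h.start.chain_name == chain_id:
            intervals.append((chain_id, h.start.res_id.seqid.num, h.end.res_id.seqid.num))
    return ParsedChain(trace, resnames, HelixAnnotation(tuple(intervals)), resids, struct_id)


def _read_source(source) -> tuple[str, str]:
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\n" not in source and Path(source).exists()):
        p = Path(source)
        return p.read_text(), p.stem
    return str(source), "input"


# ---------------------------------------------------------------------------
# FH extraction
# ---------------------------------------------------------------------------

def _window_is_fh(good_theta, good_gamma, good_bond, s: int, m: int) -> bool:
    """Angle criterion for the window [s, s+m-1], 0-based compact indexing."""
    return bool(good_theta[s + 1:s + m - 3].all()
                and good_gamma[s + 1:s + m - 4].all()
                and good_bond[s:s + m - 1].all())


def find_fh_segments(geom: InternalGeometry, seq: ReducedSequence,
                     helix: HelixAnnotation | None = None, min_len: int = 7, *,
                     resids: Sequence[int] | None = None,
                     contiguous: np.ndarray | None = None,
                     chain_id: str = "A", structure_id: str = "input") -> list[FoldedSegment]:
    """Extract folded-helical segments of a chain.

    Angle-derived segments are maximal: they cannot be extended by one
    residue in either direction without breaking the criterion (interior
    θ < 100°, interior γ in [0°, 70°]).  HELIX-record intervals contribute
    segments covering the record plus one residue on each side; where a
    record-derived stretch overlaps angle-derived ones they are merged into
    their union and flagged ``by_helix_record``.  All segments returned
    have at least ``min_len`` residues and span no chain break.
    """
    n = geom.n
    min_len = max(min_len, 7)
    if n < min_len:
        return []
    if resids is None:
        resids = list(range(1, n + 1))
    if contiguous is None:
        contiguous = np.ones(max(n - 1, 0), dtype=bool)
    contiguous = np.asarray(contiguous, dtype=bool)

    lo, hi = GAMMA_RANGE
    th = np.nan_to_num(geom.theta, nan=1e9)
    ga = np.nan_to_num(geom.gamma, nan=1e9)
    good_theta = geom.theta_defined & (th < THETA_MAX)
    good_gamma = geom.gamma_defined & (ga >= lo) & (ga <= hi)

    # --- maximal angle-derived windows -----------------------------------
    # Validity only gains constraints as a window grows, so for each start
    # the valid lengths form an interval and the right end e(s) of the
    # longest valid window is non-decreasing in s.
    angle_windows: list[tuple[int, int]] = []  # (start, end) inclusive
    ends: dict[int, int] = {}
    for s in range(n - min_len + 1):
        e_best = -1
        for e in range(s + min_len - 1, n):
            if _window_is_fh(good_theta, good_gamma, contiguous, s, e - s + 1):
                e_best = e
            else:
                break
        if e_best >= 0:
            ends[s] = e_best
    for s, e in ends.items():
        prev = ends.get(s - 1, -1)
        if prev < e:  # not contained in the window starting one earlier
            angle_windows.append((s, e))

    # --- HELIX-record windows --------------------------------------------
    rec_windows: list[tuple[int, int]] = []
    if helix is not None:
        index_of = {rid: i for i, rid in enumerate(resids)}
        for first, last in helix.for_chain(chain_id):
            present = [index_of[r] for r in range(first, last + 1) if r in index_of]
            if not present:
                continue
            a = max(min(present) - 1, 0)
            b = min(max(present) + 1, n - 1)
            # split at chain breaks
            piece = a
            for j in range(a, b):
                if not contiguous[j]:
                    if j - piece + 1 >= min_len:
                        rec_windows.append((piece, j))
                    piece = j + 1
            if b - piece + 1 >= min_len:
                rec_windows.append((piece, b))

    # --- merge ------------------------------------------------------------
    merged: list[tuple[int, int, bool]] = [(a, b, False) for a, b in angle_windows]
    for a, b in rec_windows:
        take_a, take_b = a, b
        keep = []
        absorbed = False
        for (c, d, flag) in merged:
            if c <= take_b and take_a <= d:  # overlap
                take_a, take_b = min(take_a, c), max(take_b, d)
                absorbed = absorbed or flag
            else:
                keep.append((c, d, flag))
        keep.append((take_a, take_b, True))
        merged = keep
    merged.sort()

    segments = []
    for a, b, flagged in merged:
        m = b - a + 1
        segments.append(FoldedSegment(
            source=(structure_id, chain_id), start=a, length=m,
            theta=geom.theta[a:a + m - 2].copy(),
            gamma=geom.gamma[a:a + m - 3].copy(),
            rtypes=seq[a:a + m],
            by_helix_record=flagged,
        ))
    return segments


def build_dataset(pdb_paths: Sequence, chains: Sequence[str] | None = None,
                  min_len: int = 7, use_helix_records: bool = True) -> SegmentDataset:
    """Extract FH segments from a batch of PDB files into one dataset.

    ``chains`` restricts extraction to the listed chain ids in every file
    (default: all chains).  Unreadable files are skipped with a warning.
    """
    ds = SegmentDataset()
    for path in pdb_paths:
        try:
            text, struct_id = _read_source(path)
            st = gemmi.read_pdb_string(text)
            chain_names = [c.name for c in st[0]] if len(st) else []
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("skipping unreadable file %s: %s", path, exc)
            continue
        for cid in chain_names:
            if chains is not None and cid not in chains:
                continue
            try:
                parsed = parse_pdb_chain(text, cid)
            except ValueError as exc:
                logger.warning("skipping chain %s of %s: %s", cid, path, exc)
                continue
            geom = internal_from_trace(parsed.trace)
            seq = reduce_sequence(parsed.residue_names)
            segs = find_fh_segments(
                geom, seq, parsed.helix if use_helix_records else None,
                min_len=min_len, resids=parsed.resids,
                contiguous=parsed.trace.contiguous,
                chain_id=cid, structure_id=struct_id if struct_id != "input" else str(path),
            )
            ds.segments.extend(segs)
            ds.provenance.append({
                "path": str(path), "structure": struct_id, "chain": cid,
                "n_residues": len(parsed.trace), "n_segments": len(segs),
            })
    logger.info("dataset: %d segments from %d chain(s)", len(ds), len(ds.provenance))
    return ds


def gamma_histograms(ds: SegmentDataset, bin_width: float = 10.0) -> pd.DataFrame:
    """Per-residue-pair histograms of the dihedral angles γ of a dataset.

    Returns a DataFrame with one column per ordered reduced-type pair and
    one row per bin over [0°, 360°); the row index holds the left bin edge.
    Per-pair counts sum to the number of contributing γ angles.
    """
    from .params import PAIRS
    if 360.0 % bin_width:
        raise ValueError("bin_width must divide 360")
    edges = np.arange(0.0, 360.0 + bin_width, bin_width)
    table = pd.DataFrame(0, index=pd.Index(edges[:-1], name="gamma_bin_left"),
                         columns=list(PAIRS), dtype=int)
    for seg in ds.segments:
        for j, g in enumerate(seg.gamma):
            if np.isnan(g):
                continue
            pair = seg.rtypes[j + 1] + seg.rtypes[j + 2]
            b = min(int((g % 360.0) // bin_width), len(edges) - 2)
            table.iloc[b, table.columns.get_loc(pair)] += 1
    return table


# ---------------------------------------------------------------------------
# toy-PDB fixture writing
# ---------------------------------------------------------------------------

def write_toy_pdb(trace: CAlphaTrace, residue_names: Sequence[str],
                  helix: HelixAnnotation | None = None,
                  resids: Sequence[int] | None = None) -> str:
    """Render a minimal CA-only PDB (ATOM + HELIX records) as text.

    The output round-trips through :func:`parse_pdb_chain`: coordinates to
    the 1e-3 Å precision of the format, helix intervals exactly.
    """
    n = len(trace)
    if len(residue_names) != n:
        raise ValueError("residue_names length must match trace")
    if resids is None:
        resids = list(range(1, n + 1))
    cid = (trace.chain_id or "A")[0]
    lines = []
    if helix is not None:
        for k, (chain, first, last) in enumerate(helix.intervals, start=1):
            i1 = resids.index(first) if first in resids else None
            i2 = resids.index(last) if last in resids else None
            rn1 = residue_names[i1] if i1 is not None else "ALA"
            rn2 = residue_names[i2] if i2 is not None else "ALA"
            lines.append(
                f"HELIX  {k:3d} {k:3d} {rn1:>3s} {chain:1s} {first:4d}  "
                f"{rn2:>3s} {chain:1s} {last:4d}  1{'':30s} {last - first + 1:5d}"
            )
    for i, (xyz, name, rid) in enumerate(zip(trace.coords, residue_names, resids), start=1):
        x, y, z = xyz
        lines.append(
            f"ATOM  {i:5d}  CA  {name:>3s} {cid}{rid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f" C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
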