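"""PDB parsing, folded-helical extraction, histograms, fixture round trips."""

import numpy as np
import pytest

from mtorpot import (
    HelixAnnotation,
    ReducedSequence,
    SegmentDataset,
    build_dataset,
    build_trace_from_internal,
    find_fh_segments,
    gamma_histograms,
    internal_from_trace,
    parse_pdb_chain,
    reduce_sequence,
    write_toy_pdb,
)
from mtorpot.segments import GAMMA_RANGE, THETA_MAX


def helix_pdb(n=20, theta=90.0, gamma=45.0, helix=True, names=None):
    tr = build_trace_from_internal(n, theta, gamma)
    names = names or ["ALA"] * n
    ann = HelixAnnotation((("A", 2, n - 1),)) if helix else None
    return write_toy_pdb(tr, names, ann)


def recheck_angle_criterion(seg, geom):
    """Independent re-check of the FH inequalities for an extracted segment."""
    k, m = seg.start, seg.length
    th = geom.theta[k + 1:k + m - 3]           # interior vertices only
    ga = geom.gamma[k + 1:k + m - 4]
    return (np.all(~np.isnan(th)) and np.all(th < THETA_MAX)
            and np.all(~np.isnan(ga))
            and np.all((ga >= GAMMA_RANGE[0]) & (ga <= GAMMA_RANGE[1])))


class TestParsePdbChain:
    def test_atom_count_and_helix_passthrough(self):
        parsed = parse_pdb_chain(helix_pdb(10))
        assert len(parsed.trace) == 10
        assert parsed.helix.intervals == (("A", 2, 9),)
        assert parsed.trace.contiguous.all()

    def test_altloc_resolved_by_occupancy(self):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA AALA A   2       3.800   0.000   0.000  0.60  0.00           C\n"
            "ATOM      3  CA BALA A   2       3.800   0.500   0.000  0.40  0.00           C\n"
            "ATOM      4  CA  ALA A   3       3.800   3.800   0.000  1.00  0.00           C\n"
            "END\n"
        )
        parsed = parse_pdb_chain(text, "A")
        assert parsed.trace.coords[1] == pytest.approx([3.8, 0.0, 0.0])

    def test_missing_chain_or_empty_input_raise(self):
        with pytest.raises(ValueError):
            parse_pdb_chain(helix_pdb(10), "Z")
        with pytest.raises(ValueError):
            parse_pdb_chain("REMARK nothing here\nEND\n")

    def test_residue_number_gap_breaks_contiguity(self):
        tr = build_trace_from_internal(8, 90.0, 45.0)
        text = write_toy_pdb(tr, ["ALA"] * 8, resids=[1, 2, 3, 4, 10, 11, 12, 13])
        parsed = parse_pdb_chain(text)
        assert not parsed.trace.contiguous[3]
        assert parsed.trace.contiguous[[0, 1, 2, 4, 5, 6]].all()


class TestFindFhSegments:
    def test_ideal_fragment_yields_one_maximal_segment(self):
        geom = internal_from_trace(build_trace_from_internal(12, 90.0, 45.0))
        segs = find_fh_segments(geom, ReducedSequence("A" * 12))
        assert [(s.start, s.length, s.by_helix_record) for s in segs] == [(0, 12, False)]

    def test_theta_violation_splits_into_maximal_flanks(self):
        theta = np.full(10, 90.0)
        theta[5] = 130.0   # vertex of residue 6 leaves the folded range
        geom = internal_from_trace(build_trace_from_internal(12, theta, 45.0))
        segs = find_fh_segments(geom, ReducedSequence("A" * 12))
        assert {(s.start, s.length) for s in segs} == {(0, 8), (5, 7)}

    def test_flanks_below_min_len_are_dropped(self):
        theta = np.full(7, 90.0)
        theta[3] = 130.0   # every 7-residue window constrains this vertex
        geom = internal_from_trace(build_trace_from_internal(9, theta, 45.0))
        assert find_fh_segments(geom, ReducedSequence("A" * 9)) == []

    def test_helix_record_overrides_angle_criterion(self):
        geom = internal_from_trace(build_trace_from_internal(12, 90.0, 200.0))
        ann = HelixAnnotation((("A", 2, 11),))
        segs = find_fh_segments(geom, ReducedSequence("A" * 12), ann)
        assert [(s.start, s.length, s.by_helix_record) for s in segs] == [(0, 12, True)]

    def test_overlapping_record_and_angle_segments_merge(self):
        # helical in residues 0..11, HELIX record covering 10..16 of 18
        theta = np.full(16, 90.0)
        theta[11:] = 120.0
        geom = internal_from_trace(build_trace_from_internal(18, theta, 45.0))
        ann = HelixAnnotation((("A", 11, 17),))
        segs = find_fh_segments(geom, ReducedSequence("A" * 18), ann)
        assert len(segs) == 1 and segs[0].by_helix_record
        assert (segs[0].start, segs[0].end) == (0, 17)

    def test_returned_angle_segments_pass_independent_recheck(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            n = int(rng.integers(12, 40))
            theta = rng.uniform(60.0, 130.0, n - 2)
            gamma = rng.uniform(0.0, 120.0, n - 3)
            geom = internal_from_trace(build_trace_from_internal(n, theta, gamma))
            seq = ReducedSequence("A" * n)
            for seg in find_fh_segments(geom, seq):
                assert recheck_angle_criterion(seg, geom)

    def test_angle_segments_are_maximal(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            n = int(rng.integers(12, 40))
            theta = rng.uniform(60.0, 130.0, n - 2)
            gamma = rng.uniform(0.0, 120.0, n - 3)
            geom = internal_from_trace(build_trace_from_internal(n, theta, gamma))
            for seg in find_fh_segments(geom, ReducedSequence("A" * n)):
                k, m = seg.start, seg.length
                if k > 0:
                    left = FakeSeg(k - 1, m + 1)
                    assert not recheck_angle_criterion(left, geom)
                if seg.end < n - 1:
                    right = FakeSeg(k, m + 1)
                    assert not recheck_angle_criterion(right, geom)

    def test_segments_do_not_span_chain_breaks(self):
        geom = internal_from_trace(build_trace_from_internal(16, 90.0, 45.0))
        contiguous = np.ones(15, dtype=bool)
        contiguous[7] = False
        ann = HelixAnnotation((("A", 1, 16),))
        segs = find_fh_segments(geom, ReducedSequence("A" * 16), ann, contiguous=contiguous)
        assert all(contiguous[s.start:s.end].all() for s in segs)
        assert all(s.end <= 7 or s.start >= 8 for s in segs)


class FakeSeg:
    def __init__(self, start, length):
        self.start, self.length = start, length


class TestBuildDataset:
    def test_two_single_helix_files_give_two_segments(self, tmp_path):
        for k in range(2):
            (tmp_path / f"toy{k}.pdb").write_text(helix_pdb(12 + k))
        ds = build_dataset([tmp_path / "toy0.pdb", tmp_path / "toy1.pdb"])
        assert len(ds) == 2
        assert len(ds.provenance) == 2

    def test_empty_input_gives_empty_dataset(self):
        assert len(build_dataset([])) == 0

    def test_extended_chain_contributes_nothing(self, tmp_path):
        path = tmp_path / "ext.pdb"
        path.write_text(helix_pdb(12, theta=120.0, gamma=200.0, helix=False))
        assert len(build_dataset([path])) == 0

    def test_extraction_order_independent(self, tmp_path):
        paths = []
        for k in range(3):
            p = tmp_path / f"f{k}.pdb"
            p.write_text(helix_pdb(10 + 2 * k))
            paths.append(p)
        drop = ["structure", "segment"]   # ids reflect processing order
        a = build_dataset(paths).to_frame().drop(columns=drop)
        b = build_dataset(paths[::-1]).to_frame().drop(columns=drop)
        a = a.sort_values(["length", "position"]).reset_index(drop=True)
        b = b.sort_values(["length", "position"]).reset_index(drop=True)
        assert a.equals(b)


class TestGammaHistograms:
    def test_counts_conserved_per_pair(self):
        geom = internal_from_trace(build_trace_from_internal(12, 90.0, 45.0))
        segs = find_fh_segments(geom, ReducedSequence("A" * 12))
        table = gamma_histograms(SegmentDataset(segments=segs), bin_width=10.0)
        assert table.shape == (36, 9)
        assert table["AA"].sum() == 9   # one 12-residue segment: 9 dihedrals
        assert table.drop(columns="AA").to_numpy().sum() == 0

    def test_mode_bin_contains_construction_angle(self):
        geom = internal_from_trace(build_trace_from_internal(15, 90.0, 50.0))
        segs = find_fh_segments(geom, ReducedSequence("A" * 15))
        table = gamma_histograms(SegmentDataset(segments=segs), bin_width=10.0)
        assert table["AA"].idxmax() == 50.0

    def test_empty_dataset_gives_empty_table(self):
        table = gamma_histograms(SegmentDataset(), bin_width=45.0)
        assert table.to_numpy().sum() == 0 and len(table) == 8


class TestToyPdbRoundTrip:
    def test_coordinates_survive_at_format_precision(self):
        tr = build_trace_from_internal(10, 95.0, 50.0)
        parsed = parse_pdb_chain(write_toy_pdb(tr, ["ALA"] * 10))
        assert np.abs(parsed.trace.coords - tr.coords).max() < 1e-3

    def test_helix_intervals_survive(self):
        tr = build_trace_from_internal(10, 90.0, 45.0)
        ann = HelixAnnotation((("A", 3, 8),))
        parsed = parse_pdb_chain(write_toy_pdb(tr, ["ALA"] * 10, ann))
        assert parsed.helix.intervals == ann.intervals

    def test_end_to_end_fixture_extraction(self):
        parsed = parse_pdb_chain(helix_pdb(20))
        geom = internal_from_trace(parsed.trace)
        seq = reduce_sequence(parsed.residue_names)
        segs = find_fh_segments(geom, seq, parsed.helix, resids=parsed.resids,
                                contiguous=parsed.trace.contiguous)
        assert len(segs) == 1 and segs[0].length == 20

    def test_dataset_tsv_round_trip(self, tmp_path):
        parsed = parse_pdb_chain(helix_pdb(14))
        geom = internal_from_trace(parsed.trace)
        segs = find_fh_segments(geom, reduce_sequence(parsed.residue_names))
        ds = SegmentDataset(segments=segs)
        path = tmp_path / "ds.tsv"
        ds.to_tsv(path)
        back = SegmentDataset.from_tsv(path)
        assert len(back) == len(ds)
        assert np.allclose(back.segments[0].gamma, ds.segments[0].gamma)
        assert back.segments[0].rtypes.types == ds.segments[0].rtypes.types
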