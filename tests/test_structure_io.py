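"""Structure parsing, distance matrices, and 0-255 image normalization."""

import gzip
import math

import gemmi
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import adams
from adams import fixtures as fx
from adams.errors import (
    ChainNotFoundError,
    EmptyTraceError,
    FormatError,
    InvalidInputError,
    ParameterError,
)
from adams.structure_io import (
    CalphaTrace,
    compute_distance_matrix,
    distance_image,
    load_calpha_trace,
    normalize_matrix,
    write_matrix_tsv,
)

MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.000   4.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A   3       1.500   2.500  10.000  1.00  0.00           C
END
"""

# residue 2 has no CA; its N must be skipped, not mistaken for a trace point
MISSING_CA_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   GLY A   2       1.000   1.000   1.000  1.00  0.00           N
ATOM      3  CA  SER A   3       3.000   4.000   0.000  1.00  0.00           C
END
"""

# altloc B has the higher occupancy and must win
ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.60  0.00           C
ATOM      3  CA  GLY A   2       3.000   4.000   0.000  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
TER
ATOM      3  CA  GLY B   1       0.000   0.000   5.000  1.00  0.00           C
ATOM      4  CA  GLY B   2       0.000   3.800   5.000  1.00  0.00           C
END
"""


class TestLoadCalphaTrace:
    def test_minimal_pdb_parses_in_record_order(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        trace = load_calpha_trace(p)
        assert trace.length == 3
        np.testing.assert_allclose(
            trace.coords,
            [[0, 0, 0], [3, 4, 0], [1.5, 2.5, 10.0]],
        )
        assert trace.id == "mini"

    def test_pdb_and_mmcif_give_identical_coordinates(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        cif = tmp_path / "mini.cif"
        gemmi.read_structure(str(p)).make_mmcif_document().write_file(str(cif))
        t_pdb = load_calpha_trace(p)
        t_cif = load_calpha_trace(cif)
        np.testing.assert_array_equal(t_pdb.coords, t_cif.coords)

    def test_gzip_compressed_pdb(self, tmp_path):
        gz = tmp_path / "mini.pdb.gz"
        with gzip.open(gz, "wt") as fh:
            fh.write(MINIMAL_PDB)
        trace = load_calpha_trace(gz)
        assert trace.length == 3
        assert trace.id == "mini"

    def test_residue_without_ca_is_skipped(self, tmp_path):
        p = tmp_path / "gap.pdb"
        p.write_text(MISSING_CA_PDB)
        trace = load_calpha_trace(p)
        assert trace.length == 2
        np.testing.assert_allclose(trace.coords[1], [3, 4, 0])

    def test_altloc_resolves_to_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        trace = load_calpha_trace(p)
        assert trace.length == 2
        np.testing.assert_allclose(trace.coords[0], [9, 9, 9])

    def test_chain_selection_and_default_first_chain(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(TWO_CHAIN_PDB)
        assert load_calpha_trace(p).coords[0, 2] == 0.0
        assert load_calpha_trace(p, chain="B").coords[0, 2] == 5.0
        with pytest.raises(ChainNotFoundError):
            load_calpha_trace(p, chain="Z")

    def test_no_calpha_atoms_is_an_error(self, tmp_path):
        p = tmp_path / "junk.pdb"
        p.write_text("this is not a structure\n")
        with pytest.raises((EmptyTraceError, FormatError)):
            load_calpha_trace(p)

    def test_missing_file_is_a_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            load_calpha_trace(tmp_path / "nope.pdb")


class TestDistanceMatrix:
    def test_three_four_five_triangle(self):
        trace = CalphaTrace(id="t", coords=[(0, 0, 0), (3, 4, 0)])
        di = compute_distance_matrix(trace)
        np.testing.assert_allclose(di.D, [[0, 5], [5, 0]])

    def test_single_residue_degenerate(self):
        di = compute_distance_matrix(CalphaTrace(id="t", coords=[(1, 2, 3)]))
        np.testing.assert_array_equal(di.D, [[0.0]])

    def test_matches_scalar_pairwise_loop(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(-20, 20, (10, 3))
        D = compute_distance_matrix(CalphaTrace(id="t", coords=coords)).D
        for i in range(10):
            for j in range(10):
                assert D[i, j] == pytest.approx(
                    math.dist(coords[i], coords[j]), abs=1e-9
                )

    def test_symmetry_zero_diagonal_triangle_inequality(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(-30, 30, (15, 3))
        D = compute_distance_matrix(CalphaTrace(id="t", coords=coords)).D
        np.testing.assert_array_equal(D, D.T)
        np.testing.assert_array_equal(np.diag(D), np.zeros(15))
        # D[i,k] <= D[i,j] + D[j,k] for all triples
        lhs = D[:, np.newaxis, :]
        rhs = D[:, :, np.newaxis] + D[np.newaxis, :, :]
        assert np.all(lhs <= rhs + 1e-9)

    def test_rigid_motion_leaves_matrix_invariant(self):
        trace = fx.make_helix(30, seed=5)
        rotation, translation = fx.random_rigid_transform(seed=8)
        moved = fx.apply_rigid_transform(trace, rotation, translation)
        D0 = compute_distance_matrix(trace).D
        D1 = compute_distance_matrix(moved).D
        assert np.abs(D0 - D1).max() < 1e-9
        np.testing.assert_array_equal(
            normalize_matrix(D0), normalize_matrix(D1)
        )

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(InvalidInputError):
            CalphaTrace(id="t", coords=[(0, 0, np.nan), (1, 1, 1)])


class TestNormalizeMatrix:
    def test_extremes_map_to_0_and_255(self):
        out = normalize_matrix(np.array([[0.0, 10.0], [10.0, 0.0]]))
        np.testing.assert_array_equal(out, [[0, 255], [255, 0]])

    def test_constant_matrix_maps_to_zeros(self):
        out = normalize_matrix(np.full((2, 2), 7.0))
        np.testing.assert_array_equal(out, np.zeros((2, 2)))
        np.testing.assert_array_equal(
            normalize_matrix(np.zeros((1, 1))), [[0]]
        )

    def test_truncation_formula(self):
        # 255 * 4/10 = 102.0 exactly; int() truncates, never rounds up
        D = np.array([[0.0, 4.0], [4.0, 10.0]])
        out = normalize_matrix(D)
        np.testing.assert_array_equal(out, [[0, 102], [102, 255]])

    def test_idempotent_on_full_range_input(self):
        img = np.array([[0, 100], [200, 255]], dtype=np.float64)
        out = normalize_matrix(img)
        assert out.min() == 0 and out.max() == 255
        assert out.dtype == np.uint8

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1e3), min_size=2, max_size=40, unique=True))
    def test_monotone_and_in_range(self, values):
        D = np.array(values).reshape(1, -1)
        out = normalize_matrix(D).astype(int)
        assert out.min() == 0 and out.max() == 255
        order = np.argsort(D[0])
        assert np.all(np.diff(out[0][order]) >= 0)

    def test_symmetric_input_gives_symmetric_image(self):
        trace = fx.make_helix_bundle(40, seed=2)
        di = distance_image(trace)
        np.testing.assert_array_equal(di.img, di.img.T)


def test_debug_tsv_writer_round_trips(tmp_path):
    di = distance_image(fx.make_helix(10, seed=0))
    out = tmp_path / "d.tsv"
    write_matrix_tsv(di, out)
    back = np.loadtxt(out, delimiter="\t")
    np.testing.assert_allclose(back, di.D, atol=1e-4)


def test_distance_image_convenience_fills_both_fields():
    di = adams.distance_image(fx.make_helix(12, seed=0))
    assert di.D.shape == di.img.shape == (12, 12)
    assert di.img.dtype == np.uint8
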