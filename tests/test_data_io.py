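"""Array access over inline text, text files and HDF5; dense/sparse lookup."""
import numpy as np
import pytest

from fieldml import (DataSource, DenseLayout, Model, Parameter, ParameterView,
                     SparseLayout, hdf5_resource, inline_resource, lookup,
                     read_array, read_slab, render_text_array,
                     text_file_resource, write_hdf5_dataset, write_text_array)
from fieldml.errors import (BoundsError, LookupError_, ParseError, ShapeError)

CONNECTIVITY_TEXT = "1 2 11 12\n2 3 12 13\n3 4 13 14\n"


@pytest.fixture
def connectivity_source():
    res = inline_resource("conn", CONNECTIVITY_TEXT)
    return DataSource("conn.data", res, (3, 4))


class TestReadArray:
    def test_connectivity_matrix_rows(self, connectivity_source):
        arr = read_array(connectivity_source)
        assert arr.shape == (3, 4)
        assert arr[2].tolist() == [3, 4, 13, 14]

    def test_zero_dim_source_is_scalar(self):
        src = DataSource("s", inline_resource("r", "7"), ())
        arr = read_array(src)
        assert arr.shape == () and float(arr) == 7.0

    @pytest.mark.parametrize("payload,exc", [
        ("1 2 3", ShapeError),          # too short for 2x2
        ("1 2 3 4 5", ShapeError),      # too long
        ("1 2\nx 4", ParseError),       # non-numeric token
    ])
    def test_bad_payloads(self, payload, exc):
        src = DataSource("s", inline_resource("r", payload), (2, 2))
        with pytest.raises(exc):
            read_array(src)

    def test_text_and_hdf5_paths_agree(self, tmp_path):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(5, 2))
        write_hdf5_dataset(tmp_path / "a.h5", "/x", arr)
        write_text_array(arr, tmp_path / "a.txt")
        hsrc = DataSource("h", hdf5_resource("hr", "a.h5", base=tmp_path),
                          arr.shape, dataset="/x")
        tsrc = DataSource("t", text_file_resource("tr", "a.txt", base=tmp_path),
                          arr.shape)
        h, t = read_array(hsrc), read_array(tsrc)
        assert np.array_equal(h, t) and np.array_equal(h, arr)

    def test_text_round_trip_is_exact(self):
        rng = np.random.default_rng(11)
        arr = rng.normal(size=(4, 3)) * 10.0 ** rng.integers(-8, 8, size=(4, 3))
        src = DataSource("s", inline_resource("r", render_text_array(arr)),
                         arr.shape)
        assert np.array_equal(read_array(src), arr)

    def test_record_window_selects_rows(self):
        src = DataSource("s", inline_resource("r", CONNECTIVITY_TEXT), (1, 4),
                         first_record=2, record_count=1)
        assert read_array(src).tolist() == [[2, 3, 12, 13]]


class TestReadSlab:
    def test_single_row_slab(self, connectivity_source):
        slab = read_slab(connectivity_source, [1, 0], [1, 4])
        assert slab.tolist() == [[2, 3, 12, 13]]

    def test_full_slab_equals_read_array(self, connectivity_source):
        assert np.array_equal(read_slab(connectivity_source, [0, 0], [3, 4]),
                              read_array(connectivity_source))

    def test_out_of_range_slab(self, connectivity_source):
        with pytest.raises(BoundsError):
            read_slab(connectivity_source, [2, 0], [2, 4])

    @pytest.mark.parametrize("backend", ["text", "hdf5"])
    def test_random_slabs_match_memory_slices(self, backend, tmp_path):
        rng = np.random.default_rng(20)
        arr = rng.normal(size=(20, 6))
        if backend == "text":
            src = DataSource("s", inline_resource("r", render_text_array(arr)),
                             arr.shape)
        else:
            write_hdf5_dataset(tmp_path / "s.h5", "/d", arr)
            src = DataSource("s", hdf5_resource("r", "s.h5", base=tmp_path),
                             arr.shape, dataset="/d")
        for _ in range(50):
            o = [int(rng.integers(0, 20)), int(rng.integers(0, 6))]
            c = [int(rng.integers(1, 21 - o[0])), int(rng.integers(1, 7 - o[1]))]
            expected = arr[o[0]:o[0] + c[0], o[1]:o[1] + c[1]]
            assert np.array_equal(read_slab(src, o, c), expected)

    def test_slab_of_slab_composes(self, tmp_path):
        rng = np.random.default_rng(21)
        arr = rng.normal(size=(8, 8))
        write_hdf5_dataset(tmp_path / "s.h5", "/d", arr)
        # a source that is itself a hyperslab view of the dataset
        view = DataSource("v", hdf5_resource("r", "s.h5", base=tmp_path),
                          (4, 4), dataset="/d", offset=(2, 2))
        inner = read_slab(view, [1, 1], [2, 2])
        assert np.array_equal(inner, arr[3:5, 3:5])


def _node_coords_parameter():
    """Nodes 1..4 of the unit square -> (x, y), dense over (node, component)."""
    m = Model("t")
    real = m.define_continuous("real.1d")
    nodes = m.define_ensemble("nodes", [1, 2, 3, 4])
    comps = m.define_ensemble("comps", [1, 2])
    narg, carg = m.argument("n", nodes), m.argument("c", comps)
    coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
    res = m.add_resource(inline_resource("r", render_text_array(coords)))
    src = DataSource("s", res, coords.shape)
    return Parameter("coords", real, (narg, carg), DenseLayout(src))


class TestLookup:
    def test_unit_square_node_coordinates(self):
        p = _node_coords_parameter()
        assert lookup(p, (2, 1)) == 1.0   # node 2, x component
        assert lookup(p, (2, 2)) == 0.0   # node 2, y component
        assert (lookup(p, (1, 1)), lookup(p, (1, 2))) == (0.0, 0.0)

    def test_dense_rank_uses_ascending_member_order(self):
        m = Model("t")
        real = m.define_continuous("real.1d")
        ens = m.define_ensemble("e", [9, 2, 5])  # non-contiguous, unsorted
        arg = m.argument("a", ens)
        vals = np.array([10.0, 20.0, 30.0])      # for members 2, 5, 9
        src = DataSource("s", inline_resource("r", render_text_array(vals)),
                         vals.shape)
        p = Parameter("p", real, (arg,), DenseLayout(src))
        assert lookup(p, (2,)) == 10.0
        assert lookup(p, (9,)) == 30.0

    def test_dense_and_sparse_storage_equivalent(self):
        rng = np.random.default_rng(5)
        m = Model("t")
        real = m.define_continuous("real.1d")
        A = m.define_ensemble("A", [2, 5, 9, 11])
        B = m.define_ensemble("B", [1, 2, 3])
        aa, ba = m.argument("aa", A), m.argument("ba", B)
        vals = rng.normal(size=(4, 3))
        dsrc = DataSource("d", inline_resource("dr", render_text_array(vals)),
                          vals.shape)
        dense = Parameter("dense", real, (aa, ba), DenseLayout(dsrc))
        keys = np.array([[a, b] for a in A.members for b in B.members])
        flat = np.array([vals[A.rank(a), B.rank(b)] for a, b in keys])
        ksrc = DataSource("k", inline_resource("kr", render_text_array(keys)),
                          keys.shape)
        vsrc = DataSource("v", inline_resource("vr", render_text_array(flat)),
                          flat.shape)
        sparse = Parameter("sparse", real, (aa, ba), SparseLayout(ksrc, vsrc))
        for a in A.members:
            for b in B.members:
                assert lookup(dense, (a, b)) == lookup(sparse, (a, b))

    def test_sparse_miss_is_lookup_error(self):
        m = Model("t")
        real = m.define_continuous("real.1d")
        A = m.define_ensemble("A", [1, 2, 3])
        arg = m.argument("a", A)
        keys = np.array([[1], [3]])
        vals = np.array([10.0, 30.0])
        p = Parameter("p", real, (arg,), SparseLayout(
            DataSource("k", inline_resource("kr", render_text_array(keys)),
                       keys.shape),
            DataSource("v", inline_resource("vr", render_text_array(vals)),
                       vals.shape)))
        assert lookup(p, (3,)) == 30.0
        with pytest.raises(LookupError_):
            lookup(p, (2,))

    def test_dense_nonmember_is_bounds_error(self):
        p = _node_coords_parameter()
        with pytest.raises(BoundsError):
            lookup(p, (5, 1))

    def test_ensemble_valued_parameter_returns_members(self):
        m = Model("t")
        nodes = m.define_ensemble("nodes", range(1, 15))
        elems = m.define_ensemble("elems", [1, 2, 3])
        locals_ = m.define_ensemble("locals", [1, 2, 3, 4])
        ea, la = m.argument("e", elems), m.argument("l", locals_)
        src = DataSource("s", inline_resource("r", CONNECTIVITY_TEXT), (3, 4))
        p = Parameter("conn", nodes, (ea, la), DenseLayout(src))
        assert lookup(p, (2, 3)) == 12
        assert isinstance(lookup(p, (2, 3)), int)
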