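"""Heavy data: one logical array behind text or HDF5, dense or sparse.

A data source marks up a dense array inside a resource.  Parameter
evaluators look values up either densely (position = ascending-rank of
each index member) or sparsely (key-tuple rows); both storages of the
same mapping are observationally identical.
"""
import tempfile
from pathlib import Path

import numpy as np

from fieldml import (DataSource, DenseLayout, Model, Parameter, SparseLayout,
                     hdf5_resource, inline_resource, lookup, read_array,
                     read_slab, render_text_array, write_hdf5_dataset)

m = Model("demo")
real = m.define_continuous("real.1d")
elements = m.define_ensemble("elements", [1, 2, 3])
locals_ = m.define_ensemble("localNodes", [1, 2, 3, 4])
e_arg, l_arg = m.argument("e", elements), m.argument("l", locals_)

# the classic connectivity matrix: one row per element, one column per local node
conn = np.array([[1, 2, 11, 12], [2, 3, 12, 13], [3, 4, 13, 14]])
src = DataSource("conn.data", inline_resource("conn", render_text_array(conn)),
                 conn.shape)
print("row 2 via slab:", read_slab(src, [1, 0], [1, 4]).tolist())

nodes = m.define_ensemble("nodes", range(1, 15))
p = Parameter("connectivity", nodes, (e_arg, l_arg), DenseLayout(src))
print("element 2, local node 3 -> global node", lookup(p, (2, 3)))

# the same array through HDF5 reads bit-identically
with tempfile.TemporaryDirectory() as tmp:
    write_hdf5_dataset(Path(tmp) / "conn.h5", "/conn", conn, integer=True)
    hsrc = DataSource("h", hdf5_resource("hr", "conn.h5", base=Path(tmp)),
                      conn.shape, dataset="/conn")
    print("text == hdf5:", np.array_equal(read_array(hsrc), read_array(src)))

# sparse storage: keys + values, missing keys are errors rather than zeros
keys = np.array([[1], [3]])
vals = np.array([10.0, 30.0])
sp = Parameter("sparse", real, (m.argument("i", elements),), SparseLayout(
    DataSource("k", inline_resource("kr", render_text_array(keys)), keys.shape),
    DataSource("v", inline_resource("vr", render_text_array(vals)), vals.shape)))
print("sparse lookup 3 ->", lookup(sp, (3,)))
try:
    lookup(sp, (2,))
except Exception as exc:
    print("sparse miss ->", type(exc).__name__)
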