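"""Data resources and sources: uniform array access over heavy data.

A *data resource* is a container of raw bulk data — an inline string, an
external whitespace-delimited text file, or an HDF5 file.  A *data source*
marks up part of a resource as a dense numeric array of zero or more
dimensions.  Parameter evaluators consume sources through two layouts:

dense
    one array whose extents match the index ensembles' cardinalities; a
    member's position along an axis is its rank in the ascending-sorted
    member list, so ensembles need not be contiguous.
sparse
    two aligned sources: key tuples (one column per sparse index) and
    values.  Missing keys are lookup errors, not implicit zeros.

Text arrays are whitespace/newline delimited and row-major with the last
declared index varying fastest (each leading-index record is one line, as
in a connectivity matrix with one row per element).  Text rendering uses
``%.17g`` so that a write/read round trip is exact for IEEE doubles.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import (BoundsError, DataError, DefinitionError, LookupError_,
                     MemberError, ParseError, ShapeError)
from .model import EnsembleType, Parameter

INLINE = "inline"
TEXT_FILE = "text_file"
HDF5 = "hdf5"


class DataResource:
    """A container of raw data: inline text, a text file, or an HDF5 file."""

    def __init__(self, name: str, kind: str, *, inline_text: Optional[str] = None,
                 href: Optional[str] = None, base: Optional[Path] = None):
        if kind not in (INLINE, TEXT_FILE, HDF5):
            raise DefinitionError(f"data resource {name!r}: unknown kind {kind!r}")
        if kind == INLINE and inline_text is None:
            raise DefinitionError(f"data resource {name!r}: inline resource needs text")
        if kind in (TEXT_FILE, HDF5) and not href:
            raise DefinitionError(f"data resource {name!r}: file resource needs an href")
        self.name = name
        self.kind = kind
        self.inline_text = inline_text
        self.href = href
        self.base = Path(base) if base is not None else None
        self.sources: list["DataSource"] = []

    def path(self) -> Path:
        if self.href is None:
            raise DataError(f"data resource {self.name!r} has no file location")
        p = Path(self.href)
        if not p.is_absolute() and self.base is not None:
            p = self.base / p
        return p

    def text(self) -> str:
        if self.kind == INLINE:
            return self.inline_text
        if self.kind == TEXT_FILE:
            try:
                return self.path().read_text()
            except OSError as exc:
                raise DataError(f"data resource {self.name!r}: {exc}") from exc
        raise DataError(f"data resource {self.name!r} is not textual")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DataResource {self.name!r} kind={self.kind}>"


def inline_resource(name: str, text: str) -> DataResource:
    return DataResource(name, INLINE, inline_text=text)


def text_file_resource(name: str, href: str, base: Optional[Path] = None) -> DataResource:
    return DataResource(name, TEXT_FILE, href=href, base=base)


def hdf5_resource(name: str, href: str, base: Optional[Path] = None) -> DataResource:
    return DataResource(name, HDF5, href=href, base=base)


class DataSource:
    """A dense array view (0+ dimensions) inside a data resource.

    For text resources the raw markup is a first record index (1-based) and
    a record count, one record per line; for HDF5, a dataset path and an
    optional hyperslab origin.
    """

    def __init__(self, name: str, resource: DataResource,
                 shape: Sequence[int], *,
                 first_record: int = 1,
                 record_count: Optional[int] = None,
                 dataset: Optional[str] = None,
                 offset: Optional[Sequence[int]] = None):
        shape = tuple(int(s) for s in shape)
        if any(s < 1 for s in shape):
            raise DefinitionError(f"data source {name!r}: extents must be positive")
        if resource.kind == HDF5 and dataset is None:
            raise DefinitionError(f"data source {name!r}: HDF5 source needs a dataset path")
        if first_record < 1:
            raise DefinitionError(f"data source {name!r}: first record is 1-based")
        self.name = name
        self.resource = resource
        self.shape = shape
        self.first_record = first_record
        self.record_count = (record_count if record_count is not None
                             else (shape[0] if shape else 1))
        self.dataset = dataset
        self.offset = tuple(offset) if offset is not None else None
        resource.sources.append(self)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape, dtype=np.int64)) if self.shape else 1

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DataSource {self.name!r} shape={self.shape}>"


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _parse_text_tokens(source: DataSource) -> np.ndarray:
    lines = [ln for ln in source.resource.text().splitlines() if ln.strip()]
    lo = source.first_record - 1
    hi = lo + source.record_count
    if hi > len(lines):
        raise ShapeError(
            f"data source {source.name!r}: records {source.first_record}.."
            f"{hi} requested but resource has {len(lines)} records")
    tokens: list[str] = []
    for ln in lines[lo:hi]:
        tokens.extend(ln.split())
    try:
        flat = np.array([float(t) for t in tokens], dtype=np.float64)
    except ValueError as exc:
        raise ParseError(f"data source {source.name!r}: non-numeric token ({exc})") from exc
    return flat


def read_array(source: DataSource) -> np.ndarray:
    """Read the full dense array a source declares.

    The result has exactly the declared shape (a 0-dimensional source
    yields a 0-d array holding one scalar); a payload shorter or longer
    than the shape is a shape error, a non-numeric token a parse error.
    """
    if source.resource.kind in (INLINE, TEXT_FILE):
        flat = _parse_text_tokens(source)
        if flat.size != source.size:
            raise ShapeError(
                f"data source {source.name!r}: payload has {flat.size} entries, "
                f"declared shape {source.shape} needs {source.size}")
        return flat.reshape(source.shape)
    # HDF5
    import h5py
    try:
        with h5py.File(source.resource.path(), "r") as f:
            if source.dataset not in f:
                raise DataError(f"data source {source.name!r}: dataset "
                                f"{source.dataset!r} not found")
            ds = f[source.dataset]
            if source.offset is not None:
                sel = tuple(slice(o, o + n) for o, n in zip(source.offset, source.shape))
                if len(sel) != ds.ndim:
                    raise ShapeError(f"data source {source.name!r}: offset rank "
                                     f"{len(sel)} != dataset rank {ds.ndim}")
                for (o, n, ext) in zip(source.offset, source.shape, ds.shape):
                    if o < 0 or o + n > ext:
                        raise BoundsError(f"data source {source.name!r}: hyperslab "
                                          f"outside dataset extents")
                arr = np.asarray(ds[sel], dtype=np.float64)
            else:
                arr = np.asarray(ds[()], dtype=np.float64)
            if arr.shape != source.shape:
                raise ShapeError(
                    f"data source {source.name!r}: dataset shape {arr.shape} != "
                    f"declared shape {source.shape}")
            return arr
    except OSError as exc:
        raise DataError(f"data source {source.name!r}: {exc}") from exc


def read_slab(source: DataSource, offsets: Sequence[int],
              counts: Sequence[int]) -> np.ndarray:
    """Read a hyperslab of a source: a sub-array of shape *counts*.

    Consistent with ``read_array`` followed by slicing; for HDF5 the slab
    is read directly so large datasets need not be materialised.
    """
    offsets = tuple(int(o) for o in offsets)
    counts = tuple(int(c) for c in counts)
    if len(offsets) != len(source.shape) or len(counts) != len(source.shape):
        raise BoundsError(f"data source {source.name!r}: slab rank mismatch")
    for o, c, ext in zip(offsets, counts, source.shape):
        if o < 0 or c < 0 or o + c > ext:
            raise BoundsError(
                f"data source {source.name!r}: slab [{o}:{o + c}] outside extent {ext}")
    if source.resource.kind == HDF5:
        base = source.offset or (0,) * len(source.shape)
        sub = DataSource(source.name, source.resource, counts,
                         dataset=source.dataset,
                         offset=tuple(b + o for b, o in zip(base, offsets)))
        return read_array(sub)
    arr = read_array(source)
    sel = tuple(slice(o, o + c) for o, c in zip(offsets, counts))
    return arr[sel]


# ---------------------------------------------------------------------------
# Parameter storage layouts
# ---------------------------------------------------------------------------

class ParameterStorage:
    """Base for the dense / sparse parameter layouts."""

    def resources(self) -> tuple[DataResource, ...]:
        raise NotImplementedError


class DenseLayout(ParameterStorage):
    """All index combinations stored; one array, one axis per index."""

    def __init__(self, source: DataSource):
        self.source = source

    def resources(self) -> tuple[DataResource, ...]:
        return (self.source.resource,)


class SparseLayout(ParameterStorage):
    """Sparse over the leading indexes: aligned key and value sources.

    ``keys`` has one row per stored entry and one column per sparse index;
    ``values`` is aligned row-for-row and may carry trailing dense axes for
    any remaining (dense) indexes.
    """

    def __init__(self, keys: DataSource, values: DataSource):
        if len(keys.shape) != 2:
            raise DefinitionError("sparse keys source must be a 2-d array "
                                  "(rows x sparse indexes)")
        if not values.shape or values.shape[0] != keys.shape[0]:
            raise DefinitionError(
                f"sparse layout: keys have {keys.shape[0]} rows, values have "
                f"{values.shape[0] if values.shape else 1}")
        self.keys = keys
        self.values = values
        self.n_sparse = keys.shape[1]

    def resources(self) -> tuple[DataResource, ...]:
        return (self.keys.resource, self.values.resource)


def validate_parameter_storage(parameter: Parameter) -> list[str]:
    """Structural consistency of a parameter's storage vs its indexes."""
    msgs: list[str] = []
    n = len(parameter.index_arguments)
    cards = [a.value_type.cardinality for a in parameter.index_arguments
             if isinstance(a.value_type, EnsembleType)]
    if len(cards) != n:
        return ["index arguments are not all ensemble-valued"]
    st = parameter.storage
    if isinstance(st, DenseLayout):
        if len(st.source.shape) != n:
            msgs.append(f"dense source rank {len(st.source.shape)} != "
                        f"{n} index arguments")
        else:
            for i, (ext, card) in enumerate(zip(st.source.shape, cards)):
                if ext != card:
                    msgs.append(f"axis {i}: extent {ext} != ensemble cardinality {card}")
    elif isinstance(st, SparseLayout):
        k = st.n_sparse
        dense_rank = len(st.values.shape) - 1
        if k + dense_rank != n:
            msgs.append(f"sparse keys cover {k} indexes and values carry "
                        f"{dense_rank} dense axes, but there are {n} indexes")
        else:
            for i, (ext, card) in enumerate(zip(st.values.shape[1:], cards[k:])):
                if ext != card:
                    msgs.append(f"dense axis {i}: extent {ext} != cardinality {card}")
    else:
        msgs.append(f"unknown storage layout {type(st).__name__}")
    return msgs


# ---------------------------------------------------------------------------
# Lookup
# ---------------------------------------------------------------------------

class ParameterView:
    """A parameter evaluator bound to its loaded data, ready for lookup.

    Arrays are loaded once and cached; sparse layouts additionally build a
    key-row dictionary (rejecting duplicate key rows).
    """

    def __init__(self, parameter: Parameter):
        self.parameter = parameter
        self._dense: Optional[np.ndarray] = None
        self._values: Optional[np.ndarray] = None
        self._rows: Optional[dict[tuple[int, ...], int]] = None

    def _ensure_loaded(self):
        st = self.parameter.storage
        if isinstance(st, DenseLayout):
            if self._dense is None:
                self._dense = read_array(st.source)
        else:
            if self._rows is None:
                keys = read_array(st.keys)
                self._values = read_array(st.values)
                rows: dict[tuple[int, ...], int] = {}
                for r in range(keys.shape[0]):
                    key = tuple(int(round(x)) for x in keys[r])
                    if key in rows:
                        raise DefinitionError(
                            f"parameter {self.parameter.name!r}: duplicate sparse "
                            f"key row {key}")
                    rows[key] = r
                self._rows = rows

    def lookup(self, index_tuple: Sequence[int]) -> Union[float, int]:
        """Value at one index combination, as the parameter's value type."""
        p = self.parameter
        index_tuple = tuple(int(m) for m in index_tuple)
        if len(index_tuple) != len(p.index_arguments):
            raise BoundsError(
                f"parameter {p.name!r}: {len(index_tuple)} indices given, "
                f"{len(p.index_arguments)} expected")
        self._ensure_loaded()
        st = p.storage
        if isinstance(st, DenseLayout):
            pos = []
            for m, a in zip(index_tuple, p.index_arguments):
                ens: EnsembleType = a.value_type
                try:
                    pos.append(ens.rank(m))
                except MemberError as exc:
                    raise BoundsError(str(exc)) from exc
            raw = float(self._dense[tuple(pos)])
        else:
            k = st.n_sparse
            key = index_tuple[:k]
            row = self._rows.get(key)
            if row is None:
                raise LookupError_(
                    f"parameter {p.name!r}: no value stored for sparse key {key}")
            cell = self._values[row]
            pos = []
            for m, a in zip(index_tuple[k:], p.index_arguments[k:]):
                ens: EnsembleType = a.value_type
                try:
                    pos.append(ens.rank(m))
                except MemberError as exc:
                    raise BoundsError(str(exc)) from exc
            raw = float(cell[tuple(pos)] if pos else cell)
        if isinstance(p.value_type, EnsembleType):
            member = int(round(raw))
            if member not in p.value_type:
                raise MemberError(
                    f"parameter {p.name!r}: stored value {raw} is not a member "
                    f"of {p.value_type.name!r}")
            return member
        return raw


def lookup(parameters: Union[Parameter, ParameterView],
           index_tuple: Sequence[int]) -> Union[float, int]:
    """Look up one value of a parameter evaluator at an index tuple."""
    view = parameters if isinstance(parameters, ParameterView) else ParameterView(parameters)
    return view.lookup(index_tuple)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def render_text_array(array: np.ndarray) -> str:
    """Render an array in the text layout sources expect.

    ``%.17g`` per entry, single space between entries, one line per
    leading-index record; integer-valued entries render without a decimal
    point (``%.17g`` drops it), so connectivity matrices stay readable.
    """
    arr = np.asarray(array, dtype=np.float64)
    if arr.ndim == 0:
        return "%.17g\n" % float(arr)
    rows = arr.reshape(arr.shape[0], -1)
    return "".join(" ".join("%.17g" % v for v in row) + "\n" for row in rows)


def write_text_array(array: np.ndarray, path: Union[str, Path]) -> None:
    Path(path).write_text(render_text_array(array))


def write_hdf5_dataset(path: Union[str, Path], dataset: str,
                       array: np.ndarray, integer: bool = False) -> None:
    """Write one dataset into an HDF5 file (native doubles or 64-bit ints).

    Creation-time tracking is disabled so identical data produces
    byte-identical files.
    """
    import h5py
    arr = np.asarray(array, dtype=np.int64 if integer else np.float64)
    with h5py.File(path, "a", libver="earliest") as f:
        if dataset in f:
            del f[dataset]
        f.create_dataset(dataset, data=arr, track_times=False)
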