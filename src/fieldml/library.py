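"""The standard library: coordinate types, local-node ensembles, external
interpolators and element shape predicates — plus their executable
implementations.

The library is an ordinary region.  It declares continuous chart types for
1–3 dimensional reference elements, Cartesian coordinate types, the
local-node ensembles of each interpolation basis (essentially element
local node indexes), external evaluators for the common FEM interpolation
bases (linear/quadratic Lagrange tensor products and linear simplexes) and
Boolean externals for the reference shapes, and argument evaluators for
all of these.  Because externals only carry semantics by convention, this
module also registers a closed-form implementation for every declared
external, so evaluation never falls through to the unknown-external error
for library names.

Local-node ordering: xi1 varies fastest, then xi2, then xi3, with node 1
at the origin — e.g. the bilinear nodes 1..4 sit at (0,0), (1,0), (0,1),
(1,1).  Quadratic bases use equally spaced nodes on [0,1]; simplex bases
are barycentric-linear.  Every Lagrange family satisfies the partition of
unity and the delta property at its nodes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from . import registry
from .errors import ArityError, DomainError, TypeError_
from .evaluate import BooleanValue, EvalConfig, RealValue, Value
from .model import (Argument, BooleanType, ContinuousType, EnsembleType,
                    External, Model)

LIBRARY_REGION_NAME = "library"
#: hrefs under which the standard library resolves (never fetched remotely)
LIBRARY_HREFS = (
    "FieldML_Library_0.5.xml",
    "http://www.fieldml.org/resources/xml/0.5/FieldML_Library_0.5.xml",
)


# ---------------------------------------------------------------------------
# Basis functions
# ---------------------------------------------------------------------------

def _lagrange_1d(nodes: np.ndarray, x: float) -> np.ndarray:
    """Weights of the 1-d Lagrange basis with the given node positions."""
    w = np.empty(len(nodes))
    for i, xi in enumerate(nodes):
        num = 1.0
        for j, xj in enumerate(nodes):
            if j != i:
                num *= (x - xj) / (xi - xj)
        w[i] = num
    return w


def _tensor(weights_per_dim: Sequence[np.ndarray]) -> np.ndarray:
    """Tensor-product weights flattened with the first chart axis fastest."""
    w = weights_per_dim[-1]
    for prev in reversed(weights_per_dim[:-1]):
        w = np.multiply.outer(w, prev).ravel()
    return w


def _grid_nodes(nodes_1d: np.ndarray, dim: int) -> np.ndarray:
    """Node coordinates of a tensor-product basis, xi1 fastest, node 1 at 0."""
    n = len(nodes_1d)
    coords = []
    for flat in range(n ** dim):
        idx = []
        rem = flat
        for _ in range(dim):
            idx.append(rem % n)
            rem //= n
        coords.append([nodes_1d[i] for i in idx])
    return np.array(coords)


@dataclass(frozen=True)
class InterpolatorSpec:
    """A closed-form interpolation basis over a reference shape."""
    name: str
    dimension: int
    node_count: int
    shape_name: str
    local_nodes_name: str
    node_coords: np.ndarray          # (node_count, dimension)
    weights: Callable[[Sequence[float]], np.ndarray]
    degree: int                      # highest polynomial degree reproduced


@dataclass(frozen=True)
class ShapeSpec:
    """A reference element shape as a closed-set membership predicate."""
    name: str
    dimension: int
    predicate: Callable[[Sequence[float]], bool]


def _lagrange_tensor_spec(name: str, dim: int, nodes_1d, shape_name: str,
                          local_nodes_name: str, degree: int) -> InterpolatorSpec:
    nodes_1d = np.asarray(nodes_1d, dtype=float)

    def weights(xi: Sequence[float]) -> np.ndarray:
        per_dim = [_lagrange_1d(nodes_1d, float(x)) for x in xi]
        return _tensor(per_dim)

    return InterpolatorSpec(name, dim, len(nodes_1d) ** dim, shape_name,
                            local_nodes_name, _grid_nodes(nodes_1d, dim),
                            weights, degree)


def _simplex_spec(name: str, dim: int, shape_name: str,
                  local_nodes_name: str) -> InterpolatorSpec:
    eye = np.eye(dim)
    coords = np.vstack([np.zeros(dim), eye])

    def weights(xi: Sequence[float]) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        return np.concatenate([[1.0 - xi.sum()], xi])

    return InterpolatorSpec(name, dim, dim + 1, shape_name, local_nodes_name,
                            coords, weights, 1)


SHAPES: dict[str, ShapeSpec] = {
    "shape.unit.line": ShapeSpec(
        "shape.unit.line", 1, lambda xi: 0.0 <= xi[0] <= 1.0),
    "shape.unit.square": ShapeSpec(
        "shape.unit.square", 2, lambda xi: all(0.0 <= x <= 1.0 for x in xi)),
    "shape.unit.cube": ShapeSpec(
        "shape.unit.cube", 3, lambda xi: all(0.0 <= x <= 1.0 for x in xi)),
    "shape.unit.triangle": ShapeSpec(
        "shape.unit.triangle", 2,
        lambda xi: xi[0] >= 0.0 and xi[1] >= 0.0 and xi[0] + xi[1] <= 1.0),
    "shape.unit.tetrahedron": ShapeSpec(
        "shape.unit.tetrahedron", 3,
        lambda xi: all(x >= 0.0 for x in xi) and sum(xi) <= 1.0),
}

_LINEAR = [0.0, 1.0]
_QUADRATIC = [0.0, 0.5, 1.0]

INTERPOLATORS: dict[str, InterpolatorSpec] = {s.name: s for s in [
    _lagrange_tensor_spec("interpolator.1d.unit.linearLagrange", 1, _LINEAR,
                          "shape.unit.line", "localNodes.1d.line2", 1),
    _lagrange_tensor_spec("interpolator.2d.unit.bilinearLagrange", 2, _LINEAR,
                          "shape.unit.square", "localNodes.2d.square2x2", 1),
    _lagrange_tensor_spec("interpolator.3d.unit.trilinearLagrange", 3, _LINEAR,
                          "shape.unit.cube", "localNodes.3d.cube2x2x2", 1),
    _lagrange_tensor_spec("interpolator.1d.unit.quadraticLagrange", 1, _QUADRATIC,
                          "shape.unit.line", "localNodes.1d.line3", 2),
    _lagrange_tensor_spec("interpolator.2d.unit.biquadraticLagrange", 2, _QUADRATIC,
                          "shape.unit.square", "localNodes.2d.square3x3", 2),
    _lagrange_tensor_spec("interpolator.3d.unit.triquadraticLagrange", 3, _QUADRATIC,
                          "shape.unit.cube", "localNodes.3d.cube3x3x3", 2),
    _simplex_spec("interpolator.2d.unit.linearSimplex",
                  2, "shape.unit.triangle", "localNodes.2d.triangle3"),
    _simplex_spec("interpolator.3d.unit.linearSimplex",
                  3, "shape.unit.tetrahedron", "localNodes.3d.tetrahedron4"),
]}


def _resolve_interpolator(basis: Union[str, InterpolatorSpec]) -> InterpolatorSpec:
    if isinstance(basis, InterpolatorSpec):
        return basis
    try:
        return INTERPOLATORS[basis]
    except KeyError:
        raise KeyError(f"unknown interpolator {basis!r}")


def _resolve_shape(shape: Union[str, ShapeSpec]) -> ShapeSpec:
    if isinstance(shape, ShapeSpec):
        return shape
    try:
        return SHAPES[shape]
    except KeyError:
        raise KeyError(f"unknown shape {shape!r}")


def shape_inside(shape: Union[str, ShapeSpec], xi: Sequence[float]) -> bool:
    """Closed-set membership of chart coordinates in a reference shape."""
    spec = _resolve_shape(shape)
    if len(xi) != spec.dimension:
        raise TypeError_(f"shape {spec.name!r} has dimension {spec.dimension}, "
                         f"got {len(xi)} coordinates")
    return bool(spec.predicate([float(x) for x in xi]))


def interpolate(basis: Union[str, InterpolatorSpec],
                params: Sequence[float], xi: Sequence[float],
                allow_extrapolation: bool = False) -> float:
    """Evaluate ``sum_i phi_i(xi) * params_i`` for a library basis.

    ``params`` holds one nodal value per local node, in local-node order.
    Coordinates outside the reference shape raise a domain error unless
    extrapolation is explicitly allowed.
    """
    spec = _resolve_interpolator(basis)
    params = np.asarray(params, dtype=float)
    if params.shape != (spec.node_count,):
        raise ArityError(f"{spec.name!r} takes {spec.node_count} nodal values, "
                         f"got {params.shape}")
    if len(xi) != spec.dimension:
        raise TypeError_(f"{spec.name!r} has dimension {spec.dimension}, got "
                         f"{len(xi)} coordinates")
    if not allow_extrapolation and not shape_inside(spec.shape_name, xi):
        raise DomainError(f"{tuple(xi)} is outside {spec.shape_name!r}; pass "
                          f"allow_extrapolation to override")
    return float(spec.weights(xi) @ params)


# ---------------------------------------------------------------------------
# The library region
# ---------------------------------------------------------------------------

_LOCAL_NODE_ENSEMBLES = {
    "localNodes.1d.line2": 2,
    "localNodes.1d.line3": 3,
    "localNodes.2d.square2x2": 4,
    "localNodes.2d.square3x3": 9,
    "localNodes.2d.triangle3": 3,
    "localNodes.3d.cube2x2x2": 8,
    "localNodes.3d.cube3x3x3": 27,
    "localNodes.3d.tetrahedron4": 4,
}

_library: Optional[Model] = None


def _build_library() -> Model:
    lib = Model(LIBRARY_REGION_NAME)
    boolean = lib.define_boolean("boolean")
    real = lib.define_continuous("real.1d")
    lib.argument("real.1d.argument", real)

    charts: dict[int, ContinuousType] = {}
    chart_args: dict[int, Argument] = {}
    for d in (1, 2, 3):
        t = lib.define_continuous(f"chart.{d}d", d)
        charts[d] = t
        chart_args[d] = lib.argument(f"chart.{d}d.argument", t)
        if t.component_ensemble is not None:
            lib.argument(f"chart.{d}d.component.argument", t.component_ensemble)
    for d in (1, 2, 3):
        t = lib.define_continuous(f"coordinates.rc.{d}d", d)
        lib.argument(f"coordinates.rc.{d}d.argument", t)
        if t.component_ensemble is not None:
            lib.argument(f"coordinates.rc.{d}d.component.argument",
                         t.component_ensemble)

    node_args: dict[str, Argument] = {}
    for name, count in _LOCAL_NODE_ENSEMBLES.items():
        ens = lib.define_ensemble(name, range(1, count + 1))
        node_args[name] = lib.argument(f"{name}.argument", ens)

    for spec in INTERPOLATORS.values():
        nodes = lib.types[spec.local_nodes_name]
        ptype = ContinuousType(f"parameters.{spec.name.removeprefix('interpolator.')}",
                               spec.node_count, component_ensemble=nodes)
        lib.add_type(ptype)
        parg = lib.argument(f"{ptype.name}.argument", ptype)
        lib.add_evaluator(External(spec.name, real,
                                   (chart_args[spec.dimension], parg)))

    for spec in SHAPES.values():
        lib.add_evaluator(External(spec.name, boolean,
                                   (chart_args[spec.dimension],)))
    return lib


def load_library() -> Model:
    """The standard library region (a singleton: one object graph per
    process, so imported library types stay nominally identical)."""
    global _library
    if _library is None:
        _library = _build_library()
        _register_implementations(_library)
    return _library


def parameter_vector_type(basis: Union[str, InterpolatorSpec]) -> ContinuousType:
    """The library's nodal-parameter vector type for a basis."""
    spec = _resolve_interpolator(basis)
    lib = load_library()
    return lib.types[f"parameters.{spec.name.removeprefix('interpolator.')}"]


def _register_implementations(lib: Model) -> None:
    real = lib.types["real.1d"]
    boolean = lib.types["boolean"]

    def make_interp(spec: InterpolatorSpec):
        def impl(external: External, argvals: list[Value],
                 config: EvalConfig) -> Value:
            chart, params = argvals
            if not isinstance(chart, RealValue) or len(chart.vector) != spec.dimension:
                raise TypeError_(f"{spec.name!r}: chart operand has wrong "
                                 f"dimension")
            if not isinstance(params, RealValue):
                raise TypeError_(f"{spec.name!r}: parameter operand is not a "
                                 f"real vector")
            val = interpolate(spec, params.vector, chart.vector,
                              allow_extrapolation=config.allow_extrapolation)
            return RealValue(real, (val,))
        return impl

    def make_shape(spec: ShapeSpec):
        def impl(external: External, argvals: list[Value],
                 config: EvalConfig) -> Value:
            (chart,) = argvals
            if not isinstance(chart, RealValue) or len(chart.vector) != spec.dimension:
                raise TypeError_(f"{spec.name!r}: chart operand has wrong "
                                 f"dimension")
            return BooleanValue(shape_inside(spec, chart.vector))
        return impl

    for spec in INTERPOLATORS.values():
        registry.register(spec.name, make_interp(spec))
    for spec in SHAPES.values():
        registry.register(spec.name, make_shape(spec))


def library_document() -> bytes:
    """The library serialized as an XML document (byte-identical per run)."""
    from .xmlio import write_model
    return write_model(load_library())
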