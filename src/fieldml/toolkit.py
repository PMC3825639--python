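"""Model generators, VTK export, and random fixtures.

``build_illustrative_example`` constructs the canonical worked model: a
two-quadrilateral-element 2D mesh with six global nodes carrying a scalar
pressure field and a 3-component geometry field.  The two fields share a
field template — element shapes, the local-to-global node connectivity
parameter and a bilinear-interpolation piecewise evaluator — and differ
only in the nodal parameters bound to it: the pressure field binds its
degrees of freedom through a reference evaluator; the geometry field binds
one coordinate's parameters per component through an aggregate evaluator.

``random_model`` / ``random_pipeline`` produce seeded corpora for the
round-trip and binding-substitution property suites.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .data import (DataSource, DenseLayout, SparseLayout, hdf5_resource,
                   inline_resource, render_text_array, write_hdf5_dataset)
from .errors import DefinitionError, FieldmlError
from .evaluate import (Environment, EnsembleValue, EvalConfig, RealValue,
                       evaluate, evaluate_mesh_field)
from .library import load_library, parameter_vector_type
from .model import (Aggregate, Argument, Binding, Constant, ContinuousType,
                    EnsembleType, Evaluator, External, ImportRecord, Model,
                    Parameter, Piecewise, Reference)

LIBRARY_HREF = "http://www.fieldml.org/resources/xml/0.5/FieldML_Library_0.5.xml"


# ---------------------------------------------------------------------------
# The illustrative example
# ---------------------------------------------------------------------------

@dataclass
class FixtureManifest:
    """What the generator built, for consumption by tests.

    Everything here is produced by the generator itself (object counts,
    DOF tables, spot values computed directly from the arrays), so tests
    compare the engine's output against an independent record.
    """
    model_name: str
    n_elements: int
    n_nodes: int
    object_counts: dict[str, int]
    connectivity: np.ndarray            # (n_elements, 4) global node numbers
    pressure_dofs: np.ndarray           # (n_nodes,)
    geometry_dofs: np.ndarray           # (n_nodes, 3)
    element_center_pressure: dict[int, float]  # mean of the 4 nodal DOFs


@dataclass
class IllustrativeExample:
    model: Model
    manifest: FixtureManifest
    mesh_argument: Argument
    pressure_field: Evaluator
    geometry_field: Evaluator


def _import_from_library(model: Model, lib: Model, type_names: Sequence[str],
                         evaluator_names: Sequence[str]) -> None:
    for n in type_names:
        model.add_type(lib.types[n], local_name=n)
        model.imported_names.add(n)
        model.imports.append(ImportRecord(LIBRARY_HREF, "type", n, n))
    for n in evaluator_names:
        model.add_evaluator(lib.evaluators[n], local_name=n)
        model.imported_names.add(n)
        model.imports.append(ImportRecord(LIBRARY_HREF, "evaluator", n, n))


def build_illustrative_example() -> IllustrativeExample:
    """Two unit-square elements sharing an edge, six global nodes.

    Node layout (x right, y up)::

        4 --- 5 --- 6
        |  1  |  2  |
        1 --- 2 --- 3

    Local-node order within an element is (0,0), (1,0), (0,1), (1,1), so
    the connectivity rows are [1,2,4,5] and [2,3,5,6].
    """
    lib = load_library()
    m = Model("illustrative_example")
    params_type = parameter_vector_type("interpolator.2d.unit.bilinearLagrange")
    _import_from_library(
        m, lib,
        type_names=["real.1d", "chart.2d", "coordinates.rc.3d",
                    "localNodes.2d.square2x2", params_type.name],
        evaluator_names=["chart.2d.argument",
                         "coordinates.rc.3d.component.argument",
                         "localNodes.2d.square2x2.argument",
                         f"{params_type.name}.argument",
                         "interpolator.2d.unit.bilinearLagrange",
                         "shape.unit.square"])
    real = m.types["real.1d"]
    chart2d = m.types["chart.2d"]
    local_nodes = m.types["localNodes.2d.square2x2"]
    chart_arg = m.evaluators["chart.2d.argument"]
    local_arg = m.evaluators["localNodes.2d.square2x2.argument"]
    params_arg = m.evaluators[f"{params_type.name}.argument"]
    interpolator = m.evaluators["interpolator.2d.unit.bilinearLagrange"]
    unit_square = m.evaluators["shape.unit.square"]

    # shared template -------------------------------------------------------
    nodes = m.define_ensemble("nodes", range(1, 7))
    nodes_arg = m.argument("nodes.argument", nodes)
    mesh = m.define_mesh("mesh", 2, [1, 2], unit_square, chart_type=chart2d)
    mesh_arg, elements_arg, xi_arg = m.mesh_argument("mesh.argument", mesh)

    connectivity = np.array([[1, 2, 4, 5], [2, 3, 5, 6]])
    conn_res = m.add_resource(inline_resource(
        "connectivity.resource", render_text_array(connectivity)))
    conn_src = DataSource("connectivity.data", conn_res, connectivity.shape)
    conn = m.add_evaluator(Parameter("template.connectivity", nodes,
                                     (elements_arg, local_arg),
                                     DenseLayout(conn_src)))

    dofs_arg = m.add_evaluator(Argument("template.dofs.argument", real,
                                        argument_dependencies=(nodes_arg,)))
    local_dof = m.add_evaluator(Reference("template.localdof", dofs_arg,
                                          [Binding(nodes_arg, conn)]))
    dof_vector = m.add_evaluator(Aggregate("template.dofvector", params_type,
                                           local_arg, default=local_dof))
    interp = m.add_evaluator(Reference(
        "template.interpolation", interpolator,
        [Binding(chart_arg, xi_arg), Binding(params_arg, dof_vector)]))
    template = m.add_evaluator(Piecewise("template.evaluator", real,
                                         elements_arg, {1: interp, 2: interp}))

    # pressure field --------------------------------------------------------
    pressure_dofs = np.array([0.1, 55.2, 22.7, 10.1, 88.2, 5.5])
    p_res = m.add_resource(inline_resource(
        "pressure.resource", render_text_array(pressure_dofs)))
    p_src = DataSource("pressure.data", p_res, pressure_dofs.shape)
    p_params = m.add_evaluator(Parameter("pressure.parameters", real,
                                         (nodes_arg,), DenseLayout(p_src)))
    pressure = m.add_evaluator(Reference("pressure.field", template,
                                         [Binding(dofs_arg, p_params)]))

    # geometry field --------------------------------------------------------
    geometry_dofs = np.array([
        [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0],
        [0.0, 1.0, 0.0], [1.0, 1.0, 0.0], [2.0, 1.0, 0.0]])
    rc3 = m.types["coordinates.rc.3d"]
    comp_arg = m.evaluators["coordinates.rc.3d.component.argument"]
    comps = {}
    for i, axis in enumerate("xyz"):
        res = m.add_resource(inline_resource(
            f"geometry.{axis}.resource", render_text_array(geometry_dofs[:, i])))
        src = DataSource(f"geometry.{axis}.data", res, (len(geometry_dofs),))
        pe = m.add_evaluator(Parameter(f"geometry.{axis}.parameters", real,
                                       (nodes_arg,), DenseLayout(src)))
        comps[i + 1] = m.add_evaluator(Reference(
            f"geometry.{axis}.field", template, [Binding(dofs_arg, pe)]))
    geometry = m.add_evaluator(Aggregate("geometry.field", rc3, comp_arg, comps))

    counts = {"types": len(m.types) - len([n for n in m.types
                                           if n in m.imported_names]),
              "evaluators": len([n for n in m.evaluators
                                 if n not in m.imported_names]),
              "data_resources": len(m.data_resources)}
    manifest = FixtureManifest(
        model_name=m.region_name, n_elements=2, n_nodes=6,
        object_counts=counts, connectivity=connectivity,
        pressure_dofs=pressure_dofs, geometry_dofs=geometry_dofs,
        element_center_pressure={
            e + 1: float(pressure_dofs[connectivity[e] - 1].mean())
            for e in range(2)})
    return IllustrativeExample(m, manifest, mesh_arg, pressure, geometry)


# ---------------------------------------------------------------------------
# Grid connectivity
# ---------------------------------------------------------------------------

def build_grid_connectivity(n_elements: int) -> DataSource:
    """The classic two-row grid connectivity matrix: row e is
    ``[e, e+1, e+10, e+11]`` (global node numbers for the four local nodes
    of square element e)."""
    if n_elements < 1:
        raise DefinitionError("n_elements must be >= 1")
    rows = np.array([[e, e + 1, e + 10, e + 11]
                     for e in range(1, n_elements + 1)])
    res = inline_resource("grid.connectivity.resource", render_text_array(rows))
    return DataSource("grid.connectivity.data", res, rows.shape)


# ---------------------------------------------------------------------------
# Multi-subject geometry in one HDF5 resource
# ---------------------------------------------------------------------------

@dataclass
class MultiSubjectModel:
    model: Model
    subject_fields: dict[int, Evaluator]   # subject member -> geometry field
    node_argument: Argument
    coordinates: np.ndarray                # (n_subjects, n_nodes, 3)


def build_multisubject_hdf5(n_subjects: int, nodes_per_subject: int,
                            seed: int, directory: Union[str, Path],
                            use_text: bool = False) -> MultiSubjectModel:
    """One (subjects x nodes x 3) dataset; per-subject geometry fields.

    Emulates cohort anatomy storage: a single heavy-data resource holds
    every subject's nodal coordinates, and each subject's field selects its
    slice through a subject-ensemble index.  With ``use_text`` the same
    model is built over a text resource (the equivalence twin).
    """
    if n_subjects < 1:
        raise DefinitionError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-1.0, 1.0, size=(n_subjects, nodes_per_subject, 3))
    directory = Path(directory)

    lib = load_library()
    m = Model("multisubject")
    _import_from_library(m, lib,
                         type_names=["real.1d", "coordinates.rc.3d"],
                         evaluator_names=["coordinates.rc.3d.component.argument"])
    real = m.types["real.1d"]
    rc3 = m.types["coordinates.rc.3d"]
    comp_arg = m.evaluators["coordinates.rc.3d.component.argument"]
    comp_ens = rc3.component_ensemble

    subjects = m.define_ensemble("subjects", range(1, n_subjects + 1))
    nodes = m.define_ensemble("nodes", range(1, nodes_per_subject + 1))
    subject_arg = m.argument("subjects.argument", subjects)
    node_arg = m.argument("nodes.argument", nodes)

    if use_text:
        res = m.add_resource(inline_resource(
            "geometry.resource", render_text_array(coords.reshape(n_subjects, -1))))
        src = DataSource("geometry.data", res, coords.shape)
    else:
        path = directory / "multisubject_geometry.h5"
        if path.exists():
            path.unlink()
        write_hdf5_dataset(path, "/geometry", coords)
        res = m.add_resource(hdf5_resource("geometry.resource", path.name,
                                           base=directory))
        src = DataSource("geometry.data", res, coords.shape,
                         dataset="/geometry")
    params = m.add_evaluator(Parameter(
        "geometry.parameters", real, (subject_arg, node_arg, comp_arg),
        DenseLayout(src)))

    fields: dict[int, Evaluator] = {}
    for s in subjects.members:
        const = m.constant(f"subject.{s}", subjects, str(s))
        per_comp = m.add_evaluator(Reference(
            f"geometry.subject{s}.params", params, [Binding(subject_arg, const)]))
        fields[s] = m.add_evaluator(Aggregate(
            f"geometry.subject{s}.field", rc3, comp_arg, default=per_comp))
    return MultiSubjectModel(m, fields, node_arg, coords)


# ---------------------------------------------------------------------------
# VTK export
# ---------------------------------------------------------------------------

def export_vtk(mesh_argument: Argument,
               geometry_field: Evaluator,
               scalar_fields: dict[str, Evaluator],
               samples_per_element_edge: int,
               env: Optional[Environment] = None,
               config: EvalConfig = EvalConfig()) -> str:
    """Tessellate mesh fields into a VTK legacy ASCII unstructured grid.

    Each element is sampled on a regular chart grid with
    ``samples_per_element_edge`` intervals per edge; coincident points on
    shared edges are deliberately not merged (per-element tessellation
    avoids tolerance-based merge decisions).  Supports 2D (quad cells) and
    3D (hexahedron cells) meshes; 2D geometry is padded with z = 0.
    """
    from .model import MeshType
    mesh = mesh_argument.value_type
    if not isinstance(mesh, MeshType):
        raise DefinitionError("export_vtk needs a mesh-typed argument")
    n = samples_per_element_edge
    if n < 1:
        raise DefinitionError("samples_per_element_edge must be >= 1")
    dim = mesh.dimension
    if dim not in (2, 3):
        raise DefinitionError("VTK export supports 2D and 3D meshes only")
    geo_dim = geometry_field.value_type.dimension \
        if isinstance(geometry_field.value_type, ContinuousType) else 0
    if geo_dim not in (2, 3):
        raise DefinitionError("geometry field must be 2- or 3-dimensional")

    env = env if env is not None else Environment()
    ticks = np.linspace(0.0, 1.0, n + 1)
    points: list[tuple[float, float, float]] = []
    cells: list[list[int]] = []
    scalars: dict[str, list[float]] = {name: [] for name in scalar_fields}

    for element in mesh.element_ensemble.sorted_members:
        base = len(points)
        if dim == 2:
            grid_idx = [(i, j) for j in range(n + 1) for i in range(n + 1)]
            xis = [(ticks[i], ticks[j]) for i, j in grid_idx]
        else:
            grid_idx = [(i, j, k) for k in range(n + 1)
                        for j in range(n + 1) for i in range(n + 1)]
            xis = [(ticks[i], ticks[j], ticks[k]) for i, j, k in grid_idx]
        for xi in xis:
            g = evaluate_mesh_field(geometry_field, mesh_argument, element, xi,
                                    env, config)
            vec = g.vector if isinstance(g, RealValue) else None
            if vec is None:
                raise FieldmlError("geometry field did not evaluate to a vector")
            xyz = tuple(vec) + (0.0,) * (3 - len(vec))
            points.append(xyz)
            for name, f in scalar_fields.items():
                v = evaluate_mesh_field(f, mesh_argument, element, xi, env, config)
                scalars[name].append(v.scalar)
        stride = n + 1
        if dim == 2:
            for j in range(n):
                for i in range(n):
                    p = base + j * stride + i
                    cells.append([p, p + 1, p + stride + 1, p + stride])
        else:
            plane = stride * stride
            for k in range(n):
                for j in range(n):
                    for i in range(n):
                        p = base + k * plane + j * stride + i
                        cells.append([p, p + 1, p + stride + 1, p + stride,
                                      p + plane, p + plane + 1,
                                      p + plane + stride + 1, p + plane + stride])

    cell_type = 9 if dim == 2 else 12  # VTK_QUAD / VTK_HEXAHEDRON
    npts_per_cell = 4 if dim == 2 else 8
    out = ["# vtk DataFile Version 3.0",
           "fieldml export", "ASCII", "DATASET UNSTRUCTURED_GRID",
           f"POINTS {len(points)} double"]
    out += [" ".join("%.17g" % c for c in p) for p in points]
    out.append(f"CELLS {len(cells)} {len(cells) * (npts_per_cell + 1)}")
    out += [f"{npts_per_cell} " + " ".join(str(i) for i in c) for c in cells]
    out.append(f"CELL_TYPES {len(cells)}")
    out += [str(cell_type)] * len(cells)
    if scalars:
        out.append(f"POINT_DATA {len(points)}")
        for name in sorted(scalars):
            out.append(f"SCALARS {name} double 1")
            out.append("LOOKUP_TABLE default")
            out += ["%.17g" % v for v in scalars[name]]
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Desk examples
# ---------------------------------------------------------------------------

@dataclass
class BindingDemo:
    """g(n) = {7.1 if n=1; 100 if n=2; x if n=3} and f(n) = g(n) with x
    bound to the constant k1 = 0.331."""
    model: Model
    n_argument: Argument
    x_argument: Argument
    g: Piecewise
    f: Reference


def build_binding_demo() -> BindingDemo:
    lib = load_library()
    m = Model("binding_demo")
    _import_from_library(m, lib, ["real.1d"], [])
    real = m.types["real.1d"]
    B = m.define_ensemble("B", [1, 2, 3])
    n = m.argument("n", B)
    x = m.argument("x", real)
    k1 = m.constant("k1", real, "0.331")
    g = m.add_evaluator(Piecewise("g", real, n, {
        1: m.constant("g.case1", real, "7.1"),
        2: m.constant("g.case2", real, "100"),
        3: x}))
    f = m.add_evaluator(Reference("f", g, [Binding(x, k1)]))
    return BindingDemo(m, n, x, g, f)


@dataclass
class FunctionBindingDemo:
    """g(n) = {7.1; 100; h(29)} with the function-valued argument h bound
    to the identity function, so f(3) is equivalent to identity(29) = 29."""
    model: Model
    n_argument: Argument
    f: Reference


def build_function_binding_demo() -> FunctionBindingDemo:
    lib = load_library()
    m = Model("function_binding_demo")
    _import_from_library(m, lib, ["real.1d"], [])
    real = m.types["real.1d"]
    B = m.define_ensemble("B", [1, 2, 3])
    n = m.argument("n", B)
    w = m.argument("w", real)
    h = m.add_evaluator(Argument("h", real, argument_dependencies=(w,)))
    applied = m.add_evaluator(Reference(
        "h.applied", h, [Binding(w, m.constant("operand", real, "29"))]))
    g = m.add_evaluator(Piecewise("g", real, n, {
        1: m.constant("g.case1", real, "7.1"),
        2: m.constant("g.case2", real, "100"),
        3: applied}))
    # the identity function over w is the pipeline consisting of w alone
    f = m.add_evaluator(Reference("f", g, [Binding(h, w)]))
    return FunctionBindingDemo(m, n, f)


def build_node_coordinates_demo() -> tuple[Model, Parameter, Argument, Argument]:
    """The node-coordinate parameter mapping nodes 1..4 of a unit square to
    (0,0), (1,0), (0,1), (1,1), indexed by node and Cartesian component."""
    lib = load_library()
    m = Model("node_coordinates")
    _import_from_library(m, lib, ["real.1d", "coordinates.rc.2d"],
                         ["coordinates.rc.2d.component.argument"])
    real = m.types["real.1d"]
    comp_arg = m.evaluators["coordinates.rc.2d.component.argument"]
    nodes = m.define_ensemble("nodes", [1, 2, 3, 4])
    node_arg = m.argument("nodes.argument", nodes)
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    res = m.add_resource(inline_resource("coords.resource",
                                         render_text_array(coords)))
    src = DataSource("coords.data", res, coords.shape)
    p = m.add_evaluator(Parameter("node.coordinates", real,
                                  (node_arg, comp_arg), DenseLayout(src)))
    return m, p, node_arg, comp_arg


def build_constant_vector_demo() -> tuple[Model, Aggregate]:
    """The constant Cartesian vector (0.5, -1, 20.1) via an aggregate of
    three constant evaluators."""
    lib = load_library()
    m = Model("constant_vector")
    _import_from_library(m, lib, ["real.1d", "coordinates.rc.3d"],
                         ["coordinates.rc.3d.component.argument"])
    real = m.types["real.1d"]
    rc3 = m.types["coordinates.rc.3d"]
    comp_arg = m.evaluators["coordinates.rc.3d.component.argument"]
    comps = {i + 1: m.constant(f"component.{i + 1}", real, s)
             for i, s in enumerate(["0.5", "-1", "20.1"])}
    agg = m.add_evaluator(Aggregate("vector", rc3, comp_arg, comps))
    return m, agg


# ---------------------------------------------------------------------------
# Random corpora for property suites
# ---------------------------------------------------------------------------

def random_model(seed: int) -> Model:
    """A seeded random region: ensembles, constants, inline parameters and
    piecewise/aggregate/reference nests of depth <= 4."""
    rng = random.Random(seed)
    m = Model(f"random{seed}")
    real = m.define_continuous("real.1d")
    n_ens = rng.randint(1, 3)
    ensembles = []
    for i in range(n_ens):
        k = rng.randint(2, 6)
        start = rng.randint(0, 20)
        members = sorted(rng.sample(range(start, start + 3 * k), k))
        ensembles.append(m.define_ensemble(f"ens{i}", members))
    args = {e.name: m.argument(f"{e.name}.argument", e) for e in ensembles}
    x = m.argument("x", real)
    scalars: list[Evaluator] = [x]
    for i in range(rng.randint(1, 4)):
        scalars.append(m.constant(f"c{i}", real,
                                  "%.6g" % rng.uniform(-100, 100)))
    # inline parameters over a random ensemble
    for i in range(rng.randint(0, 2)):
        e = rng.choice(ensembles)
        vals = np.array([rng.uniform(-10, 10) for _ in e.members])
        res = m.add_resource(inline_resource(f"p{i}.resource",
                                             render_text_array(vals)))
        src = DataSource(f"p{i}.data", res, vals.shape)
        scalars.append(m.add_evaluator(Parameter(
            f"p{i}", real, (args[e.name],), DenseLayout(src))))

    counter = [0]

    def nest(depth: int) -> Evaluator:
        """A random scalar-valued pipeline of the given maximum depth."""
        counter[0] += 1
        name = f"n{counter[0]}"
        if depth == 0 or rng.random() < 0.3:
            return rng.choice(scalars)
        kind = rng.choice(["piecewise", "reference"])
        if kind == "piecewise":
            e = rng.choice(ensembles)
            branches = {mem: nest(depth - 1)
                        for mem in rng.sample(e.members,
                                              rng.randint(1, e.cardinality))}
            default = nest(depth - 1) if rng.random() < 0.5 else None
            return m.add_evaluator(Piecewise(name, real, args[e.name],
                                             branches, default))
        target = nest(depth - 1)
        bindings = []
        from .model import unbound_arguments
        if rng.random() < 0.6 and x in unbound_arguments(target):
            bindings.append(Binding(x, rng.choice(scalars[1:])
                                    if len(scalars) > 1 else x))
        return m.add_evaluator(Reference(name, target, bindings))

    for i in range(rng.randint(1, 3)):
        body = nest(rng.randint(1, 3))
        if rng.random() < 0.4:
            counter[0] += 1
            dim = rng.choice([2, 3])
            vec = m.define_continuous(f"v{counter[0]}.type", dim)
            idx = m.argument(f"v{counter[0]}.index", vec.component_ensemble)
            comps = {c: (body if c == vec.component_ensemble.members[0]
                         else nest(1))
                     for c in vec.component_ensemble.members}
            m.add_evaluator(Aggregate(f"v{counter[0]}", vec, idx, comps))
    return m


@dataclass
class RandomPipeline:
    model: Model
    root: Reference                 # a reference binding `argument`
    argument: Argument              # the bound argument
    delegate: Evaluator
    env: Environment                # assigns every other free argument


def substitute(ev: Evaluator, mapping: dict[Argument, Evaluator],
               _memo: Optional[dict[int, Evaluator]] = None) -> Evaluator:
    """Textual substitution: a deep copy of the pipeline with arguments
    replaced by delegate expressions.  The independent oracle for binding
    semantics: binding then evaluating must equal substituting then
    evaluating.  Substitution respects shadowing (it stops descending for
    an argument that an inner binding re-binds)."""
    memo = _memo if _memo is not None else {}
    if id(ev) in memo:
        return memo[id(ev)]
    if isinstance(ev, Argument):
        return mapping.get(ev, ev)
    if isinstance(ev, Constant) or isinstance(ev, External):
        return ev
    if isinstance(ev, Parameter):
        new_idx = tuple(substitute(a, mapping, memo) for a in ev.index_arguments)
        if all(a is b for a, b in zip(new_idx, ev.index_arguments)):
            return ev
        raise FieldmlError("cannot substitute into a parameter index argument")

    def sub_bindings(bindings):
        inner = {k: v for k, v in mapping.items()
                 if k not in {b.argument for b in bindings}}
        new_b = tuple(Binding(b.argument, substitute(b.delegate, mapping, memo))
                      for b in bindings)
        return inner, new_b

    if isinstance(ev, Reference):
        inner, new_b = sub_bindings(ev.bindings)
        out = Reference(ev.name, substitute(ev.target, inner, memo), new_b)
    elif isinstance(ev, Piecewise):
        inner, new_b = sub_bindings(ev.bindings)
        out = Piecewise(ev.name, ev.value_type,
                        substitute(ev.index, inner, memo),
                        {k: substitute(v, inner, memo)
                         for k, v in ev.branches.items()},
                        substitute(ev.default, inner, memo)
                        if ev.default is not None else None,
                        new_b)
    elif isinstance(ev, Aggregate):
        inner, new_b = sub_bindings(ev.bindings)
        inner = {k: v for k, v in inner.items() if k is not ev.index_argument}
        out = Aggregate(ev.name, ev.value_type, ev.index_argument,
                        {k: substitute(v, inner, memo)
                         for k, v in ev.components.items()},
                        substitute(ev.default, inner, memo)
                        if ev.default is not None else None,
                        new_b)
    else:
        raise FieldmlError(f"cannot substitute into {ev!r}")
    memo[id(ev)] = out
    return out


def random_pipeline(seed: int) -> RandomPipeline:
    """A seeded pipeline plus a binding, for the substitution oracle.

    The root is a reference that binds one plain argument ``x`` to a
    random delegate; the environment covers the remaining free arguments.
    Delegates never reference arguments that are re-bound deeper in the
    pipeline, so lexical and substitution semantics coincide (the property
    under test).
    """
    rng = random.Random(seed)
    m = Model(f"pipeline{seed}")
    real = m.define_continuous("real.1d")
    e = m.define_ensemble("ens", sorted(rng.sample(range(1, 20),
                                                   rng.randint(2, 5))))
    n_arg = m.argument("n", e)
    x = m.argument("x", real)
    y = m.argument("y", real)
    consts = [m.constant(f"c{i}", real, "%.6g" % rng.uniform(-50, 50))
              for i in range(3)]
    delegate = rng.choice(consts + [y])
    # if the delegate mentions y, inner pipelines must not re-bind y, or
    # substitution would capture it where lexical binding does not
    may_rebind_y = delegate not in (y,)
    counter = [0]

    def nest(depth: int) -> Evaluator:
        counter[0] += 1
        name = f"n{counter[0]}"
        if depth == 0 or rng.random() < 0.35:
            return rng.choice([x, y] + consts)
        kind = rng.choice(["piecewise", "reference"])
        if kind == "piecewise":
            branches = {mem: nest(depth - 1) for mem in e.members}
            return m.add_evaluator(Piecewise(name, real, n_arg, branches))
        target = nest(depth - 1)
        bindings = []
        if may_rebind_y and rng.random() < 0.4:
            bindings.append(Binding(y, rng.choice(consts)))
        return m.add_evaluator(Reference(name, target, bindings))

    body = nest(rng.randint(1, 4))
    root = m.add_evaluator(Reference("root", body, [Binding(x, delegate)]))
    env = Environment({
        n_arg: EnsembleValue(e, rng.choice(e.members)),
        y: RealValue(real, (rng.uniform(-5, 5),)),
    })
    return RandomPipeline(m, root, x, delegate, env)
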