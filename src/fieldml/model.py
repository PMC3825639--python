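"""The typed object model: domain types, evaluators, bindings, regions.

A model is a named region holding domain types, evaluators, data resources
and import records.  Domain types come in four kinds — ensembles (finite
member sets with non-negative integer identifiers), the Boolean type,
continuous n-dimensional types, and mesh types (an element ensemble crossed
with a chart).  Evaluators are the nodes of a directed acyclic pipeline;
there are seven kinds (argument, constant, parameter, piecewise, aggregate,
reference, external) and every evaluator carries a value type.

Typing is *nominal*: two independently declared ensembles with identical
member sets are incompatible, and compatibility of any pair of types is
object identity of the resolved type objects.  Imported objects are the
same objects as in their source region, so imports never break
compatibility.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Iterator, Mapping, Optional, Union

from .errors import BindingError, DefinitionError, MemberError, TypeError_

if TYPE_CHECKING:  # pragma: no cover
    from .data import DataResource, ParameterStorage


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class DomainType:
    """Base class for the four kinds of domain type.

    Identity semantics: two type objects are compatible iff they are the
    same object (``a is b``).  Subclasses therefore never define ``__eq__``.
    """

    name: str

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{type(self).__name__} {self.name!r}>"


class EnsembleType(DomainType):
    """A finite discrete domain whose members are unique non-negative ints.

    Member identifiers are stored as given; an ascending order is imposed
    only where serialization or dense-array ranking requires one.
    """

    def __init__(self, name: str, members: Iterable[int]):
        members = tuple(members)
        if not members:
            raise DefinitionError(f"ensemble {name!r}: empty member set is not allowed")
        seen = set()
        for m in members:
            if not isinstance(m, (int,)) or isinstance(m, bool):
                raise DefinitionError(f"ensemble {name!r}: member {m!r} is not an integer")
            if m < 0:
                raise DefinitionError(f"ensemble {name!r}: member {m} is negative")
            if m in seen:
                raise DefinitionError(f"ensemble {name!r}: duplicate member {m}")
            seen.add(m)
        self.name = name
        self.members = members
        self._sorted = tuple(sorted(members))
        self._rank = {m: i for i, m in enumerate(self._sorted)}

    @property
    def sorted_members(self) -> tuple[int, ...]:
        return self._sorted

    @property
    def cardinality(self) -> int:
        return len(self.members)

    def __contains__(self, member: int) -> bool:
        return member in self._rank

    def rank(self, member: int) -> int:
        """Position of *member* in the ascending member order (0-based)."""
        try:
            return self._rank[member]
        except KeyError:
            raise MemberError(f"{member} is not a member of ensemble {self.name!r}")

    def is_contiguous(self) -> bool:
        lo, hi = self._sorted[0], self._sorted[-1]
        return hi - lo + 1 == len(self._sorted)


class BooleanType(DomainType):
    """The canonical two-valued type; used only by element shape predicates."""

    def __init__(self, name: str):
        self.name = name


class ContinuousType(DomainType):
    """A continuous n-dimensional real domain.

    For dimension > 1 an ensemble indexing the vector components (members
    1..n) accompanies the type; a 1-dimensional type has none.
    """

    def __init__(self, name: str, dimension: int = 1,
                 component_ensemble: Optional[EnsembleType] = None):
        if dimension < 1:
            raise DefinitionError(f"continuous type {name!r}: dimension must be >= 1")
        if dimension == 1 and component_ensemble is not None:
            raise DefinitionError(
                f"continuous type {name!r}: 1-dimensional type has no component ensemble")
        if dimension > 1:
            if component_ensemble is None:
                component_ensemble = EnsembleType(f"{name}.component",
                                                  range(1, dimension + 1))
            if component_ensemble.cardinality != dimension:
                raise DefinitionError(
                    f"continuous type {name!r}: component ensemble cardinality "
                    f"{component_ensemble.cardinality} != dimension {dimension}")
        self.name = name
        self.dimension = dimension
        self.component_ensemble = component_ensemble


class MeshType(DomainType):
    """An element ensemble crossed with a chart (local coordinate) type.

    All elements share the mesh dimension.  Every element carries a shape
    predicate: a Boolean-valued evaluator, true on the closed reference
    shape and false outside it.
    """

    def __init__(self, name: str, dimension: int, element_ensemble: EnsembleType,
                 chart_type: ContinuousType,
                 shape_map: Mapping[int, "Evaluator"]):
        if dimension < 1:
            raise DefinitionError(f"mesh {name!r}: dimension must be >= 1")
        if chart_type.dimension != dimension:
            raise DefinitionError(
                f"mesh {name!r}: chart type {chart_type.name!r} has dimension "
                f"{chart_type.dimension}, mesh has {dimension}")
        shape_map = dict(shape_map)
        for e in element_ensemble.members:
            if e not in shape_map:
                raise DefinitionError(f"mesh {name!r}: element {e} has no shape predicate")
        for e, pred in shape_map.items():
            if e not in element_ensemble:
                raise DefinitionError(f"mesh {name!r}: shape assigned to non-element {e}")
            if not isinstance(pred.value_type, BooleanType):
                raise TypeError_(
                    f"mesh {name!r}: shape predicate {pred.name!r} for element {e} "
                    f"has value type {pred.value_type.name!r}, expected Boolean")
        self.name = name
        self.dimension = dimension
        self.element_ensemble = element_ensemble
        self.chart_type = chart_type
        self.shape_map = shape_map


# ---------------------------------------------------------------------------
# Evaluators
# ---------------------------------------------------------------------------

class Evaluator:
    """Base class for the seven evaluator kinds.  Identity semantics."""

    name: str
    value_type: DomainType

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{type(self).__name__} {self.name!r}>"


@dataclass(eq=False)
class Binding:
    """Associates an upstream argument with a delegate evaluator.

    Semantically a term substitution: within the subtree the binding is
    attached to, every occurrence of ``argument`` stands for ``delegate``.
    """

    argument: "Argument"
    delegate: Evaluator


class Argument(Evaluator):
    """Names an input of the pipeline.

    A plain argument stands for a value of its type.  A function-valued
    argument additionally declares the arguments it is applied to
    (``argument_dependencies``); a delegate bound to it is applied to those
    operands at the original application site.

    ``mesh_projection`` marks the implicit accessors of a mesh-typed
    argument: ``(mesh_argument, "elements")`` extracts the element member,
    ``(mesh_argument, "xi")`` the chart coordinates.
    """

    def __init__(self, name: str, value_type: DomainType,
                 argument_dependencies: Iterable["Argument"] = (),
                 mesh_projection: Optional[tuple["Argument", str]] = None):
        self.name = name
        self.value_type = value_type
        self.argument_dependencies = tuple(argument_dependencies)
        if mesh_projection is not None:
            parent, selector = mesh_projection
            if selector not in ("elements", "xi"):
                raise DefinitionError(f"argument {name!r}: bad mesh projection {selector!r}")
            if not isinstance(parent.value_type, MeshType):
                raise DefinitionError(
                    f"argument {name!r}: mesh projection parent is not mesh-typed")
        self.mesh_projection = mesh_projection

    @property
    def is_function_valued(self) -> bool:
        return bool(self.argument_dependencies)


class Constant(Evaluator):
    """A scalar constant held as its textual representation."""

    def __init__(self, name: str, value_type: DomainType, value_string: str):
        self.name = name
        self.value_type = value_type
        self.value_string = str(value_string)
        parse_constant(value_string, value_type)  # validate eagerly


class Parameter(Evaluator):
    """A piecewise function from ensemble indices to stored data values.

    ``index_arguments`` are the ensemble-valued inputs, in declared order;
    ``storage`` (dense or sparse) addresses the backing data source(s).
    The value type is a scalar continuous type or an ensemble type.
    """

    def __init__(self, name: str, value_type: DomainType,
                 index_arguments: Iterable[Argument],
                 storage: "ParameterStorage"):
        if not (isinstance(value_type, EnsembleType)
                or (isinstance(value_type, ContinuousType) and value_type.dimension == 1)):
            raise DefinitionError(
                f"parameter {name!r}: value type must be a scalar continuous "
                f"type or an ensemble, got {value_type.name!r}")
        index_arguments = tuple(index_arguments)
        for a in index_arguments:
            if not isinstance(a.value_type, EnsembleType):
                raise TypeError_(
                    f"parameter {name!r}: index argument {a.name!r} is not ensemble-valued")
        self.name = name
        self.value_type = value_type
        self.index_arguments = index_arguments
        self.storage = storage


class Piecewise(Evaluator):
    """Branches on an ensemble-valued index evaluator.

    The usual final step of a field over a FEM mesh: the index identifies
    the element, each branch supplies the within-element evaluator.
    """

    def __init__(self, name: str, value_type: DomainType, index: Evaluator,
                 branches: Mapping[int, Evaluator],
                 default: Optional[Evaluator] = None,
                 bindings: Iterable[Binding] = ()):
        if not isinstance(index.value_type, EnsembleType):
            raise TypeError_(
                f"piecewise {name!r}: index {index.name!r} is not ensemble-valued")
        self.name = name
        self.value_type = value_type
        self.index = index
        self.branches = dict(branches)
        self.default = default
        self.bindings = tuple(bindings)


class Aggregate(Evaluator):
    """Builds a vector value component by component.

    Components are identified by members of the value type's component
    ensemble and assembled in ascending member order.  A component either
    has its own evaluator in ``components`` or falls through to ``default``
    (an index-dependent delegate evaluated with ``index_argument`` bound to
    the component member).
    """

    def __init__(self, name: str, value_type: ContinuousType,
                 index_argument: Argument,
                 components: Mapping[int, Evaluator] = (),
                 default: Optional[Evaluator] = None,
                 bindings: Iterable[Binding] = ()):
        if not isinstance(value_type, ContinuousType) or value_type.component_ensemble is None:
            raise DefinitionError(
                f"aggregate {name!r}: value type must be a continuous type with "
                f"a component ensemble")
        if index_argument.value_type is not value_type.component_ensemble:
            raise TypeError_(
                f"aggregate {name!r}: index argument {index_argument.name!r} is not "
                f"valued in the component ensemble of {value_type.name!r}")
        self.name = name
        self.value_type = value_type
        self.index_argument = index_argument
        self.components = dict(components)
        self.default = default
        self.bindings = tuple(bindings)


class Reference(Evaluator):
    """An alias for another evaluator, optionally with argument bindings."""

    def __init__(self, name: str, target: Evaluator,
                 bindings: Iterable[Binding] = ()):
        self.name = name
        self.target = target
        self.bindings = tuple(bindings)

    @property
    def value_type(self) -> DomainType:
        seen = {id(self)}
        t = self.target
        while isinstance(t, Reference):
            if id(t) in seen:
                raise DefinitionError(
                    f"reference {self.name!r}: cyclic chain of references")
            seen.add(id(t))
            t = t.target
        return t.value_type


class External(Evaluator):
    """Declares an evaluator whose semantics are fixed by convention.

    The implementation key is the fully qualified name; the evaluation
    engine dispatches on it through a registry.  Unknown externals survive
    (de)serialization untouched and fail only at evaluation time.
    """

    def __init__(self, name: str, value_type: DomainType,
                 declared_arguments: Iterable[Argument] = ()):
        self.name = name
        self.value_type = value_type
        self.declared_arguments = tuple(declared_arguments)


# ---------------------------------------------------------------------------
# Constant parsing
# ---------------------------------------------------------------------------

def parse_constant(value_string: str, value_type: DomainType):
    """Parse a constant's textual representation under its value type.

    Returns a float (scalar continuous), int member (ensemble) or bool.
    """
    s = str(value_string).strip()
    if isinstance(value_type, ContinuousType):
        if value_type.dimension != 1:
            raise DefinitionError(
                f"constant of type {value_type.name!r}: only scalar constants "
                f"are representable as a string")
        try:
            return float(s)
        except ValueError:
            raise DefinitionError(f"constant {s!r} does not parse as a real number")
    if isinstance(value_type, EnsembleType):
        try:
            member = int(s)
        except ValueError:
            raise DefinitionError(f"constant {s!r} does not parse as a member identifier")
        if member not in value_type:
            raise DefinitionError(
                f"constant {s!r} is not a member of ensemble {value_type.name!r}")
        return member
    if isinstance(value_type, BooleanType):
        if s.lower() == "true":
            return True
        if s.lower() == "false":
            return False
        raise DefinitionError(f"constant {s!r} does not parse as a Boolean")
    raise DefinitionError(f"constants of type {value_type.name!r} are not supported")


# ---------------------------------------------------------------------------
# Graph traversal
# ---------------------------------------------------------------------------

def children(ev: Evaluator) -> Iterator[Evaluator]:
    """All evaluators directly referenced by *ev* (the pipeline edges)."""
    if isinstance(ev, Argument):
        yield from ev.argument_dependencies
        if ev.mesh_projection is not None:
            yield ev.mesh_projection[0]
    elif isinstance(ev, Parameter):
        yield from ev.index_arguments
    elif isinstance(ev, Piecewise):
        yield ev.index
        yield from ev.branches.values()
        if ev.default is not None:
            yield ev.default
        for b in ev.bindings:
            yield b.argument
            yield b.delegate
    elif isinstance(ev, Aggregate):
        yield ev.index_argument
        yield from ev.components.values()
        if ev.default is not None:
            yield ev.default
        for b in ev.bindings:
            yield b.argument
            yield b.delegate
    elif isinstance(ev, Reference):
        yield ev.target
        for b in ev.bindings:
            yield b.argument
            yield b.delegate
    elif isinstance(ev, External):
        yield from ev.declared_arguments
    # Constant: no children


def _bindings_of(ev: Evaluator) -> tuple[Binding, ...]:
    return getattr(ev, "bindings", ())


def delegate_signature(ev: Evaluator) -> tuple[Argument, ...]:
    """The positional argument signature of an evaluator used as a delegate.

    Externals declare theirs; a function-valued argument's signature is its
    dependency list; a plain argument is the identity over itself; anything
    else exposes its unbound arguments in first-encounter order.
    """
    if isinstance(ev, External):
        return ev.declared_arguments
    if isinstance(ev, Argument):
        return ev.argument_dependencies if ev.is_function_valued else (ev,)
    return tuple(unbound_arguments(ev))


def unbound_arguments(ev: Evaluator) -> list[Argument]:
    """Arguments reachable from *ev* that no binding on the path satisfies.

    Bindings shadow lexically: a binding on a reference (or piecewise or
    aggregate) covers every occurrence of the bound argument within its
    inner subtree, but not the binding delegates themselves, which are
    evaluated in the enclosing scope.
    """
    out: list[Argument] = []
    seen: set[tuple[int, frozenset]] = set()

    def visit(e: Evaluator, bound: frozenset):
        key = (id(e), bound)
        if key in seen:
            return
        seen.add(key)
        if isinstance(e, Argument):
            if e.mesh_projection is not None:
                parent = e.mesh_projection[0]
                if e not in bound and parent not in bound and e not in out:
                    out.append(e)
                return
            if e not in bound and e not in out:
                out.append(e)
            for d in e.argument_dependencies:
                visit(d, bound)
            return
        binds = _bindings_of(e)
        for b in binds:
            if b.argument.is_function_valued:
                # applied at the operand site: its signature is consumed there
                sig = delegate_signature(b.delegate)
                arity = len(b.argument.argument_dependencies)
                visit_delegate_bound = bound | frozenset(sig[:arity])
                visit(b.delegate, visit_delegate_bound)
            else:
                visit(b.delegate, bound)
        inner_bound = bound | frozenset(b.argument for b in binds)
        if isinstance(e, Aggregate):
            inner_bound = inner_bound | {e.index_argument}
            visit(e.index_argument, bound | {e.index_argument})
            for c in e.components.values():
                visit(c, inner_bound)
            if e.default is not None:
                visit(e.default, inner_bound)
        elif isinstance(e, Piecewise):
            visit(e.index, inner_bound)
            for c in e.branches.values():
                visit(c, inner_bound)
            if e.default is not None:
                visit(e.default, inner_bound)
        elif isinstance(e, Reference):
            visit(e.target, inner_bound)
        elif isinstance(e, Parameter):
            for a in e.index_arguments:
                visit(a, inner_bound)
        elif isinstance(e, External):
            for a in e.declared_arguments:
                visit(a, inner_bound)
        # Constant: nothing

    visit(ev, frozenset())
    return out


# ---------------------------------------------------------------------------
# Strong typing
# ---------------------------------------------------------------------------

def type_compatible(expected: DomainType, actual: DomainType) -> bool:
    """Nominal compatibility: the same resolved type object.

    Structurally identical but independently declared types (e.g. two
    ensembles with equal member sets) are incompatible.
    """
    return expected is actual


@dataclass(frozen=True)
class ComposeVerdict:
    ok: bool
    expected: Optional[DomainType]
    actual: Optional[DomainType]
    message: str

    def __bool__(self) -> bool:
        return self.ok


def compose_check(outer: Evaluator, inner: Evaluator) -> ComposeVerdict:
    """Can ``outer ∘ inner`` be formed?

    ``outer`` must expose exactly one unbound argument; the composition is
    valid iff ``inner``'s value type is nominally compatible with that
    argument's type.  Composing through an explicit converter evaluator
    (an intermediate map between same-membered ensembles) is how otherwise
    incompatible pipelines are joined.
    """
    ub = unbound_arguments(outer)
    if len(ub) != 1:
        raise DefinitionError(
            f"compose_check: outer evaluator {outer.name!r} has {len(ub)} unbound "
            f"arguments, expected exactly 1")
    expected = ub[0].value_type
    actual = inner.value_type
    if type_compatible(expected, actual):
        return ComposeVerdict(True, expected, actual, "ok")
    return ComposeVerdict(
        False, expected, actual,
        f"cannot compose: {outer.name!r} expects {expected.name!r} but "
        f"{inner.name!r} yields {actual.name!r}")


# ---------------------------------------------------------------------------
# Model (region)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImportRecord:
    href: str
    kind: str           # "type" | "evaluator"
    remote_name: str
    local_name: str


@dataclass(frozen=True)
class Diagnostic:
    """A validation finding: the offending object and the rule violated."""
    object_name: str
    rule: str
    message: str


class Model:
    """A named region: types, evaluators, data resources and imports.

    Names are unique across all object kinds within the region.  Objects
    brought in by imports are registered under their local name but remain
    the identical objects of their source region.
    """

    def __init__(self, region_name: str):
        self.region_name = region_name
        self.types: dict[str, DomainType] = {}
        self.evaluators: dict[str, Evaluator] = {}
        self.data_resources: dict[str, "DataResource"] = {}
        self.imports: list[ImportRecord] = []
        self.imported_names: set[str] = set()
        self.diagnostics: list[Diagnostic] = []

    # -- registration -------------------------------------------------------

    def _claim(self, name: str):
        if name in self.types or name in self.evaluators or name in self.data_resources:
            raise DefinitionError(
                f"region {self.region_name!r}: name {name!r} already defined")

    def add_type(self, t: DomainType, local_name: Optional[str] = None) -> DomainType:
        name = local_name or t.name
        self._claim(name)
        self.types[name] = t
        return t

    def add_evaluator(self, ev: Evaluator, local_name: Optional[str] = None) -> Evaluator:
        name = local_name or ev.name
        self._claim(name)
        self.evaluators[name] = ev
        return ev

    def add_resource(self, r: "DataResource") -> "DataResource":
        self._claim(r.name)
        self.data_resources[r.name] = r
        return r

    # -- convenience constructors ------------------------------------------

    def define_ensemble(self, name: str, members: Iterable[int]) -> EnsembleType:
        return self.add_type(define_ensemble(name, members))

    def define_continuous(self, name: str, dimension: int = 1) -> ContinuousType:
        t = ContinuousType(name, dimension)
        self.add_type(t)
        if t.component_ensemble is not None:
            self.add_type(t.component_ensemble)
        return t

    def define_boolean(self, name: str) -> BooleanType:
        return self.add_type(BooleanType(name))

    def define_mesh(self, name: str, dimension: int,
                    element_members: Iterable[int],
                    shape_assignments: Union[Evaluator, Mapping[int, Evaluator]],
                    chart_type: Optional[ContinuousType] = None) -> MeshType:
        mesh = define_mesh(name, dimension, element_members, shape_assignments,
                           chart_type=chart_type)
        self.add_type(mesh)
        self.add_type(mesh.element_ensemble)
        if chart_type is None:
            self.add_type(mesh.chart_type)
            if mesh.chart_type.component_ensemble is not None:
                self.add_type(mesh.chart_type.component_ensemble)
        return mesh

    def argument(self, name: str, value_type: DomainType,
                 dependencies: Iterable[Argument] = ()) -> Argument:
        return self.add_evaluator(Argument(name, value_type, dependencies))

    def mesh_argument(self, name: str, mesh: MeshType
                      ) -> tuple[Argument, Argument, Argument]:
        """Create a mesh-typed argument plus its implicit accessors.

        Returns ``(location, elements, xi)`` where the accessors project the
        element member and the chart coordinates out of the mesh location.
        Accessor names follow the ``<name>.elements`` / ``<name>.xi``
        convention so they survive serialization.
        """
        loc = Argument(name, mesh)
        elems = Argument(f"{name}.elements", mesh.element_ensemble,
                         mesh_projection=(loc, "elements"))
        xi = Argument(f"{name}.xi", mesh.chart_type, mesh_projection=(loc, "xi"))
        for a in (loc, elems, xi):
            self.add_evaluator(a)
        return loc, elems, xi

    def constant(self, name: str, value_type: DomainType, value_string: str) -> Constant:
        return self.add_evaluator(Constant(name, value_type, value_string))

    def lookup(self, name: str):
        """Resolve a name to a type, evaluator or data resource."""
        for ns in (self.evaluators, self.types, self.data_resources):
            if name in ns:
                return ns[name]
        raise KeyError(f"region {self.region_name!r}: no object named {name!r}")

    # -- iteration ---------------------------------------------------------

    def all_objects(self) -> Iterator[tuple[str, object]]:
        yield from self.types.items()
        yield from self.evaluators.items()
        yield from self.data_resources.items()


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def define_ensemble(name: str, members: Iterable[int]) -> EnsembleType:
    """Define an ensemble type with the exact given member set."""
    return EnsembleType(name, members)


def define_mesh(name: str, dimension: int, element_members: Iterable[int],
                shape_assignments: Union[Evaluator, Mapping[int, Evaluator]],
                chart_type: Optional[ContinuousType] = None) -> MeshType:
    """Define a mesh type with its implicit element ensemble and chart.

    *shape_assignments* is either a single Boolean-valued evaluator applied
    to every element, or a mapping from element member to predicate.  When
    *chart_type* is omitted a fresh continuous type named ``<name>.xi`` is
    created; passing an existing chart type (e.g. the standard library's)
    lets mesh chart values flow into library interpolators under nominal
    typing.
    """
    if dimension < 1:
        raise DefinitionError(f"mesh {name!r}: dimension must be >= 1")
    element_ensemble = EnsembleType(f"{name}.elements", element_members)
    if chart_type is None:
        chart_type = ContinuousType(f"{name}.xi", dimension)
    if isinstance(shape_assignments, Evaluator):
        shape_map = {e: shape_assignments for e in element_ensemble.members}
    else:
        shape_map = dict(shape_assignments)
    return MeshType(name, dimension, element_ensemble, chart_type, shape_map)


def _check_binding(owner: str, b: Binding, target_unbound: list[Argument],
                   diags: list[Diagnostic]):
    if b.argument not in target_unbound:
        diags.append(Diagnostic(owner, "binding",
                                f"binds {b.argument.name!r}, which is not an unbound "
                                f"upstream argument of the target"))
        return
    if b.argument.is_function_valued:
        sig = delegate_signature(b.delegate)
        deps = b.argument.argument_dependencies
        if len(sig) != len(deps):
            diags.append(Diagnostic(owner, "binding-arity",
                                    f"function argument {b.argument.name!r} has arity "
                                    f"{len(deps)}, delegate {b.delegate.name!r} has "
                                    f"{len(sig)}"))
            return
        for i, (s, d) in enumerate(zip(sig, deps)):
            if not type_compatible(s.value_type, d.value_type):
                diags.append(Diagnostic(owner, "binding-type",
                                        f"position {i + 1} of function argument "
                                        f"{b.argument.name!r}: expected "
                                        f"{d.value_type.name!r}, delegate takes "
                                        f"{s.value_type.name!r}"))
    else:
        if not type_compatible(b.argument.value_type, b.delegate.value_type):
            diags.append(Diagnostic(owner, "binding-type",
                                    f"argument {b.argument.name!r} has type "
                                    f"{b.argument.value_type.name!r} but delegate "
                                    f"{b.delegate.name!r} yields "
                                    f"{b.delegate.value_type.name!r}"))


def validate_model(model: Model) -> list[Diagnostic]:
    """Check a region's structural and typing invariants.

    Returns diagnostics rather than raising; the empty list means the model
    is valid.  The result is deterministic and independent of declaration
    order (diagnostics are sorted by object name and rule).
    """
    diags: list[Diagnostic] = []
    registered_types = set(map(id, model.types.values()))
    registered_evals = set(map(id, model.evaluators.values()))
    registered_resources = set(map(id, model.data_resources.values()))
    # types embedded in a registered type count as declared
    for t in list(model.types.values()):
        if isinstance(t, ContinuousType) and t.component_ensemble is not None:
            registered_types.add(id(t.component_ensemble))
        if isinstance(t, MeshType):
            registered_types.add(id(t.element_ensemble))
            registered_types.add(id(t.chart_type))
            if t.chart_type.component_ensemble is not None:
                registered_types.add(id(t.chart_type.component_ensemble))

    def type_known(t: DomainType) -> bool:
        return id(t) in registered_types

    def eval_known(e: Evaluator) -> bool:
        return id(e) in registered_evals

    # reference resolution + per-object checks; imported objects were
    # validated in their source region, so only local ones are checked here
    for name, ev in sorted(model.evaluators.items()):
        if name in model.imported_names:
            continue
        try:
            ev.value_type
        except DefinitionError:
            continue  # cyclic reference chain; reported by the acyclicity pass
        if not type_known(ev.value_type):
            diags.append(Diagnostic(name, "dangling-type",
                                    f"value type {ev.value_type.name!r} is not "
                                    f"declared in the region"))
        for child in children(ev):
            if not eval_known(child):
                diags.append(Diagnostic(name, "dangling-reference",
                                        f"references undeclared evaluator "
                                        f"{child.name!r}"))
        if isinstance(ev, Piecewise):
            for member, branch in sorted(ev.branches.items()):
                if member not in ev.index.value_type:
                    diags.append(Diagnostic(name, "branch-member",
                                            f"branch for {member}, which is not a "
                                            f"member of {ev.index.value_type.name!r}"))
                if not type_compatible(ev.value_type, branch.value_type):
                    diags.append(Diagnostic(name, "branch-type",
                                            f"branch {member} yields "
                                            f"{branch.value_type.name!r}, declared "
                                            f"value type is {ev.value_type.name!r}"))
            if ev.default is not None and not type_compatible(ev.value_type,
                                                              ev.default.value_type):
                diags.append(Diagnostic(name, "branch-type",
                                        f"default branch yields "
                                        f"{ev.default.value_type.name!r}, declared "
                                        f"value type is {ev.value_type.name!r}"))
        if isinstance(ev, Aggregate):
            for member, comp in sorted(ev.components.items()):
                if member not in ev.value_type.component_ensemble:
                    diags.append(Diagnostic(name, "component-member",
                                            f"component {member} is not a member of "
                                            f"{ev.value_type.component_ensemble.name!r}"))
                if not (isinstance(comp.value_type, ContinuousType)
                        and comp.value_type.dimension == 1):
                    diags.append(Diagnostic(name, "component-type",
                                            f"component {member} evaluator "
                                            f"{comp.name!r} is not scalar-valued"))
            if ev.default is not None and not (
                    isinstance(ev.default.value_type, ContinuousType)
                    and ev.default.value_type.dimension == 1):
                diags.append(Diagnostic(name, "component-type",
                                        "default component evaluator is not "
                                        "scalar-valued"))
        if isinstance(ev, (Piecewise, Aggregate, Reference)):
            target_unbound = unbound_arguments(
                ev.target if isinstance(ev, Reference) else ev)
            if isinstance(ev, (Piecewise, Aggregate)):
                # bindings on piecewise/aggregate apply to their inner subtrees;
                # collect unbound args of those subtrees without the bindings
                inner: list[Argument] = []
                parts: list[Evaluator] = []
                if isinstance(ev, Piecewise):
                    parts = [ev.index, *ev.branches.values()]
                else:
                    parts = list(ev.components.values())
                if ev.default is not None:
                    parts.append(ev.default)
                for p in parts:
                    for a in unbound_arguments(p):
                        if a not in inner:
                            inner.append(a)
                if isinstance(ev, Aggregate):
                    inner = [a for a in inner if a is not ev.index_argument]
                target_unbound = inner
            for b in ev.bindings:
                _check_binding(name, b, target_unbound, diags)
        if isinstance(ev, Parameter):
            from .data import validate_parameter_storage
            for msg in validate_parameter_storage(ev):
                diags.append(Diagnostic(name, "parameter-data", msg))
            for a in ev.index_arguments:
                if not isinstance(a.value_type, EnsembleType):
                    diags.append(Diagnostic(name, "index-type",
                                            f"index argument {a.name!r} is not "
                                            f"ensemble-valued"))
            for r in ev.storage.resources():
                if id(r) not in registered_resources:
                    diags.append(Diagnostic(name, "dangling-resource",
                                            f"uses undeclared data resource "
                                            f"{r.name!r}"))

    for name, t in sorted(model.types.items()):
        if name in model.imported_names:
            continue
        if isinstance(t, MeshType):
            for e, pred in sorted(t.shape_map.items()):
                if not eval_known(pred):
                    diags.append(Diagnostic(name, "dangling-reference",
                                            f"shape predicate {pred.name!r} for "
                                            f"element {e} is not declared"))
                if not isinstance(pred.value_type, BooleanType):
                    diags.append(Diagnostic(name, "shape-type",
                                            f"shape predicate for element {e} is "
                                            f"not Boolean-valued"))
        if isinstance(t, ContinuousType) and t.component_ensemble is not None:
            if not type_known(t.component_ensemble):
                diags.append(Diagnostic(name, "dangling-type",
                                        "component ensemble is not declared"))

    # acyclicity over the whole evaluator graph
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[int, int] = {}

    def dfs(e: Evaluator, path: list[str]) -> Optional[list[str]]:
        c = color.get(id(e), WHITE)
        if c == GRAY:
            return path + [e.name]
        if c == BLACK:
            return None
        color[id(e)] = GRAY
        for ch in children(e):
            cyc = dfs(ch, path + [e.name])
            if cyc is not None:
                color[id(e)] = BLACK
                return cyc
        color[id(e)] = BLACK
        return None

    for name, ev in sorted(model.evaluators.items()):
        cyc = dfs(ev, [])
        if cyc is not None:
            diags.append(Diagnostic(name, "acyclicity",
                                    "reference cycle: " + " -> ".join(cyc)))
            break  # one diagnostic per cycle discovery is enough

    diags.sort(key=lambda d: (d.object_name, d.rule, d.message))
    return diags
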