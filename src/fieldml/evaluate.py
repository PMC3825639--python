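"""Numeric evaluation of evaluator pipelines.

The declarative object model makes every field an executable function:
given an environment assigning values to the unbound arguments, the engine
walks the pipeline eagerly and depth-first and produces a value — an
ensemble member, a Boolean, a real vector, or a mesh location.  Evaluation
is pure: identical (evaluator, environment) pairs give identical values.

Binding semantics: a binding on a reference (or piecewise or aggregate)
overrides the bound argument for every occurrence within the target
subtree, shadowing any enclosing assignment of the same argument.  Plain
bindings are evaluated eagerly in the enclosing scope (lexical scoping);
function-valued bindings install the delegate evaluator itself, which is
applied to the operands at the original application site.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

from . import registry as _registry
from .data import ParameterView
from .errors import (ArityError, BindingError, BranchError, DomainError,
                     EvaluationError, MemberError, MissingArgumentError,
                     TypeError_, UnimplementedExternalError)
from .model import (Aggregate, Argument, Binding, BooleanType, Constant,
                    ContinuousType, DomainType, EnsembleType, Evaluator,
                    External, MeshType, Parameter, Piecewise, Reference,
                    delegate_signature, parse_constant, type_compatible,
                    unbound_arguments)


# ---------------------------------------------------------------------------
# Runtime values
# ---------------------------------------------------------------------------

class Value:
    """Base class of runtime values."""


@dataclass(frozen=True)
class EnsembleValue(Value):
    type: EnsembleType
    member: int

    def __post_init__(self):
        if self.member not in self.type:
            raise MemberError(f"{self.member} is not a member of "
                              f"ensemble {self.type.name!r}")


@dataclass(frozen=True)
class BooleanValue(Value):
    value: bool


@dataclass(frozen=True)
class RealValue(Value):
    type: ContinuousType
    vector: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "vector", tuple(float(x) for x in self.vector))
        if len(self.vector) != self.type.dimension:
            raise TypeError_(f"real value of type {self.type.name!r}: vector "
                             f"length {len(self.vector)} != dimension "
                             f"{self.type.dimension}")

    @property
    def scalar(self) -> float:
        if len(self.vector) != 1:
            raise TypeError_(f"value of type {self.type.name!r} is not scalar")
        return self.vector[0]


@dataclass(frozen=True)
class MeshValue(Value):
    """A mesh location: element member plus chart coordinates."""
    mesh: MeshType
    element: int
    xi: tuple[float, ...]

    def __post_init__(self):
        if self.element not in self.mesh.element_ensemble:
            raise MemberError(f"element {self.element} is not in mesh "
                              f"{self.mesh.name!r}")
        object.__setattr__(self, "xi", tuple(float(x) for x in self.xi))
        if len(self.xi) != self.mesh.dimension:
            raise TypeError_(f"mesh location in {self.mesh.name!r}: chart "
                             f"coordinate length {len(self.xi)} != dimension "
                             f"{self.mesh.dimension}")


def value_matches_type(value: Value, t: DomainType) -> bool:
    if isinstance(value, EnsembleValue):
        return type_compatible(t, value.type)
    if isinstance(value, RealValue):
        return type_compatible(t, value.type)
    if isinstance(value, BooleanValue):
        return isinstance(t, BooleanType)
    if isinstance(value, MeshValue):
        return type_compatible(t, value.mesh)
    return False


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------

class Environment:
    """An immutable assignment of arguments to values (or delegates).

    Plain arguments map to :class:`Value` instances; function-valued
    arguments map to the delegate :class:`Evaluator` applied at their
    application sites.  ``extend`` returns a new environment that shadows
    the receiver for the given arguments.
    """

    __slots__ = ("_map",)

    def __init__(self, assignments: Optional[Mapping[Argument, object]] = None):
        m: dict[Argument, object] = {}
        if assignments:
            for arg, val in assignments.items():
                m[arg] = self._check(arg, val)
        self._map = m

    @staticmethod
    def _check(arg: Argument, val: object):
        if isinstance(val, Evaluator):
            if not arg.is_function_valued:
                raise TypeError_(f"argument {arg.name!r} is plain-valued; "
                                 f"assign a Value, not an evaluator")
            return val
        if not isinstance(val, Value):
            raise TypeError_(f"argument {arg.name!r}: {val!r} is neither a "
                             f"Value nor an evaluator")
        if not value_matches_type(val, arg.value_type):
            raise TypeError_(f"argument {arg.name!r} has type "
                             f"{arg.value_type.name!r}; assignment is "
                             f"incompatible")
        return val

    def extend(self, assignments: Mapping[Argument, object]) -> "Environment":
        new = Environment()
        new._map = dict(self._map)
        for arg, val in assignments.items():
            new._map[arg] = self._check(arg, val)
        return new

    def get(self, arg: Argument):
        return self._map.get(arg)

    def __contains__(self, arg: Argument) -> bool:
        return arg in self._map


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation options.

    ``allow_extrapolation`` disables the element-shape check when
    evaluating interpolators and mesh fields (off by default: silent
    extrapolation hides connectivity bugs).  ``registry`` overrides the
    global external-implementation registry.
    """
    allow_extrapolation: bool = False
    registry: Optional[Mapping[str, object]] = None

    def implementation_for(self, name: str):
        if self.registry is not None:
            return self.registry.get(name)
        return _registry.implementation_for(name)


_DEFAULT_CONFIG = EvalConfig()


# ---------------------------------------------------------------------------
# The engine
# ---------------------------------------------------------------------------

def _wrap_constant(ev: Constant) -> Value:
    parsed = parse_constant(ev.value_string, ev.value_type)
    if isinstance(ev.value_type, ContinuousType):
        return RealValue(ev.value_type, (parsed,))
    if isinstance(ev.value_type, EnsembleType):
        return EnsembleValue(ev.value_type, parsed)
    return BooleanValue(parsed)


def _apply_bindings(bindings: Iterable[Binding], env: Environment,
                    config: EvalConfig) -> Environment:
    if not bindings:
        return env
    new: dict[Argument, object] = {}
    for b in bindings:
        if b.argument.is_function_valued:
            new[b.argument] = b.delegate
        else:
            new[b.argument] = evaluate(b.delegate, env, config)
    return env.extend(new)


def _apply_delegate(delegate: Evaluator, func_arg: Argument,
                    env: Environment, config: EvalConfig) -> Value:
    """Apply a delegate bound to a function-valued argument.

    The operands are the argument's declared dependencies, evaluated at the
    application site; they are matched positionally against the delegate's
    own signature.
    """
    operands = [evaluate(d, env, config) for d in func_arg.argument_dependencies]
    sig = delegate_signature(delegate)
    if len(sig) < len(operands):
        raise ArityError(f"delegate {delegate.name!r} takes {len(sig)} operands, "
                         f"{len(operands)} supplied for {func_arg.name!r}")
    assignments = dict(zip(sig, operands))
    return evaluate(delegate, env.extend(assignments), config)


def evaluate(evaluator: Evaluator, env: Optional[Environment] = None,
             config: EvalConfig = _DEFAULT_CONFIG) -> Value:
    """Evaluate a pipeline under an environment.

    Eager and depth-first; every unbound argument reachable from
    *evaluator* must be assigned in *env* (or satisfied by a binding along
    the path), otherwise a missing-argument error is raised.
    """
    env = env if env is not None else Environment()

    if isinstance(evaluator, Argument):
        if evaluator in env:
            val = env.get(evaluator)
            if isinstance(val, Evaluator):
                return _apply_delegate(val, evaluator, env, config)
            return val
        if evaluator.mesh_projection is not None:
            parent, selector = evaluator.mesh_projection
            if parent in env:
                mv = env.get(parent)
                if not isinstance(mv, MeshValue):
                    raise TypeError_(f"argument {parent.name!r} did not evaluate "
                                     f"to a mesh location")
                if selector == "elements":
                    return EnsembleValue(mv.mesh.element_ensemble, mv.element)
                return RealValue(mv.mesh.chart_type, mv.xi)
        raise MissingArgumentError(
            f"argument {evaluator.name!r} has no assignment in the environment")

    if isinstance(evaluator, Constant):
        return _wrap_constant(evaluator)

    if isinstance(evaluator, Parameter):
        view = getattr(evaluator, "_view", None)
        if view is None:
            view = ParameterView(evaluator)
            evaluator._view = view
        members = []
        for a in evaluator.index_arguments:
            v = evaluate(a, env, config)
            if not isinstance(v, EnsembleValue):
                raise TypeError_(f"parameter {evaluator.name!r}: index "
                                 f"{a.name!r} did not yield an ensemble member")
            members.append(v.member)
        raw = view.lookup(members)
        if isinstance(evaluator.value_type, EnsembleType):
            return EnsembleValue(evaluator.value_type, raw)
        return RealValue(evaluator.value_type, (raw,))

    if isinstance(evaluator, Piecewise):
        env2 = _apply_bindings(evaluator.bindings, env, config)
        idx = evaluate(evaluator.index, env2, config)
        if not isinstance(idx, EnsembleValue):
            raise TypeError_(f"piecewise {evaluator.name!r}: index did not "
                             f"yield an ensemble member")
        branch = evaluator.branches.get(idx.member, evaluator.default)
        if branch is None:
            raise BranchError(f"piecewise {evaluator.name!r}: no branch for "
                              f"member {idx.member} and no default")
        return evaluate(branch, env2, config)

    if isinstance(evaluator, Aggregate):
        env2 = _apply_bindings(evaluator.bindings, env, config)
        ens = evaluator.value_type.component_ensemble
        comps: list[float] = []
        for c in ens.sorted_members:
            delegate = evaluator.components.get(c, evaluator.default)
            if delegate is None:
                raise BranchError(f"aggregate {evaluator.name!r}: no evaluator "
                                  f"for component {c} and no default")
            env3 = env2.extend({evaluator.index_argument: EnsembleValue(ens, c)})
            v = evaluate(delegate, env3, config)
            if not isinstance(v, RealValue) or len(v.vector) != 1:
                raise TypeError_(f"aggregate {evaluator.name!r}: component {c} "
                                 f"did not yield a scalar")
            comps.append(v.vector[0])
        return RealValue(evaluator.value_type, tuple(comps))

    if isinstance(evaluator, Reference):
        env2 = _apply_bindings(evaluator.bindings, env, config)
        return evaluate(evaluator.target, env2, config)

    if isinstance(evaluator, External):
        impl = config.implementation_for(evaluator.name)
        if impl is None:
            raise UnimplementedExternalError(
                f"external evaluator {evaluator.name!r} has no registered "
                f"implementation")
        argvals = [evaluate(a, env, config) for a in evaluator.declared_arguments]
        return impl(evaluator, argvals, config)

    raise EvaluationError(f"cannot evaluate object {evaluator!r}")


def evaluate_with_binding(reference: Reference,
                          env: Optional[Environment] = None,
                          config: EvalConfig = _DEFAULT_CONFIG) -> Value:
    """Evaluate a reference evaluator, first checking its bindings.

    Equivalent to ``evaluate`` but verifies that every bound argument is an
    unbound upstream argument of the target (raising a binding error
    otherwise) before evaluating.
    """
    upstream = unbound_arguments(reference.target)
    for b in reference.bindings:
        if b.argument not in upstream:
            raise BindingError(
                f"reference {reference.name!r} binds {b.argument.name!r}, which "
                f"is not an unbound upstream argument of "
                f"{reference.target.name!r}")
    return evaluate(reference, env, config)


# ---------------------------------------------------------------------------
# Mesh fields
# ---------------------------------------------------------------------------

def _shape_allows(mesh: MeshType, element: int, xi: Sequence[float],
                  env: Environment, config: EvalConfig) -> bool:
    """Evaluate the element's shape predicate at xi.

    The predicate's unbound chart-typed argument (matching the mesh
    dimension) is assigned the coordinates; predicates are Boolean-valued.
    """
    pred = mesh.shape_map[element]
    assignments: dict[Argument, Value] = {}
    for a in unbound_arguments(pred):
        if (isinstance(a.value_type, ContinuousType)
                and a.value_type.dimension == mesh.dimension):
            assignments[a] = RealValue(a.value_type, tuple(xi))
    v = evaluate(pred, env.extend(assignments), config)
    if not isinstance(v, BooleanValue):
        raise TypeError_(f"shape predicate {pred.name!r} did not yield a Boolean")
    return v.value


def evaluate_mesh_field(field_evaluator: Evaluator,
                        mesh_argument: Argument,
                        element: int,
                        xi: Sequence[float],
                        env: Optional[Environment] = None,
                        config: EvalConfig = _DEFAULT_CONFIG) -> Value:
    """Evaluate a field at a mesh location (element member + chart coords).

    The mesh-location argument is assigned ``(element, xi)``; the element
    must belong to the mesh and, unless extrapolation is explicitly
    allowed, xi must satisfy the element's shape predicate.
    """
    mesh = mesh_argument.value_type
    if not isinstance(mesh, MeshType):
        raise TypeError_(f"argument {mesh_argument.name!r} is not mesh-typed")
    if element not in mesh.element_ensemble:
        raise MemberError(f"element {element} is not in mesh {mesh.name!r}")
    env = env if env is not None else Environment()
    if not config.allow_extrapolation:
        if not _shape_allows(mesh, element, xi, env, config):
            raise DomainError(
                f"chart coordinates {tuple(xi)} are outside the shape of "
                f"element {element} of mesh {mesh.name!r}")
    location = MeshValue(mesh, element, tuple(xi))
    return evaluate(field_evaluator, env.extend({mesh_argument: location}), config)
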