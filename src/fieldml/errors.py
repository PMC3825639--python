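"""Exception hierarchy.

Every error raised by this package derives from :class:`FieldmlError`, so
callers can catch one type at an API boundary.  Subclasses distinguish the
failure classes the data model defines: definition-time errors (malformed
types or evaluators), type errors (nominal incompatibility), data access
errors (shape, parse, bounds, missing sparse keys), serialization errors,
and evaluation errors (missing arguments, unmatched piecewise branches,
unimplemented externals, out-of-shape chart coordinates).
"""


class FieldmlError(Exception):
    """Base class for all errors raised by this package."""


class DefinitionError(FieldmlError):
    """An object was constructed in violation of its invariants."""


class TypeError_(FieldmlError):
    """Nominal type incompatibility (strong typing violation)."""


class BindingError(FieldmlError):
    """A binding names an argument that is not upstream, or mismatches."""


class DataError(FieldmlError):
    """Base for data resource / source access failures."""


class ShapeError(DataError):
    """Payload size inconsistent with the declared array shape."""


class ParseError(DataError):
    """Non-numeric token or malformed payload."""


class BoundsError(DataError):
    """Index or hyperslab outside the declared extents."""


class LookupError_(DataError):
    """Sparse parameter lookup miss: no value stored for the key."""


class SerializationError(FieldmlError):
    """Model cannot be serialized (dangling references etc.)."""


class DocumentError(FieldmlError):
    """Malformed or schema-invalid XML document."""


class ImportError_(FieldmlError):
    """Unresolvable href, missing remote name, or import cycle."""


class EvaluationError(FieldmlError):
    """Base for runtime evaluation failures."""


class MissingArgumentError(EvaluationError):
    """An unbound argument reachable from the evaluator has no value."""


class BranchError(EvaluationError):
    """Piecewise index value matches no branch and no default exists."""


class UnimplementedExternalError(EvaluationError):
    """External evaluator has no registered implementation."""


class DomainError(EvaluationError):
    """Chart coordinates outside the element shape (extrapolation)."""


class MemberError(EvaluationError):
    """A value is not a member of the expected ensemble."""


class ArityError(EvaluationError):
    """Wrong number of operands or parameters."""
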