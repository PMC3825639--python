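# Methods

## The data model

A *model* is a named region holding four kinds of object: domain types,
evaluators, data resources and import records.  Fields — functions from a
domain, typically a finite-element mesh, to a value space — are expressed
declaratively as acyclic pipelines of *evaluators* rather than as code, so
a document fully describes both the structure of a model and how to compute
its field values.

**Domain types.**  Four kinds:

- *Ensembles* are finite discrete sets whose members carry unique
  non-negative integer identifiers (node numbers, element numbers,
  component indexes).  Member identifiers are stored exactly as declared
  and are never renumbered; an ascending order is imposed only where
  serialization or dense-array ranking needs one.  Empty ensembles are
  rejected: every index range must address at least one entry, and a
  zero-length serialized range has no meaningful layout.
- The *Boolean* type has exactly the two values True and False.  There are
  no Boolean operators; the type exists solely as the value type of
  element shape predicates.
- *Continuous* types are n-dimensional real domains.  For n > 1 an
  ensemble with members 1..n indexes the vector components.
- *Mesh* types combine an element ensemble with a chart (local coordinate)
  type of the mesh dimension; all elements share that dimension, and each
  element carries a Boolean-valued *shape predicate*, true on the closed
  reference shape and false outside it.

**Strong typing is nominal.**  Two ensembles with identical member sets
but separate declarations are incompatible; compatibility of any two types
is identity of the resolved type objects.  Composition of evaluators is
legal only when the value type of the inner pipeline *is* the unbound
argument type of the outer one; joining same-membered but distinct
ensembles requires an explicit converter evaluator mapping one onto the
other.  Because imported objects are the identical objects of their source
region (see Serialization), imports never break compatibility.

**Evaluators.**  Seven kinds: *argument* (a named input; function-valued
arguments additionally declare the arguments they are applied to),
*constant* (a scalar held as text), *parameter* (lookup of stored data
over ensemble indexes), *piecewise* (branch on an ensemble-valued index —
the usual final step of a mesh field, where the index is the element
member), *aggregate* (assemble a vector component by component, in
ascending component-member order), *reference* (alias another evaluator,
optionally with bindings) and *external* (declared semantics by
convention; see the standard library).  Every evaluator has a value type,
and the reference graph must be acyclic — recursive evaluators are
undefined in this data model.

**Binding** associates an upstream argument of a pipeline with a delegate
evaluator and is semantically a term substitution.  Our engine uses
lexical scoping: a binding applies to every occurrence of the argument in
the target subtree and shadows any enclosing assignment of the same name;
plain delegates are evaluated eagerly in the enclosing scope, while
delegates bound to function-valued arguments are applied at the original
application site, matching the delegate's positional signature (arity and
per-position types are checked).  The test suite verifies the semantics
against an independent inlining oracle: substituting the delegate
textually into a copy of the pipeline and evaluating plainly must give the
same value, over a seeded corpus of 200 random pipelines (capture-free by
construction — the corpus never re-binds a name that is free in a
delegate, which is the one case where lexical and substitution semantics
diverge).

## Evaluation

Evaluation is eager, depth-first and pure: identical (evaluator,
environment) pairs give identical values, and there is no result caching
(memoization would be an internal optimization that must not change
results).  Reals are IEEE doubles; constants parse with standard decimal
semantics; numeric test comparisons use absolute tolerance 1e-12 unless a
property states otherwise.

Mesh fields are evaluated at a location (element member, chart
coordinates).  The element's shape predicate is checked first; coordinates
outside the closed reference shape raise a domain error unless
extrapolation is explicitly enabled — silent extrapolation hides
connectivity bugs, so it is opt-in (`EvalConfig(allow_extrapolation=True)`
or `--allow-extrapolation` on the CLI).

A mesh-typed argument implicitly provides accessors for the element member
and the chart coordinates.  We expose them as explicit argument evaluators
named `<argument>.elements` and `<argument>.xi`; the naming convention is
this package's, chosen so the accessors survive serialization and
reconnect by name on parse.

The spec-level question of whether piecewise evaluators carry a default
branch in documents is resolved here by supporting a `default` attribute
in both the object model and the XML grammar; a piecewise with neither a
matching branch nor a default raises a branch error.

## Heavy data

A *data resource* is raw bulk data — an inline string, an external
whitespace-delimited text file, or an HDF5 file; a *data source* marks up
a dense array of zero or more dimensions inside it (text: first record and
record count, one record per line; HDF5: dataset path and optional
hyperslab origin).  Text arrays are row-major with the last declared index
varying fastest, so a connectivity matrix reads as one row per element;
rendering uses `%.17g` with single spaces, making a write/read round trip
exact for doubles.  HDF5 datasets are written as native 64-bit floats or
ints, one dataset per source, with object-creation timestamps disabled so
equal data produces byte-identical files.

Parameter evaluators use one of two layouts.  *Dense*: one array whose
axes match the index ensembles; a member's position along an axis is its
rank in the ascending member order, so ensembles need not be contiguous.
*Sparse*: two aligned sources — key tuples (one column per sparse index,
rows unique) and values, with optional trailing dense axes for remaining
indexes.  A missing sparse key is a lookup error, never an implicit zero:
no default-fill semantics are defined, and silently manufacturing zeros
would mask incomplete data.  Sparse keys must be the leading indexes;
interleaving dense before sparse indexes is not representable in this
implementation.

## Serialization

One region per document, UTF-8, version attribute `0.5`.  The writer is
deterministic (equal models produce byte-identical documents) and emits
objects grouped by kind — imports, types, data resources, evaluators —
each group in declaration order; ensembles serialize as contiguous ranges
where possible, else as ascending member lists.  The parser is
worklist-based, so declaration order inside a document does not matter;
references that never resolve produce a document error naming the
offending objects.  Two modes: strict rejects unknown XML elements,
lenient (the default, for forward compatibility) skips them with a
warning.  Unknown external evaluators are retained with their declared
value types through parse and re-write, and fail only if evaluated.

The exact element and attribute spellings of this grammar
(`EnsembleType`/`Members`/`MemberRange`, `ArgumentEvaluator`,
`PiecewiseEvaluator`/`EvaluatorMap`, `DataResource`/`ArrayDataSource`,
`Import`/`ImportType`/`ImportEvaluator`, …) are fixed by this package and
documented by the writer in `fieldml/xmlio.py`; they follow the naming
style of the format family they implement but are authoritative only for
this implementation.

Imports use simple Xlink hrefs.  Relative hrefs resolve against the
importing document's location; the locator parses each document once and
caches it, so every import of a given href yields the *same* objects —
this is what makes nominal typing survive modularisation.  Import cycles
(including self-import) are detected and rejected.  The standard library
resolves from the in-process copy under its canonical hrefs; nothing is
ever fetched from the network.

## The standard library

The library is an ordinary region declaring: continuous chart types and
Cartesian coordinate types for 1–3 dimensions with their component
ensembles; local-node ensembles per basis; external evaluators for the
interpolators — linear/bilinear/trilinear Lagrange, quadratic Lagrange
tensor products (1D/2D/3D), and linear simplex bases on the triangle and
tetrahedron — and Boolean shape externals for the unit line, square, cube,
triangle and tetrahedron; and argument evaluators for all of these.  Every
declared external has a registered closed-form implementation, so library
names never hit the unknown-external error.

Numerical conventions:

- Local-node ordering: chart axis 1 varies fastest, then axis 2, then
  axis 3, node 1 at the origin — the bilinear nodes 1..4 sit at (0,0),
  (1,0), (0,1), (1,1).
- Quadratic bases use equally spaced nodes on [0,1]; simplex bases are
  barycentric-linear.
- Shape predicates use exact closed inequalities (no tolerance): the
  boundary belongs to the shape.
- Each Lagrange family satisfies the partition of unity (checked to
  1e-12 over 1000 interior samples per basis) and reproduces polynomials
  up to its degree (to 1e-10).

A mesh may either own a fresh implicit chart type or reference an existing
one.  Passing the library's chart type at mesh definition is the intended
pattern whenever library interpolators are used, because binding the
interpolator's chart argument to the mesh's xi accessor must type-check
nominally.

## Fixtures and generators

`build_illustrative_example` constructs the canonical worked model: two
unit-square elements sharing an edge, six global nodes, connectivity rows
[1,2,4,5] and [2,3,5,6] (local order = the bilinear node order).  The
pressure DOFs (0.1, 55.2, 22.7, 10.1, 88.2, 5.5) and the flat z=0 geometry
are the generator's fixed choice of test data; the accompanying manifest
records counts, DOF tables and spot values computed directly from the
arrays, so tests compare the engine against an independent record.  The
multi-subject generator emulates cohort anatomy storage — one HDF5 dataset
of shape (subjects × nodes × 3) with per-subject fields selecting their
slice through a subject ensemble — at toy scale (defaults in the tests:
5 subjects, 4 nodes); coordinates are synthetic uniform draws, standing in
for real anatomical surfaces in structure only.

What the synthetic corpora do **not** model: degenerate or inverted
elements, meshes with mixed element shapes, very large heavy-data volumes,
and documents produced by other software with different naming
conventions.  Passing tests therefore demonstrate the correctness of the
data model, engine and round-trip machinery, not interoperability with any
external corpus.

VTK export tessellates each element on a regular chart grid and does not
merge coincident points across elements — per-element tessellation avoids
tolerance-based merge decisions; viewers handle the duplicated boundary
points correctly.

## Problem sizes

All checks run at desk scale: the round-trip corpus uses 100 random
regions of depth ≤ 4, the binding oracle 200 random pipelines, basis
properties 1000 points per interpolator, and the fixture checks a
2-element mesh.  The whole suite completes in seconds on one CPU.

## Known limitations

- No implicit fields, PDEs, differentiation, subsetting of domains, or
  topological/differential structure.
- No Boolean operators; Booleans exist only for shape predicates.
- Curvilinear coordinate support is declaration-level only (types can be
  declared; no conversion is performed).
- No Hermite/cubic bases; no algebraic (MathML-style) basis definitions.
- No parallel/MPI HDF5 I/O and no compression tuning.
- Readers for precursor mesh formats are out of scope.
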