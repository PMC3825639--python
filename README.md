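# fieldml

A Python library for declaratively representing and numerically evaluating
mathematical fields over domains — above all finite-element meshes — in
the FieldML 0.5 data model, for researchers exchanging anatomical and
physiological field models between simulation and visualisation tools.

A field f : Ω → V is not stored as code but as a pipeline of composable
*evaluators* over strongly typed domains.  A typical FEM field factors as

    f(e, ξ) = Σᵢ φᵢ(ξ) · d(c(e, i))

where e is the element member, ξ the chart (local) coordinate, φᵢ the
interpolation basis (e.g. bilinear Lagrange), c(e, i) the local-to-global
node map and d the nodal degrees of freedom.  Each factor is one evaluator
— piecewise over elements, an external interpolator, a parameter lookup —
and *binding* (term substitution) wires arguments to delegates, so the
same template yields a pressure field or a geometry field depending only
on which DOF parameters are bound into it.

The package provides:

- the typed object model (ensembles, Boolean, continuous and mesh types;
  the seven evaluator kinds; nominal type compatibility and validation),
- XML (de)serialization with deterministic output and cross-document
  imports via Xlink hrefs,
- heavy-data access through data resources/sources: inline text, text
  files and HDF5, with dense and sparse parameter layouts,
- the standard library of interpolators (linear/quadratic Lagrange tensor
  products, linear simplexes) and element shape predicates, each with an
  executable implementation,
- an evaluation engine making every declared field executable, and
- a toolkit: worked-model generators, VTK legacy export, and a small CLI
  (`fieldml validate | info | eval | export-vtk | make-example`).

## Worked example

```python
from fieldml import build_illustrative_example, evaluate_mesh_field

ex = build_illustrative_example()          # 2 elements, 6 nodes, 2 fields
v = evaluate_mesh_field(ex.pressure_field, ex.mesh_argument, 1, (0.0, 0.0))
print(v.scalar)                            # 0.1  -> the node-1 DOF exactly
v = evaluate_mesh_field(ex.pressure_field, ex.mesh_argument, 1, (0.5, 0.5))
print(v.scalar)                            # 38.400000000000006 -> mean of 4 DOFs
g = evaluate_mesh_field(ex.geometry_field, ex.mesh_argument, 2, (0.5, 0.5))
print(g.vector)                            # (1.5, 0.5, 0.0)
```

At an element corner bilinear interpolation reproduces the corresponding
nodal value exactly (the Lagrange delta property); at the element center
it returns the arithmetic mean of the element's four DOFs; the geometry
field aggregates x, y, z into a 3-vector.  `examples/` contains one short
narrative script per capability (fields, binding, XML round trips, heavy
data, VTK export); each prints the numbers it computes and what they mean.

Binding in isolation:

```python
from fieldml import build_binding_demo, evaluate_with_binding
from fieldml.evaluate import Environment, EnsembleValue

demo = build_binding_demo()   # g(n) = {7.1 | 100 | x}; f = g with x := 0.331
env = Environment({demo.n_argument:
                   EnsembleValue(demo.n_argument.value_type, 3)})
print(evaluate_with_binding(demo.f, env).scalar)   # 0.331
```

## Layout

```
src/fieldml/        model, data, evaluate, library, xmlio, toolkit, cli
tests/              pytest suite (unit, property and acceptance tests)
examples/           narrative scripts, one per capability
docs/methods.md     the model, conventions, design choices, limitations
scripts/acceptance.py
```
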