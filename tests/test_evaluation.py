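"""The evaluation engine: per-kind semantics, binding, mesh fields."""
import math

import numpy as np
import pytest

from fieldml import (Aggregate, Binding, Constant, Model, Piecewise,
                     Reference, build_binding_demo, build_constant_vector_demo,
                     build_function_binding_demo, build_node_coordinates_demo,
                     evaluate, evaluate_mesh_field, evaluate_with_binding,
                     random_pipeline, substitute)
from fieldml.errors import (BindingError, BranchError, DomainError,
                            MemberError, MissingArgumentError,
                            UnimplementedExternalError)
from fieldml.evaluate import (Environment, EnsembleValue, EvalConfig,
                              RealValue)
from fieldml.model import Argument, External


def _env_n(demo, member):
    ens = demo.n_argument.value_type
    return Environment({demo.n_argument: EnsembleValue(ens, member)})


class TestWorkedExamples:
    def test_piecewise_branches(self, real):
        demo = build_binding_demo()
        x0 = Environment({demo.n_argument: EnsembleValue(
            demo.n_argument.value_type, 2),
            demo.x_argument: RealValue(real, (0.0,))})
        assert evaluate(demo.g, x0).scalar == 100.0
        x1 = Environment({demo.n_argument: EnsembleValue(
            demo.n_argument.value_type, 1),
            demo.x_argument: RealValue(real, (0.0,))})
        assert evaluate(demo.g, x1).scalar == 7.1

    def test_binding_a_constant_for_x(self):
        demo = build_binding_demo()
        assert evaluate_with_binding(demo.f, _env_n(demo, 3)).scalar == 0.331

    def test_binding_shadows_environment_assignment(self, real):
        demo = build_binding_demo()
        env = _env_n(demo, 3).extend(
            {demo.x_argument: RealValue(real, (42.0,))})
        assert evaluate(demo.f, env).scalar == 0.331   # binding wins
        assert evaluate(demo.g, env).scalar == 42.0    # unbound g sees env

    def test_function_valued_binding_applies_at_site(self):
        demo = build_function_binding_demo()
        assert evaluate(demo.f, _env_n(demo, 3)).scalar == 29.0
        assert evaluate(demo.f, _env_n(demo, 1)).scalar == 7.1

    def test_constant_real_parses(self, real):
        assert evaluate(Constant("c", real, "1059.87")).scalar == 1059.87

    def test_aggregate_constant_vector(self):
        _, agg = build_constant_vector_demo()
        v = evaluate(agg)
        assert v.vector == (0.5, -1.0, 20.1)
        assert v.vector[2] == 20.1

    def test_parameter_node_coordinates(self):
        m, p, node_arg, comp_arg = build_node_coordinates_demo()
        nodes, comps = node_arg.value_type, comp_arg.value_type

        def coord(n, c):
            env = Environment({node_arg: EnsembleValue(nodes, n),
                               comp_arg: EnsembleValue(comps, c)})
            return evaluate(p, env).scalar

        assert (coord(2, 1), coord(2, 2)) == (1.0, 0.0)
        assert (coord(1, 1), coord(1, 2)) == (0.0, 0.0)

    def test_identity_pipeline(self, real):
        x = Argument("x", real)
        env = Environment({x: RealValue(real, (math.pi,))})
        assert evaluate(x, env).scalar == math.pi


class TestErrors:
    def test_missing_argument(self):
        demo = build_binding_demo()
        with pytest.raises(MissingArgumentError):
            evaluate(demo.f, Environment())

    def test_piecewise_without_branch_or_default(self, real):
        m = Model("t")
        m.add_type(real, "real.1d")
        B = m.define_ensemble("B", [1, 2])
        n = m.argument("n", B)
        p = Piecewise("p", real, n, {1: Constant("c", real, "1")})
        with pytest.raises(BranchError):
            evaluate(p, Environment({n: EnsembleValue(B, 2)}))

    def test_default_branch_catches_unmatched_member(self, real):
        m = Model("t")
        B = m.define_ensemble("B", [1, 2])
        n = m.argument("n", B)
        p = Piecewise("p", real, n, {1: Constant("c", real, "1")},
                      default=Constant("d", real, "-1"))
        assert evaluate(p, Environment({n: EnsembleValue(B, 2)})).scalar == -1.0

    def test_unknown_external_fails_only_at_evaluation(self, real):
        ext = External("vendor.custom.thing", real)
        with pytest.raises(UnimplementedExternalError):
            evaluate(ext)

    def test_binding_nonupstream_argument_is_binding_error(self, real):
        m = Model("t")
        m.add_type(real, "real.1d")
        x = m.argument("x", real)
        stranger = m.argument("stranger", real)
        k = m.constant("k", real, "1")
        ref = Reference("r", x, [Binding(stranger, k)])
        with pytest.raises(BindingError):
            evaluate_with_binding(ref, Environment({x: RealValue(real, (2.0,))}))


class TestBindingSubstitutionEquivalence:
    def test_matches_inlining_oracle_on_random_pipelines(self):
        """Binding then evaluating equals textual substitution then plain
        evaluation, over a seeded corpus of random pipelines."""
        for seed in range(200):
            rp = random_pipeline(seed)
            bound = evaluate(rp.root, rp.env).scalar
            inlined = substitute(rp.root.target, {rp.argument: rp.delegate})
            plain = evaluate(inlined, rp.env).scalar
            assert bound == pytest.approx(plain, abs=1e-12), seed


class TestPurity:
    def test_identical_inputs_identical_values(self):
        demo = build_binding_demo()
        env = _env_n(demo, 3)
        assert evaluate(demo.f, env) == evaluate(demo.f, env)


class TestMeshFields:
    def test_corner_dof_reproduction(self, example):
        conn = example.manifest.connectivity
        dofs = example.manifest.pressure_dofs
        corners = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)]
        for e in (1, 2):
            for local, xi in enumerate(corners):
                node = conn[e - 1][local]
                got = evaluate_mesh_field(example.pressure_field,
                                          example.mesh_argument, e, xi)
                assert got.scalar == pytest.approx(dofs[node - 1], abs=1e-12)

    def test_element_center_is_mean_of_dofs(self, example):
        for e in (1, 2):
            got = evaluate_mesh_field(example.pressure_field,
                                      example.mesh_argument, e, (0.5, 0.5))
            assert got.scalar == pytest.approx(
                example.manifest.element_center_pressure[e], abs=1e-12)

    def test_geometry_field_is_three_dimensional(self, example):
        v = evaluate_mesh_field(example.geometry_field,
                                example.mesh_argument, 2, (0.5, 0.5))
        assert len(v.vector) == 3
        assert v.vector == pytest.approx((1.5, 0.5, 0.0))

    def test_cross_edge_continuity(self, example):
        """The shared edge between the elements (xi1=1 on element 1, xi1=0
        on element 2) must agree — this exercises the local-to-global node
        map."""
        for t in np.linspace(0.0, 1.0, 11):
            a = evaluate_mesh_field(example.pressure_field,
                                    example.mesh_argument, 1, (1.0, t)).scalar
            b = evaluate_mesh_field(example.pressure_field,
                                    example.mesh_argument, 2, (0.0, t)).scalar
            assert abs(a - b) < 1e-12

    def test_piecewise_totality_over_elements(self, example):
        template = example.model.evaluators["template.evaluator"]
        mesh = example.mesh_argument.value_type
        for e in mesh.element_ensemble.members:
            assert e in template.branches or template.default is not None

    def test_outside_shape_is_domain_error(self, example):
        with pytest.raises(DomainError):
            evaluate_mesh_field(example.pressure_field,
                                example.mesh_argument, 1, (1.5, 0.5))
        v = evaluate_mesh_field(example.pressure_field, example.mesh_argument,
                                1, (1.5, 0.5),
                                config=EvalConfig(allow_extrapolation=True))
        assert isinstance(v.scalar, float)

    def test_nonexistent_element_is_member_error(self, example):
        with pytest.raises(MemberError):
            evaluate_mesh_field(example.pressure_field,
                                example.mesh_argument, 7, (0.5, 0.5))
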