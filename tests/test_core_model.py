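"""Object model: ensembles, meshes, nominal typing, composition, validation."""
import random

import pytest

from fieldml import (Aggregate, Binding, Constant, EnsembleType, Model,
                     Piecewise, Reference, compose_check, define_ensemble,
                     define_mesh, type_compatible, unbound_arguments,
                     validate_model)
from fieldml.errors import DefinitionError, TypeError_
from fieldml.model import Argument, BooleanType, ContinuousType, External


class TestEnsembles:
    def test_exact_member_set_is_kept(self):
        ens = define_ensemble("A", [4, 37, 60, 1002])
        assert ens.cardinality == 4
        assert max(ens.members) == 1002
        assert ens.sorted_members == (4, 37, 60, 1002)

    def test_member_identifiers_are_not_renumbered(self):
        ens = define_ensemble("E", [9, 2, 5])
        assert ens.members == (9, 2, 5)          # as given
        assert ens.sorted_members == (2, 5, 9)   # ascending for serialization

    @pytest.mark.parametrize("members", [[], [1, 1], [-1], [1.5]])
    def test_invalid_member_sets_rejected(self, members):
        with pytest.raises(DefinitionError):
            define_ensemble("E", members)

    def test_rank_is_ascending_position(self):
        ens = define_ensemble("E", [10, 3, 7])
        assert [ens.rank(m) for m in (3, 7, 10)] == [0, 1, 2]


class TestNominalTyping:
    def test_equal_members_distinct_declarations_incompatible(self):
        B = define_ensemble("B", [1, 2, 3])
        C = define_ensemble("C", [1, 2, 3])
        assert not type_compatible(B, C)
        assert type_compatible(B, B)

    def test_structurally_identical_continuous_types_incompatible(self, lib):
        local = ContinuousType("my.3d", 3)
        assert not type_compatible(lib.types["coordinates.rc.3d"], local)
        assert type_compatible(lib.types["coordinates.rc.3d"],
                               lib.types["coordinates.rc.3d"])


def _map_evaluator(name, domain, codomain, model):
    """An evaluator domain -> codomain with one unbound argument."""
    arg = model.argument(f"{name}.arg", domain)
    if isinstance(codomain, EnsembleType):
        out = model.constant(f"{name}.out", codomain,
                             str(codomain.sorted_members[0]))
    else:
        out = model.constant(f"{name}.out", codomain, "0")
    return model.add_evaluator(
        Piecewise(name, codomain, arg,
                  {m: out for m in domain.members})), arg


class TestComposition:
    def test_mismatched_ensembles_reject(self):
        m = Model("t")
        A = m.define_ensemble("A", [1, 2])
        B = m.define_ensemble("B", [1, 2])
        C = m.define_ensemble("C", [1, 2])
        D = m.define_ensemble("D", [1, 2])
        f, _ = _map_evaluator("f", A, B, m)
        g, _ = _map_evaluator("g", C, D, m)
        verdict = compose_check(g, f)
        assert not verdict.ok
        assert verdict.expected is C and verdict.actual is B
        assert "C" in verdict.message and "B" in verdict.message

    def test_via_converter_accepts(self):
        m = Model("t")
        A = m.define_ensemble("A", [1, 2])
        B = m.define_ensemble("B", [1, 2, 3])
        C = m.define_ensemble("C", [1, 2, 3])
        D = m.define_ensemble("D", [1, 2])
        f, _ = _map_evaluator("f", A, B, m)
        g, _ = _map_evaluator("g", C, D, m)
        # converter h: B -> C maps identifiers one to one
        h_arg = m.argument("h.arg", B)
        h = m.add_evaluator(Piecewise(
            "h", C, h_arg,
            {i: m.constant(f"h.{i}", C, str(i)) for i in B.members}))
        assert not compose_check(g, f).ok
        assert compose_check(g, h).ok
        assert compose_check(h, f).ok

    def test_identity_composes_with_itself(self):
        m = Model("t")
        B = m.define_ensemble("B", [1, 2, 3])
        ident = m.argument("id", B)
        assert compose_check(ident, ident).ok

    def test_agrees_with_edge_inlining_oracle(self):
        """Brute-force oracle: inline the two pipelines and type-check the
        single connecting edge; compose_check must agree on seeded random
        pipelines."""
        rng = random.Random(42)
        for trial in range(50):
            m = Model(f"t{trial}")
            types = [m.define_ensemble(f"E{i}", [1, 2, 3]) for i in range(4)]
            dom_f, cod_f = rng.choice(types), rng.choice(types)
            dom_g, cod_g = rng.choice(types), rng.choice(types)
            f, f_arg = _map_evaluator("f", dom_f, cod_f, m)
            g, g_arg = _map_evaluator("g", dom_g, cod_g, m)
            # oracle: the edge f.value -> g.arg must connect identical types
            oracle_ok = cod_f is dom_g
            assert compose_check(g, f).ok == oracle_ok


class TestMesh:
    def _unit_square(self, model):
        boolean = model.define_boolean("boolean")
        chart = model.define_continuous("chart2", 2)
        arg = model.argument("chart2.argument", chart)
        return model.add_evaluator(External("unit.square", boolean, (arg,)))

    def test_two_element_mesh(self):
        m = Model("t")
        pred = self._unit_square(m)
        mesh = m.define_mesh("mesh", 2, [1, 2], pred)
        assert mesh.dimension == 2
        assert mesh.element_ensemble.cardinality == 2
        assert mesh.chart_type.dimension == 2
        assert mesh.shape_map[1] is pred and mesh.shape_map[2] is pred

    def test_minimal_1d_mesh(self):
        m = Model("t")
        boolean = m.define_boolean("boolean")
        chart = m.define_continuous("chart1", 1)
        arg = m.argument("chart1.argument", chart)
        pred = m.add_evaluator(External("unit.line", boolean, (arg,)))
        mesh = m.define_mesh("m1", 1, [1], pred)
        assert mesh.element_ensemble.members == (1,)

    def test_non_boolean_shape_is_type_error(self, real):
        m = Model("t")
        scalar = Constant("notashape", real, "1.0")
        with pytest.raises(TypeError_):
            define_mesh("bad", 2, [1], scalar)

    def test_zero_dimension_and_missing_shape_rejected(self):
        m = Model("t")
        pred = self._unit_square(m)
        with pytest.raises(DefinitionError):
            define_mesh("bad", 0, [1], pred)
        with pytest.raises(DefinitionError):
            define_mesh("bad", 2, [1, 2], {1: pred})


class TestValidate:
    def test_clean_fixture_has_no_diagnostics(self, example):
        assert validate_model(example.model) == []

    def test_reference_cycle_is_reported(self, real):
        m = Model("t")
        m.add_type(real, "real.1d")
        m.imported_names.add("real.1d")
        c = m.constant("c", real, "1")
        a = m.add_evaluator(Reference("a", c))
        b = m.add_evaluator(Reference("b", a))
        a.target = b  # mutate into a cycle
        diags = validate_model(m)
        assert any(d.rule == "acyclicity" for d in diags)

    def test_branch_type_mismatch_reported(self, real):
        m = Model("t")
        m.add_type(real, "real.1d")
        m.imported_names.add("real.1d")
        B = m.define_ensemble("B", [1, 2])
        n = m.argument("n", B)
        wrong = m.constant("wrong", B, "1")
        m.add_evaluator(Piecewise("p", real, n, {1: wrong}))
        diags = validate_model(m)
        assert any(d.rule == "branch-type" and d.object_name == "p"
                   for d in diags)

    def test_idempotent_and_order_independent(self, example):
        first = validate_model(example.model)
        second = validate_model(example.model)
        assert first == second
        # re-registering objects in a different order gives the same verdict
        m = example.model
        reordered = Model(m.region_name)
        reordered.imported_names = set(m.imported_names)
        for name in sorted(m.types, reverse=True):
            reordered.types[name] = m.types[name]
        for name in sorted(m.evaluators, reverse=True):
            reordered.evaluators[name] = m.evaluators[name]
        reordered.data_resources = dict(m.data_resources)
        assert validate_model(reordered) == first


class TestUnboundArguments:
    def test_binding_shadows_argument(self, real):
        m = Model("t")
        m.add_type(real, "real.1d")
        m.imported_names.add("real.1d")
        x = m.argument("x", real)
        k = m.constant("k", real, "2.0")
        bound = m.add_evaluator(Reference("bound", x, [Binding(x, k)]))
        assert unbound_arguments(x) == [x]
        assert unbound_arguments(bound) == []

    def test_function_argument_reports_itself_not_operands(self, real):
        m = Model("t")
        m.add_type(real, "real.1d")
        m.imported_names.add("real.1d")
        w = m.argument("w", real)
        h = m.add_evaluator(Argument("h", real, argument_dependencies=(w,)))
        applied = m.add_evaluator(Reference(
            "applied", h, [Binding(w, m.constant("c", real, "29"))]))
        assert unbound_arguments(applied) == [h]
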