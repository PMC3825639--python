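"""XML round trips, determinism, imports and parse modes."""
import numpy as np
import pytest

from fieldml import (DocumentLocator, Model, load_library, models_isomorphic,
                     parse_model, random_model, resolve_imports,
                     type_compatible, write_model)
from fieldml.errors import DocumentError, ImportError_
from fieldml.evaluate import Environment, EnsembleValue, evaluate
from fieldml.library import LIBRARY_HREFS
from fieldml.model import External, ImportRecord
from fieldml.xmlio import parse_file


class TestRoundTrip:
    def test_example_fixture(self, example):
        doc = write_model(example.model)
        again = parse_model(doc, locator=DocumentLocator())
        assert again.diagnostics == []
        assert models_isomorphic(example.model, again)

    def test_library_document(self, lib):
        doc = write_model(lib)
        again = parse_model(doc)
        assert models_isomorphic(lib, again)

    def test_random_models(self):
        for seed in range(100):
            m = random_model(seed)
            again = parse_model(write_model(m))
            assert models_isomorphic(m, again), seed

    def test_double_round_trip_is_byte_stable(self, example):
        doc1 = write_model(example.model)
        doc2 = write_model(parse_model(doc1, locator=DocumentLocator()))
        assert doc1 == doc2

    def test_writer_is_deterministic(self, example):
        assert write_model(example.model) == write_model(example.model)

    def test_empty_region_is_minimal_document(self):
        doc = write_model(Model("empty"))
        m = parse_model(doc)
        assert (m.region_name, m.types, m.evaluators) == ("empty", {}, {})

    def test_inline_payload_embedded_verbatim(self, example):
        doc = write_model(example.model)
        res = example.model.data_resources["pressure.resource"]
        assert res.inline_text.encode() in doc

    def test_evaluations_preserved(self, example):
        """50 seeded (element, xi) points evaluate identically after a
        round trip through the document form."""
        from fieldml.evaluate import evaluate_mesh_field
        rng = np.random.default_rng(123)
        again = parse_model(write_model(example.model),
                            locator=DocumentLocator())
        p2 = again.evaluators["pressure.field"]
        ma2 = again.evaluators["mesh.argument"]
        for _ in range(50):
            e = int(rng.integers(1, 3))
            xi = tuple(rng.uniform(0, 1, size=2))
            before = evaluate_mesh_field(example.pressure_field,
                                         example.mesh_argument, e, xi).scalar
            after = evaluate_mesh_field(p2, ma2, e, xi).scalar
            assert before == after


class TestParsing:
    def test_malformed_xml(self):
        with pytest.raises(DocumentError, match="malformed"):
            parse_model(b"<Fieldml><unclosed>")

    def test_unknown_element_lenient_vs_strict(self):
        doc = (b'<Fieldml version="0.5" '
               b'xmlns="http://www.fieldml.org/standard/FieldML_0.5">'
               b'<Region name="r"><FancyNewThing/></Region></Fieldml>')
        m = parse_model(doc)
        assert m.parse_warnings and "FancyNewThing" in m.parse_warnings[0]
        with pytest.raises(DocumentError, match="FancyNewThing"):
            parse_model(doc, strict=True)

    def test_unknown_external_survives_round_trip(self, real):
        m = Model("r")
        m.add_type(real, "real.1d")
        m.imported_names.add("real.1d")
        m.imports.append(ImportRecord(LIBRARY_HREFS[0], "type",
                                      "real.1d", "real.1d"))
        m.add_evaluator(External("vendor.secret.sauce", real))
        again = parse_model(write_model(m), locator=DocumentLocator())
        ext = again.evaluators["vendor.secret.sauce"]
        assert isinstance(ext, External)
        assert type_compatible(ext.value_type, real)

    def test_declaration_order_does_not_matter(self, real):
        # the reference appears before its target in the document
        doc = (b'<?xml version="1.0"?>'
               b'<Fieldml version="0.5" '
               b'xmlns="http://www.fieldml.org/standard/FieldML_0.5">'
               b'<Region name="r">'
               b'<ReferenceEvaluator name="alias" evaluator="c"/>'
               b'<ContinuousType name="real"/>'
               b'<ConstantEvaluator name="c" valueType="real" value="3.5"/>'
               b'</Region></Fieldml>')
        m = parse_model(doc)
        assert evaluate(m.evaluators["alias"]).scalar == 3.5

    def test_unresolvable_reference_reports_names(self):
        doc = (b'<Fieldml version="0.5" '
               b'xmlns="http://www.fieldml.org/standard/FieldML_0.5">'
               b'<Region name="r">'
               b'<ReferenceEvaluator name="alias" evaluator="ghost"/>'
               b'</Region></Fieldml>')
        with pytest.raises(DocumentError, match="alias"):
            parse_model(doc)


def _tiny_region(name, import_href=None, ensemble=("E", "1", "3")):
    imports = ""
    if import_href:
        imports = (f'<Import xmlns:xlink="http://www.w3.org/1999/xlink" '
                   f'xlink:href="{import_href}">'
                   f'<ImportType localName="other.E" remoteName="E"/></Import>')
    ens_name, lo, hi = ensemble
    return (f'<?xml version="1.0"?>'
            f'<Fieldml version="0.5" '
            f'xmlns="http://www.fieldml.org/standard/FieldML_0.5">'
            f'<Region name="{name}">{imports}'
            f'<EnsembleType name="{ens_name}"><Members>'
            f'<MemberRange min="{lo}" max="{hi}"/></Members></EnsembleType>'
            f'</Region></Fieldml>').encode()


class TestImports:
    def test_library_type_resolves_to_the_library_object(self):
        doc = (b'<?xml version="1.0"?>'
               b'<Fieldml version="0.5" '
               b'xmlns="http://www.fieldml.org/standard/FieldML_0.5" '
               b'xmlns:xlink="http://www.w3.org/1999/xlink">'
               b'<Region name="r">'
               b'<Import xlink:href="FieldML_Library_0.5.xml">'
               b'<ImportType localName="coords" '
               b'remoteName="coordinates.rc.3d"/>'
               b'</Import></Region></Fieldml>')
        m = parse_model(doc, locator=DocumentLocator())
        lib = load_library()
        assert m.types["coords"] is lib.types["coordinates.rc.3d"]
        assert type_compatible(m.types["coords"],
                               lib.types["coordinates.rc.3d"])

    def test_same_membered_imported_ensembles_stay_incompatible(self):
        docs = {
            "a.xml": _tiny_region("a"),
            "b.xml": _tiny_region("b"),
            "main.xml": (
                b'<?xml version="1.0"?>'
                b'<Fieldml version="0.5" '
                b'xmlns="http://www.fieldml.org/standard/FieldML_0.5" '
                b'xmlns:xlink="http://www.w3.org/1999/xlink">'
                b'<Region name="main">'
                b'<Import xlink:href="a.xml">'
                b'<ImportType localName="EA" remoteName="E"/></Import>'
                b'<Import xlink:href="b.xml">'
                b'<ImportType localName="EB" remoteName="E"/></Import>'
                b'</Region></Fieldml>'),
        }
        loc = DocumentLocator(documents=docs)
        m = loc.resolve_model("main.xml")
        assert m.types["EA"].sorted_members == m.types["EB"].sorted_members
        assert not type_compatible(m.types["EA"], m.types["EB"])

    def test_two_imports_of_one_document_share_objects(self):
        docs = {"a.xml": _tiny_region("a")}
        loc = DocumentLocator(documents=docs)
        assert loc.resolve_model("a.xml") is loc.resolve_model("a.xml")

    def test_import_cycle_detected(self):
        mk = lambda me, other: (
            f'<?xml version="1.0"?>'
            f'<Fieldml version="0.5" '
            f'xmlns="http://www.fieldml.org/standard/FieldML_0.5" '
            f'xmlns:xlink="http://www.w3.org/1999/xlink">'
            f'<Region name="{me}">'
            f'<Import xlink:href="{other}">'
            f'<ImportType localName="X" remoteName="E"/></Import>'
            f'</Region></Fieldml>').encode()
        loc = DocumentLocator(documents={"a.xml": mk("a", "b.xml"),
                                         "b.xml": mk("b", "a.xml")})
        with pytest.raises(ImportError_, match="cycle"):
            loc.resolve_model("a.xml")

    def test_self_import_is_an_error(self):
        doc = (b'<?xml version="1.0"?>'
               b'<Fieldml version="0.5" '
               b'xmlns="http://www.fieldml.org/standard/FieldML_0.5" '
               b'xmlns:xlink="http://www.w3.org/1999/xlink">'
               b'<Region name="r">'
               b'<Import xlink:href="me.xml">'
               b'<ImportType localName="X" remoteName="X"/></Import>'
               b'</Region></Fieldml>')
        loc = DocumentLocator(documents={"me.xml": doc})
        with pytest.raises(ImportError_, match="cycle"):
            loc.resolve_model("me.xml")

    def test_missing_remote_name(self):
        docs = {"a.xml": _tiny_region("a"),
                "main.xml": (
                    b'<?xml version="1.0"?>'
                    b'<Fieldml version="0.5" '
                    b'xmlns="http://www.fieldml.org/standard/FieldML_0.5" '
                    b'xmlns:xlink="http://www.w3.org/1999/xlink">'
                    b'<Region name="main">'
                    b'<Import xlink:href="a.xml">'
                    b'<ImportType localName="Z" remoteName="Ghost"/></Import>'
                    b'</Region></Fieldml>')}
        with pytest.raises(ImportError_, match="Ghost"):
            DocumentLocator(documents=docs).resolve_model("main.xml")

    def test_unresolvable_href(self):
        with pytest.raises(ImportError_):
            DocumentLocator().resolve_model("no/such/file.xml")

    def test_relative_hrefs_resolve_against_importing_document(self, tmp_path):
        sub = tmp_path / "sub"
        sub.mkdir()
        (sub / "dep.xml").write_bytes(_tiny_region("dep"))
        (tmp_path / "main.xml").write_bytes(
            _tiny_region("main", import_href="sub/dep.xml",
                         ensemble=("F", "1", "2")))
        m = parse_file(tmp_path / "main.xml")
        assert m.types["other.E"].sorted_members == (1, 2, 3)

    def test_resolve_imports_registers_same_objects(self):
        docs = {"a.xml": _tiny_region("a")}
        loc = DocumentLocator(documents=docs)
        m = Model("manual")
        m.imports.append(ImportRecord("a.xml", "type", "E", "myE"))
        resolve_imports(m, loc)
        assert m.types["myE"] is loc.resolve_model("a.xml").types["E"]
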