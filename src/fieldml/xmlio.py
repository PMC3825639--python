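"""XML (de)serialization of regions, with imports across documents.

One region per document.  The writer is deterministic — equal models
produce byte-identical documents — and emits objects grouped by kind
(imports, types, data resources, evaluators), each group in declaration
order.  Ensembles serialize as contiguous ranges where possible, else as
ascending member lists.

Imports use simple Xlink hrefs.  Imported types and evaluators resolve to
the *same objects* as in their source region (the locator caches parsed
documents), so nominal typing is preserved across files.  The standard
library resolves from the in-process copy, never from the network.

Parsing is worklist-based: objects are constructed once all the names they
reference are available, so declaration order within a document does not
matter.  Two parse modes exist: strict rejects unknown XML elements;
lenient (the default) skips them with a warning, for forward compatibility.
Unknown external evaluators are retained with their declared value types
and fail only at evaluation time.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

from lxml import etree

from .data import (HDF5, INLINE, TEXT_FILE, DataResource, DataSource,
                   DenseLayout, SparseLayout)
from .errors import (DefinitionError, DocumentError, ImportError_,
                     SerializationError)
from .library import LIBRARY_HREFS, load_library
from .model import (Aggregate, Argument, Binding, BooleanType, Constant,
                    ContinuousType, DomainType, EnsembleType, Evaluator,
                    External, ImportRecord, MeshType, Model, Parameter,
                    Piecewise, Reference, validate_model)

FIELDML_NS = "http://www.fieldml.org/standard/FieldML_0.5"
XLINK_NS = "http://www.w3.org/1999/xlink"
NSMAP = {None: FIELDML_NS, "xlink": XLINK_NS}
VERSION = "0.5"


def _q(tag: str) -> str:
    return f"{{{FIELDML_NS}}}{tag}"


def _xlink(attr: str) -> str:
    return f"{{{XLINK_NS}}}{attr}"


# ---------------------------------------------------------------------------
# Locator
# ---------------------------------------------------------------------------

class DocumentLocator:
    """Resolves import hrefs to models, deterministically and cycle-safely.

    Relative hrefs resolve against the importing document's location.
    In-memory documents may be supplied as an ``href -> bytes`` mapping.
    Hrefs naming the standard library resolve to the in-process library
    region.  Each distinct document is parsed once and cached, so two
    imports of the same href yield identical objects.
    """

    def __init__(self, base: Optional[Union[str, Path]] = None,
                 documents: Optional[dict[str, Union[bytes, str]]] = None,
                 strict: bool = False):
        self.base = Path(base) if base is not None else None
        self.documents = dict(documents) if documents else {}
        self.strict = strict
        self._cache: dict[str, Model] = {}
        self._active: list[str] = []

    def _key_for(self, href: str, relative_to: Optional[Path]) -> tuple[str, Optional[Path]]:
        if href in self.documents:
            return href, None
        p = Path(href)
        if not p.is_absolute():
            root = relative_to if relative_to is not None else self.base
            if root is not None:
                p = root / p
        return str(p.resolve()), p.parent.resolve() if p.parent else None

    def resolve_model(self, href: str,
                      relative_to: Optional[Path] = None) -> Model:
        if href in LIBRARY_HREFS or Path(href).name in LIBRARY_HREFS:
            return load_library()
        key, directory = self._key_for(href, relative_to)
        if key in self._cache:
            return self._cache[key]
        if key in self._active:
            chain = " -> ".join(self._active + [key])
            raise ImportError_(f"import cycle: {chain}")
        if href in self.documents:
            payload = self.documents[href]
            directory = self.base
        else:
            p = Path(key)
            if not p.exists():
                raise ImportError_(f"cannot resolve href {href!r} (no such "
                                   f"document {key})")
            payload = p.read_bytes()
            directory = p.parent
        self._active.append(key)
        try:
            model = parse_model(payload, locator=self, strict=self.strict,
                                base=directory)
        finally:
            self._active.pop()
        self._cache[key] = model
        return model


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _members_xml(parent: etree._Element, ensemble: EnsembleType) -> None:
    members = etree.SubElement(parent, _q("Members"))
    if ensemble.is_contiguous():
        etree.SubElement(members, _q("MemberRange"),
                         min=str(ensemble.sorted_members[0]),
                         max=str(ensemble.sorted_members[-1]))
    else:
        lst = etree.SubElement(members, _q("MemberList"))
        lst.text = " ".join(str(m) for m in ensemble.sorted_members)


class _Writer:
    def __init__(self, model: Model):
        self.model = model
        self.eval_names: dict[int, str] = {id(e): n
                                           for n, e in model.evaluators.items()}
        self.type_names: dict[int, str] = {id(t): n
                                           for n, t in model.types.items()}

    def ev_name(self, ev: Evaluator) -> str:
        try:
            return self.eval_names[id(ev)]
        except KeyError:
            raise SerializationError(
                f"region {self.model.region_name!r}: evaluator {ev.name!r} is "
                f"referenced but not declared")

    def ty_name(self, t: DomainType) -> str:
        try:
            return self.type_names[id(t)]
        except KeyError:
            raise SerializationError(
                f"region {self.model.region_name!r}: type {t.name!r} is "
                f"referenced but not declared")

    # -- types -------------------------------------------------------------

    def _embedded_type_names(self) -> set[str]:
        """Names of types embedded in another type's serialization."""
        embedded: set[str] = set()
        for name, t in self.model.types.items():
            if isinstance(t, ContinuousType) and t.component_ensemble is not None:
                if t.component_ensemble.name == f"{t.name}.component":
                    embedded.add(t.component_ensemble.name)
            if isinstance(t, MeshType):
                embedded.add(t.element_ensemble.name)
                if t.chart_type.name == f"{t.name}.xi":
                    embedded.add(t.chart_type.name)
                    if t.chart_type.component_ensemble is not None:
                        embedded.add(t.chart_type.component_ensemble.name)
        return embedded

    def write_type(self, region: etree._Element, name: str, t: DomainType) -> None:
        if isinstance(t, EnsembleType):
            el = etree.SubElement(region, _q("EnsembleType"), name=name)
            _members_xml(el, t)
        elif isinstance(t, BooleanType):
            etree.SubElement(region, _q("BooleanType"), name=name)
        elif isinstance(t, ContinuousType):
            el = etree.SubElement(region, _q("ContinuousType"), name=name)
            if t.component_ensemble is not None:
                ce = t.component_ensemble
                if ce.name == f"{t.name}.component":
                    etree.SubElement(el, _q("Components"), name=ce.name,
                                     count=str(t.dimension))
                else:
                    etree.SubElement(el, _q("Components"), ref=self.ty_name(ce))
        elif isinstance(t, MeshType):
            el = etree.SubElement(region, _q("MeshType"), name=name)
            elements = etree.SubElement(el, _q("Elements"),
                                        name=t.element_ensemble.name)
            _members_xml(elements, t.element_ensemble)
            if t.chart_type.name == f"{t.name}.xi":
                etree.SubElement(el, _q("Chart"), name=t.chart_type.name,
                                 dimension=str(t.dimension))
            else:
                etree.SubElement(el, _q("Chart"), type=self.ty_name(t.chart_type))
            shapes_el = etree.SubElement(el, _q("Shapes"))
            preds = {e: self.ev_name(p) for e, p in t.shape_map.items()}
            if len(set(preds.values())) == 1:
                shapes_el.set("evaluator", next(iter(preds.values())))
            else:
                for e in sorted(preds):
                    etree.SubElement(shapes_el, _q("Shape"), element=str(e),
                                     evaluator=preds[e])
        else:
            raise SerializationError(f"unknown type kind {type(t).__name__}")

    # -- data --------------------------------------------------------------

    def write_resource(self, region: etree._Element, r: DataResource) -> None:
        el = etree.SubElement(region, _q("DataResource"), name=r.name)
        if r.kind == INLINE:
            s = etree.SubElement(el, _q("DataResourceString"))
            s.text = r.inline_text
        else:
            fmt = "PLAIN_TEXT" if r.kind == TEXT_FILE else "HDF5"
            etree.SubElement(el, _q("DataResourceHref"),
                             {_xlink("href"): r.href, "format": fmt})
        for src in getattr(r, "sources", []):
            s = etree.SubElement(el, _q("ArrayDataSource"), name=src.name,
                                 rank=str(len(src.shape)))
            if src.shape:
                size = etree.SubElement(s, _q("ArraySize"))
                size.text = " ".join(str(x) for x in src.shape)
            if r.kind in (INLINE, TEXT_FILE):
                etree.SubElement(s, _q("TextLocation"),
                                 firstRecord=str(src.first_record),
                                 recordCount=str(src.record_count))
            else:
                attrs = {"dataset": src.dataset}
                if src.offset is not None:
                    attrs["offset"] = " ".join(str(x) for x in src.offset)
                etree.SubElement(s, _q("Hdf5Location"), attrs)

    # -- evaluators ---------------------------------------------------------

    def _bindings_xml(self, parent: etree._Element, bindings) -> None:
        if not bindings:
            return
        bl = etree.SubElement(parent, _q("Bindings"))
        for b in bindings:
            etree.SubElement(bl, _q("Bind"), argument=self.ev_name(b.argument),
                             source=self.ev_name(b.delegate))

    def write_evaluator(self, region: etree._Element, name: str,
                        ev: Evaluator) -> None:
        if isinstance(ev, Argument):
            attrs = {"name": name, "valueType": self.ty_name(ev.value_type)}
            if ev.mesh_projection is not None:
                parent_arg, selector = ev.mesh_projection
                attrs["meshArgument"] = self.ev_name(parent_arg)
                attrs["projection"] = selector
            el = etree.SubElement(region, _q("ArgumentEvaluator"), attrs)
            if ev.argument_dependencies:
                args = etree.SubElement(el, _q("Arguments"))
                for d in ev.argument_dependencies:
                    etree.SubElement(args, _q("Argument"), name=self.ev_name(d))
        elif isinstance(ev, Constant):
            etree.SubElement(region, _q("ConstantEvaluator"), name=name,
                             valueType=self.ty_name(ev.value_type),
                             value=ev.value_string)
        elif isinstance(ev, External):
            el = etree.SubElement(region, _q("ExternalEvaluator"), name=name,
                                  valueType=self.ty_name(ev.value_type))
            if ev.declared_arguments:
                args = etree.SubElement(el, _q("Arguments"))
                for d in ev.declared_arguments:
                    etree.SubElement(args, _q("Argument"), name=self.ev_name(d))
        elif isinstance(ev, Reference):
            el = etree.SubElement(region, _q("ReferenceEvaluator"), name=name,
                                  evaluator=self.ev_name(ev.target))
            self._bindings_xml(el, ev.bindings)
        elif isinstance(ev, Piecewise):
            el = etree.SubElement(region, _q("PiecewiseEvaluator"), name=name,
                                  valueType=self.ty_name(ev.value_type),
                                  index=self.ev_name(ev.index))
            self._bindings_xml(el, ev.bindings)
            attrs = {}
            if ev.default is not None:
                attrs["default"] = self.ev_name(ev.default)
            emap = etree.SubElement(el, _q("EvaluatorMap"), attrs)
            for member in sorted(ev.branches):
                etree.SubElement(emap, _q("EvaluatorMapEntry"),
                                 value=str(member),
                                 evaluator=self.ev_name(ev.branches[member]))
        elif isinstance(ev, Aggregate):
            el = etree.SubElement(region, _q("AggregateEvaluator"), name=name,
                                  valueType=self.ty_name(ev.value_type),
                                  index=self.ev_name(ev.index_argument))
            self._bindings_xml(el, ev.bindings)
            attrs = {}
            if ev.default is not None:
                attrs["default"] = self.ev_name(ev.default)
            cmp_el = etree.SubElement(el, _q("ComponentEvaluators"), attrs)
            for member in sorted(ev.components):
                etree.SubElement(cmp_el, _q("ComponentEvaluator"),
                                 component=str(member),
                                 evaluator=self.ev_name(ev.components[member]))
        elif isinstance(ev, Parameter):
            el = etree.SubElement(region, _q("ParameterEvaluator"), name=name,
                                  valueType=self.ty_name(ev.value_type))
            st = ev.storage
            if isinstance(st, DenseLayout):
                d = etree.SubElement(el, _q("DenseArrayData"),
                                     data=st.source.name)
            elif isinstance(st, SparseLayout):
                d = etree.SubElement(el, _q("SparseArrayData"),
                                     data=st.values.name,
                                     keyData=st.keys.name)
            else:
                raise SerializationError(f"parameter {name!r}: unknown storage")
            for a in ev.index_arguments:
                etree.SubElement(d, _q("Index"), evaluator=self.ev_name(a))
        else:
            raise SerializationError(f"unknown evaluator kind {type(ev).__name__}")


def write_model(model: Model) -> bytes:
    """Serialize a region to a FieldML 0.5 XML document (UTF-8 bytes)."""
    w = _Writer(model)
    root = etree.Element(_q("Fieldml"), nsmap=NSMAP, version=VERSION)
    region = etree.SubElement(root, _q("Region"), name=model.region_name)
    for rec in model.imports:
        imp = etree.SubElement(region, _q("Import"), {_xlink("href"): rec.href})
        tag = "ImportType" if rec.kind == "type" else "ImportEvaluator"
        etree.SubElement(imp, _q(tag), localName=rec.local_name,
                         remoteName=rec.remote_name)
    embedded = w._embedded_type_names()
    for name, t in model.types.items():
        if name in model.imported_names or name in embedded:
            continue
        w.write_type(region, name, t)
    for r in model.data_resources.values():
        if r.name in model.imported_names:
            continue
        w.write_resource(region, r)
    for name, ev in model.evaluators.items():
        if name in model.imported_names:
            continue
        w.write_evaluator(region, name, ev)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def write_model_file(model: Model, path: Union[str, Path]) -> None:
    Path(path).write_bytes(write_model(model))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_KNOWN_TAGS = {
    "Import", "EnsembleType", "BooleanType", "ContinuousType", "MeshType",
    "DataResource", "ArgumentEvaluator", "ConstantEvaluator",
    "ExternalEvaluator", "ReferenceEvaluator", "PiecewiseEvaluator",
    "AggregateEvaluator", "ParameterEvaluator",
}


def _parse_members(parent: etree._Element, name: str) -> list[int]:
    members_el = parent.find(_q("Members"))
    if members_el is None:
        raise DocumentError(f"{name!r}: missing Members element")
    rng = members_el.find(_q("MemberRange"))
    if rng is not None:
        lo, hi = int(rng.get("min")), int(rng.get("max"))
        return list(range(lo, hi + 1))
    lst = members_el.find(_q("MemberList"))
    if lst is None or not (lst.text or "").strip():
        raise DocumentError(f"{name!r}: empty member declaration")
    return [int(tok) for tok in lst.text.split()]


class _Parser:
    """Worklist parser: builds objects once their references resolve."""

    def __init__(self, region_el: etree._Element, locator: Optional[DocumentLocator],
                 strict: bool, base: Optional[Path]):
        self.region_el = region_el
        self.locator = locator
        self.strict = strict
        self.base = base
        self.model = Model(region_el.get("name", "region"))
        self.sources: dict[str, DataSource] = {}
        self.warnings: list[str] = []

    # -- name resolution ---------------------------------------------------

    def type_ref(self, name: str) -> DomainType:
        t = self.model.types.get(name)
        if t is None:
            raise KeyError(name)
        return t

    def eval_ref(self, name: str) -> Evaluator:
        e = self.model.evaluators.get(name)
        if e is None:
            raise KeyError(name)
        return e

    def source_ref(self, name: str) -> DataSource:
        s = self.sources.get(name)
        if s is None:
            raise KeyError(name)
        return s

    # -- builders (raise KeyError when a dependency is not yet available) --

    def build(self, el: etree._Element) -> None:
        tag = etree.QName(el).localname
        getattr(self, f"_build_{tag}")(el)

    def _build_Import(self, el: etree._Element) -> None:
        href = el.get(_xlink("href"))
        if href is None:
            raise DocumentError("Import element without xlink:href")
        if self.locator is None:
            raise ImportError_(f"document imports {href!r} but no locator was "
                               f"provided")
        source = self.locator.resolve_model(href, relative_to=self.base)
        for child in el:
            ctag = etree.QName(child).localname
            local = child.get("localName")
            remote = child.get("remoteName")
            if ctag == "ImportType":
                kind = "type"
                obj = source.types.get(remote)
            elif ctag == "ImportEvaluator":
                kind = "evaluator"
                obj = source.evaluators.get(remote)
            else:
                continue
            if obj is None:
                raise ImportError_(f"import from {href!r}: no {kind} named "
                                   f"{remote!r} in region "
                                   f"{source.region_name!r}")
            if kind == "type":
                self.model.add_type(obj, local_name=local)
            else:
                self.model.add_evaluator(obj, local_name=local)
            self.model.imported_names.add(local)
            self.model.imports.append(ImportRecord(href, kind, remote, local))

    def _build_EnsembleType(self, el: etree._Element) -> None:
        name = el.get("name")
        self.model.add_type(EnsembleType(name, _parse_members(el, name)))

    def _build_BooleanType(self, el: etree._Element) -> None:
        self.model.add_type(BooleanType(el.get("name")))

    def _build_ContinuousType(self, el: etree._Element) -> None:
        name = el.get("name")
        comp = el.find(_q("Components"))
        if comp is None:
            t = ContinuousType(name, 1)
        elif comp.get("ref") is not None:
            ce = self.type_ref(comp.get("ref"))
            t = ContinuousType(name, ce.cardinality, component_ensemble=ce)
        else:
            count = int(comp.get("count"))
            ce = EnsembleType(comp.get("name", f"{name}.component"),
                              range(1, count + 1))
            t = ContinuousType(name, count, component_ensemble=ce)
            self.model.add_type(ce)
        self.model.add_type(t)

    def _build_MeshType(self, el: etree._Element) -> None:
        name = el.get("name")
        elements_el = el.find(_q("Elements"))
        chart_el = el.find(_q("Chart"))
        shapes_el = el.find(_q("Shapes"))
        if elements_el is None or chart_el is None or shapes_el is None:
            raise DocumentError(f"mesh {name!r}: needs Elements, Chart and Shapes")
        members = _parse_members(elements_el, name)
        if chart_el.get("type") is not None:
            chart = self.type_ref(chart_el.get("type"))
            implicit_chart = False
        else:
            chart = ContinuousType(chart_el.get("name", f"{name}.xi"),
                                   int(chart_el.get("dimension")))
            implicit_chart = True
        uniform = shapes_el.get("evaluator")
        if uniform is not None:
            shape_map = {m: self.eval_ref(uniform) for m in members}
        else:
            shape_map = {}
            for s in shapes_el.findall(_q("Shape")):
                shape_map[int(s.get("element"))] = self.eval_ref(s.get("evaluator"))
        elements = EnsembleType(elements_el.get("name", f"{name}.elements"),
                                members)
        mesh = MeshType(name, chart.dimension, elements, chart, shape_map)
        self.model.add_type(mesh)
        self.model.add_type(elements)
        if implicit_chart:
            self.model.add_type(chart)
            if chart.component_ensemble is not None:
                self.model.add_type(chart.component_ensemble)

    def _build_DataResource(self, el: etree._Element) -> None:
        name = el.get("name")
        inline = el.find(_q("DataResourceString"))
        href_el = el.find(_q("DataResourceHref"))
        if inline is not None:
            resource = DataResource(name, INLINE, inline_text=inline.text or "")
        elif href_el is not None:
            fmt = href_el.get("format", "PLAIN_TEXT")
            kind = HDF5 if fmt == "HDF5" else TEXT_FILE
            resource = DataResource(name, kind, href=href_el.get(_xlink("href")),
                                    base=self.base)
        else:
            raise DocumentError(f"data resource {name!r}: no payload or href")
        self.model.add_resource(resource)
        for s in el.findall(_q("ArrayDataSource")):
            sname = s.get("name")
            rank = int(s.get("rank", "0"))
            size_el = s.find(_q("ArraySize"))
            shape = ([int(tok) for tok in size_el.text.split()]
                     if size_el is not None and size_el.text else [])
            if len(shape) != rank:
                raise DocumentError(f"data source {sname!r}: rank {rank} but "
                                    f"{len(shape)} extents")
            tloc = s.find(_q("TextLocation"))
            hloc = s.find(_q("Hdf5Location"))
            kwargs = {}
            if tloc is not None:
                kwargs["first_record"] = int(tloc.get("firstRecord", "1"))
                if tloc.get("recordCount") is not None:
                    kwargs["record_count"] = int(tloc.get("recordCount"))
            if hloc is not None:
                kwargs["dataset"] = hloc.get("dataset")
                if hloc.get("offset"):
                    kwargs["offset"] = [int(t) for t in hloc.get("offset").split()]
            src = DataSource(sname, resource, shape, **kwargs)
            if sname in self.sources:
                raise DocumentError(f"duplicate data source name {sname!r}")
            self.sources[sname] = src

    def _build_ArgumentEvaluator(self, el: etree._Element) -> None:
        name = el.get("name")
        vt = self.type_ref(el.get("valueType"))
        deps = []
        args_el = el.find(_q("Arguments"))
        if args_el is not None:
            deps = [self.eval_ref(a.get("name")) for a in args_el.findall(_q("Argument"))]
        projection = None
        if el.get("meshArgument") is not None:
            projection = (self.eval_ref(el.get("meshArgument")),
                          el.get("projection"))
        self.model.add_evaluator(Argument(name, vt, deps,
                                          mesh_projection=projection))

    def _build_ConstantEvaluator(self, el: etree._Element) -> None:
        vt = self.type_ref(el.get("valueType"))
        self.model.add_evaluator(Constant(el.get("name"), vt, el.get("value")))

    def _build_ExternalEvaluator(self, el: etree._Element) -> None:
        vt = self.type_ref(el.get("valueType"))
        deps = []
        args_el = el.find(_q("Arguments"))
        if args_el is not None:
            deps = [self.eval_ref(a.get("name")) for a in args_el.findall(_q("Argument"))]
        self.model.add_evaluator(External(el.get("name"), vt, deps))

    def _bindings(self, el: etree._Element) -> list[Binding]:
        out = []
        bl = el.find(_q("Bindings"))
        if bl is not None:
            for b in bl.findall(_q("Bind")):
                out.append(Binding(self.eval_ref(b.get("argument")),
                                   self.eval_ref(b.get("source"))))
        return out

    def _build_ReferenceEvaluator(self, el: etree._Element) -> None:
        target = self.eval_ref(el.get("evaluator"))
        self.model.add_evaluator(Reference(el.get("name"), target,
                                           self._bindings(el)))

    def _build_PiecewiseEvaluator(self, el: etree._Element) -> None:
        vt = self.type_ref(el.get("valueType"))
        index = self.eval_ref(el.get("index"))
        bindings = self._bindings(el)
        emap = el.find(_q("EvaluatorMap"))
        branches = {}
        default = None
        if emap is not None:
            if emap.get("default") is not None:
                default = self.eval_ref(emap.get("default"))
            for entry in emap.findall(_q("EvaluatorMapEntry")):
                branches[int(entry.get("value"))] = self.eval_ref(
                    entry.get("evaluator"))
        self.model.add_evaluator(Piecewise(el.get("name"), vt, index, branches,
                                           default, bindings))

    def _build_AggregateEvaluator(self, el: etree._Element) -> None:
        vt = self.type_ref(el.get("valueType"))
        index_arg = self.eval_ref(el.get("index"))
        bindings = self._bindings(el)
        comp_el = el.find(_q("ComponentEvaluators"))
        components = {}
        default = None
        if comp_el is not None:
            if comp_el.get("default") is not None:
                default = self.eval_ref(comp_el.get("default"))
            for entry in comp_el.findall(_q("ComponentEvaluator")):
                components[int(entry.get("component"))] = self.eval_ref(
                    entry.get("evaluator"))
        self.model.add_evaluator(Aggregate(el.get("name"), vt, index_arg,
                                           components, default, bindings))

    def _build_ParameterEvaluator(self, el: etree._Element) -> None:
        vt = self.type_ref(el.get("valueType"))
        dense_el = el.find(_q("DenseArrayData"))
        sparse_el = el.find(_q("SparseArrayData"))
        if dense_el is not None:
            storage = DenseLayout(self.source_ref(dense_el.get("data")))
            idx_parent = dense_el
        elif sparse_el is not None:
            storage = SparseLayout(self.source_ref(sparse_el.get("keyData")),
                                   self.source_ref(sparse_el.get("data")))
            idx_parent = sparse_el
        else:
            raise DocumentError(f"parameter {el.get('name')!r}: no array data")
        indexes = [self.eval_ref(i.get("evaluator"))
                   for i in idx_parent.findall(_q("Index"))]
        self.model.add_evaluator(Parameter(el.get("name"), vt, indexes, storage))

    # -- main loop -----------------------------------------------------------

    def run(self) -> Model:
        pending = []
        for el in self.region_el:
            if not isinstance(el.tag, str):
                continue  # comments
            tag = etree.QName(el).localname
            if tag not in _KNOWN_TAGS:
                if self.strict:
                    raise DocumentError(
                        f"unknown element {tag!r} at line {el.sourceline}")
                self.warnings.append(f"skipped unknown element {tag!r} "
                                     f"(line {el.sourceline})")
                continue
            pending.append(el)

        # imports first, in document order (they cannot have local deps)
        for el in [e for e in pending if etree.QName(e).localname == "Import"]:
            self.build(el)
        pending = [e for e in pending if etree.QName(e).localname != "Import"]

        while pending:
            progressed = False
            deferred = []
            for el in pending:
                try:
                    self.build(el)
                    progressed = True
                except KeyError:
                    deferred.append(el)
            if not progressed:
                names = ", ".join(repr(e.get("name")) for e in deferred)
                raise DocumentError(
                    f"region {self.model.region_name!r}: unresolvable "
                    f"references among {names} (undeclared names or a "
                    f"declaration cycle)")
            pending = deferred
        return self.model


def parse_model(document: Union[bytes, str, Path, etree._Element],
                locator: Optional[DocumentLocator] = None,
                strict: bool = False,
                base: Optional[Path] = None) -> Model:
    """Parse a FieldML 0.5 document into a fully resolved model.

    Imports are resolved through *locator*; the model's validation
    diagnostics are attached as ``model.diagnostics`` and parse warnings
    (lenient mode) as ``model.parse_warnings``.
    """
    if isinstance(document, etree._Element):
        root = document
    else:
        if isinstance(document, Path):
            base = base or document.parent
            document = document.read_bytes()
        if isinstance(document, str):
            document = document.encode()
        try:
            root = etree.fromstring(document)
        except etree.XMLSyntaxError as exc:
            raise DocumentError(f"malformed XML: {exc}") from exc
    if etree.QName(root).localname != "Fieldml":
        raise DocumentError(f"root element is {root.tag!r}, expected Fieldml")
    version = root.get("version")
    if version != VERSION:
        raise DocumentError(f"unsupported version {version!r}")
    regions = [el for el in root if isinstance(el.tag, str)
               and etree.QName(el).localname == "Region"]
    if len(regions) != 1:
        raise DocumentError(f"document has {len(regions)} regions, expected 1")
    parser = _Parser(regions[0], locator, strict, base)
    model = parser.run()
    model.parse_warnings = parser.warnings
    model.diagnostics = validate_model(model)
    return model


def parse_file(path: Union[str, Path],
               locator: Optional[DocumentLocator] = None,
               strict: bool = False) -> Model:
    path = Path(path)
    if locator is None:
        locator = DocumentLocator(base=path.parent, strict=strict)
    return locator.resolve_model(str(path))


def resolve_imports(model: Model, locator: DocumentLocator) -> Model:
    """Resolve any unresolved import records of a model in place.

    Imported objects are registered under their local names and are the
    identical objects of the source region.  Already-resolved records are
    left untouched.
    """
    for rec in model.imports:
        if rec.local_name in model.imported_names:
            continue
        source = locator.resolve_model(rec.href)
        table = source.types if rec.kind == "type" else source.evaluators
        if rec.remote_name not in table:
            raise ImportError_(f"import from {rec.href!r}: no {rec.kind} named "
                               f"{rec.remote_name!r}")
        obj = table[rec.remote_name]
        if rec.kind == "type":
            model.add_type(obj, local_name=rec.local_name)
        else:
            model.add_evaluator(obj, local_name=rec.local_name)
        model.imported_names.add(rec.local_name)
    return model


# ---------------------------------------------------------------------------
# Structural comparison
# ---------------------------------------------------------------------------

def _type_signature(name: str, t: DomainType, model: Model):
    if isinstance(t, EnsembleType):
        return ("ensemble", name, t.sorted_members)
    if isinstance(t, BooleanType):
        return ("boolean", name)
    if isinstance(t, ContinuousType):
        comp = (t.component_ensemble.name, t.component_ensemble.sorted_members) \
            if t.component_ensemble is not None else None
        return ("continuous", name, t.dimension, comp)
    if isinstance(t, MeshType):
        shapes = tuple(sorted((e, p.name) for e, p in t.shape_map.items()))
        return ("mesh", name, t.dimension, t.element_ensemble.sorted_members,
                t.chart_type.name, shapes)
    return ("?", name)


def _evaluator_signature(name: str, ev: Evaluator):
    if isinstance(ev, Argument):
        proj = (ev.mesh_projection[0].name, ev.mesh_projection[1]) \
            if ev.mesh_projection else None
        return ("argument", name, ev.value_type.name,
                tuple(d.name for d in ev.argument_dependencies), proj)
    if isinstance(ev, Constant):
        return ("constant", name, ev.value_type.name, ev.value_string)
    if isinstance(ev, External):
        return ("external", name, ev.value_type.name,
                tuple(d.name for d in ev.declared_arguments))
    if isinstance(ev, Reference):
        return ("reference", name, ev.target.name,
                tuple(sorted((b.argument.name, b.delegate.name)
                             for b in ev.bindings)))
    if isinstance(ev, Piecewise):
        return ("piecewise", name, ev.value_type.name, ev.index.name,
                tuple(sorted((m, b.name) for m, b in ev.branches.items())),
                ev.default.name if ev.default else None,
                tuple(sorted((b.argument.name, b.delegate.name)
                             for b in ev.bindings)))
    if isinstance(ev, Aggregate):
        return ("aggregate", name, ev.value_type.name, ev.index_argument.name,
                tuple(sorted((m, c.name) for m, c in ev.components.items())),
                ev.default.name if ev.default else None,
                tuple(sorted((b.argument.name, b.delegate.name)
                             for b in ev.bindings)))
    if isinstance(ev, Parameter):
        st = ev.storage
        if isinstance(st, DenseLayout):
            data = ("dense", _source_signature(st.source))
        else:
            data = ("sparse", _source_signature(st.keys),
                    _source_signature(st.values))
        return ("parameter", name, ev.value_type.name,
                tuple(a.name for a in ev.index_arguments), data)
    return ("?", name)


def _source_signature(src: DataSource):
    r = src.resource
    payload = r.inline_text.split() if r.kind == INLINE else r.href
    return (src.name, src.shape, r.kind, payload, src.first_record,
            src.record_count, src.dataset, src.offset)


def models_isomorphic(a: Model, b: Model) -> bool:
    """Deep structural equality of two regions, ignoring document order.

    Objects are matched by name; structure, member sets, references (by
    name) and data payloads must agree.  Used as the round-trip oracle.
    """
    if a.region_name != b.region_name:
        return False
    if set(a.types) != set(b.types) or set(a.evaluators) != set(b.evaluators):
        return False
    if set(a.data_resources) != set(b.data_resources):
        return False
    for name in a.types:
        if _type_signature(name, a.types[name], a) != \
                _type_signature(name, b.types[name], b):
            return False
    for name in a.evaluators:
        if _evaluator_signature(name, a.evaluators[name]) != \
                _evaluator_signature(name, b.evaluators[name]):
            return False
    return True
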