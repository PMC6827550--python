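"""BioC XML corpus model, reader and writer.

A corpus is a collection of recipe documents; each document holds one passage
(the cleaned recipe text, at offset 0) and offset-anchored food annotations,
each carrying at least one semantic tag.  Offsets are absolute character
offsets (passage offset + within-passage position, equal here because the
single passage sits at 0), 0-based and end-exclusive.

Dialect: the document category lives in an infon with key ``category``; an
annotation's tags live in an infon with key ``semantic_tags``, semicolon-joined
bracket notation, sorted by code so serialization is deterministic.  The
space-before-bracket variant (``AG.01.z [Water]``) is accepted on read.
Serialization is byte-stable: write(read(write(c))) == write(c).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .exceptions import CorpusError
from .lexicon import SemanticTag, format_tag, parse_tag

_XML_HEADER = "<?xml version='1.0' encoding='UTF-8'?>\n<!DOCTYPE collection SYSTEM 'BioC.dtd'>\n"


@dataclass(frozen=True)
class Annotation:
    """One food-entity annotation; ``id`` is bookkeeping, not identity."""

    id: str = field(compare=False)
    text: str = ""
    offset: int = 0
    length: int = 0
    tags: frozenset[SemanticTag] = frozenset()

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class Passage:
    offset: int
    text: str
    annotations: list[Annotation] = field(default_factory=list)


@dataclass
class Document:
    id: str
    category: str = "unknown"
    passages: list[Passage] = field(default_factory=list)


@dataclass
class AnnotatedCorpus:
    source: str = "foodner"
    date: str = "20190101"
    key: str = "foodner.key"
    documents: list[Document] = field(default_factory=list)

    def validate(self) -> None:
        """Raise :class:`CorpusError` on the first structural violation."""
        seen_docs: set[str] = set()
        for doc in self.documents:
            if doc.id in seen_docs:
                raise CorpusError(f"duplicate document id {doc.id!r}")
            seen_docs.add(doc.id)
            seen_anns: set[str] = set()
            for passage in doc.passages:
                for ann in passage.annotations:
                    if ann.id in seen_anns:
                        raise CorpusError(
                            f"document {doc.id!r}: duplicate annotation id {ann.id!r}"
                        )
                    seen_anns.add(ann.id)
                    if not ann.tags:
                        raise CorpusError(
                            f"document {doc.id!r}: annotation {ann.id!r} has no tags"
                        )
                    rel = ann.offset - passage.offset
                    if rel < 0 or passage.text[rel : rel + ann.length] != ann.text:
                        raise CorpusError(
                            f"document {doc.id!r}: annotation {ann.id!r} text "
                            f"{ann.text!r} does not match passage slice at offset {ann.offset}"
                        )

    def iter_annotations(self) -> Iterable[tuple[Document, Passage, Annotation]]:
        for doc in self.documents:
            for passage in doc.passages:
                for ann in passage.annotations:
                    yield doc, passage, ann


def _tags_infon(tags: frozenset[SemanticTag]) -> str:
    return ";".join(format_tag(t) for t in sorted(tags))


def _corpus_to_element(corpus: AnnotatedCorpus) -> ET.Element:
    collection = ET.Element("collection")
    ET.SubElement(collection, "source").text = corpus.source
    ET.SubElement(collection, "date").text = corpus.date
    ET.SubElement(collection, "key").text = corpus.key
    for doc in corpus.documents:
        doc_el = ET.SubElement(collection, "document")
        ET.SubElement(doc_el, "id").text = doc.id
        infon = ET.SubElement(doc_el, "infon", {"key": "category"})
        infon.text = doc.category
        for passage in doc.passages:
            pas_el = ET.SubElement(doc_el, "passage")
            ET.SubElement(pas_el, "offset").text = str(passage.offset)
            ET.SubElement(pas_el, "text").text = passage.text
            for ann in passage.annotations:
                ann_el = ET.SubElement(pas_el, "annotation", {"id": ann.id})
                tag_infon = ET.SubElement(ann_el, "infon", {"key": "semantic_tags"})
                tag_infon.text = _tags_infon(ann.tags)
                ET.SubElement(
                    ann_el,
                    "location",
                    {"offset": str(ann.offset), "length": str(ann.length)},
                )
                ET.SubElement(ann_el, "text").text = ann.text
    return collection


def writes_bioc(corpus: AnnotatedCorpus) -> str:
    """Serialize to a BioC XML string (deterministic element/attribute order)."""
    corpus.validate()
    collection = _corpus_to_element(corpus)
    ET.indent(collection, space="  ")
    return _XML_HEADER + ET.tostring(collection, encoding="unicode") + "\n"


def write_bioc(corpus: AnnotatedCorpus, path: str | Path) -> None:
    Path(path).write_text(writes_bioc(corpus), encoding="utf-8")


def _parse_annotation(ann_el: ET.Element, doc_id: str) -> Annotation:
    ann_id = ann_el.get("id", "")
    tag_text = None
    for infon in ann_el.findall("infon"):
        if infon.get("key") == "semantic_tags":
            tag_text = infon.text or ""
    if not tag_text:
        raise CorpusError(
            f"document {doc_id!r}: annotation {ann_id!r} has an empty semantic_tags infon"
        )
    tags = frozenset(parse_tag(part) for part in tag_text.split(";") if part.strip())
    location = ann_el.find("location")
    if location is None:
        raise CorpusError(f"document {doc_id!r}: annotation {ann_id!r} has no location")
    text_el = ann_el.find("text")
    return Annotation(
        id=ann_id,
        text=text_el.text or "" if text_el is not None else "",
        offset=int(location.get("offset", "0")),
        length=int(location.get("length", "0")),
        tags=tags,
    )


def reads_bioc(xml_text: str) -> AnnotatedCorpus:
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise CorpusError(f"malformed BioC XML: {exc}") from exc
    corpus = AnnotatedCorpus(
        source=root.findtext("source") or "",
        date=root.findtext("date") or "",
        key=root.findtext("key") or "",
    )
    for doc_el in root.findall("document"):
        doc_id = doc_el.findtext("id") or ""
        category = "unknown"
        for infon in doc_el.findall("infon"):
            if infon.get("key") == "category":
                category = infon.text or "unknown"
        doc = Document(id=doc_id, category=category)
        for pas_el in doc_el.findall("passage"):
            passage = Passage(
                offset=int(pas_el.findtext("offset") or "0"),
                text=pas_el.findtext("text") or "",
            )
            for ann_el in pas_el.findall("annotation"):
                passage.annotations.append(_parse_annotation(ann_el, doc_id))
            doc.passages.append(passage)
        corpus.documents.append(doc)
    corpus.validate()
    return corpus


def read_bioc(path: str | Path) -> AnnotatedCorpus:
    return reads_bioc(Path(path).read_text(encoding="utf-8"))


def export_tsv(corpus: AnnotatedCorpus, path: str | Path) -> None:
    """Flat export: recipe_id, start, length, text, semicolon-joined tags."""
    lines = ["recipe_id\tstart\tlength\ttext\ttags"]
    for doc, _passage, ann in corpus.iter_annotations():
        lines.append(
            f"{doc.id}\t{ann.offset}\t{ann.length}\t{ann.text}\t{_tags_infon(ann.tags)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def next_annotation_id(doc: Document) -> str:
    """Smallest positive integer id unused in the document."""
    used = {
        ann.id for passage in doc.passages for ann in passage.annotations
    }
    n = 1
    while str(n) in used:
        n += 1
    return str(n)
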