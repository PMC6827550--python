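"""Cross-resource food-concept alignment.

Each semantic resource (a tagged corpus, an ontology annotation run, ...)
yields a dataset of unique food concepts: an artificial per-resource ID, the
normalized concept name and the resource's tag strings.  Concepts whose
normalized names appear in at least two datasets form the alignment table,
linking the artificial IDs across resources — a name-level join, no fuzzy
matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import FoodnerError


def normalize_name(name: str) -> str:
    return " ".join(name.lower().split())


@dataclass(frozen=True)
class ConceptRecord:
    resource: str
    concept_id: str
    name: str
    tags: frozenset[str] = frozenset()


@dataclass
class ConceptMapping:
    """name → [(resource, concept_id), ...], every row spanning ≥2 resources."""

    rows: dict[str, list[tuple[str, str]]]

    def __len__(self) -> int:
        return len(self.rows)


def build_dataset(
    annotations: Iterable[tuple[str, Iterable[str]]], resource: str
) -> list[ConceptRecord]:
    """Collapse (name, tags) pairs into unique concepts with artificial IDs.

    Names are normalized, duplicates merged by tag union, and IDs assigned as
    ``RESOURCE:000001...`` in first-appearance order.
    """
    if not resource:
        raise FoodnerError("resource name must be non-empty")
    merged: dict[str, set[str]] = {}
    for name, tags in annotations:
        norm = normalize_name(name)
        merged.setdefault(norm, set()).update(tags)
    return [
        ConceptRecord(
            resource=resource,
            concept_id=f"{resource}:{i:06d}",
            name=name,
            tags=frozenset(tags),
        )
        for i, (name, tags) in enumerate(merged.items(), start=1)
    ]


def align(datasets: Sequence[Sequence[ConceptRecord]]) -> ConceptMapping:
    """Exact normalized-name join across datasets, keeping names found in ≥2."""
    if len(datasets) < 2:
        raise FoodnerError("alignment needs at least two datasets")
    by_name: dict[str, list[tuple[str, str]]] = {}
    for dataset in datasets:
        for record in dataset:
            by_name.setdefault(record.name, []).append(
                (record.resource, record.concept_id)
            )
    rows = {
        name: sorted(entries)
        for name, entries in sorted(by_name.items())
        if len({resource for resource, _ in entries}) >= 2
    }
    return ConceptMapping(rows=rows)


def write_dataset(dataset: Sequence[ConceptRecord], path: str | Path) -> None:
    lines = [
        f"{rec.concept_id}\t{rec.name}\t{';'.join(sorted(rec.tags))}" for rec in dataset
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_dataset(path: str | Path, resource: str | None = None) -> list[ConceptRecord]:
    records = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) < 2:
            raise FoodnerError(f"{path}:{lineno}: expected at least 2 fields")
        concept_id = fields[0]
        res = resource or concept_id.split(":", 1)[0]
        tags = frozenset(t for t in fields[2].split(";") if t) if len(fields) > 2 else frozenset()
        records.append(
            ConceptRecord(
                resource=res,
                concept_id=concept_id,
                name=normalize_name(fields[1]),
                tags=tags,
            )
        )
    return records


def write_mapping(mapping: ConceptMapping, path: str | Path) -> None:
    # concept IDs already embed their resource prefix (RESOURCE:000001)
    lines = [
        f"{name}\t{';'.join(cid for _res, cid in entries)}"
        for name, entries in mapping.rows.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
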