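"""Catalog of the 19 typical entity types found across four categories of
traditional Chinese medicine literature (canonical texts, medical case
collections, herbals, and comprehensive compilations).

Two label codes in the source taxonomy collide across literature categories
(the same code was reused for "principle of treatment"/"symptoms" and for
"formula"/"dosis"); this catalog disambiguates them (``ZZE`` and ``JL``) so
that every type has a unique code and the B-/I- tag space is well defined:
19 types x {B, I} + "O" = 40 tags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["EntityType", "EntityTypeCatalog", "default_catalog", "DOC_TYPES"]

DOC_TYPES = ("canon", "medical_cases", "herbal", "comprehensive")

# (full name, unique label code, literature categories the type is typical of)
_DEFAULT_TYPES: list[tuple[str, str, tuple[str, ...]]] = [
    ("cognitive method", "RSFF", ("canon",)),
    ("traditional Chinese physiology", "ZYSL", ("canon",)),
    ("traditional Chinese pathology", "ZYBL", ("canon",)),
    ("principle of treatment", "ZZE", ("canon",)),
    ("method of treatment", "ZF", ("canon",)),
    ("Chinese materia medica", "ZY", ("medical_cases", "comprehensive")),
    ("symptoms", "ZZ", ("medical_cases", "herbal")),
    ("pulse", "MX", ("medical_cases", "comprehensive")),
    ("tongue", "SX", ("medical_cases", "comprehensive")),
    ("formula", "FJ", ("medical_cases", "comprehensive")),
    ("dosis", "JL", ("medical_cases",)),
    ("drug property", "YX", ("herbal",)),
    ("flavor of medicinals", "YW", ("herbal",)),
    ("channel tropism", "GJ", ("herbal",)),
    ("virtue", "GX", ("herbal",)),
    ("dilantin", "YM", ("herbal",)),
    ("pathogeny", "BY", ("comprehensive",)),
    ("disease", "JB", ("comprehensive",)),
    ("syndrome", "ZH", ("comprehensive",)),
]


@dataclass(frozen=True)
class EntityType:
    name: str
    label: str
    doc_types: tuple[str, ...] = ()


@dataclass
class EntityTypeCatalog:
    """Ordered, fixed list of entity types and the derived tag space."""

    types: list[EntityType] = field(default_factory=list)

    def __post_init__(self):
        labels = [t.label for t in self.types]
        if len(set(labels)) != len(labels):
            raise ValueError("entity type labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.types]

    @property
    def n_types(self) -> int:
        return len(self.types)

    def __len__(self) -> int:
        return len(self.types)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def tag_list(self) -> list[str]:
        """The full tag space: ["<pad>", "O", "B-x1", "I-x1", ...].

        A dedicated padding tag occupies index 0 (mirroring the reserved
        padding id of the character vocabulary), so 19 types yield
        2 + 2*19 = 40 tags.
        """
        tags = ["<pad>", "O"]
        for t in self.types:
            tags.append(f"B-{t.label}")
            tags.append(f"I-{t.label}")
        return tags

    @property
    def n_tags(self) -> int:
        return 2 + 2 * len(self.types)

    def labels_for_doc_type(self, doc_type: str) -> list[str]:
        if doc_type not in DOC_TYPES:
            raise ValueError(f"unknown document type {doc_type!r}")
        return [t.label for t in self.types if doc_type in t.doc_types]

    # -- JSON round trip -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = [
            {"name": t.name, "label": t.label, "doc_types": list(t.doc_types)}
            for t in self.types
        ]
        Path(path).write_text(json.dumps(payload, ensure_ascii=False, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EntityTypeCatalog":
        payload = json.loads(Path(path).read_text())
        return cls(
            types=[
                EntityType(d["name"], d["label"], tuple(d.get("doc_types", ())))
                for d in payload
            ]
        )


def default_catalog() -> EntityTypeCatalog:
    """The standard 19-type catalog."""
    return EntityTypeCatalog(
        types=[EntityType(n, l, dt) for n, l, dt in _DEFAULT_TYPES]
    )
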