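"""MeSH descriptor vocabulary and tree-number hierarchy.

MeSH descriptors sit in a poly-hierarchy encoded entirely by their *tree
numbers*: dotted path strings such as ``C04.588``.  A descriptor X is a
descendant of Y iff some tree number of X extends some tree number of Y at a
dot boundary (``C04.588`` is under ``C04``; ``C041`` is not).  The leading
letter of a tree number gives the descriptor's top-level category (A Anatomy,
C Diseases, G Phenomena and Processes, ...).  Hierarchy queries here rely
only on that string structure — no explicit parent pointers — which matches
how NLM distributes the vocabulary.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field
from typing import IO, Union

from lxml import etree

from .errors import FormatError, MeshLookupError

_TREE_NUMBER = re.compile(r"^[A-Z][0-9]+(\.[0-9]+)*$")


@dataclass(frozen=True)
class MeshDescriptor:
    ui: str
    name: str
    tree_numbers: frozenset[str]

    @property
    def category(self) -> frozenset[str]:
        """Distinct leading letters of the descriptor's tree numbers."""
        return frozenset(t[0] for t in self.tree_numbers)


@dataclass
class MeshVocabulary:
    """Descriptor collection with exact-name and tree-number indexes."""

    descriptors: dict[str, MeshDescriptor] = field(default_factory=dict)
    name_index: dict[str, str] = field(default_factory=dict)   # lowercased name -> ui
    tree_index: dict[str, str] = field(default_factory=dict)   # tree number -> ui
    _sorted_trees: list[str] = field(default_factory=list, repr=False)

    def add(self, descriptor: MeshDescriptor) -> None:
        if descriptor.ui in self.descriptors:
            raise FormatError(f"duplicate descriptor UI {descriptor.ui!r}")
        for t in descriptor.tree_numbers:
            if not _TREE_NUMBER.match(t):
                raise FormatError(
                    f"tree number {t!r} of {descriptor.ui} violates the "
                    "dotted alphanumeric grammar"
                )
            if t in self.tree_index:
                raise FormatError(
                    f"tree number {t!r} assigned to both "
                    f"{self.tree_index[t]} and {descriptor.ui}"
                )
        self.descriptors[descriptor.ui] = descriptor
        self.name_index[descriptor.name.lower()] = descriptor.ui
        for t in descriptor.tree_numbers:
            self.tree_index[t] = descriptor.ui
            bisect.insort(self._sorted_trees, t)

    def __contains__(self, ui: str) -> bool:
        return ui in self.descriptors

    def __len__(self) -> int:
        return len(self.descriptors)

    def get(self, ui: str) -> MeshDescriptor:
        try:
            return self.descriptors[ui]
        except KeyError:
            raise MeshLookupError(ui) from None

    def lookup_name(self, name: str) -> str:
        """Case-insensitive exact preferred-name match -> descriptor UI."""
        key = name.strip().lower()
        if key not in self.name_index:
            raise MeshLookupError(name)
        return self.name_index[key]

    def name_of(self, ui: str) -> str:
        return self.get(ui).name


def parse_mesh_xml(source: Union[str, bytes, IO[bytes]]) -> MeshVocabulary:
    """Parse MeSH descriptor XML (``DescriptorRecordSet`` dialect).

    Descriptors without tree numbers are retained (empty category); a
    duplicate DescriptorUI is a format error.
    """
    import io

    if isinstance(source, bytes):
        source = io.BytesIO(source)
    elif isinstance(source, str):
        source = open(source, "rb")
    vocab = MeshVocabulary()
    try:
        for _event, elem in etree.iterparse(
            source, events=("end",), tag="DescriptorRecord"
        ):
            ui_elem = elem.find("DescriptorUI")
            name_elem = elem.find("DescriptorName/String")
            ui = ui_elem.text.strip() if ui_elem is not None and ui_elem.text else None
            name = (
                name_elem.text.strip()
                if name_elem is not None and name_elem.text
                else ""
            )
            if not ui:
                elem.clear()
                continue
            trees = frozenset(
                t.text.strip()
                for t in elem.findall("TreeNumberList/TreeNumber")
                if t.text and t.text.strip()
            )
            vocab.add(MeshDescriptor(ui=ui, name=name, tree_numbers=trees))
            elem.clear()
            while elem.getprevious() is not None:
                del elem.getparent()[0]
    except etree.XMLSyntaxError as exc:
        line, column = exc.position
        raise FormatError(
            f"input is not well-formed XML (offset: line {line}, column {column})"
        ) from exc
    return vocab


def descendants(vocab: MeshVocabulary, ui: str) -> set[str]:
    """All descriptors below *ui* in the hierarchy (any depth), excluding *ui*.

    X is below Y iff some tree number of X equals ``t + "." + suffix`` for a
    tree number *t* of Y.  Implemented as a sorted prefix scan over the tree
    index, so cost is proportional to the subtree size.
    """
    desc = vocab.get(ui)
    out: set[str] = set()
    trees = vocab._sorted_trees
    for t in desc.tree_numbers:
        prefix = t + "."
        i = bisect.bisect_left(trees, prefix)
        while i < len(trees) and trees[i].startswith(prefix):
            out.add(vocab.tree_index[trees[i]])
            i += 1
    out.discard(ui)
    return out


def children(vocab: MeshVocabulary, ui: str) -> set[str]:
    """Descriptors exactly one dotted level below any tree number of *ui*."""
    desc = vocab.get(ui)
    out: set[str] = set()
    trees = vocab._sorted_trees
    for t in desc.tree_numbers:
        prefix = t + "."
        i = bisect.bisect_left(trees, prefix)
        while i < len(trees) and trees[i].startswith(prefix):
            if "." not in trees[i][len(prefix):]:
                out.add(vocab.tree_index[trees[i]])
            i += 1
    out.discard(ui)
    return out


def root_level_terms(vocab: MeshVocabulary, category_letter: str) -> set[str]:
    """Descriptors holding an undotted tree number in the given category."""
    return {
        ui
        for t, ui in vocab.tree_index.items()
        if "." not in t and t[0] == category_letter
    }
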