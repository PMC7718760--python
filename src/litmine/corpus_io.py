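"""Parsers for the external file formats and the shared CSV writer.

The formats handled here are the standard distribution formats of the
literature-mining data sources:

* PubMed/MEDLINE citation XML (baseline and incremental-update dialects,
  including ``DeleteCitation`` blocks),
* the NCBI ``gene2pubmed`` TSV linking (taxonomy id, Gene id) to PubMed ids,
* pathway-annotation, ortholog-pair and interaction-edge TSV tables,
* RFC-4180 CSV output for every tabular result.

All parsers are streaming (``lxml.etree.iterparse``) so memory stays constant
in the number of citations; malformed *optional* fields degrade to absent
rather than aborting a file, while structural problems (non-XML input, a bad
evidence label) raise :class:`~litmine.errors.FormatError`.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, NamedTuple, Optional, Sequence, Union

from lxml import etree

from .errors import FormatError, ParameterError

# Closed set of interaction-evidence labels (protein-protein, genetic,
# interolog-inferred).
EVIDENCE_TYPES = frozenset({"ppi", "genetic", "interolog"})

_YEAR_TOKEN = re.compile(r"(?<!\d)(\d{4})(?!\d)")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeshHeadingRef:
    """One MeSH heading attached to a publication (descriptor level only)."""

    descriptor_ui: str
    descriptor_name: str
    major_topic: bool = False


@dataclass(frozen=True)
class AuthorEntry:
    """One entry of an ordered author list.

    Exactly one of ``last_name`` or ``collective_name`` anchors the identity;
    consortium entries carry only ``collective_name``.
    """

    last_name: Optional[str] = None
    fore_name: Optional[str] = None
    initials: Optional[str] = None
    collective_name: Optional[str] = None
    affiliations: tuple[str, ...] = ()

    @property
    def is_person(self) -> bool:
        return self.last_name is not None


@dataclass(frozen=True)
class PubRecord:
    """One publication: identity, year, headings and ordered authors."""

    pmid: int
    year: Optional[int] = None
    title: Optional[str] = None
    journal: Optional[str] = None
    mesh_headings: tuple[MeshHeadingRef, ...] = ()
    authors: tuple[AuthorEntry, ...] = ()
    version: int = 1

    def heading_uis(self, major_only: bool = False) -> set[str]:
        return {
            h.descriptor_ui
            for h in self.mesh_headings
            if not major_only or h.major_topic
        }


@dataclass(frozen=True)
class GenePubLink:
    """One (taxonomy id, Gene id, PubMed id) association."""

    taxid: int
    gene_id: int
    pmid: int


@dataclass(frozen=True)
class PathwayAnnotation:
    pathway: str
    source: str
    taxid: int
    gene_ids: frozenset[int]


@dataclass(frozen=True)
class OrthologPair:
    """A cross-species ortholog call with an integrative vote-count score."""

    taxid_a: int
    gene_a: int
    taxid_b: int
    gene_b: int
    score: float


@dataclass(frozen=True)
class InteractionEdge:
    gene_a: int
    gene_b: int
    evidence: str

    def __post_init__(self):
        if self.evidence not in EVIDENCE_TYPES:
            raise ParameterError(
                f"evidence {self.evidence!r} not in {sorted(EVIDENCE_TYPES)}"
            )
        if self.gene_a == self.gene_b:
            raise ParameterError(f"self-interaction on gene {self.gene_a}")


@dataclass
class ParseReport:
    """Per-file accounting of parsed vs skipped elements.

    ``parsed + skipped`` equals the number of citation elements (or data
    lines) seen, so nothing is silently dropped.
    """

    parsed: int = 0
    skipped: int = 0
    errors: list[str] = field(default_factory=list)

    def skip(self, message: str) -> None:
        self.skipped += 1
        self.errors.append(message)


class PubmedParse(NamedTuple):
    records: list[PubRecord]
    deleted: set[int]
    report: ParseReport


# ---------------------------------------------------------------------------
# PubMed / MEDLINE XML
# ---------------------------------------------------------------------------

def _text(elem: Optional[etree._Element]) -> Optional[str]:
    if elem is None or elem.text is None:
        return None
    t = elem.text.strip()
    return t or None


def _parse_year(citation: etree._Element) -> Optional[int]:
    """Publication year: PubDate/Year, else first 4-digit token of MedlineDate."""
    pubdate = citation.find(".//Article/Journal/JournalIssue/PubDate")
    if pubdate is None:
        return None
    year = _text(pubdate.find("Year"))
    if year is not None:
        try:
            return int(year)
        except ValueError:
            return None
    medline_date = _text(pubdate.find("MedlineDate"))
    if medline_date:
        m = _YEAR_TOKEN.search(medline_date)
        if m:
            return int(m.group(1))
    return None


def _parse_author(elem: etree._Element) -> Optional[AuthorEntry]:
    collective = _text(elem.find("CollectiveName"))
    last = _text(elem.find("LastName"))
    affiliations = tuple(
        a for a in (_text(x) for x in elem.findall("AffiliationInfo/Affiliation"))
        if a is not None
    )
    if collective is not None and last is None:
        return AuthorEntry(collective_name=collective, affiliations=affiliations)
    if last is None:
        return None  # malformed entry degrades to absent
    return AuthorEntry(
        last_name=last,
        fore_name=_text(elem.find("ForeName")),
        initials=_text(elem.find("Initials")),
        affiliations=affiliations,
    )


def _parse_headings(citation: etree._Element) -> tuple[MeshHeadingRef, ...]:
    headings: list[MeshHeadingRef] = []
    seen: set[str] = set()
    for mh in citation.findall("MeshHeadingList/MeshHeading"):
        desc = mh.find("DescriptorName")
        if desc is None:
            continue
        ui = desc.get("UI", "").strip()
        name = _text(desc) or ""
        if not ui or ui in seen:
            continue
        seen.add(ui)
        headings.append(
            MeshHeadingRef(
                descriptor_ui=ui,
                descriptor_name=name,
                major_topic=desc.get("MajorTopicYN", "N") == "Y",
            )
        )
    return tuple(headings)


def _parse_citation(citation: etree._Element, report: ParseReport) -> Optional[PubRecord]:
    pmid_elem = citation.find("PMID")
    pmid_text = _text(pmid_elem)
    if pmid_text is None:
        report.skip("citation without PMID skipped")
        return None
    try:
        pmid = int(pmid_text)
    except ValueError:
        report.skip(f"citation with non-integer PMID {pmid_text!r} skipped")
        return None
    try:
        version = int(citation.get("VersionID", "1"))
    except ValueError:
        version = 1
    authors = tuple(
        a
        for a in (
            _parse_author(e)
            for e in citation.findall("Article/AuthorList/Author")
        )
        if a is not None
    )
    report.parsed += 1
    return PubRecord(
        pmid=pmid,
        year=_parse_year(citation),
        title=_text(citation.find("Article/ArticleTitle")),
        journal=_text(citation.find("Article/Journal/Title")),
        mesh_headings=_parse_headings(citation),
        authors=authors,
        version=version,
    )


def _as_stream(source: Union[str, bytes, IO[bytes]]) -> IO[bytes]:
    if isinstance(source, bytes):
        return io.BytesIO(source)
    if isinstance(source, str):
        return open(source, "rb")
    return source


def parse_pubmed_xml(source: Union[str, bytes, IO[bytes]]) -> PubmedParse:
    """Parse one PubMed/MEDLINE XML file (baseline or update dialect).

    Returns the per-citation records (after within-file last-version-wins
    merging, so PMIDs are unique in the result), the set of PMIDs listed
    under ``DeleteCitation``, and a :class:`ParseReport`.

    Raises :class:`FormatError` for non-XML input, naming the position of the
    first syntax error.
    """
    stream = _as_stream(source)
    report = ParseReport()
    by_pmid: dict[int, tuple[int, int, PubRecord]] = {}  # pmid -> (order, version, rec)
    deleted: set[int] = set()
    order = 0
    try:
        for _event, elem in etree.iterparse(
            stream, events=("end",), tag=("MedlineCitation", "DeleteCitation"),
            recover=False,
        ):
            if elem.tag == "MedlineCitation":
                rec = _parse_citation(elem, report)
                if rec is not None:
                    order += 1
                    prev = by_pmid.get(rec.pmid)
                    # last-version-wins within the file: later document order
                    # wins unless it carries a strictly lower VersionID
                    if prev is None or rec.version >= prev[1]:
                        by_pmid[rec.pmid] = (order, rec.version, rec)
            else:  # DeleteCitation
                for p in elem.findall("PMID"):
                    t = _text(p)
                    if t is not None:
                        try:
                            deleted.add(int(t))
                        except ValueError:
                            report.errors.append(
                                f"non-integer PMID {t!r} in DeleteCitation ignored"
                            )
            elem.clear()
            while elem.getprevious() is not None:
                del elem.getparent()[0]
    except etree.XMLSyntaxError as exc:
        line, column = exc.position
        raise FormatError(
            f"input is not well-formed XML (offset: line {line}, column {column})"
        ) from exc
    records = [rec for _o, _v, rec in sorted(by_pmid.values())]
    return PubmedParse(records=records, deleted=deleted, report=report)


# ---------------------------------------------------------------------------
# gene2pubmed TSV
# ---------------------------------------------------------------------------

def _iter_lines(source: Union[str, bytes, IO[bytes]]) -> Iterable[str]:
    stream = _as_stream(source)
    for raw in stream:
        yield raw.decode("utf-8")


def parse_gene2pubmed(
    source: Union[str, bytes, IO[bytes]],
    species_filter: Optional[set[int]] = None,
    report: Optional[ParseReport] = None,
) -> list[GenePubLink]:
    """Parse an NCBI gene2pubmed TSV (``#tax_id  GeneID  PubMed_ID``).

    Duplicate triples collapse to their first occurrence; output preserves
    input order of first occurrence.  Lines with non-integer fields are
    skipped and recorded in *report*.
    """
    if report is None:
        report = ParseReport()
    links: list[GenePubLink] = []
    seen: set[tuple[int, int, int]] = set()
    for lineno, line in enumerate(_iter_lines(source), start=1):
        line = line.rstrip("\r\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            report.skip(f"line {lineno}: expected 3 tab-separated fields")
            continue
        try:
            taxid, gene_id, pmid = (int(f) for f in fields)
        except ValueError:
            report.skip(f"line {lineno}: non-integer field in {fields!r}")
            continue
        if taxid <= 0 or gene_id <= 0 or pmid <= 0:
            report.skip(f"line {lineno}: non-positive identifier in {fields!r}")
            continue
        report.parsed += 1
        if species_filter is not None and taxid not in species_filter:
            continue
        key = (taxid, gene_id, pmid)
        if key in seen:
            continue
        seen.add(key)
        links.append(GenePubLink(taxid, gene_id, pmid))
    return links


# ---------------------------------------------------------------------------
# Pathway / ortholog / interaction tables
# ---------------------------------------------------------------------------

def parse_pathway_table(source: Union[str, bytes, IO[bytes]]) -> list[PathwayAnnotation]:
    """Parse a pathway TSV (``pathway  source  tax_id  gene_id``, one gene per line)."""
    grouped: dict[tuple[str, str, int], set[int]] = {}
    order: list[tuple[str, str, int]] = []
    for lineno, line in enumerate(_iter_lines(source), start=1):
        line = line.rstrip("\r\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"pathway table line {lineno}: expected 4 fields")
        pathway, src, taxid_s, gene_s = fields
        try:
            taxid, gene_id = int(taxid_s), int(gene_s)
        except ValueError as exc:
            raise FormatError(
                f"pathway table line {lineno}: non-integer tax/gene id"
            ) from exc
        key = (pathway, src, taxid)
        if key not in grouped:
            grouped[key] = set()
            order.append(key)
        grouped[key].add(gene_id)
    return [
        PathwayAnnotation(pathway=k[0], source=k[1], taxid=k[2],
                          gene_ids=frozenset(grouped[k]))
        for k in order
    ]


def parse_ortholog_table(source: Union[str, bytes, IO[bytes]]) -> list[OrthologPair]:
    """Parse an ortholog-pair TSV (``tax_a  gene_a  tax_b  gene_b  score``)."""
    pairs: list[OrthologPair] = []
    for lineno, line in enumerate(_iter_lines(source), start=1):
        line = line.rstrip("\r\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise FormatError(f"ortholog table line {lineno}: expected 5 fields")
        try:
            ta, ga, tb, gb = (int(f) for f in fields[:4])
            score = float(fields[4])
        except ValueError as exc:
            raise FormatError(f"ortholog table line {lineno}: bad field") from exc
        if ta == tb:
            raise FormatError(
                f"ortholog table line {lineno}: identical taxids {ta}"
            )
        if score < 0:
            raise FormatError(f"ortholog table line {lineno}: negative score")
        pairs.append(OrthologPair(ta, ga, tb, gb, score))
    return pairs


def parse_interaction_table(source: Union[str, bytes, IO[bytes]]) -> list[InteractionEdge]:
    """Parse an interaction TSV (``gene_a  gene_b  evidence``).

    Unknown evidence labels are rejected with an error naming the line and
    the allowed set.
    """
    edges: list[InteractionEdge] = []
    for lineno, line in enumerate(_iter_lines(source), start=1):
        line = line.rstrip("\r\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"interaction table line {lineno}: expected 3 fields")
        ga_s, gb_s, evidence = fields
        if evidence not in EVIDENCE_TYPES:
            raise FormatError(
                f"interaction table line {lineno}: evidence {evidence!r} "
                f"not in allowed set {sorted(EVIDENCE_TYPES)}"
            )
        try:
            ga, gb = int(ga_s), int(gb_s)
        except ValueError as exc:
            raise FormatError(f"interaction table line {lineno}: bad gene id") from exc
        edges.append(InteractionEdge(ga, gb, evidence))
    return edges


# ---------------------------------------------------------------------------
# CSV output
# ---------------------------------------------------------------------------

def _cell(value) -> str:
    """Render one cell; collections become ';'-joined sorted tokens."""
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (set, frozenset)):
        try:
            items = sorted(value)
        except TypeError:
            items = sorted(value, key=str)
        return ";".join(str(v) for v in items)
    if isinstance(value, (list, tuple)):
        return ";".join(str(v) for v in value)
    return str(value)


def write_csv(
    rows: Sequence,
    destination: Union[str, IO[str]],
    columns: Optional[Sequence[str]] = None,
) -> None:
    """Write a homogeneous result table as RFC-4180 CSV (UTF-8, header row).

    Rows may be dataclass instances, mappings, or plain sequences (the latter
    require *columns*).  Column order follows dataclass field order or the
    explicit *columns* argument, so output is byte-stable.
    """
    if rows and dataclasses.is_dataclass(rows[0]):
        names = [f.name for f in dataclasses.fields(rows[0])]
        if columns is None:
            columns = names
        values = [
            [_cell(getattr(r, c)) for c in columns] for r in rows
        ]
    elif rows and isinstance(rows[0], dict):
        if columns is None:
            columns = list(rows[0].keys())
        values = [[_cell(r.get(c)) for c in columns] for r in rows]
    else:
        if columns is None:
            raise ParameterError("columns required for sequence rows or empty tables")
        values = [[_cell(v) for v in r] for r in rows]

    def _write(fh: IO[str]) -> None:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
        writer.writerow(columns)
        writer.writerows(values)

    if isinstance(destination, str):
        with open(destination, "w", encoding="utf-8", newline="") as fh:
            _write(fh)
    else:
        _write(destination)
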