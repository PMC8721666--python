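"""Readers and writers for every external representation the toolkit touches.

Formats: plain text documents (blank-line separated abstracts or one per
line), TSV gold pairs, TSV n-best candidate files, TSV extracted-pair
output, a small XML dialect bundling documents with their gold pairs, and
SQuAD v1.1 JSON for the question-conversion route ("What does <SF> stand
for?").

All text I/O is UTF-8.  Character offsets are 0-based with half-open
spans.  Readers reject malformed rows rather than silently repairing them;
error messages carry line/element positions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

DOCUMENT_FORMATS = ("plain", "one-per-line", "xml-gold")

PAIR_COLUMNS = ("doc_id", "sf", "lf", "score")
GOLD_COLUMNS = ("doc_id", "sf", "lf")
NBEST_COLUMNS = ("doc_id", "sf", "rank", "lf_candidate", "system")


class FormatError(ValueError):
    """A file violates the declared dialect (with the offending position)."""


@dataclass(frozen=True)
class Document:
    """One input text (abstract or article); the unit of extraction."""

    doc_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass(frozen=True)
class GoldPair:
    """A gold short-form/long-form pair attached to a document."""

    doc_id: str
    sf: str
    lf: str

    def __post_init__(self) -> None:
        if not self.sf or not self.lf:
            raise ValueError("sf and lf must be non-empty")
        if len(self.sf) >= len(self.lf):
            raise ValueError(
                f"sf {self.sf!r} must be shorter than lf {self.lf!r}"
            )


@dataclass(frozen=True)
class NBestEntry:
    """One LF hypothesis from an n-best list produced by some system."""

    doc_id: str
    sf: str
    lf_candidate: str
    rank: int
    system: str = "external"

    def __post_init__(self) -> None:
        if self.rank < 0:
            raise ValueError(f"rank must be >= 0, got {self.rank}")


@dataclass(frozen=True)
class ExtractedPair:
    """An extracted (doc_id, sf, lf) pair with an optional score."""

    doc_id: str
    sf: str
    lf: str
    score: float = 1.0


def _normalize_newlines(text: str) -> str:
    return text.replace("\r\n", "\n").replace("\r", "\n")


def read_documents(path: str | Path, format: str = "plain") -> list[Document]:
    """Read a document collection.

    ``plain``: blank-line-separated abstracts; ``one-per-line``: one
    document per line; ``xml-gold``: the bundled XML dialect (gold pairs
    are retrievable from the same file via :func:`read_gold`).

    Sequential ids ``d1, d2, ...`` are assigned for the plain dialects;
    the XML dialect carries explicit ids, which must be unique.
    """
    path = Path(path)
    if format not in DOCUMENT_FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {DOCUMENT_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "xml-gold":
        docs, _ = _read_xml_gold(path)
        return docs

    text = _normalize_newlines(path.read_text(encoding="utf-8"))
    if format == "plain":
        chunks = [c.strip() for c in text.split("\n\n")]
        bodies = [c for c in chunks if c]
    else:  # one-per-line
        bodies = [line.strip() for line in text.split("\n") if line.strip()]

    if not bodies:
        logger.warning("no documents found in %s", path)
    return [Document(f"d{i + 1}", body) for i, body in enumerate(bodies)]


def _read_xml_gold(path: Path) -> tuple[list[Document], list[GoldPair]]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: malformed XML: {exc}") from exc

    docs: list[Document] = []
    pairs: list[GoldPair] = []
    seen: set[str] = set()
    for elem in tree.getroot().iter("doc"):
        doc_id = elem.get("id")
        if not doc_id:
            raise FormatError(
                f"{path}:{elem.sourceline}: <doc> element missing id attribute"
            )
        if doc_id in seen:
            raise FormatError(f"{path}:{elem.sourceline}: duplicate doc id {doc_id!r}")
        seen.add(doc_id)
        text_elem = elem.find("text")
        if text_elem is None:
            raise FormatError(f"{path}:{elem.sourceline}: <doc id={doc_id!r}> has no <text>")
        docs.append(Document(doc_id, _normalize_newlines(text_elem.text or "")))
        for pair_elem in elem.iter("pair"):
            sf, lf = pair_elem.get("sf"), pair_elem.get("lf")
            if not sf or not lf:
                raise FormatError(
                    f"{path}:{pair_elem.sourceline}: <pair> needs non-empty sf and lf"
                )
            pairs.append(GoldPair(doc_id, sf, lf))
        for child in elem:
            if child.tag not in ("text", "pair"):
                logger.info("ignoring unrecognized element <%s> in doc %s", child.tag, doc_id)
    if not docs:
        logger.warning("no <doc> records found in %s", path)
    return docs, pairs


def write_xml_gold(
    docs: Sequence[Document], pairs: Sequence[GoldPair], path: str | Path
) -> None:
    """Write documents plus their gold pairs in the XML dialect."""
    root = etree.Element("corpus")
    by_doc: dict[str, list[GoldPair]] = {}
    for p in pairs:
        by_doc.setdefault(p.doc_id, []).append(p)
    for doc in docs:
        doc_elem = etree.SubElement(root, "doc", id=doc.doc_id)
        text_elem = etree.SubElement(doc_elem, "text")
        text_elem.text = doc.text
        for p in by_doc.get(doc.doc_id, []):
            etree.SubElement(doc_elem, "pair", sf=p.sf, lf=p.lf)
    Path(path).write_bytes(
        etree.tostring(root, encoding="UTF-8", xml_declaration=True, pretty_print=True)
    )


def _check_no_tab(value: str, what: str, where: str) -> None:
    if "\t" in value:
        raise FormatError(f"{where}: tab character inside {what} is not supported")


def read_gold(path: str | Path) -> list[GoldPair]:
    """Read gold pairs from TSV (doc_id, sf, lf; header optional) or the XML dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    head = path.read_bytes()[:64].lstrip()
    if head.startswith(b"<"):
        _, pairs = _read_xml_gold(path)
        return pairs

    pairs = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if lineno == 1 and [c.lower() for c in cells[:3]] == list(GOLD_COLUMNS):
                continue  # header
            if len(cells) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            doc_id, sf, lf = cells[0].strip(), cells[1].strip(), cells[2].strip()
            if not sf or not lf:
                raise FormatError(f"{path}:{lineno}: empty sf or lf")
            try:
                pairs.append(GoldPair(doc_id, sf, lf))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return pairs


def read_nbest(path: str | Path) -> list[NBestEntry]:
    """Read n-best entries; ranks within each (doc_id, sf, system) group must be 0..k-1."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: list[NBestEntry] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if lineno == 1 and [c.lower() for c in cells[:5]] == list(NBEST_COLUMNS):
                continue
            if len(cells) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 tab-separated columns")
            try:
                rank = int(cells[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: rank {cells[2]!r} is not an integer") from exc
            try:
                entries.append(
                    NBestEntry(cells[0].strip(), cells[1].strip(), cells[3].strip(), rank, cells[4].strip())
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    validate_nbest_groups(entries)
    return entries


def validate_nbest_groups(entries: Iterable[NBestEntry]) -> None:
    """Check that ranks in each (doc_id, sf, system) group are consecutive from 0."""
    groups: dict[tuple[str, str, str], list[int]] = {}
    for e in entries:
        groups.setdefault((e.doc_id, e.sf, e.system), []).append(e.rank)
    for key, ranks in groups.items():
        if sorted(ranks) != list(range(len(ranks))):
            raise FormatError(
                f"group {key}: ranks {sorted(ranks)} are not consecutive from 0"
            )


def write_pairs(pairs: Sequence, path: str | Path) -> None:
    """Write extracted pairs as TSV (doc_id, sf, lf, score), header included.

    Accepts :class:`ExtractedPair`, :class:`GoldPair` (score defaults to 1)
    or anything with doc_id/sf/lf attributes.  Rows are written in input
    order; callers keep document order then text offset.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for p in pairs:
            score = getattr(p, "score", 1.0)
            for val, what in ((p.doc_id, "doc_id"), (p.sf, "sf"), (p.lf, "lf")):
                _check_no_tab(val, what, str(path))
            fh.write(f"{p.doc_id}\t{p.sf}\t{p.lf}\t{score:g}\n")


def write_nbest(entries: Sequence[NBestEntry], path: str | Path) -> None:
    """Write n-best entries as TSV (doc_id, sf, rank, lf_candidate, system)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(NBEST_COLUMNS) + "\n")
        for e in entries:
            fh.write(f"{e.doc_id}\t{e.sf}\t{e.rank}\t{e.lf_candidate}\t{e.system}\n")


def write_documents(docs: Sequence[Document], path: str | Path) -> None:
    """Write documents blank-line separated (the plain dialect)."""
    Path(path).write_text(
        "\n\n".join(doc.text for doc in docs) + "\n", encoding="utf-8"
    )


def export_squad(mentions: Sequence) -> str:
    """Convert definition mentions to SQuAD v1.1 JSON text.

    Each mention becomes one question "What does <SF> stand for?" with the
    definition sentence as context and the LF span as the answer.  The
    recorded LF offset must index an exact occurrence of the LF in the
    context.
    """
    data = []
    for i, m in enumerate(mentions):
        context = m.sentence
        start = m.lf_span[0]
        if context[start:start + len(m.lf)] != m.lf:
            raise ValueError(
                f"mention {i} ({m.sf!r}): LF {m.lf!r} not found at offset {start} of context"
            )
        data.append(
            {
                "title": m.doc_id,
                "paragraphs": [
                    {
                        "context": context,
                        "qas": [
                            {
                                "id": f"{m.doc_id}-{m.sf}-{i}",
                                "question": f"What does {m.sf} stand for?",
                                "answers": [{"text": m.lf, "answer_start": start}],
                            }
                        ],
                    }
                ],
            }
        )
    return json.dumps({"version": "1.1", "data": data}, ensure_ascii=False, indent=1)
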