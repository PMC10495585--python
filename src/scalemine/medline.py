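"""Reading and writing article records in MEDLINE/PubMed text format.

The field-tagged plain-text export of PubMed ("PMID- ", "TI  - ", "AB  - ",
"MH  - " lines, continuations indented six spaces) is the exchange format the
rest of the pipeline consumes.  Parsing of field content is delegated to
:mod:`Bio.Medline`; this module adds the contracts the pipeline relies on:
line-grammar validation with line numbers, duplicate-PMID detection, the
requirement that every record carries a title, and the structured split of
``MH`` values into descriptor, qualifiers and major-topic flag.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

from Bio import Medline as _biomedline

__all__ = [
    "MeshHeading",
    "ArticleRecord",
    "MedlineParseError",
    "parse_medline",
    "write_medline",
    "read_medline_file",
    "write_medline_file",
]


class MedlineParseError(ValueError):
    """Raised when MEDLINE input violates the field-tagged line grammar."""


# A field-start line: tag of 1-4 chars padded to width 4, then "- ".
_FIELD_RE = re.compile(r"^[A-Z][A-Z0-9]{0,3} {0,3}- ")
_CONTINUATION_RE = re.compile(r"^ {6}")


@dataclass(frozen=True)
class MeshHeading:
    """One MH line: a descriptor plus optional qualifiers.

    ``major_topic`` records whether any segment of the raw value carried an
    asterisk; ``major_index`` remembers which segment (0 = the descriptor)
    so the writer can reproduce the raw value.
    """

    descriptor: str
    qualifiers: tuple[str, ...] = ()
    major_topic: bool = False
    major_index: int = 0

    def __post_init__(self) -> None:
        if not self.descriptor:
            raise ValueError("MeSH heading descriptor must be non-empty")
        if "/" in self.descriptor or self.descriptor.endswith("*"):
            raise ValueError(f"descriptor not normalized: {self.descriptor!r}")

    def raw(self) -> str:
        """Re-serialize to the MH field value (leading-star convention)."""
        segments = [self.descriptor, *self.qualifiers]
        if self.major_topic:
            i = self.major_index if self.major_index < len(segments) else 0
            segments[i] = "*" + segments[i]
        return "/".join(segments)

    @classmethod
    def from_raw(cls, value: str) -> "MeshHeading":
        segments = value.split("/")
        major = False
        major_index = 0
        cleaned = []
        for i, seg in enumerate(segments):
            s = seg.strip()
            if s.startswith("*") or s.endswith("*"):
                major = True
                major_index = i
                s = s.strip("*")
            cleaned.append(s)
        if not cleaned or not cleaned[0]:
            raise ValueError(f"empty MH descriptor in {value!r}")
        return cls(
            descriptor=cleaned[0],
            qualifiers=tuple(q for q in cleaned[1:] if q),
            major_topic=major,
            major_index=major_index,
        )


@dataclass
class ArticleRecord:
    """A PubMed article: PMID, title, abstract and MeSH headings.

    ``extra`` preserves fields the pipeline does not use (AU, DP, ...)
    opaquely; they are dropped on write by default.
    """

    pmid: str
    title: str
    abstract: str = ""
    headings: list[MeshHeading] = field(default_factory=list)
    extra: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        if not self.title:
            raise ValueError(f"record {self.pmid}: title must be non-empty")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArticleRecord):
            return NotImplemented
        return (
            self.pmid == other.pmid
            and self.title == other.title
            and self.abstract == other.abstract
            and self.headings == other.headings
        )


def _validate_grammar(text: str) -> None:
    """Check every line is a field start, a continuation, or blank."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if _FIELD_RE.match(line) or _CONTINUATION_RE.match(line):
            continue
        raise MedlineParseError(
            f"line {lineno}: malformed MEDLINE line (expected 'TAG - value' "
            f"or 6-space continuation): {line[:60]!r}"
        )


def parse_medline(stream) -> list[ArticleRecord]:
    """Parse MEDLINE text into article records.

    Parameters
    ----------
    stream : str or text file object
        Empty input or a concatenation of field-tagged records, each with a
        PMID line.  Continuation lines (6 leading spaces) are joined to the
        previous field value with a single space.

    Returns
    -------
    list of ArticleRecord

    Raises
    ------
    MedlineParseError
        On a malformed field line (with its line number), a record without
        PMID or TI, or a duplicate PMID within the input.
    """
    text = stream if isinstance(stream, str) else stream.read()
    if not text.strip():
        return []
    _validate_grammar(text)

    records: list[ArticleRecord] = []
    seen: set[str] = set()
    for raw in _biomedline.parse(io.StringIO(text)):
        pmid = raw.get("PMID")
        if not pmid:
            raise MedlineParseError("record without PMID field")
        if isinstance(pmid, list):
            pmid = pmid[0]
        if pmid in seen:
            raise MedlineParseError(f"duplicate PMID {pmid} in input")
        seen.add(pmid)
        title = raw.get("TI", "")
        if not title:
            raise MedlineParseError(f"record {pmid}: missing TI field")
        headings = [MeshHeading.from_raw(v) for v in raw.get("MH", [])]
        extra = {
            k: (v if isinstance(v, list) else [v])
            for k, v in raw.items()
            if k not in ("PMID", "TI", "AB", "MH")
        }
        records.append(
            ArticleRecord(
                pmid=pmid,
                title=title,
                abstract=raw.get("AB", ""),
                headings=headings,
                extra=extra,
            )
        )
    return records


def _emit(tag: str, value: str) -> str:
    return f"{tag:<4}- {value}\n"


def write_medline(records: list[ArticleRecord]) -> str:
    """Serialize records to MEDLINE text.

    Values are written unwrapped (one physical line per field) so that the
    output reparses losslessly; field order is PMID, TI, AB, MH.  Unknown
    preserved fields are omitted.  Raises ``ValueError`` before emitting
    anything if a record violates its invariants (including duplicate PMIDs).
    """
    seen: set[str] = set()
    for rec in records:
        if not rec.pmid or not rec.title:
            raise ValueError(f"invalid record: pmid={rec.pmid!r}")
        if rec.pmid in seen:
            raise ValueError(f"duplicate PMID {rec.pmid} in record list")
        seen.add(rec.pmid)
        for h in rec.headings:
            if not h.descriptor:
                raise ValueError(f"record {rec.pmid}: empty MH descriptor")

    blocks = []
    for rec in records:
        lines = [_emit("PMID", rec.pmid), _emit("TI", rec.title)]
        if rec.abstract:
            lines.append(_emit("AB", rec.abstract))
        for h in rec.headings:
            lines.append(_emit("MH", h.raw()))
        blocks.append("".join(lines))
    return "\n".join(blocks)


def read_medline_file(path) -> list[ArticleRecord]:
    with open(path, encoding="utf-8") as fh:
        return parse_medline(fh)


def write_medline_file(records: list[ArticleRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_medline(records))
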