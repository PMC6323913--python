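"""DESC flatfile dialect: read/write property records and release files.

The on-disk format follows the two-letter line-code convention of the
Pfam/TIGRFAMs DESC files: ``CODE␣␣value`` (code and value separated by two
spaces), records terminated by ``//``.  The top half of a record describes
the property (AC accession, DE name, TP type, AU author, TH threshold,
RN/RM/RT/RA/RL literature reference blocks, DR cross-references, CC
free-text description); the bottom half, starting at the first SN line, is
the step list (SN number, ID step id, DN display name, RQ required flag,
EV evidence accessions, TG ontology terms).

A release file (``genomeProperties.txt``) is simply the concatenation of
the DESC records of all public properties.

Sidecars: a two-column status file records whether each property has been
checked and may be published, and a FASTA file provides example sequences
per InterPro-evidenced step (linked by a ``step=N`` token in the header).
"""

from __future__ import annotations

import io
import textwrap
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .model import (
    CrossRef,
    DuplicateAccessionError,
    Evidence,
    GenomeProperty,
    PropertyRegistry,
    PropertyType,
    Reference,
    Step,
)

__all__ = [
    "DescParseError",
    "StatusRecord",
    "FastaSidecar",
    "parse_desc",
    "write_desc",
    "parse_flatfile",
    "write_flatfile",
    "load_status",
    "write_status",
    "load_fasta",
    "write_fasta",
]

#: line codes understood by the parser; anything else is preserved verbatim
HEADER_CODES = {"AC", "DE", "TP", "AU", "TH", "RN", "RM", "RT", "RA", "RL", "CC", "DR"}
STEP_CODES = {"SN", "ID", "DN", "RQ", "EV", "TG"}
TERMINATOR = "//"
CC_WRAP_COLUMN = 80


class DescParseError(ValueError):
    """A record violates the DESC dialect; carries the offending line number."""

    def __init__(self, message: str, line_no: Optional[int] = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class StatusRecord:
    """Curation status of one property: releasable iff checked and public."""

    accession: str
    checked: bool
    public: bool

    @property
    def releasable(self) -> bool:
        return self.checked and self.public


@dataclass
class FastaSidecar:
    """Example sequences for a property, one or more per InterPro step.

    ``step_map`` links each FASTA header to the step number declared by its
    ``step=N`` token; headers without the token stay out of the map.
    """

    accession: str
    sequences: list[tuple[str, str]] = field(default_factory=list)
    step_map: dict[str, int] = field(default_factory=dict)

    def covered_steps(self) -> set[int]:
        return set(self.step_map.values())


def _split_line(line: str, line_no: int) -> tuple[str, str]:
    code = line[:2]
    rest = line[2:]
    if len(code) < 2 or not code.isalpha() or not code.isupper():
        raise DescParseError(f"unrecognisable line {line!r}", line_no)
    if rest and not rest.startswith("  "):
        raise DescParseError(
            f"code and value must be separated by two spaces: {line!r}", line_no
        )
    return code, rest[2:].rstrip()


def _parse_ev_value(value: str, line_no: int, permissive: bool) -> Evidence:
    tokens = [t.strip() for t in value.split(";")]
    tokens = [t for t in tokens if t]
    if not tokens:
        raise DescParseError(f"EV line with no parsable accession: {value!r}", line_no)
    try:
        return Evidence(tokens[0], tuple(tokens[1:]), permissive=permissive)
    except ValueError as exc:
        raise DescParseError(str(exc), line_no) from None


def parse_desc(text: str, permissive: bool = False) -> GenomeProperty:
    """Parse one complete DESC record into a :class:`GenomeProperty`.

    Mandatory header fields are AC, DE and TP; TH defaults to 0 when
    absent.  The step block starts at the first SN line.  Unknown line
    codes are preserved as opaque ``extras`` so that records written by a
    newer dialect survive a round trip.  CC text is whitespace-normalised
    (it is re-wrapped on write).
    """
    header: dict[str, str] = {}
    cc_parts: list[str] = []
    refs: list[dict[str, str]] = []
    xrefs: list[CrossRef] = []
    extras: list[tuple[str, str]] = []
    steps: list[Step] = []

    # current step accumulator
    cur: Optional[dict] = None

    def flush_step(line_no: int) -> None:
        nonlocal cur
        if cur is None:
            return
        if not cur["evidences"]:
            raise DescParseError(
                f"step {cur['number']} has no EV line", line_no
            )
        steps.append(
            Step(
                number=cur["number"],
                id=cur.get("id", f"step_{cur['number']}"),
                display_name=cur.get("display_name"),
                required=cur.get("required", True),
                evidences=tuple(cur["evidences"]),
                go_terms=tuple(cur["go_terms"]),
            )
        )
        cur = None

    in_steps = False
    line_no = 0
    for raw in io.StringIO(text):
        line_no += 1
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if line.strip() == TERMINATOR:
            break
        code, value = _split_line(line, line_no)

        if code == "SN":
            in_steps = True
            flush_step(line_no)
            try:
                number = int(value)
            except ValueError:
                raise DescParseError(f"non-integer step number {value!r}", line_no) from None
            cur = {"number": number, "evidences": [], "go_terms": []}
            continue

        if in_steps:
            if cur is None:
                raise DescParseError(f"step code {code} before any SN line", line_no)
            if code == "ID":
                cur["id"] = value
            elif code == "DN":
                cur["display_name"] = value
            elif code == "RQ":
                if value not in {"0", "1"}:
                    raise DescParseError(f"RQ must be 0 or 1, got {value!r}", line_no)
                cur["required"] = value == "1"
            elif code == "EV":
                cur["evidences"].append(_parse_ev_value(value, line_no, permissive))
            elif code == "TG":
                cur["go_terms"].extend(
                    t.strip() for t in value.split(";") if t.strip()
                )
            else:
                extras.append((code, value))
            continue

        # header half
        if code == "CC":
            cc_parts.append(value)
        elif code == "RN":
            refs.append({"number": value.strip("[]")})
        elif code in {"RM", "RT", "RA", "RL"}:
            if not refs:
                raise DescParseError(f"{code} line before RN", line_no)
            key = {"RM": "pmid", "RT": "title", "RA": "authors", "RL": "journal"}[code]
            refs[-1][key] = (refs[-1].get(key, "") + " " + value).strip()
        elif code == "DR":
            tokens = [t.strip() for t in value.split(";") if t.strip()]
            if len(tokens) < 2:
                raise DescParseError(f"DR line needs 'DB; ID;': {value!r}", line_no)
            xrefs.append(CrossRef(tokens[0], tokens[1]))
        elif code in {"AC", "DE", "TP", "AU", "TH"}:
            if code in header:
                raise DescParseError(f"duplicate {code} line", line_no)
            header[code] = value
        else:
            extras.append((code, value))

    flush_step(line_no)

    for mandatory in ("AC", "DE", "TP"):
        if mandatory not in header:
            raise DescParseError(f"missing mandatory field {mandatory}")
    try:
        ptype = PropertyType(header["TP"].upper())
    except ValueError:
        raise DescParseError(f"unknown type token {header['TP']!r}") from None
    th_raw = header.get("TH", "0")
    try:
        threshold = int(th_raw)
    except ValueError:
        raise DescParseError(f"non-integer TH value {th_raw!r}") from None

    references = tuple(
        Reference(
            number=int(r.get("number", i + 1)),
            pmid=r.get("pmid", ""),
            title=r.get("title", ""),
            authors=r.get("authors", ""),
            journal=r.get("journal", ""),
        )
        for i, r in enumerate(refs)
    )
    description = " ".join(" ".join(cc_parts).split())

    return GenomeProperty(
        accession=header["AC"],
        name=header["DE"],
        type=ptype,
        threshold=threshold,
        description=description,
        author=header.get("AU", ""),
        references=references,
        xrefs=tuple(xrefs),
        steps=tuple(steps),
        extras=tuple(extras),
        permissive=permissive,
    )


def _emit(code: str, value: str) -> str:
    return f"{code}  {value}\n"


def write_desc(prop: GenomeProperty) -> str:
    """Serialise a property to its DESC record (terminated by ``//``).

    Inverse of :func:`parse_desc` on the structural model: the CC text is
    re-wrapped at a fixed column, so the round trip preserves the
    whitespace-normalised description rather than original line breaks.
    """
    out: list[str] = []
    out.append(_emit("AC", prop.accession))
    out.append(_emit("DE", prop.name))
    out.append(_emit("TP", prop.type.value))
    if prop.author:
        out.append(_emit("AU", prop.author))
    out.append(_emit("TH", str(prop.threshold)))
    for ref in prop.references:
        out.append(_emit("RN", f"[{ref.number}]"))
        if ref.pmid:
            out.append(_emit("RM", ref.pmid))
        if ref.title:
            out.append(_emit("RT", ref.title))
        if ref.authors:
            out.append(_emit("RA", ref.authors))
        if ref.journal:
            out.append(_emit("RL", ref.journal))
    for xref in prop.xrefs:
        out.append(_emit("DR", f"{xref.database}; {xref.id};"))
    if prop.description:
        for line in textwrap.wrap(prop.description, width=CC_WRAP_COLUMN - 4):
            out.append(_emit("CC", line))
    for code, value in prop.extras:
        out.append(_emit(code, value))
    for step in prop.steps:
        out.append(_emit("SN", str(step.number)))
        out.append(_emit("ID", step.id))
        if step.display_name:
            out.append(_emit("DN", step.display_name))
        out.append(_emit("RQ", "1" if step.required else "0"))
        for ev in step.evidences:
            tokens = [ev.accession, *ev.raw_signatures]
            out.append(_emit("EV", "; ".join(tokens) + ";"))
        if step.go_terms:
            out.append(_emit("TG", "; ".join(step.go_terms) + ";"))
    out.append(TERMINATOR + "\n")
    return "".join(out)


def _iter_records(text: str) -> Iterable[tuple[int, str]]:
    """Split concatenated DESC text on ``//`` lines, with start line numbers."""
    buf: list[str] = []
    start = 1
    for i, line in enumerate(text.splitlines(keepends=True), start=1):
        if line.strip() == TERMINATOR:
            buf.append(line)
            yield start, "".join(buf)
            buf = []
            start = i + 1
        else:
            buf.append(line)
    if any(l.strip() for l in buf):
        yield start, "".join(buf)


def parse_flatfile(
    source: Union[str, IO[str]],
    strict: bool = False,
    permissive: bool = False,
    errors: Optional[list] = None,
) -> PropertyRegistry:
    """Parse a concatenated release flatfile into a registry.

    Lenient by default: a malformed record is collected (appended to the
    caller-supplied ``errors`` list, or surfaced as a warning) and parsing
    continues; ``strict=True`` fails fast on the first bad record.
    Duplicate accessions across records are an error in either mode's
    collection.  Dangling property citations are *not* checked here; use
    :meth:`PropertyRegistry.unresolved_evidence` / :meth:`validate_graph`.
    """
    text = source.read() if hasattr(source, "read") else source
    text = text.replace("\r\n", "\n")
    registry = PropertyRegistry()
    collected = errors if errors is not None else []
    for start, record in _iter_records(text):
        try:
            prop = parse_desc(record, permissive=permissive)
            registry.register(prop)
        except (DescParseError, DuplicateAccessionError, ValueError) as exc:
            err = DescParseError(f"record starting at line {start}: {exc}")
            if strict:
                raise err from exc
            collected.append(err)
    if errors is None and collected:
        warnings.warn(
            f"{len(collected)} record(s) failed to parse: {collected[0]}",
            stacklevel=2,
        )
    return registry


def write_flatfile(registry: PropertyRegistry, public_only: bool = True) -> str:
    """Concatenate DESC records (accession order) into a release flatfile.

    Non-public properties are excluded from release files by default.
    """
    return "".join(
        write_desc(prop)
        for prop in registry
        if prop.public or not public_only
    )


# -- sidecars ---------------------------------------------------------------

def load_status(source: Union[str, IO[str]]) -> dict[str, StatusRecord]:
    """Read a status sidecar: ``accession<TAB>checked,public`` per line."""
    text = source.read() if hasattr(source, "read") else source
    out: dict[str, StatusRecord] = {}
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            accession, flags = line.split("\t")
            checked_s, public_s = flags.split(",")
            record = StatusRecord(
                accession.strip(),
                checked=checked_s.strip() in {"1", "true", "True"},
                public=public_s.strip() in {"1", "true", "True"},
            )
        except ValueError:
            raise DescParseError(f"malformed status line {line!r}", line_no) from None
        out[record.accession] = record
    return out


def write_status(records: Iterable[StatusRecord]) -> str:
    return "".join(
        f"{r.accession}\t{int(r.checked)},{int(r.public)}\n"
        for r in sorted(records, key=lambda r: r.accession)
    )


def load_fasta(source: Union[str, IO[str]], accession: str = "") -> FastaSidecar:
    """Read a FASTA sidecar, extracting the ``step=N`` header token.

    Headers lacking the token keep their sequence but get no step mapping
    (a warning is emitted); duplicate headers and empty sequences are
    errors.
    """
    handle = io.StringIO(source) if isinstance(source, str) else source
    sidecar = FastaSidecar(accession=accession)
    seen: set[str] = set()
    for header, seq in SimpleFastaParser(handle):
        if header in seen:
            raise ValueError(f"duplicate FASTA header {header!r}")
        seen.add(header)
        seq = seq.strip()
        if not seq:
            raise ValueError(f"empty sequence for header {header!r}")
        sidecar.sequences.append((header, seq))
        step = None
        for token in header.split():
            if token.startswith("step="):
                try:
                    step = int(token[5:])
                except ValueError:
                    raise ValueError(f"bad step token in header {header!r}") from None
        if step is None:
            warnings.warn(f"FASTA header {header!r} lacks a step=N token", stacklevel=2)
        else:
            sidecar.step_map[header] = step
    return sidecar


def write_fasta(sidecar: FastaSidecar, width: int = 60) -> str:
    out = []
    for header, seq in sidecar.sequences:
        out.append(f">{header}\n")
        for i in range(0, len(seq), width):
            out.append(seq[i : i + width] + "\n")
    return "".join(out)
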