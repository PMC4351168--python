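"""Readers and writers for the three tabular inputs and the error report.

Three artifact kinds flow through the pipeline:

* **query lists** — trait-associated SNPs with rsID and GRCh37 coordinates
  (TSV; one trait per row, repeated rows encode pleiotropy);
* **array manifests** — vendor product files listing every probe with its
  chromosome and position, rsID optional (CSV, ``Name,Chr,MapInfo,RsID``-style
  columns by default);
* **tool outputs** — a query tool's per-SNP availability claims, possibly
  carrying free-text WARNING annotations (TSV).

Parsing is *total*: every input row either becomes a record or lands in the
error report with its row number, raw text and a reason — nothing is silently
dropped.  Chromosome labels are normalized at parse time so that positional
matching never fails on labelling conventions ("chr7" vs "7", "23" vs "X").
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: Normalized chromosome alphabet: autosomes 1-22, X, Y, MT.
CHROMOSOMES = tuple(str(c) for c in range(1, 23)) + ("X", "Y", "MT")

_RSID_RE = re.compile(r"^rs\d+$")

#: Warning categories a tool can attach to a claim.
WARNING_NONE = "none"
WARNING_NOT_IN_REFERENCE = "not_in_reference"
WARNING_NOT_ON_ARRAY = "not_on_array"

_MISSING_TOKENS = {"", "na", "n/a", "nan", ".", "none", "-"}


def normalize_chrom(label: str) -> str:
    """Map a chromosome label onto the normalized alphabet.

    Strips a ``chr`` prefix, uppercases X/Y/MT, and folds the numeric aliases
    23 -> X, 24 -> Y, 26/M -> MT.  Raises :class:`ValueError` for anything
    outside the alphabet.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    s = {"23": "X", "24": "Y", "26": "MT", "M": "MT"}.get(s, s)
    if s not in CHROMOSOMES:
        raise ValueError(f"unrecognized chromosome label: {label!r}")
    return s


def _validate_rsid(rsid: str) -> str:
    rsid = rsid.strip()
    if not _RSID_RE.match(rsid):
        raise ValueError(f"malformed rsID: {rsid!r}")
    return rsid


def _validate_pos(pos: object) -> int:
    p = int(str(pos).strip())
    if p < 1:
        raise ValueError(f"position must be >= 1, got {p}")
    return p


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpQuery:
    """One queried variant: rsID, GRCh37 coordinate, and its trait labels."""

    rsid: str
    chrom: str
    pos: int
    traits: frozenset[str]
    build: str = "GRCh37"

    def __post_init__(self):
        object.__setattr__(self, "rsid", _validate_rsid(self.rsid))
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "pos", _validate_pos(self.pos))
        object.__setattr__(self, "traits", frozenset(self.traits))
        if not self.traits:
            raise ValueError(f"{self.rsid}: traits must be non-empty")


@dataclass(frozen=True)
class ManifestEntry:
    """One array probe: name, coordinate, and an optional rsID.

    Vendor product files do not carry rs numbers for every probe, which is
    precisely why membership is decided by position, never by rsID.
    """

    probe_name: str
    chrom: str
    pos: int
    rsid: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "pos", _validate_pos(self.pos))
        if self.rsid is not None:
            object.__setattr__(self, "rsid", _validate_rsid(self.rsid))


@dataclass(frozen=True)
class ToolClaim:
    """A tool's availability verdict for one rsID on one array.

    ``warning`` is one of ``none`` / ``not_in_reference`` / ``not_on_array``;
    any warning forces ``claimed_present=False`` (a warned SNP is treated as
    missing by the tool even when it sits on the chip).
    """

    rsid: str
    array_name: str
    claimed_present: bool
    warning: str = WARNING_NONE
    reference: str | None = None
    warning_text: str = ""

    def __post_init__(self):
        object.__setattr__(self, "rsid", _validate_rsid(self.rsid))
        if self.warning not in (WARNING_NONE, WARNING_NOT_IN_REFERENCE, WARNING_NOT_ON_ARRAY):
            raise ValueError(f"unknown warning category: {self.warning!r}")
        if self.warning != WARNING_NONE and self.claimed_present:
            raise ValueError(
                f"{self.rsid}: a warning implies the tool claims the SNP absent"
            )
        if self.warning != WARNING_NONE and not self.warning_text:
            # canonical text so written files re-parse to the same category
            if self.warning == WARNING_NOT_ON_ARRAY:
                text = "WARNING Query snp not on any selected array"
            else:
                panel = {"HapMap3": "HapMap3_r2", "1000Genomes": "1000GenomesPilot1"}.get(
                    self.reference or "", self.reference or "reference panel")
                text = f"WARNING Query snp not in {panel}"
            object.__setattr__(self, "warning_text", text)


# ---------------------------------------------------------------------------
# dialects and parse results
# ---------------------------------------------------------------------------

@dataclass
class QueryDialect:
    """Column-name mapping and delimiter for query-list files."""

    delimiter: str = "\t"
    rsid: str = "rsid"
    chrom: str = "chrom"
    pos: str = "pos"
    trait: str = "trait"


@dataclass
class ManifestDialect:
    """Column-name mapping and delimiter for manifest files (vendor CSV)."""

    delimiter: str = ","
    probe_name: str = "Name"
    chrom: str = "Chr"
    pos: str = "MapInfo"
    rsid: str = "RsID"


@dataclass
class ClaimDialect:
    """Column-name mapping and delimiter for tool-output files."""

    delimiter: str = "\t"
    rsid: str = "rsid"
    array: str = "array"
    available: str = "available"
    warning: str = "warning"


@dataclass(frozen=True)
class RowError:
    """One rejected input row: position, raw text, and the reason."""

    row_number: int
    raw: str
    reason: str


@dataclass
class ParseResult:
    """Records plus the rejected rows; ``n_input = len(records') + len(errors)``
    where records' counts source rows (merged pleiotropy rows count per row)."""

    records: list
    errors: list[RowError] = field(default_factory=list)
    n_input_rows: int = 0


def _read_table(path: str | Path, delimiter: str) -> tuple[list[str], list[tuple[int, list[str], str]]]:
    """Read a delimited text file, skipping ``#`` comment lines.

    Returns the header cells and a list of (row_number, cells, raw_line); row
    numbers are 1-based over the physical file.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file does not exist: {path}")
    header: list[str] | None = None
    rows: list[tuple[int, list[str], str]] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            raw = line.rstrip("\n")
            if not raw.strip() or raw.lstrip().startswith("#"):
                continue
            cells = next(csv.reader([raw], delimiter=delimiter))
            if header is None:
                header = [c.strip() for c in cells]
            else:
                rows.append((lineno, cells, raw))
    if header is None:
        raise ConfigurationError(f"{path}: no header line found")
    return header, rows


def _column_map(header: Sequence[str], wanted: dict[str, str], path, optional=()) -> dict[str, int]:
    """Resolve field -> column index; missing mandatory columns are fatal."""
    lower = {h.lower(): i for i, h in enumerate(header)}
    out = {}
    for fieldname, colname in wanted.items():
        idx = lower.get(colname.lower())
        if idx is None:
            if fieldname in optional:
                continue
            raise ConfigurationError(
                f"{path}: mandatory column {colname!r} (-> {fieldname}) not in header {list(header)}"
            )
        out[fieldname] = idx
    return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_query_list(
    path: str | Path,
    dialect: QueryDialect | None = None,
    build: str = "GRCh37",
) -> ParseResult:
    """Parse a query list into :class:`SnpQuery` records.

    Rows sharing an rsID merge into one record with the union of traits,
    provided their coordinates agree; conflicting coordinates for one rsID
    raise :class:`ValidationError` naming the rsID.  Malformed rows go to the
    error report.
    """
    dialect = dialect or QueryDialect()
    header, rows = _read_table(path, dialect.delimiter)
    cols = _column_map(
        header,
        {"rsid": dialect.rsid, "chrom": dialect.chrom, "pos": dialect.pos, "trait": dialect.trait},
        path,
    )

    by_rsid: dict[str, SnpQuery] = {}
    order: list[str] = []
    errors: list[RowError] = []
    for lineno, cells, raw in rows:
        try:
            rsid = _validate_rsid(cells[cols["rsid"]])
            chrom = normalize_chrom(cells[cols["chrom"]])
            pos = _validate_pos(cells[cols["pos"]])
            trait = cells[cols["trait"]].strip()
            if not trait:
                raise ValueError("empty trait label")
        except (ValueError, IndexError) as exc:
            errors.append(RowError(lineno, raw, str(exc)))
            continue
        if rsid in by_rsid:
            prev = by_rsid[rsid]
            if (prev.chrom, prev.pos) != (chrom, pos):
                raise ValidationError(
                    f"{path}: rsID {rsid} appears with conflicting coordinates "
                    f"({prev.chrom}:{prev.pos} vs {chrom}:{pos})"
                )
            by_rsid[rsid] = replace(prev, traits=prev.traits | {trait})
        else:
            by_rsid[rsid] = SnpQuery(rsid, chrom, pos, frozenset({trait}), build=build)
            order.append(rsid)

    queries = [by_rsid[r] for r in order]
    logger.info("read %d query rows -> %d SNPs (%d rejected) from %s",
                len(rows), len(queries), len(errors), path)
    return ParseResult(records=queries, errors=errors, n_input_rows=len(rows))


def read_manifest(
    path: str | Path,
    dialect: ManifestDialect | None = None,
) -> ParseResult:
    """Parse a vendor-style manifest into :class:`ManifestEntry` records.

    Entries without an rsID are retained — the downstream membership check is
    purely positional.  Duplicate probe names raise :class:`ValidationError`.
    """
    dialect = dialect or ManifestDialect()
    header, rows = _read_table(path, dialect.delimiter)
    cols = _column_map(
        header,
        {"probe_name": dialect.probe_name, "chrom": dialect.chrom,
         "pos": dialect.pos, "rsid": dialect.rsid},
        path,
        optional=("rsid",),
    )

    entries: list[ManifestEntry] = []
    errors: list[RowError] = []
    seen: set[str] = set()
    for lineno, cells, raw in rows:
        try:
            name = cells[cols["probe_name"]].strip()
            if not name:
                raise ValueError("empty probe name")
            if name in seen:
                raise ValidationError(f"{path}: duplicate probe_name {name!r}")
            chrom = normalize_chrom(cells[cols["chrom"]])
            pos = _validate_pos(cells[cols["pos"]])
            rsid: str | None = None
            if "rsid" in cols and cols["rsid"] < len(cells):
                cell = cells[cols["rsid"]].strip()
                if cell.lower() not in _MISSING_TOKENS:
                    rsid = _validate_rsid(cell)
        except ValidationError:
            raise
        except (ValueError, IndexError) as exc:
            errors.append(RowError(lineno, raw, str(exc)))
            continue
        seen.add(name)
        entries.append(ManifestEntry(name, chrom, pos, rsid))

    if not entries:
        logger.warning("manifest %s has an empty data section", path)
    logger.info("parsed %d manifest entries (%d rejected) from %s",
                len(entries), len(errors), path)
    return ParseResult(records=entries, errors=errors, n_input_rows=len(rows))


def parse_warning_text(text: str) -> tuple[str, str | None]:
    """Classify a free-text WARNING into a category and optional panel label.

    ``"... not in HapMap3_r2"``-style messages (the query SNP is absent from
    the reference panel) map to ``not_in_reference``; messages saying the SNP
    is on no selected array map to ``not_on_array``.
    """
    t = text.strip()
    if not t:
        return WARNING_NONE, None
    low = t.lower()
    m = re.search(r"not\s+in\s+(\S+)", low)
    if m and "array" not in m.group(1):
        token = m.group(1)
        if "hapmap" in token:
            return WARNING_NOT_IN_REFERENCE, "HapMap3"
        if "1000genomes" in token or "1kg" in token:
            return WARNING_NOT_IN_REFERENCE, "1000Genomes"
        return WARNING_NOT_IN_REFERENCE, None
    if "array" in low or "chip" in low:
        return WARNING_NOT_ON_ARRAY, None
    # unrecognized warning text: the SNP is still claimed absent
    return WARNING_NOT_IN_REFERENCE, None


def read_tool_output(
    path: str | Path,
    dialect: ClaimDialect | None = None,
    reference: str | None = None,
) -> ParseResult:
    """Parse a tool-output file into :class:`ToolClaim` records.

    Any WARNING text forces ``claimed_present=False``; a reference-panel label
    recognized inside the warning overrides the file-level ``reference``.  A
    row carrying neither an availability flag nor a warning is a
    :class:`ValidationError`.
    """
    dialect = dialect or ClaimDialect()
    header, rows = _read_table(path, dialect.delimiter)
    cols = _column_map(
        header,
        {"rsid": dialect.rsid, "array": dialect.array,
         "available": dialect.available, "warning": dialect.warning},
        path,
        optional=("warning",),
    )

    claims: list[ToolClaim] = []
    errors: list[RowError] = []
    for lineno, cells, raw in rows:
        try:
            rsid = _validate_rsid(cells[cols["rsid"]])
            array = cells[cols["array"]].strip()
            warn_text = cells[cols["warning"]].strip() if "warning" in cols and cols["warning"] < len(cells) else ""
            avail_cell = cells[cols["available"]].strip()
            category, ref_from_warning = parse_warning_text(warn_text)
            if category != WARNING_NONE:
                present = False
            elif avail_cell in {"1", "true", "True", "yes"}:
                present = True
            elif avail_cell in {"0", "false", "False", "no"}:
                present = False
            else:
                raise ValidationError(
                    f"{path} row {lineno}: rsID {rsid} has neither an availability "
                    f"flag nor a warning"
                )
        except ValidationError:
            raise
        except (ValueError, IndexError) as exc:
            errors.append(RowError(lineno, raw, str(exc)))
            continue
        claims.append(ToolClaim(
            rsid=rsid,
            array_name=array,
            claimed_present=present,
            warning=category,
            reference=ref_from_warning or reference,
            warning_text=warn_text,
        ))

    logger.info("parsed %d tool claims (%d rejected) from %s",
                len(claims), len(errors), path)
    return ParseResult(records=claims, errors=errors, n_input_rows=len(rows))


# ---------------------------------------------------------------------------
# writers (round-trip counterparts of the readers)
# ---------------------------------------------------------------------------

def write_query_list(queries: Iterable[SnpQuery], path: str | Path,
                     dialect: QueryDialect | None = None) -> None:
    """Write queries as TSV, one trait per row (pleiotropy = repeated rows)."""
    dialect = dialect or QueryDialect()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=dialect.delimiter)
        w.writerow([dialect.rsid, dialect.chrom, dialect.pos, dialect.trait])
        for q in queries:
            for trait in sorted(q.traits):
                w.writerow([q.rsid, q.chrom, q.pos, trait])


def write_manifest(entries: Iterable[ManifestEntry], path: str | Path,
                   dialect: ManifestDialect | None = None) -> None:
    dialect = dialect or ManifestDialect()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=dialect.delimiter)
        w.writerow([dialect.probe_name, dialect.chrom, dialect.pos, dialect.rsid])
        for e in entries:
            w.writerow([e.probe_name, e.chrom, e.pos, e.rsid or ""])


def write_tool_output(claims: Iterable[ToolClaim], path: str | Path,
                      dialect: ClaimDialect | None = None) -> None:
    dialect = dialect or ClaimDialect()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=dialect.delimiter)
        w.writerow([dialect.rsid, dialect.array, dialect.available, dialect.warning])
        for c in claims:
            w.writerow([c.rsid, c.array_name, int(c.claimed_present), c.warning_text])


def write_error_report(errors: Iterable[RowError], path: str | Path) -> None:
    """TSV report of rejected rows: row number, raw line, reason."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["row_number", "raw_line", "reason"])
        for e in errors:
            w.writerow([e.row_number, e.raw, e.reason])
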