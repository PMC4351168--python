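"""Join tool claims with positional ground truth and build 2x2 tables.

Ground truth (the manifest lookup) is always one axis, the audited tool's
claim the other.  The four joint outcomes follow the validation vocabulary:

* TP — on chip, tool says present (concordant);
* FN — on chip, tool says absent (the failure mode under audit);
* FP — off chip, tool says present;
* TN — off chip, tool says absent (concordant).

Per-trait tables intentionally double-count pleiotropic SNPs (one contribution
per associated trait); the pooled ``ALL`` table counts every rsID exactly once.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .errors import ValidationError
from .io import ToolClaim
from .membership import MembershipCall

#: Group label for the pooled, rsID-deduplicated table.
ALL = "ALL"


class Status(str, Enum):
    TP = "TP"
    FN = "FN"
    FP = "FP"
    TN = "TN"


def classify(manifest_present: bool, tool_present: bool) -> Status:
    """Map the (ground truth, claim) pair onto TP/FN/FP/TN."""
    if manifest_present:
        return Status.TP if tool_present else Status.FN
    return Status.FP if tool_present else Status.TN


@dataclass(frozen=True)
class ConcordanceRecord:
    """Per-SNP joined verdict for one reference panel."""

    rsid: str
    traits: frozenset[str]
    chrom: str
    pos: int
    reference: str
    manifest_present: bool
    tool_present: bool
    status: Status

    def __post_init__(self):
        expected = classify(self.manifest_present, self.tool_present)
        if self.status is not expected:
            raise ValueError(
                f"{self.rsid}: status {self.status} inconsistent with "
                f"(manifest={self.manifest_present}, tool={self.tool_present})"
            )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 agreement counts between manifest and tool."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def concordances(self) -> int:
        return self.tp + self.tn

    @property
    def discordances(self) -> int:
        return self.fn + self.fp


def join_and_classify(
    calls: Sequence[MembershipCall],
    claims: Iterable[ToolClaim],
    reference: str,
) -> list[ConcordanceRecord]:
    """Pair each membership call with the tool's claim under one reference.

    Every queried rsID must have exactly one claim for ``reference``; missing
    or duplicated claims raise :class:`ValidationError` naming the rsIDs.
    """
    pool = [c for c in claims if c.reference is None or c.reference == reference]
    counts = Counter(c.rsid for c in pool)
    wanted = [c.query.rsid for c in calls]
    missing = [r for r in wanted if counts[r] == 0]
    if missing:
        raise ValidationError(
            f"no {reference} claim for rsIDs: {', '.join(missing[:10])}"
            + (" ..." if len(missing) > 10 else "")
        )
    dups = sorted(r for r in set(wanted) if counts[r] > 1)
    if dups:
        raise ValidationError(
            f"multiple {reference} claims for rsIDs: {', '.join(dups[:10])}"
        )
    by_rsid = {c.rsid: c for c in pool}
    records = []
    for call in calls:
        claim = by_rsid[call.query.rsid]
        records.append(ConcordanceRecord(
            rsid=call.query.rsid,
            traits=call.query.traits,
            chrom=call.query.chrom,
            pos=call.query.pos,
            reference=reference,
            manifest_present=call.on_chip,
            tool_present=claim.claimed_present,
            status=classify(call.on_chip, claim.claimed_present),
        ))
    return records


def tabulate(records: Iterable[ConcordanceRecord], group: str = ALL) -> ContingencyTable:
    """Count records into a 2x2 table for one trait, or pooled over all.

    For ``group=ALL`` each rsID contributes once (pleiotropic SNPs
    deduplicate); an rsID seen with two different statuses is inconsistent
    input and raises :class:`ValidationError`.
    """
    cells = Counter()
    seen: dict[str, Status] = {}
    for rec in records:
        if group != ALL and group not in rec.traits:
            continue
        if rec.rsid in seen:
            if seen[rec.rsid] is not rec.status:
                raise ValidationError(
                    f"rsID {rec.rsid} carries conflicting statuses "
                    f"{seen[rec.rsid].value} and {rec.status.value}"
                )
            continue
        seen[rec.rsid] = rec.status
        cells[rec.status] += 1
    return ContingencyTable(
        tp=cells[Status.TP], fn=cells[Status.FN],
        fp=cells[Status.FP], tn=cells[Status.TN],
    )


def trait_labels(records: Iterable[ConcordanceRecord]) -> list[str]:
    """All trait labels present, sorted for deterministic iteration."""
    return sorted({t for r in records for t in r.traits})
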