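"""Positional membership: is a query SNP on the array?

This is the independent-standard half of the comparison.  Membership is
decided by exact (chromosome, position) match against the manifest — the rsID
is never consulted, which sidesteps stale or merged rs numbers in either
source.  There is no tolerance window and no liftover: a build-tag mismatch
between queries and index is a hard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import BuildMismatchError
from .io import ManifestEntry, SnpQuery

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PositionIndex:
    """Hash index from normalized (chrom, pos) to the probe names at that locus.

    Colliding probes (two probe designs at one locus) aggregate under one key;
    the total probe count always equals the manifest size.
    """

    build: str
    loci: Mapping[tuple[str, int], frozenset[str]]
    n_probes: int

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.loci

    def __len__(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class MembershipCall:
    """Outcome of one lookup: on-chip iff at least one probe shares the locus."""

    query: SnpQuery
    on_chip: bool
    matched_probes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.on_chip != bool(self.matched_probes):
            raise ValueError("on_chip must equal non-emptiness of matched_probes")


def build_position_index(entries: Iterable[ManifestEntry], build: str = "GRCh37") -> PositionIndex:
    """Index manifest entries by locus; collisions aggregate, never overwrite."""
    table: dict[tuple[str, int], set[str]] = {}
    n = 0
    for e in entries:
        table.setdefault((e.chrom, e.pos), set()).add(e.probe_name)
        n += 1
    return PositionIndex(
        build=build,
        loci={k: frozenset(v) for k, v in table.items()},
        n_probes=n,
    )


def check_membership(query: SnpQuery, index: PositionIndex) -> MembershipCall:
    """Decide on-chip status of one query by exact positional lookup."""
    if query.build != index.build:
        raise BuildMismatchError(
            f"{query.rsid}: query build {query.build!r} != index build "
            f"{index.build!r}; refusing to match across builds"
        )
    probes = index.loci.get((query.chrom, query.pos), frozenset())
    return MembershipCall(query=query, on_chip=bool(probes), matched_probes=probes)


def check_batch(queries: Iterable[SnpQuery], index: PositionIndex) -> list[MembershipCall]:
    """Look up every query, preserving order; logs on/off-chip totals.

    Two queries landing on the same locus (e.g. a tri-allelic site) both
    match; the collision is logged, not rejected.
    """
    calls = [check_membership(q, index) for q in queries]
    seen: dict[tuple[str, int], str] = {}
    for c in calls:
        key = (c.query.chrom, c.query.pos)
        if key in seen:
            logger.info("queries %s and %s share locus %s:%d",
                        seen[key], c.query.rsid, key[0], key[1])
        else:
            seen[key] = c.query.rsid
    n_on = sum(c.on_chip for c in calls)
    logger.info("membership: %d on-chip, %d off-chip of %d queries",
                n_on, len(calls) - n_on, len(calls))
    return calls
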