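"""Render per-trait summary tables and per-SNP listings.

The summary mirrors the classic validation-table layout: one row per trait
with counts formatted as ``count (pct%)`` and a TOTAL row computed on
rsID-deduplicated records (pleiotropic SNPs count once in TOTAL even though
they appear in each of their trait rows).  Every printed cell is recomputable
from the underlying records; the renderer holds no state beyond formatting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .agreement import round_half_up, summarize
from .concordance import ALL, ConcordanceRecord, tabulate, trait_labels
from .errors import ValidationError


@dataclass(frozen=True)
class SummaryRow:
    """One rendered row: group, n, concordances/discordances with %, kappa."""

    group: str
    n: int
    concordances: int
    concordance_pct: float
    discordances: int
    discordance_pct: float
    kappa: float

    @property
    def concordances_cell(self) -> str:
        return f"{self.concordances} ({self.concordance_pct:.1f}%)"

    @property
    def discordances_cell(self) -> str:
        return f"{self.discordances} ({self.discordance_pct:.1f}%)"


def _row(records: Iterable[ConcordanceRecord], group: str) -> SummaryRow:
    table = tabulate(records, group)
    s = summarize(table)
    return SummaryRow(
        group=group,
        n=table.n,
        concordances=table.concordances,
        concordance_pct=s.concordance_pct,
        discordances=table.discordances,
        discordance_pct=s.discordance_pct,
        kappa=s.kappa,
    )


def trait_summary(
    records: Sequence[ConcordanceRecord],
    trait_order: Sequence[str] | None = None,
) -> list[SummaryRow]:
    """One SummaryRow per trait (in the given order) plus a pooled TOTAL row."""
    if not records:
        raise ValidationError("cannot summarize an empty record set")
    known = trait_labels(records)
    if trait_order is None:
        trait_order = known
    unknown = [t for t in trait_order if t not in known]
    if unknown:
        raise ValidationError(f"unknown trait labels in trait_order: {unknown}")
    rows = [_row(records, t) for t in trait_order]
    total = _row(records, ALL)
    rows.append(SummaryRow(group="TOTAL", **{
        f: getattr(total, f) for f in
        ("n", "concordances", "concordance_pct",
         "discordances", "discordance_pct", "kappa")
    }))
    return rows


_SUMMARY_COLUMNS = ("Trait", "Number of SNPs", "Concordances", "Discordances",
                    "Cohen's Kappa")


def render_summary(rows: Sequence[SummaryRow], fmt: str = "tsv") -> str:
    """Serialize summary rows as TSV or an aligned plain-text table."""
    cells = [_SUMMARY_COLUMNS] + [
        (r.group, str(r.n), r.concordances_cell, r.discordances_cell,
         f"{r.kappa:.3f}")
        for r in rows
    ]
    if fmt == "tsv":
        return "\n".join("\t".join(row) for row in cells) + "\n"
    if fmt == "txt":
        widths = [max(len(row[i]) for row in cells) for i in range(len(cells[0]))]
        lines = ["  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip()
                 for row in cells]
        lines.insert(1, "  ".join("-" * w for w in widths))
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


def parse_summary(text: str) -> list[SummaryRow]:
    """Inverse of render_summary(fmt='tsv'); counts and kappa round-trip."""
    rows = []
    reader = csv.reader(text.strip().splitlines(), delimiter="\t")
    header = next(reader)
    if tuple(header) != _SUMMARY_COLUMNS:
        raise ValidationError(f"unexpected summary header: {header}")
    for group, n, conc, disc, kappa in reader:
        c_count, c_pct = conc.rstrip("%)").replace("(", "").split()
        d_count, d_pct = disc.rstrip("%)").replace("(", "").split()
        rows.append(SummaryRow(
            group=group, n=int(n),
            concordances=int(c_count), concordance_pct=float(c_pct.rstrip("%")),
            discordances=int(d_count), discordance_pct=float(d_pct.rstrip("%")),
            kappa=float(kappa),
        ))
    return rows


def per_snp_report(
    record_sets: Sequence[ConcordanceRecord] | dict[str, Sequence[ConcordanceRecord]],
) -> pd.DataFrame:
    """Per-SNP listing, one row per rsID, one claim/status column pair per
    reference panel, sorted by chromosome then position.

    Accepts either one record collection or a mapping ``reference ->
    records`` (the same rsIDs classified against several panels merge into
    one row).
    """
    if not isinstance(record_sets, dict):
        records = list(record_sets)
        ref = records[0].reference if records else "tool"
        record_sets = {ref: records}
    frames = []
    for ref, records in record_sets.items():
        frames.append(pd.DataFrame([
            {
                "rsid": r.rsid,
                "traits": ",".join(sorted(r.traits)),
                "chrom": r.chrom,
                "pos": r.pos,
                "manifest_present": r.manifest_present,
                f"tool_present_{ref}": r.tool_present,
                f"status_{ref}": r.status.value,
            }
            for r in records
        ]))
    base_cols = ["rsid", "traits", "chrom", "pos", "manifest_present"]
    if not frames or all(f.empty for f in frames):
        return pd.DataFrame(columns=base_cols)
    out = frames[0]
    for f in frames[1:]:
        out = out.merge(f, on=base_cols, how="outer", validate="one_to_one")
    chrom_rank = {c: i for i, c in enumerate(
        [str(i) for i in range(1, 23)] + ["X", "Y", "MT"])}
    out = out.sort_values(
        by=["chrom", "pos"],
        key=lambda s: s.map(chrom_rank) if s.name == "chrom" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def write_per_snp_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
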