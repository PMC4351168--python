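"""Chance-corrected agreement statistics for 2x2 concordance tables.

Cohen's kappa for two binary raters,

    kappa = (Po - Pe) / (1 - Pe),

where Po = (tp + tn)/n is the observed agreement and

    Pe = [(tp+fn)(tp+fp) + (tn+fp)(tn+fn)] / n^2

is the agreement expected if the raters' marginal "present" rates were
independent.  A table concentrated in a single diagonal cell has Po = Pe = 1;
kappa is defined as exactly 1 there (both raters agree on every item, with no
variation left for chance correction to act on).

Two false-negative-rate conventions coexist in the validation literature and
both are exposed here:

* ``formula`` — 100*fn/(tp+fn), the textbook miss rate among truly-present
  items;
* ``reported`` — 100*fn/n, the share of all tested SNPs that were missed;
  this is the convention every per-trait and overall value in the source
  tables uses, so it is the reporting default.

Verbal interpretation follows the Landis–Koch bands (slight / fair / moderate
/ substantial / perfect, with negative kappa as "no agreement").

``reconstruct_split`` solves the inverse problem: published tables often print
only n, the concordance/discordance counts and a rounded kappa; enumerating
all integer (tp, tn) splits recovering that kappa reconstructs the full table.
A single row can never pin the split down on its own — kappa is exactly
invariant under exchanging tp and tn (the expected-agreement term is symmetric
in the two diagonal cells), so the mirror split always co-occurs.
``reconstruct_study`` therefore intersects the candidates across reference
panels and trait rows (same tn per trait under every panel, same on-chip count
tp+fn, pleiotropy bookkeeping against the pooled row) to recover the unique
joint solution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

from .concordance import ContingencyTable
from .errors import InconsistencyError, UndefinedStatisticError

def round_half_up(x: float, decimals: int) -> float:
    """Round half away from zero (0.2495 -> 0.250 at 3 dp), unlike banker's
    rounding; published tables follow this convention."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cohen_kappa(table: ContingencyTable) -> float:
    """Cohen's kappa of a 2x2 table; exact rational arithmetic internally."""
    n = table.n
    if n == 0:
        raise UndefinedStatisticError("kappa is undefined on an empty table")
    po = Fraction(table.tp + table.tn, n)
    pe = Fraction(
        (table.tp + table.fn) * (table.tp + table.fp)
        + (table.tn + table.fp) * (table.tn + table.fn),
        n * n,
    )
    if pe == 1:
        # single-diagonal-cell table: perfect agreement by convention
        return 1.0
    return float((po - pe) / (1 - pe))


def false_negative_rate(table: ContingencyTable, mode: str = "reported") -> float:
    """Percentage of missed on-chip SNPs under the chosen denominator.

    ``reported`` divides by n (all SNPs tested); ``formula`` divides by
    tp+fn (SNPs truly on the chip).
    """
    if mode == "reported":
        denom = table.n
    elif mode == "formula":
        denom = table.tp + table.fn
    else:
        raise ValueError(f"mode must be 'reported' or 'formula', got {mode!r}")
    if denom == 0:
        raise UndefinedStatisticError(f"FNR ({mode}) denominator is zero")
    return 100.0 * table.fn / denom


def false_positive_rate(table: ContingencyTable) -> float:
    """100*fp/(fp+tn): share of off-chip SNPs the tool claims present."""
    denom = table.fp + table.tn
    if denom == 0:
        raise UndefinedStatisticError("FPR denominator fp+tn is zero")
    return 100.0 * table.fp / denom


def landis_band(kappa: float) -> str:
    """Verbal Landis–Koch label for a kappa in [-1, 1].

    Bands act on the raw (unrounded) kappa: <0 no agreement, 0–0.20 slight,
    0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 substantial, >=0.81
    perfect.  kappa exactly 0 falls in "slight" per the band table, though
    prose accounts sometimes call it "no agreement".
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa out of [-1, 1]: {kappa}")
    if kappa < 0:
        return "no agreement"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa < 0.81:
        return "substantial"
    return "perfect"


def reconstruct_split(
    n: int,
    concordances: int,
    fn: int,
    fp: int,
    kappa_printed: float,
    decimals: int = 3,
) -> list[tuple[int, int]]:
    """All integer (tp, tn) splits of ``concordances`` whose kappa rounds to
    the printed value.

    Published summary rows give n, concordant/discordant counts and a rounded
    kappa but not the diagonal split; this enumerates every candidate.  An
    empty result means the printed numbers are mutually inconsistent, which is
    raised as :class:`InconsistencyError`.
    """
    if concordances + fn + fp != n:
        raise InconsistencyError(
            f"marginals inconsistent: {concordances}+{fn}+{fp} != {n}"
        )
    target = round_half_up(kappa_printed, decimals)
    hits = []
    for tp in range(concordances + 1):
        tn = concordances - tp
        k = cohen_kappa(ContingencyTable(tp=tp, fn=fn, fp=fp, tn=tn))
        if abs(round_half_up(k, decimals) - target) < 10.0 ** (-decimals) / 2:
            hits.append((tp, tn))
    if not hits:
        raise InconsistencyError(
            f"no (tp, tn) split of {concordances} concordances reproduces "
            f"kappa={kappa_printed:.{decimals}f} with fn={fn}, fp={fp}, n={n}"
        )
    return hits


@dataclass(frozen=True)
class PrintedRow:
    """One published summary row: counts plus the rounded kappa."""

    n: int
    concordances: int
    fn: int
    fp: int
    kappa: float


def reconstruct_study(
    rows: dict[str, dict[str, PrintedRow]],
    total_group: str,
    n_pleiotropic: int,
    decimals: int = 3,
) -> dict[str, dict[str, ContingencyTable]]:
    """Recover the unique full tables of a published study from its printed
    rows, given ``rows[group][reference]`` for every trait group plus the
    pooled ``total_group`` row.

    Per-row enumeration yields mirror-symmetric candidates; this intersects
    them under the structural constraints the study design imposes:

    * tn (off-chip count) identical across reference panels within a group —
      chip content does not depend on the panel the tool consulted;
    * tp + fn (on-chip count) identical across panels within a group;
    * summed over trait groups, tn and on-chip counts may exceed the pooled
      row's by at most ``n_pleiotropic`` (each pleiotropic SNP adds one
      duplicate trait membership), and the group sizes must account for every
      duplicate.

    Exactly one assignment may survive; anything else raises
    :class:`InconsistencyError`.
    """
    refs = sorted({r for group in rows.values() for r in group})
    traits = [g for g in rows if g != total_group]
    if total_group not in rows:
        raise InconsistencyError(f"total group {total_group!r} missing from rows")
    extra_n = sum(rows[g][refs[0]].n for g in traits) - rows[total_group][refs[0]].n
    if extra_n != n_pleiotropic:
        raise InconsistencyError(
            f"group sizes imply {extra_n} duplicate memberships, "
            f"not {n_pleiotropic}")

    # joint candidates per group: one (tp, tn) per reference, consistent
    # within the group
    joint: dict[str, list[dict[str, tuple[int, int]]]] = {}
    for group, per_ref in rows.items():
        options = []
        per_ref_hits = {
            ref: reconstruct_split(row.n, row.concordances, row.fn, row.fp,
                                   row.kappa, decimals)
            for ref, row in per_ref.items()
        }
        for combo in itertools.product(*(per_ref_hits[r] for r in refs)):
            tns = {tn for _, tn in combo}
            on_chip = {tp + per_ref[ref].fn for ref, (tp, _) in zip(refs, combo)}
            if len(tns) == 1 and len(on_chip) == 1:
                options.append(dict(zip(refs, combo)))
        if not options:
            raise InconsistencyError(f"group {group!r}: no cross-panel-consistent split")
        joint[group] = options

    solutions = []
    for assignment in itertools.product(*(joint[g] for g in traits)):
        chosen = dict(zip(traits, assignment))
        for total_choice in joint[total_group]:
            tn_extra = (sum(c[refs[0]][1] for c in chosen.values())
                        - total_choice[refs[0]][1])
            on_extra = (
                sum(c[refs[0]][0] + rows[g][refs[0]].fn
                    for g, c in chosen.items())
                - (total_choice[refs[0]][0] + rows[total_group][refs[0]].fn))
            if 0 <= tn_extra and 0 <= on_extra and tn_extra + on_extra == n_pleiotropic:
                solutions.append({**chosen, total_group: total_choice})
    if len(solutions) != 1:
        raise InconsistencyError(
            f"{len(solutions)} joint reconstructions satisfy the structural "
            f"constraints; expected exactly one")
    sol = solutions[0]
    return {
        group: {
            ref: ContingencyTable(tp=tp, fn=rows[group][ref].fn,
                                  fp=rows[group][ref].fp, tn=tn)
            for ref, (tp, tn) in per_ref.items()
        }
        for group, per_ref in sol.items()
    }


@dataclass(frozen=True)
class AgreementSummary:
    """All derived statistics for one 2x2 table, pre-rounded for reporting."""

    table: ContingencyTable
    n: int
    concordance_pct: float
    discordance_pct: float
    kappa: float
    band: str
    fnr_reported: float
    fnr_formula: float | None
    fpr: float | None


def summarize(table: ContingencyTable) -> AgreementSummary:
    """Compute kappa, rates and band; percentages at 1 dp, kappa at 3 dp.

    The two conditional rates are None when their denominator vanishes
    (e.g. FPR on a trait with no off-chip SNPs at all).
    """
    kappa = cohen_kappa(table)
    try:
        fnr_f = round_half_up(false_negative_rate(table, "formula"), 1)
    except UndefinedStatisticError:
        fnr_f = None
    try:
        fpr = round_half_up(false_positive_rate(table), 1)
    except UndefinedStatisticError:
        fpr = None
    return AgreementSummary(
        table=table,
        n=table.n,
        concordance_pct=round_half_up(100.0 * table.concordances / table.n, 1),
        discordance_pct=round_half_up(100.0 * table.discordances / table.n, 1),
        kappa=round_half_up(kappa, 3),
        band=landis_band(kappa),
        fnr_reported=round_half_up(false_negative_rate(table, "reported"), 1),
        fnr_formula=fnr_f,
        fpr=fpr,
    )
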