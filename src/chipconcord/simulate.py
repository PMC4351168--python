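"""Synthetic manifests, query lists and tool claims with known ground truth.

Two generators live here:

* :func:`generate` — a seeded random generator emulating the shape of a
  GWAS-follow-up audit: a custom array manifest, a trait-labelled query list
  of which a configurable fraction sits on the chip, and per-reference tool
  claims where on-chip SNPs are missed at a reference-dependent rate (the
  failure mode under audit) and off-chip SNPs may be falsely claimed present.
  Defaults mirror the audited study's conditions: 415 query SNPs, 366/415 on
  chip, miss rates 152/366 (older HapMap3-style panel) and 73/366 (newer
  1000 Genomes-style panel), zero false positives, six pleiotropic SNPs.

* :func:`published_fixture` — a fully deterministic 415-SNP dataset whose
  classification reproduces, cell for cell, the published per-trait and
  pooled 2x2 tables for both reference panels.  Statuses are assigned in
  fixed trait/status blocks, not sampled, so downstream checks are exact.

Both return plain record collections (plus a truth table) that round-trip
through the io module, so the full pipeline can be exercised end to end
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (
    WARNING_NONE,
    WARNING_NOT_IN_REFERENCE,
    WARNING_NOT_ON_ARRAY,
    ManifestEntry,
    SnpQuery,
    ToolClaim,
    write_manifest,
    write_query_list,
    write_tool_output,
)

#: Approximate GRCh37 chromosome lengths (bp), autosomes + X; the virtual
#: coordinate space loci are drawn from.
GRCH37_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560,
}

TRAIT_BP = "Blood pressure"
TRAIT_GLUCOSE = "Fasting glucose"
TRAIT_BMI = "BMI"
TRAIT_LIPIDS = "Lipids"
TRAIT_ORDER = (TRAIT_BP, TRAIT_GLUCOSE, TRAIT_BMI, TRAIT_LIPIDS)

REF_HAPMAP = "HapMap3"
REF_1000G = "1000Genomes"

ARRAY_NAME = "Cardio-Metabochip"


@dataclass
class SyntheticConfig:
    """Knobs of the random generator; defaults are the audited-study shape."""

    n_probes: int = 2000
    n_queries: int = 415
    frac_on_chip: float = 366 / 415
    miss_rates: dict[str, float] = field(
        default_factory=lambda: {REF_HAPMAP: 152 / 366, REF_1000G: 73 / 366})
    fp_rate: float = 0.0
    trait_weights: dict[str, float] = field(
        default_factory=lambda: {TRAIT_BP: 37 / 421, TRAIT_GLUCOSE: 39 / 421,
                                 TRAIT_BMI: 69 / 421, TRAIT_LIPIDS: 276 / 421})
    pleiotropy_count: int = 6
    frac_probes_with_rsid: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        probs = [self.frac_on_chip, self.fp_rate, self.frac_probes_with_rsid,
                 *self.miss_rates.values(), *self.trait_weights.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        if self.n_probes < 0 or self.n_queries < 0 or self.pleiotropy_count < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.pleiotropy_count > self.n_queries:
            raise ConfigurationError("pleiotropy_count exceeds n_queries")
        if len(self.trait_weights) < 2 and self.pleiotropy_count > 0:
            raise ConfigurationError("pleiotropy needs at least two traits")


@dataclass
class SyntheticDataset:
    """Generated inputs plus the per-SNP truth used for exact scoring."""

    manifest: list[ManifestEntry]
    queries: list[SnpQuery]
    claims: dict[str, list[ToolClaim]]
    truth: pd.DataFrame  # rsid, on_chip, claimed_<ref> per reference

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write queries.tsv, manifest.csv, claims_<ref>.tsv and truth.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "queries": outdir / "queries.tsv",
            "manifest": outdir / "manifest.csv",
            "truth": outdir / "truth.tsv",
        }
        write_query_list(self.queries, paths["queries"])
        write_manifest(self.manifest, paths["manifest"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        for ref, claims in self.claims.items():
            p = outdir / f"claims_{ref}.tsv"
            write_tool_output(claims, p)
            paths[f"claims_{ref}"] = p
        return paths


def _draw_loci(rng: np.random.Generator, count: int,
               taken: set[tuple[str, int]] | None = None) -> list[tuple[str, int]]:
    """Distinct loci from the virtual genome, chromosome chosen length-weighted."""
    taken = set(taken or ())
    chroms = list(GRCH37_LENGTHS)
    lengths = np.array([GRCH37_LENGTHS[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    loci: list[tuple[str, int]] = []
    while len(loci) < count:
        batch = max(count - len(loci), 16)
        idx = rng.choice(len(chroms), size=batch, p=weights)
        pos = 1 + np.floor(rng.random(batch) * lengths[idx]).astype(np.int64)
        for i, p in zip(idx, pos):
            key = (chroms[i], int(p))
            if key not in taken:
                taken.add(key)
                loci.append(key)
                if len(loci) == count:
                    break
    return loci


def _claim(rsid: str, present: bool, reference: str, on_chip: bool) -> ToolClaim:
    if present:
        return ToolClaim(rsid, ARRAY_NAME, True, WARNING_NONE, reference)
    warning = WARNING_NOT_IN_REFERENCE if on_chip else WARNING_NOT_ON_ARRAY
    return ToolClaim(rsid, ARRAY_NAME, False, warning, reference)


def generate(config: SyntheticConfig | None = None,
             seed: int | None = None) -> SyntheticDataset:
    """Sample a dataset under ``config``; ``seed`` overrides ``config.seed``.

    On-chip membership is Bernoulli(frac_on_chip) per query; each reference
    panel misses an on-chip SNP independently with its configured rate and
    falsely claims an off-chip SNP with fp_rate.  The truth table records
    every draw, so pipeline output can be scored exactly against intent.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    traits = list(config.trait_weights)
    tw = np.array([config.trait_weights[t] for t in traits], dtype=float)
    tw /= tw.sum()

    query_loci = _draw_loci(rng, config.n_queries)
    on_chip_flags = rng.random(config.n_queries) < config.frac_on_chip

    queries: list[SnpQuery] = []
    pleio_idx = set(rng.choice(config.n_queries, size=config.pleiotropy_count,
                               replace=False).tolist()) if config.pleiotropy_count else set()
    for i, (chrom, pos) in enumerate(query_loci):
        primary = traits[rng.choice(len(traits), p=tw)]
        labels = {primary}
        if i in pleio_idx:
            others = [t for t in traits if t != primary]
            labels.add(others[rng.choice(len(others))])
        queries.append(SnpQuery(f"rs{1_000_000 + i}", chrom, pos, frozenset(labels)))

    # manifest: every on-chip query locus, padded with background probes
    on_loci = [loc for loc, f in zip(query_loci, on_chip_flags) if f]
    n_extra = max(config.n_probes - len(on_loci), 0)
    extra_loci = _draw_loci(rng, n_extra, taken=set(query_loci))
    manifest: list[ManifestEntry] = []
    for j, (chrom, pos) in enumerate([*on_loci, *extra_loci]):
        rsid = None
        if rng.random() < config.frac_probes_with_rsid:
            rsid = f"rs{5_000_000 + j}"
        manifest.append(ManifestEntry(f"probe_{j:06d}", chrom, pos, rsid))

    claims: dict[str, list[ToolClaim]] = {ref: [] for ref in config.miss_rates}
    truth_rows = []
    for q, on_chip in zip(queries, on_chip_flags):
        row = {"rsid": q.rsid, "on_chip": bool(on_chip)}
        for ref, miss in config.miss_rates.items():
            if on_chip:
                present = bool(rng.random() >= miss)
            else:
                present = bool(rng.random() < config.fp_rate)
            claims[ref].append(_claim(q.rsid, present, ref, on_chip))
            row[f"claimed_{ref}"] = present
        truth_rows.append(row)

    return SyntheticDataset(manifest=manifest, queries=queries, claims=claims,
                            truth=pd.DataFrame(truth_rows))


def expected_kappa(frac_on_chip: float, miss_rate: float, fp_rate: float = 0.0) -> float:
    """Closed-form kappa of the expected 2x2 table under the generator model.

    With q = frac_on_chip and m = miss_rate the expected cell proportions are
    (q(1-m), qm, (1-q)f, (1-q)(1-f)); kappa follows from the usual Po/Pe.
    """
    q, m, f = frac_on_chip, miss_rate, fp_rate
    tp, fn = q * (1 - m), q * m
    fp_, tn = (1 - q) * f, (1 - q) * (1 - f)
    po = tp + tn
    pe = (tp + fn) * (tp + fp_) + (tn + fp_) * (tn + fn)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


# ---------------------------------------------------------------------------
# deterministic published-audit fixture
# ---------------------------------------------------------------------------

# Per-SNP joint categories w.r.t. the two reference panels:
#   A  on chip, claimed present by both panels        (TP / TP)
#   B  on chip, missed by the older panel only        (FN / TP)
#   C  on chip, missed by both panels                 (FN / FN)
#   D  off chip, claimed absent by both panels        (TN / TN)
# Singleton counts per trait, derived from the published per-trait tables
# (the older-panel TP set nests inside the newer-panel TP set in every trait).
_SINGLE_BLOCKS: dict[str, dict[str, int]] = {
    TRAIT_BP:      {"A": 20, "B": 7,  "C": 2,  "D": 6},
    TRAIT_GLUCOSE: {"A": 19, "B": 19, "C": 0,  "D": 0},
    TRAIT_BMI:     {"A": 25, "B": 7,  "C": 26, "D": 8},
    TRAIT_LIPIDS:  {"A": 147, "B": 46, "C": 44, "D": 33},
}

# The six pleiotropic SNPs: duplicate trait memberships carry 3 TP, 2 TN and
# 1 both-panel FN — the unique split consistent with per-trait vs pooled
# totals.  Glucose cannot host the TN or FN duplicates (its table has tn=0
# and zero newer-panel FNs).
_PLEIOTROPIC: tuple[tuple[str, tuple[str, str]], ...] = (
    ("A", (TRAIT_BP, TRAIT_LIPIDS)),
    ("A", (TRAIT_GLUCOSE, TRAIT_LIPIDS)),
    ("A", (TRAIT_BMI, TRAIT_LIPIDS)),
    ("D", (TRAIT_BP, TRAIT_LIPIDS)),
    ("D", (TRAIT_BMI, TRAIT_LIPIDS)),
    ("C", (TRAIT_BMI, TRAIT_LIPIDS)),
)

#: Background probes appended to the fixture manifest beyond the query loci,
#: so the chip is larger than the audit panel (as a real product file is).
_FIXTURE_EXTRA_PROBES = 85


def published_fixture() -> SyntheticDataset:
    """Deterministic 415-SNP dataset reproducing the published tables exactly.

    Loci are laid out on a fixed grid (no RNG anywhere); every fifth on-chip
    probe and all background probes lack an rsID, mirroring product files in
    which rs numbers are incomplete.
    """
    blocks: list[tuple[str, frozenset[str]]] = []  # (category, traits) per SNP
    for cat, pair in _PLEIOTROPIC:
        blocks.append((cat, frozenset(pair)))
    for trait in TRAIT_ORDER:
        for cat in ("A", "B", "C", "D"):
            blocks.extend((cat, frozenset({trait}))
                        for _ in range(_SINGLE_BLOCKS[trait][cat]))

    queries: list[SnpQuery] = []
    manifest: list[ManifestEntry] = []
    claims: dict[str, list[ToolClaim]] = {REF_HAPMAP: [], REF_1000G: []}
    truth_rows = []
    probe_no = 0
    for i, (cat, labels) in enumerate(blocks):
        chrom = str(i % 22 + 1)
        pos = 1_000_000 + 1_000 * i
        rsid = f"rs{10_000 + i}"
        queries.append(SnpQuery(rsid, chrom, pos, labels))
        on_chip = cat != "D"
        if on_chip:
            probe_rsid = None if probe_no % 5 == 0 else rsid
            manifest.append(ManifestEntry(f"chip_{probe_no:06d}", chrom, pos, probe_rsid))
            probe_no += 1
        present_old = cat == "A"
        present_new = cat in ("A", "B")
        claims[REF_HAPMAP].append(_claim(rsid, present_old, REF_HAPMAP, on_chip))
        claims[REF_1000G].append(_claim(rsid, present_new, REF_1000G, on_chip))
        truth_rows.append({
            "rsid": rsid, "on_chip": on_chip,
            f"claimed_{REF_HAPMAP}": present_old,
            f"claimed_{REF_1000G}": present_new,
        })

    for j in range(_FIXTURE_EXTRA_PROBES):
        chrom = str(j % 22 + 1)
        manifest.append(ManifestEntry(f"chip_{probe_no + j:06d}", chrom,
                                      90_000_000 + 1_000 * j, None))

    return SyntheticDataset(manifest=manifest, queries=queries, claims=claims,
                            truth=pd.DataFrame(truth_rows))
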