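# Methods

## The validation model

`chipconcord` treats array membership as a two-rater agreement problem. Rater
one is the array manifest itself: a query SNP is *on chip* iff its normalized
(chromosome, position) key — GRCh37, 1-based, fully closed — appears among the
manifest's probe coordinates. Rater two is the audited tool's claim for the
same rsID. The manifest side is taken as ground truth, which gives the
asymmetric false-negative / false-positive vocabulary (a FN is a SNP the tool
calls absent although the chip carries it), while Cohen's κ itself is computed
symmetrically from the 2×2 table.

Positional matching is deliberately strict:

* **exact match only** — no tolerance window; indels and multi-nucleotide
  variants are out of scope;
* **rsIDs are never consulted** on the manifest side: product files lack rs
  numbers for some probes and rs numbers merge or drift across dbSNP
  releases, whereas coordinates on a fixed build do not;
* **no liftover** — a build-tag mismatch between the query list and the index
  is a hard error rather than a silent conversion;
* strand and alleles are ignored: the workflow compares positions only.

A query locus matched by a probe carrying a *different* rsID still counts as
present (position is authoritative). Two query SNPs sharing a locus
(tri-allelic sites) are both matched and the collision is logged. Adding
manifest entries can only turn off-chip calls into on-chip calls, never the
reverse; membership is independent of manifest row order.

## Statistics

For a table (tp, fn, fp, tn) with n = tp+fn+fp+tn:

* κ = (Pₒ − Pₑ)/(1 − Pₑ) with Pₒ = (tp+tn)/n and
  Pₑ = [(tp+fn)(tp+fp) + (tn+fp)(tn+fn)]/n². Internally computed with exact
  rational arithmetic (`fractions.Fraction`) so enumeration and rounding are
  never perturbed by float error.
* **Degenerate convention**: when the whole table sits in a single diagonal
  cell, Pₒ = Pₑ = 1 and the ratio is 0/0; κ is defined as exactly 1. Both
  raters then agree on every item and there is no variation left for chance
  correction — and an all-TP trait row in a published audit does print 1.000.
* **FNR duality**: the textbook miss rate 100·fn/(tp+fn) (`mode="formula"`)
  and the all-SNPs share 100·fn/n (`mode="reported"`) are both exposed;
  reporting defaults to `reported` because that is the denominator published
  validation tables actually use. On the pooled fixture table the two differ
  meaningfully: 36.6 % vs 41.5 %.
* FPR = 100·fp/(fp+tn); `None` in summaries when no off-chip SNPs exist.
* **Landis–Koch bands** act on the unrounded κ: `<0` no agreement, `≤0.20`
  slight, `≤0.40` fair, `≤0.60` moderate, `<0.81` substantial, else perfect.
  κ = 0 is labelled "slight" per the band table even though prose accounts
  sometimes call exact zero "no agreement". The band edges are resolved so
  that any κ ≥ 0.81 is perfect and values in (0.80, 0.81) remain substantial.
* **Rounding** is half-away-from-zero (`decimal.ROUND_HALF_UP`): κ to 3
  decimals, percentages to 1. This matters: the pooled fixture κ is
  0.2495135…, which must print as 0.250.

## Reconstruction of published tables

Published summary rows typically print n, concordances, discordances and a
rounded κ, but not the (tp, tn) diagonal split. `reconstruct_split`
enumerates all integer splits and keeps those whose κ rounds to the printed
value. Because Pₑ is symmetric in tp and tn, κ is *exactly* invariant under
exchanging the diagonal cells: a single row therefore always yields a mirror
pair of candidates (or, for an all-concordant row, every split, since κ = 1
regardless). Uniqueness is a joint property: `reconstruct_study` intersects
the per-row candidates under three structural constraints — tn identical
across reference panels within a trait (chip content does not depend on the
panel), tp+fn identical across panels (same on-chip SNPs), and pleiotropy
bookkeeping (per-trait tn and on-chip sums may exceed the pooled row's by at
most the number of pleiotropic duplicate memberships, and must account for
all of them). On the published ten-row, two-panel study this leaves exactly
one solution, which is the one the deterministic fixture encodes.

## The synthetic generator

`generate(SyntheticConfig(...))` emulates the audit's data shape: loci drawn
without replacement from a virtual GRCh37 coordinate space (22 autosomes + X
with realistic length caps, chromosome chosen length-weighted), a manifest
containing every on-chip query locus plus background probes (a configurable
fraction lacking rsIDs), trait labels drawn from a weighted distribution with
a fixed number of SNPs given a second trait, and per-reference claims in
which an on-chip SNP is missed with probability `miss_rates[ref]` and an
off-chip SNP falsely claimed with `fp_rate`. One seeded
`numpy.random.Generator` is threaded through all draws; identical
config + seed gives byte-identical files. Defaults are the study conditions:
415 queries, 366/415 on chip, miss rates 152/366 and 73/366, fp_rate 0, six
pleiotropic SNPs, trait weights 37:39:69:276.

What it does *not* emulate: LD structure, allele frequencies, genotypes,
strand annotation, clustered genomic positions, or correlated misses between
reference panels (each panel misses independently). Passing tests therefore
demonstrate the pipeline's bookkeeping and statistics on realistically shaped
membership data, not robustness to every pathology of real product files.

`published_fixture()` is constructed, not sampled: each of the 415 SNPs is
assigned to a fixed block — on chip and claimed by both panels, on chip and
missed only by the older panel, on chip and missed by both, or off chip —
with block sizes per trait taken from the reconstructed tables, and the six
pleiotropic duplicates placed as 3 TP, 2 TN and 1 both-panel FN (glucose is
excluded from the TN/FN duplicates because its reconstructed table has
tn = 0 and no newer-panel FN). Loci sit on a deterministic grid; every fifth
on-chip probe and all background probes lack rsIDs.

## Problem sizes and numerical choices

The test suite and acceptance script run entirely at desk scale: the fixture
pipeline handles 415 queries against a 451-probe manifest in well under a
second; property tests enumerate tables with n ≤ 50; the
parameter-recovery check uses 200 replicates of the 415-SNP shape; the
closed-form κ convergence check uses one 12 000-query draw. The κ
implementation is cross-checked in tests against a per-item brute-force
expansion and against an independent library implementation
(`sklearn.metrics.cohen_kappa_score`); neither stands behind the shipped
code path.

Degenerate inputs: an empty table makes κ undefined (error, not NaN); FNR
and FPR raise on vanishing denominators in the raw API and surface as `None`
in rendered summaries; empty manifests produce an index that matches
nothing; empty record sets cannot be summarized.

## Known limitations

* Only binary present/absent agreement; no weighted or multi-category κ, no
  confidence intervals for κ.
* Coordinates are compared within one build; cross-build audits require
  external liftover before input.
* The tool-output schema is a reconstruction (rsid / array / available /
  warning, dialect-configurable); real tools vary and may need a dialect
  mapping. Warning texts are classified by substring heuristics
  ("not in <panel>" vs "not on … array").
* LD-proxy search for absent SNPs — the feature the audited tools layer on
  top of membership — is intentionally out of scope.
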