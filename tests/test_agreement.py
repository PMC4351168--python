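"""Cohen's kappa, FNR/FPR, Landis–Koch bands, and 2x2 reconstruction."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipconcord.agreement import (
    PrintedRow,
    cohen_kappa,
    false_negative_rate,
    false_positive_rate,
    landis_band,
    reconstruct_split,
    reconstruct_study,
    round_half_up,
    summarize,
)
from chipconcord.concordance import ContingencyTable
from chipconcord.errors import InconsistencyError, UndefinedStatisticError

# The ten published summary rows: (group, reference, n, concordances,
# discordances, kappa).  fp = 0 throughout; the (tp, tn) split is not printed
# and is recovered by reconstruct_split.
PUBLISHED_ROWS = [
    ("Blood pressure", "HapMap3", 37, 28, 9, 0.469),
    ("Fasting glucose", "HapMap3", 39, 20, 19, 0.000),
    ("BMI", "HapMap3", 69, 35, 34, 0.166),
    ("Lipids", "HapMap3", 276, 185, 91, 0.295),
    ("TOTAL", "HapMap3", 415, 263, 152, 0.250),
    ("Blood pressure", "1000Genomes", 37, 35, 2, 0.841),
    ("Fasting glucose", "1000Genomes", 39, 39, 0, 1.000),
    ("BMI", "1000Genomes", 69, 42, 27, 0.242),
    ("Lipids", "1000Genomes", 276, 231, 45, 0.525),
    ("TOTAL", "1000Genomes", 415, 342, 73, 0.487),
]


def _brute_kappa(table):
    """Independent oracle: expand the table into n paired ratings and apply
    the observed/chance agreement definition item by item."""
    truth = [1] * (table.tp + table.fn) + [0] * (table.fp + table.tn)
    tool = ([1] * table.tp + [0] * table.fn
            + [1] * table.fp + [0] * table.tn)
    n = len(truth)
    po = sum(a == b for a, b in zip(truth, tool)) / n
    p1, p2 = sum(truth) / n, sum(tool) / n
    pe = p1 * p2 + (1 - p1) * (1 - p2)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


# ---------------------------------------------------------------------------
# cohen_kappa
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("cells,expected", [
    ((21, 9, 0, 7), 0.469),      # moderate agreement, older reference panel
    ((20, 19, 0, 0), 0.000),     # observed equals chance agreement exactly
    ((25, 25, 25, 25), 0.0),     # independence
    ((10, 0, 0, 10), 1.0),       # perfect agreement
    ((0, 10, 10, 0), -1.0),      # perfect disagreement
    ((39, 0, 0, 0), 1.0),        # single diagonal cell: kappa := 1
])
def test_cohen_kappa_known_values(cells, expected):
    k = cohen_kappa(ContingencyTable(*cells))
    assert round_half_up(k, 3) == pytest.approx(expected, abs=1e-12)


def test_cohen_kappa_empty_table_is_undefined():
    with pytest.raises(UndefinedStatisticError):
        cohen_kappa(ContingencyTable(0, 0, 0, 0))


_cell = st.integers(0, 50)
_tables = st.tuples(_cell, _cell, _cell, _cell).filter(
    lambda c: 0 < sum(c) <= 50).map(lambda c: ContingencyTable(*c))


@settings(max_examples=300)
@given(_tables)
def test_kappa_matches_per_item_oracle(table):
    assert cohen_kappa(table) == pytest.approx(_brute_kappa(table), abs=1e-12)


@settings(max_examples=300)
@given(_tables)
def test_kappa_symmetry_and_bounds(table):
    k = cohen_kappa(table)
    assert -1.0 <= k <= 1.0
    # transpose the two raters (fn <-> fp)
    assert cohen_kappa(ContingencyTable(table.tp, table.fp, table.fn, table.tn)) \
        == pytest.approx(k, abs=1e-12)
    # relabel present <-> absent (tp <-> tn, fn <-> fp)
    assert cohen_kappa(ContingencyTable(table.tn, table.fp, table.fn, table.tp)) \
        == pytest.approx(k, abs=1e-12)
    # kappa is 1 exactly when there are no discordances
    assert (k == 1.0) == (table.fn == 0 and table.fp == 0)


@pytest.mark.filterwarnings("ignore::UserWarning")  # degenerate tables are skipped
@settings(max_examples=200)
@given(_tables)
def test_kappa_agrees_with_sklearn(table):
    """Cross-check against an independent library implementation where the
    statistic is defined (non-degenerate chance agreement)."""
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    truth = [1] * (table.tp + table.fn) + [0] * (table.fp + table.tn)
    tool = [1] * table.tp + [0] * table.fn + [1] * table.fp + [0] * table.tn
    ref = sklearn_metrics.cohen_kappa_score(truth, tool, labels=[0, 1])
    if math.isnan(ref):
        return
    assert cohen_kappa(table) == pytest.approx(ref, abs=1e-9)


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def test_fnr_reported_vs_formula_denominators():
    t = ContingencyTable(214, 152, 0, 49)
    assert round_half_up(false_negative_rate(t, "reported"), 1) == 36.6
    assert round_half_up(false_negative_rate(t, "formula"), 1) == 41.5


def test_fnr_zero_when_no_false_negatives():
    t = ContingencyTable(10, 0, 0, 5)
    assert false_negative_rate(t, "reported") == 0.0
    assert false_negative_rate(t, "formula") == 0.0


def test_fnr_errors():
    with pytest.raises(UndefinedStatisticError):
        false_negative_rate(ContingencyTable(0, 0, 3, 4), "formula")
    with pytest.raises(ValueError):
        false_negative_rate(ContingencyTable(1, 1, 1, 1), "bogus")


@pytest.mark.parametrize("cells,expected", [
    ((214, 152, 0, 49), 0.0),
    ((0, 0, 5, 5), 50.0),
    ((1, 1, 0, 9), 0.0),
])
def test_false_positive_rate(cells, expected):
    assert false_positive_rate(ContingencyTable(*cells)) == expected


def test_fpr_undefined_without_off_chip_snps():
    with pytest.raises(UndefinedStatisticError):
        false_positive_rate(ContingencyTable(5, 5, 0, 0))


# ---------------------------------------------------------------------------
# Landis–Koch bands
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kappa,label", [
    (-0.2, "no agreement"),
    (0.0, "slight"), (0.166, "slight"), (0.20, "slight"),
    (0.21, "fair"), (0.250, "fair"), (0.40, "fair"),
    (0.469, "moderate"), (0.525, "moderate"), (0.60, "moderate"),
    (0.61, "substantial"), (0.80, "substantial"), (0.805, "substantial"),
    (0.81, "perfect"), (0.841, "perfect"), (1.0, "perfect"),
])
def test_landis_bands(kappa, label):
    assert landis_band(kappa) == label


def test_landis_band_rejects_out_of_range():
    with pytest.raises(ValueError):
        landis_band(1.5)


# ---------------------------------------------------------------------------
# rounding
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x,nd,expected", [
    (0.249513, 3, 0.250),
    (75.6756, 1, 75.7),
    (0.0005, 3, 0.001),   # ties go away from zero, not to even
    (-0.0005, 3, -0.001),
    (36.62650, 1, 36.6),
])
def test_round_half_away_from_zero(x, nd, expected):
    assert round_half_up(x, nd) == expected


# ---------------------------------------------------------------------------
# reconstruction of unprinted (tp, tn) splits
# ---------------------------------------------------------------------------

def test_reconstruct_split_returns_mirror_pair():
    """kappa is invariant under exchanging tp and tn, so a single row always
    admits exactly the mirror pair of splits."""
    assert reconstruct_split(37, 28, 9, 0, 0.469) == [(7, 21), (21, 7)]
    assert reconstruct_split(39, 20, 19, 0, 0.000) == [(0, 20), (20, 0)]


@settings(max_examples=150)
@given(_tables)
def test_reconstruct_split_recovers_and_mirrors_any_table(table):
    """The generating split is always among the candidates, and the candidate
    set is closed under the tp<->tn exchange."""
    k = round_half_up(cohen_kappa(table), 3)
    hits = reconstruct_split(table.n, table.tp + table.tn, table.fn, table.fp, k)
    assert (table.tp, table.tn) in hits
    assert {(tn, tp) for tp, tn in hits} == set(hits)


def test_reconstruct_split_degenerate_perfect_agreement():
    # with no discordances every split gives kappa 1: all 6 splits survive
    assert reconstruct_split(5, 5, 0, 0, 1.000) == [(i, 5 - i) for i in range(6)]


def test_reconstruct_split_inconsistent_marginals():
    with pytest.raises(InconsistencyError):
        reconstruct_split(10, 5, 2, 0, 0.5)  # 5+2+0 != 10


def test_reconstruct_split_irreproducible_kappa():
    with pytest.raises(InconsistencyError):
        reconstruct_split(37, 28, 9, 0, 0.900)


def published_study_rows():
    """PUBLISHED_ROWS reshaped for reconstruct_study: group -> ref -> row."""
    study: dict[str, dict[str, PrintedRow]] = {}
    for group, ref, n, conc, disc, kappa in PUBLISHED_ROWS:
        study.setdefault(group, {})[ref] = PrintedRow(n, conc, disc, 0, kappa)
    return study


# the full tables the published rows pin down jointly
RECONSTRUCTED_SPLITS = {
    "Blood pressure": {"HapMap3": (21, 7), "1000Genomes": (28, 7)},
    "Fasting glucose": {"HapMap3": (20, 0), "1000Genomes": (39, 0)},
    "BMI": {"HapMap3": (26, 9), "1000Genomes": (33, 9)},
    "Lipids": {"HapMap3": (150, 35), "1000Genomes": (196, 35)},
    "TOTAL": {"HapMap3": (214, 49), "1000Genomes": (293, 49)},
}


def test_full_published_reconstruction_is_unique_and_consistent():
    """Intersecting the per-row mirror candidates under the study's
    structural constraints (same tn per trait across panels, same on-chip
    count, six duplicate pleiotropic memberships against the pooled row)
    leaves exactly one joint solution — the published tables' full cells."""
    sol = reconstruct_study(published_study_rows(), "TOTAL", n_pleiotropic=6)
    got = {g: {r: (t.tp, t.tn) for r, t in per.items()} for g, per in sol.items()}
    assert got == RECONSTRUCTED_SPLITS


def test_reconstruct_study_rejects_wrong_pleiotropy_count():
    with pytest.raises(InconsistencyError):
        reconstruct_study(published_study_rows(), "TOTAL", n_pleiotropic=5)


# ---------------------------------------------------------------------------
# summarize
# ---------------------------------------------------------------------------

def test_summarize_pooled_older_panel():
    s = summarize(ContingencyTable(214, 152, 0, 49))
    assert (s.n, s.concordance_pct, s.discordance_pct) == (415, 63.4, 36.6)
    assert s.kappa == 0.250 and s.band == "fair"
    assert s.fnr_reported == 36.6 and s.fnr_formula == 41.5 and s.fpr == 0.0


def test_summarize_handles_vanishing_denominators():
    s = summarize(ContingencyTable(39, 0, 0, 0))
    assert s.kappa == 1.000 and s.fpr is None and s.fnr_formula == 0.0
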