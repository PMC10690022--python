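"""Exact Fisher test, yield tables, gene frequencies, novel fractions."""
import math

import numpy as np
import pytest
from scipy import stats as sps

from nmdx.stats import (ContingencyTable, chi_square_diagnostic, fisher_exact,
                        gene_frequency, novel_fraction, yield_table)
from nmdx.types import OutcomeRecord, ValidationError


def make_2x2(a, b, c, d):
    return ContingencyTable(["r1", "r2"], ["c1", "c2"], [[a, b], [c, d]])


def hypergeom_oracle_2x2(a, b, c, d):
    """Direct summation over the 2x2 hypergeometric support."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    rv = sps.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    return sum(rv.pmf(x) for x in support if rv.pmf(x) <= p_obs * (1 + 1e-7))


def test_flat_2x2_gives_p_one():
    assert fisher_exact(make_2x2(1, 1, 1, 1)) == pytest.approx(1.0)


def test_exact_matches_hypergeometric_oracle_all_small_2x2():
    """Enumeration agrees with direct hypergeometric summation, n <= 30."""
    rng = np.random.default_rng(2024)
    checked = 0
    for _ in range(200):
        cells = rng.integers(0, 8, size=4)
        a, b, c, d = (int(x) for x in cells)
        n = a + b + c + d
        if n == 0 or n > 30 or min(a + b, c + d, a + c, b + d) == 0:
            continue
        p = fisher_exact(make_2x2(a, b, c, d))
        assert p == pytest.approx(hypergeom_oracle_2x2(a, b, c, d), abs=1e-12)
        checked += 1
    assert checked > 50


def test_paper_style_2x4_table_significant():
    ct = ContingencyTable(
        ["India", "South Africa"], ["deletion", "nonsense", "duplication", "splice"],
        [[60, 3, 0, 1], [24, 8, 7, 1]])
    p = fisher_exact(ct)
    assert 0.0 < p < 0.001


def test_montecarlo_agrees_with_exact():
    """MC and exact agree within 3 Monte-Carlo standard errors."""
    rng = np.random.default_rng(5)
    n_sim = 2000
    tested = 0
    while tested < 20:
        shape = (2, int(rng.integers(2, 4)))
        cells = rng.integers(0, 6, size=shape)
        if cells.sum() == 0 or (cells.sum(0) == 0).any() or (cells.sum(1) == 0).any():
            continue
        ct = ContingencyTable([f"r{i}" for i in range(shape[0])],
                              [f"c{j}" for j in range(shape[1])],
                              cells.tolist())
        p_ex = fisher_exact(ct)
        p_mc = fisher_exact(ct, method="montecarlo", seed=tested, n_sim=n_sim)
        se = math.sqrt(max(p_ex * (1 - p_ex), 1e-6) / n_sim)
        assert abs(p_mc - p_ex) <= 3 * se + 2 / n_sim
        tested += 1


def test_exact_p_superuniform_under_null():
    """P(p <= alpha) <= alpha (+MC error) for margin-conditional null tables."""
    rng = np.random.default_rng(99)
    row_labels = np.repeat([0, 1], [12, 8])
    col_labels = np.repeat([0, 1], [9, 11])
    n_tables = 2000
    pvals = []
    for _ in range(n_tables):
        perm = rng.permutation(row_labels)
        a = int(((perm == 0) & (col_labels == 0)).sum())
        b = 12 - a
        c = 9 - a
        d = 11 - b
        pvals.append(fisher_exact(make_2x2(a, b, c, d)))
    pvals = np.array(pvals)
    for alpha in (0.01, 0.05):
        rate = (pvals <= alpha).mean()
        mc_err = 3 * math.sqrt(alpha * (1 - alpha) / n_tables)
        assert rate <= alpha + mc_err


def test_degenerate_margin_warns_p_one():
    with pytest.warns(UserWarning):
        p = fisher_exact(make_2x2(0, 0, 3, 4))
    assert p == 1.0


def test_enumeration_bound_exceeded_raises():
    ct = make_2x2(150, 100, 90, 80)
    with pytest.raises(ValidationError, match="montecarlo"):
        fisher_exact(ct)


def test_chi_square_diagnostic_matches_reference():
    counts = [[60, 3, 0, 1], [24, 8, 7, 1]]
    ct = ContingencyTable(["a", "b"], list("wxyz"), counts)
    res = chi_square_diagnostic(ct)
    ref = sps.chi2_contingency(np.array(counts), correction=False)
    assert res["statistic"] == pytest.approx(ref.statistic)
    assert res["pvalue"] == pytest.approx(ref.pvalue)


# ---------------------------------------------------------------------------
# Yield / gene-frequency / novelty summaries
# ---------------------------------------------------------------------------

def _outcome(i, outcome, category="LGMD", modality="WES", gene=None,
             mechanism=None, novel=()):
    kwargs = {}
    if outcome != "unsolved":
        kwargs = dict(causal_variant_ids=(f"v{i}",),
                      variant_classes=("Likely pathogenic",)
                      if outcome == "solved" else ("VUS",),
                      causal_gene=gene or "DYSF", mechanism=mechanism,
                      novel_flags=novel or (False,))
    return OutcomeRecord(proband_id=f"P{i}", outcome=outcome,
                         category=category, modality=modality, **kwargs)


def test_yield_table_percentages():
    outcomes = [_outcome(i, "solved") for i in range(5)] \
        + [_outcome(i + 5, "unsolved") for i in range(5)]
    yt = yield_table(outcomes)
    assert yt.loc[0, "pct_solved"] == pytest.approx(50.0)
    assert yt.loc[0, "pct_combined_display"] == 50

    sgt = [_outcome(i, "solved", modality="SGT") for i in range(43)] \
        + [_outcome(i + 43, "unsolved", modality="SGT") for i in range(37)]
    yt2 = yield_table(sgt, by=("modality",))
    row = yt2.set_index("modality").loc["SGT"]
    assert row["n"] == 80 and row["solved"] == 43
    assert row["pct_solved_display"] == 54  # 43/80 = 53.75 -> 54


def test_yield_table_percentages_rederive_from_counts():
    outcomes = [_outcome(i, "solved") for i in range(3)] \
        + [_outcome(3, "possibly_solved")] + [_outcome(4, "unsolved")]
    yt = yield_table(outcomes)
    row = yt.iloc[0]
    assert row["pct_solved"] == pytest.approx(100 * row["solved"] / row["n"])
    assert row["pct_combined"] == pytest.approx(
        100 * (row["solved"] + row["possibly_solved"]) / row["n"])


def test_yield_table_validation():
    with pytest.raises(ValidationError):
        yield_table([])
    with pytest.raises(ValidationError):
        yield_table([_outcome(0, "solved")], by=("favourite_colour",))


def test_gene_frequency_counts_and_mechanism_split():
    outcomes = [
        _outcome(0, "solved", gene="GJB1"),
        _outcome(1, "solved", gene="GJB1"),
        _outcome(2, "solved", gene="PMP22", mechanism="dup"),
        _outcome(3, "solved", gene="PMP22"),
        _outcome(4, "unsolved"),
    ]
    gf = gene_frequency(outcomes)
    assert list(gf["gene"]) == ["GJB1", "PMP22", "PMP22 dup"]
    assert list(gf["count"]) == [2, 1, 1]
    assert gf.loc[0, "pct_of_probands"] == pytest.approx(40.0)


def test_novel_fraction_counts():
    outcomes = [_outcome(i, "solved", novel=(i < 2,)) for i in range(7)]
    res = novel_fraction(outcomes)
    assert res["fraction"] == pytest.approx(2 / 7)
    assert res["n_causal"] == 7
    with pytest.warns(UserWarning):
        empty = novel_fraction([_outcome(0, "unsolved")])
    assert empty["fraction"] is None
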