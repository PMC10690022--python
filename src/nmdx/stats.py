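"""Cohort-level statistics: yield tables, causal-gene frequencies, novel
fractions, and an exact Fisher test for r x c contingency tables.

The Fisher test is implemented from first principles. The two-sided p-value
uses the probability-mass criterion: under the null of independence with both
margins fixed, the probability of a table is multivariate hypergeometric,

    P(T) = (prod_i r_i!)(prod_j c_j!) / (N! prod_ij n_ij!),

and the p-value sums P(T') over all margin-consistent tables with
P(T') <= P(T_obs). Exact enumeration traverses the margin-constrained table
space recursively with cached log-factorials; a Monte Carlo fallback samples
margin-conditional tables by label permutation for tables too large to
enumerate.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import OutcomeRecord, ValidationError

# probability comparisons tolerate floating error relative to the table prob
_REL_TOL = 1e-7


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ContingencyTable:
    """Labelled r x c table of nonnegative integer counts."""

    rows: list
    cols: list
    counts: list  # r x c nested lists or array

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.ndim != 2 or (arr.size and arr.min() < 0):
            raise ValidationError("counts must be a 2-D nonnegative integer array")
        if arr.shape != (len(self.rows), len(self.cols)):
            raise ValidationError("counts shape must match row/column labels")
        self.counts = arr

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.rows, columns=self.cols)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

class _LogFact:
    """Cached log-factorial table."""

    def __init__(self, n: int):
        self.table = np.concatenate(
            [[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])

    def __call__(self, k) -> float:
        return self.table[k]


def _log_prob(table: np.ndarray, lf: _LogFact) -> float:
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(lf(r).sum() + lf(c).sum() - lf(n) - lf(table).sum())


def _enumerate_pvalue(counts: np.ndarray, lf: _LogFact) -> float:
    """Sum P(T') over margin-consistent tables with P(T') <= P(obs)."""
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    n = counts.sum()
    logp_obs = _log_prob(counts, lf)
    cutoff = logp_obs + abs(logp_obs) * _REL_TOL + 1e-12
    nrows, ncols = counts.shape
    # constant part of log P: margins are fixed across the enumeration
    const = float(lf(row_m).sum() + lf(col_m).sum() - lf(n))
    total = 0.0
    work = np.zeros((nrows, ncols), dtype=np.int64)

    def fill_row(i: int, remaining_cols: np.ndarray, acc_cells: float):
        nonlocal total
        if i == nrows - 1:
            # last row forced by remaining column margins
            if (remaining_cols > row_m[i]).any() or remaining_cols.sum() != row_m[i]:
                return
            logp = const - acc_cells - float(lf(remaining_cols).sum())
            if logp <= cutoff:
                total += math.exp(logp)
            return

        target = row_m[i]

        def fill_cell(j: int, left: int, acc: float):
            if j == ncols - 1:
                if left > remaining_cols[j]:
                    return
                work[i, j] = left
                remaining_cols[j] -= left
                fill_row(i + 1, remaining_cols, acc + float(lf(left)))
                remaining_cols[j] += left
                return
            hi = min(left, remaining_cols[j])
            for v in range(hi + 1):
                work[i, j] = v
                remaining_cols[j] -= v
                fill_cell(j + 1, left - v, acc + float(lf(v)))
                remaining_cols[j] += v

        fill_cell(0, int(target), 0.0)

    fill_row(0, col_m.copy(), 0.0)
    return min(total, 1.0)


def _montecarlo_pvalue(counts: np.ndarray, lf: _LogFact, n_sim: int,
                       rng: np.random.Generator) -> float:
    """Margin-conditional Monte Carlo: permute row labels against columns."""
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    nrows, ncols = counts.shape
    logp_obs = _log_prob(counts, lf)
    cutoff = logp_obs + abs(logp_obs) * _REL_TOL + 1e-12
    row_labels = np.repeat(np.arange(nrows), row_m)
    col_labels = np.repeat(np.arange(ncols), col_m)
    hits = 0
    for _ in range(n_sim):
        perm = rng.permutation(row_labels)
        flat = np.bincount(perm * ncols + col_labels, minlength=nrows * ncols)
        sim = flat.reshape(nrows, ncols)
        if _log_prob(sim, lf) <= cutoff:
            hits += 1
    return (1 + hits) / (n_sim + 1)


def fisher_exact(table: ContingencyTable, method: str = "exact",
                 seed: int = 0, n_sim: int = 10000,
                 enumeration_bound: int = 200) -> float:
    """Two-sided Fisher exact p-value for an r x c table.

    method="exact" enumerates every table with the observed margins (grand
    total must not exceed ``enumeration_bound``); method="montecarlo" samples
    ``n_sim`` margin-conditional tables with a fixed seed and returns the
    add-one estimate (1 + hits) / (n_sim + 1).
    """
    counts = np.asarray(table.counts, dtype=np.int64)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValidationError("fisher_exact requires at least a 2x2 table")
    n = int(counts.sum())
    if n == 0:
        raise ValidationError("fisher_exact requires a positive grand total")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        warnings.warn("degenerate table: a row or column margin is zero; p = 1.0")
        return 1.0
    lf = _LogFact(n)
    if method == "exact":
        if n > enumeration_bound:
            raise ValidationError(
                f"grand total {n} exceeds enumeration bound {enumeration_bound}; "
                "use method='montecarlo'")
        return _enumerate_pvalue(counts, lf)
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        return _montecarlo_pvalue(counts, lf, n_sim, rng)
    raise ValidationError(f"unknown method {method!r}")


def chi_square_diagnostic(table: ContingencyTable) -> dict:
    """Pearson chi-square without continuity correction (cross-check only)."""
    from scipy import stats as sps

    counts = np.asarray(table.counts, dtype=float)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    stat = float(terms.sum())
    dof = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return {"statistic": stat, "dof": dof, "pvalue": float(sps.chi2.sf(stat, dof))}


# ---------------------------------------------------------------------------
# Yield and gene-frequency tables
# ---------------------------------------------------------------------------

_GROUP_KEYS = ("category", "country", "modality")


def yield_table(outcomes: list, by=()) -> pd.DataFrame:
    """Solved / possibly-solved / unsolved counts and percentages.

    ``by`` may contain any of category, country, modality. Percentages are
    always recomputed from the integer counts; the display columns round
    half-up to integers to match conventional cohort reporting.
    """
    if not outcomes:
        raise ValidationError("yield_table requires at least one outcome")
    for key in by:
        if key not in _GROUP_KEYS:
            raise ValidationError(f"unknown grouping key {key!r}")
    df = pd.DataFrame([{
        "category": o.category, "country": o.country, "modality": o.modality,
        "outcome": o.outcome} for o in outcomes])
    group_cols = list(by) if by else []
    if group_cols:
        grouped = df.groupby(group_cols, sort=True)
    else:
        grouped = [((), df)]
    rows = []
    for keys, sub in grouped:
        if not isinstance(keys, tuple):
            keys = (keys,)
        n = len(sub)
        if n == 0:
            warnings.warn(f"empty group {keys}: omitted")
            continue
        counts = sub["outcome"].value_counts()
        solved = int(counts.get("solved", 0))
        possibly = int(counts.get("possibly_solved", 0))
        unsolved = int(counts.get("unsolved", 0))
        row = dict(zip(group_cols, keys))
        row.update({
            "n": n, "solved": solved, "possibly_solved": possibly,
            "unsolved": unsolved,
            "pct_solved": 100.0 * solved / n,
            "pct_possibly_solved": 100.0 * possibly / n,
            "pct_combined": 100.0 * (solved + possibly) / n,
        })
        row["pct_solved_display"] = _round_half_up(row["pct_solved"])
        row["pct_possibly_solved_display"] = _round_half_up(row["pct_possibly_solved"])
        row["pct_combined_display"] = _round_half_up(row["pct_combined"])
        rows.append(row)
    return pd.DataFrame(rows)


def _gene_label(gene: str, mechanism) -> str:
    if mechanism in ("dup", "del"):
        return f"{gene} {mechanism}"
    return gene


def gene_frequency(outcomes: list) -> pd.DataFrame:
    """Causal-gene counts among solved/possibly-solved outcomes.

    Deletion/duplication mechanisms of the same gene (e.g. PMP22) are kept as
    distinct labels. Sorted by descending count, then label.
    """
    n_probands = len(outcomes)
    counter: dict = {}
    for o in outcomes:
        if o.outcome == "unsolved" or not o.causal_gene:
            continue
        label = _gene_label(o.causal_gene, o.mechanism)
        counter[label] = counter.get(label, 0) + 1
    rows = [{"gene": g, "count": c,
             "pct_of_probands": 100.0 * c / n_probands if n_probands else 0.0}
            for g, c in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows, columns=["gene", "count", "pct_of_probands"])


def novel_fraction(outcomes: list) -> dict:
    """Fraction of causal variants flagged novel, with per-category breakdown."""
    n_causal = n_novel = 0
    per_cat: dict = {}
    for o in outcomes:
        if not o.causal_variant_ids:
            continue
        flags = o.novel_flags or (False,) * len(o.causal_variant_ids)
        cat = per_cat.setdefault(o.category, [0, 0])
        for fl in flags:
            n_causal += 1
            cat[1] += 1
            if fl:
                n_novel += 1
                cat[0] += 1
    if n_causal == 0:
        warnings.warn("novel_fraction: no causal variants; fraction undefined")
        return {"fraction": None, "n_novel": 0, "n_causal": 0, "per_category": {}}
    return {
        "fraction": n_novel / n_causal,
        "n_novel": n_novel,
        "n_causal": n_causal,
        "per_category": {cat: (nov / tot if tot else None)
                         for cat, (nov, tot) in sorted(per_cat.items())},
    }
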