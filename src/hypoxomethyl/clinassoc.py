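"""Mixed-type clinicopathologic association framework and cohort summaries.

Every variable carries exactly one declared type — categorical, binary or
continuous — and binary variables are ordered, so they travel the rank-based
(non-categorical) path. The statistic pair is a pure function of the declared
type pair, never of the data values:

* non-categorical x non-categorical  -> Spearman rho (effect) + Spearman p
* categorical x categorical          -> Cramér's V (effect) + Fisher exact p
* categorical x non-categorical      -> correlation ratio eta (effect)
                                        + Kruskal-Wallis p
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

VALID_TYPES = ("categorical", "binary", "continuous")

#: declared types treated as non-categorical (rank-based path)
NON_CATEGORICAL = ("binary", "continuous")


@dataclass
class ClinicalTable:
    data: pd.DataFrame
    types: dict[str, str]

    def __post_init__(self):
        for col, t in self.types.items():
            if t not in VALID_TYPES:
                raise ValueError(f"column {col!r}: unknown type {t!r}")

    def type_of(self, col: str) -> str:
        if col not in self.data.columns:
            raise KeyError(f"unknown column {col!r}")
        if col not in self.types:
            raise KeyError(f"column {col!r} has no declared type")
        return self.types[col]

    def is_categorical(self, col: str) -> bool:
        return self.type_of(col) == "categorical"


@dataclass(frozen=True)
class AssociationResult:
    var_a: str
    var_b: str
    method: str  # spearman | cramers_v_fisher | correlation_ratio_kw | ranksum | fisher_exact
    effect: float
    p: float
    n: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Effect measures


def cramers_v(table: np.ndarray) -> float:
    """Cramér's V from a contingency table (no bias correction)."""
    return float(stats.contingency.association(table, method="cramer", correction=False))


def correlation_ratio(groups: Sequence[np.ndarray]) -> float:
    """eta = sqrt(SS_between / SS_total) of a numeric variable across groups."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    if ss_total == 0:
        return np.nan
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    return float(np.sqrt(ss_between / ss_total))


# ---------------------------------------------------------------------------
# Fisher's exact test for r x c tables


def _log_table_prob(table: np.ndarray, log_margin_const: float) -> float:
    return log_margin_const - float(gammaln(table + 1).sum())


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=np.int64)

    def fill(i, remaining_cols):
        if i == r - 1:
            table[i, :] = remaining_cols
            if (table[i, :] >= 0).all():
                yield table
            return
        def fill_row(j, left_in_row, rem):
            if j == c - 1:
                if 0 <= left_in_row <= rem[j]:
                    table[i, j] = left_in_row
                    new_rem = rem.copy()
                    new_rem[j] -= left_in_row
                    yield new_rem
                return
            hi = min(left_in_row, rem[j])
            for v in range(hi + 1):
                table[i, j] = v
                new_rem = rem.copy()
                new_rem[j] -= v
                yield from fill_row(j + 1, left_in_row - v, new_rem)
        for rem_after in fill_row(0, int(row_sums[i]), remaining_cols):
            yield from fill(i + 1, rem_after)

    yield from fill(0, np.asarray(col_sums, dtype=np.int64).copy())


def fisher_exact_rc(
    table,
    max_exact_total: int = 200,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided Fisher exact p for an r x c contingency table.

    2x2 tables use the closed hypergeometric form; larger tables are handled
    by exhaustive enumeration of all tables with the observed margins when the
    grand total is <= ``max_exact_total``, otherwise by Monte Carlo sampling
    from the conditional null (fixed seed, add-one rule).
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("table must be a non-negative 2-D array")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    N = int(table.sum())
    log_const = float(gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(N + 1))
    logp_obs = _log_table_prob(table, log_const)
    eps = 1e-9
    if N <= max_exact_total:
        p = 0.0
        for t in _enumerate_tables(rows, cols):
            lp = _log_table_prob(t, log_const)
            if lp <= logp_obs + eps:
                p += np.exp(lp)
        return float(min(p, 1.0))
    # Monte Carlo: permute one margin's labels, vectorized over draws
    rng = np.random.default_rng(seed)
    a = np.repeat(np.arange(len(rows)), rows)
    b = np.repeat(np.arange(len(cols)), cols)
    rc = len(rows) * len(cols)
    draws = rng.permuted(np.tile(b, (n_mc, 1)), axis=1)
    codes = a[None, :] * len(cols) + draws
    flat = (np.arange(n_mc)[:, None] * rc + codes).ravel()
    counts = np.bincount(flat, minlength=n_mc * rc).reshape(n_mc, rc)
    logp_sim = log_const - gammaln(counts + 1).sum(axis=1)
    hits = int((logp_sim <= logp_obs + eps).sum())
    return float((1 + hits) / (n_mc + 1))


# ---------------------------------------------------------------------------
# Pairwise association


def _complete_pair(table: ClinicalTable, a: str, b: str) -> pd.DataFrame:
    sub = table.data[[a, b]].dropna()
    if len(sub) < 3:
        raise ValueError(f"fewer than 3 pairwise-complete rows for ({a}, {b})")
    return sub


def associate(table: ClinicalTable, var_a: str, var_b: str) -> AssociationResult:
    """Dispatch on the declared type pair and compute (effect, p)."""
    ta, tb = table.type_of(var_a), table.type_of(var_b)
    sub = _complete_pair(table, var_a, var_b)
    n = len(sub)
    xa, xb = sub[var_a], sub[var_b]
    degenerate = xa.nunique() <= 1 or xb.nunique() <= 1

    if ta != "categorical" and tb != "categorical":
        if degenerate:
            return AssociationResult(var_a, var_b, "spearman", np.nan, np.nan, n, True)
        rho, p = stats.spearmanr(xa.astype(float), xb.astype(float))
        return AssociationResult(var_a, var_b, "spearman", float(rho), float(p), n)

    if ta == "categorical" and tb == "categorical":
        if degenerate:
            return AssociationResult(var_a, var_b, "cramers_v_fisher", np.nan, np.nan, n, True)
        ct = pd.crosstab(xa, xb).to_numpy()
        return AssociationResult(
            var_a, var_b, "cramers_v_fisher", cramers_v(ct), fisher_exact_rc(ct), n
        )

    # one categorical, one numeric
    cat, num = (xa, xb) if ta == "categorical" else (xb, xa)
    if degenerate:
        return AssociationResult(var_a, var_b, "correlation_ratio_kw", np.nan, np.nan, n, True)
    groups = [g.to_numpy(float) for _, g in num.groupby(cat, observed=True)]
    eta = correlation_ratio(groups)
    _, p = stats.kruskal(*groups)
    return AssociationResult(var_a, var_b, "correlation_ratio_kw", eta, float(p), n)


def association_matrix(
    table: ClinicalTable, targets: Sequence[str], features: Sequence[str]
) -> pd.DataFrame:
    """Long-format association results for every (target, feature) pair,
    sorted by p."""
    rows = [
        associate(table, t, f).__dict__
        for t in targets
        for f in features
        if t != f
    ]
    df = pd.DataFrame(rows, columns=["var_a", "var_b", "method", "effect", "p", "n", "degenerate"])
    return df.sort_values("p", na_position="last").reset_index(drop=True)


def group_compare(table: ClinicalTable, group_col: str) -> pd.DataFrame:
    """Feature distributions across a binary group: rank-sum for numeric
    features, Fisher exact for categorical ones."""
    if table.type_of(group_col) != "binary":
        raise ValueError(f"{group_col!r} is not declared binary")
    results = []
    for col in table.data.columns:
        if col == group_col or col not in table.types:
            continue
        sub = table.data[[group_col, col]].dropna()
        if sub[group_col].nunique() != 2:
            raise ValueError(f"{group_col!r} is not binary on complete cases")
        levels = sorted(sub[group_col].unique())
        if table.is_categorical(col):
            if sub[col].nunique() <= 1:
                results.append(AssociationResult(group_col, col, "fisher_exact", np.nan, np.nan, len(sub), True))
                continue
            ct = pd.crosstab(sub[group_col], sub[col]).to_numpy()
            results.append(
                AssociationResult(group_col, col, "fisher_exact", cramers_v(ct), fisher_exact_rc(ct), len(sub))
            )
        else:
            g0 = sub.loc[sub[group_col] == levels[0], col].astype(float)
            g1 = sub.loc[sub[group_col] == levels[1], col].astype(float)
            if sub[col].nunique() <= 1:
                results.append(AssociationResult(group_col, col, "ranksum", np.nan, np.nan, len(sub), True))
                continue
            u, p = stats.mannwhitneyu(g0, g1, alternative="two-sided")
            results.append(AssociationResult(group_col, col, "ranksum", float(u), float(p), len(sub)))
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Cohort summaries


def percent(count: int, denom: int, decimals: int = 1) -> float:
    """Percentage with half-up rounding to the printed precision."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(count) * 100 / Decimal(denom)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def _summarize_stratum(data: pd.DataFrame, types: dict[str, str], decimals: int):
    rows = []
    for col, t in types.items():
        if col not in data.columns:
            continue
        vals = data[col].dropna()
        if t in ("categorical", "binary"):
            denom = len(vals)
            for level, cnt in vals.value_counts().sort_index().items():
                pct = percent(int(cnt), denom, decimals) if denom else None
                rows.append((col, str(level), int(cnt), denom, pct if pct is not None else "-"))
        else:
            if len(vals) == 0:
                rows.append((col, "median (range)", 0, 0, "-"))
            else:
                v = vals.astype(float)
                rows.append(
                    (col, f"median (range) = {v.median():g} ({v.min():g}-{v.max():g})",
                     len(v), len(v), "-")
                )
    return rows


def cohort_summary(
    table: ClinicalTable,
    stratify_by: str | None = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Counts and percentages per categorical level, median (range) per
    continuous variable, optionally stratified. Percentages use the
    non-missing denominator; empty strata render '-'."""
    if stratify_by is not None and stratify_by not in table.data.columns:
        raise KeyError(f"unknown column {stratify_by!r}")
    frames = []
    if stratify_by is None:
        rows = _summarize_stratum(table.data, table.types, decimals)
        frames.append(pd.DataFrame(rows, columns=["variable", "level", "count", "denom", "percent"]))
        frames[-1].insert(0, "stratum", "all")
    else:
        for level, sub in table.data.groupby(stratify_by, observed=True, dropna=False):
            types = {c: t for c, t in table.types.items() if c != stratify_by}
            rows = _summarize_stratum(sub, types, decimals)
            f = pd.DataFrame(rows, columns=["variable", "level", "count", "denom", "percent"])
            f.insert(0, "stratum", str(level))
            frames.append(f)
    return pd.concat(frames, ignore_index=True)
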