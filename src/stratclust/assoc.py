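"""Contingency-table association tests and partition agreement.

Fisher's exact test uses the probability-ordering two-sided convention
(summing the probabilities of all fixed-margin tables no more probable than
the observed one), either by full enumeration or by Monte-Carlo sampling.
The chi-squared test resamples tables with both margins fixed via random
permutation.  Resampled p-values use the (count + 1)/(B + 1) convention so
the attainable minimum with B = 99999 is 0.00001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "TestResult",
    "crosstab",
    "fisher_exact",
    "chisq_mc",
    "adjusted_rand_index",
    "ari_interpretation",
    "association_scan",
]

_ENUM_CAP = 1_000_000  # enumerate exactly up to this many fixed-margin tables
_PROB_TOL = 1 + 1e-7   # relative tolerance when comparing table probabilities


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list
    col_labels: list
    n_dropped: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            c = np.asarray(self.counts, dtype=int)
            if np.any(c < 0):
                raise ValueError("counts must be non-negative integers")
        if c.sum() < 1:
            raise ValueError("table is empty")
        self.counts = c

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def drop_columns(self, names) -> "ContingencyTable":
        keep = [j for j, c in enumerate(self.col_labels) if c not in set(names)]
        if not keep:
            raise ValueError("no columns left after drop")
        return ContingencyTable(self.counts[:, keep],
                                self.row_labels,
                                [self.col_labels[j] for j in keep],
                                self.n_dropped)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)


@dataclass
class TestResult:
    statistic: float | None
    p_value: float
    method: str
    B: int | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)


def crosstab(labels_a, labels_b, drop_categories=()) -> ContingencyTable:
    """Cross-tabulate two equal-length categorical vectors.

    Samples missing (NaN/None) in either vector are dropped and counted in
    ``n_dropped``; categories in ``drop_categories`` are removed afterwards
    with margins recomputed.
    """
    a = pd.Series(np.asarray(labels_a, dtype=object))
    b = pd.Series(np.asarray(labels_b, dtype=object))
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    ok = a.notna() & b.notna()
    n_dropped = int((~ok).sum())
    tab = pd.crosstab(a[ok], b[ok])
    table = ContingencyTable(tab.to_numpy(), list(tab.index), list(tab.columns),
                             n_dropped)
    if drop_categories:
        table = table.drop_columns(drop_categories)
        if table.counts.sum() < 1:
            raise ValueError("table empty after category drop")
    return table


def _log_table_prob(counts, logfact_margins, log_nfact):
    """Log hypergeometric probability of a table given both margins."""
    return logfact_margins - log_nfact - gammaln(np.asarray(counts) + 1.0).sum()


def _margin_const(table: ContingencyTable):
    lf = gammaln(table.row_margins + 1.0).sum() + gammaln(table.col_margins + 1.0).sum()
    return lf, gammaln(table.total + 1.0)


def _enumerate_tables(row_margins, col_margins, cap=_ENUM_CAP):
    """Yield every non-negative integer table with the given margins.

    Recursion over rows; each row enumerates the compositions compatible
    with the remaining column totals.  Raises ``OverflowError`` past ``cap``.
    """
    r = len(row_margins)
    out_count = [0]

    def row_fills(total, limits):
        if len(limits) == 1:
            if total <= limits[0]:
                yield (total,)
            return
        for v in range(min(total, limits[0]) + 1):
            for rest in row_fills(total - v, limits[1:]):
                yield (v,) + rest

    def rec(i, remaining_cols, acc):
        if i == r - 1:
            if all(v >= 0 for v in remaining_cols):
                out_count[0] += 1
                if out_count[0] > cap:
                    raise OverflowError("enumeration cap exceeded")
                yield acc + [list(remaining_cols)]
            return
        for row in row_fills(int(row_margins[i]), tuple(remaining_cols)):
            new_cols = tuple(c - v for c, v in zip(remaining_cols, row))
            yield from rec(i + 1, new_cols, acc + [list(row)])

    yield from rec(0, tuple(int(c) for c in col_margins), [])


def _sample_tables(table: ContingencyTable, B: int, rng: np.random.Generator,
                   chunk: int = 2000):
    """Sample B tables with both margins fixed by permuting one label vector.

    Yields arrays of shape (chunk, r, c)."""
    r, c = table.counts.shape
    a = np.repeat(np.arange(r), table.row_margins)
    b = np.repeat(np.arange(c), table.col_margins)
    n = a.size
    done = 0
    while done < B:
        s = min(chunk, B - done)
        # random permutations of b, one per row, via argsort of uniforms
        perm = rng.random((s, n)).argsort(axis=1)
        codes = a[None, :] * c + b[perm]
        offset = (np.arange(s) * (r * c))[:, None]
        flat = np.bincount((codes + offset).ravel(), minlength=s * r * c)
        yield flat.reshape(s, r, c)
        done += s


def fisher_exact(table: ContingencyTable, mode: str = "auto", B: int = 100_000,
                 seed: int | None = None) -> TestResult:
    """Fisher's exact test for an r x c table (probability-ordering, two-sided).

    ``enumerate`` sums hypergeometric probabilities of every fixed-margin
    table no more probable than the observed one; ``monte_carlo`` estimates
    the same tail by sampling; ``auto`` enumerates when the number of tables
    is at most one million and falls back to Monte-Carlo otherwise.
    """
    if mode not in ("auto", "enumerate", "monte_carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    if np.any(table.row_margins == 0) or np.any(table.col_margins == 0):
        raise ValueError("table has a zero margin; drop empty categories first")
    lf, lnf = _margin_const(table)
    logp_obs = _log_table_prob(table.counts, lf, lnf)

    # cheap upper bound on the fixed-margin table count: compositions of each
    # row margin into c parts, ignoring the column constraints
    from math import comb
    c = table.counts.shape[1]
    bound = 1
    for rm in table.row_margins[:-1]:
        bound *= comb(int(rm) + c - 1, c - 1)
        if bound > _ENUM_CAP:
            break
    tractable = bound <= _ENUM_CAP

    if mode == "enumerate" or (mode == "auto" and tractable):
        try:
            p = 0.0
            for t in _enumerate_tables(table.row_margins, table.col_margins):
                lp = _log_table_prob(t, lf, lnf)
                if np.exp(lp) <= np.exp(logp_obs) * _PROB_TOL:
                    p += np.exp(lp)
            return TestResult(statistic=None, p_value=min(1.0, p),
                              method="fisher_enumerate")
        except OverflowError:
            if mode == "enumerate":
                raise ValueError(
                    "too many fixed-margin tables to enumerate; use monte_carlo"
                ) from None

    rng = np.random.default_rng(seed)
    count = 0
    for tables in _sample_tables(table, B, rng):
        lps = (lf - lnf
               - gammaln(tables + 1.0).sum(axis=(1, 2)))
        count += int((np.exp(lps) <= np.exp(logp_obs) * _PROB_TOL).sum())
    return TestResult(statistic=None, p_value=(count + 1) / (B + 1),
                      method="fisher_monte_carlo", B=B, seed=seed)


def _chisq_stat(counts, expected):
    return float(((counts - expected) ** 2 / expected).sum())


def chisq_mc(table: ContingencyTable, B: int = 99_999,
             seed: int | None = None) -> TestResult:
    """Pearson chi-squared with a resampled p-value (both margins fixed).

    p = (1 + #{X2_sim >= X2_obs}) / (B + 1); the asymptotic chi-squared
    p-value is reported alongside.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if np.any(table.row_margins == 0) or np.any(table.col_margins == 0):
        raise ValueError("table has a zero margin; drop empty categories first")
    from scipy.stats import chi2

    expected = np.outer(table.row_margins, table.col_margins) / table.total
    x2_obs = _chisq_stat(table.counts, expected)
    rng = np.random.default_rng(seed)
    count = 0
    for tables in _sample_tables(table, B, rng):
        x2 = ((tables - expected) ** 2 / expected).sum(axis=(1, 2))
        count += int((x2 >= x2_obs - 1e-9).sum())
    r, c = table.counts.shape
    df = (r - 1) * (c - 1)
    p_asym = float(chi2.sf(x2_obs, df)) if df > 0 else 1.0
    return TestResult(statistic=x2_obs, p_value=(count + 1) / (B + 1),
                      method="chisq_mc", B=B, seed=seed,
                      extra={"df": df, "p_asymptotic": p_asym})


def adjusted_rand_index(P, Q) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    1 means identical groupings (up to relabelling); the expected value under
    random labellings is about 0.
    """
    P = np.asarray(P)
    Q = np.asarray(Q)
    if P.shape != Q.shape:
        raise ValueError("partitions must have equal length")
    tab = pd.crosstab(pd.Series(P), pd.Series(Q)).to_numpy()
    n = tab.sum()
    sum_comb = (tab * (tab - 1) / 2).sum()
    a = tab.sum(axis=1)
    b = tab.sum(axis=0)
    comb_a = (a * (a - 1) / 2).sum()
    comb_b = (b * (b - 1) / 2).sum()
    total = n * (n - 1) / 2
    expected = comb_a * comb_b / total
    max_index = (comb_a + comb_b) / 2
    if max_index == expected:
        return 1.0  # both partitions trivial (all-one-cluster or all-singletons)
    return float((sum_comb - expected) / (max_index - expected))


def ari_interpretation(ari: float) -> str:
    """Agreement band: >0.9 excellent, >0.8 good, >0.65 moderate, else poor."""
    if ari > 0.9:
        return "excellent"
    if ari > 0.8:
        return "good"
    if ari > 0.65:
        return "moderate"
    return "poor"


def association_scan(partition, sample_table, columns=None, B: int = 99_999,
                     seed: int | None = None, method_rule: str = "auto",
                     drop_categories=(), bonferroni: bool = True,
                     sample_ids=None) -> pd.DataFrame:
    """Test each categorical subphenotype against a cluster partition.

    Per variable (available-case): Fisher's exact test when any expected cell
    count is below 5, otherwise the Monte-Carlo chi-squared test.  Constant
    or all-missing variables are skipped with a warning.  Returns a report
    with one row per variable (p, method, optional Bonferroni-adjusted p).
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(partition.labels if hasattr(partition, "labels")
                        else partition)
    if columns is None:
        columns = sample_table.columns
    rows = []
    for name in columns:
        col = sample_table.column(name, sample_ids=sample_ids)
        vals = col.to_numpy(dtype=object)
        non_missing = pd.Series(vals).notna()
        if non_missing.sum() == 0 or pd.Series(vals[non_missing]).nunique() < 2:
            warnings.warn(f"variable {name!r} constant or all missing; skipped")
            continue
        table = crosstab(labels, vals, drop_categories=drop_categories)
        expected = np.outer(table.row_margins, table.col_margins) / table.total
        if method_rule == "fisher" or (method_rule == "auto" and (expected < 5).any()):
            res = fisher_exact(table, mode="auto", seed=int(rng.integers(2**31)))
        else:
            res = chisq_mc(table, B=B, seed=int(rng.integers(2**31)))
        rows.append({"variable": name, "p_value": res.p_value,
                     "method": res.method, "statistic": res.statistic,
                     "n_used": table.total})
    report = pd.DataFrame(rows)
    if bonferroni and len(report):
        report["p_bonferroni"] = np.minimum(1.0, report["p_value"] * len(report))
    return report
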