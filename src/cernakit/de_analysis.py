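"""Differential-expression calling on two-group count matrices.

Counts are CPM-normalized, per-feature tests are run on log2(CPM+1), and
significance is called with class-specific gates: a fold-change floor plus
either a raw-p or a BH-adjusted-q cutoff.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, DesignError, InputError

RNA_CLASSES = ("circRNA", "miRNA", "mRNA")

__all__ = [
    "CountMatrix",
    "DERecord",
    "DEThresholds",
    "normalize_cpm",
    "log_expression",
    "log2_fold_change",
    "de_test",
    "bh_fdr",
    "call_de",
    "run_de",
    "ddct_relative_expression",
    "de_table",
]


@dataclass
class CountMatrix:
    """Integer feature-by-sample counts with a two-group design.

    Parameters
    ----------
    feature_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    group_of : dict
        Maps every sample id to one of exactly two group labels.
    values : ndarray
        Non-negative integers, shape ``(len(feature_ids), len(sample_ids))``.
    rna_class : str
        One of ``circRNA``, ``miRNA``, ``mRNA``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    group_of: dict[str, str]
    values: np.ndarray
    rna_class: str

    def __post_init__(self) -> None:
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        if self.rna_class not in RNA_CLASSES:
            raise InputError(f"unknown rna_class {self.rna_class!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dup = _first_duplicate(self.feature_ids)
            raise InputError(f"duplicate feature id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise InputError(f"duplicate sample id {dup!r}")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise InputError(f"sample {missing[0]!r} has no group label")
        if len(self.groups) != 2:
            raise InputError(
                f"expected exactly two group labels, found {self.groups}"
            )
        values = np.asarray(self.values)
        if values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise InputError(
                f"values shape {values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(values.dtype, np.integer):
            rounded = np.rint(values)
            if not np.array_equal(rounded, values):
                raise InputError("counts must be integers")
            values = rounded.astype(np.int64)
        if (values < 0).any():
            raise InputError("counts must be non-negative")
        self.values = values
        totals = values.sum(axis=0)
        if (totals == 0).any():
            bad = self.sample_ids[int(np.argmax(totals == 0))]
            raise DegenerateInputError(f"sample {bad!r} has zero total count")

    @property
    def groups(self) -> tuple[str, ...]:
        """Group labels in order of first appearance along the sample axis."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.group_of[s], None)
        return tuple(seen)

    def group_columns(self, group: str) -> list[int]:
        return [i for i, s in enumerate(self.sample_ids) if self.group_of[s] == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


@dataclass
class DEThresholds:
    """Significance gate: fold change plus a raw-p or FDR cutoff."""

    min_fold_change: float = 2.0
    p_cutoff: float = 0.05
    use_fdr: bool = False

    def __post_init__(self) -> None:
        if not self.min_fold_change > 1:
            raise InputError("min_fold_change must exceed 1")
        if not 0 < self.p_cutoff < 1:
            raise InputError("p_cutoff must lie in (0, 1)")


@dataclass
class DERecord:
    """Per-feature differential-expression outcome (group 2 vs group 1)."""

    feature_id: str
    rna_class: str
    mean_expr_g1: float
    mean_expr_g2: float
    log2fc: float
    p_value: float
    q_value: float
    direction: str = "none"
    significant: bool = False


def normalize_cpm(counts: CountMatrix) -> np.ndarray:
    """Counts-per-million: each column rescaled to sum to 1e6."""
    totals = counts.values.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = counts.sample_ids[int(np.argmax(totals == 0))]
        raise DegenerateInputError(f"sample {bad!r} has zero total count")
    return counts.values / totals * 1e6


def log_expression(counts: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount), as a feature-by-sample DataFrame."""
    cpm = normalize_cpm(counts)
    return pd.DataFrame(
        np.log2(cpm + pseudocount),
        index=counts.feature_ids,
        columns=counts.sample_ids,
    )


def log2_fold_change(mean_g1, mean_g2, pseudocount: float = 1.0):
    """log2 ratio of group-2 to group-1 mean expression, with a pseudocount.

    Accepts scalars or arrays.
    """
    g1 = np.asarray(mean_g1, dtype=float)
    g2 = np.asarray(mean_g2, dtype=float)
    if (g1 < 0).any() or (g2 < 0).any():
        raise InputError("mean expression must be non-negative")
    if pseudocount <= 0:
        raise InputError("pseudocount must be positive")
    out = np.log2((g2 + pseudocount) / (g1 + pseudocount))
    return float(out) if out.ndim == 0 else out


def de_test(
    counts: CountMatrix,
    method: str = "welch_t",
    pseudocount: float = 1.0,
    max_exact_permutations: int = 200_000,
) -> list[tuple[str, float]]:
    """Per-feature two-group test on log2(CPM + pseudocount).

    ``welch_t`` is the default. ``permutation`` enumerates every relabelling
    of samples (two-sided, on |mean difference|) and requires at least four
    samples per group: with 3 vs 3 only 20 assignments exist and the smallest
    attainable two-sided p (0.1) can never clear a 0.05 gate.

    Features with zero variance within both groups get p = 1.
    """
    g1, g2 = counts.groups
    idx1 = counts.group_columns(g1)
    idx2 = counts.group_columns(g2)
    if min(len(idx1), len(idx2)) < 2:
        raise DesignError("de_test requires at least two samples per group")
    x = np.log2(normalize_cpm(counts) + pseudocount)
    a, b = x[:, idx1], x[:, idx2]
    flat = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)

    if method == "welch_t":
        import warnings

        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.where(flat | ~np.isfinite(p), 1.0, p)
    elif method == "permutation":
        if min(len(idx1), len(idx2)) < 4:
            raise DesignError(
                "permutation test requires at least four samples per group"
            )
        p = _permutation_pvalues(a, b, max_exact_permutations)
        p = np.where(flat, 1.0, p)
    else:
        raise InputError(f"unknown de_test method {method!r}")
    return list(zip(counts.feature_ids, (float(v) for v in p)))


def _permutation_pvalues(
    a: np.ndarray, b: np.ndarray, max_exact: int
) -> np.ndarray:
    """Exact two-sided label-permutation p on |mean(a) - mean(b)|.

    Enumerates all ways to choose the first group out of the pooled samples;
    falls back to a fixed-seed Monte-Carlo sample when the enumeration would
    exceed ``max_exact`` assignments.
    """
    pooled = np.hstack([a, b])
    n1 = a.shape[1]
    n_total = pooled.shape[1]
    observed = np.abs(a.mean(axis=1) - b.mean(axis=1))
    n_comb = math.comb(n_total, n1)
    if n_comb <= max_exact:
        assignments = itertools.combinations(range(n_total), n1)
        splits = np.array(list(assignments))
    else:
        rng = np.random.default_rng(0)
        splits = np.array(
            [rng.permutation(n_total)[:n1] for _ in range(max_exact)]
        )
    count = np.zeros(pooled.shape[0], dtype=np.int64)
    all_idx = np.arange(n_total)
    for rows in splits:
        mask = np.zeros(n_total, dtype=bool)
        mask[list(rows)] = True
        stat = np.abs(
            pooled[:, mask].mean(axis=1) - pooled[:, all_idx[~mask]].mean(axis=1)
        )
        count += stat >= observed - 1e-12
    return count / len(splits)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_de(records: pd.DataFrame, thresholds: DEThresholds) -> list[DERecord]:
    """Apply the significance gate to a table of per-feature statistics.

    ``records`` must carry columns ``feature_id, rna_class, mean_expr_g1,
    mean_expr_g2, log2fc, p_value, q_value``.
    """
    out: list[DERecord] = []
    lfc_floor = math.log2(thresholds.min_fold_change)
    for row in records.itertuples(index=False):
        stat = row.q_value if thresholds.use_fdr else row.p_value
        significant = abs(row.log2fc) >= lfc_floor and stat < thresholds.p_cutoff
        direction = "none"
        if significant:
            direction = "up" if row.log2fc > 0 else "down"
        out.append(
            DERecord(
                feature_id=row.feature_id,
                rna_class=row.rna_class,
                mean_expr_g1=float(row.mean_expr_g1),
                mean_expr_g2=float(row.mean_expr_g2),
                log2fc=float(row.log2fc),
                p_value=float(row.p_value),
                q_value=float(row.q_value),
                direction=direction,
                significant=bool(significant),
            )
        )
    return out


def run_de(
    counts: CountMatrix,
    thresholds: DEThresholds,
    method: str = "welch_t",
    pseudocount: float = 1.0,
) -> list[DERecord]:
    """CPM -> fold change -> test -> BH -> gate, in one call."""
    cpm = normalize_cpm(counts)
    g1, g2 = counts.groups
    mean1 = cpm[:, counts.group_columns(g1)].mean(axis=1)
    mean2 = cpm[:, counts.group_columns(g2)].mean(axis=1)
    lfc = log2_fold_change(mean1, mean2, pseudocount)
    p = np.array([pv for _, pv in de_test(counts, method, pseudocount)])
    q = bh_fdr(p)
    table = pd.DataFrame(
        {
            "feature_id": counts.feature_ids,
            "rna_class": counts.rna_class,
            "mean_expr_g1": mean1,
            "mean_expr_g2": mean2,
            "log2fc": lfc,
            "p_value": p,
            "q_value": q,
        }
    )
    return call_de(table, thresholds)


def de_table(records: list[DERecord], group_labels: tuple[str, str]) -> pd.DataFrame:
    """Flatten DERecords into the exported TSV layout."""
    g1, g2 = group_labels
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "class": [r.rna_class for r in records],
            f"mean_{g1}": [r.mean_expr_g1 for r in records],
            f"mean_{g2}": [r.mean_expr_g2 for r in records],
            "log2FC": [r.log2fc for r in records],
            "pvalue": [r.p_value for r in records],
            "qvalue": [r.q_value for r in records],
            "direction": [r.direction for r in records],
            "significant": [r.significant for r in records],
        }
    )


def ddct_relative_expression(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Comparative-Ct relative quantification, 2**(-ddCt)."""
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(v):
            raise InputError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
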