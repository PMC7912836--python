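"""Per-dataset COPD vs non-COPD differential expression on log2 data.

For each gene of the curated geneset detected in a cohort, a two-sample
t-test (Welch by default) compares COPD against non-COPD log2 expression.
Benjamini–Hochberg step-up FDR is applied per dataset over exactly the tested
geneset genes. Two effect statistics are reported per gene:

* log2 fold change = mean(log2 COPD) − mean(log2 non-COPD), positive when the
  gene is up in COPD;
* log10 ratio = log10(mean linear non-COPD / mean linear COPD), the dot-plot
  y-axis statistic, which deliberately has the opposite orientation.

The t statistic and the BH adjustment are computed from first principles
(only the t distribution's CDF comes from scipy); significance defaults to
raw p < alpha, with a stricter q < alpha rule available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionDataset
from .geneset import GeneSet

logger = logging.getLogger(__name__)

SIG_RULES = ("raw_p", "fdr_q")
T_VARIANTS = ("welch", "student")


def two_group_t_test(
    x: Sequence[float], y: Sequence[float], variant: str = "welch"
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test of x vs y.

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom under
    ``variant='welch'`` or pooled-variance df under ``'student'``. Swapping x
    and y negates t and leaves p unchanged.

    Degenerate inputs follow a fixed convention: both groups constant and
    equal gives (0, df, 1); both constant but unequal gives p=0 with a
    warning (the difference is certain at zero noise).
    """
    if variant not in T_VARIANTS:
        raise ValueError(f"variant must be one of {T_VARIANTS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    m1, m2 = x.mean(), y.mean()
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    df_pooled = float(n1 + n2 - 2)
    if v1 == 0.0 and v2 == 0.0:
        if m1 == m2:
            return 0.0, df_pooled, 1.0
        logger.warning(
            "two constant groups with unequal means (%g vs %g): p=0 convention",
            m1,
            m2,
        )
        t = math.inf if m1 > m2 else -math.inf
        return t, df_pooled, 0.0
    if variant == "welch":
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_pooled
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = df_pooled
    t = (m1 - m2) / math.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1, where p_(1..m) are
    the sorted p-values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential-expression statistics for one cohort."""

    gene: str
    log2fc: float
    log10_ratio: float
    t_stat: float
    df: float
    p: float
    q: float
    significant: bool
    n_copd: int
    n_noncopd: int


@dataclass
class DatasetDEResult:
    """All per-gene results for one cohort, with the significance bookkeeping."""

    dataset_id: str
    compartment: str
    results: dict[str, DEResult]
    alpha: float
    sig_rule: str

    @property
    def n_tested(self) -> int:
        return len(self.results)

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.results.values())

    def significant_genes(self) -> set[str]:
        return {g for g, r in self.results.items() if r.significant}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": r.gene,
                "log2fc": r.log2fc,
                "log10_ratio": r.log10_ratio,
                "t": r.t_stat,
                "df": r.df,
                "p": r.p,
                "q": r.q,
                "significant": int(r.significant),
            }
            for r in self.results.values()
        ]
        return pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)

    def summary(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "compartment": self.compartment,
            "n_tested": self.n_tested,
            "n_significant": self.n_significant,
            "pct_significant": (
                round(100.0 * self.n_significant / self.n_tested, 1)
                if self.n_tested
                else 0.0
            ),
            "alpha": self.alpha,
            "sig_rule": self.sig_rule,
        }


def run_diffexp(
    ds: ExpressionDataset,
    geneset: GeneSet,
    alpha: float = 0.05,
    sig_rule: str = "raw_p",
    variant: str = "welch",
) -> DatasetDEResult:
    """Test every geneset gene detected in one cohort, COPD vs non-COPD.

    The dataset must already be on log2 scale (see
    :func:`cilicopd.expression.ensure_log2`). BH FDR runs over exactly the
    tested genes — the analysis is geneset-restricted, not transcriptome-wide.
    """
    if ds.scale != "log2":
        raise ValueError(f"{ds.dataset_id}: run ensure_log2 before testing")
    if sig_rule not in SIG_RULES:
        raise ValueError(f"sig_rule must be one of {SIG_RULES}")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    genes = sorted(set(geneset.symbols) & set(ds.gene_ids))
    if not genes:
        raise ValueError(f"{ds.dataset_id}: no geneset genes present in matrix")

    gene_row = {g: i for i, g in enumerate(ds.gene_ids)}
    copd_cols = ds.group_columns("copd")
    non_cols = ds.group_columns("non_copd")
    linear = ds.linear_matrix()

    stats_per_gene = []
    for gene in genes:
        row = gene_row[gene]
        x = ds.values[row, copd_cols]  # log2 COPD
        y = ds.values[row, non_cols]  # log2 non-COPD
        t, df, p = two_group_t_test(x, y, variant=variant)
        log2fc = float(x.mean() - y.mean())
        mean_copd = float(linear[row, copd_cols].mean())
        mean_non = float(linear[row, non_cols].mean())
        if mean_copd > 0 and mean_non > 0:
            log10_ratio = math.log10(mean_non / mean_copd)
        else:
            log10_ratio = math.nan
        stats_per_gene.append((gene, log2fc, log10_ratio, t, df, p))

    qvals = bh_fdr([s[5] for s in stats_per_gene])
    results = {}
    for (gene, log2fc, log10_ratio, t, df, p), q in zip(stats_per_gene, qvals):
        sig = (p < alpha) if sig_rule == "raw_p" else (q < alpha)
        results[gene] = DEResult(
            gene=gene,
            log2fc=log2fc,
            log10_ratio=log10_ratio,
            t_stat=t,
            df=df,
            p=p,
            q=float(q),
            significant=bool(sig),
            n_copd=copd_cols.size,
            n_noncopd=non_cols.size,
        )
    return DatasetDEResult(
        dataset_id=ds.dataset_id,
        compartment=ds.compartment,
        results=results,
        alpha=alpha,
        sig_rule=sig_rule,
    )
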