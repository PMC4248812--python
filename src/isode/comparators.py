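"""Fisher's exact test baseline for differential expression.

For each gene a 2x2 contingency table is built whose first row holds the
estimated reads per kilobase of gene length in conditions A and B (derived
from FPKM) and whose second row holds normalization counts: the total
mapped reads ("total"), the reads per kilobase of a housekeeping gene
("housekeeping", POLR2A by default), or reads per kilobase of the
aggregated ERCC spike-in FPKM ("ercc").  The two-sided p-value is the exact
hypergeometric tail — the sum of probabilities of tables, with margins
fixed, no more likely than the observed one — computed in log space so
entries up to ~1e8 are safe.  P-values are adjusted with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .bootstrap_de import DECall, fold_change
from .quantify import AbundanceEstimate, reads_per_kilobase

__all__ = [
    "ContingencyTable2x2",
    "NormalizationScheme",
    "build_table",
    "fisher_p",
    "bh_adjust",
    "run_fisher_de",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for one gene: (gene rpk in A, B) over (normalization in A, B)."""

    rpk_gene_a: int
    rpk_gene_b: int
    norm_a: int
    norm_b: int

    def __post_init__(self) -> None:
        vals = (self.rpk_gene_a, self.rpk_gene_b, self.norm_a, self.norm_b)
        if any(v < 0 for v in vals):
            raise ValueError(f"contingency entries must be >= 0, got {vals}")
        if self.rpk_gene_a + self.rpk_gene_b + self.norm_a + self.norm_b == 0:
            raise ValueError("contingency table is all zero")

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.rpk_gene_a, self.rpk_gene_b], [self.norm_a, self.norm_b]],
            dtype=np.int64,
        )


@dataclass
class NormalizationScheme:
    """How the second contingency row is filled.

    kind
        ``"total"``: total mapped reads per condition.
        ``"housekeeping"``: reads per kilobase of ``housekeeping_gene``.
        ``"ercc"``: reads per kilobase of the aggregated ERCC spike-in FPKM.
    """

    kind: str = "total"
    housekeeping_gene: str = "POLR2A"
    ercc_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.kind not in ("total", "housekeeping", "ercc"):
            raise ValueError(f"unknown normalization kind {self.kind!r}")
        if self.kind == "ercc" and not self.ercc_ids:
            raise ValueError("ercc normalization requires a non-empty spike-in set")


def _norm_count(est: AbundanceEstimate, scheme: NormalizationScheme) -> int:
    if scheme.kind == "total":
        return est.total_mapped_reads
    if scheme.kind == "housekeeping":
        fpkm = est.gene_fpkm.get(scheme.housekeeping_gene, 0.0)
        rpk = reads_per_kilobase(fpkm, est.total_mapped_reads)
        if rpk == 0:
            raise ValueError(
                f"housekeeping normalization: zero signal for gene "
                f"{scheme.housekeeping_gene!r}"
            )
        return rpk
    agg = sum(est.gene_fpkm.get(e, 0.0) for e in scheme.ercc_ids)
    rpk = reads_per_kilobase(agg, est.total_mapped_reads)
    if rpk == 0:
        raise ValueError("ercc normalization: zero aggregated spike-in signal")
    return rpk


def build_table(
    gene: str,
    est_a: AbundanceEstimate,
    est_b: AbundanceEstimate,
    scheme: NormalizationScheme,
) -> ContingencyTable2x2:
    """Build the per-gene contingency table under a normalization scheme."""
    return ContingencyTable2x2(
        rpk_gene_a=reads_per_kilobase(est_a.gene_fpkm.get(gene, 0.0), est_a.total_mapped_reads),
        rpk_gene_b=reads_per_kilobase(est_b.gene_fpkm.get(gene, 0.0), est_b.total_mapped_reads),
        norm_a=_norm_count(est_a, scheme),
        norm_b=_norm_count(est_b, scheme),
    )


def _logcomb(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_p(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    With margins fixed, the top-left cell follows a hypergeometric
    distribution; the p-value sums the probabilities of all tables no more
    likely than the observed one.  Log-space pmf evaluation keeps counts up
    to ~1e8 overflow-safe.
    """
    t = table.as_array()
    r1 = int(t[0].sum())
    n = int(t.sum())
    c1 = int(t[:, 0].sum())
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0  # degenerate margins: only one table possible
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    # log hypergeometric pmf via log-gamma: log C(c1,a) + log C(n-c1,r1-a)
    # - log C(n,r1); overflow-safe for entries up to ~1e8
    logpmf = (
        _logcomb(c1, support)
        + _logcomb(n - c1, r1 - support)
        - _logcomb(n, r1)
    )
    obs = logpmf[int(t[0, 0]) - lo]
    # relative tolerance guards against log-space round-off on exact ties
    mask = logpmf <= obs + 1e-9
    pmf = np.exp(logpmf)
    # normalize: gammaln round-off leaves the support sum at 1 +- ~1e-13
    p = pmf[mask].sum() / pmf.sum()
    return float(min(1.0, p))


def bh_adjust(pvals: Sequence[float], fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, reject flags) with rejection at
    ``adjusted <= fdr``.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return adj, reject


def run_fisher_de(
    est_a: AbundanceEstimate,
    est_b: AbundanceEstimate,
    scheme: NormalizationScheme,
    f: float = 1.0,
    fdr: float = 0.05,
) -> list[DECall]:
    """Fisher's exact test DE calls over the shared gene universe.

    A gene is DE when its BH-adjusted p-value is <= ``fdr`` AND its
    reads-per-kilobase fold change meets the threshold ``f`` (inclusive) in
    the claimed direction; the direction comes from the first contingency
    row.
    """
    if f < 1:
        raise ValueError("fold threshold must be >= 1")
    genes = sorted(set(est_a.gene_fpkm) | set(est_b.gene_fpkm))
    tables = [build_table(g, est_a, est_b, scheme) for g in genes]
    pvals = np.array([fisher_p(t) for t in tables])
    _, reject = bh_adjust(pvals, fdr)
    calls = []
    for g, t, rej in zip(genes, tables, reject):
        ratio = fold_change(float(t.rpk_gene_a), float(t.rpk_gene_b))
        status = "non-DE"
        if rej:
            if ratio >= f and ratio > 1:
                status = "over"
            elif ratio <= 1.0 / f and ratio < 1:
                status = "under"
        calls.append(
            DECall(
                gene_id=g,
                status=status,
                support_over=float("nan"),
                support_under=float("nan"),
                min_supported_fold=ratio,
                mean_fpkm_a=est_a.gene_fpkm.get(g, 0.0),
                mean_fpkm_b=est_b.gene_fpkm.get(g, 0.0),
            )
        )
    return calls
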