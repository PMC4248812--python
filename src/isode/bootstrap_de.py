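"""The IsoDE differential expression test on bootstrap FPKM estimates.

Given M bootstrap FPKM estimates per condition, fold-change estimates
``a_i / b_j`` are formed either by a random one-to-one matching (N = M
pairs) or by all ordered pairs (N = M_A * M_B).  A gene is called
differentially expressed in a direction when the fraction of fold-change
estimates at or beyond the fold threshold ``f`` (``>= f`` for
overexpression, ``<= 1/f`` for underexpression) reaches the minimum
bootstrap support ``b``.  ``b`` may be given directly or calibrated from a
binomial null in which each of the N estimates independently lands on
either side of ``f`` with probability 1/2:

    b = x_min / N,   x_min = min{x : P(X >= x) <= alpha},  X ~ Binomial(N, 1/2).

No per-gene p-value and no multiple-testing correction is produced: the
output is the support itself, plus the minimum fold change still supported
at level ``b``.  Note the binomial independence assumption is exact for
matching pairing; for all-pairs the N = M^2 indicators are dependent (they
form a rank statistic), so the same threshold is anticonservative there —
see the package docs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BootstrapFolder",
    "FoldChangePairs",
    "DEConfig",
    "DECall",
    "load_bootstrap_folder",
    "merge_replicates",
    "pair_matching",
    "pair_all",
    "fold_change",
    "bootstrap_support",
    "binomial_min_support",
    "classify_gene",
    "min_supported_fold",
    "run_isode",
    "write_de_table",
]


@dataclass
class BootstrapFolder:
    """An ordered collection of per-gene FPKM maps, one per bootstrap sample."""

    estimates: list[dict[str, float]]

    @property
    def m(self) -> int:
        return len(self.estimates)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for e in self.estimates:
            out.update(e)
        return out

    def matrix(self, genes: Sequence[str]) -> np.ndarray:
        """(m, n_genes) array of FPKMs; genes absent from a sample are 0."""
        return np.array(
            [[e.get(g, 0.0) for g in genes] for e in self.estimates]
        )


@dataclass
class FoldChangePairs:
    """The N paired fold-change estimates a_i/b_j for one gene."""

    gene_id: str
    ratios: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ratios)


@dataclass
class DEConfig:
    """IsoDE test configuration.

    Exactly one of ``min_support`` / ``alpha`` drives classification: when
    ``min_support`` is None the threshold is calibrated from the binomial
    null at significance ``alpha``.
    """

    min_fold: float = 2.0
    alpha: float | None = 0.05
    min_support: float | None = None
    pairing: str = "all"

    def __post_init__(self) -> None:
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        if self.pairing not in ("all", "matching"):
            raise ValueError(f"pairing must be 'all' or 'matching', got {self.pairing!r}")
        if (self.min_support is None) == (self.alpha is None):
            raise ValueError("exactly one of min_support and alpha must be set")
        if self.min_support is not None and not 0 <= self.min_support <= 1:
            raise ValueError("min_support must be in [0, 1]")
        if self.alpha is not None and not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class DECall:
    """Per-gene verdict with its actual bootstrap support."""

    gene_id: str
    status: str  # "over" | "under" | "non-DE"
    support_over: float
    support_under: float
    min_supported_fold: float
    mean_fpkm_a: float = float("nan")
    mean_fpkm_b: float = float("nan")


def load_bootstrap_folder(path: str | os.PathLike) -> BootstrapFolder:
    """Read every ``*.tsv`` in a folder as one bootstrap FPKM estimate each.

    Files are taken in sorted name order; each must have columns
    ``gene_id`` and ``fpkm``.
    """
    path = Path(path)
    files = sorted(path.glob("*.tsv"))
    if not files:
        raise ValueError(f"no FPKM TSV files in folder {path}")
    estimates = []
    for f in files:
        try:
            df = pd.read_csv(f, sep="\t")
        except Exception as exc:
            raise ValueError(f"malformed FPKM TSV {f}: {exc}") from exc
        if "gene_id" not in df.columns or "fpkm" not in df.columns:
            raise ValueError(
                f"malformed FPKM TSV {f}: expected columns gene_id, fpkm, "
                f"got {list(df.columns)}"
            )
        estimates.append(dict(zip(df["gene_id"].astype(str), df["fpkm"].astype(float))))
    return BootstrapFolder(estimates)


def merge_replicates(folders: Sequence[BootstrapFolder]) -> BootstrapFolder:
    """Concatenate replicate folders into one combined folder per condition.

    Downstream analysis then proceeds exactly as in the replicate-free case;
    the merged folder has m equal to the sum of the replicate m's, in folder
    order.
    """
    if not folders:
        raise ValueError("need at least one bootstrap folder")
    merged: list[dict[str, float]] = []
    for f in folders:
        merged.extend(f.estimates)
    return BootstrapFolder(merged)


def fold_change(a_i: float, b_j: float) -> float:
    """Fold-change estimate a_i / b_j.

    Conventions for zero FPKMs: ``a/0 = inf`` (supports any finite fold in
    the over direction) and ``0/0 = 1`` (no evidence of change).
    """
    if a_i < 0 or b_j < 0:
        raise ValueError("FPKM values must be non-negative")
    if b_j == 0:
        return 1.0 if a_i == 0 else math.inf
    return a_i / b_j


def _ratio_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized fold_change with the 0-denominator conventions."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a / b
    r = np.where((b == 0) & (a > 0), np.inf, r)
    r = np.where((b == 0) & (a == 0), 1.0, r)
    return r


def pair_matching(
    a: BootstrapFolder, b: BootstrapFolder, seed: int
) -> dict[str, FoldChangePairs]:
    """Random one-to-one pairing of the two conditions' estimates (N = M).

    One uniformly random permutation is drawn per run and shared across all
    genes, preserving the cross-gene correlation structure of the bootstrap
    samples.  Deterministic given the seed.
    """
    if a.m != b.m:
        raise ValueError(
            f"matching requires equal bootstrap counts (got {a.m} vs {b.m}); "
            "use all-pairs for unequal counts"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(b.m)
    genes = sorted(a.genes | b.genes)
    ma = a.matrix(genes)
    mb = b.matrix(genes)[perm]
    ratios = _ratio_matrix(ma, mb)  # (M, n_genes)
    return {
        g: FoldChangePairs(gene_id=g, ratios=ratios[:, j])
        for j, g in enumerate(genes)
    }


def pair_all(a: BootstrapFolder, b: BootstrapFolder) -> dict[str, FoldChangePairs]:
    """All ordered pairs of estimates across conditions (N = M_A * M_B)."""
    if a.m < 1 or b.m < 1:
        raise ValueError("both folders must contain at least one estimate")
    genes = sorted(a.genes | b.genes)
    ma = a.matrix(genes)  # (M_A, n)
    mb = b.matrix(genes)  # (M_B, n)
    ratios = _ratio_matrix(ma[:, None, :], mb[None, :, :])  # (M_A, M_B, n)
    flat = ratios.reshape(a.m * b.m, len(genes))
    return {
        g: FoldChangePairs(gene_id=g, ratios=flat[:, j])
        for j, g in enumerate(genes)
    }


def bootstrap_support(pairs: FoldChangePairs, f: float) -> tuple[float, float]:
    """Fractions of fold-change estimates at or beyond f in each direction.

    ``support_over = |{r >= f}| / n`` and ``support_under = |{r <= 1/f}| / n``;
    both comparisons inclusive.
    """
    if pairs.n < 1:
        raise ValueError("no fold-change estimates")
    if f < 1:
        raise ValueError("fold threshold must be >= 1")
    r = pairs.ratios
    return float(np.mean(r >= f)), float(np.mean(r <= 1.0 / f))


def binomial_min_support(n: int, alpha: float) -> float:
    """Minimum bootstrap support b = x_min / n from the binomial null.

    ``x_min = min{x : P(X >= x) <= alpha}`` with X ~ Binomial(n, 1/2),
    computed from the exact binomial tail (no normal approximation).  For
    very small n the tail never drops to alpha within 0..n and x_min = n+1,
    so b > 1 is returned: no gene is callable at that n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    x = np.arange(n + 2)
    # P(X >= x) = sf(x - 1); sf(n) == 0 <= alpha always, so x_min exists
    tail = stats.binom.sf(x - 1, n, 0.5)
    x_min = int(x[tail <= alpha][0])
    return x_min / n


def min_supported_fold(pairs: FoldChangePairs, b: float) -> float:
    """Largest fold threshold f* whose bootstrap support still reaches b.

    For overexpression this is the ceil(b*n)-th largest ratio (that many
    ratios are >= it); the under direction is symmetric on reciprocals.  The
    more extreme of the two directions is reported.
    """
    if pairs.n < 1:
        raise ValueError("no fold-change estimates")
    if not 0 < b <= 1:
        raise ValueError("support level must be in (0, 1]")
    k = math.ceil(b * pairs.n)
    if k > pairs.n:  # b>1 cannot be supported
        return float("nan")
    r = np.sort(pairs.ratios)
    f_over = r[pairs.n - k]  # k-th largest
    s = r[k - 1]  # k-th smallest
    f_under = math.inf if s == 0 else 1.0 / s
    return float(max(f_over, f_under))


def classify_gene(pairs: FoldChangePairs, cfg: DEConfig) -> DECall:
    """Classify one gene as over / under / non-DE at the support threshold.

    The threshold is ``cfg.min_support`` or, when ``cfg.alpha`` is set,
    ``binomial_min_support(n, alpha)``.  Comparisons are inclusive.  If both
    directions pass (possible only near f = 1 with ties) the direction with
    larger support wins; an exact tie is reported non-DE.
    """
    b = (
        cfg.min_support
        if cfg.min_support is not None
        else binomial_min_support(pairs.n, cfg.alpha)
    )
    s_over, s_under = bootstrap_support(pairs, cfg.min_fold)
    if s_over >= b and s_under >= b:
        if s_over > s_under:
            status = "over"
        elif s_under > s_over:
            status = "under"
        else:
            status = "non-DE"
    elif s_over >= b:
        status = "over"
    elif s_under >= b:
        status = "under"
    else:
        status = "non-DE"
    msf = min_supported_fold(pairs, b) if b <= 1 else float("nan")
    return DECall(
        gene_id=pairs.gene_id,
        status=status,
        support_over=s_over,
        support_under=s_under,
        min_supported_fold=msf,
    )


def run_isode(
    folders_a: Sequence[BootstrapFolder],
    folders_b: Sequence[BootstrapFolder],
    cfg: DEConfig,
    seed: int = 0,
) -> list[DECall]:
    """End-to-end IsoDE: merge replicates, pair, support, classify.

    Returns one :class:`DECall` per gene in the union of the two gene
    universes (genes absent from a sample count as FPKM 0).  Deterministic
    given the seed.
    """
    a = merge_replicates(folders_a)
    b = merge_replicates(folders_b)
    if cfg.pairing == "matching":
        pairs = pair_matching(a, b, seed)
    else:
        pairs = pair_all(a, b)
    genes = sorted(a.genes | b.genes)
    ma = a.matrix(genes).mean(axis=0)
    mb = b.matrix(genes).mean(axis=0)
    calls = []
    for j, g in enumerate(genes):
        call = classify_gene(pairs[g], cfg)
        call.mean_fpkm_a = float(ma[j])
        call.mean_fpkm_b = float(mb[j])
        calls.append(call)
    return calls


def write_de_table(calls: Iterable[DECall], path: str | os.PathLike) -> None:
    """Write DE calls as TSV."""
    df = pd.DataFrame(
        [
            (
                c.gene_id,
                c.status,
                c.support_over,
                c.support_under,
                c.min_supported_fold,
                c.mean_fpkm_a,
                c.mean_fpkm_b,
            )
            for c in calls
        ],
        columns=[
            "gene_id",
            "status",
            "support_over",
            "support_under",
            "min_supported_fold",
            "mean_fpkm_a",
            "mean_fpkm_b",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
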