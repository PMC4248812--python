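"""Isoform-aware EM quantification of (bootstrap) alignment samples.

A deliberately simple multiread EM: each read is fractionally assigned among
its alignments in proportion to ``theta_t / eff_len_t * weight`` and the
M-step re-estimates ``theta`` from the assigned read mass.  At the fixed
point ``theta_t`` is the fraction of reads originating from transcript ``t``
and

    FPKM_t = 1e9 * assigned_reads_t / (eff_len_t * total_mapped_reads).

Isoform awareness enters through the per-transcript effective lengths, so a
gene's abundance is length-normalized per isoform rather than per gene-model
union.  Base-quality weighting, insert-size distributions and strand
inference are out of scope; the ``weight`` field of alignments future-proofs
the E-step.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .alignio import AlignmentRecord, BootstrapSample, ReadAlignmentSet

__all__ = [
    "TranscriptModel",
    "AbundanceEstimate",
    "load_gtf",
    "effective_length",
    "run_em",
    "gene_level",
    "reads_per_kilobase",
    "write_fpkm_tsv",
]


@dataclass(frozen=True)
class TranscriptModel:
    """Annotation for one transcript: its gene, length and effective length."""

    transcript_id: str
    gene_id: str
    length: int
    effective_length: float

    def __post_init__(self) -> None:
        if self.length < 1 or self.effective_length < 1:
            raise ValueError(
                f"transcript {self.transcript_id}: lengths must be >= 1 "
                f"(length={self.length}, effective={self.effective_length})"
            )


@dataclass
class AbundanceEstimate:
    """Per-transcript and per-gene FPKM from one EM run.

    ``gene_fpkm[g]`` is always the sum of ``fpkm[t]`` over transcripts of g.
    """

    fpkm: dict[str, float]
    gene_fpkm: dict[str, float]
    total_mapped_reads: int
    converged: bool = True
    n_iter: int = 0
    log_likelihood: float = float("nan")


def effective_length(length: int, mean_read_length: int = 100) -> float:
    """Standard effective length: max(1, L - mean_read_length + 1)."""
    return float(max(1, length - mean_read_length + 1))


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def load_gtf(path: str | os.PathLike, mean_read_length: int = 100) -> dict[str, TranscriptModel]:
    """Load transcript models from a GTF file.

    Transcript length is the sum of its exon lengths; files with only
    ``transcript`` features fall back to the feature span.
    """
    exon_len: dict[str, int] = {}
    span_len: dict[str, int] = {}
    gene_of: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line in {path}: {line[:80]!r}")
            feature, start, end, attrs = fields[2], int(fields[3]), int(fields[4]), fields[8]
            if feature not in ("exon", "transcript"):
                continue
            a = dict(_ATTR_RE.findall(attrs))
            tid, gid = a.get("transcript_id"), a.get("gene_id")
            if tid is None or gid is None:
                continue
            gene_of[tid] = gid
            if feature == "exon":
                exon_len[tid] = exon_len.get(tid, 0) + (end - start + 1)
            else:
                span_len[tid] = end - start + 1
    models = {}
    for tid, gid in gene_of.items():
        length = exon_len.get(tid, span_len.get(tid, 0))
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            length=length,
            effective_length=effective_length(length, mean_read_length),
        )
    if not models:
        raise ValueError(f"no transcripts found in GTF {os.fspath(path)!r}")
    return models


def _equivalence_classes(
    sample: Union[BootstrapSample, ReadAlignmentSet],
) -> tuple[list[tuple[tuple[str, float], ...]], np.ndarray, int]:
    """Collapse reads into alignment-signature equivalence classes.

    Returns (signatures, class read counts, total reads).  A read's
    signature is its multiset of (transcript, weight) alignments; reads with
    identical signatures are interchangeable in the E-step.
    """
    if isinstance(sample, BootstrapSample):
        source = sample.source
        mult = sample.multiplicities
        items = ((rid, m) for rid, m in mult.items())
        total = sample.source.num_reads
        aln_of = source.alignments
    else:
        items = ((rid, 1) for rid in sample.read_ids)
        total = sample.num_reads
        aln_of = sample.alignments
    classes: dict[tuple[tuple[str, float], ...], int] = {}
    for rid, m in items:
        sig = tuple(sorted((a.transcript_id, a.weight) for a in aln_of[rid]))
        classes[sig] = classes.get(sig, 0) + m
    sigs = list(classes)
    counts = np.array([classes[s] for s in sigs], dtype=float)
    return sigs, counts, total


def run_em(
    sample: Union[BootstrapSample, ReadAlignmentSet],
    transcripts: Mapping[str, TranscriptModel],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> AbundanceEstimate:
    """Estimate FPKM by EM over multiread alignment ambiguity.

    Parameters
    ----------
    sample
        Alignments to quantify; a :class:`BootstrapSample` contributes each
        read with its multiplicity.
    transcripts
        Transcript models keyed by transcript ID; every aligned transcript
        must be present.
    tol
        Convergence threshold on the maximum relative change of ``theta``.
    max_iter
        Iteration cap; hitting it sets ``converged=False`` and warns.
    """
    sigs, counts, total_reads = _equivalence_classes(sample)

    tids = list(transcripts)
    t_index = {t: i for i, t in enumerate(tids)}
    unknown = sorted(
        {t for sig in sigs for t, _ in sig if t not in t_index}
    )
    if unknown:
        raise KeyError(f"alignments reference unknown transcripts: {unknown[:10]}")
    eff = np.array([transcripts[t].effective_length for t in tids])
    n_t = len(tids)

    # sparse class/transcript structure: per class, transcript indices and
    # weight/eff_len factors
    cls_idx = [np.array([t_index[t] for t, _ in sig], dtype=int) for sig in sigs]
    cls_fac = [
        np.array([w / eff[t_index[t]] for t, w in sig]) for sig in sigs
    ]

    theta = np.full(n_t, 1.0 / n_t)
    assigned = np.zeros(n_t)
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        assigned[:] = 0.0
        loglik = 0.0
        for idx, fac, c in zip(cls_idx, cls_fac, counts):
            p = theta[idx] * fac
            s = p.sum()
            if s <= 0:
                # class momentarily unreachable; spread uniformly
                p = np.ones_like(p)
                s = p.sum()
            else:
                loglik += c * np.log(s)
            np.add.at(assigned, idx, c * p / s)
        new_theta = assigned / total_reads
        delta = np.abs(new_theta - theta) / np.maximum(theta, 1e-300)
        # transcripts at negligible abundance never stabilize in relative
        # terms while their mass decays; they cannot move FPKM meaningfully
        delta[np.maximum(new_theta, theta) < 1e-12] = 0.0
        theta = new_theta
        if delta.max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations "
            f"(max relative change {delta.max():.2e})",
            RuntimeWarning,
        )

    fpkm = {
        tids[i]: 1e9 * assigned[i] / (eff[i] * total_reads) for i in range(n_t)
    }
    return AbundanceEstimate(
        fpkm=fpkm,
        gene_fpkm=gene_level_from_transcripts(fpkm, transcripts),
        total_mapped_reads=total_reads,
        converged=converged,
        n_iter=it,
        log_likelihood=float(loglik),
    )


def gene_level_from_transcripts(
    fpkm: Mapping[str, float], transcripts: Mapping[str, TranscriptModel]
) -> dict[str, float]:
    gene_fpkm: dict[str, float] = {transcripts[t].gene_id: 0.0 for t in transcripts}
    for tid, v in fpkm.items():
        gene_fpkm[transcripts[tid].gene_id] += v
    return gene_fpkm


def gene_level(est: AbundanceEstimate) -> dict[str, float]:
    """Per-gene FPKM: the sum of transcript FPKMs within each gene."""
    return dict(est.gene_fpkm)


def reads_per_kilobase(gene_fpkm: float, total_mapped_reads: int) -> int:
    """Convert a gene FPKM back to an estimated read count per kilobase.

    FPKM is fragments per kilobase per *million* mapped reads, so
    ``rpk = fpkm * total / 1e6``, rounded to the nearest integer for use as
    a count in contingency tables.
    """
    if gene_fpkm < 0 or total_mapped_reads < 0:
        raise ValueError("FPKM and read counts must be non-negative")
    return int(round(gene_fpkm * total_mapped_reads / 1e6))


def bootstrap_gene_fpkm(
    sample: ReadAlignmentSet,
    transcripts: Mapping[str, TranscriptModel],
    m: int,
    base_seed: int,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> list[dict[str, float]]:
    """Gene FPKM maps from M bootstrap resamples of one sample.

    Bootstrap i uses seed ``base_seed + i`` so individual samples are
    reproducible.  The result is the per-condition estimate list a
    bootstrap folder holds.
    """
    from .alignio import bootstrap_resample

    out = []
    for i in range(1, m + 1):
        bs = bootstrap_resample(sample, base_seed + i)
        bs.index = i
        out.append(run_em(bs, transcripts, tol=tol, max_iter=max_iter).gene_fpkm)
    return out


def write_fpkm_tsv(
    est: AbundanceEstimate,
    path: str | os.PathLike,
    level: str = "gene",
    transcripts: Mapping[str, TranscriptModel] | None = None,
) -> None:
    """Write one FPKM table as TSV (the per-bootstrap-sample file format).

    Gene level: columns ``gene_id, fpkm``.  Transcript level: columns
    ``transcript_id, gene_id, fpkm`` (requires ``transcripts``).
    """
    path = Path(path)
    if level == "gene":
        df = pd.DataFrame(
            sorted(est.gene_fpkm.items()), columns=["gene_id", "fpkm"]
        )
    elif level == "transcript":
        if transcripts is None:
            raise ValueError("transcript-level output requires transcript models")
        df = pd.DataFrame(
            [
                (t, transcripts[t].gene_id, v)
                for t, v in sorted(est.fpkm.items())
            ],
            columns=["transcript_id", "gene_id", "fpkm"],
        )
    else:
        raise ValueError(f"unknown level {level!r}")
    df.to_csv(path, sep="\t", index=False)
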