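"""Synthetic transcriptomes, alignments and qPCR assays with known DE truth.

The generator emulates the statistical structure the DE test sees — a small
multi-isoform transcriptome, reads carrying one or several alignments
(multi-mapping induced by paralogous transcript pairs), two conditions with
designated fold changes, and replicate structure — at desk scale.  Reads
are simulated directly as alignment records (sequence-free); optional GTF
and SAM emission round-trips through the standard parsers.  Counts are
multinomial over expression x effective length; no GC, positional or
quality bias is modelled, since the methods under test treat alignments as
given.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pysam

from .alignio import AlignmentRecord, ReadAlignmentSet
from .evaluate import QpcrAssay
from .quantify import TranscriptModel, effective_length

__all__ = [
    "SimulationDesign",
    "Transcriptome",
    "simulate_transcriptome",
    "simulate_alignments",
    "simulate_qpcr",
    "balanced_de_spec",
    "truth_labels",
    "write_gtf",
    "write_sam",
]


@dataclass
class SimulationDesign:
    """Parameters of one synthetic two-condition experiment.

    ``de_spec`` maps gene IDs to ``(fold, direction)`` with fold >= 1 and
    direction ``"over"`` (higher in condition A) or ``"under"`` (higher in
    B).  ``coverage`` is mean reads per kilobase for a transcript of average
    expression; ``multimap_rate`` is the fraction of reads carrying more
    than one alignment.
    """

    num_genes: int = 200
    max_isoforms: int = 3
    length_range: tuple[int, int] = (500, 3000)
    de_spec: dict[str, tuple[float, str]] = field(default_factory=dict)
    coverage: float = 50.0
    multimap_rate: float = 0.2
    replicates: int = 1
    mean_read_length: int = 100
    expression_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.multimap_rate < 1:
            raise ValueError("multimap_rate must be in [0, 1)")
        for g, (fold, direction) in self.de_spec.items():
            if fold < 1:
                raise ValueError(f"{g}: fold must be >= 1, got {fold}")
            if direction not in ("over", "under"):
                raise ValueError(f"{g}: direction must be 'over' or 'under'")


@dataclass
class Transcriptome:
    """Simulated annotation plus baseline expression and paralog structure."""

    transcripts: dict[str, TranscriptModel]
    baseline_expression: dict[str, float]  # per-transcript, mean ~1
    paralog_partner: dict[str, str]  # transcript -> multimap partner


def balanced_de_spec(design: SimulationDesign, num_de: int, fold: float) -> dict[str, tuple[float, str]]:
    """A de_spec with num_de genes at the given fold, alternating direction."""
    genes = [f"G{i:04d}" for i in range(design.num_genes)]
    step = max(1, design.num_genes // max(1, num_de))
    chosen = genes[::step][:num_de]
    return {
        g: (fold, "over" if k % 2 == 0 else "under") for k, g in enumerate(chosen)
    }


def truth_labels(design: SimulationDesign) -> dict[str, str]:
    """Per-gene ground-truth labels implied by the design's de_spec."""
    labels = {}
    for i in range(design.num_genes):
        g = f"G{i:04d}"
        fold, direction = design.de_spec.get(g, (1.0, "over"))
        if fold > 1:
            labels[g] = "TOE" if direction == "over" else "TUE"
        else:
            labels[g] = "TND"
    return labels


def simulate_transcriptome(design: SimulationDesign) -> Transcriptome:
    """Generate gene/isoform models, baseline expression and paralog pairs.

    Deterministic given ``design.seed``.  When ``multimap_rate > 0`` the
    transcripts are grouped into paralog pairs; a multi-mapped read aligns
    to its transcript of origin and to the paralog partner.
    """
    rng = np.random.default_rng(design.seed)
    transcripts: dict[str, TranscriptModel] = {}
    lo, hi = design.length_range
    for i in range(design.num_genes):
        gid = f"G{i:04d}"
        n_iso = int(rng.integers(1, design.max_isoforms + 1))
        for k in range(n_iso):
            tid = f"{gid}.t{k + 1}"
            length = int(rng.integers(lo, hi + 1))
            transcripts[tid] = TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                length=length,
                effective_length=effective_length(length, design.mean_read_length),
            )
    tids = list(transcripts)
    expr = np.exp(rng.normal(0.0, design.expression_log_sd, size=len(tids)))
    expr /= expr.mean()
    baseline = dict(zip(tids, expr))

    partner: dict[str, str] = {}
    if design.multimap_rate > 0:
        shuffled = list(rng.permutation(np.array(tids, dtype=object)))
        for j in range(0, len(shuffled) - 1, 2):
            a, b = shuffled[j], shuffled[j + 1]
            partner[a] = b
            partner[b] = a
        if len(shuffled) % 2 == 1:  # odd one out joins the last pair
            partner[shuffled[-1]] = shuffled[-2]
    return Transcriptome(
        transcripts=transcripts, baseline_expression=baseline, paralog_partner=partner
    )


def _condition_expression(
    txome: Transcriptome, design: SimulationDesign, condition: str
) -> dict[str, float]:
    if condition not in ("A", "B"):
        raise ValueError(f"condition must be 'A' or 'B', got {condition!r}")
    expr = {}
    for tid, base in txome.baseline_expression.items():
        gid = txome.transcripts[tid].gene_id
        fold, direction = design.de_spec.get(gid, (1.0, "over"))
        scale = 1.0
        if fold > 1 and (
            (direction == "over" and condition == "A")
            or (direction == "under" and condition == "B")
        ):
            scale = fold
        expr[tid] = base * scale
    return expr


def simulate_alignments(
    design: SimulationDesign,
    txome: Transcriptome,
    condition: str,
    replicate: int = 0,
    seed: int | None = None,
) -> ReadAlignmentSet:
    """Simulate one sample's worth of aligned reads for a condition.

    Expected reads per transcript are ``coverage * eff_len/1000 *
    expression``; actual counts are multinomial.  A fraction
    ``multimap_rate`` of reads also aligns to the paralog partner of its
    transcript of origin.
    """
    if seed is None:
        seed = design.seed + 7919 * (replicate + 1) + (0 if condition == "A" else 104729)
    rng = np.random.default_rng(seed)
    expr = _condition_expression(txome, design, condition)
    tids = list(txome.transcripts)
    lam = np.array(
        [
            design.coverage * txome.transcripts[t].effective_length / 1000.0 * expr[t]
            for t in tids
        ]
    )
    total = int(round(lam.sum()))
    if total < 1:
        raise ValueError("design yields zero reads; raise coverage")
    counts = rng.multinomial(total, lam / lam.sum())
    grouped: dict[str, list[AlignmentRecord]] = {}
    i = 0
    for t, c in zip(tids, counts):
        part = txome.paralog_partner.get(t)
        if c == 0:
            continue
        multi = rng.random(c) < design.multimap_rate if part is not None else np.zeros(c, bool)
        for j in range(c):
            rid = f"{condition}{replicate}_r{i:07d}"
            i += 1
            recs = [AlignmentRecord(read_id=rid, transcript_id=t)]
            if multi[j]:
                recs.append(AlignmentRecord(read_id=rid, transcript_id=part))
            grouped[rid] = recs
    return ReadAlignmentSet(grouped)


def simulate_qpcr(
    labels: Mapping[str, str],
    noise_sd: float = 0.25,
    seed: int = 0,
    log2_fold: float = 2.0,
    replicates: int = 4,
    reference_gene: str = "POLR2A",
) -> list[QpcrAssay]:
    """TaqMan-style CT tables consistent with given truth labels.

    The reference gene is held constant across conditions (CT 20); each gene
    gets a baseline CT in [22, 30], shifted by ``log2_fold`` CT units in the
    appropriate condition for TOE/TUE genes, with Gaussian CT noise per
    replicate.
    """
    rng = np.random.default_rng(seed)
    assays = [
        QpcrAssay(
            gene_id=reference_gene,
            cts_cond_a=list(20.0 + rng.normal(0, noise_sd, replicates)),
            cts_cond_b=list(20.0 + rng.normal(0, noise_sd, replicates)),
        )
    ]
    for gene, label in labels.items():
        base = float(rng.uniform(22.0, 30.0))
        ct_a = ct_b = base
        if label == "TOE":  # higher expression in A -> lower CT in A
            ct_a = base - log2_fold
        elif label == "TUE":
            ct_b = base - log2_fold
        elif label != "TND":
            raise ValueError(f"unknown truth label {label!r} for gene {gene}")
        assays.append(
            QpcrAssay(
                gene_id=gene,
                cts_cond_a=list(ct_a + rng.normal(0, noise_sd, replicates)),
                cts_cond_b=list(ct_b + rng.normal(0, noise_sd, replicates)),
            )
        )
    return assays


def write_gtf(txome: Transcriptome, path: str | os.PathLike) -> None:
    """Emit the transcript models as a minimal exon-per-transcript GTF."""
    with open(path, "w") as fh:
        for t in txome.transcripts.values():
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for feature in ("transcript", "exon"):
                fh.write(
                    f"{t.transcript_id}\tsim\t{feature}\t1\t{t.length}\t.\t+\t.\t{attrs}\n"
                )


def write_sam(
    sample: ReadAlignmentSet, txome: Transcriptome, path: str | os.PathLike
) -> None:
    """Emit a transcript-space SAM; extra alignments are flagged secondary."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": t.transcript_id, "LN": t.length}
            for t in txome.transcripts.values()
        ],
    }
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as out:
        for rid in sample.read_ids:
            for k, rec in enumerate(sample.alignments[rid]):
                a = pysam.AlignedSegment(out.header)
                a.query_name = rid
                a.reference_id = out.header.get_tid(rec.transcript_id)
                a.reference_start = 0
                a.mapping_quality = 255
                rl = min(50, txome.transcripts[rec.transcript_id].length)
                a.cigarstring = f"{rl}M"
                a.flag = 256 if k > 0 else 0
                out.write(a)
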