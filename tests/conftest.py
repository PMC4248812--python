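import numpy as np
import pytest

from isode import (
    BootstrapFolder,
    SimulationDesign,
    simulate_alignments,
    simulate_transcriptome,
)
from isode.quantify import TranscriptModel, effective_length


SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:T1\tLN:1000\n@SQ\tSN:T2\tLN:2000\n"


def _sam_line(qname, flag, rname, pos=1, cigar="50M"):
    return f"{qname}\t{flag}\t{rname}\t{pos}\t255\t{cigar}\t*\t0\t0\t*\t*\n"


@pytest.fixture
def simple_sam(tmp_path):
    """3 mapped reads, one with 2 alignments, plus one unmapped read."""
    path = tmp_path / "simple.sam"
    path.write_text(
        SAM_HEADER
        + _sam_line("r1", 0, "T1")
        + _sam_line("r2", 0, "T1")
        + _sam_line("r2", 256, "T2")
        + _sam_line("r3", 0, "T2")
        + "r4\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
    )
    return path


@pytest.fixture
def paired_sam(tmp_path):
    """2 fragments x 2 mates plus 1 single-end read: 5 alignment lines."""
    path = tmp_path / "paired.sam"
    path.write_text(
        SAM_HEADER
        + _sam_line("f1", 99, "T1")
        + _sam_line("f1", 147, "T1", pos=200)
        + _sam_line("f2", 99, "T2")
        + _sam_line("f2", 147, "T2", pos=400)
        + _sam_line("s1", 0, "T2")
    )
    return path


@pytest.fixture
def two_transcripts():
    """Transcripts of lengths 1000 and 2000 in one gene (read length 100)."""
    return {
        "T1": TranscriptModel("T1", "G1", 1000, effective_length(1000)),
        "T2": TranscriptModel("T2", "G1", 2000, effective_length(2000)),
    }


def gaussian_folder(rng, gene_means, m, sd=0.05):
    """Bootstrap folder of m FPKM maps with relative Gaussian noise."""
    ests = []
    for _ in range(m):
        ests.append(
            {
                g: max(0.0, mu * (1 + rng.normal(0, sd)))
                for g, mu in gene_means.items()
            }
        )
    return BootstrapFolder(ests)


@pytest.fixture
def small_pipeline():
    """A 50-gene simulated experiment with six 4-fold DE genes."""
    from isode.synthdata import balanced_de_spec

    design = SimulationDesign(num_genes=50, seed=11)
    design.de_spec = balanced_de_spec(design, 6, 4.0)
    txome = simulate_transcriptome(design)
    sample_a = simulate_alignments(design, txome, "A")
    sample_b = simulate_alignments(design, txome, "B")
    return design, txome, sample_a, sample_b
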