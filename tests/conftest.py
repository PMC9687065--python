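from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nmdkit.features import GenomicInterval, TranscriptModel
from nmdkit.simulate import SimulationParams, TruthTable, simulate_annotation


def make_transcript(
    exon_lens_5to3,
    cds=None,
    strand="+",
    chrom="chr1",
    start=1000,
    intron=200,
    transcript_id="tx1",
    gene_id="g1",
):
    """Build a TranscriptModel from 5'->3' exon lengths."""
    lens = list(exon_lens_5to3) if strand == "+" else list(exon_lens_5to3)[::-1]
    exons, cursor = [], start
    for i, ln in enumerate(lens):
        exons.append(GenomicInterval(chrom, cursor, cursor + ln, strand))
        cursor += ln + (intron if i < len(lens) - 1 else 0)
    cds_start, cds_end = cds if cds is not None else (None, None)
    return TranscriptModel(transcript_id, gene_id, exons, cds_start, cds_end)


def random_transcript(rng, transcript_id="tx", gene_id="g"):
    """Random structure + sequence + a valid annotated CDS, for oracle tests."""
    n_exons = int(rng.integers(1, 6))
    exon_lens = [int(rng.integers(30, 400)) for _ in range(n_exons)]
    total = sum(exon_lens)
    strand = "+" if rng.random() < 0.5 else "-"
    sequence = "".join(rng.choice(list("ACGT"), size=total))
    cds_start = int(rng.integers(1, max(2, total // 3)))
    max_len = total - cds_start - 1
    n_codons = int(rng.integers(2, max(3, max_len // 3)))
    cds_end = cds_start + 3 * n_codons
    if cds_end >= total:
        cds_end = cds_start + 3 * max(2, (total - cds_start - 1) // 3)
    model = make_transcript(
        exon_lens,
        cds=(cds_start, cds_end),
        strand=strand,
        start=int(rng.integers(0, 10_000)),
        intron=int(rng.integers(50, 500)),
        transcript_id=transcript_id,
        gene_id=gene_id,
    )
    return model, sequence


def make_truth(n_background=50, n_targets=10, n_factors=5):
    """Hand-built truth table for stage-matrix tests (no annotation needed)."""
    rows = []
    total = n_background + n_targets + n_factors
    for i in range(total):
        if i < n_targets:
            cls = "target"
        elif i < n_targets + n_factors:
            cls = "factor"
        else:
            cls = "background"
        rows.append(
            dict(
                gene_id=f"G{i:04d}",
                is_planted_target=cls == "target",
                planted_features=set(),
                planted_switch=None,
                planted_alpha_only=False,
                has_feedback=False,
                in_prior_list=False,
                trajectory_class=cls,
            )
        )
    return TruthTable(pd.DataFrame(rows).set_index("gene_id"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_annotation():
    params = SimulationParams(seed=11)
    models, sequences, truth = simulate_annotation(params)
    return params, models, sequences, truth
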