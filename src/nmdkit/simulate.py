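"""Synthetic annotation, sequences, count matrices and stage matrices.

Everything downstream of alignment is emulated with known ground truth:

* ``simulate_annotation`` -- toy gene models and transcript sequences with
  planted NMD-inducing features (dEJ, uORF, long 3'UTR) and planted isoform
  switches, guaranteed by construction (non-planted transcripts are built so
  the stop codon sits in the last exon and the 5'UTR carries no ATG).
* ``simulate_counts`` -- exonic/intronic negative-binomial counts under a
  steady-state model (mature mRNA ~ alpha/beta, pre-mRNA ~ alpha/gamma) with
  decay-rate reductions planted in null samples, optionally cancelled at
  steady state by a transcriptional-feedback reduction of alpha.
* ``simulate_isoform_tpm`` -- per-isoform TPM with planted usage switches.
* ``simulate_stage_matrix`` -- a stage x lineage x cell matrix with a
  transient, lineage-specific dip of target genes mirrored by a rise of
  factor genes.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .de import CONTROL, NULL, CountTables
from .features import GenomicInterval, TranscriptModel

UORF_CASSETTE = "ATGGCGTAA"  # 3 codons including the stop
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

__all__ = [
    "SimulationParams",
    "TruthTable",
    "StageExpression",
    "simulate_annotation",
    "simulate_counts",
    "expected_count_means",
    "simulate_isoform_tpm",
    "simulate_stage_matrix",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs for the toy genome and the count model."""

    n_genes: int = 100
    isoforms_per_gene: tuple[int, int] = (1, 2)
    exon_count_range: tuple[int, int] = (1, 5)
    exon_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (100, 500)
    utr5_length_range: tuple[int, int] = (60, 120)
    utr3_length_range: tuple[int, int] = (150, 250)
    # steady-state rates (means of per-gene lognormal draws)
    alpha: float = 10.0
    beta: float = 1.0
    gamma: float = 5.0
    rate_sigma: float = 0.5
    stabilization_factor: float = 0.5
    feedback_fraction: float = 0.0
    dispersion: float = 0.2
    depth: float = 1_000_000.0
    n_null: int = 8
    n_control: int = 11
    # planting plan
    n_targets: int = 20
    target_features: tuple[str, ...] = ("dej", "uorf", "long3utr")
    n_transcription_only: int = 0
    n_switch_genes: int = 5
    n_factor_genes: int = 10
    prior_fraction: float = 0.5
    prior_background_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) <= 0:
            raise ValueError("rates must be positive")
        if not (0 < self.stabilization_factor < 1) and self.stabilization_factor != 1:
            raise ValueError("stabilization_factor must be in (0, 1]")
        if not (0 <= self.feedback_fraction <= 1):
            raise ValueError("feedback_fraction in [0, 1]")
        if self.n_null < 2 or self.n_control < 2:
            raise ValueError("need >=2 samples per genotype")
        if self.dispersion <= 0 or self.depth <= 0:
            raise ValueError("dispersion and depth must be positive")
        bad = set(self.target_features) - {"dej", "uorf", "long3utr"}
        if bad:
            raise ValueError(f"unknown features: {sorted(bad)}")
        n_special = self.n_targets + self.n_transcription_only + self.n_switch_genes
        if n_special + self.n_factor_genes > self.n_genes:
            raise ValueError("more planted genes than genes")
        if (
            self.n_targets > 0
            and "dej" in self.target_features
            and self.exon_count_range[1] < 2
        ):
            raise ValueError(
                "cannot plant a dEJ on single-exon genes; "
                "raise exon_count_range upper bound to >=2"
            )


@dataclass
class TruthTable:
    """Ground truth per gene, for recovery tests against the pipeline."""

    frame: pd.DataFrame  # indexed by gene_id

    COLUMNS = (
        "is_planted_target",
        "planted_features",
        "planted_switch",
        "planted_alpha_only",
        "has_feedback",
        "in_prior_list",
        "trajectory_class",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"truth table missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate gene ids in truth table")

    @property
    def genes(self) -> pd.Index:
        return self.frame.index

    def planted_targets(self) -> list[str]:
        return list(self.frame.index[self.frame["is_planted_target"]])

    def prior_list(self) -> list[str]:
        return list(self.frame.index[self.frame["in_prior_list"]])

    def genes_with_class(self, trajectory_class: str) -> list[str]:
        return list(
            self.frame.index[self.frame["trajectory_class"] == trajectory_class]
        )

    def to_tsv_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["planted_features"] = out["planted_features"].map(
            lambda s: ",".join(sorted(s)) if s else ""
        )
        out["planted_switch"] = out["planted_switch"].fillna("")
        return out.reset_index()


@dataclass
class StageExpression:
    """Normalized gene x cell matrix plus per-cell stage/lineage metadata."""

    matrix: pd.DataFrame
    cells: pd.DataFrame  # columns: stage, lineage
    stage_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.matrix.columns.equals(self.cells.index):
            raise ValueError("matrix columns and cell metadata disagree")
        for col in ("stage", "lineage"):
            if col not in self.cells.columns:
                raise ValueError(f"cell metadata missing {col!r}")


# ---------------------------------------------------------------------------
# Annotation


def _clean_utr(rng: np.random.Generator, length: int) -> list[str]:
    """Random sequence with every ATG neutralized."""
    seq = list(rng.choice(list("ACGT"), size=length))
    for i in range(length - 2):
        if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G":
            seq[i + 2] = "C"
    return seq


def _utr5_sequence(rng: np.random.Generator, length: int, n_uorfs: int) -> str:
    seq = _clean_utr(rng, length)
    spans = []
    for k in range(n_uorfs):
        start = 4 + k * (len(UORF_CASSETTE) + 6)
        end = start + len(UORF_CASSETTE)
        if end > length - 2:
            raise ValueError("5'UTR too short for requested uORFs")
        seq[start:end] = list(UORF_CASSETTE)
        spans.append((start, end))
    # neutralize ATGs created at cassette boundaries
    for i in range(length - 2):
        if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G":
            if not any(i == s for s, _ in spans):
                j = i + 2
                if not any(s <= j < e for s, e in spans):
                    seq[j] = "C"
    return "".join(seq)


def _cds_sequence(rng: np.random.Generator, length: int) -> str:
    if length % 3 or length < 6:
        raise ValueError("CDS length must be a positive multiple of 3 (>=6)")
    n_mid = length // 3 - 2
    body = "".join(rng.choice(_NON_STOP_CODONS, size=n_mid)) if n_mid else ""
    return "ATG" + body + "TAA"


def _transcript_sequence(
    rng: np.random.Generator, utr5: int, cds: int, utr3: int, n_uorfs: int
) -> str:
    tail = "".join(rng.choice(list("ACGT"), size=utr3))
    return _utr5_sequence(rng, utr5, n_uorfs) + _cds_sequence(rng, cds) + tail


def _structure(
    rng: np.random.Generator,
    params: SimulationParams,
    features: frozenset[str],
    force_introns: bool,
) -> tuple[list[int], int, int, int]:
    """Exon lengths plus (utr5, cds, utr3) lengths honoring planted features.

    Non-dEJ transcripts keep the stop codon inside the last exon (the 3'UTR
    is clamped to at most last-exon + 30 nt, below the 50-nt rule), so no
    incidental dEJ can arise. Planted dEJs append one extra exon past the
    stop; planted long 3'UTRs widen the last exon to hold the whole UTR.
    """
    lo, hi = params.exon_count_range
    lo = max(lo, 2 if force_introns else 1)
    if "dej" in features:
        hi = max(hi - 1, lo)  # one exon appended below
    n_exons = int(rng.integers(lo, hi + 1))
    exon_lens = [
        int(rng.integers(params.exon_length_range[0], params.exon_length_range[1] + 1))
        for _ in range(n_exons)
    ]
    utr5 = int(rng.integers(params.utr5_length_range[0], params.utr5_length_range[1] + 1))
    if "uorf" in features:
        utr5 = max(utr5, 60)

    if "dej" in features:
        utr3 = int(rng.integers(60, 121))
    elif "long3utr" in features:
        utr3 = 800
        exon_lens[-1] += utr3
    else:
        utr3 = int(rng.integers(params.utr3_length_range[0], params.utr3_length_range[1] + 1))
        utr3 = min(utr3, exon_lens[-1] + 30)

    total = sum(exon_lens)
    cds = total - utr5 - utr3
    if cds < 9:
        # short transcript: widen the first exon to make room for the ORF
        need = 9 - cds
        exon_lens[0] += need + 60
        total += need + 60
        cds = total - utr5 - utr3
    rem = cds % 3
    utr5 += rem  # absorb the remainder; keeps cds divisible by 3
    cds -= rem

    if "dej" in features:
        extra = int(rng.integers(100, 161))
        exon_lens.append(extra)
        utr3 += extra
        # the stop now sits one exon upstream of the last junction, at a
        # distance of the pre-extension 3'UTR length (57..117 nt) > 50
    return exon_lens, utr5, cds, utr3


def _place_exons(
    rng: np.random.Generator,
    params: SimulationParams,
    chrom: str,
    start: int,
    strand: str,
    exon_lens_5to3: Sequence[int],
) -> tuple[list[GenomicInterval], int]:
    """Lay exons on the genome; returns (genomic-order exons, locus end)."""
    lens = list(exon_lens_5to3) if strand == "+" else list(exon_lens_5to3)[::-1]
    exons, cursor = [], start
    for i, ln in enumerate(lens):
        exons.append(GenomicInterval(chrom, cursor, cursor + ln, strand))
        cursor += ln
        if i < len(lens) - 1:
            cursor += int(
                rng.integers(
                    params.intron_length_range[0], params.intron_length_range[1] + 1
                )
            )
    return exons, cursor


def simulate_annotation(
    params: SimulationParams,
) -> tuple[list[TranscriptModel], dict[str, str], TruthTable]:
    """Generate gene models, transcript sequences and the ground-truth table."""
    rng = np.random.default_rng([params.seed, 11])

    n = params.n_genes
    gene_ids = [f"G{i:04d}" for i in range(n)]
    # planted roles occupy the head of the gene list, then get shuffled
    roles: list[dict] = []
    feature_cycle = params.target_features
    for i in range(params.n_targets):
        feats = (
            frozenset([feature_cycle[i % len(feature_cycle)]])
            if feature_cycle
            else frozenset()
        )
        roles.append(dict(target=True, features=feats, switch=False, alpha_only=False))
    for _ in range(params.n_transcription_only):
        roles.append(
            dict(target=False, features=frozenset(), switch=False, alpha_only=True)
        )
    for _ in range(params.n_switch_genes):
        roles.append(
            dict(target=False, features=frozenset(), switch=True, alpha_only=False)
        )
    while len(roles) < n:
        roles.append(
            dict(target=False, features=frozenset(), switch=False, alpha_only=False)
        )
    order = rng.permutation(n)
    roles = [roles[i] for i in order]

    # feedback subset of the planted targets
    target_idx = [i for i, r in enumerate(roles) if r["target"]]
    n_feedback = int(round(params.feedback_fraction * len(target_idx)))
    feedback_set = set(
        rng.choice(target_idx, size=n_feedback, replace=False) if n_feedback else []
    )

    # trajectory classes: targets -> "target"; n_factor_genes background genes
    # -> "factor"; everything else "background"
    background_idx = [
        i for i, r in enumerate(roles) if not (r["target"] or r["switch"] or r["alpha_only"])
    ]
    factor_set = set(background_idx[: params.n_factor_genes])

    models: list[TranscriptModel] = []
    sequences: dict[str, str] = {}
    truth_rows = []
    cursor = 10_000
    chrom = "chr1"

    for i, gid in enumerate(gene_ids):
        role = roles[i]
        strand = "+" if rng.random() < 0.5 else "-"
        force_introns = bool(role["target"] or role["alpha_only"] or role["switch"])
        n_iso = int(
            rng.integers(params.isoforms_per_gene[0], params.isoforms_per_gene[1] + 1)
        )
        if role["switch"]:
            n_iso = max(n_iso, 2)

        features: frozenset[str] = role["features"]
        exon_lens, utr5, cds, utr3 = _structure(rng, params, features, force_introns)
        n_uorfs = 1 if "uorf" in features else 0
        tid = f"{gid}.t1"
        exons, locus_end = _place_exons(rng, params, chrom, cursor, strand, exon_lens)
        models.append(TranscriptModel(tid, gid, exons, utr5, utr5 + cds + 3))
        sequences[tid] = _transcript_sequence(rng, utr5, cds + 3, utr3 - 3, n_uorfs)
        gene_end = locus_end

        planted_switch = None
        for k in range(2, n_iso + 1):
            tid_k = f"{gid}.t{k}"
            if role["switch"] and k == 2:
                # switch isoform: same exon chain plus one appended exon ->
                # guaranteed dEJ relative to its own stop codon
                extra = int(rng.integers(100, 161))
                gap = int(
                    rng.integers(
                        params.intron_length_range[0],
                        params.intron_length_range[1] + 1,
                    )
                )
                if strand == "+":
                    new_exon = GenomicInterval(
                        chrom, locus_end + gap, locus_end + gap + extra, "+"
                    )
                    iso_exons = exons + [new_exon]
                else:
                    shift = 0
                    new_exon = GenomicInterval(
                        chrom, cursor - gap - extra + shift, cursor - gap + shift, "-"
                    )
                    # prepend genomically; it is the transcript's last exon
                    iso_exons = [new_exon] + exons
                models.append(
                    TranscriptModel(tid_k, gid, iso_exons, utr5, utr5 + cds + 3)
                )
                sequences[tid_k] = _transcript_sequence(
                    rng, utr5, cds + 3, utr3 - 3 + extra, n_uorfs
                )
                gene_end = max(gene_end, locus_end + gap + extra)
                planted_switch = tid_k
            else:
                lens_k, utr5_k, cds_k, utr3_k = _structure(
                    rng, params, frozenset(), force_introns
                )
                exons_k, end_k = _place_exons(
                    rng, params, chrom, cursor, strand, lens_k
                )
                models.append(
                    TranscriptModel(tid_k, gid, exons_k, utr5_k, utr5_k + cds_k + 3)
                )
                sequences[tid_k] = _transcript_sequence(
                    rng, utr5_k, cds_k + 3, utr3_k - 3, 0
                )
                gene_end = max(gene_end, end_k)

        cursor = gene_end + int(rng.integers(1_000, 5_000))

        if role["target"]:
            trajectory = "target"
        elif i in factor_set:
            trajectory = "factor"
        else:
            trajectory = "background"
        truth_rows.append(
            dict(
                gene_id=gid,
                is_planted_target=bool(role["target"]),
                planted_features=set(features),
                planted_switch=planted_switch,
                planted_alpha_only=bool(role["alpha_only"]),
                has_feedback=i in feedback_set,
                in_prior_list=False,
                trajectory_class=trajectory,
            )
        )

    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    # prior list: a fraction of planted targets plus background contamination
    targets = list(truth.index[truth["is_planted_target"]])
    n_prior_targets = int(round(params.prior_fraction * len(targets)))
    prior = set(targets[:n_prior_targets])
    background = [g for g in truth.index if not truth.loc[g, "is_planted_target"]]
    n_bg = int(round(params.prior_background_fraction * len(background)))
    if n_bg:
        prior |= set(rng.choice(background, size=n_bg, replace=False))
    truth["in_prior_list"] = truth.index.isin(prior)

    return models, sequences, TruthTable(truth)


# ---------------------------------------------------------------------------
# Counts


def _gene_rates(
    genes: Sequence[str], params: SimulationParams
) -> pd.DataFrame:
    """Deterministic per-gene lognormal draws around the mean rates."""
    rng = np.random.default_rng([params.seed, 23])
    s = params.rate_sigma
    draws = rng.normal(0.0, s, size=(len(genes), 2))
    return pd.DataFrame(
        {
            "alpha": params.alpha * np.exp(draws[:, 0] - s**2 / 2),
            "beta": params.beta * np.exp(draws[:, 1] - s**2 / 2),
            "gamma": params.gamma,
        },
        index=pd.Index(genes, name="gene_id"),
    )


def _representative_lengths(models: Sequence[TranscriptModel]) -> pd.DataFrame:
    """Exonic/intronic nt of each gene's first isoform."""
    rows = {}
    for m in models:
        if m.transcript_id.endswith(".t1"):
            exonic = m.length
            span = m.exons[-1].end - m.exons[0].start
            rows[m.gene_id] = dict(
                exonic_length=exonic, intronic_length=span - exonic
            )
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")


def expected_count_means(
    models: Sequence[TranscriptModel],
    truth: TruthTable,
    params: SimulationParams,
) -> dict[str, pd.DataFrame]:
    """Noise-free expected exonic/intronic means per genotype.

    Mature steady state is alpha/beta and pre-mRNA steady state alpha/gamma;
    expected counts are proportional to abundance x length x depth with a
    common normalizer taken from the control genotype, so planted fold
    changes survive in the expectations.
    """
    genes = list(truth.genes)
    rates = _gene_rates(genes, params)
    lengths = _representative_lengths(models).reindex(genes)

    out = {}
    f = params.stabilization_factor
    for genotype in (CONTROL, NULL):
        alpha = rates["alpha"].copy()
        beta = rates["beta"].copy()
        if genotype == NULL:
            planted = truth.frame["is_planted_target"]
            beta[planted] *= f
            alpha[truth.frame["has_feedback"]] *= f
            alpha[truth.frame["planted_alpha_only"]] /= f
        mature = alpha / beta
        pre = alpha / rates["gamma"]
        mu_e = mature * lengths["exonic_length"]
        mu_i = pre * lengths["intronic_length"]
        if genotype == CONTROL:
            norm = (mu_e + mu_i).sum()
        out[genotype] = pd.DataFrame(
            {
                "exonic": mu_e / norm * params.depth,
                "intronic": mu_i / norm * params.depth,
            }
        )
    return out


def simulate_counts(
    models: Sequence[TranscriptModel],
    truth: TruthTable,
    params: SimulationParams,
) -> CountTables:
    """Draw NB exonic/intronic counts for the two-genotype design."""
    means = expected_count_means(models, truth, params)
    genes = list(truth.genes)
    lengths = _representative_lengths(models).reindex(genes)

    rng = np.random.default_rng([params.seed, 31])
    sample_ids = [f"null_{i + 1:02d}" for i in range(params.n_null)] + [
        f"ctrl_{i + 1:02d}" for i in range(params.n_control)
    ]
    genotypes = [NULL] * params.n_null + [CONTROL] * params.n_control

    r = 1.0 / params.dispersion
    exonic = np.empty((len(genes), len(sample_ids)), dtype=np.int64)
    intronic = np.empty_like(exonic)
    for j, genotype in enumerate(genotypes):
        for k, layer in enumerate(("exonic", "intronic")):
            mu = means[genotype][layer].values
            p = r / (r + np.maximum(mu, 1e-12))
            draws = rng.negative_binomial(r, p)
            draws[mu <= 0] = 0
            (exonic if k == 0 else intronic)[:, j] = draws

    samples = pd.Series(genotypes, index=sample_ids, name="genotype")
    return CountTables(
        exonic=pd.DataFrame(exonic, index=genes, columns=sample_ids),
        intronic=pd.DataFrame(intronic, index=genes, columns=sample_ids),
        samples=samples,
        gene_lengths=lengths,
    )


# ---------------------------------------------------------------------------
# Isoform quantifications


def simulate_isoform_tpm(
    models: Sequence[TranscriptModel],
    truth: TruthTable,
    params: SimulationParams,
    switch_from: float = 0.2,
    switch_to: float = 0.6,
    noise_sigma: float = 0.25,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-isoform TPM table with planted usage switches in null samples.

    Planted switch isoforms move from ``switch_from`` of the gene's
    expression in controls to ``switch_to`` in nulls; other genes keep a
    fixed usage profile. Returns (tpm frame, sample sheet).
    """
    rng = np.random.default_rng([params.seed, 47])
    by_gene: dict[str, list[str]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m.transcript_id)

    genes = list(truth.genes)
    rates = _gene_rates(genes, params)
    gene_expr = (rates["alpha"] / rates["beta"]).reindex(genes)
    gene_tpm = gene_expr / gene_expr.sum() * 1e6

    sample_ids = [f"null_{i + 1:02d}" for i in range(params.n_null)] + [
        f"ctrl_{i + 1:02d}" for i in range(params.n_control)
    ]
    genotypes = [NULL] * params.n_null + [CONTROL] * params.n_control

    iso_ids, iso_genes, profiles = [], [], []
    for gid in genes:
        isos = sorted(by_gene[gid])
        k = len(isos)
        switch_iso = truth.frame.loc[gid, "planted_switch"]
        if switch_iso is not None and not pd.isna(switch_iso) and k >= 2:
            others = [t for t in isos if t != switch_iso]
            base = {t: (1.0 - switch_from) / len(others) for t in others}
            base[switch_iso] = switch_from
            null_profile = {t: (1.0 - switch_to) / len(others) for t in others}
            null_profile[switch_iso] = switch_to
        else:
            weights = rng.dirichlet(np.full(k, 5.0)) if k > 1 else np.array([1.0])
            base = dict(zip(isos, weights))
            null_profile = base
        for t in isos:
            iso_ids.append(t)
            iso_genes.append(gid)
            profiles.append((gid, base[t], null_profile[t]))

    values = np.empty((len(iso_ids), len(sample_ids)))
    for j, genotype in enumerate(genotypes):
        for i, (gid, f_ctrl, f_null) in enumerate(profiles):
            frac = f_null if genotype == NULL else f_ctrl
            noise = np.exp(rng.normal(0.0, noise_sigma))
            values[i, j] = gene_tpm[gid] * frac * noise

    tpm = pd.DataFrame(values, index=pd.Index(iso_ids, name="isoform_id"), columns=sample_ids)
    samples = pd.Series(genotypes, index=sample_ids, name="genotype")
    tpm.insert(0, "gene_id", iso_genes)
    return tpm, samples


# ---------------------------------------------------------------------------
# Stage x lineage matrix


def simulate_stage_matrix(
    truth: TruthTable,
    dip_depth: float = 1.5,
    stages: Sequence[str] = ("E3.5", "E4.5", "E5.5", "E6.5"),
    lineages: Sequence[str] = ("EPI", "PrE", "TE"),
    cells_per_group: int = 30,
    dip_stage: str = "E5.5",
    dip_lineage: str = "EPI",
    noise_sigma: float = 0.5,
    seed: int | None = None,
    params: SimulationParams | None = None,
) -> StageExpression:
    """Stage x lineage matrix with the planted transient shift at one stage.

    Genes of trajectory class ``target`` dip by ``dip_depth`` log2 units at
    ``dip_stage`` in ``dip_lineage`` only and rebound afterwards; ``factor``
    genes rise by ``dip_depth`` at ``dip_stage`` in every lineage and fall
    back by the next stage; background genes are flat in expectation.
    Per-cell noise is lognormal.
    """
    if dip_depth <= 0:
        raise ValueError("dip_depth must be positive")
    if dip_stage not in stages:
        raise ValueError(f"{dip_stage} not among stages")
    if seed is None:
        seed = params.seed if params is not None else 0
    rng = np.random.default_rng([seed, 59])

    genes = list(truth.genes)
    classes = truth.frame["trajectory_class"]
    base = np.exp(rng.normal(np.log(5.0), 0.4, size=len(genes)))

    columns, stage_meta, lineage_meta = [], [], []
    blocks = []
    for stage in stages:
        for lineage in lineages:
            effect = np.ones(len(genes))
            if stage == dip_stage:
                is_target = (classes == "target").values
                is_factor = (classes == "factor").values
                if lineage == dip_lineage:
                    effect[is_target] = 2.0 ** (-dip_depth)
                effect[is_factor] = 2.0**dip_depth
            mu = base * effect
            noise = np.exp(
                rng.normal(0.0, noise_sigma, size=(len(genes), cells_per_group))
            )
            blocks.append(mu[:, None] * noise)
            for c in range(cells_per_group):
                columns.append(f"{stage}_{lineage}_c{c:03d}")
                stage_meta.append(stage)
                lineage_meta.append(lineage)

    matrix = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(genes, name="gene_id"), columns=columns
    )
    cells = pd.DataFrame(
        {"stage": stage_meta, "lineage": lineage_meta},
        index=pd.Index(columns, name="cell_id"),
    )
    return StageExpression(matrix=matrix, cells=cells, stage_order=tuple(stages))
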