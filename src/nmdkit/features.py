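"""Transcript models, GTF/FASTA I/O, ORF assignment and NMD-feature detection.

Features are called per transcript on transcript-coordinate ORFs:

* ``dEJ`` -- an exon-exon junction downstream of the stop codon, called when
  the last junction lies more than ``dej_threshold`` nt (default 50) past the
  end of the stop codon.
* ``uORF`` -- an upstream open reading frame contained entirely within the
  5'UTR (non-overlapping with the main ORF).
* ``long 3'UTR`` -- a 3'UTR exceeding a configurable absolute length or a
  multiple of the annotation-wide median.

Internal coordinates are 0-based half-open; GTF I/O converts from/to the
1-based inclusive convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "NmdFeatureSet",
    "FeatureConfig",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "write_fasta",
    "read_fasta",
    "assign_orf",
    "detect_dej",
    "detect_uorfs",
    "measure_utr3",
    "median_utr3_length",
    "annotate_transcripts",
    "collapse_to_gene",
]


class GtfParseError(ValueError):
    """Raised when a GTF record violates the transcript-model invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One isoform: ordered exons plus an optional transcript-coordinate ORF.

    ``exons`` are kept in genomic order (ascending start); ``cds_start`` /
    ``cds_end`` are 0-based half-open bounds on the *transcript* (5'->3')
    coordinate axis and include the stop codon.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise GtfParseError(
                f"{self.transcript_id}: exons span multiple chromosomes/strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise GtfParseError(f"{self.transcript_id}: overlapping exons")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: half-specified CDS")
        if self.cds_start is not None:
            if not (0 <= self.cds_start < self.cds_end <= self.length):
                raise GtfParseError(
                    f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end})"
                    f" outside transcript of length {self.length}"
                )
            if (self.cds_end - self.cds_start) % 3 != 0:
                raise GtfParseError(
                    f"{self.transcript_id}: CDS length not divisible by 3"
                )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_lengths_5to3(self) -> list[int]:
        """Exon lengths in transcript (5'->3') order."""
        lens = [len(e) for e in self.exons]
        return lens if self.strand == "+" else lens[::-1]

    def junctions(self) -> list[int]:
        """Transcript coordinates immediately 3' of each exon-exon junction."""
        pos, out = 0, []
        for ln in self.exon_lengths_5to3()[:-1]:
            pos += ln
            out.append(pos)
        return out

    def has_cds(self) -> bool:
        return self.cds_start is not None

    def genomic_cds_segments(self) -> list[GenomicInterval]:
        """Project the transcript-coordinate CDS back onto the genome."""
        if not self.has_cds():
            return []
        segments: list[GenomicInterval] = []
        tpos = 0
        exons_5to3 = self.exons if self.strand == "+" else self.exons[::-1]
        for exon in exons_5to3:
            elen = len(exon)
            lo = max(self.cds_start, tpos)
            hi = min(self.cds_end, tpos + elen)
            if lo < hi:
                off_lo, off_hi = lo - tpos, hi - tpos
                if self.strand == "+":
                    seg = GenomicInterval(
                        exon.chrom, exon.start + off_lo, exon.start + off_hi, "+"
                    )
                else:
                    seg = GenomicInterval(
                        exon.chrom, exon.end - off_hi, exon.end - off_lo, "-"
                    )
                segments.append(seg)
            tpos += elen
        return sorted(segments, key=lambda s: s.start)


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds for the three NMD-feature detectors."""

    dej_threshold: int = 50
    uorf_min_codons: int = 3  # including the stop codon
    long_utr3_rule: str = "multiple_of_annotation_median"
    long_utr3_value: float = 2.0

    def __post_init__(self) -> None:
        if self.dej_threshold <= 0:
            raise ValueError("dej_threshold must be > 0")
        if self.long_utr3_rule not in ("absolute_nt", "multiple_of_annotation_median"):
            raise ValueError(f"unknown long_utr3_rule {self.long_utr3_rule!r}")


@dataclass
class NmdFeatureSet:
    """Per-transcript NMD feature calls; flags are None when not evaluable."""

    transcript_id: str
    gene_id: str
    evaluable: bool
    has_dej: bool | None = None
    dej_distance: float | None = None
    utr3_length: int | None = None
    is_long_utr3: bool | None = None
    n_uorfs: int | None = None

    @property
    def has_uorf(self) -> bool | None:
        return None if self.n_uorfs is None else self.n_uorfs > 0


# ---------------------------------------------------------------------------
# GTF / FASTA I/O


def _gtf_attributes(line_attrs: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in line_attrs.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> list[TranscriptModel]:
    """Parse an Ensembl-dialect GTF into transcript models.

    Only ``exon`` and ``CDS`` records are consulted; ``gene``/``transcript``
    container lines are tolerated and ignored. Coordinates are converted from
    1-based inclusive to 0-based half-open.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise GtfParseError(f"{path}:{lineno}: expected 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attr_str = parts
            if ftype not in ("exon", "CDS"):
                continue
            attrs = _gtf_attributes(attr_str)
            try:
                tid = attrs["transcript_id"]
                gid = attrs["gene_id"]
            except KeyError as exc:
                raise GtfParseError(f"{path}:{lineno}: missing {exc}") from exc
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            if tid not in exons:
                order.append(tid)
                exons[tid] = []
                cds[tid] = []
            genes[tid] = gid
            (exons if ftype == "exon" else cds)[tid].append(iv)

    models: list[TranscriptModel] = []
    for tid in order:
        model = TranscriptModel(tid, genes[tid], exons[tid])
        segs = sorted(cds[tid], key=lambda s: s.start)
        if segs:
            total = sum(len(s) for s in segs)
            first = segs[0].start if model.strand == "+" else segs[-1].end - 1
            cds_start = _genomic_to_transcript(model, first)
            model = TranscriptModel(
                tid, genes[tid], exons[tid], cds_start, cds_start + total
            )
        models.append(model)
    return models


def _genomic_to_transcript(model: TranscriptModel, gpos: int) -> int:
    """Map a genomic position (0-based) to a transcript coordinate."""
    tpos = 0
    exons = model.exons if model.strand == "+" else model.exons[::-1]
    for exon in exons:
        if exon.start <= gpos < exon.end:
            offset = gpos - exon.start if model.strand == "+" else exon.end - 1 - gpos
            return tpos + offset
        tpos += len(exon)
    raise GtfParseError(f"{model.transcript_id}: position {gpos} not exonic")


def write_gtf(models: Sequence[TranscriptModel], path) -> None:
    """Write transcript models as Ensembl-dialect GTF (CDS includes the stop)."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    with open(path, "w") as fh:
        for gid, txs in by_gene.items():
            g_start = min(t.exons[0].start for t in txs)
            g_end = max(t.exons[-1].end for t in txs)
            chrom, strand = txs[0].chrom, txs[0].strand
            attrs = f'gene_id "{gid}";'
            fh.write(
                f"{chrom}\tnmdkit\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t{attrs}\n"
            )
            for t in txs:
                tattrs = f'gene_id "{gid}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{chrom}\tnmdkit\ttranscript\t{t.exons[0].start + 1}\t"
                    f"{t.exons[-1].end}\t.\t{t.strand}\t.\t{tattrs}\n"
                )
                for exon in t.exons:
                    fh.write(
                        f"{chrom}\tnmdkit\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                        f"{t.strand}\t.\t{tattrs}\n"
                    )
                for seg in t.genomic_cds_segments():
                    fh.write(
                        f"{chrom}\tnmdkit\tCDS\t{seg.start + 1}\t{seg.end}\t.\t"
                        f"{t.strand}\t0\t{tattrs}\n"
                    )


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


# ---------------------------------------------------------------------------
# ORF assignment


def _find_orf_end(sequence: str, start: int) -> int | None:
    """Transcript coordinate just past the first in-frame stop, or None."""
    for pos in range(start + 3, len(sequence) - 2, 3):
        if sequence[pos : pos + 3] in STOP_CODONS:
            return pos + 3
    return None


def assign_orf(transcript: TranscriptModel, sequence: str) -> TranscriptModel:
    """Return a copy of ``transcript`` carrying an ORF, if one can be placed.

    An annotated CDS takes precedence; otherwise the longest ATG-initiated
    ORF ending at an in-frame stop codon is assigned. Transcripts whose ORF
    cannot be placed, or whose ORF leaves no 5'UTR or 3'UTR, come back
    without a CDS and are treated as not evaluable downstream.
    """
    if len(sequence) != transcript.length:
        raise ValueError(
            f"{transcript.transcript_id}: sequence length {len(sequence)} != "
            f"transcript length {transcript.length}"
        )
    sequence = sequence.upper()
    if transcript.has_cds():
        return transcript
    best: tuple[int, int] | None = None
    search_from = 0
    while (start := sequence.find(START_CODON, search_from)) != -1:
        end = _find_orf_end(sequence, start)
        if end is not None and (best is None or end - start > best[1] - best[0]):
            best = (start, end)
        search_from = start + 1
    if best is None:
        return transcript
    return replace(transcript, cds_start=best[0], cds_end=best[1])


def is_evaluable(transcript: TranscriptModel) -> bool:
    """True when the transcript has an ORF flanked by nonempty UTRs."""
    return (
        transcript.has_cds()
        and transcript.cds_start > 0
        and transcript.cds_end < transcript.length
    )


# ---------------------------------------------------------------------------
# Feature detectors


def detect_dej(
    transcript: TranscriptModel, config: FeatureConfig = FeatureConfig()
) -> tuple[bool, float | None]:
    """Call a downstream exon-junction: last junction > threshold nt past the stop.

    Returns ``(has_dej, dej_distance)``; the distance is signed (negative when
    the stop codon lies in the last exon) and ``None`` for single-exon
    transcripts, which cannot carry a junction.
    """
    if not transcript.has_cds():
        raise ValueError(f"{transcript.transcript_id}: no ORF assigned")
    junctions = transcript.junctions()
    if not junctions:
        return False, None
    distance = junctions[-1] - transcript.cds_end
    return distance > config.dej_threshold, float(distance)


def detect_uorfs(
    transcript: TranscriptModel,
    sequence: str,
    config: FeatureConfig = FeatureConfig(),
) -> int:
    """Count upstream ORFs fully contained in the 5'UTR.

    A uORF starts at an ATG strictly within the 5'UTR, terminates at an
    in-frame stop at or before the main start codon, and spans at least
    ``uorf_min_codons`` codons (stop included). Overlapping-uORFs (stop past
    the main ATG) are excluded.
    """
    if not transcript.has_cds():
        raise ValueError(f"{transcript.transcript_id}: no ORF assigned")
    sequence = sequence.upper()
    utr5_end = transcript.cds_start
    n = 0
    for start in range(utr5_end - 2):
        if sequence[start : start + 3] != START_CODON:
            continue
        end = _find_orf_end(sequence, start)
        if end is None or end > utr5_end:
            continue
        if (end - start) // 3 >= config.uorf_min_codons:
            n += 1
    return n


def measure_utr3(
    transcript: TranscriptModel,
    config: FeatureConfig = FeatureConfig(),
    annotation_median: float | None = None,
) -> tuple[int, bool]:
    """3'UTR length and the long-3'UTR flag under the configured rule."""
    if not transcript.has_cds():
        raise ValueError(f"{transcript.transcript_id}: no ORF assigned")
    utr3 = transcript.length - transcript.cds_end
    if config.long_utr3_rule == "absolute_nt":
        is_long = utr3 >= config.long_utr3_value
    else:
        if annotation_median is None:
            raise ValueError(
                "annotation_median required for multiple_of_annotation_median rule"
            )
        is_long = utr3 >= config.long_utr3_value * annotation_median
    return utr3, is_long


def median_utr3_length(transcripts: Iterable[TranscriptModel]) -> float:
    """Median 3'UTR length over evaluable transcripts of an annotation."""
    lengths = [
        t.length - t.cds_end for t in transcripts if t.has_cds() and is_evaluable(t)
    ]
    if not lengths:
        raise ValueError("no evaluable transcript with a 3'UTR")
    lengths.sort()
    mid = len(lengths) // 2
    if len(lengths) % 2:
        return float(lengths[mid])
    return (lengths[mid - 1] + lengths[mid]) / 2.0


# ---------------------------------------------------------------------------
# Annotation pipeline


def annotate_transcripts(
    models: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
    config: FeatureConfig = FeatureConfig(),
) -> list[NmdFeatureSet]:
    """Assign ORFs and run the three detectors on every transcript."""
    with_orf = []
    for model in models:
        seq = sequences.get(model.transcript_id)
        if seq is None:
            raise KeyError(f"no sequence for {model.transcript_id}")
        with_orf.append((assign_orf(model, seq), seq.upper()))

    median = None
    if config.long_utr3_rule == "multiple_of_annotation_median":
        evaluable = [t for t, _ in with_orf if is_evaluable(t)]
        median = median_utr3_length(evaluable) if evaluable else math.nan

    out: list[NmdFeatureSet] = []
    for model, seq in with_orf:
        if not is_evaluable(model):
            out.append(NmdFeatureSet(model.transcript_id, model.gene_id, False))
            continue
        has_dej, dist = detect_dej(model, config)
        utr3, is_long = measure_utr3(model, config, annotation_median=median)
        n_uorfs = detect_uorfs(model, seq, config)
        out.append(
            NmdFeatureSet(
                model.transcript_id,
                model.gene_id,
                True,
                has_dej=has_dej,
                dej_distance=dist,
                utr3_length=utr3,
                is_long_utr3=is_long,
                n_uorfs=n_uorfs,
            )
        )
    return out


def collapse_to_gene(feature_sets: Sequence[NmdFeatureSet]) -> pd.DataFrame:
    """OR the per-transcript flags to the gene level.

    A gene is positive for a feature if any evaluable transcript is; genes
    with no evaluable transcript are flagged ``evaluable=False`` with NA
    feature columns.
    """
    rows = []
    by_gene: dict[str, list[NmdFeatureSet]] = {}
    for fs in feature_sets:
        by_gene.setdefault(fs.gene_id, []).append(fs)
    for gid, sets in by_gene.items():
        ok = [fs for fs in sets if fs.evaluable]
        if not ok:
            rows.append(
                dict(
                    gene_id=gid,
                    evaluable=False,
                    has_dej=pd.NA,
                    has_uorf=pd.NA,
                    is_long_utr3=pd.NA,
                )
            )
        else:
            rows.append(
                dict(
                    gene_id=gid,
                    evaluable=True,
                    has_dej=any(fs.has_dej for fs in ok),
                    has_uorf=any(fs.has_uorf for fs in ok),
                    is_long_utr3=any(fs.is_long_utr3 for fs in ok),
                )
            )
    return pd.DataFrame(rows).set_index("gene_id")


def feature_table(feature_sets: Sequence[NmdFeatureSet]) -> pd.DataFrame:
    """Flat per-transcript TSV-ready table of feature calls."""
    return pd.DataFrame(
        [
            dict(
                transcript_id=fs.transcript_id,
                gene_id=fs.gene_id,
                evaluable=fs.evaluable,
                has_dej=fs.has_dej,
                dej_distance=fs.dej_distance,
                utr3_length=fs.utr3_length,
                is_long_utr3=fs.is_long_utr3,
                n_uorfs=fs.n_uorfs,
            )
            for fs in feature_sets
        ]
    )
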