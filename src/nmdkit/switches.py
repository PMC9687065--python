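"""Isoform usage, differential-usage testing and switch consequences.

Usage is the isoform fraction IF = isoform TPM / gene TPM. Filtering follows
the minimum-TPM / minimum-gene-fraction / minimum-isoform rules; testing is
a two-sample Welch t-test on arcsine-square-root transformed fractions with
BH adjustment. Consequences compare each significantly upregulated isoform
against the gene's major isoform (highest mean control IF, ties broken by
longer transcript then id).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .de import CONTROL, NULL
from .features import FeatureConfig, NmdFeatureSet, TranscriptModel, detect_dej

__all__ = [
    "SwitchFilterConfig",
    "isoform_fractions",
    "filter_isoforms",
    "dif_test",
    "major_isoforms",
    "classify_consequences",
    "switch_plot_table",
]


@dataclass(frozen=True)
class SwitchFilterConfig:
    min_tpm: float = 0.1
    min_gene_fraction: float = 0.05
    min_isoforms: int = 2

    def __post_init__(self) -> None:
        if min(self.min_tpm, self.min_gene_fraction, self.min_isoforms) < 0:
            raise ValueError("filter thresholds must be >= 0")


def _split_tpm(tpm: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    if "gene_id" not in tpm.columns:
        raise ValueError("tpm frame needs a gene_id column")
    if tpm["gene_id"].isna().any():
        bad = list(tpm.index[tpm["gene_id"].isna()])[:3]
        raise ValueError(f"isoforms without a gene: {bad}")
    return tpm["gene_id"], tpm.drop(columns="gene_id")


def isoform_fractions(tpm: pd.DataFrame) -> pd.DataFrame:
    """Per-sample isoform fractions; NaN where the gene's TPM is zero.

    ``tpm`` is indexed by isoform with a ``gene_id`` column followed by one
    column per sample.
    """
    gene_ids, values = _split_tpm(tpm)
    gene_tot = values.groupby(gene_ids).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = values / gene_tot
    frac = frac.where(gene_tot > 0)
    out = frac.copy()
    out.insert(0, "gene_id", gene_ids)
    return out


def filter_isoforms(
    tpm: pd.DataFrame, config: SwitchFilterConfig = SwitchFilterConfig()
) -> pd.DataFrame:
    """Drop weakly expressed / minor isoforms, then genes left with too few.

    An isoform is dropped when its mean TPM is below ``min_tpm`` or its mean
    fraction of the parent gene is below ``min_gene_fraction``; genes
    retaining fewer than ``min_isoforms`` isoforms are dropped entirely.
    """
    gene_ids, values = _split_tpm(tpm)
    frac = isoform_fractions(tpm).drop(columns="gene_id")
    keep = (values.mean(axis=1) >= config.min_tpm) & (
        frac.mean(axis=1) >= config.min_gene_fraction
    )
    kept = tpm.loc[keep]
    sizes = kept.groupby("gene_id")["gene_id"].transform("size")
    return kept.loc[sizes >= config.min_isoforms]


def dif_test(
    tpm: pd.DataFrame,
    samples: pd.Series,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Test per-isoform usage change (null vs control).

    dIF is the difference of mean isoform fractions (null - control); the
    p-value comes from a Welch t-test on arcsine-sqrt transformed fractions,
    with p = 1 by convention for fractions constant in both groups.
    """
    frac = isoform_fractions(tpm)
    gene_ids, values = _split_tpm(frac)
    cols_null = [c for c in values.columns if samples[c] == NULL]
    cols_ctrl = [c for c in values.columns if samples[c] == CONTROL]
    if len(cols_null) < 2 or len(cols_ctrl) < 2:
        raise ValueError("need >=2 samples per group")

    rows = []
    for iso, row in values.iterrows():
        a = row[cols_null].dropna().astype(float)
        b = row[cols_ctrl].dropna().astype(float)
        if len(a) < 2 or len(b) < 2:
            continue
        dif = a.mean() - b.mean()
        ta = np.arcsin(np.sqrt(np.clip(a, 0, 1)))
        tb = np.arcsin(np.sqrt(np.clip(b, 0, 1)))
        if ta.nunique() <= 1 and tb.nunique() <= 1 and np.isclose(ta.mean(), tb.mean()):
            p = 1.0
        elif ta.std() == 0 and tb.std() == 0:
            p = 0.0 if not np.isclose(ta.mean(), tb.mean()) else 1.0
        else:
            p = stats.ttest_ind(ta, tb, equal_var=False).pvalue
        rows.append(
            dict(isoform_id=iso, gene_id=gene_ids[iso], dif=dif, p=float(p))
        )
    result = pd.DataFrame(rows).set_index("isoform_id")
    if result.empty:
        raise ValueError("no testable isoform")
    result["q"] = multipletests(result["p"], method="fdr_bh")[1]
    result["direction"] = np.where(result["dif"] > 0, "up", "down")
    result["called"] = result["q"] < q_threshold
    return result


def major_isoforms(
    tpm: pd.DataFrame,
    samples: pd.Series,
    lengths: Mapping[str, int] | None = None,
) -> pd.Series:
    """Per gene: the isoform with the highest mean control IF.

    Ties break toward the longer transcript (if lengths are given), then the
    lexicographically smaller id. Genes whose control fractions are all
    missing are omitted.
    """
    frac = isoform_fractions(tpm)
    gene_ids, values = _split_tpm(frac)
    cols_ctrl = [c for c in values.columns if samples[c] == CONTROL]
    mean_if = values[cols_ctrl].mean(axis=1)
    out = {}
    for gid, idx in mean_if.groupby(gene_ids).groups.items():
        sub = mean_if.loc[idx].dropna()
        if sub.empty:
            continue
        ranked = sorted(
            sub.index,
            key=lambda iso: (
                -sub[iso],
                -(lengths.get(iso, 0) if lengths else 0),
                iso,
            ),
        )
        out[gid] = ranked[0]
    return pd.Series(out, name="major_isoform")


def _tss_tts(model: TranscriptModel) -> tuple[int, int]:
    if model.strand == "+":
        return model.exons[0].start, model.exons[-1].end
    return model.exons[-1].end, model.exons[0].start


def _terminal_exon(model: TranscriptModel) -> tuple[int, int]:
    exon = model.exons[-1] if model.strand == "+" else model.exons[0]
    return exon.start, exon.end


def _retains_intron(up: TranscriptModel, ref: TranscriptModel) -> bool:
    for a, b in zip(ref.exons, ref.exons[1:]):
        for e in up.exons:
            if e.start < a.end and e.end > b.start:
                return True
    return False


def classify_consequences(
    up: TranscriptModel,
    ref: TranscriptModel,
    up_features: NmdFeatureSet | None = None,
    ref_features: NmdFeatureSet | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> set[str]:
    """Consequence classes of an upregulated isoform vs the major isoform."""
    out: set[str] = set()
    up_dej = (
        up_features.has_dej
        if up_features is not None
        else (detect_dej(up, config)[0] if up.has_cds() else None)
    )
    ref_dej = (
        ref_features.has_dej
        if ref_features is not None
        else (detect_dej(ref, config)[0] if ref.has_cds() else None)
    )
    if up_dej and not ref_dej:
        out.add("nmd_sensitivity_gain")
    if ref_dej and not up_dej:
        out.add("nmd_sensitivity_loss")

    up_utr3 = (
        up_features.utr3_length
        if up_features is not None and up_features.utr3_length is not None
        else (up.length - up.cds_end if up.has_cds() else None)
    )
    ref_utr3 = (
        ref_features.utr3_length
        if ref_features is not None and ref_features.utr3_length is not None
        else (ref.length - ref.cds_end if ref.has_cds() else None)
    )
    if up_utr3 is not None and ref_utr3 is not None:
        if up_utr3 > ref_utr3:
            out.add("utr3_longer")
        elif up_utr3 < ref_utr3:
            out.add("utr3_shorter")

    if _retains_intron(up, ref):
        out.add("intron_retention")
    up_tss, up_tts = _tss_tts(up)
    ref_tss, ref_tts = _tss_tts(ref)
    if up_tss != ref_tss:
        out.add("alt_tss")
    if up_tts != ref_tts:
        out.add("alt_tts")
    if _terminal_exon(up) != _terminal_exon(ref):
        out.add("last_exon_change")
    if up.length != ref.length:
        out.add("length_change")
    if up.n_exons != ref.n_exons:
        out.add("exon_number_change")
    return out


def switch_plot_table(
    tpm: pd.DataFrame, samples: pd.Series, genes: Sequence[str]
) -> pd.DataFrame:
    """Per-isoform group mean IF +/- sem for plotting usage switches."""
    frac = isoform_fractions(tpm)
    gene_ids, values = _split_tpm(frac)
    rows = []
    for genotype in (CONTROL, NULL):
        cols = [c for c in values.columns if samples[c] == genotype]
        for iso in values.index:
            if gene_ids[iso] not in set(genes):
                continue
            vals = values.loc[iso, cols].dropna().astype(float)
            rows.append(
                dict(
                    isoform_id=iso,
                    gene_id=gene_ids[iso],
                    group=genotype,
                    mean_if=vals.mean() if len(vals) else np.nan,
                    sem=vals.sem() if len(vals) > 1 else np.nan,
                    n=len(vals),
                )
            )
    return pd.DataFrame(rows)
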