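"""Integration of DE, stability, features and switches into target lists.

Canonical high-confidence targets: genes upregulated in the null genotype
that are additionally stabilized, dEJ-positive, or on the prior list.
Alternatively-processed (AP) targets: isoforms significantly upregulated in
the null genotype that carry a dEJ, have a 3'UTR longer than the gene's
major isoform, or belong to a prior-list gene. uORF evidence is computed and
reported but excluded from the default AP rule (config-switchable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IntegrationConfig",
    "call_canonical_targets",
    "call_ap_targets",
    "combine_targets",
    "feature_enrichment",
    "utr3_comparison",
    "overlap_with_prior",
]


@dataclass(frozen=True)
class IntegrationConfig:
    de_q_threshold: float = 0.1
    switch_q_threshold: float = 0.1
    include_uorf_in_ap: bool = False


def call_canonical_targets(
    de: pd.DataFrame,
    stability: pd.DataFrame,
    gene_features: pd.DataFrame,
    prior_list: set[str] | list[str],
    config: IntegrationConfig = IntegrationConfig(),
) -> pd.DataFrame:
    """Genes upregulated AND (stabilized OR dEJ OR previously implicated).

    ``de`` needs ``log2fc``/``q``; ``stability`` needs ``stabilized``;
    ``gene_features`` needs ``has_dej`` (gene-level collapse). Returns one
    row per called gene with its evidence flags.
    """
    prior = set(prior_list)
    up = (de["q"] < config.de_q_threshold) & (de["log2fc"] > 0)
    stabilized = stability["stabilized"].reindex(de.index, fill_value=False)
    dej = (
        gene_features["has_dej"]
        .reindex(de.index)
        .map(lambda v: bool(v) if not pd.isna(v) else False)
    )
    in_prior = de.index.isin(prior)

    called = up & (stabilized | dej | in_prior)
    rows = []
    for gid in de.index[called]:
        evidence = {"upregulated"}
        if stabilized[gid]:
            evidence.add("stabilized")
        if dej[gid]:
            evidence.add("dej")
        if gid in prior:
            evidence.add("prior_list")
        rows.append(
            dict(
                gene_id=gid,
                category="canonical_high_confidence",
                evidence=",".join(sorted(evidence)),
                isoform_id="",
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "category", "evidence", "isoform_id"]
    ).set_index("gene_id")


def call_ap_targets(
    switch: pd.DataFrame,
    isoform_features: pd.DataFrame,
    major_utr3: pd.Series,
    prior_list: set[str] | list[str],
    config: IntegrationConfig = IntegrationConfig(),
) -> pd.DataFrame:
    """Upregulated switch isoforms with an NMD feature or prior-list support.

    ``switch`` is the dIF test table (``dif``, ``q``, ``gene_id``);
    ``isoform_features`` is indexed by isoform with ``has_dej``,
    ``utr3_length`` and ``has_uorf``; ``major_utr3`` maps gene ->
    major-isoform 3'UTR length.
    """
    prior = set(prior_list)
    rows = []
    for iso, row in switch.iterrows():
        if not (row["dif"] > 0 and row["q"] < config.switch_q_threshold):
            continue
        gid = row["gene_id"]
        evidence = {"isoform_upregulated"}
        feats = isoform_features.loc[iso] if iso in isoform_features.index else None
        has_dej = bool(feats["has_dej"]) if feats is not None and not pd.isna(feats["has_dej"]) else False
        if has_dej:
            evidence.add("dej")
        longer = False
        if (
            feats is not None
            and not pd.isna(feats.get("utr3_length"))
            and gid in major_utr3.index
            and not pd.isna(major_utr3[gid])
        ):
            longer = feats["utr3_length"] > major_utr3[gid]
        if longer:
            evidence.add("long_utr3")
        if gid in prior:
            evidence.add("prior_list")
        has_uorf = (
            bool(feats["has_uorf"])
            if feats is not None and "has_uorf" in feats and not pd.isna(feats["has_uorf"])
            else False
        )
        if has_uorf:
            evidence.add("uorf")

        qualifying = has_dej or longer or (gid in prior)
        if config.include_uorf_in_ap:
            qualifying = qualifying or has_uorf
        if qualifying:
            rows.append(
                dict(
                    gene_id=gid,
                    category="ap_high_confidence",
                    evidence=",".join(sorted(evidence)),
                    isoform_id=iso,
                )
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "category", "evidence", "isoform_id"]
    ).set_index("gene_id")


def combine_targets(canonical: pd.DataFrame, ap: pd.DataFrame) -> pd.DataFrame:
    """Union of the two gene lists; shared genes get category ``both``."""
    genes = list(dict.fromkeys(list(canonical.index) + list(ap.index)))
    rows = []
    for gid in genes:
        in_c, in_a = gid in canonical.index, gid in ap.index
        category = "both" if (in_c and in_a) else (
            "canonical_high_confidence" if in_c else "ap_high_confidence"
        )
        evidence = set()
        if in_c:
            evidence |= set(canonical.loc[gid, "evidence"].split(","))
        if in_a:
            for ev in ap.loc[ap.index == gid, "evidence"]:
                evidence |= set(ev.split(","))
        rows.append(
            dict(gene_id=gid, category=category, evidence=",".join(sorted(evidence)))
        )
    return pd.DataFrame(rows, columns=["gene_id", "category", "evidence"]).set_index(
        "gene_id"
    )


def feature_enrichment(
    gene_set: set[str] | list[str],
    background_features: pd.DataFrame,
    features: tuple[str, ...] = ("has_dej", "has_uorf", "is_long_utr3"),
) -> pd.DataFrame:
    """Per-feature proportion in set vs background with two-sided Fisher p.

    Background is every evaluable gene in ``background_features``; the set
    is intersected with it.
    """
    bg = background_features
    if "evaluable" in bg.columns:
        bg = bg.loc[bg["evaluable"].astype(bool)]
    set_genes = [g for g in gene_set if g in bg.index]
    if not set_genes:
        raise ValueError("gene set has no evaluable member")
    rows = []
    for feat in features:
        flags = bg[feat].astype(bool)
        in_set = flags.loc[set_genes]
        a = int(in_set.sum())
        b = len(in_set) - a
        c = int(flags.sum()) - a
        d = (len(flags) - len(in_set)) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            dict(
                feature=feat,
                prop_set=a / len(in_set),
                prop_background=flags.mean(),
                odds_ratio=odds,
                p=p,
                n_set=len(in_set),
                n_background=len(flags),
            )
        )
    return pd.DataFrame(rows).set_index("feature")


def utr3_comparison(
    gene_set: set[str] | list[str], utr3_lengths: pd.Series
) -> dict:
    """Ratio of mean 3'UTR length (set / background) with a rank-sum test."""
    in_set = utr3_lengths.loc[utr3_lengths.index.isin(set(gene_set))].dropna()
    out_set = utr3_lengths.loc[~utr3_lengths.index.isin(set(gene_set))].dropna()
    if in_set.empty or out_set.empty:
        raise ValueError("need nonempty set and background 3'UTR lengths")
    u, p = stats.mannwhitneyu(in_set, out_set, alternative="two-sided")
    return {
        "ratio_of_means": float(in_set.mean() / out_set.mean()),
        "p": float(p),
        "n_set": int(len(in_set)),
        "n_background": int(len(out_set)),
    }


def overlap_with_prior(
    gene_set: set[str] | list[str], prior_list: set[str] | list[str]
) -> float:
    """100 * |set ∩ prior| / |set|."""
    genes = set(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    return 100.0 * len(genes & set(prior_list)) / len(genes)
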