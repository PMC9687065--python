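"""Stage- and lineage-resolved gene-set expression shifts.

Per-gene log fold changes are computed from stage means against a baseline
stage; gene-set trajectories are summarized as mean +/- sem with one-sample
t-tests (Bonferroni over stages); distribution shifts are measured by the
two-sample Kolmogorov-Smirnov D against the baseline, normalized by the D of
a reference set (differential D). The same machinery runs on protein
time-courses with time points standing in for stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import StageExpression

ALL_LINEAGES = "all"

__all__ = [
    "lfc_vs_baseline",
    "gene_set_trajectory",
    "ks_shift",
    "fraction_downregulated",
    "dotplot_summary",
    "protein_trajectory",
    "stage_means",
]


def stage_means(
    expr: StageExpression, lineage: str = ALL_LINEAGES
) -> pd.DataFrame:
    """Per-gene mean expression per stage, optionally within one lineage."""
    cells = expr.cells
    out = {}
    for stage in expr.stage_order:
        mask = cells["stage"] == stage
        if lineage != ALL_LINEAGES:
            mask &= cells["lineage"] == lineage
        cols = cells.index[mask]
        if len(cols) == 0:
            out[stage] = pd.Series(np.nan, index=expr.matrix.index)
        else:
            out[stage] = expr.matrix[cols].mean(axis=1)
    return pd.DataFrame(out)


def lfc_vs_baseline(
    expr: StageExpression,
    baseline_stage: str | None = None,
    eps: float = 1e-3,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Per-gene, per-stage, per-lineage log fold change vs the baseline stage.

    LFC = log((stage mean + eps) / (baseline mean + eps)); computed pooled
    over lineages ("all") and per lineage. Lineages absent at a stage give
    missing values. Columns are a (stage, lineage) MultiIndex.
    """
    if baseline_stage is None:
        baseline_stage = expr.stage_order[0]
    if baseline_stage not in expr.stage_order:
        raise ValueError(f"baseline stage {baseline_stage!r} absent")
    lineages = [ALL_LINEAGES] + sorted(expr.cells["lineage"].unique())
    blocks = {}
    log_den = np.log(log_base)
    for lineage in lineages:
        means = stage_means(expr, lineage)
        base = means[baseline_stage]
        for stage in expr.stage_order:
            blocks[(stage, lineage)] = (
                np.log((means[stage] + eps) / (base + eps)) / log_den
            )
    out = pd.DataFrame(blocks)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["stage", "lineage"])
    return out


def gene_set_trajectory(
    lfc: pd.DataFrame,
    gene_set: set[str] | list[str],
    baseline_stage: str,
    lineages: list[str] | None = None,
) -> pd.DataFrame:
    """Mean +/- sem of set-gene LFCs per stage/lineage with Bonferroni p.

    The t-test is the set's LFC distribution against zero at each non-
    baseline stage; the Bonferroni family is the number of stage comparisons
    within one set/lineage.
    """
    genes = [g for g in lfc.index if g in set(gene_set)]
    if not genes:
        raise ValueError("gene set absent from the LFC table")
    stages = list(lfc.columns.get_level_values("stage").unique())
    if lineages is None:
        lineages = list(lfc.columns.get_level_values("lineage").unique())
    tested_stages = [s for s in stages if s != baseline_stage]
    rows = []
    for lineage in lineages:
        for stage in stages:
            vals = lfc.loc[genes, (stage, lineage)].dropna()
            mean = vals.mean() if len(vals) else np.nan
            sem = vals.sem() if len(vals) > 1 else np.nan
            if stage == baseline_stage or len(vals) < 2 or vals.std() == 0:
                p = np.nan
            else:
                p = float(stats.ttest_1samp(vals, 0.0).pvalue)
            p_bonf = (
                min(p * len(tested_stages), 1.0) if not np.isnan(p) else np.nan
            )
            rows.append(
                dict(
                    stage=stage,
                    lineage=lineage,
                    mean_lfc=mean,
                    sem=sem,
                    p=p,
                    p_bonf=p_bonf,
                    n_genes=len(vals),
                )
            )
    return pd.DataFrame(rows)


def ks_shift(
    expr: StageExpression,
    gene_set: set[str] | list[str],
    reference_set: set[str] | list[str],
    stage: str,
    baseline_stage: str | None = None,
    lineage: str = ALL_LINEAGES,
) -> dict:
    """KS D of the set's stage vs baseline expression, normalized by a reference.

    D is the two-sample KS statistic between the per-gene mean expression at
    ``stage`` and at the baseline; differential D = D(set)/D(reference) and
    is flagged undefined when the reference D is zero. A CDF table of all
    four distributions is returned for plotting.
    """
    if baseline_stage is None:
        baseline_stage = expr.stage_order[0]
    means = stage_means(expr, lineage)
    result: dict = {}
    cdf_rows = []
    for label, genes in (("set", gene_set), ("reference", reference_set)):
        sel = [g for g in means.index if g in set(genes)]
        if not sel:
            raise ValueError(f"{label} set empty at this stage")
        at_stage = means.loc[sel, stage].dropna().values
        at_base = means.loc[sel, baseline_stage].dropna().values
        if len(at_stage) == 0 or len(at_base) == 0:
            raise ValueError(f"{label} set has no values")
        d = float(stats.ks_2samp(at_stage, at_base).statistic)
        result[f"ks_d_{label}"] = d
        for which, vals in (("stage", at_stage), ("baseline", at_base)):
            order = np.sort(vals)
            ecdf = np.arange(1, len(order) + 1) / len(order)
            cdf_rows.extend(
                dict(set=label, distribution=which, value=v, cdf=c)
                for v, c in zip(order, ecdf)
            )
    d_ref = result["ks_d_reference"]
    result["ks_d"] = result["ks_d_set"]
    result["differential_d"] = (
        result["ks_d_set"] / d_ref if d_ref > 0 else float("nan")
    )
    result["differential_d_defined"] = d_ref > 0
    result["cdf"] = pd.DataFrame(cdf_rows)
    return result


def fraction_downregulated(
    lfc: pd.DataFrame,
    gene_set: set[str] | list[str],
    from_stage: str,
    to_stage: str,
    lineage: str = ALL_LINEAGES,
) -> float:
    """Fraction of set genes whose LFC decreases from one stage to the next."""
    genes = [g for g in lfc.index if g in set(gene_set)]
    if not genes:
        raise ValueError("empty gene set")
    change = (
        lfc.loc[genes, (to_stage, lineage)] - lfc.loc[genes, (from_stage, lineage)]
    ).dropna()
    if change.empty:
        raise ValueError("no gene with values at both stages")
    return float((change < 0).mean())


def dotplot_summary(
    expr: StageExpression, gene_set: set[str] | list[str]
) -> pd.DataFrame:
    """Per gene and stage: mean expression and fraction of cells detected (>0)."""
    genes = [g for g in expr.matrix.index if g in set(gene_set)]
    rows = []
    for stage in expr.stage_order:
        cols = expr.cells.index[expr.cells["stage"] == stage]
        block = expr.matrix.loc[genes, cols]
        for gid in genes:
            vals = block.loc[gid]
            rows.append(
                dict(
                    gene_id=gid,
                    stage=stage,
                    mean_expr=float(vals.mean()),
                    fraction_detected=float((vals > 0).mean()),
                )
            )
    return pd.DataFrame(rows)


def protein_trajectory(
    protein: pd.DataFrame,
    sample_times: pd.Series,
    gene_set: set[str] | list[str],
    baseline_time=None,
    eps: float = 1e-3,
) -> pd.DataFrame:
    """Gene-set trajectory over an ordered protein time-course.

    ``protein`` is genes x samples; ``sample_times`` maps sample -> time
    point. Time points replace stages and replicates replace cells; set
    members missing from the matrix are skipped.
    """
    times = sorted(sample_times.unique())
    if baseline_time is None:
        baseline_time = times[0]
    if baseline_time not in times:
        raise ValueError("baseline time point absent")
    cells = pd.DataFrame(
        {
            "stage": sample_times.astype(str),
            "lineage": ALL_LINEAGES,
        },
        index=sample_times.index,
    )
    expr = StageExpression(
        matrix=protein[sample_times.index],
        cells=cells,
        stage_order=tuple(str(t) for t in times),
    )
    present = [g for g in gene_set if g in protein.index]
    if not present:
        raise ValueError("no set gene present in the protein matrix")
    lfc = lfc_vs_baseline(expr, baseline_stage=str(baseline_time), eps=eps)
    return gene_set_trajectory(
        lfc, present, baseline_stage=str(baseline_time), lineages=[ALL_LINEAGES]
    )
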