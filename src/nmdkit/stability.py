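"""Relative mRNA stability from exonic/intronic counts and the DSS.

The per-gene, per-sample stability proxy is

    delta = log2(normalized exonic + pc) - log2(normalized intronic + pc)

with the two matrices normalized by their own median-of-ratios size factors.
A gene-specific bias is removed in three steps: per-sample centering (kills
residual library-size artifacts exactly), subtraction of a pooled local
regression of delta on log exonic abundance (the abundance-dependent bias
trend), and per-gene centering (the gene-specific offset). The differential
stability score (DSS) is the null-minus-control group mean of the residual
stability, with genes called stabilized at DSS > threshold.

The trend is fitted pooling all genes rather than per gene across samples:
in a two-group design a per-gene smoother would absorb the very group shift
the DSS is meant to measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .de import CONTROL, NULL, CountTables, normalize

MIN_QUANTIFIABLE_GENES = 50

__all__ = [
    "StabilityConfig",
    "DeltaResult",
    "delta_matrix",
    "fit_bias",
    "differential_stability",
    "run_stability",
]


@dataclass(frozen=True)
class StabilityConfig:
    pseudocount: float = 1.0
    stringency: float = 0.99
    smoother_span: float = 0.3
    dss_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.stringency <= 1):
            raise ValueError("stringency in (0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not (0 < self.smoother_span <= 1):
            raise ValueError("smoother_span in (0, 1]")


@dataclass
class DeltaResult:
    """Per-sample stability proxies restricted to quantifiable genes."""

    delta: pd.DataFrame  # quantifiable genes x samples
    abundance: pd.DataFrame  # log2 normalized exonic, same shape
    quantifiable: pd.Series  # all genes -> bool
    reason: pd.Series  # all genes -> "" | "no_introns" | "low_intronic_coverage"


def delta_matrix(
    tables: CountTables, config: StabilityConfig = StabilityConfig()
) -> DeltaResult:
    """log2 exon/intron proxy per gene and sample, with quantifiability flags.

    A gene is quantifiable when it has intronic sequence and a nonzero
    intronic count in at least ``stringency`` of the samples (at the default
    0.99 and typical sample counts this requires every sample).
    """
    norm_ex, _ = normalize(tables.exonic)
    norm_in, _ = normalize(tables.intronic.loc[(tables.intronic > 0).any(axis=1)])
    norm_in = norm_in.reindex(tables.intronic.index, fill_value=0.0)

    reason = pd.Series("", index=tables.exonic.index, dtype=object)
    if "intronic_length" in tables.gene_lengths.columns:
        intronless = tables.gene_lengths["intronic_length"].reindex(
            tables.exonic.index
        ).fillna(0) <= 0
    else:
        intronless = (tables.intronic == 0).all(axis=1)
    reason[intronless] = "no_introns"

    nonzero_frac = (tables.intronic > 0).mean(axis=1)
    low = (nonzero_frac < config.stringency) & ~intronless
    reason[low] = "low_intronic_coverage"

    quantifiable = reason == ""
    pc = config.pseudocount
    delta = np.log2(norm_ex + pc) - np.log2(norm_in + pc)
    abundance = np.log2(norm_ex + pc)
    return DeltaResult(
        delta=delta.loc[quantifiable],
        abundance=abundance.loc[quantifiable],
        quantifiable=quantifiable,
        reason=reason,
    )


def fit_bias(
    delta: pd.DataFrame,
    abundance: pd.DataFrame,
    config: StabilityConfig = StabilityConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (bias, stability) with stability = delta - bias.

    Stability is centered at 0 per gene over all samples combined; with
    fewer than three samples the smoother degenerates to the per-gene mean.
    """
    if delta.shape[0] < MIN_QUANTIFIABLE_GENES:
        raise ValueError(
            f"only {delta.shape[0]} quantifiable genes (<{MIN_QUANTIFIABLE_GENES});"
            " lower the stringency"
        )
    values = delta.values.astype(float)
    # per-sample centering: a constant offset of one sample's deltas is a
    # library artifact and must not reach the DSS; the median ignores a
    # minority of genuinely shifted genes
    centered = values - np.median(values, axis=0, keepdims=True)

    # gene-specific bias = smooth trend in the gene's overall abundance plus
    # a per-gene offset. Both are constant across samples within a gene, so
    # they cancel exactly from any between-group contrast; fitting the trend
    # on within-gene abundance deviations instead would absorb the very
    # genotype shift the DSS measures (exonic noise is shared between delta
    # and abundance, driving a spurious unit slope).
    gene_mean = centered.mean(axis=1)
    xbar = abundance.values.astype(float).mean(axis=1)
    if delta.shape[1] >= 3:
        span = max(xbar.max() - xbar.min(), 1e-9)
        fitted = lowess(
            gene_mean,
            xbar,
            frac=config.smoother_span,
            delta=0.01 * span,
            return_sorted=True,
        )
        trend = np.interp(xbar, fitted[:, 0], fitted[:, 1])
    else:
        trend = gene_mean  # degenerate smoother: per-gene mean

    resid = centered - trend[:, None]
    resid = resid - resid.mean(axis=1, keepdims=True)  # leftover gene offset
    stability = pd.DataFrame(resid, index=delta.index, columns=delta.columns)
    bias = delta - stability
    return bias, stability


def differential_stability(
    stability: pd.DataFrame,
    samples: pd.Series,
    config: StabilityConfig = StabilityConfig(),
    quantifiable: pd.Series | None = None,
) -> pd.DataFrame:
    """DSS = mean stability in null minus control, with stabilized calls."""
    cols_null = [c for c in stability.columns if samples[c] == NULL]
    cols_ctrl = [c for c in stability.columns if samples[c] == CONTROL]
    if not cols_null or not cols_ctrl:
        raise ValueError("both genotypes required")
    dss = stability[cols_null].mean(axis=1) - stability[cols_ctrl].mean(axis=1)
    out = pd.DataFrame(
        {
            "dss": dss,
            "stabilized": dss > config.dss_threshold,
            "destabilized": dss < -config.dss_threshold,
            "quantifiable": True,
        },
        index=stability.index,
    )
    if quantifiable is not None:
        full = pd.DataFrame(
            {
                "dss": np.nan,
                "stabilized": False,
                "destabilized": False,
                "quantifiable": False,
            },
            index=quantifiable.index,
        )
        full.loc[out.index, ["dss", "stabilized", "destabilized", "quantifiable"]] = out
        full["stabilized"] = full["stabilized"].astype(bool)
        full["destabilized"] = full["destabilized"].astype(bool)
        full["quantifiable"] = full["quantifiable"].astype(bool)
        return full
    return out


def run_stability(
    tables: CountTables, config: StabilityConfig = StabilityConfig()
) -> pd.DataFrame:
    """Convenience chain: delta -> bias correction -> DSS table for all genes."""
    dres = delta_matrix(tables, config)
    _, stability = fit_bias(dres.delta, dres.abundance, config)
    result = differential_stability(
        stability, tables.samples, config, quantifiable=dres.quantifiable
    )
    result["reason"] = dres.reason
    return result
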