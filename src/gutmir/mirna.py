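"""NanoString-style miRNA count processing.

Per-lane background is the mean of the negative-control probes plus twice
their sample standard deviation. Lanes are scaled to the positive (and, when
present, ligation) controls: each lane's factor is the grand geometric mean of
the control sums divided by that lane's control sum. Background subtraction
happens after scaling, with flooring at zero. Probes averaging strictly more
than 24 counts above background across all samples are called abundant.

For ordination the counts are log2(x+1)-transformed and the top-k
most-variable probes retained (the shrinkage-based regularized-log transform
some pipelines use is deliberately replaced by this plain log transform; the
divergence is recorded in the output metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError, MirnaCounts


def background_threshold(mc: MirnaCounts) -> np.ndarray:
    """Per-lane background: mean + 2 * sample SD of negative-control counts."""
    neg = mc.counts[mc.class_mask("negative")]
    if neg.shape[0] < 2:
        raise DataError(">= 2 negative control probes required")
    return neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)


def _scale_factors(control: np.ndarray, label: str) -> np.ndarray:
    sums = control.sum(axis=0)
    if (sums <= 0).any():
        lane = int(np.argmax(sums <= 0))
        raise DataError(f"lane {lane} has zero {label}-control sum")
    geo = float(np.exp(np.mean(np.log(sums))))
    return geo / sums


def normalize_counts(
    mc: MirnaCounts, subtract_background: bool = True
) -> pd.DataFrame:
    """Control-normalized, background-subtracted probe x sample matrix.

    Scaling uses positive controls, then ligation controls identically as a
    second factor when present. The background threshold is computed from the
    scaled negative controls and subtracted from every probe, flooring at 0.
    """
    factors = _scale_factors(mc.counts[mc.class_mask("positive")], "positive")
    lig = mc.counts[mc.class_mask("ligation")]
    if lig.shape[0] > 0:
        factors = factors * _scale_factors(lig, "ligation")
    scaled = mc.counts * factors[None, :]
    if subtract_background:
        scaled_mc = MirnaCounts(mc.probe_ids, mc.probe_class,
                                mc.sample_ids, scaled)
        bg = background_threshold(scaled_mc)
        scaled = np.maximum(scaled - bg[None, :], 0.0)
    return pd.DataFrame(scaled, index=mc.probe_ids, columns=mc.sample_ids)


def call_abundant(
    normalized: pd.DataFrame,
    endogenous_ids: list[str],
    threshold: float = 24.0,
) -> set[str]:
    """Endogenous probes whose mean normalized count is strictly > threshold.

    The threshold applies to normalized, background-subtracted counts (a
    flagged interpretation: whether the original ">24" rule used raw or
    normalized counts is ambiguous; see output metadata).
    """
    means = normalized.loc[endogenous_ids].mean(axis=1)
    return set(means.index[means > threshold])


def differential_mirna(
    normalized: pd.DataFrame,
    groups: dict[str, str],
    endogenous_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-probe Welch t-test between two sample groups with log2 fold change.

    log2FC uses group means with a pseudocount of 1. Zero-variance probes
    (Welch statistic undefined) get p = 1 by convention. Output is
    volcano-ready: probe, log2fc, t, p.
    """
    levels = sorted(set(groups.values()))
    if len(levels) != 2:
        raise DataError("exactly two groups required")
    a_cols = [s for s in normalized.columns if groups.get(s) == levels[0]]
    b_cols = [s for s in normalized.columns if groups.get(s) == levels[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise DataError("each group needs n >= 2 samples")
    probes = endogenous_ids if endogenous_ids is not None \
        else list(normalized.index)
    A = normalized.loc[probes, a_cols].to_numpy(float)
    B = normalized.loc[probes, b_cols].to_numpy(float)
    log2fc = np.log2(A.mean(axis=1) + 1.0) - np.log2(B.mean(axis=1) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    zero_var = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var, 1.0, p)
    return pd.DataFrame({
        "probe": probes,
        "log2fc": log2fc,
        "t": t,
        "p": p,
        "group_high": np.where(log2fc >= 0, levels[0], levels[1]),
    }).set_index("probe")


def top_variance_transform(
    normalized: pd.DataFrame, k: int = 50
) -> pd.DataFrame:
    """log2(x+1) transform, keeping the k most-variable probes.

    Intended input to PCA-style ordination of miRNA profiles.
    """
    if k <= 0:
        raise DataError("k must be positive")
    if k > normalized.shape[0]:
        raise DataError(
            f"k={k} exceeds probe count {normalized.shape[0]}"
        )
    logged = np.log2(normalized.astype(float) + 1.0)
    variances = logged.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False, kind="stable").index[:k]
    return logged.loc[top]


@dataclass
class MirnaProfileResult:
    """Full result of the miRNA processing stage."""

    background_per_lane: np.ndarray
    normalized: pd.DataFrame
    abundant_probes: set[str]
    de_table: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def profile_mirna(
    mc: MirnaCounts,
    groups: dict[str, str] | None = None,
    abundance_threshold: float = 24.0,
    top_k: int = 50,
) -> MirnaProfileResult:
    """Run the whole miRNA stage: normalize, call abundant, test groups."""
    bg = background_threshold(mc)
    norm = normalize_counts(mc)
    endo = mc.endogenous_ids
    abundant = call_abundant(norm, endo, threshold=abundance_threshold)
    de = differential_mirna(norm, groups, endogenous_ids=endo) \
        if groups is not None else pd.DataFrame()
    return MirnaProfileResult(
        background_per_lane=bg,
        normalized=norm,
        abundant_probes=abundant,
        de_table=de,
        metadata={
            "abundance_threshold": abundance_threshold,
            "abundance_scale": "normalized_background_subtracted",
            "ordination_transform": "log2(count+1), top "
                                    f"{top_k} variance probes",
        },
    )
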