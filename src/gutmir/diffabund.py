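"""Differential abundance: baseline permutation tests with effect-size
categories, and the blocked permutation repeated-measures factorial ANOVA.

The repeated-measures design has two strains x three treatments (CON,
AMP+NEO, ERY) x two timepoints with the mouse as blocking factor: the only
exchangeable labels under the null are pre/post within a mouse. With two
timepoints the split-plot algebra reduces exactly: the treatment x time and
strain x treatment x time F-ratios of the full factorial equal the treatment
and strain x treatment F-ratios of a two-way ANOVA on per-mouse (post - pre)
differences, and a within-mouse pre/post swap is a sign flip of that mouse's
difference. The permutation null is therefore generated by independent sign
flips (2^n_mice arrangements, enumerated exhaustively when feasible).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import DataError, OtuTable, SampleMeta


# ---------------------------------------------------------------------------
# relative abundance / genus collapse
# ---------------------------------------------------------------------------

def to_relative(
    table: OtuTable, collapse_to_genus: bool = False
) -> pd.DataFrame:
    """Sample x taxon relative-abundance matrix (rows sum to 1).

    With ``collapse_to_genus``, OTU columns are pooled by their genus-level
    lineage key (family+genus; unresolved genera stay separate per parent
    clade).
    """
    counts = table.counts.astype(float)
    sums = counts.sum(axis=1)
    if (sums == 0).any():
        bad = table.sample_ids[int(np.argmax(sums == 0))]
        raise DataError(f"sample {bad!r} has zero total count")
    rel = counts / sums[:, None]
    if not collapse_to_genus:
        return pd.DataFrame(rel, index=table.sample_ids,
                            columns=table.otu_ids)
    keys = [l.genus_key() for l in table.lineages]
    df = pd.DataFrame(rel, index=table.sample_ids, columns=keys)
    return df.T.groupby(level=0, sort=True).sum().T


def genus_column(relabund: pd.DataFrame, genus: str) -> str:
    """Find the genus-collapsed column whose lineage key names ``genus``."""
    matches = [c for c in relabund.columns if c.endswith(f"g_{genus}")]
    if not matches:
        raise KeyError(f"genus {genus!r} not present in table")
    if len(matches) > 1:
        raise KeyError(f"genus {genus!r} ambiguous: {matches}")
    return matches[0]


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def permutation_ttest(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 100_000,
    seed: int = 0,
    alternative: str = "two_sided",
) -> float:
    """Two-sample permutation test on the difference in means.

    Exhaustive enumeration of group assignments when C(n_x+n_y, n_x) <=
    ``n_perm`` (exact p = count/total); Monte-Carlo with the +1 correction
    otherwise. Completely degenerate input (all values identical) gives p=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DataError("both groups need n >= 2")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    nx = len(x)
    n = len(pooled)
    obs = x.mean() - y.mean()
    tol = 1e-12 * max(1.0, abs(obs))

    def extreme(stat: np.ndarray) -> np.ndarray:
        if alternative == "two_sided":
            return np.abs(stat) >= abs(obs) - tol
        if alternative == "greater":
            return stat >= obs - tol
        if alternative == "less":
            return stat <= obs + tol
        raise ValueError(f"unknown alternative {alternative!r}")

    from math import comb
    total = comb(n, nx)
    if total <= n_perm:
        stats_all = np.empty(total)
        s_all = pooled.sum()
        for k, idx in enumerate(combinations(range(n), nx)):
            sx = pooled[list(idx)].sum()
            stats_all[k] = sx / nx - (s_all - sx) / (n - nx)
        return float(extreme(stats_all).mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = perm[:nx].mean() - perm[nx:].mean()
        count += bool(extreme(np.array([stat]))[0])
    return (1 + count) / (1 + n_perm)


def posthoc_paired_permutation_ttest(
    pre: np.ndarray,
    post: np.ndarray,
    n_perm: int = 100_000,
    seed: int = 0,
) -> float:
    """Paired permutation test: mean difference, null by per-pair sign flips.

    Exhaustive over all 2^n sign patterns when that is <= ``n_perm``
    (exact p), Monte-Carlo with +1 correction otherwise.
    """
    d = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    n = len(d)
    if n < 2:
        raise DataError("need >= 2 pairs")
    if np.all(d == 0):
        return 1.0
    obs = abs(d.mean())
    tol = 1e-12 * max(1.0, obs)
    if 2 ** n <= n_perm:
        signs = np.array(
            [[1 if (k >> i) & 1 else -1 for i in range(n)]
             for k in range(2 ** n)], dtype=float)
        stats_all = np.abs(signs @ d) / n
        return float((stats_all >= obs - tol).mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    stats_all = np.abs(signs @ d) / n
    return float((1 + (stats_all >= obs - tol).sum()) / (1 + n_perm))


def bh_fdr(p_values: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# baseline strain comparison with effect categories
# ---------------------------------------------------------------------------

CATEGORIES = ("up3", "up2", "up1", "presence", "only_A", "only_B", "none")


def classify_effect(
    median_a: float,
    median_b: float,
    present_a: bool,
    present_b: bool,
    significant_presence_shift: bool = False,
) -> tuple[str, str]:
    """Effect-size category for a baseline strain difference.

    Categories follow the convention: taxon present in one strain only ->
    only_X; median difference > 10 percentage points -> up3; > 1 -> up2;
    > 0 -> up1; equal medians with a presence shift -> presence. Returns
    (category, direction) where direction names the favoured strain
    ('A', 'B' or ''). Ties resolve to the weaker category.
    """
    if present_a and not present_b:
        return "only_A", "A"
    if present_b and not present_a:
        return "only_B", "B"
    if not present_a and not present_b:
        return "none", ""
    delta = median_b - median_a
    direction = "B" if delta > 0 else ("A" if delta < 0 else "")
    mag = abs(delta)
    if mag > 0.10:
        return "up3", direction
    if mag > 0.01:
        return "up2", direction
    if mag > 0:
        return "up1", direction
    if significant_presence_shift:
        return "presence", direction
    return "none", direction


@dataclass
class TaxonTestResult:
    taxon: str
    median_A: float
    median_B: float
    effect_category: str
    direction: str
    p: float
    q: float = float("nan")


def baseline_strain_tests(
    relabund: pd.DataFrame,
    strain_of: dict[str, str],
    n_perm: int = 100_000,
    seed: int = 0,
) -> list[TaxonTestResult]:
    """Per-taxon baseline permutation tests between strains with categories.

    Strain A/B are the sorted strain labels. BH correction across all taxa.
    """
    strains = sorted({strain_of[s] for s in relabund.index})
    if len(strains) != 2:
        raise DataError("exactly two strains required")
    mask_a = np.array([strain_of[s] == strains[0] for s in relabund.index])
    rng = np.random.default_rng(seed)
    results = []
    for taxon in relabund.columns:
        v = relabund[taxon].to_numpy(float)
        x, y = v[mask_a], v[~mask_a]
        p = permutation_ttest(x, y, n_perm=n_perm,
                              seed=int(rng.integers(2 ** 31)))
        cat, direction = classify_effect(
            float(np.median(x)), float(np.median(y)),
            present_a=bool((x > 0).any()), present_b=bool((y > 0).any()),
        )
        results.append(TaxonTestResult(
            taxon=str(taxon), median_A=float(np.median(x)),
            median_B=float(np.median(y)), effect_category=cat,
            direction=direction, p=p,
        ))
    qs = bh_fdr([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# blocked repeated-measures permutation ANOVA
# ---------------------------------------------------------------------------

@dataclass
class RmAnovaResult:
    taxon: str
    f_treatment_time: float
    p_treatment_time: float
    f_strain_treatment_time: float
    p_strain_treatment_time: float
    q_treatment_time: float = float("nan")
    q_strain_treatment_time: float = float("nan")


def _design_matrices(strain: np.ndarray, treatment: np.ndarray):
    """Projection matrices for the two-way ANOVA on per-mouse differences.

    Models (on the difference scale): strain only; strain + treatment
    (additive); full strain*treatment. Treatment-effect F uses Type-II sums of
    squares (treatment after strain, ignoring the interaction); the
    interaction F compares full vs additive. Returns residual-projector
    triples plus degrees of freedom.
    """
    n = len(strain)
    s_levels, s_idx = np.unique(strain, return_inverse=True)
    t_levels, t_idx = np.unique(treatment, return_inverse=True)

    def dummies(idx, k):
        Z = np.zeros((n, k))
        Z[np.arange(n), idx] = 1.0
        return Z[:, 1:]  # drop first level; intercept added separately

    one = np.ones((n, 1))
    Xs = np.hstack([one, dummies(s_idx, len(s_levels))])
    Xst = np.hstack([Xs, dummies(t_idx, len(t_levels))])
    inter = []
    for a in range(1, len(s_levels)):
        for b in range(1, len(t_levels)):
            inter.append(((s_idx == a) & (t_idx == b)).astype(float))
    Xfull = np.hstack([Xst] + ([np.column_stack(inter)] if inter else []))

    def resid_projector(X):
        Q, _ = np.linalg.qr(X)
        return np.eye(n) - Q @ Q.T, X.shape[1]

    Rs, ps_ = resid_projector(Xs)
    Rst, pst = resid_projector(Xst)
    Rf, pf = resid_projector(Xfull)
    df_t = pst - ps_
    df_i = pf - pst
    df_e = n - pf
    if df_e <= 0:
        raise DataError("no residual degrees of freedom")
    return (Rs, Rst, Rf), (df_t, df_i, df_e)


def _f_stats(D: np.ndarray, projectors, dfs) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized F-ratios for rows of D (permutations x mice)."""
    Rs, Rst, Rf = projectors
    df_t, df_i, df_e = dfs
    rss_s = np.einsum("pi,pi->p", D @ Rs, D)
    rss_st = np.einsum("pi,pi->p", D @ Rst, D)
    rss_f = np.einsum("pi,pi->p", D @ Rf, D)
    with np.errstate(divide="ignore", invalid="ignore"):
        mse = rss_f / df_e
        f_treat = ((rss_s - rss_st) / df_t) / mse
        f_inter = ((rss_st - rss_f) / df_i) / mse
    return np.nan_to_num(f_treat), np.nan_to_num(f_inter)


def blocked_rm_permutation_anova(
    relabund: pd.DataFrame,
    meta: list[SampleMeta],
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[RmAnovaResult]:
    """Permutation-based repeated-measures factorial ANOVA per taxon.

    All treatment groups including controls enter the fit. Mice are blocks:
    the null distribution swaps (or not) the pre/post pair independently
    within each mouse, i.e. sign-flips the per-mouse difference. Exhaustive
    over 2^n_mice arrangements when that is <= ``n_perm``; Monte-Carlo with
    the +1 correction otherwise. BH correction across taxa per term.
    """
    by_mouse: dict[str, dict[str, str]] = {}
    attrs: dict[str, tuple[str, str]] = {}
    for m in meta:
        by_mouse.setdefault(m.mouse_id, {})[m.timepoint] = m.sample_id
        attrs[m.mouse_id] = (m.strain, m.treatment)
    mice = sorted(by_mouse)
    for mouse in mice:
        tp = by_mouse[mouse]
        if "pre" not in tp or "post" not in tp:
            raise DataError(f"mouse {mouse!r} is missing a timepoint")
    strain = np.array([attrs[m][0] for m in mice])
    treatment = np.array([attrs[m][1] for m in mice])
    n_mice = len(mice)
    projectors, dfs = _design_matrices(strain, treatment)

    exhaustive = 2 ** n_mice <= n_perm
    if exhaustive:
        signs = np.array(
            [[1.0 if (k >> i) & 1 else -1.0 for i in range(n_mice)]
             for k in range(2 ** n_mice)])
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_mice))

    results = []
    for taxon in relabund.columns:
        pre = np.array([relabund.loc[by_mouse[m]["pre"], taxon] for m in mice],
                       dtype=float)
        post = np.array([relabund.loc[by_mouse[m]["post"], taxon]
                         for m in mice], dtype=float)
        d = post - pre
        f_t_obs, f_i_obs = _f_stats(d[None, :], projectors, dfs)
        f_t_obs, f_i_obs = float(f_t_obs[0]), float(f_i_obs[0])
        D = signs * d[None, :]
        f_t, f_i = _f_stats(D, projectors, dfs)
        tol = 1e-12
        if exhaustive:
            p_t = float((f_t >= f_t_obs - tol).mean())
            p_i = float((f_i >= f_i_obs - tol).mean())
        else:
            p_t = (1 + int((f_t >= f_t_obs - tol).sum())) / (1 + len(signs))
            p_i = (1 + int((f_i >= f_i_obs - tol).sum())) / (1 + len(signs))
        if np.all(d == 0):
            p_t = p_i = 1.0
        results.append(RmAnovaResult(
            taxon=str(taxon),
            f_treatment_time=f_t_obs, p_treatment_time=p_t,
            f_strain_treatment_time=f_i_obs, p_strain_treatment_time=p_i,
        ))
    q_t = bh_fdr([r.p_treatment_time for r in results])
    q_i = bh_fdr([r.p_strain_treatment_time for r in results])
    for r, qt, qi in zip(results, q_t, q_i):
        r.q_treatment_time = float(qt)
        r.q_strain_treatment_time = float(qi)
    return results


def posthoc_treatment_tests(
    relabund: pd.DataFrame,
    meta: list[SampleMeta],
    taxa: list[str] | None = None,
    n_perm: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Post hoc paired pre/post tests within each strain x treatment cell."""
    taxa = list(relabund.columns) if taxa is None else taxa
    by_mouse: dict[str, dict[str, str]] = {}
    attrs: dict[str, tuple[str, str]] = {}
    for m in meta:
        by_mouse.setdefault(m.mouse_id, {})[m.timepoint] = m.sample_id
        attrs[m.mouse_id] = (m.strain, m.treatment)
    cells = sorted(set(attrs.values()))
    rng = np.random.default_rng(seed)
    rows = []
    for strain, treatment in cells:
        mice = [m for m in sorted(by_mouse) if attrs[m] == (strain, treatment)]
        for taxon in taxa:
            pre = np.array([relabund.loc[by_mouse[m]["pre"], taxon]
                            for m in mice], dtype=float)
            post = np.array([relabund.loc[by_mouse[m]["post"], taxon]
                             for m in mice], dtype=float)
            p = posthoc_paired_permutation_ttest(
                pre, post, n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
            rows.append({
                "strain": strain, "treatment": treatment, "taxon": taxon,
                "median_change": float(np.median(post - pre)), "p": p,
            })
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    return df
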