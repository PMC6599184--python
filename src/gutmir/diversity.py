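"""Rarefaction, alpha diversity, Bray-Curtis distances, PCoA and PERMANOVA.

The multiple-rarefaction scheme: each sample is rarefied repeatedly at a fixed
depth; alpha diversity is the mean over rarefaction replicates, and ordination
aggregates 100 independent rarefaction+PCoA runs into per-coordinate medians
and interquartile ranges (with per-axis sign alignment to the first run, since
eigenvector sign is arbitrary).

Shannon uses the natural log. Permutation p-values carry the +1 correction
(never zero, unbiased under the null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError, OtuTable


def rarefy(
    counts: np.ndarray, depth: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    Multivariate hypergeometric draw: the output always sums exactly to
    ``depth``. Raises when the sample holds fewer reads than requested
    (callers exclude such samples explicitly, never silently).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    c = np.asarray(counts)
    if (c < 0).any():
        raise DataError("negative counts")
    total = int(c.sum())
    if depth > total:
        raise DataError(f"depth {depth} exceeds sample total {total}")
    if depth == total:
        return c.astype(np.int64).copy()
    return rng.multivariate_hypergeometric(c.astype(np.int64), depth)


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1*(F1-1) / (2*(F2+1)).

    F1/F2 are singleton/doubleton counts. All-zero input returns 0.
    """
    c = np.asarray(counts)
    if (c < 0).any():
        raise DataError("negative counts")
    s_obs = int((c > 0).sum())
    if s_obs == 0:
        return 0.0
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts: np.ndarray) -> float:
    """Shannon index H' = -sum p_i ln p_i (natural log, nonzero terms)."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise DataError("negative counts")
    total = c.sum()
    if total <= 0:
        raise DataError("zero-sum count vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def braycurtis(x: np.ndarray, y: np.ndarray, binary: bool = False) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y); binary uses presence."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise DataError("vectors differ in length")
    if binary:
        a = (a > 0).astype(float)
        b = (b > 0).astype(float)
    denom = (a + b).sum()
    if denom == 0:
        raise DataError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(a - b).sum() / denom)


def distance_matrix(
    counts: np.ndarray, metric: str = "braycurtis"
) -> np.ndarray:
    """Pairwise sample distances. Metrics: braycurtis, binary-braycurtis."""
    binary = metric == "binary-braycurtis"
    if metric not in ("braycurtis", "binary-braycurtis"):
        raise ValueError(f"unknown metric {metric!r}")
    n = counts.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = braycurtis(counts[i], counts[j], binary=binary)
    return D


@dataclass
class PcoaResult:
    coordinates: np.ndarray  # (n_samples, n_axes), descending eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives kept)
    pct_variance: np.ndarray  # per positive axis, % of positive-eigenvalue sum


def pcoa(distance: np.ndarray) -> PcoaResult:
    """Principal coordinate analysis by Gower double-centering.

    Eigendecomposition of -1/2 * J D^2 J. Negative eigenvalues (non-Euclidean
    metrics) are reported but excluded from the percent-variance denominator;
    coordinates are returned for positive axes only. Axis signs are fixed so
    the largest-magnitude loading on each axis is positive (deterministic).
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DataError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise DataError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * abs(evals).max(initial=1.0))
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    # deterministic sign convention
    for k in range(coords.shape[1]):
        m = np.argmax(np.abs(coords[:, k]))
        if coords[m, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = evals[pos].sum()
    pct = (100.0 * evals[pos] / pos_sum) if pos_sum > 0 else evals[pos]
    return PcoaResult(coordinates=coords, eigenvalues=evals,
                      pct_variance=pct)


@dataclass
class OrdinationSummary:
    """Aggregate of PCoA over repeated rarefactions."""

    sample_ids: list[str]
    median_coordinates: np.ndarray  # (n_samples, n_axes)
    iqr_coordinates: np.ndarray
    median_pct_variance: np.ndarray
    metric: str
    depth: int
    n_rarefactions: int
    excluded_samples: list[str]


def multi_rarefaction_pcoa(
    table: OtuTable,
    depth: int = 11353,
    n_rarefactions: int = 100,
    metric: str = "braycurtis",
    seed: int = 0,
    n_axes: int = 2,
) -> OrdinationSummary:
    """PCoA on repeated random rarefactions, aggregated by medians.

    Each rarefaction run rarefies every sample to ``depth``, computes the
    distance matrix and a PCoA; axes of later runs are sign-aligned to the
    first run (flip when the correlation with the reference axis is negative)
    before per-coordinate medians/IQRs and the median percent variance are
    taken. Samples below ``depth`` total reads are excluded and listed.
    """
    totals = table.counts.sum(axis=1)
    keep = totals >= depth
    excluded = [s for s, k in zip(table.sample_ids, keep) if not k]
    counts = table.counts[keep]
    sample_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    if counts.shape[0] < 3:
        raise DataError("fewer than 3 samples at or above rarefaction depth")
    rng = np.random.default_rng(seed)

    coords_runs = []
    pct_runs = []
    ref = None
    for _ in range(n_rarefactions):
        rare = np.stack([rarefy(c, depth, rng) for c in counts])
        res = pcoa(distance_matrix(rare, metric=metric))
        k = min(n_axes, res.coordinates.shape[1])
        C = res.coordinates[:, :k]
        P = res.pct_variance[:k]
        if C.shape[1] < n_axes:  # pad degenerate runs
            C = np.pad(C, ((0, 0), (0, n_axes - C.shape[1])))
            P = np.pad(P, (0, n_axes - P.shape[0]))
        if ref is None:
            ref = C.copy()
        else:
            for a in range(n_axes):
                if np.dot(C[:, a], ref[:, a]) < 0:
                    C[:, a] = -C[:, a]
        coords_runs.append(C)
        pct_runs.append(P)

    stack = np.stack(coords_runs)  # (runs, samples, axes)
    med = np.median(stack, axis=0)
    iqr = np.percentile(stack, 75, axis=0) - np.percentile(stack, 25, axis=0)
    return OrdinationSummary(
        sample_ids=sample_ids,
        median_coordinates=med,
        iqr_coordinates=iqr,
        median_pct_variance=np.median(np.stack(pct_runs), axis=0),
        metric=metric,
        depth=depth,
        n_rarefactions=n_rarefactions,
        excluded_samples=excluded,
    )


def permanova(
    distance: np.ndarray,
    labels: np.ndarray | list,
    n_perm: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F from among/within sums of squared distances; the p-value is
    (1 + #{permuted F >= observed}) / (1 + n_perm) over random label
    permutations.
    """
    D = np.asarray(distance, dtype=float)
    labels = np.asarray(labels)
    n = D.shape[0]
    if labels.shape[0] != n:
        raise DataError("label length does not match distance matrix")
    groups, inv = np.unique(labels, return_inverse=True)
    a = len(groups)
    if a < 2:
        raise DataError("PERMANOVA needs >= 2 groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        raise DataError("every group needs >= 2 samples")
    D2 = D ** 2
    ss_total = D2[np.triu_indices(n, 1)].sum() / n

    def pseudo_f(assign: np.ndarray) -> float:
        ss_within = 0.0
        for g in range(a):
            idx = np.flatnonzero(assign == g)
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(inv)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(inv)) >= f_obs - 1e-12:
            count += 1
    return float(f_obs), (1 + count) / (1 + n_perm)


def alpha_diversity_curve(
    table: OtuTable,
    depths: list[int] | None = None,
    n_rarefactions: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean Chao1/Shannon over rarefaction replicates per sample per depth.

    The default depth grid is {1000, 2000, 5000, min sample depth} clipped to
    the minimum sample depth. Samples below a depth are excluded at that
    depth.
    """
    totals = table.counts.sum(axis=1)
    min_depth = int(totals.min())
    if depths is None:
        depths = sorted({d for d in (1000, 2000, 5000, min_depth)
                         if d <= min_depth})
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        for i, sid in enumerate(table.sample_ids):
            if totals[i] < depth:
                continue
            c_vals, s_vals = [], []
            for _ in range(n_rarefactions):
                v = rarefy(table.counts[i], depth, rng)
                c_vals.append(chao1(v))
                s_vals.append(shannon(v))
            rows.append({
                "sample_id": sid, "depth": depth,
                "chao1": float(np.mean(c_vals)),
                "shannon": float(np.mean(s_vals)),
            })
    return pd.DataFrame(rows)


def alpha_strain_tests(
    curve: pd.DataFrame, strain_of: dict[str, str]
) -> pd.DataFrame:
    """Welch t-test of each alpha metric between strains at each depth."""
    rows = []
    for depth, sub in curve.groupby("depth"):
        strains = sub["sample_id"].map(strain_of)
        levels = sorted(strains.dropna().unique())
        if len(levels) != 2:
            raise DataError("exactly two strains required")
        for metric in ("chao1", "shannon"):
            x = sub.loc[strains == levels[0], metric].to_numpy(float)
            y = sub.loc[strains == levels[1], metric].to_numpy(float)
            t, p = stats.ttest_ind(x, y, equal_var=False)
            rows.append({"depth": depth, "metric": metric,
                         "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)
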