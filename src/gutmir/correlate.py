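"""Correlate fecal miRNA abundance with predicted target taxa.

Spearman rank correlation with average ranks for ties; p from the
t-approximation with n-2 degrees of freedom, replaced by an exact
permutation distribution of rho for small n (<= 9). Reports mirror the
target-table layout: one row per (miRNA, taxon/OTU) pair with rho, p, the
supporting alignment and its annotation; significance is flagged at raw
p < alpha (as in the emulated analysis) with a BH-adjusted column alongside.
"""

from __future__ import annotations

from itertools import permutations as _permutations

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError
from .targets import CorrelationTarget

EXACT_N_MAX = 9


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and p; exact permutation p for n <= 9.

    Zero-variance input (constant vector) is undefined: returns (nan, nan)
    so callers can flag and exclude the pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("vectors differ in length")
    n = len(x)
    if n < 4:
        raise DataError("need n >= 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_N_MAX:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        obs = abs(rx_c @ ry_c)
        count = 0
        total = 0
        for perm in _permutations(range(n)):
            total += 1
            if abs(rx_c[list(perm)] @ ry_c) >= obs - 1e-12 * denom:
                count += 1
        return rho, count / total
    t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(1.0, p))


def correlate_targets(
    mirna_counts: pd.DataFrame,
    relabund_genus: pd.DataFrame,
    relabund_otu: pd.DataFrame,
    targets: list[CorrelationTarget],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlations for every predicted (miRNA, taxon) pair.

    ``mirna_counts`` is probe x sample (normalized); abundance tables are
    sample x taxon. Samples are matched by id intersection (>= 4 required).
    Genus-level targets look up genus columns (matched by name or by a
    genus-level lineage key suffix); OTU-level targets use OTU columns.
    Pairs hitting a taxon absent from the tables, or with zero variance, are
    flagged in the ``status`` column and excluded from significance counts.
    """
    samples = sorted(set(mirna_counts.columns) & set(relabund_genus.index)
                     & set(relabund_otu.index))
    if len(samples) < 4:
        raise DataError("fewer than 4 matched samples between tables")

    def genus_col(key: str) -> str | None:
        if key in relabund_genus.columns:
            return key
        matches = [c for c in relabund_genus.columns
                   if str(c).endswith(f"g_{key}")]
        return matches[0] if len(matches) == 1 else None

    seen: set[tuple[str, str]] = set()
    rows = []
    for t in targets:
        if (t.mirna_id, t.taxon_key) in seen:
            continue  # one row per (miRNA, taxon) pair; keep first (best hit)
        seen.add((t.mirna_id, t.taxon_key))
        if t.mirna_id not in mirna_counts.index:
            continue
        x = mirna_counts.loc[t.mirna_id, samples].to_numpy(float)
        if t.level == "otu":
            if t.taxon_key not in relabund_otu.columns:
                rows.append(_row(t, np.nan, np.nan, "taxon_absent"))
                continue
            y = relabund_otu.loc[samples, t.taxon_key].to_numpy(float)
        else:
            col = genus_col(t.taxon_key)
            if col is None:
                rows.append(_row(t, np.nan, np.nan, "taxon_absent"))
                continue
            y = relabund_genus.loc[samples, col].to_numpy(float)
        rho, p = spearman(x, y)
        status = "ok" if np.isfinite(rho) else "zero_variance"
        rows.append(_row(t, rho, p, status))

    df = pd.DataFrame(rows, columns=[
        "mirna_id", "taxon_key", "level", "gene_id", "annotation_id",
        "bit_score", "evalue", "spearman_rho", "p", "status",
    ])
    df["significant"] = (df["status"] == "ok") & (df["p"] < alpha)
    ok = df["status"] == "ok"
    df["q_bh"] = np.nan
    if ok.any():
        from .diffabund import bh_fdr
        df.loc[ok, "q_bh"] = bh_fdr(df.loc[ok, "p"].to_numpy())
    df.attrs["n_samples"] = len(samples)
    df.attrs["n_significant"] = int(df["significant"].sum())
    return df


def _row(t: CorrelationTarget, rho: float, p: float, status: str) -> dict:
    return {
        "mirna_id": t.mirna_id, "taxon_key": t.taxon_key, "level": t.level,
        "gene_id": t.gene_id, "annotation_id": t.annotation_id,
        "bit_score": t.bit_score, "evalue": t.evalue,
        "spearman_rho": rho, "p": p, "status": status,
    }
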