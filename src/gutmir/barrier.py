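"""Gut-barrier physiology: FITC permeability, qPCR ddCt, and correlations.

Intestinal permeability is reported as serum FITC concentration normalized to
body weight, (mg/ml / g) x 10^4. To compare across strains with different
baselines, values from treated mice are z-scored against the strain's control
group (mean and sample SD of controls). Relative gene expression uses the
comparative ddCt method with two reference genes (their Cts combined by
arithmetic mean, i.e. a geometric mean on the expression scale) and a
control-group calibrator: RQ = 2^(-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError
from .diffabund import bh_fdr, permutation_ttest


@dataclass(frozen=True)
class PermeabilityRecord:
    mouse_id: str
    strain: str
    treatment: str
    serum_fitc: float  # mg/ml
    body_weight: float  # g
    fitc_norm: float  # (mg/ml/g) x 10^4
    z: float | None  # vs strain control group; None for controls


@dataclass(frozen=True)
class QpcrRecord:
    sample_id: str
    target_gene: str
    ct_target: float
    ct_ref1: float
    ct_ref2: float
    delta_ct: float
    delta_delta_ct: float
    rq: float


def fitc_normalize(serum_fitc: float, body_weight: float) -> float:
    """(serum FITC mg/ml / body weight g) x 10^4."""
    if body_weight <= 0:
        raise DataError("body weight must be positive")
    if serum_fitc < 0:
        raise DataError("serum FITC cannot be negative")
    return serum_fitc / body_weight * 1e4


def fitc_zscore(values: np.ndarray, control_values: np.ndarray) -> np.ndarray:
    """z = (x - mean of controls) / sample SD of controls."""
    ctrl = np.asarray(control_values, dtype=float)
    if len(ctrl) < 2:
        raise DataError(">= 2 control values required")
    sd = ctrl.std(ddof=1)
    if sd == 0:
        raise DataError("control group has zero variance")
    return (np.asarray(values, dtype=float) - ctrl.mean()) / sd


def permeability_records(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize and z-score a permeability table.

    Input columns: mouse_id, strain, treatment, serum_fitc, body_weight.
    Adds fitc_norm for every mouse and z for non-control mice (z-scored
    against the same strain's CON group).
    """
    out = df.copy()
    out["fitc_norm"] = [
        fitc_normalize(f, w)
        for f, w in zip(out["serum_fitc"], out["body_weight"])
    ]
    out["z"] = np.nan
    for strain, sub in out.groupby("strain"):
        ctrl = sub.loc[sub["treatment"] == "CON", "fitc_norm"].to_numpy()
        treated = sub.index[sub["treatment"] != "CON"]
        # z-scores need a control reference; strains lacking one keep NaN
        if len(treated) and len(ctrl) >= 2:
            out.loc[treated, "z"] = fitc_zscore(
                out.loc[treated, "fitc_norm"].to_numpy(), ctrl)
    return out


# ---------------------------------------------------------------------------
# permutation ANOVA for permeability
# ---------------------------------------------------------------------------

def permeability_anova(
    records: pd.DataFrame,
    n_perm: int = 100_000,
    seed: int = 0,
) -> dict:
    """Two-way (strain x treatment) permutation ANOVA on fitc_norm.

    Main-effect F-ratios get their null by permuting that factor's labels;
    the interaction uses permutation of residuals under the additive model
    (Freedman-Lane). Pairwise treatment contrasts within strain use the
    two-sample permutation t-test. All p-values carry the +1 correction.
    """
    y = records["fitc_norm"].to_numpy(float)
    strain = records["strain"].to_numpy()
    treatment = records["treatment"].to_numpy()
    cells = pd.crosstab(records["strain"], records["treatment"])
    if (cells.values == 0).any():
        empty = [(s, t) for s in cells.index for t in cells.columns
                 if cells.loc[s, t] == 0]
        raise DataError(f"empty design cells: {empty}")
    n = len(y)
    rng = np.random.default_rng(seed)

    def projector(X):
        Q, _ = np.linalg.qr(X)
        return Q @ Q.T, X.shape[1]

    def dummies(labels):
        levels, idx = np.unique(labels, return_inverse=True)
        Z = np.zeros((n, len(levels)))
        Z[np.arange(n), idx] = 1.0
        return Z[:, 1:]

    one = np.ones((n, 1))
    Ds, Dt = dummies(strain), dummies(treatment)
    inter = np.column_stack([
        Ds[:, i] * Dt[:, j]
        for i in range(Ds.shape[1]) for j in range(Dt.shape[1])
    ]) if Ds.shape[1] and Dt.shape[1] else np.empty((n, 0))
    X_add = np.hstack([one, Ds, Dt])
    X_full = np.hstack([X_add, inter])

    P_add, p_add = projector(X_add)
    P_full, p_full = projector(X_full)
    P_s, p_s = projector(np.hstack([one, Ds]))
    P_t, p_t = projector(np.hstack([one, Dt]))
    df_e = n - p_full
    if df_e <= 0:
        raise DataError("no residual degrees of freedom")

    def f_terms(v):
        rss_full = v @ v - v @ P_full @ v
        mse = rss_full / df_e
        rss_add = v @ v - v @ P_add @ v
        rss_s = v @ v - v @ P_s @ v   # model without treatment
        rss_t = v @ v - v @ P_t @ v   # model without strain
        f_strain = ((rss_t - rss_add) / (p_add - p_t)) / mse
        f_treat = ((rss_s - rss_add) / (p_add - p_s)) / mse
        f_int = ((rss_add - rss_full) / (p_full - p_add)) / mse
        return f_strain, f_treat, f_int

    f_s_obs, f_t_obs, f_i_obs = f_terms(y)

    count_s = count_t = count_i = 0
    resid_add = y - P_add @ y
    fitted_add = P_add @ y
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_s, _, _ = f_terms(y[perm])
        perm2 = rng.permutation(n)
        _, f_t, _ = f_terms(y[perm2])
        y_star = fitted_add + resid_add[rng.permutation(n)]
        _, _, f_i = f_terms(y_star)
        count_s += f_s >= f_s_obs - 1e-12
        count_t += f_t >= f_t_obs - 1e-12
        count_i += f_i >= f_i_obs - 1e-12

    result = {
        "f_strain": float(f_s_obs), "p_strain": (1 + count_s) / (1 + n_perm),
        "f_treatment": float(f_t_obs),
        "p_treatment": (1 + count_t) / (1 + n_perm),
        "f_interaction": float(f_i_obs),
        "p_interaction": (1 + count_i) / (1 + n_perm),
    }

    pairwise = []
    for s in np.unique(strain):
        trts = sorted(np.unique(treatment[strain == s]))
        for i in range(len(trts)):
            for j in range(i + 1, len(trts)):
                a = y[(strain == s) & (treatment == trts[i])]
                b = y[(strain == s) & (treatment == trts[j])]
                p = permutation_ttest(a, b, n_perm=min(n_perm, 10_000),
                                      seed=int(rng.integers(2 ** 31)))
                pairwise.append({"strain": s, "a": trts[i], "b": trts[j],
                                 "p": p})
    result["pairwise"] = pd.DataFrame(pairwise)
    return result


# ---------------------------------------------------------------------------
# ddCt
# ---------------------------------------------------------------------------

def ddct(
    ct_target: float,
    ct_refs: tuple[float, float],
    calibrator_delta_ct: float,
) -> tuple[float, float, float]:
    """Comparative ddCt: returns (delta_ct, delta_delta_ct, rq).

    delta_ct = ct_target - mean(ct_refs); delta_delta_ct subtracts the
    calibrator group's mean delta_ct; RQ = 2^(-delta_delta_ct).
    """
    vals = (ct_target, *ct_refs, calibrator_delta_ct)
    if not all(np.isfinite(v) for v in vals):
        raise DataError("Ct values must be finite")
    delta = ct_target - (ct_refs[0] + ct_refs[1]) / 2.0
    dd = delta - calibrator_delta_ct
    return delta, dd, float(2.0 ** (-dd))


def ddct_table(
    qpcr: pd.DataFrame,
    calibrator_mask: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Apply ddCt per target gene with a control-group calibrator.

    ``qpcr`` columns: sample_id, target_gene, ct_target, ct_ref1, ct_ref2
    (plus any grouping columns, which are preserved). The calibrator for each
    gene is the mean delta-Ct over ``calibrator_mask`` rows (default: rows
    with treatment == 'CON' when a treatment column exists, else all rows).
    """
    df = qpcr.copy()
    df["delta_ct"] = df["ct_target"] - (df["ct_ref1"] + df["ct_ref2"]) / 2.0
    if calibrator_mask is None:
        if "treatment" in df.columns:
            calibrator_mask = (df["treatment"] == "CON").to_numpy()
        else:
            calibrator_mask = np.ones(len(df), dtype=bool)
    calibrator_mask = np.asarray(calibrator_mask, dtype=bool)
    out = []
    for gene, sub in df.groupby("target_gene", sort=False):
        cal = sub.loc[calibrator_mask[sub.index.to_numpy()]] \
            if len(calibrator_mask) == len(df) else sub
        cal_mean = float(cal["delta_ct"].mean())
        block = sub.copy()
        block["delta_delta_ct"] = block["delta_ct"] - cal_mean
        block["rq"] = 2.0 ** (-block["delta_delta_ct"])
        out.append(block)
    return pd.concat(out).loc[df.index]


def expression_tests(
    rq_table: pd.DataFrame,
    group_col: str = "treatment",
    control: str = "CON",
    mann_whitney_genes: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-gene treated-vs-control tests on RQ values.

    Unpaired t-test by default; genes in ``mann_whitney_genes`` use the
    Mann-Whitney U (exact for n <= 8 without ties, normal approximation with
    tie correction otherwise). Identical groups give p = 1.
    """
    rows = []
    for gene, sub in rq_table.groupby("target_gene", sort=False):
        ctrl = sub.loc[sub[group_col] == control, "rq"].to_numpy(float)
        for level in sorted(set(sub[group_col]) - {control}):
            x = sub.loc[sub[group_col] == level, "rq"].to_numpy(float)
            if len(x) < 2 or len(ctrl) < 2:
                raise DataError(f"group below n=2 for gene {gene!r}")
            pooled = np.concatenate([x, ctrl])
            if np.ptp(pooled) == 0:
                p, method = 1.0, "degenerate"
            elif gene in mann_whitney_genes:
                small = max(len(x), len(ctrl)) <= 8
                has_ties = len(np.unique(pooled)) < len(pooled)
                method_name = "exact" if small and not has_ties \
                    else "asymptotic"
                _, p = stats.mannwhitneyu(x, ctrl, alternative="two-sided",
                                          method=method_name)
                method = f"mannwhitney_{method_name}"
            else:
                _, p = stats.ttest_ind(x, ctrl, equal_var=False)
                method = "t_test"
            rows.append({"target_gene": gene, "group": level,
                         "vs": control, "p": float(p), "method": method})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlation battery
# ---------------------------------------------------------------------------

def barrier_correlations(
    records: pd.DataFrame,
    relabund: pd.DataFrame | None = None,
    targeted_taxa: list[str] | None = None,
    rq_table: pd.DataFrame | None = None,
) -> dict:
    """Taxa<->FITC-z (Spearman + BH over the targeted list),
    expression<->FITC (Pearson), expression<->taxa (Spearman).

    ``records`` must carry mouse_id and z (from permeability_records);
    abundance rows are matched to mice by index. Taxa missing from the
    abundance table are listed under 'skipped'. Constant vectors are excluded
    with a status flag.
    """
    from .correlate import spearman as _spearman
    out: dict = {"skipped": []}
    treated = records.dropna(subset=["z"])

    if relabund is not None and targeted_taxa:
        rows = []
        for taxon in targeted_taxa:
            if taxon not in relabund.columns:
                out["skipped"].append(taxon)
                continue
            mice = [m for m in treated["mouse_id"] if m in relabund.index]
            z = treated.set_index("mouse_id").loc[mice, "z"].to_numpy(float)
            v = relabund.loc[mice, taxon].to_numpy(float)
            if len(mice) < 4:
                raise DataError("fewer than 4 matched mice")
            rho, p = _spearman(z, v)
            status = "ok" if np.isfinite(rho) else "zero_variance"
            rows.append({"taxon": taxon, "spearman_rho": rho, "p": p,
                         "status": status})
        taxa_df = pd.DataFrame(rows)
        if len(taxa_df):
            ok = taxa_df["status"] == "ok"
            taxa_df["q_bh"] = np.nan
            if ok.any():
                taxa_df.loc[ok, "q_bh"] = bh_fdr(taxa_df.loc[ok, "p"])
        out["taxa_vs_fitc"] = taxa_df

    if rq_table is not None:
        zmap = treated.set_index("mouse_id")["z"]
        rows = []
        srows = []
        for gene, sub in rq_table.groupby("target_gene", sort=False):
            sub = sub[sub["sample_id"].isin(zmap.index)]
            if len(sub) < 4:
                continue
            rq = sub["rq"].to_numpy(float)
            z = zmap.loc[sub["sample_id"]].to_numpy(float)
            if np.ptp(rq) == 0:
                rows.append({"target_gene": gene, "pearson_r": np.nan,
                             "p": np.nan, "status": "zero_variance"})
                continue
            r, p = stats.pearsonr(rq, z)
            rho, sp = _spearman(rq, z)
            rows.append({"target_gene": gene, "pearson_r": float(r),
                         "p": float(p), "spearman_rho": rho,
                         "spearman_p": sp, "status": "ok"})
            if relabund is not None and targeted_taxa:
                mice = [m for m in sub["sample_id"] if m in relabund.index]
                for taxon in targeted_taxa:
                    if taxon not in relabund.columns:
                        continue
                    v = relabund.loc[mice, taxon].to_numpy(float)
                    rq_m = sub.set_index("sample_id").loc[mice, "rq"] \
                        .to_numpy(float)
                    rho2, p2 = _spearman(rq_m, v)
                    srows.append({"target_gene": gene, "taxon": taxon,
                                  "spearman_rho": rho2, "p": p2})
        out["expression_vs_fitc"] = pd.DataFrame(rows)
        out["expression_vs_taxa"] = pd.DataFrame(srows)
    return out
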