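"""Group comparisons, biomarker mixed models, effect sizes and mediation.

Group differences in BAG use non-parametric tests (the measure is skewed
and heteroscedastic in carriers): an omnibus Kruskal-Wallis test followed
by pairwise Wilcoxon rank-sum tests with Benjamini-Hochberg FDR
adjustment, plus a mean-centered Levene check of variance homogeneity.

Biomarker associations use linear mixed models with a family random
intercept, a fixed biomarker term and a group-by-biomarker interaction,
with sex, education and APOE e4 as covariates. Significant interactions
are followed by within-group Pearson correlations; a log-transform
sensitivity refit addresses biomarker skew. Whether BAG mediates
biomarker-cognition associations is assessed with a non-parametric
bootstrap of the product of paths (indirect effect a*b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._pls import fit_pls

__all__ = [
    "GroupComparison",
    "LMEFit",
    "MediationResult",
    "group_comparison",
    "levene_test",
    "fit_lme_biomarker",
    "group_correlations",
    "log_sensitivity",
    "mediate",
    "cohens_d",
]


# ---------------------------------------------------------------------------
# rank-based group comparisons

@dataclass
class GroupComparison:
    h: float
    df: int
    p: float
    pairs: pd.DataFrame   # columns: group1, group2, w, p_raw, p_fdr


def _rank_sum(x, y):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney): exact enumeration for
    combined n <= 20 without ties, otherwise normal approximation with tie
    and continuity corrections."""
    n = len(x) + len(y)
    no_ties = len(np.unique(np.concatenate([x, y]))) == n
    method = "exact" if (n <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_comparison(values, groups) -> GroupComparison:
    """Omnibus Kruskal-Wallis plus FDR-adjusted pairwise rank-sum tests."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [g for g in ("NC", "asym_MC", "sym_MC") if g in groups] or \
        list(np.unique(groups))
    samples = {g: values[groups == g] for g in levels}
    for g, s in samples.items():
        if len(s) == 0:
            raise ValueError(f"empty group {g!r}")
    if len(levels) < 2:
        raise ValueError("need at least 2 non-empty groups")
    df = len(levels) - 1
    if np.ptp(values) == 0:
        h, p = 0.0, 1.0
        rows = [(a, b, float(len(samples[a]) * len(samples[b]) / 2.0), 1.0)
                for i, a in enumerate(levels) for b in levels[i + 1:]]
    else:
        h, p = stats.kruskal(*samples.values())
        rows = []
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                if np.ptp(np.concatenate([samples[a], samples[b]])) == 0:
                    w, pr = float(len(samples[a]) * len(samples[b]) / 2.0), 1.0
                else:
                    w, pr = _rank_sum(samples[a], samples[b])
                rows.append((a, b, w, pr))
    pairs = pd.DataFrame(rows, columns=["group1", "group2", "w", "p_raw"])
    if len(pairs):
        pairs["p_fdr"] = multipletests(pairs["p_raw"], method="fdr_bh")[1]
    else:
        pairs["p_fdr"] = []
    return GroupComparison(h=float(h), df=df, p=float(p), pairs=pairs)


def levene_test(values, groups):
    """Classic mean-centered Levene test of homogeneity of variance."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 members")
    devs = np.concatenate([np.abs(s - s.mean()) for s in samples])
    if np.ptp(devs) == 0:
        return 0.0, 1.0
    w, p = stats.levene(*samples, center="mean")
    return float(w), float(p)


# ---------------------------------------------------------------------------
# family-clustered biomarker models

@dataclass
class LMEFit:
    table: pd.DataFrame       # term, estimate, se, stat, df, p, eta_p2
    interaction: dict         # joint test: {"f", "df1", "df2", "p", "eta_p2"}
    var_family: float
    sigma2: float
    n: int
    response: str
    biomarker: str


def _lme_design(table, biomarker, response, covariates):
    cols = [response, biomarker, "group", "family_id", *covariates]
    data = table.dropna(subset=[c for c in cols if c in table.columns])
    if len(data) < 20:
        raise ValueError(f"need >= 20 complete rows for {biomarker!r}")
    y = data[response].to_numpy(dtype=float)
    x = data[biomarker].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"constant regressor {biomarker!r}")
    xc = x - x.mean()
    groups = data["group"].astype(str).to_numpy()
    levels = [g for g in ("NC", "asym_MC", "sym_MC") if g in groups]
    names = ["intercept", biomarker]
    cols_mat = [np.ones(len(data)), xc]
    for lv in levels[1:]:
        cols_mat.append((groups == lv).astype(float))
        names.append(f"group[{lv}]")
    inter_idx = []
    for lv in levels[1:]:
        cols_mat.append((groups == lv) * xc)
        names.append(f"group[{lv}]:{biomarker}")
        inter_idx.append(len(names) - 1)
    for cov in covariates:
        s = data[cov]
        if s.dtype == object:
            for lv in sorted(map(str, s.unique()))[1:]:
                cols_mat.append((s.astype(str) == lv).to_numpy(dtype=float))
                names.append(f"{cov}[{lv}]")
        else:
            cols_mat.append(s.to_numpy(dtype=float))
            names.append(cov)
    Xd = np.column_stack(cols_mat)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("singular design")
    fam_levels, fam_idx = np.unique(data["family_id"].to_numpy(),
                                    return_inverse=True)
    if len(fam_levels) < 2:
        raise ValueError("need at least 2 families")
    return data, y, Xd, names, inter_idx, fam_idx, len(fam_levels)


def fit_lme_biomarker(table: pd.DataFrame, biomarker: str,
                      response: str = "bag",
                      covariates=("sex", "education", "apoe4"),
                      lambdas: dict | None = None) -> LMEFit:
    """Mixed model: response ~ biomarker * group + covariates + (1|family).

    Fixed effects get Wald t/F tests with df = n - total EDF; partial
    eta^2 per term is F*df1 / (F*df1 + df2). ``lambdas`` may fix the
    family variance ratio (key "family") instead of REML-estimating it.
    """
    covariates = [c for c in covariates if c in table.columns]
    data, y, Xd, names, inter_idx, fam_idx, n_fam = _lme_design(
        table, biomarker, response, covariates)
    pls = fit_pls(Xd, y, blocks=[], fam_idx=fam_idx, n_fam=n_fam,
                  lambdas=lambdas)
    V = pls.cov_dense()
    se = np.sqrt(np.diag(V))
    df2 = max(pls.n - pls.edf_total, 1.0)
    tstat = pls.beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df2)
    eta = (tstat**2) / (tstat**2 + df2)
    out = pd.DataFrame({"term": names, "estimate": pls.beta, "se": se,
                        "stat": tstat, "df": df2, "p": pvals, "eta_p2": eta})

    if inter_idx:
        bi = pls.beta[inter_idx]
        Vi = V[np.ix_(inter_idx, inter_idx)]
        q = len(inter_idx)
        fstat = float(bi @ np.linalg.solve(Vi, bi)) / q
        p_int = float(stats.f.sf(fstat, q, df2))
        eta_int = fstat * q / (fstat * q + df2)
        interaction = {"f": fstat, "df1": q, "df2": float(df2), "p": p_int,
                       "eta_p2": float(eta_int)}
    else:
        interaction = {"f": np.nan, "df1": 0, "df2": float(df2), "p": np.nan,
                       "eta_p2": np.nan}
    return LMEFit(table=out, interaction=interaction,
                  var_family=pls.var_family, sigma2=pls.sigma2, n=pls.n,
                  response=response, biomarker=biomarker)


def group_correlations(table: pd.DataFrame, biomarker: str, group: str,
                       response: str = "bag"):
    """Pearson correlation between a biomarker and the response in one
    group; returns (r, p, n)."""
    data = table[table["group"] == group].dropna(subset=[biomarker, response])
    if len(data) < 3:
        raise ValueError(f"need >= 3 rows in group {group!r}")
    x = data[biomarker].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(data)


def log_sensitivity(table: pd.DataFrame, biomarkers,
                    response: str = "bag",
                    covariates=("sex", "education", "apoe4")) -> dict:
    """Refit biomarker models on natural-log-transformed values.

    Returns {biomarker: {"raw": LMEFit, "log": LMEFit}}. Raises on
    non-positive biomarker values, listing the offending rows.
    """
    out = {}
    for biom in biomarkers:
        vals = table[biom]
        bad = table.index[(vals <= 0) & vals.notna()]
        if len(bad):
            raise ValueError(
                f"{biom!r} has non-positive values at rows {list(bad[:10])}"
                f"{'...' if len(bad) > 10 else ''}; cannot log-transform")
        logged = table.copy()
        logged[biom] = np.log(vals)
        out[biom] = {
            "raw": fit_lme_biomarker(table, biom, response, covariates),
            "log": fit_lme_biomarker(logged, biom, response, covariates),
        }
    return out


# ---------------------------------------------------------------------------
# mediation

@dataclass
class MediationResult:
    a: float                 # X -> M
    b: float                 # M -> Y | X
    indirect: float          # a*b
    direct: float            # c'
    total: float             # c
    ci_low: float
    ci_high: float
    label: str               # "full", "partial" or "none"
    n: int
    n_boot: int
    seed: int


def _ols_coef(X, y):
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def mediate(table: pd.DataFrame, x: str, m: str = "bag",
            y: str = "cognitive_composite",
            covariates=("sex", "education", "apoe4"),
            n_boot: int = 5000, seed: int = 0) -> MediationResult:
    """Non-parametric bootstrap mediation of x -> m -> y.

    Two linear models (m ~ x + cov; y ~ x + m + cov) give paths a and b;
    the indirect effect a*b gets a percentile bootstrap CI over participant
    resamples. For nested OLS fits total = direct + indirect exactly.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    covariates = [c for c in covariates if c in table.columns]
    data = table.dropna(subset=[x, m, y, *covariates])
    n = len(data)
    if n < 30:
        raise ValueError(f"need >= 30 complete cases, have {n}")

    cov_cols = []
    for cov in covariates:
        s = data[cov]
        if s.dtype == object:
            for lv in sorted(map(str, s.unique()))[1:]:
                cov_cols.append((s.astype(str) == lv).to_numpy(dtype=float))
        else:
            cov_cols.append(s.to_numpy(dtype=float))
    C = np.column_stack(cov_cols) if cov_cols else np.empty((n, 0))
    xv = data[x].to_numpy(dtype=float)
    mv = data[m].to_numpy(dtype=float)
    yv = data[y].to_numpy(dtype=float)
    ones = np.ones(n)

    def paths(idx):
        Xm = np.column_stack([ones[idx], xv[idx], C[idx]])
        a = _ols_coef(Xm, mv[idx])[1]
        Xy = np.column_stack([ones[idx], xv[idx], mv[idx], C[idx]])
        cy = _ols_coef(Xy, yv[idx])
        return a, cy[2], cy[1]      # a, b, c'

    full = np.arange(n)
    a, b, direct = paths(full)
    indirect = a * b
    Xt = np.column_stack([ones, xv, C])
    total = _ols_coef(Xt, yv)[1]

    # t-test of the direct path for the full/partial label
    Xy = np.column_stack([ones, xv, mv, C])
    cy = _ols_coef(Xy, yv)
    res = yv - Xy @ cy
    dof = n - Xy.shape[1]
    s2 = float(res @ res) / dof
    se_direct = np.sqrt(s2 * np.linalg.inv(Xy.T @ Xy)[1, 1])
    p_direct = 2.0 * stats.t.sf(abs(direct) / se_direct, df=dof)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(n, size=n)
        ab, bb, _ = paths(idx)
        boots[i] = ab * bb
    lo, hi = np.quantile(boots, [0.025, 0.975])

    if lo <= 0.0 <= hi:
        label = "none"
    elif p_direct < 0.05:
        label = "partial"
    else:
        label = "full"
    return MediationResult(a=float(a), b=float(b), indirect=float(indirect),
                           direct=float(direct), total=float(total),
                           ci_low=float(lo), ci_high=float(hi), label=label,
                           n=n, n_boot=n_boot, seed=seed)


def cohens_d(group1, group2):
    """Pooled-SD standardized mean difference with a normal-approximation
    95% CI (SE^2 = (n1+n2)/(n1 n2) + d^2 / (2(n1+n2-2)))."""
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 members")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD")
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2 - 2)))
    return float(d), (float(d - 1.959963984540054 * se),
                      float(d + 1.959963984540054 * se))
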