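"""Cohort statistics: covariate-adjusted group comparisons, partial
correlations, and Benjamini-Hochberg FDR control.

Group contrasts use ANCOVA-style linear models (value ~ group + age +
gender).  Associations between regional measures (median R2t*, normalized
volume) and clinical scores use partial Pearson correlations for the
cognitive tests and partial Spearman for skewed measures (EDSS, timed
walk, peg test), all controlled for age, gender, lesion load and
treatment.  The nine-hole peg test is lateralized: dominant-hand times are
paired with left-hemisphere measures and non-dominant with right, in
right-handed patients only.

P-values within each analysis family are adjusted with the
Benjamini-Hochberg step-up procedure; adjusted p < alpha (default 0.05)
flags significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "PartialCorrResult",
    "AncovaResult",
    "BatteryConfig",
    "bh_fdr",
    "partial_pearson",
    "partial_spearman",
    "ancova_compare",
    "run_correlation_battery",
]

MS_GROUPS = ("RRMS", "SPMS", "PPMS")
GROUPS = ("HC",) + MS_GROUPS


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending; q(i) = min_{j >= i} min(1, p(j) * m / j); map back to
    the input order.  Output is monotone in the input and never below it.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# Partial correlations
# ---------------------------------------------------------------------------

class PartialCorrResult(NamedTuple):
    r: float
    statistic: float
    df: int
    p: float
    n: int


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def _check_covariates(covariates, n: int) -> np.ndarray:
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    design = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the collinear columns: those whose removal restores full rank
        bad = [
            str(j)
            for j in range(cov.shape[1])
            if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1))
            == np.linalg.matrix_rank(design)
        ]
        raise ValueError(f"covariate matrix is rank-deficient (columns: {', '.join(bad)})")
    return design


def partial_pearson(x, y, covariates=None) -> PartialCorrResult:
    """Pearson correlation of x and y after removing the least-squares
    projection of each onto [intercept, covariates].

    t = r * sqrt(df / (1 - r^2)) with df = n - k - 2; two-sided p from the
    t distribution.  With no covariates this reduces to the plain Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing values: caller must drop incomplete cases")
    design = _check_covariates(covariates, n)
    k = design.shape[1] - 1
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    denom = np.sqrt(np.dot(rx, rx) * np.dot(ry, ry))
    r = float(np.dot(rx, ry) / denom) if denom > 0 else 0.0
    r = float(np.clip(r, -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrResult(r=r, statistic=float(t), df=df, p=p, n=n)


def partial_spearman(x, y, covariates=None) -> PartialCorrResult:
    """Partial Spearman: rank-transform x and y (average ranks for ties),
    then apply :func:`partial_pearson` on the ranks."""
    x = sps.rankdata(np.asarray(x, dtype=float))
    y = sps.rankdata(np.asarray(y, dtype=float))
    return partial_pearson(x, y, covariates)


# ---------------------------------------------------------------------------
# Group comparison (ANCOVA-style linear model)
# ---------------------------------------------------------------------------

@dataclass
class AncovaResult:
    f_statistic: float
    df_num: int
    df_den: int
    p_omnibus: float
    contrasts: pd.DataFrame
    n: int


def _encode_gender(gender) -> np.ndarray:
    g = pd.Series(gender).astype(str).str.upper()
    bad = set(g.unique()) - {"F", "M"}
    if bad:
        raise ValueError(f"unknown gender codes: {sorted(bad)}")
    return (g == "M").to_numpy(dtype=float)


def ancova_compare(values, group, age=None, gender=None,
                   contrasts: Sequence[tuple[str, str]] | None = None) -> AncovaResult:
    """Linear model ``value ~ group + age + gender`` fitted by OLS.

    The omnibus group effect is the extra-sum-of-squares F-test against the
    covariate-only model; pairwise group contrasts are t-tests on dummy
    coefficient differences.  By default every group is contrasted against
    every other (each MS subtype vs HC, and subtype vs subtype).  With no
    covariates the two-group contrast reduces to the pooled t-test.
    """
    values = np.asarray(values, dtype=float)
    group = pd.Series(group).astype(str).reset_index(drop=True)
    n = len(values)
    covs = []
    if age is not None:
        covs.append(np.asarray(age, dtype=float))
    if gender is not None:
        covs.append(_encode_gender(gender))
    levels = [g for g in GROUPS if g in set(group)] or sorted(group.unique())
    counts = group.value_counts()
    small = [g for g in levels if counts.get(g, 0) < 3]
    if small:
        raise ValueError(f"groups with < 3 subjects: {small}")
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")

    dummies = np.column_stack([(group == g).to_numpy(dtype=float) for g in levels[1:]])
    cov_block = np.column_stack(covs) if covs else np.empty((n, 0))
    X_full = sm.add_constant(np.column_stack([dummies, cov_block]), has_constant="add")
    X_red = sm.add_constant(cov_block, has_constant="add")
    full = sm.OLS(values, X_full).fit()
    red = sm.OLS(values, X_red).fit()
    f, p_omni, df_num = full.compare_f_test(red)

    if contrasts is None:
        contrasts = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    rows = []
    coef_index = {g: 1 + i for i, g in enumerate(levels[1:])}  # position in X_full
    k = X_full.shape[1]
    for a, b in contrasts:
        c = np.zeros(k)
        if b in coef_index:
            c[coef_index[b]] += 1.0
        if a in coef_index:
            c[coef_index[a]] -= 1.0
        tt = full.t_test(c)
        rows.append(
            dict(
                contrast=f"{b}-{a}",
                estimate=float(np.ravel(tt.effect)[0]),
                statistic=float(np.ravel(tt.tvalue)[0]),
                df=int(full.df_resid),
                p_raw=float(np.ravel(tt.pvalue)[0]),
            )
        )
    return AncovaResult(
        f_statistic=float(f),
        df_num=int(df_num),
        df_den=int(full.df_resid),
        p_omnibus=float(p_omni),
        contrasts=pd.DataFrame(rows),
        n=n,
    )


# ---------------------------------------------------------------------------
# Correlation battery
# ---------------------------------------------------------------------------

@dataclass
class BatteryConfig:
    """Which scores are tested how, and what is controlled for.

    Cognitive scores (z-scored PASAT 3s/2s and SDMT) use partial Pearson;
    EDSS, timed 25-foot walk and the nine-hole peg test use partial
    Spearman.  The peg test is restricted to right-handed patients with
    dominant/left and non-dominant/right pairing.  One FDR family per
    (measure, method) block; adjusted p < alpha is flagged significant.
    """

    pearson_scores: tuple = ("PASAT3_z", "PASAT2_z", "SDMT_z")
    spearman_scores: tuple = ("EDSS", "T25FW", "9HPT")
    covariates: tuple = ("age", "gender", "lesion_load", "treatment")
    alpha: float = 0.05
    ms_only: bool = True
    measures: dict = field(
        default_factory=lambda: {"R2t*": "median_r2t_star", "NV": "normalized_volume"}
    )


def _covariate_matrix(df: pd.DataFrame, names) -> np.ndarray:
    cols = []
    for c in names:
        if c == "gender":
            cols.append(_encode_gender(df[c]))
        else:
            cols.append(df[c].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def run_correlation_battery(
    summaries: pd.DataFrame,
    cohort: pd.DataFrame,
    config: BatteryConfig | None = None,
) -> pd.DataFrame:
    """Region x hemisphere x measure x score association table.

    ``summaries`` is tidy (subject_id, region_name, hemisphere,
    median_r2t_star, normalized_volume); ``cohort`` is one row per subject.
    Complete-case analysis per cell, n reported; BH-FDR applied within each
    (measure, method) family.
    """
    if config is None:
        config = BatteryConfig()
    missing = [c for c in config.covariates if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing required covariate columns: {missing}")

    pool = cohort[cohort.group.isin(MS_GROUPS)] if config.ms_only else cohort
    merged = summaries.merge(pool, on="subject_id", how="inner")

    rows = []
    for measure, value_col in config.measures.items():
        for (region, hemi), cell in merged.groupby(["region_name", "hemisphere"], sort=True):
            for score in config.pearson_scores:
                rows.append(
                    _battery_cell(cell, measure, value_col, region, hemi, score,
                                  "partial_pearson", config)
                )
            for score in config.spearman_scores:
                rows.append(
                    _battery_cell(cell, measure, value_col, region, hemi, score,
                                  "partial_spearman", config)
                )
    out = pd.DataFrame([r for r in rows if r is not None])
    if out.empty:
        return out
    out["p_fdr"] = np.nan
    for (_, _), idx in out.groupby(["measure", "method"]).groups.items():
        sub = out.loc[idx]
        ok = sub["p_raw"].notna()
        out.loc[sub.index[ok], "p_fdr"] = bh_fdr(sub.loc[ok, "p_raw"].to_numpy())
    out["significant"] = out["p_fdr"] < config.alpha
    out["analysis_id"] = (
        out["measure"] + ":" + out["method"] + ":" + out["region_name"]
        + ":" + out["hemisphere"] + ":" + out["test_name"]
    )
    return out


def _battery_cell(cell, measure, value_col, region, hemi, score, method, config):
    df = cell
    if score == "9HPT":
        df = df[df["handedness"] == "right"]
        score_col = "9HPT_dom" if hemi == "left" else "9HPT_nondom"
    else:
        score_col = score
    if score_col not in df.columns:
        return None
    keep = df[value_col].notna() & df[score_col].notna()
    for c in config.covariates:
        keep &= df[c].notna()
    sub = df[keep]
    base = dict(
        region_name=region, hemisphere=hemi, measure=measure, test_name=score,
        method=method, covariates=",".join(config.covariates), n=int(len(sub)),
        estimate=np.nan, statistic=np.nan, df=np.nan, p_raw=np.nan,
    )
    k = len(config.covariates)
    if len(sub) <= k + 2:
        return base
    cov = _covariate_matrix(sub, config.covariates)
    x = sub[value_col].to_numpy(dtype=float)
    y = pd.to_numeric(sub[score_col]).to_numpy(dtype=float)
    fn = partial_pearson if method == "partial_pearson" else partial_spearman
    try:
        res = fn(x, y, cov)
    except ValueError:
        return base
    base.update(estimate=res.r, statistic=res.statistic, df=res.df, p_raw=res.p)
    return base
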