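"""Statistical battery for the cohort: rank tests, effect sizes, and the
voxelwise mixed-effects model.

Small samples get exact answers: the Mann–Whitney U test enumerates all
label assignments for pooled n ≤ 12, and the Spearman p-value enumerates
permutations for n ≤ 10; larger samples fall back to the usual normal /
t approximations with tie corrections.  All p-values are two-sided and
no multiple-testing correction is applied (p < 0.05 is the significance
convention of the analysis this reproduces).

The voxelwise pH ~ Lac/Pyr association is fit as a linear mixed-effects
model with random intercepts for mouse and for lesion nested in mouse,
by REML (statsmodels MixedLM).  Degenerate fits (zero variance
components, singular designs, zero-noise data) fall back to ordinary
least squares and are flagged rather than raised.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CohortTable",
    "MixedModelFit",
    "mann_whitney_u",
    "spearman",
    "cohens_d",
    "fit_mixed_model",
    "per_mouse_aggregate",
    "write_report",
    "EXACT_MW_MAX_N",
    "EXACT_SPEARMAN_MAX_N",
]

EXACT_MW_MAX_N = 12  # pooled size up to which the U test is enumerated
EXACT_SPEARMAN_MAX_N = 10


@dataclass
class CohortTable:
    """Lesion-level and voxel-level long tables for the statistics stage."""

    lesions: pd.DataFrame  # one row per lesion (LesionRecord.to_dict rows)
    voxels: pd.DataFrame | None = None  # mouse_id, lesion_id, voxel_id, ph, lacpyr

    def __post_init__(self) -> None:
        if self.voxels is not None and len(self.voxels):
            keys = self.voxels[["lesion_id", "voxel_id"]]
            if keys.duplicated().any():
                raise ValueError("duplicated voxel keys in the voxel table")
            if len(self.lesions):
                unknown = set(self.voxels["lesion_id"]) - set(self.lesions["lesion_id"])
                if unknown:
                    raise ValueError(f"voxel rows reference unknown lesions {unknown}")


@dataclass
class MixedModelFit:
    """Fixed effects and variance components of the voxelwise model."""

    slope: float
    intercept: float
    slope_se: float
    p_value: float
    mouse_var: float
    lesion_var: float
    residual_var: float
    n_voxels: int
    converged: bool = True
    method: str = "reml"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("mouse_var", "lesion_var", "residual_var"):
            v = getattr(self, name)
            if np.isfinite(v) and v < -1e-12:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# rank tests

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: number of (a_i, b_j) pairs with a_i > b_j, ties count ½."""
    ranks = sps.rankdata(np.concatenate([a, b]))
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact permutation p for pooled n ≤ 12 (full enumeration of label
    assignments, so ties are handled exactly); otherwise the normal
    approximation with tie correction.  Returns (U of group a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    u_obs = _u_statistic(a, b)
    if np.ptp(pooled) == 0:
        return u_obs, 1.0
    n = pooled.size
    if n <= EXACT_MW_MAX_N:
        idx = np.arange(n)
        us = np.array([
            _u_statistic(pooled[list(comb)], pooled[np.setdiff1d(idx, comb)])
            for comb in itertools.combinations(idx, a.size)
        ])
        lo = np.mean(us <= u_obs + 1e-12)
        hi = np.mean(us >= u_obs - 1e-12)
        return u_obs, float(min(1.0, 2.0 * min(lo, hi)))
    # normal approximation with tie correction
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (u_obs - mu) / math.sqrt(sigma2)
    return u_obs, float(2.0 * sps.norm.sf(abs(z)))


def _rank_corr(x_ranks: np.ndarray, y_ranks: np.ndarray) -> float:
    xc = x_ranks - x_ranks.mean()
    yc = y_ranks - y_ranks.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p by full permutation enumeration for n ≤ 10, otherwise
    the t approximation.  Constant input raises (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_corr(rx, ry)
    n = x.size
    if n <= EXACT_SPEARMAN_MAX_N:
        xc = rx - rx.mean()
        yc = ry - ry.mean()
        denom = math.sqrt((xc**2).sum() * (yc**2).sum())
        count = 0
        total = 0
        # enumerate in chunks, vectorizing the correlation over permutations
        perm_iter = itertools.permutations(yc)
        while True:
            chunk = np.array(list(itertools.islice(perm_iter, 50000)))
            if chunk.size == 0:
                break
            rhos = chunk @ xc / denom
            count += int(np.sum(np.abs(rhos) >= abs(rho) - 1e-12))
            total += chunk.shape[0]
        return rho, count / total
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
    return rho, float(2.0 * sps.t.sf(abs(t), df=n - 2))


def cohens_d(group_a, group_b) -> float:
    """Cohen's d with the pooled standard deviation.

    d = (mean_a − mean_b) / s_p,
    s_p = sqrt(((n_a−1)s_a² + (n_b−1)s_b²)/(n_a+n_b−2)).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        raise ValueError("zero pooled variance: effect size undefined")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


# ---------------------------------------------------------------------------
# mixed model

def _ols_fit(df: pd.DataFrame, flags: list[str]) -> MixedModelFit:
    res = sps.linregress(df["lacpyr"], df["ph"])
    resid = df["ph"] - (res.intercept + res.slope * df["lacpyr"])
    return MixedModelFit(
        slope=float(res.slope), intercept=float(res.intercept),
        slope_se=float(res.stderr), p_value=float(res.pvalue),
        mouse_var=0.0, lesion_var=0.0,
        residual_var=float(np.var(resid, ddof=2)),
        n_voxels=len(df), converged=True, method="ols", flags=flags,
    )


def fit_mixed_model(voxel_table: CohortTable | pd.DataFrame,
                    nesting: str = "nested") -> MixedModelFit:
    """Voxelwise pH ~ Lac/Pyr linear mixed-effects model by REML.

    Random intercepts for mouse and for lesion nested in mouse
    (``nesting="nested"``, the default) or crossed mouse/lesion
    intercepts (``nesting="crossed"`` treats lesion labels as global).
    Requires ≥ 2 lesions and ≥ 10 voxels; a single grouping level or a
    degenerate/singular fit falls back to OLS with a flag instead of
    raising.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = voxel_table.voxels if isinstance(voxel_table, CohortTable) else voxel_table
    if df is None or len(df) < 10:
        raise ValueError("need at least 10 voxels")
    df = df.copy()
    if df["lesion_id"].nunique() < 2:
        return _ols_fit(df, flags=["single_lesion_ols"])
    if nesting == "nested":
        df["lesion_key"] = df["mouse_id"].astype(str) + "/" + df["lesion_id"].astype(str)
    elif nesting == "crossed":
        df["lesion_key"] = df["lesion_id"].astype(str)
    else:
        raise ValueError("nesting must be 'nested' or 'crossed'")

    flags: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = smf.mixedlm(
                "ph ~ lacpyr", df, groups=df["mouse_id"], re_formula="1",
                vc_formula={"lesion": "0 + C(lesion_key)"},
            )
            fit = model.fit(reml=True)
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                flags.append("convergence_warning")
    except (np.linalg.LinAlgError, ValueError, OverflowError):
        return _ols_fit(df, flags=["mixedlm_failed_ols_fallback"])

    slope = float(fit.params["lacpyr"])
    slope_se = float(fit.bse["lacpyr"])
    p = float(fit.pvalues["lacpyr"])
    if not np.isfinite(slope_se) or slope_se == 0:
        return _ols_fit(df, flags=flags + ["degenerate_se_ols_fallback"])
    mouse_var = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    lesion_var = float(fit.vcomp[0]) if len(fit.vcomp) else 0.0
    return MixedModelFit(
        slope=slope, intercept=float(fit.params["Intercept"]),
        slope_se=slope_se, p_value=p,
        mouse_var=max(mouse_var, 0.0), lesion_var=max(lesion_var, 0.0),
        residual_var=float(fit.scale), n_voxels=len(df),
        converged=fit.converged if fit.converged is not None else True,
        method="reml", flags=flags or (["singular_fit"] if not fit.converged else []),
    )


# ---------------------------------------------------------------------------
# cohort-level plumbing

def per_mouse_aggregate(cohort: CohortTable,
                        rule: str = "largest") -> CohortTable:
    """Keep a single ROI per mouse for the sensitivity re-analysis.

    ``rule="largest"`` keeps the lesion with the most pH voxels (ties
    broken by lesion id); ``rule="first"`` keeps the first by lesion id.
    """
    df = cohort.lesions
    if "mouse_id" not in df.columns:
        raise ValueError("lesion table must carry mouse ids")
    if not len(df):
        return CohortTable(lesions=df.copy(), voxels=cohort.voxels)
    size_col = "n_voxels_ph" if "n_voxels_ph" in df.columns else None

    def pick(group: pd.DataFrame) -> pd.DataFrame:
        g = group.sort_values("lesion_id")
        if rule == "largest" and size_col is not None:
            g = g.sort_values([size_col, "lesion_id"], ascending=[False, True],
                              kind="stable")
        elif rule not in ("largest", "first"):
            raise ValueError("rule must be 'largest' or 'first'")
        return g.iloc[[0]]

    kept = pd.concat([pick(g) for _, g in df.groupby("mouse_id", sort=True)])
    kept = kept.sort_index()
    voxels = cohort.voxels
    if voxels is not None and len(voxels):
        voxels = voxels[voxels["lesion_id"].isin(kept["lesion_id"])].copy()
    return CohortTable(lesions=kept.reset_index(drop=True), voxels=voxels)


_GROUP_METRICS = ("mean_ph", "min_ph", "mean_lacpyr", "max_lacpyr", "mean_adc")


def _group_comparisons(lesions: pd.DataFrame) -> dict:
    out: dict = {}
    low = lesions[lesions["grade"] == "low"]
    high = lesions[lesions["grade"] == "high"]
    for metric in _GROUP_METRICS:
        if metric not in lesions.columns:
            continue
        a = low[metric].dropna().to_numpy()
        b = high[metric].dropna().to_numpy()
        entry: dict = {"n_low": int(a.size), "n_high": int(b.size)}
        if a.size >= 1 and b.size >= 1:
            u, p = mann_whitney_u(a, b)
            entry["mann_whitney_u"] = u
            entry["p_value"] = p
        if a.size >= 2 and b.size >= 2:
            try:
                entry["cohens_d"] = cohens_d(a, b)
            except ValueError:
                entry["cohens_d"] = None
        entry["low_mean"] = float(a.mean()) if a.size else None
        entry["high_mean"] = float(b.mean()) if b.size else None
        out[metric] = entry
    return out


def _correlations(lesions: pd.DataFrame) -> dict:
    pairs = [
        ("min_ph", "max_lacpyr"),
        ("mean_ph", "mean_lacpyr"),
        ("mean_ph", "expr_Mct4"),
        ("mean_ph", "expr_Mct1"),
        ("mean_lacpyr", "mean_adc"),
    ]
    out: dict = {}
    for xcol, ycol in pairs:
        if xcol not in lesions.columns or ycol not in lesions.columns:
            continue
        sub = lesions[[xcol, ycol]].dropna()
        if len(sub) < 3:
            continue
        try:
            rho, p = spearman(sub[xcol], sub[ycol])
        except ValueError:
            continue
        out[f"{xcol}__{ycol}"] = {"rho": rho, "p_value": p, "n": int(len(sub))}
    return out


def write_report(cohort: CohortTable, outdir: str | Path,
                 mixed_fit: MixedModelFit | None = None) -> dict:
    """Compute the full statistics bundle and write it to disk.

    Emits ``lesions.csv``, ``voxels.csv`` (if present) and
    ``report.json`` (sorted keys, so identical inputs give byte-identical
    output).  Returns the report dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lesions = cohort.lesions
    report: dict = {
        "n_lesions": int(len(lesions)),
        "group_comparisons": _group_comparisons(lesions) if len(lesions) else {},
        "correlations": _correlations(lesions) if len(lesions) else {},
    }
    if mixed_fit is None and cohort.voxels is not None and len(cohort.voxels) >= 10 \
            and cohort.voxels["lesion_id"].nunique() >= 2:
        mixed_fit = fit_mixed_model(cohort)
    if mixed_fit is not None:
        report["mixed_model"] = {
            "slope": mixed_fit.slope,
            "intercept": mixed_fit.intercept,
            "slope_se": mixed_fit.slope_se,
            "p_value": mixed_fit.p_value,
            "mouse_var": mixed_fit.mouse_var,
            "lesion_var": mixed_fit.lesion_var,
            "residual_var": mixed_fit.residual_var,
            "n_voxels": mixed_fit.n_voxels,
            "method": mixed_fit.method,
            "flags": mixed_fit.flags,
        }
    if len(lesions) and lesions["mouse_id"].nunique() < len(lesions):
        per_mouse = per_mouse_aggregate(cohort)
        report["per_mouse"] = _group_comparisons(per_mouse.lesions)

    lesions.to_csv(outdir / "lesions.csv", index=False)
    if cohort.voxels is not None:
        cohort.voxels.to_csv(outdir / "voxels.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return report
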