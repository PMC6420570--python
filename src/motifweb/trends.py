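"""Diversity-gradient models and descriptive summaries of motif output.

Motif counts and normalised representation scores are modelled against sown
plant richness with linear mixed models: the fixed effect is log2(sown
richness) (the sown levels form a doubling series), random intercepts are
time period, block, and plot within block.  Counts are log(x+1) transformed;
normalised scores enter untransformed.  When the full random structure
cannot be fitted (singular or non-converged), the structure is downgraded
step by step and the structure actually used is recorded in the result —
never silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .motifs import COMMON_CODES, MOTIF_CODES, OTHER_CODES

_VC_LADDER: list[tuple[str, dict[str, str] | None]] = [
    ("period+block/plot", {
        "period": "0 + C(time_period)",
        "block": "0 + C(block_id)",
        "plot": "0 + C(plot_id)",
    }),
    ("period+plot", {"period": "0 + C(time_period)", "plot": "0 + C(plot_id)"}),
    ("plot", {"plot": "0 + C(plot_id)"}),
    ("none (ols)", None),
]


@dataclass(frozen=True)
class TrendResult:
    """Slope of one response against log2(sown richness)."""

    response: str
    slope: float
    se: float
    pvalue: float
    ci_low: float
    ci_high: float
    n_obs: int
    random_structure: str
    pvalue_method: str

    def as_dict(self) -> dict:
        return {
            "response": self.response,
            "slope": self.slope,
            "se": self.se,
            "pvalue": self.pvalue,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_obs": self.n_obs,
            "random_structure": self.random_structure,
            "pvalue_method": self.pvalue_method,
        }


def fit_richness_trend(
    table: pd.DataFrame,
    response: str,
    log2_richness: bool = True,
    pvalue_method: str = "wald",
) -> TrendResult:
    """Mixed-model slope of ``response`` on (log2) sown richness.

    ``table`` needs columns ``plot_id``, ``block_id``, ``time_period``,
    ``sown_richness`` and the response.  ``pvalue_method`` is ``"wald"``
    (normal approximation on the slope, two-tailed; adequate at n = 320) or
    ``"lrt"`` (likelihood-ratio test of the fixed effect under ML).
    """
    needed = ["plot_id", "block_id", "time_period", "sown_richness", response]
    df = table[needed].dropna().copy()
    if df["sown_richness"].nunique() < 2:
        raise ValueError("need at least two sown-richness levels")
    df["_x"] = np.log2(df["sown_richness"].astype(float)) if log2_richness else (
        df["sown_richness"].astype(float)
    )
    df["_y"] = df[response].astype(float)
    df["_one"] = 1

    last_err: Exception | None = None
    for structure, vc in _VC_LADDER:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if vc is None:
                    res = sm.OLS(df["_y"], sm.add_constant(df["_x"])).fit()
                    slope, se = res.params["_x"], res.bse["_x"]
                    pval = res.pvalues["_x"]
                    lo, hi = res.conf_int().loc["_x"]
                    method = "t (ols fallback)"
                else:
                    model = sm.MixedLM.from_formula(
                        "_y ~ _x", groups="_one", vc_formula=vc, re_formula="0", data=df
                    )
                    res = model.fit(reml=(pvalue_method != "lrt"))
                    slope, se = res.params["_x"], res.bse["_x"]
                    if not (np.isfinite(slope) and np.isfinite(se) and se > 0):
                        raise RuntimeError("singular fit")
                    if pvalue_method == "lrt":
                        null = sm.MixedLM.from_formula(
                            "_y ~ 1", groups="_one", vc_formula=vc, re_formula="0", data=df
                        ).fit(reml=False)
                        lr = max(0.0, 2.0 * (res.llf - null.llf))
                        pval = sps.chi2.sf(lr, 1)
                        method = "lrt"
                    else:
                        z = slope / se
                        pval = 2.0 * sps.norm.sf(abs(z))
                        method = "wald-normal"
                    lo, hi = slope - 1.96 * se, slope + 1.96 * se
            if structure != _VC_LADDER[0][0]:
                warnings.warn(
                    f"random structure downgraded to '{structure}' for {response}",
                    stacklevel=2,
                )
            return TrendResult(
                response=response,
                slope=float(slope),
                se=float(se),
                pvalue=float(min(max(pval, np.finfo(float).tiny), 1.0)),
                ci_low=float(lo),
                ci_high=float(hi),
                n_obs=len(df),
                random_structure=structure,
                pvalue_method=method,
            )
        except Exception as err:  # try next structure
            last_err = err
            continue
    raise RuntimeError(f"no random-effect structure could be fitted: {last_err}")


def analysis_table(
    counts_table: pd.DataFrame, profiles_table: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """One row per plot-period with all modelled responses attached.

    Responses: ``<class>_<scope>_logcount`` (log(x+1) of the iteration-mean
    count) and ``<class>_<scope>_nscore`` for the four common motif classes
    plus ``total_full_logcount``.
    """
    keys = ["plot_id", "time_period"]
    out = design.drop_duplicates(keys).copy()
    for scope, tag in (("full", "full"), ("consumer_subweb", "sub")):
        sub = counts_table.loc[
            counts_table["scope"] == scope, keys + list(COMMON_CODES) + ["total"]
        ].copy()
        rename = {cls: f"{cls}_{tag}_logcount" for cls in COMMON_CODES}
        rename["total"] = f"total_{tag}_logcount"
        sub = sub.rename(columns=rename)
        for c in rename.values():
            sub[c] = np.log1p(sub[c].astype(float))
        out = out.merge(sub, on=keys, how="left")

        psub = profiles_table[profiles_table["scope"] == scope]
        if len(psub):
            piv = psub.pivot_table(index=keys, columns="motif", values="n_mean")
            piv = piv[[c for c in COMMON_CODES if c in piv.columns]]
            piv.columns = [f"{c}_{tag}_nscore" for c in piv.columns]
            out = out.merge(piv.reset_index(), on=keys, how="left")
    return out.reset_index(drop=True)


def fit_all_trends(
    counts_table: pd.DataFrame,
    profiles_table: pd.DataFrame,
    design: pd.DataFrame,
    pvalue_method: str = "wald",
) -> tuple[pd.DataFrame, list[str]]:
    """Fit every standard response; returns (trends frame, skipped responses).

    Responses that are constant or (for counts) all zero — typical for the
    rare double-link classes — are skipped and listed instead of modelled.
    """
    tab = analysis_table(counts_table, profiles_table, design)
    responses = [c for c in tab.columns if c.endswith(("_logcount", "_nscore"))]
    rows, skipped = [], []
    for resp in responses:
        vals = tab[resp].dropna()
        if len(vals) < 8 or np.isclose(vals.std(), 0.0):
            skipped.append(resp)
            continue
        rows.append(fit_richness_trend(tab, resp, pvalue_method=pvalue_method).as_dict())
    return pd.DataFrame(rows), skipped


def summarize_profiles(
    counts_table: pd.DataFrame, profiles_table: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Descriptive summary per sown-richness level.

    Per level: mean total motif count (full webs); mean per-web share (%) of
    each common class and of the 'other' aggregate (s3 + double-link
    classes); per class the mean grounded and free-floating fraction of the
    full-web count; and mean normalised scores per class and scope.
    """
    design = design.drop_duplicates(["plot_id", "time_period"])
    full = counts_table[counts_table["scope"] == "full"].merge(
        design, on=["plot_id", "time_period"]
    )
    free = counts_table[counts_table["scope"] == "consumer_subweb"].merge(
        design, on=["plot_id", "time_period"]
    )
    merged = full.merge(
        free, on=["plot_id", "time_period", "sown_richness"], suffixes=("", "_free")
    )

    rows = []
    for rich, grp in merged.groupby("sown_richness"):
        row: dict[str, float] = {"sown_richness": int(rich), "n_webs": len(grp)}
        total = grp["total"].to_numpy(dtype=float)
        row["total_motifs"] = float(np.mean(total))
        pos = total > 0
        for cls in COMMON_CODES:
            share = np.full_like(total, np.nan)
            share[pos] = 100.0 * grp[cls].to_numpy(dtype=float)[pos] / total[pos]
            row[f"pct_{cls}"] = float(np.nanmean(share)) if pos.any() else np.nan
        other = grp[list(OTHER_CODES)].sum(axis=1).to_numpy(dtype=float)
        common = sum(row[f"pct_{c}"] for c in COMMON_CODES)
        row["pct_common"] = common
        row["pct_other"] = (
            float(np.nanmean(np.where(pos, 100.0 * other / np.where(pos, total, 1), np.nan)))
            if pos.any() else np.nan
        )
        for cls in MOTIF_CODES:
            fc = grp[cls].to_numpy(dtype=float)
            fr = grp[f"{cls}_free"].to_numpy(dtype=float)
            has = fc > 0
            row[f"grounded_{cls}"] = (
                float(np.mean((fc[has] - fr[has]) / fc[has])) if has.any() else np.nan
            )
            row[f"freefloating_{cls}"] = (
                float(np.mean(fr[has] / fc[has])) if has.any() else np.nan
            )
        rows.append(row)
    summary = pd.DataFrame(rows).sort_values("sown_richness", ignore_index=True)

    prof = profiles_table.merge(design, on=["plot_id", "time_period"])
    for scope, tag in (("full", "full"), ("consumer_subweb", "sub")):
        sub = prof[prof["scope"] == scope]
        piv = sub.pivot_table(index="sown_richness", columns="motif", values="n_mean")
        for cls in MOTIF_CODES:
            if cls in piv.columns:
                summary[f"n_{tag}_{cls}"] = summary["sown_richness"].map(piv[cls])
    return summary


def plot_motif_trends(
    counts_table: pd.DataFrame, design: pd.DataFrame, classes=COMMON_CODES, ax=None
):
    """Diagnostic plot: mean motif counts vs sown richness (log-x), both scopes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    design = design.drop_duplicates(["plot_id", "time_period"])
    merged = counts_table.merge(design, on=["plot_id", "time_period"])
    for scope, ls in (("full", "-"), ("consumer_subweb", "--")):
        sub = merged[merged["scope"] == scope]
        means = sub.groupby("sown_richness")[list(classes)].mean()
        for cls in classes:
            ax.plot(means.index, means[cls], ls, marker="o", label=f"{cls} ({scope})")
    ax.set_xscale("log", base=2)
    ax.set_xlabel("sown plant richness")
    ax.set_ylabel("mean motif count")
    ax.legend(fontsize=7, ncol=2)
    return ax
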