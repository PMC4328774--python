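"""Among-isolate (genetic) variance components per substrate and site.

The design is a one-way random-effects layout: isolates are random
groups, replicate plates the error stratum.  Method-of-moments
estimates:

    MS_among  = SS_among / (a - 1)
    MS_within = SS_within / (N - a)
    v_genetic = max(0, (MS_among - MS_within) / n0)

with the standard unequal-n coefficient n0 = (N - sum(n_i^2)/N)/(a - 1),
which reduces to the common replicate number for balanced data.  The
genetic standard deviation is sqrt(v_genetic); the genetic coefficient of
variation divides it by the site mean yield of the substrate; the
standardized variance SV_A is the square of that CV — by the fundamental
theorem of natural selection, the proportional advance in fitness per
generation if yield were fitness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .yield_metrics import YieldMatrix

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponentResult:
    substrate: str
    site: str
    ms_among: float
    ms_within: float
    v_genetic: float                  # truncated at 0
    genetic_sd: float
    mean_yield: float
    cv_genetic: float                 # nan when mean_yield <= 0
    f_stat: float                     # nan when ms_within == 0
    p_value: float
    df_among: int
    df_within: int
    truncated: bool                   # raw estimate was negative


@dataclass
class SignificanceSummary:
    alpha_testwise: float
    alpha_fig: float
    flags: pd.DataFrame               # substrate x {category, sig_fig_site1, sig_fig_site2}
    n_sig_both: int
    n_sig_site1_only: int
    n_sig_site2_only: int
    n_sig_neither: int


def anova_oneway_random(values_by_group: list[np.ndarray]) -> dict:
    """Core sums-of-squares decomposition on raw replicate arrays.

    ``values_by_group`` is one array of replicate observations per
    isolate.  Returns the mean squares, the unequal-n coefficient, the
    variance component, and the F test against the replicate stratum.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group if len(g) > 0]
    a = len(groups)
    if a < 2:
        raise ValueError("need at least two isolates")
    n_i = np.array([len(g) for g in groups])
    if (n_i < 2).all():
        raise ValueError("variance component undefined with a single replicate "
                         "throughout")
    N = int(n_i.sum())
    grand = np.concatenate(groups).mean()
    group_means = np.array([g.mean() for g in groups])
    ss_among = float(np.sum(n_i * (group_means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_among = a - 1
    df_within = N - a
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    n0 = (N - float(np.sum(n_i ** 2)) / N) / df_among
    raw = (ms_among - ms_within) / n0
    truncated = raw < 0
    v_genetic = max(0.0, raw)
    if ms_within > 0:
        f_stat = ms_among / ms_within
        p_value = float(stats.f.sf(f_stat, df_among, df_within))
    else:
        # zero within-group variance: any among-group spread is unambiguous
        f_stat = np.nan
        p_value = 0.0 if ms_among > 0 else 1.0
    return {
        "ms_among": ms_among, "ms_within": ms_within, "n0": n0,
        "v_genetic": v_genetic, "truncated": truncated,
        "f_stat": f_stat, "p_value": p_value,
        "df_among": df_among, "df_within": df_within,
        "grand_mean": float(grand),
    }


def anova_components(ym: YieldMatrix, substrate: str, site: str) -> VarianceComponentResult:
    """Variance-component decomposition for one substrate at one site."""
    sub_ym = ym.for_site(site)
    col = sub_ym.values[substrate]
    groups = [reps.to_numpy(dtype=float) for _, reps in col.groupby(level=0, sort=False)]
    res = anova_oneway_random(groups)
    mean_yield = res["grand_mean"]
    genetic_sd = float(np.sqrt(res["v_genetic"]))
    cv = genetic_sd / mean_yield if mean_yield > 0 else np.nan
    return VarianceComponentResult(
        substrate=substrate, site=site,
        ms_among=res["ms_among"], ms_within=res["ms_within"],
        v_genetic=res["v_genetic"], genetic_sd=genetic_sd,
        mean_yield=mean_yield, cv_genetic=cv,
        f_stat=res["f_stat"], p_value=res["p_value"],
        df_among=res["df_among"], df_within=res["df_within"],
        truncated=res["truncated"],
    )


def anova_table(ym: YieldMatrix, site: str,
                substrates: list[str] | None = None) -> pd.DataFrame:
    """Variance components for many substrates at one site, as a table."""
    subs = substrates if substrates is not None else ym.substrates
    rows = [anova_components(ym, s, site) for s in subs]
    df = pd.DataFrame([vars(r) for r in rows])
    n_trunc = int(df["truncated"].sum())
    if n_trunc:
        logger.info("site %s: %d negative variance estimates truncated at 0",
                    site, n_trunc)
    return df


def genetic_cv_summary(results: pd.DataFrame) -> float:
    """Arithmetic mean of the genetic CV over substrates (one site).

    Substrates with non-positive mean yield have undefined CV and are
    excluded with a warning.
    """
    cv = results["cv_genetic"]
    bad = cv.isna()
    if bad.any():
        logger.warning("CV undefined (mean yield <= 0) for %d substrate(s); excluded",
                       int(bad.sum()))
    if (~bad).sum() == 0:
        raise ValueError("no substrate with defined CV")
    return float(cv[~bad].mean())


def standardized_variance(cv: float) -> float:
    """SV_A = CV², the standardized (mean-scaled) genetic variance."""
    if cv < 0:
        raise ValueError("CV must be non-negative")
    return cv ** 2


def significance_summary(
    results_site1: pd.DataFrame,
    results_site2: pd.DataFrame,
    alpha_testwise: float = 0.05,
    alpha_fig: float = 0.001,
) -> SignificanceSummary:
    """Classify substrates by where their genetic variance is significant.

    ``alpha_testwise`` drives the {both, site1-only, site2-only, neither}
    classification; ``alpha_fig`` is the stricter per-test level whose
    Bonferroni product with the substrate count approximates an
    experiment-wise level (0.001 x 95 < 0.1).
    """
    s1 = results_site1.set_index("substrate")["p_value"]
    s2 = results_site2.set_index("substrate")["p_value"]
    shared = s1.index.union(s2.index)
    only = shared.difference(s1.index.intersection(s2.index))
    if len(only):
        logger.warning("substrates present at one site only: %s",
                       list(only)[:5])
    rows = []
    for sub in shared:
        sig1 = bool(s1.get(sub, 1.0) < alpha_testwise)
        sig2 = bool(s2.get(sub, 1.0) < alpha_testwise)
        category = ("both" if sig1 and sig2 else
                    "site1_only" if sig1 else
                    "site2_only" if sig2 else "neither")
        rows.append((sub, category,
                     bool(s1.get(sub, 1.0) < alpha_fig),
                     bool(s2.get(sub, 1.0) < alpha_fig)))
    flags = pd.DataFrame(rows, columns=["substrate", "category",
                                        "sig_fig_site1", "sig_fig_site2"])
    counts = flags["category"].value_counts()
    return SignificanceSummary(
        alpha_testwise=alpha_testwise, alpha_fig=alpha_fig, flags=flags,
        n_sig_both=int(counts.get("both", 0)),
        n_sig_site1_only=int(counts.get("site1_only", 0)),
        n_sig_site2_only=int(counts.get("site2_only", 0)),
        n_sig_neither=int(counts.get("neither", 0)),
    )


def _squared_pearson(x: pd.Series, y: pd.Series) -> float:
    common = x.index.intersection(y.index)
    xv = x[common].to_numpy(dtype=float)
    yv = y[common].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        logger.warning("constant vector in correlation; r^2 reported as 0")
        return 0.0
    return float(np.corrcoef(xv, yv)[0, 1] ** 2)


def cross_site_variance_correlation(
    results_site1: pd.DataFrame, results_site2: pd.DataFrame,
    column: str = "v_genetic",
) -> float:
    """r² of per-substrate genetic variance between the two site surveys."""
    return _squared_pearson(results_site1.set_index("substrate")[column],
                            results_site2.set_index("substrate")[column])


def variance_mean_correlation(results: pd.DataFrame,
                              column: str = "v_genetic") -> float:
    """r² of per-substrate genetic variance with mean yield (one site)."""
    idx = results.set_index("substrate")
    return _squared_pearson(idx[column], idx["mean_yield"])
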