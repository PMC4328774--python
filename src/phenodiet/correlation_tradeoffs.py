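"""Pairwise genetic correlations between substrates and trade-off tests.

The genetic correlation between two substrates is the Pearson correlation
of isolate-mean yields across isolates.  Because overall genetic variance
alone produces positive correlations between arbitrary traits (the
"house-car" effect), observed summaries are referred to a permutation
null built by independently shuffling each substrate's yields across
isolates, which destroys between-substrate association while preserving
every marginal distribution.

Category contrasts (core vs ancillary diet, pentose vs hexose sugars)
summarize the mean pairwise correlation between substrate sets; their
permutation p-values shuffle the values of every substrate in one of the
two categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GeneticCorrelationMatrix:
    r: pd.DataFrame                  # substrate x substrate, diagonal 1
    n_isolates: int
    scope: str                       # "pooled" or a site label
    dropped: list[str]               # zero-variance substrates excluded

    def offdiag_mean(self) -> float:
        vals = self.r.to_numpy()
        iu = np.triu_indices_from(vals, k=1)
        return float(np.nanmean(vals[iu]))


@dataclass
class PermutationNullResult:
    observed_stat: float
    null_distribution: np.ndarray
    p_value: float
    n_perm: int
    seed: int


@dataclass
class CategoryContrast:
    name: str
    category_a: list[str]
    category_b: list[str]
    mean_r: float
    sd_r: float
    n_pairs: int
    p_value: float
    n_perm: int
    seed: int


# ---------------------------------------------------------------------------


def _corr(values: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation with NaN for zero-variance columns."""
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values, rowvar=False)
    return r


def genetic_correlation_matrix(
    isolate_means: pd.DataFrame, scope: str = "pooled"
) -> GeneticCorrelationMatrix:
    """Correlations across isolates for every substrate pair.

    ``isolate_means`` is isolate x substrate.  Substrates with zero
    variance across isolates are excluded (flagged in ``dropped``).
    """
    if len(isolate_means) < 3:
        raise ValueError("need at least 3 isolates")
    sd = isolate_means.std(axis=0, ddof=1)
    dropped = sd.index[sd == 0].tolist()
    if dropped:
        logger.warning("excluding %d zero-variance substrate(s): %s",
                       len(dropped), dropped[:5])
    keep = [s for s in isolate_means.columns if s not in dropped]
    vals = isolate_means[keep].to_numpy(dtype=float)
    r = pd.DataFrame(_corr(vals), index=keep, columns=keep)
    return GeneticCorrelationMatrix(r=r, n_isolates=len(isolate_means),
                                    scope=scope, dropped=dropped)


def _mean_offdiag(r: np.ndarray) -> float:
    iu = np.triu_indices_from(r, k=1)
    return float(np.nanmean(r[iu]))


def mean_correlation_with_null(
    m: GeneticCorrelationMatrix,
    isolate_means: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationNullResult:
    """Mean off-diagonal correlation against its column-shuffle null.

    Each permutation independently shuffles every substrate's column of
    isolate means and recomputes the mean pairwise correlation.  The
    empirical p-value is two-sided with the add-one convention.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; empirical p will be coarse", n_perm)
    cols = list(m.r.columns)
    vals = isolate_means[cols].to_numpy(dtype=float).copy()
    observed = m.offdiag_mean()
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    work = vals.copy()
    n = work.shape[0]
    for b in range(n_perm):
        for j in range(work.shape[1]):
            work[:, j] = vals[rng.permutation(n), j]
        null[b] = _mean_offdiag(_corr(work))
    extreme = int(np.sum(np.abs(null) >= abs(observed)))
    p = (1 + extreme) / (1 + n_perm)
    return PermutationNullResult(observed_stat=observed, null_distribution=null,
                                 p_value=p, n_perm=n_perm, seed=seed)


def _contrast_stat(vals_a: np.ndarray, vals_b: np.ndarray,
                   within: bool) -> tuple[float, float, int]:
    """Mean and SD of pairwise correlations between two column blocks.

    For a within-category contrast (the same block twice) only unordered
    distinct pairs are used.
    """
    if within:
        r = _corr(vals_a)
        iu = np.triu_indices_from(r, k=1)
        pairs = r[iu]
    else:
        na = vals_a.shape[1]
        full = _corr(np.hstack([vals_a, vals_b]))
        pairs = full[:na, na:].ravel()
    pairs = pairs[~np.isnan(pairs)]
    if len(pairs) == 0:
        raise ValueError("no valid substrate pairs in contrast")
    return float(np.mean(pairs)), float(np.std(pairs, ddof=1)) if len(pairs) > 1 else 0.0, len(pairs)


def category_contrast(
    isolate_means: pd.DataFrame,
    cat_a: list[str],
    cat_b: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    name: str = "",
    permute: str = "b",
) -> CategoryContrast:
    """Mean pairwise correlation between (or within) substrate categories.

    The permutation null shuffles, across isolates, the values of every
    substrate in one category (``permute``: "a", "b", or "both"; default
    the second-listed category) and recomputes the contrast mean.  The
    p-value is two-sided, add-one convention.
    """
    cat_a, cat_b = list(cat_a), list(cat_b)
    within = set(cat_a) == set(cat_b)
    if within and len(cat_a) < 2:
        raise ValueError("within-category contrast needs at least 2 substrates")
    if not within and (set(cat_a) & set(cat_b)):
        raise ValueError("between-category contrast requires disjoint sets")
    A = isolate_means[cat_a].to_numpy(dtype=float)
    B = isolate_means[cat_b].to_numpy(dtype=float)
    mean_r, sd_r, n_pairs = _contrast_stat(A, B, within)

    rng = np.random.default_rng(seed)
    n = A.shape[0]
    null = np.empty(n_perm)
    for b in range(n_perm):
        Ap, Bp = A, B
        if permute in ("a", "both"):
            Ap = np.column_stack([A[rng.permutation(n), j] for j in range(A.shape[1])])
        if permute in ("b", "both"):
            Bp = np.column_stack([B[rng.permutation(n), j] for j in range(B.shape[1])])
        if within:
            # within-category null: shuffle the (single) category
            null[b] = _contrast_stat(Bp if permute != "a" else Ap,
                                     Bp if permute != "a" else Ap, True)[0]
        else:
            null[b] = _contrast_stat(Ap, Bp, False)[0]
    extreme = int(np.sum(np.abs(null) >= abs(mean_r)))
    p = (1 + extreme) / (1 + n_perm)
    return CategoryContrast(name=name or "contrast", category_a=cat_a,
                            category_b=cat_b, mean_r=mean_r, sd_r=sd_r,
                            n_pairs=n_pairs, p_value=p, n_perm=n_perm,
                            seed=seed)


STANDARD_CONTRASTS = (
    ("core/core", "diet", "core", "core"),
    ("ancillary/ancillary", "diet", "ancillary", "ancillary"),
    ("core/ancillary", "diet", "core", "ancillary"),
    ("pentose/pentose", "sugar", "pentose", "pentose"),
    ("hexose/hexose", "sugar", "hexose", "hexose"),
    ("pentose/hexose", "sugar", "pentose", "hexose"),
)


def standard_contrast_suite(
    isolate_means: pd.DataFrame,
    diet_of: dict[str, str],
    sugar_of: dict[str, str],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """The six diet and sugar-class contrasts as one table.

    ``diet_of`` and ``sugar_of`` map each substrate in ``isolate_means``
    to its diet category (core/ancillary) and sugar class.  Contrasts
    with an empty category are skipped with a warning.  The expected sign
    pattern under core/ancillary and pentose/hexose trade-offs is
    (+, +, -, +, +, -).
    """
    subs = list(isolate_means.columns)
    groups = {
        ("diet", "core"): [s for s in subs if diet_of.get(s) == "core"],
        ("diet", "ancillary"): [s for s in subs if diet_of.get(s) == "ancillary"],
        ("sugar", "pentose"): [s for s in subs if sugar_of.get(s) == "pentose"],
        ("sugar", "hexose"): [s for s in subs if sugar_of.get(s) == "hexose"],
    }
    rows = []
    for i, (label, kind, a, b) in enumerate(STANDARD_CONTRASTS):
        cat_a, cat_b = groups[(kind, a)], groups[(kind, b)]
        min_size = 2 if a == b else 1
        if len(cat_a) < min_size or len(cat_b) < min_size:
            logger.warning("contrast %s skipped: empty or singleton category", label)
            continue
        c = category_contrast(isolate_means, cat_a, cat_b, n_perm=n_perm,
                              seed=seed + i, name=label)
        rows.append((label, c.mean_r, c.sd_r, c.n_pairs, c.p_value,
                     c.n_perm, c.seed))
    return pd.DataFrame(rows, columns=["contrast", "mean_r", "sd_r", "n_pairs",
                                       "p", "n_perm", "seed"])
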