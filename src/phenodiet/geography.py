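"""Geographic structure of substrate-utilization profiles.

Continental divergence: principal-component ordination of standardized
yield profiles, a one-way ANOVA of PC scores on site, and leave-one-out
linear discriminant classification of site membership on leading PC
scores.  Local structure: Mantel tests of the correlation between
great-circle geographic distance and Euclidean distance between
profiles, the standard test for isolation by distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .yield_metrics import StandardizedYieldMatrix

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class OrdinationResult:
    scores: pd.DataFrame             # isolate x PC
    loadings: pd.DataFrame           # substrate x PC
    explained_variance: np.ndarray   # variance of each component
    explained_ratio: np.ndarray
    top_loadings: list[tuple[str, float]]  # (substrate, |PC1 loading|), descending


@dataclass
class ClassificationResult:
    label_kind: str
    accuracy: float
    predicted: pd.Series             # isolate -> predicted label
    labels: pd.Series
    n_components: int


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    seed: int
    distance_kinds: tuple[str, str]


# ---------------------------------------------------------------------------


def pca_ordination(sym: StandardizedYieldMatrix | pd.DataFrame,
                   k_top: int = 10, scale: bool = False) -> OrdinationResult:
    """Principal components of the isolate x substrate matrix.

    Columns are centered (substrates share the OD unit, so they are not
    rescaled unless ``scale=True``).  Sign convention: the
    largest-magnitude loading of each component is positive, making
    ordinations and top-loading lists deterministic.  ``top_loadings``
    ranks substrates by absolute PC1 loading.
    """
    values = sym.values if isinstance(sym, StandardizedYieldMatrix) else sym
    if len(values) < 3 or values.shape[1] < 2:
        raise ValueError("need at least 3 isolates and 2 substrates")
    X = values.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # fix component signs
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    n = X.shape[0]
    ev = s ** 2 / (n - 1)
    ratio = ev / ev.sum() if ev.sum() > 0 else ev
    pcs = [f"PC{i+1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=values.index, columns=pcs)
    loadings = pd.DataFrame(vt.T, index=values.columns, columns=pcs)
    if k_top > values.shape[1]:
        logger.warning("k_top=%d > %d substrates; truncating", k_top,
                       values.shape[1])
        k_top = values.shape[1]
    order = loadings["PC1"].abs().sort_values(ascending=False).index[:k_top]
    top = [(s_, float(abs(loadings.at[s_, "PC1"]))) for s_ in order]
    return OrdinationResult(scores=scores, loadings=loadings,
                            explained_variance=ev, explained_ratio=ratio,
                            top_loadings=top)


def pc_anova(scores: pd.DataFrame, labels: pd.Series, component: int = 1) -> float:
    """One-way ANOVA p-value of a PC's scores on a grouping label."""
    col = scores[f"PC{component}"]
    labels = labels.reindex(col.index)
    groups = []
    for lab, grp in col.groupby(labels):
        if len(grp) < 2:
            logger.warning("label %r has a single isolate; dropped from ANOVA", lab)
            continue
        groups.append(grp.to_numpy(dtype=float))
    if len(groups) < 2:
        raise ValueError("need at least two labels with >=2 isolates")
    _, p = stats.f_oneway(*groups)
    return float(p)


def lda_loo_classification(
    sym: StandardizedYieldMatrix | pd.DataFrame,
    labels: pd.Series,
    label_kind: str = "site",
    variance_threshold: float = 0.90,
) -> ClassificationResult:
    """Leave-one-out LDA of a label from utilization profiles.

    With more substrates than isolates a raw LDA is singular, so
    classification operates on the leading principal-component scores
    covering at least ``variance_threshold`` of the variance.
    """
    values = sym.values if isinstance(sym, StandardizedYieldMatrix) else sym
    labels = labels.reindex(values.index)
    classes = labels.dropna().unique()
    if len(classes) < 2:
        raise ValueError("need at least 2 labels")
    if len(values) <= len(classes):
        raise ValueError("need more isolates than labels")
    ord_res = pca_ordination(values, k_top=1)
    cum = np.cumsum(ord_res.explained_ratio)
    k = int(np.searchsorted(cum, variance_threshold) + 1)
    k = min(k, ord_res.scores.shape[1], len(values) - 2)
    X = ord_res.scores.iloc[:, :k].to_numpy(dtype=float)
    y = labels.to_numpy()
    n = len(y)
    predicted = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValueError("a class vanishes under leave-one-out; too few isolates")
        clf = LinearDiscriminantAnalysis(solver="svd")
        try:
            clf.fit(X[mask], y[mask])
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ValueError(
                "singular within-class covariance; lower variance_threshold"
            ) from exc
        predicted[i] = clf.predict(X[i:i + 1])[0]
    accuracy = float(np.mean(predicted == y))
    return ClassificationResult(
        label_kind=label_kind, accuracy=accuracy,
        predicted=pd.Series(predicted, index=values.index),
        labels=labels, n_components=k,
    )


# ---------------------------------------------------------------------------
# distances and the Mantel test


def haversine_m(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in meters (sphere of radius 6,371,000 m)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return float(2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a)))


def geo_distance_matrix(metadata: pd.DataFrame) -> pd.DataFrame:
    """Pairwise great-circle distances (meters) between isolates."""
    md = metadata.copy()
    has = md["latitude"].notna() & md["longitude"].notna()
    if (~has).any():
        logger.warning("dropping isolates without coordinates: %s",
                       md.loc[~has, "isolate_id"].tolist())
        md = md[has]
    ids = list(md["isolate_id"])
    lat = md["latitude"].to_numpy(dtype=float)
    lon = md["longitude"].to_numpy(dtype=float)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_m(lat[i], lon[i], lat[j], lon[j])
    return pd.DataFrame(d, index=ids, columns=ids)


def phenotype_distance_matrix(sym: StandardizedYieldMatrix | pd.DataFrame) -> pd.DataFrame:
    """Euclidean distances between standardized-yield profiles."""
    values = sym.values if isinstance(sym, StandardizedYieldMatrix) else sym
    d = squareform(pdist(values.to_numpy(dtype=float)))
    return pd.DataFrame(d, index=values.index, columns=values.index)


def mantel_test(d_geo: pd.DataFrame, d_pheno: pd.DataFrame,
                n_perm: int = 999, seed: int = 0) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the upper-triangle entries; the
    p-value permutes rows and columns of one matrix jointly and is
    one-sided for positive association (isolation by distance is
    directional), with the add-one convention.
    """
    common = d_geo.index.intersection(d_pheno.index)
    if len(common) < 5:
        raise ValueError("need at least 5 isolates in common")
    A = d_geo.loc[common, common].to_numpy(dtype=float)
    B = d_pheno.loc[common, common].to_numpy(dtype=float)
    for name, M in (("geographic", A), ("phenotype", B)):
        if not np.allclose(M, M.T):
            raise ValueError(f"{name} distance matrix is not symmetric")
    n = len(common)
    iu = np.triu_indices(n, k=1)
    a, b = A[iu], B[iu]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant distance matrix; Mantel r undefined")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = B[np.ix_(perm, perm)][iu]
        if np.corrcoef(a, bp)[0, 1] >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p_value=p, n_perm=n_perm, seed=seed,
                        distance_kinds=("haversine_m", "euclidean_profile"))


def race_contrast(
    sym: StandardizedYieldMatrix,
    metadata: pd.DataFrame,
    site: str,
) -> tuple[OrdinationResult, ClassificationResult]:
    """Within-site race analysis: PC summary plus LOO-LDA race accuracy."""
    md = metadata.set_index("isolate_id")
    in_site = md[md["site"] == site]
    races = in_site["race"].replace("", np.nan).dropna()
    counts = races.value_counts()
    usable = counts[counts >= 3]
    if len(usable) < 2:
        raise ValueError(f"need >=2 races with >=3 isolates at {site}")
    keep = races[races.isin(usable.index)].index
    values = sym.values.loc[sym.values.index.intersection(keep)]
    ordination = pca_ordination(values)
    cls = lda_loo_classification(values, races.loc[values.index],
                                 label_kind="race")
    return ordination, cls
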