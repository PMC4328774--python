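"""Yields, standardized yields, utilization calls, and diet classification.

Yield on a substrate is the blank-corrected endpoint OD:

    yield = OD(inoculated well, 72 h) - OD(same well, uninoculated plate)

Standardized yield removes overall-vigor differences between isolates:

    standardized yield = yield(isolate, substrate)
                         - mean over substrates of yield(isolate, .)

The efficiently utilized half of the substrate panel (top 50 % by grand
mean yield) is retained for all downstream statistics.  Within the
retained set the *core diet* is the set of substrates on which every
isolate at every site has a positive standardized yield; the remainder is
the *ancillary diet*.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .plate_io import ENDPOINT_H, SurveyDataset

logger = logging.getLogger(__name__)


@dataclass
class YieldMatrix:
    """Blank-corrected yields indexed by (isolate, replicate) x substrate.

    ``values`` has a two-level row MultiIndex (isolate_id, replicate) and
    one column per carbon substrate.  ``water`` holds the blank-corrected
    yields of the no-carbon wells, one column per plate type.
    """

    values: pd.DataFrame
    water: pd.DataFrame
    substrate_plate: pd.Series        # substrate -> plate_id
    site_labels: pd.Series            # isolate -> site

    @property
    def isolates(self) -> list[str]:
        return list(self.values.index.get_level_values(0).unique())

    @property
    def substrates(self) -> list[str]:
        return list(self.values.columns)

    @property
    def isolate_means(self) -> pd.DataFrame:
        """Mean yield over replicates, isolate x substrate."""
        return self.values.groupby(level=0, sort=False).mean()

    @property
    def grand_substrate_means(self) -> pd.Series:
        """Mean yield per substrate over all isolates of all sites."""
        return self.isolate_means.mean(axis=0)

    def site_means(self, subset: list[str] | None = None) -> pd.DataFrame:
        """Per-substrate mean yields within each site (site x substrate)."""
        im = self.isolate_means if subset is None else self.isolate_means[subset]
        return im.groupby(self.site_labels.reindex(im.index)).mean()

    def for_site(self, site: str) -> "YieldMatrix":
        keep = self.site_labels[self.site_labels == site].index
        mask = self.values.index.get_level_values(0).isin(keep)
        return YieldMatrix(
            values=self.values[mask],
            water=self.water[self.water.index.get_level_values(0).isin(keep)],
            substrate_plate=self.substrate_plate,
            site_labels=self.site_labels[self.site_labels == site],
        )

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack().rename("yield").reset_index()
        long.columns = ["isolate_id", "replicate", "substrate", "yield"]
        return long


@dataclass
class StandardizedYieldMatrix:
    """Row-centered isolate-mean yields over a substrate subset."""

    values: pd.DataFrame              # isolate x substrate, each row sums to ~0
    site_labels: pd.Series

    @property
    def substrates(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DietClassification:
    """Outcome of the top-50 % filter and the core/ancillary split."""

    retained: list[str]
    rank_table: pd.DataFrame          # substrate, rank, grand_mean
    core: list[str] = field(default_factory=list)
    ancillary: list[str] = field(default_factory=list)

    def diet_of(self, substrate: str) -> str:
        if substrate in self.core:
            return "core"
        if substrate in self.ancillary:
            return "ancillary"
        return "unassigned"

    def to_frame(self) -> pd.DataFrame:
        df = self.rank_table.copy()
        df["diet"] = [self.diet_of(s) for s in df["substrate"]]
        return df


# ---------------------------------------------------------------------------


def compute_yield(survey: SurveyDataset, time_h: int = ENDPOINT_H) -> YieldMatrix:
    """Blank-correct all inoculated plates at the given timepoint.

    The blank OD for each well is the mean over the survey's blank plates
    of that plate type (usually a single plate).  Negative yields are
    retained as-is; truncation would bias the variance components.
    """
    blank_od: dict[str, pd.Series] = {}
    for pid in survey.plate_map.plate_ids:
        blanks = survey.blanks(pid)
        if not blanks:
            raise ValueError(f"no blank plate for {pid}")
        blank_od[pid] = pd.concat([b.od(time_h) for b in blanks], axis=1).mean(axis=1)

    well_sub = {
        (e.plate_id, e.well): e.substrate
        for e in survey.plate_map.entries if e.is_carbon
    }
    substrates = survey.plate_map.carbon_substrates
    sub_plate = pd.Series(
        {e.substrate: e.plate_id for e in survey.plate_map.entries if e.is_carbon}
    )

    rows: dict[tuple[str, int], dict[str, float]] = {}
    water_rows: dict[tuple[str, int], dict[str, float]] = {}
    for p in survey.inoculated():
        y = p.od(time_h) - blank_od[p.plate_id]
        key = (p.isolate_id, p.replicate)
        rows.setdefault(key, {})
        water_rows.setdefault(key, {})
        for well, val in y.items():
            sub = well_sub.get((p.plate_id, well))
            if sub is None:
                water_rows[key][p.plate_id] = float(val)
            else:
                rows[key][sub] = float(val)

    values = pd.DataFrame.from_dict(rows, orient="index")[substrates]
    values.index = pd.MultiIndex.from_tuples(values.index,
                                             names=["isolate_id", "replicate"])
    values = values.sort_index()
    if values.isna().any().any():
        missing = values.columns[values.isna().any()].tolist()
        raise ValueError(f"incomplete plate coverage for substrates {missing[:5]}")
    water = pd.DataFrame.from_dict(water_rows, orient="index")
    water.index = values.index
    site_labels = survey.site_of()
    return YieldMatrix(values=values, water=water, substrate_plate=sub_plate,
                       site_labels=site_labels)


def standardize(
    ym: YieldMatrix | pd.DataFrame,
    substrate_subset: list[str] | None = None,
    site_labels: pd.Series | None = None,
) -> StandardizedYieldMatrix:
    """Row-center isolate-mean yields over a substrate subset.

    Accepts either a :class:`YieldMatrix` or an isolate x substrate frame
    of means.  Each isolate's standardized row sums to zero by
    construction; standardizing an already-centered matrix is a no-op.
    """
    if isinstance(ym, YieldMatrix):
        means = ym.isolate_means
        site_labels = ym.site_labels if site_labels is None else site_labels
    else:
        means = ym
        if site_labels is None:
            site_labels = pd.Series("site", index=means.index)
    subset = list(substrate_subset) if substrate_subset is not None else list(means.columns)
    if not subset:
        raise ValueError("substrate subset must be non-empty")
    sub = means[subset]
    centered = sub.sub(sub.mean(axis=1), axis=0)
    return StandardizedYieldMatrix(values=centered,
                                   site_labels=site_labels.reindex(centered.index))


def utilization_calls(
    ym: YieldMatrix, alpha: float = 0.01
) -> tuple[set[str], pd.DataFrame]:
    """Flag substrates utilizable by at least one isolate.

    For each substrate and isolate, a one-sided Welch t-test compares the
    isolate's replicate yields against the pooled water-well yields of the
    matching plate type; a substrate counts as utilized if any isolate is
    significant at the testwise ``alpha``.  Returns the utilized set and a
    per-substrate table with the minimum p-value across isolates.
    """
    water_by_plate = {
        pid: ym.water[pid].to_numpy(dtype=float) for pid in ym.water.columns
    }
    records = []
    utilized: set[str] = set()
    vals = ym.values
    for sub in ym.substrates:
        pid = ym.substrate_plate[sub]
        water = water_by_plate[pid]
        col = vals[sub]
        best_p = 1.0
        n_tested = 0
        for iso, reps in col.groupby(level=0, sort=False):
            x = reps.to_numpy(dtype=float)
            if len(x) < 2:
                logger.warning(
                    "utilization: isolate %s has <2 replicates on %s; skipped",
                    iso, sub,
                )
                continue
            n_tested += 1
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t, p = stats.ttest_ind(x, water, equal_var=False,
                                       alternative="greater")
            if math.isnan(p):
                p = 1.0
            best_p = min(best_p, float(p))
        if best_p < alpha:
            utilized.add(sub)
        records.append((sub, best_p, n_tested, best_p < alpha))
    table = pd.DataFrame(records,
                         columns=["substrate", "min_p", "n_isolates_tested",
                                  "utilized"])
    return utilized, table


def rank_filter_top_half(ym: YieldMatrix | pd.DataFrame) -> DietClassification:
    """Rank substrates by grand mean yield; retain the top half.

    Ranks are over all isolates of all sites pooled; ties are broken
    lexicographically by substrate name so the rule is deterministic.
    The retained count is ceil(n/2).
    """
    means = (ym.grand_substrate_means if isinstance(ym, YieldMatrix)
             else ym.mean(axis=0))
    if len(means) < 2:
        raise ValueError("need at least two carbon substrates to rank")
    order = sorted(means.index, key=lambda s: (-means[s], s))
    n_keep = math.ceil(len(order) / 2)
    rank_table = pd.DataFrame({
        "substrate": order,
        "rank": np.arange(1, len(order) + 1),
        "grand_mean": [means[s] for s in order],
    })
    return DietClassification(retained=order[:n_keep], rank_table=rank_table)


def detect_core_diet(
    sym: StandardizedYieldMatrix,
    dc: DietClassification | None = None,
) -> DietClassification:
    """Split the retained set into core and ancillary diets.

    A substrate is core iff every isolate at every site has a positive
    standardized (isolate-mean) yield on it — the universal-preference
    rule.  Everything else in the retained set is ancillary.
    """
    sites = sym.site_labels.dropna().unique()
    if len(sites) < 2:
        logger.warning("core diet detected from a single site only")
    positive_everywhere = (sym.values > 0).all(axis=0)
    core = [s for s in sym.substrates if positive_everywhere[s]]
    ancillary = [s for s in sym.substrates if not positive_everywhere[s]]
    if dc is None:
        means = sym.values.mean(axis=0)
        order = sorted(sym.substrates, key=lambda s: (-means[s], s))
        rank_table = pd.DataFrame({
            "substrate": order,
            "rank": np.arange(1, len(order) + 1),
            "grand_mean": [means[s] for s in order],
        })
        dc = DietClassification(retained=list(sym.substrates),
                                rank_table=rank_table)
    return DietClassification(retained=dc.retained, rank_table=dc.rank_table,
                              core=core, ancillary=ancillary)


def preference_counts(sym: StandardizedYieldMatrix) -> pd.DataFrame:
    """Per-substrate, per-site count of isolates with positive standardized yield."""
    sites = sym.site_labels.reindex(sym.values.index)
    positive = sym.values > 0
    return positive.groupby(sites).sum().T.astype(int)


def rank_regression(dc: DietClassification, scope: str = "all") -> float:
    """r² of an OLS fit of grand mean yield on rank.

    ``scope`` is ``"all"`` (whole retained set) or ``"ancillary"``.
    """
    table = dc.rank_table.set_index("substrate")
    if scope == "ancillary":
        subs = dc.ancillary
    elif scope == "all":
        subs = dc.retained
    else:
        raise ValueError(f"unknown scope {scope!r}")
    table = table.loc[subs]
    if len(table) < 3:
        raise ValueError("need at least 3 substrates for the rank regression")
    y = table["grand_mean"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        logger.warning("rank regression on constant yields; r^2 reported as 0")
        return 0.0
    res = stats.linregress(table["rank"].to_numpy(dtype=float), y)
    return float(res.rvalue ** 2)


def between_survey_correlation(
    means_site1: pd.Series, means_site2: pd.Series, scope: list[str] | None = None
) -> float:
    """Squared Pearson correlation of per-substrate mean yields of two surveys."""
    common = means_site1.index.intersection(means_site2.index)
    if scope is not None:
        common = common.intersection(pd.Index(scope))
    if len(common) < 3:
        raise ValueError("need at least 3 common substrates")
    r = np.corrcoef(means_site1[common], means_site2[common])[0, 1]
    return float(r ** 2)


def dye_validation_correlation(paired_plates) -> float:
    """R² between endpoint OD with and without redox dye across paired wells.

    ``paired_plates`` is an iterable of (dye plate, no-dye plate) pairs
    matched by plate type and well.
    """
    xs, ys = [], []
    for dye_plate, nodye_plate in paired_plates:
        if dye_plate.plate_id != nodye_plate.plate_id:
            raise ValueError(
                f"unpaired plates: {dye_plate.plate_id} vs {nodye_plate.plate_id}"
            )
        xs.append(dye_plate.od(ENDPOINT_H).to_numpy(dtype=float))
        ys.append(nodye_plate.od(ENDPOINT_H).to_numpy(dtype=float))
    if not xs:
        raise ValueError("no plate pairs supplied")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance across wells; R^2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r ** 2)


def inoculum_regression(
    ym: YieldMatrix, metadata: pd.DataFrame
) -> tuple[float, int]:
    """OLS of isolate mean yield (over all substrates) on inoculum density.

    Returns (r², sign of slope).  Isolates with missing density are
    dropped with a warning.
    """
    means = ym.isolate_means.mean(axis=1)
    dens = metadata.set_index("isolate_id")["inoculum_density"].reindex(means.index)
    dens = pd.to_numeric(dens, errors="coerce")
    if dens.isna().any():
        dropped = dens[dens.isna()].index.tolist()
        logger.warning("inoculum regression: dropping isolates without density: %s",
                       dropped)
    keep = dens.notna()
    if keep.sum() < 3:
        raise ValueError("need at least 3 isolates with inoculum density")
    res = stats.linregress(dens[keep].to_numpy(dtype=float),
                           means[keep].to_numpy(dtype=float))
    return float(res.rvalue ** 2), int(np.sign(res.slope))
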