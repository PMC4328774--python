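"""Reading, validation, and assembly of 96-well phenotype-microarray data.

A survey consists of optical-density (OD) readings of inoculated replicate
plates plus an uninoculated blank plate per plate type, a plate map linking
wells to carbon substrates, and a metadata table for the isolates (site,
race, coordinates, inoculum density).

File formats (all CSV, UTF-8, header row required):

* Plate OD table — columns ``plate_id, isolate_id, replicate, dye, well,
  time_h, od``; ``isolate_id`` is the sentinel ``BLANK`` for the
  uninoculated plate.
* Plate map — columns ``plate_id, well, substrate, is_carbon, diet,
  sugar_class, pathway``.
* Isolate metadata — columns ``isolate_id, site, race, latitude,
  longitude, inoculum_density``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BLANK = "BLANK"
#: canonical well addresses of a 96-well plate, row-major A1..H12
WELLS: tuple[str, ...] = tuple(f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13))
_WELL_SET = frozenset(WELLS)

#: timepoints (hours) a plate may carry; 72 h is mandatory and is the
#: endpoint used by all downstream statistics
TIMEPOINTS = (24, 48, 72)
ENDPOINT_H = 72


class PlateFormatError(ValueError):
    """Raised when a plate file or plate map violates the format contract."""


def canonical_well(well: str) -> str:
    """Canonicalize a well address to ``A1``..``H12`` (case-insensitive,

    leading zeros in the column accepted, e.g. ``a01`` -> ``A1``).
    """
    w = str(well).strip().upper()
    if len(w) < 2 or w[0] not in "ABCDEFGH":
        raise PlateFormatError(f"malformed well address {well!r}")
    try:
        col = int(w[1:])
    except ValueError:
        raise PlateFormatError(f"malformed well address {well!r}") from None
    if not 1 <= col <= 12:
        raise PlateFormatError(f"well column out of range in {well!r}")
    return f"{w[0]}{col}"


@dataclass
class SubstrateAnnotation:
    """Annotation of a single well: substrate identity and categories."""

    substrate: str
    plate_id: str
    well: str
    is_carbon: bool
    diet: str = "unassigned"          # core | ancillary | unassigned
    sugar_class: str = "other"        # pentose | hexose | other | none
    pathway: str = ""

    def __post_init__(self) -> None:
        self.well = canonical_well(self.well)
        if self.diet not in ("core", "ancillary", "unassigned"):
            raise PlateFormatError(f"unknown diet class {self.diet!r}")
        if self.sugar_class not in ("pentose", "hexose", "other", "none"):
            raise PlateFormatError(f"unknown sugar class {self.sugar_class!r}")
        if not self.is_carbon and not (
            self.diet == "unassigned" and self.sugar_class == "none"
        ):
            raise PlateFormatError(
                f"no-carbon well {self.plate_id}:{self.well} must have "
                "diet=unassigned and sugar_class=none"
            )
        if self.is_carbon and self.diet == "unassigned" and self.sugar_class == "none":
            raise PlateFormatError(
                f"carbon well {self.plate_id}:{self.well} lacks any annotation"
            )


@dataclass
class PlateMap:
    """Well-to-substrate mapping for the full plate set of a survey."""

    entries: list[SubstrateAnnotation]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.plate_id, e.well)
            if key in seen:
                raise PlateFormatError(f"duplicate well {key} in plate map")
            seen.add(key)
        for pid in self.plate_ids:
            wells = {e.well for e in self.entries if e.plate_id == pid}
            if wells != _WELL_SET:
                missing = sorted(_WELL_SET - wells)
                raise PlateFormatError(
                    f"plate map for {pid} does not cover all 96 wells "
                    f"(missing {missing[:3]}...)" if missing else
                    f"plate map for {pid} has unexpected wells"
                )
            n_water = sum(
                1 for e in self.entries if e.plate_id == pid and not e.is_carbon
            )
            if n_water != 1:
                raise PlateFormatError(
                    f"plate {pid} must have exactly one no-carbon well, found {n_water}"
                )
        carbon = [e.substrate for e in self.entries if e.is_carbon]
        if len(set(carbon)) != len(carbon):
            dupes = sorted({s for s in carbon if carbon.count(s) > 1})
            raise PlateFormatError(f"duplicate carbon substrate names: {dupes}")

    @property
    def plate_ids(self) -> list[str]:
        return sorted({e.plate_id for e in self.entries})

    @property
    def carbon_substrates(self) -> list[str]:
        """Carbon substrate names in (plate_id, well) order."""
        return [e.substrate for e in sorted(
            self.entries, key=lambda e: (e.plate_id, WELLS.index(e.well))
        ) if e.is_carbon]

    def water_well(self, plate_id: str) -> str:
        for e in self.entries:
            if e.plate_id == plate_id and not e.is_carbon:
                return e.well
        raise KeyError(plate_id)

    def annotation(self, substrate: str) -> SubstrateAnnotation:
        for e in self.entries:
            if e.substrate == substrate:
                return e
        raise KeyError(substrate)

    def substrates_with(self, *, diet: str | None = None,
                        sugar_class: str | None = None,
                        pathway: str | None = None) -> list[str]:
        out = []
        for e in self.entries:
            if not e.is_carbon:
                continue
            if diet is not None and e.diet != diet:
                continue
            if sugar_class is not None and e.sugar_class != sugar_class:
                continue
            if pathway is not None and e.pathway != pathway:
                continue
            out.append(e.substrate)
        return out

    def well_of(self, substrate: str) -> tuple[str, str]:
        e = self.annotation(substrate)
        return e.plate_id, e.well

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.plate_id, e.well, e.substrate, int(e.is_carbon), e.diet,
              e.sugar_class, e.pathway) for e in self.entries],
            columns=["plate_id", "well", "substrate", "is_carbon", "diet",
                     "sugar_class", "pathway"],
        )


@dataclass
class PlateODSet:
    """OD readings of one physical plate (one isolate-replicate or a blank).

    ``readings`` is indexed by canonical well address with one column per
    timepoint in hours; all values are dimensionless OD at 590 nm.
    """

    plate_id: str
    isolate_id: str
    replicate: int
    dye: bool
    readings: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.readings.copy()
        df.index = [canonical_well(w) for w in df.index]
        if set(df.index) != _WELL_SET or len(df.index) != 96:
            missing = sorted(_WELL_SET - set(df.index))
            raise PlateFormatError(
                f"plate {self.plate_id}/{self.isolate_id}: missing well(s) "
                f"{missing}" if missing else
                f"plate {self.plate_id}/{self.isolate_id}: duplicate wells"
            )
        df.columns = [int(c) for c in df.columns]
        if ENDPOINT_H not in df.columns:
            raise PlateFormatError(
                f"plate {self.plate_id}/{self.isolate_id}: 72 h timepoint missing"
            )
        if (df.to_numpy() < 0).any():
            raise PlateFormatError(
                f"plate {self.plate_id}/{self.isolate_id}: negative OD"
            )
        if self.replicate < 1:
            raise PlateFormatError("replicate must be >= 1")
        self.readings = df.loc[list(WELLS), sorted(df.columns)]

    @property
    def is_blank(self) -> bool:
        return self.isolate_id == BLANK

    def od(self, time_h: int = ENDPOINT_H) -> pd.Series:
        """OD of all 96 wells at the given timepoint, in well order."""
        if time_h not in self.readings.columns:
            raise KeyError(f"timepoint {time_h} h not present")
        return self.readings[time_h]


@dataclass
class SurveyDataset:
    """All plates of a survey, the plate map, and the isolate metadata."""

    plates: list[PlateODSet]
    plate_map: PlateMap
    metadata: pd.DataFrame
    #: optional (dye, no-dye) plate pairs from a dye-validation experiment
    dye_validation: list[tuple[PlateODSet, PlateODSet]] = field(default_factory=list)

    @property
    def isolate_ids(self) -> list[str]:
        return list(self.metadata["isolate_id"])

    @property
    def sites(self) -> list[str]:
        return sorted(self.metadata["site"].unique())

    def site_of(self) -> pd.Series:
        return self.metadata.set_index("isolate_id")["site"]

    def blanks(self, plate_id: str) -> list[PlateODSet]:
        return [p for p in self.plates if p.is_blank and p.plate_id == plate_id]

    def inoculated(self) -> list[PlateODSet]:
        return [p for p in self.plates if not p.is_blank]

    def n_replicates(self) -> int:
        reps = {
            (p.isolate_id, p.plate_id): 0 for p in self.inoculated()
        }
        for p in self.inoculated():
            reps[(p.isolate_id, p.plate_id)] += 1
        return max(reps.values())

    def summary(self) -> str:
        n_iso = len(self.isolate_ids)
        sites = ", ".join(
            f"{s} ({(self.metadata['site'] == s).sum()} isolates)"
            for s in self.sites
        )
        return (
            f"survey: {n_iso} isolates over sites {sites}; "
            f"{len(self.inoculated())} inoculated plates, "
            f"{sum(p.is_blank for p in self.plates)} blanks, "
            f"{self.n_replicates()} replicates per plate type"
        )


# ---------------------------------------------------------------------------
# readers / writers

_OD_COLUMNS = ["plate_id", "isolate_id", "replicate", "dye", "well", "time_h", "od"]


def _plates_from_frame(df: pd.DataFrame, source: str) -> list[PlateODSet]:
    missing = [c for c in _OD_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"{source}: missing column(s) {missing}")
    df = df.copy()
    df["well"] = df["well"].map(canonical_well)
    neg = df[df["od"] < 0]
    if len(neg):
        row = neg.iloc[0]
        raise PlateFormatError(
            f"{source}: negative OD {row['od']} at "
            f"{row['plate_id']}/{row['isolate_id']} well {row['well']}"
        )
    plates = []
    keys = ["plate_id", "isolate_id", "replicate", "dye"]
    for (pid, iso, rep, dye), grp in df.groupby(keys, sort=True):
        dup = grp.duplicated(subset=["well", "time_h"])
        if dup.any():
            row = grp[dup].iloc[0]
            raise PlateFormatError(
                f"{source}: duplicate (well, timepoint) row for "
                f"{pid}/{iso} well {row['well']} t={row['time_h']}"
            )
        readings = grp.pivot(index="well", columns="time_h", values="od")
        if readings.isna().any().any() or set(readings.index) != _WELL_SET:
            missing_wells = sorted(_WELL_SET - set(readings.index))
            raise PlateFormatError(
                f"{source}: missing well {missing_wells} on {pid}/{iso} rep {rep}"
                if missing_wells else
                f"{source}: incomplete timepoint grid on {pid}/{iso} rep {rep}"
            )
        plates.append(PlateODSet(str(pid), str(iso), int(rep), bool(int(dye)),
                                 readings))
    return plates


def read_od_table(path: str | Path) -> list[PlateODSet]:
    """Read a plate OD CSV holding one or more plates (lossless floats)."""
    df = pd.read_csv(path, float_precision="round_trip")
    return _plates_from_frame(df, str(path))


def read_plate_od(path: str | Path, plate_map: PlateMap | None = None) -> PlateODSet:
    """Read a CSV holding exactly one plate; validate against the map if given."""
    plates = read_od_table(path)
    if len(plates) != 1:
        raise PlateFormatError(
            f"{path}: expected a single plate, found {len(plates)}"
        )
    plate = plates[0]
    if plate_map is not None and plate.plate_id not in plate_map.plate_ids:
        raise PlateFormatError(
            f"{path}: unknown plate_id {plate.plate_id!r} "
            f"(map defines {plate_map.plate_ids})"
        )
    return plate


def write_od_table(plates: Iterable[PlateODSet], path: str | Path) -> None:
    """Write plates to the long CSV format (lossless round-trip)."""
    rows = []
    for p in plates:
        for t in p.readings.columns:
            for well in WELLS:
                rows.append((p.plate_id, p.isolate_id, p.replicate,
                             int(p.dye), well, t, repr(float(p.readings.at[well, t]))))
    df = pd.DataFrame(rows, columns=_OD_COLUMNS)
    df.to_csv(path, index=False)


def read_dye_pairs(path: str | Path) -> list[tuple[PlateODSet, PlateODSet]]:
    """Read (dye, no-dye) validation plate pairs from one OD CSV.

    Pairs are matched on (plate_id, isolate_id, replicate); every key must
    occur once with dye and once without.
    """
    plates = read_od_table(path)
    by_key: dict[tuple, dict[bool, PlateODSet]] = {}
    for p in plates:
        by_key.setdefault((p.plate_id, p.isolate_id, p.replicate), {})[p.dye] = p
    pairs = []
    for key, d in sorted(by_key.items()):
        if True not in d or False not in d:
            raise PlateFormatError(f"unpaired dye-validation plate {key}")
        pairs.append((d[True], d[False]))
    return pairs


def load_plate_map(path: str | Path) -> PlateMap:
    """Load and validate a plate-map CSV."""
    df = pd.read_csv(path, keep_default_na=False)
    required = ["plate_id", "well", "substrate", "is_carbon"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PlateFormatError(f"{path}: missing column(s) {missing}")
    entries = [
        SubstrateAnnotation(
            substrate=row["substrate"],
            plate_id=row["plate_id"],
            well=row["well"],
            is_carbon=bool(int(row["is_carbon"])),
            diet=row.get("diet", "unassigned") or "unassigned",
            sugar_class=row.get("sugar_class", "other") or "other",
            pathway=row.get("pathway", "") or "",
        )
        for _, row in df.iterrows()
    ]
    return PlateMap(entries)


def default_plate_map_path() -> Path:
    """Path of the shipped PM1 + PM2A plate map (190 carbon substrates)."""
    return Path(str(resources.files("phenodiet").joinpath("data/pm_plate_map.csv")))


def load_default_plate_map() -> PlateMap:
    return load_plate_map(default_plate_map_path())


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the isolate metadata CSV."""
    df = pd.read_csv(path, keep_default_na=False)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    required = ["isolate_id", "site"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PlateFormatError(f"metadata: missing column(s) {missing}")
    df = df.copy()
    if df["isolate_id"].duplicated().any():
        raise PlateFormatError("metadata: duplicate isolate_id")
    for col, lo, hi in (("latitude", -90.0, 90.0), ("longitude", -180.0, 180.0)):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.notna() & ((vals < lo) | (vals > hi))
            if bad.any():
                raise PlateFormatError(
                    f"metadata: {col} out of range for "
                    f"{df.loc[bad, 'isolate_id'].tolist()}"
                )
            df[col] = vals
    if "inoculum_density" in df.columns:
        dens = pd.to_numeric(df["inoculum_density"], errors="coerce")
        if (dens.notna() & (dens <= 0)).any():
            raise PlateFormatError("metadata: inoculum_density must be > 0")
        df["inoculum_density"] = dens
    if "race" not in df.columns:
        df["race"] = ""
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def assemble_survey(
    plates: Sequence[PlateODSet],
    plate_map: PlateMap,
    metadata: pd.DataFrame,
    dye_validation: Sequence[tuple[PlateODSet, PlateODSet]] = (),
) -> SurveyDataset:
    """Cross-validate plates, map, and metadata into a survey dataset.

    Requirements enforced: every inoculated plate's isolate appears in the
    metadata; at least one blank plate per plate type; equal replicate
    counts per isolate across plate types.
    """
    metadata = validate_metadata(metadata)
    known = set(metadata["isolate_id"])
    plate_ids = set(plate_map.plate_ids)
    for p in plates:
        if p.plate_id not in plate_ids:
            raise PlateFormatError(
                f"plate type {p.plate_id!r} not in the plate map"
            )
        if not p.is_blank and p.isolate_id not in known:
            raise PlateFormatError(
                f"plate references unknown isolate {p.isolate_id!r}"
            )
    for pid in plate_ids:
        if not any(p.is_blank and p.plate_id == pid for p in plates):
            raise PlateFormatError(f"no blank plate for {pid}")
    counts: dict[str, set[int]] = {}
    for p in plates:
        if p.is_blank:
            continue
        counts.setdefault(p.isolate_id, set())
    for iso in counts:
        per_type = {
            pid: sum(1 for p in plates
                     if not p.is_blank and p.isolate_id == iso and p.plate_id == pid)
            for pid in plate_ids
        }
        if len(set(per_type.values())) != 1:
            raise PlateFormatError(
                f"isolate {iso}: unequal replicate counts across plate types "
                f"{per_type}"
            )
    survey = SurveyDataset(
        plates=sorted(plates, key=lambda p: (p.plate_id, p.isolate_id, p.replicate)),
        plate_map=plate_map,
        metadata=metadata,
        dye_validation=list(dye_validation),
    )
    logger.info(survey.summary())
    return survey
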