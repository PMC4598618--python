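"""Survey ingest: flat CSV reading/writing, validation, latitudinal banding.

A survey record is one row per (haul, species) with catch-per-unit-effort
(CPUE, individuals per 1-h trawl).  Hauls are grouped into 30-minute
latitudinal bands and band-year cells, the unit on which every downstream
diversity statistic operates.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("trawlbeta")

#: default CSV column names; override via the ``schema`` mapping
DEFAULT_SCHEMA = {
    "haul_id": "haul_id",
    "year": "year",
    "quarter": "quarter",
    "lat": "lat",
    "lon": "lon",
    "species": "species",
    "cpue": "cpue",
    "temp": "temp",
}

BAND_WIDTH_DEG = 0.5  # 30' latitudinal bands


class SchemaError(ValueError):
    """A required column is missing from the survey file."""


class ValidationError(ValueError):
    """A record violates a range or type constraint."""


@dataclass
class TrawlSample:
    """One haul: a discrete 1-hour trawl at a point, with per-species CPUE.

    ``surface_temp`` is the near-surface (depth < 10 m) temperature in deg C
    recorded at the haul, if any.
    """

    haul_id: str
    year: int
    quarter: int
    latitude: float
    longitude: float
    cpue: dict[str, float] = field(default_factory=dict)
    surface_temp: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"haul {self.haul_id!r}: latitude {self.latitude} outside [-90, 90]"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(
                f"haul {self.haul_id!r}: longitude {self.longitude} outside [-180, 180]"
            )
        if self.quarter not in (1, 2, 3, 4):
            raise ValidationError(
                f"haul {self.haul_id!r}: quarter {self.quarter} not in 1..4"
            )
        for sp, v in self.cpue.items():
            if not sp:
                raise ValidationError(f"haul {self.haul_id!r}: empty species code")
            if v < 0:
                raise ValidationError(
                    f"haul {self.haul_id!r}: negative cpue {v} for species {sp!r}"
                )

    @property
    def species(self) -> set[str]:
        """Species recorded with positive CPUE in this haul."""
        return {s for s, v in self.cpue.items() if v > 0}


@dataclass(frozen=True)
class LatBand:
    """A contiguous half-open 30' latitude interval [lat_lo, lat_hi)."""

    index: int
    lat_lo: float
    lat_hi: float
    centroid_lat: float
    centroid_lon: float

    def contains(self, latitude: float) -> bool:
        return self.lat_lo <= latitude < self.lat_hi


@dataclass
class BandYearCell:
    """All hauls of one latitudinal band in one year: the rarefaction unit."""

    band: LatBand
    year: int
    hauls: list[TrawlSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        for h in self.hauls:
            if not self.band.contains(h.latitude):
                raise ValidationError(
                    f"haul {h.haul_id!r} latitude {h.latitude} outside band "
                    f"[{self.band.lat_lo}, {self.band.lat_hi})"
                )
            if h.year != self.year:
                raise ValidationError(
                    f"haul {h.haul_id!r} year {h.year} != cell year {self.year}"
                )

    @property
    def n_hauls(self) -> int:
        return len(self.hauls)


@dataclass
class SurveyFilterConfig:
    """Which hauls enter the analysis.

    quarter_keep
        Survey quarters retained (the survey design trawls in Q1).
    min_hauls_per_year
        Band-year cells with fewer hauls are dropped (thin cells make
        rarefaction meaningless).
    excluded_years
        Years removed outright, e.g. years with known under-sampling.
    """

    quarter_keep: frozenset[int] = frozenset({1})
    min_hauls_per_year: int = 1
    excluded_years: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.quarter_keep = frozenset(self.quarter_keep)
        self.excluded_years = frozenset(self.excluded_years)
        if self.min_hauls_per_year < 1:
            raise ValueError("min_hauls_per_year must be >= 1")


@dataclass
class DropCounts:
    """Reconciliation of every input haul: assigned or dropped, exactly once."""

    assigned: int = 0
    out_of_band: int = 0
    quarter: int = 0
    excluded_year: int = 0
    thin_cell: int = 0

    @property
    def total(self) -> int:
        return (
            self.assigned
            + self.out_of_band
            + self.quarter
            + self.excluded_year
            + self.thin_cell
        )


def read_survey(
    path, schema: Mapping[str, str] | None = None
) -> list[TrawlSample]:
    """Read a flat survey CSV into one :class:`TrawlSample` per haul.

    The file has one row per (haul, species); duplicate (haul, species)
    rows are summed with a logged warning, since survey exports commonly
    split a species across body-size classes.  Row order does not affect
    the result: hauls are returned sorted by haul id.
    """
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path, dtype={cols["haul_id"]: str, cols["species"]: str})
    required = ["haul_id", "year", "quarter", "lat", "lon", "species", "cpue"]
    for key in required:
        if cols[key] not in df.columns:
            raise SchemaError(f"missing required column {cols[key]!r}")
    has_temp = cols["temp"] in df.columns

    if df.empty:
        return []

    # validate with row numbers (1-based, header = row 1)
    for key, lo, hi in (("lat", -90.0, 90.0), ("lon", -180.0, 180.0)):
        bad = df.index[(df[cols[key]] < lo) | (df[cols[key]] > hi)]
        if len(bad):
            raise ValidationError(
                f"{key} out of range [{lo}, {hi}] at file row {bad[0] + 2}"
            )
    bad = df.index[df[cols["cpue"]] < 0]
    if len(bad):
        raise ValidationError(f"negative cpue at file row {bad[0] + 2}")
    bad = df.index[~df[cols["quarter"]].isin([1, 2, 3, 4])]
    if len(bad):
        raise ValidationError(f"quarter not in 1..4 at file row {bad[0] + 2}")

    dup = df.duplicated(subset=[cols["haul_id"], cols["species"]])
    if dup.any():
        logger.warning(
            "summed %d duplicate (haul, species) rows", int(dup.sum())
        )

    samples: list[TrawlSample] = []
    for haul_id, grp in df.groupby(cols["haul_id"], sort=True):
        first = grp.iloc[0]
        cpue = grp.groupby(cols["species"])[cols["cpue"]].sum().to_dict()
        temp = None
        if has_temp:
            t = first[cols["temp"]]
            temp = None if pd.isna(t) else float(t)
        samples.append(
            TrawlSample(
                haul_id=str(haul_id),
                year=int(first[cols["year"]]),
                quarter=int(first[cols["quarter"]]),
                latitude=float(first[cols["lat"]]),
                longitude=float(first[cols["lon"]]),
                cpue={str(s): float(v) for s, v in cpue.items()},
                surface_temp=temp,
            )
        )
    return samples


def write_survey(
    samples: Iterable[TrawlSample], path, schema: Mapping[str, str] | None = None
) -> None:
    """Write samples in the same flat dialect :func:`read_survey` reads.

    One row per (haul, species): the multiset of (haul, species, cpue)
    triples round-trips exactly.  A haul that caught nothing has no rows,
    as in real survey exports.
    """
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    rows = []
    for s in samples:
        for sp in sorted(s.cpue):
            rows.append(
                {
                    cols["haul_id"]: s.haul_id,
                    cols["year"]: s.year,
                    cols["quarter"]: s.quarter,
                    cols["lat"]: s.latitude,
                    cols["lon"]: s.longitude,
                    cols["species"]: sp,
                    cols["cpue"]: s.cpue[sp],
                    cols["temp"]: s.surface_temp,
                }
            )
    header = [
        cols[k] for k in ("haul_id", "year", "quarter", "lat", "lon", "species", "cpue", "temp")
    ]
    pd.DataFrame(rows, columns=header).to_csv(path, index=False)


def make_bands(
    lat_min: float, n_bands: int, centroid_lon: float = 0.0
) -> list[LatBand]:
    """Build ``n_bands`` contiguous half-open 0.5-degree latitude bands.

    All bands share a single configured centroid longitude so that
    between-band distance reflects latitudinal separation only.
    """
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    bands = []
    for i in range(n_bands):
        lo = lat_min + i * BAND_WIDTH_DEG
        bands.append(
            LatBand(
                index=i,
                lat_lo=lo,
                lat_hi=lo + BAND_WIDTH_DEG,
                centroid_lat=lo + BAND_WIDTH_DEG / 2.0,
                centroid_lon=centroid_lon,
            )
        )
    return bands


def assign_and_filter(
    samples: Sequence[TrawlSample],
    bands: Sequence[LatBand],
    config: SurveyFilterConfig,
    return_counts: bool = False,
):
    """Assign hauls to band-year cells, dropping out-of-scope hauls.

    Every haul ends in exactly one cell or one drop category (out-of-band,
    wrong quarter, excluded year, thin cell); the reconciliation totals are
    logged and returned when ``return_counts`` is set.  Band membership is
    half-open: a haul at exactly the upper edge of band *i* belongs to band
    *i + 1*.  Returned cells are sorted by (band index, year).
    """
    if not bands:
        raise ValueError("bands must be non-empty")
    counts = DropCounts()
    bins: dict[tuple[int, int], list[TrawlSample]] = {}
    band_by_index = {b.index: b for b in bands}
    for s in samples:
        if s.quarter not in config.quarter_keep:
            counts.quarter += 1
            continue
        if s.year in config.excluded_years:
            counts.excluded_year += 1
            continue
        band = next((b for b in bands if b.contains(s.latitude)), None)
        if band is None:
            counts.out_of_band += 1
            continue
        bins.setdefault((band.index, s.year), []).append(s)

    cells: list[BandYearCell] = []
    for (bi, year), hauls in sorted(bins.items()):
        if len(hauls) < config.min_hauls_per_year:
            counts.thin_cell += len(hauls)
            logger.warning(
                "DROP thin_cell band=%d year=%d hauls=%d min=%d",
                bi, year, len(hauls), config.min_hauls_per_year,
            )
            continue
        counts.assigned += len(hauls)
        cells.append(BandYearCell(band=band_by_index[bi], year=year, hauls=hauls))

    logger.info(
        "FILTER assigned=%d out_of_band=%d quarter=%d excluded_year=%d thin_cell=%d",
        counts.assigned, counts.out_of_band, counts.quarter,
        counts.excluded_year, counts.thin_cell,
    )
    if not cells:
        logger.warning("FILTER produced no cells")
    if return_counts:
        return cells, counts
    return cells


def tally_species(samples: Iterable[TrawlSample]) -> Counter:
    """Total CPUE per species across hauls (convenience for reports)."""
    c: Counter = Counter()
    for s in samples:
        c.update(s.cpue)
    return c
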