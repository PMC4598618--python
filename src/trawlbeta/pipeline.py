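"""End-to-end orchestration: ingest -> filter -> rarefy -> diversity ->
trends -> temperature link -> tidy-CSV report.

A run is fully determined by its :class:`RunConfig` (including the seed):
rerunning with the same config produces byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .survey_io import (
    BandYearCell,
    DropCounts,
    SurveyFilterConfig,
    TrawlSample,
    assign_and_filter,
    make_bands,
    read_survey,
)
from .diversity import (
    PartitionResult,
    cell_rng,
    pair_counts,
    partition_jaccard,
    rarefied_pooled_draw,
    rarefy_cell,
)
from .trends import (
    AlignmentError,
    BaselineSeries,
    DegenerateFitError,
    DistanceMatrix,
    FitResult,
    HomogenizationTrend,
    SimilarityMatrix,
    TemperatureReport,
    annual_pairwise_similarity,
    band_distance_matrix,
    baseline_beta_series,
    distance_decay,
    homogenization_trend,
    ols_fit,
    temperature_analyses,
    temperature_table,
)

logger = logging.getLogger("trawlbeta")

ALPHA_LEVEL = 0.05  # two-sided flagging level for per-band trend displays


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    effort_policy
        ``"min"`` rarefies every cell to the smallest post-filter cell size
        (equal sampling effort across bands and years); an integer fixes
        the effort for cross-dataset comparability.
    replicates
        Rarefied draws per similarity estimate.
    rarefaction_replicates
        Monte-Carlo draws for the alpha-richness rarefaction.
    """

    survey_path: str | None = None
    lat_min: float = 55.0
    n_bands: int = 9
    filter: SurveyFilterConfig = field(default_factory=SurveyFilterConfig)
    effort_policy: str | int = "min"
    metric: str = "jaccard"
    replicates: int = 100
    rarefaction_replicates: int = 1000
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.rarefaction_replicates < 1:
            raise ValueError("replicates must be >= 1")
        if isinstance(self.effort_policy, str) and self.effort_policy != "min":
            raise ValueError("effort_policy must be 'min' or an integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "filter" in raw:
            raw["filter"] = SurveyFilterConfig(**raw["filter"])
        return cls(**raw)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # the analysis, not where it is written
        d["filter"] = {
            "quarter_keep": sorted(self.filter.quarter_keep),
            "min_hauls_per_year": self.filter.min_hauls_per_year,
            "excluded_years": sorted(self.filter.excluded_years),
        }
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class BandTrend:
    band_index: int
    fit: FitResult
    significant_negative: bool
    significant_positive: bool


@dataclass
class RunReport:
    """All pipeline outputs plus the provenance block."""

    effort: int
    drop_counts: DropCounts
    alpha: pd.DataFrame
    alpha_band_trends: list[BandTrend]
    alpha_overall: FitResult | None
    baselines: dict[int, BaselineSeries]
    sim_matrices: list[SimilarityMatrix]
    homogenization: HomogenizationTrend | None
    distance: DistanceMatrix
    decay_fits: dict[int, FitResult]
    decay_slope_trend: FitResult | None
    partitions: pd.DataFrame
    turnover_share: float | None
    nestedness_share: float | None
    temperature: TemperatureReport | None
    provenance: dict


def turnover_share(partitions: Iterable[PartitionResult]) -> float:
    """Mean relative contribution of turnover to Jaccard dissimilarity.

    Comparisons with beta_jac = 0 carry no dissimilarity to attribute and
    are excluded (their count is logged).
    """
    shares = []
    skipped = 0
    for p in partitions:
        if p.beta_jac > 0:
            shares.append(p.beta_jtu / p.beta_jac)
        else:
            skipped += 1
    if skipped:
        logger.info("turnover_share: excluded %d zero-dissimilarity pairs", skipped)
    if not shares:
        raise ValueError("no comparison with beta_jac > 0")
    return float(np.mean(shares))


def _annual_pairwise_partitions(
    cells: Sequence[BandYearCell], effort: int, replicates: int, seed: int
) -> pd.DataFrame:
    """Replicate-averaged turnover/nestedness partition per band pair-year.

    Uses a draw stream distinct from the similarity stream (keyed with an
    extra component) so adding or removing analysis stages never perturbs
    each other's random draws.
    """
    by_year: dict[int, list[BandYearCell]] = {}
    for c in cells:
        by_year.setdefault(c.year, []).append(c)
    rows = []
    for year in sorted(by_year):
        ycells = sorted(by_year[year], key=lambda c: c.band.index)
        if len(ycells) < 2:
            continue
        gens = {
            c.band.index: np.random.default_rng(
                np.random.SeedSequence(
                    entropy=[int(seed), int(c.band.index), int(year), 7]
                )
            )
            for c in ycells
        }
        k = len(ycells)
        acc = np.zeros((k, k, 3))
        for _ in range(replicates):
            draws = [
                rarefied_pooled_draw(c, min(effort, c.n_hauls), gens[c.band.index])
                for c in ycells
            ]
            for i in range(k):
                for j in range(i + 1, k):
                    p = partition_jaccard(pair_counts(draws[i], draws[j]))
                    acc[i, j] += (p.beta_jac, p.beta_jtu, p.beta_jne)
        for i in range(k):
            for j in range(i + 1, k):
                jac, jtu, jne = acc[i, j] / replicates
                rows.append(
                    {
                        "year": year,
                        "band_i": ycells[i].band.index,
                        "band_j": ycells[j].band.index,
                        "beta_jac": jac,
                        "beta_jtu": jtu,
                        "beta_jne": jne,
                    }
                )
    return pd.DataFrame(
        rows, columns=["year", "band_i", "band_j", "beta_jac", "beta_jtu", "beta_jne"]
    )


def run_from_samples(
    samples: Sequence[TrawlSample], config: RunConfig
) -> RunReport:
    """Run the full analysis on in-memory samples (see :func:`run`)."""
    stage = "banding"
    try:
        lons = [s.longitude for s in samples]
        centroid_lon = float(np.mean(lons)) if lons else 0.0
        bands = make_bands(config.lat_min, config.n_bands, centroid_lon=centroid_lon)
        cells, drops = assign_and_filter(
            samples, bands, config.filter, return_counts=True
        )
        if not cells:
            raise ValueError("no band-year cells survive filtering")

        stage = "effort"
        if config.effort_policy == "min":
            effort = min(c.n_hauls for c in cells)
        else:
            effort = int(config.effort_policy)
            if effort > min(c.n_hauls for c in cells):
                raise ValueError(
                    f"fixed effort {effort} exceeds the smallest cell"
                )
        logger.info("rarefaction effort = %d hauls", effort)

        stage = "alpha"
        alpha_rows = []
        for c in cells:
            rr = rarefy_cell(
                c, effort, config.rarefaction_replicates,
                rng=cell_rng(config.seed, c.band.index, c.year),
            )
            alpha_rows.append(
                {
                    "band": c.band.index,
                    "year": c.year,
                    "n_hauls": c.n_hauls,
                    "rarefied_richness": rr.mean_richness,
                    "sd": rr.sd_richness,
                    "expected_richness": rr.analytic_expectation,
                }
            )
        alpha = pd.DataFrame(alpha_rows).sort_values(["band", "year"]).reset_index(drop=True)
        band_trends = []
        for b, grp in alpha.groupby("band"):
            if len(grp) >= 3 and grp["year"].nunique() >= 3:
                fit = ols_fit(grp["year"], grp["rarefied_richness"])
                band_trends.append(
                    BandTrend(
                        band_index=int(b),
                        fit=fit,
                        significant_negative=fit.p_value < ALPHA_LEVEL and fit.slope < 0,
                        significant_positive=fit.p_value < ALPHA_LEVEL and fit.slope > 0,
                    )
                )
        alpha_overall = None
        if alpha["year"].nunique() >= 3:
            alpha_overall = ols_fit(alpha["year"], alpha["rarefied_richness"])

        stage = "baseline_beta"
        baselines: dict[int, BaselineSeries] = {}
        by_band: dict[int, list[BandYearCell]] = {}
        for c in cells:
            by_band.setdefault(c.band.index, []).append(c)
        for b, bcells in sorted(by_band.items()):
            if len(bcells) >= 2:
                baselines[b] = baseline_beta_series(
                    bcells, effort, metric=config.metric,
                    replicates=config.replicates, seed=config.seed,
                )

        stage = "spatial_beta"
        sim_matrices = annual_pairwise_similarity(
            cells, effort, metric=config.metric,
            replicates=config.replicates, seed=config.seed,
        )
        homog = None
        if len(sim_matrices) >= 3:
            homog = homogenization_trend(sim_matrices)

        stage = "distance_decay"
        distance = band_distance_matrix(bands)
        decay_fits: dict[int, FitResult] = {}
        for m in sim_matrices:
            if len(m.labels) >= 3:
                decay_fits[m.year] = distance_decay(m, distance)
        decay_slope_trend = None
        if len(decay_fits) >= 3:
            yrs = sorted(decay_fits)
            decay_slope_trend = ols_fit(yrs, [decay_fits[y].slope for y in yrs])

        stage = "partition"
        partitions = _annual_pairwise_partitions(
            cells, effort, config.replicates, config.seed
        )
        t_share = n_share = None
        if len(partitions) and (partitions["beta_jac"] > 0).any():
            valid = partitions[partitions["beta_jac"] > 0]
            t_share = float((valid["beta_jtu"] / valid["beta_jac"]).mean())
            n_share = 1.0 - t_share

        stage = "temperature"
        temps = temperature_table(cells)
        temperature = None
        if temps.mean:
            try:
                temperature = temperature_analyses(temps, sim_matrices, bands)
            except (AlignmentError, DegenerateFitError, ValueError) as e:
                logger.warning("temperature analyses skipped: %s", e)

        stage = "provenance"
        provenance = {
            "config_digest": RunConfig.digest(config),
            "seed": config.seed,
            "effort": effort,
            "n_cells": len(cells),
            "drop_counts": dataclasses.asdict(drops),
            "versions": {
                "trawlbeta": _version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
    except Exception as e:  # tag the failing stage
        raise StageError(f"[{stage}] {e}") from e

    return RunReport(
        effort=effort,
        drop_counts=drops,
        alpha=alpha,
        alpha_band_trends=band_trends,
        alpha_overall=alpha_overall,
        baselines=baselines,
        sim_matrices=sim_matrices,
        homogenization=homog,
        distance=distance,
        decay_fits=decay_fits,
        decay_slope_trend=decay_slope_trend,
        partitions=partitions,
        turnover_share=t_share,
        nestedness_share=n_share,
        temperature=temperature,
        provenance=provenance,
    )


def _version() -> str:
    from . import __version__

    return __version__


def run(config: RunConfig) -> RunReport:
    """Read the survey, run every stage, and (optionally) write the report.

    On any stage failure partial outputs are removed and a stage-tagged
    :class:`StageError` is raised.
    """
    if config.survey_path is None:
        raise ValueError("config.survey_path is required")
    samples = read_survey(config.survey_path)
    report = run_from_samples(samples, config)
    if config.outdir is not None:
        write_report(report, config.outdir)
    return report


# ---------------------------------------------------------------------------
# tidy CSV export
# ---------------------------------------------------------------------------

def _fit_row(name: str, fit: FitResult | None, **extra) -> dict:
    if fit is None:
        return {}
    row = {
        "name": name,
        "method": fit.method,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "stat": fit.stat,
        "r_squared": fit.r_squared,
        "p_value": fit.p_value,
        "n": fit.n,
    }
    row.update(extra)
    return row


def write_report(report: RunReport, outdir: str | Path) -> list[Path]:
    """Write the report as tidy CSV tables plus a provenance JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        def _write(name: str, df: pd.DataFrame) -> None:
            p = outdir / name
            df.to_csv(p, index=False)
            written.append(p)

        _write("alpha.csv", report.alpha)

        rows = [
            {
                "band": bs.band_index,
                "year": y,
                "similarity": s,
                "year0": bs.year0,
                "within_baseline": bs.within_baseline,
            }
            for bs in report.baselines.values()
            for y, s in sorted(bs.similarity.items())
        ]
        _write("baseline_beta.csv", pd.DataFrame(
            rows, columns=["band", "year", "similarity", "year0", "within_baseline"]
        ))

        rows = [
            {"year": m.year, "band_i": i, "band_j": j, "similarity": s}
            for m in report.sim_matrices
            for i, j, s in m.pairs()
        ]
        _write("pairwise_similarity.csv", pd.DataFrame(
            rows, columns=["year", "band_i", "band_j", "similarity"]
        ))

        fits = []
        for bt in report.alpha_band_trends:
            fits.append(_fit_row(
                f"alpha_band_{bt.band_index}", bt.fit,
                flag_negative=bt.significant_negative,
                flag_positive=bt.significant_positive,
            ))
        fits.append(_fit_row("alpha_overall", report.alpha_overall))
        if report.homogenization is not None:
            fits.append(_fit_row("homogenization_pairs", report.homogenization.fit_pairs))
            fits.append(_fit_row("homogenization_annual", report.homogenization.fit_annual))
        fits.append(_fit_row("decay_slope_trend", report.decay_slope_trend))
        if report.temperature is not None:
            t = report.temperature
            fits.append(_fit_row("temperature_warming", t.warming_fit))
            fits.append(_fit_row("temperature_gradient_trend", t.gradient_trend))
            fits.append(_fit_row("temp_diff_vs_dissimilarity", t.temp_dissim_fit))
            fits.append(_fit_row("temp_diff_vs_similarity", t.temp_sim_fit))
        _write("trends.csv", pd.DataFrame(
            [r for r in fits if r],
            columns=["name", "method", "slope", "intercept", "stat",
                     "r_squared", "p_value", "n",
                     "flag_negative", "flag_positive"],
        ))

        rows = [
            {"year": y, "slope": f.slope, "intercept": f.intercept,
             "objective": f.objective, "n": f.n}
            for y, f in sorted(report.decay_fits.items())
        ]
        _write("decay.csv", pd.DataFrame(
            rows, columns=["year", "slope", "intercept", "objective", "n"]
        ))

        _write("partition.csv", report.partitions)

        trows = []
        if report.temperature is not None:
            t = report.temperature
            for y in sorted(set(t.annual_mean_diff) | set(t.gradient_slopes)):
                trows.append({
                    "year": y,
                    "mean_pairwise_temp_diff": t.annual_mean_diff.get(y),
                    "gradient_slope": t.gradient_slopes.get(y),
                })
        _write("temperature.csv", pd.DataFrame(
            trows, columns=["year", "mean_pairwise_temp_diff", "gradient_slope"]
        ))

        summary = dict(report.provenance)
        summary["turnover_share"] = report.turnover_share
        summary["nestedness_share"] = report.nestedness_share
        p = outdir / "provenance.json"
        p.write_text(json.dumps(summary, indent=1, sort_keys=True))
        written.append(p)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return written
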