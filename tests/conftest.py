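"""Shared fixtures: a hand-computed toy survey and seeded regime ensembles."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from trawlbeta import (
    RunConfig,
    SimConfig,
    TrawlSample,
    ols_fit,
    run_from_samples,
    simulate_survey,
    spearman_permutation_pvalue,
)


def toy_samples() -> list[TrawlSample]:
    """Two bands x three years, one haul per cell.

    Communities are small species sets whose Jaccard similarities,
    turnover/nestedness partitions and trend fits are all computed by hand
    in the tests that consume this fixture.
    """
    def haul(hid, year, lat, cpue, temp):
        return TrawlSample(
            haul_id=hid, year=year, quarter=1, latitude=lat, longitude=-7.0,
            cpue=cpue, surface_temp=temp,
        )

    return [
        # band 0: [55.0, 55.5)
        haul("b0y0", 2000, 55.1, {"A": 2, "B": 1, "C": 1, "D": 1}, 9.0),
        haul("b0y1", 2001, 55.2, {"A": 2, "B": 1, "C": 1, "E": 1}, 9.2),
        haul("b0y2", 2002, 55.3, {"A": 2, "B": 1, "E": 1, "F": 1}, 9.4),
        # band 1: [55.5, 56.0)
        haul("b1y0", 2000, 55.6, {"C": 1, "D": 2, "E": 1}, 8.0),
        haul("b1y1", 2001, 55.7, {"B": 1, "C": 2, "D": 1}, 8.5),
        haul("b1y2", 2002, 55.8, {"A": 1, "B": 1, "C": 1, "D": 1}, 9.0),
    ]


@pytest.fixture
def toy_survey():
    return toy_samples()


@pytest.fixture
def toy_run_config():
    return RunConfig(lat_min=55.0, n_bands=2, seed=0, replicates=3)


# ---------------------------------------------------------------------------
# regime ensembles: per-seed summary statistics of the full pipeline on the
# three generator regimes (gradient converging / stationary / drifting as a
# whole).  Session-scoped: acceptance and property tests share them.
# ---------------------------------------------------------------------------

N_ENSEMBLE_SEEDS = 100


def _pipeline_stats(cfg: SimConfig, seed: int) -> dict:
    cfg = dataclasses.replace(cfg, seed=seed)
    samples, _ = simulate_survey(cfg)
    rep = run_from_samples(samples, RunConfig(seed=seed, replicates=1))
    h = rep.homogenization
    yrs = sorted(rep.decay_fits)
    third = len(yrs) // 3
    early = float(np.mean([abs(rep.decay_fits[y].slope) for y in yrs[:third]]))
    late = float(np.mean([abs(rep.decay_fits[y].slope) for y in yrs[-third:]]))
    dst = rep.decay_slope_trend

    # pooled decline of the within-band baseline similarity series
    bx, by = [], []
    for bl in rep.baselines.values():
        for y, s in bl.similarity.items():
            bx.append(y)
            by.append(s)
    bfit = ols_fit(bx, by)

    # permutation trigger for the temperature-difference / dissimilarity link
    t = rep.temperature
    ann_sim = {
        m.year: float(np.nanmean(m.values[np.triu_indices(len(m.labels), 1)]))
        for m in rep.sim_matrices
    }
    common = sorted(set(t.annual_mean_diff) & set(ann_sim))
    d = [t.annual_mean_diff[y] for y in common]
    dis = [1.0 - ann_sim[y] for y in common]
    td_rs, td_p = spearman_permutation_pvalue(d, dis, n_perm=199, rng=seed)

    return {
        "trend_sig_pos": (h.fit_annual.p_value < 0.05) and (h.fit_annual.slope > 0),
        "trend_sig": h.fit_annual.p_value < 0.05,
        "pair_slope": h.fit_pairs.slope,
        "pair_r2": h.fit_pairs.r_squared,
        "decay_late_flatter": late < early,
        "decay_flat_trig": (dst is not None)
        and (dst.p_value < 0.05)
        and (dst.slope > 0),
        "alpha_sig": rep.alpha_overall.p_value < 0.05,
        "baseline_declines": (bfit.slope < 0) and (bfit.p_value < 0.05),
        "temp_assoc_trig": td_p < 0.05,
        "mean_richness": float(rep.alpha["rarefied_richness"].mean()),
    }


def _ensemble(cfg: SimConfig) -> dict[str, np.ndarray]:
    rows = [_pipeline_stats(cfg, seed) for seed in range(N_ENSEMBLE_SEEDS)]
    return {k: np.array([r[k] for r in rows]) for k in rows[0]}


@pytest.fixture(scope="session")
def ensemble_convergent():
    return _ensemble(SimConfig())


@pytest.fixture(scope="session")
def ensemble_stationary():
    return _ensemble(SimConfig(warming_rate_south=0.0, warming_rate_north=0.0))


@pytest.fixture(scope="session")
def ensemble_symmetric():
    return _ensemble(SimConfig(warming_rate_south=0.03, warming_rate_north=0.03))
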