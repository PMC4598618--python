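"""Community-level statistics.

Incidence bookkeeping, Jaccard and Bray-Curtis similarity, partitioning of
Jaccard dissimilarity into its turnover and nestedness components, and
sample-based rarefaction of band-year cells with an analytic
(hypergeometric) expectation alongside the Monte-Carlo estimate.

Incidence is "abundance > 0": no minimum-CPUE threshold is applied.
Comparisons of two empty assemblages raise :class:`UndefinedIndexError`
rather than returning an arbitrary 0 or 1 — a silent placeholder would
corrupt downstream trend fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .survey_io import BandYearCell, TrawlSample


class UndefinedIndexError(ValueError):
    """Similarity index undefined (e.g. both assemblages empty)."""


# ---------------------------------------------------------------------------
# pooled communities and incidence bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class PooledCommunity:
    """Summed CPUE across a set of hauls; species at 0 are dropped."""

    species_abundance: dict[str, float]
    n_hauls: int

    def __post_init__(self) -> None:
        self.species_abundance = {
            s: float(v) for s, v in self.species_abundance.items() if v > 0
        }
        if self.n_hauls < 1:
            raise ValueError("n_hauls must be >= 1")

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.species_abundance)

    @property
    def richness(self) -> int:
        return len(self.species_abundance)


def pool_hauls(hauls: Iterable[TrawlSample]) -> PooledCommunity:
    """Pool hauls into one community by summing CPUE per species."""
    abundance: dict[str, float] = {}
    n = 0
    for h in hauls:
        n += 1
        for sp, v in h.cpue.items():
            if v > 0:
                abundance[sp] = abundance.get(sp, 0.0) + v
    if n == 0:
        raise ValueError("cannot pool zero hauls")
    return PooledCommunity(species_abundance=abundance, n_hauls=n)


@dataclass(frozen=True)
class PairCounts:
    """Incidence components of a two-assemblage comparison.

    a: species shared; b: only in the first; c: only in the second.
    """

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("pair counts must be non-negative")


def pair_counts(x: PooledCommunity, y: PooledCommunity) -> PairCounts:
    sx, sy = x.species, y.species
    if not sx and not sy:
        raise UndefinedIndexError("both communities empty")
    return PairCounts(a=len(sx & sy), b=len(sx - sy), c=len(sy - sx))


# ---------------------------------------------------------------------------
# similarity indices and the turnover/nestedness partition
# ---------------------------------------------------------------------------

def jaccard_similarity(pc: PairCounts) -> float:
    """Shared-species fraction a / (a + b + c)."""
    denom = pc.a + pc.b + pc.c
    if denom == 0:
        raise UndefinedIndexError("Jaccard undefined for two empty communities")
    return pc.a / denom


def bray_curtis_similarity(x: PooledCommunity, y: PooledCommunity) -> float:
    """Abundance-weighted similarity 1 - sum|x-y| / sum(x+y) over the union."""
    total = sum(x.species_abundance.values()) + sum(y.species_abundance.values())
    if total == 0:
        raise UndefinedIndexError("Bray-Curtis undefined: no abundance")
    diff = 0.0
    for sp in x.species | y.species:
        diff += abs(x.species_abundance.get(sp, 0.0) - y.species_abundance.get(sp, 0.0))
    return 1.0 - diff / total


@dataclass(frozen=True)
class PartitionResult:
    """Jaccard dissimilarity split into turnover + nestedness components.

    beta_jac = beta_jtu + beta_jne.  Turnover (beta_jtu) is insensitive to
    richness differences; nestedness (beta_jne) captures subset-like
    impoverishment.
    """

    beta_jac: float
    beta_jtu: float
    beta_jne: float


def partition_jaccard(pc: PairCounts) -> PartitionResult:
    """Partition pairwise Jaccard dissimilarity into turnover and nestedness.

    beta_jac = (b+c)/(a+b+c);  beta_jtu = 2*min(b,c) / (a + 2*min(b,c));
    beta_jne = beta_jac - beta_jtu.
    """
    a, b, c = pc.a, pc.b, pc.c
    denom = a + b + c
    if denom == 0:
        raise UndefinedIndexError("partition undefined for two empty communities")
    beta_jac = (b + c) / denom
    m = min(b, c)
    beta_jtu = 0.0 if (a + 2 * m) == 0 else (2 * m) / (a + 2 * m)
    return PartitionResult(
        beta_jac=beta_jac, beta_jtu=beta_jtu, beta_jne=beta_jac - beta_jtu
    )


# ---------------------------------------------------------------------------
# sample-based rarefaction (the haul is the sampling unit)
# ---------------------------------------------------------------------------

@dataclass
class RarefactionResult:
    target_effort: int
    replicates: int
    mean_richness: float
    sd_richness: float
    analytic_expectation: float


def cell_rng(seed: int, band_index: int, year: int) -> np.random.Generator:
    """Deterministic per-cell random stream keyed by (band, year).

    Keying substreams on cell identity makes every cell's draws independent
    of the order in which cells are processed.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=[int(seed), int(band_index), int(year)])
    )


def expected_rarefied_richness(occupancy: Iterable[int], m: int, n: int) -> float:
    """Hypergeometric expectation of richness after drawing n of m hauls.

    E[S] = sum_i [1 - C(m - m_i, n) / C(m, n)], where m_i is the number of
    hauls occupied by species i.
    """
    if not 1 <= n <= m:
        raise ValueError("need 1 <= n <= m")
    denom = math.comb(m, n)
    e = 0.0
    for mi in occupancy:
        e += 1.0 - (math.comb(m - mi, n) / denom if m - mi >= n else 0.0)
    return e


def _incidence_matrix(cell: BandYearCell) -> tuple[np.ndarray, list[str]]:
    """Boolean hauls x species matrix and the species order."""
    species = sorted({sp for h in cell.hauls for sp in h.species})
    idx = {sp: j for j, sp in enumerate(species)}
    mat = np.zeros((len(cell.hauls), len(species)), dtype=bool)
    for i, h in enumerate(cell.hauls):
        for sp in h.species:
            mat[i, idx[sp]] = True
    return mat, species


def rarefy_cell(
    cell: BandYearCell,
    target_effort: int,
    replicates: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> RarefactionResult:
    """Monte-Carlo sample-based rarefaction of one band-year cell.

    Each replicate draws ``target_effort`` hauls uniformly without
    replacement, pools them, and counts distinct species.  The analytic
    hypergeometric expectation is reported alongside the Monte-Carlo mean.
    No extrapolation beyond the available hauls.
    """
    m = cell.n_hauls
    if not 1 <= target_effort <= m:
        raise ValueError(
            f"target_effort must be in [1, {m}], got {target_effort}"
        )
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(rng)

    inc, _ = _incidence_matrix(cell)
    occupancy = inc.sum(axis=0)

    if target_effort == m:
        pooled = int((occupancy > 0).sum())
        return RarefactionResult(
            target_effort=m, replicates=replicates,
            mean_richness=float(pooled), sd_richness=0.0,
            analytic_expectation=float(pooled),
        )

    # vectorised draws: argsort of uniform noise gives random subsets
    order = np.argsort(rng.random((replicates, m)), axis=1)[:, :target_effort]
    rich = inc[order].any(axis=1).sum(axis=1)
    return RarefactionResult(
        target_effort=target_effort,
        replicates=replicates,
        mean_richness=float(rich.mean()),
        sd_richness=float(rich.std(ddof=1)) if replicates > 1 else 0.0,
        analytic_expectation=expected_rarefied_richness(occupancy, m, target_effort),
    )


def rarefied_pooled_draw(
    cell: BandYearCell,
    target_effort: int,
    rng: np.random.Generator | int | None = None,
) -> PooledCommunity:
    """One uniform draw of ``target_effort`` hauls pooled into a community.

    Similarity metrics are computed on such equal-effort draws per
    replicate and then averaged; averaging communities first would bias
    incidence-based indices.
    """
    m = cell.n_hauls
    if not 1 <= target_effort <= m:
        raise ValueError(
            f"target_effort must be in [1, {m}], got {target_effort}"
        )
    rng = np.random.default_rng(rng)
    if target_effort == m:
        return pool_hauls(cell.hauls)
    chosen = rng.choice(m, size=target_effort, replace=False)
    return pool_hauls([cell.hauls[i] for i in chosen])
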