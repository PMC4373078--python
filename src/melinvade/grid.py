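"""Spatial randomization of invasion localities against human population.

Two tests on a masked raster of per-cell human population counts:

1. Threshold split: cells are divided at a density threshold (people/km²,
   converted to people/cell via the cell area); the probability that k
   uniformly placed localities all fall in the high group is
   (n_high / n_total)^k, with the without-replacement hypergeometric
   analogue reported alongside.

2. Resampling null: the summed count over the k invaded cells is compared
   with the sums of k-cell sets drawn uniformly (without replacement) from
   the mask; the empirical p is the fraction of draws strictly exceeding
   the observed sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

DEFAULT_CELL_AREA_KM2 = 21.0


@dataclass
class PopulationGrid:
    values: np.ndarray            # 2-D counts, people per cell
    mask: np.ndarray              # 2-D bool, included cells
    cell_area: float = DEFAULT_CELL_AREA_KM2
    nodata: float = -9999.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if np.any(self.values[self.mask] < 0):
            raise ValueError("negative population count on a masked cell")

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass(frozen=True)
class Site:
    locality: str
    row: int
    col: int


@dataclass
class InvasionSites:
    sites: list[Site]

    def __len__(self) -> int:
        return len(self.sites)

    def validate_against(self, grid: PopulationGrid) -> None:
        for s in self.sites:
            if not (0 <= s.row < grid.mask.shape[0]
                    and 0 <= s.col < grid.mask.shape[1]):
                raise ValueError(f"site {s.locality!r} off the grid")
            if not grid.mask[s.row, s.col]:
                raise ValueError(f"site {s.locality!r} falls on an unmasked cell")

    @classmethod
    def from_cells(cls, cells, labels=None) -> "InvasionSites":
        labels = labels or [f"site{i + 1}" for i in range(len(cells))]
        dedup: dict[tuple[int, int], Site] = {}
        for (r, c), lab in zip(cells, labels):
            dedup.setdefault((int(r), int(c)), Site(lab, int(r), int(c)))
        return cls(list(dedup.values()))


def read_ascii_grid(path, cell_area: float | None = None,
                    mask: np.ndarray | None = None) -> PopulationGrid:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize
    [/NODATA_value] header followed by a numeric body).

    NODATA cells are unmasked; an explicit boolean mask further restricts
    the included region.  cell_area defaults to ~21 km² (the resolution of
    the gridded-population product the analysis emulates).
    """
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value") and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for req in ("ncols", "nrows"):
        if req not in header:
            raise ValueError(f"missing {req} in ESRI ASCII header")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    body = np.array([x for r in rows for x in r], dtype=float)
    if body.size != nrows * ncols:
        raise ValueError(
            f"grid body has {body.size} values; header promises {nrows * ncols}")
    values = body.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    m = (values != nodata) & ~np.isnan(values)
    if mask is not None:
        m = m & np.asarray(mask, dtype=bool)
    return PopulationGrid(values=values, mask=m,
                          cell_area=cell_area or DEFAULT_CELL_AREA_KM2,
                          nodata=nodata,
                          xllcorner=header.get("xllcorner", 0.0),
                          yllcorner=header.get("yllcorner", 0.0),
                          cellsize=header.get("cellsize", 1.0))


def write_ascii_grid(grid: PopulationGrid, path, fmt: str = "%.6g") -> None:
    values = np.where(grid.mask, grid.values, grid.nodata)
    nrows, ncols = values.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.6g}\n")
        fh.write(f"yllcorner {grid.yllcorner:.6g}\n")
        fh.write(f"cellsize {grid.cellsize:.6g}\n")
        fh.write(f"NODATA_value {grid.nodata:.6g}\n")
        np.savetxt(fh, values, fmt=fmt)


def read_sites_csv(path, grid: PopulationGrid | None = None) -> InvasionSites:
    """Sites CSV with columns (locality,row,col) or (locality,lon,lat).

    Lon/lat are converted with the grid's affine header (row 0 = top).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    cells, labels = [], []
    if {"row", "col"} <= cols:
        for _, r in df.iterrows():
            cells.append((int(r["row"]), int(r["col"])))
            labels.append(str(r.get("locality", f"site{len(labels) + 1}")))
    elif {"lon", "lat"} <= cols:
        if grid is None:
            raise ValueError("lon/lat sites need the grid for georeferencing")
        nrows = grid.values.shape[0]
        for _, r in df.iterrows():
            col = int((r["lon"] - grid.xllcorner) / grid.cellsize)
            row = nrows - 1 - int((r["lat"] - grid.yllcorner) / grid.cellsize)
            cells.append((row, col))
            labels.append(str(r.get("locality", f"site{len(labels) + 1}")))
    else:
        raise ValueError("sites CSV needs (locality,row,col) or (locality,lon,lat)")
    return InvasionSites.from_cells(cells, labels)


def write_sites_csv(sites: InvasionSites, path) -> None:
    pd.DataFrame([asdict(s) for s in sites.sites]).to_csv(path, index=False)


@dataclass
class SplitTestResult:
    threshold_density: float
    threshold_count: float
    n_high: int
    n_low: int
    k: int
    k_in_high: int
    p_exact: float
    p_binomial_tail: float      # general form when k_in_high < k
    p_hypergeometric: float     # without-replacement analogue of p_exact

    def to_jsonable(self) -> dict:
        return asdict(self)


def density_split(grid: PopulationGrid, threshold_density: float,
                  ) -> tuple[int, int, float]:
    """Split masked cells at threshold_density (people/km²).

    Returns (n_high, n_low, threshold_count) with threshold_count =
    threshold_density x cell_area; the high group is strictly above the
    threshold count.
    """
    if threshold_density <= 0:
        raise ValueError("threshold_density must be positive")
    if grid.n_masked == 0:
        raise ValueError("empty mask")
    threshold_count = threshold_density * grid.cell_area
    vals = grid.masked_values()
    n_high = int((vals > threshold_count).sum())
    return n_high, grid.n_masked - n_high, threshold_count


def split_probability(n_high: int, n_total: int, k: int) -> float:
    """P(k independently, uniformly placed sites all land in the high group)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_high <= n_total) or k < 0:
        raise ValueError("need 0 <= n_high <= n_total and k >= 0")
    return float((n_high / n_total) ** k)


def split_probability_hypergeometric(n_high: int, n_total: int, k: int) -> float:
    """Without-replacement analogue: P(all k of a simple random sample are high)."""
    if k > n_high:
        return 0.0
    return float(math.exp(
        math.lgamma(n_high + 1) - math.lgamma(n_high - k + 1)
        - math.lgamma(n_total + 1) + math.lgamma(n_total - k + 1)))


def split_test(grid: PopulationGrid, sites: InvasionSites,
               threshold_density: float = 100.0) -> SplitTestResult:
    sites.validate_against(grid)
    n_high, n_low, thr = density_split(grid, threshold_density)
    n_total = grid.n_masked
    k = len(sites)
    k_in_high = sum(1 for s in sites.sites if grid.values[s.row, s.col] > thr)
    from scipy.stats import binom
    p_tail = float(binom.sf(k_in_high - 1, k, n_high / n_total))
    return SplitTestResult(
        threshold_density=threshold_density, threshold_count=thr,
        n_high=n_high, n_low=n_low, k=k, k_in_high=k_in_high,
        p_exact=split_probability(n_high, n_total, k),
        p_binomial_tail=p_tail,
        p_hypergeometric=split_probability_hypergeometric(n_high, n_total, k))


@dataclass
class ResampleResult:
    n_draws: int
    k: int
    observed_sum: float
    count_exceeding: int
    p_empirical: float
    seed: int
    null_min: float
    null_q1: float
    null_median: float
    null_q3: float
    null_max: float
    null_sums: np.ndarray | None = field(default=None, repr=False)

    def to_jsonable(self, include_null: bool = False) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "null_sums"}
        if include_null and self.null_sums is not None:
            d["null_sums"] = self.null_sums.tolist()
        return d


def _draw_distinct(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    # rejection sampling is fast when k << n; fall back to choice otherwise
    if k * k < n:
        while True:
            idx = rng.integers(0, n, size=k)
            if len(np.unique(idx)) == k:
                return idx
    return rng.choice(n, size=k, replace=False)


def observed_sum(grid: PopulationGrid, sites: InvasionSites) -> float:
    sites.validate_against(grid)
    return float(sum(grid.values[s.row, s.col] for s in sites.sites))


def resample_null(grid: PopulationGrid, sites: InvasionSites,
                  n_draws: int = 10000, seed: int = 0,
                  keep_null: bool = True) -> ResampleResult:
    """Monte Carlo null of summed counts over k uniformly drawn masked cells.

    Each draw takes k distinct masked cells; p_empirical is the fraction of
    draws whose sum strictly exceeds the observed sum (ties do not count).
    """
    k = len(sites)
    if k < 1:
        raise ValueError("need at least one invasion site")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    vals = grid.masked_values()
    n = vals.size
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} masked cells")
    obs = observed_sum(grid, sites)
    rng = np.random.default_rng(seed)
    sums = np.empty(n_draws)
    for i in range(n_draws):
        sums[i] = vals[_draw_distinct(rng, n, k)].sum()
    count = int((sums > obs).sum())
    q = np.quantile(sums, [0, 0.25, 0.5, 0.75, 1])
    return ResampleResult(
        n_draws=n_draws, k=k, observed_sum=obs, count_exceeding=count,
        p_empirical=count / n_draws, seed=seed,
        null_min=float(q[0]), null_q1=float(q[1]), null_median=float(q[2]),
        null_q3=float(q[3]), null_max=float(q[4]),
        null_sums=sums if keep_null else None)


def null_histogram(result: ResampleResult, bins: int = 50) -> pd.DataFrame:
    """Frequency histogram of the null sums; counts integrate to n_draws."""
    if result.null_sums is None:
        raise ValueError("resample_null must be run with keep_null=True")
    counts, edges = np.histogram(result.null_sums, bins=bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})


def enumerate_triple_tail(values: np.ndarray, threshold: float) -> float:
    """Exact P(sum of 3 distinct uniformly chosen cells > threshold).

    Counts the C(n,3) unordered triples with sum strictly above threshold
    via ordered-triple counting (pair-sum + binary search) and inclusion-
    exclusion over coincident indices.  Used as the enumeration oracle for
    resample_null at small n.
    """
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 cells")
    pair_sums = np.sort((v[:, None] + v[None, :]).ravel())  # all ordered pairs
    # A: ordered triples (i,j,l), indices free, sum > T
    a = int(np.sum(pair_sums.size - np.searchsorted(
        pair_sums, threshold - v, side="right")))
    # C1: ordered triples with i == j (any l)
    two = np.sort(2 * v)
    c1 = int(np.sum(v.size - np.searchsorted(two, threshold - v, side="right")))
    # D: i == j == l
    d = int(np.sum(3 * v > threshold))
    distinct_ordered = a - 3 * c1 + 2 * d
    total = n * (n - 1) * (n - 2)
    return distinct_ordered / total


def power_curve(grid: PopulationGrid, k: int, betas, n_reps: int,
                n_draws: int, seed: int, alpha: float = 0.05) -> pd.DataFrame:
    """Rejection rate of the resampling test under count-biased placement.

    For each bias exponent beta, places k sites with probability
    proportional to (count + 1)^beta, runs resample_null, and reports the
    fraction of replicates with p_empirical <= alpha.
    """
    from .synth import place_invasions  # placement model lives with the generators
    if any(b < 0 for b in betas):
        raise ValueError("betas must be non-negative")
    if n_reps == 0:
        return pd.DataFrame(columns=["beta", "n_reps", "rejection_rate"])
    rows = []
    ss = np.random.SeedSequence(seed)
    for b in betas:
        rejections = 0
        for rep in range(n_reps):
            child = np.random.SeedSequence(entropy=ss.entropy,
                                           spawn_key=(int(b * 1000), rep))
            s1, s2 = child.generate_state(2) % (2 ** 31)
            sites = place_invasions(grid, k, b, int(s1))
            res = resample_null(grid, sites, n_draws=n_draws, seed=int(s2),
                                keep_null=False)
            if res.p_empirical <= alpha:
                rejections += 1
        rows.append({"beta": float(b), "n_reps": n_reps,
                     "rejection_rate": rejections / n_reps if n_reps else np.nan})
    return pd.DataFrame(rows)
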