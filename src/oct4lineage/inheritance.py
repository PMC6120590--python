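"""Transmission and partitioning of OCT4 at cell division.

Groups of analyses quantifying how a mother cell's OCT4 is passed on:

* kinship similarity — |difference in lifetime-mean level| for sister,
  cousin, second-cousin and random cell pairs, with pairwise KS tests,
  and the Spearman correlation between division distance and |difference|;
* sister partition ratios — the ratio r (and 1/r) of daughter levels at
  the first post-division frame and over cumulative windows, the
  fraction of divisions at least as extreme as 5:6 / 3:4 / 1:2, the
  persistence of the early ratio to 8 h, and the comparison of OCT4
  ratios against DAPI (DNA-content) ratios by kernel density + KS;
* protein turnover — exponential half-life fitting and the percent of
  division-time protein remaining after a delay (with a 7.34 h
  half-life, 99.22% remains after 5 min);
* variance decomposition — mother-daughter traces aligned at division
  (t = 0), the R^2 between the current level and the level at +8 h
  across the maternal (t < 0), inherited [0, 1 h] and autonomous
  (> 1 h) periods, the sister-resampling estimate of the contribution
  of asymmetric partitioning, rank-mixing visualization data, and the
  autocorrelation mixing time of undisturbed traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, ks_2samp, linregress, pearsonr, spearmanr

from .lineage import CellSummary, LineageForest, sister_pairs

__all__ = [
    "KinshipDiffs",
    "DecayModel",
    "AlignedPairSet",
    "kinship_differences",
    "division_distance_correlation",
    "sister_ratios",
    "ratio_extremity_fractions",
    "ratio_persistence",
    "dapi_vs_oct4_ratios",
    "fit_half_life",
    "maternal_fraction",
    "align_mother_daughter",
    "r2_decomposition",
    "asymmetry_contribution",
    "mixing_rank_plot",
    "autocorrelation_mixing_time",
]

RATIO_LANDMARKS = {"5:6": 5 / 6, "3:4": 3 / 4, "1:2": 1 / 2}


# ---------------------------------------------------------------------------
# kinship similarity


@dataclass
class KinshipDiffs:
    """|level difference| samples per kinship category + pairwise KS tests."""

    diffs: dict[str, np.ndarray]
    ks_report: pd.DataFrame

    def medians(self) -> dict[str, float]:
        return {
            k: float(np.median(v)) for k, v in self.diffs.items() if len(v) > 0
        }


def _complete_mean_levels(
    forest: LineageForest, summaries: dict[str, CellSummary]
) -> dict[str, float]:
    """Lifetime-mean levels of complete cells only (founders excluded)."""
    return {
        cid: summaries[cid].mean_level
        for cid, c in forest.cells.items()
        if c.complete and cid in summaries
    }


def _category_pairs(forest: LineageForest) -> dict[str, list[tuple[str, str]]]:
    """Sister / cousin / second-cousin pairs enumerated from the topology."""
    out: dict[str, list[tuple[str, str]]] = {
        "sister": [],
        "cousin": [],
        "second_cousin": [],
    }
    for a, b in sister_pairs(forest):
        out["sister"].append((a, b))
        ka, kb = forest.children_of(a), forest.children_of(b)
        for x in ka:
            for y in kb:
                out["cousin"].append((x, y))
        gka = [g for x in ka for g in forest.children_of(x)]
        gkb = [g for y in kb for g in forest.children_of(y)]
        for x in gka:
            for y in gkb:
                out["second_cousin"].append((x, y))
    return out


def kinship_differences(
    forest: LineageForest,
    summaries: dict[str, CellSummary],
    n_random: int | None = None,
    seed: int = 0,
) -> KinshipDiffs:
    """|Delta lifetime-mean level| by kinship category with KS comparisons.

    The ``random`` baseline draws seeded pairs of complete cells from
    *different* roots (guaranteed unrelated within the observation
    window); its size defaults to the number of sister pairs.  Empty
    categories yield empty arrays and are skipped in the KS report.
    """
    levels = _complete_mean_levels(forest, summaries)
    cat_pairs = _category_pairs(forest)
    diffs: dict[str, np.ndarray] = {}
    for cat, pairs in cat_pairs.items():
        vals = [
            abs(levels[a] - levels[b])
            for a, b in pairs
            if a in levels and b in levels
        ]
        diffs[cat] = np.asarray(vals, dtype=float)

    rng = np.random.default_rng(seed)
    by_root: dict[str, list[str]] = {}
    for cid in levels:
        by_root.setdefault(forest.root_of(cid), []).append(cid)
    roots = sorted(by_root)
    n_rand = n_random if n_random is not None else len(diffs["sister"])
    rand_vals = []
    if len(roots) >= 2:
        for _ in range(n_rand):
            ra, rb = rng.choice(len(roots), size=2, replace=False)
            a = by_root[roots[ra]][rng.integers(len(by_root[roots[ra]]))]
            b = by_root[roots[rb]][rng.integers(len(by_root[roots[rb]]))]
            rand_vals.append(abs(levels[a] - levels[b]))
    diffs["random"] = np.asarray(rand_vals, dtype=float)

    cats = list(diffs)
    rows = []
    for i, ca in enumerate(cats):
        for cb in cats[i + 1 :]:
            if len(diffs[ca]) < 2 or len(diffs[cb]) < 2:
                continue
            res = ks_2samp(diffs[ca], diffs[cb])
            rows.append(
                {
                    "group_a": ca,
                    "group_b": cb,
                    "n_a": len(diffs[ca]),
                    "n_b": len(diffs[cb]),
                    "ks_d": float(res.statistic),
                    "p_value": float(res.pvalue),
                }
            )
    return KinshipDiffs(diffs=diffs, ks_report=pd.DataFrame(rows))


def division_distance_correlation(
    forest: LineageForest, summaries: dict[str, CellSummary]
) -> tuple[float, float, int]:
    """Spearman correlation of division distance vs |Delta level|.

    Runs over all pairs of complete cells sharing a root.  Returns
    ``(rho, p, n_pairs)``; degenerate inputs (all differences equal, or
    fewer than 3 pairs) return ``(0.0, nan, n)``.
    """
    from .lineage import kinship  # local import to avoid cycle at module load

    levels = _complete_mean_levels(forest, summaries)
    by_root: dict[str, list[str]] = {}
    for cid in levels:
        by_root.setdefault(forest.root_of(cid), []).append(cid)
    dists, deltas = [], []
    for members in by_root.values():
        members = sorted(members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                _, d = kinship(forest, a, b)
                if d is None or d == 0:
                    continue
                dists.append(d)
                deltas.append(abs(levels[a] - levels[b]))
    n = len(dists)
    if n < 3 or len(set(deltas)) == 1 or len(set(dists)) == 1:
        return 0.0, float("nan"), n
    rho, p = spearmanr(dists, deltas)
    return float(rho), float(p), n


# ---------------------------------------------------------------------------
# sister partition ratios


def sister_ratios(
    forest: LineageForest, windows: tuple[float, ...] = (5.0, 15.0, 60.0, 240.0, 480.0)
) -> pd.DataFrame:
    """Sister-level ratios per post-division window.

    The smallest window (one sampling interval) uses the first-frame
    levels — the levels measured in the anaphase frame in which the two
    daughters first appear.  Larger windows use each sister's cumulative
    mean over all frames within the window before taking the ratio.
    Both orientations r and 1/r are emitted (two rows per pair) so the
    pooled distribution is symmetric about 1 by construction.

    Output columns: pair_id (mother id), window_min, ratio.
    """
    interval = forest.sampling_interval
    rows = []
    for a, b in sister_pairs(forest):
        ca, cb = forest.cells[a], forest.cells[b]
        if ca.birth_time is None or ca.times[0] != ca.birth_time:
            continue
        if cb.birth_time is None or cb.times[0] != cb.birth_time:
            continue
        pair_id = ca.parent_id
        for w in windows:
            k = max(1, int(round(w / interval)))
            if ca.n_samples < k or cb.n_samples < k:
                continue
            la = float(np.mean(ca.levels[:k]))
            lb = float(np.mean(cb.levels[:k]))
            if la <= 0 or lb <= 0:
                warnings.warn(
                    f"non-positive level for sisters of {pair_id}; pair skipped"
                )
                continue
            r = la / lb
            rows.append({"pair_id": pair_id, "window_min": w, "ratio": r})
            rows.append({"pair_id": pair_id, "window_min": w, "ratio": 1.0 / r})
    return pd.DataFrame(rows, columns=["pair_id", "window_min", "ratio"])


def ratio_extremity_fractions(
    ratios: np.ndarray | pd.Series,
    landmarks: dict[str, float] = RATIO_LANDMARKS,
) -> dict[str, float]:
    """Fraction of divisions with a ratio at least as extreme as each landmark.

    A division with sister ratio r counts as "at least as extreme as"
    landmark q < 1 when min(r, 1/r) <= q.  Accepts either one ratio per
    pair or the pooled {r, 1/r} set (the fractions are identical).
    """
    r = np.asarray(ratios, dtype=float)
    folded = np.minimum(r, 1.0 / r)
    return {name: float(np.mean(folded <= q)) for name, q in landmarks.items()}


def ratio_persistence(
    forest: LineageForest,
    early_window: float = 15.0,
    final_offset: float = 480.0,
) -> tuple[float, float, int]:
    """Does the ratio set within 15 min of division persist to 8 h?

    Pearson correlation, on the log-ratio scale with a fixed sister
    orientation, between the cumulative-mean ratio over the first
    ``early_window`` minutes and the ratio of levels at
    ``final_offset`` minutes after division.  Returns ``(r, p, n)``;
    fewer than 3 eligible pairs returns ``(nan, nan, n)``.
    """
    interval = forest.sampling_interval
    k_early = max(1, int(round(early_window / interval)))
    k_final = int(round(final_offset / interval))
    early, final = [], []
    for a, b in sister_pairs(forest):
        ca, cb = forest.cells[a], forest.cells[b]
        if ca.n_samples <= k_final or cb.n_samples <= k_final:
            continue
        ea = np.mean(ca.levels[:k_early])
        eb = np.mean(cb.levels[:k_early])
        fa, fb = ca.levels[k_final], cb.levels[k_final]
        if min(ea, eb, fa, fb) <= 0:
            continue
        early.append(np.log(ea / eb))
        final.append(np.log(fa / fb))
    n = len(early)
    if n < 3:
        return float("nan"), float("nan"), n
    if np.std(early) == 0 or np.std(final) == 0:
        # constant traces: perfect persistence by convention
        same = np.allclose(early, final)
        return (1.0 if same else float("nan")), float("nan"), n
    r, p = pearsonr(early, final)
    return float(r), float(p), n


@dataclass
class RatioDensityComparison:
    grid: np.ndarray
    dapi_density: np.ndarray
    oct4_density: np.ndarray
    ks_d: float
    p_value: float
    n_pairs: int


def dapi_vs_oct4_ratios(
    sister_endpoints: pd.DataFrame,
    bandwidth: float | str | None = None,
    n_grid: int = 4001,
) -> RatioDensityComparison:
    """Compare sister-ratio spreads of DNA content (DAPI) vs OCT4.

    ``sister_endpoints`` needs one row per recently divided sister pair
    with columns ``dapi_ratio`` and ``oct4_ratio``.  Both ratio sets are
    pooled with their reciprocals, smoothed with a Gaussian kernel on a
    common grid, and compared by a two-sample KS test.
    """
    if sister_endpoints["dapi_ratio"].isna().any() or sister_endpoints[
        "oct4_ratio"
    ].isna().any():
        raise ValueError("mismatched pair counts: missing ratio entries")
    dapi = sister_endpoints["dapi_ratio"].to_numpy(dtype=float)
    oct4 = sister_endpoints["oct4_ratio"].to_numpy(dtype=float)
    if len(dapi) != len(oct4):  # defensive; same frame => same length
        raise ValueError("mismatched pair counts")
    dapi_pool = np.concatenate([dapi, 1.0 / dapi])
    oct4_pool = np.concatenate([oct4, 1.0 / oct4])
    kde_d = gaussian_kde(dapi_pool, bw_method=bandwidth)
    kde_o = gaussian_kde(oct4_pool, bw_method=bandwidth)
    both = np.concatenate([dapi_pool, oct4_pool])
    span = both.std() + kde_d.factor + kde_o.factor
    grid = np.linspace(both.min() - 8 * span, both.max() + 8 * span, n_grid)
    res = ks_2samp(dapi_pool, oct4_pool)
    return RatioDensityComparison(
        grid=grid,
        dapi_density=kde_d(grid),
        oct4_density=kde_o(grid),
        ks_d=float(res.statistic),
        p_value=float(res.pvalue),
        n_pairs=len(dapi),
    )


# ---------------------------------------------------------------------------
# protein turnover


@dataclass(frozen=True)
class DecayModel:
    """First-order decay, parameterized by half-life in hours."""

    half_life: float

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")

    @property
    def rate(self) -> float:
        """Decay rate ln2 / t_half, per hour."""
        return np.log(2.0) / self.half_life


def fit_half_life(times_h: np.ndarray, levels: np.ndarray) -> DecayModel:
    """Least-squares exponential fit to a translation-block time course.

    Fits log(level) ~ time; requires at least 3 points and a net
    decreasing series (a non-negative fitted slope is an error).
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(levels, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(y <= 0):
        raise ValueError("levels must be positive for a log-linear fit")
    res = linregress(t, np.log(y))
    if res.slope >= 0:
        raise ValueError("series is not decaying: fitted rate is non-negative")
    return DecayModel(half_life=float(np.log(2.0) / (-res.slope)))


def maternal_fraction(model: DecayModel, t_min: float) -> float:
    """Percent of division-time protein remaining ``t_min`` minutes later.

    Pure first-order decay with no production: 100 * (1/2)^(t / t_half).
    """
    if t_min < 0:
        raise ValueError("t must be non-negative")
    return 100.0 * 0.5 ** (t_min / (model.half_life * 60.0))


# ---------------------------------------------------------------------------
# aligned mother-daughter pairs and the R^2 decomposition


def _smooth(levels: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges average over the available samples."""
    if window <= 1:
        return levels.astype(float)
    return (
        pd.Series(levels).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


@dataclass
class AlignedPairSet:
    """Mother-daughter traces aligned at division (t = 0).

    ``matrix`` is (n_pairs, n_times) of smoothed levels on the common
    aligned ``grid`` (minutes; negative during the mother's lifetime),
    NaN outside each pair's coverage.  ``final_levels`` are the daughter
    levels at the final grid point (+8 h by default).
    """

    grid: np.ndarray
    matrix: np.ndarray
    mother_ids: list[str]
    daughter_ids: list[str]
    final_levels: np.ndarray
    inherited_window: float = 60.0  # minutes

    @property
    def n_pairs(self) -> int:
        return len(self.daughter_ids)

    def subset(self, idx: np.ndarray) -> "AlignedPairSet":
        return AlignedPairSet(
            grid=self.grid,
            matrix=self.matrix[idx],
            mother_ids=[self.mother_ids[i] for i in idx],
            daughter_ids=[self.daughter_ids[i] for i in idx],
            final_levels=self.final_levels[idx],
            inherited_window=self.inherited_window,
        )


def align_mother_daughter(
    forest: LineageForest,
    final_offset: float = 480.0,
    smooth_window_min: float = 15.0,
    inherited_window: float = 60.0,
) -> AlignedPairSet:
    """Build the aligned mother-daughter pair set.

    One pair per (mother, daughter) where the daughter is observed to at
    least ``final_offset`` minutes after its birth without dividing
    first; the mother contributes her whole observed trace at negative
    aligned times.  Traces are smoothed per cell with a centered
    moving average of ``smooth_window_min``.
    """
    interval = forest.sampling_interval
    win = max(1, int(round(smooth_window_min / interval)))
    k_final = int(round(final_offset / interval))
    entries = []
    max_mother = 0
    for mid in forest.cells:
        kids = forest.children_of(mid)
        if not kids:
            continue
        mother = forest.cells[mid]
        m_smooth = _smooth(mother.levels, win)
        for did in kids:
            d = forest.cells[did]
            if d.n_samples <= k_final:
                continue
            if d.division_time is not None and (
                d.division_time - d.birth_time
            ) < final_offset:
                continue
            d_smooth = _smooth(d.levels[: k_final + 1], win)
            entries.append((mid, did, m_smooth, d_smooth))
            max_mother = max(max_mother, mother.n_samples)
    if not entries:
        raise ValueError("no eligible mother-daughter pairs")
    grid = np.arange(-max_mother, k_final + 1) * interval
    mat = np.full((len(entries), len(grid)), np.nan)
    for i, (_, _, m, d) in enumerate(entries):
        mat[i, max_mother - len(m) : max_mother] = m
        mat[i, max_mother:] = d
    return AlignedPairSet(
        grid=grid,
        matrix=mat,
        mother_ids=[e[0] for e in entries],
        daughter_ids=[e[1] for e in entries],
        final_levels=mat[:, -1].copy(),
        inherited_window=inherited_window,
    )


def _r2_columns(
    mat: np.ndarray, final: np.ndarray, min_pairs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column R^2 of the simple regression of final on current level."""
    n_t = mat.shape[1]
    r2 = np.full(n_t, np.nan)
    counts = np.zeros(n_t, dtype=int)
    for j in range(n_t):
        col = mat[:, j]
        mask = np.isfinite(col)
        m = int(mask.sum())
        counts[j] = m
        if m < min_pairs:
            continue
        x, y = col[mask], final[mask]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            r2[j] = 1.0 if np.allclose(x - x.mean(), y - y.mean()) else np.nan
            continue
        r = np.corrcoef(x, y)[0, 1]
        r2[j] = r * r
    return r2, counts


def _period(t: np.ndarray, inherited_window: float) -> np.ndarray:
    out = np.where(t < 0, "maternal", "autonomous").astype(object)
    out[(t >= 0) & (t <= inherited_window)] = "inherited"
    return out


def r2_decomposition(
    pairs: AlignedPairSet,
    min_pairs: int = 10,
    mode: str = "instantaneous",
) -> pd.DataFrame:
    """Variance in final level explained along the aligned history.

    At each aligned time point with at least ``min_pairs`` contributing
    pairs, the R^2 of the simple regression of the +8 h level on the
    per-period statistic: the (smoothed) instantaneous level by
    default, or the running cumulative mean within the current segment
    (``mode='cumulative'``).  The final grid point reaches R^2 = 1 by
    construction under the instantaneous statistic.

    Output columns: time_min, r2, n_pairs, period.
    """
    if mode == "instantaneous":
        mat = pairs.matrix
    elif mode == "cumulative":
        mat = _segment_cumulative_mean(pairs)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    r2, counts = _r2_columns(mat, pairs.final_levels, min_pairs)
    df = pd.DataFrame(
        {
            "time_min": pairs.grid,
            "r2": r2,
            "n_pairs": counts,
            "period": _period(pairs.grid, pairs.inherited_window),
        }
    )
    return df[np.isfinite(df["r2"])].reset_index(drop=True)


def _segment_cumulative_mean(pairs: AlignedPairSet) -> np.ndarray:
    """Running mean from each segment's start (mother birth / daughter birth)."""
    mat = pairs.matrix
    split = int(np.searchsorted(pairs.grid, 0))
    out = np.full_like(mat, np.nan)
    for part in (slice(None, split), slice(split, None)):
        block = mat[:, part]
        filled = np.where(np.isfinite(block), block, 0.0)
        counts = np.cumsum(np.isfinite(block), axis=1)
        sums = np.cumsum(filled, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cm = sums / counts
        cm[counts == 0] = np.nan
        cm[~np.isfinite(block) & (counts > 0)] = np.nan  # only within coverage
        out[:, part] = cm
    return out


@dataclass
class AsymmetryResult:
    """Mean R^2 curves for both-sisters vs one-sister resampled pair sets."""

    grid: np.ndarray
    r2_both: np.ndarray  # mean over resamples
    r2_one: np.ndarray
    difference: np.ndarray  # r2_both - r2_one, raw
    difference_smoothed: np.ndarray  # centered moving average (1.25 h default)
    n_resamples: int
    n_duos: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.grid,
                "r2_both_sisters": self.r2_both,
                "r2_one_sister": self.r2_one,
                "difference": self.difference,
                "difference_smoothed": self.difference_smoothed,
            }
        )


def asymmetry_contribution(
    pairs: AlignedPairSet,
    n_resamples: int = 100,
    smooth_window_h: float = 1.25,
    seed: int = 0,
    min_pairs: int = 10,
) -> AsymmetryResult:
    """Estimate the variance explained by asymmetric partitioning.

    Mother-daughter pairs are grouped into sister duos sharing a mother
    trace.  Per resample, the one-sister set keeps one seeded-random
    sister from each of the N duos (N traces); the both-sisters set
    keeps both sisters from a random half of the duos (also N traces,
    so the two R^2 curves are compared at matched sample size).  Curves
    are averaged over ``n_resamples`` and their difference
    (both - one) is reported raw and smoothed with a centered moving
    average of ``smooth_window_h``.

    Pairing the same mother with two daughters depresses R^2 before
    division; after division the sisters' divergent inherited levels
    carry real signal, so the difference changes sign at division when
    partitioning is asymmetric.
    """
    by_mother: dict[str, list[int]] = {}
    for i, mid in enumerate(pairs.mother_ids):
        by_mother.setdefault(mid, []).append(i)
    duos = [idx for idx in by_mother.values() if len(idx) == 2]
    if len(duos) < 5:
        raise ValueError(f"need at least 5 sister duos, found {len(duos)}")
    rng = np.random.default_rng(seed)
    n_duos = len(duos)
    half = max(min_pairs // 2 + 1, n_duos // 2)

    acc_both = np.zeros((n_resamples, len(pairs.grid)))
    acc_one = np.zeros_like(acc_both)
    for r in range(n_resamples):
        pick = rng.integers(0, 2, size=n_duos)
        one_idx = np.array([duos[i][pick[i]] for i in range(n_duos)])
        chosen = rng.choice(n_duos, size=half, replace=False)
        both_idx = np.array([j for i in chosen for j in duos[i]])
        r2_one, _ = _r2_columns(
            pairs.matrix[one_idx], pairs.final_levels[one_idx], min_pairs
        )
        r2_both, _ = _r2_columns(
            pairs.matrix[both_idx], pairs.final_levels[both_idx], min_pairs
        )
        acc_one[r] = r2_one
        acc_both[r] = r2_both

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_both = np.nanmean(acc_both, axis=0)
        mean_one = np.nanmean(acc_one, axis=0)
    diff = mean_both - mean_one
    interval = float(np.median(np.diff(pairs.grid)))
    win = max(1, int(round(smooth_window_h * 60.0 / interval)))
    smoothed = (
        pd.Series(diff).rolling(win, center=True, min_periods=1).mean().to_numpy()
    )
    return AsymmetryResult(
        grid=pairs.grid,
        r2_both=mean_both,
        r2_one=mean_one,
        difference=diff,
        difference_smoothed=smoothed,
        n_resamples=n_resamples,
        n_duos=n_duos,
    )


def mixing_rank_plot(
    pairs: AlignedPairSet,
    n_cells: int = 30,
    rank_time: float = 480.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank-trajectory table for the mixing visualization.

    ``n_cells`` seeded-random pairs are ranked by their level at
    ``rank_time`` after division; each row gives one cell's level and
    within-sample rank at one aligned time point.  Rank churn before
    division against stable ranks after it is the visual signature of
    division-time mixing.
    """
    rng = np.random.default_rng(seed)
    if pairs.n_pairs < n_cells:
        warnings.warn(
            f"only {pairs.n_pairs} pairs available; using all", stacklevel=2
        )
        idx = np.arange(pairs.n_pairs)
    else:
        idx = rng.choice(pairs.n_pairs, size=n_cells, replace=False)
    sub = pairs.subset(idx)
    j_rank = int(np.argmin(np.abs(sub.grid - rank_time)))
    final_rank = np.argsort(np.argsort(sub.matrix[:, j_rank]))
    rows = []
    for j, t in enumerate(sub.grid):
        col = sub.matrix[:, j]
        mask = np.isfinite(col)
        if not mask.any():
            continue
        ranks = np.full(len(col), np.nan)
        ranks[mask] = np.argsort(np.argsort(col[mask]))
        for i in np.flatnonzero(mask):
            rows.append(
                {
                    "daughter_id": sub.daughter_ids[i],
                    "time_min": float(t),
                    "level_afu": float(col[i]),
                    "rank_at_time": int(ranks[i]),
                    "rank_at_final": int(final_rank[i]),
                }
            )
    return pd.DataFrame(rows)


def autocorrelation_mixing_time(
    traces: list[np.ndarray],
    mean_cycle_h: float,
    sampling_interval: float = 5.0,
    threshold: float = float(np.exp(-1)),
    min_traces: int = 5,
) -> tuple[float, float, pd.DataFrame]:
    """Mixing time from averaged single-cell autocorrelation.

    Each trace is mean-subtracted and its normalized autocorrelation
    computed; the per-lag average across cells (lags supported by at
    least ``min_traces`` traces) decays from 1, and the mixing time is
    the first lag at which it falls below ``threshold`` (1/e by
    convention).  Returns ``(hours, fraction_of_mean_cycle, curve)``.

    Traces shorter than 3 samples are excluded; requires >= 10 usable
    traces.
    """
    usable = [np.asarray(t, float) for t in traces if len(t) >= 3]
    if len(usable) < 10:
        raise ValueError(f"need >= 10 traces with >= 3 samples, got {len(usable)}")
    max_lag = max(len(t) // 2 for t in usable)
    acc = np.zeros(max_lag + 1)
    cnt = np.zeros(max_lag + 1, dtype=int)
    for x in usable:
        x = x - x.mean()
        denom = float(np.dot(x, x))
        if denom == 0:
            continue
        L = len(x) // 2
        for k in range(L + 1):
            acc[k] += float(np.dot(x[: len(x) - k], x[k:])) / denom
            cnt[k] += 1
    ok = cnt >= min_traces
    lags = np.arange(max_lag + 1)[ok]
    mean_acf = acc[ok] / cnt[ok]
    below = np.flatnonzero(mean_acf < threshold)
    if len(below) == 0:
        mix_lag = int(lags[-1])
    else:
        mix_lag = int(lags[below[0]])
    hours = mix_lag * sampling_interval / 60.0
    curve = pd.DataFrame(
        {"lag_min": lags * sampling_interval, "mean_acf": mean_acf, "n_traces": cnt[ok]}
    )
    return hours, hours / mean_cycle_h, curve
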