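"""Seeded synthetic lineage generator.

Emulates the statistical structure of a tracked hESC OCT4-reporter
experiment so every pipeline stage has ground truth:

* heritable per-lineage OCT4 setpoints with generational log-normal
  drift;
* protein turnover with a 7.34 h half-life: each cell's level relaxes
  toward its setpoint at rate ln2 / t_half, with additive
  Ornstein-Uhlenbeck noise;
* sporadic pulses (~1.5 h full width at half maximum, Poisson-timed,
  truncated at 7 per cycle) in a 68% subpopulation of pulser cells,
  with log-normal amplitudes whose median sits at the detector's
  200 a.f.u. prominence floor;
* cell-cycle durations from a shifted gamma with mean 14.6 h on
  support [10, 24] h;
* asymmetric partitioning at division: daughters receive 2p and
  2(1-p) times the mother's division-time level (so a symmetric
  division is concentration-neutral), with p drawn from a symmetric
  distribution calibrated to the printed sister-ratio extremity
  quantiles (38% / 12% / 3% at 5:6 / 3:4 / 1:2 or more extreme);
* a differentiation stimulus after 42 h of baseline: cells then alive
  draw a fate from a logistic model in their own lifetime features
  plus a lineage-shared propensity; descendants inherit the fate with
  a small flip probability; post-stimulus dynamics diverge and
  bimodal (OCT4, CDX2) endpoints are emitted from class-specific
  Gaussians.

Identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import lfilter
from scipy.stats import norm

from .lineage import LineageForest, build_forest

__all__ = [
    "GeneratorConfig",
    "PartitionDistribution",
    "calibrate_partition_distribution",
    "simulate_lineages",
    "SimulatedDataset",
    "make_fixture",
    "tiny_forest_table",
    "sister_endpoint_table",
]

RATIO_TARGETS = ((5 / 6, 0.38), (3 / 4, 0.12), (1 / 2, 0.03))


# ---------------------------------------------------------------------------
# partition-distribution calibration


@dataclass(frozen=True)
class PartitionDistribution:
    """Symmetric distribution of the daughter fraction p (mean 1/2).

    A central Gaussian N(1/2, s0^2) with weight ``w`` plus a symmetric
    shoulder pair N(1/2 +/- m, s^2) sharing the rest of the weight.
    ``degenerate`` collapses everything to p = 1/2.
    """

    w: float
    s0: float
    m: float
    s: float
    degenerate: bool = False

    def extremity_prob(self, ratio: float) -> float:
        """P(sister ratio at least as extreme as ``ratio`` < 1), closed form."""
        if self.degenerate:
            return 0.0 if ratio < 1 else 1.0
        d = 0.5 - ratio / (1.0 + ratio)  # |p - 1/2| threshold
        central = 2.0 * norm.sf(d / self.s0)
        pair = (
            norm.sf((d - self.m) / self.s)
            + norm.sf((d + self.m) / self.s)
            + norm.cdf((-d - self.m) / self.s)
            + norm.cdf((-d + self.m) / self.s)
        )
        return float(self.w * central + (1 - self.w) / 2.0 * pair)

    def spread(self) -> float:
        """Standard deviation of p - 1/2."""
        if self.degenerate:
            return 0.0
        var = self.w * self.s0**2 + (1 - self.w) * (self.m**2 + self.s**2)
        return float(np.sqrt(var))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw daughter fractions, resampling the negligible mass outside (0, 1)."""
        if self.degenerate:
            return np.full(n, 0.5)
        out = np.empty(n)
        filled = 0
        while filled < n:
            k = n - filled
            u = rng.random(k)
            x = np.where(
                u < self.w,
                rng.normal(0.0, self.s0, k),
                rng.normal(0.0, self.s, k)
                + self.m * np.where(rng.random(k) < 0.5, 1.0, -1.0),
            )
            x = x[(x > -0.48) & (x < 0.48)]
            out[filled : filled + len(x)] = 0.5 + x
            filled += len(x)
        return out


def calibrate_partition_distribution(
    targets: tuple[tuple[float, float], ...] = RATIO_TARGETS,
    tol: float = 1e-3,
) -> PartitionDistribution:
    """Fit the partition distribution to sister-ratio extremity quantiles.

    ``targets`` are (ratio, probability) pairs with strictly decreasing
    probabilities for increasingly extreme ratios.  The fit is a
    deterministic least-squares solve from a fixed starting point; the
    result must reproduce every target within ``tol`` or a ValueError
    is raised (infeasible targets).
    """
    ratios = np.array([t[0] for t in targets], dtype=float)
    probs = np.array([t[1] for t in targets], dtype=float)
    if np.all(probs == 0):
        return PartitionDistribution(1.0, 0.0, 0.0, 0.0, degenerate=True)
    if np.any(np.diff(probs) >= 0):
        raise ValueError("extremity probabilities must be strictly decreasing")
    d = 0.5 - ratios / (1.0 + ratios)

    def tails(params: np.ndarray) -> np.ndarray:
        w = 1.0 / (1.0 + np.exp(-params[0]))
        s0, m, s = np.exp(params[1:4])
        central = 2.0 * norm.sf(d / s0)
        pair = (
            norm.sf((d - m) / s)
            + norm.sf((d + m) / s)
            + norm.cdf((-d - m) / s)
            + norm.cdf((-d + m) / s)
        )
        return w * central + (1 - w) / 2.0 * pair

    # deterministic multi-start: the canonical start rescaled by fixed factors
    base = np.array([-1.25, np.log(0.11), np.log(0.038), np.log(0.013)])
    best = None
    for k in (1.0, 0.5, 2.0, 4.0, 0.25):
        x0 = base + np.array([0.0, np.log(k), np.log(k), np.log(k)])
        res = least_squares(lambda p: tails(p) - probs, x0, xtol=1e-15, ftol=1e-15)
        if best is None or res.cost < best.cost:
            best = res
    err = np.abs(tails(best.x) - probs).max()
    if err > tol:
        raise ValueError(
            f"partition calibration infeasible: max deviation {err:.2e} > {tol}"
        )
    w = 1.0 / (1.0 + np.exp(-best.x[0]))
    s0, m, s = np.exp(best.x[1:4])
    return PartitionDistribution(float(w), float(s0), float(m), float(s))


# ---------------------------------------------------------------------------
# generator configuration


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic lineage generator.

    Durations in hours unless suffixed ``_min``; intensities in a.f.u.
    """

    sampling_interval: float = 5.0  # minutes
    pre_stimulus_h: float = 42.0
    post_stimulus_h: float = 24.0
    undisturbed_h: float = 72.0
    half_life_h: float = 7.34
    cycle_mean_h: float = 14.6
    cycle_min_h: float = 10.0
    cycle_max_h: float = 24.0
    cycle_shape: float = 4.0  # gamma shape of (cycle - cycle_min)
    pulser_fraction: float = 0.68
    pulse_fwhm_h: float = 1.5
    max_pulses_per_cycle: int = 7
    pulse_rate_per_cycle: float = 2.5  # Poisson mean before truncation
    pulse_amplitude_afu: float = 200.0  # log-normal median
    pulse_amplitude_sigma: float = 0.6
    partition_targets: tuple = RATIO_TARGETS
    setpoint_median_afu: float = 2000.0
    setpoint_log_sd: float = 0.10  # founder heterogeneity; ~200 a.f.u. = 1 SD across cells
    setpoint_drift_sd: float = 0.08  # sigma_eta: per-generation log drift
    partition_setpoint_coupling: float = 0.6  # persistence of partitioned differences
    ou_tau_h: float = 6.0  # correlation time of the slow within-cell noise
    ou_sd_afu: float = 120.0  # must stay below the pulse detector's 200 a.f.u. floor
    fate_beta0: float = -9.2
    fate_beta_oct4: float = 6.0  # per 1000 a.f.u. of lifetime-mean level
    fate_beta_pulse: float = 2.0  # per pulse/h
    lineage_fate_sd: float = 1.5  # sd of the lineage-shared propensity
    fate_flip_prob: float = 0.03  # per post-stimulus division, per daughter
    endpoint_self_mean: tuple[float, float] = (2600.0, 300.0)  # (oct4, cdx2)
    endpoint_self_sd: tuple[float, float] = (300.0, 150.0)
    endpoint_diff_mean: tuple[float, float] = (600.0, 2600.0)
    endpoint_diff_sd: tuple[float, float] = (200.0, 300.0)
    post_self_gain: float = 1.3  # setpoint multiplier after stimulus (self fate)
    post_diff_level: float = 250.0  # setpoint after stimulus (differentiated)
    dapi_ratio_sd: float = 0.02

    def validate(self) -> None:
        positive = (
            self.sampling_interval,
            self.pre_stimulus_h,
            self.post_stimulus_h,
            self.undisturbed_h,
            self.half_life_h,
            self.cycle_mean_h,
            self.cycle_min_h,
            self.pulse_fwhm_h,
            self.setpoint_median_afu,
            self.ou_tau_h,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("all durations and scales must be positive")
        if not self.cycle_min_h < self.cycle_mean_h < self.cycle_max_h:
            raise ValueError("need cycle_min < cycle_mean < cycle_max")
        if not 0 <= self.pulser_fraction <= 1:
            raise ValueError("pulser_fraction must be in [0, 1]")
        probs = [t[1] for t in self.partition_targets]
        if any(p != 0 for p in probs) and any(
            b >= a for a, b in zip(probs, probs[1:])
        ):
            raise ValueError("partition target probabilities must decrease")
        if self.fate_beta_oct4 < 0:
            raise ValueError(
                "fate_beta_oct4 must be >= 0: higher OCT4 must raise self-renewal odds"
            )

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# simulation


@dataclass
class _Cell:
    cell_id: str
    parent_id: str | None
    birth_frame: int | None  # None for founders first seen mid-life
    division_frame: int | None  # frame of daughters' first sample; None = censored
    first_frame: int
    setpoint: float
    x0: float  # level at first_frame
    pulser: bool
    generation: int
    fate: str | None = None  # 'self' | 'diff' once the stimulus has passed
    levels: np.ndarray | None = None
    x_div: float = float("nan")  # underlying level at the division frame
    partition_p: float | None = None  # daughter fraction drawn at this cell's division


@dataclass
class SimulatedDataset:
    """Track table + endpoint table + per-cell ground truth."""

    track_table: pd.DataFrame
    endpoints: pd.DataFrame
    ground_truth: dict
    config: GeneratorConfig
    design: str
    seed: int

    def forest(self) -> LineageForest:
        df = self.track_table.copy()
        df["parent_id"] = df["parent_id"].fillna("")
        forest = build_forest(df, sampling_interval=self.config.sampling_interval)
        if len(self.endpoints):
            forest.endpoints = self.endpoints.copy()
        return forest


def _draw_cycle_frames(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    """Cycle duration in frames from the truncated shifted gamma."""
    scale = (cfg.cycle_mean_h - cfg.cycle_min_h) / cfg.cycle_shape
    for _ in range(1000):
        c = cfg.cycle_min_h + rng.gamma(cfg.cycle_shape, scale)
        if c <= cfg.cycle_max_h:
            return int(round(c * 60.0 / cfg.sampling_interval))
    return int(round(cfg.cycle_mean_h * 60.0 / cfg.sampling_interval))


def _ou_path(
    n: int, dt: float, tau_min: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-start Ornstein-Uhlenbeck sample path on the frame grid."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    alpha = np.exp(-dt / tau_min)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - alpha**2), n)
    innov[0] = 0.0  # daughters start on the partitioned level exactly
    return lfilter([1.0], [1.0, -alpha], innov)


def _relax(x0: float, setpoints: np.ndarray, beta: float) -> np.ndarray:
    """Exact solution of dX/dt = gamma (S - X) on the grid (per-frame S)."""
    out = np.empty(len(setpoints))
    x = x0
    out[0] = x
    for k in range(1, len(setpoints)):
        x = setpoints[k] + (x - setpoints[k]) * beta
        out[k] = x
    return out


def _pulse_profile(
    n: int,
    dt: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    pulser: bool,
) -> np.ndarray:
    """Additive Gaussian bumps; always consumes RNG draws identically."""
    n_p = min(int(rng.poisson(cfg.pulse_rate_per_cycle)), cfg.max_pulses_per_cycle)
    centers = rng.uniform(0.05, 0.95, n_p) * n * dt
    amps = cfg.pulse_amplitude_afu * np.exp(
        rng.normal(0.0, cfg.pulse_amplitude_sigma, n_p)
    )
    if not pulser or n_p == 0 or n == 0:
        return np.zeros(n)
    t = np.arange(n) * dt
    sigma = cfg.pulse_fwhm_h * 60.0 / 2.355
    prof = np.zeros(n)
    for c, a in zip(centers, amps):
        prof += a * np.exp(-0.5 * ((t - c) / sigma) ** 2)
    prof[0] = 0.0  # the birth frame carries the partitioned level exactly
    return prof


def simulate_lineages(
    config: GeneratorConfig,
    n_founders: int,
    seed: int,
    design: str = "stimulus",
) -> SimulatedDataset:
    """Simulate a tracked lineage experiment.

    ``design='stimulus'``: 42 h of baseline imaging, then the
    differentiation stimulus at t = pre_stimulus_h, with (OCT4, CDX2)
    endpoints at the final frame.  Internally the track-table clock
    starts at frame 0 = start of imaging; the stimulus frame is
    recorded in the ground truth so analyses can re-zero time on it.

    ``design='undisturbed'``: 72 h with no stimulus; endpoints carry the
    final OCT4 level and a DAPI intensity (DNA content) instead.
    """
    config.validate()
    if design not in ("stimulus", "undisturbed"):
        raise ValueError(f"unknown design {design!r}")
    rng = np.random.default_rng(seed)
    dt = config.sampling_interval
    gamma = np.log(2.0) / (config.half_life_h * 60.0)
    beta = np.exp(-gamma * dt)
    if design == "stimulus":
        total_h = config.pre_stimulus_h + config.post_stimulus_h
        stim_frame: int | None = int(round(config.pre_stimulus_h * 60.0 / dt))
    else:
        total_h = config.undisturbed_h
        stim_frame = None
    n_frames = int(round(total_h * 60.0 / dt)) + 1

    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"c{counter:05d}"

    cells: dict[str, _Cell] = {}
    roots: list[str] = []
    queue: list[_Cell] = []
    for _ in range(n_founders):
        cyc = _draw_cycle_frames(config, rng)
        age = int(rng.integers(0, cyc))
        setpoint = config.setpoint_median_afu * np.exp(
            rng.normal(0.0, config.setpoint_log_sd)
        )
        x0 = setpoint * np.exp(rng.normal(0.0, 0.08)) + rng.normal(
            0.0, config.ou_sd_afu
        )
        cell = _Cell(
            cell_id=new_id(),
            parent_id=None,
            birth_frame=None,
            division_frame=min(cyc - age, n_frames - 1)
            if cyc - age < n_frames
            else None,
            first_frame=0,
            setpoint=setpoint,
            x0=max(x0, 1.0),
            pulser=bool(rng.random() < config.pulser_fraction),
            generation=0,
        )
        if cyc - age >= n_frames:
            cell.division_frame = None
        roots.append(cell.cell_id)
        queue.append(cell)

    partition = calibrate_partition_distribution(config.partition_targets)
    lineage_propensity: dict[str, float] = {}
    root_of: dict[str, str] = {}

    while queue:
        cell = queue.pop(0)
        cells[cell.cell_id] = cell
        root = root_of.get(cell.parent_id, cell.cell_id)
        root_of[cell.cell_id] = root
        last = (
            cell.division_frame - 1
            if cell.division_frame is not None
            else n_frames - 1
        )
        n = last - cell.first_frame + 1  # recorded samples
        n_sim = n + 1  # one extra step to the division frame itself

        # one noise/pulse realization per cell; fate features are computed
        # from the same realization that ends up in the track table
        noise = _ou_path(n_sim, dt, config.ou_tau_h * 60.0, config.ou_sd_afu, rng)
        pulse = _pulse_profile(n_sim, dt, config, rng, cell.pulser)

        setpoints = np.full(n_sim, cell.setpoint)
        if stim_frame is not None:
            abs_frames = cell.first_frame + np.arange(n_sim)
            crosses = cell.first_frame <= stim_frame <= last + 1
            if crosses and cell.fate is None:
                # fate drawn at the stimulus from the cell's observed history
                k_stim = max(stim_frame - cell.first_frame, 1)
                pre_base = _relax(cell.x0, setpoints[:k_stim], beta)
                pre_levels = np.maximum(
                    pre_base + noise[:k_stim] + pulse[:k_stim], 1.0
                )
                mean_lvl = float(pre_levels.mean())
                hours_obs = max(k_stim * dt / 60.0, 1.0)
                pf = _count_planted_pulses(pulse[:k_stim], config) / hours_obs
                if root not in lineage_propensity:
                    lineage_propensity[root] = rng.normal(
                        0.0, config.lineage_fate_sd
                    )
                logit = (
                    config.fate_beta0
                    + config.fate_beta_oct4 * mean_lvl / 1000.0
                    + config.fate_beta_pulse * pf
                    + lineage_propensity[root]
                )
                cell.fate = (
                    "self" if rng.random() < 1.0 / (1.0 + np.exp(-logit)) else "diff"
                )
            if cell.fate is not None:
                target = (
                    cell.setpoint * config.post_self_gain
                    if cell.fate == "self"
                    else config.post_diff_level
                )
                setpoints = np.where(abs_frames > stim_frame, target, setpoints)

        base = _relax(cell.x0, setpoints, beta)
        levels = np.maximum(base + noise + pulse, 1.0)
        cell.levels = levels[:n]
        cell.x_div = float(levels[-1])

        if cell.division_frame is not None:
            p = float(partition.sample(rng, 1)[0])
            drift = np.exp(rng.normal(0.0, config.setpoint_drift_sd, 2))
            fracs = (2.0 * p, 2.0 * (1.0 - p))
            # a daughter receiving more protein keeps a proportionally higher
            # setpoint (bookmarking-like persistence of inherited differences)
            c = config.partition_setpoint_coupling
            drift = (drift[0] * fracs[0] ** c, drift[1] * fracs[1] ** c)
            for j in range(2):
                cyc = _draw_cycle_frames(config, rng)
                div = cell.division_frame + cyc
                child_fate = cell.fate
                if (
                    child_fate is not None
                    and stim_frame is not None
                    and cell.division_frame > stim_frame
                    and rng.random() < config.fate_flip_prob
                ):
                    child_fate = "self" if child_fate == "diff" else "diff"
                child = _Cell(
                    cell_id=new_id(),
                    parent_id=cell.cell_id,
                    birth_frame=cell.division_frame,
                    division_frame=div if div < n_frames else None,
                    first_frame=cell.division_frame,
                    setpoint=cell.setpoint * drift[j],
                    x0=max(fracs[j] * cell.x_div, 1.0),
                    pulser=bool(rng.random() < config.pulser_fraction),
                    generation=cell.generation + 1,
                    fate=child_fate,
                )
                queue.append(child)
            cell.partition_p = p

    # ------------------------------------------------------------------ tables
    rows = []
    for cid in sorted(cells):
        c = cells[cid]
        fr = c.first_frame + np.arange(len(c.levels))
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": cid,
                    "parent_id": c.parent_id if c.parent_id is not None else "",
                    "frame": fr,
                    "time_min": fr * dt,
                    "level_afu": np.round(c.levels, 3),
                }
            )
        )
    track = pd.concat(rows, ignore_index=True)

    terminal = [cid for cid, c in sorted(cells.items()) if c.division_frame is None]
    ep_rows = []
    if design == "stimulus":
        for cid in terminal:
            c = cells[cid]
            fate = c.fate if c.fate is not None else "self"
            mean = (
                config.endpoint_self_mean if fate == "self" else config.endpoint_diff_mean
            )
            sd = config.endpoint_self_sd if fate == "self" else config.endpoint_diff_sd
            oct4 = max(rng.normal(mean[0], sd[0]), 1.0)
            cdx2 = max(rng.normal(mean[1], sd[1]), 1.0)
            ep_rows.append({"cell_id": cid, "oct4_afu": oct4, "cdx2_afu": cdx2})
    else:
        for cid in terminal:
            c = cells[cid]
            dapi = 1000.0 * (1.0 + rng.normal(0.0, config.dapi_ratio_sd / np.sqrt(2)))
            ep_rows.append(
                {
                    "cell_id": cid,
                    "oct4_afu": float(c.levels[-1]),
                    "dapi_afu": max(dapi, 1.0),
                }
            )
    endpoints = pd.DataFrame(ep_rows)

    gt = {
        "design": design,
        "seed": seed,
        "stimulus_frame": stim_frame,
        "stimulus_time_min": None if stim_frame is None else stim_frame * dt,
        "n_frames": n_frames,
        "partition": {
            "w": partition.w,
            "s0": partition.s0,
            "m": partition.m,
            "s": partition.s,
        },
        "lineage_propensity": {k: float(v) for k, v in lineage_propensity.items()},
        "cells": {
            cid: {
                "setpoint": float(c.setpoint),
                "pulser": c.pulser,
                "generation": c.generation,
                "fate": c.fate,
                "partition_p": c.partition_p,
                "root": root_of[cid],
            }
            for cid, c in cells.items()
        },
    }
    return SimulatedDataset(
        track_table=track,
        endpoints=endpoints,
        ground_truth=gt,
        config=config,
        design=design,
        seed=seed,
    )


def _count_planted_pulses(pulse_profile: np.ndarray, cfg: GeneratorConfig) -> int:
    """Rough count of planted bumps exceeding the detector floor (feature proxy)."""
    if len(pulse_profile) < 3:
        return 0
    above = pulse_profile > cfg.pulse_amplitude_afu
    return int(np.sum(np.diff(above.astype(int)) == 1) + (1 if above[0] else 0))


def sister_endpoint_table(
    forest: LineageForest, window_min: float = 60.0, end_time: float | None = None
) -> pd.DataFrame:
    """Recently divided sister pairs with endpoint OCT4 and DAPI ratios.

    Pairs whose division happened within ``window_min`` of the final
    frame, both sisters surviving to it; OCT4 ratio from the final
    trace levels, DAPI ratio from the endpoint side table.
    """
    if forest.endpoints is None or "dapi_afu" not in forest.endpoints.columns:
        raise ValueError("forest has no DAPI endpoint measurements")
    ep = forest.endpoints.set_index("cell_id")
    if end_time is None:
        end_time = max(c.times[-1] for c in forest.cells.values())
    rows = []
    for mid in forest.cells:
        kids = forest.children_of(mid)
        if not kids:
            continue
        a, b = (forest.cells[k] for k in kids)
        if a.birth_time is None or a.birth_time < end_time - window_min:
            continue
        if a.cell_id not in ep.index or b.cell_id not in ep.index:
            continue
        if a.times[-1] != end_time or b.times[-1] != end_time:
            continue
        rows.append(
            {
                "pair_id": mid,
                "oct4_ratio": float(a.levels[-1] / b.levels[-1]),
                "dapi_ratio": float(
                    ep.loc[a.cell_id, "dapi_afu"] / ep.loc[b.cell_id, "dapi_afu"]
                ),
            }
        )
    return pd.DataFrame(rows, columns=["pair_id", "oct4_ratio", "dapi_ratio"])


# ---------------------------------------------------------------------------
# fixtures


def tiny_forest_table() -> tuple[pd.DataFrame, dict]:
    """Hand-checkable 12-cell fixture (2 roots), deterministic.

    Root A (9 cells): A -> (B, C); B -> (D, E); C -> (F, G); D -> (H, I).
    Root X (3 cells): X -> (Y, Z).  Terminal cells E, F, G, H, I, Y, Z
    carry endpoint intensities.  Levels are simple linear ramps around
    documented per-cell offsets so summaries can be verified by hand.
    """
    spec = {
        # cell: (parent, first_frame, n_frames, level0, slope)
        "A": (None, 0, 12, 2000.0, 0.0),
        "B": ("A", 12, 12, 2200.0, 10.0),
        "C": ("A", 12, 12, 1800.0, -10.0),
        "D": ("B", 24, 12, 2400.0, 0.0),
        "E": ("B", 24, 12, 2000.0, 0.0),
        "F": ("C", 24, 12, 1700.0, 0.0),
        "G": ("C", 24, 12, 1900.0, 0.0),
        "H": ("D", 36, 6, 2500.0, 0.0),
        "I": ("D", 36, 6, 2300.0, 0.0),
        "X": (None, 0, 18, 1000.0, 5.0),
        "Y": ("X", 18, 24, 1100.0, 0.0),
        "Z": ("X", 18, 24, 900.0, 0.0),
    }
    endpoints = {
        "E": (2100.0, 200.0),
        "F": (500.0, 2400.0),
        "G": (600.0, 2600.0),
        "H": (2600.0, 250.0),
        "I": (2400.0, 300.0),
        "Y": (1200.0, 180.0),
        "Z": (800.0, 2200.0),
    }
    rows = []
    for cid, (parent, f0, n, lvl, slope) in spec.items():
        for k in range(n):
            row = {
                "cell_id": cid,
                "parent_id": parent if parent else "",
                "frame": f0 + k,
                "time_min": (f0 + k) * 5.0,
                "level_afu": lvl + slope * k,
            }
            if k == n - 1 and cid in endpoints:
                row["oct4_end_afu"], row["cdx2_afu"] = endpoints[cid]
            rows.append(row)
    meta = {
        "n_cells": 12,
        "n_roots": 2,
        "terminal_cells": sorted(endpoints),
        "topology": "A->(B,C); B->(D,E); C->(F,G); D->(H,I); X->(Y,Z)",
    }
    return pd.DataFrame(rows), meta


PROFILES = {
    "tiny": {"n_founders": None},
    "default": {"n_founders": 50},
    "stress": {"n_founders": 500},
}


def make_fixture(
    profile: str,
    seed: int,
    outdir,
    design: str = "stimulus",
    config: GeneratorConfig | None = None,
) -> Path:
    """Write an on-disk synthetic dataset (track table, endpoints, truth, manifest)."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or GeneratorConfig()
    if profile == "tiny":
        track, meta = tiny_forest_table()
        track.to_csv(outdir / "track_table.csv", index=False)
        gt: dict = {"profile": "tiny", **meta}
        endpoints = (
            track.dropna(subset=["cdx2_afu"])[["cell_id", "oct4_end_afu", "cdx2_afu"]]
            .rename(columns={"oct4_end_afu": "oct4_afu"})
        )
        endpoints.to_csv(outdir / "endpoints.csv", index=False)
    else:
        ds = simulate_lineages(cfg, PROFILES[profile]["n_founders"], seed, design)
        ds.track_table.to_csv(outdir / "track_table.csv", index=False)
        ds.endpoints.to_csv(outdir / "endpoints.csv", index=False)
        gt = ds.ground_truth
        gt["profile"] = profile
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(
            {
                "profile": profile,
                "seed": seed,
                "design": design,
                "config": cfg.to_dict(),
            },
            fh,
            indent=1,
        )
    return outdir
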