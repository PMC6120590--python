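"""End-to-end orchestration of the lineage analysis.

A run takes (or simulates) two tracked datasets — a differentiation run
with a stimulus at a known time plus endpoint (OCT4, CDX2) stains, and
an undisturbed proliferation run — and executes every stage in order:
per-cell summaries, pulse detection, endpoint mixture and fate calls,
pro-fate propagation, feature extraction and the logistic classifier,
then the inheritance suite (kinship similarity, sister ratios, DAPI
comparison, aligned-pair R^2 decomposition, sister-resampling asymmetry
estimate, rank mixing, autocorrelation mixing time).

The 12 documented output artifacts of a complete run:

    cell_summaries.csv   pulses.csv           mixture_model.json
    fate_calls.csv       profate_labels.csv   feature_table.csv
    group_ks.csv         classifier_fit.json  kinship_differences.csv
    sister_ratios.csv    r2_curve.csv         asymmetry_curves.csv

plus ``manifest.json`` (config snapshot, seed, input hashes, version,
timestamps), ``summary.json`` (scalar results) and auxiliary tables
(decision surfaces, mixing ranks, KDE grids).  All stages are pure
functions of (inputs, config, seed); the per-stage seeds are forked
deterministically from the global seed by stage name, so adding a
stage never perturbs another stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fates import (
    PRO_DIFF,
    PRO_MIXED,
    PRO_SELF,
    UNDETERMINED,
    assign_fate,
    fit_endpoint_mixture,
    propagate_profate,
    sister_fate_concordance,
)
from .inheritance import (
    align_mother_daughter,
    asymmetry_contribution,
    autocorrelation_mixing_time,
    dapi_vs_oct4_ratios,
    division_distance_correlation,
    kinship_differences,
    maternal_fraction,
    mixing_rank_plot,
    r2_decomposition,
    ratio_extremity_fractions,
    ratio_persistence,
    sister_ratios,
    DecayModel,
)
from .lineage import read_track_table, summarize_cells
from .predict import compare_groups, decision_surface, extract_features, train_logistic
from .pulses import PulseParams, count_pulses
from .simulate import (
    GeneratorConfig,
    simulate_lineages,
    sister_endpoint_table,
)

log = logging.getLogger("oct4lineage")

ARTIFACTS = (
    "cell_summaries.csv",
    "pulses.csv",
    "mixture_model.json",
    "fate_calls.csv",
    "profate_labels.csv",
    "feature_table.csv",
    "group_ks.csv",
    "classifier_fit.json",
    "kinship_differences.csv",
    "sister_ratios.csv",
    "r2_curve.csv",
    "asymmetry_curves.csv",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed fork (stage-name hashing), < 2^31."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % 2**31
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "run_output",
    "simulate": {"stimulus_founders": 40, "undisturbed_founders": 40},
    "inputs": {},  # stimulus_track_table / undisturbed_track_table paths
    "stimulus_time_min": None,  # required for user-supplied stimulus tables
    "pulse_params": {"min_width": 15.0, "min_prominence": 200.0},
    "fate_thresholds": {"lower": 0.01, "upper": 0.99},
    "mixture_log10": False,
    "cv_folds": 5,
    "final_offset_min": 480.0,
    "inherited_window_min": 60.0,
    "n_resamples": 100,
    "r2_mode": "instantaneous",
    "half_life_h": 7.34,
}


def load_config(config_path) -> dict:
    with open(config_path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **user}
    for key in ("simulate", "inputs", "pulse_params", "fate_thresholds"):
        base = dict(DEFAULT_CONFIG[key])
        base.update(user.get(key) or {})
        cfg[key] = base
    return cfg


def run_pipeline(config, outdir=None) -> Path:
    """Execute the full analysis; returns the output directory.

    ``config`` is a path to a YAML file or an already-merged dict.
    Input paths are validated before any output is written; any stage
    error aborts with the stage name and cause, and the manifest flags
    the partial run.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = {**DEFAULT_CONFIG, **config}
    outdir = Path(outdir or config["output_dir"])
    seed = int(config["seed"])
    started = time.strftime("%Y-%m-%dT%H:%M:%S")

    inputs = config.get("inputs") or {}
    input_hashes = {}
    for key, p in inputs.items():
        if p and not Path(p).exists():
            raise PipelineError(f"stage load: input {key}={p} does not exist")
    outdir.mkdir(parents=True, exist_ok=True)

    summary: dict = {"seed": seed}
    failed_stage = None
    try:
        _run_stages(config, outdir, seed, inputs, input_hashes, summary)
    except PipelineError:
        raise
    except Exception as exc:  # annotate with the failing stage
        failed_stage = summary.get("_stage", "unknown")
        raise PipelineError(f"stage {failed_stage}: {exc}") from exc
    finally:
        summary.pop("_stage", None)
        manifest = {
            "command": "run_pipeline",
            "config": _jsonable(config),
            "input_hashes": input_hashes,
            "seed": seed,
            "version": __version__,
            "started": started,
            "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "failed_stage": failed_stage,
            "artifacts": list(ARTIFACTS),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=1)
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _run_stages(config, outdir, seed, inputs, input_hashes, summary) -> None:
    gen_cfg = GeneratorConfig(**(config.get("generator") or {}))

    # ---------------------------------------------------------- load/simulate
    summary["_stage"] = "simulate"
    if inputs.get("stimulus_track_table"):
        p = Path(inputs["stimulus_track_table"])
        input_hashes["stimulus_track_table"] = _sha256(p)
        stim_forest = read_track_table(p)
        endpoints = pd.read_csv(inputs["endpoint_table"], dtype={"cell_id": str})
        input_hashes["endpoint_table"] = _sha256(Path(inputs["endpoint_table"]))
        t_stim = config["stimulus_time_min"]
        if t_stim is None:
            raise PipelineError(
                "stage load: stimulus_time_min is required with user tables"
            )
    else:
        ds = simulate_lineages(
            gen_cfg,
            config["simulate"]["stimulus_founders"],
            stage_seed(seed, "simulate_stimulus"),
            design="stimulus",
        )
        ds.track_table.to_csv(outdir / "track_table_stimulus.csv", index=False)
        ds.endpoints.to_csv(outdir / "endpoint_table.csv", index=False)
        stim_forest = ds.forest()
        endpoints = ds.endpoints
        t_stim = ds.ground_truth["stimulus_time_min"]
    if inputs.get("undisturbed_track_table"):
        p = Path(inputs["undisturbed_track_table"])
        input_hashes["undisturbed_track_table"] = _sha256(p)
        und_forest = read_track_table(p)
    else:
        ds_u = simulate_lineages(
            gen_cfg,
            config["simulate"]["undisturbed_founders"],
            stage_seed(seed, "simulate_undisturbed"),
            design="undisturbed",
        )
        ds_u.track_table.to_csv(outdir / "track_table_undisturbed.csv", index=False)
        und_forest = ds_u.forest()
    log.info(
        "loaded %d stimulus-run cells, %d undisturbed cells",
        len(stim_forest),
        len(und_forest),
    )

    # ------------------------------------------------------------- summaries
    summary["_stage"] = "summarize"
    params = PulseParams(
        min_width=config["pulse_params"]["min_width"],
        min_prominence=config["pulse_params"]["min_prominence"],
        sampling_interval=stim_forest.sampling_interval,
    )
    pulse_counts = count_pulses(stim_forest, params)
    summaries = summarize_cells(stim_forest, pulse_counts)
    pd.DataFrame(
        [
            {
                "cell_id": s.cell_id,
                "mean_level_afu": s.mean_level,
                "cycle_duration_h": s.cycle_duration,
                "pulse_frequency_per_h": s.pulse_frequency,
            }
            for s in summaries.values()
        ]
    ).to_csv(outdir / "cell_summaries.csv", index=False)

    pulse_rows = []
    from .pulses import detect_pulses

    for cid, cell in stim_forest.cells.items():
        if not cell.pulse_eligible or cell.n_samples < 3:
            continue
        for p_ in detect_pulses(cell.times, cell.levels, params):
            pulse_rows.append(
                {
                    "cell_id": cid,
                    "peak_time_min": p_.peak_time,
                    "prominence_afu": p_.prominence,
                    "width_min": p_.width,
                }
            )
    pd.DataFrame(
        pulse_rows, columns=["cell_id", "peak_time_min", "prominence_afu", "width_min"]
    ).to_csv(outdir / "pulses.csv", index=False)
    log.info("summaries for %d cells, %d pulses", len(summaries), len(pulse_rows))

    # ---------------------------------------------------------- fate calling
    summary["_stage"] = "classify"
    model = fit_endpoint_mixture(
        endpoints,
        log10=config["mixture_log10"],
        seed=stage_seed(seed, "mixture"),
    )
    (outdir / "mixture_model.json").write_text(model.to_json())
    thr = config["fate_thresholds"]
    calls = assign_fate(endpoints, model, lower=thr["lower"], upper=thr["upper"])
    pd.DataFrame(
        [
            {"cell_id": c.cell_id, "p_diff": c.p_diff, "endpoint_class": c.endpoint_class}
            for c in calls.values()
        ]
    ).to_csv(outdir / "fate_calls.csv", index=False)

    summary["_stage"] = "profate"
    labels = propagate_profate(stim_forest, calls)
    pd.DataFrame(
        [{"cell_id": k, "pro_fate": v} for k, v in labels.items()]
    ).to_csv(outdir / "profate_labels.csv", index=False)
    concordance = sister_fate_concordance(stim_forest, calls)
    determined = [v for v in labels.values() if v != UNDETERMINED]
    n_det = len(determined)
    summary["profate_fractions"] = {
        lab: determined.count(lab) / n_det if n_det else None
        for lab in (PRO_SELF, PRO_DIFF, PRO_MIXED)
    }
    summary["sister_fate_concordance"] = concordance
    log.info("pro-fate determined for %d cells; concordance %s", n_det, concordance)

    # ------------------------------------------------------------ prediction
    summary["_stage"] = "predict"
    training, groups = extract_features(stim_forest, summaries, labels, t_stim)
    training.to_csv(outdir / "feature_table.csv", index=False)
    compare_groups(groups).to_csv(outdir / "group_ks.csv", index=False)
    fit = train_logistic(
        training, k=config["cv_folds"], seed=stage_seed(seed, "cv_folds")
    )
    (outdir / "classifier_fit.json").write_text(json.dumps(fit.to_dict(), indent=1))
    for fixed, name in (
        ({"cycle_duration": 14.0}, "surface_duration14h.csv"),
        ({"pulse_frequency": 0.25}, "surface_pulse025.csv"),
    ):
        decision_surface(fit, fixed).to_csv(outdir / name, index=False)
    summary["cv_accuracy"] = fit.cv_accuracy
    summary["classifier_p_values"] = fit.p_values
    summary["n_training_cells"] = int(fit.n_obs)
    log.info("classifier on %d cells: accuracy %.3f", fit.n_obs, fit.cv_accuracy)

    # ----------------------------------------------------------- inheritance
    summary["_stage"] = "inherit"
    und_summaries = summarize_cells(und_forest)
    kd = kinship_differences(
        und_forest, und_summaries, seed=stage_seed(seed, "kinship_random")
    )
    pd.concat(
        [
            pd.DataFrame({"category": cat, "abs_diff_afu": v})
            for cat, v in kd.diffs.items()
            if len(v)
        ],
        ignore_index=True,
    ).to_csv(outdir / "kinship_differences.csv", index=False)
    kd.ks_report.to_csv(outdir / "kinship_ks.csv", index=False)
    summary["kinship_medians"] = kd.medians()
    rho, rho_p, n_pairs = division_distance_correlation(und_forest, und_summaries)
    summary["division_distance_spearman"] = {"rho": rho, "p": rho_p, "n": n_pairs}

    ratios = sister_ratios(und_forest)
    ratios.to_csv(outdir / "sister_ratios.csv", index=False)
    first = ratios[ratios["window_min"] == ratios["window_min"].min()]
    summary["ratio_extremity_fractions"] = ratio_extremity_fractions(
        first["ratio"].to_numpy()
    )
    pr, pr_p, pr_n = ratio_persistence(und_forest)
    summary["ratio_persistence"] = {"r": pr, "p": pr_p, "n": pr_n}

    try:
        sisters = sister_endpoint_table(und_forest)
        cmp_ = dapi_vs_oct4_ratios(sisters)
        pd.DataFrame(
            {
                "ratio": cmp_.grid,
                "dapi_density": cmp_.dapi_density,
                "oct4_density": cmp_.oct4_density,
            }
        ).to_csv(outdir / "ratio_densities.csv", index=False)
        summary["dapi_vs_oct4"] = {
            "ks_d": cmp_.ks_d,
            "p": cmp_.p_value,
            "n_pairs": cmp_.n_pairs,
        }
    except ValueError as exc:
        log.warning("DAPI comparison skipped: %s", exc)
        summary["dapi_vs_oct4"] = None

    decay = DecayModel(half_life=config["half_life_h"])
    summary["maternal_fraction_5min_pct"] = maternal_fraction(decay, 5.0)
    summary["maternal_fraction_30min_pct"] = maternal_fraction(decay, 30.0)

    summary["_stage"] = "r2"
    pairs = align_mother_daughter(
        und_forest,
        final_offset=config["final_offset_min"],
        inherited_window=config["inherited_window_min"],
    )
    curve = r2_decomposition(pairs, mode=config["r2_mode"])
    curve.to_csv(outdir / "r2_curve.csv", index=False)
    maternal = curve[curve["period"] == "maternal"]["r2"]
    at_1h = curve[curve["time_min"] == config["inherited_window_min"]]["r2"]
    summary["r2_landmarks"] = {
        "maternal_mean": float(maternal.mean()) if len(maternal) else None,
        "end_of_inherited_window": float(at_1h.iloc[0]) if len(at_1h) else None,
        "final": float(curve["r2"].iloc[-1]),
    }
    asym = asymmetry_contribution(
        pairs,
        n_resamples=config["n_resamples"],
        seed=stage_seed(seed, "asymmetry"),
    )
    asym.to_frame().to_csv(outdir / "asymmetry_curves.csv", index=False)
    post = asym.grid > 0
    pre = asym.grid < 0
    summary["asymmetry_difference"] = {
        "post_division_mean": float(np.nanmean(asym.difference_smoothed[post])),
        "pre_division_mean": float(np.nanmean(asym.difference_smoothed[pre])),
        "n_duos": asym.n_duos,
    }
    mixing_rank_plot(pairs, seed=stage_seed(seed, "mixing")).to_csv(
        outdir / "mixing_ranks.csv", index=False
    )

    summary["_stage"] = "mixing_time"
    complete_traces = [
        c.levels for c in und_forest.cells.values() if c.complete
    ]
    cycles = [
        (c.division_time - c.birth_time) / 60.0
        for c in und_forest.cells.values()
        if c.complete
    ]
    hours, frac, acf = autocorrelation_mixing_time(
        complete_traces, float(np.mean(cycles)), und_forest.sampling_interval
    )
    acf.to_csv(outdir / "autocorrelation.csv", index=False)
    summary["mixing_time"] = {"hours": hours, "fraction_of_cycle": frac}
    log.info("mixing time %.2f h (%.0f%% of a cycle)", hours, 100 * frac)


def report(run_dir) -> str:
    """Human-readable summary of a completed (or partial) run directory."""
    run_dir = Path(run_dir)
    lines = ["OCT4 lineage analysis report", "=" * 32]
    warnings_: list[str] = []
    try:
        summary = json.loads((run_dir / "summary.json").read_text())
    except FileNotFoundError:
        return "no summary.json found: run did not start"

    def get(key, fmt="{:.3f}"):
        v = summary.get(key)
        if v is None:
            warnings_.append(f"missing: {key}")
            return "n/a"
        return fmt.format(v) if isinstance(v, (int, float)) else str(v)

    pf = summary.get("profate_fractions") or {}
    lines.append(
        "pro-fate fractions: "
        + ", ".join(
            f"{k}={pf.get(k):.2f}" if pf.get(k) is not None else f"{k}=n/a"
            for k in (PRO_SELF, PRO_DIFF, PRO_MIXED)
        )
    )
    lines.append(f"sister fate concordance: {get('sister_fate_concordance')}")
    lines.append(f"classifier CV accuracy: {get('cv_accuracy')}")
    pv = summary.get("classifier_p_values") or {}
    if pv:
        lines.append(
            "coefficient p-values: "
            + ", ".join(
                f"{k}={v:.2e}" if v is not None else f"{k}=n/a"
                for k, v in pv.items()
                if k != "intercept"
            )
        )
    ks = pd.read_csv(run_dir / "group_ks.csv") if (run_dir / "group_ks.csv").exists() else None
    if ks is not None:
        sig = (ks["tier"] != "ns").sum()
        lines.append(f"group KS tests: {sig}/{len(ks)} significant")
    else:
        warnings_.append("missing: group_ks.csv")
    ext = summary.get("ratio_extremity_fractions") or {}
    if ext:
        lines.append(
            "sister-ratio extremity: "
            + ", ".join(f">= {k}: {v:.3f}" for k, v in ext.items())
        )
    r2 = summary.get("r2_landmarks") or {}
    if r2:
        lines.append(
            "R2 landmarks: maternal {m}, +1 h {h}, final {f:.1f}".format(
                m=_fmt(r2.get("maternal_mean")),
                h=_fmt(r2.get("end_of_inherited_window")),
                f=r2.get("final", float("nan")),
            )
        )
    mt = summary.get("mixing_time") or {}
    if mt:
        lines.append(
            f"mixing time: {mt.get('hours', float('nan')):.2f} h "
            f"({100 * mt.get('fraction_of_cycle', float('nan')):.0f}% of a cycle)"
        )
    lines.append(
        f"maternal fraction: {get('maternal_fraction_5min_pct', '{:.2f}')}% at 5 min, "
        f"{get('maternal_fraction_30min_pct', '{:.2f}')}% at 30 min"
    )
    missing = [a for a in ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        warnings_.append("incomplete run, missing artifacts: " + ", ".join(missing))
    for w in warnings_:
        lines.append(f"WARNING: {w}")
    return "\n".join(lines)


def _fmt(v) -> str:
    return "n/a" if v is None else f"{v:.3f}"
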