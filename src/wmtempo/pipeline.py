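"""End-to-end orchestration: simulate -> preprocess -> analyze -> report.

A run is fully determined by (config, input data).  Every stage writes
tidy CSV/JSON outputs and the analysis emits a manifest listing each
output file with its SHA-256 hash, so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias as bias_mod
from . import inference, metrics, mixture
from .cohort import (
    INTERRUPTION,
    DesignSpec,
    GenerativeParams,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .preprocess import Thresholds, filter_trials, exclude_participants

__all__ = ["PipelineConfig", "run_simulate", "run_analysis", "run_recovery"]


@dataclass
class AnalysisOptions:
    bias_step: float = 5.0
    bias_width: float = 45.0
    mixture: mixture.FitOptions = field(default_factory=mixture.FitOptions)
    bonferroni_family_sizes: dict[str, int] = field(default_factory=lambda: {"presence_by_type": 2, "rt_onset": 3})
    chance_level_deg: float = 45.0


@dataclass
class PipelineConfig:
    design: DesignSpec = field(default_factory=DesignSpec)
    generation: GenerativeParams = field(default_factory=GenerativeParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed, design=dataclasses.replace(self.design, rng_seed=seed)
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        design = dataclasses.replace(cfg.design, **_coerce(d.get("design", {}), DesignSpec))
        gen_d = dict(d.get("generation", {}))
        if "interrupter_rt_offsets_ms" in gen_d:
            gen_d["interrupter_rt_offsets_ms"] = {
                (pred, int(onset)): float(v)
                for pred, sub in gen_d["interrupter_rt_offsets_ms"].items()
                for onset, v in sub.items()
            }
        for key in ("rt_probe_params", "rt_dial_params", "rt_interrupter_params"):
            if key in gen_d:
                gen_d[key] = tuple(gen_d[key])
        generation = dataclasses.replace(cfg.generation, **gen_d)
        thresholds = dataclasses.replace(cfg.thresholds, **d.get("preprocessing", {}))
        an_d = dict(d.get("analysis", {}))
        if "mixture" in an_d:
            an_d["mixture"] = dataclasses.replace(mixture.FitOptions(), **an_d["mixture"])
        analysis = dataclasses.replace(cfg.analysis, **an_d)
        seed = int(d.get("seed", cfg.seed))
        out = cls(design=design, generation=generation, thresholds=thresholds, analysis=analysis, seed=seed)
        return out.with_seed(seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        offs = d["generation"]["interrupter_rt_offsets_ms"]
        nested: dict[str, dict[int, float]] = {}
        for (pred, onset), v in offs.items():
            nested.setdefault(pred, {})[int(onset)] = float(v)
        d["generation"]["interrupter_rt_offsets_ms"] = nested
        return d


def _coerce(d: dict, cls) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    out = {}
    for k, v in d.items():
        if k in names:
            out[k] = tuple(v) if isinstance(v, list) else v
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_simulate(config: PipelineConfig, outdir: Path) -> Path:
    """Generate a cohort and write the trial CSV plus a config snapshot."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.design, config.generation)
    trial_path = outdir / "trials.csv"
    write_cohort(cohort, trial_path)
    with open(outdir / "config_snapshot.yaml", "w") as fh:
        yaml.safe_dump(config.snapshot(), fh, sort_keys=True)
    return trial_path


def _ttest_dict(res: inference.TTestResult) -> dict:
    return dataclasses.asdict(res)


def run_analysis(records: pd.DataFrame, config: PipelineConfig, outdir: Path) -> dict:
    """Run preprocessing, metrics, mixture, bias and inference stages.

    Returns the manifest (also written as ``manifest.json``).  Inferential
    outputs mirror the standard analysis list: interference presence x
    type ANOVA on errors; predictability x type x onset ANOVA on errors;
    predictability x onset ANOVA on interrupter RTs; 2 x 2 ANOVAs on swap
    rates and equated bias; one-sample attraction t test; and the
    interference-report deviation test against the chance level.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    opts = config.analysis
    files: dict[str, Path] = {}

    kept, log = filter_trials(records, config.thresholds)
    keep_ids = exclude_participants(log, config.thresholds.exclusion_fraction)
    kept = kept[kept["participant_id"].isin(keep_ids)].reset_index(drop=True)
    log.to_csv(outdir / "rejections.csv")
    files["rejections"] = outdir / "rejections.csv"
    with open(outdir / "rejection_summary.json", "w") as fh:
        json.dump(log.summary_dict(), fh, indent=2)
    files["rejection_summary"] = outdir / "rejection_summary.json"

    kept = metrics.add_errors(kept)
    results: dict = {
        "n_participants_in": int(records["participant_id"].nunique()),
        "n_participants_kept": len(keep_ids),
        "n_trials_kept": int(len(kept)),
    }

    # condition summaries
    presence = metrics.condition_means(kept, ["interference_type", "interference_present"])
    presence.to_csv(outdir / "summary_presence_by_type.csv", index=False)
    files["summary_presence_by_type"] = outdir / "summary_presence_by_type.csv"
    interference = kept[kept["interference_present"]]
    onset_cells = metrics.condition_means(interference, ["predictability", "interference_type", "onset_ms"])
    onset_cells.to_csv(outdir / "summary_pred_type_onset.csv", index=False)
    files["summary_pred_type_onset"] = outdir / "summary_pred_type_onset.csv"

    # ANOVAs on reproduction errors
    results["anova_presence_by_type"] = rm_anova_records(
        presence, "mean_abs_error", ["interference_present", "interference_type"]
    )
    results["anova_pred_type_onset"] = rm_anova_records(
        onset_cells, "mean_abs_error", ["predictability", "interference_type", "onset_ms"]
    )

    # interrupter RTs: predictability x onset
    interrupt = interference[interference["interference_type"] == INTERRUPTION]
    rt_cells = metrics.condition_means(interrupt, ["predictability", "onset_ms"])
    results["anova_rt_pred_onset"] = rm_anova_records(rt_cells, "mean_interrupter_rt", ["predictability", "onset_ms"])

    # swap mixture per participant x (type, predictability)
    swaps = mixture.swap_table(interference, opts=opts.mixture)
    swaps.to_csv(outdir / "swap_table.csv", index=False)
    files["swap_table"] = outdir / "swap_table.csv"
    results["anova_swaps"] = rm_anova_records(swaps, "p_nontarget", ["interference_type", "predictability"])

    # response-bias analysis
    demeaned = bias_mod.demean_signed_errors(kept)
    with_delta = demeaned[np.isfinite(demeaned["delta"])]
    per_participant = []
    curves = []
    for pid, sub in with_delta.groupby("participant_id"):
        curve = bias_mod.compute_bias_curve(
            sub["demeaned_error"], sub["delta"], step=opts.bias_step, width=opts.bias_width
        )
        cf = curve.as_frame()
        cf.insert(0, "participant_id", pid)
        curves.append(cf)
        auc = bias_mod.integrate_auc(curve)
        per_participant.append({"participant_id": pid, **auc._asdict()})
    curve_df = pd.concat(curves, ignore_index=True)
    curve_df.to_csv(outdir / "bias_curves.csv", index=False)
    files["bias_curves"] = outdir / "bias_curves.csv"
    auc_df = pd.DataFrame(per_participant)
    results["attraction_test"] = bias_mod.attraction_test(auc_df["attraction_stat"])

    eq = bias_mod.equated_bias(demeaned)
    eq.to_csv(outdir / "equated_bias.csv", index=False)
    files["equated_bias"] = outdir / "equated_bias.csv"
    results["anova_equated_bias"] = rm_anova_records(eq, "equated_bias", ["interference_type", "predictability"])

    # deviation between interference angle and report vs chance level
    dev = metrics.condition_means(
        interference.assign(
            reproduction_error=metrics.reproduction_error(
                interference["report_angle"].to_numpy(dtype=float),
                interference["interference_angle"].to_numpy(dtype=float),
            )
        ),
        [],
    )
    tt = inference.paired_t(
        dev["mean_abs_error"].to_numpy(), np.full(len(dev), opts.chance_level_deg)
    )
    results["interference_deviation_vs_chance"] = {
        "chance_deg": opts.chance_level_deg,
        "mean": float(dev["mean_abs_error"].mean()),
        **_ttest_dict(tt),
    }

    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2)
    files["results"] = outdir / "results.json"

    manifest = {
        "n_input_trials": int(len(records)),
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in sorted(files.items())},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def rm_anova_records(table: pd.DataFrame, dv: str, within: list[str]) -> list[dict]:
    out = inference.rm_anova(table, dv, within, "participant_id")
    return out.drop(columns=["ss_effect", "ss_error"]).to_dict(orient="records")


def _expected_wrapped_error(mu_deg: np.ndarray, kappa: float) -> np.ndarray:
    """E[wrap(mu + noise)] for von Mises noise (doubled circle), by quadrature."""
    from .circular import wrap_orientation

    u = np.arange(-89.975, 90.0, 0.05)
    w = np.exp(kappa * (np.cos(np.deg2rad(2.0 * u)) - 1.0))
    w /= w.sum()
    mu_unique, inverse = np.unique(np.asarray(mu_deg, dtype=float), return_inverse=True)
    exp_vals = np.array([np.sum(wrap_orientation(m + u) * w) for m in mu_unique])
    return exp_vals[inverse]


def run_recovery(config: PipelineConfig, n_seeds: int, outdir: Path | None = None) -> dict:
    """Parameter-recovery study: simulate, refit, report bias and RMSE.

    Uses a clean generator (no contamination, homogeneous kappa) so that
    the pooled-fit truth is well defined: the mixture's uniform component
    should recover p_guess, its non-target component (1 - p_guess) *
    p_swap, and kappa the base concentration.  The equated-bias oracle is
    the (1 - p_guess)-diluted grid average of the generative bias over the
    realised deltas.
    """
    base = config.generation
    params = dataclasses.replace(
        base,
        interruption_kappa_factor=1.0,
        variable_onset_kappa_factor=1.0,
        contamination_rates={},
    )
    truth = {
        "p_nontarget": (1.0 - params.p_guess) * params.p_swap,
        "p_uniform": params.p_guess,
        "kappa": params.kappa_base,
    }
    rows = []
    for i in range(n_seeds):
        spec = dataclasses.replace(config.design, rng_seed=config.seed + i)
        cohort = generate_cohort(spec, params)
        inter = cohort[cohort["interference_present"]]
        fit = mixture.fit_mixture(
            inter["report_angle"].to_numpy(dtype=float),
            inter["target_angle"].to_numpy(dtype=float),
            inter["interference_angle"].to_numpy(dtype=float),
            config.analysis.mixture,
        )
        dem = bias_mod.demean_signed_errors(cohort)
        sub = dem[np.isfinite(dem["delta"])]
        d = sub["delta"].to_numpy(dtype=float)
        e = sub["demeaned_error"].to_numpy(dtype=float)
        eq_est = (e[d > 0].mean() - e[d < 0].mean()) / 2.0
        # per-trial expected signed error: guesses contribute 0; swap reports
        # centre on the interference (wrapped mean ~ delta), target reports on
        # the sinusoidal bias; both shrink near the +/-90 boundary because
        # noise wraps, so take the exact wrapped expectation
        delta_bias = params.bias_amplitude * np.sin(2.0 * np.deg2rad(d))
        gen_bias = (1.0 - params.p_guess) * (
            (1.0 - params.p_swap) * _expected_wrapped_error(delta_bias, params.kappa_base)
            + params.p_swap * _expected_wrapped_error(d, params.kappa_base)
        )
        eq_truth = (gen_bias[d > 0].mean() - gen_bias[d < 0].mean()) / 2.0
        rows.append(
            {
                "seed": spec.rng_seed,
                "n_interference_trials": int(len(inter)),
                "p_nontarget_est": fit.p_nontarget,
                "p_uniform_est": fit.p_uniform,
                "kappa_est": fit.kappa,
                "equated_bias_est": float(eq_est),
                "equated_bias_truth": float(eq_truth),
            }
        )
    per_seed = pd.DataFrame(rows)
    report = {
        "truth": truth,
        "n_seeds": n_seeds,
        "per_seed": rows,
        "summary": {
            "p_nontarget_mean_abs_err": float((per_seed["p_nontarget_est"] - truth["p_nontarget"]).abs().mean()),
            "p_uniform_mean_abs_err": float((per_seed["p_uniform_est"] - truth["p_uniform"]).abs().mean()),
            "kappa_rel_rmse": float(
                np.sqrt(np.mean(((per_seed["kappa_est"] - truth["kappa"]) / truth["kappa"]) ** 2))
            ),
            "equated_bias_mean_err": float((per_seed["equated_bias_est"] - per_seed["equated_bias_truth"]).mean()),
        },
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "recovery.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
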