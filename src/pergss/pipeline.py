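"""End-to-end orchestration: simulate -> preprocess -> analyze -> stats.

A :class:`RunConfig` fully determines a run: the cohort design and sweep
noise model, preprocessing parameters, the timing window, and the
statistics options.  Each stage reads and writes the plain-text formats of
:mod:`pergss.sweep_io`, so any stage can be re-run in isolation from its
on-disk inputs, and identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import stats as st
from .preprocess import block_to_trace, preprocess_block, trace_to_block
from .spectral import analyze_trace
from .stimulus import StimulusCondition
from .sweep_io import (SweepArchive, read_archive, read_cohort_csv,
                       write_archive, write_cohort_csv)
from .synthetic import (CohortDesign, SweepNoiseModel, generate_sweep_archive,
                        _MODEL_COLUMNS)
from .timing import phase_to_response_time


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs."""

    seed: int = 0
    design: CohortDesign = field(default_factory=CohortDesign)
    noise: SweepNoiseModel = field(default_factory=SweepNoiseModel)
    n_sweeps: int = 100
    threshold_uV: float = 120.0
    artifact_criterion: str = "absolute"
    cutoff_hz: float = 40.0
    detrend_method: str = "protect"
    detrend_first: bool = False
    window_lo_ms: float = 30.0
    noise_method: str = "linear"
    alpha: float = 0.05
    ratio_floor_uV: float = 0.05
    check_small_deg: float = 0.8
    check_large_deg: float = 16.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"]["amplitude_model"] = self.design.amplitude_model.to_dict("records")
        d["design"]["time_model"] = self.design.time_model.to_dict("records")
        d["design"]["conditions"] = [
            {"check_size_deg": c.check_size_deg,
             "reversal_rate_rps": c.reversal_rate_rps}
            for c in self.design.conditions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        design_d = dict(d.pop("design", {}))
        noise_d = dict(d.pop("noise", {}))
        kwargs = {}
        if "amplitude_model" in design_d:
            kwargs["amplitude_model"] = pd.DataFrame(
                design_d.pop("amplitude_model"))[_MODEL_COLUMNS]
        if "time_model" in design_d:
            kwargs["time_model"] = pd.DataFrame(
                design_d.pop("time_model"))[_MODEL_COLUMNS]
        if "conditions" in design_d:
            kwargs["conditions"] = tuple(
                StimulusCondition(c["check_size_deg"], c["reversal_rate_rps"])
                for c in design_d.pop("conditions"))
        for key in ("groups", "eyes"):
            if key in design_d:
                design_d[key] = tuple(design_d[key])
        design = CohortDesign(**design_d, **kwargs)
        noise = SweepNoiseModel(**noise_d)
        return cls(design=design, noise=noise, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def validate_config(config: RunConfig) -> list[str]:
    """Every violated invariant as a message; empty iff the config is runnable."""
    problems: list[str] = []
    noise = config.noise
    nyquist = noise.sampling_rate_hz / 2.0
    if config.cutoff_hz >= nyquist:
        problems.append(
            f"low-pass cutoff {config.cutoff_hz:g} Hz is not below the Nyquist "
            f"frequency {nyquist:g} Hz")
    try:
        config.design.validate()
    except ValueError as exc:
        problems.append(f"cohort design: {exc}")
    for cond in config.design.conditions:
        try:
            k = cond.bin_index(noise.sweep_length_s)
        except ValueError as exc:
            problems.append(str(exc))
            continue
        if k < 2:
            problems.append(
                f"{cond.label()}: analysis bin {k} has no non-DC lower neighbour "
                "for the noise estimate")
        if k >= noise.n_samples / 2:
            problems.append(f"{cond.label()}: analysis bin {k} is above Nyquist")
        if cond.frequency_hz > config.cutoff_hz:
            problems.append(
                f"{cond.label()}: analysis frequency {cond.frequency_hz:g} Hz would "
                f"be removed by the {config.cutoff_hz:g} Hz low-pass filter")
    if config.threshold_uV <= 0:
        problems.append("artifact threshold must be > 0")
    if config.n_sweeps < 1:
        problems.append("n_sweeps must be >= 1")
    if not 0.0 < config.alpha < 1.0:
        problems.append("alpha must lie in (0, 1)")
    if config.window_lo_ms < 0:
        problems.append("timing window lower bound must be >= 0")
    if config.ratio_floor_uV <= 0:
        problems.append("ratio denominator floor must be > 0")
    cond_keys = {(c.check_size_deg, c.reversal_rate_rps)
                 for c in config.design.conditions}
    for check in (config.check_small_deg, config.check_large_deg):
        if not any(k[0] == check for k in cond_keys):
            problems.append(f"ratio check size {check:g} deg not among the "
                            "configured conditions")
    return problems


def stage_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate the synthetic cohort: sweep archive + ground-truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = replace(config.design, seed=config.seed)
    archive, records, truth = generate_sweep_archive(
        design, config.noise, n_sweeps=config.n_sweeps)
    write_archive(archive, out / "sweeps")
    write_cohort_csv(records, out / "ground_truth_records.csv")
    truth.to_csv(out / "ground_truth_means.csv", index=False)
    return out / "sweeps"


def stage_preprocess(archive_dir: str | Path, out_dir: str | Path,
                     config: RunConfig) -> Path:
    """Reject artifacts, average, filter, detrend; write the traces archive."""
    archive = read_archive(archive_dir)
    traces = [
        trace_to_block(preprocess_block(
            block, threshold_uV=config.threshold_uV, cutoff_hz=config.cutoff_hz,
            detrend_method=config.detrend_method,
            detrend_first=config.detrend_first,
            artifact_criterion=config.artifact_criterion))
        for block in archive
    ]
    out = Path(out_dir)
    write_archive(SweepArchive(
        blocks=traces,
        provenance={**archive.provenance, "stage": "preprocess",
                    "threshold_uV": config.threshold_uV,
                    "cutoff_hz": config.cutoff_hz,
                    "detrend_method": config.detrend_method}), out)
    return out


def stage_analyze(traces_dir: str | Path, out_csv: str | Path,
                  config: RunConfig) -> Path:
    """Spectral + timing measurement of every trace -> per-eye cohort CSV.

    ``amplitude_uV`` in the output is the noise-corrected amplitude; the
    raw fundamental amplitude and phase are carried in extra columns.
    """
    archive = read_archive(traces_dir)
    rows = []
    for block in archive:
        trace = block_to_trace(block)
        comp = analyze_trace(trace, noise_method=config.noise_method)
        rt = phase_to_response_time(comp.phase_rad, comp.frequency_hz,
                                    window_lo_ms=config.window_lo_ms)
        rows.append((trace.subject_id, trace.group, trace.eye,
                     trace.condition.check_size_deg,
                     trace.condition.reversal_rate_rps,
                     comp.corrected_amplitude_uV, comp.noise_uV, comp.snr,
                     rt.time_ms, comp.amplitude_uV, comp.phase_rad,
                     rt.cycles_added, trace.n_sweeps_used,
                     trace.n_sweeps_rejected))
    cohort = pd.DataFrame(rows, columns=[
        "subject", "group", "eye", "check_size_deg", "reversal_rate_rps",
        "amplitude_uV", "noise_uV", "snr", "response_time_ms",
        "raw_amplitude_uV", "phase_rad", "cycles_added", "n_sweeps_used",
        "n_sweeps_rejected"])
    cohort = cohort.sort_values(
        ["subject", "eye", "reversal_rate_rps", "check_size_deg"],
        ignore_index=True)
    write_cohort_csv(cohort, out_csv)
    return Path(out_csv)


def stage_stats(cohort_csv: str | Path, out_dir: str | Path,
                config: RunConfig) -> dict[str, Path]:
    """Eye averaging + the full inference layer; writes the report bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort_csv(cohort_csv)
    averaged = st.average_eyes(cohort)

    paths: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = out / f"{name}.csv"
        df.to_csv(p, index=index, float_format="%.12g")
        paths[name] = p

    save("cohort_eye_averaged", averaged)
    for dv, tag in (("amplitude_uV", "amplitude"), ("response_time_ms", "time")):
        anova = st.mixed_anova(averaged, dv)
        save(f"anova_{tag}", anova.effects.reset_index())
        posthoc = st.emm_posthoc(averaged, dv, alpha=config.alpha)
        save(f"posthoc_{tag}", posthoc)
        if dv == "amplitude_uV":
            save("effect_size_profile", st.effect_size_profile(posthoc))

    ratios = st.ratio_table(averaged, config.check_small_deg,
                            config.check_large_deg, config.ratio_floor_uV)
    save("ratios", ratios)
    ratio_anova = st.mixed_anova(ratios, "ratio", within=("reversal_rate_rps",))
    save("anova_ratio", ratio_anova.effects.reset_index())
    save("posthoc_ratio", st.emm_posthoc(ratios, "ratio",
                                         within=("reversal_rate_rps",),
                                         alpha=config.alpha))

    # pooled group and frequency comparisons (rank-based screening tests)
    subj = averaged.groupby(["subject", "group"], sort=True)
    subj_amp = subj["amplitude_uV"].mean().reset_index()
    grp = {g: c["amplitude_uV"].to_numpy()
           for g, c in subj_amp.groupby("group")}
    groups = config.design.groups
    overall_amp = st.wilcoxon_rank_sum(grp[groups[1]], grp[groups[0]],
                                       alternative="less")
    by_rate = averaged.pivot_table(index="subject", columns="reversal_rate_rps",
                                   values="amplitude_uV", aggfunc="mean")
    rates = sorted(by_rate.columns)
    freq_test = st.wilcoxon_signed_rank(
        (by_rate[rates[1]] - by_rate[rates[0]]).to_numpy(),
        alternative="less")
    save("overall_tests", pd.DataFrame([
        ("amplitude_group_one_sided", *overall_amp),
        ("amplitude_frequency_paired_one_sided", *freq_test)],
        columns=["test", "statistic", "p_value", "method"]))

    log = {
        "alpha": config.alpha,
        "noise_correction": config.noise_method,
        "detrend_method": config.detrend_method,
        "artifact_threshold_uV": config.threshold_uV,
        "artifact_criterion": config.artifact_criterion,
        "lowpass_cutoff_hz": config.cutoff_hz,
        "timing_window_lo_ms": config.window_lo_ms,
        "ratio_floor_uV": config.ratio_floor_uV,
        "emm_pooling": "all error strata pooled into one SE on the summed df",
        "gg_correction": "applied to within effects with > 2 levels",
        "effect_size_sign": f"positive = {groups[0]} larger than {groups[1]}",
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    paths["run_log"] = out / "run_log.json"
    return paths


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run every stage in order; halts at the first failing stage."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(problems))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    sweeps = stage_simulate(config, out)
    traces = stage_preprocess(sweeps, out / "traces", config)
    cohort = stage_analyze(traces, out / "cohort.csv", config)
    paths = stage_stats(cohort, out / "report", config)
    paths.update({"sweeps": sweeps, "traces": traces, "cohort": cohort})
    return paths
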