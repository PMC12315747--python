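"""End-to-end orchestration: simulate -> preprocess -> markers -> statistics -> ERP.

``run_full`` ties all stages into the two headline analyses (DFA x condition
and PSD x amino-acid x condition cluster-permutation tests), the exploratory
LRTC x PSD interaction with median split and VIF, and the ERP arm (P300
accuracy model plus marker -> P300 models).  The default configuration is a
reduced-scale study (16 electrodes, 40 subjects, 200 permutations) chosen so
a complete run finishes comfortably on one CPU; the full-scale layout
(61 electrodes, 73 subjects, B=1000) is a matter of config fields.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import clusterstats as cs
from . import erp as erp_mod
from . import markers as mk
from . import preprocess as pp
from . import synth
from .montage import default_montage

__all__ = ["RunConfig", "RunReport", "validate_config", "run_full"]

#: Contiguous right-centroparietal 16-channel subset (includes Pz) used by
#: the reduced-scale default configuration.
REDUCED_CHANNELS = ["FC1", "C1", "Cz", "C2", "C4", "FC4", "CP2", "CP4", "CP6",
                    "P4", "P6", "P8", "PO4", "PO10", "POz", "Pz"]


@dataclass
class RunConfig:
    """Validated parameters of a full pipeline run."""

    seed: int = 0
    n_subjects: int = 40
    channels: list = field(default_factory=lambda: list(REDUCED_CHANNELS))
    duration_s: float = 600.0
    fs: float = 500.0
    dfa_mean: float = synth.DEFAULT_DFA_MEAN
    dfa_sd: float = synth.DEFAULT_DFA_SD
    gamma_mean: float = synth.DEFAULT_GAMMA_MEAN
    gamma_sd: float = synth.DEFAULT_GAMMA_SD
    effects: synth.EffectConfig = field(default_factory=synth.EffectConfig)
    band_low: float = 0.5
    band_high: float = 45.0
    notch_hz: float = 50.0
    fit_range: tuple = (3.0, 40.0)
    n_permutations: int = 200
    p_thresh: float = 0.05
    min_cluster_size: int = 2
    erp_artifact_frac: float = 0.02
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "effects" in raw:
            raw["effects"] = synth.EffectConfig(**raw["effects"])
        if "fit_range" in raw:
            raw["fit_range"] = tuple(raw["fit_range"])
        return cls(**raw)


@dataclass
class RunReport:
    """Provenance, summaries and decisions of one pipeline run."""

    config: dict
    marker_summary: dict
    cluster_results: dict
    posthoc: dict
    interaction: dict
    median_split: dict
    erp_results: dict
    warnings: list

    def to_json(self, path=None) -> str:
        txt = json.dumps(self._jsonable(asdict(self)), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(txt)
        return txt

    @staticmethod
    def _jsonable(obj):
        if isinstance(obj, dict):
            return {str(k): RunReport._jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [RunReport._jsonable(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj


def validate_config(config: RunConfig) -> list[str]:
    """Schema check; returns a list of human-readable violations (empty = valid)."""
    v = []
    if config.n_subjects < 8:
        v.append("n_subjects must be >= 8")
    if config.n_permutations < 1:
        v.append("n_permutations must be positive")
    if not (0 < config.band_low < config.band_high < config.fs / 2):
        v.append("band must satisfy 0 < low < high < Nyquist")
    if config.duration_s < 50:
        v.append("duration_s must be >= 50 s for 25-s DFA windows")
    if not (0 < config.p_thresh < 1):
        v.append("p_thresh must be in (0, 1)")
    if config.min_cluster_size < 2:
        v.append("min_cluster_size must be >= 2")
    if "Pz" not in config.channels:
        v.append("channels must include Pz for the ERP stage")
    if not (0 <= config.erp_artifact_frac < 1):
        v.append("erp_artifact_frac must be in [0, 1)")
    if not (0.5 < config.dfa_mean < 1.0):
        v.append("dfa_mean must be in (0.5, 1.0)")
    if config.gamma_mean < 0:
        v.append("gamma_mean must be >= 0")
    return v


def _cluster_summary(res: cs.PermutationResult) -> dict:
    return dict(
        clusters=[dict(members=c.members, mass=c.mass, sign=c.sign,
                       p=float(p), significant=bool(s))
                  for c, p, s in zip(res.clusters, res.cluster_p, res.significant)],
        null_95th=res.threshold,
        n_permutations=len(res.null_max_masses),
        n_nonconverged=res.n_nonconverged,
        seed=res.seed,
        electrode_stats={f.electrode: dict(t=f.contrast_t, p=f.contrast_p,
                                           beta=f.contrast_beta)
                         for f in res.electrode_fits},
    )


def _cluster_average(markers_wide: pd.DataFrame, res: cs.PermutationResult) -> pd.Series:
    """Subject-level average marker over the top cluster (all electrodes if none)."""
    if res.clusters:
        cols = res.clusters[0].members
    else:
        cols = list(markers_wide.columns)
    return markers_wide[cols].mean(axis=1)


def run_full(config: RunConfig) -> RunReport:
    """Execute every stage on synthetic data and assemble the run report.

    Stages: cohort simulation, resting-EEG synthesis and preprocessing,
    marker estimation, behavior generation + RT filtering + aggregation,
    per-electrode cluster-permutation tests for the four accuracy model
    families, post-hoc condition slopes, the joint DFA x PSD model with
    median split and VIF, and the ERP arm.  Fully deterministic given the
    config (identical config -> identical report JSON).  When
    ``config.out_dir`` is set, intermediates (marker table, trial table,
    accuracy table, report) are persisted there.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    caught: list[str] = []
    root = np.random.SeedSequence(config.seed)
    s_cohort, s_rest, s_beh, s_perm, s_erp = root.spawn(5)
    montage = default_montage().subset(config.channels)

    # --- cohort & resting markers -------------------------------------
    cohort, panels = synth.synth_cohort(
        config.n_subjects, seed=np.random.default_rng(s_cohort),
        dfa_mean=config.dfa_mean, dfa_sd=config.dfa_sd,
        gamma_mean=config.gamma_mean, gamma_sd=config.gamma_sd)
    aa = pd.Series(beh.amino_acid_ratio(panels).to_numpy(),
                   index=[p.subject_id for p in cohort])
    rest_streams = s_rest.spawn(len(cohort))
    marker_rows = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        for p, ss in zip(cohort, rest_streams):
            rec = synth.synth_resting_eeg(p, montage, config.duration_s, config.fs,
                                          seed=np.random.default_rng(ss))
            rec = pp.notch(pp.bandpass(rec, config.band_low, config.band_high),
                           config.notch_hz)
            marker_rows.append(mk.compute_marker_table(rec, subject=p.subject_id,
                                                       fit_range=config.fit_range))
    caught += sorted({str(w.message) for w in wlist})
    marker_table = pd.concat(marker_rows, ignore_index=True)
    dfa_wide = marker_table.pivot(index="subject", columns="channel", values="dfa")
    psd_wide = marker_table.pivot(index="subject", columns="channel", values="gamma")
    marker_summary = dict(
        dfa_grand_mean=float(marker_table["dfa"].mean()),
        dfa_grand_sd=float(dfa_wide.mean(axis=1).std(ddof=1)),
        gamma_grand_mean=float(marker_table["gamma"].mean()),
        gamma_grand_sd=float(psd_wide.mean(axis=1).std(ddof=1)),
        rel_alpha_mean=float(marker_table["rel_alpha"].mean()),
    )

    # --- behavior ------------------------------------------------------
    trials = synth.synth_behavior(cohort, config.effects,
                                  seed=np.random.default_rng(s_beh))
    filtered, removal_log = beh.filter_trials(trials, return_log=True)
    acc = beh.accuracy_by_condition(filtered)

    # --- cluster statistics (models m1, m2, m1a, m2a) ------------------
    perm_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in s_perm.spawn(4)]
    cluster_results = {}
    specs = [("m1", psd_wide, None), ("m2", dfa_wide, None),
             ("m1a", psd_wide, aa), ("m2a", dfa_wide, aa)]
    for (fid, wide, aa_arg), ps in zip(specs, perm_seeds):
        cluster_results[fid] = cs.permutation_test(
            acc, wide, montage, formula_id=fid, aa=aa_arg,
            B=config.n_permutations, seed=ps, p_thresh=config.p_thresh,
            min_size=config.min_cluster_size)

    # --- post-hoc slopes on cluster averages ---------------------------
    dfa_cluster_avg = _cluster_average(dfa_wide, cluster_results["m2"])
    psd_cluster_avg = _cluster_average(psd_wide, cluster_results["m1a"])
    posthoc = dict(
        dfa=cs.posthoc_condition_slopes(acc, dfa_cluster_avg).to_dict("records"),
        psd_aa=cs.posthoc_condition_slopes(acc, psd_cluster_avg, aa=aa)
        .to_dict("records"))

    # --- joint LRTC x PSD model, median split, VIF ---------------------
    inter = cs.interaction_model(acc, dfa_cluster_avg, psd_cluster_avg)
    interaction = {k: inter[k] for k in ("dfa_psd", "dfa_psd_condition", "vif")}
    med = cs.median_split_analysis(acc, dfa_cluster_avg, psd_cluster_avg)

    # --- ERP arm (models m5, m6a, m6b) ---------------------------------
    gating = filtered[filtered["condition"].isin(["ignore", "update"])]
    epochs = synth.synth_erp_epochs(cohort, gating, montage, fs=config.fs,
                                    seed=np.random.default_rng(s_erp),
                                    artifact_frac=config.erp_artifact_frac)
    epochs = erp_mod.baseline_correct(epochs)
    epochs = erp_mod.reject_epochs(epochs)
    subject_report = erp_mod.exclude_noisy_subjects(epochs)
    keep_subjects = set(subject_report.loc[subject_report["keep"], "subject"])
    p300 = erp_mod.p300_amplitude(epochs)
    p300 = p300[p300["subject"].isin(keep_subjects)]
    ga = erp_mod.grand_average(epochs, "Pz")
    latency = erp_mod.peak_latency(epochs.times, ga)
    m5 = erp_mod.trial_logistic_model(p300)
    m6 = erp_mod.p300_predictor_models(
        p300, dfa_cluster_avg.reindex(sorted(keep_subjects)),
        psd_cluster_avg.reindex(sorted(keep_subjects)),
        aa.reindex(sorted(keep_subjects)))
    erp_results = dict(
        peak_latency_s=float(latency),
        p300_mean_by_condition=p300.groupby("condition", observed=True)["amplitude"]
        .mean().to_dict(),
        n_rejected=int(epochs.rejected.sum()),
        n_subjects_dropped=int((~subject_report["keep"]).sum()),
        m5=dict(coefficients=m5["coefficients"].to_dict("index"),
                sigma_subject=m5["sigma_subject"], converged=m5["converged"],
                separation=m5["separation"]),
        m6a={k: m6["m6a"][k] for k in ("beta", "se", "t", "p")},
        m6b={k: m6["m6b"][k] for k in ("beta", "se", "t", "p")},
    )

    report = RunReport(
        config={**{k: v for k, v in asdict(config).items() if k != "effects"},
                "effects": asdict(config.effects)},
        marker_summary=marker_summary,
        cluster_results={fid: _cluster_summary(r) for fid, r in cluster_results.items()},
        posthoc=posthoc,
        interaction=interaction,
        median_split=med,
        erp_results=erp_results,
        warnings=caught,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        marker_table.to_csv(out / "markers.csv", index=False)
        trials.to_csv(out / "trials.csv", index=False)
        acc.to_csv(out / "accuracy.csv", index=False)
        removal_log.to_csv(out / "rt_removals.csv", index=False)
        panels.to_csv(out / "amino_acids.csv", index=False)
        p300.to_csv(out / "p300.csv", index=False)
        report.to_json(out / "report.json")
    return report
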