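"""Synthetic EEG, behavior, and ERP generators with known ground truth.

Every downstream stage of the package (marker estimation, mixed-model
cluster statistics, ERP models) is validated closed-loop against data from
this module.  The resting-state generator is built so that the two target
statistics have *known* true values:

* the alpha-band amplitude envelope is a positive transform of fractional
  Gaussian noise (fGn), whose DFA exponent equals its Hurst parameter, and
* the broadband background is synthesized with an exact ``1/f^gamma``
  spectrum.

The generators are deliberately minimal beyond those two statistics plus a
P300-like deflection: no eye-blink/ECG artifact morphology, no volume
conduction (channels are independent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from ._filters import butter_bandpass
from .montage import Montage
from .recording import Recording

__all__ = [
    "CONDITIONS", "SubjectParams", "EffectConfig",
    "synth_fgn", "fgn_autocovariance", "synth_powerlaw_noise",
    "synth_resting_eeg", "synth_task_design", "synth_behavior",
    "synth_amino_acid_panels", "synth_cohort", "synth_erp_epochs",
]

#: Task conditions of the delayed match-to-sample gating paradigm.
CONDITIONS = ("ignore", "update", "control_short", "control_long")

# Calibration defaults: grand means / spreads the generators are centered on.
DEFAULT_DFA_MEAN = 0.768
DEFAULT_DFA_SD = 0.09          # subgroup-scale spread; see docs/methods.md
DEFAULT_GAMMA_MEAN = 1.779
DEFAULT_GAMMA_SD = 0.121
DEFAULT_CONDITION_MEANS = {
    "ignore": 0.895, "update": 0.945, "control_short": 0.955, "control_long": 0.933,
}
DEFAULT_P300_AMP = {"ignore": 1.651, "update": 1.207}  # µV


@dataclass
class SubjectParams:
    """Ground-truth generative parameters for one simulated subject.

    ``target_dfa`` is the Hurst exponent of the alpha-envelope fGn (scalar or
    one value per channel); ``target_gamma`` the exponent of the ``1/f^gamma``
    background.  ``covariates`` holds nuisance scalars (age, sex code, BMI,
    IQ, tiredness, concentration, relative alpha power, ...).
    """

    subject_id: str
    target_dfa: float | np.ndarray = DEFAULT_DFA_MEAN
    target_gamma: float | np.ndarray = DEFAULT_GAMMA_MEAN
    amino_acid_ratio: float = 0.21
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dfa = np.atleast_1d(np.asarray(self.target_dfa, dtype=float))
        if not np.all((dfa > 0.5) & (dfa < 1.0)):
            raise ValueError("target_dfa must lie in (0.5, 1.0)")
        gam = np.atleast_1d(np.asarray(self.target_gamma, dtype=float))
        if not np.all(np.isfinite(gam)) or np.any(gam < 0):
            raise ValueError("target_gamma must be finite and >= 0")
        if not self.amino_acid_ratio > 0:
            raise ValueError("amino_acid_ratio must be positive")

    @property
    def dfa_scalar(self) -> float:
        return float(np.mean(self.target_dfa))

    @property
    def gamma_scalar(self) -> float:
        return float(np.mean(self.target_gamma))


@dataclass
class EffectConfig:
    """Generative twins of the behavioral model coefficients.

    Trial-level success probability is
    ``clip(condition_mean[c] + dfa_slope[c]*z(DFA) + psd_aa_slope[c]*z(PSD)*z(AA)
    + u_subject, eps, 1-eps)`` with ``u_subject ~ N(0, subject_sd)``.
    Defaults plant the qualitative effect pattern used throughout the tests:
    marker effects in the maintenance conditions, none in update.
    """

    condition_means: dict = field(default_factory=lambda: dict(DEFAULT_CONDITION_MEANS))
    dfa_slope: dict = field(default_factory=lambda: {
        "ignore": -0.03, "update": 0.0, "control_short": -0.02, "control_long": -0.03})
    psd_aa_slope: dict = field(default_factory=lambda: {
        "ignore": -0.03, "update": 0.0, "control_short": -0.02, "control_long": -0.02})
    subject_sd: float = 0.04
    trial_noise: bool = True
    rt_log_mean: float = np.log(650.0)   # lognormal location, ms
    rt_log_sd: float = 0.30
    contaminant_rate: float = 0.03       # trials planted outside the 200–2000 ms window
    clip_eps: float = 1e-3
    clip_warn_frac: float = 0.25         # warn when more probabilities need clipping
                                         # (some ceiling censoring is expected near 95%)
    seed: int = 0

    def __post_init__(self) -> None:
        for c, m in self.condition_means.items():
            if not (0 < m < 1):
                raise ValueError(f"condition mean for {c!r} must be in (0,1)")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        for d in (self.dfa_slope, self.psd_aa_slope):
            if not all(np.isfinite(list(d.values()))):
                raise ValueError("effect coefficients must be finite")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# elementary noise generators
# ---------------------------------------------------------------------------

def fgn_autocovariance(hurst: float, lags) -> np.ndarray:
    """Closed-form autocovariance of unit-variance fGn.

    ``rho(k) = 0.5 (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})``
    """
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k ** h2 + np.abs(k - 1) ** h2)


def synth_fgn(hurst: float, n: int, seed=0) -> np.ndarray:
    """Stationary fractional Gaussian noise with exact covariance.

    Uses circulant embedding (Davies–Harte): the target autocovariance is
    embedded in a circulant matrix whose eigenvalues are obtained by FFT and
    used to color complex Gaussian noise.  For fGn the embedding is positive
    in practice; if a (numerically) negative eigenvalue appears, the function
    falls back to spectral synthesis with the fGn spectral density shape
    (``gamma = 2H - 1``) and emits a warning.

    Parameters
    ----------
    hurst
        Hurst exponent in (0, 1); the DFA exponent of the output equals it.
    n
        Number of samples (>= 2).
    seed
        Integer seed or ``numpy.random.Generator``.

    Returns
    -------
    ndarray of length ``n``, zero mean, unit variance (exactly in
    distribution; any single realization fluctuates).
    """
    if not (0 < hurst < 1):
        raise ValueError("hurst must lie in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = _rng(seed)
    r = fgn_autocovariance(hurst, np.arange(n + 1))
    # circulant first row of size 2n: r_0 .. r_n, r_{n-1} .. r_1
    c = np.concatenate([r, r[-2:0:-1]])
    lam = np.fft.fft(c).real
    if lam.min() < -1e-8 * lam.max():
        warnings.warn("circulant embedding non-positive; falling back to "
                      "spectral synthesis", RuntimeWarning)
        x = synth_powerlaw_noise(2 * hurst - 1, n, fs=1.0, seed=rng, f_plateau=0.0)
        return x
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    a = rng.standard_normal(m)
    b = rng.standard_normal(m)
    w = np.empty(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * a[0]
    w[n] = np.sqrt(lam[n] / m) * a[n]
    k = np.arange(1, n)
    w[k] = np.sqrt(lam[k] / (2 * m)) * (a[k] + 1j * b[k])
    w[m - k] = np.conj(w[k])
    return np.fft.fft(w).real[:n]


def synth_powerlaw_noise(gamma: float, n: int, fs: float = 1.0, seed=0,
                         f_plateau: float = 0.5) -> np.ndarray:
    """Gaussian noise with expected PSD proportional to ``f**(-gamma)``.

    Synthesized in the frequency domain: white complex Gaussian spectrum
    scaled by ``f**(-gamma/2)``.  Below ``f_plateau`` (Hz) the amplitude
    response is held constant to keep the variance finite and the series
    stationary; the DC bin is zeroed.  Output is zero-mean, unit-variance.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if n < 16:
        raise ValueError("n must be >= 16")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = _rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.ones_like(freqs)
    nz = freqs > 0
    f_eff = np.maximum(freqs[nz], f_plateau) if f_plateau > 0 else freqs[nz]
    amp[nz] = f_eff ** (-gamma / 2.0)
    amp[0] = 0.0
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


# ---------------------------------------------------------------------------
# resting-state EEG
# ---------------------------------------------------------------------------

def _fm_carrier(n: int, fs: float, rng, f0: float = 11.0, f_dev: float = 1.0,
                mod_cut: float = 0.5) -> np.ndarray:
    """Constant-amplitude narrowband carrier with stochastic frequency drift.

    Instantaneous frequency wanders as low-passed Gaussian noise (cut at
    ``mod_cut`` Hz) around ``f0``, clipped to ±2 SD so it stays well inside
    the flat region of the 8–14 Hz alpha passband.  A constant amplitude
    matters: band-passed white noise would carry Rayleigh envelope
    fluctuations (and phase slips) of its own, which would contaminate the
    fGn-controlled envelope and bias envelope-DFA toward 0.5.
    """
    w = rng.standard_normal(n)
    sos = _sig.butter(4, mod_cut, btype="lowpass", fs=fs, output="sos")
    m = _sig.sosfiltfilt(sos, w)
    m /= m.std()
    f_inst = f0 + f_dev * np.clip(m, -2.0, 2.0)
    phase = 2 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * np.pi)
    return np.cos(phase)


def _fgn_envelope(hurst: float, n: int, fs: float, rng,
                  env_rate: float = 8.0) -> np.ndarray:
    """Positive slow modulator: low-rate fGn, interpolated, +3 SD, rectified.

    The fGn is generated at ``env_rate`` Hz and linearly interpolated to
    ``fs`` so its variance is concentrated at the seconds-to-minutes
    timescales DFA actually measures (an envelope bandwidth of a few Hz is
    also what real alpha rhythms show); raw full-rate fGn would put almost
    all its power at fast timescales, where it is indistinguishable from
    the in-band background and the scaling exponent would be diluted.
    """
    n_lo = int(np.ceil(n * env_rate / fs)) + 1
    g = synth_fgn(hurst, n_lo, rng)
    env = np.interp(np.arange(n) / fs, np.arange(n_lo) / env_rate, g)
    return np.clip(env + 3.0, 0.0, None)


def synth_resting_eeg(params: SubjectParams, montage: Montage,
                      duration: float = 600.0, fs: float = 500.0, seed=0,
                      alpha_snr: float = 32.0, background_sd: float = 10.0,
                      alpha_band: tuple = (8.0, 14.0),
                      env_rate: float = 8.0) -> Recording:
    """Multichannel resting EEG with controllable envelope DFA and PSD slope.

    Per channel: ``x = a * env(t) * carrier(t) + background(t)`` where

    * ``env`` is a positive transform (+3 SD shift, rectification) of fGn
      with Hurst ``target_dfa``, generated at ``env_rate`` Hz,
    * ``carrier`` is constant-amplitude narrowband alpha noise
      (stochastically frequency-modulated around 11 Hz),
    * ``background`` is exact ``1/f^target_gamma`` noise scaled to
      ``background_sd`` µV,
    * ``a`` is set so the alpha-band power of the oscillatory component is
      ``alpha_snr`` times the background power inside the alpha band
      (the default 32, ~15 dB, emulates pronounced eyes-closed alpha).

    The contract is closed-loop: the markers module applied to the output
    recovers ``target_dfa`` (alpha-envelope DFA) and ``target_gamma``
    (3–40 Hz aperiodic fit) within the tolerances exercised by the tests.
    Channels are statistically independent (no volume conduction).

    Raises
    ------
    ValueError
        If ``duration`` is shorter than twice the largest DFA window (50 s).
    """
    min_dur = 50.0
    if duration < min_dur:
        raise ValueError(f"duration {duration} s too short for 25-s DFA windows; "
                         f"minimum is {min_dur} s (>= 120 s recommended)")
    n = int(round(duration * fs))
    n_ch = montage.n_channels
    dfa = np.broadcast_to(np.atleast_1d(params.target_dfa), (n_ch,))
    gamma = np.broadcast_to(np.atleast_1d(params.target_gamma), (n_ch,))
    streams = np.random.SeedSequence(
        seed.integers(2**31) if isinstance(seed, np.random.Generator) else seed
    ).spawn(n_ch)
    data = np.empty((n_ch, n))
    for ci in range(n_ch):
        rng = np.random.default_rng(streams[ci])
        env = _fgn_envelope(float(dfa[ci]), n, fs, rng, env_rate)
        carrier = _fm_carrier(n, fs, rng)
        alpha_sig = env * carrier
        background = background_sd * synth_powerlaw_noise(float(gamma[ci]), n, fs, rng)
        bg_alpha_var = butter_bandpass(background, alpha_band[0], alpha_band[1], fs).var()
        a = np.sqrt(alpha_snr * bg_alpha_var / alpha_sig.var())
        data[ci] = a * alpha_sig + background
    return Recording(data, fs, list(montage.channel_names))


# ---------------------------------------------------------------------------
# task design and behavior
# ---------------------------------------------------------------------------

def synth_task_design(n_blocks: int = 4, trials_per_block: int = 32, seed=0,
                      subject: str = "s01") -> pd.DataFrame:
    """Trial skeleton of the 4-condition delayed match-to-sample task.

    Each block holds ``trials_per_block/4`` trials per condition, shuffled
    within block; probe identity (match/non-match) is balanced within each
    condition of each block.  Defaults give the 4 x 32 = 128-trial session.
    """
    if trials_per_block % 4 != 0:
        raise ValueError("trials_per_block must be divisible by 4")
    rng = _rng(seed)
    per_cond = trials_per_block // 4
    rows = []
    for block in range(1, n_blocks + 1):
        cells = []
        for cond in CONDITIONS:
            probes = np.zeros(per_cond, dtype=int)
            probes[: per_cond // 2] = 1
            if per_cond % 2:  # balance odd cells across blocks
                probes[-1] = (block + CONDITIONS.index(cond)) % 2
            for p in probes:
                cells.append((cond, int(p)))
        order = rng.permutation(len(cells))
        for trial, idx in enumerate(order, start=1):
            cond, probe = cells[idx]
            rows.append(dict(subject=subject, block=block, trial=trial,
                             condition=cond, probe_match=probe))
    return pd.DataFrame(rows)


def _zscore_or_zero(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0 or len(x) < 2:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def synth_behavior(cohort: list[SubjectParams], effects: EffectConfig | None = None,
                   n_blocks: int = 4, trials_per_block: int = 32,
                   seed=None) -> pd.DataFrame:
    """Trial table with planted condition x marker (x amino-acid) effects.

    Success probabilities follow the generative twin of the accuracy mixed
    models; reaction times are lognormal with a configurable fraction of
    contaminant trials (<200 ms or >2000 ms) so the RT filters have work to
    do.  With ``effects.trial_noise=False`` the ``correct`` column holds the
    exact success probability instead of a Bernoulli draw.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    effects = effects or EffectConfig()
    rng = _rng(effects.seed if seed is None else seed)
    z_dfa = _zscore_or_zero([p.dfa_scalar for p in cohort])
    z_psd = _zscore_or_zero([p.gamma_scalar for p in cohort])
    z_aa = _zscore_or_zero([p.amino_acid_ratio for p in cohort])
    u = rng.normal(0.0, effects.subject_sd, size=len(cohort))
    frames = []
    n_clipped = 0
    for i, p in enumerate(cohort):
        design = synth_task_design(n_blocks, trials_per_block, rng, subject=p.subject_id)
        prob = np.empty(len(design))
        for cond in CONDITIONS:
            mask = (design["condition"] == cond).to_numpy()
            prob[mask] = (effects.condition_means[cond]
                          + effects.dfa_slope.get(cond, 0.0) * z_dfa[i]
                          + effects.psd_aa_slope.get(cond, 0.0) * z_psd[i] * z_aa[i]
                          + u[i])
        n_clipped += int(np.sum((prob < effects.clip_eps) | (prob > 1 - effects.clip_eps)))
        prob = np.clip(prob, effects.clip_eps, 1 - effects.clip_eps)
        if effects.trial_noise:
            design["correct"] = (rng.random(len(design)) < prob).astype(int)
        else:
            design["correct"] = prob
        rt = rng.lognormal(effects.rt_log_mean, effects.rt_log_sd, size=len(design))
        contam = rng.random(len(design)) < effects.contaminant_rate
        fast = contam & (rng.random(len(design)) < 0.5)
        slow = contam & ~fast
        rt[fast] = rng.uniform(50.0, 199.0, size=int(fast.sum()))
        rt[slow] = rng.uniform(2001.0, 3500.0, size=int(slow.sum()))
        design["rt_ms"] = rt
        frames.append(design)
    out = pd.concat(frames, ignore_index=True)
    if n_clipped > effects.clip_warn_frac * len(out):
        warnings.warn(f"{n_clipped} trial probabilities clipped to "
                      f"[{effects.clip_eps}, {1 - effects.clip_eps}]", RuntimeWarning)
    return out[["subject", "block", "trial", "condition", "rt_ms", "correct", "probe_match"]]


def synth_amino_acid_panels(subject_ids: list[str], seed=0) -> pd.DataFrame:
    """Fasting serum amino-acid concentrations (µmol/L), one row per subject.

    Lognormal draws around typical adult fasting means; the derived
    (Phe+Tyr)/(Ile+Lys+Met+Trp+Tau+Val) ratio lands near 0.2.
    """
    rng = _rng(seed)
    means = dict(phenylalanine=60.0, tyrosine=65.0, isoleucine=65.0, lysine=180.0,
                 methionine=25.0, tryptophan=55.0, taurine=75.0, valine=230.0)
    cv = 0.15
    cols = {"subject": list(subject_ids)}
    for aa, m in means.items():
        sigma = np.sqrt(np.log(1 + cv**2))
        cols[aa] = rng.lognormal(np.log(m) - sigma**2 / 2, sigma, size=len(subject_ids))
    return pd.DataFrame(cols)


def synth_cohort(n_subjects: int, seed=0,
                 dfa_mean: float = DEFAULT_DFA_MEAN, dfa_sd: float = DEFAULT_DFA_SD,
                 gamma_mean: float = DEFAULT_GAMMA_MEAN, gamma_sd: float = DEFAULT_GAMMA_SD,
                 ) -> tuple[list[SubjectParams], pd.DataFrame]:
    """Draw a cohort of subject parameters plus their amino-acid panels.

    Hurst targets are truncated into (0.52, 0.98) and background exponents
    into (0.3, 3.0).  The default between-subject DFA spread (0.09) follows
    the subgroup-scale variability rather than the much tighter grand-mean
    spread; pass ``dfa_sd=0.014`` for a tightly calibrated cohort.

    Returns ``(list of SubjectParams, amino-acid panel DataFrame)``.
    """
    rng = _rng(seed)
    ids = [f"s{i:03d}" for i in range(1, n_subjects + 1)]
    panels = synth_amino_acid_panels(ids, rng)
    from .behavior import amino_acid_ratio  # local import avoids cycle at import time
    ratios = amino_acid_ratio(panels)
    dfa = np.clip(rng.normal(dfa_mean, dfa_sd, n_subjects), 0.52, 0.98)
    gam = np.clip(rng.normal(gamma_mean, gamma_sd, n_subjects), 0.3, 3.0)
    cohort = []
    for i, sid in enumerate(ids):
        cov = dict(age=float(rng.uniform(20, 36)), sex=int(rng.integers(2)),
                   bmi=float(rng.normal(23.2, 2.7)), iq=float(rng.normal(108, 9.5)),
                   tiredness=float(rng.integers(1, 11)),
                   concentration=float(rng.integers(1, 11)))
        cohort.append(SubjectParams(sid, float(dfa[i]), float(gam[i]),
                                    float(ratios.iloc[i]), cov))
    return cohort, panels


# ---------------------------------------------------------------------------
# ERP epochs
# ---------------------------------------------------------------------------

def synth_erp_epochs(cohort: list[SubjectParams], trial_table: pd.DataFrame,
                     montage: Montage, fs: float = 500.0, seed=0,
                     amp_means: dict | None = None, amp_sd: float = 3.25,
                     latency: float = 0.320, width: float = 0.060,
                     noise_sd: float = 3.0, artifact_frac: float = 0.0,
                     dfa_p300_slope: float = 0.0, psd_aa_p300_slope: float = 0.0):
    """Raw (not yet baseline-corrected) task epochs with a P300-like bump.

    Each epoch spans -0.5 .. +1.8 s around stimulus onset and is pink-noise
    background plus a Gaussian-in-time positive deflection centered at
    ``latency`` s, scalp-weighted to peak at Pz.  Per-trial amplitude is
    Gaussian around the condition mean (defaults 1.651 µV ignore / 1.207 µV
    update) and can optionally be coupled to the subject's markers through
    ``dfa_p300_slope`` / ``psd_aa_p300_slope`` (ignore-condition only, to
    plant a condition-dependent effect).

    ``artifact_frac`` of the epochs receive an injected high-amplitude
    artifact constructed to trip the rejection rule (>30% of samples above
    15 µV on three channels).

    Parameters are ground truth for the ERP stage; apply
    :func:`eegate.erp.baseline_correct` before amplitude measurements.
    """
    from .erp import EpochSet, TMIN, TMAX  # avoid circular import at module load

    if "Pz" not in montage.channel_names:
        raise ValueError("montage must contain Pz")
    bad = set(trial_table["condition"]) - {"ignore", "update"}
    if bad:
        raise ValueError(f"trial_table must be restricted to ignore/update; found {bad}")
    amp_means = amp_means or dict(DEFAULT_P300_AMP)
    rng = _rng(seed)
    params = {p.subject_id: p for p in cohort}
    z_dfa = dict(zip(params, _zscore_or_zero([p.dfa_scalar for p in cohort])))
    z_psd_aa = dict(zip(params, _zscore_or_zero([p.gamma_scalar for p in cohort])
                    * _zscore_or_zero([p.amino_acid_ratio for p in cohort])))
    times = np.arange(round(TMIN * fs), round(TMAX * fs) + 1) / fs
    n_t = len(times)
    bump = np.exp(-0.5 * ((times - latency) / width) ** 2)
    # normalize so the 310-500 ms window *mean* at Pz equals the drawn
    # amplitude (the calibration targets are window means, not peak heights)
    p300_win = (times >= 0.310) & (times <= 0.500)
    bump /= bump[p300_win].mean()
    pz = montage.position_of("Pz")
    d2 = np.sum((montage.positions - pz) ** 2, axis=1)
    scalp_w = np.exp(-d2 / (2 * 0.6**2))
    n_trials = len(trial_table)
    n_ch = montage.n_channels
    data = np.empty((n_trials, n_ch, n_t))
    post = times > 0.55  # artifact block sits clear of baseline and P300 windows
    for ti, row in enumerate(trial_table.itertuples(index=False)):
        for ci in range(n_ch):
            data[ti, ci] = noise_sd * synth_powerlaw_noise(1.0, n_t, fs, rng)
        amp = rng.normal(amp_means[row.condition], amp_sd)
        if row.condition == "ignore" and row.subject in z_dfa:
            amp += (dfa_p300_slope * z_dfa[row.subject]
                    + psd_aa_p300_slope * z_psd_aa[row.subject])
        data[ti] += amp * np.outer(scalp_w, bump)
        if rng.random() < artifact_frac:
            chans = rng.choice(n_ch, size=min(3, n_ch), replace=False)
            block = slice(np.argmax(post), np.argmax(post) + int(0.40 * n_t))
            for ci in chans:
                data[ti, ci, block] += 40.0 * (1 if rng.random() < 0.5 else -1)
    info = trial_table.reset_index(drop=True).copy()
    return EpochSet(data=data, fs=fs, channel_names=list(montage.channel_names),
                    info=info)
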