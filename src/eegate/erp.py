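"""Task-EEG stage: epoching, rejection, P300 quantification, and trial models.

Epochs span -500 .. +1800 ms around the interference-phase stimulus
(ignore / update conditions), baseline-corrected to -500 .. -50 ms.  The
P300 is quantified as the mean amplitude 310-500 ms at Pz per trial; its
link to gating performance is tested with a random-intercept logistic
regression of trial accuracy on P300 x condition, and the resting-state
markers' influence on P300 with trial-level linear mixed models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .behavior import zscore
from .recording import Recording

__all__ = [
    "EpochSet", "TMIN", "TMAX", "BASELINE_WINDOW", "P300_WINDOW",
    "epoch_and_baseline", "baseline_correct", "reject_epochs",
    "exclude_noisy_subjects", "p300_amplitude", "grand_average", "peak_latency",
    "trial_logistic_model", "p300_predictor_model", "p300_predictor_models",
]

TMIN = -0.5
TMAX = 1.8
BASELINE_WINDOW = (-0.5, -0.05)
P300_WINDOW = (0.310, 0.500)


@dataclass
class EpochSet:
    """Task epochs: ``(n_trials, n_channels, n_times)`` in µV.

    ``info`` carries one row of trial metadata per epoch (subject,
    condition, correct, ...).  ``rejected``/``reject_reason`` are populated
    by :func:`reject_epochs` or when events are dropped during epoching.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    info: pd.DataFrame
    tmin: float = TMIN
    rejected: np.ndarray = None
    reject_reason: list = field(default_factory=list)
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (trials, channels, times)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names mismatch")
        if len(self.info) != self.data.shape[0]:
            raise ValueError("info rows must match number of epochs")
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[0], dtype=bool)
        if not self.reject_reason:
            self.reject_reason = [""] * self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.fs

    def channel_index(self, name: str) -> int:
        if name not in self.channel_names:
            raise ValueError(f"channel {name!r} not present")
        return self.channel_names.index(name)


def baseline_correct(epochs: EpochSet, window: tuple = BASELINE_WINDOW) -> EpochSet:
    """Subtract each channel's mean over the baseline window. Idempotent."""
    t = epochs.times
    sel = (t >= window[0]) & (t <= window[1])
    if not sel.any():
        raise ValueError("baseline window outside epoch")
    base = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base, baseline_corrected=True,
                   rejected=epochs.rejected.copy(),
                   reject_reason=list(epochs.reject_reason))


def epoch_and_baseline(recording: Recording, events: pd.DataFrame,
                       tmin: float = TMIN, tmax: float = TMAX,
                       baseline: tuple = BASELINE_WINDOW) -> EpochSet:
    """Slice a continuous recording into baseline-corrected epochs.

    ``events`` needs an ``onset_s`` column (stimulus time in seconds);
    remaining columns become the epoch metadata.  Events too close to the
    recording edges for a full ``tmin..tmax`` window are dropped with a
    reason recorded in the returned metadata (column ``dropped_reason`` of
    the attribute ``dropped``).
    """
    fs = recording.fs
    n_pre = int(round(-tmin * fs))
    n_post = int(round(tmax * fs))
    slices, kept_rows, dropped = [], [], []
    for _, row in events.iterrows():
        onset = int(round((row["onset_s"] - recording.t0) * fs))
        if onset - n_pre < 0 or onset + n_post + 1 > recording.n_samples:
            dropped.append(dict(row, dropped_reason="event too close to recording edge"))
            continue
        slices.append(recording.data[:, onset - n_pre: onset + n_post + 1])
        kept_rows.append(row)
    if not slices:
        raise ValueError("no event leaves room for a full epoch window")
    info = pd.DataFrame(kept_rows).reset_index(drop=True)
    out = EpochSet(np.stack(slices), fs, list(recording.channel_names), info, tmin=tmin)
    out = baseline_correct(out, baseline)
    out.dropped = pd.DataFrame(dropped)
    return out


def reject_epochs(epochs: EpochSet, amp_thresh_uv: float = 15.0,
                  sample_frac: float = 0.30, min_channels: int = 3) -> EpochSet:
    """Amplitude-based epoch rejection (flags only, no manual confirmation).

    An epoch is flagged iff at least ``min_channels`` channels each have
    strictly more than ``sample_frac`` of their samples exceeding
    ``amp_thresh_uv`` in absolute (baseline-corrected) amplitude.  The
    defaults implement the ">30% of samples above 15 µV in more than two
    channels" rule with strict inequalities.
    """
    if not epochs.baseline_corrected:
        warnings.warn("rejection rule expects baseline-corrected epochs", RuntimeWarning)
    frac = np.mean(np.abs(epochs.data) > amp_thresh_uv, axis=2)  # (trials, channels)
    n_bad_ch = np.sum(frac > sample_frac, axis=1)
    flag = n_bad_ch >= min_channels
    rejected = epochs.rejected | flag
    reasons = [r if not f else (r or f"amplitude: {nb} channels >30% samples >15 µV")
               for r, f, nb in zip(epochs.reject_reason, flag, n_bad_ch)]
    return replace(epochs, data=epochs.data, rejected=rejected, reject_reason=reasons)


def exclude_noisy_subjects(epochs: EpochSet, max_frac: float = 0.6) -> pd.DataFrame:
    """Per-subject rejection summary with a keep/drop decision.

    A subject is dropped iff their rejected-epoch fraction strictly exceeds
    ``max_frac`` (exactly 60% is kept).
    """
    df = pd.DataFrame({"subject": epochs.info["subject"].to_numpy(),
                       "rejected": epochs.rejected})
    out = (df.groupby("subject", observed=True)["rejected"]
           .agg(n_epochs="size", n_rejected="sum").reset_index())
    out["frac_rejected"] = out["n_rejected"] / out["n_epochs"]
    out["keep"] = out["frac_rejected"] <= max_frac
    return out


def p300_amplitude(epochs: EpochSet, channel: str = "Pz",
                   window: tuple = P300_WINDOW) -> pd.DataFrame:
    """Per-trial mean amplitude in the P300 window at one channel.

    Rejected epochs are excluded.  The returned table carries the trial
    metadata plus ``amplitude`` (µV) and ``amplitude_group`` ("high" for
    > 0 µV, "low" otherwise — the sign split used to probe latency shifts).
    """
    ci = epochs.channel_index(channel)
    t = epochs.times
    sel = (t >= window[0]) & (t <= window[1])
    if not sel.any():
        raise ValueError("P300 window outside epoch")
    amp = epochs.data[:, ci][:, sel].mean(axis=1)
    keep = ~epochs.rejected
    out = epochs.info.loc[keep].reset_index(drop=True).copy()
    out["amplitude"] = amp[keep]
    out["amplitude_group"] = np.where(amp[keep] > 0.0, "high", "low")
    return out


def grand_average(epochs: EpochSet, channel: str | None = None) -> np.ndarray:
    """Mean over non-rejected epochs; one channel if given, else all."""
    keep = ~epochs.rejected
    if not keep.any():
        raise ValueError("all epochs rejected")
    avg = epochs.data[keep].mean(axis=0)
    return avg[epochs.channel_index(channel)] if channel else avg


def peak_latency(times: np.ndarray, waveform: np.ndarray,
                 search: tuple = (0.2, 0.6)) -> float:
    """Positive-peak latency (s) with three-point parabolic refinement.

    The discrete argmax inside the search window (ties resolve to the
    earlier latency) is refined by fitting a parabola through the peak and
    its two neighbors.  A flat waveform raises.
    """
    times = np.asarray(times, dtype=float)
    w = np.asarray(waveform, dtype=float)
    sel = np.flatnonzero((times >= search[0]) & (times <= search[1]))
    if len(sel) < 3:
        raise ValueError("search window too narrow for the sampling rate")
    seg = w[sel]
    if np.ptp(seg) == 0:
        raise ValueError("flat waveform: no peak")
    k = int(np.argmax(seg))       # first maximum -> earlier tie wins
    i = sel[k]
    if 0 < i < len(w) - 1:
        y0, y1, y2 = w[i - 1], w[i], w[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            dt = times[1] - times[0]
            return float(times[i] + np.clip(delta, -0.5, 0.5) * dt)
    return float(times[i])


# ---------------------------------------------------------------------------
# trial-level models
# ---------------------------------------------------------------------------

def _gh_logistic_nll(theta, X, y, groups, nodes, wts):
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    eta = X @ beta
    nll = 0.0
    for g in groups:
        e = eta[g]
        yy = y[g]
        # (n_g, K) linear predictors across quadrature nodes
        lin = e[:, None] + np.sqrt(2.0) * sigma * nodes[None, :]
        loglik = yy[:, None] * lin - np.logaddexp(0.0, lin)
        contrib = loglik.sum(axis=0)
        mx = contrib.max()
        nll -= mx + np.log(np.dot(wts, np.exp(contrib - mx)) / np.sqrt(np.pi))
    return nll + 1e-8 * float(beta @ beta)


def _numeric_hessian(fun, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (fun(x + ei + ej) - fun(x + ei - ej)
                                 - fun(x - ei + ej) + fun(x - ei - ej)) / (4 * eps * eps)
    return H


def trial_logistic_model(p300: pd.DataFrame, n_quad: int = 15) -> dict:
    """Random-intercept logistic regression of accuracy on P300 x condition.

    ``logit P(correct) = b0 + b1 z(P300) + b2 [ignore] + b3 z(P300)x[ignore]
    + u_subject``, ``u ~ N(0, sigma^2)``, fitted by Gauss-Hermite quadrature
    maximum likelihood (``n_quad`` nodes; Laplace is the 1-node special
    case).  Reports each coefficient with Wald SE/z/p from the numerical
    Hessian, the random-intercept SD, and a separation flag (|beta| > 15 on
    the standardized scale; a tiny ridge keeps such fits finite).
    """
    need = {"subject", "condition", "amplitude", "correct"}
    if not need <= set(p300.columns):
        raise ValueError(f"p300 table must have columns {sorted(need)}")
    conds = set(p300["condition"])
    if not {"ignore", "update"} <= conds:
        raise ValueError("both ignore and update trials are required")
    z_amp = zscore(p300["amplitude"].to_numpy(dtype=float))
    ig = (p300["condition"] == "ignore").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(p300)), z_amp, ig, z_amp * ig])
    names = ["intercept", "p300", "ignore", "p300:ignore"]
    y = p300["correct"].to_numpy(dtype=float)
    subj = p300["subject"].to_numpy()
    groups = [np.flatnonzero(subj == s) for s in pd.unique(subj)]
    nodes, wts = np.polynomial.hermite.hermgauss(n_quad)
    x0 = np.concatenate([np.zeros(X.shape[1]), [np.log(0.5)]])
    res = optimize.minimize(_gh_logistic_nll, x0, args=(X, y, groups, nodes, wts),
                            method="BFGS", options=dict(maxiter=500, gtol=1e-6))
    theta = res.x
    # BFGS with finite-difference gradients often stops with a "precision
    # loss" flag at an excellent solution; judge convergence by the gradient
    grad_ok = res.jac is not None and np.max(np.abs(res.jac)) < 1e-3 * (1 + abs(res.fun))
    H = _numeric_hessian(lambda th: _gh_logistic_nll(th, X, y, groups, nodes, wts), theta)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:-1], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    beta = theta[:-1]
    z = beta / se
    table = pd.DataFrame({"beta": beta, "se": se, "z": z,
                          "p": 2 * sps.norm.sf(np.abs(z))}, index=names)
    return dict(coefficients=table, sigma_subject=float(np.exp(theta[-1])),
                converged=bool(res.success or grad_ok),
                separation=bool(np.max(np.abs(beta)) > 15), loglik=-float(res.fun))


def p300_predictor_model(p300: pd.DataFrame, marker, aa=None) -> dict:
    """Trial-level linear mixed model of P300 on a resting marker.

    ``P300 ~ z(marker) * condition + (1|subject)`` or, with ``aa``,
    ``P300 ~ z(marker) * z(aa) * condition + (1|subject)``; reports the
    marker x condition (resp. marker x aa x condition) interaction term for
    the ignore-update contrast.
    """
    import statsmodels.formula.api as smf

    df = p300.copy()
    subjects = np.array(sorted(df["subject"].unique()))
    zm = zscore(np.asarray(pd.Series(marker).reindex(subjects), dtype=float))
    df["marker"] = df["subject"].map(dict(zip(subjects, zm)))
    terms = "C(condition, Treatment('update')) * marker"
    if aa is not None:
        za = zscore(np.asarray(pd.Series(aa).reindex(subjects), dtype=float))
        df["aa"] = df["subject"].map(dict(zip(subjects, za)))
        terms += " * aa"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm("amplitude ~ " + terms, df, groups="subject").fit(reml=True)
    target = ("C(condition, Treatment('update'))[T.ignore]:marker"
              + (":aa" if aa is not None else ""))
    beta, se = float(fit.params[target]), float(fit.bse[target])
    res_df = len(df) - len(fit.fe_params)
    t = beta / se
    return dict(beta=beta, se=se, t=t, p=2 * sps.t.sf(abs(t), res_df),
                converged=bool(getattr(fit, "converged", True)), fit=fit)


def p300_predictor_models(p300: pd.DataFrame, dfa_cluster, psd_cluster, aa) -> dict:
    """Both marker->P300 models: DFA x condition and PSD x AA x condition."""
    return {"m6a": p300_predictor_model(p300, dfa_cluster),
            "m6b": p300_predictor_model(p300, psd_cluster, aa=aa)}
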