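"""Trial filtering, accuracy aggregation, and the blood amino-acid ratio.

The behavioral unit of analysis is subject x condition mean accuracy on the
4-condition working-memory gating task, computed after reaction-time
filtering.  The amino-acid ratio — (phenylalanine + tyrosine) over the sum
of six competing large neutral amino acids — proxies peripheral dopamine-
precursor availability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import CONDITIONS

__all__ = ["filter_trials", "accuracy_by_condition", "amino_acid_ratio", "zscore"]

RT_MIN_MS = 200.0
RT_MAX_MS = 2000.0

AA_NUMERATOR = ("phenylalanine", "tyrosine")
AA_DENOMINATOR = ("isoleucine", "lysine", "methionine", "tryptophan", "taurine", "valine")


def filter_trials(trials: pd.DataFrame, rt_min: float = RT_MIN_MS,
                  rt_max: float = RT_MAX_MS, return_log: bool = False):
    """Drop implausible-RT trials (false alarms and misses).

    Trials with ``rt_ms < rt_min`` (anticipations / false alarms) or
    ``rt_ms > rt_max`` (misses) are removed; boundary values are retained
    (strict inequalities).  Idempotent.  With ``return_log=True`` also
    returns removal counts per subject x condition.
    """
    keep = (trials["rt_ms"] >= rt_min) & (trials["rt_ms"] <= rt_max)
    out = trials.loc[keep].copy()
    if not return_log:
        return out
    removed = trials.loc[~keep]
    log = (removed.groupby(["subject", "condition"], observed=True)
           .size().rename("n_removed").reset_index())
    return out, log


def accuracy_by_condition(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per subject x condition (apply :func:`filter_trials` first).

    Every subject x condition cell appears in the output; cells with no
    surviving trials get ``n_trials = 0`` and missing accuracy, which the
    statistics stage drops listwise.
    """
    g = trials.groupby(["subject", "condition"], observed=True)["correct"]
    agg = g.agg(accuracy="mean", n_trials="size").reset_index()
    subjects = trials["subject"].unique()
    full = pd.MultiIndex.from_product([subjects, list(CONDITIONS)],
                                      names=["subject", "condition"]).to_frame(index=False)
    out = full.merge(agg, on=["subject", "condition"], how="left")
    out["n_trials"] = out["n_trials"].fillna(0).astype(int)
    return out


def amino_acid_ratio(panel):
    """(Phe + Tyr) / (Ile + Lys + Met + Trp + Tau + Val).

    ``panel`` may be a mapping of concentrations (one subject) or a
    DataFrame with one row per subject; concentrations must share a unit
    (the ratio is scale-invariant).  A zero denominator raises.
    """
    if isinstance(panel, pd.DataFrame):
        num = sum(panel[a] for a in AA_NUMERATOR)
        den = sum(panel[a] for a in AA_DENOMINATOR)
        if np.any(den <= 0):
            raise ValueError("amino-acid denominator sum must be positive")
        return num / den
    num = sum(float(panel[a]) for a in AA_NUMERATOR)
    den = sum(float(panel[a]) for a in AA_DENOMINATOR)
    if den <= 0:
        raise ValueError("amino-acid denominator sum must be positive")
    return num / den


def zscore(x) -> np.ndarray:
    """Z-transform using the analysis sample's own mean and SD (ddof=0).

    Continuous covariates and markers are standardized before model fitting;
    a constant input raises rather than silently returning zeros.
    """
    x = np.asarray(x, dtype=float)
    sd = np.nanstd(x, ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-score a constant or all-missing variable")
    return (x - np.nanmean(x)) / sd
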