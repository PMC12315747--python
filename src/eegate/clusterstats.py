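"""Per-electrode mixed models with cluster-based permutation inference.

The question asked at every electrode is whether a resting-state marker
(DFA exponent or aperiodic slope, optionally interacting with the amino-acid
ratio) modulates task accuracy *differently across conditions*; the contrast
of interest is the marker x condition interaction for ignore vs update.
Multiple comparisons across electrodes are controlled by a max-cluster-mass
permutation test: electrodes significant at ``p < .05`` are grouped into
spatially adjacent same-sign clusters scored by their cumulative t, and each
observed cluster mass is referred to the permutation distribution of the
largest cluster mass obtained after shuffling the subject-level marker
across subjects.

Model estimation
----------------
Accuracy is modeled with a subject random intercept (REML, statsmodels
MixedLM).  For complete balanced designs the interaction contrast is a pure
within-subject quantity, and the package reports its t in the exact
within-subject error stratum: the REML point estimate divided by the
contrast-specific standard error from the subject-level condition-difference
regression (df = n_subjects - p).  This makes the classical identity between
the mixed-model contrast and the condition-difference OLS hold exactly, and
licenses the fast OLS path used inside permutations.  For unbalanced data a
Wald t with a residual-df approximation is reported instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .behavior import zscore
from .montage import Montage

__all__ = [
    "ModelFit", "Cluster", "PermutationResult",
    "fit_electrode_model", "contrast_ols", "form_clusters", "permutation_test",
    "posthoc_condition_slopes", "interaction_model", "median_split_analysis", "vif",
]

CONTRAST_CONDITIONS = ("ignore", "update")  # contrast of interest: ignore - update


@dataclass
class ModelFit:
    """Result of one electrode's accuracy model."""

    electrode: str
    formula_id: str                       # m1/m2 (two-way), m1a/m2a (three-way), ...
    coefficients: pd.DataFrame            # index: term; columns: beta, se
    contrast_t: float
    contrast_p: float
    contrast_beta: float
    df: float
    converged: bool = True
    n_subjects: int = 0


@dataclass
class Cluster:
    """Spatially connected set of same-sign significant electrodes."""

    members: list
    mass: float                           # cumulative contrast t over members
    sign: int                             # +1 or -1

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster requires at least two electrodes")
        if np.sign(self.mass) != self.sign:
            raise ValueError("mass sign inconsistent with cluster sign")


@dataclass
class PermutationResult:
    """Observed clusters with their permutation null and decisions."""

    clusters: list
    null_max_masses: np.ndarray           # length B, |largest cluster mass| per perm
    cluster_p: np.ndarray                 # add-one permutation p per observed cluster
    significant: np.ndarray               # |mass| > 95th percentile of the null
    threshold: float                      # the null 95th percentile actually used
    seed: int
    n_nonconverged: int = 0
    electrode_fits: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# data alignment helpers
# ---------------------------------------------------------------------------

def _complete_wide(acc: pd.DataFrame, conditions=CONTRAST_CONDITIONS) -> pd.DataFrame:
    """Subject x condition accuracy in wide form, complete cases only."""
    wide = acc.pivot_table(index="subject", columns="condition", values="accuracy")
    missing = [c for c in conditions if c not in wide.columns]
    if missing:
        raise ValueError(f"accuracy table lacks condition(s): {missing}")
    return wide.dropna(subset=list(conditions)).sort_index()


def _align_marker(marker, subjects) -> np.ndarray:
    if isinstance(marker, pd.Series):
        vals = marker.reindex(subjects).to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValueError("marker missing for some subjects")
        return vals
    vals = np.asarray(marker, dtype=float)
    if len(vals) != len(subjects):
        raise ValueError("marker length does not match number of subjects")
    return vals


def _contrast_design(m: np.ndarray, a: np.ndarray | None) -> np.ndarray:
    """Design for the subject-level difference regression; contrast term last."""
    n = len(m)
    if a is None:
        return np.column_stack([np.ones(n), m])
    return np.column_stack([np.ones(n), m, a, m * a])


def _ols_last_term(X: np.ndarray, y: np.ndarray):
    """beta, t, two-sided p and df of the last column of X."""
    n, p = X.shape
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - p
    if df <= 0:
        raise ValueError("not enough subjects for the contrast regression")
    s2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(s2 * xtx_inv[-1, -1])
    t = coef[-1] / se if se > 0 else np.nan
    pval = 2 * sps.t.sf(abs(t), df)
    return float(coef[-1]), float(t), float(pval), float(se), df


# ---------------------------------------------------------------------------
# electrode-level models
# ---------------------------------------------------------------------------

def contrast_ols(acc: pd.DataFrame, marker, aa=None, electrode: str = "",
                 formula_id: str = "m2") -> ModelFit:
    """Fast path: the ignore-update condition-difference regression.

    Regresses each subject's (ignore - update) accuracy difference on the
    z-scored marker (two-way models) or on marker, amino-acid ratio and
    their product (three-way models; the product term is the contrast).
    For complete balanced designs this is exactly the mixed model's
    interaction contrast.
    """
    wide = _complete_wide(acc)
    subjects = wide.index
    m = zscore(_align_marker(marker, subjects))
    a = None if aa is None else zscore(_align_marker(aa, subjects))
    d = (wide["ignore"] - wide["update"]).to_numpy(dtype=float)
    X = _contrast_design(m, a)
    beta, t, p, se, df = _ols_last_term(X, d)
    term = "marker:aa:ignore_vs_update" if aa is not None else "marker:ignore_vs_update"
    coefs = pd.DataFrame({"beta": [beta], "se": [se]}, index=[term])
    return ModelFit(electrode, formula_id, coefs, t, p, beta, df,
                    converged=True, n_subjects=len(subjects))


def fit_electrode_model(acc: pd.DataFrame, marker, formula_id: str = "m2",
                        aa=None, covariates: pd.DataFrame | None = None,
                        ) -> ModelFit:
    """Linear mixed model of accuracy with a subject random intercept (REML).

    ``accuracy ~ condition * marker [* aa] (+ covariates) + (1 | subject)``
    with treatment coding and ``update`` as reference, so the
    marker x condition[ignore] (or marker x aa x condition[ignore]) term is
    directly the ignore-update contrast.

    ``marker`` and ``aa`` are z-scored internally; covariate columns are
    z-scored jointly-included fixed effects.  Non-convergence is flagged on
    the returned fit (such electrodes are skipped during clustering).
    """
    import statsmodels.formula.api as smf

    acc = acc.dropna(subset=["accuracy"])
    counts = acc.groupby("subject", observed=True)["condition"].nunique()
    n_cond = acc["condition"].nunique()
    complete = counts[counts == n_cond].index
    acc = acc[acc["subject"].isin(complete)].copy()
    subjects = np.array(sorted(acc["subject"].unique()))
    if len(subjects) < 4:
        raise ValueError("need at least 4 complete subjects")
    m = zscore(_align_marker(marker, subjects))
    m_map = dict(zip(subjects, m))
    acc["marker"] = acc["subject"].map(m_map)
    terms = "C(condition, Treatment('update')) * marker"
    if aa is not None:
        a = zscore(_align_marker(aa, subjects))
        acc["aa"] = acc["subject"].map(dict(zip(subjects, a)))
        terms += " * aa"
    cov_names = []
    if covariates is not None:
        for c in covariates.columns:
            acc[f"cov_{c}"] = acc["subject"].map(
                dict(zip(subjects, zscore(_align_marker(covariates[c], subjects)))))
            cov_names.append(f"cov_{c}")
    formula = "accuracy ~ " + terms + ("" if not cov_names else " + " + " + ".join(cov_names))
    # a random-intercept variance estimated at the boundary (0) is still a
    # valid converged fit; only optimizer failure flags non-convergence
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm(formula, acc, groups="subject").fit(reml=True)
    converged = bool(getattr(fit, "converged", True))
    if aa is None:
        target = "C(condition, Treatment('update'))[T.ignore]:marker"
    else:
        target = "C(condition, Treatment('update'))[T.ignore]:marker:aa"
    beta = float(fit.params[target])
    fe = fit.fe_params
    coefs = pd.DataFrame({"beta": fe.values,
                          "se": fit.bse.reindex(fe.index).values}, index=fe.index)
    balanced = (covariates is None
                and acc.groupby("subject", observed=True).size().nunique() == 1)
    if balanced:
        # exact within-subject stratum inference for the contrast
        a_vec = None if aa is None else a
        wide = _complete_wide(acc)
        d = (wide["ignore"] - wide["update"]).to_numpy(dtype=float)
        X = _contrast_design(m, a_vec)
        _, _, _, se, df = _ols_last_term(X, d)
        t = beta / se
        p = 2 * sps.t.sf(abs(t), df)
    else:
        se = float(fit.bse[target])
        df = len(acc) - len(fe)
        t = beta / se
        p = 2 * sps.t.sf(abs(t), df)
    return ModelFit("", formula_id, coefs, float(t), float(p), beta, float(df),
                    converged=converged, n_subjects=len(subjects))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _components(nodes: set, neighbors: dict) -> list[list]:
    """Connected components of ``nodes`` under the ``neighbors`` mapping."""
    comps, seen = [], set()
    for start in sorted(nodes):
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            node = stack.pop()
            comp.append(node)
            for nb in neighbors.get(node, ()):
                if nb in nodes and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        comps.append(comp)
    return comps


def _max_abs_cluster_mass(t: np.ndarray, sig: np.ndarray,
                          neighbors_idx: list, min_size: int) -> float:
    """|mass| of the largest same-sign cluster among significant electrodes."""
    best = 0.0
    for sign in (1, -1):
        nodes = {i for i in np.flatnonzero(sig) if np.sign(t[i]) == sign}
        for comp in _components(nodes, {i: neighbors_idx[i] for i in nodes}):
            if len(comp) >= min_size:
                best = max(best, abs(float(sum(t[i] for i in comp))))
    return best


def form_clusters(fits, montage: Montage, p_thresh: float = 0.05,
                  min_size: int = 2) -> list[Cluster]:
    """Connected components of same-sign significant electrodes.

    ``fits`` is a list of :class:`ModelFit` (with ``electrode`` set) or a
    DataFrame with columns ``electrode, contrast_t, contrast_p`` (and
    optionally ``converged``).  Electrodes significant at ``p < p_thresh``
    are clustered separately by the sign of their t; components with at
    least ``min_size`` members are returned with mass = sum of member t,
    sorted by decreasing |mass|.  Non-converged fits never enter a cluster.
    """
    if isinstance(fits, pd.DataFrame):
        table = fits
    else:
        table = pd.DataFrame([dict(electrode=f.electrode, contrast_t=f.contrast_t,
                                   contrast_p=f.contrast_p,
                                   converged=f.converged) for f in fits])
    if "converged" not in table.columns:
        table = table.assign(converged=True)
    sig = table[(table["contrast_p"] < p_thresh) & table["converged"]
                & np.isfinite(table["contrast_t"])]
    t_of = dict(zip(sig["electrode"], sig["contrast_t"]))
    clusters = []
    for sign in (+1, -1):
        nodes = {e for e, t in t_of.items() if np.sign(t) == sign}
        seen = set()
        for start in sorted(nodes):
            if start in seen:
                continue
            comp, stack = [], [start]
            seen.add(start)
            while stack:
                node = stack.pop()
                comp.append(node)
                for nb in montage.neighbors(node):
                    if nb in nodes and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if len(comp) >= min_size:
                mass = float(sum(t_of[e] for e in comp))
                clusters.append(Cluster(sorted(comp), mass, sign))
    return sorted(clusters, key=lambda c: -abs(c.mass))


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def _electrode_ts_fast(d: np.ndarray, M: np.ndarray, a: np.ndarray | None):
    """Contrast t per electrode via the difference regression (vectorized).

    ``d``: (n,) condition differences; ``M``: (n, E) per-electrode marker
    (already z-scored columnwise); ``a``: optional (n,) amino-acid ratio.
    """
    n, n_e = M.shape
    if a is None:
        dc = d - d.mean()
        Mc = M - M.mean(axis=0)
        denom = np.sqrt((Mc ** 2).sum(axis=0) * (dc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Mc.T @ dc) / denom
        r = np.clip(r, -0.999999999, 0.999999999)
        df = n - 2
        t = r * np.sqrt(df / (1 - r ** 2))
        return t
    t = np.empty(n_e)
    for e in range(n_e):
        X = _contrast_design(M[:, e], a)
        _, t[e], _, _, _ = _ols_last_term(X, d)
    return t


def permutation_test(acc: pd.DataFrame, markers: pd.DataFrame, montage: Montage,
                     formula_id: str = "m2", aa=None, B: int = 1000, seed: int = 0,
                     p_thresh: float = 0.05, min_size: int = 2,
                     observed_method: str = "fast") -> PermutationResult:
    """Max-cluster-mass permutation test over all electrodes.

    ``markers`` is a subject x electrode DataFrame (index: subject, columns:
    electrode labels present in ``montage``).  The null hypothesis is the
    absence of a marker x condition interaction, so each permutation shuffles
    the subject-level marker rows across subjects (jointly with ``aa`` for
    three-way models, preserving their empirical dependence) and refits all
    electrode models through the balanced-design fast path; the absolute
    cumulative t of the largest surviving cluster is recorded (0 if none).

    A cluster is significant when its |mass| strictly exceeds the null's
    95th percentile (linear-interpolation percentile); per-cluster p-values
    use the add-one rule ``(1 + #{null >= |obs|}) / (B + 1)``.

    ``observed_method`` selects how the *observed* per-electrode statistics
    are computed: ``"fast"`` (difference-regression, identical to the mixed
    model contrast for balanced data) or ``"reml"`` (full REML fits;
    non-converged electrodes are excluded from clustering and counted).
    """
    if B < 100:
        warnings.warn(f"B={B} permutations give an unstable 95th percentile",
                      RuntimeWarning)
    wide = _complete_wide(acc)
    subjects = wide.index
    electrodes = [e for e in markers.columns if e in montage.channel_names]
    if not electrodes:
        raise ValueError("no marker electrode matches the montage")
    M = np.column_stack([zscore(_align_marker(markers[e], subjects))
                         for e in electrodes])
    a = None if aa is None else zscore(_align_marker(aa, subjects))
    d = (wide["ignore"] - wide["update"]).to_numpy(dtype=float)

    n_nonconv = 0
    fits = []
    if observed_method == "reml":
        for j, e in enumerate(electrodes):
            f = fit_electrode_model(acc, pd.Series(M[:, j], index=subjects),
                                    formula_id, aa=None if a is None
                                    else pd.Series(a, index=subjects))
            f.electrode = e
            fits.append(f)
        n_nonconv = sum(not f.converged for f in fits)
    else:
        for j, e in enumerate(electrodes):
            f = contrast_ols(acc, pd.Series(M[:, j], index=subjects),
                             aa=None if a is None else pd.Series(a, index=subjects),
                             electrode=e, formula_id=formula_id)
            fits.append(f)
    observed = form_clusters(fits, montage, p_thresh, min_size)

    rng = np.random.default_rng(seed)
    n = len(subjects)
    df_t = n - 2 if a is None else n - 4
    t_crit = sps.t.ppf(1 - p_thresh / 2, df_t)
    e_index = {e: i for i, e in enumerate(electrodes)}
    neighbors_idx = [[e_index[nb] for nb in montage.neighbors(e) if nb in e_index]
                     for e in electrodes]
    null_max = np.empty(B)
    for b in range(B):
        perm = rng.permutation(n)
        t_perm = _electrode_ts_fast(d, M[perm], None if a is None else a[perm])
        sig = np.abs(t_perm) > t_crit
        null_max[b] = _max_abs_cluster_mass(t_perm, sig, neighbors_idx, min_size)
    obs_mass = np.array([abs(c.mass) for c in observed])
    cluster_p = np.array([(1 + np.sum(null_max >= m)) / (B + 1) for m in obs_mass])
    threshold = float(np.percentile(null_max, 95)) if B else np.inf
    significant = obs_mass > threshold
    return PermutationResult(observed, null_max, cluster_p, significant, threshold,
                             seed, n_nonconv, fits)


# ---------------------------------------------------------------------------
# post-hoc decompositions
# ---------------------------------------------------------------------------

def posthoc_condition_slopes(acc: pd.DataFrame, cluster_marker, aa=None) -> pd.DataFrame:
    """Per-condition regression of accuracy on the cluster-average marker.

    For each condition separately, accuracy is regressed on the z-scored
    cluster-average marker (two-way follow-up) or on marker, amino-acid
    ratio and their product, reporting the product term (three-way
    follow-up).  Returns a DataFrame with columns
    ``condition, beta, se, t, p, n``.
    """
    acc = acc.dropna(subset=["accuracy"])
    rows = []
    for cond, sub in acc.groupby("condition", observed=True):
        subjects = sub["subject"].to_numpy()
        m = _align_marker(cluster_marker, subjects)
        if np.std(m) == 0:
            raise ValueError("cluster marker has zero variance")
        m = zscore(m)
        a = None if aa is None else zscore(_align_marker(aa, subjects))
        y = sub["accuracy"].to_numpy(dtype=float)
        X = _contrast_design(m, a)
        beta, t, p, se, df = _ols_last_term(X, y)
        rows.append(dict(condition=cond, beta=beta, se=se, t=t, p=p, n=len(y)))
    return pd.DataFrame(rows)


def interaction_model(acc: pd.DataFrame, dfa_avg, psd_avg,
                      conditions=CONTRAST_CONDITIONS) -> dict:
    """Joint LRTC x PSD-slope model of accuracy (conditions ignore/update).

    Fits ``accuracy ~ z(DFA) * z(PSD) * condition + (1 | subject)`` by REML
    and reports the DFA x PSD two-way and DFA x PSD x condition three-way
    terms plus the variance inflation factors of the two predictors.
    """
    import statsmodels.formula.api as smf

    acc = acc[acc["condition"].isin(conditions)].dropna(subset=["accuracy"]).copy()
    subjects = np.array(sorted(acc["subject"].unique()))
    zd = zscore(_align_marker(dfa_avg, subjects))
    zp = zscore(_align_marker(psd_avg, subjects))
    acc["dfa"] = acc["subject"].map(dict(zip(subjects, zd)))
    acc["psd"] = acc["subject"].map(dict(zip(subjects, zp)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm("accuracy ~ dfa * psd * C(condition, Treatment('update'))",
                          acc, groups="subject").fit(reml=True)
    df = len(acc) - len(fit.fe_params)
    out = {}
    for label, term in [("dfa_psd", "dfa:psd"),
                        ("dfa_psd_condition",
                         "dfa:psd:C(condition, Treatment('update'))[T.ignore]")]:
        beta, se = float(fit.params[term]), float(fit.bse[term])
        t = beta / se
        out[label] = dict(beta=beta, se=se, t=t, p=2 * sps.t.sf(abs(t), df))
    out["vif"] = dict(zip(["dfa", "psd"], vif(np.column_stack([zd, zp]))))
    out["fit"] = fit
    return out


def median_split_analysis(acc: pd.DataFrame, dfa_avg, psd_avg) -> dict:
    """Steep- vs flat-PSD-slope subgroup analysis of the DFA-accuracy link.

    Subjects are split at the median PSD slope (with odd n, the median
    subject joins the lower/flatter group; stable sort makes ties
    deterministic).  Within each group, per-subject mean accuracy is
    regressed on the z-scored DFA average; group DFA means are compared with
    a Welch two-sample t-test.
    """
    acc = acc.dropna(subset=["accuracy"])
    subjects = np.array(sorted(acc["subject"].unique()))
    if len(subjects) < 8:
        raise ValueError("need at least 4 subjects per group")
    psd = _align_marker(psd_avg, subjects)
    dfa_ = _align_marker(dfa_avg, subjects)
    order = np.argsort(psd, kind="stable")
    n_low = (len(subjects) + 1) // 2
    low_idx, high_idx = order[:n_low], order[n_low:]
    mean_acc = (acc.groupby("subject", observed=True)["accuracy"].mean()
                .reindex(subjects).to_numpy())
    out = {}
    for name, idx in [("flat", low_idx), ("steep", high_idx)]:
        m = zscore(dfa_[idx])
        beta, t, p, se, _ = _ols_last_term(np.column_stack([np.ones(len(idx)), m]),
                                           mean_acc[idx])
        out[name] = dict(beta=beta, se=se, t=t, p=p, n=len(idx),
                         dfa_mean=float(dfa_[idx].mean()), dfa_sd=float(dfa_[idx].std(ddof=1)))
    welch = sps.ttest_ind(dfa_[low_idx], dfa_[high_idx], equal_var=False)
    out["dfa_group_test"] = dict(t=float(welch.statistic), p=float(welch.pvalue),
                                 df=float(welch.df))
    return out


def vif(predictor_matrix: np.ndarray) -> np.ndarray:
    """Variance inflation factor per predictor: ``1 / (1 - R^2_j)``.

    ``R^2_j`` comes from regressing predictor j on the remaining predictors
    (with intercept).  Perfect collinearity yields ``inf``.
    """
    X = np.asarray(predictor_matrix, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if n <= p:
        raise ValueError("need more observations than predictors")
    out = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out
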