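"""Per-feature differential statistics.

Signed fold changes on the raw intensity-ratio scale, empirical-Bayes
moderated t-statistics on log2 intensities, Benjamini-Hochberg false
discovery rates, the p/fold-change feature-selection rule, and Fisher
combination of per-family contrasts.

The moderated t shrinks each feature's pooled variance toward a prior
estimated across all features by fitting a scaled inverse-chi-square
distribution to the observed variances via moments of the log variances.
With prior degrees of freedom d0 = 0 it reduces exactly to the classical
pooled two-sample t; with homogeneous variances d0 -> infinity and every
feature is tested against the common variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import FeatureTable

__all__ = [
    "ShrinkageEstimate",
    "signed_fold_change",
    "fit_variance_prior",
    "moderated_t",
    "bh_fdr",
    "select_features",
    "combine_family_contrasts",
    "differential_analysis",
    "family_meta_analysis",
]

log = logging.getLogger("tcafinger")


def signed_fold_change(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Signed case/control mean ratio.

    r = mean(case)/mean(control); returns r when r >= 1 and -1/r otherwise,
    so a 36.9-fold decrease reports as -36.9.  Antisymmetric under swapping
    the groups; equal means map to +1.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 1 or control.size < 1:
        raise ValueError("need at least one value per group")
    mc, mn = case.mean(), control.mean()
    if mc <= 0 or mn <= 0:
        raise ValueError(f"group means must be positive (got {mc}, {mn})")
    r = mc / mn
    return r if r >= 1 else -1.0 / r


@dataclass(frozen=True)
class ShrinkageEstimate:
    """Scaled inverse-chi-square variance prior: s0^2 and d0."""

    s2_prior: float
    df_prior: float  # may be math.inf for homogeneous variances

    def __post_init__(self) -> None:
        if self.s2_prior <= 0:
            raise ValueError("prior variance must be positive")
        if self.df_prior < 0:
            raise ValueError("prior degrees of freedom must be >= 0")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def fit_variance_prior(variances: Sequence[float], df: float) -> ShrinkageEstimate:
    """Fit the variance prior by moments of the log variances.

    Under the model s^2 ~ s0^2 * F(df, d0), log s^2 has known mean/variance
    offsets (digamma/trigamma terms); matching the observed mean and excess
    variance of log s^2 yields (s0^2, d0).  When the observed spread of the
    log variances is at or below its pure-sampling expectation, d0 is
    infinite and s0^2 is the plain mean of the variances.
    """
    s2 = np.asarray(variances, dtype=float)
    if s2.size < 2:
        raise ValueError("need at least two features to fit the prior")
    if df < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    if np.all(s2 <= 0):
        raise ValueError("all variances are zero")
    if np.any(s2 <= 0):
        warnings.warn(
            "fit_variance_prior: dropping non-positive variances", stacklevel=2
        )
        s2 = s2[s2 > 0]
        if s2.size < 2:
            raise ValueError("fewer than two positive variances")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s20 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return ShrinkageEstimate(s2_prior=s20, df_prior=d0)
    return ShrinkageEstimate(s2_prior=float(s2.mean()), df_prior=np.inf)


def moderated_t(
    case_values: Sequence[float],
    control_values: Sequence[float],
    prior: ShrinkageEstimate,
) -> Tuple[float, float, float]:
    """Moderated two-sample t on the supplied values.

    The pooled variance s^2 is shrunk to
    (d0*s0^2 + d*s^2) / (d0 + d) and the statistic referred to a t
    distribution on d0 + d degrees of freedom.  With d0 = 0 this is the
    classical pooled t.  Returns (t, total df, two-sided p).
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    n1, n2 = case.size, control.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two values per group")
    d = n1 + n2 - 2
    s2 = (case.var(ddof=1) * (n1 - 1) + control.var(ddof=1) * (n2 - 1)) / d
    d0, s20 = prior.df_prior, prior.s2_prior
    if np.isinf(d0):
        s2_tilde, df_total = s20, np.inf
    else:
        s2_tilde = (d0 * s20 + d * s2) / (d0 + d)
        df_total = d0 + d
    if s2_tilde <= 0:
        raise ValueError("shrunk variance is zero; cannot form a t-statistic")
    t = (case.mean() - control.mean()) / np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(abs(t))
    else:
        p = 2.0 * stats.t.sf(abs(t), df_total)
    return float(t), float(df_total), float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_features(
    results: pd.DataFrame, p_cut: float = 0.05, fc_cut: float = 1.5
) -> pd.DataFrame:
    """Flag features with p < p_cut and |signed fold change| > fc_cut.

    Both inequalities are strict.  Adds/overwrites a boolean ``selected``
    column and logs the count.
    """
    out = results.copy()
    out["selected"] = (out["p"] < p_cut) & (out["fold_change"].abs() > fc_cut)
    log.info(
        "select_features: %d of %d features pass p<%g and |FC|>%g",
        int(out["selected"].sum()), len(out), p_cut, fc_cut,
    )
    return out


def combine_family_contrasts(p_values: Sequence[float]) -> float:
    """Fisher combination of per-family p-values for one feature.

    X = -2 sum(ln p) ~ chi-square on 2k df under the global null.  Zero
    p-values are floored at the smallest positive float with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 2:
        raise ValueError("need p-values from at least two families")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("combine_family_contrasts: flooring zero p-values", stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    return float(stats.combine_pvalues(p, method="fisher").pvalue)


# ---------------------------------------------------------------------------
# Table-level drivers
# ---------------------------------------------------------------------------


def _split_classes(t: FeatureTable) -> Tuple[np.ndarray, np.ndarray]:
    case_cols = t.class_columns("case")
    ctrl_cols = t.class_columns("control")
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need at least two samples per class")
    X = t.intensities
    return X[case_cols].to_numpy(float), X[ctrl_cols].to_numpy(float)


def differential_analysis(
    t: FeatureTable,
    p_cut: float = 0.05,
    fc_cut: float = 1.5,
    prior: Optional[ShrinkageEstimate] = None,
) -> pd.DataFrame:
    """Full per-feature differential table for a pretreated cohort.

    Fold changes are computed on the normalized intensity scale; the
    moderated t on log2 intensities (variance stabilization), with the
    variance prior fitted across all features unless one is supplied.
    Returns a frame with fold_change, log2_fc, t, df, p, q and selected.
    """
    if t.missing_mask.to_numpy().any():
        raise ValueError("differential_analysis requires an imputed table")
    case, ctrl = _split_classes(t)
    n1, n2 = case.shape[1], ctrl.shape[1]
    d = n1 + n2 - 2

    lcase, lctrl = np.log2(case), np.log2(ctrl)
    s2 = (lcase.var(axis=1, ddof=1) * (n1 - 1) + lctrl.var(axis=1, ddof=1) * (n2 - 1)) / d
    if prior is None:
        prior = fit_variance_prior(s2, d)
        log.info(
            "variance prior: s0^2=%.4g, d0=%s", prior.s2_prior, prior.df_prior
        )

    rows = []
    for i, fid in enumerate(t.features.index):
        fc = signed_fold_change(case[i], ctrl[i])
        tt, df_total, p = moderated_t(lcase[i], lctrl[i], prior)
        rows.append(
            {
                "feature_id": fid,
                "fold_change": fc,
                "log2_fc": float(lcase[i].mean() - lctrl[i].mean()),
                "t": tt,
                "df": df_total,
                "p": p,
            }
        )
    res = pd.DataFrame(rows).set_index("feature_id")
    res["q"] = bh_fdr(res["p"].to_numpy())
    res = select_features(res, p_cut=p_cut, fc_cut=fc_cut)
    out = pd.concat([t.features[["mz", "rt_seconds"]], res], axis=1)
    out.attrs["prior"] = prior
    return out


def family_meta_analysis(
    t: FeatureTable, prior: Optional[ShrinkageEstimate] = None
) -> pd.DataFrame:
    """Per-feature Fisher combination of each-family-vs-controls contrasts.

    Each family with at least two members is tested against the full
    control cohort with the moderated t; the per-family p-values are then
    combined by Fisher's method.  Families of size one cannot form a
    within-group variance and are skipped (logged).
    """
    if t.missing_mask.to_numpy().any():
        raise ValueError("family_meta_analysis requires an imputed table")
    ctrl_cols = t.class_columns("control")
    fams = sorted(
        f for f in t.samples.loc[t.samples["class"] == "case", "family"].unique()
    )
    usable = [
        f
        for f in fams
        if (t.samples["family"] == f).sum() >= 2
    ]
    skipped = sorted(set(fams) - set(usable))
    if skipped:
        log.info("family_meta_analysis: skipping single-member families %s", skipped)
    if len(usable) < 2:
        raise ValueError("need at least two families with >= 2 members")

    lctrl = np.log2(t.intensities[ctrl_cols].to_numpy(float))
    fam_p: Dict = {}
    for fam in usable:
        cols = t.samples.index[t.samples["family"] == fam]
        lfam = np.log2(t.intensities[cols].to_numpy(float))
        n1, n2 = lfam.shape[1], lctrl.shape[1]
        d = n1 + n2 - 2
        s2 = (
            lfam.var(axis=1, ddof=1) * (n1 - 1) + lctrl.var(axis=1, ddof=1) * (n2 - 1)
        ) / d
        fam_prior = prior if prior is not None else fit_variance_prior(s2, d)
        fam_p[fam] = [
            moderated_t(lfam[i], lctrl[i], fam_prior)[2] for i in range(len(t.features))
        ]
    out = pd.DataFrame(fam_p, index=t.features.index).add_prefix("p_")
    out["p_combined"] = [
        combine_family_contrasts(row) for row in out.to_numpy()
    ]
    return out
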