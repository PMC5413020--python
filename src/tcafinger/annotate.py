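"""Exact-mass annotation: match features to library metabolites via the
adduct grammar, group co-eluting ion forms, and average fold changes.

A feature matches a (metabolite, ion form) pair when the polarity agrees
and |observed - theoretical m/z| is within the mass tolerance (absolute
Da by default; ppm mode available).  All forms retained for one
metabolite must co-elute within a retention-time window.  Isobaric
library entries (identical formula, e.g. citrate vs isocitrate) produce
identical theoretical masses; such collisions are reported with an
ambiguity flag rather than resolved - distinguishing them requires MS/MS
fragmentation, which is outside the scope of exact-mass matching.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import AdductRule, delta_mz, parse_formula, theoretical_mz

__all__ = [
    "MatchedForm",
    "MetaboliteAnnotation",
    "match_features",
    "average_fold_change",
    "fingerprint_report",
    "write_report",
    "read_report",
]

log = logging.getLogger("tcafinger")

DEFAULT_TOLERANCE_DA = 0.003


@dataclass(frozen=True)
class MatchedForm:
    """One feature matched to one ion form of a metabolite."""

    feature_id: str
    form: str
    observed_mz: float
    theoretical_mz: float
    delta_mz: float
    fold_change: float = np.nan


@dataclass
class MetaboliteAnnotation:
    """All matched ion forms of one library metabolite."""

    name: str
    kegg_id: str
    formula: str
    forms: List[MatchedForm] = field(default_factory=list)
    avg_fold_change: float = np.nan
    ambiguous: bool = False
    sign_consistent: bool = True


def average_fold_change(fold_changes: Sequence[float]) -> Tuple[float, bool]:
    """Arithmetic mean of the signed per-form fold changes.

    Returns (mean, sign_consistent).  Mixed up/down signs among the forms
    are degenerate for a single metabolite and trigger a warning.  With no
    finite fold change the result is absent (NaN), never zero.
    """
    fc = np.asarray(fold_changes, dtype=float)
    fc = fc[np.isfinite(fc)]
    if fc.size == 0:
        return float("nan"), True
    consistent = bool(np.all(fc > 0) or np.all(fc < 0))
    if not consistent:
        warnings.warn(
            "average_fold_change: mixed fold-change signs among matched forms",
            stacklevel=2,
        )
    return float(fc.mean()), consistent


def _tolerance_da(tolerance: float, mode: str, mz: float) -> float:
    if mode == "da":
        return tolerance
    if mode == "ppm":
        return tolerance * mz * 1e-6
    raise ValueError(f"unknown tolerance mode {mode!r}")


def match_features(
    features: pd.DataFrame,
    library: pd.DataFrame,
    rules: Dict[str, AdductRule],
    tolerance: float = DEFAULT_TOLERANCE_DA,
    tolerance_mode: str = "da",
    rt_window: Optional[float] = None,
    fold_changes: Optional[pd.Series] = None,
) -> List[MetaboliteAnnotation]:
    """Match observed features against every (metabolite, ion form) pair.

    ``features`` needs columns mz, rt_seconds, polarity (indexed by
    feature_id).  When ``rt_window`` is given, the retained matches of one
    metabolite are the largest co-eluting subset within that window
    (earliest window on ties).  Features matching more than one metabolite
    set the ambiguity flag on every affected annotation; so do isobaric
    library collisions.
    """
    if library.empty:
        raise ValueError("empty metabolite library")
    if not rules:
        raise ValueError("empty adduct-rule set")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    required = {"mz", "rt_seconds", "polarity"}
    if not required.issubset(features.columns):
        raise ValueError(f"features missing columns {required - set(features.columns)}")

    annotations: List[MetaboliteAnnotation] = []
    hits_per_feature: Dict[str, List[int]] = {}

    for lib_i, met in library.reset_index(drop=True).iterrows():
        comp = parse_formula(met["formula"])
        matched: List[MatchedForm] = []
        for rule in rules.values():
            theo = theoretical_mz(comp, rule).mz
            pool = features[features["polarity"] == rule.polarity]
            tol = np.array([_tolerance_da(tolerance, tolerance_mode, theo)])
            close = pool[np.abs(pool["mz"].to_numpy() - theo) <= tol]
            for fid, row in close.iterrows():
                fc = (
                    float(fold_changes.get(fid, np.nan))
                    if fold_changes is not None
                    else np.nan
                )
                matched.append(
                    MatchedForm(
                        feature_id=str(fid),
                        form=rule.name,
                        observed_mz=float(row["mz"]),
                        theoretical_mz=theo,
                        delta_mz=delta_mz(float(row["mz"]), theo),
                        fold_change=fc,
                    )
                )
        if rt_window is not None and len(matched) > 1:
            matched = _coeluting_subset(matched, features, rt_window)
        ann = MetaboliteAnnotation(
            name=met["name"], kegg_id=met["kegg_id"], formula=met["formula"]
        )
        ann.forms = sorted(matched, key=lambda m: (m.theoretical_mz, m.feature_id))
        if ann.forms:
            ann.avg_fold_change, ann.sign_consistent = average_fold_change(
                [m.fold_change for m in ann.forms]
            )
        annotations.append(ann)
        for m in ann.forms:
            hits_per_feature.setdefault(m.feature_id, []).append(lib_i)

    # ambiguity: any feature claimed by more than one metabolite
    for fid, owners in hits_per_feature.items():
        if len(set(owners)) > 1:
            for i in set(owners):
                annotations[i].ambiguous = True
    n_matched = sum(len(a.forms) for a in annotations)
    log.info(
        "match_features: %d feature-form matches across %d metabolites "
        "(%d ambiguous)",
        n_matched, len(annotations), sum(a.ambiguous for a in annotations),
    )
    return annotations


def _coeluting_subset(
    matched: List[MatchedForm], features: pd.DataFrame, rt_window: float
) -> List[MatchedForm]:
    """Largest subset of matches sharing an rt window (earliest on ties)."""
    rts = np.array([features.loc[m.feature_id, "rt_seconds"] for m in matched])
    order = np.argsort(rts, kind="stable")
    best: List[int] = []
    for start in range(len(order)):
        cur = [
            order[k]
            for k in range(start, len(order))
            if rts[order[k]] - rts[order[start]] <= rt_window
        ]
        if len(cur) > len(best):
            best = cur
    keep = set(best)
    dropped = len(matched) - len(keep)
    if dropped:
        log.info("co-elution filter dropped %d match(es)", dropped)
    return [m for i, m in enumerate(matched) if i in keep]


def fingerprint_report(
    annotations: Sequence[MetaboliteAnnotation],
) -> pd.DataFrame:
    """Report table: one row per matched form, grouped by metabolite.

    Columns mirror the fingerprint summary (metabolite, KEGG id, match
    form, observed m/z, delta m/z, averaged fold change rounded to 1 dp)
    plus feature ids and flags for downstream plotting.
    """
    rows = []
    for ann in annotations:
        for m in ann.forms:
            rows.append(
                {
                    "metabolite": ann.name,
                    "kegg_id": ann.kegg_id,
                    "match_form": m.form,
                    "mz": round(m.observed_mz, 4),
                    "delta_mz": m.delta_mz,
                    "avg_fold_change": round(ann.avg_fold_change, 1)
                    if np.isfinite(ann.avg_fold_change)
                    else np.nan,
                    "feature_fold_change": m.fold_change,
                    "feature_id": m.feature_id,
                    "ambiguous": ann.ambiguous,
                }
            )
    columns = [
        "metabolite",
        "kegg_id",
        "match_form",
        "mz",
        "delta_mz",
        "avg_fold_change",
        "feature_fold_change",
        "feature_id",
        "ambiguous",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_report(report: pd.DataFrame, path: str) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_report(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
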