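"""Feature-table container and data pretreatment.

The pretreatment chain mirrors standard untargeted-metabolomics practice:

1. ``filter_missing`` — drop features missing from at least 75% of samples
   (detector noise / below detection limit almost everywhere);
2. ``impute_missing`` — replace remaining missing cells with half the
   feature's minimum observed value (detection-limit surrogate);
3. ``sum_normalize`` — express every intensity as a fraction of its
   sample's total spectral sum.

The composed chain is idempotent: running it on its own output changes
nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "filter_missing",
    "impute_missing",
    "sum_normalize",
    "pretreat",
]

log = logging.getLogger("tcafinger")

MZ_RANGE = (67.0, 1000.0)  # acquisition scan range, m/z

FEATURE_COLUMNS = ["mz", "rt_seconds", "polarity"]
SAMPLE_COLUMNS = ["class", "family", "age", "sex"]


@dataclass
class FeatureTable:
    """A features x samples LC-MS intensity matrix with metadata.

    Attributes
    ----------
    features : DataFrame indexed by feature_id with columns mz, rt_seconds,
        polarity.
    samples : DataFrame indexed by sample_id with columns class
        ("case"/"control"), family, age, sex.
    intensities : DataFrame (features x samples) of non-negative reals;
        NaN marks a missing value.
    """

    features: pd.DataFrame
    samples: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.features.index):
            raise ValueError("intensity rows do not match feature index")
        if not self.intensities.columns.equals(self.samples.index):
            raise ValueError("intensity columns do not match sample index")
        vals = self.intensities.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError("negative intensities are not allowed")
        bad = set(self.samples["class"]) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")

    # -- convenience -------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.intensities.isna()

    def class_columns(self, label: str) -> pd.Index:
        return self.samples.index[self.samples["class"] == label]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.features.copy(), self.samples.copy(), self.intensities.copy()
        )

    # -- delimited-text round trip ----------------------------------------
    def write(self, features_path: str, samples_path: str) -> None:
        """Write the documented two-file delimited format.

        The feature file holds feature_id, mz, rt_seconds, polarity and one
        intensity column per sample (empty cell = missing); the companion
        metadata file holds sample_id, class, family, age, sex.
        """
        out = self.features.copy()
        out = pd.concat([out, self.intensities], axis=1)
        out.to_csv(features_path, sep="\t", index_label="feature_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def read(cls, features_path: str, samples_path: str) -> "FeatureTable":
        feat = pd.read_csv(features_path, sep="\t", index_col="feature_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        missing_meta = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
        if missing_meta:
            raise ValueError(f"{samples_path}: missing columns {missing_meta}")
        sample_ids = [c for c in feat.columns if c not in FEATURE_COLUMNS]
        if set(sample_ids) != set(samples.index.astype(str)):
            raise ValueError(
                f"sample columns in {features_path} do not match ids in {samples_path}"
            )
        samples.index = samples.index.astype(str)
        intens = feat[sample_ids].astype(float)
        intens = intens[samples.index]  # metadata order wins
        intens.columns = samples.index
        return cls(feat[FEATURE_COLUMNS].copy(), samples, intens)


def _require_nonempty(t: FeatureTable, op: str) -> None:
    if t.n_features == 0 or t.n_samples == 0:
        raise ValueError(f"{op}: empty feature table")


def filter_missing(t: FeatureTable, threshold: float = 0.75) -> FeatureTable:
    """Drop features whose missing fraction across all samples is >= threshold.

    The boundary is inclusive ("missing from at least 75% of data"), pooled
    over cases and controls.  Feature order is preserved.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    _require_nonempty(t, "filter_missing")
    frac = t.missing_mask.mean(axis=1)
    keep = frac < threshold
    removed = int((~keep).sum())
    log.info("filter_missing: removed %d of %d features (threshold %.2f)",
             removed, t.n_features, threshold)
    return FeatureTable(
        t.features.loc[keep].copy(), t.samples.copy(), t.intensities.loc[keep].copy()
    )


def impute_missing(t: FeatureTable, method: str = "half-minimum") -> FeatureTable:
    """Replace missing cells by half the feature's minimum present value.

    Present values are never altered.  Features with no present value at
    all are rejected (they cannot survive ``filter_missing`` at any
    threshold < 1).
    """
    if method != "half-minimum":
        raise ValueError(f"unknown imputation method {method!r}")
    _require_nonempty(t, "impute_missing")
    intens = t.intensities.copy()
    n_missing = int(intens.isna().sum().sum())
    if n_missing:
        mins = intens.min(axis=1, skipna=True)
        if mins.isna().any():
            bad = list(intens.index[mins.isna()])[:5]
            raise ValueError(f"impute_missing: all-missing feature(s), e.g. {bad}")
        fill = mins / 2.0
        intens = intens.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    log.info("impute_missing: filled %d cells", n_missing)
    return FeatureTable(t.features.copy(), t.samples.copy(), intens)


def sum_normalize(t: FeatureTable) -> FeatureTable:
    """Divide each sample's intensities by that sample's total.

    After normalization every sample's present values sum to 1; within-sample
    ratios between features are unchanged.  A zero-total sample is rejected
    by name.
    """
    _require_nonempty(t, "sum_normalize")
    totals = t.intensities.sum(axis=0, skipna=True)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sum_normalize: zero-total sample(s): {list(zero.index)}")
    intens = t.intensities.div(totals, axis=1)
    log.info("sum_normalize: %d samples normalized to unit total", t.n_samples)
    return FeatureTable(t.features.copy(), t.samples.copy(), intens)


def pretreat(t: FeatureTable, missing_threshold: float = 0.75) -> FeatureTable:
    """Composed pretreatment: filter -> impute -> sum-normalize."""
    return sum_normalize(impute_missing(filter_missing(t, missing_threshold)))
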