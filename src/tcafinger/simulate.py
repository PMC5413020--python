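"""Synthetic case/control LC-MS cohort with known ground truth.

Emulates the study design behind the aconitase-deficiency plasma
fingerprint: a small patient group (8 cases drawn from 4 families) against
30 controls, with a panel of TCA-cycle and associated metabolites planted
at known signed fold changes, each emitted as several co-eluting ion forms
(adducts, isotopologues, in-source fragments), plus uninformative
background noise features.

The data model:

* intensities are log-normal around a per-form base abundance
  (multiplicative instrument + biological noise, CV ``intensity_cv``);
* the case effect is a multiplicative scaling of case intensities by the
  planted signed fold change, applied before missingness so that strongly
  suppressed metabolites can drop below the detection limit in cases;
* missingness is logistic in log intensity (detection-limit censoring):
  the logistic midpoint is calibrated so the overall expected missing
  fraction equals ``missing_rate``;
* observed m/z = theoretical m/z + Gaussian mass error (sd
  ``mass_error_sd`` Da); all forms of one metabolite share a retention
  time within ``rt_window`` seconds.

Everything is driven by one integer seed; per-stage substreams are spawned
deterministically so runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import (
    AdductRule,
    load_adduct_rules,
    load_metabolite_library,
    parse_formula,
    theoretical_mz,
)
from .preprocess import MZ_RANGE, FeatureTable

__all__ = [
    "PanelEntry",
    "CohortDesign",
    "GroundTruth",
    "default_panel",
    "generate_cohort",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass(frozen=True)
class PanelEntry:
    """One planted metabolite: library name, signed fold change, ion forms."""

    name: str
    fold_change: float
    forms: Tuple[str, ...]
    base_abundance: float = 1e6

    def __post_init__(self) -> None:
        if self.fold_change == 0:
            raise ValueError(f"{self.name}: planted fold change must be nonzero")
        if abs(self.fold_change) < 1:
            raise ValueError(
                f"{self.name}: signed fold change must satisfy |FC| >= 1"
            )


#: Default planted effects: the nine fingerprint metabolites at the averaged
#: case/control fold changes of the original cohort, with the ion forms under
#: which each was observed.
_DEFAULT_PANEL_SPEC: Tuple[Tuple[str, float, Tuple[str, ...]], ...] = (
    ("cis-aconitate", -36.9, ("M-H", "M(C13)-H", "M+Cl", "M+Cl37")),
    ("isocitrate", -17.7, ("M-H", "M+Cl", "M+Cl37", "M+ACN-H")),
    ("alpha-ketoglutarate", -4.3, ("M-H", "M+CH3COO", "M-CO2+H")),
    ("succinate", 1.1, ("M+Br", "M+Br81")),
    ("fumarate", -1.4, ("M+Cl37",)),
    ("malate", -1.1, ("M+ACN-H", "M+CH3COO")),
    ("phosphoenolpyruvate", -6.9, ("M+CH3COO", "M-HCOOK+H", "M-CO2+H")),
    (
        "glutamate",
        1.8,
        (
            "M-H",
            "M+HCOO",
            "M-C3H4O2+H",
            "M-HCOOH+H",
            "M-CO2+H",
            "M-CO+H",
            "M-H2O+H",
            "M+H",
            "M+H2O+H",
        ),
    ),
    ("hydroxybutyrate", -21.8, ("M-H", "M+Na-2H", "M+HCOO", "M+CH3COO")),
)


def default_panel() -> Tuple[PanelEntry, ...]:
    """The nine-metabolite fingerprint panel with its planted fold changes."""
    return tuple(
        PanelEntry(name=n, fold_change=fc, forms=forms)
        for n, fc, forms in _DEFAULT_PANEL_SPEC
    )


@dataclass
class CohortDesign:
    """Specification of a synthetic case/control cohort."""

    n_cases: int = 8
    n_controls: int = 30
    family_sizes: Tuple[int, ...] = (2, 3, 2, 1)
    panel: Tuple[PanelEntry, ...] = field(default_factory=default_panel)
    mass_error_sd: float = 0.0005  # Da
    rt_window: float = 5.0  # s; co-elution spread of one metabolite's forms
    intensity_cv: float = 0.2
    missing_rate: float = 0.1
    missing_slope: float = 0.5  # logistic slope in ln-intensity units
    n_noise_features: int = 1000
    noise_log10_abundance: Tuple[float, float] = (3.0, 7.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 samples per class")
        if sum(self.family_sizes) != self.n_cases:
            raise ValueError(
                f"family sizes {self.family_sizes} do not sum to n_cases={self.n_cases}"
            )
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if len(self.panel) == 0:
            raise ValueError("empty metabolite panel")


@dataclass
class GroundTruth:
    """Per-feature provenance and per-sample design of a simulated cohort.

    ``features`` has one row per feature: metabolite (or "noise"), ion form,
    theoretical m/z and the planted signed fold change (1.0 for noise).
    ``samples`` mirrors the cohort metadata (class, family).
    """

    features: pd.DataFrame
    samples: pd.DataFrame


def _signed_fc_to_ratio(fc: float) -> float:
    """Case/control intensity ratio implied by a signed fold change."""
    return fc if fc > 0 else 1.0 / abs(fc)


def _sample_frame(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    k = 0
    for fam_i, size in enumerate(design.family_sizes, start=1):
        for _ in range(size):
            k += 1
            rows.append(
                {
                    "sample_id": f"case_{k:02d}",
                    "class": "case",
                    "family": f"F{fam_i}",
                    "age": float(np.round(rng.uniform(1.8, 21.0), 1)),
                    "sex": str(rng.choice(["F", "M"])),
                }
            )
    for j in range(1, design.n_controls + 1):
        rows.append(
            {
                "sample_id": f"ctrl_{j:02d}",
                "class": "control",
                "family": "control",
                "age": float(np.round(rng.uniform(1.8, 17.0), 1)),
                "sex": str(rng.choice(["F", "M"])),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_cohort(
    design: CohortDesign,
    library: Optional[pd.DataFrame] = None,
    rules: Optional[Dict[str, AdductRule]] = None,
) -> Tuple[FeatureTable, GroundTruth]:
    """Simulate a feature table and its ground truth from a cohort design.

    Deterministic given ``design.seed``; feature count equals the number of
    requested (metabolite, form) pairs plus ``n_noise_features``.
    """
    library = library if library is not None else load_metabolite_library()
    rules = rules if rules is not None else load_adduct_rules()
    lib = library.set_index("name")
    for entry in design.panel:
        if entry.name not in lib.index:
            raise ValueError(f"panel metabolite {entry.name!r} not in library")
        for form in entry.forms:
            if form not in rules:
                raise ValueError(f"unknown ion form {form!r} for {entry.name!r}")

    root = np.random.SeedSequence(design.seed)
    rng_meta, rng_feat, rng_intens, rng_missing = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    samples = _sample_frame(design, rng_meta)
    is_case = (samples["class"] == "case").to_numpy()
    n = len(samples)

    feat_rows: List[dict] = []
    truth_rows: List[dict] = []
    base_levels: List[float] = []
    ratios: List[float] = []

    fid = 0
    for entry in design.panel:
        comp = parse_formula(lib.loc[entry.name, "formula"])
        met_rt = rng_feat.uniform(60.0, 840.0)
        ratio = _signed_fc_to_ratio(entry.fold_change)
        for form in entry.forms:
            rule = rules[form]
            theo = theoretical_mz(comp, rule).mz
            fid += 1
            feat_rows.append(
                {
                    "feature_id": f"feat_{fid:05d}",
                    "mz": theo + rng_feat.normal(0.0, design.mass_error_sd),
                    "rt_seconds": met_rt
                    + rng_feat.uniform(-design.rt_window / 2, design.rt_window / 2),
                    "polarity": rule.polarity,
                }
            )
            truth_rows.append(
                {
                    "feature_id": f"feat_{fid:05d}",
                    "metabolite": entry.name,
                    "form": form,
                    "mz_theoretical": theo,
                    "fold_change": entry.fold_change,
                }
            )
            # per-form detector response: forms of one metabolite differ in
            # ionization efficiency
            base_levels.append(entry.base_abundance * rng_feat.uniform(0.3, 1.0))
            ratios.append(ratio)

    lo10, hi10 = design.noise_log10_abundance
    for _ in range(design.n_noise_features):
        fid += 1
        feat_rows.append(
            {
                "feature_id": f"feat_{fid:05d}",
                "mz": rng_feat.uniform(*MZ_RANGE),
                "rt_seconds": rng_feat.uniform(0.0, 900.0),
                "polarity": str(rng_feat.choice(["negative", "positive"])),
            }
        )
        truth_rows.append(
            {
                "feature_id": f"feat_{fid:05d}",
                "metabolite": "noise",
                "form": "",
                "mz_theoretical": np.nan,
                "fold_change": 1.0,
            }
        )
        base_levels.append(10.0 ** rng_feat.uniform(lo10, hi10))
        ratios.append(1.0)

    features = pd.DataFrame(feat_rows).set_index("feature_id")
    truth = pd.DataFrame(truth_rows).set_index("feature_id")

    # log-normal intensities with the requested coefficient of variation
    sigma = np.sqrt(np.log1p(design.intensity_cv**2))
    base = np.asarray(base_levels)[:, None]
    ratio_mat = np.where(is_case[None, :], np.asarray(ratios)[:, None], 1.0)
    noise = np.exp(rng_intens.normal(0.0, sigma, size=(len(features), n)) - sigma**2 / 2)
    intens = base * ratio_mat * noise

    # detection-limit censoring: P(missing | x=ln I) = 1/(1+exp((x-x0)/s)),
    # with x0 calibrated so the expected overall missing fraction is
    # missing_rate
    if design.missing_rate > 0:
        x = np.log(intens)
        s = design.missing_slope

        def mean_p(x0: float) -> float:
            return float(np.mean(1.0 / (1.0 + np.exp((x - x0) / s))))

        lo, hi = x.min() - 10 * s, x.max() + 10 * s
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if mean_p(mid) < design.missing_rate:
                lo = mid
            else:
                hi = mid
        p_missing = 1.0 / (1.0 + np.exp((x - mid) / s))
        mask = rng_missing.uniform(size=intens.shape) < p_missing
        intens = np.where(mask, np.nan, intens)

    intensities = pd.DataFrame(intens, index=features.index, columns=samples.index)
    table = FeatureTable(features, samples, intensities)
    return table, GroundTruth(features=truth, samples=samples.copy())


# ---------------------------------------------------------------------------
# Ground-truth round trip
# ---------------------------------------------------------------------------


def _samples_path(path: str) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".samples" + (p.suffix or ".tsv"))


def write_ground_truth(gt: GroundTruth, path: str) -> None:
    """Write the ground truth (one feature row each; samples alongside)."""
    gt.features.to_csv(path, sep="\t", index_label="feature_id")
    gt.samples.to_csv(_samples_path(path), sep="\t", index_label="sample_id")


def read_ground_truth(path: str) -> GroundTruth:
    features = pd.read_csv(
        path, sep="\t", index_col="feature_id", keep_default_na=True
    )
    features["form"] = features["form"].fillna("")
    samples = pd.read_csv(_samples_path(path), sep="\t", index_col="sample_id")
    return GroundTruth(features=features, samples=samples)
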