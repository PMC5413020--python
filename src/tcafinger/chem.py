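"""Molecular formulas, monoisotopic masses and the adduct/fragment grammar.

Converts a neutral metabolite formula into the theoretical m/z of any of
its ion forms (deprotonated molecule, chloride/formate/acetate attachment,
in-source fragments, single heavy-isotope substitutions, ...).  Two charge
conventions are supported:

* ``proton-transfer`` — the ion is made by moving a proton, so the m/z is
  the neutral (possibly adduct/fragment-modified) mass plus or minus the
  proton mass 1.007276 Da depending on polarity.
* ``species-attachment`` — an anion/cation attaches as a whole; the m/z is
  the neutral mass plus the *neutral* monoisotopic mass of the attached
  species, with no electron-mass correction.

All ion forms here are singly charged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ElementalFormula",
    "AdductRule",
    "IonMass",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "apply_rule",
    "theoretical_mz",
    "delta_mz",
    "load_adduct_rules",
    "load_metabolite_library",
]

#: Monoisotopic atomic masses in Da.  Heavy isotopes carry a mass-number
#: prefix ("13C", "37Cl", "81Br"); bare symbols mean the most abundant
#: isotope.  Carbon-12 is exactly 12 by definition.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885268,
    "Br": 78.9183376,
    "13C": 13.00335484,
    "37Cl": 36.96590259,
    "81Br": 80.9162906,
}

#: Mass of a proton in Da (charge carrier for proton-transfer ion forms).
PROTON_MASS = 1.007276

#: A molecular composition: element-or-isotope symbol -> count (>= 1).
ElementalFormula = Dict[str, int]

_TOKEN = re.compile(r"(?:\[(\d+[A-Z][a-z]?)\]|(\d*)([A-Z][a-z]?))(\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string such as ``"C3H5O6P"``.

    Heavy isotopes are written in brackets (``"[13C]C5H8O7"``); a bare
    leading mass number (``"13CC5H8O7"``) is also accepted where
    unambiguous.  Raises ``ValueError`` for unknown symbols or
    non-positive counts.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    comp: ElementalFormula = {}
    pos = 0
    s = text.strip()
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or m.start() != pos or not (m.group(1) or m.group(3)):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        bracketed, iso, sym, num = m.groups()
        symbol = bracketed if bracketed else ((iso + sym) if iso else sym)
        if symbol not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {symbol!r} in {text!r}")
        count = int(num) if num else 1
        if count <= 0:
            raise ValueError(f"non-positive count for {symbol!r} in {text!r}")
        comp[symbol] = comp.get(symbol, 0) + count
        pos = m.end()
    return comp


_HILL_MAJOR = ("C", "13C", "H")


def format_formula(comp: Mapping[str, int]) -> str:
    """Format a composition in Hill order (C, H, then alphabetical)."""
    parts: List[str] = []

    def emit(sym: str) -> None:
        n = comp[sym]
        shown = f"[{sym}]" if sym[0].isdigit() else sym
        parts.append(f"{shown}{n if n != 1 else ''}")

    for sym in _HILL_MAJOR:
        if sym in comp:
            emit(sym)
    for sym in sorted(k for k in comp if k not in _HILL_MAJOR):
        emit(sym)
    return "".join(parts)


def monoisotopic_mass(comp: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da: sum of count x atomic mass over the formula."""
    for sym, n in comp.items():
        if sym not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {sym!r}")
        if not isinstance(n, (int,)) or n < 1:
            raise ValueError(f"invalid count {n!r} for {sym!r}")
    return sum(MONOISOTOPIC_MASS[sym] * n for sym, n in comp.items())


@dataclass(frozen=True)
class AdductRule:
    """One named ion-form transformation of a neutral molecule.

    ``isotope_substitutions`` is a tuple of (light, heavy, count) triples
    applied after atom addition/removal, e.g. ``("Cl", "37Cl", 1)``.
    """

    name: str
    polarity: str  # "negative" | "positive"
    atoms_added: Tuple[Tuple[str, int], ...] = ()
    atoms_removed: Tuple[Tuple[str, int], ...] = ()
    isotope_substitutions: Tuple[Tuple[str, str, int], ...] = ()
    charge_convention: str = "proton-transfer"

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"rule {self.name!r}: bad polarity {self.polarity!r}")
        if self.charge_convention not in ("proton-transfer", "species-attachment"):
            raise ValueError(
                f"rule {self.name!r}: bad charge convention {self.charge_convention!r}"
            )


@dataclass(frozen=True)
class IonMass:
    """Theoretical m/z of one (formula, rule) combination."""

    mz: float
    rule_name: str
    source_formula: str

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"non-positive m/z {self.mz} for {self.rule_name!r}")


def apply_rule(comp: Mapping[str, int], rule: AdductRule) -> ElementalFormula:
    """Ion composition after atom addition/removal and isotope substitution.

    Raises ``ValueError`` (naming the rule) when the rule is not applicable,
    i.e. it would remove atoms the formula does not contain.
    """
    out: ElementalFormula = dict(comp)
    for sym, n in rule.atoms_added:
        out[sym] = out.get(sym, 0) + n
    for sym, n in rule.atoms_removed:
        have = out.get(sym, 0)
        if have < n:
            raise ValueError(
                f"rule {rule.name!r} not applicable: cannot remove {n} x {sym} "
                f"from {format_formula(comp)}"
            )
        out[sym] = have - n
        if out[sym] == 0:
            del out[sym]
    for light, heavy, n in rule.isotope_substitutions:
        have = out.get(light, 0)
        if have < n:
            raise ValueError(
                f"rule {rule.name!r} not applicable: no {light} left to "
                f"substitute with {heavy}"
            )
        out[light] = have - n
        if out[light] == 0:
            del out[light]
        out[heavy] = out.get(heavy, 0) + n
    return out


#: Alkali counter-ions that neutral-loss rules may remove even when the
#: neutral formula does not contain them: acids are partly present as their
#: Na/K salts in plasma, so e.g. a potassium-formate loss can occur from
#: phosphoenolpyruvate although C3H5O6P itself carries no K.  The m/z
#: bookkeeping is plain mass arithmetic in that case.
_COUNTER_IONS = frozenset({"Na", "K"})


def _ion_mass(comp: Mapping[str, int], rule: AdductRule) -> float:
    """Neutral-species mass after the rule's atom edits (mass arithmetic).

    Elementwise applicability is enforced except for alkali counter-ion
    deficits (see ``_COUNTER_IONS``).
    """
    out: Dict[str, int] = dict(comp)
    for sym, n in rule.atoms_added:
        out[sym] = out.get(sym, 0) + n
    for sym, n in rule.atoms_removed:
        have = out.get(sym, 0)
        if have < n and sym not in _COUNTER_IONS:
            raise ValueError(
                f"rule {rule.name!r} not applicable: cannot remove {n} x {sym} "
                f"from {format_formula(comp)}"
            )
        out[sym] = have - n
    for light, heavy, n in rule.isotope_substitutions:
        if out.get(light, 0) < n:
            raise ValueError(
                f"rule {rule.name!r} not applicable: no {light} left to "
                f"substitute with {heavy}"
            )
        out[light] = out.get(light, 0) - n
        out[heavy] = out.get(heavy, 0) + n
    return sum(MONOISOTOPIC_MASS[sym] * n for sym, n in out.items() if n != 0)


def theoretical_mz(comp: Mapping[str, int], rule: AdductRule) -> IonMass:
    """Theoretical m/z of ``comp`` ionized via ``rule`` (charge magnitude 1)."""
    mass = _ion_mass(comp, rule)
    if rule.charge_convention == "proton-transfer":
        mass += PROTON_MASS if rule.polarity == "positive" else -PROTON_MASS
    return IonMass(mz=mass, rule_name=rule.name, source_formula=format_formula(comp))


def delta_mz(observed: float, theoretical: float) -> float:
    """Signed observed-minus-calculated mass difference, 4 dp.

    Rounding is half-away-from-zero on the full-precision difference, the
    convention under which the annotation tables round-trip.
    """
    if observed <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    diff = Decimal(repr(observed - theoretical))
    return float(diff.quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Bundled data-driven rule and library tables
# ---------------------------------------------------------------------------


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("tcafinger").joinpath("data", filename)))


def _parse_subs(text: str) -> Tuple[Tuple[str, str, int], ...]:
    text = (text or "").strip()
    if not text:
        return ()
    subs = []
    for part in text.split(";"):
        pair, _, count = part.partition(":")
        light, _, heavy = pair.partition(">")
        subs.append((light.strip(), heavy.strip(), int(count or 1)))
    return tuple(subs)


def load_adduct_rules(path: Optional[str] = None) -> Dict[str, AdductRule]:
    """Load the adduct-rule table (bundled 18-form table by default)."""
    p = Path(path) if path is not None else _data_path("adduct_rules.tsv")
    df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    rules: Dict[str, AdductRule] = {}
    for row in df.itertuples(index=False):
        added = tuple(sorted(parse_formula(row.atoms_added).items())) if row.atoms_added.strip() else ()
        removed = tuple(sorted(parse_formula(row.atoms_removed).items())) if row.atoms_removed.strip() else ()
        rule = AdductRule(
            name=row.name.strip(),
            polarity=row.polarity.strip(),
            atoms_added=added,
            atoms_removed=removed,
            isotope_substitutions=_parse_subs(row.isotope_substitutions),
            charge_convention=row.charge_convention.strip(),
        )
        rules[rule.name] = rule
    if not rules:
        raise ValueError(f"no adduct rules found in {p}")
    return rules


def load_metabolite_library(path: Optional[str] = None) -> pd.DataFrame:
    """Load the metabolite library (name, kegg_id, formula).

    The bundled default covers the nine TCA-cycle and associated plasma
    metabolites of the aconitase-deficiency fingerprint.
    """
    p = Path(path) if path is not None else _data_path("metabolite_library.tsv")
    df = pd.read_csv(p, sep="\t", dtype=str)
    required = {"name", "kegg_id", "formula"}
    if not required.issubset(df.columns):
        raise ValueError(f"library at {p} missing columns {required - set(df.columns)}")
    if df.empty:
        raise ValueError(f"empty metabolite library at {p}")
    for f in df["formula"]:
        parse_formula(f)  # validate eagerly
    return df
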