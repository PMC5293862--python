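"""Formula, monoisotopic-mass and adduct arithmetic for small-molecule ESI data.

Masses come from :mod:`pyteomics.mass` (CODATA monoisotopic atomic masses).
Only the elements encountered in plant flavonoids and alkaloids (C, H, N, O,
S, P) are accepted; anything else is rejected at parse time so that typos in
user-supplied formulas fail loudly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from pyteomics import mass as _ptmass

__all__ = [
    "Formula",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "PROTON_MASS",
    "C13_C12_SPACING",
    "P_13C",
    "Moiety",
    "Aglycone",
    "MOIETY_LIBRARY",
    "AGLYCONE_LIBRARY",
]

#: Mass of a proton in Da; used for [M+H]+ / [M-H]- arithmetic.
PROTON_MASS = 1.007276

#: Mass difference between 13C and 12C in Da (isotope envelope spacing).
C13_C12_SPACING = 1.00336

#: Natural abundance of 13C.
P_13C = 0.0107

SUPPORTED_ELEMENTS = frozenset({"C", "H", "N", "O", "S", "P"})

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Element -> count map, e.g. kaempferol ``C15H10O6``."""

    counts: tuple[tuple[str, int], ...]

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return self.as_dict().get(element, 0)

    def __add__(self, other: "Formula") -> "Formula":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return Formula(tuple(sorted(merged.items())))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        d = self.as_dict()
        out = []
        for el in ["C", "H"] + sorted(set(d) - {"C", "H"}):
            if d.get(el):
                out.append(el if d[el] == 1 else f"{el}{d[el]}")
        return "".join(out)


class FormulaError(ValueError):
    pass


def parse_formula(text: str) -> Formula:
    """Parse ``C15H10O6``-style text into a :class:`Formula`.

    Raises :class:`FormulaError` for empty input, unknown element symbols or
    trailing garbage.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"unparseable formula {text!r} at position {pos}")
        if not m.group(0):
            break
        el, num = m.group(1), m.group(2)
        if el not in SUPPORTED_ELEMENTS:
            raise FormulaError(f"unsupported element {el!r} in formula {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"unparseable formula {text!r} at position {pos}")
    if not counts or all(v == 0 for v in counts.values()):
        raise FormulaError(f"formula {text!r} has no atoms")
    return Formula(tuple(sorted(counts.items())))


def monoisotopic_mass(formula: Formula | str) -> float:
    """Monoisotopic neutral mass in Da (CODATA atomic masses via pyteomics)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return float(_ptmass.calculate_mass(composition=formula.as_dict()))


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of ``[M+H]+`` or ``[M-H]-`` for a neutral monoisotopic mass.

    Full float precision is retained; round to 4 dp only for display.
    """
    if neutral_mass <= 0:
        raise ValueError(f"neutral_mass must be positive, got {neutral_mass}")
    adduct = adduct.replace("−", "-")  # tolerate unicode minus
    if adduct in ("[M+H]+", "M+H"):
        return neutral_mass + PROTON_MASS
    if adduct in ("[M-H]-", "M-H"):
        return neutral_mass - PROTON_MASS
    raise ValueError(f"unsupported adduct {adduct!r}; use [M+H]+ or [M-H]-")


def ppm_error(observed: float, theoretical: float) -> float:
    """Nonnegative relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return abs(observed - theoretical) / theoretical * 1e6


# ---------------------------------------------------------------------------
# Built-in libraries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Moiety:
    """A glycosyl/acyl moiety identified by its neutral-loss mass."""

    name: str
    symbol: str
    formula: Formula
    #: monoisotopic neutral-loss mass, Da
    loss_mass: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "loss_mass", monoisotopic_mass(self.formula))


@dataclass(frozen=True)
class Aglycone:
    """A flavonoid/alkaloid core. ``reference_mz`` overrides the
    formula-derived adduct m/z when the literature reference value is the
    authority (perloline has no published formula here)."""

    name: str
    symbol: str
    formula: Formula | None
    reference_mz: float | None = None
    reference_adduct: str | None = None

    def ion_mz(self, adduct: str) -> float:
        if self.formula is not None:
            return adduct_mz(monoisotopic_mass(self.formula), adduct)
        if self.reference_mz is not None and adduct == self.reference_adduct:
            return self.reference_mz
        raise ValueError(f"no mass information for {self.name} as {adduct}")


def _moiety(name: str, symbol: str, formula: str) -> Moiety:
    return Moiety(name, symbol, parse_formula(formula))


#: Neutral losses diagnostic of departing sugar/acyl moieties. Hexose is
#: reported as Glc and deoxyhexose as Rha by field convention (glucose is the
#: dominant hexose in plant flavonoid O-glycosides; rhamnose the only
#: deoxyhexose known in natural flavonoid conjugates).
MOIETY_LIBRARY: dict[str, Moiety] = {
    m.name: m
    for m in [
        _moiety("hexose", "Glc", "C6H10O5"),          # 162.0528
        _moiety("deoxyhexose", "Rha", "C6H10O4"),     # 146.0579
        _moiety("acetylhexose", "acGlc", "C8H12O6"),  # 204.0634
        _moiety("malonylhexose", "maGlc", "C9H12O8"), # 248.0532
        _moiety("feruloylhexose", "feruloylGlc", "C16H18O8"),  # 338.1002
    ]
}

#: Flavonoid aglycones and Lolium alkaloids. Kaempferol and luteolin share
#: C15H10O6 — mass arithmetic cannot distinguish them, and annotation must
#: report the ambiguity rather than resolve it.
AGLYCONE_LIBRARY: dict[str, Aglycone] = {
    a.name: a
    for a in [
        Aglycone("kaempferol", "K", parse_formula("C15H10O6")),
        Aglycone("luteolin", "Lut", parse_formula("C15H10O6")),
        Aglycone("quercetin", "Q", parse_formula("C15H10O7")),
        Aglycone("isorhamnetin", "I", parse_formula("C16H12O7")),
        Aglycone("thesinine", "The", parse_formula("C17H21NO3")),
        Aglycone(
            "perloline", "Per", None,
            reference_mz=333.1234, reference_adduct="[M+H]+",
        ),
        Aglycone("chlorogenic acid", "CGA", parse_formula("C16H18O9")),
    ]
}

#: Reference value quoted in the literature for chlorogenic acid [M-H]-.
CGA_QUOTED_MZ = 353.0867


def cga_reference_discrepancy() -> dict[str, float]:
    """Report the mismatch between the quoted CGA [M-H]- m/z (353.0867) and
    the C16H18O9 formula-derived value, rather than silently matching either.
    """
    derived = AGLYCONE_LIBRARY["chlorogenic acid"].ion_mz("[M-H]-")
    return {
        "quoted_mz": CGA_QUOTED_MZ,
        "formula_derived_mz": round(derived, 4),
        "discrepancy_ppm": ppm_error(CGA_QUOTED_MZ, derived),
    }
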