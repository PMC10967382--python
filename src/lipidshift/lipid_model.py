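"""Lipid class definitions, formula expansion and adduct m/z computation.

A lipid class is stored as the elemental composition of the species with zero
radyl carbons and zero double bonds.  Species are generated by the increment
scheme

    composition(nC, nDB) = base + nC * CH2 - nDB * H2

followed by an ether adjustment for glycerophospholipids: an alkyl ether
(``-O``) replaces one ester linkage (-O +2H relative to the diacyl species),
an alkenyl ether (``-P``, plasmalogen) additionally carries the vinyl double
bond (net -O).  A -P species with n double bonds is therefore exactly
isobaric with the -O species with n+1; unresolved cases are displayed with a
trailing ``(')`` by the annotation layer.

Sphingolipid species are collapsed to (total carbons, total double bonds)
over the sphingoid base plus N-acyl chain, with the hydroxylation tag kept in
the name (``d`` = dihydroxy base), so ``SM(d18:1/12:0)`` and ``SM(d30:1)``
denote the same elemental composition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .chem import (
    ATOMIC_MASSES,
    CH2,
    ELECTRON_MASS,
    H2,
    ElementComposition,
    monoisotopic_mass,
)

__all__ = [
    "Adduct",
    "DEFAULT_ADDUCTS",
    "LipidClassDef",
    "LipidSpecies",
    "adduct_mz",
    "compose_formula",
    "expand_class",
    "expand_database",
    "load_class_definitions",
    "parse_species_name",
    "canonical_species_name",
    "species_name",
]

_ETHER_ORDER = {"none": 0, "O": 1, "P": 2}
_OXYGEN = ElementComposition(O=1)


@dataclass(frozen=True)
class LipidClassDef:
    """A lipid class: generic formula plus expansion ranges."""

    name: str
    category: str  # glycerophospholipid | glycerolipid | sphingolipid | fatty acyl
    base_composition: ElementComposition  # zero radyl carbons, zero double bonds
    n_radyl: int
    c_range: Tuple[int, int]
    db_range: Tuple[int, int]
    ethers: Tuple[str, ...] = ()  # subset of ("O", "P")
    sphingoid: str = ""  # "d" (dihydroxy) or "t" (trihydroxy) for sphingolipids
    tier: str = "primary"  # primary = dedicated internal standard, secondary = PE-normalized

    def __post_init__(self) -> None:
        if self.c_range[0] > self.c_range[1]:
            raise ValueError(f"{self.name}: carbon range min > max")
        if self.db_range[0] > self.db_range[1]:
            raise ValueError(f"{self.name}: double-bond range min > max")
        if self.ethers and self.category != "glycerophospholipid":
            raise ValueError(f"{self.name}: ether modifiers only allowed for glycerophospholipids")
        if self.n_radyl not in (1, 2, 3):
            raise ValueError(f"{self.name}: n_radyl must be 1-3")


@dataclass(frozen=True)
class LipidSpecies:
    """One expanded lipid species with its neutral composition and mass."""

    name: str
    lipid_class: str
    n_carbons: int
    n_double_bonds: int
    ether: str  # "none" | "O" | "P"
    sphingoid: str
    tier: str
    composition: ElementComposition
    mass: float  # neutral monoisotopic, Da


@dataclass(frozen=True)
class Adduct:
    """An ionization adduct: signed composition delta and charge."""

    name: str
    delta: Mapping[str, int]  # signed atom counts gained (+) or lost (-)
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError(f"{self.name}: adduct charge must be nonzero")

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"

    @property
    def delta_mass(self) -> float:
        return sum(n * ATOMIC_MASSES[e] for e, n in self.delta.items())


# The mobile phases contain ammonia and formic acid, so ammoniated and
# formate adducts are expected alongside (de)protonation.
DEFAULT_ADDUCTS: Tuple[Adduct, ...] = (
    Adduct("[M+H]+", {"H": 1}, +1),
    Adduct("[M+NH4]+", {"N": 1, "H": 4}, +1),
    Adduct("[M-H]-", {"H": -1}, -1),
    Adduct("[M+HCOO]-", {"C": 1, "H": 1, "O": 2}, -1),
)


def compose_formula(
    class_def: LipidClassDef, n_carbons: int, n_double_bonds: int, ether: str = "none"
) -> ElementComposition:
    """Expand the generic class formula at a given radyl length and unsaturation.

    Parameters
    ----------
    class_def
        The lipid class to expand.
    n_carbons, n_double_bonds
        Total radyl carbons / double bonds summed over all radyl positions.
    ether
        ``"none"`` for (di/tri)acyl, ``"O"`` for alkyl ether, ``"P"`` for
        alkenyl ether (plasmalogen).

    Returns
    -------
    ElementComposition
        The neutral elemental composition of the species.
    """
    lo, hi = class_def.c_range
    if not lo <= n_carbons <= hi:
        raise ValueError(
            f"{class_def.name}: carbon count {n_carbons} outside range [{lo}, {hi}]"
        )
    lo, hi = class_def.db_range
    if not lo <= n_double_bonds <= hi:
        raise ValueError(
            f"{class_def.name}: double-bond count {n_double_bonds} outside range [{lo}, {hi}]"
        )
    if ether not in ("none", "O", "P"):
        raise ValueError(f"unknown ether tag {ether!r}")
    if ether != "none" and ether not in class_def.ethers:
        raise ValueError(f"{class_def.name}: ether tag {ether!r} not allowed for this class")

    comp = class_def.base_composition + n_carbons * CH2 - n_double_bonds * H2
    if ether == "O":
        comp = comp - _OXYGEN + H2
    elif ether == "P":
        comp = comp - _OXYGEN
    return comp


def species_name(
    lipid_class: str,
    n_carbons: int,
    n_double_bonds: int,
    ether: str = "none",
    sphingoid: str = "",
    prime: bool = False,
) -> str:
    """Display name, e.g. ``PC(34:1)``, ``PE(P-36:2)``, ``SM(d34:1)``, ``PC(O-34:1)'``."""
    prefix = f"{ether}-" if ether in ("O", "P") else ""
    body = f"{sphingoid}{n_carbons}:{n_double_bonds}"
    return f"{lipid_class}({prefix}{body})" + ("'" if prime else "")


_COLLAPSED = re.compile(
    r"^(?P<cls>[A-Za-z][A-Za-z0-9]*)\("
    r"(?:(?P<ether>[OP])-)?(?P<sph>[dt])?(?P<nc>\d+):(?P<db>\d+)\)"
    r"(?P<prime>')?$"
)
_MULTICHAIN = re.compile(
    r"^(?P<cls>[A-Za-z][A-Za-z0-9]*)\((?P<sph>[dt])?(?P<chains>\d+:\d+(?:/\d+:\d+)*)\)"
    r"(?P<mult>\d?)$"
)


def parse_species_name(name: str) -> Tuple[str, int, int, str, str, bool]:
    """Parse a species name into (class, nC, nDB, ether, sphingoid, primed).

    Accepts the collapsed form ``PC(34:1)`` / ``PC(O-34:1)'`` / ``SM(d34:1)``,
    the per-chain form ``Cer(d18:1/12:0)``, and the internal-standard
    multiplier form ``PC(14:0)2`` / ``TG(14:0)3``.
    """
    m = _COLLAPSED.match(name)
    if m:
        return (
            m.group("cls"),
            int(m.group("nc")),
            int(m.group("db")),
            m.group("ether") or "none",
            m.group("sph") or "",
            bool(m.group("prime")),
        )
    m = _MULTICHAIN.match(name)
    if m:
        chains = [tuple(map(int, c.split(":"))) for c in m.group("chains").split("/")]
        mult = int(m.group("mult")) if m.group("mult") else 1
        if mult > 1 and len(chains) > 1:
            raise ValueError(f"cannot combine chain list and multiplier in {name!r}")
        nc = sum(c for c, _ in chains) * mult
        db = sum(d for _, d in chains) * mult
        return (m.group("cls"), nc, db, "none", m.group("sph") or "", False)
    raise ValueError(f"unparseable species name {name!r}")


def canonical_species_name(name: str) -> str:
    """Collapse any accepted name form to the canonical ``CLS(xC:yDB)`` form.

    ``GlcCer`` standards are mapped to the ``HexCer`` class used in the
    bundled class definitions.
    """
    cls, nc, db, ether, sph, prime = parse_species_name(name)
    if cls == "GlcCer":
        cls = "HexCer"
    return species_name(cls, nc, db, ether, sph, prime)


def expand_class(class_def: LipidClassDef, carbon_step: int = 1) -> List[LipidSpecies]:
    """Expand a class over its carbon/double-bond/ether grid.

    Returns one species per (ether, nC, nDB) combination, sorted by
    (ether, nC, nDB) with the diacyl series first.  ``carbon_step`` of 2
    restricts the grid to even-chain species when the minimum is even.
    """
    out: List[LipidSpecies] = []
    ethers = ("none",) + tuple(class_def.ethers)
    for ether in sorted(ethers, key=_ETHER_ORDER.__getitem__):
        for nc in range(class_def.c_range[0], class_def.c_range[1] + 1, carbon_step):
            for db in range(class_def.db_range[0], class_def.db_range[1] + 1):
                comp = compose_formula(class_def, nc, db, ether)
                out.append(
                    LipidSpecies(
                        name=species_name(class_def.name, nc, db, ether, class_def.sphingoid),
                        lipid_class=class_def.name,
                        n_carbons=nc,
                        n_double_bonds=db,
                        ether=ether,
                        sphingoid=class_def.sphingoid,
                        tier=class_def.tier,
                        composition=comp,
                        mass=monoisotopic_mass(comp),
                    )
                )
    return out


def adduct_mz(species_mass: float, adduct: Adduct) -> float:
    """m/z of an adduct ion of a neutral species.

    m/z = (M + delta_mass - z * m_e) / |z|, with the electron mass included
    so that protonation adds the proton mass, not the hydrogen atom mass.
    """
    return (species_mass + adduct.delta_mass - adduct.charge * ELECTRON_MASS) / abs(
        adduct.charge
    )


def load_class_definitions(path: Optional[Path | str] = None) -> Dict[str, LipidClassDef]:
    """Load class definitions from a TSV file (bundled defaults when omitted).

    Columns: class, category, base_formula (Hill notation), n_radyl, c_min,
    c_max, db_min, db_max, ethers (comma-joined or ``-``), sphingoid
    (``d``/``t`` or ``-``), tier (primary|secondary).
    """
    if path is None:
        text = resources.files("lipidshift.data").joinpath("lipid_classes.tsv").read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    defs: Dict[str, LipidClassDef] = {}
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        ethers = tuple(e for e in row["ethers"].split(",") if e and e != "-")
        defs[row["class"]] = LipidClassDef(
            name=row["class"],
            category=row["category"],
            base_composition=ElementComposition.from_formula(row["base_formula"]),
            n_radyl=int(row["n_radyl"]),
            c_range=(int(row["c_min"]), int(row["c_max"])),
            db_range=(int(row["db_min"]), int(row["db_max"])),
            ethers=ethers,
            sphingoid="" if row["sphingoid"] == "-" else row["sphingoid"],
            tier=row["tier"],
        )
    return defs


def expand_database(
    class_defs: Mapping[str, LipidClassDef] | Iterable[LipidClassDef],
    adducts: Sequence[Adduct] = DEFAULT_ADDUCTS,
    carbon_step: int = 1,
) -> pd.DataFrame:
    """Expand all classes into a species table with per-adduct m/z columns."""
    if isinstance(class_defs, Mapping):
        class_defs = list(class_defs.values())
    rows = []
    for cdef in class_defs:
        for sp in expand_class(cdef, carbon_step=carbon_step):
            row = {
                "species": sp.name,
                "lipid_class": sp.lipid_class,
                "ether": sp.ether,
                "n_carbons": sp.n_carbons,
                "n_double_bonds": sp.n_double_bonds,
                "tier": sp.tier,
                "formula": sp.composition.hill_formula(),
                "neutral_mass": sp.mass,
            }
            for add in adducts:
                row[f"mz {add.name}"] = adduct_mz(sp.mass, add)
            rows.append(row)
    return pd.DataFrame(rows)
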