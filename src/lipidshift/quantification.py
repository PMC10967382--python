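"""Internal-standard semiquantification of annotated peak areas.

Abundance of an analyte is its peak area divided by the peak area of the
class internal standard in the same sample (and acquisition mode),
multiplied by the spiked amount of that standard — a semiquantitative value
in arbitrary units (AU, nmol-equivalents).  Classes without a dedicated
standard form a secondary tier normalized against the PE standard, which is
detectable in all four acquisition modes; secondary-tier abundances are
reliable only for class-wide statistics and are excluded from species-level
tests downstream.  Ether PC/PE species, which have no dedicated standard,
are normalized against the diacyl PC/PE standards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .lipid_model import canonical_species_name, parse_species_name

__all__ = [
    "AbundanceMatrix",
    "StandardResolutionError",
    "load_internal_standards",
    "normalize",
    "normalize_secondary",
    "quantify",
    "resolve_standard",
]

MODES = ("NP", "RP")
SECONDARY_REFERENCE_CLASS = "PE"


class StandardResolutionError(KeyError):
    """No internal standard configured for a lipid class / mode."""


@dataclass
class AbundanceMatrix:
    """Species x samples semiquantitative abundances with per-species metadata.

    ``data`` holds abundances in AU (NaN marks cells flagged in ``problems``);
    ``species_info`` is indexed by species with columns ``lipid_class`` and
    ``tier``; ``problems`` records every cell or row that could not be
    normalized, with a reason — nothing is silently dropped or imputed.
    """

    data: pd.DataFrame
    species_info: pd.DataFrame
    problems: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["species", "sample_id", "reason"])
    )

    def primary(self) -> "AbundanceMatrix":
        """Restrict to primary-tier species (those with a dedicated standard)."""
        keep = self.species_info.index[self.species_info["tier"] == "primary"]
        return AbundanceMatrix(
            self.data.loc[keep], self.species_info.loc[keep], self.problems
        )


def load_internal_standards(path: Optional[Path | str] = None) -> pd.DataFrame:
    """Load the internal-standard table (bundled defaults when omitted).

    Columns: class, mode (``NP``/``RP``/``*``), standard, amount_nmol, role
    (``class_standard`` rows are used for normalization; ``auxiliary`` rows
    document additional spiked standards).
    """
    if path is None:
        src = resources.files("lipidshift.data").joinpath("internal_standards.tsv")
        with resources.as_file(src) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    if (table["amount_nmol"] <= 0).any():
        bad = table.loc[table["amount_nmol"] <= 0, "standard"].tolist()
        raise ValueError(f"non-positive internal-standard amounts for {bad}")
    return table


def _standard_map(is_table: pd.DataFrame) -> Dict[Tuple[str, str], Tuple[str, float]]:
    """(class, mode) -> (canonical standard species name, amount in nmol)."""
    out: Dict[Tuple[str, str], Tuple[str, float]] = {}
    rows = is_table[is_table["role"] == "class_standard"]
    for _, row in rows.iterrows():
        modes = MODES if row["mode"] == "*" else (row["mode"],)
        for mode in modes:
            key = (row["class"], mode)
            if key in out:
                raise ValueError(f"duplicate class standard for {key}")
            out[key] = (canonical_species_name(row["standard"]), float(row["amount_nmol"]))
    return out


def resolve_standard(
    species: str, is_table: pd.DataFrame, mode: str = "NP"
) -> Tuple[str, float]:
    """Resolve the internal standard and amount for a species in a given mode.

    Ether species resolve to the diacyl standard of their class (PC-O/PC-P to
    the PC standard, PE-O/PE-P to the PE standard); lyso classes have their
    own standards; secondary-tier classes without any standard raise.
    """
    lipid_class, *_ = parse_species_name(species)
    if lipid_class == "GlcCer":
        lipid_class = "HexCer"
    smap = _standard_map(is_table)
    try:
        return smap[(lipid_class, mode)]
    except KeyError:
        raise StandardResolutionError(
            f"no internal standard configured for class {lipid_class!r} in mode {mode!r}"
        ) from None


def _prepare(annotations: pd.DataFrame) -> pd.DataFrame:
    """Aggregate annotated areas to one row per (species, sample, mode)."""
    required = {"species", "lipid_class", "tier", "sample_id", "mode", "area"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return (
        annotations.groupby(["species", "lipid_class", "tier", "sample_id", "mode"], sort=True)[
            "area"
        ]
        .sum()
        .reset_index()
    )


def _is_areas(
    grouped: pd.DataFrame, smap: Dict[Tuple[str, str], Tuple[str, float]]
) -> Dict[Tuple[str, str, str], float]:
    """(standard name, sample, mode) -> area, from the standards' own rows."""
    std_names = {name for name, _ in smap.values()}
    rows = grouped[grouped["species"].isin(std_names)]
    return {
        (r["species"], r["sample_id"], r["mode"]): float(r["area"])
        for _, r in rows.iterrows()
    }


def _normalize_rows(
    grouped: pd.DataFrame,
    resolver,
    is_areas: Dict[Tuple[str, str, str], float],
    tier_label: str,
) -> AbundanceMatrix:
    cells: Dict[Tuple[str, str], float] = {}
    info: Dict[str, Tuple[str, str]] = {}
    problems: List[dict] = []
    for _, row in grouped.iterrows():
        species, sample, mode = row["species"], row["sample_id"], row["mode"]
        try:
            std_name, amount = resolver(row)
        except StandardResolutionError as exc:
            problems.append({"species": species, "sample_id": sample, "reason": str(exc)})
            cells[(species, sample)] = np.nan
            info[species] = (row["lipid_class"], tier_label)
            continue
        std_area = is_areas.get((std_name, sample, mode))
        info[species] = (row["lipid_class"], tier_label)
        if std_area is None:
            problems.append(
                {
                    "species": species,
                    "sample_id": sample,
                    "reason": f"missing standard peak {std_name} in sample {sample} mode {mode}",
                }
            )
            cells[(species, sample)] = np.nan
        elif std_area <= 0:
            problems.append(
                {
                    "species": species,
                    "sample_id": sample,
                    "reason": f"non-positive standard area for {std_name} in sample {sample}",
                }
            )
            cells[(species, sample)] = np.nan
        else:
            cells[(species, sample)] = float(row["area"]) / std_area * amount
    if cells:
        series = pd.Series(cells)
        data = series.unstack().sort_index()
        data = data[sorted(data.columns)]
    else:
        data = pd.DataFrame()
    species_info = pd.DataFrame(
        {name: {"lipid_class": cls, "tier": tier} for name, (cls, tier) in info.items()}
    ).T
    species_info.index.name = "species"
    return AbundanceMatrix(
        data,
        species_info.sort_index(),
        pd.DataFrame(problems, columns=["species", "sample_id", "reason"]),
    )


def normalize(
    annotations: pd.DataFrame, is_table: Optional[pd.DataFrame] = None
) -> AbundanceMatrix:
    """Normalize primary-tier analytes against their class internal standards.

    abundance(species, sample) = area / area(class standard, sample, mode)
    x amount(class standard).  The standards' own rows are consumed as the
    reference peaks and do not appear among the analytes.
    """
    if is_table is None:
        is_table = load_internal_standards()
    smap = _standard_map(is_table)
    grouped = _prepare(annotations)
    is_areas = _is_areas(grouped, smap)
    std_names = {name for name, _ in smap.values()}
    analytes = grouped[
        (grouped["tier"] == "primary") & (~grouped["species"].isin(std_names))
    ]

    def resolver(row: pd.Series) -> Tuple[str, float]:
        key = (row["lipid_class"], row["mode"])
        if key not in smap:
            raise StandardResolutionError(
                f"no internal standard configured for class {row['lipid_class']!r} "
                f"in mode {row['mode']!r}"
            )
        return smap[key]

    return _normalize_rows(analytes, resolver, is_areas, "primary")


def normalize_secondary(
    annotations: pd.DataFrame, is_table: Optional[pd.DataFrame] = None
) -> AbundanceMatrix:
    """Normalize secondary-tier analytes against the PE standard of their mode.

    These species lack a dedicated standard; PE is used because it is
    detectable in all four acquisition modes.  The resulting abundances carry
    tier ``secondary`` and are intended for class-wide statistics only.
    """
    if is_table is None:
        is_table = load_internal_standards()
    smap = _standard_map(is_table)
    grouped = _prepare(annotations)
    is_areas = _is_areas(grouped, smap)
    analytes = grouped[grouped["tier"] == "secondary"]

    def resolver(row: pd.Series) -> Tuple[str, float]:
        key = (SECONDARY_REFERENCE_CLASS, row["mode"])
        if key not in smap:
            raise StandardResolutionError(
                f"no PE reference standard configured for mode {row['mode']!r}"
            )
        return smap[key]

    return _normalize_rows(analytes, resolver, is_areas, "secondary")


def quantify(
    annotations: pd.DataFrame, is_table: Optional[pd.DataFrame] = None
) -> AbundanceMatrix:
    """Run primary and secondary normalization and stack the two tiers."""
    if is_table is None:
        is_table = load_internal_standards()
    prim = normalize(annotations, is_table)
    sec = normalize_secondary(annotations, is_table)
    if sec.data.empty:
        return prim
    data = pd.concat([prim.data, sec.data]).sort_index()
    info = pd.concat([prim.species_info, sec.species_info]).sort_index()
    problems = pd.concat([prim.problems, sec.problems], ignore_index=True)
    return AbundanceMatrix(data, info, problems)
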