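"""Accurate-mass annotation of MS1 features against an expanded lipid database.

Features (m/z, retention time, polarity, chromatography mode, peak area) are
matched to (species, adduct) ions within a ppm tolerance.  When retention-time
windows are configured for a class they act as an additional gate, which is
how chromatographically separable isobars (e.g. BMP vs PG, alkyl vs alkenyl
ethers) are told apart.  Exactly isobaric alkyl/alkenyl (O-/P-) pairs that
the windows cannot separate are reported once under the primed name, e.g.
``PC(O-34:1)'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lipid_model import Adduct, DEFAULT_ADDUCTS, LipidSpecies, adduct_mz, species_name

__all__ = [
    "FEATURE_COLUMNS",
    "build_ion_index",
    "filter_scan_range",
    "load_rt_windows",
    "match_features",
    "resolve_ether_ambiguity",
]

FEATURE_COLUMNS = ("mz", "rt", "polarity", "mode", "area", "sample_id")

# ppm difference below which two theoretical m/z are treated as one isobar
_ISOBAR_EPS_PPM = 1e-4


@dataclass(frozen=True)
class CandidateIon:
    """One (species, adduct) candidate for a feature."""

    species: str
    lipid_class: str
    ether: str
    n_carbons: int
    n_double_bonds: int
    sphingoid: str
    tier: str
    adduct: str
    ppm: float


def filter_scan_range(features: pd.DataFrame, lo: float, hi: float) -> pd.DataFrame:
    """Keep features with lo <= m/z <= hi (both bounds inclusive), order preserved."""
    if not lo < hi:
        raise ValueError(f"scan range lower bound {lo} must be < upper bound {hi}")
    return features.loc[(features["mz"] >= lo) & (features["mz"] <= hi)]


def load_rt_windows(path: Optional[Path | str] = None) -> Dict[Tuple[str, str], Tuple[float, float]]:
    """Load per-(class, mode) retention-time windows; bundled defaults when omitted.

    Mode ``*`` applies to both chromatography modes.
    """
    if path is None:
        text = resources.files("lipidshift.data").joinpath("rt_windows.tsv").read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    windows: Dict[Tuple[str, str], Tuple[float, float]] = {}
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        windows[(row["class"], row["mode"])] = (float(row["rt_min"]), float(row["rt_max"]))
    return windows


def build_ion_index(
    species: Sequence[LipidSpecies], adducts: Sequence[Adduct] = DEFAULT_ADDUCTS
) -> pd.DataFrame:
    """Long table of all (species, adduct) ions with theoretical m/z, sorted by m/z."""
    rows = []
    for sp in species:
        for add in adducts:
            rows.append(
                {
                    "species": sp.name,
                    "lipid_class": sp.lipid_class,
                    "ether": sp.ether,
                    "n_carbons": sp.n_carbons,
                    "n_double_bonds": sp.n_double_bonds,
                    "sphingoid": sp.sphingoid,
                    "tier": sp.tier,
                    "adduct": add.name,
                    "polarity": add.polarity,
                    "mz": adduct_mz(sp.mass, add),
                }
            )
    return pd.DataFrame(rows).sort_values("mz", kind="mergesort").reset_index(drop=True)


def resolve_ether_ambiguity(candidates: List[CandidateIon]) -> Tuple[str, str, CandidateIon]:
    """Collapse the candidate set of one feature to a single (name, flag, winner).

    If the isobaric tie is exactly an alkyl (O-) / alkenyl (P-) pair of the
    same class and chain length — a P species with n double bonds has the
    same composition as the O species with n+1 — the pair is reported once
    under the O name with a trailing ``(')`` and flagged ``ether-ambiguous``.
    Any other tie is broken lexicographically and flagged ``multi-candidate``.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if len(candidates) == 1:
        c = candidates[0]
        return c.species, "unique", c
    classes = {c.lipid_class for c in candidates}
    if len(candidates) == 2 and len(classes) == 1:
        by_ether = {c.ether: c for c in candidates}
        if set(by_ether) == {"O", "P"}:
            o, p = by_ether["O"], by_ether["P"]
            if o.n_carbons == p.n_carbons and o.n_double_bonds == p.n_double_bonds + 1:
                name = species_name(
                    o.lipid_class, o.n_carbons, o.n_double_bonds, "O", o.sphingoid, prime=True
                )
                return name, "ether-ambiguous", o
    winner = min(candidates, key=lambda c: c.species)
    return winner.species, "multi-candidate", winner


def match_features(
    features: pd.DataFrame,
    ion_index: pd.DataFrame,
    ppm_tol: float = 5.0,
    rt_windows: Optional[Mapping[Tuple[str, str], Tuple[float, float]]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate features by accurate mass (and optional retention windows).

    For each feature the candidate set is every (species, adduct) ion with
    matching polarity, |mass error| <= ``ppm_tol`` and, when a window is
    configured for the species' class in the feature's mode, retention time
    inside that window.  The winner is the candidate with the smallest
    absolute ppm error; exact isobars are resolved by
    :func:`resolve_ether_ambiguity`.

    Returns
    -------
    (annotations, unassigned)
        ``annotations`` has one row per matched feature with columns
        ``feature_index, sample_id, mode, polarity, rt, mz, area, species,
        lipid_class, tier, adduct, ppm, flag``; ``unassigned`` holds the
        remaining feature rows unchanged.
    """
    if ion_index.empty:
        raise ValueError("ion index is empty")
    if ppm_tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")

    db_mz = ion_index["mz"].to_numpy()
    records = ion_index.to_dict("records")

    annotated_rows = []
    unassigned_idx = []
    for idx, feat in features.iterrows():
        fmz = float(feat["mz"])
        if fmz <= 0:
            raise ValueError(f"row {idx}: non-positive m/z {fmz}")
        if float(feat["area"]) < 0:
            raise ValueError(f"row {idx}: negative area {feat['area']}")
        half = fmz * ppm_tol * 1e-6
        lo = np.searchsorted(db_mz, fmz - half, side="left")
        hi = np.searchsorted(db_mz, fmz + half, side="right")
        candidates: List[CandidateIon] = []
        for j in range(lo, hi):
            ion = records[j]
            if ion["polarity"] != feat["polarity"]:
                continue
            ppm = (fmz - ion["mz"]) / ion["mz"] * 1e6
            if abs(ppm) > ppm_tol:
                continue
            if rt_windows is not None:
                # ether-specific windows (key "PC(O)") take precedence over
                # the class-wide window when configured
                keys = []
                if ion["ether"] in ("O", "P"):
                    eth_cls = f"{ion['lipid_class']}({ion['ether']})"
                    keys += [(eth_cls, feat["mode"]), (eth_cls, "*")]
                keys += [(ion["lipid_class"], feat["mode"]), (ion["lipid_class"], "*")]
                window = next(
                    (rt_windows[k] for k in keys if k in rt_windows), None
                )
                if window is not None and not (window[0] <= feat["rt"] <= window[1]):
                    continue
            candidates.append(
                CandidateIon(
                    species=ion["species"],
                    lipid_class=ion["lipid_class"],
                    ether=ion["ether"],
                    n_carbons=ion["n_carbons"],
                    n_double_bonds=ion["n_double_bonds"],
                    sphingoid=ion["sphingoid"],
                    tier=ion["tier"],
                    adduct=ion["adduct"],
                    ppm=ppm,
                )
            )
        if not candidates:
            unassigned_idx.append(idx)
            continue
        best = min(abs(c.ppm) for c in candidates)
        ties = [c for c in candidates if abs(c.ppm) - best <= _ISOBAR_EPS_PPM]
        name, flag, winner = resolve_ether_ambiguity(ties)
        annotated_rows.append(
            {
                "feature_index": idx,
                "sample_id": feat["sample_id"],
                "mode": feat["mode"],
                "polarity": feat["polarity"],
                "rt": feat["rt"],
                "mz": fmz,
                "area": float(feat["area"]),
                "species": name,
                "lipid_class": winner.lipid_class,
                "tier": winner.tier,
                "adduct": winner.adduct,
                "ppm": winner.ppm,
                "flag": flag,
            }
        )
    annotations = pd.DataFrame(
        annotated_rows,
        columns=[
            "feature_index",
            "sample_id",
            "mode",
            "polarity",
            "rt",
            "mz",
            "area",
            "species",
            "lipid_class",
            "tier",
            "adduct",
            "ppm",
            "flag",
        ],
    )
    unassigned = features.loc[unassigned_idx]
    return annotations, unassigned
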