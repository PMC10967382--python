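"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-cell-type, three-group pneumonia cohort
(controls, patients at hospital admission, and a resampled subset of the
patients one month later) with log-normally distributed species abundances,
planted class-wide shifts, a saturation-dependent triacylglycerol effect,
and — optionally — raw MS1 feature tables with internal-standard peaks,
ppm jitter and multiplicative area noise.  Every planted effect is recorded
in a ground-truth table.

Default admission profiles mirror the qualitative direction of the study
system: in monocytes the membrane classes PC, PE and SM and the free fatty
acid pool shift down; in neutrophils BMP, DG, PA, LPE, PC, PE and the fatty
acid pool shift up while SM and SPH shift down, and triacylglycerols show a
saturation-dependent pattern (saturated species down, polyunsaturated
species up).  Monocyte changes resolve fully at recovery, neutrophil changes
only partially.  Effect magnitudes are simulation parameters, not measured
values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import load_rt_windows
from .lipid_model import (
    DEFAULT_ADDUCTS,
    LipidSpecies,
    adduct_mz,
    canonical_species_name,
    expand_class,
    load_class_definitions,
    species_name,
)
from .quantification import AbundanceMatrix, load_internal_standards

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "SimulatedFeatureSet",
    "class_truth",
    "simulate_abundances",
    "simulate_features",
]

GROUPS = ("control", "cap_admission", "cap_recovery")

# Roster grids: class -> (c_lo, c_hi, c_step, db_lo, db_hi).  Grids are kept
# clear of the internal-standard species (short 14:0/d18:1-12:0 chains) so a
# standard's peak is never also an endogenous analyte.
MONOCYTE_ROSTER: Dict[str, Tuple[int, int, int, int, int]] = {
    "PC": (32, 40, 2, 0, 3),
    "PE": (32, 40, 2, 0, 3),
    "PA": (32, 38, 2, 0, 2),
    "PG": (32, 38, 2, 0, 2),
    "BMP": (32, 38, 2, 0, 2),
    "LPC": (16, 20, 2, 0, 1),
    "LPE": (16, 20, 2, 0, 1),
    "LPA": (16, 20, 2, 0, 1),
    "LPG": (16, 20, 2, 0, 1),
    "DG": (32, 38, 2, 0, 2),
    "TG": (48, 56, 2, 0, 6),
    "Cer": (32, 40, 2, 0, 2),
    "SM": (32, 40, 2, 0, 2),
    "HexCer": (34, 38, 2, 0, 1),
    "LacCer": (34, 38, 2, 0, 1),
    "SPH": (16, 20, 2, 0, 1),
    "FA": (16, 22, 2, 0, 4),
}

NEUTROPHIL_ROSTER: Dict[str, Tuple[int, int, int, int, int]] = {
    "PC": (32, 40, 2, 0, 4),
    "PE": (32, 40, 2, 0, 4),
    "PA": (32, 40, 2, 0, 2),
    "PG": (32, 40, 2, 0, 2),
    "BMP": (32, 40, 2, 0, 2),
    "LPC": (16, 20, 2, 0, 2),
    "LPE": (16, 20, 2, 0, 2),
    "LPA": (16, 20, 2, 0, 2),
    "LPG": (16, 20, 2, 0, 2),
    "DG": (32, 40, 2, 0, 4),
    "TG": (46, 58, 2, 0, 8),
    "Cer": (32, 40, 2, 0, 2),
    "SM": (32, 40, 2, 0, 2),
    "HexCer": (34, 38, 2, 0, 1),
    "LacCer": (34, 38, 2, 0, 1),
    "SPH": (16, 20, 2, 0, 1),
    "FA": (16, 22, 2, 0, 4),
}

MONOCYTE_MULTIPLIERS = {"PC": 0.8, "PE": 0.8, "SM": 0.7, "FA": 0.7}
NEUTROPHIL_MULTIPLIERS = {
    "BMP": 2.5,
    "DG": 1.5,
    "PA": 2.0,
    "LPE": 1.5,
    "PC": 1.4,
    "PE": 1.4,
    "SM": 0.8,
    "SPH": 0.7,
    "FA": 1.5,
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the cohort generator; identical configs reproduce outputs.

    Group sizes default to the study design (25 controls, 48 patients at
    admission, 33 of them resampled at recovery).  Species abundances are
    lognormal with a default coefficient of variation of 30%; planted class
    multipliers act on the admission group and relax toward 1 at recovery as
    ``multiplier ** recovery_relax``.  The triacylglycerol multiplier is
    ``tg_base_multiplier * tg_db_multiplier ** n_double_bonds``, giving the
    saturation-dependent pattern.  Sparse species-level effects of
    ``sparse_log2fc`` (random sign) are planted on a fraction of the species
    belonging to classes without a class-wide effect, so class-level ground
    truth stays unambiguous.
    """

    seed: int = 0
    n_control: int = 25
    n_admission: int = 48
    n_recovery: int = 33
    roster: Mapping[str, Tuple[int, int, int, int, int]] = field(
        default_factory=lambda: dict(MONOCYTE_ROSTER)
    )
    class_multipliers: Mapping[str, float] = field(default_factory=dict)
    tg_base_multiplier: float = 1.0
    tg_db_multiplier: float = 1.0
    recovery_relax: float = 0.0
    baseline_log_sd: float = 1.0
    species_cv: float = 0.30
    sparse_fraction: float = 0.05
    sparse_log2fc: float = 1.0
    # raw-feature emission
    mode: str = "NP"
    adducts: Tuple[str, ...] = ("[M+H]+",)
    class_response: float = 1e5
    area_cv: float = 0.10
    is_area_cv: float = 0.05
    ppm_jitter: float = 2.0
    rt_jitter: float = 0.10
    n_decoys: int = 0
    decoy_ppm_offset: float = 50.0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_admission, self.n_recovery) <= 0:
            raise ValueError("group sizes must be positive")
        if any(m <= 0 for m in self.class_multipliers.values()):
            raise ValueError("class multipliers must be positive")
        if self.tg_base_multiplier <= 0 or self.tg_db_multiplier <= 0:
            raise ValueError("TG multipliers must be positive")
        if self.species_cv < 0 or self.area_cv < 0 or self.is_area_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")

    @classmethod
    def monocyte(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Monocyte-like profile: PC/PE/SM and the FA pool down, fully resolved at recovery."""
        base = cls(
            seed=seed,
            roster=dict(MONOCYTE_ROSTER),
            class_multipliers=dict(MONOCYTE_MULTIPLIERS),
            recovery_relax=0.0,
        )
        return replace(base, **overrides) if overrides else base

    @classmethod
    def neutrophil(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Neutrophil-like profile: broad class increases, SM/SPH down,
        saturation-dependent TG pattern, partial resolution at recovery."""
        base = cls(
            seed=seed,
            roster=dict(NEUTROPHIL_ROSTER),
            class_multipliers=dict(NEUTROPHIL_MULTIPLIERS),
            tg_base_multiplier=0.8,
            tg_db_multiplier=1.15,
            recovery_relax=0.5,
        )
        return replace(base, **overrides) if overrides else base

    def null(self) -> "SimConfig":
        """Same cohort with every planted effect removed (complete null)."""
        return replace(
            self,
            class_multipliers={},
            tg_base_multiplier=1.0,
            tg_db_multiplier=1.0,
            sparse_fraction=0.0,
        )


@dataclass
class SimulatedCohort:
    matrix: AbundanceMatrix
    truth: pd.DataFrame  # per species: baseline, multipliers, planted flags
    meta: pd.DataFrame  # sample_id, group, subject_id


@dataclass
class SimulatedFeatureSet:
    features: pd.DataFrame  # mz, rt, polarity, mode, area, sample_id
    cohort: SimulatedCohort
    n_decoys: int


def _admission_multiplier(config: SimConfig, lipid_class: str, n_db: int) -> float:
    if lipid_class == "TG" and (
        config.tg_base_multiplier != 1.0 or config.tg_db_multiplier != 1.0
    ):
        return config.tg_base_multiplier * config.tg_db_multiplier**n_db
    return float(config.class_multipliers.get(lipid_class, 1.0))


def _build_roster(config: SimConfig) -> pd.DataFrame:
    class_defs = load_class_definitions()
    rows = []
    for lipid_class in sorted(config.roster):
        if lipid_class not in class_defs:
            raise ValueError(f"roster class {lipid_class!r} not in class definitions")
        cdef = class_defs[lipid_class]
        c_lo, c_hi, c_step, db_lo, db_hi = config.roster[lipid_class]
        if not (cdef.c_range[0] <= c_lo and c_hi <= cdef.c_range[1]):
            raise ValueError(f"roster carbons for {lipid_class} outside class range")
        for nc in range(c_lo, c_hi + 1, c_step):
            for db in range(db_lo, db_hi + 1):
                rows.append(
                    {
                        "species": species_name(lipid_class, nc, db, "none", cdef.sphingoid),
                        "lipid_class": lipid_class,
                        "n_carbons": nc,
                        "n_double_bonds": db,
                        "tier": cdef.tier,
                    }
                )
    return pd.DataFrame(rows)


def _sample_frame(config: SimConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_control):
        rows.append({"sample_id": f"ctrl_{i + 1:02d}", "group": "control", "subject_id": f"C{i + 1:02d}"})
    for i in range(config.n_admission):
        rows.append(
            {"sample_id": f"adm_{i + 1:02d}", "group": "cap_admission", "subject_id": f"P{i + 1:02d}"}
        )
    # the recovery group resamples the first n_recovery admission subjects
    for i in range(config.n_recovery):
        rows.append(
            {"sample_id": f"rec_{i + 1:02d}", "group": "cap_recovery", "subject_id": f"P{i + 1:02d}"}
        )
    return pd.DataFrame(rows)


def simulate_abundances(config: SimConfig) -> SimulatedCohort:
    """Draw a seeded cohort abundance matrix with planted effects.

    Abundance of species *i* in a sample of group *g* is
    ``exp(mu_i + ln m_ig + sigma * eps)`` with per-species baseline log-mean
    ``mu_i ~ N(0, baseline_log_sd)``, group multiplier ``m_ig`` and
    ``sigma = sqrt(ln(1 + cv^2))``, so the group multiplier scales both the
    median and the mean of the lognormal exactly.
    """
    roster = _build_roster(config)
    meta = _sample_frame(config)
    rng = np.random.default_rng(config.seed)
    n_species = len(roster)

    mu = rng.normal(0.0, config.baseline_log_sd, n_species)
    mult_adm = np.array(
        [
            _admission_multiplier(config, c, d)
            for c, d in zip(roster["lipid_class"], roster["n_double_bonds"])
        ]
    )
    # sparse species-level effects, restricted to classes without a planted shift
    eligible = np.flatnonzero(mult_adm == 1.0)
    n_sparse = int(math.floor(config.sparse_fraction * len(eligible)))
    sparse_idx = rng.choice(eligible, size=n_sparse, replace=False) if n_sparse else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=n_sparse)
    sparse_mult = np.ones(n_species)
    sparse_mult[sparse_idx] = 2.0 ** (signs * config.sparse_log2fc)
    mult_adm = mult_adm * sparse_mult
    mult_rec = mult_adm**config.recovery_relax

    sigma = math.sqrt(math.log(1.0 + config.species_cv**2))
    group_mult = {"control": np.ones(n_species), "cap_admission": mult_adm, "cap_recovery": mult_rec}
    columns = {}
    for _, row in meta.iterrows():
        eps = rng.normal(0.0, 1.0, n_species)
        columns[row["sample_id"]] = np.exp(mu + np.log(group_mult[row["group"]]) + sigma * eps)
    data = pd.DataFrame(columns, index=roster["species"].to_numpy())
    data.index.name = "species"

    species_info = roster.set_index("species")[["lipid_class", "tier"]]
    truth = roster.set_index("species").copy()
    truth["baseline_log_mean"] = mu
    truth["mult_admission"] = mult_adm
    truth["mult_recovery"] = mult_rec
    truth["sparse_effect"] = False
    truth.iloc[sparse_idx, truth.columns.get_loc("sparse_effect")] = True
    truth["planted"] = mult_adm != 1.0
    return SimulatedCohort(AbundanceMatrix(data, species_info), truth, meta)


def class_truth(config: SimConfig) -> pd.DataFrame:
    """Net planted class directions: up, down, mixed (TG saturation) or none.

    Sparse species-level effects are excluded by construction (they are only
    planted in classes without a class-wide shift), so the direction reflects
    the class multiplier alone.
    """
    roster = _build_roster(config)
    rows = []
    for lipid_class, group in roster.groupby("lipid_class"):
        mults = np.array(
            [
                _admission_multiplier(config, lipid_class, d)
                for d in group["n_double_bonds"]
            ]
        )
        if np.all(mults > 1):
            direction = "up"
        elif np.all(mults < 1):
            direction = "down"
        elif np.all(mults == 1):
            direction = "none"
        else:
            direction = "mixed"
        rows.append({"lipid_class": lipid_class, "direction": direction})
    return pd.DataFrame(rows).set_index("lipid_class")


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 (degenerate at cv = 0)."""
    if cv == 0:
        return np.ones(size)
    s = math.sqrt(math.log(1.0 + cv**2))
    return np.exp(rng.normal(0.0, s, size) - s**2 / 2.0)


def simulate_features(config: SimConfig) -> SimulatedFeatureSet:
    """Emit raw MS1 feature tables for a simulated cohort.

    Each roster species yields one feature per configured adduct and sample,
    at the theoretical m/z perturbed by uniform ppm jitter, in the middle of
    its class retention window (plus jitter), with peak area = true abundance
    x class response x multiplicative noise.  Internal-standard peaks are
    emitted per sample with area = spiked amount x class response x noise, so
    the noiseless pipeline is the identity on true abundances.  Optional
    decoy features are placed at least four 5-ppm tolerances away from every
    database ion.
    """
    cohort = simulate_abundances(config)
    class_defs = load_class_definitions()
    database: Dict[str, LipidSpecies] = {}
    for cdef in class_defs.values():
        for sp in expand_class(cdef):
            database[sp.name] = sp
    missing = [s for s in cohort.matrix.data.index if s not in database]
    if missing:
        raise ValueError(f"roster species missing from database: {missing[:5]}...")

    adducts = {a.name: a for a in DEFAULT_ADDUCTS}
    try:
        used_adducts = [adducts[name] for name in config.adducts]
    except KeyError as exc:
        raise ValueError(f"unknown adduct {exc}") from None
    windows = load_rt_windows()
    centers = {
        cls: (w[0] + w[1]) / 2.0 for (cls, _mode), w in windows.items()
    }

    rng = np.random.default_rng(config.seed + 1_000_003)
    rows: List[dict] = []

    def emit(species: LipidSpecies, sample: str, area: float) -> None:
        for add in used_adducts:
            theo = adduct_mz(species.mass, add)
            jitter = rng.uniform(-config.ppm_jitter, config.ppm_jitter) * 1e-6
            rt = centers[species.lipid_class] + rng.uniform(-config.rt_jitter, config.rt_jitter)
            rows.append(
                {
                    "mz": theo * (1.0 + jitter),
                    "rt": rt,
                    "polarity": add.polarity,
                    "mode": config.mode,
                    "area": area,
                    "sample_id": sample,
                    "true_species": species.name,  # ground-truth label, empty for decoys
                }
            )

    is_table = load_internal_standards()
    standards = is_table[is_table["role"] == "class_standard"]
    standards = standards[standards["mode"].isin(("*", config.mode))]

    samples = list(cohort.matrix.data.columns)
    for sample in samples:
        values = cohort.matrix.data[sample]
        noise = _lognormal_noise(rng, config.area_cv, len(values))
        for (species_name_, true_ab), nz in zip(values.items(), noise):
            emit(database[species_name_], sample, float(true_ab) * config.class_response * nz)
        for _, std in standards.iterrows():
            std_species = database[canonical_species_name(std["standard"])]
            nz = _lognormal_noise(rng, config.is_area_cv, 1)[0]
            emit(std_species, sample, float(std["amount_nmol"]) * config.class_response * nz)

    n_placed = 0
    if config.n_decoys > 0:
        all_mz = np.sort(
            np.array(
                [adduct_mz(sp.mass, add) for sp in database.values() for add in DEFAULT_ADDUCTS]
            )
        )
        attempts = 0
        while n_placed < config.n_decoys and attempts < config.n_decoys * 50:
            attempts += 1
            base = float(rng.choice(all_mz))
            sign = rng.choice([-1.0, 1.0])
            mz = base * (1.0 + sign * config.decoy_ppm_offset * 1e-6)
            pos = np.searchsorted(all_mz, mz)
            nearest = min(
                abs(mz - all_mz[j]) / mz * 1e6
                for j in (max(pos - 1, 0), min(pos, len(all_mz) - 1))
            )
            if nearest < 20.0:  # keep decoys >= 4 x the 5 ppm default tolerance
                continue
            rows.append(
                {
                    "mz": mz,
                    "rt": float(rng.uniform(0.0, 16.0)),
                    "polarity": "positive",
                    "mode": config.mode,
                    "area": float(rng.uniform(1e3, 1e5)),
                    "sample_id": samples[int(rng.integers(len(samples)))],
                    "true_species": "",
                }
            )
            n_placed += 1
    features = pd.DataFrame(rows)
    return SimulatedFeatureSet(features, cohort, n_placed)
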