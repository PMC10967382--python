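"""Multi-level differential statistics for lipid abundance matrices.

The same nonparametric machinery is applied at every level of the lipidome:

* species level — two-sided Wilcoxon rank-sum per species with
  Benjamini-Hochberg correction across all primary-tier species of the
  dataset, log2 fold changes, and up/down/unchanged calls (volcano + pie);
* class level — per-participant sums over all species of a class, tested
  class-wide at unadjusted p < 0.05 (secondary-tier species are included
  here, the one analysis tier they are reliable for);
* ordination — PCA on the species-standardized matrix with a rank-sum test
  on the first principal component coordinates;
* saturation — species laid out on a (cumulative chain length x double
  bonds) grid with saturation categories;
* fatty-acid pool — sum of free fatty acid species per sample, plus named
  single species such as arachidonic acid FA(20:4);
* pathway score — per-sample mean of gene-wise z-scores over a gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantification import AbundanceMatrix

__all__ = [
    "GroupDesign",
    "bh_adjust",
    "class_aggregate_test",
    "fatty_acid_pool",
    "pathway_zscore",
    "pca_group_test",
    "rank_sum_test",
    "regulation_fractions",
    "saturation_grid",
    "signed_rank_test",
    "species_differential",
]

logger = logging.getLogger(__name__)

SPECIES_ALPHA = 0.05  # on BH-adjusted p
CLASS_ALPHA = 0.05  # on raw p
_EXACT_MAX_N = 25  # exact rank-sum null up to this combined sample size


@dataclass(frozen=True)
class GroupDesign:
    """Sample-to-group assignment with optional subject pairing.

    ``groups`` maps sample id -> group label; ``subjects`` (optional) maps
    sample id -> subject id, allowing paired admission/recovery comparisons.
    A subject may contribute at most one sample per group.
    """

    groups: pd.Series
    subjects: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.groups.index.has_duplicates:
            dupes = self.groups.index[self.groups.index.duplicated()].tolist()
            raise ValueError(f"samples assigned to more than one group: {dupes}")
        if self.subjects is not None:
            joint = pd.DataFrame({"group": self.groups, "subject": self.subjects}).dropna()
            counts = joint.groupby(["subject", "group"]).size()
            if (counts > 1).any():
                raise ValueError("a subject has more than one sample in the same group")

    @classmethod
    def from_frame(cls, meta: pd.DataFrame) -> "GroupDesign":
        """Build from a metadata table with columns sample_id, group[, subject_id]."""
        meta = meta.set_index("sample_id")
        subjects = meta["subject_id"] if "subject_id" in meta.columns else None
        return cls(groups=meta["group"], subjects=subjects)

    def samples(self, group: str) -> List[str]:
        return list(self.groups.index[self.groups == group])


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution for combined sample sizes up to 25
    when there are no ties, and the normal approximation with continuity
    and tie correction otherwise.  Degenerate all-identical input returns 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= _EXACT_MAX_N and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True).pvalue
    )


def signed_rank_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired test requires equal-length vectors")
    diffs = x - y
    if np.all(diffs == 0):
        return 1.0
    return float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def species_differential(
    matrix: AbundanceMatrix,
    design: GroupDesign,
    case: str,
    ref: str,
    fc_stat: str = "mean",
) -> pd.DataFrame:
    """Per-species differential abundance between two groups.

    Secondary-tier species are excluded (they are class-level only); the BH
    family is all tested species of the dataset.  Fold change is
    log2(case central tendency / reference central tendency), with the mean
    as the default central tendency.  Species whose reference or case
    central tendency is non-positive get an undefined fold change and are
    excluded from volcano classification, with a logged count.

    Returns a DataFrame indexed by species with columns ``log2fc, p, p_adj,
    status`` (status in up/down/unchanged/undefined).
    """
    if fc_stat not in ("mean", "median"):
        raise ValueError("fc_stat must be 'mean' or 'median'")
    prim = matrix.primary()
    n_excluded = len(matrix.data) - len(prim.data)
    if n_excluded:
        logger.info("species_differential: excluded %d secondary-tier species", n_excluded)
    case_samples = [s for s in design.samples(case) if s in prim.data.columns]
    ref_samples = [s for s in design.samples(ref) if s in prim.data.columns]
    if len(case_samples) < 2 or len(ref_samples) < 2:
        raise ValueError("need at least two samples per group")
    center = np.mean if fc_stat == "mean" else np.median

    rows = []
    for species, values in prim.data.iterrows():
        xv = values[case_samples].to_numpy(dtype=float)
        yv = values[ref_samples].to_numpy(dtype=float)
        if np.isnan(xv).any() or np.isnan(yv).any():
            xv = xv[~np.isnan(xv)]
            yv = yv[~np.isnan(yv)]
        if len(xv) < 2 or len(yv) < 2:
            logger.info("species_differential: %s skipped (too few complete cells)", species)
            continue
        c, r = float(center(xv)), float(center(yv))
        log2fc = np.log2(c / r) if (c > 0 and r > 0) else np.nan
        rows.append({"species": species, "log2fc": log2fc, "p": rank_sum_test(xv, yv)})
    results = pd.DataFrame(rows).set_index("species")
    results["p_adj"] = bh_adjust(results["p"].to_numpy())

    def status(row: pd.Series) -> str:
        if np.isnan(row["log2fc"]):
            return "undefined"
        if row["p_adj"] < SPECIES_ALPHA:
            return "up" if row["log2fc"] > 0 else ("down" if row["log2fc"] < 0 else "unchanged")
        return "unchanged"

    results["status"] = results.apply(status, axis=1)
    n_undef = int((results["status"] == "undefined").sum())
    if n_undef:
        logger.info("species_differential: %d species with undefined fold change", n_undef)
    return results


def regulation_fractions(results: pd.DataFrame) -> Dict[str, int]:
    """Integer percentages of up / down / unchanged species, summing to 100.

    Uses the largest-remainder rule so the rounded percentages always sum to
    exactly 100.  Species with undefined fold change are not counted.
    """
    counted = results[results["status"].isin(["up", "down", "unchanged"])]
    if counted.empty:
        raise ValueError("no classified species to summarize")
    n = len(counted)
    raw = {
        key: counted["status"].eq(key).sum() * 100.0 / n for key in ("up", "down", "unchanged")
    }
    floors = {k: int(np.floor(v)) for k, v in raw.items()}
    shortfall = 100 - sum(floors.values())
    by_remainder = sorted(raw, key=lambda k: (raw[k] - floors[k], k), reverse=True)
    for k in by_remainder[:shortfall]:
        floors[k] += 1
    return floors


def class_aggregate_test(
    matrix: AbundanceMatrix,
    design: GroupDesign,
    case: str,
    ref: str,
    paired: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Class-wide differences on per-participant sums over species of a class.

    Both tiers are included: class-level aggregation is the permitted use of
    secondary-tier species.  Unpaired comparisons use the two-sided rank-sum
    test; paired ones (e.g. admission vs recovery within subject) the
    two-sided signed-rank test on subject-matched pairs.  Significance is
    judged at unadjusted p < 0.05; direction is the sign of the difference
    in group medians of the aggregate.

    Returns
    -------
    (summary, aggregates)
        ``summary``: per class ``n_species, p, direction, significant``;
        ``aggregates``: class x samples sums.
    """
    class_of = matrix.species_info["lipid_class"]
    aggregates = matrix.data.groupby(class_of).sum()
    aggregates.index.name = "lipid_class"
    case_samples = [s for s in design.samples(case) if s in aggregates.columns]
    ref_samples = [s for s in design.samples(ref) if s in aggregates.columns]

    rows = []
    for lipid_class, values in aggregates.iterrows():
        n_species = int((class_of == lipid_class).sum())
        if n_species == 0:
            logger.info("class_aggregate_test: class %s has no species, skipped", lipid_class)
            continue
        xv = values[case_samples].to_numpy(dtype=float)
        yv = values[ref_samples].to_numpy(dtype=float)
        if paired:
            if design.subjects is None:
                raise ValueError("paired test requires subject ids in the design")
            subj = design.subjects
            case_by_subj = {subj[s]: values[s] for s in case_samples if s in subj.index}
            ref_by_subj = {subj[s]: values[s] for s in ref_samples if s in subj.index}
            shared = sorted(set(case_by_subj) & set(ref_by_subj))
            if len(shared) < 2:
                logger.info("class_aggregate_test: class %s has <2 pairs, skipped", lipid_class)
                continue
            xv = np.array([case_by_subj[s] for s in shared])
            yv = np.array([ref_by_subj[s] for s in shared])
            p = signed_rank_test(xv, yv)
        else:
            p = rank_sum_test(xv, yv)
        delta = float(np.median(xv) - np.median(yv))
        rows.append(
            {
                "lipid_class": lipid_class,
                "n_species": n_species,
                "p": p,
                "direction": "up" if delta > 0 else ("down" if delta < 0 else "none"),
                "significant": p < CLASS_ALPHA,
            }
        )
    summary = pd.DataFrame(rows).set_index("lipid_class")
    return summary, aggregates


def pca_group_test(
    matrix: AbundanceMatrix, design: GroupDesign, case: str, ref: str
) -> Dict[str, object]:
    """PCA of the species-standardized matrix with a rank-sum test on PC1.

    Species are z-standardized (centered, unit variance) across the samples
    of the two groups before decomposition; zero-variance species are dropped
    with a log entry.  PC1 is oriented so the case-group mean score is at
    least the reference-group mean score.

    Returns a dict with ``scores`` (DataFrame sample x [PC1, PC2, group]),
    ``explained_variance`` (percentages), and ``p_pc1``.
    """
    from sklearn.decomposition import PCA

    samples = [
        s
        for s in matrix.data.columns
        if s in design.groups.index and design.groups[s] in (case, ref)
    ]
    if len(samples) < 3:
        raise ValueError("PCA needs at least three samples")
    sub = matrix.data[samples].dropna(axis=0)
    if len(sub) < 2:
        raise ValueError("PCA needs at least two species with complete data")
    sd = sub.std(axis=1, ddof=1)
    zero_var = sd[sd == 0].index
    if len(zero_var):
        logger.info("pca_group_test: dropped %d zero-variance species", len(zero_var))
        sub = sub.drop(index=zero_var)
        sd = sd.drop(index=zero_var)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    n_comp = min(2, len(samples) - 1, len(z))
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(z.to_numpy().T)
    if n_comp < 2:
        scores = np.column_stack([scores, np.zeros(len(samples))])
    scores_df = pd.DataFrame(scores[:, :2], index=samples, columns=["PC1", "PC2"])
    scores_df["group"] = design.groups[samples].to_numpy()
    case_scores = scores_df.loc[scores_df["group"] == case, "PC1"]
    ref_scores = scores_df.loc[scores_df["group"] == ref, "PC1"]
    if case_scores.mean() < ref_scores.mean():
        scores_df["PC1"] = -scores_df["PC1"]
        case_scores, ref_scores = -case_scores, -ref_scores
    explained = 100.0 * pca.explained_variance_ratio_
    return {
        "scores": scores_df,
        "explained_variance": explained,
        "p_pc1": rank_sum_test(case_scores.to_numpy(), ref_scores.to_numpy()),
    }


def saturation_grid(
    results: pd.DataFrame, species_parser=None
) -> Tuple[pd.DataFrame, List[str]]:
    """Lay differential results out on the (chain length x double bonds) grid.

    Each parseable species yields a cell with cumulative carbon chain
    length, total double bonds, log2 fold change, adjusted p and a
    saturation category: ``saturated`` (0 double bonds), ``monounsaturated``
    (1), ``polyunsaturated-containing`` (2 or more).  A boolean
    ``pufa_guaranteed`` column marks species where the double-bond total
    forces at least one polyunsaturated chain: more than 4 for the
    three-chain TG class, more than 2 for two-chain classes, 2 or more for
    single-chain species.  Unparseable names are returned in a rejects list,
    never dropped silently.
    """
    if species_parser is None:
        from .lipid_model import parse_species_name as species_parser

    cells = []
    rejects: List[str] = []
    for species, row in results.iterrows():
        try:
            cls, nc, db, ether, sph, _ = species_parser(species)
        except ValueError:
            rejects.append(species)
            continue
        if db == 0:
            category = "saturated"
        elif db == 1:
            category = "monounsaturated"
        else:
            category = "polyunsaturated-containing"
        n_chains = {"TG": 3, "MG": 1, "FA": 1, "SPH": 1, "LPC": 1, "LPE": 1, "LPA": 1, "LPG": 1}.get(
            cls, 2
        )
        pufa_guaranteed = db > 4 if n_chains == 3 else (db > 2 if n_chains == 2 else db >= 2)
        cells.append(
            {
                "species": species,
                "lipid_class": cls,
                "carbons": nc,
                "double_bonds": db,
                "log2fc": row.get("log2fc", np.nan),
                "p_adj": row.get("p_adj", np.nan),
                "category": category,
                "pufa_guaranteed": bool(pufa_guaranteed),
            }
        )
    grid = pd.DataFrame(cells)
    if rejects:
        logger.info("saturation_grid: %d unparseable species names", len(rejects))
    return grid, rejects


def fatty_acid_pool(
    matrix: AbundanceMatrix,
    design: GroupDesign,
    case: str,
    ref: str,
    single_species: Optional[str] = None,
    fa_class: str = "FA",
) -> Dict[str, object]:
    """Total free fatty acid pool per sample, with group comparison.

    The pool is the sum of all free fatty acid species per sample.  A named
    single species (e.g. arachidonic acid ``FA(20:4)``) can be extracted and
    tested alongside; requesting an absent species is an error.
    """
    fa_species = matrix.species_info.index[matrix.species_info["lipid_class"] == fa_class]
    if len(fa_species) == 0:
        raise ValueError(f"no species of class {fa_class!r} in the matrix")
    pool = matrix.data.loc[fa_species].sum()
    case_samples = [s for s in design.samples(case) if s in pool.index]
    ref_samples = [s for s in design.samples(ref) if s in pool.index]
    xv, yv = pool[case_samples].to_numpy(), pool[ref_samples].to_numpy()
    out: Dict[str, object] = {
        "pool": pool,
        "pool_p": rank_sum_test(xv, yv),
        "pool_direction": "up" if np.median(xv) > np.median(yv) else "down",
    }
    if single_species is not None:
        if single_species not in matrix.data.index:
            raise KeyError(f"species {single_species!r} not present in the matrix")
        values = matrix.data.loc[single_species]
        sx, sy = values[case_samples].to_numpy(), values[ref_samples].to_numpy()
        out["species"] = single_species
        out["species_values"] = values
        out["species_p"] = rank_sum_test(sx, sy)
        out["species_direction"] = "up" if np.median(sx) > np.median(sy) else "down"
    return out


def pathway_zscore(expr: pd.DataFrame, pathway_genes: Iterable[str]) -> pd.Series:
    """Per-sample pathway score: mean gene-wise z-score over a gene set.

    Each gene is z-scored across samples (sample standard deviation, ddof 1);
    the pathway score of a sample is the mean z over the pathway's genes.
    Genes absent from the matrix or with zero cross-sample variance are
    skipped with a log entry.
    """
    if expr.shape[1] < 2:
        raise ValueError("pathway z-score needs at least two samples")
    genes = list(dict.fromkeys(pathway_genes))
    present = [g for g in genes if g in expr.index]
    missing = sorted(set(genes) - set(present))
    if missing:
        logger.info("pathway_zscore: %d pathway genes absent from matrix", len(missing))
    if not present:
        raise ValueError("no pathway gene present in the expression matrix")
    sub = expr.loc[present]
    sd = sub.std(axis=1, ddof=1)
    usable = sd[sd > 0].index
    if len(usable) < len(present):
        logger.info("pathway_zscore: skipped %d zero-variance genes", len(present) - len(usable))
    if len(usable) == 0:
        raise ValueError("all pathway genes have zero variance")
    sub = sub.loc[usable]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[usable], axis=0)
    return z.mean(axis=0)
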