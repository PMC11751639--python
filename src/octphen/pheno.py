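"""Embedding correlation structure, disease PheWAS, genotype-stratified
thickness difference maps with a dominance index, and inversion genotyping.

The dominance index d = sum(het-ref difference) / sum(hom-ref difference)
over a permutation-masked region summarizes the inheritance mode of a
variant's effect on retinal thickness: d ~ 0.5 additive, ~ 0 recessive,
~ 1 dominant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .simulate import GenotypeBlock, mode_code

__all__ = [
    "CorrelationStructure",
    "PhewasResult",
    "DominanceMap",
    "InversionCall",
    "correlation_structure",
    "phewas_logistic",
    "dominance_map",
    "call_inversion",
]


# --------------------------------------------------------------------------- #
# correlation structure
# --------------------------------------------------------------------------- #


@dataclass
class CorrelationStructure:
    """Direct (value) and genetic (effect-size) embedding correlations with a
    shared leaf order from hierarchical clustering of the direct matrix."""

    direct_r: np.ndarray  # k x k, reordered
    genetic_r: np.ndarray | None  # k x k, same order (may hold NaN)
    order: np.ndarray  # permutation of original embedding indices
    labels: list[str]
    excluded: list[int] = field(default_factory=list)


def correlation_structure(
    embeddings: np.ndarray,
    genetic_r: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> CorrelationStructure:
    """Pearson correlation of embedding values, average-linkage clustering on
    distance 1 - |r|, leaf order applied to both the direct and (optionally)
    the genetic correlation matrix.  Constant columns are excluded with a
    warning.
    """
    x = np.asarray(embeddings, float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 embeddings")
    sd = x.std(axis=0)
    keep = np.flatnonzero(sd > 0)
    excluded = [int(i) for i in np.flatnonzero(sd == 0)]
    if excluded:
        warnings.warn(f"excluding constant embedding column(s) {excluded}")
    x = x[:, keep]
    if labels is None:
        labels = [f"e{i + 1}" for i in range(len(sd))]
    labels = [labels[i] for i in keep]
    r = np.corrcoef(x, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    dist = squareform(1.0 - np.abs(r), checks=False)
    link = hierarchy.linkage(dist, method="average")
    order = np.asarray(hierarchy.leaves_list(link))
    g = None
    if genetic_r is not None:
        g = np.asarray(genetic_r, float)[np.ix_(keep, keep)][np.ix_(order, order)]
    return CorrelationStructure(
        direct_r=r[np.ix_(order, order)],
        genetic_r=g,
        order=keep[order],
        labels=[labels[i] for i in order],
        excluded=excluded,
    )


# --------------------------------------------------------------------------- #
# PheWAS
# --------------------------------------------------------------------------- #


@dataclass
class PhewasResult:
    """Logistic-regression associations of one predictor against disease codes."""

    table: pd.DataFrame  # code, beta, se, p, odds_ratio, n_cases, flagged, significant
    predictor: str
    bonferroni_threshold: float
    min_cases: int
    coding: str = "additive"


_PHEWAS_COVARIATES = ("age", "sex", "height", "weight")


def phewas_logistic(
    predictor: np.ndarray,
    cohort: pd.DataFrame,
    min_cases: int | None = None,
    min_cases_per_subject: float = 1000.0 / 85_000.0,
    coding: str = "additive",
    predictor_name: str = "predictor",
    covariates: tuple[str, ...] = _PHEWAS_COVARIATES,
) -> PhewasResult:
    """Phenome-wide association of one predictor with every outcome code.

    Outcome codes are the 3-character categories found as ``<code>_status``
    columns; only codes with more than ``min_cases`` cases are tested (default
    scales the study's >1000-case rule to the cohort size).  Per code:
    maximum-likelihood logistic regression of case status on the predictor
    plus age, sex, height and weight; the significance threshold is Bonferroni
    over the codes actually tested.  ``coding`` may be ``additive`` (as-is
    dosage) or ``recessive``/``dominant`` for genotype predictors.  Models
    with separation or non-convergence fall back to an L2-penalized fit and
    are flagged.
    """
    x = mode_code(np.asarray(predictor, float), coding) if coding != "additive" else np.asarray(
        predictor, float
    )
    n = len(cohort)
    if min_cases is None:
        min_cases = max(int(round(min_cases_per_subject * n)), 5)
    codes = sorted(c[: -len("_status")] for c in cohort.columns if c.endswith("_status"))
    cov = cohort.loc[:, list(covariates)].to_numpy(float) if covariates else np.empty((n, 0))
    design = np.column_stack([np.ones(n), x, cov])
    rows = []
    for code in codes:
        y = cohort[f"{code}_status"].to_numpy(int)
        n_cases = int(y.sum())
        if n_cases <= min_cases:
            continue
        beta = se = p = np.nan
        flagged = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
                if not fit.mle_retvals.get("converged", False) or not np.isfinite(
                    fit.bse[1]
                ):
                    raise RuntimeError("non-converged")
                beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
            except Exception:
                flagged = True
                try:
                    fit = sm.Logit(y, design).fit_regularized(
                        disp=0, alpha=1.0, L1_wt=0.0, maxiter=500
                    )
                    beta = fit.params[1]
                    se, p = np.nan, np.nan
                except Exception:
                    pass
        rows.append(
            {
                "code": code,
                "beta": beta,
                "se": se,
                "p": p,
                "odds_ratio": np.exp(beta) if np.isfinite(beta) else np.nan,
                "n_cases": n_cases,
                "flagged": flagged,
            }
        )
    table = pd.DataFrame(
        rows, columns=["code", "beta", "se", "p", "odds_ratio", "n_cases", "flagged"]
    )
    thr = 0.05 / len(table) if len(table) else np.nan
    table["significant"] = table["p"] < thr
    return PhewasResult(table, predictor_name, thr, min_cases, coding)


# --------------------------------------------------------------------------- #
# dominance difference maps
# --------------------------------------------------------------------------- #


@dataclass
class DominanceMap:
    """Genotype-stratified mean thickness maps and their differences."""

    mean_ref: np.ndarray
    diff_het: np.ndarray  # mean(het) - mean(ref)
    diff_hom: np.ndarray  # mean(hom) - mean(ref)
    significance_mask: np.ndarray  # pixels where |diff_hom| beats the permutation null
    dominance_index: float  # sum(diff_het)/sum(diff_hom) over the mask; NaN if undefined
    group_sizes: dict[int, int] = field(default_factory=dict)


def dominance_map(
    maps: np.ndarray,
    genotype: np.ndarray,
    min_group: int = 20,
    n_permutations: int = 200,
    seed: int = 0,
    mask_quantile: float = 0.95,
) -> DominanceMap:
    """Compare thickness maps across genotype classes 0/1/2.

    Per-pixel group means give the het-reference and hom-reference difference
    maps; the significance mask keeps pixels where |diff_hom| exceeds the
    ``mask_quantile`` of a genotype-permutation null; the dominance index is
    the ratio of summed differences over that mask (NaN when the hom signal
    vanishes or a genotype class is empty).
    """
    maps = np.asarray(maps, float)
    gt = np.rint(np.asarray(genotype, float)).astype(int)
    groups = {g: np.flatnonzero(gt == g) for g in (0, 1, 2)}
    sizes = {g: len(ix) for g, ix in groups.items()}
    mean_ref = maps[groups[0]].mean(axis=0) if sizes[0] else np.full(maps.shape[1:], np.nan)
    diff_het = (
        maps[groups[1]].mean(axis=0) - mean_ref if sizes[1] else np.full_like(mean_ref, np.nan)
    )
    diff_hom = (
        maps[groups[2]].mean(axis=0) - mean_ref if sizes[2] else np.full_like(mean_ref, np.nan)
    )
    if min(sizes.values()) < min_group:
        warnings.warn(
            f"genotype class sizes {sizes} below min_group={min_group}; "
            "dominance index undefined"
        )
        mask = np.zeros(maps.shape[1:], bool)
        return DominanceMap(mean_ref, diff_het, diff_hom, mask, float("nan"), sizes)

    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations,) + maps.shape[1:])
    for b in range(n_permutations):
        perm = rng.permutation(gt)
        g0 = maps[perm == 0].mean(axis=0)
        g2 = maps[perm == 2].mean(axis=0)
        null[b] = np.abs(g2 - g0)
    thresh = np.quantile(null, mask_quantile, axis=0)
    mask = np.abs(diff_hom) > thresh
    denom = float(diff_hom[mask].sum()) if mask.any() else 0.0
    if abs(denom) < 1e-9:
        d = float("nan")
    else:
        d = float(diff_het[mask].sum()) / denom
    return DominanceMap(mean_ref, diff_het, diff_hom, mask, d, sizes)


# --------------------------------------------------------------------------- #
# inversion genotyping
# --------------------------------------------------------------------------- #


@dataclass
class InversionCall:
    """Per-subject inversion genotype from tagging-allele dosage patterns."""

    classes: np.ndarray  # 0 = ref:ref, 1 = ref:inv, 2 = inv:inv
    inversion_freq: float
    mean_tag_dosage: np.ndarray
    centers: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        n = self.classes.size
        het = int((self.classes == 1).sum())
        hom = int((self.classes == 2).sum())
        expected = (het + 2 * hom) / (2.0 * n)
        if abs(expected - self.inversion_freq) > 1e-9:
            raise ValueError("inversion frequency inconsistent with class counts")


def call_inversion(
    block: GenotypeBlock,
    tag_variants: np.ndarray | list[int],
    max_iter: int = 100,
) -> InversionCall:
    """Classify subjects as ref:ref / ref:inv / inv:inv from tag variants.

    The per-subject mean alternative-allele dosage over the tag variants is
    clustered by 1-D k-means with centers initialized at 0/1/2 (ties assigned
    to the lower class).  If fewer than three classes are occupied the
    clustering is degenerate and fixed thresholds at 0.5/1.5 are used instead.
    """
    tags = np.asarray(tag_variants, int)
    if tags.size < 1:
        raise ValueError("need at least one tag variant")
    score = np.nanmean(block.dosages[:, tags], axis=1)
    centers = np.array([0.0, 1.0, 2.0])
    classes = _assign_lower_tie(score, centers)
    degenerate = False
    for _ in range(max_iter):
        occupied = [k for k in range(3) if np.any(classes == k)]
        if len(occupied) < 3:
            degenerate = True
            break
        new_centers = np.array([score[classes == k].mean() for k in range(3)])
        new_classes = _assign_lower_tie(score, new_centers)
        if np.array_equal(new_classes, classes):
            centers = new_centers
            break
        centers, classes = new_centers, new_classes
    if degenerate:
        warnings.warn("degenerate tag-dosage clustering; using fixed 0.5/1.5 thresholds")
        centers = np.array([0.0, 1.0, 2.0])
        classes = np.digitize(score, [0.5, 1.5])
    freq = float((classes == 1).sum() + 2 * (classes == 2).sum()) / (2.0 * classes.size)
    return InversionCall(classes, freq, score, centers, degenerate)


def _assign_lower_tie(score: np.ndarray, centers: np.ndarray) -> np.ndarray:
    dist = np.abs(score[:, None] - centers[None, :])
    # argmin returns the first (lower) class on exact ties
    return np.argmin(dist, axis=1)
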