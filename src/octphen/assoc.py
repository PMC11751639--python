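"""Genetic association of latent imaging traits.

Variant QC (MAF / Hardy-Weinberg / call-rate / region filters), covariate-
adjusted additive linear GWAS per inverse-rank-normalized trait, genomic
inflation, effect-size genetic correlation, a multi-trait meta-analysis that
combines z-scores across genetically correlated traits by generalized least
squares, stepwise approximate conditional selection of independent lead
variants against an LD reference, Bonferroni significance regimes, and
discovery/replication effect-size concordance.

P-values are two-sided normal on beta/se; -log10 p is carried alongside so
that planted strong effects never underflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeBlock

__all__ = [
    "VariantQCRule",
    "SummaryStats",
    "LocusSet",
    "SignificanceRegime",
    "hwe_exact_test",
    "variant_qc",
    "gwas_linear",
    "genomic_lambda",
    "genetic_correlation",
    "correlated_groups",
    "estimate_null_z_corr",
    "mtag_meta",
    "mtag_analysis",
    "cojo_select",
    "significance_regime",
    "replication_concordance",
    "round_sig",
    "trunc_sig",
]

GENOME_WIDE_ALPHA = 5e-8
_LN10 = math.log(10.0)


def _neglog10_p_from_z(z: np.ndarray) -> np.ndarray:
    """-log10 of the two-sided normal p-value, safe far beyond float underflow."""
    return -(np.log(2.0) + stats.norm.logsf(np.abs(z))) / _LN10


def _p_from_z(z: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, np.finfo(float).tiny, 1.0)


# --------------------------------------------------------------------------- #
# summary statistics container
# --------------------------------------------------------------------------- #


@dataclass
class SummaryStats:
    """Per-variant association records for one trait.

    ``df`` columns: variant_id, chromosome, position, effect_allele,
    other_allele, eaf, beta, se, p, neglog10_p, n.
    """

    df: pd.DataFrame
    trait: str = "trait"
    analysis: str = "gwas"  # gwas | mtag | pca_gwas

    REQUIRED = (
        "variant_id",
        "chromosome",
        "position",
        "effect_allele",
        "other_allele",
        "eaf",
        "beta",
        "se",
        "p",
        "neglog10_p",
        "n",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"summary stats missing columns {missing}")
        d = self.df
        if np.any(d["se"] <= 0):
            raise ValueError("standard errors must be positive")
        if np.any((d["p"] <= 0) | (d["p"] > 1)):
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def z(self) -> np.ndarray:
        return (self.df["beta"] / self.df["se"]).to_numpy()


# --------------------------------------------------------------------------- #
# variant QC
# --------------------------------------------------------------------------- #


@dataclass
class VariantQCRule:
    """Pre-association filters: common variants (MAF >= 5%), gross HWE
    violations removed (P > 1e-15 required), genotyping rate above 99%, and
    optional excluded regions (low-complexity / long-range LD / sex chroms)."""

    maf_min: float = 0.05
    hwe_p_min: float = 1e-15
    call_rate_min: float = 0.99
    exclude_regions: list[tuple[str, int, int]] = field(default_factory=list)


def hwe_exact_test(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact Hardy-Weinberg test P (two-sided, heterozygote-count conditional).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more likely than the observed one.
    """
    n_het, n_hom_rare, n_hom_common = int(n_het), int(n_hom_rare), int(n_hom_common)
    if min(n_het, n_hom_rare, n_hom_common) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_rare, n_hom_common) + n_het
    # heterozygote counts share the parity of the rare-allele count
    h_obs = n_het
    hs = list(range(rare % 2, rare + 1, 2))
    # start at the smallest feasible het count with log-prob 0; recurrence:
    # P(h+2)/P(h) = [rare-h][2n-rare-h] / [(h+2)(h+1)]   (allele bookkeeping)
    logs = [0.0]
    for h_i in hs[:-1]:
        num = (rare - h_i) * (2 * n - rare - h_i)
        den = (h_i + 2.0) * (h_i + 1.0)
        logs.append(logs[-1] + math.log(num / den))
    m = max(logs)
    ws = [math.exp(v - m) for v in logs]
    total = sum(ws)
    probs = {h_i: w / total for h_i, w in zip(hs, ws)}
    p_obs = probs.get(h_obs)
    if p_obs is None:
        raise ValueError("observed het count infeasible for the allele counts")
    p = sum(w for w in probs.values() if w <= p_obs * (1.0 + 1e-12))
    return min(p, 1.0)


def _in_regions(chrom: str, pos: int, regions: list[tuple[str, int, int]]) -> bool:
    return any(str(chrom) == str(c) and s <= pos <= e for c, s, e in regions)


def variant_qc(
    block: GenotypeBlock, rule: VariantQCRule | None = None
) -> tuple[GenotypeBlock, pd.DataFrame]:
    """Apply QC filters; return (filtered block, per-variant report).

    The report lists MAF, HWE exact P, call rate and the first failing rule
    (priority: maf, hwe, call_rate, region) for every variant.
    """
    rule = rule or VariantQCRule()
    d = block.dosages
    n_sub, n_var = d.shape
    call_rate = np.isfinite(d).mean(axis=0)
    freq = block.allele_freqs
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = np.ones(n_var)
    rounded = np.rint(d)
    for j in range(n_var):
        col = rounded[np.isfinite(rounded[:, j]), j]
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        rare, common = (n2, n0) if n2 <= n0 else (n0, n2)
        hwe_p[j] = hwe_exact_test(n1, rare, common)
    reasons = np.array([""] * n_var, dtype=object)
    ok = np.ones(n_var, bool)
    for j in range(n_var):
        if maf[j] < rule.maf_min:
            reasons[j], ok[j] = "maf", False
        elif hwe_p[j] <= rule.hwe_p_min:
            reasons[j], ok[j] = "hwe", False
        elif call_rate[j] < rule.call_rate_min:
            reasons[j], ok[j] = "call_rate", False
        elif _in_regions(block.chromosome[j], int(block.positions[j]), rule.exclude_regions):
            reasons[j], ok[j] = "region", False
    report = pd.DataFrame(
        {
            "variant_id": block.variant_ids,
            "maf": maf,
            "hwe_p": hwe_p,
            "call_rate": call_rate,
            "pass": ok,
            "reason": reasons,
        }
    )
    return block.subset_variants(np.flatnonzero(ok)), report


# --------------------------------------------------------------------------- #
# GWAS
# --------------------------------------------------------------------------- #


def _projector(c: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthonormal basis of the covariate column space (collinearity-safe)."""
    u, s, _ = np.linalg.svd(c, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if rank < c.shape[1]:
        warnings.warn(f"dropping {c.shape[1] - rank} collinear covariate dimension(s)")
    return u[:, :rank], rank


def gwas_linear(
    trait: np.ndarray,
    block: GenotypeBlock,
    covariates: pd.DataFrame | np.ndarray | None,
    trait_id: str = "trait",
    analysis: str = "gwas",
) -> SummaryStats:
    """Additive linear-model association of one normalized trait.

    Per variant: OLS of trait on dosage plus all covariates (intercept always
    included); beta, se and the two-sided normal p-value.  Variants with
    missing dosage are analysed complete-case.
    """
    y = np.asarray(trait, float)
    n = y.size
    if covariates is None:
        c = np.ones((n, 1))
    else:
        cv = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) else np.asarray(
            covariates, float
        )
        c = np.column_stack([np.ones(n), cv])
    if n < c.shape[1] + 2:
        raise ValueError("fewer subjects than covariates + 2")
    q, rank = _projector(c)

    d = block.dosages
    beta = np.zeros(d.shape[1])
    se = np.full(d.shape[1], np.inf)
    ns = np.full(d.shape[1], n)
    y_r = y - q @ (q.T @ y)
    yy = float(y_r @ y_r)
    complete = np.isfinite(d).all(axis=0)
    if complete.any():
        g = d[:, complete]
        g_r = g - q @ (q.T @ g)
        gg = np.einsum("ij,ij->j", g_r, g_r)
        gy = g_r.T @ y_r
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(gg > 0, gy / np.where(gg > 0, gg, 1.0), 0.0)
            rss = yy - b * gy
            dof = n - rank - 1
            sigma2 = np.maximum(rss, 0.0) / max(dof, 1)
            s = np.where(gg > 0, np.sqrt(sigma2 / np.where(gg > 0, gg, 1.0)), np.inf)
        beta[complete] = b
        se[complete] = s
    for j in np.flatnonzero(~complete):
        m = np.isfinite(d[:, j])
        ns[j] = int(m.sum())
        if ns[j] < rank + 2:
            continue
        qm, rm = _projector(c[m])
        ym = y[m] - qm @ (qm.T @ y[m])
        gm = d[m, j] - qm @ (qm.T @ d[m, j])
        gg = float(gm @ gm)
        if gg <= 0:
            continue
        beta[j] = float(gm @ ym) / gg
        rss = float(ym @ ym) - beta[j] ** 2 * gg
        se[j] = math.sqrt(max(rss, 0.0) / max(ns[j] - rm - 1, 1) / gg)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
    se_out = np.where(np.isfinite(se), se, 1e12)  # monomorphic: uninformative
    df = pd.DataFrame(
        {
            "variant_id": block.variant_ids,
            "chromosome": block.chromosome,
            "position": block.positions,
            "effect_allele": block.alt,
            "other_allele": block.ref,
            "eaf": block.allele_freqs,
            "beta": beta,
            "se": se_out,
            "p": _p_from_z(z),
            "neglog10_p": _neglog10_p_from_z(z),
            "n": ns,
        }
    )
    return SummaryStats(df, trait=trait_id, analysis=analysis)


def genomic_lambda(ss: SummaryStats | np.ndarray) -> float:
    """Genomic inflation factor: median chi-square over its null median."""
    chi2 = ss.z**2 if isinstance(ss, SummaryStats) else np.asarray(ss, float)
    if chi2.size < 100:
        raise ValueError("need at least 100 variants for a stable lambda")
    return float(np.median(chi2) / stats.chi2.ppf(0.5, 1))


# --------------------------------------------------------------------------- #
# genetic correlation and multi-trait meta-analysis
# --------------------------------------------------------------------------- #


def _align_effects(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two summary frames on variant, flipping b's beta when its
    effect/other alleles are swapped relative to a; mismatched pairs dropped."""
    m = a.merge(b, on="variant_id", suffixes=("_a", "_b"))
    same = (m["effect_allele_a"] == m["effect_allele_b"]) & (
        m["other_allele_a"] == m["other_allele_b"]
    )
    flipped = (m["effect_allele_a"] == m["other_allele_b"]) & (
        m["other_allele_a"] == m["effect_allele_b"]
    )
    m = m[same | flipped].copy()
    flip = flipped[same | flipped].to_numpy()
    m.loc[flip, "beta_b"] = -m.loc[flip, "beta_b"]
    m.loc[flip, "eaf_b"] = 1.0 - m.loc[flip, "eaf_b"]
    return m


def genetic_correlation(
    ss_a: SummaryStats, ss_b: SummaryStats, p_threshold: float = GENOME_WIDE_ALPHA
) -> float:
    """Pearson r of aligned effect sizes over variants significant in either
    trait.  NaN (flagged) when fewer than 3 shared variants survive."""
    m = _align_effects(ss_a.df, ss_b.df)
    sig = (m["p_a"] < p_threshold) | (m["p_b"] < p_threshold)
    m = m[sig]
    if len(m) < 3:
        warnings.warn("fewer than 3 shared significant variants; genetic r undefined")
        return float("nan")
    return float(np.corrcoef(m["beta_a"], m["beta_b"])[0, 1])


def correlated_groups(r: np.ndarray, threshold: float = 0.9) -> list[list[int]]:
    """Connected components of the |r| > threshold graph (NaN treated as 0)."""
    r = np.nan_to_num(np.asarray(r, float))
    k = r.shape[0]
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            if abs(r[i, j]) > threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values())


def estimate_null_z_corr(zmat: np.ndarray, z_cut: float = 1.96) -> np.ndarray:
    """Null z-score correlation estimated from variants null in every trait
    (all |z| < z_cut); identity fallback when fewer than 30 such variants."""
    zmat = np.asarray(zmat, float)
    nul = np.all(np.abs(zmat) < z_cut, axis=1)
    if nul.sum() < 30:
        warnings.warn("too few null variants to estimate Sigma; using identity")
        return np.eye(zmat.shape[1])
    return np.corrcoef(zmat[nul], rowvar=False)


def mtag_meta(
    zmat: np.ndarray,
    target: int,
    rho: np.ndarray,
    sigma: np.ndarray | None = None,
    ridge: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """GLS z-score combination across a correlated trait group.

    For weight vector w = Sigma^{-1} rho_t (rho_t the target column of the
    group's effect-correlation matrix, Sigma the null z correlation), the
    updated target z is  z_new = (w'z) / sqrt(w' Sigma w); p from the normal.
    A group of size 1 returns its input unchanged.
    """
    zmat = np.atleast_2d(np.asarray(zmat, float))
    t = zmat.shape[1]
    if t == 1:
        z = zmat[:, 0]
        return z, _p_from_z(z)
    if sigma is None:
        sigma = estimate_null_z_corr(zmat)
    rho = np.asarray(rho, float)
    rho_t = rho[:, target]
    try:
        w = np.linalg.solve(sigma, rho_t)
    except np.linalg.LinAlgError:
        warnings.warn("singular null correlation; ridge-regularizing")
        w = np.linalg.solve(sigma + ridge * np.eye(t), rho_t)
    denom = math.sqrt(float(w @ sigma @ w))
    z_new = zmat @ w / denom
    return z_new, _p_from_z(z_new)


def mtag_analysis(
    ss_list: list[SummaryStats],
    r_threshold: float = 0.9,
    sig_threshold: float = GENOME_WIDE_ALPHA,
) -> list[SummaryStats]:
    """Multi-trait meta-analysis of a set of per-trait GWAS.

    Traits are grouped by genetic correlation (connected components at
    |r| > 0.9 of significant-effect correlations); within each group every
    trait is updated by :func:`mtag_meta`.  Updated betas keep the original
    standard errors (beta = z_new * se).
    """
    k = len(ss_list)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r[i, j] = r[j, i] = genetic_correlation(
                    ss_list[i], ss_list[j], p_threshold=sig_threshold
                )
    out: list[SummaryStats] = [None] * k  # type: ignore[list-item]
    for group in correlated_groups(r, r_threshold):
        idx = list(group)
        if len(idx) == 1:
            i = idx[0]
            df = ss_list[i].df.copy()
            out[i] = SummaryStats(df, trait=ss_list[i].trait, analysis="mtag")
            continue
        base = ss_list[idx[0]].df[["variant_id"]]
        for i in idx[1:]:
            base = base.merge(ss_list[i].df[["variant_id"]], on="variant_id")
        vid = base["variant_id"]
        zcols = []
        for i in idx:
            d = ss_list[i].df.set_index("variant_id").loc[vid]
            zcols.append((d["beta"] / d["se"]).to_numpy())
        zmat = np.column_stack(zcols)
        rho = r[np.ix_(idx, idx)]
        np.fill_diagonal(rho, 1.0)
        sigma = estimate_null_z_corr(zmat)
        for t_local, i in enumerate(idx):
            z_new, p_new = mtag_meta(zmat, t_local, rho, sigma)
            d = ss_list[i].df.set_index("variant_id").loc[vid].reset_index()
            d["beta"] = z_new * d["se"]
            d["p"] = p_new
            d["neglog10_p"] = _neglog10_p_from_z(z_new)
            out[i] = SummaryStats(d[list(SummaryStats.REQUIRED)], ss_list[i].trait, "mtag")
    return out


# --------------------------------------------------------------------------- #
# conditional selection (approximate joint analysis)
# --------------------------------------------------------------------------- #


@dataclass
class LocusSet:
    """Conditionally independent lead variants merged into loci."""

    leads: pd.DataFrame  # variant_id, chromosome, position, beta_joint, se_joint,
    # p_joint, neglog10_p_joint, p_marginal, trait, locus
    window_bp: int = 1_000_000

    @property
    def n_loci(self) -> int:
        return int(self.leads["locus"].nunique()) if len(self.leads) else 0


def _mask_distant(r: np.ndarray, chrom: np.ndarray, pos: np.ndarray, max_bp: float) -> np.ndarray:
    """Zero LD between variants on different chromosomes or > max_bp apart."""
    same = chrom[:, None].astype(str) == chrom[None, :].astype(str)
    near = np.abs(pos[:, None] - pos[None, :]) <= max_bp
    out = np.where(same & near, r, 0.0)
    np.fill_diagonal(out, 1.0)
    return out


def assign_loci(chrom: np.ndarray, pos: np.ndarray, window_bp: int = 1_000_000) -> np.ndarray:
    """Greedy 1-D merge: variants within ``window_bp`` on a chromosome share a locus."""
    order = np.lexsort((pos, chrom.astype(str)))
    locus = np.zeros(len(pos), int)
    current = -1
    last_chrom, last_pos = None, None
    for i in order:
        if last_chrom != str(chrom[i]) or pos[i] - last_pos > window_bp:
            current += 1
        locus[i] = current
        last_chrom, last_pos = str(chrom[i]), pos[i]
    return locus


def cojo_select(
    ss: SummaryStats,
    ld: np.ndarray,
    threshold: float,
    max_ld_bp: float = 10e6,
    collinear_r: float = 0.9,
    window_bp: int = 1_000_000,
) -> LocusSet:
    """Stepwise forward selection of conditionally independent variants.

    At each step the variant with the smallest conditional p is added;
    conditional z-scores of the remainder are recomputed from the marginal
    z-scores and the LD reference as
    z_j|S = (z_j - r_jS R_SS^{-1} z_S) / sqrt(1 - r_jS R_SS^{-1} r_Sj).
    Selection stops when no conditional p is below ``threshold``.  Variants on
    different chromosomes or more than 10 Mb apart are treated as unlinked;
    candidates with |r| > 0.9 to a selected variant are skipped (collinearity
    guard).  Joint effects for the selected set come from R_SS^{-1}.
    """
    d = ss.df
    m = len(d)
    z = ss.z
    chrom = d["chromosome"].to_numpy()
    pos = d["position"].to_numpy()
    r = _mask_distant(np.asarray(ld, float), chrom, pos, max_ld_bp)
    if r.shape != (m, m):
        raise ValueError("LD matrix must be square over the summary-stat variants")

    selected: list[int] = []
    skipped = np.zeros(m, bool)
    z_cond = z.copy()
    p_cond_at_selection: dict[int, float] = {}
    while True:
        avail = np.ones(m, bool)
        avail[selected] = False
        avail &= ~skipped
        if not avail.any():
            break
        cand = np.flatnonzero(avail)[np.argmax(np.abs(z_cond[avail]))]
        p_cand = float(_p_from_z(np.array([z_cond[cand]]))[0])
        # underflowed p: compare on the log scale via z
        z_thr = stats.norm.isf(threshold / 2.0)
        if abs(z_cond[cand]) < z_thr:
            break
        selected.append(int(cand))
        p_cond_at_selection[int(cand)] = p_cand
        s = np.array(selected)
        r_ss = r[np.ix_(s, s)]
        r_ss_inv = np.linalg.pinv(r_ss)
        rest = np.flatnonzero(~np.isin(np.arange(m), s))
        a = r[np.ix_(rest, s)]
        skipped[rest[np.any(np.abs(a) > collinear_r, axis=1)]] = True
        proj = a @ r_ss_inv
        var = np.clip(1.0 - np.einsum("ij,ij->i", proj, a), 1e-12, None)
        z_cond[rest] = (z[rest] - proj @ z[s]) / np.sqrt(var)
        z_cond[s] = 0.0

    if not selected:
        empty = pd.DataFrame(
            columns=[
                "variant_id",
                "chromosome",
                "position",
                "beta_joint",
                "se_joint",
                "p_joint",
                "neglog10_p_joint",
                "p_marginal",
                "trait",
                "locus",
            ]
        )
        return LocusSet(empty, window_bp)

    s = np.array(selected)
    r_ss_inv = np.linalg.pinv(r[np.ix_(s, s)])
    # joint effects: rescale marginal betas to the standardized-genotype scale,
    # solve against the LD matrix, rescale back; with zero LD this is the identity
    sd_g = np.sqrt(2.0 * d["eaf"].to_numpy() * (1.0 - d["eaf"].to_numpy()))[s]
    sd_g = np.where(sd_g > 0, sd_g, 1.0)
    b_marg = d["beta"].to_numpy()[s]
    se_marg = d["se"].to_numpy()[s]
    beta_joint = (r_ss_inv @ (b_marg * sd_g)) / sd_g
    se_joint = se_marg * np.sqrt(np.clip(np.diag(r_ss_inv), 1e-12, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z_joint = beta_joint / se_joint
    leads = pd.DataFrame(
        {
            "variant_id": d["variant_id"].to_numpy()[s],
            "chromosome": chrom[s],
            "position": pos[s],
            "beta_joint": beta_joint,
            "se_joint": se_joint,
            "p_joint": _p_from_z(z_joint),
            "neglog10_p_joint": _neglog10_p_from_z(z_joint),
            "p_marginal": d["p"].to_numpy()[s],
            "trait": ss.trait,
        }
    )
    leads["locus"] = assign_loci(leads["chromosome"].to_numpy(), leads["position"].to_numpy(), window_bp)
    return LocusSet(leads.sort_values(["chromosome", "position"]).reset_index(drop=True), window_bp)


# --------------------------------------------------------------------------- #
# significance regimes and replication
# --------------------------------------------------------------------------- #


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    k = sig - 1 - math.floor(math.log10(abs(x)))
    return round(x, k)


def trunc_sig(x: float, sig: int = 2) -> float:
    """Truncate (round toward zero) to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    k = sig - 1 - math.floor(math.log10(abs(x)))
    return math.trunc(x * 10**k) / 10**k


@dataclass
class SignificanceRegime:
    """Computed (never hard-coded) Bonferroni thresholds for the study.

    study_wide = genome_wide / n_analyses (e.g. 64 embeddings + 64 MTAG + 25
    PC traits = 153 analyses); replication = family_alpha / n_discovery_loci.
    """

    genome_wide: float
    study_wide: float
    replication: float | None
    n_analyses: int
    n_discovery_loci: int | None

    def summary(self) -> dict:
        out = {
            "genome_wide": self.genome_wide,
            "study_wide": self.study_wide,
            "study_wide_2sf": round_sig(self.study_wide),
            "study_wide_2sf_trunc": trunc_sig(self.study_wide),
        }
        if self.replication is not None:
            out["replication"] = self.replication
            out["replication_2sf"] = round_sig(self.replication)
        return out


def significance_regime(
    n_analyses: int,
    n_discovery_loci: int | None = None,
    genome_wide: float = GENOME_WIDE_ALPHA,
    replication_family_alpha: float = 0.01,
) -> SignificanceRegime:
    if n_analyses <= 0 or (n_discovery_loci is not None and n_discovery_loci <= 0):
        raise ValueError("test counts must be positive")
    return SignificanceRegime(
        genome_wide=genome_wide,
        study_wide=genome_wide / n_analyses,
        replication=(
            replication_family_alpha / n_discovery_loci if n_discovery_loci else None
        ),
        n_analyses=n_analyses,
        n_discovery_loci=n_discovery_loci,
    )


_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def replication_concordance(
    discovery: SummaryStats,
    replication: SummaryStats,
    lead_variants: list[str] | np.ndarray | None = None,
) -> tuple[pd.DataFrame, float, float, float]:
    """Discovery vs replication effect-size concordance at lead variants.

    Returns (beta-beta table, Pearson r, sign-agreement fraction, binomial
    test p of sign agreement against 0.5).  Strand-ambiguous (A/T, C/G)
    variants and variants absent from the replication set are dropped; the
    table records the drop counts in attrs.
    """
    d = discovery.df
    if lead_variants is not None:
        d = d[d["variant_id"].isin(set(map(str, lead_variants)))]
    n_requested = len(d)
    m = _align_effects(d, replication.df)
    amb = [
        (str(a), str(b)) in _AMBIGUOUS
        for a, b in zip(m["effect_allele_a"], m["other_allele_a"])
    ]
    m = m[~np.asarray(amb, bool)] if len(m) else m
    table = pd.DataFrame(
        {
            "variant_id": m["variant_id"],
            "beta_discovery": m["beta_a"],
            "beta_replication": m["beta_b"],
            "p_discovery": m["p_a"],
            "p_replication": m["p_b"],
        }
    ).reset_index(drop=True)
    table.attrs["n_dropped"] = n_requested - len(table)
    if len(table) < 2:
        return table, float("nan"), float("nan"), float("nan")
    r = float(np.corrcoef(table["beta_discovery"], table["beta_replication"])[0, 1])
    agree = np.sign(table["beta_discovery"]) == np.sign(table["beta_replication"])
    frac = float(agree.mean())
    p = float(stats.binomtest(int(agree.sum()), len(table), 0.5).pvalue)
    return table, r, frac, p
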