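"""Synthetic cohort generator: OCT-like volumes, LD genotypes, covariates, outcomes.

Everything downstream of this module can be validated against the ground truth
it produces: boundary surfaces for the segmentation stage, closed-form
thickness fields for the map stage, per-subject morphology parameters for the
embedding stage, planted genetic effects for the association stage, and a
known proportional-hazards model for the survival stage.

Morphology model
----------------
Retinal thickness over the scanned area is

    t(s, c) = mean_thickness
              - pit_depth * exp(-d(s, c)^2 / (2 pit_width^2))   (foveal pit)
              + tilt * (c - c_mid)                              (linear gradient)
              + texture(s, c)                                   (per-subject bumps)

with ``d`` the distance from the scan centre in column units.  The mid-surface
of the retina is a shallow quadratic bowl in (slice, column); the inner (upper)
and outer (lower) boundaries sit half a thickness above/below it.  A pixel row
``r`` belongs to the retina iff ``upper <= r < lower`` (half-open), so counting
mask rows estimates the continuous thickness without systematic bias.

Genetics
--------
Haplotypes are drawn from per-block AR(1) latent Gaussians thresholded at the
allele-frequency quantile, which yields Hardy-Weinberg genotypes whose LD
decays geometrically with inter-variant distance; blocks are mutually
independent.  Causal variants add to a morphology field under additive
(dosage), dominant (dosage>=1) or recessive (dosage==2) coding.  A structural
inversion is simulated as a latent biallelic haplotype tracked by tag variants
at a configurable r^2.

Outcomes
--------
Exponential baseline hazard with a log-linear predictor over (standardized)
morphology fields and optional covariates; censoring uniform on a window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from ._rand import substream

__all__ = [
    "MorphologyParams",
    "TextureField",
    "ScanGeometry",
    "OCTVolume",
    "GenotypeBlock",
    "BlockSpec",
    "InversionRegion",
    "CausalSpec",
    "OutcomeSpec",
    "SimConfig",
    "SimulatedCohort",
    "thickness_field",
    "surfaces",
    "render_bscan",
    "render_volume",
    "simulate_ld_genotypes",
    "simulate_inversion",
    "simulate_cohort",
]

MODES = ("additive", "dominant", "recessive")


def mode_code(dosage: np.ndarray, mode: str) -> np.ndarray:
    """Genotype coding for an effect mode: dosage, carrier or homozygote indicator."""
    if mode == "additive":
        return np.asarray(dosage, float)
    if mode == "dominant":
        return (np.asarray(dosage) >= 1).astype(float)
    if mode == "recessive":
        return (np.asarray(dosage) >= 2).astype(float)
    raise ValueError(f"unknown effect mode {mode!r}")


# --------------------------------------------------------------------------- #
# morphology / imaging
# --------------------------------------------------------------------------- #


@dataclass
class TextureField:
    """Smooth per-subject idiosyncratic thickness variation (sum of Gaussian bumps)."""

    centers: np.ndarray  # (k, 2) in (slice_frac, col_frac) units on [0, 1]
    widths: np.ndarray  # (k,) in column units
    amps: np.ndarray  # (k,) px

    def evaluate(self, s: np.ndarray, c: np.ndarray, n_slices: int, n_cols: int) -> np.ndarray:
        out = np.zeros(np.broadcast(s, c).shape)
        aspect = n_cols / n_slices  # put slice axis on the column scale
        for (fs, fc), w, a in zip(self.centers, self.widths, self.amps):
            ds = (s - fs * (n_slices - 1)) * aspect
            dc = c - fc * (n_cols - 1)
            out += a * np.exp(-(ds**2 + dc**2) / (2.0 * w**2))
        return out


@dataclass
class MorphologyParams:
    """Per-subject retinal morphology (all lengths in pixels of the B-scan grid)."""

    mean_thickness: float  # global retinal thickness
    pit_depth: float  # central (foveal) depression amplitude
    pit_width: float  # Gaussian sigma of the pit, column units
    tilt: float  # px per column, linear thickness gradient
    noise_sd: float  # speckle intensity SD on the [0, 1] scale
    texture: TextureField | None = None

    def validate(self) -> None:
        if not self.mean_thickness > self.pit_depth >= 0:
            raise ValueError("require mean_thickness > pit_depth >= 0")
        if not self.pit_width > 0:
            raise ValueError("pit_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class ScanGeometry:
    """Raster-scan geometry and surface shape of the rendered volume.

    Defaults mirror a 128-slice macular volume of 650x512-px B-scans.
    """

    n_slices: int = 128
    n_rows: int = 650
    n_cols: int = 512
    center_row_frac: float = 0.45  # mid-surface row at scan centre, fraction of rows
    bowl_depth_frac: float = 0.02  # mid-surface sink toward scan edges, fraction of rows


def thickness_field(params: MorphologyParams, geometry: ScanGeometry) -> np.ndarray:
    """Closed-form ground-truth thickness, shape (n_slices, n_cols), px."""
    g = geometry
    s = np.arange(g.n_slices)[:, None].astype(float)
    c = np.arange(g.n_cols)[None, :].astype(float)
    s_mid, c_mid = (g.n_slices - 1) / 2.0, (g.n_cols - 1) / 2.0
    aspect = g.n_cols / g.n_slices
    d2 = ((s - s_mid) * aspect) ** 2 + (c - c_mid) ** 2
    t = (
        params.mean_thickness
        - params.pit_depth * np.exp(-d2 / (2.0 * params.pit_width**2))
        + params.tilt * (c - c_mid)
    )
    t = np.broadcast_to(t, (g.n_slices, g.n_cols)).copy()
    if params.texture is not None:
        t += params.texture.evaluate(s, c, g.n_slices, g.n_cols)
    return t


def surfaces(params: MorphologyParams, geometry: ScanGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (upper, lower) boundary row coordinates, shape (n_slices, n_cols)."""
    g = geometry
    t = thickness_field(params, g)
    s = np.arange(g.n_slices)[:, None].astype(float)
    c = np.arange(g.n_cols)[None, :].astype(float)
    s_mid, c_mid = (g.n_slices - 1) / 2.0, (g.n_cols - 1) / 2.0
    bowl = geometry.bowl_depth_frac * g.n_rows * (
        ((c - c_mid) / max(c_mid, 1.0)) ** 2 + ((s - s_mid) / max(s_mid, 1.0)) ** 2
    )
    mid = g.center_row_frac * g.n_rows + bowl
    mid = np.broadcast_to(mid, t.shape)
    upper = mid - t / 2.0
    lower = mid + t / 2.0
    return upper, lower


@dataclass
class OCTVolume:
    """Stack of grayscale B-scans with optional ground-truth boundary surfaces."""

    slices: np.ndarray  # (n_slices, n_rows, n_cols) in [0, 1]
    upper_surface: np.ndarray | None = None  # (n_slices, n_cols) row coords
    lower_surface: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.upper_surface is not None and self.lower_surface is not None:
            u, lo = self.upper_surface, self.lower_surface
            if not (np.all(u >= 0) and np.all(u < lo) and np.all(lo < self.slices.shape[1])):
                raise ValueError("boundary surfaces must satisfy 0 <= upper < lower < n_rows")


# intensity bands: vitreous above the retina, the bright retinal band, choroid below
_I_ABOVE, _I_BAND, _I_BELOW = 0.05, 0.75, 0.25


def render_bscan(
    params: MorphologyParams,
    slice_index: int,
    geometry: ScanGeometry,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one B-scan: piecewise-constant bands plus Gaussian speckle.

    Returns (image, upper_row, lower_row) where the surface arrays are the
    ground truth for this slice.  A pixel row r is retina iff upper <= r < lower.
    """
    g = geometry
    upper, lower = surfaces(params, g)
    u, lo = upper[slice_index], lower[slice_index]
    if np.any(u < 0) or np.any(lo > g.n_rows):
        raise ValueError("surfaces out of image bounds; shrink thickness or enlarge n_rows")
    r = np.arange(g.n_rows)[:, None].astype(float)
    img = np.full((g.n_rows, g.n_cols), _I_ABOVE)
    img[r >= lo[None, :]] = _I_BELOW
    img[(r >= u[None, :]) & (r < lo[None, :])] = _I_BAND
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32), u, lo


def render_volume(
    params: MorphologyParams,
    geometry: ScanGeometry,
    rng: np.random.Generator | None = None,
    subject_id: str = "",
) -> OCTVolume:
    """Render all slices of one subject's volume with ground-truth surfaces."""
    g = geometry
    imgs = np.empty((g.n_slices, g.n_rows, g.n_cols), dtype=np.float32)
    upper = np.empty((g.n_slices, g.n_cols))
    lower = np.empty((g.n_slices, g.n_cols))
    for i in range(g.n_slices):
        imgs[i], upper[i], lower[i] = render_bscan(params, i, g, rng)
    return OCTVolume(imgs, upper, lower, subject_id)


# --------------------------------------------------------------------------- #
# genotypes
# --------------------------------------------------------------------------- #


@dataclass
class CausalSpec:
    """A planted genetic effect on a morphology field."""

    variant: int  # column index into the genotype block
    target: str  # MorphologyParams field name
    beta: float  # effect per coding unit, px
    mode: str = "additive"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class BlockSpec:
    """One LD block: variants at ``spacing`` bp whose latent correlation is
    ``ld_decay`` per adjacent pair (so r ~ ld_decay**k at lag k)."""

    n_variants: int
    maf: float | np.ndarray = 0.3
    ld_decay: float = 0.8
    chromosome: str = "1"
    start: int = 1_000_000
    spacing: int = 5_000


@dataclass
class GenotypeBlock:
    """Dosage matrix with positions, alleles and planted-effect bookkeeping."""

    dosages: np.ndarray  # (n_subjects, n_variants) in [0, 2]
    positions: np.ndarray  # 1-based bp
    chromosome: np.ndarray  # per-variant chromosome labels
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    variant_ids: np.ndarray | None = None
    ld_decay: float | None = None
    causal_map: list[CausalSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        n = self.n_variants
        if self.variant_ids is None:
            self.variant_ids = np.array(
                [f"{c}:{p}" for c, p in zip(self.chromosome, self.positions)], dtype=object
            )
        if self.ref is None:
            self.ref = np.full(n, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(n, "G", dtype=object)
        if np.any(self.dosages < 0) or np.any(self.dosages > 2):
            raise ValueError("dosages must lie in [0, 2]")
        for chrom in np.unique(self.chromosome.astype(str)):
            pos = self.positions[self.chromosome.astype(str) == chrom]
            if np.any(np.diff(pos) < 0):
                raise ValueError("variants must be sorted by position within chromosome")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freqs(self) -> np.ndarray:
        """Empirical alternative-allele frequencies (missing-aware)."""
        d = np.ma.masked_invalid(self.dosages)
        return np.asarray(d.mean(axis=0) / 2.0)

    def subset_variants(self, idx: np.ndarray) -> "GenotypeBlock":
        idx = np.asarray(idx)
        return GenotypeBlock(
            self.dosages[:, idx],
            self.positions[idx],
            self.chromosome[idx],
            self.ref[idx],
            self.alt[idx],
            self.variant_ids[idx],
            self.ld_decay,
            [c for c in self.causal_map if c.variant in set(idx.tolist())],
        )


def _ar1_haplotypes(n_hap: int, spec: BlockSpec, rng: np.random.Generator) -> np.ndarray:
    """Binary haplotypes from a thresholded AR(1) latent Gaussian."""
    m = spec.n_variants
    maf = np.broadcast_to(np.asarray(spec.maf, float), (m,))
    if np.any((maf < 0.0) | (maf > 1.0)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    rho = float(spec.ld_decay)
    if not 0.0 <= rho <= 1.0:
        raise ValueError("ld_decay must lie in [0, 1]")
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    innov = rng.standard_normal((n_hap, m))
    sd = np.sqrt(max(1.0 - rho**2, 0.0))
    for j in range(1, m):
        z[:, j] = rho * z[:, j - 1] + sd * innov[:, j]
    thresh = stats.norm.ppf(maf)
    return (z < thresh[None, :]).astype(np.int8)


def simulate_ld_genotypes(
    n_subjects: int,
    blocks: list[BlockSpec],
    seed: int | np.random.Generator,
) -> GenotypeBlock:
    """Draw LD-structured biallelic genotypes; blocks are independent."""
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "genotypes")
    dos, pos, chrom = [], [], []
    for spec in blocks:
        h1 = _ar1_haplotypes(n_subjects, spec, rng)
        h2 = _ar1_haplotypes(n_subjects, spec, rng)
        dos.append((h1 + h2).astype(float))
        pos.append(spec.start + spec.spacing * np.arange(spec.n_variants))
        chrom.extend([spec.chromosome] * spec.n_variants)
    return GenotypeBlock(
        np.concatenate(dos, axis=1),
        np.concatenate(pos),
        np.array(chrom, dtype=object),
        ld_decay=blocks[0].ld_decay if blocks else None,
    )


@dataclass
class InversionRegion:
    """A structural inversion tracked by tag variants at a given haplotype r^2."""

    inversion_dosage: np.ndarray  # (n_subjects,) in {0, 1, 2}
    tags: GenotypeBlock  # tag-variant dosages
    tag_variants: np.ndarray  # indices into ``tags``
    inversion_freq: float
    tag_r2: float


def simulate_inversion(
    n_subjects: int,
    n_tags: int,
    inversion_freq: float,
    tag_r2: float,
    seed: int | np.random.Generator,
    chromosome: str = "17",
    start: int = 43_000_000,
    spacing: int = 20_000,
) -> InversionRegion:
    """Simulate an inversion haplotype and tag variants tracking it.

    Each tag haplotype allele copies the inversion allele with probability
    q = sqrt(tag_r2) and is otherwise an independent Bernoulli(freq) draw,
    giving haplotype-level correlation q and hence r^2 = tag_r2.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "inversion")
    p = float(inversion_freq)
    q = float(np.sqrt(tag_r2))
    inv_h = rng.random((n_subjects, 2)) < p  # inversion allele per haplotype
    tag_dos = np.empty((n_subjects, n_tags))
    for j in range(n_tags):
        copy = rng.random((n_subjects, 2)) < q
        indep = rng.random((n_subjects, 2)) < p
        tag_h = np.where(copy, inv_h, indep)
        tag_dos[:, j] = tag_h.sum(axis=1)
    tags = GenotypeBlock(
        tag_dos,
        start + spacing * np.arange(n_tags),
        np.array([chromosome] * n_tags, dtype=object),
    )
    return InversionRegion(
        inversion_dosage=inv_h.sum(axis=1).astype(float),
        tags=tags,
        tag_variants=np.arange(n_tags),
        inversion_freq=p,
        tag_r2=float(tag_r2),
    )


# --------------------------------------------------------------------------- #
# cohort
# --------------------------------------------------------------------------- #


@dataclass
class OutcomeSpec:
    """Exponential-hazard time-to-event outcome loading on morphology fields."""

    code: str  # 3-character ICD10-style category, e.g. "H40"
    baseline_hazard: float = 2e-4  # events per day at the reference morphology
    loadings: dict[str, float] = field(default_factory=dict)  # field -> log-HR per SD
    age_loghr: float = 0.0  # log-HR per 10 years of age
    censor_window: float = 3650.0  # uniform censoring on (0, window] days


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults chosen to emulate a
    macular OCT cohort: thickness ~220 px with ~15 px between-subject SD, a
    60-px foveal pit, mild speckle, common variants (MAF >= 5%) in LD blocks,
    and a 0.22-frequency inversion."""

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    # population morphology means and between-subject SDs (px)
    mean_thickness: float = 220.0
    mean_thickness_sd: float = 15.0
    pit_depth: float = 60.0
    pit_depth_sd: float = 8.0
    pit_width_frac: float = 0.12  # sigma of the pit as a fraction of n_cols
    pit_width_sd_frac: float = 0.015
    tilt: float = 0.0
    tilt_sd: float = 0.01
    noise_sd: float = 0.05
    # idiosyncratic smooth texture (keeps the map ensemble high-dimensional)
    texture_bumps: int = 24
    texture_amp: float = 4.0
    texture_width_frac: tuple[float, float] = (0.05, 0.25)
    # covariate effects on mean_thickness (px per unit)
    age_effect: float = -0.3  # per year over age 55
    sex_effect: float = 3.0
    refraction_effect: float = 0.8  # per diopter
    # genetics
    blocks: list[BlockSpec] = field(default_factory=list)
    causal_map: list[CausalSpec] = field(default_factory=list)
    inversion_freq: float = 0.22
    inversion_tags: int = 8
    inversion_tag_r2: float = 1.0
    inversion_effect: CausalSpec | None = None  # variant index ignored
    # outcomes
    outcomes: list[OutcomeSpec] = field(default_factory=list)
    n_genetic_pcs: int = 20

    def scaled_pit_width(self) -> float:
        return self.pit_width_frac * self.geometry.n_cols


@dataclass
class SimulatedCohort:
    """Bundle of everything the generator knows about one synthetic study."""

    params: list[MorphologyParams]
    morphology: pd.DataFrame  # numeric ground-truth fields per subject
    genotypes: GenotypeBlock
    inversion: InversionRegion
    cohort: pd.DataFrame  # covariates + outcome status/time columns
    volumes: list[OCTVolume] | None
    config: SimConfig
    seed: int

    @property
    def subject_ids(self) -> list[str]:
        return list(self.cohort["subject_id"])

    def thickness_fields(self) -> np.ndarray:
        """Closed-form ground-truth thickness maps, (n_subjects, n_slices, n_cols)."""
        return np.stack([thickness_field(p, self.config.geometry) for p in self.params])

    def render_subject(self, i: int, rng: np.random.Generator | None = None) -> OCTVolume:
        if rng is None:
            rng = substream(self.seed, f"render:{i}")
        return render_volume(self.params[i], self.config.geometry, rng, self.subject_ids[i])


_MORPH_FIELDS = ("mean_thickness", "pit_depth", "pit_width", "tilt")


def default_blocks(n_variants: int, n_blocks: int = 10, ld_decay: float = 0.8) -> list[BlockSpec]:
    """Partition ``n_variants`` into independent equally sized LD blocks spread
    over chromosomes, MAF drawn per block from the common range [0.1, 0.5]."""
    sizes = np.full(n_blocks, n_variants // n_blocks)
    sizes[: n_variants % n_blocks] += 1
    blocks = []
    for b, size in enumerate(sizes):
        if size == 0:
            continue
        blocks.append(
            BlockSpec(
                n_variants=int(size),
                maf=0.1 + 0.4 * ((b * 7919) % 97) / 96.0,  # deterministic spread
                ld_decay=ld_decay,
                chromosome=str(b % 22 + 1),
                start=1_000_000 + 20_000_000 * (b // 22),
            )
        )
    return blocks


def simulate_cohort(
    n_subjects: int,
    n_variants: int,
    seed: int,
    config: SimConfig | None = None,
    render_volumes: bool = True,
) -> SimulatedCohort:
    """Simulate a full study cohort; deterministic given ``seed``.

    Per-subject morphology = population baseline + covariate effects +
    mode-coded genotype effects + Gaussian between-subject noise; outcomes are
    drawn from a proportional-hazards model over morphology fields; volumes are
    rendered from the morphology (skip with ``render_volumes=False`` for
    genetics-scale cohorts).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    cfg = config if config is not None else SimConfig()
    if not cfg.blocks:
        cfg = dataclasses.replace(cfg, blocks=default_blocks(n_variants))
    g = cfg.geometry

    # covariates ----------------------------------------------------------- #
    rng = substream(seed, "covariates")
    age = rng.uniform(40.0, 70.0, n_subjects)
    sex = rng.integers(0, 2, n_subjects).astype(int)
    height = np.where(sex == 1, 175.0, 162.0) + rng.normal(0.0, 7.0, n_subjects)
    weight = 27.0 * (height / 100.0) ** 2 + rng.normal(0.0, 8.0, n_subjects)
    refraction = rng.normal(-0.5, 2.0, n_subjects)
    pcs = rng.normal(0.0, 1.0, (n_subjects, cfg.n_genetic_pcs))

    # genetics -------------------------------------------------------------- #
    geno = simulate_ld_genotypes(n_subjects, cfg.blocks, substream(seed, "genotypes"))
    geno.causal_map = list(cfg.causal_map)
    if geno.n_variants != n_variants:
        raise ValueError("block sizes must sum to n_variants")
    inversion = simulate_inversion(
        n_subjects,
        cfg.inversion_tags,
        cfg.inversion_freq,
        cfg.inversion_tag_r2,
        substream(seed, "inversion"),
    )

    # morphology ------------------------------------------------------------ #
    rng_m = substream(seed, "morphology")
    scale = g.n_rows / 650.0  # keep default px values meaningful at desk scale
    base = {
        "mean_thickness": cfg.mean_thickness * scale,
        "pit_depth": cfg.pit_depth * scale,
        "pit_width": cfg.scaled_pit_width(),
        "tilt": cfg.tilt,
    }
    sds = {
        "mean_thickness": cfg.mean_thickness_sd * scale,
        "pit_depth": cfg.pit_depth_sd * scale,
        "pit_width": cfg.pit_width_sd_frac * g.n_cols,
        "tilt": cfg.tilt_sd,
    }
    morph = {f: base[f] + sds[f] * rng_m.standard_normal(n_subjects) for f in _MORPH_FIELDS}
    morph["mean_thickness"] += (
        cfg.age_effect * (age - 55.0) * scale
        + cfg.sex_effect * sex * scale
        + cfg.refraction_effect * refraction * scale
    )
    for spec in cfg.causal_map:
        if spec.target not in morph:
            raise ValueError(f"unknown morphology target {spec.target!r}")
        morph[spec.target] = morph[spec.target] + spec.beta * mode_code(
            geno.dosages[:, spec.variant], spec.mode
        )
    if cfg.inversion_effect is not None:
        eff = cfg.inversion_effect
        morph[eff.target] = morph[eff.target] + eff.beta * mode_code(
            inversion.inversion_dosage, eff.mode
        )
    morph["pit_width"] = np.maximum(morph["pit_width"], 2.0)
    morph["pit_depth"] = np.maximum(morph["pit_depth"], 0.0)

    rng_t = substream(seed, "texture")
    params: list[MorphologyParams] = []
    lo_w = cfg.texture_width_frac[0] * g.n_cols
    hi_w = cfg.texture_width_frac[1] * g.n_cols
    for i in range(n_subjects):
        tex = None
        if cfg.texture_bumps > 0 and cfg.texture_amp > 0:
            tex = TextureField(
                centers=rng_t.random((cfg.texture_bumps, 2)),
                widths=rng_t.uniform(lo_w, hi_w, cfg.texture_bumps),
                amps=rng_t.normal(0.0, cfg.texture_amp * scale, cfg.texture_bumps),
            )
        mt = float(morph["mean_thickness"][i])
        if mt <= 0:
            raise ValueError(
                f"subject {i}: planted effects make thickness non-positive ({mt:.2f} px)"
            )
        p = MorphologyParams(
            mean_thickness=mt,
            pit_depth=float(min(morph["pit_depth"][i], 0.95 * mt)),
            pit_width=float(morph["pit_width"][i]),
            tilt=float(morph["tilt"][i]),
            noise_sd=cfg.noise_sd,
            texture=tex,
        )
        p.validate()
        params.append(p)
    _check_positive_thickness(params, g)

    morph_df = pd.DataFrame(
        {f: [getattr(p, f) for p in params] for f in _MORPH_FIELDS},
        index=pd.RangeIndex(n_subjects),
    )

    # outcomes --------------------------------------------------------------- #
    rng_o = substream(seed, "outcomes")
    subject_id = np.array([f"S{i:06d}" for i in range(n_subjects)], dtype=object)
    cohort = pd.DataFrame(
        {
            "subject_id": subject_id,
            "age": age,
            "sex": sex,
            "height": height,
            "weight": weight,
            "refraction": refraction,
        }
    )
    for k in range(cfg.n_genetic_pcs):
        cohort[f"pc{k + 1}"] = pcs[:, k]
    for spec in cfg.outcomes:
        lp = np.zeros(n_subjects)
        for fname, coef in spec.loadings.items():
            col = morph_df[fname].to_numpy()
            sd = col.std()
            lp += coef * (col - col.mean()) / (sd if sd > 0 else 1.0)
        lp += spec.age_loghr * (age - 55.0) / 10.0
        hazard = spec.baseline_hazard * np.exp(lp)
        event_time = rng_o.exponential(1.0 / hazard)
        censor_time = rng_o.uniform(0.0, spec.censor_window, n_subjects)
        status = (event_time <= censor_time).astype(int)
        time = np.minimum(event_time, censor_time)
        cohort[f"{spec.code}_status"] = status
        cohort[f"{spec.code}_time"] = np.maximum(time, 1e-6)

    volumes = None
    if render_volumes:
        volumes = [
            render_volume(params[i], g, substream(seed, f"render:{i}"), str(subject_id[i]))
            for i in range(n_subjects)
        ]

    return SimulatedCohort(params, morph_df, geno, inversion, cohort, volumes, cfg, seed)


def _check_positive_thickness(params: list[MorphologyParams], g: ScanGeometry) -> None:
    """Reject configs whose planted effects push thickness non-positive
    (checked on a subsampled grid; the fields are smooth)."""
    s = np.arange(0, g.n_slices, max(g.n_slices // 32, 1))[:, None].astype(float)
    c = np.arange(0, g.n_cols, max(g.n_cols // 64, 1))[None, :].astype(float)
    s_mid, c_mid = (g.n_slices - 1) / 2.0, (g.n_cols - 1) / 2.0
    aspect = g.n_cols / g.n_slices
    d2 = ((s - s_mid) * aspect) ** 2 + (c - c_mid) ** 2
    for i, p in enumerate(params):
        t = p.mean_thickness - p.pit_depth * np.exp(-d2 / (2.0 * p.pit_width**2)) + p.tilt * (
            c - c_mid
        )
        t = np.broadcast_to(t, d2.shape).copy()
        if p.texture is not None:
            t += p.texture.evaluate(s, c, g.n_slices, g.n_cols)
        if t.min() <= 0:
            raise ValueError(
                f"subject {i}: thickness field non-positive (min {t.min():.2f} px); "
                "reduce planted effects or pit depth"
            )
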