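"""Readers and writers for the pipeline's on-disk formats.

Genomic coordinates are 1-based inclusive (VCF convention); image coordinates
are 0-based with row 0 superior.  Volumes travel as per-subject directories of
PNG slices or as ``.npz`` archives; genotypes as uncompressed VCF (GT:DS) or a
subjects x variants dosage TSV; summary statistics as a GWAS-SSF-like TSV;
thickness maps as 16-bit PNG (value = px * 100) plus a float archive.
P-values of exactly 0 are rejected on read — underflow must be carried as
-log10 p instead.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .latent import AutoencoderConfig, EmbeddingMatrix
from .simulate import GenotypeBlock, OCTVolume
from .thickness import ThicknessMap

__all__ = [
    "write_volume_png",
    "read_volume_png",
    "write_surfaces_tsv",
    "read_surfaces_tsv",
    "write_thickness_map",
    "read_thickness_map",
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "write_summary_stats",
    "read_summary_stats",
    "write_embeddings_tsv",
    "read_embeddings_tsv",
    "write_ld_reference",
    "read_ld_reference",
    "write_provenance",
]


# --------------------------------------------------------------------------- #
# volumes and maps
# --------------------------------------------------------------------------- #


def write_volume_png(volume: OCTVolume, out_dir: str | Path) -> Path:
    """One 8-bit grayscale PNG per slice (sortable names) + surfaces TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, sl in enumerate(volume.slices):
        img = Image.fromarray((np.clip(sl, 0, 1) * 255).astype(np.uint8), mode="L")
        img.save(out / f"slice_{i:04d}.png")
    if volume.upper_surface is not None:
        write_surfaces_tsv(volume.upper_surface, volume.lower_surface, out / "surfaces.tsv")
    return out


def read_volume_png(in_dir: str | Path, subject_id: str = "") -> OCTVolume:
    in_dir = Path(in_dir)
    files = sorted(in_dir.glob("slice_*.png"))
    if not files:
        raise FileNotFoundError(f"no slice_*.png files in {in_dir}")
    slices = np.stack([np.asarray(Image.open(f), float) / 255.0 for f in files])
    upper = lower = None
    surf = in_dir / "surfaces.tsv"
    if surf.exists():
        upper, lower = read_surfaces_tsv(surf)
    return OCTVolume(slices.astype(np.float32), upper, lower, subject_id or in_dir.name)


def write_surfaces_tsv(upper: np.ndarray, lower: np.ndarray, path: str | Path) -> None:
    n_slices, n_cols = upper.shape
    s, c = np.meshgrid(np.arange(n_slices), np.arange(n_cols), indexing="ij")
    pd.DataFrame(
        {
            "slice": s.ravel(),
            "column": c.ravel(),
            "upper_row": upper.ravel(),
            "lower_row": lower.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def read_surfaces_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    n_slices = int(df["slice"].max()) + 1
    n_cols = int(df["column"].max()) + 1
    upper = df["upper_row"].to_numpy().reshape(n_slices, n_cols)
    lower = df["lower_row"].to_numpy().reshape(n_slices, n_cols)
    return upper, lower


def write_thickness_map(tmap: ThicknessMap, base: str | Path) -> None:
    """``<base>.png`` (16-bit, value = px * 100), ``<base>.npz`` (float) and
    ``<base>.qc.tsv``."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    png = np.clip(np.rint(tmap.map * 100.0), 0, 65535).astype(np.uint16)
    Image.fromarray(png, mode="I;16").save(base.with_suffix(".png"))
    np.savez(base.with_suffix(".npz"), map=tmap.map, subject_id=tmap.subject_id, eye=tmap.eye)
    pd.DataFrame([tmap.qc_metrics]).to_csv(base.with_suffix(".qc.tsv"), sep="\t", index=False)


def read_thickness_map(base: str | Path) -> ThicknessMap:
    base = Path(base)
    with np.load(base.with_suffix(".npz"), allow_pickle=False) as z:
        m = z["map"]
        sid = str(z["subject_id"])
        eye = str(z["eye"])
    qc_path = base.with_suffix(".qc.tsv")
    qc = pd.read_csv(qc_path, sep="\t").iloc[0].to_dict() if qc_path.exists() else {}
    return ThicknessMap(m, sid, eye, qc)


# --------------------------------------------------------------------------- #
# genotypes
# --------------------------------------------------------------------------- #


def write_vcf(block: GenotypeBlock, path: str | Path, sample_ids: list[str] | None = None) -> None:
    """Uncompressed VCF with GT (rounded dosage) and DS (dosage) per sample."""
    n, m = block.dosages.shape
    if sample_ids is None:
        sample_ids = [f"S{i:06d}" for i in range(n)]
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(block.chromosome.astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for j in range(m):
            col = block.dosages[:, j]
            fields = []
            for v in col:
                if np.isnan(v):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_codes[int(round(v))]}:{v:.3f}")
            fh.write(
                f"{block.chromosome[j]}\t{block.positions[j]}\t{block.variant_ids[j]}\t"
                f"{block.ref[j]}\t{block.alt[j]}\t.\t.\t.\tGT:DS\t" + "\t".join(fields) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeBlock:
    """Read dosages from DS (fallback: GT allele count) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    dosages, positions, chroms, refs, alts, vids = [], [], [], [], [], []
    for line_no, var in enumerate(vcf, start=1):
        try:
            ds = var.format("DS")
            if ds is not None:
                col = np.asarray(ds, float).reshape(-1)
            else:
                gt = np.asarray(var.genotype.array())[:, :2]
                col = np.where((gt < 0).any(axis=1), np.nan, gt.clip(0).sum(axis=1)).astype(float)
        except Exception as exc:  # pragma: no cover - malformed input
            raise ValueError(f"malformed VCF record at data line {line_no}: {exc}") from exc
        dosages.append(col)
        positions.append(var.POS)
        chroms.append(var.CHROM)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        vids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
    return GenotypeBlock(
        np.column_stack(dosages),
        np.array(positions),
        np.array(chroms, dtype=object),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        np.array(vids, dtype=object),
    )


def write_dosage_tsv(block: GenotypeBlock, path: str | Path, sample_ids=None) -> None:
    """Documented dialect: first columns variant_id/chromosome/position/ref/alt,
    then one column per subject holding the alternative-allele dosage."""
    n = block.n_subjects
    if sample_ids is None:
        sample_ids = [f"S{i:06d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "variant_id": block.variant_ids,
            "chromosome": block.chromosome,
            "position": block.positions,
            "ref": block.ref,
            "alt": block.alt,
        }
    )
    dos = pd.DataFrame(block.dosages.T, columns=sample_ids)
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_dosage_tsv(path: str | Path) -> GenotypeBlock:
    df = pd.read_csv(path, sep="\t")
    meta = ["variant_id", "chromosome", "position", "ref", "alt"]
    samples = [c for c in df.columns if c not in meta]
    return GenotypeBlock(
        df[samples].to_numpy(float).T,
        df["position"].to_numpy(),
        df["chromosome"].astype(str).to_numpy(dtype=object),
        df["ref"].astype(str).to_numpy(dtype=object),
        df["alt"].astype(str).to_numpy(dtype=object),
        df["variant_id"].astype(str).to_numpy(dtype=object),
    )


# --------------------------------------------------------------------------- #
# tables
# --------------------------------------------------------------------------- #

_COHORT_DICTIONARY = {
    "subject_id": "unique subject identifier",
    "age": "age at scan, years",
    "sex": "0 = female, 1 = male",
    "height": "standing height, cm",
    "weight": "body weight, kg",
    "refraction": "spherical equivalent refraction, diopters",
    "pc*": "genetic principal components (simulated)",
    "<code>_status": "1 = diagnosis of ICD10 category <code> after the scan",
    "<code>_time": "days from scan to diagnosis or censoring",
}


def write_cohort_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)
    dict_path = Path(path).with_suffix(".dictionary.tsv")
    pd.DataFrame(
        {"column": list(_COHORT_DICTIONARY), "description": list(_COHORT_DICTIONARY.values())}
    ).to_csv(dict_path, sep="\t", index=False)


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


_SSF_COLUMNS = {
    "chromosome": "chromosome",
    "position": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "standard_error",
    "p": "p_value",
    "neglog10_p": "neg_log10_p_value",
    "eaf": "effect_allele_frequency",
    "n": "n",
    "variant_id": "variant_id",
}


def write_summary_stats(ss, path: str | Path) -> None:
    from .assoc import SummaryStats

    assert isinstance(ss, SummaryStats)
    df = ss.df.rename(columns=_SSF_COLUMNS)
    df.insert(0, "trait", ss.trait)
    df.insert(1, "analysis", ss.analysis)
    df.to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path):
    from .assoc import SummaryStats

    df = pd.read_csv(path, sep="\t")
    inv = {v: k for k, v in _SSF_COLUMNS.items()}
    df = df.rename(columns=inv)
    if np.any(df["p"] <= 0):
        bad = int(np.flatnonzero(df["p"] <= 0)[0]) + 2  # header is line 1
        raise ValueError(
            f"p_value <= 0 at line {bad}: store underflowing p as neg_log10_p_value instead"
        )
    trait = str(df["trait"].iloc[0]) if "trait" in df else "trait"
    analysis = str(df["analysis"].iloc[0]) if "analysis" in df else "gwas"
    cols = [c for c in SummaryStats.REQUIRED]
    return SummaryStats(df[cols].copy(), trait=trait, analysis=analysis)


def write_embeddings_tsv(emb: EmbeddingMatrix, path: str | Path) -> None:
    df = pd.DataFrame(emb.values, columns=emb.feature_ids)
    df.insert(0, "subject_id", emb.subject_ids or range(len(df)))
    df.to_csv(path, sep="\t", index=False)
    sidecar = Path(path).with_suffix(".config.json")
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(emb.config).items()
    }
    cfg["reconstruction_mse_train"] = emb.reconstruction_mse_train
    cfg["reconstruction_mse_test"] = emb.reconstruction_mse_test
    sidecar.write_text(json.dumps(cfg, indent=1))


def read_embeddings_tsv(path: str | Path) -> EmbeddingMatrix:
    df = pd.read_csv(path, sep="\t")
    sidecar = Path(path).with_suffix(".config.json")
    mse_tr = mse_te = float("nan")
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        mse_tr = raw.pop("reconstruction_mse_train", float("nan"))
        mse_te = raw.pop("reconstruction_mse_test", float("nan"))
        raw["input_shape"] = tuple(raw["input_shape"])
        cfg = AutoencoderConfig(**raw)
    else:
        cfg = AutoencoderConfig(bottleneck=df.shape[1] - 1, n_train=1, n_test=0)
    feats = [c for c in df.columns if c != "subject_id"]
    return EmbeddingMatrix(
        df[feats].to_numpy(float), feats, cfg, mse_tr, mse_te, list(df["subject_id"].astype(str))
    )


def write_ld_reference(r: np.ndarray, block: GenotypeBlock, base: str | Path) -> None:
    base = Path(base)
    np.savez(base.with_suffix(".npz"), r=r)
    pd.DataFrame(
        {
            "variant_id": block.variant_ids,
            "chromosome": block.chromosome,
            "position": block.positions,
        }
    ).to_csv(base.with_suffix(".variants.tsv"), sep="\t", index=False)


def read_ld_reference(base: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    base = Path(base)
    with np.load(base.with_suffix(".npz")) as z:
        r = z["r"]
    idx = pd.read_csv(base.with_suffix(".variants.tsv"), sep="\t")
    return r, idx


def write_provenance(path: str | Path, stage: str, seed: int, config_text: str) -> None:
    """Stamp every stage output with the resolved config hash and seed."""
    h = hashlib.sha256(config_text.encode()).hexdigest()[:16]
    from . import __version__

    Path(path).write_text(
        json.dumps({"stage": stage, "seed": seed, "config_sha256": h, "version": __version__})
    )
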