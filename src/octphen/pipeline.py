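"""End-to-end orchestration: simulate -> segment -> embed -> gwas -> mtag ->
cojo -> replicate -> phewas -> dominance -> survive.

Each stage reads its inputs from, and writes its outputs to, plain files in
the run directory, so a rerun resumes from whatever artifacts already exist
(a stage is skipped when its ``.done`` marker is present).  Every stage output
directory carries a provenance stamp (stage, seed, resolved-config hash); the
resolved config itself is written next to the outputs at the start of the run.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, fileio, latent, pheno, survival as surv, thickness, unet
from ._rand import substream
from .config import PipelineConfig
from .simulate import simulate_cohort

__all__ = ["run_pipeline"]

log = logging.getLogger("octphen.pipeline")

STAGES = (
    "simulate",
    "segment",
    "embed",
    "gwas",
    "mtag",
    "cojo",
    "replicate",
    "phewas",
    "dominance",
    "survive",
)


class _Run:
    def __init__(self, config: PipelineConfig, out_dir: Path):
        self.cfg = config
        self.out = out_dir
        self.cfg_text = config.to_yaml()

    def stage_dir(self, name: str) -> Path:
        d = self.out / name
        d.mkdir(parents=True, exist_ok=True)
        return d

    def done(self, name: str) -> bool:
        return (self.out / name / ".done").exists()

    def mark_done(self, name: str) -> None:
        fileio.write_provenance(
            self.out / name / "provenance.json", name, self.cfg.seed, self.cfg_text
        )
        (self.out / name / ".done").write_text("ok")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages in order; returns the run directory.

    Any stage failure propagates with the stage name in the log and all
    artifacts of completed stages preserved on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = _Run(config, out)
    config.to_yaml(out / "config.resolved.yaml")
    state: dict = {}
    for name in STAGES:
        fn = globals()[f"_stage_{name}"]
        if run.done(name):
            log.info("stage %s: cached, skipping", name)
            continue
        log.info("stage %s: running (seed %d)", name, config.seed)
        try:
            fn(run, state)
        except Exception:
            log.error("stage %s failed; artifacts up to this stage are preserved", name)
            raise
        run.mark_done(name)
    return out


# --------------------------------------------------------------------------- #
# stage implementations (file-schema contracts; each is independently rerunnable)
# --------------------------------------------------------------------------- #


def _load_cohort(run: _Run):
    if "cohort" not in _cache(run):
        c = simulate_cohort(
            run.cfg.n_subjects, run.cfg.n_variants, run.cfg.seed, run.cfg.sim,
            render_volumes=True,
        )
        _cache(run)["cohort"] = c
    return _cache(run)["cohort"]


_RUN_CACHES: dict = {}


def _cache(run: _Run) -> dict:
    return _RUN_CACHES.setdefault(id(run), {})


def _stage_simulate(run: _Run, state: dict) -> None:
    d = run.stage_dir("simulate")
    coh = _load_cohort(run)
    fileio.write_vcf(coh.genotypes, d / "genotypes.vcf", coh.subject_ids)
    fileio.write_dosage_tsv(coh.genotypes, d / "dosages.tsv", coh.subject_ids)
    fileio.write_cohort_tsv(coh.cohort, d / "cohort.tsv")
    fileio.write_dosage_tsv(coh.inversion.tags, d / "inversion_tags.tsv", coh.subject_ids)
    pd.DataFrame({"inversion_dosage": coh.inversion.inversion_dosage}).to_csv(
        d / "inversion_truth.tsv", sep="\t", index=False
    )
    coh.morphology.to_csv(d / "morphology_truth.tsv", sep="\t", index=False)


def _stage_segment(run: _Run, state: dict) -> None:
    d = run.stage_dir("segment")
    coh = _load_cohort(run)
    seg = run.cfg.segmentation
    g = run.cfg.sim.geometry
    target = g.n_cols

    model = None
    if seg.method == "unet":
        rng = substream(run.cfg.seed, "unet-train")
        imgs, masks = [], []
        offs = thickness.crop_offset(g.n_rows, target)
        while len(imgs) < seg.unet_train_pairs:
            s_idx = int(rng.integers(0, g.n_slices))
            v = coh.volumes[int(rng.integers(0, len(coh.volumes)))]
            img = thickness.crop_bscan(v.slices[s_idx], target)
            u = np.ceil(v.upper_surface[s_idx]) - offs
            lo = np.ceil(v.lower_surface[s_idx]) - 1 - offs
            imgs.append(img)
            masks.append(thickness.mask_from_edges(u, lo, target).mask.astype(float))
        model = unet.train_unet(
            np.array(imgs), np.array(masks), epochs=seg.unet_epochs,
            seed=run.cfg.seed, depth=seg.unet_depth, base=seg.unet_base,
        )

    maps = []
    for i, vol in enumerate(coh.volumes):
        profiles = []
        for s in range(g.n_slices):
            img = thickness.crop_bscan(vol.slices[s], target)
            mask = model.segment(img) if model is not None else thickness.oracle_segment(img)
            profiles.append(thickness.thickness_profile(mask))
        tmap = thickness.assemble_map(
            profiles, subject_id=coh.subject_ids[i],
            max_missing_fraction=seg.max_missing_fraction,
        )
        maps.append(tmap)
        fileio.write_thickness_map(tmap, d / f"map_{i:05d}")
    _cache(run)["maps"] = maps


def _load_maps(run: _Run):
    cache = _cache(run)
    if "maps" not in cache:
        d = run.out / "segment"
        bases = sorted({p.with_suffix("") for p in d.glob("map_*.npz")})
        cache["maps"] = [fileio.read_thickness_map(b) for b in bases]
    return cache["maps"]


def _stage_embed(run: _Run, state: dict) -> None:
    d = run.stage_dir("embed")
    maps = _load_maps(run)
    model, emb = latent.train_autoencoder(maps, run.cfg.autoencoder)
    fileio.write_embeddings_tsv(emb, d / "embeddings.tsv")
    scores, frac = latent.embedding_pca(emb, n_components=min(25, emb.values.shape[1]))
    pd.DataFrame(
        scores, columns=[f"pc{i + 1}" for i in range(scores.shape[1])]
    ).to_csv(d / "embedding_pcs.tsv", sep="\t", index=False)
    pd.DataFrame({"component": np.arange(1, frac.size + 1), "explained_fraction": frac}).to_csv(
        d / "pca_variance.tsv", sep="\t", index=False
    )


def _assoc_inputs(run: _Run):
    emb = fileio.read_embeddings_tsv(run.out / "embed" / "embeddings.tsv")
    pcs = pd.read_csv(run.out / "embed" / "embedding_pcs.tsv", sep="\t")
    cohort = fileio.read_cohort_tsv(run.out / "simulate" / "cohort.tsv")
    geno = fileio.read_dosage_tsv(run.out / "simulate" / "dosages.tsv")
    a = run.cfg.assoc
    rule = assoc.VariantQCRule(a.maf_min, a.hwe_p_min, a.call_rate_min)
    geno_qc, report = assoc.variant_qc(geno, rule)
    pc_cols = [c for c in cohort.columns if c.startswith("pc")]
    # keep the covariate model identifiable in the smallest analysis subset
    # (the replication split); desk-scale cohorts use fewer genetic PCs
    n_repl = int(round(a.replication_fraction * len(cohort)))
    n_pcs = max(0, min(len(pc_cols), n_repl - 10))
    cov_cols = ["age", "sex", "height", "weight", "refraction"] + pc_cols[:n_pcs]
    covariates = cohort[cov_cols]
    traits = {}
    for j in range(min(a.n_embedding_traits, emb.values.shape[1])):
        traits[f"e{j + 1}"] = latent.inverse_rank_normalize(emb.values[:, j])
    for j in range(min(a.n_pca_traits, pcs.shape[1])):
        traits[f"pc{j + 1}"] = latent.inverse_rank_normalize(pcs.iloc[:, j].to_numpy())
    return geno_qc, report, covariates, traits


def _stage_gwas(run: _Run, state: dict) -> None:
    d = run.stage_dir("gwas")
    geno_qc, report, covariates, traits = _assoc_inputs(run)
    report.to_csv(d / "variant_qc.tsv", sep="\t", index=False)
    lambdas = {}
    for name, y in traits.items():
        analysis = "pca_gwas" if name.startswith("pc") else "gwas"
        ss = assoc.gwas_linear(y, geno_qc, covariates, trait_id=name, analysis=analysis)
        fileio.write_summary_stats(ss, d / f"{name}.tsv")
        if len(ss.df) >= 100:
            lambdas[name] = assoc.genomic_lambda(ss)
    pd.DataFrame(
        {"trait": list(lambdas), "lambda_gc": list(lambdas.values())}
    ).to_csv(d / "genomic_lambda.tsv", sep="\t", index=False)


def _read_gwas(run: _Run, stage: str = "gwas"):
    d = run.out / stage
    return [
        fileio.read_summary_stats(p)
        for p in sorted(d.glob("*.tsv"))
        if p.name not in {"variant_qc.tsv", "genomic_lambda.tsv"}
    ]


def _stage_mtag(run: _Run, state: dict) -> None:
    d = run.stage_dir("mtag")
    ss_list = [s for s in _read_gwas(run) if s.analysis == "gwas"]
    updated = assoc.mtag_analysis(
        ss_list,
        r_threshold=run.cfg.assoc.mtag_r_threshold,
        sig_threshold=run.cfg.assoc.genome_wide,
    )
    for ss in updated:
        fileio.write_summary_stats(ss, d / f"{ss.trait}.tsv")


def _stage_cojo(run: _Run, state: dict) -> None:
    d = run.stage_dir("cojo")
    geno_qc, _, _, traits = _assoc_inputs(run)
    x = geno_qc.dosages
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    r = np.corrcoef((x - x.mean(0)) / sd, rowvar=False)
    fileio.write_ld_reference(r, geno_qc, d / "ld_reference")
    regime = assoc.significance_regime(
        n_analyses=max(len(traits), 1), genome_wide=run.cfg.assoc.genome_wide
    )
    all_leads = []
    for ss in _read_gwas(run) + _read_gwas(run, "mtag"):
        ls = assoc.cojo_select(ss, r, threshold=regime.study_wide)
        if len(ls.leads):
            leads = ls.leads.copy()
            leads["analysis"] = ss.analysis
            all_leads.append(leads)
    leads = (
        pd.concat(all_leads, ignore_index=True)
        if all_leads
        else pd.DataFrame(columns=["variant_id", "chromosome", "position"])
    )
    if len(leads):
        leads["locus"] = assoc.assign_loci(
            leads["chromosome"].to_numpy(), leads["position"].to_numpy()
        )
    leads.to_csv(d / "lead_variants.tsv", sep="\t", index=False)
    pd.DataFrame([regime.summary()]).to_csv(d / "significance_regime.tsv", sep="\t", index=False)


def _stage_replicate(run: _Run, state: dict) -> None:
    d = run.stage_dir("replicate")
    geno_qc, _, covariates, traits = _assoc_inputs(run)
    rng = substream(run.cfg.seed, "replication-split")
    n = geno_qc.n_subjects
    test = np.zeros(n, bool)
    test[rng.choice(n, int(round(run.cfg.assoc.replication_fraction * n)), replace=False)] = True
    leads_path = run.out / "cojo" / "lead_variants.tsv"
    leads = pd.read_csv(leads_path, sep="\t") if leads_path.exists() else pd.DataFrame()
    import dataclasses as _dc

    disc_block = _dc.replace(geno_qc, dosages=geno_qc.dosages[~test], causal_map=[])
    repl_block = _dc.replace(geno_qc, dosages=geno_qc.dosages[test], causal_map=[])
    tables = []
    for name, y in traits.items():
        disc = assoc.gwas_linear(y[~test], disc_block, covariates[~test], trait_id=name)
        repl = assoc.gwas_linear(y[test], repl_block, covariates[test], trait_id=name)
        lead_ids = (
            leads.loc[leads["trait"] == name, "variant_id"].astype(str).tolist()
            if len(leads)
            else None
        )
        if lead_ids is not None and not lead_ids:
            continue
        table, r, sign_frac, p = assoc.replication_concordance(disc, repl, lead_ids)
        table["trait"] = name
        tables.append(table)
        fileio.write_summary_stats(repl, d / f"replication_{name}.tsv")
    if tables:
        bb = pd.concat(tables, ignore_index=True)
        bb.to_csv(d / "beta_beta.tsv", sep="\t", index=False)


def _stage_phewas(run: _Run, state: dict) -> None:
    d = run.stage_dir("phewas")
    cohort = fileio.read_cohort_tsv(run.out / "simulate" / "cohort.tsv")
    tags = fileio.read_dosage_tsv(run.out / "simulate" / "inversion_tags.tsv")
    call = pheno.call_inversion(tags, np.arange(tags.n_variants))
    pd.DataFrame(
        {"subject_id": cohort["subject_id"], "inversion_class": call.classes}
    ).to_csv(d / "inversion_call.tsv", sep="\t", index=False)
    for coding in ("additive", "recessive"):
        res = pheno.phewas_logistic(
            call.classes.astype(float), cohort, coding=coding, predictor_name="inversion"
        )
        res.table.to_csv(d / f"phewas_inversion_{coding}.tsv", sep="\t", index=False)


def _stage_dominance(run: _Run, state: dict) -> None:
    d = run.stage_dir("dominance")
    maps = _load_maps(run)
    arr = np.stack([m.map for m in maps])
    tags = fileio.read_dosage_tsv(run.out / "simulate" / "inversion_tags.tsv")
    call = pheno.call_inversion(tags, np.arange(tags.n_variants))
    dm = pheno.dominance_map(arr, call.classes, seed=run.cfg.seed)
    np.savez(
        d / "dominance_inversion.npz",
        mean_ref=dm.mean_ref,
        diff_het=dm.diff_het,
        diff_hom=dm.diff_hom,
        mask=dm.significance_mask,
    )
    pd.DataFrame(
        [{"predictor": "inversion", "dominance_index": dm.dominance_index, **{
            f"n_class{k}": v for k, v in dm.group_sizes.items()}}]
    ).to_csv(d / "dominance_index.tsv", sep="\t", index=False)


def _stage_survive(run: _Run, state: dict) -> None:
    d = run.stage_dir("survive")
    cohort = fileio.read_cohort_tsv(run.out / "simulate" / "cohort.tsv")
    emb = fileio.read_embeddings_tsv(run.out / "embed" / "embeddings.tsv")
    s = run.cfg.survival
    for code in s.outcome_codes:
        if f"{code}_status" not in cohort.columns:
            continue
        design = surv.SurvivalDesign(
            features=emb.values,
            time=cohort[f"{code}_time"].to_numpy(),
            event=cohort[f"{code}_status"].to_numpy(),
            sex=cohort["sex"].to_numpy(),
            penalty_strength=s.penalty_strength,
            l1_ratio=s.l1_ratio,
            n_repetitions=s.n_repetitions,
            n_folds=s.n_folds,
            seed=run.cfg.seed,
            feature_names=list(emb.feature_ids),
        )
        coef = surv.fit_cox_elasticnet(design)
        pd.DataFrame({"feature": emb.feature_ids, "log_hr": coef}).to_csv(
            d / f"coefficients_{code}.tsv", sep="\t", index=False
        )
        cv = surv.cross_validated_c(design)
        cv.to_csv(d / f"cv_c_{code}.tsv", sep="\t", index=False)
        lp = (design.features - design.features.mean(0)) @ coef
        res = surv.km_stratify(
            lp, design.time, design.event, sex=design.sex, top_fraction=s.top_fraction
        )
        for name, curve in res.km_curves.items():
            curve.to_csv(d / f"km_{code}_{name}.tsv", sep="\t", index=False)
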