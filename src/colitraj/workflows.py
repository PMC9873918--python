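"""Reproducible study-level experiments built from the pipeline modules.

These functions wire the simulator to the analysis stages into the canonical
validation experiments: null calibration of every test, planted-signal
recovery, expression/splicing orthogonality, the cross-cohort prediction
transfer, and the bootstrap-optimism check.  Both the test suite and the
acceptance script run them, so the numbers they report are always recomputed
from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from . import dynamic, fixed, predict, simulate as sim, splicing, stats, translate, vdj
from .io import Signature


# ---------------------------------------------------------------------------
# criterion-style experiments
# ---------------------------------------------------------------------------


def null_calibration(
    n_reps: int = 20,
    n_genes: int = 2000,
    n_per_group_per_day: int = 10,
    seed: int = 0,
) -> dict:
    """Null simulation (no planted effects): FDP of every discovery route.

    Under a complete null every rejection is false, so the per-replicate FDP
    is 1 when anything is called and 0 otherwise; the mean over replicates
    estimates the realized FDR.  Also pools the interaction-LRT p-values for
    a uniformity check.
    """
    fdp = {"fixed_de": [], "interaction_lrt": [], "diff_splice": []}
    lrt_p = []
    ks_stats, ks_ps = [], []
    for rep in range(n_reps):
        cfg = sim.SimulationConfig(
            n_genes=n_genes, n_per_group_per_day=n_per_group_per_day,
            n_fixed_per_day=0, trajectory_members={}, n_splice=0,
            n_splice_dynamic=0, seed=seed + rep)
        gene, exon, ann, meta, _ = sim.simulate_counts(cfg)
        de = fixed.timepoint_de(gene, meta, 5, engine="nbglm")
        fdp["fixed_de"].append(1.0 if (de["q"] <= 0.05).any() else 0.0)
        lrt = dynamic.interaction_lrt(gene, meta)
        fdp["interaction_lrt"].append(1.0 if (lrt["q"] < 0.05).any() else 0.0)
        pvec = lrt["p"].dropna().to_numpy()
        lrt_p.append(pvec)
        rep_ks = sps.kstest(pvec, "uniform")
        ks_stats.append(float(rep_ks.statistic))
        ks_ps.append(float(rep_ks.pvalue))
        ds = splicing.splice_timepoint(exon, ann, meta, 5, q_max=0.10)
        fdp["diff_splice"].append(1.0 if ds.gene["flagged"].any() else 0.0)
    pooled = np.concatenate(lrt_p)
    ks = sps.kstest(pooled, "uniform")
    return {
        "fdp_fixed_de": float(np.mean(fdp["fixed_de"])),
        "fdp_interaction_lrt": float(np.mean(fdp["interaction_lrt"])),
        "fdp_diff_splice": float(np.mean(fdp["diff_splice"])),
        "lrt_ks_statistic": float(ks.statistic),
        "lrt_ks_p": float(ks.pvalue),
        "lrt_ks_stat_per_rep": ks_stats,
        "lrt_ks_p_per_rep": ks_ps,
        "lrt_ks_min_p_per_rep": float(min(ks_ps)),
        "lrt_rate_at_005": float(np.mean(pooled <= 0.05)),
        "n_reps": n_reps,
    }


def fixed_recovery(
    seed: int = 0,
    n_genes: int = 2000,
    n_per_group_per_day: int = 10,
    effect_log2: float = 2.0,
) -> dict:
    """Sensitivity/precision for planted fixed-day effects at FDR 0.05."""
    cfg = sim.SimulationConfig(
        n_genes=n_genes, n_per_group_per_day=n_per_group_per_day,
        n_fixed_per_day=50, fixed_effect_log2=effect_log2,
        trajectory_members={}, n_splice=0, n_splice_dynamic=0, seed=seed)
    gene, _, _, meta, truth = sim.simulate_counts(cfg)
    sens, prec = [], []
    for day in cfg.days:
        de = fixed.timepoint_de(gene, meta, day, engine="nbglm")
        called = set(fixed.extract_signature(de, direction="both").genes)
        planted = set(truth.genes_with_label(f"fixed-day-{day}"))
        sens.append(len(called & planted) / len(planted))
        prec.append(len(called & planted) / max(len(called), 1))
    return {
        "sensitivity": float(np.mean(sens)),
        "precision": float(np.mean(prec)),
        "per_day_sensitivity": sens,
        "per_day_precision": prec,
    }


def trajectory_recovery(seed: int = 0, n_genes: int = 2000,
                        n_per_group_per_day: int = 10) -> dict:
    """ARI and center-shape correlations for planted temporal classes."""
    cfg = sim.SimulationConfig(
        n_genes=n_genes, n_per_group_per_day=n_per_group_per_day,
        n_fixed_per_day=0, trajectory_members={k: 40 for k in "ABCDE"},
        n_splice=0, n_splice_dynamic=0, seed=seed)
    gene, _, _, meta, truth = sim.simulate_counts(cfg)
    lrt = dynamic.interaction_lrt(gene, meta)
    hits = lrt.loc[lrt["q"] < 0.05, "gene_id"].tolist()
    we = stats.logcpm_transform(gene)
    Tz = dynamic.standardize_trajectories(
        dynamic.median_disease_trajectories(we, meta, hits))
    cl = dynamic.fuzzy_cmeans(Tz, k=5, seed=seed)
    labels = truth.gene_labels
    pairs = [(labels[g].replace("cluster-", ""), c)
             for g, c in cl.hard_labels.items() if labels[g].startswith("cluster")]
    ari = adjusted_rand_score([a for a, _ in pairs], [b for _, b in pairs])
    corrs = []
    for lab in cl.centers.index:
        if lab not in dynamic.CANONICAL_SHAPES:
            continue
        shape = np.asarray(dynamic.CANONICAL_SHAPES[lab], dtype=float)
        c = cl.centers.loc[lab].to_numpy()
        corrs.append(float(np.corrcoef(shape - shape.mean(), c - c.mean())[0, 1]))
    planted = sum(1 for v in labels if v.startswith("cluster"))
    return {
        "ari": float(ari),
        "min_center_shape_corr": float(min(corrs)),
        "center_shape_corrs": corrs,
        "n_interaction_hits": len(hits),
        "interaction_sensitivity": float(
            sum(1 for g in hits if labels[g].startswith("cluster")) / planted),
        "fuzzifier": cl.fuzzifier,
    }


def splice_orthogonality(seed: int = 0, n_genes: int = 1500,
                         n_per_group_per_day: int = 10) -> dict:
    """Cross-contamination between expression shifts and isoform switches.

    Planted switches move exon proportions without changing gene totals, and
    planted uniform shifts move totals without changing proportions; each
    should be invisible to the other test.
    """
    cfg = sim.SimulationConfig(
        n_genes=n_genes, n_per_group_per_day=n_per_group_per_day,
        n_fixed_per_day=40, trajectory_members={}, n_splice=40,
        n_splice_dynamic=0, seed=seed)
    gene, exon, ann, meta, truth = sim.simulate_counts(cfg)
    de = fixed.timepoint_de(gene, meta, 5, engine="nbglm")
    de_called = set(fixed.extract_signature(de, direction="both").genes)
    ds = splicing.splice_timepoint(exon, ann, meta, 5, q_max=0.10)
    ds_called = set(ds.gene.loc[ds.gene["flagged"], "gene_id"])
    switch = set(truth.genes_with_label("splice"))
    shift = set(truth.genes_with_label("fixed-day-5"))
    return {
        "splice_sensitivity": len(ds_called & switch) / len(switch),
        "shift_genes_splice_flagged": len(ds_called & shift) / len(shift),
        "switch_genes_de_called": len(de_called & switch) / len(switch),
        "shift_genes_de_called": len(de_called & shift) / len(shift),
    }


# ---------------------------------------------------------------------------
# cross-cohort prediction
# ---------------------------------------------------------------------------


def _cohort(cfg: sim.SimulationConfig):
    gene, exon, ann, meta, truth = sim.simulate_counts(cfg)
    clones = sim.simulate_vdj(truth.severity, cfg, seed=cfg.seed + 10_000)
    histo = sim.simulate_histology(
        truth.severity, cfg.histology_weight, cfg.histology_noise_sd,
        seed=cfg.seed + 20_000)
    prof = vdj.vdj_profile(clones, gene.library_sizes)
    return {
        "gene": gene, "exon": exon, "annotation": ann, "meta": meta,
        "truth": truth, "vdj": prof, "histology": histo,
        "we_gene": stats.logcpm_transform(gene),
        "we_exon": stats.logcpm_transform(exon),
    }


def build_transfer_features(
    seed: int = 0,
    n_genes: int = 1000,
    n_per_group_per_day: int = 5,
    signature_day: int = 17,
) -> dict:
    """Two cohorts sharing the planted structure, reduced to feature tables.

    Signatures (gene DE and exon DS at ``signature_day``) are derived on the
    training cohort only; validation features are projected with training
    loadings, never refit.
    """
    base = dict(
        n_genes=n_genes, n_per_group_per_day=n_per_group_per_day,
        n_fixed_per_day=30, trajectory_members={k: 20 for k in "ABCDE"},
        n_splice=20, n_splice_dynamic=10, structure_seed=seed)
    train = _cohort(sim.SimulationConfig(**base, seed=seed + 1))
    val = _cohort(sim.SimulationConfig(**base, seed=seed + 2))

    # moderated-t engine: at 5 mice/arm the variance moderation buys the
    # power a plain per-gene test lacks, while staying null-calibrated
    de = fixed.timepoint_de(train["gene"], train["meta"], signature_day,
                            engine="wlm")
    gene_sig = fixed.extract_signature(de, direction="both",
                                       label=f"fixed-day-{signature_day}")
    ds = splicing.splice_timepoint(train["exon"], train["annotation"],
                                   train["meta"], signature_day)
    ds_genes = set(ds.gene.loc[ds.gene["flagged"], "gene_id"])
    exon_ids = [e for e in train["exon"].feature_ids
                if e.split(":")[0] in ds_genes]
    exon_sig = Signature(f"splice-day-{signature_day}", exon_ids) if exon_ids else None

    usage_tr = splicing.relative_exon_expression(train["we_exon"],
                                                 train["annotation"])
    usage_va = splicing.relative_exon_expression(val["we_exon"],
                                                 val["annotation"])
    builder = predict.fit_feature_builder(
        train["we_gene"], usage_tr, gene_sig, exon_sig)
    return {
        "signature": gene_sig,
        "X_train": predict.build_features(builder, train["we_gene"],
                                          usage_tr, train["vdj"]),
        "X_val": predict.build_features(builder, val["we_gene"],
                                        usage_va, val["vdj"]),
        "y_train": train["histology"],
        "y_val": val["histology"],
    }


def transfer_experiment(seed: int = 0, features: dict | None = None,
                        **kwargs) -> dict:
    """Train on cohort 1, validate on cohort 2 sharing the planted structure."""
    feats = features or build_transfer_features(seed=seed, **kwargs)
    model = predict.train_rf(feats["X_train"], feats["y_train"], seed=seed)
    rep = predict.validate(model, feats["X_val"], feats["y_val"],
                           signature_label=feats["signature"].label,
                           validation_label="transfer-cohort")
    top = [name for name, _ in rep["top_predictors"]]
    rep["n_gene_pc_in_top3"] = sum(1 for t in top if t in predict.GENE_PC_COLUMNS)
    rep["retained"] = model.retained
    return rep


def noise_prediction_rhos(n_seeds: int = 20, seed: int = 0,
                          features: dict | None = None, **kwargs) -> list[float]:
    """Validation rho under pure-noise outcomes, one value per seed.

    Cohort features are built once; each seed draws fresh noise outcomes for
    both cohorts and refits the forest (the negative control for predictive
    power: any apparent transfer must vanish).
    """
    feats = features or build_transfer_features(seed=seed, **kwargs)
    rhos = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 30_000 + s)
        y_tr = pd.Series(rng.normal(size=len(feats["X_train"])),
                         index=feats["X_train"].index)
        y_va = pd.Series(rng.normal(size=len(feats["X_val"])),
                         index=feats["X_val"].index)
        model = predict.train_rf(feats["X_train"], y_tr, seed=seed + 500 + s)
        rep = predict.validate(model, feats["X_val"], y_va)
        rhos.append(rep["rho"])
    return rhos


# ---------------------------------------------------------------------------
# bootstrap optimism
# ---------------------------------------------------------------------------


def overfit_optimism(n_seeds: int = 20, n: int = 40, k: int = 10,
                     B: int = 300, seed: int = 0) -> dict:
    """Optimism correction on pure-noise models with k ~ n/2 columns."""
    below = 0
    gaps = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        X = pd.DataFrame(rng.normal(size=(n, k)),
                         columns=[f"PC{i + 1}" for i in range(k)])
        y = rng.normal(size=n)
        res = translate.bootstrap_bias_corrected_r2(X, y, B=B, seed=seed + s)
        below += res["corrected_r2"] < res["apparent_adj_r2"]
        gaps.append(res["apparent_adj_r2"] - res["corrected_r2"])
    return {
        "n_seeds": n_seeds,
        "corrected_below_apparent": int(below),
        "median_optimism_gap": float(np.median(gaps)),
    }


def prior_df_recovery(seed: int = 0, n_features: int = 5000,
                      df: int = 10, d0_true: float = 4.0) -> dict:
    """Recover a known variance-prior df from simulated chi-square variances."""
    rng = np.random.default_rng(seed)
    sigma2 = d0_true * 1.0 / rng.chisquare(d0_true, n_features)
    s2 = sigma2 * rng.chisquare(df, n_features) / df
    d0, s0 = stats.fit_f_dist(s2, np.full(n_features, float(df)))
    return {"d0_true": d0_true, "d0_est": float(d0),
            "relative_error": float(abs(d0 - d0_true) / d0_true)}


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def full_pipeline(seed: int = 0, n_genes: int = 800,
                  n_per_group_per_day: int = 6) -> dict:
    """Simulate -> signatures -> features -> predict -> translate, end to end.

    Returns a flat dict of the key numerical outputs; re-running with the
    same seed reproduces every value bit-for-bit.
    """
    cfg = sim.SimulationConfig(
        n_genes=n_genes, n_per_group_per_day=n_per_group_per_day,
        n_fixed_per_day=30, trajectory_members={k: 20 for k in "ABCDE"},
        n_splice=15, n_splice_dynamic=10, seed=seed)
    gene, exon, ann, meta, truth = sim.simulate_counts(cfg)
    clones = sim.simulate_vdj(truth.severity, cfg, seed=seed + 1)
    histo = sim.simulate_histology(truth.severity, cfg.histology_weight,
                                   cfg.histology_noise_sd, seed=seed + 2)
    prof = vdj.vdj_profile(clones, gene.library_sizes)

    de_by_day = {d: fixed.timepoint_de(gene, meta, d, engine="nbglm")
                 for d in cfg.days}
    sigs = {d: fixed.extract_signature(de_by_day[d], direction="both",
                                       label=f"fixed-day-{d}")
            for d in cfg.days}
    specificity = fixed.timepoint_specificity(sigs)

    lrt = dynamic.interaction_lrt(gene, meta)
    hits = lrt.loc[lrt["q"] < 0.05, "gene_id"].tolist()
    we = stats.logcpm_transform(gene)
    clusters = None
    if len(hits) >= 5:
        Tz = dynamic.standardize_trajectories(
            dynamic.median_disease_trajectories(we, meta, hits))
        clusters = dynamic.fuzzy_cmeans(Tz, k=5, seed=seed)

    ds = splicing.splice_timepoint(exon, ann, meta, 5)
    ortho = splicing.orthogonality_report({5: de_by_day[5]}, {5: ds})

    rho_vdj, _ = vdj.vdj_severity_correlation(prof["vdj_read_cpm"], histo)

    gene_sig = sigs[17]
    we_exon = stats.logcpm_transform(exon)
    usage = splicing.relative_exon_expression(we_exon, ann)
    ds_genes = set(ds.gene.loc[ds.gene["flagged"], "gene_id"])
    exon_ids = [e for e in exon.feature_ids if e.split(":")[0] in ds_genes]
    exon_sig = Signature("splice-day-5", exon_ids) if exon_ids else None
    builder = predict.fit_feature_builder(we, usage, gene_sig, exon_sig)
    X = predict.build_features(builder, we, usage, prof)
    model = predict.train_rf(X, histo, seed=seed)
    pred_in = model.forest.predict(X[model.retained].to_numpy())
    rho_fit, _ = stats.spearman(pred_in, histo.loc[X.index].to_numpy())

    # human-style translation on the signature PC scores vs histology
    pcs = X[predict.GENE_PC_COLUMNS].copy()
    res_r2 = translate.bootstrap_bias_corrected_r2(
        pcs, histo.loc[pcs.index], B=100, seed=seed)

    out = {
        "n_signature_genes_by_day": {int(d): len(sigs[d]) for d in cfg.days},
        "timepoint_specificity": float(specificity),
        "n_interaction_genes": len(hits),
        "n_splice_flagged": int(ds.gene["flagged"].sum()),
        "de_ds_jaccard": float(ortho["jaccard"]),
        "vdj_histology_rho": float(rho_vdj),
        "training_fit_rho": float(rho_fit),
        "retained_features": model.retained,
        "translation_adj_r2": float(res_r2["apparent_adj_r2"]),
        "translation_corrected_r2": float(res_r2["corrected_r2"]),
    }
    if clusters is not None:
        out["cluster_sizes"] = {
            str(k): int(v) for k, v in
            clusters.hard_labels.value_counts().sort_index().items()}
    return out
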