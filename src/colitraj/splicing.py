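"""Differential exon usage and isoform-level expression scores.

An exon "counting bin" is differentially used when its disease effect departs
from the gene's average disease effect: per gene, a precision-weighted mean
of the exon coefficients is removed from each exon and the residual
deviations are tested with moderated t statistics.  Gene-level evidence is
aggregated two ways — a Simes combination of the exon p-values and a
moderated F on the deviations — and a gene is flagged when either route is
significant, which deliberately ignores genes whose exons all shift together
(those are differential expression, not splicing).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .io import CountMatrix, ExonAnnotation, Signature
from .stats import LinearFit, ModeratedStats, WeightedExpression

logger = logging.getLogger("colitraj")


@dataclass
class SpliceResult:
    """Exon-level deviations plus gene-level aggregated significance."""

    exon: pd.DataFrame   # exon_id, gene_id, dev_log2fc, t, p per coefficient
    gene: pd.DataFrame   # gene_id, p_simes, q_simes, p_f, q_f, q_min, flagged
    day: int | None = None
    excluded_single_exon: list[str] | None = None


def exon_deviations(
    fit: LinearFit,
    moderated: ModeratedStats,
    annotation: ExonAnnotation,
    coefficient: str,
) -> pd.DataFrame:
    """Per-exon deviation of one coefficient from its gene's weighted mean.

    Weights are inverse squared unscaled standard errors, so the gene average
    is the precision-weighted mean and the deviation variance is
    u_e^2 - 1 / sum_w (the subtraction of an estimated mean).  Returns a frame
    with dev, dev_se_unscaled, t, p, df_total per multi-exon exon; single-exon
    genes are absent.
    """
    gene_of = annotation.gene_of()
    exons = fit.coefficients.index
    genes = gene_of.reindex(exons)
    if genes.isna().any():
        missing = exons[genes.isna()].tolist()
        raise ValueError(f"exons without annotation: {missing[:5]}")

    coef = fit.coefficients[coefficient]
    u2 = fit.stdev_unscaled[coefficient] ** 2
    w = 1.0 / u2

    df = pd.DataFrame(
        {"exon_id": exons, "gene_id": genes.to_numpy(), "coef": coef.to_numpy(),
         "w": w.to_numpy(), "u2": u2.to_numpy()}
    )
    grp = df.groupby("gene_id", sort=True)
    n_exons = grp["exon_id"].transform("size")
    multi = n_exons >= 2
    df = df[multi].copy()
    grp = df.groupby("gene_id", sort=True)
    wsum = grp["w"].transform("sum")
    gene_mean = grp.apply(
        lambda g: np.average(g["coef"], weights=g["w"]), include_groups=False
    )
    df["gene_mean"] = df["gene_id"].map(gene_mean)
    df["dev"] = df["coef"] - df["gene_mean"]
    dev_var_unscaled = np.maximum(df["u2"] - 1.0 / wsum, 1e-12)
    df["dev_se_unscaled"] = np.sqrt(dev_var_unscaled)

    var_post = moderated.var_post.reindex(df["exon_id"]).to_numpy()
    df_total = moderated.df_total.reindex(df["exon_id"]).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = df["dev"].to_numpy() / (df["dev_se_unscaled"].to_numpy() * np.sqrt(var_post))
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    df["t"] = t
    df["p"] = p
    df["df_total"] = df_total
    return df.reset_index(drop=True)


def _gene_aggregate(exon_df: pd.DataFrame, q_max: float) -> pd.DataFrame:
    """Simes and moderated-F gene-level p-values from exon deviations."""
    rows = []
    for gene, g in exon_df.groupby("gene_id", sort=True):
        k = len(g)
        p_simes = stats.simes_combine(g["p"].to_numpy())
        # moderated F: mean square of deviation t over k-1 free deviations
        f_stat = float((g["t"] ** 2).sum()) / (k - 1)
        df2 = float(g["df_total"].iloc[0])
        p_f = float(sps.f.sf(f_stat, k - 1, df2))
        rows.append((gene, k, p_simes, f_stat, p_f))
    gene = pd.DataFrame(rows, columns=["gene_id", "n_exons", "p_simes", "f", "p_f"])
    gene["q_simes"] = stats.bh_adjust(gene["p_simes"])
    gene["q_f"] = stats.bh_adjust(gene["p_f"])
    gene["q_min"] = gene[["q_simes", "q_f"]].min(axis=1)
    gene["flagged"] = gene["q_min"] < q_max
    return gene


def diff_splice(
    fit: LinearFit,
    moderated: ModeratedStats,
    annotation: ExonAnnotation,
    coefficient: str = "disease",
    q_max: float = 0.10,
    day: int | None = None,
) -> SpliceResult:
    """Differential exon usage for one tested coefficient.

    Genes with a single testable exon are excluded (usage is undefined) and
    recorded on the result.  A gene is flagged as differentially spliced when
    the smaller of its Simes-route and F-route BH q-values is below ``q_max``.
    """
    gene_of = annotation.gene_of()
    sizes = gene_of.reindex(fit.coefficients.index).value_counts()
    single = sorted(sizes.index[sizes < 2].tolist())
    if single:
        logger.info("diff_splice: excluded %d single-exon gene(s)", len(single))
    exon_df = exon_deviations(fit, moderated, annotation, coefficient)
    if exon_df.empty:
        raise ValueError("no multi-exon genes to test")
    gene_df = _gene_aggregate(exon_df, q_max)
    return SpliceResult(exon=exon_df, gene=gene_df, day=day,
                        excluded_single_exon=single)


def splice_timepoint(
    exon_counts: CountMatrix,
    annotation: ExonAnnotation,
    meta: pd.DataFrame,
    day: int,
    q_max: float = 0.10,
    min_mean: float = 1.0,
) -> SpliceResult:
    """Fixed-day differential exon usage.

    Weighted log-CPM transform, per-exon weighted LM with a group contrast,
    empirical-Bayes moderation, then gene-level deviation aggregation.
    """
    from .design import group_design
    from .fixed import _day_subset, filter_low_counts

    sub, m = _day_subset(exon_counts, meta, day)
    sub, _ = filter_low_counts(sub, min_mean=min_mean)
    design = group_design(m).loc[sub.sample_ids]
    we = stats.logcpm_transform(sub, design=design)
    fit = stats.fit_weighted_lm(we, design)
    mod = stats.moderate(fit, coefficients=["disease"])
    return diff_splice(fit, mod, annotation, "disease", q_max=q_max, day=day)


def splice_signature(result: SpliceResult, label: str | None = None) -> Signature:
    genes = result.gene.loc[result.gene["flagged"], "gene_id"].tolist()
    if label is None:
        label = f"splice-day-{result.day}" if result.day is not None else "splice"
    if not genes:
        warnings.warn(f"splice signature {label} is empty")
    return Signature(label=label, genes=genes)


def relative_exon_expression(
    we_exon: WeightedExpression, annotation: ExonAnnotation
) -> WeightedExpression:
    """Exon log2-CPM centered on the gene's per-sample average (usage signal).

    Subtracting the gene mean removes the gene-level expression component, so
    what remains is relative isoform expression — the quantity exon-level
    prediction features are built from.
    """
    gene_of = annotation.gene_of().reindex(we_exon.E.index)
    if gene_of.isna().any():
        missing = we_exon.E.index[gene_of.isna()].tolist()
        raise ValueError(f"exons without annotation: {missing[:5]}")
    gene_mean = we_exon.E.groupby(gene_of.to_numpy()).transform("mean")
    return WeightedExpression(we_exon.E - gene_mean, we_exon.weights)


# ---------------------------------------------------------------------------
# expression/splicing orthogonality
# ---------------------------------------------------------------------------


def orthogonality_report(
    de_by_day: dict[int, pd.DataFrame],
    ds_by_day: dict[int, SpliceResult],
    q_max_de: float = 0.05,
    q_max_ds: float = 0.10,
) -> dict:
    """Summarize how disjoint the DE and DS gene sets are.

    Reports the Jaccard and directional overlap of the unions, per-day
    specificity of each call type, and the Spearman correlation between
    |log2fc| and DS evidence (-log10 Simes p) among DS genes.
    """
    de_union: set[str] = set()
    ds_union: set[str] = set()
    for day, de in de_by_day.items():
        de_union |= set(de.loc[(de["q"] <= q_max_de), "gene_id"])
    for day, ds in ds_by_day.items():
        ds_union |= set(ds.gene.loc[ds.gene["q_min"] < q_max_ds, "gene_id"])
    if not de_union and not ds_union:
        raise ValueError("both DE and DS sets are empty")
    inter = de_union & ds_union
    union = de_union | ds_union
    report = {
        "n_de": len(de_union),
        "n_ds": len(ds_union),
        "overlap": len(inter),
        "jaccard": len(inter) / len(union) if union else 0.0,
        "ds_also_de_fraction": len(inter) / len(ds_union) if ds_union else float("nan"),
        "de_also_ds_fraction": len(inter) / len(de_union) if de_union else float("nan"),
    }
    # correlation of DE magnitude with DS evidence among DS genes
    if ds_union:
        rows = []
        for day, ds in ds_by_day.items():
            de = de_by_day.get(day)
            if de is None:
                continue
            lfc = de.set_index("gene_id")["log2fc"].abs()
            g = ds.gene[ds.gene["q_min"] < q_max_ds]
            for gid, p in zip(g["gene_id"], g["p_simes"]):
                if gid in lfc.index:
                    rows.append((lfc[gid], -np.log10(max(p, 1e-300))))
        if len(rows) >= 3:
            arr = np.array(rows)
            rho, pval = stats.spearman(arr[:, 0], arr[:, 1])
            report["de_vs_ds_spearman"] = rho
            report["de_vs_ds_p"] = pval
        else:
            report["de_vs_ds_spearman"] = float("nan")
    else:
        report["de_vs_ds_spearman"] = float("nan")
    return report


# ---------------------------------------------------------------------------
# isoform-specific expression
# ---------------------------------------------------------------------------


def isoform_specific_expression(
    exon_counts: CountMatrix, isoform_exon_map: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-sample mean log2-CPM over the exons specific to each isoform.

    ``isoform_exon_map`` maps isoform id -> designated exon ids; designated
    sets of the two isoforms of a gene must be disjoint (caller's contract).
    Returns isoforms x samples.
    """
    E = stats.logcpm(
        exon_counts.counts.to_numpy(dtype=float),
        exon_counts.library_sizes.to_numpy(dtype=float),
    )
    Edf = pd.DataFrame(E, index=exon_counts.counts.index, columns=exon_counts.counts.columns)
    rows = {}
    for iso, exons in isoform_exon_map.items():
        if not exons:
            raise ValueError(f"isoform {iso!r}: empty designated exon set")
        missing = [e for e in exons if e not in Edf.index]
        if missing:
            raise ValueError(f"isoform {iso!r}: exons not in matrix: {missing[:5]}")
        rows[iso] = Edf.loc[exons].mean(axis=0)
    return pd.DataFrame(rows).T


def correlated_gene_lists(
    iso_scores: pd.DataFrame, we: WeightedExpression, r_min: float = 0.8
) -> dict[str, set[str]]:
    """Genes whose Pearson correlation with an isoform score exceeds r_min."""
    if we.E.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    E = we.E[iso_scores.columns].to_numpy()
    sd = E.std(axis=1)
    ok = sd > 0
    Ec = E[ok] - E[ok].mean(axis=1, keepdims=True)
    Ec /= np.linalg.norm(Ec, axis=1, keepdims=True)
    genes = np.asarray(we.feature_ids)[ok]
    out = {}
    for iso in iso_scores.index:
        s = iso_scores.loc[iso].to_numpy(dtype=float)
        sc = s - s.mean()
        nrm = np.linalg.norm(sc)
        if nrm == 0:
            out[iso] = set()
            continue
        r = Ec @ (sc / nrm)
        out[iso] = set(genes[r > r_min])
    return out


def geneset_enrichment(
    query_genes: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each set in the query."""
    query = set(query_genes) & set(universe)
    if set(query_genes) - set(universe):
        warnings.warn("query genes outside the universe were dropped")
    rows = []
    for name, members in collection.items():
        m = set(members) & set(universe)
        if not m:
            continue
        k = len(query & m)
        p = stats.hypergeom_overlap_p(k, len(m), len(query), len(universe))
        rows.append((name, len(m), k, p))
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    df["q"] = stats.bh_adjust(df["p"]) if len(df) else np.nan
    return df.sort_values(["p", "set"]).reset_index(drop=True)
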