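"""End-to-end orchestration: trait preparation, the three association
stages, correlated meta-analysis, module/GO enrichment, and two-cohort
replication.

The in-memory entry point is :func:`analyze_cohort`, which accepts any
object with the cohort attributes produced by the synthetic generator (or
by :func:`load_cohort_inputs` from files). ``run_all`` is the file-based
driver behind the CLI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cma as cma_mod
from . import enrichment as enr
from . import io as io_mod
from . import rva as rva_mod
from . import twas as twas_mod
from .gwas import run_gwas_aggregation, single_variant_gwas
from .lmm import fit_variance_model
from .traits import inverse_normal_transform, residualize, stepwise_pc_adjust

__all__ = [
    "CohortBundle",
    "PipelineResult",
    "build_design",
    "genotype_pcs",
    "prepare_cohort_trait",
    "analyze_cohort",
    "replicate_cohorts",
    "load_cohort_inputs",
    "run_all",
]


@dataclass
class CohortBundle:
    """Aligned inputs for one cohort (mirrors the synthetic cohort)."""

    sample_ids: list
    genes: list
    variants: list
    kinship: pd.DataFrame
    covariates: pd.DataFrame
    trait: pd.Series
    expression: pd.DataFrame
    annotations: pd.DataFrame
    categories: dict
    modules: io_mod.ModuleCollection
    go_sets: io_mod.ModuleCollection

    @property
    def dosage_map(self) -> dict:
        return {v.variant_id: v.dosages for v in self.variants}


@dataclass
class PipelineResult:
    scores: pd.DataFrame  # long gene-score rows: GWAS, TWAS, RVA
    cma: cma_mod.CmaResult
    cma_rows: pd.DataFrame
    enrichment: list
    ora: list
    info: dict = field(default_factory=dict)


def build_design(covariates: pd.DataFrame, columns=None, square=("age",)) -> np.ndarray:
    """Covariate design matrix: selected columns, squared terms for the
    listed ones, and one-hot coding for low-cardinality integer columns
    (field-center style factors)."""
    cols = list(columns) if columns is not None else list(covariates.columns)
    parts = []
    for c in cols:
        x = covariates[c].to_numpy(dtype=float)
        uniq = np.unique(x)
        if len(uniq) > 2 and len(uniq) <= 10 and np.allclose(uniq, np.round(uniq)):
            for u in uniq[1:]:
                parts.append((x == u).astype(float))
        else:
            parts.append(x)
            if c in square:
                parts.append(x**2)
    return np.column_stack(parts) if parts else np.empty((len(covariates), 0))


def genotype_pcs(dosages: np.ndarray, n_pcs: int = 10, max_variants: int = 2000, seed: int = 0):
    """Top principal components of a samples x variants dosage matrix.

    Variants are subsampled (seeded) beyond ``max_variants``; columns are
    standardized; PCs come from the sample-space Gram matrix.
    """
    X = np.asarray(dosages, dtype=float)
    rng = np.random.default_rng(seed)
    if X.shape[1] > max_variants:
        idx = rng.choice(X.shape[1], size=max_variants, replace=False)
        X = X[:, idx]
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu, X)
    sd = X.std(axis=0)
    keep = sd > 0
    X = (X[:, keep] - mu[keep]) / sd[keep]
    G = X @ X.T
    lam, U = np.linalg.eigh(G)
    order = np.argsort(lam)[::-1][:n_pcs]
    return U[:, order] * np.sqrt(np.clip(lam[order], 0, None))


def prepare_cohort_trait(cohort, *, alpha: float = 0.05, n_pcs: int = 10, seed: int = 0):
    """Covariate adjustment, stepwise genetic-PC adjustment, INT.

    Returns (trait residual Series, info dict).
    """
    X = build_design(cohort.covariates)
    y = cohort.trait.to_numpy(dtype=float)
    resid = residualize(y, X)
    common = [v for v in cohort.variants if v.maf >= 0.05]
    retained: list[int] = []
    if common and n_pcs > 0:
        D = np.column_stack([v.dosages for v in common])
        pcs = genotype_pcs(D, n_pcs=n_pcs, seed=seed)
        resid, retained = stepwise_pc_adjust(resid, pcs, alpha=alpha)
    resid = inverse_normal_transform(resid)
    info = {"retained_pcs": [i + 1 for i in retained], "n_samples": len(y)}
    return pd.Series(resid, index=cohort.sample_ids), info


def analyze_cohort(
    cohort,
    trait_name: str = "trait",
    *,
    seed: int = 0,
    alpha: float = 0.05,
    window: int = 50_000,
    estimator: str = "pearson",
    empirical_null: bool = True,
    n_null: int = 10_000,
    run_enrichment: bool = True,
    run_ora: bool = True,
) -> PipelineResult:
    """Run the full single-cohort pipeline and return all stage outputs."""
    info: dict = {"trait": trait_name, "alpha": alpha, "window": window,
                  "estimator": estimator, "seed": seed}

    trait_resid, prep_info = prepare_cohort_trait(cohort, seed=seed)
    info["trait_prep"] = prep_info

    vm = fit_variance_model(trait_resid.to_numpy(), cohort.kinship.to_numpy())
    info["variance_components"] = {
        "sigma_g2": vm.sigma_g2, "sigma_e2": vm.sigma_e2,
    }

    # --- GWAS: per-variant scan on whitened data, then gene aggregation ---
    n = len(trait_resid)
    W = vm.U @ (vm.U.T / np.sqrt(vm.sigma_g2 * vm.d + vm.sigma_e2)[:, None])
    variants = cohort.variants
    D = np.vstack([v.dosages for v in variants])
    summary = single_variant_gwas(
        D,
        [v.variant_id for v in variants],
        [v.chrom for v in variants],
        [v.pos for v in variants],
        trait_resid.to_numpy(),
        whiten=W,
    )
    gwas_rows = run_gwas_aggregation(
        summary, cohort.genes, cohort.dosage_map, trait_name, window=window
    )
    info["n_variants_scanned"] = len(summary)

    # --- TWAS ---------------------------------------------------------------
    cov_design = pd.DataFrame(
        build_design(cohort.covariates), index=cohort.covariates.index
    )
    twas_rows, twas_info = twas_mod.run_twas(
        cohort.expression, trait_resid, trait_name, covariates=cov_design, vm=vm
    )
    info["twas"] = twas_info

    # --- RVA ----------------------------------------------------------------
    rva_rows = rva_mod.run_rva_all(
        cohort.genes,
        variants,
        cohort.categories,
        cohort.annotations,
        trait_resid.to_numpy(),
        vm,
        trait_name,
        window=window,
    )

    scores = pd.concat([gwas_rows, twas_rows, rva_rows], ignore_index=True)

    # --- CMA ----------------------------------------------------------------
    cma_res = cma_mod.run_cma(scores, alpha=alpha, estimator=estimator)
    cma_rows = cma_res.to_frame(trait_name)
    info["cma"] = {
        "total_tests": cma_res.total_tests,
        "threshold": cma_res.threshold,
        "n_significant": int(cma_res.significant.sum()),
        "correlations": {
            c: m.sigma.tolist() for c, m in cma_res.correlations.items()
        },
    }

    # --- module enrichment and GO ORA --------------------------------------
    enrichment_results: list = []
    ora_results: list = []
    if run_enrichment and len(cohort.modules):
        sources_per_gene: dict[str, set] = {}
        for _, row in scores.iterrows():
            sources_per_gene.setdefault(row["gene_id"], set()).add(row["source"])
        filtered = enr.filter_module_genes(cohort.modules, sources_per_gene)
        enrichment_results = enr.enrich_modules(
            filtered,
            cma_res.min_p,
            trait_name,
            empirical_null=empirical_null,
            n_null=n_null,
            seed=seed,
        )
        if run_ora and enrichment_results and len(cohort.go_sets):
            background = list(cma_res.min_p.index)
            top = enrichment_results[0]
            if top.p_corrected < alpha:
                ora_results = enr.go_ora(
                    list(top.member_minp), cohort.go_sets, background
                )
                ora_results = enr.prune_redundant_terms(ora_results)

    return PipelineResult(scores, cma_res, cma_rows, enrichment_results, ora_results, info)


def replicate_cohorts(
    discovery: PipelineResult,
    replication: PipelineResult,
    *,
    alpha: float = 0.05,
) -> dict:
    """Gene- and module-level replication calls between two cohorts.

    Gene-level thresholds divide alpha by the count of
    discovery-significant genes (GWAS, TWAS) or gene-category pairs (CMA);
    TWAS additionally reports direction-of-effect concordance. Module
    replication uses the count of discovery-enriched modules.
    """
    out: dict = {}
    thr_d = discovery.cma.threshold

    for src in ("GWAS", "TWAS"):
        disc = discovery.scores[discovery.scores["source"] == src]
        n_src = max(len(disc), 1)
        sig = disc[disc["p"] < alpha / n_src]
        rep = replication.scores[replication.scores["source"] == src]
        out[src.lower()] = cma_mod.replicate(sig, rep, mode="gene", alpha=alpha)

    disc_cma = discovery.cma_rows[
        (discovery.cma_rows["p"] < thr_d)
        & discovery.cma_rows["gene_id"].map(discovery.cma.significant)
    ]
    rep_cma = replication.cma_rows[["gene_id", "category", "p"]]
    out["cma"] = cma_mod.replicate(disc_cma, rep_cma, mode="cma", alpha=alpha)

    disc_mods = [r for r in discovery.enrichment if r.p_corrected < alpha]
    rep_by_name = {r.module: r for r in replication.enrichment}
    rows = []
    if disc_mods:
        thr = alpha / len(disc_mods)
        for r in disc_mods:
            rr = rep_by_name.get(r.module)
            rows.append(
                {
                    "module": r.module,
                    "p_replication": rr.p_raw if rr else np.nan,
                    "threshold": thr,
                    "replicated": bool(rr and rr.p_raw < thr),
                }
            )
    out["modules"] = pd.DataFrame(rows)
    return out


def load_cohort_inputs(paths: dict) -> CohortBundle:
    """Assemble a cohort bundle from input files (keys as written by the
    synthetic generator: vcf, genes, trait, covariates, kinship,
    expression, annotations, categories, modules, go)."""
    variants, vcf_samples = io_mod.read_vcf(paths["vcf"])
    genes = io_mod.read_gene_models(paths["genes"])
    trait = io_mod.read_table(paths["trait"], index_col="sample_id").iloc[:, 0]
    covariates = io_mod.read_table(paths["covariates"], index_col="sample_id")
    kinship = io_mod.read_kinship(paths["kinship"])
    expression = io_mod.read_table(paths["expression"], index_col="gene_id")
    annotations = io_mod.read_table(paths["annotations"], index_col="variant_id")
    categories = (
        io_mod.read_table(paths["categories"], index_col="variant_id")["category"].to_dict()
    )
    modules = io_mod.read_gmt(paths["modules"]) if "modules" in paths else io_mod.ModuleCollection()
    go_sets = io_mod.read_gmt(paths["go"]) if "go" in paths else io_mod.ModuleCollection()

    (trait, covariates, kinship_rows), order, dropped = io_mod.align_samples(
        trait, covariates, kinship
    )
    order_set = set(order)
    expr_cols = [c for c in expression.columns if c in order_set]
    kinship = kinship_rows[order]
    pos = {s: i for i, s in enumerate(vcf_samples)}
    take = [pos[s] for s in order]
    variants = [
        io_mod.VariantRecord(v.variant_id, v.chrom, v.pos, v.ref, v.alt, v.dosages[take])
        for v in variants
    ]
    return CohortBundle(
        order, genes, variants, kinship, covariates, trait,
        expression[expr_cols], annotations, categories, modules, go_sets,
    )


def run_all(config: dict, outdir) -> dict:
    """File-based pipeline driver (the CLI's run-all).

    ``config`` maps cohort name -> input paths, plus optional keys
    trait_name, alpha, window, estimator, empirical_null, n_null, seed.
    The first cohort is the discovery cohort; an optional second is the
    replication cohort. Writes stage TSVs and a manifest, returns result
    objects.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    opts = {
        k: config[k]
        for k in ("alpha", "window", "estimator", "empirical_null", "n_null", "seed")
        if k in config
    }
    trait_name = config.get("trait_name", "trait")
    cohort_names = [k for k in config if k not in
                    ("alpha", "window", "estimator", "empirical_null", "n_null",
                     "seed", "trait_name")]
    if not cohort_names:
        raise ValueError("config names no cohorts")

    results: dict[str, PipelineResult] = {}
    for name in cohort_names:
        bundle = load_cohort_inputs(config[name])
        res = analyze_cohort(bundle, trait_name, **opts)
        results[name] = res
        cdir = out / name
        cdir.mkdir(exist_ok=True)
        io_mod.write_gene_scores(res.scores, cdir / "gene_scores.tsv")
        res.cma_rows.to_csv(cdir / "cma_results.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"module": r.module, "trait": r.trait, "statistic": r.statistic,
                 "p_raw": r.p_raw, "p_corrected": r.p_corrected, "n_genes": r.n_genes}
                for r in res.enrichment
            ]
        ).to_csv(cdir / "module_enrichment.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"term": r.term, "overlap": r.overlap, "set_size": r.set_size,
                 "module_size": r.module_size, "background_size": r.background_size,
                 "p": r.p, "fdr": r.fdr}
                for r in res.ora
            ]
        ).to_csv(cdir / "go_ora.tsv", sep="\t", index=False)

    manifest = {"options": opts, "trait": trait_name,
                "cohorts": {n: results[n].info for n in results}}
    if len(cohort_names) >= 2:
        rep = replicate_cohorts(results[cohort_names[0]], results[cohort_names[1]])
        for key, df in rep.items():
            if isinstance(df, pd.DataFrame):
                df.to_csv(out / f"replication_{key}.tsv", sep="\t", index=False)
        manifest["replication_cohort"] = cohort_names[1]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
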