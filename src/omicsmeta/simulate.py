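"""Seeded synthetic-cohort generator.

Every pipeline stage consumes restricted individual-level data in the real
study, so this module builds a desk-scale cohort with the same statistical
structure: LD within gene-local variant blocks (latent Gaussian threshold
model with a one-factor equicorrelation), sib-pair relatedness realized by
sharing parental haplotypes, planted common-variant, expression, and
rare-variant effects on a quantitative trait, negative-binomial expression
counts, functional annotations informative for causal rare variants, and
gene-set layouts (PPI-style modules and GO terms) with one planted
enriched module.

The generator is fully deterministic under a fixed seed. It emulates the
*statistics* the pipeline assumes, not human genome content: no realistic
LD maps, population structure, or sequence context.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, ModuleCollection, RVA_CATEGORIES, VariantRecord, write_gmt

__all__ = ["PlantedGene", "SimConfig", "SyntheticCohort", "simulate_cohort", "write_cohort"]

GENE_SPACING = 210_000  # bp between gene starts; windows (+/-50 kb) stay disjoint
GENE_LENGTH = 10_000


@dataclass
class PlantedGene:
    """Effects planted on one gene.

    gwas_h2 / rva_h2 are trait-variance fractions explained by the gene's
    common-variant score / rare causal-variant burden; twas_beta is the
    trait effect per SD of the gene's latent expression.
    """

    gene_id: str
    gwas_h2: float = 0.0
    twas_beta: float = 0.0
    rva_h2: float = 0.0
    rva_category: str = "plof"


@dataclass
class SimConfig:
    seed: int = 0
    n_samples: int = 600
    n_genes: int = 300
    n_common: int = 5
    n_rare: int = 8
    rho_ld: float = 0.5
    common_maf: tuple = (0.05, 0.5)
    rare_maf: tuple = (0.005, 0.05)
    kinship: str = "sib_pairs"  # or "unrelated"
    polygenic_var: float = 0.2
    age_beta: float = 0.3
    sex_beta: float = 0.5
    noise_var: float = 1.0
    expr_dispersion: float = 0.1
    n_annotations: int = 6
    annotation_shift: float = 1.5
    n_modules: int = 100
    module_size: tuple = (5, 15)
    n_go_sets: int = 40
    go_size: tuple = (5, 25)
    planted: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in (self.n_samples, self.n_genes, self.n_common, self.n_rare):
            if c <= 0:
                raise ValueError("all counts must be positive")
        gene_ids = {f"G{i:04d}" for i in range(self.n_genes)}
        for pg in self.planted:
            if pg.gene_id not in gene_ids:
                raise ValueError(f"planted gene {pg.gene_id} outside the gene universe")
            if pg.rva_category not in RVA_CATEGORIES:
                raise ValueError(f"unknown RVA category {pg.rva_category}")


@dataclass
class SyntheticCohort:
    config: SimConfig
    sample_ids: list
    genes: list
    variants: list  # VariantRecord, common + rare
    kinship: pd.DataFrame
    covariates: pd.DataFrame  # age, sex, center
    trait: pd.Series  # raw trait values (pre-adjustment)
    expression: pd.DataFrame  # gene x sample counts
    annotations: pd.DataFrame  # rare-variant x annotation scores
    categories: dict  # rare-variant id -> functional category
    modules: ModuleCollection
    go_sets: ModuleCollection
    truth: dict

    @property
    def dosage_map(self) -> dict:
        return {v.variant_id: v.dosages for v in self.variants}


def _latent_rho(maf: float, target: float, _cache: dict = {}) -> float:
    """Latent-Gaussian correlation producing allele correlation ``target``.

    Thresholding attenuates correlation, so the latent factor must be
    stronger than the desired dosage-scale LD. Solved by bisection on the
    bivariate-normal quadrant probability; cached on rounded MAF.
    """
    if target <= 0:
        return 0.0
    key = (round(maf, 3), round(target, 3))
    if key in _cache:
        return _cache[key]
    tau = stats.norm.ppf(maf)

    def binary_corr(rho):
        p11 = stats.multivariate_normal(
            [0.0, 0.0], [[1.0, rho], [rho, 1.0]]
        ).cdf([tau, tau])
        return (p11 - maf**2) / (maf * (1.0 - maf))

    lo, hi = target, 1.0 - 1e-6
    if binary_corr(hi) < target:
        _cache[key] = hi
        return hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if binary_corr(mid) < target:
            lo = mid
        else:
            hi = mid
    _cache[key] = 0.5 * (lo + hi)
    return _cache[key]


def _sample_haplotypes(rng, n_samples: int, kinship: str):
    """Return (haplotype index pairs per sample, n_haplotypes, kinship K).

    Unrelated: 2 private haplotypes each. Sib pairs: 4 parental haplotypes
    per family; each sib independently inherits one maternal and one
    paternal haplotype (no recombination), giving expected kinship 1/4.
    """
    if kinship == "unrelated":
        hap_idx = np.arange(2 * n_samples).reshape(n_samples, 2)
        K = np.eye(n_samples) * 0.5
        return hap_idx, 2 * n_samples, K
    if kinship != "sib_pairs":
        raise ValueError(f"unknown kinship structure {kinship!r}")
    if n_samples % 2:
        raise ValueError("sib_pairs needs an even sample count")
    n_fam = n_samples // 2
    hap_idx = np.zeros((n_samples, 2), dtype=int)
    for f in range(n_fam):
        base = 4 * f
        for s in range(2):
            m = rng.integers(0, 2)
            p = rng.integers(0, 2)
            hap_idx[2 * f + s] = [base + m, base + 2 + p]
    K = np.eye(n_samples) * 0.5
    for f in range(n_fam):
        K[2 * f, 2 * f + 1] = K[2 * f + 1, 2 * f] = 0.25
    return hap_idx, 4 * n_fam, K


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    G = config.n_genes
    sample_ids = [f"S{i:05d}" for i in range(n)]
    hap_idx, n_hap, K = _sample_haplotypes(rng, n, config.kinship)

    genes = []
    for i in range(G):
        start = 1 + i * GENE_SPACING
        genes.append(GeneModel(f"G{i:04d}", "1", start, start + GENE_LENGTH - 1, "+"))

    planted = {pg.gene_id: pg for pg in config.planted}

    # --- genotypes: one-factor latent threshold model per gene block -------
    variants: list[VariantRecord] = []
    common_dosages = {}  # gene_id -> (n, n_common) matrix
    rare_dosages = {}  # gene_id -> (n, n_rare)
    rare_ids = {}
    for g in genes:
        c, r = config.n_common, config.n_rare
        # variants sharing an LD block share haplotype structure, so their
        # MAFs cluster around a block centre (disparate margins would cap
        # the achievable dosage correlation)
        centre = rng.uniform(*config.common_maf)
        maf_c = np.clip(centre * rng.uniform(0.8, 1.25, size=c), *config.common_maf)
        maf_r = rng.uniform(*config.rare_maf, size=r)
        # latent factor loading calibrated so the dosage-scale LD matches
        # rho_ld despite threshold attenuation
        rho_latent = _latent_rho(float(centre), config.rho_ld)
        sq = np.sqrt(rho_latent)
        sq1 = np.sqrt(1.0 - rho_latent)
        factor = rng.standard_normal((n_hap, 1))
        Zc = sq * factor + sq1 * rng.standard_normal((n_hap, c))
        Zr = rng.standard_normal((n_hap, r))
        alleles_c = Zc < stats.norm.ppf(maf_c)
        alleles_r = Zr < stats.norm.ppf(maf_r)
        dos_c = alleles_c[hap_idx[:, 0]].astype(float) + alleles_c[hap_idx[:, 1]]
        dos_r = alleles_r[hap_idx[:, 0]].astype(float) + alleles_r[hap_idx[:, 1]]
        common_dosages[g.gene_id] = dos_c
        rare_dosages[g.gene_id] = dos_r
        ids_r = []
        for j in range(c):
            vid = f"{g.gene_id}_c{j}"
            variants.append(
                VariantRecord(vid, g.chrom, g.start + 100 * (j + 1), "A", "G", dos_c[:, j])
            )
        for j in range(r):
            vid = f"{g.gene_id}_r{j}"
            ids_r.append(vid)
            variants.append(
                VariantRecord(vid, g.chrom, g.start + 5000 + 50 * (j + 1), "C", "T", dos_r[:, j])
            )
        rare_ids[g.gene_id] = ids_r

    # --- rare-variant categories and annotations ---------------------------
    categories: dict[str, str] = {}
    ann_rows = {}
    causal_rare: dict[str, list[str]] = {}
    for g in genes:
        pg = planted.get(g.gene_id)
        ids = rare_ids[g.gene_id]
        cats = rng.choice(RVA_CATEGORIES, size=len(ids))
        if pg is not None and pg.rva_h2 > 0:
            n_causal = max(2, len(ids) // 2)
            cats[:n_causal] = pg.rva_category
            causal_rare[g.gene_id] = ids[:n_causal]
        for vid, cat in zip(ids, cats):
            categories[vid] = str(cat)
            shift = (
                config.annotation_shift
                if vid in causal_rare.get(g.gene_id, ())
                else 0.0
            )
            ann_rows[vid] = rng.standard_normal(config.n_annotations) + shift
    annotations = pd.DataFrame.from_dict(ann_rows, orient="index")
    annotations.columns = [f"ann{j + 1}" for j in range(config.n_annotations)]
    annotations.index.name = "variant_id"

    # --- covariates ---------------------------------------------------------
    age = rng.uniform(30, 90, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    center = rng.integers(0, 3, size=n).astype(float)
    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "center": center}, index=sample_ids
    )

    # --- latent expression and trait ---------------------------------------
    def _std(x):
        s = x.std()
        return (x - x.mean()) / (s if s > 0 else 1.0)

    latent_expr = rng.standard_normal((G, n))
    y = np.zeros(n)
    for g in genes:
        pg = planted.get(g.gene_id)
        if pg is None:
            continue
        if pg.gwas_h2 > 0:
            score = common_dosages[g.gene_id].sum(axis=1)
            y += np.sqrt(pg.gwas_h2) * _std(score)
        if pg.twas_beta != 0.0:
            gi = int(g.gene_id[1:])
            y += pg.twas_beta * latent_expr[gi]
        if pg.rva_h2 > 0:
            idx = [rare_ids[g.gene_id].index(v) for v in causal_rare[g.gene_id]]
            burden = rare_dosages[g.gene_id][:, idx].sum(axis=1)
            if burden.std() > 0:
                y += np.sqrt(pg.rva_h2) * _std(burden)
    y += config.age_beta * _std(age) + config.sex_beta * sex
    if config.polygenic_var > 0:
        L = np.linalg.cholesky(2 * K + 1e-8 * np.eye(n))
        y += np.sqrt(config.polygenic_var) * (L @ rng.standard_normal(n))
    y += np.sqrt(config.noise_var) * rng.standard_normal(n)
    trait = pd.Series(y, index=sample_ids, name="trait")

    # --- expression counts: NB around library-size * baseline * 2^latent ---
    lib = rng.uniform(0.8e6, 1.2e6, size=n)
    base = np.exp(rng.normal(np.log(50e-6), 1.0, size=G))  # per-read rate
    mu = lib[None, :] * base[:, None] * np.power(2.0, 0.5 * latent_expr)
    disp = config.expr_dispersion
    # NB via gamma-Poisson mixture: shape 1/disp, mean mu
    counts = rng.poisson(mu * rng.gamma(1.0 / disp, disp, size=mu.shape))
    expression = pd.DataFrame(
        counts, index=[g.gene_id for g in genes], columns=sample_ids
    )

    # --- modules and GO sets ------------------------------------------------
    gene_ids = [g.gene_id for g in genes]
    planted_effect_genes = [
        pg.gene_id
        for pg in config.planted
        if pg.gwas_h2 > 0 or pg.twas_beta != 0 or pg.rva_h2 > 0
    ]
    # null modules are drawn from genes without planted effects so that the
    # planted/null contrast is clean; the planted module holds the planted
    # genes plus fillers up to the minimum module size
    null_genes = [g for g in gene_ids if g not in set(planted_effect_genes)]
    sets = {}
    for m in range(config.n_modules):
        size = int(rng.integers(config.module_size[0], config.module_size[1] + 1))
        size = min(size, len(null_genes))
        sets[f"M{m:03d}"] = list(rng.choice(null_genes, size=size, replace=False))
    planted_module = None
    if planted_effect_genes:
        n_fill = max(0, config.module_size[0] - len(planted_effect_genes))
        extra = list(rng.choice(null_genes, size=n_fill, replace=False))
        planted_module = "M_planted"
        sets[planted_module] = planted_effect_genes + extra
    modules = ModuleCollection(sets, provenance="synthetic-ppi")

    go = {}
    for t in range(config.n_go_sets):
        size = int(rng.integers(config.go_size[0], config.go_size[1] + 1))
        size = min(size, len(gene_ids))
        go[f"GO:{t:07d}"] = list(rng.choice(gene_ids, size=size, replace=False))
    planted_go = None
    if planted_module:
        planted_go = "GO:planted"
        go[planted_go] = list(sets[planted_module])
    go_sets = ModuleCollection(go, provenance="synthetic-go")

    kinship = pd.DataFrame(K, index=sample_ids, columns=sample_ids)
    truth = {
        "planted": [asdict(pg) for pg in config.planted],
        "planted_module": planted_module,
        "planted_go": planted_go,
        "causal_rare": causal_rare,
    }
    return SyntheticCohort(
        config,
        sample_ids,
        genes,
        variants,
        kinship,
        covariates,
        trait,
        expression,
        annotations,
        categories,
        modules,
        go_sets,
        truth,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write the cohort in the pipeline's input formats; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    vcf = out / "genotypes.vcf"
    _write_vcf(cohort, vcf)
    paths["vcf"] = vcf

    genes = pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start,
             "end": g.end, "strand": g.strand}
            for g in cohort.genes
        ]
    )
    paths["genes"] = out / "genes.tsv"
    genes.to_csv(paths["genes"], sep="\t", index=False)

    paths["trait"] = out / "trait.tsv"
    cohort.trait.rename_axis("sample_id").reset_index().to_csv(
        paths["trait"], sep="\t", index=False
    )
    paths["covariates"] = out / "covariates.tsv"
    cohort.covariates.rename_axis("sample_id").reset_index().to_csv(
        paths["covariates"], sep="\t", index=False
    )
    paths["kinship"] = out / "kinship.tsv"
    cohort.kinship.to_csv(paths["kinship"], sep="\t")
    paths["expression"] = out / "expression_counts.tsv"
    cohort.expression.rename_axis("gene_id").to_csv(paths["expression"], sep="\t")
    paths["annotations"] = out / "annotations.tsv"
    cohort.annotations.to_csv(paths["annotations"], sep="\t")
    paths["categories"] = out / "categories.tsv"
    pd.Series(cohort.categories, name="category").rename_axis("variant_id").reset_index().to_csv(
        paths["categories"], sep="\t", index=False
    )
    paths["modules"] = out / "modules.gmt"
    write_gmt(cohort.modules, paths["modules"])
    paths["go"] = out / "go_sets.gmt"
    write_gmt(cohort.go_sets, paths["go"])
    return paths


def _write_vcf(cohort: SyntheticCohort, path) -> None:
    samples = cohort.sample_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for v in sorted(cohort.variants, key=lambda v: v.pos):
            gts = [
                "./." if np.isnan(d) else codes[float(d)] for d in v.dosages
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
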