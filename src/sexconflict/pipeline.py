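"""End-to-end pipeline driver.

Runs expression classification, genotype-likelihood population genetics,
intersexual F_ST, gene-class statistics and the phylogenetic comparative
analysis from a single config, writing tidy TSVs, a run manifest and a
human-readable report. Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .expression import classify_expression, exclude_flagged_genes
from .fst import elevated_fst_count_test, gene_fst_table
from .io import FLOAT_FORMAT, read_beagle, read_gene_map, read_sample_sheet
from .pgls import pgls_fit
from .popgen import (
    GenotypeLikelihoodTable,
    estimate_sfs_em,
    filter_sites,
    saf_likelihoods,
    site_posteriors,
    tajima_constants,
    tajimas_d,
)
from .stats import (
    covariate_regression,
    flag_top_quantile,
    permutation_enrichment,
    polynomial_sexbias_fit,
    relative_tajimas_d,
    wilcoxon_contrast,
    z_subsampling_test,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "gene_popgen_table"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """All thresholds and switches of one pipeline run."""

    dataset_dir: str
    outdir: str
    seed: int = 0
    fpkm_min: float = 2.0
    tissue_lfc: float = 2.0
    sex_lfc: float = 1.0
    top_quantile: float = 0.10
    n_perm: int = 1000
    n_subsample: int = 1000
    classification_sex: str = "male"
    include_z: bool = True
    exclude_immune: bool = True
    exclude_sex_biased_for_fst: bool = True
    run_comparative: bool = True

    def __post_init__(self) -> None:
        for name in ("fpkm_min", "tissue_lfc", "sex_lfc", "top_quantile"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.classification_sex not in ("male", "female"):
            raise ValueError("classification_sex must be 'male' or 'female'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**d)


def _species_dirs(dataset_dir: Path) -> dict[str, Path]:
    dirs = sorted(p for p in dataset_dir.iterdir() if p.is_dir() and p.name.startswith("species_"))
    if not dirs:
        raise FileNotFoundError(f"no species_* directories under {dataset_dir}")
    return {p.name.removeprefix("species_"): p for p in dirs}


def _validate_inputs(config: PipelineConfig) -> dict[str, Path]:
    root = Path(config.dataset_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {root}")
    species = _species_dirs(root)
    for sp, d in species.items():
        for name in ("gl.beagle", "counts.tsv", "samples.tsv", "annotation.tsv", "genemap.tsv"):
            if not (d / name).exists():
                raise FileNotFoundError(f"species {sp}: missing {name}")
    if config.run_comparative:
        for name in ("tree.nwk", "traits.tsv"):
            if not (root / name).exists():
                raise FileNotFoundError(
                    f"comparative analysis enabled but {name} missing from {root}"
                )
    return species


def gene_popgen_table(
    table: GenotypeLikelihoodTable, genemap: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Per-gene theta and Tajima's D for one species.

    Autosomal genes use all individuals; Z-linked genes use males only
    (the Z is haploid in female birds, so female genotype likelihoods
    would violate the diploid model). Each chromosome class gets its own
    SFS estimated over all its retained sites, which then serves as the
    prior for per-site allele-frequency posteriors.
    """
    class_by_gene = genemap.set_index("gene")["chrom_class"]
    records = []
    sfs_by_class = {}
    for chrom_class in ("A", "Z"):
        gene_mask = class_by_gene.reindex(table.genes).to_numpy() == chrom_class
        if not gene_mask.any():
            continue
        sub = table.subset_sites(gene_mask)
        if chrom_class == "Z":
            sub = sub.subset_individuals(sub.sexes == "M")
        sub = filter_sites(sub, per_sex=False)
        if sub.n_sites == 0:
            continue
        two_n = 2 * sub.n_individuals
        saf = saf_likelihoods(sub.gl)
        sfs = estimate_sfs_em(saf)
        sfs_by_class[chrom_class] = sfs
        post = site_posteriors(saf, sfs)
        ok = ~np.isnan(post).any(axis=1)
        post, genes_here = post[ok], sub.genes[ok]
        a1 = tajima_constants(two_n)["a1"]
        p_var = np.clip(1.0 - post[:, 0] - post[:, -1], 0.0, 1.0)
        j = np.arange(two_n + 1, dtype=float)
        pi_site = post @ (j * (two_n - j) / (two_n * (two_n - 1) / 2.0))
        per_site = pd.DataFrame({"gene": genes_here, "p_var": p_var, "pi": pi_site})
        agg = per_site.groupby("gene", sort=False).agg(
            s_eff=("p_var", "sum"), theta_pi=("pi", "sum"), n_sites=("p_var", "size")
        )
        agg["theta_w"] = agg["s_eff"] / a1
        agg["tajimas_d"] = [
            tajimas_d(row.theta_w, row.theta_pi, row.s_eff, two_n)
            for row in agg.itertuples()
        ]
        agg["chrom_class"] = chrom_class
        records.append(agg.reset_index())
    if not records:
        raise ValueError("no sites survived filtering in any chromosome class")
    return pd.concat(records, ignore_index=True), sfs_by_class


def _to_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _species_stage(config: PipelineConfig, sp: str, spdir: Path) -> dict:
    counts = pd.read_csv(spdir / "counts.tsv", sep="\t", index_col="gene")
    samples = read_sample_sheet(spdir / "samples.tsv")
    annotation = pd.read_csv(spdir / "annotation.tsv", sep="\t")
    genemap = read_gene_map(spdir / "genemap.tsv")

    expr = classify_expression(
        counts,
        samples,
        annotation,
        classification_sex=config.classification_sex,
        fpkm_min=config.fpkm_min,
        tissue_threshold=config.tissue_lfc,
        sex_threshold=config.sex_lfc,
    )
    analysed = expr.index
    if config.exclude_immune:
        analysed = exclude_flagged_genes(analysed, annotation)
    expr = expr.loc[analysed]

    gl_table = read_beagle(spdir / "gl.beagle", samples)
    keep_sites = np.isin(gl_table.genes, analysed.to_numpy())
    gl_table = gl_table.subset_sites(keep_sites)
    popgen, _ = gene_popgen_table(gl_table, genemap)
    popgen = popgen[popgen["gene"].isin(analysed)]

    # intersexual F_ST: autosomes only, per-sex missingness filter
    ann_idx = annotation.set_index("gene")
    auto_genes = ann_idx.index[(ann_idx["chrom_class"] == "A")]
    fst_table = gl_table.subset_sites(np.isin(gl_table.genes, auto_genes))
    fst_table = filter_sites(fst_table, per_sex=True)
    fst = (
        gene_fst_table(fst_table).reset_index()
        if fst_table.n_sites > 0
        else pd.DataFrame(columns=["gene", "fst", "n_sites"])
    )

    gene_table = (
        popgen.merge(expr.reset_index(), on="gene", how="inner")
        .merge(ann_idx[["length_bp", "gc_fraction"]].reset_index(), on="gene", how="left")
        .merge(fst[["gene", "fst"]], on="gene", how="left")
        .rename(columns={"mean_cpm": "mean_expr"})
    )
    gene_table.insert(0, "species", sp)
    return {"gene_table": gene_table, "expr": expr}


def _class_contrasts(gene_table: pd.DataFrame, sp: str, seed: int) -> pd.DataFrame:
    """Relative D and Wilcoxon contrasts for each tissue class."""
    auto = gene_table[gene_table["chrom_class"] == "A"]
    rows = []
    for cls in ("gonad-biased", "spleen-biased"):
        for subset, label in ((auto, "all"), (auto[auto["sex_class"] == "unbiased"], "unbiased_only")):
            vals = subset.loc[subset["tissue_class"] == cls, "tajimas_d"].dropna()
            bg_vals = subset.loc[
                subset["tissue_class"] == "non-tissue-biased", "tajimas_d"
            ].dropna()
            if len(vals) == 0 or len(bg_vals) == 0:
                continue
            stat, p = wilcoxon_contrast(vals, bg_vals)
            rows.append(
                {
                    "species": sp,
                    "stage": "stats",
                    "seed": seed,
                    "tissue_class": cls,
                    "gene_subset": label,
                    "n_class": len(vals),
                    "n_background": len(bg_vals),
                    "relative_d": relative_tajimas_d(vals, bg_vals),
                    "wilcoxon_stat": stat,
                    "wilcoxon_p": p,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write results under ``config.outdir``.

    Stage failures raise :class:`PipelineError` naming the stage; partial
    outputs written before the failure are retained next to a ``FAILED``
    marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    try:
        species_dirs = _validate_inputs(config)
    except Exception as exc:
        raise PipelineError("validate", str(exc)) from exc

    root = Path(config.dataset_dir)
    per_species = {}
    stage = "per-species"
    try:
        for sp, spdir in species_dirs.items():
            per_species[sp] = _species_stage(config, sp, spdir)
    except Exception as exc:
        failed_marker.write_text(f"{stage}: {exc}\n")
        raise PipelineError(stage, str(exc)) from exc

    report_lines = [f"sexconflict pipeline v{__version__}", ""]
    try:
        stage = "stats"
        gene_tables = pd.concat(
            [d["gene_table"] for d in per_species.values()], ignore_index=True
        )
        gene_tables["stage"] = "popgen"
        gene_tables["seed"] = config.seed
        _to_tsv(gene_tables, outdir / "gene_table.tsv")

        contrasts = pd.concat(
            [
                _class_contrasts(d["gene_table"], sp, config.seed)
                for sp, d in per_species.items()
            ],
            ignore_index=True,
        )
        _to_tsv(contrasts, outdir / "class_contrasts.tsv")

        reg_rows, poly_rows, fst_rows = [], [], []
        for sp, d in per_species.items():
            auto = d["gene_table"][d["gene_table"]["chrom_class"] == "A"]
            try:
                reg = covariate_regression(auto)
                reg.insert(0, "species", sp)
                reg_rows.append(reg)
            except ValueError:
                pass
            for cls in ("gonad-biased", "spleen-biased"):
                sub = auto[auto["tissue_class"] == cls]
                if len(sub) > 4:
                    coef, r2 = polynomial_sexbias_fit(
                        sub["tajimas_d"], sub["log2fc_sex"], degree=2
                    )
                    poly_rows.append(
                        {
                            "species": sp,
                            "stage": "stats",
                            "seed": config.seed,
                            "tissue_class": cls,
                            "n_genes": len(sub),
                            "r2": r2,
                            **{f"coef{i}": c for i, c in enumerate(coef)},
                        }
                    )
            fst_pool = auto
            if config.exclude_sex_biased_for_fst:
                fst_pool = auto[auto["sex_class"] == "unbiased"]
            bg_fst = fst_pool.loc[
                fst_pool["tissue_class"] == "non-tissue-biased", "fst"
            ].dropna()
            for cls in ("gonad-biased", "spleen-biased"):
                focal = fst_pool.loc[fst_pool["tissue_class"] == cls, "fst"].dropna()
                if len(focal) == 0 or len(bg_fst) == 0:
                    continue
                expected, observed, p = elevated_fst_count_test(focal, bg_fst)
                fst_rows.append(
                    {
                        "species": sp,
                        "stage": "fst",
                        "seed": config.seed,
                        "tissue_class": cls,
                        "expected": expected,
                        "observed": observed,
                        "chi2_p": p,
                    }
                )
        if reg_rows:
            regs = pd.concat(reg_rows, ignore_index=True)
            regs["stage"] = "stats"
            regs["seed"] = config.seed
            _to_tsv(regs, outdir / "covariate_regression.tsv")
        _to_tsv(pd.DataFrame(poly_rows), outdir / "polynomial_sexbias.tsv")
        _to_tsv(pd.DataFrame(fst_rows), outdir / "fst_count_test.tsv")

        # cross-species: orthologues present (with D) in every species
        stage = "enrichment"
        auto_tables = gene_tables[gene_tables["chrom_class"] == "A"]
        d_wide = auto_tables.pivot_table(
            index="gene", columns="species", values="tajimas_d", aggfunc="first"
        ).dropna()
        enrich_rows = []
        if len(d_wide) >= 10:
            flags = flag_top_quantile(d_wide, config.top_quantile)
            sex_wide = auto_tables.pivot_table(
                index="gene",
                columns="species",
                values="sex_class_gonad",
                aggfunc="first",
            ).reindex(d_wide.index)
            universal_sex_biased = (sex_wide != "unbiased").all(axis=1)
            universal_unbiased = (sex_wide == "unbiased").all(axis=1)
            for label, members in (
                ("universally_sex_biased", universal_sex_biased),
                ("universally_unbiased", universal_unbiased),
            ):
                if members.sum() == 0:
                    continue
                res = permutation_enrichment(
                    flags["universal"].to_numpy(),
                    members.to_numpy(),
                    n_perm=config.n_perm,
                    seed=config.seed,
                )
                enrich_rows.append(
                    {
                        "stage": "enrichment",
                        "seed": config.seed,
                        "gene_class": label,
                        "n_class": int(members.sum()),
                        "n_orthologues": len(d_wide),
                        "n_universal_elevated": int(flags["universal"].sum()),
                        "observed": res.observed,
                        "perm_mean": res.perm_mean,
                        "empirical_p": res.empirical_p,
                        "chi2_p": res.chi2_p,
                    }
                )
        _to_tsv(pd.DataFrame(enrich_rows), outdir / "enrichment.tsv")

        # comparative stage
        stage = "comparative"
        if config.run_comparative:
            newick = (root / "tree.nwk").read_text().strip()
            traits = pd.read_csv(root / "traits.tsv", sep="\t")
            rel_rows = []
            for sp, d in per_species.items():
                auto = d["gene_table"][d["gene_table"]["chrom_class"] == "A"]
                unb = auto[auto["sex_class"] == "unbiased"]
                for label, subset in (("all", auto), ("unbiased_only", unb)):
                    for cls, col in (
                        ("gonad-biased", "relative_d_gonad"),
                        ("spleen-biased", "relative_d_spleen"),
                    ):
                        vals = subset.loc[subset["tissue_class"] == cls, "tajimas_d"].dropna()
                        bg = subset.loc[
                            subset["tissue_class"] == "non-tissue-biased", "tajimas_d"
                        ].dropna()
                        if len(vals) and len(bg):
                            rel_rows.append(
                                {
                                    "species": sp,
                                    "gene_subset": label,
                                    "measure": col,
                                    "value": relative_tajimas_d(vals, bg),
                                }
                            )
            rel = pd.DataFrame(rel_rows)
            _to_tsv(rel, outdir / "relative_d.tsv")
            pgls_rows = []
            from .pgls import tip_order

            tips = tip_order(newick)
            for subset in ("unbiased_only", "all"):
                for measure in ("relative_d_gonad", "relative_d_spleen"):
                    y_by_sp = (
                        rel[(rel["gene_subset"] == subset) & (rel["measure"] == measure)]
                        .set_index("species")["value"]
                    )
                    if not set(tips) <= set(y_by_sp.index):
                        continue
                    y = y_by_sp.loc[tips].to_numpy()
                    for trait in ("dichromatism_score", "sperm_number", "residual_testes_mass"):
                        x = traits.set_index("species")[trait].loc[tips].to_numpy()
                        fit = pgls_fit(y, x, newick, lambda_mode="ML", taxa=tips)
                        pgls_rows.append(
                            {
                                "stage": "comparative",
                                "seed": config.seed,
                                "gene_subset": subset,
                                "measure": measure,
                                "trait": trait,
                                "slope": fit.slope,
                                "intercept": fit.intercept,
                                "r2": fit.r2,
                                "p": fit.p,
                                "lambda_hat": fit.lambda_hat,
                                "loglik": fit.loglik,
                            }
                        )
            _to_tsv(pd.DataFrame(pgls_rows), outdir / "pgls.tsv")

            # Z-vs-autosome subsampling (needs Z tissue-biased genes everywhere)
            auto_all = gene_tables[gene_tables["chrom_class"] == "A"]
            z_all = gene_tables[gene_tables["chrom_class"] == "Z"]
            z_rows = []
            if config.include_z and len(z_all):
                try:
                    zres = z_subsampling_test(
                        auto_all,
                        z_all,
                        traits,
                        trait="dichromatism_score",
                        n_rep=config.n_subsample,
                        seed=config.seed,
                    )
                    z_rows.append(
                        {
                            "stage": "comparative",
                            "seed": config.seed,
                            "trait": "dichromatism_score",
                            "observed_r": zres["observed_r"],
                            "observed_slope": zres["observed_slope"],
                            "p_r": zres["p_r"],
                            "p_slope": zres["p_slope"],
                            "n_rep": zres["n_rep"],
                        }
                    )
                except ValueError as exc:
                    report_lines.append(f"Z subsampling skipped: {exc}")
            _to_tsv(pd.DataFrame(z_rows), outdir / "z_subsampling.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        failed_marker.write_text(f"{stage}: {exc}\n")
        raise PipelineError(stage, str(exc)) from exc

    cfg = asdict(config)
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": cfg_hash,
        "species": sorted(species_dirs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    report_lines.append(f"species analysed: {', '.join(sorted(species_dirs))}")
    report_lines.append(f"genes in joint orthologue set: {len(d_wide)}")
    for _, row in contrasts.iterrows():
        report_lines.append(
            f"{row['species']} {row['tissue_class']} ({row['gene_subset']}): "
            f"relative D = {row['relative_d']:+.3f}, Wilcoxon p = {row['wilcoxon_p']:.3g}"
        )
    (outdir / "report.txt").write_text("\n".join(report_lines) + "\n")
    return outdir
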