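"""Study-condition evaluation experiments.

Self-contained experiments that measure the package's statistical
behaviour under the simulated study conditions: oracle agreement for the
SAF recursion, Tajima's D and Hudson's F_ST; EM recovery of the SFS and
of inbreeding coefficients; directional recovery of planted
balancing-selection structure; null calibration of the intersexual F_ST
count test, the permutation enrichment and the PGLS slope test; and
PGLS parameter recovery. The acceptance script and the acceptance test
suite both run these.

Each experiment takes a seed and returns plain numbers; problem sizes
are fixed at desk scale (a few hundred genes, tens of sites per gene,
ten individuals) so that the full battery completes in minutes.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.special import comb

from .config import SimulationConfig, rng_for
from .expression import classify_expression
from .fst import elevated_fst_count_test, gene_fst_table, hudson_site
from .pgls import brownian_covariance, pgls_fit, tip_order
from .pipeline import gene_popgen_table
from .popgen import (
    GenotypeLikelihoodTable,
    estimate_inbreeding_em,
    estimate_sfs_em,
    filter_sites,
    gene_thetas,
    saf_likelihoods,
    site_posteriors,
    tajima_constants,
    tajimas_d,
)
from .simulate import (
    simulate_dataset,
    simulate_genotype_likelihoods,
    simulate_genotypes,
    simulate_phylogeny_traits,
    simulate_sfs_shape,
)
from .stats import permutation_enrichment, relative_tajimas_d, wilcoxon_contrast

__all__ = [
    "saf_enumeration_error",
    "tajima_textbook_error",
    "hudson_toy_error",
    "sfs_recovery",
    "inbreeding_recovery_error",
    "balancing_vs_neutral_wins",
    "gonad_relative_d_runs",
    "fst_null_rejection_rate",
    "permutation_hypergeometric_error",
    "pgls_type1_rate",
    "pgls_slope_recovery",
    "pgls_lambda_zero_ols_diff",
    "coupled_slope_positive_fraction",
]


# ----------------------------------------------------------------- oracles


def saf_enumeration_error(seed: int, n_sites: int = 5) -> float:
    """Max |SAF DP - brute-force enumeration| over random sites, N <= 3."""
    rng = rng_for(seed, "saf_enum")
    worst = 0.0
    for n_ind in (1, 2, 3):
        gl = rng.random((n_sites, n_ind, 3))
        h = saf_likelihoods(gl)
        for s in range(n_sites):
            brute = np.zeros(2 * n_ind + 1)
            for genotypes in itertools.product(range(3), repeat=n_ind):
                j = sum(genotypes)
                brute[j] += np.prod(
                    [gl[s, i, g] * comb(2, g) for i, g in enumerate(genotypes)]
                )
            brute /= comb(2 * n_ind, np.arange(2 * n_ind + 1))
            brute /= brute.max()
            worst = max(worst, float(np.max(np.abs(brute - h[s]))))
    return worst


def tajima_textbook_error(seed: int, n_sites: int = 300, n_ind: int = 10) -> float:
    """|pipeline D - classic D| on hard-called genotypes."""
    rng = rng_for(seed, "tajima_oracle")
    two_n = 2 * n_ind
    geno = rng.integers(0, 3, size=(n_sites, n_ind))
    saf = saf_likelihoods(np.eye(3)[geno])
    post = site_posteriors(saf, estimate_sfs_em(saf))
    tw, tp, seff = gene_thetas(post)
    d_pipeline = tajimas_d(tw, tp, seff, two_n)
    j = geno.sum(axis=1)
    seg = (j > 0) & (j < two_n)
    s = int(seg.sum())
    c = tajima_constants(two_n)
    pi = float(np.sum(2.0 * j[seg] * (two_n - j[seg]) / (two_n * (two_n - 1))))
    d_classic = (pi - s / c["a1"]) / np.sqrt(c["e1"] * s + c["e2"] * s * (s - 1))
    return abs(d_pipeline - d_classic)


def hudson_toy_error() -> float:
    """Max deviation of Hudson site/gene F_ST from hand arithmetic."""
    errors = []
    c = hudson_site(1.0, 0.0, 10, 10)
    errors += [abs(c.n_hat - 1.0), abs(c.d_hat - 1.0)]
    c = hudson_site(0.5, 0.5, 10, 10)
    errors += [abs(c.n_hat - (-0.25 / 9 * 2)), abs(c.d_hat - 0.5)]
    from .fst import FstSiteComponents, gene_fst

    g = gene_fst([FstSiteComponents(1.0, 1.0), FstSiteComponents(-0.05, 0.5)])
    errors.append(abs(g - 0.95 / 1.5))
    return float(max(errors))


# ------------------------------------------------------------ EM recovery


def sfs_recovery(
    seed: int,
    n_sites: int = 500,
    n_ind: int = 5,
    depth: float = 20.0,
    error_rate: float = 0.01,
) -> dict:
    """SFS EM on simulated sites: total-variation distance to the realised
    sample spectrum, plus the worst log-likelihood decrease (monotonicity)."""
    rng = rng_for(seed, "sfs_recovery")
    two_n = 2 * n_ind
    shape = simulate_sfs_shape(two_n, 0.0)
    j_true = rng.choice(np.arange(1, two_n), p=shape, size=n_sites)
    freqs = j_true / two_n
    geno = simulate_genotypes(freqs, n_ind, 0.0, rng)
    gl, _ = simulate_genotype_likelihoods(geno, depth, error_rate, rng)
    sfs = estimate_sfs_em(saf_likelihoods(gl))
    realised = np.bincount(geno.sum(axis=1), minlength=two_n + 1) / n_sites
    tv = 0.5 * float(np.abs(sfs.xi - realised).sum())
    diffs = np.diff(sfs.loglik_trace)
    worst_drop = float(-diffs.min()) if len(diffs) else 0.0
    return {"tv": tv, "worst_loglik_drop": worst_drop, "monotone": sfs.monotone}


def inbreeding_recovery_error(
    seed: int, f_true: float = 0.3, n_sites: int = 1000, depth: float = 20.0
) -> float:
    """Mean |F_hat - F| over individuals at deep coverage."""
    rng = rng_for(seed, "inbreeding")
    p = rng.uniform(0.1, 0.9, n_sites)
    geno = simulate_genotypes(p, 5, f_true, rng)
    gl, _ = simulate_genotype_likelihoods(geno, depth, 0.01, rng)
    f_hat = estimate_inbreeding_em(gl, p)
    return float(np.mean(np.abs(f_hat - f_true)))


# ----------------------------------------------------- directional signal


def _median_d(strength: float, rng: np.random.Generator, n_genes: int = 100,
              sites_per_gene: int = 30, n_ind: int = 10, depth: float = 10.0) -> float:
    two_n_pop = 4 * n_ind
    shape = simulate_sfs_shape(two_n_pop, strength)
    j = rng.choice(np.arange(1, two_n_pop), p=shape, size=n_genes * sites_per_gene)
    geno = simulate_genotypes(j / two_n_pop, n_ind, 0.0, rng)
    gl, _ = simulate_genotype_likelihoods(geno, depth, 0.01, rng)
    saf = saf_likelihoods(gl)
    post = site_posteriors(saf, estimate_sfs_em(saf))
    two_n = 2 * n_ind
    d_vals = []
    for g in range(n_genes):
        tw, tp, seff = gene_thetas(post[g * sites_per_gene : (g + 1) * sites_per_gene])
        d_vals.append(tajimas_d(tw, tp, seff, two_n))
    return float(np.nanmedian(d_vals))


def balancing_vs_neutral_wins(seed: int, n_runs: int = 20, strength: float = 4.0) -> dict:
    """Paired runs: does the balancing configuration beat neutral?"""
    wins = 0
    neutral_medians = []
    for rep in range(n_runs):
        rng_b = rng_for(seed, f"balancing:{rep}")
        rng_n = rng_for(seed, f"neutral:{rep}")
        mb = _median_d(strength, rng_b)
        mn = _median_d(0.0, rng_n)
        neutral_medians.append(mn)
        wins += mb > mn
    return {
        "win_fraction": wins / n_runs,
        "neutral_mean_median_d": float(np.mean(neutral_medians)),
        "n_runs": n_runs,
    }


def gonad_relative_d_runs(seed: int, n_runs: int = 20) -> dict:
    """Plant resolved conflict in the gonad (gonad-biased genes neutral,
    unbiased genes under balancing selection) and check the pipeline
    recovers negative relative D with a significant Wilcoxon contrast."""
    successes = 0
    rel_ds = []
    for rep in range(n_runs):
        cfg = SimulationConfig(
            n_species=2,
            n_genes=120,
            sites_per_gene=30,
            balancing_fraction=1.0,
            balancing_strength=4.0,
            coupling=0.0,
            seed=seed * 1009 + rep,
        )
        ds = simulate_dataset(cfg)
        sp = next(iter(ds.species))
        data = ds.species[sp]
        ann = ds.genes[["gene", "chrom_class", "length_bp", "gc_fraction", "immune_flag"]]
        expr = classify_expression(data["counts"], data["samples"], ann)
        popgen, _ = gene_popgen_table(data["gl_table"], data["genemap"])
        table = popgen.merge(expr.reset_index(), on="gene")
        auto = table[table["chrom_class"] == "A"]
        gonad = auto.loc[auto["tissue_class"] == "gonad-biased", "tajimas_d"].dropna()
        bg = auto.loc[auto["tissue_class"] == "non-tissue-biased", "tajimas_d"].dropna()
        rel = relative_tajimas_d(gonad, bg)
        _, p = wilcoxon_contrast(gonad, bg)
        rel_ds.append(rel)
        successes += (rel < 0) and (p < 0.01)
    return {
        "success_fraction": successes / n_runs,
        "mean_relative_d": float(np.mean(rel_ds)),
        "n_runs": n_runs,
    }


# --------------------------------------------------------- null calibration


def fst_null_rejection_rate(
    seed: int, n_reps: int = 200, n_genes: int = 300, sites_per_gene: int = 25
) -> dict:
    """With sexes as arbitrary labels, the elevated-F_ST count test should
    reject at its nominal level."""
    rejections = 0
    for rep in range(n_reps):
        rng = rng_for(seed, f"fst_null:{rep}")
        n_ind = 10
        freqs = rng.uniform(0.05, 0.95, n_genes * sites_per_gene)
        geno = simulate_genotypes(freqs, n_ind, 0.0, rng)
        gl, dep = simulate_genotype_likelihoods(geno, 8.0, 0.01, rng)
        genes = np.repeat([f"g{i}" for i in range(n_genes)], sites_per_gene)
        pos = np.tile(np.arange(1, sites_per_gene + 1), n_genes)
        table = GenotypeLikelihoodTable(
            markers=np.array([f"{a}_{b}" for a, b in zip(genes, pos)]),
            genes=genes,
            positions=pos,
            gl=gl,
            has_data=dep > 0,
            sexes=np.array(["M"] * 5 + ["F"] * 5),
            individuals=np.array([f"i{k}" for k in range(n_ind)]),
        )
        table = filter_sites(table, per_sex=True)
        fst = gene_fst_table(table)["fst"].to_numpy()
        k = len(fst) // 3  # arbitrary focal/background split
        _, _, p = elevated_fst_count_test(fst[:k], fst[k:])
        rejections += p < 0.05
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def permutation_hypergeometric_error(seed: int, n_perm: int = 10_000) -> dict:
    """Permutation tail vs the exact hypergeometric on the 10-gene toy:
    2 universal genes, class of 5 containing both, P(X >= 2) = 56/252."""
    universal = np.zeros(10, dtype=bool)
    universal[:2] = True
    member = np.zeros(10, dtype=bool)
    member[:5] = True
    res = permutation_enrichment(universal, member, n_perm=n_perm, seed=seed)
    p_true = 56 / 252
    tail = float(np.mean(res.null_counts >= 2))
    se = float(np.sqrt(p_true * (1 - p_true) / n_perm))
    return {"tail": tail, "expected": p_true, "abs_error": abs(tail - p_true), "mc_se": se}


def _relative_d_by_species(ds, truth_labels: pd.DataFrame) -> pd.Series:
    """Gonad-biased relative D per species from the popgen pipeline,
    using the generator's truth tissue labels (expression stage skipped
    for speed in calibration loops)."""
    out = {}
    gonad_genes = truth_labels.loc[
        (truth_labels["true_tissue_class"] == "gonad-biased")
        & (truth_labels["chrom_class"] == "A"),
        "gene",
    ]
    bg_genes = truth_labels.loc[
        (truth_labels["true_tissue_class"] == "non-tissue-biased")
        & (truth_labels["chrom_class"] == "A"),
        "gene",
    ]
    for sp, data in ds.species.items():
        popgen, _ = gene_popgen_table(data["gl_table"], data["genemap"])
        d_by_gene = popgen.set_index("gene")["tajimas_d"]
        out[sp] = relative_tajimas_d(
            d_by_gene.reindex(gonad_genes).dropna(), d_by_gene.reindex(bg_genes).dropna()
        )
    return pd.Series(out)


def pgls_type1_rate(seed: int, n_reps: int = 200) -> dict:
    """With coupling = 0 the PGLS slope test should reject at ~5%."""
    rejections = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_species=6,
            n_genes=60,
            sites_per_gene=15,
            mean_depth=8.0,
            coupling=0.0,
            seed=seed * 2003 + rep,
        )
        ds = simulate_dataset(cfg)
        rel = _relative_d_by_species(ds, ds.genes)
        tips = tip_order(ds.newick)
        x = ds.traits.set_index("species")["dichromatism_score"].loc[tips].to_numpy()
        fit = pgls_fit(rel.loc[tips].to_numpy(), x, ds.newick, lambda_mode="ML", taxa=tips)
        rejections += fit.p < 0.05
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


# ------------------------------------------------------- comparative recovery


def pgls_slope_recovery(seed: int, n_reps: int = 100, n_tips: int = 20) -> dict:
    """Brownian residuals on a random tree with planted slope 1.0."""
    cfg = SimulationConfig(n_species=n_tips, seed=seed)
    newick, _, _ = simulate_phylogeny_traits(cfg)
    tips = tip_order(newick)
    chol = np.linalg.cholesky(brownian_covariance(newick, 1.0, taxa=tips))
    slopes = []
    lambda_high = 0
    for rep in range(n_reps):
        rng = rng_for(seed, f"pgls_recovery:{rep}")
        x = rng.normal(size=n_tips)
        y = 1.0 * x + chol @ rng.normal(size=n_tips)
        fit = pgls_fit(y, x, newick, lambda_mode="ML", taxa=tips)
        slopes.append(fit.slope)
        lambda_high += fit.lambda_hat > 0.5
    return {
        "mean_slope": float(np.mean(slopes)),
        "lambda_above_half_fraction": lambda_high / n_reps,
        "n_reps": n_reps,
    }


def pgls_lambda_zero_ols_diff(seed: int, n_tips: int = 12) -> float:
    """Max |PGLS(lambda=0) - OLS| over slope and intercept."""
    cfg = SimulationConfig(n_species=n_tips, seed=seed)
    newick, _, _ = simulate_phylogeny_traits(cfg)
    tips = tip_order(newick)
    rng = rng_for(seed, "lambda0")
    x = rng.normal(size=n_tips)
    y = rng.normal(size=n_tips)
    fit = pgls_fit(y, x, newick, lambda_mode=0.0, taxa=tips)
    slope, intercept = np.polyfit(x, y, 1)
    return float(max(abs(fit.slope - slope), abs(fit.intercept - intercept)))


def coupled_slope_positive_fraction(seed: int, n_runs: int = 20) -> dict:
    """End to end: coupling > 0 should yield a positive D-trait slope."""
    positives = 0
    slopes = []
    for rep in range(n_runs):
        cfg = SimulationConfig(
            n_species=6,
            n_genes=150,
            sites_per_gene=25,
            coupling=2.0,
            seed=seed * 4001 + rep,
        )
        ds = simulate_dataset(cfg)
        rel = _relative_d_by_species(ds, ds.genes)
        tips = tip_order(ds.newick)
        x = ds.traits.set_index("species")["dichromatism_score"].loc[tips].to_numpy()
        fit = pgls_fit(rel.loc[tips].to_numpy(), x, ds.newick, lambda_mode="ML", taxa=tips)
        slopes.append(fit.slope)
        positives += fit.slope > 0
    return {
        "positive_fraction": positives / n_runs,
        "mean_slope": float(np.mean(slopes)),
        "n_runs": n_runs,
    }
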