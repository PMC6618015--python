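"""Gene-class statistics for sexual-conflict signal.

Relative Tajima's D (class median minus non-tissue-biased median),
Wilcoxon rank-sum contrasts, a covariate multiple regression of D on
tissue bias plus nuisance covariates, polynomial fits of D on continuous
sex bias, cross-species top-quantile permutation enrichment, and the
Z-versus-autosome subsampling test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .config import rng_for

__all__ = [
    "relative_tajimas_d",
    "wilcoxon_contrast",
    "covariate_regression",
    "polynomial_sexbias_fit",
    "flag_top_quantile",
    "permutation_enrichment",
    "z_subsampling_test",
    "PermutationEnrichmentResult",
]


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[~np.isnan(v)]


def relative_tajimas_d(class_d, background_d) -> float:
    """Median D of a gene class minus median D of the background class.

    Differencing against the species' own non-tissue-biased genes removes
    the demographic component of D, making the quantity comparable across
    species.
    """
    cls = _clean(class_d)
    bg = _clean(background_d)
    if len(cls) == 0 or len(bg) == 0:
        raise ValueError("both gene sets must be non-empty")
    return float(np.median(cls) - np.median(bg))


def wilcoxon_contrast(class_d, background_d) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two sets of D values.

    Exact null distribution when both samples have at most 25 values and
    no ties; otherwise the normal approximation with tie correction.
    """
    cls = _clean(class_d)
    bg = _clean(background_d)
    if len(cls) == 0 or len(bg) == 0:
        raise ValueError("both gene sets must be non-empty")
    combined = np.concatenate([cls, bg])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(cls) <= 25 and len(bg) <= 25 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(cls, bg, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def covariate_regression(gene_table: pd.DataFrame) -> pd.DataFrame:
    """OLS of Tajima's D on tissue bias plus log-scale covariates.

    Model: tajimas_d ~ tissue_class + log(theta_w) + log(length_bp)
    + log(gc_fraction) + log(mean_expr), with non-tissue-biased genes as
    the reference level. Zeros in a log-transformed covariate are offset
    by the smallest positive observed value of that covariate. Returns a
    tidy frame (term, estimate, se, t, p).
    """
    required = {"tajimas_d", "tissue_class", "theta_w", "length_bp", "gc_fraction", "mean_expr"}
    missing = required - set(gene_table.columns)
    if missing:
        raise ValueError(f"gene table lacks columns {sorted(missing)}")
    df = gene_table.dropna(subset=["tajimas_d"]).copy()
    n_terms = 6
    if len(df) < n_terms + 10:
        raise ValueError("need at least 10 more rows than model terms")
    if df["tissue_class"].nunique() < 2:
        raise ValueError("rank-deficient design: tissue_class is constant")
    for col in ("theta_w", "length_bp", "gc_fraction", "mean_expr"):
        v = df[col].to_numpy(dtype=float)
        if (v < 0).any():
            raise ValueError(f"negative values in covariate {col}")
        positive = v[v > 0]
        if len(positive) == 0:
            raise ValueError(f"rank-deficient design: covariate {col} is all zero")
        v = np.where(v == 0, positive.min(), v)
        df[f"log_{col}"] = np.log(v)
    model = smf.ols(
        "tajimas_d ~ C(tissue_class, Treatment('non-tissue-biased'))"
        " + log_theta_w + log_length_bp + log_gc_fraction + log_mean_expr",
        data=df,
    ).fit()
    out = pd.DataFrame(
        {
            "term": model.params.index,
            "estimate": model.params.to_numpy(),
            "se": model.bse.to_numpy(),
            "t": model.tvalues.to_numpy(),
            "p": model.pvalues.to_numpy(),
        }
    )
    out["term"] = (
        out["term"]
        .str.replace(r"C\(tissue_class, Treatment\('non-tissue-biased'\)\)\[T\.", "tissue_class[", regex=True)
    )
    return out


def polynomial_sexbias_fit(
    d_values, log2fc_sex, degree: int = 2
) -> tuple[np.ndarray, float]:
    """Least-squares polynomial of D on continuous sex bias.

    Returns (coefficients lowest order first, r_squared). Degree must be
    1-3; the fit needs more points than coefficients.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    d = np.asarray(d_values, dtype=float)
    x = np.asarray(log2fc_sex, dtype=float)
    ok = ~(np.isnan(d) | np.isnan(x))
    d, x = d[ok], x[ok]
    if len(d) <= degree + 1:
        raise ValueError("need more points than polynomial coefficients")
    design = np.vander(x, degree + 1, increasing=True)
    coef, _, _, _ = np.linalg.lstsq(design, d, rcond=None)
    fitted = design @ coef
    tss = float(np.sum((d - d.mean()) ** 2))
    rss = float(np.sum((d - fitted) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return coef, r2


def flag_top_quantile(d_by_species: pd.DataFrame, quantile: float = 0.10) -> pd.DataFrame:
    """Flag genes in the top ``quantile`` of D within each species.

    ``d_by_species`` is genes x species. A gene is flagged when its D is
    at or above the (1 - quantile) empirical quantile (linear
    interpolation) of that species' column; ties at the threshold are
    flagged inclusively. Adds a ``universal`` column: flagged in every
    species.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    flags = {}
    for sp in d_by_species.columns:
        col = d_by_species[sp].to_numpy(dtype=float)
        thresh = np.nanquantile(col, 1.0 - quantile)
        flags[sp] = col >= thresh
    out = pd.DataFrame(flags, index=d_by_species.index)
    out["universal"] = out.all(axis=1)
    return out


@dataclass
class PermutationEnrichmentResult:
    observed: int
    perm_mean: float
    empirical_p: float
    chi2_p: float
    n_perm: int
    null_counts: np.ndarray


def permutation_enrichment(
    universal_flags: np.ndarray,
    class_membership: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationEnrichmentResult:
    """Is a gene class enriched/depleted for universally elevated genes?

    Draws ``n_perm`` random classes of the same size (without
    replacement) from the orthologue universe and counts their overlap
    with the universally flagged set. The empirical p-value is two-sided
    by distance from the permutation mean, with the +1 correction; a
    chi-squared p (df = 1) compares the observed count to the
    permutation-mean expectation.
    """
    universal = np.asarray(universal_flags, dtype=bool)
    member = np.asarray(class_membership, dtype=bool)
    if len(universal) != len(member):
        raise ValueError("flag vectors must share the orthologue universe")
    k = int(member.sum())
    if k == 0:
        raise ValueError("gene class is empty")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    observed = int((universal & member).sum())
    rng = rng_for(seed, "permutation_enrichment")
    n_genes = len(universal)
    # each permutation draws a k-subset: take first k of a random permutation
    order = rng.random((n_perm, n_genes)).argsort(axis=1)[:, :k]
    null_counts = universal[order].sum(axis=1)
    mean = float(null_counts.mean())
    dist = np.abs(null_counts - mean)
    empirical_p = (1.0 + float(np.sum(dist >= abs(observed - mean)))) / (n_perm + 1.0)
    expected = np.array([mean, k - mean])
    if expected.min() <= 0:
        chi2_p = 1.0
    else:
        chi2 = float(np.sum((np.array([observed, k - observed]) - expected) ** 2 / expected))
        chi2_p = float(sps.chi2.sf(chi2, df=1))
    return PermutationEnrichmentResult(
        observed=observed,
        perm_mean=mean,
        empirical_p=float(empirical_p),
        chi2_p=chi2_p,
        n_perm=n_perm,
        null_counts=null_counts,
    )


def _relative_medians(focal: np.ndarray, background: np.ndarray) -> float:
    return float(np.median(focal) - np.median(background))


def z_subsampling_test(
    autosomal: pd.DataFrame,
    z_linked: pd.DataFrame,
    traits: pd.DataFrame,
    trait: str = "dichromatism_score",
    focal_class: str = "gonad-biased",
    n_rep: int = 1000,
    seed: int = 0,
) -> dict:
    """Is the Z relationship weaker than expected from gene numbers alone?

    The observed quantity is the across-species Pearson r (and OLS slope)
    of Z-linked relative D on a dimorphism proxy. Each replicate
    subsamples the autosomal focal genes of every species down to that
    species' Z-linked focal count, recomputes relative D against the full
    autosomal background, and records r and slope. One-sided p-values are
    the fraction of replicates with r (slope) at or below the observed Z
    value (ties counted).

    ``autosomal``/``z_linked`` need columns species, tajimas_d,
    tissue_class; ``traits`` needs species and the trait column.
    """
    trait_vals = traits.set_index("species")[trait]
    if trait_vals.nunique() <= 1:
        raise ValueError("trait is constant across species; correlation undefined")
    species = sorted(set(autosomal["species"]) & set(z_linked["species"]))
    if len(species) < 3:
        raise ValueError("need at least three species")
    focal_a, bg_a, focal_z, bg_z, n_z = {}, {}, {}, {}, {}
    for sp in species:
        a = autosomal[autosomal["species"] == sp]
        z = z_linked[z_linked["species"] == sp]
        focal_a[sp] = _clean(a.loc[a["tissue_class"] == focal_class, "tajimas_d"])
        bg_a[sp] = _clean(a.loc[a["tissue_class"] == "non-tissue-biased", "tajimas_d"])
        focal_z[sp] = _clean(z.loc[z["tissue_class"] == focal_class, "tajimas_d"])
        bg_z[sp] = _clean(z.loc[z["tissue_class"] == "non-tissue-biased", "tajimas_d"])
        n_z[sp] = len(focal_z[sp])
        if n_z[sp] < 1:
            raise ValueError(f"species {sp} has no Z-linked {focal_class} genes")
        if n_z[sp] > len(focal_a[sp]):
            raise ValueError(f"species {sp}: Z count exceeds autosomal focal count")
        if len(bg_z[sp]) == 0 or len(bg_a[sp]) == 0:
            raise ValueError(f"species {sp} lacks background genes")
    x = trait_vals.loc[species].to_numpy(dtype=float)
    rel_z = np.array([_relative_medians(focal_z[sp], bg_z[sp]) for sp in species])
    observed_r = float(np.corrcoef(rel_z, x)[0, 1])
    observed_slope = float(np.polyfit(x, rel_z, 1)[0])
    rng = rng_for(seed, "z_subsampling")
    r_null = np.empty(n_rep)
    slope_null = np.empty(n_rep)
    for rep in range(n_rep):
        rel = np.array(
            [
                _relative_medians(
                    rng.choice(focal_a[sp], size=n_z[sp], replace=False), bg_a[sp]
                )
                for sp in species
            ]
        )
        r_null[rep] = np.corrcoef(rel, x)[0, 1]
        slope_null[rep] = np.polyfit(x, rel, 1)[0]
    return {
        "observed_r": observed_r,
        "observed_slope": observed_slope,
        "p_r": float(np.mean(r_null <= observed_r)),
        "p_slope": float(np.mean(slope_null <= observed_slope)),
        "n_rep": n_rep,
        "species": species,
    }
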