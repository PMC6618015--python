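"""Intersexual Hudson's F_ST.

Allele-frequency differentiation between males and females of one
population, computed per site from sex-partitioned genotype likelihoods
and combined per gene as a ratio of sums (between-sex variance component
over total component), which is robust at small sample sizes. Includes
the elevated-F_ST count test: observed vs expected number of genes with
F_ST > 0 in a focal gene class, with expectation taken from a background
class and a 2x2 chi-squared p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .popgen import GenotypeLikelihoodTable

__all__ = [
    "FstSiteComponents",
    "ml_allele_frequency",
    "ml_allele_frequencies_batch",
    "sex_allele_frequencies",
    "hudson_site",
    "gene_fst",
    "gene_fst_table",
    "elevated_fst_count_test",
]


@dataclass
class FstSiteComponents:
    """Hudson per-site variance components.

    ``n_hat`` is the between-sex component, ``d_hat`` the total; the
    per-gene estimate is sum(n_hat)/sum(d_hat) across sites.
    """

    n_hat: float
    d_hat: float
    n_male: int = 0
    n_female: int = 0


def _freq_loglik(p: float, gl: np.ndarray) -> float:
    """Log-likelihood of allele frequency p under HWE genotype priors."""
    geno_prior = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    per_ind = gl @ geno_prior
    if np.any(per_ind <= 0):
        return -np.inf
    return float(np.sum(np.log(per_ind)))


def ml_allele_frequency(gl: np.ndarray, tol: float = 1e-6) -> float:
    """ML derived-allele frequency at one site by bounded 1-D search.

    ``gl`` is (N, 3) for the informative individuals of one sex. Returns
    NaN when the likelihoods carry no frequency information (all triples
    flat).
    """
    gl = np.asarray(gl, dtype=float)
    if gl.ndim != 2 or gl.shape[1] != 3:
        raise ValueError("gl must be (N, 3)")
    if len(gl) == 0:
        return float("nan")
    norm = gl / gl.sum(axis=1, keepdims=True)
    if np.allclose(norm, 1.0 / 3.0):
        return float("nan")
    res = optimize.minimize_scalar(
        lambda p: -_freq_loglik(p, gl), bounds=(0.0, 1.0), method="bounded",
        options={"xatol": tol},
    )
    return float(res.x)


def ml_allele_frequencies_batch(
    gl: np.ndarray, has_data: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> np.ndarray:
    """Vectorised per-site ML allele frequencies via EM.

    Same likelihood as :func:`ml_allele_frequency` (HWE prior on each
    individual's genotype), maximised by the standard EM update
    p' = mean posterior derived dosage / 2; fully vectorised over sites.
    Individuals without data are flat triples and do not move the
    estimate. Sites where every individual lacks data return NaN.
    """
    gl = np.asarray(gl, dtype=float)
    n_sites, n_ind, _ = gl.shape
    any_data = has_data.any(axis=1)
    gl_norm = gl / gl.sum(axis=2, keepdims=True)
    # flat triples contribute a constant factor; zero them out of the update
    weight = has_data.astype(float)
    n_eff = np.maximum(weight.sum(axis=1), 1.0)

    def em(p0: float) -> np.ndarray:
        # active-set EM: converged sites drop out of the update
        p = np.full(n_sites, p0)
        active = np.arange(n_sites)
        for _ in range(max_iter):
            pa = p[active]
            gla = gl_norm[active]
            j0 = gla[:, :, 0] * ((1 - pa) ** 2)[:, None]
            j1 = gla[:, :, 1] * (2 * pa * (1 - pa))[:, None]
            j2 = gla[:, :, 2] * (pa**2)[:, None]
            e_dosage = ((j1 + 2 * j2) / (j0 + j1 + j2) * weight[active]).sum(axis=1)
            p_new = np.clip(e_dosage / (2.0 * n_eff[active]), 1e-9, 1 - 1e-9)
            p[active] = p_new
            moved = np.abs(p_new - pa) >= tol
            active = active[moved]
            if active.size == 0:
                break
        return p

    def loglik(p: np.ndarray) -> np.ndarray:
        prior = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)
        per_ind = np.einsum("sig,sg->si", gl_norm, prior)
        with np.errstate(divide="ignore"):
            ll = np.where(weight > 0, np.log(np.maximum(per_ind, 1e-300)), 0.0)
        return ll.sum(axis=1)

    # the likelihood can be bimodal in p; keep the better of two EM runs
    p_lo, p_hi = em(0.1), em(0.9)
    p = np.where(loglik(p_hi) > loglik(p_lo), p_hi, p_lo)
    p[~any_data] = np.nan
    # sites whose informative triples are all flat carry no information
    informative = (np.abs(gl_norm - 1.0 / 3.0).max(axis=2) > 1e-12) & has_data
    p[~informative.any(axis=1)] = np.nan
    return p


def sex_allele_frequencies(
    table: GenotypeLikelihoodTable,
) -> pd.DataFrame:
    """Per-site ML allele frequencies and allele counts for each sex.

    Returns a frame with columns p_male, p_female, n_male, n_female
    (n = 2 x informative individuals), indexed like the site table. A sex
    with zero informative individuals at a site yields NaN frequency.
    """
    out = {}
    for sex, tag in (("M", "male"), ("F", "female")):
        cols = table.sexes == sex
        gl = table.gl[:, cols, :]
        has = table.has_data[:, cols]
        out[f"p_{tag}"] = ml_allele_frequencies_batch(gl, has)
        out[f"n_{tag}"] = 2 * has.sum(axis=1)
    return pd.DataFrame(out)


def hudson_site(p1: float, p2: float, n1: int, n2: int) -> FstSiteComponents:
    """Hudson's variance components for one site.

    N_hat = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1);
    D_hat = p1(1-p2) + p2(1-p1). ``n1``/``n2`` are allele counts; with
    fewer than two alleles in either group the components are undefined.
    """
    if n1 <= 1 or n2 <= 1:
        return FstSiteComponents(float("nan"), float("nan"), n1, n2)
    n_hat = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    d_hat = p1 * (1 - p2) + p2 * (1 - p1)
    return FstSiteComponents(float(n_hat), float(d_hat), n1, n2)


def gene_fst(components: list[FstSiteComponents]) -> float:
    """Per-gene F_ST as the ratio of summed components (may be negative).

    Missing (NaN) sites are skipped; a gene whose total component sums to
    zero (all sites monomorphic) has no defined F_ST.
    """
    n_hats = np.array([c.n_hat for c in components], dtype=float)
    d_hats = np.array([c.d_hat for c in components], dtype=float)
    ok = ~(np.isnan(n_hats) | np.isnan(d_hats))
    d_sum = d_hats[ok].sum()
    if not ok.any() or d_sum == 0:
        return float("nan")
    return float(n_hats[ok].sum() / d_sum)


def gene_fst_table(table: GenotypeLikelihoodTable) -> pd.DataFrame:
    """Per-gene intersexual F_ST from a (per-sex filtered) site table.

    Vectorised over sites: ML allele frequencies per sex, Hudson
    components, then per-gene ratio of sums. Returns a frame indexed by
    gene with columns fst and n_sites.
    """
    freqs = sex_allele_frequencies(table)
    p1 = freqs["p_male"].to_numpy()
    p2 = freqs["p_female"].to_numpy()
    n1 = freqs["n_male"].to_numpy().astype(float)
    n2 = freqs["n_female"].to_numpy().astype(float)
    valid = (~np.isnan(p1)) & (~np.isnan(p2)) & (n1 > 1) & (n2 > 1)
    n_hat = np.where(
        valid,
        (p1 - p2) ** 2
        - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
        - p2 * (1 - p2) / np.maximum(n2 - 1, 1),
        np.nan,
    )
    d_hat = np.where(valid, p1 * (1 - p2) + p2 * (1 - p1), np.nan)
    df = pd.DataFrame({"gene": table.genes, "n_hat": n_hat, "d_hat": d_hat})
    grouped = df.groupby("gene", sort=False)
    n_sum = grouped["n_hat"].sum(min_count=1)
    d_sum = grouped["d_hat"].sum(min_count=1)
    n_sites = grouped["n_hat"].count()
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = n_sum / d_sum
    fst[d_sum == 0] = np.nan
    return pd.DataFrame({"fst": fst, "n_sites": n_sites})


def elevated_fst_count_test(
    focal_fst: np.ndarray, background_fst: np.ndarray
) -> tuple[float, int, float]:
    """Observed vs expected count of focal genes with F_ST > 0.

    The expected count is the focal class size times the fraction of the
    background class with F_ST strictly above zero; the p-value comes
    from a 2x2 chi-squared (class x F_ST>0) with one degree of freedom
    and no continuity correction. Returns (expected, observed, p).
    """
    focal = np.asarray(focal_fst, dtype=float)
    background = np.asarray(background_fst, dtype=float)
    focal = focal[~np.isnan(focal)]
    background = background[~np.isnan(background)]
    if len(background) == 0:
        raise ValueError("background class has no F_ST values")
    if len(focal) == 0:
        raise ValueError("focal class has no F_ST values")
    frac_bg = float(np.mean(background > 0))
    expected = len(focal) * frac_bg
    observed = int(np.sum(focal > 0))
    contingency = np.array(
        [
            [observed, len(focal) - observed],
            [int(np.sum(background > 0)), int(np.sum(background <= 0))],
        ]
    )
    if contingency.sum(axis=0).min() == 0 or contingency.sum(axis=1).min() == 0:
        return expected, observed, 1.0
    _, p, _, _ = stats.chi2_contingency(contingency, correction=False)
    return expected, observed, float(p)
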