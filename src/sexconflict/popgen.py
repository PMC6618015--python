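"""Genotype-likelihood population genetics.

From per-site, per-individual genotype likelihoods this module computes
sample-allele-frequency (SAF) likelihoods by dynamic programming, estimates
the unfolded site frequency spectrum (SFS) by EM, turns the SFS into
per-site posteriors over derived-allele counts, and from those derives
per-gene Watterson's theta, pairwise diversity and Tajima's D. It also
provides the EM estimator of per-individual inbreeding coefficients.

All heavy paths are vectorised over sites; genotype likelihoods are stored
as a ``(sites, individuals, 3)`` array of nonnegative values, one triple
per individual for 0/1/2 copies of the derived allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GenotypeLikelihoodTable",
    "SiteFrequencySpectrum",
    "GenePopgenRecord",
    "genotype_likelihood",
    "filter_sites",
    "saf_likelihood",
    "saf_likelihoods",
    "estimate_sfs_em",
    "site_posteriors",
    "gene_thetas",
    "tajima_constants",
    "tajimas_d",
    "estimate_inbreeding_em",
]

FLAT = np.array([1.0, 1.0, 1.0]) / 3.0


@dataclass
class GenotypeLikelihoodTable:
    """Per-site tri-genotype likelihoods with sex labels and missingness.

    ``gl[s, i]`` is the (L0, L1, L2) likelihood triple of individual ``i``
    at site ``s``; triples need not be normalised but must be nonnegative
    and not all zero where data are present. ``has_data[s, i]`` is False
    for individuals with no reads at the site (their triple is flat and
    carries no information).
    """

    markers: np.ndarray          # site id strings "gene_pos"
    genes: np.ndarray            # gene id per site
    positions: np.ndarray        # 1-based position within gene
    gl: np.ndarray               # (S, N, 3) float
    has_data: np.ndarray         # (S, N) bool
    sexes: np.ndarray            # (N,) "M"/"F"
    individuals: np.ndarray      # (N,) individual ids

    def __post_init__(self) -> None:
        self.gl = np.asarray(self.gl, dtype=float)
        if self.gl.ndim != 3 or self.gl.shape[2] != 3:
            raise ValueError("gl must have shape (sites, individuals, 3)")
        if np.any(self.gl < 0):
            raise ValueError("genotype likelihoods must be nonnegative")
        bad = self.has_data & (self.gl.sum(axis=2) <= 0)
        if np.any(bad):
            raise ValueError("all-zero likelihood triple at a site with data")

    @property
    def n_sites(self) -> int:
        return self.gl.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.gl.shape[1]

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeLikelihoodTable":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeLikelihoodTable(
            markers=self.markers,
            genes=self.genes,
            positions=self.positions,
            gl=self.gl[:, mask, :],
            has_data=self.has_data[:, mask],
            sexes=self.sexes[mask],
            individuals=self.individuals[mask],
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeLikelihoodTable":
        mask = np.asarray(mask)
        return GenotypeLikelihoodTable(
            markers=self.markers[mask],
            genes=self.genes[mask],
            positions=self.positions[mask],
            gl=self.gl[mask],
            has_data=self.has_data[mask],
            sexes=self.sexes,
            individuals=self.individuals,
        )


@dataclass
class SiteFrequencySpectrum:
    """Normalised probability vector over derived-allele counts 0..2N."""

    xi: np.ndarray
    n_diploid: int
    converged: bool = True
    monotone: bool = True
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        if self.xi.ndim != 1 or len(self.xi) != 2 * self.n_diploid + 1:
            raise ValueError("xi must have length 2N + 1")
        if np.any(self.xi < 0) or not np.isclose(self.xi.sum(), 1.0):
            raise ValueError("xi must be a probability vector")


@dataclass
class GenePopgenRecord:
    """Per-gene diversity summary."""

    gene: str
    n_sites: int
    theta_w: float
    theta_pi: float
    s_eff: float
    tajimas_d: float
    chrom_class: str = "A"


def genotype_likelihood(bases, error_rates) -> np.ndarray:
    """Likelihood triple (L0, L1, L2) for one individual at one site.

    ``bases`` codes each read as 1 (matches the derived allele) or 0
    (matches the ancestral allele). Per read, a true allele is observed
    correctly with probability 1 - eps and as any given other base with
    probability eps/3; a genotype with g derived copies emits a derived
    read with probability (g/2)(1-eps) + (1-g/2)(eps/3). The triple is the
    product over reads, normalised to sum to one. With no reads all three
    genotypes are equally likely.
    """
    bases = np.asarray(bases, dtype=float)
    eps = np.broadcast_to(np.asarray(error_rates, dtype=float), bases.shape)
    if np.any((eps < 0) | (eps >= 0.5)):
        raise ValueError("error rates must lie in [0, 0.5)")
    if bases.size == 0:
        return FLAT.copy()
    g_half = np.array([0.0, 0.5, 1.0])          # g/2 for g = 0,1,2
    p_match_derived = 1.0 - eps
    p_mismatch = eps / 3.0
    # P(read | g): mixture over the two alleles of the genotype
    p_derived_read = np.outer(g_half, p_match_derived) + np.outer(1 - g_half, p_mismatch)
    p_anc_read = np.outer(g_half, p_mismatch) + np.outer(1 - g_half, 1.0 - eps)
    per_read = np.where(bases[None, :] == 1, p_derived_read, p_anc_read)
    with np.errstate(divide="ignore"):
        loglik = np.sum(np.log(per_read), axis=1)
    loglik -= loglik.max()
    lik = np.exp(loglik)
    return lik / lik.sum()


def filter_sites(
    table: GenotypeLikelihoodTable, min_ind_fraction: float = 0.5, per_sex: bool = False
) -> GenotypeLikelihoodTable:
    """Drop sites with data in fewer than half the individuals.

    With ``per_sex=True`` the half-rule is applied within each sex
    separately (used upstream of intersexual F_ST so sex-limited genes
    are not excluded by the pooled rule). Base/mapping-quality filters are
    applied upstream of this table and recorded in provenance.
    """
    informative = table.has_data
    if per_sex:
        keep = np.ones(table.n_sites, dtype=bool)
        for sex in ("M", "F"):
            cols = table.sexes == sex
            if cols.sum() == 0:
                continue
            n_inf = informative[:, cols].sum(axis=1)
            keep &= n_inf >= min_ind_fraction * cols.sum()
    else:
        n_inf = informative.sum(axis=1)
        keep = n_inf >= min_ind_fraction * table.n_individuals
    return table.subset_sites(keep)


def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def saf_likelihoods(gl: np.ndarray) -> np.ndarray:
    """Sample-allele-frequency likelihoods for a batch of sites.

    Dynamic programming over individuals: starting from w = [1], each
    individual convolves in its genotype likelihood weighted by the number
    of ways to carry g derived alleles, C(2, g) = (1, 2, 1). The result is
    divided by C(2N, j) and rescaled so each site's maximum is 1.

    Parameters
    ----------
    gl:
        ``(sites, N, 3)`` nonnegative genotype likelihoods.

    Returns
    -------
    ``(sites, 2N + 1)`` array h with ``h[s, j]`` proportional to the
    likelihood that j of the 2N sampled chromosomes carry the derived
    allele at site s.
    """
    gl = np.asarray(gl, dtype=float)
    if gl.ndim != 3 or gl.shape[2] != 3:
        raise ValueError("gl must have shape (sites, N, 3)")
    n_sites, n_ind, _ = gl.shape
    if n_ind < 1:
        raise ValueError("need at least one individual")
    row_sums = gl.sum(axis=2)
    if np.any(row_sums <= 0):
        raise ValueError("site with all-zero likelihoods for an individual")
    mult = np.array([1.0, 2.0, 1.0])
    w = np.ones((n_sites, 1))
    for i in range(n_ind):
        g = gl[:, i, :] * mult
        new = np.zeros((n_sites, w.shape[1] + 2))
        new[:, :-2] += w * g[:, [0]]
        new[:, 1:-1] += w * g[:, [1]]
        new[:, 2:] += w * g[:, [2]]
        # guard against underflow for large N
        scale = new.max(axis=1, keepdims=True)
        w = new / scale
    j = np.arange(2 * n_ind + 1, dtype=float)
    h = w / np.exp(_log_binom(2 * n_ind, j))[None, :]
    return h / h.max(axis=1, keepdims=True)


def saf_likelihood(triples, missing=None) -> np.ndarray:
    """SAF likelihood vector h(j) for a single site.

    ``triples`` is an (N, 3) array; individuals flagged in ``missing`` are
    excluded and the vector length adapts to the informative 2N.
    """
    triples = np.asarray(triples, dtype=float)
    if triples.ndim != 2 or triples.shape[1] != 3:
        raise ValueError("triples must have shape (N, 3)")
    if missing is not None:
        triples = triples[~np.asarray(missing, dtype=bool)]
    if len(triples) == 0:
        raise ValueError("all individuals missing at this site")
    return saf_likelihoods(triples[None, :, :])[0]


def estimate_sfs_em(
    saf: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
    init_rng: np.random.Generator | None = None,
) -> SiteFrequencySpectrum:
    """EM estimate of the unfolded SFS from per-site SAF likelihoods.

    The E-step computes per-site posteriors q_s(j) proportional to
    xi_j * h_s(j); the M-step replaces xi with the mean posterior. The
    marginal log-likelihood sum_s log sum_j xi_j h_s(j) is non-decreasing
    in exact arithmetic and is tracked every iteration; a decrease beyond
    round-off or failure to converge sets a warning flag rather than
    raising.

    By default EM starts from the uniform spectrum. Passing ``init_rng``
    selects the stochastic initialisation: one allele count is sampled
    per site in proportion to its SAF likelihood and the start point is
    the histogram of those draws (strictly noisier; provided for parity
    with sampling-based SFS estimators).
    """
    saf = np.asarray(saf, dtype=float)
    if saf.ndim != 2 or saf.shape[0] < 1:
        raise ValueError("need at least one site with SAF vectors of equal length")
    n_cat = saf.shape[1]
    if n_cat < 3 or n_cat % 2 == 0:
        raise ValueError("SAF vectors must have odd length 2N + 1 >= 3")
    if init_rng is None:
        xi = np.full(n_cat, 1.0 / n_cat)
    else:
        probs = saf / saf.sum(axis=1, keepdims=True)
        cum = probs.cumsum(axis=1)
        draws = (init_rng.random(saf.shape[0])[:, None] > cum).sum(axis=1)
        xi = (np.bincount(draws, minlength=n_cat) + 1.0) / (saf.shape[0] + n_cat)
    trace = []
    monotone = True
    converged = False
    for _ in range(max_iter):
        a = saf * xi[None, :]
        denom = a.sum(axis=1)
        if np.any(denom <= 0):
            raise ValueError("site with zero marginal likelihood under the SFS")
        trace.append(float(np.log(denom).sum()))
        if len(trace) > 1 and trace[-1] < trace[-2] - 1e-9:
            monotone = False
        q = a / denom[:, None]
        xi_new = q.mean(axis=0)
        if np.max(np.abs(xi_new - xi)) < tol:
            xi = xi_new
            converged = True
            break
        xi = xi_new
    return SiteFrequencySpectrum(
        xi=xi / xi.sum(),
        n_diploid=(n_cat - 1) // 2,
        converged=converged,
        monotone=monotone,
        loglik_trace=np.asarray(trace),
    )


def site_posteriors(saf: np.ndarray, sfs: SiteFrequencySpectrum) -> np.ndarray:
    """Per-site posterior over derived-allele counts, SFS as prior.

    Sites whose normaliser is zero (no overlap between prior support and
    SAF support) are returned as NaN rows and should be treated as
    uninformative.
    """
    saf = np.atleast_2d(np.asarray(saf, dtype=float))
    if saf.shape[1] != len(sfs.xi):
        raise ValueError("SAF length does not match SFS length")
    a = saf * sfs.xi[None, :]
    denom = a.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        post = a / denom
    post[denom[:, 0] <= 0] = np.nan
    return post


def tajima_constants(n: int) -> dict:
    """Tajima (1989) normalising constants for n sampled chromosomes."""
    if n < 2:
        raise ValueError("need at least two chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def gene_thetas(posteriors: np.ndarray) -> tuple[float, float, float]:
    """(theta_w, theta_pi, S_eff) for one gene from site posteriors.

    Per site, the probability of being variable is 1 - post(0) - post(2N);
    its Watterson contribution is that probability divided by a1, and its
    pairwise-diversity contribution is the posterior expectation of
    j(2N - j)/C(2N, 2). Gene values are sums over sites; NaN posterior
    rows (uninformative sites) contribute nothing.
    """
    post = np.atleast_2d(np.asarray(posteriors, dtype=float))
    if post.shape[0] < 1:
        raise ValueError("need at least one site")
    two_n = post.shape[1] - 1
    post = post[~np.isnan(post).any(axis=1)]
    if post.shape[0] == 0:
        return 0.0, 0.0, 0.0
    a1 = tajima_constants(two_n)["a1"]
    p_var = 1.0 - post[:, 0] - post[:, -1]
    p_var = np.clip(p_var, 0.0, 1.0)
    j = np.arange(two_n + 1, dtype=float)
    pi_weights = j * (two_n - j) / (two_n * (two_n - 1) / 2.0)
    theta_pi = float(np.sum(post @ pi_weights))
    theta_w = float(np.sum(p_var) / a1)
    return theta_w, theta_pi, float(np.sum(p_var))


def tajimas_d(theta_w: float, theta_pi: float, s_eff: float, two_n: int) -> float:
    """Tajima's D from gene-level theta estimates.

    Returns NaN when the effective number of segregating sites is zero
    (the statistic is undefined, not an error).
    """
    if two_n < 4:
        raise ValueError("need at least four chromosomes for Tajima's D")
    if s_eff <= 0:
        return float("nan")
    c = tajima_constants(two_n)
    var = c["e1"] * s_eff + c["e2"] * s_eff * (s_eff - 1.0)
    if var <= 0:
        return float("nan")
    return (theta_pi - theta_w) / np.sqrt(var)


def estimate_inbreeding_em(
    gl: np.ndarray,
    allele_freqs: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> np.ndarray:
    """Per-individual inbreeding coefficients by EM.

    The genotype prior at a site with derived-allele frequency p is the
    mixture P(g | p, F) = (1 - F)·HWE(g; p) + F·IBD(g; p) with
    IBD = ((1 - p), 0, p). The E-step computes the posterior probability
    that a site's genotype is identical by descent; the M-step averages it
    over sites. F is clipped to [0, 1]; convergence when max |dF| < tol.

    Parameters
    ----------
    gl:
        ``(sites, N, 3)`` genotype likelihoods.
    allele_freqs:
        Per-site derived-allele frequencies in (0, 1).
    """
    gl = np.asarray(gl, dtype=float)
    p = np.asarray(allele_freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    if gl.shape[0] != len(p):
        raise ValueError("one allele frequency per site required")
    n_ind = gl.shape[1]
    hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)   # (S, 3)
    ibd = np.stack([1 - p, np.zeros_like(p), p], axis=1)            # (S, 3)
    f = np.full(n_ind, 0.01)
    for _ in range(max_iter):
        # joint over (IBD indicator, genotype), marginalised over g
        num = np.einsum("sig,sg->si", gl, ibd)                      # (S, N)
        out = np.einsum("sig,sg->si", gl, hwe)
        joint_ibd = f[None, :] * num
        joint_out = (1 - f)[None, :] * out
        total = joint_ibd + joint_out
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(total > 0, joint_ibd / total, 0.0)
        f_new = np.clip(z.mean(axis=0), 0.0, 1.0)
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return f
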