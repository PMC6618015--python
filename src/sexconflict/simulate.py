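"""Synthetic study generator.

Emulates, at desk scale, the data structure of a multi-species RNA-seq
study of sexual conflict: for each species on a phylogeny it produces
per-site genotype likelihoods (with read-depth and sequencing-error driven
uncertainty), a raw read-count matrix with gonad/spleen samples from both
sexes, gene annotation, and species-level dimorphism proxies evolved by
Brownian motion on the tree.

Balancing selection is modelled directly as an enrichment of the site
frequency spectrum at intermediate frequencies (a multiplicative bump on
the neutral 1/j weights), which is exactly the quantity Tajima's D
responds to. Genes expressed similarly in both tissues carry this
enrichment (ongoing conflict in unbiased genes); when ``coupling`` > 0,
gonad-biased genes additionally receive a species-level intensity that
tracks the dichromatism score, planting a positive relationship between
relative Tajima's D in the gonad and phenotypic dimorphism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .config import SimulationConfig
from .popgen import GenotypeLikelihoodTable

__all__ = [
    "SimulatedDataset",
    "simulate_sfs_shape",
    "simulate_genotypes",
    "simulate_genotype_likelihoods",
    "simulate_counts",
    "simulate_phylogeny_traits",
    "simulate_species_gl",
    "simulate_dataset",
]


def simulate_sfs_shape(two_n: int, strength: float) -> np.ndarray:
    """Shape of the segregating-site frequency distribution.

    Returns the normalised probability vector over derived-allele counts
    j = 1..two_n - 1. At ``strength`` 0 the weights are the neutral 1/j
    spectrum; positive strength multiplies them by a Gaussian bump centred
    at j = two_n/2, exp(-4 * strength * (j/two_n - 1/2)^2), so that in the
    strong-selection limit all mass sits at intermediate frequency.
    """
    if two_n < 2:
        raise ValueError("two_n must be >= 2")
    if strength < 0:
        raise ValueError("strength must be >= 0")
    j = np.arange(1, two_n, dtype=float)
    w = (1.0 / j) * np.exp(-4.0 * strength * (j / two_n - 0.5) ** 2)
    return w / w.sum()


def simulate_genotypes(
    freqs: np.ndarray, n_ind: int, f: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw 0/1/2 genotypes under Hardy-Weinberg with inbreeding F.

    P(0) = (1-p)^2 + F p(1-p), P(1) = 2p(1-p)(1-F), P(2) = p^2 + F p(1-p).
    """
    p = np.asarray(freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("frequencies must lie strictly in (0, 1)")
    if not 0.0 <= f <= 1.0:
        raise ValueError("inbreeding F must lie in [0, 1]")
    fp = f * p * (1 - p)
    probs = np.stack([(1 - p) ** 2 + fp, 2 * p * (1 - p) * (1 - f), p**2 + fp], axis=1)
    u = rng.random((len(p), n_ind))
    cum = np.cumsum(probs, axis=1)
    return (u[:, :, None] > cum[:, None, :2]).sum(axis=2).astype(np.int8)


def simulate_genotype_likelihoods(
    genotypes: np.ndarray,
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
    depth_factors: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype likelihoods from Poisson depth and per-base error.

    Each individual at each site receives depth ~ Poisson(mean_depth),
    optionally scaled per site by ``depth_factors`` (used to couple depth
    to gene expression). Reads match the true allele with probability
    1 - eps and any given other base with eps/3; reads matching neither
    the derived nor the ancestral allele carry no genotype information
    (their emission probability is the same for every genotype) and are
    discarded. Likelihoods are the same per-read mixture model the
    downstream SAF machinery assumes, normalised to sum to one; zero
    depth yields the flat triple.

    Returns (gl, depths): gl has shape (sites, N, 3), depths (sites, N).
    """
    g = np.asarray(genotypes)
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    n_sites, n_ind = g.shape
    mu = np.full((n_sites, n_ind), float(mean_depth))
    if depth_factors is not None:
        mu *= np.asarray(depth_factors, dtype=float)[:, None]
    depth = rng.poisson(mu)
    eps = error_rate
    g_half = g / 2.0
    p_derived = g_half * (1 - eps) + (1 - g_half) * (eps / 3)
    p_anc = g_half * (eps / 3) + (1 - g_half) * (1 - eps)
    p_other = 2 * eps / 3
    informative = rng.binomial(depth, 1.0 - p_other)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(informative > 0, p_derived / (p_derived + p_anc), 0.0)
    derived_reads = rng.binomial(informative, cond)
    anc_reads = informative - derived_reads
    # likelihood triple per genotype hypothesis, in log space
    gh = np.array([0.0, 0.5, 1.0])
    pd_g = gh * (1 - eps) + (1 - gh) * (eps / 3)
    pa_g = gh * (eps / 3) + (1 - gh) * (1 - eps)
    with np.errstate(divide="ignore"):
        log_pd = np.log(pd_g)
        log_pa = np.log(pa_g)
    # 0 * -inf must contribute 0, not NaN (no reads of that kind observed)
    with np.errstate(invalid="ignore"):
        term_d = np.where(
            derived_reads[:, :, None] > 0, derived_reads[:, :, None] * log_pd, 0.0
        )
        term_a = np.where(anc_reads[:, :, None] > 0, anc_reads[:, :, None] * log_pa, 0.0)
    ll = term_d + term_a
    ll -= ll.max(axis=2, keepdims=True)
    gl = np.exp(ll)
    gl /= gl.sum(axis=2, keepdims=True)
    gl[informative == 0] = 1.0 / 3.0
    return gl, depth


def _sample_sheet(species: str, n_per_sex: int) -> pd.DataFrame:
    rows = []
    for sex, tag in (("male", "m"), ("female", "f")):
        for i in range(1, n_per_sex + 1):
            ind = f"{species}_{tag}{i}"
            for tissue in ("gonad", "spleen"):
                rows.append(
                    {
                        "sample": f"{ind}_{tissue}",
                        "species": species,
                        "individual": ind,
                        "sex": sex,
                        "tissue": tissue,
                    }
                )
    return pd.DataFrame(rows)


def simulate_counts(
    config: SimulationConfig,
    genes: pd.DataFrame,
    species: str,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial read counts for one species.

    Mean count = 2^(baseline + tissue effect + sex effect) * (length/1kb)
    * library factor; dispersion is ``config.nb_dispersion`` (Poisson in
    the zero limit). Tissue effects follow the truth labels in ``genes``
    (gonad-/spleen-biased genes get +tissue_bias_lfc in their tissue);
    sex effects apply in the gonad only, where male-/female-biased genes
    get +/- sex_bias_lfc for male samples.

    Returns (counts, samples): counts is genes x samples.
    """
    samples = _sample_sheet(species, config.n_individuals_per_sex)
    n_genes = len(genes)
    baseline = rng.normal(4.0, 1.5, size=n_genes)
    lib_factor = 2.0 ** rng.normal(0.0, 0.2, size=len(samples))
    tissue_eff = np.zeros((n_genes, len(samples)))
    sex_eff = np.zeros_like(tissue_eff)
    is_gonad = (samples["tissue"] == "gonad").to_numpy()
    is_male = (samples["sex"] == "male").to_numpy()
    gonad_biased = (genes["true_tissue_class"] == "gonad-biased").to_numpy()
    spleen_biased = (genes["true_tissue_class"] == "spleen-biased").to_numpy()
    tissue_eff[np.ix_(gonad_biased, is_gonad)] = config.tissue_bias_lfc
    tissue_eff[np.ix_(spleen_biased, ~is_gonad)] = config.tissue_bias_lfc
    male_biased = (genes["true_sex_class"] == "male-biased").to_numpy()
    female_biased = (genes["true_sex_class"] == "female-biased").to_numpy()
    sex_eff[np.ix_(male_biased, is_gonad & is_male)] = config.sex_bias_lfc
    sex_eff[np.ix_(female_biased, is_gonad & ~is_male)] = config.sex_bias_lfc
    length_kb = (genes["length_bp"].to_numpy() / 1000.0)[:, None]
    mu = 2.0 ** (baseline[:, None] + tissue_eff + sex_eff) * length_kb * lib_factor[None, :]
    phi = config.nb_dispersion
    if phi < 1e-8:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / phi
        counts = rng.negative_binomial(size, size / (size + mu))
    out = pd.DataFrame(counts, index=genes["gene"].to_numpy(), columns=samples["sample"])
    out.index.name = "gene"
    return out, samples


def _coalescent_newick(names: list[str], rng: np.random.Generator) -> str:
    """Random ultrametric tree: pairwise coalescence at exponential times."""
    nodes = [(name, 0.0) for name in names]
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        merged = f"({na}:{height - ha:.10f},{nb}:{height - hb:.10f})"
        nodes = [nodes[m] for m in range(k) if m not in (i, j)] + [(merged, height)]
    # rescale total depth to 1 so bm_sigma2 is per-tree-depth
    tree = dendropy.Tree.get(data=nodes[0][0] + ";", schema="newick")
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def _brownian_on_tree(
    tree: dendropy.Tree, sigma2: float, rng: np.random.Generator, root_value: float = 0.0
) -> dict[str, float]:
    """Simulate one Brownian trait; returns tip-label -> value."""
    values: dict[int, float] = {id(tree.seed_node): root_value}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = values[id(node.parent_node)]
        bl = node.edge.length or 0.0
        values[id(node)] = parent + rng.normal(0.0, np.sqrt(sigma2 * bl)) if bl > 0 else parent
    return {
        leaf.taxon.label.replace(" ", "_"): values[id(leaf)]
        for leaf in tree.leaf_node_iter()
    }


def simulate_phylogeny_traits(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[str, pd.DataFrame, pd.Series]:
    """Random ultrametric phylogeny plus Brownian dimorphism proxies.

    Three proxies are produced per species: a dichromatism score
    (Brownian motion around a positive baseline, as dichromatism is a
    nonnegative plumage score), and sperm number and residual testes
    mass, each a 0.7-weighted share of the dichromatism trait plus
    independent Brownian noise, reflecting that the proxies index a
    common axis of post-copulatory sexual selection. The species-level
    balancing intensity is max(0, coupling * dichromatism + noise).
    """
    if config.n_species < 2:
        raise ValueError("need at least two species")
    rng = rng if rng is not None else config.rng("phylogeny")
    names = [f"sp{i + 1}" for i in range(config.n_species)]
    newick = _coalescent_newick(names, rng)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    dichromatism = _brownian_on_tree(tree, config.bm_sigma2, rng, root_value=2.0)
    rho = 0.7
    resid = np.sqrt(1.0 - rho**2)
    traits = pd.DataFrame({"species": names})
    traits["dichromatism_score"] = [dichromatism[n] for n in names]
    for name in ("sperm_number", "residual_testes_mass"):
        extra = _brownian_on_tree(tree, config.bm_sigma2, rng)
        traits[name] = rho * traits["dichromatism_score"] + resid * np.array(
            [extra[n] for n in names]
        )
    noise = rng.normal(0.0, config.coupling_noise_sd, size=config.n_species)
    strength = np.maximum(
        0.0, config.coupling * traits["dichromatism_score"].to_numpy() + noise
    )
    return newick, traits, pd.Series(strength, index=names, name="balancing_strength")


def simulate_species_gl(
    config: SimulationConfig,
    genes: pd.DataFrame,
    gene_strength: np.ndarray,
    samples: pd.DataFrame,
    rng: np.random.Generator,
    depth_factors: np.ndarray | None = None,
) -> tuple[GenotypeLikelihoodTable, np.ndarray, np.ndarray]:
    """Genotype-likelihood table for one species.

    Sites are simulated gene by gene: derived-allele frequencies are drawn
    from the gene's SFS shape (neutral or balancing, per ``gene_strength``),
    genotypes follow Hardy-Weinberg with the configured inbreeding F, and
    likelihoods come from Poisson depth plus the per-base error model.
    On the Z chromosome females are haploid: their truth genotypes are a
    single allele draw (coded 0/2 on the diploid scale); downstream
    analyses use males only on the Z.

    Returns (table, true_genotypes, true_freqs).
    """
    inds = samples.drop_duplicates("individual")
    ind_ids = inds["individual"].to_numpy()
    sexes = np.where(inds["sex"].to_numpy() == "male", "M", "F")
    n_ind = len(ind_ids)
    two_n_pop = 4 * n_ind  # frequency granularity of the source population
    n_sites = len(genes) * config.sites_per_gene
    freqs = np.empty(n_sites)
    strengths = np.repeat(np.asarray(gene_strength, dtype=float), config.sites_per_gene)
    shape_cache: dict[float, np.ndarray] = {}
    for s in np.unique(strengths):
        shape_cache[s] = simulate_sfs_shape(two_n_pop, s)
    j_vals = np.arange(1, two_n_pop)
    for s, shape in shape_cache.items():
        mask = strengths == s
        freqs[mask] = j_vals[rng.choice(len(shape), size=mask.sum(), p=shape)] / two_n_pop
    genotypes = simulate_genotypes(freqs, n_ind, config.inbreeding_f, rng)
    is_z = np.repeat((genes["chrom_class"] == "Z").to_numpy(), config.sites_per_gene)
    female = sexes == "F"
    if is_z.any() and female.any():
        hap = (rng.random((int(is_z.sum()), int(female.sum()))) < freqs[is_z, None]).astype(
            np.int8
        )
        genotypes[np.ix_(is_z, female)] = 2 * hap
    df = None
    if depth_factors is not None:
        df = np.repeat(np.asarray(depth_factors, dtype=float), config.sites_per_gene)
    gl, depth = simulate_genotype_likelihoods(
        genotypes, config.mean_depth, config.error_rate, rng, depth_factors=df
    )
    gene_ids = np.repeat(genes["gene"].to_numpy(), config.sites_per_gene)
    positions = np.tile(np.arange(1, config.sites_per_gene + 1), len(genes))
    markers = np.array([f"{g}_{p}" for g, p in zip(gene_ids, positions)])
    table = GenotypeLikelihoodTable(
        markers=markers,
        genes=gene_ids,
        positions=positions,
        gl=gl,
        has_data=depth > 0,
        sexes=sexes,
        individuals=ind_ids,
    )
    return table, genotypes, freqs


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, for every species."""

    config: SimulationConfig
    genes: pd.DataFrame              # gene universe + truth labels
    newick: str
    traits: pd.DataFrame             # species-level proxies + strength
    species: dict = field(default_factory=dict)
    # species[name] holds: gl_table, true_genotypes, true_freqs, counts,
    # samples, genemap


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate the full multi-species study from one config.

    Gene identity is shared across species (the generator emulates the
    post-orthologue-selection universe, so the cross-species orthologue
    matrix is the gene list itself). Truth labels (tissue class, sex
    class, balancing status, immune flag) are generated once and drive
    both the expression and the population-genetic simulations in every
    species.
    """
    rng_cls = config.rng("classes")
    n = config.n_genes
    genes = pd.DataFrame({"gene": [f"g{i + 1:05d}" for i in range(n)]})
    genes["chrom_class"] = np.where(rng_cls.random(n) < config.z_fraction, "Z", "A")
    u = rng_cls.random(n)
    tissue = np.where(
        u < config.gonad_biased_fraction,
        "gonad-biased",
        np.where(
            u < config.gonad_biased_fraction + config.spleen_biased_fraction,
            "spleen-biased",
            "non-tissue-biased",
        ),
    )
    genes["true_tissue_class"] = tissue
    sex = np.full(n, "unbiased", dtype=object)
    pick = rng_cls.random(n) < config.sex_biased_fraction
    direction = rng_cls.random(n) < 0.5
    sex[pick & direction] = "male-biased"
    sex[pick & ~direction] = "female-biased"
    genes["true_sex_class"] = sex
    genes["length_bp"] = rng_cls.integers(500, 5001, size=n)
    genes["gc_fraction"] = rng_cls.beta(5, 5, size=n)
    genes["immune_flag"] = rng_cls.random(n) < config.immune_fraction
    unbiased = tissue == "non-tissue-biased"
    balanced = unbiased & (rng_cls.random(n) < config.balancing_fraction)
    genes["balanced"] = balanced

    newick, traits, strength = simulate_phylogeny_traits(config)
    traits = traits.merge(
        strength.rename_axis("species").reset_index(), on="species", how="left"
    )

    dataset = SimulatedDataset(config=config, genes=genes, newick=newick, traits=traits)
    gonad_biased = (genes["true_tissue_class"] == "gonad-biased").to_numpy()
    for _, row in traits.iterrows():
        sp = row["species"]
        rng_sp = config.rng(f"species:{sp}")
        counts, samples = simulate_counts(config, genes, sp, rng_sp)
        # couple sequencing depth to expression decile (transcriptome data
        # has depth proportional to expression)
        mean_expr = counts.mean(axis=1).to_numpy()
        decile = np.argsort(np.argsort(mean_expr)) * 10 // len(mean_expr)
        depth_factors = 0.55 + 0.1 * decile
        gene_strength = np.zeros(len(genes))
        gene_strength[genes["balanced"].to_numpy()] = config.balancing_strength
        gene_strength[gonad_biased] = row["balancing_strength"]
        table, true_g, true_p = simulate_species_gl(
            config, genes, gene_strength, samples, rng_sp, depth_factors=depth_factors
        )
        genemap = pd.DataFrame(
            {
                "gene": genes["gene"],
                "chrom_class": genes["chrom_class"],
                "start": 1,
                "end": config.sites_per_gene,
            }
        )
        dataset.species[sp] = {
            "gl_table": table,
            "true_genotypes": true_g,
            "true_freqs": true_p,
            "counts": counts,
            "samples": samples,
            "genemap": genemap,
        }
    return dataset
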