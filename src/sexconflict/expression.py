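"""Expression normalisation, filtering and bias classification.

Implements the expression side of the pipeline: FPKM computation and the
low-expression filter, TMM normalisation factors, fold-change-based
classification of tissue-biased (gonad vs spleen, within one sex) and
sex-biased (male vs female, within one tissue) genes, reciprocal-best-hit
orthologue selection from BLAST-style hit tables, and removal of
immune-flagged genes.

Fold changes are computed on TMM-scaled counts per million (CPM) with a
pseudo-expression offset (default 1 CPM) so that sex-limited genes, which
may have mean zero in one group, are retained rather than dropped.
Classification is purely fold-change based; thresholds are inclusive.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

__all__ = [
    "fpkm",
    "cpm",
    "tmm_factors",
    "filter_low_expression",
    "classify_tissue_bias",
    "classify_sex_bias",
    "classify_expression",
    "select_reciprocal_best_hits",
    "exclude_flagged_genes",
]

logger = logging.getLogger(__name__)

TISSUE_LFC_THRESHOLD = 2.0   # |log2 FC| >= 2 defines tissue bias
SEX_LFC_THRESHOLD = 1.0      # |log2 FC| >= 1 defines sex bias
PSEUDO_CPM = 1.0


def _validate_counts(counts: pd.DataFrame) -> None:
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")


def fpkm(
    counts: pd.DataFrame,
    gene_length_bp: pd.Series,
    library_mapped_reads: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    FPKM = count / ((length / 1e3) * (library / 1e6)). Library sizes
    default to the column sums of the count matrix.
    """
    _validate_counts(counts)
    lengths = gene_length_bp.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if library_mapped_reads is None:
        library_mapped_reads = counts.sum(axis=0)
    lib = library_mapped_reads.reindex(counts.columns)
    if lib.isna().any() or (lib <= 0).any():
        raise ValueError("library sizes must be positive for all samples")
    return counts.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)


def cpm(counts: pd.DataFrame, norm_factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on TMM-adjusted effective library sizes."""
    _validate_counts(counts)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("all-zero sample in count matrix")
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(counts.columns)
    return counts.div(lib / 1e6, axis=1)


def tmm_factors(
    counts: pd.DataFrame,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalisation factors.

    The reference sample is the one whose upper-quartile (of counts scaled
    by library size) is closest to the mean upper-quartile. For each other
    sample, genes expressed in both are ranked by log ratio M and mean
    abundance A; the top/bottom ``log_ratio_trim`` of M and
    ``abs_expr_trim`` of A are trimmed, and the factor is two to the
    precision-weighted mean of the surviving M values. Factors are
    rescaled to geometric mean one.
    """
    _validate_counts(counts)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("all-zero sample in count matrix")
    y = counts.to_numpy(dtype=float)
    scaled = y / lib[None, :]
    uq = np.quantile(scaled, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(y.shape[1])
    yr, nr = y[:, ref], lib[ref]
    for k in range(y.shape[1]):
        if k == ref:
            continue
        yk, nk = y[:, k], lib[k]
        use = (yk > 0) & (yr > 0)
        if use.sum() == 0:
            continue
        m = np.log2((yk[use] / nk) / (yr[use] / nr))
        a = 0.5 * np.log2((yk[use] / nk) * (yr[use] / nr))
        if np.max(np.abs(m)) < 1e-10:  # identical composition
            continue
        n_use = use.sum()
        lo_m = np.floor(n_use * log_ratio_trim) + 1
        lo_a = np.floor(n_use * abs_expr_trim) + 1
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (
            (rank_m >= lo_m)
            & (rank_m <= n_use + 1 - lo_m)
            & (rank_a >= lo_a)
            & (rank_a <= n_use + 1 - lo_a)
        )
        if keep.sum() == 0:
            continue
        # asymptotic (delta-method) inverse variance of M
        w = (nk - yk[use]) / (nk * yk[use]) + (nr - yr[use]) / (nr * yr[use])
        factors[k] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def filter_low_expression(
    fpkm_matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    threshold: float = 2.0,
) -> pd.Index:
    """Genes retained after the low-expression filter.

    A gene is removed when, in the gonad or in the spleen, the number of
    individuals with FPKM below ``threshold`` is at least half (ceil(n/2))
    of the individuals sampled for that tissue.
    """
    tissues = set(sample_sheet["tissue"])
    if not {"gonad", "spleen"} <= tissues:
        raise ValueError("both gonad and spleen samples are required")
    removed = np.zeros(len(fpkm_matrix), dtype=bool)
    for tissue in ("gonad", "spleen"):
        cols = sample_sheet.loc[sample_sheet["tissue"] == tissue, "sample"]
        block = fpkm_matrix[cols]
        n_low = (block < threshold).sum(axis=1).to_numpy()
        removed |= n_low >= math.ceil(len(cols) / 2)
    return fpkm_matrix.index[~removed]


def _log2_ratio(mean_a: pd.Series, mean_b: pd.Series, pseudo: float) -> pd.Series:
    return np.log2((mean_a + pseudo) / (mean_b + pseudo))


def classify_tissue_bias(
    normalized_expr: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    sex: str,
    pseudo: float = PSEUDO_CPM,
    threshold: float = TISSUE_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Gonad-/spleen-/non-tissue-biased calls within one sex.

    log2 FC = log2((mean gonad + c) / (mean spleen + c)) over the given
    sex's samples; >= threshold is gonad-biased, <= -threshold is
    spleen-biased. Returns a frame with columns ``log2fc_tissue`` and
    ``tissue_class`` indexed by gene.
    """
    sub = sample_sheet[sample_sheet["sex"] == sex]
    if sub.empty:
        raise ValueError(f"no samples for sex {sex!r}")
    gonad = sub.loc[sub["tissue"] == "gonad", "sample"]
    spleen = sub.loc[sub["tissue"] == "spleen", "sample"]
    if gonad.empty or spleen.empty:
        raise ValueError(f"sex {sex!r} lacks samples in one tissue")
    lfc = _log2_ratio(
        normalized_expr[gonad].mean(axis=1), normalized_expr[spleen].mean(axis=1), pseudo
    )
    cls = np.where(
        lfc >= threshold,
        "gonad-biased",
        np.where(lfc <= -threshold, "spleen-biased", "non-tissue-biased"),
    )
    return pd.DataFrame(
        {"log2fc_tissue": lfc, "tissue_class": cls}, index=normalized_expr.index
    )


def classify_sex_bias(
    normalized_expr: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    tissue: str,
    gene_set: pd.Index | None = None,
    pseudo: float = PSEUDO_CPM,
    threshold: float = SEX_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Male-/female-biased/unbiased calls within one tissue.

    log2 FC = log2((mean male + c) / (mean female + c)); >= threshold is
    male-biased, <= -threshold female-biased. The pseudo-expression offset
    keeps sex-limited genes (zero in one sex) in the analysis.
    """
    sub = sample_sheet[sample_sheet["tissue"] == tissue]
    male = sub.loc[sub["sex"] == "male", "sample"]
    female = sub.loc[sub["sex"] == "female", "sample"]
    if male.empty or female.empty:
        raise ValueError(f"tissue {tissue!r} lacks samples from one sex")
    expr = normalized_expr if gene_set is None else normalized_expr.loc[gene_set]
    lfc = _log2_ratio(expr[male].mean(axis=1), expr[female].mean(axis=1), pseudo)
    cls = np.where(
        lfc >= threshold, "male-biased", np.where(lfc <= -threshold, "female-biased", "unbiased")
    )
    return pd.DataFrame({"log2fc_sex": lfc, "sex_class": cls}, index=expr.index)


def classify_expression(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    annotation: pd.DataFrame,
    classification_sex: str = "male",
    fpkm_min: float = 2.0,
    tissue_threshold: float = TISSUE_LFC_THRESHOLD,
    sex_threshold: float = SEX_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Full expression classification for one species.

    Applies the FPKM filter, TMM-normalises, classifies tissue bias within
    ``classification_sex`` (Z-linked genes in a separate pass, flag
    preserved), and sex bias within each tissue. Returns one row per
    retained gene with tissue/sex classes, fold changes, mean expression
    and the Z-linkage flag.
    """
    ann = annotation.set_index("gene") if "gene" in annotation.columns else annotation
    fp = fpkm(counts, ann["length_bp"])
    kept = filter_low_expression(fp, sample_sheet, threshold=fpkm_min)
    counts = counts.loc[kept]
    factors = tmm_factors(counts)
    norm = cpm(counts, factors)
    z_linked = ann.loc[kept, "chrom_class"] == "Z"
    pieces = []
    for on_z in (False, True):  # Z classified in a separate pass
        idx = kept[z_linked.to_numpy() == on_z]
        if len(idx) == 0:
            continue
        tis = classify_tissue_bias(
            norm.loc[idx], sample_sheet, classification_sex, threshold=tissue_threshold
        )
        tis["z_linked"] = on_z
        pieces.append(tis)
    result = pd.concat(pieces).loc[kept]
    sex_gonad = classify_sex_bias(norm, sample_sheet, "gonad", threshold=sex_threshold)
    sex_spleen = classify_sex_bias(norm, sample_sheet, "spleen", threshold=sex_threshold)
    result["log2fc_sex_gonad"] = sex_gonad["log2fc_sex"]
    result["sex_class_gonad"] = sex_gonad["sex_class"]
    result["log2fc_sex_spleen"] = sex_spleen["log2fc_sex"]
    result["sex_class_spleen"] = sex_spleen["sex_class"]
    # the sex class relevant to a tissue-biased gene is the one from its tissue
    result["sex_class"] = np.where(
        result["tissue_class"] == "spleen-biased",
        result["sex_class_spleen"],
        result["sex_class_gonad"],
    )
    result["log2fc_sex"] = np.where(
        result["tissue_class"] == "spleen-biased",
        result["log2fc_sex_spleen"],
        result["log2fc_sex_gonad"],
    )
    result["mean_cpm"] = norm.mean(axis=1)
    result["classification_sex"] = classification_sex
    result.index.name = "gene"
    return result


HIT_COLUMNS = ["query", "subject", "pident", "evalue", "bitscore"]


def _best_hits(
    hits: pd.DataFrame, evalue_max: float, pident_min: float
) -> dict[str, str]:
    """Best subject per query after e-value/identity filtering.

    Ties on bitscore are broken by percent identity; queries whose two top
    hits tie on both are discarded.
    """
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table lacks columns {missing}")
    for col in ("pident", "evalue", "bitscore"):
        if hits[col].isna().any():
            row = int(hits.index[hits[col].isna()][0])
            raise ValueError(f"unparseable value in column {col!r} at row {row}")
    ok = hits[(hits["evalue"] <= evalue_max) & (hits["pident"] >= pident_min)]
    best: dict[str, str] = {}
    for query, grp in ok.groupby("query", sort=False):
        top = grp[grp["bitscore"] == grp["bitscore"].max()]
        top = top[top["pident"] == top["pident"].max()]
        if len(top) > 1 and top["subject"].nunique() > 1:
            continue  # ambiguous: gene discarded
        best[str(query)] = str(top["subject"].iloc[0])
    return best


def select_reciprocal_best_hits(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    evalue_max: float = 1e-10,
    pident_min: float = 30.0,
) -> pd.DataFrame:
    """Reciprocal-best-hit orthologue pairs from two BLAST hit tables.

    A pair (a, b) is retained iff b is a's best surviving hit in A->B and
    a is b's best surviving hit in B->A, after dropping hits with e-value
    above ``evalue_max`` or identity below ``pident_min``.
    """
    best_ab = _best_hits(hits_ab, evalue_max, pident_min)
    best_ba = _best_hits(hits_ba, evalue_max, pident_min)
    pairs = [
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    ]
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])


def exclude_flagged_genes(
    gene_set: pd.Index, annotation: pd.DataFrame, flag: str = "immune_flag"
) -> pd.Index:
    """Remove genes whose annotation flag is set (e.g. immune/MHC loci)."""
    ann = annotation.set_index("gene") if "gene" in annotation.columns else annotation
    flags = ann[flag].reindex(gene_set)
    if flags.isna().any():
        raise ValueError("annotation does not cover the gene set")
    removed = int(flags.sum())
    logger.info("excluding %d flagged genes (%s)", removed, flag)
    kept = gene_set[~flags.to_numpy(dtype=bool)]
    if len(kept) == 0:
        logger.warning("all genes were flagged; returning empty set")
    return kept
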