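"""Gene-level disome-enrichment testing and RQC-target classification.

Collided ribosomes are sampled as disome footprints; transcripts targeted
by ribosome-associated quality control (RQC) gain disomes in the
modification mutant and lose them again when the collision sensor Hel2 is
removed.  The statistical contract is a per-gene negative-binomial
generalised linear model of counts with design

    ~ fraction + genotype + fraction:genotype

tested against the reduced model ``~ fraction + genotype`` by a
likelihood-ratio test (the interaction asks whether the disome/monosome
ratio differs between genotypes).  Library sizes are normalised by
median-of-ratios size factors; per-gene dispersions are estimated by
Cox-Reid adjusted profile likelihood, shrunk toward a fitted
mean-dispersion trend (a deliberate simplification of the reference
empirical-Bayes machinery); p-values are Benjamini-Hochberg adjusted.

A gene is an RQC target when its disome enrichment is significantly
positive in the mutant-vs-wild-type contrast and significantly negative in
the triple-vs-double contrast; the sign-mirrored pattern defines
RQC-refractory transcripts (RRTs).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .core import Transcriptome, assign_a_sites
from .geometry import DEFAULT_OFFSETS, OffsetTable

_ALPHA_BOUNDS = (np.log(1e-8), np.log(10.0))


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_gene_footprints(
    records: pd.DataFrame,
    transcriptome: Transcriptome,
    offsets: OffsetTable = DEFAULT_OFFSETS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene footprint totals for every (genotype, fraction, replicate).

    A footprint counts toward a gene when its assigned A site lies inside
    the CDS; footprints in the flanks are excluded.  Returns ``(counts,
    meta)`` with counts as genes x samples and one metadata row per sample.
    """
    assigned = assign_a_sites(records, transcriptome, offsets)
    inside = assigned[assigned["codon_index"] >= 0]
    grouped = (
        inside.groupby(["transcript_id", "genotype", "fraction", "replicate"], sort=True)["count"]
        .sum()
        .reset_index()
    )
    grouped["sample"] = (
        grouped["genotype"] + "_" + grouped["fraction"] + "_" + grouped["replicate"]
    )
    counts = (
        grouped.pivot_table(index="transcript_id", columns="sample", values="count", fill_value=0)
        .reindex(sorted(transcriptome), fill_value=0)
        .astype(np.int64)
    )
    counts.index.name = "gene"
    meta = (
        grouped[["sample", "genotype", "fraction", "replicate"]]
        .drop_duplicates()
        .sort_values("sample")
        .reset_index(drop=True)
    )
    return counts, meta


# ---------------------------------------------------------------------------
# size factors and dispersion machinery
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    logc = np.log(mat[positive])
    loggeo = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - loggeo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    r = 1.0 / alpha
    return float(np.sum(stats.nbinom.logpmf(y, r, r / (r + mu))))


def _cr_adjustment(X: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Cox-Reid adjustment: -0.5 log det(X' W X) with NB IRLS weights."""
    w = mu / (1.0 + alpha * mu)
    xtwx = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    return -0.5 * logdet


def _ml_dispersion(
    y: np.ndarray,
    mu: np.ndarray,
    X: np.ndarray,
    log_prior_mean: float | None = None,
    prior_var: float | None = None,
) -> float:
    """Cox-Reid adjusted profile-likelihood dispersion estimate.

    With a prior, returns the posterior mode under a log-normal prior on
    the dispersion (maximum a posteriori shrinkage toward the trend).
    """

    def neg(loga: float) -> float:
        a = float(np.exp(loga))
        obj = _nb_loglik(y, mu, a) + _cr_adjustment(X, mu, a)
        if log_prior_mean is not None:
            obj -= (loga - log_prior_mean) ** 2 / (2.0 * prior_var)
        return -obj

    res = optimize.minimize_scalar(neg, bounds=_ALPHA_BOUNDS, method="bounded")
    return float(np.exp(res.x))


def _fit_glm(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float):
    model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100, tol=1e-8)


def _dispersion_trend(alphas: np.ndarray, means: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu by iteratively reweighted least squares on
    the genewise estimates (gamma-family style), coefficients clipped >= 0."""
    ok = np.isfinite(alphas) & np.isfinite(means) & (means > 0) & (alphas > 1e-8)
    a, m = alphas[ok], means[ok]
    if a.size < 10:
        return float(np.median(a)) if a.size else 0.1, 0.0
    A = np.column_stack([np.ones_like(m), 1.0 / m])
    coef = np.array([np.median(a), 0.0])
    for _ in range(10):
        pred = np.clip(A @ coef, 1e-8, None)
        # gamma weights: Var ~ pred^2
        W = 1.0 / pred**2
        lhs = A.T @ (A * W[:, None])
        rhs = A.T @ (a * W)
        try:
            new = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError:
            break
        new = np.clip(new, 0.0, None)
        if np.allclose(new, coef, rtol=1e-6, atol=1e-12):
            coef = new
            break
        coef = new
    return float(coef[0]), float(coef[1])


def _design_matrices(meta: pd.DataFrame, genotypes: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    is_di = (meta["fraction"] == "disome").to_numpy(dtype=float)
    is_b = (meta["genotype"] == genotypes[1]).to_numpy(dtype=float)
    ones = np.ones(len(meta))
    X_full = np.column_stack([ones, is_di, is_b, is_di * is_b])
    X_red = X_full[:, :3]
    return X_full, X_red


# ---------------------------------------------------------------------------
# interaction test
# ---------------------------------------------------------------------------

def interaction_de(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    condition_pair: tuple[str, str],
    shrink_prior_floor: float = 0.25,
) -> pd.DataFrame:
    """Likelihood-ratio test of the fraction x genotype interaction per gene.

    ``condition_pair`` names (reference, test) genotypes; both must be
    present with both fractions.  Returns a frame indexed by gene with
    columns base_mean, log2fc (interaction coefficient, log2), stat,
    p_value, p_adj; genes with all-zero counts are excluded.
    """
    meta = meta.set_index("sample").loc[counts.columns]
    meta.index.name = "sample"
    meta = meta.reset_index()
    keep = meta["genotype"].isin(condition_pair)
    meta = meta[keep].reset_index(drop=True)
    counts = counts.loc[:, meta["sample"]]
    for genotype in condition_pair:
        sub = meta[meta["genotype"] == genotype]
        if sub.empty or set(sub["fraction"]) != {"monosome", "disome"}:
            raise ValueError(f"genotype {genotype!r} must have monosome and disome samples")

    nonzero = counts.sum(axis=1) > 0
    counts = counts.loc[nonzero]
    sf = size_factors(counts)
    offset = np.log(sf.to_numpy())
    X_full, X_red = _design_matrices(meta, condition_pair)
    mat = counts.to_numpy(dtype=float)
    norm_means = (mat / sf.to_numpy()).mean(axis=1)

    # pass 1: genewise Cox-Reid dispersions at moment-initialised fits
    n_genes = mat.shape[0]
    alphas = np.full(n_genes, np.nan)
    mus = [None] * n_genes
    for g in range(n_genes):
        y = mat[g]
        try:
            fit0 = _fit_glm(y, X_full, offset, alpha=0.1)
            mu = np.clip(fit0.mu, 1e-8, None)
            alphas[g] = _ml_dispersion(y, mu, X_full)
            mus[g] = mu
        except Exception:
            pass

    # genewise estimates stuck at the lower optimisation bound carry no
    # information (sub-Poisson noise by chance); they get the trend value
    # and are excluded from the trend and prior-width fits
    usable = np.isfinite(alphas) & (alphas > 1e-6)
    a0, a1 = _dispersion_trend(np.where(usable, alphas, np.nan), norm_means)
    trend = np.clip(a0 + a1 / np.clip(norm_means, 1e-8, None), 1e-8, None)

    # MAP shrinkage toward the trend (log scale), prior width from the
    # robust spread of the log residuals minus the expected sampling noise
    m, p = X_full.shape
    sampling_var = float(special.polygamma(1, (m - p) / 2.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        logres = np.log(alphas) - np.log(trend)
    res = logres[usable]
    if res.size:
        mad_sd = 1.4826 * float(np.median(np.abs(res - np.median(res))))
        prior_var = max(mad_sd**2 - sampling_var, shrink_prior_floor)
    else:
        prior_var = shrink_prior_floor
    alpha_map = np.empty(n_genes)
    for g in range(n_genes):
        if mus[g] is None:
            alpha_map[g] = trend[g]
        else:
            alpha_map[g] = _ml_dispersion(
                mat[g], mus[g], X_full,
                log_prior_mean=float(np.log(trend[g])), prior_var=prior_var,
            )

    # pass 2: final fits and LRT
    rows = []
    for g in range(n_genes):
        y = mat[g]
        a = float(alpha_map[g])
        try:
            fit_full = _fit_glm(y, X_full, offset, a)
            fit_red = _fit_glm(y, X_red, offset, a)
            stat = max(2.0 * (fit_full.llf - fit_red.llf), 0.0)
            pval = float(stats.chi2.sf(stat, df=1))
            lfc = float(fit_full.params[3] / np.log(2.0))
        except Exception:
            stat, pval, lfc = np.nan, np.nan, np.nan
        rows.append((norm_means[g], lfc, stat, pval, a))
    out = pd.DataFrame(
        rows,
        index=counts.index,
        columns=["base_mean", "log2fc", "stat", "p_value", "dispersion"],
    )
    tested = out["p_value"].notna()
    padj = np.full(len(out), np.nan)
    if tested.any():
        padj[tested.to_numpy()] = multipletests(out.loc[tested, "p_value"], method="fdr_bh")[1]
    out["p_adj"] = padj
    return out


# ---------------------------------------------------------------------------
# classification and gene-set statistics
# ---------------------------------------------------------------------------

def classify_rqc(
    de_mut_vs_wt: pd.DataFrame,
    de_triple_vs_double: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Label genes as RQC_target / RRT / neither from the two contrasts.

    RQC target: disomes significantly up in the modification mutant vs wild
    type AND significantly down in the triple vs double mutant.  RRT: the
    sign-mirrored pattern.  Labels are mutually exclusive and cover the
    intersection of the tested gene universes.
    """
    genes = de_mut_vs_wt.index.intersection(de_triple_vs_double.index)
    d1 = de_mut_vs_wt.loc[genes]
    d2 = de_triple_vs_double.loc[genes]
    sig1 = (d1["p_adj"] < alpha).fillna(False)
    sig2 = (d2["p_adj"] < alpha).fillna(False)
    up1, dn1 = d1["log2fc"] > 0, d1["log2fc"] < 0
    up2, dn2 = d2["log2fc"] > 0, d2["log2fc"] < 0
    label = np.where(
        sig1 & up1 & sig2 & dn2,
        "RQC_target",
        np.where(sig1 & dn1 & sig2 & up2, "RRT", "neither"),
    )
    return pd.DataFrame({"label": label}, index=genes)


def compare_logfc_distributions(
    lfc_set1: Iterable[float],
    lfc_set2: Iterable[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of log2 fold-change sets.

    ``alternative`` follows scipy's convention for the empirical CDFs
    ('less': CDF of set1 lies below set2, i.e. set1 stochastically larger).
    Returns (D, p).
    """
    a = np.asarray(list(lfc_set1), dtype=float)
    b = np.asarray(list(lfc_set2), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both log2fc sets must be non-empty")
    res = stats.ks_2samp(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def aggregation_crosstab(
    labels: pd.DataFrame,
    aggregate_fold_changes: pd.Series,
    up_threshold: float = 2.0,
    down_threshold: float = 0.5,
) -> tuple[pd.DataFrame, float | None, float | None]:
    """Cross-tabulate aggregation propensity against RQC labels.

    Genes with linear-scale aggregate fold change strictly above
    ``up_threshold`` are aggregation-prone, strictly below
    ``down_threshold`` non-aggregating; others are dropped.  Returns the
    2x2 table, the odds ratio, and the two-sided Fisher's exact p-value
    (None when a margin is empty).
    """
    genes = labels.index.intersection(aggregate_fold_changes.index)
    lab = labels.loc[genes, "label"]
    fc = aggregate_fold_changes.loc[genes]
    cat = pd.Series(pd.NA, index=genes, dtype=object)
    cat[fc > up_threshold] = "aggregation_prone"
    cat[fc < down_threshold] = "non_aggregating"
    keep = cat.notna() & lab.isin(["RQC_target", "RRT"])
    table = pd.crosstab(cat[keep], lab[keep]).reindex(
        index=["aggregation_prone", "non_aggregating"],
        columns=["RQC_target", "RRT"],
        fill_value=0,
    )
    arr = table.to_numpy()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("empty category in aggregation cross-tab; test skipped", stacklevel=2)
        return table, None, None
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return table, float(odds), float(p)


def codon_content_enrichment(
    labels: pd.DataFrame,
    transcriptome: Transcriptome,
    query: Sequence[str] | Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Compare per-gene density of queried codons/pairs between RQC targets and RRTs.

    Density is occurrences per CDS codon (pairs count per adjacent sense
    codon pair).  The groups are compared with a two-sided Mann-Whitney U
    test; returns one row per group plus the test statistics as attrs.
    """
    query = list(query)
    pairs = bool(query) and not isinstance(query[0], str)

    def density(gene: str) -> float:
        ann = transcriptome[gene]
        codons = ann.codons[:-1]  # sense region
        if pairs:
            hits = sum(
                1 for i in range(1, len(codons)) if (codons[i - 1], codons[i]) in set(query)
            )
        else:
            qset = set(query)
            hits = sum(1 for c in codons if c in qset)
        return hits / len(codons)

    groups = {}
    for name in ("RQC_target", "RRT"):
        genes = labels.index[labels["label"] == name]
        if len(genes) == 0:
            raise ValueError(f"label group {name!r} is empty")
        groups[name] = np.array([density(g) for g in genes])
    u, p = stats.mannwhitneyu(groups["RQC_target"], groups["RRT"], alternative="two-sided")
    out = pd.DataFrame(
        {
            "group": list(groups),
            "n_genes": [len(v) for v in groups.values()],
            "mean_density": [float(v.mean()) for v in groups.values()],
            "median_density": [float(np.median(v)) for v in groups.values()],
        }
    )
    out.attrs["statistic"] = float(u)
    out.attrs["p_value"] = float(p)
    return out
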