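"""Codon-resolution translation-speed statistics.

Two complementary estimators of codon decoding speed:

* the position-based **pause score**: the A-site read count of a codon
  position divided by the mean count over the gene's included positions
  (15 codons trimmed from each CDS end), so that the per-gene mean pause
  score is exactly 1;
* the read-based **relative A-site occupancy**: the transcriptome-wide
  frequency of each codon in the A site normalised to its frequency at the
  +1/+2/+3 downstream sites, compared between genotypes as a
  median-centred log2 ratio.

The **vulnerability score** of a codon instance is the ratio of its pause
score in the mutant to that in the wild type, computed on pseudocounted
(+1) counts and aggregated as the median over replicate pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codons import AMINO_ACIDS, SENSE_CODONS, translate_codon
from .core import Transcriptome, assign_a_sites
from .geometry import DEFAULT_OFFSETS, OffsetTable

EXCLUDE_ENDS = 15
MIN_COVERAGE = 0.1


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

@dataclass
class CodonOccupancy:
    """Per-gene, per-codon-position A-site read counts.

    ``counts[gene]`` has one entry per CDS codon (stop included); positions
    within ``exclude_ends`` of either end are flagged excluded but retained
    so context profiles can still read them.
    """

    counts: dict[str, np.ndarray]
    transcriptome: Transcriptome
    exclude_ends: int = EXCLUDE_ENDS

    def included_slice(self, gene: str) -> slice:
        l = self.transcriptome[gene].n_codons
        return slice(self.exclude_ends, l - self.exclude_ends)

    def coverage(self, gene: str) -> float:
        """Mean reads per codon over the whole CDS."""
        return float(self.counts[gene].sum()) / self.transcriptome[gene].n_codons

    @property
    def genes(self) -> list[str]:
        return list(self.counts)


def build_occupancy(
    records: pd.DataFrame,
    transcriptome: Transcriptome,
    offsets: OffsetTable = DEFAULT_OFFSETS,
    exclude_ends: int = EXCLUDE_ENDS,
) -> CodonOccupancy:
    """Accumulate A-site-assigned counts per (gene, codon position).

    ``records`` should already be selected; footprints whose A site falls
    outside the CDS are dropped.  Genes with no footprints get all-zero
    vectors.
    """
    counts = {tid: np.zeros(ann.n_codons, dtype=np.int64) for tid, ann in transcriptome.items()}
    if len(records):
        assigned = records if "codon_index" in records.columns else assign_a_sites(
            records, transcriptome, offsets
        )
        inside = assigned[assigned["codon_index"] >= 0]
        grouped = inside.groupby(["transcript_id", "codon_index"], sort=False)["count"].sum()
        for (tid, idx), c in grouped.items():
            counts[tid][idx] += c
    return CodonOccupancy(counts=counts, transcriptome=transcriptome, exclude_ends=exclude_ends)


def occupancy_by_library(
    records: pd.DataFrame,
    transcriptome: Transcriptome,
    offsets: OffsetTable = DEFAULT_OFFSETS,
    fraction: str = "monosome",
    exclude_ends: int = EXCLUDE_ENDS,
) -> dict[tuple[str, str], CodonOccupancy]:
    """Occupancy matrices keyed by (genotype, replicate) for one fraction."""
    sub = records[records["fraction"] == fraction]
    assigned = assign_a_sites(sub, transcriptome, offsets)
    out = {}
    for (genotype, rep), grp in assigned.groupby(["genotype", "replicate"], sort=True):
        out[(genotype, rep)] = build_occupancy(grp, transcriptome, offsets, exclude_ends)
    return out


# ---------------------------------------------------------------------------
# pause scores (position-based)
# ---------------------------------------------------------------------------

@dataclass
class PauseScores:
    """Per-gene pause-score vectors; NaN outside the included positions."""

    scores: dict[str, np.ndarray]
    transcriptome: Transcriptome
    exclude_ends: int = EXCLUDE_ENDS

    @property
    def genes(self) -> list[str]:
        return list(self.scores)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene, vec in self.scores.items():
            codons = self.transcriptome[gene].codons
            idx = np.flatnonzero(~np.isnan(vec))
            rows.append(
                pd.DataFrame(
                    {
                        "gene": gene,
                        "position": idx,
                        "codon": [codons[i] for i in idx],
                        "pause_score": vec[idx],
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=["gene", "position", "codon", "pause_score"])
        return pd.concat(rows, ignore_index=True)


def pause_scores(
    occupancy: CodonOccupancy,
    min_coverage: float = MIN_COVERAGE,
    pseudocount: float = 0.0,
) -> PauseScores:
    """Pause score per included codon position of every sufficiently covered gene.

    Genes with fewer than ``min_coverage`` reads per codon (over the whole
    CDS) are dropped.  The score of position *i* is its (pseudocounted)
    count divided by the mean count over the gene's included positions, so
    the mean score per gene is exactly 1.
    """
    out: dict[str, np.ndarray] = {}
    trim = occupancy.exclude_ends
    for gene, vec in occupancy.counts.items():
        l = occupancy.transcriptome[gene].n_codons
        if l <= 2 * trim:
            continue
        if occupancy.coverage(gene) < min_coverage:
            continue
        c = vec.astype(float) + pseudocount
        included = c[trim : l - trim]
        denom = included.mean()
        if denom == 0:
            warnings.warn(f"gene {gene}: zero reads on included positions, dropped", stacklevel=2)
            continue
        s = np.full(l, np.nan)
        s[trim : l - trim] = included / denom
        out[gene] = s
    return PauseScores(scores=out, transcriptome=occupancy.transcriptome, exclude_ends=trim)


# ---------------------------------------------------------------------------
# vulnerability scores
# ---------------------------------------------------------------------------

def vulnerability_scores(
    occ_mut: Sequence[CodonOccupancy],
    occ_wt: Sequence[CodonOccupancy],
    pseudocount: float = 1.0,
    min_coverage: float = MIN_COVERAGE,
) -> pd.DataFrame:
    """Per-codon-instance mutant/wild-type pause-score ratios.

    Pause scores are recomputed on counts + ``pseudocount`` for both
    genotypes; the score is the median over all mutant x wild-type
    replicate pairs, and the p-value is a two-sample Student's t test of
    the per-replicate pause scores at that position.

    Only genes passing the coverage filter in every replicate of both
    genotypes are scored.  Returns a tidy frame with columns
    gene, position, codon, vulnerability, p_value.
    """
    mut_ps = [pause_scores(o, min_coverage, pseudocount) for o in occ_mut]
    wt_ps = [pause_scores(o, min_coverage, pseudocount) for o in occ_wt]
    gene_sets = [set(p.genes) for p in mut_ps + wt_ps]
    genes = sorted(set.intersection(*gene_sets)) if gene_sets else []
    if not genes and (occ_mut or occ_wt):
        mut_all = set.intersection(*(set(p.genes) for p in mut_ps)) if mut_ps else set()
        wt_all = set.intersection(*(set(p.genes) for p in wt_ps)) if wt_ps else set()
        only_mut = sorted(mut_all - wt_all)[:5]
        only_wt = sorted(wt_all - mut_all)[:5]
        if only_mut or only_wt:
            raise ValueError(
                f"no genes shared between genotypes after coverage filtering "
                f"(mutant-only: {only_mut}, wild-type-only: {only_wt})"
            )
    tx = occ_mut[0].transcriptome
    rows = []
    for gene in genes:
        m = np.stack([p.scores[gene] for p in mut_ps])  # (reps, l)
        w = np.stack([p.scores[gene] for p in wt_ps])
        # median over all replicate pairs of the ratio
        ratios = m[:, None, :] / w[None, :, :]  # (m_reps, w_reps, l)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # trimmed positions are all-NaN
            med = np.nanmedian(ratios.reshape(-1, ratios.shape[-1]), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-variance positions yield NaN p
            _, p = stats.ttest_ind(m, w, axis=0, equal_var=True)
        idx = np.flatnonzero(~np.isnan(med))
        codons = tx[gene].codons
        rows.append(
            pd.DataFrame(
                {
                    "gene": gene,
                    "position": idx,
                    "codon": [codons[i] for i in idx],
                    "vulnerability": med[idx],
                    "p_value": np.asarray(p)[idx],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["gene", "position", "codon", "vulnerability", "p_value"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# read-based codon speed
# ---------------------------------------------------------------------------

def _codon_frequencies(
    assigned: pd.DataFrame, transcriptome: Transcriptome, exclude_ends: int
) -> tuple[np.ndarray, np.ndarray]:
    """(A-site freq, +1/+2/+3 freq) over the 61 sense codons, count-weighted."""
    # global position lookup: gene offsets into one concatenated codon-id array
    offsets_map: dict[str, int] = {}
    ids = []
    total = 0
    for tid, ann in transcriptome.items():
        offsets_map[tid] = total
        ids.append(ann.codon_ids)
        total += ann.n_codons
    all_ids = np.concatenate(ids)
    ncod = {tid: ann.n_codons for tid, ann in transcriptome.items()}

    k = assigned["codon_index"].to_numpy()
    cnt = assigned["count"].to_numpy()
    gene_off = assigned["transcript_id"].map(offsets_map).to_numpy()
    gene_len = assigned["transcript_id"].map(ncod).to_numpy()
    included = (k >= exclude_ends) & (k < gene_len - exclude_ends)
    k, cnt, gene_off, gene_len = k[included], cnt[included], gene_off[included], gene_len[included]

    a_ids = all_ids[gene_off + k]
    fa = np.bincount(a_ids[a_ids >= 0], weights=cnt[a_ids >= 0], minlength=len(SENSE_CODONS))
    fb = np.zeros(len(SENSE_CODONS))
    for d in (1, 2, 3):
        ok = k + d < gene_len - 1  # stay on sense codons (exclude the stop)
        ids_d = all_ids[gene_off[ok] + k[ok] + d]
        good = ids_d >= 0
        fb += np.bincount(ids_d[good], weights=cnt[ok][good], minlength=len(SENSE_CODONS))
    return fa / fa.sum(), fb / fb.sum()


def read_based_speed(
    records: pd.DataFrame,
    transcriptome: Transcriptome,
    mutant: str,
    wildtype: str,
    offsets: OffsetTable = DEFAULT_OFFSETS,
    exclude_ends: int = EXCLUDE_ENDS,
    p_threshold: float = 0.05,
    lfc_threshold: float = 0.1,
) -> pd.DataFrame:
    """Relative A-site occupancy of the 61 sense codons, mutant vs wild type.

    Per replicate the A-site frequency of each codon is normalised to its
    mean frequency at the +1/+2/+3 sites; the mutant/wild-type ratio is
    log2-transformed and median-centred over the 61 codons.  Significance:
    one-sided Welch's t test (mutant slower, i.e. higher occupancy) across
    replicates at ``p < 0.05`` combined with a centred log2 fold change
    above 0.1.

    Returns a 61-row frame: codon, log2fc, p_value, significant, n_missing.
    """
    mono = records[records["fraction"] == "monosome"]
    assigned = assign_a_sites(mono, transcriptome, offsets)
    assigned = assigned[assigned["codon_index"] >= 0]

    def _rates(genotype: str) -> np.ndarray:
        reps = sorted(assigned.loc[assigned["genotype"] == genotype, "replicate"].unique())
        if not reps:
            raise ValueError(f"no monosome records for genotype {genotype!r}")
        mat = []
        for rep in reps:
            sub = assigned[(assigned["genotype"] == genotype) & (assigned["replicate"] == rep)]
            fa, fb = _codon_frequencies(sub, transcriptome, exclude_ends)
            with np.errstate(divide="ignore", invalid="ignore"):
                mat.append(np.where(fb > 0, fa / fb, np.nan))
        return np.stack(mat)  # (reps, 61)

    r_mut = _rates(mutant)
    r_wt = _rates(wildtype)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(np.nanmean(r_mut, axis=0) / np.nanmean(r_wt, axis=0))
        log_mut = np.log2(r_mut)
        log_wt = np.log2(r_wt)
    missing = ~np.isfinite(lfc)
    lfc_centered = lfc - np.nanmedian(np.where(missing, np.nan, lfc))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.ttest_ind(log_mut, log_wt, axis=0, equal_var=False, alternative="greater")
    p = np.asarray(p)
    out = pd.DataFrame(
        {
            "codon": SENSE_CODONS,
            "log2fc": lfc_centered,
            "p_value": p,
            "significant": (p < p_threshold) & (lfc_centered > lfc_threshold),
            "missing": missing,
        }
    )
    return out


# ---------------------------------------------------------------------------
# decile binning
# ---------------------------------------------------------------------------

def decile_enrichment(vulnerability: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Per-codon enrichment across rank bins of the vulnerability scores.

    Instances are ranked (ascending) and split into ``n_bins`` equal-size
    groups, remainders going to the lower bins; enrichment of codon *c* in
    bin *b* is its frequency in the bin over its overall frequency.
    Returns codons x bins (bin 1 = lowest scores).
    """
    if len(vulnerability) < n_bins:
        raise ValueError(f"need at least {n_bins} scored instances")
    ranked = vulnerability.sort_values(
        ["vulnerability", "gene", "position"], kind="mergesort"
    ).reset_index(drop=True)
    n = len(ranked)
    base, extra = divmod(n, n_bins)
    sizes = [base + 1 if b < extra else base for b in range(n_bins)]
    ranked["bin"] = np.repeat(np.arange(1, n_bins + 1), sizes)
    overall = ranked["codon"].value_counts(normalize=True)
    table = pd.DataFrame(index=pd.Index(SENSE_CODONS, name="codon"))
    for b in range(1, n_bins + 1):
        freq = ranked.loc[ranked["bin"] == b, "codon"].value_counts(normalize=True)
        table[b] = (freq / overall).reindex(SENSE_CODONS)
    return table


# ---------------------------------------------------------------------------
# positional residue enrichment ("motif" analysis)
# ---------------------------------------------------------------------------

def _upstream_residues(
    instances: pd.DataFrame, transcriptome: Transcriptome, window: int
) -> tuple[pd.DataFrame, int]:
    """(position x residue counts over -1..-window, number of skipped cells)."""
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(-window, 0, name="position"), columns=list(AMINO_ACIDS)
    )
    skipped = 0
    for gene, pos in zip(instances["gene"], instances["position"]):
        codons = transcriptome[gene].codons
        for d in range(1, window + 1):
            i = pos - d
            if i < 1:  # never read the start codon or beyond
                skipped += 1
                continue
            aa = translate_codon(codons[i])
            if aa == "*":
                continue
            counts.loc[-d, aa] += 1
    return counts, skipped


def positional_residue_enrichment(
    instances_top: pd.DataFrame,
    background: pd.DataFrame,
    transcriptome: Transcriptome,
    n_top: int = 1000,
    window: int = 30,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Residue enrichment upstream of high-vulnerability codon instances.

    Takes the ``n_top`` highest-scoring instances of each table, tallies the
    amino acid encoded at every upstream position -1..-window, and tests
    each (position, residue) cell with a two-sided binomial test of the top
    frequency against the background frequency, Bonferroni-corrected over
    positions x residues.  ``background`` is the same statistic from a
    control contrast (e.g. wild type vs wild type).

    The binomial test treats the background frequencies as fixed, so the
    family-wise error guarantee is approximate unless the background set
    is large relative to the top set; a continuity floor keeps residues
    absent from the finite background sample from forcing p = 0.
    """
    if background.empty:
        raise ValueError("empty background instance set")
    top = instances_top.nlargest(min(n_top, len(instances_top)), "vulnerability")
    bg = background.nlargest(min(n_top, len(background)), "vulnerability")
    top_counts, _ = _upstream_residues(top, transcriptome, window)
    bg_counts, _ = _upstream_residues(bg, transcriptome, window)
    n_tests = window * len(AMINO_ACIDS)
    rows = []
    for pos in top_counts.index:
        n_at_pos = int(top_counts.loc[pos].sum())
        bg_total = int(bg_counts.loc[pos].sum())
        for aa in AMINO_ACIDS:
            k = int(top_counts.loc[pos, aa])
            p0 = float(bg_counts.loc[pos, aa] / bg_total) if bg_total else 0.0
            if n_at_pos == 0 or bg_total == 0:
                p = 1.0
            else:
                # continuity floor: a residue absent from (or saturating) the
                # finite background sample must not force p = 0
                p0_adj = min(max(p0, 1.0 / (bg_total + 1)), bg_total / (bg_total + 1))
                p = stats.binomtest(k, n_at_pos, p0_adj, alternative="two-sided").pvalue
            freq = k / n_at_pos if n_at_pos else np.nan
            rows.append(
                {
                    "position": int(pos),
                    "residue": aa,
                    "freq_top": freq,
                    "freq_background": p0,
                    "p_value": p,
                    "p_bonferroni": min(1.0, p * n_tests),
                }
            )
    out = pd.DataFrame(rows)
    out["significant"] = out["p_bonferroni"] < alpha
    out["direction"] = np.where(out["freq_top"] > out["freq_background"], "enriched", "depleted")
    return out
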