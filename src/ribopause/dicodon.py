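"""P-site/A-site codon-pair pause matrices.

Each included CDS position with a P-site codon inside the trimmed region
contributes its pause score to the cell indexed by (P-site codon, A-site
codon); the cell value is the instance-weighted mean over all contributing
positions, averaged across replicates.  Ratios between genotypes are kept
raw for statistics and clamped at 2 for display, mirroring the standard
two-dimensional codon-pair visualisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS, SENSE_INDEX
from .rates import MIN_COVERAGE, CodonOccupancy, pause_scores

LOW_SUPPORT_THRESHOLD = 5


@dataclass
class DicodonMatrix:
    """61x61 codon-pair grid (rows: P site, columns: A site)."""

    values: pd.DataFrame  # mean pause score or raw ratio; NaN where empty
    counts: pd.DataFrame  # contributing instances per cell
    clamp: float | None = None  # set on ratio matrices

    @property
    def display(self) -> pd.DataFrame:
        """Clamped copy for visualisation (ratios >= clamp set to clamp)."""
        if self.clamp is None:
            return self.values.copy()
        return self.values.clip(upper=self.clamp)

    def low_support(self, threshold: int = LOW_SUPPORT_THRESHOLD) -> pd.DataFrame:
        return (self.counts < threshold) & self.values.notna()

    def count_quantiles(self, q: int = 4) -> pd.DataFrame:
        """Occurrence counts binned into ``q`` quantile categories (dot sizes)."""
        flat = self.counts.to_numpy().ravel().astype(float)
        pos = flat[flat > 0]
        edges = np.quantile(pos, np.linspace(0, 1, q + 1))
        cats = np.zeros_like(flat, dtype=int)
        cats[flat > 0] = np.clip(np.searchsorted(edges, flat[flat > 0], side="right"), 1, q)
        return pd.DataFrame(
            cats.reshape(self.counts.shape), index=self.counts.index, columns=self.counts.columns
        )


def _empty_grid() -> pd.DataFrame:
    return pd.DataFrame(
        np.zeros((len(SENSE_CODONS), len(SENSE_CODONS))),
        index=pd.Index(SENSE_CODONS, name="p_site"),
        columns=pd.Index(SENSE_CODONS, name="a_site"),
    )


def dicodon_pause(
    occupancies: Sequence[CodonOccupancy],
    min_coverage: float = MIN_COVERAGE,
) -> DicodonMatrix:
    """Mean pause score per codon pair for one genotype.

    ``occupancies`` are replicate occupancy matrices.  Genes must pass the
    coverage filter in every replicate; per replicate, each included
    position i >= trim+1 (so the P-site codon is itself inside the trim)
    adds its pause score to cell (codon_{i-1}, codon_i); cells average over
    instances, then over replicates.
    """
    per_rep = [pause_scores(o, min_coverage) for o in occupancies]
    genes = sorted(set.intersection(*(set(p.genes) for p in per_rep)))
    tx = occupancies[0].transcriptome
    n = len(SENSE_CODONS)
    sums = np.zeros((len(per_rep), n, n))
    cnts = np.zeros((n, n), dtype=np.int64)
    for gene in genes:
        ann = tx[gene]
        ids = ann.codon_ids
        trim = per_rep[0].exclude_ends
        lo, hi = trim + 1, ann.n_codons - trim  # positions with in-trim P-site codon
        pos = np.arange(lo, hi)
        p_ids = ids[pos - 1]
        a_ids = ids[pos]
        ok = (p_ids >= 0) & (a_ids >= 0)
        pos, p_ids, a_ids = pos[ok], p_ids[ok], a_ids[ok]
        np.add.at(cnts, (p_ids, a_ids), 1)
        for r, ps in enumerate(per_rep):
            np.add.at(sums[r], (p_ids, a_ids), ps.scores[gene][pos])
    with np.errstate(invalid="ignore"):
        means = np.where(cnts > 0, sums / cnts, np.nan)  # per-replicate cell means
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty cells stay NaN
        value = np.nanmean(means, axis=0) if len(per_rep) else np.full((n, n), np.nan)
    values = _empty_grid()
    values.iloc[:, :] = value
    counts = _empty_grid().astype(np.int64)
    counts.iloc[:, :] = cnts
    return DicodonMatrix(values=values, counts=counts)


def dicodon_ratio(
    matrix_mut: DicodonMatrix, matrix_wt: DicodonMatrix, clamp: float = 2.0
) -> DicodonMatrix:
    """Cell-wise mutant/wild-type ratio of mean pair pause scores.

    Cells empty (or zero) in either genotype are undefined (NaN).  The raw
    ratio is preserved; the ``display`` property applies the clamp.
    """
    wt = matrix_wt.values.to_numpy()
    mut = matrix_mut.values.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(wt > 0, mut / wt, np.nan)
    values = _empty_grid()
    values.iloc[:, :] = raw
    counts = np.minimum(matrix_mut.counts.to_numpy(), matrix_wt.counts.to_numpy())
    counts_df = _empty_grid().astype(np.int64)
    counts_df.iloc[:, :] = counts
    return DicodonMatrix(values=values, counts=counts_df, clamp=clamp)


def slice_pairs(ratio_matrix: DicodonMatrix, a_codon: str) -> pd.Series:
    """Raw (unclamped) ratios of all NNN-``a_codon`` pairs with defined cells."""
    if a_codon not in SENSE_INDEX:
        raise KeyError(f"not a sense codon: {a_codon!r}")
    col = ratio_matrix.values[a_codon]
    return col.dropna()
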