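"""Occupancy profiles aligned at codons or codon pairs of interest.

Profiles place the A-site codon of the (first stalled) ribosome at
position 0 and average pause scores (monosomes) or footprint density
(disomes) over every instance of the query across the transcriptome.
Queued collided ribosomes then appear as peaks at negative multiples of
the ribosome footprint size (10 codons).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Transcriptome
from .geometry import DEFAULT_OFFSETS, OffsetTable
from .rates import PauseScores, build_occupancy

DEFAULT_WINDOW = (-35, 10)
MIN_DIST_FROM_ENDS = 35


def find_sites(
    transcriptome: Transcriptome,
    query: str | tuple[str, str],
    min_dist_from_ends: int = MIN_DIST_FROM_ENDS,
) -> list[tuple[str, int]]:
    """Locate instances of a codon or ordered (P, A) codon pair.

    Returns (gene, position) with position the A-site codon of interest
    (for a pair, its second codon).  Instances closer than
    ``min_dist_from_ends`` codons to either CDS end are skipped so the
    alignment window stays inside the ORF.
    """
    sites = []
    pair = not isinstance(query, str)
    for tid, ann in transcriptome.items():
        codons = ann.codons
        lo = max(min_dist_from_ends, 1)
        hi = ann.n_codons - min_dist_from_ends
        for i in range(lo, hi):
            if pair:
                if codons[i - 1] == query[0] and codons[i] == query[1]:
                    sites.append((tid, i))
            elif codons[i] == query:
                sites.append((tid, i))
    return sites


def _aligned_mean(
    vectors: Mapping[str, np.ndarray],
    sites: Sequence[tuple[str, int]],
    window: tuple[int, int],
) -> np.ndarray:
    """Mean of per-gene vectors over instances, per relative position."""
    lo, hi = window
    width = hi - lo + 1
    total = np.zeros(width)
    n = np.zeros(width)
    for gene, pos in sites:
        vec = vectors.get(gene)
        if vec is None:
            continue
        lo_i, hi_i = pos + lo, pos + hi
        if lo_i < 0 or hi_i >= vec.size:
            continue
        seg = vec[lo_i : hi_i + 1]
        ok = ~np.isnan(seg)
        total[ok] += seg[ok]
        n += ok
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, total / n, np.nan)


def _band(stack: np.ndarray, band: str) -> tuple[np.ndarray, np.ndarray]:
    if band == "minmax":
        return np.nanmin(stack, axis=0), np.nanmax(stack, axis=0)
    if band == "sd":
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(stack.shape[1])
        return mean - sd, mean + sd
    raise ValueError("band must be 'minmax' or 'sd'")


def align_at_sites(
    pause_reps: Mapping[str, Sequence[PauseScores]],
    transcriptome: Transcriptome,
    query: str | tuple[str, str],
    window: tuple[int, int] = DEFAULT_WINDOW,
    band: str = "minmax",
) -> pd.DataFrame:
    """Site-aligned mean pause-score profile per genotype.

    ``pause_reps`` maps genotype label -> replicate PauseScores.  Per
    replicate the profile is the mean pause score over all query instances
    at each relative position (position 0 = the A-site codon of interest);
    across replicates the mean and a min/max (or +-sd) band are reported.
    """
    sites = find_sites(transcriptome, query, min_dist_from_ends=max(abs(window[0]), window[1]))
    if not sites:
        warnings.warn(f"query {query!r} has no usable instances", stacklevel=2)
    positions = np.arange(window[0], window[1] + 1)
    rows = []
    for genotype, reps in pause_reps.items():
        stack = np.stack([_aligned_mean(r.scores, sites, window) for r in reps])
        mean = np.nanmean(stack, axis=0)
        low, high = _band(stack, band)
        rows.append(
            pd.DataFrame(
                {
                    "genotype": genotype,
                    "position": positions,
                    "mean": mean,
                    "band_low": low,
                    "band_high": high,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def disome_site_profile(
    disome_records: pd.DataFrame,
    transcriptome: Transcriptome,
    query: str | tuple[str, str],
    window: tuple[int, int] = DEFAULT_WINDOW,
    offsets: OffsetTable = DEFAULT_OFFSETS,
    band: str = "minmax",
) -> pd.DataFrame:
    """Site-aligned disome density profile per genotype.

    Disome footprints are assigned to the A site of the stalling (lead)
    ribosome, 45 nt downstream of the 5' end; each contributes at relative
    position (assigned codon - site codon).  Values are mean footprint
    counts per instance, averaged over replicates.
    """
    sub = disome_records[disome_records["fraction"] == "disome"]
    sites = find_sites(transcriptome, query, min_dist_from_ends=max(abs(window[0]), window[1]))
    if not sites:
        warnings.warn(f"query {query!r} has no usable instances", stacklevel=2)
    positions = np.arange(window[0], window[1] + 1)
    rows = []
    for genotype, geno_grp in sub.groupby("genotype", sort=True):
        stack = []
        for _, rep_grp in geno_grp.groupby("replicate", sort=True):
            occ = build_occupancy(rep_grp, transcriptome, offsets)
            vectors = {g: v.astype(float) for g, v in occ.counts.items()}
            stack.append(_aligned_mean(vectors, sites, window))
        arr = np.stack(stack)
        mean = np.nanmean(arr, axis=0)
        low, high = _band(arr, band)
        rows.append(
            pd.DataFrame(
                {
                    "genotype": genotype,
                    "position": positions,
                    "mean": mean,
                    "band_low": low,
                    "band_high": high,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["genotype", "position", "mean", "band_low", "band_high"])
    return pd.concat(rows, ignore_index=True)


def detect_queue_peaks(
    profile: pd.DataFrame,
    spacing: int = 10,
    min_fold: float = 2.0,
    tolerance: int = 1,
) -> list[int]:
    """Positions of queueing peaks at negative multiples of ``spacing``.

    A queueing peak is a local maximum within ``tolerance`` codons of
    -m*spacing (m = 1, 2, ...) whose value exceeds ``min_fold`` times the
    profile median.  Returns positions ordered from -spacing downward.
    ``profile`` needs 'position' and a value column ('mean' or 'value').
    """
    value_col = "mean" if "mean" in profile.columns else "value"
    pos = profile["position"].to_numpy()
    val = profile[value_col].to_numpy(dtype=float)
    finite = np.isfinite(val)
    pos, val = pos[finite], val[finite]
    if pos.size == 0:
        return []
    med = float(np.median(val))
    by_pos = dict(zip(pos.tolist(), val.tolist()))
    peaks = []
    m = 1
    while -m * spacing >= pos.min():
        target = -m * spacing
        cands = [p for p in range(target - tolerance, target + tolerance + 1) if p in by_pos]
        if cands:
            p_star = max(cands, key=lambda p: by_pos[p])
            v = by_pos[p_star]
            neighbors = [by_pos.get(p_star - 1, -np.inf), by_pos.get(p_star + 1, -np.inf)]
            if v > min_fold * med and v > 0 and v >= max(neighbors):
                peaks.append(p_star)
        m += 1
    return peaks
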