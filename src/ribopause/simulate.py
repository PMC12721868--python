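"""Synthetic transcriptome, footprint and gene-count generation.

The simulator encodes the dwell-time / collision model the downstream
analysis assumes, so every pipeline stage can be exercised without real
sequencing data:

* per-codon relative dwell times, optionally multiplied by a P-site/A-site
  codon-pair factor (slow pairs), per genotype;
* explicit stall sites with a queue-depth distribution; queued elongating
  ribosomes sit 30 nt (10 codons) behind one another;
* monosome footprints of 28/29 nt emitted at the offset-consistent 5'
  position for their (length, frame) class; disome footprints emitted for
  each adjacent collided pair with the 45-nt 5'-to-lead-A-site geometry;
* initiating and terminating ribosomes as extra occupancy at the second and
  stop codon (stop-anchored 5' peaks at -18 and, for their queued partners,
  -48 = -(28 + 2 + 18));
* negative-binomial gene-level monosome/disome count tables over a
  2-genotype x 2-fraction design with planted interaction effects.

Sampling is multinomial over (gene, codon-position, read-class) cells with
probabilities proportional to transcript abundance x dwell weight.  Random
numbers are consumed in a fixed, documented order (transcriptome first,
then genotypes in listed order, replicates in order, monosome before
disome), so a seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS, START_CODON, STOP_CODONS
from .core import FLANK_NT, Transcriptome, TranscriptAnnotation
from .geometry import DEFAULT_GEOMETRY, GeometryModel


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class StallSite:
    """A planted ribosome stall.

    ``codon`` is the 0-based CDS codon index of the lead (stalled)
    ribosome's A site.  ``depth_probs`` maps total stack depth (lead
    ribosome included, >= 1) to probability.  ``weight`` is the occupancy
    weight of the stack relative to a baseline codon weight of 1.0.
    """

    transcript_id: str
    codon: int
    depth_probs: Mapping[int, float] = field(default_factory=lambda: {2: 1.0})
    weight: float = 50.0

    def depth_tail(self, max_depth: int | None = None) -> np.ndarray:
        """P(depth >= m+1) for ribosome slots m = 0, 1, ... behind the lead."""
        depths = sorted(self.depth_probs)
        if not depths or min(depths) < 1:
            raise ConfigurationError("stall depths must be >= 1")
        total = sum(self.depth_probs.values())
        top = max_depth if max_depth is not None else max(depths)
        tail = np.array(
            [sum(p for d, p in self.depth_probs.items() if d >= m + 1) / total for m in range(top)]
        )
        return tail


@dataclass(frozen=True)
class GenotypeSpec:
    """Genotype-specific dwell perturbations and stall sites."""

    dwell_multipliers: Mapping[str, float] = field(default_factory=dict)
    pair_multipliers: Mapping[tuple[str, str], float] = field(default_factory=dict)
    stall_sites: Sequence[StallSite] = ()


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic libraries.

    Defaults reflect the experimental design being emulated: yeast-scale
    CDS lengths, 28/29-nt monosome footprints dominated by frame 0,
    disome footprints of 56-64 nt, three replicates per genotype, and a
    30-nt collided-ribosome spacing.
    """

    seed: int = 0
    n_genes: int = 200
    cds_length_range: tuple[int, int] = (120, 400)  # codons, start+stop included
    codon_usage: Mapping[str, float] | None = None  # uniform over 61 if None
    base_dwell: Mapping[str, float] = field(default_factory=dict)  # default 1.0
    pair_dwell_multiplier: Mapping[tuple[str, str], float] = field(default_factory=dict)
    genotypes: Mapping[str, GenotypeSpec] = field(
        default_factory=lambda: {"wildtype": GenotypeSpec()}
    )
    n_replicates: int = 3
    read_depth: int = 1_000_000
    disome_read_depth: int | None = None  # defaults to read_depth
    length_distribution: Mapping[int, float] = field(
        default_factory=lambda: {28: 0.7, 29: 0.3}
    )
    frame2_fraction_29: float = 0.25  # share of 29-nt reads cut one nt short (frame 2)
    disome_length_range: tuple[int, int] = (56, 64)
    queue_spacing_nt: int = 30
    initiation_weight: float = 5.0
    termination_weight: float = 5.0
    termination_queue_weight: float = 2.0
    disome_background_weight: float = 0.01  # per codon, relative to stall weights
    transcript_abundance: Mapping[str, float] | None = None  # uniform if None

    def validate(self) -> None:
        lo, hi = self.cds_length_range
        if self.n_genes < 1 or lo < 4 or hi < lo:
            raise ConfigurationError("invalid n_genes or cds_length_range")
        if self.codon_usage is not None:
            bad = set(self.codon_usage) - set(SENSE_CODONS)
            if bad:
                raise ConfigurationError(f"codon_usage has non-sense codons: {sorted(bad)}")
            total = float(sum(self.codon_usage.values()))
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ConfigurationError(f"codon_usage sums to {total}, not 1")
            if any(v < 0 for v in self.codon_usage.values()):
                raise ConfigurationError("codon_usage has negative entries")
        for table in (self.base_dwell, *(g.dwell_multipliers for g in self.genotypes.values())):
            if any(v <= 0 for v in table.values()):
                raise ConfigurationError("dwell factors must be > 0")
        for table in (
            self.pair_dwell_multiplier,
            *(g.pair_multipliers for g in self.genotypes.values()),
        ):
            if any(v <= 0 for v in table.values()):
                raise ConfigurationError("pair dwell factors must be > 0")
        probs = np.array(list(self.length_distribution.values()), dtype=float)
        if not np.isclose(probs.sum(), 1.0) or (probs < 0).any():
            raise ConfigurationError("length_distribution must be a probability vector")
        if set(self.length_distribution) - {28, 29}:
            raise ConfigurationError("monosome lengths must be 28 or 29")


# ---------------------------------------------------------------------------
# transcriptome generation
# ---------------------------------------------------------------------------

def _usage_vector(config: SimulationConfig) -> np.ndarray:
    if config.codon_usage is None:
        return np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    v = np.array([config.codon_usage.get(c, 0.0) for c in SENSE_CODONS], dtype=float)
    return v / v.sum()


def generate_transcriptome(config: SimulationConfig) -> Transcriptome:
    """Draw a synthetic transcriptome.

    Each CDS starts with ATG, ends with one stop codon, has internal codons
    drawn i.i.d. from the configured codon usage, and sits between 21-nt
    random flanks.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    usage = _usage_vector(config)
    lo, hi = config.cds_length_range
    anns = []
    for g in range(config.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        internal = rng.choice(len(SENSE_CODONS), size=n_codons - 2, p=usage)
        stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
        cds = START_CODON + "".join(SENSE_CODONS[i] for i in internal) + stop
        flank5 = "".join(rng.choice(list("ACGT"), size=FLANK_NT))
        flank3 = "".join(rng.choice(list("ACGT"), size=FLANK_NT))
        seq = flank5 + cds + flank3
        anns.append(
            TranscriptAnnotation(
                transcript_id=f"g{g + 1:04d}",
                sequence=seq,
                cds_start=FLANK_NT,
                cds_end=FLANK_NT + len(cds),
            )
        )
    return Transcriptome(anns)


# ---------------------------------------------------------------------------
# footprint emission
# ---------------------------------------------------------------------------

def _dwell_weights(
    ann: TranscriptAnnotation, config: SimulationConfig, spec: GenotypeSpec
) -> np.ndarray:
    """Per-codon occupancy weight for elongating A sites (codons 1..l-2),
    plus initiation/termination weights at codon 1 and the stop codon."""
    l = ann.n_codons
    w = np.zeros(l)
    base = {c: config.base_dwell.get(c, 1.0) * spec.dwell_multipliers.get(c, 1.0) for c in SENSE_CODONS}
    pair: dict[tuple[str, str], float] = dict(config.pair_dwell_multiplier)
    for k, v in spec.pair_multipliers.items():
        pair[k] = pair.get(k, 1.0) * v
    codons = ann.codons
    for i in range(1, l - 1):
        w[i] = base[codons[i]] * pair.get((codons[i - 1], codons[i]), 1.0)
    w[1] += config.initiation_weight
    w[l - 1] += config.termination_weight
    spacing = config.queue_spacing_nt // 3
    if config.termination_queue_weight > 0 and l - 1 - spacing >= 1:
        w[l - 1 - spacing] += config.termination_queue_weight
    return w


def _apply_stalls(
    w: np.ndarray, ann: TranscriptAnnotation, sites: Sequence[StallSite], spacing: int
) -> None:
    for site in sites:
        if not 1 <= site.codon <= ann.n_codons - 2:
            raise ConfigurationError(
                f"stall site at codon {site.codon} outside CDS of {ann.transcript_id}"
            )
        tail = site.depth_tail()
        for m, p in enumerate(tail):
            pos = site.codon - m * spacing
            if pos < 1:
                raise ConfigurationError(
                    f"stall queue at {ann.transcript_id}:{site.codon} leaves the CDS"
                )
            w[pos] += site.weight * p


def _emit_monosomes(
    tx: Transcriptome,
    config: SimulationConfig,
    geometry: GeometryModel,
    spec: GenotypeSpec,
    abundance: Mapping[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    spacing = config.queue_spacing_nt // 3
    gene_ids, codon_idx, weights = [], [], []
    for tid, ann in tx.items():
        w = _dwell_weights(ann, config, spec)
        _apply_stalls(w, ann, [s for s in spec.stall_sites if s.transcript_id == tid], spacing)
        nz = np.flatnonzero(w)
        gene_ids.append(np.full(nz.size, tid, dtype=object))
        codon_idx.append(nz)
        weights.append(w[nz] * abundance[tid])
    gene_arr = np.concatenate(gene_ids)
    codon_arr = np.concatenate(codon_idx)
    p = np.concatenate(weights)
    p /= p.sum()
    counts = rng.multinomial(config.read_depth, p)

    # split each cell's counts over the (length, frame) read classes
    p29 = config.length_distribution.get(29, 0.0)
    classes = [
        (28, 0, config.length_distribution.get(28, 0.0)),
        (29, 0, p29 * (1.0 - config.frame2_fraction_29)),
        (29, 2, p29 * config.frame2_fraction_29),
    ]
    class_p = np.array([c[2] for c in classes])
    class_p /= class_p.sum()
    split = rng.multinomial(counts, class_p)  # shape (cells, 3)

    starts = {tid: ann.cds_start for tid, ann in tx.items()}
    start_arr = np.array([starts[t] for t in gene_arr])
    frames = []
    for j, (length, frame, _) in enumerate(classes):
        cnt = split[:, j]
        keep = cnt > 0
        if not keep.any():
            continue
        # vectorised form of geometry.monosome_five_prime
        off = geometry.offsets.offset(length, frame)
        fives = start_arr[keep] + 3 * codon_arr[keep] - off + ((off + frame) % 3)
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": gene_arr[keep],
                    "five_prime_pos": fives,
                    "length": length,
                    "count": cnt[keep],
                    "emitted_codon": codon_arr[keep],
                }
            )
        )
    if not frames:
        return _empty_footprints()
    out = pd.concat(frames, ignore_index=True)
    out["fraction"] = "monosome"
    return out


def _emit_disomes(
    tx: Transcriptome,
    config: SimulationConfig,
    geometry: GeometryModel,
    spec: GenotypeSpec,
    abundance: Mapping[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Disome cells: one per adjacent collided pair at each stall, with
    weight proportional to P(depth >= pair index + 1); plus an optional
    uniform background along every CDS."""
    spacing = config.queue_spacing_nt // 3
    gene_ids, lead_idx, weights = [], [], []
    for tid, ann in tx.items():
        w = np.zeros(ann.n_codons)
        if config.disome_background_weight > 0:
            # a background disome implies a trailing ribosome one spacing
            # upstream, so the lead A site starts at codon `spacing`
            w[spacing : ann.n_codons - 1] += config.disome_background_weight
        for site in (s for s in spec.stall_sites if s.transcript_id == tid):
            tail = site.depth_tail()
            # pair m (1-based) spans ribosome slots m-1 and m -> needs depth >= m+1
            for m in range(1, len(tail)):
                pos = site.codon - (m - 1) * spacing
                if pos - spacing < 0:
                    raise ConfigurationError(
                        f"disome queue at {ann.transcript_id}:{site.codon} leaves the CDS"
                    )
                w[pos] += site.weight * tail[m]
        nz = np.flatnonzero(w)
        gene_ids.append(np.full(nz.size, tid, dtype=object))
        lead_idx.append(nz)
        weights.append(w[nz] * abundance[tid])
    gene_arr = np.concatenate(gene_ids)
    lead_arr = np.concatenate(lead_idx)
    p = np.concatenate(weights)
    if p.sum() == 0:
        return _empty_footprints()
    p /= p.sum()
    depth = config.disome_read_depth if config.disome_read_depth is not None else config.read_depth
    counts = rng.multinomial(depth, p)

    lo, hi = config.disome_length_range
    lengths = np.arange(lo, hi + 1)
    length_split = rng.multinomial(counts, np.full(lengths.size, 1.0 / lengths.size))

    starts = {tid: ann.cds_start for tid, ann in tx.items()}
    start_arr = np.array([starts[t] for t in gene_arr])
    frames = []
    for j, length in enumerate(lengths):
        cnt = length_split[:, j]
        keep = cnt > 0
        if not keep.any():
            continue
        fives = start_arr[keep] + 3 * lead_arr[keep] - geometry.offsets.disome_offset
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": gene_arr[keep],
                    "five_prime_pos": fives,
                    "length": int(length),
                    "count": cnt[keep],
                    "emitted_codon": lead_arr[keep],
                }
            )
        )
    if not frames:
        return _empty_footprints()
    out = pd.concat(frames, ignore_index=True)
    out["fraction"] = "disome"
    return out


def _empty_footprints() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": pd.Series(dtype=object),
            "five_prime_pos": pd.Series(dtype=np.int64),
            "length": pd.Series(dtype=np.int64),
            "count": pd.Series(dtype=np.int64),
            "emitted_codon": pd.Series(dtype=np.int64),
            "fraction": pd.Series(dtype=object),
        }
    )


def simulate_footprints(
    transcriptome: Transcriptome,
    config: SimulationConfig,
    geometry: GeometryModel = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Simulate monosome and disome libraries for every genotype x replicate.

    Returns one footprint table with the canonical columns plus an
    ``emitted_codon`` truth column (the A-site codon of the emitting
    ribosome; for disomes, of the lead ribosome of the pair).
    """
    config.validate()
    if config.queue_spacing_nt % 3 != 0:
        raise ConfigurationError("queue_spacing_nt must be a multiple of 3")
    if config.transcript_abundance is None:
        abundance = {tid: 1.0 for tid in transcriptome}
    else:
        abundance = {tid: float(config.transcript_abundance.get(tid, 0.0)) for tid in transcriptome}
    tables = []
    for gi, (genotype, spec) in enumerate(config.genotypes.items()):
        for rep in range(1, config.n_replicates + 1):
            seed = np.random.SeedSequence([config.seed, 1, gi, rep])
            rng = np.random.default_rng(seed)
            mono = _emit_monosomes(transcriptome, config, geometry, spec, abundance, rng)
            di = _emit_disomes(transcriptome, config, geometry, spec, abundance, rng)
            for t in (mono, di):
                if len(t):
                    t["genotype"] = genotype
                    t["replicate"] = f"rep{rep}"
                    tables.append(t)
    if not tables:
        out = _empty_footprints()
        out["genotype"] = pd.Series(dtype=object)
        out["replicate"] = pd.Series(dtype=object)
        return out
    out = pd.concat(tables, ignore_index=True)
    cols = [
        "transcript_id",
        "five_prime_pos",
        "length",
        "count",
        "fraction",
        "genotype",
        "replicate",
        "emitted_codon",
    ]
    return out.loc[:, cols]


# ---------------------------------------------------------------------------
# gene-level count tables
# ---------------------------------------------------------------------------

def simulate_gene_counts(
    n_genes: int,
    genotypes: tuple[str, str] = ("wildtype", "mutant"),
    fractions: tuple[str, str] = ("monosome", "disome"),
    n_replicates: int = 2,
    nb_mean: float = 200.0,
    nb_dispersion: float = 0.05,
    interaction_log2fc: np.ndarray | float = 0.0,
    disome_log2fc: float = -1.0,
    genotype_log2fc: float = 0.0,
    mean_log_sd: float = 1.0,
    size_factor_sd: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial gene-level counts over a 2-genotype x 2-fraction design.

    The disome/monosome ratio of gene *g* changes by ``interaction_log2fc[g]``
    (log2) in the second genotype relative to the first; ``disome_log2fc``
    sets the genotype-independent disome/monosome ratio.  Per-sample library
    size factors are drawn lognormally to exercise normalisation.

    Returns ``(counts, meta)``: counts is genes x samples, meta describes
    each sample (genotype, fraction, replicate).
    """
    if nb_dispersion <= 0:
        raise ConfigurationError("nb_dispersion must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    ilfc = np.broadcast_to(np.asarray(interaction_log2fc, dtype=float), (n_genes,))
    base = np.exp(rng.normal(np.log(nb_mean), mean_log_sd, size=n_genes))
    samples, meta_rows = [], []
    counts = {}
    for genotype in genotypes:
        for fraction in fractions:
            for rep in range(1, n_replicates + 1):
                name = f"{genotype}_{fraction}_rep{rep}"
                sf = float(np.exp(rng.normal(0.0, size_factor_sd)))
                mu = base * sf
                if fraction == fractions[1]:
                    mu = mu * 2.0**disome_log2fc
                if genotype == genotypes[1]:
                    mu = mu * 2.0**genotype_log2fc
                    if fraction == fractions[1]:
                        mu = mu * 2.0**ilfc
                r = 1.0 / nb_dispersion
                counts[name] = rng.negative_binomial(r, r / (r + mu))
                samples.append(name)
                meta_rows.append((name, genotype, fraction, f"rep{rep}"))
    counts_df = pd.DataFrame(counts, index=[f"g{i + 1:04d}" for i in range(n_genes)])
    meta = pd.DataFrame(meta_rows, columns=["sample", "genotype", "fraction", "replicate"])
    return counts_df, meta


def simulate_rqc_dataset(
    n_genes: int = 2000,
    frac_rqc: float = 0.05,
    frac_rrt: float = 0.05,
    effect_log2fc: float = 1.5,
    nb_mean: float = 500.0,
    nb_dispersion: float = 0.05,
    n_replicates: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Two paired count tables realising the RQC-target truth model.

    RQC targets gain disomes in contrast 1 (modification mutant vs wild
    type, +effect) and lose them in contrast 2 (triple vs double mutant,
    -effect); RQC-refractory transcripts (RRTs) show the mirrored pattern;
    null genes have no interaction.  Returns
    ``(counts1, meta1, counts2, meta2, truth)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    labels = np.array(["neither"] * n_genes, dtype=object)
    n_rqc = int(round(frac_rqc * n_genes))
    n_rrt = int(round(frac_rrt * n_genes))
    order = rng.permutation(n_genes)
    labels[order[:n_rqc]] = "RQC_target"
    labels[order[n_rqc : n_rqc + n_rrt]] = "RRT"
    lfc1 = np.where(labels == "RQC_target", effect_log2fc, np.where(labels == "RRT", -effect_log2fc, 0.0))
    counts1, meta1 = simulate_gene_counts(
        n_genes,
        genotypes=("wildtype", "double_mutant"),
        n_replicates=n_replicates,
        nb_mean=nb_mean,
        nb_dispersion=nb_dispersion,
        interaction_log2fc=lfc1,
        seed=int(rng.integers(2**31 - 1)),
    )
    counts2, meta2 = simulate_gene_counts(
        n_genes,
        genotypes=("double_mutant", "triple_mutant"),
        n_replicates=n_replicates,
        nb_mean=nb_mean,
        nb_dispersion=nb_dispersion,
        interaction_log2fc=-lfc1,
        seed=int(rng.integers(2**31 - 1)),
    )
    truth = pd.Series(labels, index=counts1.index, name="label")
    return counts1, meta1, counts2, meta2, truth
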