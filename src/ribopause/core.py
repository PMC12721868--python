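"""Transcript annotation, footprint tables, frame/A-site assignment, metagene profiles.

Coordinates are 0-based, half-open, transcript-relative throughout.  The
CDS occupies ``[cds_start, cds_end)`` and every transcript carries at least
21 nt of flank on both sides so that footprints around start and stop codons
stay on the transcript (the ORF is "extended" by 21 nt for alignment).

Footprint collections are plain :class:`pandas.DataFrame` objects with the
columns in :data:`FOOTPRINT_COLUMNS`; one row is one distinct
(transcript, 5' position, length) footprint species with an integer count,
tagged with fraction (monosome/disome), genotype and replicate labels.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import SENSE_INDEX
from .geometry import (
    DEFAULT_OFFSETS,
    DISOME_LENGTH_RANGE_RAW,
    DISOME_SELECTION_RANGE,
    MONOSOME_LENGTH_RANGE,
    OffsetError,
    OffsetTable,
)

FLANK_NT = 21

FOOTPRINT_COLUMNS = (
    "transcript_id",
    "five_prime_pos",
    "length",
    "count",
    "fraction",
    "genotype",
    "replicate",
)

FRACTIONS = ("monosome", "disome")


class ValidationError(ValueError):
    """Malformed annotation or footprint input."""


@dataclass(frozen=True)
class TranscriptAnnotation:
    """A transcript sequence with its CDS bounds.

    The CDS length must be a multiple of three and include the stop codon;
    both flanks must be at least 21 nt.
    """

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValidationError(
                f"{self.transcript_id}: CDS length "
                f"{self.cds_end - self.cds_start} not divisible by 3"
            )
        if self.cds_start < FLANK_NT or len(self.sequence) < self.cds_end + FLANK_NT:
            raise ValidationError(
                f"{self.transcript_id}: needs >= {FLANK_NT} nt flanks around the CDS"
            )

    @property
    def n_codons(self) -> int:
        """CDS length in codons (stop codon included)."""
        return (self.cds_end - self.cds_start) // 3

    @functools.cached_property
    def codons(self) -> tuple[str, ...]:
        s, e = self.cds_start, self.cds_end
        return tuple(self.sequence[i : i + 3] for i in range(s, e, 3))

    @functools.cached_property
    def codon_ids(self) -> np.ndarray:
        """Sense-codon index per codon position; -1 for stop codons."""
        return np.array([SENSE_INDEX.get(c, -1) for c in self.codons], dtype=np.int32)

    def codon(self, index: int) -> str:
        return self.codons[index]


class Transcriptome(Mapping[str, TranscriptAnnotation]):
    """Immutable mapping transcript_id -> :class:`TranscriptAnnotation`."""

    def __init__(self, annotations: Iterable[TranscriptAnnotation]):
        self._by_id: dict[str, TranscriptAnnotation] = {}
        for ann in annotations:
            if ann.transcript_id in self._by_id:
                raise ValidationError(f"duplicate transcript id {ann.transcript_id!r}")
            self._by_id[ann.transcript_id] = ann

    def __getitem__(self, key: str) -> TranscriptAnnotation:
        return self._by_id[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._by_id)

    def __len__(self) -> int:
        return len(self._by_id)

    # ---- I/O -----------------------------------------------------------
    @classmethod
    def from_files(cls, fasta_path: str | Path, annotation_path: str | Path) -> "Transcriptome":
        sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        anns = []
        with open(annotation_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0] == "transcript_id":  # header
                    continue
                if len(fields) < 3:
                    raise ValidationError(
                        f"{annotation_path}:{lineno}: expected 3 tab-separated fields"
                    )
                tid, start, end = fields[0], int(fields[1]), int(fields[2])
                if tid not in sequences:
                    raise ValidationError(
                        f"{annotation_path}:{lineno}: unknown transcript id {tid!r}"
                    )
                try:
                    anns.append(TranscriptAnnotation(tid, sequences[tid], start, end))
                except ValidationError as err:
                    raise ValidationError(f"{annotation_path}:{lineno}: {err}") from None
        return cls(anns)

    def to_files(self, fasta_path: str | Path, annotation_path: str | Path) -> None:
        records = [
            SeqRecord(Seq(ann.sequence), id=tid, description="")
            for tid, ann in self._by_id.items()
        ]
        with open(fasta_path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
        with open(annotation_path, "w") as fh:
            fh.write("transcript_id\tcds_start\tcds_end\n")
            for tid, ann in self._by_id.items():
                fh.write(f"{tid}\t{ann.cds_start}\t{ann.cds_end}\n")


def read_annotation(fasta_path: str | Path, annotation_path: str | Path) -> Transcriptome:
    """Load transcript sequences (FASTA) plus CDS bounds (TSV)."""
    return Transcriptome.from_files(fasta_path, annotation_path)


def read_footprints(path: str | Path, transcriptome: Transcriptome | None = None) -> pd.DataFrame:
    """Read a tab-separated footprint table, validating every record.

    Counts must be non-negative; raw monosome lengths must lie in
    [25, 35] and raw disome lengths in [50, 70]; transcript ids must be
    known when a transcriptome is given.  Violations are reported with
    their line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "genotype": str, "replicate": str})
    missing = [c for c in FOOTPRINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df.loc[:, list(FOOTPRINT_COLUMNS)]
    _validate_footprints(df, transcriptome, source=str(path))
    return df


def _validate_footprints(
    df: pd.DataFrame, transcriptome: Transcriptome | None, source: str = "<records>"
) -> None:
    def _fail(mask: pd.Series, why: str) -> None:
        if mask.any():
            # +2: header line plus 1-based indexing of the data rows
            lines = (np.flatnonzero(mask.to_numpy()) + 2)[:5].tolist()
            raise ValidationError(f"{source}: {why} (lines {lines})")

    _fail(df["count"] < 0, "negative footprint count")
    bad_fraction = ~df["fraction"].isin(FRACTIONS)
    _fail(bad_fraction, f"fraction must be one of {FRACTIONS}")
    mono = df["fraction"] == "monosome"
    lo, hi = MONOSOME_LENGTH_RANGE
    _fail(mono & ~df["length"].between(lo, hi), f"monosome length outside [{lo}, {hi}]")
    lo, hi = DISOME_LENGTH_RANGE_RAW
    _fail(~mono & ~df["length"].between(lo, hi), f"disome length outside [{lo}, {hi}]")
    if transcriptome is not None:
        _fail(~df["transcript_id"].isin(transcriptome.keys()), "unknown transcript id")


def write_footprints(df: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical footprint columns as a tab-separated table."""
    df.loc[:, list(FOOTPRINT_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# frame classification / selection / A-site assignment
# ---------------------------------------------------------------------------

def classify_frame(five_prime_pos: int, cds_start: int) -> int:
    """Reading frame of a footprint 5' end: 0/1/2 for the first/second/third
    nucleotide of a codon.  Positions upstream of the CDS use the same
    modulus extended leftward."""
    return (five_prime_pos - cds_start) % 3


def add_frames(records: pd.DataFrame, transcriptome: Transcriptome) -> pd.DataFrame:
    """Return a copy of ``records`` with a ``frame`` column."""
    starts_map = {tid: ann.cds_start for tid, ann in transcriptome.items()}
    starts = records["transcript_id"].map(starts_map)
    out = records.copy()
    out["frame"] = ((records["five_prime_pos"] - starts) % 3).astype(np.int8)
    return out


def select_footprints(
    records: pd.DataFrame,
    transcriptome: Transcriptome,
    keep: Iterable[tuple[int, int]] | None = None,
    disome_lengths: tuple[int, int] = DISOME_SELECTION_RANGE,
) -> pd.DataFrame:
    """Keep monosome records whose (length, frame) is in ``keep`` (default:
    the offset-table keys) and disome records with length in 56-64 nt."""
    keep_set = frozenset(keep) if keep is not None else DEFAULT_OFFSETS.keys
    framed = add_frames(records, transcriptome)
    mono = framed["fraction"] == "monosome"
    key = framed["length"].to_numpy() * 3 + framed["frame"].to_numpy()
    allowed = np.array([l * 3 + f for l, f in keep_set], dtype=key.dtype)
    mono_ok = mono & pd.Series(np.isin(key, allowed), index=framed.index)
    di_ok = ~mono & framed["length"].between(*disome_lengths)
    out = framed.loc[mono_ok | di_ok].reset_index(drop=True)
    if out.empty and not framed.empty:
        warnings.warn("footprint selection removed every record", stacklevel=2)
    return out


def assign_a_site(
    five_prime_pos: int,
    length: int,
    annotation: TranscriptAnnotation,
    offsets: OffsetTable = DEFAULT_OFFSETS,
    fraction: str = "monosome",
) -> int | None:
    """A-site codon index (0-based within the CDS) of a single footprint.

    Monosomes use the (length, frame) offset; disomes use the fixed disome
    offset to the lead ribosome's A site.  Returns ``None`` when the A site
    falls outside the CDS.
    """
    if fraction == "disome":
        off = offsets.disome_offset
    else:
        off = offsets.offset(length, classify_frame(five_prime_pos, annotation.cds_start))
    a_nt = five_prime_pos + off
    codon = (a_nt - annotation.cds_start) // 3
    if 0 <= codon < annotation.n_codons:
        return codon
    return None


def assign_a_sites(
    records: pd.DataFrame,
    transcriptome: Transcriptome,
    offsets: OffsetTable = DEFAULT_OFFSETS,
) -> pd.DataFrame:
    """Vectorised A-site assignment.

    Returns a copy with ``frame`` and ``codon_index`` columns; footprints
    whose A site falls outside the CDS get codon_index -1.  Records must
    already be selected so that every monosome (length, frame) key exists
    in the offset table.
    """
    framed = records if "frame" in records.columns else add_frames(records, transcriptome)
    out = framed.copy()
    starts_map = {tid: ann.cds_start for tid, ann in transcriptome.items()}
    ncod_map = {tid: ann.n_codons for tid, ann in transcriptome.items()}
    starts = out["transcript_id"].map(starts_map).to_numpy()
    ncod = out["transcript_id"].map(ncod_map).to_numpy()
    off = np.full(len(out), -1, dtype=np.int64)
    is_di = (out["fraction"] == "disome").to_numpy()
    off[is_di] = offsets.disome_offset
    lengths = out["length"].to_numpy()
    frames = out["frame"].to_numpy()
    for (length, frame), o in offsets.entries.items():
        off[~is_di & (lengths == length) & (frames == frame)] = o
    unresolved = off < 0
    if unresolved.any():
        bad = sorted(
            {(int(l), int(f)) for l, f in zip(lengths[unresolved], frames[unresolved])}
        )
        raise OffsetError(f"no A-site offset configured for (length, frame) in {bad}")
    a_nt = out["five_prime_pos"].to_numpy() + off
    codon = np.floor_divide(a_nt - starts, 3)
    codon[(codon < 0) | (codon >= ncod)] = -1
    out["codon_index"] = codon.astype(np.int32)
    return out


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

def metagene_profile(
    records: pd.DataFrame,
    transcriptome: Transcriptome,
    anchor: str = "start",
    window: tuple[int, int] | None = (-60, 60),
    by_length_frame: bool = False,
) -> pd.DataFrame:
    """Summed footprint 5'-end density relative to a common anchor.

    ``anchor='start'`` places the A of the start codon at position 0;
    ``anchor='stop'`` places the last nucleotide of the stop codon at -1
    (a 5' end on that nucleotide plots at -1).  Returns a tidy frame with
    columns position, value (and length, frame when stratified).
    """
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")
    framed = records if "frame" in records.columns else add_frames(records, transcriptome)
    ref_map = {
        tid: (ann.cds_start if anchor == "start" else ann.cds_end)
        for tid, ann in transcriptome.items()
    }
    ref = framed["transcript_id"].map(ref_map)
    pos = framed["five_prime_pos"] - ref
    df = pd.DataFrame(
        {
            "position": pos.to_numpy(),
            "count": framed["count"].to_numpy(),
            "length": framed["length"].to_numpy(),
            "frame": framed["frame"].to_numpy(),
        }
    )
    if window is not None:
        df = df[(df["position"] >= window[0]) & (df["position"] <= window[1])]
    keys = ["position", "length", "frame"] if by_length_frame else ["position"]
    prof = df.groupby(keys, as_index=False)["count"].sum()
    prof = prof.rename(columns={"count": "value"}).sort_values(keys).reset_index(drop=True)
    return prof


def profile_peaks(profile: pd.DataFrame, n: int = 2) -> list[int]:
    """Positions of the ``n`` largest values in a metagene profile, ordered by
    value; ties resolved toward the position closest to the anchor (0)."""
    df = profile.sort_values(
        ["value", "position"],
        ascending=[False, True],
        key=lambda s: s.abs() if s.name == "position" else s,
    )
    return df["position"].head(n).tolist()
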