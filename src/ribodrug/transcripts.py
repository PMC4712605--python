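"""Transcript and ORF data model.

Everything downstream of file parsing works in spliced-transcript space with
0-based, half-open coordinates. GTF input (1-based, inclusive, genomic) is
converted at the boundary; minus-strand transcripts are spliced in genomic
order and then reverse-complemented, so the rest of the package is
strand-free.

ORF lengths include the stop codon: a uORF coding for a 3-amino-acid peptide
has ``nt_length`` 12 (start codon + 2 codons + stop).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_AUG = "ATG"
START_CUG = "CTG"

_SEQ_RE = re.compile(r"^[ACGTN]*$")

BIOTYPE_CODING = "coding"
BIOTYPE_LNCRNA = "lncRNA"
BIOTYPE_SNORNA = "snoRNA"
BIOTYPE_OTHER = "other-nc"


class InvalidSequenceError(ValueError):
    """Sequence contains characters outside the A/C/G/T/N alphabet."""


@dataclass(frozen=True)
class ORFRecord:
    """An open reading frame on a spliced transcript.

    ``start`` points at the first nucleotide of the start codon, ``stop_end``
    one past the last nucleotide of the stop codon (``None`` for open-ended
    ORFs that never hit an in-frame stop). ``region`` is one of ``5UTR``,
    ``lncRNA``, ``CDS`` or ``overlaps-CDS``.
    """

    transcript_id: str
    start: int
    stop_end: int | None
    start_class: str
    frame: int
    region: str

    @property
    def has_stop(self) -> bool:
        return self.stop_end is not None

    @property
    def nt_length(self) -> int | None:
        """Stop-codon-inclusive length in nucleotides."""
        if self.stop_end is None:
            return None
        return self.stop_end - self.start

    def __post_init__(self) -> None:
        if self.stop_end is not None:
            n = self.stop_end - self.start
            if n < 6 or n % 3:
                raise ValueError(
                    f"ORF length {n} must be >=6 and divisible by 3 "
                    f"({self.transcript_id}:{self.start})"
                )


@dataclass
class TranscriptModel:
    """A spliced transcript with optional CDS annotation.

    ``exons`` are genomic ``(start, end)`` half-open intervals in genomic
    order; ``cds_start``/``cds_stop`` are transcript coordinates (half-open)
    of the annotated coding sequence including the stop codon.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    sequence: str
    chrom: str = "."
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: int | None = None
    cds_stop: int | None = None
    annotated: bool = True
    start_annotated: bool = True
    stop_annotated: bool = True

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None and self.cds_stop is not None

    @property
    def utr5(self) -> tuple[int, int] | None:
        if not self.is_coding:
            return None
        return (0, self.cds_start)

    @property
    def utr3(self) -> tuple[int, int] | None:
        if not self.is_coding:
            return None
        return (self.cds_stop, len(self.sequence))

    def cds_orf(self) -> ORFRecord:
        if not self.is_coding:
            raise ValueError(f"{self.transcript_id} has no CDS")
        return ORFRecord(
            transcript_id=self.transcript_id,
            start=self.cds_start,
            stop_end=self.cds_stop,
            start_class=self.sequence[self.cds_start : self.cds_start + 3],
            frame=self.cds_start % 3,
            region="CDS",
        )

    def validate(self) -> None:
        if not _SEQ_RE.match(self.sequence):
            raise InvalidSequenceError(
                f"{self.transcript_id}: non-ACGTN characters in sequence"
            )
        if self.exons:
            exon_len = sum(e - s for s, e in self.exons)
            if exon_len != len(self.sequence):
                raise ValueError(
                    f"{self.transcript_id}: exon length {exon_len} != "
                    f"sequence length {len(self.sequence)}"
                )
        if self.is_coding:
            n = self.cds_stop - self.cds_start
            if n % 3 or n < 6:
                raise ValueError(f"{self.transcript_id}: CDS length {n} invalid")
            if self.sequence[self.cds_start : self.cds_start + 3] != START_AUG:
                raise ValueError(f"{self.transcript_id}: CDS does not start with ATG")
            if self.sequence[self.cds_stop - 3 : self.cds_stop] not in STOP_CODONS:
                raise ValueError(f"{self.transcript_id}: CDS does not end on a stop")


# ---------------------------------------------------------------------------
# ORF enumeration
# ---------------------------------------------------------------------------

def enumerate_orfs(
    seq: str,
    start_classes: Iterable[str] = (START_AUG,),
    region_bounds: tuple[int, int] | None = None,
    cds_start: int | None = None,
    transcript_id: str = "",
    region_label: str | None = None,
    include_open_ended: bool = True,
) -> list[ORFRecord]:
    """Enumerate every ORF starting with one of ``start_classes``.

    Each occurrence of a requested start codon whose first nucleotide falls in
    ``region_bounds`` is paired with the first in-frame stop codon anywhere
    downstream on the transcript. Overlapping and nested ORFs are all
    reported. ORFs whose stop lies at/after ``cds_start`` are labelled
    ``overlaps-CDS``; ORFs with no in-frame stop at all are returned as
    open-ended records (``stop_end`` None) when ``include_open_ended``.
    """
    seq = seq.upper()
    if not _SEQ_RE.match(seq):
        raise InvalidSequenceError("non-ACGTN characters in sequence")
    lo, hi = region_bounds if region_bounds is not None else (0, len(seq))
    if lo < 0 or hi > len(seq):
        raise ValueError("region bounds outside sequence")
    starts = set(c.upper() for c in start_classes)

    records: list[ORFRecord] = []
    for i in range(lo, min(hi, len(seq) - 2)):
        codon = seq[i : i + 3]
        if codon not in starts:
            continue
        stop_end: int | None = None
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in STOP_CODONS:
                stop_end = j + 3
                break
        if region_label is not None:
            region = region_label
        elif cds_start is not None:
            end_for_region = stop_end if stop_end is not None else len(seq)
            region = "5UTR" if end_for_region <= cds_start else "overlaps-CDS"
        else:
            region = "lncRNA"
        if stop_end is None and not include_open_ended:
            continue
        records.append(
            ORFRecord(
                transcript_id=transcript_id,
                start=i,
                stop_end=stop_end,
                start_class=codon,
                frame=i % 3,
                region=region,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Near-cognate start-codon arithmetic
# ---------------------------------------------------------------------------

def near_cognate_codons() -> frozenset[str]:
    """Codons one substitution away from ATG, excluding CTG (8 codons)."""
    bases = "ACGT"
    out = set()
    for pos in range(3):
        for b in bases:
            codon = START_AUG[:pos] + b + START_AUG[pos + 1 :]
            if codon not in (START_AUG, START_CUG):
                out.add(codon)
    return frozenset(out)


def near_cognate_coverage(
    base_probs: Mapping[str, float] | Sequence[float] | None = None,
    codons: Iterable[str] | None = None,
) -> float:
    """Expected fraction of positions lying on a near-cognate start codon.

    For an i.i.d. sequence each position is covered by three frames; by
    linearity of expectation the expected covered fraction is three times the
    per-position codon probability. Under uniform composition this is
    3 * 8/64 = 0.375. (As a coverage *probability* the true value is slightly
    below this because adjacent occurrences can overlap; the expectation
    arithmetic is what is implemented.)
    """
    if base_probs is None:
        probs = {b: 0.25 for b in "ACGT"}
    elif isinstance(base_probs, Mapping):
        probs = dict(base_probs)
    else:
        probs = dict(zip("ACGT", base_probs))
    total = sum(probs.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"base probabilities sum to {total}, expected 1")
    codon_set = near_cognate_codons() if codons is None else set(codons)
    p_codon = sum(
        probs.get(c[0], 0.0) * probs.get(c[1], 0.0) * probs.get(c[2], 0.0)
        for c in codon_set
    )
    return 3.0 * p_codon


# ---------------------------------------------------------------------------
# Representative transcript selection
# ---------------------------------------------------------------------------

def _start_codon_share(t: TranscriptModel, profile: np.ndarray | None) -> float:
    """Fraction of CDS footprints on the start codon +/- 1 nt."""
    if profile is None or not t.is_coding:
        return 0.0
    cds = profile[t.cds_start : t.cds_stop]
    total = float(cds.sum())
    if total <= 0:
        return 0.0
    lo = max(t.cds_start - 1, 0)
    return float(profile[lo : t.cds_start + 2].sum()) / total


def select_representative_transcript(
    candidates: Sequence[TranscriptModel],
    control_profiles: Mapping[str, np.ndarray] | None = None,
    start_share_threshold: float = 0.02,
) -> TranscriptModel:
    """Pick one transcript per gene.

    Preference order: annotated over predicted; coding over noncoding; both
    start and stop annotated over partial. Among the survivors, if any
    candidate has at least ``start_share_threshold`` of its CDS footprints on
    the start codon +/- 1 nt, the unique such candidate is taken (ties go to
    the highest CDS footprint count); otherwise the longest CDS wins. Final
    ties: longest transcript, then lexicographically smallest id.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    control_profiles = control_profiles or {}
    pool = list(candidates)
    for key in (
        lambda t: t.annotated,
        lambda t: t.is_coding,
        lambda t: t.start_annotated and t.stop_annotated,
    ):
        if any(key(t) for t in pool):
            pool = [t for t in pool if key(t)]
    if len(pool) == 1:
        return pool[0]

    def cds_counts(t: TranscriptModel) -> float:
        p = control_profiles.get(t.transcript_id)
        if p is None or not t.is_coding:
            return 0.0
        return float(p[t.cds_start : t.cds_stop].sum())

    with_pileup = [
        t
        for t in pool
        if _start_codon_share(t, control_profiles.get(t.transcript_id))
        >= start_share_threshold
    ]
    if len(with_pileup) == 1:
        return with_pileup[0]
    if with_pileup:
        best = max(cds_counts(t) for t in with_pileup)
        pool = [t for t in with_pileup if cds_counts(t) == best]

    def cds_len(t: TranscriptModel) -> int:
        return (t.cds_stop - t.cds_start) if t.is_coding else 0

    best_cds = max(cds_len(t) for t in pool)
    pool = [t for t in pool if cds_len(t) == best_cds]
    best_len = max(len(t) for t in pool)
    pool = [t for t in pool if len(t) == best_len]
    return min(pool, key=lambda t: t.transcript_id)


# ---------------------------------------------------------------------------
# GTF / FASTA IO
# ---------------------------------------------------------------------------

_BIOTYPE_MAP = {
    "protein_coding": BIOTYPE_CODING,
    "coding": BIOTYPE_CODING,
    "lncRNA": BIOTYPE_LNCRNA,
    "lincRNA": BIOTYPE_LNCRNA,
    "snoRNA": BIOTYPE_SNORNA,
}


def load_transcripts(
    gtf_path: str | Path,
    transcript_fasta: str | Path | None = None,
    genome_fasta: str | Path | None = None,
    exclude_biotypes: Iterable[str] = ("pseudogene",),
) -> dict[str, TranscriptModel]:
    """Build :class:`TranscriptModel` objects from a GTF plus sequences.

    Sequences come either from a transcript-space FASTA (keyed by transcript
    id) or are spliced out of a genome FASTA. Pseudogenes are excluded by
    default.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    tx_seqs: dict[str, str] = {}
    if transcript_fasta is not None:
        tx_seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(transcript_fasta), "fasta")
        }
    genome: dict[str, str] = {}
    if genome_fasta is not None:
        genome = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(genome_fasta), "fasta")
        }
    if not tx_seqs and not genome:
        raise ValueError("need a transcript or genome FASTA for sequences")

    excluded = set(exclude_biotypes)
    out: dict[str, TranscriptModel] = {}
    for feat in db.features_of_type("transcript"):
        tid = feat.attributes.get("transcript_id", [feat.id])[0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        raw_bt = (
            feat.attributes.get("transcript_biotype", [])
            or feat.attributes.get("gene_biotype", [])
            or ["other"]
        )[0]
        if raw_bt in excluded:
            continue
        biotype = _BIOTYPE_MAP.get(raw_bt, BIOTYPE_OTHER)
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(feat, featuretype="exon")
        )
        if not exons:
            exons = [(feat.start - 1, feat.end)]
        strand = feat.strand if feat.strand in "+-" else "+"

        if tid in tx_seqs:
            seq = tx_seqs[tid]
        else:
            chrom_seq = genome[feat.seqid]
            spliced = "".join(chrom_seq[s:e] for s, e in exons)
            seq = str(Seq(spliced).reverse_complement()) if strand == "-" else spliced

        cds_ivals = sorted(
            (f.start - 1, f.end) for f in db.children(feat, featuretype="CDS")
        )
        cds_start = cds_stop = None
        if cds_ivals:
            g2t = _genomic_to_transcript_map(exons, strand)
            coords = [g2t[p] for s, e in cds_ivals for p in (s, e - 1)]
            cds_start, cds_stop = min(coords), max(coords) + 1
            # GTF CDS features conventionally exclude the stop codon; include
            # it when the next three nucleotides form a stop.
            if (
                seq[cds_stop - 3 : cds_stop] not in STOP_CODONS
                and seq[cds_stop : cds_stop + 3] in STOP_CODONS
            ):
                cds_stop += 3

        def _flag(name: str, default: str = "True") -> bool:
            return feat.attributes.get(name, [default])[0] == "True"

        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            biotype=biotype,
            sequence=seq,
            chrom=feat.seqid,
            strand=strand,
            exons=exons,
            cds_start=cds_start,
            cds_stop=cds_stop,
            annotated=_flag("annotated"),
            start_annotated=_flag("start_annotated"),
            stop_annotated=_flag("stop_annotated"),
        )
        model.validate()
        out[tid] = model
    return out


def _genomic_to_transcript_map(
    exons: Sequence[tuple[int, int]], strand: str
) -> dict[int, int]:
    positions: list[int] = []
    for s, e in exons:
        positions.extend(range(s, e))
    if strand == "-":
        positions = positions[::-1]
    return {g: i for i, g in enumerate(positions)}


def write_orf_table(orfs: Iterable[ORFRecord], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "transcript_id": o.transcript_id,
                "start": o.start,
                "stop_end": -1 if o.stop_end is None else o.stop_end,
                "start_class": o.start_class,
                "region": o.region,
                "frame": o.frame,
            }
            for o in orfs
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
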