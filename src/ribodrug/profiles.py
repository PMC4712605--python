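"""Footprint profiles: read filtering, P-site calibration, projection.

A profile is a per-nucleotide P-site count vector on a spliced transcript for
one (condition, replicate) sample. Profiles either come from the tabular TSV
format written by the simulator (first-class input, no aligner required) or
are projected from a transcript-space SAM file after read filtering and
P-site offset calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import READ_LENGTHS, SPIKE_ID
from .transcripts import TranscriptModel

MIN_LENGTH, MAX_LENGTH = 26, 36
MIN_MAPQ = 10

PROFILE_COLUMNS = [
    "transcript_id", "position", "condition", "replicate", "read_length", "count",
]


class CalibrationError(RuntimeError):
    """Metagene has no usable signal for P-site offset calibration."""


# ---------------------------------------------------------------------------
# Profile container
# ---------------------------------------------------------------------------

class ProfileSet:
    """Long-format per-nucleotide footprint counts for many samples.

    Wraps a DataFrame with columns ``transcript_id, position, condition,
    replicate, read_length, count`` plus a transcript-length map. Count
    vectors requested without a replicate are normalized means over the
    condition's replicates.
    """

    def __init__(self, df: pd.DataFrame, transcript_lengths: Mapping[str, int]):
        self.df = df.reset_index(drop=True)
        self.lengths = dict(transcript_lengths)
        self._by_tid: dict | None = None
        self._reps = {
            cond: sorted(sub.replicate.unique())
            for cond, sub in df.groupby("condition")
        }

    @classmethod
    def from_tsv(
        cls, path: str | Path, transcript_lengths: Mapping[str, int]
    ) -> "ProfileSet":
        df = pd.read_csv(str(path), sep="\t")
        missing = [c for c in PROFILE_COLUMNS if c not in df.columns and c != "read_length"]
        if missing:
            raise ValueError(f"profile TSV missing columns: {missing}")
        if "read_length" not in df.columns:
            df["read_length"] = 0
        return cls(df, transcript_lengths)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(str(path), sep="\t", index=False)

    # -- basic introspection ------------------------------------------------
    @property
    def conditions(self) -> list[str]:
        return sorted(self._reps)

    def samples(self) -> list[tuple[str, int]]:
        return [(c, r) for c in self.conditions for r in self._reps[c]]

    def n_replicates(self, condition: str) -> int:
        return len(self._reps.get(condition, []))

    def _tid_group(self, tid: str) -> pd.DataFrame | None:
        if self._by_tid is None:
            self._by_tid = dict(tuple(self.df.groupby("transcript_id")))
        return self._by_tid.get(tid)

    # -- accessors -----------------------------------------------------------
    def vector(
        self, transcript_id: str, condition: str, replicate: int | None = None
    ) -> np.ndarray:
        """Per-nucleotide counts; replicate-mean when ``replicate`` is None."""
        length = self.lengths[transcript_id]
        out = np.zeros(length, dtype=float)
        sub = self._tid_group(transcript_id)
        if sub is None:
            return out
        sub = sub[sub.condition == condition]
        if replicate is not None:
            sub = sub[sub.replicate == replicate]
            denom = 1.0
        else:
            denom = max(self.n_replicates(condition), 1)
        if len(sub):
            np.add.at(out, sub.position.to_numpy(), sub["count"].to_numpy(dtype=float))
        return out / denom

    def region_sum(
        self,
        transcript_id: str,
        condition: str,
        start: int | None = None,
        stop: int | None = None,
        replicate: int | None = None,
    ) -> float:
        v = self.vector(transcript_id, condition, replicate)
        return float(v[slice(start, stop)].sum())

    def length_hist(
        self,
        transcript_id: str,
        condition: str,
        start: int | None = None,
        stop: int | None = None,
    ) -> np.ndarray:
        """Replicate-summed read-length histogram over lengths 26-36."""
        out = np.zeros(len(READ_LENGTHS), dtype=float)
        sub = self._tid_group(transcript_id)
        if sub is None:
            return out
        sub = sub[sub.condition == condition]
        if start is not None:
            sub = sub[sub.position >= start]
        if stop is not None:
            sub = sub[sub.position < stop]
        for length, cnt in sub.groupby("read_length")["count"].sum().items():
            if MIN_LENGTH <= length <= MAX_LENGTH:
                out[int(length) - MIN_LENGTH] += cnt
        return out

    def sample_totals(self, transcript_ids: Iterable[str] | None = None) -> pd.Series:
        df = self.df
        if transcript_ids is not None:
            df = df[df.transcript_id.isin(set(transcript_ids))]
        return df.groupby(["condition", "replicate"])["count"].sum()

    def spike_counts(self, spike_id: str = SPIKE_ID) -> pd.Series:
        sub = self.df[self.df.transcript_id == spike_id]
        return sub.groupby(["condition", "replicate"])["count"].sum()

    def transcript_totals(self, condition: str, replicate: int) -> pd.Series:
        sub = self.df[
            (self.df.condition == condition) & (self.df.replicate == replicate)
        ]
        return sub.groupby("transcript_id")["count"].sum()

    def scaled(self, factors: Mapping[tuple[str, int], float]) -> "ProfileSet":
        """Divide each sample's counts by its size factor (missing: 1)."""
        df = self.df.copy()
        keys = list(zip(df.condition, df.replicate))
        div = np.array([factors.get(k, 1.0) for k in keys])
        df["count"] = df["count"].to_numpy(dtype=float) / div
        return ProfileSet(df, self.lengths)


# ---------------------------------------------------------------------------
# Alignment filtering
# ---------------------------------------------------------------------------

def _leading_mismatch(record) -> bool:
    """True when the first base of the read (5' end) mismatches."""
    try:
        md = record.get_tag("MD")
    except KeyError:
        return False
    md = str(md)
    if not record.is_reverse:
        return len(md) > 1 and md[0] == "0" and md[1].isalpha()
    # MD runs reference-forward; a mismatch at the last aligned base (the 5'
    # base of a reverse read) shows up as "<...><base>0"
    return len(md) > 1 and md[-1] == "0" and md[-2].isalpha()


def filter_alignment(
    record,
    min_length: int = MIN_LENGTH,
    max_length: int = MAX_LENGTH,
    min_mapq: int = MIN_MAPQ,
) -> tuple[bool, str]:
    """Accept/reject one aligned read, with the rejection reason.

    Accepted reads are 26-36 nt, uniquely mapped (NH tag 1, not secondary or
    supplementary), mapping quality >= 10 and without a mismatch on the first
    (5') base.
    """
    if record.is_unmapped:
        return False, "unmapped"
    length = record.query_length or record.infer_query_length() or 0
    if not (min_length <= length <= max_length):
        return False, "length"
    if record.is_secondary or record.is_supplementary:
        return False, "multimapped"
    try:
        if int(record.get_tag("NH")) > 1:
            return False, "multimapped"
    except KeyError:
        pass
    if record.mapping_quality < min_mapq:
        return False, "quality"
    if _leading_mismatch(record):
        return False, "leading_mismatch"
    return True, "ok"


def read_starts_from_sam(
    path: str | Path, apply_filter: bool = True
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Collect filtered 5'-end read starts from a transcript-space SAM/BAM.

    Returns a frame with columns ``transcript_id, position, condition,
    replicate, read_length, count`` (condition/replicate from the XC/XR tags
    when present) and a rejection-reason counter.
    """
    import pysam

    rows: dict[tuple, int] = {}
    rejected: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if apply_filter:
                ok, reason = filter_alignment(rec)
                if not ok:
                    rejected[reason] = rejected.get(reason, 0) + 1
                    continue
            length = rec.query_length or rec.infer_query_length()
            five_prime = (
                rec.reference_end - 1 if rec.is_reverse else rec.reference_start
            )
            cond = rec.get_tag("XC") if rec.has_tag("XC") else "control"
            rep = int(rec.get_tag("XR")) if rec.has_tag("XR") else 1
            key = (rec.reference_name, five_prime, cond, rep, length)
            rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [(k[0], k[1], k[2], k[3], k[4], v) for k, v in rows.items()],
        columns=PROFILE_COLUMNS,
    )
    return df, rejected


# ---------------------------------------------------------------------------
# Metagene and P-site offset calibration
# ---------------------------------------------------------------------------

@dataclass
class Metagene:
    """Summed read-start counts around an anchor, stratified by read length.

    ``matrix`` has one row per read length (26-36) and one column per
    position in ``-window .. +window`` relative to the anchor nucleotide
    (first nt of the start codon, or first nt of the stop codon).
    """

    anchor: str
    window: int
    matrix: np.ndarray  # (n_lengths, 2*window+1)
    n_transcripts: int

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)

    def combined(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


def build_metagene(
    read_starts: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    anchor: str = "start",
    window: int = 30,
    top_n: int = 800,
    condition: str | None = "control",
) -> Metagene:
    """Sum read starts around CDS start (or stop) codons.

    Restricted to the ``top_n`` coding transcripts of highest ribosome
    density (footprint read starts per CDS nucleotide); fewer are used when
    fewer are available.
    """
    coding = {tid: t for tid, t in transcripts.items() if t.is_coding}
    if not coding:
        raise ValueError("no CDS-annotated transcripts for metagene")
    df = read_starts
    if condition is not None and "condition" in df.columns:
        df = df[df.condition == condition]
    df = df[df.transcript_id.isin(coding)]

    densities = {}
    for tid, sub in df.groupby("transcript_id"):
        t = coding[tid]
        in_cds = sub[(sub.position >= t.cds_start) & (sub.position < t.cds_stop)]
        densities[tid] = in_cds["count"].sum() / (t.cds_stop - t.cds_start)
    chosen = set(
        sorted(densities, key=lambda k: densities[k], reverse=True)[:top_n]
    )

    matrix = np.zeros((len(READ_LENGTHS), 2 * window + 1), dtype=float)
    for tid, sub in df.groupby("transcript_id"):
        if tid not in chosen:
            continue
        t = coding[tid]
        a = t.cds_start if anchor == "start" else t.cds_stop - 3
        rel = sub.position.to_numpy() - a
        inside = (rel >= -window) & (rel <= window)
        lengths = sub.read_length.to_numpy()[inside]
        lidx = np.clip(lengths, MIN_LENGTH, MAX_LENGTH) - MIN_LENGTH
        np.add.at(matrix, (lidx, rel[inside] + window), sub["count"].to_numpy()[inside])
    return Metagene(anchor=anchor, window=window, matrix=matrix, n_transcripts=len(chosen))


def _calibrate_row(row: np.ndarray, window: int) -> int | None:
    """Offset from one metagene row: 5' peak + codon-phase frame correction.

    The start pileup spreads over start +/- 1 nt, so the raw upstream peak
    pins the offset only up to +/- 1; among the three candidate offsets the
    one maximizing the downstream center-of-codon phase mass is chosen
    (ties: the peak-implied offset, then the smaller one).
    """
    upstream = row[:window]  # positions -window .. -1
    if upstream.max() <= 0:
        return None
    # peak; ties toward the smaller offset (position closest to the anchor)
    peaks = np.flatnonzero(upstream == upstream.max())
    o0 = window - int(peaks[-1])
    q = np.arange(-window, window + 1)
    best: tuple | None = None
    for o in (o0 - 1, o0, o0 + 1):
        if o < 1:
            continue
        body = (q + o >= 3) & ((q + o) % 3 == 1)  # center nt, past the pileup
        mass = float(row[body].sum())
        cand = (mass, o == o0, -o, o)
        if best is None or cand > best:
            best = cand
    return best[3]


def calibrate_psite_offsets(metagene: Metagene) -> dict[int, int]:
    """Per-read-length P-site offsets (nt from the 5' read end).

    The metagene 5' peak upstream of the start codon gives a coarse offset;
    the codon-phase mode of the downstream positions supplies a +-1 frame
    correction so that shifted footprints fall on the center nucleotide of
    codons. Length strata without reads inherit the all-length offset.
    """
    window = metagene.window
    global_offset = _calibrate_row(metagene.combined(), window)
    if global_offset is None:
        raise CalibrationError("flat metagene: no calibratable signal")
    offsets: dict[int, int] = {}
    for i, length in enumerate(READ_LENGTHS):
        o = _calibrate_row(metagene.matrix[i], window)
        offsets[int(length)] = o if o is not None else global_offset
    return offsets


def write_offsets(offsets: Mapping[int, int], path: str | Path) -> None:
    pd.DataFrame(
        {"read_length": list(offsets), "offset": list(offsets.values())}
    ).to_csv(str(path), sep="\t", index=False)


def read_offsets(path: str | Path) -> dict[int, int]:
    df = pd.read_csv(str(path), sep="\t")
    return dict(zip(df.read_length.astype(int), df.offset.astype(int)))


# ---------------------------------------------------------------------------
# Read projection
# ---------------------------------------------------------------------------

def project_reads(
    read_starts: pd.DataFrame,
    offsets: Mapping[int, int],
    transcript_lengths: Mapping[str, int],
) -> tuple[ProfileSet, int]:
    """Shift filtered read starts by their per-length P-site offset.

    Each read contributes one count at ``5'-end position + offset``. Reads on
    unknown transcripts or whose shifted position falls off the transcript
    are dropped and counted.
    """
    df = read_starts.copy()
    known = df.transcript_id.isin(transcript_lengths)
    dropped = int(df.loc[~known, "count"].sum())
    df = df[known]
    missing = sorted(set(df.read_length.unique()) - set(offsets))
    if missing:
        raise KeyError(f"no P-site offset for read lengths {missing}")
    off = df.read_length.map(offsets).to_numpy()
    psite = df.position.to_numpy() + off
    tlen = df.transcript_id.map(transcript_lengths).to_numpy()
    ok = (psite >= 0) & (psite < tlen)
    dropped += int(df.loc[~ok, "count"].sum())
    df = df[ok].copy()
    df["position"] = psite[ok]
    df = (
        df.groupby(
            ["transcript_id", "position", "condition", "replicate", "read_length"],
            as_index=False,
        )["count"]
        .sum()
    )
    return ProfileSet(df, transcript_lengths), dropped
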