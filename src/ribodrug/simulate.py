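"""Synthetic transcriptome and footprint-profile generator.

Emulates a translation-inhibitor ribosome-profiling experiment: a mixed
population of coding, lncRNA and snoRNA transcripts with log-normal
expression (lncRNAs lower-expressed), per-nucleotide P-site profiles with
codon phasing and start-codon pileups, five conditions (whole transcriptome,
control footprints, DMDA-PatA, harringtonine, puromycin) with class-specific
fold inhibitions, a 26-36 nt read-length model, and a spike-in pseudo
transcript with identical true abundance across samples.

Drug action is modelled as independent binomial thinning of the control
counts with probability 1/fold, the simplest model under which the fraction
of footprints that resist a drug is a per-ORF ratio. Puromycin folds are
attenuated on short ORFs via a per-codon geometric survival term, so that
chain termination accumulates with ORF length and short ORFs are only weakly
inhibited. Footprints not due to translation (structure- or protein-protected
fragments) are drawn uniformly along the transcript and are drug-invariant;
their rate is a free parameter of the generator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import Seq

from .transcripts import (
    BIOTYPE_CODING,
    BIOTYPE_LNCRNA,
    BIOTYPE_SNORNA,
    ORFRecord,
    START_AUG,
    START_CUG,
    STOP_CODONS,
    TranscriptModel,
)

CONDITIONS = ("transcriptome", "control", "pata", "harringtonine", "puromycin")
DRUGS = ("pata", "harringtonine", "puromycin")
READ_LENGTHS = np.arange(26, 37)
SPIKE_ID = "SPIKEIN"

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

# fractions of footprint reads per length 26..36; peaked at 30 nt for
# ribosome-protected fragments, flat for non-translational fragments
_TRANSLATED_LENGTH_PROBS = (
    0.02, 0.05, 0.10, 0.18, 0.25, 0.18, 0.10, 0.06, 0.03, 0.02, 0.01,
)
_NOISE_LENGTH_PROBS = tuple([1.0 / 11] * 11)

DEFAULT_PSITE_OFFSETS = {
    26: 11, 27: 11, 28: 12, 29: 12, 30: 13, 31: 13,
    32: 13, 33: 14, 34: 14, 35: 14, 36: 15,
}


class GeometryError(ValueError):
    """Requested ORF/UTR structure does not fit in the host sequence."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults reproduce the real experiment's printed characteristics:
    transcriptome-read medians of 345 (coding) and 50 (lncRNA), median fold
    inhibitions of 22x (DMDA-PatA), 8.7x (harringtonine) and 6.3x
    (puromycin) on coding sequences with ~1x on snoRNA footprints, a
    center-heavy codon phasing, and two biological replicates per condition.
    """

    n_coding: int = 300
    n_lncrna: int = 100
    n_snorna: int = 50
    seed: int = 0

    # expression model: log-normal read totals per biotype
    expression_medians: dict = field(
        default_factory=lambda: {
            BIOTYPE_CODING: 345.0,
            BIOTYPE_LNCRNA: 50.0,
            BIOTYPE_SNORNA: 150.0,
        }
    )
    expression_sigma: float = 1.0

    # footprint placement
    phasing: tuple = (0.2, 0.6, 0.2)
    start_pileup_fraction: float = 0.15
    stalled_fraction: float = 0.10
    stalled_pileup_fraction: float = 0.5

    # per-ORF footprint load relative to transcriptome reads
    te: dict = field(
        default_factory=lambda: {"cds": 1.0, "uorf": 0.4, "lncRNA_orf": 1.0}
    )
    snorna_load: float = 1.0
    # non-translational RNase-resistant footprints per transcriptome read;
    # kept well below 1/fold so the configured drug effects stay observable
    noise_rate: float = 0.005

    # drug effects: per drug, per ORF class median fold inhibition
    drug_folds: dict = field(
        default_factory=lambda: {
            "pata": {"cds": 22.0, "uorf": 8.5, "lncRNA_orf": 11.3, "snoRNA": 1.0},
            "harringtonine": {"cds": 8.7, "uorf": 2.0, "lncRNA_orf": 2.0, "snoRNA": 1.0},
            "puromycin": {"cds": 6.3, "uorf": 6.3, "lncRNA_orf": 6.3, "snoRNA": 1.0},
        }
    )
    fold_sigma: float = 0.5
    snorna_fold_sigma: float = 0.03
    puromycin_codon_survival: float = 0.95

    # read lengths and P-site geometry
    read_length_probs: tuple = _TRANSLATED_LENGTH_PROBS
    noise_length_probs: tuple = _NOISE_LENGTH_PROBS
    psite_offsets: dict = field(default_factory=lambda: dict(DEFAULT_PSITE_OFFSETS))

    # sampling depth / spike-in
    spike_in: int = 10_000
    spike_length: int = 300
    depth_sigma: float = 0.15
    n_replicates: int = 2

    # transcript geometry (nt)
    utr5_median: int = 150
    cds_median: int = 1200
    utr3_median: int = 400
    lncrna_median: int = 800
    lncrna_orf_median: int = 150
    snorna_length: int = 130
    snorna_orf_length: int = 45
    geometry_sigma: float = 0.35

    # uORF planting
    aug_uorf_fraction: float = 0.4
    cug_uorf_fraction: float = 0.3
    aug_uorf_translated_fraction: float = 0.5
    cug_uorf_translated_fraction: float = 0.15
    uorf_length_median: int = 33
    lncrna_translated_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.phasing), 1.0):
            raise ValueError("phasing vector must sum to 1")
        if len(self.read_length_probs) != len(READ_LENGTHS):
            raise ValueError("read_length_probs must cover lengths 26-36")
        for probs in (self.read_length_probs, self.noise_length_probs):
            if not np.isclose(sum(probs), 1.0):
                raise ValueError("length probabilities must sum to 1")
        for drug, classes in self.drug_folds.items():
            for cls, fold in classes.items():
                if cls != "snoRNA" and fold < 1:
                    raise ValueError(f"{drug}/{cls}: fold inhibition must be >= 1")
        if min(self.n_coding, self.n_lncrna, self.n_snorna) < 0:
            raise ValueError("transcript counts must be non-negative")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


@dataclass
class TruthTable:
    """Ground-truth labels for a synthetic bundle.

    ``orfs`` has one row per generated ORF (planted uORFs, annotated CDSs,
    lncRNA ORFs, snoRNA carrier ORFs) with its configured fold inhibition per
    drug; ``sample_depths`` records the per-sample depth factors the spike-in
    normalization is expected to undo.
    """

    transcripts: pd.DataFrame
    orfs: pd.DataFrame
    sample_depths: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n > 0 else ""


def _orf_sequence(rng: np.random.Generator, nt_length: int, start_codon: str) -> str:
    """Start codon + random non-stop codons + one stop codon."""
    if nt_length < 6 or nt_length % 3:
        raise GeometryError(f"ORF length {nt_length} must be >=6, divisible by 3")
    n_mid = nt_length // 3 - 2
    mid = "".join(rng.choice(_NONSTOP_CODONS, size=n_mid)) if n_mid else ""
    stop = str(rng.choice(sorted(STOP_CODONS)))
    return start_codon + mid + stop


def _lognormal_length(
    rng: np.random.Generator, median: float, sigma: float, minimum: int, multiple: int = 1
) -> int:
    n = int(rng.lognormal(np.log(median), sigma))
    n = max(n, minimum)
    if multiple > 1:
        n -= n % multiple
        n = max(n, minimum)
    return n


def _draw_fold(rng: np.random.Generator, median: float, sigma: float) -> float:
    if not np.isfinite(median):
        return np.inf
    return max(1.0, float(rng.lognormal(np.log(median), sigma)))


def generate_transcriptome(
    config: SimConfig,
) -> tuple[dict[str, TranscriptModel], TruthTable]:
    """Generate transcripts and their ground-truth translation labels.

    Coding transcripts carry a valid AUG...stop CDS with 5'/3' UTRs and a
    configurable fraction of 5'UTRs hosts planted AUG or CUG uORFs; lncRNAs
    carry one AUG ORF shorter than 200 codons; snoRNAs carry a short
    untranslated AUG ORF so that downstream scoring has a noncoding reference
    class. Planted ORFs contain no in-frame stops.
    """
    rng = np.random.default_rng([config.seed, 0])
    sigma = config.geometry_sigma
    transcripts: dict[str, TranscriptModel] = {}
    tx_rows = []
    orf_rows = []

    def add_orf(tid, start, nt_length, start_codon, region, orf_class, translated, te):
        stalled = bool(
            translated and rng.random() < config.stalled_fraction
        )
        folds = {}
        for drug in DRUGS:
            if not translated:
                folds[drug] = 1.0
            elif orf_class == "snoRNA":
                folds[drug] = _draw_fold(rng, 1.0, config.snorna_fold_sigma)
            else:
                f = _draw_fold(rng, config.drug_folds[drug][orf_class], config.fold_sigma)
                if drug == "puromycin":
                    n_codons = nt_length // 3
                    atten = 1.0 - config.puromycin_codon_survival ** n_codons
                    f = 1.0 + (f - 1.0) * atten if np.isfinite(f) else f
                folds[drug] = f
        orf_rows.append(
            {
                "transcript_id": tid,
                "start": start,
                "stop_end": start + nt_length,
                "start_class": start_codon,
                "region": region,
                "orf_class": orf_class,
                "translated": bool(translated),
                "te": te if translated else 0.0,
                "stalled": stalled,
                "fold_pata": folds["pata"],
                "fold_harringtonine": folds["harringtonine"],
                "fold_puromycin": folds["puromycin"],
            }
        )

    def expression(biotype: str) -> float:
        return float(
            rng.lognormal(
                np.log(config.expression_medians[biotype]), config.expression_sigma
            )
        )

    for i in range(config.n_coding):
        tid = f"CODING{i:05d}"
        cds_len = _lognormal_length(rng, config.cds_median, sigma, 300, 3)
        utr3_len = _lognormal_length(rng, config.utr3_median, sigma, 60)
        utr5_len = _lognormal_length(rng, config.utr5_median, sigma, 30)

        uorf = None
        r = rng.random()
        if r < config.aug_uorf_fraction:
            uorf_codon = START_AUG
            translated_p = config.aug_uorf_translated_fraction
        elif r < config.aug_uorf_fraction + config.cug_uorf_fraction:
            uorf_codon = START_CUG
            translated_p = config.cug_uorf_translated_fraction
        else:
            uorf_codon = None
            translated_p = 0.0
        if uorf_codon is not None:
            uorf_len = _lognormal_length(rng, config.uorf_length_median, sigma, 12, 3)
            # leave >=15 nt upstream so SAM reads stay on the transcript
            if utr5_len < uorf_len + 20:
                utr5_len = uorf_len + 20
            uorf_start = int(rng.integers(15, utr5_len - uorf_len + 1))
            uorf = (uorf_start, uorf_len, uorf_codon, rng.random() < translated_p)

        utr5 = _random_seq(rng, utr5_len)
        if uorf is not None:
            s, n, codon, _ = uorf
            utr5 = utr5[:s] + _orf_sequence(rng, n, codon) + utr5[s + n :]
        seq = utr5 + _orf_sequence(rng, cds_len, START_AUG) + _random_seq(rng, utr3_len)

        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=f"G_{tid}",
            biotype=BIOTYPE_CODING,
            sequence=seq,
            cds_start=utr5_len,
            cds_stop=utr5_len + cds_len,
        )
        e = expression(BIOTYPE_CODING)
        tx_rows.append(
            {"transcript_id": tid, "biotype": BIOTYPE_CODING, "expression": e,
             "translated": True}
        )
        add_orf(tid, utr5_len, cds_len, START_AUG, "CDS", "cds", True, config.te["cds"])
        if uorf is not None:
            s, n, codon, translated = uorf
            add_orf(tid, s, n, codon, "5UTR", "uorf", translated, config.te["uorf"])

    for i in range(config.n_lncrna):
        tid = f"LNC{i:05d}"
        length = _lognormal_length(rng, config.lncrna_median, sigma, 300)
        orf_len = _lognormal_length(rng, config.lncrna_orf_median, sigma, 12, 3)
        orf_len = min(orf_len, 597)  # < 200 codons
        if length < orf_len + 60:
            length = orf_len + 60
        orf_start = int(rng.integers(20, length - orf_len - 20))
        seq = _random_seq(rng, length)
        seq = seq[:orf_start] + _orf_sequence(rng, orf_len, START_AUG) + seq[orf_start + orf_len :]
        translated = rng.random() < config.lncrna_translated_fraction
        transcripts[tid] = TranscriptModel(
            transcript_id=tid, gene_id=f"G_{tid}", biotype=BIOTYPE_LNCRNA, sequence=seq
        )
        tx_rows.append(
            {"transcript_id": tid, "biotype": BIOTYPE_LNCRNA,
             "expression": expression(BIOTYPE_LNCRNA), "translated": bool(translated)}
        )
        add_orf(tid, orf_start, orf_len, START_AUG, "lncRNA", "lncRNA_orf",
                translated, config.te["lncRNA_orf"])

    for i in range(config.n_snorna):
        tid = f"SNO{i:05d}"
        length = config.snorna_length
        orf_len = config.snorna_orf_length
        if length < orf_len + 20:
            raise GeometryError("snoRNA shorter than its carrier ORF")
        orf_start = int(rng.integers(5, length - orf_len - 5))
        seq = _random_seq(rng, length)
        seq = seq[:orf_start] + _orf_sequence(rng, orf_len, START_AUG) + seq[orf_start + orf_len :]
        transcripts[tid] = TranscriptModel(
            transcript_id=tid, gene_id=f"G_{tid}", biotype=BIOTYPE_SNORNA, sequence=seq
        )
        tx_rows.append(
            {"transcript_id": tid, "biotype": BIOTYPE_SNORNA,
             "expression": expression(BIOTYPE_SNORNA), "translated": False}
        )
        # snoRNA footprints are RNase-resistant but drug-invariant; the
        # carrier ORF exists so per-ORF scores have a noncoding reference
        add_orf(tid, orf_start, orf_len, START_AUG, "lncRNA", "snoRNA", True,
                config.snorna_load)

    for t in transcripts.values():
        t.validate()
    tx_cols = ["transcript_id", "biotype", "expression", "translated"]
    orf_cols = [
        "transcript_id", "start", "stop_end", "start_class", "region",
        "orf_class", "translated", "te", "stalled",
        "fold_pata", "fold_harringtonine", "fold_puromycin",
    ]
    truth = TruthTable(
        transcripts=pd.DataFrame(tx_rows, columns=tx_cols),
        orfs=pd.DataFrame(orf_rows, columns=orf_cols),
    )
    return transcripts, truth


# ---------------------------------------------------------------------------
# Profile simulation
# ---------------------------------------------------------------------------

def _place_orf_footprints(
    rng: np.random.Generator,
    n: int,
    orf_start: int,
    nt_length: int,
    tx_length: int,
    phasing,
    pileup_fraction: float,
) -> np.ndarray:
    """P-site positions for ``n`` footprints on one ORF."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    n_pile = rng.binomial(n, pileup_fraction)
    pile_lo = max(orf_start - 1, 0)
    pile = rng.integers(pile_lo, orf_start + 2, size=n_pile)
    n_body = n - n_pile
    codons = rng.integers(0, nt_length // 3, size=n_body)
    offs = rng.choice(3, size=n_body, p=np.asarray(phasing))
    body = orf_start + 3 * codons + offs
    pos = np.concatenate([pile, body])
    return np.clip(pos, 0, tx_length - 1)


def _to_length_matrix(
    rng: np.random.Generator, positions: np.ndarray, tx_length: int, length_probs
) -> np.ndarray:
    """Scatter footprint positions into a (tx_length x n_lengths) count matrix."""
    mat = np.zeros((tx_length, len(READ_LENGTHS)), dtype=np.int64)
    if positions.size:
        lidx = rng.choice(len(READ_LENGTHS), size=positions.size, p=np.asarray(length_probs))
        np.add.at(mat, (positions, lidx), 1)
    return mat


def simulate_profiles(
    transcripts: Mapping[str, TranscriptModel],
    truth: TruthTable,
    config: SimConfig,
) -> "pd.DataFrame":
    """Simulate per-nucleotide P-site count profiles for all conditions.

    Returns a long-format frame with columns ``transcript_id, position,
    condition, replicate, read_length, count`` (plus spike-in rows under
    transcript id ``SPIKEIN`` for the footprint conditions). Control counts
    follow the configured phasing and start pileup; each drug condition is an
    independent binomial thinning of the matching control replicate by
    1/fold; every sample is further thinned by its depth factor.
    """
    rng = np.random.default_rng([config.seed, 1])
    reps = range(1, config.n_replicates + 1)
    samples = [(c, r) for c in CONDITIONS for r in reps]
    depths = {s: float(np.exp(rng.normal(0.0, config.depth_sigma))) for s in samples}
    max_depth = max(depths.values()) if depths else 1.0
    depth_p = {s: d / max_depth for s, d in depths.items()}

    expr = dict(zip(truth.transcripts.transcript_id, truth.transcripts.expression))
    orfs_by_tid: dict[str, pd.DataFrame] = dict(tuple(truth.orfs.groupby("transcript_id")))

    chunks: list[pd.DataFrame] = []

    def emit(tid: str, cond: str, rep: int, mat: np.ndarray) -> None:
        pos, lidx = np.nonzero(mat)
        if not pos.size:
            return
        chunks.append(
            pd.DataFrame(
                {
                    "transcript_id": tid,
                    "position": pos,
                    "condition": cond,
                    "replicate": rep,
                    "read_length": READ_LENGTHS[lidx],
                    "count": mat[pos, lidx],
                }
            )
        )

    for tid, t in transcripts.items():
        L = len(t)
        e = expr[tid]
        orfs = orfs_by_tid.get(tid)

        for rep in reps:
            # whole-transcriptome reads: uniform along the transcript
            n_wt = rng.poisson(e * depth_p[("transcriptome", rep)])
            wt_pos = rng.integers(0, L, size=n_wt)
            emit(tid, "transcriptome", rep,
                 _to_length_matrix(rng, wt_pos, L, config.noise_length_probs))

            # control footprints: translated ORF load + uniform noise
            per_orf_mats = []
            folds_per_orf = []
            if orfs is not None:
                for row in orfs.itertuples():
                    if not row.translated:
                        continue
                    if row.orf_class == "snoRNA":
                        n = rng.poisson(config.snorna_load * e)
                        pos = rng.integers(0, L, size=n)  # structural, whole transcript
                        mat = _to_length_matrix(rng, pos, L, config.noise_length_probs)
                    else:
                        n = rng.poisson(row.te * e)
                        pileup = (
                            config.stalled_pileup_fraction
                            if row.stalled
                            else config.start_pileup_fraction
                        )
                        pos = _place_orf_footprints(
                            rng, n, row.start, row.stop_end - row.start, L,
                            config.phasing, pileup,
                        )
                        mat = _to_length_matrix(rng, pos, L, config.read_length_probs)
                    per_orf_mats.append(mat)
                    folds_per_orf.append(
                        {d: getattr(row, f"fold_{d}") for d in DRUGS}
                    )
            n_noise = rng.poisson(config.noise_rate * e)
            noise_mat = _to_length_matrix(
                rng, rng.integers(0, L, size=n_noise), L, config.noise_length_probs
            )

            control = noise_mat + (
                np.sum(per_orf_mats, axis=0) if per_orf_mats else 0
            )
            p = depth_p[("control", rep)]
            emit(tid, "control", rep, rng.binomial(control, p))

            for drug in DRUGS:
                thinned = noise_mat.copy()  # non-translational: drug-invariant
                for mat, folds in zip(per_orf_mats, folds_per_orf):
                    f = folds[drug]
                    q = 0.0 if np.isinf(f) else 1.0 / f
                    thinned = thinned + rng.binomial(mat, q)
                emit(tid, drug, rep, rng.binomial(thinned, depth_p[(drug, rep)]))

    # spike-in: identical true abundance, perturbed only by depth
    for cond in CONDITIONS[1:]:
        for rep in reps:
            n = rng.poisson(config.spike_in * depth_p[(cond, rep)])
            pos = rng.integers(0, config.spike_length, size=n)
            emit(SPIKE_ID, cond, rep,
                 _to_length_matrix(rng, pos, config.spike_length, config.noise_length_probs))

    truth.sample_depths = pd.DataFrame(
        [
            {"condition": c, "replicate": r, "depth": depth_p[(c, r)]}
            for c, r in samples
        ]
    )
    if chunks:
        return pd.concat(chunks, ignore_index=True)
    return pd.DataFrame(
        columns=["transcript_id", "position", "condition", "replicate",
                 "read_length", "count"]
    )


# ---------------------------------------------------------------------------
# Fixture bundle IO
# ---------------------------------------------------------------------------

def _layout_genome(
    transcripts: Mapping[str, TranscriptModel], gap: int = 100, intron: int = 50
) -> tuple[str, dict[str, TranscriptModel]]:
    """Place transcripts on one synthetic contig, alternating strands and
    splitting longer transcripts into two exons so splicing is exercised."""
    chrom = "chrS"
    pieces: list[str] = []
    cursor = 0
    for k, (tid, t) in enumerate(transcripts.items()):
        seq = t.sequence
        strand = "+" if k % 2 == 0 else "-"
        gseq = str(Seq.Seq(seq).reverse_complement()) if strand == "-" else seq
        L = len(seq)
        if L > 400:
            half = L // 2
            exon_lens = [half, L - half]
        else:
            exon_lens = [L]
        exons = []
        gpos = cursor
        chunks = []
        # genomic-order exon lengths follow the genomic-strand sequence
        off = 0
        for el in exon_lens:
            exons.append((gpos, gpos + el))
            chunks.append(gseq[off : off + el])
            if len(exon_lens) > 1 and off == 0:
                chunks.append("N" * intron)
                gpos += el + intron
            else:
                gpos += el
            off += el
        pieces.append("".join(chunks))
        pieces.append("N" * gap)
        cursor = gpos + gap
        t.chrom = chrom
        t.strand = strand
        t.exons = exons
    return "".join(pieces), dict(transcripts)


def _transcript_to_genomic(t: TranscriptModel, start: int, end: int) -> list[tuple[int, int]]:
    """Map a transcript-space half-open interval to genomic intervals."""
    positions: list[int] = []
    for s, e in t.exons:
        positions.extend(range(s, e))
    if t.strand == "-":
        positions = positions[::-1]
    sel = sorted(positions[start:end])
    ivals: list[tuple[int, int]] = []
    for p in sel:
        if ivals and p == ivals[-1][1]:
            ivals[-1] = (ivals[-1][0], p + 1)
        else:
            ivals.append((p, p + 1))
    return ivals


def write_fixture_bundle(
    transcripts: Mapping[str, TranscriptModel],
    profiles: pd.DataFrame,
    truth: TruthTable,
    outdir: str | Path,
    config: SimConfig | None = None,
    write_sam: bool = False,
) -> dict[str, Path]:
    """Write FASTA/GTF/TSV (and optionally SAM) files for a synthetic bundle.

    Returns a name -> path map. The SAM file is written in transcript
    coordinate space with read starts placed ``offset`` nt upstream of each
    P-site; reads that would extend past a transcript boundary are skipped
    (their number is stored under the ``sam_skipped`` key).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genome_seq, transcripts = _layout_genome(dict(transcripts))
    paths["transcripts_fasta"] = outdir / "transcripts.fa"
    with open(paths["transcripts_fasta"], "w") as fh:
        for tid, t in transcripts.items():
            fh.write(f">{tid}\n")
            for i in range(0, len(t.sequence), 80):
                fh.write(t.sequence[i : i + 80] + "\n")

    paths["genome_fasta"] = outdir / "genome.fa"
    with open(paths["genome_fasta"], "w") as fh:
        fh.write(">chrS\n")
        for i in range(0, len(genome_seq), 80):
            fh.write(genome_seq[i : i + 80] + "\n")

    biotype_out = {
        BIOTYPE_CODING: "protein_coding",
        BIOTYPE_LNCRNA: "lncRNA",
        BIOTYPE_SNORNA: "snoRNA",
    }
    paths["gtf"] = outdir / "annotation.gtf"
    with open(paths["gtf"], "w") as fh:
        for tid, t in transcripts.items():
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{tid}"; '
                f'transcript_biotype "{biotype_out.get(t.biotype, t.biotype)}"; '
                f'annotated "True"; start_annotated "True"; stop_annotated "True";'
            )
            span = (min(s for s, _ in t.exons), max(e for _, e in t.exons))
            for feature, (s, e) in [("gene", span), ("transcript", span)]:
                fh.write(
                    f"{t.chrom}\tribodrug_sim\t{feature}\t{s + 1}\t{e}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tribodrug_sim\texon\t{s + 1}\t{e}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
            if t.is_coding:
                # CDS features conventionally exclude the stop codon
                for s, e in _transcript_to_genomic(t, t.cds_start, t.cds_stop - 3):
                    fh.write(
                        f"{t.chrom}\tribodrug_sim\tCDS\t{s + 1}\t{e}\t.\t"
                        f"{t.strand}\t0\t{attrs}\n"
                    )

    paths["profiles"] = outdir / "profiles.tsv"
    profiles.to_csv(paths["profiles"], sep="\t", index=False)
    paths["truth_transcripts"] = outdir / "truth_transcripts.tsv"
    truth.transcripts.to_csv(paths["truth_transcripts"], sep="\t", index=False)
    paths["truth_orfs"] = outdir / "truth_orfs.tsv"
    truth.orfs.to_csv(paths["truth_orfs"], sep="\t", index=False)
    if truth.sample_depths is not None:
        paths["sample_depths"] = outdir / "truth_sample_depths.tsv"
        truth.sample_depths.to_csv(paths["sample_depths"], sep="\t", index=False)
    if config is not None:
        paths["config"] = outdir / "sim_config.json"
        paths["config"].write_text(config.to_json())

    if write_sam:
        offsets = (config or SimConfig()).psite_offsets
        paths["sam"], paths["sam_skipped"] = _write_sam(
            transcripts, profiles, offsets, outdir / "reads.sam"
        )
    return paths


def _write_sam(
    transcripts: Mapping[str, TranscriptModel],
    profiles: pd.DataFrame,
    offsets: Mapping[int, int],
    path: Path,
) -> tuple[Path, int]:
    import pysam

    lengths = {tid: len(t) for tid, t in transcripts.items()}
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": tid, "LN": lengths[tid]} for tid in transcripts],
    }
    footprint = profiles[
        (profiles.condition != "transcriptome") & (profiles.transcript_id != SPIKE_ID)
    ]
    skipped = 0
    n_read = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in footprint.itertuples():
            tid = row.transcript_id
            length = int(row.read_length)
            start = int(row.position) - offsets[length]
            if start < 0 or start + length > lengths[tid]:
                skipped += int(row.count)
                continue
            seq = transcripts[tid].sequence[start : start + length]
            for _ in range(int(row.count)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"sim_{row.condition}_{row.replicate}_{n_read}"
                a.query_sequence = seq
                a.flag = 0
                a.reference_id = out.header.get_tid(tid)
                a.reference_start = start
                a.mapping_quality = 30
                a.cigarstring = f"{length}M"
                a.set_tag("NH", 1)
                a.set_tag("MD", str(length))
                a.set_tag("XC", row.condition)
                a.set_tag("XR", int(row.replicate))
                out.write(a)
                n_read += 1
    return path, skipped
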