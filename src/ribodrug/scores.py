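"""Per-ORF translation statistics.

Implements the translation-efficiency (TE) score, the ribosome-release (RR)
score in both orientations and 3'UTR dialects, the signed codon-phasing ORF
score, the FLOSS read-length-distribution score, a Kozak-context position
weight matrix score, the drug-resistant footprint fraction, start-codon
footprint accumulation and the relative per-codon footprint density used to
probe 5'UTR start-site usage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transcripts import ORFRecord, START_AUG

FLOSS_MIN, FLOSS_MAX = 26, 34  # FLOSS compares match lengths 26-34 nt

# Kozak position weight matrix; columns -5..-1 then +3, +4 relative to the A
# of the AUG (the AUG itself contributes 0).
KOZAK_POSITIONS = (-5, -4, -3, -2, -1, 3, 4)
KOZAK_MATRIX = {
    "A": (-15.22, -14.01, 100.06, 18.89, -17.78, 15.78, 28.55),
    "T": (20.47, -16.47, -34.47, -21.26, -28.30, -21.26, -27.47),
    "G": (-11.22, -21.99, 31.86, -17.78, -15.22, 43.86, -15.84),
    "C": (17.33, 75.54, -30.00, 52.81, 100.06, -13.43, 50.99),
}
KOZAK_MAX = sum(
    max(KOZAK_MATRIX[b][i] for b in KOZAK_MATRIX) for i in range(len(KOZAK_POSITIONS))
)


@dataclass(frozen=True)
class RegionCounts:
    """The four RR-score inputs (whole-transcriptome and footprint reads on
    the ORF/CDS and on its downstream 3'UTR window)."""

    reads_cds_wt: float
    reads_utr3_wt: float
    reads_cds_ribo: float
    reads_utr3_ribo: float

    def __post_init__(self):
        for v in (self.reads_cds_wt, self.reads_utr3_wt,
                  self.reads_cds_ribo, self.reads_utr3_ribo):
            if v < 0:
                raise ValueError("region counts must be non-negative")


def te_score(orf_footprints: float, scaled_transcriptome_reads: float) -> float:
    """Control footprints divided by (scaled) whole-transcriptome reads."""
    if scaled_transcriptome_reads <= 0:
        return np.nan
    return orf_footprints / scaled_transcriptome_reads


def utr3_window(
    seq: str, stop_end: int, dialect: str = "to-first-AUG"
) -> tuple[int, int]:
    """3'UTR window for the RR score: from the nucleotide after the stop
    codon to the nucleotide before the first downstream AUG (any frame), or
    the transcript end — or the entire 3'UTR under the ``full-3'UTR``
    dialect."""
    if dialect == "full-3'UTR":
        return (stop_end, len(seq))
    if dialect != "to-first-AUG":
        raise ValueError(f"unknown RR dialect {dialect!r}")
    idx = seq.find(START_AUG, stop_end)
    return (stop_end, idx if idx >= 0 else len(seq))


def rr_score(
    rc: RegionCounts,
    orientation: str = "coding-high",
    pseudocount: float = 1.0,
) -> float:
    """Ribosome-release score.

    ``as-printed`` computes (CDS_wt/UTR3_wt) / (CDS_ribo/UTR3_ribo);
    ``coding-high`` its reciprocal, so that higher means more coding-like.
    A pseudocount keeps the quotient defined when 3'UTR footprints are zero
    (the norm for coding transcripts).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    a = rc.reads_cds_wt + pseudocount
    b = rc.reads_utr3_wt + pseudocount
    c = rc.reads_cds_ribo + pseudocount
    d = rc.reads_utr3_ribo + pseudocount
    if min(a, b, c, d) <= 0:
        raise ValueError("zero region count after pseudocount")
    printed = (a / b) / (c / d)
    if orientation == "as-printed":
        return printed
    if orientation == "coding-high":
        return 1.0 / printed
    raise ValueError(f"unknown orientation {orientation!r}")


def codon_phase_counts(
    orf_counts: np.ndarray, exclusion_fraction: float = 0.7
) -> np.ndarray:
    """Summed footprints on codon positions 1..3 of an ORF.

    ``orf_counts`` is the count vector over the ORF (stop included, length a
    multiple of 3). Codons accumulating more than ``exclusion_fraction`` of
    the ORF's footprints are ignored before summation.
    """
    v = np.asarray(orf_counts, dtype=float)
    if v.size % 3:
        raise ValueError("ORF count vector length must be a multiple of 3")
    codons = v.reshape(-1, 3)
    total = codons.sum()
    if total > 0:
        codons = codons[codons.sum(axis=1) <= exclusion_fraction * total]
    return codons.sum(axis=0)


def orf_score(phase_counts: np.ndarray) -> float:
    """Signed log2 chi-square statistic of the codon-position distribution.

    ``log2(sum((Fi - Fbar)^2 / Fbar) + 1)``, negated when position 1 or 3
    outnumbers position 2 (the expected mode once footprints are assigned to
    the center nucleotide of the codon). All-zero counts score 0.
    """
    f = np.asarray(phase_counts, dtype=float)
    if f.shape != (3,):
        raise ValueError("expected counts for the 3 codon positions")
    fbar = f.mean()
    if fbar == 0:
        return 0.0
    chi2 = float(((f - fbar) ** 2 / fbar).sum())
    sign = -1.0 if (f[0] > f[1] or f[2] > f[1]) else 1.0
    return sign * float(np.log2(chi2 + 1.0))


def orf_score_from_profile(orf_counts: np.ndarray) -> float:
    return orf_score(codon_phase_counts(orf_counts))


def floss_reference(cds_hists) -> np.ndarray:
    """Aggregate read-length fractions over 26-34 nt across CDS footprints.

    ``cds_hists`` iterates over per-CDS read-length count arrays indexed from
    26 nt (at least 9 entries each).
    """
    total = None
    for h in cds_hists:
        h = np.asarray(h, dtype=float)[: FLOSS_MAX - FLOSS_MIN + 1]
        total = h if total is None else total + h
    if total is None or total.sum() <= 0:
        raise ValueError("no CDS footprints to build a FLOSS reference")
    return total / total.sum()


def floss_score(orf_hist: np.ndarray, reference: np.ndarray) -> float:
    """Half the L1 distance between two read-length distributions in [0, 1];
    lower is more coding-like."""
    f = np.asarray(orf_hist, dtype=float)[: FLOSS_MAX - FLOSS_MIN + 1]
    r = np.asarray(reference, dtype=float)[: FLOSS_MAX - FLOSS_MIN + 1]
    for name, x in (("orf", f), ("reference", r)):
        if not np.isclose(x.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{name} length distribution is not normalized")
    return 0.5 * float(np.abs(f - r).sum())


def normalize_length_hist(hist: np.ndarray) -> np.ndarray | None:
    """Restrict a 26-36 histogram to the FLOSS 26-34 support and normalize;
    None when empty."""
    h = np.asarray(hist, dtype=float)[: FLOSS_MAX - FLOSS_MIN + 1]
    s = h.sum()
    return h / s if s > 0 else None


def kozak_context(seq: str, start: int) -> str:
    """10-nt context (-5..+4) around an AUG at ``start``; off-transcript
    positions are padded with N (scored 0)."""
    left = seq[max(start - 5, 0) : start]
    left = "N" * (5 - len(left)) + left
    right = seq[start + 3 : start + 5]
    right = right + "N" * (2 - len(right))
    return left + seq[start : start + 3] + right


def kozak_score(context: str) -> float:
    """Kozak consensus position-weight-matrix score of a start-codon context.

    ``context`` covers positions -5..+4 with the AUG at index 5..7 (an 11-nt
    -5..+5 window is accepted; +5 carries no weight). N positions score 0.
    """
    ctx = context.upper().replace("U", "T")
    if len(ctx) not in (10, 11):
        raise ValueError("context must cover positions -5..+4 around the AUG")
    if ctx[5:8] != START_AUG:
        raise ValueError("context is not centered on an AUG")
    flanks = ctx[0:5] + ctx[8:10]
    return float(
        sum(
            KOZAK_MATRIX[b][i] if b in KOZAK_MATRIX else 0.0
            for i, b in enumerate(flanks)
        )
    )


def drug_resistance(
    control_norm: float, drug_norm: float, fold_cap: float = 1000.0
) -> tuple[float, float]:
    """(resistant fraction, fold inhibition) from spike-normalized counts.

    The resistant fraction is drug/control; the fold inhibition its
    reciprocal, censored at ``fold_cap`` when the drug count is zero.
    Undefined (NaN, NaN) when the control count is zero.
    """
    if control_norm <= 0:
        return (np.nan, np.nan)
    fraction = drug_norm / control_norm
    fold = min(control_norm / drug_norm if drug_norm > 0 else np.inf, fold_cap)
    return (fraction, fold)


def start_codon_accumulation(profile: np.ndarray, orf: ORFRecord) -> float:
    """Footprints per nt on the start codon +/- 1 nt over footprints per nt
    on the entire ORF; > 1 indicates pileup, > 10 flags a stalled start."""
    if orf.stop_end is None:
        raise ValueError("open-ended ORF")
    v = np.asarray(profile, dtype=float)
    orf_total = v[orf.start : orf.stop_end].sum()
    if orf_total <= 0:
        return np.nan
    lo = max(orf.start - 1, 0)
    start_counts = v[lo : orf.start + 2].sum()
    return (start_counts / 3.0) / (orf_total / orf.nt_length)


def relative_codon_density(
    utr_profile: np.ndarray, utr_seq: str, codon: str
) -> float:
    """Center-nucleotide footprint density of one codon relative to all
    codons of a 5'UTR (all three forward frames)."""
    v = np.asarray(utr_profile, dtype=float)
    codon = codon.upper().replace("U", "T")
    if len(utr_seq) != v.size:
        raise ValueError("profile and sequence lengths differ")
    if v.size < 3:
        return np.nan
    centers = [i + 1 for i in range(v.size - 2) if utr_seq[i : i + 3] == codon]
    if not centers:
        return np.nan
    all_mean = v[1 : v.size - 1].mean()
    if all_mean <= 0:
        return np.nan
    return float(v[centers].mean() / all_mean)
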