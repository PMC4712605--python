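"""Translation-status decisions.

Turns the per-ORF score table into calls: the four-way lncRNA categories
(low footprint density / too few footprints / translated / not supported),
the stringent uORF selection, quantile-threshold coding classification of
score distributions, and an expression-matched bootstrap that samples coding
transcripts to the lncRNA expression distribution.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LNC_CATEGORIES = (
    "low_density", "insufficient_footprints", "translated", "not_supported",
)

# printed thresholds of the study, used as defaults throughout
TE_THRESHOLD = 0.1
MIN_TRANSCRIPTOME_READS = 20
MIN_FOOTPRINTS = 4
MIN_ORF_FOOTPRINT_SHARE = 0.10
PATA_FOLD = 4.0
HARR_FOLD = 2.0
UORF_MIN_START_COUNTS = 8
UORF_MIN_FOOTPRINTS = 20
UORF_PATA_FOLD = 3.0

_CRITERIA = {
    "pata": ["fold_pata"],
    "harr": ["fold_harringtonine"],
    "both": ["fold_pata", "fold_harringtonine"],
}


def _drug_pass(row, criterion: str) -> bool:
    if criterion == "pata":
        return row.fold_pata >= PATA_FOLD
    if criterion == "harr":
        return row.fold_harringtonine >= HARR_FOLD
    if criterion == "both":
        return row.fold_pata >= PATA_FOLD and row.fold_harringtonine >= HARR_FOLD
    raise ValueError(f"unknown criterion {criterion!r}")


def classify_lncrna(orf_rows: pd.DataFrame, criterion: str = "pata") -> str | None:
    """Category of one noncoding transcript from its per-ORF scores.

    Only transcripts with at least one ORF carrying >= 20 transcriptome
    reads qualify (returns None otherwise); an ORF is considered only when
    it holds >= 10 % of the transcript's footprints. Categories, in order:
    ``low_density`` when no considered ORF exceeds TE 0.1; then
    ``insufficient_footprints`` when none of the TE-passing ORFs reaches 4
    footprints; then ``translated`` when any remaining ORF is blocked >= 4
    fold by DMDA-PatA (criterion ``pata``), >= 2 fold by harringtonine
    (``harr``), or both (``both``); else ``not_supported``.
    """
    needed = _CRITERIA.get(criterion)
    if needed is None:
        raise ValueError(f"unknown criterion {criterion!r}")
    for col in needed:
        if col not in orf_rows.columns:
            raise ValueError(f"criterion {criterion!r} needs column {col}")

    if not (orf_rows.transcriptome_reads >= MIN_TRANSCRIPTOME_READS).any():
        return None
    considered = orf_rows[
        orf_rows.frac_transcript_footprints.fillna(0.0) >= MIN_ORF_FOOTPRINT_SHARE
    ]
    te_pass = considered[considered.te.fillna(0.0) > TE_THRESHOLD]
    if te_pass.empty:
        return "low_density"
    covered = te_pass[te_pass.footprints >= MIN_FOOTPRINTS]
    if covered.empty:
        return "insufficient_footprints"
    if any(_drug_pass(row, criterion) for row in covered.itertuples()):
        return "translated"
    return "not_supported"


def classify_lncrna_table(
    score_table: pd.DataFrame, criterion: str = "pata",
    biotypes: Iterable[str] = ("lncRNA",),
) -> pd.DataFrame:
    """Apply :func:`classify_lncrna` per transcript; one row per qualifying
    transcript."""
    for col in _CRITERIA[criterion] if criterion in _CRITERIA else ():
        if col not in score_table.columns or score_table[col].isna().all():
            raise ValueError(f"drug condition for {criterion!r} is missing")
    rows = []
    sub = score_table[score_table.biotype.isin(set(biotypes))]
    for tid, orfs in sub.groupby("transcript_id"):
        cat = classify_lncrna(orfs, criterion)
        if cat is None:
            continue
        rows.append({"transcript_id": tid, "category": cat, "criterion": criterion})
    return pd.DataFrame(rows, columns=["transcript_id", "category", "criterion"])


def select_translated_uorfs(uorf_rows: pd.DataFrame) -> pd.DataFrame:
    """Stringent uORF selection: >= 8 footprints on the start codon +/- 1 nt,
    >= 20 on the entire ORF, and >= 3-fold DMDA-PatA inhibition (all
    boundaries inclusive)."""
    mask = (
        (uorf_rows.start_counts >= UORF_MIN_START_COUNTS)
        & (uorf_rows.footprints >= UORF_MIN_FOOTPRINTS)
        & (uorf_rows.fold_pata >= UORF_PATA_FOLD)
    )
    return uorf_rows[mask.fillna(False)]


def quantile_classify(
    scores_coding: Sequence[float],
    scores_reference_nc: Sequence[float],
    higher_is_coding: bool = True,
) -> tuple[float, float]:
    """Fractions of each group classified as coding by cross-quantile
    thresholds.

    Coding members with a score better than the 10 % best-scoring reference
    noncoding RNAs count as coding; noncoding members with a score better
    than the 10 % worst-scoring coding RNAs count as coding. Returns
    ``(fraction of coding called coding, fraction of noncoding called
    coding)``.
    """
    coding = np.asarray(scores_coding, dtype=float)
    nc = np.asarray(scores_reference_nc, dtype=float)
    if coding.size == 0 or nc.size == 0:
        raise ValueError("both score sets must be non-empty")
    if not higher_is_coding:
        coding, nc = -coding, -nc
    coding_threshold = np.quantile(nc, 0.9)  # boundary of the 10% best nc
    nc_threshold = np.quantile(coding, 0.1)  # boundary of the 10% worst coding
    frac_coding = float((coding > coding_threshold).mean())
    frac_nc = float((nc > nc_threshold).mean())
    return frac_coding, frac_nc


def expression_matched_bootstrap(
    coding_reads: pd.Series,
    lncrna_orf_reads: Sequence[float],
    n_bins: int = 100,
    n_samples: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Sample coding transcripts to the lncRNA expression distribution.

    The lncRNA ORF whole-transcriptome read counts are divided into
    ``n_bins`` equal-occupancy (quantile) bins; each bin's sampling
    probability is its lncRNA density. Every bootstrap sample draws as many
    coding transcripts (with replacement, bin-wise) as there are lncRNA
    ORFs. A populated lncRNA bin with no coding candidate falls back to the
    nearest populated bin (logged). Returns ``n_samples`` index arrays into
    ``coding_reads``.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    coding = pd.Series(coding_reads, dtype=float)
    lnc = np.asarray(lncrna_orf_reads, dtype=float)
    if coding.empty or lnc.size == 0:
        raise ValueError("empty input distributions")

    edges = np.quantile(lnc, np.linspace(0, 1, n_bins + 1))
    lnc_bin = np.clip(np.searchsorted(edges, lnc, side="right") - 1, 0, n_bins - 1)
    bin_probs = np.bincount(lnc_bin, minlength=n_bins).astype(float)
    bin_probs /= bin_probs.sum()
    cvals = coding.to_numpy()
    in_range = (cvals >= edges[0]) & (cvals <= edges[-1])
    coding_bin = np.where(
        in_range,
        np.clip(np.searchsorted(edges, cvals, side="right") - 1, 0, n_bins - 1),
        -1,  # coding transcripts outside the lncRNA range are never sampled
    )
    members = [np.flatnonzero(coding_bin == b) for b in range(n_bins)]

    populated = [b for b in range(n_bins) if members[b].size]
    if not populated:
        raise ValueError("no coding transcripts fall into any lncRNA bin")
    remap = {}
    for b in range(n_bins):
        if members[b].size:
            remap[b] = b
        else:
            remap[b] = min(populated, key=lambda p: abs(p - b))
            if bin_probs[b] > 0:
                logger.info(
                    "lncRNA bin %d has no coding candidates; using bin %d",
                    b, remap[b],
                )

    size = lnc.size
    samples = []
    for _ in range(n_samples):
        bins = rng.choice(n_bins, size=size, p=bin_probs)
        idx = np.array(
            [members[remap[b]][rng.integers(members[remap[b]].size)] for b in bins]
        )
        samples.append(idx)
    return samples


def apply_figure_filters(score_table: pd.DataFrame, filter_set: str) -> pd.DataFrame:
    """Named row-filter sets used for the standard analyses.

    ``well_expressed``: >= 100 transcriptome reads and >= 100 footprints
    (the whole-transcript drug-response comparisons);
    ``expressed_orfs``: >= 20 transcriptome reads and more than 4
    footprints, plus the 10 % footprint-share rule for ORFs on noncoding
    transcripts (score benchmarking and lncRNA categories);
    ``covered_orfs``: >= 20 footprints on the ORF (uORF drug-response
    curves; 5'UTR aggregates additionally clip the last 10 nt of the UTR);
    ``detected_transcripts``: > 8.5 mean transcriptome reads (the Kozak
    background set).
    """
    df = score_table
    if filter_set == "well_expressed":
        return df[(df.transcriptome_reads >= 100) & (df.footprints >= 100)]
    if filter_set == "expressed_orfs":
        out = df[(df.transcriptome_reads >= 20) & (df.footprints > 4)]
        if "biotype" in out.columns and "frac_transcript_footprints" in out.columns:
            noncoding = out.biotype != "coding"
            out = out[
                ~noncoding
                | (out.frac_transcript_footprints.fillna(0.0) >= MIN_ORF_FOOTPRINT_SHARE)
            ]
        return out
    if filter_set == "covered_orfs":
        return df[df.footprints >= 20]
    if filter_set == "detected_transcripts":
        return df[df.transcriptome_reads > 8.5]
    raise ValueError(f"unknown filter set {filter_set!r}")
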