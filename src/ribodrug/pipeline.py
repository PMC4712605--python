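"""End-to-end orchestration: bundle loading, normalization, score tables.

The score table is the central product: one row per ORF with all per-ORF
statistics, drug-resistant fractions and the raw filter inputs, from which
the classification and report stages are thin selections.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import normalize as norm
from . import scores as sc
from .profiles import ProfileSet
from .simulate import DRUGS, SPIKE_ID, TruthTable
from .transcripts import (
    ORFRecord,
    START_AUG,
    START_CUG,
    TranscriptModel,
    enumerate_orfs,
    load_transcripts,
)

FLOSS_MIN_CDS_FOOTPRINTS = 100.0


def load_bundle(bundle_dir: str | Path):
    """Load a fixture bundle directory -> (transcripts, profiles, truth)."""
    d = Path(bundle_dir)
    transcripts = load_transcripts(
        d / "annotation.gtf", transcript_fasta=d / "transcripts.fa"
    )
    lengths = {tid: len(t) for tid, t in transcripts.items()}
    df = pd.read_csv(d / "profiles.tsv", sep="\t")
    spike = df[df.transcript_id == SPIKE_ID]
    if len(spike):
        lengths[SPIKE_ID] = int(spike.position.max()) + 1
    profiles = ProfileSet(df, lengths)
    truth = None
    if (d / "truth_orfs.tsv").exists():
        depths = None
        if (d / "truth_sample_depths.tsv").exists():
            depths = pd.read_csv(d / "truth_sample_depths.tsv", sep="\t")
        truth = TruthTable(
            transcripts=pd.read_csv(d / "truth_transcripts.tsv", sep="\t"),
            orfs=pd.read_csv(d / "truth_orfs.tsv", sep="\t"),
            sample_depths=depths,
        )
    return transcripts, profiles, truth


def normalize_bundle(
    profiles: ProfileSet, use_spike: bool = True
) -> tuple[ProfileSet, pd.Series]:
    """Spike-normalize footprint samples; median-of-ratios for transcriptome
    replicates. With ``use_spike=False`` (no spike-in available) footprint
    samples fall back to library-size factors instead."""
    factors: dict[tuple[str, int], float] = {}
    if use_spike:
        _, spike_f = norm.spike_normalize(profiles)
        factors.update(dict(spike_f.items()))
    else:
        ribo = [c for c in profiles.conditions if c != "transcriptome"]
        factors.update(dict(norm.library_size_factors(profiles, ribo).items()))
    if "transcriptome" in profiles.conditions and profiles.n_replicates("transcriptome") > 1:
        factors.update(dict(norm.transcriptome_replicate_factors(profiles).items()))
    series = pd.Series(factors, name="size_factor")
    return profiles.scaled(factors), series


def default_orfs(
    transcripts: Mapping[str, TranscriptModel],
    uorf_starts: Sequence[str] = (START_AUG, START_CUG),
    nc_starts: Sequence[str] = (START_AUG,),
) -> list[ORFRecord]:
    """Annotated CDSs, AUG/CUG uORFs in coding 5'UTRs, and AUG ORFs on
    noncoding transcripts (open-ended ORFs are skipped)."""
    out: list[ORFRecord] = []
    for tid, t in transcripts.items():
        if t.is_coding:
            out.append(t.cds_orf())
            out.extend(
                o
                for o in enumerate_orfs(
                    t.sequence,
                    start_classes=uorf_starts,
                    region_bounds=(0, t.cds_start),
                    cds_start=t.cds_start,
                    transcript_id=tid,
                )
                if o.has_stop
            )
        else:
            out.extend(
                o
                for o in enumerate_orfs(
                    t.sequence, start_classes=nc_starts, transcript_id=tid
                )
                if o.has_stop
            )
    return out


def orfs_from_table(table: pd.DataFrame) -> list[ORFRecord]:
    """ORF records from a truth (or score) table."""
    return [
        ORFRecord(
            transcript_id=r.transcript_id,
            start=int(r.start),
            stop_end=int(r.stop_end),
            start_class=r.start_class,
            frame=int(r.start) % 3,
            region=r.region,
        )
        for r in table.itertuples()
    ]


def build_score_table(
    transcripts: Mapping[str, TranscriptModel],
    profiles: ProfileSet,
    orfs: Iterable[ORFRecord] | None = None,
    rr_dialect: str = "to-first-AUG",
    rr_pseudocount: float = 1.0,
    fold_cap: float = 1000.0,
) -> pd.DataFrame:
    """Compute every per-ORF statistic on (normalized) profiles.

    ``profiles`` should already be size-factor normalized; drug columns are
    NaN when a condition is absent from the data.
    """
    if orfs is None:
        orfs = default_orfs(transcripts)
    conditions = set(profiles.conditions)
    have_wt = "transcriptome" in conditions
    drugs = [d for d in DRUGS if d in conditions]

    # transcriptome scaled to the control footprint total (TE denominator)
    te_scale = 1.0
    if have_wt and "control" in conditions:
        totals = profiles.sample_totals(
            [t for t in profiles.lengths if t != SPIKE_ID]
        ).groupby("condition").mean()
        if totals.get("transcriptome", 0) > 0:
            te_scale = float(totals.get("control", 0) / totals["transcriptome"])

    # FLOSS reference: well-expressed annotated CDSs
    floss_ref = None
    if "control" in conditions:
        hists = []
        for tid, t in transcripts.items():
            if not t.is_coding:
                continue
            if profiles.region_sum(tid, "control", t.cds_start, t.cds_stop) < FLOSS_MIN_CDS_FOOTPRINTS:
                continue
            hists.append(profiles.length_hist(tid, "control", t.cds_start, t.cds_stop))
        if hists:
            floss_ref = sc.floss_reference(hists)

    rows = []
    orfs = sorted(orfs, key=lambda o: (o.transcript_id, o.start))
    current_tid = None
    vecs: dict[str, np.ndarray] = {}
    for orf in orfs:
        tid = orf.transcript_id
        if tid not in transcripts or not orf.has_stop:
            continue
        t = transcripts[tid]
        if tid != current_tid:
            vecs = {c: profiles.vector(tid, c) for c in conditions}
            current_tid = tid
        control = vecs.get("control")
        wt = vecs.get("transcriptome")
        s, e = orf.start, orf.stop_end

        footprints = float(control[s:e].sum()) if control is not None else np.nan
        tx_footprints = float(control.sum()) if control is not None else np.nan
        frac = footprints / tx_footprints if tx_footprints and tx_footprints > 0 else np.nan
        lo = max(s - 1, 0)
        start_counts = float(control[lo : s + 2].sum()) if control is not None else np.nan
        wt_orf = float(wt[s:e].sum()) * te_scale if wt is not None else np.nan
        wt_tx = float(wt.sum()) * te_scale if wt is not None else np.nan

        row = {
            "transcript_id": tid,
            "start": s,
            "stop_end": e,
            "start_class": orf.start_class,
            "region": orf.region,
            "frame": orf.frame,
            "biotype": t.biotype,
            "nt_length": orf.nt_length,
            "transcriptome_reads": wt_orf,
            "transcript_transcriptome_reads": wt_tx,
            "footprints": footprints,
            "transcript_footprints": tx_footprints,
            "frac_transcript_footprints": frac,
            "start_counts": start_counts,
        }
        row["te"] = (
            sc.te_score(footprints, wt_orf)
            if control is not None and wt is not None
            else np.nan
        )
        row["accumulation"] = (
            sc.start_codon_accumulation(control, orf) if control is not None else np.nan
        )
        row["orf_score"] = (
            sc.orf_score_from_profile(control[s:e]) if control is not None else np.nan
        )

        floss = np.nan
        if floss_ref is not None and control is not None:
            h = sc.normalize_length_hist(profiles.length_hist(tid, "control", s, e))
            if h is not None:
                floss = sc.floss_score(h, floss_ref)
        row["floss"] = floss

        if control is not None and wt is not None:
            u3 = sc.utr3_window(t.sequence, e, dialect=rr_dialect)
            rc = sc.RegionCounts(
                reads_cds_wt=float(wt[s:e].sum()),
                reads_utr3_wt=float(wt[u3[0] : u3[1]].sum()),
                reads_cds_ribo=footprints,
                reads_utr3_ribo=float(control[u3[0] : u3[1]].sum()),
            )
            row["rr_coding_high"] = sc.rr_score(rc, "coding-high", rr_pseudocount)
            row["rr_as_printed"] = sc.rr_score(rc, "as-printed", rr_pseudocount)
        else:
            row["rr_coding_high"] = row["rr_as_printed"] = np.nan

        row["kozak"] = (
            sc.kozak_score(sc.kozak_context(t.sequence, s))
            if orf.start_class == START_AUG
            else np.nan
        )

        for drug in DRUGS:
            if drug in drugs and control is not None:
                dv = vecs[drug]
                fraction, fold = sc.drug_resistance(
                    footprints, float(dv[s:e].sum()), fold_cap
                )
            else:
                fraction, fold = np.nan, np.nan
            row[f"resist_{drug}"] = fraction
            row[f"fold_{drug}"] = fold
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_classification(
    class_table: pd.DataFrame, truth: TruthTable
) -> dict[str, float]:
    """Sensitivity/specificity of 'translated' calls against ground truth."""
    truth_tx = truth.transcripts.set_index("transcript_id")["translated"]
    merged = class_table.set_index("transcript_id").join(truth_tx, how="inner")
    called = merged.category == "translated"
    pos = merged.translated.astype(bool)
    sens = float(called[pos].mean()) if pos.any() else np.nan
    spec = float((~called[~pos]).mean()) if (~pos).any() else np.nan
    return {
        "n": int(len(merged)),
        "n_translated_truth": int(pos.sum()),
        "sensitivity": sens,
        "specificity": spec,
    }
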