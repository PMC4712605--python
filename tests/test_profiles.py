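"""Read filtering, metagene calibration and P-site projection."""

import numpy as np
import pandas as pd
import pysam
import pytest

from ribodrug.profiles import (
    CalibrationError,
    Metagene,
    ProfileSet,
    build_metagene,
    calibrate_psite_offsets,
    filter_alignment,
    project_reads,
    read_offsets,
    read_starts_from_sam,
    write_offsets,
)
from ribodrug.simulate import DEFAULT_PSITE_OFFSETS, READ_LENGTHS
from ribodrug.transcripts import TranscriptModel


def _record(length=30, mapq=30, nh=1, md=None, flag=0, start=100):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "tx1", "LN": 2000}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = "r"
    a.query_sequence = "A" * length
    a.flag = flag
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigarstring = f"{length}M"
    a.set_tag("NH", nh)
    a.set_tag("MD", md if md is not None else str(length))
    return a


class TestFilterAlignment:
    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            (dict(length=25), "length"),
            (dict(length=37), "length"),
            (dict(mapq=9), "quality"),
            (dict(nh=2), "multimapped"),
            (dict(flag=0x100), "multimapped"),
            (dict(md="0A29"), "leading_mismatch"),
            (dict(flag=0x4), "unmapped"),
        ],
    )
    def test_rejections(self, kwargs, reason):
        ok, got = filter_alignment(_record(**kwargs))
        assert not ok and got == reason

    def test_accepts_clean_read(self):
        ok, reason = filter_alignment(_record())
        assert ok and reason == "ok"

    def test_leading_mismatch_reverse_strand(self):
        # on a reverse read the 5' base is the last aligned base
        rec = _record(md="29A0", flag=0x10)
        ok, reason = filter_alignment(rec)
        assert not ok and reason == "leading_mismatch"
        # same MD on a forward read: trailing mismatch, acceptable
        ok, _ = filter_alignment(_record(md="29A0"))
        assert ok

    def test_internal_mismatch_accepted(self):
        ok, _ = filter_alignment(_record(md="10A19"))
        assert ok


def _coding_tx(tid="tx", utr5=40, cds_codons=40, utr3=30):
    seq = "C" * utr5 + "ATG" + "GCT" * (cds_codons - 2) + "TAA" + "G" * utr3
    return TranscriptModel(
        transcript_id=tid, gene_id="g", biotype="coding", sequence=seq,
        cds_start=utr5, cds_stop=utr5 + 3 * cds_codons,
    )


def _starts_df(rows):
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "position", "condition", "replicate",
                 "read_length", "count"],
    )


class TestMetagene:
    def test_single_offset_gives_single_peak(self):
        t = _coding_tx()
        rows = [("tx", t.cds_start - 12, "control", 1, 28, 50)]
        meta = build_metagene(_starts_df(rows), {"tx": t}, window=20)
        assert meta.combined().argmax() == -12 + meta.window
        assert meta.n_transcripts == 1

    def test_empty_profile_set_is_zero_matrix(self):
        t = _coding_tx()
        meta = build_metagene(_starts_df([]), {"tx": t}, window=20)
        assert meta.matrix.sum() == 0

    def test_top_n_restriction(self):
        ts = {f"t{i}": _coding_tx(f"t{i}") for i in range(5)}
        rows = [(f"t{i}", ts[f"t{i}"].cds_start + 3, "control", 1, 30, 10 * (i + 1))
                for i in range(5)]
        meta = build_metagene(_starts_df(rows), ts, window=10, top_n=2)
        assert meta.n_transcripts == 2
        # only the two densest transcripts contribute
        assert meta.combined().sum() == 40 + 50


class TestCalibration:
    def _meta(self, per_length, window=20):
        matrix = np.zeros((len(READ_LENGTHS), 2 * window + 1))
        for length, cells in per_length.items():
            for pos, c in cells.items():
                matrix[length - 26, pos + window] = c
        return Metagene("start", window, matrix, 1)

    def test_known_offsets_recovered(self):
        meta = self._meta({28: {-12: 30, -11: 10}, 30: {-13: 30, -12: 10}})
        offsets = calibrate_psite_offsets(meta)
        assert offsets[28] == 12 and offsets[30] == 13

    def test_tie_broken_toward_smaller_offset(self):
        meta = self._meta({30: {-14: 30, -12: 30}})
        assert calibrate_psite_offsets(meta)[30] == 12

    def test_zero_stratum_imputed_from_global(self):
        meta = self._meta({30: {-13: 100}})
        offsets = calibrate_psite_offsets(meta)
        assert offsets[28] == 13  # inherited from the all-length metagene

    def test_flat_metagene_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_psite_offsets(self._meta({}))

    def test_phase_mass_resolves_pileup_ambiguity(self):
        # pileup spread over start +/- 1 (5' ends -14,-13,-12 for offset 13)
        # with downstream signal on codon centers for offset 13
        # body reads with P-site on codon centers (rel. 3k+1) have 5' ends
        # at 3k+1-13: q = 0, 3, 6 ...
        cells = {-14: 20, -13: 20, -12: 20, 0: 9, 3: 9, 6: 9}
        meta = self._meta({30: cells})
        assert calibrate_psite_offsets(meta)[30] == 13

    def test_offset_table_round_trip(self, tmp_path):
        offsets = {28: 12, 30: 13}
        write_offsets(offsets, tmp_path / "off.tsv")
        assert read_offsets(tmp_path / "off.tsv") == offsets


class TestProjection:
    def test_projection_arithmetic(self):
        df = _starts_df([("tx", 100, "control", 1, 30, 1)])
        ps, dropped = project_reads(df, {30: 13}, {"tx": 200})
        assert dropped == 0
        assert ps.vector("tx", "control", 1)[113] == 1

    def test_off_transcript_and_unknown_dropped(self):
        df = _starts_df(
            [("tx", 195, "control", 1, 30, 2), ("ghost", 5, "control", 1, 30, 3)]
        )
        ps, dropped = project_reads(df, {30: 13}, {"tx": 200})
        assert dropped == 5
        assert ps.df["count"].sum() == 0

    def test_missing_offset_raises(self):
        df = _starts_df([("tx", 10, "control", 1, 31, 1)])
        with pytest.raises(KeyError):
            project_reads(df, {30: 13}, {"tx": 200})

    def test_conservation_on_bundle(self, small_bundle, small_loaded):
        """Accepted reads = projected counts + dropped counts."""
        outdir, paths = small_bundle
        tx, _, _ = small_loaded
        starts, rejected = read_starts_from_sam(paths["sam"])
        assert not rejected  # the generator writes clean reads
        lengths = {tid: len(t) for tid, t in tx.items()}
        projected, dropped = project_reads(starts, DEFAULT_PSITE_OFFSETS, lengths)
        assert starts["count"].sum() == projected.df["count"].sum() + dropped

    def test_sam_round_trip_reproduces_profiles(self, tmp_path):
        """Projecting the bundle SAM with the true offsets reproduces the
        generator's profile TSV exactly (clean geometry, no noise)."""
        from ribodrug.simulate import (
            SimConfig, generate_transcriptome, simulate_profiles,
            write_fixture_bundle,
        )

        cfg = SimConfig(
            n_coding=6, n_lncrna=0, n_snorna=0, seed=5, noise_rate=0.0,
            aug_uorf_fraction=0.0, cug_uorf_fraction=0.0,
            utr5_median=60, utr3_median=120,
        )
        tx, truth = generate_transcriptome(cfg)
        prof = simulate_profiles(tx, truth, cfg)
        paths = write_fixture_bundle(
            tx, prof, truth, tmp_path / "b", config=cfg, write_sam=True
        )
        assert paths["sam_skipped"] == 0
        starts, _ = read_starts_from_sam(paths["sam"])
        lengths = {tid: len(t) for tid, t in tx.items()}
        projected, dropped = project_reads(starts, cfg.psite_offsets, lengths)
        assert dropped == 0
        key = ["transcript_id", "position", "condition", "replicate", "read_length"]
        orig = prof[(prof.condition != "transcriptome") & (prof.transcript_id != "SPIKEIN")]
        a = orig.groupby(key)["count"].sum()
        b = projected.df.groupby(key)["count"].sum()
        pd.testing.assert_series_equal(a, b.astype(a.dtype))


class TestCalibrationRecoveryFromData:
    def test_recovers_generator_offsets(self, small_bundle, small_loaded):
        _, paths = small_bundle
        tx, _, _ = small_loaded
        starts, _ = read_starts_from_sam(paths["sam"])
        meta = build_metagene(starts, tx)
        offsets = calibrate_psite_offsets(meta)
        assert offsets == {k: int(v) for k, v in DEFAULT_PSITE_OFFSETS.items()}

    def test_projected_mode_is_codon_center(self, small_bundle, small_loaded):
        _, paths = small_bundle
        tx, _, truth = small_loaded
        starts, _ = read_starts_from_sam(paths["sam"])
        offsets = calibrate_psite_offsets(build_metagene(starts, tx))
        lengths = {tid: len(t) for tid, t in tx.items()}
        projected, _ = project_reads(starts, offsets, lengths)
        phase = np.zeros(3)
        for tid, t in tx.items():
            if not t.is_coding:
                continue
            v = projected.vector(tid, "control")
            cds = v[t.cds_start + 6 : t.cds_stop]
            for k in range(3):
                phase[k] += cds[k::3].sum()
        assert phase.argmax() == 1


class TestProfileSet:
    def test_tsv_round_trip(self, small_loaded, small_bundle, small_sim):
        outdir, paths = small_bundle
        tx, profiles, _ = small_loaded
        _, _, prof_df = small_sim
        reloaded = ProfileSet.from_tsv(paths["profiles"], profiles.lengths)
        tid = next(t for t in tx)
        assert np.array_equal(
            reloaded.vector(tid, "control"), profiles.vector(tid, "control")
        )

    def test_length_hist_counts_match_region(self, small_loaded):
        tx, profiles, _ = small_loaded
        tid = next(t for t, m in tx.items() if m.is_coding)
        t = tx[tid]
        hist = profiles.length_hist(tid, "control", t.cds_start, t.cds_stop)
        total = profiles.vector(tid, "control", 1)[t.cds_start : t.cds_stop].sum()
        total += profiles.vector(tid, "control", 2)[t.cds_start : t.cds_stop].sum()
        assert hist.sum() == pytest.approx(total)
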