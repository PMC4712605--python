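"""Size factors and normalization.

Two distinct normalizations mirror the experimental design: whole
transcriptome replicates are normalized inter-replica by median-of-ratios
over all features, while the footprint samples (control and the three drug
conditions) are normalized across conditions on the spike-in alone, so that
drug-resistant fractions are comparable between samples of very different
translational output.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import SPIKE_ID


class NormalizationError(RuntimeError):
    pass


def estimate_size_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (features x samples).

    Per sample, the factor is the median over features of
    ``count / geometric-mean-across-samples``, computed on features with no
    zero count; factors are then re-centered to geometric mean 1. Normalized
    counts are raw counts divided by the factor.
    """
    mat = count_matrix.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise NormalizationError("no feature with nonzero counts in all samples")
    mat = mat[nonzero]
    log_geomean = np.log(mat).mean(axis=1)
    ratios = mat / np.exp(log_geomean)[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=count_matrix.columns, name="size_factor")


def spike_size_factors(spike_counts: Mapping | pd.Series) -> pd.Series:
    """Size factors that equalize the spike-in count across samples."""
    s = pd.Series(dict(spike_counts), dtype=float)
    if (s <= 0).any():
        bad = list(s.index[s <= 0])
        raise NormalizationError(f"zero spike-in count for samples {bad}")
    factors = s / np.exp(np.log(s).mean())
    factors.name = "size_factor"
    return factors


def spike_normalize(profiles, spike_counts: Mapping | pd.Series | None = None):
    """Divide each footprint sample's counts by its spike-derived factor.

    ``profiles`` is a :class:`~ribodrug.profiles.ProfileSet`; spike counts
    default to the totals of the bundled spike-in pseudo transcript. After
    scaling, the spike-in feature has equal counts in every sample.
    Returns ``(normalized ProfileSet, factors)``.
    """
    if spike_counts is None:
        spike_counts = profiles.spike_counts(SPIKE_ID)
        spike_counts = spike_counts[
            spike_counts.index.get_level_values(0) != "transcriptome"
        ]
    if len(spike_counts) == 0:
        raise NormalizationError("no spike-in counts available")
    factors = spike_size_factors(spike_counts)
    return profiles.scaled(dict(factors.items())), factors


def library_size_factors(profiles, conditions=None) -> pd.Series:
    """Total-count factors for spike-free runs. Not the experiment's own
    normalization; opt-in fallback only."""
    totals = profiles.sample_totals()
    if conditions is not None:
        totals = totals[totals.index.get_level_values(0).isin(set(conditions))]
    return spike_size_factors(totals)


def transcriptome_replicate_factors(profiles) -> pd.Series:
    """Inter-replica median-of-ratios factors for the transcriptome samples,
    computed over per-transcript count totals."""
    reps = [r for c, r in profiles.samples() if c == "transcriptome"]
    cols = {}
    for r in reps:
        cols[("transcriptome", r)] = profiles.transcript_totals("transcriptome", r)
    mat = pd.DataFrame(cols).fillna(0.0)
    mat = mat.drop(index=SPIKE_ID, errors="ignore")
    return estimate_size_factors(mat)


def scale_transcriptome_for_te(
    transcriptome_means: pd.Series, ribo_control_means: pd.Series
) -> pd.Series:
    """Scale mean transcriptome counts to the control footprint read total."""
    wt_total = float(transcriptome_means.sum())
    ribo_total = float(ribo_control_means.sum())
    if wt_total <= 0 or ribo_total <= 0:
        raise NormalizationError("cannot scale: zero total reads")
    return transcriptome_means * (ribo_total / wt_total)
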