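"""Exogenous spike-in normalization.

Each ChIP sample carries chromatin from a second species whose read count
tracks immunoprecipitation efficiency and sequencing depth. Scaling each
sample's target-genome coverage by a factor derived from its spike-in count
makes occupancies comparable across samples and genotypes.

The default convention is reference-to-minimum: within a normalization group
(one modality), ``factor_i = min_j(spikein_j) / spikein_i``, so the sample
with the fewest spike-in fragments keeps factor 1 and every other sample is
scaled down. Alternatives (mean reference, fixed reference) are available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from .models import CoverageTrack, ValidationError


class NormalizationError(ValueError):
    """Raised when a sample cannot be spike-in normalized."""


@dataclass(frozen=True)
class SpikeInStats:
    """Per-sample spike-in bookkeeping and the resulting scale factor."""

    sample_id: str
    target_fragments: int
    spikein_fragments: int
    scale_factor: Optional[float] = None


def count_spikein_fragments(track: CoverageTrack, fragment_length: int = 200) -> int:
    """Fragment count of a spike-in track.

    Uses the recorded ``total_fragments`` when present; otherwise estimates
    area / fragment_length, rounded to the nearest integer. Zero is a legal
    return (downstream normalization rejects it with a named error).
    """
    if track.namespace != "spikein":
        raise ValidationError(
            f"track {track.sample_id!r} has namespace {track.namespace!r}, expected 'spikein'"
        )
    if track.total_fragments is not None:
        return int(track.total_fragments)
    if fragment_length <= 0:
        raise ValidationError("fragment_length must be positive")
    return int(round(track.area() / fragment_length))


def compute_scale_factors(
    stats: List[SpikeInStats], convention: str = "min", reference: Optional[float] = None
) -> List[SpikeInStats]:
    """Compute per-sample scale factors within one normalization group.

    convention:
      * ``min``   — factor_i = min(spikein) / spikein_i (default; factors in (0, 1])
      * ``mean``  — factor_i = mean(spikein) / spikein_i
      * ``fixed`` — factor_i = reference / spikein_i (``reference`` required)
    """
    for s in stats:
        if s.spikein_fragments <= 0:
            raise NormalizationError(
                f"sample {s.sample_id!r} has no spike-in fragments; cannot normalize"
            )
    counts = np.array([s.spikein_fragments for s in stats], dtype=np.float64)
    if convention == "min":
        ref = counts.min()
    elif convention == "mean":
        ref = counts.mean()
    elif convention == "fixed":
        if reference is None or reference <= 0:
            raise NormalizationError("fixed convention requires a positive reference count")
        ref = float(reference)
    else:
        raise NormalizationError(f"unknown normalization convention {convention!r}")
    return [replace(s, scale_factor=float(ref / c)) for s, c in zip(stats, counts)]


def normalize_track(track: CoverageTrack, factor: float) -> CoverageTrack:
    """Multiply every coverage value by ``factor`` (> 0); runs are preserved."""
    if factor <= 0:
        raise NormalizationError(f"scale factor must be positive, got {factor}")
    return track.scaled(factor)


def factors_table(stats: List[SpikeInStats]) -> pd.DataFrame:
    """TSV-ready table of per-sample spike-in counts and factors."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in stats],
            "target_fragments": [s.target_fragments for s in stats],
            "spikein_fragments": [s.spikein_fragments for s in stats],
            "scale_factor": [s.scale_factor for s in stats],
        }
    )
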