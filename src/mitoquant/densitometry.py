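"""Whole-lane total-protein normalization of immunoblot densitometry.

Skeletal-muscle housekeeping proteins vary with the genotypes under study,
so band intensities are normalized to the whole-lane total-protein stain
(Ponceau) rather than a single loading-control band: normalized signal =
band / lane reference, and fold change = normalized / mean(normalized of
the reference group). Background subtraction is assumed already applied
upstream; inputs are per-lane scalars, not gel images.
"""

from __future__ import annotations

import pandas as pd

REQUIRED_COLUMNS = ("sample_id", "group", "band_intensity", "lane_reference")


def normalize_lanes(measurements: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    """Normalize band intensities by whole-lane signal and express fold changes.

    Parameters
    ----------
    measurements
        One row per lane with columns ``sample_id``, ``group``,
        ``band_intensity`` (background-subtracted integrated band intensity,
        >= 0) and ``lane_reference`` (whole-lane Ponceau integrated
        intensity, > 0). Extra columns (e.g. genotype factors) pass through.
    reference_group
        Level of ``group`` whose mean normalized signal defines fold = 1.

    Returns
    -------
    Copy of the input with ``normalized`` (band / lane_reference) and
    ``fold`` (normalized / reference-group mean) columns appended.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in measurements.columns]
    if missing:
        raise ValueError(f"measurements missing columns: {missing}")
    bad = measurements.loc[measurements["lane_reference"] <= 0, "sample_id"].tolist()
    if bad:
        raise ValueError(f"non-positive lane_reference for lanes: {bad}")
    if (measurements["band_intensity"] < 0).any():
        neg = measurements.loc[measurements["band_intensity"] < 0, "sample_id"].tolist()
        raise ValueError(f"negative band_intensity for lanes: {neg}")
    out = measurements.copy()
    out["normalized"] = out["band_intensity"] / out["lane_reference"]
    ref = out.loc[out["group"] == reference_group, "normalized"]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} has no lanes")
    out["fold"] = out["normalized"] / ref.mean()
    return out
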