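"""Regional specific-binding-ratio (SBR) quantification.

SBR for a target region is the unweighted mean activity over the target mask
divided by the mean over the cerebral-white-matter reference mask, minus 1.
Bilateral values use the combined left+right mask (a single pooled mean, not
the average of the per-side ratios), which is robust to unequal mask sizes;
per-side values are always retained for lowest-side classification.  No
partial-volume correction is applied.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .atlas import REFERENCE_REGION, REPORT_REGIONS, RegionAtlas, Volume
from .tables import SbrTable

__all__ = ["compute_sbr", "build_sbr_table"]


def compute_sbr(
    v: Volume,
    atlas: RegionAtlas,
    region: str,
    side: str = "bilateral",
    reference: str = REFERENCE_REGION,
) -> float:
    """SBR = mean(target) / mean(reference) - 1 on a normalized volume."""
    tmask = atlas.mask(region, side)
    rmask = atlas.mask(reference)
    if not tmask.any():
        raise ValueError(f"empty target mask for {region} ({side})")
    if not rmask.any():
        raise ValueError(f"empty reference mask for {reference}")
    ref_mean = float(v.data[rmask].mean())
    if ref_mean <= 0:
        raise ValueError(f"reference mean is not positive ({ref_mean}); SBR undefined")
    return float(v.data[tmask].mean()) / ref_mean - 1.0


def build_sbr_table(
    scans: Iterable[tuple[Volume, Mapping]],
    atlas: RegionAtlas,
    regions: Sequence[str] = REPORT_REGIONS,
    sides: Sequence[str] = ("left", "right", "bilateral"),
    reference: str = REFERENCE_REGION,
) -> SbrTable:
    """Quantify normalized scans into a long-format SBR table.

    ``scans`` yields ``(volume, meta)`` pairs where ``meta`` provides subject,
    tracer, session_years, age and sex.
    """
    rows = []
    for vol, meta in scans:
        for region in regions:
            for side in sides:
                rows.append(
                    {
                        "subject": meta["subject"],
                        "tracer": meta["tracer"],
                        "session_years": float(meta.get("session_years", 0.0)),
                        "age": float(meta["age"]),
                        "sex": int(meta["sex"]),
                        "region": region,
                        "side": side,
                        "value": compute_sbr(vol, atlas, region, side, reference),
                    }
                )
    return SbrTable(pd.DataFrame(rows))
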