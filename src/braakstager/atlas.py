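"""Braak-stage region maps and within-stage SUVR aggregation.

The Braak scheme partitions the cortex into six nested territories that tau
neurofibrillary pathology invades in order: transentorhinal cortex first
(stage I), medial temporal structures (II), then temporal neocortex (III-IV),
association cortices (V) and finally primary sensory cortices (VI).  The
default map below lists the Desikan-Killiany-Tourville regions assigned to
each stage; regional tau-PET SUVRs are averaged within a stage to give one
composite SUVR per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np

N_STAGES = 6

#: Desikan-Killiany-Tourville regions per Braak stage.
DEFAULT_STAGE_REGIONS: Dict[int, List[str]] = {
    1: ["transentorhinal"],
    2: ["entorhinal", "hippocampus"],
    3: ["amygdala", "parahippocampal", "fusiform", "lingual"],
    4: [
        "insula",
        "inferior_temporal",
        "lateral_temporal",
        "posterior_cingulate",
        "inferior_parietal",
    ],
    5: [
        "orbitofrontal",
        "superior_temporal",
        "inferior_frontal",
        "cuneus",
        "anterior_cingulate",
        "supramarginal",
        "lateral_occipital",
        "precuneus",
        "superior_parietal",
        "superior_frontal",
        "rostromedial_frontal",
    ],
    6: ["paracentral", "postcentral", "precentral", "pericalcarine"],
}


@dataclass
class BraakAtlasMap:
    """Mapping from Braak stage (1..6) to named regions, with optional weights.

    Parameters
    ----------
    stage_regions
        Stage index -> list of region labels.  Exactly six stages, each with
        at least one region; a region may belong to only one stage.
    region_weights
        Optional region label -> positive aggregation weight.  Regions absent
        from the mapping get weight 1.  Hemispheres are assumed pre-averaged.
    """

    stage_regions: Dict[int, List[str]] = field(
        default_factory=lambda: {s: list(r) for s, r in DEFAULT_STAGE_REGIONS.items()}
    )
    region_weights: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if sorted(self.stage_regions) != list(range(1, N_STAGES + 1)):
            raise ValueError(
                f"stage_regions must have stages 1..{N_STAGES}, got {sorted(self.stage_regions)}"
            )
        seen: Dict[str, int] = {}
        for stage, regions in self.stage_regions.items():
            if len(regions) == 0:
                raise ValueError(f"stage {stage} has no regions")
            for region in regions:
                if region in seen:
                    raise ValueError(
                        f"region {region!r} appears in stages {seen[region]} and {stage}"
                    )
                seen[region] = stage
        if self.region_weights is not None:
            for region, w in self.region_weights.items():
                if not (w > 0):
                    raise ValueError(f"weight for region {region!r} must be > 0, got {w}")

    @property
    def regions(self) -> List[str]:
        """All region labels in stage order."""
        return [r for s in range(1, N_STAGES + 1) for r in self.stage_regions[s]]

    def weight(self, region: str) -> float:
        if self.region_weights is None:
            return 1.0
        return float(self.region_weights.get(region, 1.0))


def aggregate_stage_suvr(
    region_values: Mapping[str, float], atlas: Optional[BraakAtlasMap] = None
) -> np.ndarray:
    """Collapse per-region SUVRs into the six stage-composite SUVRs.

    The composite for stage *s* is the weighted mean of its regions' SUVRs
    (unit weights by default).

    Parameters
    ----------
    region_values
        Region label -> SUVR; must cover every region in the atlas, all > 0.
    atlas
        Region map; defaults to :data:`DEFAULT_STAGE_REGIONS` with unit weights.

    Returns
    -------
    numpy.ndarray of shape (6,)
    """
    if atlas is None:
        atlas = BraakAtlasMap()
    out = np.empty(N_STAGES, dtype=float)
    for stage in range(1, N_STAGES + 1):
        num = 0.0
        den = 0.0
        for region in atlas.stage_regions[stage]:
            if region not in region_values:
                raise KeyError(f"missing SUVR for region {region!r} (stage {stage})")
            value = float(region_values[region])
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"SUVR for region {region!r} must be finite and > 0, got {value}"
                )
            w = atlas.weight(region)
            num += w * value
            den += w
        out[stage - 1] = num / den
    return out
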