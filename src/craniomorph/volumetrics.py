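"""Per-class tissue volumes and percent-change comparisons.

Volumes are computed by voxel counting (the pipeline's outputs are masks,
so partial-volume modelling would claim precision the inputs don't have):
``volume_cm3 = count * sx*sy*sz / 1000`` exactly.  Percent changes are used
by the robustness harnesses (tilt, defacing, intensity augmentation) to
quantify how much a perturbation moves each tissue volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BinaryMask, LabelMask


@dataclass
class VolumeReport:
    """Per-class volumes inside either the whole grid or the standardized ROI."""

    voxel_counts: dict[str, int]
    volumes_cm3: dict[str, float]
    spacing: tuple[float, float, float]
    roi_mode: str = "whole"  # "whole" | "standardized"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(self.voxel_counts),
                "voxels": list(self.voxel_counts.values()),
                "volume_cm3": [self.volumes_cm3[c] for c in self.voxel_counts],
                "roi_mode": self.roi_mode,
            }
        )


def tissue_volumes(labels: LabelMask, roi_mode: str = "whole") -> VolumeReport:
    """Voxel counts and cm³ for every non-background class.

    Classes absent from the volume report zero.
    """
    sx, sy, sz = labels.spacing
    vox_mm3 = sx * sy * sz
    counts: dict[str, int] = {}
    for value, name in sorted(labels.label_map.items()):
        if value == 0:
            continue
        counts[name] = int(np.count_nonzero(labels.data == value))
    volumes = {name: n * vox_mm3 / 1000.0 for name, n in counts.items()}
    return VolumeReport(
        voxel_counts=counts,
        volumes_cm3=volumes,
        spacing=labels.spacing,
        roi_mode=roi_mode,
    )


def mask_volume_cm3(mask: BinaryMask) -> float:
    """Volume of a binary mask in cm³."""
    sx, sy, sz = mask.spacing
    return mask.count() * sx * sy * sz / 1000.0


def percent_change(test: VolumeReport, reference: VolumeReport) -> pd.DataFrame:
    """Signed percent change and absolute cm³ difference per class.

    ``100 * (test - ref) / ref``.  A class that is empty in both reports
    changes by 0%; a class that appears only in the test report has no
    defined percent change and is flagged ``undefined``.
    """
    if set(test.volumes_cm3) != set(reference.volumes_cm3):
        raise ValueError(
            f"class mismatch: {sorted(test.volumes_cm3)} vs "
            f"{sorted(reference.volumes_cm3)}"
        )
    rows = []
    for name in reference.volumes_cm3:
        ref = reference.volumes_cm3[name]
        tst = test.volumes_cm3[name]
        diff = tst - ref
        if ref == 0:
            pct = 0.0 if tst == 0 else np.nan
            undefined = tst != 0
        else:
            pct = 100.0 * diff / ref
            undefined = False
        rows.append(
            {
                "class": name,
                "reference_cm3": ref,
                "test_cm3": tst,
                "diff_cm3": diff,
                "pct_change": pct,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)
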