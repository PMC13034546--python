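"""Electrode groups used by the searchlight analysis and the default montage.

Five sensor-space regions of interest (10-20 names). The default
simulation montage is the union of the five ROI lists; CPz and Pz — the
centro-parietal positivity (CPP) electrodes — are members of the
Centro-parietal group.
"""

from __future__ import annotations

ROI_MAP: dict[str, tuple[str, ...]] = {
    "Frontal": (
        "AF7", "AF3", "AF4", "AF8", "AFz",
        "F1", "F3", "F5", "F7", "F2", "F4", "F6", "F8", "Fz",
    ),
    "Centro-parietal": ("CP1", "CP2", "CP3", "CP4", "CPz", "Pz"),
    "Lateral-parietal": ("P1", "P3", "P5", "P7", "P9", "P2", "P4", "P6", "P8"),
    "Temporal": ("T7", "T8", "TP7", "TP8"),
    "Occipital": ("O1", "O2", "Oz", "POz", "PO7", "PO3", "PO4", "PO8"),
}

DEFAULT_MONTAGE: tuple[str, ...] = tuple(
    ch for roi in ROI_MAP.values() for ch in roi
)

# Relative CPP ramp projection: strongest at CPz, falling off over the
# neighbouring centro-parietal sites.
CPP_WEIGHTS: dict[str, float] = {
    "CPz": 1.0,
    "Pz": 0.8,
    "CP1": 0.8,
    "CP2": 0.8,
    "CP3": 0.5,
    "CP4": 0.5,
}
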