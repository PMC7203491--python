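"""Canonical brain-region inventory for the cytoarchitectonic GMD analyses.

The analysis family covers 27 cytoarchitectonically defined regions of
interest: 13 subcortical structures (basal forebrain cholinergic nuclei,
amygdala subnuclei, hippocampal subfields, entorhinal cortex and transition
areas) and 14 neocortical areas (motor, auditory, somatosensory, visual and
Broca areas).  Region labels below follow the short names used in the
published MIRIAD reliability tables; the order is the stable canonical order
used everywhere in this package (table rows, simulator output, multiplicity
tie-breaks).
"""

from __future__ import annotations

# (label, description, default healthy-control baseline standardized GMD)
# The baseline densities are simulator defaults on the unitless standardized
# GMD scale: subcortical gray runs denser than neocortex in modulated VBM
# output, so subcortical regions sit near 0.5-0.6 and neocortical regions
# near 0.35-0.5.
_REGION_TABLE: list[tuple[str, str, float]] = [
    ("Ch4", "Cholinergic nucleus 4 of the basal forebrain", 0.52),
    ("Ch123", "Cholinergic nuclei 1-3 of the basal forebrain", 0.50),
    ("CM", "Centromedial amygdala", 0.55),
    ("LB", "Laterobasal amygdala", 0.57),
    ("SF", "Superficial amygdala", 0.56),
    ("ASTR", "Amygdala-striatal transition area", 0.53),
    ("CA1", "Hippocampus area CA1", 0.54),
    ("CA2", "Hippocampus area CA2", 0.52),
    ("CA3", "Hippocampus area CA3", 0.53),
    ("DG", "Dentate gyrus", 0.55),
    ("SUBC", "Subiculum", 0.54),
    ("EC", "Entorhinal cortex", 0.58),
    ("HATA", "Hippocampal-amygdala transition area", 0.55),
    ("Motor 4A", "Primary motor cortex area 4a", 0.42),
    ("Motor 4P", "Primary motor cortex area 4p", 0.43),
    ("TE1.0", "Primary auditory cortex area TE 1.0", 0.48),
    ("TE1.1", "Primary auditory cortex area TE 1.1", 0.47),
    ("TE1.2", "Primary auditory cortex area TE 1.2", 0.48),
    ("TE3.0", "Secondary auditory cortex area TE 3", 0.49),
    ("PSC 1", "Primary somatosensory cortex area 1", 0.40),
    ("PSC 2", "Primary somatosensory cortex area 2", 0.41),
    ("PSC 3a", "Primary somatosensory cortex area 3a", 0.40),
    ("PSC 3b", "Primary somatosensory cortex area 3b", 0.39),
    ("V1", "Occipital cortex area V1", 0.45),
    ("V2", "Occipital cortex area V2", 0.46),
    ("BA44", "Broca's area 44", 0.44),
    ("BA45", "Broca's area 45", 0.44),
]

#: Stable canonical region order.
REGION_NAMES: tuple[str, ...] = tuple(r[0] for r in _REGION_TABLE)

#: Default healthy-control baseline standardized GMD per region.
DEFAULT_BASELINE_GMD: dict[str, float] = {r[0]: r[2] for r in _REGION_TABLE}

#: Human-readable region descriptions.
REGION_DESCRIPTIONS: dict[str, str] = {r[0]: r[1] for r in _REGION_TABLE}

N_REGIONS: int = len(_REGION_TABLE)
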