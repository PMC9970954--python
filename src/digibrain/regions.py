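"""Roster of the 36 regional structural MRI outcomes.

The analysis consumes a per-subject table of atlas-based regional outcomes:
34 head-size-normalized volumes in mL plus two cross-sectional areas in mm²
(corpus callosum, upper cervical cord at C2–C3).  Normalized total brain
volume is carried alongside as the single predictor of the Whole Brain model.

Population means and between-subject coefficients of variation below are
plausible values for an adult early-MS cohort and are only used by the
synthetic cohort generator; real region tables are read as-is from CSV.
Default latent-disability loadings are signed so that more disability means
smaller parenchymal volumes and larger ventricles.
"""

from __future__ import annotations

from dataclasses import dataclass

TOTAL_BRAIN_VOLUME = "Normalized total brain volume"


@dataclass(frozen=True)
class RegionInfo:
    """One regional MRI outcome: name, unit, and generator defaults."""

    name: str
    unit: str            # "mL" or "mm2"
    group: str           # cortical / deep_gm / brainstem_cord / other
    mean: float          # population mean on the region's native scale
    cv: float            # between-subject SD as a fraction of the mean
    loading: float       # default signed latent-disability loading


_CORT = "cortical"
_DEEP = "deep_gm"
_STEM = "brainstem_cord"
_OTHER = "other"

#: The 36 regional outcomes, in roster order.
REGIONS: tuple[RegionInfo, ...] = (
    # Cerebral cortex gray matter (20)
    RegionInfo("Middle frontal", "mL", _CORT, 30.0, 0.08, -0.20),
    RegionInfo("Superior frontal", "mL", _CORT, 45.0, 0.08, -0.25),
    RegionInfo("Lateral and medial orbitofrontal", "mL", _CORT, 25.0, 0.08, -0.20),
    RegionInfo("Precentral", "mL", _CORT, 27.0, 0.08, -0.25),
    RegionInfo("Postcentral", "mL", _CORT, 22.0, 0.08, -0.30),
    RegionInfo("Paracentral", "mL", _CORT, 8.0, 0.09, -0.30),
    RegionInfo("Opercularis, triangularis, orbitalis", "mL", _CORT, 20.0, 0.08, -0.20),
    RegionInfo("Insula", "mL", _CORT, 14.0, 0.07, -0.40),
    RegionInfo("Precuneus", "mL", _CORT, 19.0, 0.08, -0.25),
    RegionInfo("Cuneus, pericalcarine, lingual", "mL", _CORT, 25.0, 0.08, -0.30),
    RegionInfo("Anterior cingulate", "mL", _CORT, 8.0, 0.09, -0.15),
    RegionInfo("Posterior cingulate", "mL", _CORT, 7.0, 0.09, -0.20),
    RegionInfo("Isthmus cingulate", "mL", _CORT, 5.0, 0.10, -0.25),
    RegionInfo("Parahippocampus, fusiform, entorhinal", "mL", _CORT, 22.0, 0.08, -0.25),
    RegionInfo("Superior parietal", "mL", _CORT, 23.0, 0.08, -0.25),
    RegionInfo("Supramarginal", "mL", _CORT, 20.0, 0.08, -0.25),
    RegionInfo("Inferior parietal", "mL", _CORT, 25.0, 0.08, -0.25),
    RegionInfo("Lateral occipital", "mL", _CORT, 23.0, 0.08, -0.45),
    RegionInfo("Inferior and middle temporal", "mL", _CORT, 35.0, 0.08, -0.25),
    RegionInfo("Superior and transverse temporal", "mL", _CORT, 18.0, 0.08, -0.35),
    # Deep gray matter (7)
    RegionInfo("Thalamus", "mL", _DEEP, 15.0, 0.07, -0.50),
    RegionInfo("Hippocampus", "mL", _DEEP, 8.5, 0.08, -0.50),
    RegionInfo("Putamen", "mL", _DEEP, 10.0, 0.08, -0.45),
    RegionInfo("Globus pallidus", "mL", _DEEP, 3.5, 0.09, -0.45),
    RegionInfo("Caudate nucleus", "mL", _DEEP, 7.5, 0.08, -0.40),
    RegionInfo("Amygdala", "mL", _DEEP, 3.2, 0.09, -0.25),
    RegionInfo("Accumbens", "mL", _DEEP, 1.1, 0.10, -0.35),
    # Brainstem and upper cervical cord (4)
    RegionInfo("Midbrain", "mL", _STEM, 6.5, 0.07, -0.25),
    RegionInfo("Pons", "mL", _STEM, 15.0, 0.07, -0.35),
    RegionInfo("Medulla oblongata", "mL", _STEM, 4.5, 0.08, -0.25),
    RegionInfo("Upper cervical cord area", "mm2", _STEM, 72.0, 0.08, -0.35),
    # Other (5)
    RegionInfo("Lateral ventricles", "mL", _OTHER, 25.0, 0.35, 0.50),
    RegionInfo("Cerebral white matter", "mL", _OTHER, 480.0, 0.06, -0.45),
    RegionInfo("Corpus callosum area", "mm2", _OTHER, 620.0, 0.10, -0.40),
    RegionInfo("Cerebellum—hemispheres", "mL", _OTHER, 130.0, 0.07, -0.25),
    RegionInfo("Cerebellum—vermis", "mL", _OTHER, 10.0, 0.09, -0.25),
)

REGION_NAMES: tuple[str, ...] = tuple(r.name for r in REGIONS)
REGION_UNITS: dict[str, str] = {r.name: r.unit for r in REGIONS}

assert len(REGIONS) == 36


def region_info(name: str) -> RegionInfo:
    """Look up a region by its roster name; KeyError on unknown names."""
    for r in REGIONS:
        if r.name == name:
            return r
    raise KeyError(f"unknown MRI region: {name!r}")
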