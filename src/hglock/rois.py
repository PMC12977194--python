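"""Auditory-centric cortical parcellation: 51 regions of interest in 9 groups.

Site metadata arrives with an ROI abbreviation; the group assignment is a
fixed lookup used by every regional analysis.  Group names follow the
hierarchy from core auditory cortex outwards.
"""

from __future__ import annotations

AUDITORY_CORE = "auditory core"
STP = "STP"
STG = "STG"
VENTRAL = "Ventral"
DORSAL = "Dorsal"
LIMBIC = "Limbic"
PREFRONTAL = "Prefrontal"
SENSORIMOTOR = "Sensorimotor"
OTHER = "Other"

ROI_GROUPS: tuple[str, ...] = (
    AUDITORY_CORE, STP, STG, VENTRAL, DORSAL, LIMBIC, PREFRONTAL,
    SENSORIMOTOR, OTHER,
)

#: ROI abbreviation -> (group, full name)
ROI_TABLE: dict[str, tuple[str, str]] = {
    # Auditory core
    "HGPM": (AUDITORY_CORE, "Heschl's gyrus, posteromedial portion"),
    # Superior temporal plane (non-core)
    "HGAL": (STP, "Heschl's gyrus, anterolateral portion"),
    "PP": (STP, "Planum polare"),
    "PT": (STP, "Planum temporale"),
    # Lateral superior temporal gyrus (non-core)
    "STGM": (STG, "Superior temporal gyrus, middle portion"),
    "STGP": (STG, "Superior temporal gyrus, posterior portion"),
    # Ventral stream
    "MTGA": (VENTRAL, "Middle temporal gyrus, anterior portion"),
    "MTGM": (VENTRAL, "Middle temporal gyrus, middle portion"),
    "MTGP": (VENTRAL, "Middle temporal gyrus, posterior portion"),
    "STGA": (VENTRAL, "Superior temporal gyrus, anterior portion"),
    "STSL": (VENTRAL, "Superior temporal sulcus, lower bank"),
    "STSU": (VENTRAL, "Superior temporal sulcus, upper bank"),
    # Dorsal stream
    "AG": (DORSAL, "Angular gyrus"),
    "SMG": (DORSAL, "Supramarginal gyrus"),
    # Limbic
    "Amyg": (LIMBIC, "Amygdala"),
    "Hipp": (LIMBIC, "Hippocampus"),
    "PHG": (LIMBIC, "Parahippocampal gyrus"),
    # Prefrontal
    "ACC": (PREFRONTAL, "Anterior cingulate cortex"),
    "FP": (PREFRONTAL, "Frontal pole"),
    "GR": (PREFRONTAL, "Gyrus rectus"),
    "IFGop": (PREFRONTAL, "Inferior frontal gyrus, pars opercularis"),
    "IFGor": (PREFRONTAL, "Inferior frontal gyrus, pars orbitalis"),
    "IFGtr": (PREFRONTAL, "Inferior frontal gyrus, pars triangularis"),
    "MFG": (PREFRONTAL, "Middle frontal gyrus"),
    "OG": (PREFRONTAL, "Orbital gyri"),
    "SFG": (PREFRONTAL, "Superior frontal gyrus"),
    "SubcG": (PREFRONTAL, "Subcallosal gyrus"),
    # Sensorimotor
    "ParaCL": (SENSORIMOTOR, "Paracentral lobule"),
    "PostCG": (SENSORIMOTOR, "Postcentral gyrus"),
    "PreCG": (SENSORIMOTOR, "Precentral gyrus"),
    # Other
    "CingMA": (OTHER, "Cingulate cortex, middle anterior portion"),
    "CingMP": (OTHER, "Cingulate cortex, middle posterior portion"),
    "CingPD": (OTHER, "Cingulate cortex, posterior dorsal portion"),
    "Cun": (OTHER, "Cuneus"),
    "FG": (OTHER, "Fusiform gyrus"),
    "IOG": (OTHER, "Inferior occipital gyrus"),
    "ITGA": (OTHER, "Inferior temporal gyrus, anterior portion"),
    "ITGM": (OTHER, "Inferior temporal gyrus, middle portion"),
    "ITGP": (OTHER, "Inferior temporal gyrus, posterior portion"),
    "InsA": (OTHER, "Anterior insula"),
    "InsP": (OTHER, "Posterior insula"),
    "LingG": (OTHER, "Lingual gyrus"),
    "MOG": (OTHER, "Middle occipital gyrus"),
    "OP": (OTHER, "Occipital pole"),
    "PMC": (OTHER, "Premotor cortex"),
    "PreCun": (OTHER, "Precuneus"),
    "SOG": (OTHER, "Superior orbital gyrus"),
    "SPL": (OTHER, "Superior parietal lobule"),
    "TP": (OTHER, "Temporal pole"),
    "VStr": (OTHER, "Ventral striatum"),
    "POp": (OTHER, "Parietal operculum"),
}


def roi_group(roi: str) -> str:
    """Return the ROI-group label for a parcellation abbreviation.

    Raises ``ValueError`` listing the valid abbreviations when the label is
    not part of the 51-ROI scheme.
    """
    try:
        return ROI_TABLE[roi][0]
    except KeyError:
        valid = ", ".join(sorted(ROI_TABLE))
        raise ValueError(
            f"unknown ROI label {roi!r}; valid labels are: {valid}"
        ) from None
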