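"""Synthetic stand-in landmark inventory (39 cranium + 22 mandible points).

The digitization protocols behind published mouse craniofacial studies name
their landmarks in supplementary tables that are not redistributable here.
This module therefore ships a *constructed, synthetic* inventory: 39 cranium
and 22 mandible landmark names with plausible anatomical region tags. The
names and region assignments are a stand-in for simulation and testing only
and carry no authority about any real digitization protocol.
"""

from __future__ import annotations

# region tag -> landmark base names; counts sum to 39
CRANIUM_REGIONS: dict[str, list[str]] = {
    "premaxilla": ["premaxilla_ant", "premaxilla_post_L", "premaxilla_post_R",
                   "incisive_foramen_ant"],
    "nasal": ["nasale", "nasal_midline_post", "nasal_lat_L", "nasal_lat_R"],
    "maxilla": ["maxilla_zygomatic_L", "maxilla_zygomatic_R", "molar_ant_L",
                "molar_ant_R", "molar_post_L", "molar_post_R", "palatine_post"],
    "frontal": ["frontonasal_midline", "frontal_lat_L", "frontal_lat_R",
                "bregma"],
    "parietal": ["parietal_lat_L", "parietal_lat_R", "parietal_midline",
                 "lambda"],
    "interparietal": ["interparietal_ant", "interparietal_lat_L",
                      "interparietal_lat_R"],
    "occipital": ["opisthion", "occipital_condyle_L", "occipital_condyle_R",
                  "occipital_lat_L", "occipital_lat_R"],
    "temporal": ["squamosal_L", "squamosal_R", "auditory_bulla_L",
                 "auditory_bulla_R"],
    "base": ["basion", "basisphenoid_ant", "presphenoid_ant",
             "pterygoid_midline"],
}

# counts sum to 22
MANDIBLE_REGIONS: dict[str, list[str]] = {
    "body": ["gnathion", "mandible_body_inf_L", "mandible_body_inf_R",
             "symphysis_post"],
    "ramus": ["ramus_ant_L", "ramus_ant_R", "ramus_post_L", "ramus_post_R"],
    "coronoid": ["coronoid_tip_L", "coronoid_tip_R"],
    "condylar": ["condyle_post_L", "condyle_post_R", "condyle_sup_L",
                 "condyle_sup_R"],
    "angular": ["angular_process_L", "angular_process_R"],
    "incisor_alveolus": ["incisor_alveolus_sup", "incisor_alveolus_inf"],
    "molar_alveolus": ["molar_alveolus_ant_L", "molar_alveolus_ant_R",
                       "molar_alveolus_post_L", "molar_alveolus_post_R"],
}


def inventory(unit: str) -> list[tuple[str, str]]:
    """Return ``(landmark_name, region)`` pairs for ``cranium`` or ``mandible``."""
    regions = {"cranium": CRANIUM_REGIONS, "mandible": MANDIBLE_REGIONS}[unit]
    return [(name, tag) for tag, names in regions.items() for name in names]


def region_counts(unit: str) -> list[tuple[str, int]]:
    """Region tags with landmark counts, in inventory order."""
    regions = {"cranium": CRANIUM_REGIONS, "mandible": MANDIBLE_REGIONS}[unit]
    return [(tag, len(names)) for tag, names in regions.items()]


N_CRANIUM = sum(len(v) for v in CRANIUM_REGIONS.values())
N_MANDIBLE = sum(len(v) for v in MANDIBLE_REGIONS.values())
assert N_CRANIUM == 39 and N_MANDIBLE == 22
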