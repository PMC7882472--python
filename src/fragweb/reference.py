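"""Published community composition the synthetic generator is calibrated to.

The emulated field study (28 calcareous-grassland fragments near Göttingen,
sampled in 2010) retained 67 leafhopper species after the three exclusion
rules.  Its per-class tallies and calibration shares are recorded here so
bookkeeping can be checked and the generator's targets are explicit.  The
raw transect data themselves live in an external supplement and are not
shipped; every packaged dataset is synthetic.
"""

import pandas as pd

#: retained leafhopper community by habitat class
CLASS_SUMMARY = pd.DataFrame(
    [
        {"habitat_class": "generalist", "species": 38, "specimens": 2524,
         "pct_monophagous": 24.0},
        {"habitat_class": "specialist", "species": 29, "specimens": 4182,
         "pct_monophagous": 66.0},
    ]
)

#: share of swept specimens removed by the three exclusion rules
EXCLUDED_SPECIMEN_PCT = 5.0

#: interactions summed over the 28 quantitative webs
TOTAL_LINKS = 968

#: plant species recorded across all fragments / appearing in realized webs
PLANT_SPECIES_RECORDED = 167
PLANT_SPECIES_IN_WEBS = 65


def retained_totals() -> dict:
    """Sum the per-class tallies into the retained community totals."""
    return {
        "species": int(CLASS_SUMMARY["species"].sum()),
        "specimens": int(CLASS_SUMMARY["specimens"].sum()),
    }
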