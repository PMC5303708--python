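"""Bundled example data.

``field_trial_summary`` returns the genotype-level summary of a published
waterlogging field screening of 19 interspecific Brachiaria hybrids and 3
commercial check cultivars: least-square means of shoot biomass (g/plant)
and plant height (cm) under control and waterlogged conditions, plus the
visual evaluation score (1-5) under waterlogging.  Values are as printed in
the trial report; replicate-level raw data were not released, so this table
supports the mean/CV/percent-change arithmetic but not re-estimation of the
trial's correlations or LSDs.
"""

from __future__ import annotations

import io

import pandas as pd

_FIELD_TRIAL_CSV = """\
genotype,shb_control,shb_waterlogged,height_control,height_waterlogged,ve_waterlogged
BR12/3809,867,482,40.00,30.83,3.2
BR12/1399,1079,458,48.33,39.17,3.3
BR12/3358,526,444,36.67,30.00,3.2
BR12/1280,800,437,43.33,29.17,3.3
BR12/2321,702,426,31.67,25.00,2.8
BR12/4951,1031,416,38.33,35.00,3.2
BR12/3436,724,398,46.67,43.33,3.3
BR12/2756,561,382,40.83,33.33,3.3
BR12/3377,513,350,34.17,35.83,3.3
BR12/4856,526,346,30.35,31.67,2.8
BR12/4047,501,346,43.33,32.50,2.7
BR12/1535,790,316,41.67,35.83,3.3
BR12/0062,717,290,46.67,33.33,2.7
BR12/5082,455,290,36.67,27.50,3.2
BR12/1188,1011,221,42.50,16.67,1.8
BR12/3659,650,220,41.67,25.00,2.0
BR12/2316,384,183,24.25,15.00,1.5
BR12/1176,648,171,30.00,19.17,2.0
BR12/3018,962,125,32.50,18.33,1.8
cv. Cayman,1221,391,63.33,59.17,4.0
cv. Basilisk,774,283,32.50,19.17,2.7
cv. Marandu,586,327,25.00,20.83,3.3
"""


def field_trial_summary() -> pd.DataFrame:
    """Genotype-level means of the bundled waterlogging trial (22 genotypes).

    Columns: ``genotype``, ``shb_control``, ``shb_waterlogged`` (shoot
    biomass, g/plant), ``height_control``, ``height_waterlogged`` (cm),
    ``ve_waterlogged`` (visual score 1-5).
    """
    return pd.read_csv(io.StringIO(_FIELD_TRIAL_CSV))


def field_trial_long() -> pd.DataFrame:
    """The bundled trial in long form: one row per genotype x treatment.

    Columns: ``genotype``, ``treatment`` ('control'/'waterlogged'),
    ``shb_g``, ``height_cm``, ``ve``.  Each value is the genotype-level mean
    (replicate data were not released), so downstream genotype means are the
    values themselves.
    """
    wide = field_trial_summary()
    rows = []
    for _, r in wide.iterrows():
        rows.append({"genotype": r["genotype"], "treatment": "control",
                     "shb_g": r["shb_control"], "height_cm": r["height_control"],
                     "ve": None})
        rows.append({"genotype": r["genotype"], "treatment": "waterlogged",
                     "shb_g": r["shb_waterlogged"],
                     "height_cm": r["height_waterlogged"],
                     "ve": r["ve_waterlogged"]})
    return pd.DataFrame(rows)
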