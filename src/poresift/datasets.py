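"""Published split-flow-cell count tables for the IVT and transcriptome runs.

These are the raw per-half read (and, where reported, base) counts from
the adaptive-sampling direct-RNA study this package models, kept here so
the derived statistics — percent increases and fold changes — can be
recomputed from the primary numbers rather than restated.

Each row is one comparison: the transcript group counted, the run mode,
the decision time, and the read count in the bulk half versus the
adaptive-sampling half (accepted pool).
"""

from __future__ import annotations

import pandas as pd

_IVT_ROWS = [
    # name, mode, break_time_s, group, bulk, adaptive, unit
    ("gapdh_enrich_3p5s_reads", "enrich", 3.5, "GAPDH",
     16227, 19867, "reads"),
    ("gapdh_enrich_6p5s_reads", "enrich", 6.5, "GAPDH",
     16149, 17252, "reads"),
    ("non_eno2_deplete_2s_reads", "deplete", 2.0, "non-ENO2",
     27469, 36840, "reads"),
    ("eno2_deplete_3p5s_reads", "deplete", 3.5, "ENO2",
     56695, 12006, "reads"),
    ("non_eno2_deplete_3p5s_reads", "deplete", 3.5, "non-ENO2",
     28844, 37174, "reads"),
    ("eno2_deplete_4p5s_reads", "deplete", 4.5, "ENO2",
     50139, 9967, "reads"),
    ("non_eno2_deplete_4p5s_reads", "deplete", 4.5, "non-ENO2",
     26542, 33631, "reads"),
    ("eno2_dual_deplete_3p5s_reads", "deplete", 3.5, "ENO2",
     52850, 12786, "reads"),
    ("gapdh_dual_deplete_3p5s_reads", "deplete", 3.5, "GAPDH",
     12113, 4268, "reads"),
    ("rest_dual_deplete_3p5s_reads", "deplete", 3.5, "18S+ACTB",
     15048, 18952, "reads"),
    ("rest_dual_deplete_3p5s_bases", "deplete", 3.5, "18S+ACTB",
     18_030_000, 22_150_000, "bases"),
]

_TRANSCRIPTOME_ROWS = [
    ("band319_deplete_rest_48h_reads", "deplete", 3.5, "319-band",
     30912, 35057, "reads"),
]


def ivt_split_counts() -> pd.DataFrame:
    """Per-half counts from the 4-transcript IVT pool runs."""
    return pd.DataFrame(
        _IVT_ROWS,
        columns=["name", "mode", "break_time_s", "group", "bulk",
                 "adaptive", "unit"],
    )


def transcriptome_split_counts() -> pd.DataFrame:
    """Per-half counts from the fungal transcriptome runs."""
    return pd.DataFrame(
        _TRANSCRIPTOME_ROWS,
        columns=["name", "mode", "break_time_s", "group", "bulk",
                 "adaptive", "unit"],
    )
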