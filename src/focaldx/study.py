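"""Published study inputs: confusion tables and localization counts.

The study's test-performance table prints, per method, the cohort size and
the point estimates of sensitivity, specificity, PPV and NPV.  Together
those determine the underlying 2x2 table uniquely; the counts below are the
tables so derived and serve as inputs for re-computing every metric and
Wilson interval.  ``combined`` uses histology-or-genetics as the gold
standard, ``histology`` the post-surgical histology alone.
"""

from __future__ import annotations

from .accuracy import ConfusionTable

__all__ = ["STUDY_TABLES", "STUDY_LOCALIZATION", "DOPA_CUTOFF", "DOTANOC_CUTOFFS"]

#: Reported SUV_max-ratio cut-off applied to the DOPA score.
DOPA_CUTOFF = 1.44
#: Reported absolute-SUV_max cut-offs for DOTANOC, per gold-standard mode.
DOTANOC_CUTOFFS = {"combined": 6.77, "histology": 7.73}

STUDY_TABLES: dict[str, ConfusionTable] = {
    # combined gold standard (n = 49 DOPA, 16 DOTANOC)
    "dopa_combined": ConfusionTable(tp=22, fn=0, fp=1, tn=26),  # visual == cutoff 1.44
    "dotanoc_visual_combined": ConfusionTable(tp=7, fn=2, fp=1, tn=6),
    "dotanoc_cutoff_combined": ConfusionTable(tp=6, fn=3, fp=2, tn=5),
    # histology-only gold standard (n = 32 DOPA, 14 DOTANOC)
    "dopa_histology": ConfusionTable(tp=22, fn=0, fp=0, tn=10),
    "dotanoc_visual_histology": ConfusionTable(tp=7, fn=2, fp=1, tn=4),
    "dotanoc_cutoff_histology": ConfusionTable(tp=5, fn=4, fp=2, tn=3),
}

#: (matches, eligible) surgical-focal localization counts per method.
STUDY_LOCALIZATION = {
    "dopa": (20, 22),
    "dotanoc_visual": (7, 7),
    "dotanoc_cutoff_combined": (6, 6),
    "dotanoc_cutoff_histology": (5, 5),
}
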