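"""Published within-session test-retest summary tables for the MIRIAD cohort.

These are the per-region within-session mean %-change results (estimate,
95% CI, p-value, step-down multiplicity threshold, reject flag) printed for
the 27 cytoarchitectonic regions, one table per diagnostic group (AD
patients, healthy controls).  They serve two purposes here:

* as fixed published inputs for validating the step-down threshold
  machinery in :mod:`cytogmd.multiple_testing` (the printed threshold
  column is exactly the ``alpha/(m-k+1)`` sequence at ``alpha=0.05``,
  ``m=27`` assigned by ascending p-value), and
* as a realistic 27-test p-value family for examples.

Note on labels: the printed AD table lists "V1" twice and omits "V2"; the
second occurrence (mean %-change -0.52) is stored under the key ``V2`` so
that region keys are unique, with the label kept as printed.
"""

from __future__ import annotations

import pandas as pd

_AD_COLUMNS = ["region", "label", "mean_pct_change", "ci_lower", "ci_upper",
               "p_value", "printed_threshold", "reject"]

# Alzheimer's disease patients: within-session mean % change, 27 regions.
_AD_ROWS = [
    ("TE1.1", "Auditory Te1 1", -1.15, -1.92, -0.38, 0.004, 0.00192, False),
    ("TE1.0", "TE1.0", -1.01, -1.74, -0.27, 0.008, 0.002, False),
    ("TE1.2", "TE1.2", -0.95, -1.84, -0.05, 0.038, 0.00263, False),
    ("CA2", "CA2", -0.81, -1.35, -0.27, 0.004, 0.00185, False),
    ("BA45", "BA45", -0.76, -1.36, -0.16, 0.014, 0.00208, False),
    ("SUBC", "SUBC", -0.68, -1.33, -0.03, 0.042, 0.00278, False),
    ("DG", "DG", -0.67, -1.29, -0.05, 0.035, 0.00238, False),
    ("TE3.0", "TE3.0", -0.62, -1.2, -0.05, 0.035, 0.00227, False),
    ("V1", "V1", -0.56, -1.19, 0.06, 0.077, 0.00294, False),
    ("BA44", "BA44", -0.56, -1.28, 0.16, 0.124, 0.00333, False),
    ("LB", "LB", -0.55, -1.7, 0.6, 0.339, 0.00455, False),
    ("V2", "V1", -0.52, -1.01, -0.03, 0.037, 0.0025, False),
    ("CA1", "CA1", -0.51, -1.48, 0.46, 0.298, 0.00417, False),
    ("PSC 3a", "PSC 3a", -0.48, -1.28, 0.33, 0.243, 0.00385, False),
    ("CA3", "CA3", -0.46, -0.85, -0.07, 0.02, 0.00217, False),
    ("EC", "EC", -0.34, -1.33, 0.64, 0.486, 0.00556, False),
    ("HATA", "HATA", -0.29, -0.9, 0.33, 0.355, 0.005, False),
    ("SF", "SF", -0.13, -1.27, 1.01, 0.82, 0.01, False),
    ("PSC 3b", "PSC 3b", -0.02, -0.75, 0.7, 0.947, 0.01667, False),
    ("PSC 2", "PSC 2", 0.01, -0.81, 0.83, 0.987, 0.05, False),
    ("CM", "CM", 0.01, -0.5, 0.52, 0.962, 0.025, False),
    ("PSC 1", "PSC 1", 0.03, -0.67, 0.73, 0.93, 0.0125, False),
    ("Motor 4P", "Motor 4P", 0.2, -0.57, 0.97, 0.607, 0.00625, False),
    ("Ch4", "Ch4", 0.27, -1.06, 1.6, 0.688, 0.00833, False),
    ("ASTR", "ASTR", 0.33, -1.22, 1.88, 0.673, 0.00714, False),
    ("Motor 4A", "Motor 4A", 0.67, -0.1, 1.44, 0.087, 0.00313, False),
    ("Ch123", "Ch123", 1.24, -0.35, 2.83, 0.125, 0.00357, False),
]

# Healthy control subjects: within-session mean % change, 27 regions.
_HC_ROWS = [
    ("TE1.2", "TE1.2", -1.15, -1.97, -0.33, 0.007, 0.00192, False),
    ("TE1.0", "TE1.0", -0.76, -1.36, -0.15, 0.016, 0.00208, False),
    ("TE1.1", "TE1. 1", -0.53, -1.14, 0.07, 0.084, 0.00278, False),
    ("TE3.0", "TE3.0", -0.45, -0.78, -0.12, 0.009, 0.002, False),
    ("Ch123", "Ch123", -0.44, -1.86, 0.99, 0.538, 0.00556, False),
    ("BA45", "BA45", -0.36, -0.96, 0.24, 0.228, 0.00357, False),
    ("BA44", "BA44", -0.35, -1.0, 0.29, 0.276, 0.00385, False),
    ("SF", "SF", -0.33, -0.71, 0.05, 0.083, 0.00263, False),
    ("HATA", "HATA", -0.21, -0.85, 0.44, 0.519, 0.005, False),
    ("SUBC", "SUBC", -0.14, -0.63, 0.36, 0.579, 0.00625, False),
    ("V1", "V1", -0.13, -0.65, 0.39, 0.616, 0.01, False),
    ("V2", "V2", -0.11, -0.53, 0.31, 0.603, 0.00833, False),
    ("EC", "EC", -0.1, -0.73, 0.52, 0.739, 0.01667, False),
    ("CA3", "CA3", -0.06, -0.34, 0.21, 0.636, 0.0125, False),
    ("CA2", "CA2", -0.05, -0.4, 0.29, 0.748, 0.025, False),
    ("LB", "LB", 0.05, -0.81, 0.91, 0.906, 0.05, False),
    ("PSC 3a", "PSC 3a", 0.17, -0.46, 0.8, 0.596, 0.00714, False),
    ("DG", "DG", 0.2, -0.13, 0.53, 0.227, 0.00333, False),
    ("CM", "CM", 0.31, -0.1, 0.71, 0.133, 0.00294, False),
    ("PSC 1", "PSC 1", 0.38, -0.4, 1.17, 0.332, 0.00417, False),
    ("ASTR", "ASTR", 0.4, -0.64, 1.45, 0.438, 0.00455, False),
    ("PSC 2", "PSC 2", 0.43, -0.2, 1.05, 0.176, 0.00313, False),
    ("CA1", "CA1", 0.54, 0.04, 1.03, 0.034, 0.00227, False),
    ("PSC 3b", "PSC 3b", 0.67, -0.02, 1.36, 0.057, 0.00238, False),
    ("Motor 4P", "Motor 4P", 0.95, -0.08, 1.98, 0.071, 0.0025, False),
    ("Motor 4A", "Motor 4A", 1.05, 0.35, 1.75, 0.004, 0.00185, False),
    ("Ch4", "Ch4", 1.35, 0.17, 2.53, 0.026, 0.00217, False),
]


def within_session_table(group: str) -> pd.DataFrame:
    """Return the published within-session %-change table for ``group``.

    Parameters
    ----------
    group:
        ``"AD"`` for the Alzheimer's disease patients or ``"HC"`` for the
        healthy controls.
    """
    if group == "AD":
        rows = _AD_ROWS
    elif group == "HC":
        rows = _HC_ROWS
    else:
        raise ValueError(f"group must be 'AD' or 'HC', got {group!r}")
    return pd.DataFrame(rows, columns=_AD_COLUMNS)


def within_session_pvalues(group: str) -> pd.Series:
    """The 27 published within-session p-values, indexed by region key."""
    tab = within_session_table(group)
    return tab.set_index("region")["p_value"]
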