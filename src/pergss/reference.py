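"""Reference group-level summary statistics for the steady-state PERG protocol.

The protocol this package analyzes compares two groups — 12 patients with
major depressive disorder (MDD) and 12 age/sex-matched healthy controls —
across eight stimulus conditions: four checkerboard check sizes (0.8, 1.6,
3.2 and 16 degrees of visual angle) crossed with two pattern-reversal rates
(12.5 and 18.75 reversals per second).  The tables below hold the published
post-hoc group summaries of that protocol: per-condition group means and
standard deviations, the estimated-marginal-mean (EMM) group contrast with
its pooled standard error, and the uncorrected p-value of the contrast.

They serve two purposes here:

* default parameter tables for :mod:`pergss.synthetic` — the generator's
  group x condition means and SDs are these values, so synthetic cohorts
  carry the cohort structure the analysis assumes;
* inputs for the worked examples (effect sizes recomputed from the printed
  EMM differences and SDs; the Holm step-down on the printed p-values).

Amplitudes are noise-corrected PERG amplitudes in μV (eye-averaged);
response times are phase-derived latencies in ms.
"""

from __future__ import annotations

import pandas as pd

#: Subjects per group in the reference cohort.
N_PER_GROUP = 12

#: Check sizes (degrees of visual angle) and reversal rates (reversals/s).
CHECK_SIZES_DEG = (0.8, 1.6, 3.2, 16.0)
REVERSAL_RATES_RPS = (12.5, 18.75)

_POSTHOC_COLUMNS = [
    "check_size_deg",
    "reversal_rate_rps",
    "control_mean",
    "control_sd",
    "patient_mean",
    "patient_sd",
    "emm_difference",
    "emm_se",
    "p_uncorrected",
    "hedges_g_published",
]

# Post-hoc group comparison of PERG amplitudes (μV).
_AMPLITUDE_ROWS = [
    (0.8, 12.5, 2.9, 0.5, 2.3, 0.7, 0.621, 0.21, 0.007, 0.98),
    (1.6, 12.5, 2.5, 0.5, 2.0, 0.6, 0.549, 0.21, 0.015, 1.00),
    (3.2, 12.5, 2.3, 0.5, 1.8, 0.5, 0.553, 0.21, 0.014, 1.13),
    (16.0, 12.5, 2.3, 0.5, 1.8, 0.5, 0.490, 0.21, 0.028, 0.95),
    (0.8, 18.75, 2.5, 0.5, 1.9, 0.7, 0.630, 0.21, 0.006, 1.04),
    (1.6, 18.75, 2.2, 0.4, 1.7, 0.5, 0.514, 0.21, 0.022, 1.03),
    (3.2, 18.75, 2.1, 0.4, 1.6, 0.5, 0.431, 0.21, 0.051, 0.95),
    (16.0, 18.75, 2.2, 0.5, 1.8, 0.5, 0.331, 0.21, 0.127, 0.67),
]

# Post-hoc group comparison of phase-derived response times (ms).  The
# "<0.0001" entry is stored at its printed bound.
_TIME_ROWS = [
    (0.8, 12.5, 55.2, 2.9, 51.9, 3.0, 3.37, 0.96, 0.002, 1.09),
    (1.6, 12.5, 51.7, 2.6, 48.3, 2.8, 3.42, 0.96, 0.001, 1.22),
    (3.2, 12.5, 48.9, 2.2, 45.3, 2.4, 3.58, 0.96, 0.001, 1.53),
    (16.0, 12.5, 44.7, 2.1, 41.5, 2.4, 3.22, 0.96, 0.002, 1.36),
    (0.8, 18.75, 56.4, 1.8, 53.2, 2.5, 3.19, 0.96, 0.003, 1.41),
    (1.6, 18.75, 53.4, 2.0, 49.6, 2.3, 3.79, 0.96, 0.001, 1.69),
    (3.2, 18.75, 50.4, 2.1, 46.5, 2.0, 3.87, 0.96, 0.0001, 1.84),
    (16.0, 18.75, 46.5, 2.1, 43.0, 1.8, 3.52, 0.96, 0.001, 1.72),
]


def amplitude_posthoc_table() -> pd.DataFrame:
    """Reference post-hoc summary for PERG amplitudes (μV), one row per condition."""
    return pd.DataFrame(_AMPLITUDE_ROWS, columns=_POSTHOC_COLUMNS)


def time_posthoc_table() -> pd.DataFrame:
    """Reference post-hoc summary for response times (ms), one row per condition."""
    return pd.DataFrame(_TIME_ROWS, columns=_POSTHOC_COLUMNS)
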