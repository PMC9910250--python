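"""Published summary statistics of the trial that the synthetic cohort emulates.

These tables are the *conditions* of the study — group sizes, timepoints, scale
score distributions and regional gray-matter volumes — and are used as defaults
by :mod:`sleepfbn.simulate` and as the worked example for
:func:`sleepfbn.stats.percent_change`.

Volumes are in mm^3; scale scores are in native scale units.
"""

from __future__ import annotations

import pandas as pd

#: Canonical EEG montage: the eight 10–20 electrodes used for network nodes,
#: in fixed order, referenced to Cz at acquisition.
EEG_CHANNELS = ("C3", "C4", "P3", "P4", "O1", "O2", "P7", "P8")

#: Acquisition sampling rate (Hz).
SAMPLING_RATE = 128.0

#: Analysis band corners (Hz): high-pass and low-pass.
FILTER_BAND = (0.30, 30.0)

#: NREM-II segment policy: number of segments and duration of each (s).
N_SEGMENTS = 10
SEGMENT_DURATION = 15.0

#: Trial arms and sample sizes at enrolment.
N_TREATMENT = 15
N_CONTROL = 10

#: Scale-endpoint timepoints, in temporal order.
SCALE_TIMEPOINTS = ("baseline", "1M", "3M", "6M", "24M")

#: EEG assessment timepoints.
EEG_TIMEPOINTS = ("baseline", "6M", "24M")

#: Volumetry timepoints (paired design).
VOLUME_TIMEPOINTS = ("baseline", "6M")

#: Treatment-group baseline mean and SD for each clinical scale, with the
#: scale's valid score range used to truncate simulated values.
SCALE_BASELINES = {
    # measure: (mean, sd, (lo, hi))
    "FMFS": (24.00, 15.85, (0.0, 100.0)),
    "SS": (26.68, 18.65, (0.0, 100.0)),
    "LAS": (29.36, 21.00, (0.0, 100.0)),
    "EAS": (29.29, 21.41, (0.0, 100.0)),
    "GMFM-88-TOTAL": (52.41, 24.44, (0.0, 100.0)),
    "ADL": (34.54, 20.90, (0.0, 100.0)),
    "SDSC": (49.43, 14.27, (26.0, 130.0)),
}

#: Regional gray-matter volume summary for the treatment group (n = 9 with
#: analyzable T1 images): AAL index, abbreviation, baseline mean ± SD and
#: 6-month mean ± SD, in mm^3.  "TOTAL" is the whole-gray-matter pseudo-region.
_GM_ROWS = [
    # region_index, region, baseline_mean, baseline_sd, m6_mean, m6_sd
    (0, "TOTAL", 614239.25, 39964.24, 623498.50, 40216.82),
    (49, "SOG.L", 4924.49, 685.36, 5164.16, 729.92),
    (52, "MOG.R", 8141.31, 1263.95, 8737.89, 1148.10),
    (53, "IOG.L", 4474.26, 485.94, 4860.14, 544.49),
    (54, "IOG.R", 4239.01, 797.49, 4680.28, 814.30),
    (56, "FFG.R", 11843.16, 1078.77, 12450.73, 960.36),
    (60, "SPG.R", 5877.22, 960.71, 6482.12, 926.72),
    (62, "IPL.R", 5238.69, 587.67, 5713.49, 566.96),
    (66, "ANG.R", 6505.39, 727.61, 7008.39, 871.93),
    (87, "TPOmid.L", 2390.20, 654.50, 2586.36, 506.35),
]

#: Number of treatment-group subjects with analyzable volumetry.
N_VBM_SUBJECTS = 9


def gm_volume_summary() -> pd.DataFrame:
    """Regional gray-matter volume summary table (one row per region).

    Returns a DataFrame with columns ``region_index``, ``region``,
    ``baseline_mean``, ``baseline_sd``, ``m6_mean``, ``m6_sd``.
    """
    return pd.DataFrame(
        _GM_ROWS,
        columns=[
            "region_index",
            "region",
            "baseline_mean",
            "baseline_sd",
            "m6_mean",
            "m6_sd",
        ],
    )


#: AAL regions simulated by default (excludes the TOTAL pseudo-region).
AAL_REGIONS = {idx: abbr for idx, abbr, *_ in _GM_ROWS if abbr != "TOTAL"}
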