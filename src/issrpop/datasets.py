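"""Bundled reference data: the per-primer summary of a published 32-primer
ISSR survey of 44 Bambara groundnut (Vigna subterranea) accessions from 11
populations.

The raw 44 x 510 band matrix of that survey was never deposited; what is
public is the per-primer summary — diversity indices (na, ne, h, I, Nm) and
marker-efficiency indices (H, PIC, EMR, Havp, MI, D, RP) together with the
TSB/PB/PPB bookkeeping.  This module ships that summary as a DataFrame so
the panel-level aggregation and internal-consistency arithmetic of this
package can be exercised against published numbers without the raw scores.

Two primers named "UBC 835" (different sequences, same catalogue name in the
original panel) are disambiguated with a/b suffixes.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["bambara_issr_panel"]

# columns: primer, na, ne, h, I, TSB, PB, PPB, Nm, H, PIC, EMR, Havp, MI, D, RP
_PANEL_CSV = """\
primer,na,ne,h,I,TSB,PB,PPB,Nm,H,PIC,EMR,Havp,MI,D,RP
ISSR 11,1.95,1.43,0.275,0.431,19,18,94.74,1.48,0.304,0.257,3.545,0.0004,0.9129,0.965,7.091
ISSR 18,1.94,1.30,0.208,0.343,18,17,94.44,1.85,0.230,0.204,2.386,0.0003,0.4857,0.983,4.773
UBC 807,2.00,1.35,0.226,0.367,17,17,100.0,2.51,0.266,0.230,2.682,0.0004,0.6180,0.975,5.364
UBC 808,2.00,1.43,0.276,0.435,16,16,100.0,2.45,0.301,0.256,2.955,0.0004,0.7557,0.966,5.909
UBC 809,2.00,1.26,0.200,0.345,22,22,100.0,2.74,0.206,0.185,2.568,0.0002,0.4750,0.986,5.136
UBC 810,1.84,1.31,0.206,0.331,13,11,84.62,2.83,0.251,0.219,1.909,0.0004,0.4184,0.979,3.636
UBC 816,2.00,1.28,0.197,0.335,22,22,100.0,2.96,0.222,0.197,2.795,0.0002,0.5514,0.984,5.591
UBC 836,2.00,1.48,0.306,0.475,22,22,100.0,2.93,0.333,0.277,4.636,0.0003,1.2858,0.956,9.273
UBC 841,1.94,1.33,0.228,0.369,19,18,94.74,2.18,0.251,0.219,2.795,0.0003,0.6135,0.979,5.591
UBC 844,2.00,1.35,0.245,0.398,19,19,100.0,2.27,0.259,0.226,2.909,0.0003,0.6566,0.977,5.818
UBC 815,2.00,1.27,0.186,0.312,19,19,100.0,1.85,0.212,0.190,2.295,0.0003,0.4358,0.986,4.591
UBC 817,2.00,1.28,0.203,0.343,17,17,100.0,2.65,0.218,0.194,2.114,0.0003,0.4101,0.985,4.227
UBC 873,2.00,1.43,0.283,0.447,13,13,100.0,1.92,0.306,0.259,2.455,0.0005,0.6367,0.965,4.909
ISSR 811,2.00,1.59,0.357,0.536,12,12,100.0,0.47,0.390,0.314,3.182,0.0007,0.9983,0.930,6.182
ISSR 901,1.91,1.36,0.238,0.379,12,11,91.67,1.59,0.268,0.232,1.909,0.0005,0.4425,0.975,3.818
UBC 835a,2.00,1.27,0.178,0.299,17,17,100.0,2.14,0.216,0.192,2.091,0.0003,0.4024,0.985,4.182
ISSR 889,2.00,1.40,0.244,0.382,15,15,100.0,2.42,0.288,0.246,2.614,0.0004,0.6439,0.970,5.227
ISSR 812,2.00,1.41,0.245,0.382,15,15,100.0,2.40,0.313,0.264,2.909,0.0005,0.7674,0.963,5.818
ISSR 842,2.00,1.50,0.301,0.457,11,11,100.0,1.93,0.457,0.353,3.886,0.0009,1.3702,0.876,4.773
A-856,1.92,1.32,0.215,0.351,14,13,92.86,3.07,0.243,0.213,1.977,0.0004,0.4215,0.980,3.955
I-825,1.93,1.29,0.189,0.311,16,15,93.75,2.96,0.244,0.214,2.273,0.0003,0.4864,0.980,4.273
ISSR 10,2.00,1.56,0.321,0.483,12,12,100.0,1.86,0.369,0.301,2.932,0.0007,0.8827,0.941,5.864
ISSR 17,1.93,1.40,0.259,0.412,15,14,93.33,1.85,0.298,0.253,2.727,0.0005,0.6907,0.967,5.364
Primer 9,2.00,1.49,0.296,0.457,12,12,100.0,1.29,0.339,0.281,2.591,0.0006,0.7287,0.954,5.182
ISSR 856,2.00,1.32,0.218,0.360,18,18,100.0,2.98,0.250,0.219,2.636,0.0003,0.5768,0.979,5.273
ISSR 2M,2.00,1.42,0.274,0.434,15,15,100.0,2.69,0.307,0.260,2.841,0.0005,0.7384,0.964,5.682
UBC 835b,1.94,1.38,0.258,0.410,17,16,94.12,2.54,0.280,0.241,2.864,0.0004,0.6899,0.972,5.727
UBC 813,2.00,1.40,0.276,0.442,17,17,100.0,2.11,0.285,0.245,2.932,0.0004,0.7174,0.970,5.864
Primer 3,1.92,1.38,0.246,0.390,14,13,92.86,2.68,0.276,0.238,2.318,0.0004,0.5521,0.973,4.636
ISSR 848,2.00,1.50,0.326,0.495,15,15,100.0,1.41,0.375,0.305,3.750,0.0006,1.1426,0.938,7.227
UBC 825,2.00,1.42,0.259,0.404,13,13,100.0,2.83,0.317,0.267,2.568,0.0006,0.6852,0.961,4.864
UBC 830,1.92,1.32,0.209,0.338,14,13,92.86,2.36,0.243,0.213,1.977,0.0004,0.4215,0.980,3.955
"""


def bambara_issr_panel() -> pd.DataFrame:
    """Per-primer reference summary (32 rows), indexed by primer name."""
    return pd.read_csv(io.StringIO(_PANEL_CSV)).set_index("primer")
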