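"""Embedded worked-example data: mini-IPIP descriptive statistics.

The published mini-IPIP example (N = 8,569 respondents, 20 items) is
distributed as printed standard deviations and a lower-triangular
correlation matrix at two-decimal precision; :func:`minipip_fixture`
rebuilds the sample covariance matrix from them (cov = D R D with
D = diag(SD)).  Because the input is rounded to two decimals, statistics
refit from it are expected to match published values at printed precision,
not beyond.

Items appear here grouped by trait (e1..e4, a1..a4, ...), as published —
not in administration order; the estimator aligns by name.
"""

from __future__ import annotations

import io as _io

import numpy as np
import pandas as pd

from .moments import SampleMoments

__all__ = ["minipip_fixture", "MINIPIP_N"]

MINIPIP_N = 8569

# SD column followed by the lower triangle of the correlation matrix.
_MINIPIP_TABLE = """\
item,sd,e1,e2,e3,e4,a1,a2,a3,a4,c1,c2,c3,c4,n1,n2,n3,n4,o1,o2,o3,o4
e1,1.13,1.00,,,,,,,,,,,,,,,,,,,
e2,1.18,0.41,1.00,,,,,,,,,,,,,,,,,,
e3,1.22,0.50,0.40,1.00,,,,,,,,,,,,,,,,,
e4,1.14,0.47,0.50,0.45,1.00,,,,,,,,,,,,,,,,
a1,0.90,0.12,0.10,0.14,0.02,1.00,,,,,,,,,,,,,,,
a2,1.07,0.03,0.16,0.07,0.10,0.29,1.00,,,,,,,,,,,,,,
a3,1.08,0.09,0.07,0.16,0.02,0.43,0.24,1.00,,,,,,,,,,,,,
a4,0.92,0.14,0.26,0.20,0.26,0.34,0.38,0.22,1.00,,,,,,,,,,,,
c1,1.17,0.03,-0.01,0.07,-0.01,0.16,0.02,0.10,0.05,1.00,,,,,,,,,,,
c2,1.28,-0.03,0.02,-0.01,0.04,0.04,0.08,-0.01,0.08,0.32,1.00,,,,,,,,,,
c3,1.03,-0.03,-0.02,0.02,-0.06,0.16,0.03,0.09,0.06,0.36,0.26,1.00,,,,,,,,,
c4,1.09,-0.02,0.05,0.02,0.09,0.08,0.08,-0.03,0.18,0.32,0.40,0.29,1.00,,,,,,,,
n1,1.19,-0.01,-0.08,-0.09,-0.10,0.02,-0.05,0.09,-0.11,-0.04,-0.12,0.00,-0.23,1.00,,,,,,,
n2,1.10,-0.10,0.05,-0.15,-0.02,-0.10,0.00,0.00,-0.05,-0.03,-0.01,0.02,-0.10,0.31,1.00,,,,,,
n3,1.19,-0.04,-0.04,-0.10,-0.11,0.05,-0.01,0.12,-0.08,0.00,-0.08,0.11,-0.19,0.48,0.35,1.00,,,,,
n4,1.12,-0.10,-0.04,-0.12,-0.05,-0.02,0.02,0.03,-0.01,-0.05,-0.02,-0.05,-0.06,0.25,0.24,0.21,1.00,,,,
o1,1.08,0.15,0.08,0.15,0.07,0.22,0.03,0.15,0.10,0.01,-0.06,0.03,-0.07,0.09,-0.11,0.00,-0.02,1.00,,,
o2,1.04,0.01,0.07,0.06,0.12,0.12,0.17,0.08,0.21,-0.05,0.04,-0.04,0.03,-0.04,-0.04,-0.10,0.04,0.25,1.00,,
o3,1.01,0.07,0.09,0.10,0.16,0.11,0.11,0.05,0.20,-0.02,0.06,-0.03,0.11,-0.14,-0.11,-0.20,-0.01,0.25,0.46,1.00,
o4,1.06,0.10,0.14,0.11,0.17,0.14,0.10,0.06,0.22,-0.02,0.03,-0.01,0.09,-0.06,-0.07,-0.09,0.03,0.53,0.29,0.32,1.00
"""


def minipip_fixture() -> SampleMoments:
    """The embedded mini-IPIP sample moments (20 items, N = 8,569)."""
    table = pd.read_csv(_io.StringIO(_MINIPIP_TABLE), index_col=0)
    names = tuple(table.index)
    sds = table["sd"].to_numpy(dtype=float)
    lower = table[list(names)].to_numpy(dtype=float)
    corr = np.where(np.isnan(lower), 0.0, lower)
    corr = corr + corr.T - np.diag(np.diag(corr))
    cov = corr * np.outer(sds, sds)
    return SampleMoments(S=cov, names=names, n=MINIPIP_N)
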