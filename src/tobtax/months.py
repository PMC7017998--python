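"""Month-index arithmetic.

The whole pipeline works on 1-based integer month indices anchored at a
configurable base calendar month (default May 2015, so the 36-month study
window is months 1..36 and April 2018 is month 36).  Windows are closed
integer intervals; keeping indices integral removes date-arithmetic
ambiguity from window definitions.
"""
from __future__ import annotations

import pandas as pd

DEFAULT_MONTH0 = "2015-05"


def to_index(month, month0: str = DEFAULT_MONTH0) -> int:
    """Calendar month (anything ``pd.Period`` accepts) -> 1-based index."""
    p = pd.Period(month, freq="M")
    base = pd.Period(month0, freq="M")
    return (p - base).n + 1


def to_period(index: int, month0: str = DEFAULT_MONTH0) -> pd.Period:
    """1-based month index -> calendar month."""
    return pd.Period(month0, freq="M") + (int(index) - 1)
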