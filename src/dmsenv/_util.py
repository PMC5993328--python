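"""Small shared helpers."""

from __future__ import annotations

import pandas as pd


def bool_flag(series: pd.Series | None, index=None) -> pd.Series:
    """Coerce a possibly missing/NaN-holding flag column to plain bool.

    NaN (mutant lacks the annotation) counts as False.  Avoids pandas'
    object-dtype downcasting deprecation around fillna().
    """
    if series is None:
        return pd.Series(False, index=index)
    return series.notna() & series.eq(True)
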