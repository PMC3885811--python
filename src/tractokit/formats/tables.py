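"""CSV tables: along-tract profile matrices and statistics exports.

Dialect: comma separator, ``.`` decimal point, UTF-8, header row with column
labels, arclength (mm) as the first column and strictly increasing down the
rows. Remaining columns are one per subject (profile matrices) or one per
statistic (model outputs). Missing cells are empty fields (read back as NaN).
"""

from __future__ import annotations

import pandas as pd
import numpy as np

from ..core import StructuralError

ARCLENGTH_COLUMN = "arclength"


def read_profile_csv(path) -> pd.DataFrame:
    """Read an arclength-first CSV into a DataFrame (arclength validated)."""
    df = pd.read_csv(path, encoding="utf-8")
    if df.shape[1] < 2:
        raise StructuralError(f"{path}: need arclength plus >= 1 value column")
    arc = df.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(arc) > 0):
        raise StructuralError(f"{path}: arclength column is not strictly "
                              "increasing")
    df = df.rename(columns={df.columns[0]: ARCLENGTH_COLUMN})
    return df


def write_profile_csv(df: pd.DataFrame, path) -> None:
    """Write a DataFrame whose first column is (or becomes) arclength."""
    if df.shape[1] < 2:
        raise StructuralError("need arclength plus >= 1 value column")
    arc = df.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(arc) > 0):
        raise StructuralError("arclength column is not strictly increasing")
    df = df.rename(columns={df.columns[0]: ARCLENGTH_COLUMN})
    df.to_csv(path, index=False, encoding="utf-8")
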