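"""Map along-tract statistics back onto fiber geometry.

Each fiber point receives the statistic at its arclength (linear
interpolation between grid bins; nearest-edge beyond the grid). Points whose
value is at or above the significance threshold are assigned the sentinel
value — the threshold itself — so a viewer's color bar renders all
non-significant points in one color and grades significant points from the
threshold down.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd

from .core import FiberBundle, StructuralError
from .formats.tables import ARCLENGTH_COLUMN, read_profile_csv
from .profiles import LOCATION_INDEX


def merge_stats_with_fibers(pb: FiberBundle,
                            stats: Union[pd.DataFrame, str],
                            column: str,
                            threshold: float = 0.05,
                            interpolation: str = "linear") -> FiberBundle:
    """Attach a statistics column as per-point data on a parameterized bundle.

    Geometry and existing point data are copied untouched; the new array is
    named after the column. ``interpolation`` is ``linear`` or ``nearest``.
    Points beyond the grid ends take the edge value; their count lands in
    ``metadata['n_outside_grid']``.
    """
    if LOCATION_INDEX not in pb.point_data:
        raise StructuralError("bundle is not parameterized")
    if isinstance(stats, (str, bytes)) or hasattr(stats, "__fspath__"):
        stats = read_profile_csv(stats)
    if column not in stats.columns:
        raise StructuralError(f"column {column!r} not in statistics table "
                              f"(columns: {list(stats.columns)})")
    grid = stats[ARCLENGTH_COLUMN].to_numpy(dtype=float)
    vals = stats[column].to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    if ok.sum() < 2:
        raise StructuralError(f"column {column!r} has fewer than 2 valid bins")
    grid, vals = grid[ok], vals[ok]

    out = pb.copy()
    mapped_arrays = []
    n_outside = 0
    for arcs in pb.point_data[LOCATION_INDEX]:
        n_outside += int(((arcs < grid[0]) | (arcs > grid[-1])).sum())
        if interpolation == "linear":
            mapped = np.interp(arcs, grid, vals)
        elif interpolation == "nearest":
            j = np.clip(np.searchsorted(grid, arcs), 0, len(grid) - 1)
            j_prev = np.clip(j - 1, 0, len(grid) - 1)
            use_prev = np.abs(arcs - grid[j_prev]) <= np.abs(grid[j] - arcs)
            mapped = vals[np.where(use_prev, j_prev, j)]
        else:
            raise ValueError(f"unknown interpolation {interpolation!r}")
        mapped = np.where(mapped >= threshold, threshold, mapped)
        mapped_arrays.append(mapped)
    out.set_point_data(column, mapped_arrays)
    out.metadata["n_outside_grid"] = n_outside
    out.metadata["significance_threshold"] = threshold
    return out
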