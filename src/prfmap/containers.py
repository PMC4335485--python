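"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass(eq=False)
class CorticalSheet:
    """A flattened patch of cortex with ground-truth (or unknown) retinotopy.

    ``vertex_coords`` are 2D sheet positions in millimetres; the neighbor
    graph is a sparse symmetric matrix of edge lengths (mm) used for
    geodesic surface smoothing.  ``truth`` carries per-vertex pRF
    parameters when the sheet is synthetic (columns x0, y0, sigma, beta
    and optionally surround_sigma, surround_amp), else None.
    """

    vertex_coords: np.ndarray
    neighbor_graph: sparse.csr_matrix
    roi_label: np.ndarray
    truth: Optional[pd.DataFrame] = None
    map_params: Optional[pd.DataFrame] = None

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    def is_connected(self) -> bool:
        n, _ = sparse.csgraph.connected_components(self.neighbor_graph, directed=False)
        return n == 1


@dataclass(eq=False)
class DataMatrix:
    """Vertices-by-time percent-signal-change series with geometry.

    ``series`` has shape (n_vertices, T); ``sheet`` provides the vertex
    neighbor graph for surface smoothing.
    """

    series: np.ndarray
    tr_s: float
    sheet: Optional[CorticalSheet] = None
    vertex_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError("series must be 2D (vertices x time)")
        if self.vertex_ids is None:
            self.vertex_ids = np.arange(self.series.shape[0])

    @property
    def n_vertices(self) -> int:
        return self.series.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.series.shape[1]
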