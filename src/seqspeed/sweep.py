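"""Phase diagrams: retrieval speed/quality over the external-input plane."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import NoiseSpec
from .metrics import RetrievalSummary
from .network import ConnectivityMatrix, PatternSequence
from .presets import StandardParams, measure_speed

__all__ = ["PhaseDiagram", "sweep_phase_diagram"]


@dataclass
class PhaseDiagram:
    """Per-cell retrieval summaries over an (I_a, I_s) grid."""

    I_a_grid: np.ndarray
    I_s_grid: np.ndarray
    summaries: list[list[Optional[RetrievalSummary]]]  # [i_a][i_s]

    def speed_array(self) -> np.ndarray:
        out = np.full((self.I_a_grid.size, self.I_s_grid.size), np.nan)
        for i, row in enumerate(self.summaries):
            for j, s in enumerate(row):
                if s is not None and s.speed is not None and s.quality >= 0.05:
                    out[i, j] = s.speed
        return out

    def success_array(self) -> np.ndarray:
        out = np.zeros((self.I_a_grid.size, self.I_s_grid.size), dtype=bool)
        for i, row in enumerate(self.summaries):
            for j, s in enumerate(row):
                out[i, j] = s is not None and s.quality >= 0.05
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: I_a, I_s, speed, quality, status."""
        recs = []
        for i, I_a in enumerate(self.I_a_grid):
            for j, I_s in enumerate(self.I_s_grid):
                s = self.summaries[i][j]
                recs.append(
                    {
                        "I_a": I_a,
                        "I_s": I_s,
                        "speed": None if s is None else s.speed,
                        "quality": None if s is None else s.quality,
                        "status": "error" if s is None else s.status,
                    }
                )
        return pd.DataFrame(recs)


def sweep_phase_diagram(
    patterns: PatternSequence,
    conn: ConnectivityMatrix,
    params: StandardParams,
    I_a_grid: np.ndarray,
    I_s_grid: np.ndarray,
    T: float = 1200.0,
    seed: int = 0,
    noise: Optional[NoiseSpec] = None,
    classify: bool = False,
) -> PhaseDiagram:
    """One retrieval simulation + summary per grid cell.

    The connectivity is shared across cells (quenched network, varying
    inputs only).  Grids must be strictly monotone.  Per-cell simulation
    failures are recorded as None rather than aborting the sweep.
    """
    I_a_grid = np.asarray(I_a_grid, dtype=float)
    I_s_grid = np.asarray(I_s_grid, dtype=float)
    for g in (I_a_grid, I_s_grid):
        if g.size < 1 or (g.size > 1 and not (np.all(np.diff(g) > 0) or np.all(np.diff(g) < 0))):
            raise ValueError("input grids must be non-empty and strictly monotone")
    summaries: list[list[Optional[RetrievalSummary]]] = []
    for I_a in I_a_grid:
        row: list[Optional[RetrievalSummary]] = []
        for I_s in I_s_grid:
            try:
                row.append(
                    measure_speed(
                        patterns,
                        conn,
                        params,
                        I_a,
                        I_s,
                        T=T,
                        seed=seed,
                        noise=noise,
                        classify=classify,
                    )
                )
            except FloatingPointError:
                row.append(None)
        summaries.append(row)
    return PhaseDiagram(I_a_grid=I_a_grid, I_s_grid=I_s_grid, summaries=summaries)
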