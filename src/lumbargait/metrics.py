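"""Per-stride and per-bout spatiotemporal gait metrics.

Row-level identities: cadence = 60 / step time; gait speed = stride length
/ stride time.  Bout summaries are medians across steps (standard midpoint
convention on even counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import STRIDE_COLUMNS


@dataclass
class GaitMetricsTable:
    per_stride: pd.DataFrame
    summary: dict


def compute_metrics(strides, n_rejected: int | None = None) -> GaitMetricsTable:
    """Tabulate assembled steps and summarise the bout.

    Cadence is reported per row from its leading step time and the bout
    cadence is the median of rows (median of ratios, matching a
    median-across-steps summary), not 60 over the median step time.
    """
    rows = []
    for s in strides:
        if s.t_step is not None:
            s.cadence = 60.0 / s.t_step
        rows.append({c: getattr(s, c, None) for c in STRIDE_COLUMNS})
    df = pd.DataFrame(rows, columns=STRIDE_COLUMNS)

    summary = {"n_steps": int(len(df)),
               "n_strides": int(df["stride_time"].notna().sum())
               if len(df) else 0}
    if n_rejected is not None:
        summary["n_rejected"] = int(n_rejected)
    for col in STRIDE_COLUMNS:
        if col in ("ic", "fc_opp", "fc_same"):
            continue
        vals = df[col].dropna().to_numpy(dtype=float) if len(df) else []
        summary[f"median_{col}"] = float(np.median(vals)) if len(vals) else None
    return GaitMetricsTable(per_stride=df, summary=summary)
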