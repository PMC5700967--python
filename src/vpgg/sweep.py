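"""Parameter-plane sweeps over the return coefficient ``r`` and the loner
income coefficient ``sigma``, with CSV/JSON export.

For fixed punishment parameters ``(alpha, gamma)`` the sweep solves the
small-noise limit distribution on a rectangular grid covering
``1.1 <= r < N`` and ``0 < sigma < r - 1`` and records the aggregate
masses of the three stable classes at every grid point — the tabular
analogue of a phase diagram over ``(r, sigma)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .params import GameParameters
from .solver import (
    DEFAULT_EPS_SCHEDULE,
    ConvergenceError,
    SSEReport,
    limit_distribution,
)

logger = logging.getLogger(__name__)

R_MIN = 1.1


def r_sigma_grid(
    N: int, r_step: float = 0.25, sigma_step: float = 0.25
) -> list[tuple[float, float]]:
    """Grid points ``(r, sigma)`` with ``1.1 <= r < N``, ``0 < sigma < r-1``;
    deterministic order: r outer (ascending), sigma inner (ascending)."""
    if r_step <= 0 or sigma_step <= 0:
        raise ValueError("grid steps must be positive")
    points = []
    n_r = int(np.ceil((N - R_MIN) / r_step))
    for a in range(n_r):
        r = round(R_MIN + a * r_step, 10)
        if r >= N:
            break
        b = 1
        while True:
            sigma = round(b * sigma_step, 10)
            # strictly inside the admissible region: the boundary
            # sigma = r - 1 is degenerate (loner income ties the
            # all-cooperator group payoff) and must not be sampled, so
            # guard the comparison against float rounding of the grid.
            if sigma >= r - 1 - 1e-9:
                break
            points.append((r, sigma))
            b += 1
    return points


@dataclass
class SweepCell:
    """One grid point's limit-distribution summary."""

    r: float
    sigma: float
    report: SSEReport | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.report is not None


@dataclass
class SweepGrid:
    """Limit distributions over an (r, sigma) grid at fixed (alpha, gamma)."""

    base: GameParameters
    alpha: float
    gamma: float
    r_step: float
    sigma_step: float
    cells: list[SweepCell] = field(default_factory=list)

    def aggregate(self, cls: str) -> np.ndarray:
        """Aggregate mass of one class at every successful grid point."""
        return np.array(
            [c.report.aggregates[cls] for c in self.cells if c.ok]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells:
            row = {
                "alpha": self.alpha,
                "gamma": self.gamma,
                "r": cell.r,
                "sigma": cell.sigma,
            }
            if cell.ok:
                agg = cell.report.aggregates
                row.update(
                    p_all_L=agg["all_L"],
                    p_all_D=agg["all_D"],
                    p_c_plus_p=agg["c_plus_p"],
                    p_other=agg["other"],
                    sse_states=";".join(
                        ",".join(map(str, s)) for s in cell.report.sse_states
                    ),
                    eps_final=cell.report.eps_final,
                    converged=cell.report.converged,
                )
            else:
                row.update(
                    p_all_L=np.nan, p_all_D=np.nan, p_c_plus_p=np.nan,
                    p_other=np.nan, sse_states="", eps_final=np.nan,
                    converged=False,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def sweep_r_sigma(
    params_base: GameParameters,
    r_step: float = 0.25,
    sigma_step: float = 0.25,
    eps_schedule: tuple[float, ...] = DEFAULT_EPS_SCHEDULE,
    agg_tol: float = 1e-3,
    method: str = "direct",
) -> SweepGrid:
    """Solve the limit distribution at every (r, sigma) grid point.

    Solver failures are recorded per cell and the sweep continues.  Cells
    are independent, so the result does not depend on evaluation order.
    """
    grid = SweepGrid(
        base=params_base,
        alpha=params_base.alpha,
        gamma=params_base.gamma,
        r_step=r_step,
        sigma_step=sigma_step,
    )
    points = r_sigma_grid(params_base.N, r_step, sigma_step)
    for n, (r, sigma) in enumerate(points, 1):
        params = params_base.with_game(r=r, sigma=sigma)
        try:
            report = limit_distribution(
                params, eps_schedule=eps_schedule, agg_tol=agg_tol, method=method
            )
            cell = SweepCell(r=r, sigma=sigma, report=report)
            logger.info(
                "[%d/%d] r=%.2f sigma=%.2f eps_final=%.0e aggregates=%s",
                n, len(points), r, sigma, report.eps_final,
                {k: round(v, 4) for k, v in report.aggregates.items()},
            )
        except ConvergenceError as exc:
            cell = SweepCell(r=r, sigma=sigma, report=None, error=str(exc))
            logger.warning("[%d/%d] r=%.2f sigma=%.2f failed: %s",
                           n, len(points), r, sigma, exc)
        grid.cells.append(cell)
    return grid


class SweepRowSchema(BaseModel):
    """Schema of one exported sweep row (JSON export is validated
    against it)."""

    alpha: float
    gamma: float
    r: float
    sigma: float
    p_all_L: float | None
    p_all_D: float | None
    p_c_plus_p: float | None
    p_other: float | None
    sse_states: str
    eps_final: float | None
    converged: bool


def export_sweep(grid: SweepGrid, path: str, format: str = "csv") -> None:
    """Write the sweep table as CSV (RFC-4180, '.' decimal) or JSON."""
    frame = grid.to_frame()
    if format == "csv":
        frame.to_csv(path, index=False, float_format="%.10g")
    elif format == "json":
        records = json.loads(frame.to_json(orient="records"))
        records = [SweepRowSchema(**row).model_dump() for row in records]
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    else:
        raise ValueError(f"unknown export format {format!r}")
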