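"""Distance reduction of the per-parameter feature columns.

Eleven parameters at five offset magnitudes give 55 variables, which
inflates the type-I error of the downstream group comparisons.  For each
parameter, distances whose rank correlation with every other distance is
high are collapsed to their per-patient mean ("<parameter>_M"); a distance
that decorrelates from the rest is split out as its own variable
("<parameter>_q<k>").  Splitting is iterative and worst-first: the distance
with the lowest minimum Spearman correlation to the remaining set is removed
first and the minima are recomputed, until every remaining distance clears
the threshold or only two remain.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glcm import DISTANCES, PARAMETERS

logger = logging.getLogger(__name__)

DEFAULT_RHO_THRESHOLD = 0.8


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, str | None]:
    """Spearman rank correlation with midranks for ties.

    Returns (rho, flag); rho is 0 with a 'constant input' flag when either
    vector is constant (rank correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, "constant input"
    rho = stats.spearmanr(x, y).statistic
    return float(rho), None


@dataclass
class ParameterReduction:
    parameter: str
    rho_matrix: np.ndarray  # 5x5 Spearman matrix (NaN where degenerate)
    averaged: tuple[int, ...]
    split: tuple[int, ...]
    degenerate: tuple[int, ...] = ()  # constant columns, split out by flag

    def columns(self) -> list[str]:
        cols = []
        if self.averaged:
            cols.append(f"{self.parameter}_M")
        cols.extend(f"{self.parameter}_q{k}" for k in sorted(self.split))
        return cols


@dataclass
class ReductionReport:
    threshold: float
    parameters: dict[str, ParameterReduction] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "parameters": {
                name: {
                    "rho_matrix": [
                        [None if np.isnan(v) else round(float(v), 6) for v in row]
                        for row in pr.rho_matrix
                    ],
                    "averaged_distances": sorted(pr.averaged),
                    "split_distances": sorted(pr.split),
                    "degenerate_distances": sorted(pr.degenerate),
                }
                for name, pr in self.parameters.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def distance_correlation_matrix(
    fm: pd.DataFrame, parameter: str, distances: tuple[int, ...] = DISTANCES
) -> np.ndarray:
    """Pairwise Spearman matrix between the distances of one parameter.

    Symmetric with unit diagonal; entries involving a constant column are NaN.
    """
    cols = [f"{parameter}_q{d}" for d in distances]
    missing = [c for c in cols if c not in fm.columns]
    if missing:
        raise ValueError(f"feature matrix missing columns: {missing}")
    n = len(distances)
    rho = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            r, flag = spearman_rho(fm[cols[a]], fm[cols[b]])
            rho[a, b] = rho[b, a] = np.nan if flag else r
    return rho


def reduce_distances(
    fm: pd.DataFrame,
    threshold: float = DEFAULT_RHO_THRESHOLD,
    parameters: tuple[str, ...] = PARAMETERS,
    distances: tuple[int, ...] = DISTANCES,
) -> tuple[pd.DataFrame, ReductionReport]:
    """Collapse each parameter's distance columns into mean + split variables.

    ``fm`` must contain the '<parameter>_q<d>' columns (patient_id and group
    columns, if present, are carried through unchanged).
    """
    if len(fm) < 3:
        raise ValueError(f"need at least 3 patients for rank correlations, got {len(fm)}")
    report = ReductionReport(threshold=threshold)
    out = {}
    for key in ("patient_id", "group"):
        if key in fm.columns:
            out[key] = fm[key].to_numpy()

    dist_arr = tuple(distances)
    for param in parameters:
        rho = distance_correlation_matrix(fm, param, dist_arr)
        degenerate = {
            dist_arr[a]
            for a in range(len(dist_arr))
            if np.ptp(fm[f"{param}_q{dist_arr[a]}"].to_numpy()) == 0
        }
        active = [d for d in dist_arr if d not in degenerate]
        split: set[int] = set(degenerate)
        if degenerate:
            logger.warning("%s: constant distance columns %s split out", param, sorted(degenerate))

        def _rhos(k: int, pool: list[int]) -> list[float]:
            vals = [rho[dist_arr.index(k), dist_arr.index(j)] for j in pool if j != k]
            return [v for v in vals if not np.isnan(v)]

        def min_rho(k: int, pool: list[int]) -> float:
            vals = _rhos(k, pool)
            return min(vals) if vals else -np.inf

        def mean_rho(k: int, pool: list[int]) -> float:
            vals = _rhos(k, pool)
            return float(np.mean(vals)) if vals else -np.inf

        while len(active) > 2:
            # a rogue distance ties with its argmin partner on the minimum,
            # so break ties by the mean correlation with the remainder (the
            # rogue is low against everyone, the partner only against it)
            worst = min(active, key=lambda k: (min_rho(k, active), mean_rho(k, active), -k))
            if min_rho(worst, active) < threshold:
                active.remove(worst)
                split.add(worst)
            else:
                break

        if len(active) < 2:
            # cannot form a meaningful mean: emit all distances separately
            logger.warning(
                "%s: fewer than 2 usable distances remain; emitting 5 separate columns", param
            )
            averaged: tuple[int, ...] = ()
            split = set(dist_arr)
        else:
            averaged = tuple(sorted(active))

        pr = ParameterReduction(
            parameter=param,
            rho_matrix=rho,
            averaged=averaged,
            split=tuple(sorted(split)),
            degenerate=tuple(sorted(degenerate)),
        )
        report.parameters[param] = pr
        if averaged:
            cols = [f"{param}_q{d}" for d in averaged]
            out[f"{param}_M"] = fm[cols].to_numpy().mean(axis=1)
        for k in sorted(split):
            out[f"{param}_q{k}"] = fm[f"{param}_q{k}"].to_numpy()

    reduced = pd.DataFrame(out)
    if not np.isfinite(reduced.select_dtypes("number").to_numpy()).all():
        raise ValueError("reduced feature table contains non-finite values")
    return reduced, report
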