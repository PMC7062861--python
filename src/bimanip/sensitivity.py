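"""Sobol global sensitivity screening of the kinematic metrics.

Variance-based first- and total-order indices are estimated over the joint
box with a Saltelli-type design on quasi-random (Sobol') samples, via
:func:`scipy.stats.sobol_indices`.  Joints whose sensitivity ratio exceeds
a threshold (default 5%) are selected as state variables for the
lower-level optimization.  Selection uses the total-order index by
default; first-order is available by switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


class SensitivityError(ValueError):
    pass


@dataclass
class SensitivityReport:
    """Per-variable sensitivity ratios and the resulting selection."""

    first_order: np.ndarray
    total_order: np.ndarray
    selected: Tuple[int, ...]
    threshold: float
    index_kind: str
    n_base: int
    seed: int
    variable_names: Tuple[str, ...]
    rejected_fraction: float = 0.0
    per_metric: Dict[str, "SensitivityReport"] = field(default_factory=dict)

    @property
    def ratios(self) -> np.ndarray:
        """The index used for selection, clamped at 0 for reporting."""
        raw = self.total_order if self.index_kind == "total" else self.first_order
        return np.maximum(raw, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": list(self.variable_names),
            "first_order": self.first_order,
            "total_order": self.total_order,
            "selected": [i in self.selected for i in range(len(self.variable_names))],
        })

    def summary(self) -> str:
        lines = [f"Sobol screen (n_base={self.n_base}, seed={self.seed}, "
                 f"index={self.index_kind}, threshold={self.threshold:.2%})"]
        for i, name in enumerate(self.variable_names):
            mark = "*" if i in self.selected else " "
            lines.append(f" {mark} {name:28s} S1={self.first_order[i]:+.4f} "
                         f"ST={self.total_order[i]:+.4f}")
        return "\n".join(lines)


def sobol_screen(cost: Callable[[np.ndarray], float],
                 bounds: np.ndarray,
                 n_base: int = 4096,
                 threshold: float = 0.05,
                 seed: int = 0,
                 index_kind: str = "total",
                 variable_names: Optional[Sequence[str]] = None,
                 cost_batch: Optional[Callable[[np.ndarray], np.ndarray]] = None,
                 ) -> SensitivityReport:
    """Screen the variables of ``cost`` over a box.

    Parameters
    ----------
    cost : callable
        Scalar cost of one state vector ``x`` (shape ``(d,)``).
    bounds : array (d, 2)
        Finite per-variable (lower, upper) bounds, lower < upper.
    n_base : int
        Base sample count (power of two; the design evaluates
        ``n_base * (d + 2)`` points).
    threshold : float
        Sensitivity ratio above which a variable is selected.
    index_kind : {"total", "first"}
        Which index drives selection.
    cost_batch : callable, optional
        Vectorized evaluator mapping ``(n, d)`` states to ``(n,)`` costs;
        used instead of looping ``cost`` when provided.

    Non-finite cost values are counted as rejected samples and replaced by
    the mean of the finite evaluations; more than 1% rejections aborts.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise SensitivityError("bounds must be (d, 2)")
    if not np.all(np.isfinite(bounds)) or np.any(bounds[:, 0] >= bounds[:, 1]):
        raise SensitivityError("bounds must be finite with lower < upper")
    if n_base < 64:
        raise SensitivityError("n_base must be at least 64")
    if index_kind not in ("total", "first"):
        raise SensitivityError("index_kind must be 'total' or 'first'")
    d = bounds.shape[0]
    if variable_names is None:
        variable_names = tuple(f"x{i}" for i in range(d))
    variable_names = tuple(variable_names)

    counter = {"total": 0, "bad": 0}

    def f(x: np.ndarray) -> np.ndarray:
        # scipy passes (d, n); evaluate and sanitize
        X = np.asarray(x, dtype=float).T
        if cost_batch is not None:
            y = np.asarray(cost_batch(X), dtype=float)
        else:
            y = np.array([cost(row) for row in X], dtype=float)
        bad = ~np.isfinite(y)
        counter["total"] += y.size
        counter["bad"] += int(bad.sum())
        if bad.any():
            if bad.all():
                raise SensitivityError("cost returned no finite values")
            y[bad] = y[~bad].mean()
        return y

    dists = [stats.uniform(loc=lo, scale=hi - lo) for lo, hi in bounds]
    rng = np.random.default_rng(seed)
    res = stats.sobol_indices(func=f, n=n_base, dists=dists, rng=rng)
    if counter["total"] and counter["bad"] / counter["total"] > 0.01:
        raise SensitivityError(
            f"{counter['bad']}/{counter['total']} cost evaluations non-finite "
            "(> 1%): the cost is not usable over this box")

    s1 = np.asarray(res.first_order, dtype=float).ravel()
    st = np.asarray(res.total_order, dtype=float).ravel()
    chosen = st if index_kind == "total" else s1
    selected = tuple(int(i) for i in np.flatnonzero(np.maximum(chosen, 0.0) > threshold))
    return SensitivityReport(
        first_order=s1, total_order=st, selected=selected,
        threshold=threshold, index_kind=index_kind, n_base=n_base, seed=seed,
        variable_names=variable_names,
        rejected_fraction=(counter["bad"] / max(counter["total"], 1)))


def screen_metrics(costs: Dict[str, Callable[[np.ndarray], float]],
                   bounds: np.ndarray,
                   n_base: int = 4096,
                   threshold: float = 0.05,
                   seed: int = 0,
                   index_kind: str = "total",
                   variable_names: Optional[Sequence[str]] = None,
                   cost_batches: Optional[Dict[str, Callable]] = None,
                   ) -> SensitivityReport:
    """Screen several metrics and select the union of their sensitive
    variables; per-metric breakdowns are kept on the returned report."""
    if not costs:
        raise SensitivityError("no costs to screen")
    per_metric: Dict[str, SensitivityReport] = {}
    union: List[int] = []
    s1_max = None
    st_max = None
    for k, (name, cost) in enumerate(costs.items()):
        rep = sobol_screen(
            cost, bounds, n_base=n_base, threshold=threshold, seed=seed + k,
            index_kind=index_kind, variable_names=variable_names,
            cost_batch=None if cost_batches is None else cost_batches.get(name))
        per_metric[name] = rep
        union.extend(rep.selected)
        s1_max = rep.first_order if s1_max is None else np.maximum(s1_max, rep.first_order)
        st_max = rep.total_order if st_max is None else np.maximum(st_max, rep.total_order)
    out = SensitivityReport(
        first_order=s1_max, total_order=st_max,
        selected=tuple(sorted(set(union))), threshold=threshold,
        index_kind=index_kind, n_base=n_base, seed=seed,
        variable_names=per_metric[next(iter(per_metric))].variable_names)
    out.per_metric = per_metric
    return out
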