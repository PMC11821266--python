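"""Bootstrapped accuracy metrics and cross-model report tables.

Pearson's R, the coefficient of determination R^2 (1 - SS_res/SS_tot,
which is NOT the square of Pearson's R and can be negative), and RMSE,
each with a percentile-bootstrap 95% confidence interval: pairs are
resampled with replacement (10 000 draws by default) and the CI is read
off the empirical distribution of the metric.  The point estimate is
always the plain full-sample metric, never the bootstrap mean.  Resamples
on which a correlation metric is undefined (zero variance) are redrawn,
keeping the effective number of resamples, and the redraw count is
logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricResult",
    "pearson_r",
    "rmse",
    "r_squared",
    "bootstrap_metric",
    "build_report",
    "METRICS",
]

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (e.g. zero-variance input)."""


def _check_pair(y_true, y_pred, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(y_true, dtype=float).ravel()
    b = np.asarray(y_pred, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if len(a) < min_n:
        raise ValueError(f"need at least {min_n} points, have {len(a)}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in inputs")
    return a, b


def _snap_unit(r):
    """Snap values a few ulp away from +/-1 back onto the bound."""
    return np.where(np.abs(np.abs(r) - 1.0) < 1e-12, np.sign(r), r)


def pearson_r(y_true, y_pred) -> float:
    """Product-moment correlation; raises on zero variance (never silently 0)."""
    a, b = _check_pair(y_true, y_pred, 3)
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedMetricError("zero variance: Pearson R undefined")
    return float(_snap_unit(stats.pearsonr(a, b).statistic))


def rmse(y_true, y_pred) -> float:
    a, b = _check_pair(y_true, y_pred, 2)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    a, b = _check_pair(y_true, y_pred, 2)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedMetricError("zero variance in y_true: R^2 undefined")
    ss_res = float(np.sum((a - b) ** 2))
    return 1.0 - ss_res / ss_tot


METRICS: dict[str, Callable] = {
    "pearson_r": pearson_r,
    "rmse": rmse,
    "r_squared": r_squared,
}


@dataclass(frozen=True)
class MetricResult:
    """Point estimate plus percentile-bootstrap 95% CI for one metric."""

    metric: str
    point: float
    ci_lo: float
    ci_hi: float
    n_boot: int
    n_points: int
    seed: int
    n_redraws: int = 0

    @property
    def half_width(self) -> float:
        """The larger half-width, for Table-style "point +/- hw" rendering."""
        return max(self.point - self.ci_lo, self.ci_hi - self.point)

    def formatted(self) -> str:
        return f"{self.point:.2f} ± {self.half_width:.2f}"


def _batch_metric(name: str, T: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Metric per row of resampled (B, n) matrices; NaN where undefined."""
    if name == "rmse":
        return np.sqrt(np.mean((T - P) ** 2, axis=1))
    Tc = T - T.mean(axis=1, keepdims=True)
    if name == "r_squared":
        ss_tot = np.sum(Tc**2, axis=1)
        ss_res = np.sum((T - P) ** 2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 1.0 - ss_res / ss_tot
        out[ss_tot == 0] = np.nan
        return out
    if name == "pearson_r":
        Pc = P - P.mean(axis=1, keepdims=True)
        num = np.sum(Tc * Pc, axis=1)
        den = np.sqrt(np.sum(Tc**2, axis=1) * np.sum(Pc**2, axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            out = num / den
        out[den == 0] = np.nan
        return _snap_unit(np.clip(out, -1.0, 1.0))
    raise ValueError(f"unknown metric {name!r}")


def bootstrap_metric(
    y_true,
    y_pred,
    metric: str = "pearson_r",
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> MetricResult:
    """Percentile bootstrap of a paired metric.

    Pairs are resampled with replacement ``n_boot`` times; the CI is the
    (alpha/2, 1-alpha/2) empirical quantile pair.  Degenerate resamples
    (zero variance) are redrawn rather than dropped; the redraw count is
    recorded in the result and logged.  Deterministic under a fixed seed.
    """
    min_n = 3 if metric in ("pearson_r",) else 2
    a, b = _check_pair(y_true, y_pred, max(min_n, 3))
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    point = METRICS[metric](a, b)
    n = len(a)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    vals = _batch_metric(metric, a[idx], b[idx])
    n_redraws = 0
    for _ in range(200):
        bad = ~np.isfinite(vals)
        if not bad.any():
            break
        n_redraws += int(bad.sum())
        idx_bad = rng.integers(0, n, size=(int(bad.sum()), n))
        vals[bad] = _batch_metric(metric, a[idx_bad], b[idx_bad])
    else:
        raise UndefinedMetricError("could not draw non-degenerate bootstrap resamples")
    if n_redraws:
        logger.info("bootstrap_metric(%s): redrew %d degenerate resamples", metric, n_redraws)
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return MetricResult(
        metric=metric,
        point=float(point),
        ci_lo=float(lo),
        ci_hi=float(hi),
        n_boot=n_boot,
        n_points=n,
        seed=seed,
        n_redraws=n_redraws,
    )


@dataclass
class ReportCell:
    model: str
    benchmark: str
    result: MetricResult | None
    best: bool = False
    tied: bool = False
    insufficient: bool = False

    def text(self) -> str:
        if self.insufficient or self.result is None:
            return "insufficient"
        return self.result.formatted()


def build_report(
    predictions: dict[str, pd.DataFrame],
    labels: pd.DataFrame,
    benchmarks: dict[str, Sequence[str]] | None = None,
    metric: str = "pearson_r",
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-model x cross-benchmark metric table with best/tied flags.

    ``predictions`` maps model name -> DataFrame(complex_id, pred_pk);
    ``labels`` is DataFrame(complex_id, pk); ``benchmarks`` maps benchmark
    name -> test IDs (default: one benchmark, "all", over every labelled
    ID).  Pairing is by complex_id join, never row order.  Per benchmark,
    the highest point estimate is flagged best; any cell whose CI overlaps
    the best cell's CI is flagged tied.  Columns with fewer than 3 joined
    pairs are marked insufficient.
    """
    labels = labels.set_index("complex_id")["pk"]
    if benchmarks is None:
        benchmarks = {"all": list(labels.index)}
    rows = []
    for bench_name, ids in benchmarks.items():
        ids = [i for i in ids if i in labels.index]
        cells: list[ReportCell] = []
        for model_name, pred_df in predictions.items():
            pred = pred_df.set_index("complex_id")["pred_pk"]
            common = [i for i in ids if i in pred.index and np.isfinite(pred[i])]
            missing = len(ids) - len(common)
            if missing:
                warnings.warn(
                    f"{model_name}/{bench_name}: {missing} labelled IDs unmatched",
                    stacklevel=2,
                )
            if len(common) < 3:
                cells.append(ReportCell(model_name, bench_name, None, insufficient=True))
                continue
            res = bootstrap_metric(
                labels[common].to_numpy(), pred[common].to_numpy(),
                metric=metric, n_boot=n_boot, seed=seed,
            )
            cells.append(ReportCell(model_name, bench_name, res))
        scored = [c for c in cells if not c.insufficient]
        if scored:
            best = max(scored, key=lambda c: c.result.point)
            best.best = True
            for c in scored:
                # CI-overlap rule: tied with best if intervals intersect
                if c.result.ci_hi >= best.result.ci_lo and best.result.ci_hi >= c.result.ci_lo:
                    c.tied = True
        for c in cells:
            rows.append(
                {
                    "model": c.model,
                    "benchmark": c.benchmark,
                    "metric": metric,
                    "point": None if c.result is None else c.result.point,
                    "ci_lo": None if c.result is None else c.result.ci_lo,
                    "ci_hi": None if c.result is None else c.result.ci_hi,
                    "n_points": None if c.result is None else c.result.n_points,
                    "text": c.text(),
                    "best": c.best,
                    "tied": c.tied,
                    "insufficient": c.insufficient,
                }
            )
    return pd.DataFrame(rows)


def write_report(report: pd.DataFrame, csv_path: str | Path, md_path: str | Path | None = None) -> None:
    report.to_csv(csv_path, index=False)
    if md_path is not None:
        lines = ["| model | benchmark | value | flags |", "|---|---|---|---|"]
        for _, row in report.iterrows():
            flags = "best" if row["best"] else ("tied" if row["tied"] else "")
            lines.append(f"| {row['model']} | {row['benchmark']} | {row['text']} | {flags} |")
        Path(md_path).write_text("\n".join(lines) + "\n")
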