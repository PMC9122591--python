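"""Defined analyses downstream of psi-calls.

Three small procedures:

* stop-codon readthrough estimation from a fluorescent two-reporter
  assay: an OLS calibration line of fluorophore ratio on the fraction of
  no-stop reporter (0, 0.5, 1, 2, 4 or 8%), inverted at the mean of a
  sample's replicate ratios;
* dual-luciferase readthrough normalization (ratio of stop to no-stop
  Renilla/Firefly ratios);
* differential psi-score vs differential snoRNA expression: Spearman
  correlation of per-construct delta psi against the snoRNA's expression
  log-ratio (pseudocount 1 on normalized counts) between two cell
  contexts, with snoRNAs cut into three quantile bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CALIBRATION_FRACTIONS = (0.0, 0.005, 0.01, 0.02, 0.04, 0.08)


@dataclass(frozen=True)
class CalibrationPoint:
    no_stop_fraction: float
    ratio: float
    replicate: int = 0

    def __post_init__(self):
        if not 0 <= self.no_stop_fraction <= 1:
            raise ValueError("no_stop_fraction outside [0,1]")
        if self.ratio < 0:
            raise ValueError("fluorophore ratio must be non-negative")


def fit_calibration(
    points: Sequence[CalibrationPoint] | pd.DataFrame,
    per_replicate: bool = False,
) -> tuple[float, float]:
    """OLS of fluorophore ratio on no-stop fraction: (slope, intercept).

    By default each fraction's replicate ratios are averaged before the
    fit (the calibration line runs through replicate means);
    ``per_replicate=True`` fits all points directly.
    """
    if not isinstance(points, pd.DataFrame):
        points = pd.DataFrame([{
            "no_stop_fraction": p.no_stop_fraction, "ratio": p.ratio,
            "replicate": p.replicate,
        } for p in points])
    if points["no_stop_fraction"].nunique() < 2:
        raise ValueError("calibration needs at least 2 distinct fractions")
    if per_replicate:
        x = points["no_stop_fraction"].to_numpy(float)
        y = points["ratio"].to_numpy(float)
    else:
        means = points.groupby("no_stop_fraction")["ratio"].mean()
        x = means.index.to_numpy(float)
        y = means.to_numpy(float)
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def estimate_readthrough(
    sample_ratios: Sequence[float],
    calibration: tuple[float, float],
) -> tuple[float, bool]:
    """Invert the calibration line at the mean replicate ratio.

    Returns (estimated no-stop-equivalent fraction, below_baseline flag);
    negative estimates are reported as-is with the flag set.
    """
    slope, intercept = calibration
    if slope == 0:
        raise ValueError("calibration slope is zero; line cannot be inverted")
    if len(sample_ratios) == 0:
        raise ValueError("no sample replicates")
    est = (float(np.mean(sample_ratios)) - intercept) / slope
    return est, est < 0


def luciferase_readthrough(
    stop_fire: float, stop_ren: float, nostop_fire: float, nostop_ren: float
) -> float:
    """(stop Renilla/Firefly) / (no-stop Renilla/Firefly)."""
    if stop_fire == 0 or nostop_fire == 0 or nostop_ren == 0:
        raise ValueError("zero denominator in luciferase normalization")
    return (stop_ren / stop_fire) / (nostop_ren / nostop_fire)


def expression_log_ratio(
    expr_a: pd.Series, expr_b: pd.Series, pseudocount: float = 1.0
) -> pd.Series:
    """log2((a + pc) / (b + pc)) on normalized expression values."""
    return np.log2((expr_a + pseudocount) / (expr_b + pseudocount))


def quantile_bins(values: pd.Series, n_bins: int = 3,
                  labels: Sequence[str] = ("low", "mid", "high")) -> pd.Series:
    """Equal-quantile bins; ties broken by stable (first-occurrence) order."""
    ranked = values.rank(method="first")
    return pd.qcut(ranked, n_bins, labels=list(labels[:n_bins]))


def differential_psi_vs_expression(
    delta_psi: pd.DataFrame,
    delta_expr: pd.DataFrame,
    pseudocount: float = 1.0,
    n_bins: int = 3,
) -> tuple[float, float, pd.DataFrame]:
    """Spearman rho of per-construct delta psi vs snoRNA expression delta.

    ``delta_psi``: columns (construct_id, snorna_id, delta_psi), restricted
    by the caller to native 18S/28S and high-complementarity (8/10 nt)
    synthetic constructs.  ``delta_expr``: either (snorna_id, delta_expr)
    or (snorna_id, expr_a, expr_b), in which case the log-ratio with the
    pseudocount is computed here.  snoRNAs are cut into ``n_bins``
    equal-quantile expression bins; returns (rho, p, per-bin table with
    mean delta psi +- SE and n).
    """
    de = delta_expr.copy()
    if "delta_expr" not in de.columns:
        de["delta_expr"] = expression_log_ratio(de["expr_a"], de["expr_b"],
                                                pseudocount)
    if de["snorna_id"].nunique() < n_bins:
        raise ValueError(f"need at least {n_bins} snoRNAs for {n_bins} bins")
    de = de.drop_duplicates("snorna_id")[["snorna_id", "delta_expr"]]
    de["bin"] = quantile_bins(de.set_index("snorna_id")["delta_expr"],
                              n_bins).to_numpy()
    merged = delta_psi.merge(de, on="snorna_id")
    if len(merged) == 0:
        raise ValueError("no constructs matched to snoRNA expression deltas")
    rho, p = stats.spearmanr(merged["delta_expr"], merged["delta_psi"])
    per_bin = (
        merged.groupby("bin", observed=False)["delta_psi"]
        .agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="size")
        .reset_index()
    )
    return float(rho), float(p), per_bin
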