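"""Benchmark metrics for fine-mapping output.

Three summaries of how well posterior inclusion probabilities (PIPs)
and credible sets (CSs) recover known causal variants in simulation:

* **PIP calibration** — bin variants by PIP and compare each bin's mean
  PIP to its observed causal fraction;
* **power / FDR curves** — threshold the PIPs and count true/false
  positives, with FDR = FP / (TP + FP) and power = TP / (TP + FN);
* **CS metrics** — coverage (fraction of CSs containing a causal
  variant), power (fraction of causal variants captured by some CS),
  and median MAS, where MAS is a CS's mean absolute pairwise Pearson
  correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["pip_calibration", "power_fdr_curve", "cs_metrics", "CSMetrics",
           "default_thresholds"]


def _validate(pips, truth):
    pips = np.asarray(pips, dtype=np.float64)
    truth = np.asarray(truth, dtype=bool)
    if pips.shape != truth.shape or pips.ndim != 1:
        raise ValueError("pips and truth must be 1-d of equal length")
    if len(pips) == 0:
        raise ValueError("empty input")
    return pips, truth


def pip_calibration(pips, truth, n_bins: int = 10,
                    min_bin_count: int = 10) -> pd.DataFrame:
    """Bin PIPs into equally spaced bins and tabulate calibration.

    Bins are half-open [a, b) with the last bin closed at 1; bins with
    fewer than ``min_bin_count`` variants are dropped.  Returns columns
    ``bin_lo, bin_hi, mean_pip, causal_fraction, count``.
    """
    pips, truth = _validate(pips, truth)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(pips, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        count = int(mask.sum())
        if count < min_bin_count:
            continue
        rows.append({"bin_lo": edges[b], "bin_hi": edges[b + 1],
                     "mean_pip": float(pips[mask].mean()),
                     "causal_fraction": float(truth[mask].mean()),
                     "count": count})
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "mean_pip",
                                       "causal_fraction", "count"])


def default_thresholds() -> np.ndarray:
    """101 equally spaced thresholds on [0, 1] plus the marked 0.95."""
    return np.unique(np.concatenate([np.linspace(0.0, 1.0, 101), [0.95]]))


def power_fdr_curve(pips, truth, thresholds=None) -> pd.DataFrame:
    """Power and FDR of PIP thresholding at each threshold.

    At threshold t, positives are {PIP >= t}; FDR := FP / (TP + FP)
    (defined as 0 when there are no positives) and power :=
    TP / (TP + FN).  Returns columns ``threshold, tp, fp, fn, power,
    fdr``.
    """
    pips, truth = _validate(pips, truth)
    if thresholds is None:
        thresholds = default_thresholds()
    thresholds = np.asarray(thresholds, dtype=np.float64)
    n_causal = int(truth.sum())
    rows = []
    for t in thresholds:
        pos = pips >= t
        tp = int((pos & truth).sum())
        fp = int((pos & ~truth).sum())
        fn = n_causal - tp
        rows.append({
            "threshold": float(t), "tp": tp, "fp": fp, "fn": fn,
            "power": tp / n_causal if n_causal else 0.0,
            "fdr": fp / (tp + fp) if (tp + fp) else 0.0,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CSMetrics:
    """Credible-set summary over one or more fitted datasets."""

    coverage: float | None     # None when there are no CSs
    power: float
    median_mas: float | None
    n_cs: int


def _mean_abs_corr(members, X) -> float:
    members = list(members)
    if len(members) == 1:
        return 1.0
    cols = np.asarray(X, dtype=np.float64)[:, members]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(cols, rowvar=False)
    r = np.where(np.isfinite(r), r, 0.0)
    iu = np.triu_indices(len(members), k=1)
    return float(np.mean(np.abs(r[iu])))


def cs_metrics(cs_list, truth, X) -> CSMetrics:
    """Coverage, power and median MAS of a list of credible sets.

    ``cs_list`` holds objects with a ``members`` attribute (or plain
    index collections).  With no CSs, coverage and median MAS are
    undefined (None) and power is 0 when causal variants exist.
    """
    truth = np.asarray(truth, dtype=bool)
    member_sets = [tuple(getattr(cs, "members", cs)) for cs in cs_list]
    causal = set(np.flatnonzero(truth).tolist())
    if not member_sets:
        return CSMetrics(coverage=None,
                         power=0.0 if causal else 1.0,
                         median_mas=None, n_cs=0)
    covered = [bool(set(m) & causal) for m in member_sets]
    in_any_cs = set().union(*(set(m) for m in member_sets))
    power = (len(causal & in_any_cs) / len(causal)) if causal else 1.0
    mas = [_mean_abs_corr(m, X) for m in member_sets]
    return CSMetrics(coverage=float(np.mean(covered)), power=float(power),
                     median_mas=float(np.median(mas)),
                     n_cs=len(member_sets))
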