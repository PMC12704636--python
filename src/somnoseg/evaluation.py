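"""Agreement, fragmentation and confidence statistics on label grids.

All operations take aligned :class:`~somnoseg.hypnogram.GridLabels`
(and, where relevant, a :class:`~somnoseg.hypnogram.ProbabilityTrack`)
and return plain numbers or small pandas tables. WAKE_LIKE is the
positive class throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .hypnogram import SLEEP, WAKE_LIKE, GridLabels, ProbabilityTrack

logger = logging.getLogger(__name__)


def _aligned(pred: GridLabels, ref: GridLabels):
    if pred.resolution_s != ref.resolution_s:
        raise ContractError(
            f"resolution mismatch: {pred.resolution_s} vs {ref.resolution_s}"
        )
    if abs(pred.onset_s - ref.onset_s) > 1e-9:
        raise ContractError(f"grid onset mismatch: {pred.onset_s} vs {ref.onset_s}")
    a, b = pred.labels, ref.labels
    if a.size != b.size:
        n = min(a.size, b.size)
        logger.warning("grids of unequal length (%d vs %d); truncating to %d",
                       a.size, b.size, n)
        a, b = a[:n], b[:n]
    return a.astype(np.int64), b.astype(np.int64)


def concordance(pred: GridLabels, ref: GridLabels) -> float:
    """Percentage of cells on which the two scorings agree."""
    a, b = _aligned(pred, ref)
    return 100.0 * float(np.mean(a == b))


def cohen_kappa(pred: GridLabels, ref: GridLabels) -> float:
    """Chance-corrected agreement, kappa = (p_o - p_e) / (1 - p_e).

    When both scorings are the identical single class (p_e = 1 with
    perfect observed agreement) kappa is 1 by continuity.
    """
    a, b = _aligned(pred, ref)
    n = a.size
    p_o = float(np.mean(a == b))
    p_a1, p_b1 = float(np.mean(a)), float(np.mean(b))
    p_e = p_a1 * p_b1 + (1 - p_a1) * (1 - p_b1)
    if p_e >= 1.0 - 1e-12:
        return 1.0 if p_o >= 1.0 - 1e-12 else 0.0
    return (p_o - p_e) / (1 - p_e)


def sens_spec(pred: GridLabels, ref: GridLabels,
              positive: int = WAKE_LIKE) -> tuple[float | None, float | None]:
    """(sensitivity, specificity) for the positive class (WAKE_LIKE).

    A statistic whose denominator is empty (no positives / no
    negatives in the reference) is returned as None, not as 0.
    """
    a, b = _aligned(pred, ref)
    pos = b == positive
    neg = ~pos
    sens = float(np.mean(a[pos] == positive)) if pos.any() else None
    spec = float(np.mean(a[neg] != positive)) if neg.any() else None
    return sens, spec


def tst_and_efficiency(labels: GridLabels) -> tuple[float, float]:
    """(total sleep time in minutes, sleep efficiency in percent)."""
    n_sleep = int(np.sum(labels.labels == SLEEP))
    tst_min = n_sleep * labels.resolution_s / 60.0
    total_min = labels.labels.size * labels.resolution_s / 60.0
    return tst_min, 100.0 * tst_min / total_min


def s2w_transition_index(labels: GridLabels) -> float:
    """Sleep-to-wake transitions per hour of the grid span."""
    arr = labels.labels
    n_trans = int(np.sum((arr[:-1] == SLEEP) & (arr[1:] == WAKE_LIKE)))
    hours = arr.size * labels.resolution_s / 3600.0
    return n_trans / hours


def misclassified_runs(pred: GridLabels, ref: GridLabels) -> pd.DataFrame:
    """Histogram of contiguous-misclassification durations.

    Returns a table with columns ``duration_s``, ``count`` and
    ``percent`` (of all misclassified runs); empty when the grids agree
    everywhere.
    """
    a, b = _aligned(pred, ref)
    mism = (a != b).astype(np.int8)
    if not mism.any():
        return pd.DataFrame(columns=["duration_s", "count", "percent"])
    edges = np.flatnonzero(np.diff(mism)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [mism.size]))
    runs = [(e - s) * pred.resolution_s
            for s, e in zip(starts, ends) if mism[s] == 1]
    vals, counts = np.unique(np.asarray(runs), return_counts=True)
    return pd.DataFrame({
        "duration_s": vals,
        "count": counts,
        "percent": 100.0 * counts / counts.sum(),
    })


def confidence_stats(probs: ProbabilityTrack, pred: GridLabels,
                     ref: GridLabels, bin_width: float = 0.05):
    """Mean prediction confidence + misclassified-confidence histogram.

    Confidence of a cell is the probability of its predicted class,
    max(p_wake, 1 - p_wake). The histogram covers misclassified cells
    only, binned over [0.5, 1.0], expressed as a percentage of ALL
    cells per bin.
    """
    a, b = _aligned(pred, ref)
    if len(probs) < a.size:
        raise ContractError("probability track shorter than the label grids")
    p_wake = probs.p_wake[:a.size]
    conf = np.maximum(p_wake, 1.0 - p_wake)
    mean_conf = float(np.mean(conf))
    edges = np.arange(0.5, 1.0 + bin_width / 2, bin_width)
    mis_conf = conf[a != b]
    counts, _ = np.histogram(np.clip(mis_conf, 0.5, 1.0 - 1e-12), bins=edges)
    hist = pd.DataFrame({
        "bin_low": edges[:-1],
        "bin_high": edges[1:],
        "percent_of_total": 100.0 * counts / a.size,
    })
    return mean_conf, hist


@dataclass
class AgreementPair:
    """Cohort-level method agreement for one per-recording metric."""

    pearson_r: float | None
    p_value: float | None
    mean_diff: float
    loa_low: float
    loa_high: float
    n: int


def cohort_agreement(values_a, values_b) -> AgreementPair:
    """Pearson correlation + Bland-Altman limits between two methods.

    Differences are ``a - b`` (automatic minus manual by convention);
    limits of agreement are mean +/- 1.96 sample SD. With zero variance
    in either series the correlation is reported as missing.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size != b.size or a.size < 3:
        raise ContractError("cohort_agreement needs >= 3 paired recordings")
    if np.std(a) == 0 or np.std(b) == 0:
        r, p = None, None
    else:
        r, p = stats.pearsonr(a, b)
        r, p = float(r), float(p)
    d = a - b
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementPair(r, p, mean_diff, mean_diff - 1.96 * sd,
                         mean_diff + 1.96 * sd, a.size)


@dataclass
class MetricsReport:
    """Per-recording summary of every headline metric."""

    concordance_pct: float
    kappa: float
    sensitivity_wake: float | None
    specificity_wake: float | None
    tst_min: float
    sleep_efficiency_pct: float
    s2w_index_per_h: float
    mean_confidence: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def compute_report(pred: GridLabels, ref: GridLabels,
                   probs: ProbabilityTrack | None = None) -> MetricsReport:
    """Assemble a full MetricsReport for one recording."""
    sens, spec = sens_spec(pred, ref)
    tst, eff = tst_and_efficiency(pred)
    mean_conf = None
    if probs is not None:
        mean_conf, _ = confidence_stats(probs, pred, ref)
    return MetricsReport(
        concordance_pct=concordance(pred, ref),
        kappa=cohen_kappa(pred, ref),
        sensitivity_wake=sens,
        specificity_wake=spec,
        tst_min=tst,
        sleep_efficiency_pct=eff,
        s2w_index_per_h=s2w_transition_index(pred),
        mean_confidence=mean_conf,
    )
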