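"""Behavioural responsiveness: binomial hit-rate modelling and classification.

Participants perform a two-choice auditory task (40 trials) at each sedation
level.  A binomial model of the hit count yields an exact Clopper-Pearson
95% confidence interval on the probability of a correct response; a
participant whose moderate-sedation interval falls entirely below the
baseline interval is classified *drowsy*, otherwise *responsive*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .containers import LEVELS

RESPONSIVE = "responsive"
DROWSY = "drowsy"
UNASSIGNED = "unassigned"


@dataclass
class ParticipantRecord:
    """Per-participant behavioural and drug data across sedation levels.

    ``hits``/``trials`` map level name -> count; ``reaction_times`` maps
    level -> list of RTs (seconds) for correct trials; ``drug`` maps level ->
    measured plasma concentration (ug/ml).
    """

    participant: str
    hits: dict[str, int] = field(default_factory=dict)
    trials: dict[str, int] = field(default_factory=dict)
    reaction_times: dict[str, list[float]] = field(default_factory=dict)
    drug: dict[str, float] = field(default_factory=dict)
    group: str = UNASSIGNED

    def __post_init__(self) -> None:
        for level, h in self.hits.items():
            n = self.trials.get(level, 0)
            if not 0 <= h <= n:
                raise ValueError(f"hits must lie in [0, trials] at {level}")
        for level, c in self.drug.items():
            if c < 0:
                raise ValueError(f"negative drug concentration at {level}")

    def hit_rate(self, level: str) -> float:
        return self.hits[level] / self.trials[level]


def binomial_ci(
    hits: int, trials: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Point estimate and exact (Clopper-Pearson) confidence interval.

    Returns ``(p_hat, lower, upper)`` with endpoints clipped to [0, 1].
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= hits <= trials:
        raise ValueError("hits must lie in [0, trials]")
    p_hat = hits / trials
    lower, upper = proportion_confint(hits, trials, alpha=1 - level, method="beta")
    # statsmodels returns NaN endpoints at the boundary counts
    lower = 0.0 if np.isnan(lower) else float(np.clip(lower, 0.0, 1.0))
    upper = 1.0 if np.isnan(upper) else float(np.clip(upper, 0.0, 1.0))
    return p_hat, lower, upper


def classify_responsiveness(
    record: ParticipantRecord, level: float = 0.95
) -> str:
    """Classify a participant as responsive or drowsy.

    Drowsy iff the moderate-sedation confidence interval lies strictly below
    (non-overlapping with) the baseline interval.
    """
    for needed in ("baseline", "moderate"):
        if needed not in record.hits:
            raise ValueError(f"missing hit counts at {needed}")
    _, lo_base, _ = binomial_ci(
        record.hits["baseline"], record.trials["baseline"], level
    )
    _, _, hi_mod = binomial_ci(
        record.hits["moderate"], record.trials["moderate"], level
    )
    return DROWSY if hi_mod < lo_base else RESPONSIVE


def summarize_rt(
    record: ParticipantRecord,
    compare: tuple[str, str] = ("baseline", "moderate"),
) -> dict:
    """Per-level median reaction time and moderate-vs-baseline change.

    Levels with no correct trials yield NaN medians; the change/ratio is NaN
    if either compared level is missing.
    """
    medians = {}
    for level in LEVELS:
        rts = record.reaction_times.get(level, [])
        medians[level] = float(np.median(rts)) if len(rts) else float("nan")
    ref, tgt = compare
    change = medians[tgt] - medians[ref]
    ratio = medians[tgt] / medians[ref] if medians[ref] else float("nan")
    return {"median_rt": medians, "rt_change": change, "rt_ratio": ratio}


def median_split_predict(
    baseline_metric: np.ndarray, moderate_hit_rate: np.ndarray
) -> dict:
    """Split participants at the median of a baseline network metric and
    compare moderate-sedation hit rates between halves.

    The participant at the median (and any ties with it) goes to the lower
    half.  Group means and a Mann-Whitney rank test are returned.
    """
    x = np.asarray(baseline_metric, dtype=float)
    y = np.asarray(moderate_hit_rate, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired participants")
    if np.ptp(x) == 0:
        raise ValueError("metric values are all identical; no split possible")
    med = np.median(x)
    low = x <= med
    high = ~low
    if not high.any():  # heavy ties at the median: fall back to strict split
        low = x < med
        high = ~low
    stat, p = sps.mannwhitneyu(y[high], y[low], alternative="two-sided")
    return {
        "median": float(med),
        "low_mask": low,
        "mean_hit_rate_low": float(y[low].mean()),
        "mean_hit_rate_high": float(y[high].mean()),
        "u_statistic": float(stat),
        "p_value": float(p),
    }
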