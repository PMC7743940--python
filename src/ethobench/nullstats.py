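"""Score-shuffling permutation null, rank statistics, t-based CIs, violin summaries.

The null hypothesis under test is that combined human confidence scores
carry no information about the classifier's average bout scores.  Each
shuffled replicate permutes the observed 1-6 scores uniformly at random
across the human-annotated (TP and FN) bouts, preserving the exact count
of every score category; false positives keep their score of 0.  The
observed Kruskal-Wallis statistic and per-score "recall" rates are then
compared with their distributions over the replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ethobench.io import ValidationError
from ethobench.matching import MatchRecord

#: Upper 0.025 critical values of the t distribution are taken from
#: scipy.stats.t; the n=10 case (9 df) is 2.262157.


@dataclass(frozen=True)
class ShuffleConfig:
    n_reps: int = 50
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")


@dataclass(frozen=True)
class CIResult:
    """t-based 95% confidence interval m +/- t_{0.025}(n-1) * s / sqrt(n),
    with s the sample standard deviation (so s/sqrt(n) is the standard error)."""

    n: int
    mean: float
    sd: float
    half_width: float

    @property
    def interval(self) -> tuple[float, float]:
        return (self.mean - self.half_width, self.mean + self.half_width)


def shuffle_scores(
    records: Sequence[MatchRecord], config: ShuffleConfig
) -> list[list[MatchRecord]]:
    """Build ``n_reps`` shuffled replicates of a match-record collection.

    Replicate r permutes the human scores across TP/FN bouts with an RNG
    seeded ``base_seed + r`` (category flags, average classifier scores and
    FP records are untouched), so the whole series is reproducible.
    """
    records = list(records)
    annotated_idx = [i for i, r in enumerate(records) if r.category in ("TP", "FN")]
    if not annotated_idx:
        raise ValidationError("shuffle_scores needs at least one human-annotated bout")
    scores = np.array([records[i].human_score for i in annotated_idx])
    replicates = []
    for rep in range(config.n_reps):
        rng = np.random.default_rng(config.base_seed + rep)
        permuted = scores[rng.permutation(scores.size)]
        shuffled = list(records)
        for j, i in enumerate(annotated_idx):
            shuffled[i] = replace(records[i], human_score=int(permuted[j]))
        replicates.append(shuffled)
    return replicates


def kw_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value.

    All values identical across groups is a degenerate case where the tie
    correction divides by zero; by convention it returns H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if sum(1 for g in groups if g.size) < 2:
        raise ValidationError("kw_test needs at least two non-empty groups")
    pooled = np.concatenate([g for g in groups if g.size])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*[g for g in groups if g.size])
    return float(h), float(p)


def pairwise_mwu_bonferroni(
    groups: Mapping[int, Sequence[float]], alpha: float = 0.01
) -> list[dict]:
    """Two-sided Mann-Whitney U tests between neighboring score groups.

    Pairs are consecutive scores present in ``groups``; the Bonferroni
    divisor is the number of pairs actually tested.  The exact p-value is
    used when the combined sample size is <= 12 and there are no ties,
    the normal approximation with tie correction otherwise.  A pair with
    an empty side is skipped with a notice.
    """
    present = sorted(groups)
    pairs = list(zip(present, present[1:]))
    results: list[dict] = []
    tested = []
    for lo, hi in pairs:
        x = np.asarray(groups[lo], dtype=float)
        y = np.asarray(groups[hi], dtype=float)
        if x.size == 0 or y.size == 0:
            results.append({"pair": (lo, hi), "skipped": True, "notice": "empty group"})
            continue
        combined = np.concatenate([x, y])
        ties = np.unique(combined).size < combined.size
        method = "exact" if combined.size <= 12 and not ties else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        results.append(
            {
                "pair": (lo, hi),
                "skipped": False,
                "U": float(res.statistic),
                "p": float(min(res.pvalue, 1.0)),
                "method": method,
            }
        )
        tested.append(results[-1])
    n_tests = len(tested)
    for r in tested:
        r["n_tests"] = n_tests
        r["alpha_corrected"] = alpha / n_tests if n_tests else alpha
        r["significant"] = r["p"] < r["alpha_corrected"] if n_tests else False
    return results


def t_confidence_interval(samples: Sequence[float]) -> CIResult:
    """95% CI via the t distribution: m +/- t_{0.025}(n-1) * s / sqrt(n)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValidationError("t_confidence_interval needs n >= 2 samples")
    n = int(x.size)
    m = float(x.mean())
    s = float(x.std(ddof=1))
    t_crit = float(stats.t.ppf(0.975, n - 1))
    return CIResult(n=n, mean=m, sd=s, half_width=t_crit * s / math.sqrt(n))


def _score_groups(records: Sequence[MatchRecord]) -> dict[int, list[float]]:
    """Average classifier scores of TP+FN bouts, grouped by human score."""
    groups: dict[int, list[float]] = {}
    for r in records:
        if r.category in ("TP", "FN"):
            groups.setdefault(r.human_score, []).append(r.avg_classifier_score)
    return dict(sorted(groups.items()))


def _recall_by_score(records: Sequence[MatchRecord]) -> dict[int, float]:
    out: dict[int, float] = {}
    tally: dict[int, list[int]] = {}
    for r in records:
        if r.category in ("TP", "FN"):
            t = tally.setdefault(r.human_score, [0, 0])
            t[0] += r.category == "TP"
            t[1] += 1
    for s, (tp, total) in sorted(tally.items()):
        out[s] = tp / total
    return out


def null_comparison(
    observed: Sequence[MatchRecord],
    shuffles: Sequence[Sequence[MatchRecord]],
    threshold: float | None = None,
) -> dict:
    """Compare the observed score/classifier-score association with its
    permutation null.

    Reports the observed Kruskal-Wallis p, the distribution of shuffled
    KW p-values, and, per combined human score, the observed recall against
    the mean and t-based 95% CI of the shuffled "recall" rates, flagging
    scores whose observed recall falls outside the interval.
    """
    obs_groups = _score_groups(observed)
    h_obs, p_obs = kw_test(list(obs_groups.values()))
    shuffled_p = []
    per_score_shuffled: dict[int, list[float]] = {}
    for rep in shuffles:
        groups = _score_groups(rep)
        _, p = kw_test(list(groups.values()))
        shuffled_p.append(p)
        for s, rec in _recall_by_score(rep).items():
            per_score_shuffled.setdefault(s, []).append(rec)

    obs_recall = _recall_by_score(observed)
    per_score = {}
    for s in sorted(obs_recall):
        entry: dict = {"observed_recall": obs_recall[s]}
        reps = per_score_shuffled.get(s, [])
        if len(reps) >= 2:
            ci = t_confidence_interval(reps)
            lo, hi = ci.interval
            entry.update(
                shuffled_mean=ci.mean,
                ci_low=lo,
                ci_high=hi,
                outside_ci=not (lo <= obs_recall[s] <= hi),
            )
        else:
            raise ValidationError(
                f"score {s}: cannot form a confidence interval from "
                f"{len(reps)} shuffled replicate(s); use n_reps >= 2"
            )
        per_score[s] = entry

    return {
        "observed_kw_h": h_obs,
        "observed_kw_p": p_obs,
        "shuffled_kw_p": shuffled_p,
        "n_shuffles": len(shuffled_p),
        "observed_below_all_shuffled": bool(p_obs < min(shuffled_p)),
        "per_score": per_score,
        "threshold": threshold,
    }


def violin_summary(
    groups: Mapping[str | int, Sequence[float]], n_points: int = 64
) -> dict:
    """Kernel density summaries of average classifier scores per group.

    Violin widths are the Gaussian KDE (Scott's bandwidth rule); each
    group's width scale is its bout count relative to the largest group.
    Groups with fewer than two distinct values get an empty density.
    """
    counts = {k: len(v) for k, v in groups.items()}
    max_count = max(counts.values()) if counts else 0
    out = {}
    for key, values in groups.items():
        values = np.asarray(values, dtype=float)
        entry: dict = {
            "count": int(values.size),
            "scale": values.size / max_count if max_count else 0.0,
        }
        if values.size >= 2 and np.unique(values).size >= 2:
            kde = stats.gaussian_kde(values, bw_method="scott")
            grid = np.linspace(values.min(), values.max(), n_points)
            entry["grid"] = grid
            entry["density"] = kde(grid)
        else:
            entry["grid"] = np.array([])
            entry["density"] = np.array([])
        out[key] = entry
    return out
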