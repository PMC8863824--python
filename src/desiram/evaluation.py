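"""Evaluation machinery: LOO accuracy, random-selection baseline, exact
binomial tails, DSI and the k-of-N group spectrum.

The benchmark classifier is compared against random selection (RS), which
guesses uniformly among the NA candidate chemicals and succeeds with rate
1/NA.  Two complementary RS statistics are provided: a Monte-Carlo standard
deviation of the RS accuracy over a finite test set, and the exact binomial
tail probability that RS reaches a given accuracy, computed in rational
arithmetic (doubles underflow at the ~1e-19 scale these tails reach).

The decrease in self-information (DSI) quantifies, in bits, how much less
surprising a correct identification is under the classifier than under RS:

    DSI = log2(accuracy_classifier) - log2(accuracy_RS)
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .classifier import ClassifierConfig, classify
from .concentration import TrainingSet, fit_model_functions
from .exceptions import BadConfigError, InvalidDataError


@dataclass
class EvaluationReport:
    """Outcome of one leave-one-out discrimination benchmark."""

    group: list
    n_samples: dict  # chemical -> record count
    accuracy: float
    rs_rate: float
    rs_sd: float
    rs_tail_prob: float
    dsi: float  # bits; NaN when accuracy is 0
    per_sample: list  # (true label, predicted label) pairs
    degenerate: bool = False  # single-chemical group

    @property
    def n_total(self) -> int:
        return sum(self.n_samples.values())

    def to_dict(self) -> dict:
        return {
            "group": list(self.group),
            "n_samples": dict(self.n_samples),
            "accuracy": self.accuracy,
            "rs_rate": self.rs_rate,
            "rs_sd": self.rs_sd,
            "rs_tail_prob": self.rs_tail_prob,
            "dsi": self.dsi,
            "degenerate": self.degenerate,
            "per_sample": [list(p) for p in self.per_sample],
        }


def rs_rate(na: int) -> float:
    """Accuracy of uniform random selection among ``na`` candidates: 1/NA."""
    if na < 1:
        raise BadConfigError(f"number of attractants must be >= 1, got {na}")
    return 1.0 / na


def rs_sd_mc(n_total: int, na: int, reps: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo SD of random-selection accuracy over ``n_total`` samples.

    Each replicate guesses uniformly for every sample; the statistic is the
    empirical SD of the per-replicate accuracy.  (The closed form is
    sqrt(p(1-p)/n) with p = 1/NA.)
    """
    if n_total < 1:
        raise BadConfigError(f"n_total must be >= 1, got {n_total}")
    if reps < 1000:
        raise BadConfigError(f"reps must be >= 1000, got {reps}")
    p = rs_rate(na)
    if na == 1:
        return 0.0
    rng = np.random.default_rng(seed)
    correct = rng.binomial(n_total, p, size=reps)
    return float(np.std(correct / n_total, ddof=1))


def rs_tail_probability_exact(accuracy: float, n_total: int, na: int) -> Fraction:
    """Exact P(X >= ceil(accuracy * n)) for X ~ Binomial(n, 1/NA).

    Computed entirely in rational arithmetic; the float conversion of the
    result is the only rounding step in :func:`rs_tail_probability`.
    """
    if not (0 <= accuracy <= 1):
        raise BadConfigError(f"accuracy must lie in [0, 1], got {accuracy}")
    if n_total < 1:
        raise BadConfigError(f"n_total must be >= 1, got {n_total}")
    p = Fraction(1, na)
    q = 1 - p
    k_min = math.ceil(Fraction(accuracy) * n_total)
    if k_min <= 0:
        return Fraction(1)
    return sum(
        Fraction(math.comb(n_total, k)) * p**k * q ** (n_total - k)
        for k in range(k_min, n_total + 1)
    )


def rs_tail_probability(accuracy: float, n_total: int, na: int) -> float:
    """Probability that random selection reaches the given accuracy or better."""
    return float(rs_tail_probability_exact(accuracy, n_total, na))


def dsi(accuracy_classifier: float, accuracy_rs: float) -> float:
    """Decrease in self-information, in bits.

    log2(accuracy_classifier) - log2(accuracy_rs); positive when the
    classifier beats random selection.  Undefined at zero accuracy.
    """
    for name, a in (("accuracy_classifier", accuracy_classifier), ("accuracy_rs", accuracy_rs)):
        if not (0 < a <= 1):
            raise BadConfigError(f"{name} must lie in (0, 1], got {a}")
    return math.log2(accuracy_classifier) - math.log2(accuracy_rs)


def enumerate_groups(chemicals, k: int) -> list:
    """All unordered k-subsets, in lexicographic order of label positions."""
    chemicals = list(chemicals)
    if not (1 <= k <= len(chemicals)):
        raise BadConfigError(
            f"group size k={k} must lie in 1..{len(chemicals)} (N={len(chemicals)})"
        )
    return [list(g) for g in itertools.combinations(chemicals, k)]


def loo_accuracy(
    training: TrainingSet,
    group=None,
    basis: str = "linear",
    classifier_config: ClassifierConfig | None = None,
    rs_reps: int = 100_000,
    rs_seed: int = 0,
) -> EvaluationReport:
    """Leave-one-out discrimination accuracy for a chemical group.

    For each record of the group, the model functions are refitted on all
    remaining records (a full refit, not a re-normalisation) and the held-out
    vector classified.  Deterministic given data and configuration.
    """
    group = list(group) if group is not None else list(training.chemicals)
    sub = training.subset(group)
    for s in sub.chemicals:
        n_s = len(sub.records_for(s))
        if n_s < 4:
            raise InvalidDataError(
                f"chemical {s!r} has {n_s} records; leave-one-out needs >= 4"
            )

    na = len(sub.chemicals)
    n_samples = {s: len(sub.records_for(s)) for s in sub.chemicals}
    per_sample = []
    if na == 1:
        # Single-candidate group: every prediction is trivially correct.
        per_sample = [(r.label, r.label) for r in sub.records]
        acc = 1.0
    else:
        for idx, rec in enumerate(sub.records):
            rest = TrainingSet(
                records=[r for j, r in enumerate(sub.records) if j != idx],
                chemicals=sub.chemicals,
            )
            models = fit_model_functions(rest, basis=basis)
            pred = classify(rec, models, classifier_config)
            per_sample.append((rec.label, pred))
        acc = sum(t == p for t, p in per_sample) / len(per_sample)

    rate = rs_rate(na)
    n_total = len(sub.records)
    return EvaluationReport(
        group=sub.chemicals,
        n_samples=n_samples,
        accuracy=acc,
        rs_rate=rate,
        rs_sd=rs_sd_mc(n_total, na, reps=rs_reps, seed=rs_seed),
        rs_tail_prob=rs_tail_probability(acc, n_total, na),
        dsi=dsi(acc, rate) if acc > 0 else float("nan"),
        per_sample=per_sample,
        degenerate=(na == 1),
    )


@dataclass
class SpectrumReport:
    """Per-group reports for every k-subset, plus aggregates."""

    k: int
    reports: list  # EvaluationReport per group, in enumerate_groups order
    mean_accuracy: float
    mean_dsi: float
    matrix: pd.DataFrame | None = None  # pairwise accuracy matrix when k == 2


def accuracy_spectrum(
    training: TrainingSet,
    k: int,
    basis: str = "linear",
    classifier_config: ClassifierConfig | None = None,
    rs_reps: int = 10_000,
    rs_seed: int = 0,
) -> SpectrumReport:
    """LOO accuracy for every k-subset of the training chemicals.

    For k = 2 the result also carries the symmetric pairwise accuracy matrix
    (diagonal undefined, NaN).
    """
    groups = enumerate_groups(training.chemicals, k)
    reports = [
        loo_accuracy(
            training, g, basis=basis, classifier_config=classifier_config,
            rs_reps=rs_reps, rs_seed=rs_seed,
        )
        for g in groups
    ]
    accs = np.array([r.accuracy for r in reports])
    dsis = np.array([r.dsi for r in reports])
    matrix = None
    if k == 2:
        labels = list(training.chemicals)
        matrix = pd.DataFrame(np.nan, index=labels, columns=labels)
        for rep in reports:
            a, b = rep.group
            matrix.loc[a, b] = rep.accuracy
            matrix.loc[b, a] = rep.accuracy
    return SpectrumReport(
        k=k,
        reports=reports,
        mean_accuracy=float(accs.mean()),
        mean_dsi=float(np.nanmean(dsis)),
        matrix=matrix,
    )
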