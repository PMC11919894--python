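"""Screening statistics for comparator-aware model evaluation.

Covers the whole evaluation protocol of a screening study: 2x2 confusion
tables and the five derived statistics (accuracy, sensitivity, specificity,
PPV, NPV) with percentile-bootstrap confidence intervals; ROC curves and
AUC; two operating points — the Youden-J maximizer and the threshold
matching a comparator's sensitivity (so specificities can be compared on
equal footing); McNemar's paired test on discordant counts; decision-curve
net benefit against treat-all/treat-none and a fixed comparator; and
per-finding reports where, for each abnormality F, the positives are the
records carrying F and the negatives are all other records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n < 1:
            raise ValueError("table must contain at least one record")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_table(predicted_flags: Sequence[bool],
                    truth_flags: Sequence[bool]) -> ConfusionTable:
    pred = np.asarray(predicted_flags, dtype=bool)
    truth = np.asarray(truth_flags, dtype=bool)
    if pred.shape != truth.shape or pred.ndim != 1 or len(pred) < 1:
        raise ValueError("predicted and truth flags must be equal-length 1-D")
    return ConfusionTable(
        tp=int(np.sum(pred & truth)), fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)), tn=int(np.sum(~pred & ~truth)))


@dataclass(frozen=True)
class Estimate:
    """A proportion with a 95% confidence interval."""

    value: float
    ci_low: float
    ci_high: float

    def round(self, nd: int = 2) -> tuple[float, float, float]:
        return (round(self.value, nd), round(self.ci_low, nd), round(self.ci_high, nd))


@dataclass
class MetricsReport:
    accuracy: Optional[Estimate]
    sensitivity: Optional[Estimate]
    specificity: Optional[Estimate]
    ppv: Optional[Estimate]
    npv: Optional[Estimate]
    n: int
    ci_method: str = "percentile_bootstrap"

    def as_dict(self) -> dict:
        out = {"n": self.n, "ci_method": self.ci_method}
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            est = getattr(self, name)
            out[name] = None if est is None else {
                "value": est.value, "ci_low": est.ci_low, "ci_high": est.ci_high}
        return out


def _stat_arrays(tp, fp, fn, tn):
    """Vectorized five statistics; zero denominators give nan."""
    n = tp + fp + fn + tn
    with np.errstate(invalid="ignore", divide="ignore"):
        return {
            "accuracy": (tp + tn) / n,
            "sensitivity": np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), np.nan),
            "specificity": np.where(tn + fp > 0, tn / np.maximum(tn + fp, 1), np.nan),
            "ppv": np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan),
            "npv": np.where(tn + fn > 0, tn / np.maximum(tn + fn, 1), np.nan),
        }


def metrics(table: ConfusionTable, n_boot: int = 2000, seed: int = 0,
            alpha: float = 0.05) -> MetricsReport:
    """Point estimates plus percentile-bootstrap CIs (records resampled).

    Resampling records of a fixed 2x2 table is a multinomial draw over its
    four cells, which is how the replicates are generated. A statistic
    whose denominator is empty is reported as ``None`` (undefined), never
    as zero.
    """
    counts = np.array([table.tp, table.fp, table.fn, table.tn], dtype=float)
    point = _stat_arrays(*counts)
    rng = np.random.default_rng(seed)
    reps = rng.multinomial(table.n, counts / table.n, size=n_boot).astype(float)
    boot = _stat_arrays(reps[:, 0], reps[:, 1], reps[:, 2], reps[:, 3])
    out = {}
    for name, value in point.items():
        if np.isnan(value):
            out[name] = None
            continue
        samples = boot[name]
        samples = samples[~np.isnan(samples)]
        lo, hi = np.percentile(samples, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        out[name] = Estimate(float(value), float(lo), float(hi))
    return MetricsReport(n=table.n, **out)


# ---------------------------------------------------------------------------
# ROC, thresholds
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    thresholds: np.ndarray      # decreasing; records flagged when prob >= t
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    probabilities: np.ndarray = field(repr=False, default=None)
    truth: np.ndarray = field(repr=False, default=None)


def roc_auc(probabilities: Sequence[float], truth_flags: Sequence[bool]) -> ROCCurve:
    """Threshold sweep over unique probabilities; AUC by the trapezoid rule.

    Equal probabilities are grouped into a single threshold, so the AUC
    equals the tie-corrected rank-sum statistic.
    """
    probs = np.asarray(probabilities, dtype=float)
    truth = np.asarray(truth_flags, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(truth, probs, drop_intermediate=False)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr,
                    auc=float(_sk_auc(fpr, tpr)),
                    probabilities=probs, truth=truth)


def _candidate_thresholds(probs: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent unique probabilities, plus outer values."""
    u = np.unique(probs)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def youden_threshold(roc: ROCCurve) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties break toward the higher threshold (higher specificity). The
    returned value is a midpoint between adjacent observed probabilities,
    so it sits strictly between the groups it separates.
    """
    probs, truth = roc.probabilities, roc.truth
    cands = _candidate_thresholds(probs)
    best_t, best_j = cands[0], -np.inf
    for t in cands:
        flag = probs >= t
        tpr = np.mean(flag[truth])
        fpr = np.mean(flag[~truth])
        j = tpr - fpr
        if j > best_j or (j == best_j and t > best_t):
            best_j, best_t = j, t
    return float(best_t)


def matched_sensitivity_threshold(probabilities: Sequence[float],
                                  truth_flags: Sequence[bool],
                                  target_sensitivity: float) -> float:
    """Largest threshold whose sensitivity is at least the target.

    Maximizes specificity subject to the sensitivity floor; used to compare
    the model's specificity with a comparator's at equal sensitivity.
    """
    if not (0.0 < target_sensitivity <= 1.0):
        raise ValueError("target sensitivity must lie in (0, 1]")
    probs = np.asarray(probabilities, dtype=float)
    truth = np.asarray(truth_flags, dtype=bool)
    pos = np.sort(probs[truth])[::-1]
    if len(pos) == 0:
        raise ValueError("no positive records")
    k = math.ceil(target_sensitivity * len(pos) - 1e-12)
    return float(pos[k - 1])


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedOutcome:
    """Paired classifier outcomes: ``b`` = comparator correct only,
    ``c`` = model correct only, plus the two concordant counts."""

    b: int
    c: int
    both_correct: int = 0
    both_wrong: int = 0

    @property
    def n(self) -> int:
        return self.b + self.c + self.both_correct + self.both_wrong


def paired_outcome(model_correct: Sequence[bool],
                   comparator_correct: Sequence[bool]) -> PairedOutcome:
    m = np.asarray(model_correct, dtype=bool)
    c = np.asarray(comparator_correct, dtype=bool)
    if m.shape != c.shape:
        raise ValueError("paired outcome vectors must have equal length")
    return PairedOutcome(
        b=int(np.sum(c & ~m)), c=int(np.sum(m & ~c)),
        both_correct=int(np.sum(m & c)), both_wrong=int(np.sum(~m & ~c)))


def mcnemar_test(pairs: PairedOutcome) -> float:
    """Two-sided McNemar p-value on the discordant counts.

    Exact binomial when b + c < 25, continuity-corrected chi-square
    ((|b-c|-1)^2/(b+c)) otherwise. Returns 1.0 when there are no
    discordant pairs.
    """
    b, c = pairs.b, pairs.c
    n = b + c
    if n == 0:
        return 1.0
    if n < 25:
        k = min(b, c)
        p = 2.0 * float(stats.binom.cdf(k, n, 0.5))
        if b == c:   # the central term is counted twice
            p -= float(stats.binom.pmf(k, n, 0.5))
        return min(1.0, p)
    chi2 = (abs(b - c) - 1.0) ** 2 / n
    return float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Decision curve analysis
# ---------------------------------------------------------------------------

@dataclass
class DecisionCurve:
    pt: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_comparator: Optional[np.ndarray]
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray
    prevalence: float
    test_harm: float = 0.0


def _net_benefit(flag: np.ndarray, truth: np.ndarray, pt: float,
                 harm: float) -> float:
    n = len(truth)
    tp = np.sum(flag & truth) / n
    fp = np.sum(flag & ~truth) / n
    return float(tp - fp * pt / (1.0 - pt) - harm)


def decision_curve(probabilities: Sequence[float], truth_flags: Sequence[bool],
                   comparator_flags: Optional[Sequence[bool]] = None,
                   pt_grid: Optional[Sequence[float]] = None,
                   test_harm: float = 0.0) -> DecisionCurve:
    """Net benefit of the model across threshold probabilities.

    At each pt the model treats records with probability >= pt;
    the comparator (if given) applies its fixed flags at every pt;
    treat-all and treat-none reference curves are included. The test harm
    constant (default 0) is subtracted from every tested strategy.
    """
    probs = np.asarray(probabilities, dtype=float)
    truth = np.asarray(truth_flags, dtype=bool)
    if pt_grid is None:
        pt_grid = np.linspace(0.01, 0.99, 99)
    pt = np.asarray(pt_grid, dtype=float)
    if np.any((pt <= 0) | (pt >= 1)):
        raise ValueError("threshold probabilities must lie strictly in (0, 1)")
    prevalence = float(np.mean(truth))
    all_flag = np.ones_like(truth)
    comp = np.asarray(comparator_flags, dtype=bool) if comparator_flags is not None else None
    nb_model = np.array([_net_benefit(probs >= t, truth, t, test_harm) for t in pt])
    nb_all = np.array([_net_benefit(all_flag, truth, t, test_harm) for t in pt])
    nb_comp = (np.array([_net_benefit(comp, truth, t, test_harm) for t in pt])
               if comp is not None else None)
    return DecisionCurve(pt=pt, net_benefit_model=nb_model,
                         net_benefit_comparator=nb_comp,
                         net_benefit_all=nb_all,
                         net_benefit_none=np.zeros_like(pt) - test_harm,
                         prevalence=prevalence, test_harm=test_harm)


# ---------------------------------------------------------------------------
# Per-finding reports
# ---------------------------------------------------------------------------

@dataclass
class PerFindingReport:
    rows: dict[str, dict]

    def to_markdown(self) -> str:
        header = ("| Finding | n | Comparator sens | Comparator spec | "
                  "Model sens (matched) | Model spec | McNemar p |")
        sep = "|" + "---|" * 7
        lines = [header, sep]
        for name, r in self.rows.items():
            lines.append(
                f"| {name} | {r['n_positive']} "
                f"| {r['comparator']['sensitivity']:.2f} "
                f"| {r['comparator']['specificity']:.2f} "
                f"| {r['model']['sensitivity']:.2f} "
                f"| {r['model']['specificity']:.2f} "
                f"| {r['mcnemar_p']:.3g} |")
        return "\n".join(lines)


def per_finding_evaluation(probabilities: Sequence[float],
                           truth_findings: Sequence[set],
                           comparator_flags: Sequence[bool],
                           finding_list: Sequence[str],
                           warn=print) -> PerFindingReport:
    """Comparator vs model at matched sensitivity, per abnormality.

    For finding F: positives are records whose findings contain F and
    negatives are ALL other records, including those with different
    abnormalities. The model threshold is set so its sensitivity on F
    matches the comparator's; McNemar's test is applied to the paired
    specificity outcomes over the negative set.
    """
    probs = np.asarray(probabilities, dtype=float)
    comp = np.asarray(comparator_flags, dtype=bool)
    rows = {}
    for finding in finding_list:
        y = np.array([finding in f for f in truth_findings])
        if not y.any():
            warn(f"finding {finding!r} absent from the cohort; skipped")
            continue
        comp_sens = float(np.mean(comp[y]))
        comp_spec = float(np.mean(~comp[~y]))
        if comp_sens > 0:
            thr = matched_sensitivity_threshold(probs, y, comp_sens)
            model_flag = probs >= thr
        else:
            thr = float(np.max(probs) + 1.0)   # comparator finds none: flag none
            model_flag = np.zeros_like(y)
        model_sens = float(np.mean(model_flag[y]))
        model_spec = float(np.mean(~model_flag[~y]))
        neg = ~y
        pairs = paired_outcome(model_correct=~model_flag[neg],
                               comparator_correct=~comp[neg])
        rows[finding] = {
            "n_positive": int(y.sum()),
            "threshold": float(thr),
            "comparator": {"sensitivity": comp_sens, "specificity": comp_spec},
            "model": {"sensitivity": model_sens, "specificity": model_spec},
            "mcnemar_p": mcnemar_test(pairs),
            "discordant": {"b": pairs.b, "c": pairs.c},
        }
    return PerFindingReport(rows=rows)
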