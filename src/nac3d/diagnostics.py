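"""Diagnostic evaluation of tumour-to-NAC distances against pathology.

A short distance predicts occult nipple involvement, so a patient is called
positive when the measured distance falls at or below a cut-off (the "<="
convention of the published cut-off columns; the strict "<" reading of the
prose definition is available via ``convention="lt"``).  The module provides
2x2 contingency tables over a cut-off grid, sensitivity / specificity /
PPV / NPV / accuracy with exact Clopper-Pearson binomial intervals, the ROC
curve with its Mann-Whitney AUC, the Youden-optimal cut-off, and DeLong's
paired test for comparing the AUCs of two distance methods measured on the
same patients.

Reporting conventions: metrics to one decimal of a percent, confidence
bounds to integer percent, both with half-up rounding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateCohortError


@dataclass(frozen=True)
class CohortRecord:
    patient_id: str
    distance_mm: float
    nac_involved: bool

    def __post_init__(self):
        if self.distance_mm < 0:
            raise ValueError("distance must be >= 0")


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    tn: int
    fn: int
    cutoff_mm: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_involved(self) -> int:
        return self.tp + self.fn

    @property
    def n_uninvolved(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class DiagnosticSummary:
    """Point estimates in percent (one decimal) with exact 95% CIs (integer
    percent).  Metrics with an empty denominator are NaN and listed in
    ``undefined``."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    ci95: dict[str, tuple[int, int]] = field(default_factory=dict)
    undefined: frozenset[str] = frozenset()
    table: ContingencyTable | None = None


@dataclass(frozen=True)
class RocAnalysis:
    thresholds: np.ndarray  # observed distances, sorted ascending
    points: np.ndarray  # (m, 2) of (1 - specificity, sensitivity), with origin
    auc: float
    best_cutoff_mm: float
    youden_at_best: float
    convention: str = "le"


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal-style half-up rounding (what the printed tables use)."""
    factor = 10.0**decimals
    return math.floor(value * factor + 0.5) / factor


def _calls(distances: np.ndarray, cutoff: float, convention: str) -> np.ndarray:
    if convention == "le":
        return distances <= cutoff
    if convention == "lt":
        return distances < cutoff
    raise ValueError(f"convention must be 'le' or 'lt', got {convention!r}")


def build_contingency(
    records: list[CohortRecord], cutoff_mm: float, convention: str = "le"
) -> ContingencyTable:
    """Tally predicted-positive (distance at/below cut-off) against pathology."""
    if not records:
        raise ValueError("empty cohort")
    d = np.array([r.distance_mm for r in records], dtype=float)
    y = np.array([r.nac_involved for r in records], dtype=bool)
    if y.all() or not y.any():
        warnings.warn("degenerate cohort: only one pathology class present", stacklevel=2)
    pos = _calls(d, cutoff_mm, convention)
    return ContingencyTable(
        tp=int(np.sum(pos & y)),
        fp=int(np.sum(pos & ~y)),
        tn=int(np.sum(~pos & ~y)),
        fn=int(np.sum(~pos & y)),
        cutoff_mm=float(cutoff_mm),
    )


def clopper_pearson_ci(
    successes: int, n: int, level: float = 0.95, as_int: bool = True
) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) interval, in percent.

    Bounds come from beta-distribution quantiles; by default they are
    rounded half-up to integer percent, the convention of the reported
    intervals (e.g. 141/154 -> (86, 95))."""
    if not (0 <= successes <= n) or n <= 0:
        raise ValueError(f"need 0 <= successes <= n with n > 0, got {successes}/{n}")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else stats.beta.ppf(alpha / 2, successes, n - successes + 1)
    upper = 1.0 if successes == n else stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    lo, hi = 100.0 * lower, 100.0 * upper
    if as_int:
        return round_half_up(lo), round_half_up(hi)
    return lo, hi


def _metric(num: int, den: int) -> float:
    return round_half_up(100.0 * num / den, 1) if den > 0 else float("nan")


def diagnostic_metrics(table: ContingencyTable, level: float = 0.95) -> DiagnosticSummary:
    """Sensitivity / specificity / PPV / NPV / accuracy with exact CIs.

    Zero-denominator metrics are NaN and flagged, never a division error.
    """
    pairs = {
        "sensitivity": (table.tp, table.tp + table.fn),
        "specificity": (table.tn, table.tn + table.fp),
        "ppv": (table.tp, table.tp + table.fp),
        "npv": (table.tn, table.tn + table.fn),
        "accuracy": (table.tp + table.tn, table.n),
    }
    values = {k: _metric(num, den) for k, (num, den) in pairs.items()}
    undefined = frozenset(k for k, (_, den) in pairs.items() if den == 0)
    ci95 = {
        k: clopper_pearson_ci(num, den, level)
        for k, (num, den) in pairs.items()
        if den > 0
    }
    return DiagnosticSummary(**values, ci95=ci95, undefined=undefined, table=table)


def reconstruct_table(
    sensitivity_pct: float,
    specificity_pct: float,
    n_involved: int,
    n_uninvolved: int,
    cutoff_mm: float = float("nan"),
) -> ContingencyTable:
    """Recover the integer 2x2 table behind printed sensitivity/specificity.

    Finds the unique tp (tn) whose one-decimal percentage re-rounds to the
    printed value; raises when no or multiple integers match.
    """

    def solve(pct: float, n: int, name: str) -> int:
        hits = [k for k in range(n + 1) if round_half_up(100.0 * k / n, 1) == pct]
        if len(hits) != 1:
            raise ValueError(
                f"{name} {pct}% is consistent with {len(hits)} integer counts out of {n}"
            )
        return hits[0]

    tp = solve(sensitivity_pct, n_involved, "sensitivity")
    tn = solve(specificity_pct, n_uninvolved, "specificity")
    return ContingencyTable(tp=tp, fp=n_uninvolved - tn, tn=tn, fn=n_involved - tp,
                            cutoff_mm=cutoff_mm)


# -- ROC --------------------------------------------------------------------


def roc_curve(records: list[CohortRecord], convention: str = "le") -> RocAnalysis:
    """ROC over all observed distances, trapezoidal AUC, Youden best cut-off.

    The threshold grid is every observed distance plus the "call nothing"
    extreme, so the trapezoidal AUC equals the Mann-Whitney concordance
    probability (ties counted 1/2).  The best cut-off maximises Youden's
    J = sensitivity + specificity - 1, ties resolved toward the smaller
    cut-off.
    """
    d = np.array([r.distance_mm for r in records], dtype=float)
    y = np.array([r.nac_involved for r in records], dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateCohortError("ROC needs both involved and uninvolved patients")

    thresholds = np.unique(d)
    points = [(0.0, 0.0)]  # below every observed distance: no positive calls
    js = []
    for t in thresholds:
        pos = _calls(d, t, convention)
        tpr = np.sum(pos & y) / n1
        fpr = np.sum(pos & ~y) / n0
        points.append((fpr, tpr))
        js.append(tpr - fpr)
    points = np.asarray(points)
    if convention == "lt":  # grid needs a beyond-maximum point to reach (1,1)
        points = np.vstack([points, [1.0, 1.0]])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    best_i = int(np.argmax(js))  # first occurrence = smallest cutoff on ties
    return RocAnalysis(
        thresholds=thresholds,
        points=points,
        auc=auc,
        best_cutoff_mm=float(thresholds[best_i]),
        youden_at_best=float(js[best_i]),
        convention=convention,
    )


def best_cutoff(roc: RocAnalysis) -> float:
    """The cut-off maximising Youden's J on the ROC threshold grid."""
    return roc.best_cutoff_mm


def mann_whitney_auc(records: list[CohortRecord]) -> float:
    """Brute-force concordance probability P(d_involved < d_uninvolved) with
    ties counted 1/2 — the rank-statistic identity the trapezoidal AUC must
    satisfy."""
    d = np.array([r.distance_mm for r in records], dtype=float)
    y = np.array([r.nac_involved for r in records], dtype=bool)
    pos, neg = d[y], d[~y]
    less = (pos[:, None] < neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((less + 0.5 * ties) / (len(pos) * len(neg)))


# -- DeLong paired AUC comparison ------------------------------------------


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def _delong_auc_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and its structural components V10 (per positive) and V01 (per
    negative), via the midrank algorithm."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    tx = _midranks(pos)
    ty = _midranks(neg)
    tz = _midranks(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p_value: float


def compare_auc(
    distances_a, distances_b, nac_involved, *, higher_means_positive: bool = False
) -> DeLongResult:
    """DeLong's paired test for the difference of two correlated AUCs.

    Both distance methods must be measured on the same patients (equal-length
    arrays aligned to the same pathology labels).  Distances are negated
    internally so that the conventional "higher score = more positive"
    orientation applies; the resulting AUCs match :func:`roc_curve`.
    """
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    y = np.asarray(nac_involved, dtype=bool)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("paired comparison needs equal-length, aligned inputs")
    if y.all() or not y.any():
        raise DegenerateCohortError("need both classes for an AUC comparison")
    if not higher_means_positive:
        a, b = -a, -b

    auc_a, v10_a, v01_a = _delong_auc_components(a, y)
    auc_b, v10_b, v01_b = _delong_auc_components(b, y)
    m, n = int(y.sum()), int((~y).sum())
    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var <= np.finfo(float).eps:  # identical methods: no evidence of a difference
        z = 0.0 if abs(diff) < 1e-12 else math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(var)
    p = 1.0 if z == 0.0 else float(2.0 * stats.norm.sf(abs(z)))
    return DeLongResult(auc_a=float(auc_a), auc_b=float(auc_b), z=float(z), p_value=p)
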