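"""Chi-deviation metrics, sequential accuracy, MAD-chi, and the paired
statistical battery for method comparison.

A chi angle counts as correct when its (symmetry-corrected) deviation is at
most 40 degrees, and chi_k only counts when chi_1..chi_k are all correct
(the sequential criterion).  Per-amino-acid accuracy is

    Accuracy = (N1 + N12 + N123 + N1234) / (n_chi * N_res) * 100

where N_k is the number of residues whose first k chi angles are all
correct.  MAD-chi pools the symmetry-corrected per-chi deviations over all
residues and chi positions.  Residues a method cannot predict (off-grid) are
excluded symmetrically from both methods' denominators.

The paired comparison operates on per-residue mean deviations: a paired
two-tailed t-test with Cohen's d, a seeded percentile bootstrap of the mean
difference, McNemar's test on categorical correctness, and a Bonferroni
threshold for the per-amino-acid family of tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .geometry import NCHI, wrap_angle

__all__ = [
    "CORRECT_THRESHOLD",
    "DEFAULT_SYMMETRIC_SET",
    "DeviationRecord",
    "EvaluationReport",
    "chi_deviation",
    "symmetry_correct",
    "deviation_record",
    "correct_prefix",
    "accuracy",
    "mad_chi",
    "build_report",
    "paired_ttest",
    "bootstrap_ci",
    "mcnemar",
    "bonferroni_threshold",
]

CORRECT_THRESHOLD = 40.0

#: (aa, chi index 1-based) pairs whose deviation is two-fold degenerate.
DEFAULT_SYMMETRIC_SET = frozenset({("ASP", 2), ("PHE", 2), ("TYR", 2),
                                   ("VAL", 1)})


class EvaluationError(ValueError):
    pass


def chi_deviation(pred: float, true: float) -> float:
    """Periodic absolute difference, min(|d|, 360 - |d|), in [0, 180]."""
    d = abs(wrap_angle(pred) - wrap_angle(true))
    return min(d, 360.0 - d)


def symmetry_correct(delta: float, aa: str, chi_index: int,
                     symmetric_set=DEFAULT_SYMMETRIC_SET) -> float:
    """Fold two-fold-symmetric chi deviations into [0, 90]."""
    if not (0.0 <= delta <= 180.0):
        raise EvaluationError("delta must be in [0, 180]")
    if (aa, chi_index) in symmetric_set:
        return min(delta, 180.0 - delta)
    return delta


@dataclass(frozen=True)
class DeviationRecord:
    aa_type: str
    deltas: tuple[float, ...]          # symmetry-corrected, degrees
    corrected: tuple[bool, ...]
    correct_prefix_len: int


def correct_prefix(deltas: Sequence[float],
                   threshold: float = CORRECT_THRESHOLD) -> int:
    """Longest k with delta_1..delta_k all <= threshold (inclusive)."""
    k = 0
    for d in deltas:
        if d <= threshold:
            k += 1
        else:
            break
    return k


def deviation_record(aa: str, pred_chi: Sequence[float],
                     true_chi: Sequence[float],
                     threshold: float = CORRECT_THRESHOLD,
                     symmetric_set=DEFAULT_SYMMETRIC_SET) -> DeviationRecord:
    """Per-chi deviations of one prediction, with symmetry correction."""
    if len(pred_chi) != len(true_chi):
        raise EvaluationError("chi vectors differ in length")
    deltas = []
    corrected = []
    for k, (p, t) in enumerate(zip(pred_chi, true_chi), start=1):
        d = chi_deviation(p, t)
        ds = symmetry_correct(d, aa, k, symmetric_set)
        deltas.append(ds)
        corrected.append((aa, k) in symmetric_set)
    return DeviationRecord(aa, tuple(deltas), tuple(corrected),
                           correct_prefix(deltas, threshold))


def accuracy(records: Sequence[DeviationRecord], aa: str) -> float:
    """Sequential chi accuracy in percent for one amino acid."""
    recs = [r for r in records if r.aa_type == aa]
    if not recs:
        raise EvaluationError(f"no records for {aa}")
    nchi = NCHI[aa]
    total = sum(min(r.correct_prefix_len, nchi) for r in recs)
    return 100.0 * total / (nchi * len(recs))


def mad_chi(records: Sequence[DeviationRecord],
            per_residue_mean: bool = False) -> float:
    """Mean absolute angular deviation in degrees.

    Default pools every per-chi deviation; ``per_residue_mean`` averages the
    per-residue means instead (the unit used for paired testing).
    """
    if not records:
        raise EvaluationError("no records")
    if per_residue_mean:
        return float(np.mean([np.mean(r.deltas) for r in records]))
    pooled = [d for r in records for d in r.deltas]
    return float(np.mean(pooled))


@dataclass
class EvaluationReport:
    per_aa: dict                       # aa -> row dict
    overall_accuracy: float
    overall_mad: float
    excluded: int

    def to_rows(self) -> list[dict]:
        rows = [dict(aa=aa, **v) for aa, v in sorted(self.per_aa.items())]
        rows.append(dict(aa="Average", n_res=sum(v["n_res"] for v in self.per_aa.values()),
                         accuracy=self.overall_accuracy, mad_chi=self.overall_mad))
        return rows


def build_report(records: Sequence[DeviationRecord],
                 excluded: int = 0) -> EvaluationReport:
    """Per-amino-acid N_k counts, accuracy and MAD-chi, plus overall means."""
    if not records:
        raise EvaluationError("no records to report")
    per_aa: dict[str, dict] = {}
    for aa in sorted({r.aa_type for r in records}):
        recs = [r for r in records if r.aa_type == aa]
        nchi = NCHI[aa]
        nk = [sum(1 for r in recs if r.correct_prefix_len >= k)
              for k in range(1, 5)]
        row = {
            "n_res": len(recs),
            "N1": nk[0], "N12": nk[1], "N123": nk[2], "N1234": nk[3],
            "accuracy": accuracy(recs, aa),
            "mad_chi": mad_chi(recs),
        }
        assert row["N1"] >= row["N12"] >= row["N123"] >= row["N1234"] >= 0
        per_aa[aa] = row
    overall_acc = float(np.mean([v["accuracy"] for v in per_aa.values()]))
    overall_mad = float(np.mean([d for r in records for d in r.deltas]))
    return EvaluationReport(per_aa, overall_acc, overall_mad, excluded)


# ---------------------------------------------------------------------------
# paired statistics


def paired_ttest(deltas: Sequence[float]) -> dict:
    """Paired two-tailed t-test on per-residue deviation differences.

    ``deltas`` holds delta_method2 - delta_method1, one value per residue.
    Returns mean difference, 95% CI, t, two-sided p and Cohen's d (mean/sd).
    """
    d = np.asarray(deltas, dtype=float)
    n = d.size
    if n < 2:
        raise EvaluationError("need at least two paired differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean != 0.0:
            raise EvaluationError("zero variance with nonzero mean difference")
        return {"mean": 0.0, "ci95": (0.0, 0.0), "t": 0.0, "p": 1.0,
                "cohens_d": 0.0, "n": n}
    se = sd / math.sqrt(n)
    t = mean / se
    p = 2.0 * _sps.t.sf(abs(t), df=n - 1)
    tcrit = _sps.t.ppf(0.975, df=n - 1)
    return {"mean": mean, "ci95": (mean - tcrit * se, mean + tcrit * se),
            "t": t, "p": float(p), "cohens_d": mean / sd, "n": n}


def bootstrap_ci(deltas: Sequence[float], n_boot: int = 1000,
                 seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Seeded percentile bootstrap interval of the mean difference."""
    d = np.asarray(deltas, dtype=float)
    if d.size < 2:
        raise EvaluationError("need at least two values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    means = d[idx].mean(axis=1)
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(means, lo)),
            float(np.quantile(means, 1.0 - lo)))


def mcnemar(table: Sequence[Sequence[float]],
            correction: bool = False) -> dict:
    """McNemar chi-square test on a 2x2 both-methods-correct table.

    ``table[0][1]`` (b) and ``table[1][0]`` (c) are the discordant counts.
    Without continuity correction the statistic is (b - c)^2 / (b + c);
    with ``correction`` it is (|b - c| - 1)^2 / (b + c).  b + c = 0 returns
    statistic 0 and p = 1 (no discordance).
    """
    b = float(table[0][1])
    c = float(table[1][0])
    if b < 0 or c < 0:
        raise EvaluationError("discordant counts must be nonnegative")
    if b + c == 0:
        return {"statistic": 0.0, "p": 1.0, "b": b, "c": c}
    num = (abs(b - c) - 1.0) ** 2 if correction else (b - c) ** 2
    stat = num / (b + c)
    return {"statistic": stat, "p": float(_sps.chi2.sf(stat, df=1)),
            "b": b, "c": c}


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise corrected per-test significance level alpha / n_tests."""
    if n_tests < 1:
        raise EvaluationError("n_tests must be >= 1")
    return alpha / n_tests
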