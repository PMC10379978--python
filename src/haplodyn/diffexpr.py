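"""Differential expression by a fixed-dispersion negative-binomial exact test.

With one pooled library per condition no replicate-based dispersion can be
estimated, so the test fixes the biological coefficient of variation (BCV)
and uses the NB dispersion phi = BCV^2 (default BCV 0.1, phi 0.01).

The two libraries are first equalized: both counts are rescaled to the
geometric mean of the library sizes (mean-preserving, rounded back to
integer support).  Conditional on the equalized sum s = y1' + y2', y1' under
the null is distributed as the conditional of two i.i.d. NB variables with
common size r = 1/phi, i.e. a beta-binomial-type pmf

    P(k | s) = C(k + r - 1, k) C(s - k + r - 1, s - k) / C(s + 2r - 1, s).

The two-sided p-value sums P(k | s) over all outcomes no more likely than
the observed one (minimum-likelihood method), capped at 1.  Benjamini-
Hochberg adjustment is applied within each treated-vs-control comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import HaplodynError, SampleMeta, ValidationError

__all__ = [
    "nb_exact_test",
    "log2_fold_change",
    "bh_adjust",
    "run_de",
    "de_summary",
]

# Absolute log-pmf slack when collecting outcomes tied with the observed
# probability: large enough to absorb gammaln round-off at tiny dispersion
# (size parameters up to ~1e8), far below any genuine pmf spacing.
_TIE_LOG_TOL = 1e-6


def _conditional_log_pmf(s: int, r: float) -> np.ndarray:
    """log P(k | s) for k = 0..s under the equal-mean NB conditional."""
    k = np.arange(s + 1, dtype=float)
    return (
        gammaln(k + r)
        - gammaln(k + 1.0)
        + gammaln(s - k + r)
        - gammaln(s - k + 1.0)
        - gammaln(s + 2.0 * r)
        + gammaln(s + 1.0)
        + gammaln(2.0 * r)
        - 2.0 * gammaln(r)
    )


def _equalize(y1: float, y2: float, lib1: float, lib2: float) -> tuple[int, int]:
    """Rescale both counts to the geometric-mean library size (rounded)."""
    if lib1 <= 0 and lib2 <= 0:
        raise ValidationError("both library sizes are zero")
    target = float(np.sqrt(lib1 * lib2))
    y1s = int(np.rint(y1 * target / lib1))
    y2s = int(np.rint(y2 * target / lib2))
    return y1s, y2s


def nb_exact_test(
    y1: int, y2: int, lib1: float = 1.0, lib2: float = 1.0, dispersion: float = 0.01
) -> float:
    """Two-sided exact p-value for equality of relative abundance.

    ``dispersion`` is phi = BCV^2.  Symmetric in its two groups.
    """
    if dispersion <= 0:
        raise ValidationError("dispersion must be positive")
    if y1 < 0 or y2 < 0:
        raise ValidationError("counts must be nonnegative")
    y1s, y2s = _equalize(y1, y2, lib1, lib2)
    s = y1s + y2s
    if s == 0:
        return 1.0
    log_pmf = _conditional_log_pmf(s, 1.0 / dispersion)
    obs = log_pmf[y1s]
    mask = log_pmf <= obs + _TIE_LOG_TOL
    p = float(np.exp(log_pmf[mask]).sum())
    return min(p, 1.0)


def log2_fold_change(
    y_treated: float, y_control: float, lib_t: float, lib_c: float, prior: float = 0.5
) -> float:
    """Shrunken log2 fold change of normalized abundance, treated over
    control; ``prior`` is added to both counts before the ratio."""
    if lib_t <= 0 or lib_c <= 0:
        raise ValidationError("library sizes must be positive")
    return float(np.log2((y_treated + prior) / lib_t) - np.log2((y_control + prior) / lib_c))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# experiment-level driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Comparison:
    treatment: str
    time_h: int

    @property
    def label(self) -> str:
        return f"{self.treatment}_{self.time_h}h"


def _condition_columns(samples: Sequence[SampleMeta]) -> dict[tuple[str, int], list[str]]:
    cols: dict[tuple[str, int], list[str]] = {}
    for s in samples:
        cols.setdefault((s.treatment, s.time_h), []).append(s.sample_id)
    return cols


def _median_ratio_factor(y_t: np.ndarray, y_c: np.ndarray, lib_t: float, lib_c: float) -> float:
    """Median, over genes observed in both conditions, of the treated/control
    ratio of library-scaled counts.  Rescaling the treated library by this
    factor makes the typical (non-DE) gene show no change, which keeps the
    test calibrated when strong DE skews the raw column sums."""
    both = (y_t > 0) & (y_c > 0)
    if both.sum() < 10:
        return 1.0
    ratio = (y_t[both] / lib_t) / (y_c[both] / lib_c)
    return float(np.median(ratio))


def run_de(
    gene_counts: pd.DataFrame,
    samples: Sequence[SampleMeta],
    alpha: float = 0.05,
    bcv: float = 0.1,
    prior: float = 0.5,
    normalization: str = "median_ratio",
) -> tuple[pd.DataFrame, dict]:
    """Test every gene in every treated-vs-control comparison.

    Each (treatment, time) condition is compared against the control at the
    same time point; replicate libraries of a condition are summed.
    ``normalization`` sets the effective library sizes: "median_ratio"
    (column sums rescaled so the median expressed gene is unchanged;
    robust to composition shifts from strongly asymmetric DE) or "library"
    (raw column sums).  Returns the per-gene result table (log2fc, p, BH q,
    direction at level ``alpha``) and the DEG-set summary (per-comparison
    counts, overlap accounting across time points and stresses, and the
    direction-consistent pooled union across all comparisons).
    """
    if normalization not in ("median_ratio", "library"):
        raise ValidationError(f"unknown normalization {normalization!r}")
    phi = bcv * bcv
    cols = _condition_columns(samples)
    comparisons = sorted(
        (Comparison(tr, t) for (tr, t) in cols if tr != "control"),
        key=lambda c: (c.treatment, c.time_h),
    )
    results = []
    for comp in comparisons:
        if ("control", comp.time_h) not in cols:
            raise ValidationError(f"no control sample at {comp.time_h} h for {comp.treatment}")
        y_t = gene_counts[cols[(comp.treatment, comp.time_h)]].sum(axis=1).to_numpy()
        y_c = gene_counts[cols[("control", comp.time_h)]].sum(axis=1).to_numpy()
        lib_t, lib_c = float(y_t.sum()), float(y_c.sum())
        if lib_t == 0 or lib_c == 0:
            raise HaplodynError(f"empty library in comparison {comp.label}")
        if normalization == "median_ratio":
            lib_t = lib_t * _median_ratio_factor(y_t, y_c, lib_t, lib_c)
        p = np.array(
            [nb_exact_test(int(t), int(c), lib_t, lib_c, phi) for t, c in zip(y_t, y_c)]
        )
        q = bh_adjust(p)
        lfc = np.log2((y_t + prior) / lib_t) - np.log2((y_c + prior) / lib_c)
        direction = np.where(q <= alpha, np.where(lfc > 0, "up", np.where(lfc < 0, "down", "ns")), "ns")
        results.append(
            pd.DataFrame(
                {
                    "gene_id": gene_counts.index,
                    "treatment": comp.treatment,
                    "time_h": comp.time_h,
                    "log2fc": lfc,
                    "p_value": p,
                    "q_value": q,
                    "direction": direction,
                }
            )
        )
    table = pd.concat(results, ignore_index=True)
    return table, de_summary(table)


def _deg_sets(table: pd.DataFrame) -> dict[tuple[str, int, str], set[str]]:
    sets: dict[tuple[str, int, str], set[str]] = {}
    for (tr, t, d), sub in table[table["direction"] != "ns"].groupby(
        ["treatment", "time_h", "direction"]
    ):
        sets[(tr, int(t), d)] = set(sub["gene_id"])
    return sets


def de_summary(table: pd.DataFrame) -> dict:
    """Per-comparison up/down counts plus the overlap accounting between
    time points (within each stress) and between stresses (at equal times),
    and the direction-consistent pooled union."""
    from .enrich_intersect import upset_counts  # set algebra lives there

    sets = _deg_sets(table)
    treatments = sorted({tr for tr, _, _ in sets})
    times = sorted({t for _, t, _ in sets})

    def get(tr, t, d):
        return sets.get((tr, t, d), set())

    per_comparison = {}
    for (tr, t), sub in table.groupby(["treatment", "time_h"]):
        per_comparison[f"{tr}_{t}h"] = {
            "n_up": int((sub["direction"] == "up").sum()),
            "n_down": int((sub["direction"] == "down").sum()),
        }

    within_treatment = {
        tr: {
            d: upset_counts({f"{t}h": get(tr, t, d) for t in times})["regions"]
            for d in ("up", "down")
        }
        for tr in treatments
    }
    between_treatments = {
        f"{t}h": {
            d: upset_counts({tr: get(tr, t, d) for tr in treatments})["regions"]
            for d in ("up", "down")
        }
        for t in times
    }

    up_any = set().union(*(get(tr, t, "up") for tr in treatments for t in times))
    down_any = set().union(*(get(tr, t, "down") for tr in treatments for t in times))
    union_up = sorted(up_any - down_any)
    union_down = sorted(down_any - up_any)
    conflicting = sorted(up_any & down_any)
    return {
        "per_comparison": per_comparison,
        "within_treatment": within_treatment,
        "between_treatments": between_treatments,
        "pooled_union": {
            "n_up": len(union_up),
            "n_down": len(union_down),
            "n_conflicting": len(conflicting),
            "up": union_up,
            "down": union_down,
            "conflicting": conflicting,
        },
    }
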