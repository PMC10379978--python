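"""Allele-specific expression calling and bias-trajectory classification.

A gene pair is called biased in a condition when one allele's FPKM is at
least ``fold`` (default 2) times the other's; pairs whose higher allele
stays below an expression floor are NOT_EXPRESSED.  Per stressed time point
the collapsed biased(B)/no-bias(N) triplet over (control, NaCl, PEG) falls
into one of seven observable categories:

    CCC  conserved bias (biased in all three)        -> conserved
    BNB, NBN  status change only under NaCl          -> salt-specific
    BBN, NNB  status change only under PEG           -> drought-specific
    BNN, NBB  status change under both treatments    -> both
    NNN  (no bias anywhere) and any NOT_EXPRESSED    -> excluded

The responsiveness accounting satisfies, exactly and on every input:
n_salt_responsive = n_both + n_salt_specific, n_drought_responsive =
n_both + n_drought_specific, n_responsive = universe - conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    HaplodynError,
    SampleMeta,
    ValidationError,
    get_logger,
    models_by_id,
)
from .quantify import fpkm
from .synthetic_data import CATEGORIES

__all__ = [
    "BIAS_A",
    "BIAS_B",
    "NO_BIAS",
    "NOT_EXPRESSED",
    "call_bias",
    "classify_trajectory",
    "summarize_ase",
    "run_ase",
    "RESPONSIVENESS_OF_CATEGORY",
    "round_half_up",
]

BIAS_A = "bias_a"
BIAS_B = "bias_b"
NO_BIAS = "no_bias"
NOT_EXPRESSED = "not_expressed"

#: category -> responsiveness class (categories are collapsed B/N triplets
#: in (control, NaCl, PEG) order; CCC = biased in all three).
RESPONSIVENESS_OF_CATEGORY = {
    "CCC": "conserved",
    "BNB": "salt_specific",
    "NBN": "salt_specific",
    "BBN": "drought_specific",
    "NNB": "drought_specific",
    "BNN": "both",
    "NBB": "both",
}

_log = get_logger("ase")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as used for reported
    percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def call_bias(
    fpkm_a: float,
    fpkm_b: float,
    fold: float = 2.0,
    floor: float = 0.5,
    epsilon: float = 1e-3,
) -> str:
    """Call the allelic-bias status of one gene pair in one condition.

    BIAS_A when allele A is at least ``fold`` times allele B (inclusive
    boundary), BIAS_B symmetrically, NOT_EXPRESSED when the higher allele is
    below ``floor``.  The comparison is multiplicative (a >= fold * b), so
    no division occurs; ``epsilon`` is the pseudocount used only when a
    log2 allelic ratio is reported alongside the call.
    """
    if fpkm_a < 0 or fpkm_b < 0:
        raise ValidationError("FPKM values must be nonnegative")
    if fold <= 1:
        raise ValidationError("fold must exceed 1")
    if max(fpkm_a, fpkm_b) < floor:
        return NOT_EXPRESSED
    if fpkm_a >= fold * fpkm_b:
        return BIAS_A
    if fpkm_b >= fold * fpkm_a:
        return BIAS_B
    return NO_BIAS


def _collapse(status: str) -> str:
    return "B" if status in (BIAS_A, BIAS_B) else "N"


def classify_trajectory(
    status_control: str, status_nacl: str, status_peg: str
) -> tuple[str | None, str]:
    """Map a (control, NaCl, PEG) status triplet to its bias-dynamics
    category and responsiveness class.

    Any NOT_EXPRESSED status excludes the gene (category None); the all-N
    triplet is category "NNN" and also excluded.
    """
    statuses = (status_control, status_nacl, status_peg)
    if any(s == NOT_EXPRESSED for s in statuses):
        return None, "excluded"
    letters = "".join(_collapse(s) for s in statuses)
    if letters == "BBB":
        return "CCC", "conserved"
    if letters == "NNN":
        return "NNN", "excluded"
    return letters, RESPONSIVENESS_OF_CATEGORY[letters]


@dataclass
class ASESummary:
    """Responsiveness accounting per stressed time point plus per-chromosome
    counts of the salt- and drought-responsive gene sets."""

    per_time: dict[int, dict]
    chromosomes: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        out = {"per_time": {str(t): v for t, v in self.per_time.items()}}
        if self.chromosomes is not None:
            out["chromosomes"] = {
                str(col): self.chromosomes[col].to_dict() for col in self.chromosomes.columns
            }
        return out


def summarize_ase(
    trajectories: pd.DataFrame,
    models: Iterable[GeneModel] | None = None,
) -> ASESummary:
    """Aggregate classified trajectories into the responsiveness statistics.

    ``trajectories`` needs columns gene_id, time_h, category,
    responsiveness.  The universe at each time point is the set of
    non-excluded genes (biased in at least one condition); percentages are
    reported half-up to two decimals.
    """
    per_time: dict[int, dict] = {}
    for t in sorted(trajectories["time_h"].unique()):
        sub = trajectories[trajectories["time_h"] == t]
        included = sub[~sub["responsiveness"].isin(["excluded"])]
        cat_counts = {c: int((included["category"] == c).sum()) for c in CATEGORIES}
        universe = len(included)
        resp = included["responsiveness"]
        n_conserved = int((resp == "conserved").sum())
        n_salt_specific = int((resp == "salt_specific").sum())
        n_drought_specific = int((resp == "drought_specific").sum())
        n_both = int((resp == "both").sum())
        n_responsive = universe - n_conserved
        entry = {
            "universe": universe,
            "category_counts": cat_counts,
            "n_conserved": n_conserved,
            "n_responsive": n_responsive,
            "n_salt_specific": n_salt_specific,
            "n_drought_specific": n_drought_specific,
            "n_both": n_both,
            "n_salt_responsive": n_both + n_salt_specific,
            "n_drought_responsive": n_both + n_drought_specific,
            "n_excluded": int(len(sub)) - universe,
            "pct_responsive": round_half_up(100.0 * n_responsive / universe) if universe else 0.0,
            "pct_both_of_responsive": (
                round_half_up(100.0 * n_both / n_responsive) if n_responsive else 0.0
            ),
            "category_pct": {
                c: round_half_up(100.0 * cat_counts[c] / universe) if universe else 0.0
                for c in CATEGORIES
            },
        }
        per_time[int(t)] = entry

    chrom_table = None
    if models is not None:
        chrom_of = {m.gene_id: m.chromosome for m in models}
        resp_cols = {}
        for kind, classes in (
            ("salt_responsive", ("salt_specific", "both")),
            ("drought_responsive", ("drought_specific", "both")),
        ):
            genes = set(
                trajectories.loc[trajectories["responsiveness"].isin(classes), "gene_id"]
            )
            counts: dict[str, int] = {}
            for g in genes:
                chrom = chrom_of.get(g)
                if chrom is not None:
                    counts[chrom] = counts.get(chrom, 0) + 1
            resp_cols[kind] = counts
        chrom_table = pd.DataFrame(resp_cols).fillna(0).astype(int).sort_index()
    return ASESummary(per_time=per_time, chromosomes=chrom_table)


def _condition_sample(
    samples: Sequence[SampleMeta], treatment: str, time_h: int
) -> str | None:
    for s in samples:
        if s.treatment == treatment and s.time_h == time_h:
            return s.sample_id
    return None


def run_ase(
    allele_counts: pd.DataFrame,
    models: Iterable[GeneModel],
    samples: Sequence[SampleMeta],
    fold: float = 2.0,
    floor: float = 0.5,
    epsilon: float = 1e-3,
) -> tuple[pd.DataFrame, ASESummary, dict[str, set[str]]]:
    """Call per-condition bias from allele counts and classify trajectories.

    Allele FPKM uses the gene length for both alleles.  Treated conditions
    at each stressed time point are compared against the control at the same
    time (falling back to the 0 h control when absent).  Returns the
    trajectory table, the summary, and the responsive gene sets (per time
    and cross-time unions).
    """
    model_list = list(models)
    table = models_by_id(model_list)
    paired = [m for m in table.values() if m.has_alleles]
    resolvable = [
        m
        for m in paired
        if m.allele_a_id in allele_counts.index and m.allele_b_id in allele_counts.index
    ]
    n_unpaired = len(allele_counts.index) - 2 * len(resolvable)
    if n_unpaired > 0:
        if n_unpaired > 0.5 * len(allele_counts.index):
            raise HaplodynError(
                f"{n_unpaired} of {len(allele_counts.index)} allele rows cannot be paired"
            )
        _log.warning("excluding %d unpaired allele rows", n_unpaired)

    expr = fpkm(allele_counts, model_list)
    a_ids = [m.allele_a_id for m in resolvable]
    b_ids = [m.allele_b_id for m in resolvable]
    gene_ids = np.array([m.gene_id for m in resolvable])
    expr_a = expr.loc[a_ids].to_numpy()
    expr_b = expr.loc[b_ids].to_numpy()
    col_index = {c: i for i, c in enumerate(expr.columns)}

    def statuses_for(sample_id: str) -> np.ndarray:
        j = col_index[sample_id]
        a = expr_a[:, j]
        b = expr_b[:, j]
        out = np.where(
            a >= fold * b, BIAS_A, np.where(b >= fold * a, BIAS_B, NO_BIAS)
        ).astype(object)
        out[np.maximum(a, b) < floor] = NOT_EXPRESSED
        return out

    times = sorted(
        {s.time_h for s in samples if s.treatment != "control" and s.time_h != 0}
    )
    rows = []
    for t in times:
        ctrl = _condition_sample(samples, "control", t) or _condition_sample(
            samples, "control", 0
        )
        nacl = _condition_sample(samples, "NaCl", t)
        peg = _condition_sample(samples, "PEG", t)
        if ctrl is None or nacl is None or peg is None:
            raise ValidationError(f"missing condition sample at {t} h")
        st_c, st_n, st_p = statuses_for(ctrl), statuses_for(nacl), statuses_for(peg)
        for i, g in enumerate(gene_ids):
            category, responsiveness = classify_trajectory(st_c[i], st_n[i], st_p[i])
            rows.append(
                (
                    g,
                    t,
                    st_c[i],
                    st_n[i],
                    st_p[i],
                    category,
                    responsiveness,
                    st_c[i] != st_n[i]
                    and _collapse(st_c[i]) == "B" == _collapse(st_n[i]),
                    st_c[i] != st_p[i]
                    and _collapse(st_c[i]) == "B" == _collapse(st_p[i]),
                )
            )
    trajectories = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "time_h",
            "status_control",
            "status_nacl",
            "status_peg",
            "category",
            "responsiveness",
            "direction_flip_nacl",
            "direction_flip_peg",
        ],
    )
    summary = summarize_ase(trajectories, model_list)

    gene_sets: dict[str, set[str]] = {}
    for t in times:
        sub = trajectories[trajectories["time_h"] == t]
        gene_sets[f"salt_{t}h"] = set(
            sub.loc[sub["responsiveness"].isin(["salt_specific", "both"]), "gene_id"]
        )
        gene_sets[f"drought_{t}h"] = set(
            sub.loc[sub["responsiveness"].isin(["drought_specific", "both"]), "gene_id"]
        )
    gene_sets["salt_union"] = set().union(*(gene_sets[f"salt_{t}h"] for t in times))
    gene_sets["drought_union"] = set().union(*(gene_sets[f"drought_{t}h"] for t in times))
    return trajectories, summary, gene_sets
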