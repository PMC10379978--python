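"""Allele-resolved RNA-seq count simulator.

Generates the full input bundle the analysis consumes — an allele-level and a
gene-level fragment-count matrix, gene models with allele pairing, and the
pooled-library sample sheet (control at 0/24/48/72 h, NaCl and PEG at
24/48/72 h) — together with a ground-truth table for recovery tests.

Generative model, per gene pair:

* baseline expression: mean fragment count drawn log-normally;
* allelic bias: a fraction ``pi_bias`` of pairs carries a baseline allelic
  log2 ratio r with |r| drawn from ``log2_bias_range`` (|r| >= 1 so a truly
  biased pair satisfies the twofold calling criterion in expectation); the
  expected allele-A share of the gene mean is 2^r / (1 + 2^r);
* bias dynamics: at each stressed time point the collapsed biased/unbiased
  state of the pair under NaCl and under PEG is drawn jointly conditional on
  the control state (`BiasSwitch`); the joint form is needed because losing
  bias under the two osmotic stresses is strongly correlated in observed
  tea-plant data — independent per-treatment switches cannot reproduce the
  observed seven-category proportions;
* differential expression: per treatment, a fraction ``pi_de`` of genes gets
  a log2 fold change from ``log2_de_range`` applied to both alleles;
* co-expression modules: member genes share a per-sample latent log-scale
  factor so that their expected log-expression correlation is
  ``module_cor``; background genes have no extra-NB variation;
* counts: gamma-Poisson.  Each (gene, sample) draws one biological factor
  G ~ Gamma(1/phi, phi) with phi = bcv^2, shared by the two alleles, and
  each allele's count is Poisson(G x gene mean x allele share).  Both the
  allele counts and their sum (the gene count) are then marginally negative
  binomial with Var = mu + phi mu^2 — biological variation acts on the gene,
  not independently on its alleles.  Size factors are log-normal.

Identical seed and config give bitwise-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ConfigurationError,
    GeneModel,
    SampleMeta,
    write_count_matrix,
    write_gene_models,
    write_json,
    write_sample_sheet,
)

__all__ = [
    "CATEGORIES",
    "REFERENCE_CATEGORY_COUNTS",
    "BiasSwitch",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate",
    "table1_preset",
    "expected_category_proportions",
    "write_fixture",
    "nb_counts",
]

#: The seven observable bias-dynamics categories.  Each letter is the
#: collapsed biased(B)/no-bias(N) state in (control, NaCl, PEG) order;
#: "CCC" = biased under all three conditions (conserved bias).
CATEGORIES = ("CCC", "BBN", "BNN", "BNB", "NBN", "NBB", "NNB")

#: Observed per-category gene counts in the tea-plant salt/drought study that
#: this simulator emulates, per stressed time point.  These are the
#: calibration targets of :func:`table1_preset` and double as the reference
#: fixture for the accounting checks.
REFERENCE_CATEGORY_COUNTS: dict[int, dict[str, int]] = {
    24: {"CCC": 1842, "BBN": 130, "BNN": 247, "BNB": 149, "NBN": 221, "NBB": 196, "NNB": 185},
    48: {"CCC": 2123, "BBN": 101, "BNN": 167, "BNB": 124, "NBN": 198, "NBB": 186, "NNB": 160},
    72: {"CCC": 1823, "BBN": 172, "BNN": 389, "BNB": 106, "NBN": 194, "NBB": 163, "NNB": 162},
}

_BIASED_OUTCOMES = ("BB", "BN", "NN", "NB")  # (NaCl, PEG) state given control biased
_UNBIASED_OUTCOMES = ("BN", "BB", "NB", "NN")  # given control unbiased


@dataclass(frozen=True)
class BiasSwitch:
    """Joint (NaCl, PEG) bias-state distribution at one time point.

    ``from_biased`` maps the joint collapsed outcome "XY" (X = NaCl state,
    Y = PEG state, each B or N) to its probability given the pair is biased
    in the control; ``from_unbiased`` likewise given no control bias.
    """

    from_biased: Mapping[str, float]
    from_unbiased: Mapping[str, float]

    def __post_init__(self):
        for name, dist, keys in (
            ("from_biased", self.from_biased, _BIASED_OUTCOMES),
            ("from_unbiased", self.from_unbiased, _UNBIASED_OUTCOMES),
        ):
            if set(dist) != set(keys):
                raise ConfigurationError(f"BiasSwitch.{name}: outcomes must be {set(keys)}")
            probs = np.array([dist[k] for k in keys], dtype=float)
            if (probs < 0).any() or (probs > 1).any():
                raise ConfigurationError(f"BiasSwitch.{name}: probabilities outside [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"BiasSwitch.{name}: probabilities must sum to 1")

    @classmethod
    def independent(
        cls, gain_nacl: float, loss_nacl: float, gain_peg: float, loss_peg: float
    ) -> "BiasSwitch":
        """Two independent Bernoulli switches per treatment (special case)."""
        fb = {
            "BB": (1 - loss_nacl) * (1 - loss_peg),
            "BN": (1 - loss_nacl) * loss_peg,
            "NN": loss_nacl * loss_peg,
            "NB": loss_nacl * (1 - loss_peg),
        }
        fu = {
            "BN": gain_nacl * (1 - gain_peg),
            "BB": gain_nacl * gain_peg,
            "NB": (1 - gain_nacl) * gain_peg,
            "NN": (1 - gain_nacl) * (1 - gain_peg),
        }
        return cls(fb, fu)

    @classmethod
    def from_category_targets(
        cls, category_counts: Mapping[str, int | float], pi_bias: float
    ) -> "BiasSwitch":
        """Calibrate the joint switch so that the expected category
        proportions, conditional on the pair being biased somewhere, equal
        ``category_counts`` (up to the feasibility of ``pi_bias``)."""
        total = float(sum(category_counts[c] for c in CATEGORIES))
        c = {k: category_counts[k] / total for k in CATEGORIES}
        share_b = c["CCC"] + c["BBN"] + c["BNN"] + c["BNB"]
        share_u = 1.0 - share_b
        fb = {
            "BB": c["CCC"] / share_b,
            "BN": c["BBN"] / share_b,
            "NN": c["BNN"] / share_b,
            "NB": c["BNB"] / share_b,
        }
        # mass of control-unbiased genes that must enter the universe so the
        # biased/unbiased split matches the targets
        in_universe = pi_bias * share_u / ((1.0 - pi_bias) * share_b)
        if not 0.0 < in_universe <= 1.0:
            raise ConfigurationError(
                f"pi_bias={pi_bias} cannot reach the target biased share {share_b:.3f}"
            )
        fu = {
            "BN": in_universe * c["NBN"] / share_u,
            "BB": in_universe * c["NBB"] / share_u,
            "NB": in_universe * c["NNB"] / share_u,
            "NN": 1.0 - in_universe,
        }
        return cls(fb, fu)


def _default_switch_matrix() -> dict[int, BiasSwitch]:
    return {t: BiasSwitch.independent(0.05, 0.10, 0.05, 0.10) for t in (24, 48, 72)}


@dataclass
class SimConfig:
    """Simulation parameters.  Defaults mirror the pooled ten-library
    continuous-stress design with BCV 0.1."""

    n_genes: int = 5000
    seed: int = 0
    bcv: float = 0.1
    pi_bias: float = 0.3
    log2_bias_range: tuple[float, float] = (1.5, 3.5)
    switch_matrix: dict[int, BiasSwitch] = field(default_factory=_default_switch_matrix)
    pi_de: float = 0.1
    log2_de_range: tuple[float, float] = (1.0, 3.0)
    n_modules: int = 0
    module_size: int = 100
    module_cor: float = 0.8
    baseline_logmean_mu: float = 5.0
    baseline_logmean_sd: float = 1.0
    sample_log_sd: float = 0.5
    size_factor_sd: float = 0.1
    length_log_mu: float = 7.6
    length_log_sd: float = 0.4
    n_chromosomes: int = 15
    n_reps: int = 1

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if self.bcv <= 0:
            raise ConfigurationError("bcv must be positive")
        for name in ("pi_bias", "pi_de", "module_cor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        self.log2_bias_range = tuple(self.log2_bias_range)  # type: ignore[assignment]
        self.log2_de_range = tuple(self.log2_de_range)  # type: ignore[assignment]
        if self.log2_bias_range[0] < 1.0:
            raise ConfigurationError(
                "log2_bias_range lower bound must be >= 1 (twofold detectability)"
            )
        if self.log2_bias_range[0] > self.log2_bias_range[1]:
            raise ConfigurationError("log2_bias_range must be (low, high)")
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigurationError("n_modules * module_size exceeds n_genes")
        if set(self.switch_matrix) != {24, 48, 72}:
            raise ConfigurationError("switch_matrix must cover time points 24, 48, 72")

    def to_json(self, path: str | Path) -> None:
        write_json(_config_to_dict(self), path)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            return _config_from_dict(json.load(fh))


def _config_to_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["switch_matrix"] = {
        str(t): {"from_biased": dict(sw.from_biased), "from_unbiased": dict(sw.from_unbiased)}
        for t, sw in cfg.switch_matrix.items()
    }
    return d


def _config_from_dict(d: Mapping) -> SimConfig:
    d = dict(d)
    if "switch_matrix" in d:
        d["switch_matrix"] = {
            int(t): BiasSwitch(sw["from_biased"], sw["from_unbiased"])
            for t, sw in d["switch_matrix"].items()
        }
    for key in ("log2_bias_range", "log2_de_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)


@dataclass
class SimTruth:
    """Ground truth of one simulation.

    ``genes``: per gene — baseline mean, control allelic log2 ratio, module
    label ("" = background).  ``conditions``: per (gene, treatment, time) —
    allelic log2 ratio, truth bias flag (|ratio| >= 1), DE flag and log2
    fold change versus control.
    """

    genes: pd.DataFrame
    conditions: pd.DataFrame

    def bias_table(self, time_h: int) -> pd.DataFrame:
        """Per-gene truth collapsed states (control/NaCl/PEG) at one time."""
        sub = self.conditions[self.conditions["time_h"] == time_h]
        piv = sub.pivot(index="gene_id", columns="treatment", values="bias")
        return piv[["control", "NaCl", "PEG"]]


@dataclass
class SimResult:
    allele_counts: pd.DataFrame
    gene_counts: pd.DataFrame
    models: list[GeneModel]
    samples: list[SampleMeta]
    truth: SimTruth
    config: SimConfig


def nb_counts(rng: np.random.Generator, mean: np.ndarray, bcv: float) -> np.ndarray:
    """Negative-binomial draws with Var = mu + (bcv^2) mu^2, sampled as a
    gamma-Poisson mixture (the simulator's count law)."""
    mean = np.asarray(mean, dtype=float)
    shape = 1.0 / (bcv * bcv)
    factor = rng.gamma(shape, 1.0 / shape, size=mean.shape)
    return rng.poisson(factor * mean).astype(np.int64)


def paired_allele_counts(
    rng: np.random.Generator, gene_mean: np.ndarray, frac_a: np.ndarray, bcv: float
) -> tuple[np.ndarray, np.ndarray]:
    """Allele-A/B counts sharing one biological gamma factor per gene, so
    the gene-level sum is NB(gene_mean, bcv^2) and the allelic ratio carries
    only Poisson noise."""
    gene_mean = np.asarray(gene_mean, dtype=float)
    shape = 1.0 / (bcv * bcv)
    factor = rng.gamma(shape, 1.0 / shape, size=gene_mean.shape)
    a = rng.poisson(factor * gene_mean * frac_a).astype(np.int64)
    b = rng.poisson(factor * gene_mean * (1.0 - frac_a)).astype(np.int64)
    return a, b


def _design(n_reps: int) -> list[tuple[str, str, int]]:
    """(sample_id, treatment, time_h) for the pooled design, optionally
    replicated."""
    conditions = [("control", t) for t in (0, 24, 48, 72)]
    conditions += [("NaCl", t) for t in (24, 48, 72)]
    conditions += [("PEG", t) for t in (24, 48, 72)]
    out = []
    for treatment, time_h in conditions:
        for r in range(n_reps):
            suffix = "" if n_reps == 1 else f"_r{r + 1}"
            out.append((f"{treatment}_{time_h}h{suffix}", treatment, time_h))
    return out


def simulate(config: SimConfig) -> SimResult:
    """Draw one synthetic experiment.  See the module docstring for the
    generative model; identical config + seed is bitwise reproducible."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(n)])

    # --- static gene attributes -------------------------------------------
    lengths = np.maximum(
        np.exp(rng.normal(config.length_log_mu, config.length_log_sd, n)).astype(np.int64), 200
    )
    chroms = np.array([f"chr{c + 1:02d}" for c in rng.integers(0, config.n_chromosomes, n)])
    baseline = np.exp(rng.normal(config.baseline_logmean_mu, config.baseline_logmean_sd, n))

    # module assignment: first n_modules*module_size of a random permutation
    module = np.array([""] * n, dtype=object)
    perm = rng.permutation(n)
    for m in range(config.n_modules):
        members = perm[m * config.module_size : (m + 1) * config.module_size]
        module[members] = f"M{m + 1}"

    # --- baseline allelic bias --------------------------------------------
    lo, hi = config.log2_bias_range
    ctrl_biased = rng.random(n) < config.pi_bias
    ctrl_sign = rng.choice([-1.0, 1.0], size=n)
    ctrl_mag = rng.uniform(lo, hi, n)
    ctrl_ratio = np.where(ctrl_biased, ctrl_sign * ctrl_mag, 0.0)

    # --- DE effects (per treatment, shared across its time points) ---------
    de_lfc = {}
    for treatment in ("NaCl", "PEG"):
        is_de = rng.random(n) < config.pi_de
        sign = rng.choice([-1.0, 1.0], size=n)
        mag = rng.uniform(config.log2_de_range[0], config.log2_de_range[1], n)
        de_lfc[treatment] = np.where(is_de, sign * mag, 0.0)

    # --- bias state per (treatment, time) ----------------------------------
    ratio = {("control", t): ctrl_ratio for t in (0, 24, 48, 72)}
    for t in (24, 48, 72):
        sw = config.switch_matrix[t]
        outcome = np.empty(n, dtype="U2")
        u = rng.random(n)
        for mask, outcomes, dist in (
            (ctrl_biased, _BIASED_OUTCOMES, sw.from_biased),
            (~ctrl_biased, _UNBIASED_OUTCOMES, sw.from_unbiased),
        ):
            probs = np.array([dist[k] for k in outcomes])
            edges = np.cumsum(probs)
            idx = np.searchsorted(edges, u[mask], side="right").clip(max=len(outcomes) - 1)
            outcome[mask] = np.array(outcomes)[idx]
        for pos, treatment in ((0, "NaCl"), (1, "PEG")):
            state_b = np.array([o[pos] == "B" for o in outcome])
            gained = state_b & ~ctrl_biased
            new_ratio = rng.choice([-1.0, 1.0], size=n) * rng.uniform(lo, hi, n)
            r = np.where(state_b, np.where(gained, new_ratio, ctrl_ratio), 0.0)
            ratio[(treatment, t)] = r

    # --- per-sample means and counts ---------------------------------------
    design = _design(config.n_reps)
    n_samples = len(design)
    size_factors = np.exp(rng.normal(0.0, config.size_factor_sd, n_samples))
    # latent module factors and member noise, per sample
    tau = config.sample_log_sd
    z = rng.normal(0.0, tau * np.sqrt(config.module_cor), (config.n_modules, n_samples))
    module_index = np.full(n, -1)
    for m in range(config.n_modules):
        module_index[module == f"M{m + 1}"] = m
    member = module_index >= 0
    eps = rng.normal(0.0, tau * np.sqrt(1.0 - config.module_cor), (n, n_samples))

    counts_a = np.zeros((n, n_samples), dtype=np.int64)
    counts_b = np.zeros((n, n_samples), dtype=np.int64)
    for j, (sid, treatment, time_h) in enumerate(design):
        mu = baseline.copy()
        if treatment != "control":
            mu = mu * np.exp2(de_lfc[treatment])
        if member.any():
            extra = np.zeros(n)
            extra[member] = z[module_index[member], j] + eps[member, j]
            mu = mu * np.exp(extra)
        mu = mu * size_factors[j]
        r = ratio[(treatment, time_h)]
        frac_a = np.exp2(r) / (1.0 + np.exp2(r))
        counts_a[:, j], counts_b[:, j] = paired_allele_counts(rng, mu, frac_a, config.bcv)

    sample_ids = [d[0] for d in design]
    allele_ids = [f"{g}_{suffix}" for g in gene_ids for suffix in ("A", "B")]
    allele_values = np.empty((2 * n, n_samples), dtype=np.int64)
    allele_values[0::2] = counts_a
    allele_values[1::2] = counts_b
    allele_counts = pd.DataFrame(
        allele_values, index=pd.Index(allele_ids, name="allele_id"), columns=sample_ids
    )
    gene_counts = pd.DataFrame(
        counts_a + counts_b, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids
    )

    models = [
        GeneModel(g, chroms[i], int(lengths[i]), f"{g}_A", f"{g}_B")
        for i, g in enumerate(gene_ids)
    ]
    samples = [SampleMeta(sid, treatment, time_h) for sid, treatment, time_h in design]

    genes_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "baseline_mean": baseline,
            "length_bp": lengths,
            "chromosome": chroms,
            "module": module,
            "control_log2_ratio": ctrl_ratio,
        }
    ).set_index("gene_id")
    cond_rows = []
    for (treatment, time_h), r in sorted(ratio.items()):
        cond_rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "treatment": treatment,
                    "time_h": time_h,
                    "log2_ratio": r,
                    "bias": np.abs(r) >= 1.0,
                    "de_log2fc": 0.0 if treatment == "control" else de_lfc[treatment],
                    "de": False if treatment == "control" else de_lfc[treatment] != 0.0,
                }
            )
        )
    conditions = pd.concat(cond_rows, ignore_index=True)
    truth = SimTruth(genes=genes_truth, conditions=conditions)
    return SimResult(allele_counts, gene_counts, models, samples, truth, config)


def table1_preset(n_genes: int = 20000, seed: int = 1, **overrides) -> SimConfig:
    """A configuration whose expected bias-dynamics category proportions,
    conditional on a pair being biased somewhere, equal the observed
    tea-plant proportions in :data:`REFERENCE_CATEGORY_COUNTS`.

    The preset emulates deeply sequenced pooled libraries (baseline log-mean
    6.5, log-sd 0.8, about 1.8e7 fragments per library at 20,000 gene pairs)
    and bias magnitudes well above the twofold boundary, so that category
    identity is determined by the simulated bias states rather than counting
    noise at BCV 0.1.
    """
    pi_bias = overrides.pop("pi_bias", 0.3)
    switch = {
        t: BiasSwitch.from_category_targets(REFERENCE_CATEGORY_COUNTS[t], pi_bias)
        for t in (24, 48, 72)
    }
    params = dict(
        n_genes=n_genes,
        seed=seed,
        pi_bias=pi_bias,
        log2_bias_range=(2.0, 4.0),
        switch_matrix=switch,
        baseline_logmean_mu=6.5,
        baseline_logmean_sd=0.8,
    )
    params.update(overrides)
    return SimConfig(**params)


def expected_category_proportions(config: SimConfig) -> pd.DataFrame:
    """Expected truth-level category proportions per time point, conditional
    on the pair being biased in at least one condition (time x category)."""
    rows = {}
    p = config.pi_bias
    for t in (24, 48, 72):
        sw = config.switch_matrix[t]
        raw = {
            "CCC": p * sw.from_biased["BB"],
            "BBN": p * sw.from_biased["BN"],
            "BNN": p * sw.from_biased["NN"],
            "BNB": p * sw.from_biased["NB"],
            "NBN": (1 - p) * sw.from_unbiased["BN"],
            "NBB": (1 - p) * sw.from_unbiased["BB"],
            "NNB": (1 - p) * sw.from_unbiased["NB"],
        }
        total = sum(raw.values())
        rows[t] = {k: v / total for k, v in raw.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[list(CATEGORIES)]


def write_fixture(out_dir: str | Path, sim: SimResult) -> dict[str, Path]:
    """Write the complete simulated input bundle to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "allele_counts": out_dir / "allele_counts.tsv",
        "gene_counts": out_dir / "gene_counts.tsv",
        "gene_models": out_dir / "gene_models.tsv",
        "sample_sheet": out_dir / "sample_sheet.tsv",
        "truth_genes": out_dir / "truth_genes.tsv",
        "truth_conditions": out_dir / "truth_conditions.tsv",
        "config": out_dir / "sim_config.json",
    }
    write_count_matrix(sim.allele_counts, paths["allele_counts"])
    write_count_matrix(sim.gene_counts, paths["gene_counts"])
    write_gene_models(sim.models, paths["gene_models"])
    write_sample_sheet(sim.samples, paths["sample_sheet"])
    sim.truth.genes.to_csv(paths["truth_genes"], sep="\t")
    sim.truth.conditions.to_csv(paths["truth_conditions"], sep="\t", index=False)
    sim.config.to_json(paths["config"])
    return paths
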