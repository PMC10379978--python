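"""Twofold bias calling, trajectory classification, and accounting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from haplodyn.ase_bias import (
    BIAS_A,
    BIAS_B,
    NO_BIAS,
    NOT_EXPRESSED,
    RESPONSIVENESS_OF_CATEGORY,
    call_bias,
    classify_trajectory,
    run_ase,
    summarize_ase,
)
from haplodyn.io_formats import ValidationError
from haplodyn.synthetic_data import (
    CATEGORIES,
    BiasSwitch,
    SimConfig,
    simulate,
)


class TestCallBias:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (10.0, 4.0, BIAS_A),  # ratio 2.5
            (6.0, 6.0, NO_BIAS),
            (0.1, 0.3, NOT_EXPRESSED),  # both under the 0.5 floor
            (2.0, 1.0, BIAS_A),  # boundary ratio exactly 2 is inclusive
            (1.0, 2.0, BIAS_B),
            (0.0, 5.0, BIAS_B),
        ],
    )
    def test_examples(self, a, b, expected):
        assert call_bias(a, b) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            call_bias(-1.0, 2.0)

    @given(
        st.floats(min_value=0, max_value=1e4),
        st.floats(min_value=0, max_value=1e4),
    )
    def test_label_symmetry(self, a, b):
        swap = {BIAS_A: BIAS_B, BIAS_B: BIAS_A, NO_BIAS: NO_BIAS, NOT_EXPRESSED: NOT_EXPRESSED}
        assert call_bias(b, a) == swap[call_bias(a, b)]

    @given(
        st.floats(min_value=1.0, max_value=1e3),
        st.floats(min_value=1.0, max_value=1e3),
        st.floats(min_value=1.0, max_value=100.0),
    )
    def test_scale_invariance_above_floor(self, a, b, c):
        # pseudocount effect is negligible at these magnitudes
        assert call_bias(a, b, epsilon=0.0) == call_bias(c * a, c * b, epsilon=0.0)


class TestClassifyTrajectory:
    def test_agrees_with_exhaustive_truth_table(self):
        """All 2^3 collapsed triplets against an independent oracle."""
        for bits in itertools.product([True, False], repeat=3):
            statuses = [BIAS_A if b else NO_BIAS for b in bits]
            category, resp = classify_trajectory(*statuses)
            c, n, p = bits
            # oracle: direct reading of the definitions
            if not any(bits):
                assert (category, resp) == ("NNN", "excluded")
                continue
            salt_changed = n != c
            drought_changed = p != c
            if not salt_changed and not drought_changed:
                expected = "conserved"
            elif salt_changed and drought_changed:
                expected = "both"
            elif salt_changed:
                expected = "salt_specific"
            else:
                expected = "drought_specific"
            assert resp == expected
            expected_cat = "".join("B" if b else "N" for b in bits)
            assert category == ("CCC" if expected_cat == "BBB" else expected_cat)

    @pytest.mark.parametrize(
        "triplet,category,resp",
        [
            ((BIAS_A, NO_BIAS, NO_BIAS), "BNN", "both"),
            ((NO_BIAS, NO_BIAS, NO_BIAS), "NNN", "excluded"),
            ((BIAS_A, BIAS_B, BIAS_A), "CCC", "conserved"),  # direction-blind
            ((BIAS_A, NO_BIAS, BIAS_A), "BNB", "salt_specific"),
            ((NO_BIAS, BIAS_A, BIAS_A), "NBB", "both"),
        ],
    )
    def test_pinned_examples(self, triplet, category, resp):
        assert classify_trajectory(*triplet) == (category, resp)

    def test_not_expressed_excludes(self):
        assert classify_trajectory(NOT_EXPRESSED, BIAS_A, BIAS_A) == (None, "excluded")


def _random_trajectories(rng, n=1000):
    cats = list(CATEGORIES) + ["NNN"]
    chosen = rng.choice(cats, size=n, p=[0.5, 0.06, 0.08, 0.05, 0.07, 0.07, 0.07, 0.1])
    rows = []
    for i, cat in enumerate(chosen):
        letters = "BBB" if cat == "CCC" else cat
        statuses = [BIAS_A if ch == "B" else NO_BIAS for ch in letters]
        category, resp = classify_trajectory(*statuses)
        rows.append((f"g{i}", 24, category, resp))
    return pd.DataFrame(rows, columns=["gene_id", "time_h", "category", "responsiveness"])


class TestSummarize:
    def test_reference_fixture_accounting(self, table1_trajectories):
        """The reference category multiplicities reproduce the printed
        responsiveness statistics exactly."""
        s = summarize_ase(table1_trajectories)
        assert [s.per_time[t]["n_responsive"] for t in (24, 48, 72)] == [1128, 936, 1186]
        assert (s.per_time[24]["n_salt_responsive"], s.per_time[24]["n_drought_responsive"]) == (813, 758)
        assert (s.per_time[72]["n_salt_responsive"], s.per_time[72]["n_drought_responsive"]) == (852, 886)
        assert [s.per_time[t]["n_both"] for t in (24, 48, 72)] == [443, 353, 552]
        assert [s.per_time[t]["pct_responsive"] for t in (24, 48, 72)] == [37.98, 30.60, 39.42]
        assert [s.per_time[t]["pct_both_of_responsive"] for t in (24, 48, 72)] == [
            39.27, 37.71, 46.54,
        ]

    def test_accounting_identities_on_random_fixtures(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            traj = _random_trajectories(rng)
            e = summarize_ase(traj).per_time[24]
            assert e["n_salt_responsive"] == e["n_both"] + e["n_salt_specific"]
            assert e["n_drought_responsive"] == e["n_both"] + e["n_drought_specific"]
            assert e["n_responsive"] == (
                e["n_both"] + e["n_salt_specific"] + e["n_drought_specific"]
            )
            assert sum(e["category_counts"].values()) == e["universe"]
            assert e["n_responsive"] == e["universe"] - e["n_conserved"]

    def test_empty_input_all_zero(self):
        empty = pd.DataFrame(columns=["gene_id", "time_h", "category", "responsiveness"])
        assert summarize_ase(empty).per_time == {}


class TestRunAse:
    def test_no_bias_simulation_yields_no_ase(self):
        sw = {t: BiasSwitch.independent(0, 0, 0, 0) for t in (24, 48, 72)}
        sim = simulate(
            SimConfig(n_genes=300, seed=21, pi_bias=0.0, switch_matrix=sw,
                      baseline_logmean_mu=7.0, baseline_logmean_sd=0.5)
        )
        traj, summary, sets = run_ase(sim.allele_counts, sim.models, sim.samples)
        # high depth: no spurious twofold calls, so no responsive genes
        for t in (24, 48, 72):
            assert summary.per_time[t]["n_responsive"] <= 3
        assert len(sets["salt_union"]) <= 5

    def test_detection_sensitivity_at_depth(self):
        """Pairs with |log2 ratio| >= 1.5 and mean FPKM >= 10 are recovered
        as biased with sensitivity >= 0.9."""
        from haplodyn.quantify import fpkm

        sim = simulate(SimConfig(n_genes=4000, seed=9, pi_bias=0.3, pi_de=0.0))
        expr = fpkm(sim.gene_counts, sim.models)
        traj, _, _ = run_ase(sim.allele_counts, sim.models, sim.samples)
        mean_fpkm = expr.mean(axis=1)
        truth = sim.truth.conditions
        sub = truth[
            (truth.treatment == "NaCl")
            & (truth.time_h == 24)
            & (truth.log2_ratio.abs() >= 1.5)
        ]
        sub = sub[sub.gene_id.map(mean_fpkm) >= 10]
        assert len(sub) > 300
        t24 = traj[traj.time_h == 24].set_index("gene_id")
        called = t24.loc[sub.gene_id, "status_nacl"].isin([BIAS_A, BIAS_B])
        assert called.mean() >= 0.9

    def test_chromosome_distribution_covers_responsive_union(self, small_sim):
        traj, summary, sets = run_ase(
            small_sim.allele_counts, small_sim.models, small_sim.samples
        )
        assert summary.chromosomes is not None
        assert summary.chromosomes["salt_responsive"].sum() == len(
            set(traj.loc[traj.responsiveness.isin(["salt_specific", "both"]), "gene_id"])
        )

    def test_direction_flip_is_conserved_but_flagged(self):
        # build a two-gene fixture by hand: allele ratio flips direction under NaCl
        import pandas as pd
        from haplodyn.io_formats import GeneModel, SampleMeta

        counts = pd.DataFrame(
            {
                "control_24h": [400, 100, 100, 100],
                "NaCl_24h": [100, 400, 100, 100],
                "PEG_24h": [400, 100, 100, 100],
            },
            index=pd.Index(["g1_A", "g1_B", "g2_A", "g2_B"], name="allele_id"),
        )
        models = [
            GeneModel("g1", "chr1", 1000, "g1_A", "g1_B"),
            GeneModel("g2", "chr1", 1000, "g2_A", "g2_B"),
        ]
        samples = [
            SampleMeta("control_24h", "control", 24),
            SampleMeta("NaCl_24h", "NaCl", 24),
            SampleMeta("PEG_24h", "PEG", 24),
        ]
        traj, summary, _ = run_ase(counts, models, samples)
        g1 = traj.set_index("gene_id").loc["g1"]
        assert g1["category"] == "CCC"  # collapsed states all biased
        assert bool(g1["direction_flip_nacl"])
        assert not bool(g1["direction_flip_peg"])
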