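import numpy as np
import pytest

from noseq import (
    ChemistryModel,
    ConfigurationError,
    MeripModel,
    SimulationParams,
    ValidationError,
    condition_grid,
    condition_preset,
    simulate_reads,
)

from conftest import DNA_53MER, fully_deaminated


def zero_chem(**overrides) -> ChemistryModel:
    base = dict(p_AtoI=0.0, p_CtoU=0.0, p_GtoX=0.0, p_X_block=0.0, p_NOm6A=0.0)
    base.update(overrides)
    return ChemistryModel(**base)


class TestConditionGrid:
    def test_72_conditions(self):
        assert len(condition_grid()) == 72

    def test_first_condition_is_mildest_sorted(self):
        first = condition_grid()[0]
        assert (first.temperature, first.ph, first.time) == (50, 3.5, 1)

    def test_ph40_block_has_18_members(self):
        assert sum(1 for c in condition_grid() if c.ph == 4.0) == 3 * 6


class TestConditionPresets:
    def test_optimal_oligo_in_working_regime(self):
        chem = condition_preset("optimal_oligo")
        assert 0.10 <= chem.p_AtoI <= 0.50

    def test_guanosine_conversion_slowest(self):
        for name in ("optimal_oligo", "amplicon"):
            chem = condition_preset(name)
            assert chem.p_GtoX < min(chem.p_AtoI, chem.p_CtoU)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            condition_preset("bogus")

    def test_probabilities_validated(self):
        with pytest.raises(ValidationError):
            ChemistryModel(p_AtoI=1.2, p_CtoU=0.1, p_GtoX=0.0)


class TestSimulateReads:
    def test_zero_rates_reproduce_reference(self, ref53):
        params = SimulationParams(reference=ref53, n_reads=50,
                                  position_rate_jitter=0.0, seed=1)
        reads, truth = simulate_reads(params, zero_chem())
        assert all(r.insert == DNA_53MER for r in reads)
        assert (truth["truncated_at"] == 0).all()

    def test_deterministic_limit_of_conversion_rules(self, ref53):
        # complete A and C conversion, methylated site fully protected
        params = SimulationParams(reference=ref53, m6a_stoichiometry={33: 1.0},
                                  n_reads=20, position_rate_jitter=0.0, seed=2)
        chem = zero_chem(p_AtoI=1.0, p_CtoU=1.0)
        reads, _ = simulate_reads(params, chem)
        expected = list(fully_deaminated(DNA_53MER))
        expected[32] = "A"  # m6A resists deamination
        assert all(r.insert == "".join(expected) for r in reads)

    def test_empirical_conversion_matches_generative_rate(self, ref53):
        n = 10_000
        params = SimulationParams(reference=ref53, n_reads=n,
                                  position_rate_jitter=0.0, seed=3)
        reads, _ = simulate_reads(params, zero_chem(p_AtoI=0.3))
        stack = np.array([list(r.insert) for r in reads])
        se = 3 * np.sqrt(0.3 * 0.7 / n)
        for pos in ref53.a_positions:
            g_fraction = (stack[:, pos - 1] == "G").mean()
            assert abs(g_fraction - 0.3) < se

    def test_stoichiometry_for_unannotated_position_rejected(self, ref53):
        with pytest.raises(ValidationError, match="20"):
            SimulationParams(reference=ref53, m6a_stoichiometry={20: 0.5})

    def test_same_seed_identical_output(self, ref53):
        chem = condition_preset("optimal_oligo")
        params = SimulationParams(reference=ref53, m6a_stoichiometry={33: 0.5},
                                  n_reads=500, pcr_duplication_rate=0.1, seed=11)
        a_reads, a_truth = simulate_reads(params, chem)
        b_reads, b_truth = simulate_reads(params, chem)
        assert [(r.read_id, r.insert, r.umi) for r in a_reads] == \
               [(r.read_id, r.insert, r.umi) for r in b_reads]
        assert a_truth.equals(b_truth)

    def test_survivor_bias_from_xanthosine_blockage(self, ref53):
        """Full-length reads carry less deamination than the whole pool."""
        params = SimulationParams(reference=ref53, n_reads=4000,
                                  position_rate_jitter=0.0, seed=5)
        chem = zero_chem(p_AtoI=0.3, p_CtoU=0.3, p_GtoX=0.05, p_X_block=1.0)
        reads, truth = simulate_reads(params, chem)
        loads = truth["converted_positions"].map(
            lambda s: 0 if not s else s.count(",") + 1
        )
        full = truth["truncated_at"] == 0
        assert full.any() and (~full).any()
        assert loads[full].mean() < loads.mean()

    def test_full_blockage_truncates_at_first_x(self, ref53):
        params = SimulationParams(reference=ref53, n_reads=300,
                                  position_rate_jitter=0.0, seed=6)
        chem = zero_chem(p_GtoX=0.5, p_X_block=1.0)
        reads, truth = simulate_reads(params, chem)
        for read, trunc in zip(reads, truth["truncated_at"]):
            if trunc:
                assert len(read.insert) == trunc - 1

    def test_merip_identity_is_noop_in_distribution(self, ref53):
        chem = zero_chem(p_AtoI=0.3)
        base = dict(reference=ref53, m6a_stoichiometry={33: 0.5},
                    n_reads=20_000, position_rate_jitter=0.0)
        plain, _ = simulate_reads(SimulationParams(**base, seed=7), chem)
        merip, _ = simulate_reads(
            SimulationParams(**base, seed=7,
                             merip=MeripModel(enrichment_factor=1.0,
                                              background_retention=1.0)),
            chem,
        )
        a_plain = np.mean([r.insert[32] == "A" for r in plain])
        a_merip = np.mean([r.insert[32] == "A" for r in merip])
        # site A rate ~ 0.5 + 0.5*0.7 = 0.85 in both arms
        se = 3 * np.sqrt(0.85 * 0.15 / 20_000)
        assert abs(a_plain - a_merip) < 2 * se

    def test_merip_enrichment_raises_methylated_fraction(self, ref53):
        chem = zero_chem()
        params = SimulationParams(
            reference=ref53, m6a_stoichiometry={33: 0.10}, n_reads=20_000,
            position_rate_jitter=0.0, seed=8,
            merip=MeripModel(enrichment_factor=10.0, background_retention=1.0),
        )
        _, truth = simulate_reads(params, chem)
        meth_fraction = truth["methylation"].str.endswith(":1").mean()
        expected = 0.1 * 10 / (0.1 * 10 + 0.9)  # 0.526
        assert abs(meth_fraction - expected) < 3 * np.sqrt(expected * (1 - expected) / 20_000)

    def test_pcr_duplicates_share_sequence_and_umi(self, ref53):
        chem = condition_preset("optimal_oligo")
        params = SimulationParams(reference=ref53, n_reads=2000,
                                  pcr_duplication_rate=0.3, seed=9)
        reads, truth = simulate_reads(params, chem)
        by_id = {r.read_id: r for r in reads}
        dups = truth[truth["is_duplicate"]]
        assert len(dups) > 0
        for _, row in dups.head(50).iterrows():
            original = by_id[row["molecule_id"]]
            duplicate = by_id[row["read_id"]]
            assert duplicate.insert == original.insert
            assert duplicate.umi == original.umi
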