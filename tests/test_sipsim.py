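"""Gradient-banding simulator: physics, conservation laws, determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sipseq import gradient, sipsim
from sipseq.sipsim import GradientParams, SIPDesign, Taxon


PARAMS = GradientParams()


class TestTaxonDensity:
    @pytest.mark.parametrize(
        "gc, excess, expected",
        [
            (0.5, 0.0, 1.709),  # unlabelled mid-GC DNA
            (0.5, 1.0, 1.745),  # fully labelled adds the 0.036 shift
            (0.0, 0.0, 1.660),  # intercept
        ],
    )
    def test_affine_formula(self, gc, excess, expected):
        t = Taxon("t", gc=gc, rel_abundance=1.0, atom_excess=excess)
        assert sipsim.taxon_density(t, PARAMS) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            Taxon("t", gc=1.5, rel_abundance=1.0)
        with pytest.raises(ValueError):
            Taxon("t", gc=0.5, rel_abundance=1.0, atom_excess=-0.1)

    @given(gc=st.floats(0, 1), e1=st.floats(0, 1), e2=st.floats(0, 1))
    def test_density_monotone_in_atom_excess(self, gc, e1, e2):
        lo, hi = sorted([e1, e2])
        t_lo = Taxon("t", gc=gc, rel_abundance=1.0, atom_excess=lo)
        t_hi = Taxon("t", gc=gc, rel_abundance=1.0, atom_excess=hi)
        assert sipsim.taxon_density(t_hi, PARAMS) >= sipsim.taxon_density(t_lo, PARAMS)


class TestSimulateFractions:
    def test_narrow_band_occupies_single_fraction(self):
        # band sd far below the 0.0045 g/ml fraction width
        p = GradientParams(band_sigma=1e-4)
        taxon = Taxon("t", gc=0.55, rel_abundance=1.0)  # density 1.7139, mid-gradient
        table = sipsim.simulate_fractions([taxon], p, depth=1000, total_dna_ng=100.0, seed=0)
        assert table["dna_ng"].max() >= 0.99 * 100.0

    def test_mass_conservation_and_count_totals(self, default_dataset):
        community, dataset = default_dataset
        for table in dataset.fraction_tables.values():
            assert table["dna_ng"].sum() == pytest.approx(500.0, abs=1e-6)
            taxa = gradient.taxon_columns(table)
            # per-fraction counts sum to the drawn fraction depth
            shares = table["dna_ng"] / table["dna_ng"].sum()
            expected_depth = (dataset.design.depth * shares).round().astype(int)
            assert (table[taxa].sum(axis=1) == expected_depth).all()

    def test_refractive_index_roundtrips_to_fraction_midpoints(self, default_dataset):
        _, dataset = default_dataset
        mids = np.sort(PARAMS.fraction_midpoints())[::-1]
        for table in dataset.fraction_tables.values():
            recovered = gradient.density_from_ri(table["refractive_index"].to_numpy())
            assert np.abs(recovered - mids).max() < 1e-9
            assert np.allclose(recovered, table["density_g_ml"])

    def test_same_seed_same_table(self):
        comm = sipsim.default_community(seed=3).taxa
        t1 = sipsim.simulate_fractions(comm, PARAMS, 5000, seed=11)
        t2 = sipsim.simulate_fractions(comm, PARAMS, 5000, seed=11)
        pd.testing.assert_frame_equal(t1, t2)

    def test_label_shift_propagates_through_banding(self):
        # equal-GC labelled vs unlabelled taxa: mass-weighted mean density gap
        ta = sipsim.simulate_fractions([Taxon("lab", 0.5, 1.0, 1.0)], PARAMS, 0, 100.0, 0)
        tb = sipsim.simulate_fractions([Taxon("unlab", 0.5, 1.0, 0.0)], PARAMS, 0, 100.0, 0)
        mean_a = np.average(ta["density_g_ml"], weights=ta["dna_ng"])
        mean_b = np.average(tb["density_g_ml"], weights=tb["dna_ng"])
        assert mean_a - mean_b == pytest.approx(PARAMS.full_label_shift, abs=1e-3)

    def test_invalid_inputs(self):
        taxon = [Taxon("t", 0.5, 1.0)]
        with pytest.raises(ValueError):
            sipsim.simulate_fractions([], PARAMS, 100)
        with pytest.raises(ValueError):
            sipsim.simulate_fractions(taxon, PARAMS, depth=-1)
        with pytest.raises(ValueError):
            GradientParams(band_sigma=0.0)


class TestSimulateExperiment:
    def test_vial_cardinality(self, default_dataset):
        _, dataset = default_dataset
        # 2 substrates x 2 isotopes x 2 replicates
        assert len(dataset.fraction_tables) == 8

    def test_consumers_band_heavy_only_in_13C(self, default_dataset):
        community, dataset = default_dataset
        consumer = community.taxa[0].id
        for sub in ("ethane", "propane"):
            t13 = dataset.fraction_tables[f"{sub}_13C_rep1"]
            t12 = dataset.fraction_tables[f"{sub}_12C_rep1"]
            heavy = lambda t: t.loc[t["density_g_ml"] >= 1.7296, consumer].sum()
            light = lambda t: t.loc[t["density_g_ml"] <= 1.7216, consumer].sum()
            assert heavy(t13) > light(t13)
            assert heavy(t12) < light(t12)

    def test_truth_marks_only_13C_consumers(self, default_dataset):
        community, dataset = default_dataset
        truth = dataset.truth
        assert not truth.loc[truth.isotope == "12C", "true_label"].any()
        labelled = set(truth.loc[truth.true_label, "taxon"])
        assert labelled == {t.id for t in community.taxa if t.consumes}

    def test_unknown_substrate_flag_rejected(self):
        comm = sipsim.CommunityProfile([Taxon("t", 0.5, 1.0, 1.0, consumes=frozenset({"butane"}))])
        with pytest.raises(ValueError, match="butane"):
            sipsim.simulate_experiment(comm, SIPDesign(seed=0))


class TestHeadspaceSimulation:
    def test_zero_rate_constant_series(self):
        s = sipsim.simulate_headspace(1.0, 0.0, 100.0, np.arange(10), noise_sd=0.0)
        assert (s["pct_v_v"] == 1.0).all()

    def test_linear_depletion_hits_zero_at_closed_form_time(self):
        from sipseq.consumption import headspace_micromoles

        rate = 4.0  # umol/day
        n0 = float(headspace_micromoles(1.0, 100.0))
        t_zero = n0 / rate
        days = np.linspace(0, 15, 151)
        s = sipsim.simulate_headspace(1.0, rate, 100.0, days, noise_sd=0.0)
        above = s[s["pct_v_v"] > 0]["time_d"].max()
        assert above < t_zero <= above + 0.1 + 1e-9

    def test_same_seed_identical(self):
        a = sipsim.simulate_headspace(1.0, 2.0, 100.0, np.arange(5), noise_sd=0.05, seed=4)
        b = sipsim.simulate_headspace(1.0, 2.0, 100.0, np.arange(5), noise_sd=0.05, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sipsim.simulate_headspace(1.0, -1.0, 100.0, [0, 1])
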