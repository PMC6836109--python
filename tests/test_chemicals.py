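"""Chemical objects: formulas, adducts, workflows, replicates, CRP."""

import numpy as np
import pytest

from mzsim.chemicals import (
    CRPState,
    Formula,
    AdductSpec,
    PROTON_MASS,
    adduct_mz,
    assign_fragments,
    chemicals_from_rois,
    cooccurrence_fraction,
    isotope_proportions,
    monoisotopic_mass,
    ms1_traces,
    replicate_samples,
    sample_known_chemicals,
)
from mzsim.feature_db import MS1Feature, SpectralFeatureDatabase
from mzsim.fixtures import make_roi_pool, make_unknown_chemicals
from mzsim.roi import ROI


class TestMasses:
    @pytest.mark.parametrize(
        "formula,expected",
        [("H2O", 18.010565), ("C6H12O6", 180.063388)],
    )
    def test_monoisotopic_mass(self, formula, expected):
        assert monoisotopic_mass(formula) == pytest.approx(expected, abs=1e-3)

    def test_empty_formula_rejected(self):
        with pytest.raises(ValueError):
            Formula.parse("")

    def test_unknown_element_named(self):
        with pytest.raises(ValueError, match="Xq"):
            monoisotopic_mass("C2Xq3")

    @pytest.mark.parametrize(
        "mass,shift,charge,expected",
        [
            (180.063388, PROTON_MASS, 1, 181.070664),
            (100.0, 0.0, 2, 50.0),
            (100.0, PROTON_MASS, 1, 101.0072765),
        ],
    )
    def test_adduct_mz(self, mass, shift, charge, expected):
        adduct = AdductSpec("X", shift, charge, 1.0)
        assert adduct_mz(mass, adduct) == pytest.approx(expected, abs=1e-3)

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            AdductSpec("bad", 0.0, 0, 1.0)

    def test_isotope_proportions_sum_to_one(self):
        props = isotope_proportions(Formula.parse("C10H14N2O5"))
        assert sum(props) == pytest.approx(1.0)
        assert props[0] > props[1] > props[2]


def _db_for_sampling():
    return SpectralFeatureDatabase(
        ms1_features=[MS1Feature(300.0, 25.0, 5e5)],
        ms2_peaks=[(50.0 + i, 100.0 * (i + 1)) for i in range(20)],
        fragment_counts=[4],
        scan_durations={(1, 1): [0.4]},
        formulas=["C6H12O6"],
    )


class TestSyntheticWorkflow:
    def test_singleton_pools_fully_determine_chemical(self, rng):
        db = _db_for_sampling()
        pool = make_roi_pool(1, np.random.default_rng(1))
        (chem,) = sample_known_chemicals(db, 1, roi_pool=pool, rng=rng)
        assert str(chem.formula) == "C6H12O6"
        assert chem.start_rt == 25.0
        assert chem.max_intensity == 5e5
        assert len(chem.fragments) == 4

    def test_scale_and_invariants(self, session_db, session_roi_pool):
        chems = sample_known_chemicals(
            session_db, 500, roi_pool=session_roi_pool, rng=np.random.default_rng(3)
        )
        assert len(chems) == 500
        for chem in chems[::50]:
            total = sum(p for _, p in ms1_traces(chem))
            assert total == pytest.approx(1.0, abs=1e-9)
            assert chem.max_intensity > 0
            assert chem.chromatogram.rel_intensities.max() == pytest.approx(1.0)

    def test_same_seed_identical_lists(self, session_db, session_roi_pool):
        a = sample_known_chemicals(
            session_db, 20, roi_pool=session_roi_pool, rng=np.random.default_rng(5)
        )
        b = sample_known_chemicals(
            session_db, 20, roi_pool=session_roi_pool, rng=np.random.default_rng(5)
        )
        for x, y in zip(a, b):
            assert x.formula == y.formula
            assert x.start_rt == y.start_rt
            assert x.fragments == y.fragments

    def test_missing_formulas_rejected(self, rng):
        db = _db_for_sampling()
        db.formulas = None
        with pytest.raises(ValueError, match="formulas"):
            sample_known_chemicals(db, 1, roi_pool=make_roi_pool(1), rng=rng)

    def test_nonpositive_n_gives_empty_list(self, rng):
        assert sample_known_chemicals(_db_for_sampling(), 0, roi_pool=[], rng=rng) == []


class TestExistingSampleWorkflow:
    def test_roi_fields_carried_over(self):
        roi = ROI([100.0, 100.0, 100.0], [120.0, 121.0, 122.0], [1e5, 5e5, 2e5])
        (chem,) = chemicals_from_rois([roi])
        assert chem.max_intensity == 5e5
        assert chem.start_rt == 120.0
        assert chem.observed_mz == pytest.approx(100.0)
        assert len(ms1_traces(chem)) == 1  # single trace, by construction

    def test_order_preserved(self):
        rois = [
            ROI([100.0 * k], [10.0], [1e5]) for k in (1, 2, 3)
        ]
        chems = chemicals_from_rois(rois)
        assert [c.observed_mz for c in chems] == [100.0, 200.0, 300.0]
        assert [c.chem_id for c in chems] == [0, 1, 2]


class TestReplicates:
    def test_no_dropout_no_noise_is_identity(self, rng):
        chems = make_unknown_chemicals(50, rng)
        samples = replicate_samples(chems, 0.0, 0.0, 3, rng)
        for s in samples:
            assert s == chems

    def test_cooccurrence_at_dropout_030(self):
        chems = make_unknown_chemicals(10_000, np.random.default_rng(1))
        s = replicate_samples(chems, 0.0, 0.3, 2, np.random.default_rng(2))
        assert cooccurrence_fraction(s[0], s[1], 10_000) == pytest.approx(0.49, abs=0.015)

    def test_noise_sd_ten_thousand(self):
        chems = make_unknown_chemicals(1, np.random.default_rng(1))
        chems[0].max_intensity = 1e6  # far above the positivity floor
        rng = np.random.default_rng(3)
        samples = replicate_samples(chems, 10_000.0, 0.0, 4000, rng)
        deltas = [s[0].max_intensity - 1e6 for s in samples]
        assert np.std(deltas) == pytest.approx(10_000, rel=0.05)
        assert np.mean(deltas) == pytest.approx(0.0, abs=600)

    def test_noise_floored_at_one(self):
        chems = make_unknown_chemicals(1, np.random.default_rng(1))
        chems[0].max_intensity = 5.0
        samples = replicate_samples(chems, 1e6, 0.0, 200, np.random.default_rng(4))
        assert min(s[0].max_intensity for s in samples) >= 1.0

    def test_dropout_one_rejected(self, rng):
        with pytest.raises(ValueError):
            replicate_samples([], 0.0, 1.0, 1, rng)


class TestFragmentAssignment:
    def test_random_method_counts_and_scaling(self, rng):
        frags = assign_fragments(_db_for_sampling(), rng, "random")
        assert len(frags) == 4
        assert max(r for _, r in frags) == pytest.approx(1.0)

    def test_crp_without_state_rejected(self, rng):
        with pytest.raises(ValueError, match="CRPState"):
            assign_fragments(_db_for_sampling(), rng, "crp")

    def test_crp_empty_state_first_draw_opens_table(self, rng):
        state = CRPState(concentration=1.0)
        assign_fragments(_db_for_sampling(), rng, "crp", state)
        assert len(state.table_counts) == 4  # every first-spectrum draw is new

    def test_crp_seating_probabilities(self):
        # counts {A:3, B:1}, concentration 1 -> P(A)=0.6, P(B)=0.2, P(new)=0.2
        db = _db_for_sampling()
        db.fragment_counts = [1]
        rng = np.random.default_rng(11)
        hits = {"A": 0, "B": 0, "new": 0}
        for _ in range(10_000):
            state = CRPState(table_counts={0: 3, 1: 1}, concentration=1.0)
            ((mz, _),) = assign_fragments(db, rng, "crp", state)
            hits["A" if mz == 50.0 else "B" if mz == 51.0 else "new"] += 1
        assert hits["A"] / 10_000 == pytest.approx(0.6, abs=0.02)
        assert hits["B"] / 10_000 == pytest.approx(0.2, abs=0.02)
        assert hits["new"] / 10_000 == pytest.approx(0.2, abs=0.02)

    def test_crp_truncation_no_duplicates(self):
        db = _db_for_sampling()
        db.fragment_counts = [15]
        state = CRPState(concentration=2.0)
        rng = np.random.default_rng(12)
        for _ in range(100):
            frags = assign_fragments(db, rng, "crp", state)
            mzs = [m for m, _ in frags]
            assert len(mzs) == len(set(mzs))

    def test_crp_rich_get_richer(self):
        # a peak's accumulated count should grow its reuse frequency
        db = _db_for_sampling()
        db.fragment_counts = [3]
        state = CRPState(concentration=1.0)
        rng = np.random.default_rng(13)
        for _ in range(300):
            assign_fragments(db, rng, "crp", state)
        counts = sorted(state.table_counts.values(), reverse=True)
        # under uniform (non-reinforcing) sampling every peak would get
        # ~900/20 = 45 draws (multinomial sd ~6.5); reinforcement skews hard
        uniform = 900 / 20
        assert counts[0] > 2 * uniform
        assert counts[-1] < uniform / 2

    def test_max_mz_caps_fragments(self, rng):
        frags = assign_fragments(_db_for_sampling(), rng, "random", max_mz=55.0)
        assert all(m <= 55.0 for m, _ in frags)
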