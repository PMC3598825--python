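"""The generator must be a stoichiometric oracle: every noise-free record
closes carbon and electron balances exactly, by construction."""

import numpy as np
import pytest

from lignoferm.balances import carbon_recovery, electron_recovery
from lignoferm.composition import BiomassComposition
from lignoferm.stoichiometry import fold_change
from lignoferm.synthetic_data import (
    CELLULOLYTIC_DEFAULT,
    ETHANOLOGENIC_DEFAULT,
    InfeasibleSplitError,
    NoiseModel,
    StrainParams,
    SubstrateSpec,
    closure_gases,
    estimate_split,
    generate_outcome,
    generate_timecourse,
)

AVICEL = SubstrateSpec("avicel", 10.0, composition=BiomassComposition({"glucan": 1.0}))
POPLAR = SubstrateSpec(
    "poplar", 20.0,
    composition=BiomassComposition(
        {"glucan": 0.424, "xylan": 0.116, "galactan": 0.018, "arabinan": 0.022, "mannan": 0.026}
    ),
)
GLUCOSE = SubstrateSpec("glucose", 10.0, sugar="glucose")


@pytest.mark.parametrize(
    "split, expected_co2, expected_h2",
    [
        ((0.0, 2.0, 0.0), 2.0, 4.0),  # homoacetate: glucose -> 2 Ac + 2 CO2 + 4 H2
        ((2.0, 0.0, 0.0), 2.0, 0.0),  # homoethanol: 24 = 2 x 12
        ((0.0, 0.0, 2.0), 0.0, 0.0),  # homolactic: redox neutral
    ],
)
def test_closure_gases_classic_fermentations(split, expected_co2, expected_h2):
    co2, h2 = closure_gases(split)
    assert co2 == pytest.approx(expected_co2, abs=1e-12)
    assert h2 == pytest.approx(expected_h2, abs=1e-12)


def test_closure_gases_pentose_analog():
    # xylose -> 5/3 acetate: CO2 = 5 - 10/3, H2 = (20 - 40/3)/2
    co2, h2 = closure_gases((0.0, 5.0 / 3.0, 0.0), carbons=5)
    assert co2 == pytest.approx(5.0 - 10.0 / 3.0)
    assert h2 == pytest.approx(10.0 / 3.0)


def test_closure_gases_infeasible_split():
    # all-ethanol split leaves no electrons for biomass at gamma 4.25
    with pytest.raises(InfeasibleSplitError, match="electron deficit"):
        closure_gases((2.0, 0.0, 0.0), biomass_c=0.5)
    with pytest.raises(InfeasibleSplitError, match="overdraws"):
        closure_gases((0.0, 0.0, 2.1))


def test_strain_params_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        StrainParams(name="x", product_split=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError, match="biomass_fraction"):
        StrainParams(name="x", product_split=(0.2, 0.4, 0.4), biomass_fraction=0.5)


def test_same_seed_reproduces_record_exactly():
    kwargs = dict(noise=NoiseModel(relative_sd=0.1, seed=42))
    a = generate_outcome([CELLULOLYTIC_DEFAULT], AVICEL, **kwargs)
    b = generate_outcome([CELLULOLYTIC_DEFAULT], AVICEL, **kwargs)
    assert a == b
    c = generate_outcome([CELLULOLYTIC_DEFAULT], AVICEL, noise=NoiseModel(0.1, seed=43))
    assert c != a


@pytest.mark.parametrize("substrate", [AVICEL, POPLAR, GLUCOSE], ids=lambda s: s.name)
@pytest.mark.parametrize("coculture", [False, True])
def test_zero_noise_records_close_both_balances(substrate, coculture):
    strains = (
        [CELLULOLYTIC_DEFAULT, ETHANOLOGENIC_DEFAULT] if coculture else [CELLULOLYTIC_DEFAULT]
    )
    rec = generate_outcome(strains, substrate, ph_mode="ph-controlled-fermentor")
    assert carbon_recovery(rec.consumed_equivalents, rec.profile, rec.cells).recovery == (
        pytest.approx(100.0, abs=1e-9)
    )
    assert electron_recovery(rec.consumed_equivalents, rec.profile, rec.cells).recovery == (
        pytest.approx(100.0, abs=1e-9)
    )


def test_saccharolytic_monoculture_cannot_grow_on_cellulose():
    rec = generate_outcome([ETHANOLOGENIC_DEFAULT], AVICEL)
    assert rec.profile.total_organic == 0.0
    assert rec.substrate_final == pytest.approx(AVICEL.loading)


def test_ethanologenic_partner_raises_ethanol_at_least_twofold():
    mono_strain = StrainParams(name="cel", product_split=(0.08, 0.65, 0.27))
    partner = StrainParams(
        name="eth", product_split=(0.6, 0.14, 0.26), scope="saccharolytic",
        consumption_extent=mono_strain.consumption_extent,
    )
    mode = "ph-controlled-fermentor"
    mono = generate_outcome([mono_strain], AVICEL, ph_mode=mode)
    co = generate_outcome([mono_strain, partner], AVICEL, ph_mode=mode)
    assert fold_change(co.profile, mono.profile, "ethanol") > 2.0


def test_acidification_cap_limits_flask_but_not_fermentor():
    flask = generate_outcome([CELLULOLYTIC_DEFAULT, ETHANOLOGENIC_DEFAULT], AVICEL,
                             ph_mode="uncontrolled-flask")
    fermentor = generate_outcome([CELLULOLYTIC_DEFAULT, ETHANOLOGENIC_DEFAULT], AVICEL,
                                 ph_mode="ph-controlled-fermentor")
    assert flask.profile.total_organic < fermentor.profile.total_organic
    assert 20.0 <= flask.profile.total_organic <= 40.0
    assert fermentor.profile.total_organic > 60.0
    # the capped record still closes exactly
    assert carbon_recovery(
        flask.consumed_equivalents, flask.profile, flask.cells
    ).recovery == pytest.approx(100.0, abs=1e-9)


def test_timecourse_starts_at_zero_and_is_monotone():
    tc = generate_timecourse([CELLULOLYTIC_DEFAULT], AVICEL, n_points=12)
    assert tc.ethanol[0] == tc.acetate[0] == tc.lactate[0] == 0.0
    assert tc.substrate[0] == pytest.approx(AVICEL.loading)
    for series in (tc.ethanol, tc.acetate, tc.lactate):
        assert np.all(np.diff(series) >= -1e-12)
    assert np.all(np.diff(tc.substrate) <= 1e-12)


def test_timecourse_endpoint_matches_outcome():
    noise = NoiseModel(relative_sd=0.05, seed=7)
    tc = generate_timecourse([CELLULOLYTIC_DEFAULT], AVICEL, n_points=9, noise=noise)
    end = generate_outcome([CELLULOLYTIC_DEFAULT], AVICEL, noise=noise)
    assert tc.ethanol[-1] == pytest.approx(end.profile.ethanol, rel=1e-12)
    assert tc.lactate[-1] == pytest.approx(end.profile.lactate, rel=1e-12)
    assert tc.substrate[-1] == pytest.approx(end.substrate_final, rel=1e-12)
    with pytest.raises(ValueError):
        generate_timecourse([CELLULOLYTIC_DEFAULT], AVICEL, n_points=1)


def test_flask_timecourse_endpoint_lower_than_fermentor():
    flask = generate_timecourse([CELLULOLYTIC_DEFAULT], AVICEL, acidification_threshold=15.0)
    ferm = generate_timecourse([CELLULOLYTIC_DEFAULT], AVICEL, ph_mode="ph-controlled-fermentor")
    assert flask.profile_at(-1).total_organic < ferm.profile_at(-1).total_organic


def test_estimate_split_identity_at_zero_noise():
    strain = StrainParams(name="s", product_split=(0.25, 0.5, 0.25))
    rec = generate_outcome([strain], GLUCOSE, ph_mode="ph-controlled-fermentor")
    assert estimate_split(rec) == pytest.approx((0.25, 0.5, 0.25), abs=1e-12)

    pure = StrainParams(name="e", product_split=(0.0, 1.0, 0.0))
    rec = generate_outcome([pure], GLUCOSE, ph_mode="ph-controlled-fermentor")
    assert estimate_split(rec) == pytest.approx((0.0, 1.0, 0.0), abs=1e-12)


def test_estimate_split_mean_recovers_truth_under_noise():
    """200 replicates at 5% relative noise recover the split within 0.02."""
    truth = (0.25, 0.5, 0.25)
    strain = StrainParams(name="s", product_split=truth)
    estimates = [
        estimate_split(
            generate_outcome(
                [strain], GLUCOSE, noise=NoiseModel(relative_sd=0.05, seed=1000 + i),
                ph_mode="ph-controlled-fermentor",
            )
        )
        for i in range(200)
    ]
    mean = np.mean(estimates, axis=0)
    assert np.max(np.abs(mean - np.array(truth))) < 0.02


def test_substrate_spec_validation():
    with pytest.raises(ValueError, match="exactly one"):
        SubstrateSpec("x", 10.0)
    with pytest.raises(ValueError, match="exactly one"):
        SubstrateSpec("x", 10.0, sugar="glucose", composition=BiomassComposition({"glucan": 1.0}))
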