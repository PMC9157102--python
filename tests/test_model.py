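"""Gamete model, embryo cutting, fitness, and the generation recursion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homingdrive import (
    DriveAllele,
    DriveParams,
    FitnessModel,
    FitnessSpec,
    Genotype,
    OffTargetAllele,
    PopulationState,
    Sex,
    apply_embryo_cutting,
    carrier_frequency,
    equilibrium_carrier_frequency,
    founder_state,
    genetic_load,
    genotype_fitness,
    germline_gamete_distribution,
    next_generation,
    required_genetic_load,
    solve_homozygote_cost_for_equilibrium,
)
from homingdrive.genotypes import N_GENOTYPES, STERILE_FEMALE_MASK

WT, DR, R1, R2 = DriveAllele.WT, DriveAllele.DRIVE, DriveAllele.R1, DriveAllele.R2
IN, DIS = OffTargetAllele.INTACT, OffTargetAllele.DISRUPTED
II = (IN, IN)


# ---------------------------------------------------------------------------
# Germline gametes
# ---------------------------------------------------------------------------


def test_wild_type_parent_transmits_wild_type_only(measured_params):
    g = Genotype((WT, WT), II, Sex.FEMALE)
    dist = germline_gamete_distribution(g, measured_params)
    assert dist == {(WT, IN): 1.0}


def test_drive_het_gamete_distribution_matches_hand_arithmetic():
    # c = 0.767, total resistance 0.222, r1 fraction 0:
    # P(DRIVE) = 0.5 + 0.5*0.767, P(R2) = 0.5*0.222, P(WT) = 0.5*0.011
    p = DriveParams(offtarget_germline_cut_rate=0.0)
    g = Genotype((DR, WT), II, Sex.FEMALE)
    dist = germline_gamete_distribution(g, p)
    drive_marginal = {a: sum(v for (d, o), v in dist.items() if d == a) for a in DriveAllele}
    assert drive_marginal[DR] == pytest.approx(0.8835)
    assert drive_marginal[R2] == pytest.approx(0.111)
    assert drive_marginal[WT] == pytest.approx(0.0055)
    assert drive_marginal[R1] == 0.0
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


def test_drive_het_gametes_match_event_simulation_oracle(rng):
    """Monte-Carlo simulation of the germline event sequence agrees with
    the analytic gamete distribution."""
    p = DriveParams(relative_r1_rate=0.1)
    g = Genotype((DR, WT), (IN, DIS), Sex.MALE)
    dist = germline_gamete_distribution(g, p)

    n = 200_000
    counts: dict[tuple, int] = {}
    for _ in range(n):
        # conversion/resistance on the WT allele, then Mendelian choice
        u = rng.random()
        if u < p.conversion_male:
            wt_fate = DR
        elif u < p.conversion_male + p.relative_r1_rate * p.germline_resistance_total:
            wt_fate = R1
        elif u < p.conversion_male + p.germline_resistance_total:
            wt_fate = R2
        else:
            wt_fate = WT
        drive_allele = rng.choice([DR, wt_fate])
        # off-target: intact allele cut at rate 1 (drive carrier), then Mendelian
        ot_pair = [DIS if rng.random() < p.offtarget_germline_cut_rate else IN, DIS]
        ot_allele = ot_pair[rng.integers(2)]
        key = (DriveAllele(drive_allele), OffTargetAllele(ot_allele))
        counts[key] = counts.get(key, 0) + 1

    for key, expected in dist.items():
        observed = counts.get(key, 0) / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert observed == pytest.approx(expected, abs=max(4 * se, 1e-4))


def test_split_drive_inert_without_cas9():
    p = DriveParams(cas9_present=False)
    g = Genotype((DR, WT), II, Sex.FEMALE)
    dist = germline_gamete_distribution(g, p)
    assert dist[(DR, IN)] == pytest.approx(0.5)
    assert dist[(WT, IN)] == pytest.approx(0.5)


def test_offtarget_cut_rate_one_disrupts_all_gametes(measured_params):
    g = Genotype((DR, WT), II, Sex.FEMALE)
    dist = germline_gamete_distribution(g, measured_params)
    assert all(o is DIS for (_, o) in dist)


# ---------------------------------------------------------------------------
# Embryo cutting
# ---------------------------------------------------------------------------


def _point_mass(drive_pair, offtarget_pair=II):
    dist = np.zeros(N_GENOTYPES)
    dist[Genotype(drive_pair, offtarget_pair, Sex.FEMALE).index] = 1.0
    return dist


def test_embryo_cutting_noop_without_drive_mother(measured_params):
    dist = _point_mass((WT, WT))
    mother = Genotype((WT, R2), II, Sex.FEMALE)
    out = apply_embryo_cutting(dist, mother, measured_params)
    np.testing.assert_allclose(out, dist)


def test_embryo_cutting_survival_matches_enumeration(measured_params):
    """P(WT/WT offspring stays WT/WT) enumerated over the four cut/no-cut
    outcomes equals (1 - e)^2."""
    e = measured_params.embryo_cut_rate
    mother = Genotype((DR, WT), II, Sex.FEMALE)
    out = apply_embryo_cutting(_point_mass((WT, WT)), mother, measured_params)
    # enumeration oracle: both alleles uncut
    expected_wtwt = sum(
        (1 - e if not cut1 else e) * (1 - e if not cut2 else e)
        for cut1 in (False, True)
        for cut2 in (False, True)
        if not cut1 and not cut2
    )
    assert expected_wtwt == pytest.approx((1 - e) ** 2)
    assert out[Genotype((WT, WT), II, Sex.FEMALE).index] == pytest.approx(expected_wtwt)
    assert out[Genotype((WT, R2), II, Sex.FEMALE).index] == pytest.approx(2 * e * (1 - e))
    assert out[Genotype((R2, R2), II, Sex.FEMALE).index] == pytest.approx(e**2)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


def test_embryo_cut_rate_one_leaves_no_wild_type():
    p = DriveParams(embryo_cut_rate=1.0)
    mother = Genotype((DR, WT), II, Sex.FEMALE)
    wt_mask = np.array([WT in gp for gp in _drive_pairs_by_index()], dtype=bool)
    for pair in [(WT, WT), (DR, WT), (WT, R2)]:
        out = apply_embryo_cutting(_point_mass(pair), mother, p)
        assert out[wt_mask].sum() == pytest.approx(0.0, abs=1e-12)


def _drive_pairs_by_index():
    from homingdrive.genotypes import DRIVE_PAIRS, OFFTARGET_PAIRS

    return [dp for dp in DRIVE_PAIRS for _ in OFFTARGET_PAIRS]


def test_embryo_cutting_rejects_unnormalized_input(measured_params):
    mother = Genotype((DR, WT), II, Sex.FEMALE)
    with pytest.raises(ValueError):
        apply_embryo_cutting(np.full(N_GENOTYPES, 0.5), mother, measured_params)


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("pair", [(WT, WT), (DR, WT), (DR, DR), (R1, R2)])
def test_neutral_fitness_is_unity(pair):
    g = Genotype(pair, II, Sex.FEMALE)
    assert genotype_fitness(g, FitnessSpec()) == (1.0, 1.0, 1.0)


def test_direct_viability_square_root_heterozygote():
    spec = FitnessSpec(FitnessModel.DIRECT_VIABILITY, 0.80)
    het = Genotype((DR, WT), II, Sex.MALE)
    hom = Genotype((DR, DR), II, Sex.MALE)
    assert genotype_fitness(het, spec)[2] == pytest.approx(np.sqrt(0.80))
    assert genotype_fitness(hom, spec)[2] == pytest.approx(0.80)
    assert genotype_fitness(Genotype((WT, WT), II, Sex.MALE), spec) == (1.0, 1.0, 1.0)


def test_somatic_het_fecundity_applies_to_het_females_only():
    spec = FitnessSpec(FitnessModel.SOMATIC_HET_FECUNDITY, 0.43)
    f_het = Genotype((DR, WT), II, Sex.FEMALE)
    m_het = Genotype((DR, WT), II, Sex.MALE)
    f_hom = Genotype((DR, DR), II, Sex.FEMALE)
    assert genotype_fitness(f_het, spec)[0] == pytest.approx(0.43)
    assert genotype_fitness(m_het, spec) == (1.0, 1.0, 1.0)
    assert genotype_fitness(f_hom, spec) == (1.0, 1.0, 1.0)


def test_offtarget_models_key_on_disrupted_alleles():
    spec = FitnessSpec(FitnessModel.OFFTARGET_VIABILITY, 0.64)
    g0 = Genotype((DR, DR), (IN, IN), Sex.FEMALE)
    g1 = Genotype((WT, WT), (IN, DIS), Sex.FEMALE)
    g2 = Genotype((WT, WT), (DIS, DIS), Sex.FEMALE)
    assert genotype_fitness(g0, spec)[2] == 1.0
    assert genotype_fitness(g1, spec)[2] == pytest.approx(0.8)
    assert genotype_fitness(g2, spec)[2] == pytest.approx(0.64)


# ---------------------------------------------------------------------------
# Generation recursion
# ---------------------------------------------------------------------------


def test_all_wild_type_is_fixed_point(measured_params, neutral):
    state = founder_state(0.0, measured_params)
    out = next_generation(state, measured_params, neutral)
    np.testing.assert_allclose(out.female, state.female, atol=1e-12)
    np.testing.assert_allclose(out.male, state.male, atol=1e-12)


def test_output_distributions_normalized(measured_params, viability_cost):
    state = founder_state(0.3, measured_params)
    for _ in range(5):
        state = next_generation(state, measured_params, viability_cost)
        assert state.female.sum() == pytest.approx(1.0, abs=1e-9)
        assert state.male.sum() == pytest.approx(1.0, abs=1e-9)
        assert (state.female >= 0).all() and (state.male >= 0).all()


def test_drive_declines_without_cas9(neutral):
    """Without Cas9 the drive behaves as a recessive female-sterile allele
    and its carrier frequency declines strictly each generation."""
    p = DriveParams(cas9_present=False)
    state = founder_state(0.76, p)
    freqs = [carrier_frequency(state)]
    for _ in range(10):
        state = next_generation(state, p, neutral)
        freqs.append(carrier_frequency(state))
    assert all(b < a for a, b in zip(freqs, freqs[1:]))


def test_perfect_drive_carrier_nondecreasing_and_load_to_one(neutral):
    p = DriveParams(
        conversion_female=1.0,
        conversion_male=1.0,
        germline_resistance_total=0.0,
        embryo_cut_rate=0.0,
    )
    from homingdrive import ExtinctionError

    state = founder_state(0.2, p)
    prev = carrier_frequency(state)
    for _ in range(25):
        try:
            state = next_generation(state, p, neutral)
        except ExtinctionError:
            # complete suppression: every female is sterile
            break
        freq = carrier_frequency(state)
        assert freq >= prev - 1e-12
        prev = freq
    assert genetic_load(state, p, neutral).genetic_load > 0.99


def test_neutral_load_equals_sterile_female_fraction(measured_params, neutral):
    """Closed form: with neutral fitness the only reproductive loss is
    female sterility, so load = sterile-female fraction."""
    state = founder_state(0.5, measured_params)
    for _ in range(4):
        state = next_generation(state, measured_params, neutral)
    report = genetic_load(state, measured_params, neutral)
    sterile_frac = float(state.female[STERILE_FEMALE_MASK].sum())
    assert report.genetic_load == pytest.approx(sterile_frac, abs=1e-9)
    assert report.fertile_female_fraction == pytest.approx(1 - sterile_frac, abs=1e-9)


def test_all_wild_type_load_is_zero(measured_params, neutral):
    state = founder_state(0.0, measured_params)
    assert genetic_load(state, measured_params, neutral).genetic_load == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# Equilibrium and solvers
# ---------------------------------------------------------------------------


def test_equilibrium_invariant_to_initial_frequency(measured_params, neutral):
    eqs = [
        equilibrium_carrier_frequency(measured_params, neutral, init_carrier_freq=f)
        for f in (0.05, 0.2, 0.4)
    ]
    assert max(eqs) - min(eqs) < 1e-3


def test_equilibrium_zero_without_conversion(neutral):
    p = DriveParams(conversion_female=0.0, conversion_male=0.0)
    eq = equilibrium_carrier_frequency(p, neutral, init_carrier_freq=0.2)
    assert eq < 0.01


def test_equilibrium_monotone_in_cost_and_embryo_rate(measured_params):
    eqs = [
        equilibrium_carrier_frequency(
            measured_params,
            FitnessSpec(FitnessModel.DIRECT_VIABILITY, w) if w < 1 else FitnessSpec(),
        )
        for w in (1.0, 0.9, 0.8)
    ]
    assert eqs[0] > eqs[1] > eqs[2]
    eqs_embryo = [
        equilibrium_carrier_frequency(
            DriveParams(embryo_cut_rate=e), FitnessSpec(), init_carrier_freq=0.2
        )
        for e in (0.2, 0.5, 0.8)
    ]
    assert eqs_embryo[0] > eqs_embryo[1] > eqs_embryo[2]


def test_solve_cost_identity_at_zero_cost_equilibrium(measured_params, neutral):
    eq0 = equilibrium_carrier_frequency(measured_params, neutral)
    assert solve_homozygote_cost_for_equilibrium(eq0, measured_params) == pytest.approx(
        0.0, abs=1e-3
    )


def test_solve_cost_monotone_decreasing_in_target(measured_params):
    costs = [
        solve_homozygote_cost_for_equilibrium(t, measured_params) for t in (0.5, 0.7, 0.85)
    ]
    assert costs[0] > costs[1] > costs[2]


def test_solve_cost_rejects_unachievable_target(measured_params):
    with pytest.raises(ValueError):
        solve_homozygote_cost_for_equilibrium(0.99, measured_params)


@pytest.mark.parametrize(
    "eggs, survival, expected",
    [(20, 0.8, 0.875), (2.5, 0.8, 0.0), (10, 0.8, 0.75)],
)
def test_required_genetic_load_examples(eggs, survival, expected):
    assert required_genetic_load(eggs, survival) == pytest.approx(expected)


def test_required_genetic_load_monotone_and_bounds():
    loads = [required_genetic_load(e, 0.8) for e in (10, 20, 40)]
    assert loads[0] < loads[1] < loads[2]
    with pytest.raises(ValueError):
        required_genetic_load(2, 0.8)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    c=st.floats(0.0, 0.78),
    e=st.floats(0.0, 1.0),
    rho=st.floats(0.0, 0.05),
    init=st.floats(0.01, 0.99),
)
def test_distributions_stay_normalized(c, e, rho, init):
    p = DriveParams(
        conversion_female=c, conversion_male=c, embryo_cut_rate=e, relative_r1_rate=rho
    )
    state = founder_state(init, p)
    state = next_generation(state, p, FitnessSpec())
    assert state.female.sum() == pytest.approx(1.0, abs=1e-9)
    assert state.male.sum() == pytest.approx(1.0, abs=1e-9)
    assert (state.female >= 0).all() and (state.male >= 0).all()
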