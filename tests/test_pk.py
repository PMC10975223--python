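import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pona_tdm.exceptions import ConvergenceError, DomainError
from pona_tdm.pk import (
    DEFAULT_PK_PARAMETERS,
    DosingRegimen,
    PKParameters,
    concentration_at,
    simulate,
    simulate_states,
    steady_state_cmin,
    system_matrix,
)

# near-one-compartment limit: negligible peripheral exchange, instantaneous
# absorption, no transit chain
ONE_CPT = PKParameters(CL=20.0, Vc=100.0, Q=1e-9, Vp=100.0, ktr=1.0, ka=600.0, F=1.0, n_transit=0)


def one_cpt_bolus_conc(dose, t, CL=20.0, Vc=100.0, F=1.0):
    return F * dose * math.exp(-(CL / Vc) * t) / Vc * 1000.0


def test_zero_dose_gives_zero_concentration():
    pts = simulate(DEFAULT_PK_PARAMETERS, DosingRegimen(0.0, 24.0, 3), [0, 12, 24, 48])
    assert all(p.conc_ng_per_ml == 0.0 for p in pts)


def test_dose_proportionality_is_exact():
    times = [1.0, 6.0, 24.0, 30.0]
    a = simulate(DEFAULT_PK_PARAMETERS, DosingRegimen(15.0, 24.0, 2), times)
    b = simulate(DEFAULT_PK_PARAMETERS, DosingRegimen(30.0, 24.0, 2), times)
    for pa, pb in zip(a, b):
        assert pb.conc_ng_per_ml == pytest.approx(2.0 * pa.conc_ng_per_ml, rel=1e-12)
    assert steady_state_cmin(DEFAULT_PK_PARAMETERS, DosingRegimen(30.0)) == pytest.approx(
        2.0 * steady_state_cmin(DEFAULT_PK_PARAMETERS, DosingRegimen(15.0)), rel=1e-9
    )


def test_one_compartment_closed_form_single_dose():
    """With no peripheral exchange and near-instant absorption the profile
    matches the bolus closed form F*D*exp(-k t)/Vc within 1%."""
    times = [1.0, 2.0, 5.0, 12.0, 24.0]
    pts = simulate(ONE_CPT, DosingRegimen(100.0, 24.0, 1), times)
    for p in pts:
        assert p.conc_ng_per_ml == pytest.approx(one_cpt_bolus_conc(100.0, p.t_h), rel=0.01)


def test_one_compartment_steady_state_closed_form():
    """Superposition closed form F*D*exp(-k tau) / (Vc (1 - exp(-k tau)))."""
    k = ONE_CPT.CL / ONE_CPT.Vc
    tau = 24.0
    expected = 100.0 * math.exp(-k * tau) / (ONE_CPT.Vc * (1 - math.exp(-k * tau))) * 1000.0
    assert steady_state_cmin(ONE_CPT, DosingRegimen(100.0, tau)) == pytest.approx(expected, rel=0.01)


def test_steady_state_matches_simulated_last_trough():
    reg = DosingRegimen(45.0, 24.0, 60)
    trough = simulate(DEFAULT_PK_PARAMETERS, reg, [60 * 24.0])[0].conc_ng_per_ml
    assert steady_state_cmin(DEFAULT_PK_PARAMETERS, DosingRegimen(45.0, 24.0)) == pytest.approx(
        trough, rel=1e-6
    )


def test_concentration_at_tau_is_the_trough():
    reg = DosingRegimen(45.0, 24.0)
    assert concentration_at(DEFAULT_PK_PARAMETERS, reg, 24.0) == pytest.approx(
        steady_state_cmin(DEFAULT_PK_PARAMETERS, reg), rel=1e-9
    )


def test_peak_is_at_least_trough():
    reg = DosingRegimen(45.0, 24.0)
    trough = concentration_at(DEFAULT_PK_PARAMETERS, reg, 24.0)
    peak = max(concentration_at(DEFAULT_PK_PARAMETERS, reg, t) for t in np.arange(0.5, 24.1, 0.5))
    assert peak >= trough


def test_concentration_at_agrees_with_long_simulation():
    """Interval profile at steady state vs a 150-dose simulation, 0.5 h grid."""
    reg = DosingRegimen(45.0, 24.0)
    n = 150
    grid = np.arange(0.0, 24.5, 0.5)
    sim = simulate(DEFAULT_PK_PARAMETERS, DosingRegimen(45.0, 24.0, n), [(n - 1) * 24.0 + t for t in grid])
    for t, pt in zip(grid, sim):
        assert concentration_at(DEFAULT_PK_PARAMETERS, reg, float(t)) == pytest.approx(
            pt.conc_ng_per_ml, rel=1e-6
        )


def test_mass_balance():
    """Depot + transits + central + peripheral + cumulative elimination equals
    the administered amount F * D * (doses so far) within 1e-6 relative."""
    reg = DosingRegimen(45.0, 24.0, 3)
    times = [0.0, 5.0, 23.9, 24.5, 47.9, 48.5, 100.0]
    states, _ = simulate_states(DEFAULT_PK_PARAMETERS, reg, times)
    for t, x in zip(times, states):
        n_given = min(math.floor(t / 24.0) + 1, 3)
        total = DEFAULT_PK_PARAMETERS.F * 45.0 * n_given
        assert float(x.sum()) == pytest.approx(total, rel=1e-6)


def test_superposition():
    """n doses jointly equal the sum of shifted single-dose profiles."""
    times = [2.0, 26.0, 50.0, 70.0]
    joint = simulate(DEFAULT_PK_PARAMETERS, DosingRegimen(30.0, 24.0, 3), times)
    summed = np.zeros(len(times))
    for k in range(3):
        shifted = []
        for t in times:
            if t >= k * 24.0:
                single = simulate(DEFAULT_PK_PARAMETERS, DosingRegimen(30.0, 24.0, 1), [t - k * 24.0])
                shifted.append(single[0].conc_ng_per_ml)
            else:
                shifted.append(0.0)
        summed += np.array(shifted)
    for j, s in zip(joint, summed):
        assert j.conc_ng_per_ml == pytest.approx(s, rel=1e-8)


def test_matrix_exponential_agrees_with_ode_integrator():
    """Cross-check the expm propagator against a high-accuracy ODE solve."""
    params = DEFAULT_PK_PARAMETERS
    A = system_matrix(params, with_elimination_state=True)
    x0 = np.zeros(A.shape[0])
    x0[0] = params.F * 45.0
    sol = solve_ivp(lambda t, x: A @ x, (0.0, 24.0), x0, method="DOP853",
                    rtol=1e-12, atol=1e-13, t_eval=[6.0, 24.0])
    states, _ = simulate_states(params, DosingRegimen(45.0, 24.0, 1), [6.0, 24.0])
    for i in range(2):
        np.testing.assert_allclose(states[i], sol.y[:, i], atol=1e-8)


def test_steady_state_trough_decreases_with_clearance():
    troughs = [
        steady_state_cmin(
            PKParameters(CL=cl, Vc=120.0, Q=70.0, Vp=800.0, ktr=1.2, ka=1.2), DosingRegimen(45.0)
        )
        for cl in (10.0, 20.0, 30.0, 40.0, 60.0)
    ]
    assert all(a > b for a, b in zip(troughs, troughs[1:]))


def test_nonconvergence_is_reported():
    slow = PKParameters(CL=0.05, Vc=120.0, Q=70.0, Vp=900.0, ktr=1.2, ka=1.2)
    with pytest.raises(ConvergenceError):
        steady_state_cmin(slow, DosingRegimen(45.0, 24.0))


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(CL=-1.0, Vc=120.0, Q=70.0, Vp=800.0, ktr=1.2, ka=1.2),
        dict(CL=30.0, Vc=120.0, Q=70.0, Vp=800.0, ktr=1.2, ka=1.2, F=1.5),
        dict(CL=float("nan"), Vc=120.0, Q=70.0, Vp=800.0, ktr=1.2, ka=1.2),
    ],
)
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(DomainError):
        PKParameters(**kwargs)


def test_invalid_times_rejected():
    with pytest.raises(DomainError):
        simulate(DEFAULT_PK_PARAMETERS, DosingRegimen(45.0), [2.0, 1.0])
    with pytest.raises(DomainError):
        simulate(DEFAULT_PK_PARAMETERS, DosingRegimen(45.0), [-1.0])
    with pytest.raises(DomainError):
        concentration_at(DEFAULT_PK_PARAMETERS, DosingRegimen(45.0, 24.0), 25.0)
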