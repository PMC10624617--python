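import math

import numpy as np
import pytest
from scipy.linalg import expm

from pdpxtal.quantum import (
    S0,
    S1,
    DissipationModel,
    Pulse,
    VibronicSystem,
    build_hamiltonian,
    coherence_magnitude,
    ground_state,
    propagate,
    thermal_state,
)


def test_stationary_ground_state():
    system = VibronicSystem(n_vib=6, temperature=0.0)
    states = propagate(system, [], None, (0.0, 500.0), dt=100.0,
                       initial="ground")
    rho0 = ground_state(system).matrix
    for s in states:
        np.testing.assert_allclose(np.diag(s.matrix).real,
                                   np.diag(rho0).real, atol=1e-10)


def test_trace_hermiticity_positivity(pumped_states):
    for s in pumped_states:
        assert abs(s.trace - 1.0) < 1e-6 or s.trace <= 1.0 + 1e-9
        assert s.hermiticity_defect() < 1e-10
        assert s.min_eigenvalue() > -1e-8


def test_trace_conserved_without_dissipation():
    system = VibronicSystem(n_vib=6, temperature=0.0)
    pump = Pulse(center_time=0.0, fwhm=50.0, peak_rabi_energy=0.02)
    states = propagate(system, [pump], None, (-120.0, 200.0), dt=20.0,
                       initial="ground")
    for s in states:
        assert abs(s.trace - 1.0) < 1e-8


def test_rabi_pi_pulse():
    # n_vib = 2 with zero displacement isolates the v=0 two-level pair
    system = VibronicSystem(n_vib=2, displacement=0.0, temperature=0.0)
    pulse = Pulse(center_time=0.0, fwhm=50.0, peak_rabi_energy=0.01)
    pulse = pulse.with_area(math.pi)
    states = propagate(system, [pulse], None, (-150.0, 150.0), dt=25.0,
                       initial="ground")
    assert states[-1].population(S1) == pytest.approx(1.0, abs=1e-3)


def test_propagator_matches_matrix_exponential():
    # no dissipation, n_vib <= 3: compare against time-ordered expm
    # products on an 80x finer grid (the midpoint-expm oracle carries an
    # O(step^2) commutator error, so it needs a much finer step than the
    # adaptive integrator under test)
    system = VibronicSystem(n_vib=3, displacement=0.8, temperature=0.0)
    pulse = Pulse(center_time=0.0, fwhm=40.0, peak_rabi_energy=0.02,
                  detuning_cm1=200.0)
    t0, t1, dt = -100.0, 100.0, 20.0
    states = propagate(system, [pulse], None, (t0, t1), dt=dt,
                       initial="ground", rtol=1e-11, atol=1e-13)

    ham = build_hamiltonian(system, [pulse])
    rho = ground_state(system).matrix.astype(complex)
    fine = dt / 80.0
    idx = 0
    t = t0
    np.testing.assert_allclose(states[0].matrix, rho, atol=1e-12)
    for k, s in enumerate(states[1:], start=1):
        while t < t0 + k * dt - 1e-9:
            u = expm(-1j * ham(t + fine / 2.0) * fine)
            rho = u @ rho @ u.conj().T
            t += fine
        np.testing.assert_allclose(s.matrix, rho, atol=5e-6)


def test_lindblad_population_decay_rate():
    # only S1 decay active: pop_s1 between pulses is exponential at 1/tau
    system = VibronicSystem(n_vib=3, displacement=0.0, temperature=0.0)
    diss = DissipationModel(s1_lifetime=5.0, vib_dephasing_time=1e6,
                            elec_dephasing_time=1e9)
    dim = system.dim
    rho = np.zeros((dim, dim), complex)
    rho[system.n_vib, system.n_vib] = 1.0  # |S1, v=0>
    from pdpxtal.quantum.propagate import VibronicDensityMatrix
    init = VibronicDensityMatrix(time=0.0, matrix=rho)
    states = propagate(system, [], diss, (0.0, 10000.0), dt=500.0,
                       initial=init)
    t = np.array([s.time for s in states])
    pop = np.array([s.population(S1) for s in states])
    rate = -np.polyfit(t, np.log(pop), 1)[0]
    assert rate == pytest.approx(1.0 / 5000.0, rel=0.01)


def test_lindblad_vibrational_dephasing_rate():
    # only vibrational dephasing active: v0-v1 coherence decays at 1/T2
    system = VibronicSystem(n_vib=3, displacement=0.0, temperature=0.0)
    diss = DissipationModel(s1_lifetime=1e9, vib_dephasing_time=1.0,
                            elec_dephasing_time=1e9)
    dim = system.dim
    rho = np.zeros((dim, dim), complex)
    rho[0, 0] = rho[1, 1] = 0.5
    rho[0, 1] = rho[1, 0] = 0.5
    from pdpxtal.quantum.propagate import VibronicDensityMatrix
    init = VibronicDensityMatrix(time=0.0, matrix=rho)
    states = propagate(system, [], diss, (0.0, 2000.0), dt=100.0,
                       initial=init)
    t = np.array([s.time for s in states])
    coh = np.array([coherence_magnitude(s, S0) for s in states])
    rate = -np.polyfit(t, np.log(coh), 1)[0]
    assert rate == pytest.approx(1.0 / 1000.0, rel=0.02)


def test_thermal_state_populations():
    system = VibronicSystem(mode_frequency=120.0, n_vib=12, temperature=293.0)
    rho = thermal_state(system).matrix
    pops = np.diag(rho).real[: system.n_vib]
    # Boltzmann ratio between successive levels
    beta_ratio = pops[1] / pops[0]
    expected = math.exp(-1.4387768775 * 120.0 / 293.0)
    assert beta_ratio == pytest.approx(expected, rel=1e-3)
    assert abs(pops.sum() - 1.0) < 1e-6
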