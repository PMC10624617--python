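"""Pump-probe and pump-dump-probe numerical experiments.

The pump (400 nm nominal) impulsively excites the displaced S1 surface and
leaves Raman-driven vibrational coherence in S0; the Stokes dump (515 nm
nominal) transfers the S1 wave packet back to S0 by stimulated emission.
When the dump arrives within the vibrational dephasing time this transfer
carries the wave-packet momentum and amplifies the ground-state coherence;
after dephasing it only transfers population (and some position via the
displacement).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .observables import CoherenceTrace
from .propagate import VibronicDensityMatrix, propagate
from .system import S0, S1, DissipationModel, Pulse, VibronicSystem
from .wigner import WignerDistribution, wigner_transform


class OverlappingPulsesWarning(UserWarning):
    pass


def default_system(**overrides) -> VibronicSystem:
    """Model defaults: a low-frequency (120 cm^-1), large-displacement mode
    consistent with the ~4.4-THz impulsive bandwidth of ~100-fs pulses."""
    return VibronicSystem(**overrides)


def default_dissipation(**overrides) -> DissipationModel:
    """50-ps S1 lifetime, ~1-ps vibrational dephasing, 50-fs electronic
    dephasing."""
    return DissipationModel(**overrides)


def default_pump(peak_rabi_energy: float = 0.004, fwhm: float = 100.0) -> Pulse:
    return Pulse(center_time=0.0, fwhm=fwhm, carrier_wavelength=400.0,
                 peak_rabi_energy=peak_rabi_energy)


def default_dump(delay_fs: float, peak_rabi_energy: float = 0.01,
                 fwhm: float = 100.0) -> Pulse:
    return Pulse(center_time=delay_fs, fwhm=fwhm, carrier_wavelength=515.0,
                 peak_rabi_energy=peak_rabi_energy)


def calibrate_pump_population(
    system: VibronicSystem,
    dissipation: DissipationModel | None,
    pulse: Pulse,
    target_s1_population: float,
    max_area: float = math.pi,
    tol: float = 1e-4,
) -> Pulse:
    """Bisect the pulse area so the post-pulse S1 population hits a target.

    The population is measured 2 FWHM after the pulse centre.  Returns a
    copy of ``pulse`` with the calibrated amplitude.
    """

    def s1_after(area: float) -> float:
        p = pulse.with_area(area)
        t1 = p.center_time + 2.0 * p.fwhm
        states = propagate(system, [p], dissipation,
                           (p.center_time - 2.0 * p.fwhm, t1), dt=t1, initial="thermal",
                           rtol=1e-7, atol=1e-10)
        return states[-1].population(S1)

    lo, hi = 0.0, max_area
    if s1_after(hi) < target_s1_population:
        raise ValueError("target S1 population unreachable below max_area")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if s1_after(mid) < target_s1_population:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return pulse.with_area(0.5 * (lo + hi))


def calibrate_dump_depletion(
    system: VibronicSystem,
    dissipation: DissipationModel | None,
    pump: Pulse,
    dump: Pulse,
    max_area: float = 3.0 * math.pi,
) -> Pulse:
    """Choose the dump amplitude that maximally depletes S1.

    Scans the dump pulse area coarsely, then refines with bounded scalar
    minimisation of the post-dump S1 population.  Deterministic.
    """

    def s1_after(area: float) -> float:
        d = dump.with_area(area)
        t1 = d.center_time + 2.0 * d.fwhm
        states = propagate(system, [pump, d], dissipation,
                           (pump.center_time - 2.0 * pump.fwhm, t1), dt=t1,
                           initial="thermal", rtol=1e-7, atol=1e-10)
        return states[-1].population(S1)

    areas = np.linspace(0.2 * math.pi, max_area, 12)
    pops = [s1_after(a) for a in areas]
    i_best = int(np.argmin(pops))
    lo = areas[max(0, i_best - 1)]
    hi = areas[min(len(areas) - 1, i_best + 1)]
    res = minimize_scalar(s1_after, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-3})
    return dump.with_area(float(res.x))


@dataclass
class StudyParameters:
    """A complete, calibrated PDP study configuration."""

    system: VibronicSystem
    dissipation: DissipationModel
    pump: Pulse
    dump_fwhm: float
    dump_area: float
    dump_detuning_cm1: float

    def dump(self, delay_fs: float) -> Pulse:
        pulse = Pulse(center_time=delay_fs, fwhm=self.dump_fwhm,
                      carrier_wavelength=515.0, peak_rabi_energy=0.01,
                      detuning_cm1=self.dump_detuning_cm1)
        return pulse.with_area(self.dump_area)


def coherent_control_study() -> StudyParameters:
    """Calibrated parameters for the pump-dump-probe coherence study.

    Selective stimulated emission needs the Stokes shift (d^2 * omega,
    here 2940 cm^-1) to exceed both the electronic-dephasing linewidth
    (~53 cm^-1 at 100 fs) and the pulse bandwidths, so the displacement is
    large (3.5) and the initial state cold; the single explicit mode then
    stands in for the full Stokes-shifted emission band.  The pump
    amplitude is the output of calibrate_pump_population (12% S1
    population) and the dump area (3 pi at 200 fs FWHM) the output of a
    depletion scan; both are frozen here so study runs are deterministic
    and fast.
    """
    system = VibronicSystem(mode_frequency=120.0, displacement=3.5,
                            n_vib=40, temperature=0.0)
    dissipation = DissipationModel(s1_lifetime=50.0, vib_dephasing_time=1.0,
                                   elec_dephasing_time=100.0)
    stokes_half = 0.5 * system.displacement**2 * system.mode_frequency
    pump = Pulse(center_time=0.0, fwhm=100.0, carrier_wavelength=400.0,
                 peak_rabi_energy=0.008964547416221009,
                 detuning_cm1=stokes_half)
    return StudyParameters(system=system, dissipation=dissipation, pump=pump,
                           dump_fwhm=200.0, dump_area=3.0 * math.pi,
                           dump_detuning_cm1=-stokes_half)


@dataclass
class PDPResult:
    """Aligned pump-only and pump-dump traces plus Wigner snapshots."""

    pp_trace: CoherenceTrace
    pdp_trace: CoherenceTrace
    pp_states: list[VibronicDensityMatrix]
    pdp_states: list[VibronicDensityMatrix]
    wigner_snapshots: dict = field(default_factory=dict)

    def coherence_ratio(self, dump_time: float | None = None) -> float:
        """Peak S0 coherence of the PDP run (after the dump when its time is
        given) relative to the peak S0 coherence of the pump-only run."""
        peak_pp = self.pp_trace.peak_coherence(S0)
        peak_pdp = self.pdp_trace.peak_coherence(S0, after=dump_time)
        return peak_pdp / peak_pp


def simulate_pdp_experiment(
    system: VibronicSystem,
    dissipation: DissipationModel | None,
    pump: Pulse,
    dump: Pulse | None = None,
    t_span: tuple[float, float] | None = None,
    dt: float = 5.0,
    snapshot_times: tuple[float, ...] = (),
    initial: str | VibronicDensityMatrix = "thermal",
) -> PDPResult:
    """Run matched pump-only (PP) and pump-dump (PDP) propagations.

    With ``dump=None`` (or a zero-amplitude dump) the PDP trace equals the
    PP trace.  Overlapping pump/dump pulses trigger a warning: electronic
    coherence between the two interactions has then not dephased, outside
    the regime the model is meant for.
    """
    if dump is not None and dump.peak_rabi_energy > 0:
        if dump.center_time <= pump.center_time:
            raise ValueError("dump must arrive after the pump")
        gap = dump.center_time - pump.center_time
        if gap < 0.5 * (pump.fwhm + dump.fwhm):
            warnings.warn(
                "pump and dump pulses overlap; electronic coherence has not "
                "dephased between the interactions", OverlappingPulsesWarning)
    if t_span is None:
        t_end = (dump.center_time if dump is not None else pump.center_time) + 1500.0
        t_span = (pump.center_time - 300.0, t_end)

    pp_states = propagate(system, [pump], dissipation, t_span, dt, initial=initial)
    if dump is None or dump.peak_rabi_energy == 0:
        pdp_states = pp_states
    else:
        pdp_states = propagate(system, [pump, dump], dissipation, t_span, dt,
                               initial=initial)

    result = PDPResult(
        pp_trace=CoherenceTrace.from_states(pp_states),
        pdp_trace=CoherenceTrace.from_states(pdp_states),
        pp_states=pp_states,
        pdp_states=pdp_states,
    )
    if snapshot_times:
        times = np.array([s.time for s in pp_states])
        for t_snap in snapshot_times:
            i = int(np.argmin(np.abs(times - t_snap)))
            result.wigner_snapshots[t_snap] = {
                "pp": {e: wigner_transform(pp_states[i], e) for e in (S0, S1)},
                "pdp": {e: wigner_transform(pdp_states[i], e) for e in (S0, S1)},
            }
    return result
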