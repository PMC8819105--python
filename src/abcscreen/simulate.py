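"""Synthetic plate-reader data with the structure the analysis assumes.

The generator emulates an FGF-stimulated luciferase reporter: vehicle
wells respond to bFGF added at 0 h with a transient induction peaking
near 4-6 h; chemical exposure (at -1 h) multiplies that response on the
log scale by a concentration-dependent disruption that is either
sustained over the 24 h window or an early transient pulse.  Because the
disruption is multiplicative in the log, the ground-truth log fold
change of a chemical well against the vehicle mean is exactly
``delta(c) * w(t)``, which makes recovery of the area-between-curves
statistic analytically checkable (:func:`noiseless_abc_truth`).

Reader noise is multiplicative lognormal, independent per read; the
real instrument's noise law is unknown and this is an assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import (
    ROLE_BACKGROUND,
    ROLE_CHEMICAL_BFGF,
    ROLE_VEHICLE_BFGF,
    VEHICLE,
    PlateTimeSeries,
    RunConfig,
    StudyDesign,
    ViabilityRecord,
)

__all__ = [
    "SignalModelParams",
    "generate_timecourse",
    "generate_study",
    "generate_viability",
    "noiseless_abc_truth",
    "stimulus_response",
    "disruption_profile",
    "hill_disruption",
]


@dataclass(frozen=True)
class SignalModelParams:
    """Parameters of the synthetic luminescence signal model.

    Attributes
    ----------
    baseline
        Background luminescence ``B`` (detector units) of unstimulated
        wells.
    amplitude
        Peak fold induction ``A`` of the bFGF response over baseline;
        vehicle wells follow ``B * (1 + A * g(t))`` with ``g`` a
        unit-peak impulse response.  Strong SRE-reporter inductions are
        of order 10-100 fold.
    peak_time_h
        Time of the bFGF response peak (hours); the reporter peaks at
        roughly 4-6 h.
    delta_max
        Maximal disruption in natural-log fold-change units; signed
        (positive or negative disruption).
    ec50
        Concentration (ug/mL) of half-maximal disruption.
    hill
        Hill slope of the disruption-concentration relationship (> 0).
    profile
        Time profile of the disruption: ``"sustained"`` ramps up and
        saturates by ~10 h, ``"transient"`` pulses at ~4 h and decays,
        ``"constant"`` is a flat unit profile (testing hook).
    noise_sd
        Standard deviation of the lognormal reader noise (log scale).
    bfgf_dose_ng_ml
        Stimulus dose, metadata only.
    """

    baseline: float = 100.0
    amplitude: float = 100.0
    peak_time_h: float = 5.0
    delta_max: float = 0.5
    ec50: float = 10.0
    hill: float = 1.5
    profile: str = "sustained"
    noise_sd: float = 0.1
    bfgf_dose_ng_ml: float = 2.0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ParameterError("baseline B must be positive")
        if self.amplitude < 0:
            raise ParameterError("amplitude A must be >= 0")
        if not 0 < self.peak_time_h < 24:
            raise ParameterError("peak_time_h must lie in (0, 24)")
        if self.hill <= 0:
            raise ParameterError("hill slope must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.profile not in ("sustained", "transient", "constant"):
            raise ParameterError(f"unknown profile {self.profile!r}")


def stimulus_response(t: np.ndarray, peak_time_h: float) -> np.ndarray:
    """Unit-peak bFGF impulse response ``g(t) = (t/t_p) exp(1 - t/t_p)``."""
    t = np.asarray(t, dtype=float)
    return (t / peak_time_h) * np.exp(1.0 - t / peak_time_h)


def disruption_profile(t: np.ndarray, profile: str) -> np.ndarray:
    """Unit-peak disruption time profile ``w(t)``."""
    t = np.asarray(t, dtype=float)
    if profile == "sustained":
        return 1.0 - np.exp(-t / 4.0)
    if profile == "transient":
        return (t / 4.0) * np.exp(1.0 - t / 4.0)
    if profile == "constant":
        return np.ones_like(t)
    raise ParameterError(f"unknown profile {profile!r}")


def hill_disruption(concentration: float, params: SignalModelParams) -> float:
    """Signed disruption magnitude ``delta(c)`` (natural-log fold units)."""
    c = float(concentration)
    if c == 0:
        return 0.0
    ch = c**params.hill
    return params.delta_max * ch / (ch + params.ec50**params.hill)


def generate_timecourse(
    params: SignalModelParams,
    design: StudyDesign,
    config: RunConfig,
    seed: int,
    sample_step_h: float = 0.5,
    plate_id: str = "SIM",
) -> PlateTimeSeries:
    """Simulate one experiment: a chemical plus its control wells.

    Noiseless means: background wells read ``B``; vehicle+bFGF wells read
    ``B * (1 + A * g(t))``; chemical wells multiply the vehicle mean by
    ``exp(delta(c) * w(t))``.  Observed reads multiply the mean by
    ``exp(eps)``, ``eps ~ N(0, noise_sd^2)`` independent per read, drawn
    in a fixed well order so a seed pins the whole plate.
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.window
    n_steps = int(round((hi - lo) / sample_step_h))
    times = lo + sample_step_h * np.arange(n_steps + 1)
    g = stimulus_response(times, params.peak_time_h)
    vehicle_mean = params.baseline * (1.0 + params.amplitude * g)
    w = disruption_profile(times, params.profile)

    rows: list[pd.DataFrame] = []

    def emit(well: str, chemical: str, conc: float, role: str, rep: int, mean: np.ndarray) -> None:
        noise = rng.normal(0.0, params.noise_sd, size=times.shape) if params.noise_sd > 0 else 0.0
        rows.append(
            pd.DataFrame(
                {
                    "plate_id": plate_id,
                    "well": well,
                    "time_h": times,
                    "chemical": chemical,
                    "concentration_ug_ml": conc,
                    "role": role,
                    "replicate": rep,
                    "luminescence": mean * np.exp(noise),
                }
            )
        )

    for rep in range(1, config.n_replicates + 1):
        emit(f"BG{rep}", VEHICLE, 0.0, ROLE_BACKGROUND, rep, np.full_like(times, params.baseline))
    for rep in range(1, config.n_replicates + 1):
        emit(f"VC{rep}", VEHICLE, 0.0, ROLE_VEHICLE_BFGF, rep, vehicle_mean)
    for ci, conc in enumerate(design.concentration_series, start=1):
        delta = hill_disruption(conc, params)
        chem_mean = vehicle_mean * np.exp(delta * w)
        for rep in range(1, config.n_replicates + 1):
            emit(f"C{ci}R{rep}", design.chemical, conc, ROLE_CHEMICAL_BFGF, rep, chem_mean)

    return PlateTimeSeries(pd.concat(rows, ignore_index=True))


def generate_study(
    params_by_chemical: dict[str, SignalModelParams],
    designs: dict[str, StudyDesign],
    config: RunConfig,
    seed: int,
    sample_step_h: float = 0.5,
) -> dict[str, PlateTimeSeries]:
    """One simulated plate (experiment) per chemical, seeds spawned deterministically."""
    seeds = np.random.SeedSequence(seed).spawn(len(params_by_chemical))
    plates: dict[str, PlateTimeSeries] = {}
    for child, (chem, params) in zip(seeds, sorted(params_by_chemical.items())):
        plates[chem] = generate_timecourse(
            params,
            designs[chem],
            config,
            seed=int(child.generate_state(1)[0] % 2**31),
            sample_step_h=sample_step_h,
            plate_id=f"SIM-{chem}",
        )
    return plates


def generate_viability(
    truth: tuple[float, float, float, float],
    concentrations: list[float] | np.ndarray,
    noise_sd: float,
    seed: int,
    n_replicates: int = 3,
    abs_blank: float = 0.08,
    abs_vehicle: float = 1.20,
    chemical: str = "CHEM",
) -> list[ViabilityRecord]:
    """Simulate endpoint absorbance reads from a 4PL viability truth.

    ``truth = (b, c, d, e)`` parameterises the four-parameter
    log-logistic viability curve (see :mod:`abcscreen.doseresponse`);
    reads are ``abs_blank + (abs_vehicle - abs_blank) * f(x) + noise``.
    """
    if abs_vehicle <= abs_blank:
        raise ParameterError("abs_vehicle must exceed abs_blank")
    from .doseresponse import ll4

    b, c, d, e = truth
    rng = np.random.default_rng(seed)
    records: list[ViabilityRecord] = []
    for conc in np.asarray(concentrations, dtype=float):
        frac = ll4(conc, b, c, d, e)
        for rep in range(1, n_replicates + 1):
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            records.append(
                ViabilityRecord(
                    chemical=chemical,
                    concentration=float(conc),
                    abs_sample=abs_blank + (abs_vehicle - abs_blank) * frac + eps,
                    abs_blank=abs_blank,
                    abs_vehicle=abs_vehicle,
                    replicate=rep,
                )
            )
    return records


def noiseless_abc_truth(
    params: SignalModelParams, concentration: float, config: RunConfig, step_h: float = 0.005
) -> float:
    """Exact ABC of the generator's mean model at one concentration.

    The generator's true log fold change is ``delta(c) * w(t)``, so the
    area between curves over the window is ``|delta(c)| * int w(t) dt``,
    evaluated by fine-grid trapezoid quadrature (step <= 0.01 h) and
    expressed in the configured log base.
    """
    if step_h > 0.01:
        raise ParameterError("quadrature step must be <= 0.01 h")
    lo, hi = config.window
    t = np.arange(lo, hi + step_h / 2, step_h)
    w = disruption_profile(t, params.profile)
    delta = hill_disruption(concentration, params)
    return abs(delta) * float(np.trapezoid(np.abs(w), t)) / config.log_divisor
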