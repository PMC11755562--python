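"""Synthetic fluorescence readouts for the peptide inhibitor assay.

The real assay digests a plasmid with EcoRI in the presence of a large molar
excess of a blocking peptide and quantifies the excised product band on a
gel. The generator emulates the observed behaviour: product fluorescence
rises to a saturation plateau as a single-exponential in time, a peptide
delays the rate without changing the plateau (competitive-style rate
scaling), the effect is dose dependent, and every batch carries a
"no peptide" control. Band-densitometry noise is modelled as multiplicative
Gaussian, clamped at zero.

F(t) = f_max * plateau_shift * (1 - exp(-k_eff * t)),
k_eff = k0 / (1 + dose / d50).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

CONTROL_ID = "no_peptide"

MEASUREMENT_COLUMNS = ["peptide_id", "dose", "time_h", "replicate",
                       "fluorescence_au"]


@dataclass(frozen=True)
class AssayConfig:
    """Kinetic, sampling and noise parameters of a simulated assay.

    f_max: saturation fluorescence (arbitrary units).
    k0: control digestion rate constant (1/h); the default 1.0/h puts the
        control >= 95% of saturation at the 3 h reference time, matching the
        plateau the assay is read at.
    times: sampling grid in hours (hourly 0-5 by default).
    ref_time: the time point used for scoring (3 h).
    n_rep: replicates per condition (three in the assay).
    noise_cv: coefficient of variation of the multiplicative noise.
    doses: molar-equivalence ladder for dose-response runs (x5 to x500);
        single-dose panel runs use the standard x500 condition.
    seed: RNG seed.
    """

    f_max: float = 1000.0
    k0: float = 1.0
    times: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    ref_time: float = 3.0
    n_rep: int = 3
    noise_cv: float = 0.05
    doses: tuple = (5.0, 50.0, 150.0, 500.0)
    panel_dose: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f_max <= 0 or self.k0 <= 0:
            raise ValueError("f_max and k0 must be positive")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.ref_time not in self.times:
            raise ValueError("ref_time must be one of the sampling times")

    def with_(self, **kwargs) -> "AssayConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PeptideEffect:
    """Inhibitory effect of one peptide.

    d50: dose (molar equivalents) at which the rate constant halves.
    plateau_shift: multiplier on the saturation level (1 = unchanged, as
        observed for inhibitory peptides).
    no_band: the reaction yields no measurable product band at all (the
        nuclease-induction phenotype); fluorescence is identically zero.
    """

    peptide_id: str
    d50: float
    plateau_shift: float = 1.0
    no_band: bool = False

    def __post_init__(self) -> None:
        if self.d50 <= 0:
            raise ValueError("d50 must be positive")
        if not 0 < self.plateau_shift <= 1:
            raise ValueError("plateau_shift must be in (0, 1]")


#: An effect whose rate suppression is negligible at any tested dose.
def null_effect(peptide_id: str) -> PeptideEffect:
    return PeptideEffect(peptide_id, d50=1e12)


def expected_curve(effect: PeptideEffect | None, dose: float,
                   config: AssayConfig) -> Callable[[float], float]:
    """Noise-free fluorescence as a function of time (hours).

    ``effect=None`` (or dose 0) gives the control curve
    f_max * (1 - exp(-k0 t)).
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if effect is None:
        k_eff, shift, zero = config.k0, 1.0, False
    else:
        k_eff = config.k0 / (1.0 + dose / effect.d50)
        shift, zero = effect.plateau_shift, effect.no_band

    def curve(t: float) -> float:
        if zero:
            return 0.0
        return config.f_max * shift * (1.0 - np.exp(-k_eff * t))

    return curve


def _emit(rows: list, rng: np.random.Generator, peptide_id: str, dose: float,
          curve: Callable[[float], float], config: AssayConfig,
          times: Sequence[float]) -> None:
    for t in times:
        expected = curve(t)
        noise = rng.normal(0.0, config.noise_cv, size=config.n_rep)
        for rep, eps in enumerate(noise, start=1):
            value = max(expected * (1.0 + eps), 0.0)
            rows.append((peptide_id, dose, t, rep, value))


def simulate_panel(effects: Iterable[PeptideEffect], config: AssayConfig,
                   dose: float | None = None) -> pd.DataFrame:
    """Full time courses for every peptide at one dose, plus the control.

    Returns a tidy measurement table (peptide_id, dose, time_h, replicate,
    fluorescence_au), fully reproducible from ``config.seed``.
    """
    effects = list(effects)
    if not effects:
        raise ValueError("no peptide effects supplied")
    if dose is None:
        dose = config.panel_dose
    rng = np.random.default_rng(config.seed)
    rows: list = []
    _emit(rows, rng, CONTROL_ID, 0.0, expected_curve(None, 0.0, config),
          config, config.times)
    for effect in effects:
        _emit(rows, rng, effect.peptide_id, dose,
              expected_curve(effect, dose, config), config, config.times)
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def simulate_dose_response(effect: PeptideEffect,
                           config: AssayConfig) -> pd.DataFrame:
    """Measurements at the reference time across the dose ladder.

    The control (dose 0) is included; with noise off, the expected relative
    intensity decreases strictly with dose.
    """
    rng = np.random.default_rng(config.seed)
    rows: list = []
    _emit(rows, rng, CONTROL_ID, 0.0, expected_curve(None, 0.0, config),
          config, (config.ref_time,))
    for dose in config.doses:
        _emit(rows, rng, effect.peptide_id, dose,
              expected_curve(effect, dose, config), config, (config.ref_time,))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_measurements(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = set(MEASUREMENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame
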