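"""Synthetic reference signature catalog and the age-spectrum model.

The analysis needs reference single-base-substitution signatures usable as
SBS1, SBS5, SBS18 and the HSPC/SBSblood profile.  The published catalogs are
external data, so this module constructs a *synthetic* stand-in catalog with
the qualitative shape of each process, built deterministically from closed
forms plus a fixed-seed jitter:

* ``SBS1``  — deamination of methylated cytosine: mass concentrated on the
  four N[C>T]G channels.
* ``SBS5``  — flat, clock-like background with a mild T>C / C>T tilt.
* ``SBS18`` — reactive-oxygen damage: C>A dominated.
* ``HSPC``  — the blood-specific clock-like profile: broad, with extra
  weight on T>A and C>G relative to SBS5.

A real catalog (e.g. COSMIC) can be supplied as a channels x signatures TSV
through :func:`hsctrace.spectra.read_spectra_tsv`; every downstream routine
takes the catalog as an argument.

The age-spectrum model predicts the absolute 96-channel spectrum of a
healthy HSPC at a given age as a fetal component plus a linear postnatal
component::

    predicted(age) = birth_load * prenatal_profile + rate * age * postnatal_profile

with the profiles defined by the same age-interval signature mixture the
simulator uses, so simulated colonies and the model share one generative
story by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import BASES, CHANNELS, CHANNEL_INDEX, N_CHANNELS, spectrum_frame

SIGNATURE_NAMES = ["SBS1", "SBS5", "SBS18", "HSPC"]

# Internal construction seed for the synthetic catalog; fixed so the catalog
# is a constant of the package, independent of any analysis seed.
_CATALOG_SEED = 961


def _jitter(rng, n, scale):
    return rng.gamma(shape=1.0 / scale, scale=scale, size=n)


def _normalize(v):
    v = np.clip(np.asarray(v, dtype=float), 0.0, None)
    return v / v.sum()


def default_catalog() -> pd.DataFrame:
    """Build the synthetic reference catalog (channels x 4 signatures)."""
    rng = np.random.default_rng(_CATALOG_SEED)

    sbs1 = np.full(N_CHANNELS, 0.04 / 92)
    for five in BASES:
        sbs1[CHANNEL_INDEX[f"{five}[C>T]G"]] = 0.96 / 4 * (0.7 + 0.6 * rng.random())
    sbs1 = _normalize(sbs1 * _jitter(rng, N_CHANNELS, 0.05))

    sbs5 = np.ones(N_CHANNELS)
    for five in BASES:
        for three in BASES:
            sbs5[CHANNEL_INDEX[f"{five}[T>C]{three}"]] = 2.2
            sbs5[CHANNEL_INDEX[f"{five}[C>T]{three}"]] = 1.6
    sbs5 = _normalize(sbs5 * _jitter(rng, N_CHANNELS, 0.08))

    sbs18 = np.full(N_CHANNELS, 0.08 / 80)
    for five in BASES:
        for three in BASES:
            w = 2.0 if three in "AT" else 1.0
            sbs18[CHANNEL_INDEX[f"{five}[C>A]{three}"]] = 0.92 / 16 * w
    sbs18 = _normalize(sbs18 * _jitter(rng, N_CHANNELS, 0.10))

    hspc = np.ones(N_CHANNELS) * 0.6
    for five in BASES:
        for three in BASES:
            hspc[CHANNEL_INDEX[f"{five}[T>A]{three}"]] = 2.4
            hspc[CHANNEL_INDEX[f"{five}[C>G]{three}"]] = 1.8
            hspc[CHANNEL_INDEX[f"{five}[T>G]{three}"]] = 1.4
    hspc = _normalize(hspc * _jitter(rng, N_CHANNELS, 0.08))

    return spectrum_frame(
        {"SBS1": sbs1, "SBS5": sbs5, "SBS18": sbs18, "HSPC": hspc}
    )


#: Default age-interval signature mixture: neonatal mutations are dominated
#: by SBS1 and SBS5; postnatal accumulation adds SBS18 and the HSPC profile.
DEFAULT_SCHEDULE: tuple[tuple[float, float, dict], ...] = (
    (0.0, 0.75, {"SBS1": 0.40, "SBS5": 0.60}),
    (0.75, float("inf"), {"SBS1": 0.15, "SBS5": 0.45, "SBS18": 0.10, "HSPC": 0.30}),
)


def validate_schedule(schedule) -> None:
    for start, end, weights in schedule:
        if not end > start:
            raise ValueError("schedule interval must have end > start")
        w = np.array(list(weights.values()), dtype=float)
        if (w < 0).any():
            raise ValueError("schedule weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("each schedule row must sum to 1")


def schedule_weights(schedule, age: float) -> dict:
    """Mixture weights applicable at a given age (years since conception)."""
    for start, end, weights in schedule:
        if start <= age < end:
            return weights
    # ages at/after the last interval fall into the last row
    return schedule[-1][2]


def mixture_profile(catalog: pd.DataFrame, weights: dict) -> np.ndarray:
    prof = np.zeros(N_CHANNELS)
    for name, w in weights.items():
        prof += w * catalog[name].to_numpy()
    return _normalize(prof)


@dataclass
class AgeSpectrumModel:
    """Predicted absolute 96-channel spectrum at a given age.

    ``predicted(age) = birth_load * prenatal + rate * age * postnatal`` with
    both profiles normalized signature mixtures.  Defaults tie the model to
    the simulator's generative schedule.
    """

    birth_load: float = 84.0
    rate: float = 16.0
    prenatal_profile: np.ndarray = None
    postnatal_profile: np.ndarray = None
    catalog: pd.DataFrame = field(default_factory=default_catalog)
    schedule: tuple = DEFAULT_SCHEDULE

    def __post_init__(self):
        if self.prenatal_profile is None:
            self.prenatal_profile = mixture_profile(
                self.catalog, schedule_weights(self.schedule, 0.0)
            )
        if self.postnatal_profile is None:
            self.postnatal_profile = mixture_profile(
                self.catalog, schedule_weights(self.schedule, 10.0)
            )

    def predicted(self, age: float) -> np.ndarray:
        if age < 0:
            raise ValueError("age must be nonnegative")
        return (
            self.birth_load * self.prenatal_profile
            + self.rate * age * self.postnatal_profile
        )
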