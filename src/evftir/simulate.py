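"""Seeded generator of two-condition cell/EV ATR-FTIR absorbance spectra.

The generator emulates the statistical structure the analysis assumes, for a
study design of 2 conditions x 3 biological x 3 technical replicates per
sample type on a 4000-600 cm^-1 grid:

* Gaussian absorption bands at the fingerprint-region wavenumbers of the
  bundled assignment table, riding on one broad "matrix envelope" band (real
  fingerprint spectra sit on a broad overlapping-band background; without it,
  area normalization would couple any injected amplitude change into every
  other band's normalized intensity at a strength no real spectrum shows);
* condition effects as per-band amplitude multipliers (treated = base x
  multiplier);
* a replicate noise hierarchy: lognormal per-biological-replicate global
  scale, lognormal per-spectrum multiplicative scatter, polynomial baseline
  drift, and additive white noise.

All randomness flows from a single integer seed through counter-derived
substreams, so generating spectrum k never perturbs spectrum j < k and the
output is bit-reproducible.

Effect *directions* in the default scenarios mirror the treatment phenotype
the pipeline is meant to recover (decreases at 1240 and 1085 cm^-1 in both
sample types; additional decreases at 1056/969/915 and an increase at
991 cm^-1 in EVs); the magnitudes (x0.7 down, x1.4 up), band widths and noise
levels are generator choices documented in the methods note, not measured
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import SampleMeta, SpectraSet, WavenumberAxis

CONDITIONS = ("control", "abeta")

#: Base band amplitudes (A.U.) for every fingerprint-region band, by center.
#: Bands read as peaks in the study (the quantified targets) dominate their
#: close unobserved neighbours; otherwise, in a 14 cm^-1 doublet of equals,
#: the second-derivative apex flip-flops between partners across replicates
#: and neither reads as one stable peak.
BAND_AMPLITUDES = {
    1240.0: 0.50, 1221.0: 0.25, 1172.0: 0.40, 1170.0: 0.40, 1158.0: 0.25,
    1121.0: 0.45, 1110.0: 0.30, 1085.0: 0.60, 1056.0: 0.55, 1053.0: 0.55,
    1039.0: 0.35, 1031.0: 0.40, 1022.0: 0.35, 991.0: 0.30, 988.0: 0.30,
    969.0: 0.35, 929.0: 0.12, 923.0: 0.20, 915.0: 0.70,
}

#: Band centers present in each sample type (doublet partners are type-specific).
BAND_CENTERS = {
    "cells": (1240.0, 1170.0, 1158.0, 1121.0, 1110.0, 1085.0, 1053.0, 1039.0,
              1022.0, 988.0, 969.0, 923.0),
    "EVs": (1240.0, 1221.0, 1172.0, 1158.0, 1121.0, 1110.0, 1085.0, 1056.0,
            1031.0, 991.0, 969.0, 929.0, 915.0),
}

#: Amplitude multipliers applied to the treated condition, by sample type.
EFFECT_MULTIPLIERS = {
    "cells": {1240.0: 0.7, 1085.0: 0.7},
    "EVs": {1240.0: 0.7, 1085.0: 0.7, 1056.0: 0.7, 969.0: 0.7, 915.0: 0.7,
            991.0: 1.4},
}

DEFAULT_BAND_WIDTH = 5.0  # cm^-1 (Gaussian sd; FWHM ~ 11.8 cm^-1)

#: Broad envelope underlying the fingerprint region (center, sd, amplitude).
ENVELOPE_BAND = (1090.0, 160.0, 2.5)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band of the simulated spectrum."""

    center: float
    width_sd: float = DEFAULT_BAND_WIDTH
    base_amplitude: float = 0.3
    effect_multiplier: float = 1.0
    center_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.width_sd <= 0:
            raise ValueError("width_sd must be positive")
        if self.base_amplitude < 0 or self.effect_multiplier < 0:
            raise ValueError("amplitudes and multipliers must be >= 0")
        if self.center_jitter_sd < 0:
            raise ValueError("center_jitter_sd must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated acquisition campaign."""

    sample_type: str = "EVs"
    bands: tuple[BandSpec, ...] = ()
    grid_high: float = 4000.0
    grid_low: float = 600.0
    spacing: float = 4.0
    n_bio: int = 3
    n_tech: int = 3
    bio_sd: float = 0.15        # lognormal sd of the per-bio-replicate scale
    tech_noise_sd: float = 0.02  # additive Gaussian noise sd (A.U.)
    drift: tuple[float, ...] = (0.05, 0.01, 0.003)  # polynomial coefficients
    scatter_sd: float = 0.1     # lognormal sd of the per-spectrum scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("n_bio and n_tech must be >= 1")
        for name in ("bio_sd", "tech_noise_sd", "scatter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.drift) > 3:
            raise ValueError("drift polynomial degree must be <= 2")

    def axis(self) -> WavenumberAxis:
        n = int(round((self.grid_high - self.grid_low) / self.spacing)) + 1
        return WavenumberAxis(self.grid_high - self.spacing * np.arange(n))


def _drift(cfg: SimConfig, v: np.ndarray) -> np.ndarray:
    """Baseline drift polynomial evaluated on a scaled wavenumber variable."""
    u = (v - cfg.grid_low) / 1000.0
    out = np.zeros_like(v)
    for k, c in enumerate(cfg.drift):
        out += c * u**k
    return out


def simulate_spectrum(
    cfg: SimConfig,
    condition: str,
    bio_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One spectrum row: scattered, scaled band sum plus drift and noise.

    ``A(v) = scatter * bio_scale * sum_bands amp_cond *
    exp(-(v - center - jitter)^2 / (2 width^2)) + drift(v) + eps(v)`` with
    ``amp_cond = base`` (control) or ``base * effect_multiplier`` (abeta) and
    iid Gaussian ``eps``.  Deterministic given the generator state.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    v = cfg.axis().values
    signal = np.zeros_like(v)
    for band in cfg.bands:
        amp = band.base_amplitude
        if condition == "abeta":
            amp *= band.effect_multiplier
        jitter = rng.normal(0.0, band.center_jitter_sd) if band.center_jitter_sd else 0.0
        signal += amp * np.exp(-((v - band.center - jitter) ** 2) / (2 * band.width_sd**2))
    scatter = float(np.exp(rng.normal(0.0, cfg.scatter_sd))) if cfg.scatter_sd else 1.0
    noise = rng.normal(0.0, cfg.tech_noise_sd, v.size) if cfg.tech_noise_sd else 0.0
    return scatter * bio_scale * signal + _drift(cfg, v) + noise


def simulate_dataset(cfg: SimConfig) -> SpectraSet:
    """Simulate the full 2 x n_bio x n_tech design as a SpectraSet.

    Substreams: the per-bio-replicate scale uses stream ``[seed, 7, c, b]``
    and each spectrum stream ``[seed, 11, c, b, t]``, so the output for any
    spectrum depends only on the seed and its design coordinates.
    """
    axis = cfg.axis()
    rows, meta = [], []
    for c_idx, condition in enumerate(CONDITIONS):
        for b in range(1, cfg.n_bio + 1):
            scale_rng = np.random.default_rng([cfg.seed, 7, c_idx, b])
            bio_scale = float(np.exp(scale_rng.normal(0.0, cfg.bio_sd)))
            for t in range(1, cfg.n_tech + 1):
                rng = np.random.default_rng([cfg.seed, 11, c_idx, b, t])
                rows.append(simulate_spectrum(cfg, condition, bio_scale, rng))
                meta.append(
                    SampleMeta(
                        sample_id=f"{cfg.sample_type}_{condition}_b{b}_t{t}",
                        sample_type=cfg.sample_type,
                        condition=condition,
                        bio_rep=b,
                        tech_rep=t,
                    )
                )
    return SpectraSet(
        axis=axis,
        absorbance=np.array(rows),
        meta=tuple(meta),
        provenance=(
            f"simulate_dataset: {cfg.sample_type}, seed={cfg.seed}, "
            f"2x{cfg.n_bio}x{cfg.n_tech} design, {len(axis)} points",
        ),
    )


def default_scenario(sample_type: str, seed: int = 0) -> SimConfig:
    """The study-design scenario for one sample type.

    Bands at every fingerprint wavenumber observed in that sample type plus
    the broad envelope; treated-condition multipliers below 1 at 1240 and
    1085 cm^-1 (both types) and at 1056/969/915 cm^-1 (EVs), above 1 at
    991 cm^-1 (EVs), exactly 1 elsewhere.
    """
    if sample_type not in BAND_CENTERS:
        raise ValueError(
            f"unknown sample type {sample_type!r}; expected one of "
            f"{tuple(BAND_CENTERS)}"
        )
    effects = EFFECT_MULTIPLIERS[sample_type]
    bands = [
        BandSpec(
            center=c,
            width_sd=DEFAULT_BAND_WIDTH,
            base_amplitude=BAND_AMPLITUDES[c],
            effect_multiplier=effects.get(c, 1.0),
        )
        for c in BAND_CENTERS[sample_type]
    ]
    env_center, env_sd, env_amp = ENVELOPE_BAND
    bands.append(BandSpec(center=env_center, width_sd=env_sd, base_amplitude=env_amp))
    return SimConfig(sample_type=sample_type, bands=tuple(bands), seed=seed)


def null_scenario(sample_type: str = "EVs", seed: int = 0) -> SimConfig:
    """The default scenario with every effect multiplier reset to 1."""
    cfg = default_scenario(sample_type, seed=seed)
    return replace(
        cfg, bands=tuple(replace(b, effect_multiplier=1.0) for b in cfg.bands)
    )


def shift_scenario(seed: int = 0, jitter_sd: float = 5.0) -> SimConfig:
    """Cells scenario whose 1053 cm^-1 band wobbles between spectra.

    The per-spectrum center jitter makes the matched apex position spread by
    more than one grid step within a condition, reconstructing the situation
    where a target peak must be excluded from quantification because it does
    not sit at one position across samples of the same condition.
    """
    cfg = default_scenario("cells", seed=seed)
    bands = tuple(
        replace(b, center_jitter_sd=jitter_sd) if b.center == 1053.0 else b
        for b in cfg.bands
    )
    return replace(cfg, bands=bands)
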