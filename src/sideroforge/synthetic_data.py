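"""Seeded simulators for accurate-mass peak lists and OD growth curves.

Both simulators are fully determined by their seed, and both emit ground
truth sufficient to score the downstream stages (matcher recall/precision,
growth-rate bias) without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .assembly import AssembledProduct
from .fragmenter import predict_fragments
from .growthfit import GrowthCurve
from .matcher import Spectrum

__all__ = [
    "SpectrumSimConfig",
    "GrowthSimConfig",
    "SpikeTruth",
    "simulate_spectra",
    "simulate_growth",
]


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Peak-list simulation: spiked compounds + ppm noise + uniform decoys."""

    compounds: tuple[AssembledProduct, ...]
    mass_error_sd_ppm: float = 2.0
    decoys_per_spectrum: int = 0
    decoy_mz_range: tuple[float, float] = (66.7, 1000.0)
    fragment_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass_error_sd_ppm < 0:
            raise ValueError("mass error sd must be >= 0")
        if not 0.0 <= self.fragment_dropout <= 1.0:
            raise ValueError("fragment dropout must be in [0, 1]")
        if self.decoys_per_spectrum < 0:
            raise ValueError("decoy count must be >= 0")
        if not self.compounds and self.decoys_per_spectrum == 0:
            raise ValueError("nothing to emit: no compounds and no decoys")


@dataclass(frozen=True)
class SpikeTruth:
    """Ground truth for one spiked spectrum."""

    sample: str
    compound_id: str
    true_mz: float
    observed_mz: float


@dataclass(frozen=True)
class GrowthSimConfig:
    """Growth-curve simulation parameters."""

    model: str = "logistic"  # "exponential" | "logistic"
    rate: float = 0.3
    initial_od: float = 0.1
    carrying_capacity: float = 4.0
    lag_h: float = 0.0
    noise_sd: float = 0.0
    times: tuple[float, ...] = tuple(float(t) / 2 for t in range(0, 81))
    replicates: int = 3
    condition: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("exponential", "logistic"):
            raise ValueError(f"unknown growth model: {self.model!r}")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.initial_od <= 0:
            raise ValueError("initial OD must be positive")
        if self.model == "logistic" and self.carrying_capacity <= self.initial_od:
            raise ValueError("carrying capacity must exceed the initial OD")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def _decoy_guard_ppm(sd_ppm: float) -> float:
    # keep decoys outside +/- 3 sd of every true peak (floor of 5 ppm so
    # noiseless simulations stay unambiguous too)
    return max(3.0 * sd_ppm, 5.0)


def simulate_spectra(cfg: SpectrumSimConfig) -> tuple[list[Spectrum], list[SpikeTruth]]:
    """One spectrum per spiked compound, plus ground truth.

    Precursor and fragment m/z values are perturbed multiplicatively by
    Normal(0, sd) ppm errors; predicted fragments are dropped independently
    with the configured probability; decoy peaks are drawn uniformly from
    the configured range, rejecting positions within the guard window of any
    true peak.
    """
    rng = np.random.default_rng(cfg.seed)
    guard = _decoy_guard_ppm(cfg.mass_error_sd_ppm)
    spectra: list[Spectrum] = []
    truths: list[SpikeTruth] = []
    for index, compound in enumerate(cfg.compounds):
        true_precursor = compound.mz
        predicted = predict_fragments(compound)
        true_peaks = [true_precursor] + [f.mz for f in predicted]

        eps = rng.normal(0.0, cfg.mass_error_sd_ppm) if cfg.mass_error_sd_ppm else 0.0
        observed_precursor = true_precursor * (1.0 + eps / 1e6)

        fragments: list[float] = []
        for frag in predicted:
            if cfg.fragment_dropout and rng.random() < cfg.fragment_dropout:
                continue
            eps_f = rng.normal(0.0, cfg.mass_error_sd_ppm) if cfg.mass_error_sd_ppm else 0.0
            fragments.append(frag.mz * (1.0 + eps_f / 1e6))

        low, high = cfg.decoy_mz_range
        n_placed = 0
        while n_placed < cfg.decoys_per_spectrum:
            decoy = rng.uniform(low, min(high, observed_precursor + 0.5))
            if any(abs(decoy - mz) / mz * 1e6 <= guard for mz in true_peaks):
                continue
            fragments.append(decoy)
            n_placed += 1

        fragments.sort()
        sample = f"sim{index:03d}:{compound.id}"
        spectra.append(
            Spectrum(
                sample=sample,
                precursor_mz=observed_precursor,
                fragments=fragments,
                fed_precursor=compound.precursor_id,
            )
        )
        truths.append(
            SpikeTruth(
                sample=sample,
                compound_id=compound.id,
                true_mz=true_precursor,
                observed_mz=observed_precursor,
            )
        )
    return spectra, truths


def _model_od(cfg: GrowthSimConfig, t: np.ndarray) -> np.ndarray:
    shifted = np.maximum(t - cfg.lag_h, 0.0)
    if cfg.model == "exponential":
        return cfg.initial_od * np.exp(cfg.rate * shifted)
    ratio = cfg.carrying_capacity / cfg.initial_od - 1.0
    return cfg.carrying_capacity / (1.0 + ratio * np.exp(-cfg.rate * shifted))


def simulate_growth(cfg: GrowthSimConfig) -> tuple[list[GrowthCurve], dict[str, float]]:
    """Replicate growth curves plus the true rate per replicate."""
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.times, dtype=float)
    clean = _model_od(cfg, t)
    floor = 1e-6
    curves: list[GrowthCurve] = []
    truth: dict[str, float] = {}
    for rep in range(cfg.replicates):
        noisy = clean + (rng.normal(0.0, cfg.noise_sd, size=len(t)) if cfg.noise_sd else 0.0)
        noisy = np.maximum(noisy, floor)
        replicate = f"r{rep + 1}"
        curves.append(
            GrowthCurve(
                condition=cfg.condition,
                replicate=replicate,
                times=tuple(t),
                od=tuple(float(v) for v in noisy),
            )
        )
        truth[f"{cfg.condition}/{replicate}"] = cfg.rate
    return curves, truth
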