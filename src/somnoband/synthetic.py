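"""Synthetic labeled two-channel EEG-like epochs for the three-class task.

The source clinical recordings are private, so the pipeline ships with a
generator that emulates the structure the classifier exploits: the three
event classes (obstructive apnea OSA, central apnea CSA, normal breathing
NB) differ in band-specific power and in signal complexity.

Each epoch is a sum over the five EEG bands of band-limited noise
(white noise passed through the same zero-phase Butterworth band filter
used by the analysis chain, then rescaled to the configured band power)
plus class-dependent broadband white noise that controls sample entropy.
Both channels share the oscillatory components with class-specific gain
asymmetry (C3 vs C4) and carry independent broadband noise.

Default profiles follow the physiological direction reported for apnea:
apnea-like classes have high low-frequency (delta/theta) power and low
complexity, normal breathing the reverse; OSA and CSA are separated by
their delta-vs-theta balance and hemispheric asymmetry.  The effect sizes
are deliberately clear-cut — the generator validates the pipeline, it does
not claim physiological realism.

A direct tabular generator (:func:`generate_feature_table`) produces
Gaussian feature matrices with a known informative-column set for testing
feature selection and classification in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureColumn, FeatureMatrix
from .io import EpochSet, LABELS
from .subband import DEFAULT_BANDS, FilterBank

__all__ = ["SyntheticConfig", "generate", "generate_feature_table"]

BAND_NAMES = tuple(b.name for b in DEFAULT_BANDS)

#: relative band power per class, order (delta, theta, alpha, sigma, beta)
DEFAULT_BAND_POWER: dict[str, tuple[float, ...]] = {
    "NB": (0.8, 0.8, 1.0, 0.6, 0.8),
    "OSA": (3.5, 0.8, 0.5, 0.3, 0.3),
    "CSA": (1.8, 2.2, 0.5, 0.3, 0.3),
}

#: broadband-noise mix per class (drives sample entropy up)
DEFAULT_COMPLEXITY: dict[str, float] = {"NB": 1.5, "OSA": 0.35, "CSA": 0.5}

#: (C3 gain, C4 gain) per class
DEFAULT_ASYMMETRY: dict[str, tuple[float, float]] = {
    "NB": (1.0, 1.0),
    "OSA": (1.0, 1.35),
    "CSA": (1.25, 0.85),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults define the study conditions."""

    n_per_class: int = 100
    fs: float = 100.0
    epoch_len_s: float = 30.0
    band_power_profile: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_POWER)
    )
    complexity_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPLEXITY)
    )
    channel_asymmetry: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ASYMMETRY)
    )
    noise_sd: float = 1.0
    channel_names: tuple[str, ...] = ("C3-A2", "C4-A1")
    seed: int = 0

    def __post_init__(self) -> None:
        for cls in LABELS:
            prof = self.band_power_profile.get(cls)
            if prof is None or len(prof) != len(BAND_NAMES):
                raise ValueError(
                    f"band_power_profile for {cls!r} must give "
                    f"{len(BAND_NAMES)} band powers"
                )
            if any(p < 0 for p in prof):
                raise ValueError(f"band powers must be >= 0 ({cls!r})")
            if cls not in self.complexity_profile:
                raise ValueError(f"complexity_profile missing class {cls!r}")
            if cls not in self.channel_asymmetry:
                raise ValueError(f"channel_asymmetry missing class {cls!r}")


def _band_limited_noise(
    rng: np.random.Generator, bank: FilterBank, band_name: str, n: int
) -> np.ndarray:
    """Unit-variance band-limited noise from filtered white noise."""
    z = rng.standard_normal(n)
    x = bank.apply(z)[band_name]
    sd = x.std()
    return x / sd if sd > 0 else x


def generate(config: SyntheticConfig = SyntheticConfig()) -> EpochSet:
    """Generate a labeled EpochSet, ``n_per_class`` epochs per class.

    Fully reproducible from ``config.seed``; epochs are ordered
    OSA-block, CSA-block, NB-block.
    """
    rng = np.random.default_rng(config.seed)
    bank = FilterBank(config.fs, DEFAULT_BANDS)
    n_samp = int(round(config.epoch_len_s * config.fs))
    n_ch = len(config.channel_names)
    epochs = np.empty((config.n_per_class * len(LABELS), n_ch, n_samp))
    labels = np.empty(epochs.shape[0], dtype=object)
    row = 0
    for cls in LABELS:
        powers = config.band_power_profile[cls]
        noise_mix = config.complexity_profile[cls] * config.noise_sd
        gains = config.channel_asymmetry[cls]
        for _ in range(config.n_per_class):
            osc = np.zeros(n_samp)
            for band_name, power in zip(BAND_NAMES, powers):
                if power > 0:
                    osc += np.sqrt(power) * _band_limited_noise(
                        rng, bank, band_name, n_samp
                    )
            for c in range(n_ch):
                epochs[row, c] = gains[c] * osc + noise_mix * rng.standard_normal(
                    n_samp
                )
            labels[row] = cls
            row += 1
    return EpochSet(
        epochs=epochs,
        labels=labels,
        fs=config.fs,
        channel_names=config.channel_names,
        epoch_len_s=config.epoch_len_s,
    )


# deterministic class-shift patterns cycled over informative columns
_SHIFT_PATTERNS = (
    (0.0, 1.0, -1.0),
    (1.0, -1.0, 0.0),
    (-1.0, 0.0, 1.0),
)


def generate_feature_table(
    n: int = 300,
    informative_columns: tuple[int, ...] = (0, 1, 2, 3, 4),
    effect_size: float = 3.0,
    seed: int = 0,
    n_features: int = 20,
    class_sizes: tuple[int, int, int] | None = None,
) -> FeatureMatrix:
    """Gaussian feature matrix with a known informative-column set.

    Informative columns receive class-dependent mean shifts of
    ``effect_size`` standard deviations (patterns cycle so informative
    columns are not redundant); the remaining columns are pure noise.
    ``class_sizes`` (OSA, CSA, NB) overrides the near-equal split — e.g.
    (1229, 812, 1418) reproduces the reported clinical class imbalance.
    """
    if any(c < 0 or c >= n_features for c in informative_columns):
        raise ValueError("informative_columns out of range")
    rng = np.random.default_rng(seed)
    if class_sizes is None:
        base = n // len(LABELS)
        sizes = [base] * len(LABELS)
        for i in range(n - base * len(LABELS)):
            sizes[i] += 1
    else:
        sizes = list(class_sizes)
        n = sum(sizes)
    labels = np.concatenate(
        [np.full(s, cls, dtype=object) for s, cls in zip(sizes, LABELS)]
    )
    values = rng.standard_normal((n, n_features))
    for k, col in enumerate(informative_columns):
        pattern = _SHIFT_PATTERNS[k % len(_SHIFT_PATTERNS)]
        start = 0
        for s, shift in zip(sizes, pattern):
            values[start : start + s, col] += effect_size * shift
            start += s
    perm = rng.permutation(n)
    columns = [
        FeatureColumn(i + 1, "synthetic", "NA", f"col{i + 1}")
        for i in range(n_features)
    ]
    return FeatureMatrix(values=values[perm], columns=columns, labels=labels[perm])
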