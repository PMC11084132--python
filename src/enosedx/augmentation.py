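"""Breathprint data augmentation: NSA and SDA operators.

Two operators, both acting on the per-channel 256-point time series that
the 16x16 image grid encodes (row-major):

* **NSA** (noise-shift augmentation) — add i.i.d. Gaussian noise scaled to
  each channel's standard deviation, then shift the series backward in
  time, padding the freed tail by edge replication.

* **SDA** (semi-supervised domain-generalized augmentation) — mix the
  low-frequency Fourier *amplitude* spectrum of a sample with that of a
  partner sample while keeping the sample's own phase everywhere, then
  invert. Low frequencies carry baseline/gain/drift style; phase carries
  response kinetics. Randomizing amplitude style during training pushes the
  classifier toward site-invariant, kinetics-based features. The exact
  published formulation of this operator is not public, so this is a
  documented reconstruction following the Fourier domain-generalization
  family.

Both operators preserve tensor shape and label and are only ever applied
to the training (or fine-tuning) partition; :func:`augment_dataset` refuses
validation/test samples outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, LeakageError
from .preprocess import IMAGE_LEN, IMAGE_SIDE, BreathprintImage
from .synthetic import N_CHANNELS


@dataclass(frozen=True)
class AugmentationConfig:
    """Knobs for both augmentation operators.

    ``nsa_noise_sd`` is a fraction of each channel's own standard deviation;
    ``nsa_shift`` counts positions along the flattened 256-point axis;
    ``sda_mix_lambda`` is a fixed mixing weight in [0,1] or "uniform" to
    redraw it per call; ``sda_low_freq_fraction`` bounds the mixed band as a
    fraction of the non-negative frequency axis.
    """

    method: str = "NSA"  # "NSA" | "SDA"
    ratio: float = 1.0
    nsa_noise_sd: float = 0.30
    nsa_shift: int = 16
    nsa_circular: bool = False
    sda_mix_lambda: float | str = "uniform"
    sda_low_freq_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("NSA", "SDA"):
            raise InvalidArgumentError("method must be 'NSA' or 'SDA'")
        if self.ratio <= 0:
            raise InvalidArgumentError("ratio must be > 0")
        if self.nsa_noise_sd < 0:
            raise InvalidArgumentError("nsa_noise_sd must be >= 0")
        if not (0 <= self.nsa_shift < IMAGE_LEN):
            raise InvalidArgumentError(f"nsa_shift must be in [0, {IMAGE_LEN})")
        lam = self.sda_mix_lambda
        if lam != "uniform" and not (isinstance(lam, (int, float)) and 0 <= lam <= 1):
            raise InvalidArgumentError("sda_mix_lambda must be in [0,1] or 'uniform'")
        if not (0 < self.sda_low_freq_fraction <= 1):
            raise InvalidArgumentError("sda_low_freq_fraction must be in (0, 1]")


def nsa_augment(image: BreathprintImage, config: AugmentationConfig, seed=None) -> BreathprintImage:
    """Gaussian noise + backward time shift on each channel's series.

    Noise sd is ``nsa_noise_sd`` times the channel's standard deviation.
    The backward shift moves the series toward earlier time: an impulse at
    flattened position k lands at k - shift. The vacated tail is filled by
    replicating the last value (or wrapped, with ``nsa_circular``).
    """
    if not (0 <= config.nsa_shift < IMAGE_LEN):
        raise InvalidArgumentError(f"nsa_shift must be < {IMAGE_LEN}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    series = image.flat().copy()  # (14, 256)
    sd = series.std(axis=1, keepdims=True)
    series = series + config.nsa_noise_sd * sd * rng.standard_normal(series.shape)
    s = config.nsa_shift
    if s > 0:
        if config.nsa_circular:
            series = np.roll(series, -s, axis=1)
        else:
            shifted = np.empty_like(series)
            shifted[:, : IMAGE_LEN - s] = series[:, s:]
            shifted[:, IMAGE_LEN - s:] = series[:, -1:]
            series = shifted
    tensor = series.reshape(N_CHANNELS, IMAGE_SIDE, IMAGE_SIDE)
    return image.with_tensor(tensor)


def sda_augment(
    image_a: BreathprintImage,
    image_b: BreathprintImage,
    config: AugmentationConfig,
    seed=None,
) -> BreathprintImage:
    """Low-frequency Fourier amplitude mixing; phase of ``image_a`` kept.

    Per channel, on the flattened 256-point series: within the lowest
    ``sda_low_freq_fraction`` of non-negative frequencies the output
    amplitude is (1-lam)|A_a| + lam|A_b|; outside the band |A_a| is kept.
    The label (and all metadata) of ``image_a`` is retained.
    """
    if image_a.tensor.shape != image_b.tensor.shape:
        raise InvalidArgumentError("images must share shape")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lam = config.sda_mix_lambda
    if lam == "uniform":
        lam = rng.uniform(0.0, 1.0)

    a = image_a.flat()
    b = image_b.flat()
    fa = np.fft.rfft(a, axis=1)
    fb = np.fft.rfft(b, axis=1)
    n_freq = fa.shape[1]  # 129 for length 256
    k_max = max(1, int(math.ceil(config.sda_low_freq_fraction * n_freq)))

    amp = np.abs(fa)
    amp[:, :k_max] = (1.0 - lam) * np.abs(fa[:, :k_max]) + lam * np.abs(fb[:, :k_max])
    mixed = amp * np.exp(1j * np.angle(fa))
    series = np.fft.irfft(mixed, n=IMAGE_LEN, axis=1)
    tensor = series.reshape(N_CHANNELS, IMAGE_SIDE, IMAGE_SIDE)
    return image_a.with_tensor(tensor)


def augment_dataset(images: list[BreathprintImage], config: AugmentationConfig) -> list[BreathprintImage]:
    """Return originals plus ceil(ratio * N) augmented copies.

    Sources for the augmented copies cycle through a seeded shuffle of the
    input, so at ratio=1 every sample is augmented exactly once and every
    class count doubles exactly. SDA partners are drawn (seeded) from the
    same list. Attempting to augment validation or test samples raises
    :class:`LeakageError`.
    """
    if not images:
        raise InvalidArgumentError("cannot augment an empty dataset")
    for img in images:
        if img.partition in ("validation", "test"):
            raise LeakageError(
                f"sample {img.sample_id!r} belongs to the {img.partition} partition; "
                "augmentation is restricted to training data"
            )
    rng = np.random.default_rng(config.seed)
    n = len(images)
    n_new = int(math.ceil(config.ratio * n))
    order = rng.permutation(n)
    out = list(images)
    for i in range(n_new):
        src = images[order[i % n]]
        call_seed = int(rng.integers(0, 2**31 - 1))
        if config.method == "NSA":
            aug = nsa_augment(src, config, seed=call_seed)
        else:
            partner = images[int(rng.integers(0, n))]
            aug = sda_augment(src, partner, config, seed=call_seed)
        aug.sample_id = f"{src.sample_id}#aug{i}"
        out.append(aug)
    return out
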