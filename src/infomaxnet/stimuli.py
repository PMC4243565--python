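"""Stimulus generation: episodic external sequences and natural-image input.

Three input paths are provided:

* :class:`EpisodicSequenceStream` — a small set of external neurons firing in
  a fixed within-episode timing (neuron 1 at the first step of an episode,
  neuron 3 at the third, neuron 2 at the fifth), each stochastically with
  probability 1/2, with inter-onset gaps uniform on [50, 100] steps.  With
  three neurons the network sees 2^3 - 1 = 7 distinct non-silent episode
  variants.
* ON/OFF image encoding — 12x12 whitened image patches drawn i.i.d. per step
  and relayed by one ON and one OFF cell per pixel, firing with probability
  proportional to the positive / negative pixel intensity (gain xi).
* :func:`synthetic_image_fixture` — a download-free stand-in image ensemble
  with natural-image-like 1/f amplitude spectra, suitable input to
  :func:`whiten_images`.

All streams yield one binary vector per time step through ``next_block`` and
are seedable and chunk-invariant: the block boundaries never change the
generated sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EpisodicSequenceConfig",
    "EpisodicSequenceStream",
    "episodic_sequence_source",
    "OnOffEncoderConfig",
    "OnOffImageStream",
    "ImageSet",
    "whiten_images",
    "sample_patches",
    "onoff_encode",
    "synthetic_image_fixture",
    "calibrate_xi",
    "ZeroStream",
]


@dataclass(frozen=True)
class EpisodicSequenceConfig:
    """Timing of the episodic external-input protocol.

    ``slot_schedule`` lists (within-episode offset, external-neuron index)
    pairs; the default encodes neuron 0 firing at offset 0, neuron 2 at
    offset 2 and neuron 1 at offset 4 (the field's 1-based "first/third/
    fifth step" counting mapped to 0-based offsets).
    """

    n_ext: int = 3
    slot_schedule: tuple = ((0, 0), (2, 2), (4, 1))
    fire_prob: float = 0.5
    gap_min: int = 50
    gap_max: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.fire_prob <= 1.0):
            raise ValueError(f"fire_prob must be in (0, 1], got {self.fire_prob}")
        if self.gap_min > self.gap_max:
            raise ValueError("gap_min must be <= gap_max")
        neurons = [n for _, n in self.slot_schedule]
        offsets = [o for o, _ in self.slot_schedule]
        if len(set(neurons)) != len(neurons):
            raise ValueError("each scheduled neuron must own exactly one slot")
        if any(o < 0 for o in offsets):
            raise ValueError("offsets must be nonnegative")
        if any(n < 0 or n >= self.n_ext for n in neurons):
            raise ValueError("scheduled neuron index out of range")


class EpisodicSequenceStream:
    """Seedable stream of episodic external firing vectors.

    Episode onsets are separated by integer gaps uniform on
    [gap_min, gap_max]; within an episode each scheduled neuron fires at its
    slot independently with ``fire_prob``.  Outside episode slots the output
    is all-zero.  Every completed episode's firing combination is appended to
    :attr:`episode_log` as (onset step, fired tuple).
    """

    def __init__(self, config: EpisodicSequenceConfig, rng: np.random.Generator, log_episodes: bool = True):
        self.config = config
        self.rng = rng
        self.t = 0
        self.next_onset = int(rng.integers(config.gap_min, config.gap_max + 1))
        self._pending: list[tuple[int, int]] = []  # (absolute step, neuron)
        self.log_episodes = log_episodes
        self.episode_log: list[tuple[int, tuple]] = []

    @property
    def n_channels(self) -> int:
        return self.config.n_ext

    def next_block(self, n: int) -> np.ndarray:
        cfg = self.config
        out = np.zeros((n, cfg.n_ext), dtype=np.uint8)
        end = self.t + n
        still_pending: list[tuple[int, int]] = []
        for abs_t, neuron in self._pending:
            if abs_t < end:
                out[abs_t - self.t, neuron] = 1
            else:
                still_pending.append((abs_t, neuron))
        self._pending = still_pending
        while self.next_onset < end:
            onset = self.next_onset
            fired = tuple(
                int(self.rng.random() < cfg.fire_prob) for _ in cfg.slot_schedule
            )
            if self.log_episodes:
                self.episode_log.append((onset, fired))
            for (offset, neuron), f in zip(cfg.slot_schedule, fired):
                if f:
                    abs_t = onset + offset
                    if abs_t < end:
                        out[abs_t - self.t, neuron] = 1
                    else:
                        self._pending.append((abs_t, neuron))
            gap = int(self.rng.integers(cfg.gap_min, cfg.gap_max + 1))
            self.next_onset = onset + gap
        self.t = end
        return out

    def get_state(self) -> dict:
        return {
            "t": self.t,
            "next_onset": self.next_onset,
            "pending": list(self._pending),
            "rng_state": self.rng.bit_generator.state,
        }

    def set_state(self, state: dict) -> None:
        self.t = state["t"]
        self.next_onset = state["next_onset"]
        self._pending = [tuple(p) for p in state["pending"]]
        self.rng.bit_generator.state = state["rng_state"]


def episodic_sequence_source(
    config: EpisodicSequenceConfig, rng: np.random.Generator
) -> EpisodicSequenceStream:
    """Build the episodic external-input stream (spec-level constructor)."""
    return EpisodicSequenceStream(config, rng)


class ZeroStream:
    """All-silent external input (placeholder for wired but inactive inputs)."""

    def __init__(self, n_channels: int):
        self.n_channels = n_channels

    def next_block(self, n: int) -> np.ndarray:
        return np.zeros((n, self.n_channels), dtype=np.uint8)

    def get_state(self) -> dict:
        return {}

    def set_state(self, state: dict) -> None:
        pass


# -- images ------------------------------------------------------------------


@dataclass
class ImageSet:
    """A list of square grayscale images with a provenance tag."""

    images: list
    provenance: str = "external-file"

    def __post_init__(self) -> None:
        self.images = [np.asarray(im, dtype=np.float64) for im in self.images]
        for im in self.images:
            if im.ndim != 2 or im.shape[0] != im.shape[1]:
                raise ValueError("images must be square 2-D grayscale arrays")


@dataclass(frozen=True)
class OnOffEncoderConfig:
    """Gain and geometry of the ON/OFF relay-cell encoding."""

    xi: float = 1.65
    patch_side: int = 12

    def __post_init__(self) -> None:
        if self.xi <= 0:
            raise ValueError(f"xi must be > 0, got {self.xi}")


def whiten_images(images: ImageSet, f_c: float = 200.0) -> ImageSet:
    """Zero-center, whiten and low-pass filter every image in the frequency
    domain with the radial response L(f) = f * exp(-(f/f_c)^4), f in cycles
    per picture.  L(0) = 0, so the output is exactly zero-mean; the ramp
    flattens the ~1/f natural-image spectrum and the quartic roll-off removes
    frequencies beyond the cut-off.  The operation is linear."""
    if f_c <= 0:
        raise ValueError(f"f_c must be > 0, got {f_c}")
    out = []
    for im in images.images:
        n = im.shape[0]
        f1 = np.fft.fftfreq(n) * n  # cycles per picture on the unshifted grid
        radial = np.hypot(f1[:, None], f1[None, :])
        L = radial * np.exp(-((radial / f_c) ** 4))
        out.append(np.real(np.fft.ifft2(np.fft.fft2(im) * L)))
    return ImageSet(images=out, provenance=images.provenance)


def sample_patches(
    images: ImageSet, side: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` square patches i.i.d.: image index and top-left corner
    uniform over the valid range.  Returns an (n, side, side) array in draw
    order."""
    sides = {im.shape[0] for im in images.images}
    if any(side > s for s in sides):
        raise ValueError(f"patch side {side} exceeds an image side")
    out = np.empty((n, side, side))
    n_img = len(images.images)
    for k in range(n):
        i = int(rng.integers(n_img))
        im = images.images[i]
        limit = im.shape[0] - side + 1
        r = int(rng.integers(limit))
        c = int(rng.integers(limit))
        out[k] = im[r : r + side, c : c + side]
    return out


def onoff_encode(
    patch: np.ndarray, config: OnOffEncoderConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one ON and one OFF binary vector for a (flattened) patch.

    p(ON) = min(xi * y, 1) for positive pixels, p(OFF) = min(-xi * y, 1) for
    negative pixels; a pixel never drives both polarities, and pixels are
    sampled independently (one uniform per pixel suffices because the two
    events are exclusive)."""
    y = np.asarray(patch, dtype=np.float64).ravel()
    p_on = np.clip(config.xi * y, 0.0, 1.0)
    p_off = np.clip(-config.xi * y, 0.0, 1.0)
    u = rng.random(y.size)
    on = ((y > 0) & (u < p_on)).astype(np.uint8)
    off = ((y < 0) & (u < p_off)).astype(np.uint8)
    return on, off


class OnOffImageStream:
    """Per-step i.i.d. patch sampling relayed through ON/OFF cells.

    Channel layout: ON cells for pixels 0..npix-1 first, then OFF cells.
    With ``log_patches`` the flattened patch presented at every step is
    retained (needed for spike-triggered averaging)."""

    def __init__(
        self,
        images: ImageSet,
        config: OnOffEncoderConfig,
        rng: np.random.Generator,
        log_patches: bool = False,
    ):
        self.images = images
        self.config = config
        self.rng = rng
        self.side = config.patch_side
        sides = {im.shape[0] for im in images.images}
        if any(self.side > s for s in sides):
            raise ValueError("patch side exceeds an image side")
        self.npix = self.side ** 2
        self.log_patches = log_patches
        self.patch_log: list[np.ndarray] = []
        self.t = 0

    @property
    def n_channels(self) -> int:
        return 2 * self.npix

    def next_block(self, n: int) -> np.ndarray:
        out = np.empty((n, self.n_channels), dtype=np.uint8)
        patches = sample_patches(self.images, self.side, n, self.rng)
        for k in range(n):
            on, off = onoff_encode(patches[k], self.config, self.rng)
            out[k, : self.npix] = on
            out[k, self.npix :] = off
            if self.log_patches:
                self.patch_log.append(patches[k].ravel().copy())
        self.t += n
        return out

    def get_state(self) -> dict:
        return {"t": self.t, "rng_state": self.rng.bit_generator.state}

    def set_state(self, state: dict) -> None:
        self.t = state["t"]
        self.rng.bit_generator.state = state["rng_state"]


def synthetic_image_fixture(
    n_images: int = 10,
    side: int = 128,
    spectral_exponent: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> ImageSet:
    """Gaussian random images with a radial amplitude spectrum |f|^-exponent.

    Natural scenes have approximately 1/f amplitude spectra; this fixture
    reproduces that second-order statistic (and nothing else: no edges,
    occlusions or phase structure), which is what the whitening and encoding
    pipeline consumes.  Images are standardized to zero mean, unit variance.
    """
    if side < 16:
        raise ValueError(f"side must be >= 16, got {side}")
    if rng is None:
        rng = np.random.default_rng()
    f1 = np.fft.fftfreq(side) * side
    radial = np.hypot(f1[:, None], f1[None, :])
    with np.errstate(divide="ignore"):
        amp = np.where(radial > 0, radial ** (-spectral_exponent), 0.0)
    images = []
    for _ in range(n_images):
        white = rng.standard_normal((side, side))
        shaped = np.real(np.fft.ifft2(np.fft.fft2(white) * amp))
        shaped -= shaped.mean()
        sd = shaped.std()
        if sd > 0:
            shaped /= sd
        images.append(shaped)
    return ImageSet(images=images, provenance="synthetic-fixture")


def calibrate_xi(
    images: ImageSet,
    target_rate: float = 0.15,
    side: int = 12,
    n_probe: int = 20000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Bisect the ON/OFF gain xi so that the population-average firing rate of
    the relay cells (ON and OFF pooled) hits ``target_rate`` on this image
    ensemble.  The expected rate at gain xi is E[min(xi |y|, 1)] / 2 over
    patch pixels, a monotone function of xi."""
    if rng is None:
        rng = np.random.default_rng(0)
    patches = sample_patches(images, side, n_probe // (side * side) + 1, rng)
    absy = np.abs(patches.ravel())

    def rate(xi: float) -> float:
        return float(np.minimum(xi * absy, 1.0).mean() / 2.0)

    lo, hi = 1e-6, 1e6
    if rate(hi) < target_rate:
        raise ValueError("target rate unreachable (max is 0.5)")
    for _ in range(200):
        mid = math.sqrt(lo * hi) if hi / lo > 10 else 0.5 * (lo + hi)
        if rate(mid) < target_rate:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9 * max(1.0, hi):
            break
    return 0.5 * (lo + hi)
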