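"""Chemical-shift encoding physics for water-fat-silicone (WFS) separation.

The multi-echo signal model: at gradient-echo time ``t_j`` (signed, relative
to the spin echo) the complex image is

    x(t_j) = exp(mu * t_j) * (rho_w + Phi_f(t_j) * rho_f + Phi_s(t_j) * rho_s)

with ``mu = 2*pi*i*fB - R2'`` combining the off-resonance field map fB [Hz]
and the reversible transverse relaxation rate R2' [1/s], and species phasors

    Phi_f(t) = sum_p alpha_p * exp(2*pi*i*f_fp*t),   Phi_s(t) = exp(2*pi*i*fs*t).

Fat is modelled with nine peaks (amplitudes summing to one), silicone with a
single peak at -4.9 ppm. Per pixel this is a linear system x = A(mu) rho with
an Nt x 3 encoding matrix; separation is per-pixel least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import constants

log = logging.getLogger(__name__)

__all__ = [
    "SpectralModel",
    "EchoTimes",
    "FieldParams",
    "SpeciesImages",
    "fat_phasor",
    "silicone_phasor",
    "species_phasors",
    "encoding_matrix",
    "forward_species",
    "lsq_separate",
]


@dataclass(frozen=True)
class SpectralModel:
    """Fat/silicone spectral model at a given field strength.

    Parameters
    ----------
    larmor_hz
        Proton Larmor frequency [Hz] (sets the ppm -> Hz conversion).
    fat_ppm, fat_amp
        Water-relative fat peak shifts [ppm] and relative amplitudes.
        Amplitudes are renormalized to sum to 1 on construction.
    silicone_ppm
        Water-relative silicone shift [ppm].
    """

    larmor_hz: float = constants.DEFAULT_LARMOR_HZ
    fat_ppm: np.ndarray = field(
        default_factory=lambda: np.asarray(constants.NINE_PEAK_FAT_PPM, float)
    )
    fat_amp: np.ndarray = field(
        default_factory=lambda: np.asarray(constants.NINE_PEAK_FAT_AMP, float)
    )
    silicone_ppm: float = constants.SILICONE_PPM

    def __post_init__(self) -> None:
        fat_ppm = np.atleast_1d(np.asarray(self.fat_ppm, float))
        fat_amp = np.atleast_1d(np.asarray(self.fat_amp, float))
        if fat_ppm.shape != fat_amp.shape:
            raise ValueError("fat_ppm and fat_amp must have equal length")
        if not (np.all(np.isfinite(fat_ppm)) and np.all(np.isfinite(fat_amp))):
            raise ValueError("fat model values must be finite")
        if not np.isfinite(self.larmor_hz) or self.larmor_hz <= 0:
            raise ValueError("larmor_hz must be positive and finite")
        if not np.isfinite(self.silicone_ppm):
            raise ValueError("silicone_ppm must be finite")
        total = fat_amp.sum()
        if total <= 0:
            raise ValueError("fat amplitudes must have positive sum")
        object.__setattr__(self, "fat_ppm", fat_ppm)
        object.__setattr__(self, "fat_amp", fat_amp / total)

    @property
    def n_fat_peaks(self) -> int:
        return int(self.fat_ppm.size)

    @property
    def fat_hz(self) -> np.ndarray:
        """Fat peak offsets [Hz] relative to water."""
        return self.fat_ppm * 1e-6 * self.larmor_hz

    @property
    def silicone_hz(self) -> float:
        """Silicone offset [Hz] relative to water."""
        return float(self.silicone_ppm * 1e-6 * self.larmor_hz)

    @property
    def mean_fat_hz(self) -> float:
        """Amplitude-weighted bulk fat frequency [Hz] (used for the bulk
        chemical-shift displacement)."""
        return float(np.dot(self.fat_amp, self.fat_hz))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "larmor_hz": float(self.larmor_hz),
            "fat_ppm": [float(v) for v in self.fat_ppm],
            "fat_amp": [float(v) for v in self.fat_amp],
            "silicone_ppm": float(self.silicone_ppm),
            "constants_version": constants.CONSTANTS_VERSION,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralModel":
        return cls(
            larmor_hz=float(d["larmor_hz"]),
            fat_ppm=np.asarray(d["fat_ppm"], float),
            fat_amp=np.asarray(d["fat_amp"], float),
            silicone_ppm=float(d["silicone_ppm"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "SpectralModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class EchoTimes:
    """Gradient-echo times [s], signed relative to the spin echo."""

    t: np.ndarray
    delta_te: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("echo times must be a 1-D array")
        if not np.all(np.isfinite(t)):
            raise ValueError("echo times must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("echo times must be strictly increasing")
        object.__setattr__(self, "t", t)

    @property
    def n_echoes(self) -> int:
        return int(self.t.size)

    @classmethod
    def symmetric(cls, n: int = 7, delta_te: float = 1.0e-3) -> "EchoTimes":
        """Echo train symmetric about the spin echo, e.g. {-3..3} * delta_te."""
        idx = np.arange(n) - (n - 1) / 2.0
        return cls(t=idx * delta_te, delta_te=float(delta_te))


@dataclass
class FieldParams:
    """Off-resonance field map fB [Hz] and R2' [1/s]; mu = 2*pi*i*fB - R2'."""

    fB: np.ndarray
    r2p: np.ndarray

    def __post_init__(self) -> None:
        self.fB = np.asarray(self.fB, float)
        self.r2p = np.asarray(self.r2p, float)
        if self.fB.shape != self.r2p.shape:
            raise ValueError("fB and r2p must have the same shape")
        if np.any(self.r2p < 0):
            raise ValueError("r2p must be non-negative")

    @property
    def mu(self) -> np.ndarray:
        return 2j * np.pi * self.fB - self.r2p

    @classmethod
    def zeros(cls, shape) -> "FieldParams":
        return cls(fB=np.zeros(shape), r2p=np.zeros(shape))


@dataclass
class SpeciesImages:
    """Complex water/fat/silicone images of identical shape."""

    w: np.ndarray
    f: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, complex)
        self.f = np.asarray(self.f, complex)
        self.s = np.asarray(self.s, complex)
        if not (self.w.shape == self.f.shape == self.s.shape):
            raise ValueError("species images must share one shape")

    @property
    def shape(self):
        return self.w.shape

    def stack(self) -> np.ndarray:
        """(3, ...) array in water, fat, silicone order."""
        return np.stack([self.w, self.f, self.s])

    @classmethod
    def from_stack(cls, arr: np.ndarray) -> "SpeciesImages":
        return cls(w=arr[0], f=arr[1], s=arr[2])

    @classmethod
    def zeros(cls, shape) -> "SpeciesImages":
        z = np.zeros(shape, complex)
        return cls(w=z.copy(), f=z.copy(), s=z.copy())


# ---------------------------------------------------------------------------
# phasors and encoding
# ---------------------------------------------------------------------------

def fat_phasor(t, model: SpectralModel):
    """Multi-peak fat phasor Phi_f(t) = sum_p alpha_p exp(2 pi i f_p t).

    ``t`` may be a scalar or array of echo times [s]; broadcasts elementwise.
    """
    t = np.asarray(t, float)
    if not np.all(np.isfinite(t)):
        raise ValueError("echo time must be finite")
    ph = np.exp(2j * np.pi * np.multiply.outer(t, model.fat_hz))
    out = ph @ model.fat_amp
    return complex(out) if out.ndim == 0 else out


def silicone_phasor(t, model: SpectralModel):
    """Single-peak silicone phasor Phi_s(t) = exp(2 pi i fs t)."""
    t = np.asarray(t, float)
    if not np.all(np.isfinite(t)):
        raise ValueError("echo time must be finite")
    out = np.exp(2j * np.pi * model.silicone_hz * t)
    return complex(out) if out.ndim == 0 else out


def species_phasors(times: EchoTimes, model: SpectralModel) -> np.ndarray:
    """(Nt, 3) matrix with columns [1, Phi_f(t_j), Phi_s(t_j)]."""
    t = times.t
    return np.column_stack(
        [np.ones(t.size, complex), fat_phasor(t, model), silicone_phasor(t, model)]
    )


def encoding_matrix(mu_px: complex, times: EchoTimes, model: SpectralModel) -> np.ndarray:
    """Per-pixel Nt x 3 chemical-shift encoding matrix A(mu).

    Row j is ``exp(mu*t_j) * [1, Phi_f(t_j), Phi_s(t_j)]``.
    """
    if not np.isfinite(mu_px):
        raise ValueError("mu must be finite")
    B = species_phasors(times, model)
    return np.exp(mu_px * times.t)[:, None] * B


def _decay(field: FieldParams, times: EchoTimes) -> np.ndarray:
    """exp(mu * t_j) for every pixel: shape (Nt, *image_shape)."""
    t = times.t.reshape((-1,) + (1,) * field.fB.ndim)
    return np.exp(field.mu[None] * t)


def forward_species(
    rho: SpeciesImages, field: FieldParams, times: EchoTimes, model: SpectralModel
) -> np.ndarray:
    """Map species images to the Nt echo images, x(t_j) = A(mu) rho per pixel.

    Returns an array of shape (Nt, *image_shape). Linear in ``rho``.
    """
    if rho.shape != field.fB.shape:
        raise ValueError("species and field maps must share one shape")
    B = species_phasors(times, model)  # (Nt, 3)
    mix = np.tensordot(B, rho.stack(), axes=(1, 0))  # (Nt, ...)
    return _decay(field, times) * mix


def lsq_separate(
    echoes: np.ndarray, field: FieldParams, times: EchoTimes, model: SpectralModel
) -> SpeciesImages:
    """Per-pixel least-squares species separation given a field estimate.

    Solves ``min_rho |x - A(mu) rho|^2`` pixelwise via the (batched)
    pseudo-inverse of the 3x3 normal matrix. Exact inverse of
    :func:`forward_species` for noiseless data with the correct mu.
    Rank-deficient pixels return zero and trigger a logged warning.
    """
    echoes = np.asarray(echoes, complex)
    if echoes.shape[0] < 3:
        raise ValueError("need at least 3 echoes for 3-species separation")
    if echoes.shape[1:] != field.fB.shape:
        raise ValueError("echoes and field maps must share the image shape")
    B = species_phasors(times, model)  # (Nt, 3)
    e = _decay(field, times)  # (Nt, ...)
    # A(px) = diag(e(px)) @ B  =>  A^H A = sum_j |e_j|^2 B_j^H B_j
    Bout = np.einsum("jk,jl->jkl", B.conj(), B)  # (Nt, 3, 3)
    w2 = np.abs(e) ** 2
    G = np.einsum("j...,jkl->...kl", w2, Bout)  # (..., 3, 3) Hermitian
    rhs = np.einsum("jk,j...->...k", B.conj(), e.conj() * echoes)  # (..., 3)

    evals = np.linalg.eigvalsh(G)
    bad = evals[..., 0] <= 1e-12 * np.maximum(evals[..., -1], 1e-300)
    Ginv = np.linalg.pinv(G, hermitian=True)
    sol = np.einsum("...kl,...l->...k", Ginv, rhs)
    if np.any(bad):
        log.warning(
            "lsq_separate: %d rank-deficient pixels set to zero", int(bad.sum())
        )
        sol[bad] = 0
    sol = np.moveaxis(sol, -1, 0)
    return SpeciesImages.from_stack(sol)
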