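"""Digital phantom and bipolar multi-echo k-space simulation.

The phantom emulates an axial breast-like slice with a silicone implant: an
elliptical tissue support containing piecewise-smooth water/fat mixtures, a
disc of pure silicone (the implant), a smooth off-resonance field map fB, a
smooth R2' map, multi-channel coil sensitivities, and a spatially smooth
readout-polarity phase difference (the Nyquist ghost phase).

k-space simulation reuses :class:`wfsrecon.operators.JointOperator` — the
exact operator the reconstructions invert — so simulation and reconstruction
are adjoint-consistent by construction and a noiseless fully sampled
acquisition is exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from .operators import JointOperator
from .sampling import SamplingPattern
from .spectral import EchoTimes, FieldParams, SpectralModel, SpeciesImages

__all__ = ["PhantomConfig", "Phantom", "KSpaceData", "make_phantom",
           "simulate_kspace", "ghost_sensitivities"]


@dataclass
class PhantomConfig:
    """Study conditions for the synthetic phantom.

    noise_sigma is the complex-Gaussian k-space standard deviation relative
    to the peak image-domain coil signal magnitude (the unitary DFT makes
    image- and k-space noise levels equal), so e.g. 10**(-30/20) ~ 0.0316
    corresponds to ~30 dB peak SNR.
    """

    shape: tuple = (128, 128)
    n_coils: int = 8
    implant_radius_frac: float = 0.28
    fB_amplitude: float = 120.0  # Hz
    fB_smoothness: float = 24.0  # pixels
    r2p_range: tuple = (5.0, 40.0)  # 1/s
    ghost_phase_coeffs: tuple = (0.2, 0.6, 0.15)  # rad: const, linear, quadratic
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 32:
            raise ValueError("phantom shape must be at least 32x32")
        for v in (self.implant_radius_frac, self.fB_amplitude, self.fB_smoothness,
                  self.noise_sigma):
            if not np.isfinite(v):
                raise ValueError("phantom config scalars must be finite")


@dataclass
class Phantom:
    truth: SpeciesImages
    field: FieldParams
    coils: np.ndarray  # (nc, Ny, Nx) complex
    ghost_phase: np.ndarray  # (Ny, Nx) radians
    roi_implant: np.ndarray  # bool
    roi_tissue: np.ndarray  # bool
    support: np.ndarray  # bool
    config: PhantomConfig | None = None


@dataclass
class KSpaceData:
    """Sampled multichannel bipolar k-space, (2, Nt, nc, Ny, Nx)."""

    y: np.ndarray
    pattern: SamplingPattern
    times: EchoTimes | None = None
    noise_sigma: float = 0.0
    meta: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, complex)
        if self.y.ndim != 5 or self.y.shape[0] != 2:
            raise ValueError("k-space must be (2, Nt, nc, Ny, Nx)")


def _smooth_field(rng, shape, sigma) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    m = np.abs(f).max()
    return f / m if m > 0 else f


def _grids(shape):
    ny, nx = shape
    y = (np.arange(ny) - ny / 2) / (ny / 2)
    x = (np.arange(nx) - nx / 2) / (nx / 2)
    return np.meshgrid(y, x, indexing="ij")


def make_phantom(cfg: PhantomConfig) -> Phantom:
    """Deterministic (seeded) synthetic ground truth."""
    rng = np.random.default_rng(cfg.seed)
    ny, nx = cfg.shape
    Y, X = _grids(cfg.shape)

    support = (Y / 0.88) ** 2 + (X / 0.88) ** 2 <= 1.0

    # implant: disc of pure silicone, offset toward one side
    r_imp = cfg.implant_radius_frac
    cy, cx = 0.05, -0.30
    implant = (Y - cy) ** 2 + (X - cx) ** 2 <= r_imp**2
    implant &= support

    # tissue composition: predominantly adipose breast with a compact
    # fibroglandular water region, sparse bright fluid, and a thin skin rim —
    # the regime in which the water image is compressible in the image domain
    tissue = support & ~implant
    fatfrac = np.clip(0.85 + 0.07 * _smooth_field(rng, cfg.shape, 10), 0, 1)
    # fibroglandular region opposite the implant
    cyg, cxg = rng.uniform(-0.15, 0.15), rng.uniform(0.25, 0.45)
    ryg, rxg = rng.uniform(0.28, 0.40, 2)
    fibro = ((Y - cyg) / ryg) ** 2 + ((X - cxg) / rxg) ** 2 <= 1.0
    fatfrac = np.where(fibro & tissue,
                       np.clip(0.22 + 0.1 * _smooth_field(rng, cfg.shape, 8), 0, 1),
                       fatfrac)
    base = 0.85 + 0.1 * _smooth_field(rng, cfg.shape, 16)
    w_mag = np.where(tissue, base * (1 - fatfrac), 0.0)
    f_mag = np.where(tissue, base * fatfrac, 0.0)
    # sparse bright fluid (cysts/ducts) in the water channel
    for _ in range(3):
        cy2, cx2 = rng.uniform(-0.5, 0.5, 2)
        r2 = rng.uniform(0.03, 0.07)
        blob = ((Y - cy2) ** 2 + (X - cx2) ** 2 <= r2**2) & tissue
        w_mag = np.where(blob, 1.25, w_mag)
        f_mag = np.where(blob, 0.0, f_mag)
    # thin skin rim carries water signal
    rim = (((Y / 0.88) ** 2 + (X / 0.88) ** 2 >= 0.90) & support)
    w_mag = np.where(rim & tissue, 0.55, w_mag)
    f_mag = np.where(rim & tissue, 0.25, f_mag)
    s_mag = np.where(implant, 1.0, 0.0) if cfg.implant_radius_frac > 0 else np.zeros(cfg.shape)

    # smooth low-order phases per species
    def phase():
        a, b, c = rng.uniform(-0.6, 0.6, 3)
        return np.exp(1j * (a + b * X + c * Y))

    truth = SpeciesImages(w=w_mag * phase(), f=f_mag * phase(), s=s_mag * phase())

    # field map: low-order polynomial + smooth random component + bump
    poly = rng.uniform(-0.5, 0.5) + rng.uniform(-1, 1) * X + rng.uniform(-1, 1) * Y \
        + rng.uniform(-1, 1) * X * Y + rng.uniform(-1, 1) * (X**2 - 0.5) \
        + rng.uniform(-1, 1) * (Y**2 - 0.5)
    bump = np.exp(-(((Y - cy) ** 2 + (X - cx - r_imp) ** 2) / (2 * 0.15**2)))
    fB = poly + 0.8 * _smooth_field(rng, cfg.shape, cfg.fB_smoothness) + 0.6 * bump
    fB = fB / max(np.abs(fB).max(), 1e-12) * cfg.fB_amplitude

    lo, hi = cfg.r2p_range
    r2p = lo + (hi - lo) * (0.5 + 0.5 * _smooth_field(rng, cfg.shape, 18))
    r2p = np.clip(r2p, 0, None)

    # coil sensitivities: offset-Gaussian magnitude, smooth phase
    coils = np.zeros((cfg.n_coils,) + tuple(cfg.shape), complex)
    for c in range(cfg.n_coils):
        th = 2 * np.pi * c / cfg.n_coils
        cy3, cx3 = 1.1 * np.sin(th), 1.1 * np.cos(th)
        mag = np.exp(-(((Y - cy3) ** 2 + (X - cx3) ** 2) / (2 * 0.85**2)))
        ph = np.exp(1j * (rng.uniform(-np.pi, np.pi)
                          + rng.uniform(-1.5, 1.5) * X + rng.uniform(-1.5, 1.5) * Y))
        coils[c] = mag * ph
    rss = np.sqrt((np.abs(coils) ** 2).sum(axis=0))
    coils /= max(rss[support].mean(), 1e-12)

    c0, c1, c2 = cfg.ghost_phase_coeffs
    ghost = c0 + c1 * X + c2 * X**2

    erode = ndimage.binary_erosion
    roi_implant = erode(implant, iterations=2)
    roi_tissue = erode(tissue, iterations=2)

    return Phantom(truth=truth, field=FieldParams(fB=fB, r2p=r2p), coils=coils,
                   ghost_phase=ghost, roi_implant=roi_implant,
                   roi_tissue=roi_tissue, support=support, config=cfg)


def ghost_sensitivities(coils: np.ndarray, ghost_phase: np.ndarray) -> np.ndarray:
    """Polarity-resolved sensitivity stack (2, nc, Ny, Nx).

    The readout-polarity phase difference is split symmetrically,
    exp(+i phi/2) on the positive and exp(-i phi/2) on the negative polarity;
    only the difference is physically identifiable.
    """
    return np.stack([coils * np.exp(0.5j * ghost_phase),
                     coils * np.exp(-0.5j * ghost_phase)])


def simulate_kspace(
    ph: Phantom,
    pattern: SamplingPattern,
    times: EchoTimes,
    model: SpectralModel,
    cfg: PhantomConfig | None = None,
    shifts=(0.0, 0.0, 0.0),
) -> KSpaceData:
    """Simulate sampled bipolar multi-echo multi-coil k-space.

    Applies the full joint forward operator (chemical-shift displacement,
    spectral encoding with the true mu, coil/ghost sensitivities, unitary
    DFT, sampling masks), then adds complex Gaussian noise to the sampled
    entries only, with std ``cfg.noise_sigma`` relative to the peak
    image-domain coil signal.
    """
    cfg = cfg if cfg is not None else ph.config
    if cfg is None:
        raise ValueError("need a PhantomConfig (pass cfg or build phantom with one)")
    if pattern.nky != ph.truth.shape[0]:
        raise ValueError("pattern ky size must match the phantom shape")
    if pattern.n_echoes != times.n_echoes:
        raise ValueError("pattern echo count must match the echo times")
    s_stack = ghost_sensitivities(ph.coils, ph.ghost_phase)
    op = JointOperator(ph.field.mu, s_stack, pattern.mask, times, model,
                       shifts=shifts)
    y = op.forward(ph.truth.stack())
    sigma = 0.0
    if cfg.noise_sigma > 0:
        # peak image-domain coil signal sets the noise scale
        peak = max(np.abs(ph.coils[None] * ph.truth.stack()[:, None]).max(), 1e-300)
        sigma = cfg.noise_sigma * peak
        rng = np.random.default_rng(cfg.seed + 9973)
        noise = sigma / np.sqrt(2) * (
            rng.standard_normal(y.shape) + 1j * rng.standard_normal(y.shape)
        )
        y = y + pattern.mask[:, :, None, :, None] * noise
    return KSpaceData(y=y, pattern=pattern, times=times, noise_sigma=sigma,
                      meta={"shifts": tuple(np.asarray(shifts, float))})
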