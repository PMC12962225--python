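"""Shared linear operators for simulation and reconstruction.

The simulator and every reconstruction use the *same* operator code so that
the forward model is adjoint-consistent by construction: unitary centered
2-D DFTs, Fourier-domain sub-pixel shifts along the readout axis, per-pixel
chemical-shift encoding, polarity-resolved coil/ghost sensitivities, and
binary ky sampling masks.

Array conventions
-----------------
Images are ``(Ny, Nx)`` with axis 0 the phase-encode (ky) direction and
axis 1 the readout. Multi-coil k-space is ``(2, Nt, nc, Ny, Nx)`` with the
leading axis indexing readout polarity (0 = positive/standard,
1 = negative/flipped). Sampling masks are ``(2, Nt, Nky)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.fft as sfft

__all__ = [
    "fft2c",
    "ifft2c",
    "shift_operator",
    "JointOperator",
    "PerEchoOperator",
    "cg_normal",
    "power_iteration",
]


def fft2c(img: np.ndarray) -> np.ndarray:
    """Unitary centered 2-D DFT over the last two axes."""
    return sfft.fftshift(
        sfft.fft2(sfft.ifftshift(img, axes=(-2, -1)), axes=(-2, -1), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    """Unitary centered 2-D inverse DFT over the last two axes."""
    return sfft.fftshift(
        sfft.ifft2(sfft.ifftshift(ksp, axes=(-2, -1)), axes=(-2, -1), norm="ortho"),
        axes=(-2, -1),
    )


def _shift_ramp(n: int, dx: float) -> np.ndarray:
    """Unit-modulus Fourier phase ramp implementing a +dx pixel shift."""
    k = np.fft.fftfreq(n)
    return np.exp(-2j * np.pi * k * dx)


def shift_operator(img: np.ndarray, dx: float) -> np.ndarray:
    """Sub-pixel circular shift by ``dx`` pixels along the readout (last) axis.

    Implemented as a Fourier phase ramp; exactly unitary, and
    ``shift_operator(., -dx)`` is both the inverse and the adjoint.
    """
    if not np.isfinite(dx):
        raise ValueError("shift must be finite")
    if dx == 0:
        return np.asarray(img, complex).copy()
    img = np.asarray(img, complex)
    X = sfft.fft(img, axis=-1)
    return sfft.ifft(X * _shift_ramp(img.shape[-1], dx), axis=-1)


class JointOperator:
    """Forward model E of the joint WFS reconstruction.

    E rho = D_+- F S_+- A(mu) M_+- rho: per polarity, each species image is
    displaced by its bulk chemical shift (+dx on the positive readout, -dx on
    the negative), mixed through the per-pixel chemical-shift encoding
    ``exp(mu t_j) [1, Phi_f, Phi_s]``, multiplied by the polarity-resolved
    coil/ghost sensitivities, Fourier transformed, and sampled by the binary
    ky mask of that (polarity, echo).

    Parameters
    ----------
    mu : (Ny, Nx) complex
        2*pi*i*fB - R2' map used in the forward model.
    s_stack : (2, nc, Ny, Nx) complex
        Polarity-resolved sensitivities (ghost phase absorbed).
    mask : (2, Nt, Nky) binary
        Sampling masks per polarity and echo.
    times, model
        Echo times and spectral model (define the species phasors).
    shifts : (dx_w, dx_f, dx_s)
        Per-species readout displacement [pixels] on the positive polarity;
        negated on the negative polarity. Water is conventionally 0.
    """

    def __init__(self, mu, s_stack, mask, times, model, shifts=(0.0, 0.0, 0.0)):
        from .spectral import species_phasors  # local import avoids cycle

        self.mu = np.asarray(mu, complex)
        self.s_stack = np.asarray(s_stack, complex)
        self.mask = np.asarray(mask)
        self.times = times
        self.model = model
        self.shifts = np.asarray(shifts, float)
        ny, nx = self.mu.shape
        if self.s_stack.shape[0] != 2 or self.s_stack.shape[-2:] != (ny, nx):
            raise ValueError("s_stack must be (2, nc, Ny, Nx) matching mu")
        if self.mask.shape[0] != 2 or self.mask.shape[-1] != ny:
            raise ValueError("mask must be (2, Nt, Nky) with Nky == Ny")
        if self.mask.shape[1] != times.n_echoes:
            raise ValueError("mask echo dimension must match echo times")
        self.B = species_phasors(times, model)  # (Nt, 3)
        self.E_decay = np.exp(self.mu[None] * times.t[:, None, None])  # (Nt,Ny,Nx)
        # Fourier ramps per polarity/species (2, 3, Nx)
        sgn = np.array([1.0, -1.0])
        self.ramps = np.stack(
            [
                np.stack([_shift_ramp(nx, s * dx) for dx in self.shifts])
                for s in sgn
            ]
        )
        self.n_coils = self.s_stack.shape[1]
        self.n_echoes = times.n_echoes
        self.image_shape = (ny, nx)
        self.y_shape = (2, self.n_echoes, self.n_coils, ny, nx)

    # -- core ---------------------------------------------------------------
    def _shift_species(self, rho_stack: np.ndarray, pol: int, adjoint: bool) -> np.ndarray:
        ramps = self.ramps[pol]  # (3, Nx)
        if adjoint:
            ramps = ramps.conj()
        X = sfft.fft(rho_stack, axis=-1)
        return sfft.ifft(X * ramps[:, None, :], axis=-1)

    def forward(self, rho_stack: np.ndarray) -> np.ndarray:
        """(3, Ny, Nx) species -> (2, Nt, nc, Ny, Nx) sampled k-space."""
        rho_stack = np.asarray(rho_stack, complex)
        if rho_stack.shape != (3,) + self.image_shape:
            raise ValueError("rho_stack must be (3, Ny, Nx)")
        y = np.empty(self.y_shape, complex)
        for p in (0, 1):
            shifted = self._shift_species(rho_stack, p, adjoint=False)
            mix = np.tensordot(self.B, shifted, axes=(1, 0))  # (Nt, Ny, Nx)
            imgs = self.E_decay * mix
            coil = self.s_stack[p][None, :] * imgs[:, None]  # (Nt, nc, Ny, Nx)
            y[p] = self.mask[p][:, None, :, None] * fft2c(coil)
        return y

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """(2, Nt, nc, Ny, Nx) k-space -> (3, Ny, Nx) species (E^H y)."""
        y = np.asarray(y, complex)
        if y.shape != self.y_shape:
            raise ValueError(f"y must have shape {self.y_shape}")
        rho = np.zeros((3,) + self.image_shape, complex)
        for p in (0, 1):
            imgs = ifft2c(self.mask[p][:, None, :, None] * y[p])
            comb = np.sum(self.s_stack[p].conj()[None, :] * imgs, axis=1)  # (Nt,Ny,Nx)
            comb = self.E_decay.conj() * comb
            mix = np.tensordot(self.B.conj().T, comb, axes=(1, 0))  # (3, Ny, Nx)
            rho += self._shift_species(mix, p, adjoint=True)
        return rho

    def normal(self, rho_stack: np.ndarray) -> np.ndarray:
        return self.adjoint(self.forward(rho_stack))

    # -- diagnostics --------------------------------------------------------
    def dot_test(self, rng=None) -> float:
        """Relative adjoint dot-product error |<Ex,y> - <x,E^H y>| / (|Ex||y|)."""
        rng = np.random.default_rng(rng)
        x = rng.standard_normal((3,) + self.image_shape) + 1j * rng.standard_normal(
            (3,) + self.image_shape
        )
        y = rng.standard_normal(self.y_shape) + 1j * rng.standard_normal(self.y_shape)
        Ex = self.forward(x)
        Ehy = self.adjoint(y)
        lhs = np.vdot(y, Ex)
        rhs = np.vdot(Ehy, x)
        return abs(lhs - rhs) / max(np.linalg.norm(Ex) * np.linalg.norm(y), 1e-300)

    def max_eig(self, n_iter: int = 30, seed: int = 0) -> float:
        """Largest eigenvalue of E^H E by power iteration."""
        return power_iteration(self.normal, (3,) + self.image_shape, n_iter, seed)


class PerEchoOperator:
    """Polarity-stacked SENSE operator for a single echo.

    E_j x = [D_j+ F (S_+ x); D_j- F (S_- x)] — the ghost-corrected parallel
    imaging forward model used for per-echo reconstruction and NGC.
    """

    def __init__(self, s_stack, mask_echo):
        self.s_stack = np.asarray(s_stack, complex)  # (2, nc, Ny, Nx)
        self.mask = np.asarray(mask_echo)  # (2, Nky)
        self.image_shape = self.s_stack.shape[-2:]
        self.n_coils = self.s_stack.shape[1]
        self.y_shape = (2, self.n_coils) + self.image_shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        coil = self.s_stack * x[None, None]
        return self.mask[:, None, :, None] * fft2c(coil)

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        imgs = ifft2c(self.mask[:, None, :, None] * y)
        return np.sum(self.s_stack.conj() * imgs, axis=(0, 1))

    def normal(self, x: np.ndarray) -> np.ndarray:
        return self.adjoint(self.forward(x))

    def max_eig(self, n_iter: int = 30, seed: int = 0) -> float:
        return power_iteration(self.normal, self.image_shape, n_iter, seed)


@dataclass
class CGResult:
    x: np.ndarray
    residuals: list = dfield(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def cg_normal(op, y: np.ndarray, tol: float = 1e-9, max_iter: int = 100,
              x0: np.ndarray | None = None) -> CGResult:
    """Conjugate gradients on the normal equations ``op.normal(x) = op.adjoint(y)``.

    Residuals reported are relative data residuals ``|E x - y| / |y|``.
    """
    b = op.adjoint(y)
    x = np.zeros_like(b) if x0 is None else x0.astype(complex).copy()
    r = b - op.normal(x)
    p = r.copy()
    rs = np.vdot(r, r).real
    ynorm = max(np.linalg.norm(y), 1e-300)
    res = CGResult(x=x)
    for it in range(max_iter):
        Ap = op.normal(p)
        denom = np.vdot(p, Ap).real
        if denom <= 0:
            break
        alpha = rs / denom
        x += alpha * p
        r -= alpha * Ap
        rs_new = np.vdot(r, r).real
        data_res = np.linalg.norm(op.forward(x) - y) / ynorm
        res.residuals.append(float(data_res))
        res.n_iter = it + 1
        if data_res <= tol:
            res.converged = True
            break
        p = r + (rs_new / max(rs, 1e-300)) * p
        rs = rs_new
    res.x = x
    return res


def power_iteration(normal_fn, shape, n_iter: int = 30, seed: int = 0) -> float:
    """Largest eigenvalue of a Hermitian PSD operator given its apply-function."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(n_iter):
        w = normal_fn(v)
        lam = float(np.linalg.norm(w))
        if lam == 0:
            return 0.0
        v = w / lam
    return lam
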