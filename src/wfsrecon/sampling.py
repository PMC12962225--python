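"""ky-TE undersampling pattern design for bipolar multi-echo FSE.

Three pattern families are provided, all with a fully sampled central
autocalibration (ACS) block in *both* readout polarities:

* ``uniform`` — regular ky lattice, identical at every echo within a
  polarity, complementary half-stride offset between polarities.
* ``vd`` — variable-density random ky, identical across echoes within a
  polarity, density ~ (1 - |ky|/kmax)^p.
* ``incoherent_kyte`` — trajectory-based incoherent ky-TE sampling: each
  excitation traces one ky path across the echo train with bounded
  inter-echo jumps (|dky| <= max_jump), odd/even echo entries assigned to
  the standard/flipped interleaf.

Acceleration R is quoted for the combined positive+negative data
(total mask entries / sampled entries).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .operators import JointOperator

__all__ = [
    "SamplingPattern",
    "acs_slice",
    "make_uniform",
    "make_vd",
    "make_incoherent_kyte",
    "check_trajectories",
    "psf",
    "PSFReport",
]


def acs_slice(nky: int, n_acs: int) -> slice:
    """Centered ACS row range (center convention matches the centered DFT)."""
    c = nky // 2
    lo = c - n_acs // 2
    return slice(max(lo, 0), min(lo + n_acs, nky))


@dataclass
class SamplingPattern:
    """Binary ky sampling masks per polarity and echo.

    mask has shape (2, Nt, Nky); index 0 is the positive/standard polarity.
    For trajectory-based patterns ``trajectories`` holds the per-excitation
    ky paths (n_exc, Nt) so the jump constraint can be checked exhaustively.
    """

    mask: np.ndarray
    n_acs: int
    R_nominal: float
    kind: str
    seed: int | None = None
    trajectories: np.ndarray | None = None
    max_jump: int | None = None
    meta: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3 or self.mask.shape[0] != 2:
            raise ValueError("mask must be (2, Nt, Nky)")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        self.mask = self.mask.astype(np.uint8)

    @property
    def nky(self) -> int:
        return self.mask.shape[2]

    @property
    def n_echoes(self) -> int:
        return self.mask.shape[1]

    @property
    def achieved_R(self) -> float:
        """Total entries / sampled entries over both polarities."""
        n = int(self.mask.sum())
        return self.mask.size / max(n, 1)

    def echo_union(self, j: int) -> np.ndarray:
        """Combined-polarity sampled-line indicator at echo j."""
        return np.clip(self.mask[0, j] + self.mask[1, j], 0, 1)


def _with_acs(mask: np.ndarray, n_acs: int) -> np.ndarray:
    if n_acs > 0:
        mask[:, :, acs_slice(mask.shape[2], n_acs)] = 1
    return mask


def _check_feasible(nky: int, R: float, n_acs: int) -> None:
    if R < 1:
        raise ValueError("R must be >= 1")
    if R > nky:
        raise ValueError("R exceeds the number of ky lines")
    if R > 1 and nky / R < n_acs:
        raise ValueError(
            f"infeasible: fully sampled ACS of {n_acs} lines alone exceeds the "
            f"R={R} budget of {nky / R:.1f} lines per echo/polarity"
        )


def _outer_stride(nky: int, R: float, n_acs: int) -> int:
    """Per-polarity stride in the outer region that keeps the net combined
    acceleration at R despite the fully sampled ACS block."""
    target_lines = nky / R  # per echo per polarity, ACS included
    outer_lines = max(target_lines - n_acs, 1.0)
    stride = int(round((nky - n_acs) / outer_lines))
    return max(stride, 1)


def make_uniform(nky: int, nt: int, R: float, n_acs: int = 0,
                 alternate_te: bool = False) -> SamplingPattern:
    """Regular lattice sampling, complementary between polarities.

    By default every echo within a polarity samples the same ky comb, with
    the negative polarity offset by half the per-polarity stride so the
    combined data form a twice-denser lattice. With ``alternate_te=True``
    the two complementary combs alternate between odd and even echoes within
    each polarity — the pattern a blip-free bipolar echo train actually
    produces when its two interleaves are grouped by readout polarity.
    """
    _check_feasible(nky, R, n_acs)
    mask = np.zeros((2, nt, nky), np.uint8)
    if R == 1:
        mask[:] = 1
        return SamplingPattern(mask, n_acs, R, "uniform")
    stride = _outer_stride(nky, R, n_acs)
    offset = stride // 2
    comb_a = np.zeros(nky, np.uint8)
    comb_a[0::stride] = 1
    comb_b = np.zeros(nky, np.uint8)
    comb_b[offset::stride] = 1
    for j in range(nt):
        if alternate_te and j % 2 == 1:
            mask[0, j], mask[1, j] = comb_b, comb_a
        else:
            mask[0, j], mask[1, j] = comb_a, comb_b
    mask = _with_acs(mask, n_acs)
    return SamplingPattern(mask, n_acs, R, "uniform",
                           meta={"alternate_te": alternate_te})


def _vd_weights(nky: int, power: float) -> np.ndarray:
    ky = np.arange(nky) - nky // 2
    w = (1.0 - np.abs(ky) / (nky / 2 + 1.0)) ** power
    return w / w.sum()


def make_vd(
    nky: int, nt: int, R: float, n_acs: int = 0, density_power: float = 2.0,
    seed: int = 0,
) -> SamplingPattern:
    """Variable-density random ky pattern (echo-independent within polarity).

    ky lines are drawn without replacement from a centered polynomial
    density ~ (1 - |ky|/kmax)^density_power; the two polarities receive
    disjoint draws outside the ACS block.
    """
    _check_feasible(nky, R, n_acs)
    rng = np.random.default_rng(seed)
    target = nky / R  # lines per echo per polarity, ACS included
    n_outer = int(round(max(target - n_acs, 0)))
    acs = acs_slice(nky, n_acs)
    outer_idx = np.array(
        [k for k in range(nky) if not (acs.start <= k < acs.stop)] if n_acs else
        list(range(nky))
    )
    mask = np.zeros((2, nt, nky), np.uint8)
    n_draw = min(2 * n_outer, outer_idx.size)
    if n_draw > 0:
        w = _vd_weights(nky, density_power)[outer_idx]
        drawn = rng.choice(outer_idx, size=n_draw, replace=False, p=w / w.sum())
        drawn = rng.permutation(drawn)
        mask[0, :, drawn[: n_draw // 2]] = 1
        mask[1, :, drawn[n_draw // 2: 2 * (n_draw // 2)]] = 1
        if n_draw % 2:
            mask[1, :, drawn[-1]] = 1
    mask = _with_acs(mask, n_acs)
    return SamplingPattern(mask, n_acs, R, "vd", seed=seed,
                           meta={"density_power": density_power})


def make_incoherent_kyte(
    nky: int, nt: int, R: float, n_acs: int = 0, max_jump: int = 12, seed: int = 0,
    density_power: float = 2.0,
) -> SamplingPattern:
    """Incoherent ky-TE pattern from per-excitation ky trajectories.

    Each excitation contributes one ky value per echo; consecutive echoes in
    one excitation differ by at most ``max_jump`` ky steps (a per-readout-
    train gradient-blip constraint). Even echo indices (0-based: echoes
    1, 3, 5, ... in 1-based counting) populate the standard interleaf and
    odd indices the flipped interleaf, so adjacent same-polarity echoes are
    two trajectory steps apart. Trajectory starts are drawn from a centered
    variable density; steps are uniform in [-max_jump, max_jump] with
    reflection at the ky boundaries.
    """
    _check_feasible(nky, R, n_acs)
    if max_jump < 1 and R > 1:
        raise ValueError("max_jump must allow ky to change when undersampling")
    rng = np.random.default_rng(seed)
    mask = np.zeros((2, nt, nky), np.uint8)
    mask = _with_acs(mask, n_acs)
    if R == 1:
        mask[:] = 1
        return SamplingPattern(mask, n_acs, R, "incoherent_kyte", seed=seed,
                               max_jump=max_jump)

    total_target = int(round(mask.size / R))
    w_start = _vd_weights(nky, density_power)
    trajs = []
    max_exc = 4 * nky  # safety cap
    union = mask.any(axis=(0, 1)).astype(bool)  # ky lines sampled anywhere
    while int(mask.sum()) < total_target and len(trajs) < max_exc:
        traj = np.zeros(nt, int)
        # start preferentially on a ky line not yet covered at any echo,
        # to spread aggregate encoding across the full ky axis
        w0 = w_start * np.where(union, 0.05, 1.0)
        ky = int(rng.choice(nky, p=w0 / w0.sum()))
        for j in range(nt):
            if j > 0:
                lo = max(ky - max_jump, 0)
                hi = min(ky + max_jump, nky - 1)
                cand = np.arange(lo, hi + 1)
                # preference order: globally uncovered ky, then lines free at
                # this (echo, polarity), then anything in the jump window
                fresh = cand[~union[cand]]
                free = cand[mask[j % 2, j, cand] == 0]
                pool = fresh if fresh.size else (free if free.size else cand)
                ky = int(rng.choice(pool))
            traj[j] = ky
            mask[j % 2, j, ky] = 1
            union[ky] = True
        trajs.append(traj)
    return SamplingPattern(mask, n_acs, R, "incoherent_kyte", seed=seed,
                           trajectories=np.array(trajs, int), max_jump=max_jump,
                           meta={"density_power": density_power})


def check_trajectories(pattern: SamplingPattern) -> bool:
    """Exhaustively verify the per-excitation adjacent-echo jump constraint."""
    if pattern.trajectories is None:
        raise ValueError("pattern has no stored trajectories")
    jumps = np.abs(np.diff(pattern.trajectories, axis=1))
    return bool((jumps <= pattern.max_jump).all())


@dataclass
class PSFReport:
    """Point-spread analysis of a sampling pattern.

    per_echo : (2, Nt, Nky) complex — inverse DFT along ky of each
        polarity/echo mask.
    species : (3, Nky) complex — species-domain PSF: a centered delta in each
        species channel passed through the joint normal operator E^H E
        (unit sensitivities, mu = 0), normalized per channel.
    max_sidelobe : worst-case |sidelobe|/|mainlobe| of the same-species
        species-domain PSF, measured outside a small mainlobe neighborhood
        (``mainlobe_radius`` pixels) — the central skirt produced by the
        fully sampled ACS is resolution/apodization, not aliasing.
    per_echo_sidelobe : worst per-(polarity, echo) |sidelobe|/|mainlobe|,
        same exclusion.
    """

    per_echo: np.ndarray
    species: np.ndarray
    max_sidelobe: float
    per_echo_sidelobe: float
    mainlobe_radius: int = 3


def _ifft1c(v: np.ndarray) -> np.ndarray:
    import scipy.fft as sfft
    return sfft.fftshift(sfft.ifft(sfft.ifftshift(v, axes=-1), axis=-1, norm="ortho"),
                         axes=-1)


def psf(pattern: SamplingPattern, times=None, model=None,
        mainlobe_radius: int = 3) -> PSFReport:
    """Per-echo and species-domain point-spread functions of a pattern.

    The species-domain PSF measures how ky-TE aliasing energy lands in the
    separated species: it is computed on a 1-D (ky) version of the joint
    operator with unit coil sensitivity and zero field map, so only the
    interplay of the masks and the spectral encoding enters.
    """
    from .spectral import EchoTimes, SpectralModel

    if times is None:
        times = EchoTimes.symmetric(pattern.n_echoes)
    if model is None:
        model = SpectralModel()
    nky = pattern.nky
    per_echo = _ifft1c(pattern.mask.astype(complex))  # (2, Nt, Nky)

    # 1-D joint operator: image axis = ky, single "readout" column.
    mu = np.zeros((nky, 1), complex)
    s = np.ones((2, 1, nky, 1), complex)
    op = JointOperator(mu, s, pattern.mask, times, model)
    center = nky // 2
    lo, hi = center - mainlobe_radius, center + mainlobe_radius + 1
    species = np.zeros((3, nky), complex)
    ratios = []
    for k in range(3):
        delta = np.zeros((3, nky, 1), complex)
        delta[k, center, 0] = 1.0
        out = op.normal(delta)[k, :, 0]
        main = abs(out[center])
        side = np.abs(out.copy())
        side[lo:hi] = 0
        ratios.append(side.max() / max(main, 1e-300))
        species[k] = out / max(main, 1e-300)

    pe_ratios = []
    for p in (0, 1):
        for j in range(pattern.n_echoes):
            v = np.abs(per_echo[p, j]).copy()
            main = v[center]
            v[lo:hi] = 0
            pe_ratios.append(v.max() / max(main, 1e-300))
    return PSFReport(
        per_echo=per_echo,
        species=species,
        max_sidelobe=float(max(ratios)),
        per_echo_sidelobe=float(max(pe_ratios)),
        mainlobe_radius=mainlobe_radius,
    )
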