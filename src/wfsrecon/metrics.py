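"""Image-quality and species-leakage metrics.

SSIM, PSNR and GMSD are computed on magnitude images normalized to the
reference's 99th percentile, making every metric invariant to a common
positive rescaling of image and reference. Leakage percentages quantify
cross-contamination between separated species:

* ``SWFS`` — water/fat leakage: mean silicone-image signal in the
  tissue ROI over its mean in the implant ROI, in percent.
* ``WS`` / ``FS`` — silicone leakage: mean water (resp. fat) signal in the
  implant ROI over the mean silicone signal there, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

__all__ = ["EvalReport", "ssim", "psnr", "gmsd",
           "leakage_swfs", "leakage_ws", "leakage_fs", "evaluate_species"]

PSNR_CAP_DB = 200.0


def _normalize_pair(img: np.ndarray, ref: np.ndarray):
    img = np.abs(np.asarray(img))
    ref = np.abs(np.asarray(ref))
    if img.shape != ref.shape:
        raise ValueError("image and reference must have equal shapes")
    peak = np.percentile(ref, 99)
    if peak <= 0:
        raise ValueError("reference has no signal (99th percentile <= 0)")
    return img / peak, ref / peak


def ssim(img: np.ndarray, ref: np.ndarray) -> float:
    """Structural similarity (11x11 Gaussian window, sigma 1.5, K1=0.01,
    K2=0.03) of magnitude images, reference-peak normalized."""
    a, b = _normalize_pair(img, ref)
    return float(structural_similarity(
        a, b, gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
        K1=0.01, K2=0.03, data_range=1.0,
    ))


def psnr(img: np.ndarray, ref: np.ndarray) -> float:
    """Peak signal-to-noise ratio [dB] relative to the reference peak,
    capped at 200 dB for identical images."""
    a, b = _normalize_pair(img, ref)
    mse = float(np.mean((a - b) ** 2))
    peak = float(b.max())
    if mse == 0:
        return PSNR_CAP_DB
    return float(min(10 * np.log10(peak**2 / mse), PSNR_CAP_DB))


def _prewitt_gm(img: np.ndarray) -> np.ndarray:
    # Prewitt kernels normalized by 1/3 as in the GMSD publication
    kx = np.array([[1, 0, -1], [1, 0, -1], [1, 0, -1]]) / 3.0
    gx = ndimage.convolve(img, kx, mode="nearest")
    gy = ndimage.convolve(img, kx.T, mode="nearest")
    return np.sqrt(gx**2 + gy**2)


def gmsd(img: np.ndarray, ref: np.ndarray, c: float = 170.0) -> float:
    """Gradient magnitude similarity deviation.

    Follows the original formulation: 2x2 average filtering and downsampling
    by 2, Prewitt gradient magnitudes, pixelwise similarity
    (2 g1 g2 + c) / (g1^2 + g2^2 + c) with c = 170 on a 0-255 intensity
    scale, and the population standard deviation of the similarity map.
    Identical images give 0.
    """
    a, b = _normalize_pair(img, ref)
    a, b = a * 255.0, b * 255.0
    a = ndimage.uniform_filter(a, 2)[::2, ::2]
    b = ndimage.uniform_filter(b, 2)[::2, ::2]
    g1, g2 = _prewitt_gm(a), _prewitt_gm(b)
    gms = (2 * g1 * g2 + c) / (g1**2 + g2**2 + c)
    return float(np.std(gms))


def _roi_mean(img: np.ndarray, roi: np.ndarray) -> float:
    roi = np.asarray(roi, bool)
    if not roi.any():
        raise ValueError("empty ROI")
    return float(np.abs(img)[roi].mean())


def leakage_swfs(sil_img: np.ndarray, roi_wf: np.ndarray, roi_s: np.ndarray) -> float:
    """Water/fat-region leakage on the silicone image [%]:
    100 * mean|I_S| over the tissue ROI / mean|I_S| over the implant ROI."""
    roi_wf, roi_s = np.asarray(roi_wf, bool), np.asarray(roi_s, bool)
    if (roi_wf & roi_s).any():
        raise ValueError("ROIs must be disjoint")
    return 100.0 * _roi_mean(sil_img, roi_wf) / _roi_mean(sil_img, roi_s)


def leakage_ws(w_img: np.ndarray, s_img: np.ndarray, roi_s: np.ndarray) -> float:
    """Silicone-ROI leakage into water [%]: 100 * mean|I_W| / mean|I_S|,
    both over the implant ROI."""
    return 100.0 * _roi_mean(w_img, roi_s) / _roi_mean(s_img, roi_s)


def leakage_fs(f_img: np.ndarray, s_img: np.ndarray, roi_s: np.ndarray) -> float:
    """Silicone-ROI leakage into fat [%]: 100 * mean|I_F| / mean|I_S|,
    both over the implant ROI."""
    return 100.0 * _roi_mean(f_img, roi_s) / _roi_mean(s_img, roi_s)


@dataclass
class EvalReport:
    """Per-species quality metrics plus leakage percentages."""

    ssim_w: float
    ssim_f: float
    ssim_s: float
    psnr_w: float
    psnr_f: float
    psnr_s: float
    gmsd_w: float
    gmsd_f: float
    gmsd_s: float
    leakage_swfs: float
    leakage_ws: float
    leakage_fs: float

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate_species(rho, reference, roi_tissue, roi_implant) -> EvalReport:
    """Full evaluation of separated species against a reference."""
    vals = {}
    for name, img, ref in (("w", rho.w, reference.w), ("f", rho.f, reference.f),
                           ("s", rho.s, reference.s)):
        vals[f"ssim_{name}"] = ssim(np.abs(img), np.abs(ref))
        vals[f"psnr_{name}"] = psnr(np.abs(img), np.abs(ref))
        vals[f"gmsd_{name}"] = gmsd(np.abs(img), np.abs(ref))
    vals["leakage_swfs"] = leakage_swfs(rho.s, roi_tissue, roi_implant)
    vals["leakage_ws"] = leakage_ws(rho.w, rho.s, roi_implant)
    vals["leakage_fs"] = leakage_fs(rho.f, rho.s, roi_implant)
    return EvalReport(**vals)
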