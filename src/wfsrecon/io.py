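"""HDF5 dataset container and NIfTI export.

One HDF5 file holds a simulated (or, later, adapted scanner) dataset:

    /truth/{w,f,s}          complex species ground truth (if synthetic)
    /field/{fB,r2p}         true field maps
    /coils                  complex coil sensitivities
    /ghost_phase            polarity phase-difference map [rad]
    /rois/{implant,tissue,support}
    /kspace/{pos,neg}       (Nt, nc, Ny, Nx) complex sampled k-space
    /pattern/{mask,...}     sampling masks and bookkeeping
    /calib/{s_pos,s_neg}    estimated polarity sensitivities
    /field_est/{fB,r2p}     estimated field maps
    /meta                   spectral model, echo times, seeds (attrs/JSON)

Images export to NIfTI with a 1 mm isotropic affine; magnitudes are stored
(complex images are saved as magnitude volumes).
"""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np

from .ngc import PolaritySensitivities
from .phantom import KSpaceData, Phantom, PhantomConfig
from .sampling import SamplingPattern
from .spectral import EchoTimes, FieldParams, SpectralModel, SpeciesImages

__all__ = ["save_container", "load_container", "save_nifti", "load_nifti"]


def _write_pattern(g: h5py.Group, p: SamplingPattern) -> None:
    g.create_dataset("mask", data=p.mask)
    g.attrs["n_acs"] = p.n_acs
    g.attrs["R_nominal"] = p.R_nominal
    g.attrs["kind"] = p.kind
    g.attrs["seed"] = -1 if p.seed is None else p.seed
    if p.max_jump is not None:
        g.attrs["max_jump"] = p.max_jump
    if p.trajectories is not None:
        g.create_dataset("trajectories", data=p.trajectories)


def _read_pattern(g: h5py.Group) -> SamplingPattern:
    seed = int(g.attrs["seed"])
    return SamplingPattern(
        mask=g["mask"][()],
        n_acs=int(g.attrs["n_acs"]),
        R_nominal=float(g.attrs["R_nominal"]),
        kind=str(g.attrs["kind"]),
        seed=None if seed < 0 else seed,
        trajectories=g["trajectories"][()] if "trajectories" in g else None,
        max_jump=int(g.attrs["max_jump"]) if "max_jump" in g.attrs else None,
    )


def save_container(
    path,
    *,
    phantom: Phantom | None = None,
    kspace: KSpaceData | None = None,
    sens: PolaritySensitivities | None = None,
    field_est: FieldParams | None = None,
    species: SpeciesImages | None = None,
    times: EchoTimes | None = None,
    model: SpectralModel | None = None,
) -> None:
    """Write any subset of the pipeline state to one HDF5 file."""
    with h5py.File(path, "w") as h5:
        if phantom is not None:
            t = h5.create_group("truth")
            for k, v in (("w", phantom.truth.w), ("f", phantom.truth.f),
                         ("s", phantom.truth.s)):
                t.create_dataset(k, data=v)
            fg = h5.create_group("field")
            fg.create_dataset("fB", data=phantom.field.fB)
            fg.create_dataset("r2p", data=phantom.field.r2p)
            h5.create_dataset("coils", data=phantom.coils)
            h5.create_dataset("ghost_phase", data=phantom.ghost_phase)
            rg = h5.create_group("rois")
            rg.create_dataset("implant", data=phantom.roi_implant)
            rg.create_dataset("tissue", data=phantom.roi_tissue)
            rg.create_dataset("support", data=phantom.support)
            if phantom.config is not None:
                h5.attrs["phantom_config"] = json.dumps(
                    {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in phantom.config.__dict__.items()})
        if kspace is not None:
            kg = h5.create_group("kspace")
            kg.create_dataset("pos", data=kspace.y[0])
            kg.create_dataset("neg", data=kspace.y[1])
            kg.attrs["noise_sigma"] = kspace.noise_sigma
            _write_pattern(h5.create_group("pattern"), kspace.pattern)
            if kspace.times is not None and times is None:
                times = kspace.times
        if sens is not None:
            cg = h5.create_group("calib")
            cg.create_dataset("s_pos", data=sens.s_pos)
            cg.create_dataset("s_neg", data=sens.s_neg)
            cg.attrs["method"] = sens.method
            if sens.eigval is not None:
                cg.create_dataset("eigval", data=sens.eigval)
        if field_est is not None:
            fg = h5.create_group("field_est")
            fg.create_dataset("fB", data=field_est.fB)
            fg.create_dataset("r2p", data=field_est.r2p)
        if species is not None:
            sg = h5.create_group("species")
            for k, v in (("w", species.w), ("f", species.f), ("s", species.s)):
                sg.create_dataset(k, data=v)
        mg = h5.create_group("meta")
        if times is not None:
            mg.create_dataset("echo_times", data=times.t)
            mg.attrs["delta_te"] = times.delta_te
        if model is not None:
            mg.attrs["spectral_model"] = json.dumps(model.to_dict())


def load_container(path) -> dict:
    """Read a container back into domain objects (keys mirror the groups)."""
    out: dict = {}
    with h5py.File(path, "r") as h5:
        times = None
        if "meta" in h5:
            mg = h5["meta"]
            if "echo_times" in mg:
                times = EchoTimes(t=mg["echo_times"][()],
                                  delta_te=float(mg.attrs["delta_te"]))
                out["times"] = times
            if "spectral_model" in mg.attrs:
                out["model"] = SpectralModel.from_dict(
                    json.loads(mg.attrs["spectral_model"]))
        if "truth" in h5:
            truth = SpeciesImages(w=h5["truth/w"][()], f=h5["truth/f"][()],
                                  s=h5["truth/s"][()])
            field = FieldParams(fB=h5["field/fB"][()], r2p=h5["field/r2p"][()])
            cfg = None
            if "phantom_config" in h5.attrs:
                d = json.loads(h5.attrs["phantom_config"])
                d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
                cfg = PhantomConfig(**d)
            out["phantom"] = Phantom(
                truth=truth, field=field, coils=h5["coils"][()],
                ghost_phase=h5["ghost_phase"][()],
                roi_implant=h5["rois/implant"][()].astype(bool),
                roi_tissue=h5["rois/tissue"][()].astype(bool),
                support=h5["rois/support"][()].astype(bool), config=cfg)
        if "pattern" in h5:
            out["pattern"] = _read_pattern(h5["pattern"])
        if "kspace" in h5:
            y = np.stack([h5["kspace/pos"][()], h5["kspace/neg"][()]])
            out["kspace"] = KSpaceData(
                y=y, pattern=out["pattern"], times=times,
                noise_sigma=float(h5["kspace"].attrs["noise_sigma"]))
        if "calib" in h5:
            out["sens"] = PolaritySensitivities(
                s_pos=h5["calib/s_pos"][()], s_neg=h5["calib/s_neg"][()],
                method=str(h5["calib"].attrs["method"]),
                eigval=h5["calib/eigval"][()] if "eigval" in h5["calib"] else None)
        if "field_est" in h5:
            out["field_est"] = FieldParams(fB=h5["field_est/fB"][()],
                                           r2p=h5["field_est/r2p"][()])
        if "species" in h5:
            out["species"] = SpeciesImages(w=h5["species/w"][()],
                                           f=h5["species/f"][()],
                                           s=h5["species/s"][()])
    return out


def save_nifti(img: np.ndarray, path, voxel_mm: float = 1.0) -> None:
    """Save an image (magnitude taken for complex input) as NIfTI with an
    isotropic affine."""
    data = np.abs(np.asarray(img)).astype(np.float32)
    if data.ndim == 2:
        data = data[..., None]
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)
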