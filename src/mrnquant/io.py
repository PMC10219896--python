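"""File layout and NIfTI/CSV serialization.

On-disk layout under a run directory::

    images/<participant_id>/slab-<k>_e1.nii.gz   short-echo magnitude volume
    images/<participant_id>/slab-<k>_e2.nii.gz   long-echo magnitude volume
    images/<participant_id>/slab-<k>_mask.nii.gz binary nerve ROI
    ground_truth.csv                             generator ground truth
    clinical.csv                                 covariate table

Volumes are NIfTI-1 with an affine encoding the in-plane pixel spacing and
the center-to-center slice distance (thickness + gap).
"""

from __future__ import annotations

import re
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import InvalidParameterError
from .protocol import AcquisitionProtocol
from .relaxometry import DualEchoVolume, NerveMask
from .synthetic import ParticipantData

_SLAB_RE = re.compile(r"slab-(\d+)_e1\.nii(\.gz)?$")


def _affine(protocol: AcquisitionProtocol) -> np.ndarray:
    sp = protocol.pixel_spacing
    return np.diag([sp, sp, protocol.slice_spacing, 1.0])


def write_participant_images(participant: ParticipantData, run_dir,
                             protocol: AcquisitionProtocol) -> Path:
    """Write one participant's volumes and masks; returns their directory."""
    pdir = Path(run_dir) / "images" / participant.participant_id
    pdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(protocol)
    for vol, msk in zip(participant.volumes, participant.masks):
        k = vol.slab_id
        nib.save(nib.Nifti1Image(np.asarray(vol.image_te1), aff),
                 pdir / f"slab-{k}_e1.nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(vol.image_te2), aff),
                 pdir / f"slab-{k}_e2.nii.gz")
        nib.save(nib.Nifti1Image(msk.mask.astype(np.uint8), aff),
                 pdir / f"slab-{k}_mask.nii.gz")
    return pdir


def read_participant_images(participant_dir,
                            protocol: AcquisitionProtocol
                            ) -> tuple[list[DualEchoVolume], list[NerveMask]]:
    """Read every slab pair + mask from one participant directory."""
    pdir = Path(participant_dir)
    volumes, masks = [], []
    e1_files = sorted(p for p in pdir.iterdir() if _SLAB_RE.search(p.name))
    if not e1_files:
        raise InvalidParameterError(f"no slab images found under {pdir}")
    for e1_path in e1_files:
        slab_id = int(_SLAB_RE.search(e1_path.name).group(1))
        e2_path = pdir / e1_path.name.replace("_e1.", "_e2.")
        mask_path = pdir / e1_path.name.replace("_e1.", "_mask.")
        if not e2_path.exists() or not mask_path.exists():
            raise InvalidParameterError(
                f"slab {slab_id}: missing long-echo image or mask in {pdir}"
            )
        e1 = np.asarray(nib.load(str(e1_path)).dataobj)
        e2 = np.asarray(nib.load(str(e2_path)).dataobj)
        m = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        volumes.append(DualEchoVolume(
            image_te1=e1, image_te2=e2, te1=protocol.te1, te2=protocol.te2,
            pixel_spacing=protocol.pixel_spacing, slab_id=slab_id,
            slice_offset=protocol.slab_slice_range(slab_id).start,
            participant_id=pdir.name,
        ))
        masks.append(NerveMask(mask=m, slab_id=slab_id, provenance="manual"))
    return volumes, masks


def list_participant_dirs(run_dir) -> list[Path]:
    images = Path(run_dir) / "images"
    if not images.is_dir():
        raise InvalidParameterError(f"no images/ directory under {run_dir}")
    return sorted(p for p in images.iterdir() if p.is_dir())
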