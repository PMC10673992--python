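"""Volume and mesh I/O.

Volumes are exchanged as NRRD/NIfTI (via SimpleITK) or DICOM series
(read via SimpleITK with rescale slope/intercept applied; written via
pydicom, one CT slice per file).  Arrays are held in (x, y, z) axis
order in memory; SimpleITK's native pixel buffer is (z, y, x), so
transposition happens at the boundary.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .phantom import CTVolume
from .segmentation import BoneMask

__all__ = [
    "read_volume",
    "write_volume",
    "write_dicom_series",
    "read_mask",
    "write_mask",
]


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NRRD or NIfTI, chosen by file extension."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels.T))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read NRRD/NIfTI (file) or a DICOM series (directory) as HU."""
    import SimpleITK as sitk

    path = Path(path)
    if path.is_dir():
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(str(path))
        if not files:
            raise FileNotFoundError(f"no DICOM series found in {path}")
        reader.SetFileNames(files)
        img = reader.Execute()
    else:
        img = sitk.ReadImage(str(path))
    vox = sitk.GetArrayFromImage(img).T.astype(np.float32)
    return CTVolume(
        voxels=vox,
        spacing=tuple(float(s) for s in img.GetSpacing()),
        origin=tuple(float(o) for o in img.GetOrigin()),
    )


def write_dicom_series(volume: CTVolume, directory: str | os.PathLike) -> list[Path]:
    """Write a volume as a CT DICOM series, one slice per file.

    Pixels are stored as signed 16-bit with rescale slope 1 and
    intercept 0, i.e. stored values are HU directly.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    nx, ny, nz = volume.shape
    sx, sy, sz = volume.spacing
    paths = []
    data = np.clip(np.rint(volume.voxels), -32768, 32767).astype(np.int16)
    for k in range(nz):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientName = "phantom"
        ds.PatientID = "phantom"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [
            float(volume.origin[0]),
            float(volume.origin[1]),
            float(volume.origin[2] + k * sz),
        ]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [float(sy), float(sx)]
        ds.SliceThickness = float(sz)
        ds.Rows = ny
        ds.Columns = nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        # DICOM rows are y, columns are x.
        ds.PixelData = np.ascontiguousarray(data[:, :, k].T).tobytes()
        out = directory / f"slice_{k:04d}.dcm"
        pydicom.dcmwrite(out, ds, enforce_file_format=True)
        paths.append(out)
    return paths


def write_mask(mask: BoneMask, path: str | os.PathLike) -> None:
    """Write a binary mask as NRRD/NIfTI (uint8)."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(mask.voxels.T).astype(np.uint8))
    img.SetSpacing(tuple(float(s) for s in mask.spacing))
    sitk.WriteImage(img, str(path))


def read_mask(path: str | os.PathLike, hu_window=(float("nan"), float("nan"))) -> BoneMask:
    """Read a binary mask; provenance thresholds may be supplied by the caller."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    vox = sitk.GetArrayFromImage(img).T.astype(bool)
    return BoneMask(
        voxels=vox,
        spacing=tuple(float(s) for s in img.GetSpacing()),
        hu_window=(float(hu_window[0]), float(hu_window[1])),
        source_id=str(path),
    )
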