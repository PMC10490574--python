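"""Shared fixtures: phantoms, masks, and a programmatic DICOM writer."""

import numpy as np
import pytest

from pfb.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom with its ground truth (default healthy geometry)."""
    spec = PhantomSpec(rng_seed=3, salt_pepper_fraction=0.0, bone_intensity_sd=0.0)
    image, mask = generate_phantom(spec)
    return spec, image, mask


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom under the default acquisition-noise conditions."""
    spec = PhantomSpec(rng_seed=2)
    image, mask = generate_phantom(spec)
    return spec, image, mask


def write_test_dicom(path, pixels, *, slope=None, intercept=None,
                     protocol=None, patient_id="sub1"):
    """Write a minimal single-frame monochrome DICOM for fixtures."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    ds = Dataset()
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientID = patient_id
    pixels = np.asarray(pixels)
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.astype(np.uint16).tobytes()
    if slope is not None:
        ds.RescaleSlope = slope
    if intercept is not None:
        ds.RescaleIntercept = intercept
    if protocol is not None:
        ds.RepetitionTime = protocol["TR"]
        ds.EchoTime = protocol["TE"]
        ds.FlipAngle = protocol["flip_angle"]
    ds.save_as(path, enforce_file_format=True)
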