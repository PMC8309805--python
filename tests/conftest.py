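import numpy as np
import pytest

from mammocad import MammogramImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gray_image(rng):
    return MammogramImage(rng.random((12, 16)), pixel_spacing_mm=0.1)


@pytest.fixture
def rgb_image(rng):
    return MammogramImage(rng.random((8, 8, 3)))


def make_dicom(path, pixels, patient_id="P001", photometric="MONOCHROME2",
               with_pixels=True):
    """Write a minimal synthetic secondary-capture DICOM for tests."""
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import (
        ExplicitVRLittleEndian,
        SecondaryCaptureImageStorage,
        generate_uid,
    )

    pixels = np.asarray(pixels)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientID = patient_id
    ds.PatientAge = "048Y"
    ds.Modality = "MG"
    ds.StudyDate = "20200101"
    ds.ViewPosition = "CC"
    ds.Rows, ds.Columns = pixels.shape
    ds.PhotometricInterpretation = photometric
    ds.SamplesPerPixel = 1
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    if with_pixels:
        ds.PixelData = pixels.astype("<u2").tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path
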