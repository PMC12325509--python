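import numpy as np
import pytest

from lungdens import (AirwaySpec, PhantomSpec, generate_thorax_phantom,
                      remove_airways, segment_lungs)


@pytest.fixture(scope="session")
def default_phantom():
    """One default 128-cubed thorax phantom shared across the session."""
    spec = PhantomSpec(seed=7)
    vol, lung, airway = generate_thorax_phantom(spec)
    return spec, vol, lung, airway


@pytest.fixture(scope="session")
def segmented_phantom(default_phantom):
    spec, vol, lung, airway = default_phantom
    mask = segment_lungs(vol)
    parenchyma = remove_airways(vol, mask)
    return spec, vol, lung, airway, mask, parenchyma


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A coarse, fast phantom for pipeline-level tests."""
    def make(seed, mixture=None):
        return PhantomSpec(
            dims=(72, 72, 80), spacing=(1.6, 1.6, 1.6),
            lung_mixture=mixture or [(0.2, -980.0, 15.0), (0.8, -850.0, 60.0)],
            airway=AirwaySpec(radius=4.0, wall_thickness=3.0), seed=seed)
    return make


def write_dicom_series(dirpath, slices, spacing=(0.7, 0.7, 1.0),
                       slope=1.0, intercept=-1024.0, series_uid=None,
                       z_positions=None):
    """Write a list of 2-D stored-value arrays as a classic CT DICOM series."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    series_uid = series_uid or generate_uid()
    dx, dy, dz = spacing
    if z_positions is None:
        z_positions = [i * dz for i in range(len(slices))]
    paths = []
    for i, (arr, z) in enumerate(zip(slices, z_positions)):
        arr = np.asarray(arr, dtype=np.int16)
        sop = generate_uid()
        fm = FileMetaDataset()
        fm.TransferSyntaxUID = ExplicitVRLittleEndian
        fm.MediaStorageSOPClassUID = CTImageStorage
        fm.MediaStorageSOPInstanceUID = sop
        ds = Dataset()
        ds.file_meta = fm
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = sop
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = arr.shape
        ds.PixelSpacing = [dy, dx]      # row spacing, column spacing
        ds.SliceThickness = dz
        ds.ImagePositionPatient = [0.0, 0.0, float(z)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.PixelData = arr.tobytes()
        path = dirpath / f"slice_{series_uid[-6:]}_{i:03d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths
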