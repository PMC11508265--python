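import numpy as np
import pytest

from t2adc.phantom import PhantomSpec, generate_subject
from t2adc.preprocess import Volume, crop_to_mask, extract_slices, zscore


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise- and lesion-free phantom: intensities are a pure function of
    the zone label map."""
    return PhantomSpec(n_lesions=0, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def default_subject():
    return generate_subject(PhantomSpec(seed=3))


def cropped_slice_pairs(subject, subject_id="sub", margin=(5.0, 5.0, 0.0)):
    """Preprocess one phantom subject into paired X/Y slice samples."""
    t2c, box = crop_to_mask(subject.t2_volume, subject.mask_volume, margin)
    sl = tuple(slice(lo, hi) for lo, hi in box)
    adcc = Volume(subject.adc_volume.data[sl], subject.adc_volume.spacing_mm,
                  role="adc")
    maskc = Volume(subject.mask_volume.data[sl], subject.mask_volume.spacing_mm,
                   role="mask")
    samples = extract_slices(zscore(t2c), zscore(adcc), maskc,
                             subject_id=subject_id, crop_box=box)
    xs = [s for s in samples if s.domain == "X"]
    ys = [s for s in samples if s.domain == "Y"]
    return xs, ys
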