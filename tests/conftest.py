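import numpy as np
import pytest

import lvtrab as lt
from lvtrab.frames import ED, ES, Label

REGION4 = (Label.COMPACT, Label.TRABECULATION, Label.RECESS, Label.CENTRAL_CAVITY)
REGIONS = REGION4 + (Label.PAPILLARY,)


def ef_of(q, label):
    ed, es = q.get(label, ED), q.get(label, ES)
    return (ed - es) / ed


def dice_per_region(study, predicted, phase):
    """3-D Dice per label, pooled over the slices of one phase."""
    gt = np.stack([f.labels for f in study.frames(phase, gray=False)])
    pr = np.stack(
        [f.labels for f in sorted(
            (l for l in predicted if l.phase == phase),
            key=lambda f: f.slice_index or 0)]
    )
    out = {}
    for lbl in REGIONS:
        a, b = gt == int(lbl), pr == int(lbl)
        denom = a.sum() + b.sum()
        out[lbl] = 2 * np.sum(a & b) / denom if denom else 1.0
    return out


@pytest.fixture(scope="session")
def noiseless_sa_study():
    """Full default short-axis phantom rendered without blur or noise."""
    spec = lt.default_short_axis_spec(noise_sd=0.0, blur_sigma=0.0)
    return lt.generate_short_axis_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_sa_small():
    """Two-slice noiseless short-axis phantom (fast unit-level fixture)."""
    spec = lt.default_short_axis_spec(noise_sd=0.0, blur_sigma=0.0, n_slices=2)
    return lt.generate_short_axis_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_4ch_study():
    spec = lt.default_four_chamber_spec(noise_sd=0.0, blur_sigma=0.0)
    return lt.generate_four_chamber_phantom(spec)


@pytest.fixture(scope="session")
def noisy_sa_small():
    """Two-slice phantom at the default noise/blur level."""
    spec = lt.default_short_axis_spec(n_slices=2, seed=7)
    return lt.generate_short_axis_phantom(spec)


@pytest.fixture()
def table2_excessive_quantities():
    """The excessive-trabeculation baseline as measured region volumes."""
    return lt.baseline("excessive").to_quantities()
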