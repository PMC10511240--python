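import numpy as np
import pytest

from ippdyn import imaging, synthetic


@pytest.fixture(scope="session")
def default_noisy_field():
    """One default noisy field (seed 7) shared across imaging tests."""
    return synthetic.generate_image_fixture(synthetic.ImageFieldSpec(seed=7))


@pytest.fixture(scope="session")
def segmented_noisy_field(default_noisy_field):
    fx = default_noisy_field
    cell_labels = imaging.segment_cells(fx.images[0])
    nucleus_labels, flags = imaging.segment_nuclei(fx.images[1], cell_labels)
    return fx, cell_labels, nucleus_labels, flags


def match_to_truth(pred_labels, fx):
    """Map predicted cell ids to ground-truth ids by majority overlap."""
    mapping = {}
    for pid in np.unique(pred_labels[pred_labels > 0]):
        vals = fx.cell_labels[pred_labels == pid]
        vals = vals[vals > 0]
        if vals.size:
            mapping[int(pid)] = int(np.bincount(vals).argmax())
    return mapping
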