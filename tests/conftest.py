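import numpy as np
import pytest

from myofuse import defaults, make_culture
from myofuse.image_io import select_channel
from myofuse.nucleus_segmentation import detect_nuclei
from myofuse.tube_segmentation import segment_myotubes


@pytest.fixture(scope="session")
def params():
    return defaults()


@pytest.fixture(scope="session")
def culture512():
    """A small seeded culture: 1 myotube (4 nuclei), 2 myoblasts, 6 free nuclei."""
    return make_culture(
        height=512,
        width=512,
        n_tubes=1,
        nuclei_per_tube=[4],
        n_myoblasts=2,
        n_free_nuclei=6,
        noise_sigma=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def culture512_analysis(culture512, params):
    """Segmentation products for the small culture, computed once."""
    image, truth = culture512
    tubes = segment_myotubes(select_channel(image, params.myotube_channel), params)
    nuclei = detect_nuclei(select_channel(image, params.nuc_channel), params)
    return {"image": image, "truth": truth, "tubes": tubes, "nuclei": nuclei}


def match_detections(true_centres, detected_centres, tol=12.0):
    """Greedy one-to-one matching of detections to ground-truth centres.

    Returns the indices of matched true centres; used to score recovery.
    """
    true = list(enumerate(true_centres))
    matched = set()
    for dr, dc in detected_centres:
        best, best_d = None, tol
        for i, (tr, tc) in true:
            if i in matched:
                continue
            d = np.hypot(tr - dr, tc - dc)
            if d < best_d:
                best, best_d = i, d
        if best is not None:
            matched.add(best)
    return matched
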