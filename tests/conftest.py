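import numpy as np
import pytest

from wsiscreen.synthetic_data import CenterStyle, SlideSpec, generate_slide


@pytest.fixture(scope="session")
def cancer_slide_bundle():
    """One deterministic 1024-px cancer slide with annotations and truth raster."""
    spec = SlideSpec("fix_cancer", width=1024, height=1024, label="cancer", seed=424242)
    slide, annotations, label, truth = generate_slide(spec, CenterStyle(), return_truth=True)
    return dict(spec=spec, slide=slide, annotations=annotations, label=label, truth=truth)


@pytest.fixture(scope="session")
def normal_slide_bundle():
    spec = SlideSpec("fix_normal", width=1024, height=1024, label="normal", seed=90125)
    slide, annotations, label, truth = generate_slide(spec, CenterStyle(), return_truth=True)
    return dict(spec=spec, slide=slide, annotations=annotations, label=label, truth=truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
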