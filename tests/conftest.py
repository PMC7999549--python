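import numpy as np
import pandas as pd
import pytest

from muroquant import murolib, synth


@pytest.fixture(scope="session")
def default_library():
    return murolib.build_library(max_order=4, stem_lengths=(3, 4, 5), allow_anhydro=True)


@pytest.fixture(scope="session")
def published_quant():
    """Quant table whose species-level percentages realise the published
    whole-sacculus composition: monomers 45.16 (7.95 of them anhydro),
    dimers 43.29, trimers 10.54, tetramers 1.01."""
    quant = pd.DataFrame(
        {
            "name": ["D44", "M4", "M4N", "Q4444", "T444"],
            "area": [43.29, 37.21, 7.95, 1.01, 10.54],
        }
    )
    quant["molar_percent"] = 100 * quant["area"] / quant["area"].sum()
    return quant


@pytest.fixture(scope="session")
def published_library(published_quant):
    return synth.library_for_quant(published_quant)


@pytest.fixture(scope="session")
def small_cell_population():
    """One rendered image pair with 60 cells, analysed once per session."""
    from muroquant import cells

    pair = synth.gen_cell_images(60, seed=0)
    geoms, longs, shorts, bg = cells.analyze_pair(
        pair.phase, pair.fluor, pair.pixel_size_um
    )
    return pair, geoms, longs, shorts, bg
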