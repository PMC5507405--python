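import numpy as np
import pytest

from dermapattern import network, tracks as tk
from dermapattern.synthetic import TrackGenConfig, gen_tracks


@pytest.fixture(scope="session")
def default_matrix():
    return network.default_matrix()


@pytest.fixture(scope="session")
def default_grouping():
    return network.default_grouping()


def analyze_dataset(seed: int, **cfg_overrides):
    """Generate one synthetic tracking dataset and run the full pipeline.

    Returns (window-record frame, per-track summary frame, rois, truth).
    """
    tdf, rdf, truth = gen_tracks(TrackGenConfig(seed=seed, **cfg_overrides))
    trs = tk.tracks_from_frame(tdf)
    rois = tk.rois_from_frame(rdf)
    wins, summ = tk.analyze_tracks(trs, rois)
    return wins, summ, rois, truth


def two_species_turing_oracle(J: np.ndarray, d: np.ndarray) -> bool:
    """Closed-form Turing conditions for a 2-species system:
    tr J < 0, det J > 0, d2*J11 + d1*J22 > 2*sqrt(d1*d2*det J)."""
    trJ = J[0, 0] + J[1, 1]
    detJ = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    if not (trJ < 0 and detJ > 0):
        return False
    lhs = d[1] * J[0, 0] + d[0] * J[1, 1]
    return bool(lhs > 0 and lhs > 2.0 * np.sqrt(d[0] * d[1] * detJ))
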