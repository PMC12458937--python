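from __future__ import annotations

import pandas as pd
import pytest


@pytest.fixture
def make_series():
    """Build a one-phage/one-strain/one-replicate dilution series frame."""

    def _make(counts, dilutions, volume_ml=0.003, halos=None):
        n = len(counts)
        halos = halos or [False] * n
        return pd.DataFrame(
            {
                "phage": ["HK022"] * n,
                "strain": ["test"] * n,
                "replicate": [1] * n,
                "dilution_factor": dilutions,
                "spot_volume_ml": [volume_ml] * n,
                "plaque_count": [None if h else c for c, h in zip(counts, halos)],
                "is_halo": halos,
                "plaque_radii_mm": [None] * n,
            }
        )

    return _make
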