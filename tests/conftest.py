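import pytest

import raschscale as rs


@pytest.fixture(scope="session")
def ess_table() -> rs.ScoreLogitTable:
    """Packaged ESS calibration: 25 raw scores, logits -4.323..4.265."""
    return rs.load_ess_table()


@pytest.fixture(scope="session")
def ess_published():
    """Published transformed columns for the six reference transformations."""
    return rs.load_ess_published()


@pytest.fixture(scope="session")
def ess_specs(ess_table):
    """The six transformation specs used in the published ESS table."""
    return {
        "user24": rs.TransformSpec.resolve(ess_table, "user", wanted_range=24),
        "user10": rs.TransformSpec.resolve(ess_table, "user", wanted_range=10),
        "user100": rs.TransformSpec.resolve(ess_table, "user", wanted_range=100),
        "lmd": rs.TransformSpec.resolve(ess_table, "lmd"),
        "sem": rs.TransformSpec.resolve(ess_table, "sem"),
        "lsd": rs.TransformSpec.resolve(ess_table, "lsd"),
    }


@pytest.fixture(scope="session")
def ess_like_instrument() -> rs.Instrument:
    """8 items x 4 categories (L = 24), evenly spread locations/thresholds."""
    return rs.generate_instrument(rs.SimulationConfig())
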