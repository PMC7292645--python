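import pytest

from sacquant.synthetic import generate_sector_plate, match_records_to_truth  # noqa: F401


def make_sector_plate(n_colonies, fractions, seed, image_size=512, radius=10.0, min_sep=30.0):
    return generate_sector_plate(
        n_colonies, fractions, seed, image_size=image_size, radius=radius, min_sep=min_sep
    )


@pytest.fixture
def small_plate():
    """50 colonies, 10% loss events, deterministic."""
    from sacquant.synthetic import generate_plate

    return generate_plate(50, loss_fraction=0.1, seed=7, image_size=512)
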