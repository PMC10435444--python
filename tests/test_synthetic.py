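"""Synthetic generator: monotone water signal, separability, determinism,
design arithmetic (blocks, references, dates)."""

import numpy as np
import pytest

from vinespec.filtering import cosine_similarity
from vinespec.sensors import SENSOR_1, SENSOR_2
from vinespec.synthetic import (
    INTERFERENCE_CLASSES,
    SceneMix,
    default_layout,
    default_water_model,
    make_interference,
    make_leaf_reflectance,
    reference_leaf_signature,
    simulate_campaign,
    simulate_pass,
)


def test_wetter_leaf_absorbs_more_at_1454nm():
    wet = make_leaf_reflectance(-0.5, SENSOR_2, noise_sd=0.0, scatter=(1.0, 0.0))
    dry = make_leaf_reflectance(-2.0, SENSOR_2, noise_sd=0.0, scatter=(1.0, 0.0))
    ch = wet.channel_nearest(1454.0)
    assert wet.values[ch] < dry.values[ch]


def test_band_depth_strictly_monotone_in_psi():
    psis = np.linspace(-2.2, -0.3, 40)
    depths = []
    for psi in psis:
        s = make_leaf_reflectance(psi, SENSOR_2, noise_sd=0.0, scatter=(1.0, 0.0))
        ch = s.channel_nearest(1454.0)
        # depth relative to a nearby off-band shoulder
        depths.append(s.values[s.channel_nearest(1286.0)] - s.values[ch])
    assert np.all(np.diff(depths) > 0)  # deeper band as psi rises toward 0


def test_leaf_generation_is_deterministic_under_seed():
    a = make_leaf_reflectance(-1.2, SENSOR_2, noise_sd=0.01, rng_seed=7)
    b = make_leaf_reflectance(-1.2, SENSOR_2, noise_sd=0.01, rng_seed=7)
    np.testing.assert_array_equal(a.values, b.values)


def test_sensor1_spectrum_has_501_channels():
    s = make_leaf_reflectance(-1.13, SENSOR_1, noise_sd=0.0)
    assert len(s) == 501
    assert s.wavelengths[0] == 1100.0 and s.wavelengths[-1] == 2100.0


def test_psi_domain_errors():
    with pytest.raises(ValueError):
        make_leaf_reflectance(0.5, SENSOR_2)
    with pytest.raises(ValueError):
        make_leaf_reflectance(-3.0, SENSOR_2)


@pytest.mark.parametrize("kind", INTERFERENCE_CLASSES)
def test_interference_fails_cosine_screen(kind, sensor):
    leaf = make_leaf_reflectance(-1.0, sensor, noise_sd=0.0, scatter=(1.0, 0.0))
    interf = make_interference(kind, sensor, rng_seed=3)
    assert cosine_similarity(interf, leaf) < 0.985


def test_sky_gap_is_bright_and_flat():
    s = make_interference("sky_gap", SENSOR_2, rng_seed=0)
    assert s.values.min() > 0.8
    ch_in = s.values[s.channel_nearest(1454.0)]
    ch_out = s.values[s.channel_nearest(1286.0)]
    assert abs(ch_out - ch_in) < 0.05  # no water dip


def test_leaf_and_interference_cosines_straddle_threshold(sensor, rng):
    """Separability: the two similarity populations are disjoint around 0.985."""
    signature = reference_leaf_signature(sensor)
    leaf_cos = [
        cosine_similarity(make_leaf_reflectance(psi, sensor, rng_seed=rng), signature)
        for psi in np.linspace(-2.2, -0.3, 15)
    ]
    interf_cos = [
        cosine_similarity(make_interference(k, sensor, rng_seed=rng), signature)
        for k in INTERFERENCE_CLASSES
        for _ in range(5)
    ]
    assert min(leaf_cos) > 0.985 > max(interf_cos)


def test_pass_reference_counts_match_design():
    model = default_water_model()
    mix = SceneMix()
    # 12 blocks x 3 groups -> 36 references per date
    p12 = simulate_pass(default_layout(n_replicates=4), model, mix, rng_seed=1)
    assert len(p12.references) == 36
    # 9 blocks (3 replicates) -> 27 references per date
    p9 = simulate_pass(default_layout(n_replicates=3), model, mix, rng_seed=1)
    assert len(p9.references) == 27


def test_pass_frame_count_follows_row_geometry():
    layout = default_layout()
    p = simulate_pass(layout, default_water_model(), SceneMix(), rng_seed=0)
    row_seconds = layout.row_length_m / (3.0 / 3.6)
    expected = int(round(row_seconds * SENSOR_2.rate_hz)) * len(layout.blocks)
    assert len(p.frames) == expected


def test_pass_gps_points_lie_inside_block_polygons():
    from shapely.geometry import Point

    layout = default_layout()
    p = simulate_pass(layout, default_water_model(), SceneMix(), rng_seed=2)
    proj = layout.projection
    hits = 0
    for _, g in p.gps_feed[:: 50]:
        x, y = proj.to_xy(g.lon, g.lat)
        if any(b.polygon.intersects(Point(float(x), float(y))) for b in layout.blocks):
            hits += 1
    assert hits == len(p.gps_feed[::50])


def test_pass_rejects_unknown_date():
    with pytest.raises(KeyError):
        simulate_pass(default_layout(), default_water_model(), SceneMix(), date="1999-01-01")


def test_campaign_design_arithmetic_and_drying_trend():
    c = simulate_campaign(seed=5)
    refs = c.references
    assert len(refs) == 216  # 6 dates x 12 blocks x 3 groups
    assert (refs.psi_mpa <= 0).all()
    assert refs.psi_mpa.min() >= c.model.psi_floor
    t2 = refs[refs.treatment == "T2"].groupby("date").psi_mpa.mean().sort_index()
    assert t2.iloc[-1] < t2.iloc[0]  # unirrigated vines dry down over the season


def test_campaign_reruns_bit_identically():
    a = simulate_campaign(seed=9)
    b = simulate_campaign(seed=9)
    assert a.checksum() == b.checksum()
    assert a.manifest == b.manifest
    c = simulate_campaign(seed=10)
    assert c.checksum() != a.checksum()


def test_campaign_requires_two_dates():
    with pytest.raises(ValueError):
        simulate_campaign(dates=["2021-07-07"])
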