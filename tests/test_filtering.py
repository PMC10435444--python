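"""Cosine screening: metric identities, brute-force oracle equivalence,
block allocation and averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vinespec.filtering import (
    BlockAssignment,
    FilterConfig,
    assign_blocks,
    block_average,
    cosine_similarity,
    filter_stream,
)
from vinespec.sensors import SENSOR_2
from vinespec.spectra import GeoPoint, Spectrum
from vinespec.synthetic import (
    SceneMix,
    default_layout,
    default_water_model,
    make_interference,
    make_leaf_reflectance,
    simulate_pass,
)

WL2 = np.array([1.0, 2.0])


def _s(values, wl=None, **kw):
    v = np.asarray(values, float)
    return Spectrum(wl if wl is not None else np.arange(v.size, dtype=float), v, **kw)


def test_cosine_identities():
    a = _s([1.0, 2.0, 3.0])
    assert cosine_similarity(a, a) == pytest.approx(1.0)
    assert cosine_similarity(_s([1, 0]), _s([0, 1])) == pytest.approx(0.0)
    assert cosine_similarity(a, _s(2 * a.values)) == pytest.approx(1.0)


def test_cosine_errors():
    with pytest.raises(ValueError):
        cosine_similarity(_s([0.0, 0.0]), _s([1.0, 1.0]))
    with pytest.raises(ValueError):
        cosine_similarity(_s([1.0, 1.0]), _s([1.0, 1.0, 1.0]))


@settings(max_examples=30, deadline=None)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_filter_decision_scale_invariant(scale):
    sig = _s(np.sin(np.linspace(0, 3, 20)) + 2)
    frame = _s((np.sin(np.linspace(0, 3, 20)) + 2) * scale)
    acc, rej = filter_stream([frame], sig, FilterConfig(threshold=0.9999))
    assert len(acc) == 1 and len(rej) == 0


def test_boundary_cosine_equal_to_threshold_is_accepted():
    sig = _s([1.0, 0.0])
    # 3-4-5 triangle: cosine(frame, sig) = 3/5 = 0.6 exactly in floats
    frame = _s([3.0, 4.0])
    acc, rej = filter_stream([frame], sig, FilterConfig(threshold=0.6))
    assert len(acc) == 1


def test_threshold_one_rejects_near_duplicates():
    sig = _s([1.0, 2.0, 3.0])
    frame = _s([1.0, 2.0, 3.1])
    acc, _ = filter_stream([frame], sig, FilterConfig(threshold=1.0))
    assert len(acc) == 0


def test_threshold_near_zero_accepts_all_nonnegative_spectra(rng):
    sig = _s(rng.uniform(0.1, 1, 30))
    frames = [_s(rng.uniform(0.0, 1, 30) + 1e-6) for _ in range(20)]
    acc, rej = filter_stream(frames, sig, FilterConfig(threshold=1e-9))
    assert len(acc) == 20 and not rej


def test_filter_matches_brute_force_oracle_on_mixed_stream(rng):
    """1000 mixed leaf/interference frames: the streaming filter must agree
    with an independent per-frame cosine computation, and the partition must
    conserve the frame count and preserve order."""
    sensor = SENSOR_2
    signature = make_leaf_reflectance(-1.0, sensor, noise_sd=0.0, scatter=(1.0, 0.0))
    kinds = ["leaf"] * 700 + ["sky_gap", "wood", "wire", "pipe", "berry"] * 60
    rng.shuffle(kinds)
    frames = []
    for i, k in enumerate(kinds[:1000]):
        if k == "leaf":
            s = make_leaf_reflectance(float(rng.uniform(-2.2, -0.3)), sensor, rng_seed=rng)
        else:
            s = make_interference(k, sensor, rng_seed=rng)
        s.meta["i"] = i
        frames.append(s)
    cfg = FilterConfig(threshold=0.985)
    acc, rej = filter_stream(frames, signature, cfg)
    # independent oracle: plain numpy cosine per frame
    sig = signature.values
    expect = [
        f.values @ sig / (np.linalg.norm(f.values) * np.linalg.norm(sig)) >= cfg.threshold
        for f in frames
    ]
    assert len(acc) + len(rej) == 1000
    assert [f.meta["i"] for f in acc] == [i for i, e in enumerate(expect) if e]
    assert [f.meta["i"] for f in rej] == [i for i, e in enumerate(expect) if not e]
    assert [f.meta["i"] for f in acc] == sorted(f.meta["i"] for f in acc)  # order kept


def test_signature_copies_plus_interference_counts():
    sensor = SENSOR_2
    signature = make_leaf_reflectance(-1.0, sensor, noise_sd=0.0, scatter=(1.0, 0.0))
    frames = [signature] * 10 + [make_interference(k, sensor, rng_seed=1) for k in ("wood", "wire", "berry")]
    acc, rej = filter_stream(frames, signature, FilterConfig(threshold=0.985))
    assert len(acc) == 10 and len(rej) == 3


def test_assign_blocks_centroid_and_outside_point():
    layout = default_layout()
    proj = layout.projection
    blk = layout.blocks[3]
    cx, cy = blk.polygon.centroid.x, blk.polygon.centroid.y
    lon, lat = proj.to_lonlat(cx, cy)
    inside = _s(np.ones(4), wl=np.arange(4.0), geo=GeoPoint(float(lon), float(lat)))
    lon_out, lat_out = proj.to_lonlat(-500.0, -500.0)
    outside = _s(np.ones(4), wl=np.arange(4.0), geo=GeoPoint(float(lon_out), float(lat_out)))
    assignments, dropped = assign_blocks([inside, outside], layout)
    by_id = {a.block_id: a for a in assignments}
    assert len(by_id[blk.block_id].spectra) == 1
    assert dropped == 1


def test_full_pass_fills_every_block():
    layout = default_layout()
    p = simulate_pass(layout, default_water_model(), SceneMix(), rng_seed=6)
    from vinespec.acquisition import run_session

    session = run_session(p.frames, p.dark, p.white, p.signature_raw, gps_feed=p.gps_feed)
    assignments, dropped = assign_blocks(session.accepted, layout)
    assert all(len(a.spectra) > 0 for a in assignments)
    assert sum(len(a.spectra) for a in assignments) + dropped == len(session.accepted)


def test_block_average_cases():
    wl = np.arange(5.0)
    a = BlockAssignment("B01", "T0", [_s([0, 0, 0, 0, 0.0], wl=wl), _s([1, 1, 1, 1, 1.0], wl=wl)])
    mean = block_average(a)
    np.testing.assert_allclose(mean.values, 0.5)
    assert mean.meta["n_averaged"] == 2
    same = BlockAssignment("B02", "T1", [_s([2, 3, 4, 5, 6.0], wl=wl)] * 4)
    np.testing.assert_allclose(block_average(same).values, [2, 3, 4, 5, 6.0])
    with pytest.raises(ValueError, match="B03"):
        block_average(BlockAssignment("B03", "T2", []))
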