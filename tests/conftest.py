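"""Shared fixtures: small seeded scenes so every stage can be scored
against exact ground truth without any stored data."""

from __future__ import annotations

import numpy as np
import pytest

from mitospim import detect as det
from mitospim import dynamics as dyn
from mitospim import synthetic as syn


def psnr(x: np.ndarray, ref: np.ndarray) -> float:
    return float(10 * np.log10(ref.max() ** 2 / np.mean((x - ref) ** 2)))


def small_scene(seed: int = 0, **kw) -> syn.SceneSpec:
    """A spheroid small enough for per-test rendering (~25 nuclei)."""
    defaults = dict(
        spheroid_radius_um=22.0,
        volume_shape_vox=(64, 96, 96),
        n_nuclei=25,
        margin_um=5.0,
        seed=seed,
    )
    defaults.update(kw)
    return syn.SceneSpec(**defaults)


NOISE_FREE = syn.OpticsSpec(photon_scale=0.0, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def tiny_truth():
    spec = small_scene(seed=3)
    return spec, syn.place_nuclei(spec)


@pytest.fixture(scope="session")
def rendered_scene(tiny_truth):
    spec, truth = tiny_truth
    vol = syn.render_volume(truth, spec, syn.OpticsSpec(), seed=3)
    return spec, truth, vol


def detect_pipeline(vol, params=None, thresholds=None):
    params = params or det.DetectParams()
    thresholds = thresholds or det.ClassifyThresholds()
    dets = det.detect_nuclei(vol, params)
    dets, labels = det.segment_and_measure(vol, dets, params)
    dets = det.classify_mitotic(dets, thresholds)
    return dets, labels


def two_arm_movie(seed: int, paclitaxel: bool, n_frames: int = 24,
                  entries=(1, 2)):
    """Render one arm of the division experiment and extract its events."""
    spec = small_scene(seed=seed, mitotic_fraction=0.0)
    truth0 = syn.place_nuclei(spec)
    rim = [
        n.id
        for n in truth0.nuclei
        if n.labeled and truth0.depth_of(n.id) <= spec.rim_thickness_um
    ]
    events = tuple((nid, f) for nid, f in zip(rim[:2], entries))
    tl = syn.TimelapseSpec(
        n_frames=n_frames, division_events=events, paclitaxel_mode=paclitaxel,
        seed=seed,
    )
    vols, truth = syn.render_timelapse(spec, syn.OpticsSpec(), None, tl)
    per_frame = [detect_pipeline(v)[0] for v in vols]
    tracks = dyn.link_tracks(per_frame)
    evs = dyn.extract_mitotic_events(tracks, tl.frame_interval_min)
    by_id = {t.track_id: t for t in tracks}
    for e in evs:
        t = by_id[e.track_id]
        end = e.exit_frame if e.exit_frame is not None else t.end + 1
        masses = {
            p.frame: dyn.chromosome_mass_from_volume(
                vols[p.frame], p.centroid_um, spec.nucleus_radius_um
            )
            for p in t.points
            if e.entry_frame <= p.frame < end and p.klass == det.MITOTIC
        }
        dyn.alignment_score(e, masses)
    return evs, truth, tracks, vols
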