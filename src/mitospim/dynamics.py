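"""Tracking of nuclei across time and scoring of mitotic dynamics.

Detections are linked frame-to-frame by greedy nearest-neighbor
assignment under a distance gate, with short gaps bridged; a mitotic
track succeeded by two fresh interphase tracks within the gate is a
division, and the new tracks become its daughters. Maximal runs of
mitotic classification delimit mitotic events, whose duration comes from
the frame interval; an event still mitotic at the end of the movie is
censored unless it has already lasted past the arrest threshold (60 min
by default — the horizon over which paclitaxel-blocked cells were
observed stuck in mitosis), in which case it is scored as arrested.
Metaphase-plate formation is detected from the planarity of the
chromosome mass (smallest-to-middle eigenvalue ratio of its second
moments): arrested chromosomes jitter as a ball and never flatten.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import mannwhitneyu

from .detect import Detection, INTERPHASE, MITOTIC
from .volume import ImageVolume

COMPLETED = "completed"
ARRESTED = "arrested"
CENSORED = "censored"


@dataclass
class TrackPoint:
    frame: int
    det_id: int | None          # None for a bridged gap
    centroid_um: np.ndarray
    klass: str | None


@dataclass
class Track:
    track_id: int
    points: list[TrackPoint] = field(default_factory=list)
    parent_id: int | None = None
    child_ids: tuple[int, int] | None = None

    @property
    def start(self) -> int:
        return self.points[0].frame

    @property
    def end(self) -> int:
        return self.points[-1].frame

    def klass_at(self, frame: int) -> str | None:
        for p in self.points:
            if p.frame == frame:
                return p.klass
        return None


@dataclass
class MitoticEvent:
    track_id: int
    entry_frame: int
    exit_frame: int | None
    duration_min: float
    outcome: str                      # completed | arrested | censored
    aligned: bool | None = None
    alignment: float | None = None    # min planarity ratio over the event
    daughter_track_ids: tuple[int, int] | None = None


# --------------------------------------------------------------------------
# Linking


def link_tracks(
    per_frame_detections: list[list[Detection]],
    gate_um: float = 10.0,
    max_gap: int = 1,
) -> list[Track]:
    """Greedy nearest-neighbor linking with gap bridging and division
    detection.

    Each frame's detections are assigned to open tracks in ascending
    distance order (ties by smallest detection id) under the gate;
    leftovers start new tracks; a track missing for more than
    ``max_gap`` frames closes. Two division-specific rules: an
    unassigned *mitotic* detection within the gate of a track that is
    mitotic this frame is an anaphase twin mass of that same cell and
    is suppressed rather than starting a track of its own; and a
    mitotic track succeeded by two fresh interphase tracks within the
    gate becomes their parent (whether the linker continued into one
    daughter or stopped at the division).
    """
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    for frame, dets in enumerate(per_frame_detections):
        ids = [d.id for d in dets]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate detection ids in frame {frame}")
        # drop tracks that have been silent too long
        open_tracks = [t for t in open_tracks if frame - t.end <= max_gap + 1]

        cand = []
        for ti, t in enumerate(open_tracks):
            last = t.points[-1].centroid_um
            for d in dets:
                dist = float(np.linalg.norm(d.centroid_um - last))
                if dist <= gate_um:
                    cand.append((dist, d.id, ti, d))
        cand.sort(key=lambda c: (c[0], c[1]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, did, ti, d in cand:
            if ti in used_tracks or did in used_dets:
                continue
            used_tracks.add(ti)
            used_dets.add(did)
            t = open_tracks[ti]
            # bridge skipped frames by linear interpolation
            last = t.points[-1]
            for g in range(last.frame + 1, frame):
                frac = (g - last.frame) / (frame - last.frame)
                c = last.centroid_um + frac * (d.centroid_um - last.centroid_um)
                t.points.append(TrackPoint(g, None, c, last.klass))
            t.points.append(TrackPoint(frame, d.id, d.centroid_um, d.klass))
        for d in dets:
            if d.id in used_dets:
                continue
            if d.klass == MITOTIC and any(
                t.end == frame
                and t.points[-1].klass == MITOTIC
                and np.linalg.norm(d.centroid_um - t.points[-1].centroid_um) <= gate_um
                for t in open_tracks
            ):
                # separating anaphase chromosome mass of an existing
                # mitotic cell, not a new nucleus
                continue
            t = Track(track_id=len(tracks))
            t.points.append(TrackPoint(frame, d.id, d.centroid_um, d.klass))
            tracks.append(t)
            open_tracks.append(t)

    _split_divisions(tracks, gate_um)
    _link_daughters(tracks, gate_um, max_gap)
    return tracks


def _split_divisions(tracks: list[Track], gate_um: float) -> None:
    """Split tracks the greedy linker continued through a division.

    When a mitotic track transitions to interphase at the same frame a
    fresh interphase track starts nearby, the continuation is really one
    of the two daughters: the track is cut at the transition and the
    tail becomes a new track, so daughter linking sees two births.
    """
    for t in list(tracks):
        cut = None
        for i in range(len(t.points) - 1):
            if t.points[i].klass == MITOTIC and t.points[i + 1].klass == INTERPHASE:
                cut = i
                break
        if cut is None:
            continue
        birth_frame = t.points[cut + 1].frame
        pos = t.points[cut].centroid_um
        sibling = any(
            s.track_id != t.track_id
            and s.parent_id is None
            and s.start == birth_frame
            and s.points[0].klass != MITOTIC
            and np.linalg.norm(s.points[0].centroid_um - pos) <= 2 * gate_um
            for s in tracks
        )
        if not sibling:
            continue
        tail = Track(track_id=len(tracks), points=t.points[cut + 1:])
        t.points = t.points[: cut + 1]
        tracks.append(tail)


def _link_daughters(tracks: list[Track], gate_um: float, max_gap: int) -> None:
    for t in tracks:
        if t.points[-1].klass != MITOTIC:
            continue
        end = t.end
        last_pos = t.points[-1].centroid_um
        cands = []
        for s in tracks:
            if s.track_id == t.track_id or s.parent_id is not None:
                continue
            if not (end < s.start <= end + max_gap + 1):
                continue
            if s.points[0].klass == MITOTIC:
                continue
            dist = float(np.linalg.norm(s.points[0].centroid_um - last_pos))
            if dist <= 2 * gate_um:
                cands.append((dist, s.track_id, s))
        if len(cands) >= 2:
            cands.sort(key=lambda c: (c[0], c[1]))
            d1, d2 = cands[0][2], cands[1][2]
            d1.parent_id = d2.parent_id = t.track_id
            t.child_ids = (d1.track_id, d2.track_id)


# --------------------------------------------------------------------------
# Event extraction


def extract_mitotic_events(
    tracks: list[Track],
    frame_interval_min: float,
    arrest_threshold_min: float = 60.0,
    min_run_frames: int = 2,
) -> list[MitoticEvent]:
    """Delimit mitotic events and score their outcome.

    Entry is the first frame of a maximal mitotic run (runs shorter
    than ``min_run_frames`` are discarded as classification flicker).
    Exit is the first frame with daughters (completed); a run that
    reaches the end of the movie is censored, or arrested once its
    observed duration passes ``arrest_threshold_min``. A reversion to
    interphase without detected daughters has an ambiguous fate and is
    scored censored at the reversion frame.
    """
    if frame_interval_min is None or frame_interval_min <= 0:
        raise ValueError("frame interval must be a positive number of minutes")
    by_id = {t.track_id: t for t in tracks}
    events: list[MitoticEvent] = []
    for t in tracks:
        frames = [p.frame for p in t.points]
        mito = [p.klass == MITOTIC for p in t.points]
        i = 0
        while i < len(t.points):
            if not mito[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(t.points) and mito[j + 1]:
                j += 1
            run_len = j - i + 1
            entry, last = frames[i], frames[j]
            if run_len >= min_run_frames:
                events.append(
                    _score_run(t, entry, last, j == len(t.points) - 1,
                               frame_interval_min, arrest_threshold_min, by_id)
                )
            i = j + 1
    return events


def _score_run(
    t: Track,
    entry: int,
    last_mitotic: int,
    at_track_end: bool,
    interval: float,
    arrest_threshold: float,
    by_id: dict[int, Track],
) -> MitoticEvent:
    daughters = None
    if t.child_ids is not None:
        d1 = by_id[t.child_ids[0]]
        birth = d1.start
        if birth > entry:
            daughters = t.child_ids
    if at_track_end and daughters is not None:
        exit_frame = by_id[daughters[0]].start
        return MitoticEvent(
            t.track_id, entry, exit_frame,
            (exit_frame - entry) * interval, COMPLETED,
            daughter_track_ids=daughters,
        )
    if at_track_end:
        observed = (last_mitotic - entry) * interval
        outcome = ARRESTED if observed >= arrest_threshold else CENSORED
        return MitoticEvent(t.track_id, entry, None, observed, outcome)
    # reversion to interphase without daughters: ambiguous fate
    exit_frame = last_mitotic + 1
    return MitoticEvent(
        t.track_id, entry, exit_frame, (exit_frame - entry) * interval, CENSORED
    )


# --------------------------------------------------------------------------
# Metaphase-plate alignment


def mass_planarity(points_um: np.ndarray, weights: np.ndarray) -> float | None:
    """Smallest-to-middle eigenvalue ratio of the weighted second-moment
    tensor; ~0 for a flat plate, ~1 for a ball. None when degenerate."""
    if points_um.shape[0] < 8 or weights.sum() <= 0:
        return None
    mu = np.average(points_um, axis=0, weights=weights)
    d = points_um - mu
    cov = (weights[:, None] * d).T @ d / weights.sum()
    ev = np.linalg.eigvalsh(cov)
    if ev[1] <= 0:
        return None
    return float(ev[0] / ev[1])


def chromosome_mass_from_volume(
    vol: ImageVolume, center_um: np.ndarray, radius_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel positions and weights of the chromosome mass around a
    tracked cell: voxels above half the local maximum in a window of
    ``2 * radius_um``, restricted to the connected component containing
    the cell (neighboring nuclei clipping into the window would
    otherwise distort the moments)."""
    spacing = np.array(vol.spacing_zyx)
    c = np.asarray(center_um, dtype=float)
    lo = np.maximum(np.floor((c - 2 * radius_um) / spacing).astype(int), 0)
    hi = np.minimum(
        np.ceil((c + 2 * radius_um) / spacing).astype(int) + 1, np.array(vol.shape)
    )
    sub = vol.data[tuple(slice(l, h) for l, h in zip(lo, hi))]
    if sub.size == 0 or sub.max() <= 0:
        return np.empty((0, 3)), np.empty(0)
    thr = 0.5 * sub.max()
    sel = sub >= thr
    comps, n = ndimage.label(sel)
    if n > 1:
        cidx = np.clip(np.round(c / spacing).astype(int) - lo, 0, np.array(sub.shape) - 1)
        own = comps[tuple(cidx)]
        if own == 0:
            # center fell just outside the mask: take the component of
            # the nearest above-threshold voxel
            cand = np.argwhere(sel)
            own = comps[tuple(cand[np.linalg.norm((cand - cidx) * spacing, axis=1).argmin()])]
        sel = comps == own
    coords = (np.argwhere(sel) + lo) * spacing
    return coords, sub[sel] - thr


def alignment_score(
    event: MitoticEvent,
    masses: dict[int, tuple[np.ndarray, np.ndarray]],
    plate_threshold: float = 0.35,
    min_consecutive: int = 2,
) -> MitoticEvent:
    """Set the event's aligned flag from per-frame chromosome masses.

    ``masses`` maps frame -> (points_um, weights). The event is aligned
    when the planarity ratio stays below ``plate_threshold`` for at
    least ``min_consecutive`` consecutive frames; the score is the
    minimum ratio observed. With no usable frame the score is censored
    (``aligned=None``).
    """
    ratios: list[tuple[int, float | None]] = []
    for frame in sorted(masses):
        pts, w = masses[frame]
        ratios.append((frame, mass_planarity(pts, w)))
    valid = [r for _, r in ratios if r is not None]
    if not valid:
        event.aligned = None
        event.alignment = None
        return event
    event.alignment = float(min(valid))
    run = best_run = 0
    prev_frame = None
    for frame, r in ratios:
        flat = r is not None and r < plate_threshold
        contiguous = prev_frame is None or frame == prev_frame + 1
        run = run + 1 if (flat and contiguous) else (1 if flat else 0)
        best_run = max(best_run, run)
        prev_frame = frame
    event.aligned = best_run >= min_consecutive
    return event


# --------------------------------------------------------------------------
# Condition comparison


def compare_conditions(
    events_control: list[MitoticEvent],
    events_treated: list[MitoticEvent],
) -> dict:
    """Two-arm summary: counts, durations, arrest and alignment
    fractions, and a Mann-Whitney rank test on observed durations
    (arrested durations enter as observed lower bounds)."""
    if not events_control or not events_treated:
        raise ValueError("both arms need at least one event")

    def arm(events: list[MitoticEvent]) -> dict:
        completed = [e for e in events if e.outcome == COMPLETED]
        arrested = [e for e in events if e.outcome == ARRESTED]
        censored = [e for e in events if e.outcome == CENSORED]
        aligned_known = [e.aligned for e in events if e.aligned is not None]
        durs = [e.duration_min for e in completed]
        out = {
            "n_events": len(events),
            "n_completed": len(completed),
            "n_arrested": len(arrested),
            "n_censored": len(censored),
            "arrested_fraction": len(arrested) / len(events),
            "aligned_fraction": (
                float(np.mean(aligned_known)) if aligned_known else None
            ),
            "median_completed_duration_min": (
                float(np.median(durs)) if durs else None
            ),
        }
        if not durs and (arrested or censored):
            bounds = [e.duration_min for e in arrested + censored]
            out["median_duration_lower_bound_min"] = float(np.median(bounds))
            out["all_durations_censored"] = True
        return out

    def observed(events: list[MitoticEvent]) -> list[float]:
        return [e.duration_min for e in events if e.outcome in (COMPLETED, ARRESTED)]

    summary = {"control": arm(events_control), "treated": arm(events_treated)}
    dc, dt = observed(events_control), observed(events_treated)
    if dc and dt and (len(set(dc + dt)) > 1):
        stat, p = mannwhitneyu(dt, dc, alternative="greater")
        summary["duration_test"] = {
            "statistic": float(stat),
            "p_value": float(p),
            "test": "Mann-Whitney U, treated > control",
        }
    else:
        summary["duration_test"] = None
    summary["arrested_fraction_difference"] = (
        summary["treated"]["arrested_fraction"] - summary["control"]["arrested_fraction"]
    )
    return summary
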