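"""Seeded synthetic SPIM stacks of H2B-labelled spheroids with ground truth.

The forward model emulates a single-plane illumination microscope imaging
a multicellular tumor spheroid whose nuclei carry a histone-fluorescent
reporter: nuclei are Gaussian blobs (condensed mitotic chromosomes are
brighter, elongated masses), the light sheet is attenuated exponentially
along its propagation axis ``x`` by scattering/absorption in the tissue,
detection blur grows with depth along ``z``, photon shot noise and camera
read noise corrupt the signal, and sample-dependent horizontal stripes —
white noise convolved with an elongated stripe pattern — add on top.
Every random quantity is a pure function of the specs and their seeds, and
everything injected (nucleus positions/classes, per-frame states, drift,
stripe fields, clean volumes) is recorded so that downstream stages can be
scored against exact truth.

Coordinates: arrays are ``(z, y, x)``; physical positions are kept in the
same order, with the voxel-center of index ``i`` at ``i * spacing``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as spsignal

from .kernels import stripe_kernel
from .volume import DEFAULT_VOXEL_SIZE_UM, ImageVolume

# Peak intensity of an interphase nucleus on the [0, 1] scale, before
# attenuation and noise. Mitotic peaks are this times the mitotic gain.
INTERPHASE_PEAK = 0.4

# Shape constants: interphase blob sigma as a fraction of the nucleus
# radius; condensed chromosome mass is narrower and prolate.
_INTERPHASE_SIGMA_FRAC = 0.5
_CONDENSED_SIGMA_FRAC = 0.35
_CONDENSED_AXIS_RATIO = 2.5
_PLATE_FLAT_FRAC = 0.18      # metaphase plate thickness (fraction of radius)
_PLATE_WIDE_FRAC = 0.6       # metaphase plate lateral extent
_PACLITAXEL_JITTER_UM = 0.8  # per-frame centroid jitter of arrested chromosomes

INTERPHASE = "interphase"
MITOTIC = "mitotic"
CONDENSED = "condensed"
METAPHASE = "metaphase"
ANAPHASE = "anaphase"
DAUGHTER = "daughter"


# --------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class SceneSpec:
    """Static geometry and population of a synthetic spheroid."""

    spheroid_radius_um: float = 50.0
    nucleus_radius_um: float = 4.5
    min_separation_um: float = 9.0
    labeled_fraction: float = 0.5
    mitotic_fraction: float = 0.25
    rim_thickness_um: float = 15.0
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    volume_shape_vox: tuple[int, int, int] = (128, 192, 192)  # (z, y, x)
    n_nuclei: int = 180
    margin_um: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.labeled_fraction <= 1 and 0 <= self.mitotic_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.rim_thickness_um > self.spheroid_radius_um:
            raise ValueError("rim_thickness_um must not exceed spheroid_radius_um")
        if self.min_separation_um < self.nucleus_radius_um:
            raise ValueError("min_separation_um must be >= nucleus_radius_um")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be positive")
        extent = self.extent_um
        needed = 2 * (self.spheroid_radius_um + self.margin_um)
        for ax, size in zip("zyx", extent):
            if size < needed:
                raise ValueError(
                    f"volume extent along {ax} is {size:.1f} um but the spheroid "
                    f"plus margin needs {needed:.1f} um"
                )

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        vx, vy, vz = self.voxel_size_um
        return (vz, vy, vx)

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.volume_shape_vox, self.spacing_zyx))

    @property
    def center_um(self) -> np.ndarray:
        return np.array([0.5 * e for e in self.extent_um])


@dataclass(frozen=True)
class OpticsSpec:
    """Optical transfer of the simulated SPIM.

    ``attenuation_length_um`` is the 1/e decay length of the light sheet
    inside the spheroid (the progressive signal loss along ``x``);
    ``blur_sigma0_um`` + ``blur_growth_per_um * depth`` is the in-plane
    detection blur at tissue depth ``depth`` along ``z``; ``mitotic_gain``
    is the peak-brightness factor of condensed chromosomes over interphase
    chromatin; shot noise is Poisson at ``photon_scale`` photons per unit
    intensity with additive Gaussian read noise.
    """

    attenuation_length_um: float = 150.0
    blur_sigma0_um: float = 1.0
    blur_growth_per_um: float = 0.01
    mitotic_gain: float = 2.0
    photon_scale: float = 2000.0
    read_noise_sd: float = 0.01

    def validate(self) -> None:
        if not self.attenuation_length_um > 0:
            raise ValueError("attenuation_length_um must be > 0")
        if self.blur_sigma0_um < 0 or self.blur_growth_per_um < 0:
            raise ValueError("blur parameters must be >= 0")
        if self.mitotic_gain < 1:
            raise ValueError("mitotic_gain must be >= 1")


@dataclass(frozen=True)
class StripeSpec:
    """Stationary stripe noise: sparse white noise convolved with an
    elongated elementary pattern running along the illumination axis."""

    psi_sigma_along_um: float = 30.0
    psi_sigma_across_um: float = 1.0
    noise_density: float = 0.05
    noise_sd: float = 0.5
    per_slice: bool = True

    def validate(self) -> None:
        if not self.psi_sigma_along_um > self.psi_sigma_across_um:
            raise ValueError("stripes must be elongated: sigma_along > sigma_across")
        if not (0 <= self.noise_density <= 1):
            raise ValueError("noise_density must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TimelapseSpec:
    """Time-lapse acquisition and division dynamics."""

    n_frames: int = 20
    frame_interval_min: float = 3.0
    drift_per_frame_um: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (z, y, x)
    mitosis_duration_min: float = 45.0
    division_events: tuple[tuple[int, int], ...] = ()  # (nucleus id, entry frame)
    paclitaxel_mode: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        for nid, entry in self.division_events:
            if not (0 <= entry < self.n_frames):
                raise ValueError(f"division entry frame {entry} outside movie")


# --------------------------------------------------------------------------
# Truth containers


@dataclass
class Nucleus:
    id: int
    center_um: np.ndarray  # (z, y, x)
    klass: str             # interphase | mitotic
    labeled: bool
    orientation: np.ndarray | None = None  # spindle/long axis unit vector (z, y, x)


@dataclass
class NucleusState:
    state: str                # interphase|condensed|metaphase|anaphase|daughter
    center_um: np.ndarray     # (z, y, x), drift included
    separation_um: float = 0.0  # anaphase mass separation (center to center)
    orientation: np.ndarray | None = None


@dataclass
class FrameTruth:
    frame: int
    time_min: float
    drift_um: np.ndarray                     # cumulative (z, y, x)
    states: dict[int, NucleusState]
    clean: np.ndarray | None = None          # rendered, noise included, stripe-free
    stripe: np.ndarray | None = None         # injected stripe field b
    lam: np.ndarray | None = None            # stripe noise coefficients


@dataclass
class SceneTruth:
    """Ground truth of a synthetic scene (static or time-lapse)."""

    nuclei: list[Nucleus]
    spheroid_center_um: np.ndarray
    spheroid_radius_um: float
    frames: list[FrameTruth] = field(default_factory=list)
    daughters: dict[int, tuple[int, int]] = field(default_factory=dict)  # parent -> ids
    skipped_events: list[tuple[int, int, str]] = field(default_factory=list)

    def by_id(self, nid: int) -> Nucleus:
        for n in self.nuclei:
            if n.id == nid:
                return n
        raise KeyError(nid)

    @property
    def mitotic_ids(self) -> list[int]:
        return [n.id for n in self.nuclei if n.klass == MITOTIC]

    def depth_of(self, nid: int) -> float:
        n = self.by_id(nid)
        return self.spheroid_radius_um - float(
            np.linalg.norm(n.center_um - self.spheroid_center_um)
        )


# --------------------------------------------------------------------------
# Placement


def place_nuclei(spec: SceneSpec) -> SceneTruth:
    """Dart-throwing placement of nuclei inside the spheroid.

    Centers are drawn uniformly in the sphere and accepted if at least
    ``min_separation_um`` from all previous centers. Each nucleus is
    labeled with probability ``labeled_fraction`` (only a subpopulation
    of cells expresses the reporter). Nuclei within ``rim_thickness_um``
    of the surface — the proliferating outer layers — are mitotic with
    probability ``mitotic_fraction``; deeper (quiescent) nuclei never.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    center = spec.center_um
    R = spec.spheroid_radius_um - 0.5 * spec.nucleus_radius_um  # keep blobs inside
    centers: list[np.ndarray] = []
    max_attempts = 2000 * spec.n_nuclei
    attempts = 0
    while len(centers) < spec.n_nuclei:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_nuclei} nuclei with separation "
                f"{spec.min_separation_um} um in a {spec.spheroid_radius_um} um "
                f"spheroid after {max_attempts} attempts; reduce density"
            )
        attempts += 1
        p = rng.uniform(-R, R, size=3)
        if p @ p > R * R:
            continue
        p = center + p
        if all(np.linalg.norm(p - q) >= spec.min_separation_um for q in centers):
            centers.append(p)

    nuclei = []
    for i, c in enumerate(centers):
        labeled = bool(rng.random() < spec.labeled_fraction)
        depth = spec.spheroid_radius_um - float(np.linalg.norm(c - center))
        mitotic = depth <= spec.rim_thickness_um and rng.random() < spec.mitotic_fraction
        orientation = _random_unit(rng) if mitotic else None
        nuclei.append(
            Nucleus(
                id=i,
                center_um=c,
                klass=MITOTIC if mitotic else INTERPHASE,
                labeled=labeled,
                orientation=orientation,
            )
        )
    return SceneTruth(
        nuclei=nuclei,
        spheroid_center_um=center.copy(),
        spheroid_radius_um=spec.spheroid_radius_um,
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# --------------------------------------------------------------------------
# Rendering primitives


def _add_blob(
    out: np.ndarray,
    spacing: tuple[float, float, float],
    center_um: np.ndarray,
    sigmas_um: np.ndarray,
    amplitude: float,
    axis: np.ndarray | None = None,
) -> None:
    """Add an (optionally rotated anisotropic) Gaussian blob in place.

    ``sigmas_um`` are the principal standard deviations ``(long, short,
    short)``; ``axis`` is the long-axis unit vector in (z, y, x). The blob
    is evaluated on a window truncated at 4 sigma.
    """
    spacing = np.asarray(spacing, dtype=float)
    sig = np.asarray(sigmas_um, dtype=float)
    reach = 4.0 * sig.max()
    lo = np.maximum(np.floor((center_um - reach) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center_um + reach) / spacing).astype(int) + 1, out.shape)
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *(np.arange(l, h) * s for l, h, s in zip(lo, hi, spacing)), indexing="ij"
    )
    d = np.stack([g - c for g, c in zip(grids, center_um)], axis=-1)
    if axis is None or np.allclose(sig, sig[0]):
        q = np.sum((d / sig) ** 2, axis=-1)
    else:
        u = np.asarray(axis, dtype=float)
        u = u / np.linalg.norm(u)
        along = d @ u
        perp2 = np.sum(d * d, axis=-1) - along**2
        q = (along / sig[0]) ** 2 + perp2 / sig[1] ** 2
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(-0.5 * q)


def _render_items(
    items: list[tuple[np.ndarray, np.ndarray, float, np.ndarray | None]],
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    out = np.zeros(shape, dtype=np.float64)
    for center, sigmas, amp, axis in items:
        _add_blob(out, spacing, center, sigmas, amp, axis)
    return out


def _attenuation_field(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    sphere_center_um: np.ndarray,
    radius_um: float,
    ell_um: float,
) -> np.ndarray:
    """exp(-d_x / ell) with d_x the chord length travelled inside the
    ideal spheroid from the illumination entry point to each voxel."""
    if not math.isfinite(ell_um):
        return np.ones(shape)
    nz, ny, nx = shape
    sz, sy, sx = spacing
    z = np.arange(nz) * sz - sphere_center_um[0]
    y = np.arange(ny) * sy - sphere_center_um[1]
    x = np.arange(nx) * sx  # absolute x coordinate
    rho2 = z[:, None] ** 2 + y[None, :] ** 2
    inside = rho2 < radius_um**2
    half_chord = np.sqrt(np.maximum(radius_um**2 - rho2, 0.0))
    x_entry = sphere_center_um[2] - half_chord  # light propagates toward +x
    d = x[None, None, :] - x_entry[:, :, None]
    d = np.clip(d, 0.0, 2.0 * half_chord[:, :, None])
    d = np.where(inside[:, :, None], d, 0.0)
    return np.exp(-d / ell_um)


def _depth_blur(
    vol: np.ndarray,
    spacing: tuple[float, float, float],
    sphere_center_um: np.ndarray,
    radius_um: float,
    sigma0_um: float,
    growth: float,
) -> np.ndarray:
    """Per-slice lateral blur growing with tissue depth along z."""
    if sigma0_um == 0 and growth == 0:
        return vol
    sz, sy, sx = spacing
    out = np.empty_like(vol)
    z_top = sphere_center_um[0] - radius_um
    for iz in range(vol.shape[0]):
        depth = min(max(iz * sz - z_top, 0.0), 2 * radius_um)
        sigma_um = sigma0_um + growth * depth
        if sigma_um <= 0:
            out[iz] = vol[iz]
        else:
            out[iz] = ndimage.gaussian_filter(vol[iz], (sigma_um / sy, sigma_um / sx))
    return out


def _shape_params(
    state: str, scene: SceneSpec, gain: float
) -> tuple[np.ndarray, float]:
    """Principal sigmas (long, short, short) in um and peak amplitude."""
    r = scene.nucleus_radius_um
    if state in (INTERPHASE, DAUGHTER):
        s = _INTERPHASE_SIGMA_FRAC * r
        return np.array([s, s, s]), INTERPHASE_PEAK
    if state in (CONDENSED, MITOTIC):
        s = _CONDENSED_SIGMA_FRAC * r
        return np.array([_CONDENSED_AXIS_RATIO * s, s, s]), INTERPHASE_PEAK * gain
    if state == METAPHASE:
        # flat disc: thin along the spindle axis, wide across
        return (
            np.array([_PLATE_FLAT_FRAC * r, _PLATE_WIDE_FRAC * r, _PLATE_WIDE_FRAC * r]),
            INTERPHASE_PEAK * gain,
        )
    if state == ANAPHASE:
        s = 0.3 * r
        return np.array([s, s, s]), INTERPHASE_PEAK * gain
    raise ValueError(f"unknown nucleus state {state!r}")


def _items_for_state(
    nid: int, st: NucleusState, scene: SceneSpec, gain: float
) -> list[tuple[np.ndarray, np.ndarray, float, np.ndarray | None]]:
    sig, amp = _shape_params(st.state, scene, gain)
    if st.state == ANAPHASE:
        u = st.orientation if st.orientation is not None else np.array([0.0, 0.0, 1.0])
        off = 0.5 * st.separation_um * u
        return [(st.center_um + off, sig, amp, None), (st.center_um - off, sig, amp, None)]
    if st.state == METAPHASE:
        # the plate's flat (short) axis is the spindle axis
        return [(st.center_um, sig, amp, st.orientation)]
    axis = st.orientation if st.state in (CONDENSED, MITOTIC) else None
    return [(st.center_um, sig, amp, axis)]


def _static_items(
    truth: SceneTruth, scene: SceneSpec, gain: float
) -> list[tuple[np.ndarray, np.ndarray, float, np.ndarray | None]]:
    items = []
    for n in truth.nuclei:
        if not n.labeled:
            continue
        st = NucleusState(
            state=CONDENSED if n.klass == MITOTIC else INTERPHASE,
            center_um=n.center_um,
            orientation=n.orientation,
        )
        items.extend(_items_for_state(n.id, st, scene, gain))
    return items


def render_volume(
    truth: SceneTruth,
    scene: SceneSpec,
    optics: OpticsSpec,
    seed: int = 0,
    sphere_center_um: np.ndarray | None = None,
) -> ImageVolume:
    """Render a static scene: blobs, attenuation, depth blur, noise.

    Only labeled nuclei contribute. Intensities are on [0, 1] before
    noise; noise may push outside and is not clipped (linearity is
    preserved for quantitative tests).
    """
    optics.validate()
    spacing = scene.spacing_zyx
    center = (
        np.asarray(sphere_center_um, dtype=float)
        if sphere_center_um is not None
        else truth.spheroid_center_um
    )
    items = _static_items(truth, scene, optics.mitotic_gain)
    sig = _render_items(items, scene.volume_shape_vox, spacing)
    sig *= _attenuation_field(
        sig.shape, spacing, center, truth.spheroid_radius_um, optics.attenuation_length_um
    )
    sig = _depth_blur(
        sig, spacing, center, truth.spheroid_radius_um,
        optics.blur_sigma0_um, optics.blur_growth_per_um,
    )
    sig = _apply_noise(sig, optics, seed)
    return ImageVolume(sig, scene.voxel_size_um)


def _apply_noise(sig: np.ndarray, optics: OpticsSpec, seed: int) -> np.ndarray:
    if optics.photon_scale <= 0 and optics.read_noise_sd <= 0:
        return sig
    rng = np.random.default_rng(seed)
    out = sig
    if optics.photon_scale > 0 and math.isfinite(optics.photon_scale):
        out = rng.poisson(np.clip(out, 0, None) * optics.photon_scale) / optics.photon_scale
    if optics.read_noise_sd > 0:
        out = out + rng.normal(0.0, optics.read_noise_sd, size=out.shape)
    return out


def render_opposing_views(
    truth: SceneTruth,
    scene: SceneSpec,
    optics: OpticsSpec,
    seed: int = 0,
) -> tuple[ImageVolume, ImageVolume, ImageVolume]:
    """Render one scene as acquired at 0 and 180 degrees about y.

    The 180-degree acquisition images the sample flipped in x and z, so
    each view is attenuated from its own light-entry side; fusing the two
    recovers signal the other view lost. Returns
    ``(view0, view180, unattenuated)`` where the last is the noise-free,
    attenuation-free reference for fusion scoring.
    """
    optics.validate()
    spacing = scene.spacing_zyx
    shape = scene.volume_shape_vox
    S = _render_items(_static_items(truth, scene, optics.mitotic_gain), shape, spacing)
    ref = ImageVolume(S.copy(), scene.voxel_size_um)

    def acquire(sample: np.ndarray, sphere_c: np.ndarray, noise_seed: int) -> ImageVolume:
        sig = sample * _attenuation_field(
            shape, spacing, sphere_c, truth.spheroid_radius_um,
            optics.attenuation_length_um,
        )
        sig = _depth_blur(
            sig, spacing, sphere_c, truth.spheroid_radius_um,
            optics.blur_sigma0_um, optics.blur_growth_per_um,
        )
        return ImageVolume(_apply_noise(sig, optics, noise_seed), scene.voxel_size_um)

    center = truth.spheroid_center_um
    v0 = acquire(S, center, seed)
    S180 = S[::-1, :, ::-1]
    c180 = center.copy()
    c180[0] = (shape[0] - 1) * spacing[0] - center[0]
    c180[2] = (shape[2] - 1) * spacing[2] - center[2]
    v180 = acquire(S180, c180, seed + 1)
    return v0, v180, ref


# --------------------------------------------------------------------------
# Stripe field


def make_stripe_field(
    shape_vox: tuple[int, int, int],
    stripes: StripeSpec,
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a stripe field ``b = lam (*) psi`` and its coefficients.

    ``lam`` is Bernoulli(noise_density) x Gaussian(0, noise_sd^2) white
    noise over the full volume; ``psi`` is the elongated stripe kernel.
    Convolution is linear (zero-padded FFT), per z-slice when
    ``per_slice`` else fully 3D.
    """
    stripes.validate()
    if any(n <= 0 for n in shape_vox):
        raise ValueError(f"shape must be positive, got {shape_vox}")
    rng = np.random.default_rng(seed)
    mask = rng.random(shape_vox) < stripes.noise_density
    lam = np.where(mask, rng.normal(0.0, stripes.noise_sd, size=shape_vox), 0.0)
    if stripes.per_slice:
        psi = stripe_kernel(stripes.psi_sigma_along_um, stripes.psi_sigma_across_um,
                            voxel_size_um)
        b = np.stack(
            [spsignal.fftconvolve(sl, psi, mode="same") for sl in lam]
        )
    else:
        psi = stripe_kernel(
            stripes.psi_sigma_along_um, stripes.psi_sigma_across_um, voxel_size_um,
            sigma_z_um=stripes.psi_sigma_across_um,
        )
        b = spsignal.fftconvolve(lam, psi, mode="same")
    return b, lam


# --------------------------------------------------------------------------
# Time lapse


def frame_seeds(base_seed: int, frame: int) -> tuple[int, int]:
    """Deterministic (render_seed, stripe_seed) for one movie frame."""
    h = (base_seed * 1_000_003 + frame) % (2**31 - 1)
    return h, (h + 777_767) % (2**31 - 1)


def _choose_spindle_axis(
    truth: SceneTruth,
    nid: int,
    scene: SceneSpec,
    rng: np.random.Generator,
    n_candidates: int = 24,
) -> np.ndarray:
    """Spindle axis of a dividing cell, oriented into free space.

    Cells divide where there is room: among random candidate directions
    the one whose daughter positions (one nucleus radius to either side)
    keep the largest clearance from neighboring nuclei — and stay inside
    the spheroid — is chosen. This keeps daughters from overlapping
    neighbors, which would violate the scene's minimum-separation
    geometry. Deterministic given the movie seed.
    """
    c = truth.by_id(nid).center_um
    others = np.array(
        [n.center_um for n in truth.nuclei if n.id != nid]
    )
    r = scene.nucleus_radius_um
    best_u, best_score = None, -np.inf
    for _ in range(n_candidates):
        u = _random_unit(rng)
        score = np.inf
        for sign in (+1.0, -1.0):
            d = c + sign * r * u
            if others.size:
                score = min(score, float(np.linalg.norm(others - d, axis=1).min()))
            overshoot = (
                np.linalg.norm(d - truth.spheroid_center_um)
                - (truth.spheroid_radius_um - 0.5 * r)
            )
            if overshoot > 0:
                score -= 2.0 * overshoot
        if score > best_score:
            best_u, best_score = u, score
    return best_u


def _division_schedule(
    entry: int, n_frames: int, duration_min: float, interval_min: float
) -> dict[int, str]:
    """Frame -> state for one completing division.

    The mitotic phase spans ``ceil(duration / interval)`` frames split
    into condensed, metaphase (aligned plate) and anaphase; daughters
    appear on the first frame after the mitotic run.
    """
    n_mit = max(int(math.ceil(duration_min / interval_min)), 1)
    n_ana = max(int(round(0.3 * n_mit)), 1)
    n_meta = max(int(round(0.35 * n_mit)), 1) if n_mit >= 3 else 0
    n_cond = n_mit - n_ana - n_meta
    if n_cond < 0:
        n_meta += n_cond
        n_cond = 0
    sched: dict[int, str] = {}
    f = entry
    for _ in range(n_cond):
        sched[f] = CONDENSED
        f += 1
    for _ in range(n_meta):
        sched[f] = METAPHASE
        f += 1
    for _ in range(n_ana):
        sched[f] = ANAPHASE
        f += 1
    sched[f] = DAUGHTER  # first daughter frame (= entry + n_mit)
    return {k: v for k, v in sched.items() if k < n_frames}


def render_timelapse(
    scene: SceneSpec,
    optics: OpticsSpec,
    stripes: StripeSpec | None,
    tl: TimelapseSpec,
    keep_fields: bool = True,
) -> tuple[list[ImageVolume], SceneTruth]:
    """Render a drifting, dividing time-lapse movie with full truth.

    Frame ``t`` is translated by ``t * drift_per_frame_um`` before
    rendering. Each division event walks interphase -> condensed ->
    metaphase -> anaphase -> two daughters over ``mitosis_duration_min``;
    in paclitaxel mode chromosomes condense and then jitter without ever
    forming a plate or segregating, through the end of the movie. A fresh
    stripe field is drawn per frame; the returned volumes are
    ``clean + stripe`` exactly.
    """
    scene.validate()
    optics.validate()
    tl.validate()
    if stripes is not None:
        stripes.validate()

    truth = place_nuclei(scene)
    drift = np.asarray(tl.drift_per_frame_um, dtype=float)
    rng = np.random.default_rng(tl.seed + 986_243)

    # validate events; build schedules
    schedules: dict[int, dict[int, str]] = {}
    orientations: dict[int, np.ndarray] = {}
    next_id = max(n.id for n in truth.nuclei) + 1
    daughter_ids: dict[int, tuple[int, int]] = {}
    for nid, entry in tl.division_events:
        try:
            nuc = truth.by_id(nid)
        except KeyError:
            truth.skipped_events.append((nid, entry, "unknown nucleus id"))
            warnings.warn(f"division event on unknown nucleus {nid}; skipped")
            continue
        if not nuc.labeled:
            truth.skipped_events.append((nid, entry, "unlabeled nucleus"))
            warnings.warn(f"division event on unlabeled nucleus {nid}; skipped")
            continue
        if truth.depth_of(nid) > scene.rim_thickness_um:
            truth.skipped_events.append((nid, entry, "nucleus too deep"))
            warnings.warn(f"division event on too-deep nucleus {nid}; skipped")
            continue
        orientations[nid] = _choose_spindle_axis(truth, nid, scene, rng)
        if tl.paclitaxel_mode:
            schedules[nid] = {f: CONDENSED for f in range(entry, tl.n_frames)}
        else:
            schedules[nid] = _division_schedule(
                entry, tl.n_frames, tl.mitosis_duration_min, tl.frame_interval_min
            )
            daughter_ids[nid] = (next_id, next_id + 1)
            next_id += 2

    ana_speed_um_per_frame = {}
    for nid, sched in schedules.items():
        n_ana = sum(1 for s in sched.values() if s == ANAPHASE)
        if n_ana:
            # masses end up one nucleus diameter apart at the last anaphase frame
            ana_speed_um_per_frame[nid] = 2 * scene.nucleus_radius_um / n_ana

    jitters: dict[int, np.ndarray] = {
        nid: np.zeros(3) for nid in schedules if tl.paclitaxel_mode
    }

    volumes: list[ImageVolume] = []
    for t in range(tl.n_frames):
        shift = t * drift
        states: dict[int, NucleusState] = {}
        for n in truth.nuclei:
            if not n.labeled:
                continue
            base = n.center_um + shift
            sched = schedules.get(n.id)
            if sched is None:
                state = CONDENSED if n.klass == MITOTIC else INTERPHASE
                states[n.id] = NucleusState(state, base, orientation=n.orientation)
                continue
            entry = min(sched)
            if t < entry:
                states[n.id] = NucleusState(INTERPHASE, base)
                continue
            daughter_frame = next(
                (f for f, st in sched.items() if st == DAUGHTER), None
            )
            if daughter_frame is not None and t >= daughter_frame:
                u = orientations[n.id]
                off = scene.nucleus_radius_um * u
                d1, d2 = daughter_ids[n.id]
                states[d1] = NucleusState(DAUGHTER, base + off)
                states[d2] = NucleusState(DAUGHTER, base - off)
                continue
            s = sched[t]
            if tl.paclitaxel_mode and s == CONDENSED:
                jitters[n.id] = 0.5 * jitters[n.id] + rng.normal(
                    0.0, _PACLITAXEL_JITTER_UM, size=3
                )
                states[n.id] = NucleusState(
                    CONDENSED, base + jitters[n.id], orientation=_random_unit(rng)
                )
            elif s == ANAPHASE:
                ana_start = min(f for f, st in sched.items() if st == ANAPHASE)
                sep = (t - ana_start + 1) * ana_speed_um_per_frame[n.id]
                states[n.id] = NucleusState(
                    ANAPHASE, base, separation_um=sep, orientation=orientations[n.id]
                )
            else:
                states[n.id] = NucleusState(s, base, orientation=orientations[n.id])

        items = []
        for nid, st in states.items():
            items.extend(_items_for_state(nid, st, scene, optics.mitotic_gain))
        spacing = scene.spacing_zyx
        sphere_c = truth.spheroid_center_um + shift
        sig = _render_items(items, scene.volume_shape_vox, spacing)
        sig *= _attenuation_field(
            sig.shape, spacing, sphere_c, truth.spheroid_radius_um,
            optics.attenuation_length_um,
        )
        sig = _depth_blur(
            sig, spacing, sphere_c, truth.spheroid_radius_um,
            optics.blur_sigma0_um, optics.blur_growth_per_um,
        )
        render_seed, stripe_seed = frame_seeds(tl.seed, t)
        clean = _apply_noise(sig, optics, render_seed)
        if stripes is not None:
            b, lam = make_stripe_field(
                scene.volume_shape_vox, stripes, scene.voxel_size_um, stripe_seed
            )
        else:
            b = np.zeros_like(clean)
            lam = None
        frame = FrameTruth(
            frame=t,
            time_min=t * tl.frame_interval_min,
            drift_um=shift.copy(),
            states=states,
            clean=clean if keep_fields else None,
            stripe=b if keep_fields else None,
            lam=lam if keep_fields else None,
        )
        truth.frames.append(frame)
        volumes.append(ImageVolume(clean + b, scene.voxel_size_um))

    truth.daughters = daughter_ids
    return volumes, truth
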