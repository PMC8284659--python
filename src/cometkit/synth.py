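"""Synthetic fluorescence movies of axonal EB-comet dynamics with ground truth.

Simulates the imaging experiments the downstream modules quantify: an axon
is a calibrated polyline trace (optionally looping through "curled"
regions of known enclosed area); growing microtubule plus-ends appear as
comet-shaped puncta that nucleate as a Poisson process along the axon,
advance at constant velocity and disappear after exponentially distributed
lifetimes.  Each comet is rendered as a line emitter with a Gaussian
leading edge and an exponential trailing tail (tail pointing towards the
soma for anterograde comets), convolved with a Gaussian PSF, on top of a
uniform lattice fluorescence painted along the trace.  Optional Poisson
shot noise and additive Gaussian read noise are applied last.

``comet_amplitude`` parameterises the *integrated* (background-subtracted)
intensity a comet deposits in the image, so total comet flux is conserved
when the PSF width changes; the resulting peak pixel value can be obtained
numerically via :func:`comet_peak_intensity`.

Every simulation is fully reproducible: an equal :class:`SimConfig`
(including ``rng_seed``) yields bit-identical stacks and ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import AxonTrace, MovieStack, Image2D, write_stack, write_rois
from .morpho import shoelace_area_px

__all__ = [
    "SimConfig",
    "CometTrackTruth",
    "CurlRegionTruth",
    "simulate_axon_trace",
    "simulate_comet_movie",
    "render_still",
    "comet_peak_intensity",
    "write_simulation",
]

_OVERSAMPLE = 3  # sub-pixel rendering factor
_MARGIN_PX = 8   # image margin around the trace


@dataclass
class SimConfig:
    """Acquisition and biology parameters for one simulated neuron.

    Defaults emulate spinning-disk imaging of fly primary neurons: 1 s
    frame interval for 1 min, ~0.1 um pixels, EB comets moving
    anterogradely at 0.2 um/s with ~8 s lifetimes and ~1 um tails.
    """

    pixel_size_um: float = 0.1
    frame_interval_s: float = 1.0
    n_frames: int = 60
    image_shape: tuple[int, int] | None = None  # (rows, cols); None = auto-fit
    axon_length_um: float = 60.0
    comet_velocity_um_s: float = 0.2  # signed; + = anterograde (away from soma)
    comet_nucleation_rate_per_um_min: float = 0.6
    comet_lifetime_mean_s: float = 8.0
    comet_tail_length_um: float = 1.0
    comet_amplitude: float = 4000.0  # integrated comet flux (intensity units)
    lattice_intensity: float = 150.0  # lattice flux per um of axon
    bg_offset: float = 100.0
    gaussian_noise_sd: float = 2.0
    poisson_noise: bool = True
    psf_sigma_um: float = 0.11
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positives = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "axon_length_um": self.axon_length_um,
            "comet_lifetime_mean_s": self.comet_lifetime_mean_s,
            "comet_tail_length_um": self.comet_tail_length_um,
            "psf_sigma_um": self.psf_sigma_um,
        }
        for name, value in positives.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        for name, value in (("comet_nucleation_rate_per_um_min",
                             self.comet_nucleation_rate_per_um_min),
                            ("comet_amplitude", self.comet_amplitude),
                            ("lattice_intensity", self.lattice_intensity),
                            ("bg_offset", self.bg_offset),
                            ("gaussian_noise_sd", self.gaussian_noise_sd)):
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass
class CometTrackTruth:
    """Ground truth for one simulated comet."""

    birth_time_s: float
    death_time_s: float
    birth_arclength_um: float
    velocity_um_s: float
    amplitude: float
    tail_length_um: float

    def __post_init__(self) -> None:
        if not self.death_time_s > self.birth_time_s:
            raise ValueError("death_time_s must exceed birth_time_s")

    def position_um(self, t_s: float) -> float:
        return self.birth_arclength_um + self.velocity_um_s * (t_s - self.birth_time_s)

    def alive_at(self, t_s: float) -> bool:
        return self.birth_time_s <= t_s < self.death_time_s

    @property
    def lifetime_s(self) -> float:
        return self.death_time_s - self.birth_time_s


@dataclass
class CurlRegionTruth:
    """Ground truth for one curled (disorganised) region of the trace."""

    polygon_px: np.ndarray
    area_um2: float
    arclength_span_um: tuple[float, float]


# ---------------------------------------------------------------------------
# Axon trace with curl loops
# ---------------------------------------------------------------------------

def simulate_axon_trace(config: SimConfig,
                        curl_specs: list[tuple[float, float]] = ()
                        ) -> tuple[AxonTrace, list[CurlRegionTruth]]:
    """Build a synthetic axon trace, inserting circular curl loops.

    ``curl_specs`` is a list of ``(arclength_um, target_area_um2)`` pairs:
    at each stated arclength the trace loops through a circle enclosing
    the target area.  The loop consumes exactly its own circumference of
    arclength, so the total trace arclength stays at
    ``config.axon_length_um``.
    """
    L = config.axon_length_um
    px = config.pixel_size_um

    spans = []
    for s_c, area in curl_specs:
        if not area > 0:
            raise ValueError(f"curl target area must be > 0, got {area}")
        r = math.sqrt(area / math.pi)
        c = 2 * math.pi * r
        span = (s_c - c / 2, s_c + c / 2)
        if span[0] < 0 or span[1] > L:
            raise ValueError(
                f"curl span {span[0]:.2f}-{span[1]:.2f} um (centre {s_c} um, "
                f"area {area} um^2) does not fit inside [0, {L}] um")
        spans.append((span, r))
    spans.sort(key=lambda t: t[0][0])
    for (a, _), (b, _) in zip(spans, spans[1:]):
        if b[0] < a[1]:
            raise ValueError(
                f"curl spans {a[0]:.2f}-{a[1]:.2f} and {b[0]:.2f}-{b[1]:.2f} um overlap")

    # Build in intrinsic coordinates (baseline y = 0, soma at x = 0), then
    # translate into the image.
    verts = [(0.0, 0.0)]
    truths_raw = []
    x = 0.0
    s_done = 0.0
    r_max = 0.0
    for (s0, s1), r in spans:
        x += (s0 - s_done) / px  # straight run up to the loop
        verts.append((x, 0.0))
        r_px = r / px
        r_max = max(r_max, r_px)
        n = max(48, int(math.ceil(2 * math.pi * r_px / 1.0)))
        theta = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
        loop = np.stack([x + r_px * np.sin(theta), r_px * (1 - np.cos(theta))], axis=1)
        verts.extend(map(tuple, loop[1:]))
        verts.append((x, 0.0))  # close the loop, tangent restored along +x
        truths_raw.append((loop, (s0, s1)))
        s_done = s1
    x += (L - s_done) / px
    verts.append((x, 0.0))
    verts = np.asarray(verts, dtype=float)

    # Translate into image coordinates with a safety margin.
    offset = np.array([_MARGIN_PX, _MARGIN_PX], dtype=float) - verts.min(axis=0)
    verts = verts + offset
    extent = verts.max(axis=0)
    needed = (int(math.ceil(extent[1])) + _MARGIN_PX + 1,
              int(math.ceil(extent[0])) + _MARGIN_PX + 1)
    if config.image_shape is None:
        config.image_shape = needed
    rows, cols = config.image_shape
    if extent[0] > cols - 5 or extent[1] > rows - 5:
        bad = spans[0][0] if spans else (0.0, L)
        raise ValueError(
            f"trace (curl span {bad[0]:.2f}-{bad[1]:.2f} um) is not realisable "
            f"inside image_shape {config.image_shape}; needs at least {needed}")

    truths = []
    for loop, span in truths_raw:
        poly = loop + offset
        truths.append(CurlRegionTruth(
            polygon_px=poly,
            area_um2=shoelace_area_px(poly) * px**2,
            arclength_span_um=span,
        ))
    return AxonTrace(verts, px), truths


# ---------------------------------------------------------------------------
# Comet rendering
# ---------------------------------------------------------------------------

def _axial_profile(u_um: np.ndarray, config: SimConfig) -> np.ndarray:
    """Intrinsic comet emission density along the motion axis.

    ``u`` is the signed distance from the tip along the direction of
    motion (positive = ahead of the tip): Gaussian leading edge of width
    ``psf_sigma_um``, exponential trailing tail of decay length
    ``comet_tail_length_um``.  Normalised to unit integral.
    """
    sigma, tail = config.psf_sigma_um, config.comet_tail_length_um
    p = np.where(u_um >= 0,
                 np.exp(-0.5 * (u_um / sigma) ** 2),
                 np.exp(u_um / tail))
    norm = sigma * math.sqrt(math.pi / 2) + tail
    return p / norm


def _render_noiseless(trace: AxonTrace, comet_states, config: SimConfig) -> np.ndarray:
    """Render lattice + comets (no offset, no noise) at the configured shape.

    ``comet_states`` is an iterable of ``(tip_arclength_um, direction,
    flux)`` tuples; emitters are deposited on a 3x-oversampled grid and
    convolved with the Gaussian PSF, so pixel values are fluxes per pixel.
    """
    if config.image_shape is None:
        hi = trace.vertices.max(axis=0)
        config.image_shape = (int(math.ceil(hi[1])) + _MARGIN_PX + 1,
                              int(math.ceil(hi[0])) + _MARGIN_PX + 1)
    rows, cols = config.image_shape
    os_ = _OVERSAMPLE
    px = config.pixel_size_um
    cell_um = px / os_
    grid = np.zeros((rows * os_, cols * os_), dtype=float)
    L = trace.arclength_um

    def deposit(s_um: np.ndarray, w: np.ndarray) -> None:
        pts = trace.point_at_arclength_um(s_um)
        ox = np.rint(pts[:, 0] * os_ + (os_ - 1) / 2).astype(int)
        oy = np.rint(pts[:, 1] * os_ + (os_ - 1) / 2).astype(int)
        ok = (ox >= 0) & (ox < grid.shape[1]) & (oy >= 0) & (oy < grid.shape[0])
        np.add.at(grid, (oy[ok], ox[ok]), w[ok])

    step = cell_um / 2  # sub-cell sampling along the line
    if config.lattice_intensity > 0:
        s = np.arange(0.0, L, step)
        deposit(s, np.full(s.shape, config.lattice_intensity * step))

    sigma, tail = config.psf_sigma_um, config.comet_tail_length_um
    for tip, direction, flux in comet_states:
        if not (0.0 <= tip <= L):
            raise ValueError(f"comet tip at arclength {tip:.3f} um is outside "
                             f"the trace domain [0, {L:.3f}] um")
        u = np.arange(-6.0 * tail, 4.0 * sigma, step)
        s = tip + direction * u
        ok = (s >= 0.0) & (s <= L)
        deposit(s[ok], flux * _axial_profile(u[ok], config) * step)

    grid = gaussian_filter(grid, sigma=config.psf_sigma_um / cell_um, mode="constant")
    # pixel values are intensity surface density (flux per um^2), so the
    # same physical scene renders identically at any pixel size
    return grid.reshape(rows, os_, cols, os_).sum(axis=(1, 3)) / px**2


def _comet_states_at(comets, t_s: float):
    states = []
    for c in comets:
        if c.alive_at(t_s):
            direction = 1.0 if c.velocity_um_s >= 0 else -1.0
            states.append((c.position_um(t_s), direction, c.amplitude))
    return states


def _apply_noise(img: np.ndarray, config: SimConfig, rng: np.random.Generator
                 ) -> np.ndarray:
    out = img + config.bg_offset
    if config.poisson_noise:
        out = rng.poisson(np.clip(out, 0.0, None)).astype(float)
    if config.gaussian_noise_sd > 0:
        out = out + rng.normal(0.0, config.gaussian_noise_sd, size=out.shape)
    return out


def render_still(trace: AxonTrace, comets, t_s: float, config: SimConfig,
                 noise: bool = False) -> Image2D:
    """Render a single frame at time ``t_s`` (noiseless unless ``noise``).

    Comets not alive at ``t_s`` are omitted; a live comet whose tip lies
    outside the trace domain raises.
    """
    if not (0.0 <= t_s <= config.duration_s):
        raise ValueError(f"t_s={t_s} outside movie duration [0, {config.duration_s}] s")
    img = _render_noiseless(trace, _comet_states_at(comets, t_s), config)
    if noise:
        img = _apply_noise(img, config, np.random.default_rng(config.rng_seed))
    else:
        img = img + config.bg_offset
    return Image2D(img, config.pixel_size_um)


def simulate_comet_movie(trace: AxonTrace, config: SimConfig
                         ) -> tuple[MovieStack, list[CometTrackTruth]]:
    """Simulate a time-lapse movie of comets running along ``trace``.

    Comets nucleate as a homogeneous Poisson process in time x arclength
    at ``comet_nucleation_rate_per_um_min``, advance at the configured
    velocity, and die after exponential lifetimes (truncated where the
    trajectory leaves the axon).  Returns the noisy stack and the ground
    truth track list, both fully determined by ``config.rng_seed``.
    """
    if config.n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if config.comet_nucleation_rate_per_um_min < 0:
        raise ValueError("nucleation rate must be >= 0")
    rng = np.random.default_rng(config.rng_seed)
    L = trace.arclength_um
    duration = config.duration_s
    v = config.comet_velocity_um_s

    expected = config.comet_nucleation_rate_per_um_min * L * duration / 60.0
    n = rng.poisson(expected)
    births = np.sort(rng.uniform(0.0, duration, size=n))
    positions = rng.uniform(0.0, L, size=n)
    lifetimes = rng.exponential(config.comet_lifetime_mean_s, size=n)

    truth = []
    for t0, s0, life in zip(births, positions, lifetimes):
        death = t0 + life
        if v > 0:
            exit_t = t0 + (L - s0) / v
        elif v < 0:
            exit_t = t0 + s0 / (-v)
        else:
            exit_t = math.inf
        death = min(death, exit_t)
        if death <= t0:
            continue  # nucleated exactly on the boundary, immediately gone
        truth.append(CometTrackTruth(
            birth_time_s=float(t0), death_time_s=float(death),
            birth_arclength_um=float(s0), velocity_um_s=v,
            amplitude=config.comet_amplitude,
            tail_length_um=config.comet_tail_length_um,
        ))

    frames = []
    for k in range(config.n_frames):
        t = k * config.frame_interval_s
        img = _render_noiseless(trace, _comet_states_at(truth, t), config)
        frames.append(_apply_noise(img, config, rng))
    stack = MovieStack(np.asarray(frames), config.pixel_size_um,
                       config.frame_interval_s)
    return stack, truth


def comet_peak_intensity(config: SimConfig) -> float:
    """Peak pixel value (above background) of one isolated comet.

    Rendered mid-trace on a straight axon with the lattice switched off;
    use this to set signal-to-noise ratios in experiments.
    """
    cfg = replace(config, image_shape=None, lattice_intensity=0.0)
    trace, _ = simulate_axon_trace(cfg)
    img = _render_noiseless(
        trace, [(cfg.axon_length_um / 2, 1.0, cfg.comet_amplitude)], cfg)
    return float(img.max())


def write_simulation(out_dir, stack: MovieStack, truth: list[CometTrackTruth],
                     trace: AxonTrace, curls: list[CurlRegionTruth] = ()) -> None:
    """Write a simulated movie plus ground truth to ``out_dir``.

    Emits ``movie.tif`` (+ sidecar calibration), ``tracks_truth.csv``,
    ``curls_truth.csv`` and ``rois.json`` (the trace, plus curl polygons).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stack(stack, out / "movie.tif")

    with open(out / "tracks_truth.csv", "w") as fh:
        fh.write("track_id,birth_time_s,death_time_s,birth_arclength_um,"
                 "velocity_um_s,amplitude,tail_length_um\n")
        for i, c in enumerate(truth):
            fh.write(f"{i},{c.birth_time_s},{c.death_time_s},{c.birth_arclength_um},"
                     f"{c.velocity_um_s},{c.amplitude},{c.tail_length_um}\n")
    with open(out / "curls_truth.csv", "w") as fh:
        fh.write("curl_id,area_um2,arclength_start_um,arclength_end_um\n")
        for i, c in enumerate(curls):
            fh.write(f"{i},{c.area_um2},{c.arclength_span_um[0]},"
                     f"{c.arclength_span_um[1]}\n")
    from .io import PolygonROI
    polys = [PolygonROI(c.polygon_px, "curl") for c in curls]
    write_rois(out / "rois.json", traces=[trace], polygons=polys)
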