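"""Ground-truthed synthetic inputs for every pipeline stage.

Real single-fly recordings, membranes and confocal stacks are not shipped
with the package, so each analysis stage has a generator here that produces
inputs with known ground truth:

* :func:`simulate_walker` — a two-state (rest/run) Markov walker confined to
  a circular arena, the minimal generative model the locomotor metrics can
  be validated against (the analysis itself dichotomizes behavior at a
  speed threshold, so a two-state chain is the matching null model).
* :func:`render_frames` — arena video frames with a bright fly blob on a
  noisy background, test input for the threshold-centroid tracker.
* :func:`synth_dotblot` — a membrane with darkened spots whose darkness is
  proportional to analyte concentration, emulating a serial-dilution series.
* :func:`synth_brain_stack` — an image stack that is uniform except for a
  darkened circular "pedunculus" region of known contrast in known slices.

All generators are deterministic given their seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WalkerParams",
    "GroundTruth",
    "RenderParams",
    "DotBlotPhantom",
    "BrainPhantomParams",
    "simulate_walker",
    "render_frames",
    "synth_dotblot",
    "synth_brain_stack",
]


@dataclass(frozen=True)
class WalkerParams:
    """Generative parameters of the rest/run arena walker.

    The walker alternates between *rest* and *run* according to a
    continuous-time two-state Markov chain sampled at ``frame_rate``.
    During a run bout it moves at a per-bout speed drawn from a normal law
    (truncated below at 1 mm/s so that runs classify as runs), with heading
    persistence controlled by a von Mises concentration.  During rest it
    jitters isotropically with small mean speed.  At the wall the position
    is projected back onto the boundary and, with weight ``wall_bias``, the
    heading is rotated toward the local tangent — which produces the
    wall-following ("centrophobic") paths real flies show in these arenas.

    Parameters
    ----------
    rate_rest_to_run, rate_run_to_rest:
        Markov switching rates, 1/s.  The stationary run-state probability
        is ``k1 / (k1 + k2)``.
    run_speed_mean, run_speed_sd:
        Mean and SD (mm/s) of the per-bout running speed law.
    rest_speed_mean:
        Mean speed of the isotropic rest jitter, mm/s; must stay below the
        1 mm/s rest/run classification threshold.
    turning_concentration:
        von Mises concentration of per-frame heading increments during
        runs; larger values give straighter paths.
    wall_bias:
        0 = position projection only, 1 = full tangential alignment of the
        heading on wall contact.
    arena_radius:
        mm; the standard chamber is 20 mm across, radius 10.
    """

    rate_rest_to_run: float = 0.1
    rate_run_to_rest: float = 0.1
    run_speed_mean: float = 4.0
    run_speed_sd: float = 1.0
    rest_speed_mean: float = 0.2
    turning_concentration: float = 4.0
    wall_bias: float = 0.7
    arena_radius: float = 10.0
    frame_rate: float = 10.0
    duration: float = 3600.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rate_rest_to_run",
            "rate_run_to_rest",
            "run_speed_mean",
            "run_speed_sd",
            "rest_speed_mean",
            "turning_concentration",
            "wall_bias",
            "arena_radius",
            "frame_rate",
            "duration",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")
        if self.run_speed_mean < 1.0:
            raise ValueError("run_speed_mean must be >= 1 mm/s so runs classify as runs")
        if not 0.0 <= self.rest_speed_mean < 1.0:
            raise ValueError("rest_speed_mean must lie in [0, 1) mm/s")
        if not 0.0 <= self.wall_bias <= 1.0:
            raise ValueError("wall_bias must lie in [0, 1]")
        if self.arena_radius <= 0 or self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("arena_radius, frame_rate and duration must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Simulated walker output: positions, per-frame states and parameters."""

    t: np.ndarray  # s
    x: np.ndarray  # mm, arena-centered
    y: np.ndarray  # mm, arena-centered
    states: np.ndarray  # uint8, 0 = rest, 1 = run
    params: WalkerParams

    def __len__(self) -> int:
        return self.t.size

    @property
    def run_fraction(self) -> float:
        """Empirical fraction of frames spent in the run state."""
        return float(np.mean(self.states))


@dataclass(frozen=True)
class RenderParams:
    """How walker positions are turned into 8-bit arena frames.

    The fly is drawn as a radially symmetric Gaussian blob of peak
    ``fly_peak_intensity`` on a noisy background.  The invariant
    ``fly_peak_intensity > 60 > background_mean + 3 * background_sd``
    keeps the fly detectable by the intensity-60 threshold rule while the
    background essentially never crosses it.
    """

    image_size: int = 256
    mm_per_pixel: float = 0.1
    fly_peak_intensity: float = 200.0
    fly_radius_sigma: float = 2.5
    background_mean: float = 20.0
    background_sd: float = 0.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.bit_depth != 8:
            raise ValueError("only 8-bit rendering is supported")
        if not self.fly_peak_intensity > 60.0:
            raise ValueError("fly_peak_intensity must exceed the detection threshold 60")
        if not self.background_mean + 3.0 * self.background_sd < 60.0:
            raise ValueError(
                "background must stay below the detection threshold: "
                "background_mean + 3*background_sd < 60 required"
            )
        if self.image_size < 8 or self.mm_per_pixel <= 0 or self.fly_radius_sigma <= 0:
            raise ValueError("invalid render geometry")

    @property
    def center_px(self) -> float:
        """Arena center in pixel coordinates (pixel centers at integers)."""
        return (self.image_size - 1) / 2.0


@dataclass(frozen=True)
class DotBlotPhantom:
    """A membrane with gridded spots darkened in proportion to concentration.

    Spot interior intensity is ``background_mean - darkness_per_unit *
    concentration`` (darkness clipped so intensity stays >= 0), emulating a
    serial-dilution standard series on a light membrane.
    """

    spot_centers: tuple  # ((row, col), ...) in pixels
    concentrations: tuple  # arbitrary units, one per spot
    spot_radius: float = 8.0
    darkness_per_unit: float = 10.0
    background_mean: float = 200.0
    background_sd: float = 0.0
    image_size: tuple = (128, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.spot_centers) != len(self.concentrations):
            raise ValueError("one concentration per spot center required")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        if self.spot_radius <= 0 or self.darkness_per_unit < 0:
            raise ValueError("spot_radius must be positive, darkness_per_unit non-negative")
        centers = list(self.spot_centers)
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = math.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
                if d <= 2 * self.spot_radius:
                    raise ValueError(f"spots {i} and {j} overlap (center distance {d:.1f} px)")


@dataclass(frozen=True)
class BrainPhantomParams:
    """Uniform image stack with a darkened circular pedunculus region.

    In ``dimmed_slices`` the disk of radius ``ped_radius`` at ``ped_center``
    has intensity ``ped_contrast * surround_intensity``; everywhere else the
    stack is uniform at ``surround_intensity``, plus optional Gaussian noise.
    """

    stack_size: tuple = (10, 96, 96)  # (slices, height, width)
    surround_intensity: float = 200.0
    ped_center: tuple = (60, 48)  # (row, col)
    ped_radius: float = 16.0
    ped_contrast: float = 0.5
    dimmed_slices: tuple = (4, 5, 6)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.ped_contrast <= 1.0:
            raise ValueError("ped_contrast must lie in (0, 1]")
        nz, ny, nx = self.stack_size
        r, c = self.ped_center
        if not (r - self.ped_radius >= 0 and r + self.ped_radius < ny
                and c - self.ped_radius >= 0 and c + self.ped_radius < nx):
            raise ValueError("pedunculus disk must lie strictly inside the image")
        if any(not 0 <= s < nz for s in self.dimmed_slices):
            raise ValueError("dimmed_slices must be valid slice indices")


def _run_bout_slices(states: np.ndarray):
    """Maximal [start, stop) index ranges of consecutive run frames."""
    padded = np.concatenate(([0], states.astype(np.int8), [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def simulate_walker(params: WalkerParams) -> GroundTruth:
    """Simulate a rest/run Markov walker confined to the arena disk.

    The continuous-time chain is sampled exactly at the frame grid (the
    per-frame switch probability is ``1 - exp(-rate * dt)``), the running
    speed is drawn once per run bout, heading increments are von Mises, and
    rest jitter is Rayleigh-distributed with the requested mean speed.
    The initial state is drawn from the chain's stationary distribution so
    long records are stationary from the first frame.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.frame_rate))
    if n < 1:
        raise ValueError("duration * frame_rate must give at least one frame")
    dt = 1.0 / params.frame_rate
    k1, k2 = params.rate_rest_to_run, params.rate_run_to_rest
    p_rest_to_run = -math.expm1(-k1 * dt)
    p_run_to_rest = -math.expm1(-k2 * dt)

    ktot = k1 + k2
    p_run0 = k1 / ktot if ktot > 0 else 0.0
    state = 1 if rng.random() < p_run0 else 0

    u = rng.random(n)
    states = np.empty(n, dtype=np.uint8)
    s = state
    for i in range(n):
        states[i] = s
        if s:
            if u[i] < p_run_to_rest:
                s = 0
        elif u[i] < p_rest_to_run:
            s = 1

    # per-bout run speeds; truncated below at 1 mm/s (negligible mass for
    # realistic means) so every run bout is a run by the classification rule
    bouts = _run_bout_slices(states)
    step_len = np.zeros(n)
    if bouts:
        bout_speeds = rng.normal(params.run_speed_mean, params.run_speed_sd, len(bouts))
        bout_speeds = np.maximum(bout_speeds, 1.0)
        for (b0, b1), v in zip(bouts, bout_speeds):
            step_len[b0:b1] = v * dt

    kappa = params.turning_concentration
    if kappa > 0:
        dtheta = rng.vonmises(0.0, kappa, n)
    else:
        dtheta = rng.uniform(-math.pi, math.pi, n)
    rest_scale = params.rest_speed_mean * dt * math.sqrt(2.0 / math.pi)
    rest_steps = rng.rayleigh(rest_scale, n) if rest_scale > 0 else np.zeros(n)
    rest_dirs = rng.uniform(0.0, 2.0 * math.pi, n)

    R = params.arena_radius
    R2 = R * R
    wall_bias = params.wall_bias
    # start uniformly over the disk
    r0 = R * math.sqrt(rng.random())
    a0 = rng.uniform(0.0, 2.0 * math.pi)
    x = r0 * math.cos(a0)
    y = r0 * math.sin(a0)
    heading = rng.uniform(0.0, 2.0 * math.pi)

    xs = np.empty(n)
    ys = np.empty(n)
    cos, sin, atan2, sqrt = math.cos, math.sin, math.atan2, math.sqrt
    half_pi = math.pi / 2.0
    states_list = states.tolist()
    step_list = step_len.tolist()
    dtheta_list = dtheta.tolist()
    rest_step_list = rest_steps.tolist()
    rest_dir_list = rest_dirs.tolist()

    for i in range(n):
        xs[i] = x
        ys[i] = y
        if states_list[i]:
            heading += dtheta_list[i]
            step = step_list[i]
            dx = step * cos(heading)
            dy = step * sin(heading)
        else:
            step = rest_step_list[i]
            d = rest_dir_list[i]
            dx = step * cos(d)
            dy = step * sin(d)
        nx = x + dx
        ny = y + dy
        r2 = nx * nx + ny * ny
        if r2 > R2:
            # project back onto the boundary (just inside, to keep the
            # confinement invariant strict under floating arithmetic)
            scale = R * (1.0 - 1e-12) / sqrt(r2)
            nx *= scale
            ny *= scale
            phi = atan2(ny, nx)  # outward normal angle at the contact point
            # specular reflection of the heading across the wall tangent
            # (wall_bias = 0 leaves it at that), then rotate toward the
            # nearer tangent direction with weight wall_bias
            heading = 2.0 * phi + math.pi - heading
            if wall_bias > 0.0:
                t1 = phi + half_pi
                d1 = atan2(sin(t1 - heading), cos(t1 - heading))
                t2 = phi - half_pi
                d2 = atan2(sin(t2 - heading), cos(t2 - heading))
                dmin = d1 if abs(d1) <= abs(d2) else d2
                heading += wall_bias * dmin
        x, y = nx, ny

    t = np.arange(n) * dt
    return GroundTruth(t=t, x=xs, y=ys, states=states, params=params)


def render_frames(truth: GroundTruth, rp: RenderParams, seed: int = 0,
                  draw_fly: bool = True) -> np.ndarray:
    """Render walker positions as a stack of 8-bit grayscale frames.

    Each frame is Gaussian background noise plus a radially symmetric
    Gaussian blob of peak ``fly_peak_intensity`` centered at the fly
    position.  Returns an array of shape ``(n_frames, size, size)``.
    ``draw_fly=False`` renders background only (all frames then contain no
    detection).
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    size = rp.image_size
    c = rp.center_px
    px = c + truth.x / rp.mm_per_pixel
    py = c - truth.y / rp.mm_per_pixel
    if draw_fly and (px.min() < 0 or px.max() > size - 1 or py.min() < 0 or py.max() > size - 1):
        raise ValueError("fly position falls outside the image; increase image_size "
                         "or decrease mm_per_pixel")

    frames = np.empty((n, size, size), dtype=np.uint8)
    sigma = rp.fly_radius_sigma
    win = int(math.ceil(4 * sigma))
    yy, xx = np.mgrid[0:size, 0:size]
    for i in range(n):
        if rp.background_sd > 0:
            frame = rng.normal(rp.background_mean, rp.background_sd, (size, size))
        else:
            frame = np.full((size, size), float(rp.background_mean))
        if draw_fly:
            cx, cy = px[i], py[i]
            r0 = max(int(cy) - win, 0)
            r1 = min(int(cy) + win + 2, size)
            c0 = max(int(cx) - win, 0)
            c1 = min(int(cx) + win + 2, size)
            d2 = (xx[r0:r1, c0:c1] - cx) ** 2 + (yy[r0:r1, c0:c1] - cy) ** 2
            frame[r0:r1, c0:c1] += rp.fly_peak_intensity * np.exp(-d2 / (2 * sigma * sigma))
        np.clip(np.rint(frame), 0, 255, out=frame)
        frames[i] = frame.astype(np.uint8)
    return frames


def synth_dotblot(phantom: DotBlotPhantom) -> np.ndarray:
    """Render a dot-blot membrane image (8-bit grayscale).

    Spot interiors (disk masks, no anti-aliasing) sit at
    ``background_mean - darkness_per_unit * concentration``; the rest of
    the membrane is at ``background_mean``; Gaussian pixel noise of SD
    ``background_sd`` is added everywhere.
    """
    rng = np.random.default_rng(phantom.seed)
    h, w = phantom.image_size
    img = np.full((h, w), float(phantom.background_mean))
    yy, xx = np.mgrid[0:h, 0:w]
    for (r, c), conc in zip(phantom.spot_centers, phantom.concentrations):
        darkness = min(phantom.darkness_per_unit * conc, phantom.background_mean)
        mask = (yy - r) ** 2 + (xx - c) ** 2 <= phantom.spot_radius ** 2
        img[mask] = phantom.background_mean - darkness
    if phantom.background_sd > 0:
        img += rng.normal(0.0, phantom.background_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def synth_brain_stack(bp: BrainPhantomParams) -> np.ndarray:
    """Render a brain phantom stack (slices, height, width), 8-bit.

    Uniform at ``surround_intensity`` except that in ``dimmed_slices`` the
    pedunculus disk carries intensity ``ped_contrast * surround_intensity``.
    """
    rng = np.random.default_rng(bp.seed)
    nz, ny, nx = bp.stack_size
    stack = np.full((nz, ny, nx), float(bp.surround_intensity))
    yy, xx = np.mgrid[0:ny, 0:nx]
    r, c = bp.ped_center
    mask = (yy - r) ** 2 + (xx - c) ** 2 <= bp.ped_radius ** 2
    for z in bp.dimmed_slices:
        sl = stack[z]
        sl[mask] = bp.ped_contrast * bp.surround_intensity
    if bp.noise_sd > 0:
        stack += rng.normal(0.0, bp.noise_sd, stack.shape)
    return np.clip(np.rint(stack), 0, 255).astype(np.uint8)
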