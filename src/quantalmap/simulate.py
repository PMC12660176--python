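"""Synthetic NMJ generator: geometry, puncta stacks, quantal movies, photoconversion.

The simulator stands in for raw microscopy of *Drosophila* larval
neuromuscular junctions (NMJs).  It produces

* a :class:`GroundTruth` geometry — active zones (AZs) grouped into synaptic
  boutons, each AZ opposed by a postsynaptic density (PSD), with a true evoked
  release probability (Pr), a true spontaneous fusion rate, a synapse age and a
  Cac (Ca_v2 channel) occupancy flag;
* rendered multi-plane puncta Z-stacks (Gaussian spots + noise) for any
  AZ/PSD channel;
* single-plane GCaMP time-lapse movies with 1 Hz nerve stimulation, Bernoulli
  evoked flashes per AZ and Poisson spontaneous flashes, together with the
  ground-truth event log;
* two-channel photoconversion pulse-chase series in which the red ("old")
  channel decays as 2**(-t/half_life) and the green ("new") channel
  accumulates linearly.

All randomness flows through :class:`numpy.random.SeedSequence` children of a
single integer seed, so every artefact is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_PIXEL_SIZE = 0.133  # um/px, typical 60x objective + EMCCD
AGE_MAX_DAYS = 6.0  # larval development window
SPONT_FLOOR_PER_MIN = 0.1  # Cac-negative sites stay spontaneous-capable

# Fixed spawn order for per-call random sub-streams (documented contract).
_STREAM_GEOMETRY, _STREAM_PR, _STREAM_SPONT, _STREAM_MISC = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """True NMJ geometry and per-synapse parameters.

    Positions are in um from the field origin (x = column direction,
    y = row direction); ``field_shape`` is (rows, cols) in pixels.
    """

    az_centroids: np.ndarray      # (n_az, 2) um, columns (x, y)
    psd_centroids: np.ndarray     # (n_psd, 2) um; first n_az rows oppose AZs
    true_pr: np.ndarray           # (n_az,) in [0, 1]
    true_spont_rate: np.ndarray   # (n_az,) events/min, >= 0
    age_days: np.ndarray          # (n_az,) >= 0
    cac_positive: np.ndarray      # (n_az,) bool
    bouton_index: np.ndarray      # (n_az,) int, terminal bouton = 0
    pixel_size: float
    field_shape: tuple[int, int]
    seed: int

    def __post_init__(self) -> None:
        for name in ("az_centroids", "psd_centroids", "true_pr",
                     "true_spont_rate", "age_days", "cac_positive",
                     "bouton_index"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if np.any(self.true_pr < 0) or np.any(self.true_pr > 1):
            raise ValueError("true_pr must lie in [0, 1]")
        if np.any(self.true_spont_rate < 0):
            raise ValueError("spontaneous rates must be >= 0")
        if np.any(self.age_days < 0):
            raise ValueError("ages must be >= 0")
        if np.any(self.true_pr[~self.cac_positive.astype(bool)] > 0):
            raise ValueError("Cac-negative AZs cannot have evoked Pr > 0")
        ny, nx = self.field_shape
        for pts in (self.az_centroids, self.psd_centroids):
            if len(pts) and (
                np.any(pts < 0)
                or np.any(pts[:, 0] > nx * self.pixel_size)
                or np.any(pts[:, 1] > ny * self.pixel_size)
            ):
                raise ValueError("centroids must lie inside the field bounds")

    @property
    def n_az(self) -> int:
        return len(self.az_centroids)

    def to_frame(self) -> pd.DataFrame:
        """Sidecar table, one row per AZ."""
        return pd.DataFrame({
            "az_id": np.arange(self.n_az),
            "x_um": self.az_centroids[:, 0],
            "y_um": self.az_centroids[:, 1],
            "true_pr": self.true_pr,
            "spont_per_min": self.true_spont_rate,
            "age_days": self.age_days,
            "cac_positive": self.cac_positive.astype(bool),
            "bouton_index": self.bouton_index,
        })


@dataclass(frozen=True)
class MovieSpec:
    """Acquisition/stimulation protocol for a quantal-imaging movie."""

    frame_rate: float = 8.0        # Hz
    stim_rate: float = 1.0         # Hz
    duration: float = 180.0        # s ("3-5 min" protocol)
    flash_amplitude: float = 60.0  # dF units above background
    flash_sigma: float = 0.3       # um, spatial spread of one quantal flash
    flash_decay_frames: int = 3    # frames; geometric decay, ratio flash_decay_ratio
    flash_decay_ratio: float = 0.4
    noise_sd: float = 10.0         # per-pixel Gaussian noise
    background: float = 100.0

    def validate(self) -> None:
        if not (self.frame_rate > self.stim_rate > 0):
            raise ValueError("require frame_rate > stim_rate > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.flash_amplitude <= 0:
            raise ValueError("flash_amplitude must be > 0")
        if self.flash_decay_frames < 1:
            raise ValueError("flash_decay_frames must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def n_stimulations(self) -> int:
        return int(np.floor(self.duration * self.stim_rate))

    def stim_frames(self) -> np.ndarray:
        """Frame index of each stimulus: floor(t_stim * frame_rate)."""
        t = np.arange(self.n_stimulations) / self.stim_rate
        return np.floor(t * self.frame_rate).astype(int)


# ---------------------------------------------------------------------------
# named distributions
# ---------------------------------------------------------------------------

def _draw(dist, rng: np.random.Generator, n: int,
          age_days: np.ndarray | None = None) -> np.ndarray:
    """Draw n values from a named distribution spec ``(name, params)``.

    Supported: constant {value}, uniform {low, high}, beta {a, b, scale},
    exponential {mean}, and (Pr only) age_linear {slope, intercept, noise_sd}
    which models maturation as Pr increasing with synapse age.
    """
    if isinstance(dist, (int, float)):
        dist = ("constant", {"value": float(dist)})
    name, params = dist
    if name == "constant":
        v = float(params["value"])
        if v < 0:
            raise ValueError("constant value must be >= 0")
        return np.full(n, v)
    if name == "uniform":
        low, high = float(params["low"]), float(params["high"])
        if not (0 <= low <= high):
            raise ValueError("uniform requires 0 <= low <= high")
        return rng.uniform(low, high, n)
    if name == "beta":
        a, b = float(params["a"]), float(params["b"])
        scale = float(params.get("scale", 1.0))
        if a <= 0 or b <= 0 or scale <= 0:
            raise ValueError("beta requires a, b, scale > 0")
        return scale * rng.beta(a, b, n)
    if name == "exponential":
        mean = float(params["mean"])
        if mean < 0:
            raise ValueError("exponential mean must be >= 0")
        return rng.exponential(mean, n) if mean > 0 else np.zeros(n)
    if name == "age_linear":
        if age_days is None:
            raise ValueError("age_linear distribution needs synapse ages")
        slope = float(params["slope"])
        intercept = float(params.get("intercept", 0.0))
        noise_sd = float(params.get("noise_sd", 0.0))
        v = intercept + slope * age_days + rng.normal(0.0, noise_sd, n)
        return np.clip(v, 0.0, 1.0)
    raise ValueError(f"unknown distribution {name!r}")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _place_in_disk(rng: np.random.Generator, center: np.ndarray, radius: float,
                   n: int, min_spacing: float) -> np.ndarray:
    """Dart-throwing placement of n points in a disk with a spacing floor."""
    pts: list[np.ndarray] = []
    for _ in range(4000 * n):
        r = radius * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        p = center + r * np.array([np.cos(th), np.sin(th)])
        if all(np.hypot(*(p - q)) >= min_spacing for q in pts):
            pts.append(p)
            if len(pts) == n:
                return np.array(pts)
    raise ValueError(
        f"cannot place {n} AZs with spacing {min_spacing} um in a "
        f"{radius:.2f} um bouton; reduce az_per_bouton or min_spacing")


def make_geometry(
    n_boutons: int,
    az_per_bouton: int,
    pr_distribution=("uniform", {"low": 0.02, "high": 0.5}),
    spont_distribution=("uniform", {"low": 0.2, "high": 2.0}),
    cac_negative_fraction: float = 0.1,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    seed: int = 0,
    *,
    min_spacing: float = 1.0,
    growth_mode: str = "stretching",
    psd_jitter_um: float = 0.05,
    orphan_psd_fraction: float = 0.0,
    age_max: float = AGE_MAX_DAYS,
) -> GroundTruth:
    """Generate a ground-truth NMJ.

    Boutons are disks chained along the terminal axis; bouton 0 is the
    terminal bouton.  ``growth_mode`` sets how synapse age maps onto bouton
    position: ``"stretching"`` (new boutons intercalate internally, so the
    terminal bouton is enriched for old synapses, the M6/7 pattern) or
    ``"budding"`` (new boutons bud from the end, the M4 pattern).

    Cac-negative AZs model immature sites lacking Ca channels: their evoked
    Pr is forced to 0 while their spontaneous rate stays positive.
    """
    if n_boutons < 1 or az_per_bouton < 1:
        raise ValueError("counts must be >= 1")
    if not 0 <= cac_negative_fraction <= 1:
        raise ValueError("cac_negative_fraction must be in [0, 1]")
    if not 0 <= orphan_psd_fraction <= 1:
        raise ValueError("orphan_psd_fraction must be in [0, 1]")
    if growth_mode not in ("stretching", "budding"):
        raise ValueError("growth_mode must be 'stretching' or 'budding'")

    streams = np.random.SeedSequence(seed).spawn(4)
    rng_geo = np.random.default_rng(streams[_STREAM_GEOMETRY])
    rng_pr = np.random.default_rng(streams[_STREAM_PR])
    rng_spont = np.random.default_rng(streams[_STREAM_SPONT])
    rng_misc = np.random.default_rng(streams[_STREAM_MISC])

    n_az = n_boutons * az_per_bouton
    bouton_radius = max(1.5, 0.75 * np.sqrt(az_per_bouton) * min_spacing)
    margin = 2.0
    pitch = 2 * bouton_radius + 0.6

    az = np.empty((n_az, 2))
    bouton_index = np.repeat(np.arange(n_boutons), az_per_bouton)
    for b in range(n_boutons):
        cx = margin + bouton_radius + b * pitch
        cy = margin + bouton_radius + rng_geo.normal(0, 0.3)
        pts = _place_in_disk(rng_geo, np.array([cx, cy]), bouton_radius,
                             az_per_bouton, min_spacing)
        az[bouton_index == b] = pts

    psd = az + rng_geo.normal(0.0, psd_jitter_um, az.shape)
    n_orphan = int(round(orphan_psd_fraction * n_az))
    if n_orphan:
        extent = az.max(axis=0) + margin
        orphans = rng_geo.uniform([margin, margin], extent, (n_orphan, 2))
        psd = np.vstack([psd, orphans])

    ny = int(np.ceil((max(az[:, 1].max(), psd[:, 1].max()) + margin) / pixel_size))
    nx = int(np.ceil((max(az[:, 0].max(), psd[:, 0].max()) + margin) / pixel_size))

    # Age: per-bouton mean ages encode the growth mode, clipped to [0, age_max].
    if n_boutons == 1:
        bouton_mean_age = np.array([age_max / 2])
    else:
        ramp = np.linspace(age_max * 0.85, age_max * 0.15, n_boutons)
        bouton_mean_age = ramp if growth_mode == "stretching" else ramp[::-1]
    age = np.clip(
        rng_misc.normal(bouton_mean_age[bouton_index], age_max / 4), 0, age_max)

    pr = np.clip(_draw(pr_distribution, rng_pr, n_az, age_days=age), 0.0, 1.0)
    spont = np.maximum(_draw(spont_distribution, rng_spont, n_az), 0.0)

    cac_positive = rng_misc.uniform(size=n_az) >= cac_negative_fraction
    pr[~cac_positive] = 0.0
    spont[~cac_positive] = np.maximum(spont[~cac_positive], SPONT_FLOOR_PER_MIN)

    return GroundTruth(az, psd, pr, spont, age, cac_positive, bouton_index,
                       pixel_size, (ny, nx), seed)


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _add_gaussian_spot(img: np.ndarray, x_um: float, y_um: float,
                       amplitude: float, sigma_um: float,
                       pixel_size: float) -> None:
    """Add a 2D Gaussian of peak ``amplitude`` in place; 5-sigma support."""
    ny, nx = img.shape
    s_px = sigma_um / pixel_size
    cx, cy = x_um / pixel_size, y_um / pixel_size  # continuous px coords
    half = int(np.ceil(5 * s_px))
    j0, j1 = max(0, int(cx - half)), min(nx, int(cx + half) + 2)
    i0, i1 = max(0, int(cy - half)), min(ny, int(cy + half) + 2)
    if j0 >= j1 or i0 >= i1:
        return
    jj = np.arange(j0, j1) + 0.5  # pixel centers
    ii = np.arange(i0, i1) + 0.5
    gx = np.exp(-((jj - cx) ** 2) / (2 * s_px ** 2))
    gy = np.exp(-((ii - cy) ** 2) / (2 * s_px ** 2))
    img[i0:i1, j0:j1] += amplitude * np.outer(gy, gx)


def _render_stack(centroids: np.ndarray, amplitudes: np.ndarray,
                  field_shape: tuple[int, int], pixel_size: float,
                  psf_sigma: float, noise_sd: float, n_planes: int,
                  background: float, rng: np.random.Generator,
                  z_planes: np.ndarray | None = None) -> np.ndarray:
    """Render a Z-stack of Gaussian spots.

    Each spot sits at an integer focal plane (drawn uniformly unless
    ``z_planes`` pins it) with a Gaussian axial profile (sigma = 1 plane),
    so the max projection carries the full peak amplitude.
    """
    ny, nx = field_shape
    stack = np.full((n_planes, ny, nx), background, dtype=np.float64)
    if len(centroids):
        z = (rng.integers(0, n_planes, len(centroids))
             if z_planes is None else np.asarray(z_planes))
        for (x, y), amp, zi in zip(centroids, amplitudes, z):
            if not (0 <= x <= nx * pixel_size and 0 <= y <= ny * pixel_size):
                raise ValueError(f"centroid ({x:.2f}, {y:.2f}) outside field")
            for p in range(n_planes):
                w = np.exp(-((p - zi) ** 2) / 2.0)
                if w > 1e-4:
                    _add_gaussian_spot(stack[p], x, y, amp * w,
                                       psf_sigma, pixel_size)
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, stack.shape)
    return stack.astype(np.float32)


def default_spot_values(gt: GroundTruth, channel: str) -> np.ndarray:
    """Per-synapse intensity units for a named channel.

    ``glur_red`` scales with synapse age (photoconverted receptor pool),
    ``cac`` is zero at Cac-negative AZs, everything else is uniform.
    """
    if channel == "glur_red":
        return gt.age_days.astype(float)
    if channel == "cac":
        return gt.cac_positive.astype(float)
    return np.ones(gt.n_az)


def render_puncta_stack(
    gt: GroundTruth,
    channel: str = "az",
    intensity_per_unit: float = 100.0,
    psf_sigma: float = 0.2,
    noise_sd: float = 5.0,
    n_planes: int = 5,
    seed: int = 0,
    *,
    per_spot_intensity: np.ndarray | None = None,
    background: float = 10.0,
    z_planes: np.ndarray | None = None,
) -> np.ndarray:
    """Render one channel of the NMJ as a multi-plane Z-stack.

    PSD channels (``glur_red``, ``glur_green``, ``psd``) are rendered at the
    PSD centroids, all others at the AZ centroids.  Spot peak amplitude is
    ``intensity_per_unit * per_spot_intensity`` (defaults per channel from
    :func:`default_spot_values`).
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    use_psd = channel in ("glur_red", "glur_green", "psd")
    centroids = gt.psd_centroids if use_psd else gt.az_centroids
    if per_spot_intensity is None:
        values = default_spot_values(gt, channel)
        if use_psd and len(centroids) > gt.n_az:  # orphan PSDs render at unit
            values = np.concatenate([values, np.ones(len(centroids) - gt.n_az)])
    else:
        values = np.asarray(per_spot_intensity, dtype=float)
    channel_salt = zlib.crc32(channel.encode()) % (2 ** 31)
    rng = np.random.default_rng(np.random.SeedSequence([seed, channel_salt]))
    return _render_stack(centroids, intensity_per_unit * values,
                         gt.field_shape, gt.pixel_size, psf_sigma, noise_sd,
                         n_planes, background, rng, z_planes)


# ---------------------------------------------------------------------------
# quantal movie
# ---------------------------------------------------------------------------

def simulate_quantal_movie(
    gt: GroundTruth,
    spec: MovieSpec | None = None,
    seed: int = 0,
    *,
    render: bool = True,
) -> tuple[np.ndarray | None, pd.DataFrame, dict]:
    """Simulate a GCaMP quantal-imaging movie and its ground-truth event log.

    At each stimulus frame every AZ flashes independently with probability
    ``true_pr``; spontaneous flashes follow per-AZ Poisson processes and land
    on non-stimulus frames.  Each flash is an additive 2D Gaussian with a
    single-frame rise and geometric decay over ``flash_decay_frames`` frames.

    Returns ``(movie, events, info)``; ``movie`` is None when ``render`` is
    False (event log only).  ``events`` has columns frame, az_id, x_um, y_um,
    kind ('evoked'|'spontaneous').
    """
    spec = spec or MovieSpec()
    spec.validate()
    n_frames = spec.n_frames
    stim_frames = spec.stim_frames()
    streams = np.random.SeedSequence(seed).spawn(gt.n_az + 1)
    rng_global = np.random.default_rng(streams[0])

    non_stim = np.setdiff1d(np.arange(n_frames), stim_frames)
    rows: list[tuple] = []
    for i in range(gt.n_az):
        rng = np.random.default_rng(streams[i + 1])  # per-AZ sub-stream
        hits = rng.uniform(size=len(stim_frames)) < gt.true_pr[i]
        for f in stim_frames[hits]:
            rows.append((int(f), i, "evoked"))
        n_spont = rng.poisson(gt.true_spont_rate[i] * spec.duration / 60.0)
        if n_spont and len(non_stim):
            for f in rng.choice(non_stim, size=n_spont, replace=True):
                rows.append((int(f), i, "spontaneous"))

    events = pd.DataFrame(rows, columns=["frame", "az_id", "kind"])
    events["x_um"] = gt.az_centroids[events["az_id"], 0] if len(events) else []
    events["y_um"] = gt.az_centroids[events["az_id"], 1] if len(events) else []
    events = events.sort_values(["frame", "az_id"], kind="stable",
                                ignore_index=True)
    events = events[["frame", "az_id", "x_um", "y_um", "kind"]]

    info = {
        "n_frames": n_frames,
        "n_stimulations": spec.n_stimulations,
        "stim_frames": stim_frames,
        "duration": spec.duration,
        "frame_rate": spec.frame_rate,
    }
    if not render:
        return None, events, info

    ny, nx = gt.field_shape
    movie = np.full((n_frames, ny, nx), spec.background, dtype=np.float64)
    ratios = spec.flash_decay_ratio ** np.arange(spec.flash_decay_frames)
    for frame, az_id in zip(events["frame"].to_numpy(),
                            events["az_id"].to_numpy()):
        x, y = gt.az_centroids[az_id]
        for j, r in enumerate(ratios):
            if frame + j >= n_frames:
                break
            _add_gaussian_spot(movie[frame + j], x, y,
                               spec.flash_amplitude * r, spec.flash_sigma,
                               gt.pixel_size)
    if spec.noise_sd > 0:
        movie += rng_global.normal(0.0, spec.noise_sd, movie.shape)
    return movie.astype(np.float32), events, info


# ---------------------------------------------------------------------------
# photoconversion pulse-chase
# ---------------------------------------------------------------------------

@dataclass
class PhotoconversionSeries:
    """Two-channel stacks per chase timepoint plus the generative truth."""

    timepoints: list[float]                  # days
    red_stacks: list[np.ndarray]             # photoconverted ("old") channel
    green_stacks: list[np.ndarray]           # newly delivered ("new") channel
    red_true: np.ndarray                     # (n_t, n_spots) true red peaks
    green_true: np.ndarray                   # (n_t, n_spots)
    pre_pc_green: np.ndarray                 # (n_spots,) pre-conversion pool
    half_life_days: float


def simulate_photoconversion_series(
    gt: GroundTruth,
    half_life_days: float,
    timepoints,
    delivery_rate: float = 30.0,
    seed: int = 0,
    *,
    channel: str = "psd",
    abundance_mean: float = 100.0,
    abundance_sigma: float = 0.3,
    intensity_scale: float = 1.0,
    psf_sigma: float = 0.2,
    noise_sd: float = 5.0,
    n_planes: int = 5,
) -> PhotoconversionSeries:
    """Simulate a photoconversion pulse-chase of one NMJ.

    At t=0 the entire green pool converts to red (red(0) equals the pre-PC
    green total and the green channel restarts at ~0).  The red channel then
    decays as ``2**(-t/half_life_days)`` (first-order turnover) while green
    signal accumulates at ``delivery_rate`` intensity units/day per synapse.
    The same geometry is imaged at every timepoint (longitudinal series).
    """
    timepoints = [float(t) for t in timepoints]
    if any(t < 0 for t in timepoints):
        raise ValueError("timepoints must be >= 0")
    if sorted(timepoints) != timepoints:
        raise ValueError("timepoints must be sorted ascending")
    if half_life_days <= 0:
        raise ValueError("half_life_days must be > 0")

    centroids = (gt.psd_centroids if channel in ("psd", "glur_red", "glur_green")
                 else gt.az_centroids)
    n = len(centroids)
    streams = np.random.SeedSequence(seed).spawn(2 + 2 * len(timepoints))
    rng0 = np.random.default_rng(streams[0])
    pre_pc_green = intensity_scale * rng0.lognormal(
        np.log(abundance_mean), abundance_sigma, n)
    # each synapse keeps its focal plane across the whole series
    z_planes = rng0.integers(0, n_planes, n)

    red_true = np.empty((len(timepoints), n))
    green_true = np.empty((len(timepoints), n))
    red_stacks, green_stacks = [], []
    for k, t in enumerate(timepoints):
        red_true[k] = pre_pc_green * 2.0 ** (-t / half_life_days)
        green_true[k] = intensity_scale * delivery_rate * t
        rng_r = np.random.default_rng(streams[2 + 2 * k])
        rng_g = np.random.default_rng(streams[3 + 2 * k])
        red_stacks.append(_render_stack(
            centroids, red_true[k], gt.field_shape, gt.pixel_size,
            psf_sigma, noise_sd, n_planes, 10.0, rng_r, z_planes))
        green_stacks.append(_render_stack(
            centroids, green_true[k], gt.field_shape, gt.pixel_size,
            psf_sigma, noise_sd, n_planes, 10.0, rng_g, z_planes))
    return PhotoconversionSeries(timepoints, red_stacks, green_stacks,
                                 red_true, green_true, pre_pc_green,
                                 half_life_days)
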