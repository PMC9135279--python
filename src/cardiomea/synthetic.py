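"""Synthetic MEA recordings and quiescent-period samples with ground truth.

Every estimator in this package is exercised against data whose answer is
known by construction. The recording generator places a field-potential
template at each electrode with a propagation delay

    t(e, b) = beat_time(b) + ||coords(e) - origin(b)|| / speed,

i.e. a radially spreading wave from a scripted per-beat origin at constant
speed, at a constant beat rate. The template is the sum of a sharp biphasic
R-complex (two narrow Gaussians of opposite sign, the negative lobe
dominant, matching the usual extracellular polarity) and a slower, smaller
Gaussian T-wave at a fixed latency. White Gaussian noise of chosen sigma is
added; designated faulty electrodes emit noise only. The signal-to-noise
ratio is R-peak magnitude over noise sigma.

Ground truth is computed from the template itself, once, on a fine
(0.01 ms) grid: the true R-peak time, maximum upstroke slope, intrinsicoid
(LAT) offset, T-peak time and trapezoid-method T endpoint. These are
analytic in the sense that they do not depend on the recording's sampling
grid or noise, only on the template parameters.

Quiescent-period samplers provide independent draws from each heavy-tailed
family (inverse-CDF sampling; rejection sampling for the exponentially
cut-off power law), serving as oracles for the fitting module.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ElectrodeConfig
from .io import Recording

__all__ = [
    "TemplateSpec",
    "SimSpec",
    "GroundTruth",
    "template_landmarks",
    "generate_recording",
    "write_ascii",
    "sample_quiescent_periods",
]


@dataclass(frozen=True)
class TemplateSpec:
    """Field-potential template: biphasic R-complex plus Gaussian T-wave.

    Amplitudes in uV, times in ms. The R-complex is
    ``r_pos * G(t + 3*r_sigma) - r_neg * G(t)`` with G a unit Gaussian of
    width ``r_sigma``; the T-wave is ``t_amp * G_t(t - t_latency)`` with
    width ``t_sigma``.
    """

    r_pos: float = 120.0
    r_neg: float = 300.0
    r_sigma: float = 3.0
    t_amp: float = 150.0
    t_sigma: float = 40.0
    t_latency: float = 250.0  # T-peak latency after the R trough, ms

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the template at times t (ms, R trough near t = 0)."""
        t = np.asarray(t, dtype=float)
        g = lambda x, s: np.exp(-0.5 * (x / s) ** 2)
        return (
            self.r_pos * g(t + 3.0 * self.r_sigma, self.r_sigma)
            - self.r_neg * g(t, self.r_sigma)
            + self.t_amp * g(t - self.t_latency, self.t_sigma)
        )

    @property
    def span(self) -> tuple[float, float]:
        """Support of the template (ms relative to the R trough), generous."""
        return (-6.0 * self.r_sigma - 5.0, self.t_latency + 5.0 * self.t_sigma)


@dataclass(frozen=True)
class TemplateLandmarks:
    """True template timings (ms, relative to the scheduled beat time) and slopes."""

    r_peak: float  # R trough location (the detected "peak" on the oriented trace)
    r_amplitude: float  # max - min over the R window, uV
    dvdt_max: float  # max upstroke slope of the oriented trace before the peak, uV/ms
    lat: float  # intrinsicoid offset: max negative derivative after the peak
    t_peak: float
    t_end: float  # trapezoid-method endpoint (150 ms distal point)
    fpd: float  # t_end - r_peak


def template_landmarks(
    tpl: TemplateSpec, r_offset_ms: float = 150.0, resolution_ms: float = 0.01
) -> TemplateLandmarks:
    """Numerically exact landmarks of a template on a fine reference grid."""
    lo, hi = tpl.span
    t = np.arange(lo, hi + r_offset_ms, resolution_ms)
    v = tpl(t)
    w = -v  # oriented: dominant lobe positive
    ipk = int(np.argmax(w))
    r_peak = float(t[ipk])
    d = np.diff(w) / resolution_ms
    pre = d[: ipk]
    dvdt = float(np.max(pre))
    # LAT: max negative derivative after the peak, within the R downstroke
    win = int(round(min(150.0, 6 * tpl.r_sigma + 20) / resolution_ms))
    lat_idx = ipk + 1 + int(np.argmin(d[ipk : ipk + win]))
    lat = float(t[lat_idx])
    # T landmarks on the raw trace
    mask = t > r_peak + 50.0
    it = int(np.argmax(np.abs(v * mask)))
    t_peak = float(t[it])
    sign = 1.0 if v[it] >= 0 else -1.0
    ir = int(np.argmin(np.abs(t - (t_peak + r_offset_ms))))
    wv = sign * v
    dd = np.diff(wv[it : ir + 1]) / resolution_ms
    im = it + 1 + int(np.argmin(dd))
    x_m, y_m = t[im], wv[im]
    x_r = t[ir]
    xi, yi = t[im : ir + 1], wv[im : ir + 1]
    area = 0.5 * (y_m - yi) * (2.0 * x_r - xi - x_m)
    t_end = float(t[im + int(np.argmax(area))])
    amp_win = (t > r_peak - 25.0) & (t < r_peak + 25.0)
    return TemplateLandmarks(
        r_peak=r_peak,
        r_amplitude=float(v[amp_win].max() - v[amp_win].min()),
        dvdt_max=dvdt,
        lat=lat,
        t_peak=t_peak,
        t_end=t_end,
        fpd=t_end - r_peak,
    )


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one synthetic recording.

    ``origin_path`` maps beat ranges to origins: a list of
    ``((first_beat, last_beat), (x_um, y_um))`` entries covering beats 0..n-1.
    Speed is the radial conduction speed in um/ms; ``noise_sigma`` the white
    noise level in uV (S/N = r_neg / noise_sigma).
    """

    cfg: ElectrodeConfig
    origin_path: tuple[tuple[tuple[int, int], tuple[float, float]], ...]
    speed: float = 300.0
    bpm: float = 40.0
    n_beats: int = 10
    template: TemplateSpec = field(default_factory=TemplateSpec)
    noise_sigma: float = 0.0
    faulty_electrodes: frozenset[str] = frozenset()
    seed: int = 0
    fs_hz: float = 1000.0

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.bpm <= 0 or self.n_beats < 1:
            raise ValueError("speed, bpm and n_beats must be positive")
        x0, y0, x1, y1 = self.cfg.bounding_box
        covered: set[int] = set()
        for (b0, b1), (x, y) in self.origin_path:
            if not (x0 <= x <= x1 and y0 <= y <= y1):
                raise ValueError(f"origin ({x}, {y}) outside the array bounds")
            covered.update(range(b0, b1 + 1))
        if covered != set(range(self.n_beats)):
            raise ValueError("origin_path must cover beats 0..n_beats-1 exactly")

    def origin_of_beat(self, b: int) -> tuple[float, float]:
        for (b0, b1), xy in self.origin_path:
            if b0 <= b <= b1:
                return xy
        raise ValueError(f"beat {b} not covered by origin_path")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows: scheduled times are exact by construction."""

    beat_times: np.ndarray  # scheduled R times at the origin, ms
    peak_times: np.ndarray  # beats x electrodes true R-trough times, ms
    lat_times: np.ndarray  # beats x electrodes true intrinsicoid times, ms
    t_end_times: np.ndarray  # beats x electrodes true T endpoints, ms
    origins: np.ndarray  # beats x 2, um
    landmarks: TemplateLandmarks
    spec: SimSpec

    @property
    def fpd(self) -> float:
        return self.landmarks.fpd


def generate_recording(spec: SimSpec) -> tuple[Recording, GroundTruth]:
    """Simulate a propagating-wave MEA recording; identical seed, identical output."""
    cfg = spec.cfg
    tpl = spec.template
    lm = template_landmarks(tpl)
    period = 60000.0 / spec.bpm
    span_lo, span_hi = tpl.span
    if span_hi - span_lo >= period:
        raise ValueError(
            f"template ({span_hi - span_lo:.0f} ms) does not fit the beat period "
            f"({period:.0f} ms): lower bpm or shorten the template"
        )
    dt = 1000.0 / spec.fs_hz
    coords = np.array([cfg.coords[l] for l in cfg.labels])
    beat_times = 500.0 + period * np.arange(spec.n_beats)
    origins = np.array([spec.origin_of_beat(b) for b in range(spec.n_beats)])
    # max propagation delay across the array
    max_delay = cfg.diagonal / spec.speed
    t_total = beat_times[-1] + max_delay + span_hi + 200.0
    time = np.arange(0.0, t_total, dt)
    volts = np.zeros((cfg.n_electrodes, time.size))
    delays = np.hypot(
        coords[None, :, 0] - origins[:, None, 0],
        coords[None, :, 1] - origins[:, None, 1],
    ) / spec.speed  # beats x electrodes
    arrivals = beat_times[:, None] + delays
    for b in range(spec.n_beats):
        for e in range(cfg.n_electrodes):
            t0 = arrivals[b, e]
            i0 = max(0, int((t0 + span_lo) / dt))
            i1 = min(time.size, int((t0 + span_hi + 160.0) / dt) + 1)
            volts[e, i0:i1] += tpl(time[i0:i1] - t0)
    rng = np.random.default_rng(spec.seed)
    for e, label in enumerate(cfg.labels):
        if label in spec.faulty_electrodes:
            volts[e] = 0.0
    if spec.noise_sigma > 0 or spec.faulty_electrodes:
        noise = rng.normal(0.0, max(spec.noise_sigma, 1e-12), volts.shape)
        volts += noise
    rec = Recording(time=time, voltages=volts, cfg=cfg, source=f"<synthetic seed={spec.seed}>")
    gt = GroundTruth(
        beat_times=beat_times,
        peak_times=arrivals + lm.r_peak,
        lat_times=arrivals + lm.lat,
        t_end_times=arrivals + lm.t_end,
        origins=origins,
        landmarks=lm,
        spec=spec,
    )
    return rec, gt


def write_ascii(rec: Recording, path: str | os.PathLike) -> None:
    """Write a recording in the column-wise ASCII dialect the reader accepts.

    One header line with column names, then tab-separated numeric rows;
    values keep 10 significant figures so a write/read round trip is exact to
    well beyond 6 significant figures.
    """
    header = "t[ms]\t" + "\t".join(rec.cfg.labels)
    data = np.column_stack([rec.time, rec.voltages.T])
    np.savetxt(path, data, fmt="%.10g", delimiter="\t", header=header, comments="")


def radial_spec(
    cfg: ElectrodeConfig,
    origin: tuple[float, float],
    *,
    speed: float = 300.0,
    bpm: float = 40.0,
    n_beats: int = 10,
    noise_sigma: float = 0.0,
    seed: int = 0,
    **kw,
) -> SimSpec:
    """Convenience: a single stationary origin for all beats."""
    return SimSpec(
        cfg=cfg, origin_path=(((0, n_beats - 1), origin),),
        speed=speed, bpm=bpm, n_beats=n_beats, noise_sigma=noise_sigma, seed=seed, **kw,
    )


# ---------------------------------------------------------------------------
# quiescent-period samplers (independent oracles for the fitting module)


def sample_quiescent_periods(
    family: str, params: dict[str, float], n: int, seed: int
) -> np.ndarray:
    """Draw a quiescent-period sample from a named heavy-tailed family.

    Families and parameters (all tails start at ``xmin``):

    * ``power_law``: alpha, xmin — inverse CDF ``xmin * (1-u)^(-1/(alpha-1))``
    * ``exponential``: lam, xmin — shifted exponential
    * ``lognormal``: mu, sigma, xmin — inverse CDF of the conditioned tail
    * ``weibull`` / ``stretched_exponential``: beta, lam, xmin — likewise
    * ``truncated_power_law``: alpha, lam, xmin — rejection from a power-law
      proposal with acceptance ``exp(-lam * (x - xmin))``
    """
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    xmin = float(params.get("xmin", 1.0))
    if family == "power_law":
        a = params["alpha"]
        u = rng.random(n)
        return xmin * (1.0 - u) ** (-1.0 / (a - 1.0))
    if family == "exponential":
        return xmin + rng.exponential(1.0 / params["lam"], n)
    if family == "lognormal":
        from scipy.stats import lognorm

        dist = lognorm(s=params["sigma"], scale=np.exp(params["mu"]))
        sf0 = dist.sf(xmin)
        u = rng.random(n)
        return dist.ppf(1.0 - u * sf0)
    if family in ("weibull", "stretched_exponential"):
        beta, lam = params["beta"], params["lam"]
        z0 = (xmin / lam) ** beta
        u = rng.random(n)
        return lam * (z0 - np.log(1.0 - u)) ** (1.0 / beta)
    if family == "truncated_power_law":
        a, lam = params["alpha"], params["lam"]
        out = np.empty(0)
        while out.size < n:
            m = max(4 * (n - out.size), 1000)
            u = rng.random(m)
            x = xmin * (1.0 - u) ** (-1.0 / (a - 1.0)) if a > 1 else None
            if x is None:
                raise ValueError("rejection sampler needs alpha > 1")
            acc = rng.random(m) < np.exp(-lam * (x - xmin))
            out = np.concatenate([out, x[acc]])
        return out[:n]
    raise ValueError(f"unknown family {family!r}")
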