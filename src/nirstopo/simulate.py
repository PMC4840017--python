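"""Synthetic multi-subject fNIRS datasets with known ground truth.

Emulates an event-related colour-word Stroop protocol on a 52-channel
prefrontal probe: 80 frequent (congruent) and 20 rare (incongruent) events
with inter-stimulus intervals uniform in 9-12 s, sampled at 10 Hz.  Per
subject, active channels carry an HRF-convolved response whose amplitude is
w_n = w_pop + z_n with z_n ~ N(0, sigma_b^2) (between-subject variability),
on top of AR(1) noise and sinusoidal cardiac/respiratory components whose
frequencies sit inside the preprocessing stopbands.

All randomness flows through one seeded generator with named substreams
(events, noise, subjects), so a master seed reproduces a dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import lfilter

from .first_level import EventTable, HrfParams, canonical_hrf
from .optics import HbSeries
from .scalp import ProbeLayout, disc_to_sphere

__all__ = [
    "SimulationTruth",
    "stroop_probe_layout",
    "simulate_events",
    "simulate_subject",
    "simulate_group",
]

#: ratio of the HbR to the HbO evoked amplitude (opposite sign, smaller)
_HBR_RATIO = -0.35


@dataclass
class SimulationTruth:
    """Generative parameters of the synthetic group study.

    Amplitudes are in mM of HbO (typical evoked oxy-hemoglobin changes are a
    few micromolar); sigma_w is the stationary SD of the AR(1) channel noise,
    sigma_b the between-subject SD of the effect amplitude.
    """

    active_channels: list[str] = field(
        default_factory=lambda: ["CH14", "CH15", "CH35"]
    )
    effect_size: dict[str, float] = field(
        default_factory=lambda: {"congruent": 0.002, "incongruent": 0.004}
    )
    sigma_w: float = 0.002
    sigma_b: float = 0.002
    rho: float = 0.5
    physio: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.001, 1.1), (0.001, 0.25)]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_w < 0 or self.sigma_b < 0:
            raise ValueError("noise SDs must be >= 0")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")

    def to_dict(self) -> dict:
        return asdict(self)


def stroop_probe_layout(
    head_radius: float = 85.0, separation_cm: float = 3.0
) -> ProbeLayout:
    """Synthetic 52-channel prefrontal probe on the canonical head sphere.

    A 3 x 11 optode array (17 sources, 16 detectors in a checkerboard) is
    draped over the forehead band of an 85 mm sphere with 3 cm optode
    spacing; the 52 channels are the midpoints of horizontally and
    vertically adjacent source-detector pairs (30 + 22), mirroring a
    whole-forehead continuous-wave topography montage.
    """
    spacing = separation_cm * 10.0  # mm arc length
    n_rows, n_cols = 3, 11
    # disc (azimuthal-equidistant) coordinates: rows are circles around the
    # vertex; the bottom row sits near the forehead/ear band
    rho0 = head_radius * np.radians(85.0)
    rows = [rho0 - r * spacing for r in range(n_rows)]
    dphi = spacing / rows[1]  # angular step from the middle row
    phis = (np.arange(n_cols) - (n_cols - 1) / 2.0) * dphi
    pos = {}
    for r, rho in enumerate(rows):
        for k, phi in enumerate(phis):
            xy = rho * np.array([np.cos(phi), np.sin(phi)])
            pos[(r, k)] = disc_to_sphere(xy, head_radius)[0] * head_radius
    sources, detectors = [], []
    role = {}
    for (r, k), p in pos.items():
        if (r + k) % 2 == 0:
            role[(r, k)] = ("S", len(sources))
            sources.append(p)
        else:
            role[(r, k)] = ("D", len(detectors))
            detectors.append(p)
    pairs = []
    for r in range(n_rows):
        for k in range(n_cols - 1):
            pairs.append(((r, k), (r, k + 1)))
    for r in range(n_rows - 1):
        for k in range(n_cols):
            pairs.append(((r, k), (r + 1, k)))
    channel_pairs = []
    for a, b in pairs:
        (ta, ia), (tb, ib) = role[a], role[b]
        s, d = (ia, ib) if ta == "S" else (ib, ia)
        channel_pairs.append((s, d))
    return ProbeLayout(
        source_pos=np.array(sources),
        detector_pos=np.array(detectors),
        channel_pairs=channel_pairs,
        channel_ids=[f"CH{j + 1}" for j in range(len(channel_pairs))],
        separation=separation_cm,
    )


def simulate_events(
    n_freq: int = 80,
    n_rare: int = 20,
    isi_range: tuple[float, float] = (9.0, 12.0),
    max_rt: float = 2.0,
    seed: int | np.random.Generator = 0,
    labels: tuple[str, str] = ("congruent", "incongruent"),
) -> EventTable:
    """Randomly ordered event table with uniform inter-stimulus intervals."""
    if n_freq < 0 or n_rare < 0:
        raise ValueError("event counts must be >= 0")
    lo, hi = isi_range
    if not lo < hi:
        raise ValueError("isi_range must satisfy low < high")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conds = [labels[0]] * n_freq + [labels[1]] * n_rare
    order = rng.permutation(len(conds))
    conds = [conds[i] for i in order]
    isis = rng.uniform(lo, hi, size=len(conds))
    onsets = 10.0 + np.concatenate(([0.0], np.cumsum(isis[:-1])))
    durations = np.zeros(len(conds))
    return EventTable(onsets=onsets, durations=durations, conditions=conds)


def _ar1_noise(
    rng: np.random.Generator, M: int, J: int, rho: float, sd: float
) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd``."""
    innov = rng.standard_normal((M, J)) * sd * np.sqrt(1.0 - rho**2)
    innov[0] = rng.standard_normal(J) * sd  # stationary start
    return lfilter([1.0], [1.0, -rho], innov, axis=0)


def simulate_subject(
    truth: SimulationTruth,
    layout: ProbeLayout,
    events: EventTable,
    fs: float = 10.0,
    duration: float | None = None,
    rng: np.random.Generator | None = None,
    hrf_params: HrfParams = HrfParams(),
) -> tuple[HbSeries, dict[str, np.ndarray]]:
    """One subject's HbO/HbR time series plus the realized effect amplitudes.

    Returns ``(series, w_n)`` where ``w_n[condition]`` is the per-channel
    amplitude actually used (zero on inactive channels).
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    needed = float(np.max(events.onsets)) + hrf_params.length if len(events.onsets) else 1.0
    if duration is None:
        duration = needed
    if duration < needed:
        raise ValueError(
            f"duration {duration} s shorter than last event + {hrf_params.length} s"
        )
    M = int(round(duration * fs))
    J = layout.n_channels
    active = np.array([cid in set(truth.active_channels) for cid in layout.channel_ids])
    hrf = canonical_hrf(1.0 / fs, hrf_params)
    signal = np.zeros((M, J))
    w_n: dict[str, np.ndarray] = {}
    for cond, amp in truth.effect_size.items():
        sel = [i for i, c in enumerate(events.conditions) if c == cond]
        u = np.zeros(M)
        for onset in events.onsets[sel]:
            u[int(round(onset * fs))] += 1.0
        reg = np.convolve(u, hrf)[:M]
        w = np.zeros(J)
        w[active] = amp + truth.sigma_b * rng.standard_normal(int(active.sum()))
        w_n[cond] = w
        signal += np.outer(reg, w)
    hbo = signal + _ar1_noise(rng, M, J, truth.rho, truth.sigma_w)
    hbr = _HBR_RATIO * signal + _ar1_noise(rng, M, J, truth.rho, 0.5 * truth.sigma_w)
    t = np.arange(M) / fs
    for amp, freq in truth.physio:
        if freq >= fs / 2:
            raise ValueError(f"physio frequency {freq} Hz at or above Nyquist")
        phases = rng.uniform(0, 2 * np.pi, size=J)
        osc = amp * np.sin(2 * np.pi * freq * t[:, None] + phases[None, :])
        hbo += osc
        hbr += 0.3 * osc
    series = HbSeries(hbo=hbo, hbr=hbr, fs=fs, channel_ids=list(layout.channel_ids))
    return series, w_n


def simulate_group(
    truth: SimulationTruth,
    layout: ProbeLayout | None = None,
    N: int = 21,
    seed: int | None = None,
    fs: float = 10.0,
    n_freq: int = 80,
    n_rare: int = 20,
    isi_range: tuple[float, float] = (9.0, 12.0),
) -> dict:
    """N independent subjects sharing the population effect w_pop.

    Returns a dict with keys ``subjects`` (list of per-subject records with
    ``subject_id``, ``series``, ``events``, ``w_n``), ``layout`` and
    ``truth``.  Substreams are spawned from the master seed, so the full
    dataset is reproducible bit for bit.
    """
    if N < 2:
        raise ValueError("need N >= 2 subjects")
    layout = layout if layout is not None else stroop_probe_layout()
    master = np.random.SeedSequence(truth.seed if seed is None else seed)
    streams = master.spawn(N)
    subjects = []
    for n, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        events = simulate_events(n_freq, n_rare, isi_range, seed=rng)
        series, w_n = simulate_subject(truth, layout, events, fs=fs, rng=rng)
        subjects.append(
            {
                "subject_id": f"sub-{n + 1:02d}",
                "series": series,
                "events": events,
                "w_n": w_n,
            }
        )
    return {"subjects": subjects, "layout": layout, "truth": truth}
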