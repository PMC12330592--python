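"""In-vivo micro-ECoG analysis recipes.

Preprocessing (LFP extraction, artifact masking), spike analysis
(threshold detection, K-means sorting, empirical SNR), band-power
statistics (task-vs-baseline change maps, multitaper z-scored
spectrograms), and the paradigm-specific statistical procedures for
behavioral, tactile, electrical-stimulation, and optogenetic sessions.

Power convention throughout: a segment's power is the sum of the squared
(band-passed) signal divided by its duration in seconds.  Filters are
4th-order zero-phase Butterworth (forward-backward), notches Q = 30.
Significance testing uses t-tests with Bonferroni correction across
channels at a family-wise error rate of 0.05.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

__all__ = [
    "Event",
    "RecordingSession",
    "BandSet",
    "DEFAULT_BANDS",
    "SpikeSet",
    "extract_lfp",
    "detect_spikes",
    "sort_spikes",
    "spike_snr",
    "band_power",
    "power_change_map",
    "mt_spectrogram_z",
    "artifact_reject",
    "stim_block_analysis",
    "evoked_window_test",
    "impedance_normalized_response",
    "save_session",
    "load_session",
]


@dataclass(frozen=True)
class Event:
    type: str
    time: float  # seconds


@dataclass
class RecordingSession:
    """Multichannel raw recording with a typed event table.

    ``signals`` is (n_channels, n_samples); ``channel_positions`` maps a
    channel id to its (x, y) layout position in mm for map interpolation;
    ``impedances`` maps channel ids to |Z| in ohms when available.
    """

    signals: np.ndarray
    sample_rate: float
    channel_ids: list
    events: list = field(default_factory=list)
    channel_positions: dict = field(default_factory=dict)
    impedances: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals))
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals must be finite")
        dur = self.duration
        for ev in self.events:
            if not 0 <= ev.time <= dur:
                raise ValueError(f"event at {ev.time}s outside recording")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def duration(self) -> float:
        return self.signals.shape[1] / self.sample_rate

    def event_times(self, event_type: str) -> np.ndarray:
        return np.array([e.time for e in self.events if e.type == event_type])


# canonical analysis bands (Hz); gamma is split differently for the
# stimulation paradigm (30-59 / 60-150) than for behavior (30-70) — both
# conventions are carried as named bands
DEFAULT_BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 70.0),
    "low_gamma": (30.0, 59.0),
    "high_gamma": (60.0, 150.0),
    "tactile_low": (4.0, 15.0),
    "opto_low": (4.0, 40.0),
}


@dataclass
class BandSet:
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))

    def validate(self, sample_rate: float) -> None:
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo < hi < sample_rate / 2:
                raise ValueError(f"band {name} ({lo}-{hi} Hz) invalid at "
                                 f"fs={sample_rate}")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bands[name]


@dataclass
class SpikeSet:
    """Detected spikes of one channel: times, aligned snippets, labels."""

    times: np.ndarray               # s
    waveforms: np.ndarray           # (n_spikes, n_samples), trough-aligned
    background_sd: float            # σb, robust SD of the background, V
    sample_rate: float
    labels: np.ndarray | None = None
    amplitude_mode: str = "peak_to_trough"   # or "trough"

    @property
    def mean_amplitude(self) -> float:
        """A_spike of the mean waveform, per ``amplitude_mode``."""
        if len(self.waveforms) == 0:
            raise ValueError("no spikes")
        mean_wf = self.waveforms.mean(axis=0)
        if self.amplitude_mode == "trough":
            return float(-mean_wf.min())
        return float(mean_wf.max() - mean_wf.min())


# --------------------------------------------------------------------------
# filtering helpers
# --------------------------------------------------------------------------

def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float,
              order: int = 4) -> np.ndarray:
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def _lowpass(x: np.ndarray, cutoff: float, fs: float, order: int = 4) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def _highpass(x: np.ndarray, cutoff: float, fs: float, order: int = 4) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def _notch(x: np.ndarray, freq: float, fs: float, q: float = 30.0) -> np.ndarray:
    b, a = sps.iirnotch(freq, q, fs=fs)
    return sps.filtfilt(b, a, x, axis=-1)


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def extract_lfp(session: RecordingSession, lfp_rate: float = 1000.0,
                notches: tuple = (60.0, 120.0, 180.0)) -> RecordingSession:
    """LFP band: zero-phase 250 Hz low-pass, line notches, decimate to 1 kHz."""
    fs = session.sample_rate
    if fs < 2000.0:
        raise ValueError("sample rate below 2 kHz; LFP extraction undefined")
    factor = fs / lfp_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("sample rate must be an integer multiple of the LFP rate")
    # anti-alias low-pass needs a steeper skirt than the analysis band-passes:
    # 8th order gives > 20 dB by 1.2x the cutoff after forward-backward
    x = _lowpass(session.signals, 250.0, fs, order=8)
    for f0 in notches:
        x = _notch(x, f0, fs)
    x = x[:, ::int(round(factor))]
    return RecordingSession(signals=x, sample_rate=lfp_rate,
                            channel_ids=list(session.channel_ids),
                            events=list(session.events),
                            channel_positions=dict(session.channel_positions),
                            impedances=dict(session.impedances))


def artifact_reject(signal_1d, threshold_sd: float = 10.0,
                    guard_samples: int = 0) -> np.ndarray:
    """Mask (True = artifact) where |z-scored signal| exceeds the threshold.

    The signal is normalized to its own mean and SD; an optional guard
    margin dilates each supra-threshold excursion.
    """
    x = np.asarray(signal_1d, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance input; normalization undefined")
    z = (x - x.mean()) / sd
    mask = np.abs(z) > threshold_sd
    if guard_samples > 0 and mask.any():
        kernel = np.ones(2 * guard_samples + 1)
        mask = np.convolve(mask.astype(float), kernel, mode="same") > 0
    return mask


# --------------------------------------------------------------------------
# spikes
# --------------------------------------------------------------------------

def robust_background_sd(x: np.ndarray) -> float:
    """MAD-based SD estimate median(|x|)/0.6745, insensitive to spikes."""
    return float(np.median(np.abs(x)) / 0.6745)


def detect_spikes(session: RecordingSession, channel: int = 0,
                  threshold_sd: float = -6.0, refractory_s: float = 1e-3,
                  snippet_s: tuple[float, float] = (0.6e-3, 1.0e-3)) -> SpikeSet:
    """Threshold-crossing spike detection on one channel.

    The trace is high-pass filtered at 250 Hz; the detection threshold is
    ``threshold_sd`` (default −6) times the robust background SD.
    Detections are trough-aligned, with a refractory hold-off.
    """
    fs = session.sample_rate
    x = _highpass(session.signals[channel], 250.0, fs)
    sd = robust_background_sd(x)
    if sd == 0:
        raise ValueError("degenerate background: flat signal")
    thr = threshold_sd * sd
    below = x < thr
    cross = np.nonzero(below & ~np.roll(below, 1))[0]
    refr = int(round(refractory_s * fs))
    n_pre = int(round(snippet_s[0] * fs))
    n_post = int(round(snippet_s[1] * fs))
    align_win = int(round(0.5e-3 * fs))

    times, waveforms = [], []
    last = -np.inf
    for c in cross:
        if c - last < refr:
            continue
        seg = x[c:min(c + align_win, len(x))]
        trough = c + int(np.argmin(seg))
        if trough - n_pre < 0 or trough + n_post >= len(x):
            continue
        last = trough
        times.append(trough / fs)
        waveforms.append(x[trough - n_pre:trough + n_post])
    wf = np.array(waveforms) if waveforms else np.empty((0, n_pre + n_post))
    return SpikeSet(times=np.array(times), waveforms=wf,
                    background_sd=sd, sample_rate=fs)


def sort_spikes(spikes: SpikeSet, k: int, seed: int = 0,
                n_components: int = 3) -> SpikeSet:
    """K-means clustering of spike waveforms on their principal components."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    n = len(spikes.waveforms)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of spikes ({n})")
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        feats = PCA(n_components=min(n_components, n, spikes.waveforms.shape[1]),
                    random_state=seed).fit_transform(spikes.waveforms)
        labels = KMeans(n_clusters=k, random_state=seed,
                        n_init=10).fit_predict(feats)
    return SpikeSet(times=spikes.times, waveforms=spikes.waveforms,
                    background_sd=spikes.background_sd,
                    sample_rate=spikes.sample_rate, labels=labels,
                    amplitude_mode=spikes.amplitude_mode)


def spike_snr(spikes: SpikeSet) -> dict:
    """Empirical spike SNR: A_spike/σb and its dB value 20 log10(·)."""
    if len(spikes.waveforms) == 0:
        raise ValueError("no spikes in set")
    if spikes.background_sd <= 0:
        raise ValueError("background SD must be > 0")
    ratio = spikes.mean_amplitude / spikes.background_sd
    return {"ratio": ratio, "db": 20.0 * np.log10(ratio)}


# --------------------------------------------------------------------------
# band power
# --------------------------------------------------------------------------

def band_power(segment, band: tuple[float, float], sample_rate: float) -> float:
    """Band-limited power: band-pass, then sum of squares over duration (s).

    For a unit-amplitude in-band sinusoid this evaluates to ≈ fs/2
    regardless of duration.  The segment must span at least 3 cycles of
    the band's low edge for the filter to be meaningful.
    """
    x = np.asarray(segment, dtype=float)
    duration = len(x) / sample_rate
    if duration < 3.0 / band[0]:
        raise ValueError("segment shorter than 3 cycles of the band low edge")
    xf = _bandpass(x, band, sample_rate)
    return float(np.sum(xf ** 2) / duration)


def _windowed_power(xf: np.ndarray, fs: float, start: float, stop: float) -> float:
    # power of a pre-filtered trace on [start, stop) seconds
    i0, i1 = int(round(start * fs)), int(round(stop * fs))
    if i0 < 0 or i1 > xf.shape[-1] or i1 <= i0:
        raise ValueError(f"window [{start}, {stop})s outside the recording")
    seg = xf[..., i0:i1]
    return float(np.sum(seg ** 2) / ((i1 - i0) / fs))


def power_change_map(session: RecordingSession, event_times,
                     task_window: tuple[float, float],
                     baseline_window: tuple[float, float],
                     band: tuple[float, float], alpha: float = 0.05,
                     grid_n: int = 64) -> dict:
    """Per-channel task-vs-baseline band-power change with significance.

    For each trial and channel the power in the task and baseline windows
    (offsets in seconds relative to each event) is computed on the
    band-passed trace; channels are tested with a paired t-test across
    trials, Bonferroni-corrected over channels (FWER ``alpha``).  The
    returned ``change`` is the mean relative change
    mean(P_task)/mean(P_base) − 1.  If the session carries channel layout
    positions, a linearly interpolated map of the change is included;
    channels without positions stay in the table but are left off the map.
    """
    times = np.asarray(event_times, dtype=float)
    if times.size < 2:
        raise ValueError("at least 2 trials required")
    fs = session.sample_rate
    xf = _bandpass(session.signals, band, fs)
    n_ch = session.n_channels
    p_task = np.empty((n_ch, times.size))
    p_base = np.empty((n_ch, times.size))
    for j, t0 in enumerate(times):
        for ch in range(n_ch):
            p_task[ch, j] = _windowed_power(xf[ch], fs, t0 + task_window[0],
                                            t0 + task_window[1])
            p_base[ch, j] = _windowed_power(xf[ch], fs, t0 + baseline_window[0],
                                            t0 + baseline_window[1])
    change = p_task.mean(axis=1) / p_base.mean(axis=1) - 1.0
    if task_window == baseline_window:
        pvals = np.ones(n_ch)
        tstat = np.zeros(n_ch)
    else:
        tstat, pvals = stats.ttest_rel(p_task, p_base, axis=1)
    p_corr = np.minimum(pvals * n_ch, 1.0)
    significant = p_corr < alpha

    interp_map = None
    pos = [session.channel_positions.get(cid) for cid in session.channel_ids]
    have = [i for i, p in enumerate(pos) if p is not None]
    if len(have) >= 3:
        from scipy.interpolate import griddata
        pts = np.array([pos[i] for i in have])
        vals = change[have]
        gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_n)
        gy = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_n)
        mx, my = np.meshgrid(gx, gy)
        interp_map = {"x": gx, "y": gy,
                      "values": griddata(pts, vals, (mx, my), method="linear")}

    return {"channel_ids": list(session.channel_ids), "change": change,
            "t": tstat, "p": pvals, "p_corrected": p_corr,
            "significant": significant,
            "power_task": p_task, "power_baseline": p_base,
            "map": interp_map}


# --------------------------------------------------------------------------
# multitaper spectrogram
# --------------------------------------------------------------------------

def mt_spectrogram_z(trials: np.ndarray, sample_rate: float,
                     window_s: float, step_s: float,
                     baseline_interval: tuple[float, float],
                     nw: float = 3.0, n_tapers: int = 5) -> dict:
    """Trial-averaged multitaper spectrogram, z-scored to a baseline span.

    ``trials`` is (n_trials, n_samples) of aligned segments; times are
    relative to segment start.  Per trial, a DPSS multitaper power
    estimate (time-bandwidth ``nw``, ``n_tapers`` tapers) is computed in
    sliding windows; the trial average is z-scored per frequency row
    against the mean and SD over windows whose centers fall inside
    ``baseline_interval``.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    n_trials, n_samp = trials.shape
    win = int(round(window_s * sample_rate))
    step = max(int(round(step_s * sample_rate)), 1)
    if win > n_samp:
        raise ValueError("window longer than the trial segment")
    tapers = sps.windows.dpss(win, nw, Kmax=n_tapers)   # (K, win)
    starts = np.arange(0, n_samp - win + 1, step)
    centers = (starts + win / 2) / sample_rate
    freqs = np.fft.rfftfreq(win, 1.0 / sample_rate)

    spec = np.zeros((len(freqs), len(starts)))
    for tr in trials:
        segs = np.stack([tr[s:s + win] for s in starts])       # (n_win, win)
        tapered = segs[:, None, :] * tapers[None, :, :]        # (n_win, K, win)
        power = (np.abs(np.fft.rfft(tapered, axis=-1)) ** 2).mean(axis=1)
        spec += power.T
    spec /= n_trials

    in_base = (centers >= baseline_interval[0]) & (centers < baseline_interval[1])
    if not in_base.any():
        raise ValueError("no spectrogram windows inside the baseline interval")
    mu = spec[:, in_base].mean(axis=1, keepdims=True)
    sd = spec[:, in_base].std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return {"time": centers, "frequency": freqs, "z": (spec - mu) / sd,
            "power": spec}


# --------------------------------------------------------------------------
# paradigm statistics
# --------------------------------------------------------------------------

def stim_block_analysis(session: RecordingSession, blocks: list,
                        band: tuple[float, float], alpha: float = 0.05,
                        artifact_threshold_sd: float = 10.0) -> dict:
    """Spontaneous vs stimulation-induced band-power change across blocks.

    Each block is a dict with ``baseline1``, ``baseline2`` and ``post``
    (start, stop) intervals in seconds.  Per channel the signal is
    artifact-masked per period, normalized to the mean and SD of the
    first baseline period, band-passed, and its power per period
    computed.  Δ_spont = P(b2) − P(b1), Δ_induced = P(post) − P(b1).
    Network-level (channel-averaged) deltas are tested across blocks with
    one-sample t-tests against 0 and a paired t-test Δ_induced vs
    Δ_spont; per-channel paired tests are Bonferroni-corrected.
    """
    fs = session.sample_rate
    required = ("baseline1", "baseline2", "post")
    for blk in blocks:
        for key in required:
            if key not in blk:
                raise ValueError(f"block missing period '{key}'")
    n_ch = session.n_channels
    n_blk = len(blocks)
    d_spont = np.empty((n_ch, n_blk))
    d_ind = np.empty((n_ch, n_blk))

    for b, blk in enumerate(blocks):
        for ch in range(n_ch):
            x = session.signals[ch]

            def period_slice(iv):
                i0, i1 = int(round(iv[0] * fs)), int(round(iv[1] * fs))
                if i0 < 0 or i1 > len(x) or i1 <= i0:
                    raise ValueError(f"period {iv} outside the recording")
                return x[i0:i1]

            b1 = period_slice(blk["baseline1"])
            mask1 = artifact_reject(b1, artifact_threshold_sd)
            mu, sd = b1[~mask1].mean(), b1[~mask1].std()
            if sd == 0:
                raise ValueError("degenerate baseline1 period")

            powers = {}
            for key in required:
                seg = (period_slice(blk[key]) - mu) / sd
                mask = artifact_reject(seg, artifact_threshold_sd) \
                    if seg.std() > 0 else np.zeros(len(seg), bool)
                seg = seg.copy()
                seg[mask] = 0.0
                xf = _bandpass(seg, band, fs)
                dur = (len(seg) - mask.sum()) / fs
                powers[key] = float(np.sum(xf ** 2) / dur)
            d_spont[ch, b] = powers["baseline2"] - powers["baseline1"]
            d_ind[ch, b] = powers["post"] - powers["baseline1"]

    net_spont = d_spont.mean(axis=0)
    net_ind = d_ind.mean(axis=0)
    t1s, p1s = stats.ttest_1samp(net_spont, 0.0)
    t1i, p1i = stats.ttest_1samp(net_ind, 0.0)
    tp, pp = stats.ttest_rel(net_ind, net_spont)
    _, p_ch = stats.ttest_rel(d_ind, d_spont, axis=1)
    p_ch_corr = np.minimum(p_ch * n_ch, 1.0)
    return {
        "delta_spontaneous": d_spont, "delta_induced": d_ind,
        "network_spontaneous": net_spont, "network_induced": net_ind,
        "p_spontaneous_vs_zero": float(p1s), "p_induced_vs_zero": float(p1i),
        "p_induced_vs_spontaneous": float(pp),
        "t_induced_vs_spontaneous": float(tp),
        "per_channel_p_corrected": p_ch_corr,
        "per_channel_significant": p_ch_corr < alpha,
    }


def evoked_window_test(session: RecordingSession, stim_onsets,
                       pre_window: float = 0.1, post_window: float = 0.2,
                       band: tuple[float, float] = DEFAULT_BANDS["tactile_low"],
                       alpha: float = 0.05) -> dict:
    """Pre/post stimulus band-power comparison per channel.

    Power is computed ``pre_window`` seconds before and ``post_window``
    seconds after each onset (each normalized by its own duration) on the
    band-passed trace; channels are compared with a two-sample t-test and
    Bonferroni correction.  Windows must not overlap adjacent trials.
    """
    onsets = np.sort(np.asarray(stim_onsets, dtype=float))
    if onsets.size < 2:
        raise ValueError("at least 2 trials required")
    if np.any(np.diff(onsets) < pre_window + post_window):
        raise ValueError("pre/post windows overlap adjacent trials")
    fs = session.sample_rate
    xf = _bandpass(session.signals, band, fs)
    n_ch = session.n_channels
    p_pre = np.empty((n_ch, onsets.size))
    p_post = np.empty((n_ch, onsets.size))
    for j, t0 in enumerate(onsets):
        for ch in range(n_ch):
            p_pre[ch, j] = _windowed_power(xf[ch], fs, t0 - pre_window, t0)
            p_post[ch, j] = _windowed_power(xf[ch], fs, t0, t0 + post_window)
    tstat, pvals = stats.ttest_ind(p_post, p_pre, axis=1)
    p_corr = np.minimum(pvals * n_ch, 1.0)
    return {"channel_ids": list(session.channel_ids),
            "power_pre": p_pre, "power_post": p_post,
            "t": tstat, "p": pvals, "p_corrected": p_corr,
            "significant": p_corr < alpha}


def impedance_normalized_response(z_power_map: dict, impedances: dict) -> dict:
    """Divide per-channel averaged z-band responses by |Z| per channel.

    Removes the influence of impedance differences between electrodes;
    channels without an impedance entry are excluded with a warning.
    """
    out = {}
    missing = []
    for ch, val in z_power_map.items():
        z = impedances.get(ch)
        if z is None or z == 0:
            missing.append(ch)
            continue
        out[ch] = val / abs(z)
    if missing:
        warnings.warn(f"channels without impedance excluded: {missing}",
                      stacklevel=2)
    return out


# --------------------------------------------------------------------------
# session container (HDF5 + JSON sidecar)
# --------------------------------------------------------------------------

def save_session(session: RecordingSession, h5_path, ground_truth=None) -> None:
    """int16-with-scale-factor HDF5 container plus a JSON sidecar."""
    import h5py
    from pathlib import Path

    h5_path = Path(h5_path)
    peak = np.abs(session.signals).max()
    scale = peak / 32000.0 if peak > 0 else 1.0
    with h5py.File(h5_path, "w") as f:
        ds = f.create_dataset(
            "signals", data=np.round(session.signals / scale).astype(np.int16))
        ds.attrs["scale_factor"] = scale
        f.attrs["sample_rate"] = session.sample_rate
    sidecar = {
        "format_version": 1,
        "sample_rate": session.sample_rate,
        "channel_ids": [str(c) for c in session.channel_ids],
        "events": [{"type": e.type, "time": e.time} for e in session.events],
        "channel_positions": {str(k): list(v)
                              for k, v in session.channel_positions.items()},
        "impedances": {str(k): v for k, v in session.impedances.items()},
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth
    h5_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_session(h5_path) -> RecordingSession:
    import h5py
    from pathlib import Path

    h5_path = Path(h5_path)
    with h5py.File(h5_path, "r") as f:
        scale = f["signals"].attrs["scale_factor"]
        signals = f["signals"][...] * scale
        fs = float(f.attrs["sample_rate"])
    meta = json.loads(h5_path.with_suffix(".json").read_text())
    return RecordingSession(
        signals=signals, sample_rate=fs,
        channel_ids=meta["channel_ids"],
        events=[Event(e["type"], e["time"]) for e in meta["events"]],
        channel_positions={k: tuple(v)
                           for k, v in meta["channel_positions"].items()},
        impedances=meta.get("impedances", {}))
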