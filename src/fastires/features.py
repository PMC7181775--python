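"""Spike and ictal feature pipelines: epoching, spectra, energy maps, EZ extraction.

Spike imaging averages peak-locked 2-s windows and summarizes the solved
source map over a 40 ms window around the spike peak.  Ictal imaging finds the
dominant seizure rhythm by contrasting the first five post-onset seconds with
the five pre-onset seconds (five 1-s periodograms per side, averaged), filters
the source time courses to that band, and takes their energy over the first
second after onset.  The epileptogenic-zone estimate is the support of the
energy map above a numerical-zero cut — not a statistical threshold: the
solver's background is exactly sparse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.signal import butter, sosfiltfilt, periodogram
from scipy.sparse.csgraph import connected_components

from .mesh import CorticalMesh, SourcePatch
from .solver import SourceEstimate
from .tbf import EEGRecording

__all__ = [
    "SpikeFeature",
    "IctalFeature",
    "EnergyMap",
    "average_spikes",
    "dominant_ictal_band",
    "spike_energy_map",
    "ictal_energy_map",
    "extract_ez",
]


@dataclass
class SpikeFeature:
    """Peak-locked averaged spike waveform (2-s symmetric window)."""

    averaged_epoch: np.ndarray  # E x T_e
    peak_time: float  # seconds within the epoch (center)
    spike_type: object = 0
    n_spikes: int = 1
    sfreq: float = 500.0


@dataclass
class IctalFeature:
    """Denoised ictal segment with its dominant rhythm band."""

    segment: np.ndarray  # E x T_i
    onset: float  # seconds within the segment
    dominant_band: tuple  # (f_lo, f_hi) Hz
    window: tuple = (0.0, 1.0)  # analysis window, seconds post onset
    sfreq: float = 500.0


@dataclass
class EnergyMap:
    """Per-vertex source energy over an analysis window."""

    values: np.ndarray
    mode: str
    window: tuple = (0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("energy map contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("energies must be nonnegative")


def average_spikes(eeg: EEGRecording, peaks, type_labels=None,
                   epoch_half: float = 1.0):
    """Average peak-locked 2-s epochs, independently per spike type.

    Returns one :class:`SpikeFeature` per distinct type label (all spikes one
    type if ``type_labels`` is None).  Peaks whose window does not fit inside
    the recording are skipped with a warning.
    """
    peaks = list(peaks)
    if type_labels is None:
        type_labels = [0] * len(peaks)
    if len(type_labels) != len(peaks):
        raise ValueError("type_labels must match peaks in length")
    half = int(round(epoch_half * eeg.sfreq))
    features = []
    for label in dict.fromkeys(type_labels):  # preserve first-seen order
        epochs = []
        for p, l in zip(peaks, type_labels):
            if l != label:
                continue
            i = int(round(p * eeg.sfreq))
            if i - half < 0 or i + half > eeg.n_times:
                warnings.warn(f"spike at {p} s too close to the record edge; skipped")
                continue
            epochs.append(eeg.data[:, i - half:i + half])
        if not epochs:
            continue
        features.append(SpikeFeature(
            averaged_epoch=np.mean(epochs, axis=0), peak_time=epoch_half,
            spike_type=label, n_spikes=len(epochs), sfreq=eeg.sfreq,
        ))
    return features


def _side_spectrum(data: np.ndarray, sfreq: float, n_segments: int = 5):
    """Channel-averaged mean of per-second periodograms (1 Hz resolution)."""
    seg = int(round(sfreq))
    spectra = []
    for k in range(n_segments):
        chunk = data[:, k * seg:(k + 1) * seg]
        f, p = periodogram(chunk, fs=sfreq, window="boxcar", axis=1)
        spectra.append(p.mean(axis=0))
    return f, np.mean(spectra, axis=0)


def dominant_ictal_band(eeg: EEGRecording, onset: float,
                        side_seconds: float = 5.0) -> tuple:
    """Dominant ictal rhythm from pre- versus post-onset spectra.

    Averages five 1-s periodograms on each side of onset (channel-averaged),
    keeps frequencies where the post-onset spectrum exceeds the pre-onset one,
    and returns the contiguous band containing the largest increase — side
    lobes are rejected even if they also exceed the pre-ictal spectrum.
    """
    sf = eeg.sfreq
    n_seg = int(round(side_seconds))
    i_on = int(round(onset * sf))
    need = n_seg * int(round(sf))
    if i_on - need < 0 or i_on + need > eeg.n_times:
        raise ValueError(f"need >= {side_seconds} s on both sides of onset")
    f, pre = _side_spectrum(eeg.data[:, i_on - need:i_on], sf, n_seg)
    _, post = _side_spectrum(eeg.data[:, i_on:i_on + need], sf, n_seg)
    diff = post - pre
    candidates = (diff > 0) & (f > 0)
    if not candidates.any():
        raise ValueError("no dominant ictal rhythm: post-onset spectrum never "
                         "exceeds the pre-onset spectrum")
    peak = np.argmax(np.where(candidates, diff, -np.inf))
    lo = peak
    while lo - 1 >= 0 and candidates[lo - 1]:
        lo -= 1
    hi = peak
    while hi + 1 < len(f) and candidates[hi + 1]:
        hi += 1
    return float(f[lo]), float(f[hi])


def spike_energy_map(estimate: SourceEstimate, peak_time: float,
                     sfreq: float, window_half: float = 0.020) -> EnergyMap:
    """Mean squared source amplitude over a 40 ms window around the spike peak."""
    S = estimate.S
    a = int(round((peak_time - window_half) * sfreq))
    b = int(round((peak_time + window_half) * sfreq))
    if a < 0 or b > S.shape[1] or a >= b:
        raise ValueError(
            f"window [{peak_time - window_half}, {peak_time + window_half}) s "
            "outside the estimate span"
        )
    vals = np.mean(S[:, a:b] ** 2, axis=1)
    return EnergyMap(values=vals, mode="spike",
                     window=(peak_time - window_half, peak_time + window_half))


def ictal_energy_map(estimate: SourceEstimate, band: tuple, onset: float,
                     sfreq: float, window_seconds: float = 1.0) -> EnergyMap:
    """Energy of band-passed source signals over 1 s from seizure onset.

    Each vertex time course is zero-phase band-pass filtered at the dominant
    rhythm (single-bin bands are widened by +-0.5 Hz to a realizable filter),
    then averaged as squared amplitude over ``[onset, onset + 1 s)``.
    """
    f_lo, f_hi = band
    if f_lo > f_hi:
        raise ValueError("band must satisfy f_lo <= f_hi")
    if f_hi >= sfreq / 2:
        raise ValueError(f"band edge {f_hi} Hz at or above Nyquist")
    lo = max(f_lo - 0.5, 0.1) if f_lo == f_hi else f_lo
    hi = f_hi + 0.5 if f_lo == f_hi else f_hi
    S = estimate.S
    a = int(round(onset * sfreq))
    b = int(round((onset + window_seconds) * sfreq))
    if a < 0 or b > S.shape[1]:
        raise ValueError("analysis window outside the estimate span")
    sos = butter(4, [lo, hi], btype="bandpass", fs=sfreq, output="sos")
    filtered = sosfiltfilt(sos, S, axis=1)
    vals = np.mean(filtered[:, a:b] ** 2, axis=1)
    return EnergyMap(values=vals, mode="ictal", window=(onset, onset + window_seconds))


def extract_ez(energy_map: EnergyMap, mesh: CorticalMesh,
               tau_numerical: float = 1e-6, return_components: bool = False):
    """Epileptogenic-zone estimate: support of the energy map.

    The cut ``tau_numerical * max`` only strips floating-point dust — the
    solver's background is exactly sparse, so no statistical threshold is
    involved.  Optionally also returns the geodesically connected components
    of the active set.
    """
    vals = energy_map.values
    top = vals.max() if vals.size else 0.0
    if top == 0:
        warnings.warn("all-zero energy map: empty EZ estimate")
        empty = SourcePatch(vertex_ids=np.array([], dtype=int), seed=-1, area=0.0)
        return (empty, []) if return_components else empty
    active = np.flatnonzero(vals > tau_numerical * top)
    area = float(mesh.vertex_areas[active].sum())
    seed = int(active[np.argmax(vals[active])])
    patch = SourcePatch(vertex_ids=active, seed=seed, area=area)
    if not return_components:
        return patch
    # split into geodesically connected components on the mesh
    pos = {v: k for k, v in enumerate(active)}
    rows, cols = [], []
    for k, v in enumerate(active):
        for nb in mesh.adjacency[v]:
            if nb in pos:
                rows.append(k)
                cols.append(pos[nb])
    g = sp.coo_matrix((np.ones(len(rows)), (rows, cols)),
                      shape=(len(active), len(active)))
    n_comp, labels = connected_components(g, directed=False)
    parts = []
    for c in range(n_comp):
        members = active[labels == c]
        s = int(members[np.argmax(vals[members])])
        parts.append(SourcePatch(
            vertex_ids=members, seed=s,
            area=float(mesh.vertex_areas[members].sum()),
        ))
    return patch, parts
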