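"""Welch power spectral density and relative band power.

Relative power in a band is the fraction of total 2-46 Hz spectral power
falling in that band, per electrode.  No aperiodic (1/f) component is
removed before forming the ratio: the broadband background is part of the
total power by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .data_model import ANALYSIS_RANGE, BandScheme, EpochedRecording


@dataclass
class PowerSpectrum:
    freqs: np.ndarray  # Hz, strictly increasing
    psd: np.ndarray  # (n_channels, n_freqs), uV^2/Hz
    labels: list[str]
    window_len_s: float
    overlap: float
    window: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.psd < 0):
            raise ValueError("PSD must be non-negative")
        if self.psd.shape != (len(self.labels), len(self.freqs)):
            raise ValueError("psd shape mismatch")


@dataclass
class BandPowerTable:
    """Channel x band relative power (rows sum to 1 over a partition)."""

    values: pd.DataFrame  # index = channel labels, columns = band names
    scheme: BandScheme

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("relative powers must lie in [0, 1]")


def welch_psd(
    epoched: EpochedRecording,
    window_len_s: float = 2.0,
    overlap: float = 0.5,
    window: str = "hamming",
) -> PowerSpectrum:
    """Welch PSD over the retained epochs, concatenated in time.

    Density normalisation: the integral of the PSD over frequency equals the
    signal variance (up to windowing bias).  Epochs are concatenated rather
    than averaged per-epoch so that window length is not capped by the 1-s
    epoch duration; segment boundaries falling across epoch joins contribute
    negligible broadband leakage at these lengths.
    """
    x = epoched.continuous()
    nperseg = int(round(window_len_s * epoched.fs))
    if nperseg > x.shape[1]:
        raise ValueError(
            f"Welch window of {nperseg} samples exceeds data length {x.shape[1]}"
        )
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    freqs, psd = welch(
        x,
        fs=epoched.fs,
        window=window,
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return PowerSpectrum(
        freqs=freqs, psd=psd, labels=list(epoched.labels),
        window_len_s=window_len_s, overlap=overlap, window=window,
    )


def relative_band_power(ps: PowerSpectrum, scheme: BandScheme | None = None) -> BandPowerTable:
    """RP(ch, band) = sum of PSD bins in [lo, hi) / sum over the analysis range.

    Bins are assigned half-open, so a contiguous band partition yields rows
    that sum to exactly 1.
    """
    scheme = scheme or BandScheme.default()
    lo_all, hi_all = ANALYSIS_RANGE
    in_range = (ps.freqs >= lo_all) & (ps.freqs < hi_all)
    total = ps.psd[:, in_range].sum(axis=1)
    if np.any(total <= 0):
        bad = [ps.labels[i] for i in np.flatnonzero(total <= 0)]
        raise ValueError(f"zero total power in channel(s): {', '.join(bad)}")
    cols = {}
    for name, lo, hi in scheme.bands:
        sel = (ps.freqs >= lo) & (ps.freqs < hi)
        cols[name] = ps.psd[:, sel].sum(axis=1) / total
    return BandPowerTable(
        values=pd.DataFrame(cols, index=ps.labels), scheme=scheme
    )


def band_power_study_table(tables: dict[str, BandPowerTable]) -> pd.DataFrame:
    """Stack per-subject tables into a tidy subject x channel x band frame."""
    frames = []
    for subject, tab in tables.items():
        long = tab.values.reset_index(names="channel").melt(
            id_vars="channel", var_name="band", value_name="relative_power"
        )
        long.insert(0, "subject", subject)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)
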