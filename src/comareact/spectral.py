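"""Spectral power in unit-width frequency bins (2–20 Hz) and band contrasts.

The estimator is FFT-based: Welch averaging of tapered, overlapping segments
within each 10-s epoch (default 2-s Hann, 50% overlap); a single
rectangular full-epoch window reduces it to the plain periodogram, which is
the mode the oracle tests pin down.  Spectra are normalized per electrode
to relative power over [2, 20) Hz and integrated over the 18 half-open
unit bins [2,3), [3,4), …, [19,20).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io_formats import (
    REST,
    STIM_CONDITIONS,
    VALENCE_PAIRS,
    EpochSet,
)

#: Integration range and the 19 edges of the 18 unit-width bins.
FREQ_LO, FREQ_HI = 2.0, 20.0
BIN_EDGES = np.arange(FREQ_LO, FREQ_HI + 1.0)
N_BINS = len(BIN_EDGES) - 1

#: Band scheme used for stimulation-vs-rest contrasts.
CONTRAST_BANDS: dict[str, tuple[float, float]] = {
    "slow": (2.0, 6.0),
    "theta": (4.0, 6.0),
    "alpha": (11.0, 13.0),
    "beta": (17.0, 20.0),
}
#: Alternate scheme used for resting-state group comparisons.
RESTING_BANDS: dict[str, tuple[float, float]] = {
    "slow": (2.0, 6.0),
    "theta": (4.0, 6.0),
    "alpha": (8.0, 12.0),
    "beta": (16.0, 20.0),
}
BAND_SCHEMES = {"contrast": CONTRAST_BANDS, "resting": RESTING_BANDS}


@dataclass(frozen=True)
class WindowSpec:
    """Welch segmentation: segment length (s), fractional overlap, taper.

    ``segment_seconds=None`` means one full-epoch segment.  ``window
    ='boxcar'`` with a full-epoch segment is the plain periodogram.
    """

    segment_seconds: float | None = 2.0
    overlap: float = 0.5
    window: str = "hann"

    def nperseg(self, n_samples: int, rate: float) -> int:
        if self.segment_seconds is None:
            return n_samples
        n = int(round(self.segment_seconds * rate))
        if n > n_samples:
            raise ValueError(
                f"epoch of {n_samples} samples is shorter than the "
                f"{self.segment_seconds:g}-s analysis window"
            )
        return n


PERIODOGRAM = WindowSpec(segment_seconds=None, overlap=0.0, window="boxcar")


def compute_psd(epoch: np.ndarray, rate: float,
                window_spec: WindowSpec = WindowSpec()) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD per electrode for one epoch (or a stack of epochs).

    ``epoch`` is (..., n_samples); returns ``(freqs, psd)`` with ``psd`` of
    shape (..., n_freqs) in power per Hz.  Requires at least 2 s of data.
    """
    epoch = np.asarray(epoch, dtype=float)
    n_samples = epoch.shape[-1]
    if n_samples < 2 * rate:
        raise ValueError("epoch must contain at least 2 s of samples")
    if np.isnan(epoch).any():
        raise ValueError("epoch contains NaN samples")
    nperseg = window_spec.nperseg(n_samples, rate)
    noverlap = int(round(window_spec.overlap * nperseg))
    freqs, psd = signal.welch(
        epoch, fs=rate, window=window_spec.window,
        nperseg=nperseg, noverlap=noverlap, detrend=False, axis=-1,
    )
    return freqs, psd


def _integral(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Trapezoidal integral of the density over [lo, hi], interpolating edges."""
    inside = (freqs > lo) & (freqs < hi)
    xs = np.concatenate(([lo], freqs[inside], [hi]))
    edge_lo = _interp_along(freqs, psd, lo)
    edge_hi = _interp_along(freqs, psd, hi)
    ys = np.concatenate(
        [edge_lo[..., None], psd[..., inside], edge_hi[..., None]], axis=-1
    )
    return np.trapezoid(ys, xs, axis=-1)


def _interp_along(freqs, psd, f0):
    idx = np.searchsorted(freqs, f0)
    if idx < len(freqs) and freqs[idx] == f0:
        return psd[..., idx]
    x0, x1 = freqs[idx - 1], freqs[idx]
    w = (f0 - x0) / (x1 - x0)
    return (1 - w) * psd[..., idx - 1] + w * psd[..., idx]


def normalize_spectrum(freqs: np.ndarray, psd: np.ndarray,
                       mode: str = "relative") -> np.ndarray:
    """Divide each electrode's spectrum by its total power over [2, 20) Hz.

    After unit-bin integration the 18 bins then sum to 1 (relative power).
    ``mode='none'`` passes the spectrum through unchanged.
    """
    if mode == "none":
        return psd
    if mode != "relative":
        raise ValueError("mode must be 'relative' or 'none'")
    total = _integral(freqs, psd, FREQ_LO, FREQ_HI)
    if np.any(total <= 0):
        raise ValueError("zero total power in [2, 20) Hz: degenerate flat signal")
    return psd / total[..., None]


def integrate_bins(freqs: np.ndarray, psd: np.ndarray) -> np.ndarray:
    """Integrate the density over the 18 half-open unit bins [2,3), …, [19,20).

    Returns (..., 18).  The frequency grid must resolve the bins (spacing
    ≤ 1 Hz) and cover [2, 20].
    """
    freqs = np.asarray(freqs)
    if freqs[0] > FREQ_LO or freqs[-1] < FREQ_HI:
        raise ValueError("spectrum must cover [2, 20] Hz")
    if np.max(np.diff(freqs)) > 1.0 + 1e-12:
        raise ValueError("frequency grid coarser than 1 Hz cannot resolve unit bins")
    out = np.empty(psd.shape[:-1] + (N_BINS,), dtype=float)
    for b in range(N_BINS):
        out[..., b] = _integral(freqs, psd, BIN_EDGES[b], BIN_EDGES[b + 1])
    return out


def band_power(bins: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Mean of the unit-bin powers whose bins lie within [low, high)."""
    lo, hi = band
    if not (FREQ_LO <= lo < hi <= FREQ_HI):
        raise ValueError(f"band {band} outside [{FREQ_LO:g}, {FREQ_HI:g})")
    if lo != int(lo) or hi != int(hi):
        raise ValueError(f"band {band} must align with integer bin edges")
    i0, i1 = int(lo - FREQ_LO), int(hi - FREQ_LO)
    return np.asarray(bins)[..., i0:i1].mean(axis=-1)


def epoch_bin_spectrum(epochs: np.ndarray, rate: float,
                       window_spec: WindowSpec = WindowSpec(),
                       normalize: str = "relative") -> np.ndarray:
    """Per-epoch pipeline: PSD → normalize → unit bins, for a stack of epochs."""
    freqs, psd = compute_psd(epochs, rate, window_spec)
    psd = normalize_spectrum(freqs, psd, mode=normalize)
    return integrate_bins(freqs, psd)


def merged_conditions(merge_rule: str) -> dict[str, tuple[str, ...]]:
    """Condition groupings for a merge rule; rest is always kept separate."""
    if merge_rule == "per-stimulus-type":
        groups = {c: (c,) for c in STIM_CONDITIONS}
    elif merge_rule == "valence-pairs":
        groups = dict(VALENCE_PAIRS)
    elif merge_rule == "all-stimulation":
        groups = {"stimulation": STIM_CONDITIONS}
    else:
        raise ValueError(
            "merge_rule must be 'per-stimulus-type', 'valence-pairs' or "
            "'all-stimulation'"
        )
    return {REST: (REST,), **groups}


def condition_table(
    epoch_sets: list[EpochSet],
    band_scheme: dict[str, tuple[float, float]] = CONTRAST_BANDS,
    window_spec: WindowSpec = WindowSpec(),
    merge_rule: str = "per-stimulus-type",
    normalize: str = "relative",
) -> pd.DataFrame:
    """Long-format band-power table: subject × condition × electrode × band.

    Per subject and (merged) condition the PSD is the mean of the per-epoch
    raw spectra (equivalent in expectation to concatenating the epochs),
    then normalized, binned and band-averaged.  Conditions missing for a
    subject are recorded as absent; downstream contrasts exclude such
    subjects.
    """
    rows = []
    groups = merged_conditions(merge_rule)
    for es in epoch_sets:
        channels = es.channels
        for merged_name, members in groups.items():
            stacks = [es.epochs[c] for c in members if c in es.epochs]
            if not stacks:
                continue
            stack = np.concatenate(stacks, axis=0)
            freqs, psd = compute_psd(stack, es.sample_rate, window_spec)
            mean_psd = psd.mean(axis=0)  # (n_ch, n_freq)
            mean_psd = normalize_spectrum(freqs, mean_psd, mode=normalize)
            bins = integrate_bins(freqs, mean_psd)
            for band_name, band in band_scheme.items():
                bp = band_power(bins, band)
                for ci, ch in enumerate(channels):
                    rows.append((es.subject_id, es.group, merged_name,
                                 ch, band_name, bp[ci]))
    return pd.DataFrame(
        rows, columns=["subject", "group", "condition", "electrode", "band", "power"]
    )


def contrast(table: pd.DataFrame, band: str,
             stim_rule: str | list[str] = "all") -> pd.DataFrame:
    """Stimulation-minus-rest band-power difference per subject × electrode.

    ``stim_rule='all'`` averages the band power over every non-rest
    condition present; a list restricts to named conditions.  Subjects
    lacking rest or all requested stimulation conditions are dropped.
    Returns a wide DataFrame indexed by subject with electrode columns.
    """
    sub = table[table["band"] == band]
    if sub.empty:
        raise ValueError(f"band {band!r} not present in the table")
    rows = {}
    for subject, st in sub.groupby("subject", sort=False):
        rest = st[st["condition"] == REST]
        if stim_rule == "all":
            stim = st[st["condition"] != REST]
        else:
            stim = st[st["condition"].isin(list(stim_rule))]
        if rest.empty or stim.empty:
            continue
        rest_p = rest.set_index("electrode")["power"]
        stim_p = stim.groupby("electrode", sort=False)["power"].mean()
        rows[subject] = (stim_p - rest_p).dropna()
    if not rows:
        raise ValueError("no subject retains both rest and stimulation conditions")
    out = pd.DataFrame(rows).T
    out.index.name = "subject"
    if out.isna().any().any():
        raise ValueError("electrode sets differ across conditions")
    return out
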