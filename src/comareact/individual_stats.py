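"""Per-subject significance of stimulation-vs-rest band-power change.

Each subject contributes 4 × 10 stimulation trials and 40 rest fragments
(10 s each); per electrode the per-trial band powers are compared with a
two-sample rank test, Bonferroni-corrected across the 19 electrodes
(0.05 / 19 ≈ 0.0026).  The stimulation trials and rest fragments are not
naturally paired, so the default test is the unpaired rank-sum
(Mann–Whitney-equivalent) form; a paired signed-rank mode exists for
equal-count paired designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import spectral
from .io_formats import REST, STIM_CONDITIONS, EpochSet
from .spectral import CONTRAST_BANDS, WindowSpec

#: Exact enumeration below this per-group size (tie-free); normal
#: approximation with tie correction at or above it.
APPROX_MIN_N = 20


def trial_band_powers(epoch_set: EpochSet, band: tuple[float, float],
                      conditions=STIM_CONDITIONS,
                      window_spec: WindowSpec = WindowSpec(),
                      normalize: str = "relative") -> np.ndarray:
    """One band-power value per trial per electrode.

    Stacks the epochs of the given conditions and runs the single-epoch
    spectral pipeline (PSD → normalize → unit bins → band) trial-wise.
    Returns (n_trials, n_electrodes).
    """
    if isinstance(conditions, str):
        conditions = (conditions,)
    stacks = [epoch_set.epochs[c] for c in conditions if c in epoch_set.epochs]
    if not stacks:
        raise ValueError(f"no epochs for conditions {tuple(conditions)}")
    stack = np.concatenate(stacks, axis=0)
    bins = spectral.epoch_bin_spectrum(stack, epoch_set.sample_rate,
                                       window_spec, normalize)
    return spectral.band_power(bins, band)


def wilcoxon_rank(stim_values, rest_values, mode: str = "unpaired"
                  ) -> tuple[float, float]:
    """Rank test of stimulation vs rest per-trial values: returns (W, p).

    Unpaired mode is the rank-sum test (midrank ties; exact enumeration
    for small tie-free samples, normal approximation with tie correction
    for ≥ 20 per group); W is the rank sum of the stimulation sample.
    Paired mode is the signed-rank test on differences.  If every value in
    both groups is identical the test is flagged degenerate with p = 1.
    """
    stim = np.asarray(stim_values, dtype=float)
    rest = np.asarray(rest_values, dtype=float)
    if stim.size < 5 or rest.size < 5:
        raise ValueError("need at least 5 values per condition")
    if mode == "paired":
        if stim.size != rest.size:
            raise ValueError("paired mode requires equal counts")
        diff = stim - rest
        if np.all(diff == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(stim, rest)
        return float(res.statistic), float(res.pvalue)
    if mode != "unpaired":
        raise ValueError("mode must be 'unpaired' or 'paired'")

    pooled = np.concatenate([stim, rest])
    if np.all(pooled == pooled[0]):
        w = stim.size * (pooled.size + 1) / 2.0
        return float(w), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    small = min(stim.size, rest.size) < APPROX_MIN_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(stim, rest, alternative="two-sided", method=method)
    w = float(res.statistic) + stim.size * (stim.size + 1) / 2.0  # rank sum
    return w, float(res.pvalue)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test alpha controlling the family-wise rate: alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def display_threshold(alpha: float, n_tests: int) -> float:
    """Corrected threshold rounded to 2 significant figures for display."""
    value = bonferroni_threshold(alpha, n_tests)
    return float(f"{value:.2g}")


@dataclass
class IndividualResult:
    """Per-electrode reactivity test for one subject and band."""

    subject_id: str
    group: str
    band: str
    table: pd.DataFrame  # electrode, W, p, significant, direction
    corrected_alpha: float
    responder: bool
    responder_direction: str

    def significant_electrodes(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "electrode"])


def individual_map(epoch_set: EpochSet, band_name: str = "theta",
                   band_scheme: dict[str, tuple[float, float]] = CONTRAST_BANDS,
                   alpha: float = 0.05,
                   n_tests: int | None = None,
                   direction: str = "decrease",
                   window_spec: WindowSpec = WindowSpec(),
                   mode: str = "unpaired") -> IndividualResult:
    """Per-electrode stimulation-vs-rest test for one subject.

    A subject is flagged a *responder* when at least one electrode is
    significant at the Bonferroni-corrected threshold with the stated
    direction of change (default: band-power decrease).
    """
    band = band_scheme[band_name]
    stim = trial_band_powers(epoch_set, band, STIM_CONDITIONS, window_spec)
    rest = trial_band_powers(epoch_set, band, (REST,), window_spec)
    n_electrodes = stim.shape[1]
    corrected = bonferroni_threshold(alpha, n_tests or n_electrodes)

    rows = []
    for ci, electrode in enumerate(epoch_set.channels):
        w, p = wilcoxon_rank(stim[:, ci], rest[:, ci], mode=mode)
        delta = np.median(stim[:, ci]) - np.median(rest[:, ci])
        change = "decrease" if delta < 0 else ("increase" if delta > 0 else "none")
        rows.append((electrode, w, p, p < corrected, change))
    table = pd.DataFrame(
        rows, columns=["electrode", "W", "p", "significant", "direction"])
    hits = table[table["significant"] & (table["direction"] == direction)]
    return IndividualResult(
        subject_id=epoch_set.subject_id, group=epoch_set.group, band=band_name,
        table=table, corrected_alpha=corrected,
        responder=not hits.empty, responder_direction=direction,
    )


def star_map(results: list[IndividualResult]) -> str:
    """Text grid of significant electrodes (rows: subjects, *: significant)."""
    if not results:
        return ""
    electrodes = list(results[0].table["electrode"])
    lines = ["subject " + " ".join(f"{e:>3s}" for e in electrodes)]
    for res in results:
        flags = res.table.set_index("electrode")["significant"]
        cells = " ".join(f"{'  *' if flags[e] else '  .'}" for e in electrodes)
        lines.append(f"{res.subject_id:>7s} {cells}")
    return "\n".join(lines)
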