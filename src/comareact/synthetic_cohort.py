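"""Synthetic study cohort: EEG epochs, morphometry tables, clinical outcomes.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage is testable without patient data:

* EEG epochs are 1/f background noise plus band-limited oscillatory
  components (zero-phase band-pass filtered Gaussian noise, scaled so the
  mean periodogram band power hits the component target).  Patients have
  elevated slow-wave (2–6 Hz) and reduced alpha/beta power at rest;
  stimulation multiplies the theta component by ``1 − d`` where ``d`` is a
  per-patient latent suppression effect, and raises alpha/beta power in
  both groups.
* Morphometry follows group-specific normal distributions for cortical
  thickness; patient volume covariates and outcome are coupled to the
  latent suppression through a Gaussian copula, so the Spearman correlation
  between the theta contrast (stimulation − rest, decreasing in ``d``) and
  each covariate is controlled in expectation.
* Outcomes (GOSe) are quantile-mapped onto the empirical clinical
  distribution of the study cohort and rank-coupled to suppression.

Trial structure defaults: 4 stimulus types × 10 presentations × 10 s, plus
40 rest fragments of 10 s, at 250 Hz on the 19-channel 10-20 montage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sps

from . import spectral
from .io_formats import (
    ALL_CONDITIONS,
    REST,
    ClinicalRecord,
    EpochSet,
    MorphometryRecord,
    epochs_to_recording,
    write_clinical,
    write_edf,
    write_epoch_archive,
    write_morphometry,
)
from .montage import ELECTRODES

PATIENT, CONTROL = "patient", "control"

#: Observed clinical scores of the study's ten patients (outcome and
#: admission coma depth); the generator resamples these empirical
#: distributions by quantile mapping.
OBSERVED_GOSE: tuple[int, ...] = (6, 3, 5, 3, 3, 5, 6, 3, 5, 7)
OBSERVED_GCS: tuple[int, ...] = (5, 7, 7, 6, 5, 6, 7, 5, 6, 5)

#: Cortical thickness distributions (mm): region -> hemi -> (control mean,
#: control sd, patient mean, patient sd), as tabulated for the study groups.
THICKNESS_TABLE: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "anteriorcingulate": {"rh": (2.7, 0.3, 2.5, 0.2), "lh": (2.8, 0.2, 2.7, 0.4)},
    "posteriorcingulate": {"rh": (2.5, 0.2, 2.5, 0.2), "lh": (2.6, 0.1, 2.4, 0.2)},
    "middlefrontal": {"rh": (2.6, 0.1, 2.6, 0.2), "lh": (2.5, 0.1, 2.4, 0.2)},
    "parahippocampal": {"rh": (2.8, 0.3, 2.8, 0.3), "lh": (2.8, 0.3, 2.9, 0.2)},
    "inferiorparietal": {"rh": (2.5, 0.1, 2.4, 0.1), "lh": (2.5, 0.1, 2.4, 0.1)},
    "superiorparietal": {"rh": (2.2, 0.1, 2.2, 0.1), "lh": (2.2, 0.1, 2.1, 0.1)},
    "paracentral": {"rh": (2.5, 0.1, 2.3, 0.1), "lh": (2.4, 0.2, 2.3, 0.1)},
    "postcentral": {"rh": (2.0, 0.1, 2.0, 0.1), "lh": (2.0, 0.1, 2.0, 0.1)},
    "precentral": {"rh": (2.6, 0.1, 2.3, 0.2), "lh": (2.6, 0.1, 2.3, 0.2)},
    "precuneus": {"rh": (2.4, 0.1, 2.4, 0.1), "lh": (2.4, 0.1, 2.4, 0.1)},
    "supramarginal": {"rh": (2.6, 0.1, 2.4, 0.2), "lh": (2.6, 0.1, 2.4, 0.2)},
    "insula": {"rh": (3.1, 0.1, 2.9, 0.2), "lh": (3.1, 0.1, 2.8, 0.2)},
}

#: Volume covariates (voxel counts): name -> group -> (mean, sd).
VOLUME_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "right-putamen": {CONTROL: (5800.0, 500.0), PATIENT: (4600.0, 600.0)},
    "left-putamen": {CONTROL: (5700.0, 500.0), PATIENT: (4550.0, 600.0)},
    "right-insula": {CONTROL: (7400.0, 600.0), PATIENT: (6200.0, 700.0)},
    "left-insula": {CONTROL: (7300.0, 600.0), PATIENT: (6150.0, 700.0)},
}
TOTAL_GRAY = {CONTROL: (650000.0, 40000.0), PATIENT: (520000.0, 50000.0)}
SURFACE_HOLES = {CONTROL: (25.0, 10.0), PATIENT: (90.0, 35.0)}


def _default_band_power() -> dict[str, dict[str, float]]:
    # Oscillatory component targets (µV² within the component band) at rest.
    # Patients: elevated slow-wave (delta+theta) and reduced alpha/beta.
    return {
        CONTROL: {"delta": 10.0, "theta": 10.0, "alpha": 40.0, "beta": 10.0},
        PATIENT: {"delta": 45.0, "theta": 40.0, "alpha": 12.0, "beta": 5.0},
    }


def _default_coupling() -> dict[str, float]:
    # Target Spearman correlation between the per-subject theta contrast
    # (stimulation − rest; negative under suppression) and each covariate.
    return {
        "total_gray_volume": 0.85,
        "right_putamen": 0.85,
        "right_insula": 0.85,
        "surface_holes": -0.85,
        "gose": -0.70,
    }


@dataclass
class CohortSpec:
    """Study-design parameters of the synthetic cohort."""

    n_patients: int = 10
    n_controls: int = 15
    sample_rate: float = 250.0
    epoch_seconds: float = 10.0
    trials_per_condition: int = 10
    n_rest_fragments: int = 40
    #: Component frequency bands (Hz) used for synthesis.
    component_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "delta": (2.0, 4.0), "theta": (4.0, 6.0),
            "alpha": (8.0, 13.0), "beta": (16.0, 20.0),
        }
    )
    band_power: dict[str, dict[str, float]] = field(default_factory=_default_band_power)
    #: 1/f background: spectral exponent and total 2–20 Hz power (µV²),
    #: sized so the control resting alpha SNR is about 2.
    background_exponent: float = 1.0
    background_power: float = 110.0
    #: Multiplier on alpha/beta component power under stimulation (both groups).
    stim_alpha_beta_gain: float = 1.15
    #: Range of the latent theta-suppression effect in patients.
    suppression_range: tuple[float, float] = (0.15, 0.65)
    coupling: dict[str, float] = field(default_factory=_default_coupling)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("cohort counts must be positive")
        if self.trials_per_condition <= 0 or self.n_rest_fragments <= 0:
            raise ValueError("trial counts must be positive")
        for group, powers in self.band_power.items():
            for band, p in powers.items():
                if p < 0:
                    raise ValueError(f"band power {group}/{band} must be >= 0")
        if self.background_power < 0:
            raise ValueError("background_power must be >= 0")
        for name, rho in self.coupling.items():
            if abs(rho) > 0.99:
                raise ValueError(
                    f"target correlation {name}={rho} unreachable (|rho| > 0.99)"
                )
        lo, hi = self.suppression_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("suppression_range must satisfy 0 <= lo <= hi < 1")

    # -- subject bookkeeping ------------------------------------------------
    def patient_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_patients)]

    def control_ids(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_controls)]

    def subjects(self) -> list[tuple[str, str]]:
        return [(s, PATIENT) for s in self.patient_ids()] + \
               [(s, CONTROL) for s in self.control_ids()]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        spec = cls(**d)
        spec.component_bands = {k: tuple(v) for k, v in spec.component_bands.items()}
        spec.suppression_range = tuple(spec.suppression_range)
        return spec


@dataclass
class GroundTruth:
    """Latent quantities behind a generated cohort (for recovery tests)."""

    seed: int
    suppression: dict[str, float]   # subject -> d in [0, 1)
    latent: dict[str, float]        # subject -> standard-normal z behind d
    coupling: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _rng(spec: CohortSpec, *stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, *stream])


def draw_ground_truth(spec: CohortSpec) -> GroundTruth:
    """Draw the latent suppression effects; controls have d = 0."""
    spec.validate()
    rng = _rng(spec, 1)
    lo, hi = spec.suppression_range
    suppression, latent = {}, {}
    from scipy.stats import norm

    for i, sid in enumerate(spec.patient_ids()):
        z = float(rng.standard_normal())
        latent[sid] = z
        suppression[sid] = lo + (hi - lo) * float(norm.cdf(z))
    for sid in spec.control_ids():
        latent[sid] = 0.0
        suppression[sid] = 0.0
    return GroundTruth(
        seed=spec.seed, suppression=suppression, latent=latent,
        coupling=dict(spec.coupling),
    )


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _band_envelope(n: int, rate: float, lo: float, hi: float) -> np.ndarray:
    """Squared magnitude response of a zero-phase 4th-order Butterworth
    band-pass — the spectral envelope of forward-backward filtered noise."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=rate, output="sos")
    _, h = sps.sosfreqz(sos, worN=freqs, fs=rate)
    return np.abs(h) ** 2


@lru_cache(maxsize=8)
def _background_envelope(n: int, rate: float, exponent: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    amp = np.ones_like(freqs)
    nz = freqs >= 1.0
    amp[nz] = freqs[nz] ** (-exponent / 2.0)
    amp[0] = 0.0
    return amp


def _shaped_spectrum(rng, shape, amp: np.ndarray) -> np.ndarray:
    """Complex Gaussian spectrum with the given amplitude envelope."""
    eps = (rng.standard_normal(shape + (len(amp),))
           + 1j * rng.standard_normal(shape + (len(amp),)))
    return amp * eps


def _calibrated(spec_arr: np.ndarray, freqs: np.ndarray, n: int, rate: float,
                lo: float, hi: float, target: float) -> np.ndarray:
    """Scale a spectrum so its mean periodogram power in [lo, hi] is target.

    The one-sided periodogram of ``irfft(S)`` is 2|S|²/(rate·n), so the
    band power is read off the spectrum directly.
    """
    psd = 2.0 * np.abs(spec_arr) ** 2 / (rate * n)
    v = float(np.mean(spectral._integral(freqs, psd.mean(axis=(0, 1)), lo, hi)))
    return spec_arr * np.sqrt(target / v)


def generate_eeg(spec: CohortSpec, ground_truth: GroundTruth,
                 subject_id: str, condition: str,
                 n_epochs: int | None = None) -> np.ndarray:
    """Generate the epochs of one subject × condition.

    Returns an array (n_epochs, 19, epoch_samples).  Deterministic in
    (seed, subject, condition): regenerating with the same arguments
    reproduces the data exactly.
    """
    spec.validate()
    if condition not in ALL_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if subject_id not in ground_truth.suppression:
        raise ValueError(f"unknown subject {subject_id!r}")
    group = PATIENT if subject_id.startswith("P") else CONTROL
    if n_epochs is None:
        n_epochs = (spec.n_rest_fragments if condition == REST
                    else spec.trials_per_condition)
    n = int(round(spec.epoch_seconds * spec.sample_rate))
    n_ch = len(ELECTRODES)
    subj_code = int(subject_id[1:]) + (0 if group == PATIENT else 1000)
    cond_code = ALL_CONDITIONS.index(condition)
    rng = _rng(spec, 2, subj_code, cond_code)

    powers = dict(spec.band_power[group])
    if condition != REST:
        d = ground_truth.suppression[subject_id]
        powers["theta"] = powers["theta"] * (1.0 - d)
        powers["alpha"] = powers["alpha"] * spec.stim_alpha_beta_gain
        powers["beta"] = powers["beta"] * spec.stim_alpha_beta_gain

    rate = spec.sample_rate
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    total = np.zeros((n_epochs, n_ch, len(freqs)), dtype=complex)
    if spec.background_power > 0:
        bg = _shaped_spectrum(rng, (n_epochs, n_ch),
                              _background_envelope(n, rate, spec.background_exponent))
        total += _calibrated(bg, freqs, n, rate, spectral.FREQ_LO,
                             spectral.FREQ_HI, spec.background_power)
    for band, (lo, hi) in spec.component_bands.items():
        target = powers.get(band, 0.0)
        comp = _shaped_spectrum(rng, (n_epochs, n_ch),
                                _band_envelope(n, rate, lo, hi))
        if target <= 0:
            continue
        total += _calibrated(comp, freqs, n, rate, lo, hi, target)
    if n % 2 == 0:
        total[..., -1] = total[..., -1].real
    return np.fft.irfft(total, n=n, axis=-1)


def generate_subject_epochs(spec: CohortSpec, ground_truth: GroundTruth,
                            subject_id: str) -> EpochSet:
    """All five conditions of one subject as an EpochSet."""
    group = PATIENT if subject_id.startswith("P") else CONTROL
    epochs = {
        cond: generate_eeg(spec, ground_truth, subject_id, cond)
        for cond in ALL_CONDITIONS
    }
    return EpochSet(
        subject_id=subject_id, group=group, channels=ELECTRODES,
        sample_rate=spec.sample_rate, epochs=epochs,
    )


# ---------------------------------------------------------------------------
# morphometry and outcomes (Gaussian-copula coupling)
# ---------------------------------------------------------------------------

def _pearson_for_spearman(rho_s: float) -> float:
    """Bivariate-normal Pearson correlation that yields Spearman rho_s."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _coupled_normal(rng, u: np.ndarray, rho_s: float) -> np.ndarray:
    """Standard-normal vector with Spearman correlation rho_s to latent u."""
    rho_p = _pearson_for_spearman(rho_s)
    eps = rng.standard_normal(u.shape)
    return rho_p * u + np.sqrt(1.0 - rho_p ** 2) * eps


def generate_morphometry(spec: CohortSpec,
                         ground_truth: GroundTruth) -> list[MorphometryRecord]:
    """Per-subject thickness and volume records.

    Patient volume covariates are monotone transforms of latents coupled to
    the theta contrast (which decreases in the latent suppression), so the
    target Spearman correlations hold in expectation; controls and
    non-covariate structures are uncoupled.
    """
    spec.validate()
    rng = _rng(spec, 3)
    # Latent axis of the theta *contrast*: contrast = stim − rest falls as
    # d (hence z) rises, so the contrast is monotone in −z.
    z = np.array([ground_truth.latent[s] for s in spec.patient_ids()])
    u = -z
    coupled = {
        "total_gray_volume": _coupled_normal(
            rng, u, spec.coupling.get("total_gray_volume", 0.0)),
        "right-putamen": _coupled_normal(
            rng, u, spec.coupling.get("right_putamen", 0.0)),
        "right-insula": _coupled_normal(
            rng, u, spec.coupling.get("right_insula", 0.0)),
        "surface_holes": _coupled_normal(
            rng, u, spec.coupling.get("surface_holes", 0.0)),
    }

    records = []
    for group, ids in ((PATIENT, spec.patient_ids()), (CONTROL, spec.control_ids())):
        for i, sid in enumerate(ids):
            thickness: dict[str, dict[str, float]] = {"lh": {}, "rh": {}}
            for region, hemis in THICKNESS_TABLE.items():
                for hemi, (cm, cs, pm, ps) in hemis.items():
                    mean, sd = (pm, ps) if group == PATIENT else (cm, cs)
                    value = mean + sd * rng.standard_normal()
                    thickness[hemi][region] = float(np.clip(value, 0.5, 5.5))
            volumes = {}
            for name, per_group in VOLUME_TABLE.items():
                mean, sd = per_group[group]
                if group == PATIENT and name in coupled:
                    w = coupled[name][i]
                else:
                    w = rng.standard_normal()
                volumes[name] = float(max(0.0, mean + sd * w))
            mean, sd = TOTAL_GRAY[group]
            w = coupled["total_gray_volume"][i] if group == PATIENT \
                else rng.standard_normal()
            total_gray = float(max(0.0, mean + sd * w))
            mean, sd = SURFACE_HOLES[group]
            w = coupled["surface_holes"][i] if group == PATIENT \
                else rng.standard_normal()
            holes = float(max(0.0, round(mean + sd * w)))
            records.append(
                MorphometryRecord(
                    subject_id=sid, thickness=thickness, volumes=volumes,
                    total_gray_volume=total_gray, surface_holes=holes,
                )
            )
    return records


def _empirical_quantile(sorted_values: tuple[int, ...], u: np.ndarray) -> np.ndarray:
    idx = np.minimum((u * len(sorted_values)).astype(int), len(sorted_values) - 1)
    return np.array(sorted_values)[idx]


def generate_outcomes(spec: CohortSpec,
                      ground_truth: GroundTruth) -> list[ClinicalRecord]:
    """Clinical records: GOSe rank-coupled to suppression, GCS uncoupled."""
    spec.validate()
    rng = _rng(spec, 4)
    from scipy.stats import norm

    z = np.array([ground_truth.latent[s] for s in spec.patient_ids()])
    w = _coupled_normal(rng, -z, spec.coupling.get("gose", 0.0))
    gose = _empirical_quantile(tuple(sorted(OBSERVED_GOSE)), norm.cdf(w))
    gcs = _empirical_quantile(
        tuple(sorted(OBSERVED_GCS)), rng.uniform(size=spec.n_patients))
    records = [
        ClinicalRecord(subject_id=sid, gcs=int(gcs[i]), gose=int(gose[i]),
                       group=PATIENT)
        for i, sid in enumerate(spec.patient_ids())
    ]
    records += [
        ClinicalRecord(subject_id=sid, gcs=15, gose=8, group=CONTROL)
        for sid in spec.control_ids()
    ]
    return records


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A generated study: tables in memory, EEG produced on demand."""

    spec: CohortSpec
    ground_truth: GroundTruth
    morphometry: list[MorphometryRecord]
    clinical: list[ClinicalRecord]

    def subjects(self) -> list[tuple[str, str]]:
        return self.spec.subjects()

    def epoch_set(self, subject_id: str) -> EpochSet:
        return generate_subject_epochs(self.spec, self.ground_truth, subject_id)


def generate_cohort(spec: CohortSpec) -> Cohort:
    gt = draw_ground_truth(spec)
    return Cohort(
        spec=spec,
        ground_truth=gt,
        morphometry=generate_morphometry(spec, gt),
        clinical=generate_outcomes(spec, gt),
    )


def write_cohort(cohort: Cohort, out_dir, dialect: str = "epoch_archive") -> Path:
    """Write a full cohort in the I/O dialects the pipeline reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    eeg_dir = out_dir / "eeg"
    eeg_dir.mkdir(exist_ok=True)
    for sid, _group in cohort.subjects():
        es = cohort.epoch_set(sid)
        if dialect == "epoch_archive":
            write_epoch_archive(es, eeg_dir / sid)
        elif dialect == "edf":
            write_edf(epochs_to_recording(es), eeg_dir / f"{sid}.edf")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    write_morphometry(cohort.morphometry, out_dir / "morphometry")
    write_clinical(cohort.clinical, out_dir / "clinical.tsv")
    with open(out_dir / "cohort.yaml", "w") as fh:
        yaml.safe_dump(cohort.spec.to_dict(), fh, sort_keys=True)
    with open(out_dir / "ground_truth.json", "w") as fh:
        fh.write(cohort.ground_truth.to_json())
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({"dialect": dialect, "seed": cohort.spec.seed,
                   "subjects": [s for s, _ in cohort.subjects()]}, fh, indent=1)
    return out_dir


def load_spec(path) -> CohortSpec:
    with open(path) as fh:
        return CohortSpec.from_dict(yaml.safe_load(fh))
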