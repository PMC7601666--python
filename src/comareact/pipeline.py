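"""Orchestration of the full study replica.

``run_simulate`` writes a synthetic cohort to disk in the package's I/O
dialects; ``run_analyze`` chains the analysis — band-power tables, group
statistics (rank tests, 2 GROUP × 5 CONDITIONS mixed ANOVA), per-subject
reactivity maps, and the cluster-based permutation battery — and writes
tab-separated result tables plus a run manifest; ``run_report`` renders a
human-readable summary of a finished results directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_perm, group_stats, individual_stats, spectral
from .cluster_perm import PermConfig
from .io_formats import (
    REST,
    FormatError,
    extract_epochs,
    read_clinical,
    read_epoch_archive,
    read_morphometry,
    read_recording,
    write_results,
)
from .spectral import BAND_SCHEMES, WindowSpec
from .synthetic_cohort import Cohort, CohortSpec, generate_cohort, load_spec, write_cohort

#: Covariates correlated with the theta contrast (volumes, damage, outcome)
#: and with the beta contrast (somatosensory cortical thickness).
THETA_BATTERY = ("total_gray_volume", "right_putamen", "right_insula",
                 "surface_holes", "gose")
BETA_BATTERY = ("paracentral_thickness", "precentral_thickness")


@dataclass
class RunConfig:
    """Run-level configuration: schemes, windows, permutations, seed."""

    band_scheme: str = "contrast"
    window: WindowSpec = field(default_factory=WindowSpec)
    perm: PermConfig = field(default_factory=PermConfig)
    seed: int = 0
    verbosity: int = 1

    def validate(self) -> None:
        if self.band_scheme not in BAND_SCHEMES:
            raise ValueError(
                f"band_scheme must be one of {sorted(BAND_SCHEMES)}")
        self.perm.validate()


class DiskCohort:
    """Cohort previously written by ``run_simulate``, read lazily."""

    def __init__(self, directory):
        directory = Path(directory)
        manifest_path = directory / "manifest.json"
        if not manifest_path.exists():
            raise FormatError(f"{directory}: no cohort manifest.json")
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        self.directory = directory
        self.dialect = manifest["dialect"]
        self._subjects = manifest["subjects"]
        self.spec = load_spec(directory / "cohort.yaml")
        self.clinical = read_clinical(directory / "clinical.tsv")
        morph_dir = directory / "morphometry"
        for name in ("lh.aparc.thickness.tsv", "rh.aparc.thickness.tsv",
                     "aseg.volume.tsv"):
            if not (morph_dir / name).exists():
                raise FileNotFoundError(morph_dir / name)
        self.morphometry = read_morphometry(
            {"lh": morph_dir / "lh.aparc.thickness.tsv",
             "rh": morph_dir / "rh.aparc.thickness.tsv"},
            morph_dir / "aseg.volume.tsv",
        )

    def subjects(self):
        groups = {c.subject_id: c.group for c in self.clinical}
        return [(s, groups.get(s, "unknown")) for s in self._subjects]

    def epoch_set(self, subject_id):
        if self.dialect == "epoch_archive":
            return read_epoch_archive(self.directory / "eeg" / subject_id)
        recording = read_recording(
            self.directory / "eeg" / f"{subject_id}.edf", dialect="edf")
        return extract_epochs(recording, self.spec.epoch_seconds)


def run_simulate(spec: CohortSpec, out_dir, dialect: str = "epoch_archive") -> Path:
    """Generate and write a synthetic cohort; returns the cohort directory."""
    spec.validate()
    cohort = generate_cohort(spec)
    return write_cohort(cohort, out_dir, dialect=dialect)


def _electrode_averaged_bins(cohort, window) -> pd.DataFrame:
    """Electrode-averaged relative unit-bin power per subject × condition."""
    rows = []
    for sid, group in cohort.subjects():
        es = cohort.epoch_set(sid)
        for cond, stack in es.epochs.items():
            freqs, psd = spectral.compute_psd(stack, es.sample_rate, window)
            mean_psd = spectral.normalize_spectrum(freqs, psd.mean(axis=0))
            bins = spectral.integrate_bins(freqs, mean_psd).mean(axis=0)
            for b, value in enumerate(bins):
                rows.append((sid, group, cond, int(spectral.BIN_EDGES[b]), value))
    return pd.DataFrame(
        rows, columns=["subject", "group", "condition", "bin_lo", "power"])


def _anova_tables(bin_table: pd.DataFrame,
                  bands: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Mixed ANOVA per 1-Hz bin, repeated for merged frequency bands."""
    rows = []

    def _run(label, response_table):
        design = group_stats.AnovaDesign(response_table)
        try:
            res = group_stats.rm_anova_2x5(design)
        except ValueError:
            return
        for effect, tr in res.items():
            rows.append((label, effect, tr.statistic, tr.df[0], tr.df[1],
                         tr.effect.get("ms", np.nan), tr.p))

    for bin_lo, sub in bin_table.groupby("bin_lo"):
        resp = sub.rename(columns={"power": "response"})[
            ["subject", "group", "condition", "response"]]
        _run(f"bin_{bin_lo}-{bin_lo + 1}Hz", resp)
    for band_name, (lo, hi) in bands.items():
        sub = bin_table[(bin_table["bin_lo"] >= lo) & (bin_table["bin_lo"] < hi)]
        resp = (sub.groupby(["subject", "group", "condition"], as_index=False)
                ["power"].mean().rename(columns={"power": "response"}))
        _run(f"band_{band_name}", resp)
    return pd.DataFrame(
        rows, columns=["response", "effect", "F", "df1", "df2", "MS", "p"])


def _morphometry_tests(cohort) -> pd.DataFrame:
    """Patient-vs-control Mann–Whitney comparisons of structural measures."""
    groups = {c.subject_id: c.group for c in cohort.clinical}
    patients = [m for m in cohort.morphometry if groups.get(m.subject_id) == "patient"]
    controls = [m for m in cohort.morphometry if groups.get(m.subject_id) == "control"]
    rows = []

    def _compare(label, pat_vals, ctl_vals):
        res = group_stats.mann_whitney_u(pat_vals, ctl_vals)
        rows.append((label, res.statistic, res.effect["z"], res.p,
                     float(np.median(pat_vals)), float(np.median(ctl_vals))))

    _compare("total_gray_volume",
             [m.total_gray_volume for m in patients],
             [m.total_gray_volume for m in controls])
    _compare("surface_holes",
             [m.surface_holes for m in patients],
             [m.surface_holes for m in controls])
    region_set = sorted({r for m in cohort.morphometry
                         for h in m.thickness.values() for r in h})
    for hemi in ("lh", "rh"):
        for region in region_set:
            try:
                pat = [m.thickness[hemi][region] for m in patients]
                ctl = [m.thickness[hemi][region] for m in controls]
            except KeyError:
                continue
            _compare(f"{hemi}_{region}_thickness", pat, ctl)
    return pd.DataFrame(
        rows, columns=["measure", "U", "Z", "p", "median_patient",
                       "median_control"])


def run_analyze(cohort, out_dir, config: RunConfig = RunConfig()) -> Path:
    """Run the full analysis chain and write result tables.

    ``cohort`` is an in-memory Cohort or a directory written by
    ``run_simulate``.  Stages: band-power tables → group statistics →
    individual reactivity maps → cluster-permutation batteries → summary.
    """
    config.validate()
    if not isinstance(cohort, (Cohort, DiskCohort)):
        cohort = DiskCohort(cohort)
    out_dir = Path(out_dir)
    bands = BAND_SCHEMES[config.band_scheme]
    stage = "band powers"
    try:
        subjects = cohort.subjects()
        band_table = spectral.condition_table(
            [cohort.epoch_set(s) for s, _ in subjects],
            band_scheme=bands, window_spec=config.window,
        )

        stage = "group statistics"
        bin_table = _electrode_averaged_bins(cohort, config.window)
        anova_table = _anova_tables(bin_table, bands)
        morph_table = _morphometry_tests(cohort)

        stage = "individual maps"
        individual_rows = []
        star_maps = {}
        for band_name in ("theta", "alpha", "beta"):
            results = []
            for sid, _group in subjects:
                res = individual_stats.individual_map(
                    cohort.epoch_set(sid), band_name, bands,
                    window_spec=config.window)
                results.append(res)
                for r in res.table.itertuples():
                    individual_rows.append(
                        (sid, res.group, band_name, r.electrode, r.W, r.p,
                         r.significant, r.direction, res.responder))
            star_maps[band_name] = individual_stats.star_map(results)
        individual_table = pd.DataFrame(
            individual_rows,
            columns=["subject", "group", "band", "electrode", "W", "p",
                     "significant", "direction", "responder"])

        stage = "cluster permutation"
        patient_table = band_table[band_table["group"] == "patient"]
        perm = PermConfig(
            n_permutations=config.perm.n_permutations,
            lower_quantile=config.perm.lower_quantile,
            upper_quantile=config.perm.upper_quantile,
            min_cluster_size=config.perm.min_cluster_size,
            threshold_mode=config.perm.threshold_mode,
            bonferroni_covariates=config.perm.bonferroni_covariates,
            seed=config.seed,
        )
        theta_contrast = spectral.contrast(patient_table, "theta")
        theta_results = cluster_perm.run_covariate_battery(
            theta_contrast, cohort.morphometry, cohort.clinical, perm,
            covariates=THETA_BATTERY)
        beta_contrast = spectral.contrast(patient_table, "beta")
        beta_results = cluster_perm.run_covariate_battery(
            beta_contrast, cohort.morphometry, cohort.clinical, perm,
            covariates=BETA_BATTERY)
        cluster_tables = pd.concat([
            cluster_perm.cluster_table(theta_results).assign(band="theta"),
            cluster_perm.cluster_table(beta_results).assign(band="beta"),
        ], ignore_index=True)

        stage = "writing results"
        write_results(
            {
                "band_power": band_table,
                "anova": anova_table,
                "morphometry_tests": morph_table,
                "individual_maps": individual_table,
                "clusters": cluster_tables,
                "theta_contrast": theta_contrast.reset_index(),
                "beta_contrast": beta_contrast.reset_index(),
            },
            out_dir,
            parameters={"band_scheme": config.band_scheme,
                        "n_permutations": perm.n_permutations},
            seed=config.seed,
        )
        for band_name, text in star_maps.items():
            (out_dir / f"star_map_{band_name}.txt").write_text(text + "\n")
        run_report(out_dir)
    except Exception as exc:
        raise RuntimeError(f"analysis stage failed: {stage}: {exc}") from exc
    return out_dir


def run_report(results_dir) -> Path:
    """Render a markdown summary of a finished results directory."""
    results_dir = Path(results_dir)
    required = ["band_power.tsv", "anova.tsv", "clusters.tsv",
                "individual_maps.tsv"]
    missing = [n for n in required if not (results_dir / n).exists()]
    if set(missing) == set(required):
        raise FileNotFoundError(f"{results_dir}: no analysis results found")
    lines = ["# Tactile-reactivity analysis report", ""]
    if missing:
        lines.append(f"**Warning**: missing tables: {', '.join(missing)}")

    bp = pd.read_csv(results_dir / "band_power.tsv", sep="\t")
    rest = bp[bp["condition"] == REST]
    med = rest.groupby(["group", "band"])["power"].median().unstack(0)
    lines += ["## Resting-state band power (relative, median per group)", "",
              med.to_markdown(), ""]
    for band in ("slow", "alpha", "beta"):
        if band not in med.index or med.shape[1] < 2:
            continue
        direction = "higher" if med.loc[band, "patient"] > med.loc[band, "control"] \
            else "lower"
        lines.append(f"- {band}: patients {direction} than controls")
    lines.append("")

    if (results_dir / "anova.tsv").exists():
        anova = pd.read_csv(results_dir / "anova.tsv", sep="\t")
        sig = anova[(anova["p"] < 0.05) & anova["response"].str.startswith("band")]
        lines += ["## Mixed ANOVA (GROUP × CONDITION), significant band effects", ""]
        lines.append(sig.to_markdown(index=False) if not sig.empty
                     else "none at p < 0.05")
        lines.append("")

    im = pd.read_csv(results_dir / "individual_maps.tsv", sep="\t")
    resp = (im[im["band"] == "theta"].groupby(["subject", "group"])["responder"]
            .first().reset_index())
    counts = resp.groupby("group")["responder"].sum()
    totals = resp.groupby("group")["responder"].size()
    lines += ["## Individual theta reactivity (responders)", ""]
    for group in counts.index:
        lines.append(f"- {group}: {int(counts[group])}/{int(totals[group])} "
                     "subjects with a significant theta decrease")
    lines.append("")

    cl = pd.read_csv(results_dir / "clusters.tsv", sep="\t")
    sig = cl[cl["significant"]]
    lines += ["## Cluster-permutation battery (significant clusters)", ""]
    lines.append(sig.to_markdown(index=False) if not sig.empty
                 else "no significant clusters")
    lines.append("")

    report_path = results_dir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
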