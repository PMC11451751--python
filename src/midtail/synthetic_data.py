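"""Seeded generator of ground-truth proteoform mixtures and EThcD spectra.

Emulates the acquisition the pipeline is built for: chimeric charge-8 EThcD
MS2 scans of TMT-tagged H3(1-32) tail peptides (precursors around
480-540 m/z), with

* fragment peaks at theoretical c/z m/z plus Gaussian ppm jitter and
  log-normal intensities,
* +1 heavy-isotope companion peaks at a configurable fraction of the
  monoisotopic intensity (0.45 by default, typical of ~4 kDa peptides),
* uniform random noise peaks,
* six TMT reporter channels drawn log-normally around condition means with
  the label impurity matrix applied forward, and
* a PSM table whose score distributions include a stated fraction of rows
  generated to fail the confidence filters.

Scan-to-proteoform assignment uses largest-remainder apportionment of the
mixture fractions (stratified rather than iid sampling), so in the
noiseless limit the pipeline recovers the input fractions exactly.
Everything derives from one seeded generator: the same seed reproduces the
emitted files byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    PSMRecord,
    RunDesign,
    Spectrum,
    default_run_design,
    write_psm_table,
    write_spectra_mzml,
)
from .mass_model import (
    C13_C12_SPACING,
    Proteoform,
    default_modification_registry,
    fragment_ladder,
    precursor_mz,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "default_proteoform_mixture",
    "simulate_dataset",
    "write_dataset",
    "simulate_bottom_up",
]


def default_proteoform_mixture() -> list[tuple[Proteoform, float]]:
    """A realistic 5-proteoform H3 tail mixture (acetyl/methyl combinatorics)."""
    return [
        (Proteoform("H3.1", ((14, "Acetyl"), (23, "Acetyl"), (27, "Dimethyl"))), 0.30),
        (Proteoform("H3.1", ((9, "Acetyl"), (14, "Acetyl"), (23, "Acetyl"), (27, "Dimethyl"))), 0.25),
        (Proteoform("H3.1", ((9, "Trimethyl"), (14, "Acetyl"))), 0.20),
        (Proteoform("H3.3", ((27, "Trimethyl"),)), 0.15),
        (Proteoform("H3.1", ((18, "Acetyl"), (23, "Acetyl"))), 0.10),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the simulator; defaults are the standard study conditions."""

    seed: int = 0
    proteoforms: list[tuple[Proteoform, float]] = field(
        default_factory=default_proteoform_mixture
    )
    n_scans: int = 200
    chimera_rate: float = 0.15
    precursor_charge: int = 8
    fragment_series: tuple[str, ...] = ("c", "z")
    fragment_charges: tuple[int, ...] = (1, 2)
    fragment_log_intensity_mu: float = math.log(1000.0)
    fragment_log_intensity_sigma: float = 0.8
    isotope_plus1_ratio: float = 0.45
    noise_peaks_per_scan: int = 30
    noise_intensity_range: tuple[float, float] = (1.0, 50.0)
    noise_mz_range: tuple[float, float] = (150.0, 1500.0)
    ppm_jitter_sigma: float = 3.0
    condition_effects: dict[str, float] = field(default_factory=dict)
    treated_condition: str | None = None  # defaults to the design's last condition
    reporter_base_intensity: float = 1e5
    reporter_cv: float = 0.3
    reporter_dropout: float = 0.05
    impurity_matrix: np.ndarray | None = None
    psm_fail_fraction: float = 0.1

    def validate(self) -> None:
        total = sum(f for _, f in self.proteoforms)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {total}, not 1")
        for rate in (self.chimera_rate, self.reporter_dropout, self.psm_fail_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if not 0.0 <= self.isotope_plus1_ratio <= 1.0:
            raise ValueError("isotope_plus1_ratio outside [0, 1]")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        known = {p.canonical_id for p, _ in self.proteoforms}
        unknown = set(self.condition_effects) - known
        if unknown:
            raise ValueError(f"condition effects for proteoforms not in the mixture: {unknown}")

    def noiseless(self) -> "SimulationConfig":
        """A copy with every stochastic corruption switched off."""
        return replace(
            self,
            chimera_rate=0.0,
            fragment_log_intensity_sigma=0.0,
            noise_peaks_per_scan=0,
            ppm_jitter_sigma=0.0,
            reporter_cv=0.0,
            reporter_dropout=0.0,
            psm_fail_fraction=0.0,
        )


@dataclass
class GroundTruth:
    """What the generator actually put into the files."""

    fractions: dict[str, float]
    scan_assignments: dict[str, list[str]]
    condition_effects: dict[str, float]
    condition_means_log2: dict[str, dict[str, float]]  # proteoform -> condition -> mean log2
    failing_rows: list[tuple[str, str]]  # (scan_id, proteoform_id)
    proteoforms: list[tuple[Proteoform, float]]

    def to_json(self, path) -> None:
        data = {
            "fractions": self.fractions,
            "scan_assignments": self.scan_assignments,
            "condition_effects": self.condition_effects,
            "condition_means_log2": self.condition_means_log2,
            "failing_rows": [list(t) for t in self.failing_rows],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)


@dataclass
class SimulatedDataset:
    spectra: list[Spectrum]
    psms: list[PSMRecord]
    design: RunDesign
    truth: GroundTruth


def _apportion(fractions: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n scans across mixture fractions."""
    quotas = [f * n for f in fractions]
    counts = [int(math.floor(q)) for q in quotas]
    short = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate spectra, PSM records, run design and ground truth from a config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    registry = default_modification_registry()
    design = default_run_design()
    if config.impurity_matrix is not None:
        design.impurity_matrix = np.asarray(config.impurity_matrix, dtype=float)
    treated = config.treated_condition or design.conditions[-1]
    if treated not in design.conditions:
        raise ValueError(f"treated condition {treated!r} not in the design")

    forms = [p for p, _ in config.proteoforms]
    fractions = [f for _, f in config.proteoforms]
    pids = [p.canonical_id for p in forms]

    # --- scan-to-proteoform assignment -------------------------------------
    n_chimeric = int(round(config.chimera_rate * config.n_scans))
    n_single = config.n_scans - n_chimeric
    assignments: list[list[int]] = []
    for i, c in enumerate(_apportion(fractions, n_single)):
        assignments.extend([[i]] * c)
    probs = np.asarray(fractions)
    for _ in range(n_chimeric):
        if len(forms) >= 2:
            pair = rng.choice(len(forms), size=2, replace=False, p=probs)
            assignments.append(sorted(int(j) for j in pair))
        else:
            assignments.append([0])
    order = rng.permutation(len(assignments))
    assignments = [assignments[int(k)] for k in order]

    # --- theoretical fragment ladders (cache) -------------------------------
    ladder_cache: dict[str, list] = {}
    for p in forms:
        frags = fragment_ladder(
            p,
            max_charge=max(config.fragment_charges),
            losses=("none",),
            series=config.fragment_series,
            registry=registry,
        )
        ladder_cache[p.canonical_id] = [
            f for f in frags if f.charge in config.fragment_charges
        ]

    sigma_ln = math.sqrt(math.log(1.0 + config.reporter_cv**2))
    spacing = C13_C12_SPACING
    spectra: list[Spectrum] = []
    psms: list[PSMRecord] = []
    failing: list[tuple[str, str]] = []
    scan_assignments: dict[str, list[str]] = {}

    for scan_num, members in enumerate(assignments, start=1):
        scan_id = f"scan{scan_num}"
        scan_forms = [forms[i] for i in members]
        scan_assignments[scan_id] = [p.canonical_id for p in scan_forms]

        # fragment peaks; coincident theoretical m/z across the scan's PSMs merge
        peak_map: dict[float, float] = {}
        for p in scan_forms:
            for frag in ladder_cache[p.canonical_id]:
                inten = float(
                    rng.lognormal(
                        config.fragment_log_intensity_mu,
                        config.fragment_log_intensity_sigma,
                    )
                )
                key = round(frag.theoretical_mz, 6)
                peak_map[key] = peak_map.get(key, 0.0) + inten

        charge_map: dict[float, int] = {}
        for p in scan_forms:
            for frag in ladder_cache[p.canonical_id]:
                charge_map[round(frag.theoretical_mz, 6)] = frag.charge

        mzs: list[float] = []
        intens: list[float] = []
        frag_items = sorted(peak_map.items())
        jitter = rng.normal(0.0, config.ppm_jitter_sigma, size=2 * len(frag_items))
        for j, (theo, inten) in enumerate(frag_items):
            mzs.append(theo * (1.0 + jitter[2 * j] * 1e-6))
            intens.append(inten)
            # +1 heavy-isotope companion so the fragment passes confirmation
            comp_theo = theo + spacing / charge_map[theo]
            mzs.append(comp_theo * (1.0 + jitter[2 * j + 1] * 1e-6))
            intens.append(inten * config.isotope_plus1_ratio)

        # noise peaks
        for _ in range(config.noise_peaks_per_scan):
            mzs.append(float(rng.uniform(*config.noise_mz_range)))
            intens.append(float(rng.uniform(*config.noise_intensity_range)))

        # TMT reporters: log-normal around condition means, impurities forward
        effect = float(
            np.mean([config.condition_effects.get(p.canonical_id, 0.0) for p in scan_forms])
        )
        true_rep = np.zeros(len(design.channels))
        dropped = np.zeros(len(design.channels), dtype=bool)
        for k, ch in enumerate(design.channels):
            shift = effect if design.channel_condition[ch] == treated else 0.0
            noise = float(rng.lognormal(0.0, sigma_ln)) if sigma_ln > 0 else 1.0
            true_rep[k] = config.reporter_base_intensity * (2.0**shift) * noise
            dropped[k] = bool(rng.random() < config.reporter_dropout)
        observed_rep = design.impurity_matrix @ true_rep
        for k, ch in enumerate(design.channels):
            if not dropped[k]:
                mzs.append(design.reporter_mz[ch])
                intens.append(float(observed_rep[k]))

        pmz = float(np.mean([precursor_mz(p, config.precursor_charge, registry) for p in scan_forms]))
        spectra.append(
            Spectrum(scan_id, pmz, config.precursor_charge,
                     np.array(mzs), np.array(intens))
        )

        # PSM rows with score model
        for p in scan_forms:
            fail = bool(rng.random() < config.psm_fail_fraction)
            if fail:
                if rng.random() < 0.5:
                    pep = float(rng.uniform(0.051, 0.5))
                    delta = float(rng.uniform(10.0, 60.0))
                else:
                    pep = float(rng.uniform(0.0, 0.05))
                    delta = float(rng.uniform(0.0, 9.9))
                failing.append((scan_id, p.canonical_id))
            else:
                pep = float(rng.uniform(0.0, 0.05))
                delta = float(rng.uniform(15.0, 60.0))
            psms.append(
                PSMRecord(scan_id, p, pep, delta, n_psms_on_scan=len(scan_forms))
            )

    vehicle = next(c for c in design.conditions if c != treated)
    base_log2 = math.log2(config.reporter_base_intensity)
    condition_means = {
        pid: {
            vehicle: base_log2,
            treated: base_log2 + config.condition_effects.get(pid, 0.0),
        }
        for pid in pids
    }
    truth = GroundTruth(
        fractions=dict(zip(pids, fractions)),
        scan_assignments=scan_assignments,
        condition_effects=dict(config.condition_effects),
        condition_means_log2=condition_means,
        failing_rows=failing,
        proteoforms=list(config.proteoforms),
    )
    return SimulatedDataset(spectra=spectra, psms=psms, design=design, truth=truth)


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Emit spectra.mzML, psms.tsv, design.yaml and truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "spectra": out_dir / "spectra.mzML",
        "psms": out_dir / "psms.tsv",
        "design": out_dir / "design.yaml",
        "truth": out_dir / "truth.json",
    }
    write_spectra_mzml(ds.spectra, paths["spectra"])
    write_psm_table(ds.psms, paths["psms"])
    ds.design.to_yaml(paths["design"])
    ds.truth.to_json(paths["truth"])
    return paths


def simulate_bottom_up(
    truth: GroundTruth,
    sigma: float = 0.05,
    seed: int = 0,
    conditions: Sequence[str] = ("vehicle", "treated"),
):
    """Site-level abundance table emulating an orthogonal bottom-up analysis.

    The true mixture's site marginals plus iid Gaussian noise, clipped to
    [0, 1], replicated per condition.  A synthetic stand-in for the
    site-level table a bottom-up (site-centric) workflow would export.
    """
    from .diff_stats import marginalize_sites

    rng = np.random.default_rng(seed)
    marginals = marginalize_sites(truth.proteoforms)
    frames = []
    for cond in conditions:
        f = marginals.copy()
        noise = rng.normal(0.0, sigma, size=len(f)) if sigma > 0 else np.zeros(len(f))
        f["abundance"] = np.clip(f["abundance"].to_numpy() + noise, 0.0, 1.0)
        f["condition"] = cond
        frames.append(f)
    import pandas as pd

    return pd.concat(frames, ignore_index=True)
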