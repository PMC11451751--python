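"""Proteoform quantification from annotated EThcD spectra.

The computation, in the order it runs:

1. **PSM filtering** — keep high-confidence matches (posterior error
   probability <= 0.05 and delta-mod localization score >= 10 by default;
   boundary values pass).
2. **Annotation** — for every PSM on a scan, match observed peaks against
   the proteoform's theoretical a/b/c/y/z ladder within a ppm tolerance
   (15 ppm default), with deterministic tie-breaking.
3. **Isotope confirmation** — a fragment match is high-confidence only if a
   +1 heavy-isotope companion peak (13C spacing / charge) is present within
   the same tolerance.  TMT reporter ions are exempt.
4. **Intensity attribution** — confirmed peak intensity is credited to the
   matching PSM; a peak shared by k PSMs (chimeric scans) is split equally.
5. **Abundance** — a proteoform's relative abundance is its attributed
   intensity as a fraction of all attributed intensity.
6. **Reporter quantification** — extract the 6 TMT reporter intensities,
   correct label isotopic impurities (non-negative least squares), channel
   normalize to the maximum average channel over all PSM-bearing scans, and
   keep scans with at least 2 reporters per treatment condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from .io_formats import PSMRecord, RunDesign, Spectrum
from .mass_model import (
    FragmentIon,
    ModificationDelta,
    Proteoform,
    default_modification_registry,
    fragment_ladder,
    ppm_error,
    C13_C12_SPACING,
)

logger = logging.getLogger("midtail")

__all__ = [
    "QuantParams",
    "FragmentMatch",
    "AnnotatedSpectrum",
    "ProteoformQuant",
    "PipelineResult",
    "filter_psms",
    "annotate",
    "confirm_isotope",
    "attribute_intensity",
    "proteoform_abundance",
    "extract_reporters",
    "correct_impurities",
    "normalize_channels",
    "reporter_quant_filter",
    "run_pipeline",
]


@dataclass(frozen=True)
class QuantParams:
    """Tunable thresholds of the pipeline, defaulting to the study settings."""

    tol_ppm: float = 15.0
    pep_max: float = 0.05
    deltamod_min: float = 10.0
    min_reporters_per_condition: int = 2
    norm_method: str = "mean"  # or "median"
    max_fragment_charge: int = 4
    fragment_series: tuple[str, ...] = ("a", "b", "c", "y", "z")
    neutral_losses: tuple[str, ...] = ("none", "NH3", "H2O")
    z_radical: bool = True
    equal_split: bool = True  # equal division of shared-ion intensity


# ---------------------------------------------------------------------------
# PSM filtering
# ---------------------------------------------------------------------------


def filter_psms(
    psms: Sequence[PSMRecord],
    pep_max: float = 0.05,
    deltamod_min: float = 10.0,
) -> list[PSMRecord]:
    """Keep PSMs with ``pep <= pep_max`` and ``delta_mod >= deltamod_min``.

    Both comparisons are inclusive, so boundary-valued records pass.
    """
    kept = [r for r in psms if r.pep <= pep_max and r.delta_mod >= deltamod_min]
    logger.info("PSM filter: kept %d of %d (PEP<=%g, delta-mod>=%g)",
                len(kept), len(psms), pep_max, deltamod_min)
    return kept


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


@dataclass
class FragmentMatch:
    """One peak <-> theoretical-fragment match for one PSM."""

    peak_index: int
    psm_index: int
    fragment: FragmentIon
    ppm: float
    isotope_confirmed: bool = False


@dataclass
class AnnotatedSpectrum:
    """A scan with its per-PSM fragment matches and reporter intensities."""

    spectrum: Spectrum
    psms: list[PSMRecord]
    matches: list[FragmentMatch] = field(default_factory=list)
    reporter_raw: dict[str, float] = field(default_factory=dict)
    reporter_corrected: dict[str, float] = field(default_factory=dict)

    def peak_psm_counts(self, confirmed_only: bool = True) -> dict[int, int]:
        """Number of PSMs matching each peak (for shared-ion splitting)."""
        counts: dict[int, int] = {}
        for m in self.matches:
            if confirmed_only and not m.isotope_confirmed:
                continue
            counts[m.peak_index] = counts.get(m.peak_index, 0) + 1
        return counts


def _ladder_for(
    p: Proteoform,
    params: QuantParams,
    registry: Mapping[str, ModificationDelta],
    precursor_charge: int,
    cache: dict | None = None,
) -> list[FragmentIon]:
    max_charge = max(1, min(params.max_fragment_charge, precursor_charge - 1))
    key = (p, max_charge)
    if cache is not None and key in cache:
        return cache[key]
    ladder = fragment_ladder(
        p,
        max_charge=max_charge,
        losses=params.neutral_losses,
        series=params.fragment_series,
        registry=registry,
        z_radical=params.z_radical,
    )
    ladder.sort(key=lambda f: f.theoretical_mz)
    if cache is not None:
        cache[key] = ladder
    return ladder


def _best_fragment_for_peak(
    mz: float, ladder: list[FragmentIon], ladder_mz: np.ndarray, tol_ppm: float
) -> tuple[FragmentIon, float] | None:
    """The in-tolerance fragment minimizing |ppm|, with deterministic ties.

    Ties on |ppm| go to the lower fragment index, then series order
    a<b<c<y<z, then lower charge.
    """
    half_width = mz * tol_ppm * 1e-6
    lo = int(np.searchsorted(ladder_mz, mz - half_width, side="left"))
    hi = int(np.searchsorted(ladder_mz, mz + half_width, side="right"))
    best: tuple[float, tuple[int, int, int], FragmentIon, float] | None = None
    for k in range(lo, hi):
        frag = ladder[k]
        err = ppm_error(frag.theoretical_mz, mz)
        if abs(err) > tol_ppm:
            continue
        key = (abs(err), frag.sort_key())
        if best is None or key < (best[0], best[1]):
            best = (abs(err), frag.sort_key(), frag, err)
    if best is None:
        return None
    return best[2], best[3]


def confirm_isotope(
    spectrum: Spectrum,
    matched_mz: float,
    charge: int,
    tol_ppm: float = 15.0,
    spacing: float = C13_C12_SPACING,
) -> bool:
    """True iff a +1 heavy-isotope companion peak exists for a matched peak.

    The companion is expected at ``matched_mz + spacing/charge`` within the
    same ppm tolerance and must have intensity > 0.
    """
    target = matched_mz + spacing / charge
    half_width = target * tol_ppm * 1e-6
    lo = int(np.searchsorted(spectrum.mz, target - half_width, side="left"))
    hi = int(np.searchsorted(spectrum.mz, target + half_width, side="right"))
    return bool(np.any(spectrum.intensity[lo:hi] > 0))


def annotate(
    spectrum: Spectrum,
    psms_on_scan: Sequence[PSMRecord],
    params: QuantParams = QuantParams(),
    registry: Mapping[str, ModificationDelta] | None = None,
    ladder_cache: dict | None = None,
) -> AnnotatedSpectrum:
    """Match observed peaks to each PSM's theoretical fragment ladder.

    Each peak is assigned at most one fragment per PSM (the in-tolerance
    fragment with the smallest |ppm|); a peak consistent with several PSMs'
    ladders carries one match per PSM.  Isotope confirmation is evaluated
    per match at the matched fragment's charge.  Peaks that lie at the +1
    heavy-isotope position of another matched peak of the same PSM are
    treated as isotope companions, not independent fragments — their own
    fragment matches are discarded so isotopologue intensity is never
    double-counted.
    """
    registry = registry if registry is not None else default_modification_registry()
    for r in psms_on_scan:
        if r.scan_id != spectrum.scan_id:
            raise ValueError(
                f"PSM for scan {r.scan_id} passed with spectrum {spectrum.scan_id}"
            )
    annotated = AnnotatedSpectrum(spectrum=spectrum, psms=list(psms_on_scan))
    for psm_index, psm in enumerate(psms_on_scan):
        ladder = _ladder_for(
            psm.proteoform, params, registry, spectrum.precursor_charge, ladder_cache
        )
        ladder_mz = np.array([f.theoretical_mz for f in ladder])
        candidates: list[FragmentMatch] = []
        for peak_index, mz in enumerate(spectrum.mz):
            hit = _best_fragment_for_peak(float(mz), ladder, ladder_mz, params.tol_ppm)
            if hit is None:
                continue
            frag, err = hit
            confirmed = confirm_isotope(spectrum, float(mz), frag.charge, params.tol_ppm)
            candidates.append(FragmentMatch(peak_index, psm_index, frag, err, confirmed))
        companion_peaks = _companion_peak_indices(spectrum, candidates, params.tol_ppm)
        annotated.matches.extend(
            m for m in candidates if m.peak_index not in companion_peaks
        )
    return annotated


def _companion_peak_indices(
    spectrum: Spectrum, matches: Sequence[FragmentMatch], tol_ppm: float
) -> set[int]:
    """Peak indices sitting at the +1 isotope position of any matched peak.

    A candidate is only flagged as a companion if it is less intense than
    its putative monoisotopic parent — at this peptide size the +1
    isotopologue is well below the monoisotopic peak, so an equal-or-larger
    peak at that position is more plausibly an independent fragment.
    """
    out: set[int] = set()
    for m in matches:
        parent_intensity = float(spectrum.intensity[m.peak_index])
        target = float(spectrum.mz[m.peak_index]) + C13_C12_SPACING / m.fragment.charge
        half_width = target * tol_ppm * 1e-6
        lo = int(np.searchsorted(spectrum.mz, target - half_width, side="left"))
        hi = int(np.searchsorted(spectrum.mz, target + half_width, side="right"))
        out.update(
            k for k in range(lo, hi) if float(spectrum.intensity[k]) < parent_intensity
        )
    return out


# ---------------------------------------------------------------------------
# Intensity attribution and abundance
# ---------------------------------------------------------------------------


def attribute_intensity(
    annotated: AnnotatedSpectrum, equal_split: bool = True
) -> dict[int, float]:
    """Per-PSM attributed intensity for one scan.

    Confirmed matches credit the peak's intensity to their PSM; a peak whose
    confirmed matches span k PSMs credits ``intensity / k`` to each
    (equal-split policy).  With ``equal_split=False`` the split is
    proportional to each PSM's unique confirmed evidence on the scan.
    Unconfirmed matches contribute nothing.
    """
    confirmed = [m for m in annotated.matches if m.isotope_confirmed]
    counts = annotated.peak_psm_counts(confirmed_only=True)
    out = {i: 0.0 for i in range(len(annotated.psms))}

    if equal_split:
        for m in confirmed:
            out[m.psm_index] += float(annotated.spectrum.intensity[m.peak_index]) / counts[m.peak_index]
        return out

    # proportional-to-unique-evidence split
    unique = {i: 0.0 for i in out}
    for m in confirmed:
        if counts[m.peak_index] == 1:
            unique[m.psm_index] += float(annotated.spectrum.intensity[m.peak_index])
    for peak_index, k in counts.items():
        inten = float(annotated.spectrum.intensity[peak_index])
        sharers = [m.psm_index for m in confirmed if m.peak_index == peak_index]
        if k == 1:
            out[sharers[0]] += inten
            continue
        weights = np.array([unique[i] for i in sharers])
        if weights.sum() == 0:
            weights = np.ones(len(sharers))
        weights = weights / weights.sum()
        for i, w in zip(sharers, weights):
            out[i] += inten * w
    return out


def proteoform_abundance(
    attributions: Iterable[tuple[Proteoform, float]],
) -> list[tuple[str, float]]:
    """Relative abundance: each proteoform's share of total attributed intensity.

    PSMs of the same proteoform (across scans) pool.  Returns
    ``(canonical id, fraction)`` sorted by abundance descending, id ascending;
    empty with a warning if no intensity was attributed.
    """
    totals: dict[str, float] = {}
    for p, inten in attributions:
        pid = p.canonical_id
        totals[pid] = totals.get(pid, 0.0) + float(inten)
    grand = sum(totals.values())
    if grand <= 0:
        logger.warning("no confirmed fragment intensity attributed; abundance undefined")
        return []
    out = [(pid, v / grand) for pid, v in totals.items()]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


# ---------------------------------------------------------------------------
# Reporter quantification
# ---------------------------------------------------------------------------


def extract_reporters(
    spectrum: Spectrum, design: RunDesign, tol_ppm: float = 15.0
) -> dict[str, float]:
    """Raw reporter intensity per channel; missing channels map to ``nan``.

    The nearest peak within tolerance of each reporter m/z is used; a
    zero-intensity peak counts as missing.
    """
    out: dict[str, float] = {}
    for ch in design.channels:
        target = design.reporter_mz[ch]
        half_width = target * tol_ppm * 1e-6
        lo = int(np.searchsorted(spectrum.mz, target - half_width, side="left"))
        hi = int(np.searchsorted(spectrum.mz, target + half_width, side="right"))
        if hi <= lo:
            out[ch] = math.nan
            continue
        window = spectrum.mz[lo:hi]
        best = lo + int(np.argmin(np.abs(window - target)))
        inten = float(spectrum.intensity[best])
        out[ch] = inten if inten > 0 else math.nan
    return out


def correct_impurities(
    raw: Mapping[str, float], design: RunDesign
) -> dict[str, float]:
    """Invert label isotopic impurities by non-negative least squares.

    Solves ``M x = raw`` for x >= 0 where column j of M is the isotopic
    distribution of label j over the channels.  Missing channels are treated
    as zero signal for the solve and stay missing in the output; with the
    identity matrix the input passes through unchanged.
    """
    M = design.impurity_matrix
    if np.allclose(M, np.eye(len(design.channels))):
        return dict(raw)
    if abs(np.linalg.det(M)) < 1e-12:
        raise ValueError("impurity matrix in the run design is singular")
    vec = np.array([0.0 if math.isnan(raw[ch]) else raw[ch] for ch in design.channels])
    x, _ = nnls(M, vec)
    exact = np.linalg.solve(M, vec)
    if np.any(exact < -1e-9 * max(1.0, float(np.abs(vec).max()))):
        logger.warning("impurity correction clipped a negative solution at zero")
    out = {}
    for ch, val in zip(design.channels, x):
        out[ch] = math.nan if math.isnan(raw[ch]) else float(val)
    return out


def normalize_channels(
    scan_reporters: Mapping[str, Mapping[str, float]],
    design: RunDesign,
    method: str = "mean",
) -> tuple[dict[str, dict[str, float]], dict[str, float]]:
    """Channel normalization to the maximum average channel.

    For each channel, its mean (or median) intensity over all PSM-bearing
    scans is computed; every intensity in that channel is then scaled by
    ``max_channel_statistic / channel_statistic`` so all channel statistics
    coincide afterwards.  Returns the normalized per-scan intensities and
    the scale factors.  All-zero/missing channels are excluded from the max
    with a warning and left unscaled.
    """
    if method not in ("mean", "median"):
        raise ValueError("norm method must be 'mean' or 'median'")
    if not scan_reporters:
        raise ValueError("channel normalization needs at least one scan with a PSM")
    stat = np.nanmean if method == "mean" else np.nanmedian
    stats: dict[str, float] = {}
    for ch in design.channels:
        vals = np.array([rep.get(ch, math.nan) for rep in scan_reporters.values()])
        with np.errstate(all="ignore"):
            s = float(stat(vals)) if np.any(~np.isnan(vals)) else math.nan
        stats[ch] = s
    usable = {ch: s for ch, s in stats.items() if not math.isnan(s) and s > 0}
    if not usable:
        raise ValueError("no channel has nonzero reporter signal")
    if len(usable) < len(design.channels):
        logger.warning("channels with no signal excluded from normalization: %s",
                       sorted(set(design.channels) - set(usable)))
    top = max(usable.values())
    factors = {ch: (top / s if ch in usable else 1.0) for ch, s in stats.items()}
    normalized = {
        scan: {ch: rep.get(ch, math.nan) * factors[ch] for ch in design.channels}
        for scan, rep in scan_reporters.items()
    }
    return normalized, factors


def reporter_quant_filter(
    scan_reporters: Mapping[str, Mapping[str, float]],
    design: RunDesign,
    min_per_condition: int = 2,
) -> list[str]:
    """Scans eligible for reporter quantification.

    A scan is kept iff every treatment condition has at least
    ``min_per_condition`` non-missing reporter intensities.
    """
    eligible = []
    for scan, rep in scan_reporters.items():
        ok = True
        for cond in design.conditions:
            n = sum(
                1
                for ch in design.condition_channels(cond)
                if not math.isnan(rep.get(ch, math.nan))
            )
            if n < min_per_condition:
                ok = False
                break
        if ok:
            eligible.append(scan)
    return eligible


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class ProteoformQuant:
    """Per-proteoform quantification pooled over its scans."""

    proteoform_id: str
    proteoform: Proteoform | None
    attributed_intensity: float
    abundance: float
    channel_log2: dict[str, list[float]]
    n_scans: int


@dataclass
class PipelineResult:
    quants: list[ProteoformQuant]
    annotated: list[AnnotatedSpectrum]
    counts: dict[str, int]


def run_pipeline(
    spectra: Sequence[Spectrum],
    psms: Sequence[PSMRecord],
    design: RunDesign,
    params: QuantParams = QuantParams(),
    registry: Mapping[str, ModificationDelta] | None = None,
) -> PipelineResult:
    """Filter, annotate, attribute, quantify: the full middle-down pipeline.

    Reporter-based (channel) quantification pools log2 normalized reporter
    intensities over eligible single-proteoform scans; chimeric scans still
    contribute to abundance and to the channel-normalization statistics.
    """
    registry = registry if registry is not None else default_modification_registry()
    counts: dict[str, int] = {"psms_total": len(psms), "spectra_total": len(spectra)}

    kept = filter_psms(psms, params.pep_max, params.deltamod_min)
    counts["psms_pass_filter"] = len(kept)

    by_scan: dict[str, list[PSMRecord]] = {}
    for r in kept:
        by_scan.setdefault(r.scan_id, []).append(r)
    spectra_by_id = {s.scan_id: s for s in spectra}

    ladder_cache: dict = {}
    annotated: list[AnnotatedSpectrum] = []
    attributions: list[tuple[Proteoform, float]] = []
    scan_proteoforms: dict[str, list[Proteoform]] = {}
    for scan_id, scan_psms in by_scan.items():
        spectrum = spectra_by_id.get(scan_id)
        if spectrum is None:
            logger.warning("PSM scan %s not present in the spectrum file; skipped", scan_id)
            continue
        ann = annotate(spectrum, scan_psms, params, registry, ladder_cache)
        ann.reporter_raw = extract_reporters(spectrum, design, params.tol_ppm)
        ann.reporter_corrected = correct_impurities(ann.reporter_raw, design)
        annotated.append(ann)
        per_psm = attribute_intensity(ann, params.equal_split)
        for i, psm in enumerate(scan_psms):
            attributions.append((psm.proteoform, per_psm[i]))
        scan_proteoforms[scan_id] = [r.proteoform for r in scan_psms]
    counts["scans_annotated"] = len(annotated)

    abundances = dict(proteoform_abundance(attributions))
    attr_totals: dict[str, float] = {}
    proteoform_objs: dict[str, Proteoform] = {}
    scans_per_proteoform: dict[str, int] = {}
    for p, inten in attributions:
        pid = p.canonical_id
        attr_totals[pid] = attr_totals.get(pid, 0.0) + inten
        proteoform_objs[pid] = p
    for scan_id, forms in scan_proteoforms.items():
        for pid in {p.canonical_id for p in forms}:
            scans_per_proteoform[pid] = scans_per_proteoform.get(pid, 0) + 1

    # reporter quantification over all PSM-bearing scans
    scan_reporters = {a.spectrum.scan_id: a.reporter_corrected for a in annotated}
    channel_log2: dict[str, dict[str, list[float]]] = {
        pid: {ch: [] for ch in design.channels} for pid in proteoform_objs
    }
    if scan_reporters:
        normalized, factors = normalize_channels(scan_reporters, design, params.norm_method)
        eligible = set(
            reporter_quant_filter(normalized, design, params.min_reporters_per_condition)
        )
        counts["scans_reporter_eligible"] = len(eligible)
        for scan_id in eligible:
            forms = {p.canonical_id for p in scan_proteoforms[scan_id]}
            if len(forms) != 1:
                continue  # chimeric scans are not attributable to a single proteoform
            (pid,) = forms
            for ch, val in normalized[scan_id].items():
                if not math.isnan(val) and val > 0:
                    channel_log2[pid][ch].append(math.log2(val))
    else:
        counts["scans_reporter_eligible"] = 0

    quants = [
        ProteoformQuant(
            proteoform_id=pid,
            proteoform=proteoform_objs[pid],
            attributed_intensity=attr_totals.get(pid, 0.0),
            abundance=abundances.get(pid, 0.0),
            channel_log2=channel_log2[pid],
            n_scans=scans_per_proteoform.get(pid, 0),
        )
        for pid in sorted(proteoform_objs)
    ]
    quants.sort(key=lambda q: (-q.abundance, q.proteoform_id))
    counts["proteoforms_detected"] = len(quants)
    logger.info("pipeline: %s", counts)
    return PipelineResult(quants=quants, annotated=annotated, counts=counts)
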