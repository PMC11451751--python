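"""Annotation, attribution, abundance and reporter quantification."""

import math

import numpy as np
import pytest

from midtail import (
    Proteoform,
    PSMRecord,
    QuantParams,
    SimulationConfig,
    Spectrum,
    annotate,
    attribute_intensity,
    confirm_isotope,
    correct_impurities,
    extract_reporters,
    filter_psms,
    fragment_ladder,
    normalize_channels,
    proteoform_abundance,
    reporter_quant_filter,
    run_pipeline,
    simulate_dataset,
)
from midtail.mass_model import C13_C12_SPACING, ppm_error
from midtail.quantify import AnnotatedSpectrum, FragmentMatch, _best_fragment_for_peak
from midtail.io_formats import default_run_design


def _psm(scan_id, proteoform, pep=0.01, delta=25.0, n=1):
    return PSMRecord(scan_id, proteoform, pep, delta, n)


class TestFilterPsms:
    def test_boundary_values_pass(self):
        p = Proteoform("H3.1")
        assert filter_psms([_psm("s", p, pep=0.05, delta=10.0)]) != []

    def test_either_criterion_drops(self):
        p = Proteoform("H3.1")
        assert filter_psms([_psm("s", p, pep=0.06, delta=50.0)]) == []
        assert filter_psms([_psm("s", p, pep=0.01, delta=9.9)]) == []

    def test_count_on_generated_table(self):
        rng = np.random.default_rng(0)
        p = Proteoform("H3.1")
        records, expected = [], 0
        for _ in range(100):
            pep = float(rng.uniform(0, 0.1))
            delta = float(rng.uniform(0, 20))
            records.append(_psm("s", p, pep=pep, delta=delta))
            expected += int(pep <= 0.05 and delta >= 10.0)
        assert len(filter_psms(records)) == expected


class TestTieBreaking:
    def test_smaller_ppm_wins_then_index_then_series(self):
        from midtail.mass_model import FragmentIon

        def ion(series, index, mz):
            return FragmentIon(series, index, 1, "none", mz, mz - 1.007276466)

        ladder = sorted(
            [ion("c", 5, 500.000), ion("y", 3, 500.004)], key=lambda f: f.theoretical_mz
        )
        mzs = np.array([f.theoretical_mz for f in ladder])
        # closer to y3
        frag, _ = _best_fragment_for_peak(500.0035, ladder, mzs, 15.0)
        assert (frag.series, frag.index) == ("y", 3)
        # exact tie in |ppm| is impossible at different m/z; same m/z ties break
        # by index then series order a<b<c<y<z
        ladder = sorted([ion("y", 3, 500.0), ion("c", 3, 500.0), ion("c", 7, 500.0)],
                        key=lambda f: f.theoretical_mz)
        mzs = np.array([f.theoretical_mz for f in ladder])
        frag, _ = _best_fragment_for_peak(500.0, ladder, mzs, 15.0)
        assert (frag.series, frag.index) == ("c", 3)

    def test_out_of_tolerance_peak_unmatched(self):
        from midtail.mass_model import FragmentIon

        ladder = [FragmentIon("c", 1, 1, "none", 500.0, 498.99)]
        assert _best_fragment_for_peak(500.010, ladder, np.array([500.0]), 15.0) is None


class TestAnnotateAndConfirm:
    @pytest.fixture()
    def c5(self, registry):
        p = Proteoform("H3.1")
        return p, next(
            f for f in fragment_ladder(p, registry=registry)
            if f.series == "c" and f.index == 5 and f.charge == 1 and f.neutral_loss == "none"
        )

    def _spectrum(self, peaks):
        mz, inten = zip(*peaks)
        return Spectrum("s1", 495.0, 8, np.array(mz), np.array(inten))

    def test_match_with_ppm_offset_and_isotope_confirmation(self, c5, params):
        p, frag = c5
        mz = frag.theoretical_mz * (1 + 5e-6)  # +5 ppm
        spec = self._spectrum([(mz, 100.0), (mz + C13_C12_SPACING, 45.0)])
        ann = annotate(spec, [_psm("s1", p)], params)
        match = next(m for m in ann.matches if m.fragment.label == frag.label)
        assert match.ppm == pytest.approx(5.0, abs=0.1)
        assert match.isotope_confirmed

    def test_lone_peak_not_confirmed(self, c5, params):
        p, frag = c5
        spec = self._spectrum([(frag.theoretical_mz, 100.0)])
        ann = annotate(spec, [_psm("s1", p)], params)
        match = next(m for m in ann.matches if m.fragment.label == frag.label)
        assert not match.isotope_confirmed

    def test_companion_at_wrong_spacing_not_confirmed(self, c5, params):
        p, frag = c5
        spec = self._spectrum(
            [(frag.theoretical_mz, 100.0), (frag.theoretical_mz + 1.5 * C13_C12_SPACING, 45.0)]
        )
        ann = annotate(spec, [_psm("s1", p)], params)
        match = next(m for m in ann.matches if m.fragment.label == frag.label)
        assert not match.isotope_confirmed

    def test_chimeric_shared_peak_lists_both_psms(self, params):
        """Two co-isolated proteoforms share unmodified prefix fragments."""
        a = Proteoform("H3.1", ((23, "Acetyl"),))
        b = Proteoform("H3.1", ((27, "Acetyl"),))
        from dataclasses import replace

        cfg = replace(
            SimulationConfig(seed=2, n_scans=4, proteoforms=[(a, 0.5), (b, 0.5)]).noiseless(),
            chimera_rate=1.0,
        )
        ds = simulate_dataset(cfg)
        ann = annotate(ds.spectra[0], [r for r in ds.psms if r.scan_id == ds.spectra[0].scan_id],
                       params)
        shared = [k for k, v in ann.peak_psm_counts(confirmed_only=False).items() if v == 2]
        assert shared  # e.g. c1..c22 identical for both proteoforms

    def test_oracle_equivalence_small_spectra(self, registry, params):
        """annotate() agrees with an exhaustive all-pairs ppm search (<=30 peaks)."""
        rng = np.random.default_rng(5)
        p = Proteoform("H3.1", ((9, "Acetyl"),))
        ladder = fragment_ladder(p, max_charge=4, registry=registry)
        for _ in range(20):
            chosen = rng.choice(len(ladder), size=12, replace=False)
            mzs = [ladder[i].theoretical_mz * (1 + rng.normal(0, 5e-6)) for i in chosen]
            mzs += list(rng.uniform(100, 3000, size=10))
            spec = Spectrum("s1", 495.0, 8, np.array(mzs), rng.uniform(10, 100, size=len(mzs)))
            ann = annotate(spec, [_psm("s1", p)], params, registry)

            # independent exhaustive search with the documented tie rule
            first_pass = {}
            for k, mz in enumerate(spec.mz):
                best = None
                for f in ladder:
                    err = ppm_error(f.theoretical_mz, float(mz))
                    if abs(err) > params.tol_ppm:
                        continue
                    key = (abs(err), f.index, "abcyz".index(f.series), f.charge)
                    if best is None or key < best[0]:
                        best = (key, f)
                if best:
                    first_pass[k] = best[1]
            companions = set()
            for k, f in first_pass.items():
                target = float(spec.mz[k]) + C13_C12_SPACING / f.charge
                for j, mz in enumerate(spec.mz):
                    if (abs(ppm_error(target, float(mz))) <= params.tol_ppm
                            and spec.intensity[j] < spec.intensity[k]):
                        companions.add(j)
            expected = {k: f.label for k, f in first_pass.items() if k not in companions}
            got = {m.peak_index: m.fragment.label for m in ann.matches}
            assert got == expected

    def test_loosening_tolerance_never_loses_matches(self, registry, small_dataset):
        """Peak-fragment matching is monotone in the ppm tolerance."""
        ds = small_dataset
        spec = ds.spectra[0]
        psm = next(r for r in ds.psms if r.scan_id == spec.scan_id)
        ladder = sorted(
            fragment_ladder(psm.proteoform, max_charge=4, registry=registry),
            key=lambda f: f.theoretical_mz,
        )
        mzs = np.array([f.theoretical_mz for f in ladder])
        n_prev = -1
        for tol in (5.0, 15.0, 30.0):
            n = sum(
                _best_fragment_for_peak(float(mz), ladder, mzs, tol) is not None
                for mz in spec.mz
            )
            assert n >= n_prev
            n_prev = n


class TestAttribution:
    def _annotated(self, intensities, matches):
        spec = Spectrum("s", 495.0, 8,
                        np.arange(1, len(intensities) + 1, dtype=float) * 100,
                        np.array(intensities, dtype=float))
        p = Proteoform("H3.1")
        ann = AnnotatedSpectrum(spectrum=spec, psms=[_psm("s", p), _psm("s", p)])
        ann.matches = matches
        return ann

    def _match(self, peak, psm, confirmed=True):
        from midtail.mass_model import FragmentIon

        frag = FragmentIon("c", peak + 1, 1, "none", 100.0 * (peak + 1), 100.0)
        return FragmentMatch(peak, psm, frag, 0.0, confirmed)

    def test_shared_peak_split_equally(self):
        ann = self._annotated([100.0], [self._match(0, 0), self._match(0, 1)])
        out = attribute_intensity(ann)
        assert out == {0: pytest.approx(50.0), 1: pytest.approx(50.0)}

    def test_unique_plus_shared(self):
        ann = self._annotated(
            [300.0, 100.0],
            [self._match(0, 0), self._match(1, 0), self._match(1, 1)],
        )
        out = attribute_intensity(ann)
        assert out[0] == pytest.approx(350.0)
        assert out[1] == pytest.approx(50.0)

    def test_unconfirmed_matches_contribute_zero(self):
        ann = self._annotated([100.0], [self._match(0, 0, confirmed=False)])
        assert attribute_intensity(ann) == {0: 0.0, 1: 0.0}

    def test_intensity_conservation_on_simulated_scans(self, params, small_dataset):
        """Sum of attributed intensity equals sum of confirmed matched peak intensity."""
        ds = small_dataset
        by_scan = {}
        for r in ds.psms:
            by_scan.setdefault(r.scan_id, []).append(r)
        for spec in ds.spectra[:10]:
            psms = by_scan[spec.scan_id]
            ann = annotate(spec, psms, params)
            out = attribute_intensity(ann)
            confirmed_peaks = {m.peak_index for m in ann.matches if m.isotope_confirmed}
            expected = float(spec.intensity[sorted(confirmed_peaks)].sum())
            assert sum(out.values()) == pytest.approx(expected, rel=1e-12)


class TestAbundance:
    def test_two_proteoforms(self):
        a, b = Proteoform("H3.1"), Proteoform("H3.3")
        out = dict(proteoform_abundance([(a, 300.0), (b, 100.0)]))
        assert out[a.canonical_id] == pytest.approx(0.75)
        assert out[b.canonical_id] == pytest.approx(0.25)

    def test_single_proteoform_is_unity_and_scans_pool(self):
        a = Proteoform("H3.1")
        out = dict(proteoform_abundance([(a, 10.0), (a, 30.0)]))
        assert out == {a.canonical_id: pytest.approx(1.0)}

    def test_all_zero_gives_empty(self):
        assert proteoform_abundance([(Proteoform("H3.1"), 0.0)]) == []

    def test_abundances_sum_to_one_on_simulation(self, small_dataset):
        res = run_pipeline(small_dataset.spectra, small_dataset.psms, small_dataset.design)
        assert sum(q.abundance for q in res.quants) == pytest.approx(1.0, abs=1e-9)


class TestReporters:
    def _reporter_spectrum(self, design, skip=(), decoy_ppm=None):
        mzs, intens = [], []
        for i, ch in enumerate(design.channels):
            if ch in skip:
                continue
            mzs.append(design.reporter_mz[ch])
            intens.append(100.0 + i)
        if decoy_ppm is not None:
            mzs.append(design.reporter_mz["128"] * (1 + decoy_ppm * 1e-6))
            intens.append(999.0)
        return Spectrum("s", 495.0, 8, np.array(mzs), np.array(intens))

    def test_all_channels_extracted(self, design):
        out = extract_reporters(self._reporter_spectrum(design), design)
        assert all(not math.isnan(v) for v in out.values())
        assert len(out) == 6

    def test_missing_channel_is_nan(self, design):
        out = extract_reporters(self._reporter_spectrum(design, skip=("128",)), design)
        assert math.isnan(out["128"])

    def test_decoy_30ppm_off_not_extracted(self, design):
        out = extract_reporters(
            self._reporter_spectrum(design, skip=("128",), decoy_ppm=30.0), design
        )
        assert math.isnan(out["128"])

    def test_identity_impurity_matrix_is_passthrough(self, design):
        raw = {ch: float(i) for i, ch in enumerate(design.channels)}
        assert correct_impurities(raw, design) == raw

    def test_forward_mixing_inverted_exactly(self, design):
        rng = np.random.default_rng(3)
        M = np.eye(6)
        for j in range(6):  # 5% bleed into neighbours
            if j > 0:
                M[j - 1, j] = 0.05
            if j < 5:
                M[j + 1, j] = 0.05
            M[j, j] = 1 - 0.05 * ((j > 0) + (j < 5))
        design2 = default_run_design()
        design2.impurity_matrix = M
        truth = rng.uniform(1e4, 1e5, size=6)
        observed = M @ truth
        raw = dict(zip(design2.channels, observed))
        corrected = correct_impurities(raw, design2)
        rel = np.abs(np.array([corrected[ch] for ch in design2.channels]) - truth) / truth
        assert rel.max() < 1e-6

    def test_negative_solution_clipped_at_zero(self, design):
        design2 = default_run_design()
        M = np.eye(6)
        M[1, 0] = 0.5
        M[0, 0] = 0.5
        design2.impurity_matrix = M
        raw = {ch: 0.0 for ch in design2.channels}
        raw["126"] = 100.0  # label-1 bleed without any label-2 signal -> exact solve < 0
        corrected = correct_impurities(raw, design2)
        assert all(v >= 0 for v in corrected.values())


class TestNormalization:
    def test_scale_to_maximum_average_channel(self, design):
        scans = {
            "s1": {ch: (100.0 if cond == "vehicle" else 50.0)
                   for ch, cond in design.channel_condition.items()},
            "s2": {ch: (100.0 if cond == "vehicle" else 50.0)
                   for ch, cond in design.channel_condition.items()},
        }
        normalized, factors = normalize_channels(scans, design)
        for ch, cond in design.channel_condition.items():
            assert factors[ch] == pytest.approx(1.0 if cond == "vehicle" else 2.0)
        means = {ch: np.mean([normalized[s][ch] for s in scans]) for ch in design.channels}
        assert all(m == pytest.approx(100.0) for m in means.values())

    def test_balanced_channels_are_identity(self, design):
        scans = {"s1": {ch: 42.0 for ch in design.channels}}
        _, factors = normalize_channels(scans, design)
        assert all(f == pytest.approx(1.0) for f in factors.values())

    def test_mean_and_median_agree_on_symmetric_data(self, design):
        rng = np.random.default_rng(8)
        base = {ch: 2.0 ** (i % 3) for i, ch in enumerate(design.channels)}
        scans = {}
        for k in range(41):
            offset = float(rng.choice([-10.0, 0.0, 10.0], p=[0.25, 0.5, 0.25]))
            scans[f"s{k}"] = {ch: 1000.0 * base[ch] + offset for ch in design.channels}
        _, f_mean = normalize_channels(scans, design, "mean")
        _, f_median = normalize_channels(scans, design, "median")
        for ch in design.channels:
            assert f_mean[ch] == pytest.approx(f_median[ch], rel=1e-2)


class TestReporterQuantFilter:
    def _scan(self, present, design):
        return {ch: (1.0 if ch in present else math.nan) for ch in design.channels}

    def test_two_per_condition_kept(self, design):
        scans = {"s": self._scan({"126", "127", "129", "130"}, design)}
        assert reporter_quant_filter(scans, design) == ["s"]

    def test_one_in_a_condition_dropped(self, design):
        scans = {"s": self._scan({"126", "129", "130", "131"}, design)}
        assert reporter_quant_filter(scans, design) == []

    def test_all_present_kept_and_monotone_in_threshold(self, design):
        scans = {"s": self._scan(set(design.channels), design)}
        assert reporter_quant_filter(scans, design) == ["s"]
        prev = 2
        for k in (1, 2, 3, 4):
            n = len(reporter_quant_filter(scans, design, min_per_condition=k))
            if k > 1:
                assert n <= prev
            prev = n
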