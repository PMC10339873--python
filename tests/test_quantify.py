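"""Quantification: unit conversion, BLD imputation, QC cascade, end-to-end."""

import math
from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fgmtools import (
    CORTISOL,
    AssayConfig,
    ConfigError,
    ExtractionRecord,
    PipelineConfig,
    PlateRecord,
    QCFlag,
    Role,
    Well,
    apply_qc,
    fit_4pl,
    impute_bld,
    inter_assay_cv,
    quantify_plate,
    supersede_reruns,
    to_fecal_concentration,
)
from fgmtools.simulate import default_extractions, simulate_plate


def fit_plate_curve(plate):
    standards = [
        (conc, plate.percent_bound_of((o1 + o2) / 2.0))
        for conc, (o1, o2) in plate.standard_pairs().items()
    ]
    return fit_4pl(standards, plate_id=plate.plate_id)


class TestFecalConversion:
    @pytest.mark.parametrize(
        "conc,dil,vol,mass,expected",
        [
            (1.0, 10.0, 2.0, 0.2, 100.0),
            (1.0, 1.0, 2.0, 0.2, 10.0),
            (0.5, 30.0, 2.0, 0.25, 120.0),
        ],
    )
    def test_known_conversions(self, conc, dil, vol, mass, expected):
        assert to_fecal_concentration(conc, dil, vol, mass) == pytest.approx(expected)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            to_fecal_concentration(1.0, 10.0, 2.0, 0.0)

    @given(
        conc=st.floats(0.01, 100),
        dil=st.floats(1, 100),
        mass=st.floats(0.05, 0.5),
        k=st.floats(0.1, 10),
    )
    def test_unit_conservation(self, conc, dil, mass, k):
        """Linear in concentration and dilution, inverse-linear in mass."""
        base = to_fecal_concentration(conc, dil, 2.0, mass)
        assert to_fecal_concentration(k * conc, dil, 2.0, mass) == pytest.approx(
            k * base, rel=1e-12
        )
        assert to_fecal_concentration(conc, k * dil, 2.0, mass) == pytest.approx(
            k * base, rel=1e-12
        )
        assert to_fecal_concentration(conc, dil, 2.0, k * mass) == pytest.approx(
            base / k, rel=1e-12
        )


class TestBLDImputation:
    def test_assay_constants(self):
        # half the lowest standard, converted by the 2 mL / 0.2 g ratio only
        assert impute_bld("cortisol") == pytest.approx(0.78)
        assert impute_bld("corticosterone") == pytest.approx(0.16)

    def test_matches_closed_form_for_custom_assay(self):
        assay = AssayConfig("custom", (100.0, 1000.0), default_dilution=5.0)
        # 0.5 * 0.1 ng/mL * (2 mL / 0.2 g) = 0.5 ng/g
        assert impute_bld(assay) == pytest.approx(0.5)

    def test_dilution_switch(self):
        assay = AssayConfig(
            "cortisol", CORTISOL.standards_pg_ml, 10.0, bld_include_dilution=True
        )
        assert impute_bld(assay) == pytest.approx(7.8)

    def test_unknown_assay_is_config_error(self):
        with pytest.raises(ConfigError):
            impute_bld("aldosterone")


def _jitter_sample(plate, sample_id, factor):
    """Return a new plate with one well of a sample's duplicate scaled."""
    wells = []
    seen = False
    for w in plate.wells:
        if w.role is Role.SAMPLE and w.sample_id == sample_id and not seen:
            wells.append(
                Well(
                    plate_id=w.plate_id, position=w.position, role=w.role,
                    od=w.od * factor, sample_id=w.sample_id, dilution=w.dilution,
                )
            )
            seen = True
        else:
            wells.append(w)
    return PlateRecord(plate_id=plate.plate_id, assay=plate.assay, wells=wells)


def _jitter_standard(plate, conc, factor):
    wells = []
    seen = False
    for w in plate.wells:
        if w.role is Role.STANDARD and w.standard_conc == conc and not seen:
            wells.append(
                Well(
                    plate_id=w.plate_id, position=w.position, role=w.role,
                    od=w.od * factor, standard_conc=w.standard_conc,
                )
            )
            seen = True
        else:
            wells.append(w)
    return PlateRecord(plate_id=plate.plate_id, assay=plate.assay, wells=wells)


class TestQCCascade:
    def test_clean_plate_no_failures(self, clean_plate, config):
        plate, _ = clean_plate
        qc = apply_qc(plate, None, config)
        assert not qc.duplicate_failures
        assert not qc.standards_cv_fail
        assert not qc.plate_rerun_required
        assert qc.intra_assay_cv == 0.0

    def test_majority_duplicate_failures_force_rerun(self, config):
        # 10 samples, 6 with CV > 10% -> 60% > 50% -> plate re-run
        concs = [(f"S{i}", 500.0 + 100 * i) for i in range(10)]
        plate, _ = simulate_plate(concs, CORTISOL)
        for i in range(6):
            plate = _jitter_sample(plate, f"S{i}", 1.35)
        qc = apply_qc(plate, None, config)
        assert len(qc.duplicate_failures) == 6
        assert qc.plate_rerun_required

    def test_exactly_half_failures_do_not_force_rerun(self, config):
        concs = [(f"S{i}", 500.0 + 100 * i) for i in range(10)]
        plate, _ = simulate_plate(concs, CORTISOL)
        for i in range(5):
            plate = _jitter_sample(plate, f"S{i}", 1.35)
        assert not apply_qc(plate, None, config).plate_rerun_required

    def test_failing_standards_force_rerun_regardless_of_samples(self, clean_plate, config):
        plate, _ = clean_plate
        bad = _jitter_standard(plate, 625.0, 1.4)  # CV ~ 12%+
        qc = apply_qc(bad, None, config)
        assert qc.standards_cv_fail
        assert qc.plate_rerun_required
        assert not qc.duplicate_failures

    def test_rerun_monotonicity(self, config):
        """Adding a failing duplicate never rescues a rerun-required plate."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            concs = [(f"S{i}", float(rng.uniform(300, 5000))) for i in range(n)]
            plate, _ = simulate_plate(concs, CORTISOL)
            n_fail = int(rng.integers(0, n + 1))
            for i in range(n_fail):
                plate = _jitter_sample(plate, f"S{i}", 1.4)
            before = apply_qc(plate, None, config).plate_rerun_required
            grown, _ = simulate_plate(
                concs + [("EXTRA", 800.0)], CORTISOL
            )
            for i in range(n_fail):
                grown = _jitter_sample(grown, f"S{i}", 1.4)
            grown = _jitter_sample(grown, "EXTRA", 1.4)
            after = apply_qc(grown, None, config).plate_rerun_required
            if before:
                assert after

    def test_inter_assay_cv(self):
        assert inter_assay_cv([10.0]) is None
        vals = [10.0, 11.0, 9.5]
        expected = 100 * np.std(vals, ddof=1) / np.mean(vals)
        assert inter_assay_cv(vals) == pytest.approx(expected)


class TestQuantifyPlate:
    def test_zero_noise_recovers_truth(self, clean_plate, config):
        plate, truth = clean_plate
        curve = fit_plate_curve(plate)
        ms = quantify_plate(plate, curve, default_extractions(truth), config)
        by_id = {m.sample_id: m for m in ms}
        for r in truth.itertuples():
            m = by_id[r.sample_id]
            assert not m.qc_flags
            assert m.fecal_conc_ng_g == pytest.approx(r.true_fecal_ng_g, rel=1e-6)

    def test_below_curve_sample_gets_bld_constant(self, config):
        plate, truth = simulate_plate(
            [("LOW", 15.0), ("MID", 1000.0)], CORTISOL
        )  # 15 pg/mL ~ 0.1x lowest standard
        curve = fit_plate_curve(plate)
        ms = {m.sample_id: m for m in quantify_plate(
            plate, curve, default_extractions(truth), config)}
        assert QCFlag.BLD_IMPUTED in ms["LOW"].qc_flags
        assert ms["LOW"].fecal_conc_ng_g == pytest.approx(0.78)
        assert not ms["MID"].qc_flags

    def test_above_curve_sample_flagged_and_excluded(self, config):
        plate, truth = simulate_plate([("HIGH", 50000.0)], CORTISOL)
        curve = fit_plate_curve(plate)
        (m,) = quantify_plate(plate, curve, default_extractions(truth), config)
        assert QCFlag.ABOVE_CURVE in m.qc_flags
        assert math.isnan(m.fecal_conc_ng_g)
        assert not m.usable

    def test_sub_mass_extraction_discarded(self, clean_plate, config):
        plate, truth = clean_plate
        curve = fit_plate_curve(plate)
        ext = default_extractions(truth)
        first = truth.sample_id.iloc[0]
        ext[first] = ExtractionRecord(
            sample_id=first, animal_id="A1",
            collection_datetime=datetime(2020, 1, 1, 9),
            dry_mass_g=0.15,
        )
        ms = {m.sample_id: m for m in quantify_plate(plate, curve, ext, config)}
        assert QCFlag.MASS_DISCARD in ms[first].qc_flags
        assert math.isnan(ms[first].fecal_conc_ng_g)

    def test_missing_extraction_record_names_sample(self, clean_plate, config):
        plate, truth = clean_plate
        curve = fit_plate_curve(plate)
        ext = default_extractions(truth)
        del ext[truth.sample_id.iloc[0]]
        with pytest.raises(KeyError, match=truth.sample_id.iloc[0]):
            quantify_plate(plate, curve, ext, config)

    def test_noisy_recovery_mid_curve(self, config):
        """5% OD noise: median absolute relative error < 10% at mid-curve."""
        from fgmtools.simulate import PlateSimConfig

        rng = np.random.default_rng(11)
        errs = []
        for rep in range(30):
            concs = [(f"S{i}", float(c)) for i, c in enumerate(
                np.geomspace(600, 4000, 6))]
            plate, truth = simulate_plate(
                concs, CORTISOL, PlateSimConfig(noise_cv=0.05), seed=rng
            )
            curve = fit_plate_curve(plate)
            ms = {m.sample_id: m for m in quantify_plate(
                plate, curve, default_extractions(truth), config)}
            for r in truth.itertuples():
                m = ms[r.sample_id]
                if m.usable:
                    errs.append(abs(m.fecal_conc_ng_g / r.true_fecal_ng_g - 1))
        assert np.median(errs) < 0.10

    def test_rerun_supersedence(self, clean_plate, config):
        plate, truth = clean_plate
        curve = fit_plate_curve(plate)
        ext = default_extractions(truth)
        first = quantify_plate(_jitter_sample(plate, "S1", 1.4), curve, ext, config)
        second = quantify_plate(plate, curve, ext, config)
        effective = {m.sample_id: m for m in supersede_reruns(first + second)}
        assert effective["S1"].usable
        # a later flagged result never displaces an earlier usable one
        effective2 = {m.sample_id: m for m in supersede_reruns(second + first)}
        assert effective2["S1"].usable
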