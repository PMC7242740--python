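"""Cell segmentation, endpoint extraction, normalization, and the OMI index."""

import numpy as np
import pandas as pd
import pytest

from omihet.flim import DecayStack, FitOptions, LifetimeImage, bin_decays, fit_stack
from omihet.quantify import (
    SegmentationOptions,
    extract_cell_endpoints,
    normalize_to_control,
    omi_index,
    segment_cytoplasms,
)
from omihet.simulate import (
    CellGeometry,
    FlimSimSpec,
    NADPH,
    FAD,
    default_cell_truth,
    generate_flim_stack,
    generate_irf,
)


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


def _uniform_lifetime(shape, tau_m=1.0, tau1=0.4, tau2=2.5, alpha1=0.7,
                      intensity=100.0):
    img = LifetimeImage.empty(shape)
    img.tau_m[:] = tau_m
    img.tau1[:] = tau1
    img.tau2[:] = tau2
    img.alpha1_frac[:] = alpha1
    img.alpha2_frac[:] = 1 - alpha1
    img.background_c[:] = 0.0
    img.chi2_reduced[:] = 0.0
    img.intensity[:] = intensity
    img.valid[:] = True
    return img


class TestSegmentCytoplasms:
    def test_two_disjoint_cells_recovered(self):
        spec = FlimSimSpec(image_width=48, image_height=48, cells=[
            CellGeometry((12, 12), 7, truth=default_cell_truth()),
            CellGeometry((32, 34), 7, truth=default_cell_truth()),
        ], seed=5)
        stacks, truth_mask, _ = generate_flim_stack(spec)
        labels = segment_cytoplasms(stacks[NADPH].sum(axis=2).astype(float),
                                    SegmentationOptions(min_area=30))
        assert labels.max() == 2
        for lab in (1, 2):
            best = max(_dice(labels == s, truth_mask == lab)
                       for s in range(1, labels.max() + 1))
            assert best >= 0.8

    def test_touching_cells_split_by_watershed(self):
        spec = FlimSimSpec(image_width=48, image_height=48, cells=[
            CellGeometry((24, 18), 8, truth=default_cell_truth()),
            CellGeometry((24, 31), 8, truth=default_cell_truth()),
        ], seed=6)
        stacks, _, _ = generate_flim_stack(spec)
        labels = segment_cytoplasms(stacks[NADPH].sum(axis=2).astype(float),
                                    SegmentationOptions(min_area=30))
        assert labels.max() == 2

    def test_blank_image_empty_mask(self):
        with pytest.warns(UserWarning):
            labels = segment_cytoplasms(np.zeros((32, 32)))
        assert labels.max() == 0


class TestExtractCellEndpoints:
    def test_single_label_equals_image_means(self):
        shape = (10, 10)
        nadph = _uniform_lifetime(shape, intensity=200.0)
        fad = _uniform_lifetime(shape, tau_m=0.8, intensity=100.0)
        mask = np.ones(shape, dtype=np.uint16)
        table, report = extract_cell_endpoints(mask, nadph, fad, {"treatment": "control"})
        assert len(table) == 1 and report["n_dropped"] == 0
        row = table.iloc[0]
        assert row.nadph_tau_m == pytest.approx(1.0)
        assert row.fad_tau_m == pytest.approx(0.8)
        assert row.redox_ratio_raw == pytest.approx(2.0)  # 200 / 100

    def test_small_labels_dropped(self):
        shape = (10, 10)
        mask = np.zeros(shape, dtype=np.uint16)
        mask[0, 0] = 1  # below min_valid_pixels
        mask[5:, :] = 2
        table, report = extract_cell_endpoints(
            mask, _uniform_lifetime(shape), _uniform_lifetime(shape), {})
        assert report["n_dropped"] == 1
        assert table.cell_id.tolist() == [2]

    def test_invariant_to_label_renumbering(self):
        shape = (12, 12)
        mask = np.zeros(shape, dtype=np.uint16)
        mask[:6] = 1
        mask[6:] = 2
        nadph, fad = _uniform_lifetime(shape), _uniform_lifetime(shape, tau_m=0.9)
        t1, _ = extract_cell_endpoints(mask, nadph, fad, {})
        renumbered = np.where(mask == 1, 7, np.where(mask == 2, 3, 0)).astype(np.uint16)
        t2, _ = extract_cell_endpoints(renumbered, nadph, fad, {})
        a = t1.drop(columns="cell_id").sort_values("n_pixels").reset_index(drop=True)
        b = t2.drop(columns="cell_id").sort_values("n_pixels").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_round_trip_through_simulator_and_fitter(self):
        """A uniform noise-free cell fits back to its generating endpoints."""
        truth = default_cell_truth()
        spec = FlimSimSpec(image_width=20, image_height=20, background_rate=0.0,
                           cells=[CellGeometry((10, 10), 6, truth=truth)], seed=0)
        stacks, mask, _ = generate_flim_stack(spec, noise=False)
        irf = generate_irf(spec.irf_fwhm, spec.n_time_bins, spec.bin_width)
        images = {}
        for ch in (NADPH, FAD):
            stack = bin_decays(
                DecayStack(stacks[ch], spec.bin_width, ch, irf), 1)
            images[ch] = fit_stack(stack, FitOptions.for_channel(ch))
        table, _ = extract_cell_endpoints(mask, images[NADPH], images[FAD], {},
                                          min_valid_pixels=10)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.nadph_tau_m == pytest.approx(truth[NADPH].tau_m, rel=0.01)
        assert row.fad_tau_m == pytest.approx(truth[FAD].tau_m, rel=0.01)
        assert row.nadph_alpha1_frac == pytest.approx(truth[NADPH].alpha1_frac, rel=0.01)


def _cells(rows):
    base = {"patient_id": "P01", "organoid_id": "P01-O1", "timepoint_h": 24.0}
    records = []
    for i, r in enumerate(rows, start=1):
        rec = dict(base, cell_id=i, **r)
        records.append(rec)
    return pd.DataFrame(records)


class TestNormalizeToControl:
    def test_all_control_equal_ratio(self):
        cells = _cells([{"treatment": "control", "redox_ratio_raw": 1.4}] * 4)
        out = normalize_to_control(cells)
        assert np.allclose(out.redox_ratio_norm, 1.0)

    def test_treated_normalized_by_control_mean(self):
        cells = _cells(
            [{"treatment": "control", "redox_ratio_raw": v} for v in (1.0, 2.0, 3.0)]
            + [{"treatment": "drug", "redox_ratio_raw": 4.0}])
        out = normalize_to_control(cells)
        assert out.loc[out.treatment == "drug", "redox_ratio_norm"].iloc[0] == \
               pytest.approx(2.0)

    def test_strata_are_independent(self):
        rows = ([{"treatment": "control", "redox_ratio_raw": 1.0}] * 3
                + [{"treatment": "drug", "redox_ratio_raw": 2.0}])
        a = _cells(rows)
        b = a.copy()
        b["patient_id"] = "P02"
        b["redox_ratio_raw"] *= 3.0
        combined = pd.concat([a, b], ignore_index=True)
        flipped = pd.concat([b, a], ignore_index=True)
        out1 = normalize_to_control(combined).sort_values(
            ["patient_id", "cell_id"]).reset_index(drop=True)
        out2 = normalize_to_control(flipped).sort_values(
            ["patient_id", "cell_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(out1, out2)
        assert np.allclose(out1.groupby("patient_id").redox_ratio_norm.mean()[:2],
                           [1.25, 1.25])

    def test_no_controls_anywhere_is_error(self):
        cells = _cells([{"treatment": "drug", "redox_ratio_raw": 1.0}] * 3)
        with pytest.raises(ValueError):
            normalize_to_control(cells)


class TestOmiIndex:
    @staticmethod
    def _full(rows):
        df = _cells(rows)
        return df

    def test_control_stratum_centers_to_zero(self):
        rows = [{"treatment": "control", "redox_ratio_raw": v,
                 "nadph_tau_m": 1.0 + 0.1 * v, "fad_tau_m": 0.8 + 0.05 * v}
                for v in (0.8, 1.0, 1.2, 1.5)]
        out = omi_index(self._full(rows))
        assert out.omi_index.mean() == pytest.approx(0.0, abs=1e-9)

    def test_linear_combination_arithmetic(self):
        rows = ([{"treatment": "control", "redox_ratio_raw": 1.0,
                  "nadph_tau_m": 1.0, "fad_tau_m": 1.0}] * 3
                + [{"treatment": "drug", "redox_ratio_raw": 0.9,
                    "nadph_tau_m": 0.9, "fad_tau_m": 1.1}])
        out = omi_index(self._full(rows))
        treated = out.loc[out.treatment == "drug", "omi_index"].iloc[0]
        assert treated == pytest.approx(-0.3, abs=1e-12)

    def test_monotone_in_nadph_lifetime(self):
        values = []
        for tau in (0.8, 0.9, 1.0, 1.1):
            rows = ([{"treatment": "control", "redox_ratio_raw": 1.0,
                      "nadph_tau_m": 1.0, "fad_tau_m": 1.0}] * 3
                    + [{"treatment": "drug", "redox_ratio_raw": 1.0,
                        "nadph_tau_m": tau, "fad_tau_m": 1.0}])
            out = omi_index(self._full(rows))
            values.append(out.loc[out.treatment == "drug", "omi_index"].iloc[0])
        assert np.all(np.diff(values) > 0)

    def test_response_direction_is_negative(self):
        """Lower redox + shorter NAD(P)H tau_m + longer FAD tau_m => omi < 0."""
        rng = np.random.default_rng(0)
        rows = [{"treatment": "control",
                 "redox_ratio_raw": 1.0 + 0.05 * rng.standard_normal(),
                 "nadph_tau_m": 1.0 + 0.05 * rng.standard_normal(),
                 "fad_tau_m": 1.0 + 0.05 * rng.standard_normal()} for _ in range(50)]
        rows += [{"treatment": "drug",
                  "redox_ratio_raw": 0.85 + 0.05 * rng.standard_normal(),
                  "nadph_tau_m": 0.85 + 0.05 * rng.standard_normal(),
                  "fad_tau_m": 1.15 + 0.05 * rng.standard_normal()} for _ in range(50)]
        out = omi_index(self._full(rows))
        assert out.loc[out.treatment == "drug", "omi_index"].mean() < 0
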