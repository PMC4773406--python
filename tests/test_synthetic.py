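"""Statistical and determinism contracts of the synthetic plate generator."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import ndimage as ndi

from phenoplate import synthetic
from phenoplate.aggregate import fit_geometric_clumps
from phenoplate.plate_io import PlateLayout, UNUSED, ALL_WELLS, discover_images
from phenoplate.synthetic import (
    ConditionParams,
    PackingError,
    SimulationParams,
    default_params,
    params_from_yaml,
    params_to_yaml,
    render_field,
    sample_plate_truth,
    sample_well_population,
    simulate_plate,
)


def _small_params(**condition_kwargs) -> SimulationParams:
    """Compact single-condition parameter set for fast unit tests."""
    base = dict(expected_attached_cells=40.0, clump_geometric_p=0.55,
                cell_area_median_um2=400.0, nucleus_area_median_um2=150.0)
    base.update(condition_kwargs)
    return SimulationParams(conditions={"Fn5": ConditionParams(**base)},
                            image_shape=(512, 512))


def _layout(wells: dict) -> PlateLayout:
    full = dict.fromkeys(ALL_WELLS, UNUSED)
    full.update(wells)
    return PlateLayout(plate_id="sim", wells=full)


class TestWellPopulation:
    def test_zero_expected_cells_gives_empty_truth(self):
        params = _small_params(expected_attached_cells=0.0, feeder_rate=0.0)
        truth = sample_well_population(params, "Fn5", seed=0)
        assert len(truth) == 0

    def test_degenerate_geometric_all_singletons(self):
        params = _small_params(clump_geometric_p=1.0, feeder_rate=0.0)
        truth = sample_well_population(params, "Fn5", seed=1)
        assert len(truth) > 0
        assert (truth["clump_size"] == 1).all()

    def test_unknown_condition_rejected(self):
        with pytest.raises(KeyError, match="Fn99"):
            sample_well_population(_small_params(), "Fn99", seed=0)

    def test_geometric_mean_clump_size(self, sim_params):
        """Pooled clump sizes match the 1/p geometric mean within 3 SE."""
        p = 0.4
        sizes = []
        for seed in range(12):
            truth = sample_well_population(sim_params, "Fn25", seed=seed)
            sizes.extend(truth.groupby("clump_id")["clump_size"].first())
        sizes = np.asarray(sizes, dtype=float)
        assert len(sizes) >= 1000
        se = np.sqrt((1 - p) / p**2 / len(sizes))
        assert abs(sizes.mean() - 1 / p) <= 3 * se

    def test_clump_size_histogram_fits_geometric_law(self, sim_params):
        """Chi-square GOF of pooled simulated sizes vs geometric(p-hat)."""
        sizes = []
        for seed in range(40):
            truth = sample_well_population(sim_params, "Fn5", seed=seed)
            truth = truth[~truth["is_feeder"]]
            sizes.extend(truth.groupby("clump_id")["clump_size"].first())
        sizes = np.asarray(sizes, dtype=float)
        assert len(sizes) >= 4000
        fit = fit_geometric_clumps(sizes)
        assert fit.p_value > 0.01

    def test_edu_labels_bernoulli(self, sim_params):
        labels = []
        for seed in range(10):
            truth = sample_well_population(sim_params, "Fn5", seed=seed)
            labels.extend(truth.loc[~truth["is_feeder"], "edu_label"])
        labels = np.asarray(labels)
        f = sim_params.conditions["Fn5"].edu_positive_fraction
        se = np.sqrt(f * (1 - f) / len(labels))
        assert abs(labels.mean() - f) <= 4 * se

    def test_clump_sizes_equal_id_multiplicity(self, well_truth):
        by_id = well_truth.groupby("clump_id").agg(
            n=("object_id", "size"), size=("clump_size", "first"))
        assert (by_id["n"] == by_id["size"]).all()
        assert well_truth["object_id"].is_unique

    def test_sampling_is_deterministic(self, sim_params):
        a = sample_well_population(sim_params, "Fn1", seed=42)
        b = sample_well_population(sim_params, "Fn1", seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_impossible_packing_raises(self):
        params = SimulationParams(
            conditions={"Fn5": ConditionParams(expected_attached_cells=5000.0,
                                               cell_area_median_um2=900.0)},
            image_shape=(256, 256), n_fields=1)
        with pytest.raises(PackingError):
            sample_well_population(params, "Fn5", seed=0)

    def test_clumps_in_contact_and_separated(self, sim_params):
        """Rendered cell bodies form one component per clump, none merged."""
        truth = sample_well_population(sim_params, "Fn25", seed=3)
        sub = truth[truth["field"] == 1]
        image = render_field(sub, sim_params, seed=9)
        bg = sim_params.intensity.cellmask_background[0]
        foreground = image.channels["cellmask647"] > bg + 200
        _, n_components = ndi.label(foreground, structure=np.ones((3, 3)))
        assert n_components == sub["clump_id"].nunique()


class TestRenderField:
    def test_empty_truth_pure_noise(self, sim_params):
        empty = sample_well_population(
            _small_params(expected_attached_cells=0.0, feeder_rate=0.0),
            "Fn5", seed=0)
        image = render_field(empty, sim_params, seed=5)
        im = sim_params.intensity
        assert image.channels["dapi"].max() < im.dapi_background[0] * 2
        assert image.channels["brightfield"].min() >= 1.0

    def test_same_seed_bit_identical(self, sim_params, well_truth):
        sub = well_truth[well_truth["field"] == 2]
        a = render_field(sub, sim_params, seed=7)
        b = render_field(sub, sim_params, seed=7)
        for channel in a.channels:
            np.testing.assert_array_equal(a.channels[channel],
                                          b.channels[channel])

    def test_negative_cell_median_in_component_range(self, sim_params):
        """A single EdU- cell's median lands in the negative 99% interval."""
        params = _small_params(expected_attached_cells=8.0,
                               clump_geometric_p=1.0, feeder_rate=0.0,
                               edu_positive_fraction=0.0)
        truth = sample_well_population(params, "Fn5", seed=8)
        assert len(truth) >= 1
        truth = truth[truth["field"] == truth["field"].iloc[0]]
        image = render_field(truth.iloc[[0]], params, seed=2)
        row = truth.iloc[0]
        from skimage.draw import ellipse as draw_ellipse
        rr, cc = draw_ellipse(row.centroid_row, row.centroid_col,
                              row.nucleus_b_px, row.nucleus_a_px,
                              shape=params.image_shape,
                              rotation=row.orientation)
        median = np.median(image.channels["edu488"][rr, cc])
        im = params.intensity
        lo = 10 ** (im.edu_negative_log_mean - 2.58 * im.edu_negative_log_sd)
        hi = 10 ** (im.edu_negative_log_mean + 2.58 * im.edu_negative_log_sd)
        background = im.edu_background[0]
        assert background + lo <= median <= background + hi


class TestPlate:
    def test_nine_well_plate_counts(self, tmp_path):
        conditions = {c: ConditionParams(expected_attached_cells=15.0)
                      for c in ("Fn1", "Fn5", "Fn25")}
        params = SimulationParams(conditions=conditions,
                                  image_shape=(384, 384))
        wells = {f"B{c:02d}": cond
                 for c, cond in zip((2, 3, 4), ("Fn1", "Fn5", "Fn25"))}
        wells.update({f"C{c:02d}": cond
                      for c, cond in zip((2, 3, 4), ("Fn1", "Fn5", "Fn25"))})
        wells.update({f"D{c:02d}": cond
                      for c, cond in zip((2, 3, 4), ("Fn1", "Fn5", "Fn25"))})
        layout = _layout(wells)
        truth = simulate_plate(layout, params, seed=4, outdir=tmp_path)
        result = discover_images(tmp_path)
        assert len(result.fields) == 9 * 9          # wells x fields
        assert result.diagnostics == []
        assert set(truth["well"]) <= set(wells)
        image = result.fields[0].load(params.pixel_size_um)
        assert image.shape == (384, 384)

    def test_default_presets_order_cell_counts(self, sim_params):
        layout = _layout({
            "B02": "Fn1", "C02": "Fn1", "D02": "Fn1",
            "B03": "Fn5", "C03": "Fn5", "D03": "Fn5",
            "B04": "Fn25", "C04": "Fn25", "D04": "Fn25",
        })
        truth = sample_plate_truth(layout, sim_params, seed=6)
        counts = truth.groupby("well").size()
        mean = {c: counts[[w for w in layout.wells_for(c)]].mean()
                for c in ("Fn1", "Fn5", "Fn25")}
        assert mean["Fn25"] > mean["Fn5"] > mean["Fn1"]

    def test_exchangeable_presets_give_equal_counts(self):
        shared = ConditionParams(expected_attached_cells=100.0)
        params = SimulationParams(
            conditions={"A": shared, "B": shared, "C": shared},
            image_shape=(768, 768))
        wells = {}
        for i, row in enumerate("BCDEFG"):
            for j, cond in enumerate("ABC"):
                wells[f"{row}{j + 2:02d}"] = cond
        truth = sample_plate_truth(_layout(wells), params, seed=13)
        counts = truth.groupby("well").size()
        by_condition = {c: [counts.get(w, 0) for w, cc in wells.items() if cc == c]
                        for c in "ABC"}
        means = {c: np.mean(v) for c, v in by_condition.items()}
        # compound-Poisson SE of a 6-well condition mean
        p = shared.clump_geometric_p
        lam = shared.expected_attached_cells * p
        var = lam * (2 - p) / p**2
        se_diff = np.sqrt(2 * var / 6)
        assert max(means.values()) - min(means.values()) <= 4 * se_diff

    def test_fewer_cells_give_more_singles_across_presets(self, sim_params):
        """Default presets couple low adhesion to low density and more singles."""
        layout = _layout({"B02": "Fn1", "B03": "Fn5", "B04": "Fn25",
                          "C02": "Fn1", "C03": "Fn5", "C04": "Fn25",
                          "D02": "Fn1", "D03": "Fn5", "D04": "Fn25"})
        truth = sample_plate_truth(layout, sim_params, seed=21)
        stats = {}
        for condition in ("Fn1", "Fn5", "Fn25"):
            sub = truth[truth["well"].isin(layout.wells_for(condition))]
            singles = (sub["clump_size"] == 1).mean()
            stats[condition] = (len(sub) / 3, singles)
        assert stats["Fn1"][0] < stats["Fn5"][0] < stats["Fn25"][0]
        assert stats["Fn1"][1] > stats["Fn5"][1] > stats["Fn25"][1]

    def test_plate_truth_deterministic_and_matches_stream(self, sim_params):
        layout = _layout({"B02": "Fn1", "B03": "Fn5", "B04": "Fn25"})
        a = sample_plate_truth(layout, sim_params, seed=17)
        b = sample_plate_truth(layout, sim_params, seed=17)
        pd.testing.assert_frame_equal(a, b)
        streamed = []
        for image, sub in synthetic.iter_simulated_fields(layout, sim_params, 17):
            streamed.append(sub)
        streamed = pd.concat(streamed, ignore_index=True)
        merged = streamed.sort_values(["well", "object_id"]).reset_index(drop=True)
        expected = a.sort_values(["well", "object_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, expected)

    def test_unknown_layout_condition_fails_before_rendering(self, sim_params):
        layout = _layout({"B02": "Fn1", "B03": "Mystery"})
        with pytest.raises(KeyError, match="Mystery"):
            sample_plate_truth(layout, sim_params, seed=0)


class TestParamsIO:
    def test_yaml_round_trip(self, tmp_path, sim_params):
        path = params_to_yaml(sim_params, tmp_path / "params.yaml")
        back = params_from_yaml(path)
        assert back == sim_params

    def test_mixture_separability_enforced(self):
        with pytest.raises(ValueError, match="separable"):
            synthetic.IntensityModel(edu_negative_log_mean=3.0,
                                     edu_positive_log_mean=2.5)

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            ConditionParams(clump_geometric_p=0.0)
        with pytest.raises(ValueError):
            ConditionParams(edu_positive_fraction=1.5)
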