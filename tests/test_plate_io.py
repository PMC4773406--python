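"""Plate layout parsing, image discovery and table round-trip I/O."""

import numpy as np
import pandas as pd
import pytest
import tifffile

from phenoplate import plate_io
from phenoplate.plate_io import (
    CHANNELS,
    INTERIOR_WELLS,
    LayoutError,
    SchemaError,
    discover_images,
    is_border_well,
    load_plate_layout,
    make_column_layout,
    read_table,
    write_table,
)


def _write_layout(tmp_path, rows):
    path = tmp_path / "layout.csv"
    pd.DataFrame(rows, columns=["well", "condition"]).to_csv(path, index=False)
    return path


class TestLayout:
    def test_interior_wells_are_the_60_assignable_ones(self):
        assert len(INTERIOR_WELLS) == 60
        assert all(not is_border_well(w) for w in INTERIOR_WELLS)
        assert is_border_well("A01") and is_border_well("H12")
        assert is_border_well("A05") and is_border_well("D12") and is_border_well("D01")

    def test_three_condition_layout_loads(self, tmp_path):
        path = _write_layout(tmp_path, [("B02", "Fn1"), ("B03", "Fn5"),
                                        ("B04", "Fn25")])
        layout = load_plate_layout(path)
        assert layout.conditions == ("Fn1", "Fn25", "Fn5")
        assert layout.assay_wells == ("B02", "B03", "B04")
        assert layout.condition_of("C05") == "unused"

    def test_border_well_assignment_rejected(self, tmp_path):
        path = _write_layout(tmp_path, [("A01", "Fn1"), ("B02", "Fn1"),
                                        ("B03", "Fn1"), ("B04", "Fn1")])
        with pytest.raises(LayoutError, match="border"):
            load_plate_layout(path)

    def test_malformed_well_name_rejected(self, tmp_path):
        path = _write_layout(tmp_path, [("B2", "Fn1")])
        with pytest.raises(LayoutError, match="malformed well name"):
            load_plate_layout(path)
        with pytest.raises(LayoutError):
            is_border_well("Z99")

    def test_empty_table_gives_vacuous_layout(self, tmp_path, caplog):
        path = _write_layout(tmp_path, [])
        with caplog.at_level("WARNING"):
            layout = load_plate_layout(path)
        assert layout.assay_wells == ()
        assert "zero assay wells" in caplog.text

    def test_sub_triplicate_conditions_warn_or_raise(self, tmp_path, caplog):
        path = _write_layout(tmp_path, [("B02", "Fn1")])
        with caplog.at_level("WARNING"):
            load_plate_layout(path)
        assert "triplicate" in caplog.text
        with pytest.raises(LayoutError, match="triplicate"):
            load_plate_layout(path, require_triplicates=True)

    def test_column_layout_has_replicates_off_border(self):
        layout = make_column_layout(("Fn1", "Fn5", "Fn25"), seed=3)
        for condition in ("Fn1", "Fn5", "Fn25"):
            wells = layout.wells_for(condition)
            assert len(wells) == 6
            assert all(not is_border_well(w) for w in wells)
        # each interior column carries a single condition
        by_column = {}
        for well in layout.assay_wells:
            by_column.setdefault(well[1:], set()).add(layout.condition_of(well))
        assert all(len(conds) == 1 for conds in by_column.values())


class TestDiscovery:
    def _touch_field(self, root, well, field, channels=CHANNELS):
        for channel in channels:
            arr = np.zeros((4, 4), dtype=np.uint16)
            tifffile.imwrite(root / f"{well}_f{field}_{channel}.tif", arr)

    def test_full_plate_counts(self, tmp_path):
        for well in INTERIOR_WELLS:
            for fld in range(1, 10):
                for channel in CHANNELS:
                    (tmp_path / f"{well}_f{fld}_{channel}.tif").touch()
        result = discover_images(tmp_path)
        assert len(result.fields) == 60 * 9
        assert result.diagnostics == []

    def test_missing_channel_reported_not_dropped_silently(self, tmp_path):
        self._touch_field(tmp_path, "B02", 1)
        self._touch_field(tmp_path, "B02", 2,
                          channels=("dapi", "cellmask647", "brightfield"))
        result = discover_images(tmp_path)
        assert [(r.well, r.field) for r in result.fields] == [("B02", 1)]
        assert any("edu488" in d for d in result.diagnostics)

    def test_all_edu_missing_gives_zero_refs_full_diagnostics(self, tmp_path):
        for fld in (1, 2, 3):
            self._touch_field(tmp_path, "C04", fld,
                              channels=("dapi", "cellmask647", "brightfield"))
        result = discover_images(tmp_path)
        assert result.fields == []
        assert len(result.diagnostics) == 3

    def test_unparseable_name_skipped_with_warning(self, tmp_path, caplog):
        self._touch_field(tmp_path, "B02", 1)
        (tmp_path / "snapshot.tif").touch()
        with caplog.at_level("WARNING"):
            result = discover_images(tmp_path)
        assert len(result.fields) == 1
        assert any("unparseable" in d for d in result.diagnostics)

    def test_reference_loads_all_four_channels(self, tmp_path):
        self._touch_field(tmp_path, "D05", 3)
        ref = discover_images(tmp_path).fields[0]
        image = ref.load(pixel_size_um=0.65)
        assert image.shape == (4, 4)
        assert set(image.channels) == set(CHANNELS)

    def test_pattern_must_expose_groups(self, tmp_path):
        with pytest.raises(ValueError, match="capture group"):
            discover_images(tmp_path, naming=r".*\.tif$")


def _random_object_table(rng, n):
    return pd.DataFrame({
        "plate": "p1", "well": "B02", "field": 1,
        "object_id": np.arange(1, n + 1),
        "centroid_row": rng.uniform(0, 100, n),
        "centroid_col": rng.uniform(0, 100, n),
        "nucleus_area_um2": rng.uniform(60, 600, n),
        "nucleus_roundness": rng.uniform(0.2, 1, n),
        "nucleus_width_to_length": rng.uniform(0.2, 1, n),
        "cell_area_um2": rng.uniform(600, 6000, n),
        "cell_roundness": rng.uniform(0.2, 1, n),
        "cell_width_to_length": rng.uniform(0.2, 1, n),
        "dapi_median": rng.uniform(500, 10000, n),
        "edu488_median": rng.uniform(100, 9000, n),
        "brightfield_median": rng.uniform(400, 600, n),
        "n_per_clump": rng.integers(1, 6, n).astype(float),
        "qc_stage": "cell",
    })


class TestTables:
    def test_object_table_round_trip_identity(self, tmp_path, rng):
        table = _random_object_table(rng, 1000)
        path = write_table(table, tmp_path / "objects.csv", kind="object")
        back = read_table(path, kind="object")
        pd.testing.assert_frame_equal(back, table, check_dtype=False)

    def test_missing_values_survive_round_trip(self, tmp_path, rng):
        table = _random_object_table(rng, 5)
        table.loc[2, "n_per_clump"] = np.nan
        table.loc[4, "edu488_median"] = np.nan
        path = write_table(table, tmp_path / "objects.csv", kind="object")
        back = read_table(path, kind="object")
        assert back["n_per_clump"].isna().tolist() == table["n_per_clump"].isna().tolist()
        pd.testing.assert_frame_equal(back, table, check_dtype=False)

    def test_schema_error_names_missing_columns(self, tmp_path, rng):
        table = _random_object_table(rng, 3).drop(columns=["edu488_median"])
        table.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(SchemaError, match="edu488_median"):
            read_table(tmp_path / "bad.csv", kind="object")
        with pytest.raises(SchemaError):
            write_table(table, tmp_path / "x.csv", kind="object")

    def test_round_trip_property_on_random_tables(self, tmp_path):
        from hypothesis import given, settings, strategies as st

        finite = st.floats(min_value=1e-3, max_value=1e5, allow_nan=False)
        maybe_missing = st.one_of(st.just(np.nan), finite)

        @settings(max_examples=25, deadline=None, derandomize=True)
        @given(st.lists(st.tuples(finite, maybe_missing, st.integers(0, 500)),
                        min_size=1, max_size=20))
        def check(rows):
            table = pd.DataFrame({
                "plate": "p1",
                "well": [f"B{2 + i % 10:02d}" for i in range(len(rows))],
                "condition": "Fn5",
                "cell_count": [r[2] for r in rows],
                "edu_positive_fraction": [r[1] for r in rows],
                "fraction_single": [r[0] for r in rows],
                "inverse_mean_clump_size": [r[0] for r in rows],
                "n_clumps": [r[2] for r in rows],
            })
            path = write_table(table, tmp_path / "ws.csv", kind="well_summary")
            back = read_table(path, kind="well_summary")
            pd.testing.assert_frame_equal(back, table, check_dtype=False)

        check()

    @pytest.mark.parametrize("kind,maker", [
        ("clump", lambda rng: pd.DataFrame({
            "well": "B02", "field": 1, "clump_id": [1, 2],
            "clump_size": [3, 1], "members": ["1;2;3", "4"]})),
        ("well_summary", lambda rng: pd.DataFrame({
            "plate": "p1", "well": ["B02", "B03"], "condition": "Fn1",
            "cell_count": [10, 0], "edu_positive_fraction": [0.3, np.nan],
            "fraction_single": [0.4, np.nan],
            "inverse_mean_clump_size": [0.7, np.nan], "n_clumps": [7, 0]})),
    ])
    def test_other_kinds_round_trip(self, tmp_path, rng, kind, maker):
        table = maker(rng)
        path = write_table(table, tmp_path / f"{kind}.csv", kind=kind)
        back = read_table(path, kind=kind)
        pd.testing.assert_frame_equal(back, table, check_dtype=False)
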