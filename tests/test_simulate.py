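"""Generator: effect algebra, rendering oracles, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pydantic import ValidationError

from scpnscreen.simulate import (NULL_EFFECT, CompoundEffect, ImageSpec,
                                 PlateDesign, PopulationModel, Toxicity,
                                 WellSpec, adjusted_subtype_fractions,
                                 default_screen_scenario, generate_plate,
                                 place_cells, primary_neuron_model,
                                 render_field, sample_plate_truth,
                                 sample_population)


def _positivity(df, marker_subtypes):
    v = df[df["viable"]]
    return v["subtype"].isin(marker_subtypes).mean()


class TestSamplePopulation:
    def test_empty_input(self, rng):
        df = sample_population(primary_neuron_model(), NULL_EFFECT, 0, rng)
        assert len(df) == 0

    def test_negative_n_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_population(primary_neuron_model(), NULL_EFFECT, -1, rng)

    def test_baseline_positivity_matches_primary_culture(self, rng):
        """Defaults reproduce ~25% CTIP2+ and ~35% SATB2+ among viable nuclei."""
        df = sample_population(primary_neuron_model(), NULL_EFFECT, 10_000, rng)
        n_v = int(df["viable"].sum())
        se = lambda p: np.sqrt(p * (1 - p) / n_v)  # noqa: E731
        assert abs(_positivity(df, ["ctip2_only", "dual"]) - 0.25) < 3 * se(0.25)
        assert abs(_positivity(df, ["satb2_only", "dual"]) - 0.35) < 3 * se(0.35)

    def test_refinement_shift_converts_duals(self, rng):
        """delta=0.5 halves the dual fraction and moves it to CTIP2-only.

        Expected values from the closed-form adjusted fractions:
        f'_co = 0.05 + 0.5*0.20 = 0.15, f'_dual = 0.5*0.20 = 0.10.
        """
        eff = CompoundEffect(refinement_shift=0.5)
        df = sample_population(primary_neuron_model(), eff, 10_000, rng)
        v = df[df["viable"]]
        n_v = len(v)
        se = lambda p: np.sqrt(p * (1 - p) / n_v)  # noqa: E731
        assert abs((v["subtype"] == "ctip2_only").mean() - 0.15) < 3 * se(0.15)
        assert abs((v["subtype"] == "dual").mean() - 0.10) < 3 * se(0.10)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValidationError):
            PopulationModel(subtype_fractions=(0.5, 0.5, 0.5, -0.5))
        with pytest.raises(ValidationError):
            PopulationModel(subtype_fractions=(0.3, 0.3, 0.3, 0.2))

    def test_kill_and_pyknosis(self, rng):
        eff = CompoundEffect(toxicity=Toxicity.severe, kill_fraction=0.5,
                             pyknotic_fraction=0.4)
        df = sample_population(primary_neuron_model(), eff, 8_000, rng)
        assert abs(len(df) / 8_000 - 0.5) < 3 * np.sqrt(0.25 / 8_000)
        pyk = df[df["pyknotic"]]
        assert len(pyk) / len(df) > 0.3
        # pyknotic nuclei are small and Hoechst-bright
        assert (pyk["area_um2"] < 33).all()
        assert (pyk["i_hoechst"] >= 900).all()


class TestEffectAlgebra:
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 0.5))
    def test_conversion_conserves_ctip2_positivity(self, delta, f_co_raw, f_dual):
        f_co = f_co_raw * (1 - f_dual)
        rest = 1 - f_co - f_dual
        f = (f_co, rest / 2, f_dual, rest / 2)
        fp = adjusted_subtype_fractions(f, delta)
        assert fp[0] + fp[2] == pytest.approx(f[0] + f[2], abs=1e-12)
        assert abs(sum(fp) - 1) < 1e-9

    def test_monotone_in_delta(self):
        f = (0.05, 0.15, 0.20, 0.60)
        deltas = [0, 0.25, 0.5, 0.75, 1.0]
        cos = [adjusted_subtype_fractions(f, d)[0] for d in deltas]
        duals = [adjusted_subtype_fractions(f, d)[2] for d in deltas]
        assert all(a < b for a, b in zip(cos, cos[1:]))
        assert all(a > b for a, b in zip(duals, duals[1:]))

    def test_toxicity_none_requires_zero_fractions(self):
        with pytest.raises(ValidationError):
            CompoundEffect(toxicity=Toxicity.none, kill_fraction=0.2)

    def test_dose_response_scaling(self):
        eff = CompoundEffect(refinement_shift=0.6, ec50_um=1.0)
        assert eff.at_dose(1.0).refinement_shift == pytest.approx(0.3)
        assert eff.at_dose(10.0).refinement_shift > eff.at_dose(0.1).refinement_shift
        assert CompoundEffect(refinement_shift=0.6).at_dose(0.1).refinement_shift == 0.6


def _one_cell_frame(area_um2=50.0, ecc=0.0, x_px=60.0, y_px=50.0,
                    i_hoechst=600.0, i_marker=0.0):
    return pd.DataFrame({
        "x_px": [x_px], "y_px": [y_px], "area_um2": [area_um2],
        "eccentricity": [ecc], "angle_rad": [0.3],
        "i_hoechst": [i_hoechst], "i_ctip2": [i_marker],
        "i_satb2": [i_marker], "i_ctip1": [i_marker],
    })


class TestRenderField:
    SPEC = ImageSpec(width_px=120, height_px=100)

    def test_background_only(self, rng):
        imgs = render_field(pd.DataFrame(), self.SPEC, rng)
        npx = self.SPEC.width_px * self.SPEC.height_px
        se = self.SPEC.noise_sd / np.sqrt(npx)
        for arr in imgs.values():
            assert abs(arr.mean() - self.SPEC.background) < 3 * se + 0.5

    def test_half_maximum_area_recovers_truth(self, rng):
        """Pixel count above the footprint half-maximum gives the true area."""
        imgs = render_field(_one_cell_frame(area_um2=50.0, ecc=0.4),
                            self.SPEC, rng)
        h = imgs["hoechst"].astype(float) - self.SPEC.background
        area = (h > 300.0).sum() * self.SPEC.pixel_scale ** 2
        assert area == pytest.approx(50.0, rel=0.10)

    def test_zero_marker_signal_is_background(self, rng):
        imgs = render_field(_one_cell_frame(i_marker=0.0), self.SPEC, rng)
        npx = self.SPEC.width_px * self.SPEC.height_px
        se = self.SPEC.noise_sd / np.sqrt(npx)
        assert abs(imgs["ch488"].mean() - self.SPEC.background) < 3 * se + 0.5

    def test_centroid_outside_field_rejected(self, rng):
        with pytest.raises(ValueError):
            render_field(_one_cell_frame(x_px=500.0), self.SPEC, rng)

    def test_invalid_image_spec_rejected(self):
        with pytest.raises(ValidationError):
            ImageSpec(width_px=0)
        with pytest.raises(ValidationError):
            ImageSpec(pixel_scale=-1.0)


class TestPlateGeneration:
    def _tiny(self, seed=7):
        return default_screen_scenario(
            n_compounds=2, n_enhancers=1, n_toxic=0, seed=seed,
            doses=(10.0,), replicates=1, control_replicates=1, density=60,
            image_spec=ImageSpec(width_px=160, height_px=120))

    def test_same_seed_bit_identical(self):
        p1 = generate_plate(*self._tiny())
        p2 = generate_plate(*self._tiny())
        assert set(p1.images) == set(p2.images)
        for key in p1.images:
            for ch in p1.images[key]:
                assert np.array_equal(p1.images[key][ch], p2.images[key][ch])
        pd.testing.assert_frame_equal(p1.truth, p2.truth)

    def test_distinct_seeds_differ(self):
        p1 = generate_plate(*self._tiny(seed=7))
        p2 = generate_plate(*self._tiny(seed=8))
        key = next(iter(p1.images))
        assert not np.array_equal(p1.images[key]["hoechst"],
                                  p2.images[key]["hoechst"])

    def test_field_counts_follow_density(self):
        """Per-field nucleus counts are Poisson with the configured mean."""
        design, models, effects = default_screen_scenario(
            n_compounds=0, n_enhancers=0, n_toxic=0, control_replicates=1,
            fields_per_well=30, density=150, seed=1)
        design = design.model_copy(update={"wells": design.wells[:4]})
        plate = sample_plate_truth(design, models, effects)
        counts = plate.truth.groupby(["well", "field"]).size()
        n_fields = len(counts)
        assert n_fields >= 100
        assert abs(counts.mean() - 150) < 3 * np.sqrt(150 / n_fields)

    def test_default_design_doses_in_duplicate(self):
        """Every compound appears in duplicate wells at 10, 1, and 0.1 uM."""
        design, _, _ = default_screen_scenario(n_compounds=5, n_enhancers=1,
                                               n_toxic=1)
        pm = pd.DataFrame([w.model_dump() for w in design.wells])
        per = pm[pm["compound"].notna()].groupby(["compound", "dose_um"]).size()
        assert (per == 2).all()
        for compound in pm["compound"].dropna().unique():
            doses = set(pm.loc[pm["compound"] == compound, "dose_um"])
            assert doses == {10.0, 1.0, 0.1}

    def test_unbalanced_design_rejected(self):
        wells = [WellSpec(well="A1", condition="compound_fezf2", compound="X",
                          dose_um=10.0, replicate=1),
                 WellSpec(well="A2", condition="compound_fezf2", compound="X",
                          dose_um=10.0, replicate=2),
                 WellSpec(well="A3", condition="compound_fezf2", compound="X",
                          dose_um=1.0, replicate=1)]
        with pytest.raises(ValidationError):
            PlateDesign(wells=wells)

    def test_duplicate_well_ids_rejected(self):
        wells = [WellSpec(well="A1", condition="untreated"),
                 WellSpec(well="A1", condition="dmso")]
        with pytest.raises(ValidationError):
            PlateDesign(wells=wells)

    def test_missing_model_or_effect_rejected(self):
        design, models, effects = self._tiny()
        with pytest.raises(ValueError, match="condition"):
            generate_plate(design, {}, effects)
        with pytest.raises(ValueError, match="compound"):
            generate_plate(design, models, {})


def test_placement_respects_field_margin(rng):
    spec = ImageSpec(width_px=200, height_px=150)
    cells = sample_population(primary_neuron_model(), NULL_EFFECT, 150, rng)
    placed = place_cells(cells, spec, rng, clump_fraction=0.1)
    assert (placed["x_px"] >= 0).all() and (placed["x_px"] < 200).all()
    assert (placed["y_px"] >= 0).all() and (placed["y_px"] < 150).all()
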