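"""Element/material data layer: conversions, attenuation, fluorescence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mosaicfocus.xray_data import (
    MaterialSpec,
    element_mass_attenuation,
    energy_to_wavelength,
    fluorescence_lines,
    get_material,
    load_materials_yaml,
    mass_attenuation,
    wavelength_to_energy,
    K_EDGE_KEV,
)


class TestWavelength:
    def test_known_values(self):
        assert energy_to_wavelength(59.0) == pytest.approx(0.21014, abs=2e-5)
        # Cu K-alpha1 check
        assert energy_to_wavelength(8.048) == pytest.approx(1.5406, abs=2e-4)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(min_value=0.5, max_value=500.0))
    def test_round_trip(self, e):
        assert wavelength_to_energy(energy_to_wavelength(e)) == pytest.approx(e, rel=1e-12)

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            energy_to_wavelength(0.0)


class TestAttenuation:
    def test_carbon_transport_total_60kev(self):
        # reference tabulation value ~0.175 cm^2/g
        mu = element_mass_attenuation("C", 60.0, "transport_total")
        assert mu == pytest.approx(0.175, rel=0.08)

    @pytest.mark.parametrize("material", ["graphite", "water", "soft_tissue", "lead"])
    @pytest.mark.parametrize("energy", [10.0, 59.0, 120.0])
    def test_component_additivity(self, material, energy):
        mat = get_material(material)
        parts = sum(
            mass_attenuation(mat, energy, c)
            for c in ("photoelectric", "compton", "rayleigh")
        )
        total = mass_attenuation(mat, energy, "transport_total")
        assert parts == pytest.approx(total, rel=1e-9)

    def test_hafnium_k_edge_jump(self):
        edge = K_EDGE_KEV["Hf"]
        below = element_mass_attenuation("Hf", edge * 0.999)
        above = element_mass_attenuation("Hf", edge * 1.001)
        assert above > 3 * below

    def test_mixture_rule_linearity(self):
        half = MaterialSpec("half", (("C", 0.5), ("Al", 0.5)), 2.0)
        for e in (10.0, 59.0, 150.0):
            expect = 0.5 * element_mass_attenuation("C", e) + \
                0.5 * element_mass_attenuation("Al", e)
            assert mass_attenuation(half, e, "transport_total") == pytest.approx(expect)

    @pytest.mark.parametrize("sym", ["H", "C", "O", "Al", "Si"])
    def test_monotone_decrease_between_edges(self, sym):
        # no edges above 2 keV for these elements
        e = np.linspace(2.0, 199.0, 300)
        mu = element_mass_attenuation(sym, e, "transport_total")
        assert np.all(np.diff(mu) < 0)

    def test_unknown_element_raises(self):
        with pytest.raises(KeyError):
            element_mass_attenuation("Xx", 60.0)

    def test_bad_mass_fractions_rejected(self):
        with pytest.raises(ValueError):
            MaterialSpec("broken", (("C", 0.6), ("O", 0.3)), 1.0)


class TestFluorescence:
    def test_tungsten_k_alpha_doublet(self):
        lines = {ln.label: ln.energy for ln in fluorescence_lines("W")}
        assert lines["Ka1"] == pytest.approx(59.32, abs=0.01)
        assert lines["Ka2"] == pytest.approx(57.98, abs=0.01)

    def test_contrast_agent_lines(self):
        pd = {ln.label: ln.energy for ln in fluorescence_lines("Pd")}
        ba = {ln.label: ln.energy for ln in fluorescence_lines("Ba")}
        assert pd["Ka1"] == pytest.approx(21.18, abs=0.05)
        assert ba["Ka1"] == pytest.approx(32.19, abs=0.05)

    @pytest.mark.parametrize("sym", sorted(K_EDGE_KEV))
    def test_series_probabilities_and_edges(self, sym):
        lines = fluorescence_lines(sym)
        assert sum(ln.probability for ln in lines) == pytest.approx(1.0)
        assert all(0 <= ln.omega_k <= 1 for ln in lines)
        assert all(ln.energy < K_EDGE_KEV[sym] for ln in lines)

    def test_unsupported_element(self):
        with pytest.raises(KeyError):
            fluorescence_lines("C")


def test_yaml_material_override(tmp_path):
    path = tmp_path / "mats.yaml"
    path.write_text(
        "materials:\n  my_gel:\n    density: 1.02\n"
        "    composition: {H: 0.11, O: 0.89}\n"
    )
    loaded = load_materials_yaml(path)
    assert loaded[0].density == 1.02
    assert get_material("my_gel") is loaded[0]
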