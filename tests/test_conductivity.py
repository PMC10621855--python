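"""Electroporation conductivity sigmoid."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from pfafield import TissueLabel, TissueProperties, half_rise_field, sigma_of_E


@pytest.fixture(scope="module")
def props():
    return TissueProperties()


def test_asymptotic_and_center_values(props):
    # lower asymptote
    assert sigma_of_E(TissueLabel.MYOCARDIUM, 0.0, props) == pytest.approx(
        0.4, abs=1e-8)
    # at the sigmoid center the rise term is (s1-s0)/(1+prefactor)
    assert sigma_of_E(TissueLabel.MYOCARDIUM, 58000.0, props) == pytest.approx(
        0.4 + 0.2 / 11.0, abs=1e-10)
    # upper asymptote
    assert sigma_of_E(TissueLabel.MYOCARDIUM, 3e5, props) == pytest.approx(
        0.6, abs=1e-3)


@pytest.mark.parametrize("label,expected", [
    (TissueLabel.FIBROSIS, 0.85),
    (TissueLabel.FAT, 0.08),
    (TissueLabel.BLOOD, 0.6),
    (TissueLabel.CONNECTIVE, 0.115),
])
def test_field_independent_tissues(label, expected, props):
    for E in (0.0, 58000.0, 1e6):
        assert sigma_of_E(label, E, props) == expected


def test_negative_field_rejected(props):
    with pytest.raises(ValueError):
        sigma_of_E(TissueLabel.MYOCARDIUM, -1.0, props)


@given(st.floats(min_value=0.0, max_value=1e7),
       st.floats(min_value=0.0, max_value=1e7))
def test_monotone_and_bounded(E1, E2):
    props = TissueProperties()
    s1 = sigma_of_E(TissueLabel.MYOCARDIUM, E1, props)
    s2 = sigma_of_E(TissueLabel.MYOCARDIUM, E2, props)
    assert 0.4 <= s1 <= 0.6
    if E1 <= E2:
        assert s1 <= s2 + 1e-15


def test_half_rise_point_matches_root_finder(props):
    """sigma = (s0+s1)/2 occurs at Ec + Es*ln(prefactor)."""
    target = 0.5 * (0.4 + 0.6)
    root = brentq(lambda E: sigma_of_E(TissueLabel.MYOCARDIUM, E, props)
                  - target, 1e3, 1e6, xtol=1e-6)
    assert half_rise_field(props) == pytest.approx(root, abs=0.1)
    assert half_rise_field(props) == pytest.approx(
        58000.0 + 3000.0 * np.log(10.0), abs=1e-6)


def test_vectorized_over_labels_and_fields(props):
    labels = np.array([int(TissueLabel.MYOCARDIUM), int(TissueLabel.FAT),
                       int(TissueLabel.FIBROSIS)])
    E = np.array([1e5, 1e5, 1e5])
    out = sigma_of_E(labels, E, props)
    assert out.shape == (3,)
    assert out[1] == 0.08 and out[2] == 0.85


def test_alternative_fat_value_and_roundtrip(props):
    alt = props.with_fat(0.015)
    assert sigma_of_E(TissueLabel.FAT, 1e5, alt) == 0.015
    again = TissueProperties.from_config(alt.to_config())
    assert again == alt
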