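"""RC, CNR, with/without ratios, exclusion rule and noise change."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phantomiq as pq


def make_records(tbrs=(2.0, 5.0, 10.5), amplitudes=(0.0, 7.0, 10.0, 20.0, 30.0),
                 diameters=(10.0, 13.0, 17.0, 22.0, 28.0, 37.0), seed=0):
    """Random but well-formed factorial record table (both corrected flags)."""
    rng = np.random.default_rng(seed)
    records = []
    for tbr, amp, (k, d) in itertools.product(
            tbrs, amplitudes, enumerate(diameters)):
        b_in, t_in = 2.0, 2.0 * tbr
        for corrected in (False, True):
            b_mean = b_in * (1 + 0.05 * rng.standard_normal())
            t_mean = t_in * rng.uniform(0.3, 0.9)
            t_max = t_mean * rng.uniform(1.0, 1.4)
            sigma = abs(rng.normal(0.2, 0.02))
            records.append(pq.MeasurementRecord(
                sphere_id=k, sphere_diameter_mm=d,
                sphere_volume_ml=round(pq.sphere_volume_ml(d), 1),
                amplitude=amp, tbr=tbr, corrected=corrected,
                t_max=t_max, t_mean=t_mean, b_mean=b_mean, sigma_b=sigma,
                t_in=t_in, b_in=b_in))
    return pq.records_to_frame(records)


@pytest.mark.parametrize("args,expected", [
    ((5.0, 2.0, 10.5, 2.1), 0.5),        # hand-evaluated ratio of ratios
    ((4.0, 2.0, 10.0, 5.0), 1.0),        # perfect recovery
])
def test_recovery_coefficient_examples(args, expected):
    assert pq.recovery_coefficient(*args) == pytest.approx(expected)


@settings(deadline=None, max_examples=50)
@given(t=st.floats(0.1, 100), b=st.floats(0.1, 100),
       scale=st.floats(0.1, 10))
def test_recovery_coefficient_scale_invariance(t, b, scale):
    rc = pq.recovery_coefficient(t, b, 10.0, 2.0)
    assert pq.recovery_coefficient(t * scale, b * scale, 10.0, 2.0) == \
        pytest.approx(rc, rel=1e-9)


def test_recovery_coefficient_rejects_nonpositive_denominators():
    with pytest.raises(ValueError):
        pq.recovery_coefficient(1.0, 0.0, 10.0, 2.0)
    with pytest.raises(ValueError):
        pq.recovery_coefficient(1.0, 2.0, -1.0, 2.0)


def test_contrast_to_noise_examples_and_antisymmetry():
    assert pq.contrast_to_noise(12.0, 2.0, 2.0) == pytest.approx(5.0)
    assert pq.contrast_to_noise(2.0, 2.0, 1.0) == 0.0
    delta = 0.7
    assert pq.contrast_to_noise(2.0 - delta, 2.0, 0.3) == pytest.approx(
        -pq.contrast_to_noise(2.0 + delta, 2.0, 0.3))
    with pytest.raises(ValueError):
        pq.contrast_to_noise(1.0, 2.0, 0.0)


def test_ddmc_ratio():
    assert pq.ddmc_ratio(1.4, 1.0) == pytest.approx(1.4)
    assert pq.ddmc_ratio(3.3, 3.3) == 1.0
    assert math.isnan(pq.ddmc_ratio(1.0, 0.0))


def test_formula_integrity_bit_exact():
    """RC and CNR stored on each record equal a one-line recomputation."""
    df = make_records()
    for _, r in df.iterrows():
        assert r["rc_max"] == (r["t_max"] / r["b_mean"]) / (r["t_in"] / r["b_in"])
        assert r["rc_mean"] == (r["t_mean"] / r["b_mean"]) / (r["t_in"] / r["b_in"])
        assert r["cnr_max"] == (r["t_max"] - r["b_mean"]) / r["sigma_b"]
        assert r["cnr_mean"] == (r["t_mean"] - r["b_mean"]) / r["sigma_b"]


def test_aggregate_ratios_simple_means():
    df = make_records()
    table = pq.aggregate_ratios(df, "over_tbr")
    # 6 spheres x 5 amplitudes x 4 parameters
    assert len(table) == 6 * 5 * 4
    assert set(table["n_included"]) <= {0, 1, 2, 3}
    over_sphere = pq.aggregate_ratios(df, "over_sphere")
    assert len(over_sphere) == 3 * 5 * 4


def test_aggregate_ratios_matches_brute_force_recomputation():
    """Equivalence with an independent recomputation from the raw table."""
    df = make_records(seed=42)
    table = pq.aggregate_ratios(df, "over_tbr")
    for _, row in table.iterrows():
        sub = df[(df["sphere_volume_ml"] == row["sphere_volume_ml"]) &
                 (df["amplitude"] == row["amplitude"])]
        ratios = []
        n_excluded = 0
        for tbr in sorted(sub["tbr"].unique()):
            cell = sub[sub["tbr"] == tbr]
            v_with = cell[cell["corrected"]][row["parameter"]].iloc[0]
            v_without = cell[~cell["corrected"]][row["parameter"]].iloc[0]
            if v_with < 0 or v_without < 0 or v_without == 0:
                n_excluded += 1
            else:
                ratios.append(v_with / v_without)
        assert row["n_included"] == len(ratios)
        assert len(row["excluded"]) == n_excluded
        if ratios:
            assert row["ratio"] == pytest.approx(np.mean(ratios), rel=1e-12)
        else:
            assert math.isnan(row["ratio"])


def test_aggregate_ratios_exclusion_rule_and_locality():
    """A negative CNR cell is dropped from its average and nothing else moves."""
    df = make_records(tbrs=(2.0, 5.0, 10.5), amplitudes=(0.0, 20.0),
                      diameters=(10.0, 37.0), seed=3)
    # force one negative with-correction CNR cell: sphere 10 mm, amp 20, tbr 5
    mask = ((df["sphere_diameter_mm"] == 10.0) & (df["amplitude"] == 20.0)
            & (df["tbr"] == 5.0) & df["corrected"])
    df.loc[mask, "cnr_max"] = -0.2
    before = pq.aggregate_ratios(df, "over_tbr")
    cell = before[(before["parameter"] == "cnr_max") &
                  (before["sphere_volume_ml"] == 0.5) &
                  (before["amplitude"] == 20.0)].iloc[0]
    assert cell["n_included"] == 2
    assert cell["excluded"] == (5.0,)
    # mean of the two surviving per-TBR ratios
    survivors = []
    for tbr in (2.0, 10.5):
        sub = df[(df["sphere_diameter_mm"] == 10.0) & (df["amplitude"] == 20.0)
                 & (df["tbr"] == tbr)]
        survivors.append(sub[sub["corrected"]]["cnr_max"].iloc[0]
                         / sub[~sub["corrected"]]["cnr_max"].iloc[0])
    assert cell["ratio"] == pytest.approx(np.mean(survivors))
    # locality: other cells unchanged vs the unmodified table
    df_clean = make_records(tbrs=(2.0, 5.0, 10.5), amplitudes=(0.0, 20.0),
                            diameters=(10.0, 37.0), seed=3)
    clean = pq.aggregate_ratios(df_clean, "over_tbr")
    changed = (before["ratio"] != clean["ratio"]) & ~(
        before["ratio"].isna() & clean["ratio"].isna())
    assert changed.sum() == 1


def test_three_ratio_mean():
    df = make_records(tbrs=(2.0, 5.0, 10.5), amplitudes=(0.0,),
                      diameters=(22.0,), seed=1)
    # overwrite so the three per-TBR rc_max ratios are exactly 1.1, 1.2, 1.3
    for tbr, ratio in zip((2.0, 5.0, 10.5), (1.1, 1.2, 1.3)):
        for corrected, value in ((False, 1.0), (True, ratio)):
            m = (df["tbr"] == tbr) & (df["corrected"] == corrected)
            df.loc[m, "rc_max"] = value
    cell = pq.aggregate_ratios(df, "over_tbr").query("parameter == 'rc_max'")
    assert cell["ratio"].iloc[0] == pytest.approx(1.2)


def test_noise_change_aggregation():
    df = make_records(seed=9)
    # fix sigma so each TBR has a known uniform change: +15%, +61%, +37%
    changes = {2.0: 15.0, 5.0: 61.0, 10.5: 37.0}
    for tbr, pct in changes.items():
        df.loc[(df["tbr"] == tbr) & ~df["corrected"], "sigma_b"] = 0.2
        df.loc[(df["tbr"] == tbr) & df["corrected"], "sigma_b"] = 0.2 * (1 + pct / 100)
    out = pq.noise_change(df)
    for tbr, pct in changes.items():
        assert out["per_tbr_mean"][tbr] == pytest.approx(pct)
    # mean of per-TBR means: (15 + 61 + 37) / 3
    assert out["overall_mean_of_tbr_means"] == pytest.approx(37.666666666667)
    assert out["overall_mean_of_cells"] == pytest.approx(37.666666666667)


def test_noise_change_degenerate_single_tbr_and_zero_change():
    df = make_records(tbrs=(5.0,), seed=2)
    sigma = df.loc[~df["corrected"], "sigma_b"].to_numpy()
    df.loc[df["corrected"], "sigma_b"] = sigma
    out = pq.noise_change(df)
    assert out["overall_mean_of_tbr_means"] == pytest.approx(0.0, abs=1e-12)
    assert out["per_cell"]["sigma_b_change_pct"].abs().max() == pytest.approx(0.0, abs=1e-12)


def test_noise_change_missing_pair_is_an_error():
    df = make_records(tbrs=(2.0, 5.0), amplitudes=(0.0, 10.0), seed=4)
    df = df[~((df["tbr"] == 5.0) & (df["amplitude"] == 10.0) & df["corrected"])]
    with pytest.raises(ValueError, match="missing"):
        pq.noise_change(df)


def test_rc_partial_volume_ordering(default_phantom, default_static):
    """Static, noise-free: RC_mean grows with sphere size and stays in (0, 1.1]."""
    records = pq.measure_image(default_static, default_phantom, 0.0, False,
                               background_center_mm=(-80.0, -52.0, 0.0))
    df = pq.records_to_frame(records).sort_values("sphere_diameter_mm")
    rc = df["rc_mean"].to_numpy()
    assert rc[-1] > rc[0]                 # 37 mm recovers more than 10 mm
    assert np.all(rc > 0) and np.all(rc <= 1.1)
    assert np.all(df["rc_max"].to_numpy() >= rc)
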