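import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from seqshift import kernel
from seqshift.database import Entry, ShiftRecord
from seqshift.kernel import (
    CorrectionTable,
    DensityFunction,
    KernelModel,
    build_density,
    calibrate_nw,
    correction_weight,
    expected_shift,
    model_from_dict,
    model_to_dict,
    pairwise_correction,
    silverman_bandwidth,
    train_kernel_model,
)
from seqshift.residues import ResidueState


def analytic_gaussian_density(mean, sd, lo, hi, step=0.002):
    grid = np.arange(lo, hi + step, step)
    dens = norm.pdf(grid, mean, sd)
    dens /= np.trapezoid(dens, grid)
    return DensityFunction(grid=grid, density=dens, n_obs=1000, bandwidth=sd)


# ---------------------------------------------------------------------------
# build_density


def test_single_kernel_peaks_at_sample():
    d = build_density([4.0], bandwidth=0.1)
    assert d.grid[np.argmax(d.density)] == pytest.approx(4.0, abs=d.step)
    assert d.integral() == pytest.approx(1.0, abs=1e-6)


def test_two_kernels_symmetric_about_midpoint():
    d = build_density([1.0, 3.0], bandwidth=0.1)
    mean = np.trapezoid(d.grid * d.density, d.grid)
    assert mean == pytest.approx(2.0, abs=1e-6)


def test_density_mean_matches_monte_carlo_oracle():
    rng = np.random.default_rng(42)
    samples = rng.normal(55.0, 1.0, size=5000)
    d = build_density(samples, silverman_bandwidth(samples, "13C"))
    mean = np.trapezoid(d.grid * d.density, d.grid)
    # the KDE expectation equals the sample mean (independent oracle)
    assert mean == pytest.approx(samples.mean(), abs=0.001)
    assert mean == pytest.approx(55.0, abs=0.05)


def test_empty_sample_is_error():
    with pytest.raises(ValueError):
        build_density([], 0.1)


def test_grid_covers_samples_plus_five_bandwidths():
    d = build_density([1.0, 2.0], bandwidth=0.2)
    assert d.grid[0] <= 1.0 - 5 * 0.2
    assert d.grid[-1] >= 2.0 + 5 * 0.2


@settings(max_examples=30, deadline=None)
@given(
    st.lists(st.floats(min_value=-50, max_value=200), min_size=1, max_size=100),
    st.floats(min_value=0.02, max_value=2.0),
)
def test_density_normalization_property(samples, bandwidth):
    d = build_density(samples, bandwidth)
    assert d.integral() == pytest.approx(1.0, abs=1e-6)
    assert np.all(d.density >= 0)


# ---------------------------------------------------------------------------
# expected_shift


def test_expected_shift_symmetric_mean():
    rng = np.random.default_rng(0)
    samples = 2.0 + rng.normal(0, 0.3, size=2000)
    samples = np.concatenate([samples, 4.0 - samples])  # exactly symmetric about 2.0
    d = build_density(samples, 0.1)
    assert expected_shift(d, n_min_mean=50) == pytest.approx(2.0, abs=d.step)


def test_expected_shift_bimodal_small_n_takes_mode():
    samples = [1.0] * 7 + [5.0] * 3
    d = build_density(samples, 0.1)
    assert expected_shift(d, n_min_mean=50) == pytest.approx(1.0, abs=d.step)


def test_expected_shift_skewed_matches_trapezoid_oracle():
    rng = np.random.default_rng(1)
    samples = rng.gamma(2.0, 1.5, size=4000) + 50.0
    bw = silverman_bandwidth(samples, "13C")
    d = build_density(samples, bw)
    # independent oracle: direct fine-grid numerical integration of the KDE
    fine = np.linspace(samples.min() - 6 * bw, samples.max() + 6 * bw, 200001)
    dens = norm.pdf(fine[:, None], samples[None, :5], bw).sum(axis=1)
    for start in range(5, len(samples), 500):
        dens += norm.pdf(fine[:, None], samples[None, start : start + 500], bw).sum(axis=1)
    dens /= np.trapezoid(dens, fine)
    oracle = np.trapezoid(fine * dens, fine)
    assert expected_shift(d, n_min_mean=50) == pytest.approx(oracle, abs=1e-3)


def test_expected_shift_mode_tie_breaks_low():
    grid = np.arange(0.0, 10.0 + 0.01, 0.01)
    dens = np.zeros_like(grid)
    dens[100] = dens[800] = 1.0  # equal peaks at 1.0 and 8.0
    dens /= np.trapezoid(dens, grid)
    d = DensityFunction(grid=grid, density=dens, n_obs=5, bandwidth=0.01)
    assert expected_shift(d, n_min_mean=50) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# correction_weight


def test_weight_identical_densities_zero():
    d = build_density([1.0, 2.0, 3.0], 0.2)
    assert correction_weight(d, d) == 0.0


def test_weight_disjoint_supports_one():
    a = build_density([0.0], 0.05)
    b = build_density([100.0], 0.05)
    assert correction_weight(a, b) == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("sep", [0.0, 1.0, 2.0, 4.0])
def test_weight_matches_bruteforce_overlap(sep):
    a = analytic_gaussian_density(0.0, 1.0, -9.0, sep + 9.0)
    b = analytic_gaussian_density(sep, 1.0, -9.0, sep + 9.0)
    w = correction_weight(a, b)
    # brute-force fine-grid overlap integral, independent of the implementation
    fine = np.linspace(-12.0, sep + 12.0, 400001)
    overlap = np.trapezoid(np.minimum(norm.pdf(fine), norm.pdf(fine, sep)), fine)
    assert w == pytest.approx(1.0 - overlap, abs=1e-4)


@settings(max_examples=25, deadline=None)
@given(
    st.lists(st.floats(min_value=0, max_value=20), min_size=1, max_size=30),
    st.lists(st.floats(min_value=0, max_value=20), min_size=1, max_size=30),
)
def test_weight_bounded_property(sa, sb):
    a = build_density(sa, 0.3)
    b = build_density(sb, 0.3)
    w = correction_weight(a, b)
    assert 0.0 <= w <= 1.0


# ---------------------------------------------------------------------------
# pairwise corrections


def _pair_db(rng, n_entries=40, length=80, effect=0.5, noise=0.1, alphabet="ACDG"):
    """CA-only database where a G at offset -1 shifts the center by +effect."""
    base = {a: 50.0 + 3.0 * i for i, a in enumerate(alphabet)}
    entries = []
    for e in range(n_entries):
        letters = [str(a) for a in rng.choice(list(alphabet), size=length)]
        seq = [ResidueState(a) for a in letters]
        records = []
        for i, aa in enumerate(letters):
            value = base[aa]
            if i > 0 and letters[i - 1] == "G":
                value += effect
            records.append(
                ShiftRecord(f"P{e}", i + 1, seq[i], "CA", value + rng.normal(0, noise))
            )
        entries.append(Entry(f"P{e}", seq, records=records))
    return entries


def test_planted_pair_effect_recovered():
    # 20-letter alphabet keeps the marginal almost free of the planted pair
    from seqshift.residues import AA1

    rng = np.random.default_rng(3)
    entries = _pair_db(rng, n_entries=200, length=80, alphabet=AA1)
    model = train_kernel_model(entries, calibrate=False, n_min_mean=20)
    dd, n_pair, averaged = pairwise_correction(model, "CA", "A", "G", -1)
    assert n_pair >= 20
    assert not averaged
    # the marginal over A already contains the effect at P(G) = 1/20
    assert dd == pytest.approx(0.5 * (1 - 1 / 20), abs=0.05)


def test_pair_below_threshold_uses_averaged_flag():
    rng = np.random.default_rng(4)
    entries = _pair_db(rng, n_entries=3, length=30)
    model = train_kernel_model(entries, calibrate=False)
    term = model.corrections.lookup("CA", "A", "G", -1)
    assert term.n_pair < 20
    assert term.averaged


def test_pair_identical_to_marginal_gives_zero_correction():
    rng = np.random.default_rng(5)
    entries = _pair_db(rng, effect=0.0, noise=0.1)
    model = train_kernel_model(entries, calibrate=False)
    dd, _, _ = pairwise_correction(model, "CA", "A", "C", -1)
    assert dd == pytest.approx(0.0, abs=0.03)


def test_unobserved_neighbor_returns_zero():
    rng = np.random.default_rng(6)
    entries = _pair_db(rng)
    model = train_kernel_model(entries, calibrate=False)
    term = model.corrections.lookup("CA", "A", "W", -1)  # W never generated
    assert term.ddelta == 0.0 and term.w == 0.0 and term.n_pair == 0


def test_parameter_recovery_correlation(idp_db, idp_model):
    config, _, _ = idp_db
    recovered, planted = [], []
    for (atom, j, off), (dd, w, n) in idp_model.corrections.averaged.items():
        if n < 200:
            continue
        recovered.append(dd)
        planted.append(config.neighbor_effects.get((atom, j, off), 0.0))
    r = np.corrcoef(recovered, planted)[0, 1]
    assert r > 0.95


# ---------------------------------------------------------------------------
# N_W calibration


def _bare_model(expectation=50.0):
    table = CorrectionTable()
    return KernelModel(
        condition="idp",
        ph_bin=6.4,
        primary={("CA", "A"): kernel.PrimaryStat(expectation, 100, 0.1)},
        corrections=table,
        n_w={"CA": 1.0},
        atoms=["CA"],
    )


def test_calibrate_flat_returns_grid_floor():
    model = _bare_model()
    seq = [ResidueState("A")] * 10
    records = [ShiftRecord("E1", i, ResidueState("A"), "CA", 50.0) for i in range(1, 11)]
    entry = Entry("E1", seq, records=records)
    assert calibrate_nw(model, [entry], "CA") == pytest.approx(0.5)


def test_calibrate_no_data_defaults_to_one():
    model = _bare_model()
    entry = Entry("E1", [ResidueState("G")], records=[])
    assert calibrate_nw(model, [entry], "CA") == 1.0


def test_nw_round_trip():
    # generate data exactly by the assembled prediction with N_W = 2.0
    model = _bare_model()
    model.corrections.averaged[("CA", "G", -1)] = (1.0, 0.8, 100)
    true_nw = 2.0
    rng = np.random.default_rng(8)
    entries = []
    for e in range(30):
        letters = [str(a) for a in rng.choice(list("AG"), size=50)]
        seq = [ResidueState(a) for a in letters]
        records = []
        for i, aa in enumerate(letters):
            if aa != "A":
                continue
            value = 50.0
            if i > 0 and letters[i - 1] == "G":
                value += (0.8 * 1.0) / true_nw
            records.append(
                ShiftRecord(f"E{e}", i + 1, seq[i], "CA", value + rng.normal(0, 0.02))
            )
        entries.append(Entry(f"E{e}", seq, records=records))
    assert calibrate_nw(model, entries, "CA") == pytest.approx(2.0, abs=0.1)


def test_calibrated_nw_is_argmin(idp_db, idp_model):
    _, entries, _ = idp_db
    from seqshift.database import records_frame
    from seqshift.kernel import correction_sums

    df = records_frame(entries[:10])
    df = df[df["atom"] == "CA"]
    y = df["shift"].to_numpy()
    p = np.array([idp_model.primary[("CA", k)].expectation for k in df["res_key"]])
    c, _, _ = correction_sums(df, idp_model.corrections)
    nw_star = kernel._nw_search(y, p, c)
    rmsd_at = lambda nw: float(np.sqrt(np.mean((y - p - c / nw) ** 2)))
    assert all(rmsd_at(nw_star) <= rmsd_at(nw) + 1e-12 for nw in kernel.NW_GRID)


# ---------------------------------------------------------------------------
# serialization


def test_model_serialization_bit_exact(tmp_path, idp_model):
    path = tmp_path / "model.json"
    kernel.save_model(idp_model, path)
    loaded = kernel.load_model(path)
    assert model_to_dict(loaded) == model_to_dict(idp_model)
    # and the file itself is reproducible byte for byte
    path2 = tmp_path / "model2.json"
    kernel.save_model(loaded, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_model_dict_round_trip(idp_model):
    d = json.loads(json.dumps(model_to_dict(idp_model)))
    model = model_from_dict(d)
    assert model.n_w == idp_model.n_w
    assert model.primary[("CA", "A")].expectation == idp_model.primary[("CA", "A")].expectation
    term_a = model.corrections.lookup("CA", "A", "G", -1)
    term_b = idp_model.corrections.lookup("CA", "A", "G", -1)
    assert term_a == term_b
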