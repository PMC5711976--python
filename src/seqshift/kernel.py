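"""Gaussian-kernel shift statistics.

Per (atom, residue) densities give the primary expectation; pair-conditioned
densities give additive neighbor corrections weighted by the negative overlap
with the primary density; a per-atom normalization factor balances the two.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .database import OFFSETS, offset_column, records_frame
from .residues import nucleus_of

logger = logging.getLogger(__name__)

#: bandwidth floors in ppm, per nucleus (avoid degenerate spikes)
BANDWIDTH_FLOOR = {"1H": 0.02, "13C": 0.05, "15N": 0.05}
#: below this pair count, averaged neighbor corrections are used
N_MIN_PAIR = 20
#: below this sample count, the density mode is used instead of its mean
N_MIN_MEAN = 50
#: search grid for the correction normalization factor
NW_GRID = np.round(np.arange(0.5, 10.0 + 1e-9, 0.1), 10)

CONDITIONS = ("idp", "helix", "strand", "coil")

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# densities


@dataclass
class DensityFunction:
    """A normalized kernel density on a uniform ppm grid."""

    grid: np.ndarray
    density: np.ndarray
    n_obs: int
    bandwidth: float

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0]) if self.grid.size > 1 else self.bandwidth / 4

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def silverman_bandwidth(shifts, nucleus: str | None = None) -> float:
    """Silverman's rule of thumb, floored per nucleus."""
    floor = BANDWIDTH_FLOOR.get(nucleus, min(BANDWIDTH_FLOOR.values()))
    arr = np.asarray(shifts, dtype=float)
    n = arr.size
    if n < 2:
        return floor
    sd = arr.std(ddof=1)
    q75, q25 = np.percentile(arr, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34) if q75 > q25 else sd
    h = 0.9 * spread * n ** (-0.2)
    return max(float(h), floor)


def build_density(shifts, bandwidth: float) -> DensityFunction:
    """Sum of unit-mass Gaussian kernels centered at the observed shifts.

    The grid is uniform with step bandwidth/4, extended 5 bandwidths past the
    sample range; the result is renormalized so its trapezoidal integral is 1.
    """
    arr = np.asarray(shifts, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot build a density from an empty sample")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    lo = arr.min() - 5.0 * bandwidth
    hi = arr.max() + 5.0 * bandwidth
    step = bandwidth / 4.0
    npts = int(np.ceil((hi - lo) / step)) + 1
    grid = lo + step * np.arange(npts)

    density = np.zeros(npts)
    # chunk the sample axis to bound the (grid x sample) workspace
    chunk = max(1, int(2e7) // npts)
    for start in range(0, arr.size, chunk):
        part = arr[start : start + chunk]
        z = (grid[:, None] - part[None, :]) / bandwidth
        density += np.exp(-0.5 * z * z).sum(axis=1)
    density /= arr.size * bandwidth * np.sqrt(2.0 * np.pi)
    norm = np.trapezoid(density, grid)
    density /= norm
    return DensityFunction(grid=grid, density=density, n_obs=int(arr.size), bandwidth=bandwidth)


def density_for(shifts, atom: str | None = None) -> DensityFunction:
    """Convenience: density with a rule-of-thumb bandwidth for the atom's nucleus."""
    nucleus = nucleus_of(atom) if atom else None
    return build_density(shifts, silverman_bandwidth(shifts, nucleus))


def expected_shift(density: DensityFunction, n_min_mean: int = N_MIN_MEAN) -> float:
    """Expectation of a density: weighted mean for rich statistics, mode otherwise.

    Ties in the mode are broken toward lower ppm.
    """
    if density.n_obs >= n_min_mean:
        return float(np.trapezoid(density.grid * density.density, density.grid))
    return float(density.grid[int(np.argmax(density.density))])


def correction_weight(d_primary: DensityFunction, d_pair: DensityFunction) -> float:
    """Negative overlap weight: 1 minus the integral of the pointwise minimum.

    Both densities are resampled by linear interpolation onto the union grid
    (step = the finer of the two); identical densities give exactly 0.
    """
    if d_primary.grid.shape == d_pair.grid.shape and np.array_equal(
        d_primary.grid, d_pair.grid
    ):
        grid, a, b = d_primary.grid, d_primary.density, d_pair.density
    else:
        step = min(d_primary.step, d_pair.step)
        lo = min(d_primary.grid[0], d_pair.grid[0])
        hi = max(d_primary.grid[-1], d_pair.grid[-1])
        npts = int(np.ceil((hi - lo) / step)) + 1
        grid = lo + step * np.arange(npts)
        a = np.interp(grid, d_primary.grid, d_primary.density, left=0.0, right=0.0)
        b = np.interp(grid, d_pair.grid, d_pair.density, left=0.0, right=0.0)
    overlap = float(np.trapezoid(np.minimum(a, b), grid))
    w = 1.0 - overlap
    if abs(w) < 1e-9:
        return 0.0
    return float(min(max(w, 0.0), 1.0))


# ---------------------------------------------------------------------------
# correction table


@dataclass(frozen=True)
class CorrectionTerm:
    ddelta: float
    w: float
    n_pair: int
    averaged: bool


class CorrectionTable:
    """Neighbor corrections per (atom, center, neighbor, offset).

    Pair-specific terms are stored when the pair has at least ``n_min``
    observations; otherwise lookup falls back to the averaged effect of the
    neighbor type at that offset, pooled over all center types.
    """

    def __init__(self, n_min: int = N_MIN_PAIR):
        self.n_min = n_min
        self.pair: dict = {}  # (atom, i, j, offset) -> (ddelta, w)
        self.pair_counts: dict = {}  # (atom, i, j, offset) -> n
        self.averaged: dict = {}  # (atom, j, offset) -> (ddelta, w, n)

    def lookup(self, atom: str, i: str, j: str, offset: int) -> CorrectionTerm:
        key = (atom, i, j, offset)
        n = self.pair_counts.get(key, 0)
        if n >= self.n_min and key in self.pair:
            dd, w = self.pair[key]
            return CorrectionTerm(dd, w, n, False)
        avg = self.averaged.get((atom, j, offset))
        if avg is not None:
            dd, w, _ = avg
            return CorrectionTerm(dd, w, n, True)
        return CorrectionTerm(0.0, 0.0, 0, True)

    def __len__(self):
        return len(self.pair) + len(self.averaged)


@dataclass
class PrimaryStat:
    expectation: float
    n_obs: int
    bandwidth: float
    density: DensityFunction | None = field(default=None, repr=False)


@dataclass
class KernelModel:
    """Trained per-condition shift statistics."""

    condition: str
    ph_bin: float
    primary: dict  # (atom, res_key) -> PrimaryStat
    corrections: CorrectionTable
    n_w: dict  # atom -> float
    atoms: list
    n_min_mean: int = N_MIN_MEAN

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        for (atom, i, _, _) in self.corrections.pair:
            if (atom, i) not in self.primary:
                raise ValueError(f"correction without primary entry: {(atom, i)}")
        for atom, nw in self.n_w.items():
            if nw <= 0:
                raise ValueError(f"N_W for {atom} must be positive")

    def expectation(self, atom: str, res_key: str) -> float | None:
        stat = self.primary.get((atom, res_key))
        return None if stat is None else stat.expectation


# ---------------------------------------------------------------------------
# training


def correction_sums(df: pd.DataFrame, table: CorrectionTable):
    """Per-record weighted correction sum and bookkeeping flags.

    Returns (c, used_averaged, missing_neighbor) arrays where
    c[r] = sum over offsets of w * ddelta for record r.
    """
    n = len(df)
    c = np.zeros(n)
    used_avg = np.zeros(n, dtype=bool)
    missing = np.zeros(n, dtype=bool)
    atoms = df["atom"].to_numpy()
    centers = df["res_key"].to_numpy()
    for offset in OFFSETS:
        col = df[offset_column(offset)].to_numpy()
        for r in range(n):
            j = col[r]
            if j is None:
                missing[r] = True
                continue
            term = table.lookup(atoms[r], centers[r], j, offset)
            c[r] += term.w * term.ddelta
            if term.averaged:
                used_avg[r] = True
    return c, used_avg, missing


def _nw_search(y, p, c, grid=NW_GRID) -> float:
    resid = (y - p)[None, :] - c[None, :] / grid[:, None]
    rmsd = np.sqrt(np.mean(resid * resid, axis=1))
    return float(grid[int(np.argmin(rmsd))])


def calibrate_nw(model: KernelModel, entries, atom: str, grid=NW_GRID) -> float:
    """Grid-search the normalization factor minimizing the prediction RMSD."""
    df = entries if isinstance(entries, pd.DataFrame) else records_frame(entries)
    df = df[df["atom"] == atom]
    df = df[[(atom, k) in model.primary for k in df["res_key"]]]
    if df.empty:
        logger.warning("no data to calibrate N_W for %s; defaulting to 1.0", atom)
        return 1.0
    p = np.array([model.primary[(atom, k)].expectation for k in df["res_key"]])
    c, _, _ = correction_sums(df, model.corrections)
    return _nw_search(df["shift"].to_numpy(), p, c, np.asarray(grid, dtype=float))


def train_kernel_model(
    entries,
    atoms=None,
    condition: str = "idp",
    ph: float = 6.4,
    n_min: int = N_MIN_PAIR,
    n_min_mean: int = N_MIN_MEAN,
    calibrate: bool = True,
    keep_densities: bool = False,
) -> KernelModel:
    """Fit primary densities, neighbor corrections and N_W from assigned shifts."""
    df = entries if isinstance(entries, pd.DataFrame) else records_frame(entries, atoms)
    if df.empty:
        raise ValueError("no training records")
    if atoms is None:
        atoms = sorted(df["atom"].unique())
    else:
        df = df[df["atom"].isin(atoms)]

    # primary densities and expectations per (atom, residue category)
    primary: dict = {}
    for (atom, res_key), grp in df.groupby(["atom", "res_key"], sort=True):
        samples = grp["shift"].to_numpy()
        bw = silverman_bandwidth(samples, nucleus_of(atom))
        dens = build_density(samples, bw)
        primary[(atom, res_key)] = PrimaryStat(
            expectation=expected_shift(dens, n_min_mean),
            n_obs=dens.n_obs,
            bandwidth=bw,
            density=dens,
        )

    expect_map = {k: v.expectation for k, v in primary.items()}
    df = df.assign(
        residual=df["shift"].to_numpy()
        - np.array([expect_map[(a, r)] for a, r in zip(df["atom"], df["res_key"])])
    )

    # pooled recentred density per atom: reference for averaged-correction weights
    pooled: dict = {}
    for atom, grp in df.groupby("atom", sort=True):
        res = grp["residual"].to_numpy()
        pooled[atom] = build_density(res, silverman_bandwidth(res, nucleus_of(atom)))

    table = CorrectionTable(n_min=n_min)

    # averaged terms: effect of neighbor type j at each offset, pooled over centers
    for offset in OFFSETS:
        col = offset_column(offset)
        for (atom, j), grp in df.groupby(["atom", col], sort=True):
            res = grp["residual"].to_numpy()
            dd = float(res.mean())
            d_j = build_density(res, silverman_bandwidth(res, nucleus_of(atom)))
            w = correction_weight(pooled[atom], d_j)
            table.averaged[(atom, j, offset)] = (dd, w, int(res.size))

    # pair-specific terms where statistics allow
    for offset in OFFSETS:
        col = offset_column(offset)
        for (atom, i, j), grp in df.groupby(["atom", "res_key", col], sort=True):
            key = (atom, i, j, offset)
            n = len(grp)
            table.pair_counts[key] = n
            if n < n_min:
                continue
            samples = grp["shift"].to_numpy()
            bw = silverman_bandwidth(samples, nucleus_of(atom))
            dens = build_density(samples, bw)
            dd = expected_shift(dens, n_min_mean) - expect_map[(atom, i)]
            w = correction_weight(primary[(atom, i)].density, dens)
            table.pair[key] = (float(dd), w)

    n_w = {atom: 1.0 for atom in atoms}
    model = KernelModel(
        condition=condition,
        ph_bin=ph,
        primary=primary,
        corrections=table,
        n_w=n_w,
        atoms=list(atoms),
        n_min_mean=n_min_mean,
    )
    if calibrate:
        for atom in atoms:
            sub = df[df["atom"] == atom]
            if sub.empty:
                continue
            p = np.array([expect_map[(atom, k)] for k in sub["res_key"]])
            c, _, _ = correction_sums(sub, table)
            model.n_w[atom] = _nw_search(sub["shift"].to_numpy(), p, c)
    if not keep_densities:
        for stat in primary.values():
            stat.density = None
    return model


def pairwise_correction(model: KernelModel, atom: str, i: str, j: str, offset: int):
    """(ddelta, n_pair, averaged flag) for a neighbor j at a signed offset from i."""
    if (atom, i) not in model.primary:
        raise KeyError(f"no primary statistics for {(atom, i)}")
    term = model.corrections.lookup(atom, i, j, offset)
    return term.ddelta, term.n_pair, term.averaged


# ---------------------------------------------------------------------------
# serialization (JSON; floats round-trip exactly via repr)


def model_to_dict(model: KernelModel) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "kind": "kernel",
        "condition": model.condition,
        "ph_bin": model.ph_bin,
        "atoms": model.atoms,
        "n_min_mean": model.n_min_mean,
        "n_min_pair": model.corrections.n_min,
        "n_w": model.n_w,
        "primary": {
            f"{atom}|{res}": [s.expectation, s.n_obs, s.bandwidth]
            for (atom, res), s in model.primary.items()
        },
        "pair": {
            f"{atom}|{i}|{j}|{off}": list(v) for (atom, i, j, off), v in model.corrections.pair.items()
        },
        "pair_counts": {
            f"{atom}|{i}|{j}|{off}": n
            for (atom, i, j, off), n in model.corrections.pair_counts.items()
        },
        "averaged": {
            f"{atom}|{j}|{off}": list(v) for (atom, j, off), v in model.corrections.averaged.items()
        },
    }


def model_from_dict(d: dict) -> KernelModel:
    if d.get("format_version") != FORMAT_VERSION or d.get("kind") != "kernel":
        raise ValueError("not a kernel model file of a supported version")
    table = CorrectionTable(n_min=d["n_min_pair"])
    for key, (dd, w) in d["pair"].items():
        atom, i, j, off = key.split("|")
        table.pair[(atom, i, j, int(off))] = (dd, w)
    for key, n in d["pair_counts"].items():
        atom, i, j, off = key.split("|")
        table.pair_counts[(atom, i, j, int(off))] = n
    for key, (dd, w, n) in d["averaged"].items():
        atom, j, off = key.split("|")
        table.averaged[(atom, j, int(off))] = (dd, w, n)
    primary = {}
    for key, (e, n, bw) in d["primary"].items():
        atom, res = key.split("|")
        primary[(atom, res)] = PrimaryStat(expectation=e, n_obs=n, bandwidth=bw)
    return KernelModel(
        condition=d["condition"],
        ph_bin=d["ph_bin"],
        primary=primary,
        corrections=table,
        n_w=dict(d["n_w"]),
        atoms=list(d["atoms"]),
        n_min_mean=d["n_min_mean"],
    )


def save_model(model: KernelModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, sort_keys=True)


def load_model(path) -> KernelModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
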