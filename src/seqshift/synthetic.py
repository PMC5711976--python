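"""Synthetic shift databases with known ground truth.

The generator plants per-(residue, atom) base values, additive neighbor
effects over a +-2 window, per-state secondary-structure offsets with linear
boundary ramps, Gaussian observation noise, and optional outliers and
referencing offsets — the exact structure the predictors are built to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .database import Entry, ShiftRecord
from .idp import ABSENT_ATOMS
from .q3 import Q3Segmentation, boundary_context
from .residues import AA1, ResidueState, nucleus_of

DEFAULT_ATOMS = ("C", "CA", "CB", "H", "HA", "N")
DEFAULT_NOISE = {"C": 0.3, "CA": 0.3, "CB": 0.3, "N": 1.0, "H": 0.05, "HA": 0.05}

_BASE_CENTER = {"CA": 58.0, "CB": 33.0, "C": 176.0, "N": 119.0, "H": 8.2, "HA": 4.35}
_BASE_SPREAD = {"CA": 2.5, "CB": 4.0, "C": 1.5, "N": 4.0, "H": 0.4, "HA": 0.3}


def default_base_shifts(atoms=DEFAULT_ATOMS) -> dict:
    """Deterministic per-(residue, atom) base table around realistic centers."""
    rng = np.random.default_rng(20170101)
    table = {}
    for atom in sorted(atoms):
        center = _BASE_CENTER.get(atom, 50.0)
        spread = _BASE_SPREAD.get(atom, 1.0)
        for aa in AA1:
            table[(aa, atom)] = float(center + rng.uniform(-spread, spread))
    return table


@dataclass
class GeneratorConfig:
    n_entries: int = 50
    length_range: tuple = (60, 120)
    atoms: tuple = DEFAULT_ATOMS
    base_shifts: dict = field(default_factory=default_base_shifts)
    neighbor_effects: dict = field(default_factory=dict)  # (atom, j_key, offset) -> ppm
    q3_offsets: dict | None = None  # (atom, state) -> ppm; None = disordered database
    min_segment_len: int = 10
    segment_p: float = 0.18  # geometric tail of segment lengths
    boundary_ramp_len: int = 0  # residues on each side of a boundary that morph
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    outlier_fraction: float = 0.0
    outlier_z: float = 5.0
    ref_offset_entries: int = 0
    ref_offsets: dict = field(default_factory=lambda: {"13C": 2.0, "1H": 0.7, "15N": 4.5})
    ph: float = 6.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_entries < 1:
            raise ValueError("n_entries must be >= 1")
        if self.length_range[0] < 5 or self.length_range[0] > self.length_range[1]:
            raise ValueError("bad length_range")
        for atom in self.atoms:
            if self.noise_sd.get(atom, 0.0) <= 0.0:
                raise ValueError(f"noise SD for {atom} must be positive")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction outside [0,1]")
        if self.q3_offsets is not None and self.boundary_ramp_len > self.min_segment_len:
            raise ValueError("boundary ramp longer than the minimum segment")
        if self.ref_offset_entries > self.n_entries:
            raise ValueError("more referencing-offset entries than entries")


@dataclass
class SyntheticTruth:
    """Noiseless shift for every record plus the planted parameter tables."""

    config: GeneratorConfig
    true_shifts: dict  # (entry_id, res_index, atom) -> ppm
    outlier_keys: set = field(default_factory=set)
    ref_offset_by_entry: dict = field(default_factory=dict)  # entry_id -> {nucleus: ppm}


def _draw_q3(rng, length: int, config: GeneratorConfig) -> str:
    labels = []
    state = str(rng.choice(list("HEC")))
    while len(labels) < length:
        run = config.min_segment_len + int(rng.geometric(config.segment_p)) - 1
        labels.extend(state * run)
        state = str(rng.choice([s for s in "HEC" if s != state]))
    return "".join(labels[:length])


def _q3_term(config: GeneratorConfig, atom: str, labels: str, ctx, pos: int) -> float:
    state = labels[pos]
    offsets = config.q3_offsets
    base = offsets.get((atom, state), 0.0)
    if config.boundary_ramp_len <= 0 or ctx is None or ctx[pos] is None:
        return base
    d, trans = ctx[pos]
    ramp = config.boundary_ramp_len
    if abs(d) > ramp:
        return base
    left, right = trans.split(">")
    off_l = offsets.get((atom, left), 0.0)
    off_r = offsets.get((atom, right), 0.0)
    return off_l + (off_r - off_l) * (d + ramp) / (2.0 * ramp)


def generate(config: GeneratorConfig):
    """Produce (entries, truth), fully deterministic given the config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    entries = []
    truth = SyntheticTruth(config=config, true_shifts={})

    for e in range(config.n_entries):
        entry_id = f"SYN{e:04d}"
        length = int(rng.integers(lo, hi + 1))
        letters = [str(a) for a in rng.choice(list(AA1), size=length)]
        sequence = [ResidueState(a) for a in letters]
        q3 = None
        ctx = None
        if config.q3_offsets is not None:
            q3_str = _draw_q3(rng, length, config)
            q3 = list(q3_str)
            ctx = boundary_context(Q3Segmentation(q3_str))
        records = []
        for pos in range(length):
            key = letters[pos]
            for atom in config.atoms:
                if atom in ABSENT_ATOMS.get(key, ()):
                    continue
                value = config.base_shifts[(key, atom)]
                for off in (-2, -1, 1, 2):
                    q = pos + off
                    if 0 <= q < length:
                        value += config.neighbor_effects.get((atom, letters[q], off), 0.0)
                if config.q3_offsets is not None:
                    value += _q3_term(config, atom, "".join(q3), ctx, pos)
                truth.true_shifts[(entry_id, pos + 1, atom)] = value
                observed = value + rng.normal(0.0, config.noise_sd[atom])
                records.append(
                    ShiftRecord(entry_id, pos + 1, ResidueState(key), atom, observed)
                )
        entries.append(Entry(entry_id, sequence, ph=config.ph, records=records, q3=q3))

    # planted outliers
    if config.outlier_fraction > 0.0:
        all_keys = [
            (ei, ri) for ei, entry in enumerate(entries) for ri in range(len(entry.records))
        ]
        n_out = int(round(config.outlier_fraction * len(all_keys)))
        chosen = rng.choice(len(all_keys), size=n_out, replace=False)
        for flat in sorted(chosen):
            ei, ri = all_keys[flat]
            rec = entries[ei].records[ri]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            bumped = rec.shift + sign * config.outlier_z * config.noise_sd[rec.atom]
            entries[ei].records[ri] = ShiftRecord(
                rec.entry_id, rec.residue_index, rec.residue, rec.atom, bumped
            )
            truth.outlier_keys.add((rec.entry_id, rec.residue_index, rec.atom))

    # planted referencing offsets (constant per nucleus in the chosen entries)
    if config.ref_offset_entries > 0:
        chosen = rng.choice(config.n_entries, size=config.ref_offset_entries, replace=False)
        for ei in sorted(chosen):
            entry = entries[ei]
            truth.ref_offset_by_entry[entry.entry_id] = dict(config.ref_offsets)
            entry.records = [
                ShiftRecord(
                    r.entry_id,
                    r.residue_index,
                    r.residue,
                    r.atom,
                    r.shift + config.ref_offsets.get(nucleus_of(r.atom), 0.0),
                )
                for r in entry.records
            ]

    for entry in entries:
        entry.validate()
    return entries, truth


# ---------------------------------------------------------------------------
# presets (CI-sized)


def _balanced_effects(rng, atoms, noise_sd, per_offset: int = 1) -> dict:
    """Sparse neighbor-effect table: per atom and offset, ``per_offset`` letters
    get +magnitude and as many get -magnitude (zero-mean by construction).

    Effects are sparse and strong (3 noise SDs) so pair-conditioned densities
    separate cleanly from the primary density."""
    effects = {}
    for atom in sorted(atoms):
        mag = 3.0 * noise_sd[atom]
        for off in (-2, -1, 1, 2):
            letters = rng.choice(list(AA1), size=2 * per_offset, replace=False)
            for j in letters[:per_offset]:
                effects[(atom, str(j), off)] = mag
            for j in letters[per_offset:]:
                effects[(atom, str(j), off)] = -mag
    return effects


def idp_preset(seed: int = 0) -> GeneratorConfig:
    """Disordered-database preset: planted neighbor effects, no Q3 structure."""
    rng = np.random.default_rng(seed)
    noise = dict(DEFAULT_NOISE)
    return GeneratorConfig(
        n_entries=50,
        length_range=(60, 120),
        atoms=DEFAULT_ATOMS,
        neighbor_effects=_balanced_effects(rng, DEFAULT_ATOMS, noise),
        q3_offsets=None,
        noise_sd=noise,
        seed=seed,
    )


#: planted per-state offsets (ppm); helix CA is +3.2 by construction
FOLDED_Q3_OFFSETS = {
    ("CA", "H"): 3.2, ("CA", "E"): -1.4, ("CA", "C"): 0.0,
    ("CB", "H"): -0.4, ("CB", "E"): 2.2, ("CB", "C"): 0.0,
    ("C", "H"): 1.9, ("C", "E"): -1.3, ("C", "C"): 0.0,
    ("N", "H"): -0.95, ("N", "E"): 2.5, ("N", "C"): 0.0,
    ("H", "H"): -0.2, ("H", "E"): 0.45, ("H", "C"): 0.0,
    ("HA", "H"): -0.25, ("HA", "E"): 0.4, ("HA", "C"): 0.0,
}


def folded_preset(seed: int = 0) -> GeneratorConfig:
    """Folded-database preset: Q3 offsets with 4-residue boundary ramps."""
    return GeneratorConfig(
        n_entries=60,
        length_range=(80, 140),
        atoms=DEFAULT_ATOMS,
        neighbor_effects={},
        q3_offsets=dict(FOLDED_Q3_OFFSETS),
        min_segment_len=10,
        segment_p=0.18,
        boundary_ramp_len=4,
        noise_sd=dict(DEFAULT_NOISE),
        seed=seed,
    )


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("entry_id\tres_index\tatom\ttrue_shift_ppm\n")
        for (entry_id, res_index, atom), value in truth.true_shifts.items():
            fh.write(f"{entry_id}\t{res_index}\t{atom}\t{value!r}\n")


def variant_config(config: GeneratorConfig, **changes) -> GeneratorConfig:
    """Copy a config with field overrides (convenience over dataclasses.replace)."""
    return replace(config, **changes)
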