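"""Q3-conditioned prediction for folded proteins.

Separate kernel models are trained for helix, strand and coil residues;
residues near a boundary between secondary-structure segments receive an
additive correction that replaces the state's mean secondary shift by the
boundary profile value at their signed distance from the boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .database import records_frame
from .idp import FLAG_BOUNDARY, FLAG_NO_PROFILE, PredictionTable, predict_cells
from .kernel import (
    FORMAT_VERSION,
    KernelModel,
    model_from_dict,
    model_to_dict,
    train_kernel_model,
)

logger = logging.getLogger(__name__)

DEFAULT_HALF_WINDOW = 6

#: 8-state (DSSP) to 3-state merge: helixes together, strands together, rest coil
_MERGE = {
    "H": "H", "G": "H",
    "E": "E",
    "I": "C", "B": "C", "T": "C", "S": "C", "-": "C", "C": "C",
}

STATE_NAME = {"H": "helix", "E": "strand", "C": "coil"}


@dataclass
class Q3Segmentation:
    """Per-residue 3-state labels with the derived constant-label segments."""

    labels: str
    segments: list = field(init=False)  # list[(start, end, label)], 1-based inclusive

    def __post_init__(self):
        bad = sorted({c for c in self.labels if c not in "HEC"})
        if bad:
            raise ValueError(f"labels must be 3-state H/E/C, got {bad}")
        segments = []
        start = 1
        for i in range(1, len(self.labels) + 1):
            if i == len(self.labels) or self.labels[i] != self.labels[i - 1]:
                segments.append((start, i, self.labels[i - 1]))
                start = i + 1
        self.segments = segments

    @property
    def boundaries(self):
        """(position of last residue of the first segment, left label, right label)."""
        return [
            (end, label, self.segments[k + 1][2])
            for k, (start, end, label) in enumerate(self.segments[:-1])
        ]


def merge_to_q3(labels) -> Q3Segmentation:
    """Collapse 8-state (or already 3-state) labels to H/E/C segments."""
    if not isinstance(labels, str):
        labels = "".join(labels)
    merged = []
    for c in labels.upper():
        if c not in _MERGE:
            raise ValueError(f"unknown secondary-structure letter {c!r}")
        merged.append(_MERGE[c])
    return Q3Segmentation("".join(merged))


def parse_ss2(path) -> str:
    """Labels from a psipred .ss2 vertical file (index, residue, state, 3 probs)."""
    labels = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3 or not parts[0].isdigit():
                continue
            labels[int(parts[0])] = parts[2]
    if not labels:
        raise ValueError(f"{path}: no states parsed")
    return "".join(labels[i] for i in sorted(labels))


def parse_q3_tsv(path) -> str:
    """Labels from a 2-column TSV of (res_index, state)."""
    labels = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            idx, state = line.split()[:2]
            labels[int(idx)] = state
    if not labels:
        raise ValueError(f"{path}: no states parsed")
    return "".join(labels[i] for i in sorted(labels))


def boundary_context(labels: str):
    """Nearest-boundary assignment per residue.

    Returns a list of (signed distance, 'L>R' transition key) or None where no
    boundary lies within the chain. Distance -1 is the last residue of the
    earlier segment, +1 the first residue of the later one; ties between two
    equidistant boundaries go to the earlier boundary.
    """
    seg = labels if isinstance(labels, Q3Segmentation) else Q3Segmentation(labels)
    bounds = seg.boundaries
    out = []
    for p in range(1, len(seg.labels) + 1):
        best = None
        for b, left, right in bounds:
            d = p - b - 1 if p <= b else p - b
            if best is None or abs(d) < abs(best[0]):
                best = (d, f"{left}>{right}")
        out.append(best)
    return out


def trim_mask(labels, k: int):
    """Evaluation mask discarding k residues from each end of every Q3 segment."""
    seg = labels if isinstance(labels, Q3Segmentation) else Q3Segmentation(labels)
    mask = [False] * len(seg.labels)
    for start, end, _ in seg.segments:
        for p in range(start + k, end - k + 1):
            mask[p - 1] = True
    return mask


# ---------------------------------------------------------------------------
# training


def train_q3_kernels(
    entries,
    atoms=None,
    exclude_boundary: int = 0,
    ph: float = 6.4,
    **kernel_kwargs,
) -> dict:
    """One kernel model per Q3 state; each record trains only its own state.

    ``exclude_boundary`` drops records within that many residues of a segment
    boundary from the kernel statistics (they are handled by the boundary
    profiles instead).
    """
    df = entries if isinstance(entries, pd.DataFrame) else records_frame(entries, atoms)
    df = df[df["q3"].notna()]
    if df.empty:
        raise ValueError("no Q3-labeled records to train on")
    if exclude_boundary > 0:
        keep = _interior_mask(entries, df, exclude_boundary)
        df = df[keep]
    models = {}
    for state in "HEC":
        sub = df[df["q3"] == state]
        if sub.empty:
            logger.warning("no records for state %s; model absent", state)
            continue
        models[state] = train_kernel_model(
            sub, atoms=atoms, condition=STATE_NAME[state], ph=ph, **kernel_kwargs
        )
    return models


def _interior_mask(entries, df: pd.DataFrame, half_window: int) -> np.ndarray:
    contexts = {
        e.entry_id: boundary_context(Q3Segmentation("".join(e.q3)))
        for e in entries
        if e.q3 is not None
    }
    keep = np.ones(len(df), dtype=bool)
    for r, (eid, idx) in enumerate(zip(df["entry_id"], df["res_index"])):
        ctx = contexts.get(eid)
        if ctx is None:
            continue
        best = ctx[idx - 1]
        if best is not None and abs(best[0]) <= half_window:
            keep[r] = False
    return keep


@dataclass
class BoundaryProfile:
    """Mean/SD of secondary shifts by transition type, atom and boundary distance."""

    half_window: int
    cells: dict = field(default_factory=dict)  # (trans, atom, d) -> (mean, sd, n)
    state_means: dict = field(default_factory=dict)  # (atom, state) -> mean secondary shift

    def cell(self, trans: str, atom: str, d: int):
        return self.cells.get((trans, atom, d))


def build_boundary_profiles(
    entries, coil_model: KernelModel, half_window: int = DEFAULT_HALF_WINDOW, atoms=None
) -> BoundaryProfile:
    """Profile of secondary shifts (observed minus coil expectation) around boundaries.

    Also accumulates the per-(atom, state) mean secondary shift over interior
    residues (no boundary within the half window), used as the baseline that a
    boundary correction replaces.
    """
    cells: dict = {}
    interior: dict = {}
    for entry in entries:
        if entry.q3 is None:
            continue
        ctx = boundary_context(Q3Segmentation("".join(entry.q3)))
        for rec in entry.records:
            if atoms is not None and rec.atom not in atoms:
                continue
            coil = coil_model.expectation(rec.atom, rec.residue.key)
            if coil is None:
                continue
            sec = rec.shift - coil
            best = ctx[rec.residue_index - 1]
            state = entry.q3[rec.residue_index - 1]
            if best is not None and abs(best[0]) <= half_window:
                d, trans = best
                cells.setdefault((trans, rec.atom, d), []).append(sec)
            else:
                interior.setdefault((rec.atom, state), []).append(sec)
    profile = BoundaryProfile(half_window=half_window)
    for key, vals in cells.items():
        arr = np.asarray(vals)
        profile.cells[key] = (
            float(arr.mean()),
            float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            int(arr.size),
        )
    for key, vals in interior.items():
        profile.state_means[key] = float(np.mean(vals))
    return profile


# ---------------------------------------------------------------------------
# prediction


def predict_folded(
    sequence,
    q3,
    models: dict,
    profiles: BoundaryProfile | None = None,
    atoms=None,
) -> PredictionTable:
    """Per-residue prediction from the model of each residue's Q3 state.

    Residues within the profile half-window of a boundary get the boundary
    correction: profile mean minus the state's interior mean secondary shift.
    """
    seg = q3 if isinstance(q3, Q3Segmentation) else merge_to_q3(q3)
    if len(seg.labels) != len(sequence):
        raise ValueError("Q3 labels and sequence differ in length")
    if "C" not in models and not models:
        raise ValueError("no trained state models")
    keys = [None if r is None else r.key for r in sequence]

    extra: dict = {}
    if profiles is not None:
        ctx = boundary_context(seg)
        atom_list = atoms or sorted({a for m in models.values() for a in m.atoms})
        for pos, best in enumerate(ctx, start=1):
            if best is None or abs(best[0]) > profiles.half_window:
                continue
            d, trans = best
            state = seg.labels[pos - 1]
            for atom in atom_list:
                cell = profiles.cell(trans, atom, d)
                if cell is None:
                    extra[(pos, atom)] = (0.0, FLAG_NO_PROFILE)
                    continue
                baseline = profiles.state_means.get((atom, state), 0.0)
                extra[(pos, atom)] = (cell[0] - baseline, FLAG_BOUNDARY)

    parts = []
    for state in sorted(set(seg.labels)):
        model = models.get(state)
        if model is None:
            model = models.get("C")
            if model is None:
                raise ValueError(f"no model for state {state} and no coil fallback")
            logger.warning("no model for state %s; falling back to coil", state)
        table = predict_cells(keys, model, atoms, extra=extra if profiles else None)
        sel = [seg.labels[i - 1] == state for i in table.df["res_index"]]
        parts.append(table.df[sel])
    df = pd.concat(parts, ignore_index=True).sort_values(["res_index", "atom"])
    return PredictionTable(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# folded-bundle serialization


def folded_bundle_to_dict(models: dict, profiles: BoundaryProfile | None, nn: dict | None = None):
    from . import nn as nn_mod

    return {
        "format_version": FORMAT_VERSION,
        "kind": "folded",
        "models": {state: model_to_dict(m) for state, m in models.items()},
        "profiles": None
        if profiles is None
        else {
            "half_window": profiles.half_window,
            "cells": {f"{t}|{a}|{d}": list(v) for (t, a, d), v in profiles.cells.items()},
            "state_means": {f"{a}|{s}": v for (a, s), v in profiles.state_means.items()},
        },
        "nn": None if nn is None else {atom: nn_mod.nn_to_dict(m) for atom, m in nn.items()},
    }


def folded_bundle_from_dict(d: dict):
    from . import nn as nn_mod

    if d.get("format_version") != FORMAT_VERSION or d.get("kind") != "folded":
        raise ValueError("not a folded model file of a supported version")
    models = {state: model_from_dict(md) for state, md in d["models"].items()}
    profiles = None
    if d.get("profiles") is not None:
        profiles = BoundaryProfile(half_window=d["profiles"]["half_window"])
        for key, v in d["profiles"]["cells"].items():
            t, a, dist = key.rsplit("|", 2)
            profiles.cells[(t, a, int(dist))] = tuple(v)
        for key, v in d["profiles"]["state_means"].items():
            a, s = key.split("|")
            profiles.state_means[(a, s)] = v
    nn = None
    if d.get("nn") is not None:
        nn = {atom: nn_mod.nn_from_dict(md) for atom, md in d["nn"].items()}
    return models, profiles, nn


def save_folded_bundle(path, models, profiles=None, nn=None) -> None:
    with open(path, "w") as fh:
        json.dump(folded_bundle_to_dict(models, profiles, nn), fh, sort_keys=True)


def load_folded_bundle(path):
    with open(path) as fh:
        return folded_bundle_from_dict(json.load(fh))
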