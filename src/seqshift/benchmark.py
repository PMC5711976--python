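"""RMSD scoring and the leave-one-out evaluation protocol."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


def rmsd(experimental, calculated=None) -> float:
    """Root mean square deviation between experimental and calculated shifts.

    Accepts either two arrays or a single iterable of (experimental,
    calculated) pairs.
    """
    if calculated is None:
        pairs = np.asarray(list(experimental), dtype=float)
        if pairs.size == 0:
            raise ValueError("rmsd of an empty set")
        exp, calc = pairs[:, 0], pairs[:, 1]
    else:
        exp = np.asarray(experimental, dtype=float)
        calc = np.asarray(calculated, dtype=float)
        if exp.size == 0:
            raise ValueError("rmsd of an empty set")
    diff = exp - calc
    return float(np.sqrt(np.mean(diff * diff)))


@dataclass
class BenchmarkResult:
    per_atom: dict  # atom -> (rmsd, n)
    per_entry: dict  # entry_id -> rmsd
    metadata: dict = field(default_factory=dict)

    def pooled_rmsd(self) -> float:
        total, n = 0.0, 0
        for r, m in self.per_atom.values():
            total += r * r * m
            n += m
        if n == 0:
            raise ValueError("no residuals pooled")
        return float(np.sqrt(total / n))


def _training_checksum(entries) -> str:
    return hashlib.sha256("|".join(sorted(e.entry_id for e in entries)).encode()).hexdigest()


def collect_residuals(entry, predictions: dict, mask=None):
    """(atom, residual) pairs matching an entry's records against a prediction map.

    ``predictions`` maps (res_index, atom) to the calculated shift; ``mask``
    optionally restricts evaluation to a set of residue indices.
    """
    out = []
    for rec in entry.records:
        if mask is not None and rec.residue_index not in mask:
            continue
        calc = predictions.get((rec.residue_index, rec.atom))
        if calc is None:
            continue
        out.append((rec.atom, rec.shift - calc))
    return out


def leave_one_out(entries, train_fn, predict_fn, mask_fn=None) -> BenchmarkResult:
    """Retrain with each entry held out, predict it, and pool residuals per atom.

    ``train_fn(training_entries) -> model``;
    ``predict_fn(model, entry) -> {(res_index, atom): shift}``;
    ``mask_fn(entry) -> set of residue indices`` (optional evaluation mask).
    """
    if len(entries) < 2:
        raise ValueError("leave-one-out needs at least 2 entries")
    residuals: dict = {}
    per_entry: dict = {}
    checksums = {}
    skipped = []
    for k, held_out in enumerate(entries):
        training = entries[:k] + entries[k + 1 :]
        assert all(e.entry_id != held_out.entry_id for e in training)
        checksums[held_out.entry_id] = _training_checksum(training)
        try:
            model = train_fn(training)
        except Exception as exc:  # noqa: BLE001 - a failed fold is recorded, not fatal
            logger.warning("fold %s failed to retrain: %s", held_out.entry_id, exc)
            skipped.append(held_out.entry_id)
            continue
        predictions = predict_fn(model, held_out)
        mask = mask_fn(held_out) if mask_fn is not None else None
        pairs = collect_residuals(held_out, predictions, mask)
        if pairs:
            per_entry[held_out.entry_id] = float(
                np.sqrt(np.mean([d * d for _, d in pairs]))
            )
        for atom, diff in pairs:
            residuals.setdefault(atom, []).append(diff)
    per_atom = {
        atom: (float(np.sqrt(np.mean(np.square(ds)))), len(ds))
        for atom, ds in sorted(residuals.items())
    }
    return BenchmarkResult(
        per_atom=per_atom,
        per_entry=per_entry,
        metadata={
            "protocol": "leave-one-out",
            "fold_checksums": checksums,
            "skipped_folds": skipped,
        },
    )


def evaluate(test_entries, predict_fn, mask_fn=None) -> BenchmarkResult:
    """Score a fixed predictor on held-out entries (no retraining)."""
    residuals: dict = {}
    per_entry: dict = {}
    for entry in test_entries:
        predictions = predict_fn(entry)
        mask = mask_fn(entry) if mask_fn is not None else None
        pairs = collect_residuals(entry, predictions, mask)
        if pairs:
            per_entry[entry.entry_id] = float(np.sqrt(np.mean([d * d for _, d in pairs])))
        for atom, diff in pairs:
            residuals.setdefault(atom, []).append(diff)
    per_atom = {
        atom: (float(np.sqrt(np.mean(np.square(ds)))), len(ds))
        for atom, ds in sorted(residuals.items())
    }
    return BenchmarkResult(per_atom=per_atom, per_entry=per_entry, metadata={"protocol": "held-out"})
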