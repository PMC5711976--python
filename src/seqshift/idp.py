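"""Per-residue shift prediction for disordered sequences: primary expectation
plus overlap-weighted neighbor corrections scaled by 1/N_W."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .database import OFFSETS, read_fasta
from .kernel import KernelModel
from .residues import ResidueState

logger = logging.getLogger(__name__)

# flag letters used in prediction tables
FLAG_AVERAGED = "A"  # at least one correction used the averaged fallback
FLAG_TERMINUS = "T"  # at least one neighbor absent (chain end / unknown residue)
FLAG_BOUNDARY = "B"  # boundary-profile correction applied (folded mode)
FLAG_NO_PROFILE = "X"  # boundary cell missing from the profile

#: backbone atoms chemically absent for a residue type
ABSENT_ATOMS = {"P": {"H"}, "P_cis": {"H"}, "G": {"CB"}}


@dataclass
class PredictionTable:
    """Predicted shifts per (residue index, atom); predicted = primary + correction."""

    df: pd.DataFrame  # columns: res_index, res, atom, shift, primary, correction, flags

    def get(self, res_index: int, atom: str) -> float | None:
        sel = self.df[(self.df.res_index == res_index) & (self.df.atom == atom)]
        return None if sel.empty else float(sel["shift"].iloc[0])

    def as_mapping(self) -> dict:
        return {
            (int(r.res_index), r.atom): float(r.shift) for r in self.df.itertuples(index=False)
        }

    def to_tsv(self, path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("res_index\tres\tatom\tshift_ppm\tprimary\tcorrection\tflags\n")
            for r in self.df.itertuples(index=False):
                fh.write(
                    f"{r.res_index}\t{r.res}\t{r.atom}\t{r.shift:.4f}\t"
                    f"{r.primary:.4f}\t{r.correction:.4f}\t{r.flags}\n"
                )

    def to_talos(self, path, sequence) -> None:
        """TALOS-style shift table (DATA SEQUENCE / VARS / FORMAT header)."""
        seq_str = "".join(r.aa if r is not None else "X" for r in sequence)
        with open(path, "w") as fh:
            for start in range(0, len(seq_str), 50):
                fh.write(f"DATA SEQUENCE {seq_str[start:start + 50]}\n")
            fh.write("\nVARS RESID RESNAME ATOMNAME SHIFT\n")
            fh.write("FORMAT %4d %1s %4s %8.3f\n\n")
            for r in self.df.itertuples(index=False):
                aa = ResidueState.from_key(r.res).aa
                fh.write(f"{r.res_index:4d} {aa} {r.atom:>4s} {r.shift:8.3f}\n")


def _atom_applicable(atom: str, res_key: str) -> bool:
    return atom not in ABSENT_ATOMS.get(res_key, ())


def predict_cells(seq_keys, model: KernelModel, atoms=None, extra=None) -> PredictionTable:
    """Assemble the prediction table for a sequence of residue-category keys.

    ``seq_keys`` may contain ``None`` for unknown positions (skipped as centers,
    absent as neighbors). ``extra`` optionally maps (res_index, atom) to an
    additional (correction ppm, flag string) contribution.
    """
    atoms = list(atoms) if atoms is not None else model.atoms
    n = len(seq_keys)
    rows = []
    for pos in range(n):
        key = seq_keys[pos]
        if key is None:
            continue
        for atom in atoms:
            if not _atom_applicable(atom, key):
                continue
            stat = model.primary.get((atom, key))
            if stat is None:
                logger.warning("no statistics for (%s, %s); cell omitted", atom, key)
                continue
            total = 0.0
            flags = set()
            for offset in OFFSETS:
                q = pos + offset
                j = seq_keys[q] if 0 <= q < n else None
                if j is None:
                    flags.add(FLAG_TERMINUS)
                    continue
                term = model.corrections.lookup(atom, key, j, offset)
                total += term.w * term.ddelta
                if term.averaged:
                    flags.add(FLAG_AVERAGED)
            correction = total / model.n_w[atom]
            if extra is not None:
                add, add_flags = extra.get((pos + 1, atom), (0.0, ""))
                correction += add
                flags.update(add_flags)
            rows.append(
                {
                    "res_index": pos + 1,
                    "res": key,
                    "atom": atom,
                    "shift": stat.expectation + correction,
                    "primary": stat.expectation,
                    "correction": correction,
                    "flags": "".join(sorted(flags)),
                }
            )
    return PredictionTable(
        pd.DataFrame(
            rows, columns=["res_index", "res", "atom", "shift", "primary", "correction", "flags"]
        )
    )


def predict_idp(sequence, model: KernelModel, atoms=None) -> PredictionTable:
    """Predict disordered-state shifts for a sequence of ResidueStates."""
    if len(sequence) < 1:
        raise ValueError("sequence must contain at least one residue")
    keys = [None if r is None else r.key for r in sequence]
    return predict_cells(keys, model, atoms)


def read_variant_overrides(path) -> dict:
    """Sidecar file of per-position variants: lines of '<res_index> <variant>'."""
    overrides = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected '<index> <variant>'")
            overrides[int(parts[0])] = parts[1]
    return overrides


def sequence_from_string(seq: str, variants: dict | None = None):
    """Build ResidueStates from a one-letter string plus optional variant overrides."""
    states = []
    for i, aa in enumerate(seq, start=1):
        variant = (variants or {}).get(i, "none")
        states.append(ResidueState(aa, variant))
    return states


def predict_from_fasta(path, model: KernelModel, atoms=None, variants: dict | None = None):
    """Predict every record of a FASTA file; returns {record_id: PredictionTable}."""
    out = {}
    for rec_id, seq in read_fasta(path):
        sequence = sequence_from_string(seq, variants)
        out[rec_id] = predict_idp(sequence, model, atoms)
    return out
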