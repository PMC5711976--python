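"""Shift-database model and curation: parsing, identity clustering, referencing QC
and outlier removal."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .residues import ResidueState, nucleus_of, THREE_TO_ONE, VARIANT_NONE

logger = logging.getLogger(__name__)

DEFAULT_PH = 6.4
#: referencing tolerances (ppm) per nucleus
DEFAULT_TOLERANCES = {"13C": 1.5, "1H": 0.5, "15N": 3.5}
DEFAULT_Z_MAX = 3.5

Q3_STATES = ("H", "E", "C")

TSV_COLUMNS = ["entry_id", "res_index", "res_letter", "variant", "atom", "shift_ppm", "ph", "q3"]


@dataclass(frozen=True)
class ShiftRecord:
    """One assigned chemical-shift observation."""

    entry_id: str
    residue_index: int  # 1-based
    residue: ResidueState
    atom: str
    shift: float

    def __post_init__(self):
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        if not np.isfinite(self.shift):
            raise ValueError("shift must be finite")


@dataclass
class Entry:
    """One protein entry: sequence, conditions and its shift observations.

    ``sequence[i]`` may be ``None`` when the residue type at position ``i+1``
    is unknown (no observation mentions it); such positions contribute no
    neighbor information.
    """

    entry_id: str
    sequence: list  # list[ResidueState | None]
    ph: float = DEFAULT_PH
    records: list = field(default_factory=list)
    q3: list | None = None  # per-residue labels in {H, E, C}, or None

    def validate(self) -> None:
        n = len(self.sequence)
        if self.q3 is not None and len(self.q3) != n:
            raise ValueError(f"entry {self.entry_id}: q3 length != sequence length")
        for rec in self.records:
            if rec.residue_index > n:
                raise ValueError(
                    f"entry {self.entry_id}: record index {rec.residue_index} outside sequence"
                )
            seq_res = self.sequence[rec.residue_index - 1]
            if seq_res is not None and seq_res != rec.residue:
                raise ValueError(
                    f"entry {self.entry_id}: residue mismatch at index {rec.residue_index}"
                )

    @property
    def sequence_str(self) -> str:
        return "".join("X" if r is None else r.aa for r in self.sequence)

    def n_records(self) -> int:
        return len(self.records)


@dataclass
class CurationReport:
    entries_in: int
    entries_out: int
    removed_entries: list  # list[(entry_id, reason)]
    removed_values: int
    removed_values_fraction: float

    def __post_init__(self):
        if self.entries_out + len(self.removed_entries) != self.entries_in:
            raise ValueError("curation bookkeeping does not balance")
        if not 0.0 <= self.removed_values_fraction <= 1.0:
            raise ValueError("removed_values_fraction outside [0,1]")


# ---------------------------------------------------------------------------
# parsing


def _parse_tsv(path) -> list[Entry]:
    blocks: dict[str, dict] = {}
    closed: set[str] = set()
    current = None
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in TSV_COLUMNS[:6] if c not in header]
                if missing:
                    raise ValueError(f"{path}: line {lineno}: missing columns {missing}")
                idx = {c: header.index(c) for c in header}
                continue
            try:
                entry_id = fields[idx["entry_id"]]
                res_index = int(fields[idx["res_index"]])
                letter = fields[idx["res_letter"]]
                variant = fields[idx["variant"]] if "variant" in idx else VARIANT_NONE
                atom = fields[idx["atom"]]
                shift = float(fields[idx["shift_ppm"]])
                ph = float(fields[idx["ph"]]) if "ph" in idx and fields[idx["ph"]] else DEFAULT_PH
                q3 = fields[idx["q3"]] if "q3" in idx and len(fields) > idx["q3"] else ""
                residue = ResidueState(letter, variant or VARIANT_NONE)
                rec = ShiftRecord(entry_id, res_index, residue, atom, shift)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row ({exc})") from exc

            if entry_id != current:
                if entry_id in closed:
                    raise ValueError(f"{path}: duplicate entry_id {entry_id!r}")
                if current is not None:
                    closed.add(current)
                current = entry_id
                blocks.setdefault(entry_id, {"ph": ph, "records": [], "seq": {}, "q3": {}})
            block = blocks[entry_id]
            block["records"].append(rec)
            prev = block["seq"].get(res_index)
            if prev is not None and prev != residue:
                raise ValueError(
                    f"{path}: line {lineno}: entry {entry_id} residue letter at index "
                    f"{res_index} disagrees with earlier rows"
                )
            block["seq"][res_index] = residue
            if q3:
                if q3 not in Q3_STATES:
                    raise ValueError(f"{path}: line {lineno}: bad q3 label {q3!r}")
                block["q3"][res_index] = q3

    entries = []
    for entry_id, block in blocks.items():
        n = max(block["seq"])
        sequence = [block["seq"].get(i) for i in range(1, n + 1)]
        q3 = None
        if block["q3"]:
            q3 = [block["q3"].get(i, "C") for i in range(1, n + 1)]
        entry = Entry(entry_id, sequence, ph=block["ph"], records=block["records"], q3=q3)
        entry.validate()
        entries.append(entry)
    if not entries:
        raise ValueError(f"{path}: no entries parsed")
    return entries


def _parse_nmrstar_lite(path) -> list[Entry]:
    """Minimal NMR-STAR loop reader for Atom_chem_shift tables.

    Understands ``loop_`` blocks whose tags start with ``_Atom_chem_shift.``;
    everything else is skipped. Required tags: Seq_ID, Comp_ID, Atom_ID, Val.
    Entry_ID is taken from the tag if present, else from ``data_`` blocks.
    """
    rows = []
    data_name = "entry"
    with open(path) as fh:
        lines = iter(enumerate(fh, start=1))
        for lineno, line in lines:
            s = line.strip()
            if s.startswith("data_"):
                data_name = s[5:] or data_name
            if s != "loop_":
                continue
            tags = []
            for lineno, line in lines:
                s = line.strip()
                if s.startswith("_"):
                    tags.append(s.split()[0])
                else:
                    break
            else:
                break
            if not tags or not tags[0].startswith("_Atom_chem_shift."):
                continue
            names = [t.split(".", 1)[1] for t in tags]
            # first data line already read into `s`
            while s and s not in ("stop_",) and not s.startswith(("loop_", "data_", "#")):
                vals = s.split()
                if len(vals) == len(names):
                    rows.append((dict(zip(names, vals)), data_name, lineno))
                try:
                    lineno, line = next(lines)
                except StopIteration:
                    break
                s = line.strip()

    entries: dict[str, dict] = {}
    for row, data_name, lineno in rows:
        try:
            entry_id = row.get("Entry_ID", data_name)
            res_index = int(row["Seq_ID"])
            comp = row["Comp_ID"].upper()
            letter = THREE_TO_ONE.get(comp, comp if comp in THREE_TO_ONE.values() else None)
            if letter is None:
                raise ValueError(f"unknown residue {comp!r}")
            atom = row["Atom_ID"]
            shift = float(row["Val"])
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: line {lineno}: malformed shift row ({exc})") from exc
        residue = ResidueState(letter)
        block = entries.setdefault(entry_id, {"records": [], "seq": {}})
        block["records"].append(ShiftRecord(entry_id, res_index, residue, atom, shift))
        block["seq"][res_index] = residue

    out = []
    for entry_id, block in entries.items():
        n = max(block["seq"])
        sequence = [block["seq"].get(i) for i in range(1, n + 1)]
        entry = Entry(entry_id, sequence, records=block["records"])
        entry.validate()
        out.append(entry)
    if not out:
        raise ValueError(f"{path}: no entries parsed")
    return out


def read_entries(path, format: str = "tsv") -> list[Entry]:
    """Read a shift database from ``tsv`` or ``nmrstar_lite`` format."""
    if format == "tsv":
        return _parse_tsv(path)
    if format == "nmrstar_lite":
        return _parse_nmrstar_lite(path)
    raise ValueError(f"unknown format {format!r}")


def write_entries_tsv(entries, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for entry in entries:
            for rec in entry.records:
                q3 = ""
                if entry.q3 is not None:
                    q3 = entry.q3[rec.residue_index - 1]
                fh.write(
                    f"{entry.entry_id}\t{rec.residue_index}\t{rec.residue.aa}\t"
                    f"{rec.residue.variant}\t{rec.atom}\t{rec.shift!r}\t{entry.ph!r}\t{q3}\n"
                )


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs; sequences must use the 20 standard letters."""
    from Bio import SeqIO

    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = sorted({c for c in seq if c not in "ACDEFGHIKLMNPQRSTVWY"})
        if bad:
            raise ValueError(f"record {record.id!r}: non-amino-acid letters {bad}")
        out.append((record.id, seq))
    if not out:
        raise ValueError(f"{path}: empty FASTA")
    return out


# ---------------------------------------------------------------------------
# identity clustering


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Needleman-Wunsch with match=1, mismatch=0, gap=-1 (alignment only; the
    score does not enter the identity).
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_by_identity(entries, max_identity: float = 0.9):
    """Greedy representative selection at a pairwise-identity ceiling.

    Entries are visited by descending record count (ties by entry_id); an
    entry is kept iff its identity to every already-kept entry is
    <= ``max_identity``.
    """
    if not entries:
        raise ValueError("no entries to cluster")
    if not 0.0 < max_identity < 1.0:
        raise ValueError("max_identity must be in (0, 1)")
    order = sorted(entries, key=lambda e: (-e.n_records(), e.entry_id))
    kept: list[Entry] = []
    removed: list[tuple[str, str]] = []
    for entry in order:
        seq = entry.sequence_str
        for rep in kept:
            if pairwise_identity(seq, rep.sequence_str) > max_identity:
                removed.append((entry.entry_id, "identity"))
                break
        else:
            kept.append(entry)
    return kept, removed


# ---------------------------------------------------------------------------
# reference statistics, referencing QC, outlier removal


def reference_stats(entries, min_n: int = 2):
    """Per-category centers and SDs from the collection itself.

    Categories are (atom, residue key, q3 label) when the entry carries Q3
    labels, else (atom, residue key, None). Lookup falls back from the labeled
    to the unlabeled key.
    """
    samples: dict[tuple, list] = {}
    for entry in entries:
        for rec in entry.records:
            q3 = entry.q3[rec.residue_index - 1] if entry.q3 is not None else None
            samples.setdefault((rec.atom, rec.residue.key, q3), []).append(rec.shift)
            if q3 is not None:
                samples.setdefault((rec.atom, rec.residue.key, None), []).append(rec.shift)
    centers, sds = {}, {}
    for key, vals in samples.items():
        if len(vals) < min_n:
            continue
        arr = np.asarray(vals)
        centers[key] = float(arr.mean())
        sds[key] = float(arr.std(ddof=1))
    return centers, sds


def _lookup_center(centers, rec: ShiftRecord, q3):
    key = (rec.atom, rec.residue.key, q3)
    if key in centers:
        return centers[key], key
    key = (rec.atom, rec.residue.key, None)
    if key in centers:
        return centers[key], key
    return None, None


@dataclass
class QCResult:
    entry_id: str
    passed: bool
    offsets: dict  # nucleus -> mean(observed - expected center)
    skipped: list  # nuclei with no usable records


def referencing_qc(entry: Entry, centers, tolerances=None) -> QCResult:
    """Per-nucleus referencing check against expected distribution centers."""
    tolerances = tolerances or DEFAULT_TOLERANCES
    residuals: dict[str, list] = {}
    for rec in entry.records:
        q3 = entry.q3[rec.residue_index - 1] if entry.q3 is not None else None
        center, _ = _lookup_center(centers, rec, q3)
        if center is None:
            continue
        residuals.setdefault(nucleus_of(rec.atom), []).append(rec.shift - center)
    offsets, skipped = {}, []
    passed = True
    for nucleus, tol in tolerances.items():
        if nucleus not in residuals:
            skipped.append(nucleus)
            continue
        offset = float(np.mean(residuals[nucleus]))
        offsets[nucleus] = offset
        if abs(offset) > tol:
            passed = False
    return QCResult(entry.entry_id, passed, offsets, skipped)


def remove_outlier_values(entries, centers, sds, z_max: float = DEFAULT_Z_MAX):
    """Drop individual shifts more than ``z_max`` SDs from their category center."""
    if z_max <= 0:
        raise ValueError("z_max must be positive")
    removed = 0
    out = []
    for entry in entries:
        kept_records = []
        for rec in entry.records:
            q3 = entry.q3[rec.residue_index - 1] if entry.q3 is not None else None
            center, key = _lookup_center(centers, rec, q3)
            if center is None:
                kept_records.append(rec)
                continue
            sd = sds.get(key, 0.0)
            if sd == 0.0:
                logger.debug("zero SD for %s, outlier check skipped", key)
                kept_records.append(rec)
                continue
            if abs(rec.shift - center) / sd > z_max:
                removed += 1
            else:
                kept_records.append(rec)
        out.append(
            Entry(entry.entry_id, entry.sequence, ph=entry.ph, records=kept_records, q3=entry.q3)
        )
    return out, removed


def curate(entries, max_identity: float = 0.9, tolerances=None, z_max: float = DEFAULT_Z_MAX):
    """Full curation pipeline: identity clustering, referencing QC, outlier removal."""
    n_in = len(entries)
    n_values_in = sum(e.n_records() for e in entries)
    kept, removed_entries = cluster_by_identity(entries, max_identity)
    centers, sds = reference_stats(kept)
    surviving = []
    for entry in kept:
        qc = referencing_qc(entry, centers, tolerances)
        if qc.passed:
            surviving.append(entry)
        else:
            removed_entries.append((entry.entry_id, "referencing"))
    centers, sds = reference_stats(surviving)
    surviving, removed_values = remove_outlier_values(surviving, centers, sds, z_max)
    report = CurationReport(
        entries_in=n_in,
        entries_out=len(surviving),
        removed_entries=removed_entries,
        removed_values=removed_values,
        removed_values_fraction=removed_values / n_values_in if n_values_in else 0.0,
    )
    return surviving, report


def ph_bin(ph: float) -> float:
    """Nearest calibrated pH parameterization: 2.8 for acidic, else 6.4."""
    return 2.8 if ph <= 4.5 else 6.4


# ---------------------------------------------------------------------------
# tabular view used by model training

OFFSETS = (-2, -1, 1, 2)
_OFFSET_COL = {-2: "j_m2", -1: "j_m1", 1: "j_p1", 2: "j_p2"}


def offset_column(offset: int) -> str:
    return _OFFSET_COL[offset]


def records_frame(entries, atoms=None) -> pd.DataFrame:
    """Flatten entries into a DataFrame with neighbor-category columns.

    Columns: entry_id, res_index, res_key, atom, shift, q3 (may be None),
    j_m2/j_m1/j_p1/j_p2 (neighbor residue keys, None past the termini or at
    unknown positions).
    """
    rows = []
    for entry in entries:
        keys = [None if r is None else r.key for r in entry.sequence]
        n = len(keys)
        for rec in entry.records:
            if atoms is not None and rec.atom not in atoms:
                continue
            i = rec.residue_index - 1
            q3 = entry.q3[i] if entry.q3 is not None else None
            neighbors = {
                col: (keys[i + off] if 0 <= i + off < n else None)
                for off, col in _OFFSET_COL.items()
            }
            rows.append(
                {
                    "entry_id": entry.entry_id,
                    "res_index": rec.residue_index,
                    "res_key": rec.residue.key,
                    "atom": rec.atom,
                    "shift": rec.shift,
                    "q3": q3,
                    **neighbors,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["entry_id", "res_index", "res_key", "atom", "shift", "q3", *_OFFSET_COL.values()],
    )
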