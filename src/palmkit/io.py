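"""Shared domain records and file I/O.

The pipeline touches a small number of plain-text formats: multi-record
FASTA for protein sequences, a two-column TSV mapping sequence ids to
binder/non-binder labels, TSV tables of densitometry bands and imaging
counts, newick trees, and JSON reports.  Everything written here is
byte-stable: identical inputs and configuration produce identical output
bytes (keys sorted, fixed float formatting, trailing newline).
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("palmkit")

#: Amino-acid letters accepted in sequences.  The 20 standard residues plus
#: the ambiguity/rare codes X, B, Z and U, all treated as literal symbols
#: that match only themselves.
AMINO_ACID_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU")

#: Recognised class labels for a sequence in a labeled set.
VALID_LABELS = ("binder", "nonbinder", "excluded")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence keyed by a stable accession-style id."""

    id: str
    sequence: str
    name: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - AMINO_ACID_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid sequence characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabeledSequenceSet:
    """Protein records partitioned into binders, non-binders and excluded.

    Excluded records are dropped from both classes before any motif search
    (e.g. a user choosing to set aside poorly expressed family members).
    At least one binder and one non-binder are required, and every record
    must carry a label.
    """

    records: tuple[ProteinRecord, ...]
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "labels", dict(self.labels))
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")
        id_set = set(ids)
        for key, lab in self.labels.items():
            if key not in id_set:
                raise ValueError(f"label for unknown id {key!r}")
            if lab not in VALID_LABELS:
                raise ValueError(
                    f"unknown label {lab!r} for id {key!r}; "
                    f"expected one of {VALID_LABELS}"
                )
        missing = id_set - set(self.labels)
        if missing:
            raise ValueError(f"records without a label: {sorted(missing)}")
        if not self.binders:
            raise ValueError("labeled set has no binder records")
        if not self.nonbinders:
            raise ValueError("labeled set has no nonbinder records")

    @property
    def binders(self) -> tuple[ProteinRecord, ...]:
        return tuple(r for r in self.records if self.labels[r.id] == "binder")

    @property
    def nonbinders(self) -> tuple[ProteinRecord, ...]:
        return tuple(r for r in self.records if self.labels[r.id] == "nonbinder")

    @property
    def excluded(self) -> tuple[ProteinRecord, ...]:
        return tuple(r for r in self.records if self.labels[r.id] == "excluded")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters shared across pipeline stages.

    ``alignment_mode`` selects Needleman-Wunsch-style global or
    Smith-Waterman-style local alignment; the substitution/gap scheme
    defaults to BLOSUM62 with affine gaps costing ``gap_open + gap_extend *
    L`` for a length-L gap (blastp's 11/1 defaults).  ``identity_convention``
    chooses the denominator for percent identity: aligned columns
    (``"columns"``, the NCBI convention) or the shorter input sequence
    (``"shorter"``).  ``floor`` is the value assigned to bait-normalized
    co-IP recoveries at or below background.
    """

    seed: int = 0
    motif_min_len: int = 2
    alignment_mode: str = "global"
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    identity_convention: str = "columns"
    floor: float = 0.01

    def __post_init__(self) -> None:
        if self.motif_min_len < 2:
            raise ValueError("motif_min_len must be >= 2")
        if self.alignment_mode not in ("global", "local"):
            raise ValueError("alignment_mode must be 'global' or 'local'")
        if self.identity_convention not in ("columns", "shorter"):
            raise ValueError("identity_convention must be 'columns' or 'shorter'")
        for attr in ("gap_open", "gap_extend", "floor"):
            v = float(getattr(self, attr))
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{attr} must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a YAML file; unknown keys raise."""
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import dataclasses as _dc

        import yaml

        Path(path).write_text(
            yaml.safe_dump(_dc.asdict(self), sort_keys=True)
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and input order is preserved.  An empty file,
    duplicate ids, or characters outside the amino-acid alphabet raise
    :class:`ParseError` naming the offending line where possible.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            try:
                records.append(
                    ProteinRecord(
                        id=rec.id, sequence=str(rec.seq), name=rec.description
                    )
                )
            except ValueError as exc:
                line = _find_bad_line(path, rec.id)
                raise ParseError(f"{path}:{line}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def _find_bad_line(path: Path, record_id: str) -> int:
    """Best-effort line number of the first invalid body line of a record."""
    in_record = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(">"):
            in_record = line[1:].split()[0] == record_id if line[1:] else False
            continue
        if in_record:
            body = set(line.strip().upper())
            if body - AMINO_ACID_ALPHABET:
                return lineno
    return 0


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, 60 columns per line, stable byte output."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.name) for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqrecords, handle, "fasta")


def fasta_bytes(records: Iterable[ProteinRecord]) -> bytes:
    """FASTA serialization as bytes (for checksums and determinism checks)."""
    buf = _io.StringIO()
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description=r.name) for r in records],
        buf,
        "fasta",
    )
    return buf.getvalue().encode()


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def load_labels(
    path: str | Path, records: Iterable[ProteinRecord]
) -> LabeledSequenceSet:
    """Read an ``id<TAB>label`` TSV and validate it against *records*.

    Labels must be one of ``binder``, ``nonbinder``, ``excluded``.  Class
    counts are reported on the log; unknown ids, unknown label tokens and
    degenerate labelings (no binder or no non-binder) raise errors.
    """
    path = Path(path)
    records = list(records)
    labels: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 'id<TAB>label', got {line!r}"
                )
            seq_id, label = parts
            if seq_id == "id" and label == "label":  # optional header
                continue
            labels[seq_id] = label
    sset = LabeledSequenceSet(records=tuple(records), labels=labels)
    logger.info(
        "loaded labels from %s: %d binders, %d nonbinders, %d excluded",
        path,
        len(sset.binders),
        len(sset.nonbinders),
        len(sset.excluded),
    )
    return sset


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("id\tlabel\n")
        for seq_id in labels:
            handle.write(f"{seq_id}\t{labels[seq_id]}\n")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _float_fmt(x) -> object:
    """Round-trip floats through fixed 9-digit formatting for stable bytes."""
    if isinstance(x, float):
        return float(f"{x:.9g}")
    return x


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item") and callable(obj.item) and not isinstance(obj, str):
        try:
            return _float_fmt(obj.item())  # numpy scalars
        except Exception:
            pass
    return _float_fmt(obj)


def write_report(obj, path: str | Path, format: str = "json") -> None:
    """Serialize a pipeline result deterministically.

    ``json`` accepts any dataclass/dict/list composite; ``tsv`` accepts a
    pandas DataFrame; ``newick`` accepts a tree with a ``write`` method
    (branch lengths fixed to 6 decimals via :func:`tree_to_newick`).
    """
    path = Path(path)
    if format == "json":
        text = json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n"
        path.write_text(text)
    elif format == "tsv":
        try:
            obj.to_csv(path, sep="\t", index=True, float_format="%.6f")
        except AttributeError:
            raise ValueError(f"cannot write {type(obj).__name__} as TSV")
    elif format == "newick":
        from .conservation import tree_to_newick

        path.write_text(tree_to_newick(obj) + "\n")
    else:
        raise ValueError(f"unsupported report format {format!r}")
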