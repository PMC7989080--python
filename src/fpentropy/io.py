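"""Reading and writing compound tables and fingerprint matrices.

Matrix files are UTF-8 CSV/TSV, delimiter sniffed from the header line, with a
header row of bit labels, a first column of compound identifiers, and body
cells that are strictly ``"0"`` or ``"1"`` so that a write/read round trip is
bit-exact.

Fingerprint *generation* is delegated to a pluggable backend (any toolkit that
exposes MACCS/PubChem-style bits); the math core never depends on one.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np

from .matrix import CompoundRecord, FingerprintMatrix

__all__ = [
    "read_compound_table",
    "read_class_labels",
    "read_matrix",
    "write_matrix",
    "FingerprintBackend",
    "RDKitBackend",
    "compute_fingerprints",
]


class ParseError(ValueError):
    """A malformed input row; the message names the offending line."""


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_compound_table(
    path: str | Path,
    format: str | None = None,
    smiles_first: bool = True,
) -> list[CompoundRecord]:
    """Read a compound table as a list of :class:`CompoundRecord`.

    ``format`` is ``"smi"`` (whitespace-delimited, one compound per line;
    ``smiles_first`` picks SMILES-first vs id-first column order) or ``"csv"``
    (header must contain ``id`` and ``smiles`` columns; an optional ``class``
    column fills ``class_label``).  When omitted, the format is taken from the
    file suffix.  Duplicate ids are rejected.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() in {".csv", ".tsv"} else "smi"
    if format not in {"smi", "csv"}:
        raise ValueError(f"unknown compound table format: {format!r}")

    records: list[CompoundRecord] = []
    seen: set[str] = set()

    def add(rec: CompoundRecord, lineno: int) -> None:
        if rec.id in seen:
            raise ValueError(f"duplicate compound id {rec.id!r} at line {lineno}")
        seen.add(rec.id)
        records.append(rec)

    text = path.read_text(encoding="utf-8")
    if format == "smi":
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(
                    f"line {lineno}: expected an id and a SMILES field, got {line!r}"
                )
            smiles, cid = (fields[0], fields[1]) if smiles_first else (fields[1], fields[0])
            add(CompoundRecord(id=cid, smiles=smiles), lineno)
    else:
        lines = text.splitlines()
        if not lines:
            raise ParseError("empty file")
        delim = _sniff_delimiter(lines[0])
        reader = csv.DictReader(lines, delimiter=delim)
        cols = {c.lower(): c for c in (reader.fieldnames or [])}
        if "id" not in cols or "smiles" not in cols:
            raise ParseError("CSV header must contain 'id' and 'smiles' columns")
        for lineno, row in enumerate(reader, start=2):
            cid = (row[cols["id"]] or "").strip()
            smi = (row[cols["smiles"]] or "").strip()
            if not cid or not smi:
                raise ParseError(f"line {lineno}: missing id or SMILES")
            label = (row.get(cols.get("class", ""), "") or "").strip() or None
            add(CompoundRecord(id=cid, smiles=smi, class_label=label), lineno)
    return records


def read_class_labels(path: str | Path) -> dict[str, str]:
    """Two-column (id, class) CSV/TSV -> mapping; a header row is optional."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError("empty class-label file")
    delim = _sniff_delimiter(lines[0])
    out: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) < 2:
            raise ParseError(f"line {lineno}: expected two columns")
        if lineno == 1 and parts[0].lower() in {"id", "compound_id"}:
            continue
        out[parts[0]] = parts[1]
    return out


def read_matrix(path: str | Path, scheme_name: str | None = None) -> FingerprintMatrix:
    """Read a fingerprint matrix: header of bit labels, first column of ids.

    Cells must be strictly ``"0"`` or ``"1"``; anything else raises with the
    offending row/column coordinates.  Round-trips bit-exactly with
    :func:`write_matrix`.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError("empty matrix file")
    delim = _sniff_delimiter(lines[0])
    rows = list(csv.reader(lines, delimiter=delim))
    header = rows[0]
    bit_labels = header[1:]
    if not bit_labels:
        raise ParseError("header must list at least one bit label (n >= 1 violated)")
    body = rows[1:]
    if not body:
        raise ValueError("matrix has no compound rows (m >= 1 violated)")
    ids: list[str] = []
    values = np.empty((len(body), len(bit_labels)), dtype=np.int8)
    for r, row in enumerate(body):
        if len(row) != len(bit_labels) + 1:
            raise ParseError(
                f"row {r + 1} ({row[0] if row else '?'!r}): expected "
                f"{len(bit_labels) + 1} fields, got {len(row)}"
            )
        ids.append(row[0])
        for c, cell in enumerate(row[1:]):
            if cell == "0":
                values[r, c] = 0
            elif cell == "1":
                values[r, c] = 1
            else:
                raise ValueError(
                    f"non-binary cell {cell!r} at row {r + 1} "
                    f"(id {row[0]!r}), column {c + 1} ({bit_labels[c]!r})"
                )
    return FingerprintMatrix(values, ids, bit_labels, scheme_name or path.stem)


def write_matrix(M: FingerprintMatrix, path: str | Path, delimiter: str = ",") -> None:
    """Write a matrix in the dialect :func:`read_matrix` reads back bit-exactly."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["id", *M.bit_labels])
        for cid, row in zip(M.compound_ids, M.values):
            w.writerow([cid, *(str(int(v)) for v in row)])


# --------------------------------------------------------------------- backends
class FingerprintBackend(Protocol):
    """Adapter contract for a fingerprint toolkit.

    A backend canonicalizes SMILES and maps a molecule to a fixed-length binary
    vector for each scheme it supports.  ``fingerprint`` returns ``None`` for
    SMILES the toolkit cannot parse.
    """

    def schemes(self) -> dict[str, int]:
        """Supported scheme name -> bit count (e.g. ``{"MACCS": 166}``)."""
        ...

    def canonicalize(self, smiles: str) -> str | None: ...

    def fingerprint(self, smiles: str, scheme: str) -> np.ndarray | None: ...


class RDKitBackend:
    """MACCS-key backend on RDKit.

    RDKit emits 167 MACCS bits with bit 0 unused as a placeholder; that bit is
    dropped so vectors have the canonical 166 bits.
    """

    def __init__(self) -> None:
        from rdkit import Chem  # deferred: chemistry toolkit is optional
        from rdkit.Chem import MACCSkeys

        self._Chem = Chem
        self._MACCSkeys = MACCSkeys

    def schemes(self) -> dict[str, int]:
        return {"MACCS": 166}

    def _mol(self, smiles: str):
        return self._Chem.MolFromSmiles(smiles)

    def canonicalize(self, smiles: str) -> str | None:
        mol = self._mol(smiles)
        return None if mol is None else self._Chem.MolToSmiles(mol)

    def fingerprint(self, smiles: str, scheme: str) -> np.ndarray | None:
        if scheme != "MACCS":
            raise KeyError(f"RDKitBackend does not support scheme {scheme!r}")
        mol = self._mol(smiles)
        if mol is None:
            return None
        bv = self._MACCSkeys.GenMACCSKeys(mol)
        arr = np.zeros(bv.GetNumBits(), dtype=np.int8)
        for b in bv.GetOnBits():
            arr[b] = 1
        return arr[1:]  # bit 0 is a placeholder


@dataclass
class FingerprintFailure:
    id: str
    smiles: str
    reason: str


def compute_fingerprints(
    records: list[CompoundRecord],
    backend: FingerprintBackend,
    scheme: str,
) -> tuple[FingerprintMatrix, list[FingerprintFailure]]:
    """One matrix row per record, in input order; unparseable SMILES are
    collected as :class:`FingerprintFailure` rather than aborting the batch.

    Raises if the backend does not support ``scheme`` or if no record could be
    fingerprinted at all.
    """
    schemes = backend.schemes()
    if scheme not in schemes:
        raise KeyError(
            f"backend does not support scheme {scheme!r}; offers {sorted(schemes)}"
        )
    n_bits = schemes[scheme]
    rows: list[np.ndarray] = []
    ids: list[str] = []
    failures: list[FingerprintFailure] = []
    for rec in records:
        fp = backend.fingerprint(rec.smiles, scheme)
        if fp is None:
            failures.append(FingerprintFailure(rec.id, rec.smiles, "unparseable SMILES"))
            continue
        if fp.shape != (n_bits,):
            raise ValueError(
                f"backend returned {fp.shape[0]} bits for scheme {scheme!r}, "
                f"expected {n_bits}"
            )
        rows.append(fp)
        ids.append(rec.id)
    if not rows:
        raise ValueError("no record could be fingerprinted")
    return FingerprintMatrix(np.vstack(rows), ids, scheme_name=scheme), failures
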