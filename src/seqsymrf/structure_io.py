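"""Sequence and secondary-structure I/O with pluggable folding backends.

Pre-miRNA hairpins are represented by an :class:`RnaRecord` (the sequence)
and a :class:`SecondaryStructure` (dot-bracket string plus minimum free
energy in kcal/mol).  Structures can come from three providers:

* ``precomputed`` — a Vienna-style fold file written by an external tool,
* ``external``    — an RNAfold-compatible executable invoked per record,
* ``fallback``    — a bundled Nussinov maximum base-pairing folder whose
  "mfe" is a pair-count proxy (−1.0 per pair), suitable for tests and
  self-contained runs, not for thermodynamic work.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "RnaRecord",
    "SecondaryStructure",
    "ParseError",
    "StructureValidationError",
    "read_fasta",
    "write_fasta",
    "read_vienna",
    "write_vienna",
    "fold_fallback",
    "external_folder",
    "get_structures",
]

_VALID_BASES = frozenset("ACGU")

#: canonical Watson-Crick pairs plus the GU wobble
CAN_PAIR = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


class StructureValidationError(ValueError):
    """Raised when a dot-bracket string violates the structure invariants."""


def _check_balanced(dotbracket: str) -> None:
    depth = 0
    for ch in dotbracket:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise StructureValidationError(
                    f"unbalanced brackets in {dotbracket!r}: ')' before matching '('"
                )
        elif ch != ".":
            raise StructureValidationError(
                f"illegal structure character {ch!r} in {dotbracket!r}"
            )
    if depth != 0:
        raise StructureValidationError(
            f"unbalanced brackets in {dotbracket!r}: {depth} unmatched '('"
        )


@dataclass(frozen=True)
class RnaRecord:
    """An RNA sequence over {A, C, G, U} with an identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SecondaryStructure:
    """Dot-bracket secondary structure with its minimum free energy (kcal/mol)."""

    dotbracket: str
    mfe: float

    def __post_init__(self) -> None:
        _check_balanced(self.dotbracket)

    @property
    def length(self) -> int:
        return len(self.dotbracket)

    @property
    def n_pairs(self) -> int:
        return self.dotbracket.count("(")


def _clean_sequence(raw: str, line_no: int) -> str:
    """Uppercase, convert T to U, and validate the alphabet."""
    seq = raw.strip().upper().replace("T", "U")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ParseError(
            f"line {line_no}: illegal sequence character(s) {sorted(bad)!r}"
        )
    return seq


def read_fasta(path: str | Path) -> list[RnaRecord]:
    """Read a FASTA file into :class:`RnaRecord` objects.

    T is silently converted to U and lowercase letters are uppercased
    (miRBase files mix both conventions).  Identifiers are taken from the
    header up to the first whitespace.  Parse errors name the offending
    line number.
    """
    path = Path(path)
    records: list[RnaRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        if not chunks:
            raise ParseError(f"line {header_line}: header {header!r} has no sequence")
        records.append(RnaRecord(id=header, sequence="".join(chunks)))

    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ParseError(f"line {line_no}: empty FASTA header")
                header_line = line_no
                chunks = []
            else:
                if header is None:
                    raise ParseError(
                        f"line {line_no}: sequence data before any FASTA header"
                    )
                chunks.append(_clean_sequence(line, line_no))
    _flush()
    return records


def write_fasta(records: Iterable[RnaRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


_STRUCT_RE = re.compile(r"^([().]+)\s+\(\s*(-?\d+(?:\.\d+)?)\s*\)$")


def read_vienna(path: str | Path) -> list[tuple[RnaRecord, SecondaryStructure]]:
    """Read a Vienna-style fold file of 3-line records.

    Each record is ``>id`` / sequence / ``dotbracket (mfe)``.  The structure
    must match the sequence length and have balanced brackets; violations
    raise :class:`StructureValidationError` naming the record id.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.open() if ln.strip()]
    if len(lines) % 3 != 0:
        raise ParseError(
            f"{path}: expected 3-line records (header, sequence, structure); "
            f"got {len(lines)} non-empty lines"
        )
    out: list[tuple[RnaRecord, SecondaryStructure]] = []
    for i in range(0, len(lines), 3):
        header, seq_line, struct_line = lines[i : i + 3]
        if not header.startswith(">"):
            raise ParseError(f"line {3 * (i // 3) + 1}: expected '>' header, got {header!r}")
        rid = header[1:].split()[0]
        seq = _clean_sequence(seq_line, i + 2)
        m = _STRUCT_RE.match(struct_line.strip())
        if m is None:
            raise ParseError(
                f"record {rid!r}: structure line {struct_line!r} does not match "
                f"'dotbracket (mfe)'"
            )
        dotbracket, mfe = m.group(1), float(m.group(2))
        if len(dotbracket) != len(seq):
            raise StructureValidationError(
                f"record {rid!r}: structure length {len(dotbracket)} != "
                f"sequence length {len(seq)}"
            )
        try:
            structure = SecondaryStructure(dotbracket=dotbracket, mfe=mfe)
        except StructureValidationError as exc:
            raise StructureValidationError(f"record {rid!r}: {exc}") from None
        out.append((RnaRecord(id=rid, sequence=seq), structure))
    return out


def write_vienna(
    pairs: Iterable[tuple[RnaRecord, SecondaryStructure]], path: str | Path
) -> None:
    """Write 3-line Vienna fold records; mfe printed to 2 decimals."""
    with Path(path).open("w", newline="\n") as fh:
        for rec, structure in pairs:
            if len(structure.dotbracket) != rec.length:
                raise StructureValidationError(
                    f"record {rec.id!r}: structure/sequence length mismatch"
                )
            fh.write(
                f">{rec.id}\n{rec.sequence}\n"
                f"{structure.dotbracket} ({structure.mfe:.2f})\n"
            )


def fold_fallback(record: RnaRecord, min_loop: int = 3) -> SecondaryStructure:
    """Nussinov maximum base-pairing fold with Watson-Crick + GU wobble pairs.

    Hairpin loops span at least ``min_loop`` unpaired nucleotides.  The
    reported mfe is a pair-count proxy, -1.0 per base pair (0.0 for a
    fully unpaired sequence); it is NOT a thermodynamic energy.
    Traceback ties are broken by pairing the smallest available 5' index
    with its smallest admissible partner, so output is deterministic.
    """
    seq = record.sequence
    n = len(seq)
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if (seq[i], seq[k]) in CAN_PAIR:
                    inner = dp[i + 1][k - 1]
                    right = dp[k + 1][j] if k + 1 <= j else 0
                    if inner + right + 1 > best:
                        best = inner + right + 1
            dp[i][j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i][j] == 0:
            continue
        if dp[i][j] == dp[i + 1][j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) not in CAN_PAIR:
                continue
            inner = dp[i + 1][k - 1]
            right = dp[k + 1][j] if k + 1 <= j else 0
            if inner + right + 1 == dp[i][j]:
                structure[i] = "("
                structure[k] = ")"
                stack.append((i + 1, k - 1))
                if k + 1 <= j:
                    stack.append((k + 1, j))
                break
    dotbracket = "".join(structure)
    n_pairs = dotbracket.count("(")
    return SecondaryStructure(dotbracket=dotbracket, mfe=-1.0 * n_pairs)


# RNAfold prints e.g. "(((....))) ( -2.10)" or "(((....))) (-2.10)"
_RNAFOLD_RE = re.compile(r"^([().]+)\s+\(\s*(-?\d+(?:\.\d+)?)\s*\)")


def external_folder(
    record: RnaRecord, command: Sequence[str] = ("RNAfold", "--noPS")
) -> SecondaryStructure:
    """Fold one record with an external RNAfold-compatible executable.

    The command receives FASTA on stdin and must print the sequence line
    followed by ``dotbracket (mfe)``.  Extra user flags are passed verbatim.
    """
    exe = command[0]
    if shutil.which(exe) is None:
        raise RuntimeError(
            f"external folding tool {exe!r} not found on PATH; supply a "
            f"precomputed Vienna file or use the bundled fallback folder"
        )
    proc = subprocess.run(
        list(command),
        input=f">{record.id}\n{record.sequence}\n",
        capture_output=True,
        text=True,
        check=True,
    )
    for line in proc.stdout.splitlines():
        m = _RNAFOLD_RE.match(line.strip())
        if m:
            dotbracket, mfe = m.group(1), float(m.group(2))
            if len(dotbracket) != record.length:
                raise StructureValidationError(
                    f"record {record.id!r}: external structure length "
                    f"{len(dotbracket)} != sequence length {record.length}"
                )
            return SecondaryStructure(dotbracket=dotbracket, mfe=mfe)
    raise ParseError(
        f"record {record.id!r}: could not parse structure from output of {exe!r}"
    )


def get_structures(
    records: Sequence[RnaRecord],
    backend: str = "precomputed",
    vienna_path: str | Path | None = None,
    command: Sequence[str] = ("RNAfold", "--noPS"),
    min_loop: int = 3,
) -> dict[str, SecondaryStructure]:
    """Resolve a secondary structure for every record via the chosen backend.

    backend ``"precomputed"`` reads ``vienna_path`` (the default; errors if a
    record is missing from the file), ``"external"`` calls
    :func:`external_folder` per record, ``"fallback"`` uses
    :func:`fold_fallback`.
    """
    if backend == "precomputed":
        if vienna_path is None:
            raise ValueError("backend 'precomputed' requires vienna_path")
        folded = {rec.id: s for rec, s in read_vienna(vienna_path)}
        missing = [rec.id for rec in records if rec.id not in folded]
        if missing:
            raise KeyError(
                f"no precomputed structure for record(s) {missing[:5]!r} "
                f"in {vienna_path}"
            )
        return {rec.id: folded[rec.id] for rec in records}
    if backend == "external":
        return {rec.id: external_folder(rec, command) for rec in records}
    if backend == "fallback":
        return {rec.id: fold_fallback(rec, min_loop=min_loop) for rec in records}
    raise ValueError(f"unknown structure backend {backend!r}")
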