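"""Sequence primitives shared by every MORFIN module.

Conventions used throughout the package:

* Coordinates are 0-based and half-open.  Positions *between* bases
  ("bonds") are indexed ``0..L``; bond ``i`` lies immediately after base
  ``i - 1``.  This makes transposase cut-site arithmetic unambiguous.
* Plasmids are circular by default; all interval arithmetic is modulo the
  plasmid length.  Linear records refuse wrap-around operations.
* Translation uses the bacterial/archaeal code (NCBI table 11) with ``*``
  for stop codons.  ``translate`` does no start-codon special-casing.
* Sequences are normalized to uppercase.  ``N`` is tolerated where noted
  (reads, reverse complement); IUPAC ambiguity codes other than ``N`` are
  rejected with :class:`AlphabetError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MorfinError",
    "AlphabetError",
    "ParseError",
    "ConfigurationError",
    "DesignError",
    "TopologyError",
    "ParameterError",
    "revcomp",
    "translate",
    "OrfAnnotation",
    "PlasmidRecord",
    "SangerRead",
    "read_plasmid",
    "write_plasmid",
    "read_fasta_sequences",
    "write_fasta_sequences",
]


class MorfinError(Exception):
    """Base class for all errors raised by this package."""


class AlphabetError(MorfinError, ValueError):
    """A sequence contains characters outside the permitted alphabet."""


class ParseError(MorfinError, ValueError):
    """An input file could not be parsed."""


class ConfigurationError(MorfinError, ValueError):
    """Inputs are individually valid but inconsistent with each other."""


class DesignError(MorfinError, ValueError):
    """An amplicon or primer design precondition was violated."""


class TopologyError(MorfinError, ValueError):
    """An operation requires a topology the record does not have."""


class ParameterError(MorfinError, ValueError):
    """A numeric parameter is outside its valid domain."""


_DNA = frozenset("ACGT")
_DNA_N = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _check_alphabet(seq: str, *, allow_n: bool, context: str = "sequence") -> str:
    up = seq.upper()
    allowed = _DNA_N if allow_n else _DNA
    bad = set(up) - allowed
    if bad:
        raise AlphabetError(
            f"{context} contains non-nucleotide characters: {sorted(bad)!r} "
            f"(allowed: {''.join(sorted(allowed))})"
        )
    return up


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (alphabet A/C/G/T/N).

    Involution: ``revcomp(revcomp(x)) == x``.  Case is normalized to upper.
    """
    up = _check_alphabet(seq, allow_n=True)
    return up.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int = 0) -> str:
    """Translate ``seq`` in the given frame with the bacterial code (table 11).

    Stop codons are rendered as ``"*"``; a trailing partial codon is
    dropped.  Only A/C/G/T are accepted — reads with Ns must be handled
    upstream.
    """
    if frame not in (0, 1, 2):
        raise ParameterError(f"frame must be 0, 1 or 2, got {frame}")
    up = _check_alphabet(seq, allow_n=False)
    coding = up[frame:]
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate(table=11))


@dataclass(frozen=True)
class OrfAnnotation:
    """One annotated open reading frame on a plasmid.

    ``start`` is the 0-based position of the first base of the start codon;
    ``end`` is exclusive, one past the last base of the stop codon.  The
    span may wrap the origin only on circular records.
    """

    label: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParameterError(f"strand must be '+' or '-', got {self.strand!r}")

    def nt_length(self, plasmid_len: int) -> int:
        span = (self.end - self.start) % plasmid_len
        return span if span else plasmid_len

    def codon_count(self, plasmid_len: int) -> int:
        """Total codons including the stop codon."""
        return self.nt_length(plasmid_len) // 3


@dataclass
class PlasmidRecord:
    """A (usually circular) annotated DNA molecule — the transposition target."""

    name: str
    sequence: str
    circular: bool = True
    orfs: list[OrfAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = _check_alphabet(
            self.sequence, allow_n=False, context=f"plasmid {self.name!r}"
        )
        for orf in self.orfs:
            self._validate_orf(orf)

    def _validate_orf(self, orf: OrfAnnotation) -> None:
        L = len(self.sequence)
        if not (0 <= orf.start < L and 0 < orf.end <= L):
            raise ConfigurationError(
                f"ORF {orf.label!r} interval [{orf.start}, {orf.end}) outside [0, {L})"
            )
        if orf.end <= orf.start and not self.circular:
            raise TopologyError(
                f"ORF {orf.label!r} wraps the origin but {self.name!r} is linear"
            )
        n = orf.nt_length(L)
        if n % 3 or n < 6:
            raise ConfigurationError(
                f"ORF {orf.label!r} length {n} nt is not a positive multiple of 3"
            )
        pep = translate(self.orf_sense(orf))
        if not pep.startswith("M"):
            raise ConfigurationError(
                f"ORF {orf.label!r} does not begin with a start codon (got {pep[:1]!r})"
            )
        if not pep.endswith("*") or "*" in pep[:-1]:
            raise ConfigurationError(
                f"ORF {orf.label!r} must have exactly one, terminal, stop codon"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def get_orf(self, label: str) -> OrfAnnotation:
        for orf in self.orfs:
            if orf.label == label:
                return orf
        raise ConfigurationError(
            f"target ORF {label!r} not annotated on plasmid {self.name!r} "
            f"(available: {[o.label for o in self.orfs]})"
        )

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end) with modular wrap-around when circular."""
        L = len(self.sequence)
        if 0 <= start <= end <= L:
            return self.sequence[start:end]
        if not self.circular:
            raise TopologyError(
                f"interval [{start}, {end}) wraps the origin of linear record {self.name!r}"
            )
        start %= L
        span = end - start if end >= start else (end % L) - start + L
        return (self.sequence + self.sequence)[start : start + span]

    def orf_sense(self, orf: OrfAnnotation) -> str:
        """The coding-strand sequence of an ORF, start codon first."""
        raw = self.fetch(orf.start, orf.end if orf.end > orf.start else orf.end + len(self))
        return raw if orf.strand == "+" else revcomp(raw)


@dataclass(frozen=True)
class SangerRead:
    """One Sanger-style read, entering as plain FASTA (no chromatograms)."""

    name: str
    sequence: str
    source: str = "external"  # {simulated, external}

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParameterError(f"read {self.name!r} is empty")
        object.__setattr__(
            self,
            "sequence",
            _check_alphabet(self.sequence, allow_n=True, context=f"read {self.name!r}"),
        )


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

_GENBANK_EXT = {".gb", ".gbk", ".genbank"}


def _orf_label(feature: SeqFeature, index: int) -> str:
    for key in ("label", "gene", "locus_tag", "product"):
        if key in feature.qualifiers:
            return str(feature.qualifiers[key][0])
    return f"CDS_{index}"


def read_plasmid(path: str | Path, sidecar: str | Path | None = None) -> PlasmidRecord:
    """Read a plasmid from GenBank, or FASTA plus a coordinate sidecar.

    GenBank: topology from the LOCUS line, one CDS feature per ORF; only the
    first record of a multi-record file is used.  FASTA: ``sidecar`` must
    point to a key=value file with lines ``orf=LABEL:START-END:STRAND``
    (1-based inclusive coordinates, GenBank convention) and optionally
    ``topology=linear``.
    """
    path = Path(path)
    if path.suffix.lower() in _GENBANK_EXT:
        return _read_genbank(path)
    if sidecar is None:
        candidate = path.with_suffix(path.suffix + ".orfs")
        if candidate.exists():
            sidecar = candidate
        else:
            raise ConfigurationError(
                f"FASTA plasmid {path} needs a coordinate sidecar "
                f"(none given and {candidate} not found)"
            )
    return _read_fasta_sidecar(path, Path(sidecar))


def _read_genbank(path: Path) -> PlasmidRecord:
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError) as exc:
        raise ParseError(f"could not parse GenBank file {path}: {exc}") from exc
    orfs = []
    for i, feat in enumerate(rec for rec in record.features if rec.type == "CDS"):
        strand = "-" if feat.location.strand == -1 else "+"
        orfs.append(
            OrfAnnotation(
                label=_orf_label(feat, i),
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand=strand,
            )
        )
    if not orfs:
        raise ConfigurationError(f"GenBank file {path} contains no CDS annotation")
    circular = record.annotations.get("topology", "circular") == "circular"
    return PlasmidRecord(record.id or path.stem, str(record.seq), circular, orfs)


def _read_fasta_sidecar(path: Path, sidecar: Path) -> PlasmidRecord:
    try:
        record = next(SeqIO.parse(str(path), "fasta"))
    except (StopIteration, ValueError) as exc:
        raise ParseError(f"could not parse FASTA file {path}: {exc}") from exc
    circular = True
    orfs: list[OrfAnnotation] = []
    for lineno, line in enumerate(sidecar.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"{sidecar}:{lineno}: expected key=value, got {line!r}")
        key, value = line.split("=", 1)
        key, value = key.strip(), value.strip()
        if key == "topology":
            circular = value.lower() != "linear"
        elif key == "orf":
            try:
                label, span, strand = value.split(":")
                start_s, end_s = span.split("-")
                orfs.append(
                    OrfAnnotation(label, int(start_s) - 1, int(end_s), strand)
                )
            except (ValueError, ParameterError) as exc:
                raise ParseError(
                    f"{sidecar}:{lineno}: malformed orf entry {value!r} "
                    "(expected LABEL:START-END:STRAND, 1-based inclusive)"
                ) from exc
        else:
            raise ParseError(f"{sidecar}:{lineno}: unknown key {key!r}")
    if not orfs:
        raise ConfigurationError(f"sidecar {sidecar} declares no ORF annotation")
    return PlasmidRecord(record.id or path.stem, str(record.seq), circular, orfs)


def write_plasmid(record: PlasmidRecord, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write a plasmid as GenBank (by extension) or FASTA + sidecar."""
    path = Path(path)
    if path.suffix.lower() in _GENBANK_EXT:
        seqrec = SeqRecord(
            Seq(record.sequence),
            id=record.name[:16] or "plasmid",
            name=record.name[:16] or "plasmid",
            description="",
            annotations={
                "molecule_type": "DNA",
                "topology": "circular" if record.circular else "linear",
            },
        )
        for orf in record.orfs:
            seqrec.features.append(
                SeqFeature(
                    FeatureLocation(orf.start, orf.end, strand=1 if orf.strand == "+" else -1),
                    type="CDS",
                    qualifiers={"label": [orf.label]},
                )
            )
        SeqIO.write([seqrec], str(path), "genbank")
        return
    SeqIO.write(
        [SeqRecord(Seq(record.sequence), id=record.name, description="")], str(path), "fasta"
    )
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(path.suffix + ".orfs")
    lines = [] if record.circular else ["topology=linear"]
    lines += [
        f"orf={o.label}:{o.start + 1}-{o.end}:{o.strand}" for o in record.orfs
    ]
    sidecar.write_text("\n".join(lines) + "\n")


def read_fasta_sequences(path: str | Path) -> list[tuple[str, str]]:
    """All (name, sequence) pairs of a FASTA file, uppercased."""
    out = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not out:
        raise ParseError(f"no FASTA records in {path}")
    return out


def write_fasta_sequences(
    entries: Iterable[tuple[str, str] | tuple[str, str, str]], path: str | Path
) -> None:
    """Write (name, sequence[, description]) tuples as FASTA."""
    records = []
    for entry in entries:
        name, seq = entry[0], entry[1]
        desc = entry[2] if len(entry) > 2 else ""
        records.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(records, str(path), "fasta")
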