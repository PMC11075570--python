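"""Donor amplicon and PCR primer design for Tn5 insertion mutagenesis.

A donor amplicon is a blunt-end PCR product that the Tn5 transposase will
insert into a target plasmid.  Its layout on the coding strand is::

    ME(19) | fp[1:3] | extra5 | fp[3:-3] | readthrough | revcomp(ME)(19)

where ``ME`` is the 19-nt mosaic-end recognition element the transposase
requires as an inverted repeat at both ends, and ``fp`` is the fluorescent
protein ORF (ATG .. stop).  Three frame-preserving edits make the amplicon
a single continuous ORF from its first to its last base:

* the first base of the FP start codon is dropped, so the 19th element
  base completes a tTG (Leu) codon in place of ATG — no internal start;
* the FP stop codon is ablated: for the ``none``/``extra3`` linker
  variants it is replaced by ``TT``, which the first base of the 3'
  element completes to a TTa Leu read-through codon; for ``extra6`` it is
  replaced by ``CAGTCCGA`` (+ element base), read through as Gln-Ser-Glu;
* optional extra linker codons are inserted between the modified start
  codon and the second FP codon.

The resulting non-native junction codons in an eventual in-frame fusion
are 6/9/12 at the 5' side (element codons plus inserted extras) and
9/9/12 at the 3' side (element codons plus the duplicated target triplet)
for the none/extra3/extra6 variants respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .seq_core import (
    DesignError,
    ParseError,
    read_fasta_sequences,
    revcomp,
    translate,
    write_fasta_sequences,
)

__all__ = [
    "ME_ELEMENT",
    "ME_LEN",
    "LinkerOption",
    "DonorAmplicon",
    "design_amplicon",
    "emit_primers",
    "validate_amplicon",
    "ValidationReport",
    "write_amplicon_fasta",
    "read_amplicon_fasta",
    "write_primers_tsv",
]

#: The 19-nt Tn5 mosaic-end recognition element (coding strand, 5' end).
ME_ELEMENT = "CTGTCTCTTATACACATCT"
ME_LEN = len(ME_ELEMENT)

_STOPS = ("TAA", "TAG", "TGA")

# Canonical linker inserts.  5' inserts sit between the modified start codon
# and the second FP codon; the extra6 variant additionally replaces the FP
# stop with an 8-nt segment read through into the 3' element.
_EXTRA5 = {
    "none": "",
    "extra3": "GAGCAATCC",  # E Q S
    "extra6": "CACAAACAGGAGCAATCC",  # H K Q E Q S
}
_READTHROUGH = {
    "none": "TT",  # stop -> TTa (Leu), completed by the 3' element
    "extra3": "TT",
    "extra6": "CAGTCCGA",  # stop -> CAG TCC GAa (Q S E)
}


@dataclass(frozen=True)
class LinkerOption:
    """One of the three linker layouts (no extra / 3 extra / 6 extra codons)."""

    variant: str
    extra5_codons: str = ""
    extra3prime_codons: str = ""

    def __post_init__(self) -> None:
        if self.variant not in _EXTRA5:
            raise DesignError(
                f"unknown linker variant {self.variant!r}; choose from {sorted(_EXTRA5)}"
            )
        if len(self.extra5_codons) not in (0, 9, 18) or len(self.extra5_codons) % 3:
            raise DesignError(
                f"extra5_codons must be 0, 9 or 18 nt, got {len(self.extra5_codons)}"
            )
        for name, seq in (("extra5_codons", self.extra5_codons),
                          ("extra3prime_codons", self.extra3prime_codons)):
            pep = translate(seq) if len(seq) >= 3 else ""
            if "*" in pep:
                raise DesignError(f"{name} contains an in-frame stop codon: {seq}")

    @classmethod
    def from_variant(cls, variant: str) -> "LinkerOption":
        if variant not in _EXTRA5:
            raise DesignError(
                f"unknown linker variant {variant!r}; choose from {sorted(_EXTRA5)}"
            )
        extra3p = _READTHROUGH[variant] if variant == "extra6" else ""
        return cls(variant, _EXTRA5[variant], extra3p)

    @property
    def readthrough(self) -> str:
        return _READTHROUGH[self.variant]


@dataclass
class DonorAmplicon:
    """A designed linear blunt-end donor with ME ends and a start/stop-ablated FP ORF."""

    sequence: str
    fp_name: str
    linker: LinkerOption
    fwd_primer: str = ""
    rev_primer: str = ""
    me_len: int = field(default=ME_LEN, init=False)

    @property
    def extra5(self) -> str:
        return self.linker.extra5_codons

    @property
    def readthrough(self) -> str:
        return self.linker.readthrough

    @property
    def fp_core_start(self) -> int:
        """Offset of the second FP codon (after ME, modified start, extras)."""
        return ME_LEN + 2 + len(self.extra5)

    @property
    def fp_core_end(self) -> int:
        """Offset one past the FP's last sense codon."""
        return len(self.sequence) - ME_LEN - len(self.readthrough)

    @property
    def fp_core(self) -> str:
        """The unmodified FP interior (FP codon 2 .. last sense codon)."""
        return self.sequence[self.fp_core_start : self.fp_core_end]

    @property
    def tail3(self) -> str:
        """Read-through segment plus the 3' element."""
        return self.sequence[self.fp_core_end :]

    @property
    def linker5_codons(self) -> int:
        """Non-native codons 5' of the FP in a fusion: 6 element + extras."""
        return 6 + len(self.extra5) // 3

    @property
    def linker3_codons(self) -> int:
        """Non-native element-encoded codons 3' of the FP (excl. the
        duplicated target triplet).  The TTa read-through codon counts as
        the FP's substituted terminal codon, not linker."""
        if self.readthrough == "TT":
            return 6
        return (len(self.readthrough) + ME_LEN) // 3

    @property
    def linker5_peptide(self) -> str:
        return translate(ME_ELEMENT[:18]) + translate(self.extra5)

    @property
    def linker3_peptide(self) -> str:
        pep = translate(self.tail3)
        return pep[1:] if self.readthrough == "TT" else pep

    def __len__(self) -> int:
        return len(self.sequence)


def _check_fp_orf(fp_orf: str) -> str:
    fp = fp_orf.upper()
    if len(fp) % 3:
        raise DesignError(f"FP ORF length {len(fp)} is not a multiple of 3")
    if len(fp) < 30:
        raise DesignError(f"FP ORF is implausibly short ({len(fp)} nt)")
    if not fp.startswith("ATG"):
        raise DesignError(f"FP ORF must start with ATG, got {fp[:3]}")
    if fp[-3:] not in _STOPS:
        raise DesignError(f"FP ORF must end with a stop codon, got {fp[-3:]}")
    pep = translate(fp)
    if "*" in pep[:-1]:
        at = pep.index("*")
        raise DesignError(f"FP ORF has an internal in-frame stop at codon {at + 1}")
    return fp


def design_amplicon(
    fp_orf: str,
    linker: LinkerOption | str = "none",
    fp_name: str = "FP",
    anneal_fwd: int = 15,
    anneal_rev: int = 15,
) -> DonorAmplicon:
    """Build the donor amplicon (and its primer pair) for an FP ORF.

    ``fp_orf`` must be the full coding sequence, ATG through stop, with no
    internal in-frame stop.  ``anneal_fwd`` counts FP-derived bases in the
    forward primer starting at the modified start codon; ``anneal_rev``
    counts FP sense bases upstream of the ablated stop.
    """
    if isinstance(linker, str):
        linker = LinkerOption.from_variant(linker)
    fp = _check_fp_orf(fp_orf)
    sequence = (
        ME_ELEMENT
        + fp[1:3]
        + linker.extra5_codons
        + fp[3:-3]
        + linker.readthrough
        + revcomp(ME_ELEMENT)
    )
    amplicon = DonorAmplicon(sequence=sequence, fp_name=fp_name, linker=linker)
    pep = translate(sequence)
    if "*" in pep:  # cannot happen for a valid FP ORF; guards the contract
        raise DesignError(
            f"designed amplicon translation contains a stop at codon {pep.index('*') + 1}"
        )
    amplicon.fwd_primer, amplicon.rev_primer = emit_primers(
        amplicon, anneal_len=anneal_fwd, anneal_rev=anneal_rev
    )
    return amplicon


def emit_primers(
    amplicon: DonorAmplicon, anneal_len: int = 15, anneal_rev: int | None = None
) -> tuple[str, str]:
    """The PCR primer pair that produces ``amplicon`` from the native FP ORF.

    Forward primer: first ``19 + len(extra5) + anneal_len`` nt of the
    amplicon (the element tail plus linker insert, annealing on the FP 5'
    end).  Reverse primer: reverse complement of the terminal segment of
    equal construction.  Splicing forward head, FP interior, and
    revcomp(reverse) reconstructs the amplicon exactly.
    """
    if anneal_rev is None:
        anneal_rev = anneal_len
    for name, val in (("anneal_len", anneal_len), ("anneal_rev", anneal_rev)):
        if val < 15:
            raise DesignError(f"{name} must be at least 15 nt, got {val}")
    fp_interior = amplicon.fp_core_end - ME_LEN  # modified start + extras + core
    if anneal_len + len(amplicon.extra5) > fp_interior or anneal_rev > fp_interior:
        raise DesignError(
            f"annealing length exceeds the FP portion of the amplicon ({fp_interior} nt)"
        )
    fwd = amplicon.sequence[: ME_LEN + len(amplicon.extra5) + anneal_len]
    tail = ME_LEN + len(amplicon.readthrough) + anneal_rev
    rev = revcomp(amplicon.sequence[-tail:])
    return fwd, rev


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class ValidationReport:
    checks: tuple[CheckResult, ...]

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[CheckResult]:
        return [c for c in self.checks if not c.passed]


def validate_amplicon(seq: str) -> ValidationReport:
    """Check the structural contract of a donor amplicon sequence.

    Always returns a report; each failed check carries the offending
    position.  Checks: 19-nt element at both ends as an inverted repeat,
    length divisible by 3, and stop-free frame-0 translation.
    """
    seq = seq.upper()
    checks: list[CheckResult] = []

    head_ok = seq.startswith(ME_ELEMENT)
    checks.append(
        CheckResult(
            "me_5prime",
            head_ok,
            "" if head_ok else f"first {ME_LEN} nt are {seq[:ME_LEN]!r}, expected {ME_ELEMENT}",
        )
    )
    tail_ok = seq.endswith(revcomp(ME_ELEMENT))
    checks.append(
        CheckResult(
            "me_3prime_inverted_repeat",
            tail_ok,
            ""
            if tail_ok
            else f"last {ME_LEN} nt are {seq[-ME_LEN:]!r}, expected {revcomp(ME_ELEMENT)}"
            f" (position {max(len(seq) - ME_LEN, 0)})",
        )
    )
    len_ok = len(seq) % 3 == 0
    checks.append(
        CheckResult(
            "length_multiple_of_3",
            len_ok,
            "" if len_ok else f"length {len(seq)} leaves {len(seq) % 3} trailing nt",
        )
    )
    try:
        pep = translate(seq)
        stop_at = pep.find("*")
        stop_ok = stop_at == -1
        detail = "" if stop_ok else f"stop codon at codon {stop_at + 1} (nt {stop_at * 3})"
    except Exception as exc:  # alphabet problems surface as a failed check
        stop_ok, detail = False, str(exc)
    checks.append(CheckResult("stop_free_frame0", stop_ok, detail))
    return ValidationReport(tuple(checks))


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def write_amplicon_fasta(amplicon: DonorAmplicon, path: str | Path) -> None:
    desc = (
        f"fp={amplicon.fp_name} variant={amplicon.linker.variant} "
        f"length={len(amplicon.sequence)}"
    )
    write_fasta_sequences(
        [(f"{amplicon.fp_name}_{amplicon.linker.variant}_amplicon", amplicon.sequence, desc)],
        path,
    )


def read_amplicon_fasta(path: str | Path) -> DonorAmplicon:
    """Reload an amplicon written by :func:`write_amplicon_fasta`.

    The linker variant is recovered from the description line; the ME ends
    are re-validated so a corrupted file fails loudly.
    """
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"), None)
    if record is None:
        raise ParseError(f"no FASTA records in {path}")
    fields = dict(
        item.split("=", 1) for item in record.description.split() if "=" in item
    )
    if "variant" not in fields:
        raise ParseError(
            f"{path}: amplicon FASTA description lacks 'variant=' metadata"
        )
    linker = LinkerOption.from_variant(fields["variant"])
    amplicon = DonorAmplicon(
        sequence=str(record.seq).upper(),
        fp_name=fields.get("fp", record.id),
        linker=linker,
    )
    report = validate_amplicon(amplicon.sequence)
    if not report.ok:
        raise ParseError(
            f"{path}: not a valid donor amplicon: "
            + "; ".join(f"{c.name}: {c.detail}" for c in report.failures())
        )
    return amplicon


def write_primers_tsv(amplicon: DonorAmplicon, path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "name": f"{amplicon.fp_name}_{amplicon.linker.variant}_fwd",
            "sequence": amplicon.fwd_primer,
            "description": f"forward, {amplicon.linker.variant} linker",
        },
        {
            "name": f"{amplicon.fp_name}_{amplicon.linker.variant}_rev",
            "sequence": amplicon.rev_primer,
            "description": f"reverse, {amplicon.linker.variant} linker",
        },
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
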