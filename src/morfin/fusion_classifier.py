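"""Classify transposition events against a target ORF.

An insertion yields a fluorescent colony only if it passes every
sequence-level requirement of the plate screen; the classifier applies the
corresponding ordered rules:

1. the cut and its 9-mer must lie wholly inside the ORF interior (codon 2
   through the last sense codon) — otherwise ``backbone`` (no overlap with
   the ORF) or ``orf_edge`` (overlapping the start/stop codon);
2. the donor ORF strand must match the target strand — else
   ``wrong_orientation``;
3. the cut must fall on a codon boundary — else ``out_of_frame``;
4. the frame-0 translation of the reconstructed fusion ORF must be
   stop-free up to the native stop — else ``out_of_frame``.

Survivors are ``in_frame_candidate``: the fusion reads target codons
1..N+3, the 5' linker, the FP, the 3' linker, the duplicated codons
N+1..N+3 again, and the rest of the target.  Fluorescence itself is not
predicted — expression level and folding are outside the sequence-level
model.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy.stats import binomtest

from .seq_core import ConfigurationError, OrfAnnotation, PlasmidRecord, translate
from .transposition_sim import TSD_LEN, InsertionEvent

__all__ = [
    "CLASSES",
    "FusionReport",
    "classify_event",
    "LibrarySummary",
    "summarize_library",
    "write_fusions_tsv",
    "write_chimeras_fasta",
]

CLASSES = (
    "in_frame_candidate",
    "out_of_frame",
    "wrong_orientation",
    "backbone",
    "orf_edge",
)


@dataclass(frozen=True)
class FusionReport:
    """Classification of one insertion event against one target ORF."""

    event_id: int
    classification: str
    target_label: str
    codon_N: int | None = None
    duplicated_codons: str | None = None
    linker5_peptide: str = ""
    linker3_peptide: str = ""
    chimera: str | None = None

    @property
    def codon_N3(self) -> int | None:
        """Codon N+3 — the last duplicated codon, for site conventions that
        report the insertion after the second duplication copy."""
        return None if self.codon_N is None else self.codon_N + 3


def _interval_overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def classify_event(
    event: InsertionEvent,
    plasmid: PlasmidRecord | None = None,
    target: OrfAnnotation | str | None = None,
) -> FusionReport:
    """Classify one event; see the module docstring for the rule order."""
    plasmid = plasmid if plasmid is not None else event.plasmid
    if plasmid.sequence != event.plasmid.sequence:
        raise ConfigurationError(
            "event was produced against a different plasmid sequence"
        )
    if target is None:
        if not plasmid.orfs:
            raise ConfigurationError(f"plasmid {plasmid.name!r} has no annotated ORF")
        orf = plasmid.orfs[0]
    elif isinstance(target, str):
        orf = plasmid.get_orf(target)
    else:
        orf = target

    L = len(plasmid)
    orf_nt = orf.nt_length(L)
    # shift coordinates so the ORF occupies [0, orf_nt) on the + strand
    d = (event.cut_bond - orf.start) % L
    overlap = _interval_overlap(d, d + TSD_LEN, 0, orf_nt)
    if d + TSD_LEN > L:  # duplication wraps the plasmid origin
        overlap += _interval_overlap(0, d + TSD_LEN - L, 0, orf_nt)

    def report(classification: str, **extra) -> FusionReport:
        return FusionReport(
            event_id=event.event_id,
            classification=classification,
            target_label=orf.label,
            **extra,
        )

    if overlap == 0:
        return report("backbone")
    if not (3 <= d <= orf_nt - TSD_LEN - 3):
        return report("orf_edge")
    if (event.orientation == "forward") != (orf.strand == "+"):
        return report("wrong_orientation")

    # position of the duplication on the ORF sense strand
    q = d if orf.strand == "+" else orf_nt - d - TSD_LEN
    if q % 3:
        return report("out_of_frame")

    sense = plasmid.orf_sense(orf)
    fusion_nt = sense[: q + TSD_LEN] + event.amplicon.sequence + sense[q:]
    pep = translate(fusion_nt)
    if "*" in pep[:-1] or not pep.endswith("*"):
        return report("out_of_frame")

    amp = event.amplicon
    return report(
        "in_frame_candidate",
        codon_N=q // 3,
        duplicated_codons=translate(sense[q : q + TSD_LEN]),
        linker5_peptide=amp.linker5_peptide,
        linker3_peptide=amp.linker3_peptide,
        chimera=pep[:-1],
    )


@dataclass(frozen=True)
class LibrarySummary:
    """Aggregate view of a classified insertion library."""

    n_events: int
    class_counts: dict[str, int] = field(default_factory=dict)
    site_histogram: dict[int, int] = field(default_factory=dict)
    in_frame_fraction: float = 0.0
    ci_low: float = 0.0
    ci_high: float = 0.0

    @property
    def n_in_frame(self) -> int:
        return self.class_counts.get("in_frame_candidate", 0)


def summarize_library(reports: Sequence[FusionReport]) -> LibrarySummary:
    """Per-class counts, per-codon-N recovery histogram, and the in-frame
    fraction with its exact (Clopper-Pearson) 95% binomial interval."""
    if not reports:
        warnings.warn("summarize_library called with no reports", stacklevel=2)
        return LibrarySummary(n_events=0)
    counts = Counter(r.classification for r in reports)
    sites = Counter(
        r.codon_N for r in reports if r.classification == "in_frame_candidate"
    )
    n = len(reports)
    k = counts.get("in_frame_candidate", 0)
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return LibrarySummary(
        n_events=n,
        class_counts=dict(counts),
        site_histogram=dict(sorted(sites.items())),
        in_frame_fraction=k / n,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


def write_fusions_tsv(reports: Sequence[FusionReport], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "event_id": [r.event_id for r in reports],
            "class": [r.classification for r in reports],
            "target": [r.target_label for r in reports],
            "codon_N": [r.codon_N for r in reports],
            "codon_N3": [r.codon_N3 for r in reports],
            "duplicated_codons": [r.duplicated_codons for r in reports],
            "linker5_peptide": [r.linker5_peptide for r in reports],
            "linker3_peptide": [r.linker3_peptide for r in reports],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_chimeras_fasta(reports: Sequence[FusionReport], path: str | Path) -> None:
    from .seq_core import write_fasta_sequences

    entries = [
        (
            f"event{r.event_id}_N{r.codon_N}",
            r.chimera,
            f"target={r.target_label} dup={r.duplicated_codons}",
        )
        for r in reports
        if r.classification == "in_frame_candidate" and r.chimera
    ]
    write_fasta_sequences(entries, path)
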