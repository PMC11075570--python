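"""Insertion-site calling from Sanger reads across the 3' FP/target junction.

The sequencing strategy uses one "universal" primer per FP amplicon: it
anneals about 60 nt upstream of the FP ORF's 3' end and reads across the
read-through codon(s), the 3' mosaic-end element, the duplicated target
codons, and into the flanking target gene.  A single read therefore
confirms (i) that the FP is present, (ii) that the reading frame is intact
at the junction, and (iii) where the insert sits in the target.  Only the
3' junction is assessed — the 5' junction must already be correct for a
colony to fluoresce.

Calling proceeds by locating the 3' element (reverse complement of the
19-nt recognition element, as it appears on the amplicon coding strand) in
the read — exact match first, then a banded Hamming scan — and mapping the
following flank against the target ORF on both strands.  Because the
downstream flank begins at the *duplicated* copy of codons N+1..N+3, a
flank matching the target at codon M implies the insertion sits after
codon N = M - 1.  Repeated target sequence yields status ``ambiguous``;
ambiguity is surfaced, never resolved by a tie-break, because a silent
choice would fabricate a site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .amplicon_designer import ME_ELEMENT, ME_LEN, DonorAmplicon
from .seq_core import (
    DesignError,
    OrfAnnotation,
    PlasmidRecord,
    SangerRead,
    revcomp,
)
from .transposition_sim import TSD_LEN, InsertionEvent

__all__ = [
    "CallerConfig",
    "JunctionCall",
    "design_universal_primer",
    "simulate_read",
    "simulate_reads",
    "call_insertion",
]

STATUSES = (
    "confirmed_in_frame",
    "frame_violation",
    "element_not_found",
    "flank_unmapped",
    "ambiguous",
)


@dataclass(frozen=True)
class CallerConfig:
    """Matching thresholds; declared defaults, configurable not inferred."""

    min_flank: int = 24  # nt of target flank required for a site call
    max_mismatches: int = 2  # per located segment (element, flank)
    primer_offset: int = 60  # nt between primer 3' end and FP core 3' end
    primer_len: int = 20
    read_len: int = 700


@dataclass(frozen=True)
class JunctionCall:
    read_name: str
    status: str
    codon_N: int | None = None
    matched_flank_len: int = 0
    mismatches: int = 0
    orientation: str | None = None  # strand of the target the flank matched
    duplicated_codons: str | None = None


def design_universal_primer(
    amplicon: DonorAmplicon, offset: int = 60, length: int = 20
) -> str:
    """The coding-strand primer ending ``offset`` nt upstream of the FP
    core 3' end, directing sequencing toward the 3' junction."""
    core_len = amplicon.fp_core_end - ME_LEN
    if not 0 <= offset < core_len:
        raise DesignError(
            f"primer offset {offset} outside the FP portion ({core_len} nt)"
        )
    end = amplicon.fp_core_end - offset
    start = end - length
    if start < 0:
        raise DesignError(
            f"primer of length {length} at offset {offset} runs off the amplicon 5' end"
        )
    return amplicon.sequence[start:end]


def _apply_substitutions(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_read(
    event: InsertionEvent,
    config: CallerConfig = CallerConfig(),
    error_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
    name: str | None = None,
) -> SangerRead:
    """Simulate the universal-primer Sanger read for one insertion event.

    The read runs along the donor coding strand of the circular product,
    starting at the primer site, with an optional substitution-only error
    model (no indels, mirroring high-quality Sanger base calls).
    """
    if isinstance(rng, int) or rng is None:
        rng = np.random.default_rng(rng)
    product = event.product
    amp_len = len(event.amplicon)
    if event.orientation == "forward":
        strand = product
        amp_start = event.insert_offset
    else:
        strand = revcomp(product)
        amp_start = len(product) - event.insert_offset - amp_len
    primer_end_in_amp = event.amplicon.fp_core_end - config.primer_offset
    read_start = amp_start + primer_end_in_amp - config.primer_len
    doubled = strand + strand  # the product is circular
    raw = doubled[read_start : read_start + config.read_len]
    seq = _apply_substitutions(raw, error_rate, rng)
    return SangerRead(
        name=name or f"read_event{event.event_id}",
        sequence=seq,
        source="simulated",
    )


def simulate_reads(
    events: Sequence[InsertionEvent],
    config: CallerConfig = CallerConfig(),
    error_rate: float = 0.0,
    seed: int | None = None,
) -> list[SangerRead]:
    rng = np.random.default_rng(seed)
    return [
        simulate_read(ev, config, error_rate, rng, name=f"read_event{ev.event_id}")
        for ev in events
    ]


def _find_approx(haystack: str, needle: str, max_mm: int) -> list[tuple[int, int]]:
    """All (position, mismatches) of ``needle`` in ``haystack`` at minimal
    Hamming distance <= max_mm.  Exact hits short-circuit the scan."""
    exact = []
    start = haystack.find(needle)
    while start != -1:
        exact.append((start, 0))
        start = haystack.find(needle, start + 1)
    if exact or max_mm == 0:
        return exact
    n, m = len(haystack), len(needle)
    if m > n:
        return []
    hay = np.frombuffer(haystack.encode(), dtype="S1")
    ned = np.frombuffer(needle.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(hay, m)
    dists = (windows != ned).sum(axis=1)
    best = int(dists.min())
    if best > max_mm:
        return []
    return [(int(i), best) for i in np.nonzero(dists == best)[0]]


def call_insertion(
    read: SangerRead,
    amplicon: DonorAmplicon,
    plasmid: PlasmidRecord,
    target: OrfAnnotation | str,
    config: CallerConfig = CallerConfig(),
) -> JunctionCall:
    """Call the insertion codon from one junction-spanning read."""
    orf = plasmid.get_orf(target) if isinstance(target, str) else target
    element3 = revcomp(ME_ELEMENT)  # 3' element on the amplicon coding strand
    seq = read.sequence.replace("N", "A")  # Ns count as mismatches downstream

    hits = _find_approx(seq, element3, config.max_mismatches)
    if not hits:
        return JunctionCall(read.name, "element_not_found")
    # the amplicon carries the element once; take the first (5'-most) hit
    elem_pos, _elem_mm = hits[0]
    flank = seq[elem_pos + ME_LEN :]
    if len(flank) < config.min_flank:
        return JunctionCall(read.name, "flank_unmapped")

    sense = plasmid.orf_sense(orf)
    L = len(plasmid)
    orf_nt = len(sense)
    # extend past the stop so flanks from insertions near the ORF 3' end map
    if orf.strand == "+":
        down = plasmid.fetch(orf.end, orf.end + config.min_flank)
    else:
        down = revcomp(plasmid.fetch((orf.start - config.min_flank) % L,
                                     (orf.start - config.min_flank) % L + config.min_flank))
    space_fwd = sense + down
    space_rev = revcomp(space_fwd)

    prefix = flank[: config.min_flank]
    fwd_hits = [h for h in _find_approx(space_fwd, prefix, config.max_mismatches)
                if h[0] < orf_nt]
    rev_hits = [h for h in _find_approx(space_rev, prefix, config.max_mismatches)]
    candidates = [("+", p, mm) for p, mm in fwd_hits] + [("-", p, mm) for p, mm in rev_hits]
    if not candidates:
        return JunctionCall(read.name, "flank_unmapped")
    best_mm = min(mm for _, _, mm in candidates)
    candidates = [c for c in candidates if c[2] == best_mm]
    if len(candidates) > 1:
        return JunctionCall(read.name, "ambiguous", mismatches=best_mm)

    strand_rel, p, mm = candidates[0]
    # extend the match greedily beyond the prefix for reporting
    space = space_fwd if strand_rel == "+" else space_rev
    matched = config.min_flank
    while (
        matched < len(flank)
        and p + matched < len(space)
        and flank[matched] == space[p + matched]
    ):
        matched += 1

    if strand_rel == "-":
        # flank maps to the opposite strand of the target: the donor was
        # inserted against the target's sense — never an in-frame fusion
        return JunctionCall(
            read.name, "frame_violation", matched_flank_len=matched,
            mismatches=mm, orientation="-",
        )
    if p % 3 or p < 3 or p + TSD_LEN > orf_nt - 3:
        return JunctionCall(
            read.name, "frame_violation", matched_flank_len=matched,
            mismatches=mm, orientation="+",
        )
    codon_N = p // 3  # flank starts at the duplicated copy of codon N+1
    from .seq_core import translate

    return JunctionCall(
        read_name=read.name,
        status="confirmed_in_frame",
        codon_N=codon_N,
        matched_flank_len=matched,
        mismatches=mm,
        orientation="+",
        duplicated_codons=translate(sense[p : p + TSD_LEN]),
    )
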